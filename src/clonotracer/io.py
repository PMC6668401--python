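"""Readers and writers for the formats the pipeline consumes and emits.

Supported representations of a cells x variants genotype dataset:

* a multi-sample VCF in which each sample column is one cell barcode
  (GT required; DP/GQ optional, recorded as 0 when absent), read via cyvcf2
  and written via pysam;
* a trio of CSV matrices (genotype 0/1/2/NA, depth, quality) with a
  companion panel TSV, which round-trips bit-exactly.

The panel TSV has columns ``chrom, pos, ref, alt, gene, hgvs_label,
category`` with category in {common, pathogenic, ado_control}.
"""

from __future__ import annotations

import logging
import os
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .core import (
    MISSING,
    FormatError,
    GenotypeMatrix,
    PanelOverlapError,
    PanelVariant,
    check_panel,
)

log = logging.getLogger(__name__)

PANEL_COLUMNS = ["chrom", "pos", "ref", "alt", "gene", "hgvs_label", "category"]


# ---------------------------------------------------------------------------
# panel TSV
# ---------------------------------------------------------------------------

def read_panel(path: str | os.PathLike) -> list[PanelVariant]:
    try:
        df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    except Exception as exc:  # pragma: no cover - pandas error text varies
        raise FormatError(f"cannot read panel file {path}: {exc}") from exc
    missing_cols = set(PANEL_COLUMNS) - set(df.columns)
    if missing_cols:
        raise FormatError(f"panel file {path} lacks columns {sorted(missing_cols)}")
    variants = [
        PanelVariant(
            chrom=row.chrom,
            pos=int(row.pos),
            ref=row.ref,
            alt=row.alt,
            gene=row.gene,
            hgvs_label=row.hgvs_label,
            category=row.category,
        )
        for row in df.itertuples()
    ]
    check_panel(variants)
    return variants


def write_panel(variants: Sequence[PanelVariant], path: str | os.PathLike) -> None:
    df = pd.DataFrame(
        [
            {
                "chrom": v.chrom,
                "pos": v.pos,
                "ref": v.ref,
                "alt": v.alt,
                "gene": v.gene,
                "hgvs_label": v.hgvs_label,
                "category": v.category,
            }
            for v in variants
        ],
        columns=PANEL_COLUMNS,
    )
    df.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------

def read_vcf_to_matrix(
    path: str | os.PathLike,
    panel: Sequence[PanelVariant],
    sample_id: str = "",
    timepoint: str = "",
) -> GenotypeMatrix:
    """Read a multi-sample (one column per cell barcode) VCF into a matrix.

    GT is mapped 0/0 -> WT, 0/1 or 1/0 -> HET, 1/1 -> HOM; any call containing
    a ``.`` becomes MISSING.  Phased separators are treated like unphased.
    Records not in the panel are skipped with a warning; for multi-allelic
    records only the first ALT is considered.  Columns follow panel order,
    restricted to panel variants actually present in the file.
    """
    import cyvcf2

    check_panel(panel)
    try:
        vcf = cyvcf2.VCF(str(path))
    except Exception as exc:
        raise FormatError(f"cannot open VCF {path}: {exc}") from exc

    cells = list(vcf.samples)
    key_to_col = {v.key: i for i, v in enumerate(panel)}
    found: dict[int, tuple[np.ndarray, np.ndarray, np.ndarray]] = {}

    try:
        for rec in vcf:
            alts = rec.ALT
            if not alts:
                log.warning("record %s:%s has no ALT; skipped", rec.CHROM, rec.POS)
                continue
            if len(alts) > 1:
                log.warning(
                    "multi-allelic record %s:%s: only first ALT %s considered",
                    rec.CHROM, rec.POS, alts[0],
                )
            key = (rec.CHROM, rec.POS, rec.REF, alts[0])
            col = key_to_col.get(key)
            if col is None:
                log.warning(
                    "variant %s:%s:%s>%s not in panel; skipped",
                    rec.CHROM, rec.POS, rec.REF, alts[0],
                )
                continue
            # allele pairs, -1 for '.'; any half-missing call becomes MISSING,
            # and alleles beyond the first ALT are not representable
            alleles = np.asarray(rec.genotypes, dtype=np.int16)[:, :2]
            codes = alleles.sum(axis=1).astype(np.int8)
            codes[(alleles < 0).any(axis=1)] = MISSING
            beyond = (alleles > 1).any(axis=1)
            if beyond.any():
                log.warning(
                    "calls with >1st ALT allele at %s:%s set MISSING",
                    rec.CHROM, rec.POS,
                )
                codes[beyond] = MISSING
            dp = rec.format("DP")
            if dp is None:
                depth = np.zeros(len(cells), dtype=np.int32)
            else:
                depth = np.asarray(dp, dtype=np.float64).reshape(len(cells), -1)[:, 0]
                depth = np.where(np.isfinite(depth) & (depth >= 0), depth, 0)
                depth = depth.astype(np.int32)
            gq = rec.format("GQ")
            if gq is None:
                qual = np.zeros(len(cells), dtype=np.int32)
            else:
                qual = np.asarray(gq, dtype=np.float64).reshape(len(cells), -1)[:, 0]
                qual = np.where(np.isfinite(qual) & (qual >= 0), qual, 0)
                qual = qual.astype(np.int32)
            found[col] = (codes, depth, qual)
    except FormatError:
        raise
    except Exception as exc:
        raise FormatError(f"defective VCF {path}: {exc}") from exc

    if not found and panel and _vcf_has_records(path):
        raise PanelOverlapError(
            f"no variant in {path} overlaps the {len(panel)}-variant panel"
        )
    cols = sorted(found)
    variants = [panel[c] for c in cols]
    n = len(cells)
    geno = np.full((n, len(cols)), MISSING, dtype=np.int8)
    depth = np.zeros((n, len(cols)), dtype=np.int32)
    qual = np.zeros((n, len(cols)), dtype=np.int32)
    for j, c in enumerate(cols):
        geno[:, j], depth[:, j], qual[:, j] = found[c]
    return GenotypeMatrix(
        cell_ids=cells,
        variants=variants,
        genotypes=geno,
        depth=depth,
        quality=qual,
        sample_id=sample_id,
        timepoint=timepoint,
    )


def _vcf_has_records(path: str | os.PathLike) -> bool:
    with open(path, "rt") as fh:
        for line in fh:
            if line and not line.startswith("#"):
                return True
    return False


_CODE_TO_GT = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}


def write_vcf(matrix: GenotypeMatrix, path: str | os.PathLike) -> None:
    """Write a matrix as an uncompressed multi-sample VCF (GT:DP:GQ)."""
    import pysam

    header = pysam.VariantHeader()
    for chrom in dict.fromkeys(v.chrom for v in matrix.variants):
        header.contigs.add(chrom)
    header.formats.add("GT", 1, "String", "Genotype")
    header.formats.add("DP", 1, "Integer", "Read depth")
    header.formats.add("GQ", 1, "Integer", "Genotype quality")
    for cell in matrix.cell_ids:
        header.add_sample(cell)

    code_to_alleles = {0: (0, 0), 1: (0, 1), 2: (1, 1), MISSING: (None, None)}
    with pysam.VariantFile(str(path), "w", header=header) as out:
        for j, v in enumerate(matrix.variants):
            rec = out.new_record(
                contig=v.chrom, start=v.pos - 1, alleles=(v.ref, v.alt)
            )
            for i, cell in enumerate(matrix.cell_ids):
                smp = rec.samples[cell]
                smp["GT"] = code_to_alleles[int(matrix.genotypes[i, j])]
                smp["DP"] = int(matrix.depth[i, j])
                smp["GQ"] = int(matrix.quality[i, j])
            out.write(rec)


# ---------------------------------------------------------------------------
# CSV matrices
# ---------------------------------------------------------------------------

GENOTYPE_CSV = "genotypes.csv"
DEPTH_CSV = "depth.csv"
QUALITY_CSV = "quality.csv"
PANEL_TSV = "panel.tsv"
METADATA_JSON = "metadata.json"


def write_matrix_csv(matrix: GenotypeMatrix, out_dir: str | os.PathLike) -> dict[str, Path]:
    """Emit genotype/depth/quality CSVs plus a panel TSV into ``out_dir``.

    Column order is panel order; row order is input cell order; MISSING
    genotype calls are written as ``NA``.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cols = matrix.variant_ids
    geno = pd.DataFrame(
        matrix.genotypes.astype(object), index=matrix.cell_ids, columns=cols
    )
    geno = geno.mask(geno == MISSING, "NA")
    depth = pd.DataFrame(matrix.depth, index=matrix.cell_ids, columns=cols)
    qual = pd.DataFrame(matrix.quality, index=matrix.cell_ids, columns=cols)
    paths = {
        "genotypes": out / GENOTYPE_CSV,
        "depth": out / DEPTH_CSV,
        "quality": out / QUALITY_CSV,
        "panel": out / PANEL_TSV,
        "metadata": out / METADATA_JSON,
    }
    geno.to_csv(paths["genotypes"], index_label="cell_id")
    depth.to_csv(paths["depth"], index_label="cell_id")
    qual.to_csv(paths["quality"], index_label="cell_id")
    write_panel(matrix.variants, paths["panel"])
    import json

    paths["metadata"].write_text(json.dumps(
        {"sample_id": matrix.sample_id, "timepoint": matrix.timepoint},
        sort_keys=True) + "\n")
    return paths


def read_matrix_csv(
    genotype_csv: str | os.PathLike,
    depth_csv: str | os.PathLike,
    quality_csv: str | os.PathLike,
    panel: str | os.PathLike | Sequence[PanelVariant],
    sample_id: str = "",
    timepoint: str = "",
) -> GenotypeMatrix:
    """Inverse of :func:`write_matrix_csv`; round-trips bit-exactly."""
    if isinstance(panel, (str, os.PathLike)):
        variants = read_panel(panel)
    else:
        variants = list(panel)
    geno = pd.read_csv(genotype_csv, index_col="cell_id", keep_default_na=False)
    depth = pd.read_csv(depth_csv, index_col="cell_id")
    qual = pd.read_csv(quality_csv, index_col="cell_id")
    for name, df in (("depth", depth), ("quality", qual)):
        if list(df.index) != list(geno.index) or list(df.columns) != list(geno.columns):
            raise FormatError(
                f"{name} CSV headers do not match the genotype CSV headers"
            )
    panel_ids = [v.id for v in variants]
    unknown = [c for c in geno.columns if c not in set(panel_ids)]
    if unknown:
        raise FormatError(f"genotype CSV columns not in panel: {unknown}")
    ordered = [vid for vid in panel_ids if vid in set(geno.columns)]
    variant_objs = [variants[panel_ids.index(vid)] for vid in ordered]
    geno = geno[ordered]
    depth = depth[ordered]
    qual = qual[ordered]
    raw_codes = geno.astype(str).to_numpy()
    codes = np.where(raw_codes == "NA", "-1", raw_codes)
    try:
        codes = codes.astype(np.float64)
    except ValueError as exc:
        raise FormatError(f"genotype CSV values must be 0/1/2/NA: {exc}") from exc
    if not np.all(np.isin(codes, [-1, 0, 1, 2])):
        raise FormatError("genotype CSV values must be 0/1/2/NA")
    return GenotypeMatrix(
        cell_ids=[str(c) for c in geno.index],
        variants=variant_objs,
        genotypes=codes.astype(np.int8),
        depth=depth.to_numpy(dtype=np.int64),
        quality=qual.to_numpy(dtype=np.int64),
        sample_id=sample_id,
        timepoint=timepoint,
    )


def read_matrix_dir(
    dir_path: str | os.PathLike, sample_id: str = "", timepoint: str = ""
) -> GenotypeMatrix:
    """Read the file set produced by :func:`write_matrix_csv` from one directory."""
    import json

    d = Path(dir_path)
    meta_path = d / METADATA_JSON
    if meta_path.is_file() and not (sample_id or timepoint):
        meta = json.loads(meta_path.read_text())
        sample_id = meta.get("sample_id", "")
        timepoint = meta.get("timepoint", "")
    return read_matrix_csv(
        d / GENOTYPE_CSV,
        d / DEPTH_CSV,
        d / QUALITY_CSV,
        d / PANEL_TSV,
        sample_id=sample_id,
        timepoint=timepoint,
    )
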