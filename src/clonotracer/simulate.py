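"""Synthetic droplet single-cell genotype experiments with known truth.

The generator emulates a longitudinal bone-marrow-transplant study design:
2-3 timepoints (pre-BMT, post-BMT, relapse), a few thousand cells per
sample, a targeted panel of ~19 common germline SNVs (a subset of which
differ between donor and recipient and therefore discriminate cell origin),
1-4 pathogenic variants defining recipient-derived clones, and >=3
allele-dropout control amplicons that are heterozygous in every cell by
design.

Noise model, applied in this order to each cell's germline-plus-clone
genotype:

1. allele dropout (ADO): each HET call is corrupted with probability
   ``ado_rate``, falling to WT or HOM with equal probability (symmetric
   allele loss);
2. missing data: each call is independently replaced by MISSING with
   probability ``missing_rate`` (amplicon/call failure);
3. read depth drawn from a negative binomial (default mean 80,
   dispersion 5), independent of genotype, and a genotype-quality score
   (default constant 60, optionally a two-point mixture straddling the
   QC threshold).

Defaults mirror the study conditions the pipeline is meant to analyse:
cells per timepoint in the 1,500-4,700 range, ADO in the 5-12% band
(default 8%), donor fractions 0/48.3%/27.3%, and an oncogenic clone whose
whole-population frequency runs 9% -> 42% -> 70%.  The oncogenic clone
carries its pathogenic variants in HOM state (mutant-allele-only cells, as
observed for relapse TP53 clones).

Every random draw flows from a single integer seed through
``numpy.random.SeedSequence``, so identical config implies byte-identical
outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .core import ConfigError, GenotypeMatrix, MISSING, PanelVariant
from . import io as _io

DONOR = "donor"
RECIPIENT = "recipient"
DONOR_CLONE = "donor"

_PATHOGENIC_GENES = ["TP53", "SF3B1", "PTPN11", "DNMT3A", "FLT3", "NPM1"]
_COMMON_GENES = [
    "IDH1", "IDH2", "KRAS", "NRAS", "JAK2", "KIT", "CEBPA", "RUNX1", "ASXL1",
    "TET2", "WT1", "EZH2", "GATA2", "U2AF1", "SRSF2", "CBL", "KMT2A", "BRAF",
    "CSF3R", "SETBP1", "MPL", "CALR", "ETV6", "PHF6", "RAD21", "SMC1A",
]
_BASES = ["A", "C", "G", "T"]


@dataclass
class CloneSpec:
    """One recipient-derived clone.

    ``frequencies`` are per-timepoint frequencies *within the
    recipient-derived population* (they sum to 1 over clones at each
    timepoint).  ``pathogenic_genotypes`` maps pathogenic-locus index
    (0-based within the pathogenic variants of the panel) to a genotype code
    (1=HET, 2=HOM); unlisted pathogenic loci stay WT.
    """

    frequencies: tuple[float, ...]
    pathogenic_genotypes: dict[int, int] = field(default_factory=dict)


def patient1_like_clone_table(
    onc_population_freqs: Sequence[float] = (0.09, 0.42, 0.70),
    donor_fractions: Sequence[float] = (0.0, 0.483, 0.273),
    pathogenic_genotypes: Mapping[int, int] | None = None,
) -> dict[str, CloneSpec]:
    """Two recipient clones (founder-WT plus an expanding oncogenic clone)
    whose *whole-population* oncogenic frequencies hit the given targets once
    donor cells are mixed in at the given fractions."""
    if pathogenic_genotypes is None:
        pathogenic_genotypes = {0: 2, 1: 2}
    onc_rec = []
    for f_pop, f_donor in zip(onc_population_freqs, donor_fractions):
        recip = 1.0 - f_donor
        if recip <= 0:
            raise ConfigError("donor fraction 1.0 leaves no recipient cells to carry clones")
        r = f_pop / recip
        if not 0.0 <= r <= 1.0:
            raise ConfigError(
                f"population clone frequency {f_pop} infeasible at donor fraction {f_donor}"
            )
        onc_rec.append(r)
    return {
        "founder_wt": CloneSpec(frequencies=tuple(1.0 - r for r in onc_rec)),
        "oncogenic": CloneSpec(
            frequencies=tuple(onc_rec),
            pathogenic_genotypes=dict(pathogenic_genotypes),
        ),
    }


@dataclass
class SimulationConfig:
    """Study design and noise parameters for one simulated experiment."""

    timepoints: tuple[str, ...] = ("pre_bmt", "post_bmt", "relapse")
    n_cells_per_timepoint: tuple[int, ...] = (1500, 3000, 4700)
    donor_fraction_per_timepoint: tuple[float, ...] = (0.0, 0.483, 0.273)
    n_common_snvs: int = 19
    n_discriminative: int = 13
    n_pathogenic: int = 2
    n_ado_controls: int = 4
    clone_table: dict[str, CloneSpec] = field(default_factory=patient1_like_clone_table)
    ado_rate: float = 0.08
    missing_rate: float = 0.02
    depth_mean: float = 80.0
    depth_dispersion: float = 5.0
    quality_high: int = 60
    quality_low: int = 20
    quality_low_fraction: float = 0.0
    germline_probs: tuple[float, float, float] = (0.5, 0.35, 0.15)
    donor_pathogenic_genotypes: dict[int, int] = field(default_factory=dict)
    doublet_rate: float = 0.0
    seed: int = 0

    def validate(self) -> None:
        nt = len(self.timepoints)
        if nt < 1:
            raise ConfigError("at least one timepoint required")
        if len(self.n_cells_per_timepoint) != nt:
            raise ConfigError("n_cells_per_timepoint length mismatch")
        if len(self.donor_fraction_per_timepoint) != nt:
            raise ConfigError("donor_fraction_per_timepoint length mismatch")
        if any(n < 1 for n in self.n_cells_per_timepoint):
            raise ConfigError("cell counts must be positive")
        if any(not 0.0 <= f <= 1.0 for f in self.donor_fraction_per_timepoint):
            raise ConfigError("donor fractions must lie in [0, 1]")
        if self.n_discriminative > self.n_common_snvs:
            raise ConfigError(
                f"n_discriminative={self.n_discriminative} exceeds "
                f"n_common_snvs={self.n_common_snvs}"
            )
        if self.n_ado_controls < 3:
            raise ConfigError("at least 3 ADO control loci are required")
        for rate_name in ("ado_rate", "missing_rate", "doublet_rate"):
            r = getattr(self, rate_name)
            if not 0.0 <= r <= 1.0:
                raise ConfigError(f"{rate_name}={r} outside [0, 1]")
        if not self.clone_table:
            raise ConfigError("clone_table must define at least one recipient clone")
        for name, spec in self.clone_table.items():
            if len(spec.frequencies) != nt:
                raise ConfigError(f"clone {name!r} frequency trajectory length mismatch")
            for locus, code in spec.pathogenic_genotypes.items():
                if not 0 <= locus < self.n_pathogenic:
                    raise ConfigError(f"clone {name!r} references pathogenic locus {locus}")
                if code not in (1, 2):
                    raise ConfigError(f"clone {name!r} pathogenic genotype must be HET/HOM")
        for t in range(nt):
            tot = sum(spec.frequencies[t] for spec in self.clone_table.values())
            if abs(tot - 1.0) > 1e-9:
                raise ConfigError(
                    f"clone frequencies at timepoint {self.timepoints[t]!r} sum to {tot}"
                )
        if abs(sum(self.germline_probs) - 1.0) > 1e-9:
            raise ConfigError("germline_probs must sum to 1")
        if self.depth_mean <= 0 or self.depth_dispersion <= 0:
            raise ConfigError("depth model parameters must be positive")

    # -- (de)serialisation for the config echo -------------------------------

    def to_dict(self) -> dict:
        d = asdict(self)
        d["clone_table"] = {
            name: {
                "frequencies": list(spec.frequencies),
                "pathogenic_genotypes": {int(k): int(v) for k, v in
                                         spec.pathogenic_genotypes.items()},
            }
            for name, spec in self.clone_table.items()
        }
        for key in ("timepoints", "n_cells_per_timepoint",
                    "donor_fraction_per_timepoint", "germline_probs"):
            d[key] = list(d[key])
        return d

    @classmethod
    def from_dict(cls, d: Mapping) -> "SimulationConfig":
        d = dict(d)
        d["clone_table"] = {
            name: CloneSpec(
                frequencies=tuple(spec["frequencies"]),
                pathogenic_genotypes={int(k): int(v) for k, v in
                                      spec.get("pathogenic_genotypes", {}).items()},
            )
            for name, spec in d.get("clone_table", {}).items()
        }
        for key in ("timepoints", "n_cells_per_timepoint",
                    "donor_fraction_per_timepoint", "germline_probs"):
            if key in d:
                d[key] = tuple(d[key])
        if "donor_pathogenic_genotypes" in d:
            d["donor_pathogenic_genotypes"] = {
                int(k): int(v) for k, v in d["donor_pathogenic_genotypes"].items()
            }
        return cls(**d)


@dataclass
class SimulationTruth:
    """Ground truth of a simulated experiment.

    ``cells`` has one row per simulated cell (cell_id, timepoint, origin,
    clone).  Realized per-timepoint fractions are always recomputed from the
    per-cell labels, so they are exact by construction.
    """

    cells: pd.DataFrame
    panel: list[PanelVariant]
    donor_profile: np.ndarray
    recipient_profile: np.ndarray
    discriminative_ids: list[str]
    clone_signatures: dict[str, np.ndarray]
    ado_rate: float
    clean_genotypes: dict[str, np.ndarray]

    def origin_fractions(self, timepoint: str) -> dict[str, float]:
        sub = self.cells[self.cells.timepoint == timepoint]
        if len(sub) == 0:
            raise KeyError(f"no cells at timepoint {timepoint!r}")
        frac = sub.origin.value_counts(normalize=True).to_dict()
        return {DONOR: frac.get(DONOR, 0.0), RECIPIENT: frac.get(RECIPIENT, 0.0)}

    def clone_fractions(self, timepoint: str) -> dict[str, float]:
        """Whole-population clone fractions (donor cells count as one clone)."""
        sub = self.cells[self.cells.timepoint == timepoint]
        if len(sub) == 0:
            raise KeyError(f"no cells at timepoint {timepoint!r}")
        return sub.clone.value_counts(normalize=True).to_dict()

    def labels_for(self, cell_ids: Sequence[str], column: str) -> np.ndarray:
        lut = self.cells.set_index("cell_id")[column]
        return lut.loc[list(cell_ids)].to_numpy()


# ---------------------------------------------------------------------------
# building blocks
# ---------------------------------------------------------------------------

def make_panel(config: SimulationConfig) -> list[PanelVariant]:
    """Deterministic amplicon panel: common SNVs, pathogenic variants, then
    ADO-control loci (panel order is fixed by the config alone)."""
    variants: list[PanelVariant] = []
    for i in range(config.n_common_snvs):
        ref = _BASES[i % 4]
        alt = _BASES[(i + 1) % 4]
        gene = _COMMON_GENES[i % len(_COMMON_GENES)]
        variants.append(PanelVariant(
            chrom=f"chr{(i % 22) + 1}", pos=1_000_000 + 1_000 * i, ref=ref, alt=alt,
            gene=gene, hgvs_label=f"{gene} common_{i}", category="common",
        ))
    for i in range(config.n_pathogenic):
        ref = _BASES[(i + 2) % 4]
        alt = _BASES[(i + 3) % 4]
        gene = _PATHOGENIC_GENES[i % len(_PATHOGENIC_GENES)]
        variants.append(PanelVariant(
            chrom=f"chr{(i % 22) + 1}", pos=5_000_000 + 1_000 * i, ref=ref, alt=alt,
            gene=gene, hgvs_label=f"{gene} pathogenic_{i}", category="pathogenic",
        ))
    for i in range(config.n_ado_controls):
        ref = _BASES[i % 4]
        alt = _BASES[(i + 2) % 4]
        variants.append(PanelVariant(
            chrom=f"chr{(i % 22) + 1}", pos=9_000_000 + 1_000 * i, ref=ref, alt=alt,
            gene="", hgvs_label=f"ADO_ctrl_{i}", category="ado_control",
        ))
    return variants


def apply_ado(matrix: GenotypeMatrix, rate: float, seed: int) -> GenotypeMatrix:
    """Corrupt HET calls by symmetric allele dropout.

    Each HET call independently becomes WT or HOM with total probability
    ``rate``, split 50/50 between losing the alternate and losing the
    reference allele.  WT/HOM/MISSING calls are untouched.
    """
    if not 0.0 <= rate <= 1.0:
        raise ConfigError(f"ado rate {rate} outside [0, 1]")
    rng = np.random.default_rng(seed)
    out = matrix.copy()
    het = out.genotypes == 1
    n_het = int(het.sum())
    if n_het == 0 or rate == 0.0:
        return out
    u = rng.random(n_het)
    direction = rng.random(n_het) < 0.5
    corrupted = u < rate
    new_vals = np.where(direction, 0, 2).astype(np.int8)
    values = out.genotypes[het]
    values[corrupted] = new_vals[corrupted]
    out.genotypes[het] = values
    return out


def _sample_depth(rng: np.random.Generator, shape, mean: float, dispersion: float) -> np.ndarray:
    p = dispersion / (dispersion + mean)
    return rng.negative_binomial(dispersion, p, size=shape).astype(np.int32)


# ---------------------------------------------------------------------------
# main entry point
# ---------------------------------------------------------------------------

def simulate_experiment(
    config: SimulationConfig,
) -> tuple[list[GenotypeMatrix], SimulationTruth]:
    """Simulate a multi-timepoint single-cell genotype experiment.

    Returns one :class:`GenotypeMatrix` per timepoint plus the
    :class:`SimulationTruth` needed for recovery testing.  Fully
    deterministic for a fixed config (including its seed).
    """
    config.validate()
    panel = make_panel(config)
    n_common = config.n_common_snvs
    n_path = config.n_pathogenic
    p = len(panel)
    path_offset = n_common
    ctrl_offset = n_common + n_path

    ss = np.random.SeedSequence(config.seed)
    seeds = ss.spawn(2 + 4 * len(config.timepoints))
    rng_germ = np.random.default_rng(seeds[0])

    # germline profiles over the full panel
    recipient = np.empty(p, dtype=np.int8)
    recipient[:n_common] = rng_germ.choice(
        3, size=n_common, p=np.asarray(config.germline_probs)
    )
    recipient[path_offset:ctrl_offset] = 0          # pathogenic loci WT in germline
    recipient[ctrl_offset:] = 1                     # controls HET by design
    donor = recipient.copy()
    disc_idx = np.sort(rng_germ.choice(n_common, size=config.n_discriminative,
                                       replace=False))
    probs = np.asarray(config.germline_probs, dtype=float)
    for i in disc_idx:
        others = [g for g in (0, 1, 2) if g != recipient[i]]
        w = probs[others] / probs[others].sum()
        donor[i] = rng_germ.choice(others, p=w)
    for locus, code in config.donor_pathogenic_genotypes.items():
        donor[path_offset + locus] = code

    clone_names = list(config.clone_table)
    clone_signatures: dict[str, np.ndarray] = {DONOR_CLONE: donor.copy()}
    for name in clone_names:
        sig = recipient.copy()
        for locus, code in config.clone_table[name].pathogenic_genotypes.items():
            sig[path_offset + locus] = code
        clone_signatures[name] = sig

    matrices: list[GenotypeMatrix] = []
    rows: list[dict] = []
    clean: dict[str, np.ndarray] = {}

    for t, tp in enumerate(config.timepoints):
        n = config.n_cells_per_timepoint[t]
        rng_cells = np.random.default_rng(seeds[2 + 4 * t])
        is_donor = rng_cells.random(n) < config.donor_fraction_per_timepoint[t]
        freqs = np.array([config.clone_table[c].frequencies[t] for c in clone_names])
        clone_draw = rng_cells.choice(len(clone_names), size=n, p=freqs)
        cell_ids = [f"{tp}_c{i:05d}" for i in range(n)]

        geno = np.empty((n, p), dtype=np.int8)
        clones = []
        for i in range(n):
            if is_donor[i]:
                clones.append(DONOR_CLONE)
                geno[i] = donor
            else:
                cname = clone_names[clone_draw[i]]
                clones.append(cname)
                geno[i] = clone_signatures[cname]
        origins = np.where(is_donor, DONOR, RECIPIENT)

        if config.doublet_rate > 0:
            rng_dbl = np.random.default_rng(seeds[2 + 4 * t + 3])
            dbl = rng_dbl.random(n) < config.doublet_rate
            partners = rng_dbl.integers(0, n, size=n)
            for i in np.flatnonzero(dbl):
                geno[i] = np.maximum(geno[i], geno[partners[i]])

        clean[tp] = geno.copy()

        base = GenotypeMatrix(
            cell_ids=cell_ids, variants=panel, genotypes=geno,
            depth=np.zeros((n, p), dtype=np.int32),
            quality=np.zeros((n, p), dtype=np.int32),
            sample_id=tp, timepoint=tp,
        )
        ado_seed = int(np.random.default_rng(seeds[2 + 4 * t + 1]).integers(2**31))
        mat = apply_ado(base, config.ado_rate, ado_seed)

        rng_noise = np.random.default_rng(seeds[2 + 4 * t + 2])
        if config.missing_rate > 0:
            miss = rng_noise.random((n, p)) < config.missing_rate
            mat.genotypes[miss] = MISSING
        else:
            rng_noise.random((n, p))  # keep stream alignment across configs
        mat.depth = _sample_depth(rng_noise, (n, p), config.depth_mean,
                                  config.depth_dispersion)
        qual = np.full((n, p), config.quality_high, dtype=np.int32)
        if config.quality_low_fraction > 0:
            low = rng_noise.random((n, p)) < config.quality_low_fraction
            qual[low] = config.quality_low
        mat.quality = qual
        matrices.append(mat)

        for cid, orig, cl in zip(cell_ids, origins, clones):
            rows.append({"cell_id": cid, "timepoint": tp, "origin": orig, "clone": cl})

    cells = pd.DataFrame(rows, columns=["cell_id", "timepoint", "origin", "clone"])
    disc_ids = [panel[i].id for i in disc_idx if donor[i] != recipient[i]]
    truth = SimulationTruth(
        cells=cells, panel=panel, donor_profile=donor,
        recipient_profile=recipient, discriminative_ids=disc_ids,
        clone_signatures=clone_signatures, ado_rate=config.ado_rate,
        clean_genotypes=clean,
    )
    return matrices, truth


# ---------------------------------------------------------------------------
# file output
# ---------------------------------------------------------------------------

def write_simulation(
    matrices: Sequence[GenotypeMatrix],
    truth: SimulationTruth,
    out_dir: str | Path,
    config: SimulationConfig | None = None,
    include_vcf: bool = False,
) -> dict[str, Path]:
    """Write per-timepoint matrix CSVs (optionally VCFs), the truth TSV and a
    config echo, so the full pipeline can run from files alone."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    for mat in matrices:
        tp_dir = out / mat.timepoint
        _io.write_matrix_csv(mat, tp_dir)
        paths[mat.timepoint] = tp_dir
        if include_vcf:
            _io.write_vcf(mat, tp_dir / "cells.vcf")
    truth_path = out / "truth.tsv"
    truth.cells.to_csv(truth_path, sep="\t", index=False)
    paths["truth"] = truth_path
    panel_path = out / "panel.tsv"
    _io.write_panel(list(matrices[0].variants) if matrices else truth.panel, panel_path)
    paths["panel"] = panel_path
    if config is not None:
        cfg_path = out / "config.yaml"
        with open(cfg_path, "w") as fh:
            yaml.safe_dump(config.to_dict(), fh, sort_keys=True)
        paths["config"] = cfg_path
    return paths
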