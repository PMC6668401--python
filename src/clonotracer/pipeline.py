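"""End-to-end orchestration: load -> QC/ADO -> chimerism -> clones ->
evolution -> VAF/zygosity, from a single YAML config, with deterministic
outputs for a fixed config+seed.

Stage order follows the analysis narrative of a longitudinal transplant
study: quality control and allele-dropout measurement first, then
donor/recipient demultiplexing (when at least two timepoints exist, the
first timepoint taken as the pre-transplant, recipient-pure sample), clone
calling per timepoint, clone matching and oncogenic-expansion flagging,
and finally pseudo-bulk VAF plus zygosity diagnostics for the pathogenic
panel variants.

All reports are plain JSON/TSV with sorted keys and fixed row order, so
identical config+seed yields byte-identical report files; wall-clock
timings live only in the run manifest.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .core import ClonotracerError, ConfigError, GenotypeMatrix, NoChimerismError
from . import io as _io
from .qc import QCConfig, apply_qc, estimate_ado
from .chimerism import (
    ChimerismResult,
    OriginProfiles,
    compute_chimerism,
    infer_origin_profiles,
    longitudinal_chimerism,
)
from .clonal import (
    cluster_cells,
    flag_expanding_oncogenic_clones,
    heatmap_frame,
    match_clones,
)
from .vaf import (
    bulk_concordance_table,
    pseudobulk_vaf,
    zygosity_report,
)
from .embedding import concat_matrices, export_embedding

log = logging.getLogger(__name__)


class PipelineError(ClonotracerError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class TimepointInput:
    label: str
    matrix_dir: str | None = None
    vcf: str | None = None

    def validate(self) -> None:
        if (self.matrix_dir is None) == (self.vcf is None):
            raise ConfigError(
                f"timepoint {self.label!r}: provide exactly one of matrix_dir/vcf"
            )


@dataclass
class PipelineConfig:
    panel: str
    timepoints: list[TimepointInput]
    output_dir: str
    bulk_vaf: str | None = None
    qc: QCConfig = field(default_factory=QCConfig)
    clone_k: list[int | None] | None = None
    linkage_method: str = "complete"
    match_threshold: float = 0.2
    min_increase: float = 0.02
    embedding_enabled: bool = False
    perplexity: float = 30.0
    seed: int = 0
    log_level: str = "INFO"

    def validate(self) -> None:
        if not self.timepoints:
            raise ConfigError("at least one timepoint input is required")
        for tp in self.timepoints:
            tp.validate()
        if not Path(self.panel).is_file():
            raise ConfigError(f"panel file not found: {self.panel}")
        for tp in self.timepoints:
            path = tp.matrix_dir or tp.vcf
            if not Path(path).exists():
                raise ConfigError(f"timepoint {tp.label!r} input not found: {path}")
        if self.bulk_vaf is not None and not Path(self.bulk_vaf).is_file():
            raise ConfigError(f"bulk VAF file not found: {self.bulk_vaf}")
        if self.clone_k is not None and len(self.clone_k) != len(self.timepoints):
            raise ConfigError("clone_k must list one entry (or null) per timepoint")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        return cls.from_dict(raw, base_dir=Path(path).parent)

    @classmethod
    def from_dict(cls, raw: dict, base_dir: Path | None = None) -> "PipelineConfig":
        def resolve(p):
            if p is None:
                return None
            p = Path(p)
            if base_dir is not None and not p.is_absolute():
                p = base_dir / p
            return str(p)

        tps = [
            TimepointInput(
                label=t["label"],
                matrix_dir=resolve(t.get("matrix_dir")),
                vcf=resolve(t.get("vcf")),
            )
            for t in raw["timepoints"]
        ]
        qc = QCConfig(**raw.get("qc", {}))
        clones = raw.get("clones", {})
        emb = raw.get("embedding", {})
        return cls(
            panel=resolve(raw["panel"]),
            timepoints=tps,
            output_dir=resolve(raw["output_dir"]),
            bulk_vaf=resolve(raw.get("bulk_vaf")),
            qc=qc,
            clone_k=clones.get("k"),
            linkage_method=clones.get("linkage", "complete"),
            match_threshold=float(clones.get("match_threshold", 0.2)),
            min_increase=float(clones.get("min_increase", 0.02)),
            embedding_enabled=bool(emb.get("enabled", False)),
            perplexity=float(emb.get("perplexity", 30.0)),
            seed=int(raw.get("seed", 0)),
            log_level=raw.get("log_level", "INFO"),
        )

    def echo(self) -> dict:
        return {
            "panel": self.panel,
            "timepoints": [
                {"label": t.label, "matrix_dir": t.matrix_dir, "vcf": t.vcf}
                for t in self.timepoints
            ],
            "output_dir": self.output_dir,
            "bulk_vaf": self.bulk_vaf,
            "qc": {
                "min_variant_quality": self.qc.min_variant_quality,
                "min_depth": self.qc.min_depth,
                "max_cell_missing_fraction": self.qc.max_cell_missing_fraction,
                "max_variant_missing_fraction": self.qc.max_variant_missing_fraction,
            },
            "clones": {
                "k": self.clone_k,
                "linkage": self.linkage_method,
                "match_threshold": self.match_threshold,
                "min_increase": self.min_increase,
            },
            "embedding": {"enabled": self.embedding_enabled,
                          "perplexity": self.perplexity},
            "seed": self.seed,
        }


@dataclass
class RunManifest:
    config: dict
    version: str
    stages: dict[str, dict] = field(default_factory=dict)
    outputs: list[str] = field(default_factory=list)
    status: str = "ok"
    failed_stage: str | None = None

    def to_dict(self) -> dict:
        return {
            "config": self.config, "version": self.version,
            "stages": self.stages, "outputs": sorted(self.outputs),
            "status": self.status, "failed_stage": self.failed_stage,
        }


def _write_json(obj, path: Path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True)
        fh.write("\n")


def _read_bulk_vafs(path: str) -> dict[str, dict[str, float | None]]:
    """Bulk VAF TSV (variant, timepoint, vaf with 'undetected' allowed) ->
    {timepoint: {variant_id: vaf or None}}."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    out: dict[str, dict[str, float | None]] = {}
    for row in df.itertuples():
        vaf = None if row.vaf.lower() == "undetected" else float(row.vaf)
        out.setdefault(row.timepoint, {})[row.variant] = vaf
    return out


def run_pipeline(config: PipelineConfig) -> RunManifest:
    """Execute the full analysis; writes all reports under
    ``config.output_dir`` and returns the run manifest."""
    config.validate()
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(config=config.echo(), version=__version__)
    stage = "setup"

    def finish_stage(name: str, t0: float, **counts) -> None:
        manifest.stages[name] = {"wall_clock_s": round(time.monotonic() - t0, 3),
                                 **counts}

    def emit(path: Path) -> Path:
        manifest.outputs.append(str(path.relative_to(out)))
        return path

    try:
        # ---- load ----------------------------------------------------------
        stage = "load"
        t0 = time.monotonic()
        panel = _io.read_panel(config.panel)
        raw: list[GenotypeMatrix] = []
        for tp in config.timepoints:
            if tp.matrix_dir is not None:
                mat = _io.read_matrix_dir(tp.matrix_dir, sample_id=tp.label,
                                          timepoint=tp.label)
            else:
                mat = _io.read_vcf_to_matrix(tp.vcf, panel, sample_id=tp.label,
                                             timepoint=tp.label)
            raw.append(mat)
        finish_stage("load", t0, cells=[m.n_cells for m in raw],
                     variants=[m.n_variants for m in raw])

        # ---- QC + ADO ------------------------------------------------------
        stage = "qc"
        t0 = time.monotonic()
        mats: list[GenotypeMatrix] = []
        qc_summary = {}
        ado_summary = {}
        for mat in raw:
            filtered, report = apply_qc(mat, config.qc)
            mats.append(filtered)
            qc_summary[mat.timepoint] = report.to_dict()
            ado_summary[mat.timepoint] = estimate_ado(filtered).to_dict()
        _write_json(qc_summary, emit(out / "qc_report.json"))
        _write_json(ado_summary, emit(out / "ado.json"))
        finish_stage("qc", t0, cells=[m.n_cells for m in mats],
                     variants=[m.n_variants for m in mats])

        # ---- chimerism -----------------------------------------------------
        origins_by_tp: dict[str, np.ndarray] = {}
        profiles: OriginProfiles | None = None
        if len(mats) >= 2:
            stage = "chimerism"
            t0 = time.monotonic()
            try:
                profiles = infer_origin_profiles(
                    mats[0], mats[1], linkage_method=config.linkage_method,
                )
            except NoChimerismError as exc:
                log.warning("chimerism skipped: %s", exc)
                _write_json({"skipped": str(exc)}, emit(out / "chimerism.json"))
                finish_stage("chimerism", t0, skipped=True)
            else:
                profiles.to_frame().to_csv(
                    emit(out / "origin_profiles.tsv"), sep="\t", index=False
                )
                results: list[ChimerismResult] = []
                for mat in mats:
                    res = compute_chimerism(mat, profiles)
                    origins_by_tp[mat.timepoint] = res.labels
                    results.append(res)
                _write_json({r.timepoint: r.to_dict() for r in results},
                            emit(out / "chimerism.json"))
                longitudinal_chimerism(results).to_csv(
                    emit(out / "chimerism_by_timepoint.tsv"), sep="\t", index=False
                )
                finish_stage("chimerism", t0,
                             discriminative_loci=len(profiles.discriminative_loci))

        # ---- clone calling -------------------------------------------------
        stage = "clones"
        t0 = time.monotonic()
        clone_sets = []
        for i, mat in enumerate(mats):
            k = config.clone_k[i] if config.clone_k else None
            cs = cluster_cells(mat, k=k, linkage_method=config.linkage_method)
            clone_sets.append(cs)
            assign = pd.DataFrame({"cell_id": cs.cell_ids, "clone": cs.labels})
            if mat.timepoint in origins_by_tp:
                assign["origin"] = origins_by_tp[mat.timepoint]
            assign.to_csv(emit(out / f"clones_{mat.timepoint}.tsv"),
                          sep="\t", index=False)
            heatmap_frame(mat, cs,
                          origins=origins_by_tp.get(mat.timepoint)).to_csv(
                emit(out / f"heatmap_{mat.timepoint}.tsv"), sep="\t")
        finish_stage("clones", t0,
                     n_clones=[cs.n_clones for cs in clone_sets])

        # ---- clone matching & flagging -------------------------------------
        flagged: list[str] = []
        if len(clone_sets) >= 2:
            stage = "evolution"
            t0 = time.monotonic()
            table = match_clones(clone_sets, threshold=config.match_threshold)
            table.frequencies.to_csv(emit(out / "evolution.tsv"), sep="\t",
                                     index_label="lineage")
            flagged, annotation = flag_expanding_oncogenic_clones(
                table, panel, min_increase=config.min_increase
            )
            _write_json(
                {"flagged": flagged, "annotation": annotation,
                 "pathogenic": {k: bool(v) for k, v in table.pathogenic.items()}},
                emit(out / "oncogenic_flags.json"),
            )
            finish_stage("evolution", t0, lineages=len(table.lineages),
                         flagged=len(flagged))

        # ---- VAF & zygosity ------------------------------------------------
        stage = "vaf"
        t0 = time.monotonic()
        bulk = _read_bulk_vafs(config.bulk_vaf) if config.bulk_vaf else None
        vaf_rows = []
        zygosity = {}
        for mat in mats:
            path_idx = mat.category_indices("pathogenic")
            ado_rate = estimate_ado(mat).mean_rate
            for j in path_idx:
                rec = pseudobulk_vaf(mat, mat.variants[j])
                if bulk is not None:
                    rec.bulk_vaf = bulk.get(mat.timepoint, {}).get(rec.variant.id)
                vaf_rows.append(rec)
                rep = zygosity_report(mat, mat.variants[j], ado_rate)
                if not rep.empty:
                    zygosity[f"{mat.timepoint}:{rep.variant.id}"] = rep.to_dict()
        pd.DataFrame([r.to_dict() for r in vaf_rows]).to_csv(
            emit(out / "vaf.tsv"), sep="\t", index=False
        )
        if bulk is not None:
            by_tp = []
            for mat in mats:
                recs = [r for r in vaf_rows if r.timepoint == mat.timepoint]
                tp_bulk = bulk.get(mat.timepoint, {})
                if recs and tp_bulk:
                    by_tp.append(bulk_concordance_table(recs, tp_bulk))
            if by_tp:
                pd.concat(by_tp, ignore_index=True).to_csv(
                    emit(out / "bulk_concordance.tsv"), sep="\t", index=False
                )
        _write_json(zygosity, emit(out / "zygosity.json"))
        finish_stage("vaf", t0, n_records=len(vaf_rows))

        # ---- embedding (optional) ------------------------------------------
        if config.embedding_enabled:
            stage = "embedding"
            t0 = time.monotonic()
            combined = concat_matrices(mats) if len(mats) > 1 else mats[0]
            ann = {"timepoint": np.concatenate([
                np.repeat(m.timepoint, m.n_cells) for m in mats
            ])}
            if origins_by_tp:
                ann["origin"] = np.concatenate([
                    origins_by_tp.get(m.timepoint,
                                      np.repeat("", m.n_cells)) for m in mats
                ])
            coords = export_embedding(combined, labels=ann, seed=config.seed,
                                      perplexity=config.perplexity)
            coords.to_csv(emit(out / "embedding.tsv"), sep="\t")
            finish_stage("embedding", t0, cells=combined.n_cells)

    except Exception as exc:
        manifest.status = "FAILED"
        manifest.failed_stage = stage
        _write_json(manifest.to_dict(), out / "manifest.json")
        if isinstance(exc, ClonotracerError):
            raise PipelineError(stage, exc) from exc
        raise PipelineError(stage, exc) from exc

    _write_json(manifest.to_dict(), out / "manifest.json")
    return manifest
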