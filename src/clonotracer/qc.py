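"""Call-, variant- and cell-level quality control plus allele-dropout estimation.

Filter conventions (read literally from the platform's filter set):

* a call passes when depth >= ``min_depth`` (default 10) AND quality >=
  ``min_variant_quality`` (default 30); failing calls are masked to MISSING
  but keep their raw depth/quality for diagnostics;
* variants whose missing fraction exceeds ``max_variant_missing_fraction``
  (default 1.0, i.e. off) are removed;
* cells with *more than* ``max_cell_missing_fraction`` (default 7.5%)
  missing data across all retained variants are removed (strict inequality:
  exactly 7.5% is kept).

The fixed order is mask calls -> filter variants -> filter cells, because
the cell rule is defined over the called variant set.

The ADO rate is estimated from control amplicons that are heterozygous in
every cell by design: per control locus, rate = (# cells with a WT or HOM
call) / (# cells with any call); MISSING calls are excluded from both
numerator and denominator (a no-call is not evidence of allele dropout).
The mean over >=3 control loci is the reported rate.  ADO is a QC metric
only; it never rewrites genotypes downstream.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin

from .core import GenotypeMatrix, MISSING, QCError

log = logging.getLogger(__name__)


@dataclass
class QCConfig:
    min_variant_quality: float = 30.0
    min_depth: int = 10
    max_cell_missing_fraction: float = 0.075
    max_variant_missing_fraction: float = 1.0

    def __post_init__(self) -> None:
        if self.min_depth < 0 or self.min_variant_quality < 0:
            raise ValueError("QC thresholds must be non-negative")
        for f in (self.max_cell_missing_fraction, self.max_variant_missing_fraction):
            if not 0.0 <= f <= 1.0:
                raise ValueError("missing-fraction thresholds must lie in [0, 1]")


@dataclass
class QCReport:
    cells_in: int
    cells_out: int
    variants_in: int
    variants_out: int
    calls_masked_low_depth: int = 0
    calls_masked_low_quality: int = 0
    cell_missing_fraction: dict[str, float] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "cells_in": self.cells_in,
            "cells_out": self.cells_out,
            "variants_in": self.variants_in,
            "variants_out": self.variants_out,
            "calls_masked_low_depth": self.calls_masked_low_depth,
            "calls_masked_low_quality": self.calls_masked_low_quality,
            "cell_missing_fraction": dict(self.cell_missing_fraction),
        }


@dataclass
class ADOEstimate:
    per_locus_rate: dict[str, float]
    mean_rate: float
    n_loci: int
    n_cells_used: int

    def to_dict(self) -> dict:
        return {
            "per_locus_rate": dict(self.per_locus_rate),
            "mean_rate": self.mean_rate,
            "n_loci": self.n_loci,
            "n_cells_used": self.n_cells_used,
        }


def mask_low_confidence_calls(
    matrix: GenotypeMatrix, config: QCConfig | None = None
) -> tuple[GenotypeMatrix, QCReport]:
    """Mask calls below the depth/quality thresholds to MISSING (inclusive
    thresholds: depth 10 passes at min_depth 10)."""
    config = config or QCConfig()
    out = matrix.copy()
    called = out.genotypes != MISSING
    low_depth = called & (out.depth < config.min_depth)
    low_quality = called & (out.quality < config.min_variant_quality)
    out.genotypes[low_depth | low_quality] = MISSING
    report = QCReport(
        cells_in=matrix.n_cells, cells_out=out.n_cells,
        variants_in=matrix.n_variants, variants_out=out.n_variants,
        calls_masked_low_depth=int(low_depth.sum()),
        calls_masked_low_quality=int(low_quality.sum()),
        cell_missing_fraction=dict(zip(out.cell_ids, out.missing_fraction_per_cell())),
    )
    return out, report


def filter_variants(
    matrix: GenotypeMatrix, config: QCConfig | None = None
) -> tuple[GenotypeMatrix, QCReport]:
    """Drop variants whose missing fraction exceeds the threshold (panel
    order preserved)."""
    config = config or QCConfig()
    frac = matrix.missing_fraction_per_variant()
    keep = frac <= config.max_variant_missing_fraction
    if matrix.n_variants and not keep.any():
        raise QCError("no variants survive the missing-fraction filter")
    out = matrix.subset_variants(np.flatnonzero(keep))
    report = QCReport(
        cells_in=matrix.n_cells, cells_out=out.n_cells,
        variants_in=matrix.n_variants, variants_out=out.n_variants,
        cell_missing_fraction=dict(zip(out.cell_ids, out.missing_fraction_per_cell())),
    )
    return out, report


def filter_cells(
    matrix: GenotypeMatrix, config: QCConfig | None = None
) -> tuple[GenotypeMatrix, QCReport]:
    """Drop cells with strictly more than the allowed missing fraction
    (surviving cell order preserved)."""
    config = config or QCConfig()
    frac = matrix.missing_fraction_per_cell()
    keep = frac <= config.max_cell_missing_fraction
    if matrix.n_cells and not keep.any():
        raise QCError("no cells survive QC")
    out = matrix.subset_cells(np.flatnonzero(keep))
    report = QCReport(
        cells_in=matrix.n_cells, cells_out=out.n_cells,
        variants_in=matrix.n_variants, variants_out=out.n_variants,
        cell_missing_fraction=dict(zip(matrix.cell_ids, frac)),
    )
    return out, report


def apply_qc(
    matrix: GenotypeMatrix, config: QCConfig | None = None
) -> tuple[GenotypeMatrix, QCReport]:
    """Mask low-confidence calls, then filter variants, then filter cells."""
    config = config or QCConfig()
    masked, r1 = mask_low_confidence_calls(matrix, config)
    vfilt, _ = filter_variants(masked, config)
    out, r3 = filter_cells(vfilt, config)
    report = QCReport(
        cells_in=matrix.n_cells, cells_out=out.n_cells,
        variants_in=matrix.n_variants, variants_out=out.n_variants,
        calls_masked_low_depth=r1.calls_masked_low_depth,
        calls_masked_low_quality=r1.calls_masked_low_quality,
        cell_missing_fraction=r3.cell_missing_fraction,
    )
    return out, report


def estimate_ado(matrix: GenotypeMatrix, min_loci: int = 3) -> ADOEstimate:
    """Estimate the allele-dropout rate from ado_control loci.

    Raises :class:`QCError` when fewer than ``min_loci`` informative control
    loci are available.
    """
    ctrl = matrix.category_indices("ado_control")
    if len(ctrl) < min_loci:
        raise QCError(
            f"ADO estimation requires at least {min_loci} control loci; "
            f"panel has {len(ctrl)}"
        )
    per_locus: dict[str, float] = {}
    used_cells = 0
    for j in ctrl:
        calls = matrix.genotypes[:, j]
        called = calls != MISSING
        n_called = int(called.sum())
        if n_called == 0:
            log.warning(
                "control locus %s has no called cells; excluded from ADO",
                matrix.variants[j].id,
            )
            continue
        non_het = int((calls[called] != 1).sum())
        per_locus[matrix.variants[j].id] = non_het / n_called
        used_cells = max(used_cells, n_called)
    if len(per_locus) < min_loci:
        raise QCError(
            f"only {len(per_locus)} control loci have called cells; "
            f"at least {min_loci} required"
        )
    mean_rate = float(np.mean(list(per_locus.values())))
    return ADOEstimate(
        per_locus_rate=per_locus, mean_rate=mean_rate,
        n_loci=len(per_locus), n_cells_used=used_cells,
    )


class GenotypeQC(TransformerMixin, BaseEstimator):
    """Sklearn-style transformer applying the full QC chain to a matrix.

    ``transform`` returns the filtered :class:`GenotypeMatrix`; the report of
    the last transform is available as ``report_``.
    """

    def __init__(self, min_variant_quality: float = 30.0, min_depth: int = 10,
                 max_cell_missing_fraction: float = 0.075,
                 max_variant_missing_fraction: float = 1.0):
        self.min_variant_quality = min_variant_quality
        self.min_depth = min_depth
        self.max_cell_missing_fraction = max_cell_missing_fraction
        self.max_variant_missing_fraction = max_variant_missing_fraction

    def _config(self) -> QCConfig:
        return QCConfig(
            min_variant_quality=self.min_variant_quality,
            min_depth=self.min_depth,
            max_cell_missing_fraction=self.max_cell_missing_fraction,
            max_variant_missing_fraction=self.max_variant_missing_fraction,
        )

    def fit(self, X: GenotypeMatrix, y=None) -> "GenotypeQC":
        if not isinstance(X, GenotypeMatrix):
            raise TypeError("GenotypeQC operates on GenotypeMatrix inputs")
        self._config()  # validates parameters
        self.n_features_in_ = X.n_variants
        return self

    def transform(self, X: GenotypeMatrix) -> GenotypeMatrix:
        out, report = apply_qc(X, self._config())
        self.report_ = report
        return out


class ADORateEstimator(BaseEstimator):
    """Sklearn-style estimator for the control-amplicon allele-dropout rate.

    After ``fit``, exposes ``mean_rate_``, ``per_locus_rate_`` and
    ``n_loci_``.
    """

    def __init__(self, min_loci: int = 3):
        self.min_loci = min_loci

    def fit(self, X: GenotypeMatrix, y=None) -> "ADORateEstimator":
        est = estimate_ado(X, min_loci=self.min_loci)
        self.estimate_ = est
        self.per_locus_rate_ = est.per_locus_rate
        self.mean_rate_ = est.mean_rate
        self.n_loci_ = est.n_loci
        return self
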