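"""Pseudo-bulk variant allele frequencies and zygosity diagnostics.

Pseudo-bulk VAF aggregates the allele counts implied by per-cell diploid
genotype calls:

    VAF = (n_het + 2 * n_hom) / (2 * (n_wt + n_het + n_hom))

MISSING cells are excluded from the denominator.  This is comparable to a
bulk-sequencing VAF over the same cell population.

The clonal-fraction rule converts a bulk VAF into a clone-frequency
estimate: under the heterozygosity assumption the clone frequency is twice
the VAF (capped at 1); for a homozygous variant it equals the VAF.

The zygosity diagnostic asks whether an observed excess of homozygous
mutant calls can be explained by allele dropout alone: under symmetric ADO
at rate r, a truly heterozygous cell appears HOM with probability r/2, so
among cells still called mutant P(HOM | mutant) = (r/2) / (1 - r/2); the
binomial tail of the observed HOM count under that rate is reported.  The
read-depth comparison between mutant- and wild-type-called cells (two-sided
Wilcoxon rank-sum) checks that apparent zygosity structure is not a
coverage artifact.  The report surfaces the three candidate explanations —
true homozygosity, loss of heterozygosity, or unbalanced dropout — without
adjudicating between them.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .core import GenotypeMatrix, MISSING, PanelVariant
from .qc import ADOEstimate


@dataclass
class VafRecord:
    variant: PanelVariant
    n_wt: int
    n_het: int
    n_hom: int
    n_missing: int
    pseudo_bulk_vaf: float | None
    timepoint: str = ""
    bulk_vaf: float | None = None

    @property
    def n_called(self) -> int:
        return self.n_wt + self.n_het + self.n_hom

    @property
    def undefined(self) -> bool:
        return self.pseudo_bulk_vaf is None

    def to_dict(self) -> dict:
        return {
            "variant": self.variant.id,
            "gene": self.variant.gene,
            "timepoint": self.timepoint,
            "n_wt": self.n_wt,
            "n_het": self.n_het,
            "n_hom": self.n_hom,
            "n_missing": self.n_missing,
            "pseudo_bulk_vaf": self.pseudo_bulk_vaf,
            "bulk_vaf": self.bulk_vaf,
        }


def pseudobulk_vaf(matrix: GenotypeMatrix, variant: PanelVariant | str) -> VafRecord:
    """Aggregate per-cell genotype calls at one variant into a pseudo-bulk
    VAF; flagged undefined (not an error) when no cell has a call."""
    j = matrix.variant_index(variant)
    calls = matrix.genotypes[:, j]
    n_wt = int((calls == 0).sum())
    n_het = int((calls == 1).sum())
    n_hom = int((calls == 2).sum())
    n_missing = int((calls == MISSING).sum())
    called = n_wt + n_het + n_hom
    vaf = (n_het + 2 * n_hom) / (2 * called) if called else None
    return VafRecord(
        variant=matrix.variants[j], n_wt=n_wt, n_het=n_het, n_hom=n_hom,
        n_missing=n_missing, pseudo_bulk_vaf=vaf, timepoint=matrix.timepoint,
    )


@dataclass
class ClonalFractionEstimate:
    """Clone-frequency estimate inferred from a bulk VAF.

    Carries a provenance note naming the zygosity assumption under which the
    conversion holds.
    """

    fraction: float
    vaf: float
    zygosity: str
    note: str

    def __float__(self) -> float:
        return self.fraction


def clonal_fraction_from_vaf(vaf: float, zygosity: str = "het") -> ClonalFractionEstimate:
    """Infer the clone frequency implied by a bulk VAF.

    het: clone frequency = min(2 * VAF, 1) — each clone cell contributes one
    mutant allele of two.  hom: clone frequency = VAF.
    """
    if not 0.0 <= vaf <= 1.0:
        raise ValueError(f"VAF {vaf} outside [0, 1]")
    if zygosity == "het":
        frac = min(2.0 * vaf, 1.0)
        note = ("assumes the variant is heterozygous in every clone cell; "
                "clone frequency = 2 x VAF (capped at 1)")
    elif zygosity == "hom":
        frac = vaf
        note = ("assumes the variant is homozygous in every clone cell; "
                "clone frequency = VAF")
    else:
        raise ValueError(f"zygosity must be 'het' or 'hom', got {zygosity!r}")
    return ClonalFractionEstimate(fraction=frac, vaf=vaf, zygosity=zygosity, note=note)


def bulk_concordance_table(
    vaf_records: list[VafRecord],
    bulk_vafs: dict[str, float | None],
    tolerance: float = 0.10,
) -> pd.DataFrame:
    """Side-by-side single-cell vs bulk VAF table.

    ``bulk_vafs`` maps variant id -> VAF, with None meaning the bulk assay
    did not detect the variant.  Rows detected by only one assay are
    labelled rather than dropped; concordance = |difference| <= tolerance.
    """
    sc_ids = {r.variant.id for r in vaf_records if not r.undefined}
    if not (sc_ids | set(bulk_vafs)):
        raise ValueError("no variants shared between single-cell and bulk inputs")
    rows = []
    seen = set()
    for rec in vaf_records:
        vid = rec.variant.id
        seen.add(vid)
        sc = rec.pseudo_bulk_vaf
        bulk = bulk_vafs.get(vid)
        if sc is not None and bulk is not None:
            delta = abs(sc - bulk)
            status = "both"
            concordant = delta <= tolerance
            direction = ("single_cell_higher" if sc > bulk
                         else "bulk_higher" if bulk > sc else "equal")
        elif sc is not None:
            delta, status, concordant, direction = None, "single_cell_only", False, None
        elif bulk is not None:
            delta, status, concordant, direction = None, "bulk_only", False, None
        else:
            delta, status, concordant, direction = None, "undetected", False, None
        rows.append({
            "variant": vid, "timepoint": rec.timepoint,
            "single_cell_vaf": sc, "bulk_vaf": bulk, "abs_difference": delta,
            "status": status, "concordant": concordant, "direction": direction,
        })
    for vid, bulk in bulk_vafs.items():
        if vid not in seen and bulk is not None:
            rows.append({
                "variant": vid, "timepoint": "", "single_cell_vaf": None,
                "bulk_vaf": bulk, "abs_difference": None, "status": "bulk_only",
                "concordant": False, "direction": None,
            })
    df = pd.DataFrame(rows)
    if not ((df.status == "both") | (df.status == "single_cell_only")
            | (df.status == "bulk_only")).any():
        raise ValueError("no variants shared between single-cell and bulk inputs")
    return df


@dataclass
class DepthComparison:
    variant: PanelVariant
    mutant_depths: np.ndarray
    wildtype_depths: np.ndarray
    statistic: float
    p_value: float
    alpha: float
    significant: bool
    mutant_group: str = "het_hom"

    def to_dict(self) -> dict:
        return {
            "variant": self.variant.id,
            "n_mutant": int(self.mutant_depths.size),
            "n_wildtype": int(self.wildtype_depths.size),
            "median_mutant_depth": float(np.median(self.mutant_depths)),
            "median_wildtype_depth": float(np.median(self.wildtype_depths)),
            "statistic": self.statistic,
            "p_value": self.p_value,
            "alpha": self.alpha,
            "significant": self.significant,
            "mutant_group": self.mutant_group,
        }


def compare_depth_by_genotype(
    matrix: GenotypeMatrix,
    variant: PanelVariant | str,
    alpha: float = 0.05,
    mutant_group: str = "het_hom",
) -> DepthComparison:
    """Two-sided Wilcoxon rank-sum comparison of read depths between
    mutant-call and wild-type-call cells at one variant.

    ``mutant_group`` is ``het_hom`` (default) or ``hom_only`` for the
    mutant-allele-only comparison.
    """
    j = matrix.variant_index(variant)
    calls = matrix.genotypes[:, j]
    depth = matrix.depth[:, j]
    if mutant_group == "het_hom":
        mut_mask = (calls == 1) | (calls == 2)
    elif mutant_group == "hom_only":
        mut_mask = calls == 2
    else:
        raise ValueError("mutant_group must be 'het_hom' or 'hom_only'")
    wt_mask = calls == 0
    if not mut_mask.any():
        raise ValueError(f"no mutant-call cells at {matrix.variants[j].id}")
    if not wt_mask.any():
        raise ValueError(f"no wild-type-call cells at {matrix.variants[j].id}")
    mut = depth[mut_mask]
    wt = depth[wt_mask]
    stat, p = stats.mannwhitneyu(mut, wt, alternative="two-sided")
    return DepthComparison(
        variant=matrix.variants[j], mutant_depths=mut, wildtype_depths=wt,
        statistic=float(stat), p_value=float(p), alpha=alpha,
        significant=bool(p < alpha), mutant_group=mutant_group,
    )


@dataclass
class ZygosityReport:
    """Evidence summary for apparent homozygosity at a mutant locus.

    ``flags`` may contain ``homozygosity_exceeds_ado_expectation`` and/or
    ``true_homozygosity_or_loh``; ``possibilities`` always lists the three
    candidate explanations — the report never adjudicates.
    """

    variant: PanelVariant
    n_het: int
    n_hom: int
    expected_hom_given_ado: float
    hom_tail_probability: float | None
    ado_rate: float
    depth_comparison: DepthComparison | None
    flags: list[str] = field(default_factory=list)
    possibilities: tuple[str, str, str] = (
        "true_homozygosity",
        "loss_of_heterozygosity",
        "unbalanced_allele_dropout",
    )

    @property
    def empty(self) -> bool:
        return (self.n_het + self.n_hom) == 0

    def to_dict(self) -> dict:
        return {
            "variant": self.variant.id,
            "n_het": self.n_het,
            "n_hom": self.n_hom,
            "expected_hom_given_ado": self.expected_hom_given_ado,
            "hom_tail_probability": self.hom_tail_probability,
            "ado_rate": self.ado_rate,
            "depth_comparison": (self.depth_comparison.to_dict()
                                 if self.depth_comparison else None),
            "flags": list(self.flags),
            "possibilities": list(self.possibilities),
        }


def zygosity_report(
    matrix: GenotypeMatrix,
    variant: PanelVariant | str,
    ado: ADOEstimate | float,
    alpha: float = 0.05,
) -> ZygosityReport:
    """Ask whether observed mutant homozygosity exceeds what the measured
    ADO rate alone explains; attach the depth-by-genotype verdict."""
    j = matrix.variant_index(variant)
    calls = matrix.genotypes[:, j]
    n_het = int((calls == 1).sum())
    n_hom = int((calls == 2).sum())
    rate = ado.mean_rate if isinstance(ado, ADOEstimate) else float(ado)
    n_mut = n_het + n_hom
    p_hom = (rate / 2.0) / (1.0 - rate / 2.0) if rate < 2.0 else 1.0
    flags: list[str] = []
    if n_mut == 0:
        return ZygosityReport(
            variant=matrix.variants[j], n_het=0, n_hom=0,
            expected_hom_given_ado=0.0, hom_tail_probability=None,
            ado_rate=rate, depth_comparison=None, flags=[],
        )
    tail = float(stats.binom.sf(n_hom - 1, n_mut, p_hom)) if n_hom > 0 else 1.0
    if rate == 0.0 and n_hom > 0:
        flags.append("true_homozygosity_or_loh")
    elif tail < alpha:
        flags.append("homozygosity_exceeds_ado_expectation")
    try:
        depth_cmp = compare_depth_by_genotype(matrix, variant, alpha=alpha)
    except ValueError:
        depth_cmp = None
    return ZygosityReport(
        variant=matrix.variants[j], n_het=n_het, n_hom=n_hom,
        expected_hom_given_ado=p_hom * n_mut, hom_tail_probability=tail,
        ado_rate=rate, depth_comparison=depth_cmp, flags=flags,
    )
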