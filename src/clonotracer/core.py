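"""Domain types for targeted single-cell DNA-seq genotype analysis.

The central container is :class:`GenotypeMatrix`: a cells x variants grid of
categorical genotype calls (WT / HET / HOM / MISSING) with parallel read-depth
and genotype-quality layers, annotated with the amplicon panel
(:class:`PanelVariant`) and a sample/timepoint label.

Genotype calls are stored as small integer codes (``int8``):
``0`` = WT (homozygous reference), ``1`` = HET, ``2`` = HOM (homozygous
alternate), ``-1`` = MISSING (no call).  The 0/1/2 coding doubles as the
alternate-allele count of a diploid genotype, which the pseudo-bulk VAF and
distance computations rely on; MISSING never participates in either.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np


class Genotype(enum.IntEnum):
    """Diploid genotype call; the integer value is the ALT allele count."""

    WT = 0
    HET = 1
    HOM = 2
    MISSING = -1


MISSING: int = int(Genotype.MISSING)

#: Panel variant categories: well-annotated common/germline SNVs used for
#: donor/recipient discrimination, disease-related (pathogenic) variants, and
#: control amplicons at known-heterozygous sites used for allele-dropout
#: estimation.
CATEGORIES = ("common", "pathogenic", "ado_control")

_VALID_CODES = frozenset({-1, 0, 1, 2})


class ClonotracerError(Exception):
    """Base class for all package-specific errors."""


class FormatError(ClonotracerError):
    """Unreadable or structurally defective input file."""


class PanelOverlapError(ClonotracerError):
    """No variant in the input overlaps the amplicon panel."""


class ConfigError(ClonotracerError):
    """Invalid or infeasible configuration."""


class QCError(ClonotracerError):
    """A quality-control step removed everything or cannot be computed."""


class NoChimerismError(ClonotracerError):
    """No donor population is detectable in the post-transplant sample."""


@dataclass(frozen=True)
class PanelVariant:
    """One locus of the targeted amplicon panel.

    Parameters
    ----------
    chrom, pos : str, int
        Chromosome name and 1-based position (VCF convention).
    ref, alt : str
        Reference and alternate allele strings.
    gene : str
        Gene symbol, e.g. ``"TP53"``.
    hgvs_label : str
        Free-text label such as ``"TP53 c.379T>A"``.
    category : str
        One of ``common``, ``pathogenic``, ``ado_control``.
    """

    chrom: str
    pos: int
    ref: str
    alt: str
    gene: str = ""
    hgvs_label: str = ""
    category: str = "common"

    def __post_init__(self) -> None:
        if self.category not in CATEGORIES:
            raise ConfigError(
                f"unknown variant category {self.category!r}; "
                f"expected one of {CATEGORIES}"
            )
        if self.pos < 1:
            raise ConfigError(f"variant position must be 1-based positive, got {self.pos}")

    @property
    def key(self) -> tuple[str, int, str, str]:
        return (self.chrom, self.pos, self.ref, self.alt)

    @property
    def id(self) -> str:
        """Compact unique identifier used as a column header."""
        return f"{self.chrom}:{self.pos}:{self.ref}>{self.alt}"


def check_panel(variants: Sequence[PanelVariant]) -> None:
    """Validate uniqueness of (chrom, pos, ref, alt) within a panel."""
    keys = [v.key for v in variants]
    if len(set(keys)) != len(keys):
        seen: set = set()
        for k in keys:
            if k in seen:
                raise ConfigError(f"duplicate panel variant {k}")
            seen.add(k)


@dataclass
class GenotypeMatrix:
    """Cells x variants genotype calls with depth and quality layers.

    All three grids share the shape ``(n_cells, n_variants)``.  Depth and
    quality are retained even where the genotype is MISSING (a call masked by
    QC keeps its raw depth for diagnostics).
    """

    cell_ids: list[str]
    variants: list[PanelVariant]
    genotypes: np.ndarray
    depth: np.ndarray
    quality: np.ndarray
    sample_id: str = ""
    timepoint: str = ""

    def __post_init__(self) -> None:
        self.cell_ids = list(self.cell_ids)
        self.variants = list(self.variants)
        self.genotypes = np.asarray(self.genotypes, dtype=np.int8)
        self.depth = np.asarray(self.depth, dtype=np.int32)
        self.quality = np.asarray(self.quality, dtype=np.int32)
        shape = (len(self.cell_ids), len(self.variants))
        for name, grid in (("genotypes", self.genotypes),
                           ("depth", self.depth),
                           ("quality", self.quality)):
            if grid.shape != shape:
                raise ConfigError(
                    f"{name} grid has shape {grid.shape}, expected {shape}"
                )
        bad = set(np.unique(self.genotypes)) - _VALID_CODES
        if bad:
            raise ConfigError(f"invalid genotype codes {sorted(bad)}")
        if self.depth.size and self.depth.min() < 0:
            raise ConfigError("negative read depth")
        if self.quality.size and self.quality.min() < 0:
            raise ConfigError("negative quality score")
        if len(set(self.cell_ids)) != len(self.cell_ids):
            raise ConfigError("duplicate cell barcodes")
        check_panel(self.variants)

    # -- basic introspection -------------------------------------------------

    @property
    def n_cells(self) -> int:
        return len(self.cell_ids)

    @property
    def n_variants(self) -> int:
        return len(self.variants)

    @property
    def variant_ids(self) -> list[str]:
        return [v.id for v in self.variants]

    def variant_index(self, variant: PanelVariant | str) -> int:
        """Index of a variant, matched by identity key or by ``id`` string."""
        if isinstance(variant, PanelVariant):
            wanted = variant.key
            for i, v in enumerate(self.variants):
                if v.key == wanted:
                    return i
            raise KeyError(f"variant {variant.id} not in matrix")
        for i, v in enumerate(self.variants):
            if v.id == variant:
                return i
        raise KeyError(f"variant {variant!r} not in matrix")

    def category_indices(self, *categories: str) -> np.ndarray:
        """Column indices of variants whose category is in ``categories``."""
        return np.array(
            [i for i, v in enumerate(self.variants) if v.category in categories],
            dtype=int,
        )

    # -- derived quantities --------------------------------------------------

    def missing_fraction_per_cell(self) -> np.ndarray:
        if self.n_variants == 0:
            return np.zeros(self.n_cells)
        return (self.genotypes == MISSING).mean(axis=1)

    def missing_fraction_per_variant(self) -> np.ndarray:
        if self.n_cells == 0:
            return np.zeros(self.n_variants)
        return (self.genotypes == MISSING).mean(axis=0)

    def n_called(self) -> int:
        """Number of non-MISSING genotype entries."""
        return int((self.genotypes != MISSING).sum())

    # -- subsetting ----------------------------------------------------------

    def copy(self) -> "GenotypeMatrix":
        return GenotypeMatrix(
            cell_ids=list(self.cell_ids),
            variants=list(self.variants),
            genotypes=self.genotypes.copy(),
            depth=self.depth.copy(),
            quality=self.quality.copy(),
            sample_id=self.sample_id,
            timepoint=self.timepoint,
        )

    def subset_cells(self, index: Iterable[int] | np.ndarray) -> "GenotypeMatrix":
        idx = np.asarray(list(index) if not isinstance(index, np.ndarray) else index)
        if idx.dtype == bool:
            idx = np.flatnonzero(idx)
        return GenotypeMatrix(
            cell_ids=[self.cell_ids[i] for i in idx],
            variants=list(self.variants),
            genotypes=self.genotypes[idx],
            depth=self.depth[idx],
            quality=self.quality[idx],
            sample_id=self.sample_id,
            timepoint=self.timepoint,
        )

    def subset_variants(self, index: Iterable[int] | np.ndarray) -> "GenotypeMatrix":
        idx = np.asarray(list(index) if not isinstance(index, np.ndarray) else index)
        if idx.dtype == bool:
            idx = np.flatnonzero(idx)
        return GenotypeMatrix(
            cell_ids=list(self.cell_ids),
            variants=[self.variants[i] for i in idx],
            genotypes=self.genotypes[:, idx],
            depth=self.depth[:, idx],
            quality=self.quality[:, idx],
            sample_id=self.sample_id,
            timepoint=self.timepoint,
        )

    def with_genotypes(self, genotypes: np.ndarray) -> "GenotypeMatrix":
        out = self.copy()
        out.genotypes = np.asarray(genotypes, dtype=np.int8)
        if out.genotypes.shape != self.genotypes.shape:
            raise ConfigError("replacement genotype grid has wrong shape")
        return out

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, GenotypeMatrix):
            return NotImplemented
        return (
            self.cell_ids == other.cell_ids
            and self.variants == other.variants
            and np.array_equal(self.genotypes, other.genotypes)
            and np.array_equal(self.depth, other.depth)
            and np.array_equal(self.quality, other.quality)
            and self.sample_id == other.sample_id
            and self.timepoint == other.timepoint
        )


def consensus_genotypes(codes: np.ndarray) -> np.ndarray:
    """Per-locus majority genotype over a set of cells.

    MISSING calls are ignored; a locus with no call in any cell stays MISSING.
    Ties break toward the lower code (WT < HET < HOM), deterministically.
    """
    codes = np.asarray(codes)
    if codes.ndim != 2:
        raise ValueError("expected a cells x variants code array")
    counts = np.stack([(codes == g).sum(axis=0) for g in (0, 1, 2)])
    called = counts.sum(axis=0)
    out = counts.argmax(axis=0).astype(np.int8)
    out[called == 0] = MISSING
    return out


def profile_hamming(a: np.ndarray, b: np.ndarray, normalized: bool = True) -> float:
    """Hamming distance between two genotype profiles over loci where both
    are non-MISSING.  Returns 1.0 (or the locus count) when nothing is
    comparable."""
    a = np.asarray(a)
    b = np.asarray(b)
    both = (a != MISSING) & (b != MISSING)
    n = int(both.sum())
    if n == 0:
        return 1.0 if normalized else float(len(a))
    d = int((a[both] != b[both]).sum())
    return d / n if normalized else float(d)
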