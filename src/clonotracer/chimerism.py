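"""Donor/recipient demultiplexing after bone-marrow transplantation.

A pre-transplant sample is, by study design, 100% recipient-derived; its
per-locus majority genotype over the common (germline) SNVs anchors the
recipient profile.  The post-transplant sample is 2-way clustered on the
same loci; the cluster whose consensus is nearer (Hamming over non-MISSING
loci) to the recipient profile keeps that label and the other cluster's
consensus becomes the donor profile.  Loci where the two profiles carry
different non-MISSING genotypes are the discriminative SNVs (a HET vs HOM
difference counts).

Each cell is then assigned by exact-genotype majority vote over the
discriminative loci at which it has a call; ties — including cells with no
usable call — are reported as ambiguous, never silently redistributed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .core import (
    GenotypeMatrix,
    MISSING,
    NoChimerismError,
    PanelVariant,
    consensus_genotypes,
    profile_hamming,
)
from .clonal import CloneCaller

DONOR = "donor"
RECIPIENT = "recipient"
AMBIGUOUS = "ambiguous"


@dataclass
class OriginProfiles:
    """Inferred donor and recipient germline genotypes over common SNVs."""

    variants: list[PanelVariant]
    donor: np.ndarray
    recipient: np.ndarray

    def __post_init__(self) -> None:
        self.donor = np.asarray(self.donor, dtype=np.int8)
        self.recipient = np.asarray(self.recipient, dtype=np.int8)
        if not (len(self.variants) == self.donor.size == self.recipient.size):
            raise ValueError("profile arrays must match the variant list")

    @property
    def discriminative_mask(self) -> np.ndarray:
        return (
            (self.donor != MISSING)
            & (self.recipient != MISSING)
            & (self.donor != self.recipient)
        )

    @property
    def discriminative_loci(self) -> list[PanelVariant]:
        return [v for v, m in zip(self.variants, self.discriminative_mask) if m]

    def swapped(self) -> "OriginProfiles":
        return OriginProfiles(
            variants=list(self.variants),
            donor=self.recipient.copy(),
            recipient=self.donor.copy(),
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "variant": [v.id for v in self.variants],
            "donor_gt": self.donor,
            "recipient_gt": self.recipient,
            "discriminative": self.discriminative_mask,
        })


@dataclass
class ChimerismResult:
    sample_id: str
    timepoint: str
    donor_fraction: float
    recipient_fraction: float
    ambiguous_fraction: float
    n_cells: int
    labels: np.ndarray

    def __post_init__(self) -> None:
        total = self.donor_fraction + self.recipient_fraction + self.ambiguous_fraction
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"origin fractions sum to {total}, not 1")

    def to_dict(self) -> dict:
        return {
            "sample_id": self.sample_id,
            "timepoint": self.timepoint,
            "donor_fraction": self.donor_fraction,
            "recipient_fraction": self.recipient_fraction,
            "ambiguous_fraction": self.ambiguous_fraction,
            "n_cells": self.n_cells,
        }


def _common_codes(matrix: GenotypeMatrix) -> tuple[np.ndarray, list[PanelVariant]]:
    idx = matrix.category_indices("common")
    return matrix.genotypes[:, idx], [matrix.variants[i] for i in idx]


def infer_origin_profiles(
    pre_bmt: GenotypeMatrix,
    post_bmt: GenotypeMatrix,
    linkage_method: str = "complete",
    silhouette_floor: float = 0.25,
    min_profile_divergence: float = 0.1,
) -> OriginProfiles:
    """Infer donor and recipient germline profiles from a pre-BMT (pure
    recipient) and a post-BMT (mixed) sample.

    Raises :class:`NoChimerismError` when the post-BMT sample does not split
    into two germline clusters, when the two cluster consensuses diverge at
    fewer than ``min_profile_divergence`` (normalized Hamming) of the common
    SNVs — unrelated germlines differ at many loci, so a near-identical
    split is dropout noise, not chimerism — or when the inferred profiles
    share every genotype (zero discriminative loci).
    """
    pre_codes, pre_vars = _common_codes(pre_bmt)
    post_codes, post_vars = _common_codes(post_bmt)
    if len(pre_vars) < 2:
        raise ValueError("need at least 2 common SNVs to infer origin profiles")
    if [v.key for v in pre_vars] != [v.key for v in post_vars]:
        raise ValueError("pre- and post-BMT matrices must share the common-SNV panel")

    recipient = consensus_genotypes(pre_codes)

    caller = CloneCaller(k=None, max_k=2, linkage_method=linkage_method,
                         silhouette_floor=silhouette_floor).fit(post_codes)
    if caller.n_clusters_ < 2:
        raise NoChimerismError(
            "post-BMT sample forms a single germline cluster; "
            "no donor population detected"
        )
    cons = [consensus_genotypes(post_codes[caller.labels_ == c]) for c in (0, 1)]
    divergence = profile_hamming(cons[0], cons[1])
    if divergence < min_profile_divergence:
        raise NoChimerismError(
            f"post-BMT germline clusters diverge at only {divergence:.3f} of "
            f"common SNVs (< {min_profile_divergence}); no donor population "
            "detected"
        )
    d_to_recipient = [profile_hamming(c, recipient) for c in cons]
    if d_to_recipient[0] == d_to_recipient[1]:
        raise NoChimerismError(
            "cannot orient post-BMT clusters: both consensus profiles are "
            "equidistant from the recipient profile"
        )
    donor_cluster = int(np.argmax(d_to_recipient))
    profiles = OriginProfiles(
        variants=pre_vars, donor=cons[donor_cluster], recipient=recipient
    )
    if not profiles.discriminative_mask.any():
        raise NoChimerismError(
            "inferred donor and recipient profiles are identical at every "
            "common SNV; no discriminative loci"
        )
    return profiles


def _matrix_common_codes_for(
    matrix: GenotypeMatrix, profiles: OriginProfiles
) -> np.ndarray:
    """Cell genotypes over the profile's variant list, MISSING where the
    matrix lacks a locus (e.g. removed by variant-level QC)."""
    out = np.full((matrix.n_cells, len(profiles.variants)), MISSING, dtype=np.int8)
    keys = {v.key: j for j, v in enumerate(matrix.variants)}
    for i, v in enumerate(profiles.variants):
        j = keys.get(v.key)
        if j is not None:
            out[:, i] = matrix.genotypes[:, j]
    return out


def assign_cell_origin(cell_genotypes: np.ndarray, profiles: OriginProfiles) -> str:
    """Assign one cell's origin by exact-match majority vote over the
    discriminative loci (ambiguous on ties or zero usable loci)."""
    labels = assign_origins(np.asarray(cell_genotypes)[None, :], profiles)
    return str(labels[0])


def assign_origins(codes: np.ndarray, profiles: OriginProfiles) -> np.ndarray:
    """Vectorised origin assignment for a cells x common-SNV code array."""
    mask = profiles.discriminative_mask
    if not mask.any():
        raise ValueError("profiles carry no discriminative loci")
    codes = np.asarray(codes)
    if codes.shape[1] != len(profiles.variants):
        raise ValueError("genotype columns must match the profile's variant list")
    sub = codes[:, mask]
    valid = sub != MISSING
    donor_matches = ((sub == profiles.donor[mask]) & valid).sum(axis=1)
    recip_matches = ((sub == profiles.recipient[mask]) & valid).sum(axis=1)
    labels = np.full(codes.shape[0], AMBIGUOUS, dtype=object)
    labels[donor_matches > recip_matches] = DONOR
    labels[recip_matches > donor_matches] = RECIPIENT
    return labels


def compute_chimerism(
    matrix: GenotypeMatrix, profiles: OriginProfiles
) -> ChimerismResult:
    """Per-sample donor/recipient/ambiguous fractions over all cells
    (ambiguous reported separately, never redistributed)."""
    if matrix.n_cells == 0:
        raise ValueError("cannot compute chimerism on an empty matrix")
    codes = _matrix_common_codes_for(matrix, profiles)
    labels = assign_origins(codes, profiles)
    n = matrix.n_cells
    return ChimerismResult(
        sample_id=matrix.sample_id,
        timepoint=matrix.timepoint,
        donor_fraction=float((labels == DONOR).sum()) / n,
        recipient_fraction=float((labels == RECIPIENT).sum()) / n,
        ambiguous_fraction=float((labels == AMBIGUOUS).sum()) / n,
        n_cells=n,
        labels=labels,
    )


class OriginClassifier(BaseEstimator):
    """Sklearn-style donor/recipient cell classifier.

    ``fit(pre_bmt, post_bmt)`` infers the two germline profiles;
    ``predict(matrix)`` returns per-cell labels in
    {donor, recipient, ambiguous}; ``chimerism(matrix)`` wraps the
    fractions into a :class:`ChimerismResult`.
    """

    def __init__(self, linkage_method: str = "complete",
                 silhouette_floor: float = 0.25,
                 min_profile_divergence: float = 0.1):
        self.linkage_method = linkage_method
        self.silhouette_floor = silhouette_floor
        self.min_profile_divergence = min_profile_divergence

    def fit(self, X: GenotypeMatrix, y: GenotypeMatrix | None = None) -> "OriginClassifier":
        if y is None:
            raise ValueError(
                "OriginClassifier.fit requires (pre_bmt, post_bmt) matrices"
            )
        self.profiles_ = infer_origin_profiles(
            X, y, linkage_method=self.linkage_method,
            silhouette_floor=self.silhouette_floor,
            min_profile_divergence=self.min_profile_divergence,
        )
        self.classes_ = np.array([AMBIGUOUS, DONOR, RECIPIENT])
        return self

    def predict(self, X: GenotypeMatrix) -> np.ndarray:
        codes = _matrix_common_codes_for(X, self.profiles_)
        return assign_origins(codes, self.profiles_)

    def chimerism(self, X: GenotypeMatrix) -> ChimerismResult:
        return compute_chimerism(X, self.profiles_)


def longitudinal_chimerism(
    results: list[ChimerismResult],
) -> pd.DataFrame:
    """Per-timepoint donor/recipient/ambiguous fractions, in input order, to
    expose longitudinal trends (e.g. declining donor chimerism)."""
    return pd.DataFrame([r.to_dict() for r in results])
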