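"""2-D t-SNE embedding of per-cell genotype profiles for visualization.

The embedding runs on the 0/1/2-encoded common+pathogenic variant columns;
MISSING calls are imputed to the per-locus mode *for the embedding only*
(imputed values never flow back into any analysis stage).  The t-SNE core
is scikit-learn's, at default perplexity, seeded for reproducibility.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.manifold import TSNE

from .core import GenotypeMatrix, MISSING
from .clonal import CLUSTER_CATEGORIES


def _impute_mode(codes: np.ndarray) -> np.ndarray:
    out = codes.astype(np.float64)
    for j in range(out.shape[1]):
        col = out[:, j]
        miss = col == MISSING
        if not miss.any():
            continue
        called = col[~miss]
        if called.size == 0:
            out[:, j] = 0.0
            continue
        vals, counts = np.unique(called, return_counts=True)
        out[miss, j] = vals[np.argmax(counts)]
    return out


def concat_matrices(matrices: list[GenotypeMatrix]) -> GenotypeMatrix:
    """Stack cells from several timepoints over a shared variant panel."""
    first = matrices[0]
    keys = [v.key for v in first.variants]
    for m in matrices[1:]:
        if [v.key for v in m.variants] != keys:
            raise ValueError("matrices must share an identical variant panel")
    return GenotypeMatrix(
        cell_ids=[c for m in matrices for c in m.cell_ids],
        variants=list(first.variants),
        genotypes=np.vstack([m.genotypes for m in matrices]),
        depth=np.vstack([m.depth for m in matrices]),
        quality=np.vstack([m.quality for m in matrices]),
        sample_id="+".join(m.sample_id for m in matrices),
        timepoint="combined",
    )


def export_embedding(
    matrix: GenotypeMatrix,
    labels: pd.DataFrame | dict | None = None,
    seed: int = 0,
    perplexity: float = 30.0,
) -> pd.DataFrame:
    """t-SNE coordinates per cell, joined with annotation columns.

    ``labels`` maps annotation name -> per-cell values (aligned with the
    matrix's cell order), e.g. clone, origin and timepoint labels.
    """
    n = matrix.n_cells
    if n < 4 * perplexity:
        raise ValueError(
            f"t-SNE needs at least 4 x perplexity cells "
            f"({4 * perplexity:.0f}); got {n}. Lower the perplexity."
        )
    idx = matrix.category_indices(*CLUSTER_CATEGORIES)
    if len(idx) == 0:
        idx = np.arange(matrix.n_variants)
    codes = _impute_mode(matrix.genotypes[:, idx])
    coords = TSNE(
        n_components=2, perplexity=perplexity, random_state=seed, init="pca",
    ).fit_transform(codes)
    df = pd.DataFrame(
        {"tsne1": coords[:, 0], "tsne2": coords[:, 1]},
        index=pd.Index(matrix.cell_ids, name="cell_id"),
    )
    if labels is not None:
        if isinstance(labels, dict):
            labels = pd.DataFrame(labels, index=df.index)
        for col in labels.columns:
            df[col] = np.asarray(labels[col])
    return df
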