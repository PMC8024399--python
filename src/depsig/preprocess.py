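"""Normalization and filtering of log2 expression matrices.

Three steps, applied in this order in the standard workflow:

1. :func:`quantile_normalize` — force every sample to share the mean
   distribution of order statistics (ties receive the mean of their
   assigned quantile values).
2. :func:`filter_expressed` — keep genes with median >= ``min_median``
   and across-sample SD strictly > ``min_sd``; the surviving genes define
   the "expressed" universe used by the gene-set stages.  The strict
   inequality guarantees no zero-variance gene ever reaches z-scoring.
3. :func:`remove_latent_factors` — a simplified factor adjustment that
   subtracts the projection onto the top-k principal components of the
   residual matrix after removing group x timepoint means, reducing the
   correlation structure that inflates multiple-testing error.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .io import CohortDesign, ExpressionMatrix

__all__ = ["PreprocessReport", "quantile_normalize", "filter_expressed", "remove_latent_factors"]


@dataclass
class PreprocessReport:
    n_genes_in: int
    n_genes_kept: int
    normalization: str = "none"
    expressed_threshold: float = 0.0
    sd_threshold: float = 0.0
    factors_removed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes_kept > self.n_genes_in:
            raise ValueError("n_genes_kept cannot exceed n_genes_in")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([vars(self)])


def quantile_normalize(m: ExpressionMatrix) -> ExpressionMatrix:
    """Quantile-normalize samples to the mean of order statistics.

    After normalization every sample's sorted value vector equals the
    across-sample mean of order statistics; within-sample ties receive
    the mean of the quantile values their ranks span, so tied inputs stay
    tied.  Idempotent.  Requires at least two samples.
    """
    values = m.values
    n_genes, n_samples = values.shape
    if n_samples < 2:
        raise ValueError("quantile normalization needs at least 2 samples")
    mean_order_stats = np.sort(values, axis=0).mean(axis=1)
    out = np.empty_like(values)
    for j in range(n_samples):
        # average ranks (1-based); ties -> mean of the tied quantile values
        ranks = stats.rankdata(values[:, j], method="average")
        lo = np.floor(ranks).astype(int) - 1
        hi = np.ceil(ranks).astype(int) - 1
        out[:, j] = 0.5 * (mean_order_stats[lo] + mean_order_stats[hi])
    return ExpressionMatrix(pd.DataFrame(out, index=m.gene_ids, columns=m.sample_ids))


def filter_expressed(
    m: ExpressionMatrix, min_median: float = 1.0, min_sd: float = 0.0
) -> tuple[ExpressionMatrix, PreprocessReport]:
    """Keep genes with median >= ``min_median`` and SD > ``min_sd``.

    The SD comparison is strict so constant genes are always dropped at
    ``min_sd = 0``.  Raises if every gene is removed.
    """
    if min_median < 0 or min_sd < 0:
        raise ValueError("thresholds must be >= 0")
    med = m.data.median(axis=1)
    sd = m.data.std(axis=1, ddof=0)
    keep = (med >= min_median) & (sd > min_sd)
    if not keep.any():
        raise ValueError("filter_expressed removed every gene")
    out = ExpressionMatrix(m.data.loc[keep].copy())
    report = PreprocessReport(
        n_genes_in=m.shape[0],
        n_genes_kept=out.shape[0],
        normalization="none",
        expressed_threshold=min_median,
        sd_threshold=min_sd,
    )
    return out, report


def remove_latent_factors(m: ExpressionMatrix, design: CohortDesign, k: int) -> ExpressionMatrix:
    """Subtract the top-k principal components of the condition-centered residual.

    The residual is the expression matrix minus per-gene group x
    timepoint cell means; its top-k right singular vectors (sample-space
    components) capture latent structure (batches, cell-proportion
    shifts) orthogonal to the design, and their projection is removed
    from the original matrix.  ``k = 0`` is the identity.
    """
    n_samples = m.shape[1]
    if k >= n_samples:
        raise ValueError(f"k must be < number of samples ({n_samples})")
    if k < 0:
        raise ValueError("k must be >= 0")
    if k == 0:
        return ExpressionMatrix(m.data.copy())
    t = design.table.loc[m.sample_ids]
    cells = t["group"].astype(str) + "/" + t["timepoint"].astype(str)
    resid = m.data.to_numpy().copy()
    for cell in cells.unique():
        cols = np.flatnonzero((cells == cell).to_numpy())
        resid[:, cols] -= resid[:, cols].mean(axis=1, keepdims=True)
    # sample-space principal components of the residual
    _, _, vt = np.linalg.svd(resid, full_matrices=False)
    v_k = vt[:k].T  # (samples, k)
    adjusted = m.data.to_numpy() - resid @ v_k @ v_k.T
    return ExpressionMatrix(pd.DataFrame(adjusted, index=m.gene_ids, columns=m.sample_ids))
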