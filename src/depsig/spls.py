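"""Sparse partial least squares regression for gene selection.

One PLS component at a time: the X-loading is the covariance between
each standardized gene and the (standardized) response, soft-thresholded
so that exactly ``keep_x`` loadings stay nonzero, then renormalized to
unit length.  X is deflated by its own scores between components
(regression mode; y is not deflated).  The use case is variable
selection — finding the genes whose expression tracks a continuous
depression severity score — so one component is the default.

With ``keep_x`` equal to the number of genes no thresholding occurs and
the single-component loading is proportional to the vector of Pearson
correlations between each gene and the response; with smaller ``keep_x``
the selected genes are exactly those with the largest absolute
covariance with y (per component, on the deflated matrix).

Exposed statsmodels-style: ``SPLS(expr, y).fit() -> SPLSResults`` with a
``summary()`` table, plus thin functional wrappers.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import ExpressionMatrix

__all__ = ["SPLS", "SPLSResults", "fit_spls", "threshold_by_r"]


def _soft_threshold_keep(w: np.ndarray, keep: int, gene_ids: list[str]) -> np.ndarray:
    """Soft-threshold ``w`` so exactly ``keep`` entries remain nonzero.

    The threshold is the (keep+1)-th largest |w|; ties at the threshold
    are broken by gene-id lexicographic order for determinism.
    """
    p = w.size
    if keep >= p:
        return w.copy()
    order = np.lexsort((np.asarray(gene_ids), -np.abs(w)))
    lam = np.abs(w[order[keep]])
    out = np.sign(w) * np.maximum(np.abs(w) - lam, 0.0)
    # ties at |w| == lam shrink to exactly 0; enforce the keep_x budget
    nonzero = np.flatnonzero(out)
    if nonzero.size > keep:  # pragma: no cover - defensive, ties handled above
        keep_idx = order[:keep]
        mask = np.zeros(p, dtype=bool)
        mask[keep_idx] = True
        out[~mask] = 0.0
    return out


@dataclass
class SPLSResults:
    """Fitted sparse-PLS selection.

    Attributes
    ----------
    loadings : pandas.DataFrame
        genes × components weight matrix; unit Euclidean norm per
        component, at most ``keep_x`` nonzeros each, sign fixed so the
        largest-magnitude loading of each component is positive.
    selected : pandas.DataFrame
        Union of nonzero-loading genes across components with their
        Pearson correlation ``r`` to the response, sorted by |r|
        descending.
    """

    loadings: pd.DataFrame
    selected: pd.DataFrame
    n_components: int
    keep_x: int

    def threshold_by_r(self, r_min: float) -> dict[str, list[str]]:
        """Split selected genes with |r| > ``r_min`` into up/down lists."""
        sel = self.selected[self.selected["r"].abs() > r_min]
        return {
            "up": list(sel.index[sel["r"] > 0]),
            "down": list(sel.index[sel["r"] < 0]),
        }

    def summary(self) -> str:
        lines = [
            "Sparse PLS regression (selection mode)",
            f"  components: {self.n_components}   keep_x: {self.keep_x}",
            f"  genes selected: {len(self.selected)}",
        ]
        head = self.selected.head(10)
        lines.append(head.to_string(float_format=lambda v: f"{v: .4f}"))
        return "\n".join(lines)


class SPLS:
    """Sparse PLS of a continuous response on an expression matrix.

    Parameters
    ----------
    m : ExpressionMatrix
        genes × samples log2 expression.
    y : array-like
        Response per sample (e.g. MADRS), same order as ``m.sample_ids``.
    """

    def __init__(self, m: ExpressionMatrix, y) -> None:
        y = np.asarray(y, dtype=float)
        if y.shape != (m.shape[1],):
            raise ValueError("length of y must equal the number of samples")
        if np.std(y) == 0:
            raise ValueError("response y has zero variance")
        self.m = m
        self.y = y

    def fit(self, keep_x: int = 2000, n_components: int = 1) -> SPLSResults:
        if keep_x <= 0:
            raise ValueError("keep_x must be positive")
        if n_components < 1:
            raise ValueError("n_components must be >= 1")
        genes = self.m.gene_ids
        keep_x = min(keep_x, len(genes))
        # samples × genes, standardized per gene (population SD); constant
        # genes get zero weight rather than a divide-by-zero
        x = self.m.values.T.astype(float)
        mu = x.mean(axis=0)
        sd = x.std(axis=0)
        sd_safe = np.where(sd > 0, sd, 1.0)
        x = (x - mu) / sd_safe
        x[:, sd == 0] = 0.0
        yz = (self.y - self.y.mean()) / self.y.std()

        n = x.shape[0]
        loadings = np.zeros((len(genes), n_components))
        xd = x.copy()
        for comp in range(n_components):
            w = xd.T @ yz / n  # covariance of standardized variables
            w = _soft_threshold_keep(w, keep_x, genes)
            norm = np.linalg.norm(w)
            if norm == 0:
                break
            w /= norm
            if w[np.argmax(np.abs(w))] < 0:  # sign convention
                w = -w
            loadings[:, comp] = w
            t = xd @ w
            denom = t @ t
            if denom > 0:
                xd = xd - np.outer(t, t @ xd) / denom
        load_df = pd.DataFrame(
            loadings, index=genes, columns=[f"comp{i + 1}" for i in range(n_components)]
        )
        sel_mask = (loadings != 0).any(axis=1)
        sel_idx = np.flatnonzero(sel_mask)
        sel_genes = [genes[i] for i in sel_idx]
        # Pearson r of each standardized gene with the standardized response
        r = x[:, sel_idx].T @ yz / n
        sel = pd.DataFrame({"r": r}, index=pd.Index(sel_genes, name="gene"))
        sel["direction"] = np.where(sel["r"] >= 0, "up", "down")
        sel = sel.iloc[np.argsort(-np.abs(sel["r"].to_numpy()), kind="stable")]
        return SPLSResults(load_df, sel, n_components, keep_x)


def fit_spls(m: ExpressionMatrix, y, keep_x: int = 2000, n_components: int = 1) -> SPLSResults:
    """Functional wrapper around :class:`SPLS`."""
    return SPLS(m, y).fit(keep_x=keep_x, n_components=n_components)


def threshold_by_r(result: SPLSResults, r_min: float) -> dict[str, list[str]]:
    """Genes from ``result`` with |r| > ``r_min``, split by sign."""
    return result.threshold_by_r(r_min)
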