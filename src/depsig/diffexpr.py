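"""Differential expression for the paired pre/post cohort design.

Three contrasts are supported:

* unpaired — MDD vs non-MDD within a timepoint (per-gene Welch t-test by
  default, or a moderated t that shrinks gene-wise variances toward a
  pooled prior);
* paired — post vs baseline within a group (one-sample t on the
  within-patient differences; dropouts are excluded and counted);
* :func:`bh_adjust` — Benjamini–Hochberg step-up FDR over all tested
  genes.

Genes with adjusted FDR <= 0.05 are conventionally called differentially
expressed.  Direction is the sign of log2 fold change; a zero fold
change is labelled "up" only when t > 0.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special, stats
from statsmodels.stats.multitest import multipletests

from .io import CohortDesign, ExpressionMatrix

logger = logging.getLogger(__name__)

__all__ = ["DEResult", "unpaired_de", "paired_de", "bh_adjust", "significant_genes"]


@dataclass
class DEResult:
    """Per-gene differential expression table plus contrast metadata."""

    table: pd.DataFrame  # columns: log2fc, t_stat, df, p, fdr, direction
    contrast: str
    n_samples: tuple[int, int]
    n_excluded: int = 0
    method: str = "welch"

    def significant(self, fdr: float = 0.05) -> pd.DataFrame:
        return self.table[self.table["fdr"] <= fdr]

    def gene_lists(self, fdr: float = 0.05) -> dict[str, list[str]]:
        sig = self.significant(fdr)
        return {
            "up": list(sig.index[sig["direction"] == "up"]),
            "down": list(sig.index[sig["direction"] == "down"]),
        }


def bh_adjust(p) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values, input order preserved."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def _moderate_variances(s2: np.ndarray, df: float) -> tuple[np.ndarray, float]:
    """Empirical-Bayes shrinkage of gene variances toward a pooled prior.

    Moment estimation on log sample variances: for s² ~ s0²·χ²_d/d the
    log variance has known digamma/trigamma moments, giving prior df d0
    and prior variance s0².  Returns posterior variances
    (d0·s0² + d·s²)/(d0 + d) and the extra df d0 (inf when the log
    variances are underdispersed, i.e. complete pooling).
    """
    s2 = np.maximum(s2, 1e-300)
    z = np.log(s2)
    e = z - special.digamma(df / 2) + np.log(df / 2)
    var_excess = np.var(z, ddof=1) - special.polygamma(1, df / 2)
    if var_excess <= 0:
        return np.full_like(s2, np.exp(e.mean())), np.inf
    # invert trigamma by Newton iteration (standard approach)
    y = var_excess
    x = 0.5 + 1.0 / y
    for _ in range(50):
        tri = special.polygamma(1, x)
        delta = tri * (1 - tri / y) / special.polygamma(2, x)
        x += delta
        if abs(delta) < 1e-10:
            break
    d0 = 2 * x
    s0_2 = np.exp(e.mean() + special.digamma(x) - np.log(x))
    post = (d0 * s0_2 + df * s2) / (d0 + df)
    return post, d0


def _finish_table(
    log2fc: np.ndarray, t: np.ndarray, df: np.ndarray, genes: list[str]
) -> pd.DataFrame:
    # degenerate genes (zero SE and zero difference): t = 0, p = 1
    degenerate = np.isnan(t)
    t = np.where(degenerate, 0.0, t)
    p = np.minimum(2 * stats.t.sf(np.abs(t), df), 1.0)
    p = np.where(degenerate, 1.0, p)
    direction = np.where(log2fc > 0, "up", np.where(log2fc < 0, "down", np.where(t > 0, "up", "down")))
    table = pd.DataFrame(
        {
            "log2fc": log2fc,
            "t_stat": t,
            "df": df,
            "p": p,
            "fdr": bh_adjust(p),
            "direction": direction,
            "degenerate": degenerate,
        },
        index=pd.Index(genes, name="gene"),
    )
    return table.sort_values("p", kind="stable")


def unpaired_de(
    m: ExpressionMatrix,
    design: CohortDesign,
    contrast: tuple[str, str] = ("MDD", "nonMDD"),
    timepoint: str = "baseline",
    method: str = "welch",
) -> DEResult:
    """Per-gene two-sample test of group1 − group2 at one timepoint.

    ``method="welch"`` (default) uses unequal-variance t-tests;
    ``method="moderated"`` uses pooled-variance t with empirical-Bayes
    variance shrinkage and correspondingly increased df.
    """
    g1, g2 = contrast
    s1 = design.samples(group=g1, timepoint=timepoint)
    s2 = design.samples(group=g2, timepoint=timepoint)
    if len(s1) < 2 or len(s2) < 2:
        raise ValueError(f"each group needs >=2 samples (got {len(s1)}, {len(s2)})")
    x1 = m.subset_samples(s1).values
    x2 = m.subset_samples(s2).values
    n1, n2 = x1.shape[1], x2.shape[1]
    log2fc = x1.mean(axis=1) - x2.mean(axis=1)
    if method == "welch":
        v1 = x1.var(axis=1, ddof=1)
        v2 = x2.var(axis=1, ddof=1)
        se2 = v1 / n1 + v2 / n2
        with np.errstate(divide="ignore", invalid="ignore"):
            t = log2fc / np.sqrt(se2)
            df = se2**2 / ((v1 / n1) ** 2 / (n1 - 1) + (v2 / n2) ** 2 / (n2 - 1))
        df = np.where(np.isfinite(df), df, 1.0)
    elif method == "moderated":
        df_resid = n1 + n2 - 2
        s2_pooled = ((n1 - 1) * x1.var(axis=1, ddof=1) + (n2 - 1) * x2.var(axis=1, ddof=1)) / df_resid
        s2_post, d0 = _moderate_variances(s2_pooled, df_resid)
        with np.errstate(divide="ignore", invalid="ignore"):
            t = log2fc / np.sqrt(s2_post * (1 / n1 + 1 / n2))
        df = np.full_like(t, df_resid + (0 if np.isinf(d0) else d0))
        if np.isinf(d0):
            df = np.full_like(t, 1e6)  # effectively normal reference
    else:
        raise ValueError(f"unknown method {method!r}")
    table = _finish_table(log2fc, t, df, m.gene_ids)
    return DEResult(table, f"{timepoint}-{g1}-vs-{g2}", (n1, n2), method=method)


def paired_de(
    m: ExpressionMatrix, design: CohortDesign, group: str, method: str = "welch"
) -> DEResult:
    """Per-gene paired test of post − baseline within one group.

    One-sample t on the within-patient differences; patients lost to
    follow-up are excluded from the test and counted in ``n_excluded``.
    """
    patients = design.paired_patients(group=group)
    all_base = design.samples(group=group, timepoint="baseline")
    n_excluded = len(all_base) - len(patients)
    if len(patients) < 2:
        raise ValueError(f"need >=2 complete pairs in group {group!r} (got {len(patients)})")
    if n_excluded:
        logger.info("paired_de(%s): excluded %d patient(s) without follow-up", group, n_excluded)
    post_ids = [design.sample_of(p, "post") for p in patients]
    base_ids = [design.sample_of(p, "baseline") for p in patients]
    d = m.subset_samples(post_ids).values - m.subset_samples(base_ids).values
    n = d.shape[1]
    log2fc = d.mean(axis=1)
    if method == "welch":
        sd = d.std(axis=1, ddof=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            t = log2fc / (sd / np.sqrt(n))
        df = np.full_like(t, float(n - 1))
    elif method == "moderated":
        s2 = d.var(axis=1, ddof=1)
        s2_post, d0 = _moderate_variances(s2, n - 1)
        with np.errstate(divide="ignore", invalid="ignore"):
            t = log2fc / np.sqrt(s2_post / n)
        df = np.full_like(t, (n - 1) + (0 if np.isinf(d0) else d0))
        if np.isinf(d0):
            df = np.full_like(t, 1e6)
    else:
        raise ValueError(f"unknown method {method!r}")
    # all-zero differences: undefined t reported as 0 with p = 1
    table = _finish_table(log2fc, t, df, m.gene_ids)
    return DEResult(table, f"paired-{group}", (n, n), n_excluded=n_excluded, method=method)


def significant_genes(result: DEResult, fdr: float = 0.05) -> list[str]:
    """Gene ids with adjusted FDR <= threshold, sorted by p."""
    return list(result.significant(fdr).index)
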