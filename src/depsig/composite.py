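"""Composite transcription-factor z-score biomarkers.

The biomarker for a regulator (e.g. TP53, NR3C1/GR, RELA/NF-κB) is, per
patient sample, the mean standardized expression of the regulator's
target genes:

    z(g, i) = (x(g, i) − μ_g) / σ_g        (μ, σ over the cohort;
                                            σ is the population SD, divisor n)
    score(i, r) = mean over usable targets g of z(g, i)

"Usable" targets are the regulator's genes present in the expressed-gene
universe and the matrix.  Standardizing over the whole analyzed cohort
(baseline + post jointly, the default) places pre- and post-surgery
scores on one scale; a baseline-only mode is available for
sensitivity analysis.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .io import ExpressionMatrix, GeneSetCollection

__all__ = ["ZScoreMatrix", "zscore_matrix", "composite_scores"]


@dataclass
class ZScoreMatrix:
    """Standardized expression with the μ/σ used per gene."""

    z: pd.DataFrame  # genes × samples
    mu: pd.Series
    sigma: pd.Series

    @property
    def gene_ids(self) -> list[str]:
        return list(self.z.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.z.columns)


def zscore_matrix(m: ExpressionMatrix, cohort: Sequence[str] | None = None) -> ZScoreMatrix:
    """Standardize each gene over the cohort with the population SD.

    ``cohort`` restricts both the μ/σ estimation and the returned
    columns; the default is every sample in ``m``.  A zero-σ gene is an
    upstream filtering bug and raises by name.
    """
    if cohort is None:
        cohort = m.sample_ids
    sub = m.subset_samples(list(cohort))
    mu = sub.data.mean(axis=1)
    sigma = sub.data.std(axis=1, ddof=0)  # population SD, divisor n
    zero = sigma[sigma == 0]
    if len(zero):
        raise ValueError(
            f"zero-variance gene(s) reached z-scoring (filter first): {list(zero.index)[:5]}"
        )
    z = sub.data.sub(mu, axis=0).div(sigma, axis=0)
    return ZScoreMatrix(z, mu, sigma)


def composite_scores(
    z: ZScoreMatrix,
    sets: GeneSetCollection,
    expressed: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Per-sample composite z-score for each regulator.

    Returns a samples × regulators table; ``n_targets_used`` per
    regulator is attached as ``DataFrame.attrs["n_targets_used"]``.  A
    regulator with no usable target is an error.  Targets outside the
    expressed universe are ignored, so padding a set with unexpressed
    genes cannot move the score.
    """
    universe = set(z.gene_ids if expressed is None else expressed) & set(z.gene_ids)
    scores = {}
    n_used = {}
    for name in sets.names():
        usable = [g for g in sets[name] if g in universe]
        if not usable:
            raise ValueError(f"regulator {name!r} has no expressed target in the matrix")
        scores[name] = z.z.loc[usable].mean(axis=0)
        n_used[name] = len(usable)
    out = pd.DataFrame(scores)
    out.index.name = "sample_id"
    out.attrs["n_targets_used"] = n_used
    return out
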