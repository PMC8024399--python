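"""High-level Model/Results interface over the composite-biomarker workflow.

:class:`CompositeBiomarkerModel` is built from an expression matrix, a
cohort design and transcription-factor target sets; ``fit()`` normalizes
and filters the expression, standardizes it over the chosen cohort,
computes per-sample composite z-scores for every regulator, and runs the
validation layer (group × surgery ANOVA, baseline MADRS regressions
crude and adjusted, and the paired remission-delta regression).  The
returned :class:`CompositeBiomarkerResults` carries the scores and all
statistics and prints a combined ``summary()`` table.

Example
-------
>>> from depsig import SimulationConfig, simulate_cohort, CompositeBiomarkerModel
>>> expr, design, sets, _ = simulate_cohort(SimulationConfig(seed=1))
>>> res = CompositeBiomarkerModel(expr, design, sets).fit()
>>> print(res.summary())                                # doctest: +SKIP
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .composite import ZScoreMatrix, composite_scores, zscore_matrix
from .evaluate import AnovaResult, RegressionResult, delta_regression, regress_madrs, two_way_anova
from .io import CohortDesign, ExpressionMatrix, GeneSetCollection
from .preprocess import PreprocessReport, filter_expressed, quantile_normalize, remove_latent_factors

__all__ = ["CompositeBiomarkerModel", "CompositeBiomarkerResults"]


@dataclass
class CompositeBiomarkerResults:
    """Fitted composite biomarkers plus their validation statistics."""

    scores: pd.DataFrame  # samples × regulators
    zmatrix: ZScoreMatrix
    report: PreprocessReport
    anova: dict[str, AnovaResult]
    regressions: dict[str, RegressionResult]
    adjusted_regressions: dict[str, RegressionResult]
    delta: dict[str, RegressionResult]
    expressed_genes: list[str] = field(default_factory=list)

    def summary(self) -> str:
        lines = [
            "Composite TF z-score biomarkers",
            f"  genes: {self.report.n_genes_kept}/{self.report.n_genes_in} expressed, "
            f"normalization: {self.report.normalization}",
            f"  regulators: {', '.join(self.scores.columns)}",
            "",
            f"{'regulator':<10} {'interaction p':>13} {'beta_std':>9} {'F':>8} {'p':>10} {'delta beta':>11} {'delta p':>9}",
        ]
        for reg in self.scores.columns:
            an = self.anova.get(reg)
            rg = self.regressions[reg]
            dl = self.delta.get(reg)
            lines.append(
                f"{reg:<10} "
                + (f"{an.interaction_p:>13.3g} " if an else f"{'--':>13} ")
                + f"{rg.beta_std:>9.3f} {rg.F:>8.2f} {rg.p:>10.3g} "
                + (f"{dl.beta_std:>11.3f} {dl.p:>9.3g}" if dl else f"{'--':>11} {'--':>9}")
            )
        return "\n".join(lines)


class CompositeBiomarkerModel:
    """Composite z-score biomarker analysis of a paired cohort.

    Parameters
    ----------
    expression : ExpressionMatrix
        Raw log2 genes × samples matrix.
    design : CohortDesign
        Sample metadata; every expression column must appear in it.
    gene_sets : GeneSetCollection
        Regulator → target lists (e.g. ChIP-seq-derived, GMT).
    cohort : {"all", "baseline-only"}
        Standardization cohort for the z-scores.  "all" (default) puts
        baseline and post-surgery samples on one scale.
    normalize : bool
        Apply quantile normalization first.
    min_median, min_sd : float
        Expressed-gene filter thresholds (log2 units).
    n_latent_factors : int
        Principal components of the condition-centered residual to
        remove before scoring (0 disables the adjustment).
    covariates : list of str
        Covariates for the adjusted MADRS regressions (present in the
        design; default age, sex, bmi when available).
    """

    def __init__(
        self,
        expression: ExpressionMatrix,
        design: CohortDesign,
        gene_sets: GeneSetCollection,
        cohort: str = "all",
        normalize: bool = True,
        min_median: float = 1.0,
        min_sd: float = 0.0,
        n_latent_factors: int = 0,
        covariates: list[str] | None = None,
    ) -> None:
        unknown = set(expression.sample_ids) - set(design.sample_ids)
        if unknown:
            raise ValueError(f"samples without design rows: {sorted(unknown)[:5]}")
        if cohort not in ("all", "baseline-only"):
            raise ValueError("cohort must be 'all' or 'baseline-only'")
        self.expression = expression
        self.design = design
        self.gene_sets = gene_sets
        self.cohort = cohort
        self.normalize = normalize
        self.min_median = min_median
        self.min_sd = min_sd
        self.n_latent_factors = n_latent_factors
        if covariates is None:
            covariates = [c for c in ("age", "sex", "bmi") if c in design.table.columns]
        self.covariates = covariates

    def fit(self) -> CompositeBiomarkerResults:
        m = self.expression
        if self.normalize:
            m = quantile_normalize(m)
        m, report = filter_expressed(m, self.min_median, self.min_sd)
        report.normalization = "quantile" if self.normalize else "none"
        if self.n_latent_factors:
            m = remove_latent_factors(m, self.design, self.n_latent_factors)
            report.factors_removed = self.n_latent_factors
        if self.cohort == "baseline-only":
            cohort_ids = [s for s in m.sample_ids if s in set(self.design.samples(timepoint="baseline"))]
        else:
            cohort_ids = m.sample_ids
        z = zscore_matrix(m, cohort_ids)
        scores = composite_scores(z, self.gene_sets, expressed=m.gene_ids)

        anova: dict[str, AnovaResult] = {}
        regressions: dict[str, RegressionResult] = {}
        adjusted: dict[str, RegressionResult] = {}
        delta: dict[str, RegressionResult] = {}
        for reg in scores.columns:
            s = scores[reg]
            if self.cohort == "all":
                anova[reg] = two_way_anova(s, self.design)
                delta[reg] = delta_regression(s, self.design)
            regressions[reg] = regress_madrs(s, self.design)
            if self.covariates:
                adjusted[reg] = regress_madrs(s, self.design, covariates=self.covariates)
        return CompositeBiomarkerResults(
            scores=scores,
            zmatrix=z,
            report=report,
            anova=anova,
            regressions=regressions,
            adjusted_regressions=adjusted,
            delta=delta,
            expressed_genes=m.gene_ids,
        )
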