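"""End-to-end orchestration of the analysis stages.

``run_pipeline`` executes preprocess → sPLS selection → differential
expression (three contrasts) → upstream-regulator scoring → transcript
origin analysis → composite scores → statistical evaluation, writing one
TSV per stage into a run directory.  Every output carries a header
comment with the package version, the config hash and the seed; a
manifest records row counts per stage.  Any stage failure aborts with
the stage name while partial outputs stay on disk.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .composite import composite_scores, zscore_matrix
from .diffexpr import DEResult, paired_de, unpaired_de
from .evaluate import cohort_tests, delta_regression, regress_madrs, two_way_anova
from .io import (
    CohortDesign,
    ExpressionMatrix,
    GeneSetCollection,
    read_design,
    read_expression,
    read_gmt,
    write_design,
    write_expression,
    write_gmt,
)
from .preprocess import filter_expressed, quantile_normalize, remove_latent_factors
from .regulators import compare_contrasts, score_regulators
from .spls import fit_spls
from .toa import diagnosticity, toa_profile

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "run_pipeline"]


@dataclass
class PipelineConfig:
    expression: str
    design: str
    gmt: str
    reference: str | None = None
    min_median: float = 1.0
    min_sd: float = 0.0
    n_latent_factors: int = 0
    keep_x: int = 2000
    r_min: float = 0.5
    fdr: float = 0.05
    n_boot: int = 2000
    cohort: str = "all"
    covariates: list[str] = field(default_factory=lambda: ["age", "sex", "bmi"])
    de_method: str = "welch"
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config key(s): {sorted(unknown)}")
        for key in ("expression", "design", "gmt"):
            if key not in raw:
                raise ValueError(f"config missing required path {key!r}")
        return cls(**raw)

    def digest(self) -> str:
        blob = json.dumps({k: getattr(self, k) for k in self.__dataclass_fields__}, sort_keys=True)
        return hashlib.sha1(blob.encode()).hexdigest()[:12]

    def validate_paths(self) -> None:
        for key in ("expression", "design", "gmt"):
            p = getattr(self, key)
            if not Path(p).exists():
                raise FileNotFoundError(f"config path {key} = {p!r} does not exist")
        if self.reference and not Path(self.reference).exists():
            raise FileNotFoundError(f"config path reference = {self.reference!r} does not exist")


def _write(df: pd.DataFrame, path: Path, header: str, index: bool = True) -> None:
    with open(path, "w") as fh:
        fh.write(f"# {header}\n")
        df.to_csv(fh, sep="\t", index=index)


def run_pipeline(config: PipelineConfig, out_dir: str | Path) -> Path:
    """Run every stage; returns the run directory."""
    config.validate_paths()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    header = f"depsig {__version__} config={config.digest()} seed={config.seed}"
    manifest: dict[str, object] = {"version": __version__, "config": config.digest(), "seed": config.seed, "stages": {}}
    stages: dict[str, int] = manifest["stages"]  # type: ignore[assignment]

    stage = "load"
    try:
        expr = read_expression(config.expression)
        design = read_design(config.design)
        sets = read_gmt(config.gmt)

        stage = "preprocess"
        m = quantile_normalize(expr)
        m, report = filter_expressed(m, config.min_median, config.min_sd)
        report.normalization = "quantile"
        if config.n_latent_factors:
            m = remove_latent_factors(m, design, config.n_latent_factors)
            report.factors_removed = config.n_latent_factors
        write_expression(m, out / "filtered.tsv", header)
        _write(report.to_frame(), out / "preprocess_report.tsv", header, index=False)
        stages["preprocess"] = m.shape[0]

        stage = "spls"
        baseline = design.samples(timepoint="baseline")
        mb = m.subset_samples(baseline)
        y = design.table.loc[baseline, "madrs"].to_numpy(dtype=float)
        spls_res = fit_spls(mb, y, keep_x=min(config.keep_x, m.shape[0]))
        sel = spls_res.selected.copy()
        sel["above_r_min"] = sel["r"].abs() > config.r_min
        _write(sel, out / "spls_selected.tsv", header)
        stages["spls"] = len(sel)

        stage = "diffexpr"
        de_results: dict[str, DEResult] = {
            "baseline-MDD-vs-nonMDD": unpaired_de(m, design, method=config.de_method),
            "paired-MDD": paired_de(m, design, "MDD", method=config.de_method),
            "paired-nonMDD": paired_de(m, design, "nonMDD", method=config.de_method),
        }
        for name, res in de_results.items():
            _write(res.table, out / f"de_{name}.tsv", f"{header} contrast={name} method={res.method}")
            stages[f"de:{name}"] = int((res.table["fdr"] <= config.fdr).sum())

        stage = "regulators"
        universe = m.gene_ids
        reg_tables = {}
        for name, res in de_results.items():
            if res.significant(config.fdr).empty:
                logger.info("regulators: no significant genes in %s, skipped", name)
                continue
            tab = score_regulators(res, sets, universe, fdr=config.fdr)
            reg_tables[name] = tab
            _write(tab, out / f"regulators_{name}.tsv", header)
        if len(reg_tables) >= 2:
            _write(compare_contrasts(reg_tables), out / "regulators_comparison.tsv", header)
        stages["regulators"] = len(reg_tables)

        stage = "toa"
        if config.reference:
            ref = read_expression(config.reference)
            scores_dx = diagnosticity(ref)
            lists = de_results["baseline-MDD-vs-nonMDD"].gene_lists(config.fdr)
            if lists["up"] or lists["down"]:
                toa_tab = toa_profile(
                    lists["up"], lists["down"], scores_dx, n_boot=config.n_boot, seed=config.seed
                )
                _write(toa_tab, out / "toa.tsv", header, index=False)
                stages["toa"] = len(toa_tab)
            else:
                logger.info("toa: no significant genes at baseline, skipped")
                stages["toa"] = 0
        else:
            stages["toa"] = 0

        stage = "composite"
        cohort_ids = (
            design.samples(timepoint="baseline") if config.cohort == "baseline-only" else m.sample_ids
        )
        z = zscore_matrix(m, [s for s in m.sample_ids if s in set(cohort_ids)])
        scores = composite_scores(z, sets, expressed=m.gene_ids)
        _write(scores, out / "composite_scores.tsv", header)
        stages["composite"] = scores.shape[0]

        stage = "evaluate"
        covs = [c for c in config.covariates if c in design.table.columns]
        anova_rows, reg_rows, delta_rows = [], [], []
        for reg in scores.columns:
            s = scores[reg]
            crude = regress_madrs(s, design)
            reg_rows.append({"regulator": reg, "model": "crude", "beta_std": crude.beta_std, "F": crude.F, "p": crude.p, "n": crude.n})
            if covs:
                adj = regress_madrs(s, design, covariates=covs)
                reg_rows.append({"regulator": reg, "model": "adjusted", "beta_std": adj.beta_std, "F": adj.F, "p": adj.p, "n": adj.n})
            if config.cohort == "all":
                an = two_way_anova(s, design)
                for eff in an.effects.index:
                    anova_rows.append({"regulator": reg, "effect": eff, **an.effects.loc[eff].to_dict()})
                dl = delta_regression(s, design)
                delta_rows.append({"regulator": reg, "beta_std": dl.beta_std, "F": dl.F, "p": dl.p, "n_pairs": dl.n})
        if anova_rows:
            _write(pd.DataFrame(anova_rows), out / "anova.tsv", header, index=False)
        _write(pd.DataFrame(reg_rows), out / "regressions.tsv", header, index=False)
        if delta_rows:
            _write(pd.DataFrame(delta_rows), out / "delta.tsv", header, index=False)
        _write(cohort_tests(design), out / "cohort_tests.tsv", header, index=False)
        stages["evaluate"] = len(reg_rows)
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return out
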