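import numpy as np
import pandas as pd
import pytest

from depsig import (
    cohort_tests,
    delta_regression,
    fisher_2x2,
    prevalence_pct,
    regress_madrs,
    two_way_anova,
)
from depsig.io import CohortDesign


def design_of(records):
    """records: (sample, patient, group, timepoint, madrs, extra-dict)"""
    rows = []
    for rec in records:
        extra = rec[5] if len(rec) > 5 else {}
        rows.append(
            {"sample_id": rec[0], "patient_id": rec[1], "group": rec[2], "timepoint": rec[3], "madrs": rec[4], **extra}
        )
    return CohortDesign(pd.DataFrame(rows).set_index("sample_id"))


def balanced_2x2_design(cells):
    """cells: dict (group, timepoint) -> score values; returns (score, design).

    Each observation gets its own patient; post-only observations receive a
    dummy baseline row (required by the pairing invariant) that carries no
    score and therefore never enters the ANOVA.
    """
    recs, scores = [], {}
    i = 0
    for (g, tp), values in cells.items():
        for v in values:
            pid = f"P{i}"
            if tp == "post":
                recs.append((f"{pid}_b", pid, g, "baseline", 10.0))
                sid = f"{pid}_p"
            else:
                sid = f"{pid}_b"
            recs.append((sid, pid, g, tp, 10.0))
            scores[sid] = v
            i += 1
    return pd.Series(scores, name="score"), design_of(recs)


def brute_force_anova(score, design):
    """Hand sums-of-squares for a balanced 2x2 with interaction."""
    d = design.table.loc[score.index]
    df = pd.DataFrame({"y": score, "g": d["group"], "t": d["timepoint"]})
    grand = df["y"].mean()
    cell = df.groupby(["g", "t"])["y"].mean()
    gm = df.groupby("g")["y"].mean()
    tm = df.groupby("t")["y"].mean()
    n_cell = df.groupby(["g", "t"])["y"].count()
    ss_int = sum(
        n_cell[c] * (cell[c] - gm[c[0]] - tm[c[1]] + grand) ** 2 for c in cell.index
    )
    sse = sum((row.y - cell[(row.g, row.t)]) ** 2 for row in df.itertuples())
    df_err = len(df) - 4
    return ss_int / 1, sse / df_err


class TestTwoWayAnova:
    def cells_fixture(self):
        return {
            ("MDD", "baseline"): [0.0, 2.0],
            ("MDD", "post"): [1.0, 3.0],
            ("nonMDD", "baseline"): [2.0, 4.0],
            ("nonMDD", "post"): [7.0, 9.0],
        }

    def test_hand_computed_interaction_f(self):
        score, design = balanced_2x2_design(self.cells_fixture())
        res = two_way_anova(score, design)
        assert res.effects.loc["interaction", "F"] == pytest.approx(4.0, abs=1e-9)
        assert res.effects.loc["interaction", "df1"] == 1
        assert res.effects.loc["interaction", "df2"] == 4

    def test_equal_cell_means_zero_interaction(self):
        cells = {
            ("MDD", "baseline"): [1.0, 3.0],
            ("MDD", "post"): [1.5, 2.5],
            ("nonMDD", "baseline"): [0.5, 3.5],
            ("nonMDD", "post"): [2.2, 1.8],
        }
        score, design = balanced_2x2_design(cells)
        res = two_way_anova(score, design)
        assert res.effects.loc["interaction", "F"] == pytest.approx(0.0, abs=1e-9)

    def test_matches_brute_force_on_random_balanced_data(self):
        rng = np.random.default_rng(0)
        for _ in range(5):
            cells = {
                ("MDD", "baseline"): list(rng.normal(0, 1, 4)),
                ("MDD", "post"): list(rng.normal(0.5, 1, 4)),
                ("nonMDD", "baseline"): list(rng.normal(-0.5, 1, 4)),
                ("nonMDD", "post"): list(rng.normal(1.0, 1, 4)),
            }
            score, design = balanced_2x2_design(cells)
            res = two_way_anova(score, design)
            ms_int, mse = brute_force_anova(score, design)
            assert res.effects.loc["interaction", "F"] == pytest.approx(ms_int / mse, abs=1e-9)

    def test_posthoc_bonferroni_never_below_raw(self, simulated):
        expr, design, sets, _ = simulated
        from depsig import composite_scores, zscore_matrix

        scores = composite_scores(zscore_matrix(expr), sets)
        res = two_way_anova(scores["TP53"], design)
        assert (res.posthoc["p_bonferroni"] >= res.posthoc["p_raw"] - 1e-15).all()
        assert len(res.posthoc) == 4

    def test_empty_cell_rejected(self):
        cells = {
            ("MDD", "baseline"): [1.0, 2.0],
            ("MDD", "post"): [1.0, 2.0],
            ("nonMDD", "baseline"): [1.0, 2.0],
        }
        score, design = balanced_2x2_design(cells)
        with pytest.raises(ValueError):
            two_way_anova(score, design)


class TestRegressMadrs:
    def test_closed_form_simple_regression(self):
        d = design_of(
            [(f"S{i}", f"P{i}", "MDD", "baseline", y) for i, y in enumerate([1.0, 2.0, 3.0, 5.0])]
        )
        score = pd.Series([1.0, 2.0, 3.0, 4.0], index=[f"S{i}" for i in range(4)], name="score")
        res = regress_madrs(score, d)
        assert res.beta_std == pytest.approx(0.98270, abs=1e-4)
        assert res.F == pytest.approx(res.beta_std**2 * 2 / (1 - res.beta_std**2), rel=1e-6)
        assert res.df == (1.0, 2.0)

    def test_beta_std_is_pearson_r_and_f_is_t_squared(self):
        rng = np.random.default_rng(1)
        n = 25
        score = pd.Series(rng.normal(0, 1, n), index=[f"S{i}" for i in range(n)], name="s")
        madrs = 5 + 2 * score.to_numpy() + rng.normal(0, 1, n)
        d = design_of([(f"S{i}", f"P{i}", "MDD", "baseline", madrs[i]) for i in range(n)])
        res = regress_madrs(score, d)
        r = np.corrcoef(score, madrs)[0, 1]
        assert res.beta_std == pytest.approx(r, rel=1e-9)
        assert abs(res.beta_std) <= 1

    def test_orthogonal_covariate_barely_moves_beta(self):
        rng = np.random.default_rng(2)
        n = 60
        score = rng.normal(0, 1, n)
        madrs = 10 + 3 * score + rng.normal(0, 1, n)
        cov = rng.normal(0, 1, n)  # independent of both
        d = design_of(
            [
                (f"S{i}", f"P{i}", "MDD", "baseline", madrs[i], {"age": cov[i]})
                for i in range(n)
            ]
        )
        s = pd.Series(score, index=[f"S{i}" for i in range(n)], name="s")
        crude = regress_madrs(s, d)
        adj = regress_madrs(s, d, covariates=["age"])
        assert abs(crude.beta_std - adj.beta_std) < 0.02

    def test_zero_variance_score_rejected(self):
        d = design_of([(f"S{i}", f"P{i}", "MDD", "baseline", float(i)) for i in range(5)])
        s = pd.Series(1.0, index=[f"S{i}" for i in range(5)])
        with pytest.raises(ValueError):
            regress_madrs(s, d)


class TestDeltaRegression:
    def _paired(self, score_pre, score_post, madrs_pre, madrs_post):
        recs, svals = [], {}
        for i in range(len(score_pre)):
            recs.append((f"P{i}_b", f"P{i}", "MDD", "baseline", madrs_pre[i]))
            recs.append((f"P{i}_p", f"P{i}", "MDD", "post", madrs_post[i]))
            svals[f"P{i}_b"] = score_pre[i]
            svals[f"P{i}_p"] = score_post[i]
        return pd.Series(svals, name="score"), design_of(recs)

    def test_collinear_deltas_beta_one(self):
        rng = np.random.default_rng(3)
        pre = rng.normal(1, 1, 6)
        post = rng.normal(0, 1, 6)
        # delta MADRS = 2 * delta score exactly
        score, design = self._paired(pre, post, 10 + 2 * (pre - post), np.full(6, 10.0))
        res = delta_regression(score, design)
        assert res.beta_std == pytest.approx(1.0, abs=1e-9)

    def test_too_few_pairs_rejected(self):
        score, design = self._paired([1.0, 2.0], [0.5, 1.0], [20.0, 18.0], [5.0, 6.0])
        with pytest.raises(ValueError):
            delta_regression(score, design)

    def test_shuffled_pairs_kill_association(self):
        """Permuting score deltas across patients leaves only chance association."""
        rng = np.random.default_rng(4)
        rejections = 0
        n_seeds = 600  # enough replicates that a calibrated 5% rate clears 7%
        for _ in range(n_seeds):
            n = 24
            d_score = rng.normal(0, 1, n)
            d_madrs = 8 + 4 * rng.normal(0, 1, n)  # independent of d_score
            pre = rng.normal(0, 1, n)
            score, design = self._paired(pre, pre - d_score, 10 + d_madrs, np.full(n, 10.0))
            res = delta_regression(score, design)
            rejections += res.p < 0.05
        assert rejections / n_seeds <= 0.07


class TestCohortHelpers:
    def test_prevalence_from_group_sizes(self):
        assert prevalence_pct(15, 33) == pytest.approx(45.4545, abs=1e-3)

    def test_remission_fisher_below_printed_bound(self):
        assert fisher_2x2([[15, 18], [0, 24]]) < 0.0006

    def test_cohort_table_identical_groups_degenerate(self):
        recs = [
            (f"S{i}", f"P{i}", g, "baseline", 10.0, {"age": 40.0, "sex": "F", "bmi": 42.0})
            for i, g in enumerate(["MDD"] * 3 + ["nonMDD"] * 3)
        ]
        tab = cohort_tests(design_of(recs))
        age_row = tab[tab["test"].str.startswith("age")].iloc[0]
        assert age_row["statistic"] == 0.0 and age_row["p"] == 1.0

    def test_cohort_table_on_simulated_design(self, simulated):
        _, design, _, _ = simulated
        tab = cohort_tests(design)
        prev = tab[tab["test"].str.contains("prevalence @ baseline")].iloc[0]
        assert prev["statistic"] == pytest.approx(prevalence_pct(15, 33))
        fisher = tab[tab["test"] == "MDD prevalence baseline vs post"].iloc[0]
        assert fisher["p"] < 0.0006
        bmi = tab[tab["test"] == "BMI pre vs post (paired)"].iloc[0]
        assert bmi["p"] < 1e-4 and bmi["statistic"] > 0
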