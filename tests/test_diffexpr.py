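import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from depsig import ExpressionMatrix, bh_adjust, paired_de, unpaired_de
from depsig.io import CohortDesign


def brute_force_bh(p):
    """Explicit min-over-suffix step-up, the independent oracle."""
    p = np.asarray(p, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    ranks = np.empty(m, dtype=int)
    ranks[order] = np.arange(1, m + 1)
    q = np.empty(m)
    for i in range(m):
        q[i] = min(min(p[j] * m / ranks[j] for j in range(m) if ranks[j] >= ranks[i]), 1.0)
    return q


def design_from(groups, timepoints, madrs=None):
    n = len(groups)
    rows = {
        "patient_id": [f"P{i}" for i in range(n)],
        "group": groups,
        "timepoint": timepoints,
        "madrs": madrs if madrs is not None else [10.0] * n,
    }
    return CohortDesign(pd.DataFrame(rows, index=[f"S{i}" for i in range(n)]))


def expr_from(rows, samples):
    arr = np.asarray(rows, dtype=float)
    return ExpressionMatrix(
        pd.DataFrame(arr, index=[f"G{i + 1}" for i in range(arr.shape[0])], columns=samples)
    )


class TestBhAdjust:
    @pytest.mark.parametrize(
        "p, expected",
        [
            ([0.01, 0.02, 0.03], [0.03, 0.03, 0.03]),
            ([0.04, 0.5], [0.08, 0.5]),
            ([0.2], [0.2]),
        ],
    )
    def test_hand_computed_step_up(self, p, expected):
        np.testing.assert_allclose(bh_adjust(p), expected)

    def test_agrees_with_brute_force_oracle(self):
        rng = np.random.default_rng(0)
        for _ in range(100):
            p = rng.uniform(0, 1, rng.integers(1, 40))
            np.testing.assert_allclose(bh_adjust(p), brute_force_bh(p), atol=1e-12)

    @given(st.lists(st.floats(min_value=0, max_value=1), min_size=1, max_size=25))
    @settings(max_examples=50, deadline=None)
    def test_bounds_and_monotonicity(self, p):
        q = bh_adjust(p)
        assert ((q >= 0) & (q <= 1)).all()
        order = np.argsort(p, kind="stable")
        assert (np.diff(q[order]) >= -1e-12).all()

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.2])


class TestUnpairedDe:
    def test_welch_closed_form(self):
        m = expr_from([[1, 2, 3, 2, 3, 4]], [f"S{i}" for i in range(6)])
        d = design_from(["MDD"] * 3 + ["nonMDD"] * 3, ["baseline"] * 6)
        res = unpaired_de(m, d)
        row = res.table.loc["G1"]
        assert row["t_stat"] == pytest.approx(-1.224744871, abs=1e-6)
        assert row["df"] == pytest.approx(4.0, abs=1e-9)
        assert row["log2fc"] == pytest.approx(-1.0)

    def test_identical_groups_degenerate(self):
        m = expr_from([[2, 3, 4, 2, 3, 4]], [f"S{i}" for i in range(6)])
        d = design_from(["MDD", "MDD", "MDD", "nonMDD", "nonMDD", "nonMDD"], ["baseline"] * 6)
        # same values but group assignment aligned -> identical means/vars
        res = unpaired_de(m, d)
        row = res.table.loc["G1"]
        assert row["t_stat"] == 0.0
        assert row["p"] == 1.0

    def test_constant_equal_groups_flagged(self):
        m = expr_from([[5, 5, 5, 5]], [f"S{i}" for i in range(4)])
        d = design_from(["MDD", "MDD", "nonMDD", "nonMDD"], ["baseline"] * 4)
        row = unpaired_de(m, d).table.loc["G1"]
        assert row["degenerate"] and row["t_stat"] == 0.0 and row["p"] == 1.0

    def test_contrast_antisymmetric(self, simulated):
        expr, design, _, _ = simulated
        a = unpaired_de(expr, design, ("MDD", "nonMDD"))
        b = unpaired_de(expr, design, ("nonMDD", "MDD"))
        ta = a.table.sort_index()
        tb = b.table.sort_index()
        np.testing.assert_allclose(ta["log2fc"], -tb["log2fc"], atol=1e-12)
        np.testing.assert_allclose(ta["t_stat"], -tb["t_stat"], atol=1e-10)
        np.testing.assert_allclose(ta["p"], tb["p"], atol=1e-12)
        np.testing.assert_allclose(ta["fdr"], tb["fdr"], atol=1e-12)

    def test_small_group_rejected(self):
        m = expr_from([[1, 2, 3]], ["S0", "S1", "S2"])
        d = design_from(["MDD", "nonMDD", "nonMDD"], ["baseline"] * 3)
        with pytest.raises(ValueError):
            unpaired_de(m, d)

    def test_moderated_mode_runs_and_shrinks(self, simulated):
        expr, design, _, _ = simulated
        res = unpaired_de(expr, design, method="moderated")
        assert res.method == "moderated"
        welch = unpaired_de(expr, design)
        assert (res.table["df"] >= welch.table["df"].min()).all()


class TestPairedDe:
    def _paired_setup(self, diffs):
        n = len(diffs)
        samples, rows_meta = [], []
        pre = np.full(n, 5.0)
        post = pre + np.asarray(diffs, dtype=float)
        values = []
        for i in range(n):
            samples += [f"P{i}_b", f"P{i}_p"]
            values += [pre[i], post[i]]
            rows_meta += [(f"P{i}", "MDD", "baseline"), (f"P{i}", "MDD", "post")]
        m = ExpressionMatrix(pd.DataFrame([values], index=["G1"], columns=samples))
        d = CohortDesign(
            pd.DataFrame(
                {
                    "patient_id": [r[0] for r in rows_meta],
                    "group": [r[1] for r in rows_meta],
                    "timepoint": [r[2] for r in rows_meta],
                    "madrs": 10.0,
                },
                index=samples,
            )
        )
        return m, d

    def test_one_sample_t_closed_form(self):
        m, d = self._paired_setup([1, 2, 3])
        row = paired_de(m, d, "MDD").table.loc["G1"]
        assert row["t_stat"] == pytest.approx(2 / (1 / np.sqrt(3)), abs=1e-9)
        assert row["df"] == 2

    def test_all_zero_differences_degenerate(self):
        m, d = self._paired_setup([0, 0, 0])
        row = paired_de(m, d, "MDD").table.loc["G1"]
        assert row["degenerate"] and row["t_stat"] == 0.0 and row["p"] == 1.0

    def test_dropout_excluded_and_counted(self, simulated):
        expr, design, _, _ = simulated
        res = paired_de(expr, design, "MDD")
        n_mdd_base = len(design.samples(group="MDD", timepoint="baseline"))
        n_pairs = len(design.paired_patients("MDD"))
        assert res.n_excluded == n_mdd_base - n_pairs
        assert res.n_samples == (n_pairs, n_pairs)

    def test_too_few_pairs_rejected(self):
        m, d = self._paired_setup([1])
        with pytest.raises(ValueError):
            paired_de(m, d, "MDD")


class TestNullCalibration:
    def test_empirical_fdr_under_null(self):
        """Complete null: the average false-discovery proportion stays near the nominal level."""
        from depsig import SimulationConfig, simulate_cohort

        fdps = []
        for seed in range(60):
            cfg = SimulationConfig(
                seed=seed, n_genes=400, targets_per_regulator=10, coupling_alpha=0.0,
                n_cell_types=2, markers_per_type=10,
            )
            expr, design, _, _ = simulate_cohort(cfg)
            res = unpaired_de(expr, design)
            n_disc = int((res.table["fdr"] <= 0.05).sum())
            fdps.append(1.0 if n_disc else 0.0)  # every discovery is false under the null
        assert np.mean(fdps) <= 0.075
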