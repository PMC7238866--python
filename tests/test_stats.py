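"""Repeated-measures ANOVA, Greenhouse-Geisser, OLS / adjusted R^2."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from tvor.stats import gg_epsilon, ols_adjusted_r2, relabel_direction, rm_anova


def _long(values, factors, subject_col="subject"):
    """Build a long table from an array shaped (subjects, l1, l2, ...)."""
    values = np.asarray(values, float)
    n = values.shape[0]
    levels = [list(range(1, s + 1)) for s in values.shape[1:]]
    rows = []
    for s in range(n):
        for idx in np.ndindex(*values.shape[1:]):
            row = {subject_col: s + 1, "y": values[(s,) + idx]}
            for f, lv, i in zip(factors, levels, idx):
                row[f] = lv[i]
            rows.append(row)
    return pd.DataFrame(rows)


class TestRmAnova:
    def test_two_level_factor_equals_paired_t(self):
        rng = np.random.default_rng(42)
        y = rng.normal(size=(12, 2)) + [0.0, 0.4]
        table = rm_anova(_long(y, ["cond"]), dv="y", within=["cond"])
        t, p = sps.ttest_rel(y[:, 0], y[:, 1])
        assert table.F.iloc[0] == pytest.approx(t ** 2, abs=1e-8)
        assert table.p_uncorrected.iloc[0] == pytest.approx(p, abs=1e-10)
        assert table.epsilon_gg.iloc[0] == 1.0   # two levels: epsilon fixed

    def test_one_way_against_brute_force_oracle(self):
        rng = np.random.default_rng(7)
        y = rng.normal(size=(8, 4)) + np.array([0, 0.3, 0.5, 0.1])
        table = rm_anova(_long(y, ["f"]), dv="y", within=["f"])
        # classical cell-means oracle
        gm = y.mean()
        ss_cond = y.shape[0] * ((y.mean(axis=0) - gm) ** 2).sum()
        ss_subj = y.shape[1] * ((y.mean(axis=1) - gm) ** 2).sum()
        ss_tot = ((y - gm) ** 2).sum()
        ss_err = ss_tot - ss_cond - ss_subj
        F = (ss_cond / 3) / (ss_err / 21)
        assert table.F.iloc[0] == pytest.approx(F, abs=1e-8)

    def test_matches_pingouin_two_way(self):
        pg = pytest.importorskip("pingouin")
        rng = np.random.default_rng(3)
        y = rng.normal(size=(10, 3, 4))
        y += rng.normal(size=(1, 3, 4))          # random cell effects
        df = _long(y, ["a", "b"])
        ours = rm_anova(df, dv="y", within=["a", "b"]).set_index("effect")
        ref = pg.rm_anova(data=df, dv="y", within=["a", "b"],
                          subject="subject", detailed=True)
        pairs = {"a": "a", "b": "b", "a x b": "a * b"}
        for mine, theirs in pairs.items():
            r = ref[ref.Source == theirs].iloc[0]
            assert ours.loc[mine, "F"] == pytest.approx(r["F"], rel=1e-6)
            assert ours.loc[mine, "p_uncorrected"] == pytest.approx(
                r["p_unc"], rel=1e-6)
            assert ours.loc[mine, "eta_g_squared"] == pytest.approx(
                r["ng2"], rel=1e-6)

    def test_three_way_runs_and_has_seven_effects(self):
        rng = np.random.default_rng(5)
        y = rng.normal(size=(6, 3, 2, 2))
        table = rm_anova(_long(y, ["a", "b", "c"]), dv="y",
                         within=["a", "b", "c"])
        assert len(table) == 7
        assert set(table.df_num) == {2, 1}

    def test_constant_dv(self):
        y = np.full((5, 3), 2.0)
        table = rm_anova(_long(y, ["f"]), dv="y", within=["f"])
        assert np.isnan(table.F.iloc[0])
        assert table.eta_g_squared.iloc[0] == 0.0

    def test_eta_g_invariant_to_affine_rescaling(self):
        rng = np.random.default_rng(9)
        y = rng.normal(size=(9, 4)) + np.array([0, 1, 0, 2])
        e1 = rm_anova(_long(y, ["f"]), dv="y", within=["f"]).eta_g_squared
        e2 = rm_anova(_long(3.5 * y - 7, ["f"]), dv="y",
                      within=["f"]).eta_g_squared
        assert np.allclose(e1, e2)

    def test_injected_frequency_effect_detected(self):
        # Experiment A-shaped design: 5 frequencies x 6 cycles, 20 subjects
        rng = np.random.default_rng(1)
        effect = np.linspace(0, 30, 5)[:, None]             # ms across frequency
        y = rng.normal(scale=8.0, size=(20, 5, 6)) + effect
        y += rng.normal(scale=5.0, size=(20, 1, 1))         # subject offsets
        table = rm_anova(_long(y, ["frequency", "cycle"]), dv="y",
                         within=["frequency", "cycle"]).set_index("effect")
        assert table.loc["frequency", "p_gg"] < 0.001
        assert table.loc["frequency", "eta_g_squared"] > 0

    def test_missing_cells_rejected(self):
        y = np.random.default_rng(0).normal(size=(5, 3))
        df = _long(y, ["f"]).iloc[:-1]
        with pytest.raises(ValueError):
            rm_anova(df, dv="y", within=["f"])

    def test_too_few_subjects_rejected(self):
        y = np.zeros((2, 3))
        with pytest.raises(ValueError):
            rm_anova(_long(y, ["f"]), dv="y", within=["f"])

    def test_gg_corrected_type_one_error_controlled(self):
        # null simulations with a non-spherical covariance
        rng = np.random.default_rng(123)
        k, n, reps, alpha = 4, 10, 400, 0.05
        cov = np.diag([1.0, 1.0, 3.0, 6.0])
        rejections = 0
        chol = np.linalg.cholesky(cov)
        for _ in range(reps):
            y = rng.normal(size=(n, k)) @ chol.T
            p = rm_anova(_long(y, ["f"]), dv="y", within=["f"]).p_gg.iloc[0]
            rejections += p < alpha
        rate = rejections / reps
        assert rate <= alpha + 2.5 * np.sqrt(alpha * (1 - alpha) / reps)


class TestGgEpsilon:
    def test_compound_symmetry_gives_one(self):
        cov = 0.5 * np.ones((4, 4)) + 0.5 * np.eye(4)
        assert gg_epsilon(cov) == pytest.approx(1.0)

    def test_two_levels_gives_one(self):
        assert gg_epsilon(np.array([[2.0, 0.3], [0.3, 1.0]])) == 1.0

    def test_fixed_matrix_against_formula_oracle(self):
        cov = np.array([[4.0, 1.0, 0.5],
                        [1.0, 2.0, 0.2],
                        [0.5, 0.2, 1.0]])
        # direct evaluation of the classical epsilon formula
        k = 3
        dbar = np.diag(cov).mean()
        mbar = cov.mean()
        row = cov.mean(axis=1)
        num = (k * (dbar - mbar)) ** 2
        den = (k - 1) * ((cov ** 2).sum() - 2 * k * (row ** 2).sum()
                         + k ** 2 * mbar ** 2)
        assert gg_epsilon(cov) == pytest.approx(num / den, abs=1e-10)

    def test_bounded_below(self):
        cov = np.diag([1.0, 1e-6, 1e-6, 1e-6])
        assert gg_epsilon(cov) >= 1.0 / 3.0

    def test_asymmetric_rejected(self):
        with pytest.raises(ValueError):
            gg_epsilon(np.array([[1.0, 0.5], [0.1, 1.0]]))


class TestOls:
    def test_perfect_plane(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(30, 2))
        y = 1.0 + 2.0 * X[:, 0] - 0.5 * X[:, 1]
        out = ols_adjusted_r2(y, X, names=["a", "b"])
        assert out["adj_r2"] == pytest.approx(1.0)
        assert out["coefficients"]["a"] == pytest.approx(2.0)

    def test_null_model_near_zero(self):
        rng = np.random.default_rng(1)
        out = ols_adjusted_r2(rng.normal(size=2000), rng.normal(size=(2000, 2)))
        assert abs(out["adj_r2"]) < 0.05

    def test_collinear_rejected(self):
        X = np.ones((20, 2)); X[:, 0] = np.arange(20); X[:, 1] = 2 * X[:, 0]
        with pytest.raises(ValueError):
            ols_adjusted_r2(np.arange(20.0), X)

    def test_underdetermined_rejected(self):
        with pytest.raises(ValueError):
            ols_adjusted_r2(np.zeros(3), np.zeros((3, 2)))

    def test_per_coefficient_f_is_t_squared(self):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(50, 2))
        y = X[:, 0] + rng.normal(size=50)
        out = ols_adjusted_r2(y, X)
        assert (out["table"]["F"] >= 0).all()


class TestRelabelDirection:
    def test_parity_rule(self):
        df = pd.DataFrame({
            "cycle_index": [1, 2, 1, 2],
            "start_condition": ["dorsiflexion", "dorsiflexion",
                                "plantarflexion", "plantarflexion"],
        })
        out = relabel_direction(df)
        assert list(out.direction) == ["up", "down", "down", "up"]

    def test_pairs_conditions_complementarily(self):
        # odd dorsiflexion half-cycles pool with even plantarflexion ones
        df = pd.DataFrame({
            "cycle_index": list(range(1, 23)) * 2,
            "start_condition": ["dorsiflexion"] * 22 + ["plantarflexion"] * 22,
        })
        out = relabel_direction(df)
        up = out[out.direction == "up"]
        assert len(up) == 22
        assert (up[up.start_condition == "dorsiflexion"].cycle_index % 2 == 1).all()
        assert (up[up.start_condition == "plantarflexion"].cycle_index % 2 == 0).all()
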