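"""Repeated-measures harness vs independent oracles (hand formulas,
brute-force decompositions, and pingouin as an external cross-check)."""

import numpy as np
import pandas as pd
import pingouin as pg
import pytest
from scipy import stats as sps

from vizreach.stats import (
    aggregate_cells,
    friedman_kendall,
    greenhouse_geisser_epsilon,
    mauchly_test,
    partial_eta_squared,
    posthoc_paired,
    rm_anova_1way,
    rm_anova_2way,
    rm_manova_oneway,
)

CONDS = ["IVR", "AR", "Screen"]
DEPTHS = ["no_depth", "only_depth", "combined_depth"]


def _random_table(n, seed, conds=CONDS, depths=DEPTHS):
    rng = np.random.default_rng(seed)
    rows = []
    for i in range(n):
        for c in conds:
            for d in depths:
                rows.append((f"s{i}", c, d, rng.normal()))
    return pd.DataFrame(rows, columns=["participant", "condition", "depth_class", "value"])


def _brute_force_ss(table):
    """Independent SS decomposition by explicit looping over level means."""
    subs = sorted(table["participant"].unique())
    conds = sorted(table["condition"].unique())
    depths = sorted(table["depth_class"].unique())
    val = {
        (r.participant, r.condition, r.depth_class): r.value
        for r in table.itertuples()
    }
    n, a, b = len(subs), len(conds), len(depths)
    grand = np.mean(list(val.values()))
    ma = {c: np.mean([val[s, c, d] for s in subs for d in depths]) for c in conds}
    mb = {d: np.mean([val[s, c, d] for s in subs for c in conds]) for d in depths}
    ms = {s: np.mean([val[s, c, d] for c in conds for d in depths]) for s in subs}
    mab = {(c, d): np.mean([val[s, c, d] for s in subs]) for c in conds for d in depths}
    msa = {(s, c): np.mean([val[s, c, d] for d in depths]) for s in subs for c in conds}
    msb = {(s, d): np.mean([val[s, c, d] for c in conds]) for s in subs for d in depths}
    ss_a = n * b * sum((ma[c] - grand) ** 2 for c in conds)
    ss_b = n * a * sum((mb[d] - grand) ** 2 for d in depths)
    ss_as = b * sum((msa[s, c] - ma[c] - ms[s] + grand) ** 2 for s in subs for c in conds)
    ss_bs = a * sum((msb[s, d] - mb[d] - ms[s] + grand) ** 2 for s in subs for d in depths)
    ss_ab = n * sum(
        (mab[c, d] - ma[c] - mb[d] + grand) ** 2 for c in conds for d in depths
    )
    ss_abs = sum(
        (
            val[s, c, d] - mab[c, d] - msa[s, c] - msb[s, d]
            + ma[c] + mb[d] + ms[s] - grand
        ) ** 2
        for s in subs for c in conds for d in depths
    )
    return {
        "condition": (ss_a, ss_as, a - 1, (a - 1) * (n - 1)),
        "depth_class": (ss_b, ss_bs, b - 1, (b - 1) * (n - 1)),
        "condition:depth_class": (
            ss_ab, ss_abs, (a - 1) * (b - 1), (a - 1) * (b - 1) * (n - 1)
        ),
    }


class TestRmAnova2Way:
    @pytest.mark.parametrize("seed", range(5))
    def test_f_matches_brute_force_oracle(self, seed):
        table = _random_table(5, seed)
        res = rm_anova_2way(table)
        for name, (ss_e, ss_err, df1, df2) in _brute_force_ss(table).items():
            eff = res.effects[name]
            expected_F = (ss_e / df1) / (ss_err / df2)
            assert eff.F == pytest.approx(expected_F, rel=1e-8)
            assert eff.ss_effect == pytest.approx(ss_e, rel=1e-8)
            assert eff.partial_eta_sq == pytest.approx(ss_e / (ss_e + ss_err), rel=1e-8)

    def test_matches_pingouin(self):
        table = _random_table(9, 42)
        res = rm_anova_2way(table)
        pgr = pg.rm_anova(
            data=table, dv="value", within=["condition", "depth_class"],
            subject="participant", detailed=True, effsize="np2",
        ).set_index("Source")
        for name, key in [
            ("condition", "condition"),
            ("depth_class", "depth_class"),
            ("condition:depth_class", "condition * depth_class"),
        ]:
            assert res.effects[name].F == pytest.approx(pgr.loc[key, "F"], rel=1e-9)
            assert res.effects[name].p == pytest.approx(pgr.loc[key, "p_unc"], rel=1e-9)
            assert res.effects[name].partial_eta_sq == pytest.approx(
                pgr.loc[key, "np2"], rel=1e-9
            )

    def test_location_invariance(self):
        table = _random_table(6, 1)
        shifted = table.assign(value=table["value"] + 17.3)
        a = rm_anova_2way(table)
        b = rm_anova_2way(shifted)
        for name in a.effects:
            assert a.effects[name].F == pytest.approx(b.effects[name].F, rel=1e-9)

    def test_participant_label_permutation_invariance(self):
        table = _random_table(6, 2)
        relabeled = table.assign(
            participant=table["participant"].map(
                {f"s{i}": f"p{99 - i}" for i in range(6)}
            )
        )
        a = rm_anova_2way(table)
        b = rm_anova_2way(relabeled)
        for name in a.effects:
            assert a.effects[name].F == pytest.approx(b.effects[name].F, rel=1e-9)

    def test_row_order_invariance(self):
        table = _random_table(6, 3)
        shuffled = table.sample(frac=1.0, random_state=0)
        a = rm_anova_2way(table)
        b = rm_anova_2way(shuffled)
        for name in a.effects:
            assert a.effects[name].F == pytest.approx(b.effects[name].F, rel=1e-12)

    def test_missing_cells_rejected_with_listing(self):
        table = _random_table(5, 4).iloc[:-1]
        with pytest.raises(ValueError, match="missing cells"):
            rm_anova_2way(table)


class TestEpsilonAndMauchly:
    def test_compound_symmetry_gives_one(self):
        S = 0.3 * np.ones((3, 3)) + 0.7 * np.eye(3)
        assert greenhouse_geisser_epsilon(S) == pytest.approx(1.0)

    @pytest.mark.parametrize("seed", range(10))
    def test_lower_bound_for_three_levels(self, seed):
        rng = np.random.default_rng(seed)
        A = rng.normal(size=(3, 3))
        eps = greenhouse_geisser_epsilon(A @ A.T)
        assert 0.5 - 1e-12 <= eps <= 1.0 + 1e-12

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_double_centering_formula(self, seed):
        # independent oracle: Box's epsilon via the double-centered
        # covariance matrix eigen-form
        rng = np.random.default_rng(seed)
        A = rng.normal(size=(4, 4))
        S = A @ A.T
        k = 4
        J = np.eye(k) - np.ones((k, k)) / k
        Sc = J @ S @ J
        lam = np.linalg.eigvalsh(Sc)
        oracle = lam.sum() ** 2 / ((k - 1) * (lam**2).sum())
        assert greenhouse_geisser_epsilon(S) == pytest.approx(oracle, rel=1e-10)

    def test_epsilon_matches_pingouin_oneway(self):
        rng = np.random.default_rng(7)
        data = pd.DataFrame(rng.normal(size=(12, 3)), columns=CONDS)
        eps_pg = pg.epsilon(data, correction="gg")
        long = data.reset_index().melt(
            id_vars="index", var_name="condition", value_name="value"
        ).rename(columns={"index": "participant"})
        res = rm_anova_1way(long)
        assert res.effects["condition"].eps == pytest.approx(eps_pg, rel=1e-9)

    def test_mauchly_matches_pingouin(self):
        rng = np.random.default_rng(8)
        data = pd.DataFrame(rng.normal(size=(15, 3)), columns=CONDS)
        spher = pg.sphericity(data)
        scores = data.to_numpy() @ np.array(
            [[1, -1, 0], [0.5, 0.5, -1]]
        ).T  # any contrasts spanning the same space give the same W
        from scipy.linalg import helmert

        W, p = mauchly_test(data.to_numpy() @ helmert(3, full=False).T)
        assert W == pytest.approx(spher.W, rel=1e-6)
        assert p == pytest.approx(spher.pval, rel=1e-6)


class TestManova:
    def _long(self, wide):
        return wide.reset_index().melt(
            id_vars="index", var_name="condition", value_name="value"
        ).rename(columns={"index": "participant"})

    def test_single_dv_two_conditions_equals_paired_t(self):
        rng = np.random.default_rng(0)
        wide = pd.DataFrame(rng.normal(size=(10, 2)), columns=["IVR", "Screen"])
        res = rm_manova_oneway({"dv": self._long(wide)})
        t, p = sps.ttest_rel(wide["IVR"], wide["Screen"])
        uni = rm_anova_1way(self._long(wide))
        assert res.F == pytest.approx(t**2, rel=1e-9)
        assert res.F == pytest.approx(uni.effects["condition"].F, rel=1e-9)
        assert res.p == pytest.approx(p, rel=1e-9)

    def test_single_dv_three_conditions_equals_hotelling(self):
        rng = np.random.default_rng(1)
        wide = pd.DataFrame(rng.normal(size=(12, 3)), columns=CONDS)
        res = rm_manova_oneway({"dv": self._long(wide)})
        # brute-force oracle: Hotelling's T^2 on the two difference scores
        d = np.column_stack(
            [wide.iloc[:, 0] - wide.iloc[:, 1], wide.iloc[:, 1] - wide.iloc[:, 2]]
        )
        n = len(d)
        T2 = n * d.mean(0) @ np.linalg.solve(np.cov(d, rowvar=False), d.mean(0))
        assert res.wilks_lambda == pytest.approx(1 / (1 + T2 / (n - 1)), rel=1e-9)

    @pytest.mark.parametrize("seed", range(3))
    def test_lambda_matches_determinant_ratio(self, seed):
        rng = np.random.default_rng(seed)
        tables = {}
        raw = {}
        for dv in ("a", "b"):
            wide = pd.DataFrame(rng.normal(size=(8, 3)), columns=CONDS)
            raw[dv] = wide
            tables[dv] = self._long(wide)
        res = rm_manova_oneway(tables)
        from scipy.linalg import helmert

        C = helmert(3, full=False)
        Y = np.hstack([raw[dv].to_numpy() @ C.T for dv in ("a", "b")])
        yb = Y.mean(0)
        E = (Y - yb).T @ (Y - yb)
        H = len(Y) * np.outer(yb, yb)
        assert res.wilks_lambda == pytest.approx(
            np.linalg.det(E) / np.linalg.det(E + H), rel=1e-9
        )
        assert res.partial_eta_sq == pytest.approx(1 - res.wilks_lambda, rel=1e-12)

    def test_identical_conditions_lambda_one(self):
        base = pd.DataFrame(
            np.tile(np.arange(6, dtype=float)[:, None], (1, 3)), columns=CONDS
        )
        res = rm_manova_oneway({"dv": self._long(base)})
        assert res.wilks_lambda == 1.0

    def test_too_many_dvs_rejected(self):
        rng = np.random.default_rng(2)
        tables = {
            f"dv{i}": self._long(pd.DataFrame(rng.normal(size=(5, 3)), columns=CONDS))
            for i in range(4)
        }
        with pytest.raises(ValueError, match="error degrees of freedom"):
            rm_manova_oneway(tables)


class TestFriedman:
    def test_perfect_concordance(self):
        # every participant orders the conditions identically, no ties
        X = np.array([[1, 2, 3], [4, 6, 8], [0, 5, 9], [2, 3, 4]], dtype=float)
        res = friedman_kendall(X)
        assert res.kendalls_W == pytest.approx(1.0)
        assert res.chi_sq == pytest.approx(len(X) * (3 - 1))

    def test_all_equal_gives_zero(self):
        res = friedman_kendall(np.ones((5, 3)))
        assert res.chi_sq == 0.0 and res.kendalls_W == 0.0

    def test_hand_computed_4x3(self):
        X = np.array([[1, 2, 3], [2, 1, 3], [1, 3, 2], [1, 2, 3]], dtype=float)
        # rank sums: [5, 8, 11]; chi2 = 12/(4*3*4) * (25+64+121) - 3*4*4 = 4.5
        res = friedman_kendall(X)
        assert res.chi_sq == pytest.approx(4.5)
        assert res.kendalls_W == pytest.approx(4.5 / (4 * 2))

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_scipy_with_ties(self, seed):
        rng = np.random.default_rng(seed)
        X = rng.integers(0, 5, size=(8, 4)).astype(float)
        if np.all(np.ptp(X, axis=1) == 0):
            return
        res = friedman_kendall(X)
        chi2, p = sps.friedmanchisquare(*X.T)
        assert res.chi_sq == pytest.approx(chi2, rel=1e-10)
        assert res.p == pytest.approx(p, rel=1e-10)

    def test_two_conditions_equals_sign_test_chi2(self):
        rng = np.random.default_rng(3)
        X = rng.normal(size=(12, 2))
        res = friedman_kendall(X)
        signs = np.sign(X[:, 0] - X[:, 1])
        n_pos, n_neg = np.sum(signs > 0), np.sum(signs < 0)
        assert res.chi_sq == pytest.approx((n_pos - n_neg) ** 2 / len(X))

    def test_invariants(self):
        rng = np.random.default_rng(4)
        X = rng.normal(size=(10, 3))
        res = friedman_kendall(X)
        assert 0 <= res.kendalls_W <= 1
        assert res.kendalls_W == pytest.approx(res.chi_sq / (10 * 2))

    def test_missing_cells_rejected(self):
        X = np.ones((4, 3))
        X[0, 0] = np.nan
        with pytest.raises(ValueError):
            friedman_kendall(X)


class TestPosthoc:
    def test_bonferroni_arithmetic(self):
        rng = np.random.default_rng(0)
        wide = pd.DataFrame(rng.normal(size=(10, 3)), columns=CONDS)
        results = posthoc_paired(wide)
        assert len(results) == 3
        for r in results:
            assert r.p_adjusted == pytest.approx(min(1.0, 3 * r.p_raw))
            assert r.p_adjusted >= r.p_raw

    def test_t_and_dz_match_hand_formulas(self):
        rng = np.random.default_rng(1)
        wide = pd.DataFrame(rng.normal(size=(14, 2)), columns=["IVR", "Screen"])
        (r,) = posthoc_paired(wide)
        d = wide["IVR"] - wide["Screen"]
        t_hand = d.mean() / (d.std(ddof=1) / np.sqrt(len(d)))
        assert r.t == pytest.approx(t_hand, rel=1e-10)
        assert r.cohen_d == pytest.approx(d.mean() / d.std(ddof=1), rel=1e-10)
        t_sp, p_sp = sps.ttest_rel(wide["IVR"], wide["Screen"])
        assert r.t == pytest.approx(t_sp, rel=1e-10)
        assert r.p_raw == pytest.approx(p_sp, rel=1e-10)

    def test_dav_convention(self):
        rng = np.random.default_rng(2)
        wide = pd.DataFrame(rng.normal(size=(10, 2)), columns=["a", "b"])
        (r,) = posthoc_paired(wide, d_convention="dav")
        d = wide["a"] - wide["b"]
        expected = d.mean() / ((wide["a"].std(ddof=1) + wide["b"].std(ddof=1)) / 2)
        assert r.cohen_d == pytest.approx(expected, rel=1e-10)

    def test_constant_shift_degenerate(self):
        x = np.arange(8, dtype=float)
        wide = pd.DataFrame({"a": x, "b": x + 2.0})
        (r,) = posthoc_paired(wide)
        assert r.degenerate
        assert np.isinf(r.t) and r.t < 0
        assert r.p_raw == 0.0


class TestPartialEtaSquared:
    @pytest.mark.parametrize(
        "ss_e,ss_err,expected", [(3, 9, 0.25), (5, 0, 1.0), (0, 4, 0.0)]
    )
    def test_examples(self, ss_e, ss_err, expected):
        assert partial_eta_squared(ss_e, ss_err) == expected

    def test_both_zero_rejected(self):
        with pytest.raises(ValueError):
            partial_eta_squared(0, 0)


def test_aggregate_cells_excludes_missing_listwise_per_metric():
    df = pd.DataFrame(
        {
            "participant": ["a", "a", "b", "b"],
            "condition": ["IVR", "IVR", "IVR", "IVR"],
            "depth_class": ["no_depth"] * 4,
            "onset_s": [0.2, np.nan, 0.3, 0.5],
        }
    )
    cells = aggregate_cells(df, "onset_s")
    assert len(cells) == 2
    assert cells.loc[cells["participant"] == "a", "value"].iloc[0] == pytest.approx(0.2)
    assert cells.loc[cells["participant"] == "b", "value"].iloc[0] == pytest.approx(0.4)
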