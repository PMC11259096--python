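"""Routed statistics: gates, omnibus tests, post-hoc tables, calibration."""

from itertools import combinations

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from angiokit.stats import (
    GroupData,
    anova_tukey,
    dunn_posthoc,
    games_howell,
    gate_assumptions,
    route_and_test,
    trimmed_welch_f,
    welch_anova,
)


def normal_groups(rng, k=3, n=50, sds=None):
    sds = sds or [1.0] * k
    return GroupData({f"g{i}": rng.normal(0, sds[i], n) for i in range(k)})


class TestGate:
    def test_gaussian_groups_pass_both_gates(self):
        data = normal_groups(np.random.default_rng(1))
        normal, homo, ev = gate_assumptions(data)
        assert normal and homo
        assert ev["variance_test"] == "bartlett"
        # gate p-values are exactly the reference implementations'
        for label, vals in data.groups.items():
            assert ev["normality_pvalues"][label] == sps.shapiro(vals).pvalue
        assert ev["variance_pvalue"] == sps.bartlett(*data.arrays()).pvalue

    def test_exponential_group_flags_non_normal(self, rng):
        data = GroupData(
            {
                "a": rng.normal(0, 1, 50),
                "b": rng.exponential(1, 50),
                "c": rng.normal(0, 1, 50),
            }
        )
        normal, _, ev = gate_assumptions(data)
        assert not normal
        assert ev["variance_test"] == "levene_median"

    def test_identical_groups_trivially_homoscedastic(self):
        x = [1.0, 2.0, 3.0, 4.0, 5.0]
        data = GroupData({"a": x, "b": x, "c": x})
        _, homo, _ = gate_assumptions(data)
        assert homo

    def test_small_groups_get_low_power_warning(self, rng):
        data = GroupData({f"g{i}": rng.normal(0, 1, 4) for i in range(3)})
        _, _, ev = gate_assumptions(data)
        assert any("low power" in w for w in ev["warnings"])

    def test_too_small_group_rejected(self):
        with pytest.raises(ValueError):
            gate_assumptions(GroupData({"a": [1.0, 2.0], "b": [1.0, 3.0, 4.0]}))


class TestWelchAnova:
    def test_two_groups_equals_welch_t_test(self, rng):
        data = GroupData({"a": rng.normal(0, 1, 8), "b": rng.normal(1, 2, 12)})
        w = welch_anova(data)
        t = sps.ttest_ind(*data.arrays(), equal_var=False)
        assert w.statistic == pytest.approx(t.statistic**2, abs=1e-10)
        assert w.pvalue == pytest.approx(t.pvalue, abs=1e-10)

    def test_matches_pingouin_reference(self, rng):
        pg = pytest.importorskip("pingouin")
        data = normal_groups(rng, sds=[1.0, 2.0, 0.5])
        df = pd.concat(
            [pd.DataFrame({"g": k, "v": v}) for k, v in data.groups.items()]
        )
        ref = pg.welch_anova(dv="v", between="g", data=df)
        mine = welch_anova(data)
        assert mine.pvalue == pytest.approx(float(ref["p_unc"][0]), abs=1e-12)
        assert mine.statistic == pytest.approx(float(ref["F"][0]), abs=1e-10)

    def test_location_shift_invariance(self, rng):
        data = normal_groups(rng)
        shifted = GroupData({k: v + 1000.0 for k, v in data.groups.items()})
        assert welch_anova(shifted).statistic == pytest.approx(
            welch_anova(data).statistic
        )


class TestTrimmedWelch:
    def test_trim_zero_reduces_to_welch(self, rng):
        data = normal_groups(rng, sds=[1.0, 3.0, 0.7])
        t0 = trimmed_welch_f(data, trim=0.0)
        w = welch_anova(data)
        assert t0.statistic == pytest.approx(w.statistic, abs=1e-10)
        assert t0.pvalue == pytest.approx(w.pvalue, abs=1e-10)

    def test_symmetric_data_close_to_untrimmed(self):
        data = normal_groups(np.random.default_rng(0), n=40)
        p_trim = trimmed_welch_f(data, trim=0.2).pvalue
        p_welch = welch_anova(data).pvalue
        assert p_trim == pytest.approx(p_welch, rel=0.10)

    def test_single_gross_outlier_stability(self):
        rng = np.random.default_rng(3)
        base = {f"g{i}": rng.normal([0, 0, 1.5][i], 1, 15) for i in range(3)}
        clean = GroupData({k: v.copy() for k, v in base.items()})
        spoiled_arrays = {k: v.copy() for k, v in base.items()}
        spoiled_arrays["g0"][0] = 50.0
        spoiled = GroupData(spoiled_arrays)
        # the outlier falls inside the trimmed fraction: trimmed p unmoved
        dt = abs(
            trimmed_welch_f(spoiled, 0.2).pvalue - trimmed_welch_f(clean, 0.2).pvalue
        )
        dw = abs(welch_anova(spoiled).pvalue - welch_anova(clean).pvalue)
        assert dt < 1e-6
        assert dw > 0.01
        assert dt < dw

    def test_over_trimming_rejected(self):
        data = GroupData({"a": [1.0, 2.0, 3.0], "b": [2.0, 3.0, 4.0]})
        with pytest.raises(ValueError):
            trimmed_welch_f(data, trim=0.4)


class TestGamesHowell:
    def test_equal_groups_p_near_one(self, rng):
        x = rng.normal(0, 1, 30)
        data = GroupData({"a": x, "b": x + 1e-9 * rng.normal(size=30)})
        table = games_howell(data)
        assert table["p_raw"].iloc[0] > 0.99

    def test_matches_pingouin_to_1e10(self, rng):
        pg = pytest.importorskip("pingouin")
        data = normal_groups(rng, sds=[1.0, 2.0, 0.5], n=12)
        df = pd.concat(
            [pd.DataFrame({"g": k, "v": v}) for k, v in data.groups.items()]
        )
        ref = pg.pairwise_gameshowell(dv="v", between="g", data=df)
        mine = games_howell(data)
        ref_p = np.sort(ref["pval"].to_numpy())
        my_p = np.sort(mine["p_raw"].to_numpy())
        assert np.max(np.abs(ref_p - my_p)) < 1e-10

    def test_agrees_with_tukey_under_equal_variance_equal_n(self, rng):
        # identical sample variances by construction (shifted copies)
        x = rng.normal(0, 1, 50)
        data = GroupData({"a": x, "b": x + 0.25, "c": x + 0.12})
        gh = games_howell(data)["p_raw"].to_numpy()
        tk = anova_tukey(data)["p_raw"].to_numpy()
        assert np.max(np.abs(gh - tk) / tk) < 0.05

    def test_zero_variance_pair_rejected(self):
        data = GroupData({"a": [1.0, 1.0, 1.0], "b": [2.0, 2.0, 2.0]})
        with pytest.raises(ValueError):
            games_howell(data)


class TestDunn:
    def test_identical_groups_z_zero_p_one(self):
        data = GroupData({"a": [1.0, 2.0, 3.0], "b": [1.0, 2.0, 3.0]})
        table = dunn_posthoc(data)
        assert table["statistic"].iloc[0] == pytest.approx(0.0)
        assert table["p_raw"].iloc[0] == pytest.approx(1.0)

    def test_shifted_group_found_null_pair_not(self, rng):
        data = GroupData(
            {
                "a": rng.normal(0, 1, 20),
                "b": rng.normal(0, 1, 20),
                "c": rng.normal(8, 1, 20),
            }
        )
        t = dunn_posthoc(data).set_index(["group1", "group2"])
        assert t.loc[("a", "c"), "p_adj"] < 0.05
        assert t.loc[("b", "c"), "p_adj"] < 0.05
        assert t.loc[("a", "b"), "p_adj"] > 0.05

    def test_adjustment_dominance_bonferroni_holm_raw(self, rng):
        data = normal_groups(rng, k=4, n=10)
        raw = dunn_posthoc(data, adjust="none")["p_adj"].to_numpy()
        holm = dunn_posthoc(data, adjust="holm")["p_adj"].to_numpy()
        bonf = dunn_posthoc(data, adjust="bonferroni")["p_adj"].to_numpy()
        assert np.all(bonf >= holm - 1e-15)
        assert np.all(holm >= raw - 1e-15)

    def test_tie_correction_against_direct_formula(self):
        data = GroupData(
            {"a": [1.0, 1.0, 2.0, 3.0], "b": [2.0, 2.0, 3.0, 4.0], "c": [3.0, 4.0, 4.0, 5.0]}
        )
        pooled = np.concatenate(data.arrays())
        n = pooled.size
        ranks = sps.rankdata(pooled)
        _, cnt = np.unique(pooled, return_counts=True)
        var = n * (n + 1) / 12 - ((cnt**3 - cnt).sum()) / (12 * (n - 1))
        r_a = ranks[:4].mean()
        r_b = ranks[4:8].mean()
        z_expected = (r_a - r_b) / np.sqrt(var * (1 / 4 + 1 / 4))
        table = dunn_posthoc(data, adjust="none").set_index(["group1", "group2"])
        assert table.loc[("a", "b"), "statistic"] == pytest.approx(z_expected)

    def test_all_tied_rejected(self):
        data = GroupData({"a": [1.0, 1.0, 1.0], "b": [1.0, 1.0, 1.0]})
        with pytest.raises(ValueError):
            dunn_posthoc(data)

    def test_monotone_transform_invariance_of_ranks(self, rng):
        data = GroupData({"a": rng.normal(0, 1, 12), "b": rng.normal(1, 1, 12)})
        warped = GroupData({k: np.exp(v) for k, v in data.groups.items()})
        z1 = dunn_posthoc(data)["statistic"].to_numpy()
        z2 = dunn_posthoc(warped)["statistic"].to_numpy()
        assert np.allclose(z1, z2)


class TestKruskalPermutationOracle:
    def test_routed_kruskal_p_matches_brute_force_enumeration(self):
        """No-tie (3,3,3) case: the router's Kruskal-Wallis p-value must
        equal the exact permutation tail probability, computed here by an
        independent brute force calling scipy's H on every one of the 1680
        partitions."""
        groups = [[1.0, 2.0, 3.0], [2.5, 3.5, 4.0], [10.0, 11.0, 12.0]]
        obs = sps.kruskal(*groups).statistic
        pooled = np.array([x for g in groups for x in g])
        idx = set(range(9))
        hits = total = 0
        for c1 in combinations(range(9), 3):
            rest = idx - set(c1)
            for c2 in combinations(sorted(rest), 3):
                c3 = sorted(rest - set(c2))
                h = sps.kruskal(
                    pooled[list(c1)], pooled[list(c2)], pooled[c3]
                ).statistic
                total += 1
                hits += h >= obs - 1e-12
        assert total == 1680
        p_exact = hits / total

        data = GroupData({"a": groups[0], "b": groups[1], "c": groups[2]})
        res = route_and_test(data, force_route=(False, True), posthoc=False)
        assert res.omnibus.name == "kruskal_wallis"
        assert res.omnibus.pvalue == pytest.approx(p_exact, abs=1e-6)


class TestRouter:
    @pytest.mark.parametrize(
        "force,expected",
        [
            ((True, True), ("anova", "tukey")),
            ((True, False), ("welch_anova", "games_howell")),
            ((False, True), ("kruskal_wallis", "dunn")),
            ((False, False), ("trimmed_welch", "games_howell")),
        ],
    )
    def test_forced_route_runs_matching_pair(self, rng, force, expected):
        data = normal_groups(rng, n=12)
        res = route_and_test(data, force_route=force)
        assert res.omnibus.name == expected[0]
        assert res.posthoc_name == expected[1]
        assert res.forced

    def test_identical_groups_never_rejected(self):
        x = [1.0, 2.0, 3.0, 4.0, 5.0, 6.0]
        data = GroupData({"a": x, "b": x, "c": x})
        res = route_and_test(data)
        assert res.omnibus.pvalue > 0.05

    def test_adjusted_p_at_least_raw(self, rng):
        data = GroupData(
            {
                "a": rng.exponential(1, 15),
                "b": rng.exponential(1.5, 15),
                "c": rng.exponential(1, 15),
            }
        )
        res = route_and_test(data, force_route=(False, True))
        assert np.all(
            res.posthoc["p_adj"].to_numpy() >= res.posthoc["p_raw"].to_numpy() - 1e-15
        )

    def test_route_matches_gate_verdicts(self, rng):
        data = normal_groups(rng)
        res = route_and_test(data)
        from angiokit.stats import ROUTES

        assert (res.omnibus.name, res.posthoc_name) == ROUTES[
            (res.normal, res.homoscedastic)
        ]

    def test_fewer_than_two_groups_rejected(self):
        with pytest.raises(ValueError):
            GroupData({"a": [1.0, 2.0, 3.0]})

    def test_type_one_error_calibration(self):
        """Routed omnibus rejection rate under the null (3 groups, n=6,
        standard normal) stays near the nominal 5% level."""
        rng = np.random.default_rng(2024)
        n_sim = 2000
        rejections = 0
        for _ in range(n_sim):
            data = GroupData({f"g{i}": rng.normal(0, 1, 6) for i in range(3)})
            res = route_and_test(data, posthoc=False)
            rejections += res.omnibus.pvalue < 0.05
        rate = rejections / n_sim
        assert 0.035 <= rate <= 0.065
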