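import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from heatscreen.replicated_analysis import (
    cross_trial_correlation,
    dunnett_pvalue,
    dunnett_vs_controls,
    letters_from_significance,
    tukey_letters,
    tukey_pairwise,
    two_way_anova,
)


def _long(groups: dict[str, list[float]]) -> pd.DataFrame:
    rows = [(g, v) for g, vals in groups.items() for v in vals]
    return pd.DataFrame(rows, columns=["genotype_id", "value"])


class TestDunnett:
    def test_identical_samples_not_different(self):
        sample = [9.8, 10.1, 10.4, 9.9, 10.0]
        res = dunnett_vs_controls(_long({"ctl": sample, "a": sample, "b": sample}), "ctl")
        assert (res.table["call"] == "not_different").all()
        assert res.table["p_adj"].to_numpy() == pytest.approx(1.0)

    def test_shifted_genotype_flagged_higher(self):
        rng = np.random.default_rng(3)
        groups = {
            "ctl": list(rng.normal(10, 1, 5)),
            "hi": list(rng.normal(15, 1, 5)),  # 5 within-SD units up
            "same": list(rng.normal(10, 1, 5)),
        }
        res = dunnett_vs_controls(_long(groups), "ctl")
        table = res.table.set_index("genotype_id")
        assert table.loc["hi", "call"] == "higher"
        assert table.loc["same", "call"] == "not_different"

    @pytest.mark.parametrize("seed", range(5))
    def test_pvalues_match_scipy_reference(self, seed):
        rng = np.random.default_rng(seed)
        groups = {g: list(rng.normal(10, 2, 6)) for g in ("ctl", "a", "b", "c")}
        res = dunnett_vs_controls(_long(groups), "ctl")
        ref = stats.dunnett(
            *(np.array(groups[g]) for g in sorted(set(groups) - {"ctl"})),
            control=np.array(groups["ctl"]),
            random_state=12345,
        )
        # scipy evaluates the same probability by randomized QMC; agreement
        # is limited by its integration accuracy
        assert res.table["p_adj"].to_numpy() == pytest.approx(ref.pvalue, abs=5e-4)
        assert res.table["tstat"].to_numpy() == pytest.approx(ref.statistic, abs=1e-10)

    def test_shift_invariance(self):
        rng = np.random.default_rng(7)
        groups = {g: list(rng.normal(10, 1, 4)) for g in ("ctl", "a", "b")}
        base = dunnett_vs_controls(_long(groups), "ctl")
        shifted = {g: [v + 500.0 for v in vals] for g, vals in groups.items()}
        moved = dunnett_vs_controls(_long(shifted), "ctl")
        assert moved.table["p_adj"].to_numpy() == pytest.approx(
            base.table["p_adj"].to_numpy(), abs=1e-9
        )

    def test_missing_control_errors(self):
        with pytest.raises(ValueError, match="ctl"):
            dunnett_vs_controls(_long({"a": [1, 2, 3]}), "ctl")

    def test_single_replicate_genotype_excluded(self):
        groups = {"ctl": [1.0, 2.0, 3.0], "a": [2.0, 3.0, 4.0], "solo": [9.0]}
        res = dunnett_vs_controls(_long(groups), "ctl")
        assert res.excluded == ["solo"]
        assert set(res.table["genotype_id"]) == {"a"}

    def test_one_sided_pvalue_smaller_for_positive_shift(self):
        p_two = dunnett_pvalue(2.0, [5, 5], 5, 12, alternative="two-sided")
        p_one = dunnett_pvalue(2.0, [5, 5], 5, 12, alternative="larger")
        assert p_one < p_two


class TestTukeyLetters:
    def test_identical_samples_share_one_letter(self):
        sample = [9.5, 10.0, 10.5, 10.2]
        letters = tukey_letters(_long({"a": sample, "b": sample, "c": sample}))
        assert set(letters.values()) == {"a"}

    def test_two_separated_clusters_get_disjoint_letters(self):
        rng = np.random.default_rng(0)
        groups = {
            "hi1": list(rng.normal(20, 1, 5)), "hi2": list(rng.normal(20, 1, 5)),
            "lo1": list(rng.normal(0, 1, 5)), "lo2": list(rng.normal(0, 1, 5)),
        }
        letters = tukey_letters(_long(groups))
        assert letters["hi1"] == letters["hi2"] == "a"
        assert letters["lo1"] == letters["lo2"] == "b"

    @pytest.mark.parametrize("seed", range(8))
    def test_letters_consistent_with_pairwise_matrix(self, seed):
        # genotypes share a letter iff their Tukey comparison is non-significant
        rng = np.random.default_rng(seed)
        k = int(rng.integers(3, 7))
        groups = {
            f"g{i}": list(rng.normal(rng.uniform(0, 6), 1, 5)) for i in range(k)
        }
        frame = _long(groups)
        letters = tukey_letters(frame)
        pairwise = tukey_pairwise(frame)
        for _, row in pairwise.iterrows():
            shared = set(letters[str(row.group1)]) & set(letters[str(row.group2)])
            assert bool(shared) == (not row.reject)

    def test_insertion_matches_exhaustive_search(self):
        # brute force: a valid letter display needs, for every non-significant
        # pair, some letter set containing both, and no set containing a
        # significant pair
        order = ["a", "b", "c", "d"]
        significant = {("a", "d"), ("a", "c")}
        letters = letters_from_significance(order, significant)
        for x, y in itertools.combinations(order, 2):
            shared = set(letters[x]) & set(letters[y])
            if (x, y) in significant or (y, x) in significant:
                assert not shared
            else:
                assert shared

    def test_fewer_than_two_genotypes_errors(self):
        with pytest.raises(ValueError):
            tukey_letters(_long({"a": [1.0, 2.0]}))


def _balanced_table(rng, n_geno=3, n_env=2, reps=3, interaction=0.0):
    rows = []
    for i in range(n_geno):
        for j in range(n_env):
            mean = i * 2.0 + j * 1.5 + interaction * i * j
            for _ in range(reps):
                rows.append((f"g{i}", f"e{j}", mean + rng.normal(0, 1)))
    return pd.DataFrame(rows, columns=["genotype_id", "env", "value"])


class TestTwoWayAnova:
    def test_additive_noise_free_table_has_zero_interaction(self):
        rows = []
        for i in range(3):
            for j in range(2):
                for r in range(2):
                    rows.append((f"g{i}", f"e{j}", 10.0 + i * 2 + j * 3 + 0.1 * r))
        frame = pd.DataFrame(rows, columns=["genotype_id", "env", "value"])
        anova = two_way_anova(frame)
        assert anova.term("GxE")["sum_sq"] == pytest.approx(0.0, abs=1e-18)

    def test_hand_computed_2x2x2_decomposition(self):
        # y_ijk laid out so cell/row/column means are simple fractions
        data = {
            ("g0", "e0"): [10.0, 12.0], ("g0", "e1"): [14.0, 16.0],
            ("g1", "e0"): [20.0, 22.0], ("g1", "e1"): [30.0, 32.0],
        }
        rows = [(g, e, v) for (g, e), vals in data.items() for v in vals]
        frame = pd.DataFrame(rows, columns=["genotype_id", "env", "value"])
        # hand decomposition: grand=19.5; G means 13/26; E means 16/23
        # SS(G)=2*2*(6.5^2+6.5^2)=338; SS(E)=2*2*(3.5^2+3.5^2)=98
        # cell means 11,15,21,31; interaction deviations -/+1.5
        # SS(GxE)=2*4*1.5^2=18; SS(err)=8*1=8
        anova = two_way_anova(frame)
        assert anova.term("G")["sum_sq"] == pytest.approx(338.0)
        assert anova.term("E")["sum_sq"] == pytest.approx(98.0)
        assert anova.term("GxE")["sum_sq"] == pytest.approx(18.0)
        assert anova.term("error")["sum_sq"] == pytest.approx(8.0)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_direct_balanced_decomposition(self, seed):
        rng = np.random.default_rng(seed)
        frame = _balanced_table(rng, n_geno=4, n_env=3, reps=2, interaction=0.7)
        anova = two_way_anova(frame)
        # independent oracle: balanced means algebra
        y = frame["value"].to_numpy()
        grand = y.mean()
        g_means = frame.groupby("genotype_id")["value"].mean()
        e_means = frame.groupby("env")["value"].mean()
        cell = frame.groupby(["genotype_id", "env"])["value"].mean()
        reps, n_env, n_geno = 2, 3, 4
        ss_g = reps * n_env * ((g_means - grand) ** 2).sum()
        ss_e = reps * n_geno * ((e_means - grand) ** 2).sum()
        ss_cells = reps * ((cell - grand) ** 2).sum()
        ss_gxe = ss_cells - ss_g - ss_e
        ss_tot = ((y - grand) ** 2).sum()
        assert anova.term("G")["sum_sq"] == pytest.approx(ss_g, abs=1e-8)
        assert anova.term("E")["sum_sq"] == pytest.approx(ss_e, abs=1e-8)
        assert anova.term("GxE")["sum_sq"] == pytest.approx(ss_gxe, abs=1e-8)
        assert anova.table["sum_sq"].sum() == pytest.approx(ss_tot, abs=1e-8)
        assert anova.table["df"].sum() == len(frame) - 1

    def test_rejects_unbalanced_table(self):
        rng = np.random.default_rng(0)
        frame = _balanced_table(rng)
        with pytest.raises(ValueError, match="unbalanced"):
            two_way_anova(frame.iloc[:-1])

    def test_names_empty_cells(self):
        rng = np.random.default_rng(0)
        frame = _balanced_table(rng)
        frame = frame[~((frame.genotype_id == "g2") & (frame.env == "e1"))]
        with pytest.raises(ValueError, match="g2"):
            two_way_anova(frame)

    def test_type_i_error_calibration_under_null(self):
        # F test for G at nominal 5% on simulated null data
        rng = np.random.default_rng(2024)
        n_sim, rejections = 400, 0
        for _ in range(n_sim):
            frame = _balanced_table(rng, n_geno=3, n_env=2, reps=2, interaction=0.0)
            frame["value"] = rng.normal(0, 1, len(frame))
            anova = two_way_anova(frame)
            if anova.term("G")["p"] < 0.05:
                rejections += 1
        rate = rejections / n_sim
        # binomial 3-sigma band around 0.05
        assert abs(rate - 0.05) < 3 * np.sqrt(0.05 * 0.95 / n_sim)


class TestCrossTrialCorrelation:
    def test_perfect_correlation(self):
        x = pd.Series([1.0, 2, 3, 4], index=list("abcd"))
        r, p, flag = cross_trial_correlation(x, x)
        assert r == pytest.approx(1.0)
        assert flag == "**"

    def test_perfect_anticorrelation(self):
        x = pd.Series([1.0, 2, 3, 4], index=list("abcd"))
        r, _, _ = cross_trial_correlation(x, -x)
        assert r == pytest.approx(-1.0)

    def test_hand_formula_on_ten_pairs(self):
        rng = np.random.default_rng(5)
        x = pd.Series(rng.normal(0, 1, 10), index=[f"g{i}" for i in range(10)])
        y = pd.Series(rng.normal(0, 1, 10), index=[f"g{i}" for i in range(10)])
        r, _, _ = cross_trial_correlation(x, y)
        xa, ya = x.to_numpy(), y.to_numpy()
        hand = ((xa - xa.mean()) * (ya - ya.mean())).sum() / np.sqrt(
            ((xa - xa.mean()) ** 2).sum() * ((ya - ya.mean()) ** 2).sum()
        )
        assert r == pytest.approx(hand, abs=1e-12)

    def test_symmetry_and_intersection_pairing(self):
        x = pd.Series([1.0, 2, 3, 9], index=list("abcz"))
        y = pd.Series([2.0, 1, 5, 7], index=list("abcd"))
        r_xy, _, _ = cross_trial_correlation(x, y)
        r_yx, _, _ = cross_trial_correlation(y, x)
        assert r_xy == pytest.approx(r_yx)

    def test_too_few_pairs_errors(self):
        x = pd.Series([1.0, 2], index=list("ab"))
        with pytest.raises(ValueError, match="3"):
            cross_trial_correlation(x, x)
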