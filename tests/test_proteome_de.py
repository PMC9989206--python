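"""Perseus-style proteome statistics: filtering, on/off, imputation,
permutation FDR, targeted t-tests."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from discomics.proteome_de import (
    ProteinTable,
    ProteomeParams,
    call_on_off,
    combine_de_proteins,
    impute_missing,
    permutation_fdr_ttest,
    preprocess_table,
    summarize_targeted,
    targeted_ttest,
)
from discomics.synthetic_data import gen_protein_table

GROUPS = pd.Series({"AC1": "AC", "AC2": "AC", "AC3": "AC",
                    "MSC1": "MSC", "MSC2": "MSC", "MSC3": "MSC"})


def _table(rows, contaminants=None):
    intens = pd.DataFrame(rows, columns=GROUPS.index, dtype=float)
    intens.index = [f"P{i}" for i in range(len(intens))]
    contam = None
    if contaminants:
        contam = pd.Series(False, index=intens.index)
        contam[contaminants] = True
    return ProteinTable(intens, GROUPS, contam)


NA = np.nan


class TestPreprocess:
    def test_two_of_three_in_one_group_retained(self):
        table = _table([[1e6, 1e6, NA, NA, NA, NA]])
        assert list(preprocess_table(table).index) == ["P0"]

    def test_one_and_one_removed(self):
        table = _table([[1e6, NA, NA, 1e6, NA, NA]])
        assert len(preprocess_table(table)) == 0

    def test_contaminant_removed_despite_full_values(self):
        table = _table([[1e6] * 6, [2e6] * 6], contaminants=["P0"])
        assert list(preprocess_table(table).index) == ["P1"]

    def test_log10_applied(self):
        table = _table([[1e6] * 6])
        assert np.allclose(preprocess_table(table), 6.0)

    def test_idempotent(self):
        table = _table([[1e6, 1e6, NA, NA, NA, NA], [1e6, NA, NA, 1e6, NA, NA]])
        logged = preprocess_table(table)
        again = preprocess_table(
            ProteinTable(10.0**logged, GROUPS)
        )
        pd.testing.assert_frame_equal(logged, again)

    def test_nonpositive_intensity_errors(self):
        with pytest.raises(ValueError):
            _table([[0.0, 1e6, 1e6, NA, NA, NA]])


class TestOnOff:
    def test_full_one_group_is_on_off(self):
        logged = preprocess_table(_table([[1e6, 1e6, 1e6, NA, NA, NA]]))
        out = call_on_off(logged, GROUPS)
        assert out.loc["P0", "direction"] == "on_in_AC"

    def test_single_value_in_other_group_disqualifies(self):
        logged = preprocess_table(_table([[1e6, 1e6, NA, 1e6, NA, NA]]))
        assert len(call_on_off(logged, GROUPS)) == 0

    def test_planted_on_off_recovered_exactly(self):
        table, truth = gen_protein_table(13, n_proteins=400, n_onoff=20)
        logged = preprocess_table(table)
        out = call_on_off(logged, table.groups)
        assert set(out.index) == set(truth["onoff"])
        for prot, grp in truth["onoff"].items():
            assert out.loc[prot, "direction"] == f"on_in_{grp}"


class TestImputation:
    def test_no_missing_returned_unchanged(self):
        logged = preprocess_table(_table([[1e6] * 6, [2e5] * 6]))
        out = impute_missing(logged, ProteomeParams(rng_seed=1))
        pd.testing.assert_frame_equal(out, logged)

    def test_reproducible_for_seed_and_only_missing_cells_change(self):
        table, _ = gen_protein_table(17, n_proteins=300, mcar_rate=0.15)
        logged = preprocess_table(table)
        params = ProteomeParams(rng_seed=5)
        out1 = impute_missing(logged, params)
        out2 = impute_missing(logged, params)
        pd.testing.assert_frame_equal(out1, out2)
        out3 = impute_missing(logged, ProteomeParams(rng_seed=6))
        observed = logged.notna()
        assert ((out1 == out3) | ~observed).all().all()
        assert not out1.equals(out3)

    def test_moments_match_downshifted_normal(self):
        # one column with many missing values: the imputed sample must match
        # Normal(mean - 1.8 SD, (0.3 SD)^2) of the observed values
        rng = np.random.default_rng(4)
        n = 200_000
        observed = rng.normal(6.0, 0.8, size=n)
        col = pd.Series(observed)
        col[rng.random(n) < 0.5] = np.nan
        frame = col.to_frame("s1")
        out = impute_missing(frame, ProteomeParams(rng_seed=2))
        mu, sd = frame["s1"].mean(), frame["s1"].std(ddof=1)
        imputed = out["s1"][frame["s1"].isna()]
        assert imputed.mean() == pytest.approx(mu - 1.8 * sd, abs=0.01 * abs(mu - 1.8 * sd))
        assert imputed.std(ddof=1) == pytest.approx(0.3 * sd, rel=0.02)

    def test_too_few_observed_errors(self):
        frame = pd.DataFrame({"s1": [1.0, np.nan, np.nan]})
        with pytest.raises(ValueError):
            impute_missing(frame, ProteomeParams(rng_seed=1))


class TestPermutationFdr:
    def test_null_table_rarely_significant(self):
        zeros = 0
        for seed in range(20):
            rng = np.random.default_rng(1000 + seed)
            frame = pd.DataFrame(
                rng.normal(6, 0.5, size=(1000, 6)), columns=GROUPS.index
            )
            res = permutation_fdr_ttest(frame, GROUPS, ProteomeParams())
            zeros += int(res["significant"].sum() == 0)
        assert zeros >= 18

    def test_strong_planted_signal_fully_detected(self):
        table, truth = gen_protein_table(
            5, n_proteins=1000, n_de=50, effect_fold=10**1.5, mcar_rate=0.0
        )
        logged = preprocess_table(table)
        complete = impute_missing(logged, ProteomeParams(rng_seed=3))
        res = permutation_fdr_ttest(complete, table.groups, ProteomeParams())
        detected = set(res[res["significant"]].index)
        assert set(truth["de"]) <= detected

    def test_fold_change_rule_excludes_small_shifts(self):
        rng = np.random.default_rng(9)
        frame = pd.DataFrame(rng.normal(6, 0.05, size=(500, 6)), columns=GROUPS.index)
        # strong t but only ~1.5-fold (log10 ~ 0.176 < log10 2)
        frame.iloc[0, 3:] += np.log10(1.5)
        res = permutation_fdr_ttest(frame, GROUPS, ProteomeParams())
        row = res.iloc[0]
        assert not row["fold_ok"] and not row["significant"]

    def test_permutation_granularity_floor(self):
        rng = np.random.default_rng(10)
        frame = pd.DataFrame(rng.normal(6, 0.5, size=(50, 6)), columns=GROUPS.index)
        res = permutation_fdr_ttest(frame, GROUPS, ProteomeParams())
        assert res.attrs["n_permutations"] == 9  # C(6,3)/2 - observed split
        assert (res["perm_p"] >= 1.0 / 10).all()

    def test_unbalanced_groups_error(self):
        frame = pd.DataFrame(np.ones((3, 5)), columns=list("abcde"))
        groups = pd.Series({"a": "AC", "b": "AC", "c": "AC", "d": "MSC", "e": "MSC"})
        with pytest.raises(ValueError):
            permutation_fdr_ttest(frame, groups, ProteomeParams())


class TestTargeted:
    def test_hand_computed_t_test(self):
        values = pd.DataFrame([[1, 2, 3, 4, 5, 6]], columns=GROUPS.index, dtype=float)
        res = targeted_ttest(values, GROUPS)
        t_expected, p_expected = stats.ttest_ind([1, 2, 3], [4, 5, 6])
        assert abs(res["t"].iloc[0]) == pytest.approx(3.674, abs=1e-3)
        assert res["p_value"].iloc[0] == pytest.approx(p_expected)
        assert res["significant"].iloc[0]

    def test_identical_groups_degenerate_p_one(self):
        values = pd.DataFrame([[5.0] * 6], columns=GROUPS.index)
        assert targeted_ttest(values, GROUPS)["p_value"].iloc[0] == 1.0

    def test_group_swap_symmetry(self):
        rng = np.random.default_rng(11)
        values = pd.DataFrame(rng.normal(5, 1, size=(10, 6)), columns=GROUPS.index)
        swapped = GROUPS.map({"AC": "MSC", "MSC": "AC"})
        p1 = targeted_ttest(values, GROUPS)["p_value"]
        p2 = targeted_ttest(values, swapped)["p_value"]
        assert np.allclose(p1, p2)

    def test_summarize_targeted_top3_then_peptide_mean(self):
        rows = []
        for pep, areas in [("pep1", [10, 8, 6, 1]), ("pep2", [4, 4, 4])]:
            for ion, area in enumerate(areas):
                rows.append({"protein": "P1", "peptide": pep, "sample": "s1",
                             "area": float(area), "ion": ion})
        long = pd.DataFrame(rows)
        out = summarize_targeted(long)
        # pep1: mean of top-3 (10, 8, 6) = 8; pep2: 4; protein mean = 6
        assert out.loc["P1", "s1"] == pytest.approx(6.0)


class TestCombine:
    def test_union_with_source_tags_and_overlaps(self):
        on_off = pd.DataFrame({"direction": ["on_in_AC"]}, index=["P1"])
        lfq = pd.DataFrame(
            {"significant": [True, True], "direction": ["up_in_AC", "up_in_MSC"]},
            index=["P1", "P2"],
        )
        targeted = pd.DataFrame(
            {"significant": [True], "direction": ["up_in_MSC"]}, index=["P3"]
        )
        out = combine_de_proteins(on_off, lfq, targeted)
        assert len(out) == 3
        assert out.loc["P1", "sources"] == "on_off|lfq_fdr"
        assert out.attrs["overlaps"]["on_off&lfq_fdr"] == 1
        assert out.loc["P1", "direction"] == "up_in_AC"
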