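"""Contingency tables, test selection, exact tests, report replicas."""

import itertools

import numpy as np
import pandas as pd
import pytest
from math import comb
from scipy.stats import fisher_exact as scipy_fisher

from acceptmap import datasets
from acceptmap.simulate import CorpusConfig, generate_reference
from acceptmap.stats import (
    ContingencyTable,
    EnumerationError,
    adherence_report,
    fisher_exact_rxc,
    pearson_chi2,
    pct,
    select_test,
    table1_report,
    tabulate,
)


def ct(rows):
    return ContingencyTable(pd.DataFrame(rows))


class TestTabulate:
    def test_reconstructed_study_counts_match_published_table(self):
        es = datasets.study_evaluations()
        t = tabulate(es, "result_intake", "timepoint")
        assert t.counts.loc["fully"].tolist() == [57, 57, 57]
        assert t.counts.loc["not_taken"].tolist() == [1, 0, 1]
        r = tabulate(es, "reaction", "timepoint")
        assert r.missing_per_col.tolist() == [2, 1, 0]

    def test_column_conservation(self):
        es = generate_reference(CorpusConfig(n_evaluations=50, seed=4))
        for var in es.codebook.variable_names:
            t = tabulate(es, var, "timepoint")
            assert (t.counts[1].sum() + t.missing_per_col[1]) == 50

    def test_unknown_variable(self):
        es = datasets.study_evaluations()
        with pytest.raises(KeyError):
            tabulate(es, "palatability", "timepoint")


class TestSelectTest:
    def test_published_flag_examples(self):
        t1 = datasets.table1_counts()
        assert select_test(t1["reaction"]) == "fisher_exact"
        t2 = datasets.table2_counts()
        assert select_test(t2["extra_device"]) == "chi_square"

    def test_all_expected_25_gives_chi2(self):
        assert select_test(ct([[25, 25], [25, 25]])) == "chi_square"

    def test_small_expected_gives_fisher(self):
        assert select_test(ct([[2, 1], [1, 2]])) == "fisher_exact"

    def test_degenerate_table_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            select_test(ct([[5, 5], [0, 0]]))


class TestPearsonChi2:
    def test_expected_table_gives_zero(self):
        r = pearson_chi2(ct([[10, 10], [10, 10]]))
        assert r.statistic == pytest.approx(0.0, abs=1e-12)
        assert r.p_value == pytest.approx(1.0)

    def test_hand_computed_example(self):
        r = pearson_chi2(ct([[10, 20], [20, 10]]))
        assert r.statistic == pytest.approx(20.0 / 3.0, abs=1e-12)
        assert r.p_value == pytest.approx(0.0098, abs=2e-4)

    def test_permutation_invariance(self):
        base = np.array([[3, 9, 6], [8, 2, 7]])
        r0 = pearson_chi2(ct(base))
        r1 = pearson_chi2(ct(base[:, [2, 0, 1]]))
        r2 = pearson_chi2(ct(base[[1, 0], :]))
        assert r0.statistic == pytest.approx(r1.statistic, abs=1e-12)
        assert r0.statistic == pytest.approx(r2.statistic, abs=1e-12)


def brute_force_fisher(counts: np.ndarray) -> float:
    """Independent Freeman-Halton oracle by direct table enumeration."""
    from math import prod

    counts = np.asarray(counts, dtype=int)
    row_m, col_m = counts.sum(1), counts.sum(0)
    N = counts.sum()

    def prob(tab):
        # multivariate hypergeometric with both margins fixed
        from math import factorial

        p = (
            prod(factorial(m) for m in row_m)
            * prod(factorial(m) for m in col_m)
            / factorial(N)
        )
        for row in tab:
            for v in row:
                p /= factorial(v)
        return p

    def tables(row_idx, remaining_cols):
        if row_idx == len(row_m) - 1:
            yield [list(remaining_cols)]
            return
        target = row_m[row_idx]
        ranges = [range(min(target, c) + 1) for c in remaining_cols]
        for combo in itertools.product(*ranges):
            if sum(combo) != target:
                continue
            rest = [c - v for c, v in zip(remaining_cols, combo)]
            for tail in tables(row_idx + 1, rest):
                yield [list(combo)] + tail

    p_obs = prob(counts.tolist())
    return sum(
        p for tab in tables(0, list(col_m)) if (p := prob(tab)) <= p_obs * (1 + 1e-12)
    )


class TestFisherExact:
    def test_uniform_2x2_p_is_one(self):
        assert fisher_exact_rxc(ct([[1, 1], [1, 1]])).p_value == pytest.approx(1.0)

    def test_diagonal_2x2(self):
        r = fisher_exact_rxc(ct([[10, 0], [0, 10]]))
        assert r.p_value == pytest.approx(2 / comb(20, 10), rel=1e-12)

    def test_printed_result_intake_table_p_one(self):
        """The published intake-by-timepoint table is the most probable
        table under its margins, so every table qualifies and p = 1."""
        r = fisher_exact_rxc(datasets.table1_counts()["result_intake"])
        assert r.p_value == pytest.approx(1.0, abs=1e-12)

    @pytest.mark.parametrize(
        "rows",
        [
            [[3, 5], [8, 2]],
            [[1, 7], [6, 1]],
            [[4, 4, 2], [2, 6, 5]],
            [[9, 1], [2, 8]],
            [[2, 3, 4], [5, 1, 0], [1, 4, 3]],
        ],
    )
    def test_agrees_with_brute_force_enumeration(self, rows):
        ours = fisher_exact_rxc(ct(rows)).p_value
        assert ours == pytest.approx(brute_force_fisher(np.array(rows)), rel=1e-9)

    @pytest.mark.parametrize(
        "rows", [[[3, 5], [8, 2]], [[1, 7], [6, 1]], [[9, 1], [2, 8]], [[5, 0], [3, 7]]]
    )
    def test_2x2_agrees_with_scipy(self, rows):
        ours = fisher_exact_rxc(ct(rows)).p_value
        assert ours == pytest.approx(scipy_fisher(np.array(rows)).pvalue, rel=1e-9)

    def test_capacity_error(self):
        big = ct([[200, 180, 150], [150, 180, 140]])
        with pytest.raises(EnumerationError):
            fisher_exact_rxc(big, max_tables=1000)


class TestReports:
    def test_reconstructed_table1_strings(self):
        """Percent strings reproduce the published report exactly."""
        rep = table1_report(datasets.study_evaluations())
        lookup = rep.set_index(["variable", "category"])
        assert lookup.loc[("result_intake", "fully"), "1"] == "57 (98)"
        assert lookup.loc[("extra_device", "yes"), "1"] == "32 (55)"
        assert lookup.loc[("reaction", "negative"), "1"] == "5 (9)"
        assert lookup.loc[("food_drink", "yes"), "1"] == "8 (14)"
        assert lookup.loc[("reaction", "positive"), "2"] == "31 (55)"
        assert lookup.loc[("prep_admin_time", "medium"), "3"] == "29 (58)"

    def test_no_variation_rows_have_no_test(self):
        rep = table1_report(datasets.study_evaluations())
        first_rows = rep.groupby("variable", sort=False).first()
        assert first_rows.loc["alteration", "test"] == ""
        assert first_rows.loc["reward", "test"] == ""
        assert first_rows.loc["result_intake", "test"].startswith("F")

    def test_identical_synthetic_data_all_100pct(self):
        from conftest import make_evalset

        es = make_evalset([{"patient_id": f"P{i}", "timepoint": t}
                           for i in range(10) for t in (1, 2, 3)])
        rep = table1_report(es)
        lookup = rep.set_index(["variable", "category"])
        assert lookup.loc[("result_intake", "fully"), "1"] == "10 (100)"
        assert lookup.loc[("restraint", "no"), "3"] == "10 (100)"

    def test_adherence_report_matches_published(self):
        rep = adherence_report(datasets.study_evaluations()).set_index("band")
        assert rep.loc["81-100", "n"] == 54
        assert rep.loc["81-100", "pct"] == 96
        assert rep.loc["61-80", "n"] == 2
        assert rep.loc["difficulty reported", "n"] == 2
        bands = rep.drop("difficulty reported")
        assert abs(bands["pct"].sum() - 100) <= len(bands)  # rounding slack

    def test_empty_adherence_warns(self):
        from conftest import make_evalset

        es = make_evalset([{}])
        with pytest.warns(UserWarning, match="no adherence"):
            rep = adherence_report(es)
        assert rep.empty


class TestPct:
    def test_half_rounds_up(self):
        assert pct(21, 56) == 38  # 37.5 -> 38, matches the published table
        assert pct(5, 56) == 9
        assert pct(0, 0) == 0
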