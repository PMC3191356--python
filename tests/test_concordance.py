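"""Agreement statistics, patient aggregation and FISH concordance."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import assume, given, settings
from hypothesis import strategies as st

from memconnect import (
    InputError,
    aggregate_patient,
    aggregate_patients,
    amplification_flag,
    build_contingency,
    code_score,
    fish_category_table,
    fish_positive,
    load_fish_cohort,
    log_pearson,
    percent_agreement,
    polysomy_flag,
    weighted_kappa,
)


def spots_frame(ve1, ve2=None, da=None, patient="p1", connectivity=None):
    n = len(ve1)
    return pd.DataFrame(
        {
            "patient_id": [patient] * n,
            "spot_id": [f"{patient}-s{i}" for i in range(n)],
            "ve1": ve1,
            "ve2": ve2 or ve1,
            "da": da or ve1,
            "connectivity": connectivity if connectivity is not None else [0.1] * n,
            "adequate": [True] * n,
        }
    )


class TestScoreCoding:
    @pytest.mark.parametrize(
        "raw,expected",
        [("0/1+", 0), ("2+", 1), ("3+", 2), ("0", 0), ("1+", 0), (1, 0), (2, 1), (3, 2), (0, 0)],
    )
    def test_accepted_codings(self, raw, expected):
        assert code_score(raw) == expected

    def test_unknown_score_rejected(self):
        with pytest.raises(InputError):
            code_score("4+")
        with pytest.raises(InputError):
            code_score(7)


class TestPatientAggregation:
    def test_maximum_and_range_over_mixed_spots(self):
        record = aggregate_patient(spots_frame(["0/1+", "2+", "3+"]))
        assert record.ve1max == "3+"
        assert record.ve1range == 2

    def test_single_high_spot_dominates(self):
        record = aggregate_patient(spots_frame(["3+", "0/1+", "0/1+", "0/1+"]))
        assert record.ve1max == "3+"
        assert record.ve1range == 2

    def test_single_spot_patient_is_rejected(self):
        assert aggregate_patient(spots_frame(["2+"]), min_spots=2) is None

    def test_identical_spots_have_zero_range(self):
        record = aggregate_patient(spots_frame(["2+", "2+", "2+"]))
        assert record.ve1range == 0
        assert record.ve1max == "2+"

    def test_connect_max_is_max_over_adequate_spots(self):
        frame = spots_frame(["2+", "2+", "2+"], connectivity=[0.2, 0.5, 0.3])
        frame.loc[1, "adequate"] = False
        record = aggregate_patient(frame)
        assert record.connect_max == 0.3
        assert record.n_spots == 2

    def test_empty_input_rejected(self):
        with pytest.raises(InputError):
            aggregate_patient(spots_frame([]).iloc[:0])

    def test_cohort_aggregation_drops_short_patients(self):
        spots = pd.concat(
            [spots_frame(["2+", "2+"], patient="a"), spots_frame(["3+"], patient="b")]
        )
        patients = aggregate_patients(spots, min_spots=2)
        assert list(patients["patient_id"]) == ["a"]


class TestContingency:
    def test_single_pair_lands_in_centre_cell(self):
        table = build_contingency(spots_frame(["2+"], ve2=["2+"]), "ve1", "ve2")
        assert table[1, 1] == 1
        assert table.sum() == 1

    def test_empty_records_give_zero_table_and_kappa_errors(self):
        table = build_contingency(spots_frame([]).iloc[:0], "ve1", "ve2")
        assert table.sum() == 0
        with pytest.raises(InputError):
            weighted_kappa(table)
        with pytest.raises(InputError):
            percent_agreement(table)


def kappa_oracle(table: np.ndarray) -> float:
    """Direct evaluation of the defining sums of linearly weighted kappa."""
    table = np.asarray(table, dtype=float)
    p = table / table.sum()
    k = table.shape[0]
    po = pe = 0.0
    for i in range(k):
        for j in range(k):
            w = 1.0 - abs(i - j) / (k - 1)
            po += w * p[i, j]
            pe += w * p[i].sum() * p[:, j].sum()
    return (po - pe) / (1.0 - pe)


class TestWeightedKappa:
    def test_perfect_diagonal_gives_kappa_one(self):
        res = weighted_kappa(np.diag([10, 10, 10]))
        assert res.kappa == pytest.approx(1.0, abs=1e-12)
        assert res.percent_agreement == 100.0

    def test_independence_table_gives_kappa_zero(self):
        res = weighted_kappa(np.array([[4, 2, 2], [2, 1, 1], [2, 1, 1]]))
        assert res.kappa == pytest.approx(0.0, abs=1e-12)

    def test_symmetric_under_transposition(self):
        table = np.array([[30, 5, 1], [2, 10, 4], [0, 3, 20]])
        assert weighted_kappa(table).kappa == pytest.approx(
            weighted_kappa(table.T).kappa, abs=1e-12
        )

    def test_kappa_is_one_only_without_disagreements(self):
        assert weighted_kappa(np.diag([3, 4, 5])).kappa == pytest.approx(1.0)
        off = np.diag([3, 4, 5])
        off[0, 1] = 1
        assert weighted_kappa(off).kappa < 1.0

    @settings(max_examples=300, deadline=None)
    @given(
        cells=st.lists(st.integers(0, 10), min_size=9, max_size=9),
    )
    def test_matches_brute_force_oracle(self, cells):
        table = np.array(cells).reshape(3, 3)
        assume(table.sum() > 0)
        p = table / table.sum()
        k = 3
        w = 1 - np.abs(np.subtract.outer(np.arange(k), np.arange(k))) / (k - 1)
        pe = (np.outer(p.sum(1), p.sum(0)) * w).sum()
        assume(pe < 1 - 1e-9)
        assert weighted_kappa(table).kappa == pytest.approx(
            kappa_oracle(table), abs=1e-12
        )

    def test_degenerate_marginals_rejected(self):
        table = np.zeros((3, 3))
        table[1, 1] = 12
        with pytest.raises(InputError):
            weighted_kappa(table)

    def test_ci_brackets_kappa(self):
        res = weighted_kappa(np.array([[30, 5, 1], [2, 10, 4], [0, 3, 20]]))
        assert res.ci_low <= res.kappa <= res.ci_high


class TestPercentAgreement:
    def test_trace_over_total(self):
        table = np.array([[475, 15, 0], [0, 21, 4], [0, 4, 56]])
        assert percent_agreement(table) == pytest.approx(96.0, abs=0.05)


class TestFishRules:
    @pytest.mark.parametrize(
        "ratio,positive", [(2.0, False), (2.1, True), (0.0, False), (13.3, True)]
    )
    def test_strict_ratio_rule(self, ratio, positive):
        assert fish_positive(ratio) is positive

    def test_polysomy_and_amplification_are_strict(self):
        assert polysomy_flag(3.0) is False
        assert polysomy_flag(3.1) is True
        assert amplification_flag(6.0) is False
        assert amplification_flag(9.0) is True
        assert amplification_flag(0.0) is False

    def test_high_copy_polysomy_case_splits_the_flags(self):
        # mean HER2 9.0 with CEP17 5.2: amplified by copies, ratio-negative
        assert amplification_flag(9.0) is True
        assert fish_positive(9.0 / 5.2) is False

    def test_missing_ratio_rejected(self):
        with pytest.raises(InputError):
            fish_positive(float("nan"))


class TestFishCategoryTable:
    def test_totals_cover_every_patient_with_fish_data(self):
        cohort = load_fish_cohort()
        for rater in ("ve1max", "ve2max", "damax"):
            table = fish_category_table(cohort, rater)
            assert table["total"].sum() == len(cohort)

    def test_empty_category_has_undefined_percent(self):
        cohort = load_fish_cohort().copy()
        cohort["ve1max"] = "3+"
        table = fish_category_table(cohort, "ve1max").set_index("category")
        assert table.loc["0/1+", "total"] == 0
        assert np.isnan(table.loc["0/1+", "percent"])


class TestLogPearson:
    def test_exact_proportionality_gives_r_one(self):
        x = np.linspace(1.0, 9.0, 20)
        r, p = log_pearson(x, 2.0 * x)
        assert r == pytest.approx(1.0, abs=1e-12)
        assert p < 1e-10

    def test_independent_samples_are_uncorrelated(self):
        rng = np.random.default_rng(5)
        x = rng.uniform(0.1, 1.0, 1000)
        y = rng.uniform(0.1, 1.0, 1000)
        r, _ = log_pearson(x, y)
        assert abs(r) < 0.1

    def test_nonpositive_values_under_log_rejected(self):
        with pytest.raises(InputError):
            log_pearson([1.0, 0.0, 2.0], [1.0, 2.0, 3.0])

    def test_zero_variance_rejected(self):
        with pytest.raises(InputError):
            log_pearson([2.0, 2.0, 2.0], [1.0, 2.0, 3.0])

    def test_too_few_pairs_rejected(self):
        with pytest.raises(InputError):
            log_pearson([1.0, 2.0], [1.0, 2.0])
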