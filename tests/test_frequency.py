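"""Observation-frequency statistics: correction, chi-square, FDR,
aggregation and the end-to-end screen."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy.special import erfc
from statsmodels.stats.multitest import multipletests

from peptidome.frequency import (
    average_chi_per_symbol,
    bh_fdr,
    chi2_pvalue,
    chi_square_eq1,
    correct_control,
    count_frequency,
    quantile_export,
    run_frequency_comparison,
    select_candidates,
    stream_totals,
)
from peptidome.model import (
    SelectionConfig,
    StreamTotals,
    ValidationError,
)


def brute_force_bh(pvalues):
    """Independent step-up oracle: for each hypothesis, the smallest
    alpha at which the BH procedure would reject it, by exhaustively
    running the procedure over every candidate alpha level."""
    p = list(pvalues)
    m = len(p)
    order = sorted(range(m), key=lambda i: p[i])
    q = [None] * m
    for rank_pos in range(m):
        i = order[rank_pos]
        # min over j >= rank of p_(j) * m / j, by direct enumeration
        q[i] = min(
            p[order[j]] * m / (j + 1) for j in range(rank_pos, m)
        )
        q[i] = min(q[i], 1.0)
    return q


class TestCounting:
    def test_tally_by_symbol(self, make_psm):
        psms = [make_psm(gene_symbol="DISC1") for _ in range(3)] + [
            make_psm(gene_symbol="KIF12") for _ in range(2)
        ]
        assert count_frequency(psms) == {"DISC1": 3, "KIF12": 2}
        assert count_frequency([]) == {}
        assert count_frequency([make_psm(gene_symbol="C2")]) == {"C2": 1}

    def test_counts_conserve_input_size(self, make_psm):
        psms = [make_psm(gene_symbol=f"G{i % 7}") for i in range(40)]
        assert sum(count_frequency(psms).values()) == len(psms)

    def test_empty_symbol_rejected(self, make_psm):
        with pytest.raises(ValidationError, match="gene_symbol"):
            count_frequency([make_psm(gene_symbol="")])

    def test_stream_totals_are_cardinalities(self, make_psm):
        t = stream_totals([make_psm() for _ in range(100)], [make_psm() for _ in range(80)])
        assert (t.total_case, t.total_control) == (100, 80)
        empty = stream_totals([make_psm()], [])
        with pytest.raises(ValidationError):
            empty.correction_factor


class TestCorrection:
    def test_equal_totals_identity(self):
        assert correct_control(42, StreamTotals(500, 500)) == 42.0

    def test_printed_totals_arithmetic(self):
        # 100 * 486367 / 424591 = 114.549..., by independent arithmetic
        got = correct_control(100, StreamTotals(486_367, 424_591))
        assert got == pytest.approx(100 * 486_367 / 424_591, rel=1e-15)
        assert f"{got:.10f}".startswith("114.549")

    def test_zero_count_stays_zero(self):
        assert correct_control(0, StreamTotals(486_367, 424_591)) == 0.0

    def test_zero_control_total_errors(self):
        with pytest.raises(ValidationError):
            correct_control(5, StreamTotals(10, 0))


class TestChiSquare:
    @pytest.mark.parametrize(
        "case, control, expected",
        [(0, 0, 0.0), (10, 0, 100.0), (4, 4, 0.0), (30, 10, 400 / 11)],
    )
    def test_direct_evaluation(self, case, control, expected):
        assert chi_square_eq1(case, control) == pytest.approx(expected, rel=1e-12)

    def test_negative_inputs_error(self):
        with pytest.raises(ValidationError):
            chi_square_eq1(-1, 0)
        with pytest.raises(ValidationError):
            chi_square_eq1(0, -1)

    def test_approaches_textbook_one_cell_statistic(self):
        # (obs-exp)^2/exp in the limit of large expected counts
        for expected_count in (1e3, 1e5, 1e7):
            obs = expected_count * 1.1
            ours = chi_square_eq1(obs, expected_count)
            textbook = (obs - expected_count) ** 2 / expected_count
            assert abs(ours - textbook) / textbook < 2 / expected_count

    def test_monotone_in_absolute_difference(self):
        b = 37.0
        vals = [chi_square_eq1(b + d, b) for d in np.linspace(0, 50, 40)]
        assert all(x <= y for x, y in zip(vals, vals[1:]))

    @pytest.mark.parametrize(
        "chi2, bound", [(25.0, 1e-3), (9.0, 1e-2), (0.0, 1.0)]
    )
    def test_tail_probability_thresholds(self, chi2, bound):
        assert chi2_pvalue(chi2) <= bound

    def test_tail_matches_erfc_closed_form(self):
        grid = np.linspace(0.0, 60.0, 601)
        for x in grid:
            assert chi2_pvalue(x) == pytest.approx(
                max(float(erfc(math.sqrt(x / 2))), 5e-324), abs=1e-12
            )

    def test_negative_chi2_errors(self):
        with pytest.raises(ValidationError):
            chi2_pvalue(-0.1)


class TestBH:
    def test_single_p_is_identity(self):
        assert bh_fdr([0.04]) == pytest.approx([0.04])

    def test_hand_example(self):
        assert bh_fdr([0.01, 0.02, 0.03]) == pytest.approx([0.03, 0.03, 0.03])

    def test_all_equal_stay_equal(self):
        assert bh_fdr([0.2, 0.2, 0.2]) == pytest.approx([0.2, 0.2, 0.2])

    def test_out_of_range_rejected(self):
        for bad in ([0.0], [1.5], [-0.1], [float("nan")]):
            with pytest.raises(ValidationError):
                bh_fdr(bad)

    @given(
        st.lists(
            st.floats(1e-6, 1.0, exclude_min=False, allow_nan=False), min_size=1, max_size=12
        )
    )
    def test_matches_brute_force_step_up(self, pvals):
        got = bh_fdr(pvals)
        expected = brute_force_bh(pvals)
        assert got == pytest.approx(expected, rel=1e-12)

    @given(
        st.lists(st.floats(1e-6, 1.0, allow_nan=False), min_size=2, max_size=40)
    )
    def test_matches_statsmodels_and_is_monotone_in_p(self, pvals):
        got = bh_fdr(pvals)
        sm_q = multipletests(pvals, method="fdr_bh")[1]
        assert got == pytest.approx(sm_q, rel=1e-9)
        order = np.argsort(pvals, kind="stable")
        assert all(
            got[order[i]] <= got[order[i + 1]] + 1e-15 for i in range(len(pvals) - 1)
        )


class TestAggregation:
    def test_single_accession_identity(self):
        frame = pd.DataFrame(
            [
                {
                    "gene_symbol": "G",
                    "protein_accession": "A",
                    "stream": "TRYP",
                    "count_case": 10,
                    "count_control": 5,
                    "corrected_control": 5.0,
                    "delta": 5.0,
                    "chi2": chi_square_eq1(10, 5.0),
                }
            ]
        )
        out = average_chi_per_symbol(frame)
        assert len(out) == 1
        assert out.loc[0, "chi2_mean"] == pytest.approx(out.loc[0, "chi2"])

    def test_mean_of_accession_chi2(self):
        rows = []
        for acc, chi2 in (("A1", 100.0), ("A2", 50.0)):
            rows.append(
                {
                    "gene_symbol": "G",
                    "protein_accession": acc,
                    "stream": "TRYP",
                    "count_case": 10,
                    "count_control": 2,
                    "corrected_control": 2.0,
                    "chi2": chi2,
                    "delta": 8.0,
                }
            )
        out = average_chi_per_symbol(pd.DataFrame(rows))
        assert out.loc[0, "chi2_mean"] == pytest.approx(75.0)
        assert out.loc[0, "count_case"] == 20
        # pooled chi2 recomputed from summed counts satisfies the identity
        assert out.loc[0, "chi2"] == pytest.approx(chi_square_eq1(20, 4.0))

    def test_empty_input(self):
        assert average_chi_per_symbol(pd.DataFrame()).empty


class TestSelection:
    @pytest.mark.parametrize(
        "delta, chi2, selected",
        [(10, 30, True), (5, 100, False), (9, 25, True), (100, 24.9, False)],
    )
    def test_gate_is_inclusive_and_requires_both(self, delta, chi2, selected):
        frame = pd.DataFrame(
            [{"gene_symbol": "G", "delta": delta, "chi2": chi2}]
        )
        out = select_candidates(frame, SelectionConfig())
        assert (len(out) == 1) is selected

    def test_ordering_descending_chi2_ties_by_symbol(self):
        frame = pd.DataFrame(
            [
                {"gene_symbol": "B", "delta": 10, "chi2": 50.0},
                {"gene_symbol": "A", "delta": 10, "chi2": 50.0},
                {"gene_symbol": "C", "delta": 10, "chi2": 90.0},
            ]
        )
        out = select_candidates(frame)
        assert out["gene_symbol"].tolist() == ["C", "A", "B"]


class TestEndToEnd:
    def test_null_self_comparison(self, make_psm):
        psms = [make_psm(gene_symbol=f"G{i % 5}") for i in range(50)]
        tables, meta = run_frequency_comparison(psms, psms)
        table = tables["TRYP"]
        assert (table["chi2"] == 0).all()
        assert not table["selected"].any()
        assert meta["streams"]["TRYP"]["correction_factor"] == 1.0

    def test_hand_worked_single_symbol(self, make_psm):
        # 30 vs 10 for the symbol of interest, padded so totals are equal
        case = [make_psm(gene_symbol="DISC1") for _ in range(30)] + [
            make_psm(gene_symbol="PAD") for _ in range(10)
        ]
        control = [make_psm(gene_symbol="DISC1") for _ in range(10)] + [
            make_psm(gene_symbol="PAD") for _ in range(30)
        ]
        tables, meta = run_frequency_comparison(case, control)
        assert meta["streams"]["TRYP"]["correction_factor"] == 1.0
        row = tables["TRYP"].set_index("gene_symbol").loc["DISC1"]
        assert row["chi2"] == pytest.approx(400 / 11, rel=1e-12)
        assert bool(row["selected"])

    def test_conservation_of_counts(self, make_psm):
        case = [make_psm(gene_symbol=f"G{i % 4}") for i in range(37)]
        control = [make_psm(gene_symbol=f"G{i % 3}") for i in range(23)]
        tables, meta = run_frequency_comparison(case, control)
        t = tables["TRYP"]
        assert t["count_case"].sum() == meta["streams"]["TRYP"]["total_case"]
        assert t["count_control"].sum() == meta["streams"]["TRYP"]["total_control"]

    def test_quantile_export_sorted(self):
        frame = pd.DataFrame({"delta": [3.0, -1.0, 2.0], "chi2": [9.0, 1.0, 4.0]})
        out = quantile_export(frame)
        assert out["delta_sorted"].tolist() == [-1.0, 2.0, 3.0]
        assert out["chi2_sorted"].tolist() == [1.0, 4.0, 9.0]

    def test_sub_threshold_and_redundant_rows_excluded(self, make_psm):
        kept = make_psm(gene_symbol="G1", precursor_intensity=20_000)
        low = make_psm(gene_symbol="G1", precursor_intensity=5_000)
        dup_hi = make_psm(spectrum_id="dup", score=5.0, gene_symbol="G1")
        dup_lo = make_psm(spectrum_id="dup", score=1.0, gene_symbol="G1")
        case = [kept, low, dup_hi, dup_lo]
        control = [make_psm(gene_symbol="G1") for _ in range(2)]
        tables, meta = run_frequency_comparison(case, control)
        assert meta["streams"]["TRYP"]["total_case"] == 2  # low + dup removed
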