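"""Odds ratios, intervals, chi-square, Fisher, Wilcoxon and BH adjustment."""

from __future__ import annotations

import numpy as np
import pytest
import scipy.stats as st
from hypothesis import given, settings
from hypothesis import strategies as hst

from oracles import fisher_exact_oracle

from ieiburden.association import (
    ANY_IEI,
    ContingencyTable,
    bh_adjust,
    chi_square_2x2,
    fisher_exact,
    odds_ratio,
    run_association_suite,
    wilcoxon_rank_sum,
    woolf_ci,
)
from ieiburden.association import TestKind as StatTest
from ieiburden.candidate_filter import SubjectIEIProfile


class TestOddsRatio:
    def test_black_race_table(self):
        t = ContingencyTable(53, 147, 17, 113)
        assert odds_ratio(t) == pytest.approx(2.3966, abs=1e-4)

    def test_ecmo_table(self):
        assert odds_ratio(ContingencyTable(18, 182, 3, 127)) == pytest.approx(4.19, abs=0.005)

    @pytest.mark.parametrize("k", [1, 5, 40])
    def test_symmetric_table_is_unity(self, k):
        assert odds_ratio(ContingencyTable(k, k, k, k)) == pytest.approx(1.0)

    def test_zero_cell_uses_haldane(self):
        t = ContingencyTable(5, 0, 3, 7)
        assert odds_ratio(t) == pytest.approx((5.5 * 7.5) / (0.5 * 3.5))

    def test_all_zero_undefined(self):
        with pytest.raises(ValueError):
            odds_ratio(ContingencyTable(0, 0, 0, 0))

    @given(
        hst.tuples(*[hst.integers(min_value=1, max_value=200)] * 4)
    )
    @settings(max_examples=100, deadline=None)
    def test_exposure_flip_reciprocity(self, cells):
        a, b, c, d = cells
        assert odds_ratio(ContingencyTable(a, b, c, d)) * odds_ratio(
            ContingencyTable(b, a, d, c)
        ) == pytest.approx(1.0)


class TestWoolfCI:
    def test_black_race_interval(self):
        low, high = woolf_ci(ContingencyTable(53, 147, 17, 113))
        assert low == pytest.approx(1.317, abs=0.005)
        assert high == pytest.approx(4.36, abs=0.005)

    def test_ecmo_interval(self):
        low, high = woolf_ci(ContingencyTable(18, 182, 3, 127))
        assert low == pytest.approx(1.21, abs=0.005)
        assert high == pytest.approx(14.5, abs=0.05)

    def test_symmetric_interval_contains_unity(self):
        low, high = woolf_ci(ContingencyTable(10, 10, 10, 10))
        assert low < 1.0 < high

    def test_interval_brackets_estimate(self):
        t = ContingencyTable(12, 3, 7, 30)
        low, high = woolf_ci(t)
        assert low <= odds_ratio(t) <= high

    def test_coverage_calibration(self):
        """95% Woolf interval covers the true OR 93-97% of the time."""
        rng = np.random.default_rng(11)
        n, p1, p2 = 1000, 0.3, 0.15
        true_or = (p1 / (1 - p1)) / (p2 / (1 - p2))
        reps = 2000
        a = rng.binomial(n, p1, size=reps)
        c = rng.binomial(n, p2, size=reps)
        covered = 0
        for ai, ci in zip(a, c):
            low, high = woolf_ci(ContingencyTable(ai, n - ai, ci, n - ci))
            covered += low <= true_or <= high
        assert 0.93 <= covered / reps <= 0.97


class TestChiSquare:
    def test_printed_table1_p(self):
        assert chi_square_2x2(ContingencyTable(53, 147, 17, 113)) == pytest.approx(
            0.004, abs=5e-4
        )

    def test_balanced_table_p_one(self):
        assert chi_square_2x2(ContingencyTable(10, 10, 10, 10)) == pytest.approx(1.0)

    def test_closed_form_value(self):
        # N(ad-bc)^2 / (r1 r2 c1 c2), upper tail with 1 df
        assert chi_square_2x2(ContingencyTable(38, 32, 92, 238)) == pytest.approx(
            1.83e-5, rel=0.01
        )

    def test_zero_margin_warns_and_returns_one(self):
        with pytest.warns(UserWarning, match="zero margin"):
            assert chi_square_2x2(ContingencyTable(0, 0, 5, 7)) == 1.0

    @given(hst.tuples(*[hst.integers(min_value=0, max_value=50)] * 4))
    @settings(max_examples=100, deadline=None)
    def test_transposition_invariance(self, cells):
        a, b, c, d = cells
        if a + b + c + d == 0:
            return
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            assert chi_square_2x2(ContingencyTable(a, b, c, d)) == pytest.approx(
                chi_square_2x2(ContingencyTable(a, c, b, d))
            )


class TestFisher:
    def test_balanced_unit_table(self):
        assert fisher_exact(ContingencyTable(1, 1, 1, 1)) == pytest.approx(1.0)

    def test_diagonal_two_table(self):
        # margins (2,2)/(2,2): three tables with probabilities 1/6, 4/6, 1/6
        assert fisher_exact(ContingencyTable(2, 0, 0, 2)) == pytest.approx(1 / 3)

    @given(hst.tuples(*[hst.integers(min_value=0, max_value=12)] * 4))
    @settings(max_examples=200, deadline=None)
    def test_matches_exact_enumeration(self, cells):
        a, b, c, d = cells
        if a + b + c + d == 0:
            return
        expected = fisher_exact_oracle(a, b, c, d)
        assert fisher_exact(ContingencyTable(a, b, c, d)) == pytest.approx(
            expected, rel=1e-9, abs=1e-12
        )

    def test_matches_scipy_convention(self):
        rng = np.random.default_rng(3)
        for _ in range(50):
            a, b, c, d = rng.integers(0, 40, size=4)
            if a + b + c + d == 0:
                continue
            expected = st.fisher_exact([[a, b], [c, d]]).pvalue
            assert fisher_exact(ContingencyTable(a, b, c, d)) == pytest.approx(
                expected, rel=1e-9
            )


class TestWilcoxon:
    def test_identical_samples_null_center(self):
        assert wilcoxon_rank_sum([1, 2, 3], [1, 2, 3]) > 0.6

    def test_small_sample_exact_p(self):
        # full separation of 3 vs 3: 2 / C(6,3) = 0.1
        assert wilcoxon_rank_sum([1, 2, 3], [4, 5, 6]) == pytest.approx(0.1)

    def test_large_shift_detected(self):
        rng = np.random.default_rng(5)
        x = rng.normal(0, 1, 200)
        y = rng.normal(1.5, 1, 200)
        assert wilcoxon_rank_sum(x, y) < 1e-3

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            wilcoxon_rank_sum([], [1.0])


class TestBenjaminiHochberg:
    def test_single_p_unchanged(self):
        assert bh_adjust([0.03], m=1) == [pytest.approx(0.03)]

    def test_hand_computed_step_up(self):
        assert bh_adjust([0.01, 0.02, 0.03, 0.04], m=4) == pytest.approx([0.04] * 4)

    def test_input_order_invariance(self):
        p = [0.04, 0.001, 0.3, 0.04, 0.9]
        adjusted = bh_adjust(p)
        perm = [2, 0, 4, 1, 3]
        permuted = bh_adjust([p[i] for i in perm])
        assert [adjusted[i] for i in perm] == pytest.approx(permuted)

    def test_external_family_size_respected(self):
        """BH with declared m (e.g. 131 variants) scales by m, not list length."""
        p = [0.001, 0.01]
        q = bh_adjust(p, m=131)
        assert q[0] == pytest.approx(min(0.001 * 131 / 1, 0.01 * 131 / 2))
        assert q[1] == pytest.approx(0.01 * 131 / 2)

    def test_never_below_raw_p(self):
        rng = np.random.default_rng(9)
        p = rng.random(30)
        q = bh_adjust(p.tolist())
        assert all(qi >= pi - 1e-12 for qi, pi in zip(q, p))

    def test_m_smaller_than_list_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.1, 0.2], m=1)

    def test_matches_statsmodels_when_m_equals_length(self):
        from statsmodels.stats.multitest import multipletests

        rng = np.random.default_rng(13)
        p = rng.random(25)
        ours = bh_adjust(p.tolist())
        theirs = multipletests(p, method="fdr_bh")[1]
        assert ours == pytest.approx(theirs.tolist())


class TestAssociationSuite:
    def _cohort(self, rng, n=200, effect=True):
        import pandas as pd

        from conftest import K_CFH, make_annotation, make_call
        from ieiburden.candidate_filter import CandidateVariant, Basis, SatisfiedMode
        from ieiburden.reference_data import IUISCategory

        profiles = {}
        exposed = rng.random(n) < 0.5
        for i in range(n):
            sid = f"P{i}"
            p = SubjectIEIProfile(subject_id=sid)
            if exposed[i]:
                cand = CandidateVariant(
                    call=make_call(sid, K_CFH),
                    basis=Basis.HGMD_DM,
                    satisfied_mode=SatisfiedMode.AD,
                    annotation=make_annotation(K_CFH, "CFH"),
                    iuis_category=IUISCategory.COMPLEMENT,
                )
                p.candidates.append(cand)
            profiles[sid] = p
        p_outcome = np.where(exposed, 0.5 if effect else 0.25, 0.25)
        outcome = rng.random(n) < p_outcome
        pheno = pd.DataFrame(
            {"subject_id": [f"P{i}" for i in range(n)], "fever": outcome}
        ).set_index("subject_id")
        return profiles, pheno

    def test_any_iei_uses_chi_square_groups_use_fisher(self, rng):
        profiles, pheno = self._cohort(rng)
        results = run_association_suite(profiles, pheno, ["fever"])
        by_label = {r.exposure_label: r for r in results}
        assert by_label[ANY_IEI].test_used is StatTest.CHI_SQUARE
        assert by_label["complement"].test_used is StatTest.FISHER
        assert all(r.p_adjusted >= r.p_value - 1e-12 for r in results)

    def test_unknown_outcome_rejected(self, rng):
        profiles, pheno = self._cohort(rng)
        with pytest.raises(ValueError, match="unknown outcome"):
            run_association_suite(profiles, pheno, ["nonexistent"])

    def test_missing_outcome_subjects_dropped(self, rng):
        profiles, pheno = self._cohort(rng, n=50)
        pheno = pheno.astype(object)
        pheno.iloc[:10, 0] = None
        results = run_association_suite(profiles, pheno, ["fever"])
        any_result = next(r for r in results if r.exposure_label == ANY_IEI)
        assert any_result.table.total == 40
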