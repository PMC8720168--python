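"""The candidate-variant filter: gates, inheritance rules, and profiles."""

from __future__ import annotations

import numpy as np
import pytest

from conftest import (
    K_CFH,
    K_IL2RG,
    K_NLRP3,
    K_UNC13D_1,
    K_UNC13D_2,
    make_annotation,
    make_call,
)
from oracles import brute_force_decisions, random_micro_cohort

from ieiburden.candidate_filter import (
    Basis,
    FilterConfig,
    FilterFunnel,
    SatisfiedMode,
    Sex,
    Zygosity,
    evaluate_inheritance,
    flag_recurrent_nulls,
    is_null_variant,
    is_nonsynonymous,
    is_rare,
    passes_qc,
    pathogenicity_basis,
    run_candidate_filter,
)
from ieiburden.reference_data import (
    Consequence,
    PathogenicityClass,
    ValidationError,
    VariantKey,
)


class TestQualityGate:
    @pytest.mark.parametrize(
        "depth,qual,expected",
        [
            (11, 21.0, True),
            (10, 50.0, False),  # depth boundary is strict
            (100, 20.0, False),  # quality boundary is strict
            (11, 20.5, True),
        ],
    )
    def test_strict_thresholds(self, depth, qual, expected):
        call = make_call("P1", K_NLRP3, depth=depth, quality=qual)
        assert passes_qc(call, FilterConfig()) is expected


class TestConsequenceGates:
    @pytest.mark.parametrize(
        "consequence,nonsyn,null",
        [
            (Consequence.MISSENSE, True, False),
            (Consequence.NONSENSE, True, True),
            (Consequence.FRAMESHIFT, True, True),
            (Consequence.SPLICE_SITE, True, True),
            (Consequence.START_LOST, True, True),
            (Consequence.SYNONYMOUS, False, False),
            (Consequence.OTHER, False, False),
        ],
    )
    def test_nonsynonymous_and_null_sets(self, consequence, nonsyn, null):
        ann = make_annotation(K_NLRP3, "NLRP3", consequence=consequence)
        assert is_nonsynonymous(ann) is nonsyn
        assert is_null_variant(ann) is null


class TestRarity:
    def test_one_common_database_disqualifies(self):
        ann = make_annotation(K_NLRP3, "NLRP3", mafs={"gnomAD": 0.06})
        assert not is_rare(ann, FilterConfig())

    def test_all_below_threshold_is_rare(self):
        mafs = {db: 0.049 for db in ("ExAC", "1000G", "ESP6500", "gnomAD")}
        assert is_rare(make_annotation(K_NLRP3, "NLRP3", mafs=mafs), FilterConfig())

    def test_exactly_at_threshold_is_not_rare(self):
        assert not is_rare(
            make_annotation(K_NLRP3, "NLRP3", mafs={"ExAC": 0.05}), FilterConfig()
        )

    def test_absent_everywhere_follows_missing_policy(self):
        ann = make_annotation(K_NLRP3, "NLRP3", mafs={})
        assert is_rare(ann, FilterConfig(maf_missing_is_rare=True))
        assert not is_rare(ann, FilterConfig(maf_missing_is_rare=False))


class TestPathogenicityBasis:
    @pytest.mark.parametrize(
        "cls,consequence,expected",
        [
            (PathogenicityClass.DM, Consequence.MISSENSE, Basis.HGMD_DM),
            (PathogenicityClass.DM_QUERY, Consequence.MISSENSE, Basis.HGMD_DM_QUERY),
            (PathogenicityClass.NONE, Consequence.FRAMESHIFT, Basis.NOVEL_NULL),
            (PathogenicityClass.NONE, Consequence.MISSENSE, None),
            (PathogenicityClass.DM, Consequence.NONSENSE, Basis.HGMD_DM),
        ],
    )
    def test_basis_assignment(self, cls, consequence, expected):
        ann = make_annotation(K_NLRP3, "NLRP3", consequence=consequence, cls=cls)
        assert pathogenicity_basis(ann) is expected


class TestRecurrentNulls:
    def _cohort(self, n_carriers, key, ann):
        calls = [make_call(f"P{i}", key) for i in range(n_carriers)]
        return calls, {key: ann}

    def test_carrier_fraction_above_threshold_flagged(self):
        ann = make_annotation(
            K_NLRP3, "NLRP3", consequence=Consequence.NONSENSE, cls=PathogenicityClass.NONE
        )
        calls, anns = self._cohort(30, K_NLRP3, ann)
        assert flag_recurrent_nulls(calls, anns, 330, FilterConfig()) == {K_NLRP3}

    def test_single_carrier_not_flagged(self):
        ann = make_annotation(
            K_NLRP3, "NLRP3", consequence=Consequence.NONSENSE, cls=PathogenicityClass.NONE
        )
        calls, anns = self._cohort(1, K_NLRP3, ann)
        assert flag_recurrent_nulls(calls, anns, 330, FilterConfig()) == set()

    def test_curated_variants_exempt(self):
        """DM missense recurrence is never treated as sequencing error."""
        ann = make_annotation(K_NLRP3, "NLRP3", cls=PathogenicityClass.DM)
        calls, anns = self._cohort(30, K_NLRP3, ann)
        assert flag_recurrent_nulls(calls, anns, 330, FilterConfig()) == set()


class TestInheritance:
    def test_ar_only_single_het_emits_nothing(self, tiny_panel):
        calls = [(make_call("P1", K_UNC13D_1), Basis.HGMD_DM)]
        assert evaluate_inheritance(tiny_panel["UNC13D"], Sex.FEMALE, calls) == []

    def test_ar_only_homozygote_qualifies(self, tiny_panel):
        calls = [(make_call("P1", K_UNC13D_1, Zygosity.HOM_ALT), Basis.HGMD_DM)]
        out = evaluate_inheritance(tiny_panel["UNC13D"], Sex.MALE, calls)
        assert [c.satisfied_mode for c in out] == [SatisfiedMode.AR_HOM]

    def test_ar_only_two_distinct_hets_are_putative_compound_het(self, tiny_panel):
        calls = [
            (make_call("P1", K_UNC13D_1), Basis.HGMD_DM),
            (make_call("P1", K_UNC13D_2), Basis.NOVEL_NULL),
        ]
        out = evaluate_inheritance(tiny_panel["UNC13D"], Sex.FEMALE, calls)
        assert len(out) == 2
        assert {c.satisfied_mode for c in out} == {SatisfiedMode.AR_COMPOUND_HET}

    def test_dual_mode_gene_single_het_qualifies_as_ad(self, tiny_panel):
        calls = [(make_call("P1", K_CFH), Basis.HGMD_DM_QUERY)]
        out = evaluate_inheritance(tiny_panel["CFH"], Sex.FEMALE, calls)
        assert [c.satisfied_mode for c in out] == [SatisfiedMode.AD]

    def test_xlr_male_hemizygote_qualifies(self, tiny_panel):
        calls = [(make_call("P1", K_IL2RG, Zygosity.HEMI), Basis.HGMD_DM)]
        out = evaluate_inheritance(tiny_panel["IL2RG"], Sex.MALE, calls)
        assert [c.satisfied_mode for c in out] == [SatisfiedMode.XL_MALE]

    def test_xlr_female_needs_biallelic(self, tiny_panel):
        het = [(make_call("P1", K_IL2RG), Basis.HGMD_DM)]
        assert evaluate_inheritance(tiny_panel["IL2RG"], Sex.FEMALE, het) == []
        hom = [(make_call("P1", K_IL2RG, Zygosity.HOM_ALT), Basis.HGMD_DM)]
        out = evaluate_inheritance(tiny_panel["IL2RG"], Sex.FEMALE, hom)
        assert [c.satisfied_mode for c in out] == [SatisfiedMode.XL_FEMALE_BIALLELIC]

    def test_female_hemizygote_is_data_error(self, tiny_panel):
        calls = [(make_call("P1", K_IL2RG, Zygosity.HEMI), Basis.HGMD_DM)]
        with pytest.raises(ValidationError, match="hemizygous"):
            evaluate_inheritance(tiny_panel["IL2RG"], Sex.FEMALE, calls)

    def test_output_sorted_by_position(self, tiny_panel):
        calls = [
            (make_call("P1", K_UNC13D_2), Basis.HGMD_DM),
            (make_call("P1", K_UNC13D_1), Basis.HGMD_DM),
        ]
        out = evaluate_inheritance(tiny_panel["UNC13D"], Sex.MALE, calls)
        assert [c.call.key.position for c in out] == [2000, 2100]


class TestRunCandidateFilter:
    def _three_subject_cohort(self, tiny_annotations):
        sexes = {"P1": Sex.FEMALE, "P2": Sex.MALE, "P3": Sex.FEMALE}
        calls = [
            make_call("P1", K_NLRP3),  # AD het DM -> candidate
            make_call("P2", K_UNC13D_1),  # AR single het -> nothing
        ]
        return calls, sexes

    def test_hand_traced_three_subject_fixture(
        self, tiny_panel, tiny_annotations
    ):
        calls, sexes = self._three_subject_cohort(tiny_annotations)
        profiles = run_candidate_filter(calls, sexes, tiny_panel, tiny_annotations)
        assert profiles["P1"].iei_positive
        assert profiles["P1"].variant_count == 1
        assert not profiles["P2"].iei_positive
        assert not profiles["P3"].iei_positive

    def test_empty_cohort_gives_empty_map(self, tiny_panel, tiny_annotations):
        assert run_candidate_filter([], {}, tiny_panel, tiny_annotations) == {}

    def test_unknown_subject_rejected(self, tiny_panel, tiny_annotations):
        with pytest.raises(ValidationError, match="P9"):
            run_candidate_filter(
                [make_call("P9", K_NLRP3)], {"P1": Sex.MALE}, tiny_panel, tiny_annotations
            )

    def test_two_categories_set_multiple_groups(self, tiny_panel, tiny_annotations):
        sexes = {"P1": Sex.FEMALE}
        calls = [make_call("P1", K_NLRP3), make_call("P1", K_CFH)]
        profiles = run_candidate_filter(calls, sexes, tiny_panel, tiny_annotations)
        assert len(profiles["P1"].iuis_groups) == 2
        assert profiles["P1"].multiple_groups

    def test_order_insensitivity(self, tiny_panel, tiny_annotations, rng):
        sexes = {"P1": Sex.FEMALE, "P2": Sex.MALE}
        calls = [
            make_call("P1", K_NLRP3),
            make_call("P1", K_CFH),
            make_call("P2", K_UNC13D_1),
            make_call("P2", K_UNC13D_2),
        ]
        baseline = run_candidate_filter(calls, sexes, tiny_panel, tiny_annotations)
        for _ in range(5):
            perm = [calls[i] for i in rng.permutation(len(calls))]
            shuffled = run_candidate_filter(perm, sexes, tiny_panel, tiny_annotations)
            for sid in sexes:
                assert shuffled[sid].candidates == baseline[sid].candidates

    def test_funnel_conservation(self, tiny_panel, tiny_annotations):
        sexes = {"P1": Sex.FEMALE, "P2": Sex.MALE}
        calls = [
            make_call("P1", K_NLRP3),
            make_call("P1", K_NLRP3, depth=5),  # fails QC
            make_call("P2", K_UNC13D_1),  # inheritance unsatisfied
            make_call("P2", VariantKey("7", 1, "A", "C")),  # unresolvable
        ]
        funnel = FilterFunnel()
        run_candidate_filter(calls, sexes, tiny_panel, tiny_annotations, funnel=funnel)
        assert funnel.conserved()
        assert funnel.unresolvable == 1
        assert funnel.failed_qc == 1
        assert funnel.inheritance_unsatisfied == 1

    def test_maf_threshold_monotonicity(self, tiny_panel, rng):
        """Raising the MAF threshold never removes a candidate."""
        anns = {
            K_NLRP3: make_annotation(K_NLRP3, "NLRP3", mafs={"gnomAD": 0.03}),
            K_CFH: make_annotation(K_CFH, "CFH", mafs={"gnomAD": 0.001}),
        }
        sexes = {"P1": Sex.FEMALE}
        calls = [make_call("P1", K_NLRP3), make_call("P1", K_CFH)]
        thresholds = [0.0005, 0.02, 0.04, 0.05, 0.2]
        previous: set = set()
        for t in thresholds:
            profiles = run_candidate_filter(
                calls, sexes, tiny_panel, anns, FilterConfig(maf_threshold=t)
            )
            current = {c.call.key for c in profiles["P1"].candidates}
            assert previous <= current
            previous = current

    def test_filter_idempotence(self, tiny_panel, tiny_annotations):
        sexes = {"P1": Sex.FEMALE, "P2": Sex.MALE}
        calls = [
            make_call("P1", K_NLRP3),
            make_call("P1", K_CFH),
            make_call("P2", K_UNC13D_1, Zygosity.HOM_ALT),
        ]
        first = run_candidate_filter(calls, sexes, tiny_panel, tiny_annotations)
        surviving_calls = [
            c.call for p in first.values() for c in p.candidates
        ]
        second = run_candidate_filter(
            surviving_calls, sexes, tiny_panel, tiny_annotations
        )
        for sid in sexes:
            assert [c.call for c in second[sid].candidates] == [
                c.call for c in first[sid].candidates
            ]


def test_micro_cohort_oracle_agreement():
    """Pipeline decisions match a brute-force textual-rule checker."""
    rng = np.random.default_rng(7)
    for _ in range(50):
        calls, sexes, panel, annotations, config = random_micro_cohort(rng)
        profiles = run_candidate_filter(calls, sexes, panel, annotations, config)
        expected = brute_force_decisions(calls, sexes, panel, annotations, config)
        got = {
            sid: {(c.call.key, c.satisfied_mode.value) for c in p.candidates}
            for sid, p in profiles.items()
        }
        assert got == expected
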