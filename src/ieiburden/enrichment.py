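"""Cohort allele-frequency enrichment against a reference database.

For every identified variant the cohort minor-allele frequency (AC/AN) is
compared to a gnomAD-style reference by uncorrected Pearson chi-square on
the 2x2 allele-count table, in three comparison families:

1. whole cohort versus the overall reference,
2. a declared subject stratum (e.g. self-reported race) versus its
   complement within the cohort,
3. the stratum versus a matched reference ancestry.

p-values are Benjamini-Hochberg adjusted per family with the family size
set to the total number of unique identified variants (which may exceed
the number of tests actually run in a family).

Allele-number conventions: autosomes AN = 2 x subjects; chromosome X
AN = 2 x females + 1 x males, with male alt calls contributing one allele.
"""

from __future__ import annotations

import math
from collections import defaultdict
from dataclasses import dataclass
from enum import Enum
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .association import ContingencyTable, bh_adjust, chi_square_2x2
from .candidate_filter import GenotypeCall, Sex, Zygosity
from .reference_data import ReferenceFrequencyEntry, ValidationError, VariantKey

__all__ = [
    "AlleleCount",
    "ComparisonKind",
    "MAFComparisonResult",
    "StratumSpec",
    "cohort_allele_counts",
    "compare_frequencies",
    "run_enrichment",
    "results_to_frame",
]


@dataclass(frozen=True)
class AlleleCount:
    allele_count: int
    allele_number: int

    def __post_init__(self) -> None:
        if not (0 <= self.allele_count <= self.allele_number):
            raise ValidationError(
                f"invalid allele counts {self.allele_count}/{self.allele_number}"
            )

    @property
    def maf(self) -> float:
        return self.allele_count / self.allele_number if self.allele_number else 0.0


class ComparisonKind(str, Enum):
    COHORT_VS_REFERENCE = "cohort_vs_reference"
    STRATUM_VS_COMPLEMENT = "stratum_vs_complement"
    STRATUM_VS_REFERENCE_ANCESTRY = "stratum_vs_reference_ancestry"


@dataclass
class MAFComparisonResult:
    key: VariantKey
    comparison: ComparisonKind
    cohort_counts: AlleleCount
    reference_counts: AlleleCount
    maf_ratio: float  # math.inf encodes "nonzero / 0"
    p_value: float
    n_carriers: int
    p_adjusted: float | None = None


@dataclass(frozen=True)
class StratumSpec:
    """A user-declared cohort stratum and its reference ancestry mapping.

    ``column`` / ``value`` select subjects from the subject table (exact
    string match); ``reference_ancestry`` names the paired ac_/an_ columns
    of the reference table used for the stratum-vs-reference comparison.
    """

    column: str
    value: str
    reference_ancestry: str | None = None
    label: str | None = None

    @property
    def name(self) -> str:
        return self.label or f"{self.column}={self.value}"


def _allele_contribution(zygosity: Zygosity, on_x: bool, sex: Sex) -> int:
    if on_x and sex is Sex.MALE:
        # male X: one allele whether coded hemi, het or hom
        return 1
    if zygosity is Zygosity.HOM_ALT:
        return 2
    if zygosity is Zygosity.HET:
        return 1
    if zygosity is Zygosity.HEMI:
        raise ValidationError("hemizygous call outside male X context")
    return 0


def cohort_allele_counts(
    calls: Iterable[GenotypeCall],
    subject_sexes: Mapping[str, Sex],
    key: VariantKey,
) -> AlleleCount:
    """Cohort AC/AN for one variant over all subjects in the table.

    ``calls`` are the carrier genotypes at ``key`` (subjects without a call
    count as homozygous reference).
    """
    n_male = sum(1 for s in subject_sexes.values() if s is Sex.MALE)
    n_female = len(subject_sexes) - n_male
    on_x = key.is_x
    an = 2 * n_female + n_male if on_x else 2 * len(subject_sexes)
    ac = 0
    for call in calls:
        if call.key != key:
            continue
        sex = subject_sexes.get(call.subject_id)
        if sex is None:
            raise ValidationError(f"call for unknown subject {call.subject_id}")
        ac += _allele_contribution(call.zygosity, on_x, sex)
    if ac > an:
        raise ValidationError(f"{key}: cohort AC {ac} exceeds AN {an}")
    return AlleleCount(allele_count=ac, allele_number=an)


def compare_frequencies(
    cohort: AlleleCount, reference: AlleleCount
) -> tuple[float, float]:
    """(MAF ratio, chi-square p) for a cohort-vs-reference allele table.

    The ratio is cohort MAF / reference MAF, ``math.inf`` when the
    reference MAF is zero but the cohort's is not, and ``nan`` when both
    are zero. The p-value is the uncorrected Pearson chi-square on
    [[AC, AN-AC], [AC_ref, AN_ref-AC_ref]].
    """
    if cohort.allele_number <= 0 or reference.allele_number <= 0:
        raise ValidationError("allele numbers must be positive")
    table = ContingencyTable(
        a=cohort.allele_count,
        b=cohort.allele_number - cohort.allele_count,
        c=reference.allele_count,
        d=reference.allele_number - reference.allele_count,
    )
    p = chi_square_2x2(table)
    if reference.maf == 0.0:
        ratio = math.inf if cohort.maf > 0 else math.nan
    else:
        ratio = cohort.maf / reference.maf
    return ratio, p


def run_enrichment(
    cohort_calls: Iterable[GenotypeCall],
    subjects: pd.DataFrame,
    subject_sexes: Mapping[str, Sex],
    reference: Mapping[VariantKey, ReferenceFrequencyEntry],
    variant_keys: Sequence[VariantKey],
    strata: Sequence[StratumSpec] = (),
    m: int | None = None,
) -> list[MAFComparisonResult]:
    """Run the three enrichment comparison families over identified variants.

    ``variant_keys`` are the unique identified variants; ``m`` (default:
    their number) is the BH family size applied within each family.
    Variants lacking a reference entry are skipped in reference-based
    families; a stratum selecting no subjects is an error.
    """
    keys = list(dict.fromkeys(variant_keys))
    if m is None:
        m = len(keys)
    calls_by_key: dict[VariantKey, list[GenotypeCall]] = defaultdict(list)
    for call in cohort_calls:
        calls_by_key[call.key].append(call)

    subjects = subjects.copy()
    subjects["subject_id"] = subjects["subject_id"].astype(str)

    def sexes_for(ids: set[str]) -> dict[str, Sex]:
        return {sid: sex for sid, sex in subject_sexes.items() if sid in ids}

    all_ids = set(subjects["subject_id"])
    missing_sex = all_ids - set(subject_sexes)
    if missing_sex:
        raise ValidationError(f"subjects without sex assignment: {sorted(missing_sex)}")

    families: dict[ComparisonKind, list[MAFComparisonResult]] = {
        kind: [] for kind in ComparisonKind
    }

    def carriers(calls: list[GenotypeCall], ids: set[str] | None = None) -> int:
        subs = {c.subject_id for c in calls}
        return len(subs if ids is None else subs & ids)

    # family 1: cohort vs overall reference
    for key in keys:
        entry = reference.get(key)
        if entry is None:
            continue
        cohort_ac = cohort_allele_counts(calls_by_key.get(key, []), subject_sexes, key)
        ref_ac = AlleleCount(entry.allele_count, entry.allele_number)
        ratio, p = compare_frequencies(cohort_ac, ref_ac)
        families[ComparisonKind.COHORT_VS_REFERENCE].append(
            MAFComparisonResult(
                key=key,
                comparison=ComparisonKind.COHORT_VS_REFERENCE,
                cohort_counts=cohort_ac,
                reference_counts=ref_ac,
                maf_ratio=ratio,
                p_value=p,
                n_carriers=carriers(calls_by_key.get(key, [])),
            )
        )

    for spec in strata:
        if spec.column not in subjects.columns:
            raise ValidationError(f"stratum column '{spec.column}' not in subject table")
        in_ids = set(
            subjects.loc[subjects[spec.column].astype(str) == spec.value, "subject_id"]
        )
        if not in_ids:
            raise ValidationError(f"stratum {spec.name} selects no subjects")
        out_ids = all_ids - in_ids
        in_sexes, out_sexes = sexes_for(in_ids), sexes_for(out_ids)

        for key in keys:
            in_calls = [c for c in calls_by_key.get(key, []) if c.subject_id in in_ids]
            out_calls = [c for c in calls_by_key.get(key, []) if c.subject_id in out_ids]
            stratum_ac = cohort_allele_counts(in_calls, in_sexes, key)

            # family 2: stratum vs its in-cohort complement
            if out_sexes:
                complement_ac = cohort_allele_counts(out_calls, out_sexes, key)
                ratio, p = compare_frequencies(stratum_ac, complement_ac)
                families[ComparisonKind.STRATUM_VS_COMPLEMENT].append(
                    MAFComparisonResult(
                        key=key,
                        comparison=ComparisonKind.STRATUM_VS_COMPLEMENT,
                        cohort_counts=stratum_ac,
                        reference_counts=complement_ac,
                        maf_ratio=ratio,
                        p_value=p,
                        n_carriers=carriers(in_calls),
                    )
                )

            # family 3: stratum vs matched reference ancestry
            entry = reference.get(key)
            if spec.reference_ancestry and entry is not None:
                pair = entry.per_ancestry.get(spec.reference_ancestry)
                if pair is not None and pair[1] > 0:
                    ref_ac = AlleleCount(*pair)
                    ratio, p = compare_frequencies(stratum_ac, ref_ac)
                    families[ComparisonKind.STRATUM_VS_REFERENCE_ANCESTRY].append(
                        MAFComparisonResult(
                            key=key,
                            comparison=ComparisonKind.STRATUM_VS_REFERENCE_ANCESTRY,
                            cohort_counts=stratum_ac,
                            reference_counts=ref_ac,
                            maf_ratio=ratio,
                            p_value=p,
                            n_carriers=carriers(in_calls),
                        )
                    )

    results: list[MAFComparisonResult] = []
    for kind, members in families.items():
        if not members:
            continue
        family_m = max(m, len(members))
        adjusted = bh_adjust([r.p_value for r in members], m=family_m)
        for r, q in zip(members, adjusted):
            r.p_adjusted = q
        results.extend(members)
    results.sort(key=lambda r: (r.p_adjusted if r.p_adjusted is not None else 1.0))
    return results


def results_to_frame(results: Iterable[MAFComparisonResult]) -> pd.DataFrame:
    rows = []
    for r in results:
        rows.append(
            {
                "chrom": r.key.chromosome,
                "pos": r.key.position,
                "ref": r.key.ref_allele,
                "alt": r.key.alt_allele,
                "comparison": r.comparison.value,
                "cohort_ac": r.cohort_counts.allele_count,
                "cohort_an": r.cohort_counts.allele_number,
                "ref_ac": r.reference_counts.allele_count,
                "ref_an": r.reference_counts.allele_number,
                "maf_ratio": r.maf_ratio,
                "n_carriers": r.n_carriers,
                "p": r.p_value,
                "p_adj": r.p_adjusted,
            }
        )
    return pd.DataFrame(rows)
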