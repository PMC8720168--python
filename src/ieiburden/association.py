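"""2x2 association statistics for genotype-phenotype comparisons.

The statistical toolkit of the analysis: odds ratios with Woolf (logit)
confidence intervals and Haldane-Anscombe zero-cell handling, Pearson
chi-square without continuity correction, the Fisher exact test under the
probability-mass two-sided convention, the Wilcoxon rank-sum test, and
Benjamini-Hochberg step-up adjustment that honors an externally declared
family size. :func:`run_association_suite` wires these into the cohort
comparison: "any IEI" versus no variant by chi-square, and each IUIS
functional group (plus the "multiple" group) versus the no-variant
reference by Fisher exact, with BH adjustment per outcome family.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from enum import Enum
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .candidate_filter import SubjectIEIProfile
from .reference_data import IUISCategory

__all__ = [
    "ContingencyTable",
    "AssociationResult",
    "TestKind",
    "odds_ratio",
    "woolf_ci",
    "chi_square_2x2",
    "fisher_exact",
    "wilcoxon_rank_sum",
    "bh_adjust",
    "run_association_suite",
    "GROUP_EXPOSURES",
    "ANY_IEI",
    "MULTIPLE",
]

ANY_IEI = "any_iei"
MULTIPLE = "multiple"
#: group-level exposure labels: the nine IUIS categories plus "multiple"
GROUP_EXPOSURES = tuple(c.value for c in IUISCategory) + (MULTIPLE,)


class TestKind(str, Enum):
    CHI_SQUARE = "chi_square"
    FISHER = "fisher"


@dataclass(frozen=True)
class ContingencyTable:
    """2x2 counts: a = exposed & outcome, b = exposed & no outcome,
    c = unexposed & outcome, d = unexposed & no outcome."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("contingency cells must be non-negative")

    @property
    def total(self) -> int:
        return self.a + self.b + self.c + self.d

    @property
    def has_zero_cell(self) -> bool:
        return min(self.a, self.b, self.c, self.d) == 0

    def cells(self) -> tuple[float, float, float, float]:
        return float(self.a), float(self.b), float(self.c), float(self.d)

    def adjusted_cells(self) -> tuple[float, float, float, float]:
        """Haldane-Anscombe: add 0.5 to every cell when any cell is zero."""
        if self.has_zero_cell:
            return (self.a + 0.5, self.b + 0.5, self.c + 0.5, self.d + 0.5)
        return self.cells()

    @staticmethod
    def from_flags(exposed: Sequence[bool], outcome: Sequence[bool]) -> "ContingencyTable":
        e = np.asarray(exposed, dtype=bool)
        o = np.asarray(outcome, dtype=bool)
        return ContingencyTable(
            a=int((e & o).sum()),
            b=int((e & ~o).sum()),
            c=int((~e & o).sum()),
            d=int((~e & ~o).sum()),
        )


def odds_ratio(t: ContingencyTable) -> float:
    """Odds ratio (a*d)/(b*c); Haldane-Anscombe applied when any cell is zero."""
    if t.total == 0:
        raise ValueError("odds ratio undefined for an all-zero table")
    a, b, c, d = t.adjusted_cells()
    return (a * d) / (b * c)


def woolf_ci(t: ContingencyTable, level: float = 0.95) -> tuple[float, float]:
    """Woolf logit confidence interval exp(ln OR +/- z*sqrt(sum 1/cell))."""
    a, b, c, d = t.adjusted_cells()
    if min(a, b, c, d) <= 0:
        raise ValueError("Woolf interval needs positive cells")
    log_or = np.log((a * d) / (b * c))
    se = np.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    z = stats.norm.ppf(0.5 + level / 2)
    return float(np.exp(log_or - z * se)), float(np.exp(log_or + z * se))


def chi_square_2x2(t: ContingencyTable) -> float:
    """Pearson chi-square p-value, 1 df, no continuity correction.

    A zero margin makes the statistic degenerate; the test returns p = 1
    with a warning.
    """
    a, b, c, d = t.cells()
    n = a + b + c + d
    if n == 0:
        raise ValueError("chi-square undefined for an all-zero table")
    r1, r2, c1, c2 = a + b, c + d, a + c, b + d
    if min(r1, r2, c1, c2) == 0:
        warnings.warn("zero margin in 2x2 table; chi-square p set to 1", stacklevel=2)
        return 1.0
    statistic = n * (a * d - b * c) ** 2 / (r1 * r2 * c1 * c2)
    return float(stats.chi2.sf(statistic, df=1))


_FISHER_RELTOL = 1e-7


def fisher_exact(t: ContingencyTable) -> float:
    """Two-sided Fisher exact p-value, probability-mass convention.

    Sums the hypergeometric probabilities of every table with the observed
    margins whose probability does not exceed that of the observed table
    (with a small relative tolerance on the comparison, as in mainstream
    statistical software).
    """
    a, b, c, d = t.a, t.b, t.c, t.d
    n = t.total
    if n == 0:
        raise ValueError("Fisher exact undefined for an all-zero table")
    r1, c1 = a + b, a + c
    lo = max(0, r1 + c1 - n)
    hi = min(r1, c1)
    support = np.arange(lo, hi + 1)
    pmf = stats.hypergeom.pmf(support, n, c1, r1)
    p_obs = pmf[a - lo]
    p = pmf[pmf <= p_obs * (1 + _FISHER_RELTOL)].sum()
    return float(min(1.0, p))


def wilcoxon_rank_sum(x: Sequence[float], y: Sequence[float]) -> float:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney) p-value.

    Exact null distribution for combined n <= 20 without ties; normal
    approximation with tie correction otherwise.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    combined = np.concatenate([x, y])
    no_ties = np.unique(combined).size == combined.size
    method = "exact" if (combined.size <= 20 and no_ties) else "asymptotic"
    res = stats.mannwhitneyu(
        x, y, alternative="two-sided", method=method, use_continuity=False
    )
    return float(res.pvalue)


def bh_adjust(p_values: Sequence[float], m: int | None = None) -> list[float]:
    """Benjamini-Hochberg step-up adjusted p-values, in input order.

    ``m`` is the declared family size and may exceed the list length (as
    when a family of m tests is reported piecemeal); it defaults to the
    list length and must be at least that.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return []
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0,1]")
    if m is None:
        m = p.size
    if m < p.size:
        raise ValueError(f"family size m={m} smaller than number of p-values {p.size}")
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, p.size + 1)
    q = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.minimum(q, 1.0)
    out = np.empty_like(q)
    out[order] = q
    return out.tolist()


@dataclass
class AssociationResult:
    exposure_label: str
    outcome_label: str
    table: ContingencyTable
    odds_ratio: float
    ci_low: float
    ci_high: float
    p_value: float
    test_used: TestKind
    zero_cell_adjusted: bool
    p_adjusted: float | None = None


def _exposure_membership(
    profiles: Mapping[str, SubjectIEIProfile],
) -> dict[str, set[str]]:
    """Subject sets per exposure label; a subject joins every category it
    carries, plus "multiple" when it spans >= 2 categories."""
    members: dict[str, set[str]] = {label: set() for label in (ANY_IEI,) + GROUP_EXPOSURES}
    for sid, profile in profiles.items():
        if not profile.iei_positive:
            continue
        members[ANY_IEI].add(sid)
        for cat in profile.iuis_groups:
            members[cat.value].add(sid)
        if profile.multiple_groups:
            members[MULTIPLE].add(sid)
    return members


def run_association_suite(
    profiles: Mapping[str, SubjectIEIProfile],
    phenotypes: pd.DataFrame,
    outcomes: Iterable[str],
    include_any_in_family: bool = True,
) -> list[AssociationResult]:
    """Genotype-phenotype association over the configured binary outcomes.

    For each outcome (a boolean / nullable-boolean column of ``phenotypes``,
    indexed by subject_id): the "any IEI" exposure versus variant-negative
    subjects is tested by uncorrected chi-square; each IUIS group and the
    "multiple" group versus the variant-negative reference by Fisher exact.
    BH adjustment is applied per outcome over the group tests (including
    the "any IEI" test when ``include_any_in_family``). Subjects whose
    outcome is missing are dropped from that outcome's tables.
    """
    outcomes = list(outcomes)
    unknown = [o for o in outcomes if o not in phenotypes.columns]
    if unknown:
        raise ValueError(f"unknown outcome labels: {unknown}")
    members = _exposure_membership(profiles)
    negatives = {sid for sid, p in profiles.items() if not p.iei_positive}
    pheno_ids = set(phenotypes.index.astype(str))

    results: list[AssociationResult] = []
    for outcome in outcomes:
        col = phenotypes[outcome]
        observed = {
            sid
            for sid in pheno_ids
            if sid in profiles and not pd.isna(col.loc[sid])
        }

        def build(label: str, exposed_ids: set[str], test: TestKind) -> AssociationResult:
            exposed = sorted(exposed_ids & observed)
            unexposed = sorted(negatives & observed)
            table = ContingencyTable(
                a=sum(bool(col.loc[s]) for s in exposed),
                b=sum(not col.loc[s] for s in exposed),
                c=sum(bool(col.loc[s]) for s in unexposed),
                d=sum(not col.loc[s] for s in unexposed),
            )
            p = chi_square_2x2(table) if test is TestKind.CHI_SQUARE else fisher_exact(table)
            low, high = woolf_ci(table)
            return AssociationResult(
                exposure_label=label,
                outcome_label=outcome,
                table=table,
                odds_ratio=odds_ratio(table),
                ci_low=low,
                ci_high=high,
                p_value=p,
                test_used=test,
                zero_cell_adjusted=table.has_zero_cell,
            )

        any_result = build(ANY_IEI, members[ANY_IEI], TestKind.CHI_SQUARE)
        group_results = [
            build(label, members[label], TestKind.FISHER) for label in GROUP_EXPOSURES
        ]
        family = ([any_result] if include_any_in_family else []) + group_results
        adjusted = bh_adjust([r.p_value for r in family])
        for r, q in zip(family, adjusted):
            r.p_adjusted = q
        results.append(any_result)
        results.extend(group_results)
    return results


def results_to_frame(results: Iterable[AssociationResult]) -> pd.DataFrame:
    """Flatten association results for TSV/JSON export."""
    rows = []
    for r in results:
        rows.append(
            {
                "exposure": r.exposure_label,
                "outcome": r.outcome_label,
                "a": r.table.a,
                "b": r.table.b,
                "c": r.table.c,
                "d": r.table.d,
                "odds_ratio": r.odds_ratio,
                "ci_low": r.ci_low,
                "ci_high": r.ci_high,
                "p": r.p_value,
                "p_adj": r.p_adjusted,
                "test_used": r.test_used.value,
                "zero_cell_adjusted": r.zero_cell_adjusted,
            }
        )
    return pd.DataFrame(rows)
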