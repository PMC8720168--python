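"""Candidate-variant filter and per-subject IEI profiling.

The filter reproduces a gene-panel exome screen for inborn errors of
immunity (IEI): genotype calls are restricted to panel genes, gated on
sequencing quality (depth > 10x and PHRED > 20, strict), restricted to
nonsynonymous consequences, to rare alleles (MAF < 0.05 in every population
database where the variant is present), and to a pathogenicity basis —
a curated disease-mutation class (DM / DM?) or a novel null consequence
(nonsense, frameshift, +/-1-2 splice site, start loss). Highly recurrent
novel nulls are removed as likely sequencing artifacts. Surviving variants
are then tested for a disease-consistent inheritance pattern per gene:

* one variant for autosomal-dominant disorders (or dual AD/AR disorders),
* two variants — homozygous, or two distinct heterozygous calls taken as a
  *putative* compound heterozygote (phase is unknown without parental
  genotypes) — for autosomal-recessive-only disorders,
* one variant for X-linked disorders in males; females need biallelic
  calls under XLR and a single call under XLD.

The output is one :class:`SubjectIEIProfile` per subject with the
qualifying candidates, IEI status, and the set of IUIS functional
categories the candidate genes belong to.
"""

from __future__ import annotations

import logging
from collections import defaultdict
from dataclasses import dataclass, field, replace
from enum import Enum
from typing import Iterable, Mapping, Sequence

from .reference_data import (
    Consequence,
    GenePanelEntry,
    InheritanceMode,
    IUISCategory,
    PathogenicityClass,
    ValidationError,
    VariantAnnotation,
    VariantKey,
)

__all__ = [
    "Sex",
    "Zygosity",
    "Basis",
    "SatisfiedMode",
    "GenotypeCall",
    "FilterConfig",
    "CandidateVariant",
    "SubjectIEIProfile",
    "FilterFunnel",
    "passes_qc",
    "is_nonsynonymous",
    "is_rare",
    "is_null_variant",
    "pathogenicity_basis",
    "flag_recurrent_nulls",
    "evaluate_inheritance",
    "run_candidate_filter",
]

logger = logging.getLogger(__name__)

NONSYNONYMOUS = frozenset(
    {
        Consequence.MISSENSE,
        Consequence.NONSENSE,
        Consequence.FRAMESHIFT,
        Consequence.SPLICE_SITE,
        Consequence.START_LOST,
    }
)

#: null (loss-of-function) consequence set used by the novel-null rule
NULL_CONSEQUENCES = frozenset(
    {
        Consequence.NONSENSE,
        Consequence.FRAMESHIFT,
        Consequence.SPLICE_SITE,
        Consequence.START_LOST,
    }
)


class Sex(str, Enum):
    MALE = "male"
    FEMALE = "female"


class Zygosity(str, Enum):
    HET = "het"
    HOM_ALT = "hom_alt"
    HEMI = "hemi"


class Basis(str, Enum):
    """Why a variant is considered (potentially) pathogenic."""

    HGMD_DM = "HGMD_DM"
    HGMD_DM_QUERY = "HGMD_DM_query"
    NOVEL_NULL = "NOVEL_NULL"


class SatisfiedMode(str, Enum):
    """Which inheritance pattern the candidate satisfies for its subject."""

    AD = "AD"
    AR_HOM = "AR_hom"
    AR_COMPOUND_HET = "AR_compound_het"
    XL_MALE = "XL_male"
    XL_FEMALE_BIALLELIC = "XL_female_biallelic"


@dataclass(frozen=True)
class GenotypeCall:
    """One subject x variant genotype with its QC metrics."""

    subject_id: str
    key: VariantKey
    zygosity: Zygosity
    read_depth: int
    quality: float

    def __post_init__(self) -> None:
        if self.read_depth < 0:
            raise ValidationError(f"{self.subject_id} {self.key}: negative depth")


@dataclass(frozen=True)
class FilterConfig:
    """Thresholds of the candidate filter.

    All comparisons are strict: depth must exceed ``min_depth``, quality
    must exceed ``min_qual``, each present database MAF must be below
    ``maf_threshold``, and a novel null is removed when its carrier
    fraction exceeds ``recurrent_null_carrier_fraction``.
    """

    min_depth: int = 10
    min_qual: float = 20.0
    maf_threshold: float = 0.05
    recurrent_null_carrier_fraction: float = 0.05
    maf_missing_is_rare: bool = True

    def __post_init__(self) -> None:
        if self.min_depth < 0 or self.min_qual < 0:
            raise ValidationError("QC thresholds must be non-negative")
        if not (0.0 <= self.maf_threshold <= 1.0):
            raise ValidationError("maf_threshold must lie in [0,1]")
        if not (0.0 <= self.recurrent_null_carrier_fraction <= 1.0):
            raise ValidationError("recurrent_null_carrier_fraction must lie in [0,1]")


@dataclass(frozen=True)
class CandidateVariant:
    """A qualifying variant call with the rule that admitted it.

    ``annotation`` and ``iuis_category`` are attached by the pipeline; the
    inheritance evaluator emits candidates with only call/basis/mode set.
    """

    call: GenotypeCall
    basis: Basis
    satisfied_mode: SatisfiedMode
    annotation: VariantAnnotation | None = None
    iuis_category: IUISCategory | None = None


@dataclass
class SubjectIEIProfile:
    """Per-subject filter output.

    Invariants: ``iei_positive`` iff at least one candidate;
    ``multiple_groups`` iff candidates span >= 2 IUIS categories.
    """

    subject_id: str
    candidates: list[CandidateVariant] = field(default_factory=list)

    @property
    def variant_count(self) -> int:
        return len(self.candidates)

    @property
    def iei_positive(self) -> bool:
        return self.variant_count >= 1

    @property
    def iuis_groups(self) -> frozenset[IUISCategory]:
        return frozenset(
            c.iuis_category for c in self.candidates if c.iuis_category is not None
        )

    @property
    def multiple_groups(self) -> bool:
        return len(self.iuis_groups) >= 2


@dataclass
class FilterFunnel:
    """Per-stage exclusion counters; input = survivors + sum of exclusions."""

    input_calls: int = 0
    unresolvable: int = 0
    off_panel: int = 0
    failed_qc: int = 0
    not_nonsynonymous: int = 0
    not_rare: int = 0
    no_pathogenicity_basis: int = 0
    recurrent_null: int = 0
    inheritance_unsatisfied: int = 0
    survivors: int = 0

    def as_dict(self) -> dict[str, int]:
        return dict(self.__dict__)

    def conserved(self) -> bool:
        excluded = (
            self.unresolvable
            + self.off_panel
            + self.failed_qc
            + self.not_nonsynonymous
            + self.not_rare
            + self.no_pathogenicity_basis
            + self.recurrent_null
            + self.inheritance_unsatisfied
        )
        return self.input_calls == excluded + self.survivors


def passes_qc(call: GenotypeCall, config: FilterConfig = FilterConfig()) -> bool:
    """Coverage and quality gate: depth > min_depth AND quality > min_qual."""
    return call.read_depth > config.min_depth and call.quality > config.min_qual


def is_nonsynonymous(annotation: VariantAnnotation) -> bool:
    return annotation.consequence in NONSYNONYMOUS


def is_rare(annotation: VariantAnnotation, config: FilterConfig = FilterConfig()) -> bool:
    """Rarity gate: every *present* database MAF below the threshold.

    A variant absent from all databases counts as rare when
    ``maf_missing_is_rare`` (novel alleles have no database frequency).
    """
    mafs = annotation.population_mafs
    if not mafs:
        return config.maf_missing_is_rare
    return all(maf < config.maf_threshold for maf in mafs.values())


def is_null_variant(annotation: VariantAnnotation) -> bool:
    return annotation.consequence in NULL_CONSEQUENCES


def pathogenicity_basis(annotation: VariantAnnotation) -> Basis | None:
    """Basis for retaining a variant, or ``None`` when it has none.

    DM and DM? classes qualify directly; an unclassified variant qualifies
    only through the novel-null rule.
    """
    if annotation.pathogenicity_class is PathogenicityClass.DM:
        return Basis.HGMD_DM
    if annotation.pathogenicity_class is PathogenicityClass.DM_QUERY:
        return Basis.HGMD_DM_QUERY
    if is_null_variant(annotation):
        return Basis.NOVEL_NULL
    return None


def flag_recurrent_nulls(
    cohort_calls: Iterable[GenotypeCall],
    annotations: Mapping[VariantKey, VariantAnnotation],
    n_subjects: int,
    config: FilterConfig = FilterConfig(),
) -> set[VariantKey]:
    """Keys of novel-null variants carried by more than the allowed cohort fraction.

    Applies only to variants whose basis is the novel-null rule; curated
    DM/DM? variants are never flagged regardless of recurrence.
    """
    if n_subjects <= 0:
        raise ValidationError("n_subjects must be positive")
    carriers: dict[VariantKey, set[str]] = defaultdict(set)
    for call in cohort_calls:
        ann = annotations.get(call.key)
        if ann is None:
            continue
        if pathogenicity_basis(ann) is Basis.NOVEL_NULL:
            carriers[call.key].add(call.subject_id)
    return {
        key
        for key, subs in carriers.items()
        if len(subs) / n_subjects > config.recurrent_null_carrier_fraction
    }


def _sort_key(c: CandidateVariant) -> tuple[str, int, str]:
    k = c.call.key
    return (k.chromosome, k.position, k.alt_allele)


def evaluate_inheritance(
    entry: GenePanelEntry,
    subject_sex: Sex,
    qualifying_calls: Sequence[tuple[GenotypeCall, Basis]],
) -> list[CandidateVariant]:
    """Apply the disease-consistent inheritance rules for one subject x gene.

    ``qualifying_calls`` must already have passed QC, consequence, rarity,
    pathogenicity and recurrence gates. Each variant yields at most one
    candidate; with several modes on the disorder, the dominant-style
    branches (AD, then XLD, then XLR, then AR) label a call first.
    """
    for call, _ in qualifying_calls:
        if call.zygosity is Zygosity.HEMI and subject_sex is Sex.FEMALE:
            raise ValidationError(
                f"hemizygous call for female subject {call.subject_id} at {call.key}"
            )

    modes = entry.inheritance_modes
    chosen: dict[VariantKey, CandidateVariant] = {}

    def emit(call: GenotypeCall, basis: Basis, mode: SatisfiedMode) -> None:
        if call.key not in chosen:
            chosen[call.key] = CandidateVariant(call=call, basis=basis, satisfied_mode=mode)

    if InheritanceMode.AD in modes:
        # single variant suffices, het or hom; also covers dual AD/AR disorders
        for call, basis in qualifying_calls:
            emit(call, basis, SatisfiedMode.AD)

    if InheritanceMode.XLD in modes:
        for call, basis in qualifying_calls:
            mode = SatisfiedMode.XL_MALE if subject_sex is Sex.MALE else SatisfiedMode.AD
            emit(call, basis, mode)

    if InheritanceMode.XLR in modes:
        if subject_sex is Sex.MALE:
            # hemizygous or het-coded male X calls all qualify
            for call, basis in qualifying_calls:
                emit(call, basis, SatisfiedMode.XL_MALE)
        else:
            for call, basis in qualifying_calls:
                if call.zygosity is Zygosity.HOM_ALT:
                    emit(call, basis, SatisfiedMode.XL_FEMALE_BIALLELIC)

    if InheritanceMode.AR in modes and InheritanceMode.AD not in modes and not entry.is_x_linked:
        for call, basis in qualifying_calls:
            if call.zygosity is Zygosity.HOM_ALT:
                emit(call, basis, SatisfiedMode.AR_HOM)
        hets = [(c, b) for c, b in qualifying_calls if c.zygosity is Zygosity.HET]
        if len({c.key for c, _ in hets}) >= 2:
            # putative compound heterozygote: phase unknown without parents
            for call, basis in hets:
                emit(call, basis, SatisfiedMode.AR_COMPOUND_HET)

    return sorted(chosen.values(), key=_sort_key)


def run_candidate_filter(
    cohort_calls: Iterable[GenotypeCall],
    subject_sexes: Mapping[str, Sex],
    panel: Mapping[str, GenePanelEntry],
    annotations: Mapping[VariantKey, VariantAnnotation],
    config: FilterConfig = FilterConfig(),
    funnel: FilterFunnel | None = None,
) -> dict[str, SubjectIEIProfile]:
    """Run the full candidate filter and build per-subject IEI profiles.

    Stages, in order: panel-gene restriction -> QC -> nonsynonymous ->
    rarity -> pathogenicity basis -> recurrent-null removal -> per-gene
    inheritance evaluation. Every subject in ``subject_sexes`` receives a
    profile (possibly empty); a call for a subject not in the table is an
    error. Calls whose key is absent from the annotation table are logged
    and skipped.
    """
    calls = list(cohort_calls)
    unknown = sorted({c.subject_id for c in calls} - set(subject_sexes))
    if unknown:
        raise ValidationError(
            f"genotype calls for subjects absent from the subject table: {unknown}"
        )
    if funnel is None:
        funnel = FilterFunnel()
    funnel.input_calls = len(calls)
    n_subjects = len(subject_sexes)
    if n_subjects == 0:
        return {}

    # stage gates up to pathogenicity basis
    surviving: list[tuple[GenotypeCall, VariantAnnotation, Basis]] = []
    for call in calls:
        ann = annotations.get(call.key)
        if ann is None:
            logger.warning("skipping unresolvable variant key %s", call.key)
            funnel.unresolvable += 1
            continue
        if ann.gene_symbol not in panel:
            funnel.off_panel += 1
            continue
        if not passes_qc(call, config):
            funnel.failed_qc += 1
            continue
        if not is_nonsynonymous(ann):
            funnel.not_nonsynonymous += 1
            continue
        if not is_rare(ann, config):
            funnel.not_rare += 1
            continue
        basis = pathogenicity_basis(ann)
        if basis is None:
            funnel.no_pathogenicity_basis += 1
            continue
        surviving.append((call, ann, basis))

    recurrent = flag_recurrent_nulls(
        [c for c, _, _ in surviving], annotations, n_subjects, config
    )
    kept: list[tuple[GenotypeCall, VariantAnnotation, Basis]] = []
    for call, ann, basis in surviving:
        if basis is Basis.NOVEL_NULL and call.key in recurrent:
            funnel.recurrent_null += 1
        else:
            kept.append((call, ann, basis))

    # group per subject per gene and apply inheritance rules
    by_subject_gene: dict[tuple[str, str], list[tuple[GenotypeCall, VariantAnnotation, Basis]]]
    by_subject_gene = defaultdict(list)
    for call, ann, basis in kept:
        by_subject_gene[(call.subject_id, ann.gene_symbol)].append((call, ann, basis))

    profiles = {sid: SubjectIEIProfile(subject_id=sid) for sid in subject_sexes}
    for (sid, gene), items in sorted(by_subject_gene.items()):
        entry = panel[gene]
        ann_by_key = {call.key: ann for call, ann, _ in items}
        cands = evaluate_inheritance(
            entry, subject_sexes[sid], [(call, basis) for call, _, basis in items]
        )
        emitted = [
            replace(
                cand,
                annotation=ann_by_key[cand.call.key],
                iuis_category=entry.iuis_category,
            )
            for cand in cands
        ]
        funnel.inheritance_unsatisfied += len(items) - len(emitted)
        profiles[sid].candidates.extend(emitted)

    for profile in profiles.values():
        profile.candidates.sort(key=_sort_key)
        funnel.survivors += len(profile.candidates)
    return profiles
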