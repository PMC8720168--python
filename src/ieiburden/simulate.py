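"""Synthetic severe-sepsis cohort generator.

Produces complete, statistically controlled inputs for the pipeline —
genotypes (VCF), variant annotations, gene panel, reference allele
frequencies, subject demographics/outcomes and long-format clinical
records — without any external data.

The generative model:

* subjects are assigned sex and an ancestry stratum by declared
  proportions;
* genotypes are drawn per variant under Hardy-Weinberg equilibrium at the
  stratum-specific allele frequency, with X-chromosome variants sampled
  per sex (males hemizygous);
* binary phenotypes are linked to carrier status through a logistic
  model, ``logit(p) = logit(baseline) + ln(OR) * exposed``, one planted
  odds ratio per (exposure, outcome) pair;
* culture records realize the drawn infection outcomes inside the +/-48 h
  enrollment window, with contaminant organisms and out-of-window
  positives planted at configurable rates, and lab series (2-4 points)
  realize the drawn extreme-value inflammatory flags.

Every source of randomness flows from one master seed through named
``numpy`` substreams, so each output file is reproducible independently.
The default configuration mirrors the structure of the study cohort this
package analyzes: n = 330 subjects, ~54% male, ~21% of subjects in an
African-American-like stratum with enriched complement-variant
frequencies, variant frequencies tuned so roughly 60% of subjects carry at
least one qualifying variant, and planted odds ratios in the 1.7-4.2
range for the inflammatory and support outcomes.
"""

from __future__ import annotations

import hashlib
import json
import math
from collections import defaultdict
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .association import ContingencyTable
from .candidate_filter import GenotypeCall, Sex, Zygosity
from .reference_data import (
    Consequence,
    GenePanelEntry,
    InheritanceMode,
    IUISCategory,
    PathogenicityClass,
    ReferenceFrequencyEntry,
    VariantAnnotation,
    VariantKey,
    write_annotation_table,
    write_gene_panel,
    write_reference_frequencies,
)
from .vcf_io import write_vcf

__all__ = [
    "AncestryStratum",
    "SimVariant",
    "PlantedEffect",
    "SimulationConfig",
    "default_config",
    "substreams",
    "simulate_subjects",
    "simulate_genotypes",
    "build_panel",
    "build_annotations",
    "build_reference",
    "planted_exposures",
    "draw_outcome",
    "simulate_two_arm_table",
    "simulate_phenotypes",
    "write_cohort_bundle",
]

CULTURE_OUTCOMES = {
    "blood_positive": "blood",
    "urine_positive": "urine",
    "respiratory_positive": "respiratory",
    "viral_positive": "viral_test",
}
LAB_OUTCOMES = {
    "lymphopenia": "lymphocytes",
    "hyperferritinemia": "ferritin",
    "thrombocytopenia": "platelets",
    "crp_high": "crp",
}
_PATHOGENS = {
    "blood": "escherichia coli",
    "urine": "klebsiella pneumoniae",
    "respiratory": "staphylococcus aureus",
    "viral_test": "rhinovirus",
}
_CONTAMINANTS = [
    ("blood", "coagulase-negative staphylococcus"),
    ("urine", "mixed flora"),
    ("respiratory", "candida albicans"),
]


@dataclass(frozen=True)
class AncestryStratum:
    label: str
    proportion: float
    reference_ancestry: str | None = None


@dataclass(frozen=True)
class SimVariant:
    """One pool variant: identity, annotation, and per-stratum frequencies.

    ``stratum_freqs`` are cohort allele frequencies per stratum label;
    ``ref_maf`` / ``ref_ancestry_mafs`` parameterize the reference table.
    ``in_databases`` False makes the variant novel (no population MAFs in
    the annotation table and no reference row).
    """

    gene: str
    chromosome: str
    position: int
    ref: str
    alt: str
    consequence: Consequence
    pathogenicity_class: PathogenicityClass
    stratum_freqs: tuple[tuple[str, float], ...]
    ref_maf: float = 0.0
    ref_ancestry_mafs: tuple[tuple[str, float], ...] = ()
    in_databases: bool = True

    @property
    def key(self) -> VariantKey:
        return VariantKey(self.chromosome, self.position, self.ref, self.alt)

    def freq(self, stratum: str) -> float:
        return dict(self.stratum_freqs).get(stratum, 0.0)


@dataclass(frozen=True)
class PlantedEffect:
    """A controlled exposure -> outcome link with a planted odds ratio."""

    exposure: str  # "any_iei" or a gene symbol
    outcome: str
    odds_ratio: float
    baseline: float  # outcome probability in the unexposed

    def __post_init__(self) -> None:
        if self.odds_ratio <= 0:
            raise ValueError("odds_ratio must be positive")
        if not (0.0 <= self.baseline <= 1.0):
            raise ValueError("baseline must lie in [0,1]")


@dataclass(frozen=True)
class PanelGene:
    gene: str
    chromosome: str
    category: IUISCategory
    modes: tuple[str, ...]
    disorder: str = ""


@dataclass(frozen=True)
class SimulationConfig:
    n_subjects: int = 330
    seed: int = 0
    sex_ratio_male: float = 0.542
    strata: tuple[AncestryStratum, ...] = ()
    panel_genes: tuple[PanelGene, ...] = ()
    variant_pool: tuple[SimVariant, ...] = ()
    planted_effects: tuple[PlantedEffect, ...] = ()
    lab_missingness: tuple[tuple[str, float], ...] = (
        ("lymphocytes", 0.05),
        ("ferritin", 0.25),
        ("platelets", 0.03),
        ("crp", 0.15),
    )
    contaminant_rate: float = 0.08
    out_of_window_rate: float = 0.05
    qc_fail_rate: float = 0.02
    reference_an: int = 282_912  # 2 x 141,456 reference individuals
    ancestry_an: tuple[tuple[str, int], ...] = (("afr", 24_000),)

    def __post_init__(self) -> None:
        if self.strata and not math.isclose(
            sum(s.proportion for s in self.strata), 1.0, abs_tol=1e-9
        ):
            raise ValueError("stratum proportions must sum to 1")
        for v in self.variant_pool:
            for _, f in v.stratum_freqs:
                if not (0.0 <= f <= 1.0):
                    raise ValueError(f"{v.gene}: frequency outside [0,1]")

    def config_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def _gene_pool() -> list[PanelGene]:
    C = IUISCategory
    return [
        PanelGene("CFH", "1", C.COMPLEMENT, ("AD", "AR"), "aHUS"),
        PanelGene("C3", "19", C.COMPLEMENT, ("AD", "AR"), "aHUS / C3 deficiency"),
        PanelGene("CFHR3", "1", C.COMPLEMENT, ("AD",), "aHUS"),
        PanelGene("CFI", "4", C.COMPLEMENT, ("AD",), "aHUS"),
        PanelGene("MEFV", "16", C.AUTOINFLAMMATORY, ("AR", "AD"), "familial Mediterranean fever"),
        PanelGene("NLRP3", "1", C.AUTOINFLAMMATORY, ("AD",), "CAPS"),
        PanelGene("TNFRSF1A", "12", C.AUTOINFLAMMATORY, ("AD",), "TRAPS"),
        PanelGene("KMT2D", "12", C.COMBINED_SYNDROMIC, ("AD",), "Kabuki syndrome"),
        PanelGene("SPINK5", "5", C.COMBINED_SYNDROMIC, ("AR",), "Netherton syndrome"),
        PanelGene("ELANE", "19", C.PHAGOCYTE, ("AD",), "severe congenital neutropenia"),
        PanelGene("ITGB2", "21", C.PHAGOCYTE, ("AR",), "leukocyte adhesion deficiency"),
        PanelGene("UNC13D", "17", C.IMMUNE_DYSREGULATION, ("AR",), "FHL3"),
        PanelGene("FAS", "10", C.IMMUNE_DYSREGULATION, ("AD",), "ALPS"),
        PanelGene("XIAP", "X", C.IMMUNE_DYSREGULATION, ("XLR",), "XLP2"),
        PanelGene("IRF3", "19", C.INNATE_INTRINSIC, ("AD",), "herpes simplex encephalitis"),
        PanelGene("STAT1", "2", C.INNATE_INTRINSIC, ("AD",), "CMC"),
        PanelGene("TERT", "5", C.MARROW_FAILURE, ("AD", "AR"), "dyskeratosis congenita"),
        PanelGene("RTEL1", "20", C.MARROW_FAILURE, ("AD", "AR"), "dyskeratosis congenita"),
        PanelGene("TNFRSF13B", "17", C.ANTIBODY, ("AD", "AR"), "CVID"),
        PanelGene("TCF3", "19", C.ANTIBODY, ("AD",), "agammaglobulinemia"),
        PanelGene("IL2RG", "X", C.CELLULAR_HUMORAL, ("XLR",), "X-SCID"),
        PanelGene("TAP1", "6", C.CELLULAR_HUMORAL, ("AR",), "MHC class I deficiency"),
    ]


def default_config(seed: int = 0, n_subjects: int = 330) -> SimulationConfig:
    """The study-structure default: strata, pool, and planted effects."""
    strata = (
        AncestryStratum("White", 0.68, None),
        AncestryStratum("Black", 0.21, "afr"),
        AncestryStratum("Other", 0.11, None),
    )
    DM, DMQ, NONE = (
        PathogenicityClass.DM,
        PathogenicityClass.DM_QUERY,
        PathogenicityClass.NONE,
    )
    MIS, NON, FS = Consequence.MISSENSE, Consequence.NONSENSE, Consequence.FRAMESHIFT

    def freqs(base: float, black: float | None = None):
        black = base if black is None else black
        return (("White", base), ("Black", black), ("Other", base))

    pool = [
        # complement variants, enriched in the Black stratum and vs reference
        SimVariant("CFH", "1", 196_700_000, "A", "T", MIS, DM, freqs(0.022, 0.066), 0.008, (("afr", 0.015),)),
        SimVariant("C3", "19", 6_710_000, "G", "C", MIS, DM, freqs(0.018, 0.120), 0.004, (("afr", 0.010),)),
        SimVariant("C3", "19", 6_714_000, "G", "A", MIS, DMQ, freqs(0.0, 0.012), 0.00002, (("afr", 0.0001),)),
        SimVariant("CFHR3", "1", 196_750_000, "C", "T", MIS, DM, freqs(0.018, 0.110), 0.007, (("afr", 0.012),)),
        SimVariant("CFI", "4", 110_660_000, "G", "A", MIS, DMQ, freqs(0.013), 0.011),
        # autoinflammatory
        SimVariant("MEFV", "16", 3_293_000, "T", "C", MIS, DM, freqs(0.044), 0.040),
        SimVariant("NLRP3", "1", 247_580_000, "C", "A", MIS, DM, freqs(0.066), 0.040),
        SimVariant("TNFRSF1A", "12", 6_440_000, "C", "T", MIS, DMQ, freqs(0.013, 0.065), 0.005, (("afr", 0.012),)),
        # combined / syndromic
        SimVariant("KMT2D", "12", 49_420_000, "C", "T", MIS, DMQ, freqs(0.033), 0.030),
        SimVariant("SPINK5", "5", 147_480_000, "G", "A", MIS, DM, freqs(0.025), 0.022),
        # phagocyte
        SimVariant("ELANE", "19", 853_000, "G", "A", MIS, DMQ, freqs(0.033), 0.030),
        SimVariant("ITGB2", "21", 46_320_000, "C", "T", MIS, DM, freqs(0.030), 0.029),
        # immune dysregulation
        SimVariant("UNC13D", "17", 73_830_000, "C", "T", MIS, DM, freqs(0.040), 0.039),
        SimVariant("FAS", "10", 90_760_000, "A", "G", MIS, DM, freqs(0.022), 0.020),
        SimVariant("XIAP", "X", 123_020_000, "G", "A", MIS, DMQ, freqs(0.006), 0.005),
        # innate / intrinsic
        SimVariant("IRF3", "19", 50_165_000, "G", "A", MIS, DM, freqs(0.031), 0.008, (("afr", 0.008),)),
        SimVariant("STAT1", "2", 191_850_000, "C", "T", MIS, DMQ, freqs(0.018), 0.016),
        # marrow failure
        SimVariant("TERT", "5", 1_280_000, "C", "T", MIS, DM, freqs(0.026), 0.024),
        SimVariant("RTEL1", "20", 62_320_000, "G", "A", MIS, DMQ, freqs(0.026), 0.024),
        # antibody
        SimVariant("TNFRSF13B", "17", 16_840_000, "C", "A", MIS, DM, freqs(0.040), 0.038),
        SimVariant("TCF3", "19", 1_615_000, "C", "T", MIS, DMQ, freqs(0.018), 0.016),
        # cellular & humoral
        SimVariant("IL2RG", "X", 70_330_000, "C", "T", MIS, DMQ, freqs(0.005), 0.004),
        SimVariant("TAP1", "6", 32_845_000, "G", "A", MIS, DM, freqs(0.025), 0.024),
        # novel null: rare, absent from every database
        SimVariant("ELANE", "19", 855_500, "C", "T", NON, NONE, freqs(0.004), in_databases=False),
        SimVariant("TAP1", "6", 32_846_500, "G", "GA", FS, NONE, freqs(0.006), in_databases=False),
        # controls the filter must reject:
        SimVariant("NLRP3", "1", 247_581_200, "G", "A", Consequence.SYNONYMOUS, NONE, freqs(0.050), 0.05),
        SimVariant("MEFV", "16", 3_294_100, "C", "G", MIS, DMQ, freqs(0.150), 0.200),
        SimVariant("CFH", "1", 196_701_800, "G", "T", NON, NONE, freqs(0.080), in_databases=False),
    ]
    effects = (
        PlantedEffect("any_iei", "hyperferritinemia", 2.16, 0.20),
        PlantedEffect("any_iei", "lymphopenia", 1.66, 0.30),
        PlantedEffect("any_iei", "thrombocytopenia", 1.76, 0.30),
        PlantedEffect("any_iei", "crp_high", 1.71, 0.30),
        PlantedEffect("any_iei", "blood_positive", 2.82, 0.06),
        PlantedEffect("any_iei", "urine_positive", 8.23, 0.01),
        PlantedEffect("any_iei", "respiratory_positive", 1.0, 0.25),
        PlantedEffect("any_iei", "viral_positive", 1.0, 0.20),
        PlantedEffect("any_iei", "ecmo", 4.19, 0.023),
        PlantedEffect("any_iei", "mortality", 1.0, 0.08),
    )
    return SimulationConfig(
        n_subjects=n_subjects,
        seed=seed,
        strata=strata,
        panel_genes=tuple(_gene_pool()),
        variant_pool=tuple(pool),
        planted_effects=effects,
    )


def substreams(seed: int, names: Sequence[str]) -> dict[str, np.random.Generator]:
    """Named independent RNG substreams derived from one master seed."""
    children = np.random.SeedSequence(seed).spawn(len(names))
    return {name: np.random.default_rng(seq) for name, seq in zip(names, children)}


_STREAMS = ("subjects", "genotypes", "qc", "outcomes", "labs", "cultures")


def simulate_subjects(config: SimulationConfig, rng: np.random.Generator) -> pd.DataFrame:
    n = config.n_subjects
    ids = [f"S{i:04d}" for i in range(1, n + 1)]
    sex = np.where(rng.random(n) < config.sex_ratio_male, "male", "female")
    if config.strata:
        labels = [s.label for s in config.strata]
        probs = [s.proportion for s in config.strata]
        race = rng.choice(labels, size=n, p=probs)
    else:
        race = np.repeat("unspecified", n)
    age = np.round(rng.gamma(shape=1.6, scale=4.5, size=n).clip(0.1, 17.9), 1)
    return pd.DataFrame(
        {"subject_id": ids, "sex": sex, "race": race, "age_years": age}
    )


def simulate_genotypes(
    config: SimulationConfig,
    subjects: pd.DataFrame,
    rng: np.random.Generator,
    qc_rng: np.random.Generator | None = None,
) -> list[GenotypeCall]:
    """Hardy-Weinberg genotype draws per stratum frequency.

    X variants are sampled per sex (males Bernoulli(f), hemizygous).
    A ``qc_fail_rate`` fraction of calls receives sub-threshold depth or
    quality to exercise the QC gate.
    """
    if qc_rng is None:
        qc_rng = rng
    calls: list[GenotypeCall] = []
    sexes = subjects["sex"].to_numpy()
    races = subjects["race"].to_numpy()
    ids = subjects["subject_id"].to_numpy()
    for variant in config.variant_pool:
        key = variant.key
        on_x = key.is_x
        f = np.array([variant.freq(r) for r in races])
        u = rng.random((len(ids), 2))
        for i, sid in enumerate(ids):
            fi = f[i]
            if fi <= 0.0:
                continue
            if on_x and sexes[i] == "male":
                if u[i, 0] < fi:
                    zyg = Zygosity.HEMI
                else:
                    continue
            else:
                n_alt = int(u[i, 0] < fi) + int(u[i, 1] < fi)
                if n_alt == 0:
                    continue
                zyg = Zygosity.HOM_ALT if n_alt == 2 else Zygosity.HET
            if qc_rng.random() < config.qc_fail_rate:
                depth, qual = int(qc_rng.integers(1, 10)), float(qc_rng.integers(5, 20))
            else:
                depth = int(qc_rng.poisson(80) + 11)
                qual = float(qc_rng.integers(30, 99))
            calls.append(
                GenotypeCall(
                    subject_id=str(sid), key=key, zygosity=zyg, read_depth=depth, quality=qual
                )
            )
    return calls


def build_panel(config: SimulationConfig) -> dict[str, GenePanelEntry]:
    return {
        g.gene: GenePanelEntry(
            gene_symbol=g.gene,
            iuis_category=g.category,
            disorder_name=g.disorder or g.gene,
            inheritance_modes=frozenset(InheritanceMode(m) for m in g.modes),
            chromosome=g.chromosome,
        )
        for g in config.panel_genes
    }


def build_annotations(config: SimulationConfig) -> dict[VariantKey, VariantAnnotation]:
    annotations = {}
    for v in config.variant_pool:
        mafs: dict[str, float] = {}
        if v.in_databases:
            # the four databases agree up to small deterministic offsets
            for i, db in enumerate(("ExAC", "1000G", "ESP6500", "gnomAD")):
                mafs[db] = min(1.0, v.ref_maf * (1.0 + 0.02 * i))
        annotations[v.key] = VariantAnnotation(
            key=v.key,
            gene_symbol=v.gene,
            consequence=v.consequence,
            pathogenicity_class=v.pathogenicity_class,
            population_mafs=mafs,
        )
    return annotations


def build_reference(config: SimulationConfig) -> dict[VariantKey, ReferenceFrequencyEntry]:
    an_by_label = dict(config.ancestry_an)
    table = {}
    for v in config.variant_pool:
        if not v.in_databases:
            continue
        ac = int(round(v.ref_maf * config.reference_an))
        per_anc = {}
        for label, maf in v.ref_ancestry_mafs:
            an = an_by_label.get(label, 20_000)
            per_anc[label] = (int(round(maf * an)), an)
        table[v.key] = ReferenceFrequencyEntry(
            key=v.key,
            allele_count=ac,
            allele_number=config.reference_an,
            per_ancestry=per_anc,
        )
    return table


def planted_exposures(
    config: SimulationConfig,
    subjects: pd.DataFrame,
    calls: Iterable[GenotypeCall],
) -> dict[str, set[str]]:
    """Exposure truth from planted carrier status and the design rules.

    A subject is exposed under ``any_iei`` when it carries a variant with a
    pathogenicity basis in a disease-consistent pattern: any carrier for a
    gene with a dominant mode, male X carriers, homozygotes (or >= 2
    distinct hets in one gene) for recessive-only genes. Computed directly
    from the drawn genotypes — independent of the filter pipeline.
    """
    calls = list(calls)
    panel = build_panel(config)
    by_variant = {v.key: v for v in config.variant_pool}
    sex_of = dict(zip(subjects["subject_id"].astype(str), subjects["sex"]))

    def has_basis(v: SimVariant) -> bool:
        if v.pathogenicity_class in (PathogenicityClass.DM, PathogenicityClass.DM_QUERY):
            return True
        null = v.consequence in (
            Consequence.NONSENSE,
            Consequence.FRAMESHIFT,
            Consequence.SPLICE_SITE,
            Consequence.START_LOST,
        )
        if not null:
            return False
        # recurrent novel nulls are design-excluded when the expected
        # carrier fraction exceeds the removal threshold
        max_freq = max(f for _, f in v.stratum_freqs)
        return 2 * max_freq <= 0.05

    def is_rare_by_design(v: SimVariant) -> bool:
        return (not v.in_databases) or v.ref_maf < 0.05

    hets_per_gene: dict[tuple[str, str], set[VariantKey]] = defaultdict(set)
    exposed: set[str] = set()
    deferred: list[tuple[str, str, VariantKey]] = []
    for call in calls:
        v = by_variant.get(call.key)
        if v is None or v.gene not in panel:
            continue
        if not (has_basis(v) and is_rare_by_design(v)):
            continue
        if v.consequence == Consequence.SYNONYMOUS or v.consequence == Consequence.OTHER:
            continue
        entry = panel[v.gene]
        sex = sex_of[call.subject_id]
        modes = entry.inheritance_modes
        dominant = InheritanceMode.AD in modes or InheritanceMode.XLD in modes
        if dominant:
            exposed.add(call.subject_id)
        elif InheritanceMode.XLR in modes:
            if sex == "male" or call.zygosity is Zygosity.HOM_ALT:
                exposed.add(call.subject_id)
        elif InheritanceMode.AR in modes:
            if call.zygosity is Zygosity.HOM_ALT:
                exposed.add(call.subject_id)
            else:
                hets_per_gene[(call.subject_id, v.gene)].add(call.key)
    for (sid, _), ks in hets_per_gene.items():
        if len(ks) >= 2:
            exposed.add(sid)

    out: dict[str, set[str]] = {"any_iei": exposed}
    for effect in config.planted_effects:
        if effect.exposure != "any_iei" and effect.exposure not in out:
            gene_carriers = {
                c.subject_id
                for c in calls
                if by_variant.get(c.key) is not None
                and by_variant[c.key].gene == effect.exposure
            }
            out[effect.exposure] = gene_carriers
    return out


def draw_outcome(
    exposed: np.ndarray, odds_ratio: float, baseline: float, rng: np.random.Generator
) -> np.ndarray:
    """Bernoulli outcomes under logit(p) = logit(baseline) + ln(OR) * exposed."""
    exposed = np.asarray(exposed, dtype=bool)
    if baseline == 0.0:
        return np.zeros(exposed.shape, dtype=bool)
    if baseline == 1.0:
        return np.ones(exposed.shape, dtype=bool)
    logit = math.log(baseline / (1 - baseline)) + math.log(odds_ratio) * exposed
    p = 1.0 / (1.0 + np.exp(-logit))
    return rng.random(exposed.shape) < p


def simulate_two_arm_table(
    n: int,
    exposure_prevalence: float,
    baseline: float,
    odds_ratio: float,
    rng: np.random.Generator,
) -> ContingencyTable:
    """One replicate of the exposure -> outcome kernel as a 2x2 table."""
    exposed = rng.random(n) < exposure_prevalence
    outcome = draw_outcome(exposed, odds_ratio, baseline, rng)
    return ContingencyTable.from_flags(exposed, outcome)


def simulate_phenotypes(
    config: SimulationConfig,
    subjects: pd.DataFrame,
    exposures: Mapping[str, set[str]],
    rng_outcomes: np.random.Generator,
    rng_labs: np.random.Generator,
    rng_cultures: np.random.Generator,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Draw outcomes and realize them as clinical records.

    Returns (records, subjects-with-outcome-columns). Culture outcomes
    become positive culture rows inside the enrollment window; lab
    outcomes become 2-4 point series whose extreme value crosses (or
    stays clear of) the phenotype threshold; any other outcome label
    becomes a boolean subject-table column.
    """
    subjects = subjects.copy()
    ids = subjects["subject_id"].astype(str).to_numpy()
    n = len(ids)
    records: list[dict] = []
    for sid in ids:
        records.append(
            {
                "subject_id": sid,
                "record_type": "enrollment",
                "site_or_analyte": "",
                "organism": "",
                "value": 0,
                "time_h": 0.0,
            }
        )

    truth: dict[str, np.ndarray] = {}
    for effect in config.planted_effects:
        exposed_ids = exposures.get(effect.exposure, set())
        exposed = np.array([sid in exposed_ids for sid in ids])
        truth[effect.outcome] = draw_outcome(
            exposed, effect.odds_ratio, effect.baseline, rng_outcomes
        )

    missingness = dict(config.lab_missingness)
    for outcome, analyte in LAB_OUTCOMES.items():
        flags = truth.get(outcome, np.zeros(n, dtype=bool))
        miss = rng_labs.random(n) < missingness.get(analyte, 0.0)
        for i, sid in enumerate(ids):
            if miss[i]:
                continue
            values = _lab_series(analyte, bool(flags[i]), rng_labs)
            for t, v in values:
                records.append(
                    {
                        "subject_id": sid,
                        "record_type": "lab",
                        "site_or_analyte": analyte,
                        "organism": "",
                        "value": v,
                        "time_h": t,
                    }
                )

    for outcome, site in CULTURE_OUTCOMES.items():
        flags = truth.get(outcome, np.zeros(n, dtype=bool))
        for i, sid in enumerate(ids):
            if flags[i]:
                records.append(
                    {
                        "subject_id": sid,
                        "record_type": "culture",
                        "site_or_analyte": site,
                        "organism": _PATHOGENS[site],
                        "value": 1,
                        "time_h": float(rng_cultures.uniform(-44, 44)),
                    }
                )
            elif rng_cultures.random() < config.out_of_window_rate:
                # positive outside the window: must not flip the flag
                records.append(
                    {
                        "subject_id": sid,
                        "record_type": "culture",
                        "site_or_analyte": site,
                        "organism": _PATHOGENS[site],
                        "value": 1,
                        "time_h": float(rng_cultures.uniform(55, 120)),
                    }
                )
    for i, sid in enumerate(ids):
        if rng_cultures.random() < config.contaminant_rate:
            site, organism = _CONTAMINANTS[int(rng_cultures.integers(len(_CONTAMINANTS)))]
            records.append(
                {
                    "subject_id": sid,
                    "record_type": "culture",
                    "site_or_analyte": site,
                    "organism": organism,
                    "value": 1,
                    "time_h": float(rng_cultures.uniform(-44, 44)),
                }
            )

    for outcome, flags in truth.items():
        if outcome not in LAB_OUTCOMES and outcome not in CULTURE_OUTCOMES:
            subjects[outcome] = flags
    records_df = pd.DataFrame(
        records,
        columns=["subject_id", "record_type", "site_or_analyte", "organism", "value", "time_h"],
    )
    return records_df, subjects


def _lab_series(
    analyte: str, flag: bool, rng: np.random.Generator
) -> list[tuple[float, float]]:
    n_points = int(rng.integers(2, 5))
    times = np.sort(rng.uniform(-40, 40, size=n_points))
    if analyte == "lymphocytes":
        base = rng.normal(2500, 600, size=n_points).clip(1100, 8000)
        if flag:
            base[int(rng.integers(n_points))] = rng.uniform(100, 950)
    elif analyte == "ferritin":
        base = np.exp(rng.normal(5.0, 0.5, size=n_points)).clip(20, 480)
        if flag:
            base[int(rng.integers(n_points))] = rng.uniform(600, 8000)
    elif analyte == "platelets":
        base = rng.normal(260_000, 50_000, size=n_points).clip(160_000, 600_000)
        if flag:
            base[int(rng.integers(n_points))] = rng.uniform(20_000, 140_000)
    elif analyte == "crp":
        base = rng.uniform(0.2, 9.0, size=n_points)
        if flag:
            base[int(rng.integers(n_points))] = rng.uniform(11, 40)
    else:  # pragma: no cover - unused analytes
        base = rng.normal(0, 1, size=n_points)
    return [(float(t), float(round(v, 2))) for t, v in zip(times, base)]


def write_cohort_bundle(config: SimulationConfig, out_dir: str | Path) -> dict[str, Path]:
    """Generate a full cohort and write the five pipeline inputs + manifest.

    Files: ``genotypes.vcf``, ``annotations.tsv``, ``panel.tsv``,
    ``reference_freqs.tsv``, ``subjects.tsv``, ``clinical_records.tsv``
    and ``manifest.json`` (seed and configuration hash). Deterministic:
    the same config yields byte-identical files.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rngs = substreams(config.seed, _STREAMS)

    subjects = simulate_subjects(config, rngs["subjects"])
    calls = simulate_genotypes(config, subjects, rngs["genotypes"], rngs["qc"])
    exposures = planted_exposures(config, subjects, calls)
    records, subjects = simulate_phenotypes(
        config, subjects, exposures, rngs["outcomes"], rngs["labs"], rngs["cultures"]
    )

    paths = {name: out_dir / fname for name, fname in [
        ("genotypes", "genotypes.vcf"),
        ("annotations", "annotations.tsv"),
        ("panel", "panel.tsv"),
        ("reference", "reference_freqs.tsv"),
        ("subjects", "subjects.tsv"),
        ("records", "clinical_records.tsv"),
        ("manifest", "manifest.json"),
    ]}

    by_key: dict[VariantKey, dict[str, tuple[Zygosity, int, float]]] = defaultdict(dict)
    for call in calls:
        by_key[call.key][call.subject_id] = (call.zygosity, call.read_depth, call.quality)
    all_keys = [v.key for v in config.variant_pool]
    write_vcf(
        paths["genotypes"],
        list(subjects["subject_id"]),
        [(key, by_key.get(key, {})) for key in all_keys],
    )
    write_annotation_table(build_annotations(config), paths["annotations"])
    write_gene_panel(build_panel(config), paths["panel"])
    write_reference_frequencies(build_reference(config), paths["reference"])
    subjects.to_csv(paths["subjects"], sep="\t", index=False)
    records.to_csv(paths["records"], sep="\t", index=False)
    manifest = {
        "seed": config.seed,
        "config_hash": config.config_hash(),
        "n_subjects": config.n_subjects,
        "n_variants": len(config.variant_pool),
        "files": {k: p.name for k, p in paths.items() if k != "manifest"},
    }
    paths["manifest"].write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return paths
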