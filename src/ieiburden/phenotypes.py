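"""Clinical phenotype derivation for a severe-sepsis cohort.

Turns raw clinical records — microbiology cultures with site/organism/time,
and laboratory time series — into the binary phenotypes used downstream:

* infection-site positivity (blood / urine / respiratory / viral testing)
  restricted to a +/-48 h window around enrollment, after excluding likely
  contaminants by site (e.g. coagulase-negative staphylococci in blood,
  mixed flora in urine);
* culture-negative sepsis: no positive bacterial or viral testing from any
  site in the window after contaminant exclusion;
* extreme-value inflammatory flags, using the most abnormal value per
  subject: lymphopenia (minimum lymphocyte count < 1000/uL),
  hyperferritinemia (maximum ferritin > 500 ng/mL), thrombocytopenia
  (minimum platelets < 150,000/uL), and CRP > 10 mg/dL;
* pediatric SIRS criteria (0-4) and sepsis / severe-sepsis classification
  with the six organ-failure definitions.

Analytes with no data yield a *missing* flag (``None``), never ``False``;
subjects with a missing flag are dropped from that phenotype's 2x2 table.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

__all__ = [
    "CultureSite",
    "CultureResult",
    "SubjectPhenotype",
    "SepsisAssessment",
    "SirsInputs",
    "OrganFailureInputs",
    "LabThresholds",
    "default_contaminants",
    "load_contaminants",
    "default_age_norms",
    "select_in_window",
    "apply_contaminant_exclusions",
    "derive_infection_flags",
    "derive_inflammatory_flags",
    "assess_sirs",
    "classify_severe_sepsis",
    "derive_cohort_phenotypes",
    "INFLAMMATORY_FLAGS",
    "INFECTION_FLAGS",
]

WINDOW_HOURS = 48.0


class CultureSite(str, Enum):
    BLOOD = "blood"
    URINE = "urine"
    RESPIRATORY = "respiratory"
    VIRAL_TEST = "viral_test"
    OTHER = "other"


@dataclass(frozen=True)
class CultureResult:
    subject_id: str
    site: CultureSite
    organism: str
    collected_at: float  # hours relative to the cohort clock
    positive: bool

    def __post_init__(self) -> None:
        if self.positive and not self.organism.strip():
            raise ValueError(
                f"{self.subject_id}: positive culture requires a non-empty organism"
            )


INFECTION_FLAGS = (
    "blood_positive",
    "urine_positive",
    "respiratory_positive",
    "viral_positive",
)
INFLAMMATORY_FLAGS = ("lymphopenia", "hyperferritinemia", "thrombocytopenia", "crp_high")


@dataclass
class SubjectPhenotype:
    """Derived binary phenotypes; inflammatory flags are ``None`` when the
    analyte was never measured for the subject."""

    subject_id: str
    blood_positive: bool = False
    urine_positive: bool = False
    respiratory_positive: bool = False
    viral_positive: bool = False
    culture_negative: bool = True
    lymphopenia: bool | None = None
    hyperferritinemia: bool | None = None
    thrombocytopenia: bool | None = None
    crp_high: bool | None = None
    demographics: dict = field(default_factory=dict)


@dataclass(frozen=True)
class LabThresholds:
    """Extreme-value definitions; comparators are strict as defined.

    ``ferritin_strict`` toggles > (default) versus >= for the
    hyperferritinemia bound.
    """

    lymphocyte_below: float = 1000.0  # /uL, min value strictly below
    ferritin_above: float = 500.0  # ng/mL, max value strictly above
    platelet_below: float = 150_000.0  # /uL
    crp_above: float = 10.0  # mg/dL
    ferritin_strict: bool = True


def default_contaminants() -> dict[CultureSite, frozenset[str]]:
    """Likely-contaminant organisms by culture site (lowercase)."""
    return {
        CultureSite.BLOOD: frozenset(
            {"coagulase-negative staphylococcus", "viridans group streptococcus"}
        ),
        CultureSite.RESPIRATORY: frozenset(
            {"candida albicans", "viridans group streptococcus"}
        ),
        CultureSite.URINE: frozenset({"mixed flora"}),
    }


def load_contaminants(path: str | Path | None = None) -> dict[CultureSite, frozenset[str]]:
    """Load a site -> organism contaminant map from TSV (columns site, organism).

    Without a path, the packaged default list is used.
    """
    if path is None:
        source = resources.files("ieiburden.data") / "contaminants.tsv"
        with resources.as_file(source) as p:
            df = pd.read_csv(p, sep="\t")
    else:
        df = pd.read_csv(path, sep="\t")
    out: dict[CultureSite, set[str]] = {}
    for _, row in df.iterrows():
        out.setdefault(CultureSite(row["site"]), set()).add(
            str(row["organism"]).strip().lower()
        )
    return {site: frozenset(orgs) for site, orgs in out.items()}


def select_in_window(
    cultures: Iterable[CultureResult],
    enrollment: float,
    window_hours: float = WINDOW_HOURS,
) -> list[CultureResult]:
    """Keep results collected within +/-``window_hours`` of enrollment, inclusive."""
    return [c for c in cultures if abs(c.collected_at - enrollment) <= window_hours]


def apply_contaminant_exclusions(
    cultures: Iterable[CultureResult],
    contaminants: Mapping[CultureSite, frozenset[str]] | None = None,
) -> list[CultureResult]:
    """Demote positives whose (site, organism) is on the contaminant list.

    Organisms match case-insensitively. Excluded results are returned as
    non-positive so downstream counting still sees the specimen.
    """
    if contaminants is None:
        contaminants = default_contaminants()
    out = []
    for c in cultures:
        if c.positive and c.organism.strip().lower() in contaminants.get(c.site, frozenset()):
            out.append(
                CultureResult(
                    subject_id=c.subject_id,
                    site=c.site,
                    organism=c.organism,
                    collected_at=c.collected_at,
                    positive=False,
                )
            )
        else:
            out.append(c)
    return out


_SITE_FLAG = {
    CultureSite.BLOOD: "blood_positive",
    CultureSite.URINE: "urine_positive",
    CultureSite.RESPIRATORY: "respiratory_positive",
    CultureSite.VIRAL_TEST: "viral_positive",
}


def derive_infection_flags(cultures: Iterable[CultureResult]) -> dict[str, bool]:
    """Site positivity flags and culture-negative status.

    Expects cultures already windowed and decontaminated. A site flag is
    true iff at least one remaining positive result at that site;
    culture-negative iff all four site flags are false.
    """
    flags = {name: False for name in INFECTION_FLAGS}
    for c in cultures:
        if c.positive and c.site in _SITE_FLAG:
            flags[_SITE_FLAG[c.site]] = True
    flags["culture_negative"] = not any(flags[name] for name in INFECTION_FLAGS)
    return flags


def derive_inflammatory_flags(
    labs: Mapping[str, Sequence[float]],
    thresholds: LabThresholds = LabThresholds(),
) -> dict[str, bool | None]:
    """Extreme-value inflammatory flags from per-analyte value lists.

    Uses the per-subject minimum for lymphocytes/platelets and maximum for
    ferritin/CRP. Analytes with no values give ``None`` (missing), not
    ``False``.
    """

    def flag(analyte: str, extreme, bound: float, below: bool, strict: bool = True):
        values = labs.get(analyte)
        if not values:
            return None
        v = extreme(values)
        if below:
            return v < bound
        return v > bound if strict else v >= bound

    return {
        "lymphopenia": flag("lymphocytes", min, thresholds.lymphocyte_below, True),
        "hyperferritinemia": flag(
            "ferritin", max, thresholds.ferritin_above, False, thresholds.ferritin_strict
        ),
        "thrombocytopenia": flag("platelets", min, thresholds.platelet_below, True),
        "crp_high": flag("crp", max, thresholds.crp_above, False),
    }


# ---------------------------------------------------------------------------
# SIRS / severe sepsis


def default_age_norms() -> pd.DataFrame:
    """Default 90th-percentile heart-rate / respiratory-rate table by age.

    Columns ``age_low`` (inclusive, years), ``age_high`` (exclusive),
    ``hr_p90`` (/min), ``rr_p90`` (/min). Modeled on the pediatric sepsis
    consensus age brackets; replace with an institution-specific table via
    the same columns when available.
    """
    source = resources.files("ieiburden.data") / "sirs_age_norms.tsv"
    with resources.as_file(source) as p:
        return pd.read_csv(p, sep="\t")


@dataclass(frozen=True)
class SirsInputs:
    """Per-subject extremes feeding the four pediatric SIRS criteria."""

    age_years: float
    heart_rate_max: float | None = None
    respiratory_rate_max: float | None = None
    temperature_min: float | None = None  # Celsius
    temperature_max: float | None = None
    wbc_min: float | None = None  # /uL
    wbc_max: float | None = None
    immature_neutrophil_fraction: float | None = None  # 0..1


def assess_sirs(inputs: SirsInputs, age_norms: pd.DataFrame | None = None) -> int:
    """Count of pediatric SIRS criteria met (0-4).

    Criteria: tachycardia (HR > 90th percentile for age), tachypnea
    (RR > 90th percentile for age), temperature < 36 or > 38.5 C, and
    abnormal WBC (> 12,000/uL, < 4000/uL, or > 10% immature neutrophils).
    Missing measurements do not satisfy a criterion.
    """
    if age_norms is None:
        age_norms = default_age_norms()
    bracket = age_norms[
        (age_norms["age_low"] <= inputs.age_years) & (inputs.age_years < age_norms["age_high"])
    ]
    if bracket.empty:
        raise ValueError(f"age {inputs.age_years} y outside norm-table coverage")
    hr_p90 = float(bracket.iloc[0]["hr_p90"])
    rr_p90 = float(bracket.iloc[0]["rr_p90"])

    count = 0
    if inputs.heart_rate_max is not None and inputs.heart_rate_max > hr_p90:
        count += 1
    if inputs.respiratory_rate_max is not None and inputs.respiratory_rate_max > rr_p90:
        count += 1
    if (inputs.temperature_min is not None and inputs.temperature_min < 36.0) or (
        inputs.temperature_max is not None and inputs.temperature_max > 38.5
    ):
        count += 1
    if (
        (inputs.wbc_max is not None and inputs.wbc_max > 12_000)
        or (inputs.wbc_min is not None and inputs.wbc_min < 4000)
        or (
            inputs.immature_neutrophil_fraction is not None
            and inputs.immature_neutrophil_fraction > 0.10
        )
    ):
        count += 1
    return count


@dataclass(frozen=True)
class OrganFailureInputs:
    """Flags and lab extremes feeding the six organ-failure definitions."""

    on_vasoactive_infusion: bool = False
    mechanical_ventilation: bool = False
    pf_ratio: float | None = None  # PaO2/FiO2
    bilirubin_max: float | None = None  # mg/dL
    alt_max: float | None = None  # IU/L
    creatinine_max: float | None = None  # mg/dL
    urine_output_min: float | None = None  # mL/kg/h
    platelet_min: float | None = None  # /uL
    inr_max: float | None = None  # ratio to normal
    gcs_min: float | None = None
    on_sedatives: bool = False


@dataclass
class SepsisAssessment:
    subject_id: str
    sirs_criteria_met: int
    organ_failures: frozenset[str]
    sepsis: bool
    severe_sepsis: bool


def classify_severe_sepsis(
    subject_id: str,
    sirs_criteria_met: int,
    organs: OrganFailureInputs,
    suspected_infection: bool = True,
) -> SepsisAssessment:
    """Sepsis (infection + >=2 SIRS criteria) and severe sepsis (+ >=1 organ failure).

    Organ failures: cardiovascular — vasoactive infusion support;
    pulmonary — mechanical ventilation with PaO2/FiO2 < 300; hepatic —
    bilirubin > 1.0 mg/dL and ALT > 100 IU/L; renal — creatinine > 1.0
    mg/dL and urine output < 0.5 mL/kg/h; hematologic — platelets
    < 100,000/uL and INR > 1.5x normal; CNS — GCS < 12 without sedatives.
    """
    failures = set()
    if organs.on_vasoactive_infusion:
        failures.add("cardiovascular")
    if organs.mechanical_ventilation and organs.pf_ratio is not None and organs.pf_ratio < 300:
        failures.add("pulmonary")
    if (
        organs.bilirubin_max is not None
        and organs.bilirubin_max > 1.0
        and organs.alt_max is not None
        and organs.alt_max > 100
    ):
        failures.add("hepatic")
    if (
        organs.creatinine_max is not None
        and organs.creatinine_max > 1.0
        and organs.urine_output_min is not None
        and organs.urine_output_min < 0.5
    ):
        failures.add("renal")
    if (
        organs.platelet_min is not None
        and organs.platelet_min < 100_000
        and organs.inr_max is not None
        and organs.inr_max > 1.5
    ):
        failures.add("hematologic")
    if organs.gcs_min is not None and organs.gcs_min < 12 and not organs.on_sedatives:
        failures.add("cns")

    sepsis = suspected_infection and sirs_criteria_met >= 2
    return SepsisAssessment(
        subject_id=subject_id,
        sirs_criteria_met=sirs_criteria_met,
        organ_failures=frozenset(failures),
        sepsis=sepsis,
        severe_sepsis=sepsis and len(failures) >= 1,
    )


# ---------------------------------------------------------------------------
# cohort-level wrapper over the long-format clinical records table


def derive_cohort_phenotypes(
    records: pd.DataFrame,
    subjects: pd.DataFrame,
    contaminants: Mapping[CultureSite, frozenset[str]] | None = None,
    window_hours: float = WINDOW_HOURS,
    thresholds: LabThresholds = LabThresholds(),
) -> pd.DataFrame:
    """Derive all binary phenotypes for every subject in the cohort.

    ``records`` is the long-format clinical TSV with columns subject_id,
    record_type (culture | lab | enrollment), site_or_analyte, organism,
    value, time_h. ``subjects`` must carry subject_id; its demographic and
    outcome columns are copied through to the result. Returns a DataFrame
    indexed by subject_id with the infection and inflammatory flags
    (inflammatory flags as nullable booleans).
    """
    if contaminants is None:
        contaminants = default_contaminants()
    records = records.copy()
    records["subject_id"] = records["subject_id"].astype(str)

    enroll = {
        str(r.subject_id): float(r.time_h)
        for r in records[records["record_type"] == "enrollment"].itertuples()
    }

    rows = []
    for sid in subjects["subject_id"].astype(str):
        sub = records[records["subject_id"] == sid]
        cultures = [
            CultureResult(
                subject_id=sid,
                site=CultureSite(r.site_or_analyte),
                organism=str(r.organism),
                collected_at=float(r.time_h),
                positive=bool(int(float(r.value))),
            )
            for r in sub[sub["record_type"] == "culture"].itertuples()
        ]
        windowed = select_in_window(cultures, enroll.get(sid, 0.0), window_hours)
        cleaned = apply_contaminant_exclusions(windowed, contaminants)
        flags = derive_infection_flags(cleaned)

        labs: dict[str, list[float]] = {}
        for r in sub[sub["record_type"] == "lab"].itertuples():
            labs.setdefault(str(r.site_or_analyte), []).append(float(r.value))
        flags.update(derive_inflammatory_flags(labs, thresholds))
        flags["subject_id"] = sid
        rows.append(flags)

    pheno = pd.DataFrame(rows).set_index("subject_id")
    for col in INFLAMMATORY_FLAGS:
        pheno[col] = pheno[col].astype(object)
    out = subjects.copy()
    out["subject_id"] = out["subject_id"].astype(str)
    out = out.set_index("subject_id").join(pheno)
    return out
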