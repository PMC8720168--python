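"""Reference tables consumed by the pipeline.

Three user-supplied TSVs drive every downstream stage:

* the **gene panel** — one row per gene of the IUIS (International Union of
  Immunological Societies) primary-immunodeficiency catalog, carrying the
  functional category, the associated disorder, and the disorder's reported
  inheritance modes;
* the **variant annotation table** — one row per variant, with the gene
  symbol, the molecular consequence, the curated pathogenicity class
  (``DM`` = reported disease mutation, ``DM?`` = questionable association),
  and the population minor-allele frequencies in up to four databases;
* the **reference allele-frequency table** — gnomAD-style allele counts
  (AC) and allele numbers (AN), overall and optionally per ancestry.

Loaders validate invariants eagerly and raise :class:`FormatError` /
:class:`ValidationError` with row context; absent MAF cells are preserved
as missing, never coerced to zero.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Mapping

import pandas as pd

__all__ = [
    "IUISCategory",
    "InheritanceMode",
    "Consequence",
    "PathogenicityClass",
    "VariantKey",
    "GenePanelEntry",
    "VariantAnnotation",
    "ReferenceFrequencyEntry",
    "FormatError",
    "ValidationError",
    "MAF_DATABASES",
    "load_gene_panel",
    "load_annotation_table",
    "load_reference_frequencies",
    "write_gene_panel",
    "write_annotation_table",
    "write_reference_frequencies",
]


class FormatError(ValueError):
    """A required column or structural element of an input table is missing."""


class ValidationError(ValueError):
    """A cell value violates a domain invariant (range, vocabulary, uniqueness)."""


class IUISCategory(str, Enum):
    """The nine functional classes of primary immunodeficiency."""

    COMPLEMENT = "complement"
    AUTOINFLAMMATORY = "autoinflammatory"
    COMBINED_SYNDROMIC = "combined_syndromic"
    PHAGOCYTE = "phagocyte"
    IMMUNE_DYSREGULATION = "immune_dysregulation"
    INNATE_INTRINSIC = "innate_intrinsic"
    MARROW_FAILURE = "marrow_failure"
    ANTIBODY = "antibody"
    CELLULAR_HUMORAL = "cellular_humoral"


class InheritanceMode(str, Enum):
    AD = "AD"
    AR = "AR"
    XLR = "XLR"
    XLD = "XLD"


class Consequence(str, Enum):
    """Molecular consequence vocabulary.

    ``splice_site`` means a variant at the +/-1 or +/-2 intronic positions;
    anything intronic beyond that, UTR, or intergenic is ``other``.
    """

    MISSENSE = "missense"
    NONSENSE = "nonsense"
    FRAMESHIFT = "frameshift"
    SPLICE_SITE = "splice_site"
    START_LOST = "start_lost"
    SYNONYMOUS = "synonymous"
    OTHER = "other"


class PathogenicityClass(str, Enum):
    """Curated mutation-database class: DM (disease mutation), DM? or none."""

    DM = "DM"
    DM_QUERY = "DM?"
    NONE = "none"


#: population databases whose MAF columns the annotation table may carry
MAF_DATABASES = ("ExAC", "1000G", "ESP6500", "gnomAD")

_MAF_COLUMNS = {
    "maf_exac": "ExAC",
    "maf_1000g": "1000G",
    "maf_esp": "ESP6500",
    "maf_gnomad": "gnomAD",
}

_X_NAMES = {"X", "CHRX"}


def _is_x(chromosome: str) -> bool:
    return chromosome.upper() in _X_NAMES


@dataclass(frozen=True, order=True)
class VariantKey:
    """Join identity of a variant across VCF, annotation and reference tables.

    Coordinates are 1-based as in VCF; alleles are stored uppercase. No
    left-alignment is performed — inputs are expected pre-normalized and
    biallelic.
    """

    chromosome: str
    position: int
    ref_allele: str
    alt_allele: str

    def __post_init__(self) -> None:
        if self.position < 1:
            raise ValidationError(f"position must be >= 1, got {self.position}")
        object.__setattr__(self, "ref_allele", self.ref_allele.upper())
        object.__setattr__(self, "alt_allele", self.alt_allele.upper())
        if self.ref_allele == self.alt_allele:
            raise ValidationError(
                f"ref and alt alleles identical ({self.ref_allele}) at "
                f"{self.chromosome}:{self.position}"
            )

    @property
    def is_x(self) -> bool:
        return _is_x(self.chromosome)

    def __str__(self) -> str:  # pragma: no cover - repr sugar
        return f"{self.chromosome}:{self.position}:{self.ref_allele}>{self.alt_allele}"


@dataclass(frozen=True)
class GenePanelEntry:
    """One panel gene: IUIS category, disorder, and inheritance modes."""

    gene_symbol: str
    iuis_category: IUISCategory
    disorder_name: str
    inheritance_modes: frozenset[InheritanceMode]
    chromosome: str

    def __post_init__(self) -> None:
        if not self.inheritance_modes:
            raise ValidationError(f"{self.gene_symbol}: inheritance_modes empty")
        x_modes = {InheritanceMode.XLR, InheritanceMode.XLD}
        if (self.inheritance_modes & x_modes) and not _is_x(self.chromosome):
            raise ValidationError(
                f"{self.gene_symbol}: X-linked mode on chromosome {self.chromosome}"
            )

    @property
    def is_x_linked(self) -> bool:
        return _is_x(self.chromosome)


@dataclass(frozen=True)
class VariantAnnotation:
    """Per-variant annotation: gene, consequence, class, and population MAFs.

    ``population_mafs`` only contains entries for databases where the
    variant was observed; a variant absent everywhere has an empty mapping.
    """

    key: VariantKey
    gene_symbol: str
    consequence: Consequence
    pathogenicity_class: PathogenicityClass
    population_mafs: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for db, maf in self.population_mafs.items():
            if not (0.0 <= maf <= 1.0):
                raise ValidationError(
                    f"{self.key}: MAF for {db} outside [0,1]: {maf}"
                )


@dataclass(frozen=True)
class ReferenceFrequencyEntry:
    """Reference AC/AN for one variant, overall and optionally per ancestry."""

    key: VariantKey
    allele_count: int
    allele_number: int
    per_ancestry: Mapping[str, tuple[int, int]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.allele_number <= 0:
            raise ValidationError(f"{self.key}: overall AN must be > 0")
        _check_ac_an(self.key, self.allele_count, self.allele_number)
        for label, (ac, an) in self.per_ancestry.items():
            _check_ac_an(self.key, ac, an, label)

    @property
    def maf(self) -> float:
        return self.allele_count / self.allele_number


def _check_ac_an(key: VariantKey, ac: int, an: int, label: str = "overall") -> None:
    if ac < 0 or an < 0 or ac > an:
        raise ValidationError(f"{key}: invalid AC/AN ({ac}/{an}) for {label}")


def _read_tsv(path: str | Path, required: list[str]) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FormatError(f"input file not found: {path}")
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    for col in required:
        if col not in df.columns:
            raise FormatError(f"{path}: missing required column '{col}'")
    return df


def _row_key(row: pd.Series, rownum: int) -> VariantKey:
    try:
        return VariantKey(
            chromosome=str(row["chrom"]).strip(),
            position=int(row["pos"]),
            ref_allele=str(row["ref"]).strip(),
            alt_allele=str(row["alt"]).strip(),
        )
    except (ValueError, ValidationError) as exc:
        raise ValidationError(f"row {rownum}: bad variant key: {exc}") from exc


def load_gene_panel(path: str | Path) -> dict[str, GenePanelEntry]:
    """Load the gene panel TSV into a mapping gene symbol -> entry.

    Columns: ``gene``, ``iuis_category``, ``disorder``, ``inheritance_modes``
    (pipe-separated codes among AD/AR/XLR/XLD) and ``chromosome``. Duplicate
    gene symbols are rejected.
    """
    df = _read_tsv(path, ["gene", "iuis_category", "disorder", "inheritance_modes", "chromosome"])
    panel: dict[str, GenePanelEntry] = {}
    for i, row in enumerate(df.itertuples(index=False), start=2):
        gene = row.gene.strip()
        if gene in panel:
            raise ValidationError(f"row {i}: duplicate gene symbol '{gene}'")
        try:
            category = IUISCategory(row.iuis_category.strip())
        except ValueError:
            raise ValidationError(
                f"row {i}: unknown IUIS category '{row.iuis_category}'"
            ) from None
        modes = set()
        for tok in row.inheritance_modes.split("|"):
            tok = tok.strip()
            if not tok:
                continue
            try:
                modes.add(InheritanceMode(tok))
            except ValueError:
                raise ValidationError(
                    f"row {i}: unknown inheritance code '{tok}'"
                ) from None
        try:
            panel[gene] = GenePanelEntry(
                gene_symbol=gene,
                iuis_category=category,
                disorder_name=row.disorder.strip(),
                inheritance_modes=frozenset(modes),
                chromosome=row.chromosome.strip(),
            )
        except ValidationError as exc:
            raise ValidationError(f"row {i}: {exc}") from None
    return panel


def load_annotation_table(path: str | Path) -> dict[VariantKey, VariantAnnotation]:
    """Load the variant annotation TSV keyed by :class:`VariantKey`.

    Empty MAF cells are stored as *missing* (no entry for that database),
    never as zero.
    """
    df = _read_tsv(
        path,
        ["chrom", "pos", "ref", "alt", "gene", "consequence", "pathogenicity_class"]
        + list(_MAF_COLUMNS),
    )
    table: dict[VariantKey, VariantAnnotation] = {}
    for i, (_, row) in enumerate(df.iterrows(), start=2):
        key = _row_key(row, i)
        try:
            consequence = Consequence(row["consequence"].strip())
        except ValueError:
            raise ValidationError(
                f"row {i}: unparseable consequence '{row['consequence']}'"
            ) from None
        cls_raw = row["pathogenicity_class"].strip()
        try:
            cls = PathogenicityClass(cls_raw if cls_raw else "none")
        except ValueError:
            raise ValidationError(
                f"row {i}: unknown pathogenicity class '{cls_raw}'"
            ) from None
        mafs: dict[str, float] = {}
        for col, db in _MAF_COLUMNS.items():
            cell = str(row[col]).strip()
            if cell == "":
                continue
            try:
                value = float(cell)
            except ValueError:
                raise ValidationError(f"row {i}: non-numeric MAF '{cell}' in {col}") from None
            if not (0.0 <= value <= 1.0):
                raise ValidationError(f"row {i}: MAF {value} outside [0,1] in {col}")
            mafs[db] = value
        table[key] = VariantAnnotation(
            key=key,
            gene_symbol=row["gene"].strip(),
            consequence=consequence,
            pathogenicity_class=cls,
            population_mafs=mafs,
        )
    return table


def load_reference_frequencies(path: str | Path) -> dict[VariantKey, ReferenceFrequencyEntry]:
    """Load the gnomAD-style reference AC/AN table.

    Optional ancestry strata come as paired ``ac_<label>`` / ``an_<label>``
    columns; a stratum cell pair left empty for a row is treated as absent.
    """
    df = _read_tsv(path, ["chrom", "pos", "ref", "alt", "ac", "an"])
    ancestry_labels = [
        col[3:]
        for col in df.columns
        if col.startswith("ac_") and f"an_{col[3:]}" in df.columns
    ]
    table: dict[VariantKey, ReferenceFrequencyEntry] = {}
    for i, (_, row) in enumerate(df.iterrows(), start=2):
        key = _row_key(row, i)
        try:
            ac, an = int(row["ac"]), int(row["an"])
        except ValueError:
            raise ValidationError(f"row {i}: non-integer AC/AN") from None
        per_ancestry: dict[str, tuple[int, int]] = {}
        for label in ancestry_labels:
            ac_cell = str(row[f"ac_{label}"]).strip()
            an_cell = str(row[f"an_{label}"]).strip()
            if ac_cell == "" and an_cell == "":
                continue
            try:
                per_ancestry[label] = (int(ac_cell), int(an_cell))
            except ValueError:
                raise ValidationError(
                    f"row {i}: non-integer AC/AN for ancestry '{label}'"
                ) from None
        try:
            table[key] = ReferenceFrequencyEntry(
                key=key, allele_count=ac, allele_number=an, per_ancestry=per_ancestry
            )
        except ValidationError as exc:
            raise ValidationError(f"row {i}: {exc}") from None
    return table


# ---------------------------------------------------------------------------
# writers (round-trip counterparts, used by the simulator's bundle writer)


def write_gene_panel(panel: Mapping[str, GenePanelEntry], path: str | Path) -> None:
    rows = [
        {
            "gene": e.gene_symbol,
            "iuis_category": e.iuis_category.value,
            "disorder": e.disorder_name,
            "inheritance_modes": "|".join(
                sorted(m.value for m in e.inheritance_modes)
            ),
            "chromosome": e.chromosome,
        }
        for e in sorted(panel.values(), key=lambda e: e.gene_symbol)
    ]
    pd.DataFrame(rows, columns=["gene", "iuis_category", "disorder", "inheritance_modes", "chromosome"]).to_csv(
        path, sep="\t", index=False
    )


def write_annotation_table(
    annotations: Mapping[VariantKey, VariantAnnotation], path: str | Path
) -> None:
    rows = []
    for ann in sorted(annotations.values(), key=lambda a: a.key):
        row = {
            "chrom": ann.key.chromosome,
            "pos": ann.key.position,
            "ref": ann.key.ref_allele,
            "alt": ann.key.alt_allele,
            "gene": ann.gene_symbol,
            "consequence": ann.consequence.value,
            "pathogenicity_class": ann.pathogenicity_class.value,
        }
        for col, db in _MAF_COLUMNS.items():
            maf = ann.population_mafs.get(db)
            row[col] = "" if maf is None else repr(float(maf))
        rows.append(row)
    cols = ["chrom", "pos", "ref", "alt", "gene", "consequence", "pathogenicity_class"] + list(_MAF_COLUMNS)
    pd.DataFrame(rows, columns=cols).to_csv(path, sep="\t", index=False)


def write_reference_frequencies(
    table: Mapping[VariantKey, ReferenceFrequencyEntry], path: str | Path
) -> None:
    labels = sorted({lab for e in table.values() for lab in e.per_ancestry})
    rows = []
    for entry in sorted(table.values(), key=lambda e: e.key):
        row = {
            "chrom": entry.key.chromosome,
            "pos": entry.key.position,
            "ref": entry.key.ref_allele,
            "alt": entry.key.alt_allele,
            "ac": entry.allele_count,
            "an": entry.allele_number,
        }
        for lab in labels:
            pair = entry.per_ancestry.get(lab)
            row[f"ac_{lab}"] = "" if pair is None else pair[0]
            row[f"an_{lab}"] = "" if pair is None else pair[1]
        rows.append(row)
    cols = ["chrom", "pos", "ref", "alt", "ac", "an"]
    for lab in labels:
        cols += [f"ac_{lab}", f"an_{lab}"]
    pd.DataFrame(rows, columns=cols).to_csv(path, sep="\t", index=False)
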