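from __future__ import annotations

import numpy as np
import pytest

from ieiburden.candidate_filter import FilterConfig, GenotypeCall, Sex, Zygosity
from ieiburden.reference_data import (
    Consequence,
    GenePanelEntry,
    InheritanceMode,
    IUISCategory,
    PathogenicityClass,
    VariantAnnotation,
    VariantKey,
)


def make_call(
    subject: str,
    key: VariantKey,
    zygosity: Zygosity = Zygosity.HET,
    depth: int = 50,
    quality: float = 60.0,
) -> GenotypeCall:
    return GenotypeCall(
        subject_id=subject, key=key, zygosity=zygosity, read_depth=depth, quality=quality
    )


def make_annotation(
    key: VariantKey,
    gene: str,
    consequence: Consequence = Consequence.MISSENSE,
    cls: PathogenicityClass = PathogenicityClass.DM,
    mafs: dict[str, float] | None = None,
) -> VariantAnnotation:
    return VariantAnnotation(
        key=key,
        gene_symbol=gene,
        consequence=consequence,
        pathogenicity_class=cls,
        population_mafs=mafs or {},
    )


@pytest.fixture
def tiny_panel() -> dict[str, GenePanelEntry]:
    def entry(gene, category, modes, chrom):
        return GenePanelEntry(
            gene_symbol=gene,
            iuis_category=category,
            disorder_name=f"{gene} disorder",
            inheritance_modes=frozenset(InheritanceMode(m) for m in modes),
            chromosome=chrom,
        )

    return {
        "NLRP3": entry("NLRP3", IUISCategory.AUTOINFLAMMATORY, ("AD",), "1"),
        "UNC13D": entry("UNC13D", IUISCategory.IMMUNE_DYSREGULATION, ("AR",), "17"),
        "CFH": entry("CFH", IUISCategory.COMPLEMENT, ("AD", "AR"), "1"),
        "IL2RG": entry("IL2RG", IUISCategory.CELLULAR_HUMORAL, ("XLR",), "X"),
    }


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20240917)


@pytest.fixture
def default_filter_config() -> FilterConfig:
    return FilterConfig()


# keys reused across filter tests
K_NLRP3 = VariantKey("1", 1000, "C", "A")
K_UNC13D_1 = VariantKey("17", 2000, "G", "A")
K_UNC13D_2 = VariantKey("17", 2100, "C", "T")
K_CFH = VariantKey("1", 3000, "A", "T")
K_IL2RG = VariantKey("X", 4000, "C", "T")


@pytest.fixture
def tiny_annotations() -> dict[VariantKey, VariantAnnotation]:
    return {
        K_NLRP3: make_annotation(K_NLRP3, "NLRP3", mafs={"gnomAD": 0.01}),
        K_UNC13D_1: make_annotation(K_UNC13D_1, "UNC13D", mafs={"gnomAD": 0.02}),
        K_UNC13D_2: make_annotation(K_UNC13D_2, "UNC13D", mafs={"ExAC": 0.01}),
        K_CFH: make_annotation(
            K_CFH, "CFH", cls=PathogenicityClass.DM_QUERY, mafs={"gnomAD": 0.003}
        ),
        K_IL2RG: make_annotation(K_IL2RG, "IL2RG", mafs={"gnomAD": 0.001}),
    }
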