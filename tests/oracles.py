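"""Independent brute-force oracles used to cross-check the pipeline.

These re-derive expected results from first principles — exact integer
arithmetic for the Fisher test, and a direct textual-rule walk for the
candidate filter — deliberately sharing no code with the implementation.
"""

from __future__ import annotations

from math import comb

from ieiburden.candidate_filter import FilterConfig, GenotypeCall, Sex, Zygosity
from ieiburden.reference_data import (
    Consequence,
    GenePanelEntry,
    InheritanceMode,
    PathogenicityClass,
    VariantAnnotation,
    VariantKey,
)


def fisher_exact_oracle(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher p by exhaustive enumeration in exact integers.

    With fixed margins every table probability shares the denominator
    C(n, r1), so the probability-mass comparison reduces to comparing
    integer numerators exactly — no floating point until the final ratio.
    """
    r1, c1, n = a + b, a + c, a + b + c + d
    lo, hi = max(0, r1 + c1 - n), min(r1, c1)

    def numerator(k: int) -> int:
        return comb(c1, k) * comb(n - c1, r1 - k)

    nums = [numerator(k) for k in range(lo, hi + 1)]
    num_obs = nums[a - lo]
    return sum(v for v in nums if v <= num_obs) / comb(n, r1)


def random_micro_cohort(rng):
    """Random <=5 subjects x <=6 variants cohort exercising every rule edge.

    Returns (calls, sexes, panel, annotations, config). Genotypes sit on
    both sides of each QC/MAF boundary; genes mix AD, AR-only, dual and
    X-linked modes; classes mix DM, DM? and unclassified nulls.
    """
    n_sub = int(rng.integers(1, 6))
    n_var = int(rng.integers(1, 7))
    sexes = {
        f"P{i}": Sex.MALE if rng.random() < 0.5 else Sex.FEMALE for i in range(n_sub)
    }

    gene_specs = [
        ("G_AD", ("AD",), "2", IUISCategoryChoice(rng)),
        ("G_AR", ("AR",), "3", IUISCategoryChoice(rng)),
        ("G_DUAL", ("AD", "AR"), "5", IUISCategoryChoice(rng)),
        ("G_XLR", ("XLR",), "X", IUISCategoryChoice(rng)),
        ("G_XLD", ("XLD",), "X", IUISCategoryChoice(rng)),
    ]
    panel = {}
    for gene, modes, chrom, cat in gene_specs:
        panel[gene] = GenePanelEntry(
            gene_symbol=gene,
            iuis_category=cat,
            disorder_name=gene,
            inheritance_modes=frozenset(InheritanceMode(m) for m in modes),
            chromosome=chrom,
        )
    off_panel_gene = "G_OFF"

    consequences = list(Consequence)
    classes = [PathogenicityClass.DM, PathogenicityClass.DM_QUERY, PathogenicityClass.NONE]
    annotations: dict[VariantKey, VariantAnnotation] = {}
    keys = []
    for j in range(n_var):
        gene, _, chrom, _ = gene_specs[int(rng.integers(len(gene_specs)))]
        if rng.random() < 0.1:
            gene, chrom = off_panel_gene, "9"
        key = VariantKey(chrom, 100 + 10 * j, "A", "T")
        mafs = {}
        for db in ("ExAC", "1000G", "ESP6500", "gnomAD"):
            r = rng.random()
            if r < 0.4:
                continue  # absent from this database
            mafs[db] = float(rng.choice([0.001, 0.049, 0.05, 0.2]))
        annotations[key] = VariantAnnotation(
            key=key,
            gene_symbol=gene,
            consequence=consequences[int(rng.integers(len(consequences)))],
            pathogenicity_class=classes[int(rng.integers(len(classes)))],
            population_mafs=mafs,
        )
        keys.append(key)

    calls = []
    for sid, sex in sexes.items():
        for key in keys:
            if rng.random() < 0.45:
                continue  # non-carrier
            on_x = key.chromosome == "X"
            if on_x and sex is Sex.MALE:
                zyg = Zygosity.HEMI if rng.random() < 0.7 else Zygosity.HET
            else:
                zyg = Zygosity.HOM_ALT if rng.random() < 0.3 else Zygosity.HET
            depth = int(rng.choice([5, 10, 11, 80]))
            qual = float(rng.choice([10.0, 20.0, 21.0, 90.0]))
            calls.append(
                GenotypeCall(
                    subject_id=sid, key=key, zygosity=zyg, read_depth=depth, quality=qual
                )
            )
    config = FilterConfig(recurrent_null_carrier_fraction=float(rng.choice([0.05, 0.3])))
    return calls, sexes, panel, annotations, config


def IUISCategoryChoice(rng):
    from ieiburden.reference_data import IUISCategory

    cats = list(IUISCategory)
    return cats[int(rng.integers(len(cats)))]


NULL_SET = {
    Consequence.NONSENSE,
    Consequence.FRAMESHIFT,
    Consequence.SPLICE_SITE,
    Consequence.START_LOST,
}
NONSYN_SET = NULL_SET | {Consequence.MISSENSE}


def brute_force_decisions(
    calls: list[GenotypeCall],
    sexes: dict[str, Sex],
    panel: dict[str, GenePanelEntry],
    annotations: dict[VariantKey, VariantAnnotation],
    config: FilterConfig,
) -> dict[str, set[tuple[VariantKey, str]]]:
    """Expected (variant, satisfied-mode) set per subject, rule by rule.

    Walks every (subject, gene) pair and applies the textual filter rules
    directly, without reusing any pipeline stage.
    """

    def survives_single_gates(call: GenotypeCall) -> bool:
        ann = annotations.get(call.key)
        if ann is None or ann.gene_symbol not in panel:
            return False
        if not (call.read_depth > config.min_depth and call.quality > config.min_qual):
            return False
        if ann.consequence not in NONSYN_SET:
            return False
        mafs = ann.population_mafs
        if mafs:
            if any(m >= config.maf_threshold for m in mafs.values()):
                return False
        elif not config.maf_missing_is_rare:
            return False
        # pathogenicity basis: curated class, or novel null
        if ann.pathogenicity_class == PathogenicityClass.NONE:
            if ann.consequence not in NULL_SET:
                return False
        return True

    survivors = [c for c in calls if survives_single_gates(c)]

    # recurrent-null removal, novel nulls only
    removed: set[VariantKey] = set()
    for key in {c.key for c in survivors}:
        ann = annotations[key]
        if ann.pathogenicity_class != PathogenicityClass.NONE:
            continue
        if ann.consequence not in NULL_SET:
            continue
        n_carriers = len({c.subject_id for c in survivors if c.key == key})
        if n_carriers / len(sexes) > config.recurrent_null_carrier_fraction:
            removed.add(key)
    survivors = [c for c in survivors if c.key not in removed]

    out: dict[str, set[tuple[VariantKey, str]]] = {sid: set() for sid in sexes}
    for sid, sex in sexes.items():
        for gene, entry in panel.items():
            mine = [
                c
                for c in survivors
                if c.subject_id == sid and annotations[c.key].gene_symbol == gene
            ]
            if not mine:
                continue
            modes = entry.inheritance_modes
            decided: dict[VariantKey, str] = {}
            if InheritanceMode.AD in modes:
                for c in mine:
                    decided.setdefault(c.key, "AD")
            if InheritanceMode.XLD in modes:
                for c in mine:
                    decided.setdefault(c.key, "XL_male" if sex is Sex.MALE else "AD")
            if InheritanceMode.XLR in modes:
                if sex is Sex.MALE:
                    for c in mine:
                        decided.setdefault(c.key, "XL_male")
                else:
                    for c in mine:
                        if c.zygosity is Zygosity.HOM_ALT:
                            decided.setdefault(c.key, "XL_female_biallelic")
            if (
                InheritanceMode.AR in modes
                and InheritanceMode.AD not in modes
                and not entry.is_x_linked
            ):
                for c in mine:
                    if c.zygosity is Zygosity.HOM_ALT:
                        decided.setdefault(c.key, "AR_hom")
                het_keys = {c.key for c in mine if c.zygosity is Zygosity.HET}
                if len(het_keys) >= 2:
                    for c in mine:
                        if c.zygosity is Zygosity.HET:
                            decided.setdefault(c.key, "AR_compound_het")
            out[sid].update(decided.items())
    return out
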