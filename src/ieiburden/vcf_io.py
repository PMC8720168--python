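"""VCF plumbing: read cohort genotype calls, write simulated cohorts.

Only biallelic VCF v4.2 records are accepted; multi-allelic sites must be
pre-split (e.g. ``bcftools norm -m-``) so variant identity stays the
unambiguous (chromosome, position, ref, alt) tuple. The GT field defines
zygosity; DP and GQ feed the quality-control gate, with the site QUAL used
when a sample lacks GQ.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pysam

from .candidate_filter import GenotypeCall, Sex, Zygosity
from .reference_data import FormatError, VariantKey

__all__ = ["read_genotype_calls", "write_vcf"]


def _zygosity(alleles: tuple[int | None, ...]) -> Zygosity | None:
    called = [a for a in alleles if a is not None]
    if not called:
        return None
    alt = [a for a in called if a > 0]
    if not alt:
        return None
    if len(called) == 1:
        return Zygosity.HEMI
    return Zygosity.HOM_ALT if len(alt) == len(called) else Zygosity.HET


def read_genotype_calls(
    path: str | Path,
    subject_sexes: Mapping[str, Sex] | None = None,
) -> tuple[list[GenotypeCall], list[str]]:
    """Read per-subject alt genotype calls from a biallelic VCF.

    Returns (calls, sample names). Reference-homozygous and uncalled
    genotypes produce no call. When ``subject_sexes`` is given, male calls
    on chromosome X are normalized to hemizygous regardless of GT coding.
    """
    calls: list[GenotypeCall] = []
    with pysam.VariantFile(str(path)) as vcf:
        samples = list(vcf.header.samples)
        for record in vcf:
            if record.alts is None or len(record.alts) != 1:
                raise FormatError(
                    f"{path}: multi-allelic record at {record.chrom}:{record.pos}; "
                    "pre-split records (e.g. bcftools norm -m-) before filtering"
                )
            key = VariantKey(
                chromosome=record.chrom,
                position=record.pos,
                ref_allele=record.ref,
                alt_allele=record.alts[0],
            )
            qual = record.qual if record.qual is not None else 0.0
            for sample in samples:
                data = record.samples[sample]
                zyg = _zygosity(data.allele_indices)
                if zyg is None:
                    continue
                if (
                    subject_sexes is not None
                    and key.is_x
                    and subject_sexes.get(sample) is Sex.MALE
                ):
                    zyg = Zygosity.HEMI
                depth = data.get("DP")
                gq = data.get("GQ")
                calls.append(
                    GenotypeCall(
                        subject_id=sample,
                        key=key,
                        zygosity=zyg,
                        read_depth=int(depth) if depth is not None else 0,
                        quality=float(gq) if gq is not None else float(qual),
                    )
                )
    return calls, samples


def write_vcf(
    path: str | Path,
    samples: Sequence[str],
    records: Iterable[tuple[VariantKey, Mapping[str, tuple[Zygosity, int, float]]]],
    contigs: Sequence[str] | None = None,
) -> None:
    """Write a minimal biallelic VCF v4.2 with GT:DP:GQ per sample.

    ``records`` yields (key, {subject_id: (zygosity, depth, gq)}); subjects
    absent from a record's mapping are written homozygous reference with
    nominal depth/quality.
    """
    records = list(records)
    if contigs is None:
        contigs = sorted({k.chromosome for k, _ in records}, key=_contig_order)
    gt = {Zygosity.HET: "0/1", Zygosity.HOM_ALT: "1/1", Zygosity.HEMI: "1"}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=ieiburden-simulator\n")
        for contig in contigs:
            fh.write(f"##contig=<ID={contig}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write('##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">\n')
        fh.write('##FORMAT=<ID=GQ,Number=1,Type=Integer,Description="Genotype quality">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(samples)
            + "\n"
        )
        order = {c: i for i, c in enumerate(contigs)}
        for key, genotypes in sorted(
            records, key=lambda r: (order[r[0].chromosome], r[0].position, r[0].alt_allele)
        ):
            cols = [
                key.chromosome,
                str(key.position),
                ".",
                key.ref_allele,
                key.alt_allele,
                "100",
                "PASS",
                ".",
                "GT:DP:GQ",
            ]
            for sample in samples:
                entry = genotypes.get(sample)
                if entry is None:
                    cols.append("0/0:80:99")
                else:
                    zyg, depth, gq = entry
                    cols.append(f"{gt[zyg]}:{depth}:{int(round(gq))}")
            fh.write("\t".join(cols) + "\n")


def _contig_order(contig: str) -> tuple[int, str]:
    name = contig.upper().removeprefix("CHR")
    if name.isdigit():
        return (int(name), "")
    return (100, name)
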