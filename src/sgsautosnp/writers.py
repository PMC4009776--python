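"""Serialisation of SNP calls and statistics to the five output dialects.

Formats: the human-readable ``.snp`` table, the per-scaffold ``.stat``
summary, GFF3 (genome-browser track), VCF 4.2 (one haploid-style sample per
cultivar) and Flapjack (map + genotype matrix).  The in-memory model is
0-based half-open; every writer converts to 1-based coordinates at the point
of serialisation and nowhere else.  All writers are deterministic: identical
input produces byte-identical files.

The ``.snp`` columns are: scaffold, 1-based scaffold position, 1-based
chromosome position, SNP score, genotypes as ``cultivar:base=count`` joined
by ``;`` (cultivar-sorted), and the allele pair ``X/Y``.
"""

from __future__ import annotations

from typing import Dict, List, Mapping, Optional, Sequence, TextIO, Tuple

from .snp_caller import ScaffoldStats, SnpCall, classify_substitution, total_stats

GFF_SOURCE = "SGSautoSNP"


def _genotype_field(snp: SnpCall) -> str:
    return ";".join(
        f"{cultivar}:{base}={count}"
        for cultivar, (base, count) in sorted(snp.genotypes.items())
    )


def write_snp_text(snps: Sequence[SnpCall], path: str) -> None:
    with open(path, "w") as fh:
        for snp in snps:
            fh.write(
                "\t".join(
                    [
                        snp.contig,
                        str(snp.pos + 1),
                        str(snp.chrom_pos + 1),
                        str(snp.snp_score),
                        _genotype_field(snp),
                        f"{snp.alleles[0]}/{snp.alleles[1]}",
                    ]
                )
                + "\n"
            )


def parse_snp_text(path: str) -> List[SnpCall]:
    """Read a ``.snp`` file back into calls.

    The chromosome *name* is not carried by the format; it is restored as the
    contig name (identity placement).
    """
    snps = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) != 6:
                raise ValueError(f"{path}:{lineno}: expected 6 columns")
            contig, pos1, chrom_pos1, score, genotype_field, allele_field = parts
            genotypes: Dict[str, Tuple[str, int]] = {}
            for item in genotype_field.split(";"):
                cultivar, assignment = item.split(":")
                base, count = assignment.split("=")
                genotypes[cultivar] = (base, int(count))
            a, b = allele_field.split("/")
            snps.append(
                SnpCall(
                    contig=contig,
                    pos=int(pos1) - 1,
                    chrom=contig,
                    chrom_pos=int(chrom_pos1) - 1,
                    alleles=(a, b),
                    snp_score=int(score),
                    genotypes=genotypes,
                    substitution_class=classify_substitution(a, b),
                )
            )
    return snps


def write_stat(stats: Sequence[ScaffoldStats], path: str) -> None:
    """Per-scaffold SNP statistics with a final TOTAL summary row."""
    with open(path, "w") as fh:
        fh.write("scaffold\tsnps\ttransitions\ttransversions\tlength\n")
        for row in list(stats) + [total_stats(stats)]:
            fh.write(
                f"{row.contig}\t{row.snp_count}\t{row.transitions}"
                f"\t{row.transversions}\t{row.length}\n"
            )


def write_gff3(snps: Sequence[SnpCall], path: str) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for i, snp in enumerate(snps, 1):
            attributes = (
                f"ID=snp{i};alleles={snp.alleles[0]}/{snp.alleles[1]};"
                f"genotypes={_genotype_field(snp)}"
            )
            fh.write(
                "\t".join(
                    [
                        snp.contig,
                        GFF_SOURCE,
                        "SNP",
                        str(snp.pos + 1),
                        str(snp.pos + 1),
                        str(snp.snp_score),
                        ".",
                        ".",
                        attributes,
                    ]
                )
                + "\n"
            )


def write_vcf(
    snps: Sequence[SnpCall],
    reference: Mapping[str, str],
    path: str,
    cultivars: Optional[Sequence[str]] = None,
) -> None:
    """VCF 4.2 with one haploid-genotype sample column per cultivar.

    REF is the reference base at the position (the caller itself never uses
    it); called alleles other than REF go to ALT, so a locus where the
    reference matches neither allele lists both in ALT.  Uncovered cultivars
    get ``.``.
    """
    if cultivars is None:
        seen = set()
        for snp in snps:
            seen.update(snp.genotypes)
        cultivars = sorted(seen)
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write(
            '##INFO=<ID=SNPSCORE,Number=1,Type=Integer,'
            'Description="Minimum allele redundancy score">\n'
        )
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            '##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">\n'
        )
        for name, seq in reference.items():
            fh.write(f"##contig=<ID={name},length={len(seq)}>\n")
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(cultivars)
            + "\n"
        )
        for snp in snps:
            if snp.contig not in reference:
                raise ValueError(f"contig {snp.contig!r} absent from reference")
            seq = reference[snp.contig]
            if snp.pos >= len(seq):
                raise ValueError(
                    f"no reference base at {snp.contig}:{snp.pos + 1}"
                )
            ref_base = seq[snp.pos].upper()
            alts = [a for a in snp.alleles if a != ref_base]
            allele_index = {ref_base: 0}
            for k, alt in enumerate(alts, 1):
                allele_index[alt] = k
            samples = []
            for cultivar in cultivars:
                genotype = snp.genotypes.get(cultivar)
                if genotype is None:
                    samples.append(".:.")
                else:
                    base, depth = genotype
                    samples.append(f"{allele_index[base]}:{depth}")
            fh.write(
                "\t".join(
                    [
                        snp.contig,
                        str(snp.pos + 1),
                        ".",
                        ref_base,
                        ",".join(alts) if alts else ".",
                        ".",
                        "PASS",
                        f"SNPSCORE={snp.snp_score}",
                        "GT:DP",
                    ]
                    + samples
                )
                + "\n"
            )


def write_flapjack(
    snps: Sequence[SnpCall],
    path_prefix: str,
    cultivars: Optional[Sequence[str]] = None,
) -> Tuple[str, str]:
    """Flapjack map + genotype files; returns their paths.

    Marker names are ``<contig>_<1-based pos>``; the genotype matrix has one
    row per cultivar and one column per marker, ``-`` where the cultivar is
    uncovered.  Marker order is identical in both files.
    """
    if cultivars is None:
        seen = set()
        for snp in snps:
            seen.update(snp.genotypes)
        cultivars = sorted(seen)
    map_path = path_prefix + ".map"
    genotype_path = path_prefix + ".genotype"
    markers = [f"{snp.contig}_{snp.pos + 1}" for snp in snps]
    with open(map_path, "w") as fh:
        for marker, snp in zip(markers, snps):
            fh.write(f"{marker}\t{snp.chrom}\t{snp.chrom_pos + 1}\n")
    with open(genotype_path, "w") as fh:
        fh.write("\t" + "\t".join(markers) + "\n")
        for cultivar in cultivars:
            cells = []
            for snp in snps:
                genotype = snp.genotypes.get(cultivar)
                cells.append(genotype[0] if genotype else "-")
            fh.write(cultivar + "\t" + "\t".join(cells) + "\n")
    return map_path, genotype_path


ALL_FORMATS = ("snp", "stat", "gff3", "vcf", "flapjack")


def write_output_bundle(
    snps: Sequence[SnpCall],
    stats: Sequence[ScaffoldStats],
    reference: Mapping[str, str],
    prefix: str,
    formats: Sequence[str] = ALL_FORMATS,
    cultivars: Optional[Sequence[str]] = None,
) -> Dict[str, str]:
    """Write the selected output formats under ``prefix``; returns paths."""
    paths: Dict[str, str] = {}
    for fmt in formats:
        if fmt == "snp":
            paths["snp"] = prefix + ".snp"
            write_snp_text(snps, paths["snp"])
        elif fmt == "stat":
            paths["stat"] = prefix + ".stat"
            write_stat(stats, paths["stat"])
        elif fmt == "gff3":
            paths["gff3"] = prefix + ".gff3"
            write_gff3(snps, paths["gff3"])
        elif fmt == "vcf":
            paths["vcf"] = prefix + ".vcf"
            write_vcf(snps, reference, paths["vcf"], cultivars=cultivars)
        elif fmt == "flapjack":
            map_path, genotype_path = write_flapjack(
                snps, prefix, cultivars=cultivars
            )
            paths["flapjack_map"] = map_path
            paths["flapjack_genotype"] = genotype_path
        else:
            raise ValueError(f"unknown output format {fmt!r}")
    return paths
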