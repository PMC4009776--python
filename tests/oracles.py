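"""Independent brute-force oracles used to cross-check the pipeline.

Deliberately naive transcriptions of the calling and consensus rules,
written position-by-position with no shared code with the package, so that
agreement between the two routes is meaningful.
"""

from collections import Counter, defaultdict

IUPAC_BY_SET = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "AG": "R", "CT": "Y", "CG": "S", "AT": "W", "GT": "K", "AC": "M",
    "CGT": "B", "AGT": "D", "ACT": "H", "ACG": "V", "ACGT": "N",
}


def tally_positions(reads):
    """position -> cultivar -> Counter of bases, by brute force."""
    tally = defaultdict(lambda: defaultdict(Counter))
    for read in reads:
        for i, base in enumerate(read.sequence):
            if base in "ACGT":
                tally[read.start + i][read.cultivar][base] += 1
    return tally


def naive_call(cultivar_counts, min_redundancy=2, min_cultivars=2):
    """Literal rule evaluation for one locus.

    Returns (alleles, score) for a call or the rejection reason string.
    cultivar_counts: cultivar -> {base: count} with positive counts.
    """
    covered = {c: k for c, k in cultivar_counts.items() if sum(k.values()) > 0}
    if any(len(k) > 1 for k in covered.values()):
        return "heterozygous"
    bases = sorted({next(iter(k)) for k in covered.values()})
    if len(bases) == 1:
        return "monomorphic"
    if len(bases) > 2:
        return "multiallelic"
    totals = {b: 0 for b in bases}
    deep_cultivars = 0
    deep_alleles = set()
    for k in covered.values():
        (base, depth), = k.items()
        totals[base] += depth
        if depth >= min_redundancy:
            deep_cultivars += 1
            deep_alleles.add(base)
    if deep_cultivars < min_cultivars or deep_alleles != set(bases):
        return "insufficient_redundancy"
    return tuple(bases), min(totals.values())


def naive_snp_positions(reads, min_redundancy=2, min_cultivars=2):
    """All positions where the naive rules call a SNP, with alleles+score."""
    out = {}
    for pos, per_cultivar in tally_positions(reads).items():
        result = naive_call(
            {c: dict(k) for c, k in per_cultivar.items()},
            min_redundancy,
            min_cultivars,
        )
        if isinstance(result, tuple):
            out[pos] = result
    return out


def naive_consensus(reads, length):
    """Per-position consensus by direct rule transcription."""
    pooled = [Counter() for _ in range(length)]
    for read in reads:
        for i, base in enumerate(read.sequence):
            if base in "ACGT":
                pooled[read.start + i][base] += 1
    symbols = []
    for counter in pooled:
        total = sum(counter.values())
        if total == 0:
            symbols.append("N")
        elif total == 1:
            symbols.append(next(iter(counter)))
        else:
            strong = sorted(b for b, c in counter.items() if c >= 2)
            if not strong:
                symbols.append(IUPAC_BY_SET["".join(sorted(counter))])
            elif len(strong) == 1:
                symbols.append(strong[0])
            else:
                symbols.append(IUPAC_BY_SET["".join(strong)])
    return "".join(symbols)
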