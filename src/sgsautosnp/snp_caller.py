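"""Core redundancy-based inter-cultivar SNP caller.

The method targets homozygous (typically inbred crop) genomes and never
consults the reference allele: reads from several cultivars are piled up on a
shared reference purely to position them, and polymorphisms are called
between the reads themselves.  Two rules replace base-quality filtering:

* **Redundancy** — a SNP allele must be seen on at least ``min_redundancy``
  reads (default 2), in at least ``min_cultivars`` cultivars overall
  (default 2); the minimum callable locus coverage is therefore 4 reads.
* **Homogeneity** — within a homozygous cultivar every read at a locus must
  carry the same base.  Any intra-cultivar disagreement marks the column as
  heterozygous-looking and rejects it: in a polyploid this is the signature
  of reads mismapped from a homoeologous copy, not of a cultivar SNP.

Only biallelic columns are called.  The SNP score is the smaller of the two
alleles' total read support summed over cultivars.
"""

from __future__ import annotations

import logging
from collections import defaultdict
from concurrent.futures import ThreadPoolExecutor
from dataclasses import dataclass, field
from typing import Dict, Iterable, Iterator, List, Mapping, Optional, Sequence, Tuple

from .alignment_io import AlignedRead
from .dna import BASES, is_transition

logger = logging.getLogger(__name__)

TRANSITION = "transition"
TRANSVERSION = "transversion"

# no-call reason codes
HETEROZYGOUS = "heterozygous"
MONOMORPHIC = "monomorphic"
MULTIALLELIC = "multiallelic"
INSUFFICIENT_REDUNDANCY = "insufficient_redundancy"
DEPTH_EXCEEDED = "depth_exceeded"


@dataclass(frozen=True)
class CallerParams:
    """Calling thresholds.

    min_redundancy: reads per cultivar needed for that cultivar to vouch for
        its allele (default 2).
    min_cultivars: cultivars that must reach min_redundancy for the locus to
        be callable (default 2).
    max_depth: optional cap on total locus depth, for repeat-rich data;
        ``None`` means unlimited.
    """

    min_redundancy: int = 2
    min_cultivars: int = 2
    max_depth: Optional[int] = None

    def __post_init__(self) -> None:
        if self.min_redundancy < 1:
            raise ValueError("min_redundancy must be >= 1")
        if self.min_cultivars < 2:
            raise ValueError("min_cultivars must be >= 2")


@dataclass
class PileupColumn:
    """Per-position, per-cultivar base counts (N bases excluded)."""

    contig: str
    pos: int
    counts: Dict[str, Dict[str, int]]

    def total_depth(self) -> int:
        return sum(sum(c.values()) for c in self.counts.values())


@dataclass(frozen=True)
class SnpCall:
    """A called biallelic inter-cultivar SNP.

    ``genotypes`` maps every covered cultivar to (base, read count), including
    depth-1 cultivars that contributed nothing to the redundancy evidence.
    Alleles are ordered lexicographically.
    """

    contig: str
    pos: int
    chrom: str
    chrom_pos: int
    alleles: Tuple[str, str]
    snp_score: int
    genotypes: Dict[str, Tuple[str, int]]
    substitution_class: str


@dataclass(frozen=True)
class NoCall:
    """Rejected column with the reason code."""

    contig: str
    pos: int
    reason: str


@dataclass
class ScaffoldStats:
    contig: str
    length: int
    snp_count: int = 0
    transitions: int = 0
    transversions: int = 0


def classify_substitution(a: str, b: str) -> str:
    """Classify an a<->b substitution as transition or transversion."""
    if a == b:
        raise ValueError("substitution requires two distinct bases")
    if a not in BASES or b not in BASES:
        raise ValueError(f"non-ACGT base in substitution: {a!r}/{b!r}")
    return TRANSITION if is_transition(a, b) else TRANSVERSION


def build_pileup(
    reads: Iterable[AlignedRead],
    contig: str,
    contig_length: Optional[int] = None,
) -> Iterator[PileupColumn]:
    """Pile reads of one contig into per-cultivar base-count columns.

    Yields one column per covered position, in coordinate order.  The
    reference sequence contributes nothing — counts come from reads only.
    N bases are excluded from counts.
    """
    columns: Dict[int, Dict[str, Dict[str, int]]] = defaultdict(dict)
    for read in reads:
        if read.contig != contig:
            raise ValueError(
                f"read {read.read_id} on {read.contig}, expected {contig}"
            )
        if contig_length is not None and read.end > contig_length:
            raise ValueError(
                f"read {read.read_id} overhangs contig {contig} "
                f"({read.end} > {contig_length})"
            )
        for offset, base in enumerate(read.sequence):
            if base not in BASES:
                continue
            col = columns[read.start + offset]
            cultivar_counts = col.setdefault(read.cultivar, {})
            cultivar_counts[base] = cultivar_counts.get(base, 0) + 1
    for pos in sorted(columns):
        yield PileupColumn(contig=contig, pos=pos, counts=columns[pos])


def call_snp(column: PileupColumn, params: CallerParams = CallerParams()):
    """Apply the redundancy + homogeneity rules to one pileup column.

    Returns a :class:`SnpCall` or a :class:`NoCall` carrying the reason the
    column was rejected: ``heterozygous`` (intra-cultivar disagreement, the
    mismapping signature), ``monomorphic``, ``multiallelic``, or
    ``insufficient_redundancy``.
    """
    covered = {c: counts for c, counts in column.counts.items() if sum(counts.values()) > 0}
    if not covered:
        raise ValueError("call_snp requires a column with >=1 covered cultivar")

    if params.max_depth is not None and column.total_depth() > params.max_depth:
        return NoCall(column.contig, column.pos, DEPTH_EXCEEDED)

    # homogeneity: all reads within a cultivar must agree
    genotypes: Dict[str, Tuple[str, int]] = {}
    for cultivar, counts in covered.items():
        if len(counts) > 1:
            return NoCall(column.contig, column.pos, HETEROZYGOUS)
        (base, depth), = counts.items()
        genotypes[cultivar] = (base, depth)

    alleles = sorted({base for base, _ in genotypes.values()})
    if len(alleles) == 1:
        return NoCall(column.contig, column.pos, MONOMORPHIC)
    if len(alleles) > 2:
        return NoCall(column.contig, column.pos, MULTIALLELIC)

    # redundancy: each allele vouched for by >=1 cultivar at min_redundancy,
    # and >= min_cultivars cultivars at min_redundancy overall
    support = {a: 0 for a in alleles}
    qualifying = 0
    allele_backed = {a: False for a in alleles}
    for base, depth in genotypes.values():
        support[base] += depth
        if depth >= params.min_redundancy:
            qualifying += 1
            allele_backed[base] = True
    if qualifying < params.min_cultivars or not all(allele_backed.values()):
        return NoCall(column.contig, column.pos, INSUFFICIENT_REDUNDANCY)

    a, b = alleles
    return SnpCall(
        contig=column.contig,
        pos=column.pos,
        chrom=column.contig,
        chrom_pos=column.pos,
        alleles=(a, b),
        snp_score=min(support[a], support[b]),
        genotypes=genotypes,
        substitution_class=classify_substitution(a, b),
    )


# ---------------------------------------------------------------------------
# whole-dataset scan


@dataclass
class PlacementTable:
    """Maps contigs to chromosome coordinates (syntenic build placement)."""

    entries: Dict[str, Tuple[str, int, str]]  # contig -> (chrom, 0-based offset, strand)

    @classmethod
    def from_tsv(cls, path: str) -> "PlacementTable":
        entries = {}
        with open(path) as fh:
            for lineno, line in enumerate(fh, 1):
                line = line.rstrip("\n")
                if not line or line.startswith("#"):
                    continue
                parts = line.split("\t")
                if len(parts) != 4:
                    raise ValueError(
                        f"{path}:{lineno}: expected 4 columns (contig, chrom, offset, strand)"
                    )
                contig, chrom, offset, strand = parts
                if strand != "+":
                    raise ValueError(
                        f"{path}:{lineno}: only '+' placements supported"
                    )
                entries[contig] = (chrom, int(offset), strand)
        return cls(entries)

    def place(self, contig: str, pos: int) -> Tuple[str, int]:
        if contig not in self.entries:
            return contig, pos
        chrom, offset, _ = self.entries[contig]
        return chrom, offset + pos


def reference_lengths(reference: Mapping[str, str]) -> Dict[str, int]:
    return {name: len(seq) for name, seq in reference.items()}


def scan(
    alignments: Iterable[AlignedRead],
    reference: Mapping[str, str],
    params: CallerParams = CallerParams(),
    placement: Optional[PlacementTable] = None,
    workers: int = 1,
) -> Tuple[List[SnpCall], List[ScaffoldStats]]:
    """Run pileup + calling over every contig of a merged sorted stream.

    ``reference`` maps contig name to sequence (used for lengths and contig
    order only — alleles never depend on the reference base).  Contigs are
    processed on a thread pool of ``workers`` and results concatenated in
    reference order, so output is independent of scheduling.
    """
    by_contig: Dict[str, List[AlignedRead]] = defaultdict(list)
    for read in alignments:
        if read.contig not in reference:
            raise ValueError(f"contig {read.contig!r} absent from reference")
        by_contig[read.contig].append(read)

    contigs = [name for name in reference if name in by_contig]

    def process(contig: str) -> Tuple[List[SnpCall], ScaffoldStats]:
        length = len(reference[contig])
        stats = ScaffoldStats(contig=contig, length=length)
        calls: List[SnpCall] = []
        for column in build_pileup(by_contig[contig], contig, length):
            result = call_snp(column, params)
            if isinstance(result, SnpCall):
                chrom, chrom_pos = (
                    placement.place(contig, result.pos)
                    if placement
                    else (contig, result.pos)
                )
                result = SnpCall(
                    contig=result.contig,
                    pos=result.pos,
                    chrom=chrom,
                    chrom_pos=chrom_pos,
                    alleles=result.alleles,
                    snp_score=result.snp_score,
                    genotypes=result.genotypes,
                    substitution_class=result.substitution_class,
                )
                calls.append(result)
                stats.snp_count += 1
                if result.substitution_class == TRANSITION:
                    stats.transitions += 1
                else:
                    stats.transversions += 1
        return calls, stats

    all_calls: List[SnpCall] = []
    all_stats: List[ScaffoldStats] = []
    if workers <= 1:
        results = [process(c) for c in contigs]
    else:
        with ThreadPoolExecutor(max_workers=workers) as pool:
            results = list(pool.map(process, contigs))
    for contig, (calls, stats) in zip(contigs, results):
        all_calls.extend(calls)
        all_stats.append(stats)
        logger.debug("contig %s: %d SNPs", contig, stats.snp_count)

    # contigs with reads absent entirely from output would hide zero-SNP
    # scaffolds; keep a stats row for every contig that had coverage, plus
    # rows for covered-but-empty contigs already handled above.
    return all_calls, all_stats


def total_stats(stats: Sequence[ScaffoldStats]) -> ScaffoldStats:
    """Grand-total summary row over per-scaffold statistics."""
    return ScaffoldStats(
        contig="TOTAL",
        length=sum(s.length for s in stats),
        snp_count=sum(s.snp_count for s in stats),
        transitions=sum(s.transitions for s in stats),
        transversions=sum(s.transversions for s in stats),
    )
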