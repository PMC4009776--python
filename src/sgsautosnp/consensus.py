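"""Per-contig consensus sequence from the read alignment.

The consensus summarises what the reads — not the reference — say at every
position, using a five-step rule cascade per position:

1. no coverage                           -> ``N``
2. one read                              -> that read's base
3. several reads, unanimous              -> the shared base
4. several reads, a lone dissenter       -> dissenter dropped as an error,
   majority base emitted
5. several reads, >=2 reads on >=2 bases -> IUPAC degenerate code over the
   bases with count >= 2 (singleton bases dropped as errors)

When more than one read covers a position but every base is a singleton
(e.g. two reads, A and G), dropping all singletons would leave nothing, so
the degenerate code over all observed bases is emitted instead.

Cultivar identity is ignored: all reads are pooled, matching the consensus's
role as template for marker design over the combined panel.  A per-cultivar
consensus is available by pre-filtering the read stream.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Iterable, List, Mapping, Optional

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .alignment_io import AlignedRead
from .dna import BASES, iupac_code


@dataclass
class ConsensusSequence:
    contig: str
    sequence: str


def consensus_base(counts: Mapping[str, int]) -> str:
    """Consensus symbol for one position from pooled base counts."""
    for base, count in counts.items():
        if count < 0:
            raise ValueError(f"negative count for base {base}")
        if base not in BASES:
            raise ValueError(f"non-ACGT base in counts: {base!r}")
    counts = {b: c for b, c in counts.items() if c > 0}
    total = sum(counts.values())
    if total == 0:
        return "N"
    if total == 1:
        return next(iter(counts))
    supported = [b for b, c in counts.items() if c >= 2]
    if not supported:
        # several reads, all singletons: nothing outvotes anything
        return iupac_code(counts)
    if len(supported) == 1:
        return supported[0]
    return iupac_code(supported)


def build_consensus(
    reads: Iterable[AlignedRead],
    contig: str,
    contig_length: int,
    cultivar: Optional[str] = None,
) -> ConsensusSequence:
    """Apply :func:`consensus_base` at every position of ``contig``.

    ``cultivar`` restricts the consensus to one cultivar's reads; default
    pools everything.
    """
    if contig_length <= 0:
        raise ValueError("contig_length must be positive")
    counts: List[Dict[str, int]] = [dict() for _ in range(contig_length)]
    for read in reads:
        if read.contig != contig:
            raise ValueError(
                f"read {read.read_id} on {read.contig}, expected {contig}"
            )
        if cultivar is not None and read.cultivar != cultivar:
            continue
        if read.end > contig_length:
            raise ValueError(
                f"read {read.read_id} overhangs contig end "
                f"({read.end} > {contig_length})"
            )
        for offset, base in enumerate(read.sequence):
            if base not in BASES:
                continue
            col = counts[read.start + offset]
            col[base] = col.get(base, 0) + 1
    sequence = "".join(consensus_base(col) for col in counts)
    return ConsensusSequence(contig=contig, sequence=sequence)


def write_consensus_fasta(
    consensuses: Iterable[ConsensusSequence], path: str
) -> None:
    """Write consensus sequences as one multi-FASTA file."""
    records = [
        SeqRecord(Seq(c.sequence), id=c.contig, description="")
        for c in consensuses
    ]
    SeqIO.write(records, path, "fasta")


def read_consensus_fasta(path: str) -> Dict[str, ConsensusSequence]:
    return {
        rec.id: ConsensusSequence(contig=rec.id, sequence=str(rec.seq).upper())
        for rec in SeqIO.parse(path, "fasta")
    }
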