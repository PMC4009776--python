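"""Ingest paired-read alignments and present them as a uniform read stream.

The caller consumes coordinate-sorted streams of :class:`AlignedRead`, one
logical set per cultivar, with the cultivar identity carried on the read ID
(suffix ``#<cultivar>``).  Three on-disk sources are supported: SAM, BAM and
the classic SOAPaligner text output (converted on the fly).

Only reads mapped in a proper pair are admitted — a single short read can sit
at many places in a repeat-rich genome, but two mates at the expected insert
distance pin the placement down.  The alignment model is ungapped: a read is
one match block on the reference, and records whose CIGAR contains insertions
or deletions are skipped (and counted).  Both rules are re-enforced here
regardless of what the upstream mapper did.
"""

from __future__ import annotations

import heapq
from dataclasses import dataclass, field, replace
from typing import Iterable, Iterator, List, Optional, Sequence, Tuple

import pysam

from .dna import revcomp

TAG_DELIMITER = "#"

_CIGAR_GAP_OPS = {1, 2, 3}  # I, D, N (reference skip)


class AlignmentFormatError(ValueError):
    """A record could not be parsed in the declared format."""


@dataclass(frozen=True)
class AlignedRead:
    """One mapped read, ungapped, in reference-forward orientation.

    ``start`` is the 0-based leftmost reference position; ``sequence`` spans
    exactly ``length`` reference bases.  ``mate_contig``/``mate_start`` are
    ``""``/``-1`` when the source format does not expose them.
    """

    read_id: str
    cultivar: str
    contig: str
    start: int
    length: int
    strand: str  # "+" or "-"
    sequence: str
    is_proper_pair: bool = True
    mate_contig: str = ""
    mate_start: int = -1

    def __post_init__(self) -> None:
        if self.start < 0:
            raise ValueError(f"negative start for read {self.read_id}")
        if len(self.sequence) != self.length:
            raise ValueError(
                f"read {self.read_id}: sequence length {len(self.sequence)} "
                f"!= aligned span {self.length}"
            )
        if self.strand not in ("+", "-"):
            raise ValueError(f"read {self.read_id}: bad strand {self.strand!r}")

    @property
    def end(self) -> int:
        """0-based exclusive end on the reference."""
        return self.start + self.length


@dataclass
class CultivarManifest:
    """Ordered (cultivar label, alignment path) pairs; >=2 distinct labels."""

    entries: List[Tuple[str, str]]

    def __post_init__(self) -> None:
        labels = [c for c, _ in self.entries]
        if len(set(labels)) < 2:
            raise ValueError("manifest needs >=2 distinct cultivar labels")
        for label in labels:
            if TAG_DELIMITER in label:
                raise ValueError(
                    f"cultivar label {label!r} contains the tag delimiter "
                    f"{TAG_DELIMITER!r}"
                )

    @property
    def cultivars(self) -> List[str]:
        return [c for c, _ in self.entries]

    @classmethod
    def from_tsv(cls, path: str) -> "CultivarManifest":
        entries = []
        with open(path) as fh:
            for lineno, line in enumerate(fh, 1):
                line = line.rstrip("\n")
                if not line or line.startswith("#"):
                    continue
                parts = line.split("\t")
                if len(parts) != 2:
                    raise AlignmentFormatError(
                        f"{path}:{lineno}: expected 2 tab-separated columns"
                    )
                entries.append((parts[0], parts[1]))
        return cls(entries)


@dataclass
class LoadStats:
    """Bookkeeping for one load: reads_in = yielded + skipped_*."""

    yielded: int = 0
    skipped_unpaired: int = 0
    skipped_unmapped: int = 0
    skipped_gapped: int = 0

    @property
    def skipped(self) -> int:
        return self.skipped_unpaired + self.skipped_unmapped + self.skipped_gapped

    @property
    def reads_in(self) -> int:
        return self.yielded + self.skipped


class AlignmentStream:
    """Iterator over AlignedReads that exposes skip counters in ``.stats``."""

    def __init__(self, iterator: Iterator[AlignedRead], stats: LoadStats):
        self._iterator = iterator
        self.stats = stats

    def __iter__(self) -> Iterator[AlignedRead]:
        return self._iterator


def load_alignments(path: str, format: str, cultivar: str) -> AlignmentStream:
    """Stream proper-pair mapped reads from ``path`` tagged with ``cultivar``.

    ``format`` is one of ``sam``, ``bam``, ``soap-text``.  Unmapped, unpaired
    and gapped records are counted and skipped; every yielded read carries the
    given cultivar label (read IDs are not rewritten here — see
    :func:`tag_read_ids`).
    """
    stats = LoadStats()
    if format in ("sam", "bam"):
        iterator = _iter_sam(path, format, cultivar, stats)
    elif format == "soap-text":
        iterator = _iter_soap(path, cultivar, stats)
    else:
        raise AlignmentFormatError(f"unknown alignment format: {format!r}")
    return AlignmentStream(iterator, stats)


def _iter_sam(path: str, format: str, cultivar: str, stats: LoadStats):
    mode = "rb" if format == "bam" else "r"
    with pysam.AlignmentFile(path, mode, check_sq=False) as fh:
        for rec in fh:
            if rec.is_unmapped or rec.reference_name is None:
                stats.skipped_unmapped += 1
                continue
            if not (rec.is_paired and rec.is_proper_pair):
                stats.skipped_unpaired += 1
                continue
            cigar = rec.cigartuples or []
            if any(op in _CIGAR_GAP_OPS for op, _ in cigar):
                stats.skipped_gapped += 1
                continue
            seq = rec.query_alignment_sequence
            if seq is None:
                stats.skipped_unmapped += 1
                continue
            mate_contig = ""
            mate_start = -1
            if rec.next_reference_id >= 0:
                mate_contig = rec.next_reference_name or ""
                mate_start = rec.next_reference_start
            stats.yielded += 1
            yield AlignedRead(
                read_id=rec.query_name or "",
                cultivar=cultivar,
                contig=rec.reference_name,
                start=rec.reference_start,
                length=len(seq),
                strand="-" if rec.is_reverse else "+",
                sequence=seq.upper(),
                is_proper_pair=True,
                mate_contig=mate_contig,
                mate_start=mate_start,
            )


def _iter_soap(path: str, cultivar: str, stats: LoadStats):
    # SOAP paired-end output holds only pair-mapped hits, so every parsed
    # record passes the proper-pair rule by construction.  Records are sorted
    # here because SOAP output is read-ordered, not coordinate-ordered.
    reads = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip():
                continue
            read = parse_soap_record(line, lineno=lineno)
            reads.append(replace(read, cultivar=cultivar))
    reads.sort(key=lambda r: (r.contig, r.start, r.read_id))
    for read in reads:
        stats.yielded += 1
        yield read


def parse_soap_record(line: str, lineno: int = 0) -> AlignedRead:
    """Parse one SOAPaligner text record into an :class:`AlignedRead`.

    Consumed columns (0-based): 0 read id, 1 sequence, 6 strand (+/-),
    7 contig, 8 1-based leftmost position.  Trailing columns are ignored.
    Reverse-strand sequences are reverse-complemented to reference-forward
    orientation.
    """
    parts = line.rstrip("\n").split("\t")
    if len(parts) < 9:
        raise AlignmentFormatError(
            f"SOAP record at line {lineno}: expected >=9 columns, got {len(parts)}"
        )
    read_id, seq, strand, contig, pos = (
        parts[0],
        parts[1].upper(),
        parts[6],
        parts[7],
        parts[8],
    )
    if strand not in ("+", "-"):
        raise AlignmentFormatError(
            f"SOAP record at line {lineno}: bad strand {strand!r}"
        )
    try:
        start = int(pos) - 1
    except ValueError:
        raise AlignmentFormatError(
            f"SOAP record at line {lineno}: non-integer position {pos!r}"
        ) from None
    if strand == "-":
        seq = revcomp(seq)
    return AlignedRead(
        read_id=read_id,
        cultivar="",
        contig=contig,
        start=start,
        length=len(seq),
        strand=strand,
        sequence=seq,
        is_proper_pair=True,
    )


def tag_read_ids(
    reads: Iterable[AlignedRead], cultivar: str
) -> Iterator[AlignedRead]:
    """Append ``#<cultivar>`` to each read ID (idempotent) and set the field."""
    if not cultivar:
        raise ValueError("cultivar label must be non-empty")
    if TAG_DELIMITER in cultivar:
        raise ValueError(
            f"cultivar label {cultivar!r} contains {TAG_DELIMITER!r}"
        )
    suffix = TAG_DELIMITER + cultivar
    for read in reads:
        read_id = read.read_id
        if not read_id.endswith(suffix):
            read_id = read_id + suffix
        yield replace(read, read_id=read_id, cultivar=cultivar)


def tag_read_id(read_id: str, cultivar: str) -> str:
    """Tag a bare read-ID string; used by the BAM-level CLI plumbing."""
    suffix = TAG_DELIMITER + cultivar
    return read_id if read_id.endswith(suffix) else read_id + suffix


def merge_sorted(
    sets: Sequence[Iterable[AlignedRead]],
    contig_order: Optional[Sequence[str]] = None,
) -> Iterator[AlignedRead]:
    """K-way merge of per-cultivar coordinate-sorted streams.

    Contigs follow ``contig_order`` (reference FASTA order) when given, else
    first-seen lexicographic order.  Ties at one position are broken by input
    set order then read ID, so the merge is fully deterministic.  A stream
    found out of order raises ``ValueError`` naming the stream and record.
    """
    rank = {}
    if contig_order is not None:
        rank = {name: i for i, name in enumerate(contig_order)}

    def contig_rank(contig: str):
        if contig_order is not None:
            if contig not in rank:
                raise ValueError(f"contig {contig!r} absent from contig_order")
            return rank[contig]
        return contig

    def keyed(stream, index):
        last_key = None
        for position, read in enumerate(stream):
            key = (contig_rank(read.contig), read.start)
            if last_key is not None and key < last_key:
                raise ValueError(
                    f"input stream {index} unsorted at record {position} "
                    f"({read.contig}:{read.start})"
                )
            last_key = key
            yield (*key, index, read.read_id), read

    merged = heapq.merge(*(keyed(s, i) for i, s in enumerate(sets)))
    for _, read in merged:
        yield read
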