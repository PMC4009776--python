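"""Synthetic alignment generator with a known SNP truth set.

Emulates the caller's study conditions end to end: several homozygous
cultivars that differ at planted biallelic SNPs with a controllable
transition fraction, paired reads of fixed length and insert size with
uniform per-base substitution errors, and — the method's central confounder
— read pairs mismapped from a diverged homoeologous copy of a contig, which
create intra-cultivar conflicts the homogeneity rule must reject.

Reads are emitted pre-aligned at their generative coordinates (mapping is an
external step in the real pipeline); a SAM writer lets real mappers be
slotted in instead.  Pair placement is stratified — one pair jittered inside
each equal-width window — so a nominal coverage guarantees a minimum depth
everywhere away from contig edges, and planted variants are kept one insert
length from the ends where paired coverage decays.

All randomness is driven by explicit integer seeds; a fixed seed reproduces
the dataset byte for byte.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pysam
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .alignment_io import AlignedRead
from .dna import BASES, is_transition

DEFAULT_READ_LENGTH = 100
DEFAULT_INSERT = 300
#: transition fraction typical of real crop SNP panels (methylC deamination bias)
DEFAULT_TSTV = 0.68

_TRANSITION_PARTNER = {"A": "G", "G": "A", "C": "T", "T": "C"}
_TRANSVERSION_PARTNERS = {
    "A": ("C", "T"),
    "G": ("C", "T"),
    "C": ("A", "G"),
    "T": ("A", "G"),
}


@dataclass
class TruthSet:
    """Planted variants: (contig, 0-based pos, cultivar -> base)."""

    variants: List[Tuple[str, int, Dict[str, str]]]
    tstv_target: float = DEFAULT_TSTV

    def positions(self) -> set:
        return {(contig, pos) for contig, pos, _ in self.variants}

    def transition_fraction(self) -> float:
        if not self.variants:
            return float("nan")
        n_ts = 0
        for _, _, genotypes in self.variants:
            a, b = sorted(set(genotypes.values()))
            n_ts += is_transition(a, b)
        return n_ts / len(self.variants)


def generate_reference(
    n_contigs: int,
    length: int,
    gc: float = 0.5,
    seed: int = 0,
    name_prefix: str = "contig",
) -> Dict[str, str]:
    """Random reference contigs with the requested GC content."""
    if length <= 0:
        raise ValueError("contig length must be positive")
    if not 0.0 <= gc <= 1.0:
        raise ValueError("gc must be in [0, 1]")
    rng = np.random.default_rng(seed)
    probabilities = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]  # A C G T
    reference = {}
    for i in range(1, n_contigs + 1):
        bases = rng.choice(list(BASES), size=length, p=probabilities)
        reference[f"{name_prefix}_{i}"] = "".join(bases)
    return reference


def plant_variants(
    reference: Mapping[str, str],
    cultivars: Sequence[str],
    n_snps: int,
    tstv: float = DEFAULT_TSTV,
    seed: int = 0,
    edge_margin: int = DEFAULT_INSERT,
) -> Tuple[Dict[str, Dict[str, str]], TruthSet]:
    """Derive per-cultivar haplotypes differing at ``n_snps`` planted sites.

    Each site is biallelic with a random non-trivial cultivar split; the
    alternate base is a transition of the original with probability
    ``tstv``.  Sites stay ``edge_margin`` bases from contig ends, where
    paired-read coverage decays.  Haplotypes equal the reference elsewhere.
    """
    if len(cultivars) < 2:
        raise ValueError("need >=2 cultivars")
    rng = np.random.default_rng(seed)
    candidates = [
        (contig, pos)
        for contig, seq in reference.items()
        for pos in range(edge_margin, len(seq) - edge_margin)
    ]
    if n_snps > len(candidates):
        raise ValueError(
            f"cannot plant {n_snps} SNPs in {len(candidates)} eligible positions"
        )
    chosen = rng.choice(len(candidates), size=n_snps, replace=False)
    sites = sorted(candidates[i] for i in chosen)

    haplotypes = {c: {ctg: list(seq) for ctg, seq in reference.items()} for c in cultivars}
    variants = []
    for contig, pos in sites:
        ref_base = reference[contig][pos]
        if rng.random() < tstv:
            alt = _TRANSITION_PARTNER[ref_base]
        else:
            alt = _TRANSVERSION_PARTNERS[ref_base][rng.integers(2)]
        # non-trivial split: 1..len-1 cultivars carry the alternate base
        n_alt = int(rng.integers(1, len(cultivars)))
        carriers = rng.choice(len(cultivars), size=n_alt, replace=False)
        genotypes = {}
        for i, cultivar in enumerate(cultivars):
            base = alt if i in carriers else ref_base
            genotypes[cultivar] = base
            haplotypes[cultivar][contig][pos] = base
        variants.append((contig, pos, genotypes))

    haplotype_seqs = {
        c: {ctg: "".join(chars) for ctg, chars in per_contig.items()}
        for c, per_contig in haplotypes.items()
    }
    return haplotype_seqs, TruthSet(variants=variants, tstv_target=tstv)


def simulate_read_pairs(
    haplotype: str,
    contig: str,
    cultivar: str,
    coverage: float,
    read_len: int = DEFAULT_READ_LENGTH,
    insert: int = DEFAULT_INSERT,
    error_rate: float = 0.0,
    seed: int = 0,
) -> List[AlignedRead]:
    """Paired reads from one contig haplotype at their true coordinates.

    ``insert`` is the outer fragment length (mate starts are ``insert -
    read_len`` apart); pre-condition ``insert >= 2*read_len``.  Placement is
    stratified over equal windows so realised depth tracks ``coverage``
    tightly.  Errors are uniform substitutions at ``error_rate`` per base.
    """
    if insert < 2 * read_len:
        raise ValueError("insert must be >= 2 * read_len")
    if coverage <= 0:
        raise ValueError("coverage must be positive")
    length = len(haplotype)
    if length < insert:
        raise ValueError(f"contig {contig} shorter than insert size")
    rng = np.random.default_rng(seed)
    n_pairs = max(1, round(coverage * length / (2 * read_len)))
    max_start = length - insert
    window = (max_start + 1) / n_pairs
    reads = []
    for i in range(n_pairs):
        low = int(i * window)
        high = max(low + 1, int((i + 1) * window))
        start = int(rng.integers(low, min(high, max_start + 1)))
        fragment_id = f"sim_{cultivar}_{contig}_{i}"
        fwd_seq = _with_errors(haplotype[start:start + read_len], rng, error_rate)
        rev_start = start + insert - read_len
        rev_seq = _with_errors(
            haplotype[rev_start:rev_start + read_len], rng, error_rate
        )
        reads.append(
            AlignedRead(
                read_id=fragment_id + "/1",
                cultivar=cultivar,
                contig=contig,
                start=start,
                length=read_len,
                strand="+",
                sequence=fwd_seq,
                is_proper_pair=True,
                mate_contig=contig,
                mate_start=rev_start,
            )
        )
        reads.append(
            AlignedRead(
                read_id=fragment_id + "/2",
                cultivar=cultivar,
                contig=contig,
                start=rev_start,
                length=read_len,
                strand="-",
                sequence=rev_seq,
                is_proper_pair=True,
                mate_contig=contig,
                mate_start=start,
            )
        )
    reads.sort(key=lambda r: (r.start, r.read_id))
    return reads


def _with_errors(seq: str, rng: np.random.Generator, error_rate: float) -> str:
    if error_rate <= 0:
        return seq
    chars = list(seq)
    hits = np.nonzero(rng.random(len(chars)) < error_rate)[0]
    for i in hits:
        alternatives = [b for b in BASES if b != chars[i]]
        chars[i] = alternatives[rng.integers(3)]
    return "".join(chars)


def make_diverged_copy(
    seq: str, divergence: float = 0.02, seed: int = 0
) -> Tuple[str, List[int]]:
    """A homoeolog-like copy of ``seq``: substitutions at rate ``divergence``.

    Returns the copy and the list of diverged positions.
    """
    rng = np.random.default_rng(seed)
    chars = list(seq)
    positions = sorted(np.nonzero(rng.random(len(chars)) < divergence)[0].tolist())
    for i in positions:
        alternatives = [b for b in BASES if b != chars[i]]
        chars[i] = alternatives[rng.integers(3)]
    return "".join(chars), positions


def inject_mismapped_reads(
    reads: Sequence[AlignedRead],
    diverged_contig: str,
    rate: float,
    seed: int = 0,
) -> List[AlignedRead]:
    """Re-source a fraction of read *pairs* from a diverged copy of the contig.

    The selected reads keep their coordinates but their sequence is taken
    from ``diverged_contig`` at the same positions — exactly what a read
    mismapped across homoeologs looks like.  Returns a new read list.
    """
    if not 0.0 <= rate <= 1.0:
        raise ValueError("rate must be in [0, 1]")
    if rate == 0 or not reads:
        return list(reads)
    rng = np.random.default_rng(seed)
    fragments = sorted({r.read_id.rsplit("/", 1)[0] for r in reads})
    selected = {f for f in fragments if rng.random() < rate}
    out = []
    for read in reads:
        fragment = read.read_id.rsplit("/", 1)[0]
        if fragment in selected:
            new_seq = diverged_contig[read.start:read.end]
            out.append(replace(read, sequence=new_seq))
        else:
            out.append(read)
    return out


# ---------------------------------------------------------------------------
# on-disk fixture emission


def write_reference_fasta(reference: Mapping[str, str], path: str) -> None:
    records = [
        SeqRecord(Seq(seq), id=name, description="")
        for name, seq in reference.items()
    ]
    SeqIO.write(records, path, "fasta")


def write_sam(
    reads: Iterable[AlignedRead],
    reference_lengths: Mapping[str, int],
    path: str,
) -> None:
    """Write reads as a coordinate-sorted SAM file with proper-pair flags."""
    header = {
        "HD": {"VN": "1.6", "SO": "coordinate"},
        "SQ": [
            {"SN": name, "LN": length}
            for name, length in reference_lengths.items()
        ],
    }
    contig_index = {name: i for i, name in enumerate(reference_lengths)}
    sorted_reads = sorted(
        reads, key=lambda r: (contig_index[r.contig], r.start, r.read_id)
    )
    with pysam.AlignmentFile(path, "wh", header=header) as fh:
        for read in sorted_reads:
            rec = pysam.AlignedSegment(fh.header)
            rec.query_name = read.read_id
            rec.query_sequence = read.sequence
            rec.flag = 0x1 | 0x2  # paired, proper pair
            if read.strand == "-":
                rec.flag |= 0x10
            else:
                rec.flag |= 0x20  # mate reverse for the forward mate
            if read.read_id.endswith("/2"):
                rec.flag |= 0x80
            else:
                rec.flag |= 0x40
            rec.reference_id = contig_index[read.contig]
            rec.reference_start = read.start
            rec.mapping_quality = 60
            rec.cigartuples = [(0, read.length)]
            if read.mate_contig in contig_index and read.mate_start >= 0:
                rec.next_reference_id = contig_index[read.mate_contig]
                rec.next_reference_start = read.mate_start
                span = (
                    max(read.start + read.length, read.mate_start + read.length)
                    - min(read.start, read.mate_start)
                )
                rec.template_length = span if read.start <= read.mate_start else -span
            rec.query_qualities = pysam.qualitystring_to_array("I" * read.length)
            fh.write(rec)


def write_truth_table(truth: TruthSet, path: str) -> None:
    """Truth variants as a TSV: contig, 1-based pos, cultivar=base pairs."""
    with open(path, "w") as fh:
        for contig, pos, genotypes in truth.variants:
            field = ";".join(f"{c}={b}" for c, b in sorted(genotypes.items()))
            fh.write(f"{contig}\t{pos + 1}\t{field}\n")


@dataclass
class SimulatedDataset:
    reference: Dict[str, str]
    cultivars: List[str]
    truth: TruthSet
    reads: Dict[str, List[AlignedRead]]  # cultivar -> sorted reads


def simulate_dataset(
    n_contigs: int = 10,
    length: int = 10_000,
    cultivars: Sequence[str] = ("Drysdale", "Excalibur", "Gladius", "RAC875"),
    n_snps: int = 200,
    coverage: float = 10.0,
    tstv: float = DEFAULT_TSTV,
    error_rate: float = 0.0,
    read_len: int = DEFAULT_READ_LENGTH,
    insert: int = DEFAULT_INSERT,
    gc: float = 0.45,
    seed: int = 0,
) -> SimulatedDataset:
    """One-call fixture: reference, planted truth and per-cultivar reads."""
    seed_sequence = np.random.SeedSequence(seed)
    ref_seed, plant_seed, *read_seeds = seed_sequence.generate_state(
        2 + len(cultivars) * n_contigs
    )
    reference = generate_reference(n_contigs, length, gc=gc, seed=int(ref_seed) & 0x7FFFFFFF)
    haplotypes, truth = plant_variants(
        reference, cultivars, n_snps, tstv=tstv, seed=int(plant_seed) & 0x7FFFFFFF,
        edge_margin=insert,
    )
    reads: Dict[str, List[AlignedRead]] = {}
    k = 0
    for cultivar in cultivars:
        cultivar_reads: List[AlignedRead] = []
        for contig in reference:
            cultivar_reads.extend(
                simulate_read_pairs(
                    haplotypes[cultivar][contig],
                    contig,
                    cultivar,
                    coverage=coverage,
                    read_len=read_len,
                    insert=insert,
                    error_rate=error_rate,
                    seed=int(read_seeds[k]) & 0x7FFFFFFF,
                )
            )
            k += 1
        contig_index = {name: i for i, name in enumerate(reference)}
        cultivar_reads.sort(
            key=lambda r: (contig_index[r.contig], r.start, r.read_id)
        )
        reads[cultivar] = cultivar_reads
    return SimulatedDataset(
        reference=reference,
        cultivars=list(cultivars),
        truth=truth,
        reads=reads,
    )
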