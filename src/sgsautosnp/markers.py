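"""Genotyping-assay design records from called SNPs plus the consensus.

Array assay design (GoldenGate/Infinium style) needs the SNP in its local
sequence context: 150 consensus bases on each side, with the SNP written as
``[X/Y]``.  Probes anneal within 60 bp of the SNP, so any ``N`` in that
window makes the assay undesignable and the record is discarded; an ``N``
further out (61-150 bp) is tolerated.  Assays whose flank is truncated below
60 bases by a contig edge cannot fit a probe either and are discarded.
"""

from __future__ import annotations

import csv
import os
from collections import Counter
from dataclasses import dataclass, replace
from typing import Dict, Iterable, List, Mapping, Sequence

from .consensus import ConsensusSequence
from .snp_caller import SnpCall

FLANK_LENGTH = 150
PROBE_WINDOW = 60

PASS = "pass"
DISCARDED_N = "discarded_N"
DISCARDED_EDGE = "discarded_edge"

GOLDENDB_COLUMNS = [
    "Locus_Name",
    "Sequence",
    "Target_Type",
    "Genome_Build_Version",
    "Chromosome",
    "Coordinate",
    "Species",
    "Source",
    "Source_Version",
]


@dataclass
class MarkerAssay:
    locus_name: str
    contig: str
    pos: int  # 0-based on the contig
    chrom: str
    chrom_pos: int
    left_flank: str
    snp_bracket: str  # "[X/Y]", alleles lexicographic
    right_flank: str
    status: str

    @property
    def sequence(self) -> str:
        return self.left_flank + self.snp_bracket + self.right_flank


@dataclass
class AssayMeta:
    """Run-level fields copied into every design row."""

    species: str
    library_name: str
    version: str
    chromosome: str

    def __post_init__(self) -> None:
        for name in ("species", "library_name", "version", "chromosome"):
            if not getattr(self, name):
                raise ValueError(f"assay meta field {name} must be non-empty")


def extract_flanks(
    consensus: ConsensusSequence,
    snp: SnpCall,
    locus_name: str = "",
    flank_length: int = FLANK_LENGTH,
) -> MarkerAssay:
    """Cut the +/-150-base context of ``snp`` out of the consensus.

    Flanks are truncated at contig edges; an assay whose flank falls below
    the probe window (60 bases) is marked ``discarded_edge``.
    """
    seq = consensus.sequence
    pos = snp.pos
    if not 0 <= pos < len(seq):
        raise ValueError(
            f"SNP position {pos} outside consensus {consensus.contig} "
            f"(length {len(seq)})"
        )
    left = seq[max(0, pos - flank_length):pos]
    right = seq[pos + 1:pos + 1 + flank_length]
    status = PASS
    if len(left) < PROBE_WINDOW or len(right) < PROBE_WINDOW:
        status = DISCARDED_EDGE
    return MarkerAssay(
        locus_name=locus_name,
        contig=snp.contig,
        pos=pos,
        chrom=snp.chrom,
        chrom_pos=snp.chrom_pos,
        left_flank=left,
        snp_bracket=f"[{snp.alleles[0]}/{snp.alleles[1]}]",
        right_flank=right,
        status=status,
    )


def screen_assay(assay: MarkerAssay, probe_window: int = PROBE_WINDOW) -> MarkerAssay:
    """Discard the assay if an ``N`` sits within the probe window.

    Only the ``probe_window`` flank bases nearest the SNP are screened; edge
    discards from extraction are left untouched.
    """
    if assay.status == DISCARDED_EDGE:
        return assay
    near_left = assay.left_flank[-probe_window:]
    near_right = assay.right_flank[:probe_window]
    if "N" in near_left or "N" in near_right:
        return replace(assay, status=DISCARDED_N)
    return replace(assay, status=PASS)


def design_assays(
    consensuses: Mapping[str, ConsensusSequence],
    snps: Sequence[SnpCall],
    chromosome: str,
) -> List[MarkerAssay]:
    """Extract and screen an assay for every SNP; names are UQ<chrom><serial>."""
    assays = []
    for serial, snp in enumerate(snps, 1):
        if snp.contig not in consensuses:
            raise ValueError(f"no consensus for contig {snp.contig!r}")
        assay = extract_flanks(
            consensuses[snp.contig], snp, locus_name=f"UQ{chromosome}{serial}"
        )
        assays.append(screen_assay(assay))
    return assays


def write_marker_files(
    assays: Sequence[MarkerAssay], meta: AssayMeta, outdir: str
) -> Dict[str, str]:
    """Write the design CSV and the screening statistics file.

    Returns {"csv": path, "stat": path}.  The CSV contains one row per
    *passing* assay; discards are only tallied in the stat file.
    """
    os.makedirs(outdir, exist_ok=True)
    csv_path = os.path.join(outdir, f"{meta.library_name}_GoldenDB.csv")
    stat_path = os.path.join(outdir, f"{meta.library_name}_marker.stat")

    with open(csv_path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(GOLDENDB_COLUMNS)
        for assay in assays:
            if assay.status != PASS:
                continue
            writer.writerow(
                [
                    assay.locus_name,
                    assay.sequence,
                    "SNP",
                    meta.version,
                    meta.chromosome,
                    assay.chrom_pos + 1,  # 1-based in output
                    meta.species,
                    "SGSautoSNP",
                    meta.version,
                ]
            )

    tally = Counter(a.status for a in assays)
    with open(stat_path, "w") as fh:
        fh.write(f"total\t{len(assays)}\n")
        fh.write(f"pass\t{tally.get(PASS, 0)}\n")
        fh.write(f"discarded_N\t{tally.get(DISCARDED_N, 0)}\n")
        fh.write(f"discarded_edge\t{tally.get(DISCARDED_EDGE, 0)}\n")
    return {"csv": csv_path, "stat": stat_path}
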