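"""Small nucleotide helpers shared across the pipeline.

Everything operates on upper-case single characters; reads are stored in
reference-forward orientation so no per-operation strand handling is needed
downstream of alignment ingestion.
"""

from __future__ import annotations

BASES = ("A", "C", "G", "T")

_COMPLEMENT = str.maketrans("ACGTNRYSWKMBDHV", "TGCANYRSWMKVHDB")

#: IUPAC degenerate code for each non-empty subset of {A,C,G,T}.
IUPAC = {
    frozenset("A"): "A",
    frozenset("C"): "C",
    frozenset("G"): "G",
    frozenset("T"): "T",
    frozenset("AG"): "R",
    frozenset("CT"): "Y",
    frozenset("CG"): "S",
    frozenset("AT"): "W",
    frozenset("GT"): "K",
    frozenset("AC"): "M",
    frozenset("CGT"): "B",
    frozenset("AGT"): "D",
    frozenset("ACT"): "H",
    frozenset("ACG"): "V",
    frozenset("ACGT"): "N",
}


def revcomp(seq: str) -> str:
    """Reverse complement of ``seq`` (IUPAC-aware)."""
    return seq.translate(_COMPLEMENT)[::-1]


def iupac_code(bases) -> str:
    """IUPAC symbol covering the given collection of bases."""
    key = frozenset(bases)
    if not key:
        raise ValueError("iupac_code requires at least one base")
    try:
        return IUPAC[key]
    except KeyError:
        raise ValueError(f"not a set of A/C/G/T bases: {sorted(key)}") from None


def is_transition(a: str, b: str) -> bool:
    """True iff a<->b is a purine<->purine or pyrimidine<->pyrimidine change."""
    pair = frozenset((a, b))
    return pair == frozenset("AG") or pair == frozenset("CT")
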