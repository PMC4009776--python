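"""Pairwise SNP filtering and the all-pairs cultivar SNP-count matrix.

Whole-panel calling keeps every inter-cultivar polymorphism; downstream
marker work usually needs the subset that separates two named parents.  A
SNP counts for a pair only when both cultivars are covered at the locus with
at least the calling redundancy and carry different bases.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Sequence

import numpy as np

from .snp_caller import SnpCall


@dataclass
class SnpMatrix:
    """Symmetric, zero-diagonal table of pairwise SNP counts."""

    cultivars: List[str]
    counts: np.ndarray

    def to_tsv(self) -> str:
        lines = ["\t".join(["cultivar"] + self.cultivars)]
        for i, name in enumerate(self.cultivars):
            lines.append(
                "\t".join([name] + [str(int(v)) for v in self.counts[i]])
            )
        return "\n".join(lines) + "\n"


def filter_pair(
    snps: Sequence[SnpCall],
    c1: str,
    c2: str,
    declared: Sequence[str] | None = None,
    min_redundancy: int = 2,
) -> List[SnpCall]:
    """SNPs polymorphic between cultivars ``c1`` and ``c2``.

    Both cultivars must be genotyped at the locus with >= ``min_redundancy``
    reads each and carry different bases; a locus where either lacks coverage
    is excluded.  Input order is preserved.
    """
    if c1 == c2:
        raise ValueError("filter_pair requires two distinct cultivars")
    if declared is not None:
        for c in (c1, c2):
            if c not in declared:
                raise ValueError(f"unknown cultivar {c!r}")
    kept = []
    for snp in snps:
        g1 = snp.genotypes.get(c1)
        g2 = snp.genotypes.get(c2)
        if g1 is None or g2 is None:
            continue
        if g1[1] < min_redundancy or g2[1] < min_redundancy:
            continue
        if g1[0] != g2[0]:
            kept.append(snp)
    return kept


def pairwise_matrix(
    snps: Sequence[SnpCall],
    cultivars: Sequence[str],
    min_redundancy: int = 2,
) -> SnpMatrix:
    """SNP counts between all cultivar pairs (the ``.matrix`` output)."""
    if len(cultivars) < 2:
        raise ValueError("pairwise_matrix needs >=2 declared cultivars")
    n = len(cultivars)
    counts = np.zeros((n, n), dtype=int)
    for i in range(n):
        for j in range(i + 1, n):
            k = len(
                filter_pair(snps, cultivars[i], cultivars[j], min_redundancy=min_redundancy)
            )
            counts[i, j] = counts[j, i] = k
    return SnpMatrix(cultivars=list(cultivars), counts=counts)


def write_matrix(matrix: SnpMatrix, path: str) -> None:
    with open(path, "w") as fh:
        fh.write(matrix.to_tsv())
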