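"""Result summaries: Ts/Tv proportions, per-chromosome totals, and wet-lab
validation arithmetic.

The validation summary mirrors how marker-validation panels are scored:
assays that fail PCR or Sanger sequencing are set aside as chemistry
failures, and the confirmation rate is computed over the *clean* assays only
— ``true SNP`` vs. the two error modes a homozygous-panel caller can show
(a heterozygous pattern from homoeologous amplification, or a monomorphic
locus).  A bundled wheat group-7 validation panel of 40 assays across the
A, B and D genomes serves as reference input.
"""

from __future__ import annotations

from collections import Counter, defaultdict
from dataclasses import dataclass
from importlib import resources
from typing import Dict, List, Sequence

from .snp_caller import TRANSITION, SnpCall

TRUE_SNP = "true_snp"
FAILED = "failed"
HETEROZYGOUS = "heterozygous"
MONOMORPHIC = "monomorphic"

_OUTCOME_ALIASES = {
    "true snp": TRUE_SNP,
    "true_snp": TRUE_SNP,
    "failed": FAILED,
    "heterozygous": HETEROZYGOUS,
    "monomorphic": MONOMORPHIC,
}

BUNDLED_VALIDATION_PANEL = "wheat_group7_validation.tsv"


@dataclass(frozen=True)
class ValidationRecord:
    locus_name: str
    snp_score: int
    outcome: str

    @property
    def genome(self) -> str:
        """Sub-genome letter (A/B/D) parsed from the UQ<chrom><serial> name."""
        for ch in self.locus_name:
            if ch in "ABD" and not self.locus_name.startswith(ch):
                return ch
        raise ValueError(f"cannot parse genome from {self.locus_name!r}")


@dataclass(frozen=True)
class ValidationSummary:
    n_total: int
    n_failed: int
    n_clean: int
    n_true: int
    n_heterozygous: int
    n_monomorphic: int
    pct_true_of_clean: int
    per_genome: Dict[str, int]


def parse_validation_table(lines) -> List[ValidationRecord]:
    """Parse a tab-delimited validation table (locus, score, outcome)."""
    records = []
    for lineno, line in enumerate(lines, 1):
        line = line.rstrip("\n")
        if not line or line.lower().startswith("locus_name"):
            continue
        parts = line.split("\t")
        if len(parts) < 3:
            raise ValueError(f"validation table line {lineno}: expected 3 columns")
        outcome = _OUTCOME_ALIASES.get(parts[2].strip().lower())
        if outcome is None:
            raise ValueError(
                f"validation table line {lineno}: unknown outcome {parts[2]!r}"
            )
        records.append(
            ValidationRecord(
                locus_name=parts[0], snp_score=int(parts[1]), outcome=outcome
            )
        )
    return records


def load_bundled_validation_panel() -> List[ValidationRecord]:
    text = (
        resources.files("sgsautosnp.data")
        .joinpath(BUNDLED_VALIDATION_PANEL)
        .read_text()
    )
    return parse_validation_table(text.splitlines())


def summarize_validation(records: Sequence[ValidationRecord]) -> ValidationSummary:
    """Score a validation panel; percentage is over clean assays, rounded."""
    if not records:
        raise ValueError("summarize_validation requires a non-empty panel")
    tally = Counter(r.outcome for r in records)
    per_genome: Dict[str, int] = defaultdict(int)
    for r in records:
        per_genome[r.genome] += 1
    n_total = len(records)
    n_failed = tally.get(FAILED, 0)
    n_clean = n_total - n_failed
    n_true = tally.get(TRUE_SNP, 0)
    pct = round(100 * n_true / n_clean) if n_clean else 0
    return ValidationSummary(
        n_total=n_total,
        n_failed=n_failed,
        n_clean=n_clean,
        n_true=n_true,
        n_heterozygous=tally.get(HETEROZYGOUS, 0),
        n_monomorphic=tally.get(MONOMORPHIC, 0),
        pct_true_of_clean=pct,
        per_genome=dict(per_genome),
    )


@dataclass(frozen=True)
class CallSummary:
    n_total: int
    per_chromosome: Dict[str, int]
    transitions: int
    transversions: int
    pct_transitions: float  # nan when no calls
    pct_transversions: float


def summarize_calls(snps: Sequence[SnpCall]) -> CallSummary:
    """Per-chromosome totals and transition/transversion proportions."""
    per_chromosome: Dict[str, int] = defaultdict(int)
    n_ts = 0
    for snp in snps:
        per_chromosome[snp.chrom] += 1
        if snp.substitution_class == TRANSITION:
            n_ts += 1
    n = len(snps)
    n_tv = n - n_ts
    if n:
        pct_ts = 100.0 * n_ts / n
        pct_tv = 100.0 * n_tv / n
    else:
        pct_ts = pct_tv = float("nan")
    return CallSummary(
        n_total=n,
        per_chromosome=dict(per_chromosome),
        transitions=n_ts,
        transversions=n_tv,
        pct_transitions=pct_ts,
        pct_transversions=pct_tv,
    )


def render_validation_summary(summary: ValidationSummary) -> str:
    per_genome = "  ".join(
        f"{g}:{summary.per_genome[g]}" for g in sorted(summary.per_genome)
    )
    return (
        f"assays\t{summary.n_total}\n"
        f"per_genome\t{per_genome}\n"
        f"failed\t{summary.n_failed}\n"
        f"clean\t{summary.n_clean}\n"
        f"true_snp\t{summary.n_true}\n"
        f"heterozygous\t{summary.n_heterozygous}\n"
        f"monomorphic\t{summary.n_monomorphic}\n"
        f"pct_true_of_clean\t{summary.pct_true_of_clean}\n"
    )
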