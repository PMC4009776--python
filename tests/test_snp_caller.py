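"""Core caller: pileup construction, the redundancy/homogeneity rules, scan."""

import itertools
import random
from collections import Counter

import pytest
from hypothesis import given, settings, strategies as st

from sgsautosnp.simulate import simulate_read_pairs
from sgsautosnp.snp_caller import (
    HETEROZYGOUS,
    INSUFFICIENT_REDUNDANCY,
    MONOMORPHIC,
    MULTIALLELIC,
    CallerParams,
    NoCall,
    PileupColumn,
    PlacementTable,
    SnpCall,
    build_pileup,
    call_snp,
    classify_substitution,
    scan,
    total_stats,
)

from conftest import make_read
from oracles import naive_call, naive_snp_positions, tally_positions


def column(counts, contig="c1", pos=0):
    return PileupColumn(contig=contig, pos=pos, counts=counts)


class TestBuildPileup:
    def test_single_read_direct_pileup(self):
        cols = list(build_pileup([make_read("ACG", cultivar="D")], "c1"))
        assert [(c.pos, c.counts) for c in cols] == [
            (0, {"D": {"A": 1}}),
            (1, {"D": {"C": 1}}),
            (2, {"D": {"G": 1}}),
        ]

    def test_overlapping_reads_add(self):
        reads = [
            make_read("AAAAAA", start=0, cultivar="D"),
            make_read("AAAA", start=2, cultivar="D"),
        ]
        cols = {c.pos: c for c in build_pileup(reads, "c1")}
        assert cols[5].counts == {"D": {"A": 2}}

    def test_n_bases_excluded(self):
        cols = list(build_pileup([make_read("ANG", cultivar="D")], "c1"))
        assert [c.pos for c in cols] == [0, 2]

    def test_overhanging_read_rejected(self):
        with pytest.raises(ValueError, match="overhang"):
            list(build_pileup([make_read("ACGT", start=8)], "c1", contig_length=10))

    def test_matches_brute_force_tally(self):
        rng = random.Random(21)
        haplotype = "".join(rng.choice("ACGT") for _ in range(200))
        reads = []
        for i in range(50):
            start = rng.randrange(0, 180)
            reads.append(
                make_read(
                    haplotype[start:start + 20],
                    start=start,
                    cultivar=rng.choice("AB"),
                    read_id=f"r{i}",
                )
            )
        expected = tally_positions(reads)
        got = {c.pos: c.counts for c in build_pileup(reads, "c1")}
        assert set(got) == set(expected)
        for pos in got:
            assert {c: dict(k) for c, k in expected[pos].items()} == got[pos]


class TestCallSnp:
    def test_two_cultivars_two_reads_each_is_called(self):
        result = call_snp(column({"A": {"G": 2}, "B": {"T": 3}}))
        assert isinstance(result, SnpCall)
        assert result.alleles == ("G", "T")
        assert result.snp_score == 2
        assert result.substitution_class == "transversion"
        assert result.genotypes == {"A": ("G", 2), "B": ("T", 3)}

    @pytest.mark.parametrize(
        "counts,reason",
        [
            ({"A": {"G": 2}, "B": {"T": 1}}, INSUFFICIENT_REDUNDANCY),
            ({"A": {"G": 2, "T": 1}, "B": {"T": 3}}, HETEROZYGOUS),
            ({"A": {"G": 5}, "B": {"G": 4}}, MONOMORPHIC),
            ({"A": {"G": 2}, "B": {"T": 2}, "C": {"A": 1}}, MULTIALLELIC),
        ],
    )
    def test_rejection_reasons(self, counts, reason):
        result = call_snp(column(counts))
        assert isinstance(result, NoCall)
        assert result.reason == reason

    def test_depth_one_cultivar_in_genotypes_but_not_redundancy(self):
        # third cultivar's single concordant read is reported but contributes
        # no redundancy evidence
        result = call_snp(column({"A": {"G": 2}, "B": {"T": 2}, "C": {"G": 1}}))
        assert isinstance(result, SnpCall)
        assert result.genotypes["C"] == ("G", 1)
        assert result.snp_score == 2  # T side: 2; G side: 2+1=3

    def test_score_is_min_allele_total_across_cultivars(self):
        result = call_snp(
            column({"A": {"G": 4}, "B": {"G": 3}, "C": {"T": 5}, "D": {"T": 2}})
        )
        assert result.snp_score == min(4 + 3, 5 + 2)

    def test_max_depth_cap(self):
        params = CallerParams(max_depth=5)
        result = call_snp(column({"A": {"G": 4}, "B": {"T": 4}}), params)
        assert isinstance(result, NoCall)

    def test_exhaustive_depth_sweep_matches_rule_table(self):
        """All 2-cultivar base configurations with depth 0-3 agree with the naive rules."""
        bases = "ACGT"
        per_cultivar = []
        for depth in range(4):
            for combo in itertools.combinations_with_replacement(bases, depth):
                per_cultivar.append(dict(Counter(combo)))
        checked = 0
        for counts_a in per_cultivar:
            for counts_b in per_cultivar:
                counts = {}
                if counts_a:
                    counts["A"] = dict(counts_a)
                if counts_b:
                    counts["B"] = dict(counts_b)
                if not counts:
                    continue
                expected = naive_call(counts)
                got = call_snp(column(counts))
                if isinstance(expected, tuple):
                    assert isinstance(got, SnpCall)
                    assert got.alleles == expected[0]
                    assert got.snp_score == expected[1]
                else:
                    assert isinstance(got, NoCall)
                    assert got.reason == expected
                checked += 1
        assert checked == 35 * 35 - 1


@pytest.mark.parametrize(
    "a,b,expected",
    [
        ("A", "G", "transition"),
        ("G", "A", "transition"),
        ("C", "T", "transition"),
        ("A", "C", "transversion"),
        ("A", "T", "transversion"),
        ("G", "T", "transversion"),
        ("C", "G", "transversion"),
    ],
)
def test_classify_substitution(a, b, expected):
    assert classify_substitution(a, b) == expected


def test_classify_substitution_rejects_identity_and_nonbase():
    with pytest.raises(ValueError):
        classify_substitution("A", "A")
    with pytest.raises(ValueError):
        classify_substitution("A", "N")


# strategy: random per-cultivar base counts for one column
_counts_strategy = st.dictionaries(
    st.sampled_from(["A", "B", "C", "D"]),
    st.dictionaries(st.sampled_from("ACGT"), st.integers(1, 5), min_size=1, max_size=3),
    min_size=1,
    max_size=4,
)


@settings(max_examples=200, deadline=None, derandomize=True)
@given(counts=_counts_strategy)
def test_minimum_coverage_and_oracle_agreement(counts):
    """Any call has total depth >=4 under defaults, and matches the naive rules."""
    got = call_snp(column(counts))
    expected = naive_call(counts)
    if isinstance(got, SnpCall):
        assert sum(c for k in counts.values() for c in k.values()) >= 4
        assert (got.alleles, got.snp_score) == expected
    else:
        assert got.reason == expected


@settings(max_examples=100, deadline=None, derandomize=True)
@given(counts=_counts_strategy, cultivar=st.sampled_from(["A", "B", "C", "D"]))
def test_mismap_injection_converts_call_to_heterozygous(counts, cultivar):
    """One conflicting read inside any cultivar of a called locus forces a no-call."""
    got = call_snp(column(counts))
    if not isinstance(got, SnpCall) or cultivar not in counts:
        return
    conflicted = {c: dict(k) for c, k in counts.items()}
    present = next(iter(conflicted[cultivar]))
    other = "A" if present != "A" else "G"
    conflicted[cultivar][other] = conflicted[cultivar].get(other, 0) + 1
    result = call_snp(column(conflicted))
    assert isinstance(result, NoCall)
    assert result.reason == HETEROZYGOUS


class TestScan:
    def test_single_planted_snp_found(self):
        reference = {"c1": "A" * 40}
        reads = []
        for cultivar, base in [("D", "G"), ("E", "T")]:
            for i in range(4):
                reads.append(
                    make_read(
                        "AAAA" + base + "AAAA",
                        start=6,
                        cultivar=cultivar,
                        read_id=f"{cultivar}{i}",
                    )
                )
        snps, stats = scan(reads, reference)
        assert [(s.contig, s.pos, s.alleles) for s in snps] == [("c1", 10, ("G", "T"))]
        assert stats[0].snp_count == 1

    def test_worker_count_does_not_change_output(self, small_dataset_merged, small_dataset):
        ds = small_dataset
        snps1, stats1 = scan(list(small_dataset_merged), ds.reference, workers=1)
        snps4, stats4 = scan(list(small_dataset_merged), ds.reference, workers=4)
        assert snps1 == snps4
        assert stats1 == stats4

    def test_reference_base_never_consulted(self, small_dataset_merged, small_dataset):
        """Recoding the reference at called positions changes no call."""
        ds = small_dataset
        snps, _ = scan(list(small_dataset_merged), ds.reference)
        assert snps
        recoded = {name: list(seq) for name, seq in ds.reference.items()}
        for snp in snps:
            current = recoded[snp.contig][snp.pos]
            recoded[snp.contig][snp.pos] = {"A": "C", "C": "A", "G": "T", "T": "G"}[current]
        recoded = {name: "".join(seq) for name, seq in recoded.items()}
        snps_recoded, _ = scan(list(small_dataset_merged), recoded)
        assert snps == snps_recoded

    def test_matches_naive_oracle_on_simulated_reads(self, small_dataset_merged):
        reads = list(small_dataset_merged)
        expected = {}
        for contig in {r.contig for r in reads}:
            contig_reads = [r for r in reads if r.contig == contig]
            for pos, call in naive_snp_positions(contig_reads).items():
                expected[(contig, pos)] = call
        reference = {c: "A" * 3000 for c in {r.contig for r in reads}}
        snps, _ = scan(reads, reference)
        got = {(s.contig, s.pos): (s.alleles, s.snp_score) for s in snps}
        assert got == expected

    def test_unknown_contig_rejected(self):
        with pytest.raises(ValueError, match="absent"):
            scan([make_read("ACGT", contig="nope")], {"c1": "A" * 10})

    def test_placement_table_fills_chromosome_coordinates(self, tmp_path):
        table = tmp_path / "placement.tsv"
        table.write_text("c1\t7A\t1000\t+\n")
        placement = PlacementTable.from_tsv(str(table))
        reference = {"c1": "A" * 40}
        reads = [
            make_read("G" * 10, start=5, cultivar="D", read_id="d1"),
            make_read("G" * 10, start=5, cultivar="D", read_id="d2"),
            make_read("T" * 10, start=5, cultivar="E", read_id="e1"),
            make_read("T" * 10, start=5, cultivar="E", read_id="e2"),
        ]
        snps, _ = scan(reads, reference, placement=placement)
        assert all(s.chrom == "7A" and s.chrom_pos == 1000 + s.pos for s in snps)

    def test_total_stats_sums_columns(self, small_dataset_merged, small_dataset):
        _, stats = scan(list(small_dataset_merged), small_dataset.reference)
        total = total_stats(stats)
        assert total.snp_count == sum(s.snp_count for s in stats)
        assert total.snp_count == total.transitions + total.transversions
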