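# Methods

## Model and assumptions

The caller targets panels of **homozygous individuals** (inbred crop
cultivars) sequenced with short paired reads and aligned to a shared
reference. Three assumptions shape every rule:

* Each cultivar carries one base per locus. Intra-cultivar disagreement is
  therefore evidence of error — in a polyploid, most often a read mismapped
  from a homoeologous sub-genome copy — not of heterozygosity, and any
  disagreeing column is rejected outright ("heterozygous" no-call).
* Base-quality scores are not trusted; confidence comes from **redundancy**:
  an allele counts only when ≥ `min_redundancy` reads (default 2) support it
  within a cultivar, and ≥ `min_cultivars` cultivars (default 2) reach that
  support. The minimum callable coverage is thus 4 reads.
* The reference is a scaffold for positioning only. Alleles are compared
  **between reads**, never against the reference base, so the caller also
  works with a reference from a divergent genotype or species. The VCF
  writer is the one place the reference base reappears (as REF), and a locus
  where REF matches neither allele simply lists both in ALT.

The alignment model is ungapped: a read is one match block, and records with
insertions/deletions in their CIGAR are skipped and counted. Only proper
pairs are admitted. Multiallelic columns (>2 bases across cultivars) are
rejected since every downstream format is biallelic; a depth-1 cultivar
participates in the homogeneity check and the genotype output but never in
redundancy, and a depth-1 third allele makes a column multiallelic
(conservative by design). The SNP score is the minimum over the two alleles
of total supporting reads summed across cultivars — consistent with
observed scores well above any single cultivar's depth. Allele pairs are
ordered lexicographically (A<C<G<T) everywhere.

## Parameters

| parameter | default | units | role |
|---|---|---|---|
| `min_redundancy` | 2 | reads | per-cultivar allele support threshold |
| `min_cultivars` | 2 | cultivars | cultivars that must reach support |
| `max_depth` | unlimited | reads | optional cap for repeat-rich loci |
| flank length | 150 | bases | assay context each side of the SNP |
| probe window | 60 | bases | N-free zone required beside the SNP |

## Consensus rules

Per position, pooled over cultivars: no coverage → `N`; one read → its
base; several reads unanimous → that base; a lone dissenter against a
majority → dissenter dropped; otherwise the IUPAC code over all bases with
count ≥ 2 (singletons dropped as errors; if one base remains, it is
emitted). Degenerate corner case: several reads, all singletons (e.g. one A
and one G) — dropping every singleton would leave nothing, so the IUPAC
code over all observed bases is emitted. Consequently an IUPAC symbol in
the output implies either ≥2 bases at count ≥2 or an all-singleton column.

## Assay design

150 consensus bases are cut on each side of the SNP, written as
`left[X/Y]right`. Probes anneal within 60 bp of the SNP, so an `N`
anywhere in the 60 flank bases nearest the SNP discards the assay
(`discarded_N`); an `N` at distance 61–150 is tolerated. A flank truncated
below 60 bases by a contig edge cannot fit a probe and is discarded
(`discarded_edge`); truncation between 60 and 150 bases is kept. Locus
names are `UQ<chromosome><serial>`.

## Synthetic data generator

The simulator emulates the study conditions: several homozygous cultivars
(default four, mirroring a typical elite-cultivar panel), biallelic planted
SNPs with a controllable transition fraction (default 0.68, the excess
observed in real crop SNP sets from methyl-C deamination), paired reads of
length 100 with outer insert 300, uniform substitution errors, and a
homoeolog mismapping injector that re-sources a fraction of pairs from a
2%-diverged copy of the contig while keeping their coordinates.

Deliberate design choices, fixed once:

* **Stratified pair placement** — one pair jittered uniformly inside each
  equal-width start window — so nominal coverage guarantees a minimum depth
  away from contig edges. This makes "error-free depth 10 recovers every
  planted SNP" a deterministic property rather than a coin flip on coverage
  gaps, which is the property the caller is specified to have when its
  depth precondition holds.
* **Edge margin**: planted sites stay one insert length (300 bp) from
  contig ends, where paired coverage necessarily decays.
* Reads are emitted pre-aligned at generative coordinates; mapping is an
  external step in the real pipeline. A SAM writer allows real mappers to
  be slotted in.

What the simulator does **not** model: indels, quality-score structure,
non-uniform error profiles, genuine repeat families, or realistic wheat
homoeolog structure beyond a fixed-rate diverged copy. Passing tests
therefore demonstrate the algorithm's rule correctness and its rejection of
the modelled mismapping signature, not performance on real repeat-rich
libraries.

## Numerical and formatting choices

Internal coordinates are 0-based half-open; writers convert to 1-based at
serialisation, nowhere else. Genotype fields are cultivar-sorted and every
writer is deterministic (byte-identical output for identical input).
Parallel scans distribute whole contigs over a thread pool and concatenate
results in reference order, so output is independent of worker count and
scheduling. Validation-panel confirmation percentage is rounded to the
nearest integer over clean (non-failed) assays.

Problem sizes used in the test and acceptance suites — 10 contigs × 10 kb,
4 cultivars, 200 planted SNPs at 10× for parameter recovery; 20 random
10 kb instances for oracle equivalence — were chosen as the smallest scales
at which every rule (redundancy, homogeneity, multiallelic rejection,
edge/N discards) is exercised many times over.

## Known limitations

* Substitutions only; indel polymorphism is invisible.
* Strict homogeneity: a single discordant read vetoes a locus, so
  sensitivity drops in high-depth noisy data; there is no tolerated
  discordance fraction.
* Heterozygous (outbreeding) material violates the core assumption and
  will be systematically rejected rather than genotyped.
* The `.snp`, `.stat`, `.matrix` and design-file layouts are declared
  dialects of this implementation, frozen by the round-trip and golden
  tests in the suite.
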