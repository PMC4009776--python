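# sgsautosnp

Redundancy-based discovery of single-nucleotide polymorphisms **between
homozygous cultivars** from paired-read alignments, built for large,
repeat-rich and polyploid crop genomes (the motivating case is hexaploid
bread wheat, with its A, B and D sub-genomes) where conventional
diploid-heterozygote callers perform poorly.

## The method

Reads from each cultivar are aligned to a shared reference, but the
reference allele itself is **never** consulted: the reference only positions
the reads, and SNPs are called between the piled-up reads of different
cultivars. Sequencing base-quality scores are ignored as unreliable; two
structural rules take their place at every locus:

1. **Redundancy.** A SNP allele must be supported by at least
   *r* = 2 reads within a cultivar, and at least *m* = 2 cultivars must
   reach that support — so the minimum callable locus coverage is 4 reads.
   The SNP score is min(∑ reads supporting allele 1, ∑ reads supporting
   allele 2) over all cultivars.
2. **Homogeneity.** Each cultivar is homozygous, so all of its reads at a
   locus must carry one base. Any intra-cultivar disagreement marks the
   column as heterozygous-looking and rejects it — in a polyploid this is
   the signature of reads mismapped from a homoeologous chromosome copy,
   the main confounder the method is designed to filter.

Only mapped **proper pairs** are used (a lone short read can sit anywhere in
a repeat-rich genome; a pair at the expected insert is trustworthy), and
only biallelic columns are called. Around the caller sit: pairwise
filtering with an all-pairs SNP-count matrix; an IUPAC consensus builder
(N → no coverage, degenerate codes where ≥2 bases each have ≥2 reads);
genotyping-array assay design (150-base flanks, `[A/C]` bracket, discard on
any N within 60 bp of the SNP); writers for `.snp`/`.stat`/GFF3/VCF/
Flapjack; and a paired-read simulator with planted truth used throughout
the test suite.

## Worked example

```sh
sgs simulate --contigs 3 --length 5000 --cultivars 4 --snps 40 \
    --coverage 10 --seed 7 -o demo
sgs call --ref demo/reference.fa --manifest demo/manifest.tsv --out demo/run
head -2 demo/run.snp
```

prints (tab-separated: scaffold, scaffold position, chromosome position,
SNP score, genotypes, allele):

```
contig_1  593   593   21  cultivar1:A=10;cultivar2:A=11;cultivar3:G=11;cultivar4:G=11  A/G
contig_1  1091  1091  20  cultivar1:T=11;cultivar2:G=10;cultivar3:G=11;cultivar4:T=9   G/T
```

The first row is an A/G SNP at position 593 (1-based) of `contig_1`:
cultivars 1-2 carry A (10 and 11 reads), cultivars 3-4 carry G, and the
score 21 is the weaker allele's total support (10+11). Continuing,

```sh
sgs consensus --ref demo/reference.fa -o demo/consensus.fa demo/cultivar1.sam
sgs markers --consensus demo/consensus.fa --snp demo/run.snp \
    --species wheat --library UQv1 --chrom 7A -o demo/markers
sgs filter --pair cultivar1,cultivar2 demo/run.snp
sgs report
```

designs array assays (`UQv1_GoldenDB.csv`, names `UQ7A1`, `UQ7A2`, …),
selects the 20 of 40 SNPs that separate cultivars 1 and 2, and summarises
the bundled wheat group-7 validation panel:

```
assays            40
per_genome        A:18  B:9  D:13
failed            12
clean             28
true_snp          26
pct_true_of_clean 93
```

i.e. of 28 assays with clean Sanger data, 26 (93%) confirmed the predicted
genotype.

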