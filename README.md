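# introscan

Introgression inference from multi-species genotype data.

When DNA crosses a species boundary through hybridization and backcrossing,
it leaves several complementary signatures: an excess of shared derived
alleles between the recipient and the donor (ABBA–BABA imbalance), local
peaks of the window statistic *f*<sub>d</sub>, runs of donor-diagnostic
alleles (introgression haplotypes) in recipient genomes, and gene trees in
which the recipient sits on the donor's branch. `introscan` implements this
whole inference chain as a tested, reusable library with a thin CLI, aimed
at population geneticists studying historical gene flow between diverged
lineages (e.g. different genera of birds) from modest-coverage whole-genome
genotype calls.

## What it computes

For the taxon arrangement ((P1, P2), P3, Outgroup) with per-site derived
allele frequencies *p₁…p₄*, the site-pattern weights are

    C_ABBA = (1 − p₁) p₂ p₃ (1 − p₄)
    C_BABA = p₁ (1 − p₂) p₃ (1 − p₄)

and

* **D** = Σ(C_ABBA − C_BABA) / Σ(C_ABBA + C_BABA), with a delete-one block
  jackknife (contiguous blocks of equal informative-site counts, 200 by
  default) for the standard error and Z-score;
* ***f*<sub>d</sub>** = Σ(C_ABBA − C_BABA) / Σ(C_ABBA(P_D) − C_BABA(P_D)),
  where P_D is whichever of P2/P3 has the higher derived frequency at each
  site — a window-stable estimate of the locally introgressed fraction,
  scanned in 10-kb tiles with empirical-percentile outlier calls;
* **f4-ratio** α̂ = f4(P1,P2;P3a,O) / f4(P1,P3b;P3a,O), the genome-wide
  admixture proportion, with P3's called alleles split into random halves
  per site;
* **haplotype painting**: sites fixed (or nearly fixed, frequency ≥ τ) for
  different alleles between two lineages are used to paint recipient
  genotypes by donor-allele dosage and call maximal donor-carrying runs as
  haplotype blocks, including the shared core across recipient species;
* **gene-tree displacement**: the taxa that fall inside a donor clade at a
  given locus, recovered set-theoretically from rooted gene/species trees;
* **divergence dating**: relative node depths scaled by externally
  estimated crown ages into (min, mean, max) age ranges;
* **coding analysis**: exon splicing, translation, and residues private to
  a focal species set;
* **serial-introgression reasoning**: event counts under independent /
  hub / chain scenarios and a Monte-Carlo tract-decay model (with closed
  form) that motivates ranking recipients by surviving block length.

A synthetic-data module generates multi-species diploid genotypes along a
species tree (Beta root frequencies, truncated-Gaussian drift, binomial
sampling) with planted introgression tracts — optionally incompletely fixed,
with configured heterozygous carriers — plus gene trees with recipients
grafted into donor clades, so every stage is testable end to end against a
known truth set.

## Worked example

Simulate one 10-kb tract transferred from P3 into P2 on a 1-Mb chromosome
(20,000 SNPs, 4 diploids per species), then test for gene flow and scan for
the tract:

```python
import introscan as isc

tree = "(((P1:0.4,P2:0.4):0.4,P3:0.8):0.6,OUT:1.4);"
cfg = isc.SimConfig(
    species_tree=tree, n_individuals=4, chrom_length=1_000_000,
    n_sites=20_000, seed=1,
    events=[isc.IntrogressionEvent("P3", "P2", (500_001, 510_000), rho=0.9)],
)
geno, pops, truth = isc.simulate_genotypes(cfg)

st = isc.genome_stat(geno, pops, "P1", "P2", "P3", "OUT", seed=1)
print(f"D = {st.D:.4f} +/- {st.se:.4f} (Z = {st.Z:.2f});  "
      f"f4-ratio = {st.f4_ratio:.4f} +/- {st.f4_se:.4f}")

wins = isc.windowed_fd(geno, pops, "P1", "P2", "P3", "OUT",
                       chrom_sizes={"chr1": 1_000_000})
out = isc.call_outliers(wins, q=0.999, gene_interval=("chr1", 500_000, 510_000))
print(out[out["flagged"]][["chrom", "start", "end", "n_snps", "fd",
                           "within_proximity"]].to_string(index=False))
```

which prints:

```
D = 0.0090 +/- 0.0089 (Z = 1.02);  f4-ratio = 0.0210 +/- 0.0185
chrom  start    end  n_snps      fd  within_proximity
 chr1 500000 510000     205 0.50181              True
```

Read: genome-wide gene flow is indistinguishable from zero (the tract is
only 1% of the chromosome; D and α̂ sit within about one standard error of
0), yet the windowed scan flags exactly the tract-containing window as the
99.9th-percentile outlier, with *f*<sub>d</sub> ≈ 0.5 matching the planted
per-site retention and incomplete fixation, and annotates it as within
10 kb of the queried gene interval. This is the characteristic fingerprint
of a localized adaptive introgression event against a quiet genomic
background.

The same operations are available from the shell:

```
introscan simulate --config sim.yaml --seed 1
introscan dstat --vcf sim.vcf --popmap popmap.tsv \
    --p1 P1 --p2 P2 --p3 P3 --outgroup OUT
introscan scan --vcf sim.vcf --popmap popmap.tsv \
    --p1 P1 --p2 P2 --p3 P3 --outgroup OUT --gene chr1:500001-510000
introscan localize --vcf sim.vcf --popmap popmap.tsv \
    --group-a P3 --group-b P1 --tau 0.9 --recipients P2
```

plus `discord`, `dates`, `decay`, `order`, and `protein` subcommands.

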