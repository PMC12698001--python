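# Methods

This note documents the models behind `introscan`, the parameter defaults
and why they were chosen, and what the synthetic-data experiments do and do
not demonstrate.

## Site-pattern statistics

All four-taxon statistics are frequency-weighted (population-sample)
versions for the arrangement ((P1, P2), P3, Outgroup). Per site, with
derived-allele frequencies *p₁…p₄*:

- `C_ABBA = (1 − p₁) p₂ p₃ (1 − p₄)`, `C_BABA = p₁ (1 − p₂) p₃ (1 − p₄)`.
- **D** = Σ(C_ABBA − C_BABA) / Σ(C_ABBA + C_BABA). Symmetric drift makes
  the numerator mean-zero without gene flow; P2–P3 gene flow drives it
  positive. Swapping P1 and P2 negates D exactly.
- ***f*<sub>d</sub>** divides the same numerator by its value when the
  "donor-like" population P_D — whichever of P2/P3 has the higher derived
  frequency at that site — occupies both the P2 and P3 positions. The
  ratio estimates the fraction of the window that is introgressed; it is
  reported as 0 when the ABBA excess is non-positive and NA when the
  denominator vanishes with a positive numerator or the window has fewer
  than `min_snps` informative sites.
- **f4-ratio**: α̂ = f4(P1,P2;P3a,O) / f4(P1,P3b;P3a,O), where
  f4(A,B;C,D) = Σ (p_A − p_B)(p_C − p_D) and P3a/P3b are disjoint random
  halves of P3's called alleles, re-drawn per site (hypergeometric split,
  seeded). The split keeps the sampling noise of the numerator's and
  denominator's shared P3a factor independent of the denominator's P3b
  factor, which is what makes the ratio consistent for the admixture
  proportion. Sites need ≥ 2 called P3 alleles.

**Polarization.** The derived allele is the outgroup's minor allele, ties
broken toward ALT. Sites where any of the four groups has no called allele
are excluded and counted. The choice of polarization convention is the
standard one for these statistics; the statistics are insensitive to it in
expectation but individual site weights differ between conventions.

**Block jackknife.** Uncertainty comes from a delete-one jackknife over
contiguous blocks holding equal numbers of informative sites (200 blocks by
default). Each block spans all sites between its first informative site and
the next block's, so sites carrying numerator signal but a zero denominator
term still contribute to the leave-one-out sums — necessary for the
f4-ratio, where the two can differ. SE = √((n−1)/n · Σ(θ₍ᵢ₎ − θ̄)²),
Z = θ/SE; zero jackknife variance flags Z as undefined (NaN) rather than
infinite.

## Genome scan and haplotype localization

Windows tile each chromosome from coordinate 0 in non-overlapping 10-kb
steps (size configurable; the window statistic, not the anchoring, is the
scientific content, so the simplest deterministic tiling is used).
`min_snps` defaults to 10 to suppress noise-dominated ratios in sparse
windows. Outliers are windows at or above the empirical q-quantile
(linear-interpolation estimator, ties flagged inclusively, q = 0.999 by
default); an optional gene interval expanded by 10 kb per side annotates
flagged windows as "within proximity".

Diagnostic sites are SNPs where lineage A carries its majority allele at
frequency ≥ τ_A, lineage B carries the other allele at frequency ≥ τ_B
(τ = 0.9 by default; τ = 1.0 means strictly fixed), and each group's
fraction of missing genotypes is within its cap. Recipients under test are
excluded from both filter groups by the caller. Painting records each
recipient's dosage of the donor-diagnostic allele (2/1/0/missing);
species-level states are the majority across individuals with missing
excluded and ties resolved to heterozygous. Blocks are maximal runs of
diagnostic sites carrying ≥ 1 donor allele; up to `gap_tolerance`
consecutive donor-free sites may be bridged (default 0 — the delineation
rule is explicit rather than visual), and missing sites neither extend nor
break a run. The shared core of several species' blocks is their plain
coordinate intersection.

## Trees

Trees are rooted `dendropy` objects; rooting is always on a user-named
outgroup (midpoint of its edge). Neighbor joining (plumbing for building
input trees from distances, not a contribution) delegates to scikit-bio
with negative branch lengths clamped to zero.

**Displacement.** Given a donor clade C (monophyletic in the species tree),
the displaced set X is the leaf set of the smallest gene-tree clade
containing C, minus C. Concordant gene trees give X = ∅. This set-theoretic
rule is deterministic and support-blind; it detects taxa grafted *inside*
the donor clade, which is how the gene-tree simulator plants displacement
(uniformly chosen edge within the donor subtree). A recipient attached as
sister to the entire donor clade is not separable from a deeper concordant
arrangement by this rule and is out of scope. Detection needs |C| ≥ 2 to be
informative.

**Dating.** The relative depth of a node is its mean path length to
descendant tips divided by the tree-wide mean root-to-tip length (root = 1);
multiplying by each externally estimated crown age gives an age per
calibration source, reported as (min, mean, max). A preorder repair clamps
each child's depth to its parent's so ages are monotone along every path.
This mean-path transform is a simple, monotone, declared substitute for
model-based rate smoothing; it reproduces clock-like trees exactly and
scales linearly in the crown age, but on strongly non-clock trees it is a
first-order approximation only.

## Synthetic data

The generator produces the statistical structure the analyses consume
without a coalescent model:

- site positions uniform without replacement on [1, L];
- per-site root frequency ~ Beta(0.8, 0.8) (mildly U-shaped, as expected
  for standing variation surviving to be sampled across genera);
- frequencies evolve along the species tree by Gaussian increments with
  variance `drift_scale × branch length`, clamped to [0, 1];
- diploid genotypes sampled binomially from tip frequencies; optional
  uniform missingness;
- introgression = frequency replacement: within a planted tract each site
  independently (probability ρ) takes the donor's tip frequency in the
  recipient. The `polymorphic` fixation mode instead assigns configured
  donor-haplotype copy numbers (2/1/0) to named carrier individuals,
  emulating introgression that has not reached fixation;
- gene trees are species-tree copies with lognormal branch jitter;
  displaced loci have recipients pruned and re-grafted inside the donor
  clade.

Defaults — `drift_scale = 0.1` with inter-group branches of order 1, four
diploids per species — make near-fixed differences between long-separated
groups common, which is the regime fixed-difference introgression analyses
(inter-generic comparisons) operate in; the fraction of near-fixed
inter-group differences grows monotonically with `drift_scale`. The
`round_tip_freqs` switch rounds tip frequencies to 0/1 for the noiseless,
fully sorted condition used by the exact-localization checks. Everything is
driven by one seeded generator, so equal seeds give bitwise-identical
output including VCF text.

What this generator does **not** emulate: linkage disequilibrium and
coalescent gene-tree variance within loci, recombination-structured tract
boundaries, sequencing error and depth-dependent genotype quality, sites
ascertained through variant-calling filters, and selection. Passing tests
therefore demonstrate correctness of the statistics and recovery machinery
under the assumed frequency model, not robustness to the error structure of
real resequencing data. The interface is backend-shaped so a coalescent
simulator (e.g. msprime) could be substituted where LD realism matters.

## Serial introgression and tract decay

Scenario bookkeeping counts introgression pulses per recipient: independent
(all 1), hub (1 then 2s), chain (1, 2, 3, …; totals k(k+1)/2). The decay
model: each pulse exposes the surviving tract to crossover breakpoints
accumulating as a homogeneous Poisson process with intensity r·t per unit
length; under strong selection the tract containing the focal donor site
survives as the interval between the nearest flanking breakpoints (unlinked
donor DNA is deliberately ignored). A one-sided flank of available length f
has expected surviving length (1 − e^(−rtf))/(rt), the analytic oracle for
the Monte-Carlo simulator; chained rounds superpose (two rounds of t equal
one round of 2t in distribution). Units are abstract — only r·t·length
products matter.

`infer_transfer_order` ranks recipients by surviving block length, longest
first, and is labeled a heuristic: with one realized block per recipient
the *full* ordering of three recipients is correct in only ~40% of
realizations at practical decay rates (tract-length variance is
exponential-scale), while the first-order recipient tops the ranking in a
clear majority and the correct ordering is the modal permutation — which is
exactly how the validation suite states the property.

## Numerical conventions and edge cases

- Coordinates are 1-based inclusive internally (VCF); BED output is 0-based
  half-open; windows are 0-based half-open.
- Phasing ignored (`0|1` ≡ `0/1`); multiallelic and non-SNP records are
  skipped with a logged count, not split.
- Ratio denominators below 1e−12 in magnitude yield NaN ("undefined
  statistic") rather than an exception; degenerate jackknife variance
  yields NaN Z.
- Codons containing N or IUPAC ambiguity translate to X; within-species
  polymorphism in protein alignments is expected pre-collapsed to X, and X
  never matches any residue. A trailing partial codon is dropped with a
  warning.
- Problem sizes used by the validation experiments (chosen to estimate the
  relevant rates with adequate replication): 10⁵ sites × 20 seeds for null
  and admixture calibration, 50 replicates of a 1-Mb chromosome with
  20,000 SNPs for tract recovery, 100 random 20-leaf trees for
  displacement, 10⁵ replicates for the decay oracle.
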