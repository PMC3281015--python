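# Methods

## Statistical model

Traits are strain means of an RI panel; strains are homozygous at every
marker, so a biallelic marker partitions the panel into A-allele and
B-allele groups (A = the ISS/C57BL/6J-like parent, B = the
ILS/DBA/2J-like parent; this fixes the sign convention: effect sign +1
means higher values in B-allele carriers). The single-marker model is a
two-group Gaussian mean shift with shared variance, scored by

    LRS = N ln(RSS0 / RSS1),

where RSS0 is the residual sum of squares about the grand mean and RSS1
about the two group means, over the N strains with both a trait value
and a genotype call (missing data are dropped pairwise per trait-marker
combination). This equals -N ln(1 - r^2) for the Pearson correlation r
between trait and {0,1}-coded genotype, and LOD = LRS / (2 ln 10); both
identities are enforced by tests against an explicit maximum-likelihood
oracle. No kinship or interval model is used: with a few dozen strains
and thousands of markers, marker regression on strain means is the
standard scan for this design.

Per trait, QTLs are the chromosome-wise LRS maxima (ties broken toward
the smaller genomic position). Significance is always a strict
inequality, LRS > threshold.

### Permutation calibration

Transcriptome-wide thresholds come from permutations of strain labels.
By default one shuffle per iteration is shared by all traits, which
preserves the trait-trait correlation structure of the observed matrix;
a `shared_permutation: false` switch gives independent per-trait
shuffles. Two selectors are derived from the permuted scans:

* an FDR table over an LRS grid θ: FDR(θ) = (mean permuted count of
  trait-chromosome maxima above θ) / (observed count above θ), reported
  as missing where the observed count is zero, and made non-increasing
  in θ by a running **maximum** from the right. The monotone curve is
  deliberately the conservative envelope: a noisy dip of the raw
  estimate at some θ can then never select a too-lenient threshold,
  because a θ is only reported at or below target when every larger θ
  is too. The reported panel threshold is the smallest grid θ with
  monotone FDR ≤ target.
* a genome-wide null threshold: the (1 - α) quantile of the pooled
  permuted per-trait genome-wide maxima. This is the quantity that is
  well defined even on a study with no real signal (where the FDR
  estimate is ≈ 1 everywhere), and it is what the null-calibration
  benchmark checks: on pure-noise studies the fraction of traits whose
  observed genome-wide maximum exceeds it should be α.

Behavioral traits use the standard genome-wide empirical p-value
p = (1 + #{permutations with max LRS ≥ observed max}) / (n_perm + 1).

In the pipeline, one threshold per panel is kept: the strictest of the
per-treatment thresholds, so a single panel-wide cutoff (in the spirit
of a fixed 24/26-style panel constant) is valid for all four arms.
Fixed per-panel thresholds can be supplied in the config instead for
replication-style runs.

## Activity patterns and conservation

The activity pattern of a significant (trait, marker) pair is the 4-bit
vector of per-treatment LRS exceedances at that fixed marker, in the
fixed order (SC, EC, SR, ER); the pattern index uses SC as the most
significant bit, so 15 non-null patterns exist for four arms. Pairs are
collected as the union over treatments of significant chromosome-max
hits, represented by the treatment with the highest LRS.

Cross-panel conservation matches the hit's marker to the other map's
nearest same-chromosome marker (distance ties toward the lower
position); `mode="identical"` restricts to markers present in both maps
as a sensitivity check. Conservation under a treatment means the other
panel's LRS at the matched marker exceeds the **other panel's**
threshold; `conserved_any` is the OR over treatments, and
`pattern_identical` compares full bit vectors. A trait without a
counterpart in the other panel yields a missing record; downstream,
candidate selection treats it as not conserved (conservation cannot be
demonstrated), and conservation tracks count it as not conserved.

The conservation ratio in a half-open window [x, x + 50 Mb), stepped by
5 Mb (both configurable; the window width is the analysis's defining
scale, the step only controls track smoothness), is
n_conserved / (n_features × global fraction), missing in empty windows;
windows overhanging a chromosome end are kept and flagged. The same
operation serves eQTL features (hit marker positions flagged by
`conserved_any`) and SNP panels (positions flagged as segregating in
both panels), and tracks are compared by Pearson correlation over
windows non-missing in both.

## Candidate genes and networks

A behavioral QTL region (chromosome, interval, focal panel, focal
treatment — EC by default, matching ethanol-activated loci) scores every
trait by an 8-entry vector: per panel × treatment, the maximum LRS over
markers inside the closed interval. Region-max rather than a single
marker is used because regions, not points, are the unit of behavioral
QTL support. Candidates are genes whose focal-panel hit inside the
region has SC bit 0, EC bit 1, and is not conserved in the other panel.
Networks include transcripts passing a focal LRS > 20 prefilter whose
8-vector correlates with the phenotype's above 0.7 (pairwise deletion of
missing entries, at least 4 shared entries); edges — including
transcript-transcript edges, distinguished by an `edge_kind` column —
require r > 0.8. A constant phenotype vector is an error, since its
correlations are undefined.

## The synthetic study generator

The generator emulates a two-panel (LXS-like and BXD-like), four-arm
hippocampal eQTL study. Defaults keep the emulated panel structure: 31
and 30 strains, 2659 and 3796 markers over the 19 mouse autosomes plus
X, four treatment arms, 78 881 SNPs. The expression-trait count
defaults to 200 (tens of thousands of probes would add nothing to the
statistics being exercised); benchmark configurations scale markers,
traits and SNPs further down (300–500 markers, 45–80 traits, 500–4000
SNPs) so whole-study replicates run in milliseconds — these sizes are
the package's choices and are recorded with each benchmark.

* **Genotypes.** Each strain's chromosome is a two-state Markov chain
  along the sorted markers: first allele A/B with probability 1/2,
  transition probability between adjacent markers d Mb apart
  p = (1 - exp(-2 r d)) / 2 with breakpoint rate r = 0.02/Mb by default
  (roughly 3 breakpoints per 150-Mb chromosome, an RI-like density).
  RI map expansion is not modeled explicitly — only linkage structure,
  not centimorgan fidelity, matters for the statistics, and the methods
  operate purely on physical positions.
* **Expression traits.** Value = per-trait baseline (Normal(8, 1),
  log-intensity-like units) + Σ effect_size_c × I[B at causal marker] +
  Normal(0, σ) noise, independent per strain × arm; σ = 1 by default and
  effect sizes are drawn from {2σ, 3σ} with random sign. Causal
  variants sit at genotyped markers of a randomly chosen anchor panel.
  Gene annotations are placed by designed geometry: within 2 Mb of the
  causal marker (cis), on the same chromosome but > 12 Mb away
  (syntenic trans), or on another chromosome (non-syntenic trans).
  Designed activity patterns are single-treatment or all-four; the
  single-treatment fraction is class-dependent (0.85 for non-syntenic
  trans, 0.3 for cis, 0.5 for syntenic trans), planting the qualitative
  contrast that trans regulation is more treatment-specific.
* **Cross-panel sharing.** Each causal variant is shared between panels
  with probability given by a position-dependent sharing function
  (default: 0.9 inside conserved patches on distal chr 3, distal chr 4
  and proximal chr 12, 0.15 elsewhere); shared effects are planted in
  both panels at each panel's nearest marker with identical sizes. SNP
  conservation flags are drawn from the same function, so eQTL and SNP
  conservation tracks are positively related by construction.
* **Behavioral traits.** Two zero-maze-like phenotypes (activity count
  and open-quadrant time) carry planted QTLs: ethanol-only loci on
  chr 3 @ 136 Mb and chr 14 @ 9 Mb in the first panel and chr 1 @ 25 Mb
  in the second, plus a non-ethanol locus at chr 1 @ 160 Mb, with
  effect size 1.5σ.
* **Group sizes.** Per-arm strain subsets can be made unequal
  (`unequal_groups`), mirroring real designs where treatment groups
  have different strain counts; default equal.

What the generator does **not** emulate: probe-level microarray noise
and normalization, batch and sex effects, heteroskedastic strain means
(within-strain replicate counts are not modeled — strain means are
generated directly), polygenic background, linkage disequilibrium with
untyped causal variants, and realistic marker ascertainment. Passing
tests therefore demonstrate the correctness and calibration of the
statistics under the stated generative model, not robustness to those
real-data complications.

## Numerical choices

* Genotype codes: A/B/missing (int8 0/1/-1); heterozygous or unknown
  codes in `.geno` input become missing with a logged count.
* A genotype group with fewer than 2 usable strains makes the marker
  unusable for that trait (skipped with a reason code).
* RSS below 1e-12 × the trait's sum of squares is treated as an exact
  fit: RSS0 ≈ 0 (constant trait) gives LRS = 0; RSS1 ≈ 0 (perfect
  within-group fit) gives a capped LRS (default 300) with a flag,
  instead of infinity.
* Effect sign is sign(mean_B - mean_A), 0 only on an exact tie.
* Chromosome order for all sorted output: autosomes 1..19 numerically,
  then X; positions are Mb reals taken as given (no build conversion).
* The 5 Mb cis window is inclusive; the gene "position" is the single
  annotation-supplied coordinate (for synthetic data, the planted gene
  position).
* Seeds: one global seed per run, expanded into per-stage seeds by a
  fixed counter scheme (`SeedSequence([seed, stage_index])`), so stages
  are individually re-runnable and reruns are byte-identical.

## Benchmarks and their problem sizes

`scripts/acceptance.py` (and the mirror tests in
`tests/test_acceptance.py`) recompute: pattern-space cardinality (15);
the LRS/LOD ratio (2 ln 10 ≈ 4.61); worst-case LRS disagreement with the
correlation identity over 1000 random instances; null calibration (100
pure-noise studies, 25 traits × 30 strains × 120 markers on four
chromosomes, 200 permutations each — the calibration benchmark uses
independent per-trait shuffles, which are distributionally identical
for independent null traits and pool to a smoother null maximum
distribution); planted-pattern recovery (50 replicate two-panel studies,
60 strains, 3σ effects, fixed 24/26 thresholds) with the trans-vs-cis
treatment-specificity contrast; conservation-track correlation under
step-function sharing (50 replicates, four chromosomes, 50-Mb windows
stepped by 25 Mb); and candidate selection in a noise-free constructed
region (six pattern-matching and six pattern-violating genes). Measured
direct-simulation power figures frozen into tests: a 2σ effect at 40
strains clears the panel's own permutation-calibrated threshold in
≈ 99% of replicates; an ethanol-only 1.5σ behavioral QTL at 40 strains
is detected in EC (genome-wide p < 0.05) and not in SC in ≈ 88% of
replicates under the two-chromosome test map.

## Known limitations

* FDR estimation assumes exchangeable strains; family structure beyond
  the RI design is not modeled (no kinship correction, as appropriate
  for classical RI strain means).
* Nearest-marker matching can pair loci several Mb apart when maps are
  sparse; the identical-marker mode exists precisely to bound this
  effect.
* The probe-SNP filter needs externally supplied probe flags; it is
  disabled by default for panels without parental sequence.
* Conservation tracks carry no significance bands; the track correlation
  is descriptive.
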