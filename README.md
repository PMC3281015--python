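# qtlact

Treatment- and population-dependent QTL activity patterns for
recombinant inbred (RI) mouse panels.

## The problem

Genetic control of gene expression and behavior is rarely constant
across environments: a locus may drive hippocampal expression of a gene
only after an ethanol injection, or only under restraint stress, and the
same locus may act in one RI family (say LXS, from ILS x ISS) but not in
another (BXD, from C57BL/6J x DBA/2J). `qtlact` implements the analysis
toolchain for studies of this kind: strain-mean expression and
behavioral phenotypes measured under four treatment arms — SC (saline
control), EC (ethanol), SR (saline + restraint), ER (ethanol +
restraint) — in two RI panels, mapped against each panel's marker grid.

Because RI strains are homozygous, a marker splits the panel into two
allele groups and the association of a trait with a marker is scored by
the likelihood ratio statistic of a two-group Gaussian mean shift:

    LRS = N ln(RSS0 / RSS1) = -N ln(1 - r^2),      LOD = LRS / (2 ln 10)

with N strains used, RSS0/RSS1 the residual sums of squares about the
grand mean and the genotype-group means, and r the trait-genotype
Pearson correlation. Per trait, the QTL on each chromosome is the
marker with the maximum LRS; transcriptome-wide significance thresholds
come from permutations of strain labels (one shared shuffle per
iteration, preserving co-expression), and behavioral traits get
genome-wide empirical p-values the same way.

The package's core concept is the **QTL activity pattern**: the 4-bit
vector recording in which treatments a trait-marker association exceeds
the panel threshold (strictly). Four conditions give 2^4 - 1 = 15
possible patterns. On top of this it provides:

* **eQTL classes** — cis (gene and marker within 5 Mb, inclusive),
  syntenic trans (same chromosome, farther), non-syntenic trans
  (different chromosomes) — and a probe-SNP filter that removes
  artifact cis-eQTLs (probe contains a SNP, expression apparently higher
  for reference-allele carriers, pattern significant in all four arms).
* **Cross-panel conservation** via nearest-marker matching between the
  two maps, judged with the other panel's own threshold, with an
  identical-marker sensitivity mode.
* **Conservation-ratio tracks** — in 50-Mb sliding windows, the observed
  number of features (eQTLs or SNPs) conserved across panels divided by
  the count expected from the genome-wide conserved fraction — and their
  Pearson correlation.
* **Candidate-gene selection and correlation networks** around
  behavioral QTL regions: genes whose eQTL is silent in SC, significant
  in EC and not conserved in the other panel; networks connect traits
  whose 8-entry (2 panels x 4 treatments) region-max LRS vectors
  correlate above 0.8 (nodes enter above 0.7 after an LRS > 20
  prefilter).
* A **synthetic two-panel study generator** with planted, treatment-
  dependent cis/trans effects, position-dependent sharing of causal
  variants between panels, and full ground truth, so the entire pipeline
  is testable without any external data.

## Worked example

The whole pipeline runs from one config:

```sh
qtlact run --config configs/demo.yaml --out-dir runs/demo
```

This simulates two 20-strain panels (200 markers, 50 expression traits,
planted cis/trans effects), derives per-panel LRS thresholds from 200
permutations at a 5% FDR target, and prints

```
pipeline finished; thresholds {'LXS': 22.0, 'BXD': 21.0}
```

The run directory then contains, among others,
`patterns/LXS_patterns.tsv` with one row per significant eQTL:

```
trait    marker      chromosome  position_mb  eqtl_class  pattern_index  bits  conserved_other_panel
TR00001  lxs_7_0082  7           83.9423      cis         3              0011  False
TR00006  lxs_5_0057  5           81.4826      cis         7              0111  False
```

— TR00001's eQTL is active only under the two restraint arms (bits
0011 in SC, EC, SR, ER order), TR00006's in everything except the saline
control — and `conservation/correlation.json` with the genome-wide
agreement of eQTL and SNP conservation tracks:

```
{"eqtl_snp_correlation": 0.7643977044905941, ...}
```

a positive correlation by construction, since the generator plants
shared causal variants and conserved SNPs in the same genomic patches.
Individual stages are also exposed (`qtlact simulate|scan|fdr|
pheno-scan|classify|conservation|candidates|network`); see
`qtlact <cmd> --help`.

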