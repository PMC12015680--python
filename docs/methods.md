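# Methods

`lncnet` reconstructs, as a tested desk-scale pipeline, the analysis chain
used to screen long non-coding RNA (lncRNA) regulators of messenger RNAs in
a four-group bulk RNA-seq design: term labor (TL), term premature rupture
of membranes (PROM), preterm birth (PTB) and preterm PROM (PPROM), six
biological replicates each. This note records the models, the defaults and
why they were chosen, what the synthetic generator does and does not
emulate, and the numerical decisions a maintainer would want to know.

## Normalization and filtering

Expression is quantified as FPKM,

    fpkm[g, s] = counts[g, s] * 1e9 / (length_bp[g] * T_s),

with `length_bp` the union of the gene's exon intervals (falling back to
the gene-body span for genes annotated without exons) and `T_s` the column
sum of the count matrix. Using the in-matrix column sum instead of the
total mapped-fragment count of the original alignments is a deliberate
divergence: alignment is out of scope, and the column sum is the only
denominator available from a count matrix. FPKM columns are invariant to
uniform rescaling of a sample's counts.

Genes are kept when FPKM >= 0.1 in at least 2 samples (both configurable).
The filter exists to keep near-constant rows out of the Pearson screen,
where they produce undefined or unstable correlations; it is deliberately
permissive.

PCA sample scores are computed on log2(FPKM + 1), gene-centered, by SVD.
The log transform stabilizes the variance of skewed FPKM values; it can be
switched off. Each component's sign is fixed by making its
largest-magnitude gene loading positive, so scores are reproducible across
runs and BLAS implementations with equal values. A constant matrix yields
zero scores and a logged warning rather than an error.

## Differential expression

The published analysis used DESeq2. `lncnet` implements a transparent
per-gene negative-binomial (NB) Wald test as a stand-in rather than a
bit-exact clone: the full DESeq2 machinery (dispersion trend, MAP
shrinkage, independent filtering, outlier replacement) is out of scope, and
correctness is instead established by simulation calibration against the
generator's known truth.

Per contrast B vs A:

* Size factors are median-of-ratios: for genes with nonzero counts in all
  samples, `factor_s = median_g counts[g, s] / geomean_g`. Factors are not
  rescaled further.
* Group abundances are the means of size-factor-normalized counts,
  `q_g = mean(counts / sf)`. When one group's mean is zero, a
  pseudo-abundance `eps = 0.5 / sqrt(n_a + n_b)` enters both the fold
  change and the information so the statistic stays finite and
  conservative.
* One dispersion per gene and contrast, shared across both groups, is
  estimated by maximizing the Cox-Reid adjusted NB likelihood (the plain
  ML profile minus half the log determinant of the per-group information),
  with a method-of-moments estimate bracketing the bounded search in
  log-alpha over [1e-8, 50]. The 1e-8 floor is the Poisson limit.
* The Wald statistic `log(q_b/q_a) / se`, with
  `se^2 = 1/I_a + 1/I_b` and `I_g = sum_i mu_ig / (1 + alpha * mu_ig)`,
  is referred to a Student t with `n_a + n_b - 2` degrees of freedom.

The Cox-Reid adjustment and the t reference both address the same
small-sample problem: at 6 replicates per group, plain ML underestimates
the dispersion and a normal reference ignores that the dispersion was
estimated. With neither correction the null rejection rate at p < 0.01 is
about 0.04 in simulation; with both it is about 0.009, i.e. calibrated.
Exchanging the group labels negates log2fc and leaves p unchanged up to the
optimizer's convergence tolerance.

DEGs are called at the study thresholds: raw p < 0.01 and fold change >= 2
or <= 0.5. Raw p (not FDR) is used deliberately, matching the published
screen; a BH-adjusted mode can be layered on by the caller via
`bh_adjust`. The fold-change boundary is inclusive by default (`FC = 2`
qualifies); `strict_fc` restores the strict inequality. All six ordered
group contrasts are run by default.

## Co-expression targets and cis/trans assignment

Candidate regulator-target pairs are all lncRNA x protein-coding-gene
combinations with |Pearson r| > 0.6 and p <= 0.01 across the 24 samples of
all four groups pooled, computed on log2(FPKM + 1). The p-value is the
two-sided Student-t transform `t = r * sqrt(df / (1 - r^2))` with
`df = n - 2`. Constant rows are skipped. The pooled default mirrors the
original screen; `scope="within_group"` group-centers each gene first
(df shrinks by the number of groups minus one), which removes the
correlation that group-level differential expression induces between any
two DE genes — a substantial confound in pooled cross-condition
correlations and a large part of why such screens return very large pair
counts.

The t-based p is an approximation to the randomization-exact permutation
p. At n = 24 the two differ per dataset by up to about 0.01 absolute
(roughly 10-20% relative at moderate p), because the permutation null's
higher moments depend on the observed sample; the package's tests quantify
this and check the approximation at that honest tolerance.

A retained pair is **cis** when the two gene bodies sit on the same
chromosome with an interval gap of at most 100 kb (boundary inclusive,
overlap counting as gap 0), **trans** otherwise. The window is
strand-agnostic and anchored on the gene body rather than the TSS — the
weaker, more inclusive reading of "100 kb upstream and downstream" — and
both the window and the anchor convention are configurable at the call
site. The cis pair set is exactly the intersection of the co-expression
set with the co-location set.

Which lncRNAs enter pairing is configurable: all expressed lncRNAs
(default) or the union of differentially expressed lncRNAs over all
contrasts (`lncrna_selection: de_union`), the published variant. The
default keeps the co-expression screen's operating characteristics
measurable on their own: with the DE-union gate, pair recovery on
synthetic data compounds DE detection and correlation detection into one
number.

The network summary counts pairs and distinct lncRNAs/genes overall and
within the positive- and negative-correlation strata; positive + negative
pairs always equals the total. Exports are GraphML (node attributes: role,
per-contrast DE direction; edge attributes: r, sign, relation) and SIF,
with sorted node and edge order so re-export is byte-identical.

## Overlap screening and key-lncRNA nomination

For each of four contrast pairings — (PPROM vs TL, PROM vs TL),
(PPROM vs PTB, PROM vs PTB), (PTB vs TL, PTB vs PROM),
(PPROM vs PROM, PPROM vs TL), labeled term-PROM, preterm-PROM, PTB and
PROM respectively — and each direction, the overlap of the two DE-lncRNA
sets is tested with Fisher's exact test. The universe is the number of
expressed lncRNAs (the natural population the DEG sets were drawn from;
the original report does not state one). A pairing may reference the
reverse of a computed contrast; its up/down sets are obtained by swapping
the computed contrast's down/up sets, which is exact because the NB test
is antisymmetric in the group labels.

The two-sided p uses the point-probability rule: the sum of all
hypergeometric outcome probabilities not exceeding the observed table's.
Probabilities are handled as exact integer numerators over a common
denominator, so the inclusion decision is exact integer comparison and the
only floating-point operation is the final division; agreement with
brute-force enumeration is at the 1e-15 level. A one-sided mode equals the
hypergeometric survival function. The odds ratio is the sample
cross-product ratio, infinite when a zero cell forces it.

Candidates are ranked by the number of pairings in which they recur, ties
broken lexicographically, and carry the phenotype labels of their pairings.
The labels are annotations only; they add no statistical content.

## Enrichment

Over-representation of a target-gene set against user-supplied GMT
collections uses the hypergeometric upper tail P(X >= k), i.e.
over-representation only, with Benjamini-Hochberg FDR across all reported
terms. The universe defaults to all expressed protein-coding genes; terms
are intersected with the universe before testing, and terms with no query
overlap are reported at p = 1 (droppable). Database retrieval is out of
scope by design — the pipeline consumes any GMT, and the generator emits
one. `bh_adjust` implements the step-up rule directly and is cross-checked
against statsmodels to 1e-12.

## The synthetic generator

The generator exists so that every stage has measurable ground truth
without any external download. It emulates:

* a gene annotation on 5 chromosomes (300 lncRNAs, 2000 protein-coding
  genes; exonic lengths 500-10000 bp, 1-3 exons) in which 30% of lncRNAs
  have a designated protein-coding partner placed with an interval gap
  uniform in [0, 100 kb], while every other lncRNA-mRNA combination is
  separated by more than the window — so the co-location truth is exactly
  the designated pairs;
* NB counts (dispersion 0.05, base means log-uniform in [20, 500]) with
  per-sample depth factors log-uniform in [0.7, 1.4] for the 4 x 6 design;
* planted differential expression: 75 genes per group shifted by +-2
  log2 units in that group only (so each pairwise contrast carries ~150
  planted DE genes), plus 2 "key" lncRNAs shifted up in both preterm
  groups so the pairing screen has a planted recurrent hit mirroring the
  2 x 2 (term/preterm x intact/ruptured) structure of the design;
* 200 regulatory pairs — the 90 designated cis partners plus 110 trans
  pairs, 70% positive (the approximate positive share of the published
  pair statistics) — whose members share a per-sample standard-normal
  latent factor on the log2 scale, the mRNA loading negated for negative
  pairs. The loading is calibrated by bisection, simulating probe pairs
  through the same NB machinery and targeting a median sample Pearson r of
  0.85 on log2(FPKM + 1) at 24 samples (there is no usable closed form
  once NB sampling noise and the FPKM transform are involved);
* one planted GMT term containing 60% of the planted target mRNAs (capped
  at the term size of 50, padded with random genes) among 24 size-matched
  random decoy terms.

Planted DE genes and planted pair members are disjoint. This is the one
place the generator deliberately departs from the biology it mimics (a
regulator's target would itself shift): genes that are differentially
expressed in the same group correlate strongly in pooled 24-sample
correlations (population r near 0.8 for a fourfold shift), so planting
pairs through group effects would make "false" pair rates unmeasurable —
every same-group DE pair would be a true positive of the pooled-correlation
estimand. Keeping the two structures disjoint makes DE recovery,
pair recovery and enrichment recovery each measure one stage.

What the generator does **not** emulate: batch effects or other technical
confounders, isoform structure and alternative splicing, read-level noise
(counts are drawn directly, not simulated as alignments), correlated
gene-gene backgrounds beyond the planted latent factors, and hub
regulators (each planted lncRNA regulates exactly one mRNA). Recovery
results on this generator therefore demonstrate that the implementation
detects the structure its statistics are designed for — not that the
thresholds are optimal for real fetal-membrane data.

## Determinism and numerics

All generator randomness flows from numpy `default_rng` seeded with
`[stage, seed]` pairs, so each artifact is reproducible in isolation. The
pipeline itself is deterministic: outputs are sorted, no timestamps are
written, and two runs from the same config produce byte-identical files
(hash-checked in the tests). Degenerate inputs are handled explicitly:
all-zero genes are flagged with p = 1, constant vectors are skipped in the
correlation screen with a log entry, an empty pair table exports a valid
empty GraphML document, and a failed stage removes the partial outputs it
had written and raises an error naming the stage.

Default problem sizes (2300 genes x 24 samples, 600k candidate
correlations, ~14k NB fits) were chosen so that the complete synthetic
pipeline runs in well under a minute on one CPU and the full verification
suite in about half a minute, while leaving every recovery margin wide.

## Known limitations

* The NB test is a per-gene stand-in for DESeq2: no dispersion shrinkage
  across genes, no outlier handling, no independent filtering. Its p-values
  are calibrated in simulation at 6v6; behavior at 2-3 replicates will be
  more conservative.
* FPKM's denominator is the in-matrix column sum (see above).
* The pooled-correlation screen inherits the DE-induced-correlation
  confound of the original design; the within-group mode is provided for
  exactly that reason.
* Fisher-universe and enrichment-universe choices follow stated defaults;
  the original report specifies neither.
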