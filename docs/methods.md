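# Methods

`ovorate` implements a multilayered molecular-evolution analysis linking
the protein-coding divergence of candidate genes to the divergence of a
quantitative phenotype — ovariole number per female — across a clade of
closely related *Drosophila* species.  The layers are: codon-model
inference of dN/dS (gene-wide, per-branch, and branch-site), expression
specificity (tau), threshold screens against genome-wide medians,
positive-selection enrichment tests, and phylogenetic regression (PGLS)
of the tip phenotype on per-branch dN/dS.

## Codon substitution model

All rate inference uses the Goldman–Yang codon model on the 61 sense
codons of the universal genetic code (stop codons are excluded from the
state space).  The instantaneous rate from codon *i* to codon *j* is

* 0 if the codons differ at more than one nucleotide position,
* proportional to the target frequency *π_j* otherwise,
* multiplied by *κ* when the single change is a transition,
* multiplied by *ω* when it is nonsynonymous.

The matrix is scaled so one unit of branch length is one expected
substitution per codon.  Codon frequencies default to equal (1/61); F3x4
frequencies estimated from the alignment are available as an option.
The model is reversible, so likelihoods are computed from the spectral
decomposition of the symmetrized rate matrix, and rooting is arbitrary
(verified by a pulley-principle test).

Likelihoods use Felsenstein pruning over compressed site patterns with
per-node rescaling.  Gap or ambiguous codons are treated as missing data.

Three fitted models:

* **M0** — one ω for all branches and sites.  Reported gene-wide.
* **Free-ratio** — an independent ω per branch.  Branch rates are
  decomposed into dN and dS by dividing the branch's nonsynonymous and
  synonymous substitution flux by the site proportions computed from the
  same model with ω set to 1 (so dN/dS equals the branch ω identically,
  and dN = dS at neutrality).
* **Branch-site model A** — four site classes (0: ω0 < 1 everywhere;
  1: neutral everywhere; 2a/2b: ω2 ≥ 1 on a designated foreground
  branch over a conserved/neutral background).  The test compares the
  model against the same model with ω2 fixed at 1 by a likelihood-ratio
  test referred to the upper tail of χ²(1) — not the recommended mixture
  null, deliberately, because that is the convention the analysis it
  supports uses.  P < 0.05 is reported as positive selection; no
  per-site empirical-Bayes identification is computed.  No
  multiple-testing correction is applied, again matching the supported
  analysis.

A modeling detail that matters: in the site-class mixture, each branch's
rate matrices are scaled by the *mixture-average* substitution rate, so
conserved classes genuinely accumulate fewer substitutions.  Scaling
each class to unit rate separately (a tempting shortcut) silently gives
conserved sites the same substitution load shifted onto synonymous
changes; in our experiments this reduced the power of the branch-site
test to roughly the significance level.  The simulator uses the same
convention as the likelihood, and the type-I error of the test is
verified by simulation.

### Optimization

Maximum-likelihood fits run bounded L-BFGS-B on log-transformed κ, ω
and branch lengths (logit-transformed class proportions and ω0 for
model A), with branch lengths initialized from corrected pairwise codon
distances least-squares-fitted to the tree, relative tolerance 1e-9,
and (by default) two random restarts.  The replicate studies below pass
`n_restarts=0`: with the least-squares initialization the fits are
single-basin at those problem sizes, and the saved restarts buy more
replicates.  The branch-site alternative is warm-started from the null
fit, but with the class-mixing parameters reset to interior values: at
the null optimum the class-2 proportion is unidentified and often
collapses to zero, which would otherwise park the alternative at a
saddle point where the ω2 gradient vanishes.

### Sentinel conventions

Free-ratio branch estimates with dS below 0.001 cannot support a finite
ratio.  Records with dS < 0.001 < dN are coded `GT1` (printed `>1`,
read as dN/dS > 1, i.e. positive selection); records with both rates
below 0.001 are coded `LOWDIV` (printed `-`, too little divergence to
determine).  The threshold (0.001) is configurable.  Saturation
filtering flags branch records with dN or dS at or above 1.5.

## Expression specificity (tau)

For one gene over *n* conditions, tau = Σ(1 − x_i/max(x))/(n − 1),
computed on raw expression values (RPKM); an optional log2(x+1)
pre-transform exists but is off by default, because the supported
analysis states the raw formula.  tau is 1 for single-condition
expression, 0 for uniform expression, and (n−k)/(n−1) for equal
expression in k of n conditions.  Genes with tau strictly above 0.90
are classed highly specific.  All-zero genes are excluded with a logged
count.

Cell-type profiles are clustered by average linkage on per-gene
standardized expression (z-scores across conditions; zero-variance
genes dropped and logged).  The distance metric is not dictated by the
source analysis (a GUI tool was used there); the default is Euclidean
distance on standardized profiles with a correlation-distance option.
Columns are processed in lexicographic order, fixing tie-breaks.

## Screens

* Fold screens pass a gene when its statistic (M0 ω, or the maximum
  per-branch ω) is **≥** fold × the genome-wide median of M0 ω.  The
  conventions mirror the supported analysis: 1.5× for the
  signaling-gene set, 2.2× (≈ ω ≥ 0.20) for the expression-derived
  sets.
* The distant-clade (Hawaiian) branch screen passes a gene when any
  branch ω is **strictly** above 0.33 or ≥ 1.5× that branch's
  genome-wide median.
* `GT1` sentinels outrank any finite threshold and any numeric branch
  maximum; `LOWDIV` records never pass.
* Upregulation gates: P < 0.05 for single-cell contrasts, P < 0.01 for
  bulk differential expression (configurable).  Ranking is by log2 fold
  change, ties broken lexicographically by gene id, so screens are
  permutation-invariant.
* Screens emit per-gene criteria traces (criterion, value, threshold,
  pass) so any pass/fail decision can be audited and re-evaluated.

## Enrichment

The frequency of positive-selection calls in a gene set is compared to
the genome-wide proportion by a Pearson goodness-of-fit test on the
2-cell table, one-tailed by halving the χ²(1) tail in the enrichment
direction.  Both the uncorrected and the Yates-corrected variants are
exposed because the published one-tailed values reproduce with the
correction for small tables (2/8 vs 5.4% → 0.047) and without it for
larger ones (6/27 vs 12.0% → 0.05); the default is uncorrected.  One
published value (TF cells, *D. sechellia*, printed 0.077) is not exactly
reproduced by either variant from the printed counts (closest 0.0755
with Yates); it is carried as data with this note.

## PGLS

Ovariole number per species is regressed on per-branch dN/dS under
generalized least squares with the Brownian-motion covariance matrix
(entry (i,j) = root-to-MRCA path length).  The slope's two-sided P uses
a t test at n − 2 df (3 residual df with five species).  Sentinels are
imputed before fitting: `>1` → ω = 1.5 and `-` → ω = 0.  These defaults
are back-solved from the published prediction table (two independent
rows pin 1.5, two pin 0) and verified across all 85 published
prediction cells; they are configurable and logged when applied.  Genes
with two or more `>1` branches are flagged untestable (the published
analysis excluded one such gene).  Plain Brownian motion is used — no
Pagel's λ — matching the stated procedure.  The published per-gene PGLS
P values and coefficients are shipped as data, not recomputed: the ML
branch lengths behind them are unpublished, so predictions (intercept +
slope × ω) are the reproducible surface and P values are not.

## Synthetic data

Every input layer has a seeded generator; each is a pure function of
its arguments (same seed → byte-identical output).

* **Codon alignments** evolve root codons drawn from the equilibrium
  frequencies along each branch by sampling from exact
  matrix-exponential transition probabilities (not Gillespie paths,
  which are equivalent in distribution here and slower), with optional
  site-class mixtures for branch-site simulations.
* **Genome rate tables** draw M0 ω from a gamma distribution whose
  *distribution* median is set exactly (default 0.0909, the value
  implied by a 0.20 threshold at 2.2× the median); per-branch dS is
  log-normal with dN = ω·dS; positive-selection flags are Bernoulli at
  per-branch frequencies; designated "rapid" genes can be planted at
  known ω so screens can be checked against a constructed truth; small
  fractions of `GT1`/`LOWDIV` records arise from forced near-zero
  rates.
* **Expression matrices** give each gene a breadth k (conditions
  expressed); expressed conditions get log-normal values, so with zero
  noise tau hits (n−k)/(n−1) exactly.  Defaults: 59 conditions,
  breadth uniform on 1..59 — a deliberately simple mixture of narrow
  and broad genes, not a fit to any organism's breadth distribution.
* **Phenotypes** are y = intercept + slope·ω + ε with ε multivariate
  normal under σ²·V(BM) on the tree.

What the generators do *not* emulate: alignment error, indels,
selection on synonymous sites, codon-frequency biases, expression
normalization artifacts, or correlated evolution among genes.  Passing
recovery tests on these inputs shows the estimators and screens are
correct and calibrated under the model's own assumptions; it does not
certify published real-data values, which additionally depend on
unpublished alignments and runtime settings.

## Study sizes and design choices in the verification suite

* M0 recovery: 5-taxon star trees (branch length 0.15), ω = 0.2,
  κ = 2, 5,000 codons × 50 replicates; median relative error of ω̂
  ≤ 10%.
* Free-ratio recovery: 5-taxon star, one branch at ω = 0.8 against
  0.1, 2,000 codons × 100 replicates; the planted branch is the branch
  maximum in ≥ 95%.  Star trees put one free ω on every terminal
  branch — the configuration the per-species-branch analysis cares
  about — and keep the replicate studies cheap.
* Branch-site: type-I error on 3-taxon trees (t = 0.2), 200 codons ×
  300 null replicates, rejection ≤ 8% at α = 0.05 (empirically ~2–3%:
  the χ²(1) reference is conservative for this test); power spot-check
  with ω2 = 4 on 10% of sites at 2,000 codons.
* PGLS: slope recovery (generating slope −40, BM noise) over 200
  replicates on a fixed 5-taxon tree; star-tree equivalence to OLS at
  1e-10; covariance against brute-force shared-path sums on random
  trees.

Runtimes are desk-scale: the full test suite runs in minutes on one
core.

## Known limitations

* Published per-gene ω values for real genes are not re-estimated: the
  genome alignments and exact codeml settings behind them are not
  available, so numerical agreement with published M0/branch values is
  not claimed.  The published tables ship as data and everything
  derivable from them (predictions, enrichment P values, branch maxima,
  testability) is recomputed.
* The branch-site test uses χ²(1), which is conservative; power at
  weak selection intensities (ω2 near 1–4) on short branches is low,
  as expected for this test.
* The PGLS assumes plain Brownian motion and a user-supplied tree; with
  five tips the power to detect model violations is negligible.
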