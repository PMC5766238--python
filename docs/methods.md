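# Methods

## Model

The package explains per-sample gene expression from nucleotide-level
sequence features alone.  For each sample, expression is modelled as

    y(g) = a + sum_i b_i * x_{i,g} + e(g)

where `x_{i,g}` is feature `i` of gene `g` and `e(g)` is residual error.
The model is fitted as a lasso: predictors are standardized (mean 0,
SD 1), the response is centered, and the coefficient vector minimizes
`||y_c - X_s b||^2 + lambda * sum |b_i|`.  The penalty `lambda` is chosen
by k-fold (default 10) cross-validated MSE on a log-spaced grid of 100
values from `lambda_max` (the smallest penalty with an all-zero solution)
down to `lambda_max * 1e-4`; coefficients are then refit at the selected
penalty on the full data.

Model quality is always reported out-of-fold: the gene set is split into
k parts, each part is predicted by a model — including its own penalty
selection (nested CV; avoids the optimistic bias of reusing one penalty) —
trained on the remaining genes, and the pooled out-of-fold predictions
are scored by Spearman correlation and MSE.  Per-gene absolute errors
from this pooling feed the error-tree grouping.

### A structural property of pooled out-of-fold correlation

When the signal is null, the fitted models reduce to fold-complement mean
predictors, and the pooled Spearman correlation acquires a small negative
offset of about `-sqrt(n / (n_train * n_test))` (= -0.074 at n=2000,
k=10): a fold with above-average response necessarily has a
below-average training mean.  This is a property of the evaluation
scheme, not a bug; it shrinks as n grows and is documented here because
null-calibration checks must budget for it.

## Regions

Eight region kinds per gene, derived from a GTF annotation in 0-based
half-open coordinates:

| region | definition |
|---|---|
| DU   | promoter [-2000, -500) around the chosen TSS (transcription coordinates) |
| CORE | promoter [-500, +500) (wider than the classical core promoter) |
| DD   | promoter [+500, +2000) |
| UTR5 / CDS / UTR3 | all annotated intervals of that kind, merged (union, bookended intervals included) and concatenated |
| INTR | gene span minus all UTR/CDS intervals — constitutive introns |
| DFR  | the 1 kb immediately after the gene 3' end |

The TSS is selectable as first/second/third/last of the gene's
transcription-ordered TSS list, with fallback (second -> first when only
one exists, third -> second when only two).  On the minus strand the
promoter segments are mirrored genomically (transcription-coordinate
window [a, b) maps to genomic [t-b, t-a)), and all extracted sequences
are reverse-complemented so features are computed on the sense strand.
Segments clipped by a chromosome boundary are kept truncated (with a
logged warning) rather than dropped, since percentages are
length-normalized.

## Features

* Composition: `100 * #N / l` per nucleotide and `100 * #kmer /
  (#valid windows)` per di-/trinucleotide; windows containing ambiguous
  bases are excluded from numerator and denominator.  Empty or
  all-ambiguous sequences are missing-coded (NaN), and genes with any
  missing configured feature are dropped from model fitting with a
  logged count.
* Motif scores: log-odds of a JASPAR-style PWM against a background
  prior, `sum_j ln(P(s_{i+j}|w_j) / P(s_{i+j}))`, summarised as the
  maximum (default) or sum over scan positions.  Natural log; a
  pseudocount of 1e-3 is added per column and renormalized, so
  zero-count cells never produce -inf.  The prior defaults to the pooled
  composition of the scanned sequences (uniform available).  Scanning is
  sense-strand only by default; a flag takes the max over both strands.
* DNA shape: per-sequence means of pentamer-table values for MGW, HelT,
  ProT and Roll over all pentamer windows; missing pentamers are looked
  up via their reverse complement.  The table is consumed as input; the
  package ships only a synthetic stand-in generator for testing.
* dsDNA mode: reverse-complement k-mer classes are summed, giving 2
  nucleotide groups and the 10 canonical duplex dinucleotide steps
  (6 pairs + ApT, TpA, CpG, GpC).  This merge is the unique one that is
  strand-symmetric: collapsed features of a sequence equal those of its
  reverse complement.

The default full model is 4 + 16 composition percentages in 8 regions =
160 variables; promoter-only configurations (60 variables) and added
motif/shape/trinucleotide families are available through `FeatureConfig`.

## Selection

* Forward region selection: region feature blocks are added greedily,
  each step keeping the block that maximizes out-of-fold Spearman
  correlation of the cumulative model, ties broken lexicographically,
  until all blocks are included.
* Stability selection: the lasso is refit `n_iter` (default 500) times;
  each iteration uses a uniform 50% gene subsample and scales every
  standardized variable by an independent U[0.5, 1] weight (equivalent,
  by change of variables, to per-variable penalty reweighting).  The
  iteration's penalty is chosen by 5-fold CV-MSE on its own subsample —
  a documented stand-in for the original stability-path penalty rule,
  which the source method leaves open.  Variables selected (nonzero) in
  more than 70% of iterations are "stable".
* Effect signs: OLS of expression on the stable standardized variables;
  the coefficient sign gives the activating/inhibiting direction.  A
  collinear stable set falls back to the minimum-norm solution with a
  warning.

## Grouping and TAD statistics

A CART regression tree predicts per-gene absolute model error from the
composition features (min 100 genes per leaf), pruned by cost-complexity
with the penalty chosen by 10-fold CV; within numerical reach of the CV
minimum the strongest pruning is preferred.  Leaves are gene groups;
pooling groups over samples, "well predicted" groups are those with mean
error strictly below the first quartile (linear-interpolation / type-7
quantile) of all group mean errors.  The quartile is pooled across
samples (a per-sample variant is a flag away); the pooled reading was
chosen because group mean errors are only comparable on a common scale.

TAD statistics: genes are assigned to a TAD when their span midpoint
lies inside the TAD interval (overlap semantics are otherwise
ambiguous).  For every TAD with more than 10 member genes and every
composition variable, a two-sample Kolmogorov-Smirnov test (asymptotic
p-values) compares in-TAD genes with all others; Benjamini-Hochberg
correction is applied over all (TAD, variable) pairs jointly and a TAD
is flagged when any q < 0.05.  Group/TAD over-representation uses the
upper-tail hypergeometric probability P(X >= k); the headline fraction
of groups with an enriched TAD is reported at raw p < 0.05, with BH
q-values emitted alongside.  The Gini coefficient (relative mean
absolute difference) measures expression ubiquity across samples, and
its Spearman correlation with per-gene model error (plus a bottom-vs-top
Gini-quartile rank-sum test) quantifies whether ubiquitously expressed
genes are better predicted.

## Synthetic data

The generator emulates the statistical structure the pipeline assumes,
with known ground truth:

* Sequences are i.i.d. per nucleotide from a configurable base
  composition (default uniform).  A TAD-level dinucleotide shift of `s`
  (probability units) is realised by a first-order Markov chain that
  adds `s / P(N)` to the N->M transition and rescales the rest of the
  row — the simplest mechanism with direct control over dinucleotide
  percentages (a +0.04 CpG shift moves intronic CpG by ~4 percentage
  points).
* One synthetic chromosome per TAD plus one for TAD-free genes avoids
  interval edge effects; genes are laid out without overlap with enough
  flanking space that promoter/DFR windows never clip.
* Each gene has a 5'UTR / intron / CDS / intron / 3'UTR layout with
  region lengths drawn +/-40% around configurable means (defaults 300 /
  3000 / 1500 / 900 bp for UTR5/INTR/CDS/UTR3 — compact relative to
  human genes but preserving the rank order of region sizes), a random
  strand, and 1-4 TSSs emitted as alternative transcripts.
* Expression follows the fitted model's generative mirror:
  `y = a + sum b_i x~_i + e`, `e ~ N(0, noise_sd^2)` independent per
  gene and sample, with `x~` the feature standardized across genes.
  Expression is written on the already-log scale, so the pipeline's
  log1p transform is reserved for count-like real input.
* PWMs are random Dirichlet-column count matrices in JASPAR PFM text;
  the shape table generator produces a synthetic pentamer table with
  realistic scales (it is a stand-in, not a physical model).

What the generator does not emulate: isochore structure, read-level
noise, expression correlation between samples beyond the shared signal,
annotation errors, copy-number or methylation effects.  Passing tests
therefore demonstrate correctness of the machinery and calibration of
the statistics under the assumed model, not performance on real tissue
data.

## Numerical choices

* Coordinate descent: penalty-path candidates are computed with warm
  starts, Gram precomputation and a bounded sweep count (max_iter 300,
  tol 1e-4); the selected penalty is always refit to full convergence
  (max_iter 10000).  Candidates only need to be ranked by held-out MSE.
* Simulation-scale studies (acceptance script and heavy tests) use a
  50-point penalty grid with 5-fold inner CV and n = 600-2000 genes;
  library defaults are 100 points / 10 folds.
* Spearman ties use average ranks; KS tests use the asymptotic
  two-sample p-value; max-score ties in PWM scanning resolve to the
  smallest position.
* Zero-variance variables are dropped before standardization (warned);
  degenerate inputs (empty TSS list, all-ambiguous sequence, all-zero
  Gini input, sub-minimum subsample) raise or missing-code as documented
  per function.
* All randomness flows through explicit integer seeds; a fixed
  configuration reproduces byte-identical pipeline outputs, verified by
  content hashes in the run manifest.

## Known limitations

* The per-iteration penalty rule in stability selection differs from the
  original stability-path formulation; frequencies are comparable in
  spirit but not numerically identical to it.
* Minus-strand promoter mirroring follows a genomic-window convention
  that is 1 bp offset from exact reverse-complement symmetry; composition
  features are insensitive to this at promoter length scales.
* The hypergeometric enrichment treats gene groups as simple random sets;
  spatial autocorrelation of errors along chromosomes would inflate
  significance on real data.
* Asymptotic KS p-values are approximate for TADs barely above the
  10-gene filter; an exact variant is available for small samples.
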