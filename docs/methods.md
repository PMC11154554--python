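# Methods

## Problem

Given m simultaneous two-group comparisons (the motivating case is
differential expression across m genes), multiple-hypothesis-testing
procedures order the per-test evidence and look for the point separating
null-dominated from alternative-dominated tests while controlling the false
discovery rate (FDR) and false non-rejection rate (FNR).  `mhtcnn` casts
this as a sequence-labelling problem: a convolutional network reads the
ordered evidence sequence and emits, per position, the probability that the
test at that position belongs to the alternative set.

## Evidence: unscaled Bayes factors

Each test i compares H0: mu_X = mu_Y against H1: mu_X != mu_Y for two
normal samples with a common unknown scale sigma.  Objective improper
priors — flat on the common location, flat on the standardized shift
delta/sigma, and the right-invariant d(sigma)/sigma on the scale — give the
marginal-likelihood ratio in closed form:

    log B = 1/2 log(2 pi N / (n_x n_y)) + (N - 1)/2 * log(1 + t^2 / (N - 2)),

with N = n_x + n_y and t the pooled two-sample t statistic.  Because the
priors are improper, B is defined only up to a positive constant c ("unscaled"):
individual magnitudes are meaningless, but the ordering of the B_i within a
battery and their ratios are well defined.  The closed form is verified in
the test suite against an independent Gauss–Legendre quadrature of both
marginal likelihoods (relative agreement ~1e-9 on random small samples).
A fully flat prior on *both* means was rejected as the default because it
leaves log B scale-dependent (an extra 0.5 log of the pooled sum of squares),
destroying the monotone-in-|t| property that makes the ordering meaningful; a
Behrens–Fisher variant (separate scales, numerical integration) is available
via `EvidenceSpec(options={"heteroskedastic": True})` but is not the default.

P-values from any source can enter the same pipeline through the universal
lower bound B >= [-e p ln p]^(-1) for p < 1/e (else 1).  Non-positive
p-values are clamped to 1e-300 with a warning, since the bound diverges.

## The W sequence

Sorting the m log-BFs ascending and differencing gives the relative-evidence
sequence W_i = log B_(i) - log B_(i-1), with W_1 := 1 kept as a fixed
sentinel.  The unknown constant c cancels in the differences, so W is
invariant to the prior normalisation.  Nulls concentrate in a narrow band of
log-BF values while alternatives spread over a wide range, so the *level* of
W shifts upward at the boundary position m0 + 1 — the signal the classifier
detects.  Sorting is stable with ties broken by original index, and the
permutation is recorded so per-position outputs map back to test ids.

## Classifier

A fully convolutional 1D network maps the (preprocessed) sequence to
per-position logits: seven same-padded dilated convolutions
(64, 64, 48, 48, 32, 32, 24 filters; kernel 3; dilations 1, 2, 4, 8, 16, 32,
64; ReLU), a linear aggregation layer (kernel 5, dilation 16) and a fixed,
non-trainable moving average of the logits over 101 positions, renormalised
at the edges so boundary positions average fewer taps instead of
zero-padding.  The receptive field is a few hundred positions.  Design
rationale:

- No length-collapsing layer appears anywhere, so one trained network scores
  sequences of any length — transfer to real batteries of 10^4–10^5 tests
  needs no retraining.
- Narrow kernels with growing dilation give local feature detection plus a
  wide enough context to average over the heavy local noise of spacing
  sequences; with a small receptive field (tens of positions) the decision
  profile is fuzzy and the recovered separation point unstable.
- The fixed moving-average head exists because the scientific object of
  interest is a *monotone-ish step* in p-hat along the sorted sequence;
  averaging logits suppresses position-to-position flicker across the
  transition without touching the location of the step.

Preprocessing for W input: clip at the sequence's own 99.99% quantile (the
single spike at the separation point otherwise dominates), divide by the
mean of the clipped sequence, then log1p.  The mean of W telescopes to
(range of log-BFs)/m, so this normalisation is insensitive to the unknown
null fraction; the log compresses the remaining heavy tail.  The quantile is
recorded in the model artifact and re-applied per input sequence.  The
ordered-p-value pathway feeds raw descending-ordered p-values (already in
[0, 1]).

Training minimises per-position binary cross-entropy with Adam
(learning rate 1e-3) for 30 epochs.  An epoch is a pass over 48 random
crops of length 1,024 drawn from the training sequence (minibatches of 8).
Crops rather than whole-sequence batches serve two purposes: they provide
enough gradient steps within 30 epochs for full-batch-sized problems, and
they present the null/alternative boundary at varying window offsets, which
discourages the network from memorising the boundary's training position.
Everything is seeded and deterministic (pure numpy; no backend
nondeterminism).

## Decisions and benchmarks

The alternative set at FDR level q is {i : p_hat_i > 1 - q}.  The
Benjamini–Hochberg step-up procedure on Welch-corrected t-test p-values is
the benchmark; both are scored by the Mann–Whitney (midrank) AUC of their
scores against ground truth, plus observed FPR (false rejections among
rejections) and FNP (missed alternatives among non-rejections), with
0-protected denominators.  The benchmark's ROC is traced over the
BH-adjusted p-value threshold, so its AUC is computed from the adjusted
values.  One consequence deserves emphasis: the step-up adjustment is
monotone, but its running minimum creates tie groups — massive ones in
weak-signal batteries, where almost every adjusted value collapses onto one
plateau — and midrank tie handling then pulls the benchmark's AUC toward
0.5.  Because that collapse is a property of the adjusted scale rather than
of the underlying p-value ranking, `run_grid` also reports the tie-free
raw-p AUC as a separate `bh_raw` row; the two coincide when signal is
strong and ties are rare.

## Synthetic data

`simulate` generates seeded batteries: independent mode draws each test's
two samples from Normal(0, sigma_X^2) and Normal(mu, sigma_Y^2) (mu = 0 for
nulls, mu_alt for alternatives; only the second population shifts).  Block
mode partitions tests into consecutive blocks; within a block, replicate
vectors across tests are multivariate normal under a correlation matrix with
iid Uniform(-1, 1) off-diagonals projected to the nearest positive
semidefinite matrix (eigenvalue clipping, diagonal renormalised); x and y
blocks get independent draws, matrices are redrawn per battery, and a
trailing partial block is generated as a smaller block.  The canonical
training battery fixes m = 10,000, null fraction 0.9, n = 10, mu_alt = 3,
unit variances, independent tests.

What the generator does *not* emulate: count-valued data (RNA-seq enters
only as externally computed Bayes factors or p-values through the evidence
TSV pathway), per-test variance heterogeneity within a battery (sigmas are
per-scenario), and paired or longitudinal designs.  Passing tests therefore
demonstrate transfer across Gaussian test batteries of varying signal,
size, null fraction and dependence — not across arbitrary likelihoods.

## Evaluation harness

`run_grid` scores each scenario cell over independent replications with the
*single* pre-trained classifier, reporting mean AUC with
normal-approximation confidence intervals (default level 99.9%) and mean
FDR/FNR per method.  Defaults are scaled for a single CPU: 50 replications
per cell (the confidence level is kept at 99.9% so tables are structurally
comparable at any replication count; full-scale runs are a parameter away).
`proposition1_check` instantiates the asymptotic argument that the
evidence gap W at the true separation position diverges with n: it reports
the median (and IQR) of W at sorted position m0 + 1 across replicate
batteries for each n.

## Numerical choices and edge cases

- All Bayes-factor arithmetic is in log space; the spacing sequence is
  formed from log-BFs directly, so the separation spike cannot overflow.
- Degenerate input (zero pooled within-sample variability) raises an
  explicit error rather than returning an infinite statistic.
- Probabilities are clipped to (1e-12, 1 - 1e-12) so downstream logs are
  finite while outputs stay strictly inside (0, 1).
- Sigmoid/binary cross-entropy are evaluated in the numerically stable
  logits formulation.
- Sub-seeds for grids and replications are spawned hierarchically with
  `numpy.random.SeedSequence`, so any cell is reproducible in isolation.

## Known limitations

- p-hat carries no uncertainty statement; the network output is a point
  estimate.
- Training uses a single simulated battery by design (the transfer premise);
  users whose evidence differs wildly from two-sample-normal behaviour
  should retrain on a calibration battery of their own via the same API.
- The heteroskedastic Bayes-factor variant integrates numerically per test
  and is markedly slower than the closed form; it exists for sensitivity
  analysis, not routine use.
- With m below a few hundred, the receptive field spans a large fraction of
  the sequence and edge effects grow; results on very short batteries
  should be read with care.
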