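# mhtcnn

Multiple hypothesis testing from ordered evidence sequences with a
convolutional sequence classifier.

## The problem

Large two-group screens — differential expression over m genes being the
canonical case — need to split m simultaneous tests into a null set H0 and
an alternative set H1 while controlling the false discovery rate (FDR) and
the false non-rejection rate (FNR).  Standard procedures such as
Benjamini–Hochberg (BH) act on p-values and lean on calibration and
dependence assumptions that real screens often violate.

`mhtcnn` takes a Bayesian route that sidesteps per-test prior elicitation.
For each test it computes an *unscaled* Bayes factor: for two normal samples
with common unknown scale, under objective improper priors,

    log B_i = ½ log(2πN / (n_x n_y)) + (N−1)/2 · log(1 + t_i² / (N−2)),

with N = n_x + n_y and t_i the pooled two-sample t statistic.  Improper
priors leave B_i defined only up to a constant c, but c cancels in the
ordered, differenced sequence

    W_i = log B_(i) − log B_(i−1)   (ascending order, W_1 := 1),

which jumps in level at the boundary between null-dominated and
alternative-dominated positions.  A fully convolutional network, trained
*once* on a simulated labelled battery (m = 10,000 tests, 9,000 nulls,
1,000 alternatives with mean shift 3, n = 10 per arm), reads any W sequence
and emits per-position probabilities p̂_i of membership in H1; tests with
p̂_i > 1 − q form the rejection set at FDR level q.  Because every layer is
a same-padded convolution, the same trained network scores batteries of any
length and composition — transfer, in the machine-learning sense.  P-values
from non-Bayesian analyses can enter the same pipeline through the lower
bound B ≥ [−e·p·ln p]⁻¹ (p < 1/e).

## Worked example

```python
from mhtcnn import SequenceMHT, make_training_battery, ScenarioConfig, \
    generate_battery, run_grid

battery = make_training_battery(seed=101)          # canonical training set
results = SequenceMHT.from_battery(battery).fit(seed=101)
print(results.summary())
```

```
Sequence MHT classifier results
===============================================
input kind                  w
training sequence length    10000
true alternatives           1000
epochs                      30
final training loss         0.0282
training accuracy           0.9896
misclassified fraction      0.0104
0.5-crossings               5
main crossing position      8999
model fingerprint           68f7dfb5e1e84a5b
```

The fitted probability profile steps from ≈0 to ≈1 at position 8999 —
two positions off the true null/alternative boundary at 9001 — and 99% of
the 10,000 positions are classified correctly.

The trained object transfers to new evidence without retraining:

```python
weak = generate_battery(ScenarioConfig(m=1000, m0_frac=0.9, n=3,
                                       mu_alt=1.0, seed=5))
decision = results.apply(weak, q=0.05)             # MHTResult
table = run_grid([ScenarioConfig(m=1000, m0_frac=0.9, n=3, mu_alt=1.0)],
                 results.classifier, reps=50, seed=7)
```

`run_grid` compares the classifier against the BH benchmark by mean AUC
with 99.9% confidence intervals; in weak-signal scenarios like the one
above the W-sequence classifier's mean AUC exceeds BH's.

A command-line interface wraps the same pipeline:

```
mhtcnn simulate --canonical --seed 1 -o out/battery
mhtcnn train --battery out/battery -o out/model
mhtcnn apply --model out/model --evidence evidence.tsv -o out/results
mhtcnn calibrate --evidence pvalues.tsv -o calibrated.tsv
```

where `evidence.tsv` has columns `id` and `log_bf` (or `id` and `pvalue`,
routed through the Bayes-factor lower bound).

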