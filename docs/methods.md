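# Methods

This note records the models implemented in `kldnet`, the parameters that
matter, and the design decisions taken where the problem was genuinely open.

## KL-divergence gene selection

For gene *g* with disease-group values $x^d$ and control-group values
$x^c$, both are transformed with $t(x) = \log_2(x+1)$ (variance-stabilizing
for counts; `transform="none"` is available for pre-transformed input) and
histogrammed on shared equal-width bin edges spanning the pooled
min–max. Each bin count receives an additive pseudocount before
normalization, giving probability vectors $P$ (disease) and $Q$ (control)
with strictly positive entries, and the gene's score is the plug-in
divergence $D(P\|Q)=\sum_i P_i \ln(P_i/Q_i)$ in nats. Genes with score
strictly above the threshold are selected, ordered by descending score
(ties broken lexicographically so selection is a pure function of the score
table).

Estimation choices, with defaults:

- **`n_bins` = 20.** Coarse enough that a control group of a few dozen
  samples populates the histogram, fine enough to resolve a one-to-two
  log2-unit shift.
- **`pseudocount` = 0.05 per bin.** The smoothing exists only to keep
  $Q_i > 0$ (finite divergence). Its total mass across 20 bins is one
  pseudo-observation, small against group sizes of ~15+. This matters
  quantitatively: heavier smoothing (e.g. 0.5/bin = 10 pseudo-observations)
  is comparable to a small control group's entire mass, flattens both
  distributions toward uniform, and compresses the score scale so much that
  a fully separated gene pair cannot reach 3 nats — the conventional
  selection threshold becomes unsatisfiable. At 0.05, on the simulator's
  default conditions, genes shifted by 2 log2 units score ≈ 3–4 nats while
  null genes stay below ≈ 1.7 (99th percentile ≈ 1.4), so the threshold of
  3 separates cleanly and fewer than 1% of null genes pass.
- **Direction: P = disease, Q = control** (`disease_vs_control`). KL
  divergence is asymmetric and no convention is canonical here; the
  reversed and symmetrized ($\tfrac12(D(P\|Q)+D(Q\|P))$) variants are
  exposed in `SelectionConfig`.
- **Degenerate range.** If every pooled value is identical the bin range is
  widened to $[v-\tfrac12, v+\tfrac12]$ and both distributions are set
  uniform, so the score is exactly 0: an invariant gene must never be
  selected.
- **Selection uses strict inequality** (`score > threshold`), so
  `threshold=3` excludes a gene scoring exactly 3.

Not implemented by design: parametric (Gaussian / negative-binomial) KL
estimators, and any FDR- or permutation-calibrated threshold — the
threshold is a plain configuration value.

## The classifier

A two-hidden-layer perceptron with relu activations and a sigmoid output:
$\hat y = \sigma(\mathrm{relu}(\mathrm{relu}(xW_1+b_1)W_2+b_2)\cdot w_3+b_3)$.
Default hidden widths (64, 16): small relative to a feature set of
~50–200 selected genes and a few hundred samples. A `strict_output` mode
reproduces the bias-free literal architecture in which the second layer
*is* the output unit (width 1, sigmoid applied to its pre-activation, no
$w_3/b_3$, no trained biases); note that applying the sigmoid *after* the
relu would confine all predictions to $[0.5, 1)$, which is why strict mode
takes the pre-activation.

**Losses.** Mean binary cross-entropy, or the focal loss
$-y\,\alpha(1-\hat y)^\gamma \log\hat y-(1-y)\,\hat y^\gamma\log(1-\hat y)$
with defaults $\alpha = 0.25$, $\gamma = 2$ (the reference values from the
focal-loss literature). Two variants are provided: `as_printed` (above;
no $\alpha$-dependent factor on the negative-class term) and `standard`,
which multiplies the negative term by $(1-\alpha)$ so that $\alpha$ acts as
a proper two-sided class weight. With $\gamma=0,\ \alpha=1$ both variants
reduce exactly to cross-entropy. Probabilities are clipped to
$[10^{-7}, 1-10^{-7}]$ before logarithms.

**Training.** Full backpropagation with analytic gradients (verified
against central finite differences to relative error $<10^{-5}$ in the
test suite), Adam with $\beta_1=0.9$, $\beta_2=0.999$, $\epsilon=10^{-8}$,
learning rate $10^{-3}$, 200 epochs, batch size 32 (full batch when the
data are smaller). Everything is driven by one seeded generator —
initialization (He for the relu layers) and per-epoch shuffling — so a
seed determines the trained parameters bit for bit. Features are
standardized by log2(x+1) then per-gene z-scoring with statistics computed
on the training data only and stored in the model (prediction is
self-contained); `standardize="none"` feeds raw counts.

## Evaluation

Confusion matrices count a sample as predicted positive when
$\hat y \ge t$ (ties at the threshold are positive); the default decision
threshold is 0.5. Accuracy, recall and precision follow the usual
confusion-matrix formulas; a zero denominator yields an explicit `None`
rather than 0 or NaN. AUC is computed by the rank (Mann–Whitney)
formulation with ties counted ½, and the ROC curve groups tied scores so
its trapezoidal area equals the rank AUC exactly.

Cross-validation is stratified k-fold (default k = 5, shuffled with the
report seed). Two protocols:

- **`leak_free` (default):** gene selection is re-fit on each training
  fold; held-out estimates are honest.
- **`paper_protocol`:** selection happens once on the full dataset before
  splitting — the ordering many published pipelines use. It leaks held-out
  information into the feature set and typically inflates estimates; it is
  provided for comparison.

"Best model" means the fold with the highest held-out AUC (ties to the
earlier fold); fold means and standard deviations are reported alongside
because either summary may be the one a published figure refers to.

## The synthetic-data generator

Counts are negative-binomial, $\mathrm{var} = \mu + d\mu^2$, with per-gene
baseline means $\mu_g = 2^{u_g}$, $u_g \sim U(2, 12)$, shared dispersion
$d = 0.1$, and a planted set of differential genes whose tumor mean is
multiplied by $2^{\mathrm{LFC}}$ (default LFC 2, up-regulated in tumor;
a symmetric mode flips half down). Defaults — 2,000 genes, 180 tumor vs
20 normal (9:1), 50 planted genes — mirror the shape of real tumor/normal
bulk cohorts: many genes, few samples, strong imbalance, overdispersion.

Deliberately not modelled: library-size variation, gene–gene correlation,
batch effects, and realistic annotation structure. Passing tests on this
generator therefore demonstrate that the pipeline recovers *marginal*
per-gene distributional shifts under overdispersed counts and imbalance —
not that it is robust to the correlation structure or technical artefacts
of real repository data.

## The loss-comparison experiment

The focal-vs-cross-entropy comparison (exercised in the acceptance tests)
measures mean held-out recall over 10 paired generator seeds at 19:1
imbalance with the **tumor class rare** (20 tumor vs 380 normal), weak
signal (300 genes, 20 planted at LFC 1.0, dispersion 0.25), selection
threshold 0 (every gene passes, so the comparison isolates the loss), a
budget of 30 training epochs, and focal parameters $\alpha=0.75$,
$\gamma=2$, `variant="standard"`.

These conditions are where the focal mechanism is actually expressed, and
each is a deliberate choice:

- *Rare positives.* Recall is sensitivity on the positive class; with a
  majority positive class an all-positive predictor already has recall 1
  and the comparison is vacuous.
- *$\alpha$ up-weighting the rare class.* $\alpha$ exists to rebalance the
  classes; the literature default 0.25 assumes the opposite imbalance and
  would further down-weight the rare positives here.
- *Limited training budget.* A pointwise analysis shows the per-sample
  focal optimum never crosses 0.5, so a fully converged high-capacity
  model gains no decision-boundary advantage from the focal loss; the
  benefit is dynamical. Early in training, cross-entropy spends most of
  its gradient on the abundant easy negatives, while the
  $\hat y^\gamma$ factor suppresses them and redirects capacity to the
  rare positives. Thirty epochs sits inside that window.

## Numerical conventions

- KL scores are clamped at 0 from below ($>-10^{-12}$ float residue only);
  a genuinely negative sum raises, since it means the probability-vector
  invariants were broken upstream.
- Sigmoid is computed in the numerically stable split form, and network
  outputs are clipped to $(10^{-15}, 1-10^{-15})$ so they remain in the
  open interval even where the float sigmoid saturates.
- Per-gene z-scoring maps a constant feature to 0 (scale forced to 1).
- Training aborts with a diagnostic if the epoch loss goes non-finite.
- Problem sizes in the test suite (e.g. 300–2,000 simulated genes, 10
  paired seeds in the loss comparison) keep the full suite around half a
  minute on one CPU while leaving every measured effect far from its
  acceptance margin.

## Known limitations

- The histogram KL estimator is biased at small sample sizes and its scale
  depends on `n_bins`/`pseudocount`; scores are comparable within one
  configuration, not across configurations.
- Thresholds (selection 3 nats, decision 0.5) are conventions, not
  calibrated quantities.
- No GPU path, no regularization beyond early stopping by epoch budget,
  no multi-class outputs, and no ingestion of repository archive formats —
  inputs are plain delimited text matrices, label tables and biotype maps.
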