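# Methods

## Model

`evimol` implements binary molecular property classifiers whose output layer
is an evidential head rather than a Softmax.  An encoder maps a molecule to a
latent point `z ∈ R^latent_dim`; two normalizing flows define per-class
densities `P_0(z)` and `P_1(z)`; the Dirichlet concentration parameters are

    α_c = 1 + N_c · P_c(z),   c ∈ {0, 1},

where `N_c` is the number of training molecules of class `c` (taken from the
training fold that fitted the model, since cross-validation folds see
different training sets).  The predictive probability is the Dirichlet mean
`p̄ = α_1 / (α_0 + α_1)`, which equals the posterior expectation of the
categorical parameter.  The total evidence `α_0 + α_1` is an epistemic
uncertainty score: where both class densities vanish, `α → (1, 1)`, giving
`p̄ = 0.5` with evidence at its floor of 2.  This is the mechanism that makes
out-of-distribution inputs default to maximal uncertainty — something a
Softmax output cannot guarantee, because logits are unconstrained off the
training manifold.

### Encoders

Two interchangeable encoders are provided; the head is agnostic to the
choice.

* **Graph attention encoder** — atom features (element one-hot, degree
  one-hot, formal charge, aromaticity, attached-H count) pass through gated
  attention message passing (attention over incoming neighbor messages, a
  GRU-style gated state update) followed by an attention-weighted readout and
  a small readout GRU stack.  This is a generic attentive message-passing
  network with the usual knobs (`hidden_dim`, `n_message_steps`,
  `n_readout_steps`, `dropout`), not a re-implementation of any specific
  published architecture: the contribution implemented here is the head, and
  the encoder only needs to be a reasonable representative of its class.
* **Fingerprint MLP** — Morgan fingerprints (radius 2, 2048 bits by default)
  through a one-hidden-layer tanh MLP.  Fast and deterministic; used widely
  in the test suite.

The attention readout matters for out-of-distribution behavior: it
concentrates the molecular embedding on the label-relevant atom environments,
which suppresses skeleton-level noise and leaves inputs lacking any such
environment in a visibly different latent region.  The fingerprint MLP, which
pools all substructure bits with fixed weights, separates out-of-distribution
inputs much less reliably; the out-of-distribution experiment therefore uses
the graph encoder.

### Flow densities

Each class density is a stack of `n_density` radial transforms over a
standard-normal base:

    f(z) = z + β h(α, r)(z − z0),  h = 1/(α + r),  r = ‖z − z0‖,

with `β ≥ −α` enforced by reparameterization (`β = −α + softplus(b)`), which
keeps each layer bijective.  The log-Jacobian has the closed form
`(d−1)·log(1+βh) + log(1+βh−βrh²)`, so `log P_c(z)` follows directly from the
change-of-variables formula with forward passes only.  Radial layers were
chosen over coupling flows because the latent space is low-dimensional
(2–10), the exact log-determinant is one line, and the layer count maps
directly onto the `n_density` hyperparameter.  Initialization draws layer
centers near the origin with near-zero strengths, so the initial density is
close to the base normal.

A batch-normalization step (no affine part) is applied to `z` before density
evaluation (configurable, default on): without it the scale of `z` drifts
during joint training of encoder and flows, and the densities chase a moving
target.  Evaluation mode uses running statistics.

Numerical guards: `log P_c(z)` is clamped to `[−40, 30]` before
exponentiation in the evidence map.  The lower clamp maps density underflow
to `α_c ≈ 1` with a finite gradient; an exact `−inf` input maps to exactly 1.
The radius calculation adds `1e−12` inside the square root so the gradient is
defined at `z = z0`.

### Loss

Training minimizes the mean uncertain cross-entropy minus a weighted
Dirichlet entropy:

    L = (1/N) Σ_i [ ψ(α_0 + α_1) − ψ(α_{c*}) − w · H(Dir(α)) ],

with ψ the digamma function and `c*` the true label.  The UCE term is the
expected cross-entropy under the predicted Dirichlet; the entropy term
regularizes toward the uniform prior.  The default weight is `w = 1e−5`: the
unweighted objective (`w = 1`) is available and is the literal form of the
training objective, but on small batches an unweighted regularizer dominates
the UCE signal, so the small default follows the established practice of
this model family.  The Softmax baseline trains with standard cross-entropy.

All gradients come from a small reverse-mode autodiff engine written over
numpy (`evimol.autodiff`); its primitives are finite-difference-checked in
the test suite, and the full loss gradient through encoder + flows is checked
to relative error ≤ 1e−3.

## Training pipeline

Adam (default learning rate 1e−3; the out-of-distribution experiment uses
2e−3) with mini-batches whose order, together with parameter initialization,
dropout masks, and fold assignment, derives from a single run seed — two runs
with the same seed produce bit-identical loss curves.  Early stopping
monitors a configurable validation metric (loss, auROC, or BEDROC for
screening tasks) with a patience counter and restores the best parameter
state.  Batches of size 1 are skipped because batch normalization needs at
least two samples.

Cross-validation uses stratified folds by default (a pure-random option
exists); each sample is predicted exactly once out-of-fold.  Ensembling
averages member probabilities arithmetically; the reported ensemble
"evidence" is the mean of member evidences and is flagged as a ranking score
rather than the evidence of any single Dirichlet.  Grid search over
`(latent_dim, n_density)` evaluates each cell by out-of-fold metric and
breaks ties toward the smaller cell.

## Synthetic benchmark

The generator assembles molecules from a random carbon/oxygen grammar:
atom-by-atom random trees (20 % oxygen) with valence bookkeeping, one
optional ring closure, up to 17 heavy atoms (echoing the size regime of
large enumerated small-molecule libraries), then decorates them with 1–3
nitrogen and/or 1–3 fluorine atoms according to category.  The variable
decoration count mirrors molecules drawn from an enumerated library, where
an element-containing molecule carries that element in varying amounts and
contexts; with a fixed single decoration atom the categories degenerate into
"skeleton plus one atom" and are barely separable from the undecorated
NULLmol in any learned representation.

| category  | elements      | label            | role                    |
|-----------|---------------|------------------|-------------------------|
| `Nmol`    | N, no F       | 0                | learnable negative      |
| `Fmol`    | F, no N       | 1                | learnable positive      |
| `N_Fmol`  | both          | fair coin        | aleatoric uncertainty   |
| `NULLmol` | neither       | fair coin, dummy | epistemic (OoD), test-only |

Membership is re-verified by an element scan before a molecule is accepted;
canonical-SMILES deduplication plus a single partition guarantees train/test
disjointness.  `NULLmol` labels are dummies so metric code runs; the category
is evaluated on prediction *behavior* (p̄ and evidence), never accuracy.

What this generator does not emulate: realistic chemistry beyond valence
rules (no aromatic systems, charges, or stereochemistry), realistic property
distributions, or scaffold structure between splits.  Passing the synthetic
experiment demonstrates the uncertainty mechanics of the head, not benchmark
performance on real ADMET or screening data.

## The out-of-distribution experiment

Desk-scale study conditions (`evimol.experiment`): 500 training molecules
per in-distribution category (1,500 total, 10 % held out for validation),
test split of 200 molecules per category including NULLmol.  Five evidential
models (graph encoder, `latent_dim` 4, `hidden_dim` 32, `n_density` 6,
learning rate 2e−3) are trained from consecutive seeds and ensembled by
prediction averaging, mirroring the ensemble methodology this model family
is used with; five Softmax baselines trained on the identical schedule
provide the overconfidence comparison, scored per member.

Both heads train for a fixed 150 epochs and keep the final parameter state
rather than an early-stopped checkpoint.  Discrimination on this task
saturates within ~20 epochs, so any accuracy-based stopping rule freezes the
model long before the flow densities have concentrated onto the training
clusters — and the density concentration is precisely what drives the
evidence separation under study.  The epoch count balances two failure
modes: too few epochs leave the densities too diffuse to separate NULLmol
from populated regions; many more (≈250+) over-concentrate them until
NULLmol falls into one class's tail and both heads grow overconfident.
`latent_dim` 4 sits in the recommended 2–10 range; very low dimensions
over-concentrate the density and push NULLmol toward one class cluster,
while larger ones inflate run time without changing the qualitative picture.

Expected outcomes, asserted by the acceptance tests: in-distribution
accuracy ≥ 0.95; mean p̄ within [0.35, 0.65] for both N_Fmol and NULLmol;
mean NULLmol evidence below both the 5th percentile of in-distribution
evidence and the N_Fmol mean (the decoupling of aleatoric from epistemic
uncertainty); and mean overconfident-false rate of the evidential members no
worse than the Softmax members.

## Metrics

Conventions: hard predictions threshold at `p > 0.5`; confidence is
`max(p, 1−p)`; "high confidence" means `p < 0.1` or `p > 0.9`; all rankings
are stable sorts with input-order tie-breaking.

* **ECE** — 10 equal-width confidence bins by default (the bin count is
  inherited from the evaluation lineage this suite follows and is
  configurable), sample-weighted mean |accuracy − confidence| per bin.
* **Brier** — mean squared error of `p` against the binary label.
* **OFR** — wrong high-confidence predictions over all high-confidence
  predictions; `NaN` when no prediction is high-confidence (returning 0
  would reward never-confident models).  **OFN** — confident-negative errors
  (`p < 0.1`, `y = 1`) over all samples.
* **Confidence-percentile curve** — rank by binary entropy of `p`, drop the
  `⌈fN⌉` most uncertain, report accuracy of the rest per grid fraction `f`;
  fractions that would drop everything are skipped with a warning.
* **EF@f** — hit rate in the top `⌈fN⌉` by score over the base rate.
* **BEDROC** — exact Truchon–Bayly closed form; α defaults to 80.5
  (configurable; the default again follows the source-code lineage of the
  screening literature this suite matches).
* Standard classification metrics (auROC, auPRC, ACC, precision, recall,
  F1, MCC) delegate to scikit-learn.  Paired two-sided t-tests between
  per-fold metric vectors are provided as reporting plumbing only.

Binary entropy uses natural log throughout; it is only used for ranking, so
the base is immaterial.

## Design notes and limitations

* Multiclass (K > 2) heads are out of scope; the head is binary throughout.
* SDF/InChI input, stereochemistry-aware features, and 3-D conformers are
  not supported; input is SMILES CSV only.
* The atom/bond feature set is a pragmatic choice, not a published standard;
  changing it changes encoders' numerical outputs but not any package
  contract.
* Unparseable SMILES are skipped with a per-row log rather than failing the
  read, since public benchmark exports contain occasional bad rows; labels
  other than {0, 1} are a hard error (no silent coercion).
* The autodiff engine implements exactly the primitives the models need; it
  is not a general-purpose framework (no higher-order derivatives, no GPU).
* Model serialization is plain JSON text; files are small at the latent
  sizes used here but would be impractical for much larger encoders.
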