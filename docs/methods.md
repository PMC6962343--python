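# Methods

## The model

`advdta` predicts continuous drug–target binding affinities (pKd, KIBA
score, or arbitrary units) from raw sequence text alone: a protein's
amino-acid string and a compound's SMILES string. It is a semi-supervised
two-round procedure.

**Round one — adversarial representation learning.** One generative
adversarial network is trained per modality on an *unlabeled* sequence pool
(the labeled sequences are folded into the pool, since no labels are needed
here). The generator is a four-layer fully connected network mapping a noise
vector z ~ N(0, I) to per-position softmax distributions over the
vocabulary; real sequences enter as one-hot matrices so real and fake
samples share one continuous representation — a fully connected generator
cannot emit discrete strings, and no Gumbel/REINFORCE relaxation is used
because sequence generation is not a product feature. The discriminator is a
three-layer fully connected network decomposed as

    D(s) = σ(φ_lᵀ F(s; φ_f)),

where F — the first two affine layers with leaky-ReLU activations — is the
feature extractor and φ_l is the bias-free sigmoid head. Training alternates
one discriminator step (maximise log D(x) + log(1 − D(G(z)))) and one
generator step (maximise log D(G(z)), the non-saturating form, which avoids
the vanishing gradient of the saturating loss). For a fixed generator the
optimal discriminator is D*(x) = P_data(x)/(P_data(x) + P_G(x)); the test
suite verifies a trained discriminator approaches this closed form on a
two-outcome toy problem.

**Round two — frozen-feature regression.** The leaked feature vectors
f_drug and f_protein are concatenated (drug block first) and treated as a
one-channel 1-D signal. Three convolution layers (16, 32, 48 output
channels, kernel size 4, stride 1, no padding, ReLU after each) feed a
flatten and a single affine output unit with identity activation. The
regressor minimises the mean squared error with Adam at initial learning
rate 1e-4 while the extractor weights stay frozen (verified by hashing them
before and after; the run report records both hashes).

**Evaluation.** A pair-level 80/20 split (seeded shuffle, round-half-up
train size). Test-fold metrics:

* CI — concordance index with the step function h (ties in predictions
  score 0.5; ties in the measured values are excluded from the normaliser);
* MSE;
* rm2 = r²(1 − √(r² − r₀²)), with r² the squared Pearson correlation and
  r₀² the squared correlation of the least-squares fit of observations on
  predictions *through the origin* (r₀² = 1 − Σ(y − kp)²/Σ(y − ȳ)²,
  k = Σpy/Σp²). The radicand is clamped at 0 when r₀² > r² numerically.
  Only the prediction-direction variant is computed, not the bidirectional
  average from the rm2 literature;
* AUPR via the average-precision estimator (mean over positives of the
  precision at their rank, stable descending-score sort, ties broken by
  original index) after binarising affinities at a threshold, with ≥
  counted as a binder. Conventional thresholds: pKd 7 for dissociation
  data, 12.1 for KIBA scores. When binarisation leaves one class the report
  marks AUPR unavailable with the reason instead of failing.

The average-precision estimator and a trapezoidal PR-curve area are
different conventions; they agree within ~0.02 on the instances the tests
draw, and average precision is the contract here.

## Encoding

Character-level tokenization for both modalities — the model consumes raw
ASCII, so the simplest deterministic contract is one index per character.
Indices are assigned in lexicographic order (a permuted corpus yields an
identical vocabulary); index 0 is reserved for padding and index |V|+1 for
unknown characters, so one-hot encodings have |V|+2 columns and held-out
sequences with unseen characters remain usable rather than erroring.
Decoding renders unknown positions as `?` — lossy by necessity. A protein
vocabulary always covers the 20 canonical amino acids. Multi-character
SMILES atoms (Cl, Br) are split into characters — a known limitation of
character-level tokenization. Default maximum lengths are 1000 (protein)
and 100 (SMILES), covering typical kinase-benchmark sequences; both are
configurable and the desk-scale pipeline defaults use 100/40 to match the
synthetic universe below.

## The numerical stack

No autodiff framework is used: the networks are small and fully specified,
so the package carries its own float32 feed-forward layers (dense,
leaky-ReLU, per-position softmax, 1-D convolution via im2col + BLAS matmul)
with hand-written backprop and Adam (β₁ 0.9, β₂ 0.999, ε 1e-8). Analytic
gradients are verified against central finite differences in the test
suite with a norm-relative tolerance of 2% — finite differences are
themselves biased where the perturbation crosses a ReLU kink, so the
comparison is on the whole gradient, not per entry. All randomness flows
through `numpy.random.Generator` instances seeded from explicit arguments;
a single global pipeline seed fans out as seed, seed+1, … to the per-phase
generators, making entire runs bit-reproducible (run reports compare equal
after stripping wall-clock fields). Logistic and cross-entropy functions
use the stable softplus forms; discriminator probabilities are clipped away
from exact 0/1 so D(s) stays strictly inside the unit interval.

## The synthetic universe

`advdta.synthetic` generates desk-scale universes with a known latent
affinity so every stage — including the semi-supervised mechanism — is
testable offline. Sequences are uniform random strings over the modality
alphabets (proteins: the 20 amino acids; drugs: the SMILES-flavoured set
`CON=()12`; no chemical validity is claimed, the model treats SMILES as raw
text). The latent affinity is linear in substring counts,

    a(d, p) = c + Σ_m w_m·count(m, p) + Σ_t w_t·count(t, d),

chosen so the Bayes-optimal predictor is closed-form and a regressor over
sequence-level features can plausibly learn it. The default ground truth
uses protein composition weights (K +0.30, E −0.25, W +0.40), one planted
3-mer motif (CDE +0.90, inserted into half the proteins), drug token
weights (N +0.35, = −0.30, 1 +0.25) and intercept 7.0 — an affinity scale
and spread (sd ≈ 1.5) resembling kinase pKd data. Gaussian measurement
noise defaults to 10% of the latent standard deviation; affinities are
clipped to [0, 16]. Unlabeled pools are drawn from the same generative
process, mirroring the premise that freely available unlabeled sequences
share the data distribution.

The default study condition is 200 drugs × 50 proteins (10 000 labeled
pairs, dense), proteins of length 50–80, SMILES of length 15–35, and 300
unlabeled sequences per modality. With the desk-scale pipeline defaults
(feature_dim 64 per modality, discriminator hidden 256, generator
64→128→128→128, 40 GAN epochs at batch 64, 30 regressor epochs at batch
128) a full run takes about 1.5 minutes on one CPU core and reaches test
CI ≈ 0.96 with test MSE near the injected noise floor.

The semi-supervised premise — pretraining the extractors on a larger
unlabeled pool should not hurt, and may help, relative to labeled-only
pretraining — is probed on a smaller condition sized for quick repetition:
625 labeled pairs (25 × 25) with 400 unlabeled sequences per modality,
three seeds per arm, compared on mean held-out CI with a 0.02 tolerance.

What passing these tests shows — and does not show: the pipeline recovers a
composition-linear signal through adversarially trained features on
synthetic text; real binding data have motif interactions, family
structure, assay noise and dataset shift that this generator deliberately
omits, so desk-scale results do not certify benchmark performance.

## Design choices where the design was open

* **Feature layer.** "The last layer of D" is read as the penultimate
  (pre-sigmoid) hidden layer — the only reading consistent with the
  decomposition D = σ(φ_lᵀ f). The head carries no bias so the
  decomposition is an exact dot product.
* **Regression input layout.** The concatenated feature vector is a
  length-N one-channel sequence for the convolutions; flatten → single
  affine unit is the minimal reading of a linear output layer (no pooling,
  no hidden fully connected layers).
* **Split.** Pair-level (warm) split, not cold-drug/cold-target; an
  optional validation fraction exists but no automatic tuning is performed.
* **Conditioning.** Regressor inputs are z-scored with training-set
  statistics and the output bias starts at the training-target mean. Both
  leave the model class unchanged and matter at learning rate 1e-4, where
  the output bias alone would otherwise need thousands of steps to traverse
  the affinity scale.
* **Missing values.** "NA"/"nan"/empty cells; sparse (KIBA-style) matrices
  are dense matrices with missing cells, keeping one loader code path.
* **Uniform optimiser.** Adam at 1e-4 for both rounds; the learning rate is
  stated once for the whole model and applied uniformly.

## Known limitations

* Character-level SMILES splits two-letter atoms; grammar-aware
  tokenization and canonicalization are out of scope.
* GAN training uses the vanilla objective only — no Wasserstein, spectral
  norm or least-squares variants — and generated sequences are a training
  by-product, not a product feature.
* Metrics come without confidence intervals; no model-comparison tests.
* The rm2 radicand clamp makes the metric continuous but slightly optimistic
  when r₀² marginally exceeds r².
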