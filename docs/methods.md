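# Methods

## Model and procedure

The framework treats augmented-sample quality control as an uncertainty
estimation problem. A point classifier trained with dropout defines, at
inference time, a distribution over predictors: each stochastic forward pass
samples one dropout mask, i.e. one set of effective parameters. Running
T passes over an input yields per-class probability samples `p_t^c`; their
mean `μ(p_c)` estimates the predictive probability and their sample standard
deviation `u(p_c) = sqrt( Σ_t (p_t^c − μ)² / (T−1) )` its spread (Monte-Carlo
dropout). A well-learned, unambiguous augmented sample should be predicted
(i) stably (low *u*), (ii) decisively (high μ), and (iii) in agreement with
the label it inherited from its source vector. The selection rule keeps
exactly the samples satisfying all three, with strict inequalities
`u < λ` and `μ > γ`; both μ and *u* are evaluated at the pseudo-label class
`y′ = argmax_c μ(p_c)`, the only class at which `μ > γ > 0.5` is satisfiable.
Argmax ties break toward the negative class; this matters only for exactly
balanced means, which strict γ > 0.5 excludes from selection anyway.

The loop re-initializes and retrains the model each iteration rather than
fine-tuning, so a bad selection in iteration *i* cannot permanently poison
the parameters; the selected set is recomputed from the full augmented pool
every iteration for the same reason. The augmented pool itself is generated
once, before the loop.

## Parameters

| parameter | default | meaning |
|---|---|---|
| ω | 0.006 | perturbation factor; max relative change of any perturbed coordinate (dimensionless) |
| N/R | 2 | augmented samples per original training sample |
| λ | 0.03 | uncertainty threshold (std of a probability, so in [0, ~0.5]) |
| γ | 0.8 | confidence threshold (probability) |
| T | 10 | MC-dropout passes |
| I | 10 | selection iterations |
| E | 50 | training epochs per iteration |
| dropout | 0.3 | after the first and second hidden layers |
| lr | 0.001 | initial SGD learning rate, halved every 20 epochs |
| batch | 32 | mini-batch size |
| n_aaif | 50 | retained mRMR columns of the positional index feature |

ω is deliberately tiny: the perturbation is multiplicative, so 0.006 keeps
every augmented vector within 0.6 % of its source per coordinate —
augmentation densifies class clusters rather than exploring between them.
λ and γ jointly control selectivity; the label-consistency predicate does
most of the noise rejection, while λ and γ remove samples the model finds
ambiguous even when consistent.

## Descriptor conventions

Residue rank order is alphabetical (A, C, D, …, Y) for BPF, OPE and AAC.
Length standardization to 40 (truncate / pad with X) applies only to OPE and
the positional index feature; BPF truncates to the first 7 residues; CKSAAGP
and AAC operate on the raw sequence of length L. Padded positions are coded
−1 in OPE and 0 in the index feature (no physicochemical value is defined
for X). CKSAAGP blocks with `L ≤ k+1` are all-zero rather than undefined.

mRMR uses the MID (difference) criterion with 5 equal-frequency bins and a
plug-in discrete mutual-information estimator; ties break toward the lowest
column index, making selection deterministic. The selection is fitted on
each cross-validation training split only — never on held-out data — and the
fitted encoder state is serializable so train/test encoding is reproducible.

The bundled index table holds 22 physicochemical scales: canonical published
scales (Kyte–Doolittle hydropathy, Hopp–Woods hydrophilicity, Eisenberg and
Fauchère–Pliska hydrophobicities, Grantham polarity, Chou–Fasman secondary
structure propensities, Zimmerman bulkiness, Janin buriedness, residue mass,
volume, isoelectric point, flexibility) plus simple structural and
charge/aromaticity indicator scales. Any user table in TSV or AAindex1
flat-file form can substitute; 531 scales reproduce the classic 21,240-wide
raw positional feature.

## Numerical choices

The classifier is a pure-NumPy five-layer MLP. Three training choices were
made for numerical reasons and differ from the most literal reading of the
training recipe; each is switchable:

* **He-normal initialization, zero biases.** The network is narrow and five
  layers deep; fan-in-scaled *uniform* draws (bound `1/√fan_in`) attenuate
  backpropagated gradients by ~2.4× per layer, and at lr = 0.001 the first
  layer barely moves within 50 epochs. The ReLU-gain normal scheme
  (std `√(2/fan_in)`) preserves gradient magnitude through the stack.
* **Classical momentum 0.9.** With ~150 training vectors and batch 32, 50
  epochs is only ~250 SGD steps; plain SGD at lr = 0.001 cannot fit even
  linearly separable data in that budget. Momentum raises the effective step
  without touching the prescribed learning rate.
* **Training-fold z-scoring (on by default).** Raw descriptor scales span
  four orders of magnitude (OPE integers up to 799 vs. compositions ≤ 1),
  which ill-conditions the first layer. The scaler is fitted on training
  data only and stored with the model; `TrainConfig(standardize=False)`
  restores raw inputs.

Other numerics: softmax is computed with max-subtraction; cross-entropy
clips probabilities at 1e−12; dropout is inverted (activations scaled by
`1/(1−p)` at train and MC-inference time), so rate 0 is exactly
deterministic; the pass-summary std is forced to exactly 0 when all T passes
agree, so the zero-dropout limit gives u = 0 without floating-point dust.
Degenerate metric denominators (empty negative class, no predicted
positives, zero MCC denominator factor) map to 0 to keep the metrics total.
Model re-initialization seeds derive deterministically from (master seed,
iteration), so iterations differ but reruns are bit-identical.

## Synthetic data: what it does and does not emulate

The generator produces peptides whose classes differ by residue composition:
positives are multiplicatively tilted toward the cationic residues K/R/H
(the physicochemical signature of ACPs), negatives toward D/E/S/T, with
uniform lengths in [10, 40] by default and tilt strength `class_bias`
(multiplier `1/(1−bias)`, renormalized; bias 0 makes the classes
exchangeable). This gives descriptor-separable classes — AAC, CKSAAGP and
the index features all see composition — which is what the selection
machinery needs to be exercised end to end.

It does **not** emulate positional sequence motifs, length–class
correlations, the 90 %-identity structure of curated benchmark sets, or the
much weaker separability of real ACP vs. non-ACP data. Passing the bundled
benchmark therefore demonstrates that the mechanics are correct (masking,
scoring, selection, leakage-free cross-validation, noise exclusion), not
that any particular accuracy will be reached on real peptides — on real
data all metrics are substantially lower.

The bundled noisy benchmark uses 200 peptides (100 per class, bias 0.9),
N/R = 2, ω = 0.006, 30 % of augmented labels flipped, and five seeds; these
sizes keep a full three-regime comparison around three minutes on one CPU
while leaving each training fold (160 peptides) comparable in size to the
small public ACP benchmarks.

## Known limitations

* mRMR relevance uses equal-frequency binning; features that are constant on
  the training split get zero relevance and are effectively excluded, which
  is intended, but heavily skewed features may bin coarsely.
* The selection loop's cost is I × (training + T forward passes over the
  augmented pool); it scales linearly in N/R and I.
* Class-imbalanced source sets are sampled uniformly during augmentation, so
  the augmented pool mirrors the imbalance rather than correcting it.
* Uncertainty from MC dropout is a heuristic posterior approximation; λ is
  a threshold on a probability's std, not a calibrated error rate.
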