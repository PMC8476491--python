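# Methods

## Problem

Given a multiple sequence alignment (MSA) of a protein family with a
designated focus (wild-type) sequence, predict the effect of single
amino-acid substitutions in the focus sequence without any labelled
training data.  The premise is evolutionary: substitutions rarely observed
among homologs at a position are likely deleterious.  Because the approach
is fully unsupervised, it cannot inherit the train/test circularity that
inflates reported performance of supervised variant effect predictors.

## Generative model

Sequence probability is factorized autoregressively,

    p(x) = prod_i p(x_i | x_<i, theta),

so exact log-likelihoods are sums of per-position conditional
log-probabilities.  The network computing the conditionals is a temporal
convolutional architecture: an embedding layer over the residue alphabet
(20 canonical amino acids, a gap code, an unknown code, plus an input-only
begin-of-sequence token), a stack of dilated causal convolution blocks with
residual connections, a causally masked attention layer, and a fully
connected output layer producing logits at every position.  Causality is
structural: the input stream is the target sequence shifted right by one
position, convolutions only reach backwards, and attention masks future
positions, so the conditional at position i never sees x_i.

Because the model consumes *aligned* columns, a learned positional
embedding is added to the input embedding.  Without it a convolutional
model can only infer which column it is predicting from the content of the
preceding context (or from distance to the start token, within the
receptive field), which makes the conditionals needlessly
context-sensitive; with it, per-column conditional distributions are
directly representable.  This markedly improves the recovery of
site-specific profiles on synthetic families.

Defaults: embedding 24, 32 convolution channels, kernel 2 with dilations
(1, 2, 4, 8) (receptive field 16, with attention providing full-history
context beyond it), one attention head of width 32.  All sizes are
configurable; the method, not one fixed architecture, is the point.  The
unknown code is excluded as a prediction target (its logit is treated as
-inf when distributions are formed), since unknowns are annotation
artifacts rather than states of nature; training positions whose target is
unknown are excluded from the loss.

The network, its backpropagation and the Adam optimizer are implemented
directly in NumPy (float32 parameters; float64 for likelihood sums at
scoring time).  Gradients are verified against finite differences in the
test suite.

## Alignment preprocessing

* Columns with **more than 30%** gap symbols are dropped (a column at
  exactly 30% is kept).  Variants addressing dropped columns, positions
  where the focus sequence itself has a gap, or positions whose stated
  wild-type residue disagrees with the focus sequence are excluded from
  prediction, with the reason reported.
* A2M input is normalized by removing insert states (lowercase and `.`);
  `.` in plain FASTA is read as a gap; non-canonical residue letters
  (B, J, O, U, Z, X) collapse onto the unknown code.
* Each sequence is weighted 1/(number of alignment members within 80%
  identity over retained columns, itself included); the weight sum n_eff
  is the effective number of sequences.  Identity counts gaps as symbols.
  The 80% threshold is the convention of the alignment-modelling
  literature; the original description states only that weights are based
  on sequence similarity, so the threshold is exposed as a parameter.
* Weights enter training through minibatch sampling probabilities, not as
  loss multipliers, so a sequence's influence is counted exactly once.

## Born-again training

Stage one trains the teacher by minimizing the label loss: the mean
per-position cross entropy between each training sequence and the model's
softmax output (the negative conditional log-likelihood).  Stage two
trains a student of *identical capacity* on the unweighted sum of the
label loss and the teacher loss: the cross entropy between the student's
distribution and the teacher's temperature-softened distribution,

    p_i = exp(z_i / T) / sum_j exp(z_j / T),     T = 4 by default.

The student is freshly initialized (different seed stream), and the
teacher is frozen (verified by parameter hash).  Both distillation
conventions are supported: by default the student's distribution is
softened at the same temperature as the teacher's (the standard
formulation); a flag restores the literal reading in which the student's
ordinary softmax is penalized.  No T^2 gradient rescaling is applied, and
the two loss terms are summed without a mixing coefficient.

Optimization uses Adam with the two-level schedule: learning rate 0.001
while the iteration index is below 3000 and 0.0001 from iteration 3000
onwards (the boundary iteration takes the lower rate).  Reference
schedules are 500,000 iterations per stage at batch size 128 (published
setting) or 200,000 (server setting); desk-scale runs in this package use
2,000-5,000 iterations, which suffices for the synthetic families below.
Weight decay, dropout and gradient clipping are available nowhere: the
reference description does not mention them and defaults are off.

## Variant scoring

For a scorable variant, the raw score is the log-probability ratio

    score = log p(x_mut | theta) - log p(x_wt | theta)

with x_mut the focus row carrying a single retained-column substitution;
lower scores are more deleterious.  Scores are standardized into z-scores
against all 19 x L' possible substitutions of the focus sequence
(population standard deviation, so the set has mean 0 and std 1 exactly).

Calibration bins a labelled variant set into equal-width z-score intervals
(default 20 bins, spanning the observed z range); each bin's deleterious
fraction is the probability of deleteriousness for any variant landing in
it.  Empty bins inherit the nearest non-empty bin's proportion (lower-z
side preferred on ties); out-of-range z-scores clamp to the end bins.  The
label cutoff is the bin edge maximizing the accuracy of the rule
"z < cutoff is deleterious" (smallest maximizing edge on ties; a z equal
to the cutoff is benign).  No monotonicity is enforced on the per-bin
proportions.

## Evaluation metrics

ROC-AUC uses the rank (Mann-Whitney U) definition with ties counting one
half, on -z as the deleteriousness score; PR-AUC is average precision (a
step integral over the score-sorted sweep, no linear interpolation).  The
seven label-based metrics follow the standard confusion-matrix formulas;
degenerate denominators (MCC with a zero factor, precision/NPV with an
empty denominator, F-score at precision+recall = 0) return 0 so reports
are always total.  `reconstruct_confusion` inverts rates printed at three
decimals (half-up rounding) back to the unique integer confusion matrix on
known class sizes; it raises if zero or several matrices are consistent.

## Synthetic families

The generator draws a site profile per column from a symmetric
Dirichlet(alpha) and samples members independently per column: alpha = 0.1
(the default) yields strongly conserved columns in which one to three
residues dominate.  The consensus is prepended as the gap-free focus row.
Because sites are independent, the exact effect of a substitution is
log pi(mut) - log pi(wt), which is exactly what the model's score
estimates — the generator is therefore a closed-form oracle, and an
"ideal model" whose conditionals equal the profiles reproduces the true
effects to machine precision (used as a scoring-stack oracle in tests).

Redundancy is emulated by copying founder sequences with light per-site
resampling noise (50 founders x 20 copies at rate 0.01 in the recovery
fixture, with alpha = 1 so founders fall below the identity threshold of
each other); per-column gap injection exercises the gap filter.  Real
alignments additionally contain covariation between sites, phylogenetic
correlation and alignment errors, none of which the generator produces —
passing recovery tests shows the pipeline estimates site profiles
correctly, not that it captures epistasis.

Desk-scale study conditions used by the tests and the acceptance script:
families of 2,000 sequences of length 40 at alpha = 0.1, 3,000 training
iterations per stage at batch size 128.  Under these conditions the
teacher's Spearman correlation between variant scores and ground-truth
log-ratios is about 0.81-0.85 depending on the seed, and the born-again
student consistently matches or slightly exceeds it; about half of the 760 possible variants involve residues never
observed in a 2,000-sequence sample, which bounds attainable rank
correlation (an empirical per-column frequency estimator with pseudocounts
reaches ~0.87 under the same conditions).

## Numerical and design notes

* Tempered softmax and log-softmax are computed with max-shift
  stabilization; the tempered softmax is invariant to logit shifts.
* Minibatch sampling, initialization and training are reproducible from
  (seed, data, config); identical seeds give identical parameters and logs.
* Checkpoints are single `.npz` archives with the model config and a
  manifest (seed, column-map hash) embedded; scoring refuses a checkpoint
  whose column map does not match the alignment.
* The z-score set must contain at least two distinct scores (a degenerate
  model raises); calibration requires both classes and at least two
  distinct z values.
* Ties in `select_cutoff` and in the empty-bin fallback are resolved
  deterministically (smallest edge; lower-z bin).

## Known limitations

* Single substitutions only; no indels or multi-site variants.
* The model scores only variants at retained (well-aligned, focus-occupied)
  columns — the same restriction the original pipeline reports.
* The site-independent synthetic oracle cannot validate the attention
  layer's ability to exploit covariation; it validates the scoring stack
  and profile recovery.
* Desk-scale iteration counts are far below the published schedules; the
  published benchmark numbers (ROC-AUC 0.883 on 1709+1709 human variants)
  require the original large alignment collection and labelled human
  variant sets and are not reproducible here; the package instead verifies
  the internal consistency of the published metric table exactly.
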