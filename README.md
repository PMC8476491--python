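# banvep

Unsupervised prediction of the deleteriousness of single amino-acid
variants from the multiple sequence alignment (MSA) of a protein family,
using an autoregressive generative model improved by born-again-network
(BAN) knowledge distillation.

The package is for computational biologists who have an aligned protein
family with a designated wild-type (focus) sequence and want per-variant
effect predictions without any labelled training data — and therefore
without the train/test circularity that inflates supervised predictors.

## Method

An autoregressive network (embedding with positional encodings, dilated
causal convolutions, causally masked attention, softmax output) models the
probability of an aligned sequence as

```
p(x | θ) = ∏ᵢ p(xᵢ | x₍<ᵢ₎, θ)
```

It is trained in two stages on the gap-filtered, redundancy-reweighted
alignment.  First a **teacher** minimizes the label loss (cross entropy
between each training sequence and its softmax output).  Then a **student
of identical capacity** — the born-again network — minimizes the sum of the
label loss and the teacher loss, the cross entropy against the teacher's
temperature-softened distribution pᵢ = exp(zᵢ/T) / Σⱼ exp(zⱼ/T) with
T = 4.  A variant x^mut of the wild type x^wt is scored by

```
score = log p(x^mut | θ) − log p(x^wt | θ)
```

(lower = more deleterious), standardized into a z-score against all 19·L′
possible substitutions of the focus sequence, converted into a probability
of deleteriousness by equal-width z-score binning of a labelled calibration
set, and thresholded into a deleterious/benign label at the
accuracy-maximizing bin edge.  Nine evaluation metrics (ROC-AUC, PR-AUC,
accuracy, MCC, precision, specificity, sensitivity, F-score, NPV) are
provided.  See `docs/methods.md` for assumptions, parameters and
limitations.

## Worked example

Simulate a conserved synthetic family (known ground truth), train at desk
scale, and score variants:

```bash
banvep simulate --config example.yaml --seed 3 --outdir sim
banvep train --alignment sim/family.fasta --config example.yaml --seed 3 --outdir run
banvep score --alignment sim/family.fasta --checkpoint run/student.npz \
             --variants variants.txt --outdir preds
```

with `example.yaml`:

```yaml
family:   {length: 12, n_sequences: 300, alpha: 0.1}
training: {iterations_teacher: 2000, iterations_student: 2000, batch_size: 128}
```

and `variants.txt` naming one variant per line in `A123V` notation
(wild-type residue, 1-based focus position, mutant residue) — here
`P12G`, `L8K` and `A99V` against the simulated focus sequence
`PWTVNPSLHGNP`.  The run prints the preprocessing and training summary to
stderr:

```
INFO banvep: alignment: 301 sequences, 12/12 columns kept, n_eff=279.6
INFO banvep: teacher trained: final label loss 0.8558
INFO banvep: student trained: final label 0.9858 + teacher 2.0990
INFO banvep: scored 2 variants (1 excluded)
```

and `preds/predictions.tsv` contains one row per requested variant:

```
variant	log_prob_score	z_score	prob_deleterious	predicted_label	status
P12G	-47.660114	-3.509620			scored
L8K	-0.322322	1.495480			scored
A99V					excluded(out_of_range)
```

`P12G` replaces a strongly conserved proline: the mutant sequence is about
e⁻⁴⁸ as probable as the wild type and its z-score (−3.51) sits far in the
deleterious tail of the 228-variant score distribution.  `L8K` lands at a
variable position and scores near the wild type (z = +1.50).  `A99V` lies
outside the 12-residue focus sequence and is excluded with the reason
rather than silently dropped.  The probability and label columns fill in
when a calibration table (from `banvep calibrate`, given a labelled
variant set) is passed via `--calibration`.

The same workflow is available as a library (`banvep.sample_family`,
`banvep.train_teacher`, `banvep.train_student`,
`banvep.zscore_all_variants`, ...).

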