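"""Two-stage born-again-network training of the sequence model.

Stage one trains the teacher on the reweighted alignment by minimizing the
label loss: the per-position cross entropy between each training sequence
and the model's softmax output (equivalently, the mean negative conditional
log-likelihood).  Stage two trains a student of identical capacity against
the sum of the label loss and the teacher loss: the cross entropy between
the student's output distribution and the teacher's temperature-softened
("dark knowledge") distribution.  The teacher is frozen throughout stage
two; the two loss terms are summed with no mixing coefficient.

Sequence weights enter through minibatch sampling (rows drawn with
probability proportional to their weight), not as loss multipliers, so a
sequence's influence is counted exactly once.

The learning rate follows a two-level schedule: a high rate for the first
3000 iterations, then a lower rate for the remainder of training.  The
published schedule runs 500,000 iterations per stage at batch size 128 with
rates 0.001 / 0.0001 and temperature 4; desk-scale runs shorten the
iteration count only.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .alignment import EncodedMsa, SequenceWeights
from .model import (
    AutoregressiveModel,
    ConfigurationError,
    PositionalDistributions,
    backward,
    forward,
    log_softmax,
    tempered_softmax,
)

PUBLISHED_ITERATIONS = 500_000
SERVER_ITERATIONS = 200_000


class TrainingDivergenceError(RuntimeError):
    def __init__(self, iteration: int):
        super().__init__(f"non-finite loss at iteration {iteration}")
        self.iteration = iteration


@dataclass(frozen=True)
class TrainingConfig:
    temperature: float = 4.0
    iterations_teacher: int = 3000
    iterations_student: int = 3000
    batch_size: int = 128
    lr_high: float = 1e-3
    lr_low: float = 1e-4
    lr_switch_iteration: int = 3000
    seed: int = 0
    distill_student_temperature: bool = True
    log_every: int = 100

    def __post_init__(self) -> None:
        if not self.temperature > 0:
            raise ValueError("temperature must be positive")
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")
        if self.iterations_teacher < 1 or self.iterations_student < 1:
            raise ValueError("iteration counts must be >= 1")


def lr_at(config: TrainingConfig, iteration: int) -> float:
    """Learning rate at a 0-based iteration index.

    The high rate applies while the iteration index is below the switch
    point; from the switch iteration onwards the low rate applies.
    """
    return config.lr_high if iteration < config.lr_switch_iteration else config.lr_low


@dataclass
class TrainingLog:
    records: list[dict] = field(default_factory=list)

    def append(self, **kv) -> None:
        self.records.append(kv)

    def column(self, name: str) -> list:
        return [r[name] for r in self.records]

    def at_iteration(self, iteration: int) -> dict:
        for r in self.records:
            if r["iteration"] == iteration:
                return r
        raise KeyError(f"iteration {iteration} not logged")

    def write_tsv(self, path: str | Path) -> None:
        cols = ["iteration", "label_loss", "teacher_loss", "lr"]
        with open(path, "w") as fh:
            fh.write("\t".join(cols) + "\n")
            for r in self.records:
                fh.write(
                    "\t".join(
                        "" if r.get(c) is None else f"{r[c]:.6g}"
                        if isinstance(r.get(c), float)
                        else str(r.get(c))
                        for c in cols
                    )
                    + "\n"
                )


# --- losses ---------------------------------------------------------------


def sample_minibatch(
    encoded: EncodedMsa,
    weights: SequenceWeights,
    batch_size: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Draw rows with replacement, with probability proportional to weight."""
    if batch_size < 1:
        raise ValueError("batch_size must be >= 1")
    p = weights.w / weights.w.sum()
    idx = rng.choice(encoded.n_rows, size=batch_size, p=p)
    return encoded.matrix[idx].astype(np.int64)


def label_loss(dists: PositionalDistributions, target: np.ndarray) -> float:
    """Mean negative conditional log-probability of the target sequence."""
    target = np.asarray(target)
    if target.size != dists.log_probs.shape[0]:
        raise ValueError("target length does not match distributions")
    return float(-dists.log_probs[np.arange(target.size), target].mean())


def teacher_loss(
    student_logits: np.ndarray,
    teacher_logits: np.ndarray,
    T: float,
    temper_student: bool = True,
) -> float:
    """Cross entropy of the student against the softened teacher distribution.

    The teacher's logits are always softened at temperature T; by default
    the student's distribution is softened at the same temperature (the
    standard distillation formulation), with ``temper_student=False`` giving
    the variant where the student's ordinary softmax is penalized instead.
    """
    if not T > 0:
        raise ValueError("temperature must be positive")
    if student_logits.shape != teacher_logits.shape:
        raise ValueError("logit shapes disagree")
    p = tempered_softmax(np.asarray(teacher_logits, dtype=np.float64), T)
    q_log = log_softmax(
        np.asarray(student_logits, dtype=np.float64) / (T if temper_student else 1.0)
    )
    ce = -np.where(p > 0, p * q_log, 0.0).sum(axis=-1)
    return float(ce.mean())


# --- batched loss/gradient internals (float32, masked alphabet) ----------


def _masked32(logits: np.ndarray, model: AutoregressiveModel) -> np.ndarray:
    codes = model.config.resolved_masked_codes()
    if codes:
        logits = logits.copy()
        logits[..., list(codes)] = -1e9
    return logits


def _softmax32(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def _label_loss_grad(logits, targets, model):
    """Masked-alphabet NLL over a batch; positions with masked targets are
    excluded from the mean (they carry no probability mass by construction)."""
    codes = model.config.resolved_masked_codes()
    logits = _masked32(logits, model)
    B, L, K = logits.shape
    valid = np.ones((B, L), dtype=bool)
    for c in codes:
        valid &= targets != c
    n_valid = max(int(valid.sum()), 1)
    probs = _softmax32(logits)
    z = logits - logits.max(axis=-1, keepdims=True)
    logp = z - np.log(np.exp(z).sum(axis=-1, keepdims=True))
    ii, jj = np.ogrid[:B, :L]
    loss = float(-(logp[ii, jj, targets] * valid).sum() / n_valid)
    dlogits = probs
    dlogits[ii, jj, targets] -= 1.0
    dlogits *= (valid / n_valid)[..., None]
    return loss, dlogits.astype(logits.dtype)


def _teacher_loss_grad(student_logits, teacher_logits, model, T, temper_student):
    sl = _masked32(student_logits, model)
    tl = _masked32(teacher_logits, model)
    B, L, _ = sl.shape
    p = _softmax32(tl / T)
    q_logits = sl / T if temper_student else sl
    q = _softmax32(q_logits)
    z = q_logits - q_logits.max(axis=-1, keepdims=True)
    q_log = z - np.log(np.exp(z).sum(axis=-1, keepdims=True))
    loss = float(-np.where(p > 0, p * q_log, 0.0).sum() / (B * L))
    dlogits = (q - p) / (B * L)
    if temper_student:
        dlogits /= T
    return loss, dlogits.astype(sl.dtype)


class Adam:
    """Adaptive-moment stochastic gradient optimizer."""

    def __init__(self, params, beta1=0.9, beta2=0.999, eps=1e-8):
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.t = 0
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}

    def step(self, params, grads, lr):
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        corr1 = 1 - b1**self.t
        corr2 = 1 - b2**self.t
        for k, g in grads.items():
            m = self.m[k]
            v = self.v[k]
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * g * g
            params[k] -= lr * (m / corr1) / (np.sqrt(v / corr2) + self.eps)


# --- training loops -------------------------------------------------------


def train_teacher(
    model: AutoregressiveModel,
    encoded: EncodedMsa,
    weights: SequenceWeights,
    config: TrainingConfig,
) -> tuple[AutoregressiveModel, TrainingLog]:
    """Stage one: minimize the label loss on weighted minibatches."""
    rng = np.random.default_rng(config.seed)
    opt = Adam(model.params)
    log = TrainingLog()
    n_iter = config.iterations_teacher
    for it in range(n_iter):
        batch = sample_minibatch(encoded, weights, config.batch_size, rng)
        logits, cache = forward(model, batch, want_cache=True)
        loss, dlogits = _label_loss_grad(logits, batch, model)
        if not np.isfinite(loss):
            raise TrainingDivergenceError(it)
        grads = backward(model, cache, dlogits)
        opt.step(model.params, grads, lr_at(config, it))
        if it % config.log_every == 0 or it == n_iter - 1:
            log.append(
                iteration=it, label_loss=loss, teacher_loss=None,
                lr=lr_at(config, it),
            )
    return model, log


def train_student(
    student: AutoregressiveModel,
    teacher: AutoregressiveModel,
    encoded: EncodedMsa,
    weights: SequenceWeights,
    config: TrainingConfig,
) -> tuple[AutoregressiveModel, TrainingLog]:
    """Stage two: label loss plus softened-teacher cross entropy.

    The student must share the teacher's architecture (equal capacity is the
    premise of born-again training) and the teacher's parameters are frozen;
    a parameter hash taken before and after training verifies this.
    """
    if student.config != teacher.config:
        raise ConfigurationError("student and teacher configs must match")
    teacher_hash = teacher.params_hash()
    rng = np.random.default_rng([config.seed, 1])
    opt = Adam(student.params)
    log = TrainingLog()
    n_iter = config.iterations_student
    for it in range(n_iter):
        batch = sample_minibatch(encoded, weights, config.batch_size, rng)
        s_logits, cache = forward(student, batch, want_cache=True)
        t_logits = forward(teacher, batch)
        l_loss, d_label = _label_loss_grad(s_logits, batch, student)
        t_loss, d_teach = _teacher_loss_grad(
            s_logits, t_logits, student, config.temperature,
            config.distill_student_temperature,
        )
        total = l_loss + t_loss
        if not np.isfinite(total):
            raise TrainingDivergenceError(it)
        grads = backward(student, cache, d_label + d_teach)
        opt.step(student.params, grads, lr_at(config, it))
        if it % config.log_every == 0 or it == n_iter - 1:
            log.append(
                iteration=it, label_loss=l_loss, teacher_loss=t_loss,
                lr=lr_at(config, it),
            )
    assert teacher.params_hash() == teacher_hash, "teacher parameters changed"
    return student, log
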