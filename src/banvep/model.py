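"""Autoregressive generative model of aligned protein sequences.

The model factorizes the probability of an aligned sequence as a product of
per-position conditionals p(x_i | x_<i), so the exact log-likelihood of any
sequence is a sum of conditional log-probabilities.  The architecture is a
temporal convolutional network: an embedding layer, a stack of dilated
causal convolution blocks with residual connections, a causally masked
attention layer, and a fully connected output layer producing logits over
the residue alphabet at every position.

Causality is structural: the input is shifted right by one position behind a
begin-of-sequence token, convolutions only look backwards in the shifted
stream, and the attention layer masks future positions, so the conditional
at position i can never see x_i or anything after it.

The network, its backpropagation, and the (separate) Adam optimizer are
implemented directly in NumPy; parameters live in a flat dict of arrays.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Mapping

import numpy as np

from .alignment import ALPHABET_SIZE, UNKNOWN_CODE

_NEG = np.float64(-np.inf)


class ConfigurationError(ValueError):
    pass


@dataclass(frozen=True)
class ModelConfig:
    """Architecture hyperparameters.

    ``masked_codes`` lists alphabet codes that are never predicted (their
    logits are taken as -inf whenever distributions are formed); by default
    the unknown-residue code is masked for the protein alphabet and nothing
    is masked for other alphabet sizes.
    """

    alphabet_size: int = ALPHABET_SIZE
    seq_length: int = 0
    embedding_dim: int = 24
    conv_channels: int = 32
    kernel_size: int = 2
    dilation_schedule: tuple[int, ...] = (1, 2, 4, 8)
    attention_heads: int = 1
    attention_dim: int = 32
    positional_embedding: bool = True
    masked_codes: tuple[int, ...] | None = None

    def __post_init__(self) -> None:
        dims = (
            self.alphabet_size,
            self.seq_length,
            self.embedding_dim,
            self.conv_channels,
            self.kernel_size,
            self.attention_heads,
            self.attention_dim,
        )
        if any(d < 1 for d in dims):
            raise ConfigurationError("all model dimensions must be positive")
        if any(d < 1 for d in self.dilation_schedule):
            raise ConfigurationError("dilations must be positive")
        if self.attention_dim % self.attention_heads != 0:
            raise ConfigurationError("attention_dim must divide into heads")

    @property
    def receptive_field(self) -> int:
        """Number of trailing positions the convolution stack can see."""
        return 1 + (self.kernel_size - 1) * sum(self.dilation_schedule)

    def resolved_masked_codes(self) -> tuple[int, ...]:
        if self.masked_codes is not None:
            return self.masked_codes
        if self.alphabet_size == ALPHABET_SIZE:
            return (UNKNOWN_CODE,)
        return ()

    @property
    def bos_code(self) -> int:
        """Begin-of-sequence code; an extra embedding row, never an output."""
        return self.alphabet_size


@dataclass
class AutoregressiveModel:
    params: dict[str, np.ndarray]
    config: ModelConfig

    def n_parameters(self) -> int:
        return int(sum(p.size for p in self.params.values()))

    def copy(self) -> "AutoregressiveModel":
        return AutoregressiveModel(
            params={k: v.copy() for k, v in self.params.items()},
            config=self.config,
        )

    def params_hash(self) -> str:
        import hashlib

        h = hashlib.sha256()
        for k in sorted(self.params):
            h.update(k.encode())
            h.update(np.ascontiguousarray(self.params[k]).tobytes())
        return h.hexdigest()


@dataclass
class PositionalDistributions:
    """Per-position conditional log-probabilities, one row per position."""

    log_probs: np.ndarray  # (L, K)


def build_model(
    config: ModelConfig, rng_seed: int, dtype=np.float32
) -> AutoregressiveModel:
    """Deterministically initialize a model from a seed."""
    rng = np.random.default_rng(rng_seed)
    K, E, C = config.alphabet_size, config.embedding_dim, config.conv_channels
    A = config.attention_dim

    def glorot(shape):
        limit = np.sqrt(6.0 / (shape[0] + shape[1]))
        return rng.uniform(-limit, limit, size=shape).astype(dtype)

    def he(shape):
        return (rng.standard_normal(shape) * np.sqrt(2.0 / shape[0])).astype(dtype)

    params: dict[str, np.ndarray] = {}
    params["emb"] = (rng.standard_normal((K + 1, E)) * 0.05).astype(dtype)
    if config.positional_embedding:
        if config.seq_length < 1:
            raise ConfigurationError(
                "positional embeddings need a fixed seq_length"
            )
        # columns of an aligned family are positional by nature; a learned
        # per-column embedding lets conditionals be column-specific instead
        # of inferred from context content
        params["pos"] = (
            rng.standard_normal((config.seq_length, E)) * 0.05
        ).astype(dtype)
    params["in_w"] = glorot((E, C))
    params["in_b"] = np.zeros(C, dtype=dtype)
    for layer in range(len(config.dilation_schedule)):
        for tap in range(config.kernel_size):
            params[f"conv{layer}_w{tap}"] = he((C, C)) / np.sqrt(config.kernel_size)
        params[f"conv{layer}_b"] = np.zeros(C, dtype=dtype)
    for name in ("att_wq", "att_wk", "att_wv"):
        params[name] = glorot((C, A))
    params["att_wo"] = glorot((A, C))
    params["out_w"] = (rng.standard_normal((C, K)) * 0.01).astype(dtype)
    params["out_b"] = np.zeros(K, dtype=dtype)
    return AutoregressiveModel(params=params, config=config)


# --- forward / backward ---------------------------------------------------


def _lag(h: np.ndarray, steps: int) -> np.ndarray:
    """Shift a (B, L, C) tensor ``steps`` positions later, zero-padding."""
    if steps == 0:
        return h
    out = np.zeros_like(h)
    out[:, steps:] = h[:, :-steps]
    return out


def _unlag(g: np.ndarray, steps: int) -> np.ndarray:
    """Adjoint of :func:`_lag`."""
    if steps == 0:
        return g
    out = np.zeros_like(g)
    out[:, :-steps] = g[:, steps:]
    return out


def forward(
    model: AutoregressiveModel, x: np.ndarray, want_cache: bool = False
):
    """Compute logits (B, L, K) for integer sequences ``x`` of shape (B, L).

    The output at position i is conditioned on a begin-of-sequence token and
    the symbols at positions < i only.
    """
    cfg, p = model.config, model.params
    x = np.atleast_2d(np.asarray(x))
    B, L = x.shape
    if cfg.seq_length and L != cfg.seq_length:
        raise ValueError(f"sequence length {L} != model length {cfg.seq_length}")
    inp = np.empty((B, L), dtype=np.int64)
    inp[:, 0] = cfg.bos_code
    inp[:, 1:] = x[:, :-1]

    X = p["emb"][inp]                       # (B, L, E)
    if cfg.positional_embedding:
        X = X + p["pos"]
    H = X @ p["in_w"] + p["in_b"]           # (B, L, C)
    h_inputs, z_list = [], []
    for layer, d in enumerate(cfg.dilation_schedule):
        h_inputs.append(H)
        Z = p[f"conv{layer}_b"].copy()
        Z = Z + sum(
            _lag(H, tap * d) @ p[f"conv{layer}_w{tap}"]
            for tap in range(cfg.kernel_size)
        )
        z_list.append(Z)
        H = H + np.maximum(Z, 0)

    # causally masked multi-head attention
    nh = cfg.attention_heads
    hd = cfg.attention_dim // nh
    scale = 1.0 / np.sqrt(hd)

    def split(t):  # (B, L, A) -> (B, nh, L, hd)
        return t.reshape(B, L, nh, hd).transpose(0, 2, 1, 3)

    Ha = H
    Q, Kt, V = (split(Ha @ p[n]) for n in ("att_wq", "att_wk", "att_wv"))
    S = np.matmul(Q, Kt.transpose(0, 1, 3, 2)) * scale  # (B, nh, L, L)
    causal = np.triu(np.ones((L, L), dtype=bool), k=1)
    S = np.where(causal, np.array(-1e30, dtype=S.dtype), S)
    S = S - S.max(axis=-1, keepdims=True)
    P = np.exp(S)
    P /= P.sum(axis=-1, keepdims=True)
    O = np.matmul(P, V)                                  # (B, nh, L, hd)
    O_merged = O.transpose(0, 2, 1, 3).reshape(B, L, cfg.attention_dim)
    Hf = Ha + O_merged @ p["att_wo"]

    logits = Hf @ p["out_w"] + p["out_b"]
    if not want_cache:
        return logits
    cache = dict(
        inp=inp, X=X, h_inputs=h_inputs, z_list=z_list, Ha=Ha,
        Q=Q, Kt=Kt, V=V, P=P, O_merged=O_merged, Hf=Hf, scale=scale, shape=(B, L),
    )
    return logits, cache


def backward(
    model: AutoregressiveModel, cache: Mapping, dlogits: np.ndarray
) -> dict[str, np.ndarray]:
    """Gradients of a scalar loss w.r.t. all parameters, given dL/dlogits."""
    cfg, p = model.config, model.params
    B, L = cache["shape"]
    C, E = cfg.conv_channels, cfg.embedding_dim
    nh = cfg.attention_heads
    hd = cfg.attention_dim // nh
    grads: dict[str, np.ndarray] = {}

    def mm(a, b):  # (B,L,m)^T @ (B,L,n) summed over batch and position
        return a.reshape(-1, a.shape[-1]).T @ b.reshape(-1, b.shape[-1])

    Hf = cache["Hf"]
    grads["out_w"] = mm(Hf, dlogits)
    grads["out_b"] = dlogits.sum(axis=(0, 1))
    dHf = dlogits @ p["out_w"].T

    # attention block
    dHa = dHf.copy()
    dO_merged = dHf @ p["att_wo"].T
    grads["att_wo"] = mm(cache["O_merged"], dHf)
    dO = dO_merged.reshape(B, L, nh, hd).transpose(0, 2, 1, 3)
    P, Q, Kt, V = cache["P"], cache["Q"], cache["Kt"], cache["V"]
    dP = np.matmul(dO, V.transpose(0, 1, 3, 2))
    dV = np.matmul(P.transpose(0, 1, 3, 2), dO)
    dS = P * (dP - (dP * P).sum(axis=-1, keepdims=True))
    dS *= cache["scale"]
    dQ = np.matmul(dS, Kt)
    dKt = np.matmul(dS.transpose(0, 1, 3, 2), Q)

    def merge(t):  # (B, nh, L, hd) -> (B, L, A)
        return t.transpose(0, 2, 1, 3).reshape(B, L, nh * hd)

    Ha = cache["Ha"]
    for name, dT in (("att_wq", dQ), ("att_wk", dKt), ("att_wv", dV)):
        dT_m = merge(dT)
        grads[name] = mm(Ha, dT_m)
        dHa += dT_m @ p[name].T

    # conv stack, reversed
    dH = dHa
    for layer in reversed(range(len(cfg.dilation_schedule))):
        d = cfg.dilation_schedule[layer]
        Z = cache["z_list"][layer]
        H_in = cache["h_inputs"][layer]
        dZ = dH * (Z > 0)
        grads[f"conv{layer}_b"] = dZ.sum(axis=(0, 1))
        dH_new = dH.copy()
        for tap in range(cfg.kernel_size):
            lagged = _lag(H_in, tap * d)
            grads[f"conv{layer}_w{tap}"] = mm(lagged, dZ)
            dH_new += _unlag(dZ @ p[f"conv{layer}_w{tap}"].T, tap * d)
        dH = dH_new

    grads["in_w"] = mm(cache["X"], dH)
    grads["in_b"] = dH.sum(axis=(0, 1))
    dX = dH @ p["in_w"].T
    if cfg.positional_embedding:
        grads["pos"] = dX.sum(axis=0)
    demb = np.zeros_like(p["emb"])
    np.add.at(demb, cache["inp"].ravel(), dX.reshape(-1, E))
    grads["emb"] = demb
    return grads


# --- distributions and likelihoods ---------------------------------------


def mask_logits(logits: np.ndarray, config: ModelConfig) -> np.ndarray:
    """Set never-predicted codes to -inf so they get zero probability."""
    codes = config.resolved_masked_codes()
    if not codes:
        return np.asarray(logits, dtype=np.float64)
    out = np.asarray(logits, dtype=np.float64).copy()
    out[..., list(codes)] = _NEG
    return out


def log_softmax(logits: np.ndarray) -> np.ndarray:
    z = np.asarray(logits, dtype=np.float64)
    zmax = np.max(z, axis=-1, keepdims=True)
    shifted = z - zmax
    with np.errstate(divide="ignore"):
        return shifted - np.log(np.exp(shifted).sum(axis=-1, keepdims=True))


def conditional_log_probs(
    model: AutoregressiveModel, seq: np.ndarray
) -> PositionalDistributions:
    """Per-position conditional log distributions for one encoded sequence."""
    seq = np.asarray(seq)
    if seq.ndim != 1:
        raise ValueError("expected a single encoded sequence")
    logits = forward(model, seq[None, :])[0]
    return PositionalDistributions(
        log_probs=log_softmax(mask_logits(logits, model.config))
    )


def sequence_log_likelihood(model: AutoregressiveModel, seq: np.ndarray) -> float:
    """Exact log p(seq) in nats: the sum of conditional log-probabilities."""
    seq = np.asarray(seq)
    dists = conditional_log_probs(model, seq)
    return float(dists.log_probs[np.arange(seq.size), seq].sum())


def batch_log_likelihoods(model: AutoregressiveModel, seqs: np.ndarray) -> np.ndarray:
    """Log-likelihood of each row of an integer matrix (N, L)."""
    seqs = np.atleast_2d(np.asarray(seqs))
    out = np.empty(seqs.shape[0], dtype=np.float64)
    chunk = max(1, 2**20 // max(1, seqs.shape[1] * model.config.alphabet_size))
    for start in range(0, seqs.shape[0], chunk):
        block = seqs[start : start + chunk]
        logp = log_softmax(mask_logits(forward(model, block), model.config))
        idx = np.ogrid[: block.shape[0], : block.shape[1]]
        out[start : start + chunk] = logp[idx[0], idx[1], block].sum(axis=1)
    return out


def tempered_softmax(logits: np.ndarray, T: float) -> np.ndarray:
    """Softmax of logits divided by a temperature T > 0.

    Higher temperatures soften the distribution (entropy is non-decreasing
    in T); T=1 recovers the ordinary softmax.  Invariant to adding a
    constant to all logits.
    """
    if not T > 0:
        raise ValueError("temperature must be positive")
    z = np.asarray(logits, dtype=np.float64) / T
    z = z - z.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


# --- checkpointing --------------------------------------------------------


def save_checkpoint(
    model: AutoregressiveModel, path: str | Path, manifest: dict | None = None
) -> None:
    """Save parameters plus JSON-embedded config/manifest to one .npz file."""
    meta = dict(asdict(model.config))
    payload = {f"param/{k}": v for k, v in model.params.items()}
    payload["__config__"] = np.frombuffer(
        json.dumps(meta).encode(), dtype=np.uint8
    )
    payload["__manifest__"] = np.frombuffer(
        json.dumps(manifest or {}).encode(), dtype=np.uint8
    )
    with open(path, "wb") as fh:
        np.savez(fh, **payload)


def load_checkpoint(path: str | Path) -> tuple[AutoregressiveModel, dict]:
    with np.load(path) as data:
        meta = json.loads(bytes(data["__config__"]).decode())
        manifest = json.loads(bytes(data["__manifest__"]).decode())
        for key in ("dilation_schedule", "masked_codes"):
            if meta.get(key) is not None:
                meta[key] = tuple(meta[key])
        config = ModelConfig(**meta)
        params = {
            k[len("param/"):]: data[k] for k in data.files if k.startswith("param/")
        }
    return AutoregressiveModel(params=params, config=config), manifest
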