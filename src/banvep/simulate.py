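"""Synthetic protein families with known ground-truth variant effects.

The generator draws a site-specific amino-acid profile for every column
from a symmetric Dirichlet(alpha) — small alpha gives strongly conserved
columns — and samples family members independently per column from those
profiles.  Because sites are independent, the exact probability of any
sequence is the product of its column probabilities, so the effect of a
substitution has the closed form

    true_effect(pos, wt -> mut) = log pi_pos(mut) - log pi_pos(wt),

exactly the quantity the model's log-probability score estimates.  This
makes the generator a ground-truth oracle for end-to-end recovery tests.

Redundancy (founder sequences copied with light per-site noise) emulates
the phylogenetic over-representation that sequence reweighting corrects;
per-column gap injection emulates poorly covered alignment regions for the
gap-filter logic.  Real alignments additionally contain covariation between
sites and phylogenetic correlation, which this generator deliberately
omits.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .alignment import AMINO_ACIDS, GAP, Msa, Variant
from .scoring import BENIGN, DELETERIOUS


@dataclass(frozen=True)
class Redundancy:
    n_founders: int
    copies_per_founder: int
    copy_mutation_rate: float

    def __post_init__(self) -> None:
        if not 0 <= self.copy_mutation_rate <= 1:
            raise ValueError("copy_mutation_rate must be in [0, 1]")


@dataclass(frozen=True)
class FamilySpec:
    """Parameters of a synthetic family.

    ``alpha`` is the Dirichlet concentration of the column profiles
    (alpha = 0.1 gives conserved columns where 1-3 residues dominate);
    ``gap_rate`` is the per-cell gap probability applied to non-focus rows
    of the designated gappy columns (all columns when ``gap_columns`` is
    None covers the uniform case).  With redundancy set, the family is
    ``n_founders x copies_per_founder`` noisy copies instead of independent
    draws.
    """

    length: int = 40
    n_sequences: int = 2000
    alpha: float = 0.1
    gap_rate: float = 0.0
    gap_columns: tuple[int, ...] | None = None
    redundancy: Redundancy | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.length < 1 or self.n_sequences < 1:
            raise ValueError("length and n_sequences must be >= 1")
        if not 0 <= self.gap_rate <= 0.9:
            raise ValueError("gap_rate must be in [0, 0.9]")
        if not self.alpha > 0:
            raise ValueError("alpha must be positive")


@dataclass
class GroundTruth:
    """Column profiles and the closed-form variant effects they imply."""

    profiles: np.ndarray  # (L, 20), rows sum to 1
    wild_type: str        # consensus (per-column argmax) sequence

    def true_effect(self, variant: Variant) -> float:
        """log pi(mut) - log pi(wt) at the variant's column, in nats."""
        row = np.maximum(self.profiles[variant.position - 1], 1e-300)
        wt = AMINO_ACIDS.index(variant.wt_aa)
        mut = AMINO_ACIDS.index(variant.mut_aa)
        return float(np.log(row[mut]) - np.log(row[wt]))

    def all_variants(self) -> list[Variant]:
        out = []
        for pos, wt in enumerate(self.wild_type, start=1):
            out.extend(
                Variant(pos, wt, mut) for mut in AMINO_ACIDS if mut != wt
            )
        return out

    def write_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("position\taa\tprobability\n")
            for pos in range(self.profiles.shape[0]):
                for a, aa in enumerate(AMINO_ACIDS):
                    fh.write(f"{pos + 1}\t{aa}\t{self.profiles[pos, a]:.8f}\n")


def sample_family(spec: FamilySpec) -> tuple[Msa, GroundTruth]:
    """Draw a family alignment and its generating profiles.

    The consensus sequence is prepended as the focus row (id "focus") and
    never receives gaps, so every column is addressable in focus
    coordinates.
    """
    rng = np.random.default_rng(spec.seed)
    L = spec.length
    profiles = rng.dirichlet(np.full(20, spec.alpha), size=L)
    consensus_codes = profiles.argmax(axis=1)
    wild_type = "".join(AMINO_ACIDS[c] for c in consensus_codes)

    cum = profiles.cumsum(axis=1)
    cum[:, -1] = 1.0

    def draw(n_rows: int) -> np.ndarray:
        u = rng.random((n_rows, L))
        codes = np.empty((n_rows, L), dtype=np.int64)
        for col in range(L):
            codes[:, col] = np.searchsorted(cum[col], u[:, col], side="right")
        return codes

    if spec.redundancy is None:
        codes = draw(spec.n_sequences)
    else:
        red = spec.redundancy
        founders = draw(red.n_founders)
        codes = np.repeat(founders, red.copies_per_founder, axis=0)
        mutate = rng.random(codes.shape) < red.copy_mutation_rate
        if mutate.any():
            fresh = draw(codes.shape[0])
            codes = np.where(mutate, fresh, codes)

    chars = np.frombuffer(AMINO_ACIDS.encode(), dtype="S1")[codes]
    if spec.gap_rate > 0:
        gap_cols = (
            np.arange(L) if spec.gap_columns is None else np.array(spec.gap_columns)
        )
        gap_mask = np.zeros(chars.shape, dtype=bool)
        gap_mask[:, gap_cols] = rng.random((chars.shape[0], gap_cols.size)) < spec.gap_rate
        chars = np.where(gap_mask, GAP.encode(), chars)

    rows = [wild_type] + [r.tobytes().decode() for r in chars]
    ids = ["focus"] + [f"seq{i + 1}" for i in range(chars.shape[0])]
    msa = Msa(ids=ids, rows=rows, focus_index=0)
    return msa, GroundTruth(profiles=profiles, wild_type=wild_type)


def labelled_variants(
    truth: GroundTruth,
    n: int,
    effect_threshold: float | None = None,
    rng: np.random.Generator | None = None,
) -> list[tuple[Variant, float, str]]:
    """Sample a class-balanced labelled variant set from the ground truth.

    A variant is deleterious iff its true effect is below the threshold
    (default: the median effect over all possible variants, which balances
    the classes by construction).  Returns (variant, effect, label) rows;
    the effect doubles as a z-like score for calibration exercises.
    """
    if n < 2:
        raise ValueError("need n >= 2 to cover both classes")
    rng = rng or np.random.default_rng()
    pool = truth.all_variants()
    effects = np.array([truth.true_effect(v) for v in pool])
    if effect_threshold is None:
        effect_threshold = float(np.median(effects))
    del_idx = np.flatnonzero(effects < effect_threshold)
    ben_idx = np.flatnonzero(effects >= effect_threshold)
    n_del = n // 2
    n_ben = n - n_del
    if len(del_idx) < n_del or len(ben_idx) < n_ben:
        raise ValueError(
            "effect_threshold leaves too few variants in one class to balance"
        )
    chosen = np.r_[
        rng.choice(del_idx, size=n_del, replace=False),
        rng.choice(ben_idx, size=n_ben, replace=False),
    ]
    rng.shuffle(chosen)
    return [
        (
            pool[i],
            float(effects[i]),
            DELETERIOUS if effects[i] < effect_threshold else BENIGN,
        )
        for i in chosen
    ]


def gap_column_fixture(
    n_rows: int = 100, seed: int = 0
) -> tuple[Msa, dict[int, float]]:
    """An alignment with columns at exact gap fractions 0, 0.30, 0.31, 0.50.

    Built for exercising the more-than-30%-gaps column filter: with the
    default 100 rows the designated fractions are exact, the focus row
    (row 0) is gap-free, and only the 0 and 0.30 columns survive the
    filter.
    """
    if n_rows < 100:
        raise ValueError("need >= 100 rows for exact percent fractions")
    rng = np.random.default_rng(seed)
    fractions = {0: 0.0, 1: 0.30, 2: 0.31, 3: 0.50}
    aa = np.frombuffer(AMINO_ACIDS.encode(), dtype="S1")
    cols = []
    for col, frac in sorted(fractions.items()):
        n_gaps = round(frac * n_rows)
        column = aa[rng.integers(0, 20, size=n_rows)]
        gap_rows = 1 + rng.choice(n_rows - 1, size=n_gaps, replace=False)
        column[gap_rows] = GAP.encode()
        cols.append(column)
    mat = np.stack(cols, axis=1)
    rows = [r.tobytes().decode() for r in mat]
    ids = [f"row{i}" for i in range(n_rows)]
    return Msa(ids=ids, rows=rows, focus_index=0), fractions


def ideal_model(profiles: np.ndarray):
    """A model whose conditionals equal the generating column profiles.

    Constructed by zeroing every layer except identity input/output
    projections and a positional embedding holding the profile
    log-probabilities, so for site-independent data the model is exact:
    its log-probability score equals the ground-truth effect for every
    variant.  Used as a closed-form oracle in tests.
    """
    from .model import ModelConfig, build_model

    L = profiles.shape[0]
    K = 22
    cfg = ModelConfig(
        alphabet_size=K, seq_length=L, embedding_dim=K, conv_channels=K,
        dilation_schedule=(1,), attention_dim=2,
    )
    model = build_model(cfg, rng_seed=0, dtype=np.float64)
    for k in model.params:
        model.params[k][:] = 0
    model.params["in_w"][:] = np.eye(K)
    model.params["out_w"][:] = np.eye(K)
    pos = np.full((L, K), -50.0)
    pos[:, :20] = np.log(np.maximum(profiles, 1e-300))
    model.params["pos"][:] = pos
    return model


def write_fasta(msa: Msa, path: str | Path) -> None:
    with open(path, "w") as fh:
        for sid, row in zip(msa.ids, msa.rows):
            fh.write(f">{sid}\n{row}\n")
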