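"""Variant scoring: log-probability ratios, z-scores, calibrated probabilities.

For a variant x^mut of the wild-type sequence x^wt, the raw score is the
log-probability ratio under the trained generative model,

    score = log p(x_mut | theta) - log p(x_wt | theta),

where x_mut is the wild-type row with a single retained-column substitution.
Lower scores indicate more deleterious variants.  Because raw score
distributions vary between protein families, each variant's score is
standardized into a z-score against the scores of *all* possible single
substitutions of the focus sequence (19 per retained focus position).

A calibration step turns z-scores into a probability of deleteriousness: a
labelled variant set is binned into equal-width z-score intervals and each
bin's deleterious fraction becomes the probability for any variant landing
in it.  The same bin edges serve as candidate cutoffs, and the edge that
maximizes classification accuracy under the rule "z below the cutoff is
deleterious" becomes the label threshold.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np

from .alignment import (
    AMINO_ACIDS,
    ColumnMask,
    MappedVariant,
    Variant,
)
from .model import AutoregressiveModel, batch_log_likelihoods

DELETERIOUS = "deleterious"
BENIGN = "benign"

_AA_CODES = {aa: i for i, aa in enumerate(AMINO_ACIDS)}


@dataclass
class VariantScore:
    variant: Variant
    log_prob_score: float
    z_score: float
    prob_deleterious: float | None = None
    label: str | None = None


@dataclass
class CalibrationTable:
    """Equal-width z-score bins with per-bin deleterious proportions."""

    bin_edges: np.ndarray            # (n_bins + 1,) strictly increasing
    proportion_deleterious: np.ndarray  # (n_bins,)
    n_per_bin: np.ndarray            # (n_bins,)
    z_cutoff: float = float("nan")

    @property
    def n_bins(self) -> int:
        return len(self.proportion_deleterious)

    def bin_index(self, z: float) -> int:
        """Bin containing z; out-of-range values clamp to the end bins."""
        edges = self.bin_edges
        idx = int(np.searchsorted(edges, z, side="right") - 1)
        return min(max(idx, 0), self.n_bins - 1)

    def write_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write(f"# z_cutoff={self.z_cutoff!r}\n")
            fh.write("bin_low\tbin_high\tproportion_deleterious\tn\n")
            for b in range(self.n_bins):
                fh.write(
                    f"{self.bin_edges[b]:.6f}\t{self.bin_edges[b + 1]:.6f}\t"
                    f"{self.proportion_deleterious[b]:.6f}\t{self.n_per_bin[b]}\n"
                )


# --- raw scores -----------------------------------------------------------


def _mutant_row(focus_row: np.ndarray, column: int, mut_aa: str) -> np.ndarray:
    mutant = focus_row.copy()
    mutant[column] = _AA_CODES[mut_aa]
    return mutant


def log_prob_score(
    model: AutoregressiveModel,
    focus_row: np.ndarray,
    mapped: MappedVariant,
    wt_log_likelihood: float | None = None,
) -> float:
    """log p(mutant) - log p(wild-type) for one mapped variant (nats)."""
    if wt_log_likelihood is None:
        wt_log_likelihood = float(batch_log_likelihoods(model, focus_row[None, :])[0])
    mutant = _mutant_row(focus_row, mapped.retained_column, mapped.variant.mut_aa)
    mut_ll = float(batch_log_likelihoods(model, mutant[None, :])[0])
    return mut_ll - wt_log_likelihood


def all_possible_variants(mask: ColumnMask, focus_row: np.ndarray) -> list[MappedVariant]:
    """The 19 substitutions at every retained focus position."""
    out = []
    for pos in sorted(mask.col_map):
        col = mask.col_map[pos]
        wt = mask.focus_residues[pos]
        for mut in AMINO_ACIDS:
            if mut != wt:
                out.append(MappedVariant(Variant(pos, wt, mut), col))
    return out


def zscore_all_variants(
    model: AutoregressiveModel, focus_row: np.ndarray, mask: ColumnMask
) -> list[VariantScore]:
    """Score and standardize all possible missense variants of the focus.

    z-scores are computed against the full 19 x L' score set with the
    population standard deviation, so they have mean 0 and std 1 exactly.
    """
    variants = all_possible_variants(mask, focus_row)
    rows = np.empty((len(variants), focus_row.size), dtype=np.int64)
    for i, mv in enumerate(variants):
        rows[i] = _mutant_row(focus_row, mv.retained_column, mv.variant.mut_aa)
    wt_ll = float(batch_log_likelihoods(model, focus_row[None, :])[0])
    scores = batch_log_likelihoods(model, rows) - wt_ll
    std = scores.std()
    if std == 0:
        raise ValueError("degenerate model: all variant scores identical")
    z = (scores - scores.mean()) / std
    return [
        VariantScore(variant=mv.variant, log_prob_score=float(s), z_score=float(zz))
        for mv, s, zz in zip(variants, scores, z)
    ]


def zscores_for(
    scored_all: list[VariantScore], mapped: list[MappedVariant]
) -> list[VariantScore]:
    """Look up requested variants in the all-variants score table."""
    index = {str(vs.variant): vs for vs in scored_all}
    return [index[str(mv.variant)] for mv in mapped]


# --- calibration ----------------------------------------------------------


def calibrate(
    labelled: list[tuple[float, str]], n_bins: int = 20
) -> CalibrationTable:
    """Bin labelled z-scores into equal-width intervals.

    Each bin's probability of deleteriousness is its deleterious fraction;
    empty bins inherit the proportion of the nearest non-empty bin, taking
    the lower-z side on ties, so every z-score maps to a defined value.
    """
    if n_bins < 2:
        raise ValueError("need at least 2 bins")
    z = np.array([v for v, _ in labelled], dtype=float)
    labels = np.array([lab == DELETERIOUS for _, lab in labelled])
    if not labels.any() or labels.all():
        raise ValueError("calibration needs both deleterious and benign variants")
    lo, hi = z.min(), z.max()
    if lo == hi:
        raise ValueError("all z-scores identical; cannot form intervals")
    edges = np.linspace(lo, hi, n_bins + 1)
    idx = np.clip(np.searchsorted(edges, z, side="right") - 1, 0, n_bins - 1)
    n_per_bin = np.bincount(idx, minlength=n_bins)
    n_del = np.bincount(idx, weights=labels.astype(float), minlength=n_bins)
    with np.errstate(invalid="ignore"):
        prop = np.where(n_per_bin > 0, n_del / np.maximum(n_per_bin, 1), np.nan)
    nonempty = np.flatnonzero(n_per_bin > 0)
    for b in np.flatnonzero(n_per_bin == 0):
        nearest = nonempty[np.argmin(np.abs(nonempty - b) + (nonempty > b) * 0.5)]
        prop[b] = prop[nearest]
    return CalibrationTable(
        bin_edges=edges, proportion_deleterious=prop, n_per_bin=n_per_bin
    )


def select_cutoff(
    labelled: list[tuple[float, str]], table: CalibrationTable
) -> float:
    """Accuracy-maximizing bin edge for the rule "z < cutoff => deleterious".

    Ties resolve to the smallest maximizing edge.
    """
    z = np.array([v for v, _ in labelled], dtype=float)
    labels = np.array([lab == DELETERIOUS for _, lab in labelled])
    best_edge, best_acc = None, -1.0
    for edge in table.bin_edges:
        acc = float(((z < edge) == labels).mean())
        if acc > best_acc:
            best_edge, best_acc = float(edge), acc
    return best_edge


def fit_calibration(
    labelled: list[tuple[float, str]], n_bins: int = 20
) -> CalibrationTable:
    """Calibrate and select the cutoff in one step."""
    table = calibrate(labelled, n_bins=n_bins)
    return replace(table, z_cutoff=select_cutoff(labelled, table))


def predict(
    scores: list[VariantScore], table: CalibrationTable
) -> list[VariantScore]:
    """Attach probability of deleteriousness and label to scored variants.

    The probability is the deleterious proportion of the bin containing the
    variant's z-score (end bins for out-of-range values); the label is
    deleterious exactly when the z-score is strictly below the cutoff.
    """
    if not np.isfinite(table.z_cutoff):
        raise ValueError("calibration table has no cutoff; run select_cutoff")
    out = []
    for vs in scores:
        b = table.bin_index(vs.z_score)
        out.append(
            replace(
                vs,
                prob_deleterious=float(table.proportion_deleterious[b]),
                label=DELETERIOUS if vs.z_score < table.z_cutoff else BENIGN,
            )
        )
    return out


# --- tabular output -------------------------------------------------------

PREDICTION_COLUMNS = [
    "variant", "log_prob_score", "z_score", "prob_deleterious",
    "predicted_label", "status",
]


def write_predictions(
    scored: list[VariantScore], excluded, path: str | Path, header_comment: str = ""
) -> None:
    """Write the prediction table (TSV), excluded variants included."""
    with open(path, "w") as fh:
        if header_comment:
            fh.write(f"# {header_comment}\n")
        fh.write("\t".join(PREDICTION_COLUMNS) + "\n")
        for vs in scored:
            prob = "" if vs.prob_deleterious is None else f"{vs.prob_deleterious:.4f}"
            lab = vs.label or ""
            fh.write(
                f"{vs.variant}\t{vs.log_prob_score:.6f}\t{vs.z_score:.6f}\t"
                f"{prob}\t{lab}\tscored\n"
            )
        for ev in excluded:
            fh.write(f"{ev.variant}\t\t\t\t\texcluded({ev.reason})\n")
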