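"""Alignment reading, filtering, reweighting and integer encoding.

The model is trained on a multiple sequence alignment (MSA) of a protein
family with a designated focus (wild-type) sequence.  Before training the
alignment is cleaned up the way the prediction pipeline expects:

* columns with more than 30% gap symbols are dropped;
* sequences are down-weighted by the size of their identity neighbourhood
  (inverse of the number of alignment members at >= 80% identity), so that
  over-represented sub-families do not dominate the likelihood;
* residues are mapped to a fixed integer alphabet of the 20 canonical amino
  acids plus a gap code and an "unknown" code.

Variant coordinates are 1-based positions in the focus sequence; a variant
is scorable only if its position lands on a retained column whose wild-type
residue matches the stated one.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from Bio import SeqIO

# --- alphabet -------------------------------------------------------------

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
GAP = "-"
UNKNOWN = "X"
ALPHABET = AMINO_ACIDS + GAP + UNKNOWN
GAP_CODE = ALPHABET.index(GAP)        # 20
UNKNOWN_CODE = ALPHABET.index(UNKNOWN)  # 21
ALPHABET_SIZE = len(ALPHABET)          # 22

# non-canonical residue letters collapsed onto the unknown code
_NON_CANONICAL = "BJOUZX*"
_CHAR_TO_CODE = {c: i for i, c in enumerate(ALPHABET)}
for _c in _NON_CANONICAL:
    _CHAR_TO_CODE[_c] = UNKNOWN_CODE


class AlignmentError(ValueError):
    """Malformed or degenerate alignment input."""


@dataclass(frozen=True)
class Variant:
    """A single amino-acid substitution in focus-sequence coordinates."""

    position: int  # 1-based position in the (ungapped) focus sequence
    wt_aa: str
    mut_aa: str

    def __post_init__(self) -> None:
        if self.wt_aa == self.mut_aa:
            raise ValueError(f"variant {self} is not a substitution")
        for aa in (self.wt_aa, self.mut_aa):
            if aa not in AMINO_ACIDS:
                raise ValueError(f"non-canonical amino acid {aa!r} in variant")
        if self.position < 1:
            raise ValueError("variant positions are 1-based")

    def __str__(self) -> str:
        return f"{self.wt_aa}{self.position}{self.mut_aa}"


_VARIANT_RE = re.compile(r"^([A-Za-z])(\d+)([A-Za-z])$")


def parse_variant(text: str) -> Variant:
    """Parse ``"A123V"`` notation into a :class:`Variant`."""
    m = _VARIANT_RE.match(text.strip())
    if m is None:
        raise ValueError(f"cannot parse variant {text!r}; expected e.g. 'A123V'")
    wt, pos, mut = m.group(1).upper(), int(m.group(2)), m.group(3).upper()
    return Variant(position=pos, wt_aa=wt, mut_aa=mut)


def read_variant_list(path: str | Path) -> list[Variant]:
    """Read a plain-text variant list, one ``A123V`` entry per line."""
    variants = []
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if line and not line.startswith("#"):
            variants.append(parse_variant(line))
    return variants


# --- MSA container --------------------------------------------------------


@dataclass
class Msa:
    """An aligned protein family with a designated focus sequence."""

    ids: list[str]
    rows: list[str]
    focus_index: int

    def __post_init__(self) -> None:
        if not self.rows:
            raise AlignmentError("empty alignment")
        widths = {len(r) for r in self.rows}
        if len(widths) != 1:
            raise AlignmentError(f"rows have unequal lengths: {sorted(widths)}")
        if not 0 <= self.focus_index < len(self.rows):
            raise AlignmentError("focus_index out of range")

    @property
    def n_rows(self) -> int:
        return len(self.rows)

    @property
    def n_cols(self) -> int:
        return len(self.rows[0])

    @property
    def focus_row(self) -> str:
        return self.rows[self.focus_index]

    def focus_sequence(self) -> str:
        """The focus sequence with alignment gaps removed."""
        return self.focus_row.replace(GAP, "")


def _normalize_fasta_row(seq: str) -> str:
    return seq.upper().replace(".", GAP)


def _normalize_a2m_row(seq: str) -> str:
    # A2M: uppercase/'-' are match states, lowercase/'.' are insert states
    # relative to the model; inserts are not columns and are removed.
    return "".join(c for c in seq if not (c.islower() or c == "."))


def _sanitize(seq: str) -> str:
    out = []
    for c in seq:
        if c in _CHAR_TO_CODE:
            out.append(UNKNOWN if _CHAR_TO_CODE[c] == UNKNOWN_CODE else c)
        else:
            raise AlignmentError(f"unexpected symbol {c!r} in alignment")
    return "".join(out)


def read_alignment(
    path: str | Path, format: str = "fasta", focus_id: str = "first"
) -> Msa:
    """Read a FASTA or A2M alignment and resolve the focus sequence.

    ``format="a2m"`` removes insert states (lowercase and ``.``) so that the
    remaining match columns form a rectangular alignment.  ``focus_id`` names
    the record holding the wild-type sequence, or ``"first"`` for record 0.
    """
    if format not in ("fasta", "a2m"):
        raise ValueError(f"unsupported alignment format {format!r}")
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise AlignmentError(f"no sequences found in {path}")
    norm = _normalize_a2m_row if format == "a2m" else _normalize_fasta_row
    ids = [r.id for r in records]
    rows = [_sanitize(norm(str(r.seq)).upper()) for r in records]
    if focus_id == "first":
        focus_index = 0
    else:
        try:
            focus_index = ids.index(focus_id)
        except ValueError:
            raise KeyError(f"focus sequence {focus_id!r} not in alignment") from None
    return Msa(ids=ids, rows=rows, focus_index=focus_index)


# --- column filtering -----------------------------------------------------


@dataclass
class ColumnMask:
    """Retained-column bookkeeping for the 30%-gap filter.

    ``col_map`` maps a 1-based focus-sequence position to the index of the
    corresponding *retained* column; positions at dropped columns are absent.
    ``focus_residues`` records the wild-type residue at every focus position,
    retained or not, so mismatching variants can be diagnosed.
    """

    gap_fraction: np.ndarray          # (n_cols,) fraction of gap symbols
    kept: np.ndarray                  # (n_cols,) bool
    kept_original_index: np.ndarray   # (L',) original column index per retained col
    col_map: dict[int, int]           # focus position (1-based) -> retained index
    focus_positions: dict[int, int] = field(default_factory=dict)  # pos -> orig col
    focus_residues: dict[int, str] = field(default_factory=dict)   # pos -> residue

    @property
    def n_kept(self) -> int:
        return int(self.kept.sum())


def compute_gap_mask(msa: Msa, max_gap_fraction: float = 0.30) -> ColumnMask:
    """Drop columns whose gap fraction exceeds ``max_gap_fraction``.

    A column with gap fraction exactly at the threshold is kept (only "more
    than" 30% gaps drops a column).  The focus-coordinate map covers only
    columns where the focus sequence itself is non-gap: a variant cannot
    address a column its own sequence does not occupy.
    """
    mat = np.frombuffer("".join(msa.rows).encode("ascii"), dtype="S1")
    mat = mat.reshape(msa.n_rows, msa.n_cols)
    gap_fraction = (mat == GAP.encode()).mean(axis=0)
    kept = gap_fraction <= max_gap_fraction
    if not kept.any():
        raise AlignmentError("all columns exceed the gap-fraction threshold")
    kept_original = np.flatnonzero(kept)
    retained_of_original = {int(c): r for r, c in enumerate(kept_original)}
    col_map: dict[int, int] = {}
    focus_positions: dict[int, int] = {}
    focus_residues: dict[int, str] = {}
    pos = 0
    for c, residue in enumerate(msa.focus_row):
        if residue == GAP:
            continue
        pos += 1
        focus_positions[pos] = c
        focus_residues[pos] = residue
        if kept[c]:
            col_map[pos] = retained_of_original[c]
    return ColumnMask(
        gap_fraction=gap_fraction,
        kept=kept,
        kept_original_index=kept_original,
        col_map=col_map,
        focus_positions=focus_positions,
        focus_residues=focus_residues,
    )


# --- encoding -------------------------------------------------------------


@dataclass
class EncodedMsa:
    """Integer-encoded alignment restricted to retained columns."""

    matrix: np.ndarray   # (N, L') int8
    alphabet: str
    focus_row: np.ndarray  # (L',)

    @property
    def n_rows(self) -> int:
        return self.matrix.shape[0]

    @property
    def seq_length(self) -> int:
        return self.matrix.shape[1]


def encode(msa: Msa, mask: ColumnMask) -> EncodedMsa:
    """Integer-encode the alignment over the retained columns."""
    lut = np.full(128, -1, dtype=np.int8)
    for c, code in _CHAR_TO_CODE.items():
        lut[ord(c)] = code
    raw = np.frombuffer("".join(msa.rows).encode("ascii"), dtype=np.uint8)
    codes = lut[raw].reshape(msa.n_rows, msa.n_cols)
    if (codes < 0).any():
        bad = chr(int(raw[(codes < 0).ravel()][0]))
        raise AlignmentError(f"symbol {bad!r} outside the alphabet")
    matrix = np.ascontiguousarray(codes[:, mask.kept])
    return EncodedMsa(
        matrix=matrix, alphabet=ALPHABET, focus_row=matrix[msa.focus_index].copy()
    )


def decode(encoded: np.ndarray, alphabet: str = ALPHABET) -> list[str]:
    """Inverse of :func:`encode` on retained columns."""
    arr = np.atleast_2d(np.asarray(encoded))
    return ["".join(alphabet[int(c)] for c in row) for row in arr]


# --- sequence weighting ---------------------------------------------------


@dataclass
class SequenceWeights:
    """Inverse-neighbourhood-size sequence weights."""

    w: np.ndarray
    identity_threshold: float

    @property
    def n_eff(self) -> float:
        return float(self.w.sum())


def compute_sequence_weights(
    encoded: EncodedMsa, identity_threshold: float = 0.8
) -> SequenceWeights:
    """Weight each sequence by 1 / (number of neighbours at >= threshold identity).

    Identity is the fraction of retained columns at which two rows carry the
    same symbol, gaps included; the neighbourhood always contains the
    sequence itself, so weights are in (0, 1] and n_eff in [1, N].
    """
    mat = encoded.matrix
    n, length = mat.shape
    min_matches = identity_threshold * length
    counts = np.zeros(n, dtype=np.int64)
    chunk = max(1, 2**24 // max(1, n * length))
    for start in range(0, n, chunk):
        block = mat[start : start + chunk]
        matches = (block[:, None, :] == mat[None, :, :]).sum(axis=2)
        counts[start : start + chunk] = (matches >= min_matches).sum(axis=1)
    return SequenceWeights(w=1.0 / counts, identity_threshold=identity_threshold)


# --- variant mapping ------------------------------------------------------

EXCLUDE_OUT_OF_RANGE = "out_of_range"
EXCLUDE_WT_MISMATCH = "wild_type_mismatch"
EXCLUDE_DROPPED_COLUMN = "dropped_column"


@dataclass(frozen=True)
class MappedVariant:
    variant: Variant
    retained_column: int


@dataclass(frozen=True)
class ExcludedVariant:
    variant: Variant
    reason: str


def map_variants(
    mask: ColumnMask, msa: Msa, variants: Iterable[Variant]
) -> tuple[list[MappedVariant], list[ExcludedVariant]]:
    """Partition variants into scorable (mapped to a retained column) and excluded.

    Exclusion is a result, not an error: variants falling outside the focus
    sequence, disagreeing with the wild-type residue, or addressing a dropped
    column are returned with the corresponding reason.
    """
    scorable: list[MappedVariant] = []
    excluded: list[ExcludedVariant] = []
    for v in variants:
        if v.position not in mask.focus_positions:
            excluded.append(ExcludedVariant(v, EXCLUDE_OUT_OF_RANGE))
        elif mask.focus_residues[v.position] != v.wt_aa:
            excluded.append(ExcludedVariant(v, EXCLUDE_WT_MISMATCH))
        elif v.position not in mask.col_map:
            excluded.append(ExcludedVariant(v, EXCLUDE_DROPPED_COLUMN))
        else:
            scorable.append(MappedVariant(v, mask.col_map[v.position]))
    return scorable, excluded


# --- tabular output -------------------------------------------------------


def write_column_map(mask: ColumnMask, path: str | Path) -> None:
    """Write the retained-column table (TSV)."""
    pos_of_col = {c: p for p, c in mask.focus_positions.items()}
    with open(path, "w") as fh:
        fh.write("original_index\tfocus_position\tgap_fraction\tkept\n")
        for c in range(len(mask.kept)):
            pos = pos_of_col.get(c, "")
            fh.write(
                f"{c}\t{pos}\t{mask.gap_fraction[c]:.6f}\t{int(mask.kept[c])}\n"
            )


def write_weights(
    weights: SequenceWeights, ids: Sequence[str], path: str | Path
) -> None:
    with open(path, "w") as fh:
        fh.write(f"# identity_threshold={weights.identity_threshold}\n")
        fh.write(f"# n_eff={weights.n_eff:.6f}\n")
        fh.write("id\tweight\n")
        for sid, w in zip(ids, weights.w):
            fh.write(f"{sid}\t{w:.8f}\n")
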