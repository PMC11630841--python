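"""Global pairwise alignment and percent identity against a template bank.

Sequence identity between a query and its candidate templates drives how much
a template can improve a prediction, so the pipeline needs a deterministic
global aligner.  Alignment is Needleman-Wunsch/Gotoh with affine gaps via
Biopython's :class:`Bio.Align.PairwiseAligner`, scored with BLOSUM62 in which
the ambiguous residue ``X`` scores 0 against everything.  Percent identity is
the number of identical aligned residue pairs over the total number of
alignment columns (gap columns included) -- a conservative denominator.

Default gap penalties are the standard BLOSUM62 pairing, open -11 / extend -1,
where a gap of length k costs open + (k-1) * extend.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache
from typing import Sequence

import numpy as np
from Bio import Align
from Bio.Align import substitution_matrices

from .exceptions import EmptyBankError, ValidationError

__all__ = [
    "AlignmentResult",
    "blosum62_x_neutral",
    "global_align",
    "identity_percent",
    "closest_template_identity",
    "DEFAULT_GAP_OPEN",
    "DEFAULT_GAP_EXTEND",
]

DEFAULT_GAP_OPEN = -11.0
DEFAULT_GAP_EXTEND = -1.0

_VALID_CHARS = set("ACDEFGHIKLMNPQRSTVWYX")


@dataclass(frozen=True)
class AlignmentResult:
    """An optimal global alignment with its score and percent identity."""

    score: float
    aligned_a: str
    aligned_b: str
    identity_pct: float


@lru_cache(maxsize=1)
def blosum62_x_neutral() -> substitution_matrices.Array:
    """BLOSUM62 with the X row/column zeroed (X is scoring-neutral)."""
    m = substitution_matrices.load("BLOSUM62")
    m = m.copy()
    for ch in m.alphabet:
        m["X", ch] = 0.0
        m[ch, "X"] = 0.0
    return m


def _check_sequence(seq: str, label: str) -> None:
    if not seq:
        raise ValidationError(f"{label}: empty sequence")
    bad = set(seq) - _VALID_CHARS
    if bad:
        raise ValidationError(
            f"{label}: unknown residue character(s) {''.join(sorted(bad))}"
        )


def _make_aligner(
    matrix: substitution_matrices.Array | None,
    gap_open: float,
    gap_extend: float,
) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = (
        matrix if matrix is not None else blosum62_x_neutral()
    )
    # Biopython convention: open_gap_score is the first gap column's score,
    # so a k-long gap costs open + (k-1) * extend.
    aligner.open_gap_score = gap_open
    aligner.extend_gap_score = gap_extend
    return aligner


def identity_percent(aligned_a: str, aligned_b: str) -> float:
    """Percent of alignment columns where both sequences agree (gaps count as columns)."""
    if len(aligned_a) != len(aligned_b):
        raise ValidationError("aligned strings must have equal length")
    matches = sum(
        1 for x, y in zip(aligned_a, aligned_b) if x == y and x != "-"
    )
    return 100.0 * matches / len(aligned_a)


def global_align(
    a: str,
    b: str,
    matrix: substitution_matrices.Array | None = None,
    gap_open: float = DEFAULT_GAP_OPEN,
    gap_extend: float = DEFAULT_GAP_EXTEND,
) -> AlignmentResult:
    """Optimal global alignment of two amino-acid sequences.

    Returns the optimal score under affine gaps and one deterministic optimal
    traceback, with the identity computed over that traceback's columns.
    """
    _check_sequence(a, "sequence a")
    _check_sequence(b, "sequence b")
    aligner = _make_aligner(matrix, gap_open, gap_extend)
    alignments = aligner.align(a, b)
    best = alignments[0]
    aligned_a, aligned_b = str(best[0]), str(best[1])
    return AlignmentResult(
        score=float(best.score),
        aligned_a=aligned_a,
        aligned_b=aligned_b,
        identity_pct=identity_percent(aligned_a, aligned_b),
    )


def closest_template_identity(
    query: str,
    bank: Sequence[tuple[str, str]],
    matrix: substitution_matrices.Array | None = None,
    gap_open: float = DEFAULT_GAP_OPEN,
    gap_extend: float = DEFAULT_GAP_EXTEND,
) -> tuple[str, float]:
    """Template with the highest percent identity to the query.

    ``bank`` is a sequence of (template_id, sequence).  Ties on identity break
    to the higher alignment score, then lexicographically smaller id.
    """
    if not bank:
        raise EmptyBankError("template bank is empty")
    best_key: tuple[float, float, str] | None = None
    best_id, best_identity = "", 0.0
    for template_id, seq in bank:
        res = global_align(query, seq, matrix, gap_open, gap_extend)
        key = (-res.identity_pct, -res.score, template_id)
        if best_key is None or key < best_key:
            best_key = key
            best_id, best_identity = template_id, res.identity_pct
    return best_id, best_identity
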