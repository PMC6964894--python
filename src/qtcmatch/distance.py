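"""Edit distance between QTC matrix sequences.

Substituting one matrix for another costs the sum, over all informative
pairs and both characters of each cell, of the conceptual distance
between the characters.  The default conceptual distances follow the
neighbourhood chain '-' <-> '0' <-> '+': adjacent symbols cost 1,
opposite symbols cost 2, identical symbols cost 0.  Inserting or
deleting a matrix costs the maximum possible substitution cost for the
roster, so an indel is never cheaper than the worst substitution.

The distance between two sequences is the minimum total cost over all
alignments (a Levenshtein distance with these costs), computed by
dynamic programming.  Dividing by ``max(len_a, len_b) * c_max`` — the
tight upper bound attained by aligning against an empty sequence — maps
raw costs onto relative distances in [0, 1].
"""

from __future__ import annotations

from dataclasses import dataclass, field
from math import comb
from typing import Optional

import numpy as np

from .encoding import QTCMatrix, QTCSequence
from .errors import QTCMatchError, RosterMismatchError, ValidationError

__all__ = [
    "CostScheme",
    "DEFAULT_SCHEME",
    "AlignmentResult",
    "character_distance",
    "matrix_cost",
    "max_matrix_cost",
    "levenshtein_distance",
    "levenshtein_with_cutoff",
    "normalized_distance",
    "pairwise_distance",
]

_CHAR_INDEX = {"-": 0, "0": 1, "+": 2}

#: Chain-metric conceptual distances, indexed by ('-', '0', '+') positions.
_CHAIN_TABLE = np.array(
    [[0, 1, 2],
     [1, 0, 1],
     [2, 1, 0]], dtype=np.int64
)


@dataclass(frozen=True)
class CostScheme:
    """Substitution costs between QTC characters plus the indel policy.

    ``table[i, j]`` is the cost of substituting character i for j with
    characters ordered '-', '0', '+'.  The table must be symmetric with a
    zero diagonal and satisfy the triangle inequality; indels are always
    charged at the roster's maximum matrix substitution cost.
    """

    table: np.ndarray = field(default_factory=lambda: _CHAIN_TABLE.copy())
    description: str = "conceptual neighbourhood chain (-..0..+), indel = max substitution"

    def __post_init__(self) -> None:
        tab = np.asarray(self.table)
        if tab.shape != (3, 3):
            raise ValidationError("cost table must be 3x3")
        if np.issubdtype(tab.dtype, np.integer):
            tab = tab.astype(np.int64)
        else:
            tab = tab.astype(float)
        if np.any(tab < 0):
            raise ValidationError("cost table entries must be non-negative")
        if np.any(np.diag(tab) != 0):
            raise ValidationError("cost table diagonal must be zero")
        if not np.array_equal(tab, tab.T):
            raise ValidationError("cost table must be symmetric")
        for i in range(3):
            for j in range(3):
                for k in range(3):
                    if tab[i, j] > tab[i, k] + tab[k, j]:
                        raise ValidationError(
                            "cost table violates the triangle inequality"
                        )
        object.__setattr__(self, "table", tab)

    @property
    def d_max(self):
        """Largest single-character substitution cost (2 under the chain metric)."""
        return self.table.max()


DEFAULT_SCHEME = CostScheme()


@dataclass(frozen=True)
class AlignmentResult:
    """Raw and normalized distance between two sequences."""

    raw_cost: float
    normalized: float
    length_a: int
    length_b: int
    c_max: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.normalized <= 1.0):
            raise QTCMatchError(
                f"normalized distance {self.normalized} outside [0, 1]"
            )
        if self.raw_cost < 0:
            raise QTCMatchError(f"negative raw cost {self.raw_cost}")


def character_distance(a: str, b: str, scheme: CostScheme = DEFAULT_SCHEME):
    """Conceptual distance between two QTC characters."""
    try:
        return scheme.table[_CHAR_INDEX[a], _CHAR_INDEX[b]]
    except KeyError:
        raise ValidationError(f"invalid QTC character in ({a!r}, {b!r})") from None


def _check_roster(a, b) -> None:
    if a.objects != b.objects or a.n_moving != b.n_moving:
        raise RosterMismatchError(
            f"object rosters differ: {a.objects} (moving {a.n_moving}) vs "
            f"{b.objects} (moving {b.n_moving})"
        )


def matrix_cost(m1: QTCMatrix, m2: QTCMatrix, scheme: CostScheme = DEFAULT_SCHEME):
    """Substitution cost between two matrices over the same roster."""
    _check_roster(m1, m2)
    return scheme.table[m1.codes + 1, m2.codes + 1].sum()


def max_matrix_cost(n_moving: int, n_static: int = 0, scheme: CostScheme = DEFAULT_SCHEME):
    """Maximum possible substitution cost for a roster; also the indel cost.

    Every informative pair (both-moving or moving–static) contributes two
    characters, each at worst ``d_max``:
    ``(C(m + s, 2) - C(s, 2)) * 2 * d_max``.
    """
    if n_moving < 1:
        raise ValidationError("at least one moving object required")
    if n_static < 0:
        raise ValidationError("n_static must be >= 0")
    n_pairs = comb(n_moving + n_static, 2) - comb(n_static, 2)
    return n_pairs * 2 * scheme.d_max


def _subst_costs(seq_a: QTCSequence, seq_b: QTCSequence, scheme: CostScheme) -> np.ndarray:
    """(len_a, len_b) matrix-substitution costs, fully vectorised."""
    a = seq_a.codes + 1  # (la, P, 2)
    b = seq_b.codes + 1  # (lb, P, 2)
    return scheme.table[a[:, None, :, :], b[None, :, :, :]].sum(axis=(2, 3))


def _indel_cost(seq: QTCSequence, scheme: CostScheme):
    return max_matrix_cost(seq.n_moving, seq.n_static, scheme)


def _dp_rows(sub: np.ndarray, gap):
    """Generate successive DP rows of the edit-distance table.

    Row i holds d(a[:i], b[:j]) for all j.  The in-row dependency
    (insertion from the left) is resolved with the prefix-minimum
    identity  cur[j] = gap*j + min_{k<=j}(cand[k] - gap*k).
    """
    la, lb = sub.shape
    j_gap = gap * np.arange(lb + 1)
    prev = j_gap.copy()
    yield prev
    for i in range(1, la + 1):
        cand = np.empty(lb + 1, dtype=prev.dtype)
        cand[0] = i * gap
        np.minimum(prev[1:] + gap, prev[:-1] + sub[i - 1], out=cand[1:])
        cur = j_gap + np.minimum.accumulate(cand - j_gap)
        yield cur
        prev = cur


def levenshtein_distance(
    seq_a: QTCSequence, seq_b: QTCSequence, scheme: CostScheme = DEFAULT_SCHEME
):
    """Minimum-cost alignment of two QTC matrix sequences.

    Substitution cost is :func:`matrix_cost`; insertion and deletion cost
    the roster's :func:`max_matrix_cost`.
    """
    _check_roster(seq_a, seq_b)
    gap = _indel_cost(seq_a, scheme)
    if len(seq_a) == 0 or len(seq_b) == 0:
        return gap * max(len(seq_a), len(seq_b))
    sub = _subst_costs(seq_a, seq_b, scheme)
    for row in _dp_rows(sub, gap):
        pass
    return row[-1]


def levenshtein_with_cutoff(
    seq_a: QTCSequence,
    seq_b: QTCSequence,
    scheme: CostScheme = DEFAULT_SCHEME,
    threshold=0,
) -> Optional[float]:
    """Exact distance if it does not exceed ``threshold``, else ``None``.

    The dynamic program is aborted as soon as every entry of the current
    row exceeds the threshold, since row minima never decrease.
    """
    if threshold < 0:
        raise ValidationError(f"threshold must be >= 0, got {threshold}")
    _check_roster(seq_a, seq_b)
    gap = _indel_cost(seq_a, scheme)
    if gap * abs(len(seq_a) - len(seq_b)) > threshold:
        return None
    if len(seq_a) == 0 or len(seq_b) == 0:
        d = gap * max(len(seq_a), len(seq_b))
        return d if d <= threshold else None
    sub = _subst_costs(seq_a, seq_b, scheme)
    for row in _dp_rows(sub, gap):
        if row.min() > threshold:
            return None
    d = row[-1]
    return d if d <= threshold else None


def normalized_distance(
    seq_a: QTCSequence, seq_b: QTCSequence, scheme: CostScheme = DEFAULT_SCHEME
) -> AlignmentResult:
    """Alignment cost divided by the maximum possible distance.

    The denominator ``max(len_a, len_b) * c_max`` is the cost of the
    worst admissible alignment, so the quotient lies in [0, 1].  Two
    empty sequences have distance 0 by convention.
    """
    _check_roster(seq_a, seq_b)
    c_max = _indel_cost(seq_a, scheme)
    la, lb = len(seq_a), len(seq_b)
    if la == 0 and lb == 0:
        return AlignmentResult(0, 0.0, 0, 0, c_max)
    raw = levenshtein_distance(seq_a, seq_b, scheme)
    return AlignmentResult(raw, float(raw) / (max(la, lb) * c_max), la, lb, c_max)


def pairwise_distance(
    seq_a: QTCSequence, seq_b: QTCSequence, scheme: CostScheme = DEFAULT_SCHEME
):
    """Position-aligned comparison baseline: no insertions or deletions.

    Requires equal lengths; sums the matrix substitution cost at each
    position.  Always an upper bound on the Levenshtein distance.
    """
    _check_roster(seq_a, seq_b)
    if len(seq_a) != len(seq_b):
        raise QTCMatchError(
            f"pairwise comparison needs equal lengths, got {len(seq_a)} and {len(seq_b)}"
        )
    if len(seq_a) == 0:
        return 0
    a = seq_a.codes + 1
    b = seq_b.codes + 1
    return scheme.table[a, b].sum()
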