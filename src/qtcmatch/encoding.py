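"""QTC_B encoding of fragments.

For an ordered pair of objects (k, l) and one inter-sample interval
[t1, t2], the basic Qualitative Trajectory Calculus records whether k
moves towards ('-'), away from ('+'), or neither ('0') with respect to
l's position at t1:

    delta = dist(k(t2), l(t1)) - dist(k(t1), l(t1))
    '-' if delta < -epsilon,  '+' if delta > +epsilon,  else '0'

with Euclidean distance and a dead-band ``epsilon`` (metres, default 0).
A QTC matrix collects the two-character cell for every *informative*
unordered pair — a pair with at least one moving member; static–static
pairs carry no information and are excluded.  A fragment of m samples
encodes to a sequence of m - 1 matrices.

Because only relative distances enter the relations, encoding at
epsilon = 0 is invariant under translation, rotation, reflection and
uniform scaling applied to every object of the fragment.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import QTCMatchError, ValidationError
from .trajectory import Fragment

__all__ = [
    "CHARS",
    "qtc_character",
    "qtc_matrix",
    "encode_sequence",
    "empty_sequence",
    "QTCMatrix",
    "QTCSequence",
]

#: The three QTC_B symbols, indexed by internal code + 1.
CHARS = ("-", "0", "+")

_CODE_TO_CHAR = {-1: "-", 0: "0", 1: "+"}
_CHAR_TO_CODE = {"-": -1, "0": 0, "+": 1}


def qtc_character(
    pos_k_t1,
    pos_k_t2,
    pos_l_t1,
    epsilon: float = 0.0,
) -> str:
    """QTC_B relation of object k with respect to l's interval-start position."""
    if epsilon < 0:
        raise ValidationError(f"epsilon must be >= 0, got {epsilon}")
    p1 = np.asarray(pos_k_t1, dtype=float)
    p2 = np.asarray(pos_k_t2, dtype=float)
    q = np.asarray(pos_l_t1, dtype=float)
    if not (np.all(np.isfinite(p1)) and np.all(np.isfinite(p2)) and np.all(np.isfinite(q))):
        raise ValidationError("non-finite coordinates")
    delta = float(np.linalg.norm(p2 - q) - np.linalg.norm(p1 - q))
    if delta < -epsilon:
        return "-"
    if delta > epsilon:
        return "+"
    return "0"


def _informative_pairs(n_moving: int, n_total: int) -> list[tuple[int, int]]:
    """Index pairs (i < j, roster order) with at least one moving member."""
    return [
        (i, j)
        for i in range(n_total)
        for j in range(i + 1, n_total)
        if i < n_moving or j < n_moving
    ]


@dataclass(frozen=True)
class QTCMatrix:
    """Pairwise QTC_B relations for one inter-sample interval.

    ``codes`` holds one row per informative pair: two int8 codes in
    {-1, 0, +1} standing for '-', '0', '+'.  The first code of the pair
    (a, b) is a's relation w.r.t. b, the second is b's w.r.t. a.
    """

    objects: tuple[str, ...]
    n_moving: int
    pairs: tuple[tuple[str, str], ...]
    codes: np.ndarray  # (n_pairs, 2) int8

    def cell(self, id_a: str, id_b: str) -> tuple[str, str]:
        """Characters (a w.r.t. b, b w.r.t. a); order of arguments respected."""
        for idx, (pa, pb) in enumerate(self.pairs):
            if (pa, pb) == (id_a, id_b):
                c = self.codes[idx]
                return (_CODE_TO_CHAR[int(c[0])], _CODE_TO_CHAR[int(c[1])])
            if (pa, pb) == (id_b, id_a):
                c = self.codes[idx]
                return (_CODE_TO_CHAR[int(c[1])], _CODE_TO_CHAR[int(c[0])])
        raise QTCMatchError(f"no informative pair ({id_a!r}, {id_b!r}) in matrix")

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, QTCMatrix):
            return NotImplemented
        return (
            self.objects == other.objects
            and self.n_moving == other.n_moving
            and np.array_equal(self.codes, other.codes)
        )

    __hash__ = None  # type: ignore[assignment]


@dataclass(frozen=True)
class QTCSequence:
    """Ordered QTC matrices describing one fragment.

    Length equals the fragment's sample count minus one.  ``start_index``
    and ``downsample_factor`` record where the source window sits in the
    original recording and how it was thinned; they are metadata and do
    not affect comparisons.
    """

    objects: tuple[str, ...]
    n_moving: int
    pairs: tuple[tuple[str, str], ...]
    codes: np.ndarray  # (n_intervals, n_pairs, 2) int8
    start_index: int = 0
    downsample_factor: int = 1

    @property
    def n_static(self) -> int:
        return len(self.objects) - self.n_moving

    def __len__(self) -> int:
        return self.codes.shape[0]

    def __getitem__(self, i: int) -> QTCMatrix:
        return QTCMatrix(self.objects, self.n_moving, self.pairs, self.codes[i])

    def __iter__(self):
        for i in range(len(self)):
            yield self[i]

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, QTCSequence):
            return NotImplemented
        return (
            self.objects == other.objects
            and self.n_moving == other.n_moving
            and np.array_equal(self.codes, other.codes)
        )

    __hash__ = None  # type: ignore[assignment]

    def to_text(self) -> str:
        """Plain-text debug serialization: one line per interval.

        Cells are rendered ``idA|idB:xy`` with x = relation of idA w.r.t.
        idB, ids within a cell and cells on a line in lexicographic order.
        Bit-exact across platforms.
        """
        ordered = []
        for idx, (a, b) in enumerate(self.pairs):
            if a <= b:
                ordered.append(((a, b), idx, False))
            else:
                ordered.append(((b, a), idx, True))
        ordered.sort(key=lambda item: item[0])
        lines = []
        for t in range(len(self)):
            cells = []
            for (a, b), idx, flipped in ordered:
                c0, c1 = int(self.codes[t, idx, 0]), int(self.codes[t, idx, 1])
                if flipped:
                    c0, c1 = c1, c0
                cells.append(f"{a}|{b}:{_CODE_TO_CHAR[c0]}{_CODE_TO_CHAR[c1]}")
            lines.append(" ".join(cells))
        return "\n".join(lines) + ("\n" if lines else "")


def _encode_codes(fragment: Fragment, epsilon: float) -> np.ndarray:
    """Vectorised relation codes for all informative pairs and intervals."""
    n_mov = len(fragment.moving)
    n_samp = fragment.n_samples
    statics = fragment.statics
    pos = np.empty((n_mov + len(statics), n_samp, 2), dtype=float)
    for i, tr in enumerate(fragment.moving):
        pos[i] = tr.positions
    for j, sp in enumerate(statics):
        pos[n_mov + j] = sp.position

    p_t1 = pos[:, :-1, :]  # (O, T-1, 2) positions at interval start
    p_t2 = pos[:, 1:, :]   # (O, T-1, 2) positions at interval end
    # dist(k at t2, l at t1) and dist(k at t1, l at t1), broadcast over pairs
    d_after = np.linalg.norm(p_t2[:, None, :, :] - p_t1[None, :, :, :], axis=-1)
    d_before = np.linalg.norm(p_t1[:, None, :, :] - p_t1[None, :, :, :], axis=-1)
    delta = d_after - d_before  # (O, O, T-1); delta[k, l, t] is k w.r.t. l

    codes = np.zeros(delta.shape, dtype=np.int8)
    codes[delta < -epsilon] = -1
    codes[delta > epsilon] = 1

    pairs_idx = _informative_pairs(n_mov, n_mov + len(statics))
    ii = np.array([p[0] for p in pairs_idx])
    jj = np.array([p[1] for p in pairs_idx])
    # stack → (P, T-1, 2); first char = row object w.r.t. column object
    out = np.stack([codes[ii, jj, :], codes[jj, ii, :]], axis=-1)
    return np.ascontiguousarray(out.transpose(1, 0, 2))


def qtc_matrix(fragment: Fragment, interval_index: int, epsilon: float = 0.0) -> QTCMatrix:
    """QTC matrix for one inter-sample interval of the fragment."""
    if fragment.n_samples < 2:
        raise ValidationError("fragment must have at least 2 samples to encode")
    if not (0 <= interval_index < fragment.n_samples - 1):
        raise ValidationError(
            f"interval index {interval_index} out of range "
            f"[0, {fragment.n_samples - 1})"
        )
    seq = encode_sequence(fragment, epsilon)
    return seq[interval_index]


def encode_sequence(
    fragment: Fragment,
    epsilon: float = 0.0,
    *,
    downsample_factor: int = 1,
) -> QTCSequence:
    """Encode a fragment into its QTC_B matrix sequence.

    An m-sample fragment yields m - 1 matrices, one per inter-sample
    interval, each covering every informative object pair.
    """
    if epsilon < 0:
        raise ValidationError(f"epsilon must be >= 0, got {epsilon}")
    if fragment.n_samples < 2:
        raise ValidationError("fragment must have at least 2 samples to encode")
    n_mov = len(fragment.moving)
    roster = fragment.object_ids
    pairs_idx = _informative_pairs(n_mov, len(roster))
    pairs = tuple((roster[i], roster[j]) for i, j in pairs_idx)
    codes = _encode_codes(fragment, epsilon)
    return QTCSequence(
        objects=roster,
        n_moving=n_mov,
        pairs=pairs,
        codes=codes,
        start_index=fragment.start_index,
        downsample_factor=downsample_factor,
    )


def empty_sequence(template: QTCSequence) -> QTCSequence:
    """Zero-length sequence over the same roster (useful as a comparison base)."""
    return QTCSequence(
        objects=template.objects,
        n_moving=template.n_moving,
        pairs=template.pairs,
        codes=np.empty((0,) + template.codes.shape[1:], dtype=np.int8),
        start_index=template.start_index,
        downsample_factor=template.downsample_factor,
    )
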