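"""Independent reference implementations used only to check the package.

These are deliberately naive (exhaustive enumeration, per-cell loops) and
share no code with the dynamic-programming implementation they verify.
"""

from __future__ import annotations

import numpy as np

from qtcmatch.encoding import QTCSequence, _informative_pairs


def exhaustive_alignment_cost(costs_a_b, gap, i=0, j=0):
    """Minimum alignment cost by full recursion over all alignments.

    ``costs_a_b`` is the (len_a, len_b) substitution-cost table, ``gap``
    the insertion/deletion cost.  Exponential; only for tiny sequences.
    """
    la, lb = costs_a_b.shape
    if i == la:
        return (lb - j) * gap
    if j == lb:
        return (la - i) * gap
    return min(
        costs_a_b[i, j] + exhaustive_alignment_cost(costs_a_b, gap, i + 1, j + 1),
        gap + exhaustive_alignment_cost(costs_a_b, gap, i + 1, j),
        gap + exhaustive_alignment_cost(costs_a_b, gap, i, j + 1),
    )


def cellwise_matrix_cost(m1, m2, char_cost) -> float:
    """Matrix substitution cost summed cell by cell with a plain loop."""
    total = 0
    for id_a, id_b in m1.pairs:
        a1, a2 = m1.cell(id_a, id_b)
        b1, b2 = m2.cell(id_a, id_b)
        total += char_cost(a1, b1) + char_cost(a2, b2)
    return total


def random_sequence(
    rng: np.random.Generator,
    length: int,
    n_moving: int = 2,
    n_static: int = 0,
) -> QTCSequence:
    """Random but structurally valid QTC sequence (statics contribute '0')."""
    roster = tuple(f"P{i}" for i in range(n_moving)) + tuple(
        f"S{i}" for i in range(n_static)
    )
    pairs_idx = _informative_pairs(n_moving, n_moving + n_static)
    pairs = tuple((roster[i], roster[j]) for i, j in pairs_idx)
    codes = rng.integers(-1, 2, size=(length, len(pairs_idx), 2)).astype(np.int8)
    for p, (i, j) in enumerate(pairs_idx):
        if j >= n_moving:  # static member: its own relation character is '0'
            codes[:, p, 1] = 0
    return QTCSequence(roster, n_moving, pairs, codes)
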