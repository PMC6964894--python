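"""Reference-fragment matching over sliding candidate windows.

A query fixes a reference fragment, a candidate window geometry
(window length, stride, downsample factor) and the comparison
parameters.  Every fully contained window of the recording is encoded
and compared to the reference; windows that share samples with the
reference window are excluded (otherwise the reference would trivially
rank first).  Results are sorted by ascending normalized distance with
earlier start index breaking ties, then optionally thinned so that no
kept window overlaps a better-ranked one, and cut to the top k.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field, replace
from typing import Mapping, Optional, Sequence

from .distance import CostScheme, DEFAULT_SCHEME, normalized_distance
from .encoding import encode_sequence
from .errors import QTCMatchError, ValidationError
from .trajectory import (
    Fragment,
    Trajectory,
    count_windows,
    downsample,
    make_fragment,
)

__all__ = [
    "MatchQuery",
    "MatchResult",
    "match_reference",
    "match_with_permutations",
    "filter_non_overlapping",
    "top_k",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class MatchQuery:
    """Parameters of one matching run.

    ``window`` defaults to the reference length; ``permutable_ids`` names
    the moving objects whose roles may be exchanged between reference and
    candidate (empty = no permutation search).
    """

    reference: Fragment
    object_ids: tuple[str, ...]
    window: Optional[int] = None
    stride: int = 10
    downsample_factor: int = 10
    epsilon: float = 0.0
    scheme: CostScheme = field(default_factory=lambda: DEFAULT_SCHEME)
    k: int = 9
    permutable_ids: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        object.__setattr__(self, "object_ids", tuple(self.object_ids))
        object.__setattr__(self, "permutable_ids", tuple(self.permutable_ids))
        if self.k < 1:
            raise ValidationError(f"k must be >= 1, got {self.k}")
        if self.stride < 1:
            raise ValidationError(f"stride must be >= 1, got {self.stride}")
        if self.downsample_factor < 1:
            raise ValidationError(
                f"downsample_factor must be >= 1, got {self.downsample_factor}"
            )
        win = self.effective_window
        if win < 2 * self.downsample_factor:
            raise ValidationError(
                f"window ({win}) must be at least twice the downsample factor "
                f"({self.downsample_factor}) to leave >= 2 samples after thinning"
            )
        moving = set(self.reference.moving_ids)
        bad = [p for p in self.permutable_ids if p not in moving]
        if bad:
            raise ValidationError(
                f"permutable ids must be moving objects of the reference: {bad}"
            )

    @property
    def effective_window(self) -> int:
        return self.window if self.window is not None else self.reference.n_samples


@dataclass(frozen=True)
class MatchResult:
    """One candidate window with its distance to the reference."""

    start_index: int
    end_index: int
    start_seconds: float
    raw_cost: float
    normalized: float
    rank: int
    permutation_used: Optional[dict[str, str]] = None


def _overlaps(a_start: int, a_end: int, b_start: int, b_end: int) -> bool:
    """Half-open interval overlap at original sample resolution."""
    return a_start < b_end and b_start < a_end


def _permuted_window(
    recording: Mapping[str, Trajectory],
    query: MatchQuery,
    start: int,
    perm: dict[str, str],
) -> Fragment:
    """Candidate window where role p is played by player perm[p].

    Trajectories are relabelled back to the roster ids so the encoded
    roster matches the reference's.
    """
    window = query.effective_window
    moving = []
    for oid in query.object_ids:
        src = recording[perm.get(oid, oid)]
        seg = src.window(start, window)
        moving.append(Trajectory(oid, seg.positions, seg.sample_interval))
    return Fragment(start, tuple(moving), query.reference.statics)


def _candidate_sequences(query, recording, perms):
    """Yield (start, permutation, QTCSequence) for every admissible window."""
    window = query.effective_window
    ref = query.reference
    n = recording[query.object_ids[0]].n_samples
    total = count_windows(n, window, query.stride)
    excluded = 0
    for w in range(total):
        start = w * query.stride
        if _overlaps(start, start + window, ref.start_index, ref.end_index):
            excluded += 1
            continue
        for perm in perms:
            if perm is None:
                frag = make_fragment(
                    recording, query.object_ids, start, window, ref.statics
                )
            else:
                frag = _permuted_window(recording, query, start, perm)
            thin = downsample(frag, query.downsample_factor)
            seq = encode_sequence(
                thin, query.epsilon, downsample_factor=query.downsample_factor
            )
            yield start, perm, seq
    logger.info(
        "windows generated: %d, excluded (reference overlap): %d",
        total, excluded,
    )


def _run_match(
    query: MatchQuery,
    recording: Mapping[str, Trajectory],
    perms: Sequence[Optional[dict[str, str]]],
) -> list[MatchResult]:
    missing = [oid for oid in query.object_ids if oid not in recording]
    if missing:
        raise ValidationError(f"unknown object id(s): {missing}")
    ref_roster = query.reference.moving_ids
    if tuple(query.object_ids) != ref_roster:
        raise QTCMatchError(
            f"query roster {tuple(query.object_ids)} does not match the "
            f"reference's moving objects {ref_roster}"
        )
    window = query.effective_window
    n = recording[query.object_ids[0]].n_samples
    if window > n:
        raise ValidationError(
            f"recording ({n} samples) shorter than the window ({window})"
        )
    sample_interval = recording[query.object_ids[0]].sample_interval

    ref_thin = downsample(query.reference, query.downsample_factor)
    ref_seq = encode_sequence(
        ref_thin, query.epsilon, downsample_factor=query.downsample_factor
    )

    best: dict[int, tuple[float, float, Optional[dict[str, str]]]] = {}
    for start, perm, seq in _candidate_sequences(query, recording, perms):
        res = normalized_distance(ref_seq, seq, query.scheme)
        cur = best.get(start)
        if cur is None or res.normalized < cur[0]:
            best[start] = (res.normalized, res.raw_cost, perm)

    ordered = sorted(best.items(), key=lambda kv: (kv[1][0], kv[0]))
    return [
        MatchResult(
            start_index=start,
            end_index=start + window,
            start_seconds=start * sample_interval,
            raw_cost=raw,
            normalized=norm,
            rank=rank,
            permutation_used=perm,
        )
        for rank, (start, (norm, raw, perm)) in enumerate(ordered, start=1)
    ]


def match_reference(
    query: MatchQuery, recording: Mapping[str, Trajectory]
) -> list[MatchResult]:
    """Rank all non-overlapping-with-reference candidate windows.

    The reference is encoded once; each window is downsampled, encoded
    and scored with the normalized edit distance.  Returns the full
    ranked list (apply :func:`filter_non_overlapping` / :func:`top_k`
    separately).
    """
    return _run_match(query, recording, perms=[None])


def match_with_permutations(
    query: MatchQuery, recording: Mapping[str, Trajectory]
) -> list[MatchResult]:
    """Like :func:`match_reference` but minimising over role permutations.

    Every permutation of ``query.permutable_ids`` is tried per window and
    the cheapest kept; the identity permutation is always among them, so
    the permuted distance never exceeds the plain one.
    """
    if not query.permutable_ids:
        raise ValidationError("permutable_ids must be non-empty")
    static_ids = set(query.reference.static_ids)
    bad = [p for p in query.permutable_ids if p in static_ids]
    if bad:
        raise ValidationError(f"static points cannot be permuted: {bad}")
    perms: list[Optional[dict[str, str]]] = []
    for assignment in itertools.permutations(query.permutable_ids):
        perms.append(dict(zip(query.permutable_ids, assignment)))
    results = _run_match(query, recording, perms=perms)
    # report identity assignments as "no permutation"
    cleaned = []
    for r in results:
        perm = r.permutation_used
        if perm is not None and all(k == v for k, v in perm.items()):
            r = replace(r, permutation_used=None)
        cleaned.append(r)
    return cleaned


def filter_non_overlapping(ranked: Sequence[MatchResult]) -> list[MatchResult]:
    """Greedily keep best-ranked windows whose intervals are pairwise disjoint.

    Input must already be sorted by rank; survivors are re-ranked 1..n.
    """
    for prev, cur in zip(ranked, ranked[1:]):
        if cur.rank < prev.rank:
            raise QTCMatchError("input to filter_non_overlapping must be sorted by rank")
    kept: list[MatchResult] = []
    for res in ranked:
        if any(
            _overlaps(res.start_index, res.end_index, k.start_index, k.end_index)
            for k in kept
        ):
            continue
        kept.append(res)
    return [replace(r, rank=i) for i, r in enumerate(kept, start=1)]


def top_k(filtered: Sequence[MatchResult], k: int) -> list[MatchResult]:
    """First ``min(k, len)`` results."""
    if k < 1:
        raise ValidationError(f"k must be >= 1, got {k}")
    return list(filtered[:k])
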