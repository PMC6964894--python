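"""Trajectory and fragment data model.

A recording is a mapping ``object_id -> Trajectory`` of uniformly sampled
2-D positions (metres).  A :class:`Fragment` is a time window over one or
more of those trajectories plus optional static anchor points; it is the
unit that gets encoded and compared.  Time is kept as 0-based sample
indices; seconds are derived as ``index * sample_interval``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np

from .errors import ValidationError

__all__ = [
    "Trajectory",
    "StaticPoint",
    "Fragment",
    "make_fragment",
    "downsample",
    "count_windows",
    "slide_windows",
    "samples_for_duration",
]

#: Relative tolerance for declaring two sample intervals equal.
_INTERVAL_RTOL = 1e-9


@dataclass(frozen=True)
class Trajectory:
    """Uniformly sampled 2-D track of one object.

    Parameters
    ----------
    object_id
        Opaque identifier of the tracked object.
    positions
        Array of shape ``(n, 2)`` with x, y in metres; n >= 1.
    sample_interval
        Seconds between consecutive samples (> 0); 0.04 s for 25 Hz feeds.
    """

    object_id: str
    positions: np.ndarray
    sample_interval: float

    def __post_init__(self) -> None:
        pos = np.asarray(self.positions, dtype=float)
        if pos.ndim != 2 or pos.shape[1] != 2 or pos.shape[0] < 1:
            raise ValidationError(
                f"trajectory {self.object_id!r}: positions must be a non-empty "
                f"(n, 2) array, got shape {pos.shape}"
            )
        if not np.all(np.isfinite(pos)):
            raise ValidationError(
                f"trajectory {self.object_id!r}: non-finite coordinates"
            )
        if not (self.sample_interval > 0):
            raise ValidationError(
                f"trajectory {self.object_id!r}: sample_interval must be > 0, "
                f"got {self.sample_interval}"
            )
        object.__setattr__(self, "positions", pos)

    @property
    def n_samples(self) -> int:
        return self.positions.shape[0]

    def window(self, start: int, length: int) -> "Trajectory":
        """Copy of samples ``[start, start + length)``."""
        if start < 0 or length < 1 or start + length > self.n_samples:
            raise ValidationError(
                f"window [{start}, {start + length}) out of range for "
                f"trajectory {self.object_id!r} with {self.n_samples} samples"
            )
        return Trajectory(
            self.object_id, self.positions[start : start + length].copy(),
            self.sample_interval,
        )


@dataclass(frozen=True)
class StaticPoint:
    """A non-moving anchor (e.g. a field corner) with a finite position."""

    point_id: str
    position: tuple[float, float]

    def __post_init__(self) -> None:
        pos = (float(self.position[0]), float(self.position[1]))
        if not np.all(np.isfinite(pos)):
            raise ValidationError(f"static point {self.point_id!r}: non-finite position")
        object.__setattr__(self, "position", pos)


@dataclass(frozen=True)
class Fragment:
    """Movements of a set of objects during one time window.

    ``moving`` trajectories all share the same length and sample interval;
    ``statics`` are anchor points whose position holds for the whole window.
    ``start_index`` locates the window in the source recording at the
    original sampling resolution (it is not rescaled by downsampling).
    """

    start_index: int
    moving: tuple[Trajectory, ...]
    statics: tuple[StaticPoint, ...] = ()

    def __post_init__(self) -> None:
        moving = tuple(self.moving)
        statics = tuple(self.statics)
        if len(moving) < 1:
            raise ValidationError("fragment needs at least one moving trajectory")
        n = moving[0].n_samples
        dt = moving[0].sample_interval
        for tr in moving[1:]:
            if tr.n_samples != n:
                raise ValidationError(
                    f"moving trajectories differ in length: {moving[0].object_id!r} "
                    f"has {n} samples, {tr.object_id!r} has {tr.n_samples}"
                )
            if not np.isclose(tr.sample_interval, dt, rtol=_INTERVAL_RTOL, atol=0):
                raise ValidationError(
                    f"moving trajectories differ in sample interval: "
                    f"{dt} vs {tr.sample_interval} ({tr.object_id!r})"
                )
        ids = [tr.object_id for tr in moving] + [sp.point_id for sp in statics]
        if len(set(ids)) != len(ids):
            raise ValidationError(f"duplicate object ids in fragment: {ids}")
        object.__setattr__(self, "moving", moving)
        object.__setattr__(self, "statics", statics)

    @property
    def n_samples(self) -> int:
        return self.moving[0].n_samples

    @property
    def sample_interval(self) -> float:
        return self.moving[0].sample_interval

    @property
    def moving_ids(self) -> tuple[str, ...]:
        return tuple(tr.object_id for tr in self.moving)

    @property
    def static_ids(self) -> tuple[str, ...]:
        return tuple(sp.point_id for sp in self.statics)

    @property
    def object_ids(self) -> tuple[str, ...]:
        """Roster order: moving objects first, then statics."""
        return self.moving_ids + self.static_ids

    @property
    def end_index(self) -> int:
        """One past the last original-resolution sample index (half-open)."""
        return self.start_index + self.n_samples


def make_fragment(
    recording: Mapping[str, Trajectory],
    object_ids: Sequence[str],
    start: int,
    length: int,
    statics: Iterable[StaticPoint] = (),
) -> Fragment:
    """Window ``[start, start + length)`` of the requested objects.

    All requested trajectories must exist, cover the window, and share one
    length and sample interval; violations raise :class:`ValidationError`.
    """
    if not object_ids:
        raise ValidationError("object_ids must not be empty")
    missing = [oid for oid in object_ids if oid not in recording]
    if missing:
        raise ValidationError(f"unknown object id(s): {missing}")
    trajs = [recording[oid] for oid in object_ids]
    n = trajs[0].n_samples
    dt = trajs[0].sample_interval
    for tr in trajs[1:]:
        if tr.n_samples != n or not np.isclose(
            tr.sample_interval, dt, rtol=_INTERVAL_RTOL, atol=0
        ):
            raise ValidationError(
                f"recording objects have mismatched sampling: "
                f"{trajs[0].object_id!r} ({n} samples @ {dt} s) vs "
                f"{tr.object_id!r} ({tr.n_samples} samples @ {tr.sample_interval} s)"
            )
    if start < 0 or length < 1 or start + length > n:
        raise ValidationError(
            f"window [{start}, {start + length}) out of range for a "
            f"{n}-sample recording"
        )
    return Fragment(
        start_index=start,
        moving=tuple(tr.window(start, length) for tr in trajs),
        statics=tuple(statics),
    )


def downsample(fragment: Fragment, factor: int) -> Fragment:
    """Keep samples at indices 0, factor, 2*factor, ...

    The sample interval is multiplied by ``factor``; statics and the
    original-resolution ``start_index`` are unchanged.
    """
    if int(factor) != factor or factor < 1:
        raise ValidationError(f"downsample factor must be a positive integer, got {factor}")
    factor = int(factor)
    if factor == 1:
        return fragment
    moving = tuple(
        Trajectory(tr.object_id, tr.positions[::factor].copy(),
                   tr.sample_interval * factor)
        for tr in fragment.moving
    )
    return Fragment(fragment.start_index, moving, fragment.statics)


def count_windows(n_samples: int, window: int, stride: int) -> int:
    """Number of fully contained windows starting at 0, stride, 2*stride, ...

    Equals ``floor((n_samples - window) / stride) + 1``.
    """
    if stride < 1:
        raise ValidationError(f"stride must be >= 1, got {stride}")
    if window < 1:
        raise ValidationError(f"window must be >= 1, got {window}")
    if window > n_samples:
        raise ValidationError(
            f"window ({window}) exceeds recording length ({n_samples})"
        )
    return (n_samples - window) // stride + 1


def slide_windows(
    recording: Mapping[str, Trajectory],
    object_ids: Sequence[str],
    window: int,
    stride: int,
    statics: Iterable[StaticPoint] = (),
) -> Iterator[Fragment]:
    """Yield every fully contained window as a Fragment, in start order."""
    statics = tuple(statics)
    if not object_ids:
        raise ValidationError("object_ids must not be empty")
    if object_ids[0] not in recording:
        raise ValidationError(f"unknown object id(s): {[object_ids[0]]}")
    n = recording[object_ids[0]].n_samples
    total = count_windows(n, window, stride)
    for i in range(total):
        yield make_fragment(recording, object_ids, i * stride, window, statics)


def samples_for_duration(seconds: float, rate_hz: float) -> int:
    """Sample count covering ``seconds`` at ``rate_hz`` (e.g. 20 s @ 25 Hz = 500)."""
    if seconds <= 0 or rate_hz <= 0:
        raise ValidationError("duration and rate must be positive")
    n = seconds * rate_hz
    rounded = round(n)
    if abs(n - rounded) > 1e-6 * max(1.0, abs(n)):
        raise ValidationError(
            f"duration {seconds} s at {rate_hz} Hz is not a whole number of samples"
        )
    return int(rounded)
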