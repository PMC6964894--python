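"""Seeded generators for trajectories and full synthetic scenes.

The scene generator emulates the kind of recording the matcher is built
for: 25 Hz pitch-constrained tracks on a 105 m x 68 m field, made of
random-walk "traffic" with known occurrences of a two-player movement
motif (a fast straight run followed by a direction change at lower
speed) planted at annotated windows, optionally under a similarity
transform (translation, rotation, uniform scale).  Traffic samples
carry Gaussian measurement noise; planted motif samples are inserted
exactly so that ground-truth copies are genuinely identical in their
relative movements.  Every generator is a pure function of its seed and
arguments.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple, Optional, Sequence

import numpy as np

from .errors import ValidationError
from .trajectory import Fragment, StaticPoint, Trajectory

__all__ = [
    "straight_run",
    "random_walk",
    "random_fragment",
    "transform_fragment",
    "WarpSegment",
    "time_warp",
    "SceneSpec",
    "PlantedMotif",
    "soccer_scene",
    "two_player_motif",
]

DEFAULT_RATE = 25.0
DEFAULT_FIELD = (105.0, 68.0)


def straight_run(
    start,
    direction,
    speed: float,
    n: int,
    rate: float = DEFAULT_RATE,
    object_id: str = "P1",
) -> Trajectory:
    """Constant-velocity run: position_i = start + i * (speed / rate) * direction."""
    if n < 2:
        raise ValidationError(f"need at least 2 samples, got {n}")
    if speed < 0:
        raise ValidationError(f"speed must be >= 0, got {speed}")
    d = np.asarray(direction, dtype=float)
    norm = np.linalg.norm(d)
    if norm == 0:
        raise ValidationError("direction vector must have non-zero length")
    d = d / norm
    step = (speed / rate) * d
    pos = np.asarray(start, dtype=float) + np.arange(n)[:, None] * step
    return Trajectory(object_id, pos, 1.0 / rate)


def random_walk(
    seed: int,
    start,
    n: int,
    step_sigma: float,
    bounds: Optional[tuple[float, float, float, float]] = None,
    rate: float = DEFAULT_RATE,
    object_id: str = "P1",
) -> Trajectory:
    """Gaussian-step walk, reflected at rectangular bounds (xmin, xmax, ymin, ymax)."""
    if n < 2:
        raise ValidationError(f"need at least 2 samples, got {n}")
    if step_sigma < 0:
        raise ValidationError(f"step_sigma must be >= 0, got {step_sigma}")
    rng = np.random.default_rng(seed)
    steps = rng.normal(0.0, step_sigma, size=(n - 1, 2))
    pos = np.empty((n, 2), dtype=float)
    pos[0] = np.asarray(start, dtype=float)
    if bounds is not None:
        xmin, xmax, ymin, ymax = bounds
        if not (xmin < xmax and ymin < ymax):
            raise ValidationError(f"invalid bounds {bounds}")
    for i in range(1, n):
        p = pos[i - 1] + steps[i - 1]
        if bounds is not None:
            p[0] = _reflect(p[0], xmin, xmax)
            p[1] = _reflect(p[1], ymin, ymax)
        pos[i] = p
    return Trajectory(object_id, pos, 1.0 / rate)


def _reflect(v: float, lo: float, hi: float) -> float:
    span = hi - lo
    v = (v - lo) % (2 * span)
    return lo + (v if v <= span else 2 * span - v)


def random_fragment(
    seed: int,
    n_moving: int,
    n_samples: int,
    statics: Sequence[StaticPoint] = (),
    field: tuple[float, float] = DEFAULT_FIELD,
    step_sigma: float = 0.25,
    rate: float = DEFAULT_RATE,
) -> Fragment:
    """Fragment of independent bounded random walks (one child seed per walk)."""
    rng = np.random.default_rng(seed)
    bounds = (0.0, field[0], 0.0, field[1])
    moving = []
    for i in range(n_moving):
        start = (rng.uniform(0, field[0]), rng.uniform(0, field[1]))
        child = int(rng.integers(0, 2**31 - 1))
        moving.append(
            random_walk(child, start, n_samples, step_sigma, bounds, rate,
                        object_id=f"P{i + 1}")
        )
    return Fragment(0, tuple(moving), tuple(statics))


def transform_fragment(
    fragment: Fragment,
    translation=(0.0, 0.0),
    rotation: float = 0.0,
    scale: float = 1.0,
    transform_statics: bool = False,
) -> Fragment:
    """Apply a similarity transform to every moving position.

    Statics stay fixed by default, so a translated copy moves relative to
    its anchors; pass ``transform_statics=True`` to carry them along.
    """
    if scale <= 0:
        raise ValidationError(f"scale must be > 0, got {scale}")
    t = np.asarray(translation, dtype=float)
    c, s = np.cos(rotation), np.sin(rotation)
    rot = np.array([[c, -s], [s, c]])

    def apply(points: np.ndarray) -> np.ndarray:
        return scale * (points @ rot.T) + t

    moving = tuple(
        Trajectory(tr.object_id, apply(tr.positions), tr.sample_interval)
        for tr in fragment.moving
    )
    statics = fragment.statics
    if transform_statics:
        statics = tuple(
            StaticPoint(sp.point_id, tuple(apply(np.asarray(sp.position)[None, :])[0]))
            for sp in fragment.statics
        )
    return Fragment(fragment.start_index, moving, statics)


class WarpSegment(NamedTuple):
    """Re-timing of samples [start, stop): repeat each sample ``factor``
    times (slow down) or, with ``decimate=True``, keep every ``factor``-th
    sample (speed up).  ``factor`` is a positive integer."""

    start: int
    stop: int
    factor: int
    decimate: bool = False


def time_warp(fragment: Fragment, segment_factors: Sequence[WarpSegment]) -> Fragment:
    """Re-time segments of a fragment along its unchanged spatial path.

    Integer repetition/decimation guarantees the warped trajectories
    revisit exactly the original coordinates, so any distance between the
    original and the warp reflects timing alone.
    """
    n = fragment.n_samples
    segs = [WarpSegment(*s) for s in segment_factors]
    for seg in segs:
        if seg.stop <= seg.start:
            raise ValidationError(f"empty warp segment {seg}")
        if seg.start < 0 or seg.stop > n:
            raise ValidationError(f"warp segment {seg} out of range for {n} samples")
        if int(seg.factor) != seg.factor or seg.factor < 1:
            raise ValidationError(f"warp factor must be a positive integer: {seg}")
    segs.sort(key=lambda s: s.start)
    for a, b in zip(segs, segs[1:]):
        if b.start < a.stop:
            raise ValidationError(f"overlapping warp segments {a} and {b}")

    index: list[int] = []
    cursor = 0
    for seg in segs:
        index.extend(range(cursor, seg.start))
        if seg.decimate:
            index.extend(range(seg.start, seg.stop, seg.factor))
        else:
            for i in range(seg.start, seg.stop):
                index.extend([i] * seg.factor)
        cursor = seg.stop
    index.extend(range(cursor, n))
    idx = np.asarray(index, dtype=int)
    if len(idx) < 2:
        raise ValidationError("warp leaves fewer than 2 samples")

    moving = tuple(
        Trajectory(tr.object_id, tr.positions[idx].copy(), tr.sample_interval)
        for tr in fragment.moving
    )
    return Fragment(fragment.start_index, moving, fragment.statics)


def two_player_motif(
    n_samples: int,
    rate: float = DEFAULT_RATE,
    object_ids: tuple[str, str] = ("P1", "P2"),
) -> np.ndarray:
    """Canonical planted motif, centred at the origin: two parallel players
    sprint (7 m/s) then cut ~110 degrees and slow to 4 m/s.

    Returns positions of shape (2, n_samples, 2).
    """
    if n_samples < 4:
        raise ValidationError("motif needs at least 4 samples")
    split = int(round(n_samples * 0.6))
    n2 = n_samples - split
    offsets = np.array([[0.0, 0.0], [0.0, 6.0]])
    out = np.empty((2, n_samples, 2), dtype=float)
    for p in range(2):
        leg1 = straight_run(offsets[p], (1.0, 0.15), 7.0, split + 1, rate).positions
        # direction change: continue from the last point of leg 1
        leg2 = straight_run(leg1[-1], (-0.35, 0.95), 4.0, max(n2, 2) + 1, rate).positions
        path = np.vstack([leg1[:-1], leg2[1 : n2 + 1]])
        out[p] = path[:n_samples]
    out -= out.reshape(-1, 2).mean(axis=0)
    return out


@dataclass(frozen=True)
class SceneSpec:
    """Recipe for a synthetic tracking scene with planted motif windows.

    Defaults mirror a professional-match setting: 25 Hz sampling on a
    105 m x 68 m pitch, random-walk traffic with 5 cm measurement noise.
    """

    seed: int = 0
    n_players: int = 2
    duration: float = 120.0
    rate: float = DEFAULT_RATE
    field: tuple[float, float] = DEFAULT_FIELD
    step_sigma: float = 0.25
    noise_sigma: float = 0.05
    motif_length: int = 200
    n_exact: int = 3
    n_transformed: int = 2
    plant_grid: int = 1
    margin: int = 50

    def __post_init__(self) -> None:
        if self.rate <= 0 or self.duration <= 0:
            raise ValidationError("rate and duration must be positive")
        if self.n_players < 2:
            raise ValidationError("scene needs at least the two motif players")
        if self.noise_sigma < 0 or self.step_sigma < 0:
            raise ValidationError("sigmas must be >= 0")
        if self.plant_grid < 1 or self.margin < 0:
            raise ValidationError("plant_grid must be >= 1 and margin >= 0")

    @property
    def n_samples(self) -> int:
        return int(round(self.duration * self.rate))


class PlantedMotif(NamedTuple):
    """Ground-truth annotation of one planted window."""

    motif_id: str
    start_index: int
    end_index: int
    transform: str


def _plant_starts(rng, spec: SceneSpec, n_copies: int) -> list[int]:
    """Non-overlapping, grid-aligned start indices with a safety margin."""
    slot = spec.motif_length + spec.margin
    free = spec.n_samples - n_copies * slot
    if free < 0:
        raise ValidationError(
            f"{n_copies} motif copies of {spec.motif_length} samples do not "
            f"fit in {spec.n_samples} samples"
        )
    offsets = np.sort(rng.integers(0, free + 1, size=n_copies))
    starts = []
    for i, off in enumerate(offsets):
        s = int(off) + i * slot
        s = (s // spec.plant_grid) * spec.plant_grid
        starts.append(s)
    return starts


def soccer_scene(spec: SceneSpec):
    """Generate a recording plus ground-truth annotations of planted motifs.

    Returns ``(recording, annotations)``: a mapping id -> Trajectory for
    players P1..Pn, and one :class:`PlantedMotif` per planted window.
    The first two players carry the planted copies; exact copies differ
    from the canonical motif only by translation (hence identical
    relative movements), transformed copies additionally by rotation and
    uniform scale.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n_samples
    if spec.n_exact + spec.n_transformed > 0 and spec.motif_length > n:
        raise ValidationError("motif longer than the scene")
    bounds = (0.0, spec.field[0], 0.0, spec.field[1])

    tracks = {}
    for i in range(spec.n_players):
        start = (rng.uniform(5, spec.field[0] - 5), rng.uniform(5, spec.field[1] - 5))
        child = int(rng.integers(0, 2**31 - 1))
        base = random_walk(child, start, n, spec.step_sigma, bounds, spec.rate,
                           object_id=f"P{i + 1}")
        noisy = base.positions + rng.normal(0.0, spec.noise_sigma, size=(n, 2))
        np.clip(noisy[:, 0], 0.0, spec.field[0], out=noisy[:, 0])
        np.clip(noisy[:, 1], 0.0, spec.field[1], out=noisy[:, 1])
        tracks[f"P{i + 1}"] = noisy

    annotations: list[PlantedMotif] = []
    n_copies = spec.n_exact + spec.n_transformed
    if n_copies:
        motif = two_player_motif(spec.motif_length, spec.rate)
        # worst-case placement radius: any rotation, scale up to 1.2
        half_extent = float(np.linalg.norm(motif, axis=-1).max()) * 1.2 + 1.0
        cx = (half_extent, spec.field[0] - half_extent)
        cy = (half_extent, spec.field[1] - half_extent)
        if cx[0] >= cx[1] or cy[0] >= cy[1]:
            raise ValidationError(
                f"motif of {spec.motif_length} samples (radius ~{half_extent:.1f} m) "
                f"does not fit on a {spec.field[0]} x {spec.field[1]} m field"
            )
        starts = _plant_starts(rng, spec, n_copies)
        kinds = ["exact"] * spec.n_exact + ["transformed"] * spec.n_transformed
        for j, (start, kind) in enumerate(zip(starts, kinds)):
            centre = np.array([rng.uniform(*cx), rng.uniform(*cy)])
            if kind == "exact":
                rotation, scale = 0.0, 1.0
                label = "exact"
            else:
                rotation = float(rng.uniform(0, 2 * np.pi))
                scale = float(rng.uniform(0.7, 1.2))
                label = f"sim(rot={rotation:.3f},scale={scale:.3f})"
            c, s = np.cos(rotation), np.sin(rotation)
            rot = np.array([[c, -s], [s, c]])
            placed = scale * (motif @ rot.T) + centre
            for p in range(2):
                tracks[f"P{p + 1}"][start : start + spec.motif_length] = placed[p]
            annotations.append(
                PlantedMotif(f"copy{j}", start, start + spec.motif_length, label)
            )

    recording = {
        oid: Trajectory(oid, pos, 1.0 / spec.rate) for oid, pos in tracks.items()
    }
    return recording, annotations
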