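"""Synthetic scenes, trajectories and group samples with exact ground truth.

Scenes are built from pixelated disks so true object areas and pairwise
overlaps are known pixel-for-pixel. Inter-channel overlap is engineered by
copying objects between channels (full overlap) plus at most one
connected partial object carved out of a source disk, so the total overlap
area hits ``round(f * smaller-channel designated area)`` exactly rather than
in expectation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import ndimage

from .io import IntensityImage, ProbabilityMask
from .locomotion import Trajectory
from .stats import GroupData

__all__ = [
    "ChannelSpec",
    "OverlapSpec",
    "SceneSpec",
    "GroundTruth",
    "Scene",
    "TrajectorySpec",
    "generate_scene",
    "generate_trajectory",
    "analytic_time_above",
    "generate_groups",
]


# ---------------------------------------------------------------------------
# scene specification
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ChannelSpec:
    """Recipe for one fluorescence channel of disk-like objects."""

    name: str
    n_objects: int
    radius_min: int = 3
    radius_max: int = 5
    interior_probability: float = 1.0
    intensity: float = 100.0

    def __post_init__(self) -> None:
        if self.n_objects < 0:
            raise ValueError("n_objects must be >= 0")
        if not 1 <= self.radius_min <= self.radius_max:
            raise ValueError("need 1 <= radius_min <= radius_max")
        if not 0 < self.interior_probability <= 1:
            raise ValueError("interior_probability must be in (0, 1]")
        if self.intensity <= 0:
            raise ValueError("intensity must be positive")


@dataclass(frozen=True)
class OverlapSpec:
    """Engineered overlap between two channels (by index into the channel list)."""

    channel_a: int = 0
    channel_b: int = 1
    fraction: float = 0.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.fraction <= 1.0:
            raise ValueError("fraction must be in [0, 1]")


@dataclass(frozen=True)
class SceneSpec:
    shape: tuple[int, int] = (128, 128)
    channels: tuple[ChannelSpec, ...] = ()
    overlap: OverlapSpec | None = None
    probability_blur_sigma: float = 0.0
    background_noise_prob: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.shape) < 8:
            raise ValueError("scene must be at least 8x8")
        if not self.channels:
            raise ValueError("at least one channel required")
        if not 0.0 <= self.background_noise_prob < 1.0:
            raise ValueError("background_noise_prob must be in [0, 1)")
        if self.probability_blur_sigma < 0:
            raise ValueError("blur sigma must be >= 0")
        if self.overlap is not None:
            k = len(self.channels)
            if not (0 <= self.overlap.channel_a < k and 0 <= self.overlap.channel_b < k):
                raise ValueError("overlap channel index out of range")
            if self.overlap.channel_a == self.overlap.channel_b:
                raise ValueError("overlap channels must differ")


@dataclass
class GroundTruth:
    """Exact per-channel labels/areas and the engineered pairwise overlap."""

    label_maps: list[np.ndarray]
    areas: list[list[int]]
    overlap_area_px: int
    overlap_mask: np.ndarray | None


@dataclass
class Scene:
    spec: SceneSpec
    intensity: list[IntensityImage]
    probability: list[ProbabilityMask]
    truth: GroundTruth


# ---------------------------------------------------------------------------
# disk machinery
# ---------------------------------------------------------------------------

def _disk_offsets(radius: int) -> np.ndarray:
    """(k, 2) row/col offsets of pixels whose centers fall within ``radius``."""
    rr, cc = np.mgrid[-radius : radius + 1, -radius : radius + 1]
    keep = rr**2 + cc**2 <= radius**2
    return np.column_stack([rr[keep], cc[keep]])


def _place_disks(
    rng: np.random.Generator,
    shape: tuple[int, int],
    radii: Sequence[int],
    blocked: list[tuple[int, int, int]],
    max_tries: int = 2000,
) -> list[tuple[int, int, int]]:
    """Rejection-sample non-overlapping integer disk centers avoiding ``blocked``.

    Entries are (row, col, radius); separation > r1 + r2 + 1 guarantees the
    pixelated disks neither touch nor merge under 8-connectivity.
    """
    placed: list[tuple[int, int, int]] = []
    for r in radii:
        lo_r, hi_r = r + 1, shape[0] - r - 2
        lo_c, hi_c = r + 1, shape[1] - r - 2
        if hi_r < lo_r or hi_c < lo_c:
            raise ValueError(f"disk radius {r} does not fit the grid {shape}")
        for _ in range(max_tries):
            row = int(rng.integers(lo_r, hi_r + 1))
            col = int(rng.integers(lo_c, hi_c + 1))
            ok = all(
                (row - pr) ** 2 + (col - pc) ** 2 > (r + pr2 + 1) ** 2
                for pr, pc, pr2 in placed + blocked
            )
            if ok:
                placed.append((row, col, r))
                break
        else:
            raise ValueError(
                "could not place all objects; the scene spec is too dense"
            )
    return placed


def _partial_subset(offsets: np.ndarray, k: int) -> np.ndarray:
    """A connected k-pixel subset of a disk: leftmost full columns plus a
    centered slice of the next column (always 8-connected to the previous one)."""
    order = np.lexsort((offsets[:, 0], offsets[:, 1]))  # by column then row
    offsets = offsets[order]
    taken: list[np.ndarray] = []
    count = 0
    for col in np.unique(offsets[:, 1]):
        col_px = offsets[offsets[:, 1] == col]
        col_px = col_px[np.argsort(col_px[:, 0])]
        need = k - count
        if need <= 0:
            break
        if need >= len(col_px):
            taken.append(col_px)
            count += len(col_px)
        else:
            start = (len(col_px) - need) // 2  # centered slice spans the mid-row
            taken.append(col_px[start : start + need])
            count += need
    return np.concatenate(taken)


def _paint(labels: np.ndarray, pixels: np.ndarray, label: int) -> None:
    labels[pixels[:, 0], pixels[:, 1]] = label


# ---------------------------------------------------------------------------
# scene generation
# ---------------------------------------------------------------------------

def generate_scene(spec: SceneSpec) -> Scene:
    """Render a seeded synthetic scene with exact ground truth.

    Within a channel, objects never touch. For the designated overlap pair,
    the total inter-channel overlap equals ``round(f * S)`` exactly, where
    ``S`` is the total designated area of the smaller channel. Probability
    masks carry ``interior_probability`` inside objects, optional uniform
    salt noise on the background, then optional Gaussian blur.
    """
    rng = np.random.default_rng(spec.seed)
    shape = spec.shape
    n_ch = len(spec.channels)
    pixel_sets: list[list[np.ndarray]] = [[] for _ in range(n_ch)]

    ov = spec.overlap
    order = list(range(n_ch))
    if ov is not None:
        # generate the source channel first so the partner can copy from it
        order.remove(ov.channel_a)
        order.insert(0, ov.channel_a)

    blocked: list[tuple[int, int, int]] = []
    radii_by_ch: dict[int, list[int]] = {}
    for ci in order:
        ch = spec.channels[ci]
        radii = [
            int(rng.integers(ch.radius_min, ch.radius_max + 1))
            for _ in range(ch.n_objects)
        ]
        radii_by_ch[ci] = radii
        if ov is not None and ci == ov.channel_b:
            continue  # constructed below from channel_a
        centers = _place_disks(rng, shape, radii, blocked)
        blocked.extend(centers)
        for row, col, r in centers:
            pixel_sets[ci].append(_disk_offsets(r) + (row, col))

    overlap_area = 0
    if ov is not None:
        pixel_sets[ov.channel_b], overlap_area = _build_overlap_channel(
            rng,
            shape,
            src_objects=pixel_sets[ov.channel_a],
            radii=radii_by_ch[ov.channel_b],
            fraction=ov.fraction,
            blocked=blocked,
        )

    label_maps, areas = [], []
    for ci in range(n_ch):
        labels = np.zeros(shape, dtype=np.int32)
        for i, px in enumerate(pixel_sets[ci], start=1):
            _paint(labels, px, i)
        label_maps.append(labels)
        areas.append([len(px) for px in pixel_sets[ci]])

    overlap_mask = None
    if ov is not None:
        overlap_mask = (label_maps[ov.channel_a] > 0) & (label_maps[ov.channel_b] > 0)
        assert int(overlap_mask.sum()) == overlap_area, "overlap bookkeeping broke"

    intensity, probability = [], []
    for ci, ch in enumerate(spec.channels):
        fg = label_maps[ci] > 0
        img = np.where(fg, ch.intensity, 0.0)
        probs = np.where(fg, ch.interior_probability, 0.0)
        if spec.background_noise_prob > 0:
            salt = (rng.random(shape) < spec.background_noise_prob) & ~fg
            probs = np.where(salt, rng.random(shape), probs)
        if spec.probability_blur_sigma > 0:
            probs = ndimage.gaussian_filter(probs, spec.probability_blur_sigma)
            probs = np.clip(probs, 0.0, 1.0)
        # rendered masks must agree with ground truth pixel-for-pixel
        assert np.array_equal(fg, label_maps[ci] > 0)
        intensity.append(IntensityImage(img, channel_name=ch.name))
        probability.append(ProbabilityMask(probs, channel_name=ch.name))

    truth = GroundTruth(
        label_maps=label_maps,
        areas=areas,
        overlap_area_px=overlap_area,
        overlap_mask=overlap_mask,
    )
    return Scene(spec=spec, intensity=intensity, probability=probability, truth=truth)


def _build_overlap_channel(
    rng: np.random.Generator,
    shape: tuple[int, int],
    src_objects: list[np.ndarray],
    radii: list[int],
    fraction: float,
    blocked: list[tuple[int, int, int]],
) -> tuple[list[np.ndarray], int]:
    """Construct the partner channel so total overlap is exact.

    Overlap budget K = round(f * S_small): filled with full copies of source
    objects, then one connected partial subset of the next source object; the
    remaining object quota is placed disjoint from everything.
    """
    src_areas = [len(px) for px in src_objects]
    cap_b = sum(src_areas[: len(radii)]) if radii else 0
    s_small = min(sum(src_areas), cap_b) if radii else 0
    target = int(round(fraction * s_small))

    objects: list[np.ndarray] = []
    remaining = target
    used = 0
    for px in src_objects:
        if len(objects) >= len(radii) or remaining == 0:
            break
        if remaining >= len(px):
            objects.append(px.copy())
            remaining -= len(px)
        else:
            objects.append(_partial_subset(px, remaining))
            remaining = 0
        used += 1
    if remaining > 0:
        raise ValueError(
            f"overlap fraction {fraction} not achievable: short {remaining} px"
        )
    n_free = len(radii) - len(objects)
    if n_free:
        centers = _place_disks(rng, shape, radii[:n_free], blocked)
        blocked.extend(centers)
        for row, col, r in centers:
            objects.append(_disk_offsets(r) + (row, col))
    return objects, target


# ---------------------------------------------------------------------------
# trajectories
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TrajectorySpec:
    """Piecewise-constant-speed track recipe.

    ``segments`` are ``(length_s, speed_mm_s, heading_rad)`` and must tile
    ``duration_s`` in whole multiples of ``dt_s``; ``immobile_runs`` are
    ``(start_s, length_s)`` windows forced to zero velocity, also dt-aligned.
    """

    duration_s: float = 300.0
    dt_s: float = 1.0
    segments: tuple[tuple[float, float, float], ...] = ((300.0, 3.0, 0.0),)
    immobile_runs: tuple[tuple[float, float], ...] = ()
    seed: int = 0

    def __post_init__(self) -> None:
        if self.dt_s <= 0 or self.duration_s <= 0:
            raise ValueError("duration and dt must be positive")
        total = sum(s[0] for s in self.segments)
        if abs(total - self.duration_s) > 1e-9:
            raise ValueError("segments must tile the duration exactly")
        for length, speed, _ in self.segments:
            if speed < 0:
                raise ValueError("speeds must be >= 0")
            if abs(length / self.dt_s - round(length / self.dt_s)) > 1e-9:
                raise ValueError("segment lengths must be multiples of dt")
        for start, length in self.immobile_runs:
            for v in (start, length):
                if abs(v / self.dt_s - round(v / self.dt_s)) > 1e-9:
                    raise ValueError("immobile runs must be dt-aligned")
            if start < 0 or start + length > self.duration_s + 1e-9:
                raise ValueError("immobile run outside the assay window")


def _interval_speed_plan(spec: TrajectorySpec) -> np.ndarray:
    """Nominal speed of every dt interval after immobile-run overrides."""
    n = int(round(spec.duration_s / spec.dt_s))
    speeds = np.empty(n)
    headings = np.empty(n)
    i = 0
    for length, speed, heading in spec.segments:
        m = int(round(length / spec.dt_s))
        speeds[i : i + m] = speed
        headings[i : i + m] = heading
        i += m
    for start, length in spec.immobile_runs:
        a = int(round(start / spec.dt_s))
        b = a + int(round(length / spec.dt_s))
        speeds[a:b] = 0.0
    return np.column_stack([speeds, headings])


def generate_trajectory(spec: TrajectorySpec, fly_id: str = "fly") -> Trajectory:
    """Sample the track at dt resolution; each interval's sampled speed equals
    its nominal segment speed up to float rounding (exactly, for axis-aligned
    headings)."""
    plan = _interval_speed_plan(spec)
    n = len(plan)
    t = np.arange(n + 1) * spec.dt_s
    dx = plan[:, 0] * np.cos(plan[:, 1]) * spec.dt_s
    dy = plan[:, 0] * np.sin(plan[:, 1]) * spec.dt_s
    x = np.concatenate([[0.0], np.cumsum(dx)])
    y = np.concatenate([[0.0], np.cumsum(dy)])
    return Trajectory(t=t, x=x, y=y, fly_id=fly_id)


def analytic_time_above(spec: TrajectorySpec, threshold_mm_s: float) -> float:
    """Exact time the planned speed is strictly above ``threshold_mm_s``.

    Matches the sampled trajectory's metric whenever every segment speed is
    farther from the threshold than float rounding error.
    """
    plan = _interval_speed_plan(spec)
    return float(np.sum(plan[:, 0] > threshold_mm_s) * spec.dt_s)


# ---------------------------------------------------------------------------
# group samples for the statistics module
# ---------------------------------------------------------------------------

def generate_groups(
    k: int,
    n_per_group: int,
    shift: Sequence[float] | float = 0.0,
    seed: int = 0,
    scale: float = 1.0,
) -> GroupData:
    """Draw ``k`` normal groups with per-group location shifts.

    ``shift`` may be a scalar applied to every group after the first, or a
    length-k sequence; all-zero shifts give an exchangeable null.
    """
    if n_per_group < 1:
        raise ValueError("n_per_group must be >= 1")
    if np.isscalar(shift):
        shifts = [0.0] + [float(shift)] * (k - 1)
    else:
        shifts = [float(s) for s in shift]  # type: ignore[union-attr]
        if len(shifts) != k:
            raise ValueError("shift sequence must have length k")
    rng = np.random.default_rng(seed)
    return GroupData(
        groups={
            f"g{i}": rng.normal(loc=shifts[i], scale=scale, size=n_per_group)
            for i in range(k)
        }
    )
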