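"""Movement-phase analytics on time-ordered PCA score trajectories.

The frames of an ultrasound loop, projected onto the first few principal
components, trace a trajectory in the score plot.  Direction changes of that
trajectory mark the turning phases of the movement; the Euclidean distance
between adjacent frames measures instantaneous tissue dynamics; repeated
movements (e.g. successive heel raises) appear as repeated score excursions
whose similarity can be quantified by correlating their time-normalised
score profiles.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import find_peaks

__all__ = [
    "ScoreTrajectory",
    "RepetitionSegments",
    "SegmentationError",
    "DegenerateSegmentError",
    "adjacent_distances",
    "detect_turning_points",
    "segment_repetitions",
    "repetition_correlation",
]


class SegmentationError(ValueError):
    """Could not split the trajectory into the requested repetitions."""


class DegenerateSegmentError(ValueError):
    """A repetition segment has no score variation; correlation undefined."""


@dataclass
class ScoreTrajectory:
    """Time-ordered score vectors with optional phase annotations.

    Row order is acquisition order.  ``annotations`` is a list of
    ``(frame_index, label)`` marks.
    """

    scores: np.ndarray
    frame_rate: float | None = None
    annotations: list[tuple[int, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.scores = np.atleast_2d(np.asarray(self.scores, dtype=np.float64))
        if self.scores.shape[0] < self.scores.shape[1] and self.scores.shape[0] == 1:
            self.scores = self.scores.T  # single component given as a row
        for idx, _label in self.annotations:
            if not 0 <= idx < self.n_frames:
                raise ValueError(f"annotation frame {idx} out of range")

    @property
    def n_frames(self) -> int:
        return self.scores.shape[0]

    @property
    def n_components(self) -> int:
        return self.scores.shape[1]

    def component(self, index: int) -> np.ndarray:
        if not 0 <= index < self.n_components:
            raise ValueError(f"component {index} out of range (k={self.n_components})")
        return self.scores[:, index]

    def annotate(self, frame_index: int, label: str) -> None:
        if not 0 <= frame_index < self.n_frames:
            raise ValueError(f"annotation frame {frame_index} out of range")
        self.annotations.append((int(frame_index), label))


@dataclass
class RepetitionSegments:
    """Ordered, non-overlapping half-open ``[start, end)`` frame intervals."""

    segments: list[tuple[int, int]]
    n_frames: int

    def __post_init__(self) -> None:
        prev_end = 0
        for i, (s, e) in enumerate(self.segments):
            if not 0 <= s < e <= self.n_frames:
                raise ValueError(f"segment {i} = [{s}, {e}) outside sequence of {self.n_frames}")
            if s < prev_end:
                raise ValueError(f"segment {i} overlaps its predecessor")
            prev_end = e

    def __len__(self) -> int:
        return len(self.segments)

    def __iter__(self):
        return iter(self.segments)

    def __getitem__(self, i: int) -> tuple[int, int]:
        return self.segments[i]


def _smoothed(x: np.ndarray, window: int) -> np.ndarray:
    """Centered moving average with reflected edges; window forced odd."""
    n = x.size
    if window < 1:
        raise ValueError(f"smooth_window must be >= 1, got {window}")
    if window >= n:
        raise ValueError(f"smooth_window={window} must be smaller than the series length {n}")
    if window == 1:
        return x.astype(np.float64)
    if window % 2 == 0:
        window += 1
    half = window // 2
    padded = np.pad(x.astype(np.float64), half, mode="reflect")
    kernel = np.full(window, 1.0 / window)
    return np.convolve(padded, kernel, mode="valid")


def _plateau_center(s: np.ndarray, peak: int, prominence: float) -> int:
    """Median frame of the contiguous band around ``peak`` within 5% of its
    prominence; robust location for flat, noise-dominated extrema."""
    thresh = s[peak] - 0.05 * prominence
    lo = peak
    while lo > 0 and s[lo - 1] >= thresh:
        lo -= 1
    hi = peak
    while hi < s.size - 1 and s[hi + 1] >= thresh:
        hi += 1
    return lo + (hi - lo) // 2


def adjacent_distances(traj: ScoreTrajectory) -> np.ndarray:
    """Euclidean distance between consecutive frames in score space.

    Large distances mark dynamic phases (tissue compressing or stretching);
    tethered frames mark holds and turning zones.  Invariant to orthogonal
    rotations of the score space.
    """
    if traj.n_frames < 2:
        raise ValueError("need at least 2 frames")
    return np.linalg.norm(np.diff(traj.scores, axis=0), axis=1)


def detect_turning_points(
    traj: ScoreTrajectory,
    component: int = 0,
    smooth_window: int = 5,
    min_separation: int = 10,
    min_prominence: float | None = None,
    return_kinds: bool = False,
):
    """Frames at which the chosen score changes direction.

    The score is smoothed with a centered moving average, then interior local
    extrema are located (maxima and minima), at least ``min_separation``
    frames apart.  ``min_prominence`` (default: 5% of the smoothed score's
    range) suppresses noise-scale wiggles in flat phases; endpoints are never
    returned.

    Returns sorted frame indices; with ``return_kinds`` also an array of
    +1 (maximum) / -1 (minimum) per turn.
    """
    if traj.n_frames < 3:
        raise ValueError("need at least 3 frames to detect turns")
    s = _smoothed(traj.component(component), smooth_window)
    if min_prominence is None:
        min_prominence = 0.05 * float(np.ptp(s))
    if min_separation < 1:
        raise ValueError(f"min_separation must be >= 1, got {min_separation}")
    kwargs = dict(distance=min_separation, prominence=min_prominence or None)
    maxima, props_max = find_peaks(s, **kwargs)
    minima, props_min = find_peaks(-s, **kwargs)
    # a hold phase makes the extremum a noisy plateau: re-centre each turn on
    # the median frame of the band within 5% of the peak's prominence
    maxima = np.array(
        [_plateau_center(s, f, p) for f, p in zip(maxima, props_max["prominences"])], dtype=int
    ) if maxima.size else maxima
    minima = np.array(
        [_plateau_center(-s, f, p) for f, p in zip(minima, props_min["prominences"])], dtype=int
    ) if minima.size else minima
    turns = np.concatenate([maxima, minima])
    kinds = np.concatenate([np.ones(maxima.size, int), -np.ones(minima.size, int)])
    order = np.argsort(turns)
    turns, kinds = turns[order], kinds[order]
    if return_kinds:
        return turns, kinds
    return turns


def segment_repetitions(
    traj: ScoreTrajectory,
    n_reps: int,
    component: int = 0,
    smooth_window: int = 5,
) -> RepetitionSegments:
    """Split the trajectory into ``n_reps`` repetition segments.

    The chosen score is smoothed and oriented so that movement excursions
    point away from the starting (rest) level: repetitions are assumed to
    begin and end near rest, so the score is flipped when the start level
    sits closer to the maximum than to the minimum.  The sequence is then
    cut at the ``n_reps - 1`` deepest return-to-baseline dips, where the
    baseline is the median of the smoothed score — robust to asymmetric
    dwell times.  Each cut lands at the deepest frame of an interior
    below-baseline run.
    """
    n = traj.n_frames
    if n_reps < 1:
        raise ValueError(f"n_reps must be >= 1, got {n_reps}")
    if n_reps == 1:
        return RepetitionSegments([(0, n)], n)
    s = _smoothed(traj.component(component), smooth_window)
    rest_level = float(np.mean(s[: max(smooth_window, 2)]))
    if (s.max() - rest_level) < (rest_level - s.min()):
        s = -s
    baseline = float(np.median(s))
    below = s <= baseline
    # contiguous interior below-baseline runs
    runs: list[tuple[int, int]] = []
    start = None
    for i, b in enumerate(below):
        if b and start is None:
            start = i
        elif not b and start is not None:
            runs.append((start, i))
            start = None
    if start is not None:
        runs.append((start, n))
    interior = [(a, b) for a, b in runs if a > 0 and b < n]
    if len(interior) < n_reps - 1:
        raise SegmentationError(
            f"found only {len(interior)} return-to-baseline dips but need {n_reps - 1}; "
            "supply manual boundaries or reduce n_reps"
        )
    cuts = []
    for a, b in interior:
        run = s[a:b]
        smin = float(run.min())
        depth = baseline - smin
        # the dip bottom can be flat and noise-dominated; cut at the median
        # frame of the near-minimum band rather than the raw argmin
        band = np.flatnonzero(run <= smin + 0.05 * depth)
        idx = a + int(band[band.size // 2])
        cuts.append((depth, idx))
    cuts.sort(key=lambda t: (-t[0], t[1]))
    boundaries = sorted(idx for _depth, idx in cuts[: n_reps - 1])
    edges = [0, *boundaries, n]
    return RepetitionSegments([(edges[i], edges[i + 1]) for i in range(n_reps)], n)


def repetition_correlation(
    traj: ScoreTrajectory,
    segs: RepetitionSegments,
    component: int = 0,
    resample_len: int = 100,
) -> np.ndarray:
    """Pairwise Pearson correlation of time-normalised repetition profiles.

    Each segment's chosen score is linearly resampled to ``resample_len``
    points before correlating, which absorbs duration differences between
    repetitions.  The result is symmetric with a unit diagonal and is
    invariant to affine rescaling of each segment's score.
    """
    if len(segs) < 2:
        raise ValueError("need at least 2 segments")
    if resample_len < 3:
        raise ValueError("resample_len must be >= 3")
    score = traj.component(component)
    profiles = []
    for i, (a, b) in enumerate(segs):
        y = score[a:b]
        if y.size < 3:
            raise ValueError(f"segment {i} has fewer than 3 frames")
        if np.ptp(y) == 0 or np.std(y) < 1e-15:
            raise DegenerateSegmentError(f"segment {i} is constant; correlation undefined")
        xs = np.linspace(0.0, 1.0, y.size)
        xt = np.linspace(0.0, 1.0, resample_len)
        profiles.append(np.interp(xt, xs, y))
    return np.corrcoef(np.stack(profiles))
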