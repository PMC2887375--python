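"""Synthetic speckle sequences with exact ground truth.

No study data accompany the method, so validation runs on simulated
ultrasound-like loops: random point scatterers blurred by a Gaussian
point-spread function give a speckle-textured base image, which is warped
per frame by a known motion model and corrupted with additive noise.  The
warp is depth-graded shear (superficial tissue moves less than deep tissue,
as in a heel raise), rigid translation, or cyclic flexion-like motion, with
an amplitude profile built from rest / concentric / hold / eccentric phases.
Because the motion map is piecewise linear in depth it is inverted exactly,
so every rendered frame is consistent with the returned dense displacement
field by construction.

Same spec + seed => bit-identical frames and ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter, map_coordinates, spline_filter

from .image_io import ImageSequence

__all__ = [
    "MotionPhase",
    "SyntheticSpec",
    "GroundTruth",
    "build_phase_profile",
    "render_sequence",
    "heel_raise_preset",
]

DEFAULT_FRAME_RATE = 78.6  # typical high-frame-rate musculoskeletal acquisition

_PHASE_LABELS = ("rest", "concentric", "hold", "eccentric")


@dataclass(frozen=True)
class MotionPhase:
    """One phase of a movement amplitude profile.

    ``concentric`` ramps the amplitude linearly up to the repetition peak,
    ``hold`` keeps it there, ``eccentric`` ramps linearly back to zero and
    ``rest`` holds zero.
    """

    label: str
    duration: int

    def __post_init__(self) -> None:
        if self.label not in _PHASE_LABELS:
            raise ValueError(f"label must be one of {_PHASE_LABELS}, got {self.label!r}")
        if self.duration < 1:
            raise ValueError(f"duration must be >= 1, got {self.duration}")


def build_phase_profile(
    phases: list[MotionPhase], peaks: float | list[float] = 1.0
) -> tuple[np.ndarray, list[str]]:
    """Per-frame amplitude in [0, 1] plus phase labels, continuous across
    phase boundaries.  ``peaks`` may be a per-repetition list (consumed one
    peak per concentric phase) to model inter-repetition variation."""
    if np.isscalar(peaks):
        peaks = [float(peaks)] * sum(1 for ph in phases if ph.label == "concentric")
    peaks = list(peaks)
    amp: list[float] = []
    labels: list[str] = []
    cur = 0.0
    rep = 0
    target = 0.0
    for ph in phases:
        if ph.label == "concentric":
            target = peaks[rep]
            rep += 1
            steps = cur + (target - cur) * (np.arange(1, ph.duration + 1) / ph.duration)
        elif ph.label == "eccentric":
            steps = cur + (0.0 - cur) * (np.arange(1, ph.duration + 1) / ph.duration)
        else:  # rest / hold keep the current amplitude
            steps = np.full(ph.duration, cur)
        amp.extend(steps.tolist())
        labels.extend([ph.label] * ph.duration)
        cur = float(steps[-1])
    profile = np.asarray(amp)
    m = profile.max()
    if m > 1.0:
        profile = profile / m
    return profile, labels


@dataclass
class SyntheticSpec:
    """Full description of a synthetic speckle sequence.

    motion models
    -------------
    ``translation``   rigid motion of ``translation_per_frame`` px per frame.
    ``depth_shear``   row-direction displacement growing linearly with depth
                      from ``surface_gain * max_displacement`` at the top row
                      to ``max_displacement`` at the bottom row (optionally
                      through ``layer_boundaries``/``layer_gains`` knots),
                      scaled by the amplitude profile.
    ``cyclic_flexion`` depth shear driven by a cyclic amplitude profile
                      (``period`` frames per cycle when no explicit profile
                      is given).
    """

    frame_shape: tuple[int, int] = (128, 128)
    n_frames: int = 100
    scatterer_density: float = 0.05
    psf_sigma: float = 1.2
    motion_model: str = "depth_shear"
    max_displacement: float = 6.0
    surface_gain: float = 0.25
    translation_per_frame: tuple[float, float] = (0.0, 0.0)
    period: int | None = None
    amplitude_profile: np.ndarray | None = None
    phase_labels: list[str] | None = None
    layer_boundaries: list[int] | None = None
    layer_gains: list[float] | None = None
    noise_sigma: float = 0.01
    seed: int = 0
    frame_rate: float = DEFAULT_FRAME_RATE
    padding: int | None = None
    turning_frames: list[int] = field(default_factory=list)
    repetition_boundaries: list[int] = field(default_factory=list)
    repetition_segments: list[tuple[int, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.motion_model not in ("translation", "depth_shear", "cyclic_flexion"):
            raise ValueError(f"unknown motion model {self.motion_model!r}")
        if self.n_frames < 2:
            raise ValueError("n_frames must be >= 2")
        if self.scatterer_density <= 0 or self.psf_sigma <= 0:
            raise ValueError("scatterer_density and psf_sigma must be > 0")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")


@dataclass
class GroundTruth:
    """Exact per-frame motion information for a rendered sequence."""

    amplitude: np.ndarray
    phase_labels: list[str]
    turning_frames: list[int]
    repetition_boundaries: list[int]
    repetition_segments: list[tuple[int, int]]
    gain_row: np.ndarray | None  # (H,) row-direction gain per depth, px at amplitude 1
    translation: np.ndarray | None  # (n_frames, 2) cumulative rigid displacement
    frame_shape: tuple[int, int]

    def displacement_field(self, t: int) -> np.ndarray:
        """(H, W, 2) displacement of the material point at each frame-0 pixel."""
        h, w = self.frame_shape
        d = np.zeros((h, w, 2))
        if self.translation is not None:
            d[:, :, 0] = self.translation[t, 0]
            d[:, :, 1] = self.translation[t, 1]
        else:
            d[:, :, 0] = (self.amplitude[t] * self.gain_row)[:, None]
        return d

    def mean_transversal_displacement(self) -> np.ndarray:
        """(n_frames,) image-average row-direction displacement."""
        if self.translation is not None:
            return self.translation[:, 0].copy()
        return self.amplitude * float(np.mean(self.gain_row))


def _gain_profile(spec: SyntheticSpec) -> np.ndarray:
    """(H,) depth gain in px at amplitude 1, piecewise linear in the row."""
    h = spec.frame_shape[0]
    rows = np.arange(h, dtype=np.float64)
    if spec.layer_boundaries is not None and spec.layer_gains is not None:
        knots = np.asarray(spec.layer_boundaries, dtype=np.float64)
        gains = np.asarray(spec.layer_gains, dtype=np.float64) * spec.max_displacement
        return np.interp(rows, knots, gains)
    g0 = spec.surface_gain * spec.max_displacement
    return g0 + (spec.max_displacement - g0) * rows / max(h - 1, 1)


def _amplitude(spec: SyntheticSpec) -> tuple[np.ndarray, list[str]]:
    if spec.amplitude_profile is not None:
        a = np.asarray(spec.amplitude_profile, dtype=np.float64)
        if a.size != spec.n_frames:
            raise ValueError("amplitude_profile length must equal n_frames")
        if a.min() < 0 or a.max() > 1 + 1e-12:
            raise ValueError("amplitude profile must lie in [0, 1]")
        labels = spec.phase_labels or ["concentric"] * spec.n_frames
        return a, list(labels)
    if spec.motion_model == "cyclic_flexion":
        period = spec.period or spec.n_frames
        t = np.arange(spec.n_frames)
        a = 0.5 * (1.0 - np.cos(2.0 * np.pi * t / period))
        return a, ["concentric"] * spec.n_frames
    # default depth_shear: one linear ramp over the sequence
    return np.arange(spec.n_frames) / (spec.n_frames - 1), ["concentric"] * spec.n_frames


def render_sequence(spec: SyntheticSpec) -> tuple[ImageSequence, GroundTruth]:
    """Render the sequence described by ``spec`` together with its ground truth.

    Scatterers of random position and amplitude are splatted onto a padded
    canvas, blurred by the Gaussian PSF, warped per frame with exact inverse
    maps (subpixel cubic-spline interpolation), and corrupted with additive
    Gaussian noise.
    """
    h, w = spec.frame_shape
    rng = np.random.default_rng(spec.seed)
    if spec.motion_model == "translation":
        v = np.asarray(spec.translation_per_frame, dtype=np.float64)
        translation = np.arange(spec.n_frames)[:, None] * v[None, :]
        amplitude = np.zeros(spec.n_frames)
        labels = ["concentric"] * spec.n_frames
        gain = None
        max_disp = float(np.abs(translation).max()) if translation.size else 0.0
    else:
        amplitude, labels = _amplitude(spec)
        gain = _gain_profile(spec)
        translation = None
        max_disp = float(amplitude.max() * np.abs(gain).max())
    pad = int(np.ceil(max_disp)) + int(np.ceil(4 * spec.psf_sigma)) + 2
    if spec.padding is not None:
        if spec.padding < pad:
            raise ValueError(
                f"padding={spec.padding} is smaller than the {pad} px the motion requires"
            )
        pad = spec.padding
    ch, cw = h + 2 * pad, w + 2 * pad
    n_scatter = int(round(spec.scatterer_density * ch * cw))
    pos = rng.uniform([0, 0], [ch - 1, cw - 1], size=(n_scatter, 2))
    amps = rng.uniform(0.1, 1.0, size=n_scatter)
    canvas = np.zeros((ch, cw))
    r0 = np.floor(pos[:, 0]).astype(int)
    c0 = np.floor(pos[:, 1]).astype(int)
    fr = pos[:, 0] - r0
    fc = pos[:, 1] - c0
    np.add.at(canvas, (r0, c0), amps * (1 - fr) * (1 - fc))
    np.add.at(canvas, (r0 + 1, c0), amps * fr * (1 - fc))
    np.add.at(canvas, (r0, c0 + 1), amps * (1 - fr) * fc)
    np.add.at(canvas, (r0 + 1, c0 + 1), amps * fr * fc)
    base = gaussian_filter(canvas, spec.psf_sigma, mode="constant")
    base *= 0.85 / base.max()
    coeffs = spline_filter(base, order=3, mode="mirror")
    frames = np.empty((spec.n_frames, h, w))
    col_target = np.arange(w, dtype=np.float64) + pad
    row_target = np.arange(h, dtype=np.float64) + pad
    if gain is not None:
        # forward map breakpoints (canvas coords): clamped piecewise-linear gain
        knot_rows = np.concatenate([[0.0], np.arange(h) + pad, [ch - 1.0]])
        knot_gain = np.concatenate([[gain[0]], gain, [gain[-1]]])
    for t in range(spec.n_frames):
        if translation is not None:
            rows_src = row_target - translation[t, 0]
            cols_src = col_target - translation[t, 1]
            rr, cc = np.meshgrid(rows_src, cols_src, indexing="ij")
        else:
            fwd = knot_rows + amplitude[t] * knot_gain
            rows_src = np.interp(row_target, fwd, knot_rows)
            rr, cc = np.meshgrid(rows_src, col_target, indexing="ij")
        frame = map_coordinates(coeffs, [rr, cc], order=3, prefilter=False, mode="mirror")
        if spec.noise_sigma > 0:
            frame = frame + rng.normal(0.0, spec.noise_sigma, size=frame.shape)
        frames[t] = np.clip(frame, 0.0, 1.0)
    seq = ImageSequence(frames, frame_rate=spec.frame_rate)
    truth = GroundTruth(
        amplitude=amplitude,
        phase_labels=labels,
        turning_frames=list(spec.turning_frames),
        repetition_boundaries=list(spec.repetition_boundaries),
        repetition_segments=list(spec.repetition_segments),
        gain_row=gain,
        translation=translation,
        frame_shape=(h, w),
    )
    return seq, truth


def heel_raise_preset(
    n_reps: int = 3,
    frames_per_rep: int = 140,
    seed: int = 0,
    jitter: float = 0.05,
    frame_shape: tuple[int, int] = (128, 128),
    max_displacement: float = 6.0,
    noise_sigma: float = 0.01,
) -> SyntheticSpec:
    """Spec emulating repeated heel raises.

    Each repetition is concentric -> short hold -> eccentric, followed by a
    short rest; superficial layers move less than deep layers (depth shear).
    ``jitter`` is the relative standard deviation of per-repetition peak
    amplitude (0 gives identical repetitions).  Ground-truth turning frames
    sit at the hold centers; repetition boundaries at the inter-repetition
    rest centers.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    # Rest is split symmetrically around every repetition boundary (3 frames
    # before each movement, 2 after), so that with zero jitter all
    # repetition segments are congruent frame-for-frame.
    hold = 6
    rest = 5
    move = frames_per_rep - rest
    conc = (move - hold) // 2
    ecc = move - hold - conc
    if conc < 3 or ecc < 3:
        raise ValueError(f"frames_per_rep={frames_per_rep} too short for a repetition")
    head, tail = 3, 2
    phases: list[MotionPhase] = [MotionPhase("rest", head)]
    turning: list[int] = []
    boundaries: list[int] = []
    segments: list[tuple[int, int]] = []
    cursor = head
    for r in range(n_reps):
        phases += [
            MotionPhase("concentric", conc),
            MotionPhase("hold", hold),
            MotionPhase("eccentric", ecc),
        ]
        turning.append(cursor + conc + hold // 2)
        if r < n_reps - 1:
            phases.append(MotionPhase("rest", rest))
            boundaries.append(cursor + move + tail)
            cursor += move + rest
        else:
            phases.append(MotionPhase("rest", tail))
    n_frames = n_reps * frames_per_rep
    edges = [0, *boundaries, n_frames]
    segments = [(edges[i], edges[i + 1]) for i in range(n_reps)]
    rng = np.random.default_rng(seed)
    peaks = 1.0 + np.clip(rng.normal(0.0, jitter, size=n_reps), -2 * jitter, 2 * jitter)
    profile, labels = build_phase_profile(phases, peaks=list(peaks))
    return SyntheticSpec(
        frame_shape=frame_shape,
        n_frames=n_frames,
        motion_model="cyclic_flexion",
        max_displacement=max_displacement,
        surface_gain=0.25,
        amplitude_profile=profile,
        phase_labels=labels,
        noise_sigma=noise_sigma,
        seed=seed,
        turning_frames=turning,
        repetition_boundaries=boundaries,
        repetition_segments=segments,
    )
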