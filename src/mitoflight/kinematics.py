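"""Take-off kinematics from 3D videogrammetry coordinates.

A take-off is recorded as a time-ordered track of (x, y, z) positions in
metres at a known frame rate. Instantaneous velocity is the backward finite
difference of position scaled by the frame rate; per-frame mechanical energy
is kinetic (half m v^2) plus gravitational potential (m g z) with heights
referenced to the onset frame; take-off energy expenditure is the arithmetic
mean of total energy over a fixed window (default 10 frames) starting at the
detected onset of motion.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .constants import (
    DEFAULT_SPEED_THRESHOLD,
    DEFAULT_WINDOW_LENGTH,
    G,
)
from .errors import InsufficientDataError, NoTakeoffDetectedError, ValidationError

__all__ = [
    "FrameSeries",
    "TakeoffResult",
    "instantaneous_velocity",
    "frame_energy",
    "detect_takeoff_onset",
    "takeoff_energy",
]


@dataclass
class FrameSeries:
    """One take-off track: (n, 3) coordinates in metres, z vertical.

    Attributes
    ----------
    coords : (n_frames, 3) float array, metres. Column order x, y, z.
    fps : frame rate, frames s^-1.
    mass : body mass, kg.
    bird_id : label carried through to outputs.
    """

    coords: np.ndarray
    fps: float
    mass: float
    bird_id: str = ""

    def __post_init__(self):
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 2 or self.coords.shape[1] != 3:
            raise ValidationError("coords", "expected an (n, 3) array of x,y,z positions")
        if len(self.coords) < 2:
            raise ValidationError("coords", "need at least 2 frames")
        if not np.all(np.isfinite(self.coords)):
            raise ValidationError("coords", "coordinates contain NaN or infinite values")
        if not self.fps > 0:
            raise ValidationError("fps", "frame rate must be positive")
        if not self.mass > 0:
            raise ValidationError("mass", "body mass must be positive")

    @property
    def n_frames(self) -> int:
        return len(self.coords)


@dataclass
class TakeoffResult:
    """Per-frame kinematic quantities and the windowed take-off energy.

    Arrays have one entry per frame; index 0 of every per-frame series is NaN
    because the backward difference leaves the first frame's speed undefined.
    Heights are referenced to the onset frame, so potential energy at onset
    is zero.
    """

    speed: np.ndarray          # m s^-1
    kinetic: np.ndarray        # J
    potential: np.ndarray      # J
    total: np.ndarray          # J
    onset_frame: int
    takeoff_energy: float      # J, mean of `total` over the window
    window_length: int = DEFAULT_WINDOW_LENGTH
    bird_id: str = ""

    @property
    def window(self) -> slice:
        return slice(self.onset_frame, self.onset_frame + self.window_length)


def _smooth(coords: np.ndarray, width: int = 3) -> np.ndarray:
    """Centred moving average per axis with edge replication."""
    half = width // 2
    padded = np.pad(coords, ((half, half), (0, 0)), mode="edge")
    kernel = np.ones(width) / width
    return np.column_stack(
        [np.convolve(padded[:, j], kernel, mode="valid") for j in range(3)]
    )


def instantaneous_velocity(frames: FrameSeries, smooth: bool = False) -> np.ndarray:
    """Backward-difference speed series in m s^-1.

    speed[n] = ||coords[n] - coords[n-1]|| * fps for n >= 1; speed[0] is NaN
    (there is no previous frame to difference against). Optional pre-smoothing
    applies a width-3 moving average to the coordinates before differencing;
    it is off by default.
    """
    if frames.n_frames < 2:
        raise InsufficientDataError("need at least 2 frames to compute velocity")
    coords = _smooth(frames.coords) if smooth else frames.coords
    disp = np.diff(coords, axis=0)
    speed = np.empty(frames.n_frames)
    speed[0] = np.nan
    speed[1:] = np.linalg.norm(disp, axis=1) * frames.fps
    return speed


def frame_energy(speed, height, mass: float):
    """Kinetic, potential and total mechanical energy (J).

    kinetic = 1/2 m v^2, potential = m g z, total = kinetic + potential.
    `speed` and `height` may be scalars or arrays of matching shape.
    """
    if not mass > 0:
        raise ValidationError("mass", "body mass must be positive")
    speed = np.asarray(speed, dtype=float)
    height = np.asarray(height, dtype=float)
    kinetic = 0.5 * mass * speed**2
    potential = mass * G * height
    return kinetic, potential, kinetic + potential


def detect_takeoff_onset(
    frames: FrameSeries,
    speed_threshold: float = DEFAULT_SPEED_THRESHOLD,
    window_length: int = DEFAULT_WINDOW_LENGTH,
    smooth: bool = False,
) -> int:
    """First frame whose speed exceeds the threshold with a full window after it.

    Deterministic: scans defined speeds (frame 1 onward) in order and returns
    the first index n with speed[n] > speed_threshold and n + window_length - 1
    within the track.
    """
    if frames.n_frames < window_length + 1:
        raise InsufficientDataError(
            f"track has {frames.n_frames} frames; onset detection needs at least "
            f"{window_length + 1}"
        )
    speed = instantaneous_velocity(frames, smooth=smooth)
    last_admissible = frames.n_frames - window_length
    for n in range(1, last_admissible + 1):
        if speed[n] > speed_threshold:
            return n
    raise NoTakeoffDetectedError(
        f"no frame exceeds {speed_threshold} m/s with {window_length} analysable "
        "frames after it"
    )


def takeoff_energy(
    frames: FrameSeries,
    window_length: int = DEFAULT_WINDOW_LENGTH,
    speed_threshold: float = DEFAULT_SPEED_THRESHOLD,
    smooth: bool = False,
    onset_frame: int | None = None,
) -> TakeoffResult:
    """Mean mechanical energy over the take-off window.

    The window is `window_length` consecutive frames starting at the onset
    (detected unless `onset_frame` is given). Heights are referenced to the
    onset frame's z so the result is invariant under rigid translation and
    under rotation about the vertical axis.
    """
    if onset_frame is None:
        onset_frame = detect_takeoff_onset(
            frames, speed_threshold=speed_threshold,
            window_length=window_length, smooth=smooth,
        )
    else:
        if onset_frame < 1:
            raise ValidationError("onset_frame", "must be >= 1 (frame 0 has no speed)")
        if onset_frame + window_length > frames.n_frames:
            raise InsufficientDataError(
                f"window of {window_length} frames starting at frame {onset_frame} "
                f"exceeds track length {frames.n_frames}"
            )
    speed = instantaneous_velocity(frames, smooth=smooth)
    height = frames.coords[:, 2] - frames.coords[onset_frame, 2]
    kinetic, potential, total = frame_energy(speed, height, frames.mass)
    window = slice(onset_frame, onset_frame + window_length)
    energy = float(np.mean(total[window]))
    return TakeoffResult(
        speed=speed,
        kinetic=kinetic,
        potential=potential,
        total=total,
        onset_frame=onset_frame,
        takeoff_energy=energy,
        window_length=window_length,
        bird_id=frames.bird_id,
    )
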