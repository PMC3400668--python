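"""Fast-start escape-response kinematics.

Extracts the three standard escape metrics from a frame-indexed
center-of-mass (CM) trajectory filmed at high speed (500 frames s^-1 in the
standard setup):

* response latency t (ms): time from stimulus onset to the first frame with
  detectable CM motion;
* maximum linear velocity Vmax (m s^-1): peak central-difference speed of the
  (optionally smoothed) CM path after motion onset;
* turning radius r (mm): radius of the least-squares circle fitted to the CM
  path during the initial turn.

All three are invariant to rigid motions of the coordinate frame.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .errors import InsufficientDataError, InvalidParameterError

#: Absolute floor for the motion-onset displacement threshold, mm per frame.
ONSET_THRESHOLD_FLOOR_MM = 0.2

#: Default window for the turning-radius circle fit, ms after motion onset.
TURN_WINDOW_MS = 20.0


@dataclass
class FastStartTrajectory:
    """Center-of-mass coordinates of one filmed escape response.

    ``frames`` must be contiguous integers; ``x``/``y`` are in mm;
    ``stim_frame`` indexes the frame at which the stimulus fired.
    """

    frames: np.ndarray
    x: np.ndarray
    y: np.ndarray
    fps: float
    stim_frame: int

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=int)
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if not (self.frames.shape == self.x.shape == self.y.shape):
            raise InvalidParameterError("frames, x and y must have equal length")
        if self.frames.size < 3:
            raise InsufficientDataError("trajectory too short")
        if np.any(np.diff(self.frames) != 1):
            raise InvalidParameterError("frames must be contiguous")
        if self.fps <= 0:
            raise InvalidParameterError("fps must be positive")
        if not (self.frames[0] <= self.stim_frame <= self.frames[-1]):
            raise InvalidParameterError("stim_frame must lie within the recording")
        if not (np.all(np.isfinite(self.x)) and np.all(np.isfinite(self.y))):
            raise InvalidParameterError("coordinates must be finite")

    @property
    def coords(self) -> np.ndarray:
        return np.column_stack([self.x, self.y])

    def index_of(self, frame: int) -> int:
        return int(frame - self.frames[0])


@dataclass
class FastStartMetrics:
    """Escape metrics for one fish; ``None`` marks a flagged/undefined value."""

    latency_ms: float | None  # None: no response detected
    vmax_m_s: float | None
    turn_radius_mm: float | None  # None: straight escape, radius undefined
    responded: bool


def _step_displacements(traj: FastStartTrajectory) -> np.ndarray:
    """Frame-to-frame CM displacement magnitudes, mm; entry i is step i-1 -> i."""
    d = np.diff(traj.coords, axis=0)
    return np.hypot(d[:, 0], d[:, 1])


def onset_threshold(traj: FastStartTrajectory, factor: float = 3.0) -> float:
    """Noise-adaptive motion threshold: ``factor`` x pre-stimulus displacement SD.

    Floored at 0.2 mm so that a perfectly still synthetic fish does not yield
    a zero threshold.
    """
    i_stim = traj.index_of(traj.stim_frame)
    pre = _step_displacements(traj)[:max(i_stim, 1)]
    sd = float(np.std(pre)) if pre.size else 0.0
    return max(factor * sd, ONSET_THRESHOLD_FLOOR_MM)


def detect_response_latency(
    traj: FastStartTrajectory, speed_threshold: float | None = None
) -> float | None:
    """Response latency in ms, or ``None`` if no motion exceeds the threshold.

    The latency is the offset of the first post-stimulus frame whose
    displacement from the previous frame exceeds ``speed_threshold``
    (mm per frame), quantized to the frame period 1000/fps ms.
    """
    n_post = traj.frames[-1] - traj.stim_frame
    if n_post < 5:
        raise InsufficientDataError("need at least 5 post-stimulus frames")
    if speed_threshold is None:
        speed_threshold = onset_threshold(traj)
    disp = _step_displacements(traj)
    i_stim = traj.index_of(traj.stim_frame)
    # disp[i] is the step into frame index i+1
    for i in range(i_stim, disp.size):
        if disp[i] > speed_threshold:
            first_moving = i + 1
            return (first_moving - i_stim) * 1000.0 / traj.fps
    return None


def onset_index(traj: FastStartTrajectory, speed_threshold: float | None = None) -> int | None:
    """Array index of the first moving frame, or ``None`` for no response."""
    latency = detect_response_latency(traj, speed_threshold)
    if latency is None:
        return None
    return traj.index_of(traj.stim_frame) + round(latency * traj.fps / 1000.0)


def _smooth(coords: np.ndarray, window: int) -> np.ndarray:
    """Centered moving average along the path; window must be odd, >= 1."""
    if window <= 1:
        return coords
    if window % 2 == 0:
        raise InvalidParameterError("smooth_window must be odd")
    kernel = np.ones(window) / window
    out = np.empty_like(coords)
    half = window // 2
    for j in range(coords.shape[1]):
        out[:, j] = np.convolve(coords[:, j], kernel, mode="same")
    # Edges of the convolution average over fewer true points; restore raw values there.
    out[:half] = coords[:half]
    out[-half:] = coords[-half:]
    return out


def max_linear_velocity(
    traj: FastStartTrajectory,
    smooth_window: int = 3,
    diff_halfwidth: int = 1,
    speed_threshold: float | None = None,
) -> float:
    """Maximum linear CM velocity after motion onset, m s^-1.

    Speeds are central differences ``|p[i+w] - p[i-w]| / (2w)`` (mm/frame,
    ``w = diff_halfwidth``) on a moving-average-smoothed path.  A fish that
    never moves has Vmax 0.
    """
    i0 = onset_index(traj, speed_threshold)
    if i0 is None:
        return 0.0
    n = traj.frames.size
    w = diff_halfwidth
    if n - i0 < smooth_window + 2:
        raise InsufficientDataError("too few frames after onset for the smoothing window")
    path = _smooth(traj.coords, smooth_window)
    lo = max(i0, w)
    idx = np.arange(lo, n - w)
    step = path[idx + w] - path[idx - w]
    speeds_mm_per_frame = np.hypot(step[:, 0], step[:, 1]) / (2 * w)
    return float(speeds_mm_per_frame.max() * traj.fps / 1000.0)


def fit_circle(points: np.ndarray) -> tuple[float, np.ndarray]:
    """Algebraic (Kasa) least-squares circle fit.

    Solves ``a x + b y + c = x^2 + y^2`` in least squares; returns
    ``(radius, center)``.  Raises :class:`InvalidParameterError` for fewer
    than 3 points and flags collinearity by raising ``np.linalg.LinAlgError``
    upstream -- callers should use :func:`turning_radius` which converts
    collinear input into an undefined-radius flag.
    """
    pts = np.asarray(points, dtype=float)
    if pts.shape[0] < 3:
        raise InvalidParameterError("circle fit needs at least 3 points")
    x, y = pts[:, 0], pts[:, 1]
    A = np.column_stack([x, y, np.ones_like(x)])
    rhs = x**2 + y**2
    sol, _, rank, _ = np.linalg.lstsq(A, rhs, rcond=None)
    if rank < 3 or _collinear(pts):
        raise np.linalg.LinAlgError("points are collinear; circle is degenerate")
    a, b, c = sol
    center = np.array([a / 2.0, b / 2.0])
    r2 = c + center @ center
    if r2 <= 0:
        raise np.linalg.LinAlgError("degenerate circle fit")
    return float(math.sqrt(r2)), center


def _collinear(pts: np.ndarray, rel_tol: float = 1e-9) -> bool:
    centered = pts - pts.mean(axis=0)
    sv = np.linalg.svd(centered, compute_uv=False)
    return sv[0] == 0 or sv[-1] / sv[0] < rel_tol


def turning_radius(
    traj: FastStartTrajectory,
    turn_window_ms: float = TURN_WINDOW_MS,
    speed_threshold: float | None = None,
) -> float | None:
    """Turning radius (mm) of the CM path in the initial escape turn.

    Fits an algebraic least-squares circle to the frames within
    ``turn_window_ms`` after motion onset.  Returns ``None`` (undefined
    radius) for a straight-line escape or no detected response.
    """
    i0 = onset_index(traj, speed_threshold)
    if i0 is None:
        return None
    n_window = max(3, int(round(turn_window_ms * traj.fps / 1000.0)) + 1)
    seg = traj.coords[max(i0 - 1, 0): i0 + n_window]
    if seg.shape[0] < 3:
        raise InsufficientDataError("too few frames inside the turn window")
    try:
        radius, _ = fit_circle(seg)
    except np.linalg.LinAlgError:
        return None
    return radius


def analyze_trajectory(
    traj: FastStartTrajectory,
    smooth_window: int = 3,
    diff_halfwidth: int = 1,
    turn_window_ms: float = TURN_WINDOW_MS,
    speed_threshold: float | None = None,
) -> FastStartMetrics:
    """All three escape metrics for one trajectory."""
    latency = detect_response_latency(traj, speed_threshold)
    if latency is None:
        return FastStartMetrics(None, None, None, responded=False)
    vmax = max_linear_velocity(traj, smooth_window, diff_halfwidth, speed_threshold)
    radius = turning_radius(traj, turn_window_ms, speed_threshold)
    return FastStartMetrics(latency, vmax, radius, responded=True)
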