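"""Synthetic-data generators with known ground truth.

Every input the analysis pipeline consumes can be generated here under a
fixed seed: closed-phase oxygen-depletion traces, incremental-velocity
(Ucrit) trials, MO2-versus-speed series from the exponential power model,
high-speed center-of-mass escape trajectories, 17-landmark body-shape
configurations deformed along a known covariate, and aligned cytochrome-b
style sequence sets evolved under the Kimura 2-parameter process.  The
generators are phenomenological: they reproduce the measurement models the
analysis assumes, not fish hydrodynamics.

The built-in site table carries the environmental parameters of the five
Wujiang River collection sites (two lower-reach, two middle-reach, one
upper-reach; no upper-reach tributary site exists, which is what makes the
downstream two-way ANOVA a missing-cell design).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .errors import InvalidParameterError
from .faststart import FastStartTrajectory
from .morpho import LandmarkConfig
from .popgen import AlignedSequences
from .respirometry import O2Trace
from .swim import StepProtocol


# ---------------------------------------------------------------------------
# Site ecology
# ---------------------------------------------------------------------------

@dataclass
class SiteEcology:
    """Environmental parameters of one collection site."""

    site_id: str
    reach: str  # upper / middle / lower
    stream: str  # main / tributary
    river_slope: float  # per-mille
    water_velocity: float  # m s^-1
    temperature: float  # deg C
    altitude: float  # m
    predator_size: float  # g
    predator_abundance: float  # %
    dissolved_oxygen: float  # % saturation

    def __post_init__(self) -> None:
        nums = [
            self.river_slope, self.water_velocity, self.temperature, self.altitude,
            self.predator_size, self.predator_abundance, self.dissolved_oxygen,
        ]
        if not all(math.isfinite(v) for v in nums):
            raise InvalidParameterError("all numeric site fields must be finite")
        if not 0 <= self.predator_abundance <= 100:
            raise InvalidParameterError("predator_abundance must be in [0, 100] %")
        if self.dissolved_oxygen <= 0:
            raise InvalidParameterError("dissolved_oxygen must be positive")


def builtin_site_table() -> list[SiteEcology]:
    """The five Wujiang River collection sites and their habitat parameters."""
    rows = [
        # site, reach, stream, slope, velocity, temp, alt, pred_size, pred_abund, DO
        ("YJ", "lower", "main", 0.62, 1.10, 26.0, 173, 1243, 15.1, 102.0),
        ("HK", "lower", "tributary", 4.08, 1.90, 25.0, 320, 1020, 6.1, 103.0),
        ("SN", "middle", "main", 0.97, 1.45, 23.8, 362, 826, 3.3, 82.5),
        ("SD", "middle", "tributary", 5.30, 1.82, 21.5, 780, 325, 2.6, 98.7),
        ("DG", "upper", "main", 3.65, 2.32, 21.3, 859, 435, 4.5, 97.9),
    ]
    return [SiteEcology(*r) for r in rows]


@dataclass
class FishGroundTruth:
    """True per-fish parameters used to generate and later score a data set."""

    site_id: str
    mass: float  # kg
    body_length: float  # cm
    true_rmr: float  # mg O2 kg^-1 h^-1
    true_beta: float  # (cm s^-1)^-1
    true_ucrit: float  # cm s^-1
    true_latency: float  # ms
    true_vmax: float  # m s^-1
    true_turn_radius: float  # mm
    seed: int

    def __post_init__(self) -> None:
        if self.mass <= 0 or self.true_beta <= 0 or self.true_ucrit <= 0:
            raise InvalidParameterError("mass, true_beta and true_ucrit must be positive")


# ---------------------------------------------------------------------------
# Respirometry and Ucrit protocol
# ---------------------------------------------------------------------------

def gen_o2_trace(
    mo2_true: float,
    resp_volume: float,
    fish_volume: float,
    mass: float,
    duration: float = 20.0,
    interval: float = 2.0,
    noise_sd: float = 0.0,
    seed: int | None = None,
    o2_start: float = 8.0,
    speed: float | None = None,
) -> O2Trace:
    """Closed-phase oxygen trace whose expected depletion matches ``mo2_true``.

    The noiseless depletion slope is ``mo2_true * mass / (resp_volume -
    fish_volume)`` mg L^-1 h^-1, sampled every ``interval`` minutes for
    ``duration`` minutes; independent Gaussian noise of SD ``noise_sd``
    (mg L^-1) is added per sample.
    """
    if resp_volume <= 0 or fish_volume <= 0 or mass <= 0:
        raise InvalidParameterError("volumes and mass must be positive")
    if resp_volume <= fish_volume:
        raise InvalidParameterError("resp_volume must exceed fish_volume")
    if duration < 2 * interval:
        raise InvalidParameterError("duration must cover at least two sampling intervals")
    if noise_sd < 0:
        raise InvalidParameterError("noise_sd must be non-negative")
    rng = np.random.default_rng(seed)
    times = np.arange(0.0, duration + 1e-9, interval)
    slope_per_h = mo2_true * mass / (resp_volume - fish_volume)
    o2 = o2_start - slope_per_h * times / 60.0
    if noise_sd > 0:
        o2 = o2 + rng.normal(0.0, noise_sd, size=times.size)
    return O2Trace(
        times=times, o2=o2, resp_volume=resp_volume, fish_mass=mass,
        fish_volume=fish_volume, speed=speed,
    )


def gen_ucrit_trial(
    true_ucrit: float,
    delta_v: float = 6.0,
    period: float = 30.0,
    start_v: float = 6.0,
) -> StepProtocol:
    """Incremental-velocity trial whose Brett Ucrit equals ``true_ucrit`` exactly.

    The fish completes every step up to the largest grid speed V <=
    ``true_ucrit`` and fatigues after ``t = (true_ucrit - V)/delta_v *
    period`` minutes of the next step.  Fatigue exactly on a step boundary is
    assigned to t = 0 of the higher step, which keeps the round-trip identity
    continuous from the right.
    """
    if delta_v <= 0 or period <= 0:
        raise InvalidParameterError("delta_v and period must be positive")
    if true_ucrit <= start_v:
        raise InvalidParameterError("true_ucrit must exceed the starting speed")
    n_completed = math.floor((true_ucrit - start_v) / delta_v + 1e-12)
    completed_speed = start_v + n_completed * delta_v
    t = (true_ucrit - completed_speed) / delta_v * period
    if t < 1e-9 * period:
        t = 0.0
    history = [(start_v + i * delta_v, period) for i in range(n_completed + 1)]
    history.append((completed_speed + delta_v, t))
    return StepProtocol(
        delta_v=delta_v, period=period, completed_speed=completed_speed,
        time_at_final=t, step_history=history,
    )


def gen_mo2_speed_series(
    alpha: float,
    beta: float,
    speeds,
    cv: float = 0.0,
    seed: int | None = None,
) -> list[tuple[float, float]]:
    """(speed, MO2) pairs from the exponential power curve MO2 = alpha e^(beta U).

    ``cv`` is the multiplicative coefficient of variation of the measurement
    noise; ``cv = 0`` returns the curve exactly.
    """
    speeds = np.asarray(list(speeds), dtype=float)
    if speeds.size == 0:
        raise InvalidParameterError("speed list must be non-empty")
    if alpha <= 0 or beta <= 0 or cv < 0:
        raise InvalidParameterError("need alpha > 0, beta > 0 and cv >= 0")
    rng = np.random.default_rng(seed)
    mo2 = alpha * np.exp(beta * speeds)
    if cv > 0:
        mo2 = mo2 * (1.0 + rng.normal(0.0, cv, size=speeds.size))
    return list(zip(speeds.tolist(), mo2.tolist()))


# ---------------------------------------------------------------------------
# Fast-start trajectories
# ---------------------------------------------------------------------------

def gen_fast_start_traj(
    stim_frame: int,
    latency_ms: float,
    vmax: float,
    turn_radius: float,
    fps: float = 500.0,
    n_frames: int = 150,
    noise_sd: float = 0.0,
    seed: int | None = None,
    ramp_frames: int = 5,
    plateau_frames: int = 15,
) -> FastStartTrajectory:
    """Center-of-mass escape trajectory with known latency, Vmax and radius.

    The CM is stationary (plus digitizing noise) until the response onset --
    ``latency_ms`` snapped to the frame grid -- then accelerates along a
    circular arc of radius ``turn_radius`` (mm), speed ramping linearly over
    ``ramp_frames`` frames to ``vmax`` (m s^-1) and holding for at least
    ``plateau_frames`` frames.
    """
    if fps <= 0:
        raise InvalidParameterError("fps must be positive")
    if vmax <= 0 or turn_radius <= 0:
        raise InvalidParameterError("vmax and turn_radius must be positive")
    if latency_ms < 0:
        raise InvalidParameterError("latency must be non-negative")
    if stim_frame < 5:
        raise InvalidParameterError("need at least 5 pre-stimulus frames")
    n_lat = round(latency_ms * fps / 1000.0)  # snap to the frame grid
    onset = stim_frame + n_lat  # first moving frame
    if n_frames < onset + ramp_frames + plateau_frames + 2:
        raise InvalidParameterError(
            f"n_frames={n_frames} too small to contain the burst "
            f"(needs >= {onset + ramp_frames + plateau_frames + 2})"
        )
    rng = np.random.default_rng(seed)
    vmax_mm_per_frame = vmax * 1000.0 / fps
    # per-step speeds: step f is the move from frame f to f+1
    step_speed = np.zeros(n_frames - 1)
    for f in range(onset - 1, n_frames - 1):
        j = f - (onset - 1)
        step_speed[f] = vmax_mm_per_frame * min(1.0, (j + 1) / ramp_frames)
    arc = np.concatenate([[0.0], np.cumsum(step_speed)])  # arc length at each frame
    theta = arc / turn_radius
    x = turn_radius * np.cos(theta)
    y = turn_radius * np.sin(theta)
    if noise_sd > 0:
        x = x + rng.normal(0.0, noise_sd, size=n_frames)
        y = y + rng.normal(0.0, noise_sd, size=n_frames)
    return FastStartTrajectory(
        frames=np.arange(n_frames), x=x, y=y, fps=fps, stim_frame=stim_frame
    )


# ---------------------------------------------------------------------------
# Landmarks
# ---------------------------------------------------------------------------

#: Stylized 17-point lateral fish outline (snout to caudal fin and back),
#: in arbitrary image units.  Stands in for a digitizing scheme of 17
#: morphological features on a cyprinid body.
FISH_TEMPLATE_17 = np.array(
    [
        [0.00, 0.00],   # snout tip
        [0.35, 0.30],   # top of head
        [0.60, 0.42],   # nape
        [1.60, 0.62],   # anterior dorsal-fin base
        [2.20, 0.55],   # posterior dorsal-fin base
        [3.05, 0.28],   # dorsal caudal peduncle
        [3.55, 0.22],   # dorsal caudal-fin base
        [3.90, 0.55],   # upper caudal-fin tip
        [3.70, 0.00],   # caudal fork
        [3.90, -0.55],  # lower caudal-fin tip
        [3.55, -0.22],  # ventral caudal-fin base
        [3.05, -0.28],  # ventral caudal peduncle
        [2.35, -0.45],  # anal-fin base
        [1.55, -0.60],  # pelvic-fin insertion
        [0.85, -0.50],  # pectoral-fin insertion
        [0.45, -0.28],  # lower opercular edge
        [0.20, -0.10],  # lower jaw
    ]
)


def _tps_warp(points: np.ndarray, src: np.ndarray, dst: np.ndarray) -> np.ndarray:
    """Thin-plate-spline interpolation mapping control points src -> dst."""
    m = src.shape[0]
    d = src[:, None, :] - src[None, :, :]
    r2 = (d**2).sum(-1)
    with np.errstate(divide="ignore", invalid="ignore"):
        kmat = np.where(r2 > 0, r2 * np.log(r2), 0.0)
    p = np.column_stack([np.ones(m), src])
    lmat = np.zeros((m + 3, m + 3))
    lmat[:m, :m] = kmat
    lmat[:m, m:] = p
    lmat[m:, :m] = p.T
    rhs = np.zeros((m + 3, 2))
    rhs[:m] = dst
    coef = np.linalg.solve(lmat, rhs)
    dd = points[:, None, :] - src[None, :, :]
    rr2 = (dd**2).sum(-1)
    with np.errstate(divide="ignore", invalid="ignore"):
        u = np.where(rr2 > 0, rr2 * np.log(rr2), 0.0)
    return u @ coef[:m] + np.column_stack([np.ones(len(points)), points]) @ coef[m:]


@dataclass
class LandmarkSample:
    """Generated configurations plus their ground-truth shape covariate."""

    configs: list[LandmarkConfig]
    covariate: np.ndarray  # (n,), the true deformation score per specimen


def _template(k: int) -> np.ndarray:
    if k == 17:
        return FISH_TEMPLATE_17.copy()
    # fallback template for other landmark counts: points on an ellipse
    t = np.linspace(0.0, 2 * np.pi, k, endpoint=False)
    return np.column_stack([2.0 * np.cos(t), np.sin(t)])


def gen_landmarks(
    n: int,
    k: int = 17,
    deformation_magnitude: float = 0.0,
    noise_sd: float = 0.0,
    seed: int | None = None,
    covariate=None,
) -> LandmarkSample:
    """n landmark configurations: template + covariate-scaled TPS deformation + noise.

    Each specimen i receives the smooth deformation field scaled by
    ``deformation_magnitude * c_i`` where the covariate ``c_i ~ N(0, 1)``
    (or the supplied ``covariate`` vector) is returned as ground truth, plus
    isotropic landmark noise of SD ``noise_sd`` (template units).
    """
    if k < 4:
        raise InvalidParameterError("need at least 4 landmarks")
    if n < 2:
        raise InvalidParameterError("need at least 2 specimens")
    if deformation_magnitude < 0 or noise_sd < 0:
        raise InvalidParameterError("deformation and noise magnitudes must be non-negative")
    rng = np.random.default_rng(seed)
    template = _template(k)
    scale = template.std()

    # fixed smooth deformation field from a TPS with a deterministic pattern of
    # control-point displacements (deepening the mid-body, thinning the peduncle)
    lo, hi = template.min(axis=0), template.max(axis=0)
    gx, gy = np.meshgrid(np.linspace(lo[0], hi[0], 3), np.linspace(lo[1], hi[1], 3))
    src = np.column_stack([gx.ravel(), gy.ravel()])
    pattern_rng = np.random.default_rng(20120719)  # fixed: the field is part of the design
    dst = src + 0.15 * scale * pattern_rng.standard_normal(src.shape)
    field = _tps_warp(template, src, dst) - template  # displacement at each landmark

    if covariate is None:
        covariate = rng.standard_normal(n)
    else:
        covariate = np.asarray(covariate, dtype=float)
        if covariate.shape != (n,):
            raise InvalidParameterError("covariate must have one value per specimen")
    configs = []
    for i in range(n):
        coords = template + deformation_magnitude * covariate[i] * field
        if noise_sd > 0:
            coords = coords + rng.normal(0.0, noise_sd, size=coords.shape)
        configs.append(LandmarkConfig(specimen_id=f"spec{i:03d}", coords=coords))
    return LandmarkSample(configs=configs, covariate=covariate)


# ---------------------------------------------------------------------------
# Sequences
# ---------------------------------------------------------------------------

_BASES = np.array(list("ACGT"))
_TS_MAP = np.array([2, 3, 0, 1])  # A<->G, C<->T (indices into ACGT)


def _k2p_site_probs(d: float, kappa: float) -> tuple[float, float]:
    """(P_transition, P_transversion_total) after branch length d under K2P."""
    if d == 0:
        return 0.0, 0.0
    beta_t = d / (kappa + 2.0)
    alpha_t = kappa * beta_t
    p_ts = 0.25 + 0.25 * math.exp(-4.0 * beta_t) - 0.5 * math.exp(-2.0 * (alpha_t + beta_t))
    p_tv = 0.5 - 0.5 * math.exp(-4.0 * beta_t)
    return p_ts, p_tv


def _evolve(seq_idx: np.ndarray, d: float, kappa: float, rng: np.random.Generator) -> np.ndarray:
    """Evolve an index-coded sequence along a branch of length d (subs/site)."""
    p_ts, p_tv = _k2p_site_probs(d, kappa)
    u = rng.random(seq_idx.size)
    out = seq_idx.copy()
    ts_mask = u < p_ts
    tv_mask = (u >= p_ts) & (u < p_ts + p_tv)
    out[ts_mask] = _TS_MAP[out[ts_mask]]
    if tv_mask.any():
        # each base has two transversion partners, equally likely
        partner_choice = rng.integers(0, 2, size=int(tv_mask.sum()))
        cur = out[tv_mask]
        is_purine = (cur == 0) | (cur == 2)
        # purines -> {C, T} = {1, 3}; pyrimidines -> {A, G} = {0, 2}
        tv_target = np.where(is_purine, 1 + 2 * partner_choice, 2 * partner_choice)
        out[tv_mask] = tv_target
    return out


def gen_sequences(
    groups: int,
    n_per_group: int,
    length: int,
    within_d: float,
    between_d: float,
    kappa: float = 2.0,
    seed: int | None = None,
    group_labels: list[str] | None = None,
) -> AlignedSequences:
    """Aligned sequence set of ``groups`` populations under the K2P process.

    Group ancestors diverge from a common root and tips diverge from their
    group ancestor so that the expected pairwise K2P distance is
    ``within_d`` inside a group and ``between_d`` across groups (path
    additivity of the K2P model).  Fixed seeds reproduce identical sets.
    """
    if length <= 0:
        raise InvalidParameterError("length must be positive")
    if groups < 1 or n_per_group < 1:
        raise InvalidParameterError("need at least one group and one sequence per group")
    if not 0 <= within_d < between_d:
        raise InvalidParameterError("need 0 <= within_d < between_d")
    if kappa <= 0:
        raise InvalidParameterError("kappa must be positive")
    if group_labels is not None and len(group_labels) != groups:
        raise InvalidParameterError("group_labels must name every group")
    rng = np.random.default_rng(seed)
    tip_branch = within_d / 2.0
    ancestor_branch = (between_d - within_d) / 2.0
    root = rng.integers(0, 4, size=length)
    labels = group_labels or [f"pop{g + 1}" for g in range(groups)]
    ids, seqs, grp = [], [], []
    for g in range(groups):
        anc = _evolve(root, ancestor_branch, kappa, rng)
        for i in range(n_per_group):
            tip = _evolve(anc, tip_branch, kappa, rng)
            ids.append(f"{labels[g]}_{i + 1:02d}")
            seqs.append("".join(_BASES[tip]))
            grp.append(labels[g])
    return AlignedSequences(ids=ids, sequences=seqs, groups=grp)
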