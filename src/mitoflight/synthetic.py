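"""Synthetic trajectories, respirometry traces and cohorts.

The generators reproduce the statistical structure the downstream analysis
assumes, so every stage is testable without field data:

* ``simulate_takeoff`` — ballistic launch (optionally after stationary
  perch frames) sampled at the video frame rate with i.i.d. Gaussian
  coordinate noise.
* ``simulate_o2k_trace`` — a closed-chamber O2 concentration trace declining
  piecewise-linearly at the flux of the active respiration state, with an
  exponential transition (time constant 15 s) after each titration event and
  a stepped CCCP flux profile rising to a peak and declining 10% per later
  step.
* ``simulate_cohort`` — n individuals with mutually correlated mitochondrial
  states, a linear endurance–ETS/mass link calibrated so the fitted
  three-predictor endurance model has the target expected R², endurance
  truncated to the observed 20–411 s range, and a take-off arm generated
  independently of everything mitochondrial (a built-in null).

All three are deterministic given their seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import ndtr
from scipy.stats import truncnorm

from .constants import DEFAULT_FPS, G, TRANSITION_TAU_S
from .errors import AnoxiaError, UnattainableRSquaredError, ValidationError
from .kinematics import FrameSeries
from .respirometry import O2Trace, TitrationEvent, TitrationProtocol
from .schema import COHORT_COLUMNS

__all__ = [
    "TrajectorySimParams",
    "TraceSimParams",
    "CohortSimParams",
    "simulate_takeoff",
    "simulate_o2k_trace",
    "simulate_cohort",
    "default_protocol",
    "replicate_seeds",
    "ENDURANCE_BOUNDS",
]

#: Observed endurance range (s); generated endurance is confined to it.
ENDURANCE_BOUNDS = (20.0, 411.0)


def replicate_seeds(seed: int, n: int) -> list[int]:
    """n independent child seeds (< 2^31) for a replicate simulation study.

    Uses a seed sequence so replicate streams are mutually independent even
    for adjacent base seeds.
    """
    state = np.random.SeedSequence(seed).generate_state(n, dtype=np.uint32)
    return [int(s) % 2**31 for s in state]


# --------------------------------------------------------------------------
# take-off trajectories
# --------------------------------------------------------------------------

@dataclass
class TrajectorySimParams:
    """Ballistic take-off simulation parameters.

    launch_angle is in radians above the horizontal; n_prelaunch stationary
    frames may precede the launch (frame 0 is always at the origin).
    """

    mass: float = 0.0275          # kg
    fps: float = DEFAULT_FPS      # frames s^-1
    n_frames: int = 40
    launch_speed: float = 3.0     # m s^-1
    launch_angle: float = 0.6     # rad
    coord_noise_sd: float = 0.0   # m
    n_prelaunch: int = 0
    seed: int = 0

    def __post_init__(self):
        if not self.mass > 0:
            raise ValidationError("mass", "must be positive")
        if not self.fps > 0:
            raise ValidationError("fps", "must be positive")
        if self.n_frames < 12:
            raise ValidationError("n_frames", "need at least 12 frames")
        if self.coord_noise_sd < 0:
            raise ValidationError("coord_noise_sd", "must be non-negative")
        if self.launch_speed < 0:
            raise ValidationError("launch_speed", "must be non-negative")
        if self.n_prelaunch < 0 or self.n_prelaunch > self.n_frames - 12:
            raise ValidationError("n_prelaunch", "must leave >= 12 airborne frames")


def simulate_takeoff(params: TrajectorySimParams) -> FrameSeries:
    """Ballistic trajectory under gravity with additive coordinate noise.

    Frames 0..n_prelaunch are at the origin; from frame n_prelaunch onward the
    bird follows projectile motion r(t) = v t (cos a, 0, sin a) - g t^2/2 e_z
    with t counted from the pre-launch frame. Deterministic given the seed.
    """
    rng = np.random.default_rng(params.seed)
    n = params.n_frames
    dt = 1.0 / params.fps
    if params.launch_speed == 0.0:
        # degenerate launch: the bird never leaves the perch (no free fall)
        coords = np.zeros((n, 3))
    else:
        t = np.maximum(np.arange(n) - params.n_prelaunch, 0) * dt
        vx = params.launch_speed * math.cos(params.launch_angle)
        vz = params.launch_speed * math.sin(params.launch_angle)
        coords = np.column_stack([
            vx * t,
            np.zeros(n),
            vz * t - 0.5 * G * t**2,
        ])
    if params.coord_noise_sd > 0:
        coords = coords + rng.normal(0.0, params.coord_noise_sd, size=coords.shape)
    return FrameSeries(coords=coords, fps=params.fps, mass=params.mass, bird_id="sim")


# --------------------------------------------------------------------------
# respirometry traces
# --------------------------------------------------------------------------

def default_protocol(
    n_cccp_steps: int = 4,
    routine_s: float = 300.0,
    postpyruvate_s: float = 180.0,
    leak_s: float = 240.0,
    cccp_step_s: float = 150.0,
) -> TitrationProtocol:
    """The assay's standard event schedule with one pyruvate addition."""
    if n_cccp_steps < 1:
        raise ValidationError("n_cccp_steps", "need at least one CCCP step")
    events = [TitrationEvent(routine_s, "pyruvate")]
    t = routine_s + postpyruvate_s
    events.append(TitrationEvent(t, "oligomycin"))
    t += leak_s
    for _ in range(n_cccp_steps):
        events.append(TitrationEvent(t, "cccp_step"))
        t += cccp_step_s
    events.append(TitrationEvent(t, "antimycin"))
    return TitrationProtocol(events)


@dataclass
class TraceSimParams:
    """O2 trace simulation parameters.

    Fluxes are in pmol O2 s^-1 ml^-1 (chamber basis). If `protocol` is None a
    default schedule with `n_cccp_steps` CCCP steps is built; the trace always
    extends `tail_s` seconds past the antimycin event. true_postpyruvate
    defaults to true_routine.
    """

    true_routine: float = 30.0
    true_leak: float = 8.0
    true_ets_peak: float = 60.0
    true_nonmito: float = 3.0
    true_postpyruvate: float | None = None
    protocol: TitrationProtocol | None = None
    initial_o2: float = 200.0        # uM
    sampling_interval: float = 2.0   # s
    noise_sd: float = 0.2            # uM
    n_cccp_steps: int = 4
    tail_s: float = 300.0
    seed: int = 0

    def __post_init__(self):
        if not self.true_routine > self.true_leak:
            raise ValidationError("true_routine", "must exceed true_leak")
        if not self.true_leak >= self.true_nonmito:
            raise ValidationError("true_leak", "must be >= true_nonmito")
        if self.true_nonmito < 0:
            raise ValidationError("true_nonmito", "must be non-negative")
        if not self.true_ets_peak >= self.true_routine:
            raise ValidationError("true_ets_peak", "must be >= true_routine")
        if not self.initial_o2 > 0:
            raise ValidationError("initial_o2", "must be positive")
        if not self.sampling_interval > 0:
            raise ValidationError("sampling_interval", "must be positive")
        if self.noise_sd < 0:
            raise ValidationError("noise_sd", "must be non-negative")
        if self.n_cccp_steps < 1:
            raise ValidationError("n_cccp_steps", "need at least one CCCP step")


def _cccp_profile(leak: float, peak: float, n_steps: int) -> list[float]:
    """Step fluxes rising to the peak, then declining 10% per later step.

    The peak sits at step max(1, n_steps - 1); rising steps interpolate
    linearly from midway between LEAK and the peak, so the maximum rule is
    exercised with both an ascent and (for n_steps >= 2) a descent.
    """
    p = max(1, n_steps - 1)
    lo = 0.5 * (leak + peak)
    fluxes = [lo + (peak - lo) * i / p for i in range(1, p + 1)]
    fluxes += [peak * 0.9 ** (i - p) for i in range(p + 1, n_steps + 1)]
    return fluxes


def _flux_schedule(params: TraceSimParams, protocol: TitrationProtocol):
    """(start_time, target_flux) pairs, one per protocol segment."""
    post = params.true_postpyruvate
    if post is None:
        post = params.true_routine
    n_steps = len(protocol.times_of("cccp_step"))
    cccp = _cccp_profile(params.true_leak, params.true_ets_peak, n_steps)
    schedule = [(0.0, params.true_routine)]
    i_cccp = 0
    for ev in sorted(protocol.events, key=lambda e: e.time_s):
        if ev.kind == "pyruvate":
            schedule.append((ev.time_s, post))
        elif ev.kind == "oligomycin":
            schedule.append((ev.time_s, params.true_leak))
        elif ev.kind == "cccp_step":
            schedule.append((ev.time_s, cccp[i_cccp]))
            i_cccp += 1
        elif ev.kind == "antimycin":
            schedule.append((ev.time_s, params.true_nonmito))
    return schedule


def _integrate_concentration(times, schedule, initial_o2, tau=TRANSITION_TAU_S):
    """Closed-form concentration for a piecewise flux with exponential relaxation.

    Within a segment starting at s with entry flux f0 and target g, the flux is
    g + (f0 - g) exp(-(t-s)/tau) and the consumed O2 integrates analytically.
    Concentration converts via 1 uM = 1000 pmol ml^-1.
    """
    starts = np.array([s for s, _ in schedule])
    targets = np.array([g for _, g in schedule])
    k = len(schedule)
    entry = np.empty(k)
    consumed_at_start = np.empty(k)
    entry[0] = targets[0]  # no transition at t = 0
    consumed_at_start[0] = 0.0
    for i in range(1, k):
        dt = starts[i] - starts[i - 1]
        g, f0 = targets[i - 1], entry[i - 1]
        consumed_at_start[i] = consumed_at_start[i - 1] + g * dt + (f0 - g) * tau * (
            1.0 - math.exp(-dt / tau)
        )
        entry[i] = g + (f0 - g) * math.exp(-dt / tau)
    idx = np.searchsorted(starts, times, side="right") - 1
    dt = times - starts[idx]
    g, f0 = targets[idx], entry[idx]
    consumed = consumed_at_start[idx] + g * dt + (f0 - g) * tau * (1.0 - np.exp(-dt / tau))
    return initial_o2 - consumed / 1000.0


def simulate_o2k_trace(params: TraceSimParams) -> O2Trace:
    """Simulate a full titration trace; raises AnoxiaError on O2 exhaustion."""
    protocol = params.protocol or default_protocol(n_cccp_steps=params.n_cccp_steps)
    protocol.validate()
    t_end = protocol.time_of("antimycin") + params.tail_s
    times = np.arange(0.0, t_end + 0.5 * params.sampling_interval, params.sampling_interval)
    schedule = _flux_schedule(params, protocol)
    conc = _integrate_concentration(times, schedule, params.initial_o2)
    if conc.min() <= 0:
        raise AnoxiaError(
            f"chamber would reach {conc.min():.1f} uM O2 before the protocol ends; "
            f"increase initial_o2 (currently {params.initial_o2} uM)"
        )
    if params.noise_sd > 0:
        rng = np.random.default_rng(params.seed)
        conc = conc + rng.normal(0.0, params.noise_sd, size=conc.shape)
    return O2Trace(time=times, o2_um=conc, events=protocol, sample_id="sim")


# --------------------------------------------------------------------------
# cohorts
# --------------------------------------------------------------------------

@dataclass
class CohortSimParams:
    """Cohort generation parameters.

    The endurance link is endurance = intercept + slope_ets*ETS +
    slope_mass*mass + eps; the other printed slopes are carried as reference
    values (the correlated mitochondrial states make them emerge in single-
    predictor fits, they do not enter the generative equation). ets_sd=None
    derives the ETS spread from target_r2_ets, endurance_sd and the mass
    contribution, so the generated cohorts reproduce both the endurance
    dispersion and the target model R². takeoff_effect is fixed at 0: the
    take-off arm is a built-in null.
    """

    n: int = 53
    endurance_mean: float = 163.8    # s
    endurance_sd: float = 85.39      # s
    slope_routine: float = 5.780     # s per pmol s^-1 ul^-1 (reference)
    slope_oxphos: float = 8.919      # reference
    slope_ets: float = 3.858         # generative
    slope_coupling: float = 345.097  # s per unit ratio (reference)
    slope_mass: float = 15.583       # s g^-1, generative
    target_r2_ets: float = 0.29
    mito_correlation: float = 0.8
    leak_correlation: float = 0.2
    takeoff_effect: float = 0.0
    # placeholder marginals (no field values are published for these)
    routine_mean: float = 15.0
    routine_sd: float = 4.0
    leak_mean: float = 3.0
    leak_sd: float = 1.0
    ets_mean: float = 30.0
    ets_sd: float | None = None
    mass_mean: float = 27.5          # g
    mass_sd: float = 1.5             # g
    cellcount_mean: float = 3.5e6    # cells ul^-1
    cellcount_sd: float = 5.0e5
    takeoff_mean: float = 0.14       # J
    takeoff_sd: float = 0.03         # J
    seed: int = 0

    def __post_init__(self):
        if self.n < 3:
            raise ValidationError("n", "need at least 3 individuals")
        if not self.endurance_sd > 0:
            raise ValidationError("endurance_sd", "must be positive")
        if not 0 < self.mito_correlation < 1:
            raise ValidationError("mito_correlation", "must lie in (0, 1)")
        if not 0 <= self.leak_correlation < 1:
            raise ValidationError("leak_correlation", "must lie in [0, 1)")
        if self.takeoff_effect != 0.0:
            raise ValidationError("takeoff_effect", "fixed at 0 (null take-off arm)")
        if not 0 < self.target_r2_ets < 1:
            raise ValidationError("target_r2_ets", "must lie in (0, 1)")


def _tn_moments(alpha, beta):
    """Mean offset and variance factor of a standard normal truncated to [alpha, beta].

    When the interval mass underflows (both bounds deep in one tail, reached
    only at the extremes of the bisection bracket) the mean collapses to the
    nearer bound and the variance to its asymptotic 1/bound^2; the closed
    form is used everywhere else.
    """
    alpha = np.asarray(alpha, dtype=float)
    beta = np.asarray(beta, dtype=float)
    z = np.maximum(ndtr(beta) - ndtr(alpha), 1e-300)
    phi_a = np.exp(-0.5 * np.square(alpha)) / math.sqrt(2 * math.pi)
    phi_b = np.exp(-0.5 * np.square(beta)) / math.sqrt(2 * math.pi)
    with np.errstate(over="ignore", invalid="ignore"):
        m = (phi_a - phi_b) / z
        v = 1.0 + (alpha * phi_a - beta * phi_b) / z - m * m
    far = z <= 1e-12
    if np.any(far):
        edge = np.where(alpha > 0, alpha, beta)
        m = np.where(far, edge, m)
        v = np.where(far, 1.0 / np.maximum(np.square(edge), 1.0), v)
    return m, v


def _recenter_location(a, b, sigma, iters: int = 80):
    """Location delta of TruncNorm([a, b], loc=delta, scale=sigma) with mean 0.

    Requires a < 0 < b elementwise. The truncated mean is monotone in the
    location, so a vectorised bisection converges unconditionally.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    lo = a - 12.0 * sigma
    hi = b + 12.0 * sigma
    for _ in range(iters):
        mid = 0.5 * (lo + hi)
        m, _ = _tn_moments((a - mid) / sigma, (b - mid) / sigma)
        mean = mid + sigma * m
        below = mean < 0.0
        lo = np.where(below, mid, lo)
        hi = np.where(below, hi, mid)
    return 0.5 * (lo + hi)


_SIGMA_CACHE: dict[tuple, float] = {}


def _calibrate_residual_scale(target_var, mu_mean, mu_sd, bounds=ENDURANCE_BOUNDS):
    """Residual draw scale whose mean truncated variance over mu equals target_var.

    The residual of each individual is a mean-zero truncated Gaussian on
    [lo - mu, hi - mu]; truncation shrinks its variance below the draw scale
    squared, so the scale solving E_mu[Var] = target_var is found by 1-D root
    search with Gauss–Hermite quadrature over the linear-predictor
    distribution N(mu_mean, mu_sd^2).
    """
    key = (round(target_var, 9), round(mu_mean, 9), round(mu_sd, 9), bounds)
    if key in _SIGMA_CACHE:
        return _SIGMA_CACHE[key]
    lo_b, hi_b = bounds
    nodes, weights = np.polynomial.hermite_e.hermegauss(31)
    mu = mu_mean + mu_sd * nodes
    w = weights / weights.sum()
    keep = (mu > lo_b + 5.0) & (mu < hi_b - 5.0)
    mu, w = mu[keep], w[keep] / w[keep].sum()
    a, b = lo_b - mu, hi_b - mu

    def avg_var(sigma):
        delta = _recenter_location(a, b, sigma)
        _, v = _tn_moments((a - delta) / sigma, (b - delta) / sigma)
        return float(np.sum(w * v) * sigma**2)

    s0 = math.sqrt(target_var)
    f_lo = avg_var(s0) - target_var
    if f_lo > 0:  # numerically impossible: truncation only shrinks variance
        sigma = s0
    else:
        hi = 6.0 * s0
        if avg_var(hi) - target_var < 0:
            raise UnattainableRSquaredError(
                "residual variance exceeds what the endurance truncation interval "
                "can carry",
                bound=avg_var(hi),
            )
        sigma = brentq(lambda s: avg_var(s) - target_var, s0, hi, xtol=1e-6)
    _SIGMA_CACHE[key] = sigma
    return sigma


def _resolve_variances(params: CohortSimParams):
    """ETS spread, signal variance and effective residual variance.

    The fitted endurance model has p = 3 predictors (mito state, mass, cell
    count). Its expected R² exceeds the population value by the usual
    finite-sample inflation, inverted here via
    E[R²] ≈ 1 - (1 - rho²) (n - p - 1)/(n - 1).
    """
    p = 3
    shrink = (params.n - p - 1) / (params.n - 1)
    if shrink <= 0:
        raise ValidationError("n", "too few individuals for a 3-predictor model")
    rho2 = 1.0 - (1.0 - params.target_r2_ets) / shrink
    floor = p / (params.n - 1)
    if rho2 <= 0:
        raise UnattainableRSquaredError(
            "target_r2_ets is below the chance-level R² of a "
            f"{p}-predictor fit at n = {params.n}",
            bound=floor,
        )
    mass_var = (params.slope_mass * params.mass_sd) ** 2
    if params.ets_sd is None:
        if params.slope_ets == 0:
            ets_sd = 9.0  # fallback spread for null-slope cohorts
            signal = params.slope_ets**2 * ets_sd**2 + mass_var
        else:
            signal = rho2 * params.endurance_sd**2
            ets_var = (signal - mass_var) / params.slope_ets**2
            if ets_var <= 0:
                raise UnattainableRSquaredError(
                    "target_r2_ets is not attainable: the body-mass term alone "
                    "already exceeds the requested signal variance",
                    bound=1.0 - (1.0 - mass_var / params.endurance_sd**2) * shrink,
                )
            ets_sd = math.sqrt(ets_var)
    else:
        ets_sd = params.ets_sd
        signal = params.slope_ets**2 * ets_sd**2 + mass_var
    if signal > 0:
        resid_var = signal * (1.0 - rho2) / rho2
    else:
        resid_var = params.endurance_sd**2  # pure-noise endurance (null slopes)
    return ets_sd, signal, resid_var


def _mito_covariance(params: CohortSimParams, ets_sd: float) -> np.ndarray:
    r_m, r_l = params.mito_correlation, params.leak_correlation
    sds = np.array([params.routine_sd, params.leak_sd, ets_sd])
    corr = np.array([
        [1.0, r_l, r_m],
        [r_l, 1.0, r_l],
        [r_m, r_l, 1.0],
    ])
    return corr * np.outer(sds, sds)


def simulate_cohort(params: CohortSimParams) -> pd.DataFrame:
    """Generate one cohort table (one row per bird).

    Mitochondrial states (ROUTINE, LEAK, ETS) are multivariate Gaussian with
    pairwise correlation `mito_correlation` between ROUTINE and ETS and the
    weaker `leak_correlation` for LEAK; OXPHOS and both flux control ratios
    are derived from them. Endurance follows the calibrated linear link with
    a mean-zero truncated-Gaussian residual confined to 20–411 s; take-off
    energy, body mass and blood cell count are drawn independently. Rows
    whose mitochondrial draw violates 0 < LEAK < ROUTINE, ETS > 0, or whose
    linear predictor leaves the truncation-compatible range, are redrawn
    (all are rare events at the defaults).
    """
    rng = np.random.default_rng(params.seed)
    ets_sd, signal, resid_var = _resolve_variances(params)
    cov = _mito_covariance(params, ets_sd)
    means = np.array([params.routine_mean, params.leak_mean, params.ets_mean])
    lo_b, hi_b = ENDURANCE_BOUNDS
    intercept = (
        params.endurance_mean
        - params.slope_ets * params.ets_mean
        - params.slope_mass * params.mass_mean
    )

    n = params.n
    mito = np.empty((n, 3))
    mass = np.empty(n)
    todo = np.ones(n, dtype=bool)
    for _ in range(200):
        k = int(todo.sum())
        if k == 0:
            break
        mito[todo] = rng.multivariate_normal(means, cov, size=k, method="cholesky")
        mass[todo] = rng.normal(params.mass_mean, params.mass_sd, size=k)
        mu = intercept + params.slope_ets * mito[:, 2] + params.slope_mass * mass
        ok = (
            (mito[:, 1] > 0)
            & (mito[:, 0] > mito[:, 1])
            & (mito[:, 2] > 0)
            & (mu > lo_b + 5.0)
            & (mu < hi_b - 5.0)
        )
        todo = ~ok
    else:
        raise ValidationError(
            "params", "could not draw an admissible cohort; the marginals place "
            "almost no mass on valid states"
        )

    routine, leak, ets = mito.T
    oxphos = routine - leak
    coupling = 1.0 - leak / routine
    reserve = 1.0 - routine / ets

    mu = intercept + params.slope_ets * ets + params.slope_mass * mass
    sigma = _calibrate_residual_scale(
        resid_var, params.endurance_mean, math.sqrt(signal)
    )
    a, b = lo_b - mu, hi_b - mu
    delta = _recenter_location(a, b, sigma)
    eps = truncnorm.rvs(
        (a - delta) / sigma, (b - delta) / sigma,
        loc=delta, scale=sigma, random_state=rng,
    )
    endurance = mu + eps

    cells = np.abs(rng.normal(params.cellcount_mean, params.cellcount_sd, size=n))
    takeoff = np.abs(rng.normal(params.takeoff_mean, params.takeoff_sd, size=n))

    table = pd.DataFrame({
        "bird_id": [f"bird_{i:03d}" for i in range(n)],
        "body_mass_g": mass,
        "blood_cell_count_per_ul": cells,
        "endurance_s": endurance,
        "takeoff_energy_j": takeoff,
        "routine_c": routine,
        "leak_c": leak,
        "oxphos_c": oxphos,
        "ets_c": ets,
        "coupling_efficiency": coupling,
        "reserve_capacity": reserve,
    })[COHORT_COLUMNS]
    table.attrs["params"] = {
        **{k: v for k, v in params.__dict__.items()},
        "ets_sd_resolved": ets_sd,
        "residual_scale": sigma,
        "intercept": intercept,
    }
    return table
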