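"""High-resolution respirometry: O2 traces to respiration states and ratios.

An intact-blood-cell assay in a closed 2 ml chamber proceeds through a fixed
titration sequence: baseline (ROUTINE, endogenous substrates and ADP), an
optional pyruvate addition, oligomycin (ATP-synthase inhibition -> LEAK),
step-titrated CCCP (uncoupling, maximal electron-transport-system flux ETS),
and antimycin A (complex-III inhibition -> non-mitochondrial O2 consumption).
Each state's O2 flux is the negative least-squares slope of the concentration
trace over a steady-state window at the end of its segment. Non-mitochondrial
flux is subtracted from every other state, rates are rescaled from per-ml
chamber to per-ul blood, OXPHOS is ROUTINE - LEAK, and two flux control
ratios summarise the states independently of mitochondrial quantity:

* OXPHOS coupling efficiency  E = 1 - LEAK/ROUTINE
* OXPHOS reserve capacity   FCR = 1 - ROUTINE/ETS
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps

from .constants import (
    DEFAULT_BLOOD_VOLUME_UL,
    DEFAULT_CHAMBER_VOLUME_ML,
    DEFAULT_FLUX_WINDOW_S,
    DEFAULT_SETTLE_S,
)
from .errors import (
    InsufficientDataError,
    ProtocolError,
    SegmentTooShortError,
    UndefinedRatioError,
    ValidationError,
    WindowSpansEventError,
)

__all__ = [
    "TitrationEvent",
    "TitrationProtocol",
    "O2Trace",
    "FluxEstimate",
    "RawStates",
    "RespirationStates",
    "FluxControlRatios",
    "estimate_flux",
    "segment_states",
    "correct_and_normalize",
    "coupling_efficiency",
    "reserve_capacity",
    "flux_control_ratios",
    "process_trace",
]

EVENT_KINDS = ("pyruvate", "oligomycin", "cccp_step", "antimycin")

#: Nominal doses, carried as labels only (the analysis never uses them).
NOMINAL_DOSES = {
    "pyruvate": "5 ul of 2 mM pyruvate",
    "oligomycin": "2.5 ul of 0.5 mM oligomycin",
    "cccp_step": "1 ul of 1 mM CCCP per step",
    "antimycin": "5 ul of 1 mM antimycin A",
}


@dataclass(frozen=True)
class TitrationEvent:
    time_s: float
    kind: str

    def __post_init__(self):
        if self.kind not in EVENT_KINDS:
            raise ValidationError("kind", f"unknown event kind {self.kind!r}")


@dataclass
class TitrationProtocol:
    """Ordered titration events with realized times.

    Invariants: times strictly increasing; exactly one oligomycin and one
    antimycin; at least one cccp_step between them; pyruvate (if present)
    precedes oligomycin.
    """

    events: list[TitrationEvent]

    def __post_init__(self):
        self.validate()

    def validate(self) -> None:
        times = [e.time_s for e in self.events]
        if any(b <= a for a, b in zip(times, times[1:])):
            raise ProtocolError("event times must be strictly increasing")
        kinds = [e.kind for e in self.events]
        if kinds.count("oligomycin") != 1:
            raise ProtocolError("protocol needs exactly one oligomycin event")
        if kinds.count("antimycin") != 1:
            raise ProtocolError("protocol needs exactly one antimycin event")
        if kinds.count("pyruvate") > 1:
            raise ProtocolError("protocol allows at most one pyruvate event")
        i_oligo = kinds.index("oligomycin")
        i_anti = kinds.index("antimycin")
        if i_anti < i_oligo:
            raise ProtocolError("antimycin must follow oligomycin")
        steps_between = [
            k for k in kinds[i_oligo + 1 : i_anti] if k == "cccp_step"
        ]
        if not steps_between:
            raise ProtocolError("need at least one cccp_step between oligomycin and antimycin")
        if "pyruvate" in kinds and kinds.index("pyruvate") > i_oligo:
            raise ProtocolError("pyruvate must precede oligomycin")

    def times_of(self, kind: str) -> list[float]:
        return [e.time_s for e in self.events if e.kind == kind]

    def time_of(self, kind: str) -> float:
        return self.times_of(kind)[0]


@dataclass
class O2Trace:
    """An O2 concentration time series with chamber metadata.

    Concentration is in uM (== nmol per ml); times in seconds, strictly
    increasing. The default chamber reading is 50 ul whole blood diluted in
    0.95 ml medium, added to a chamber holding 1 ml medium: 2 ml total,
    50 ul blood.
    """

    time: np.ndarray            # s
    o2_um: np.ndarray           # uM
    events: TitrationProtocol
    chamber_volume_ml: float = DEFAULT_CHAMBER_VOLUME_ML
    blood_volume_ul: float = DEFAULT_BLOOD_VOLUME_UL
    sample_id: str = ""

    def __post_init__(self):
        self.time = np.asarray(self.time, dtype=float)
        self.o2_um = np.asarray(self.o2_um, dtype=float)
        if self.time.shape != self.o2_um.shape or self.time.ndim != 1:
            raise ValidationError("o2_um", "time and concentration must be equal-length 1-D arrays")
        if np.any(np.diff(self.time) <= 0):
            raise ValidationError("time", "time must be strictly increasing")
        if not np.all(np.isfinite(self.o2_um)):
            raise ValidationError("o2_um", "concentration must be finite")
        if not self.chamber_volume_ml > 0:
            raise ValidationError("chamber_volume_ml", "must be positive")
        if not self.blood_volume_ul > 0:
            raise ValidationError("blood_volume_in_chamber", "must be positive")


@dataclass
class FluxEstimate:
    """Windowed least-squares flux: pmol O2 s^-1 ml^-1 with standard error."""

    flux: float
    se: float
    n_samples: int
    window: tuple[float, float]


@dataclass
class RawStates:
    """Per-state raw fluxes in pmol O2 s^-1 ml^-1 (chamber volume basis)."""

    routine: FluxEstimate
    leak: FluxEstimate
    cccp_fluxes: list[FluxEstimate]
    nonmito: FluxEstimate
    postpyruvate: FluxEstimate | None = None

    @property
    def ets(self) -> FluxEstimate:
        """Maximal single-plateau CCCP flux (the uncoupled ETS state)."""
        return max(self.cccp_fluxes, key=lambda f: f.flux)


@dataclass
class RespirationStates:
    """Raw and antimycin-corrected, blood-normalised respiration rates.

    Corrected rates are (raw - nonmito) * chamber_ml / blood_ul in
    pmol O2 s^-1 ul blood^-1. oxphos_c == routine_c - leak_c exactly.
    Negative corrected rates are retained (clamping would bias the ratios)
    and flagged; routine_c <= 0 or ets_c < routine_c also set flags.
    """

    routine: float
    leak: float
    ets: float
    nonmito: float
    routine_c: float
    leak_c: float
    ets_c: float
    oxphos_c: float
    windows: dict = field(default_factory=dict)
    flags: list[str] = field(default_factory=list)
    postpyruvate: float | None = None
    sample_id: str = ""


@dataclass
class FluxControlRatios:
    """Dimensionless flux control ratios; None when undefined (flagged)."""

    coupling_efficiency: float | None
    reserve_capacity: float | None
    flags: list[str] = field(default_factory=list)


def estimate_flux(trace: O2Trace, window: tuple[float, float]) -> FluxEstimate:
    """O2 flux from the concentration slope over a time window.

    flux = -slope(o2_um vs time) * 1000, converting uM s^-1 (nmol ml^-1 s^-1)
    to pmol s^-1 ml^-1; the standard error is the regression slope SE on the
    same scale. The window must not contain a titration event in its interior
    (events exactly at a boundary are allowed: the ROUTINE window ends at the
    pyruvate event).
    """
    t0, t1 = window
    if not t1 > t0:
        raise ValidationError("window", "window end must exceed its start")
    for ev in trace.events.events:
        if t0 < ev.time_s < t1:
            raise WindowSpansEventError(
                f"window ({t0:.1f}, {t1:.1f}) s contains {ev.kind} at {ev.time_s:.1f} s"
            )
    mask = (trace.time >= t0) & (trace.time <= t1)
    if int(mask.sum()) < 5:
        raise InsufficientDataError(
            f"window ({t0:.1f}, {t1:.1f}) s holds {int(mask.sum())} samples; need >= 5"
        )
    res = sps.linregress(trace.time[mask], trace.o2_um[mask])
    return FluxEstimate(
        flux=float(-res.slope * 1000.0),
        se=float(res.stderr * 1000.0),
        n_samples=int(mask.sum()),
        window=(float(t0), float(t1)),
    )


def _segments(trace: O2Trace):
    """(name, start, end) for every protocol segment, in order."""
    events = sorted(trace.events.events, key=lambda e: e.time_s)
    t_start, t_end = float(trace.time[0]), float(trace.time[-1])
    bounds = [t_start] + [e.time_s for e in events] + [t_end]
    names = []
    cccp_i = 0
    pre = "routine"
    names.append(pre)
    for e in events:
        if e.kind == "pyruvate":
            names.append("postpyruvate")
        elif e.kind == "oligomycin":
            names.append("leak")
        elif e.kind == "cccp_step":
            cccp_i += 1
            names.append(f"cccp_{cccp_i}")
        elif e.kind == "antimycin":
            names.append("nonmito")
    return [(name, bounds[i], bounds[i + 1]) for i, name in enumerate(names)]


def segment_states(
    trace: O2Trace,
    settle: float = DEFAULT_SETTLE_S,
    window: float = DEFAULT_FLUX_WINDOW_S,
) -> RawStates:
    """Estimate every protocol state's raw flux from its segment.

    Each state is measured over the last `window` seconds of its segment,
    which must last at least settle + window seconds (the settle time lets
    the post-titration transition decay). ETS is the maximum across CCCP
    plateaus; ROUTINE comes from the window ending at the pyruvate event
    (oligomycin if the protocol omits pyruvate); the post-pyruvate segment
    is reported as an auxiliary state only.
    """
    trace.events.validate()
    estimates: dict[str, FluxEstimate] = {}
    cccp: list[FluxEstimate] = []
    for name, t0, t1 in _segments(trace):
        length = t1 - t0
        if length < settle + window:
            raise SegmentTooShortError(name, length, settle + window)
        est = estimate_flux(trace, (t1 - window, t1))
        if name.startswith("cccp_"):
            cccp.append(est)
        else:
            estimates[name] = est
    return RawStates(
        routine=estimates["routine"],
        leak=estimates["leak"],
        cccp_fluxes=cccp,
        nonmito=estimates["nonmito"],
        postpyruvate=estimates.get("postpyruvate"),
    )


def correct_and_normalize(raw: RawStates, trace: O2Trace) -> RespirationStates:
    """Antimycin correction and per-ul-blood normalisation.

    corrected = (raw - nonmito) * chamber_volume_ml / blood_volume_ul, turning
    pmol s^-1 per ml chamber into pmol s^-1 per ul blood. OXPHOS is derived as
    ROUTINE - LEAK on the corrected scale. Negative corrected values are kept
    but flagged.
    """
    if not trace.blood_volume_ul > 0:
        raise ValidationError("blood_volume_in_chamber", "must be positive")
    scale = trace.chamber_volume_ml / trace.blood_volume_ul
    nonmito = raw.nonmito.flux

    def corr(est: FluxEstimate) -> float:
        return (est.flux - nonmito) * scale

    routine_c = corr(raw.routine)
    leak_c = corr(raw.leak)
    ets_c = corr(raw.ets)
    oxphos_c = routine_c - leak_c
    flags = []
    if routine_c <= 0:
        flags.append("nonpositive_routine")
    if ets_c < routine_c:
        flags.append("ets_below_routine")
    if min(routine_c, leak_c, ets_c) < 0:
        flags.append("negative_corrected_rate")
    windows = {
        "routine": raw.routine.window,
        "leak": raw.leak.window,
        "ets": raw.ets.window,
        "nonmito": raw.nonmito.window,
    }
    return RespirationStates(
        routine=raw.routine.flux,
        leak=raw.leak.flux,
        ets=raw.ets.flux,
        nonmito=nonmito,
        routine_c=routine_c,
        leak_c=leak_c,
        ets_c=ets_c,
        oxphos_c=oxphos_c,
        windows=windows,
        flags=flags,
        postpyruvate=raw.postpyruvate.flux if raw.postpyruvate else None,
        sample_id=trace.sample_id,
    )


def coupling_efficiency(states: RespirationStates) -> float:
    """OXPHOS coupling efficiency E = 1 - LEAK/ROUTINE.

    The fraction of baseline O2 consumption linked to ATP synthesis: 0.80
    means 80% of O2 use drives phosphorylation, 20% compensates proton leak.
    Equals oxphos_c / routine_c. Undefined for routine_c <= 0.
    """
    if not states.routine_c > 0:
        raise UndefinedRatioError(
            f"coupling efficiency undefined: routine_c = {states.routine_c:.4g} <= 0"
        )
    return 1.0 - states.leak_c / states.routine_c


def reserve_capacity(states: RespirationStates) -> float:
    """OXPHOS reserve capacity FCR = 1 - ROUTINE/ETS.

    The scope to raise respiration above baseline: 0.80 means respiration can
    increase by 80% of maximal capacity. Negative (flagged upstream) when the
    uncoupled maximum fell below baseline. Undefined for ets_c <= 0.
    """
    if not states.ets_c > 0:
        raise UndefinedRatioError(
            f"reserve capacity undefined: ets_c = {states.ets_c:.4g} <= 0"
        )
    return 1.0 - states.routine_c / states.ets_c


def flux_control_ratios(states: RespirationStates) -> FluxControlRatios:
    """Both ratios, with None + flag instead of a numeric result when undefined."""
    flags = []
    try:
        e = coupling_efficiency(states)
    except UndefinedRatioError:
        e, flags = None, flags + ["coupling_undefined"]
    try:
        fcr = reserve_capacity(states)
    except UndefinedRatioError:
        fcr = None
        flags.append("reserve_undefined")
    if fcr is not None and fcr < 0:
        flags.append("negative_reserve")
    return FluxControlRatios(coupling_efficiency=e, reserve_capacity=fcr, flags=flags)


def process_trace(
    trace: O2Trace,
    settle: float = DEFAULT_SETTLE_S,
    window: float = DEFAULT_FLUX_WINDOW_S,
) -> tuple[RespirationStates, FluxControlRatios]:
    """Full per-sample pipeline: segment, correct, normalise, ratios."""
    raw = segment_states(trace, settle=settle, window=window)
    states = correct_and_normalize(raw, trace)
    return states, flux_control_ratios(states)
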