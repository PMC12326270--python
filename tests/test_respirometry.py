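import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import make_states
from mitoflight.errors import (
    InsufficientDataError,
    ProtocolError,
    SegmentTooShortError,
    UndefinedRatioError,
    WindowSpansEventError,
)
from mitoflight.respirometry import (
    O2Trace,
    TitrationEvent,
    TitrationProtocol,
    correct_and_normalize,
    coupling_efficiency,
    estimate_flux,
    flux_control_ratios,
    process_trace,
    reserve_capacity,
    segment_states,
)
from mitoflight.synthetic import TraceSimParams, simulate_o2k_trace


def linear_trace(slope_um_per_s=-0.01, n=101, dt=1.0, c0=200.0):
    """A single-state trace with events placed far beyond its samples."""
    t = np.arange(n) * dt
    protocol = TitrationProtocol([
        TitrationEvent(1e5, "oligomycin"),
        TitrationEvent(1e5 + 100, "cccp_step"),
        TitrationEvent(1e5 + 200, "antimycin"),
    ])
    trace = O2Trace(time=t, o2_um=c0 + slope_um_per_s * t, events=protocol)
    return trace


class TestEstimateFlux:
    def test_slope_identity(self):
        est = estimate_flux(linear_trace(-0.01), (0.0, 100.0))
        assert est.flux == pytest.approx(10.0, rel=1e-9)
        assert est.se == pytest.approx(0.0, abs=1e-9)

    def test_constant_concentration_gives_zero(self):
        est = estimate_flux(linear_trace(0.0), (0.0, 100.0))
        assert est.flux == pytest.approx(0.0, abs=1e-12)

    def test_window_spanning_event_rejected(self, noiseless_trace):
        t_oligo = noiseless_trace.events.time_of("oligomycin")
        with pytest.raises(WindowSpansEventError):
            estimate_flux(noiseless_trace, (t_oligo - 30, t_oligo + 30))

    def test_boundary_event_allowed(self, noiseless_trace):
        t_pyr = noiseless_trace.events.time_of("pyruvate")
        est = estimate_flux(noiseless_trace, (t_pyr - 60, t_pyr))
        assert est.flux == pytest.approx(30.0, rel=1e-6)

    def test_too_few_samples_rejected(self):
        with pytest.raises(InsufficientDataError):
            estimate_flux(linear_trace(), (0.0, 3.0))

    def test_se_covers_truth_in_monte_carlo(self, rng):
        """The regression SE is honest: +-2 SE covers the generating flux in
        about 95% of noisy replicates (well above the 93% floor)."""
        t = np.arange(0.0, 122.0, 2.0)
        true_flux = 30.0
        hits = 0
        n_rep = 1000
        protocol = linear_trace().events
        for _ in range(n_rep):
            conc = 200.0 - true_flux / 1000.0 * t + rng.normal(0, 0.2, size=t.size)
            trace = O2Trace(time=t, o2_um=conc, events=protocol)
            est = estimate_flux(trace, (0.0, 120.0))
            hits += abs(est.flux - true_flux) <= 2 * est.se
        assert hits / n_rep >= 0.93


class TestSegmentStates:
    def test_noiseless_round_trip(self, noiseless_trace):
        raw = segment_states(noiseless_trace)
        assert raw.routine.flux == pytest.approx(30.0, rel=0.01)
        assert raw.leak.flux == pytest.approx(8.0, rel=0.01)
        assert raw.ets.flux == pytest.approx(60.0, rel=0.01)
        assert raw.nonmito.flux == pytest.approx(3.0, rel=0.01)
        assert raw.postpyruvate.flux == pytest.approx(30.0, rel=0.01)

    def test_ets_is_maximum_across_cccp_plateaus(self):
        trace = simulate_o2k_trace(TraceSimParams(noise_sd=0.0, n_cccp_steps=3))
        raw = segment_states(trace)
        fluxes = [f.flux for f in raw.cccp_fluxes]
        assert len(fluxes) == 3
        assert raw.ets.flux == max(fluxes)
        # the generator's profile peaks before the last step, so the maximum
        # rule is genuinely exercised
        assert fluxes[-1] < raw.ets.flux
        assert raw.ets.flux == pytest.approx(60.0, rel=0.01)

    def test_missing_antimycin_rejected(self):
        with pytest.raises(ProtocolError):
            TitrationProtocol([
                TitrationEvent(100.0, "oligomycin"),
                TitrationEvent(200.0, "cccp_step"),
            ])

    def test_cccp_outside_oligomycin_antimycin_rejected(self):
        with pytest.raises(ProtocolError):
            TitrationProtocol([
                TitrationEvent(50.0, "cccp_step"),
                TitrationEvent(100.0, "oligomycin"),
                TitrationEvent(200.0, "antimycin"),
            ])

    def test_pyruvate_after_oligomycin_rejected(self):
        with pytest.raises(ProtocolError):
            TitrationProtocol([
                TitrationEvent(100.0, "oligomycin"),
                TitrationEvent(150.0, "pyruvate"),
                TitrationEvent(200.0, "cccp_step"),
                TitrationEvent(300.0, "antimycin"),
            ])

    def test_short_segment_names_the_state(self, noiseless_trace):
        # the 180 s post-pyruvate segment is the shortest one in the default
        # protocol, so it is the first to violate settle + window = 190 s
        with pytest.raises(SegmentTooShortError, match="postpyruvate"):
            segment_states(noiseless_trace, settle=30.0, window=160.0)

    def test_window_independence_on_noiseless_segment(self, noiseless_trace):
        a = estimate_flux(noiseless_trace, (100.0, 200.0))
        b = estimate_flux(noiseless_trace, (150.0, 290.0))
        assert a.flux == pytest.approx(b.flux, abs=1e-9)


class TestCorrectAndNormalize:
    def test_arithmetic_under_stated_convention(self, noiseless_trace):
        raw = segment_states(noiseless_trace)
        raw.routine.flux, raw.nonmito.flux = 30.0, 5.0
        states = correct_and_normalize(raw, noiseless_trace)  # 2 ml, 50 ul
        assert states.routine_c == pytest.approx((30.0 - 5.0) * 2.0 / 50.0)

    def test_leak_equal_to_nonmito_corrects_to_zero(self, noiseless_trace):
        raw = segment_states(noiseless_trace)
        raw.leak.flux = raw.nonmito.flux
        states = correct_and_normalize(raw, noiseless_trace)
        assert states.leak_c == pytest.approx(0.0, abs=1e-12)

    def test_oxphos_identity(self, noiseless_trace):
        states, _ = process_trace(noiseless_trace)
        assert states.oxphos_c + states.leak_c == states.routine_c  # exact

    def test_negative_rates_flagged_not_clamped(self, noiseless_trace):
        raw = segment_states(noiseless_trace)
        raw.leak.flux = raw.nonmito.flux - 1.0
        states = correct_and_normalize(raw, noiseless_trace)
        assert states.leak_c < 0
        assert "negative_corrected_rate" in states.flags


class TestFluxControlRatios:
    def test_coupling_worked_case(self):
        assert coupling_efficiency(make_states(10.0, 2.0)) == pytest.approx(0.80)

    def test_coupling_limits(self):
        assert coupling_efficiency(make_states(5.0, 5.0)) == pytest.approx(0.0)
        assert coupling_efficiency(make_states(5.0, 0.0)) == pytest.approx(1.0)

    def test_coupling_equals_oxphos_over_routine(self, noiseless_trace):
        states, ratios = process_trace(noiseless_trace)
        assert ratios.coupling_efficiency * states.routine_c == pytest.approx(
            states.oxphos_c, rel=1e-12
        )

    def test_reserve_worked_case(self):
        assert reserve_capacity(make_states(2.0, 0.5, ets_c=10.0)) == pytest.approx(0.80)

    def test_reserve_no_headroom(self):
        assert reserve_capacity(make_states(10.0, 2.0, ets_c=10.0)) == pytest.approx(0.0)

    def test_reserve_negative_when_ets_below_routine(self):
        states = make_states(12.0, 2.0, ets_c=10.0)
        ratios = flux_control_ratios(states)
        assert ratios.reserve_capacity == pytest.approx(-0.2)
        assert "negative_reserve" in ratios.flags

    def test_undefined_ratios_flagged(self):
        states = make_states(-1.0, 0.5, ets_c=0.0)
        with pytest.raises(UndefinedRatioError):
            coupling_efficiency(states)
        ratios = flux_control_ratios(states)
        assert ratios.coupling_efficiency is None
        assert ratios.reserve_capacity is None
        assert "coupling_undefined" in ratios.flags

    def test_round_trip_ratios_match_generating_fluxes(self, noiseless_trace):
        _, ratios = process_trace(noiseless_trace)
        # generating fluxes: routine 30, leak 8, ets 60, nonmito 3 -> corrected
        # routine 27, leak 5, ets 57 (per-ml basis, scale cancels in ratios)
        assert ratios.coupling_efficiency == pytest.approx(1 - 5 / 27, abs=1e-3)
        assert ratios.reserve_capacity == pytest.approx(1 - 27 / 57, abs=1e-3)

    @settings(max_examples=10, derandomize=True, deadline=None)
    @given(k=st.floats(0.5, 3.0))
    def test_scale_equivariance(self, k):
        """Scaling every generating flux by k scales every state by k and
        leaves both flux control ratios unchanged."""
        base = TraceSimParams(noise_sd=0.0)
        scaled = TraceSimParams(
            true_routine=30.0 * k, true_leak=8.0 * k,
            true_ets_peak=60.0 * k, true_nonmito=3.0 * k, noise_sd=0.0,
        )
        s1, r1 = process_trace(simulate_o2k_trace(base))
        s2, r2 = process_trace(simulate_o2k_trace(scaled))
        assert s2.routine_c == pytest.approx(k * s1.routine_c, rel=1e-6)
        assert s2.ets_c == pytest.approx(k * s1.ets_c, rel=1e-6)
        assert r2.coupling_efficiency == pytest.approx(r1.coupling_efficiency, abs=1e-6)
        assert r2.reserve_capacity == pytest.approx(r1.reserve_capacity, abs=1e-6)
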