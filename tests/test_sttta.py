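import math

import numpy as np
import pytest
from hypothesis import given, strategies as st

from gaitphase.signal_io import GcfRecording
from gaitphase.sttta import (
    ContactStatus,
    StttaParams,
    ThresholdTriple,
    classify_sample,
    fixed_point_thresholds,
    init_state,
    run_sttta,
    step,
)
from gaitphase.synthetic import GaitProfileParams, generate_walk


class TestInitState:
    def test_defaults(self, default_params):
        state = init_state(default_params)
        assert state.thresholds.as_tuple() == (15.0, 20.0, 25.0)
        assert state.i == 0 and state.j == 0
        assert state.max_acc is None and state.min_acc is None
        assert state.phase_point.value == "unsynced"

    @pytest.mark.parametrize(
        "kwargs",
        [
            dict(t_l0=20.0, t_m0=20.0),  # not strictly ordered
            dict(beta=0.042, gamma=0.071),  # gamma >= beta
            dict(gamma=0.0),
            dict(lam=1.0),
        ],
    )
    def test_invalid_params_rejected(self, kwargs):
        with pytest.raises(ValueError):
            StttaParams(**kwargs)


class TestClassifySample:
    @pytest.mark.parametrize(
        "f,t_h,on",
        [(30.0, 25.0, True), (25.0, 25.0, True), (24.999, 25.0, False)],
    )
    def test_boundary_counts_as_contact(self, f, t_h, on):
        expected = ContactStatus.ON_GROUND if on else ContactStatus.OFF_GROUND
        assert classify_sample(f, t_h) is expected

    def test_nonfinite_rejected(self):
        with pytest.raises(ValueError):
            classify_sample(math.nan, 25.0)


class TestStep:
    def test_square_wave_first_cycle_retunes(self, square_wave, default_params):
        """Hand-applied update rules on a 500 N / 0 N square wave."""
        _, trace = run_sttta(square_wave, default_params)
        ev = {(e.name, e.cycle_i): e.new for e in trace.events}
        assert ev[("t_h", 0)] == pytest.approx(0.071 * 485 + 15)  # 49.435
        assert ev[("t_m", 0)] == pytest.approx(0.042 * 485 + 15)  # 35.37
        assert ev[("t_l", 1)] == pytest.approx(0.5 * 0 + 0.5 * 35.37)  # 17.685

    def test_subthreshold_input_never_retunes(self, default_params):
        state = init_state(default_params)
        for _ in range(5000):
            assert step(state, 10.0) is ContactStatus.OFF_GROUND
        assert state.thresholds.as_tuple() == (15.0, 20.0, 25.0)
        assert state.i == 0 and state.j == 0 and not state.events

    def test_nonfinite_force_rejected(self, default_params):
        state = init_state(default_params)
        with pytest.raises(ValueError):
            step(state, math.inf)

    def test_incomplete_cycles_allow_i_neq_j(self, default_params):
        # a full hump, then a bump that crosses t_m but never reaches t_h
        # (incomplete cycle: a minimum closes without a new maximum)
        f = np.concatenate(
            [
                np.zeros(50),
                500 * np.sin(np.linspace(0, np.pi, 200)) ** 2,
                np.zeros(200),
                40 * np.sin(np.linspace(0, np.pi, 200)) ** 2,  # sub-t_h bump
                np.zeros(200),
                30 * np.ones(50),  # rise above t_l closes the second cycle
            ]
        )
        rec = GcfRecording.from_force(f, 1000.0, "heel")
        state = init_state(default_params)
        for x in f.tolist():
            step(state, x)
        assert state.j == 1  # only one maximum finalized
        assert state.i == 2  # but two minimum regions closed
        assert state.j != state.i

    def test_recrossing_after_retune_does_not_reopen_max_region(
        self, default_params
    ):
        """A post-update excursion above t_h must not retune twice."""
        hump = 500 * np.sin(np.linspace(0, np.pi, 300)) ** 2
        dip = np.concatenate([hump[:150], 30 * np.ones(50), hump[150:]])
        cycle = np.concatenate([np.zeros(100), dip, np.zeros(300)])
        rec = GcfRecording.from_force(np.tile(cycle, 3), 1000.0, "heel")
        _, trace = run_sttta(rec, default_params)
        th_events = [e for e in trace.events if e.name == "t_h"]
        by_cycle = {}
        for e in th_events:
            by_cycle.setdefault(e.cycle_i, 0)
            by_cycle[e.cycle_i] += 1
        assert all(v == 1 for v in by_cycle.values())
        # the split hump still yields the full 500 N maximum
        assert th_events[0].new == pytest.approx(0.071 * (500 - 15) + 15, abs=0.2)

    def test_disordering_update_rejected_with_warning(self, default_params):
        # big first cycle raises t_m high; a barely-supra-threshold second
        # cycle would compute t_h below t_m and must be rejected
        big = 1000 * np.sin(np.linspace(0, np.pi, 300)) ** 2
        state = init_state(default_params)
        for x in np.concatenate([np.zeros(50), big, np.zeros(300)]):
            step(state, float(x))
        t_h_before = state.t_h
        small = (t_h_before + 5) * np.sin(np.linspace(0, np.pi, 300)) ** 2
        with pytest.warns(UserWarning, match="rejected t_h"):
            for x in np.concatenate([small, np.zeros(300)]):
                step(state, float(x))
        assert state.t_h == t_h_before  # previous value retained
        assert state.rejected_updates == 1
        assert state.t_l < state.t_m < state.t_h


class TestRunSttta:
    def test_one_status_per_sample(self, clean_walk, default_params):
        _, ball, heel, _ = clean_walk
        status, trace = run_sttta(heel, default_params)
        assert status.size == heel.n == trace.t_h.size

    def test_retune_count_matches_cycle_count(self, clean_walk, default_params):
        _, _, heel, _ = clean_walk
        _, trace = run_sttta(heel, default_params)
        state_i = max(e.cycle_i for e in trace.events)
        th = [e for e in trace.events if e.name == "t_h" and e.cycle_i < state_i]
        assert len(th) == state_i

    @pytest.mark.filterwarnings("ignore:rejected")
    def test_streaming_equals_batch(self, default_params):
        # raw (unfiltered) noise exercises bounce paths; both routes must
        # still agree sample for sample
        params = GaitProfileParams(noise_sd=2.0, seed=5)
        ball, heel, _ = generate_walk(params, duration_s=30.0, fs=2000.0)
        batch_status, batch_trace = run_sttta(heel, default_params)
        state = init_state(default_params)
        stream = np.array(
            [step(state, f) is ContactStatus.ON_GROUND for f in heel.f.tolist()]
        )
        np.testing.assert_array_equal(stream, batch_status)
        assert state.t_h == batch_trace.t_h[-1]
        assert tuple(state.events) == batch_trace.events

    def test_causality_of_status(self, default_params):
        params = GaitProfileParams(noise_sd=2.0, seed=9)
        _, heel, _ = generate_walk(params, duration_s=4.0, fs=1000.0)
        cut = 2500
        full, _ = run_sttta(heel, default_params)
        altered = heel.f.copy()
        altered[cut:] = 0.0
        trunc, _ = run_sttta(heel.with_force(altered), default_params)
        np.testing.assert_array_equal(full[:cut], trunc[:cut])


class TestFixedPoint:
    def test_reference_solution(self, default_params):
        fp = fixed_point_thresholds(1000.0, 0.0, default_params)
        # t_l* = (0.5*0 + 0.5*0.042*1000) / (0.5 + 0.5*0.042) = 21 / 0.521
        assert fp.t_l == pytest.approx(21.0 / 0.521, rel=1e-12)
        assert (fp.t_l, fp.t_m, fp.t_h) == pytest.approx(
            (40.307, 80.614, 108.445), abs=5e-4
        )

    def test_lambda_one_limit_pins_t_l_to_minimum(self):
        params = StttaParams(lam=1.0 - 1e-9)
        fp = fixed_point_thresholds(500.0, 3.0, params)
        assert fp.t_l == pytest.approx(3.0, abs=1e-5)

    def test_degenerate_extrema_rejected(self, default_params):
        with pytest.raises(ValueError):
            fixed_point_thresholds(100.0, 100.0, default_params)

    def test_matches_brute_force_iteration(self, default_params):
        """Independent oracle: iterate the three update maps to stationarity."""
        M, m = 700.0, 2.0
        p = default_params
        t_l = p.t_l0
        for _ in range(200):
            t_m = p.gamma * (M - t_l) + t_l
            t_l = p.lam * m + (1 - p.lam) * t_m
        t_m = p.gamma * (M - t_l) + t_l
        t_h = p.beta * (M - t_l) + t_l
        fp = fixed_point_thresholds(M, m, p)
        assert (fp.t_l, fp.t_m, fp.t_h) == pytest.approx((t_l, t_m, t_h), rel=1e-12)

    @given(
        M=st.floats(100.0, 2000.0),
        m=st.floats(0.0, 10.0),
        beta=st.floats(0.02, 0.5),
        frac=st.floats(0.1, 0.9),
        lam=st.floats(0.05, 0.95),
    )
    def test_ordering_preserved_for_any_valid_inputs(self, M, m, beta, frac, lam):
        params = StttaParams(beta=beta, gamma=beta * frac, lam=lam)
        fp = fixed_point_thresholds(M, m, params)
        assert fp.t_l < fp.t_m < fp.t_h

    def test_detector_converges_geometrically(self, default_params):
        """On strictly periodic input the t_l error contracts by
        (1-lam)(1-gamma) per cycle, reaching 1e-6 N within ~25 cycles."""
        profile = GaitProfileParams(noise_sd=0.0, baseline=0.0).with_peak(1000.0)
        _, heel, _ = generate_walk(profile, duration_s=30.0, fs=2000.0)
        _, trace = run_sttta(heel, default_params)
        fp = fixed_point_thresholds(1000.0, 0.0, default_params)
        err = np.maximum.reduce(
            [
                np.abs(trace.t_l - fp.t_l),
                np.abs(trace.t_m - fp.t_m),
                np.abs(trace.t_h - fp.t_h),
            ]
        )
        fs, cadence = 2000.0, profile.cadence_hz
        end = lambda c: int(c * fs / cadence) - 1
        assert err[end(26)] < 1e-6
        # contraction rate of the t_l recursion
        rate = (1 - default_params.lam) * (1 - default_params.gamma)
        tl_err = np.abs(trace.t_l - fp.t_l)
        ratios = [tl_err[end(c + 1)] / tl_err[end(c)] for c in range(3, 10)]
        assert np.allclose(ratios, rate, rtol=0.05)


def test_threshold_triple_validates_ordering():
    with pytest.raises(ValueError):
        ThresholdTriple(10.0, 10.0, 20.0)
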