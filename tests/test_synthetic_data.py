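import numpy as np
import pytest
import sympy
from scipy.integrate import solve_ivp

from petinput.core_model import ExperimentConfig, FrameSchedule, TimeActivityCurve, UNITS_SUV
from petinput.input_function import FengModel
from petinput.kinetics import TwoTissueParams
from petinput import synthetic_data as sd


class TestFengCurve:
    def test_zero_at_onset(self, dense_t, feng_reference):
        v = sd.feng_curve(feng_reference.with_onset(12.0), dense_t)
        assert v[dense_t <= 12.0] == pytest.approx(0.0)
        # continuity just past onset
        assert abs(v[13]) < feng_reference.A1 * 2

    def test_single_exponential_peak_location_and_height(self):
        # with A2=A3=0 the curve is A1*t*e^{-l1 t}: peak at 1/l1, height A1/(l1*e)
        m = FengModel(A1=2.0, A2=0.0, A3=0.0, l1=0.1, l2=0.01, l3=0.001, t0=0.0)
        t = np.arange(0.0, 200.0, 0.01)
        v = sd.feng_curve(m, t)
        assert t[np.argmax(v)] == pytest.approx(10.0, abs=0.02)
        assert v.max() == pytest.approx(2.0 / (0.1 * np.e), rel=1e-6)

    def test_matches_symbolic_evaluation(self, feng_reference):
        ts = sympy.symbols("t", positive=True)
        m = feng_reference
        expr = (
            (m.A1 * (ts - m.t0) - m.A2 - m.A3) * sympy.exp(-m.l1 * (ts - m.t0))
            + m.A2 * sympy.exp(-m.l2 * (ts - m.t0))
            + m.A3 * sympy.exp(-m.l3 * (ts - m.t0))
        )
        grid = np.arange(5.0, 300.0, 7.0)
        expected = np.array([float(expr.subs(ts, x)) for x in grid])
        assert np.allclose(sd.feng_curve(m, grid), expected, rtol=1e-10)

    def test_eigenvalue_ordering_enforced(self):
        with pytest.raises(ValueError):
            FengModel(A1=1.0, A2=0.1, A3=0.1, l1=0.01, l2=0.1, l3=0.001)


class TestShapeInjection:
    def test_auc_preserved(self, dense_t):
        # bolus with support well inside the scan window
        m = FengModel(A1=2.0, A2=0.5, A3=0.2, l1=0.1, l2=0.02, l3=0.005, t0=10.0)
        bolus = sd.feng_curve(m, dense_t)
        for dur in (15.0, 30.0, 60.0):
            shaped = sd.shape_injection(dense_t, bolus, dur)
            assert np.trapezoid(shaped, dense_t) == pytest.approx(
                np.trapezoid(bolus, dense_t), rel=1e-3
            )

    def test_peak_decreases_with_duration(self, dense_t, feng_reference):
        bolus = sd.feng_curve(feng_reference, dense_t)
        peaks = [sd.shape_injection(dense_t, bolus, d).max() for d in (15.0, 30.0, 60.0)]
        assert peaks[0] > peaks[1] > peaks[2]

    def test_subgrid_duration_is_identity_with_warning(self, dense_t, feng_reference):
        bolus = sd.feng_curve(feng_reference, dense_t)
        with pytest.warns(UserWarning):
            out = sd.shape_injection(dense_t, bolus, 0.25)
        assert np.array_equal(out, bolus)


class TestForward2TCM:
    def test_zero_uptake_zero_vb_is_zero(self, dense_t):
        p = TwoTissueParams(K1=0.0, k2=0.3, k3=0.05, k4=0.01, vB=0.0)
        cp = np.ones_like(dense_t)
        assert np.all(sd.forward_2tcm(p, cp, cp, dense_t) == 0)

    def test_one_tissue_closed_form(self):
        # constant input, k3=k4=0, vB=0: C(t) = (K1/k2)(1 - e^{-k2 t})
        t = np.arange(0.0, 3600.0, 1.0)
        cp = np.ones_like(t)
        p = TwoTissueParams(K1=0.3, k2=0.5, k3=0.0, k4=0.0, vB=0.0)
        expected = (0.3 / 0.5) * (1.0 - np.exp(-0.5 * t / 60.0))
        assert np.allclose(sd.forward_2tcm(p, cp, cp, t), expected, atol=1e-8)

    def test_matches_stiff_ode_oracle(self, dense_t, feng_reference):
        cp = sd.shape_injection(dense_t, sd.feng_curve(feng_reference, dense_t), 30.0)
        p = TwoTissueParams(K1=0.24, k2=0.42, k3=0.06, k4=0.012, vB=0.05)

        def rhs(tt, y):
            c = np.interp(tt, dense_t, cp)
            K1, k2, k3, k4 = (x / 60.0 for x in (p.K1, p.k2, p.k3, p.k4))
            return [K1 * c - (k2 + k3) * y[0] + k4 * y[1], k3 * y[0] - k4 * y[1]]

        sol = solve_ivp(rhs, (0, dense_t[-1]), [0, 0], t_eval=dense_t, method="LSODA",
                        rtol=1e-10, atol=1e-12)
        oracle = (1 - p.vB) * (sol.y[0] + sol.y[1]) + p.vB * cp
        mine = sd.forward_2tcm(p, cp, cp, dense_t)
        assert np.abs(mine - oracle).max() / np.abs(oracle).max() < 1e-4

    def test_negative_rates_rejected(self):
        with pytest.raises(ValueError):
            TwoTissueParams(K1=-0.1, k2=0.3, k3=0.0, k4=0.0)


class TestFrameAverage:
    def test_constant_curve(self, dense_t, schedule):
        tac = sd.frame_average(dense_t, np.ones_like(dense_t), schedule)
        assert np.allclose(tac.values, 1.0)

    def test_linear_ramp_single_frame(self):
        t = np.arange(0.0, 4.0, 0.01)
        sched = FrameSchedule(np.array([0.0]), np.array([2.0]))
        tac = sd.frame_average(t, t, sched)
        assert tac.values[0] == pytest.approx(1.0, abs=1e-6)

    def test_matches_trapezoid_oracle(self, dense_t, schedule, feng_reference):
        v = sd.feng_curve(feng_reference, dense_t)
        tac = sd.frame_average(dense_t, v, schedule)
        for i in (0, 10, 40, 70, 85):
            mask = (dense_t >= schedule.start[i]) & (dense_t <= schedule.end[i])
            oracle = np.trapezoid(v[mask], dense_t[mask]) / schedule.duration[i]
            assert tac.values[i] == pytest.approx(oracle, rel=1e-6, abs=1e-9)

    def test_frame_outside_grid_rejected(self, schedule):
        t = np.arange(0.0, 100.0, 1.0)
        with pytest.raises(ValueError):
            sd.frame_average(t, np.ones_like(t), schedule)


class TestDispersion:
    def test_step_response_closed_form(self):
        t = np.arange(0.0, 300.0, 0.5)
        step = np.ones_like(t)
        out = sd.apply_dispersion(t, step, sd.DispersionSpec(tau=10.0, delay=0.0))
        assert np.allclose(out, 1.0 - np.exp(-t / 10.0), atol=5e-3)

    def test_tau_zero_delay_zero_is_identity(self, dense_t, feng_reference):
        v = sd.feng_curve(feng_reference, dense_t)
        out = sd.apply_dispersion(dense_t, v, sd.DispersionSpec(tau=0.0, delay=0.0))
        assert np.array_equal(out, v)

    def test_auc_preserved_on_finite_bolus(self, dense_t):
        # fast-decaying bolus has negligible mass beyond the window
        m = FengModel(A1=2.0, A2=0.5, A3=0.2, l1=0.1, l2=0.02, l3=0.005, t0=10.0)
        v = sd.feng_curve(m, dense_t)
        out = sd.apply_dispersion(dense_t, v, sd.DispersionSpec(tau=10.0, delay=0.0))
        assert np.trapezoid(out, dense_t) == pytest.approx(
            np.trapezoid(v, dense_t), rel=5e-3
        )

    def test_peak_decreases_monotonically_in_tau(self, dense_t, feng_reference):
        v = sd.shape_injection(dense_t, sd.feng_curve(feng_reference, dense_t), 30.0)
        peaks = [
            sd.apply_dispersion(dense_t, v, sd.DispersionSpec(tau=tau, delay=0.0)).max()
            for tau in (0.0, 2.0, 5.0, 10.0, 30.0)
        ]
        assert all(a > b for a, b in zip(peaks, peaks[1:]))


class TestNoise:
    def test_scale_zero_is_identity(self, dense_t, schedule):
        tac = sd.frame_average(dense_t, np.ones_like(dense_t), schedule)
        out = sd.add_noise(tac, sd.NoiseSpec(scale=0.0, seed=1))
        assert np.array_equal(out.values, tac.values)

    def test_seeded_reproducibility(self, dense_t, schedule):
        tac = sd.frame_average(dense_t, np.full_like(dense_t, 4.0), schedule)
        a = sd.add_noise(tac, sd.NoiseSpec(scale=0.2, seed=7))
        b = sd.add_noise(tac, sd.NoiseSpec(scale=0.2, seed=7))
        c = sd.add_noise(tac, sd.NoiseSpec(scale=0.2, seed=8))
        assert np.array_equal(a.values, b.values)
        assert not np.array_equal(a.values, c.values)

    def test_empirical_sd_matches_nominal(self):
        # fixed frame: value 4, duration 2 s, scale 0.3 -> SD = 0.3*sqrt(2)
        sched = FrameSchedule(np.array([0.0]), np.array([2.0]))
        tac = TimeActivityCurve(sched.mid, np.array([4.0]), UNITS_SUV, "brain", sched)
        draws = np.array(
            [sd.add_noise(tac, sd.NoiseSpec(scale=0.3, seed=s)).values[0] for s in range(1000)]
        )
        nominal = 0.3 * np.sqrt(4.0 / 2.0)
        assert draws.std() == pytest.approx(nominal, rel=0.05)


class TestBloodSamples:
    def test_cv_zero_equals_truth(self, dense_t, feng_reference):
        curve = TimeActivityCurve(dense_t, sd.feng_curve(feng_reference, dense_t), UNITS_SUV)
        samples = sd.draw_blood_samples(curve, [1800.0, 2250.0, 2700.0], cv=0.0, seed=0)
        for s in samples:
            assert s.concentration == pytest.approx(float(curve.interp(s.time)))

    def test_mean_of_many_draws_unbiased(self, dense_t, feng_reference):
        curve = TimeActivityCurve(dense_t, sd.feng_curve(feng_reference, dense_t), UNITS_SUV)
        truth = float(curve.interp(2000.0))
        vals = [
            sd.draw_blood_samples(curve, [2000.0], cv=0.05, seed=s)[0].concentration
            for s in range(1000)
        ]
        assert np.mean(vals) == pytest.approx(truth, rel=0.01)

    def test_out_of_support_time_rejected(self, dense_t, feng_reference):
        curve = TimeActivityCurve(dense_t, sd.feng_curve(feng_reference, dense_t), UNITS_SUV)
        with pytest.raises(ValueError):
            sd.draw_blood_samples(curve, [5000.0], cv=0.0, seed=0)


class TestSimulateSubject:
    def test_clean_detector_trace_equals_truth(self, feng_reference):
        cfg = ExperimentConfig(withdrawal_rate_ul_min=1e9, catheter_delay_s=1e-12)
        # tau ~ 0 through the withdrawal link; unit gain; no noise
        s = sd.simulate_subject(cfg, noise_scale=0.0, sample_cv=0.0, detector_gain=1.0, seed=0)
        assert np.allclose(s.detector_trace.values, s.true_aif.values, atol=1e-9)

    def test_lv_equals_blood_when_rc_is_one(self):
        cfg = ExperimentConfig(recovery_coefficient=1.0)
        s = sd.simulate_subject(cfg, noise_scale=0.0, sample_cv=0.0, seed=0)
        framed_blood = sd.frame_average(s.dense_times, s.true_aif.values, s.schedule)
        assert np.allclose(s.tacs["left_ventricle"].values, framed_blood.values, rtol=1e-10)

    def test_regeneration_is_bit_identical(self, reference_config):
        a = sd.simulate_subject(reference_config, seed=123)
        b = sd.simulate_subject(reference_config, seed=123)
        assert np.array_equal(a.detector_trace.values, b.detector_trace.values)
        for r in a.tacs:
            assert np.array_equal(a.tacs[r].values, b.tacs[r].values)
        assert [s.concentration for s in a.blood_samples] == [
            s.concentration for s in b.blood_samples
        ]


class TestSimulateCohort:
    def test_zero_cv_single_subject_uses_default_parameters(self, reference_config):
        spec = sd.CohortSpec(n_subjects=1, config=reference_config)
        for dists in spec.kinetic_dists.values():
            for d in dists.values():
                d.cv = 0.0
        for d in spec.feng_dists.values():
            d.cv = 0.0
        subj = sd.simulate_cohort(spec, seed=5)[0]
        assert subj.truth_feng == sd.DEFAULT_FENG
        assert subj.truth_kinetics["brain"] == sd.DEFAULT_KINETICS["brain"]

    def test_reference_group_smoke(self, reference_config):
        subjects = sd.simulate_cohort(sd.CohortSpec(n_subjects=9, config=reference_config), seed=1)
        assert len(subjects) == 9
        # subjects differ biologically
        k1s = {s.truth_kinetics["brain"].K1 for s in subjects}
        assert len(k1s) == 9

    def test_sample_mean_tracks_specified_mean(self, reference_config):
        spec = sd.CohortSpec(n_subjects=200, config=reference_config)
        rng_draws = []
        ss = np.random.SeedSequence([11, 0xC0407])
        param_rng = np.random.default_rng(ss.spawn(1)[0])
        for _ in range(200):
            _, kin = sd._draw_subject_params(spec, param_rng)
            rng_draws.append(kin["brain"].K1)
        assert np.mean(rng_draws) == pytest.approx(sd.DEFAULT_KINETICS["brain"].K1, rel=0.02)

    def test_negative_cv_rejected(self):
        with pytest.raises(ValueError):
            sd.ParamDist(mean=1.0, cv=-0.1)


class TestTripleInjection:
    def test_noiseless_trace_is_sum_of_components(self):
        trip = sd.simulate_triple_injection(
            [sd.DEFAULT_FENG] * 3, [0.0, 900.0, 1800.0], noise_scale=0.0, seed=0
        )
        total = sum(c.values for c in trip.components)
        assert np.allclose(trip.trace.values, total, atol=1e-12)

    def test_disjoint_support_segments_match_components(self):
        # fast-decaying bolus: negligible carry-over across 900 s spacing
        fast = FengModel(A1=2.0, A2=0.5, A3=0.2, l1=0.1, l2=0.03, l3=0.01, t0=2.0)
        trip = sd.simulate_triple_injection(
            [fast] * 3, [0.0, 900.0, 1800.0], noise_scale=0.0, seed=0
        )
        t = trip.dense_times
        seg2 = (t >= 900) & (t < 1800)
        carry = trip.components[0].values[seg2] + trip.components[1].values[:0].sum()
        assert carry.max() < 1e-3 * trip.components[0].values.max()

    def test_paper_protocol_sampling_times(self):
        trip = sd.simulate_triple_injection(
            [sd.DEFAULT_FENG] * 3, [0.0, 900.0, 1800.0], noise_scale=0.0, seed=0
        )
        assert [s.time for s in trip.samples] == [600.0, 1500.0, 2400.0]

    def test_unordered_injections_rejected(self):
        with pytest.raises(ValueError):
            sd.simulate_triple_injection([sd.DEFAULT_FENG] * 3, [0.0, 900.0, 800.0], seed=0)
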