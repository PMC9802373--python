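"""Tests of the fluctuation-analysis pipeline: windowed statistics,
autocorrelation, rotation-curve fits, calibration, domain-size inference,
state segmentation, plectoneme stiffness, and dwell-time kinetics."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from plectonemics import analysis, synth, theory
from plectonemics.analysis import (
    ExtensionTrace,
    FluctuationCalibration,
    RotationCurve,
)
from plectonemics.params import ElasticParams, MoleculeSpec

P = ElasticParams()


def make_trace(z, rate=1000.0, **kw):
    t = np.arange(len(z)) / rate
    return ExtensionTrace(t, z, rate, **kw)


class TestWindowedStats:
    def test_constant_trace_zero_variance(self):
        tr = make_trace(np.full(5000, 700.0))
        ws = analysis.windowed_stats(tr, 1.0)
        assert np.all(ws.variances == 0.0)
        assert ws.pooled_var == 0.0

    def test_iid_gaussian_recovers_variance(self):
        rng = np.random.default_rng(1)
        s2 = 40.0
        tr = make_trace(rng.normal(0, math.sqrt(s2), 120_000))
        ws = analysis.windowed_stats(tr, 1.0)
        # chi-square sampling: Var(s²) = 2σ⁴/(n−1) per window, pooled /n_win
        se = s2 * math.sqrt(2.0 / 999) / math.sqrt(120)
        assert abs(ws.pooled_var - s2) < 3 * se

    def test_ou_windowed_variance_close_to_model(self):
        m = synth.TraceModel(
            mean=0.0, variance=150.0, corr_time=0.01,
            acquisition_rate=1000.0, duration=300.0,
        )
        tr = synth.generate_ou_trace(m, seed=4)
        ws = analysis.windowed_stats(make_trace(tr.z), 1.0)
        # finite-window OU bias is ≈ 2τ_c/T_w = 2% here
        assert ws.pooled_var == pytest.approx(150.0, rel=0.05)

    def test_window_too_short_rejected(self):
        tr = make_trace(np.zeros(5000))
        with pytest.raises(ValueError):
            analysis.windowed_stats(tr, 0.005)


class TestAutocorrelationTime:
    def test_ou_tau_recovered(self):
        m = synth.TraceModel(
            mean=0.0, variance=100.0, corr_time=0.005,
            acquisition_rate=1000.0, duration=600.0,
        )
        tr = synth.generate_ou_trace(m, seed=11)
        tau = analysis.autocorrelation_time(make_trace(tr.z))
        assert tau == pytest.approx(0.005, rel=0.10)

    def test_white_noise_within_sample_interval(self):
        rng = np.random.default_rng(3)
        tr = make_trace(rng.standard_normal(200_000))
        assert analysis.autocorrelation_time(tr) <= 1e-3

    def test_harmonic_relation_recovers_friction(self):
        # γ̂ = k_BT·τ̂_c/⟨Δz²⟩ against the generator's γ
        m = synth.TraceModel(
            mean=0.0, variance=120.0, corr_time=0.02,
            acquisition_rate=1000.0, duration=1000.0,
        )
        tr = synth.generate_ou_trace(m, seed=13)
        et = make_trace(tr.z)
        tau = analysis.autocorrelation_time(et)
        gamma_hat = m.kT * tau / tr.z.var(ddof=1)
        assert gamma_hat == pytest.approx(m.friction, rel=0.15)

    def test_nondecaying_flagged(self):
        t = np.arange(50_000) / 1000.0
        tr = make_trace(np.sin(2 * np.pi * t / 200.0))  # period ≫ trace/4
        with pytest.raises(ValueError):
            analysis.autocorrelation_time(tr)


def theory_curve(force=0.5, n_bp=7900, n=30, frac=0.9):
    mol = MoleculeSpec(n_bp)
    (ds,) = synth.generate_rotation_dataset(
        [force], molecule=mol, params=P, rel_noise=0.0, n_sigma=n,
        sigma_max_frac=frac, seed=0,
    )
    return (
        RotationCurve(
            sigma=ds.sigma, z_mean=ds.z_mean, z_var=ds.z_var, force=force,
            contour_length=ds.contour_length, lk0=mol.lk0,
        ),
        ds,
        mol,
    )


class TestRotationFit:
    def test_noiseless_slope_matches_gamma(self):
        curve, ds, mol = theory_curve()
        fit = analysis.fit_rotation_curve(curve)
        coex = theory.solve_coexistence(0.5, P)
        # postbuckling: z = Γ·L·(σp − σ), slope per turn = Γ·L/Lk0
        assert fit.slope == pytest.approx(
            -coex.gamma * ds.contour_length, rel=1e-6
        )
        assert abs(fit.slope) / mol.lk0 == pytest.approx(
            coex.gamma * ds.contour_length / mol.lk0, rel=1e-6
        )

    def test_pure_quadratic_curvature_exact(self):
        sig = np.linspace(0, 0.05, 20)
        y = 3.0 - 250.0 * sig**2
        # append a linear tail so both regimes exist
        sig2 = np.linspace(0.052, 0.09, 10)
        y2 = y[-1] + (sig2 - sig[-1]) * (-2 * 250.0 * sig[-1])
        curve = RotationCurve(
            sigma=np.r_[sig, sig2], z_mean=np.r_[y, y2], z_var=np.r_[y, y2],
            force=1.0, contour_length=1000.0,
        )
        fit = analysis.fit_rotation_curve(curve)
        assert fit.curvature == pytest.approx(-250.0, rel=1e-6)

    def test_buckling_recovery_under_noise(self):
        _, ds, mol = theory_curve(n=40)
        errs = []
        for seed in range(100):
            rng = np.random.default_rng(1000 + seed)
            z = ds.z_true + rng.standard_normal(ds.sigma.size) * 0.02 * np.max(
                np.abs(ds.z_true)
            )
            curve = RotationCurve(
                sigma=ds.sigma, z_mean=z, z_var=ds.var_true, force=0.5,
                contour_length=ds.contour_length, lk0=mol.lk0,
            )
            fit = analysis.fit_rotation_curve(curve)
            errs.append(abs(fit.sigma_buckling - ds.sigma_s) / ds.sigma_s)
        assert float(np.mean(errs)) < 0.05


class TestCalibration:
    def test_noiseless_sigma_p_and_kappa_match_theory(self):
        curve, ds, _ = theory_curve()
        calib = analysis.calibrate(curve, sigma_min=ds.sigma_s + 0.004)
        assert calib.sigma_p == pytest.approx(ds.sigma_p, rel=1e-4)
        assert calib.kappa == pytest.approx(ds.kappa, rel=1e-3)

    def test_kappa_equals_variance_limit(self):
        # Eq.-7-style definition: κ is ⟨Δz²⟩/L at σ → σ_p
        curve, ds, _ = theory_curve()
        calib = analysis.calibrate(curve, sigma_min=ds.sigma_s + 0.004)
        lim = theory.extension_variance(ds.sigma_p, 0.5, P)
        assert calib.kappa == pytest.approx(lim, rel=1e-3)

    def test_unreliable_extrapolation_flagged(self):
        curve, ds, _ = theory_curve(frac=0.45)
        with pytest.warns(UserWarning, match="unreliable"):
            calib = analysis.calibrate(curve, sigma_min=ds.sigma_s + 0.002)
        assert not calib.extrapolation_reliable


def fake_calib(kappa=2.0, kappa_se=0.0):
    return FluctuationCalibration(
        sigma_p=0.08, sigma_p_se=0.0, kappa=kappa, kappa_se=kappa_se,
        slope_per_turn=50.0, force=0.5, contour_length=2686.0,
        sigma_fit_min=0.03, sigma_fit_max=0.06, extrapolation_reliable=True,
    )


class TestDomainSize:
    def test_no_drop_gives_zero(self):
        res = analysis.infer_domain_size(300.0, 300.0, fake_calib())
        assert res.delta_L == 0.0
        assert not res.bridging_detected

    def test_forward_construction_inverts_exactly(self):
        calib = fake_calib(kappa=1.7)
        drop = calib.kappa * 254.0
        res = analysis.infer_domain_size(500.0, 500.0 - drop, calib)
        assert res.delta_L == pytest.approx(254.0, rel=1e-12)

    @given(
        kappa=st.floats(0.1, 10.0),
        dl=st.floats(0.0, 2000.0),
    )
    @settings(max_examples=100, deadline=None)
    def test_roundtrip_identity_property(self, kappa, dl):
        calib = fake_calib(kappa=kappa)
        var_before = kappa * dl + 100.0  # keep the after-variance positive
        res = analysis.infer_domain_size(
            var_before, var_before - kappa * dl, calib
        )
        assert res.delta_L == pytest.approx(dl, rel=1e-9, abs=1e-9)

    def test_negative_drop_diagnostic_not_exception(self):
        res = analysis.infer_domain_size(200.0, 250.0, fake_calib())
        assert res.delta_L == 0.0
        assert not res.bridging_detected


class TestMeanExtensionChange:
    def test_identical_traces_zero(self):
        rng = np.random.default_rng(5)
        z = rng.normal(700, 5, 20_000)
        tr = make_trace(z, force=0.5, sigma=0.04)
        dz, se = analysis.mean_extension_change(tr, tr)
        assert dz == 0.0

    def test_constructed_shift_recovered(self):
        rng = np.random.default_rng(6)
        z = rng.normal(700, 5, 50_000)
        t1 = make_trace(z, force=0.5, sigma=0.04)
        t2 = make_trace(z + 10.0, force=0.5, sigma=0.04)
        dz, se = analysis.mean_extension_change(t1, t2)
        assert dz == pytest.approx(10.0, abs=3 * se + 1e-9)

    def test_mismatched_conditions_rejected(self):
        z = np.zeros(20_000)
        t1 = make_trace(z, force=0.5, sigma=0.04)
        t2 = make_trace(z, force=1.0, sigma=0.04)
        with pytest.raises(ValueError):
            analysis.mean_extension_change(t1, t2)


class TestSegmentStates:
    def test_single_level_ou_single_state(self):
        m = synth.TraceModel(
            mean=700.0, variance=100.0, corr_time=0.01,
            acquisition_rate=100.0, duration=600.0,
        )
        tr = synth.generate_ou_trace(m, seed=21)
        model = analysis.segment_states(
            make_trace(tr.z, rate=100.0), filter_window_s=10.0
        )
        assert model.n_levels == 1

    def test_square_wave_occupancies(self):
        rate = 100.0
        rng = np.random.default_rng(8)
        half = int(60 * rate)
        z = np.concatenate(
            [np.full(half, 700.0), np.full(half, 652.0)] * 4
        ) + rng.normal(0, 3.0, 8 * half)
        model = analysis.segment_states(make_trace(z, rate=rate), 10.0)
        assert model.n_levels == 2
        assert np.all(np.abs(model.occupancy - 0.5) < 0.05)
        assert model.spacing == pytest.approx(48.0, abs=2.0)

    def test_three_level_switching_recovery(self):
        base = synth.TraceModel(
            mean=800.0, variance=150.0, corr_time=0.01,
            acquisition_rate=200.0, duration=3000.0,
        )
        sw = synth.SwitchingModel(
            level_spacing=48.0, rebinding_time=30.0, n_levels=3
        )
        tr = synth.generate_switching_trace(sw, base, seed=31)
        model = analysis.segment_states(make_trace(tr.z, rate=200.0), 10.0)
        assert model.n_levels >= 3
        assert model.spacing == pytest.approx(48.0, abs=2.0)
        # ≥95% of samples assigned to the ground-truth level
        truth = tr.state_path - tr.state_path.min()
        truth_z = 800.0 - 48.0 * tr.state_levels[tr.state_path]
        got_z = model.level_z[model.assignments]
        match = np.abs(got_z - truth_z) < 24.0
        assert match.mean() >= 0.95


class TestPlectonemeStiffness:
    def test_forward_constructed_gaussian_gives_p20(self):
        # occupancies from a Gaussian of variance ΔL/(4π²·20) with ΔL=254 nm
        dl = 254.0
        var = dl / (4 * math.pi**2 * 20.0)
        k = np.arange(-2, 3)
        occ = np.exp(-(k**2) / (2 * var))
        occ /= occ.sum()
        model = analysis.StateModel(
            level_index=k, level_z=800 - 48.0 * k, occupancy=occ,
            spacing=48.0, spacing_se=0.5,
            assignments=np.zeros(10, dtype=np.int64),
            filter_window_s=10.0, acquisition_rate=1000.0,
        )
        P_est, P_se = analysis.plectoneme_stiffness(model, dl)
        assert P_est == pytest.approx(20.0, rel=1e-3)

    def test_doubling_loop_doubles_p(self):
        dl = 254.0
        var = dl / (4 * math.pi**2 * 20.0)
        k = np.arange(-2, 3)
        occ = np.exp(-(k**2) / (2 * var))
        occ /= occ.sum()
        model = analysis.StateModel(
            level_index=k, level_z=800 - 48.0 * k, occupancy=occ,
            spacing=48.0, spacing_se=0.5,
            assignments=np.zeros(10, dtype=np.int64),
            filter_window_s=10.0, acquisition_rate=1000.0,
        )
        p1, _ = analysis.plectoneme_stiffness(model, dl)
        p2, _ = analysis.plectoneme_stiffness(model, 2 * dl)
        assert p2 == pytest.approx(2 * p1, rel=1e-12)

    def test_too_few_levels_rejected(self):
        model = analysis.StateModel(
            level_index=np.array([0, 1]), level_z=np.array([800.0, 752.0]),
            occupancy=np.array([0.6, 0.4]), spacing=48.0, spacing_se=0.5,
            assignments=np.zeros(10, dtype=np.int64),
            filter_window_s=10.0, acquisition_rate=1000.0,
        )
        with pytest.raises(ValueError):
            analysis.plectoneme_stiffness(model, 254.0)


class TestDwellTimes:
    @staticmethod
    def synthetic_model(taus, occupancies, rate=10.0, n_events=400, seed=5):
        rng = np.random.default_rng(seed)
        levels = np.arange(len(taus))
        seq = []
        states = []
        s = 0
        for _ in range(n_events):
            nxt = rng.choice(len(taus), p=occupancies)
            if nxt == s:
                continue
            s = nxt
            dur = rng.exponential(taus[s])
            seq.append(max(1, int(round(dur * rate))))
            states.append(s)
        assign = np.concatenate(
            [np.full(n, st, dtype=np.int64) for n, st in zip(seq, states)]
        )
        return analysis.StateModel(
            level_index=levels, level_z=800 - 48.0 * levels,
            occupancy=np.asarray(occupancies, dtype=float),
            spacing=48.0, spacing_se=0.5, assignments=assign,
            filter_window_s=0.1, acquisition_rate=rate,
        )

    def test_exponential_mle_is_arithmetic_mean(self):
        model = self.synthetic_model([30.0, 30.0], [0.5, 0.5])
        states, durations = analysis._dwells_from_assignments(
            model.assignments, model.acquisition_rate
        )
        res = analysis.dwell_time_analysis(model, min_events=20, top_states=2)
        for s in res.states:
            d = durations[states == (s.level_index)] - model.filter_window_s
            d = d[d >= 0]
            assert s.tau == pytest.approx(d.mean(), rel=1e-6)

    def test_symmetric_two_state_relation(self):
        # p = (0.5, 0.5) with observed τ_i = 20 s implies τ_p = 10 s
        model = self.synthetic_model([20.0, 20.0], [0.5, 0.5], n_events=800)
        res = analysis.dwell_time_analysis(model, min_events=20, top_states=2)
        assert res.tau_p == pytest.approx(10.0, rel=0.15)

    def test_too_few_events_warns_and_skips(self):
        # the rare third state has too few dwells and is skipped; the two
        # frequent states are still analyzed
        model = self.synthetic_model([5.0, 5.0, 500.0], [0.45, 0.45, 0.1],
                                     n_events=150)
        with pytest.warns(UserWarning):
            res = analysis.dwell_time_analysis(model, min_events=20)
        analyzed = {s.level_index for s in res.states}
        assert 2 not in analyzed
        assert len(analyzed) == 2


class TestPipelineRecovery:
    """End-to-end recovery on the loop-kinetics study conditions."""

    def test_spacing_recovered(self, kinetics_statemodel):
        assert kinetics_statemodel.n_levels >= 3
        assert kinetics_statemodel.spacing == pytest.approx(48.0, rel=0.05)

    def test_assignment_accuracy(self, kinetics_trace, kinetics_statemodel):
        tr = kinetics_trace["trace"]
        truth_z = 800.0 - 48.0 * tr.state_levels[tr.state_path]
        got_z = kinetics_statemodel.level_z[kinetics_statemodel.assignments]
        assert (np.abs(got_z - truth_z) < 24.0).mean() >= 0.95

    def test_stiffness_recovered(self, kinetics_statemodel, kinetics_trace):
        sw = kinetics_trace["switching"]
        P_est, P_se = analysis.plectoneme_stiffness(
            kinetics_statemodel, sw.loop_length
        )
        assert P_est == pytest.approx(sw.plectoneme_stiffness, rel=0.20)

    def test_occupancies_near_truth(self, kinetics_statemodel, kinetics_trace):
        sw = kinetics_trace["switching"]
        occ = kinetics_statemodel.occupancy
        # compare the three dominant states
        top = np.argsort(-occ)[:3]
        truth = np.sort(sw.occupancies)[::-1][:3]
        assert np.all(np.abs(np.sort(occ[top])[::-1] - truth) < 0.08)
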