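"""Both calibration routes, their error propagation and mutual consistency."""

import math

import numpy as np
import pytest

import lipidspring as ls
from lipidspring.calibration import gaussian_fit, detect_linear_range
from lipidspring.constants import KB

from conftest import LAC2_UNBIASED, LEX_PULLING, TEMPERATURE_K


def _gaussian_pool(rng, mu, sigma, n_replicas=8, n_frames=20_000):
    return [
        ls.ZSeries(np.arange(n_frames, dtype=float),
                   rng.normal(mu, sigma, n_frames), label=f"rep{i}")
        for i in range(n_replicas)
    ]


class TestGaussianFit:
    def test_recovers_known_gaussian(self, rng):
        fit = gaussian_fit(_gaussian_pool(rng, -0.31, 0.20))
        assert fit.mu == pytest.approx(-0.31, abs=3 * fit.mu_se)
        assert fit.sigma == pytest.approx(0.20, abs=3 * fit.sigma_se)

    def test_constant_series_rejected(self):
        s = ls.ZSeries(np.arange(2000.0), np.full(2000, -0.3))
        with pytest.raises(ValueError, match="zero variance"):
            gaussian_fit([s])

    def test_bimodal_input_flags_poor_fit(self, rng):
        z = np.concatenate([rng.normal(-0.5, 0.05, 10_000), rng.normal(0.5, 0.05, 10_000)])
        s = ls.ZSeries(np.arange(z.size, dtype=float), z)
        fit = gaussian_fit([s])
        assert any("non-Gaussian" in w for w in fit.warnings)


class TestBoltzmannRoute:
    def test_inverts_known_sigma(self, rng):
        # sigma = 0.211 nm at 303 K corresponds to k ~ 94 pN/nm
        pool = _gaussian_pool(rng, -0.31, 0.211)
        cal = ls.boltzmann_calibrate(pool, temperature=303.0)
        assert cal.k == pytest.approx(KB * 303.0 / 0.211**2, abs=3 * cal.k_se)
        assert cal.method == "boltzmann" and cal.n_replicas == 8

    def test_doubling_sigma_quarters_k(self, rng):
        k1 = ls.boltzmann_calibrate(_gaussian_pool(rng, 0.0, 0.1), 303.0).k
        k2 = ls.boltzmann_calibrate(_gaussian_pool(rng, 0.0, 0.2), 303.0).k
        assert k1 / k2 == pytest.approx(4.0, rel=0.05)

    def test_recovers_generator_ground_truth_lac2_like(self):
        pool = [
            ls.simulate_ou(
                ls.default_params(seed=300 + i, temperature=TEMPERATURE_K, **LAC2_UNBIASED),
                2000.0,
            )
            for i in range(8)
        ]
        cal = ls.boltzmann_calibrate(pool, temperature=TEMPERATURE_K)
        assert cal.k == pytest.approx(LAC2_UNBIASED["k"], abs=3 * cal.k_se)
        assert cal.z0 == pytest.approx(LAC2_UNBIASED["z0"], abs=3 * cal.z0_se)

    def test_invariant_under_frame_reordering(self, rng):
        pool = _gaussian_pool(rng, -0.3, 0.2, n_replicas=3)
        cal_a = ls.boltzmann_calibrate(pool, 303.0)
        shuffled = [
            ls.ZSeries(s.times, rng.permutation(s.z), label=s.label) for s in pool
        ]
        cal_b = ls.boltzmann_calibrate(shuffled, 303.0)
        assert cal_a.k == pytest.approx(cal_b.k, rel=1e-12)


class TestPullingRoute:
    def test_exact_linear_data_recovers_spring_exactly(self):
        # noiseless means z = z0 + F/k must be reproduced exactly
        entries = []
        for force in [0.0, 5.0, 10.0, 15.0, 20.0]:
            for rep in range(2):
                z = np.full(200, -0.34 + force / 86.0)
                entries.append((force, rep, ls.ZSeries(np.arange(200.0), z)))
        cal = ls.pulling_calibrate(ls.PullingDataset(entries))
        assert cal.k == pytest.approx(86.0, rel=1e-9)
        assert cal.z0 == pytest.approx(-0.34, abs=1e-12)

    def test_full_stochastic_recovery(self):
        params = ls.default_params(seed=77, temperature=TEMPERATURE_K, **LEX_PULLING)
        ds = ls.simulate_pulling_set(
            params, [0.0, 5.0, 10.0, 15.0, 20.0], replicas=5, duration=1000.0
        )
        cal = ls.pulling_calibrate(ds, linear_max_force=20.0)
        assert cal.method == "pulling" and cal.linear_max_force == 20.0
        assert cal.k == pytest.approx(LEX_PULLING["k"], abs=3 * cal.k_se)
        assert cal.z0 == pytest.approx(LEX_PULLING["z0"], abs=3 * cal.z0_se)

    def test_anharmonic_spring_needs_restricted_fit_range(self):
        # with quartic hardening, points beyond ~20 pN bend below the line:
        # including them inflates the apparent spring constant
        params = ls.default_params(seed=78, quartic_coeff=500.0, **LEX_PULLING)
        forces = [0.0] + [2.5 * i for i in range(1, 13)]
        ds = ls.simulate_pulling_set(params, forces, replicas=4, duration=500.0)
        cal_lin = ls.pulling_calibrate(ds, linear_max_force=20.0)
        cal_all = ls.pulling_calibrate(ds, linear_max_force=30.0)
        assert cal_all.k > cal_lin.k
        assert abs(cal_lin.k - LEX_PULLING["k"]) < abs(cal_all.k - LEX_PULLING["k"])

    def test_weighted_fit_matches_ols_for_equal_errors(self):
        rng = np.random.default_rng(5)
        forces = np.array([0.0, 5.0, 10.0, 15.0, 20.0])
        z = -0.3 + forces / 90.0 + rng.normal(0, 0.005, forces.size)
        from lipidspring.calibration import _weighted_linear_fit

        i_w, s_w, _, _ = _weighted_linear_fit(forces, z, np.full(forces.size, 0.01))
        coef = np.polyfit(forces, z, 1)
        assert s_w == pytest.approx(coef[0], rel=1e-9)
        assert i_w == pytest.approx(coef[1], rel=1e-9)

    def test_missing_force_free_reference_rejected(self):
        entries = [
            (f, r, ls.ZSeries(np.arange(200.0), np.random.default_rng(r).normal(0, 0.1, 200)))
            for f in (5.0, 10.0, 15.0)
            for r in range(2)
        ]
        with pytest.raises(ValueError, match="force-free"):
            ls.PullingDataset(entries)

    def test_single_replica_level_rejected(self):
        rng = np.random.default_rng(6)
        entries = [
            (f, r, ls.ZSeries(np.arange(200.0), rng.normal(f / 90.0, 0.1, 200)))
            for f in (0.0, 10.0, 20.0)
            for r in range(2)
        ]
        entries.append((30.0, 0, ls.ZSeries(np.arange(200.0), rng.normal(0.3, 0.1, 200))))
        with pytest.raises(ValueError, match="fewer than 2 replicas"):
            ls.pulling_calibrate(ls.PullingDataset(entries), linear_max_force=30.0)

    def test_non_restoring_slope_rejected(self):
        rng = np.random.default_rng(7)
        entries = [
            (f, r, ls.ZSeries(np.arange(200.0), rng.normal(-f / 90.0, 0.02, 200)))
            for f in (0.0, 10.0, 20.0)
            for r in range(3)
        ]
        with pytest.raises(ValueError, match="no restoring spring"):
            ls.pulling_calibrate(ls.PullingDataset(entries))

    def test_linear_range_detector_flags_hardening(self):
        params = ls.default_params(seed=79, quartic_coeff=800.0, **LEX_PULLING)
        forces = [0.0] + [2.5 * i for i in range(1, 13)]
        ds = ls.simulate_pulling_set(params, forces, replicas=4, duration=500.0)
        cal = ls.pulling_calibrate(ds, linear_max_force=30.0)
        assert detect_linear_range(cal.force_table) < 30.0


class TestForceLaw:
    def test_zero_at_reference_and_linearity(self, lex_boltzmann_cal):
        cal = lex_boltzmann_cal
        assert ls.spring_force(cal.z0, cal) == pytest.approx(0.0, abs=1e-12)
        d = 0.1
        f1 = ls.spring_force(cal.z0 + d, cal) - ls.spring_force(cal.z0, cal)
        f2 = ls.spring_force(cal.z0 + 2 * d, cal) - ls.spring_force(cal.z0, cal)
        assert f2 == pytest.approx(2 * f1, rel=1e-12)

    def test_external_force_magnitude_at_typical_bound_protrusion(self):
        cal = ls.SpringCalibration(k=94.0, k_se=4.0, z0=-0.31, z0_se=0.01,
                                   method="boltzmann", temperature=303.0)
        assert ls.external_force(cal.z0 + 0.25, cal) == pytest.approx(23.5)
        assert ls.spring_force(cal.z0 + 0.25, cal) == pytest.approx(-23.5)


class TestRouteConsistency:
    def test_comparison_arithmetic_on_reported_style_values(self):
        a = ls.SpringCalibration(k=94.0, k_se=4.0, z0=-0.31, z0_se=0.01,
                                 method="boltzmann", temperature=303.0)
        b = ls.SpringCalibration(k=86.0, k_se=5.0, z0=-0.34, z0_se=0.01,
                                 method="pulling", temperature=303.0, linear_max_force=20.0)
        rep = ls.compare_calibrations(a, b, n_se=2.0)
        assert rep.delta_k == pytest.approx(8.0)
        assert rep.combined_se_k == pytest.approx(math.hypot(4.0, 5.0))
        assert rep.consistent_k

    def test_identical_calibrations_are_consistent(self, lex_boltzmann_cal):
        rep = ls.compare_calibrations(lex_boltzmann_cal, lex_boltzmann_cal)
        assert rep.delta_k == 0.0 and rep.consistent_k and rep.consistent_z0

    def test_clearly_different_springs_flagged(self):
        a = ls.SpringCalibration(k=94.0, k_se=1.0, z0=-0.31, z0_se=0.01,
                                 method="boltzmann", temperature=303.0)
        b = ls.SpringCalibration(k=70.0, k_se=1.0, z0=-0.31, z0_se=0.01,
                                 method="boltzmann", temperature=303.0)
        assert not ls.compare_calibrations(a, b).consistent_k

    @pytest.mark.parametrize("k_true", [50.0, 94.0, 150.0])
    def test_route_equivalence_on_harmonic_systems(self, k_true):
        """Boltzmann inversion and constant-force pulling must agree with
        each other and with the generating spring within 3 combined SE."""
        z0_true = -0.32
        seed = int(k_true)
        pool = [
            ls.simulate_ou(ls.default_params(k=k_true, z0=z0_true, seed=seed + i), 2000.0)
            for i in range(6)
        ]
        cal_b = ls.boltzmann_calibrate(pool, temperature=303.0)
        ds = ls.simulate_pulling_set(
            ls.default_params(k=k_true, z0=z0_true, seed=seed + 1000),
            [0.0, 5.0, 10.0, 15.0, 20.0], replicas=5, duration=1000.0,
        )
        cal_p = ls.pulling_calibrate(ds, linear_max_force=20.0)
        assert cal_b.k == pytest.approx(k_true, abs=3 * cal_b.k_se)
        assert cal_p.k == pytest.approx(k_true, abs=3 * cal_p.k_se)
        rep = ls.compare_calibrations(cal_b, cal_p, n_se=3.0)
        assert rep.consistent_k and rep.consistent_z0

    def test_noise_scaling_of_k_se(self, rng):
        # doubling the spread of per-replica sigmas roughly doubles k_se
        def pool_with_jitter(scale):
            r = np.random.default_rng(99)
            return [
                ls.ZSeries(np.arange(5000.0),
                           r.normal(0.0, 0.2 * (1 + scale * (i - 2) / 10), 5000))
                for i in range(5)
            ]

        se1 = ls.boltzmann_calibrate(pool_with_jitter(0.5), 303.0).k_se
        se2 = ls.boltzmann_calibrate(pool_with_jitter(1.0), 303.0).k_se
        assert se2 / se1 == pytest.approx(2.0, rel=0.3)
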