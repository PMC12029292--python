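"""Transport: sampling distributions, conservation, geometry, multiplicity."""

import numpy as np
import pytest
from scipy import integrate, stats

from phantomwaxs.detector_image import DetectorGeometry
from phantomwaxs.materials import Material, default_adipose
from phantomwaxs.reduction import pixel_to_q
from phantomwaxs.transport import (
    ABSORBED,
    ESCAPED,
    EventRecord,
    PhantomGeometry,
    RayleighSampler,
    SimulationConfig,
    classify_detected_events,
    compton_energy,
    propagate_to_plane,
    q_from_angle,
    rotate_directions,
    run_simulation,
    sample_compton,
    sample_free_path,
    sample_rayleigh,
    select_interaction,
    single_scatter_share,
    trace_photon,
    wavelength_nm,
)

LAM_22 = float(wavelength_nm(22.0))


def spike_material(q0=14.5, eps=0.3):
    """Material whose F² is a narrow spike at q0 (delta-like)."""
    q = np.sort(np.unique(np.concatenate([
        np.linspace(0, 250, 501), [q0 - eps, q0, q0 + eps]
    ])))
    f = np.where(np.abs(q - q0) < eps, 1.0, 0.0)
    f[np.argmin(np.abs(q - q0))] = 1.0
    return Material(
        name="spike", density=1.0, energy_keV=np.array([1.0, 30.0]),
        mu_photo_table=np.array([0.1, 0.1]), mu_rayleigh_table=np.array([0.3, 0.3]),
        mu_compton_table=np.array([0.1, 0.1]), ff_q=q, ff_sq=f,
    )


class TestFreePath:
    def test_mean(self, rng):
        s = sample_free_path(0.5, rng, size=100_000)
        se = 2.0 / np.sqrt(s.size)
        assert abs(s.mean() - 2.0) < 3 * se

    def test_tail_fraction_at_breast_mu(self, rng):
        """P(path > 10 cm) at μ = 0.16 is exp(−1.6) ≈ 0.2019."""
        s = sample_free_path(0.16, rng, size=100_000)
        p = np.mean(s > 10.0)
        se = np.sqrt(0.2019 * (1 - 0.2019) / s.size)
        assert abs(p - np.exp(-1.6)) < 3 * se

    def test_zero_mu_rejected(self, rng):
        with pytest.raises(ValueError):
            sample_free_path(0.0, rng)


class TestSelectInteraction:
    def test_photoelectric_fraction(self, adipose, rng):
        kinds = select_interaction(adipose, 22.0, rng, size=100_000)
        p = np.mean(kinds == "photoelectric")
        expected = 0.16 / 0.51  # 0.3137
        se = np.sqrt(expected * (1 - expected) / kinds.size)
        assert abs(p - expected) < 3 * se

    def test_pure_photoelectric(self, rng):
        mat = default_adipose(mu_photo=1.0, mu_rayleigh=0.0, mu_compton=0.0)
        kinds = select_interaction(mat, 22.0, rng, size=1000)
        assert np.all(kinds == "photoelectric")

    def test_chi_square_against_exact_ratios(self, adipose, rng):
        kinds = select_interaction(adipose, 22.0, rng, size=100_000)
        obs = [np.sum(kinds == k) for k in ("photoelectric", "rayleigh", "compton")]
        exp = np.array([0.16, 0.25, 0.10]) / 0.51 * 100_000
        _, p = stats.chisquare(obs, exp)
        assert p > 0.001

    def test_all_zero_mu_rejected(self, rng):
        mat = default_adipose(mu_photo=0.0, mu_rayleigh=0.0, mu_compton=0.0)
        with pytest.raises(ValueError):
            select_interaction(mat, 22.0, rng)


class TestRayleighSampling:
    def test_ks_against_target_density(self, adipose, rng):
        """Sampled θ distribution matches the F²-weighted Thomson density."""
        sampler = RayleighSampler(adipose, 22.0)
        theta = sampler.sample(rng, 1_000_000)

        def target_cdf(t):
            # independent quadrature of the (unnormalised) angular density
            f = lambda x: (np.sin(x) * 0.5 * (1 + np.cos(x) ** 2)
                           * adipose.form_factor_sq(q_from_angle(x, LAM_22)))
            total = integrate.quad(f, 0, np.pi, limit=200)[0]
            return np.array([integrate.quad(f, 0, ti, limit=200)[0] / total for ti in t])

        grid = np.linspace(0.001, np.pi - 0.001, 400)
        cdf_emp = np.searchsorted(np.sort(theta), grid) / theta.size
        ks = np.max(np.abs(cdf_emp - target_cdf(grid)))
        assert ks < 0.005

    def test_spike_form_factor_mode(self, rng):
        mat = spike_material(q0=14.5)
        theta, _ = sample_rayleigh(mat, 22.0, rng, size=50_000)
        q = q_from_angle(theta, LAM_22)
        hist, edges = np.histogram(q, bins=np.arange(0, 30, 0.5))
        mode = edges[np.argmax(hist)]
        assert abs(mode + 0.25 - 14.5) <= 0.5  # within one bin

    def test_uniform_azimuth(self, adipose, rng):
        _, phi = sample_rayleigh(adipose, 22.0, rng, size=100_000)
        se = (2 * np.pi / np.sqrt(12)) / np.sqrt(phi.size)
        assert abs(phi.mean() - np.pi) < 3 * se

    def test_degenerate_form_factor_rejected(self):
        mat = spike_material()
        mat.ff_sq = np.zeros_like(mat.ff_sq)
        with pytest.raises(ValueError):
            RayleighSampler(mat, 22.0)


class TestComptonSampling:
    def test_forward_scatter_keeps_energy(self):
        assert compton_energy(22.0, 0.0) == pytest.approx(22.0)

    def test_backscatter_closed_form(self):
        """E′(180°) = 22/(1 + 44/511) ≈ 20.26 keV."""
        expected = 22.0 / (1.0 + 2 * 22.0 / 510.99895)
        assert compton_energy(22.0, np.pi) == pytest.approx(expected, rel=1e-6)
        assert expected == pytest.approx(20.26, abs=0.01)

    def test_energy_never_increases(self, rng):
        _, _, Ep = sample_compton(22.0, rng, size=10_000)
        assert np.all(Ep <= 22.0 + 1e-12)

    def test_ks_against_klein_nishina(self, rng):
        theta, _, _ = sample_compton(22.0, rng, size=1_000_000)
        c = np.cos(theta)
        kappa = 22.0 / 510.99895

        def kn(x):
            r = 1.0 / (1.0 + kappa * (1.0 - x))
            return r * r * (r + 1.0 / r - (1.0 - x * x))

        total = integrate.quad(kn, -1, 1)[0]
        grid = np.linspace(-0.999, 0.999, 400)
        cdf_target = np.array([integrate.quad(kn, -1, g)[0] / total for g in grid])
        cdf_emp = np.searchsorted(np.sort(c), grid) / c.size
        assert np.max(np.abs(cdf_emp - cdf_target)) < 0.01

    def test_invalid_energy(self, rng):
        with pytest.raises(ValueError):
            sample_compton(-1.0, rng)


class TestGeometryOracles:
    def test_direction_rotation_preserves_unit_norm_and_angle(self, rng):
        d = rng.normal(size=(500, 3))
        d /= np.linalg.norm(d, axis=1, keepdims=True)
        cos_t = rng.uniform(-1, 1, 500)
        phi = rng.uniform(0, 2 * np.pi, 500)
        out = rotate_directions(d, cos_t, phi)
        assert np.allclose(np.linalg.norm(out, axis=1), 1.0, atol=1e-9)
        assert np.allclose(np.sum(out * d, axis=1), cos_t, atol=1e-9)

    def test_midplane_scatter_lands_at_effective_radius(self):
        """A photon deflected by 2θ at the phantom mid-plane lands at
        (platform − t/2)·tan 2θ from the beam axis."""
        t, platform = 4.0, 72.0
        two_theta = 0.12
        pos = np.array([[0.0, 0.0, -t / 2]])
        d = np.array([[np.sin(two_theta), 0.0, -np.cos(two_theta)]])
        x, y, reaches = propagate_to_plane(pos, d, -platform)
        assert reaches[0]
        r = np.hypot(x[0], y[0])
        assert r == pytest.approx((platform - t / 2) * np.tan(two_theta), rel=1e-12)

    def test_free_streaming_limit(self):
        """Negligible attenuation: photons arrive unscattered at the beam spot."""
        mat = default_adipose(mu_photo=1e-9, mu_rayleigh=1e-12, mu_compton=1e-12)
        det = DetectorGeometry(beam_center_px=(384.0, 256.0))
        cfg = SimulationConfig(
            phantom=PhantomGeometry(thickness_cm=10.0, material=mat),
            detector=det, n_photons=2000, seed=7,
        )
        res = run_simulation(cfg)
        assert res.tally["detected"] == 2000
        assert np.all(res.events.n_rayleigh + res.events.n_compton == 0)
        assert np.all(np.hypot(res.events.x_mm, res.events.y_mm) < 0.11)


class TestBeerLambertLimit:
    def test_detected_fraction_matches_attenuation(self):
        """Scattering off, μ_photo = 0.16, 10 cm → exp(−1.6) ≈ 0.2019."""
        mat = default_adipose(mu_rayleigh=0.0, mu_compton=0.0)
        det = DetectorGeometry(beam_center_px=(384.0, 256.0))  # beam fully on-array
        cfg = SimulationConfig(
            phantom=PhantomGeometry(thickness_cm=10.0, material=mat),
            detector=det, n_photons=100_000, seed=8,
        )
        res = run_simulation(cfg)
        p = res.tally["detected"] / cfg.n_photons
        expected = np.exp(-1.6)
        se = np.sqrt(expected * (1 - expected) / cfg.n_photons)
        assert abs(p - expected) < 3 * se


class TestRunSimulation:
    def test_determinism(self):
        cfg = SimulationConfig(phantom=PhantomGeometry(thickness_cm=4.0),
                               n_photons=50_000, seed=5)
        a = run_simulation(cfg)
        b = run_simulation(cfg)
        assert a.tally == b.tally
        assert a.events.equals(b.events)

    def test_tally_conservation(self, mc_thickness_series):
        for t, res in mc_thickness_series.items():
            assert sum(res.tally.values()) == res.config.n_photons

    def test_energy_bounded_and_rayleigh_elastic(self, mc_4cm):
        ev = mc_4cm.events
        assert np.all(ev.energy_keV <= 22.0 + 1e-9)
        pure_rayleigh = ev[ev.n_compton == 0]
        assert np.allclose(pure_rayleigh.energy_keV, 22.0)

    def test_single_scatter_fraction_decreases_with_thickness(self, mc_thickness_series):
        shares = [single_scatter_share(mc_thickness_series[t].events)
                  for t in sorted(mc_thickness_series)]
        assert all(a > b for a, b in zip(shares, shares[1:]))

    def test_mean_q_estimator_stability(self):
        """Mean detected q of single-Rayleigh photons shifts < 2% on doubling n."""
        means = []
        for n, seed in ((400_000, 61), (800_000, 62)):
            cfg = SimulationConfig(phantom=PhantomGeometry(thickness_cm=4.0),
                                   n_photons=n, seed=seed)
            res = run_simulation(cfg)
            ev = res.events
            sel = (ev.n_rayleigh == 1) & (ev.n_compton == 0)
            r = np.hypot(ev.x_mm[sel], ev.y_mm[sel])
            D_eff = 10.0 * cfg.effective_distance_cm
            means.append(np.mean(pixel_to_q(r.values, D_eff, LAM_22)))
        assert abs(means[1] - means[0]) / means[0] < 0.02

    def test_invalid_config(self):
        with pytest.raises(ValueError):
            SimulationConfig(phantom=PhantomGeometry(thickness_cm=4.0), n_photons=0)
        with pytest.raises(ValueError):
            PhantomGeometry(thickness_cm=-1.0)


class TestTracePhoton:
    def test_returns_record_or_fate(self, adipose, detector, rng):
        fates = [trace_photon(PhantomGeometry(thickness_cm=4.0), detector, rng)
                 for _ in range(200)]
        kinds = {type(f) if isinstance(f, EventRecord) else f for f in fates}
        assert kinds <= {EventRecord, ABSORBED, ESCAPED}
        assert any(isinstance(f, EventRecord) for f in fates)


class TestClassification:
    def test_multiplicity_assignment(self):
        ev = {"n_rayleigh": [1, 1, 0], "n_compton": [0, 1, 0]}
        table = classify_detected_events(ev)
        assert table.loc["1", "rayleigh_only"] == 1
        assert table.loc["2", "mixed"] == 1
        assert table.loc["0", "unscattered"] == 1
        assert table.values.sum() == 3

    def test_empty_events(self):
        table = classify_detected_events({"n_rayleigh": [], "n_compton": []})
        assert table.values.sum() == 0

    def test_share_requires_scattered_events(self):
        with pytest.raises(ValueError):
            single_scatter_share({"n_rayleigh": [0], "n_compton": [0]})


class TestThinSampleAnalyticOracle:
    def test_single_scatter_spectrum_matches_analytic_integral(self, adipose):
        """2 mm slab: the single-Rayleigh q spectrum matches the first-order
        analytic integral (form-factor-weighted Thomson density × azimuthal
        detector coverage) within 5% per bin over q ∈ [10, 18]."""
        det = DetectorGeometry()
        thickness = 0.2
        cfg = SimulationConfig(phantom=PhantomGeometry(thickness_cm=thickness),
                               detector=det, n_photons=10_000_000, seed=77)
        res = run_simulation(cfg)
        ev = res.events
        sel = (ev.n_rayleigh == 1) & (ev.n_compton == 0)
        D_eff_mm = 10.0 * cfg.effective_distance_cm
        q_obs = pixel_to_q(np.hypot(ev.x_mm[sel], ev.y_mm[sel]).values, D_eff_mm, LAM_22)

        edges = np.arange(10.0, 18.0 + 1e-9, 1.0)
        obs, _ = np.histogram(q_obs, bins=edges)

        # analytic per-bin weight: ∫ p(θ) dθ over the θ-interval of the bin,
        # times the azimuthal fraction of the ring on the sensitive area
        def density(theta):
            return (np.sin(theta) * 0.5 * (1 + np.cos(theta) ** 2)
                    * adipose.form_factor_sq(q_from_angle(theta, LAM_22)))

        def azimuthal_fraction(r_mm):
            cf, cs = det.beam_center_px
            x_lo, x_hi = -cf * det.pitch_mm, (det.n_fast - cf) * det.pitch_mm
            y_lo, y_hi = -cs * det.pitch_mm, (det.n_slow - cs) * det.pitch_mm
            phi = np.linspace(0, 2 * np.pi, 20_000, endpoint=False)
            x, y = r_mm * np.cos(phi), r_mm * np.sin(phi)
            return np.mean((x >= x_lo) & (x < x_hi) & (y >= y_lo) & (y < y_hi))

        expected = []
        for qa, qb in zip(edges[:-1], edges[1:]):
            ta = 2 * np.arcsin(qa * LAM_22 / (4 * np.pi))
            tb = 2 * np.arcsin(qb * LAM_22 / (4 * np.pi))
            # coverage varies steeply where rings leave the array: integrate
            # density × coverage over the bin rather than using the midpoint
            tg = np.linspace(ta, tb, 80)
            cover = np.array([azimuthal_fraction(D_eff_mm * np.tan(t_)) for t_ in tg])
            expected.append(np.trapezoid(density(tg) * cover, tg))
        expected = np.array(expected)

        obs_n = obs / obs.sum()
        exp_n = expected / expected.sum()
        has_support = exp_n > 1e-4
        assert np.all(obs_n[~has_support] == 0)
        assert np.all(np.abs(obs_n[has_support] - exp_n[has_support])
                      / exp_n[has_support] < 0.05)
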