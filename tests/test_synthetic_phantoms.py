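"""Tests for the phantom generator and the PGSE dataset simulator."""

import numpy as np
import pytest

import poremri as pm
from poremri.synthetic_phantoms import DEFAULT_RHO2, PHANTOM_PRESETS


class TestPhantomSpec:
    def test_presets_are_valid(self):
        for name in PHANTOM_PRESETS:
            spec = pm.phantom_preset(name)
            assert spec.label == name
            assert name in DEFAULT_RHO2

    def test_bad_mixture_weights_rejected(self):
        with pytest.raises(ValueError):
            pm.PhantomSpec(
                components=((0.5, 0.0, 0.3), (0.3, 1.0, 0.3)),
                n_fibers=10, max_radius=10.0,
            )

    def test_non_unit_orientation_rejected(self):
        with pytest.raises(ValueError):
            pm.PhantomSpec(
                components=((1.0, 0.0, 0.3),),
                n_fibers=10, max_radius=10.0,
                orientations=(((0.0, 0.0, 2.0), 1.0),),
            )

    def test_unknown_preset_rejected(self):
        with pytest.raises(KeyError):
            pm.phantom_preset("phantom99")


class TestSampleRadii:
    def test_same_seed_reproduces(self):
        spec = pm.phantom_preset("phantom1", n_fibers=200)
        s1 = pm.sample_radii(spec, seed=42)
        s2 = pm.sample_radii(spec, seed=42)
        np.testing.assert_array_equal(s1.radii, s2.radii)

    def test_truncation_support(self):
        spec = pm.phantom_preset("phantom1", n_fibers=5000)
        s = pm.sample_radii(spec, seed=0)
        assert np.all(s.radii > 0)
        assert np.all(s.radii <= spec.max_radius)

    @pytest.mark.parametrize(
        "name,target", [("phantom1", 1.07), ("phantom3", 0.70),
                        ("phantom4", 1.18), ("phantom5", 1.21)]
    )
    def test_preset_means_match_sem_measurements(self, name, target):
        s = pm.sample_radii(pm.phantom_preset(name), seed=13)
        assert abs(s.radii.mean() - target) / target < 0.02


class TestAddRician:
    def test_zero_sigma_identity(self):
        sig = np.linspace(0.0, 1.0, 10)
        np.testing.assert_array_equal(pm.add_rician(sig, 0.0, seed=0), sig)

    def test_determinism(self):
        sig = np.full(100, 0.5)
        a = pm.add_rician(sig, 0.1, seed=5)
        b = pm.add_rician(sig, 0.1, seed=5)
        np.testing.assert_array_equal(a, b)

    def test_second_moment_identity(self):
        # E[|S + n1 + i n2|^2] = S^2 + 2 sigma^2
        S, sigma, n = 0.3, 0.1, 100_000
        noisy = pm.add_rician(np.full(n, S), sigma, seed=1)
        expected = S**2 + 2 * sigma**2
        assert np.mean(noisy**2) == pytest.approx(expected, rel=0.01)

    def test_negative_sigma_rejected(self):
        with pytest.raises(ValueError):
            pm.add_rician(np.ones(3), -0.1)


class TestUniformDirections:
    def test_unit_norm_and_determinism(self):
        d1 = pm.uniform_directions(48)
        d2 = pm.uniform_directions(48)
        np.testing.assert_array_equal(d1, d2)
        np.testing.assert_allclose(np.linalg.norm(d1, axis=1), 1.0, atol=1e-12)

    def test_antipodal_spread(self):
        d = pm.uniform_directions(48)
        dots = np.abs(d @ d.T)
        np.fill_diagonal(dots, 0.0)
        # no two directions (or their antipodes) closer than ~15 degrees
        assert dots.max() < np.cos(np.deg2rad(15.0))


class TestSimulateDwi:
    def test_b0_volumes_are_direction_independent(self):
        spec = pm.phantom_preset("phantom1", n_fibers=100)
        sample = pm.sample_radii(spec, seed=3)
        ds = pm.simulate_dwi(sample, spec, scheme=pm.phantom_scheme("t2"), snr=np.inf)
        b0 = ds.scheme["is_b0"].to_numpy()
        te = ds.scheme["TE_ms"].to_numpy()
        for TE in np.unique(te):
            vals = ds.noiseless[b0 & (te == TE)]
            assert np.ptp(vals) == 0.0

    def test_noiseless_spherical_mean_matches_unified_model(self, protocol, diff):
        spec = pm.phantom_preset("phantom1", n_fibers=800)
        sample = pm.sample_radii(spec, seed=8)
        relax = pm.RelaxationParams(3000.0, DEFAULT_RHO2["phantom1"])
        ds = pm.simulate_dwi(sample, spec, scheme=pm.phantom_scheme("both"), snr=np.inf)
        tab = ds.spherical_mean_table()
        for _, row in tab.iterrows():
            ref = pm.joint_signal(
                row["b_s_mm2"], row["TE_ms"], sample, relax, diff, protocol
            )
            assert abs(row["mean"] - ref) / ref < 0.01

    def test_crossing_and_parallel_agree(self):
        spec1 = pm.phantom_preset("phantom1", n_fibers=400)
        spec2 = pm.phantom_preset("phantom2", n_fibers=400)
        sample = pm.sample_radii(spec1, seed=21)
        scheme = pm.phantom_scheme("t2")
        t1 = pm.simulate_dwi(sample, spec1, scheme=scheme, snr=np.inf).spherical_mean_table()
        t2 = pm.simulate_dwi(sample, spec2, scheme=scheme, snr=np.inf).spherical_mean_table()
        np.testing.assert_allclose(t2["mean"], t1["mean"], rtol=0.01)

    def test_volume_weighting_quadruples_with_doubled_radius(self, protocol, diff):
        # two-fiber toy: the larger fiber's share of the b0 signal is r^2-weighted
        spec = pm.PhantomSpec(
            components=((1.0, 0.0, 0.3),), n_fibers=2, max_radius=10.0, label="toy"
        )
        relax = pm.RelaxationParams(3000.0, 0.0)  # no relaxation contrast
        sample = pm.RadiusSample(radii=np.array([1.0, 2.0]), label="toy")
        ds = pm.simulate_dwi(
            sample, spec, scheme=pm.phantom_scheme("t2"), relax=relax, snr=np.inf
        )
        # first volume is the TE=51 ms b0: only the bulk-T2 factor survives
        assert ds.noiseless[0] == pytest.approx(np.exp(-51.0 / 3000.0), rel=1e-12)
        np.testing.assert_allclose(sample.volume_weights, [0.2, 0.8], atol=1e-15)

    def test_snr_roundtrip_on_b0_stack(self):
        spec = pm.phantom_preset("phantom1", n_fibers=200)
        sample = pm.sample_radii(spec, seed=9)
        ds = pm.simulate_dwi(
            sample, spec, scheme=pm.phantom_scheme("dmri"), snr=34.0, seed=17,
            n_voxels=10_000,
        )
        stack = ds.b0_stack(TE=51.0)
        assert stack.shape == (10_000, 5)
        got = pm.estimate_snr(stack)
        assert abs(got - 34.0) / 34.0 < 0.05

    def test_noise_reproducible_given_seed(self):
        spec = pm.phantom_preset("phantom3", n_fibers=50)
        sample = pm.sample_radii(spec, seed=1)
        d1 = pm.simulate_dwi(sample, spec, scheme=pm.phantom_scheme("t2"), snr=34.0, seed=5)
        d2 = pm.simulate_dwi(sample, spec, scheme=pm.phantom_scheme("t2"), snr=34.0, seed=5)
        np.testing.assert_array_equal(d1.data, d2.data)

    def test_non_unit_scheme_directions_rejected(self):
        spec = pm.phantom_preset("phantom1", n_fibers=10)
        sample = pm.sample_radii(spec, seed=1)
        scheme = pm.phantom_scheme("t2")
        scheme.loc[scheme.index[1], ["gx", "gy", "gz"]] = [1.0, 1.0, 1.0]
        with pytest.raises(ValueError):
            pm.simulate_dwi(sample, spec, scheme=scheme, snr=np.inf)


class TestFullSyntheticLoop:
    def test_t2_branch_closes_through_calibration(self, te_grid):
        # simulator -> spherical means -> rho2 calibration -> T2 fit ->
        # radius inversion reproduces the radius fitted to the
        # volume-weighted synthetic series at the calibrated rho2 (the
        # near-perfect one-to-one line of the individually calibrated
        # comparison)
        spec = pm.phantom_preset("phantom1", n_fibers=1500)
        sample = pm.sample_radii(spec, seed=6)
        ds = pm.simulate_dwi(sample, spec, scheme=pm.phantom_scheme("t2"), snr=np.inf)
        tab = ds.spherical_mean_table().sort_values("TE_ms")
        series = pm.SphericalMeanSeries(
            "TE", tab["TE_ms"].to_numpy(), tab["mean"].to_numpy()
        )
        cal = pm.calibrate_rho2(series, sample)
        relax_cal = pm.RelaxationParams(3000.0, cal.rho2)
        t2fit = pm.fit_monoexp_t2(series)
        r_mri = pm.radius_from_t2(t2fit.T2i, relax_cal)
        ref = pm.fit_single_cylinder_relaxation(
            (te_grid, pm.synth_relaxation_series(sample, te_grid, relax_cal)),
            relax_cal,
        )
        assert r_mri == pytest.approx(ref.r_eff, rel=0.01)

    def test_diffusion_branch_closes_without_relaxation_contrast(
        self, protocol, diff, b_grid
    ):
        # with rho2 = 0 (uniform T2) the measured b-series is an undistorted
        # volume-weighted mixture; in the ideal powder-average limit the
        # pipeline reproduces the distribution-level diffusion effective
        # radius to 1%.  The finite 48-direction estimate of the powder
        # average carries a few-tenths-percent quadrature error which the
        # ill-conditioned radius fit amplifies; it stays within 10%.
        spec = pm.phantom_preset("phantom1", n_fibers=1500)
        sample = pm.sample_radii(spec, seed=6)
        relax0 = pm.RelaxationParams(3000.0, 0.0)
        ref = pm.fit_single_cylinder_diffusion(
            (b_grid, pm.synth_diffusion_series(sample, b_grid, protocol, diff)),
            protocol, diff,
        )
        # exact powder-average series (direction count -> infinity)
        ideal = np.array(
            [
                pm.joint_signal(b, 51.0, sample, relax0, diff, protocol)
                for b in b_grid
            ]
        )
        fit_ideal = pm.fit_diffusion_radius(
            pm.SphericalMeanSeries("b", b_grid, ideal), protocol, diff
        )
        assert fit_ideal.r_eff == pytest.approx(ref.r_eff, rel=0.01)

        ds = pm.simulate_dwi(
            sample, spec, scheme=pm.phantom_scheme("dmri"), relax=relax0, snr=np.inf
        )
        tab = ds.spherical_mean_table().sort_values("b_s_mm2")
        fit_48 = pm.fit_diffusion_radius(
            pm.SphericalMeanSeries(
                "b", tab["b_s_mm2"].to_numpy(), tab["mean"].to_numpy()
            ),
            protocol, diff,
        )
        assert fit_48.r_eff == pytest.approx(ref.r_eff, rel=0.10)

    def test_relaxation_neglect_inflates_diffusion_radius(self, protocol, diff, b_grid):
        # fitting the diffusion model to a TE=51 ms series simulated WITH
        # surface relaxation yields a larger radius than without: the
        # relaxation weighting inflates the right tail of the apparent
        # distribution
        spec = pm.phantom_preset("phantom1", n_fibers=1500)
        sample = pm.sample_radii(spec, seed=6)
        scheme = pm.phantom_scheme("dmri")
        relax_on = pm.RelaxationParams(3000.0, 3.5)
        relax_off = pm.RelaxationParams(3000.0, 0.0)
        r = {}
        for tag, relax in (("on", relax_on), ("off", relax_off)):
            ds = pm.simulate_dwi(sample, spec, scheme=scheme, relax=relax, snr=np.inf)
            tab = ds.spherical_mean_table().sort_values("b_s_mm2")
            series = pm.SphericalMeanSeries(
                "b", tab["b_s_mm2"].to_numpy(), tab["mean"].to_numpy()
            )
            r[tag] = pm.fit_diffusion_radius(series, protocol, diff).r_eff
        assert r["on"] > r["off"]
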