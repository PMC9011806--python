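"""Equal-mass tuning derivation, rolling horizons and speed responses."""

import json

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from dese.encoding import (FWHM_OVER_SIGMA, DensityModel, EfficientSpeedEncoder,
                           NoFlowDataError, RollingHorizon, SpeedDistribution,
                           TuningCurve, build_speed_distribution, derive_tuning,
                           speed_response, update_horizon)
from helpers import random_distribution


class _Frame:
    """Minimal flow-like object: a grid of magnitudes."""

    def __init__(self, mags):
        self._m = np.asarray(mags, float)

    def speed(self):
        return self._m


# ---------------------------------------------------------------------------
# distributions
# ---------------------------------------------------------------------------

class TestSpeedDistribution:
    def test_empty_input_rejected(self):
        with pytest.raises(NoFlowDataError, match="no flow data"):
            build_speed_distribution([])
        with pytest.raises(NoFlowDataError):
            SpeedDistribution.from_samples([])

    def test_constant_field_is_point_mass(self):
        d = build_speed_distribution([_Frame(np.full((8, 8), 2.0))])
        assert d.is_point_mass
        assert d.support == (2.0, 2.0)
        assert d.n_samples == 64

    def test_two_field_symmetry(self):
        d = build_speed_distribution(
            [_Frame(np.full((8, 8), 1.0)), _Frame(np.full((8, 8), 3.0))],
            bins=4)
        # equal grid sizes: half the mass in the bin holding 1.0, half at 3.0
        assert d.bin_mass.sum() == pytest.approx(1.0, abs=1e-12)
        idx1 = np.searchsorted(d.bin_edges, 1.0, side="right") - 1
        assert d.bin_mass[idx1] == pytest.approx(0.5)
        assert d.bin_mass[-1] == pytest.approx(0.5)

    def test_uniform_sampling_within_binomial_error(self, rng):
        n, bins = 100_000, 128
        d = SpeedDistribution.from_samples(rng.uniform(0, 50, n), bins=bins)
        p = 1.0 / bins
        se = np.sqrt(p * (1 - p) / n)
        # the top bin holds the max sample by construction; 3-sigma binomial
        assert np.all(np.abs(d.bin_mass - p) < 3 * se + 1e-12)

    def test_cdf_properties(self, rng):
        d = random_distribution(rng)
        s = np.linspace(*d.support, 300)
        c = d.cdf(s)
        assert np.all(np.diff(c) >= -1e-12)
        assert d.cdf(d.bin_edges[-1]) == pytest.approx(1.0, abs=1e-9)

    def test_density_model_integral_equals_n(self, rng):
        d = random_distribution(rng)
        m = DensityModel(7, d)
        widths = np.diff(d.bin_edges)
        centers = 0.5 * (d.bin_edges[:-1] + d.bin_edges[1:])
        assert np.sum(m.density(centers) * widths) == pytest.approx(7.0, rel=0.05)
        assert m.integral() == pytest.approx(7.0, abs=1e-6)

    def test_serialization_round_trip(self, rng):
        d = random_distribution(rng)
        d2 = SpeedDistribution.from_dict(json.loads(json.dumps(d.to_dict())))
        np.testing.assert_allclose(d2.bin_edges, d.bin_edges)
        np.testing.assert_allclose(d2.bin_mass, d.bin_mass)


# ---------------------------------------------------------------------------
# tuning derivation
# ---------------------------------------------------------------------------

class TestDeriveTuning:
    def test_uniform_closed_form(self, uniform_dist):
        t = derive_tuning(uniform_dist, 7)
        np.testing.assert_allclose(t.mu, 50.0 * np.arange(1, 8) / 7, rtol=1e-9)
        np.testing.assert_allclose(t.fwhm, 50.0 / 7, rtol=1e-9)
        np.testing.assert_allclose(t.sigma, 50.0 / 7 / FWHM_OVER_SIGMA, rtol=1e-9)

    def test_half_offset_placement(self, uniform_dist):
        t = derive_tuning(uniform_dist, 7, placement="half_offset")
        np.testing.assert_allclose(t.mu, 50.0 * (np.arange(1, 8) - 0.5) / 7,
                                   rtol=1e-9)

    def test_point_mass_collapses_to_degenerate(self):
        d = SpeedDistribution.from_samples(np.full(100, 5.0))
        t = derive_tuning(d, 7)
        assert t.degenerate
        np.testing.assert_allclose(t.mu, 5.0)
        assert all(c.degenerate for c in t.curves)

    def test_sigma_floor_stabilizes_collapse(self):
        d = SpeedDistribution.from_samples(np.full(100, 5.0))
        t = derive_tuning(d, 7, sigma_floor=0.05)
        np.testing.assert_allclose(t.sigma, 0.05)

    def test_equal_mass_and_reciprocity_on_random_histograms(self, rng):
        # acceptance-grade sweep: 200 random histograms
        for _ in range(200):
            d = random_distribution(rng, n_samples=2000)
            t = derive_tuning(d, 7)
            mass = np.diff(np.concatenate([[0.0], d.cdf(t.mu)]))
            np.testing.assert_allclose(mass, 1 / 7, atol=0.01)
            assert np.all(np.diff(t.mu) >= -1e-12)
            # sigma_n * d(mu_n) = 1/2.355
            np.testing.assert_allclose(t.sigma * 7 * d.pdf(t.mu),
                                       1 / FWHM_OVER_SIGMA, atol=1e-6)

    def test_quantile_matches_dense_grid_inversion(self, rng):
        d = random_distribution(rng, bins=64)
        lo, hi = d.support
        grid = np.linspace(lo, hi, 100_000)
        cdf = d.cdf(grid)
        step = grid[1] - grid[0]
        t = derive_tuning(d, 7)
        for n, mu in enumerate(t.mu, start=1):
            # brute force: first grid point whose CDF reaches n/7
            brute = grid[np.searchsorted(cdf, n / 7 - 1e-12)]
            assert abs(mu - brute) <= step + 1e-9

    def test_width_tracks_inverse_density(self):
        # two wide bins with masses 0.8/0.2: deep-interior curves differ in
        # width by exactly the mass ratio
        d = SpeedDistribution(np.array([0.0, 10.0, 20.0]),
                              np.array([0.8, 0.2]), n_samples=1000)
        t = derive_tuning(d, 7)
        assert t.curves[1].mu < 5.0 and t.curves[6].mu == pytest.approx(20.0)
        assert t.curves[6].fwhm / t.curves[1].fwhm == pytest.approx(4.0, rel=1e-9)

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(st.integers(0, 10_000), st.integers(2, 12))
    def test_equal_mass_property(self, seed, n_neurons):
        rng = np.random.default_rng(seed)
        d = random_distribution(rng, n_samples=3000)
        t = derive_tuning(d, n_neurons)
        mass = np.diff(np.concatenate([[0.0], d.cdf(t.mu)]))
        np.testing.assert_allclose(mass, 1 / n_neurons, atol=0.01)
        assert np.all(np.diff(t.mu) >= -1e-12)


# ---------------------------------------------------------------------------
# responses
# ---------------------------------------------------------------------------

class TestSpeedResponse:
    @pytest.fixture
    def curve(self):
        fwhm = 2.355
        return TuningCurve(1, mu=4.0, fwhm=fwhm, sigma=fwhm / FWHM_OVER_SIGMA)

    def test_peak_half_and_cutoff(self, curve):
        assert speed_response(curve.mu, curve) == pytest.approx(1.0)
        # half maximum at +-FWHM/2, to the precision of the 2.355 constant
        assert speed_response(curve.mu + curve.fwhm / 2, curve) == pytest.approx(0.5, abs=1e-4)
        assert speed_response(curve.mu - curve.fwhm / 2, curve) == pytest.approx(0.5, abs=1e-4)
        assert speed_response(curve.mu + 5 * curve.sigma, curve) == 0.0
        # sigma derived from FWHM=2.355 is exactly 1
        assert curve.sigma == pytest.approx(1.0)

    def test_negative_speed_rejected(self, curve):
        with pytest.raises(ValueError, match="non-negative"):
            speed_response(-0.1, curve)

    def test_set_response_matrix(self, uniform_dist):
        t = derive_tuning(uniform_dist, 7)
        r = t.response(t.mu)
        np.testing.assert_allclose(np.diag(r), 1.0)
        assert r.shape == (7, 7)
        assert np.all((r >= 0) & (r <= 1))


# ---------------------------------------------------------------------------
# rolling horizon
# ---------------------------------------------------------------------------

class TestRollingHorizon:
    def test_window_of_one_equals_single_frame(self):
        h = RollingHorizon(1, bins=16)
        f1 = _Frame(np.linspace(0.5, 4.0, 64).reshape(8, 8))
        f2 = _Frame(np.linspace(1.0, 9.0, 64).reshape(8, 8))
        h.update(f1)
        got = update_horizon(h, f2)
        ref = build_speed_distribution([f2], bins=16)
        np.testing.assert_allclose(got.bin_edges, ref.bin_edges)
        np.testing.assert_allclose(got.bin_mass, ref.bin_mass)

    def test_fifo_eviction_hand_enumerated(self):
        h = RollingHorizon(2, bins=4)
        h.update(_Frame(np.full((4, 4), 1.0)))
        d = h.update(_Frame(np.full((4, 4), 3.0)))
        # A(1) + B(3): half the mass at each speed
        assert d.cdf(2.0) == pytest.approx(0.5)
        d = h.update(_Frame(np.full((4, 4), 3.0)))
        # A evicted: point mass at 3
        assert d.is_point_mass and d.support == (3.0, 3.0)

    def test_stationary_stream_matches_static_tuning(self):
        frame = _Frame(np.abs(np.sin(np.arange(64))).reshape(8, 8) * 3 + 0.1)
        h = RollingHorizon(10, bins=32)
        for _ in range(12):
            d = h.update(frame)
        static = derive_tuning(build_speed_distribution([frame], bins=32), 7)
        dynamic = derive_tuning(d, 7)
        np.testing.assert_allclose(dynamic.mu, static.mu, atol=1e-9)
        np.testing.assert_allclose(dynamic.sigma, static.sigma, atol=1e-9)

    def test_buffer_bounded(self):
        h = RollingHorizon(3)
        for _ in range(10):
            h.update(_Frame(np.random.default_rng(0).uniform(0, 1, (4, 4))))
        assert len(h) == 3


# ---------------------------------------------------------------------------
# sklearn estimator surface
# ---------------------------------------------------------------------------

class TestEfficientSpeedEncoder:
    def test_fit_transform_shapes_and_peaks(self, rng):
        enc = EfficientSpeedEncoder(n_neurons=7, bins=64)
        X = rng.lognormal(0, 0.5, 5000)
        enc.fit(X)
        assert enc.mu_.shape == (7,)
        R = enc.transform(enc.mu_)
        np.testing.assert_allclose(np.diag(R), 1.0)

    def test_get_set_params_round_trip(self):
        enc = EfficientSpeedEncoder(n_neurons=5, placement="half_offset")
        params = enc.get_params()
        enc2 = EfficientSpeedEncoder().set_params(**params)
        assert enc2.n_neurons == 5 and enc2.placement == "half_offset"

    def test_fit_from_distribution_object(self, uniform_dist):
        enc = EfficientSpeedEncoder().fit(uniform_dist)
        np.testing.assert_allclose(enc.mu_, 50.0 * np.arange(1, 8) / 7, rtol=1e-9)

    def test_tuning_json_round_trip(self, tmp_path, uniform_dist):
        enc = EfficientSpeedEncoder().fit(uniform_dist)
        path = tmp_path / "tuning.json"
        enc.tuning_.to_json(path)
        from dese.encoding import TuningCurveSet
        back = TuningCurveSet.from_json(path)
        np.testing.assert_allclose(back.mu, enc.tuning_.mu)
        np.testing.assert_allclose(back.sigma, enc.tuning_.sigma)
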