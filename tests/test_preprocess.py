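"""Band-pass filter, delay embedding, local least squares, PSR denoiser,
and 2-s segmentation."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from sparnet import (
    LsqFitSpec,
    Recording,
    bandpass,
    embed,
    lsq_local_fit,
    psr_denoise,
    segment,
    select_delay_mi,
    select_dim_fnn,
)
from sparnet.preprocess import (
    DegenerateInputError,
    SeriesTooShortError,
    SingularDesignError,
    _lagged_mi,
)

FS = 250.0


def _rec(sig):
    sig = np.atleast_2d(sig)
    names = tuple(f"E{i + 1}" for i in range(sig.shape[0]))
    return Recording("s", "CONTROL", FS, names, sig)


# ---------------------------------------------------------------------------
# band-pass


class TestBandpass:
    def test_dc_removed(self):
        out = bandpass(_rec(np.ones(5000))).signal[0]
        assert np.abs(out).max() < 1e-6

    @pytest.mark.parametrize("f0, lo, hi", [(10.0, 0.99, 1.01), (50.0, 0.0, 0.15)])
    def test_tone_gain(self, f0, lo, hi):
        t = np.arange(int(60 * FS)) / FS
        x = np.sin(2 * np.pi * f0 * t)
        y = bandpass(_rec(x)).signal[0]
        sl = slice(int(FS), -int(FS))  # ignore 1-s edges
        ratio = np.sqrt(np.mean(y[sl] ** 2)) / np.sqrt(np.mean(x[sl] ** 2))
        assert lo <= ratio <= hi

    def test_linearity(self, rng):
        x = rng.normal(size=3000)
        y = rng.normal(size=3000)
        lhs = bandpass(_rec(2.0 * x - 3.0 * y)).signal[0]
        rhs = 2.0 * bandpass(_rec(x)).signal[0] - 3.0 * bandpass(_rec(y)).signal[0]
        np.testing.assert_allclose(lhs, rhs, atol=1e-9)

    def test_band_edges_must_respect_nyquist(self):
        with pytest.raises(ValueError, match="Nyquist"):
            bandpass(_rec(np.zeros(1000)), low_hz=1, high_hz=130)


# ---------------------------------------------------------------------------
# embedding-parameter selection


class TestDelayAndDimension:
    def test_sinusoid_delay_near_quarter_period(self):
        x = np.sin(2 * np.pi * np.arange(1, 3001) / 24)
        t = select_delay_mi(x, max_lag=20)
        assert 4 <= t <= 8
        # agrees with a brute-force first-local-minimum scan of the same MI
        mi = [_lagged_mi(x, lag, 12) for lag in range(1, 21)]
        brute = next(
            lag + 2
            for lag in range(len(mi) - 2)
            if mi[lag + 1] < mi[lag] and mi[lag + 1] <= mi[lag + 2]
        )
        assert t == brute

    def test_iid_noise_gives_small_delay(self):
        u = np.random.default_rng(0).uniform(size=5000)
        assert select_delay_mi(u, max_lag=20) <= 3

    def test_constant_series_rejected(self):
        with pytest.raises(DegenerateInputError):
            select_delay_mi(np.ones(1000), max_lag=10)

    def test_short_series_rejected(self):
        with pytest.raises(SeriesTooShortError):
            select_delay_mi(np.arange(50.0), max_lag=20)

    def test_fnn_sinusoid_saturates_low(self):
        x = np.sin(2 * np.pi * np.arange(1, 3001) / 24)
        assert select_dim_fnn(x, select_delay_mi(x, 20)) <= 3

    def test_fnn_noise_never_saturates(self):
        u = np.random.default_rng(1).uniform(size=2000)
        assert select_dim_fnn(u, t=1, max_dim=10) == 10

    def test_fnn_length_precondition(self):
        with pytest.raises(SeriesTooShortError):
            select_dim_fnn(np.arange(5.0), t=3)


# ---------------------------------------------------------------------------
# delay embedding


class TestEmbed:
    def test_example_matrix(self):
        e = embed(np.array([1.0, 2, 3, 4, 5, 6]), d=3, t=2)
        np.testing.assert_array_equal(e.vectors, [[1, 3, 5], [2, 4, 6]])

    def test_dimension_one_is_identity_column(self):
        x = np.arange(7.0)
        np.testing.assert_array_equal(embed(x, 1, 3).vectors, x[:, None])

    @given(
        n=st.integers(10, 60),
        d=st.integers(1, 4),
        t=st.integers(1, 5),
        seed=st.integers(0, 10_000),
    )
    def test_index_identity(self, n, d, t, seed):
        if n - (d - 1) * t < 1:
            return
        x = np.random.default_rng(seed).normal(size=n)
        v = embed(x, d, t).vectors
        for i in range(v.shape[0]):
            for k in range(d):
                assert v[i, k] == x[i + k * t]

    def test_aligned_coordinates_average_back_to_source(self, rng):
        x = rng.normal(size=100)
        v = embed(x, 3, 4).vectors
        recon_sum = np.zeros_like(x)
        count = np.zeros_like(x)
        for k in range(3):
            recon_sum[k * 4 : k * 4 + v.shape[0]] += v[:, k]
            count[k * 4 : k * 4 + v.shape[0]] += 1
        np.testing.assert_allclose(recon_sum / count, x, rtol=0, atol=1e-12)

    def test_too_short_raises(self):
        with pytest.raises(SeriesTooShortError):
            embed(np.arange(4.0), d=3, t=2)


# ---------------------------------------------------------------------------
# local least squares


class TestLsqFit:
    def test_collinear_points_exact(self):
        v, c = lsq_local_fit([1, 2, 3], [2, 4, 6], LsqFitSpec(basis_degree=1), x0=2)
        assert v == pytest.approx(4.0, abs=1e-12)
        np.testing.assert_allclose(c, [0.0, 2.0], atol=1e-12)

    def test_own_basis_reproduced_exactly(self):
        xs = np.linspace(-2, 2, 5)
        v, c = lsq_local_fit(xs, xs**2, LsqFitSpec(basis_degree=2), x0=0.7)
        residual = np.sum((np.polyval(c[::-1], xs) - xs**2) ** 2)
        assert residual < 1e-18
        assert v == pytest.approx(0.49, abs=1e-12)

    def test_matches_explicit_normal_equations(self, rng):
        xs = rng.uniform(-1, 1, size=20)
        ys = rng.normal(size=20)
        spec = LsqFitSpec(basis_degree=3)
        _, c = lsq_local_fit(xs, ys, spec)
        R = np.vander(xs, 4, increasing=True)
        oracle = np.linalg.inv(R.T @ R) @ R.T @ ys
        np.testing.assert_allclose(c, oracle, atol=1e-8)

    def test_duplicate_abscissae_singular(self):
        with pytest.raises(SingularDesignError):
            lsq_local_fit([1, 1, 1], [1, 2, 3], LsqFitSpec(basis_degree=2))


# ---------------------------------------------------------------------------
# PSR denoiser


class TestPsrDenoise:
    def test_polynomial_passes_through(self):
        i = np.arange(300.0)
        x = 0.5 + 0.3 * i - 0.002 * i**2
        np.testing.assert_allclose(psr_denoise(x, t=3), x, atol=1e-9)

    def test_constant_passes_through(self):
        x = np.ones(200)
        np.testing.assert_allclose(psr_denoise(x, t=2), x, rtol=0, atol=1e-12)

    def test_spike_rmse_strictly_reduced(self):
        clean = np.sin(2 * np.pi * 10 * np.arange(2000) / FS)
        noisy = clean.copy()
        noisy[1000] += 20.0
        den = psr_denoise(noisy, t=6)
        before = np.sqrt(np.mean((noisy - clean) ** 2))
        after = np.sqrt(np.mean((den - clean) ** 2))
        assert after < before

    def test_in_span_rmse_never_degrades(self, rng):
        # noiseless input inside the quadratic basis span: RMSE stays ~0
        i = np.arange(400.0)
        x = 1.0 - 0.05 * i + 3e-4 * i**2
        den = psr_denoise(x, t=5)
        assert np.sqrt(np.mean((den - x) ** 2)) <= 0.05 * max(np.sqrt(np.mean(x**2)), 1)

    def test_output_length_and_auto_delay(self, rng):
        x = np.cumsum(rng.normal(size=1500))
        assert len(psr_denoise(x)) == 1500


# ---------------------------------------------------------------------------
# segmentation


class TestSegment:
    def test_300s_recording_gives_148_windows(self):
        rec = _rec(np.zeros((1, 75000)))
        ep = segment(rec)
        assert ep.windows.shape == (148, 1, 500)

    def test_edge_windows_dropped(self, rng):
        rec = _rec(rng.normal(size=(2, 2500)))  # 10 s -> 5 windows -> 3 kept
        ep = segment(rec)
        assert ep.n_windows == 3

    def test_kept_windows_reproduce_source_span(self, rng):
        rec = _rec(rng.normal(size=(2, 2600)))  # trailing partial discarded
        ep = segment(rec)
        flat = ep.windows.transpose(1, 0, 2).reshape(2, -1)
        np.testing.assert_array_equal(flat, rec.signal[:, 500:2000])

    def test_too_short_raises(self):
        with pytest.raises(SeriesTooShortError):
            segment(_rec(np.zeros((1, 1250))))  # 5 s -> 2 complete windows
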