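"""Time-domain preprocessing: band-pass filtering, phase-space-reconstruction
denoising with local least-squares fitting, and fixed-window segmentation.

The denoiser embeds each channel in a 3-dimensional delay-coordinate phase
space (Takens embedding, lag chosen at the first minimum of lagged mutual
information), predicts every sample of each coordinate series from a
symmetric window of its neighbours by polynomial least squares (the fitted
point is excluded from its own fit, so isolated transients cannot defend
themselves), and averages the aligned coordinate estimates back into a
single series.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import signal as sps
from scipy.spatial import cKDTree

from .cohort import Recording

__all__ = [
    "PhaseSpaceEmbedding",
    "LsqFitSpec",
    "EpochSet",
    "bandpass",
    "select_delay_mi",
    "select_dim_fnn",
    "embed",
    "lsq_local_fit",
    "psr_denoise",
    "denoise_recording",
    "segment",
]


class DegenerateInputError(ValueError):
    """Raised for inputs on which an estimator is undefined (e.g. constant series)."""


class SeriesTooShortError(ValueError):
    """Raised when a series is too short for the requested embedding/segmentation."""


# ---------------------------------------------------------------------------
# Band-pass filtering


def _design_bandpass(low_hz: float, high_hz: float, order: int, fs: float):
    nyq = fs / 2.0
    if not (0.0 < low_hz < high_hz < nyq):
        raise ValueError(
            f"band edges must satisfy 0 < low ({low_hz}) < high ({high_hz}) "
            f"< Nyquist ({nyq})"
        )
    return sps.butter(order, [low_hz, high_hz], btype="bandpass", fs=fs, output="sos")


def bandpass(rec: Recording, low_hz: float = 1.0, high_hz: float = 40.0, order: int = 6) -> Recording:
    """Zero-phase Butterworth band-pass of every channel.

    The filter is applied forward-backward (``sosfiltfilt``) so epochs keep
    their phase; ``order`` is the low-pass prototype order (the band-pass
    magnitude falls off at 6·order dB/octave outside the band).
    """
    sos = _design_bandpass(low_hz, high_hz, order, rec.sampling_rate)
    filtered = sps.sosfiltfilt(sos, rec.signal, axis=-1)
    return replace(rec, signal=np.ascontiguousarray(filtered))


def bandpass_series(x: np.ndarray, fs: float, low_hz=1.0, high_hz=40.0, order=6) -> np.ndarray:
    sos = _design_bandpass(low_hz, high_hz, order, fs)
    return sps.sosfiltfilt(sos, np.asarray(x, dtype=float))


# ---------------------------------------------------------------------------
# Embedding-parameter selection


def _digitize_equal_width(x: np.ndarray, bins: int) -> np.ndarray:
    lo, hi = x.min(), x.max()
    idx = ((x - lo) * (bins / (hi - lo))).astype(np.int64)
    return np.clip(idx, 0, bins - 1)


def _mi_from_joint(joint: np.ndarray) -> float:
    p = joint / joint.sum()
    px = p.sum(axis=1, keepdims=True)
    py = p.sum(axis=0, keepdims=True)
    nz = p > 0
    return float(np.sum(p[nz] * np.log(p[nz] / (px @ py)[nz])))


def _lagged_mi(x: np.ndarray, lag: int, bins: int) -> float:
    """Mutual information (nats) between x_i and x_{i+lag}, equal-width histogram."""
    bi = _digitize_equal_width(np.asarray(x, dtype=float), bins)
    joint = np.bincount(
        bi[:-lag] * bins + bi[lag:], minlength=bins * bins
    ).reshape(bins, bins).astype(float)
    return _mi_from_joint(joint)


def select_delay_mi(x: np.ndarray, max_lag: int = 25, bins: int = 12) -> int:
    """Embedding delay at the first local minimum of lagged mutual information.

    Falls back to the first lag where MI drops below MI(1)/e, then to
    ``max_lag``, when no local minimum exists in ``[1, max_lag]``.
    """
    x = np.asarray(x, dtype=float)
    if max_lag < 2:
        raise ValueError("max_lag must be >= 2")
    if len(x) <= 4 * max_lag:
        raise SeriesTooShortError(
            f"series of length {len(x)} too short for max_lag={max_lag}"
        )
    if np.ptp(x) == 0:
        raise DegenerateInputError("mutual information undefined for a constant series")
    bi = _digitize_equal_width(x, bins)
    mi = np.empty(max_lag)
    for lag in range(1, max_lag + 1):
        joint = np.bincount(
            bi[:-lag] * bins + bi[lag:], minlength=bins * bins
        ).reshape(bins, bins).astype(float)
        mi[lag - 1] = _mi_from_joint(joint)
    for t in range(1, max_lag - 1):  # mi index t is lag t+1
        if mi[t] < mi[t - 1] and mi[t] <= mi[t + 1]:
            return t + 1
    below = np.nonzero(mi < mi[0] / np.e)[0]
    if below.size:
        return int(below[0]) + 1
    return max_lag


def _fnn_fraction(x: np.ndarray, d: int, t: int, rtol: float, atol: float) -> float:
    """Fraction of nearest neighbours in dimension d that are false in d+1."""
    n_vec = len(x) - d * t  # rows usable in both d and d+1
    if n_vec < 2:
        raise SeriesTooShortError("series too short for FNN test")
    emb = embed(x, d, t).vectors[:n_vec]
    tree = cKDTree(emb)
    dist, idx = tree.query(emb, k=2)
    dist, idx = dist[:, 1], idx[:, 1]
    extra = np.abs(x[np.arange(n_vec) + d * t] - x[idx + d * t])
    sd = x.std()
    with np.errstate(divide="ignore", invalid="ignore"):
        # coincident d-dim neighbours are judged on the added coordinate alone
        ratio = np.where(dist > 0, extra / dist, np.where(extra > 0, np.inf, 0.0))
    false = (ratio > rtol) | (extra > atol * sd)
    # a coordinate increase below numerical precision is never "false":
    # exactly periodic series produce near-duplicate vectors whose ratio
    # test is pure floating-point noise
    false &= extra > 1e-9 * sd
    return float(false.mean())


def select_dim_fnn(
    x: np.ndarray, t: int, max_dim: int = 10, rtol: float = 15.0, atol: float = 2.0,
    threshold: float = 0.05,
) -> int:
    """Smallest embedding dimension with false-nearest-neighbour fraction below threshold.

    Capped at ``max_dim``; provided as a diagnostic (the denoiser fixes d=3).
    """
    x = np.asarray(x, dtype=float)
    if len(x) < 2 * t + 2:
        raise SeriesTooShortError(
            f"series of length {len(x)} cannot be embedded at dimension 2 with t={t}"
        )
    for d in range(1, max_dim):
        if _fnn_fraction(x, d, t, rtol, atol) < threshold:
            return d
    return max_dim


# ---------------------------------------------------------------------------
# Delay embedding


@dataclass
class PhaseSpaceEmbedding:
    """Delay-coordinate matrix: row i is (x(i), x(i+t), ..., x(i+(d-1)t))."""

    source_length: int
    delay: int
    dimension: int
    vectors: np.ndarray


def embed(x: np.ndarray, d: int, t: int) -> PhaseSpaceEmbedding:
    """Takens delay embedding with dimension ``d`` and lag ``t``."""
    x = np.asarray(x, dtype=float)
    n = len(x)
    if d < 1 or t < 1:
        raise ValueError("d and t must be >= 1")
    rows = n - (d - 1) * t
    if rows < 1:
        raise SeriesTooShortError(
            f"cannot embed length-{n} series at d={d}, t={t} (needs {(d - 1) * t + 1})"
        )
    idx = np.arange(rows)[:, None] + t * np.arange(d)[None, :]
    return PhaseSpaceEmbedding(n, t, d, x[idx])


# ---------------------------------------------------------------------------
# Local least-squares fitting


@dataclass
class LsqFitSpec:
    """Polynomial least-squares window: degree of the monomial basis and the
    number of points taken on each side of the predicted sample."""

    basis_degree: int = 2
    half_window: int = 4

    @property
    def n_basis(self) -> int:
        return self.basis_degree + 1


class SingularDesignError(np.linalg.LinAlgError):
    """Raised when the design matrix is rank-deficient."""


def lsq_local_fit(xs, ys, spec: LsqFitSpec, x0: float = 0.0):
    """Fit a degree-``spec.basis_degree`` polynomial to (xs, ys) and evaluate at x0.

    Returns ``(fitted_value, coefficients)`` with coefficients in increasing
    power order.  Solved by a numerically stable least-squares routine, not an
    explicit normal-equation inverse.
    """
    xs = np.asarray(xs, dtype=float)
    ys = np.asarray(ys, dtype=float)
    m = spec.n_basis
    if len(xs) < m:
        raise ValueError(f"need at least {m} points for degree {spec.basis_degree}")
    R = np.vander(xs, m, increasing=True)
    coeffs, _, rank, _ = np.linalg.lstsq(R, ys, rcond=None)
    if rank < m:
        raise SingularDesignError(
            "design matrix is rank-deficient (duplicate abscissae?)"
        )
    fitted = float((np.vander(np.array([x0]), m, increasing=True) @ coeffs)[0])
    return fitted, coeffs


def _prediction_kernel(spec: LsqFitSpec) -> np.ndarray:
    """Weights w such that the LSQ prediction at offset 0 from neighbours at
    offsets (-hw..-1, 1..hw) equals w · y; the centre sample is excluded."""
    hw = spec.half_window
    offsets = np.concatenate([np.arange(-hw, 0), np.arange(1, hw + 1)]).astype(float)
    m = spec.n_basis
    if len(offsets) < m:
        raise ValueError("window too small for basis degree")
    R = np.vander(offsets, m, increasing=True)
    # prediction = e0^T (R^T R)^{-1} R^T y ; computed via a stable solve
    G = np.linalg.solve(R.T @ R, R.T)
    return G[0]  # row selecting the constant term == value at offset 0


def _smooth_series(y: np.ndarray, spec: LsqFitSpec) -> np.ndarray:
    """Pointwise LSQ prediction of every interior sample; edges pass through."""
    hw = spec.half_window
    n = len(y)
    out = y.copy()
    if n < 2 * hw + 1:
        return out
    w = _prediction_kernel(spec)
    kernel = np.concatenate([w[:hw], [0.0], w[hw:]])
    # np.convolve flips the kernel; offsets are symmetric so flip back explicitly
    smoothed = np.convolve(y, kernel[::-1], mode="valid")
    out[hw : n - hw] = smoothed
    return out


def psr_denoise(
    x: np.ndarray,
    d: int = 3,
    t: int | None = None,
    spec: LsqFitSpec | None = None,
    max_lag: int = 25,
    mi_subsample: int | None = 30000,
) -> np.ndarray:
    """Phase-space-reconstruction denoising of one channel.

    Embeds ``x`` at dimension ``d`` (lag from mutual information when not
    given), smooths each coordinate series by local least-squares prediction,
    and averages the aligned estimates of every original sample.  Output has
    the same length as the input; samples whose fitting window is incomplete
    pass through unchanged.
    """
    x = np.asarray(x, dtype=float)
    if spec is None:
        spec = LsqFitSpec()
    if t is None:
        xi = x[:mi_subsample] if mi_subsample else x
        t = select_delay_mi(xi, max_lag=max_lag)
    emb = embed(x, d, t)
    n = len(x)
    rows = emb.vectors.shape[0]
    est_sum = np.zeros(n)
    est_cnt = np.zeros(n)
    for k in range(d):
        smoothed = _smooth_series(emb.vectors[:, k], spec)
        lo = k * t
        est_sum[lo : lo + rows] += smoothed
        est_cnt[lo : lo + rows] += 1.0
    out = x.copy()
    covered = est_cnt > 0
    out[covered] = est_sum[covered] / est_cnt[covered]
    return out


def denoise_recording(rec: Recording, **kwargs) -> Recording:
    """Apply :func:`psr_denoise` channel-wise to a recording."""
    den = np.empty_like(rec.signal)
    for c in range(rec.n_channels):
        den[c] = psr_denoise(rec.signal[c], **kwargs)
    return replace(rec, signal=den)


# ---------------------------------------------------------------------------
# Segmentation


@dataclass
class EpochSet:
    """Non-overlapping fixed-length windows cut from one recording."""

    subject_id: str
    label: str
    sampling_rate: float
    channel_names: tuple
    window_s: float
    windows: np.ndarray  # (n_windows, n_channels, window_samples)

    @property
    def n_windows(self) -> int:
        return self.windows.shape[0]


def segment(
    rec: Recording, window_s: float = 2.0, drop_first: bool = True, drop_last: bool = True
) -> EpochSet:
    """Cut a recording into consecutive non-overlapping ``window_s`` windows.

    The trailing partial window is discarded, and (by default) so are the
    first and last complete windows, where start/end-of-session interference
    is largest.  A 300 s recording at 250 Hz yields 148 two-second windows.
    """
    wlen = int(round(window_s * rec.sampling_rate))
    n_complete = rec.n_samples // wlen
    n_dropped = int(drop_first) + int(drop_last)
    if n_complete - n_dropped < 1:
        raise SeriesTooShortError(
            f"{n_complete} complete windows; need more than {n_dropped}"
        )
    start = 1 if drop_first else 0
    stop = n_complete - (1 if drop_last else 0)
    trimmed = rec.signal[:, : n_complete * wlen]
    wins = trimmed.reshape(rec.n_channels, n_complete, wlen).transpose(1, 0, 2)
    return EpochSet(
        subject_id=rec.subject_id,
        label=rec.label,
        sampling_rate=rec.sampling_rate,
        channel_names=rec.channel_names,
        window_s=window_s,
        windows=np.ascontiguousarray(wins[start:stop]),
    )
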