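"""Frequency-domain features on an integer 1-40 Hz grid, plus the 3-sigma
across-window feature-smoothing rule and a raw time-domain representation
for the ablation study.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps

from .preprocess import EpochSet

__all__ = [
    "SpectralFeatures",
    "SmoothingReport",
    "to_spectrum",
    "smooth",
    "features_time_domain",
]

FREQ_LO, FREQ_HI = 1, 40


@dataclass
class SpectralFeatures:
    """Per-window, per-channel feature tensor.

    ``amplitudes`` has shape (n_windows J, n_channels, n_features); for the
    frequency representation the feature axis is FFT magnitude at integer
    frequencies 1..40 Hz, for the time representation it is the (possibly
    decimated) raw window.
    """

    subject_id: str
    label: str
    channel_names: tuple
    amplitudes: np.ndarray
    freq_axis: np.ndarray | None
    representation: str = "freq"
    metadata: dict = field(default_factory=dict)

    @property
    def n_windows(self) -> int:
        return self.amplitudes.shape[0]

    @property
    def n_channels(self) -> int:
        return self.amplitudes.shape[1]


@dataclass
class SmoothingReport:
    """Which cells the 3-sigma rule replaced."""

    flags: np.ndarray  # bool, same shape as amplitudes
    n_replaced: np.ndarray  # int, (n_channels, n_features)

    @property
    def total_replaced(self) -> int:
        return int(self.n_replaced.sum())


def to_spectrum(ep: EpochSet) -> SpectralFeatures:
    """FFT magnitude of every window at integer frequencies 1..40 Hz.

    Magnitudes use a rectangular window scaled by 2/N, so a bin-aligned
    sinusoid of amplitude A reports A at its frequency.  A 2-s window at
    250 Hz has 0.5 Hz resolution and integer frequency i is read at bin 2i.
    """
    wlen = ep.windows.shape[-1]
    df = ep.sampling_rate / wlen
    if ep.sampling_rate / 2.0 < FREQ_HI or wlen < 2 * FREQ_HI * ep.window_s:
        raise ValueError(
            f"window of {wlen} samples at {ep.sampling_rate} Hz cannot resolve "
            f"{FREQ_HI} Hz on a 1 Hz grid"
        )
    mags = np.abs(np.fft.rfft(ep.windows, axis=-1)) * (2.0 / wlen)
    freqs = np.arange(FREQ_LO, FREQ_HI + 1)
    bins = np.round(freqs / df).astype(int)
    return SpectralFeatures(
        subject_id=ep.subject_id,
        label=ep.label,
        channel_names=ep.channel_names,
        amplitudes=np.ascontiguousarray(mags[..., bins]),
        freq_axis=freqs,
        representation="freq",
        metadata={"window_s": ep.window_s, "sampling_rate": ep.sampling_rate},
    )


def smooth(sf: SpectralFeatures) -> tuple[SpectralFeatures, SmoothingReport]:
    """Replace across-window outliers by the mean of their nearest clean neighbours.

    Independently per (channel, feature): with mean E(Y) and population
    standard deviation sigma over the J windows, any value deviating from
    E(Y) by strictly more than 3 sigma is flagged; each flagged value becomes
    the mean of the nearest unflagged windows before and after it (one-sided
    at the boundary).  Statistics come from the unmodified data; unflagged
    values are never touched.
    """
    y = sf.amplitudes
    J = y.shape[0]
    if J < 3:
        raise ValueError(f"need at least 3 windows to smooth, got {J}")
    mu = y.mean(axis=0)
    sigma = np.sqrt(np.mean((y - mu) ** 2, axis=0))  # population (1/J)
    with np.errstate(invalid="ignore"):
        flags = np.abs(y - mu) > 3.0 * sigma
    flags &= sigma > 0  # sigma == 0 -> nothing can be flagged

    out = y.copy()
    for ch, fi in zip(*np.nonzero(flags.any(axis=0))):
        col_flags = flags[:, ch, fi]
        clean = np.nonzero(~col_flags)[0]
        for j in np.nonzero(col_flags)[0]:
            before = clean[clean < j]
            after = clean[clean > j]
            vals = []
            if before.size:
                vals.append(y[before[-1], ch, fi])
            if after.size:
                vals.append(y[after[0], ch, fi])
            out[j, ch, fi] = float(np.mean(vals))
    report = SmoothingReport(flags=flags, n_replaced=flags.sum(axis=0))
    smoothed = SpectralFeatures(
        subject_id=sf.subject_id,
        label=sf.label,
        channel_names=sf.channel_names,
        amplitudes=out,
        freq_axis=sf.freq_axis,
        representation=sf.representation,
        metadata={**sf.metadata, "smoothed": True},
    )
    return smoothed, report


def features_time_domain(ep: EpochSet, decimate: int | None = None) -> SpectralFeatures:
    """Raw window samples packaged as a feature tensor (ablation input).

    With ``decimate`` set, windows are anti-alias filtered and subsampled by
    that factor (FIR, zero phase) so the network input stays small.
    """
    wins = ep.windows
    if decimate and decimate > 1:
        wins = sps.decimate(wins, decimate, axis=-1, ftype="fir", zero_phase=True)
    return SpectralFeatures(
        subject_id=ep.subject_id,
        label=ep.label,
        channel_names=ep.channel_names,
        amplitudes=np.ascontiguousarray(wins),
        freq_axis=None,
        representation="time",
        metadata={
            "window_s": ep.window_s,
            "sampling_rate": ep.sampling_rate,
            "decimate": decimate,
        },
    )
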