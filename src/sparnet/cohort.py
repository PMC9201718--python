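"""Synthetic resting-state EEG cohorts.

Generates seeded cohorts of multi-channel recordings with the statistical
structure the classification pipeline assumes: band-limited oscillations
(delta/theta/alpha/beta) with random phases, 1/f-shaped background noise,
50 Hz line interference and sparse high-amplitude transients.  Class
differences are injected as multiplicative band-amplitude gains restricted
to named brain regions, so a depressed (MDD) cohort differs from controls
only where and how the effect specification says it should.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "BANDS",
    "Recording",
    "NoiseSpec",
    "CohortSpec",
    "make_cohort",
]

#: Canonical EEG band edges in Hz.
BANDS: dict[str, tuple[float, float]] = {
    "delta": (1.0, 4.0),
    "theta": (4.0, 8.0),
    "alpha": (8.0, 13.0),
    "beta": (13.0, 30.0),
}

#: Baseline per-band RMS amplitudes in microvolts (resting, eyes closed:
#: alpha-dominant posterior rhythm scale).
BASE_AMPLITUDES_UV: dict[str, float] = {
    "delta": 8.0,
    "theta": 6.0,
    "alpha": 12.0,
    "beta": 4.0,
}

MDD = "MDD"
CONTROL = "CONTROL"

DEFAULT_MONTAGE = tuple(f"E{i}" for i in range(1, 129))


class CohortSpecError(ValueError):
    """Raised when a cohort specification field is invalid."""


@dataclass
class Recording:
    """One subject's continuous multichannel EEG.

    Attributes
    ----------
    subject_id : str
        Unique subject identifier.
    label : str
        Class label, ``"MDD"`` or ``"CONTROL"``.
    sampling_rate : float
        Samples per second.
    channel_names : tuple of str
        Ordered montage labels, one per signal row.
    signal : ndarray, shape (n_channels, n_samples)
        Microvolt-scale samples.
    """

    subject_id: str
    label: str
    sampling_rate: float
    channel_names: tuple
    signal: np.ndarray

    def __post_init__(self) -> None:
        self.channel_names = tuple(self.channel_names)
        self.signal = np.asarray(self.signal, dtype=np.float64)
        if self.label not in (MDD, CONTROL):
            raise CohortSpecError(f"label must be MDD or CONTROL, got {self.label!r}")
        if self.sampling_rate <= 0:
            raise CohortSpecError("sampling_rate must be positive")
        if self.signal.ndim != 2:
            raise CohortSpecError("signal must be 2-D (channels x samples)")
        if len(self.channel_names) != self.signal.shape[0]:
            raise CohortSpecError(
                f"{len(self.channel_names)} channel names for "
                f"{self.signal.shape[0]} signal rows"
            )
        if len(set(self.channel_names)) != len(self.channel_names):
            raise CohortSpecError("channel names must be unique")
        if not np.all(np.isfinite(self.signal)):
            raise CohortSpecError("signal contains non-finite values")

    @property
    def n_channels(self) -> int:
        return self.signal.shape[0]

    @property
    def n_samples(self) -> int:
        return self.signal.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.sampling_rate


@dataclass
class NoiseSpec:
    """Background-noise model for the generator.

    ``one_over_f_exponent`` is the spectral slope beta of the 1/f background
    (power ~ f^-beta); ``pink_sd`` its standard deviation in microvolts.
    ``line_amplitude`` is the 50 Hz mains sinusoid amplitude.  Artifacts are
    raised-cosine bursts at Poisson event times (``artifact_rate`` events per
    minute) whose amplitude is ``artifact_amplitude_sd`` times the channel's
    clean standard deviation.
    """

    one_over_f_exponent: float = 1.0
    pink_sd: float = 5.0
    white_sd: float = 2.0
    line_freq_hz: float = 50.0
    line_amplitude: float = 2.0
    artifact_rate_per_min: float = 2.0
    artifact_amplitude_sd: float = 10.0
    artifact_width_s: float = 0.2

    def validate(self) -> None:
        for name in (
            "pink_sd",
            "white_sd",
            "line_amplitude",
            "artifact_rate_per_min",
            "artifact_amplitude_sd",
        ):
            if getattr(self, name) < 0:
                raise CohortSpecError(f"noise.{name} must be >= 0")
        if self.artifact_width_s <= 0:
            raise CohortSpecError("noise.artifact_width_s must be > 0")


@dataclass
class CohortSpec:
    """Specification of a synthetic cohort.

    ``effect`` maps region name -> band name -> amplitude multiplier applied
    to MDD subjects' oscillations on channels of that region, e.g.
    ``{"F": {"theta": 3.0}}`` triples frontal theta amplitude in the MDD
    class.  ``region_channels`` maps region names to channel-name lists;
    when omitted the shipped region map is used so the effect vocabulary
    matches the classifier's region slicing.
    """

    n_mdd: int
    n_control: int
    duration_s: float = 300.0
    sampling_rate: float = 250.0
    seed: int = 0
    effect: dict = field(default_factory=dict)
    noise: NoiseSpec = field(default_factory=NoiseSpec)
    channel_names: tuple = DEFAULT_MONTAGE
    region_channels: dict | None = None
    subject_amp_jitter: float = 0.02

    def validate(self) -> None:
        if self.n_mdd < 1:
            raise CohortSpecError("n_mdd must be >= 1")
        if self.n_control < 1:
            raise CohortSpecError("n_control must be >= 1")
        if self.duration_s <= 0:
            raise CohortSpecError("duration_s must be > 0")
        if self.sampling_rate <= 0:
            raise CohortSpecError("sampling_rate must be > 0")
        if self.subject_amp_jitter < 0:
            raise CohortSpecError("subject_amp_jitter must be >= 0")
        for region, bands in self.effect.items():
            for band, mult in bands.items():
                if band not in BANDS:
                    raise CohortSpecError(
                        f"effect band {band!r} in region {region!r} unknown "
                        f"(known: {sorted(BANDS)})"
                    )
                if mult < 0:
                    raise CohortSpecError(
                        f"effect multiplier for {region}/{band} must be >= 0"
                    )
        self.noise.validate()


def _effect_channel_sets(spec: CohortSpec) -> dict:
    """Resolve region names in ``spec.effect`` to channel-index arrays."""
    if not spec.effect:
        return {}
    region_channels = spec.region_channels
    if region_channels is None:
        from .regions import load_region_map

        region_channels = load_region_map("final").regions
    index = {name: i for i, name in enumerate(spec.channel_names)}
    resolved = {}
    for region, bands in spec.effect.items():
        if region not in region_channels:
            raise CohortSpecError(
                f"effect region {region!r} unknown (known: {sorted(region_channels)})"
            )
        idx = np.array(
            [index[ch] for ch in region_channels[region] if ch in index], dtype=int
        )
        resolved[region] = (idx, bands)
    return resolved


def _one_over_f_noise(rng: np.random.Generator, n: int, beta: float, sd: float) -> np.ndarray:
    """Gaussian noise spectrally shaped to power ~ f^-beta, unit-free then scaled to sd."""
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    f = np.fft.rfftfreq(n, d=1.0)
    scale = np.ones_like(f)
    nz = f > 0
    scale[nz] = f[nz] ** (-beta / 2.0)
    scale[0] = 0.0  # no DC drift
    shaped = np.fft.irfft(spec * scale, n)
    s = shaped.std()
    if s > 0:
        shaped *= sd / s
    return shaped


def _band_oscillation(
    rng: np.random.Generator, n: int, fs: float, lo: float, hi: float, rms: float
) -> np.ndarray:
    """Band-limited oscillation with random phases and target RMS.

    Synthesised in the Fourier domain: every in-band component gets an
    independent random amplitude and phase (complex Gaussian coefficient),
    so the band has a smooth spectrum and windows decorrelate over time, as
    in resting EEG rhythms, rather than a line spectrum.
    """
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    coeff = np.zeros(len(freqs), dtype=complex)
    band = (freqs >= lo) & (freqs < hi)
    k = int(band.sum())
    if k == 0:
        return np.zeros(n)
    coeff[band] = rng.standard_normal(k) + 1j * rng.standard_normal(k)
    x = np.fft.irfft(coeff, n)
    s = x.std()
    if s > 0:
        x *= rms / s
    return x


def _artifact_train(
    rng: np.random.Generator,
    n: int,
    fs: float,
    rate_per_min: float,
    width_s: float,
    amplitude: float,
) -> np.ndarray:
    """Sparse raised-cosine bursts at Poisson event times."""
    out = np.zeros(n)
    if rate_per_min <= 0 or amplitude <= 0:
        return out
    expected = rate_per_min * n / fs / 60.0
    n_events = rng.poisson(expected)
    width = max(int(round(width_s * fs)), 3)
    burst = amplitude * 0.5 * (1.0 - np.cos(2.0 * np.pi * np.arange(width) / (width - 1)))
    for _ in range(n_events):
        start = rng.integers(0, max(n - width, 1))
        sign = 1.0 if rng.random() < 0.5 else -1.0
        out[start : start + width] += sign * burst[: n - start]
    return out


def _make_recording(
    spec: CohortSpec,
    subject_id: str,
    label: str,
    rng: np.random.Generator,
    effect_sets: dict,
) -> Recording:
    fs = spec.sampling_rate
    n = int(round(spec.duration_s * fs))
    t = np.arange(n) / fs
    n_ch = len(spec.channel_names)
    noise = spec.noise

    # Per-subject band amplitude jitter, shared across channels so the
    # subject has a coherent spectral fingerprint.
    subj_gain = {
        band: float(np.exp(rng.normal(0.0, spec.subject_amp_jitter)))
        for band in BANDS
    }
    # Per-channel band multipliers from the class effect.
    ch_mult = np.ones((n_ch, len(BANDS)))
    if label == MDD:
        band_order = list(BANDS)
        for idx, bands in effect_sets.values():
            for band, mult in bands.items():
                ch_mult[idx, band_order.index(band)] *= mult

    signal = np.empty((n_ch, n))
    band_items = list(BANDS.items())
    for c in range(n_ch):
        x = np.zeros(n)
        for b, (band, (lo, hi)) in enumerate(band_items):
            rms = BASE_AMPLITUDES_UV[band] * subj_gain[band] * ch_mult[c, b]
            if rms > 0:
                x += _band_oscillation(rng, n, fs, lo, hi, rms)
        x += _one_over_f_noise(rng, n, noise.one_over_f_exponent, noise.pink_sd)
        if noise.white_sd > 0:
            x += rng.normal(0.0, noise.white_sd, n)
        if noise.line_amplitude > 0:
            x += noise.line_amplitude * np.sin(
                2.0 * np.pi * noise.line_freq_hz * t + rng.uniform(0, 2 * np.pi)
            )
        x += _artifact_train(
            rng,
            n,
            fs,
            noise.artifact_rate_per_min,
            noise.artifact_width_s,
            noise.artifact_amplitude_sd * x.std(),
        )
        signal[c] = x

    return Recording(
        subject_id=subject_id,
        label=label,
        sampling_rate=fs,
        channel_names=spec.channel_names,
        signal=signal,
    )


def make_cohort(spec: CohortSpec) -> list[Recording]:
    """Generate ``spec.n_mdd + spec.n_control`` seeded recordings.

    MDD subjects come first (``mdd01`` ...), then controls (``ctl01`` ...).
    The same spec (including seed) always yields bit-identical signals.
    """
    spec.validate()
    effect_sets = _effect_channel_sets(spec)
    n_total = spec.n_mdd + spec.n_control
    streams = np.random.SeedSequence(spec.seed).spawn(n_total)
    out = []
    for i in range(spec.n_mdd):
        rng = np.random.default_rng(streams[i])
        out.append(_make_recording(spec, f"mdd{i + 1:02d}", MDD, rng, effect_sets))
    for i in range(spec.n_control):
        rng = np.random.default_rng(streams[spec.n_mdd + i])
        out.append(_make_recording(spec, f"ctl{i + 1:02d}", CONTROL, rng, effect_sets))
    return out
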