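"""Synthetic resting-state EEG cohorts with class-dependent band power.

The generator emulates the acquisition conditions of the study cohort — 32
channels, 512 samples/s, roughly two-minute recordings, 16 healthy controls
(HC) and 15 Parkinson's patients each recorded OFF and ON medication — while
injecting a controllable spectral contrast between the classes.  Each channel
is the sum of

* a 1/f^alpha background (spectrally shaped Gaussian noise),
* band-limited sinusoidal oscillators with randomised frequencies and phases
  in the five canonical EEG bands (delta 1-4, theta 4-8, alpha 8-12,
  beta 12-35, gamma 35-45 Hz), and
* additive white noise.

The default class contrast follows the spectral changes reported for
non-demented Parkinson's disease: elevated theta power and reduced beta and
gamma power OFF medication relative to controls, with the ON-medication state
placed midway between the two.  This is a learnable caricature, not
physiological EEG: there are no artifacts, no nonstationarity beyond band
mixing, and no phase-amplitude coupling.

All randomness flows from a single master seed through
``numpy.random.SeedSequence`` so cohorts are reproducible element-wise.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import IntEnum
from typing import Mapping, Sequence

import numpy as np
from scipy import signal as sp_signal

from .io import MONTAGE_32, Recording

__all__ = [
    "BANDS",
    "ClassLabel",
    "ClassSpectrum",
    "CohortSpec",
    "default_spectra",
    "strong_contrast_spectra",
    "generate_recording",
    "generate_cohort",
    "band_power_summary",
]

#: Canonical EEG band edges in Hz (lower inclusive, upper exclusive).
BANDS: dict[str, tuple[float, float]] = {
    "delta": (1.0, 4.0),
    "theta": (4.0, 8.0),
    "alpha": (8.0, 12.0),
    "beta": (12.0, 35.0),
    "gamma": (35.0, 45.0),
}


class ClassLabel(IntEnum):
    """Diagnostic class encoding used throughout the pipeline."""

    HC = 0
    PD_OFF = 1
    PD_ON = 2


@dataclass(frozen=True)
class ClassSpectrum:
    """Spectral recipe for one diagnostic class.

    ``band_powers`` maps band name to the oscillator amplitude for that band
    (arbitrary units, >= 0); ``background_exponent`` is the alpha in the
    1/f^alpha background; ``noise_sd`` the white-noise standard deviation.
    """

    class_label: ClassLabel
    band_powers: Mapping[str, float]
    background_exponent: float = 1.0
    background_amplitude: float = 1.0
    noise_sd: float = 0.25
    bands: Mapping[str, tuple[float, float]] = field(default_factory=lambda: dict(BANDS))
    oscillators_per_band: int = 3

    def __post_init__(self) -> None:
        for name, amp in self.band_powers.items():
            if name not in self.bands:
                raise ValueError(f"unknown band {name!r}; known: {list(self.bands)}")
            if amp < 0:
                raise ValueError(f"band amplitude for {name!r} must be >= 0, got {amp}")
        for name, (lo, hi) in self.bands.items():
            if not 0 < lo < hi:
                raise ValueError(f"band {name!r} edges must satisfy 0 < lo < hi, got ({lo}, {hi})")
        if int(self.class_label) not in (0, 1, 2):
            raise ValueError("class_label must be 0 (HC), 1 (PD_OFF) or 2 (PD_ON)")

    def max_band_edge(self) -> float:
        return max(hi for _, hi in self.bands.values())


@dataclass(frozen=True)
class CohortSpec:
    """Cohort layout; defaults mirror the study (16 HC, 15 PD, 512 S/s, 32 ch)."""

    n_hc: int = 16
    n_pd: int = 15
    duration_s: float = 120.0
    fs: float = 512.0
    n_channels: int = 32
    seed: int = 0


_HC_POWERS = {"delta": 1.0, "theta": 0.8, "alpha": 1.5, "beta": 1.0, "gamma": 0.4}
_PD_OFF_POWERS = {"delta": 1.0, "theta": 1.6, "alpha": 1.5, "beta": 0.5, "gamma": 0.2}


def default_spectra() -> dict[ClassLabel, ClassSpectrum]:
    """Realistic-contrast recipes: PD-OFF has 2x theta, halved beta/gamma
    relative to HC; PD-ON is the elementwise midpoint of the two."""
    pd_on = {
        b: 0.5 * (_HC_POWERS[b] + _PD_OFF_POWERS[b]) for b in _HC_POWERS
    }
    return {
        ClassLabel.HC: ClassSpectrum(ClassLabel.HC, dict(_HC_POWERS)),
        ClassLabel.PD_OFF: ClassSpectrum(ClassLabel.PD_OFF, dict(_PD_OFF_POWERS)),
        ClassLabel.PD_ON: ClassSpectrum(ClassLabel.PD_ON, pd_on),
    }


def strong_contrast_spectra() -> dict[ClassLabel, ClassSpectrum]:
    """Exaggerated class contrast for separability experiments: the same
    effect directions as :func:`default_spectra` but with wide amplitude
    gaps and reduced background/noise, so a classifier with modest capacity
    can resolve the classes from short recordings."""
    hc = {"delta": 0.8, "theta": 0.3, "alpha": 1.5, "beta": 2.0, "gamma": 0.8}
    off = {"delta": 0.8, "theta": 3.0, "alpha": 1.5, "beta": 0.2, "gamma": 0.1}
    on = {b: 0.5 * (hc[b] + off[b]) for b in hc}
    kw = dict(background_amplitude=0.4, noise_sd=0.1)
    return {
        ClassLabel.HC: ClassSpectrum(ClassLabel.HC, hc, **kw),
        ClassLabel.PD_OFF: ClassSpectrum(ClassLabel.PD_OFF, off, **kw),
        ClassLabel.PD_ON: ClassSpectrum(ClassLabel.PD_ON, on, **kw),
    }


def _one_over_f(rng: np.random.Generator, n: int, exponent: float, fs: float) -> np.ndarray:
    """Gaussian noise spectrally shaped to a 1/f^alpha amplitude profile,
    rescaled to unit standard deviation."""
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    shaping = np.ones_like(freqs)
    nz = freqs > 0
    shaping[nz] = freqs[nz] ** (-exponent / 2.0)
    shaping[0] = 0.0  # no DC component
    shaped = np.fft.irfft(spec * shaping, n=n)
    sd = shaped.std()
    return shaped / sd if sd > 0 else shaped


def generate_recording(
    spectrum: ClassSpectrum,
    duration_s: float,
    fs: float,
    n_channels: int,
    subject_id: str,
    seed: int | np.random.SeedSequence,
    channel_names: Sequence[str] | None = None,
) -> Recording:
    """Synthesise one multichannel recording from a class recipe.

    Deterministic for a fixed ``(spectrum, seed)``: every channel draws from
    its own seeded substream, so the output is reproducible element-wise.
    """
    if duration_s <= 0:
        raise ValueError(f"duration_s must be positive, got {duration_s}")
    if fs <= 0:
        raise ValueError(f"fs must be positive, got {fs}")
    if spectrum.max_band_edge() >= fs / 2:
        raise ValueError(
            f"highest band edge {spectrum.max_band_edge()} Hz is at or above "
            f"the Nyquist frequency {fs / 2} Hz"
        )
    if n_channels < 1:
        raise ValueError("n_channels must be >= 1")
    if channel_names is None:
        channel_names = (
            MONTAGE_32[:n_channels]
            if n_channels <= len(MONTAGE_32)
            else [f"ch{i}" for i in range(n_channels)]
        )
    n = int(round(duration_s * fs))
    t = np.arange(n) / fs
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    samples = np.empty((n_channels, n))
    n_osc = spectrum.oscillators_per_band
    for ch, child in enumerate(ss.spawn(n_channels)):
        rng = np.random.default_rng(child)
        x = spectrum.background_amplitude * _one_over_f(
            rng, n, spectrum.background_exponent, fs
        )
        for band, amp in spectrum.band_powers.items():
            if amp == 0:
                continue
            lo, hi = spectrum.bands[band]
            f_osc = rng.uniform(lo, hi, size=n_osc)
            phases = rng.uniform(0.0, 2.0 * np.pi, size=n_osc)
            osc = np.sin(2.0 * np.pi * f_osc[:, None] * t + phases[:, None])
            x = x + (amp / np.sqrt(n_osc)) * osc.sum(axis=0)
        if spectrum.noise_sd > 0:
            x = x + spectrum.noise_sd * rng.standard_normal(n)
        samples[ch] = x
    return Recording(
        subject_id=subject_id,
        class_label=int(spectrum.class_label),
        fs=fs,
        channel_names=list(channel_names),
        samples=samples,
    )


def generate_cohort(
    cohort: CohortSpec,
    spectra: Mapping[ClassLabel, ClassSpectrum] | None = None,
) -> list[Recording]:
    """Generate a full cohort: ``n_hc`` HC recordings plus ``n_pd`` OFF/ON
    pairs sharing a subject_id (so 16 HC + 15 PD yields 46 recordings).

    PD subjects' OFF and ON recordings draw from independent substreams: the
    two sessions share identity but not noise realisations.
    """
    if cohort.n_hc < 1 and cohort.n_pd < 1:
        raise ValueError("cohort must contain at least one subject")
    if spectra is None:
        spectra = default_spectra()
    needed = [ClassLabel.HC] * (cohort.n_hc > 0) + (
        [ClassLabel.PD_OFF, ClassLabel.PD_ON] if cohort.n_pd > 0 else []
    )
    for lbl in needed:
        if lbl not in spectra:
            raise ValueError(f"no ClassSpectrum supplied for class {lbl!r}")
    master = np.random.SeedSequence(cohort.seed)
    streams = iter(master.spawn(cohort.n_hc + 2 * cohort.n_pd))
    recordings: list[Recording] = []
    for i in range(cohort.n_hc):
        recordings.append(
            generate_recording(
                spectra[ClassLabel.HC],
                cohort.duration_s,
                cohort.fs,
                cohort.n_channels,
                subject_id=f"hc{i + 1:02d}",
                seed=next(streams),
            )
        )
    for i in range(cohort.n_pd):
        sid = f"pd{i + 1:02d}"
        for lbl in (ClassLabel.PD_OFF, ClassLabel.PD_ON):
            recordings.append(
                generate_recording(
                    spectra[lbl],
                    cohort.duration_s,
                    cohort.fs,
                    cohort.n_channels,
                    subject_id=sid,
                    seed=next(streams),
                )
            )
    return recordings


def band_power_summary(
    recording: Recording,
    bands: Mapping[str, tuple[float, float]] | None = None,
    nperseg: int | None = None,
) -> dict[str, float]:
    """Channel-averaged band-integrated power from a Welch PSD.

    A test oracle for the generator: Welch PSD per channel, averaged over
    channels, integrated over each band with the trapezoidal rule.
    """
    if recording.n_samples == 0 or recording.n_channels == 0:
        raise ValueError("cannot summarise an empty recording")
    if bands is None:
        bands = BANDS
    if nperseg is None:
        nperseg = int(min(recording.n_samples, 4 * recording.fs))
    freqs, psd = sp_signal.welch(
        recording.samples, fs=recording.fs, nperseg=nperseg, axis=-1
    )
    mean_psd = psd.mean(axis=0)
    out = {}
    for name, (lo, hi) in bands.items():
        mask = (freqs >= lo) & (freqs <= hi)
        out[name] = float(np.trapezoid(mean_psd[mask], freqs[mask])) if mask.sum() > 1 else 0.0
    return out
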