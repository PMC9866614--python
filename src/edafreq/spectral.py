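"""One-sided amplitude spectra and per-segment frequency-domain features.

For a segment x(0..N-1) the unnormalized forward DFT is

    X(b) = sum_k x(k) * exp(-i 2 pi b k / N),   b = 0 .. N/2,

kept one-sided with frequency resolution fs/N (equivalently 1/(ts*N)). From
the magnitudes |X| the per-segment features are: per frequency band the
arithmetic mean, sample standard deviation (divisor N_b - 1) and maximum of
the in-band magnitudes; and, band-independent, the half-energy frequency
f_P/2 — the smallest bin frequency at which the normalized cumulative
energy sum reaches 0.5. For m bands this yields 3*m + 1 features.

The number of in-band bins N_b is obtained by counting bins against the
band edges at the actual resolution fs/N (a 1 Hz band of a 12 s segment at
4 Hz holds 12 bins). Band edges default to half-open [f_low, f_high) so a
shared edge frequency belongs to exactly one band; the closed-interval rule
is available for fidelity experiments but double-counts shared edges.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .errors import EmptyBandError, ZeroEnergySegmentError
from .segmentation import Segment

logger = logging.getLogger(__name__)

EDGE_RULES = ("half-open", "closed")
NORMALIZE_MODES = ("energy", "none")


@dataclass
class AmplitudeSpectrum:
    """One-sided DFT magnitudes of an N-sample segment, bins 0..N/2."""

    magnitudes: np.ndarray
    fs: float
    N: int

    def __post_init__(self) -> None:
        self.magnitudes = np.asarray(self.magnitudes, dtype=float)
        if self.magnitudes.ndim != 1 or len(self.magnitudes) != self.N // 2 + 1:
            raise ValueError("one-sided spectrum of an N-sample segment has N//2 + 1 bins")
        if np.any(self.magnitudes < 0):
            raise ValueError("magnitudes must be non-negative")

    @property
    def resolution(self) -> float:
        """Bin spacing in Hz: fs/N = 1/(ts*N)."""
        return self.fs / self.N

    @property
    def frequencies(self) -> np.ndarray:
        return np.arange(len(self.magnitudes)) * self.resolution


@dataclass(frozen=True)
class FrequencyBand:
    """A contiguous frequency interval over which band features are taken."""

    f_low: float
    f_high: float
    edge_rule: str = "half-open"

    def __post_init__(self) -> None:
        if not 0 <= self.f_low < self.f_high:
            raise ValueError(f"need 0 <= f_low < f_high, got [{self.f_low}, {self.f_high}]")
        if self.edge_rule not in EDGE_RULES:
            raise ValueError(f"edge_rule must be one of {EDGE_RULES}")

    @property
    def name(self) -> str:
        return f"{_fmt(self.f_low)}_{_fmt(self.f_high)}"


#: The two bands proposed for 4 Hz wrist EDA: low (0-1 Hz) and high (1-2 Hz).
DEFAULT_BANDS = (FrequencyBand(0.0, 1.0), FrequencyBand(1.0, 2.0))


@dataclass
class EnergyProfile:
    """Per-bin energy density and its normalized cumulative sum."""

    frequencies: np.ndarray
    psi: np.ndarray
    psi_cum: np.ndarray


def _fmt(f: float) -> str:
    s = format(float(f), "g")
    return s if "." in s or "e" in s else s + ".0"


def amplitude_spectrum(seg: Segment) -> AmplitudeSpectrum:
    """One-sided amplitude spectrum of a segment (unnormalized DFT)."""
    n = len(seg.values)
    if n < 2:
        raise ValueError(f"segment must have at least 2 samples, got {n}")
    return AmplitudeSpectrum(magnitudes=np.abs(np.fft.rfft(seg.values)), fs=seg.fs, N=n)


def normalize_spectrum(spec: AmplitudeSpectrum, mode: str = "energy") -> AmplitudeSpectrum:
    """Rescale a spectrum to unit total energy (sum of squared magnitudes).

    An all-zero spectrum is returned unchanged with a logged warning;
    ``mode="none"`` is the identity.
    """
    if mode not in NORMALIZE_MODES:
        raise ValueError(f"unknown normalize mode {mode!r}; use one of {NORMALIZE_MODES}")
    if mode == "none":
        return spec
    energy = float(np.sum(spec.magnitudes**2))
    if energy == 0.0:
        logger.warning("cannot energy-normalize an all-zero spectrum; returning unchanged")
        return spec
    return AmplitudeSpectrum(magnitudes=spec.magnitudes / np.sqrt(energy), fs=spec.fs, N=spec.N)


def band_bins(spec: AmplitudeSpectrum, band: FrequencyBand) -> np.ndarray:
    """Indices of the spectrum bins falling inside a band; N_b is their count."""
    nyquist = spec.fs / 2
    if band.f_high > nyquist + 1e-12:
        raise ValueError(f"band [{band.f_low}, {band.f_high}] exceeds Nyquist {nyquist} Hz")
    freqs = spec.frequencies
    if band.edge_rule == "half-open":
        mask = (freqs >= band.f_low - 1e-12) & (freqs < band.f_high - 1e-12)
    else:
        mask = (freqs >= band.f_low - 1e-12) & (freqs <= band.f_high + 1e-12)
    bins = np.flatnonzero(mask)
    if len(bins) == 0:
        raise EmptyBandError(
            f"band [{band.f_low}, {band.f_high}) contains no bins at resolution "
            f"{spec.resolution:g} Hz"
        )
    return bins


def band_mean(spec: AmplitudeSpectrum, band: FrequencyBand) -> float:
    """Arithmetic mean of the in-band magnitudes (divisor N_b)."""
    return float(spec.magnitudes[band_bins(spec, band)].mean())


def band_std(spec: AmplitudeSpectrum, band: FrequencyBand) -> float:
    """Sample standard deviation of the in-band magnitudes (divisor N_b - 1)."""
    bins = band_bins(spec, band)
    if len(bins) < 2:
        raise EmptyBandError(
            f"band [{band.f_low}, {band.f_high}) has {len(bins)} bin(s); "
            "standard deviation needs at least 2"
        )
    return float(spec.magnitudes[bins].std(ddof=1))


def band_max(spec: AmplitudeSpectrum, band: FrequencyBand) -> float:
    """Maximum in-band magnitude."""
    return float(spec.magnitudes[band_bins(spec, band)].max())


def energy_profile(spec: AmplitudeSpectrum, include_dc: bool = False) -> EnergyProfile:
    """Energy density |X|^2 per bin and its normalized cumulative sum.

    With ``include_dc=False`` (default) bin 0 is dropped from both the
    density and the normalizing total, so a tonic offset cannot swamp the
    distribution of energy over genuine frequencies.

    Raises
    ------
    ZeroEnergySegmentError
        If the retained bins carry no energy (the caller decides whether to
        drop the segment).
    """
    start = 0 if include_dc else 1
    freqs = spec.frequencies[start:]
    psi = spec.magnitudes[start:] ** 2
    total = float(psi.sum())
    if total == 0.0:
        raise ZeroEnergySegmentError("segment spectrum carries no energy")
    return EnergyProfile(frequencies=freqs, psi=psi, psi_cum=np.cumsum(psi) / total)


def half_energy_frequency(profile: EnergyProfile) -> float:
    """The smallest bin frequency at which the cumulative energy reaches 0.5.

    Discrete rule, no interpolation: reproducible, monotone, and invariant
    under positive rescaling of the signal.
    """
    idx = int(np.argmax(profile.psi_cum >= 0.5 - 1e-12))
    return float(profile.frequencies[idx])


def feature_names(bands: Sequence[FrequencyBand] = DEFAULT_BANDS) -> list[str]:
    """Deterministic base-feature names: mean/std/max per band, then fhalf."""
    names: list[str] = []
    for band in bands:
        names += [f"mean_{band.name}", f"std_{band.name}", f"max_{band.name}"]
    names.append("fhalf")
    return names


def extract_segment_features(
    seg: Segment,
    bands: Sequence[FrequencyBand] = DEFAULT_BANDS,
    normalize: str = "none",
    include_dc: bool = False,
) -> dict[str, float]:
    """All base features of one segment: 3 per band plus f_P/2 (3m + 1 total).

    Band features are scale-covariant, so spectra are used raw by default;
    ``normalize="energy"`` rescales each spectrum to unit energy first.

    Raises
    ------
    ZeroEnergySegmentError
        Propagated from :func:`energy_profile` for energy-free segments.
    """
    spec = normalize_spectrum(amplitude_spectrum(seg), normalize)
    profile = energy_profile(spec, include_dc=include_dc)
    features: dict[str, float] = {}
    for band in bands:
        features[f"mean_{band.name}"] = band_mean(spec, band)
        features[f"std_{band.name}"] = band_std(spec, band)
        features[f"max_{band.name}"] = band_max(spec, band)
    features["fhalf"] = half_energy_frequency(profile)
    return features
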