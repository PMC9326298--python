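"""Spectrograms, Welch power spectral densities, dBFS scaling and band decay.

All time-frequency analysis uses one set of conventions: an FFT of 1024
bins with a symmetric flat-top window of 1024 samples and 3/4 overlap
(hop 256 samples).  The flat-top window's large equivalent-noise
bandwidth is handled by scipy's density scaling.  Power levels are
expressed in dB full scale (dBFS): dB relative to the maximum power
value observed across the analysed collection of signals, so the global
maximum maps to 0 dBFS and everything else is negative.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
from scipy import signal as sps

from woodstrid.audio_io import Recording, RecordingMetadata
from woodstrid.errors import ScaleError, SignalTooShortError

#: Linear-power floor relative to the global maximum, applied before
#: any dB conversion so silent cells map to -120 dBFS instead of -inf.
DB_FLOOR_RATIO = 1e-12


@dataclass(frozen=True)
class SpectralParams:
    """Analysis settings shared by spectrogram and Welch PSD estimation."""

    n_fft: int = 1024
    window: str = "flattop"
    window_length: int = 1024
    overlap_fraction: float = 0.75

    def __post_init__(self) -> None:
        if not 0 <= self.overlap_fraction < 1:
            raise ValueError("overlap_fraction must be in [0, 1)")
        if self.window_length < 2 or self.n_fft < self.window_length:
            raise ValueError("need n_fft >= window_length >= 2")

    @property
    def hop(self) -> int:
        return int(round(self.window_length * (1 - self.overlap_fraction)))

    @property
    def noverlap(self) -> int:
        return self.window_length - self.hop

    def get_window(self) -> np.ndarray:
        # symmetric (non-periodic) window, matching visual-analysis practice
        return sps.get_window(self.window, self.window_length, fftbins=False)


DEFAULT_PARAMS = SpectralParams()


@dataclass
class Spectrogram:
    """One-sided power spectrogram: ``power[f_bin, frame]``."""

    power: np.ndarray
    freqs: np.ndarray
    times: np.ndarray
    params: SpectralParams = DEFAULT_PARAMS
    dbfs: bool = False

    def __post_init__(self) -> None:
        self.power = np.asarray(self.power, dtype=np.float64)
        self.freqs = np.asarray(self.freqs, dtype=np.float64)
        self.times = np.asarray(self.times, dtype=np.float64)
        if self.power.shape != (self.freqs.size, self.times.size):
            raise ValueError("power matrix does not match axis lengths")
        if np.any(np.diff(self.freqs) <= 0):
            raise ValueError("freqs must be strictly increasing")


@dataclass
class PowerSpectrum:
    """Per-bin power ``u_i`` on a frequency axis ``f_i``; linear or dBFS."""

    u: np.ndarray
    freqs: np.ndarray
    dbfs: bool = False

    def __post_init__(self) -> None:
        self.u = np.asarray(self.u, dtype=np.float64)
        self.freqs = np.asarray(self.freqs, dtype=np.float64)
        if self.u.shape != self.freqs.shape:
            raise ValueError("u and freqs must have the same length")
        if not self.dbfs and np.any(self.u < 0):
            raise ValueError("linear-scale power must be non-negative")

    @property
    def df(self) -> float:
        return float(self.freqs[1] - self.freqs[0])


@dataclass
class BandDecayTable:
    """Mean power (dBFS) per (frequency band, distance) cell.

    ``mean_power[i, j]`` is the dBFS power of band
    ``band_edges[i]..band_edges[i+1]`` at ``distances[j]`` cm.
    """

    band_edges: np.ndarray
    distances: np.ndarray
    mean_power: np.ndarray

    def __post_init__(self) -> None:
        self.band_edges = np.asarray(self.band_edges, dtype=np.float64)
        self.distances = np.asarray(self.distances, dtype=np.float64)
        self.mean_power = np.asarray(self.mean_power, dtype=np.float64)
        if self.mean_power.shape != (
            self.band_edges.size - 1,
            self.distances.size,
        ):
            raise ValueError("mean_power shape does not match axes")

    def to_frame(self):
        """Long-format DataFrame: band_low_hz, band_high_hz, distance_cm, mean_power_dbfs."""
        import pandas as pd

        rows = []
        for i in range(self.band_edges.size - 1):
            for j, z in enumerate(self.distances):
                rows.append(
                    {
                        "band_low_hz": self.band_edges[i],
                        "band_high_hz": self.band_edges[i + 1],
                        "distance_cm": z,
                        "mean_power_dbfs": self.mean_power[i, j],
                    }
                )
        return pd.DataFrame(rows)


def compute_spectrogram(
    rec: Recording, params: SpectralParams = DEFAULT_PARAMS
) -> Spectrogram:
    """One-sided linear-power spectrogram of a recording.

    Frames are taken without boundary padding, so the frame count is
    ``floor((N - window_length) / hop) + 1``; frequency resolution is
    ``sample_rate / n_fft``.
    """
    x = rec.samples
    if x.size < params.window_length:
        raise SignalTooShortError(
            f"signal of {x.size} samples is shorter than one "
            f"{params.window_length}-sample window"
        )
    freqs, times, power = sps.spectrogram(
        x,
        fs=rec.sample_rate,
        window=params.get_window(),
        nperseg=params.window_length,
        noverlap=params.noverlap,
        nfft=params.n_fft,
        detrend=False,
        mode="psd",
    )
    return Spectrogram(power, freqs, times, params=params)


def compute_psd_welch(
    rec: Recording, params: SpectralParams = DEFAULT_PARAMS
) -> PowerSpectrum:
    """Welch power spectral density of a recording (or segment).

    Density normalization: the integral of the PSD over frequency
    approximates the mean squared amplitude of the signal (Parseval).
    Signals shorter than one Welch segment are zero-padded to a single
    segment, with a warning.
    """
    x = rec.samples
    if x.size < params.window_length:
        warnings.warn(
            "signal shorter than one Welch segment; zero-padding to a "
            "single segment",
            stacklevel=2,
        )
        x = np.pad(x, (0, params.window_length - x.size))
    freqs, psd = sps.welch(
        x,
        fs=rec.sample_rate,
        window=params.get_window(),
        nperseg=params.window_length,
        noverlap=params.noverlap,
        nfft=params.n_fft,
        detrend=False,
        scaling="density",
    )
    return PowerSpectrum(psd, freqs)


def _collection(spectra) -> list:
    if isinstance(spectra, (PowerSpectrum, Spectrogram)):
        return [spectra]
    return list(spectra)


def dbfs_reference(spectra) -> float:
    """Global maximum linear power across a collection of spectra."""
    items = _collection(spectra)
    ref = 0.0
    for s in items:
        arr = s.u if isinstance(s, PowerSpectrum) else s.power
        if s.dbfs:
            raise ScaleError("collection already contains dBFS-scaled items")
        if arr.size:
            ref = max(ref, float(np.max(arr)))
    if ref <= 0:
        raise ScaleError("all-zero collection: no positive power to reference")
    return ref


def linear_to_dbfs(arr: np.ndarray, reference: float) -> np.ndarray:
    """``10*log10(P / reference)`` with the floor at ``DB_FLOOR_RATIO``."""
    floored = np.maximum(np.asarray(arr, dtype=np.float64), DB_FLOOR_RATIO * reference)
    return 10.0 * np.log10(floored / reference)


def to_dbfs(spectra, reference: float | None = None):
    """Convert spectra to dB full scale against the collection's maximum.

    The reference — by default the maximum power value across *all*
    items passed — maps to 0 dBFS; every other value is negative.  Pass
    ``reference`` explicitly to pin the scale to a wider collection
    (e.g. a whole experiment) than the items being converted.

    Returns an object of the same kind as the input: a single spectrum
    or spectrogram in, the converted single object out; a sequence in,
    a list out.
    """
    single = isinstance(spectra, (PowerSpectrum, Spectrogram))
    items = _collection(spectra)
    if reference is None:
        reference = dbfs_reference(items)
    out = []
    for s in items:
        if isinstance(s, PowerSpectrum):
            out.append(replace(s, u=linear_to_dbfs(s.u, reference), dbfs=True))
        else:
            out.append(
                Spectrogram(
                    linear_to_dbfs(s.power, reference),
                    s.freqs,
                    s.times,
                    params=s.params,
                    dbfs=True,
                )
            )
    return out[0] if single else out


def band_power_decay(
    psd_by_recording: list[tuple[RecordingMetadata, PowerSpectrum]],
    band_width_hz: float = 2000.0,
    reference: float | None = None,
) -> BandDecayTable:
    """Distance-wise mean power in contiguous frequency bands, in dBFS.

    For each 2 kHz band (default) and each distance present in the
    metadata, the cell is the mean — in linear power, converted to dB
    last — over recordings at that distance of the mean PSD value
    within the band.  The dBFS reference is the global maximum over all
    input PSDs unless given explicitly.
    """
    if not psd_by_recording:
        raise ValueError("empty PSD collection")
    freqs = psd_by_recording[0][1].freqs
    for _, psd in psd_by_recording:
        if psd.dbfs:
            raise ScaleError("band_power_decay expects linear-scale PSDs")
        if psd.freqs.shape != freqs.shape or not np.allclose(psd.freqs, freqs):
            raise ValueError("all PSDs must share one frequency axis")
    if reference is None:
        reference = dbfs_reference([p for _, p in psd_by_recording])

    nyquist = freqs[-1]
    n_bands = int(np.ceil(nyquist / band_width_hz))
    edges = np.arange(n_bands + 1) * band_width_hz
    distances = np.unique([m.distance_cm for m, _ in psd_by_recording])

    table = np.full((n_bands, distances.size), np.nan)
    for j, z in enumerate(distances):
        stack = np.vstack(
            [p.u for m, p in psd_by_recording if m.distance_cm == z]
        )
        mean_psd = stack.mean(axis=0)
        for i in range(n_bands):
            in_band = (freqs >= edges[i]) & (freqs < edges[i + 1])
            if i == n_bands - 1:
                in_band |= freqs == edges[i + 1]
            if not np.any(in_band):
                raise ValueError(
                    f"band {edges[i]:.0f}-{edges[i + 1]:.0f} Hz contains no bins"
                )
            table[i, j] = mean_psd[in_band].mean()
    return BandDecayTable(edges, distances, linear_to_dbfs(table, reference))
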