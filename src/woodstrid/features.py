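"""The five per-stridulation acoustic features and feature-table handling.

Each detected call is described by five features computed from its mean
spectrum (the mean over the segment's frames of the linear spectrogram
columns):

* centroid frequency ``f_c = sum(f_i * u_i) / sum(u_i)`` — the
  power-weighted mean frequency, analogous to a centre of mass;
* dominant frequency — the bin of maximal power (ties broken toward
  the lowest frequency);
* -3 dB bandwidth — span between the outermost half-power crossings,
  located by linear interpolation between adjacent bins;
* duration — segment length in seconds, ``n_frames * hop / fs``;
* mean amplitude — mean spectral power in dBFS.

Feature tables are min-max normalized to [0, 1] per feature before
clustering or classification, with the (min, max) pairs stored so the
scaling can be inverted exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from woodstrid.errors import ScaleError
from woodstrid.spectral import (
    PowerSpectrum,
    SpectralParams,
    Spectrogram,
    linear_to_dbfs,
)
from woodstrid.segmentation import SegmentInterval

FEATURE_COLUMNS = (
    "centroid_hz",
    "dominant_hz",
    "bandwidth_hz",
    "duration_s",
    "mean_amplitude_dbfs",
)


@dataclass(frozen=True)
class FeatureVector:
    """Five acoustic features of one stridulation."""

    centroid_hz: float
    dominant_hz: float
    bandwidth_hz: float
    duration_s: float
    mean_amplitude_dbfs: float
    bandwidth_degenerate: bool = False

    def as_array(self) -> np.ndarray:
        return np.array(
            [
                self.centroid_hz,
                self.dominant_hz,
                self.bandwidth_hz,
                self.duration_s,
                self.mean_amplitude_dbfs,
            ]
        )


@dataclass
class FeatureTable:
    """Feature rows plus metadata; optionally min-max normalized.

    ``data`` holds one row per stridulation with the five feature
    columns and any metadata columns (species, distance_cm, tissue,
    recording_id, segment_index).  ``norm_bounds`` maps feature name to
    the (min, max) used for scaling, or is None when unnormalized.
    """

    data: pd.DataFrame
    norm_bounds: dict[str, tuple[float, float]] | None = None
    constant_columns: list[str] = field(default_factory=list)

    @property
    def normalized(self) -> bool:
        return self.norm_bounds is not None

    def feature_matrix(self) -> np.ndarray:
        return self.data.loc[:, list(FEATURE_COLUMNS)].to_numpy(dtype=float)


def _require_linear(spec: PowerSpectrum) -> None:
    if spec.dbfs:
        raise ScaleError("feature extraction requires a linear-scale spectrum")


def centroid_frequency(spec: PowerSpectrum) -> float:
    """Power-weighted mean frequency of a linear spectrum."""
    _require_linear(spec)
    total = spec.u.sum()
    if total <= 0:
        raise ValueError("all-zero spectrum has no centroid")
    return float((spec.freqs * spec.u).sum() / total)


def dominant_frequency(spec: PowerSpectrum) -> float:
    """Frequency of the maximal bin; ties go to the lowest frequency."""
    if spec.u.size == 0:
        raise ValueError("empty spectrum")
    return float(spec.freqs[int(np.argmax(spec.u))])  # argmax takes first max


def bandwidth_3db(spec: PowerSpectrum) -> tuple[float, bool]:
    """-3 dB (half-power) bandwidth and a degeneracy flag.

    Cut-offs are the outermost crossings of half the peak power,
    located by linear interpolation between adjacent bins.  Returns
    ``(bandwidth_hz, degenerate)`` where ``degenerate`` marks spectra
    that never drop 3 dB below the peak within the axis (bandwidth is
    then the full axis span) or single-bin spectra (bandwidth is one
    frequency-resolution width).
    """
    _require_linear(spec)
    u, f = spec.u, spec.freqs
    peak_idx = int(np.argmax(u))
    peak = u[peak_idx]
    if peak <= 0:
        raise ValueError("all-zero spectrum has no bandwidth")
    half = peak / 2.0
    above = u >= half

    if np.all(above):
        return float(f[-1] - f[0]), True

    df = spec.df if f.size > 1 else 0.0
    first = int(np.argmax(above))  # lowest bin at/above half power
    last = len(u) - 1 - int(np.argmax(above[::-1]))  # highest such bin
    if first == last:
        return float(df), True

    if first == 0:
        f_low = f[0]
    else:
        # interpolate the upward crossing between bins first-1 and first
        u0, u1 = u[first - 1], u[first]
        f_low = f[first - 1] + (half - u0) / (u1 - u0) * (f[first] - f[first - 1])
    if last == len(u) - 1:
        f_high = f[-1]
    else:
        u0, u1 = u[last], u[last + 1]
        f_high = f[last] + (u0 - half) / (u0 - u1) * (f[last + 1] - f[last])
    return float(f_high - f_low), False


def duration(
    seg: SegmentInterval,
    params: SpectralParams | None = None,
    sample_rate: int = 44100,
) -> float:
    """Segment length in seconds: ``n_frames * hop / sample_rate``."""
    hop = (params or SpectralParams()).hop
    return seg.n_frames * hop / sample_rate


def mean_amplitude(spec: PowerSpectrum, reference: float) -> float:
    """Mean spectral power in dB relative to the global dBFS reference."""
    _require_linear(spec)
    mean_p = float(spec.u.mean())
    if mean_p <= 0:
        raise ValueError("all-zero spectrum has no amplitude")
    return float(linear_to_dbfs(np.array(mean_p), reference))


def mean_segment_spectrum(spec: Spectrogram, seg: SegmentInterval) -> PowerSpectrum:
    """Mean over the segment's frames of the linear spectrogram columns."""
    if spec.dbfs:
        raise ScaleError("mean segment spectrum requires linear power")
    cols = spec.power[:, seg.start_frame : seg.end_frame]
    return PowerSpectrum(cols.mean(axis=1), spec.freqs)


def segment_features(
    spec: Spectrogram,
    seg: SegmentInterval,
    reference: float,
    sample_rate: int = 44100,
) -> FeatureVector:
    """All five features of one segmented stridulation."""
    mean_spec = mean_segment_spectrum(spec, seg)
    bw, degenerate = bandwidth_3db(mean_spec)
    return FeatureVector(
        centroid_hz=centroid_frequency(mean_spec),
        dominant_hz=dominant_frequency(mean_spec),
        bandwidth_hz=bw,
        duration_s=duration(seg, spec.params, sample_rate),
        mean_amplitude_dbfs=mean_amplitude(mean_spec, reference),
        bandwidth_degenerate=degenerate,
    )


def features_to_table(
    rows: list[tuple[dict, FeatureVector]],
) -> FeatureTable:
    """Build an unnormalized FeatureTable from (metadata dict, vector) pairs."""
    records = []
    for meta, vec in rows:
        rec = dict(meta)
        rec.update(
            centroid_hz=vec.centroid_hz,
            dominant_hz=vec.dominant_hz,
            bandwidth_hz=vec.bandwidth_hz,
            duration_s=vec.duration_s,
            mean_amplitude_dbfs=vec.mean_amplitude_dbfs,
        )
        records.append(rec)
    return FeatureTable(pd.DataFrame.from_records(records))


def normalize_features(table: FeatureTable) -> FeatureTable:
    """Min-max scale each feature column to [0, 1], keeping bounds.

    A constant column cannot be scaled; it is set to 0.5 everywhere and
    flagged in ``constant_columns``.  The stored (min, max) bounds make
    :func:`denormalize_features` an exact inverse for non-constant
    columns.
    """
    if table.normalized:
        raise ValueError("table is already normalized")
    if len(table.data) < 2:
        raise ValueError("need at least 2 rows to normalize")
    df = table.data.copy()
    bounds: dict[str, tuple[float, float]] = {}
    constant: list[str] = []
    for col in FEATURE_COLUMNS:
        lo, hi = float(df[col].min()), float(df[col].max())
        bounds[col] = (lo, hi)
        if hi > lo:
            df[col] = (df[col] - lo) / (hi - lo)
        else:
            df[col] = 0.5
            constant.append(col)
    return FeatureTable(df, norm_bounds=bounds, constant_columns=constant)


def denormalize_features(table: FeatureTable) -> FeatureTable:
    """Invert min-max scaling using the stored per-feature bounds."""
    if not table.normalized:
        raise ValueError("table is not normalized")
    df = table.data.copy()
    for col in FEATURE_COLUMNS:
        lo, hi = table.norm_bounds[col]
        if hi > lo:
            df[col] = df[col] * (hi - lo) + lo
        else:
            df[col] = lo
    return FeatureTable(df)
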