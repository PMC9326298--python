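"""Threshold-based segmentation of stridulations from a spectrogram.

A stridulation is detected from the per-frame mean of the linear-power
spectrogram (the energy envelope): the arithmetic mean of that envelope
serves as the detection threshold, and maximal runs of frames strictly
above it are the candidate calls.  Because the threshold scales with
the envelope, segmentation is invariant to global amplitude scaling of
the recording.  The envelope is computed on linear power: a mean
threshold on dB values would be dominated by the noise floor.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from woodstrid.errors import ScaleError
from woodstrid.spectral import SpectralParams, Spectrogram

#: Defaults sized well below beetle chirp durations (~40-60 ms; one
#: frame is ~5.8 ms at hop 256 / 44.1 kHz), exposed as configuration.
DEFAULT_MIN_LEN_FRAMES = 3
DEFAULT_MAX_GAP_FRAMES = 2


@dataclass
class EnergyEnvelope:
    """Per-frame mean spectrogram power and its mean-value threshold."""

    values: np.ndarray
    times: np.ndarray
    threshold: float

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        self.times = np.asarray(self.times, dtype=np.float64)
        if self.values.shape != self.times.shape:
            raise ValueError("values and times must have equal length")


@dataclass(frozen=True, order=True)
class SegmentInterval:
    """One detected stridulation, frames half-open ``[start, end)``."""

    start_frame: int
    end_frame: int
    start_s: float
    end_s: float

    def __post_init__(self) -> None:
        if self.end_frame <= self.start_frame:
            raise ValueError("end_frame must exceed start_frame")

    @property
    def n_frames(self) -> int:
        return self.end_frame - self.start_frame


def energy_envelope(spec: Spectrogram) -> EnergyEnvelope:
    """Average the spectrogram over frequency; threshold = mean of the result."""
    if spec.dbfs:
        raise ScaleError("energy envelope requires a linear-power spectrogram")
    values = spec.power.mean(axis=0)
    return EnergyEnvelope(values, spec.times, float(values.mean()))


def segment_stridulations(
    env: EnergyEnvelope,
    min_len_frames: int = DEFAULT_MIN_LEN_FRAMES,
    max_gap_frames: int = DEFAULT_MAX_GAP_FRAMES,
    sample_rate: int = 44100,
    params: SpectralParams | None = None,
) -> list[SegmentInterval]:
    """Detect maximal supra-threshold runs as stridulation intervals.

    Frames with envelope value strictly above the threshold are active
    (so a constant envelope yields no segments); active runs separated
    by at most ``max_gap_frames`` inactive frames are merged; runs
    shorter than ``min_len_frames`` are discarded.  Returned intervals
    are sorted and non-overlapping.
    """
    if env.values.size == 0:
        raise ValueError("empty envelope")
    active = env.values > env.threshold
    runs: list[list[int]] = []  # [start, end) pairs, mutably merged
    start = None
    for i, a in enumerate(active):
        if a and start is None:
            start = i
        elif not a and start is not None:
            runs.append([start, i])
            start = None
    if start is not None:
        runs.append([start, active.size])

    merged: list[list[int]] = []
    for run in runs:
        if merged and run[0] - merged[-1][1] <= max_gap_frames:
            merged[-1][1] = run[1]
        else:
            merged.append(run)

    hop = (params or SpectralParams()).hop
    out = []
    for s, e in merged:
        if e - s < min_len_frames:
            continue
        out.append(
            SegmentInterval(
                start_frame=s,
                end_frame=e,
                start_s=s * hop / sample_rate,
                end_s=e * hop / sample_rate,
            )
        )
    return out
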