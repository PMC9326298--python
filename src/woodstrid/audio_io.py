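"""Mono WAV input/output and the recording manifest.

Recordings are stored as float arrays in [-1, 1], normalized by
``2**(bit_depth - 1)`` so that dB-full-scale references are
well-defined.  24-bit PCM — the acquisition depth used for
substrate-borne beetle recordings — is read and written natively by
packing/unpacking 3-byte little-endian samples; 16-bit and 32-bit
integer PCM are also accepted.
"""

from __future__ import annotations

import csv
import wave
from dataclasses import dataclass
from enum import Enum
from pathlib import Path

import numpy as np

from woodstrid.errors import AudioFormatError, ManifestError, MultiChannelError

#: Canonical acquisition settings: 44.1 kHz sampling, 24-bit resolution.
DEFAULT_SAMPLE_RATE = 44100
DEFAULT_BIT_DEPTH = 24

#: Source-sensor distances (cm) of the standard measurement design.
STUDY_DISTANCES_CM = (5, 10, 15, 20, 30, 40, 60, 80, 100)


class Tissue(str, Enum):
    """Tissue layer the sensor is coupled to."""

    BARK = "bark"
    PHLOEM = "phloem"


@dataclass(frozen=True)
class RecordingMetadata:
    """Acquisition metadata for one recording.

    Parameters
    ----------
    species : str
        Species label, e.g. ``"H_ligniperda"`` or ``"H_ater"``.
    distance_cm : float
        Source-sensor distance z in cm (>= 0).
    tissue : Tissue
        ``bark`` (outer, dry layer) or ``phloem`` (inner, living layer).
    tissue_width_cm : float
        Width w of the tissue layer in cm (> 0).
    log_id, subject_id : str
        Identifiers of the log and the individual insect.
    path : str, optional
        File reference when loaded from a manifest.
    """

    species: str
    distance_cm: float
    tissue: Tissue
    tissue_width_cm: float
    log_id: str = ""
    subject_id: str = ""
    path: str = ""

    def __post_init__(self) -> None:
        if self.distance_cm < 0:
            raise ManifestError(f"distance_cm must be >= 0, got {self.distance_cm}")
        if self.tissue_width_cm <= 0:
            raise ManifestError(
                f"tissue_width_cm must be > 0, got {self.tissue_width_cm}"
            )
        if not isinstance(self.tissue, Tissue):
            object.__setattr__(self, "tissue", Tissue(self.tissue))


@dataclass
class Recording:
    """A mono waveform with acquisition metadata.

    ``samples`` are dimensionless amplitudes in [-1, 1]; ``sample_rate``
    in Hz; ``bit_depth`` the PCM resolution the data came from (or will
    be written at).
    """

    samples: np.ndarray
    sample_rate: int = DEFAULT_SAMPLE_RATE
    bit_depth: int = DEFAULT_BIT_DEPTH
    meta: RecordingMetadata | None = None

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=np.float64)
        if self.samples.ndim != 1 or self.samples.size == 0:
            raise ValueError("samples must be a non-empty 1-D array")
        if self.sample_rate <= 0:
            raise ValueError("sample_rate must be positive")
        peak = float(np.max(np.abs(self.samples)))
        if peak > 1.0 + 2.0 ** -(self.bit_depth - 1):
            raise ValueError(f"samples exceed full scale (max |x| = {peak:.4g})")

    @property
    def duration_s(self) -> float:
        return self.samples.size / self.sample_rate


def _pcm_to_float(raw: bytes, sampwidth: int) -> np.ndarray:
    if sampwidth == 2:
        x = np.frombuffer(raw, dtype="<i2").astype(np.float64)
        return x / 2.0**15
    if sampwidth == 3:
        b = np.frombuffer(raw, dtype=np.uint8).reshape(-1, 3)
        # sign-extend 3-byte little-endian into int32
        x = (
            b[:, 0].astype(np.int32)
            | (b[:, 1].astype(np.int32) << 8)
            | (b[:, 2].astype(np.int32) << 16)
        )
        x = np.where(x >= 1 << 23, x - (1 << 24), x)
        return x.astype(np.float64) / 2.0**23
    if sampwidth == 4:
        x = np.frombuffer(raw, dtype="<i4").astype(np.float64)
        return x / 2.0**31
    raise AudioFormatError(f"unsupported PCM sample width: {sampwidth} bytes")


def _float_to_pcm(x: np.ndarray, sampwidth: int) -> bytes:
    full = 2 ** (8 * sampwidth - 1)
    q = np.clip(np.rint(x * full), -full, full - 1).astype(np.int64)
    if sampwidth == 2:
        return q.astype("<i2").tobytes()
    if sampwidth == 3:
        q = np.where(q < 0, q + (1 << 24), q).astype(np.uint32)
        b = np.empty((q.size, 3), dtype=np.uint8)
        b[:, 0] = q & 0xFF
        b[:, 1] = (q >> 8) & 0xFF
        b[:, 2] = (q >> 16) & 0xFF
        return b.tobytes()
    if sampwidth == 4:
        return q.astype("<i4").tobytes()
    raise AudioFormatError(f"unsupported PCM sample width: {sampwidth} bytes")


def read_wav(path: str | Path, meta: RecordingMetadata | None = None) -> Recording:
    """Read a mono PCM WAV file into a :class:`Recording`.

    Raises ``FileNotFoundError`` for a missing file,
    :class:`MultiChannelError` for multi-channel input and
    :class:`AudioFormatError` for unsupported encodings.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(str(path))
    try:
        with wave.open(str(path), "rb") as wf:
            n_channels = wf.getnchannels()
            if n_channels != 1:
                raise MultiChannelError(
                    f"{path} has {n_channels} channels; only mono is supported"
                )
            sampwidth = wf.getsampwidth()
            rate = wf.getframerate()
            raw = wf.readframes(wf.getnframes())
    except wave.Error as exc:
        raise AudioFormatError(f"{path}: {exc}") from exc
    samples = _pcm_to_float(raw, sampwidth)
    return Recording(samples, sample_rate=rate, bit_depth=8 * sampwidth, meta=meta)


def write_wav(path: str | Path, rec: Recording) -> None:
    """Write a :class:`Recording` as little-endian PCM WAV at its bit depth."""
    sampwidth = rec.bit_depth // 8
    if sampwidth not in (2, 3, 4):
        raise AudioFormatError(f"cannot write {rec.bit_depth}-bit PCM")
    with wave.open(str(path), "wb") as wf:
        wf.setnchannels(1)
        wf.setsampwidth(sampwidth)
        wf.setframerate(rec.sample_rate)
        wf.writeframes(_float_to_pcm(rec.samples, sampwidth))


MANIFEST_COLUMNS = (
    "path",
    "species",
    "distance_cm",
    "tissue",
    "tissue_width_cm",
    "log_id",
    "subject_id",
)


def load_manifest(path: str | Path) -> list[RecordingMetadata]:
    """Load a recording manifest CSV into metadata entries, row order preserved.

    The CSV must carry the columns ``path, species, distance_cm, tissue,
    tissue_width_cm, log_id, subject_id``.  Every row maps to exactly one
    entry or one :class:`ManifestError` naming the offending row.
    """
    path = Path(path)
    with path.open(newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        header = reader.fieldnames or []
        missing = [c for c in MANIFEST_COLUMNS if c not in header]
        if missing:
            raise ManifestError(f"manifest missing column(s): {', '.join(missing)}")
        entries: list[RecordingMetadata] = []
        for i, row in enumerate(reader, start=2):  # 1-based incl. header
            try:
                tissue = Tissue(row["tissue"].strip().lower())
            except ValueError as exc:
                raise ManifestError(
                    f"row {i}: unknown tissue {row['tissue']!r} "
                    f"(expected one of {[t.value for t in Tissue]})"
                ) from exc
            try:
                entries.append(
                    RecordingMetadata(
                        species=row["species"].strip(),
                        distance_cm=float(row["distance_cm"]),
                        tissue=tissue,
                        tissue_width_cm=float(row["tissue_width_cm"]),
                        log_id=row["log_id"].strip(),
                        subject_id=row["subject_id"].strip(),
                        path=row["path"].strip(),
                    )
                )
            except (ValueError, ManifestError) as exc:
                raise ManifestError(f"row {i}: {exc}") from exc
    return entries


def write_manifest(path: str | Path, entries: list[RecordingMetadata]) -> None:
    """Write metadata entries as a manifest CSV (inverse of :func:`load_manifest`)."""
    with Path(path).open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(MANIFEST_COLUMNS)
        for m in entries:
            writer.writerow(
                [
                    m.path,
                    m.species,
                    m.distance_cm,
                    m.tissue.value,
                    m.tissue_width_cm,
                    m.log_id,
                    m.subject_id,
                ]
            )
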