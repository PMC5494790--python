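"""Bonn-format EEG segment I/O and a synthetic three-class EEG generator.

The Bonn archive distributes each single-channel EEG segment as a plain
ASCII text file, one sample per line.  The synthetic generator emulates the
three subsets used in three-class seizure-detection work:

* ``A`` -- normal (awake) EEG: low-amplitude pink-ish background with a
  posterior-dominant ~10 Hz rhythm,
* ``D`` -- interictal EEG: the same background carrying sparse biphasic
  epileptiform spikes,
* ``E`` -- ictal EEG: high-amplitude rhythmic 3-7 Hz spike-wave activity.

These qualitative distinctions are exactly what max/std subband features
pick up, so the generator makes the full pipeline testable without any
external download.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "CLASS_LABELS",
    "EEGSegment",
    "ClassParams",
    "SynthSpec",
    "read_bonn_segment",
    "write_bonn_segment",
    "generate_synthetic_dataset",
    "write_dataset",
    "read_dataset",
]

#: Class labels in canonical order: normal, interictal, ictal.
CLASS_LABELS: tuple[str, str, str] = ("A", "D", "E")

DEFAULT_FS = 173.61  # Hz, the Bonn archive sampling rate


@dataclass(frozen=True)
class EEGSegment:
    """A labelled single-channel EEG recording.

    Parameters
    ----------
    samples
        Sample values in microvolts.
    fs
        Sampling rate in Hz (must be positive).
    label
        One of ``"A"`` (normal), ``"D"`` (interictal), ``"E"`` (ictal),
        or ``None`` for unlabelled data.
    segment_id
        Opaque identifier carried through the pipeline.
    """

    samples: np.ndarray
    fs: float = DEFAULT_FS
    label: str | None = None
    segment_id: str = ""

    def __post_init__(self) -> None:
        samples = np.asarray(self.samples, dtype=float)
        if samples.ndim != 1 or samples.size < 1:
            raise ValueError("samples must be a non-empty 1-D sequence")
        object.__setattr__(self, "samples", samples)
        if not self.fs > 0:
            raise ValueError(f"fs must be positive, got {self.fs}")
        if self.label is not None and self.label not in CLASS_LABELS:
            raise ValueError(
                f"label must be one of {CLASS_LABELS} or None, got {self.label!r}"
            )

    def __len__(self) -> int:
        return int(self.samples.size)

    @property
    def duration(self) -> float:
        """Segment duration in seconds."""
        return len(self) / self.fs


@dataclass(frozen=True)
class ClassParams:
    """Per-class generator parameters.

    amplitude : dominant-rhythm amplitude scale (µV)
    band      : dominant rhythm frequency range (Hz)
    spike_rate: expected epileptiform spike rate (events/s)
    noise_std : standard deviation of the pink-ish background (µV)
    """

    amplitude: float
    band: tuple[float, float]
    spike_rate: float
    noise_std: float

    def validate(self, fs: float) -> None:
        if self.amplitude < 0 or self.spike_rate < 0 or self.noise_std < 0:
            raise ValueError("amplitude, spike_rate and noise_std must be >= 0")
        lo, hi = self.band
        if not (0 < lo < hi < fs / 2):
            raise ValueError(
                f"rhythm band {self.band} must satisfy 0 < lo < hi < fs/2 ({fs / 2:g} Hz)"
            )


def default_class_params() -> dict[str, ClassParams]:
    """Default per-class parameters (amplitudes in µV, Bonn-like scale)."""
    return {
        "A": ClassParams(amplitude=10.0, band=(9.0, 11.0), spike_rate=0.0, noise_std=10.0),
        "D": ClassParams(amplitude=10.0, band=(9.0, 11.0), spike_rate=0.7, noise_std=12.0),
        "E": ClassParams(amplitude=60.0, band=(3.0, 7.0), spike_rate=0.0, noise_std=15.0),
    }


@dataclass(frozen=True)
class SynthSpec:
    """Specification of a synthetic three-class dataset.

    Identical ``SynthSpec`` values (including ``seed``) reproduce the same
    dataset bit for bit.
    """

    n_segments_per_class: int = 100
    segment_length: int = 4096
    fs: float = DEFAULT_FS
    seed: int = 0
    class_params: Mapping[str, ClassParams] = field(default_factory=default_class_params)

    def validate(self) -> None:
        if self.n_segments_per_class < 0:
            raise ValueError("n_segments_per_class must be >= 0")
        if self.segment_length < 1:
            raise ValueError("segment_length must be >= 1")
        if not self.fs > 0:
            raise ValueError("fs must be positive")
        for label in CLASS_LABELS:
            if label not in self.class_params:
                raise ValueError(f"class_params missing class {label!r}")
            self.class_params[label].validate(self.fs)


def read_bonn_segment(
    path: str | os.PathLike,
    fs: float = DEFAULT_FS,
    label: str | None = None,
    segment_id: str | None = None,
) -> EEGSegment:
    """Read one Bonn-format segment: plain text, one sample per line.

    Integer or float samples are accepted; surrounding whitespace and blank
    lines are tolerated.  A non-numeric line raises ``ValueError`` naming
    the offending line number; an empty file raises ``ValueError``.
    """
    path = Path(path)
    values: list[float] = []
    with open(path, "r") as fh:
        for lineno, line in enumerate(fh, start=1):
            text = line.strip()
            if not text:
                continue
            try:
                values.append(float(text))
            except ValueError:
                raise ValueError(
                    f"{path}: line {lineno} is not a number: {text!r}"
                ) from None
    if not values:
        raise ValueError(f"{path}: file contains no samples")
    return EEGSegment(
        samples=np.asarray(values, dtype=float),
        fs=fs,
        label=label,
        segment_id=segment_id if segment_id is not None else path.stem,
    )


def write_bonn_segment(segment: EEGSegment, path: str | os.PathLike) -> None:
    """Write a segment in Bonn text format (one sample per line, ``%.17g``)."""
    with open(path, "w") as fh:
        for v in segment.samples:
            fh.write(f"{v:.17g}\n")


# ---------------------------------------------------------------------------
# synthetic generation


def _pink_noise(rng: np.random.Generator, n: int, fs: float) -> np.ndarray:
    """Unit-variance 1/f-shaped Gaussian noise (flat below 1 Hz)."""
    white = rng.standard_normal(n)
    spectrum = np.fft.rfft(white)
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    shaping = 1.0 / np.sqrt(np.maximum(freqs, 1.0))
    pink = np.fft.irfft(spectrum * shaping, n=n)
    sd = pink.std()
    return pink / sd if sd > 0 else pink


def _biphasic_spike(fs: float, width_s: float = 0.07) -> np.ndarray:
    """A biphasic (derivative-of-Gaussian) epileptiform spike template."""
    half = max(int(round(3 * width_s * fs)), 2)
    t = np.arange(-half, half + 1) / fs
    w = width_s / 2.0
    shape = -t / w * np.exp(0.5 - (t / w) ** 2 / 2.0)
    return shape / np.max(np.abs(shape))


def _synth_segment(rng: np.random.Generator, label: str, spec: SynthSpec) -> np.ndarray:
    p = spec.class_params[label]
    n, fs = spec.segment_length, spec.fs
    t = np.arange(n) / fs
    x = p.noise_std * _pink_noise(rng, n, fs)

    freq = rng.uniform(*p.band)
    phase = rng.uniform(0.0, 2.0 * np.pi)
    rhythm = np.sin(2.0 * np.pi * freq * t + phase)
    if label == "E":
        # sharpened spike-wave morphology: add phase-locked harmonics
        rhythm = rhythm + 0.5 * np.sin(2.0 * (2.0 * np.pi * freq * t + phase))
        rhythm = rhythm + 0.2 * np.sin(3.0 * (2.0 * np.pi * freq * t + phase))
    x = x + p.amplitude * rhythm

    if p.spike_rate > 0:
        template = _biphasic_spike(fs)
        n_spikes = rng.poisson(p.spike_rate * n / fs)
        for _ in range(n_spikes):
            center = rng.integers(0, n)
            amp = 4.0 * p.noise_std * rng.uniform(0.8, 1.4) * rng.choice([-1.0, 1.0])
            lo = center - len(template) // 2
            hi = lo + len(template)
            s0, s1 = max(lo, 0), min(hi, n)
            x[s0:s1] += amp * template[s0 - lo : s1 - lo]
    return x


def generate_synthetic_dataset(spec: SynthSpec) -> list[EEGSegment]:
    """Generate ``n_segments_per_class`` labelled segments for each class.

    Deterministic for a fixed ``spec`` (including its ``seed``); distinct
    seeds give distinct sample sequences.  Segments are returned grouped by
    class in ``CLASS_LABELS`` order.
    """
    spec.validate()
    root = np.random.SeedSequence(spec.seed)
    children = root.spawn(3 * spec.n_segments_per_class) if spec.n_segments_per_class else []
    segments: list[EEGSegment] = []
    k = 0
    for label in CLASS_LABELS:
        for i in range(spec.n_segments_per_class):
            rng = np.random.default_rng(children[k])
            k += 1
            segments.append(
                EEGSegment(
                    samples=_synth_segment(rng, label, spec),
                    fs=spec.fs,
                    label=label,
                    segment_id=f"{label}{i:03d}",
                )
            )
    return segments


def write_dataset(segments: Sequence[EEGSegment], directory: str | os.PathLike) -> pd.DataFrame:
    """Write segments as Bonn text files plus a TSV manifest.

    Returns the manifest (columns ``segment_id``, ``label``, ``path``),
    which is also written to ``<directory>/manifest.tsv``.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    rows = []
    for seg in segments:
        path = directory / f"{seg.segment_id}.txt"
        write_bonn_segment(seg, path)
        rows.append({"segment_id": seg.segment_id, "label": seg.label or "", "path": str(path)})
    manifest = pd.DataFrame(rows, columns=["segment_id", "label", "path"])
    manifest.to_csv(directory / "manifest.tsv", sep="\t", index=False)
    return manifest


def read_dataset(manifest_path: str | os.PathLike, fs: float = DEFAULT_FS) -> list[EEGSegment]:
    """Read back a dataset written by :func:`write_dataset`."""
    manifest = pd.read_csv(manifest_path, sep="\t", dtype=str, keep_default_na=False)
    segments = []
    for row in manifest.itertuples(index=False):
        segments.append(
            read_bonn_segment(
                row.path, fs=fs, label=row.label or None, segment_id=row.segment_id
            )
        )
    return segments
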