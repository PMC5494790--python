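"""Epoching and the 8-dimensional max/std subband feature vector.

Segments are cut into 512-sample windows advanced by 256 samples (50 %
overlap); at 173.61 Hz that is 2.94 s windows overlapping by 1.47 s.  A
window is started every hop while its start lies inside the segment, and a
final window running past the end is zero-padded, so a 4096-sample segment
yields 16 epochs and 100 segments per subset yield 1600.

Each epoch is decomposed into the A3/D3/D2/D1 subbands and summarised by
the signed maximum and the population standard deviation of each subband,
giving the feature vector

    (max A3, std A3, max D3, std D3, max D2, std D2, max D1, std D1).

Features are deliberately not standardised: kernel widths in the
classifier are tuned on the raw µV scale.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .dwt import Boundary, SubbandSet, bandpass_0_32, decompose3
from .io_synth import EEGSegment

__all__ = [
    "Epoch",
    "FeatureVector",
    "PipelineConfig",
    "FEATURE_NAMES",
    "make_epochs",
    "extract_features",
    "build_dataset",
    "features_to_frame",
    "frame_to_arrays",
]

FEATURE_NAMES: tuple[str, ...] = (
    "max_A3", "std_A3", "max_D3", "std_D3", "max_D2", "std_D2", "max_D1", "std_D1",
)


@dataclass(frozen=True)
class Epoch:
    """One analysis window of a segment."""

    samples: np.ndarray
    segment_id: str
    start_index: int
    label: str | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "samples", np.asarray(self.samples, dtype=float))

    @property
    def epoch_id(self) -> str:
        return f"{self.segment_id}:{self.start_index}"


@dataclass(frozen=True)
class FeatureVector:
    """The 8 subband features of one epoch, plus its label."""

    values: np.ndarray
    label: str | None = None
    epoch_id: str = ""

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        if values.shape != (8,):
            raise ValueError(f"expected 8 features, got shape {values.shape}")
        if not np.all(np.isfinite(values)):
            raise ValueError("features must be finite")
        object.__setattr__(self, "values", values)


@dataclass(frozen=True)
class PipelineConfig:
    """Feature-extraction pipeline settings.

    ``pad_final=True`` starts a window every ``hop`` samples while the
    start is inside the segment and zero-pads the last one; ``False``
    keeps only full windows.  ``signed_max=False`` switches the maximum to
    the absolute-value convention; ``population_std=False`` switches the
    standard deviation to the n-1 (sample) form.  ``zscore`` standardises
    each feature column over the dataset (off by default: raw scale).
    """

    window: int = 512
    hop: int = 256
    bandpass: bool = True
    bandpass_order: int = 4
    boundary: Boundary = "periodic"
    pad_final: bool = True
    signed_max: bool = True
    population_std: bool = True
    zscore: bool = False

    def __post_init__(self) -> None:
        if self.window <= 0 or self.hop <= 0:
            raise ValueError("window and hop must be positive")
        if self.hop > self.window:
            raise ValueError("hop must not exceed window")


def make_epochs(
    segment: EEGSegment, window: int = 512, hop: int = 256, pad_final: bool = True
) -> list[Epoch]:
    """Slice a segment into overlapping windows.

    Windows start at 0, hop, 2*hop, ... for every start strictly inside the
    segment; adjacent epochs share ``window - hop`` samples.  With
    ``pad_final`` a window extending past the end is zero-padded to full
    length, so the epoch count is ``ceil(len(segment) / hop)``.
    """
    if window <= 0 or hop <= 0:
        raise ValueError("window and hop must be positive")
    x = segment.samples
    epochs: list[Epoch] = []
    for start in range(0, len(x), hop):
        chunk = x[start : start + window]
        if chunk.size < window:
            if not pad_final:
                continue
            chunk = np.concatenate([chunk, np.zeros(window - chunk.size)])
        epochs.append(
            Epoch(
                samples=chunk,
                segment_id=segment.segment_id,
                start_index=start,
                label=segment.label,
            )
        )
    return epochs


def extract_features(
    subbands: SubbandSet,
    label: str | None = None,
    signed_max: bool = True,
    population_std: bool = True,
) -> FeatureVector:
    """Maximum and standard deviation of each subband, A3 first.

    The maximum is the signed maximum of the raw coefficients and the
    standard deviation uses the population (n-denominator) formula; both
    conventions are switchable.
    """
    values = []
    for name, band in subbands.bands().items():
        if band.size == 0:
            raise ValueError(f"subband {name} is empty")
        mx = float(np.max(band if signed_max else np.abs(band)))
        sd = float(np.std(band, ddof=0 if population_std else 1))
        values.extend((mx, sd))
    return FeatureVector(values=np.array(values), label=label, epoch_id=subbands.epoch_id)


def build_dataset(
    segments: Iterable[EEGSegment],
    config: PipelineConfig = PipelineConfig(),
    require_labels: bool = True,
) -> list[FeatureVector]:
    """Run band-pass -> epoch -> decompose -> extract over segments.

    Band-limiting is applied to the whole segment before epoching.  The
    output has one feature vector per epoch, labels carried through; the
    path is fully deterministic.
    """
    feats: list[FeatureVector] = []
    for segment in segments:
        if require_labels and segment.label is None:
            raise ValueError(f"segment {segment.segment_id!r} is unlabelled")
        seg = bandpass_0_32(segment, order=config.bandpass_order) if config.bandpass else segment
        for epoch in make_epochs(seg, config.window, config.hop, config.pad_final):
            sb = decompose3(epoch.samples, epoch_id=epoch.epoch_id, boundary=config.boundary)
            feats.append(
                extract_features(
                    sb,
                    label=epoch.label,
                    signed_max=config.signed_max,
                    population_std=config.population_std,
                )
            )
    if config.zscore and feats:
        X = np.array([f.values for f in feats])
        mu, sd = X.mean(axis=0), X.std(axis=0)
        sd[sd == 0] = 1.0
        feats = [
            FeatureVector(values=(f.values - mu) / sd, label=f.label, epoch_id=f.epoch_id)
            for f in feats
        ]
    return feats


def features_to_frame(features: Sequence[FeatureVector]) -> pd.DataFrame:
    """Feature table with columns epoch_id, segment_id, label, f1..f8."""
    rows = []
    for f in features:
        segment_id = f.epoch_id.rsplit(":", 1)[0] if ":" in f.epoch_id else f.epoch_id
        row = {"epoch_id": f.epoch_id, "segment_id": segment_id, "label": f.label or ""}
        row.update({f"f{i + 1}": v for i, v in enumerate(f.values)})
        rows.append(row)
    cols = ["epoch_id", "segment_id", "label"] + [f"f{i + 1}" for i in range(8)]
    return pd.DataFrame(rows, columns=cols)


def frame_to_arrays(frame: pd.DataFrame) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Split a feature table into (X, labels, epoch_ids) arrays."""
    X = frame[[f"f{i + 1}" for i in range(8)]].to_numpy(dtype=float)
    y = frame["label"].to_numpy(dtype=object)
    ids = frame["epoch_id"].to_numpy(dtype=object)
    return X, y, ids
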