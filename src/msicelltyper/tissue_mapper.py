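"""Pixel-wise tissue typing: offline batch maps and streaming recognition.

Every measured pixel is pushed through the fixed preprocessing chain
(RMS-normalize, bin on the model's grid) and classified by the recognition
model. The result is a :class:`LabelMap` whose per-label area percentages
are taken over the measured region only (unmeasured pixels are excluded
from the 100% denominator).

Streaming mode classifies spectra one at a time as they arrive — the
per-laser-spot use case — and is stateless per spot, so its labels are
identical to the batch map on the same spectra.
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass, field
from typing import Iterable, Iterator

import numpy as np
import pandas as pd

from .msio import CentroidSpectrum, SpectrumImage
from .preprocess import bin_spectrum, rms_normalize
from .recognizer import RecognitionModel, _classify_matrix

logger = logging.getLogger(__name__)

UNMEASURED = "UNMEASURED"

__all__ = ["UNMEASURED", "LabelMap", "StreamEvent", "classify_image",
           "area_percentages", "stream_classify"]


@dataclass
class LabelMap:
    """Per-pixel class assignment over a tissue image with area percentages."""

    shape: tuple[int, int]
    labels: np.ndarray
    pixel_um: float
    percentages: pd.Series = field(repr=False)

    def __post_init__(self) -> None:
        if self.labels.shape != self.shape:
            raise ValueError("label matrix shape mismatch")
        total = float(self.percentages.sum())
        if self.percentages.size and abs(total - 100.0) > 0.01:
            raise ValueError(f"label percentages sum to {total}, not 100")

    @property
    def measured(self) -> np.ndarray:
        return self.labels != UNMEASURED


def _feature_row(model: RecognitionModel, spec: CentroidSpectrum) -> np.ndarray | None:
    """Preprocess one pixel spectrum; None when empty/all-zero (unmeasured)."""
    if len(spec) == 0 or spec.tic == 0.0:
        return None
    return bin_spectrum(rms_normalize(spec), model.grid).values


def area_percentages(label_map: LabelMap) -> pd.Series:
    """Label shares (%) of the measured region, in descending order."""
    labels = label_map.labels[label_map.measured]
    if labels.size == 0:
        raise ValueError("label map has no measured pixels")
    counts = pd.Series(labels.ravel()).value_counts()
    pct = 100.0 * counts / counts.sum()
    return pct.sort_values(ascending=False)


def classify_image(
    model: RecognitionModel, image: SpectrumImage, mode: str = "outlier"
) -> LabelMap:
    """Classify every measured pixel of a tissue image.

    Absent or all-zero pixels become ``UNMEASURED``; percentages are over
    measured pixels only.
    """
    rows, cols = image.shape
    out = np.full((rows, cols), UNMEASURED, dtype=object)
    coords, feats = [], []
    for coord, spec in image.iter_spectra():
        x = _feature_row(model, spec)
        if x is not None:
            coords.append(coord)
            feats.append(x)
    if not feats:
        raise ValueError("image has no measured (nonzero) pixels")
    labels, _ = _classify_matrix(model, np.array(feats), mode)
    for coord, label in zip(coords, labels):
        out[coord] = label
    lm = LabelMap(
        shape=(rows, cols),
        labels=out,
        pixel_um=image.pixel_um,
        percentages=pd.Series(dtype=float),
    )
    lm.percentages = area_percentages(lm)
    return lm


@dataclass
class StreamEvent:
    """One classified laser spot: label, per-spot latency, source coordinate."""

    index: int
    coordinate: tuple[int, int] | None
    label: str | None
    latency_s: float
    error: str | None = None


def stream_classify(
    model: RecognitionModel,
    spectra: Iterable[CentroidSpectrum],
    mode: str = "outlier",
) -> Iterator[StreamEvent]:
    """Classify spectra one by one as they arrive, yielding per-spot events.

    Each spectrum is classified independently (stateless per spot) and its
    event emitted before the next spectrum is consumed, so replaying an
    image through the stream reproduces the batch label map exactly.
    Malformed records are logged and skipped; the stream continues.
    """
    for i, spec in enumerate(spectra):
        t0 = time.perf_counter()
        try:
            x = _feature_row(model, spec)
            if x is None:
                label = UNMEASURED
            else:
                labels, _ = _classify_matrix(model, x[None, :], mode)
                label = str(labels[0])
        except Exception as err:  # malformed record: log, keep streaming
            logger.warning("stream record %d failed: %s", i, err)
            yield StreamEvent(
                index=i,
                coordinate=getattr(spec, "coordinate", None),
                label=None,
                latency_s=time.perf_counter() - t0,
                error=str(err),
            )
            continue
        yield StreamEvent(
            index=i,
            coordinate=spec.coordinate,
            label=label,
            latency_s=time.perf_counter() - t0,
        )


def replay_image(image: SpectrumImage) -> Iterator[CentroidSpectrum]:
    """Yield an image's measured spectra in row-major acquisition order."""
    for _, spec in image.iter_spectra():
        yield spec
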