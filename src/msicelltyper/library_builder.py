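"""Build the labeled single-cell spectral library from images plus ROI sets.

Each cell ROI becomes one library row: the RMS-normalized, binned mean
spectrum of its pixels, tagged with cell-line label, receptor-subtype label,
slide id and cell id. Per slide, cells can first be ranked by total ion
count and only the highest-intensity ones kept.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .msio import SpectrumImage
from .preprocess import BinGrid, FeatureVector, roi_mean_spectrum

logger = logging.getLogger(__name__)

__all__ = [
    "CellROI",
    "SpectralLibrary",
    "select_high_intensity_cells",
    "build_library",
    "repeatability_report",
]


@dataclass(frozen=True)
class CellROI:
    """One cell's region of interest: pixel set plus labels."""

    cell_id: str
    pixels: frozenset
    line_label: str
    subtype_label: str = "NA"
    slide_id: str = "slide_1"

    def __post_init__(self) -> None:
        if not self.pixels:
            raise ValueError(f"ROI {self.cell_id!r} has no pixels")
        if not self.cell_id or not self.line_label:
            raise ValueError("cell id and line label must be non-empty")


@dataclass
class SpectralLibrary:
    """Matrix of per-cell binned mean spectra with labels — the training corpus."""

    grid: BinGrid
    X: np.ndarray
    line_labels: np.ndarray
    subtype_labels: np.ndarray
    slide_ids: np.ndarray
    cell_ids: np.ndarray

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        if self.X.ndim != 2 or self.X.shape[1] != self.grid.n_bins:
            raise ValueError(
                f"library matrix shape {self.X.shape} does not match grid "
                f"({self.grid.n_bins} bins)"
            )
        n = self.X.shape[0]
        for name in ("line_labels", "subtype_labels", "slide_ids", "cell_ids"):
            arr = np.asarray(getattr(self, name), dtype=object)
            if arr.shape != (n,):
                raise ValueError(f"{name} must have one entry per library row")
            setattr(self, name, arr)

    def __len__(self) -> int:
        return self.X.shape[0]

    @property
    def classes(self) -> list[str]:
        return sorted(set(self.line_labels))

    @property
    def subtypes(self) -> list[str]:
        return sorted(set(self.subtype_labels))

    def labels(self, level: str) -> np.ndarray:
        """Row labels at ``'cell_line'`` or ``'subtype'`` level."""
        if level == "cell_line":
            return self.line_labels
        if level == "subtype":
            return self.subtype_labels
        raise ValueError(f"unknown label level {level!r}")

    def subset(self, index: np.ndarray) -> "SpectralLibrary":
        return SpectralLibrary(
            grid=self.grid,
            X=self.X[index],
            line_labels=self.line_labels[index],
            subtype_labels=self.subtype_labels[index],
            slide_ids=self.slide_ids[index],
            cell_ids=self.cell_ids[index],
        )

    def sorted_by_cell_id(self) -> "SpectralLibrary":
        return self.subset(np.argsort(self.cell_ids.astype(str), kind="stable"))

    def to_frame(self) -> pd.DataFrame:
        cols = [f"bin_{i}" for i in range(self.grid.n_bins)]
        df = pd.DataFrame(self.X, columns=cols)
        df.insert(0, "cell_id", self.cell_ids)
        df.insert(1, "line_label", self.line_labels)
        df.insert(2, "subtype_label", self.subtype_labels)
        df.insert(3, "slide_id", self.slide_ids)
        return df

    def save_csv(self, path) -> None:
        df = self.to_frame()
        df.attrs = {}
        header = (
            f"# msicelltyper-library v1 lo={self.grid.lo!r} hi={self.grid.hi!r} "
            f"width={self.grid.width!r}\n"
        )
        with open(path, "w") as fh:
            fh.write(header)
            df.to_csv(fh, index=False)

    @classmethod
    def load_csv(cls, path) -> "SpectralLibrary":
        with open(path) as fh:
            first = fh.readline()
            kv = dict(
                tok.split("=", 1) for tok in first.split() if "=" in tok
            )
            grid = BinGrid(
                lo=float(kv.get("lo", 600.0)),
                hi=float(kv.get("hi", 950.0)),
                width=float(kv.get("width", 0.2)),
            )
            df = pd.read_csv(fh)
        bins = [c for c in df.columns if c.startswith("bin_")]
        return cls(
            grid=grid,
            X=df[bins].to_numpy(float),
            line_labels=df["line_label"].to_numpy(object),
            subtype_labels=df["subtype_label"].to_numpy(object),
            slide_ids=df["slide_id"].to_numpy(object),
            cell_ids=df["cell_id"].astype(str).to_numpy(object),
        )


def _check_disjoint(rois: list[CellROI]) -> None:
    seen: dict = {}
    for roi in rois:
        for p in roi.pixels:
            if p in seen:
                raise ValueError(
                    f"ROIs {seen[p]!r} and {roi.cell_id!r} overlap at pixel {p}: "
                    "a pixel may contribute to only one library cell"
                )
            seen[p] = roi.cell_id


def select_high_intensity_cells(
    image: SpectrumImage, rois: list[CellROI], keep: int | float
) -> list[CellROI]:
    """Keep the ``keep`` highest-intensity ROIs, ranked by raw total ion count.

    ``keep`` may be a count or a fraction of the ROI list. TIC is summed raw
    (pre-normalization) intensity over the ROI's pixels; ties break by
    lexicographic cell id.
    """
    _check_disjoint(rois)
    if isinstance(keep, float) and 0 < keep <= 1:
        n_keep = max(1, int(round(keep * len(rois))))
    else:
        n_keep = int(keep)
    if n_keep > len(rois):
        raise ValueError(f"asked to keep {n_keep} of {len(rois)} ROIs")
    tics = []
    for roi in rois:
        tic = sum(image.spectra[p].tic for p in roi.pixels if p in image.spectra)
        tics.append(tic)
    ranked = sorted(zip(rois, tics), key=lambda t: (-t[1], t[0].cell_id))
    return [roi for roi, _ in ranked[:n_keep]]


def build_library(
    batches: list[tuple[SpectrumImage, list[CellROI]]],
    grid: BinGrid | None = None,
) -> SpectralLibrary:
    """One library row per ROI: its mean binned spectrum plus labels.

    Batches typically correspond to slides measured on different days; ROIs
    within a batch must be disjoint. Classes with fewer than two rows are
    allowed here but flagged, since model fitting will refuse them.
    """
    grid = grid if grid is not None else BinGrid()
    rows, lines, subs, slides, cells = [], [], [], [], []
    for image, rois in batches:
        _check_disjoint(rois)
        for roi in rois:
            vec: FeatureVector = roi_mean_spectrum(image, roi.pixels, grid)
            rows.append(vec.values)
            lines.append(roi.line_label)
            subs.append(roi.subtype_label)
            slides.append(roi.slide_id)
            cells.append(roi.cell_id)
    if not rows:
        raise ValueError("no ROIs supplied")
    lib = SpectralLibrary(
        grid=grid,
        X=np.array(rows),
        line_labels=np.array(lines, dtype=object),
        subtype_labels=np.array(subs, dtype=object),
        slide_ids=np.array(slides, dtype=object),
        cell_ids=np.array(cells, dtype=object),
    )
    if len(set(lib.cell_ids)) != len(lib):
        raise ValueError("duplicate cell ids across batches")
    counts = pd.Series(lib.line_labels).value_counts()
    small = counts[counts < 2]
    if len(small):
        warnings.warn(
            f"classes with fewer than 2 cells (model fitting will refuse them): "
            f"{', '.join(small.index)}",
            stacklevel=2,
        )
    return lib


def repeatability_report(library: SpectralLibrary) -> pd.DataFrame:
    """Mean pairwise cosine similarity of library rows, within and across slides.

    One row per class with columns ``within_slide`` and ``across_slide``;
    a class measured on a single slide gets NaN across slides and is flagged
    in the ``single_slide`` column.
    """
    records = []
    for cls in library.classes:
        idx = np.where(library.line_labels == cls)[0]
        X = library.X[idx]
        norms = np.linalg.norm(X, axis=1)
        unit = X / norms[:, None]
        sim = unit @ unit.T
        slides = library.slide_ids[idx]
        within, across = [], []
        for i in range(len(idx)):
            for j in range(i + 1, len(idx)):
                (within if slides[i] == slides[j] else across).append(sim[i, j])
        records.append(
            {
                "class": cls,
                "n_cells": len(idx),
                "within_slide": float(np.mean(within)) if within else np.nan,
                "across_slide": float(np.mean(across)) if across else np.nan,
                "single_slide": len(set(slides)) < 2,
            }
        )
    return pd.DataFrame.from_records(records).set_index("class")
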