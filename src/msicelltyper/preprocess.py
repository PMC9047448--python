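"""Spectral preprocessing: RMS normalization, mass binning, ROI mean spectra.

The chain applied to every cell or pixel before modeling is fixed:

1. divide the centroid intensities by their root mean square (RMS),
2. accumulate centroids onto a uniform bin grid over the model mass range
   (default m/z 600–950 at 0.2 Da per bin, i.e. 1750 bins),
3. for multi-pixel ROIs, average the binned vectors element-wise.

The order is normalize → bin → mean, and the ROI mean is *not* re-normalized
afterward; normalizing after averaging gives a different (and here
unsupported) statistic.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable

import numpy as np

from .msio import CentroidSpectrum, SpectrumImage

__all__ = ["BinGrid", "FeatureVector", "rms_normalize", "bin_spectrum", "roi_mean_spectrum"]


@dataclass(frozen=True)
class BinGrid:
    """Uniform half-open mass bins ``[lo + i*width, lo + (i+1)*width)``.

    Defaults cover m/z 600–950 at 0.2 Da, giving 1750 bins. ``(hi - lo)``
    must be an integral number of bin widths.
    """

    lo: float = 600.0
    hi: float = 950.0
    width: float = 0.2

    def __post_init__(self) -> None:
        if not self.lo < self.hi:
            raise ValueError("mass range lo must be < hi")
        if self.width <= 0:
            raise ValueError("bin width must be positive")
        n = (self.hi - self.lo) / self.width
        if abs(n - round(n)) > 1e-6:
            raise ValueError(
                f"mass range {self.hi - self.lo} is not an integral number of "
                f"bins of width {self.width}"
            )

    @property
    def n_bins(self) -> int:
        return int(round((self.hi - self.lo) / self.width))

    def bin_index(self, mz: np.ndarray) -> np.ndarray:
        """Bin index per m/z; -1 for centroids outside ``[lo, hi)``."""
        mz = np.asarray(mz, dtype=float)
        idx = np.floor((mz - self.lo) / self.width).astype(int)
        idx[(mz < self.lo) | (mz >= self.hi)] = -1
        # guard against float round-off at the upper edge
        idx[idx >= self.n_bins] = -1
        return idx

    def centers(self) -> np.ndarray:
        return self.lo + (np.arange(self.n_bins) + 0.5) * self.width


@dataclass
class FeatureVector:
    """A binned spectrum on a :class:`BinGrid` plus its provenance."""

    grid: BinGrid
    values: np.ndarray
    provenance: str | tuple | None = None
    label: str | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (self.grid.n_bins,):
            raise ValueError(
                f"feature vector length {self.values.shape} does not match "
                f"grid bin count {self.grid.n_bins}"
            )


def rms_normalize(spectrum: CentroidSpectrum) -> CentroidSpectrum:
    """Divide intensities by their root mean square; m/z values unchanged.

    The RMS is taken over the detected centroids only, so the output
    intensity vector has RMS exactly 1. Raises on an all-zero spectrum.
    """
    rms = float(np.sqrt(np.mean(np.square(spectrum.intensity)))) if len(spectrum) else 0.0
    if rms == 0.0:
        raise ValueError("cannot RMS-normalize an all-zero or empty spectrum")
    return CentroidSpectrum(
        spectrum.mz, spectrum.intensity / rms, spectrum.coordinate, spectrum.instrument
    )


def bin_spectrum(spectrum: CentroidSpectrum, grid: BinGrid) -> FeatureVector:
    """Sum centroid intensities into the half-open bins of ``grid``.

    Centroids outside ``[lo, hi)`` are dropped; within a bin intensities are
    summed, so total binned signal equals total in-range signal.
    """
    values = np.zeros(grid.n_bins)
    idx = grid.bin_index(spectrum.mz)
    keep = idx >= 0
    np.add.at(values, idx[keep], spectrum.intensity[keep])
    return FeatureVector(grid=grid, values=values, provenance=spectrum.coordinate)


def roi_mean_spectrum(
    image: SpectrumImage,
    roi_pixels: Iterable[tuple[int, int]],
    grid: BinGrid,
) -> FeatureVector:
    """Mean binned spectrum of an ROI: per-pixel RMS-normalize, bin, average.

    Pixels whose spectrum is empty or all-zero are excluded with a warning;
    an ROI with no usable pixel is an error.
    """
    import logging

    roi_pixels = list(roi_pixels)
    if not roi_pixels:
        raise ValueError("ROI is empty")
    vectors = []
    for coord in roi_pixels:
        if coord not in image.spectra:
            raise KeyError(f"ROI pixel {coord} is not measured in the image")
        spec = image.spectra[coord]
        if len(spec) == 0 or spec.tic == 0.0:
            logging.getLogger(__name__).warning(
                "ROI pixel %s has an all-zero spectrum; excluded from the mean", coord
            )
            continue
        vectors.append(bin_spectrum(rms_normalize(spec), grid).values)
    if not vectors:
        raise ValueError("all ROI pixels have all-zero spectra")
    return FeatureVector(grid=grid, values=np.mean(vectors, axis=0), provenance=tuple(roi_pixels[0]))
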