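"""Reading and writing of MSI images, ROI tables, label maps and recognition models.

Two image formats are supported:

* **imzML** (processed mode only) via :mod:`pyimzml` — per-pixel centroid
  lists, the open interchange standard for mass spectrometry imaging.
* A plain **CSV spectrum table** with columns ``row,col,mz,intensity`` and an
  optional leading comment line carrying pixel size and grid shape, so that a
  full :class:`SpectrumImage` survives a text round trip.

Conventions
-----------
Pixel coordinates are 0-based ``(row, col)``, row-major. imzML stores 1-based
``x``/``y``; on write we map ``x = col + 1``, ``y = row + 1`` and invert on
read. All writers go through a temporary file followed by an atomic rename,
so a crashed write never leaves a truncated file behind.
"""

from __future__ import annotations

import json
import logging
import os
import tempfile
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Mapping

import numpy as np

logger = logging.getLogger(__name__)

MODEL_FORMAT_VERSION = 1

__all__ = [
    "CentroidSpectrum",
    "SpectrumImage",
    "read_image",
    "write_image",
    "read_roi_table",
    "write_roi_table",
    "read_label_matrix",
    "write_label_matrix",
    "read_model",
    "write_model",
]


@dataclass
class CentroidSpectrum:
    """A centroided mass spectrum: peak apex positions and intensities.

    Parameters
    ----------
    mz
        Strictly ascending m/z values in Da.
    intensity
        Nonnegative intensities (arbitrary units), same length as ``mz``.
    coordinate
        Optional ``(row, col)`` pixel coordinate within an image.
    instrument
        Optional free-text instrument identifier.
    """

    mz: np.ndarray
    intensity: np.ndarray
    coordinate: tuple[int, int] | None = None
    instrument: str | None = None

    def __post_init__(self) -> None:
        self.mz = np.asarray(self.mz, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.mz.ndim != 1 or self.intensity.ndim != 1:
            raise ValueError("mz and intensity must be 1-D vectors")
        if self.mz.size != self.intensity.size:
            raise ValueError(
                f"mz and intensity lengths differ ({self.mz.size} vs {self.intensity.size})"
            )
        if self.mz.size > 1 and not np.all(np.diff(self.mz) > 0):
            raise ValueError("mz values must be strictly ascending")
        if np.any(self.intensity < 0):
            raise ValueError("intensities must be nonnegative")

    def __len__(self) -> int:
        return int(self.mz.size)

    @property
    def tic(self) -> float:
        """Total ion count: the summed intensity of all centroids."""
        return float(self.intensity.sum())

    def scaled(self, factor: float) -> "CentroidSpectrum":
        return CentroidSpectrum(
            self.mz, self.intensity * factor, self.coordinate, self.instrument
        )


@dataclass
class SpectrumImage:
    """A grid of per-pixel centroid spectra plus acquisition metadata.

    ``spectra`` maps 0-based ``(row, col)`` coordinates to
    :class:`CentroidSpectrum`; pixels absent from the mapping are unmeasured.
    """

    pixel_um: float
    shape: tuple[int, int]
    spectra: dict[tuple[int, int], CentroidSpectrum] = field(default_factory=dict)
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.pixel_um <= 0:
            raise ValueError("pixel size must be positive")
        rows, cols = self.shape
        for (r, c) in self.spectra:
            if not (0 <= r < rows and 0 <= c < cols):
                raise ValueError(f"coordinate {(r, c)} outside grid {self.shape}")

    @property
    def n_pixels(self) -> int:
        return len(self.spectra)

    def coordinates(self) -> list[tuple[int, int]]:
        """Measured coordinates in row-major order."""
        return sorted(self.spectra)

    def iter_spectra(self) -> Iterator[tuple[tuple[int, int], CentroidSpectrum]]:
        for coord in self.coordinates():
            yield coord, self.spectra[coord]


# ---------------------------------------------------------------------------
# atomic write helper


class _AtomicPath:
    """Context manager yielding a temp path renamed onto the target on success."""

    def __init__(self, target: Path):
        self.target = Path(target)
        fd, tmp = tempfile.mkstemp(
            dir=self.target.parent, prefix=f".{self.target.name}.", suffix=".tmp"
        )
        os.close(fd)
        self.tmp = Path(tmp)

    def __enter__(self) -> Path:
        return self.tmp

    def __exit__(self, exc_type, exc, tb) -> None:
        if exc_type is None:
            os.replace(self.tmp, self.target)
        else:
            self.tmp.unlink(missing_ok=True)


# ---------------------------------------------------------------------------
# CSV spectrum-table dialect

_CSV_HEADER = "row,col,mz,intensity"


def _write_image_csv(image: SpectrumImage, path: Path) -> None:
    with _AtomicPath(path) as tmp:
        with open(tmp, "w") as fh:
            rows, cols = image.shape
            fh.write(
                f"# msicelltyper-spectra v1 pixel_um={image.pixel_um!r} "
                f"rows={rows} cols={cols}\n"
            )
            fh.write(_CSV_HEADER + "\n")
            for (r, c), spec in image.iter_spectra():
                for mz, inten in zip(spec.mz, spec.intensity):
                    fh.write(f"{r},{c},{float(mz)!r},{float(inten)!r}\n")


def _read_image_csv(path: Path) -> SpectrumImage:
    pixel_um = 1.0
    shape: tuple[int, int] | None = None
    per_pixel: dict[tuple[int, int], list[tuple[float, float]]] = {}
    with open(path) as fh:
        lines = fh.readlines()
    start = 0
    if lines and lines[0].startswith("#"):
        for tok in lines[0].split():
            if tok.startswith("pixel_um="):
                pixel_um = float(tok.split("=", 1)[1])
            elif tok.startswith("rows="):
                shape = (int(tok.split("=", 1)[1]), 0 if shape is None else shape[1])
            elif tok.startswith("cols="):
                shape = ((0 if shape is None else shape[0]), int(tok.split("=", 1)[1]))
        start = 1
    if start < len(lines) and lines[start].strip() == _CSV_HEADER:
        start += 1
    elif start < len(lines):
        raise ValueError(
            f"{path}: line {start + 1}: expected header '{_CSV_HEADER}', "
            f"got {lines[start].strip()!r}"
        )
    for i, line in enumerate(lines[start:], start=start + 1):
        line = line.strip()
        if not line:
            continue
        parts = line.split(",")
        if len(parts) != 4:
            raise ValueError(f"{path}: line {i}: expected 4 comma-separated fields")
        try:
            r, c = int(parts[0]), int(parts[1])
            mz, inten = float(parts[2]), float(parts[3])
        except ValueError as err:
            raise ValueError(f"{path}: line {i}: {err}") from None
        per_pixel.setdefault((r, c), []).append((mz, inten))

    spectra = {}
    for coord, peaks in per_pixel.items():
        peaks.sort()
        mzs = np.array([p[0] for p in peaks])
        ints = np.array([p[1] for p in peaks])
        spectra[coord] = CentroidSpectrum(mzs, ints, coordinate=coord)
    if shape is None or shape[0] == 0 or shape[1] == 0:
        if per_pixel:
            shape = (
                max(r for r, _ in per_pixel) + 1,
                max(c for _, c in per_pixel) + 1,
            )
        else:
            shape = (0, 0)
    return SpectrumImage(pixel_um=pixel_um, shape=shape, spectra=spectra)


# ---------------------------------------------------------------------------
# imzML


# degenerate zero-pixel images: pyimzml cannot emit or parse an empty
# spectrum list, so we write a minimal processed-mode document ourselves
_EMPTY_IMZML = """<?xml version="1.0" encoding="ISO-8859-1"?>
<mzML xmlns="http://psi.hupo.org/ms/mzml" version="1.1">
  <fileDescription>
    <fileContent>
      <cvParam cvRef="IMS" accession="IMS:1000031" name="processed" value=""/>
      <cvParam cvRef="IMS" accession="IMS:1000080" name="universally unique identifier" value="{{{uuid}}}"/>
    </fileContent>
  </fileDescription>
  <run id="run0">
    <spectrumList count="0"></spectrumList>
  </run>
</mzML>
"""


def _write_image_imzml(image: SpectrumImage, path: Path) -> None:
    from pyimzml.ImzMLWriter import ImzMLWriter

    path = Path(path)
    if image.n_pixels == 0:
        import uuid as uuid_mod

        uid = uuid_mod.uuid4()
        with _AtomicPath(path) as tmp:
            tmp.write_text(_EMPTY_IMZML.format(uuid=uid))
        with _AtomicPath(path.with_suffix(".ibd")) as tmp:
            tmp.write_bytes(uid.bytes)
        sidecar = {"pixel_um": image.pixel_um, "shape": list(image.shape)}
        with _AtomicPath(path.with_suffix(".meta.json")) as tmp:
            tmp.write_text(json.dumps(sidecar))
        return
    # pyimzml writes <base>.imzML plus <base>.ibd; stage both under a temp
    # basename in the target directory, then rename the pair into place.
    tmp_base = path.parent / f".{path.stem}.tmp{os.getpid()}"
    try:
        with ImzMLWriter(
            str(tmp_base) + ".imzML",
            mz_dtype=np.float64,
            intensity_dtype=np.float64,
            mode="processed",
            spec_type="centroid",
        ) as writer:
            for (r, c), spec in image.iter_spectra():
                writer.addSpectrum(spec.mz, spec.intensity, (c + 1, r + 1, 1))
        os.replace(str(tmp_base) + ".ibd", path.with_suffix(".ibd"))
        os.replace(str(tmp_base) + ".imzML", path)
    finally:
        for suffix in (".imzML", ".ibd"):
            Path(str(tmp_base) + suffix).unlink(missing_ok=True)
    sidecar = {"pixel_um": image.pixel_um, "shape": list(image.shape)}
    with _AtomicPath(path.with_suffix(".meta.json")) as tmp:
        tmp.write_text(json.dumps(sidecar))


def _read_image_imzml(path: Path) -> SpectrumImage:
    from pyimzml.ImzMLParser import ImzMLParser

    text_head = Path(path).read_text()[:4096]
    if 'spectrumList count="0"' in text_head:
        pixel_um, shape = 1.0, (0, 0)
        sidecar = Path(path).with_suffix(".meta.json")
        if sidecar.exists():
            meta = json.loads(sidecar.read_text())
            pixel_um = float(meta.get("pixel_um", 1.0))
            shape = tuple(meta.get("shape", (0, 0)))
        return SpectrumImage(pixel_um=pixel_um, shape=shape, spectra={})
    parser = ImzMLParser(str(path))
    try:
        params = parser.metadata.file_description.param_by_name
        if "continuous" in params and "processed" not in params:
            raise ValueError(
                f"{path}: continuous-mode imzML is not supported; centroid the "
                "data and re-export in processed mode"
            )
    except AttributeError:  # pragma: no cover - older pyimzml metadata layout
        pass

    pixel_um, shape = 1.0, None
    sidecar = Path(path).with_suffix(".meta.json")
    if sidecar.exists():
        meta = json.loads(sidecar.read_text())
        pixel_um = float(meta.get("pixel_um", 1.0))
        if "shape" in meta:
            shape = tuple(meta["shape"])
    spectra = {}
    for i, (x, y, _z) in enumerate(parser.coordinates):
        mzs, ints = parser.getspectrum(i)
        coord = (int(y) - 1, int(x) - 1)
        spectra[coord] = CentroidSpectrum(
            np.asarray(mzs, dtype=float), np.asarray(ints, dtype=float), coordinate=coord
        )
    if shape is None:
        rows = max((r for r, _ in spectra), default=-1) + 1
        cols = max((c for _, c in spectra), default=-1) + 1
        shape = (rows, cols)
    return SpectrumImage(pixel_um=pixel_um, shape=shape, spectra=spectra)


def read_image(path: str | Path, format: str | None = None) -> SpectrumImage:
    """Read a :class:`SpectrumImage` from imzML (processed mode) or CSV.

    ``format`` is inferred from the file extension when not given.
    """
    path = Path(path)
    fmt = format or ("imzml" if path.suffix.lower() == ".imzml" else "csv")
    if fmt == "imzml":
        return _read_image_imzml(path)
    if fmt == "csv":
        return _read_image_csv(path)
    raise ValueError(f"unknown image format {fmt!r}; expected 'imzml' or 'csv'")


def write_image(image: SpectrumImage, path: str | Path, format: str | None = None) -> Path:
    """Write a :class:`SpectrumImage` as processed-mode imzML or CSV."""
    path = Path(path)
    fmt = format or ("imzml" if path.suffix.lower() == ".imzml" else "csv")
    if fmt == "imzml":
        _write_image_imzml(image, path)
    elif fmt == "csv":
        _write_image_csv(image, path)
    else:
        raise ValueError(f"unknown image format {fmt!r}; expected 'imzml' or 'csv'")
    return path


# ---------------------------------------------------------------------------
# ROI tables and label matrices


def read_roi_table(path: str | Path) -> list[tuple[str, set[tuple[int, int]], str]]:
    """Read a cell ROI table (CSV columns ``cell_id,row,col,label``).

    Pixels are grouped per cell id. A pixel shared by two cells is accepted
    with a logged warning (library construction rejects overlap later);
    conflicting labels for one cell id are an error.
    """
    path = Path(path)
    pixels: dict[str, set[tuple[int, int]]] = {}
    labels: dict[str, str] = {}
    seen_pixels: dict[tuple[int, int], str] = {}
    with open(path) as fh:
        header = fh.readline().strip()
        if header != "cell_id,row,col,label":
            raise ValueError(
                f"{path}: expected header 'cell_id,row,col,label', got {header!r}"
            )
        for i, line in enumerate(fh, start=2):
            line = line.strip()
            if not line:
                continue
            parts = line.split(",")
            if len(parts) != 4:
                raise ValueError(f"{path}: line {i}: expected 4 fields")
            cell_id, r, c, label = parts[0], int(parts[1]), int(parts[2]), parts[3]
            if cell_id in labels and labels[cell_id] != label:
                raise ValueError(
                    f"{path}: line {i}: cell {cell_id!r} labeled both "
                    f"{labels[cell_id]!r} and {label!r}"
                )
            labels[cell_id] = label
            coord = (r, c)
            if coord in seen_pixels and seen_pixels[coord] != cell_id:
                logger.warning(
                    "pixel %s shared by cells %r and %r", coord, seen_pixels[coord], cell_id
                )
            seen_pixels[coord] = cell_id
            pixels.setdefault(cell_id, set()).add(coord)
    return [(cid, pixels[cid], labels[cid]) for cid in sorted(pixels)]


def write_roi_table(
    rois: list[tuple[str, set[tuple[int, int]], str]], path: str | Path
) -> Path:
    path = Path(path)
    with _AtomicPath(path) as tmp:
        with open(tmp, "w") as fh:
            fh.write("cell_id,row,col,label\n")
            for cell_id, pix, label in rois:
                for r, c in sorted(pix):
                    fh.write(f"{cell_id},{r},{c},{label}\n")
    return path


def write_label_matrix(labels: np.ndarray, path: str | Path) -> Path:
    """Write a per-pixel label matrix as CSV rows ``row,col,label``."""
    path = Path(path)
    with _AtomicPath(path) as tmp:
        with open(tmp, "w") as fh:
            fh.write("row,col,label\n")
            rows, cols = labels.shape
            for r in range(rows):
                for c in range(cols):
                    fh.write(f"{r},{c},{labels[r, c]}\n")
    return path


def read_label_matrix(path: str | Path) -> np.ndarray:
    path = Path(path)
    entries: dict[tuple[int, int], str] = {}
    with open(path) as fh:
        header = fh.readline().strip()
        if header != "row,col,label":
            raise ValueError(f"{path}: expected header 'row,col,label'")
        for line in fh:
            line = line.strip()
            if not line:
                continue
            r, c, label = line.split(",", 2)
            entries[(int(r), int(c))] = label
    rows = max((r for r, _ in entries), default=-1) + 1
    cols = max((c for _, c in entries), default=-1) + 1
    out = np.full((rows, cols), "", dtype=object)
    for (r, c), label in entries.items():
        out[r, c] = label
    return out


# ---------------------------------------------------------------------------
# model serialization (versioned JSON text format)


def write_model(model, path: str | Path) -> Path:
    """Serialize a fitted recognition model to a versioned JSON text file.

    Floats are emitted with ``repr`` round-trip precision, so every numeric
    member is restored bitwise by :func:`read_model`.
    """
    payload = {"format": "msicelltyper-model", "version": MODEL_FORMAT_VERSION}
    payload.update(model.to_mapping())
    path = Path(path)
    with _AtomicPath(path) as tmp:
        tmp.write_text(json.dumps(payload, indent=1))
    return path


def read_model(path: str | Path):
    """Load a recognition model written by :func:`write_model`."""
    from .recognizer import RecognitionModel

    path = Path(path)
    try:
        payload = json.loads(path.read_text())
    except json.JSONDecodeError as err:
        raise ValueError(f"{path}: corrupt or truncated model file: {err}") from None
    if not isinstance(payload, Mapping) or payload.get("format") != "msicelltyper-model":
        raise ValueError(f"{path}: not a msicelltyper model file")
    if payload.get("version") != MODEL_FORMAT_VERSION:
        raise ValueError(
            f"{path}: model format version {payload.get('version')!r} not supported "
            f"(expected {MODEL_FORMAT_VERSION})"
        )
    return RecognitionModel.from_mapping(payload)
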