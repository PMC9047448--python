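"""Synthetic single-cell and tissue MSI data with the structure the pipeline assumes.

No public single-cell MALDI-MSI corpus of breast-cancer lines exists with the
properties the downstream analysis needs, so this module generates one:

* a fixed 79-lipid panel in m/z 600–950 (phosphatidylcholines PC 34:1 at
  760.585 Da and PC 36:1 at 788.610 Da are always members);
* per-cell-line relative abundance profiles — every class carries the *same*
  lipids in different ratios, produced as a shared Dirichlet base profile
  modulated by sparse log-scale perturbations at both the receptor-subtype
  and the individual-line level;
* centroid spectra with multiplicative lognormal noise of a chosen
  coefficient of variation, plus sparse low-intensity off-panel background
  peaks;
* single-cell images (5 µm pixels, non-overlapping disk-shaped cells of
  20–150 µm diameter) and tissue images (30 µm pixels, one dominant tumor
  class, a contiguous necrotic subregion of low-intensity distorted spectra,
  background border).

Every generator is a pure function of its arguments including the seed.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass, field

import numpy as np

from .msio import CentroidSpectrum, SpectrumImage

SUBTYPES = ("TRIPLE_NEG", "HER2_POS", "ER_PR_POS")
"""Receptor subtypes: triple negative, HER2+, ER+PR+ (round-robin over lines)."""

NECROTIC = "NECROTIC"
BACKGROUND = "BACKGROUND"

__all__ = [
    "SUBTYPES",
    "NECROTIC",
    "BACKGROUND",
    "LipidPanel",
    "CellLineProfile",
    "GroundTruth",
    "default_panel",
    "make_profiles",
    "synth_spectrum",
    "synth_background_spectrum",
    "synth_cell_image",
    "synth_tissue_image",
    "synthetic_library",
]


@dataclass(frozen=True)
class LipidPanel:
    """An ordered panel of named lipid species with [M+H]+ centroid masses."""

    entries: tuple[tuple[str, float], ...]

    def __post_init__(self) -> None:
        names = [n for n, _ in self.entries]
        if len(set(names)) != len(names):
            raise ValueError("lipid names must be unique")
        mzs = [m for _, m in self.entries]
        if any(not (600.0 <= m < 950.0) for m in mzs):
            raise ValueError("all panel masses must lie in [600, 950)")
        if any(b <= a for a, b in zip(mzs, mzs[1:])):
            raise ValueError("panel must be sorted strictly ascending by m/z")

    def __len__(self) -> int:
        return len(self.entries)

    @property
    def names(self) -> list[str]:
        return [n for n, _ in self.entries]

    @property
    def mz(self) -> np.ndarray:
        return np.array([m for _, m in self.entries])


def default_panel() -> LipidPanel:
    """The default 79-lipid synthetic panel spanning m/z 600–950.

    PC 34:1 (760.585) and PC 36:1 (788.610) carry their literature masses;
    the remaining 77 species are synthetic stand-ins at fixed, mutually
    separated masses (≥ 0.3 Da apart) drawn once from a hard-coded stream.
    """
    anchors = [("PC 34:1", 760.585), ("PC 36:1", 788.610)]
    rng = np.random.default_rng(790331)
    masses = [m for _, m in anchors]
    while len(masses) < 79:
        m = round(float(rng.uniform(601.0, 949.0)), 3)
        if min(abs(m - x) for x in masses) >= 0.3:
            masses.append(m)
    entries = []
    anchor_by_mass = dict((m, n) for n, m in anchors)
    for m in sorted(masses):
        entries.append((anchor_by_mass.get(m, f"LIP {m:.3f}"), m))
    return LipidPanel(tuple(entries))


@dataclass(frozen=True)
class CellLineProfile:
    """Ground-truth relative lipid abundances of one synthetic cell line."""

    label: str
    subtype: str
    abundance: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "abundance", np.asarray(self.abundance, dtype=float))
        if self.subtype not in SUBTYPES and self.subtype != NECROTIC:
            raise ValueError(f"unknown subtype {self.subtype!r}")
        a = self.abundance
        if np.any(a < 0) or not np.any(a > 0):
            raise ValueError("abundances must be nonnegative with at least one positive")
        if abs(float(a.sum()) - 1.0) > 1e-9:
            raise ValueError(f"abundances must sum to 1 (got {a.sum()!r})")


@dataclass
class GroundTruth:
    """Per-pixel true labels and per-cell masks for a generated image."""

    label_image: np.ndarray
    cell_masks: list[tuple[str, frozenset, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        seen: set = set()
        for cell_id, pixels, label in self.cell_masks:
            overlap = seen & set(pixels)
            if overlap:
                raise ValueError(f"cell masks overlap at {sorted(overlap)[:3]}")
            seen |= set(pixels)
            for r, c in pixels:
                if self.label_image[r, c] != label:
                    raise ValueError(
                        f"pixel {(r, c)} labeled {self.label_image[r, c]!r} but "
                        f"belongs to cell {cell_id!r} of class {label!r}"
                    )


def _sparse_log_effect(rng: np.random.Generator, n: int, density: float = 0.25,
                       scale: float = 0.6) -> np.ndarray:
    mask = rng.random(n) < density
    return np.where(mask, rng.normal(0.0, scale, n), 0.0)


def make_profiles(
    n_classes: int,
    panel: LipidPanel | None = None,
    separation: float = 1.0,
    seed: int = 0,
) -> list[CellLineProfile]:
    """Generate ``n_classes`` cell-line profiles over the panel.

    All classes share one Dirichlet-drawn base composition; each receives a
    subtype-level and a line-level sparse log-scale perturbation, both scaled
    by ``separation`` (``separation=0`` makes every profile identical to the
    base). Subtype labels cycle round-robin over the three receptor subtypes.
    """
    if n_classes < 1:
        raise ValueError("n_classes must be >= 1")
    if separation < 0:
        raise ValueError("separation must be nonnegative")
    panel = panel if panel is not None else default_panel()
    n = len(panel)
    if n == 0:
        raise ValueError("cannot build profiles over an empty panel")
    rng = np.random.default_rng(seed)
    base = rng.dirichlet(np.full(n, 5.0))
    subtype_effects = [_sparse_log_effect(rng, n) for _ in SUBTYPES]
    profiles = []
    for i in range(n_classes):
        line_effect = _sparse_log_effect(rng, n)
        log_shift = separation * (subtype_effects[i % 3] + line_effect)
        abun = base * np.exp(log_shift)
        abun /= abun.sum()
        profiles.append(
            CellLineProfile(
                label=f"LINE_{i + 1:02d}", subtype=SUBTYPES[i % 3], abundance=abun
            )
        )
    return profiles


def _background_peaks(
    rng: np.random.Generator,
    intensity_scale: float,
    panel_mz: np.ndarray,
    n_min: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Sparse low-intensity off-panel peaks, each > 0.06 Da from any panel mass."""
    n_bg = max(n_min, int(rng.poisson(8.0)))
    mzs: list[float] = []
    while len(mzs) < n_bg:
        m = float(rng.uniform(600.5, 949.5))
        if panel_mz.size and np.min(np.abs(panel_mz - m)) <= 0.06:
            continue
        if mzs and min(abs(m - x) for x in mzs) <= 0.01:
            continue
        mzs.append(m)
    ints = intensity_scale * rng.uniform(0.0005, 0.005, size=n_bg)
    return np.array(mzs), ints


def _lognormal_factors(rng: np.random.Generator, cv: float, n: int) -> np.ndarray:
    # unit-mean lognormal with coefficient of variation cv
    if cv == 0:
        return np.ones(n)
    sigma = np.sqrt(np.log1p(cv * cv))
    return np.exp(rng.normal(-0.5 * sigma * sigma, sigma, n))


def synth_spectrum(
    profile: CellLineProfile,
    panel: LipidPanel | None = None,
    intensity_scale: float = 1000.0,
    noise_cv: float = 0.05,
    seed: int = 0,
    rng: np.random.Generator | None = None,
    background: bool = True,
    instrument: str | None = None,
    coordinate: tuple[int, int] | None = None,
) -> CentroidSpectrum:
    """One centroid spectrum of a cell of the given class.

    Each panel lipid yields one centroid at its mass with intensity
    ``intensity_scale × abundance × lognormal(cv=noise_cv)`` (unit mean);
    sparse off-panel background peaks are appended unless ``background``
    is disabled.
    """
    if intensity_scale <= 0:
        raise ValueError("intensity_scale must be positive")
    if noise_cv < 0:
        raise ValueError("noise_cv must be nonnegative")
    panel = panel if panel is not None else default_panel()
    if len(profile.abundance) != len(panel):
        raise ValueError("profile and panel lengths differ")
    rng = rng if rng is not None else np.random.default_rng(seed)
    mz = panel.mz
    intensity = intensity_scale * profile.abundance * _lognormal_factors(
        rng, noise_cv, len(panel)
    )
    if background:
        bg_mz, bg_int = _background_peaks(rng, intensity_scale, mz)
        mz = np.concatenate([mz, bg_mz])
        intensity = np.concatenate([intensity, bg_int])
    order = np.argsort(mz)
    return CentroidSpectrum(
        mz[order], intensity[order], coordinate=coordinate, instrument=instrument
    )


def synth_background_spectrum(
    intensity_scale: float = 1000.0,
    panel: LipidPanel | None = None,
    seed: int = 0,
    rng: np.random.Generator | None = None,
    coordinate: tuple[int, int] | None = None,
) -> CentroidSpectrum:
    """A background-only (off-cell) pixel spectrum: sparse faint peaks."""
    panel = panel if panel is not None else default_panel()
    rng = rng if rng is not None else np.random.default_rng(seed)
    mzs, ints = _background_peaks(rng, intensity_scale, panel.mz, n_min=2)
    order = np.argsort(mzs)
    return CentroidSpectrum(mzs[order], ints[order], coordinate=coordinate)


# ---------------------------------------------------------------------------
# single-cell images


def synth_cell_image(
    profiles: list[CellLineProfile],
    cells_per_class: int,
    panel: LipidPanel | None = None,
    pixel_um: float = 5.0,
    diameter_range_um: tuple[float, float] = (20.0, 150.0),
    noise_cv: float = 0.05,
    seed: int = 0,
    intensity_scale: float = 1000.0,
    max_tries: int = 500,
) -> tuple[SpectrumImage, GroundTruth]:
    """A single-cell image: non-overlapping disks of cells on a pixel grid.

    Cell diameters are uniform over ``diameter_range_um``; a pixel belongs to
    a cell iff its center lies inside the cell's disk. At the default 5 µm
    pixel size every cell of ≥ 20 µm diameter covers at least 4 pixels.
    Background pixels carry background-only spectra.
    """
    panel = panel if panel is not None else default_panel()
    d_lo, d_hi = diameter_range_um
    if not (0 < d_lo <= d_hi):
        raise ValueError("invalid diameter range")
    if cells_per_class < 0:
        raise ValueError("cells_per_class must be nonnegative")
    rng = np.random.default_rng(seed)
    n_cells = len(profiles) * cells_per_class

    if n_cells == 0:
        rows = cols = 16
        spectra = {
            (r, c): synth_background_spectrum(
                intensity_scale, panel, rng=rng, coordinate=(r, c)
            )
            for r in range(rows)
            for c in range(cols)
        }
        image = SpectrumImage(pixel_um=pixel_um, shape=(rows, cols), spectra=spectra)
        gt = GroundTruth(np.full((rows, cols), BACKGROUND, dtype=object), [])
        return image, gt

    class_idx = np.repeat(np.arange(len(profiles)), cells_per_class)
    diameters = rng.uniform(d_lo, d_hi, n_cells)

    # size the field for ~22% areal packing, then place largest cells first
    cell_area = float(np.sum(np.pi * (diameters / 2.0) ** 2))
    side_um = max(np.sqrt(cell_area / 0.22), d_hi + 4 * pixel_um)
    n_px = int(np.ceil(side_um / pixel_um))
    side_um = n_px * pixel_um
    if d_hi >= side_um:
        raise ValueError("diameter range exceeds image extent")

    order = np.argsort(-diameters)
    placed: list[tuple[float, float, float]] = []  # (cy, cx, radius) in µm
    placement: list[tuple[int, float, float, float]] = []  # (cell index, cy, cx, r)
    for k, ci in enumerate(order):
        r_um = diameters[ci] / 2.0
        ok = False
        for _ in range(max_tries):
            cy = rng.uniform(r_um + pixel_um, side_um - r_um - pixel_um)
            cx = rng.uniform(r_um + pixel_um, side_um - r_um - pixel_um)
            if all(
                (cy - py) ** 2 + (cx - px) ** 2 > (r_um + pr + 0.5) ** 2
                for py, px, pr in placed
            ):
                ok = True
                break
        if not ok:
            raise ValueError(
                f"could not place all cells without overlap: placed {k} of {n_cells}"
            )
        placed.append((cy, cx, r_um))
        placement.append((int(ci), cy, cx, r_um))

    label_image = np.full((n_px, n_px), BACKGROUND, dtype=object)
    masks: list[tuple[str, frozenset, str]] = []
    cell_pixels: dict[tuple[int, int], int] = {}
    placement.sort(key=lambda t: t[0])  # stable cell ids in class order
    for cell_no, (ci, cy, cx, r_um) in enumerate(placement):
        label = profiles[class_idx[ci]].label
        r0 = max(0, int((cy - r_um) / pixel_um) - 1)
        r1 = min(n_px - 1, int((cy + r_um) / pixel_um) + 1)
        c0 = max(0, int((cx - r_um) / pixel_um) - 1)
        c1 = min(n_px - 1, int((cx + r_um) / pixel_um) + 1)
        pix = []
        for r in range(r0, r1 + 1):
            yc = (r + 0.5) * pixel_um
            for c in range(c0, c1 + 1):
                xc = (c + 0.5) * pixel_um
                if (yc - cy) ** 2 + (xc - cx) ** 2 <= r_um * r_um:
                    pix.append((r, c))
                    label_image[r, c] = label
                    cell_pixels[(r, c)] = ci
        masks.append((f"cell_{cell_no:04d}", frozenset(pix), label))

    spectra: dict[tuple[int, int], CentroidSpectrum] = {}
    for r in range(n_px):
        for c in range(n_px):
            if (r, c) in cell_pixels:
                prof = profiles[class_idx[cell_pixels[(r, c)]]]
                spectra[(r, c)] = synth_spectrum(
                    prof, panel, intensity_scale, noise_cv, rng=rng, coordinate=(r, c)
                )
            else:
                spectra[(r, c)] = synth_background_spectrum(
                    intensity_scale, panel, rng=rng, coordinate=(r, c)
                )

    image = SpectrumImage(
        pixel_um=pixel_um,
        shape=(n_px, n_px),
        spectra=spectra,
        metadata={"kind": "synthetic-cells", "seed": seed},
    )
    return image, GroundTruth(label_image, masks)


# ---------------------------------------------------------------------------
# tissue images


def necrotic_profile(main_profile: CellLineProfile) -> CellLineProfile:
    """Necrosis stand-in: the tumor profile mixed 50/50 with a uniform profile.

    Combined with a 10× intensity drop, this places necrotic spectra far
    outside the tumor class's dispersion so the SD×3 outlier rule trips.
    """
    n = len(main_profile.abundance)
    abun = 0.5 * main_profile.abundance + 0.5 / n
    return CellLineProfile(label=NECROTIC, subtype=NECROTIC, abundance=abun / abun.sum())


def synth_tissue_image(
    main_profile: CellLineProfile,
    necrotic_fraction: float = 0.0,
    panel: LipidPanel | None = None,
    pixel_um: float = 30.0,
    size: tuple[int, int] = (64, 64),
    noise_cv: float = 0.05,
    seed: int = 0,
    intensity_scale: float = 1000.0,
    include_background: bool = False,
) -> tuple[SpectrumImage, GroundTruth]:
    """A tissue image: elliptical tumor of one class, necrotic core, background.

    The necrotic subregion is grown contiguously (breadth-first) from a random
    interior tumor pixel until it holds ``round(necrotic_fraction × tumor
    pixels)`` pixels; its spectra use :func:`necrotic_profile` at 10% of the
    tumor intensity scale. The background border is unmeasured (no spectra)
    unless ``include_background`` is set, matching acquisitions that cover
    only the tissue section.
    """
    if not 0.0 <= necrotic_fraction <= 1.0:
        raise ValueError("necrotic_fraction must lie in [0, 1]")
    rows, cols = size
    if rows < 8 or cols < 8:
        raise ValueError("tissue image must be at least 8×8 pixels")
    panel = panel if panel is not None else default_panel()
    rng = np.random.default_rng(seed)

    rr, cc = np.mgrid[0:rows, 0:cols]
    cy, cx = (rows - 1) / 2.0, (cols - 1) / 2.0
    ay, ax = 0.38 * rows, 0.38 * cols
    tumor = ((rr - cy) / ay) ** 2 + ((cc - cx) / ax) ** 2 <= 1.0
    tumor_pixels = [tuple(p) for p in np.argwhere(tumor)]
    n_necrotic = int(round(necrotic_fraction * len(tumor_pixels)))

    necrotic: set[tuple[int, int]] = set()
    if n_necrotic > 0:
        start = tumor_pixels[int(rng.integers(len(tumor_pixels)))]
        tumor_set = set(tumor_pixels)
        queue = deque([start])
        while queue and len(necrotic) < n_necrotic:
            p = queue.popleft()
            if p in necrotic:
                continue
            necrotic.add(p)
            r, c = p
            for q in ((r - 1, c), (r + 1, c), (r, c - 1), (r, c + 1)):
                if q in tumor_set and q not in necrotic:
                    queue.append(q)

    nec_prof = necrotic_profile(main_profile)
    label_image = np.full((rows, cols), BACKGROUND, dtype=object)
    spectra: dict[tuple[int, int], CentroidSpectrum] = {}
    for r in range(rows):
        for c in range(cols):
            if tumor[r, c]:
                if (r, c) in necrotic:
                    label_image[r, c] = NECROTIC
                    spectra[(r, c)] = synth_spectrum(
                        nec_prof, panel, intensity_scale * 0.1, noise_cv,
                        rng=rng, coordinate=(r, c),
                    )
                else:
                    label_image[r, c] = main_profile.label
                    spectra[(r, c)] = synth_spectrum(
                        main_profile, panel, intensity_scale, noise_cv,
                        rng=rng, coordinate=(r, c),
                    )
            elif include_background:
                spectra[(r, c)] = synth_background_spectrum(
                    intensity_scale, panel, rng=rng, coordinate=(r, c)
                )
    image = SpectrumImage(
        pixel_um=pixel_um,
        shape=(rows, cols),
        spectra=spectra,
        metadata={"kind": "synthetic-tissue", "seed": seed},
    )
    return image, GroundTruth(label_image, [])


# ---------------------------------------------------------------------------
# direct library synthesis (bypassing image placement)


def synthetic_library(
    profiles: list[CellLineProfile] | None = None,
    cells_per_class: int = 16,
    panel: LipidPanel | None = None,
    grid=None,
    noise_cv: float = 0.05,
    seed: int = 0,
    n_slides: int = 3,
    intensity_scale: float = 1000.0,
):
    """Build a labeled spectral library directly: one spectrum per cell.

    Each cell contributes the RMS-normalized, binned version of one
    :func:`synth_spectrum` draw; slide ids cycle round-robin so repeatability
    summaries have within- and across-slide pairs.
    """
    from .library_builder import SpectralLibrary
    from .preprocess import BinGrid, bin_spectrum, rms_normalize

    panel = panel if panel is not None else default_panel()
    profiles = profiles if profiles is not None else make_profiles(14, panel, seed=seed)
    grid = grid if grid is not None else BinGrid()
    rng = np.random.default_rng(seed)
    rows, line_labels, subtype_labels, slide_ids, cell_ids = [], [], [], [], []
    for prof in profiles:
        for j in range(cells_per_class):
            spec = synth_spectrum(prof, panel, intensity_scale, noise_cv, rng=rng)
            rows.append(bin_spectrum(rms_normalize(spec), grid).values)
            line_labels.append(prof.label)
            subtype_labels.append(prof.subtype)
            slide_ids.append(f"slide_{j % n_slides + 1}")
            cell_ids.append(f"{prof.label}_cell_{j:03d}")
    return SpectralLibrary(
        grid=grid,
        X=np.array(rows),
        line_labels=np.array(line_labels, dtype=object),
        subtype_labels=np.array(subtype_labels, dtype=object),
        slide_ids=np.array(slide_ids, dtype=object),
        cell_ids=np.array(cell_ids, dtype=object),
    )
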