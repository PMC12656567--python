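"""Seeded synthetic hyperspectral scenes with known ground truth.

Emulates the geometry of NEON AOP Level-3 surface-reflectance tiles (1 m
pixels, 426 bands at 5 nm spacing) so that every downstream stage —
masking, band exclusion, endmember extraction, unmixing, trend mapping,
accuracy assessment — can be exercised against a known answer without any
download. The forward model is the same linear mixing model the unmixer
inverts: each pixel is a convex combination of class endmember spectra plus
i.i.d. Gaussian noise, with injected defects (corrupted water-absorption
bands, no-data and negative pixels) matching what real tiles exhibit.

All randomness flows from one explicit integer seed through named
`numpy.random.Generator` instances; no global state.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.ndimage

from .errors import DataError
from .types import (
    EndmemberLibrary,
    FractionStack,
    ReferencePoints,
    SpectralCube,
    NODATA_SENTINEL,
    REFLECTANCE_SCALE,
)

__all__ = [
    "ClassSpec",
    "SceneTruth",
    "DEFAULT_CLASSES",
    "DEFAULT_CORRUPTED_RANGES",
    "neon_wavelength_grid",
    "generate_endmember_spectra",
    "generate_fraction_field",
    "render_cube",
    "sample_reference_points",
    "make_scene_truth",
]

#: NEON-like band grid: 426 bands, 5 nm spacing starting at 380 nm.
N_BANDS_NEON = 426

#: Water-absorption windows injected by default (1-based inclusive band
#: indices), mirroring the ~1400 nm and ~1900 nm atmospheric windows.
DEFAULT_CORRUPTED_RANGES = ((192, 212), (282, 314))


@dataclass(frozen=True)
class ClassSpec:
    """Shape descriptor for one synthetic endmember class.

    ``kind`` selects the spectral archetype: ``"vegetation"`` has the
    green-peak / red-trough / near-infrared-plateau shape of photosynthetic
    cover, ``"soil"`` a monotone-trending bright spectrum without a red
    edge. ``nir_reflectance`` scales the vegetation NIR plateau (unitless
    reflectance); ``brightness`` scales the soil ramp.
    """

    name: str
    kind: str = "vegetation"
    nir_reflectance: float = 0.45
    green_peak_nm: float = 550.0
    brightness: float = 1.0


DEFAULT_CLASSES = (
    ClassSpec("herbaceous", "vegetation", nir_reflectance=0.48, green_peak_nm=552.0),
    ClassSpec("mixed_forbs", "vegetation", nir_reflectance=0.34, green_peak_nm=540.0),
    ClassSpec("bare_soil", "soil", brightness=1.0),
)


def neon_wavelength_grid(n_bands: int = N_BANDS_NEON) -> np.ndarray:
    """Band-centre wavelengths 380 + 5k nm, k = 0..n_bands-1."""
    if n_bands < 2:
        raise DataError("need at least 2 bands")
    return 380.0 + 5.0 * np.arange(n_bands)


def _vegetation_spectrum(wl, spec: ClassSpec):
    """Smooth leaf-like reflectance: green bump, red trough, NIR plateau,
    declining short-wave infrared with liquid-water dips."""
    nir = spec.nir_reflectance
    base = 0.04 + 0.06 * np.exp(-0.5 * ((wl - spec.green_peak_nm) / 35.0) ** 2)
    red_edge = nir / (1.0 + np.exp(-(wl - 715.0) / 16.0))
    swir_decline = 1.0 / (1.0 + np.exp((wl - 1650.0) / 420.0))
    dips = 0.55 * np.exp(-0.5 * ((wl - 1450.0) / 55.0) ** 2) + 0.65 * np.exp(
        -0.5 * ((wl - 1940.0) / 70.0) ** 2
    )
    r = base + red_edge * swir_decline * (1.0 - np.clip(dips, 0.0, 0.95))
    return r


def _soil_spectrum(wl, spec: ClassSpec):
    """Monotone-trending bright soil with a gentle clay feature near 2200 nm."""
    ramp = 0.10 + 0.28 * (wl - wl[0]) / (wl[-1] - wl[0])
    clay = 0.03 * np.exp(-0.5 * ((wl - 2200.0) / 60.0) ** 2)
    return spec.brightness * (ramp - clay)


def _smooth_perturbation(rng, n_bands, amplitude=0.01, sigma=25.0):
    """Seeded, band-correlated wiggle that makes each class unique."""
    noise = rng.normal(0.0, 1.0, n_bands)
    smooth = scipy.ndimage.gaussian_filter1d(noise, sigma, mode="reflect")
    peak = np.abs(smooth).max()
    return amplitude * smooth / peak if peak > 0 else smooth


def generate_endmember_spectra(
    n_bands: int,
    class_specs=DEFAULT_CLASSES,
    seed: int = 0,
    min_separation_rad: float = 0.02,
) -> EndmemberLibrary:
    """Build K smooth, non-negative endmember spectra on the NEON-like grid.

    Vegetation-shaped classes rise between the red and near-infrared
    regions; the soil-shaped class trends monotonically without that rise.
    A small seeded band-correlated perturbation individualises classes.
    Raises if any pair of classes falls below ``min_separation_rad``
    spectral angle.
    """
    class_specs = list(class_specs)
    if n_bands < 2:
        raise DataError("n_bands must be at least 2")
    if len(class_specs) < 2:
        raise DataError("need at least 2 classes")
    wl = neon_wavelength_grid(n_bands)
    rng = np.random.default_rng(seed)
    rows = []
    for spec in class_specs:
        if spec.kind == "vegetation":
            r = _vegetation_spectrum(wl, spec)
        elif spec.kind == "soil":
            r = _soil_spectrum(wl, spec)
        else:
            raise DataError(f"unknown class kind {spec.kind!r}")
        r = r + _smooth_perturbation(rng, n_bands)
        rows.append(np.clip(r, 1e-4, None))
    spectra = np.vstack(rows)
    lib = EndmemberLibrary(
        spectra=spectra,
        class_names=[s.name for s in class_specs],
        wavelengths_nm=wl,
    )
    angles = _pairwise_angles(spectra)
    if angles.min() < min_separation_rad:
        i, j = np.unravel_index(np.argmin(angles), angles.shape)
        raise DataError(
            f"classes {lib.class_names[i]!r} and {lib.class_names[j]!r} are "
            f"spectrally too similar ({angles[i, j]:.4f} rad)"
        )
    return lib


def _pairwise_angles(spectra):
    norms = np.linalg.norm(spectra, axis=1)
    cos = (spectra @ spectra.T) / np.outer(norms, norms)
    ang = np.arccos(np.clip(cos, -1.0, 1.0))
    np.fill_diagonal(ang, np.inf)
    return ang


def generate_fraction_field(
    rows: int,
    cols: int,
    concentration,
    smoothness_px: float = 0.0,
    seed: int = 0,
    class_names=None,
) -> FractionStack:
    """Simplex-distributed per-pixel fractions, optionally smoothed.

    Each pixel draws a Dirichlet vector with the given concentration
    weights; each class layer is then smoothed by an isotropic Gaussian
    kernel of width ``smoothness_px`` and the stack renormalised per pixel,
    which preserves exact simplex membership while producing the spatially
    coherent patches real cover maps show.
    """
    concentration = np.asarray(concentration, dtype=np.float64)
    if rows < 1 or cols < 1:
        raise DataError("rows and cols must be at least 1")
    if concentration.ndim != 1 or concentration.size < 1:
        raise DataError("concentration must be a 1-D weight vector")
    if np.any(concentration <= 0):
        raise DataError("concentration weights must be positive")
    if smoothness_px < 0:
        raise DataError("smoothness must be non-negative")
    k = concentration.size
    rng = np.random.default_rng(seed)
    draws = rng.dirichlet(concentration, size=(rows, cols))  # (rows, cols, K)
    layers = np.moveaxis(draws, -1, 0)
    if smoothness_px > 0:
        layers = np.stack(
            [
                scipy.ndimage.gaussian_filter(l, smoothness_px, mode="reflect")
                for l in layers
            ]
        )
    layers = np.clip(layers, 0.0, None)
    layers /= layers.sum(axis=0, keepdims=True)
    if class_names is None:
        class_names = [f"class_{i + 1}" for i in range(k)]
    return FractionStack(
        fractions=layers,
        class_names=class_names,
        mode="fcls",
        residual_rmse=np.zeros((rows, cols)),
    )


@dataclass
class SceneTruth:
    """Everything needed to render a scene and check recovery against it.

    ``corrupted_band_ranges`` are 1-based inclusive index pairs whose bands
    are overwritten with high-variance noise; ``nodata_pixels`` and
    ``negative_pixels`` are (row, col) arrays of injected defects.
    """

    fractions: FractionStack
    library: EndmemberLibrary
    noise_sd: float = 0.0
    seed: int = 0
    corrupted_band_ranges: tuple = ()
    nodata_pixels: np.ndarray = field(default_factory=lambda: np.empty((0, 2), int))
    negative_pixels: np.ndarray = field(default_factory=lambda: np.empty((0, 2), int))

    def __post_init__(self):
        if self.fractions.n_classes != self.library.n_classes:
            raise DataError(
                "fraction stack and library disagree on the number of classes"
            )
        if self.fractions.class_names != self.library.class_names:
            raise DataError("fraction stack and library class names differ")
        self.nodata_pixels = np.asarray(self.nodata_pixels, dtype=int).reshape(-1, 2)
        self.negative_pixels = np.asarray(self.negative_pixels, dtype=int).reshape(
            -1, 2
        )
        sums = self.fractions.fractions.sum(axis=0)
        valid = self.fractions.pixel_valid
        if np.any(np.abs(sums[valid] - 1.0) > 1e-9) or np.any(
            self.fractions.fractions[:, valid] < 0
        ):
            raise DataError("ground-truth fractions must lie on the unit simplex")


def render_cube(truth: SceneTruth) -> SpectralCube:
    """Render a reflectance cube from ground truth via the forward model.

    Each pixel is the abundance-weighted sum of the library spectra plus
    Gaussian noise of sd ``noise_sd``; corrupted band ranges are replaced by
    high-variance noise, no-data pixels by the sentinel value, and negative
    pixels get one band pushed below zero.
    """
    lib = truth.library
    frac = truth.fractions.fractions  # (K, rows, cols)
    k, rows, cols = frac.shape
    rng = np.random.default_rng(truth.seed)
    cube_data = np.einsum("krc,kb->rcb", frac, lib.spectra)
    if truth.noise_sd > 0:
        cube_data = cube_data + rng.normal(0.0, truth.noise_sd, cube_data.shape)
    for lo, hi in truth.corrupted_band_ranges:
        if not 1 <= lo <= hi <= lib.n_bands:
            raise DataError(f"corrupted band range ({lo}, {hi}) outside 1..{lib.n_bands}")
        sl = slice(lo - 1, hi)
        cube_data[:, :, sl] = rng.normal(0.4, 0.5, cube_data[:, :, sl].shape)
    for r, c in truth.negative_pixels:
        band = int(rng.integers(0, lib.n_bands))
        cube_data[r, c, band] = -abs(cube_data[r, c, band]) - 0.01
    sentinel_reflectance = NODATA_SENTINEL / REFLECTANCE_SCALE
    for r, c in truth.nodata_pixels:
        cube_data[r, c, :] = sentinel_reflectance
    return SpectralCube(
        reflectance=cube_data,
        wavelengths_nm=lib.wavelengths_nm.copy(),
        pixel_size_m=truth.fractions.pixel_size_m,
        origin_xy=tuple(truth.fractions.origin_xy),
        crs_label=truth.fractions.crs_label,
    )


def sample_reference_points(
    truth: SceneTruth,
    n_per_class: int,
    purity: float = 0.75,
    seed: int = 0,
) -> ReferencePoints:
    """Purity-thresholded stratified reference points with known labels.

    Emulates manually digitised validation points: for each class, sample
    ``n_per_class`` distinct pixels whose true fraction of that class is at
    least ``purity`` (defect pixels excluded), placing each point at the
    pixel centre.
    """
    if not 0 < purity <= 1:
        raise DataError("purity must be in (0, 1]")
    rng = np.random.default_rng(seed)
    frac = truth.fractions.fractions
    k, rows, cols = frac.shape
    excluded = np.zeros((rows, cols), dtype=bool)
    for r, c in np.concatenate([truth.nodata_pixels, truth.negative_pixels]):
        excluded[r, c] = True
    xs, ys, labels = [], [], []
    stack = truth.fractions
    for ci, name in enumerate(stack.class_names):
        qualifying = np.argwhere((frac[ci] >= purity) & ~excluded)
        if qualifying.shape[0] < n_per_class:
            raise DataError(
                f"class {name!r} has only {qualifying.shape[0]} pixels with "
                f"fraction >= {purity}, need {n_per_class}"
            )
        pick = rng.choice(qualifying.shape[0], size=n_per_class, replace=False)
        for r, c in qualifying[pick]:
            x = stack.origin_xy[0] + (c + 0.5) * stack.pixel_size_m
            y = stack.origin_xy[1] - (r + 0.5) * stack.pixel_size_m
            xs.append(x)
            ys.append(y)
            labels.append(name)
    return ReferencePoints(
        x=np.asarray(xs),
        y=np.asarray(ys),
        labels=labels,
        class_list=list(stack.class_names),
    )


def make_scene_truth(
    rows: int = 100,
    cols: int = 100,
    n_bands: int = N_BANDS_NEON,
    class_specs=DEFAULT_CLASSES,
    concentration=(0.15, 0.12, 0.10),
    smoothness_px: float = 0.3,
    noise_sd: float = 0.01,
    corrupted_band_ranges=DEFAULT_CORRUPTED_RANGES,
    n_nodata: int = 5,
    n_negative: int = 5,
    seed: int = 0,
) -> SceneTruth:
    """Convenience builder wiring sub-seeds for a complete NEON-like scene.

    Sub-generators (spectra, fraction field, rendering, defect placement)
    each receive an independent stream derived from ``seed`` via
    `numpy.random.SeedSequence.spawn`, so scenes are reproducible and the
    streams do not interact.
    """
    ss = np.random.SeedSequence(seed)
    s_lib, s_field, s_render, s_defect = (
        int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(4)
    )
    lib = generate_endmember_spectra(n_bands, class_specs, seed=s_lib)
    field = generate_fraction_field(
        rows,
        cols,
        concentration,
        smoothness_px=smoothness_px,
        seed=s_field,
        class_names=[s.name for s in class_specs],
    )
    rng = np.random.default_rng(s_defect)
    n_defect = n_nodata + n_negative
    flat = rng.choice(rows * cols, size=n_defect, replace=False) if n_defect else []
    defects = np.column_stack(np.unravel_index(flat, (rows, cols))) if n_defect else (
        np.empty((0, 2), int)
    )
    return SceneTruth(
        fractions=field,
        library=lib,
        noise_sd=noise_sd,
        seed=s_render,
        corrupted_band_ranges=tuple(tuple(r) for r in corrupted_band_ranges),
        nodata_pixels=defects[:n_nodata],
        negative_pixels=defects[n_nodata:],
    )
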