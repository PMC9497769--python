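"""Synthetic hyperspectral cohort generator.

Emulates the structure of an intraoperative porcine dataset: one annotated
hypercube per animal, two tissue classes — colon-mesocolon (to be resected)
and retroperitoneum (to be preserved) — with reflectance spectra shaped by
oxy/deoxy-hemoglobin absorption in the visible range, an adipose (lipid)
feature near 740 nm and a water feature near 980 nm, per-animal spectral
variability, and a ~4.3:1 colon:retroperitoneum pixel imbalance with thin
retroperitoneal regions.

The generative model is Beer-Lambert-shaped: reflectance(λ) =
baseline(λ) · exp(−Σ_a c_a · A_a(λ)) + noise, where the absorber curves
A_a are smooth parametric stand-ins pinned only by the peak locations the
physiology dictates (water ≈ 980 nm, lipid ≈ 740 nm, distinct oxy/deoxy
hemoglobin shapes at 500-600 nm).  Class separability is a configurable
dial: with ``separation = 0`` the two class models coincide exactly.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .io import (
    BINNED_WAVELENGTHS,
    AnnotationMask,
    Hypercube,
    write_cube,
    write_mask,
)

logger = logging.getLogger(__name__)

ABSORBERS = ("oxyhemoglobin", "deoxyhemoglobin", "water", "lipid")

# concentration parameterization (unitless): class = base + separation * delta
_BASE_CONC = {"oxyhemoglobin": 0.45, "deoxyhemoglobin": 0.30,
              "water": 0.40, "lipid": 0.30}
_DELTA_COLON = {"oxyhemoglobin": +0.25, "deoxyhemoglobin": -0.05,
                "water": -0.18, "lipid": +0.45}
_DELTA_RETRO = {"oxyhemoglobin": -0.10, "deoxyhemoglobin": +0.20,
                "water": +0.40, "lipid": -0.15}


class ConfigurationError(ValueError):
    """Cohort configuration cannot produce a valid scene."""


def _gaussian(wl: np.ndarray, center: float, width: float) -> np.ndarray:
    return np.exp(-0.5 * ((wl - center) / width) ** 2)


@dataclass
class AbsorberBasis:
    """Smooth, non-negative absorber curves on a common wavelength grid."""

    wavelengths: np.ndarray
    spectra: dict[str, np.ndarray]

    def __post_init__(self) -> None:
        wl = self.wavelengths
        for name, curve in self.spectra.items():
            if curve.shape != wl.shape:
                raise ValueError(f"absorber '{name}' not on the basis wavelength grid")
            if curve.min() < 0:
                raise ValueError(f"absorber '{name}' has negative values")
        water_peak = wl[np.argmax(self.spectra["water"])]
        if not (970.0 <= water_peak <= 990.0):
            raise ValueError(f"water curve peaks at {water_peak} nm, expected 980 +/- 10")
        lipid_peak = wl[np.argmax(self.spectra["lipid"])]
        if not (730.0 <= lipid_peak <= 750.0):
            raise ValueError(f"lipid curve peaks at {lipid_peak} nm, expected 740 +/- 10")

    def matrix(self) -> np.ndarray:
        """Absorber curves stacked as an (n_absorbers, B) matrix in ABSORBERS order."""
        return np.stack([self.spectra[a] for a in ABSORBERS])


def make_absorber_basis(wavelengths: np.ndarray = BINNED_WAVELENGTHS) -> AbsorberBasis:
    """Build the four-absorber basis on a wavelength grid within 500-1000 nm.

    Water peaks at 980 nm, lipid at 740 nm.  The hemoglobin curves are
    qualitative templates: oxyhemoglobin shows the double absorption band
    near 542/577 nm falling off steeply past 600 nm, deoxyhemoglobin a
    single broad band near 556 nm plus a weak bump near 760 nm, giving the
    oxy/deoxy crossover structure seen in tissue spectra.
    """
    wl = np.asarray(wavelengths, dtype=np.float64)
    if wl.min() < 500.0 or wl.max() > 1000.0:
        raise ValueError(
            f"wavelengths must lie within [500, 1000] nm, got [{wl.min()}, {wl.max()}]"
        )
    spectra = {
        "water": _gaussian(wl, 980.0, 45.0),
        "lipid": _gaussian(wl, 740.0, 25.0),
        "oxyhemoglobin": (0.85 * _gaussian(wl, 542.0, 13.0)
                          + 1.00 * _gaussian(wl, 577.0, 11.0)
                          + 0.30 * _gaussian(wl, 515.0, 20.0)),
        "deoxyhemoglobin": (1.00 * _gaussian(wl, 556.0, 18.0)
                            + 0.20 * _gaussian(wl, 760.0, 25.0)
                            + 0.15 * _gaussian(wl, 520.0, 30.0)),
    }
    return AbsorberBasis(wl, spectra)


@dataclass
class TissueModel:
    """Generative reflectance model for one tissue class.

    Reflectance(λ) = scattering(λ) · exp(−Σ_a c_a A_a(λ)) + N(0, noise_sd²),
    clipped at zero.  ``animal_sd`` is the SD of per-animal additive offsets
    on each concentration; ``pixel_jitter_sd`` the per-pixel analogue.
    """

    class_label: int
    concentrations: dict[str, float]
    animal_sd: dict[str, float]
    scattering_amplitude: float = 0.85
    scattering_exponent: float = 0.65
    noise_sd: float = 0.01
    pixel_jitter_sd: float = 0.03

    def __post_init__(self) -> None:
        for name, c in self.concentrations.items():
            if c < 0:
                raise ValueError(f"negative concentration for '{name}': {c}")
        if self.noise_sd < 0 or any(s < 0 for s in self.animal_sd.values()):
            raise ValueError("noise_sd and animal_sd must be non-negative")

    def scattering_baseline(self, wavelengths: np.ndarray) -> np.ndarray:
        """Slowly decaying, positive scattering background (Mie-like power law)."""
        return self.scattering_amplitude * (np.asarray(wavelengths) / 800.0) ** (
            -self.scattering_exponent)


def class_tissue_models(separation: float = 1.0, noise_sd: float = 0.01,
                        animal_sd: float = 0.05,
                        pixel_jitter_sd: float = 0.03) -> dict[int, TissueModel]:
    """Default tissue models for labels 1 (colon-mesocolon) and 2 (retroperitoneum).

    ``separation`` scales the between-class concentration contrast: 0 makes
    the class models identical (chance-level task); 1 is the default, at
    which even a nearest-class-mean classifier separates the classes.
    """
    models = {}
    for label, delta in ((1, _DELTA_COLON), (2, _DELTA_RETRO)):
        conc = {a: max(0.0, _BASE_CONC[a] + separation * delta[a]) for a in ABSORBERS}
        models[label] = TissueModel(
            class_label=label,
            concentrations=conc,
            animal_sd={a: animal_sd for a in ABSORBERS},
            noise_sd=noise_sd,
            pixel_jitter_sd=pixel_jitter_sd,
        )
    return models


def render_spectrum(model: TissueModel, basis: AbsorberBasis,
                    rng: np.random.Generator) -> np.ndarray:
    """Draw one reflectance spectrum (B,) from a tissue model."""
    return _render_pixels(model, basis, rng, n_pixels=1,
                          animal_offset=np.zeros(len(ABSORBERS)))[0]


def _render_pixels(model: TissueModel, basis: AbsorberBasis,
                   rng: np.random.Generator, n_pixels: int,
                   animal_offset: np.ndarray) -> np.ndarray:
    """Render (n_pixels, B) reflectance with per-pixel concentration jitter."""
    mean = np.array([model.concentrations[a] for a in ABSORBERS])
    conc = mean[None, :] + animal_offset[None, :]
    if model.pixel_jitter_sd > 0:
        conc = conc + rng.normal(0.0, model.pixel_jitter_sd, (n_pixels, len(ABSORBERS)))
    else:
        conc = np.broadcast_to(conc, (n_pixels, len(ABSORBERS)))
    conc = np.clip(conc, 0.0, None)
    baseline = model.scattering_baseline(basis.wavelengths)
    refl = baseline[None, :] * np.exp(-conc @ basis.matrix())
    if model.noise_sd > 0:
        refl = refl + rng.normal(0.0, model.noise_sd, refl.shape)
    return np.clip(refl, 0.0, None).astype(np.float32)


@dataclass
class CohortConfig:
    """Study-condition knobs for the synthetic cohort.

    Defaults emulate the study design at desk scale: 20 animals, one image
    each, a large colon-mesocolon region and a thin retroperitoneal strip
    per image at a ~4.3:1 pixel imbalance.
    """

    n_animals: int = 20
    image_shape: tuple[int, int] = (160, 120)   # (H, W)
    target_imbalance: float = 4.3
    retro_region_thickness: int = 6             # strip thickness, pixels
    colon_region_area: int = 170                # nominal colon-mesocolon pixels
    separation: float = 1.0
    noise_sd: float = 0.01
    animal_sd: float = 0.05
    pixel_jitter_sd: float = 0.03
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_animals < 1:
            raise ConfigurationError("n_animals must be >= 1")
        if self.target_imbalance <= 0:
            raise ConfigurationError("target_imbalance must be positive")


def _animal_rng(cfg: CohortConfig, animal_index: int) -> np.random.Generator:
    """Per-animal substream derived by stable hashing of (seed, animal_index)."""
    return np.random.default_rng(np.random.SeedSequence((cfg.seed, animal_index)))


def _ellipse_mask(h: int, w: int, center: tuple[float, float],
                  semi_axes: tuple[float, float], angle: float) -> np.ndarray:
    rows, cols = np.mgrid[0:h, 0:w]
    dr, dc = rows - center[0], cols - center[1]
    ca, sa = np.cos(angle), np.sin(angle)
    u = ca * dr + sa * dc
    v = -sa * dr + ca * dc
    return (u / semi_axes[0]) ** 2 + (v / semi_axes[1]) ** 2 <= 1.0


def _strip_mask(h: int, w: int, center: tuple[float, float], angle: float,
                half_length: float, half_thickness: float) -> np.ndarray:
    rows, cols = np.mgrid[0:h, 0:w]
    dr, dc = rows - center[0], cols - center[1]
    along = np.cos(angle) * dr + np.sin(angle) * dc
    across = -np.sin(angle) * dr + np.cos(angle) * dc
    return (np.abs(along) <= half_length) & (np.abs(across) <= half_thickness)


def generate_animal(cfg: CohortConfig, animal_index: int,
                    basis: AbsorberBasis | None = None
                    ) -> tuple[Hypercube, AnnotationMask]:
    """Generate one animal's hypercube and annotation mask.

    The mask contains one large colon-mesocolon region (ellipse), one thin
    retroperitoneal strip, and unlabeled background rendered from a mixed,
    noisier tissue model.  Deterministic given (cfg.seed, animal_index).
    """
    if animal_index >= cfg.n_animals:
        raise ValueError(f"animal_index {animal_index} >= n_animals {cfg.n_animals}")
    h, w = cfg.image_shape
    margin = 4  # keep annotated regions clear of the patch-window border
    if h < 8 * margin or w < 8 * margin:
        raise ConfigurationError(
            f"image shape {cfg.image_shape} too small to place both tissue regions")

    rng = _animal_rng(cfg, animal_index)
    basis = basis or make_absorber_basis()
    models = class_tissue_models(cfg.separation, cfg.noise_sd,
                                 cfg.animal_sd, cfg.pixel_jitter_sd)

    # scene geometry: ellipse on one side, thin strip on the other
    area = cfg.colon_region_area * rng.uniform(0.9, 1.1)
    aspect = rng.uniform(1.4, 2.0)
    a_ax = np.sqrt(area * aspect / np.pi)
    b_ax = area / (np.pi * a_ax)
    if 2 * a_ax > h - 4 * margin or 2 * a_ax > w / 2:
        raise ConfigurationError(
            f"colon region (semi-axis {a_ax:.0f}px) does not fit image {cfg.image_shape}")
    ell_center = (rng.uniform(0.30, 0.70) * h, rng.uniform(0.22, 0.38) * w)
    colon = _ellipse_mask(h, w, ell_center, (a_ax, b_ax), rng.uniform(0, np.pi))

    strip_area = area / cfg.target_imbalance
    half_t = cfg.retro_region_thickness / 2.0
    half_len = strip_area / (2.0 * cfg.retro_region_thickness)
    strip_center = (rng.uniform(0.30, 0.70) * h, rng.uniform(0.68, 0.82) * w)
    strip_angle = rng.uniform(-0.45, 0.45) + np.pi / 2  # roughly vertical strip
    retro = _strip_mask(h, w, strip_center, strip_angle, half_len, half_t)
    retro &= ~colon  # regions never overlap

    # keep every annotated pixel inside the patch-window margin
    border = np.zeros((h, w), dtype=bool)
    border[margin:h - margin, margin:w - margin] = True
    colon &= border
    retro &= border
    if colon.sum() == 0 or retro.sum() == 0:
        raise ConfigurationError("a tissue region vanished; image too small")

    labels = np.zeros((h, w), dtype=np.uint8)
    labels[colon] = 1
    labels[retro] = 2

    # shared per-animal concentration offsets (animal-level spectral variability)
    animal_offset = rng.normal(0.0, cfg.animal_sd, len(ABSORBERS))

    data = np.empty((h, w, len(basis.wavelengths)), dtype=np.float32)
    unlabeled = labels == 0
    mixed_conc = {a: 0.5 * (models[1].concentrations[a] + models[2].concentrations[a])
                  for a in ABSORBERS}
    background = replace(models[1], class_label=0, concentrations=mixed_conc,
                         noise_sd=3.0 * cfg.noise_sd,
                         pixel_jitter_sd=2.0 * cfg.pixel_jitter_sd)
    for model, region in ((background, unlabeled), (models[1], colon), (models[2], retro)):
        n = int(region.sum())
        if n:
            data[region] = _render_pixels(model, basis, rng, n, animal_offset)

    cube = Hypercube(data, basis.wavelengths.astype(np.float32),
                     animal_id=f"animal{animal_index:02d}",
                     capture_meta={"synthetic": "true", "animal_index": animal_index})
    return cube, AnnotationMask(labels)


def generate_cohort(cfg: CohortConfig, out_dir=None,
                    ) -> list[tuple[Hypercube, AnnotationMask]]:
    """Generate the full cohort (one image per animal), optionally writing it.

    When ``out_dir`` is given, cubes (HDF5), masks (PNG) and a manifest CSV
    (animal_id, files, per-label pixel counts) are written there.
    """
    basis = make_absorber_basis()
    cohort = [generate_animal(cfg, i, basis) for i in range(cfg.n_animals)]

    pooled = {1: 0, 2: 0}
    for _, mask in cohort:
        counts = mask.label_counts()
        pooled[1] += counts.get(1, 0)
        pooled[2] += counts.get(2, 0)
    logger.info("cohort imbalance: %.2f:1 (target %.2f:1)",
                pooled[1] / max(pooled[2], 1), cfg.target_imbalance)

    if out_dir is not None:
        from pathlib import Path

        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        rows = []
        for cube, mask in cohort:
            cube_file = out / f"{cube.animal_id}.h5"
            mask_file = out / f"{cube.animal_id}_mask.png"
            write_cube(cube, cube_file)
            write_mask(mask, mask_file)
            counts = mask.label_counts()
            rows.append({"animal_id": cube.animal_id,
                         "cube_file": cube_file.name, "mask_file": mask_file.name,
                         "n_colon_mesocolon": counts.get(1, 0),
                         "n_retroperitoneum": counts.get(2, 0)})
        pd.DataFrame(rows).to_csv(out / "manifest.csv", index=False)
    return cohort
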