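"""Hypercube and annotation-mask I/O, spectral binning, display rendering.

A hypercube is an H x W x B reflectance volume (relative, unitless values)
with a strictly increasing wavelength vector of band centers in nm.  The
camera emulated here acquires 501 one-nanometre bands from 500-1000 nm and
bins them 5x into 100 bins whose nominal wavelengths are the bin-start
values 500, 505, ..., 995 nm.  Annotation masks are H x W integer fields
over {0 = unlabeled, 1 = colon-mesocolon (resect), 2 = retroperitoneum
(preserve)}, stored as lossless PNG with a fixed color palette.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import h5py
import numpy as np
import yaml
from PIL import Image

logger = logging.getLogger(__name__)

N_RAW_BANDS = 501
N_BINNED_BANDS = 100
BIN_FACTOR = 5
BINNED_WAVELENGTHS = np.arange(500.0, 1000.0, 5.0, dtype=np.float32)

#: exact annotation palette: label -> RGB triplet (configurable via YAML)
DEFAULT_PALETTE = {1: (0, 255, 0), 2: (128, 0, 128)}
DEFAULT_DISPLAY_WAVELENGTHS = (640.0, 550.0, 500.0)

LABEL_UNLABELED = 0
LABEL_COLON_MESOCOLON = 1
LABEL_RETROPERITONEUM = 2


class HypercubeFormatError(ValueError):
    """A container file is missing a required dataset or attribute."""


class ShapeError(ValueError):
    """Spatial or spectral dimensions do not match the contract."""


@dataclass
class Hypercube:
    """Reflectance volume with wavelength calibration and animal identity.

    Attributes
    ----------
    data : ndarray, shape (H, W, B)
        Relative reflectance, finite and non-negative.
    wavelengths : ndarray, shape (B,)
        Band-center wavelengths in nm, strictly increasing.
    animal_id : str
        Opaque identifier of the source animal.
    capture_meta : dict
        Optional free-form acquisition metadata.
    """

    data: np.ndarray
    wavelengths: np.ndarray
    animal_id: str
    capture_meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float32)
        self.wavelengths = np.asarray(self.wavelengths, dtype=np.float32)
        if self.data.ndim != 3:
            raise ShapeError(f"hypercube must be H x W x B, got shape {self.data.shape}")
        if self.wavelengths.ndim != 1 or len(self.wavelengths) != self.data.shape[2]:
            raise ShapeError(
                f"wavelength vector length {self.wavelengths.shape} does not match "
                f"band count {self.data.shape[2]}"
            )
        if not np.all(np.diff(self.wavelengths) > 0):
            raise ValueError("wavelengths must be strictly increasing")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("reflectance values must be finite")
        if self.data.min() < 0:
            raise ValueError("reflectance values must be non-negative")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def n_bands(self) -> int:
        return self.data.shape[2]


@dataclass
class AnnotationMask:
    """Per-pixel tissue labels: 0 unlabeled, 1 colon-mesocolon, 2 retroperitoneum."""

    labels: np.ndarray

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=np.uint8)
        if self.labels.ndim != 2:
            raise ShapeError(f"mask must be 2-D, got shape {self.labels.shape}")
        bad = set(np.unique(self.labels)) - {0, 1, 2}
        if bad:
            raise ValueError(f"mask contains invalid labels {sorted(bad)}; allowed: 0, 1, 2")

    @property
    def shape(self) -> tuple[int, int]:
        return self.labels.shape

    def label_counts(self) -> dict[int, int]:
        """Pixel count per label value actually present."""
        values, counts = np.unique(self.labels, return_counts=True)
        return {int(v): int(c) for v, c in zip(values, counts)}


def bin_spectral(raw_cube: np.ndarray, factor: int = BIN_FACTOR) -> Hypercube:
    """Bin a raw 501-band, 1 nm cube (500-1000 nm) down to 100 spectral bins.

    Bin ``i`` is the arithmetic mean of the five 1 nm bands at
    ``500 + 5i .. 504 + 5i`` nm, so the final 1000 nm band is unused and
    bin 99 averages 995-999 nm.  Output wavelengths are the bin-start
    values 500, 505, ..., 995 nm.

    Parameters
    ----------
    raw_cube : ndarray, shape (H, W, 501) or Hypercube
    factor : int
        Binning factor; must divide 500 (default 5).
    """
    animal_id = "unknown"
    meta: dict = {}
    if isinstance(raw_cube, Hypercube):
        animal_id, meta = raw_cube.animal_id, raw_cube.capture_meta
        raw_cube = raw_cube.data
    raw_cube = np.asarray(raw_cube, dtype=np.float32)
    if raw_cube.ndim != 3 or raw_cube.shape[2] != N_RAW_BANDS:
        raise ShapeError(
            f"raw cube must have exactly {N_RAW_BANDS} bands (500-1000 nm at 1 nm), "
            f"got shape {raw_cube.shape}"
        )
    if factor <= 0 or 500 % factor != 0:
        raise ValueError(f"binning factor must divide 500, got {factor}")
    h, w, _ = raw_cube.shape
    n_bins = 500 // factor
    # drop the trailing 1000 nm band, then average disjoint groups of `factor`
    binned = raw_cube[:, :, :500].reshape(h, w, n_bins, factor).mean(axis=3)
    wavelengths = np.arange(500.0, 1000.0, float(factor), dtype=np.float32)
    return Hypercube(binned.astype(np.float32), wavelengths, animal_id, dict(meta))


def write_cube(cube: Hypercube, path: str | Path) -> None:
    """Write a hypercube to a single-file HDF5 container."""
    with h5py.File(path, "w") as f:
        f.create_dataset("reflectance", data=cube.data.astype(np.float32))
        f.create_dataset("wavelengths_nm", data=cube.wavelengths.astype(np.float32))
        f.attrs["animal_id"] = cube.animal_id
        for key, value in cube.capture_meta.items():
            f.attrs[f"meta_{key}"] = value


def read_cube(path: str | Path) -> Hypercube:
    """Read a hypercube written by :func:`write_cube`.

    Raises
    ------
    HypercubeFormatError
        If a required dataset ("reflectance", "wavelengths_nm") or the
        "animal_id" attribute is missing.
    """
    with h5py.File(path, "r") as f:
        for name in ("reflectance", "wavelengths_nm"):
            if name not in f:
                raise HypercubeFormatError(f"{path}: missing required dataset '{name}'")
        if "animal_id" not in f.attrs:
            raise HypercubeFormatError(f"{path}: missing required attribute 'animal_id'")
        data = f["reflectance"][()]
        wavelengths = f["wavelengths_nm"][()]
        animal_id = f.attrs["animal_id"]
        if isinstance(animal_id, bytes):
            animal_id = animal_id.decode()
        meta = {
            k[len("meta_"):]: v for k, v in f.attrs.items() if k.startswith("meta_")
        }
    return Hypercube(data, wavelengths, str(animal_id), meta)


def read_cohort(directory: str | Path) -> list[Hypercube]:
    """Read every ``*.h5`` cube in a directory, sorted by filename."""
    paths = sorted(Path(directory).glob("*.h5"))
    return [read_cube(p) for p in paths]


def write_mask(mask: AnnotationMask, path: str | Path,
               palette: dict[int, tuple[int, int, int]] | None = None) -> None:
    """Write a mask as a lossless RGB PNG using the annotation palette."""
    palette = palette or DEFAULT_PALETTE
    h, w = mask.shape
    rgb = np.zeros((h, w, 3), dtype=np.uint8)
    for label, color in palette.items():
        rgb[mask.labels == label] = color
    Image.fromarray(rgb).save(path, format="PNG")


def read_mask(path: str | Path,
              expected_shape: tuple[int, int] | None = None,
              palette: dict[int, tuple[int, int, int]] | None = None) -> AnnotationMask:
    """Read an annotation PNG back into labels (exact color match).

    Pixels exactly matching the palette's green map to label 1
    (colon-mesocolon), purple to 2 (retroperitoneum); everything else is 0.
    """
    palette = palette or DEFAULT_PALETTE
    rgb = np.asarray(Image.open(path).convert("RGB"))
    labels = np.zeros(rgb.shape[:2], dtype=np.uint8)
    for label, color in palette.items():
        labels[np.all(rgb == np.array(color, dtype=np.uint8), axis=-1)] = label
    mask = AnnotationMask(labels)
    if expected_shape is not None and mask.shape != tuple(expected_shape):
        raise ShapeError(
            f"{path}: mask shape {mask.shape} does not match paired cube "
            f"spatial shape {tuple(expected_shape)}"
        )
    logger.debug("read_mask %s: label counts %s", path, mask.label_counts())
    return mask


def extract_rgb(cube: Hypercube,
                display_wavelengths: tuple[float, float, float] = DEFAULT_DISPLAY_WAVELENGTHS
                ) -> np.ndarray:
    """Render an H x W x 3 display image from three spectral bands.

    Each channel takes the band nearest the requested display wavelength
    (default 640/550/500 nm for R/G/B) and is independently min-max scaled
    to [0, 1]; a zero-range band renders as constant 0.5 gray.
    """
    lo, hi = float(cube.wavelengths[0]), float(cube.wavelengths[-1])
    out = np.zeros((*cube.shape[:2], 3), dtype=np.float32)
    for i, wl in enumerate(display_wavelengths):
        if not (lo <= wl <= hi):
            raise ValueError(
                f"display wavelength {wl} nm outside cube range [{lo}, {hi}] nm"
            )
        band = cube.data[:, :, int(np.argmin(np.abs(cube.wavelengths - wl)))]
        rng = band.max() - band.min()
        out[:, :, i] = 0.5 if rng == 0 else (band - band.min()) / rng
    return out


@dataclass
class DisplayConfig:
    """Rendering and palette settings, loadable from a YAML file."""

    display_wavelengths: tuple[float, float, float] = DEFAULT_DISPLAY_WAVELENGTHS
    palette: dict[int, tuple[int, int, int]] = field(
        default_factory=lambda: dict(DEFAULT_PALETTE))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "DisplayConfig":
        with open(path) as f:
            raw = yaml.safe_load(f) or {}
        kwargs = {}
        if "display_wavelengths" in raw:
            kwargs["display_wavelengths"] = tuple(float(x) for x in raw["display_wavelengths"])
        if "palette" in raw:
            kwargs["palette"] = {int(k): tuple(int(c) for c in v)
                                 for k, v in raw["palette"].items()}
        return cls(**kwargs)
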