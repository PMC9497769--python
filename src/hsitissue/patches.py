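"""Sub-volume extraction and class-balance weighting.

Every annotated pixel whose full spatial window fits inside the image
yields one training sample: a ``window x window x B`` sub-volume centered
on the pixel (default 5 x 5 x 100).  Class imbalance is handled downstream
by inverse median frequency weighting of the loss.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import h5py
import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .io import AnnotationMask, Hypercube, ShapeError

logger = logging.getLogger(__name__)


@dataclass
class PatchSet:
    """N annotated sub-volumes with labels, provenance and coordinates.

    Attributes
    ----------
    patches : ndarray, shape (N, window, window, B)
    labels : ndarray, shape (N,), values in {1, 2}
    animal_ids : ndarray of str, shape (N,)
    coords : ndarray, shape (N, 2)
        (row, col) center position of each patch in its source image.
    n_excluded_border : int
        Annotated pixels skipped because their window crossed the border.
    """

    patches: np.ndarray
    labels: np.ndarray
    animal_ids: np.ndarray
    coords: np.ndarray
    n_excluded_border: int = 0

    def __len__(self) -> int:
        return len(self.labels)

    @property
    def window(self) -> int:
        return self.patches.shape[1]

    def label_counts(self) -> dict[int, int]:
        values, counts = np.unique(self.labels, return_counts=True)
        return {int(v): int(c) for v, c in zip(values, counts)}

    def subset(self, index: np.ndarray) -> "PatchSet":
        return PatchSet(self.patches[index], self.labels[index],
                        self.animal_ids[index], self.coords[index],
                        self.n_excluded_border)


def count_labeled_inbounds(mask: AnnotationMask, window: int = 5) -> int:
    """Annotated pixels whose full window fits inside the image."""
    margin = (window - 1) // 2
    h, w = mask.shape
    interior = np.zeros((h, w), dtype=bool)
    if h > 2 * margin and w > 2 * margin:
        interior[margin:h - margin, margin:w - margin] = True
    return int(((mask.labels > 0) & interior).sum())


def extract_patches(cube: Hypercube, mask: AnnotationMask,
                    window: int = 5) -> PatchSet:
    """Extract one sub-volume per in-bounds annotated pixel.

    Samples are ordered row-major by center coordinate.  Annotated pixels
    too close to the border for a full window are excluded (no padding) and
    counted in ``n_excluded_border``.
    """
    if window % 2 == 0 or window < 1:
        raise ValueError(f"window must be a positive odd integer, got {window}")
    if cube.shape[:2] != mask.shape:
        raise ShapeError(
            f"cube spatial shape {cube.shape[:2]} != mask shape {mask.shape}")
    margin = (window - 1) // 2
    h, w = mask.shape
    labeled = mask.labels > 0
    interior = np.zeros((h, w), dtype=bool)
    if h >= window and w >= window:
        interior[margin:h - margin, margin:w - margin] = True
    keep = labeled & interior
    n_excluded = int(labeled.sum() - keep.sum())
    if n_excluded:
        logger.debug("extract_patches: excluded %d border-adjacent annotated pixels",
                     n_excluded)

    coords = np.argwhere(keep)  # row-major order by construction
    n = len(coords)
    b = cube.n_bands
    if n == 0:
        return PatchSet(np.empty((0, window, window, b), dtype=np.float32),
                        np.empty(0, dtype=np.int64),
                        np.empty(0, dtype=object),
                        np.empty((0, 2), dtype=np.int64), n_excluded)

    # windows[r, c] is the window whose top-left corner is (r, c)
    windows = sliding_window_view(cube.data, (window, window), axis=(0, 1))
    patches = windows[coords[:, 0] - margin, coords[:, 1] - margin]  # (N, B, win, win)
    patches = np.ascontiguousarray(np.moveaxis(patches, 1, -1))      # (N, win, win, B)
    labels = mask.labels[coords[:, 0], coords[:, 1]].astype(np.int64)
    animal_ids = np.full(n, cube.animal_id, dtype=object)
    return PatchSet(patches.astype(np.float32), labels, animal_ids,
                    coords.astype(np.int64), n_excluded)


def concat_patchsets(patchsets: list[PatchSet]) -> PatchSet:
    """Concatenate patch sets (e.g., one per image) preserving order."""
    if not patchsets:
        raise ValueError("no patch sets to concatenate")
    return PatchSet(
        np.concatenate([p.patches for p in patchsets]),
        np.concatenate([p.labels for p in patchsets]),
        np.concatenate([p.animal_ids for p in patchsets]),
        np.concatenate([p.coords for p in patchsets]),
        sum(p.n_excluded_border for p in patchsets),
    )


@dataclass
class ClassWeights:
    """Per-class loss weights from inverse median frequency balancing."""

    weights: dict[int, float]

    def __post_init__(self) -> None:
        if any(w <= 0 for w in self.weights.values()):
            raise ValueError("class weights must be positive")

    def as_array(self, classes: tuple[int, ...] = (1, 2)) -> np.ndarray:
        return np.array([self.weights[c] for c in classes], dtype=np.float32)


def compute_class_weights(label_counts: dict[int, int]) -> ClassWeights:
    """Inverse median frequency weights: w_c = median(frequencies) / frequency_c.

    For two classes the median of the two frequencies is their midpoint, so
    w_c · f_c = 1/2 for both classes.  Equal counts give weights (1, 1);
    the minority class always receives the larger weight.
    """
    if not label_counts:
        raise ValueError("no classes given")
    for c, n in label_counts.items():
        if n <= 0:
            raise ValueError(
                f"class {c} has count {n}; every class must be present in training data")
    total = sum(label_counts.values())
    freqs = {c: n / total for c, n in label_counts.items()}
    med = float(np.median(list(freqs.values())))
    return ClassWeights({c: med / f for c, f in freqs.items()})


def save_patchset(ps: PatchSet, path) -> None:
    """Serialize a patch set to the HDF5 container."""
    with h5py.File(path, "w") as f:
        f.create_dataset("patches", data=ps.patches)
        f.create_dataset("labels", data=ps.labels)
        f.create_dataset("animal_ids",
                         data=np.asarray(ps.animal_ids, dtype="S"))
        f.create_dataset("coords", data=ps.coords)
        f.attrs["n_excluded_border"] = ps.n_excluded_border


def load_patchset(path) -> PatchSet:
    with h5py.File(path, "r") as f:
        return PatchSet(
            f["patches"][()], f["labels"][()],
            np.array([s.decode() for s in f["animal_ids"][()]], dtype=object),
            f["coords"][()], int(f.attrs.get("n_excluded_border", 0)),
        )
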