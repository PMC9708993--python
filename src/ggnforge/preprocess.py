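"""Slice preprocessing: lung seed-fill, background stripping, normalisation,
and nodule erasure into training pairs.

The chain mirrors standard inpainting-style preparation of annotated chest
slices: (1) segment the lung fields by seed-filling the low-attenuation
region around an interior point, (2) zero the non-lung background and centre
the lung content on a fixed-size canvas, (3) window-normalise intensities to
[0, 1], and (4) blank a fixed-size square region of interest (ROI) around
each nodule, keeping the original slice as the ground-truth target.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .types import Box, CTSlice, NoduleAnnotation, TrainingPair

__all__ = [
    "PreprocessConfig",
    "segment_lung_seed_fill",
    "auto_seed_points",
    "strip_and_pad",
    "normalize_intensity",
    "blank_roi",
    "SeedPlacementError",
]


class SeedPlacementError(ValueError):
    """Seed pixel is at or above the fill threshold."""


@dataclass
class PreprocessConfig:
    target_size: int = 512
    roi_size: int = 32
    hu_window: tuple[float, float] = (-1000.0, 400.0)
    seed_points: list[tuple[int, int]] | str = "auto"

    def __post_init__(self) -> None:
        if self.roi_size >= self.target_size:
            raise ValueError("roi_size must be smaller than target_size")
        lo, hi = self.hu_window
        if lo >= hi:
            raise ValueError(f"degenerate window {self.hu_window}")


def segment_lung_seed_fill(
    slice_: CTSlice, seed_point: tuple[int, int], threshold: float
) -> np.ndarray:
    """Region-grow from ``seed_point`` over pixels below ``threshold``.

    Returns the 4-connected component of ``pixels < threshold`` that
    contains the seed — the flood fill grows outward from the interior
    point until it meets the at-or-above-threshold boundary.
    """
    r, c = seed_point
    px = slice_.pixels
    if not (0 <= r < px.shape[0] and 0 <= c < px.shape[1]):
        raise SeedPlacementError(f"seed {seed_point} outside the grid")
    if px[r, c] >= threshold:
        raise SeedPlacementError(
            f"seed pixel intensity {px[r, c]} is not below threshold {threshold}"
        )
    below = px < threshold
    structure = np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]])  # 4-connectivity
    labels, _ = ndimage.label(below, structure=structure)
    return labels == labels[r, c]


def auto_seed_points(slice_: CTSlice, threshold: float) -> list[tuple[int, int]]:
    """Pick one interior seed per lung on the mid-height row.

    Scans the middle row of the body for runs of below-threshold pixels and
    returns the midpoint of the two longest runs (left and right lung).
    """
    px = slice_.pixels
    mid = px.shape[0] // 2
    row = px[mid] < threshold
    runs: list[tuple[int, int]] = []
    start = None
    for j, low in enumerate(list(row) + [False]):
        if low and start is None:
            start = j
        elif not low and start is not None:
            runs.append((start, j))
            start = None
    # drop runs touching the image border (air outside the body)
    interior = [(a, b) for a, b in runs if a > 0 and b < px.shape[1]]
    interior.sort(key=lambda ab: ab[1] - ab[0], reverse=True)
    return [(mid, (a + b) // 2) for a, b in interior[:2]]


def strip_and_pad(
    slice_: CTSlice, lung_mask: np.ndarray, target_size: int
) -> tuple[CTSlice, tuple[int, int]]:
    """Zero non-lung pixels and centre the lung bbox on a zero canvas.

    Returns the padded slice and the (row, col) offset that maps original
    coordinates into the new canvas (new = old - bbox_min + offset_in_canvas),
    so annotation coordinates can be remapped.
    """
    lung_mask = np.asarray(lung_mask, dtype=bool)
    if not lung_mask.any():
        raise ValueError("empty lung mask")
    rows = np.flatnonzero(lung_mask.any(axis=1))
    cols = np.flatnonzero(lung_mask.any(axis=0))
    r0, r1 = int(rows[0]), int(rows[-1]) + 1
    c0, c1 = int(cols[0]), int(cols[-1]) + 1
    h, w = r1 - r0, c1 - c0
    if h > target_size or w > target_size:
        raise ValueError(
            f"mask bbox {h}x{w} does not fit in target size {target_size}"
        )
    stripped = np.where(lung_mask, slice_.pixels, 0.0)
    canvas = np.zeros((target_size, target_size))
    ro = (target_size - h) // 2
    co = (target_size - w) // 2
    canvas[ro : ro + h, co : co + w] = stripped[r0:r1, c0:c1]
    offset = (ro - r0, co - c0)
    out = CTSlice(canvas, spacing=slice_.spacing, normalized=slice_.normalized,
                  id=slice_.id)
    return out, offset


def normalize_intensity(slice_: CTSlice, hu_window: tuple[float, float]) -> CTSlice:
    """Clip to the window and rescale linearly to [0, 1]."""
    lo, hi = hu_window
    if lo >= hi:
        raise ValueError(f"degenerate window {hu_window}")
    scaled = np.clip((slice_.pixels - lo) / (hi - lo), 0.0, 1.0)
    return CTSlice(scaled, spacing=slice_.spacing, normalized=True, id=slice_.id)


def roi_box_for(
    centroid: tuple[int, int], roi_size: int, shape: tuple[int, int]
) -> Box:
    """Square box of side roi_size centred on the centroid, shifted (never
    shrunk) to fit inside ``shape``."""
    r, c = centroid
    half = roi_size // 2
    r0 = min(max(r - half, 0), shape[0] - roi_size)
    c0 = min(max(c - half, 0), shape[1] - roi_size)
    return (r0, c0, r0 + roi_size, c0 + roi_size)


def blank_roi(
    slice_: CTSlice, annotation: NoduleAnnotation, roi_size: int
) -> TrainingPair:
    """Erase the fixed-size ROI around the nodule; return the training pair."""
    if not slice_.normalized:
        raise ValueError("blank_roi expects a normalized slice")
    n_r, n_c = slice_.shape
    if roi_size >= min(n_r, n_c):
        raise ValueError(f"roi_size {roi_size} must be smaller than the image side")
    r, c = annotation.centroid
    if not (0 <= r < n_r and 0 <= c < n_c):
        raise ValueError(f"centroid {annotation.centroid} outside the grid")
    box = roi_box_for(annotation.centroid, roi_size, (n_r, n_c))
    mask = np.zeros((n_r, n_c), dtype=bool)
    r0, c0, r1, c1 = box
    mask[r0:r1, c0:c1] = True
    blanked = slice_.pixels.copy()
    blanked[mask] = 0.0
    inp = CTSlice(blanked, spacing=slice_.spacing, normalized=True,
                  id=slice_.id + "-blanked")
    return TrainingPair(
        input_image=inp,
        target_image=slice_.copy(),
        roi_mask=mask,
        roi_box=box,
        annotation_id=annotation.id,
    )
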