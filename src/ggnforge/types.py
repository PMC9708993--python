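"""Core in-memory containers shared by every stage of the pipeline.

A :class:`CTSlice` is one 2-D grayscale slice with isotropic pixel spacing,
either on a raw Hounsfield-like scale or normalised to [0, 1].  A
:class:`NoduleAnnotation` locates a single nodule on a slice using 0-based
(row, col) coordinates and half-open bounding boxes.  A
:class:`TrainingPair` is the supervision unit for inpainting: the target
slice, the same slice with the nodule region blanked to zero, and the mask /
box of the blanked region.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

__all__ = ["CTSlice", "NoduleAnnotation", "TrainingPair", "Box"]

#: Half-open bounding box (row_min, col_min, row_max, col_max), 0-based.
Box = tuple[int, int, int, int]


@dataclass
class CTSlice:
    """One 2-D grayscale intensity grid plus pixel-spacing metadata."""

    pixels: np.ndarray
    spacing: float = 1.0
    normalized: bool = False
    id: str = ""

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=np.float64)
        if self.pixels.ndim != 2 or self.pixels.size == 0:
            raise ValueError("pixels must be a non-empty 2-D grid")
        if self.spacing <= 0:
            raise ValueError("spacing must be positive")
        if self.normalized:
            lo, hi = float(self.pixels.min()), float(self.pixels.max())
            if lo < -1e-9 or hi > 1 + 1e-9:
                raise ValueError(
                    f"normalized slice has intensities outside [0, 1]: [{lo}, {hi}]"
                )

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape  # type: ignore[return-value]

    def copy(self, **changes) -> "CTSlice":
        out = replace(self, **changes)
        if "pixels" not in changes:
            out.pixels = self.pixels.copy()
        return out


@dataclass
class NoduleAnnotation:
    """Location and texture grade of one nodule on a slice.

    Grades follow the five-level solidity scale used for screening CT
    nodules: 1 = pure ground-glass opacity, 5 = solid; grades 1-2 are
    treated as ground-glass nodules (GGNs).
    """

    centroid: tuple[int, int]
    bbox: Box
    grade: int
    id: str = ""

    def __post_init__(self) -> None:
        if not 1 <= self.grade <= 5:
            raise ValueError(f"grade must be in 1..5, got {self.grade}")
        r0, c0, r1, c1 = self.bbox
        if not (r0 < r1 and c0 < c1):
            raise ValueError(f"bbox must be non-empty and half-open, got {self.bbox}")
        r, c = self.centroid
        if not (r0 <= r < r1 and c0 <= c < c1):
            raise ValueError(f"bbox {self.bbox} does not contain centroid {self.centroid}")

    @property
    def is_ggn(self) -> bool:
        return self.grade <= 2


@dataclass
class TrainingPair:
    """(blanked input, ground-truth target, ROI mask, ROI box) for the GAN.

    Invariants: input == target wherever the mask is 0, input == 0 wherever
    the mask is 1, and the mask support is exactly the interior of roi_box.
    """

    input_image: CTSlice
    target_image: CTSlice
    roi_mask: np.ndarray
    roi_box: Box
    annotation_id: str = ""

    def __post_init__(self) -> None:
        self.roi_mask = np.asarray(self.roi_mask, dtype=bool)
        if self.roi_mask.shape != self.target_image.shape:
            raise ValueError("roi_mask shape must match the images")
        if self.input_image.shape != self.target_image.shape:
            raise ValueError("input and target shapes differ")
        box_mask = np.zeros_like(self.roi_mask)
        r0, c0, r1, c1 = self.roi_box
        box_mask[r0:r1, c0:c1] = True
        if not np.array_equal(box_mask, self.roi_mask):
            raise ValueError("roi_mask support must equal the interior of roi_box")
        inp, tgt = self.input_image.pixels, self.target_image.pixels
        if np.any(inp[self.roi_mask] != 0):
            raise ValueError("input_image must be 0 inside the ROI")
        if np.any(inp[~self.roi_mask] != tgt[~self.roi_mask]):
            raise ValueError("input_image must equal target_image outside the ROI")
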