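"""Seeded synthetic lung-slice phantoms with implanted nodules.

Generates 2-D chest-slice look-alikes on a Hounsfield-like intensity scale:
air background around an elliptical body, two elliptical low-attenuation
lung fields with additive noise and bright curvilinear vessels, and a single
implanted lesion per slice -- either subsolid (ground-glass, grades 1-2,
radially decaying textured opacity) or solid (grade 5, near-uniform disc).
Every output is a pure function of (config, seed), so the phantoms serve as
a fully reproducible stand-in for annotated screening-CT slices.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .types import CTSlice, NoduleAnnotation

__all__ = [
    "PhantomConfig",
    "generate_lung_slice",
    "implant_lesion",
    "make_phantom_dataset",
    "DegenerateLesionError",
    "PlacementError",
]

# Hounsfield-like reference intensities
AIR_HU = -1000.0
LUNG_HU = -800.0
TISSUE_HU = 40.0

#: pixels changed by more than this amount count as lesion support
LESION_EPS = 1e-6

_MAX_PLACEMENT_ATTEMPTS = 20


class PlacementError(ValueError):
    """Lesion centre falls outside the lung mask."""


class DegenerateLesionError(ValueError):
    """Lesion parameters produce no visible intensity change."""


@dataclass
class PhantomConfig:
    image_size: int = 64
    # two lung ellipses as (center_row_frac, center_col_frac, ax_row_frac, ax_col_frac)
    lung_ellipse_params: tuple[tuple[float, float, float, float], ...] = (
        (0.52, 0.30, 0.33, 0.17),
        (0.52, 0.70, 0.33, 0.17),
    )
    vessel_count: int = 6
    noise_sd: float = 25.0
    lesion_radius_range: tuple[float, float] = (3.0, 7.0)
    lesion_peak_opacity_range: tuple[float, float] = (0.35, 0.75)
    texture_scale: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.image_size <= 0:
            raise ValueError(f"image_size must be positive, got {self.image_size}")
        lo, hi = self.lesion_radius_range
        if hi > self.image_size / 8:
            raise ValueError("lesion radius must be <= image_size / 8")
        olo, ohi = self.lesion_peak_opacity_range
        if not (0 < olo <= ohi <= 1):
            raise ValueError("opacity range must lie within (0, 1]")


def _ellipse_mask(size: int, cr: float, cc: float, ar: float, ac: float) -> np.ndarray:
    rr, cc_ = np.mgrid[0:size, 0:size]
    return ((rr - cr * size) / (ar * size)) ** 2 + ((cc_ - cc * size) / (ac * size)) ** 2 <= 1.0


def _body_mask(size: int) -> np.ndarray:
    # soft-tissue thorax ellipse surrounding both lungs
    return _ellipse_mask(size, 0.52, 0.50, 0.42, 0.45)


def generate_lung_slice(
    config: PhantomConfig, seed: int | None = None
) -> tuple[CTSlice, np.ndarray]:
    """Render one phantom slice; returns the slice and its lung-field mask.

    Outside the body the intensity is air (-1000); the body is soft tissue
    (+40); the two lung ellipses sit at -800 plus Gaussian noise of sd
    ``config.noise_sd``, threaded by ``config.vessel_count`` bright
    curvilinear vessels.  Identical (config, seed) gives bit-identical
    output.
    """
    if config.image_size < 32:
        raise ValueError(f"image_size must be >= 32, got {config.image_size}")
    if seed is None:
        seed = config.seed
    rng = np.random.default_rng(seed)
    n = config.image_size

    img = np.full((n, n), AIR_HU)
    body = _body_mask(n)
    img[body] = TISSUE_HU

    lung = np.zeros((n, n), dtype=bool)
    for cr, cc, ar, ac in config.lung_ellipse_params:
        lung |= _ellipse_mask(n, cr, cc, ar, ac)
    lung &= body
    img[lung] = LUNG_HU

    if config.noise_sd > 0:
        noise = rng.normal(0.0, config.noise_sd, size=(n, n))
        img[lung] += noise[lung]

    # vessels: smooth random-walk polylines through the lungs, drawn bright
    lung_idx = np.argwhere(lung)
    for _ in range(config.vessel_count):
        if len(lung_idx) == 0:
            break
        r, c = lung_idx[rng.integers(len(lung_idx))].astype(float)
        direction = rng.uniform(0, 2 * np.pi)
        for _step in range(n):
            ri, ci = int(round(r)), int(round(c))
            if not (0 <= ri < n and 0 <= ci < n) or not lung[ri, ci]:
                break
            img[ri, ci] = LUNG_HU + 500.0
            direction += rng.normal(0.0, 0.35)
            r += np.sin(direction)
            c += np.cos(direction)

    return CTSlice(img, spacing=0.7, normalized=False, id=f"phantom-{seed}"), lung


def implant_lesion(
    slice_: CTSlice,
    lung_mask: np.ndarray,
    center: tuple[int, int],
    radius: float,
    peak_opacity: float,
    grade: int,
    seed: int = 0,
    texture_sigma: float = 2.0,
) -> tuple[CTSlice, NoduleAnnotation]:
    """Add one nodule at ``center`` and return the new slice plus annotation.

    Subsolid lesions (grade <= 2) use a radial raised-cosine opacity profile
    modulated by multiplicative smoothed noise, so their interior texture is
    non-constant; grade-5 lesions are near-uniform solid discs.  The lesion
    raises intensity from the local value toward soft tissue by
    ``peak_opacity`` at the centre, is clipped to the lung mask, and leaves
    all pixels outside its support untouched.
    """
    if radius <= 0:
        raise ValueError(f"radius must be positive, got {radius}")
    r0, c0 = center
    lung_mask = np.asarray(lung_mask, dtype=bool)
    n_r, n_c = slice_.shape
    if not (0 <= r0 < n_r and 0 <= c0 < n_c) or not lung_mask[r0, c0]:
        raise PlacementError(f"lesion center {center} is outside the lung mask")

    rng = np.random.default_rng(seed)
    rr, cc = np.mgrid[0:n_r, 0:n_c]
    dist = np.hypot(rr - r0, cc - c0)

    if grade <= 2:
        # smooth raised-cosine falloff: 1 at centre, 0 at radius
        profile = np.where(dist <= radius, 0.5 * (1 + np.cos(np.pi * dist / radius)), 0.0)
        texture = rng.normal(0.0, 1.0, size=(n_r, n_c))
        texture = ndimage.gaussian_filter(texture, max(0.5, texture_sigma))
        if texture.std() > 0:
            texture = texture / texture.std()
        profile = profile * np.clip(1.0 + 0.15 * texture, 0.0, None)
        profile = np.clip(profile, 0.0, 1.0)
    else:
        # solid: flat disc
        profile = np.where(dist <= radius, 1.0, 0.0)

    target_level = 1.0 if slice_.normalized else TISSUE_HU
    new = slice_.pixels.copy()
    add = peak_opacity * profile * (target_level - new)
    add[~lung_mask] = 0.0
    new = new + add

    changed = np.abs(new - slice_.pixels) > LESION_EPS
    if not changed.any():
        raise DegenerateLesionError(
            "lesion produced no intensity change (peak_opacity or radius too small)"
        )
    rows = np.flatnonzero(changed.any(axis=1))
    cols = np.flatnonzero(changed.any(axis=0))
    bbox = (int(rows[0]), int(cols[0]), int(rows[-1]) + 1, int(cols[-1]) + 1)
    ann = NoduleAnnotation(
        centroid=(int(r0), int(c0)),
        bbox=bbox,
        grade=grade,
        id=f"{slice_.id}-lesion-g{grade}",
    )
    out = slice_.copy(pixels=new)
    return out, ann


def make_phantom_dataset(
    n_slices: int,
    ggn_fraction: float,
    config: PhantomConfig | None = None,
    seed: int = 0,
) -> list[tuple[CTSlice, list[NoduleAnnotation], np.ndarray]]:
    """Generate ``n_slices`` phantom slices, one lesion each.

    Exactly ``round(n_slices * ggn_fraction)`` lesions are ground-glass
    (grade drawn from {1, 2}); the rest are solid (grade 5).  Lesion
    placement is retried up to a bounded attempt count before raising.
    Returns (slice, [annotation], lung_mask) triples.
    """
    if n_slices < 1:
        raise ValueError("n_slices must be >= 1")
    if not 0 <= ggn_fraction <= 1:
        raise ValueError("ggn_fraction must be in [0, 1]")
    if config is None:
        config = PhantomConfig()
    rng = np.random.default_rng(seed)

    n_ggn = int(round(n_slices * ggn_fraction))
    is_ggn_flags = np.zeros(n_slices, dtype=bool)
    is_ggn_flags[:n_ggn] = True
    rng.shuffle(is_ggn_flags)

    out = []
    for i in range(n_slices):
        slice_seed = int(rng.integers(0, 2**31 - 1))
        sl, lung = generate_lung_slice(config, seed=slice_seed)
        margin = config.lesion_radius_range[1] + 1
        # candidate centres: lung pixels eroded so the blob fits comfortably
        eroded = ndimage.binary_erosion(lung, iterations=int(margin))
        candidates = np.argwhere(eroded if eroded.any() else lung)
        last_err: Exception | None = None
        for _attempt in range(_MAX_PLACEMENT_ATTEMPTS):
            center = tuple(int(v) for v in candidates[rng.integers(len(candidates))])
            radius = rng.uniform(*config.lesion_radius_range)
            opacity = rng.uniform(*config.lesion_peak_opacity_range)
            grade = int(rng.integers(1, 3)) if is_ggn_flags[i] else 5
            try:
                sl2, ann = implant_lesion(
                    sl, lung, center, radius, opacity, grade,
                    seed=int(rng.integers(0, 2**31 - 1)),
                    texture_sigma=config.texture_scale,
                )
                break
            except (PlacementError, DegenerateLesionError) as err:  # pragma: no cover
                last_err = err
        else:  # pragma: no cover - bounded retry exhausted
            raise PlacementError(f"could not place lesion on slice {i}: {last_err}")
        sl2.id = f"phantom-{seed}-{i:04d}"
        ann.id = f"{sl2.id}-n0"
        out.append((sl2, [ann], lung))
    return out
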