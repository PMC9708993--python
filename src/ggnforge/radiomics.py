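"""Radiomic feature extraction: 93 features across six families.

Computes, over a masked 2-D region, the standard quantitative-imaging
feature set: 18 first-order statistics plus five texture-matrix families --
grey level co-occurrence (GLCM, 24), grey level dependence (GLDM, 14), grey
level run length (GLRLM, 16), grey level size zone (GLSZM, 16) and
neighbouring grey tone difference (NGTDM, 5).  Definitions follow the
reference formulations used by the common open-source radiomics extractors:
intensities are discretised with a fixed bin width (default 25 on the raw
Hounsfield-like scale), texture matrices use distance-1 neighbourhoods,
GLCM/GLRLM are computed per direction (4 directions in 2-D, symmetric) and
averaged, and GLSZM zones are 8-connected.

Log bases: entropy-type features use log2 with a small epsilon guard.
Degenerate conventions: a constant region has variance 0, skewness 0 and
kurtosis 0, and correlation-type features fall back to their no-variance
limits.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .types import CTSlice

__all__ = [
    "RadiomicsConfig", "FeatureVector", "extract_features",
    "FAMILY_COUNTS", "FEATURE_NAMES",
]

_EPS = np.finfo(np.float64).eps

FAMILY_COUNTS = {
    "firstorder": 18,
    "GLCM": 24,
    "GLDM": 14,
    "GLRLM": 16,
    "GLSZM": 16,
    "NGTDM": 5,
}

FEATURE_NAMES: dict[str, tuple[str, ...]] = {
    "firstorder": (
        "Energy", "TotalEnergy", "Entropy", "Minimum", "10Percentile",
        "90Percentile", "Maximum", "Mean", "Median", "InterquartileRange",
        "Range", "MeanAbsoluteDeviation", "RobustMeanAbsoluteDeviation",
        "RootMeanSquared", "Skewness", "Kurtosis", "Variance", "Uniformity",
    ),
    "GLCM": (
        "Autocorrelation", "JointAverage", "ClusterProminence", "ClusterShade",
        "ClusterTendency", "Contrast", "Correlation", "DifferenceAverage",
        "DifferenceEntropy", "DifferenceVariance", "JointEnergy", "JointEntropy",
        "Imc1", "Imc2", "Idm", "Idmn", "Id", "Idn", "InverseVariance",
        "MaximumProbability", "MCC", "SumAverage", "SumEntropy", "SumSquares",
    ),
    "GLDM": (
        "SmallDependenceEmphasis", "LargeDependenceEmphasis",
        "GrayLevelNonUniformity", "DependenceNonUniformity",
        "DependenceNonUniformityNormalized", "GrayLevelVariance",
        "DependenceVariance", "DependenceEntropy", "LowGrayLevelEmphasis",
        "HighGrayLevelEmphasis", "SmallDependenceLowGrayLevelEmphasis",
        "SmallDependenceHighGrayLevelEmphasis",
        "LargeDependenceLowGrayLevelEmphasis",
        "LargeDependenceHighGrayLevelEmphasis",
    ),
    "GLRLM": (
        "ShortRunEmphasis", "LongRunEmphasis", "GrayLevelNonUniformity",
        "GrayLevelNonUniformityNormalized", "RunLengthNonUniformity",
        "RunLengthNonUniformityNormalized", "RunPercentage",
        "GrayLevelVariance", "RunVariance", "RunEntropy",
        "LowGrayLevelRunEmphasis", "HighGrayLevelRunEmphasis",
        "ShortRunLowGrayLevelEmphasis", "ShortRunHighGrayLevelEmphasis",
        "LongRunLowGrayLevelEmphasis", "LongRunHighGrayLevelEmphasis",
    ),
    "GLSZM": (
        "SmallAreaEmphasis", "LargeAreaEmphasis", "GrayLevelNonUniformity",
        "GrayLevelNonUniformityNormalized", "SizeZoneNonUniformity",
        "SizeZoneNonUniformityNormalized", "ZonePercentage",
        "GrayLevelVariance", "ZoneVariance", "ZoneEntropy",
        "LowGrayLevelZoneEmphasis", "HighGrayLevelZoneEmphasis",
        "SmallAreaLowGrayLevelEmphasis", "SmallAreaHighGrayLevelEmphasis",
        "LargeAreaLowGrayLevelEmphasis", "LargeAreaHighGrayLevelEmphasis",
    ),
    "NGTDM": ("Coarseness", "Contrast", "Busyness", "Complexity", "Strength"),
}


@dataclass
class RadiomicsConfig:
    """Discretisation and geometry settings for feature extraction."""

    bin_width: float = 25.0
    distance: int = 1
    voxel_shift: float = 0.0  # added to intensities for Energy / RMS


class FeatureVector(dict):
    """Mapping (family, feature name) -> value with fixed cardinalities."""

    def validate(self) -> "FeatureVector":
        counts: dict[str, int] = {}
        for family, _name in self.keys():
            counts[family] = counts.get(family, 0) + 1
        if counts != FAMILY_COUNTS:
            raise ValueError(f"family cardinalities {counts} != {FAMILY_COUNTS}")
        if len(self) != 93:
            raise ValueError(f"expected 93 features, got {len(self)}")
        return self

    def family(self, family: str) -> dict[str, float]:
        return {name: v for (fam, name), v in self.items() if fam == family}

    def as_array(self, order: list[tuple[str, str]] | None = None) -> np.ndarray:
        keys = order if order is not None else sorted(self.keys())
        return np.array([self[k] for k in keys])


# --------------------------------------------------------------------------
# Discretisation
# --------------------------------------------------------------------------

def _discretise(values: np.ndarray, bin_width: float) -> np.ndarray:
    """Fixed-bin-width grey levels starting at 1."""
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    lo = np.floor(values.min() / bin_width)
    return (np.floor(values / bin_width) - lo + 1).astype(np.int64)


# --------------------------------------------------------------------------
# First order
# --------------------------------------------------------------------------

def _first_order(x: np.ndarray, disc: np.ndarray, spacing: float,
                 shift: float) -> dict[str, float]:
    n = x.size
    xs = x + shift
    mean = x.mean()
    var = x.var()  # population
    p10, p25, p50, p75, p90 = np.percentile(x, [10, 25, 50, 75, 90])
    robust = x[(x >= p10) & (x <= p90)]
    _, counts = np.unique(disc, return_counts=True)
    p = counts / n
    if var > 0:
        sd = np.sqrt(var)
        skew = np.mean((x - mean) ** 3) / sd ** 3
        kurt = np.mean((x - mean) ** 4) / var ** 2
    else:
        skew, kurt = 0.0, 0.0
    return {
        "Energy": float(np.sum(xs ** 2)),
        "TotalEnergy": float(spacing * spacing * np.sum(xs ** 2)),
        "Entropy": float(-np.sum(p * np.log2(p + _EPS))),
        "Minimum": float(x.min()),
        "10Percentile": float(p10),
        "90Percentile": float(p90),
        "Maximum": float(x.max()),
        "Mean": float(mean),
        "Median": float(p50),
        "InterquartileRange": float(p75 - p25),
        "Range": float(x.max() - x.min()),
        "MeanAbsoluteDeviation": float(np.mean(np.abs(x - mean))),
        "RobustMeanAbsoluteDeviation": float(
            np.mean(np.abs(robust - robust.mean())) if robust.size else 0.0
        ),
        "RootMeanSquared": float(np.sqrt(np.mean(xs ** 2))),
        "Skewness": float(skew),
        "Kurtosis": float(kurt),
        "Variance": float(var),
        "Uniformity": float(np.sum(p ** 2)),
    }


# --------------------------------------------------------------------------
# GLCM
# --------------------------------------------------------------------------

_ANGLES_2D = ((0, 1), (1, 1), (1, 0), (1, -1))


def _glcm_matrices(gl: np.ndarray, mask: np.ndarray, ng: int,
                   distance: int) -> list[np.ndarray]:
    """Symmetric, normalised co-occurrence matrix per direction."""
    mats = []
    h, w = gl.shape
    for dr, dc in _ANGLES_2D:
        dr, dc = dr * distance, dc * distance
        P = np.zeros((ng, ng))
        r0a, r1a = max(0, -dr), min(h, h - dr)
        c0a, c1a = max(0, -dc), min(w, w - dc)
        src_m = mask[r0a:r1a, c0a:c1a]
        dst_m = mask[r0a + dr : r1a + dr, c0a + dc : c1a + dc]
        both = src_m & dst_m
        src = gl[r0a:r1a, c0a:c1a][both] - 1
        dst = gl[r0a + dr : r1a + dr, c0a + dc : c1a + dc][both] - 1
        np.add.at(P, (src, dst), 1.0)
        P = P + P.T  # symmetric
        if P.sum() > 0:
            P = P / P.sum()
        mats.append(P)
    return mats


def _glcm_features_single(P: np.ndarray) -> dict[str, float]:
    ng = P.shape[0]
    i = np.arange(1, ng + 1)
    ii, jj = np.meshgrid(i, i, indexing="ij")
    px = P.sum(axis=1)
    py = P.sum(axis=0)
    ux = float(np.sum(i * px))
    uy = float(np.sum(i * py))
    sx = float(np.sqrt(np.sum((i - ux) ** 2 * px)))
    sy = float(np.sqrt(np.sum((i - uy) ** 2 * py)))

    ks = np.arange(2, 2 * ng + 1)
    pxy_sum = np.zeros(ks.size)
    kd = np.arange(0, ng)
    pxy_diff = np.zeros(kd.size)
    np.add.at(pxy_sum, (ii + jj - 2).ravel(), P.ravel())
    np.add.at(pxy_diff, np.abs(ii - jj).ravel(), P.ravel())

    hx = -np.sum(px * np.log2(px + _EPS))
    hy = -np.sum(py * np.log2(py + _EPS))
    hxy = -np.sum(P * np.log2(P + _EPS))
    pxpy = np.outer(px, py)
    hxy1 = -np.sum(P * np.log2(pxpy + _EPS))
    hxy2 = -np.sum(pxpy * np.log2(pxpy + _EPS))

    imc1 = (hxy - hxy1) / max(hx, hy) if max(hx, hy) > 0 else 0.0
    imc2 = np.sqrt(max(0.0, 1.0 - np.exp(-2.0 * (hxy2 - hxy))))

    da = float(np.sum(kd * pxy_diff))

    # maximal correlation coefficient: sqrt of 2nd-largest eigenvalue of Q
    with np.errstate(divide="ignore", invalid="ignore"):
        denom = px[:, None] * py[None, :]
        Q = np.einsum("ik,jk->ij", P / np.where(px[:, None] > 0, px[:, None], 1.0),
                      P / np.where(py[:, None] > 0, py[:, None], 1.0))
    eig = np.sort(np.abs(np.linalg.eigvals(Q)))
    mcc = float(np.sqrt(eig[-2])) if eig.size > 1 else 1.0

    if sx > 0 and sy > 0:
        corr = (np.sum(ii * jj * P) - ux * uy) / (sx * sy)
    else:
        corr = 1.0

    off = ii != jj
    inv_var = float(np.sum(P[off] / (ii - jj)[off] ** 2)) if off.any() else 0.0

    return {
        "Autocorrelation": float(np.sum(P * ii * jj)),
        "JointAverage": ux,
        "ClusterProminence": float(np.sum(P * (ii + jj - ux - uy) ** 4)),
        "ClusterShade": float(np.sum(P * (ii + jj - ux - uy) ** 3)),
        "ClusterTendency": float(np.sum(P * (ii + jj - ux - uy) ** 2)),
        "Contrast": float(np.sum(P * (ii - jj) ** 2)),
        "Correlation": float(corr),
        "DifferenceAverage": da,
        "DifferenceEntropy": float(-np.sum(pxy_diff * np.log2(pxy_diff + _EPS))),
        "DifferenceVariance": float(np.sum((kd - da) ** 2 * pxy_diff)),
        "JointEnergy": float(np.sum(P ** 2)),
        "JointEntropy": float(hxy),
        "Imc1": float(imc1),
        "Imc2": float(imc2),
        "Idm": float(np.sum(P / (1.0 + (ii - jj) ** 2))),
        "Idmn": float(np.sum(P / (1.0 + (ii - jj) ** 2 / ng ** 2))),
        "Id": float(np.sum(P / (1.0 + np.abs(ii - jj)))),
        "Idn": float(np.sum(P / (1.0 + np.abs(ii - jj) / ng))),
        "InverseVariance": inv_var,
        "MaximumProbability": float(P.max()),
        "MCC": mcc,
        "SumAverage": float(np.sum(ks * pxy_sum)),
        "SumEntropy": float(-np.sum(pxy_sum * np.log2(pxy_sum + _EPS))),
        "SumSquares": float(np.sum(P * (ii - ux) ** 2)),
    }


def _glcm_features(gl, mask, ng, distance) -> dict[str, float]:
    per_angle = [_glcm_features_single(P)
                 for P in _glcm_matrices(gl, mask, ng, distance)]
    return {k: float(np.mean([f[k] for f in per_angle])) for k in per_angle[0]}


# --------------------------------------------------------------------------
# GLRLM
# --------------------------------------------------------------------------

def _lines(gl_masked: np.ndarray, direction: tuple[int, int]):
    """Scan lines of the grid along a direction; 0 marks out-of-mask."""
    h, w = gl_masked.shape
    dr, dc = direction
    if (dr, dc) == (0, 1):
        yield from gl_masked
    elif (dr, dc) == (1, 0):
        yield from gl_masked.T
    else:
        flipped = gl_masked[:, ::-1] if dc == -1 else gl_masked
        for k in range(-(h - 1), w):
            yield np.diagonal(flipped, offset=k)


def _glrlm_single(gl_masked: np.ndarray, ng: int,
                  direction: tuple[int, int]) -> np.ndarray:
    h, w = gl_masked.shape
    max_run = max(h, w)
    P = np.zeros((ng, max_run))
    for line in _lines(gl_masked, direction):
        if line.size == 0:
            continue
        run_val = 0
        run_len = 0
        for v in line:
            if v == run_val:
                run_len += 1
            else:
                if run_val > 0:
                    P[run_val - 1, run_len - 1] += 1
                run_val, run_len = int(v), 1
        if run_val > 0:
            P[run_val - 1, run_len - 1] += 1
    return P


def _run_type_features(P: np.ndarray, n_pixels: int, prefix: str) -> dict[str, float]:
    """Shared feature formulas for run-length (j = run length) and size-zone
    (j = zone size) matrices."""
    ng, nr_max = P.shape
    i = np.arange(1, ng + 1)
    j = np.arange(1, nr_max + 1)
    ii, jj = np.meshgrid(i, j, indexing="ij")
    nr = P.sum()
    if nr == 0:
        nr = 1.0
    p = P / nr                 # joint probabilities
    pg = P.sum(axis=1) / nr    # marginal over gray level
    pr = P.sum(axis=0) / nr    # marginal over run length / zone size
    mu_i = np.sum(p * ii)
    mu_j = np.sum(p * jj)
    long_name, short_name, length_word = {
        "Run": ("LongRun", "ShortRun", "RunLength"),
        "Area": ("LargeArea", "SmallArea", "SizeZone"),
    }[prefix]
    run_word = "Run" if prefix == "Run" else "Zone"
    feats = {
        f"{short_name}Emphasis": np.sum(pr / j ** 2),
        f"{long_name}Emphasis": np.sum(pr * j ** 2),
        "GrayLevelNonUniformity": np.sum((pg * nr) ** 2) / nr,
        "GrayLevelNonUniformityNormalized": np.sum(pg ** 2),
        f"{length_word}NonUniformity": np.sum((pr * nr) ** 2) / nr,
        f"{length_word}NonUniformityNormalized": np.sum(pr ** 2),
        f"{run_word}Percentage": nr / n_pixels,
        "GrayLevelVariance": np.sum(p * (ii - mu_i) ** 2),
        f"{run_word}Variance": np.sum(p * (jj - mu_j) ** 2),
        f"{run_word}Entropy": -np.sum(p * np.log2(p + _EPS)),
        f"LowGrayLevel{run_word}Emphasis": np.sum(pg / i ** 2),
        f"HighGrayLevel{run_word}Emphasis": np.sum(pg * i ** 2),
        f"{short_name}LowGrayLevelEmphasis": np.sum(p / (ii ** 2 * jj ** 2)),
        f"{short_name}HighGrayLevelEmphasis": np.sum(p * ii ** 2 / jj ** 2),
        f"{long_name}LowGrayLevelEmphasis": np.sum(p * jj ** 2 / ii ** 2),
        f"{long_name}HighGrayLevelEmphasis": np.sum(p * ii ** 2 * jj ** 2),
    }
    return {k: float(v) for k, v in feats.items()}


def _glrlm_features(gl, mask, ng, n_pixels) -> dict[str, float]:
    gl_masked = np.where(mask, gl, 0)
    per_dir = []
    for direction in _ANGLES_2D:
        P = _glrlm_single(gl_masked, ng, direction)
        per_dir.append(_run_type_features(P, n_pixels, "Run"))
    return {k: float(np.mean([f[k] for f in per_dir])) for k in per_dir[0]}


# --------------------------------------------------------------------------
# GLSZM
# --------------------------------------------------------------------------

def _glszm_features(gl, mask, ng, n_pixels) -> dict[str, float]:
    structure = np.ones((3, 3))  # zones are 8-connected
    max_size = int(mask.sum())
    P = np.zeros((ng, max_size))
    for level in range(1, ng + 1):
        level_mask = (gl == level) & mask
        if not level_mask.any():
            continue
        labels, n_zones = ndimage.label(level_mask, structure=structure)
        sizes = np.bincount(labels.ravel())[1:]
        for s in sizes:
            P[level - 1, s - 1] += 1
    return _run_type_features(P, n_pixels, "Area")


# --------------------------------------------------------------------------
# GLDM
# --------------------------------------------------------------------------

def _gldm_features(gl, mask, ng, n_pixels, alpha: float = 0.0) -> dict[str, float]:
    h, w = gl.shape
    offsets = [(-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1)]
    dep = np.zeros((h, w), dtype=np.int64)
    for dr, dc in offsets:
        r0a, r1a = max(0, -dr), min(h, h - dr)
        c0a, c1a = max(0, -dc), min(w, w - dc)
        nb_mask = np.zeros((h, w), dtype=bool)
        src = gl[r0a:r1a, c0a:c1a]
        nb = gl[r0a + dr : r1a + dr, c0a + dc : c1a + dc]
        ok = (mask[r0a:r1a, c0a:c1a]
              & mask[r0a + dr : r1a + dr, c0a + dc : c1a + dc]
              & (np.abs(src - nb) <= alpha))
        nb_mask[r0a:r1a, c0a:c1a] = ok
        dep += nb_mask
    nd_max = 9
    P = np.zeros((ng, nd_max))
    glm = gl[mask] - 1
    depm = dep[mask]  # dependence count j-1 in 0..8
    np.add.at(P, (glm, depm), 1.0)

    i = np.arange(1, ng + 1)
    j = np.arange(1, nd_max + 1)
    ii, jj = np.meshgrid(i, j, indexing="ij")
    nz = P.sum()
    p = P / nz
    pg = P.sum(axis=1) / nz
    pd = P.sum(axis=0) / nz
    mu_i = np.sum(p * ii)
    mu_j = np.sum(p * jj)
    return {
        "SmallDependenceEmphasis": float(np.sum(pd / j ** 2)),
        "LargeDependenceEmphasis": float(np.sum(pd * j ** 2)),
        "GrayLevelNonUniformity": float(np.sum(P.sum(axis=1) ** 2) / nz),
        "DependenceNonUniformity": float(np.sum(P.sum(axis=0) ** 2) / nz),
        "DependenceNonUniformityNormalized": float(np.sum(pd ** 2)),
        "GrayLevelVariance": float(np.sum(p * (ii - mu_i) ** 2)),
        "DependenceVariance": float(np.sum(p * (jj - mu_j) ** 2)),
        "DependenceEntropy": float(-np.sum(p * np.log2(p + _EPS))),
        "LowGrayLevelEmphasis": float(np.sum(pg / i ** 2)),
        "HighGrayLevelEmphasis": float(np.sum(pg * i ** 2)),
        "SmallDependenceLowGrayLevelEmphasis": float(np.sum(p / (ii ** 2 * jj ** 2))),
        "SmallDependenceHighGrayLevelEmphasis": float(np.sum(p * ii ** 2 / jj ** 2)),
        "LargeDependenceLowGrayLevelEmphasis": float(np.sum(p * jj ** 2 / ii ** 2)),
        "LargeDependenceHighGrayLevelEmphasis": float(np.sum(p * ii ** 2 * jj ** 2)),
    }


# --------------------------------------------------------------------------
# NGTDM
# --------------------------------------------------------------------------

def _ngtdm_features(gl, mask, ng, n_pixels) -> dict[str, float]:
    h, w = gl.shape
    offsets = [(-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1)]
    nb_sum = np.zeros((h, w))
    nb_cnt = np.zeros((h, w))
    glf = gl.astype(np.float64)
    for dr, dc in offsets:
        r0a, r1a = max(0, -dr), min(h, h - dr)
        c0a, c1a = max(0, -dc), min(w, w - dc)
        valid = mask[r0a + dr : r1a + dr, c0a + dc : c1a + dc]
        nb_sum[r0a:r1a, c0a:c1a] += np.where(
            valid, glf[r0a + dr : r1a + dr, c0a + dc : c1a + dc], 0.0
        )
        nb_cnt[r0a:r1a, c0a:c1a] += valid
    s = np.zeros(ng)
    n_i = np.zeros(ng)
    has_nb = mask & (nb_cnt > 0)
    avg = np.zeros((h, w))
    avg[has_nb] = nb_sum[has_nb] / nb_cnt[has_nb]
    for level in range(1, ng + 1):
        sel = (gl == level) & has_nb
        n_i[level - 1] = sel.sum()
        s[level - 1] = np.abs(level - avg[sel]).sum()
    n_tot = n_i.sum()
    p_i = n_i / n_tot if n_tot > 0 else n_i
    present = p_i > 0
    i = np.arange(1, ng + 1)
    ngp = int(present.sum())

    sum_ps = float(np.sum(p_i * s))
    coarseness = 1.0 / sum_ps if sum_ps > 0 else 1e6

    if ngp > 1:
        ip, pp, sp = i[present], p_i[present], s[present]
        di = ip[:, None] - ip[None, :]
        contrast = (np.sum(pp[:, None] * pp[None, :] * di ** 2)
                    / (ngp * (ngp - 1))) * (s.sum() / n_tot)
        busy_den = float(np.sum(np.abs((ip * pp)[:, None] - (ip * pp)[None, :])))
        busyness = sum_ps / busy_den if busy_den > 0 else 0.0
        complexity = float(np.sum(np.abs(di)
                                  * (pp[:, None] * sp[:, None] + pp[None, :] * sp[None, :])
                                  / (pp[:, None] + pp[None, :]))) / n_tot
        strength_num = float(np.sum((pp[:, None] + pp[None, :]) * di ** 2))
        strength = strength_num / s.sum() if s.sum() > 0 else 0.0
    else:
        contrast = busyness = complexity = strength = 0.0

    return {
        "Coarseness": float(coarseness),
        "Contrast": float(contrast),
        "Busyness": float(busyness),
        "Complexity": float(complexity),
        "Strength": float(strength),
    }


# --------------------------------------------------------------------------
# Public entry point
# --------------------------------------------------------------------------

def extract_features(
    image: CTSlice | np.ndarray,
    mask: np.ndarray,
    config: RadiomicsConfig | None = None,
) -> FeatureVector:
    """Extract the full 93-feature vector over the masked region."""
    if config is None:
        config = RadiomicsConfig()
    if isinstance(image, CTSlice):
        pixels = image.pixels
        spacing = image.spacing
    else:
        pixels = np.asarray(image, dtype=np.float64)
        spacing = 1.0
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != pixels.shape:
        raise ValueError("mask shape must match the image")
    if not mask.any():
        raise ValueError("empty mask")

    values = pixels[mask]
    disc_values = _discretise(values, config.bin_width)
    gl = np.zeros(pixels.shape, dtype=np.int64)
    gl[mask] = disc_values
    ng = int(disc_values.max())
    n_pixels = int(mask.sum())

    fv = FeatureVector()
    for name, val in _first_order(values, disc_values, spacing,
                                  config.voxel_shift).items():
        fv[("firstorder", name)] = val
    for name, val in _glcm_features(gl, mask, ng, config.distance).items():
        fv[("GLCM", name)] = val
    for name, val in _gldm_features(gl, mask, ng, n_pixels).items():
        fv[("GLDM", name)] = val
    for name, val in _glrlm_features(gl, mask, ng, n_pixels).items():
        fv[("GLRLM", name)] = val
    for name, val in _glszm_features(gl, mask, ng, n_pixels).items():
        fv[("GLSZM", name)] = val
    for name, val in _ngtdm_features(gl, mask, ng, n_pixels).items():
        fv[("NGTDM", name)] = val
    return fv.validate()
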