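"""Radiomic feature extraction over the bladder-wall ROI.

Four feature families are computed:

* morphological — wall volume, outer surface area, sphericity, local wall
  thickness statistics (double Euclidean distance transform sampled on the
  medial surface), equivalent-sphere diameters, bounding-box extents;
* intensity — first-order statistics of the in-mask intensity histogram;
* texture — Haralick statistics of gray-level co-occurrence matrices
  (GLCM) computed in sliding in-plane windows and averaged over the wall,
  swept over angles ``a``, distances ``d``, quantization bins ``b`` and
  window sizes ``w``;
* clinical — age, prostate size and BMI passed through from the record.

Texture is computed per-slice in 2D windows by default: the source images
are thick-slice sagittal acquisitions whose through-plane resolution is an
order of magnitude coarser than in-plane, so 3D offsets would mix
physically incommensurate scales.  A whole-ROI 3D co-occurrence mode is
available behind ``TextureConfig.mode``.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from functools import lru_cache
from typing import Iterable, Optional, Sequence

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from scipy import ndimage, stats
from skimage import measure

from .core import (
    CaseRecord,
    FeatureDescriptor,
    FeatureTable,
    HARALICK_FEATURES,
    VolumeImage,
    WallMask,
    WallRadError,
    is_hollow_shell,
)

logger = logging.getLogger(__name__)

#: in-plane co-occurrence offsets (row, col) per angle in degrees,
#: counterclockwise, matching the usual GLCM convention
ANGLE_OFFSETS_2D = {
    0.0: (0, 1),
    45.0: (-1, 1),
    90.0: (-1, 0),
    135.0: (-1, -1),
}

#: the 13 unique 3D lattice directions (one per +/- pair)
DIRECTIONS_3D = (
    (1, 0, 0), (0, 1, 0), (0, 0, 1),
    (1, 1, 0), (1, -1, 0), (1, 0, 1), (1, 0, -1), (0, 1, 1), (0, 1, -1),
    (1, 1, 1), (1, 1, -1), (1, -1, 1), (1, -1, -1),
)

STANDARD_RANGE = (0.0, 4095.0)


@dataclass(frozen=True)
class TextureConfig:
    """Sweep grids and policies for windowed GLCM texture extraction."""

    angles_deg: tuple[float, ...] = (0.0, 45.0, 90.0, 135.0)
    distances: tuple[int, ...] = (1, 2, 4)
    bins: tuple[int, ...] = (8, 16, 32)
    windows: tuple[int, ...] = (5, 9, 15)
    features: tuple[str, ...] = HARALICK_FEATURES
    #: 'robust' quantizes over the in-mask [p1, p99] range (clipped);
    #: 'minmax' uses the full in-mask range
    range_policy: str = "robust"
    min_in_mask_fraction: float = 0.5
    aggregate: str = "mean"
    mode: str = "2d"
    symmetric: bool = True

    def __post_init__(self) -> None:
        if not (self.angles_deg and self.distances and self.bins and self.windows and self.features):
            raise WallRadError("all texture sweep grids must be non-empty")
        if any(w < 3 or w % 2 == 0 for w in self.windows):
            raise WallRadError("window sizes must be odd and >= 3")
        if any(b < 2 for b in self.bins):
            raise WallRadError("bins must be >= 2")
        if any(d < 1 for d in self.distances):
            raise WallRadError("distances must be >= 1")
        unknown = set(self.features) - set(HARALICK_FEATURES)
        if unknown:
            raise WallRadError(f"unknown Haralick features: {sorted(unknown)}")
        if self.range_policy not in ("robust", "minmax"):
            raise WallRadError(f"unknown range policy {self.range_policy!r}")
        if self.aggregate not in ("mean", "median"):
            raise WallRadError(f"unknown aggregation {self.aggregate!r}")
        if self.mode not in ("2d", "3d"):
            raise WallRadError(f"unknown texture mode {self.mode!r}")

    def n_columns(self) -> int:
        return (
            len(self.angles_deg) * len(self.distances) * len(self.bins)
            * len(self.windows) * len(self.features)
        )


# ---------------------------------------------------------------------------
# quantization and GLCM


def quantize(
    intensities: np.ndarray,
    bins: int,
    value_range: Optional[tuple[float, float]] = None,
) -> np.ndarray:
    """Equal-width quantization to integer levels in [0, bins-1].

    Values are clipped to ``value_range`` (default: the data range).  A
    zero-width range maps everything to level 0.
    """
    if bins < 2:
        raise WallRadError("bins must be >= 2")
    x = np.asarray(intensities, dtype=np.float64)
    if value_range is None:
        lo, hi = (float(x.min()), float(x.max())) if x.size else (0.0, 0.0)
    else:
        lo, hi = float(value_range[0]), float(value_range[1])
    if hi - lo <= 0:
        logger.debug("zero-width quantization range; all voxels map to level 0")
        return np.zeros(x.shape, dtype=np.int64)
    levels = np.floor((np.clip(x, lo, hi) - lo) / (hi - lo) * bins).astype(np.int64)
    return np.clip(levels, 0, bins - 1)


def robust_range(values: np.ndarray, policy: str = "robust") -> tuple[float, float]:
    values = np.asarray(values, dtype=np.float64)
    if policy == "robust":
        lo, hi = np.percentile(values, [1.0, 99.0])
    else:
        lo, hi = values.min(), values.max()
    return float(lo), float(hi)


def _offset_from_angle(angle, distance: int, ndim: int) -> tuple[int, ...]:
    if isinstance(angle, (tuple, list, np.ndarray)):
        direction = tuple(int(a) for a in angle)
    else:
        try:
            direction = ANGLE_OFFSETS_2D[float(angle)]
        except KeyError:
            raise WallRadError(f"unsupported in-plane angle {angle!r}") from None
    if len(direction) != ndim:
        raise WallRadError(f"offset {direction} does not match array dimensionality {ndim}")
    return tuple(int(distance) * c for c in direction)


def glcm(
    levels: np.ndarray,
    mask: Optional[np.ndarray],
    angle,
    distance: int = 1,
    *,
    n_levels: Optional[int] = None,
    symmetric: bool = True,
    normalize: bool = True,
) -> np.ndarray:
    """Gray-level co-occurrence matrix of a quantized array.

    ``angle`` is either an in-plane angle in degrees (2D arrays) or an
    integer direction vector matching the array dimensionality.  A pair
    counts only when both voxels lie in the mask.  With ``symmetric`` both
    orderings count; with ``normalize`` entries sum to one.  If no valid
    pair exists the zero matrix is returned (callers treat a zero-sum
    matrix as "empty").
    """
    levels = np.asarray(levels)
    if not np.issubdtype(levels.dtype, np.integer):
        raise WallRadError("glcm expects integer level arrays; quantize first")
    if mask is None:
        mask = np.ones(levels.shape, dtype=bool)
    mask = np.asarray(mask).astype(bool)
    if mask.shape != levels.shape:
        raise WallRadError("mask shape must match levels shape")
    b = int(n_levels) if n_levels is not None else int(levels.max()) + 1
    if levels.min() < 0 or levels.max() >= b:
        raise WallRadError(f"levels outside [0, {b})")
    offset = _offset_from_angle(angle, distance, levels.ndim)

    src_sl, dst_sl = [], []
    for o, n in zip(offset, levels.shape):
        if abs(o) >= n:
            return np.zeros((b, b), dtype=np.float64)
        if o >= 0:
            src_sl.append(slice(0, n - o))
            dst_sl.append(slice(o, n))
        else:
            src_sl.append(slice(-o, n))
            dst_sl.append(slice(0, n + o))
    src_sl, dst_sl = tuple(src_sl), tuple(dst_sl)
    valid = mask[src_sl] & mask[dst_sl]
    i = levels[src_sl][valid]
    j = levels[dst_sl][valid]
    counts = np.bincount(i * b + j, minlength=b * b).reshape(b, b).astype(np.float64)
    if symmetric:
        counts = counts + counts.T
    if normalize:
        total = counts.sum()
        if total > 0:
            counts = counts / total
    return counts


# ---------------------------------------------------------------------------
# Haralick statistics


@lru_cache(maxsize=16)
def _haralick_weights(b: int) -> np.ndarray:
    """(b*b, 11) stack of flattened weight matrices for the linear moments."""
    idx = np.arange(b, dtype=np.float64)
    i = np.repeat(idx, b)
    j = np.tile(idx, b)
    d = i - j
    s = i + j
    return np.column_stack(
        [d**2, np.abs(d), 1.0 / (1.0 + d**2), i, j, i**2, j**2, i * j, s**2, s**3, s**4]
    )


def _haralick_stack(p: np.ndarray) -> dict[str, np.ndarray]:
    """All supported Haralick statistics for a stack of normalized GLCMs.

    ``p`` has shape (n, b, b) with each slice summing to 1.  Returns one
    length-n vector per feature.  Conventions: 0*log2(0) := 0 and
    correlation := 0 when either marginal SD vanishes.

    Every statistic that is linear in p is a single matrix product with
    precomputed weight vectors; cluster shade and prominence come from
    the raw moments of i+j (central-moment expansion around S1 = E[i+j]).
    """
    n, b, _ = p.shape
    pf = p.reshape(n, b * b)
    M = pf @ _haralick_weights(b)
    contrast, dissim, homog = M[:, 0], M[:, 1], M[:, 2]
    mu_x, mu_y = M[:, 3], M[:, 4]
    var_x = M[:, 5] - mu_x**2
    var_y = M[:, 6] - mu_y**2
    cov = M[:, 7] - mu_x * mu_y
    s1 = mu_x + mu_y
    s2, s3, s4 = M[:, 8], M[:, 9], M[:, 10]

    out: dict[str, np.ndarray] = {}
    out["contrast"] = contrast
    out["dissimilarity"] = dissim
    out["homogeneity"] = homog
    out["energy"] = np.einsum("nk,nk->n", pf, pf)
    # adding a denormal offset keeps 0 * log2(.) == 0 without branching
    out["entropy"] = -np.einsum("nk,nk->n", pf, np.log2(pf + 1e-300))
    denom = np.sqrt(np.maximum(var_x, 0.0) * np.maximum(var_y, 0.0))
    out["correlation"] = np.where(denom > 1e-12, cov / np.where(denom > 0, denom, 1.0), 0.0)
    out["variance"] = var_x
    out["sum-average"] = s1
    out["cluster-shade"] = s3 - 3.0 * s1 * s2 + 2.0 * s1**3
    out["cluster-prominence"] = s4 - 4.0 * s1 * s3 + 6.0 * s1**2 * s2 - 3.0 * s1**4
    return out


def haralick(glcm_matrix: np.ndarray, feature: str) -> float:
    """One Haralick statistic of one normalized GLCM.

    An all-zero ("empty") matrix yields NaN, resolved later at table
    assembly.
    """
    if feature not in HARALICK_FEATURES:
        raise WallRadError(f"unknown Haralick feature {feature!r}")
    p = np.asarray(glcm_matrix, dtype=np.float64)
    if p.ndim != 2 or p.shape[0] != p.shape[1]:
        raise WallRadError("GLCM must be square")
    total = p.sum()
    if total == 0:
        return float("nan")
    if abs(total - 1.0) > 1e-6:
        raise WallRadError("haralick expects a normalized GLCM")
    return float(_haralick_stack(p[None])[feature][0])


# ---------------------------------------------------------------------------
# windowed texture


def _windowed_features_volume(
    code_maps: tuple[np.ndarray, ...],
    center_ok: np.ndarray,
    w: int,
    b: int,
    symmetric: bool,
) -> Optional[np.ndarray]:
    """Per-window Haralick features over all slices for one (angle, d, b, w).

    Each map in ``code_maps`` holds pair codes i*b+j anchored at one pair
    endpoint (-1 where invalid); windows are in-plane ``w x w`` boxes
    around every qualifying center.  In symmetric mode two maps are given
    (one per endpoint), so a pair contributes once per endpoint inside the
    window — this makes reversing the offset a no-op and window counts
    exactly consistent under 90-degree in-plane rotations.  Returns
    (n_windows, n_features) or None when no window has a valid pair.
    """
    if not center_ok.any():
        return None
    half = w // 2
    chunks = []
    for code_vol in code_maps:
        padded = np.pad(
            code_vol, ((half, half), (half, half), (0, 0)), constant_values=-1
        )
        win = sliding_window_view(padded, (w, w), axis=(0, 1))  # (X, Y, Z, w, w)
        chunks.append(win[center_ok].reshape(-1, w * w))
    codes = np.concatenate(chunks, axis=1)
    ncent = codes.shape[0]
    flat = codes.ravel()
    ok = flat >= 0
    rows = np.repeat(np.arange(ncent), codes.shape[1])[ok]
    counts = np.bincount(rows * (b * b) + flat[ok], minlength=ncent * b * b)
    counts = counts.reshape(ncent, b, b).astype(np.float64)
    if symmetric:
        counts = counts + counts.transpose(0, 2, 1)
    totals = counts.sum(axis=(1, 2))
    keep = totals > 0
    if not keep.any():
        return None
    p = counts[keep] / totals[keep][:, None, None]
    feats = _haralick_stack(p)
    return np.column_stack([feats[f] for f in HARALICK_FEATURES])


def windowed_texture(
    image: VolumeImage,
    mask: WallMask,
    cfg: TextureConfig,
    value_range: Optional[tuple[float, float]] = None,
) -> tuple[list[FeatureDescriptor], np.ndarray]:
    """Windowed GLCM texture columns for one case.

    For every (angle, distance, bins, window, feature) combination a
    window of ``w x w`` in-plane voxels slides over every wall voxel whose
    window contains at least ``min_in_mask_fraction`` wall voxels; the
    per-window Haralick values are aggregated over all qualifying windows
    of the volume.  A combination with no qualifying window yields NaN
    (imputed at table assembly).
    """
    if mask.shape != image.shape:
        raise WallRadError("mask grid does not match image grid")
    in_mask = image.data[mask.data.astype(bool)]
    if value_range is None:
        value_range = robust_range(in_mask, cfg.range_policy)

    if cfg.mode == "3d":
        return _texture_3d(image, mask, cfg, value_range)

    agg = np.nanmean if cfg.aggregate == "mean" else np.nanmedian
    mask3 = mask.data.astype(bool)
    # crop to the mask bounding box: windows beyond it never qualify at
    # fraction >= 0.5, and padding restores boundary behaviour
    fg = np.argwhere(mask3)
    pad = max(cfg.windows) // 2
    lo = np.maximum(fg.min(axis=0) - pad, 0)
    hi = np.minimum(fg.max(axis=0) + pad + 1, mask3.shape)
    box = tuple(slice(int(a), int(c)) for a, c in zip(lo, hi))
    mask3 = mask3[box]

    quantized = {b: quantize(image.data[box], b, value_range) for b in cfg.bins}
    center_by_w = {
        w: mask3
        & (
            ndimage.uniform_filter(mask3.astype(np.float64), size=(w, w, 1), mode="constant")
            >= cfg.min_in_mask_fraction - 1e-12
        )
        for w in cfg.windows
    }

    descriptors: list[FeatureDescriptor] = []
    values: list[float] = []
    for a in cfg.angles_deg:
        for d in cfg.distances:
            dr, dc = _offset_from_angle(a, d, 2)
            for b in cfg.bins:
                fwd = _pair_codes_volume(quantized[b], mask3, (dr, dc), b)
                if cfg.symmetric:
                    rev = _pair_codes_volume(quantized[b], mask3, (-dr, -dc), b)
                    code_maps = tuple(m for m in (fwd, rev) if m is not None)
                else:
                    code_maps = (fwd,) if fwd is not None else ()
                for w in cfg.windows:
                    rows = (
                        _windowed_features_volume(
                            code_maps, center_by_w[w], w, b, cfg.symmetric
                        )
                        if code_maps
                        else None
                    )
                    for fi, f in enumerate(HARALICK_FEATURES):
                        if f not in cfg.features:
                            continue
                        name = f"{f}_a{a:g}_d{d}_b{b}_w{w}"
                        descriptors.append(
                            FeatureDescriptor(
                                name=name, category="texture",
                                angle=float(a), distance=int(d), bins=int(b),
                                window=int(w), haralick=f,
                            )
                        )
                        if rows is None:
                            values.append(float("nan"))
                            logger.info("no qualifying window for texture column %s", name)
                        else:
                            values.append(float(agg(rows[:, fi])))
    return descriptors, np.asarray(values, dtype=np.float64)


def _pair_codes_volume(L3: np.ndarray, m3: np.ndarray, offset, b: int) -> Optional[np.ndarray]:
    """In-plane pair code map for a whole volume.

    Code ``i*b + j`` is stored at the pair's first voxel for every
    in-plane pair at the given (row, col) offset whose endpoints both lie
    in the mask; -1 elsewhere.
    """
    dr, dc = offset
    H, W, _ = L3.shape
    if abs(dr) >= H or abs(dc) >= W:
        return None
    code = np.full(L3.shape, -1, dtype=np.int64)
    rs = slice(max(0, -dr), min(H, H - dr))
    cs = slice(max(0, -dc), min(W, W - dc))
    rd = slice(max(0, dr), min(H, H + dr))
    cd = slice(max(0, dc), min(W, W + dc))
    valid = m3[rs, cs, :] & m3[rd, cd, :]
    codes = L3[rs, cs, :] * b + L3[rd, cd, :]
    block = np.full(codes.shape, -1, dtype=np.int64)
    block[valid] = codes[valid]
    code[rs, cs, :] = block
    return code if (code >= 0).any() else None


def _texture_3d(image, mask, cfg, value_range):
    """Whole-ROI 3D co-occurrence (no windows): one GLCM per (direction, d, b)."""
    descriptors, values = [], []
    mask3 = mask.data.astype(bool)
    for ai, direction in enumerate(DIRECTIONS_3D):
        for d in cfg.distances:
            for b in cfg.bins:
                L = quantize(image.data, b, value_range)
                P = glcm(L, mask3, direction, d, n_levels=b, symmetric=cfg.symmetric)
                stats_all = (
                    _haralick_stack(P[None]) if P.sum() > 0 else None
                )
                for f in cfg.features:
                    name = f"{f}_dir{ai}_d{d}_b{b}_w0"
                    descriptors.append(
                        FeatureDescriptor(
                            name=name, category="texture",
                            angle=float(ai), distance=int(d), bins=int(b),
                            window=3, haralick=f,
                        )
                    )
                    values.append(
                        float(stats_all[f][0]) if stats_all is not None else float("nan")
                    )
    return descriptors, np.asarray(values, dtype=np.float64)


# ---------------------------------------------------------------------------
# morphology, intensity, clinical


def morphological_features(mask: WallMask, spacing: Optional[Sequence[float]] = None) -> dict[str, float]:
    """Shell morphometry of the wall mask (units: mm, mm², mm³).

    Local thickness is twice the Euclidean distance transform sampled on
    the medial surface (ridge of the distance map).  The outer surface is
    the hole-filled mask; its area comes from a marching-cubes mesh.
    """
    if spacing is None:
        spacing = mask.spacing
    spacing = tuple(float(s) for s in spacing)
    if not is_hollow_shell(WallMask(data=mask.data, spacing=spacing)):
        raise WallRadError("morphometry requires a hollow shell mask")
    m = mask.data.astype(bool)
    voxvol = float(np.prod(spacing))
    wall_volume = m.sum() * voxvol

    filled = ndimage.binary_fill_holes(m)
    cavity = filled & ~m
    outer_volume = filled.sum() * voxvol
    cavity_volume = cavity.sum() * voxvol

    padded = np.pad(filled, 1).astype(np.float64)
    verts, faces, _, _ = measure.marching_cubes(padded, level=0.5, spacing=spacing)
    outer_area = float(measure.mesh_surface_area(verts, faces))
    sphericity = (math.pi ** (1 / 3)) * (6.0 * outer_volume) ** (2 / 3) / outer_area

    edt = ndimage.distance_transform_edt(m, sampling=spacing)
    ridge = m & (edt >= ndimage.maximum_filter(edt, size=3) - 1e-9)
    thick = 2.0 * edt[ridge]
    if thick.size == 0:  # cannot happen for a non-empty mask; belt and braces
        thick = 2.0 * edt[m]

    fg = np.argwhere(m)
    extents = (fg.max(axis=0) - fg.min(axis=0) + 1) * np.asarray(spacing)

    def eq_diam(v: float) -> float:
        return (6.0 * v / math.pi) ** (1 / 3)

    return {
        "morph_wall_volume_mm3": wall_volume,
        "morph_outer_volume_mm3": outer_volume,
        "morph_cavity_volume_mm3": cavity_volume,
        "morph_outer_surface_area_mm2": outer_area,
        "morph_sphericity": float(sphericity),
        "morph_thickness_mean_mm": float(thick.mean()),
        "morph_thickness_median_mm": float(np.median(thick)),
        "morph_thickness_max_mm": float(thick.max()),
        "morph_thickness_sd_mm": float(thick.std()),
        "morph_outer_eq_diam_mm": eq_diam(outer_volume),
        "morph_cavity_eq_diam_mm": eq_diam(cavity_volume) if cavity_volume > 0 else 0.0,
        "morph_bbox_extent_x_mm": float(extents[0]),
        "morph_bbox_extent_y_mm": float(extents[1]),
        "morph_bbox_extent_z_mm": float(extents[2]),
    }


def intensity_features(
    image: VolumeImage,
    mask: WallMask,
    standard_range: tuple[float, float] = STANDARD_RANGE,
) -> dict[str, float]:
    """First-order in-mask intensity statistics.

    Histogram entropy uses 64 fixed-width bins over the standardized
    intensity range, so it is comparable across cases.  Skewness and
    kurtosis (Fisher) of a zero-variance wall are defined as 0.
    """
    vals = image.data[mask.data.astype(bool)]
    sd = float(vals.std())
    p5, p25, p50, p75, p95 = np.percentile(vals, [5, 25, 50, 75, 95])
    if sd > 1e-12:
        skew = float(stats.skew(vals))
        kurt = float(stats.kurtosis(vals))
    else:
        skew = kurt = 0.0
    hist, _ = np.histogram(vals, bins=64, range=standard_range)
    p = hist[hist > 0] / hist.sum()
    entropy = float(-(p * np.log2(p)).sum()) if hist.sum() else 0.0
    return {
        "int_mean": float(vals.mean()),
        "int_median": float(p50),
        "int_sd": sd,
        "int_min": float(vals.min()),
        "int_max": float(vals.max()),
        "int_p5": float(p5),
        "int_p25": float(p25),
        "int_p75": float(p75),
        "int_p95": float(p95),
        "int_skewness": skew,
        "int_kurtosis": kurt,
        "int_hist_entropy": entropy,
    }


def clinical_features(case: CaseRecord) -> dict[str, float]:
    """Clinical covariates, passed through in stable order."""
    return {
        "clin_age": float(case.age),
        "clin_prostate_size": float(case.prostate_size),
        "clin_bmi": float(case.bmi),
    }


# ---------------------------------------------------------------------------
# per-case extraction and table assembly


def extract_case_features(
    image: VolumeImage,
    mask: WallMask,
    case: CaseRecord,
    texture_cfg: Optional[TextureConfig] = None,
    standard_range: tuple[float, float] = STANDARD_RANGE,
) -> tuple[list[FeatureDescriptor], np.ndarray]:
    """All four feature families for one case, in category order
    morphological, intensity, texture, clinical."""
    cfg = texture_cfg or TextureConfig()
    descriptors: list[FeatureDescriptor] = []
    values: list[float] = []
    for name, v in morphological_features(mask).items():
        descriptors.append(FeatureDescriptor(name=name, category="morphological"))
        values.append(v)
    for name, v in intensity_features(image, mask, standard_range).items():
        descriptors.append(FeatureDescriptor(name=name, category="intensity"))
        values.append(v)
    tex_desc, tex_vals = windowed_texture(image, mask, cfg)
    descriptors.extend(tex_desc)
    values.extend(tex_vals.tolist())
    for name, v in clinical_features(case).items():
        descriptors.append(FeatureDescriptor(name=name, category="clinical"))
        values.append(v)
    return descriptors, np.asarray(values, dtype=np.float64)


def assemble_feature_table(
    case_ids: Sequence[str],
    descriptors: Sequence[FeatureDescriptor],
    rows: np.ndarray,
    max_sentinel_fraction: float = 0.5,
) -> FeatureTable:
    """Assemble per-case rows into a finite FeatureTable.

    NaN sentinels (degenerate windows, empty GLCMs) are imputed with the
    column median over cases and logged; a column with more than
    ``max_sentinel_fraction`` sentinels is dropped with a warning.
    """
    rows = np.asarray(rows, dtype=np.float64)
    if rows.ndim != 2 or rows.shape[1] != len(descriptors):
        raise WallRadError("rows must be a cases x descriptors matrix")
    keep: list[int] = []
    for j in range(rows.shape[1]):
        col = rows[:, j]
        n_nan = int(np.isnan(col).sum())
        if n_nan > max_sentinel_fraction * rows.shape[0]:
            logger.warning(
                "dropping column %s: %d/%d sentinel values",
                descriptors[j].name, n_nan, rows.shape[0],
            )
            continue
        if n_nan:
            med = np.nanmedian(col)
            col[np.isnan(col)] = med if np.isfinite(med) else 0.0
            logger.info("imputed %d sentinels in column %s", n_nan, descriptors[j].name)
        keep.append(j)
    return FeatureTable(
        values=rows[:, keep],
        descriptors=tuple(descriptors[j] for j in keep),
        case_ids=tuple(case_ids),
    )


def extract_cohort_table(
    cases: Iterable[tuple[VolumeImage, WallMask, CaseRecord]],
    texture_cfg: Optional[TextureConfig] = None,
    standard_range: tuple[float, float] = STANDARD_RANGE,
) -> FeatureTable:
    """Extract and assemble the feature table for a whole cohort."""
    ids, all_rows, descriptors = [], [], None
    for image, mask, record in cases:
        d, v = extract_case_features(image, mask, record, texture_cfg, standard_range)
        if descriptors is None:
            descriptors = d
        elif [x.name for x in d] != [x.name for x in descriptors]:
            raise WallRadError("inconsistent feature inventory across cases")
        ids.append(record.case_id)
        all_rows.append(v)
    if descriptors is None:
        raise WallRadError("no cases to extract")
    return assemble_feature_table(ids, descriptors, np.vstack(all_rows))
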