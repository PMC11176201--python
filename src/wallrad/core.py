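"""Core domain types for the bladder-wall radiomics pipeline.

The pipeline operates on single 3D T2-weighted MR volumes with a
co-registered binary mask of the bladder wall (a hollow shell enclosing
the lumen), a per-case clinical record, and a cases-by-features matrix
assembled from the extracted radiomic features.

Conventions frozen here: 0-based voxel indices with axis order (x, y, z)
as produced by the NIfTI reader; all geometric operations work in voxel
space and convert to millimetres via the voxel spacing only where the
unit demands it.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Optional, Sequence

import numpy as np
from scipy import ndimage


class WallRadError(ValueError):
    """Base class for domain errors."""


class GridMismatchError(WallRadError):
    """Mask and image do not share the same voxel lattice."""


class EmptyMaskError(WallRadError):
    """Mask has no foreground voxel."""


class NotHollowShellError(WallRadError):
    """Mask foreground does not enclose an interior cavity."""


Label = Literal["negative", "positive"]

#: IPSS threshold separating mild (below) from moderate-to-severe (at or above).
IPSS_POSITIVE_THRESHOLD = 8
IPSS_MIN, IPSS_MAX = 0, 35


def ipss_to_label(ipss: int) -> Label:
    """Dichotomize an IPSS total score.

    Scores below 8 (mild symptoms) map to ``"negative"``; scores of 8 or
    above (moderate-to-severe) map to ``"positive"``.
    """
    ipss = int(ipss)
    if not (IPSS_MIN <= ipss <= IPSS_MAX):
        raise WallRadError(f"IPSS {ipss} outside valid range [{IPSS_MIN}, {IPSS_MAX}]")
    return "positive" if ipss >= IPSS_POSITIVE_THRESHOLD else "negative"


@dataclass(frozen=True)
class VolumeImage:
    """A 3D scalar MR intensity field on a regular grid.

    Parameters
    ----------
    data
        3D array of real intensities (arbitrary MR units).
    spacing
        Voxel edge lengths ``(sx, sy, sz)`` in mm, all strictly positive.
    """

    data: np.ndarray
    spacing: tuple[float, float, float]

    def __post_init__(self) -> None:
        data = np.asarray(self.data, dtype=np.float64)
        if data.ndim != 3:
            raise WallRadError(f"expected 3D volume, got {data.ndim}D array")
        if not np.all(np.isfinite(data)):
            raise WallRadError("volume contains non-finite intensities")
        spacing = tuple(float(s) for s in self.spacing)
        if len(spacing) != 3 or any(s <= 0 for s in spacing):
            raise WallRadError(f"voxel spacing must be three positive values, got {spacing}")
        object.__setattr__(self, "data", data)
        object.__setattr__(self, "spacing", spacing)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]

    def with_data(self, data: np.ndarray) -> "VolumeImage":
        """Same grid, new intensities."""
        return VolumeImage(data=data, spacing=self.spacing)


@dataclass(frozen=True)
class WallMask:
    """Binary region of interest on the same lattice as its image.

    Foreground (1) voxels mark the bladder wall.  Basic validity (binary,
    non-empty) is checked at construction; the hollow-shell property is
    checked by :func:`is_hollow_shell` at ingestion and by consumers that
    require a shell, because derived masks (e.g. tight crops) may legally
    lose the cavity.
    """

    data: np.ndarray
    spacing: tuple[float, float, float]

    def __post_init__(self) -> None:
        data = np.asarray(self.data)
        if data.ndim != 3:
            raise WallRadError(f"expected 3D mask, got {data.ndim}D array")
        uniq = np.unique(data)
        if not np.all(np.isin(uniq, (0, 1))):
            raise WallRadError("mask values must be in {0, 1}")
        data = data.astype(np.uint8)
        if not data.any():
            raise EmptyMaskError("empty mask")
        spacing = tuple(float(s) for s in self.spacing)
        if len(spacing) != 3 or any(s <= 0 for s in spacing):
            raise WallRadError(f"voxel spacing must be three positive values, got {spacing}")
        object.__setattr__(self, "data", data)
        object.__setattr__(self, "spacing", spacing)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]

    @property
    def n_foreground(self) -> int:
        return int(self.data.sum())


def cavity_mask(mask: WallMask) -> np.ndarray:
    """Background voxels enclosed by the wall (6-connectivity flood fill).

    A background component is part of the cavity iff it does not touch
    the grid border.
    """
    filled = ndimage.binary_fill_holes(mask.data)
    return filled & (mask.data == 0)


def is_hollow_shell(mask: WallMask) -> bool:
    """True iff the foreground encloses at least one interior cavity."""
    return bool(cavity_mask(mask).any())


@dataclass(frozen=True)
class CaseRecord:
    """One subject: file references, clinical variables, IPSS and label."""

    case_id: str
    image_ref: Optional[str]
    mask_ref: Optional[str]
    age: float
    bmi: float
    prostate_size: float
    ipss: int
    label: Label = field(init=False)

    def __post_init__(self) -> None:
        for name in ("age", "bmi", "prostate_size"):
            v = getattr(self, name)
            if not np.isfinite(v) or v <= 0:
                raise WallRadError(f"clinical variable {name}={v!r} must be finite and > 0")
        object.__setattr__(self, "ipss", int(self.ipss))
        object.__setattr__(self, "label", ipss_to_label(self.ipss))


CATEGORIES = ("morphological", "intensity", "texture", "clinical")

#: Haralick summary statistics supported for GLCM texture features.
HARALICK_FEATURES = (
    "contrast",
    "dissimilarity",
    "homogeneity",
    "energy",
    "entropy",
    "correlation",
    "variance",
    "sum-average",
    "cluster-shade",
    "cluster-prominence",
)


@dataclass(frozen=True)
class FeatureDescriptor:
    """Per-column metadata for a feature table.

    Texture descriptors carry the full GLCM parameterization
    (angle ``a`` in degrees, distance ``d`` in voxels, bins ``b``,
    window ``w`` in voxels, Haralick feature ``f``); descriptors of the
    other categories carry none of it.
    """

    name: str
    category: str
    angle: Optional[float] = None
    distance: Optional[int] = None
    bins: Optional[int] = None
    window: Optional[int] = None
    haralick: Optional[str] = None

    def __post_init__(self) -> None:
        if self.category not in CATEGORIES:
            raise WallRadError(f"unknown feature category {self.category!r}")
        params = (self.angle, self.distance, self.bins, self.window, self.haralick)
        if self.category == "texture":
            if any(p is None for p in params):
                raise WallRadError(
                    f"texture descriptor {self.name!r} must carry angle/distance/bins/window/haralick"
                )
            if self.haralick not in HARALICK_FEATURES:
                raise WallRadError(f"unknown Haralick feature {self.haralick!r}")
        elif any(p is not None for p in params):
            raise WallRadError(
                f"non-texture descriptor {self.name!r} must not carry texture parameters"
            )

    def to_dict(self) -> dict:
        d = {"name": self.name, "category": self.category}
        if self.category == "texture":
            d.update(
                angle=self.angle,
                distance=self.distance,
                bins=self.bins,
                window=self.window,
                haralick=self.haralick,
            )
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "FeatureDescriptor":
        return cls(**d)


@dataclass(frozen=True)
class FeatureTable:
    """Cases-by-features matrix with per-column descriptors."""

    values: np.ndarray
    descriptors: tuple[FeatureDescriptor, ...]
    case_ids: tuple[str, ...]

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=np.float64)
        if values.ndim != 2:
            raise WallRadError("feature values must be a 2D cases x features matrix")
        descriptors = tuple(self.descriptors)
        case_ids = tuple(str(c) for c in self.case_ids)
        if values.shape[0] != len(case_ids):
            raise WallRadError(
                f"{values.shape[0]} rows but {len(case_ids)} case ids"
            )
        if values.shape[1] != len(descriptors):
            raise WallRadError(
                f"{values.shape[1]} columns but {len(descriptors)} descriptors"
            )
        names = [d.name for d in descriptors]
        if len(set(names)) != len(names):
            raise WallRadError("descriptor names must be unique")
        if not np.all(np.isfinite(values)):
            raise WallRadError("feature table contains non-finite entries")
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "descriptors", descriptors)
        object.__setattr__(self, "case_ids", case_ids)

    @property
    def n_cases(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    @property
    def feature_names(self) -> tuple[str, ...]:
        return tuple(d.name for d in self.descriptors)

    def column_index(self, name: str) -> int:
        try:
            return self.feature_names.index(name)
        except ValueError:
            raise WallRadError(f"unknown feature {name!r}") from None

    def columns(self, names: Sequence[str]) -> np.ndarray:
        """Sub-matrix of the named columns, in the given order."""
        idx = [self.column_index(n) for n in names]
        return self.values[:, idx]

    def category_of(self, name: str) -> str:
        return self.descriptors[self.column_index(name)].category
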