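"""Histogram-landmark intensity standardization (Nyul-Udupa style).

Two phases: a training phase learns a standard intensity scale by mapping
each training image's landmark percentiles (deciles by default) linearly
onto a fixed range anchored at robust tail percentiles, then averaging the
mapped landmarks across images; an application phase transforms any image
piecewise-linearly so its own landmarks land on the learned scale.

The transform is monotone non-decreasing, approximately idempotent, and
invariant to affine re-scalings of the input (a positive gain plus offset
leaves the output essentially unchanged) — the properties that make MR
intensities comparable across scans.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from .core import VolumeImage, WallMask, WallRadError

DEFAULT_LANDMARKS = tuple(float(p) for p in range(10, 100, 10))  # deciles


@dataclass(frozen=True)
class StandardizationConfig:
    pc_low: float = 1.0
    pc_high: float = 99.0
    landmark_percentiles: tuple[float, ...] = DEFAULT_LANDMARKS
    s_min: float = 0.0
    s_max: float = 4095.0
    #: percentile of the whole volume below which voxels are treated as air
    #: and excluded from landmark estimation when no mask is given; 0 uses
    #: every voxel.  Trimming composes poorly with the tail clipping of an
    #: already-standardized volume (the collapsed low tail shifts the
    #: trimmed set and with it the landmarks), so trimming is off by
    #: default and meant for volumes with a genuine air peak.
    foreground_percentile: float = 0.0

    def __post_init__(self) -> None:
        lm = tuple(float(p) for p in self.landmark_percentiles)
        if not all(a < b for a, b in zip(lm, lm[1:])):
            raise WallRadError("landmark percentiles must be strictly increasing")
        if not (0 <= self.pc_low < lm[0] and lm[-1] < self.pc_high <= 100):
            raise WallRadError("landmarks must lie strictly between the tail percentiles")
        if not self.s_min < self.s_max:
            raise WallRadError("standard range must have s_min < s_max")
        object.__setattr__(self, "landmark_percentiles", lm)


@dataclass(frozen=True)
class StandardizationModel:
    """A learned standard scale: target values for tails and landmarks."""

    config: StandardizationConfig
    #: learned landmark targets L1*..Lk* on [s_min, s_max]
    standard_landmarks: tuple[float, ...]

    def __post_init__(self) -> None:
        full = self.full_scale()
        if not all(a < b for a, b in zip(full, full[1:])):
            raise WallRadError("standard scale must be strictly increasing")

    def full_scale(self) -> tuple[float, ...]:
        return (self.config.s_min, *self.standard_landmarks, self.config.s_max)

    def to_json(self, path: Path | str) -> None:
        payload = {
            "pc_low": self.config.pc_low,
            "pc_high": self.config.pc_high,
            "landmark_percentiles": list(self.config.landmark_percentiles),
            "s_min": self.config.s_min,
            "s_max": self.config.s_max,
            "foreground_percentile": self.config.foreground_percentile,
            "standard_landmarks": list(self.standard_landmarks),
        }
        Path(path).write_text(json.dumps(payload, indent=2))

    @classmethod
    def from_json(cls, path: Path | str) -> "StandardizationModel":
        d = json.loads(Path(path).read_text())
        landmarks = d.pop("standard_landmarks")
        cfg = StandardizationConfig(
            pc_low=d["pc_low"],
            pc_high=d["pc_high"],
            landmark_percentiles=tuple(d["landmark_percentiles"]),
            s_min=d["s_min"],
            s_max=d["s_max"],
            foreground_percentile=d["foreground_percentile"],
        )
        return cls(config=cfg, standard_landmarks=tuple(landmarks))


def _body_voxels(
    image: VolumeImage, mask: Optional[WallMask], cfg: StandardizationConfig
) -> np.ndarray:
    """Voxels used for percentile estimation.

    With a mask, the mask's bounding region (the anatomy of interest plus
    surroundings); otherwise all voxels above a low percentile of the
    volume, which discards the air background peak.
    """
    data = image.data
    if mask is not None:
        fg = np.argwhere(mask.data)
        lo, hi = fg.min(axis=0), fg.max(axis=0) + 1
        sl = tuple(slice(int(a), int(b)) for a, b in zip(lo, hi))
        return data[sl].ravel()
    if cfg.foreground_percentile <= 0:
        return data.ravel()
    thr = np.percentile(data, cfg.foreground_percentile)
    body = data[data > thr]
    return body if body.size else data.ravel()


def _image_landmarks(values: np.ndarray, cfg: StandardizationConfig) -> tuple[float, float, np.ndarray]:
    p_low, p_high = np.percentile(values, [cfg.pc_low, cfg.pc_high])
    landmarks = np.percentile(values, cfg.landmark_percentiles)
    return float(p_low), float(p_high), np.asarray(landmarks, dtype=float)


def train_standardizer(
    images: Sequence[VolumeImage],
    masks: Optional[Sequence[Optional[WallMask]]] = None,
    config: Optional[StandardizationConfig] = None,
) -> StandardizationModel:
    """Learn the standard scale from training images.

    Each image's landmarks are mapped linearly onto [s_min, s_max]
    anchored at its tail percentiles; the standard landmark L_j* is the
    mean of mapped landmark j over the training images.  Images with zero
    intensity spread are excluded with a warning.
    """
    cfg = config or StandardizationConfig()
    if not images:
        raise WallRadError("need at least one training image")
    if masks is None:
        masks = [None] * len(images)
    mapped = []
    for i, (img, msk) in enumerate(zip(images, masks)):
        values = _body_voxels(img, msk, cfg)
        p_low, p_high, lms = _image_landmarks(values, cfg)
        if p_high - p_low < 1e-12:
            warnings.warn(f"training image {i} has zero intensity spread; excluded")
            continue
        scale = (cfg.s_max - cfg.s_min) / (p_high - p_low)
        mapped.append(cfg.s_min + (lms - p_low) * scale)
    if not mapped:
        raise WallRadError("all training images had zero intensity spread")
    standard = np.mean(np.vstack(mapped), axis=0)
    return StandardizationModel(config=cfg, standard_landmarks=tuple(float(v) for v in standard))


def apply_standardizer(
    model: StandardizationModel,
    image: VolumeImage,
    mask: Optional[WallMask] = None,
) -> VolumeImage:
    """Map an image piecewise-linearly onto the model's standard scale.

    The image's own (pc_low, L1..Lk, pc_high) are sent to
    (s_min, L1*..Lk*, s_max); values beyond the tails follow the end
    segments and are clipped to [s_min, s_max] (with monotone segments the
    linear extrapolation beyond a tail lands outside the range, so
    extrapolate-then-clip reduces to clipping).
    """
    cfg = model.config
    values = _body_voxels(image, mask, cfg)
    p_low, p_high, lms = _image_landmarks(values, cfg)
    if p_high - p_low < 1e-12:
        raise WallRadError("image has zero intensity spread; cannot standardize")
    src = np.array([p_low, *lms, p_high], dtype=float)
    dst = np.array(model.full_scale(), dtype=float)
    # percentile estimates can tie on heavily discretized data; nudge to
    # keep the map well-defined and monotone
    src = np.maximum.accumulate(src)
    tie = np.diff(src) <= 0
    if tie.any():
        eps = max(1e-9, 1e-9 * (src[-1] - src[0]))
        for j in np.where(tie)[0]:
            src[j + 1] = src[j] + eps
    out = np.interp(image.data, src, dst)
    return image.with_data(np.clip(out, cfg.s_min, cfg.s_max))
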