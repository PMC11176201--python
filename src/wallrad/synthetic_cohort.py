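"""Synthetic phantom cohorts with the statistical structure the analysis assumes.

Each case is a hollow ellipsoidal shell (the "bladder wall") embedded in a
small isotropic grid.  The wall carries a stationary correlated Gaussian
random field; the two classes differ only in the correlation length of
that field (scaled by ``texture_effect``), while wall morphology, the
marginal intensity distribution, age and BMI are matched between classes.
Prostate size is the one clinical variable with a class difference by
default, mirroring cohorts where outlet obstruction tracks prostate
enlargement.  A per-case global affine intensity distortion (gain and
offset) emulates inter-scan intensity drift, which the standardization
stage is expected to remove.

The generator emulates the *category* of class contrast — texture, not
morphology or intensity — not anatomically realistic bladder shapes.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
from scipy import ndimage

from .core import CaseRecord, VolumeImage, WallMask, WallRadError
from .io_formats import write_manifest, write_mask, write_volume


@dataclass(frozen=True)
class ClinicalModel:
    """Per-class Gaussian means/SDs for the clinical variables.

    Defaults: age and BMI identically distributed in both classes;
    prostate size larger in the positive class.
    """

    age_mean: tuple[float, float] = (66.0, 66.0)  # (negative, positive)
    age_sd: tuple[float, float] = (8.0, 8.0)
    bmi_mean: tuple[float, float] = (28.0, 28.0)
    bmi_sd: tuple[float, float] = (4.0, 4.0)
    prostate_mean: tuple[float, float] = (40.0, 55.0)  # mL
    prostate_sd: tuple[float, float] = (14.0, 18.0)


@dataclass(frozen=True)
class SyntheticConfig:
    """Generation parameters for one phantom cohort.

    ``texture_effect`` multiplies the positive class's texture correlation
    length: length_pos = length_neg * (1 + texture_effect).  With all
    three effects at 0 the classes are exchangeable in their image
    features (null cohort).
    """

    n_negative: int = 50
    n_positive: int = 37
    grid_shape: tuple[int, int, int] = (40, 40, 40)
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)  # mm
    outer_radii_mm: tuple[float, float] = (10.0, 15.0)  # ellipsoid semi-axis range
    wall_thickness_mm: tuple[float, float] = (3.5, 6.0)
    texture_effect: float = 1.0
    intensity_effect: float = 0.0  # class difference in wall mean intensity
    morphology_effect: float = 0.0  # class difference in mean wall thickness (mm)
    clinical_model: ClinicalModel = field(default_factory=ClinicalModel)
    noise_sd: float = 60.0  # texture field SD in raw intensity units
    base_corr_length_mm: float = 0.8
    wall_intensity: float = 400.0
    cavity_intensity: float = 900.0  # urine is bright on T2
    background_intensity: float = 80.0
    background_noise_sd: float = 20.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_negative < 1 or self.n_positive < 1:
            raise WallRadError("class counts must be >= 1")
        if self.wall_thickness_mm[0] < 2 * min(self.spacing):
            raise WallRadError(
                "minimum wall thickness must be at least 2 voxels at the given spacing"
            )
        for name in ("texture_effect", "morphology_effect", "noise_sd"):
            if getattr(self, name) < 0:
                raise WallRadError(f"{name} must be >= 0")


@dataclass(frozen=True)
class SyntheticCase:
    """In-memory generated case: image, mask and record together."""

    record: CaseRecord
    image: VolumeImage
    mask: WallMask


def _ellipsoid(shape, center, semi_axes_vox) -> np.ndarray:
    grids = np.ogrid[tuple(slice(0, n) for n in shape)]
    acc = np.zeros(shape, dtype=np.float64)
    for g, c, a in zip(grids, center, semi_axes_vox):
        acc = acc + ((g - c) / a) ** 2
    return acc <= 1.0


def _correlated_field(shape, corr_length_vox, rng) -> np.ndarray:
    """Stationary Gaussian field, ~unit variance, given correlation length.

    Gaussian smoothing of white noise with kernel sigma equal to the
    correlation length, renormalized empirically to unit SD so that the
    marginal intensity distribution does not depend on the length.
    """
    white = rng.standard_normal(shape)
    smooth = ndimage.gaussian_filter(white, sigma=corr_length_vox, mode="wrap")
    sd = smooth.std()
    if sd < 1e-12:  # pathological, only for absurd correlation lengths
        return np.zeros(shape)
    return smooth / sd


def _sample_clinical(model: ClinicalModel, positive: bool, rng) -> tuple[float, float, float]:
    i = 1 if positive else 0

    def draw(mean, sd, lo):
        for _ in range(100):
            v = rng.normal(mean[i], sd[i])
            if v > lo:
                return float(v)
        return float(lo + abs(rng.normal(0, sd[i])))  # fallback, keeps positivity

    age = draw(model.age_mean, model.age_sd, 30.0)
    bmi = draw(model.bmi_mean, model.bmi_sd, 15.0)
    prostate = draw(model.prostate_mean, model.prostate_sd, 10.0)
    return age, bmi, prostate


def generate_case(
    config: SyntheticConfig,
    class_label: str,
    rng: np.random.Generator,
    case_id: str = "case",
) -> SyntheticCase:
    """Generate one phantom case of the given class.

    The outer surface is an ellipsoid with random semi-axes; the cavity is
    the concentric ellipsoid eroded inward by a sampled wall thickness.
    Wall voxels receive a class-dependent correlated texture field; cavity
    and background receive distinct base intensities plus white noise; a
    global per-case gain/offset is applied at the end.
    """
    if class_label not in ("negative", "positive"):
        raise WallRadError(f"unknown class label {class_label!r}")
    positive = class_label == "positive"
    shape = config.grid_shape
    spacing = np.asarray(config.spacing)

    lo_t, hi_t = config.wall_thickness_mm
    if positive:
        lo_t, hi_t = lo_t + config.morphology_effect, hi_t + config.morphology_effect
    lo_r, hi_r = config.outer_radii_mm

    mask_arr = None
    for _ in range(100):
        semi_axes_mm = rng.uniform(lo_r, hi_r, size=3)
        thickness_mm = rng.uniform(lo_t, hi_t)
        inner_mm = semi_axes_mm - thickness_mm
        if np.any(inner_mm / spacing < 1.5):
            continue
        if thickness_mm / spacing.min() < 2:
            continue
        center = np.array(shape) / 2.0 - 0.5 + rng.uniform(-1.5, 1.5, size=3)
        outer = _ellipsoid(shape, center, semi_axes_mm / spacing)
        inner = _ellipsoid(shape, center, inner_mm / spacing)
        wall = outer & ~inner
        if wall.any() and inner.any():
            mask_arr = wall
            cavity = inner
            break
    if mask_arr is None:
        raise WallRadError("failed to sample a valid wall geometry in 100 tries")

    corr_mm = config.base_corr_length_mm * (1 + (config.texture_effect if positive else 0.0))
    field3d = _correlated_field(shape, corr_mm / spacing, rng)

    wall_base = config.wall_intensity + (config.intensity_effect if positive else 0.0)
    data = np.full(shape, config.background_intensity, dtype=np.float64)
    data += rng.normal(0.0, config.background_noise_sd, size=shape)
    data[cavity] = config.cavity_intensity + rng.normal(
        0.0, config.background_noise_sd, size=int(cavity.sum())
    )
    data[mask_arr] = wall_base + config.noise_sd * field3d[mask_arr]

    # per-case scanner-like affine intensity distortion; removed downstream
    # by histogram-landmark standardization
    gain = rng.uniform(0.8, 1.2)
    offset = rng.uniform(-20.0, 20.0)
    data = gain * data + offset

    ipss = int(rng.integers(8, 36)) if positive else int(rng.integers(0, 8))
    age, bmi, prostate = _sample_clinical(config.clinical_model, positive, rng)

    record = CaseRecord(
        case_id=case_id,
        image_ref=None,
        mask_ref=None,
        age=age,
        bmi=bmi,
        prostate_size=prostate,
        ipss=ipss,
    )
    spacing_t = tuple(float(s) for s in config.spacing)
    return SyntheticCase(
        record=record,
        image=VolumeImage(data=data, spacing=spacing_t),
        mask=WallMask(data=mask_arr.astype(np.uint8), spacing=spacing_t),
    )


def _case_rng(master_seed: int, index: int) -> np.random.Generator:
    # per-case independent, reproducible streams
    return np.random.default_rng(np.random.SeedSequence([master_seed, index]))


def generate_cohort(
    config: SyntheticConfig, out_dir: Optional[Path] = None
) -> list[SyntheticCase]:
    """Generate a full cohort; optionally write NIfTI volumes plus manifest.

    Deterministic given ``config`` (including its ``seed``): each case
    draws from an independent stream derived from the master seed, so any
    single case can be regenerated without the rest.
    """
    cases: list[SyntheticCase] = []
    labels = ["negative"] * config.n_negative + ["positive"] * config.n_positive
    for i, lab in enumerate(labels):
        case_id = f"syn{i:03d}"
        case = generate_case(config, lab, _case_rng(config.seed, i), case_id=case_id)
        cases.append(case)

    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        records = []
        for case in cases:
            img_path = out_dir / f"{case.record.case_id}_img.nii.gz"
            msk_path = out_dir / f"{case.record.case_id}_mask.nii.gz"
            write_volume(case.image, img_path)
            write_mask(case.mask, msk_path)
            records.append(
                dataclasses.replace(
                    case.record, image_ref=img_path.name, mask_ref=msk_path.name
                )
            )
        header = [f"config {k}={v}" for k, v in _config_echo(config).items()]
        write_manifest(records, out_dir / "manifest.csv", header_lines=header)
    return cases


def _config_echo(config: SyntheticConfig) -> dict:
    d = dataclasses.asdict(config)
    d["clinical_model"] = dataclasses.asdict(config.clinical_model)
    return d
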