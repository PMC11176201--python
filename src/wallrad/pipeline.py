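"""End-to-end orchestration of the analysis stages.

Chains: synthetic cohort (or a manifest on disk) → intensity
standardization → feature extraction → univariate analysis → hybrid
feature selection → repeated cross-validated evaluation.  A single global
seed fans out to per-stage seeds by stable hashing of the stage name, so
stages can be re-run independently yet reproducibly.
"""

from __future__ import annotations

import dataclasses
import logging
import zlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np

from .core import FeatureTable
from .evaluation import EvaluationReport, naive_baseline, subset_comparison
from .feature_extraction import STANDARD_RANGE, TextureConfig, extract_cohort_table
from .feature_selection import SelectionConfig, SelectionResult, obm_search
from .io_formats import labels_from_records, load_manifest, read_mask, read_volume
from .standardization import StandardizationConfig, apply_standardizer, train_standardizer
from .synthetic_cohort import SyntheticCase, SyntheticConfig, generate_cohort
from .univariate_analysis import UnivariateResult, univariate_pvalues

logger = logging.getLogger(__name__)


def stage_seed(global_seed: int, stage: str) -> int:
    """Derive a per-stage seed below 2**31 by hashing the stage name."""
    return int((zlib.crc32(stage.encode()) ^ (int(global_seed) & 0xFFFFFFFF)) % (2**31))


@dataclass(frozen=True)
class PipelineConfig:
    synthetic: SyntheticConfig = field(default_factory=SyntheticConfig)
    standardization: StandardizationConfig = field(default_factory=StandardizationConfig)
    texture: TextureConfig = field(default_factory=TextureConfig)
    selection: SelectionConfig = field(default_factory=SelectionConfig)
    eval_folds: int = 5
    eval_repeats: int = 100
    classifier: str = "linear_svm"
    seed: int = 0


@dataclass
class PipelineResult:
    table: FeatureTable
    labels: np.ndarray
    univariate: UnivariateResult
    selection: SelectionResult
    report: EvaluationReport
    naive: dict
    comparisons: dict[str, EvaluationReport]


def standardize_cohort(
    cases: list[SyntheticCase],
    config: Optional[StandardizationConfig] = None,
) -> list[SyntheticCase]:
    """Train a standardizer on the whole cohort, then transform each volume."""
    model = train_standardizer(
        [c.image for c in cases], [c.mask for c in cases], config
    )
    return [
        SyntheticCase(record=c.record, image=apply_standardizer(model, c.image, c.mask), mask=c.mask)
        for c in cases
    ]


def cohort_feature_table(
    cases: list[SyntheticCase],
    texture_cfg: Optional[TextureConfig] = None,
    standardization_cfg: Optional[StandardizationConfig] = None,
    standardize: bool = True,
) -> tuple[FeatureTable, np.ndarray]:
    """Standardize (optionally) and extract the feature table for a cohort."""
    if standardize:
        cases = standardize_cohort(cases, standardization_cfg)
    table = extract_cohort_table(
        ((c.image, c.mask, c.record) for c in cases),
        texture_cfg,
        standard_range=STANDARD_RANGE,
    )
    labels = labels_from_records([c.record for c in cases])
    return table, labels


def load_cohort(manifest_path: Path | str) -> list[SyntheticCase]:
    """Load a cohort from a manifest CSV with NIfTI volume/mask references."""
    manifest_path = Path(manifest_path)
    records = load_manifest(manifest_path)
    cases = []
    for rec in records:
        image = read_volume(manifest_path.parent / rec.image_ref)
        mask = read_mask(manifest_path.parent / rec.mask_ref, image)
        cases.append(SyntheticCase(record=rec, image=image, mask=mask))
    return cases


def run_all(config: Optional[PipelineConfig] = None) -> PipelineResult:
    """Run the full analysis on a synthetic cohort.

    The final evaluation reuses one shared fold-seed stream across the
    optimal subset, the single-clinical-variable models, and the
    all-clinical model, so the comparison is paired.
    """
    cfg = config or PipelineConfig()
    syn = dataclasses.replace(cfg.synthetic, seed=stage_seed(cfg.seed, "simulate"))
    cases = generate_cohort(syn)
    table, labels = cohort_feature_table(cases, cfg.texture, cfg.standardization)

    uni = univariate_pvalues(table, labels)
    sel_cfg = dataclasses.replace(cfg.selection, seed=stage_seed(cfg.seed, "select"))
    selection = obm_search(table, labels, sel_cfg, univariate=uni)

    eval_seed = stage_seed(cfg.seed, "evaluate")
    subsets = {
        "optimal": list(selection.selected),
        "age_only": ["clin_age"],
        "bmi_only": ["clin_bmi"],
        "prostate_only": ["clin_prostate_size"],
        "all_clinical": ["clin_age", "clin_bmi", "clin_prostate_size"],
    }
    comparisons = subset_comparison(
        table, labels, subsets,
        k=cfg.eval_folds, repeats=cfg.eval_repeats, seed=eval_seed,
        classifier=cfg.classifier,
    )
    return PipelineResult(
        table=table,
        labels=labels,
        univariate=uni,
        selection=selection,
        report=comparisons["optimal"],
        naive=naive_baseline(labels),
        comparisons=comparisons,
    )
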