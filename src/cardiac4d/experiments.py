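"""Desk-scale reference experiments on phantom cohorts.

These drive both the validation suite and the reproduction script: a seeded
phantom cohort with realistic spread of volumes and ejection fractions, and
an end-to-end train/held-out-test run of the segmentation stage.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import cardiometrics as cm
from .io_core import FOREGROUND_CLASSES, Cine4D, LabelMap4D
from .phantom import PhantomParams, PhantomTruth, generate_phantom
from .segmenter import (
    ModelConfig,
    ModelState,
    TrainConfig,
    infer,
    postprocess_largest_component,
    train,
)

__all__ = ["phantom_cohort", "SegmentationRun", "end_to_end_experiment"]


def phantom_cohort(
    n: int, seed: int, n_phases: int = 2
) -> list[tuple[PhantomParams, Cine4D, PhantomTruth]]:
    """Generate ``n`` seeded phantoms with varied anatomy and contrast.

    End-diastolic volumes span 120-170 mL and ejection fractions 35-70%
    (covering reduced-EF through healthy hearts), wall thickness 8-11 mm,
    alternating bSSFP-like and GRE-like contrast.
    """
    rng = np.random.default_rng(seed)
    cohort = []
    for i in range(n):
        params = PhantomParams(
            n_phases=n_phases,
            target_EDV_ml=float(rng.uniform(120, 170)),
            target_EF_pct=float(rng.uniform(35, 70)),
            wall_thickness_mm=float(rng.uniform(8, 11)),
            rv_scale=float(rng.uniform(0.9, 1.05)),
            contrast_mode="bssfp_like" if i % 2 == 0 else "gre_like",
            seed=int(rng.integers(0, 2**31 - 1)),
        )
        cine, truth = generate_phantom(params)
        cohort.append((params, cine, truth))
    return cohort


@dataclass
class SegmentationRun:
    model: ModelState
    dice_per_subject: list[dict[int, float]]      # pooled ED+ES Dice per structure
    mean_dice: dict[int, float]
    volume_errors_pct: list[dict[str, float]]     # ED/ES LV volume error vs truth
    predictions: list[LabelMap4D]
    truths: list[PhantomTruth]


def end_to_end_experiment(
    seed: int,
    n_train: int = 12,
    n_test: int = 4,
    epochs: int = 40,
) -> SegmentationRun:
    """Train on a phantom cohort, infer on held-out phantoms, post-process,
    and evaluate pooled ED+ES Dice and clinical volume recovery."""
    cohort = phantom_cohort(n_train + n_test, seed=seed)
    train_pairs = []
    for _, cine, truth in cohort[:n_train]:
        for p in (truth.ed_phase, truth.es_phase):
            train_pairs.append((cine.phase(p), truth.labels.voxels[..., p]))

    model = train(
        ModelConfig(),
        train_pairs,
        cfg=TrainConfig(epochs=epochs, seed=seed),
        spacing_mm=cohort[0][0].spacing_mm,
    )

    dice_rows, vol_rows, preds, truths = [], [], [], []
    for _, cine, truth in cohort[n_train:]:
        pred = postprocess_largest_component(infer(model, cine))
        ed, es = truth.ed_phase, truth.es_phase
        row = {}
        for code in FOREGROUND_CLASSES:
            inter = size = 0
            for p in (ed, es):
                a = pred.voxels[..., p] == code
                b = truth.labels.voxels[..., p] == code
                inter += int((a & b).sum())
                size += int(a.sum()) + int(b.sum())
            row[code] = 2.0 * inter / size if size else 1.0
        dice_rows.append(row)
        sp = cine.spacing_mm
        vol_rows.append(
            {
                "edv_err_pct": abs(
                    cm.label_volume_ml(pred.voxels[..., ed], 1, sp) - truth.lvb_volume_ml[ed]
                ) / truth.lvb_volume_ml[ed] * 100.0,
                "esv_err_pct": abs(
                    cm.label_volume_ml(pred.voxels[..., es], 1, sp) - truth.lvb_volume_ml[es]
                ) / truth.lvb_volume_ml[es] * 100.0,
            }
        )
        preds.append(pred)
        truths.append(truth)

    mean_dice = {
        code: float(np.mean([r[code] for r in dice_rows])) for code in FOREGROUND_CLASSES
    }
    return SegmentationRun(model, dice_rows, mean_dice, vol_rows, preds, truths)
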