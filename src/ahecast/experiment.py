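"""Experiment orchestration: patient-level splits, class balancing, the
observation-by-gap model grid, and transfer-learning fine-tuning.

Data are always split by patient, never by window, so no patient
contributes to more than one of train/validation/test; a leakage check
enforces this and fails the run on violation. Training and validation sets
are class-balanced by randomly down-sampling negatives (a 2:1
negative:positive policy is also supported); the test set keeps every
negative so reported metrics reflect the deployment class imbalance.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .annotation import AnnotationConfig, annotate_record
from .evaluation import auroc
from .models import (
    DecayGRUSpec,
    LSTMSpec,
    TrainSpec,
    baseline_logreg,
    baseline_svm,
    build_decay_gru,
    build_lstm,
    fit,
    predict_proba,
)
from .nn import binary_cross_entropy, constant_schedule
from .records import Cohort
from .windowing import GAP_LENGTHS, OBS_LENGTHS, WindowDataset, build_dataset

logger = logging.getLogger(__name__)

MODEL_FAMILIES = ("lstm", "decay_gru", "logreg", "svm")
DEEP_FAMILIES = ("lstm", "decay_gru")


class PatientLeakageError(RuntimeError):
    """A patient id appears in more than one data split."""


@dataclass
class SplitPlan:
    train_patients: set[str]
    val_patients: set[str]
    test_patients: set[str]

    def __post_init__(self) -> None:
        if (
            self.train_patients & self.val_patients
            or self.train_patients & self.test_patients
            or self.val_patients & self.test_patients
        ):
            raise PatientLeakageError("patient sets must be pairwise disjoint")


@dataclass
class GridPlan:
    obs_lengths: tuple[int, ...] = OBS_LENGTHS
    gap_lengths: tuple[int, ...] = GAP_LENGTHS
    model_families: tuple[str, ...] = DEEP_FAMILIES

    def cells(self) -> list[tuple[int, int]]:
        return [(o, g) for o in self.obs_lengths for g in self.gap_lengths]

    def n_models_per_family(self) -> int:
        return len(self.obs_lengths) * len(self.gap_lengths)

    def n_models_total(self) -> int:
        return self.n_models_per_family() * len(self.model_families)


@dataclass
class TransferPlan:
    tune_sizes: tuple[int, ...] = (10, 20, 30, 40, 50)
    fine_tune_lr: float = 1e-4
    epochs: int = 30
    seed: int = 0


def split_by_patient(
    cohort: Cohort | list[str],
    fractions: tuple[float, float, float] = (0.8, 0.1, 0.1),
    seed: int = 0,
) -> SplitPlan:
    """Deterministic disjoint train/val/test patient sets."""
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise ValueError("fractions must sum to 1")
    ids = cohort.patient_ids() if isinstance(cohort, Cohort) else list(cohort)
    if not ids:
        raise ValueError("cohort is empty")
    rng = np.random.default_rng(seed)
    order = [ids[i] for i in rng.permutation(len(ids))]
    n = len(order)
    n_train = int(round(fractions[0] * n))
    n_val = int(round(fractions[1] * n))
    n_train = min(n_train, n)
    n_val = min(n_val, n - n_train)
    return SplitPlan(
        train_patients=set(order[:n_train]),
        val_patients=set(order[n_train : n_train + n_val]),
        test_patients=set(order[n_train + n_val :]),
    )


def check_no_leakage(*datasets: WindowDataset) -> None:
    """Fail if any patient id appears in more than one dataset."""
    seen: set[str] = set()
    for ds in datasets:
        ids = set(map(str, ds.patient_ids))
        overlap = seen & ids
        if overlap:
            raise PatientLeakageError(
                f"patients in multiple splits: {sorted(overlap)[:5]}"
            )
        seen |= ids


def _subset_by_patients(ds: WindowDataset, patients: set[str]) -> WindowDataset:
    idx = np.array([pid in patients for pid in ds.patient_ids], dtype=bool)
    return ds.subset(np.flatnonzero(idx))


def balance_classes(
    ds: WindowDataset, seed: int = 0, neg_per_pos: float = 1.0
) -> WindowDataset:
    """Randomly down-sample negatives to ``neg_per_pos`` times the positives."""
    pos_idx = np.flatnonzero(ds.y == 1)
    neg_idx = np.flatnonzero(ds.y == 0)
    if len(pos_idx) == 0:
        raise ValueError("cannot balance a set with zero positive samples")
    n_neg = min(len(neg_idx), int(round(neg_per_pos * len(pos_idx))))
    rng = np.random.default_rng(seed)
    keep_neg = rng.choice(neg_idx, size=n_neg, replace=False)
    keep = np.sort(np.concatenate([pos_idx, keep_neg]))
    return ds.subset(keep)


def balance_training_sets(
    train: WindowDataset,
    val: WindowDataset,
    test: WindowDataset,
    seed: int = 0,
    neg_per_pos: float = 1.0,
) -> tuple[WindowDataset, WindowDataset, WindowDataset]:
    """Balance train and val by negative down-sampling; test is untouched."""
    return (
        balance_classes(train, seed=seed, neg_per_pos=neg_per_pos),
        balance_classes(val, seed=seed + 1, neg_per_pos=neg_per_pos),
        test,
    )


def annotate_cohort(
    cohort: Cohort, config: AnnotationConfig | None = None
) -> dict[str, list]:
    """Patient-specific episode annotations for every record."""
    config = config or AnnotationConfig()
    return {r.patient_id: annotate_record(r, config) for r in cohort.records}


def prepare_cell(
    cohort: Cohort,
    events: dict[str, list],
    split: SplitPlan,
    obs_length: int,
    gap_length: int,
    seed: int = 0,
    neg_per_pos: float = 1.0,
) -> tuple[WindowDataset, WindowDataset, WindowDataset]:
    """Build balanced train/val and full test datasets for one grid cell."""
    full = build_dataset(cohort, events, obs_length, gap_length)
    train = _subset_by_patients(full, split.train_patients)
    val = _subset_by_patients(full, split.val_patients)
    test = _subset_by_patients(full, split.test_patients)
    check_no_leakage(train, val, test)
    return balance_training_sets(train, val, test, seed=seed, neg_per_pos=neg_per_pos)


def _fit_family(
    family: str,
    train: WindowDataset,
    val: WindowDataset,
    test: WindowDataset,
    obs_length: int,
    train_spec: TrainSpec,
) -> np.ndarray:
    """Fit one model family on a prepared cell; return test scores."""
    if family == "lstm":
        model = build_lstm(LSTMSpec(), timesteps=obs_length, seed=train_spec.seed)
        model, _ = fit(model, train, val, train_spec)
        return predict_proba(model, test)
    if family == "decay_gru":
        model = build_decay_gru(
            DecayGRUSpec(), timesteps=obs_length, seed=train_spec.seed
        )
        model, _ = fit(model, train, val, train_spec)
        return predict_proba(model, test)
    if family == "logreg":
        return baseline_logreg(train, test, seed=train_spec.seed)[0]
    if family == "svm":
        return baseline_svm(train, test, seed=train_spec.seed)[0]
    raise ValueError(f"unknown model family {family!r}")


def run_grid(
    cohort: Cohort,
    plan: GridPlan | None = None,
    train_spec: TrainSpec | None = None,
    fractions: tuple[float, float, float] = (0.8, 0.1, 0.1),
    seed: int = 0,
    annotation_config: AnnotationConfig | None = None,
) -> pd.DataFrame:
    """Fit and evaluate one model per family per (observation, gap) cell.

    Returns a tidy frame with one row per fitted model:
    family, obs, gap, auroc, n_train, n_pos_test, n_neg_test.
    Cells are independent: each is rebuilt from the cohort and the shared
    patient split, so any single cell can be reproduced in isolation.
    """
    plan = plan or GridPlan()
    train_spec = train_spec or TrainSpec(seed=seed)
    events = annotate_cohort(cohort, annotation_config)
    split = split_by_patient(cohort, fractions, seed=seed)
    rows = []
    for obs, gap in plan.cells():
        train, val, test = prepare_cell(cohort, events, split, obs, gap, seed=seed)
        if train.n_pos == 0 or test.n_pos == 0 or val.n_pos == 0:
            raise ValueError(
                f"cell obs={obs} gap={gap}: a split has no positive windows"
            )
        for family in plan.model_families:
            scores = _fit_family(family, train, val, test, obs, train_spec)
            rows.append(
                {
                    "family": family,
                    "obs": obs,
                    "gap": gap,
                    "auroc": auroc(scores, test.y),
                    "n_train": len(train),
                    "n_pos_test": test.n_pos,
                    "n_neg_test": test.n_neg,
                }
            )
            logger.info("grid cell %s", rows[-1])
    return pd.DataFrame(rows)


@dataclass
class TransferResult:
    tune_size: int
    model: object
    val_loss: float


def transfer_finetune(
    source_model,
    tune: WindowDataset,
    val: WindowDataset,
    plan: TransferPlan | None = None,
) -> tuple[object, list[TransferResult]]:
    """Fine-tune copies of a trained model on growing class-balanced tune sets.

    For each tune size a fresh copy of the source weights is fine-tuned at
    the reduced learning rate and the copy with the best target-domain
    validation loss is returned. The source model is never mutated.
    """
    plan = plan or TransferPlan()
    results: list[TransferResult] = []
    rng = np.random.default_rng(plan.seed)
    pos_idx = np.flatnonzero(tune.y == 1)
    neg_idx = np.flatnonzero(tune.y == 0)
    for size in plan.tune_sizes:
        half = size // 2
        if half > len(pos_idx) or half > len(neg_idx):
            raise ValueError(
                f"tune size {size} exceeds available balanced windows "
                f"({len(pos_idx)} pos / {len(neg_idx)} neg)"
            )
        idx = np.sort(
            np.concatenate(
                [
                    rng.choice(pos_idx, size=half, replace=False),
                    rng.choice(neg_idx, size=half, replace=False),
                ]
            )
        )
        subset = tune.subset(idx)
        model = source_model.clone()
        if hasattr(source_model, "x_mean"):
            model.x_mean = source_model.x_mean.copy()
        spec = TrainSpec(
            epochs=plan.epochs,
            batch_size=min(size, 64),
            seed=plan.seed + size,
            lr_schedule=constant_schedule(plan.fine_tune_lr),
        )
        if plan.epochs > 0:
            model, _ = fit(model, subset, val, spec)
        val_probs = predict_proba(model, val)
        results.append(
            TransferResult(
                tune_size=size,
                model=model,
                val_loss=binary_cross_entropy(val_probs, val.y.astype(float)),
            )
        )
    best = min(results, key=lambda r: r.val_loss)
    return best.model, results
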