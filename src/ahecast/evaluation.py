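"""Discrimination metrics with bootstrap uncertainty.

AUROC is the Mann-Whitney probability that a randomly chosen positive
window outscores a randomly chosen negative one (ties count half).
Confidence intervals are percentile bootstrap over windows by default, with
a cluster (by-patient) variant available since windows from one patient are
dependent. Sensitivity, specificity and PPV are reported at an operating
threshold (default 0.5); PPV is NaN, not zero, when nothing is predicted
positive. The per-patient classification rate is the fraction of a
patient's windows correctly classified at the threshold.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np
from scipy.stats import rankdata
from sklearn.metrics import roc_curve


def auroc(scores: np.ndarray, labels: np.ndarray) -> float:
    """Probability a random positive outscores a random negative (ties half).

    Computed through the rank-sum (Mann-Whitney) identity
    ``AUC = (R_pos - n_pos(n_pos+1)/2) / (n_pos n_neg)`` with average ranks,
    so tied scores count half.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(bool)
    n_pos = int(labels.sum())
    n_neg = int(len(labels) - n_pos)
    if n_pos == 0 or n_neg == 0:
        raise ValueError("AUROC needs both classes present")
    ranks = rankdata(scores)
    r_pos = ranks[labels].sum()
    return float((r_pos - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg))


def bootstrap_ci(
    scores: np.ndarray,
    labels: np.ndarray,
    metric: Callable[[np.ndarray, np.ndarray], float] = auroc,
    n_boot: int = 1000,
    alpha: float = 0.05,
    seed: int = 0,
    patient_ids: np.ndarray | None = None,
) -> tuple[float, float]:
    """Percentile bootstrap interval for ``metric``.

    Resamples windows with replacement (or whole patients when
    ``patient_ids`` is given); resamples lacking a class are redrawn.
    Deterministic given the seed.
    """
    if n_boot < 100:
        raise ValueError("n_boot must be >= 100")
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    if len(np.unique(labels)) < 2:
        raise ValueError("bootstrap needs both classes present")
    rng = np.random.default_rng(seed)
    n = len(scores)
    values = np.empty(n_boot)
    max_redraws = 1000
    for b in range(n_boot):
        for attempt in range(max_redraws):
            if patient_ids is None:
                idx = rng.integers(0, n, size=n)
            else:
                unique = np.unique(patient_ids)
                chosen = rng.choice(unique, size=len(unique), replace=True)
                idx = np.concatenate(
                    [np.flatnonzero(patient_ids == pid) for pid in chosen]
                )
            if len(np.unique(labels[idx])) == 2:
                break
        else:
            raise ValueError("metric undefined on all bootstrap resamples")
        values[b] = metric(scores[idx], labels[idx])
    lo, hi = np.quantile(values, [alpha / 2.0, 1.0 - alpha / 2.0])
    return float(lo), float(hi)


def confusion_metrics(
    scores: np.ndarray, labels: np.ndarray, threshold: float = 0.5
) -> tuple[float, float, float]:
    """(sensitivity, specificity, ppv) at a threshold; undefined PPV is NaN."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(bool)
    if labels.all() or not labels.any():
        raise ValueError("confusion metrics need both classes present")
    pred = scores >= threshold
    tp = int((pred & labels).sum())
    fn = int((~pred & labels).sum())
    tn = int((~pred & ~labels).sum())
    fp = int((pred & ~labels).sum())
    sens = tp / (tp + fn)
    spec = tn / (tn + fp)
    ppv = tp / (tp + fp) if (tp + fp) > 0 else float("nan")
    return sens, spec, ppv


def per_patient_rates(
    scores: np.ndarray,
    labels: np.ndarray,
    patient_ids: np.ndarray,
    threshold: float = 0.5,
    cutoffs: tuple[float, ...] = (0.85, 0.90),
) -> tuple[dict[str, float], dict[float, int]]:
    """Fraction of each patient's windows correctly classified at the
    threshold, plus the number of patients at or above each rate cutoff."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(int)
    patient_ids = np.asarray(patient_ids)
    correct = (scores >= threshold).astype(int) == labels
    rates: dict[str, float] = {}
    for pid in np.unique(patient_ids):
        sel = patient_ids == pid
        rates[str(pid)] = float(correct[sel].mean())
    counts = {
        c: int(sum(rate >= c for rate in rates.values())) for c in cutoffs
    }
    return rates, counts


@dataclass
class EvalReport:
    """Full discrimination report for one model on one test set."""

    auroc: float
    ci95: tuple[float, float]
    roc_points: np.ndarray  # [k, 2] (fpr, tpr)
    sensitivity: float
    specificity: float
    ppv: float
    threshold: float
    n_pos: int
    n_neg: int
    per_patient: dict[str, float] = field(default_factory=dict)
    patients_at_cutoff: dict[float, int] = field(default_factory=dict)


def evaluate(
    scores: np.ndarray,
    labels: np.ndarray,
    patient_ids: np.ndarray | None = None,
    threshold: float = 0.5,
    n_boot: int = 1000,
    seed: int = 0,
) -> EvalReport:
    """Compute the full report (AUROC + bootstrap CI, ROC, threshold metrics)."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(int)
    fpr, tpr, _ = roc_curve(labels, scores)
    sens, spec, ppv = confusion_metrics(scores, labels, threshold)
    rates: dict[str, float] = {}
    counts: dict[float, int] = {}
    if patient_ids is not None:
        rates, counts = per_patient_rates(scores, labels, patient_ids, threshold)
    return EvalReport(
        auroc=auroc(scores, labels),
        ci95=bootstrap_ci(scores, labels, n_boot=n_boot, seed=seed),
        roc_points=np.column_stack([fpr, tpr]),
        sensitivity=sens,
        specificity=spec,
        ppv=ppv,
        threshold=threshold,
        n_pos=int(labels.sum()),
        n_neg=int(len(labels) - labels.sum()),
        per_patient=rates,
        patients_at_cutoff=counts,
    )


def plot_roc(report: EvalReport, path: str, title: str = "ROC") -> None:
    """Save a ROC curve figure."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(4, 4))
    ax.plot(report.roc_points[:, 0], report.roc_points[:, 1])
    ax.plot([0, 1], [0, 1], ls="--", color="grey")
    ax.set_xlabel("False positive rate")
    ax.set_ylabel("True positive rate")
    ax.set_title(f"{title} (AUROC {report.auroc:.3f})")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_grid_heatmap(results, value_col: str, path: str, title: str = "") -> None:
    """Save an observation-by-gap heatmap from a grid-results DataFrame."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    pivot = results.pivot(index="obs", columns="gap", values=value_col)
    fig, ax = plt.subplots(figsize=(5, 4))
    im = ax.imshow(pivot.to_numpy(), cmap="viridis", aspect="auto")
    ax.set_xticks(range(len(pivot.columns)), pivot.columns)
    ax.set_yticks(range(len(pivot.index)), pivot.index)
    ax.set_xlabel("Gap length (min)")
    ax.set_ylabel("Observation length (min)")
    ax.set_title(title)
    fig.colorbar(im, ax=ax, label=value_col)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
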