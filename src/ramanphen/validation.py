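"""Leave-one-out DAPC validation with random-chance baselines.

Every spectrum is held out in turn; PCA and DAPC are refit on the
remainder (no leakage) and the held-out spectrum is classified.  The
tally is summarised per class one-vs-rest — sensitivity (true-positive
rate), specificity (true-negative rate) and binary accuracy — plus the
overall multiclass accuracy.  A model is only informative if it beats
the random-chance values of a predictor drawing one of the k observed
classes uniformly at random: sensitivity 100/k %, specificity
100(1 - 1/k) %, and one-vs-rest accuracy 100[p/k + (1-p)(1-1/k)] % for a
class of prevalence p.
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np
import pandas as pd

from .chemometrics import fit_dapc, fit_pca, predict
from .spectra_io import SpectrumSet

__all__ = [
    "ValidationReport",
    "loo_validate",
    "random_chance_baseline",
    "monte_carlo_chance",
    "pc_sweep",
]


@dataclasses.dataclass
class ValidationReport:
    """Confusion matrix and derived per-class metrics for one model size.

    ``confusion`` rows are truth, columns predictions, both in
    ``class_labels`` order.  ``per_class`` has columns class, accuracy,
    sensitivity, specificity (percent); ``random_chance`` mirrors it for
    the uniform random predictor.
    """

    class_labels: list
    confusion: np.ndarray
    per_class: pd.DataFrame
    overall_accuracy: float
    random_chance: pd.DataFrame
    n_pcs: int
    variance_captured: float

    def __post_init__(self) -> None:
        if np.any(self.confusion < 0):
            raise ValueError("confusion counts must be nonnegative")
        if int(np.trace(self.confusion)) != round(
            self.overall_accuracy / 100.0 * self.confusion.sum()
        ):
            raise ValueError("overall accuracy inconsistent with confusion trace")

    def to_dict(self) -> dict:
        return {
            "class_labels": [str(c) for c in self.class_labels],
            "confusion": self.confusion.tolist(),
            "per_class": self.per_class.to_dict(orient="records"),
            "overall_accuracy": self.overall_accuracy,
            "random_chance": self.random_chance.to_dict(orient="records"),
            "n_pcs": self.n_pcs,
            "variance_captured": self.variance_captured,
        }

    def summary(self) -> str:
        """Human-readable validation-summary table (percent, one decimal)."""
        lines = [
            f"DAPC leave-one-out validation  (n_pcs={self.n_pcs}, "
            f"variance captured {100 * self.variance_captured:.1f}%)",
            f"overall accuracy: {self.overall_accuracy:.1f}%",
            f"{'class':>20} {'accuracy':>9} {'sensitivity':>12} {'specificity':>12}",
        ]
        for _, r in self.per_class.iterrows():
            lines.append(
                f"{str(r['class']):>20} {r['accuracy']:>8.1f}% "
                f"{r['sensitivity']:>11.1f}% {r['specificity']:>11.1f}%"
            )
        rc = self.random_chance.iloc[0]
        lines.append(
            f"{'random chance':>20} {rc['accuracy']:>8.1f}% "
            f"{rc['sensitivity']:>11.1f}% {rc['specificity']:>11.1f}%"
        )
        return "\n".join(lines)


def _metrics_from_confusion(classes: list, confusion: np.ndarray) -> tuple[pd.DataFrame, float]:
    total = confusion.sum()
    rows = []
    for i, c in enumerate(classes):
        tp = confusion[i, i]
        fn = confusion[i].sum() - tp
        fp = confusion[:, i].sum() - tp
        tn = total - tp - fn - fp
        sens = 100.0 * tp / (tp + fn) if tp + fn else np.nan
        spec = 100.0 * tn / (tn + fp) if tn + fp else np.nan
        acc = 100.0 * (tp + tn) / total
        rows.append({"class": c, "accuracy": acc, "sensitivity": sens, "specificity": spec})
    overall = 100.0 * np.trace(confusion) / total
    return pd.DataFrame(rows), overall


def _resolve_labels(sset: SpectrumSet, labels) -> np.ndarray:
    if isinstance(labels, str):
        return np.asarray([str(v) for v in sset.factor_values(labels)], dtype=object)
    labels = np.asarray(labels, dtype=object)
    if labels.size != len(sset):
        raise ValueError("one label per spectrum required")
    return labels


def loo_validate(sset: SpectrumSet, labels, n_pcs: int) -> ValidationReport:
    """Leave-one-out validation of a DAPC model with ``n_pcs`` retained PCs.

    ``labels`` is either a metadata column name or one class label per
    spectrum.  PCA is refit inside every fold; every class must keep at
    least 2 members after the hold-out.
    """
    y = _resolve_labels(sset, labels)
    classes = sorted(pd.unique(y).tolist())
    counts = pd.Series(y).value_counts()
    if (counts < 2).any():
        bad = counts[counts < 2].index[0]
        raise ValueError(f"class {bad!r} has fewer than 2 members")
    n = len(sset)
    if n_pcs > n - 2:
        raise ValueError(f"n_pcs={n_pcs} infeasible with {n - 1} training spectra per fold")
    idx_by_class = {c: i for i, c in enumerate(classes)}
    confusion = np.zeros((len(classes), len(classes)), dtype=int)
    all_idx = np.arange(n)
    for held in range(n):
        train = all_idx[all_idx != held]
        sub = sset.subset(train)
        pca = fit_pca(sub)
        dapc = fit_dapc(pca, y[train], n_pcs)
        pred = predict(dapc, pca, sset.spectra[held])
        confusion[idx_by_class[y[held]], idx_by_class[pred]] += 1
    per_class, overall = _metrics_from_confusion(classes, confusion)
    full_pca = fit_pca(sset)
    variance = float(np.sum(full_pca.explained_variance_ratio[:n_pcs]))
    return ValidationReport(
        class_labels=classes,
        confusion=confusion,
        per_class=per_class,
        overall_accuracy=overall,
        random_chance=random_chance_baseline(y),
        n_pcs=n_pcs,
        variance_captured=variance,
    )


def random_chance_baseline(labels: Sequence) -> pd.DataFrame:
    """Closed-form expected metrics of a uniform random predictor.

    For k observed classes, evaluated one-vs-rest per class: sensitivity
    = 100/k, specificity = 100(1 - 1/k), and binary accuracy
    = 100[p/k + (1 - p)(1 - 1/k)] where p is the class prevalence.
    """
    y = np.asarray(labels, dtype=object)
    classes = sorted(pd.unique(y).tolist())
    k = len(classes)
    if k < 2:
        raise ValueError("random-chance metrics need at least 2 classes")
    n = y.size
    rows = []
    for c in classes:
        p = np.count_nonzero(y == c) / n
        rows.append(
            {
                "class": c,
                "accuracy": 100.0 * (p / k + (1.0 - p) * (1.0 - 1.0 / k)),
                "sensitivity": 100.0 / k,
                "specificity": 100.0 * (1.0 - 1.0 / k),
            }
        )
    return pd.DataFrame(rows)


def monte_carlo_chance(labels: Sequence, n_draws: int = 100_000, seed: int = 0) -> pd.DataFrame:
    """Monte-Carlo estimate of the random-chance metrics (cross-check).

    Draws ``n_draws`` full prediction vectors uniformly over the observed
    classes and averages the one-vs-rest metrics.
    """
    y = np.asarray(labels, dtype=object)
    classes = sorted(pd.unique(y).tolist())
    k = len(classes)
    if k < 2:
        raise ValueError("random-chance metrics need at least 2 classes")
    rng = np.random.default_rng(seed)
    n = y.size
    y_idx = np.asarray([classes.index(v) for v in y])
    preds = rng.integers(0, k, size=(n_draws, n))
    rows = []
    for i, c in enumerate(classes):
        truth_pos = y_idx == i
        pred_pos = preds == i
        tp = (pred_pos[:, truth_pos]).sum(axis=1)
        fn = truth_pos.sum() - tp
        fp = (pred_pos[:, ~truth_pos]).sum(axis=1)
        tn = (~truth_pos).sum() - fp
        sens = 100.0 * tp / np.maximum(tp + fn, 1)
        spec = 100.0 * tn / np.maximum(tn + fp, 1)
        acc = 100.0 * (tp + tn) / n
        rows.append(
            {
                "class": c,
                "accuracy": float(acc.mean()),
                "sensitivity": float(sens.mean()),
                "specificity": float(spec.mean()),
            }
        )
    return pd.DataFrame(rows)


def pc_sweep(sset: SpectrumSet, labels, pc_grid: Sequence[int]) -> tuple[list[ValidationReport], int]:
    """One leave-one-out report per retained-PC count.

    Returns ``(reports, best_index)``; the best performer maximises
    overall accuracy, ties broken toward fewer PCs.
    """
    pc_grid = list(pc_grid)
    if not pc_grid:
        raise ValueError("empty pc_grid")
    reports = [loo_validate(sset, labels, n) for n in pc_grid]
    accs = np.asarray([r.overall_accuracy for r in reports])
    order = sorted(range(len(pc_grid)), key=lambda i: (-accs[i], pc_grid[i]))
    return reports, order[0]
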