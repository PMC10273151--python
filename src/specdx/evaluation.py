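"""ROC/AUC analysis, Youden cutoffs, diagnostic metrics, bootstrap CIs.

Empirical ROC curves group tied scores into a single step (trapezoid
tie credit), which makes the trapezoidal AUC identical to the
Mann-Whitney statistic U/(n_pos * n_neg) with half credit for ties.
Confidence intervals are specimen-level percentile bootstrap: the
resampling unit is the specimen, never the individual spectrum, because
spectra within a specimen are strongly correlated.
"""

from __future__ import annotations

import dataclasses
from typing import Callable, Sequence

import numpy as np
import pandas as pd
import sklearn.metrics

__all__ = [
    "ROCCurve",
    "DiagnosticMetrics",
    "roc_curve",
    "auc",
    "youden_index",
    "youden_cutoffs",
    "diagnostic_metrics",
    "bootstrap_ci",
    "plot_roc",
]


@dataclasses.dataclass(frozen=True)
class ROCCurve:
    """Ordered (cutoff, TPR, FPR) triples from (0, 0) to (1, 1).

    Cutoffs are decreasing; the first entry is an unattainable cutoff
    above the largest score, giving the (0, 0) corner.
    """

    cutoffs: np.ndarray
    tpr: np.ndarray
    fpr: np.ndarray
    n_pos: int
    n_neg: int


def roc_curve(scores: Sequence[float], labels: Sequence[int]) -> ROCCurve:
    """Empirical ROC over all distinct score cutoffs (ties grouped)."""
    y = np.asarray(labels, dtype=int)
    s = np.asarray(scores, dtype=float)
    n_pos = int((y == 1).sum())
    n_neg = int((y == 0).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("ROC needs at least one positive and one negative label")
    fpr, tpr, cutoffs = sklearn.metrics.roc_curve(y, s, drop_intermediate=False)
    return ROCCurve(cutoffs=cutoffs, tpr=tpr, fpr=fpr, n_pos=n_pos, n_neg=n_neg)


def auc(curve: ROCCurve) -> float:
    """Trapezoidal area under the ROC curve (= Mann-Whitney U/(n1*n0))."""
    return float(np.trapezoid(curve.tpr, curve.fpr))


def youden_index(sensitivity: float, specificity: float) -> float:
    return sensitivity + specificity - 1.0


def youden_cutoffs(curve: ROCCurve) -> pd.DataFrame:
    """All operating points ranked by Youden's J (descending).

    Ties in J break toward higher sensitivity, then lower cutoff.  The
    synthetic (0, 0) corner at the unattainable top cutoff is dropped.
    """
    df = pd.DataFrame(
        {
            "cutoff": curve.cutoffs,
            "sensitivity": curve.tpr,
            "specificity": 1.0 - curve.fpr,
        }
    ).iloc[1:]
    df["youden_j"] = df["sensitivity"] + df["specificity"] - 1.0
    df = df.sort_values(
        ["youden_j", "sensitivity", "cutoff"], ascending=[False, False, True]
    ).reset_index(drop=True)
    return df


@dataclasses.dataclass
class DiagnosticMetrics:
    """Confusion counts and the derived diagnostic metrics (fractions).

    ``ppv``/``npv`` are None (and flagged) when no positive/negative
    calls were made, rather than propagating NaN.
    """

    tp: int
    fp: int
    fn: int
    tn: int
    accuracy: float
    sensitivity: float | None
    specificity: float | None
    ppv: float | None
    npv: float | None
    undefined: frozenset[str]
    ci: dict[str, tuple[float, float]] = dataclasses.field(default_factory=dict)

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.fn + self.tn

    def as_percentages(self, ndigits: int = 2) -> dict[str, float | None]:
        def pct(v):
            return None if v is None else round(100.0 * v, ndigits)

        return {
            "accuracy": pct(self.accuracy),
            "sensitivity": pct(self.sensitivity),
            "specificity": pct(self.specificity),
            "ppv": pct(self.ppv),
            "npv": pct(self.npv),
        }


def diagnostic_metrics(calls: Sequence, labels: Sequence) -> DiagnosticMetrics:
    """Accuracy / sensitivity / specificity / PPV / NPV from paired calls.

    ``calls`` and ``labels`` are equal-length binary vectors (any values
    comparable for equality; the positive class is whatever ``1``, True
    or ``"IAC"``-like value matches between them).  Here we canonicalise
    via truthiness of equality with the positive label "IAC"/1/True.
    """
    c = _binarize(calls)
    y = _binarize(labels)
    if len(c) != len(y):
        raise ValueError("calls and labels must have equal length")
    if len(c) == 0:
        raise ValueError("cannot compute metrics from empty input")
    tp = int(np.sum((c == 1) & (y == 1)))
    fp = int(np.sum((c == 1) & (y == 0)))
    fn = int(np.sum((c == 0) & (y == 1)))
    tn = int(np.sum((c == 0) & (y == 0)))
    undefined: set[str] = set()

    def ratio(num: int, den: int, name: str) -> float | None:
        if den == 0:
            undefined.add(name)
            return None
        return num / den

    return DiagnosticMetrics(
        tp=tp,
        fp=fp,
        fn=fn,
        tn=tn,
        accuracy=(tp + tn) / len(c),
        sensitivity=ratio(tp, tp + fn, "sensitivity"),
        specificity=ratio(tn, tn + fp, "specificity"),
        ppv=ratio(tp, tp + fp, "ppv"),
        npv=ratio(tn, tn + fn, "npv"),
        undefined=frozenset(undefined),
    )


def _binarize(values: Sequence) -> np.ndarray:
    out = []
    for v in values:
        sv = getattr(v, "value", v)
        if sv in (1, True, "IAC", "1"):
            out.append(1)
        elif sv in (0, False, "NON_IAC", "0"):
            out.append(0)
        else:
            raise ValueError(f"cannot binarize value {v!r}")
    return np.array(out, dtype=int)


def bootstrap_ci(
    statistic: Callable[[np.ndarray], float | None],
    n_units: int,
    b: int = 2000,
    seed: int = 0,
    level: float = 0.95,
    max_redraws: int = 100,
) -> tuple[float, float, int]:
    """Percentile bootstrap CI over resampled units (specimens).

    ``statistic(indices)`` evaluates the metric on a resample given unit
    indices (with repetition) and may return None for a degenerate
    resample (e.g. single-class); degenerate resamples are redrawn and
    counted.  Returns (low, high, n_redrawn).
    """
    if b < 100:
        raise ValueError("bootstrap needs at least 100 resamples")
    rng = np.random.default_rng(seed)
    values = np.empty(b)
    redrawn = 0
    for i in range(b):
        for _ in range(max_redraws):
            idx = rng.integers(0, n_units, size=n_units)
            v = statistic(idx)
            if v is not None:
                values[i] = v
                break
            redrawn += 1
        else:
            raise RuntimeError("bootstrap: too many degenerate resamples")
    alpha = (1.0 - level) / 2.0
    lo, hi = np.quantile(values, [alpha, 1.0 - alpha])
    return float(lo), float(hi), redrawn


def plot_roc(curves: dict[str, ROCCurve], path: str) -> None:
    """Write a ROC plot (one line per named curve) to an image file."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 5))
    for name, curve in curves.items():
        ax.plot(curve.fpr, curve.tpr, label=f"{name} (AUC {auc(curve):.3f})")
    ax.plot([0, 1], [0, 1], "k:", lw=0.8)
    ax.set_xlabel("1 - specificity")
    ax.set_ylabel("sensitivity")
    ax.legend(loc="lower right")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
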