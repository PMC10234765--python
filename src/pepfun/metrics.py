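"""Multi-label evaluation metrics and the subset-resampling model comparison.

Five set-based metrics over true label sets ``L_i`` and predicted sets
``L_i*`` (N samples, M classes)::

    Precision      = mean_i |L_i ∩ L_i*| / |L_i*|      (0 when L_i* is empty)
    Coverage       = mean_i |L_i ∩ L_i*| / |L_i|
    Accuracy       = mean_i |L_i ∩ L_i*| / |L_i ∪ L_i*|
    Absolute true  = mean_i [L_i* == L_i]
    Absolute false = mean_i (|L_i ∪ L_i*| - |L_i ∩ L_i*|) / M

Model comparison follows the subset-resampling protocol: draw five random
80% subsets of the test set, evaluate both models on each, and compare the
per-subset metric vectors with a paired two-sided Student's t-test at a
Bonferroni-corrected significance level.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = [
    "MetricsReport",
    "MetricComparison",
    "ComparisonResult",
    "threshold_predictions",
    "evaluate",
    "make_subsets",
    "bonferroni",
    "compare_models",
]

METRIC_NAMES = ("precision", "coverage", "accuracy", "absolute_true", "absolute_false")


@dataclass(frozen=True)
class MetricsReport:
    precision: float
    coverage: float
    accuracy: float
    absolute_true: float
    absolute_false: float
    n_samples: int

    def as_dict(self) -> dict[str, float]:
        return {name: getattr(self, name) for name in METRIC_NAMES}

    def __str__(self) -> str:
        lines = [f"{name:>15s}: {getattr(self, name):.4f}" for name in METRIC_NAMES]
        lines.append(f"{'n_samples':>15s}: {self.n_samples}")
        return "\n".join(lines)


def threshold_predictions(P, tau: float = 0.5) -> np.ndarray:
    """Binarize probabilities: predict positive iff p >= tau (tie -> positive)."""
    if not (0.0 <= tau <= 1.0):
        raise ValueError(f"threshold must lie in [0, 1], got {tau}")
    P = np.asarray(P, dtype=float)
    if ((P < 0) | (P > 1)).any():
        raise ValueError("probabilities must lie in [0, 1]")
    return (P >= tau).astype(np.int8)


def _check_binary(name: str, A: np.ndarray) -> np.ndarray:
    A = np.asarray(A)
    if A.ndim != 2:
        raise ValueError(f"{name} must be 2-D (N, M)")
    if not np.isin(A, (0, 1)).all():
        raise ValueError(f"{name} must be binary")
    return A.astype(bool)


def evaluate(true_labels, predicted_labels) -> MetricsReport:
    """Compute the five set-based multi-label metrics."""
    T = _check_binary("true_labels", true_labels)
    Pr = _check_binary("predicted_labels", predicted_labels)
    if T.shape != Pr.shape:
        raise ValueError(f"shape mismatch: {T.shape} vs {Pr.shape}")
    if (T.sum(1) == 0).any():
        raise ValueError("every true-label row needs at least one positive")
    N, M = T.shape
    inter = (T & Pr).sum(1)
    union = (T | Pr).sum(1)
    pred_sz = Pr.sum(1)
    with np.errstate(invalid="ignore", divide="ignore"):
        precision = np.where(pred_sz > 0, inter / np.maximum(pred_sz, 1), 0.0)
    coverage = inter / T.sum(1)
    accuracy = inter / union  # union >= |L_i| >= 1
    abs_true = (inter == union).astype(float)
    abs_false = (union - inter) / M
    return MetricsReport(
        precision=float(precision.mean()),
        coverage=float(coverage.mean()),
        accuracy=float(accuracy.mean()),
        absolute_true=float(abs_true.mean()),
        absolute_false=float(abs_false.mean()),
        n_samples=N,
    )


def make_subsets(indices, fraction: float = 0.8, n_subsets: int = 5,
                 seed: int | None = None) -> list[np.ndarray]:
    """Independent random subsets (each without replacement) of the index list."""
    indices = np.asarray(indices)
    if not (0 < fraction <= 1):
        raise ValueError("fraction must lie in (0, 1]")
    size = int(round(fraction * len(indices)))
    if size < 1:
        raise ValueError("fraction * N must be at least 1")
    rng = np.random.default_rng(seed)
    return [rng.choice(indices, size=size, replace=False) for _ in range(n_subsets)]


def bonferroni(family_alpha: float, n_comparisons: int) -> float:
    """Corrected per-test significance level alpha / k."""
    if not (0 < family_alpha < 1):
        raise ValueError("family_alpha must lie in (0, 1)")
    if n_comparisons < 1:
        raise ValueError("n_comparisons must be >= 1")
    return family_alpha / n_comparisons


@dataclass(frozen=True)
class MetricComparison:
    metric: str
    t_statistic: float
    p_value: float
    significant: bool
    degenerate: bool


@dataclass(frozen=True)
class ComparisonResult:
    comparisons: tuple[MetricComparison, ...]
    corrected_alpha: float
    n_subsets: int

    def __str__(self) -> str:
        rows = [f"{'metric':>15s}  {'t':>8s}  {'p':>10s}  significant"]
        for c in self.comparisons:
            flag = "yes" if c.significant else ("degenerate" if c.degenerate else "no")
            rows.append(f"{c.metric:>15s}  {c.t_statistic:8.3f}  {c.p_value:10.3g}  {flag}")
        rows.append(f"corrected alpha = {self.corrected_alpha:g} "
                    f"({self.n_subsets} subsets)")
        return "\n".join(rows)


def compare_models(metric_samples_a: dict[str, np.ndarray],
                   metric_samples_b: dict[str, np.ndarray],
                   family_alpha: float = 0.01,
                   n_comparisons: int = 5) -> ComparisonResult:
    """Paired two-sided t-tests per metric at a Bonferroni-corrected level.

    Both models must have been evaluated on the same subsets, so the per-
    subset values are paired. Zero-variance differences are reported with
    p = 1 and a degenerate flag rather than a spurious infinity.
    """
    alpha = bonferroni(family_alpha, n_comparisons)
    comps = []
    n_subsets = None
    for metric in metric_samples_a:
        a = np.asarray(metric_samples_a[metric], dtype=float)
        b = np.asarray(metric_samples_b[metric], dtype=float)
        if a.shape != b.shape or a.ndim != 1 or len(a) < 2:
            raise ValueError(f"metric {metric!r}: need equal-length paired samples >= 2")
        n_subsets = len(a)
        diff = a - b
        if np.allclose(diff.std(ddof=1), 0.0):
            comps.append(MetricComparison(metric, t_statistic=0.0, p_value=1.0,
                                          significant=False, degenerate=True))
            continue
        t, p = stats.ttest_rel(a, b)
        comps.append(MetricComparison(metric, float(t), float(p),
                                      significant=bool(p < alpha), degenerate=False))
    return ComparisonResult(tuple(comps), corrected_alpha=alpha,
                            n_subsets=n_subsets or 0)
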