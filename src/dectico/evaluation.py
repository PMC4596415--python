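"""Verification harness: stability and generality tests, F1, paired t-test.

The stability test repeatedly draws random training subsets, runs the
full selection pipeline on each, and reports the spread (sample standard
deviation) of the optimal rounds' LOOCV accuracies: a stable algorithm
yields similar classifiers from different training draws.

The generality test trains a single classifier on one random training
subset and evaluates it on many random held-out test subsets; since the
test subsets may be class-imbalanced, performance is summarized by the
F1-measure on the positive (diseased) class, and its spread measures how
consistently the classifier generalizes.

Subsets are drawn stratified per class, without replacement, with
per-repeat sub-seeds derived from a master seed, so every report is
exactly reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd
from scipy import stats

from .features import FeatureMatrix
from .kpls import KernelSpec
from .selection import ClassifierSpec, DectICO, SelectionLadder

__all__ = [
    "EvaluationReport",
    "PairedTestResult",
    "f1_measure",
    "paired_t_test",
    "stability_test",
    "generality_test",
]


@dataclass
class EvaluationReport:
    """Per-repeat metric values with mean/std summary and config echo."""

    mode: str  # 'stability' or 'generality'
    values: np.ndarray
    config: dict = field(default_factory=dict)

    @property
    def mean(self) -> float:
        return float(np.mean(self.values))

    @property
    def std(self) -> float:
        # sample (n-1) convention
        return float(np.std(self.values, ddof=1)) if len(self.values) > 1 else 0.0

    @property
    def repeats(self) -> int:
        return len(self.values)

    def to_frame(self) -> pd.DataFrame:
        metric = "loocv_accuracy" if self.mode == "stability" else "f1_measure"
        return pd.DataFrame({"repeat": np.arange(1, self.repeats + 1), metric: self.values})

    def to_tsv(self, path) -> None:
        df = self.to_frame()
        with open(path, "w") as fh:
            df.to_csv(fh, sep="\t", index=False, float_format="%.6f")
            fh.write(f"# mode\t{self.mode}\n")
            fh.write(f"# mean\t{self.mean:.6f}\n")
            fh.write(f"# std\t{self.std:.6f}\n")
            for key, val in self.config.items():
                fh.write(f"# {key}\t{val}\n")


@dataclass
class PairedTestResult:
    """Paired t-test on matched metric values."""

    t: float
    p: float
    n: int

    @property
    def undefined(self) -> bool:
        return bool(np.isnan(self.t))


def f1_measure(
    predicted: Sequence[int], true: Sequence[int], positive: int = 1
) -> float:
    """F1 = 2PR/(P+R) on the positive class.

    Degenerate cases (no predicted positives, no true positives, or
    P + R = 0) return 0 by convention.
    """
    predicted = np.asarray(predicted)
    true = np.asarray(true)
    if predicted.shape != true.shape:
        raise ValueError(
            f"length mismatch: {predicted.shape} predicted vs {true.shape} true"
        )
    tp = int(np.sum((predicted == positive) & (true == positive)))
    fp = int(np.sum((predicted == positive) & (true != positive)))
    fn = int(np.sum((predicted != positive) & (true == positive)))
    if tp + fp == 0 or tp + fn == 0:
        return 0.0
    precision = tp / (tp + fp)
    recall = tp / (tp + fn)
    if precision + recall == 0:
        return 0.0
    return 2 * precision * recall / (precision + recall)


def paired_t_test(values_a: Sequence[float], values_b: Sequence[float]) -> PairedTestResult:
    """Two-sided paired t-test on matched values.

    When the differences have zero spread the statistic is undefined and
    reported as NaN rather than raising.
    """
    a = np.asarray(values_a, dtype=np.float64)
    b = np.asarray(values_b, dtype=np.float64)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("paired test requires equal-length 1-D value vectors")
    if a.size < 2:
        raise ValueError("paired test requires at least 2 pairs")
    diff = a - b
    if np.std(diff, ddof=1) == 0:
        return PairedTestResult(t=float("nan"), p=float("nan"), n=a.size)
    t, p = stats.ttest_rel(a, b)
    return PairedTestResult(t=float(t), p=float(p), n=a.size)


def _stratified_draw(
    labels: np.ndarray,
    n_pos: int,
    n_neg: int,
    rng: np.random.Generator,
    pool: Optional[np.ndarray] = None,
) -> np.ndarray:
    """Indices of a without-replacement stratified draw from the pool."""
    idx = np.arange(labels.size) if pool is None else np.asarray(pool)
    pos = idx[labels[idx] == 1]
    neg = idx[labels[idx] == -1]
    if n_pos > pos.size or n_neg > neg.size:
        raise ValueError(
            f"requested {n_pos}+/{n_neg}- exceeds pool of {pos.size}+/{neg.size}-"
        )
    chosen = np.concatenate(
        [rng.choice(pos, size=n_pos, replace=False), rng.choice(neg, size=n_neg, replace=False)]
    )
    return np.sort(chosen)


def _as_sizes(size: Union[int, tuple[int, int]]) -> tuple[int, int]:
    if isinstance(size, int):
        return size, size
    return int(size[0]), int(size[1])


def _run_pipeline(
    F: FeatureMatrix,
    ladder: Optional[Union[SelectionLadder, Sequence[int]]],
    mode: str,
    classifier: Optional[ClassifierSpec],
    kernel: Optional[KernelSpec],
    n_components: Optional[int],
):
    if ladder is not None and not isinstance(ladder, SelectionLadder):
        ladder = SelectionLadder(tuple(ladder))
    return DectICO(
        F, ladder=ladder, mode=mode, classifier=classifier, kernel=kernel,
        n_components=n_components,
    ).fit()


def stability_test(
    F: FeatureMatrix,
    train_size: Union[int, tuple[int, int]],
    repeats: int = 20,
    seed: int = 0,
    ladder: Optional[Union[SelectionLadder, Sequence[int]]] = None,
    mode: str = "dynamic",
    classifier: Optional[ClassifierSpec] = None,
    kernel: Optional[KernelSpec] = None,
    n_components: Optional[int] = None,
) -> EvaluationReport:
    """Spread of optimal LOOCV accuracies over random training subsets.

    For each of ``repeats`` repeats a stratified training subset
    (``train_size`` per class, or a ``(n_pos, n_neg)`` pair) is drawn
    without replacement, the full selection pipeline is run on it, and
    the optimal round's LOOCV accuracy recorded.
    """
    if F.labels is None:
        raise ValueError("stability test requires labels")
    n_pos, n_neg = _as_sizes(train_size)
    values = np.zeros(repeats)
    for r in range(repeats):
        rng = np.random.default_rng([seed, r])
        rows = _stratified_draw(F.labels, n_pos, n_neg, rng)
        sub = F.subset_rows(rows)
        res = _run_pipeline(sub, ladder, mode, classifier, kernel, n_components)
        values[r] = res.best_accuracy
    return EvaluationReport(
        mode="stability",
        values=values,
        config={
            "train_size": (n_pos, n_neg),
            "repeats": repeats,
            "seed": seed,
            "mode": mode,
        },
    )


def generality_test(
    F: FeatureMatrix,
    train_size: Union[int, tuple[int, int]],
    test_size: Union[int, tuple[int, int]],
    repeats: int = 20,
    seed: int = 0,
    ladder: Optional[Union[SelectionLadder, Sequence[int]]] = None,
    mode: str = "dynamic",
    classifier: Optional[ClassifierSpec] = None,
    kernel: Optional[KernelSpec] = None,
    n_components: Optional[int] = None,
) -> EvaluationReport:
    """Spread of F1-measures of ONE trained classifier over random test sets.

    A single stratified training subset is drawn and the pipeline run
    once; then ``repeats`` stratified test subsets are drawn from the
    remaining samples and the F1-measure on the positive class recorded
    for each.
    """
    if F.labels is None:
        raise ValueError("generality test requires labels")
    n_pos, n_neg = _as_sizes(train_size)
    t_pos, t_neg = _as_sizes(test_size)
    rng = np.random.default_rng([seed, 0])
    train_rows = _stratified_draw(F.labels, n_pos, n_neg, rng)
    res = _run_pipeline(
        F.subset_rows(train_rows), ladder, mode, classifier, kernel, n_components
    )
    remainder = np.setdiff1d(np.arange(F.n_samples), train_rows)
    values = np.zeros(repeats)
    for r in range(repeats):
        sub_rng = np.random.default_rng([seed, r + 1])
        rows = _stratified_draw(F.labels, t_pos, t_neg, sub_rng, pool=remainder)
        test = F.subset_rows(rows)
        pred = res.predict(test)
        values[r] = f1_measure(pred, test.labels, positive=1)
    return EvaluationReport(
        mode="generality",
        values=values,
        config={
            "train_size": (n_pos, n_neg),
            "test_size": (t_pos, t_neg),
            "repeats": repeats,
            "seed": seed,
            "mode": mode,
        },
    )
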