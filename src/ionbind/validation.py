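"""Balanced resampling, split protocols and evaluation metrics.

Negative segments vastly outnumber positives, so training sets are
balanced by undersampling: all positives plus an equal-size uniform
random sample of negatives, drawn independently 10 times; reported
metrics are arithmetic means over the repeats.  Model selection uses
segment-level 5-fold cross-validation inside each balanced set; the
independent test assigns whole chains 80/20 so no chain contributes
segments to both sides.

Metrics are sensitivity, specificity and accuracy as percentages and
the Matthews correlation coefficient

    MCC = (TP*TN - FP*FN) / sqrt((TP+FP)(TP+FN)(TN+FP)(TN+FN))

with MCC defined as 0 when any denominator factor vanishes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal, Sequence

import numpy as np
from sklearn.model_selection import KFold, StratifiedKFold


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.tn, self.fp, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn

    def __add__(self, other: "ConfusionCounts") -> "ConfusionCounts":
        return ConfusionCounts(
            self.tp + other.tp, self.tn + other.tn,
            self.fp + other.fp, self.fn + other.fn,
        )

    @staticmethod
    def from_labels(y_true: np.ndarray, y_pred: np.ndarray) -> "ConfusionCounts":
        t = np.asarray(y_true, dtype=bool)
        p = np.asarray(y_pred, dtype=bool)
        if t.shape != p.shape:
            raise ValueError("label vectors differ in length")
        return ConfusionCounts(
            tp=int((t & p).sum()), tn=int((~t & ~p).sum()),
            fp=int((~t & p).sum()), fn=int((t & ~p).sum()),
        )


@dataclass
class EvaluationResult:
    """Sn/Sp/Acc (percent), MCC, and the counts they derive from.

    For multi-repeat protocols, the top-level values are arithmetic
    means over ``per_repeat`` and ``counts`` is the sum of counts.
    """

    sn: float
    sp: float
    acc: float
    mcc: float
    counts: ConfusionCounts
    n_repeats: int = 1
    per_repeat: list["EvaluationResult"] = field(default_factory=list)


def metrics(counts: ConfusionCounts) -> EvaluationResult:
    """Single-evaluation metrics from confusion counts."""
    tp, tn, fp, fn = counts.tp, counts.tn, counts.fp, counts.fn
    if counts.total == 0:
        raise ValueError("cannot compute metrics from all-zero counts")
    sn = 100.0 * tp / (tp + fn) if tp + fn else 0.0
    sp = 100.0 * tn / (tn + fp) if tn + fp else 0.0
    acc = 100.0 * (tp + tn) / counts.total
    denom = (
        float(tp + fp) * float(tp + fn) * float(tn + fp) * float(tn + fn)
    )
    mcc = 0.0 if denom == 0 else (tp * tn - fp * fn) / math.sqrt(denom)
    return EvaluationResult(sn=sn, sp=sp, acc=acc, mcc=mcc, counts=counts)


def average_results(results: Sequence[EvaluationResult]) -> EvaluationResult:
    """Arithmetic mean of metric values; counts are summed for audit."""
    if not results:
        raise ValueError("no results to average")
    counts = results[0].counts
    for r in results[1:]:
        counts = counts + r.counts
    return EvaluationResult(
        sn=float(np.mean([r.sn for r in results])),
        sp=float(np.mean([r.sp for r in results])),
        acc=float(np.mean([r.acc for r in results])),
        mcc=float(np.mean([r.mcc for r in results])),
        counts=counts,
        n_repeats=len(results),
        per_repeat=list(results),
    )


# ---------------------------------------------------------------------------
# Balancing

def balance(pos: Sequence, neg: Sequence, seed: int) -> list:
    """All positives plus an equal-size random sample of negatives."""
    if len(neg) < len(pos):
        raise ValueError(
            f"{len(neg)} negatives < {len(pos)} positives; undersampling assumes "
            "a negative majority"
        )
    rng = np.random.default_rng(seed)
    idx = rng.choice(len(neg), size=len(pos), replace=False)
    return list(pos) + [neg[i] for i in idx]


def repeat_balanced(
    pos: Sequence, neg: Sequence, n_rep: int = 10, base_seed: int = 0
) -> list[list]:
    """n_rep independent balanced sets with seeds base_seed + r."""
    if n_rep < 1:
        raise ValueError("n_rep must be >= 1")
    return [balance(pos, neg, base_seed + r) for r in range(n_rep)]


# ---------------------------------------------------------------------------
# Split plans

@dataclass
class SplitPlan:
    kind: Literal["kfold", "chain_independent"]
    seed: int
    k: int | None = None
    train_fraction: float | None = None
    folds: list[np.ndarray] | None = None        # kfold: test indices per fold
    train_chains: set[str] | None = None
    test_chains: set[str] | None = None


def kfold(
    n: int,
    k: int = 5,
    seed: int = 0,
    labels: Sequence[bool] | None = None,
) -> SplitPlan:
    """Random partition of n items into k folds of near-equal size.

    Pass ``labels`` for a stratified partition; the default is the plain
    random partition.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    if n < k:
        raise ValueError(f"cannot split {n} items into {k} folds")
    if labels is None:
        splitter = KFold(n_splits=k, shuffle=True, random_state=seed)
        folds = [test for _, test in splitter.split(np.zeros(n))]
    else:
        splitter = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
        folds = [test for _, test in splitter.split(np.zeros(n), np.asarray(labels))]
    return SplitPlan(kind="kfold", seed=seed, k=k, folds=folds)


def chain_split(
    chain_ids: Sequence[str],
    train_fraction: float = 0.8,
    seed: int = 0,
) -> SplitPlan:
    """Assign whole chains to train/test with round(train_fraction * n) in train."""
    ids = list(chain_ids)
    if len(ids) < 2:
        raise ValueError("need at least two chains for an independent split")
    if not 0.0 < train_fraction < 1.0:
        raise ValueError("train_fraction must be in (0, 1)")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(ids))
    n_train = int(round(train_fraction * len(ids)))
    n_train = min(max(n_train, 1), len(ids) - 1)
    train = {ids[i] for i in order[:n_train]}
    test = {ids[i] for i in order[n_train:]}
    return SplitPlan(
        kind="chain_independent", seed=seed, train_fraction=train_fraction,
        train_chains=train, test_chains=test,
    )


def write_report(
    rows: Iterable[tuple[str, str, EvaluationResult]], path: str | Path
) -> None:
    """Write (ligand, model, result) rows as a tab-separated report."""
    with Path(path).open("w") as fh:
        fh.write("#ligand\tmodel\tSn\tSp\tAcc\tMCC\tn_repeats\n")
        for ligand, model, r in rows:
            fh.write(
                f"{ligand}\t{model}\t{r.sn:.1f}\t{r.sp:.1f}\t{r.acc:.1f}\t"
                f"{r.mcc:.3f}\t{r.n_repeats}\n"
            )
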