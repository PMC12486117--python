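"""Splitting protocols and the evaluation metric suite.

Two protocols: a stratified patient-level 70/15/15 split and a site-held-out
split that reserves every patient from one acquisition site for testing.
Metrics: accuracy, precision, recall, F1 from the thresholded confusion
table; AUC by the Mann-Whitney pair-counting estimator (identical to the
trapezoidal ROC integral); ECE by hard equal-width binning of the top-label
confidence max(p, 1-p) over [0.5, 1].
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np


# --------------------------------------------------------------------------
# splits
# --------------------------------------------------------------------------


@dataclass
class SplitIndices:
    train: list[str]
    val: list[str]
    test: list[str]
    kind: str  # patient_level | site_held_out
    seed: int
    held_site: str | None = None

    def __post_init__(self) -> None:
        sets = [set(self.train), set(self.val), set(self.test)]
        for i in range(3):
            for j in range(i + 1, 3):
                if sets[i] & sets[j]:
                    raise ValueError("splits must be pairwise disjoint")

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, path) -> "SplitIndices":
        with open(path) as fh:
            return cls(**json.load(fh))


def _largest_remainder(total: int, fractions: Sequence[float]) -> list[int]:
    raw = [total * f for f in fractions]
    base = [int(np.floor(x)) for x in raw]
    short = total - sum(base)
    order = np.argsort([-(x - b) for x, b in zip(raw, base)], kind="stable")
    for i in range(short):
        base[order[i]] += 1
    return base


def patient_split(
    patient_ids: Sequence[str],
    labels: Sequence[int],
    fractions: tuple[float, float, float] = (0.70, 0.15, 0.15),
    stratified: bool = True,
    seed: int = 0,
) -> SplitIndices:
    """Stratified train/val/test assignment with largest-remainder rounding.

    Per-stratum quotas are rounded first; a repair pass then moves single
    patients between splits so the global sizes match the largest-remainder
    rounding of n * fractions exactly.
    """
    ids = list(patient_ids)
    labels = np.asarray(labels, dtype=int)
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise ValueError("fractions must sum to 1")
    if len(ids) < 10:
        raise ValueError("need at least 10 patients to split")
    rng = np.random.default_rng(seed)
    if stratified:
        strata = [np.flatnonzero(labels == 0), np.flatnonzero(labels == 1)]
        for v, s in zip((0, 1), strata):
            if s.size < 3:
                raise ValueError(f"label stratum {v} has fewer than 3 patients")
    else:
        strata = [np.arange(len(ids))]

    global_quota = _largest_remainder(len(ids), fractions)
    quotas = [_largest_remainder(s.size, fractions) for s in strata]
    # repair: align per-split totals with the global quota one move at a time
    for split_idx in range(3):
        while sum(q[split_idx] for q in quotas) > global_quota[split_idx]:
            deficit = next(
                j for j in range(3) if sum(q[j] for q in quotas) < global_quota[j]
            )
            donor = max(range(len(quotas)), key=lambda s: quotas[s][split_idx])
            quotas[donor][split_idx] -= 1
            quotas[donor][deficit] += 1

    parts: list[list[str]] = [[], [], []]
    for s, quota in zip(strata, quotas):
        perm = rng.permutation(s)
        start = 0
        for j, q in enumerate(quota):
            parts[j].extend(ids[i] for i in perm[start : start + q])
            start += q
    return SplitIndices(train=parts[0], val=parts[1], test=parts[2], kind="patient_level", seed=seed)


def site_holdout_split(
    patient_ids: Sequence[str],
    labels: Sequence[int],
    site_ids: Sequence[str],
    held_site: str,
    val_fraction: float = 0.1765,  # 15/85: same val share as the patient-level split
    seed: int = 0,
) -> SplitIndices:
    """Hold an entire site out for testing; split the rest train/val."""
    ids = list(patient_ids)
    labels = np.asarray(labels, dtype=int)
    sites = list(site_ids)
    if held_site not in set(sites):
        raise ValueError(f"held_site {held_site!r} not present in the cohort")
    if len(set(sites)) < 2:
        raise ValueError("site holdout needs at least 2 sites")
    test = [pid for pid, s in zip(ids, sites) if s == held_site]
    rest = [i for i, s in enumerate(sites) if s != held_site]
    rng = np.random.default_rng(seed)
    parts: list[list[str]] = [[], []]
    for v in (0, 1):
        stratum = [i for i in rest if labels[i] == v]
        perm = rng.permutation(len(stratum))
        n_val = int(round(val_fraction * len(stratum)))
        for r, j in enumerate(perm):
            parts[1 if r < n_val else 0].append(ids[stratum[j]])
    return SplitIndices(
        train=parts[0], val=parts[1], test=test, kind="site_held_out", seed=seed, held_site=held_site
    )


# --------------------------------------------------------------------------
# metrics
# --------------------------------------------------------------------------


@dataclass
class MetricsReport:
    acc: float
    precision: float
    recall: float
    f1: float
    auc: float
    ece: float
    threshold: float
    tp: int
    tn: int
    fp: int
    fn: int
    degenerate: bool  # a zero-denominator precision/recall was defined as 0
    bins: list[dict] = field(default_factory=list)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2, sort_keys=True)


def _confidence_bins(p: np.ndarray, correct: np.ndarray, M: int) -> list[dict]:
    """Right-closed equal-width bins of confidence max(p, 1-p) over [0.5, 1]."""
    conf = np.maximum(p, 1.0 - p)
    w = 0.5 / M
    idx = np.clip(np.ceil((conf - 0.5) / w).astype(int) - 1, 0, M - 1)
    bins = []
    for m in range(M):
        member = idx == m
        bins.append(
            {
                "lo": 0.5 + m * w,
                "hi": 0.5 + (m + 1) * w,
                "count": int(member.sum()),
                "accuracy": float(correct[member].mean()) if member.any() else None,
                "confidence": float(conf[member].mean()) if member.any() else None,
            }
        )
    return bins


def expected_calibration_error(p: Sequence[float], y: Sequence[int], M: int = 10) -> float:
    """Hard-binned ECE: sum_m (|B_m|/n) * |acc(B_m) - conf(B_m)|."""
    p = np.asarray(p, dtype=float)
    y = np.asarray(y, dtype=int)
    correct = (p >= 0.5).astype(int) == y
    bins = _confidence_bins(p, correct, M)
    n = p.size
    return float(
        sum(b["count"] / n * abs(b["accuracy"] - b["confidence"]) for b in bins if b["count"])
    )


def compute_metrics(
    p: Sequence[float], y: Sequence[int], threshold: float = 0.5, M: int = 10
) -> MetricsReport:
    p = np.asarray(p, dtype=float)
    y = np.asarray(y, dtype=int)
    if p.shape != y.shape:
        raise ValueError("predictions and labels must have equal length")
    pred = (p >= threshold).astype(int)
    tp = int(np.sum((pred == 1) & (y == 1)))
    tn = int(np.sum((pred == 0) & (y == 0)))
    fp = int(np.sum((pred == 1) & (y == 0)))
    fn = int(np.sum((pred == 0) & (y == 1)))
    degenerate = False
    if tp + fp == 0 or tp + fn == 0:
        degenerate = True
    precision = tp / (tp + fp) if tp + fp else 0.0
    recall = tp / (tp + fn) if tp + fn else 0.0
    f1 = 2 * precision * recall / (precision + recall) if precision + recall else 0.0
    acc = (tp + tn) / p.size
    auc_val = auc(p, y) if len(np.unique(y)) == 2 else 0.5
    correct = pred == y
    ece = expected_calibration_error(p, y, M)
    return MetricsReport(
        acc=float(acc),
        precision=float(precision),
        recall=float(recall),
        f1=float(f1),
        auc=float(auc_val),
        ece=float(ece),
        threshold=float(threshold),
        tp=tp,
        tn=tn,
        fp=fp,
        fn=fn,
        degenerate=degenerate,
        bins=_confidence_bins(p, correct, M),
    )


def auc(p: Sequence[float], y: Sequence[int]) -> float:
    """Mann-Whitney AUC: fraction of positive/negative pairs ranked
    correctly, ties counted 1/2.  Equals the ROC trapezoid area."""
    p = np.asarray(p, dtype=float)
    y = np.asarray(y, dtype=int)
    pos = p[y == 1]
    neg = p[y == 0]
    if pos.size == 0 or neg.size == 0:
        raise ValueError("AUC undefined: both classes must be present")
    greater = (pos[:, None] > neg[None, :]).sum()
    ties = (pos[:, None] == neg[None, :]).sum()
    return float((greater + 0.5 * ties) / (pos.size * neg.size))


def roc_curve(p: Sequence[float], y: Sequence[int]) -> np.ndarray:
    """(FPR, TPR, threshold) triples from sweeping unique scores descending.

    Starts at (0, 0) with an effective +inf threshold and ends at (1, 1).
    """
    p = np.asarray(p, dtype=float)
    y = np.asarray(y, dtype=int)
    n_pos = int(np.sum(y == 1))
    n_neg = int(np.sum(y == 0))
    if n_pos == 0 or n_neg == 0:
        raise ValueError("ROC undefined: both classes must be present")
    points = [(0.0, 0.0, np.inf)]
    for t in np.unique(p)[::-1]:
        pred = p >= t
        tpr = np.sum(pred & (y == 1)) / n_pos
        fpr = np.sum(pred & (y == 0)) / n_neg
        points.append((float(fpr), float(tpr), float(t)))
    return np.array(points)


def roc_auc_trapezoid(curve: np.ndarray) -> float:
    return float(np.trapezoid(curve[:, 1], curve[:, 0]))


def reliability_curve(p: Sequence[float], y: Sequence[int], M: int = 10) -> list[dict]:
    """The ECE bin table (edges, count, accuracy, mean confidence per bin)."""
    p = np.asarray(p, dtype=float)
    y = np.asarray(y, dtype=int)
    correct = (p >= 0.5).astype(int) == y
    return _confidence_bins(p, correct, M)


def save_curve_csv(path, rows: Sequence[dict] | np.ndarray, header: Sequence[str]) -> None:
    with open(path, "w") as fh:
        fh.write(",".join(header) + "\n")
        for row in rows:
            if isinstance(row, dict):
                fh.write(",".join("" if row[h] is None else repr(row[h]) for h in header) + "\n")
            else:
                fh.write(",".join(repr(float(v)) for v in row) + "\n")
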