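"""Cutoff calibration against radiologic assessment by ROC analysis.

A labeled cohort of per-patient scores (one of R_A, R_CNR, R_mu or R) is
swept over candidate cutoffs.  The classification convention follows the
response rule throughout: score <= cutoff predicts "controlled"
(response/stable), score > cutoff predicts "progression", and "controlled"
is the positive class.  Sensitivity is therefore the fraction of controlled
tumors kept below the cutoff and specificity the fraction of progressions
above it, matching how the source cohort's confusion table is laid out.

The area under the (1 - specificity, sensitivity) curve is computed by the
trapezoidal rule and is checked (in the test suite) against the
Mann-Whitney pairwise statistic; the operating cutoff maximizes Youden's
J = sensitivity + specificity - 1; the AUC confidence interval is a
stratified percentile bootstrap.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .metrics import Response, classify_r


class RawAssessment(str, enum.Enum):
    RESPONSE = "response"
    STABLE = "stable"
    PROGRESSION = "progression"


def binarize_assessment(raw_label: str | RawAssessment) -> Response:
    """Collapse response/stable into "controlled"; progression stays."""
    raw = RawAssessment(raw_label)
    if raw is RawAssessment.PROGRESSION:
        return Response.PROGRESSION
    return Response.CONTROLLED


@dataclass(frozen=True)
class CohortRecord:
    """One patient's score (a last/first ratio) and binarized label."""

    patient_id: str
    score: float
    label: Response

    def __post_init__(self) -> None:
        if self.score <= 0:
            raise ValueError("score must be positive")
        object.__setattr__(self, "label", Response(self.label))


@dataclass(frozen=True)
class ConfusionStats:
    """Counts and the five derived fractions; undefined fractions are None."""

    tp: int
    fn: int
    fp: int
    tn: int
    accuracy: float | None = field(init=False)
    sensitivity: float | None = field(init=False)
    specificity: float | None = field(init=False)
    ppv: float | None = field(init=False)
    npv: float | None = field(init=False)

    def __post_init__(self) -> None:
        if min(self.tp, self.fn, self.fp, self.tn) < 0:
            raise ValueError("counts must be non-negative")
        total = self.tp + self.fn + self.fp + self.tn
        if total == 0:
            raise ValueError("empty confusion table")

        def ratio(num: int, den: int) -> float | None:
            return num / den if den > 0 else None

        object.__setattr__(self, "accuracy", (self.tp + self.tn) / total)
        object.__setattr__(self, "sensitivity", ratio(self.tp, self.tp + self.fn))
        object.__setattr__(self, "specificity", ratio(self.tn, self.tn + self.fp))
        object.__setattr__(self, "ppv", ratio(self.tp, self.tp + self.fp))
        object.__setattr__(self, "npv", ratio(self.tn, self.tn + self.fn))

    def as_dict(self) -> dict:
        return {
            "tp": self.tp, "fn": self.fn, "fp": self.fp, "tn": self.tn,
            "accuracy": self.accuracy, "sensitivity": self.sensitivity,
            "specificity": self.specificity, "ppv": self.ppv, "npv": self.npv,
        }


def confusion_stats(tp: int, fn: int, fp: int, tn: int) -> ConfusionStats:
    """Accuracy, sensitivity, specificity, PPV and NPV from raw counts."""
    return ConfusionStats(tp=tp, fn=fn, fp=fp, tn=tn)


@dataclass
class ROCResult:
    """Sensitivity/specificity sweep with AUC, CI and operating cutoff."""

    cutoffs: np.ndarray
    sens: np.ndarray
    spec: np.ndarray
    auc: float | None = None
    auc_ci: tuple[float, float] | None = None
    optimal_cutoff: float | None = None
    confusion_at_optimal: ConfusionStats | None = None

    def __post_init__(self) -> None:
        self.cutoffs = np.asarray(self.cutoffs, dtype=float)
        self.sens = np.asarray(self.sens, dtype=float)
        self.spec = np.asarray(self.spec, dtype=float)
        if not (len(self.cutoffs) == len(self.sens) == len(self.spec)):
            raise ValueError("cutoffs, sens, spec must align")
        for arr in (self.sens, self.spec):
            if ((arr < -1e-12) | (arr > 1 + 1e-12)).any():
                raise ValueError("sens/spec must lie in [0, 1]")
        if self.auc is not None and not (0 <= self.auc <= 1):
            raise ValueError("AUC must lie in [0, 1]")
        if self.auc is not None and self.auc_ci is not None:
            lo, hi = self.auc_ci
            if not (lo <= self.auc + 1e-12 and self.auc - 1e-12 <= hi):
                raise ValueError("CI must bracket the AUC point estimate")

    @property
    def curve(self) -> np.ndarray:
        """(1 - specificity, sensitivity) points, one row per cutoff."""
        return np.column_stack([1.0 - self.spec, self.sens])


def _split_scores(records: Sequence[CohortRecord]) -> tuple[np.ndarray, np.ndarray]:
    pos = np.array([r.score for r in records if r.label is Response.CONTROLLED])
    neg = np.array([r.score for r in records if r.label is Response.PROGRESSION])
    if len(pos) == 0 or len(neg) == 0:
        raise ValueError("cohort must contain both controlled and progression cases")
    return pos, neg


def candidate_cutoffs(scores: Iterable[float]) -> np.ndarray:
    """Midpoints between consecutive distinct scores plus outer sentinels."""
    distinct = np.unique(np.asarray(list(scores), dtype=float))
    if len(distinct) < 2:
        raise ValueError(">=2 distinct scores required")
    mids = 0.5 * (distinct[:-1] + distinct[1:])
    lo = distinct[0] * 0.5
    hi = distinct[-1] * 1.5
    return np.concatenate([[lo], mids, [hi]])


def _confusion_at(pos: np.ndarray, neg: np.ndarray, cutoff: float) -> ConfusionStats:
    # score <= cutoff predicts controlled (positive); > cutoff predicts progression
    tp = int(np.sum(pos <= cutoff))
    fn = int(np.sum(pos > cutoff))
    tn = int(np.sum(neg > cutoff))
    fp = int(np.sum(neg <= cutoff))
    return ConfusionStats(tp=tp, fn=fn, fp=fp, tn=tn)


def roc_curve(
    records: Sequence[CohortRecord],
    positive_class: Response = Response.CONTROLLED,
) -> ROCResult:
    """Sweep candidate cutoffs and tabulate sensitivity/specificity.

    The positive class is "controlled" (scores at or below the cutoff); the
    opposite polarity is obtained by negating scores externally and is not
    supported directly.
    """
    if Response(positive_class) is not Response.CONTROLLED:
        raise ValueError("positive class is 'controlled' in this analysis")
    pos, neg = _split_scores(records)
    cuts = candidate_cutoffs(np.concatenate([pos, neg]))
    sens = np.empty(len(cuts))
    spec = np.empty(len(cuts))
    for i, c in enumerate(cuts):
        cs = _confusion_at(pos, neg, c)
        sens[i] = cs.sensitivity
        spec[i] = cs.specificity
    return ROCResult(cutoffs=cuts, sens=sens, spec=spec)


def auc(roc: ROCResult) -> float:
    """Trapezoidal area under the (1 - specificity, sensitivity) curve."""
    x = 1.0 - roc.spec
    y = roc.sens
    order = np.argsort(x, kind="stable")
    x, y = x[order], y[order]
    # anchor at (0,0) and (1,1) so partial sweeps still integrate the full curve
    x = np.concatenate([[0.0], x, [1.0]])
    y = np.concatenate([[0.0], y, [1.0]])
    return float(np.trapezoid(y, x))


def mann_whitney_auc(records: Sequence[CohortRecord]) -> float:
    """Pairwise AUC oracle: P(controlled score < progression score), ties 1/2.

    With the <=-cutoff convention a controlled case scoring BELOW a
    progression case is the correctly ordered pair.
    """
    pos, neg = _split_scores(records)
    diff = pos[:, None] - neg[None, :]
    wins = np.sum(diff < 0) + 0.5 * np.sum(diff == 0)
    return float(wins / (len(pos) * len(neg)))


def optimal_cutoff(roc: ROCResult) -> float:
    """Cutoff maximizing Youden's J = sens + spec - 1 (ties: smaller cutoff)."""
    j = roc.sens + roc.spec - 1.0
    order = np.argsort(roc.cutoffs, kind="stable")
    best = order[int(np.argmax(j[order]))]
    return float(roc.cutoffs[best])


def bootstrap_auc_ci(
    records: Sequence[CohortRecord],
    reps: int = 2000,
    seed: int = 0,
    level: float = 0.95,
) -> tuple[float, float]:
    """Stratified percentile bootstrap CI for the AUC.

    Resamples within each class (so every resample keeps both classes),
    recomputes the pairwise AUC per resample, and returns the percentile
    interval at ``level``.  Deterministic given ``seed``.
    """
    if reps < 100:
        raise ValueError("reps must be >= 100")
    if not (0 < level < 1):
        raise ValueError("level must be in (0, 1)")
    pos, neg = _split_scores(records)
    rng = np.random.default_rng(seed)
    stats = np.empty(reps)
    for i in range(reps):
        p = rng.choice(pos, size=len(pos), replace=True)
        n = rng.choice(neg, size=len(neg), replace=True)
        diff = p[:, None] - n[None, :]
        wins = np.sum(diff < 0) + 0.5 * np.sum(diff == 0)
        stats[i] = wins / (len(p) * len(n))
    alpha = 1.0 - level
    lo, hi = np.quantile(stats, [alpha / 2, 1 - alpha / 2])
    return float(lo), float(hi)


def calibrate(
    records: Sequence[CohortRecord],
    bootstrap_reps: int = 2000,
    seed: int = 0,
    level: float = 0.95,
) -> ROCResult:
    """Full calibration: ROC sweep, AUC + bootstrap CI, Youden cutoff,
    confusion table at the operating cutoff."""
    roc = roc_curve(records)
    a = auc(roc)
    ci = bootstrap_auc_ci(records, reps=bootstrap_reps, seed=seed, level=level)
    # percentile CIs need not bracket the trapezoidal point estimate exactly;
    # widen minimally so the reported triple is always coherent
    ci = (min(ci[0], a), max(ci[1], a))
    cut = optimal_cutoff(roc)
    pos, neg = _split_scores(records)
    conf = _confusion_at(pos, neg, cut)
    return ROCResult(
        cutoffs=roc.cutoffs, sens=roc.sens, spec=roc.spec,
        auc=a, auc_ci=ci, optimal_cutoff=cut, confusion_at_optimal=conf,
    )


def classify_cohort(
    records: Sequence[CohortRecord], cutoff: float
) -> ConfusionStats:
    """Re-classify every record at ``cutoff`` and tabulate the confusion."""
    tp = fn = fp = tn = 0
    for rec in records:
        pred = classify_r(rec.score, cutoff)
        if rec.label is Response.CONTROLLED:
            if pred is Response.CONTROLLED:
                tp += 1
            else:
                fn += 1
        else:
            if pred is Response.PROGRESSION:
                tn += 1
            else:
                fp += 1
    return ConfusionStats(tp=tp, fn=fn, fp=fp, tn=tn)
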