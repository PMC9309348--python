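"""Daytime hypertension detection: confusion metrics, ROC and cut-off tuning.

Patients are classified from their daytime mean BP at guideline
cut-offs (>= 135 mmHg systolic and/or >= 85 mmHg diastolic; the
boundary counts as hypertensive).  The reference device's daytime means
define the ground-truth label; the test device's daytime means are the
classifier scores.  On top of the fixed-cut-off confusion matrix the
module provides an ROC sweep with trapezoidal AUC and the Youden
optimum, and PPV/NPV optimisation curves over a cut-off grid.

Undefined metrics (zero denominators) propagate as NaN - never as 0 or
100 - so extreme cut-offs do not silently distort the curves.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd

from .core_data import DAY, REFERENCE, TEST, CohortData, period_means

CUTOFF_SBP = 135.0
CUTOFF_DBP = 85.0
MODES = ("systolic", "diastolic", "either")


@dataclasses.dataclass(frozen=True)
class ConfusionMatrix:
    tp: int
    fp: int
    fn: int
    tn: int

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


@dataclasses.dataclass(frozen=True)
class AccuracyMetrics:
    """Sensitivity/specificity/PPV/NPV in percent; NaN when undefined."""

    sensitivity: float
    specificity: float
    ppv: float
    npv: float


@dataclasses.dataclass(frozen=True)
class ROCResult:
    """ROC sweep over score thresholds (classification rule: score >= t).

    ``thresholds``/``se``/``sp`` tabulate the curve on a uniform display
    grid; ``auc``, ``youden_*`` are computed on the exact empirical
    threshold set so the trapezoidal AUC equals the Mann-Whitney
    concordance probability.  ``youden_cutoff`` is reported at the
    midpoint between the optimal threshold's adjacent observed scores.
    """

    thresholds: np.ndarray
    se: np.ndarray
    sp: np.ndarray
    auc: float
    youden_threshold: float
    youden_cutoff: float
    youden_j: float
    n_pos: int
    n_neg: int


@dataclasses.dataclass(frozen=True)
class PPVNPVCurve:
    """PPV/NPV over a cut-off grid with the PPV+NPV optimum."""

    grid: np.ndarray
    ppv: np.ndarray
    npv: np.ndarray
    optimal_cutoff: float
    optimal_ppv: float
    optimal_npv: float
    best_ppv_cutoff: float
    best_npv_cutoff: float


def classify_hypertension(
    mean_sbp,
    mean_dbp,
    cutoff_sbp: float = CUTOFF_SBP,
    cutoff_dbp: float = CUTOFF_DBP,
    mode: str = "either",
):
    """Hypertension label from daytime means; ``None`` when undecidable.

    ``systolic``: sbp >= cutoff; ``diastolic``: dbp >= cutoff;
    ``either``: three-valued OR (a missing arm only matters when the
    other arm is negative).
    """
    if mode not in MODES:
        raise ValueError(f"mode must be one of {MODES}, got {mode!r}")

    def _arm(value, cutoff):
        if value is None or (isinstance(value, float) and np.isnan(value)):
            return None
        return bool(value >= cutoff)

    s = _arm(mean_sbp, cutoff_sbp)
    d = _arm(mean_dbp, cutoff_dbp)
    if mode == "systolic":
        return s
    if mode == "diastolic":
        return d
    if s or d:
        return True
    if s is None or d is None:
        return None
    return False


def confusion_matrix(pred: pd.Series, truth: pd.Series) -> ConfusionMatrix:
    """2x2 patient counts; patients with a missing label are excluded."""
    df = pd.DataFrame({"pred": pred, "truth": truth}).dropna()
    p = df["pred"].astype(bool)
    t = df["truth"].astype(bool)
    return ConfusionMatrix(
        tp=int((p & t).sum()),
        fp=int((p & ~t).sum()),
        fn=int((~p & t).sum()),
        tn=int((~p & ~t).sum()),
    )


def _rate(num: int, den: int) -> float:
    return 100.0 * num / den if den > 0 else float("nan")


def accuracy_metrics(cm: ConfusionMatrix) -> AccuracyMetrics:
    """Se = tp/(tp+fn), Sp = tn/(tn+fp), PPV = tp/(tp+fp), NPV = tn/(tn+fn)."""
    if min(cm.tp, cm.fp, cm.fn, cm.tn) < 0:
        raise ValueError("confusion counts must be non-negative")
    return AccuracyMetrics(
        sensitivity=_rate(cm.tp, cm.tp + cm.fn),
        specificity=_rate(cm.tn, cm.tn + cm.fp),
        ppv=_rate(cm.tp, cm.tp + cm.fp),
        npv=_rate(cm.tn, cm.tn + cm.fn),
    )


def _clean_scores(scores, truth):
    s = np.asarray(scores, dtype=float)
    y = np.asarray(truth)
    if y.dtype != bool:
        y = y.astype(float) >= 0.5
    keep = np.isfinite(s)
    s, y = s[keep], y[keep]
    if len(s) == 0 or y.all() or (~y).all():
        raise ValueError("need finite scores with both classes present")
    return s, y


def _rates_at(s: np.ndarray, y: np.ndarray, thresholds: np.ndarray):
    pos = s[:, None] >= thresholds[None, :]
    se = 100.0 * pos[y].mean(axis=0)
    sp = 100.0 * (~pos[~y]).mean(axis=0)
    return se, sp


def roc_curve(scores, truth, grid_step: float = 0.1) -> ROCResult:
    """ROC over thresholds in [min - step, max + step]; rule: score >= t.

    The display arrays use the uniform ``grid_step`` grid; AUC (by
    trapezoidal integration over (1 - Sp, Se)) and the Youden optimum
    use the exact set of observed scores, so every attainable confusion
    matrix is visited.  Youden ties break toward the lower threshold.
    """
    s, y = _clean_scores(scores, truth)
    uniq = np.unique(s)
    cand = np.concatenate([uniq, [uniq[-1] + max(grid_step, 1e-9)]])
    se_c, sp_c = _rates_at(s, y, cand)
    tpr = se_c / 100.0
    fpr = (100.0 - sp_c) / 100.0
    auc = float(np.trapezoid(tpr[::-1], fpr[::-1]))

    j = se_c + sp_c - 100.0
    i = int(np.argmax(j))  # candidates ascending -> lowest threshold on ties
    thr = float(cand[i])
    below = uniq[uniq < thr]
    cutoff = float((below[-1] + thr) / 2.0) if len(below) else thr

    lo = s.min() - grid_step
    hi = s.max() + grid_step
    n_grid = int(round((hi - lo) / grid_step)) + 1
    thresholds = lo + grid_step * np.arange(n_grid)
    se, sp = _rates_at(s, y, thresholds)
    return ROCResult(
        thresholds=thresholds,
        se=se,
        sp=sp,
        auc=auc,
        youden_threshold=thr,
        youden_cutoff=cutoff,
        youden_j=float(j[i]),
        n_pos=int(y.sum()),
        n_neg=int((~y).sum()),
    )


def concordance_auc(scores, truth) -> float:
    """Mann-Whitney AUC: P(case score > control score) with ties as 1/2.

    Brute-force over all case-control pairs; the independent check of
    the trapezoidal AUC.
    """
    s, y = _clean_scores(scores, truth)
    s1, s0 = s[y], s[~y]
    gt = (s1[:, None] > s0[None, :]).sum()
    eq = (s1[:, None] == s0[None, :]).sum()
    return float((gt + 0.5 * eq) / (len(s1) * len(s0)))


def youden_from_rates(se: float, sp: float) -> float:
    """Youden index J = Se + Sp - 100, in percentage points."""
    if not (0 <= se <= 100 and 0 <= sp <= 100):
        raise ValueError("sensitivity and specificity must be in [0, 100]")
    return se + sp - 100.0


def ppv_npv_curve(
    scores, truth, grid_lo: float, grid_hi: float, step: float = 1.0
) -> PPVNPVCurve:
    """PPV/NPV per cut-off on [grid_lo, grid_hi]; optimum = max(PPV + NPV).

    Undefined values are NaN; the optimum is taken over cut-offs where
    both are defined, the best-PPV/best-NPV points over cut-offs where
    that value is defined.  All ties break toward the lower cut-off.
    """
    s, y = _clean_scores(scores, truth)
    n_steps = int(np.floor((grid_hi - grid_lo) / step + 1e-9)) + 1
    if n_steps <= 0 or grid_hi < grid_lo:
        raise ValueError("empty cut-off grid")
    grid = grid_lo + step * np.arange(n_steps)
    ppv = np.full(n_steps, np.nan)
    npv = np.full(n_steps, np.nan)
    for i, c in enumerate(grid):
        pos = s >= c
        tp = int((pos & y).sum())
        tn = int((~pos & ~y).sum())
        ppv[i] = _rate(tp, int(pos.sum()))
        npv[i] = _rate(tn, int((~pos).sum()))

    def _argbest(values: np.ndarray) -> int | None:
        masked = np.where(np.isfinite(values), values, -np.inf)
        if not np.isfinite(masked).any() or masked.max() == -np.inf:
            return None
        return int(np.argmax(masked))  # first max -> lower cut-off

    i_opt = _argbest(np.where(np.isfinite(ppv) & np.isfinite(npv), ppv + npv, np.nan))
    i_ppv = _argbest(ppv)
    i_npv = _argbest(npv)
    nan = float("nan")
    return PPVNPVCurve(
        grid=grid,
        ppv=ppv,
        npv=npv,
        optimal_cutoff=float(grid[i_opt]) if i_opt is not None else nan,
        optimal_ppv=float(ppv[i_opt]) if i_opt is not None else nan,
        optimal_npv=float(npv[i_opt]) if i_opt is not None else nan,
        best_ppv_cutoff=float(grid[i_ppv]) if i_ppv is not None else nan,
        best_npv_cutoff=float(grid[i_npv]) if i_npv is not None else nan,
    )


# -- cohort-level helpers ---------------------------------------------------

def daytime_scores(cohort: CohortData, variable: str) -> tuple[pd.Series, pd.Series]:
    """(test-device daytime means, reference hypertension labels) per patient.

    Patients missing either mean are dropped from both series.
    """
    cutoff = CUTOFF_SBP if variable == "sbp" else CUTOFF_DBP
    scores = period_means(cohort, TEST, variable, DAY)
    ref_means = period_means(cohort, REFERENCE, variable, DAY)
    keep = scores.notna() & ref_means.notna()
    return scores[keep], (ref_means[keep] >= cutoff)


def screen_cohort(
    cohort: CohortData,
    mode: str = "either",
    cutoff_sbp: float = CUTOFF_SBP,
    cutoff_dbp: float = CUTOFF_DBP,
) -> tuple[ConfusionMatrix, AccuracyMetrics]:
    """Fixed-cut-off screening of test vs reference daytime means."""
    ref_s = period_means(cohort, REFERENCE, "sbp", DAY)
    ref_d = period_means(cohort, REFERENCE, "dbp", DAY)
    test_s = period_means(cohort, TEST, "sbp", DAY)
    test_d = period_means(cohort, TEST, "dbp", DAY)
    truth = pd.Series(
        [
            classify_hypertension(s, d, cutoff_sbp, cutoff_dbp, mode)
            for s, d in zip(ref_s, ref_d)
        ],
        index=ref_s.index,
        dtype=object,
    )
    pred = pd.Series(
        [
            classify_hypertension(s, d, cutoff_sbp, cutoff_dbp, mode)
            for s, d in zip(test_s, test_d)
        ],
        index=test_s.index,
        dtype=object,
    )
    cm = confusion_matrix(pred, truth)
    return cm, accuracy_metrics(cm)
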