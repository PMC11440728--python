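"""Survival-model evaluation: concordance, time-dependent ROC, KM, log-rank,
bootstrap model comparison and Monte-Carlo Shapley attribution.

The concordance index follows the pairwise definition: over all subject pairs
where the shorter observed time carries an event (and times differ), a pair is
concordant when that subject has the higher predicted risk; tied risks credit
0.5. The time-dependent ROC uses the cumulative-cases / dynamic-controls
definition with inverse-probability-of-censoring weights from the KM estimate
of the censoring distribution.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test
from scipy import stats


@dataclass
class ConcordanceReport:
    concordant: float
    evaluable: int
    c_index: float


@dataclass
class TimedRocReport:
    times: list[float]
    auc: dict[float, float] = field(default_factory=dict)
    sensitivity: dict[float, float] = field(default_factory=dict)
    specificity: dict[float, float] = field(default_factory=dict)
    threshold: dict[float, float] = field(default_factory=dict)
    auc_ci: dict[float, tuple[float, float]] = field(default_factory=dict)


def _unpack(outcome) -> tuple[np.ndarray, np.ndarray]:
    if isinstance(outcome, pd.DataFrame):
        return outcome["time"].to_numpy(np.float64), outcome["event"].to_numpy(bool)
    return np.asarray(outcome["time"], dtype=np.float64), np.asarray(outcome["event"], dtype=bool)


def concordance_index(outcome, risk) -> ConcordanceReport:
    """C-index = concordant pairs / evaluable pairs (risk ties credit 0.5)."""
    time, event = _unpack(outcome)
    risk = np.asarray(risk, dtype=np.float64)
    n = len(time)
    concordant = 0.0
    evaluable = 0
    for i in range(n):
        if not event[i]:
            continue
        later = time > time[i]
        evaluable += int(later.sum())
        concordant += float((risk[i] > risk[later]).sum())
        concordant += 0.5 * float((risk[i] == risk[later]).sum())
    if evaluable == 0:
        raise ValueError("no evaluable pairs")
    return ConcordanceReport(concordant, evaluable, concordant / evaluable)


def _censoring_km(time: np.ndarray, event: np.ndarray):
    """KM estimator of the censoring survival function G(t) = P(C > t)."""
    km = KaplanMeierFitter()
    km.fit(time, 1 - event.astype(int))
    return km


def time_dependent_roc(outcome, risk, t: float, ipcw: bool = True,
                       n_thresholds: int | None = None):
    """Cumulative/dynamic ROC at horizon ``t`` with optional IPCW weights.

    Cases: event by ``t`` (weight 1/G(T_i-)); controls: followed beyond ``t``
    (weight 1/G(t)). Returns ``(fpr, tpr, thresholds, auc)``; AUC by the
    weighted Mann-Whitney statistic (equivalent to trapezoid integration of
    the weighted ROC).
    """
    time, event = _unpack(outcome)
    risk = np.asarray(risk, dtype=np.float64)
    cases = (time <= t) & event
    controls = time > t
    if cases.sum() == 0 or controls.sum() == 0:
        raise ValueError(f"no cases or no controls at t={t}")

    if ipcw:
        km = _censoring_km(time, event)
        g_at = lambda s: max(float(km.predict(s)), 1e-12)
        w_case = np.array([1.0 / g_at(ti - 1e-9) for ti in time[cases]])
        w_ctrl = np.full(int(controls.sum()), 1.0 / g_at(t))
    else:
        w_case = np.ones(int(cases.sum()))
        w_ctrl = np.ones(int(controls.sum()))

    r_case, r_ctrl = risk[cases], risk[controls]
    # weighted Mann-Whitney AUC
    order = np.argsort(r_ctrl, kind="stable")
    rc_sorted, wc_sorted = r_ctrl[order], w_ctrl[order]
    cum_w = np.concatenate(([0.0], np.cumsum(wc_sorted)))
    lo = np.searchsorted(rc_sorted, r_case, side="left")
    hi = np.searchsorted(rc_sorted, r_case, side="right")
    below = cum_w[lo]
    ties = cum_w[hi] - cum_w[lo]
    auc = float((w_case * (below + 0.5 * ties)).sum() / (w_case.sum() * w_ctrl.sum()))

    thresholds = np.unique(np.concatenate((r_case, r_ctrl)))[::-1]
    tpr = np.array([(w_case[r_case >= c]).sum() for c in thresholds]) / w_case.sum()
    fpr = np.array([(w_ctrl[r_ctrl >= c]).sum() for c in thresholds]) / w_ctrl.sum()
    return fpr, tpr, thresholds, auc


def timed_roc_report(outcome, risk, times=(1.0, 2.0, 3.0, 6.0),
                     n_boot: int = 100, seed: int = 0, ipcw: bool = True) -> TimedRocReport:
    """AUC + Youden-optimal sensitivity/specificity (+ bootstrap percentile CI)."""
    time, event = _unpack(outcome)
    risk = np.asarray(risk, dtype=np.float64)
    rep = TimedRocReport(times=list(times))
    rng = np.random.default_rng(seed)
    n = len(time)
    for t in times:
        fpr, tpr, thr, auc = time_dependent_roc(outcome, risk, t, ipcw=ipcw)
        youden = tpr - fpr
        k = int(np.argmax(youden))
        rep.auc[t] = auc
        rep.sensitivity[t] = float(tpr[k])
        rep.specificity[t] = float(1.0 - fpr[k])
        rep.threshold[t] = float(thr[k])
        if n_boot:
            aucs = []
            attempts = 0
            while len(aucs) < n_boot and attempts < 20 * n_boot:
                attempts += 1
                idx = rng.integers(0, n, size=n)
                try:
                    _, _, _, a = time_dependent_roc(
                        {"time": time[idx], "event": event[idx]}, risk[idx], t, ipcw=ipcw)
                    aucs.append(a)
                except ValueError:
                    continue
            if aucs:
                rep.auc_ci[t] = (float(np.percentile(aucs, 2.5)),
                                 float(np.percentile(aucs, 97.5)))
    return rep


def km_estimate(outcome) -> pd.DataFrame:
    """Kaplan-Meier product-limit curve: columns ``time`` and ``survival``."""
    time, event = _unpack(outcome)
    km = KaplanMeierFitter()
    km.fit(time, event.astype(int))
    sf = km.survival_function_
    return pd.DataFrame({"time": sf.index.to_numpy(np.float64),
                         "survival": sf.iloc[:, 0].to_numpy(np.float64)})


def log_rank(outcome_a, outcome_b) -> tuple[float, float]:
    """Two-group log-rank test: (chi-square statistic, p)."""
    ta, ea = _unpack(outcome_a)
    tb, eb = _unpack(outcome_b)
    if len(ta) == 0 or len(tb) == 0:
        raise ValueError("both groups must be nonempty")
    if ea.sum() + eb.sum() == 0:
        raise ValueError("no events in either group")
    res = logrank_test(ta, tb, event_observed_A=ea.astype(int),
                       event_observed_B=eb.astype(int))
    return float(res.test_statistic), float(res.p_value)


def bootstrap_compare(outcome, risk_a, risk_b, times=(1.0, 2.0, 3.0, 6.0),
                      n_boot: int = 100, seed: int = 0,
                      ipcw: bool = True) -> pd.DataFrame:
    """Paired t-test of bootstrap AUC(t) between two risk scores.

    Subjects are resampled with replacement ``n_boot`` times; degenerate
    replicates (no cases or controls at some horizon) are redrawn and counted.
    """
    time, event = _unpack(outcome)
    risk_a = np.asarray(risk_a, dtype=np.float64)
    risk_b = np.asarray(risk_b, dtype=np.float64)
    rng = np.random.default_rng(seed)
    n = len(time)
    auc_a = {t: [] for t in times}
    auc_b = {t: [] for t in times}
    redrawn = 0
    done = 0
    while done < n_boot and redrawn < 50 * n_boot:
        idx = rng.integers(0, n, size=n)
        sub = {"time": time[idx], "event": event[idx]}
        try:
            vals_a = [time_dependent_roc(sub, risk_a[idx], t, ipcw=ipcw)[3] for t in times]
            vals_b = [time_dependent_roc(sub, risk_b[idx], t, ipcw=ipcw)[3] for t in times]
        except ValueError:
            redrawn += 1
            continue
        for t, a, b in zip(times, vals_a, vals_b):
            auc_a[t].append(a)
            auc_b[t].append(b)
        done += 1
    rows = []
    for t in times:
        a, b = np.asarray(auc_a[t]), np.asarray(auc_b[t])
        if len(a) < 2:
            rows.append((t, np.nan, np.nan, np.nan, np.nan))
            continue
        if np.allclose(a, b):
            tstat, p = 0.0, 1.0
        else:
            tstat, p = stats.ttest_rel(a, b)
        rows.append((t, float(a.mean()), float(b.mean()), float(tstat), float(p)))
    return pd.DataFrame(rows, columns=["time", "mean_auc_a", "mean_auc_b",
                                       "t_statistic", "p_value"])


def shapley_attribution(score_fn, X: pd.DataFrame, background=None,
                        n_permutations: int = 128, seed: int = 0) -> pd.DataFrame:
    """Monte-Carlo permutation estimate of Shapley values of a risk score.

    Features are toggled from the background (training-mean) value to the
    subject's value in random orders; the average marginal change in the score
    estimates each feature's Shapley value. Attributions plus the background
    score sum to the subject's score (efficiency) up to Monte-Carlo error.
    """
    if n_permutations < 1:
        raise ValueError("n_permutations must be >= 1")
    X = pd.DataFrame(X)
    cols = list(X.columns)
    bg = (np.asarray(background, dtype=np.float64) if background is not None
          else X.to_numpy(np.float64).mean(axis=0))
    rng = np.random.default_rng(seed)
    Xv = X.to_numpy(np.float64)
    n, d = Xv.shape
    attr = np.zeros((n, d))
    for _ in range(n_permutations):
        perm = rng.permutation(d)
        cur = np.tile(bg, (n, 1))
        prev_score = np.asarray(score_fn(pd.DataFrame(cur, columns=cols)), dtype=np.float64)
        for j in perm:
            cur[:, j] = Xv[:, j]
            new_score = np.asarray(score_fn(pd.DataFrame(cur, columns=cols)), dtype=np.float64)
            attr[:, j] += new_score - prev_score
            prev_score = new_score
    attr /= n_permutations
    return pd.DataFrame(attr, columns=cols, index=X.index)
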