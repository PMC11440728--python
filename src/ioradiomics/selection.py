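"""Two-step feature selection for survival prediction.

Step 1 screens each feature univariately — Cox proportional-hazards regression
(Breslow ties, Newton iterations) for continuous features, Pearson chi-squared
against the progression-event indicator for categorical ones — keeping
p < 0.05. Step 2 runs sequential forward selection (SFS): greedy addition of
the candidate that most improves the concordance index of a linear Cox model
fitted on the training split and scored on the validation split.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sksurv.linear_model import CoxPHSurvivalAnalysis

from .metrics import concordance_index


def split_cohort(n: int, fractions=(0.55, 0.15, 0.30), seed: int = 0):
    """Random disjoint train/validation/test partition (largest-remainder sizes)."""
    if n < 3:
        raise ValueError("need at least 3 subjects to split")
    fr = np.asarray(fractions, dtype=np.float64)
    if abs(fr.sum() - 1.0) > 1e-9:
        raise ValueError("fractions must sum to 1")
    exact = fr * n
    sizes = np.floor(exact).astype(int)
    rem = exact - sizes
    for i in np.argsort(-rem)[: n - sizes.sum()]:
        sizes[i] += 1
    perm = np.random.default_rng(seed).permutation(n)
    out, start = [], 0
    for s in sizes:
        out.append(np.sort(perm[start:start + s]))
        start += s
    return tuple(out)


# ---------------------------------------------------------------------------
# univariate Cox (Breslow, Newton)
# ---------------------------------------------------------------------------

def cox_partial_loglik(beta: float, x: np.ndarray, time: np.ndarray,
                       event: np.ndarray) -> float:
    """Breslow partial log-likelihood of a single-covariate Cox model."""
    eta = beta * x
    order = np.argsort(-time, kind="stable")  # descending time
    eta_s, t_s, e_s = eta[order], time[order], event[order]
    # risk set of an event at t_i = all subjects with t_j >= t_i
    m = np.max(eta_s)
    csum = np.cumsum(np.exp(eta_s - m))
    # subjects with equal times must share the risk set: take the last index
    # of each tied block in the descending order
    loglik = 0.0
    i = 0
    n = len(t_s)
    while i < n:
        j = i
        while j + 1 < n and t_s[j + 1] == t_s[i]:
            j += 1
        denom = np.log(csum[j]) + m
        for k in range(i, j + 1):
            if e_s[k]:
                loglik += eta_s[k] - denom
        i = j + 1
    return float(loglik)


def univariate_cox(x, time, event, tol: float = 1e-8, max_iter: int = 60):
    """Single-covariate Cox PH fit: (beta, HR, SE, Wald p).

    Newton iterations on the Breslow partial likelihood to |dbeta| < 1e-8;
    monotone-likelihood (perfect separation) is flagged with an infinite
    hazard-ratio sentinel.
    """
    x = np.asarray(x, dtype=np.float64)
    time = np.asarray(time, dtype=np.float64)
    event = np.asarray(event).astype(bool)
    if event.sum() < 2:
        raise ValueError("need at least 2 events")
    if x.std() == 0:
        raise ValueError("constant feature")

    order = np.argsort(-time, kind="stable")
    x_s, t_s, e_s = x[order], time[order], event[order]
    n = len(t_s)
    # index of the last element of each tied block (shared risk set boundary)
    block_end = np.empty(n, dtype=int)
    i = 0
    while i < n:
        j = i
        while j + 1 < n and t_s[j + 1] == t_s[i]:
            j += 1
        block_end[i:j + 1] = j
        i = j + 1

    beta = 0.0
    for _ in range(max_iter):
        eta = beta * x_s
        m = eta.max()
        w = np.exp(eta - m)
        s0 = np.cumsum(w)[block_end]
        s1 = np.cumsum(w * x_s)[block_end]
        s2 = np.cumsum(w * x_s**2)[block_end]
        xbar = s1 / s0
        varx = s2 / s0 - xbar**2
        grad = float(np.sum((x_s - xbar)[e_s]))
        info = float(np.sum(varx[e_s]))
        if info <= 1e-12:
            break
        step = grad / info
        step = float(np.clip(step, -5.0, 5.0))
        beta += step
        if abs(step) < tol:
            break
        if abs(beta) > 25:  # monotone likelihood
            se = np.sqrt(1.0 / info) if info > 0 else np.inf
            return np.sign(beta) * np.inf, np.exp(np.sign(beta) * np.inf), se, np.nan

    eta = beta * x_s
    m = eta.max()
    w = np.exp(eta - m)
    s0 = np.cumsum(w)[block_end]
    s1 = np.cumsum(w * x_s)[block_end]
    s2 = np.cumsum(w * x_s**2)[block_end]
    info = float(np.sum((s2 / s0 - (s1 / s0) ** 2)[e_s]))
    se = float(np.sqrt(1.0 / info)) if info > 0 else np.inf
    z = beta / se if se > 0 and np.isfinite(se) else 0.0
    p = float(2.0 * stats.norm.sf(abs(z)))
    return float(beta), float(np.exp(beta)), se, p


def chi_squared(categorical, event) -> tuple[float, int, float]:
    """Pearson chi-squared (no continuity correction) of level x event status."""
    categorical = pd.Series(categorical).astype(str)
    event = pd.Series(np.asarray(event).astype(int)).set_axis(categorical.index)
    table = pd.crosstab(categorical, event)
    # drop zero-margin rows/cols
    rows = table.sum(axis=1) > 0
    cols = table.sum(axis=0) > 0
    if (~rows).any() or (~cols).any():
        warnings.warn("dropping zero-margin levels from contingency table")
        table = table.loc[rows, cols]
    if table.shape[0] < 2 or table.shape[1] < 2:
        raise ValueError("need at least a 2x2 contingency table")
    chi2, p, dof, _ = stats.chi2_contingency(table.to_numpy(), correction=False)
    return float(chi2), int(dof), float(p)


# ---------------------------------------------------------------------------
# screening
# ---------------------------------------------------------------------------

@dataclass
class ScreeningResult:
    table: pd.DataFrame

    @property
    def passed(self) -> list[str]:
        return list(self.table.index[self.table["pass"]])


class CoxChi2Screener:
    """Univariate screen: Cox for continuous columns, chi-squared for categorical.

    Features with p < ``alpha`` pass (no multiplicity adjustment). sklearn
    transformer protocol; ``y`` is a structured array with ``event``/``time``
    fields.
    """

    def __init__(self, alpha: float = 0.05):
        self.alpha = alpha

    def get_params(self, deep: bool = True) -> dict:
        return {"alpha": self.alpha}

    def set_params(self, **params) -> "CoxChi2Screener":
        for k, v in params.items():
            setattr(self, k, v)
        return self

    def fit(self, X: pd.DataFrame, y: np.ndarray) -> "CoxChi2Screener":
        X = pd.DataFrame(X)
        time, event = y["time"], y["event"]
        rows = []
        for col in X.columns:
            s = X[col]
            is_cat = (s.dtype == object or isinstance(s.dtype, pd.CategoricalDtype)
                      or s.dtype == bool)
            try:
                if is_cat:
                    c2, dof, p = chi_squared(s, event)
                    rows.append((col, "chi_squared", c2, np.nan, p))
                else:
                    beta, hr, se, p = univariate_cox(
                        s.to_numpy(dtype=np.float64), time, event)
                    stat = (beta / se) ** 2 if se > 0 and np.isfinite(beta) else np.inf
                    rows.append((col, "cox", stat, hr, p))
            except ValueError:
                rows.append((col, "skipped", np.nan, np.nan, np.nan))
        tab = pd.DataFrame(rows, columns=["feature", "test", "statistic",
                                          "hazard_ratio", "p_value"]).set_index("feature")
        tab["pass"] = tab["p_value"] < self.alpha
        self.result_ = ScreeningResult(tab)
        self.selected_features_ = self.result_.passed
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        return pd.DataFrame(X)[self.selected_features_]

    def fit_transform(self, X, y) -> pd.DataFrame:
        return self.fit(X, y).transform(X)


def screen(feature_table: pd.DataFrame, outcome: np.ndarray,
           alpha: float = 0.05) -> ScreeningResult:
    """Functional wrapper over :class:`CoxChi2Screener`."""
    s = CoxChi2Screener(alpha=alpha).fit(feature_table, outcome)
    return s.result_


# ---------------------------------------------------------------------------
# sequential forward selection
# ---------------------------------------------------------------------------

@dataclass
class SelectionTrace:
    steps: list[tuple[str, float]] = field(default_factory=list)

    @property
    def selected(self) -> list[str]:
        return [name for name, _ in self.steps]


class SequentialForwardSelector:
    """Greedy forward selection against validation concordance.

    At each step the candidate maximizing the validation C-index of a linear
    Cox model (small ridge for numerical stability) fitted on the training
    rows is added; ties break by lower screening p-value then candidate order;
    stops after ``patience`` consecutive non-improving steps or at
    ``max_features``.
    """

    def __init__(self, max_features: int = 15, patience: int = 1,
                 ridge: float = 1e-6):
        self.max_features = max_features
        self.patience = patience
        self.ridge = ridge

    def get_params(self, deep: bool = True) -> dict:
        return {"max_features": self.max_features, "patience": self.patience,
                "ridge": self.ridge}

    def set_params(self, **params) -> "SequentialForwardSelector":
        for k, v in params.items():
            setattr(self, k, v)
        return self

    def _criterion(self, X_tr, y_tr, X_va, y_va, cols) -> float:
        model = CoxPHSurvivalAnalysis(alpha=self.ridge)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            try:
                model.fit(X_tr[cols].to_numpy(dtype=np.float64), y_tr)
            except Exception:
                return -np.inf
        risk = model.predict(X_va[cols].to_numpy(dtype=np.float64))
        try:
            return concordance_index(y_va, risk).c_index
        except ValueError:
            return -np.inf

    def fit(self, X_train: pd.DataFrame, y_train: np.ndarray,
            X_val: pd.DataFrame, y_val: np.ndarray,
            candidates: list[str] | None = None,
            screening_p: dict[str, float] | None = None) -> "SequentialForwardSelector":
        X_train, X_val = pd.DataFrame(X_train), pd.DataFrame(X_val)
        cand = list(candidates if candidates is not None else X_train.columns)
        if not cand:
            raise ValueError("candidate set must be nonempty")
        pvals = screening_p or {}
        selected: list[str] = []
        trace = SelectionTrace()
        best = -np.inf
        bad_steps = 0
        while cand and len(selected) < self.max_features:
            scores = []
            for j, c in enumerate(cand):
                crit = self._criterion(X_train, y_train, X_val, y_val, selected + [c])
                scores.append((crit, -pvals.get(c, 1.0), -j, c))
            crit, _, _, chosen = max(scores)
            if not np.isfinite(crit):
                break
            if crit > best:
                best = crit
                bad_steps = 0
                selected.append(chosen)
                cand.remove(chosen)
                trace.steps.append((chosen, float(crit)))
            else:
                bad_steps += 1
                if bad_steps >= self.patience:
                    break
                cand.remove(chosen)
        self.trace_ = trace
        self.selected_features_ = selected
        self.best_criterion_ = best if np.isfinite(best) else None
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        if not self.selected_features_:
            raise ValueError("empty selection")
        return pd.DataFrame(X)[self.selected_features_]


def sequential_forward_selection(X_train, y_train, X_val, y_val,
                                 candidates=None, screening_p=None,
                                 max_features: int = 15,
                                 patience: int = 1) -> SelectionTrace:
    """Functional wrapper over :class:`SequentialForwardSelector`."""
    sel = SequentialForwardSelector(max_features=max_features, patience=patience)
    sel.fit(X_train, y_train, X_val, y_val, candidates=candidates,
            screening_p=screening_p)
    return sel.trace_
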