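"""Correlation screen, multicollinearity filter and stepwise regression.

The analysis chain mirrors the study design: Shapiro-Wilk normality
annotation, Spearman rank correlations with seeded bootstrap percentile
confidence intervals (clamped to [-1, 1]), retention at p < alpha with
no multiplicity correction, an iterative variance-inflation-factor
filter at threshold 5, backward elimination on slope p-values and a
final forward-selected ordinary-least-squares model.

Spearman p-values are exact (full permutation null, computed by a
subset-sum dynamic programme over rank displacement) for n <= 10 with
untied ranks, and t-approximate otherwise.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import MissingPredictor, SampleTooSmall

_EXACT_PERM_MAX_N = 10


# --------------------------------------------------------------------------
# result containers

@dataclass
class CorrelationResult:
    variable: str
    rho: float
    p_value: float
    ci95: Optional[Tuple[float, float]]
    n: int
    p_method: str
    ci_method: Optional[str] = None
    retained: bool = False
    flag: Optional[str] = None


@dataclass
class RegressionReport:
    """Final fitted model plus the full selection audit trail."""

    intercept: float
    coefficients: Dict[str, float]
    r_squared: float
    f_stat: float
    df: Tuple[int, int]
    p_value: float
    n: int
    predictions: Optional[pd.DataFrame] = None
    forward_trace: List[dict] = field(default_factory=list)
    backward_trace: List[dict] = field(default_factory=list)
    vif_table: List[dict] = field(default_factory=list)
    correlations: List[CorrelationResult] = field(default_factory=list)
    warnings: List[str] = field(default_factory=list)

    @property
    def predictors(self) -> List[str]:
        return list(self.coefficients)


# --------------------------------------------------------------------------
# ordinary least squares (hand-rolled so p-value edge cases are explicit)

@dataclass
class _OLSFit:
    params: np.ndarray          # intercept first
    p_values: np.ndarray        # per parameter
    r_squared: float
    rss: float
    n: int
    k: int                      # number of slopes

    @property
    def df2(self) -> int:
        return self.n - self.k - 1


def _ols(y: np.ndarray, X: np.ndarray) -> _OLSFit:
    """OLS of y on [1, X]; slope p-values from t statistics.

    With an (almost) perfect fit the residual variance collapses; a
    slope with |beta| above numerical noise is then reported p = 0 and a
    null slope p = 1, instead of the 0/0 = nan a naive formula yields.
    """
    n = len(y)
    design = np.column_stack([np.ones(n), X]) if X.size else np.ones((n, 1))
    k = design.shape[1] - 1
    beta, _, rank, _ = np.linalg.lstsq(design, y, rcond=None)
    fitted = design @ beta
    resid = y - fitted
    rss = float(resid @ resid)
    tss = float(np.sum((y - y.mean()) ** 2))
    r2 = 0.0 if tss == 0 else 1.0 - rss / tss  # no variance -> nothing explained
    df2 = n - k - 1
    p_values = np.ones(k + 1)
    if df2 > 0 and rank == k + 1:
        sigma2 = rss / df2
        xtx_inv = np.linalg.pinv(design.T @ design)
        se = np.sqrt(np.maximum(np.diag(xtx_inv) * sigma2, 0.0))
        scale = max(float(np.max(np.abs(y))), 1.0)
        for j in range(k + 1):
            if se[j] > 0:
                p_values[j] = 2.0 * sps.t.sf(abs(beta[j]) / se[j], df2)
            else:
                p_values[j] = 0.0 if abs(beta[j]) > 1e-8 * scale else 1.0
    return _OLSFit(params=beta, p_values=p_values, r_squared=r2,
                   rss=rss, n=n, k=k)


def f_from_r2(r2: float, df1: int, df2: int) -> float:
    """F statistic implied by R^2: (R^2/df1) / ((1-R^2)/df2)."""
    if df1 <= 0 or df2 <= 0:
        return float("nan")
    if r2 >= 1.0 - 1e-12:
        return float("inf")
    return (r2 / df1) / ((1.0 - r2) / df2)


# --------------------------------------------------------------------------
# Spearman correlation with exact small-sample permutation p-values

@lru_cache(maxsize=None)
def _sum_d2_null_counts(n: int) -> np.ndarray:
    """Permutation-null counts of S = sum (i - pi(i))^2 over all pi.

    Subset dynamic programme: position ``i`` (the popcount of the mask)
    is matched with every unused rank ``j``, adding (i - j)^2 to S.
    Exact for the untied-rank Spearman null; counts fit in doubles up to
    n = 10 (10! = 3 628 800).
    """
    s_max = n * (n * n - 1) // 3
    size = 1 << n
    dp = np.zeros((size, s_max + 1))
    dp[0, 0] = 1.0
    popcount = np.array([bin(m).count("1") for m in range(size)])
    for mask in range(size):
        row = dp[mask]
        if not row.any():
            continue
        i = popcount[mask]
        for j in range(n):
            bit = 1 << j
            if mask & bit:
                continue
            shift = (i - j) ** 2
            dp[mask | bit, shift:] += row[: s_max + 1 - shift]
    return dp[size - 1]


def _exact_spearman_p(rho: float, n: int) -> float:
    counts = _sum_d2_null_counts(n)
    s_values = np.arange(len(counts))
    rhos = 1.0 - 6.0 * s_values / (n * (n * n - 1))
    mask = np.abs(rhos) >= abs(rho) - 1e-12
    return float(counts[mask].sum() / counts.sum())


def _rank(x: np.ndarray) -> np.ndarray:
    return sps.rankdata(x, method="average")


def spearman_rho(x: Sequence[float], y: Sequence[float]) -> float:
    """Spearman rho as the Pearson correlation of average ranks."""
    rx, ry = _rank(np.asarray(x, float)), _rank(np.asarray(y, float))
    if np.ptp(rx) == 0 or np.ptp(ry) == 0:
        return float("nan")
    return float(np.corrcoef(rx, ry)[0, 1])


def spearman_with_ci(x: Sequence[float], y: Sequence[float],
                     n_boot: int = 10_000, seed: int = 0,
                     ci_method: str = "bootstrap",
                     variable: str = "") -> CorrelationResult:
    """Spearman rho with p-value and a 95% CI.

    p is an exact permutation value for n <= 10 with untied ranks, else
    the usual t approximation.  The CI is a seeded bootstrap percentile
    over athletes clamped to [-1, 1] (``ci_method="fisher-z"`` gives the
    classical transform instead; ``n_boot=0`` skips the CI).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 4:
        raise ValueError("need >= 4 paired finite observations")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise ValueError("inputs must be finite")
    n = len(x)
    rho = spearman_rho(x, y)
    if np.isnan(rho):
        return CorrelationResult(variable=variable, rho=float("nan"),
                                 p_value=float("nan"), ci95=None, n=n,
                                 p_method="undefined", flag="zero_rank_variance")
    rx, ry = _rank(x), _rank(y)
    tied = len(np.unique(rx)) < n or len(np.unique(ry)) < n
    if n <= _EXACT_PERM_MAX_N and not tied:
        p = _exact_spearman_p(rho, n)
        p_method = "exact_permutation"
    else:
        p = float(sps.spearmanr(x, y).pvalue)
        p_method = "t_approximation" + ("_ties" if tied else "")

    ci: Optional[Tuple[float, float]] = None
    used_ci_method: Optional[str] = None
    if ci_method == "fisher-z":
        z = np.arctanh(np.clip(rho, -1 + 1e-12, 1 - 1e-12))
        half = 1.959963984540054 / np.sqrt(n - 3)
        ci = (float(np.clip(np.tanh(z - half), -1, 1)),
              float(np.clip(np.tanh(z + half), -1, 1)))
        used_ci_method = "fisher-z"
    elif n_boot > 0:
        rng = np.random.default_rng(seed)
        idx = rng.integers(0, n, size=(n_boot, n))
        xb, yb = x[idx], y[idx]
        rxb = sps.rankdata(xb, axis=1, method="average")
        ryb = sps.rankdata(yb, axis=1, method="average")
        rxb = rxb - rxb.mean(axis=1, keepdims=True)
        ryb = ryb - ryb.mean(axis=1, keepdims=True)
        denom = np.sqrt((rxb ** 2).sum(axis=1) * (ryb ** 2).sum(axis=1))
        with np.errstate(invalid="ignore", divide="ignore"):
            rhos = (rxb * ryb).sum(axis=1) / denom
        rhos = rhos[np.isfinite(rhos)]
        lo, hi = np.percentile(rhos, [2.5, 97.5])
        ci = (float(np.clip(lo, -1, 1)), float(np.clip(hi, -1, 1)))
        used_ci_method = "bootstrap_percentile"
    return CorrelationResult(variable=variable, rho=rho, p_value=p, ci95=ci,
                             n=n, p_method=p_method, ci_method=used_ci_method)


def shapiro_wilk_screen(frame: pd.DataFrame) -> pd.DataFrame:
    """Shapiro-Wilk p-value per column; constant columns are flagged."""
    rows = []
    for col in frame.columns:
        x = frame[col].dropna().to_numpy(dtype=float)
        if len(x) < 3:
            rows.append({"variable": col, "p_value": np.nan,
                         "flag": "too_few_observations"})
        elif np.ptp(x) == 0:
            rows.append({"variable": col, "p_value": np.nan,
                         "flag": "constant_column"})
        else:
            rows.append({"variable": col,
                         "p_value": float(sps.shapiro(x).pvalue),
                         "flag": None})
    return pd.DataFrame(rows)


def correlation_screen(frame: pd.DataFrame, outcome: str,
                       alpha: float = 0.05, n_boot: int = 10_000,
                       seed: int = 0) -> List[CorrelationResult]:
    """Spearman of each candidate column against the outcome.

    Retains p < alpha with no multiplicity correction (the family-wise
    error is inflated by design; callers annotate this in reports).
    """
    if outcome not in frame.columns:
        raise KeyError(f"outcome column missing: {outcome}")
    y = frame[outcome].to_numpy(dtype=float)
    results = []
    for j, col in enumerate(c for c in frame.columns if c != outcome):
        res = spearman_with_ci(frame[col].to_numpy(dtype=float), y,
                               n_boot=n_boot, seed=seed + j, variable=col)
        res.retained = bool(np.isfinite(res.p_value) and res.p_value < alpha)
        results.append(res)
    return results


# --------------------------------------------------------------------------
# multicollinearity filter and stepwise selection

def _r2_of_on(frame: pd.DataFrame, target: str, others: List[str]) -> float:
    y = frame[target].to_numpy(dtype=float)
    X = frame[others].to_numpy(dtype=float)
    return _ols(y, X).r_squared


def compute_vifs(frame: pd.DataFrame, predictors: List[str]
                 ) -> Dict[str, float]:
    """VIF_j = 1 / (1 - R^2_j) from regressing j on the other predictors."""
    out = {}
    for name in predictors:
        others = [p for p in predictors if p != name]
        if not others:
            out[name] = 1.0
            continue
        r2 = _r2_of_on(frame, name, others)
        out[name] = float("inf") if r2 >= 1.0 - 1e-10 else 1.0 / (1.0 - r2)
    return out


def vif_filter(frame: pd.DataFrame, predictors: Sequence[str],
               threshold: float = 5.0
               ) -> Tuple[List[str], List[dict]]:
    """Iteratively drop the largest-VIF predictor while any exceeds
    ``threshold``.  Ties (and infinite VIFs) break alphabetically.
    Returns the retained predictors and a per-round audit table.
    """
    remaining = list(predictors)
    table: List[dict] = []
    while len(remaining) >= 2:
        vifs = compute_vifs(frame, remaining)
        worst = max(sorted(vifs), key=lambda k: (vifs[k], ))
        record = {"vifs": dict(vifs), "removed": None, "flag": None}
        if vifs[worst] > threshold:
            record["removed"] = worst
            if np.isinf(vifs[worst]):
                record["flag"] = "InfiniteVIF"
            remaining.remove(worst)
            table.append(record)
        else:
            table.append(record)
            break
    return remaining, table


def backward_eliminate(frame: pd.DataFrame, outcome: str,
                       predictors: Sequence[str],
                       alpha_stay: float = 0.05
                       ) -> Tuple[List[str], List[dict]]:
    """Drop the largest-p slope while it exceeds ``alpha_stay``.

    If the initial set cannot be fitted (n < p + 2) the most redundant
    predictor of the most-correlated pair is pre-dropped, with a flag,
    until the model is estimable.
    """
    remaining = list(predictors)
    trace: List[dict] = []
    y = frame[outcome].to_numpy(dtype=float)
    n = len(y)
    while len(remaining) > n - 2 and len(remaining) > 1:
        corr = frame[remaining].corr().abs().to_numpy()
        np.fill_diagonal(corr, 0.0)
        i, j = np.unravel_index(np.argmax(corr), corr.shape)
        drop = max(remaining[i], remaining[j])  # alphabetical tie-break
        trace.append({"removed": drop, "p_value": None,
                      "flag": "pre_drop_redundant"})
        remaining.remove(drop)
    while remaining:
        fit = _ols(y, frame[remaining].to_numpy(dtype=float))
        slope_p = {name: (1.0 if np.isnan(p) else float(p))
                   for name, p in zip(remaining, fit.p_values[1:])}
        worst = max(sorted(slope_p), key=lambda k: (slope_p[k], ))
        if slope_p[worst] > alpha_stay:
            trace.append({"removed": worst, "p_value": slope_p[worst],
                          "flag": None})
            remaining.remove(worst)
        else:
            break
    if not remaining:
        trace.append({"removed": None, "p_value": None,
                      "flag": "all_predictors_eliminated"})
    return remaining, trace


def forward_select_and_fit(frame: pd.DataFrame, outcome: str,
                           candidates: Sequence[str],
                           alpha_enter: float = 0.05
                           ) -> RegressionReport:
    """Greedy forward selection by R^2 gain with entry p < alpha.

    The final ordinary-least-squares model reports coefficients, R^2,
    F = (R^2/df1)/((1-R^2)/df2), the (df1, df2) pair and the model p.
    An empty selection yields an intercept-only report.
    """
    y = frame[outcome].to_numpy(dtype=float)
    n = len(y)
    selected: List[str] = []
    trace: List[dict] = []
    pool = sorted(candidates)
    current_r2 = 0.0
    while pool and len(selected) < n - 2:
        gains = {}
        for cand in pool:
            fit = _ols(y, frame[selected + [cand]].to_numpy(dtype=float))
            gains[cand] = fit.r_squared - current_r2
        best = max(sorted(gains), key=lambda k: (gains[k], ))
        fit = _ols(y, frame[selected + [best]].to_numpy(dtype=float))
        entry_p = fit.p_values[-1]
        entry_p = 1.0 if np.isnan(entry_p) else float(entry_p)
        if entry_p < alpha_enter and gains[best] > 1e-12:
            selected.append(best)
            pool.remove(best)
            current_r2 = fit.r_squared
            trace.append({"entered": best, "p_value": entry_p,
                          "r_squared": fit.r_squared})
        else:
            break

    fit = _ols(y, frame[selected].to_numpy(dtype=float)
               if selected else np.empty((n, 0)))
    df1, df2 = len(selected), n - len(selected) - 1
    f_stat = f_from_r2(fit.r_squared, df1, df2) if selected else 0.0
    if selected:
        if np.isinf(f_stat):
            model_p = 0.0
        else:
            model_p = float(sps.f.sf(f_stat, df1, df2))
    else:
        model_p = 1.0
    coefs = {name: float(b) for name, b in zip(selected, fit.params[1:])}
    predictions = pd.DataFrame({
        "observed": y,
        "predicted": fit.params[0] + (
            frame[selected].to_numpy(dtype=float) @ fit.params[1:]
            if selected else 0.0),
    })
    return RegressionReport(intercept=float(fit.params[0]),
                            coefficients=coefs, r_squared=fit.r_squared,
                            f_stat=f_stat, df=(df1, df2), p_value=model_p,
                            n=n, predictions=predictions,
                            forward_trace=trace)


def predict_race_time(report: RegressionReport,
                      markers_wkg: Dict[str, float]) -> float:
    """Evaluate the fitted model: intercept + sum(coef * marker)."""
    missing = [k for k in report.coefficients if k not in markers_wkg]
    if missing:
        raise MissingPredictor("missing predictors: " + ", ".join(missing))
    return report.intercept + sum(b * markers_wkg[k]
                                  for k, b in report.coefficients.items())


def analyze_markers(frame: pd.DataFrame, outcome: str,
                    alpha_screen: float = 0.05, vif_threshold: float = 5.0,
                    alpha_stay: float = 0.05, alpha_enter: float = 0.05,
                    n_boot: int = 10_000, seed: int = 0,
                    min_cases: int = 6) -> RegressionReport:
    """Full analysis chain: screen -> VIF filter -> backward -> forward.

    ``frame`` holds one row per athlete with candidate predictor columns
    plus the outcome column; incomplete rows are dropped (complete-case
    analysis) and a warning records the count.
    """
    complete = frame.dropna()
    warnings = []
    if len(complete) < len(frame):
        warnings.append(
            f"dropped {len(frame) - len(complete)} incomplete case(s); "
            f"analysing n={len(complete)}")
    if len(complete) < min_cases:
        raise SampleTooSmall(
            f"{len(complete)} complete cases < required {min_cases}")
    correlations = correlation_screen(complete, outcome, alpha=alpha_screen,
                                      n_boot=n_boot, seed=seed)
    warnings.append("screen applies no multiple-testing correction; "
                    "family-wise error is inflated")
    retained = [c.variable for c in correlations if c.retained]
    vif_table: List[dict] = []
    backward_trace: List[dict] = []
    if len(retained) >= 2:
        survivors, vif_table = vif_filter(complete, retained,
                                          threshold=vif_threshold)
    else:
        survivors = retained
    if survivors:
        survivors, backward_trace = backward_eliminate(
            complete, outcome, survivors, alpha_stay=alpha_stay)
    report = forward_select_and_fit(complete, outcome, survivors,
                                    alpha_enter=alpha_enter)
    report.correlations = correlations
    report.vif_table = vif_table
    report.backward_trace = backward_trace
    report.warnings = warnings + report.warnings
    return report
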