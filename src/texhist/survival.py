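"""Median-split survival screening and stepwise Cox selection.

The statistical procedure applied to the analysis table:

1. each candidate marker is dichotomized at its sample median (above vs at-or-
   below);
2. Kaplan-Meier curves are estimated per group and compared with the 1-df
   log-rank test;
3. raw p-values are Benjamini-Hochberg adjusted within one family per
   endpoint (FDR level q = 0.30 by default);
4. the BH-significant markers enter a forward-Wald stepwise Cox proportional-
   hazards model (entry p < 0.05, no removal step): at each step the
   candidate with the largest Wald statistic among those with Wald p below
   the entry threshold joins the model.

Kaplan-Meier estimation and the log-rank test are delegated to lifelines;
Cox partial-likelihood maximization to statsmodels PHReg (Breslow tie
handling by default, Efron selectable); BH adjustment to statsmodels
``multipletests``.  The dichotomization, screening loop, and forward-Wald
selection are implemented here.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test as _ll_logrank
from sklearn.base import BaseEstimator
from statsmodels.duration.hazard_regression import PHReg
from statsmodels.stats.multitest import multipletests

__all__ = [
    "KmCurve",
    "MarkerResult",
    "CoxResult",
    "DegenerateSplitError",
    "dichotomize_at_median",
    "km_estimate",
    "logrank_test",
    "bh_adjust",
    "fit_cox",
    "forward_wald_select",
    "run_univariate_screen",
    "MedianSplitScreen",
    "ForwardWaldCoxSelector",
]

Z_95 = 1.959963984540054  # two-sided 95% normal quantile


class DegenerateSplitError(ValueError):
    """All marker values identical: the median split is empty on one side."""


# ---------------------------------------------------------------------------
# Building blocks
# ---------------------------------------------------------------------------

def dichotomize_at_median(values: Sequence[float]) -> tuple[float, np.ndarray, int]:
    """Split values at the sample median.

    Returns ``(threshold, above, n_missing)`` where ``above`` is a boolean
    array over the non-missing values: True for values strictly greater than
    the median, False for values at or below it (ties go to the "below"
    group).  Missing (NaN) values are excluded and counted.

    Raises
    ------
    DegenerateSplitError
        If fewer than 2 non-missing values remain or all values are
        identical (one group would be empty).
    """
    v = np.asarray(values, dtype=np.float64)
    finite = np.isfinite(v)
    n_missing = int((~finite).sum())
    v = v[finite]
    if v.size < 2:
        raise DegenerateSplitError("need >= 2 non-missing values")
    threshold = float(np.median(v))
    above = v > threshold
    if above.all() or not above.any():
        raise DegenerateSplitError("degenerate split: all values on one side of the median")
    return threshold, above, n_missing


@dataclass
class KmCurve:
    """Kaplan-Meier product-limit estimate.

    ``median`` is the smallest time with S(t) <= 0.5, or ``inf`` when the
    curve never reaches 0.5 ("not reached").
    """

    timeline: np.ndarray
    survival: np.ndarray
    at_risk: np.ndarray
    median: float
    n: int
    n_events: int

    @property
    def median_label(self) -> str:
        return "Not reached" if np.isinf(self.median) else f"{self.median:g}"


def km_estimate(times: Sequence[float], events: Sequence[bool]) -> KmCurve:
    """Product-limit survival estimate with median survival time."""
    t = np.asarray(times, dtype=np.float64)
    e = np.asarray(events).astype(bool)
    if t.size == 0:
        raise ValueError("need at least one subject")
    if (t < 0).any():
        raise ValueError("negative survival time")
    kmf = KaplanMeierFitter()
    kmf.fit(t, event_observed=e)
    timeline = kmf.survival_function_.index.to_numpy(dtype=float)
    surv = kmf.survival_function_.iloc[:, 0].to_numpy(dtype=float)
    at_risk = kmf.event_table["at_risk"].reindex(kmf.survival_function_.index).to_numpy()
    median = float(kmf.median_survival_time_)  # inf when S stays above 0.5
    return KmCurve(
        timeline=timeline,
        survival=surv,
        at_risk=at_risk,
        median=median,
        n=int(t.size),
        n_events=int(e.sum()),
    )


def logrank_test(
    times_a: Sequence[float],
    events_a: Sequence[bool],
    times_b: Sequence[float],
    events_b: Sequence[bool],
) -> tuple[float, float]:
    """Two-group 1-df log-rank test; returns (chi-square statistic, p)."""
    ta = np.asarray(times_a, dtype=float)
    tb = np.asarray(times_b, dtype=float)
    ea = np.asarray(events_a).astype(bool)
    eb = np.asarray(events_b).astype(bool)
    if ta.size == 0 or tb.size == 0:
        raise ValueError("both groups must be nonempty")
    if ea.sum() + eb.sum() == 0:
        raise ValueError("no events in either group")
    res = _ll_logrank(ta, tb, event_observed_A=ea, event_observed_B=eb)
    return float(res.test_statistic), float(res.p_value)


def bh_adjust(
    pvalues: Sequence[float], q: float = 0.30
) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini-Hochberg step-up adjustment over one family of tests.

    Returns ``(adjusted_p, significant)``.  Adjusted p-values are the usual
    monotone min-over-tail of ``p * m / rank`` capped at 1; a test is
    significant iff its rank falls at or below the largest i with
    ``p_(i) <= i * q / m``.
    """
    p = np.asarray(pvalues, dtype=np.float64)
    if p.size == 0:
        return np.array([]), np.array([], dtype=bool)
    if ((p < 0) | (p > 1)).any() or not np.isfinite(p).all():
        raise ValueError("p-values must lie in [0, 1]")
    if not 0 < q <= 1:
        raise ValueError("q must be in (0, 1]")
    reject, adjusted, _, _ = multipletests(p, alpha=q, method="fdr_bh")
    return adjusted, reject


@dataclass
class MarkerResult:
    """Univariate screening result for one marker at one endpoint."""

    marker: str
    endpoint: str
    threshold: float
    poor_prognosis: str  # "above" or "below" the cut-off
    n_below: int
    n_above: int
    median_below: float
    median_above: float
    p_raw: float
    p_adjusted: float = float("nan")
    significant: bool = False
    n_missing: int = 0

    def to_row(self) -> dict:
        def fmt(m):
            return "Not reached" if np.isinf(m) else m

        return {
            "marker": self.marker,
            "endpoint": self.endpoint,
            "cutoff": self.threshold,
            "poor_prognosis_direction": self.poor_prognosis,
            "n_below": self.n_below,
            "n_above": self.n_above,
            "median_survival_below": fmt(self.median_below),
            "median_survival_above": fmt(self.median_above),
            "p_raw": self.p_raw,
            "p_adjusted": self.p_adjusted,
            "significant": self.significant,
            "n_missing": self.n_missing,
        }


@dataclass
class CoxResult:
    """Final stepwise Cox model: per-covariate estimates plus entry trace."""

    covariates: list[str]
    coef: np.ndarray
    hr: np.ndarray
    ci_low: np.ndarray
    ci_high: np.ndarray
    wald_p: np.ndarray
    trace: list[dict] = field(default_factory=list)

    def summary(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "coef": self.coef,
                "HR": self.hr,
                "CI95_low": self.ci_low,
                "CI95_high": self.ci_high,
                "wald_p": self.wald_p,
            },
            index=pd.Index(self.covariates, name="covariate"),
        )


def fit_cox(
    X: pd.DataFrame | np.ndarray,
    times: Sequence[float],
    events: Sequence[bool],
    ties: str = "breslow",
) -> pd.DataFrame:
    """Cox proportional-hazards fit via partial-likelihood maximization.

    Returns a DataFrame with per-covariate coef, HR = exp(coef), normal-
    approximation 95% CI, and Wald p from (coef/SE)^2 on chi-square(1).
    Monotone partial likelihood (perfect separation) is reported as a
    warning with the diverging coefficient, not an exception.
    """
    if ties not in ("breslow", "efron"):
        raise ValueError("ties must be 'breslow' or 'efron'")
    Xdf = pd.DataFrame(X)
    names = [str(c) for c in Xdf.columns]
    arr = Xdf.to_numpy(dtype=np.float64)
    t = np.asarray(times, dtype=np.float64)
    e = np.asarray(events).astype(int)
    if arr.ndim != 2 or arr.shape[0] != t.size:
        raise ValueError("covariate matrix and times are not aligned")
    if (arr.std(axis=0) == 0).any():
        const = [n for n, s in zip(names, arr.std(axis=0)) if s == 0]
        raise ValueError(f"constant covariate(s): {const}")
    if e.sum() < arr.shape[1] + 1:
        raise ValueError("need more events than covariates")

    model = PHReg(t, arr, status=e, ties=ties)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = model.fit(disp=False)
    coef = np.asarray(res.params, dtype=float)
    se = np.asarray(res.bse, dtype=float)
    if np.abs(coef).max() > 15 or not np.isfinite(se).all():
        warnings.warn(
            "possible monotone partial likelihood (separation): "
            f"coefficients {dict(zip(names, coef))}",
            stacklevel=2,
        )
    from scipy import stats as _st

    wald_p = _st.chi2.sf((coef / se) ** 2, df=1)
    with np.errstate(over="ignore"):
        return pd.DataFrame(
            {
                "coef": coef,
                "HR": np.exp(coef),
                "CI95_low": np.exp(coef - Z_95 * se),
                "CI95_high": np.exp(coef + Z_95 * se),
                "se": se,
                "wald_p": wald_p,
            },
            index=pd.Index(names, name="covariate"),
        )


def forward_wald_select(
    candidates: pd.DataFrame,
    times: Sequence[float],
    events: Sequence[bool],
    entry_p: float = 0.05,
    ties: str = "breslow",
) -> CoxResult:
    """Forward-Wald stepwise Cox selection over dichotomized candidate markers.

    At each step every remaining candidate is added to the current model in
    turn; the one with the largest Wald statistic enters if its conditional
    Wald p is below ``entry_p``.  There is no removal step.  Candidates whose
    trial fit fails (separation, collinearity) are skipped for that step.
    An empty candidate set yields an empty (valid) model.
    """
    t = np.asarray(times, dtype=float)
    e = np.asarray(events).astype(int)
    selected: list[str] = []
    trace: list[dict] = []
    remaining = [c for c in candidates.columns]

    while remaining:
        best = None  # (wald_stat, name, fit)
        for name in remaining:
            cols = selected + [name]
            try:
                fit = fit_cox(candidates[cols], t, e, ties=ties)
            except Exception:
                continue
            w = (fit.loc[name, "coef"] / fit.loc[name, "se"]) ** 2
            if not np.isfinite(w):
                continue
            if best is None or w > best[0]:
                best = (float(w), name, fit)
        if best is None:
            break
        wstat, name, fit = best
        pval = float(fit.loc[name, "wald_p"])
        trace.append({"step": len(selected) + 1, "candidate": name,
                      "wald_stat": wstat, "wald_p": pval, "entered": pval < entry_p})
        if pval >= entry_p:
            break
        selected.append(name)
        remaining.remove(name)

    if not selected:
        empty = np.array([])
        return CoxResult([], empty, empty, empty, empty, empty, trace)
    final = fit_cox(candidates[selected], t, e, ties=ties)
    return CoxResult(
        covariates=selected,
        coef=final["coef"].to_numpy(),
        hr=final["HR"].to_numpy(),
        ci_low=final["CI95_low"].to_numpy(),
        ci_high=final["CI95_high"].to_numpy(),
        wald_p=final["wald_p"].to_numpy(),
        trace=trace,
    )


# ---------------------------------------------------------------------------
# Univariate screen
# ---------------------------------------------------------------------------

def _poor_direction(km_below: KmCurve, km_above: KmCurve, times, events, above) -> str:
    """Which side of the cut-off has the worse survival.

    Primary comparison is the KM median; when medians tie or are both not
    reached, the restricted mean survival time over the observed horizon
    breaks the tie.
    """
    mb, ma = km_below.median, km_above.median
    if ma < mb:
        return "above"
    if mb < ma:
        return "below"
    from lifelines.utils import restricted_mean_survival_time

    t = np.asarray(times, dtype=float)
    e = np.asarray(events).astype(bool)
    horizon = float(t.max())
    kmf_b = KaplanMeierFitter().fit(t[~above], e[~above])
    kmf_a = KaplanMeierFitter().fit(t[above], e[above])
    rm_b = restricted_mean_survival_time(kmf_b, t=horizon)
    rm_a = restricted_mean_survival_time(kmf_a, t=horizon)
    return "above" if rm_a < rm_b else "below"


def run_univariate_screen(
    table: pd.DataFrame,
    endpoint: str,
    markers: Sequence[str],
    q: float = 0.30,
) -> tuple[list[MarkerResult], list[dict]]:
    """Median-split KM + log-rank screen of every marker at one endpoint.

    ``endpoint`` is "pfs" or "os"; the table must carry
    ``{endpoint}_months`` and ``{endpoint}_event`` columns.  One BH family
    spans all markers tested at this endpoint.  Markers with a degenerate
    split (or other per-marker failures) are skipped and logged, not dropped
    silently.

    Returns ``(results, skip_log)`` with results ordered as the input marker
    list.
    """
    endpoint = endpoint.lower()
    tcol, ecol = f"{endpoint}_months", f"{endpoint}_event"
    if tcol not in table.columns or ecol not in table.columns:
        raise ValueError(f"table lacks {tcol}/{ecol} columns")

    results: list[MarkerResult] = []
    skip_log: list[dict] = []
    for marker in markers:
        values = table[marker].to_numpy(dtype=float)
        finite = np.isfinite(values)
        try:
            threshold, above, n_missing = dichotomize_at_median(values)
        except DegenerateSplitError as exc:
            skip_log.append({"marker": marker, "endpoint": endpoint, "reason": str(exc)})
            continue
        t = table[tcol].to_numpy(dtype=float)[finite]
        e = table[ecol].to_numpy()[finite].astype(bool)
        try:
            stat, p = logrank_test(t[~above], e[~above], t[above], e[above])
        except ValueError as exc:
            skip_log.append({"marker": marker, "endpoint": endpoint, "reason": str(exc)})
            continue
        km_below = km_estimate(t[~above], e[~above])
        km_above = km_estimate(t[above], e[above])
        direction = _poor_direction(km_below, km_above, t, e, above)
        results.append(
            MarkerResult(
                marker=marker,
                endpoint=endpoint,
                threshold=threshold,
                poor_prognosis=direction,
                n_below=km_below.n,
                n_above=km_above.n,
                median_below=km_below.median,
                median_above=km_above.median,
                p_raw=p,
                n_missing=n_missing,
            )
        )

    if results:
        adjusted, reject = bh_adjust([r.p_raw for r in results], q=q)
        for r, pa, sig in zip(results, adjusted, reject):
            r.p_adjusted = float(pa)
            r.significant = bool(sig)
    return results, skip_log


# ---------------------------------------------------------------------------
# Estimator façades
# ---------------------------------------------------------------------------

class MedianSplitScreen(BaseEstimator):
    """Univariate prognostic screen as a scikit-learn style estimator.

    ``fit(X, y)`` takes the marker matrix ``X`` (DataFrame, one row per
    patient) and a structured outcome ``y = (times, events)``.  Fitted
    attributes: ``results_`` (DataFrame shaped like the study's summary
    tables), ``significant_`` (marker names passing BH), ``skip_log_``.
    """

    def __init__(self, q: float = 0.30, endpoint: str = "os") -> None:
        self.q = q
        self.endpoint = endpoint

    def fit(self, X: pd.DataFrame, y: tuple[Sequence[float], Sequence[bool]]):
        times, events = y
        table = X.copy()
        table[f"{self.endpoint}_months"] = np.asarray(times, dtype=float)
        table[f"{self.endpoint}_event"] = np.asarray(events).astype(int)
        res, skip = run_univariate_screen(
            table, self.endpoint, list(X.columns), q=self.q
        )
        self.marker_results_ = res
        self.results_ = pd.DataFrame([r.to_row() for r in res])
        self.significant_ = [r.marker for r in res if r.significant]
        self.skip_log_ = skip
        return self


class ForwardWaldCoxSelector(BaseEstimator):
    """Forward-Wald stepwise Cox selection as an estimator.

    ``fit(X, y)`` with candidate (typically median-dichotomized binary)
    covariates ``X`` and ``y = (times, events)``.  Fitted attributes:
    ``selected_``, ``summary_`` (coef/HR/CI/Wald p), ``trace_``.
    """

    def __init__(self, entry_p: float = 0.05, ties: str = "breslow") -> None:
        self.entry_p = entry_p
        self.ties = ties

    def fit(self, X: pd.DataFrame, y: tuple[Sequence[float], Sequence[bool]]):
        times, events = y
        result = forward_wald_select(
            pd.DataFrame(X), times, events, entry_p=self.entry_p, ties=self.ties
        )
        self.result_ = result
        self.selected_ = result.covariates
        self.summary_ = result.summary()
        self.trace_ = result.trace
        return self
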