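"""Assay-level statistics: limiting-dilution (ELDA-style) stem-cell frequency,
IHC H-score, multiplex subtype calling, Kaplan-Meier / log-rank, and
relative-signal normalization.

The limiting-dilution model is the single-hit Poisson: a well seeded with x
cells responds with probability 1 - exp(-f x), where f is the frequency of
response-competent (stem) cells. f is estimated by a binomial GLM with a
complementary log-log link and offset log(x), the standard ELDA formulation.
"""

from __future__ import annotations

import dataclasses
import logging

import numpy as np
import pandas as pd
import statsmodels.api as sm
from lifelines import KaplanMeierFitter
from scipy import optimize, stats
from sklearn.base import BaseEstimator

logger = logging.getLogger(__name__)


@dataclasses.dataclass
class FrequencyEstimate:
    """Active-cell frequency with 95% CI; boundary tables carry one-sided bounds."""

    f_hat: float
    ci_lower: float
    ci_upper: float
    log_likelihood: float
    boundary: bool = False


def _validate_dilution(table: pd.DataFrame) -> pd.DataFrame:
    required = ["cells_per_well", "wells_tested", "wells_responding"]
    missing = [c for c in required if c not in table.columns]
    if missing:
        raise ValueError(f"dilution table missing columns {missing}")
    if table.empty:
        raise ValueError("empty dilution table")
    t = table[required].astype(float)
    if (t["wells_tested"] <= 0).any():
        raise ValueError("wells_tested must be positive")
    if ((t["wells_responding"] < 0) |
            (t["wells_responding"] > t["wells_tested"])).any():
        raise ValueError("wells_responding must lie in [0, wells_tested]")
    zero = t[t["cells_per_well"] == 0]
    if (zero["wells_responding"] > 0).any():
        raise ValueError("dose-0 wells must have 0 responders")
    pos = t[t["cells_per_well"] > 0]
    if pos.empty:
        raise ValueError("need at least one row with cells_per_well > 0")
    return pos


def _dilution_loglik(f: float, x, n, k) -> float:
    p = np.clip(1.0 - np.exp(-f * x), 1e-300, 1.0 - 1e-15)
    return float(np.sum(k * np.log(p) + (n - k) * np.log1p(-p)))


def elda_fit(table: pd.DataFrame, ci_method: str = "wald") -> FrequencyEstimate:
    """Single-hit frequency estimate from a limiting-dilution plate.

    Dose-0 rows are consistency-checked (must have 0 responders) then
    excluded. All-negative or all-positive plates put the MLE on the
    boundary: they return a one-sided 95% bound (solved from the exact
    likelihood) with the boundary flag set. Otherwise the complementary
    log-log binomial GLM yields f = exp(intercept) with a Wald 95% CI on
    log f; ``ci_method="profile"`` replaces it with a profile-likelihood CI.
    """
    pos = _validate_dilution(table)
    x = pos["cells_per_well"].to_numpy(dtype=float)
    n = pos["wells_tested"].to_numpy(dtype=float)
    k = pos["wells_responding"].to_numpy(dtype=float)

    if k.sum() == 0:  # all negative: f_hat on the lower boundary
        # one-sided upper bound: P(all wells negative | f) = 0.05
        upper = -np.log(0.05) / float((x * n).sum())
        return FrequencyEstimate(0.0, 0.0, min(upper, 1.0),
                                 _dilution_loglik(1e-12, x, n, k), boundary=True)
    if (k == n).all():  # all positive: f_hat on the upper boundary
        def all_pos_prob(f):
            return _dilution_loglik(f, x, n, k) - np.log(0.05)
        try:
            lower = optimize.brentq(all_pos_prob, 1e-12, 1.0)
        except ValueError:
            lower = 0.0
        return FrequencyEstimate(1.0, lower, 1.0,
                                 _dilution_loglik(1.0, x, n, k), boundary=True)

    endog = np.column_stack([k, n - k])
    exog = np.ones((len(pos), 1))
    model = sm.GLM(endog, exog, family=sm.families.Binomial(
        link=sm.families.links.CLogLog()), offset=np.log(x))
    fit = model.fit(maxiter=200, tol=1e-10)
    log_f = float(fit.params[0])
    se = float(fit.bse[0])
    f_hat = float(np.exp(log_f))
    if ci_method == "wald":
        zcrit = stats.norm.ppf(0.975)
        ci = (float(np.exp(log_f - zcrit * se)), float(np.exp(log_f + zcrit * se)))
    elif ci_method == "profile":
        ci = _profile_ci(f_hat, x, n, k)
    else:
        raise ValueError(f"unknown ci_method {ci_method!r}")
    return FrequencyEstimate(f_hat, min(ci[0], 1.0), min(ci[1], 1.0),
                             float(fit.llf), boundary=False)


def _profile_ci(f_hat: float, x, n, k, level: float = 0.95) -> tuple:
    target = _dilution_loglik(f_hat, x, n, k) - stats.chi2.ppf(level, 1) / 2.0

    def deficit(log_f):
        return _dilution_loglik(np.exp(log_f), x, n, k) - target

    lo_bracket = np.log(max(f_hat, 1e-12)) - 15
    hi_bracket = min(np.log(max(f_hat, 1e-12)) + 15, 0.0)
    try:
        lo = float(np.exp(optimize.brentq(deficit, lo_bracket,
                                          np.log(f_hat))))
    except ValueError:
        lo = 0.0
    try:
        hi = float(np.exp(optimize.brentq(deficit, np.log(f_hat), hi_bracket)))
    except ValueError:
        hi = 1.0
    return lo, hi


class LimitingDilutionModel(BaseEstimator):
    """Sklearn-style wrapper over :func:`elda_fit`.

    fit(table) sets ``frequency_``, ``ci_`` and ``boundary_``.
    """

    def __init__(self, ci_method: str = "wald"):
        self.ci_method = ci_method

    def fit(self, table: pd.DataFrame, y=None):
        est = elda_fit(table, ci_method=self.ci_method)
        self.frequency_ = est.f_hat
        self.ci_ = (est.ci_lower, est.ci_upper)
        self.boundary_ = est.boundary
        self.log_likelihood_ = est.log_likelihood
        return self


def elda_compare(a: pd.DataFrame, b: pd.DataFrame) -> dict:
    """Likelihood-ratio test of equal stem-cell frequency (1 df).

    Compares the pooled single-frequency model against separate frequencies;
    symmetric in its arguments.
    """
    ll_sep = 0.0
    for t in (a, b):
        pos = _validate_dilution(t)
        f = _mle_frequency(pos)
        ll_sep += _dilution_loglik(f, pos["cells_per_well"].to_numpy(float),
                                   pos["wells_tested"].to_numpy(float),
                                   pos["wells_responding"].to_numpy(float))
    pooled = pd.concat([a, b], ignore_index=True)
    pos = _validate_dilution(pooled)
    f0 = _mle_frequency(pos)
    ll_pool = _dilution_loglik(f0, pos["cells_per_well"].to_numpy(float),
                               pos["wells_tested"].to_numpy(float),
                               pos["wells_responding"].to_numpy(float))
    chi2 = max(0.0, 2.0 * (ll_sep - ll_pool))
    return {"chi2": float(chi2), "p": float(stats.chi2.sf(chi2, 1))}


def _mle_frequency(pos: pd.DataFrame) -> float:
    x = pos["cells_per_well"].to_numpy(float)
    n = pos["wells_tested"].to_numpy(float)
    k = pos["wells_responding"].to_numpy(float)
    if k.sum() == 0:
        return 1e-12
    if (k == n).all():
        return 1.0
    res = optimize.minimize_scalar(
        lambda log_f: -_dilution_loglik(np.exp(log_f), x, n, k),
        bounds=(np.log(1e-9), 0.0), method="bounded",
        options={"xatol": 1e-12})
    return float(np.exp(res.x))


# ---------------------------------------------------------------------------
# H-score
# ---------------------------------------------------------------------------

def h_score(p_weak: float, p_moderate: float, p_strong: float,
            p_negative: float | None = None) -> float:
    """IHC H-score: 100*weak + 200*moderate + 300*strong area fractions.

    Fractions are of total area and must sum to 1 together with the negative
    fraction (inferred when omitted). The score lies in [0, 300].
    """
    fracs = [p_weak, p_moderate, p_strong]
    if p_negative is None:
        p_negative = 1.0 - sum(fracs)
        if p_negative < -1e-9:
            raise ValueError("intensity fractions sum to more than 1")
        p_negative = max(p_negative, 0.0)
    all_fracs = np.asarray(fracs + [p_negative], dtype=float)
    if ((all_fracs < -1e-9) | (all_fracs > 1 + 1e-9)).any():
        raise ValueError("area fractions must lie in [0, 1]")
    if abs(all_fracs.sum() - 1.0) > 1e-9:
        raise ValueError("area fractions must sum to 1")
    return float(100.0 * p_weak + 200.0 * p_moderate + 300.0 * p_strong)


# ---------------------------------------------------------------------------
# Subtype calling from multiplex markers
# ---------------------------------------------------------------------------

MES_CALL_MARKERS = ("CD44", "YKL40")
PN_CALL_MARKERS = ("SOX2", "OLIG2")


def call_subtype(marker_values: pd.DataFrame) -> pd.DataFrame:
    """Call MES vs PN per sample from multiplex marker intensities.

    Each marker is z-scored across samples; a sample is MES when its mean
    MES-marker z exceeds its mean PN-marker z, otherwise PN (exact ties go to
    PN by convention and are flagged). The margin (MES z - PN z) is reported.
    """
    needed = list(MES_CALL_MARKERS + PN_CALL_MARKERS)
    missing = [m for m in needed if m not in marker_values.columns]
    if missing:
        raise ValueError(f"missing markers {missing}")
    sub = marker_values[needed].astype(float)
    sd = sub.std(ddof=0)
    if (sd == 0).any():
        bad = sd.index[sd == 0].tolist()
        raise ValueError(f"zero-variance markers: {bad}")
    z = (sub - sub.mean()) / sd
    mes = z[list(MES_CALL_MARKERS)].mean(axis=1)
    pn = z[list(PN_CALL_MARKERS)].mean(axis=1)
    margin = mes - pn
    return pd.DataFrame({
        "subtype": np.where(margin > 0, "MES", "PN"),
        "margin": margin,
        "tie": margin == 0,
    }, index=marker_values.index)


# ---------------------------------------------------------------------------
# Survival
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class SurvivalComparison:
    """Per-group Kaplan-Meier curves with the log-rank chi-square and p."""

    km_curves: dict      # group -> survival step function (DataFrame)
    chi2: float
    p: float


def logrank_chi2(times, events, groups) -> tuple[float, float]:
    """Standard two-group log-rank chi-square (1 df) and its p-value.

    Tied event times are handled by simultaneous risk-set accounting
    (hypergeometric variance with the (N-d)/(N-1) tie correction).
    """
    t = np.asarray(times, dtype=float)
    e = np.asarray(events, dtype=int)
    g = np.asarray(groups)
    names = np.unique(g)
    if names.size != 2:
        raise ValueError(f"need exactly two groups, got {names.tolist()}")
    in_a = g == names[0]
    event_times = np.unique(t[e == 1])
    t_sorted = np.sort(t)
    ta_sorted = np.sort(t[in_a])
    n_risk = t.size - np.searchsorted(t_sorted, event_times, side="left")
    na_risk = ta_sorted.size - np.searchsorted(ta_sorted, event_times,
                                               side="left")
    d = np.array([np.sum((t == et) & (e == 1)) for et in event_times],
                 dtype=float)
    da = np.array([np.sum((t == et) & (e == 1) & in_a) for et in event_times],
                  dtype=float)
    frac_a = na_risk / n_risk
    expected = d * frac_a
    with np.errstate(invalid="ignore", divide="ignore"):
        var = d * frac_a * (1.0 - frac_a) * (n_risk - d) / \
            np.maximum(n_risk - 1.0, 1.0)
    var = np.where(n_risk > 1, var, 0.0)
    total_var = var.sum()
    if total_var == 0:
        return 0.0, 1.0
    u = float((da - expected).sum())
    chi2 = u * u / float(total_var)
    return chi2, float(stats.chi2.sf(chi2, 1))


def km_logrank(times, events, groups) -> SurvivalComparison:
    """Kaplan-Meier estimates per group plus the standard 1-df log-rank test."""
    df = pd.DataFrame({"time": np.asarray(times, dtype=float),
                       "event": np.asarray(events, dtype=int),
                       "group": np.asarray(groups)})
    names = sorted(df["group"].unique())
    if len(names) != 2:
        raise ValueError(f"need exactly two groups, got {names}")
    curves = {}
    for name, sub in df.groupby("group"):
        if sub["event"].sum() == 0:
            raise ValueError(f"group {name!r} has no events")
        kmf = KaplanMeierFitter()
        kmf.fit(sub["time"], event_observed=sub["event"], label=str(name))
        curves[name] = kmf.survival_function_
    chi2, p = logrank_chi2(df["time"], df["event"], df["group"])
    return SurvivalComparison(km_curves=curves, chi2=chi2, p=p)


def relative_signal(series) -> np.ndarray:
    """Normalize an ordered positive series to its first value."""
    arr = np.asarray(series, dtype=float)
    if arr.size == 0:
        raise ValueError("empty series")
    if arr[0] <= 0:
        raise ValueError("first value must be positive")
    return arr / arr[0]
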