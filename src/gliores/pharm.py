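"""Dose-response modelling, IC50 screening and ZIP drug-synergy scoring.

Inhibition is modelled with a four-parameter log-logistic curve
y(d) = L + (U - L) * d^h / (d^h + m^h) on a percentage scale. IC50 is the
smallest dose with 50% inhibition (undefined when the upper asymptote never
reaches 50). The ZIP synergy score compares observed combination inhibition
against the Bliss-style expectation built from the fitted monotherapy
margins: y_zip(a, b) = yA(a) + yB(b) - yA(a) * yB(b); the summary score is
the mean delta (observed - expected, percentage points) over all
strictly-positive dose pairs.
"""

from __future__ import annotations

import dataclasses
import logging

import numpy as np
import pandas as pd
from scipy import optimize, stats
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.utils.validation import check_is_fitted
from statsmodels.stats.multitest import multipletests

from .subclusters import mean_sem_grouping

logger = logging.getLogger(__name__)


@dataclasses.dataclass
class DoseResponseCurve:
    """Fitted log-logistic curve on the inhibition-percentage scale."""

    slope: float          # h > 0
    midpoint: float       # m > 0, dose units
    lower: float          # L, inhibition at dose 0
    upper: float          # U, asymptotic inhibition
    rss: float = float("nan")
    converged: bool = True

    def predict(self, doses) -> np.ndarray:
        d = np.asarray(doses, dtype=float)
        with np.errstate(divide="ignore", invalid="ignore"):
            frac = d ** self.slope / (d ** self.slope + self.midpoint ** self.slope)
        frac = np.where(d == 0, 0.0, frac)
        return self.lower + (self.upper - self.lower) * frac


@dataclasses.dataclass
class DoseResponseMatrix:
    """Inhibition-percentage grid over two dose axes, each including 0.

    Entries are clamped to [0, 100] for analysis; the raw grid is preserved.
    """

    doses_a: np.ndarray
    doses_b: np.ndarray
    raw: np.ndarray

    def __post_init__(self) -> None:
        self.doses_a = np.asarray(self.doses_a, dtype=float)
        self.doses_b = np.asarray(self.doses_b, dtype=float)
        self.raw = np.asarray(self.raw, dtype=float)
        for name, d in (("A", self.doses_a), ("B", self.doses_b)):
            if d[0] != 0.0 or (np.diff(d) <= 0).any():
                raise ValueError(f"agent-{name} doses must increase strictly from 0")
        if self.raw.shape != (self.doses_a.size, self.doses_b.size):
            raise ValueError("grid shape does not match dose vectors")
        if not np.isfinite(self.raw).all():
            raise ValueError("inhibition grid contains non-finite entries")
        self.inhibition = np.clip(self.raw, 0.0, 100.0)


@dataclasses.dataclass
class SynergyResult:
    """ZIP delta matrix over positive dose pairs plus its mean summary score."""

    delta: pd.DataFrame       # positive doses_a x positive doses_b, pp
    summary: float            # mean of delta entries, percentage points
    curve_a: DoseResponseCurve
    curve_b: DoseResponseCurve
    converged: bool = True


class LogLogisticModel(BaseEstimator, RegressorMixin):
    """Sklearn-style wrapper for bounded multi-start log-logistic fitting.

    Parameters fix or bound the asymptotes: ``lower_fixed`` pins L (default
    0), ``upper_max`` caps U (default 100, U free below the cap). Fitted
    attributes: ``curve_`` and ``ic50_`` (None when undefined).
    """

    def __init__(self, lower_fixed: float | None = 0.0, upper_max: float = 100.0,
                 n_starts: int = 5, random_state: int = 0):
        self.lower_fixed = lower_fixed
        self.upper_max = upper_max
        self.n_starts = n_starts
        self.random_state = random_state

    def fit(self, X, y):
        doses = np.asarray(X, dtype=float).ravel()
        self.curve_ = fit_loglogistic(doses, np.asarray(y, dtype=float),
                                      lower_fixed=self.lower_fixed,
                                      upper_max=self.upper_max,
                                      n_starts=self.n_starts,
                                      seed=self.random_state)
        self.ic50_ = ic50(self.curve_)
        return self

    def predict(self, X):
        check_is_fitted(self, "curve_")
        return self.curve_.predict(np.asarray(X, dtype=float).ravel())


def fit_loglogistic(doses, inhibitions, lower_fixed: float | None = 0.0,
                    upper_max: float = 100.0, n_starts: int = 5,
                    seed: int = 0) -> DoseResponseCurve:
    """Bounded least-squares fit of the log-logistic inhibition curve.

    Multi-start (``n_starts`` seeded initializations) trust-region fitting;
    non-convergence or a flat response yields a flagged result rather than an
    exception. Requires >=3 distinct doses including 0.
    """
    doses = np.asarray(doses, dtype=float)
    y = np.asarray(inhibitions, dtype=float)
    if doses.shape != y.shape:
        raise ValueError("doses and inhibitions must align")
    if np.unique(doses).size < 3 or 0.0 not in doses:
        raise ValueError("need >=3 distinct doses including 0")
    if (doses < 0).any():
        raise ValueError("doses must be nonnegative")

    if np.ptp(y) < 1e-9:  # flat response: degenerate fit, flagged
        level = float(y.mean())
        return DoseResponseCurve(slope=1.0,
                                 midpoint=float(np.median(doses[doses > 0])),
                                 lower=level if lower_fixed is None else lower_fixed,
                                 upper=level, rss=0.0, converged=False)

    fit_lower = lower_fixed is None
    pos = doses[doses > 0]

    def unpack(theta):
        h, log_m = theta[0], theta[1]
        upper = theta[2]
        lower = theta[3] if fit_lower else lower_fixed
        return DoseResponseCurve(h, float(np.exp(log_m)), lower, upper)

    def residuals(theta):
        return unpack(theta).predict(doses) - y

    rng = np.random.default_rng(seed)
    best = None
    lo = [1e-3, np.log(pos.min() / 10.0), 1.0] + ([0.0] if fit_lower else [])
    hi = [20.0, np.log(pos.max() * 10.0), upper_max] + \
        ([upper_max] if fit_lower else [])
    for start in range(n_starts):
        h0 = 1.0 if start == 0 else float(rng.uniform(0.5, 4.0))
        m0 = float(np.median(pos)) if start == 0 else \
            float(rng.choice(pos) * rng.uniform(0.5, 2.0))
        u0 = min(max(float(y.max()), 2.0), upper_max)
        theta0 = [h0, np.log(m0), u0] + ([max(float(y.min()), 0.0)]
                                         if fit_lower else [])
        try:
            res = optimize.least_squares(residuals, theta0, bounds=(lo, hi),
                                         method="trf", max_nfev=2000)
        except Exception:  # pragma: no cover - scipy failures are flagged below
            continue
        if best is None or res.cost < best.cost:
            best = res
    if best is None:
        return DoseResponseCurve(1.0, float(np.median(pos)), 0.0,
                                 float(y.max()), rss=float("inf"),
                                 converged=False)
    curve = unpack(best.x)
    curve.rss = float(2.0 * best.cost)
    curve.converged = bool(best.success)
    return curve


def ic50(curve: DoseResponseCurve) -> float | None:
    """Smallest dose with 50% inhibition; None (undefined) when U <= 50."""
    if curve.upper <= 50.0:
        return None
    if curve.lower >= 50.0:
        return 0.0
    frac = (50.0 - curve.lower) / (curve.upper - curve.lower)
    return float(curve.midpoint * (frac / (1.0 - frac)) ** (1.0 / curve.slope))


def ic50_from_viability(doses, viability, **fit_kwargs) -> tuple:
    """Convenience: inhibition = 100 - viability %, fit, return (ic50, curve)."""
    inhibition = 100.0 - np.asarray(viability, dtype=float)
    curve = fit_loglogistic(np.asarray(doses, dtype=float),
                            np.clip(inhibition, 0.0, 100.0), **fit_kwargs)
    return ic50(curve), curve


# ---------------------------------------------------------------------------
# Differential-IC50 screen
# ---------------------------------------------------------------------------

def differential_ic50_screen(ic50_table: pd.DataFrame, driver_expr: pd.Series,
                             alpha: float = 0.05,
                             max_undefined_frac: float = 0.5) -> pd.DataFrame:
    """Screen drugs for selective potency in high-driver cell lines.

    Lines are split high/low/intermediate by mean±SEM on driver expression
    (intermediate lines excluded). Per drug: Welch t on log10 IC50 between
    groups, log2 fold change (high over low), BH FDR, and a sensitivity flag
    (lower IC50 in the high-driver group AND p < alpha). Drugs with undefined
    IC50 in more than ``max_undefined_frac`` of lines are dropped and logged.

    ``ic50_table`` is lines x drugs (NaN = undefined IC50).
    """
    driver_expr = driver_expr.reindex(ic50_table.index)
    groups = mean_sem_grouping(driver_expr)
    high = groups.index[groups == "high"]
    low = groups.index[groups == "low"]
    if len(high) < 2 or len(low) < 2:
        raise ValueError("need >=2 lines per group after mean±SEM grouping "
                         f"(high={len(high)}, low={len(low)})")
    rows = []
    for drug in ic50_table.columns:
        vals = ic50_table[drug]
        if vals.isna().mean() > max_undefined_frac:
            logger.info("drug %s: IC50 undefined in >%.0f%% of lines; dropped",
                        drug, 100 * max_undefined_frac)
            continue
        hi_vals = np.log10(vals.loc[high].dropna().astype(float))
        lo_vals = np.log10(vals.loc[low].dropna().astype(float))
        if len(hi_vals) < 2 or len(lo_vals) < 2:
            logger.info("drug %s: <2 defined IC50 per group; dropped", drug)
            continue
        t, p = stats.ttest_ind(hi_vals, lo_vals, equal_var=False)
        log2fc = float((hi_vals.mean() - lo_vals.mean()) / np.log10(2.0))
        rows.append((drug, log2fc, float(p)))
    table = pd.DataFrame(rows, columns=["drug", "log2fc", "p"]).set_index("drug")
    if table.empty:
        return table.assign(fdr=[], msn_sensitive=[])
    table["fdr"] = multipletests(table["p"].to_numpy(), method="fdr_bh")[1]
    table["msn_sensitive"] = (table["log2fc"] < 0) & (table["p"] < alpha)
    return table


def filter_bbb(screen: pd.DataFrame, bbb_flags: pd.Series) -> pd.DataFrame:
    """Restrict the sensitive hits to drugs that cross the blood-brain barrier."""
    missing = [d for d in screen.index if d not in bbb_flags.index]
    if missing:
        raise ValueError(f"missing BBB flags for drugs {missing[:5]}")
    flags = bbb_flags.reindex(screen.index).astype(bool)
    out = screen.copy()
    out["bbb"] = flags
    return out[out["msn_sensitive"] & out["bbb"]]


# ---------------------------------------------------------------------------
# ZIP synergy
# ---------------------------------------------------------------------------

def zip_delta(matrix: DoseResponseMatrix, refit_margins: bool = False
              ) -> SynergyResult:
    """ZIP synergy: observed combination inhibition minus the Bliss expectation
    of the fitted monotherapy margins.

    Margins (row B=0 and column A=0) are fitted as log-logistic fractions;
    delta is reported in percentage points over strictly-positive dose pairs
    and summarized by its arithmetic mean. With ``refit_margins`` the
    expectation averages, per combination, the two curves re-fitted along
    that row and column (closer to the full ZIP formulation).
    """
    if matrix.doses_a.size < 3 or matrix.doses_b.size < 3:
        raise ValueError("each monotherapy margin needs >=3 doses")
    mono_a = matrix.inhibition[:, 0]
    mono_b = matrix.inhibition[0, :]
    curve_a = fit_loglogistic(matrix.doses_a, mono_a)
    curve_b = fit_loglogistic(matrix.doses_b, mono_b)
    converged = curve_a.converged and curve_b.converged
    if not converged:
        logger.warning("monotherapy margin fit did not converge; "
                       "synergy result flagged")
    pos_a = matrix.doses_a[1:]
    pos_b = matrix.doses_b[1:]
    ya = curve_a.predict(pos_a) / 100.0
    yb = curve_b.predict(pos_b) / 100.0
    if refit_margins:
        expected = _refit_expectation(matrix) * 100.0
    else:
        expected = (ya[:, None] + yb[None, :] - ya[:, None] * yb[None, :]) * 100.0
    observed = matrix.inhibition[1:, 1:]
    delta = pd.DataFrame(observed - expected, index=pos_a, columns=pos_b)
    return SynergyResult(delta=delta, summary=float(delta.to_numpy().mean()),
                         curve_a=curve_a, curve_b=curve_b, converged=converged)


def _refit_expectation(matrix: DoseResponseMatrix) -> np.ndarray:
    """Average of row-wise and column-wise refitted ZIP expectations."""
    na, nb = matrix.doses_a.size - 1, matrix.doses_b.size - 1
    exp_rows = np.empty((na, nb))
    exp_cols = np.empty((na, nb))
    for j in range(1, nb + 1):  # fix B dose, refit response along A
        curve = fit_loglogistic(matrix.doses_a, matrix.inhibition[:, j],
                                lower_fixed=None)
        exp_cols[:, j - 1] = curve.predict(matrix.doses_a[1:]) / 100.0
    for i in range(1, na + 1):
        curve = fit_loglogistic(matrix.doses_b, matrix.inhibition[i, :],
                                lower_fixed=None)
        exp_rows[i - 1, :] = curve.predict(matrix.doses_b[1:]) / 100.0
    return (exp_rows + exp_cols) / 2.0


def select_optimal_combo(result: SynergyResult, inhibition: DoseResponseMatrix,
                         min_inhibition: float = 50.0) -> dict:
    """Pick the dose pair with maximal ZIP delta among sufficiently potent combos.

    Qualifying combos reach ``min_inhibition`` percent observed inhibition;
    ties on delta break toward lower toxicity, i.e. lower partner-drug (B)
    dose first, then lower primary (A) dose. If nothing qualifies, the
    best-available pair is returned with a warning flag.
    """
    delta = result.delta
    if delta.empty:
        raise ValueError("empty delta matrix")
    obs = pd.DataFrame(inhibition.inhibition[1:, 1:], index=delta.index,
                       columns=delta.columns)
    records = []
    for a in delta.index:
        for b in delta.columns:
            records.append((float(delta.loc[a, b]), float(obs.loc[a, b]),
                            float(a), float(b)))
    qualified = [r for r in records if r[1] >= min_inhibition]
    warned = not qualified
    pool = qualified or records
    # max delta; ties -> lower B dose, then lower A dose
    best = max(pool, key=lambda r: (r[0], -r[3], -r[2]))
    if warned:
        logger.warning("no combination reaches %.1f%% inhibition; "
                       "reporting best available", min_inhibition)
    return {"dose_a": best[2], "dose_b": best[3], "delta": best[0],
            "inhibition": best[1], "meets_constraint": not warned,
            "rule": f"max delta s.t. inhibition >= {min_inhibition}; "
                    "ties -> lower partner dose, then lower primary dose"}
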