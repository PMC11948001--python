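"""Resistance-signature derivation: cohort stratification, differential
expression, volcano filtering, signature intersection and enrichment.

The driver-discovery chain is: split dead, chemoradiotherapy-treated patients
by survival; split cell lines by treatment-induced apoptosis; run differential
expression in each stratification; volcano-filter both tables into
resistant-up signatures; intersect. A gene surviving the intersection is a
candidate chemoradiotherapy-resistance driver.
"""

from __future__ import annotations

import dataclasses
import logging

import numpy as np
import pandas as pd
from scipy import special, stats
from statsmodels.stats.multitest import multipletests

from .io import ExpressionMatrix

logger = logging.getLogger(__name__)

DIRECTIONS = ("resistant-up", "sensitive-up")


@dataclasses.dataclass(frozen=True)
class GeneSignature:
    """An ordered, unique set of gene ids with a shared direction of effect."""

    genes: tuple
    direction: str
    provenance: str = ""

    def __post_init__(self) -> None:
        if self.direction not in DIRECTIONS:
            raise ValueError(f"direction must be one of {DIRECTIONS}")
        if len(set(self.genes)) != len(self.genes):
            raise ValueError("signature genes must be unique")

    def __len__(self) -> int:
        return len(self.genes)

    def __contains__(self, gene) -> bool:
        return gene in self.genes


def stratify_by_survival(cohort: pd.DataFrame, rule: str = "median",
                         q: float = 0.5) -> pd.DataFrame:
    """Label dead, chemoradiotherapy-treated samples resistant/sensitive by survival.

    Restricts the cohort to samples with vital_status == "dead" and therapy ==
    "chemoradiotherapy", then computes the survival cutoff (median, or the
    ``q`` quantile for rule="quantile"). Resistant = survival strictly below
    the cutoff; samples at or above the cutoff are sensitive (ties go to
    sensitive so the split is deterministic).
    """
    sub = cohort[(cohort["vital_status"] == "dead") &
                 (cohort["therapy"] == "chemoradiotherapy")].copy()
    if len(sub) < 2:
        raise ValueError(
            f"fewer than 2 dead chemoradiotherapy-treated samples ({len(sub)})")
    times = sub["survival_time"].to_numpy(dtype=float)
    if (times <= 0).any():
        raise ValueError("survival times must be positive")
    if np.ptp(times) == 0:
        raise ValueError("all survival times identical: degenerate cutoff")
    if rule == "median":
        cutoff = float(np.median(times))
    elif rule == "quantile":
        cutoff = float(np.quantile(times, q))
    else:
        raise ValueError(f"unknown rule {rule!r}")
    sub["group"] = np.where(times < cutoff, "resistant", "sensitive")
    logger.info("survival split: %d samples restricted from %d; cutoff %.3f; "
                "%d resistant / %d sensitive", len(sub), len(cohort), cutoff,
                (sub["group"] == "resistant").sum(), (sub["group"] == "sensitive").sum())
    return sub


def stratify_by_apoptosis(apoptosis: pd.DataFrame, alpha: float = 0.05
                          ) -> pd.DataFrame:
    """Label each cell line resistant/sensitive by treatment-induced apoptosis.

    A line is resistant when no treated condition shows a significant apoptosis
    increase over its own control (two-sided two-sample t-test on replicate
    fractions, significant iff p < alpha and the treated mean exceeds control).
    Returns a per-line table with the per-condition p-values.
    """
    rows = []
    for line, sub in apoptosis.groupby("line", sort=True):
        control = sub.loc[sub["condition"] == "control", "apoptosis_fraction"]
        if control.empty:
            raise ValueError(f"line {line!r} has no control condition")
        treated_conditions = [c for c in sub["condition"].unique() if c != "control"]
        if not treated_conditions:
            raise ValueError(f"line {line!r} has no treated condition")
        pvals = {}
        significant = False
        for cond in treated_conditions:
            treated = sub.loc[sub["condition"] == cond, "apoptosis_fraction"]
            if len(control) < 2 or len(treated) < 2:
                raise ValueError(
                    f"line {line!r}, condition {cond!r}: need >=2 replicates")
            t, p = stats.ttest_ind(treated, control, equal_var=True)
            pvals[cond] = float(p)
            if p < alpha and treated.mean() > control.mean():
                significant = True
        row = {"line": line, "label": "sensitive" if significant else "resistant"}
        row.update({f"p_{c}": pvals[c] for c in treated_conditions})
        rows.append(row)
    return pd.DataFrame(rows).set_index("line")


# ---------------------------------------------------------------------------
# Differential expression
# ---------------------------------------------------------------------------

def _fit_f_dist(s2: np.ndarray, df: float) -> tuple[float, float]:
    """Moment estimates of the scaled-F prior (d0, s0^2) for variance shrinkage.

    Matches the mean and variance of log(s^2) against the theoretical
    moments of log chi-square variates (digamma/trigamma), the standard
    empirical-Bayes recipe for moderated t statistics.
    """
    s2 = np.maximum(s2, 1e-12)
    z = np.log(s2)
    e = z - special.digamma(df / 2.0) + np.log(df / 2.0)
    e_mean = float(np.mean(e))
    e_var = float(np.var(e, ddof=1)) - float(special.polygamma(1, df / 2.0))
    if e_var <= 0:
        return np.inf, float(np.exp(e_mean))
    # invert trigamma(d0/2) = e_var by bisection on d0
    lo, hi = 1e-3, 1e6
    for _ in range(200):
        mid = np.sqrt(lo * hi)
        if special.polygamma(1, mid / 2.0) > e_var:
            lo = mid
        else:
            hi = mid
    d0 = float(np.sqrt(lo * hi))
    s0_sq = float(np.exp(e_mean + special.digamma(d0 / 2.0) - np.log(d0 / 2.0)))
    return d0, s0_sq


def differential_expression(expr: ExpressionMatrix, labels: pd.Series,
                            method: str = "welch") -> pd.DataFrame:
    """Per-gene resistant-vs-sensitive differential expression on log-scale data.

    log2FC = mean(resistant) - mean(sensitive). p-values come from a Welch
    t-test (default) or a variance-moderated t-test that shrinks per-gene
    sample variances toward an empirical-Bayes prior before forming the
    statistic. FDR is Benjamini-Hochberg over all tested genes; genes with
    zero variance in both groups are dropped (and logged).
    """
    if expr.scale != "lognorm":
        raise ValueError("differential expression expects log-scale expression")
    labels = labels.reindex(expr.samples)
    if labels.isna().any():
        missing = labels.index[labels.isna()].tolist()
        raise ValueError(f"labels missing for samples {missing[:5]}")
    res_cols = labels.index[labels == "resistant"]
    sen_cols = labels.index[labels == "sensitive"]
    if len(res_cols) < 2 or len(sen_cols) < 2:
        raise ValueError("need >=2 samples per group")

    a = expr.data[res_cols].to_numpy(dtype=float)
    b = expr.data[sen_cols].to_numpy(dtype=float)
    n1, n2 = a.shape[1], b.shape[1]
    mean_a, mean_b = a.mean(axis=1), b.mean(axis=1)
    var_a, var_b = a.var(axis=1, ddof=1), b.var(axis=1, ddof=1)
    log2fc = mean_a - mean_b

    keep = (var_a > 0) | (var_b > 0)
    if not keep.all():
        logger.info("dropping %d genes with zero variance in both groups",
                    int((~keep).sum()))

    if method == "welch":
        se2 = var_a / n1 + var_b / n2
        with np.errstate(divide="ignore", invalid="ignore"):
            t = log2fc / np.sqrt(se2)
            df = se2 ** 2 / ((var_a / n1) ** 2 / (n1 - 1) +
                             (var_b / n2) ** 2 / (n2 - 1))
        p = 2.0 * stats.t.sf(np.abs(t), df)
    elif method == "moderated":
        df_resid = n1 + n2 - 2
        s2_pooled = ((n1 - 1) * var_a + (n2 - 1) * var_b) / df_resid
        d0, s0_sq = _fit_f_dist(s2_pooled[keep], df_resid)
        if np.isinf(d0):
            s2_post = np.full_like(s2_pooled, s0_sq)
            df_total = np.inf
        else:
            s2_post = (d0 * s0_sq + df_resid * s2_pooled) / (d0 + df_resid)
            df_total = d0 + df_resid
        with np.errstate(divide="ignore", invalid="ignore"):
            t = log2fc / np.sqrt(s2_post * (1.0 / n1 + 1.0 / n2))
        if np.isinf(df_total):
            p = 2.0 * stats.norm.sf(np.abs(t))
        else:
            p = 2.0 * stats.t.sf(np.abs(t), df_total)
        df = np.full_like(t, df_total)
    else:
        raise ValueError(f"unknown method {method!r}")

    table = pd.DataFrame({
        "log2fc": log2fc,
        "mean_resistant": mean_a,
        "mean_sensitive": mean_b,
        "t": t,
        "df": df,
        "p": p,
    }, index=expr.genes)[keep]
    table["fdr"] = multipletests(table["p"].to_numpy(), method="fdr_bh")[1]
    return table


def volcano_filter(de: pd.DataFrame, lfc_min: float = 0.5, p_max: float = 0.05,
                   direction: str = "resistant-up",
                   provenance: str = "") -> GeneSignature:
    """Volcano-plot filter: |log2FC| >= lfc_min in the stated direction, p <= p_max.

    Boundary comparisons are inclusive: a gene at exactly (lfc_min, p_max)
    is kept.
    """
    if lfc_min <= 0 or p_max <= 0:
        raise ValueError("thresholds must be positive")
    if direction == "resistant-up":
        mask = (de["log2fc"] >= lfc_min) & (de["p"] <= p_max)
    elif direction == "sensitive-up":
        mask = (de["log2fc"] <= -lfc_min) & (de["p"] <= p_max)
    else:
        raise ValueError(f"direction must be one of {DIRECTIONS}")
    genes = tuple(de.index[mask])
    logger.info("volcano filter kept %d / %d genes (%s, lfc>=%g, p<=%g)",
                len(genes), len(de), direction, lfc_min, p_max)
    return GeneSignature(genes, direction, provenance=provenance)


def intersect_signatures(a: GeneSignature, b: GeneSignature) -> GeneSignature:
    """Set intersection of two signatures; directions must agree.

    An empty intersection is allowed (with a warning); a direction mismatch
    yields an empty result since no gene's direction can agree.
    """
    if a.direction != b.direction:
        logger.warning("signature directions disagree (%s vs %s): empty intersection",
                       a.direction, b.direction)
        genes: tuple = ()
    else:
        genes = tuple(g for g in a.genes if g in set(b.genes))
    if not genes:
        logger.warning("signature intersection is empty")
    return GeneSignature(genes, a.direction,
                         provenance=f"({a.provenance} & {b.provenance})")


def correlate_gene(expr: ExpressionMatrix, gene: str, geneset) -> pd.DataFrame:
    """Two-sided Pearson correlation of one gene against each gene in a set."""
    if gene not in expr.genes:
        raise KeyError(f"gene {gene!r} not in matrix")
    if expr.shape[1] < 3:
        raise ValueError("need >=3 samples for correlation")
    x = expr.data.loc[gene].to_numpy(dtype=float)
    if np.ptp(x) == 0:
        raise ValueError(f"gene {gene!r} has zero variance")
    rows = []
    for g in geneset:
        if g not in expr.genes:
            logger.info("correlate_gene: %s absent from matrix, skipped", g)
            continue
        y = expr.data.loc[g].to_numpy(dtype=float)
        if np.ptp(y) == 0:
            logger.info("correlate_gene: %s has zero variance, skipped", g)
            continue
        r, p = stats.pearsonr(x, y)
        rows.append((g, float(r), float(p)))
    return pd.DataFrame(rows, columns=["gene", "r", "p"]).set_index("gene")


def preranked_enrichment(ranked_stats: pd.Series, geneset, n_perm: int = 1000,
                         seed: int = 0) -> dict:
    """Weighted Kolmogorov-Smirnov preranked enrichment with permutation p.

    The running sum walks the ranking (descending by statistic); hits advance
    by |stat| (normalized), misses retreat uniformly. The enrichment score is
    the extremum of the running sum (sign reported). The p-value compares
    |ES| against ``n_perm`` random gene sets of the same size (gene-label
    permutation), with the +1 small-sample correction.
    """
    if n_perm <= 0:
        raise ValueError("n_perm must be positive")
    stats_arr = ranked_stats.astype(float)
    if not np.isfinite(stats_arr.to_numpy()).all():
        raise ValueError("ranking statistics must be finite")
    universe = list(stats_arr.index)
    hits = [g for g in geneset if g in set(universe)]
    if not hits:
        raise ValueError("geneset does not intersect the ranked universe")
    order = stats_arr.sort_values(ascending=False, kind="mergesort")
    is_hit = np.isin(order.index.to_numpy(), np.asarray(hits, dtype=object))
    es = _running_es(order.to_numpy(), is_hit)

    rng = np.random.default_rng(seed)
    k = int(is_hit.sum())
    null = np.empty(n_perm)
    vals = order.to_numpy()
    n = len(vals)
    for i in range(n_perm):
        perm_hit = np.zeros(n, dtype=bool)
        perm_hit[rng.choice(n, size=k, replace=False)] = True
        null[i] = _running_es(vals, perm_hit)
    p = (1.0 + np.sum(np.abs(null) >= abs(es))) / (n_perm + 1.0)
    return {"es": float(es), "p": float(p), "n_hits": k, "n_perm": n_perm}


def _running_es(values: np.ndarray, is_hit: np.ndarray) -> float:
    w = np.abs(values)
    hit_w = np.where(is_hit, w, 0.0)
    total_hit = hit_w.sum()
    if total_hit == 0:  # all hit stats are zero: fall back to unweighted steps
        hit_w = is_hit.astype(float)
        total_hit = hit_w.sum()
    n_miss = (~is_hit).sum()
    p_hit = np.cumsum(hit_w) / total_hit
    p_miss = np.cumsum(~is_hit) / max(n_miss, 1)
    running = p_hit - p_miss
    return float(running[np.argmax(np.abs(running))])
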