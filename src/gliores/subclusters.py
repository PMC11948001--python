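"""Cluster-level driver scoring, mean±SEM grouping and marker detection.

Glioma subclusters are scored on two axes: mean driver-gene expression and
enrichment of the chemoradiotherapy-resistance signature. On each axis,
clusters above mean + SEM of the cluster-level values are "high", below
mean - SEM "low", and everything else intermediate (strict inequalities, so
boundary clusters stay intermediate). Intersecting the two axes isolates the
high-driver resistant subclusters.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io import ExpressionMatrix
from .signature import GeneSignature

logger = logging.getLogger(__name__)


def cluster_mean_expression(expr: ExpressionMatrix, clusters: pd.Series,
                            gene: str) -> pd.Series:
    """Arithmetic mean of one gene's log-normalized expression per cluster."""
    if gene not in expr.genes:
        raise KeyError(f"gene {gene!r} not in matrix")
    values = expr.to_lognorm().data.loc[gene]
    clusters = clusters.reindex(values.index)
    if clusters.isna().any():
        raise ValueError("every cell needs a cluster label")
    return values.groupby(clusters).mean().rename(gene)


def mean_sem_grouping(values: pd.Series, high_label: str = "high",
                      low_label: str = "low",
                      mid_label: str = "intermediate") -> pd.Series:
    """Classify each value as high (> mean + SEM), low (< mean - SEM) or intermediate.

    SEM is computed across the supplied values themselves (sample SD / sqrt(k),
    k = number of values). Inequalities are strict: values exactly at a
    boundary — including every value when the vector is constant, where
    SEM = 0 — are intermediate.
    """
    vals = values.astype(float)
    k = len(vals)
    if k < 2:
        raise ValueError("need >=2 values for a mean±SEM split")
    mean = float(vals.mean())
    sem = float(vals.std(ddof=1)) / np.sqrt(k)
    out = pd.Series(mid_label, index=vals.index, dtype=object)
    out[vals > mean + sem] = high_label
    out[vals < mean - sem] = low_label
    return out


def signature_score_clusters(expr: ExpressionMatrix, clusters: pd.Series,
                             signature: GeneSignature,
                             method: str = "mean_z") -> pd.Series:
    """Per-cluster enrichment score of a gene signature.

    Default "mean_z": z-score each signature gene across all cells, average
    over signature genes per cell, then average within cluster. Signature
    genes absent from the matrix are logged and skipped; constant genes
    contribute 0.
    """
    if method != "mean_z":
        raise ValueError(f"unknown method {method!r}")
    logdata = expr.to_lognorm().data
    present = [g for g in signature.genes if g in logdata.index]
    if not present:
        raise ValueError("no signature gene present in the matrix")
    if len(present) < len(signature):
        logger.info("signature genes missing from matrix: %d of %d",
                    len(signature) - len(present), len(signature))
    sub = logdata.loc[present]
    mu = sub.mean(axis=1)
    sd = sub.std(axis=1, ddof=0).replace(0, np.inf)  # constant genes -> z = 0
    z = sub.sub(mu, axis=0).div(sd, axis=0)
    per_cell = z.mean(axis=0)
    clusters = clusters.reindex(per_cell.index)
    if clusters.isna().any():
        raise ValueError("every cell needs a cluster label")
    return per_cell.groupby(clusters).mean().rename("signature_score")


def intersect_groups(msn_groups: pd.Series, resist_groups: pd.Series,
                     grades: pd.Series | None = None,
                     cluster_of_cell: pd.Series | None = None) -> dict:
    """Intersect the driver-expression and resistance-enrichment groupings.

    Returns the double-positive set (high driver AND resistant), the
    double-negative set (low driver AND sensitive) and the remainder, plus an
    optional per-grade composition table when cell-level grades are supplied.
    """
    if set(msn_groups.index) != set(resist_groups.index):
        raise ValueError("cluster universes differ between the two groupings")
    resist = resist_groups.reindex(msn_groups.index)
    high_res = set(msn_groups.index[(msn_groups == "high") & (resist == "resistant")])
    low_sen = set(msn_groups.index[(msn_groups == "low") & (resist == "sensitive")])
    other = set(msn_groups.index) - high_res - low_sen
    if not high_res:
        logger.warning("no high-driver resistant subcluster found")
    result = {"high_msn_resistant": high_res, "low_msn_sensitive": low_sen,
              "other": other}
    if grades is not None and cluster_of_cell is not None:
        comp = pd.DataFrame({"cluster": cluster_of_cell, "grade": grades})
        comp["set"] = comp["cluster"].map(
            lambda c: "high_msn_resistant" if c in high_res
            else ("low_msn_sensitive" if c in low_sen else "other"))
        result["composition"] = comp.groupby(["set", "grade"]).size().unstack(
            fill_value=0)
    return result


def find_markers(expr: ExpressionMatrix, clusters: pd.Series,
                 min_frac: float = 0.25, lfc_min: float = 0.5) -> pd.DataFrame:
    """One-vs-rest positive marker detection per cluster.

    Keeps genes detected (count > 0) in at least ``min_frac`` of in-cluster
    cells with in-minus-rest log2 mean difference >= ``lfc_min`` (positive
    markers only). p-values come from a Wilcoxon rank-sum test on the
    log-normalized values; FDR is Benjamini-Hochberg within each cluster.
    Clusters with fewer than 3 cells are skipped and logged.
    """
    clusters = clusters.reindex(expr.samples)
    if clusters.isna().any():
        raise ValueError("every cell needs a cluster label")
    if clusters.nunique() < 2:
        raise ValueError("need >=2 clusters")
    logdata = expr.to_lognorm().data
    detected = expr.data > 0
    rows = []
    for cluster in sorted(clusters.unique()):
        in_cells = clusters.index[clusters == cluster]
        out_cells = clusters.index[clusters != cluster]
        if len(in_cells) < 3:
            logger.info("cluster %s has <3 cells; skipped", cluster)
            continue
        frac = detected[in_cells].mean(axis=1)
        lfc = logdata[in_cells].mean(axis=1) - logdata[out_cells].mean(axis=1)
        candidates = logdata.index[(frac >= min_frac) & (lfc >= lfc_min)]
        if candidates.empty:
            continue
        a = logdata.loc[candidates, in_cells].to_numpy()
        b = logdata.loc[candidates, out_cells].to_numpy()
        p = stats.ranksums(a, b, axis=1).pvalue
        fdr = multipletests(p, method="fdr_bh")[1]
        for g, l, f, pv, q in zip(candidates, lfc[candidates], frac[candidates],
                                  p, fdr):
            rows.append((cluster, g, float(l), float(f), float(pv), float(q)))
    return pd.DataFrame(rows, columns=["cluster", "gene", "log2fc", "fraction",
                                       "p", "fdr"])
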