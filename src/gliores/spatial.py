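"""Label transfer from single-cell subclusters onto spatial transcriptomics.

Spatial clusters (or single spots) are decomposed as nonnegative mixtures of
single-cell subcluster centroids on shared highly-variable genes, z-scored
with the single-cell statistics; the row-normalized mixture weights serve as
prediction scores. Region enrichment then asks where the high-driver
resistant subclusters sit among the anatomical annotations (CT, IT, LE, MP,
PSEU).
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy.optimize import nnls
from sklearn.base import BaseEstimator
from sklearn.utils.validation import check_is_fitted

from .io import ExpressionMatrix
from .synthetic import SpatialDataset

logger = logging.getLogger(__name__)


def select_shared_hvgs(sc_expr: ExpressionMatrix, spatial_expr: pd.DataFrame,
                       n_top: int = 2000) -> list[str]:
    """Top-dispersion single-cell genes restricted to the shared namespace.

    Dispersion = variance / mean of the log-normalized single-cell values.
    Ordering is deterministic (dispersion descending, ties broken by gene id).
    """
    shared = sorted(set(sc_expr.genes) & set(spatial_expr.columns))
    if len(shared) < 50:
        raise ValueError(f"gene overlap too small ({len(shared)} < 50)")
    logdata = sc_expr.to_lognorm().data.loc[shared]
    mean = logdata.mean(axis=1)
    var = logdata.var(axis=1, ddof=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        disp = (var / mean).replace([np.inf, -np.inf], np.nan).fillna(0.0)
    ranked = disp.sort_index().sort_values(ascending=False, kind="mergesort")
    if n_top > len(ranked):
        logger.warning("n_top %d exceeds overlap %d; using all shared genes",
                       n_top, len(ranked))
    return list(ranked.index[:n_top])


class CentroidLabelTransfer(BaseEstimator):
    """Nonnegative-mixture label transfer from sc subclusters to spatial data.

    fit() learns per-gene z-statistics and subcluster centroids from the
    single-cell data on a shared highly-variable gene set; predict_proba()
    solves a nonnegative least-squares mixture of those centroids for each
    spatial cluster (or spot) and row-normalizes the weights to prediction
    scores summing to 1.

    Fitted attributes: ``genes_``, ``gene_mean_``, ``gene_std_``,
    ``centroids_`` (subclusters x genes), ``classes_``.
    """

    def __init__(self, n_top: int = 2000):
        self.n_top = n_top

    def fit(self, sc_expr: ExpressionMatrix, sc_clusters: pd.Series,
            shared_genes=None):
        logdata = sc_expr.to_lognorm().data
        if shared_genes is None:
            genes = list(logdata.index)
        else:
            genes = [g for g in shared_genes if g in logdata.index]
        if not genes:
            raise ValueError("no shared genes to fit on")
        sub = logdata.loc[genes]
        self.genes_ = genes
        self.gene_mean_ = sub.mean(axis=1)
        self.gene_std_ = sub.std(axis=1, ddof=0).replace(0, 1.0)
        z = sub.sub(self.gene_mean_, axis=0).div(self.gene_std_, axis=0)
        clusters = sc_clusters.reindex(z.columns)
        if clusters.isna().any():
            raise ValueError("every sc cell needs a cluster label")
        self.centroids_ = z.T.groupby(clusters).mean()  # subclusters x genes
        if self.centroids_.empty:
            raise ValueError("empty subcluster centroids")
        self.classes_ = list(self.centroids_.index)
        return self

    def predict_proba(self, spatial_expr: pd.DataFrame,
                      spot_clusters: pd.Series | None = None) -> pd.DataFrame:
        """Prediction-score matrix; rows = spatial clusters (or spots), sum to 1.

        The spatial side is z-scored with its own per-gene statistics so the
        mixture is solved in platform-free units on both sides (the sc side
        was z-scored with sc statistics in :meth:`fit`).
        """
        check_is_fitted(self, "centroids_")
        expr = spatial_expr.reindex(columns=self.genes_, fill_value=0.0)
        sp_mean = expr.mean(axis=0).to_numpy()
        sp_std = expr.std(axis=0, ddof=0).replace(0, 1.0).to_numpy()
        z = (expr - sp_mean[None, :]) / sp_std[None, :]
        if spot_clusters is not None:
            spot_clusters = spot_clusters.reindex(expr.index)
            targets = pd.DataFrame(z, index=expr.index).groupby(spot_clusters).mean()
        else:
            targets = pd.DataFrame(z, index=expr.index)
        basis = self.centroids_.to_numpy().T  # genes x subclusters
        # Centered z-centroids are collinear (they sum to ~0 across
        # subclusters), so plain NNLS is degenerate along the all-positive
        # null direction; a soft sum-to-one row pins the mixture scale.
        rho = float(np.linalg.norm(basis, axis=0).mean())
        aug_basis = np.vstack([basis, rho * np.ones(basis.shape[1])])
        scores = np.empty((len(targets), len(self.classes_)))
        for i, row in enumerate(targets.to_numpy()):
            w, _ = nnls(aug_basis, np.append(row, rho))
            total = w.sum()
            scores[i] = w / total if total > 0 else np.full(len(w),
                                                            1.0 / len(w))
        return pd.DataFrame(scores, index=targets.index, columns=self.classes_)


def transfer_scores(sc_expr: ExpressionMatrix, sc_clusters: pd.Series,
                    spatial: SpatialDataset, genes=None,
                    per_spot: bool = False) -> pd.DataFrame:
    """Prediction scores of sc subclusters across spatial clusters (or spots)."""
    if genes is None:
        genes = select_shared_hvgs(sc_expr, spatial.expression)
    model = CentroidLabelTransfer().fit(sc_expr, sc_clusters, shared_genes=genes)
    spot_clusters = None if per_spot else spatial.spot_clusters
    return model.predict_proba(spatial.expression, spot_clusters=spot_clusters)


def region_enrichment(spot_scores: pd.DataFrame, region_labels: pd.Series,
                      groups: dict) -> dict:
    """Per-region enrichment of subcluster groups, z-normalized across regions.

    ``spot_scores`` is spots x subclusters; each group's per-spot score is
    the sum of its member subclusters' prediction scores. Per region the mean
    over member spots is taken, then z-normalized across regions (constant
    group scores map to all-zero enrichment). Returns z-scores and raw means.
    """
    region_labels = region_labels.reindex(spot_scores.index)
    if region_labels.isna().any():
        raise ValueError("every spot needs a region label")
    regions = sorted(region_labels.unique())
    if len(regions) < 2:
        raise ValueError("z-normalization undefined with a single region")
    raw = {}
    for group, members in groups.items():
        members = [m for m in members if m in spot_scores.columns]
        if not members:
            raise ValueError(f"group {group!r} has no subcluster in the score matrix")
        per_spot = spot_scores[members].sum(axis=1)
        means = per_spot.groupby(region_labels).mean().reindex(regions)
        if means.isna().any():
            empty = means.index[means.isna()].tolist()
            raise ValueError(f"regions with zero spots: {empty}")
        raw[group] = means
    raw_df = pd.DataFrame(raw)
    sd = raw_df.std(ddof=0)
    z = (raw_df - raw_df.mean()) / sd.replace(0, np.inf)
    z = z.fillna(0.0)
    return {"z": z, "raw": raw_df}
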