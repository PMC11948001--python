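"""Single-cell copy-number inference from position-ordered expression.

Relative CNV profiles are inferred the way expression-based CNV callers do it:
log-normalize counts, center every gene on the mean of a designated reference
(non-tumor) cell set, smooth with a moving average along each chromosome,
re-standardize per cell against its own median, clip to [-clip, +clip]
(default 1) and zero out entries below the noise filter (default 0.2).
The per-cell CNV score is the quadratic summation (sum of squares) of the
smoothed profile, and cells are called CNV+ when their score exceeds a
reference-derived threshold.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_is_fitted

from .io import ExpressionMatrix, validate_positions

logger = logging.getLogger(__name__)


class CNVProfiler(BaseEstimator, TransformerMixin):
    """Infer smoothed relative-CNV profiles relative to a reference cell set.

    Parameters
    ----------
    window : odd moving-average width in genes; smoothing never crosses a
        chromosome boundary and the window shrinks (with a warning) if it
        exceeds the smallest chromosome's gene count.
    noise_filter : entries with magnitude below this are set to exactly 0.
    clip : profiles are clamped to [-clip, +clip] after re-standardization.
    cutoff : genes whose mean log-normalized expression across all cells is
        <= cutoff are dropped before smoothing (0 keeps every expressed gene).
    target_sum : per-cell library-size target for log-normalization.

    Fitted attributes: ``reference_mean_`` (per-gene reference baseline),
    ``gene_order_`` (position-sorted genes kept), ``chromosomes_``.
    """

    def __init__(self, window: int = 101, noise_filter: float = 0.2,
                 clip: float = 1.0, cutoff: float = 0.0,
                 target_sum: float = 1e4):
        self.window = window
        self.noise_filter = noise_filter
        self.clip = clip
        self.cutoff = cutoff
        self.target_sum = target_sum

    # X is cells x genes throughout, the sklearn sample orientation.

    def fit(self, X: pd.DataFrame, y=None, *, positions: pd.DataFrame):
        positions = validate_positions(positions)
        missing = [g for g in X.columns if g not in set(positions["gene"])]
        if missing:
            raise ValueError(f"genes without positions: {missing[:5]}")
        if X.shape[0] == 0:
            raise ValueError("reference cell set is empty")
        ordered = [g for g in positions["gene"] if g in set(X.columns)]
        log_ref = self._lognorm(X[ordered])
        mean_expr = log_ref.mean(axis=0)
        keep = mean_expr.to_numpy() > self.cutoff
        if not keep.any():
            raise ValueError("no gene passes the expression cutoff")
        self.gene_order_ = [g for g, k in zip(ordered, keep) if k]
        pos_kept = positions.set_index("gene").loc[self.gene_order_]
        self.chromosomes_ = pos_kept["chrom"].to_numpy()
        self.reference_mean_ = log_ref[self.gene_order_].mean(axis=0)
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        check_is_fitted(self, "reference_mean_")
        logx = self._lognorm(X.reindex(columns=self.gene_order_, fill_value=0))
        centered = logx.to_numpy() - self.reference_mean_.to_numpy()[None, :]
        smoothed = np.empty_like(centered)
        for chrom in pd.unique(self.chromosomes_):
            idx = np.flatnonzero(self.chromosomes_ == chrom)
            win = self.window
            if win > idx.size:
                logger.warning("window %d exceeds %s gene count %d; shrinking",
                               win, chrom, idx.size)
                win = idx.size if idx.size % 2 == 1 else idx.size - 1
            win = max(win, 1)
            smoothed[:, idx] = _moving_average(centered[:, idx], win)
        # Re-standardize per cell: subtract the cell's median profile value.
        smoothed -= np.median(smoothed, axis=1, keepdims=True)
        smoothed = np.clip(smoothed, -self.clip, self.clip)
        smoothed[np.abs(smoothed) < self.noise_filter] = 0.0
        return pd.DataFrame(smoothed, index=X.index, columns=self.gene_order_)

    def _lognorm(self, df: pd.DataFrame) -> pd.DataFrame:
        totals = df.sum(axis=1).replace(0, 1.0)
        return np.log2(df.div(totals, axis=0) * self.target_sum + 1.0)


def _moving_average(block: np.ndarray, window: int) -> np.ndarray:
    """Centered moving average along axis 1 with shrinking edge windows."""
    if window <= 1:
        return block.copy()
    n = block.shape[1]
    csum = np.cumsum(block, axis=1)
    csum = np.concatenate([np.zeros((block.shape[0], 1)), csum], axis=1)
    half = window // 2
    lo = np.maximum(np.arange(n) - half, 0)
    hi = np.minimum(np.arange(n) + half + 1, n)
    return (csum[:, hi] - csum[:, lo]) / (hi - lo)


def infer_cnv_profile(counts: ExpressionMatrix, reference_cells,
                      positions: pd.DataFrame, window: int = 101,
                      noise_filter: float = 0.2, clip: float = 1.0,
                      cutoff: float = 0.0) -> pd.DataFrame:
    """Functional wrapper over :class:`CNVProfiler`.

    ``counts`` is genes x cells (the pipeline's on-disk orientation);
    ``reference_cells`` names the non-tumor cells the baseline is taken from.
    Returns a cells x genes smoothed profile matrix whose entries satisfy
    |v| <= clip and (v == 0 or |v| >= noise_filter).
    """
    reference_cells = list(reference_cells)
    if not reference_cells:
        raise ValueError("reference cell set is empty")
    missing = [c for c in reference_cells if c not in counts.samples]
    if missing:
        raise ValueError(f"reference cells absent from matrix: {missing[:5]}")
    if set(reference_cells) == set(counts.samples):
        logger.warning("reference set covers every cell; profiles are "
                       "self-referential")
    cells_by_genes = counts.data.T
    profiler = CNVProfiler(window=window, noise_filter=noise_filter,
                           clip=clip, cutoff=cutoff)
    profiler.fit(cells_by_genes.loc[reference_cells], positions=positions)
    return profiler.transform(cells_by_genes)


def cnv_score(profiles: pd.DataFrame) -> pd.Series:
    """Quadratic summation: per-cell sum of squared profile entries."""
    vals = profiles.to_numpy(dtype=float)
    return pd.Series(np.einsum("ij,ij->i", vals, vals), index=profiles.index,
                     name="cnv_score")


def classify_cnv(scores: pd.Series, reference_scores: pd.Series,
                 rule: str = "percentile", percentile: float = 95.0
                 ) -> pd.DataFrame:
    """Call cells CNV+ / CNV- from their scores against a reference distribution.

    Default rule: CNV+ iff score > the ``percentile``-th percentile of the
    reference scores. The alternative "kmeans2" rule splits scores into two
    1-D clusters and calls the higher-center cluster CNV+.
    """
    if reference_scores.empty:
        raise ValueError("reference scores are empty")
    if np.ptp(reference_scores.to_numpy(dtype=float)) == 0:
        raise ValueError("reference score distribution is degenerate")
    if rule == "percentile":
        threshold = float(np.percentile(reference_scores, percentile))
        positive = scores > threshold
    elif rule == "kmeans2":
        from scipy.cluster.vq import kmeans2
        vals = scores.to_numpy(dtype=float)[:, None]
        centers, labels = kmeans2(vals, 2, minit="++", seed=0)
        hi = int(np.argmax(centers.ravel()))
        positive = pd.Series(labels == hi, index=scores.index)
        threshold = float(np.mean(centers))
    else:
        raise ValueError(f"unknown rule {rule!r}")
    return pd.DataFrame({
        "cnv_score": scores,
        "cnv_class": np.where(positive, "CNV+", "CNV-"),
        "rule": rule,
    })
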