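"""Transcriptomic signature of the high-instability grade.

Given an RMA-style probe x sample log2 expression matrix and a grade-3
versus rest labelling, probes differentially expressed by Welch's t-test
at a raw p-value threshold (default 5e-3, no multiplicity correction)
form the signature; samples can then be re-clustered on the signature or
classified against group centroids by nearest Pearson correlation.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats as sps

from .cluster import ClusterAssignment, cluster_distance_matrix

logger = logging.getLogger(__name__)


def welch_t_signature(
    expr: pd.DataFrame,
    in_group: np.ndarray,
    p_threshold: float = 5e-3,
    bh_adjust: bool = False,
) -> pd.DataFrame:
    """Per-probe Welch t-test (unequal variances, Satterthwaite df).

    ``expr`` is probe x sample; ``in_group`` flags the focal (grade-3)
    samples.  Returns a frame indexed by probe with columns t, df, p,
    mean_diff and selected (p below threshold; two-sided).  Probes with
    zero variance in both groups are skipped with a warning.  With
    ``bh_adjust`` the Benjamini-Hochberg adjusted p is thresholded
    instead (off by default, matching the raw-p convention).
    """
    in_group = np.asarray(in_group, dtype=bool)
    if in_group.sum() < 2 or (~in_group).sum() < 2:
        raise ValueError("each group needs at least two samples")
    x = expr.loc[:, expr.columns[in_group]].to_numpy(dtype=float)
    y = expr.loc[:, expr.columns[~in_group]].to_numpy(dtype=float)
    n1, n2 = x.shape[1], y.shape[1]
    m1, m2 = x.mean(axis=1), y.mean(axis=1)
    v1 = x.var(axis=1, ddof=1) / n1
    v2 = y.var(axis=1, ddof=1) / n2
    denom = v1 + v2
    degenerate = denom == 0
    if degenerate.any():
        logger.warning(
            "%d probe(s) with zero variance in both groups skipped",
            int(degenerate.sum()),
        )
    with np.errstate(divide="ignore", invalid="ignore"):
        t = (m1 - m2) / np.sqrt(denom)
        df = denom**2 / (v1**2 / (n1 - 1) + v2**2 / (n2 - 1))
    p = 2 * sps.t.sf(np.abs(t), df)
    p[degenerate] = np.nan
    if bh_adjust:
        from statsmodels.stats.multitest import multipletests

        ok = ~np.isnan(p)
        adj = np.full(len(p), np.nan)
        adj[ok] = multipletests(p[ok], method="fdr_bh")[1]
        selected = adj < p_threshold
    else:
        selected = p < p_threshold
    selected = np.where(np.isnan(p), False, selected)
    return pd.DataFrame(
        {
            "t": t, "df": df, "p": p, "mean_diff": m1 - m2,
            "selected": selected.astype(bool),
        },
        index=expr.index,
    )


def _pearson_distance(mat: np.ndarray) -> np.ndarray:
    """1 - Pearson r between columns; undefined pairs -> 0 if identical else 1."""
    r = pd.DataFrame(mat).corr().to_numpy()
    dist = 1.0 - r
    undef = np.isnan(dist)
    if undef.any():
        logger.warning("constant sample(s): correlation undefined for some pairs")
        for i, j in zip(*np.where(undef)):
            dist[i, j] = 0.0 if np.allclose(mat[:, i], mat[:, j]) else 1.0
    np.fill_diagonal(dist, 0.0)
    return (dist + dist.T) / 2.0


def cluster_by_signature(
    expr: pd.DataFrame, signature: pd.Index | list[str], k: int = 2,
    linkage: str = "ward",
) -> ClusterAssignment:
    """Hierarchical clustering of samples on the signature probes only."""
    probes = pd.Index(signature)
    if len(probes) == 0:
        raise ValueError("empty signature")
    sub = expr.loc[probes.intersection(expr.index)]
    if sub.empty:
        raise ValueError("no signature probe present in the matrix")
    dist = _pearson_distance(sub.to_numpy(dtype=float))
    return cluster_distance_matrix(dist, k, sample_ids=list(expr.columns), linkage=linkage)


def signature_centroids(
    expr: pd.DataFrame, signature: pd.Index | list[str], labels: np.ndarray
) -> pd.DataFrame:
    """Mean signature-probe expression per class: probe x class frame."""
    sub = expr.loc[pd.Index(signature)]
    out = {}
    labels = np.asarray(labels)
    for lab in pd.unique(labels):
        out[lab] = sub.loc[:, sub.columns[labels == lab]].mean(axis=1)
    return pd.DataFrame(out)


def centroid_classify(
    expr_new: pd.DataFrame, centroids: pd.DataFrame, min_overlap: float = 0.5
) -> pd.Series:
    """Nearest-centroid class per sample by Pearson correlation.

    Requires at least ``min_overlap`` of the signature probes in the new
    matrix; exact correlation ties yield ``"unclassified"``.
    """
    shared = centroids.index.intersection(expr_new.index)
    if len(shared) < min_overlap * len(centroids.index):
        raise ValueError(
            f"only {len(shared)}/{len(centroids.index)} signature probes present "
            f"(need >= {min_overlap:.0%})"
        )
    sub = expr_new.loc[shared].to_numpy(dtype=float)
    cents = centroids.loc[shared].to_numpy(dtype=float)
    calls = []
    for j in range(sub.shape[1]):
        cors = []
        for c in range(cents.shape[1]):
            with np.errstate(invalid="ignore"):
                r = np.corrcoef(sub[:, j], cents[:, c])[0, 1]
            cors.append(-np.inf if np.isnan(r) else r)
        cors = np.asarray(cors)
        best = np.flatnonzero(cors == cors.max())
        calls.append(
            "unclassified" if len(best) != 1 else str(centroids.columns[best[0]])
        )
    return pd.Series(calls, index=expr_new.columns, name="class")
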