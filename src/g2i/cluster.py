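"""Unsupervised clustering of GNL profiles and recurrence screens.

Profiles are compared by correlation distance on their gain/normal/loss
status vectors (1 - Pearson r, missing clones pairwise-excluded) and
grouped by agglomerative hierarchical clustering with Ward linkage; both
choices are configurable.  Per-group frequency profiles, recurrent-region
extraction and the Fisher-exact differential screen between groups follow
the filtering conventions of BAC-array studies (raw p-value and frequency
cut-offs, no multiplicity correction).
"""

from __future__ import annotations

import dataclasses
import logging

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform
from scipy.stats import fisher_exact

from .core import GNLProfile
from .genome import CloneMap, runs

logger = logging.getLogger(__name__)


def _status_matrix(profiles: list[GNLProfile]) -> np.ndarray:
    """samples x clones float matrix with NaN for missing."""
    mat = np.stack([p.statuses.astype(float) for p in profiles])
    for i, p in enumerate(profiles):
        mat[i, p.missing] = np.nan
    return mat


def gnl_distance(profiles: list[GNLProfile], metric: str = "pearson") -> np.ndarray:
    """Pairwise distance matrix between GNL profiles.

    ``pearson``: 1 - Pearson correlation (range [0, 2]); a pair involving a
    constant (e.g. all-normal) profile has undefined correlation and gets
    distance 0 if the two vectors are identical, else 1 (logged).
    ``manhattan``: mean absolute status difference over shared clones.
    """
    if len(profiles) < 2:
        raise ValueError("need at least two profiles")
    mat = _status_matrix(profiles)
    n = len(profiles)
    if metric == "pearson":
        r = pd.DataFrame(mat.T).corr(min_periods=2).to_numpy()
        dist = 1.0 - r
        undef = np.isnan(dist)
        if undef.any():
            logger.warning(
                "correlation undefined for %d profile pair(s) (constant profile); "
                "distance set to 0 for identical pairs, 1 otherwise",
                int(undef.sum() - undef.diagonal().sum()) // 2,
            )
            for i, j in zip(*np.where(undef)):
                both = ~np.isnan(mat[i]) & ~np.isnan(mat[j])
                identical = both.any() and np.array_equal(mat[i, both], mat[j, both])
                dist[i, j] = 0.0 if identical else 1.0
    elif metric == "manhattan":
        dist = np.zeros((n, n))
        for i in range(n):
            for j in range(i + 1, n):
                both = ~np.isnan(mat[i]) & ~np.isnan(mat[j])
                d = float(np.mean(np.abs(mat[i, both] - mat[j, both]))) if both.any() else 1.0
                dist[i, j] = dist[j, i] = d
    else:
        raise ValueError("metric must be 'pearson' or 'manhattan'")
    np.fill_diagonal(dist, 0.0)
    return (dist + dist.T) / 2.0


@dataclasses.dataclass
class ClusterAssignment:
    sample_ids: list[str]
    labels: np.ndarray          # 1..k, renumbered by first appearance
    linkage_matrix: np.ndarray  # scipy merge history

    def as_series(self) -> pd.Series:
        return pd.Series(self.labels, index=self.sample_ids, name="cluster")


def cluster_distance_matrix(
    dist: np.ndarray, k: int, sample_ids: list[str] | None = None,
    linkage: str = "ward",
) -> ClusterAssignment:
    """Agglomerative clustering of a precomputed distance matrix, cut at k."""
    n = dist.shape[0]
    if not 1 <= k <= n:
        raise ValueError(f"k={k} outside [1, {n}]")
    Z = hierarchy.linkage(squareform(dist, checks=False), method=linkage)
    raw = hierarchy.fcluster(Z, t=k, criterion="maxclust")
    # canonical labels: 1..k in order of first appearance
    remap: dict[int, int] = {}
    labels = np.empty(n, dtype=int)
    for i, lab in enumerate(raw):
        if lab not in remap:
            remap[lab] = len(remap) + 1
        labels[i] = remap[lab]
    ids = sample_ids if sample_ids is not None else [str(i) for i in range(n)]
    return ClusterAssignment(sample_ids=list(ids), labels=labels, linkage_matrix=Z)


def agglomerative_cluster(
    profiles: list[GNLProfile], k: int = 6,
    metric: str = "pearson", linkage: str = "ward",
) -> ClusterAssignment:
    """Cluster GNL profiles into k genomic groups (default k=6)."""
    dist = gnl_distance(profiles, metric=metric)
    return cluster_distance_matrix(
        dist, k, sample_ids=[p.sample_id for p in profiles], linkage=linkage
    )


def frequency_profile(profiles: list[GNLProfile]) -> pd.DataFrame:
    """Per-clone gain and loss fractions within a group of profiles."""
    if not profiles:
        raise ValueError("group is empty")
    mat = _status_matrix(profiles)
    present = ~np.isnan(mat)
    denom = np.maximum(present.sum(axis=0), 1)
    gain = np.nansum(mat == 1, axis=0) / denom
    loss = np.nansum(mat == -1, axis=0) / denom
    return pd.DataFrame({"gain": gain, "loss": loss})


def recurrent_regions(
    freq: pd.DataFrame, clone_map: CloneMap, threshold: float = 0.8,
    direction: str = "loss",
) -> pd.DataFrame:
    """Maximal clone runs whose gain (or loss) fraction strictly exceeds
    ``threshold``."""
    if not 0.0 < threshold <= 1.0:
        raise ValueError("threshold must be in (0, 1]")
    passing = (freq[direction].to_numpy() > threshold).astype(int)
    rows = []
    codes = clone_map.chrom_codes
    chroms = clone_map.chromosome
    for code in np.unique(codes):
        idx = np.flatnonzero(codes == code)
        for first, last, value in runs(passing[idx]):
            if value == 1:
                rows.append({
                    "chromosome": str(chroms[idx[first]]),
                    "first_clone": int(idx[first]),
                    "last_clone": int(idx[last]),
                    "n_clones": last - first + 1,
                    "direction": direction,
                })
    return pd.DataFrame(rows, columns=["chromosome", "first_clone", "last_clone",
                                       "n_clones", "direction"])


def differential_regions(
    profiles: list[GNLProfile],
    in_group: np.ndarray,
    clone_map: CloneMap,
    p_max: float = 1e-4,
    freq_min: float = 0.5,
) -> pd.DataFrame:
    """Clone runs altered significantly more often in the focal group.

    Per clone and per direction, a two-sided Fisher exact test compares
    altered-vs-not between the focal group and the rest; clones passing
    both the raw p-value filter (p <= p_max) and the focal-group frequency
    filter (>= freq_min) are merged into maximal runs.  Raw p-values are
    reported without multiplicity correction.
    """
    in_group = np.asarray(in_group, dtype=bool)
    if in_group.sum() < 2 or (~in_group).sum() < 2:
        raise ValueError("each group needs at least two samples")
    mat = _status_matrix(profiles)
    g1, g2 = mat[in_group], mat[~in_group]
    rows = []
    codes = clone_map.chrom_codes
    chroms = clone_map.chromosome
    for direction, code_value in (("gain", 1), ("loss", -1)):
        p_values = np.ones(mat.shape[1])
        freqs = np.zeros(mat.shape[1])
        for j in range(mat.shape[1]):
            a1 = int(np.nansum(g1[:, j] == code_value))
            n1 = int(np.sum(~np.isnan(g1[:, j])))
            a2 = int(np.nansum(g2[:, j] == code_value))
            n2 = int(np.sum(~np.isnan(g2[:, j])))
            if n1 == 0 or n2 == 0:
                continue
            freqs[j] = a1 / n1
            _, p_values[j] = fisher_exact([[a1, n1 - a1], [a2, n2 - a2]])
        passing = ((p_values <= p_max) & (freqs >= freq_min)).astype(int)
        for code in np.unique(codes):
            idx = np.flatnonzero(codes == code)
            for first, last, value in runs(passing[idx]):
                if value == 1:
                    span = idx[first : last + 1]
                    rows.append({
                        "chromosome": str(chroms[idx[first]]),
                        "first_clone": int(idx[first]),
                        "last_clone": int(idx[last]),
                        "n_clones": int(last - first + 1),
                        "direction": direction,
                        "min_p": float(p_values[span].min()),
                        "max_freq": float(freqs[span].max()),
                    })
    return pd.DataFrame(rows, columns=["chromosome", "first_clone", "last_clone",
                                       "n_clones", "direction", "min_p", "max_freq"])
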