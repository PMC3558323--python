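"""Piecewise-constant segmentation and gain/normal/loss calling.

Copy-number profiles are smoothed per chromosome by exact penalized
least-squares segmentation (dynamic programming), and each clone is then
called gained or lost when its smoothed value exceeds, in absolute value,
the residual standard deviation between the normalized and smoothed
ratios over all autosomes.
"""

from __future__ import annotations

import dataclasses
import logging

import numpy as np

from .core import GNLProfile, Log2Profile
from .genome import CloneMap

logger = logging.getLogger(__name__)


@dataclasses.dataclass(frozen=True)
class Segment:
    chromosome: str
    first_clone: int  # positional index into the clone map
    last_clone: int
    mean_log2: float
    n_clones: int


def robust_noise_sd(values: np.ndarray, chrom_codes: np.ndarray) -> float:
    """Noise scale from median absolute first differences within chromosomes.

    For i.i.d. Gaussian noise, successive differences have sd sqrt(2) times
    the noise sd; the median absolute difference estimator is insensitive to
    the (sparse) true copy-number breakpoints.
    """
    diffs = []
    for code in np.unique(chrom_codes):
        v = values[chrom_codes == code]
        v = v[np.isfinite(v)]
        if len(v) >= 2:
            diffs.append(np.abs(np.diff(v)))
    if not diffs:
        return 0.0
    mad = float(np.median(np.concatenate(diffs)))
    return mad / (np.sqrt(2.0) * 0.6744897501960817)


def _segment_1d(y: np.ndarray, penalty: float, min_seg_len: int) -> list[tuple[int, int]]:
    """Exact minimizer of sum of squared errors + penalty * (#segments).

    O(n^2) dynamic programme over admissible breakpoints; every segment has
    at least ``min_seg_len`` points.  Returns (first, last) index pairs.
    """
    n = len(y)
    if n == 0:
        return []
    if n < 2 * min_seg_len or not np.isfinite(penalty):
        return [(0, n - 1)]
    cs = np.concatenate([[0.0], np.cumsum(y)])
    cs2 = np.concatenate([[0.0], np.cumsum(y * y)])

    def seg_cost(i: np.ndarray, j: int) -> np.ndarray:
        # cost of segment y[i:j] (half-open), vectorized over i
        length = j - i
        s = cs[j] - cs[i]
        return (cs2[j] - cs2[i]) - s * s / length

    best = np.full(n + 1, np.inf)
    prev = np.zeros(n + 1, dtype=np.int64)
    best[0] = 0.0
    for j in range(min_seg_len, n + 1):
        starts = np.concatenate([[0], np.arange(min_seg_len, j - min_seg_len + 1)])
        starts = starts[starts <= j - min_seg_len]
        cand = best[starts] + seg_cost(starts, j) + penalty
        k = int(np.argmin(cand))  # ties: earliest admissible start
        best[j] = cand[k]
        prev[j] = starts[k]
    bounds = []
    j = n
    while j > 0:
        i = int(prev[j])
        bounds.append((i, j - 1))
        j = i
    return bounds[::-1]


def segment_profile(
    profile: Log2Profile,
    clone_map: CloneMap,
    penalty: float | str = "bic",
    min_seg_len: int = 2,
) -> tuple[list[Segment], np.ndarray]:
    """Segment one profile per chromosome; returns segments and smoothed values.

    ``penalty="bic"`` uses 2 * sd^2 * log(n) with a robust first-difference
    noise estimate; a float fixes the penalty directly.  Missing clones get
    NaN smoothed values and belong to no segment.
    """
    profile.check_aligned(clone_map)
    if min_seg_len < 1:
        raise ValueError("min_seg_len must be >= 1")
    values = profile.values
    codes = clone_map.chrom_codes
    if penalty == "bic":
        n_finite = int(np.isfinite(values).sum())
        sd = robust_noise_sd(values, codes)
        pen = 2.0 * sd * sd * np.log(max(n_finite, 2))
    else:
        pen = float(penalty)
        if np.isnan(pen):
            raise ValueError("penalty must be a finite number, +inf, or 'bic'")
    smoothed = np.full(len(values), np.nan)
    segments: list[Segment] = []
    chroms = clone_map.chromosome
    for code in np.unique(codes):
        on_chrom = np.flatnonzero(codes == code)
        finite = on_chrom[np.isfinite(values[on_chrom])]
        if finite.size == 0:
            continue
        y = values[finite]
        for i, j in _segment_1d(y, pen, min(min_seg_len, len(y))):
            mean = float(np.mean(y[i : j + 1]))
            idx = finite[i : j + 1]
            smoothed[idx] = mean
            segments.append(
                Segment(
                    chromosome=str(chroms[idx[0]]),
                    first_clone=int(idx[0]),
                    last_clone=int(idx[-1]),
                    mean_log2=mean,
                    n_clones=len(idx),
                )
            )
    return segments, smoothed


def residual_sd(
    profile: Log2Profile, smoothed: np.ndarray, clone_map: CloneMap
) -> float:
    """Sample sd (n-1 denominator) of normalized - smoothed over autosomes."""
    profile.check_aligned(clone_map)
    res = profile.values - smoothed
    usable = clone_map.autosomal & np.isfinite(res)
    if usable.sum() < 2:
        raise ValueError("need >= 2 autosomal clones with finite residuals")
    return float(np.std(res[usable], ddof=1))


def call_gnl(
    sample_id: str,
    smoothed: np.ndarray,
    sd: float,
    sd_multiplier: float = 1.0,
) -> GNLProfile:
    """Call gain (+1) / loss (-1) where |smoothed| strictly exceeds the
    threshold ``sd_multiplier * sd``; values exactly at the threshold are
    normal."""
    if sd < 0:
        raise ValueError("sd must be >= 0")
    threshold = sd_multiplier * sd
    smoothed = np.asarray(smoothed, dtype=float)
    missing = np.isnan(smoothed)
    if threshold == 0 and np.any(np.abs(smoothed[~missing]) > 0):
        logger.warning(
            "sample %s: zero residual sd (degenerate noise estimate); "
            "any nonzero smoothed value is called altered", sample_id,
        )
    statuses = np.zeros(len(smoothed), dtype=np.int8)
    with np.errstate(invalid="ignore"):
        statuses[smoothed > threshold] = 1
        statuses[smoothed < -threshold] = -1
    statuses[missing] = 0
    return GNLProfile(sample_id=sample_id, statuses=statuses, missing=missing)
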