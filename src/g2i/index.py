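"""The two-parameter genomic instability index (G2I).

For each sample the discrete gain/normal/loss profile yields:

* ``A`` — the mean, over chromosome arms, of the fraction of altered
  (gained or lost) clones on the arm; a whole-arm aneusomy contributes 1
  for its arm regardless of arm size.
* ``N`` — the number of altered genomic regions: maximal runs of
  non-normal status within a chromosome, a proxy for breakpoint count.

Grade 1 (stable): A < a1 and N <= n1.  Grade 3 (unstable): A > a2 and
N >= n2.  Everything else is grade 2.  Published thresholds:
a1 = 0.48, n1 = 42, a2 = 0.35, n2 = 65.  Sex chromosomes are excluded
from both parameters by default.
"""

from __future__ import annotations

import dataclasses
import logging

import numpy as np
import pandas as pd

from .core import G2IScore, G2IThresholds, GNLProfile, Log2Profile
from .genome import CloneMap, contiguous_blocks, runs
from .segment import call_gnl, residual_sd, segment_profile

logger = logging.getLogger(__name__)

#: Maximal missing-clone gap that is bridged when forming runs.
MAX_BRIDGE = 4


def local_score_smooth(
    gnl: GNLProfile, clone_map: CloneMap, min_run: int = 2
) -> GNLProfile:
    """Remove short artifactual runs by a local-score rule.

    Iteratively, any maximal run shorter than ``min_run`` whose two
    neighbouring runs (same chromosome) carry one and the same status is
    reassigned that status, until a fixed point.  Runs at chromosome ends
    or between disagreeing neighbours are left unchanged.  Idempotent and
    never increases the number of altered regions.
    """
    if min_run < 1:
        raise ValueError("min_run must be >= 1")
    gnl.check_aligned(clone_map)
    statuses = gnl.statuses.copy()
    for block in contiguous_blocks(clone_map.chrom_codes, gnl.missing, MAX_BRIDGE):
        seq = statuses[block]
        changed = True
        while changed:
            changed = False
            rr = runs(seq)
            for k in range(1, len(rr) - 1):
                first, last, value = rr[k]
                if last - first + 1 < min_run and rr[k - 1][2] == rr[k + 1][2]:
                    seq[first : last + 1] = rr[k - 1][2]
                    changed = True
                    break  # runs merged; recompute run structure
        statuses[block] = seq
    return GNLProfile(sample_id=gnl.sample_id, statuses=statuses, missing=gnl.missing.copy())


def fraction_genome_altered(
    gnl: GNLProfile, clone_map: CloneMap, include_sex: bool = False
) -> float:
    """A: unweighted mean over arms of the altered-clone proportion."""
    gnl.check_aligned(clone_map)
    usable = ~gnl.missing
    if not include_sex:
        usable = usable & clone_map.autosomal
    arms = clone_map.arm_labels
    fractions = []
    for arm in pd.unique(arms):
        on_arm = (arms == arm) & usable
        n = int(on_arm.sum())
        if n == 0:
            if ((arms == arm) & (clone_map.autosomal if not include_sex else True)).any():
                logger.warning("arm %s has no usable clones; dropped from A", arm)
            continue
        fractions.append(float((gnl.statuses[on_arm] != 0).sum()) / n)
    if not fractions:
        raise ValueError("no arm has a usable clone")
    return float(np.mean(fractions))


def count_altered_regions(
    gnl: GNLProfile, clone_map: CloneMap, include_sex: bool = False
) -> int:
    """N: number of maximal non-normal runs, per chromosome, summed."""
    gnl.check_aligned(clone_map)
    missing = gnl.missing.copy()
    if not include_sex:
        missing = missing | ~clone_map.autosomal
    n = 0
    for block in contiguous_blocks(clone_map.chrom_codes, missing, MAX_BRIDGE):
        n += sum(1 for _, _, v in runs(gnl.statuses[block]) if v != 0)
    return n


def classify_g2i(
    A: float, N: int, thresholds: G2IThresholds = G2IThresholds(),
    boundary: str = "prose",
) -> int:
    """Total, deterministic grade assignment.

    ``boundary="prose"`` (default): grade 1 iff A < a1 and N <= n1, grade 3
    iff A > a2 and N >= n2.  ``boundary="strict"`` uses strict inequalities
    on N as well.  With thresholds for which both predicates could hold,
    grade 3 takes precedence (impossible at the published values).
    """
    if not (np.isfinite(A) and np.isfinite(N)):
        raise ValueError("A and N must be finite")
    t = thresholds
    if boundary == "prose":
        low, high = (A < t.a1 and N <= t.n1), (A > t.a2 and N >= t.n2)
    elif boundary == "strict":
        low, high = (A < t.a1 and N < t.n1), (A > t.a2 and N > t.n2)
    else:
        raise ValueError("boundary must be 'prose' or 'strict'")
    if high:
        return 3
    if low:
        return 1
    return 2


@dataclasses.dataclass
class SampleResult:
    """Full per-sample trace: smoothed values, GNL calls and the score."""

    score: G2IScore
    gnl: GNLProfile
    smoothed: np.ndarray
    residual_sd: float


def score_sample(
    profile: Log2Profile,
    clone_map: CloneMap,
    thresholds: G2IThresholds = G2IThresholds(),
    penalty: float | str = "bic",
    min_run: int = 2,
    sd_multiplier: float = 1.0,
    boundary: str = "prose",
) -> SampleResult:
    """segment -> call GNL -> local-score smooth -> (A, N) -> grade."""
    _, smoothed = segment_profile(profile, clone_map, penalty=penalty)
    sd = residual_sd(profile, smoothed, clone_map)
    gnl = call_gnl(profile.sample_id, smoothed, sd, sd_multiplier=sd_multiplier)
    gnl = local_score_smooth(gnl, clone_map, min_run=min_run)
    A = fraction_genome_altered(gnl, clone_map)
    N = count_altered_regions(gnl, clone_map)
    grade = classify_g2i(A, N, thresholds, boundary=boundary)
    logger.info(
        "sample %s: sd=%.4f A=%.4f N=%d grade=%d", profile.sample_id, sd, A, N, grade
    )
    score = G2IScore(sample_id=profile.sample_id, A=A, N=N, grade=grade)
    return SampleResult(score=score, gnl=gnl, smoothed=smoothed, residual_sd=sd)


def score_cohort(
    profiles: list[Log2Profile], clone_map: CloneMap, **kwargs
) -> pd.DataFrame:
    """Score every profile; returns a (sample_id, A, N, grade) table."""
    rows = []
    for p in profiles:
        s = score_sample(p, clone_map, **kwargs).score
        rows.append({"sample_id": s.sample_id, "A": s.A, "N": s.N, "grade": s.grade})
    return pd.DataFrame(rows)


def _deviance(relapse: np.ndarray, grades: np.ndarray) -> float:
    """Deviance of the saturated 3-class relapse-rate model (-2 log L)."""
    dev = 0.0
    for g in np.unique(grades):
        k = int(relapse[grades == g].sum())
        n = int((grades == g).sum())
        for count, p_hat in ((k, k / n), (n - k, 1 - k / n)):
            if count > 0:
                dev -= 2.0 * count * np.log(p_hat)
    return dev


def optimize_thresholds(
    scores: pd.DataFrame,
    relapse: np.ndarray,
    a_grid: np.ndarray,
    n_grid: np.ndarray,
    boundary: str = "prose",
) -> G2IThresholds:
    """Exhaustive grid search for the four cut-offs.

    Minimizes the deviance of the per-grade relapse-rate model over all
    (a1, n1, a2, n2) combinations from the grids (a1 >= a2 permitted, as in
    the published thresholds).  Ties break toward fewer grade-2 samples,
    then lexicographically on (a1, n1, a2, n2).
    """
    relapse = np.asarray(relapse)
    if len(np.unique(relapse)) < 2:
        raise ValueError("need both relapse outcomes present")
    A = scores["A"].to_numpy(dtype=float)
    N = scores["N"].to_numpy(dtype=float)
    le_n = np.less_equal if boundary == "prose" else np.less
    ge_n = np.greater_equal if boundary == "prose" else np.greater
    best: tuple | None = None
    any_split = False
    for a1 in a_grid:
        low_a = A < a1
        for n1 in n_grid:
            low = low_a & le_n(N, n1)
            for a2 in a_grid:
                high_a = A > a2
                for n2 in n_grid:
                    high = high_a & ge_n(N, n2)
                    grades = np.where(high, 3, np.where(low, 1, 2))
                    if len(np.unique(grades)) == 1:
                        continue
                    any_split = True
                    dev = _deviance(relapse, grades)
                    key = (
                        round(dev, 12),
                        int((grades == 2).sum()),
                        float(a1), float(n1), float(a2), float(n2),
                    )
                    if best is None or key < best:
                        best = key
    if not any_split:
        raise ValueError("degenerate grid: every candidate puts all samples in one grade")
    _, _, a1, n1, a2, n2 = best
    return G2IThresholds(a1=a1, n1=int(n1), a2=a2, n2=int(n2))
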