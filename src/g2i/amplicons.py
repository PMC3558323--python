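"""High-level amplification calling and cohort summaries.

An amplicon is a maximal run of at least two contiguous clones whose
inferred copy number exceeds three.  Copy number is inferred from the
smoothed (segment-mean) log2 ratio assuming a diploid reference and full
tumor cellularity: CN = ploidy * 2**log2ratio, so the default rule is
equivalent to a smoothed log2 cutoff of log2(3/2) ~ 0.585.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .core import AmpliconCall, Log2Profile
from .genome import CloneMap, contiguous_blocks, runs


def call_amplicons(
    profile: Log2Profile,
    clone_map: CloneMap,
    cn_threshold: float = 3.0,
    min_clones: int = 2,
    ploidy: float = 2.0,
) -> list[AmpliconCall]:
    """Maximal runs of >= min_clones contiguous clones with CN > cn_threshold."""
    if ploidy <= 0:
        raise ValueError("ploidy must be positive")
    if profile.smoothed is None:
        raise ValueError("profile has no smoothed values; segment it first")
    profile.check_aligned(clone_map)
    smoothed = profile.smoothed
    cn = ploidy * np.exp2(smoothed)
    over = np.zeros(len(cn), dtype=int)
    finite = np.isfinite(cn)
    over[finite & (cn > cn_threshold)] = 1
    calls: list[AmpliconCall] = []
    chroms = clone_map.chromosome
    missing = ~finite
    for block in contiguous_blocks(clone_map.chrom_codes, missing, max_bridge=0):
        for first, last, value in runs(over[block]):
            if value != 1 or last - first + 1 < min_clones:
                continue
            span = block[first : last + 1]
            calls.append(
                AmpliconCall(
                    sample_id=profile.sample_id,
                    chromosome=str(chroms[span[0]]),
                    first_clone=int(span[0]),
                    last_clone=int(span[-1]),
                    n_clones=len(span),
                    max_log2=float(np.max(smoothed[span])),
                    max_copy_number=float(np.max(cn[span])),
                )
            )
    return calls


def calls_to_frame(calls: list[AmpliconCall]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "sample_id": c.sample_id, "chromosome": c.chromosome,
                "first_clone": c.first_clone, "last_clone": c.last_clone,
                "n_clones": c.n_clones, "max_log2": c.max_log2,
                "max_copy_number": c.max_copy_number,
            }
            for c in calls
        ],
        columns=["sample_id", "chromosome", "first_clone", "last_clone",
                 "n_clones", "max_log2", "max_copy_number"],
    )


def amplicon_summary(
    calls: pd.DataFrame,
    sample_ids: list[str],
    group_labels: dict[str, object] | None = None,
) -> pd.DataFrame:
    """Per-group amplicon burden: tumors with amplicons, totals and means.

    ``sample_ids`` is the full cohort (tumors without calls count in the
    denominators); ``group_labels`` maps sample_id -> group (default: one
    group ``"all"``).
    """
    labels = {s: (group_labels.get(s) if group_labels else "all") for s in sample_ids}
    per_sample = (
        calls.groupby("sample_id").size() if len(calls) else pd.Series(dtype=int)
    )
    rows = []
    for group in pd.unique(pd.Series(list(labels.values()))):
        members = [s for s in sample_ids if labels[s] == group]
        counts = np.array([int(per_sample.get(s, 0)) for s in members])
        bearing = int((counts > 0).sum())
        total = int(counts.sum())
        rows.append({
            "group": group,
            "n_tumors": len(members),
            "tumors_with_amplicons": bearing,
            "total_amplicons": total,
            "mean_per_tumor": total / len(members) if members else 0.0,
            "mean_per_bearing_tumor": total / bearing if bearing else 0.0,
        })
    return pd.DataFrame(rows)


def recurrent_amplicon_regions(calls: pd.DataFrame) -> pd.DataFrame:
    """Merge overlapping calls across samples into recurrent regions.

    Two calls overlap when their clone-index spans intersect on the same
    chromosome; each merged region reports how many distinct samples
    contribute.
    """
    rows = []
    for chrom, sub in calls.groupby("chromosome", sort=False):
        intervals = sub.sort_values("first_clone")[
            ["first_clone", "last_clone", "sample_id"]
        ].to_numpy(dtype=object)
        current = None
        for first, last, sample in intervals:
            if current is None or first > current[1]:
                if current is not None:
                    rows.append((chrom, *current[:2], len(current[2])))
                current = [int(first), int(last), {sample}]
            else:
                current[1] = max(current[1], int(last))
                current[2].add(sample)
        if current is not None:
            rows.append((chrom, *current[:2], len(current[2])))
    return pd.DataFrame(
        rows, columns=["chromosome", "first_clone", "last_clone", "n_samples"]
    )
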