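"""Genomic scaffold: clone maps and chromosome-arm tables.

A BAC-array experiment measures one log2 ratio per clone; everything
downstream (segmentation, GNL calling, the A/N instability index) is
defined relative to an ordered clone map and a partition of each
chromosome into p and q arms.  Coordinates are 1-based, fully closed
intervals, matching cytogenetic convention; the genome build is treated
as opaque.
"""

from __future__ import annotations

import dataclasses
import functools

import numpy as np
import pandas as pd

#: Recognised chromosome labels, in genome order.
CHROMOSOMES: tuple[str, ...] = tuple(str(i) for i in range(1, 23)) + ("X", "Y")

#: Autosome labels.
AUTOSOMES: tuple[str, ...] = tuple(str(i) for i in range(1, 23))

#: Acrocentric chromosomes: their p arms carry no clones on BAC arrays
#: (heterochromatic / rDNA short arms), so the default arm catalogue has
#: 39 autosomal arms rather than 44.
ACROCENTRIC: frozenset[str] = frozenset({"13", "14", "15", "21", "22"})

_CHROM_ORDER = {c: i for i, c in enumerate(CHROMOSOMES)}

# Approximate human chromosome lengths and centromere midpoints (Mb scale,
# stored in bp).  Only ratios of arm lengths matter for the simulator.
_ARM_DATA = [
    ("1", 125.0, 249.3), ("2", 93.3, 243.2), ("3", 91.0, 198.0),
    ("4", 50.4, 191.2), ("5", 48.4, 180.9), ("6", 61.0, 171.1),
    ("7", 59.9, 159.1), ("8", 45.6, 146.4), ("9", 49.0, 141.2),
    ("10", 40.2, 135.5), ("11", 53.7, 135.0), ("12", 35.8, 133.9),
    ("13", 17.9, 115.2), ("14", 17.6, 107.3), ("15", 19.0, 102.5),
    ("16", 36.6, 90.4), ("17", 24.0, 81.2), ("18", 17.2, 78.1),
    ("19", 26.5, 59.1), ("20", 27.5, 63.0), ("21", 13.2, 48.1),
    ("22", 14.7, 51.3), ("X", 60.6, 155.3),
]


class FormatError(ValueError):
    """Raised when an input table violates the documented format."""


@dataclasses.dataclass(frozen=True)
class ArmTable:
    """Per-chromosome centromere position and length (bp).

    Columns: ``chromosome``, ``centromere``, ``length``.
    """

    df: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.df
        required = {"chromosome", "centromere", "length"}
        if not required.issubset(df.columns):
            raise FormatError(f"arm table needs columns {sorted(required)}")
        bad = set(df["chromosome"].astype(str)) - set(CHROMOSOMES)
        if bad:
            raise FormatError(f"unknown chromosome label(s) in arm table: {sorted(bad)}")
        if not ((df["centromere"] > 0) & (df["centromere"] < df["length"])).all():
            raise FormatError("centromere must lie strictly inside the chromosome")

    def centromere(self, chromosome: str) -> float:
        row = self.df.loc[self.df["chromosome"].astype(str) == str(chromosome)]
        if row.empty:
            raise KeyError(f"chromosome {chromosome!r} not in arm table")
        return float(row["centromere"].iloc[0])

    @property
    def chromosomes(self) -> list[str]:
        return [str(c) for c in self.df["chromosome"]]


def default_arm_table() -> ArmTable:
    """Human arm table for autosomes 1-22 and X (the default array design)."""
    df = pd.DataFrame(_ARM_DATA, columns=["chromosome", "centromere", "length"])
    df["centromere"] = (df["centromere"] * 1e6).astype(np.int64)
    df["length"] = (df["length"] * 1e6).astype(np.int64)
    return ArmTable(df)


def chrom_sort_key(chromosome: pd.Series) -> pd.Series:
    return chromosome.astype(str).map(_CHROM_ORDER)


@dataclasses.dataclass(frozen=True)
class CloneMap:
    """Ordered BAC clones with chromosome, span and arm assignment.

    Columns: ``clone_id``, ``chromosome``, ``start``, ``end``, ``arm``.
    Clones are strictly ordered by (chromosome, start); a clone spanning
    the centromere is assigned to the arm containing its midpoint.
    """

    df: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.df
        required = ["clone_id", "chromosome", "start", "end", "arm"]
        missing = [c for c in required if c not in df.columns]
        if missing:
            raise FormatError(f"clone map missing columns {missing}")
        if df["clone_id"].duplicated().any():
            dup = df.loc[df["clone_id"].duplicated(), "clone_id"].iloc[0]
            raise FormatError(f"duplicate clone_id {dup!r}")
        bad = set(df["chromosome"].astype(str)) - set(CHROMOSOMES)
        if bad:
            raise FormatError(f"unknown chromosome label(s): {sorted(bad)}")
        if (df["end"] < df["start"]).any():
            raise FormatError("clone end < start")
        order = np.lexsort((df["start"].to_numpy(), chrom_sort_key(df["chromosome"]).to_numpy()))
        if not np.array_equal(order, np.arange(len(df))):
            raise FormatError("clone map not in genome order")

    def __len__(self) -> int:
        return len(self.df)

    @classmethod
    def from_records(cls, df: pd.DataFrame, arm_table: ArmTable | None = None) -> "CloneMap":
        """Build a map from unordered records, assigning arms if needed."""
        df = df.copy()
        df["chromosome"] = df["chromosome"].astype(str)
        df = df.sort_values(
            ["chromosome", "start"], key=lambda s: chrom_sort_key(s) if s.name == "chromosome" else s
        ).reset_index(drop=True)
        if "arm" not in df.columns or df["arm"].isna().any():
            if arm_table is None:
                raise FormatError("arm assignment requires an arm table")
            mid = (df["start"] + df["end"]) / 2.0
            cen = df["chromosome"].map(
                {str(c): arm_table.centromere(c) for c in arm_table.chromosomes}
            )
            if cen.isna().any():
                missing = df.loc[cen.isna(), "chromosome"].iloc[0]
                raise FormatError(f"chromosome {missing!r} absent from arm table")
            df["arm"] = np.where(mid <= cen, "p", "q")
        return cls(df[["clone_id", "chromosome", "start", "end", "arm"]])

    # -- cached layout arrays (the map is immutable) --------------------------

    @functools.cached_property
    def chromosome(self) -> np.ndarray:
        return self.df["chromosome"].to_numpy(dtype=object)

    @functools.cached_property
    def chrom_codes(self) -> np.ndarray:
        """Integer chromosome code per clone (genome order)."""
        return chrom_sort_key(self.df["chromosome"]).to_numpy()

    @functools.cached_property
    def autosomal(self) -> np.ndarray:
        """Boolean mask of autosomal clones."""
        return np.isin(self.df["chromosome"].to_numpy(), AUTOSOMES)

    @functools.cached_property
    def arm_labels(self) -> np.ndarray:
        """Per-clone arm label, e.g. ``"1q"``."""
        return (self.df["chromosome"].astype(str) + self.df["arm"].astype(str)).to_numpy(dtype=object)

    def arm_indices(self, arm: str) -> np.ndarray:
        """Positional indices of the clones on an arm label like ``"16q"``."""
        return np.flatnonzero(self.arm_labels == arm)

    @functools.cached_property
    def midpoints(self) -> np.ndarray:
        return (self.df["start"].to_numpy() + self.df["end"].to_numpy()) / 2.0


def contiguous_blocks(
    chrom_codes: np.ndarray,
    missing: np.ndarray,
    max_bridge: int = 4,
) -> list[np.ndarray]:
    """Split non-missing clone indices into contiguous runs.

    A run never crosses a chromosome boundary; within a chromosome a gap of
    up to ``max_bridge`` consecutive missing clones is bridged, a longer gap
    breaks the run.  Returns positional index arrays, in genome order.
    """
    idx = np.flatnonzero(~missing)
    if idx.size == 0:
        return []
    breaks = np.flatnonzero(
        (chrom_codes[idx[1:]] != chrom_codes[idx[:-1]])
        | (np.diff(idx) - 1 > max_bridge)
    )
    return np.split(idx, breaks + 1)


def runs(values: np.ndarray) -> list[tuple[int, int, float]]:
    """Maximal constant runs of a 1-D array as (first, last, value) triples."""
    if len(values) == 0:
        return []
    change = np.flatnonzero(values[1:] != values[:-1])
    starts = np.concatenate([[0], change + 1])
    ends = np.concatenate([change, [len(values) - 1]])
    return [(int(s), int(e), values[s]) for s, e in zip(starts, ends)]
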