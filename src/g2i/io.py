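"""Readers and writers for the tab-delimited interchange formats.

All files are UTF-8 TSV with optional ``#`` comment lines.  Coordinates
are 1-based closed intervals.  The formats:

* clone map: columns ``clone_id  chromosome  start  end  [arm]``
* arm table: columns ``chromosome  centromere  length``
* log2 matrix: first column ``clone_id``, one column per sample
* GNL matrix: same layout, values in {-1, 0, 1} (empty = missing)
* clinical table: one row per sample, see ``CLINICAL_ALPHABETS``
* scores table: ``sample_id  A  N  grade``
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .core import GNLProfile, Log2Profile
from .genome import CHROMOSOMES, ArmTable, CloneMap, FormatError

logger = logging.getLogger(__name__)

#: Allowed categories for the categorical clinical fields.
CLINICAL_ALPHABETS: dict[str, set[str]] = {
    "node_status": {"pN0", "pN+"},
    "age_group": {"<=55", ">55"},
    "sbr_grade": {"1", "2", "3"},
    "hr_status": {"+", "-"},
    "npi_class": {"1", "2", "3", "4"},
    "mib1": {"<20%", ">=20%"},
    "intrinsic_class": {"LA", "LB", "HER2", "Basal", "unclassified"},
}


def _data_lines(path: str | Path):
    with open(path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            yield lineno, line.split("\t")


# ---------------------------------------------------------------------------
# clone map / arm table


def read_clone_map(path: str | Path, arm_table: ArmTable | None = None) -> CloneMap:
    """Read a clone map TSV; rows may be unordered, output is genome-ordered.

    Raises :class:`FormatError` naming the offending line for unknown
    chromosome labels, non-numeric coordinates and duplicate clone ids.
    """
    rows = []
    header: list[str] | None = None
    seen: dict[str, int] = {}
    for lineno, fields in _data_lines(path):
        if header is None:
            header = fields
            required = ["clone_id", "chromosome", "start", "end"]
            missing = [c for c in required if c not in header]
            if missing:
                raise FormatError(f"{path}:{lineno}: missing column(s) {missing}")
            continue
        rec = dict(zip(header, fields))
        chrom = str(rec["chromosome"]).strip()
        if chrom not in CHROMOSOMES:
            raise FormatError(f"{path}:{lineno}: unknown chromosome {chrom!r}")
        try:
            start, end = int(rec["start"]), int(rec["end"])
        except (ValueError, KeyError) as exc:
            raise FormatError(f"{path}:{lineno}: non-numeric coordinate") from exc
        cid = rec["clone_id"].strip()
        if cid in seen:
            raise FormatError(
                f"{path}:{lineno}: duplicate clone_id {cid!r} (first at line {seen[cid]})"
            )
        seen[cid] = lineno
        row = {"clone_id": cid, "chromosome": chrom, "start": start, "end": end}
        if "arm" in rec and str(rec["arm"]).strip() in ("p", "q"):
            row["arm"] = str(rec["arm"]).strip()
        rows.append(row)
    if not rows:
        raise FormatError(f"{path}: no clone records")
    df = pd.DataFrame(rows)
    if "arm" not in df.columns or df["arm"].isna().any():
        if arm_table is None:
            raise FormatError(f"{path}: no arm column and no arm table supplied")
    return CloneMap.from_records(df, arm_table=arm_table)


def write_clone_map(clone_map: CloneMap, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("# BAC clone map; 1-based closed coordinates\n")
        clone_map.df.to_csv(fh, sep="\t", index=False)


def read_arm_table(path: str | Path) -> ArmTable:
    df = pd.read_csv(path, sep="\t", comment="#", dtype={"chromosome": str})
    return ArmTable(df)


def write_arm_table(arm_table: ArmTable, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("# chromosome arm table; centromere/length in bp\n")
        arm_table.df.to_csv(fh, sep="\t", index=False)


# ---------------------------------------------------------------------------
# log2 / GNL matrices


def _read_matrix(path: str | Path, clone_map: CloneMap) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", comment="#", dtype={"clone_id": str})
    if df.columns[0] != "clone_id":
        raise FormatError(f"{path}: first column must be clone_id")
    unknown = ~df["clone_id"].isin(clone_map.df["clone_id"])
    if unknown.any():
        dropped = df.loc[unknown, "clone_id"].tolist()
        logger.warning(
            "%s: dropping %d clone(s) absent from the clone map (e.g. %s)",
            path, len(dropped), dropped[:3],
        )
        df = df.loc[~unknown]
    # align to map order; absent clones become missing
    df = df.set_index("clone_id").reindex(clone_map.df["clone_id"])
    return df


def read_log2_table(path: str | Path, clone_map: CloneMap) -> list[Log2Profile]:
    """Read a clone x sample log2-ratio matrix aligned to ``clone_map``."""
    df = _read_matrix(path, clone_map)
    profiles = []
    for sample in df.columns:
        values = pd.to_numeric(df[sample], errors="coerce").to_numpy(dtype=float)
        if not np.isfinite(values).any():
            raise FormatError(f"{path}: sample column {sample!r} has no finite values")
        profiles.append(Log2Profile(sample_id=str(sample), values=values))
    return profiles


def write_log2_table(
    profiles: list[Log2Profile], clone_map: CloneMap, path: str | Path, decimals: int = 4
) -> None:
    out = pd.DataFrame({"clone_id": clone_map.df["clone_id"]})
    for p in profiles:
        p.check_aligned(clone_map)
        out[p.sample_id] = np.round(p.values, decimals)
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("# normalized log2 ratios, one column per sample\n")
        out.to_csv(fh, sep="\t", index=False)


def read_gnl_table(path: str | Path, clone_map: CloneMap) -> list[GNLProfile]:
    df = _read_matrix(path, clone_map)
    profiles = []
    for sample in df.columns:
        values = pd.to_numeric(df[sample], errors="coerce").to_numpy(dtype=float)
        missing = np.isnan(values)
        statuses = np.where(missing, 0, values)
        if not np.isin(statuses, (-1, 0, 1)).all():
            raise FormatError(f"{path}: sample {sample!r} has codes outside {{-1,0,1}}")
        profiles.append(
            GNLProfile(sample_id=str(sample), statuses=statuses.astype(np.int8), missing=missing)
        )
    return profiles


def write_gnl_table(
    profiles: list[GNLProfile], clone_map: CloneMap, path: str | Path
) -> None:
    out = pd.DataFrame({"clone_id": clone_map.df["clone_id"]})
    for p in profiles:
        p.check_aligned(clone_map)
        col = p.statuses.astype(object)
        col[p.missing] = np.nan
        out[p.sample_id] = col
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("# gain/normal/loss status matrix: 1 gain, 0 normal, -1 loss\n")
        out.to_csv(fh, sep="\t", index=False)


# ---------------------------------------------------------------------------
# clinical table


def read_clinical_table(path: str | Path) -> pd.DataFrame:
    """Read and validate a per-sample clinical annotation table.

    Required columns: ``sample_id``, ``relapse`` (0/1), ``follow_up``
    (months, > 0).  Optional categorical columns must draw from
    :data:`CLINICAL_ALPHABETS`; empty cells are explicit missing values.
    """
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    return validate_clinical(df, source=str(path))


def validate_clinical(df: pd.DataFrame, source: str = "clinical table") -> pd.DataFrame:
    df = df.copy()
    for col in ("sample_id", "relapse", "follow_up"):
        if col not in df.columns:
            raise FormatError(f"{source}: missing required column {col!r}")
    df["sample_id"] = df["sample_id"].astype(str)
    relapse = pd.to_numeric(df["relapse"], errors="coerce")
    if not relapse.isin([0, 1]).all():
        bad = df.loc[~relapse.isin([0, 1]), "relapse"].iloc[0]
        raise FormatError(f"{source}: relapse value {bad!r} outside {{0,1}}")
    df["relapse"] = relapse.astype(int)
    follow_up = pd.to_numeric(df["follow_up"], errors="coerce")
    if (follow_up <= 0).any() or follow_up.isna().any():
        raise FormatError(f"{source}: follow_up must be a positive number of months")
    df["follow_up"] = follow_up.astype(float)
    if "size_mm" in df.columns:
        df["size_mm"] = pd.to_numeric(df["size_mm"], errors="coerce")
    if "tp53_altered" in df.columns:
        tp53 = pd.to_numeric(df["tp53_altered"], errors="coerce")
        if not tp53.dropna().isin([0, 1]).all():
            raise FormatError(f"{source}: tp53_altered outside {{0,1}}")
        df["tp53_altered"] = tp53
    for col, alphabet in CLINICAL_ALPHABETS.items():
        if col not in df.columns:
            continue
        values = df[col].astype("string").str.strip()
        values = values.replace("", pd.NA)
        bad = values.dropna()[~values.dropna().isin(alphabet)]
        if len(bad):
            raise FormatError(
                f"{source}: column {col!r} has unknown category {bad.iloc[0]!r} "
                f"(allowed: {sorted(alphabet)})"
            )
        df[col] = values
    return df


def write_clinical_table(df: pd.DataFrame, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("# clinical annotations; empty cell = missing\n")
        df.to_csv(fh, sep="\t", index=False)


# ---------------------------------------------------------------------------
# scores


def read_scores_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", comment="#")
    for col in ("sample_id", "A", "N", "grade"):
        if col not in df.columns:
            raise FormatError(f"{path}: missing column {col!r}")
    df["sample_id"] = df["sample_id"].astype(str)
    return df


def write_scores_table(df: pd.DataFrame, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("# G2I scores: A = mean per-arm altered fraction, N = altered regions\n")
        df.to_csv(fh, sep="\t", index=False)
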