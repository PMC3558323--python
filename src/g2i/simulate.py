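"""Synthetic aCGH cohorts with the statistical structure of breast-tumor
copy-number profiles.

The generator emulates a ~5,878-clone BAC array (median inter-clone
spacing about 0.5 Mb) and six genomic archetypes mirroring the recurrent
profile families seen in breast carcinoma:

* ``flat_a``       — no recurrent change (quiet genome);
* ``t1q16q_b``     — 1q gain with 16q loss (the der(1;16) pattern);
* ``c1q7_c``       — 1q gain plus whole chromosome 7 gain;
* ``chr8_16_d``    — 8p-/8q+ with 16p+/16q- whole-arm swaps;
* ``complex_e``    — many whole-arm aneusomies plus scattered focal events;
* ``firestorm_f``  — highly rearranged: dozens of focal events, mainly
  losses, plus amplicons.

Log2 values are planted segment means (gain +0.4, loss -0.5, amplicon
+1.0, normal 0) plus i.i.d. Gaussian probe noise (sd 0.1 by default).
Relapse is drawn conditionally on the planted instability grade with
default probabilities 1/19, 23/88 and 21/28 for grades 1/2/3; relapse
times are uniform on (6, 120) months and non-relapsers are censored
beyond 131 months.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd

from .core import G2IThresholds, GNLProfile, Log2Profile
from .genome import ACROCENTRIC, AUTOSOMES, ArmTable, CloneMap, default_arm_table, runs
from .index import classify_g2i, count_altered_regions, fraction_genome_altered

GAIN_LEVEL = 0.4
LOSS_LEVEL = -0.5
AMPLICON_LEVEL = 1.0


@dataclasses.dataclass(frozen=True)
class ArchetypeSpec:
    """Event recipe for one genomic archetype."""

    name: str
    arm_events: tuple[tuple[str, int], ...] = ()
    focal_count_mean: float = 0.0       # Poisson mean of focal event count
    focal_len_min: int = 2              # clones
    focal_len_mean: float = 6.0         # mean clones per focal event
    focal_loss_fraction: float = 0.5
    amplicon_count_mean: float = 0.0    # Poisson mean; +1 offset via min
    amplicon_count_min: int = 0
    amplicon_len_range: tuple[int, int] = (2, 5)
    noise_sd: float = 0.1
    gain_level: float = GAIN_LEVEL
    loss_level: float = LOSS_LEVEL
    amplicon_level: float = AMPLICON_LEVEL

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.focal_len_min < 1:
            raise ValueError("focal event length must be >= 1 clone")


ARCHETYPES: dict[str, ArchetypeSpec] = {
    "flat_a": ArchetypeSpec(name="flat_a"),
    "t1q16q_b": ArchetypeSpec(
        name="t1q16q_b", arm_events=(("1q", 1), ("16q", -1)),
    ),
    "c1q7_c": ArchetypeSpec(
        name="c1q7_c",
        arm_events=(("1q", 1), ("7p", 1), ("7q", 1), ("8q", 1)),
        amplicon_count_mean=2.3,
    ),
    "chr8_16_d": ArchetypeSpec(
        name="chr8_16_d",
        arm_events=(("8p", -1), ("8q", 1), ("16p", 1), ("16q", -1)),
        amplicon_count_mean=1.8,
    ),
    "complex_e": ArchetypeSpec(
        name="complex_e",
        arm_events=(
            ("1p", -1), ("1q", 1), ("4q", -1), ("5p", 1), ("5q", 1),
            ("6q", -1), ("8q", 1), ("11q", -1), ("12q", 1), ("13q", -1),
            ("16p", 1), ("16q", -1), ("17p", -1), ("17q", 1),
            ("20p", 1), ("20q", 1),
        ),
        focal_count_mean=40.0, focal_len_min=3, focal_len_mean=8.0,
        amplicon_count_mean=2.0,
    ),
    "firestorm_f": ArchetypeSpec(
        name="firestorm_f",
        arm_events=(("16p", 1), ("20q", 1)),
        focal_count_mean=90.0, focal_len_min=2, focal_len_mean=28.0,
        focal_loss_fraction=0.65,
        amplicon_count_mean=4.3, amplicon_count_min=1,
    ),
}

#: Archetype mixture matching the development cohort's cluster sizes.
DEFAULT_WEIGHTS: dict[str, float] = {
    "flat_a": 34 / 135, "t1q16q_b": 25 / 135, "c1q7_c": 16 / 135,
    "chr8_16_d": 13 / 135, "complex_e": 35 / 135, "firestorm_f": 12 / 135,
}

#: Relapse probability given planted grade (grades 1, 2, 3).
DEFAULT_RELAPSE_PROBS: tuple[float, float, float] = (1 / 19, 23 / 88, 21 / 28)


@dataclasses.dataclass(frozen=True)
class SimulationConfig:
    n_samples: int = 135
    n_clones: int = 5878
    weights: dict[str, float] = dataclasses.field(
        default_factory=lambda: dict(DEFAULT_WEIGHTS)
    )
    relapse_probs: tuple[float, float, float] = DEFAULT_RELAPSE_PROBS
    seed: int = 0
    noise_sd: float | None = None  # overrides every archetype when set

    def __post_init__(self) -> None:
        total = sum(self.weights.values())
        if not np.isclose(total, 1.0):
            raise ValueError(f"archetype weights sum to {total}, not 1")
        unknown = set(self.weights) - set(ARCHETYPES)
        if unknown:
            raise ValueError(f"unknown archetype(s): {sorted(unknown)}")
        if not all(0.0 <= p <= 1.0 for p in self.relapse_probs):
            raise ValueError("relapse probabilities must lie in [0, 1]")


@dataclasses.dataclass
class TruthRecord:
    """Ground truth for one simulated sample."""

    sample_id: str
    archetype: str
    statuses: np.ndarray          # planted GNL vector
    amplicons: list[tuple[str, int, int]]  # (chromosome, first, last) clone idx
    A: float
    N: int
    grade: int
    relapse: int | None = None

    def segments(self, clone_map: CloneMap) -> pd.DataFrame:
        """Planted tiling of the genome into constant-status segments."""
        rows = []
        codes = clone_map.chrom_codes
        chroms = clone_map.chromosome
        for code in np.unique(codes):
            idx = np.flatnonzero(codes == code)
            for first, last, value in runs(self.statuses[idx]):
                rows.append({
                    "chromosome": str(chroms[idx[first]]),
                    "first_clone": int(idx[first]),
                    "last_clone": int(idx[last]),
                    "status": int(value),
                })
        return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# clone map


def simulate_clone_map(
    n_clones: int = 5878,
    arm_table: ArmTable | None = None,
    seed: int | np.random.Generator = 0,
    clone_length: int = 150_000,
) -> CloneMap:
    """Lay clones on chromosome arms proportionally to arm length.

    Acrocentric p arms (13p, 14p, 15p, 21p, 22p) carry no clones, so the
    default design has 39 autosomal arms plus Xp/Xq.  Median inter-clone
    spacing approximates covered_genome_length / n_clones.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    arm_table = arm_table or default_arm_table()
    arms = []  # (chromosome, arm, start, end)
    for _, row in arm_table.df.iterrows():
        chrom = str(row["chromosome"])
        cen, length = int(row["centromere"]), int(row["length"])
        if chrom not in ACROCENTRIC:
            arms.append((chrom, "p", 1, cen))
        arms.append((chrom, "q", cen + 1, length))
    if n_clones < len(arms):
        raise ValueError(
            f"n_clones={n_clones} cannot cover the {len(arms)} arms of the design"
        )
    lengths = np.array([end - start + 1 for _, _, start, end in arms], dtype=float)
    quota = n_clones * lengths / lengths.sum()
    counts = np.maximum(np.floor(quota).astype(int), 1)
    # largest-remainder top-up to hit n_clones exactly
    while counts.sum() < n_clones:
        counts[np.argmax(quota - counts)] += 1
    while counts.sum() > n_clones:
        over = np.where(counts > 1, counts - quota, -np.inf)
        counts[np.argmax(over)] -= 1
    rows = []
    k = 0
    for (chrom, arm, start, end), count in zip(arms, counts):
        spacing = (end - start + 1) / count
        jitter = rng.uniform(-0.2, 0.2, size=count) * spacing
        centers = start + (np.arange(count) + 0.5) * spacing + jitter
        for c in centers:
            s = max(int(c) - clone_length // 2, start)
            e = min(s + clone_length - 1, end)
            rows.append({
                "clone_id": f"BAC-{k:05d}", "chromosome": chrom,
                "start": s, "end": e, "arm": arm,
            })
            k += 1
    df = pd.DataFrame(rows)
    # ids were assigned in arm order == genome order; re-id after sort for safety
    df = df.sort_values(["chromosome", "start"],
                        key=lambda s: s.map({c: i for i, c in enumerate(
                            [str(i) for i in range(1, 23)] + ["X", "Y"])})
                        if s.name == "chromosome" else s).reset_index(drop=True)
    df["clone_id"] = [f"BAC-{i:05d}" for i in range(len(df))]
    return CloneMap(df)


# ---------------------------------------------------------------------------
# single profile


def _free_intervals(statuses: np.ndarray, clone_map: CloneMap) -> list[list[int]]:
    """Maximal autosomal runs of still-normal clones, as [first, last] pairs."""
    codes = clone_map.chrom_codes
    auto = clone_map.autosomal
    free = []
    occupied = (statuses != 0) | ~auto
    idx = np.flatnonzero(~occupied)
    if idx.size == 0:
        return []
    breaks = np.flatnonzero((np.diff(idx) > 1) | (codes[idx[1:]] != codes[idx[:-1]]))
    for chunk in np.split(idx, breaks + 1):
        free.append([int(chunk[0]), int(chunk[-1])])
    return free


def _place_events(
    statuses: np.ndarray,
    clone_map: CloneMap,
    lengths: list[int],
    directions: list[int],
    rng: np.random.Generator,
) -> list[tuple[int, int, int]]:
    """Place non-overlapping, non-adjacent events on normal autosomal clones.

    Events are placed longest-first into free intervals chosen with
    probability proportional to their placement capacity; a two-clone
    buffer keeps planted events from merging in the truth tiling and
    keeps every normal gap segmentable at the default minimum segment
    length of two clones.
    """
    free = _free_intervals(statuses, clone_map)
    placed = []
    order = np.argsort(lengths)[::-1]

    # An event either touches a free-interval edge or leaves >= 2 normal
    # clones, so no 1-clone normal gap ever arises.  With raw start window
    # width W = b - length + 1 - a + 1, the allowed starts are
    # {a} u [a+2, b-length-1] u {b-length+1}; closed-form count and k-th
    # value avoid materializing the candidate arrays.
    def n_allowed(W: np.ndarray) -> np.ndarray:
        out = np.where(W >= 5, W - 2, 0)
        out = np.where((W == 3) | (W == 4), 2, out)
        return np.where(W == 1, 1, out)

    def kth_allowed(a: int, smax: int, W: int, k: int) -> int:
        if W == 1:
            return a
        if W in (3, 4):
            return a if k == 0 else smax
        if k == 0:
            return a
        if k == W - 3:  # last of the W - 2 allowed values
            return smax
        return a + 1 + k

    for i in order:
        length, direction = lengths[i], directions[i]
        arr = np.asarray(free, dtype=np.int64).reshape(-1, 2)
        W = arr[:, 1] - length + 2 - arr[:, 0]
        caps = n_allowed(np.maximum(W, 0)).astype(float)
        if caps.sum() == 0:
            raise ValueError(
                f"cannot place a {length}-clone event: genome too crowded "
                "(archetype requests more focal events than clones available)"
            )
        which = int(rng.choice(len(free), p=caps / caps.sum()))
        a, b = free[which]
        k = int(rng.integers(0, caps[which]))
        s = kth_allowed(a, b - length + 1, int(W[which]), k)
        e = s + length - 1
        statuses[s : e + 1] = direction
        placed.append((s, e, direction))
        free.pop(which)
        if s - 3 >= a:
            free.append([a, s - 3])
        if e + 3 <= b:
            free.append([e + 3, b])
    return placed


def simulate_profile(
    archetype: ArchetypeSpec | str,
    clone_map: CloneMap,
    seed: int | np.random.Generator = 0,
    sample_id: str = "S0",
    thresholds: G2IThresholds = G2IThresholds(),
) -> tuple[Log2Profile, TruthRecord]:
    """Simulate one log2 profile plus its ground truth."""
    if isinstance(archetype, str):
        archetype = ARCHETYPES[archetype]
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n = len(clone_map)
    statuses = np.zeros(n, dtype=np.int8)
    arm_labels = clone_map.arm_labels
    for arm, direction in archetype.arm_events:
        idx = np.flatnonzero(arm_labels == arm)
        if idx.size == 0:
            raise ValueError(f"archetype {archetype.name}: arm {arm!r} has no clones")
        statuses[idx] = direction

    n_focal = int(rng.poisson(archetype.focal_count_mean)) if archetype.focal_count_mean else 0
    extra = max(archetype.focal_len_mean - archetype.focal_len_min, 0.0)
    lengths = [
        archetype.focal_len_min + (int(rng.poisson(extra)) if extra else 0)
        for _ in range(n_focal)
    ]
    directions = [
        -1 if rng.random() < archetype.focal_loss_fraction else 1 for _ in range(n_focal)
    ]
    _place_events(statuses, clone_map, lengths, directions, rng)

    n_amp = 0
    if archetype.amplicon_count_mean or archetype.amplicon_count_min:
        n_amp = max(
            int(rng.poisson(archetype.amplicon_count_mean)), archetype.amplicon_count_min
        )
    amp_lengths = [
        int(rng.integers(archetype.amplicon_len_range[0], archetype.amplicon_len_range[1] + 1))
        for _ in range(n_amp)
    ]
    amp_mask = np.zeros(n, dtype=bool)
    amplicons = []
    if n_amp:
        before = statuses.copy()
        placed = _place_events(statuses, clone_map, amp_lengths, [1] * n_amp, rng)
        chroms = clone_map.chromosome
        for s, e, _ in placed:
            amp_mask[s : e + 1] = True
            amplicons.append((str(chroms[s]), s, e))
        del before

    means = np.zeros(n)
    means[statuses == 1] = archetype.gain_level
    means[statuses == -1] = archetype.loss_level
    means[amp_mask] = archetype.amplicon_level
    values = means + rng.normal(0.0, archetype.noise_sd, size=n)

    truth_gnl = GNLProfile(sample_id=sample_id, statuses=statuses)
    A = fraction_genome_altered(truth_gnl, clone_map)
    N = count_altered_regions(truth_gnl, clone_map)
    grade = classify_g2i(A, N, thresholds)
    truth = TruthRecord(
        sample_id=sample_id, archetype=archetype.name, statuses=statuses,
        amplicons=amplicons, A=A, N=N, grade=grade,
    )
    return Log2Profile(sample_id=sample_id, values=values), truth


# ---------------------------------------------------------------------------
# cohort

# P(pN0 | grade) and P(age<=55 | grade) matching the development cohort.
_PN0_BY_GRADE = {1: 12 / 19, 2: 43 / 88, 3: 20 / 28}
_YOUNG_BY_GRADE = {1: 8 / 19, 2: 51 / 88, 3: 11 / 28}


def simulate_cohort(
    config: SimulationConfig,
    clone_map: CloneMap | None = None,
    arm_table: ArmTable | None = None,
) -> tuple[list[Log2Profile], pd.DataFrame, list[TruthRecord]]:
    """Simulate a full cohort: profiles, clinical annotations and truths.

    Relapse is Bernoulli in the planted grade's probability; relapsers get
    event times uniform on (6, 120) months, non-relapsers are censored
    uniformly on (131, 180) months.
    """
    rng = np.random.default_rng(config.seed)
    if clone_map is None:
        clone_map = simulate_clone_map(config.n_clones, arm_table, seed=rng)
    names = sorted(config.weights)
    probs = np.array([config.weights[a] for a in names])
    profiles, truths, rows = [], [], []
    for i in range(config.n_samples):
        sample_id = f"T{i:04d}"
        name = names[rng.choice(len(names), p=probs)]
        spec = ARCHETYPES[name]
        if config.noise_sd is not None:
            spec = dataclasses.replace(spec, noise_sd=config.noise_sd)
        profile, truth = simulate_profile(spec, clone_map, seed=rng, sample_id=sample_id)
        p_relapse = config.relapse_probs[truth.grade - 1]
        relapse = int(rng.random() < p_relapse)
        truth.relapse = relapse
        follow_up = rng.uniform(6.0, 120.0) if relapse else rng.uniform(131.0, 180.0)
        rows.append({
            "sample_id": sample_id,
            "relapse": relapse,
            "follow_up": round(float(follow_up), 1),
            "node_status": "pN0" if rng.random() < _PN0_BY_GRADE[truth.grade] else "pN+",
            "age_group": "<=55" if rng.random() < _YOUNG_BY_GRADE[truth.grade] else ">55",
        })
        profiles.append(profile)
        truths.append(truth)
    clinical = pd.DataFrame(rows)
    return profiles, clinical, truths


def write_truth_table(truths: list[TruthRecord], path) -> None:
    rows = [
        {
            "sample_id": t.sample_id, "archetype": t.archetype, "A": round(t.A, 4),
            "N": t.N, "grade": t.grade, "relapse": t.relapse,
            "n_amplicons": len(t.amplicons),
        }
        for t in truths
    ]
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("# planted ground truth per simulated sample\n")
        pd.DataFrame(rows).to_csv(fh, sep="\t", index=False)
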