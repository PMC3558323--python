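"""Core domain types: log2 profiles, GNL profiles, scores and thresholds."""

from __future__ import annotations

import dataclasses

import numpy as np

from .genome import CloneMap

GAIN, NORMAL, LOSS = 1, 0, -1


@dataclasses.dataclass
class Log2Profile:
    """Per-clone normalized log2 ratios for one sample, aligned to a CloneMap.

    Missing measurements are NaN.  ``smoothed`` holds the piecewise-constant
    segment means once the profile has been segmented.
    """

    sample_id: str
    values: np.ndarray
    smoothed: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.smoothed is not None:
            self.smoothed = np.asarray(self.smoothed, dtype=float)
            if self.smoothed.shape != self.values.shape:
                raise ValueError("smoothed values misaligned with raw values")

    @property
    def missing(self) -> np.ndarray:
        return np.isnan(self.values)

    def check_aligned(self, clone_map: CloneMap) -> None:
        if len(self.values) != len(clone_map):
            raise ValueError(
                f"profile {self.sample_id!r} has {len(self.values)} values "
                f"for a map of {len(clone_map)} clones"
            )


@dataclasses.dataclass
class GNLProfile:
    """Discrete gain/normal/loss (+1/0/-1) status per clone for one sample."""

    sample_id: str
    statuses: np.ndarray
    missing: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.statuses = np.asarray(self.statuses, dtype=np.int8)
        bad = ~np.isin(self.statuses, (-1, 0, 1))
        if bad.any():
            raise ValueError(f"status codes outside {{-1,0,1}} in {self.sample_id!r}")
        if self.missing is None:
            self.missing = np.zeros(self.statuses.shape, dtype=bool)
        else:
            self.missing = np.asarray(self.missing, dtype=bool)
            if self.missing.shape != self.statuses.shape:
                raise ValueError("missing mask misaligned with statuses")

    def check_aligned(self, clone_map: CloneMap) -> None:
        if len(self.statuses) != len(clone_map):
            raise ValueError(
                f"GNL profile {self.sample_id!r} misaligned with clone map"
            )


@dataclasses.dataclass(frozen=True)
class G2IThresholds:
    """The four published cut-offs of the instability index.

    Grade 1 requires A < a1 and N <= n1; grade 3 requires A > a2 and
    N >= n2; everything else is grade 2.  The published values let the A
    conditions overlap (a2 < a1): the N conditions keep the grades disjoint.
    """

    a1: float = 0.48
    n1: int = 42
    a2: float = 0.35
    n2: int = 65

    def __post_init__(self) -> None:
        if not (0.0 <= self.a1 <= 1.0 and 0.0 <= self.a2 <= 1.0):
            raise ValueError("A thresholds must lie in [0, 1]")
        if self.n1 <= 0 or self.n2 <= 0:
            raise ValueError("N thresholds must be positive")


@dataclasses.dataclass(frozen=True)
class G2IScore:
    """Two-parameter instability score for one sample.

    A: mean per-arm fraction of altered clones, in [0, 1].
    N: number of altered genomic regions (breakpoint-delimited runs).
    """

    sample_id: str
    A: float
    N: int
    grade: int

    def __post_init__(self) -> None:
        if not 0.0 <= self.A <= 1.0:
            raise ValueError(f"A={self.A} outside [0, 1]")
        if self.N < 0:
            raise ValueError("N must be >= 0")
        if self.grade not in (1, 2, 3):
            raise ValueError("grade must be 1, 2 or 3")


@dataclasses.dataclass(frozen=True)
class AmpliconCall:
    """Maximal run of >= 2 contiguous clones with inferred copy number > 3."""

    sample_id: str
    chromosome: str
    first_clone: int
    last_clone: int
    n_clones: int
    max_log2: float
    max_copy_number: float

    def __post_init__(self) -> None:
        if self.n_clones < 2:
            raise ValueError("an amplicon spans at least two clones")
        if self.last_clone - self.first_clone + 1 != self.n_clones:
            raise ValueError("amplicon clone span inconsistent")
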