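import numpy as np
import pandas as pd
import pytest

from g2i.core import GNLProfile, Log2Profile
from g2i.genome import ArmTable, CloneMap
from g2i.simulate import simulate_clone_map


def make_map(chrom_arms: list[tuple[str, str, int]], spacing: int = 1_000_000) -> CloneMap:
    """Toy clone map: list of (chromosome, arm, n_clones) blocks in order."""
    rows, k, pos = [], 0, {}
    for chrom, arm, n in chrom_arms:
        start = pos.get(chrom, 1)
        for i in range(n):
            rows.append({
                "clone_id": f"c{k:03d}", "chromosome": chrom,
                "start": start + i * spacing, "end": start + i * spacing + 150_000,
                "arm": arm,
            })
            k += 1
        pos[chrom] = start + n * spacing
    return CloneMap(pd.DataFrame(rows))


def gnl(statuses, sample_id="s", missing=None) -> GNLProfile:
    return GNLProfile(sample_id=sample_id, statuses=np.asarray(statuses, dtype=np.int8),
                      missing=missing)


def log2p(values, sample_id="s", smoothed=None) -> Log2Profile:
    return Log2Profile(sample_id=sample_id, values=np.asarray(values, dtype=float),
                       smoothed=smoothed)


@pytest.fixture(scope="session")
def full_map() -> CloneMap:
    """Default-design 5,878-clone map shared by the heavier tests."""
    return simulate_clone_map(5878, seed=1)


@pytest.fixture(scope="session")
def toy_arm_table() -> ArmTable:
    return ArmTable(pd.DataFrame({
        "chromosome": ["1", "2"],
        "centromere": [5_000_000, 3_000_000],
        "length": [10_000_000, 8_000_000],
    }))
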