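import numpy as np
import pytest

from ecomorphdiv.io_formats import SampleSheet, SyncRecord
from ecomorphdiv.synthdata import SimConfig


@pytest.fixture(scope="session")
def small_config() -> SimConfig:
    return SimConfig(n_genes=60, seed=11)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)


def make_site(
    contig: str,
    position: int,
    pool_counts: list[dict[str, int]],
    ref: str = "A",
) -> SyncRecord:
    """Build a SyncRecord from per-pool {base: count} dicts."""
    order = "A T C G N del".split()
    tuples = []
    for pc in pool_counts:
        tuples.append(tuple(pc.get(b, 0) for b in order))
    return SyncRecord(contig, position, ref, tuple(tuples))


def two_morph_sheet(n_pools: int = 3, tissues=("radula", "mantle", "foot")):
    samples, morphs, tiss, pools = [], [], [], []
    for morph in ("wood", "rock"):
        for t in tissues:
            for p in range(1, n_pools + 1):
                samples.append(f"{morph}_{t}_p{p}")
                morphs.append(morph)
                tiss.append(t)
                pools.append(p)
    return SampleSheet(tuple(samples), tuple(morphs), tuple(tiss), tuple(pools))
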