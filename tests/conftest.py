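import numpy as np
import pandas as pd
import pytest

from ms4c import readproc as rp
from ms4c import simulate as sim


@pytest.fixture(scope="session")
def seq_genome():
    """Small two-chromosome genome with sequence, for read-level tests."""
    return sim.digest_genome(
        {"chr1": 600_000, "chr2": 300_000}, mean_fragment=3000, seed=7,
        with_sequence=True,
    )


@pytest.fixture(scope="session")
def seq_bait(seq_genome):
    return sim.make_bait(seq_genome, "B1", "chr1", 10)


@pytest.fixture(scope="session")
def std_genome():
    """Standard simulated study chromosome: 12 Mb, ~3 kb HindIII fragments."""
    return sim.digest_genome({"chr1": 12_000_000}, mean_fragment=3000, seed=99)


@pytest.fixture(scope="session")
def std_bait(std_genome):
    """Bait viewpoint ~1 Mb into the standard chromosome."""
    return sim.make_bait(std_genome, "B", "chr1", 300)


def make_counts(
    rmap: dict[str, np.ndarray],
    raw: dict[str, np.ndarray],
    bait_chrom: str = "chr1",
    bait_pos: int | None = None,
    name: str = "T",
    wiggle_window: int = 1000,
) -> rp.SiteCounts:
    """Build a SiteCounts by hand from junction-assigned raw counts; the
    wiggle track is derived with the +/-1000 bp rule."""
    counts = {}
    total = 0
    cis = trans = 0
    for chrom, sites in rmap.items():
        r = np.asarray(raw[chrom], dtype=np.int64)
        w = np.zeros_like(r)
        for k, c in enumerate(r):
            if c:
                lo = int(np.searchsorted(sites, sites[k] - wiggle_window, side="left"))
                hi = int(np.searchsorted(sites, sites[k] + wiggle_window, side="right"))
                w[lo:hi] += c
        counts[chrom] = w
        total += int(r.sum())
        if chrom == bait_chrom:
            cis += int(r.sum())
        else:
            trans += int(r.sum())
    return rp.SiteCounts(
        bait_name=name, bait_chrom=bait_chrom,
        bait_pos=int(rmap[bait_chrom][0]) if bait_pos is None else bait_pos,
        restriction_map={c: np.asarray(s, dtype=np.int64) for c, s in rmap.items()},
        counts=counts,
        raw={c: np.asarray(v, dtype=np.int64) for c, v in raw.items()},
        total=total, cis=cis, trans=trans,
    )


@pytest.fixture()
def grid_rmap():
    """Regular 3 kb site grid on one 1.2 Mb chromosome."""
    return {"chr1": np.arange(100, 1_200_000, 3000, dtype=np.int64)}


def processed_from_truth(truth: pd.DataFrame) -> list[rp.ProcessedPair]:
    """ProcessedPair objects straight from a simulation truth sidecar."""
    return [
        rp.ProcessedPair(r.bait, r.chrom, "+", int(r.site_pos), int(r.site_index),
                         int(r.breakpoint))
        for r in truth.itertuples(index=False)
    ]
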