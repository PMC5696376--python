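"""Transcriptional gene classes from a chromatin-state segmentation.

Promoters carrying both H3K4me3 and H3K27me3 ("bivalent" promoters) appear
in ChromHMM-style 15-state segmentations as the Poised_Promoter state.  A
gene is classified by which pooled superstate occupies the plurality of
the 500 bp window around its TSS:

* Poised_Promoter                      -> bivalent
* Active_Promoter or Weak_Promoter     -> active
* Repressed or Heterochrom             -> repressive
* anything else (or an occupancy tie)  -> other

The pools are configurable; the defaults mirror the ENCODE Broad ChromHMM
15-state vocabulary.  Base pairs not covered by any segment count toward a
null state outside every pool, so occupancy fractions always sum to 1.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

DEFAULT_POOLS: dict[str, tuple[str, ...]] = {
    "bivalent": ("Poised_Promoter",),
    "active": ("Active_Promoter", "Weak_Promoter"),
    "repressive": ("Repressed", "Heterochrom"),
}

UNCOVERED_STATE = "_uncovered"


@dataclass
class GeneStateCall:
    gene: str
    chrom: str
    tss: int
    occupancy: dict[str, float]  # state label -> fraction of the window
    assigned_class: str


@dataclass
class ClassifierConfig:
    tss_halfwidth: int = 250
    pools: dict[str, tuple[str, ...]] = field(default_factory=lambda: dict(DEFAULT_POOLS))


def _occupancy(
    window_start: int, window_end: int, seg_chrom: pd.DataFrame
) -> dict[str, float]:
    width = window_end - window_start
    occ: dict[str, float] = {}
    covered = 0
    starts = seg_chrom["start"].to_numpy()
    ends = seg_chrom["end"].to_numpy()
    states = seg_chrom["state"].to_numpy()
    lo = int(np.searchsorted(ends, window_start, side="right"))
    for i in range(lo, len(starts)):
        if starts[i] >= window_end:
            break
        ov = min(int(ends[i]), window_end) - max(int(starts[i]), window_start)
        if ov > 0:
            occ[states[i]] = occ.get(states[i], 0.0) + ov
            covered += ov
    if covered < width:
        occ[UNCOVERED_STATE] = occ.get(UNCOVERED_STATE, 0.0) + (width - covered)
    return {s: v / width for s, v in occ.items()}


def classify_gene_states(
    genes: pd.DataFrame,
    segmentation: pd.DataFrame,
    config: ClassifierConfig | None = None,
    chrom_lengths: dict[str, int] | None = None,
    tally: dict | None = None,
) -> list[GeneStateCall]:
    """Classify every gene by state occupancy of [TSS - hw, TSS + hw).

    ``genes`` needs columns gene, chrom, strand, tss (TSS already
    strand-resolved); ``segmentation`` needs chrom, start, end, state with
    non-overlapping intervals per chromosome.  The class is the pool with
    a strict plurality of occupied bp; no occupied pool or a tie gives
    "other".  Genes whose window leaves the chromosome (when lengths are
    provided) are excluded and tallied.
    """
    config = config or ClassifierConfig()
    tally = tally if tally is not None else {}
    tally.setdefault("off_chromosome", 0)
    seg_sorted = {
        chrom: grp.sort_values("start").reset_index(drop=True)
        for chrom, grp in segmentation.groupby("chrom")
    }
    for chrom, grp in seg_sorted.items():
        if (grp["start"].to_numpy()[1:] < grp["end"].to_numpy()[:-1]).any():
            raise ValueError(f"overlapping segmentation intervals on {chrom}")
    empty = pd.DataFrame(columns=["start", "end", "state"])
    out: list[GeneStateCall] = []
    hw = config.tss_halfwidth
    for row in genes.itertuples(index=False):
        tss = int(row.tss)
        ws, we = tss - hw, tss + hw
        if ws < 0 or (
            chrom_lengths is not None and we > chrom_lengths.get(row.chrom, we)
        ):
            tally["off_chromosome"] += 1
            continue
        occ = _occupancy(ws, we, seg_sorted.get(row.chrom, empty))
        pool_occ = {
            pool: sum(occ.get(s, 0.0) for s in members)
            for pool, members in config.pools.items()
        }
        best = max(pool_occ.values(), default=0.0)
        winners = [p for p, v in pool_occ.items() if v == best]
        cls = winners[0] if best > 0 and len(winners) == 1 else "other"
        out.append(GeneStateCall(row.gene, row.chrom, tss, occ, cls))
    return out


def calls_to_frame(calls: list[GeneStateCall]) -> pd.DataFrame:
    return pd.DataFrame(
        [(c.gene, c.chrom, c.tss, c.assigned_class) for c in calls],
        columns=["gene", "chrom", "tss", "assigned_class"],
    )
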