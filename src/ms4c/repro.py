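"""Reproducibility of interaction profiles between libraries.

Raw per-site 4C counts are too noisy for direct correlation, so profiles
are first reduced to cis-hit coverage: counts are binarized (any read = 1)
and averaged over all restriction sites within 100 kb of each site.  The
resulting smooth [0, 1] tracks from two libraries on the same site grid
are compared by Spearman rank correlation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .readproc import SiteCounts


@dataclass
class CoverageTrack:
    """Smoothed binary interaction profile on the bait chromosome."""

    bait_name: str
    chrom: str
    site_positions: np.ndarray
    coverage: np.ndarray  # values in [0, 1]


def cis_hit_coverage(counts: SiteCounts, window: int = 100_000) -> CoverageTrack:
    """Per site: fraction of sites within +/- window bp (inclusive) of it
    that carry at least one read.  Windows are truncated at chromosome
    ends; a site always contains itself, so coverage is always defined."""
    chrom = counts.bait_chrom
    sites = counts.restriction_map[chrom]
    binary = (counts.counts[chrom] > 0).astype(float)
    csum = np.concatenate([[0.0], np.cumsum(binary)])
    lo = np.searchsorted(sites, sites - window, side="left")
    hi = np.searchsorted(sites, sites + window, side="right")
    cov = (csum[hi] - csum[lo]) / (hi - lo)
    return CoverageTrack(counts.bait_name, chrom, sites.copy(), cov)


def replicate_correlation(a: CoverageTrack, b: CoverageTrack) -> float:
    """Spearman rho between two coverage tracks on identical site grids
    (average ranks under ties).  A constant track has no rank ordering, so
    the coefficient is undefined and returned as NaN, never coerced to 0."""
    if a.chrom != b.chrom or not np.array_equal(a.site_positions, b.site_positions):
        raise ValueError("coverage tracks are on different site grids")
    if np.all(a.coverage == a.coverage[0]) or np.all(b.coverage == b.coverage[0]):
        return float("nan")
    rho, _ = stats.spearmanr(a.coverage, b.coverage)
    return float(rho)


def correlation_matrix(tracks: dict[str, CoverageTrack]):
    """Pairwise Spearman rho across named samples (same grid required)."""
    import pandas as pd

    names = list(tracks)
    mat = np.full((len(names), len(names)), np.nan)
    for i, ni in enumerate(names):
        for j, nj in enumerate(names):
            mat[i, j] = 1.0 if i == j else replicate_correlation(tracks[ni], tracks[nj])
    return pd.DataFrame(mat, index=names, columns=names)
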