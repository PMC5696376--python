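"""Lamina-associated domains (LADs) from DamID log2-ratio probe tracks.

A LAD is a genomic interval whose DamID log2(Dam-LMNB1/Dam) signal is
positive, indicating nuclear-lamina contact.  Calling follows the classic
microarray procedure: binarize the per-probe signal (positive -> +1,
non-positive -> -1), slide a two-sided 99-probe filter along the array and
score each probe by the difference of the mean binary value between its
right and left windows; local extrema of |D| above a threshold mark LAD
edges (D > 0 a left edge, D < 0 a right edge), and edge pairs whose raw
mean signal is positive become LADs.  Per-gene lamina association is the
mean raw signal over probes inside the gene body, compared between gene
groups by ECDFs and Mann-Whitney tests.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats


@dataclass
class LadSet:
    """Called LADs on one chromosome plus the evidence behind them."""

    chrom: str
    lads: list[tuple[int, int]]          # intervals in bp (probe coordinates)
    left_edges: list[int]                # probe indices
    right_edges: list[int]
    binary: np.ndarray                   # per-probe +1/-1
    edge_score: np.ndarray               # D(i); NaN where undefined


@dataclass
class GeneLaminaSignal:
    gene: str
    mean_signal: float
    probe_count: int


def binarize(values: np.ndarray) -> np.ndarray:
    """Positive -> +1, non-positive -> -1 (zero treated as non-lamina)."""
    return np.where(np.asarray(values) > 0, 1, -1).astype(np.int8)


def edge_filter(binary: np.ndarray, halfwidth: int = 99) -> np.ndarray:
    """D(i) = mean(binary of the right ``halfwidth`` probes) - mean(binary
    of the left ``halfwidth`` probes), excluding probe i itself; NaN where
    a full window does not fit."""
    n = len(binary)
    d = np.full(n, np.nan)
    if n < 2 * halfwidth + 1:
        return d
    csum = np.concatenate([[0], np.cumsum(binary.astype(np.int64))])
    idx = np.arange(halfwidth, n - halfwidth)
    left = (csum[idx] - csum[idx - halfwidth]) / halfwidth
    right = (csum[idx + 1 + halfwidth] - csum[idx + 1]) / halfwidth
    d[idx] = right - left
    return d


def _local_maxima(absd: np.ndarray, threshold: float) -> list[int]:
    """Indices where |D| >= threshold and |D| is a local maximum among the
    immediate neighbours; on plateaus the leftmost probe wins."""
    out = []
    n = len(absd)
    for i in range(n):
        v = absd[i]
        if not np.isfinite(v) or v < threshold:
            continue
        prev = absd[i - 1] if i > 0 else -np.inf
        nxt = absd[i + 1] if i < n - 1 else -np.inf
        prev = prev if np.isfinite(prev) else -np.inf
        nxt = nxt if np.isfinite(nxt) else -np.inf
        if v > prev and v >= nxt:
            out.append(i)
    return out


def call_lads(
    probes: np.ndarray,
    values: np.ndarray,
    chrom: str = "chr1",
    filter_halfwidth: int = 99,
    edge_threshold: float = 1.0,
) -> LadSet | None:
    """Call LADs on one chromosome from probe positions and log2 ratios.

    Needs at least 2 x halfwidth + 1 probes (else returns None with a
    warning).  Candidate LADs run from each left edge (D > 0) to the next
    right edge (D < 0); a leading right edge extends a LAD from the first
    probe, a trailing left edge to the last probe, and an edge-free
    all-positive track is one chromosome-spanning LAD.  Candidates are
    kept only if their mean raw signal is positive.
    """
    probes = np.asarray(probes)
    values = np.asarray(values)
    if len(probes) < 2 * filter_halfwidth + 1:
        warnings.warn(f"{chrom}: too few probes for the {filter_halfwidth}-probe filter")
        return None
    binary = binarize(values)
    d = edge_filter(binary, filter_halfwidth)
    cands = _local_maxima(np.abs(d), edge_threshold)
    left = [i for i in cands if d[i] > 0]
    right = [i for i in cands if d[i] < 0]
    events = sorted([(i, "L") for i in left] + [(i, "R") for i in right])

    candidates: list[tuple[int, int]] = []  # probe-index intervals, inclusive
    open_left: int | None = None
    saw_edge = False
    for i, kind in events:
        saw_edge = True
        if kind == "L":
            if open_left is None:
                open_left = i
        else:
            start = 0 if open_left is None else open_left
            candidates.append((start, i))
            open_left = None
    if open_left is not None:
        candidates.append((open_left, len(probes) - 1))
    if not saw_edge:
        candidates.append((0, len(probes) - 1))

    lads: list[tuple[int, int]] = []
    for a, b in candidates:
        if b <= a:
            continue
        if values[a : b + 1].mean() > 0:
            lads.append((int(probes[a]), int(probes[b])))
    return LadSet(
        chrom=chrom, lads=lads,
        left_edges=left, right_edges=right,
        binary=binary, edge_score=d,
    )


def gene_lamina_signal(
    probes: np.ndarray,
    values: np.ndarray,
    genes: pd.DataFrame,
    chrom: str | None = None,
    tally: dict | None = None,
) -> list[GeneLaminaSignal]:
    """Mean probe signal over each gene body [start, end).

    ``genes`` needs columns gene, start, end (and chrom when ``chrom`` is
    given, to restrict to that chromosome).  Genes covering no probe are
    excluded and tallied.
    """
    tally = tally if tally is not None else {}
    tally.setdefault("no_probes", 0)
    probes = np.asarray(probes)
    values = np.asarray(values)
    out: list[GeneLaminaSignal] = []
    for row in genes.itertuples(index=False):
        if chrom is not None and getattr(row, "chrom", chrom) != chrom:
            continue
        lo = int(np.searchsorted(probes, row.start, side="left"))
        hi = int(np.searchsorted(probes, row.end, side="left"))
        if hi <= lo:
            tally["no_probes"] += 1
            continue
        out.append(GeneLaminaSignal(row.gene, float(values[lo:hi].mean()), hi - lo))
    return out


@dataclass
class GroupComparison:
    ecdf: dict[str, tuple[np.ndarray, np.ndarray]]  # group -> (sorted x, F(x))
    reference: str | None
    pvalues: dict[str, float | None]  # group -> two-sided Mann-Whitney p vs reference


def compare_groups_ecdf(
    signals_by_group: dict[str, list[float]],
    reference: str | None = None,
) -> GroupComparison:
    """ECDF per gene group plus two-sided Mann-Whitney tests against the
    reference group (default: the first group).  Pairs where either group
    has fewer than 2 values get p = None (undefined, not 0)."""
    if not signals_by_group:
        raise ValueError("at least one group required")
    ecdf = {}
    for g, vals in signals_by_group.items():
        x = np.sort(np.asarray(vals, dtype=float))
        ecdf[g] = (x, np.arange(1, len(x) + 1) / len(x) if len(x) else np.array([]))
    pvals: dict[str, float | None] = {}
    if len(signals_by_group) >= 2:
        reference = reference or next(iter(signals_by_group))
        ref = signals_by_group[reference]
        for g, vals in signals_by_group.items():
            if g == reference:
                continue
            if len(ref) < 2 or len(vals) < 2:
                pvals[g] = None
            else:
                res = stats.mannwhitneyu(vals, ref, alternative="two-sided")
                pvals[g] = float(res.pvalue)
    else:
        reference = None
    return GroupComparison(ecdf=ecdf, reference=reference, pvalues=pvals)


def plot_ecdf(comparison: GroupComparison, path: str, xlabel: str = "log2(Dam-LMNB1/Dam)") -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 4))
    for g, (x, f) in comparison.ecdf.items():
        if len(x):
            ax.step(x, f, where="post", label=g)
    ax.set_xlabel(xlabel)
    ax.set_ylabel("cumulative fraction")
    ax.legend(fontsize=7)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
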