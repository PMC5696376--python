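"""Contact probabilities per restriction site and per gene; domainograms.

The enrichment of reads in a small window around a position, relative to a
large local window, measures contact probability while cancelling the
distance-decay background.  Window bounds follow the 4C convention of
distances in bp rather than numbers of sites: small windows up to 100 kb,
large windows of 3 Mb.  Two statistics are used depending on distance from
the bait: within 8 Mb (proximal) a one-sided Mann-Whitney U test compares
per-site counts inside the small window against the rest of the large
window; beyond 8 Mb (distal) a one-sided binomial test compares the read
count in the small window against the expectation from the site fraction.
Gene-level contact probability uses the binomial form on a TSS +/- 25 kb
window with Benjamini-Hochberg adjustment across all genes tested per bait.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .readproc import SiteCounts


@dataclass
class WindowConfig:
    """Window geometry and calling defaults (all sizes in bp)."""

    small_window_max: int = 100_000
    large_window: int = 3_000_000
    proximal_bound: int = 8_000_000
    gene_small_window: int = 25_000
    window_ladder: list[int] = field(default_factory=list)
    alpha: float = 0.05
    q_cutoff: float = 0.05
    domainogram_cap: float = 10.0

    def __post_init__(self) -> None:
        if not self.window_ladder:
            # 20 log-spaced half-widths, 2 kb .. 100 kb
            self.window_ladder = [
                int(round(x)) for x in np.geomspace(2_000, self.small_window_max, 20)
            ]
        if max(self.window_ladder) > self.small_window_max:
            raise ValueError("ladder scales must not exceed small_window_max")
        if self.small_window_max >= self.large_window:
            raise ValueError("small_window_max must be below large_window")
        if self.proximal_bound <= self.large_window:
            raise ValueError("proximal_bound must exceed large_window")


@dataclass
class DomainogramMatrix:
    """Capped -log10(p) per (ladder scale, site); the plotted object."""

    bait_name: str
    chrom: str
    site_positions: np.ndarray
    scales: list[int]
    neglogp: np.ndarray  # shape (len(scales), len(site_positions)), values in [0, cap]
    cap: float = 10.0

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.neglogp, index=self.scales, columns=self.site_positions)
        df.index.name = "scale_bp"
        df.columns.name = "site_pos"
        return df


@dataclass
class GeneContact:
    bait_name: str
    gene: str
    chrom: str
    tss: int
    rpm: float
    p: float
    q: float = float("nan")
    called: bool = False


def binomial_tail_p(k: int, n: int, p0: float) -> float:
    """One-sided upper-tail binomial p-value, P(X >= k | n, p0)."""
    if n == 0:
        return 1.0
    if k <= 0:
        return 1.0
    return float(stats.binom.sf(k - 1, n, p0))


def _window_slice(sites: np.ndarray, center: int, halfwidth: int) -> slice:
    lo = int(np.searchsorted(sites, center - halfwidth, side="left"))
    hi = int(np.searchsorted(sites, center + halfwidth, side="right"))
    return slice(lo, hi)


def site_contact_probability(
    counts: SiteCounts, site_index: int, config: WindowConfig, scale: int
) -> tuple[float, str]:
    """Contact p-value of one restriction site on the bait chromosome.

    Proximal sites (|site - bait| <= proximal_bound) use the one-sided
    Mann-Whitney U (alternative "greater") on per-site counts, small window
    (+/- scale, inclusive) vs the large window minus the small window;
    normal approximation with tie correction.  Distal sites use the exact
    one-sided binomial with k = reads in the small window, n = reads in the
    large window, p0 = sites(small) / sites(large).  Windows are truncated
    at chromosome ends.  Returns (p, flag) with flag "ok" or
    "uninformative".
    """
    chrom = counts.bait_chrom
    sites = counts.restriction_map[chrom]
    vals = counts.stat_counts(chrom)
    pos = int(sites[site_index])
    small = _window_slice(sites, pos, scale)
    large = _window_slice(sites, pos, config.large_window)
    large_total = int(vals[large].sum())
    if large_total == 0:
        return 1.0, "uninformative"
    distance = abs(pos - counts.bait_pos)
    if distance <= config.proximal_bound:
        x = vals[small]
        mask = np.ones(large.stop - large.start, dtype=bool)
        mask[small.start - large.start : small.stop - large.start] = False
        y = vals[large][mask]
        if len(x) == 0 or len(y) == 0:
            return 1.0, "uninformative"
        if x.max(initial=0) == x.min(initial=0) and y.max(initial=0) == y.min(initial=0) \
                and x.max(initial=0) == y.max(initial=0):
            return 1.0, "uninformative"  # fully tied, U-test degenerate
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = stats.mannwhitneyu(x, y, alternative="greater", method="asymptotic")
        p = float(res.pvalue)
        if np.isnan(p):
            return 1.0, "uninformative"
        return p, "ok"
    k = int(vals[small].sum())
    n_small = small.stop - small.start
    n_large = large.stop - large.start
    if n_large == 0 or n_small == 0:
        return 1.0, "uninformative"
    p0 = n_small / n_large
    return binomial_tail_p(k, large_total, p0), "ok"


def build_domainogram(counts: SiteCounts, config: WindowConfig) -> DomainogramMatrix:
    """Multi-scale significance matrix over every site of the bait
    chromosome: entry (scale, site) = min(-log10 p, cap), the black-to-
    yellow colour scale running from p = 1 to p = 1e-10."""
    if not config.window_ladder:
        raise ValueError("window ladder must be non-empty")
    chrom = counts.bait_chrom
    sites = counts.restriction_map[chrom]
    mat = np.zeros((len(config.window_ladder), len(sites)))
    for i, scale in enumerate(config.window_ladder):
        for j in range(len(sites)):
            p, _ = site_contact_probability(counts, j, config, scale)
            mat[i, j] = min(-np.log10(max(p, 1e-300)), config.domainogram_cap)
    return DomainogramMatrix(
        bait_name=counts.bait_name, chrom=chrom, site_positions=sites.copy(),
        scales=list(config.window_ladder), neglogp=mat, cap=config.domainogram_cap,
    )


def plot_domainogram(matrix: DomainogramMatrix, path: str) -> None:
    """Render the domainogram as position x scale heat map, black (p = 1)
    through yellow (p <= 1e-10)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from matplotlib.colors import LinearSegmentedColormap

    cmap = LinearSegmentedColormap.from_list(
        "domainogram", [(0, 0, 0), (0.7, 0.2, 0.0), (1.0, 1.0, 0.0)]
    )
    fig, ax = plt.subplots(figsize=(10, 3))
    extent = [
        matrix.site_positions[0], matrix.site_positions[-1],
        0, len(matrix.scales),
    ]
    im = ax.imshow(
        matrix.neglogp, aspect="auto", origin="lower", cmap=cmap,
        vmin=0.0, vmax=matrix.cap, extent=extent, interpolation="nearest",
    )
    ax.set_yticks(np.arange(len(matrix.scales)) + 0.5)
    ax.set_yticklabels([f"{s/1000:g}k" for s in matrix.scales], fontsize=5)
    ax.set_xlabel(f"{matrix.chrom} position (bp)")
    ax.set_ylabel("window half-width")
    ax.set_title(f"domainogram: {matrix.bait_name}")
    fig.colorbar(im, ax=ax, label="-log10 p")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def gene_contact_table(
    counts: SiteCounts,
    genes: pd.DataFrame,
    config: WindowConfig,
    tally: dict | None = None,
) -> list[GeneContact]:
    """Gene-to-gene contact probabilities on the bait chromosome.

    Per gene: small window = TSS +/- gene_small_window, large window =
    TSS +/- large_window (both truncated at chromosome ends); one-sided
    binomial as for distal sites; q = Benjamini-Hochberg across all genes
    tested for this bait.  Genes with no restriction site in the small
    window, and genes whose small window intersects the bait mask
    (bait +/- small_window_max, the religation-dominated zone), are
    excluded and tallied.
    """
    chrom = counts.bait_chrom
    sites = counts.restriction_map[chrom]
    vals = counts.stat_counts(chrom)
    tally = tally if tally is not None else {}
    tally.setdefault("no_sites", 0)
    tally.setdefault("bait_masked", 0)
    tally.setdefault("off_chromosome", 0)
    out: list[GeneContact] = []
    for row in genes.itertuples(index=False):
        if row.chrom != chrom:
            tally["off_chromosome"] += 1
            continue
        tss = int(row.tss)
        if abs(tss - counts.bait_pos) <= config.gene_small_window + config.small_window_max:
            tally["bait_masked"] += 1
            continue
        small = _window_slice(sites, tss, config.gene_small_window)
        large = _window_slice(sites, tss, config.large_window)
        n_small = small.stop - small.start
        n_large = large.stop - large.start
        if n_small == 0:
            tally["no_sites"] += 1
            continue
        k = int(vals[small].sum())
        n = int(vals[large].sum())
        p0 = n_small / n_large
        p = binomial_tail_p(k, n, p0)
        out.append(GeneContact(
            bait_name=counts.bait_name, gene=row.gene, chrom=chrom, tss=tss,
            rpm=k * counts.rpm_factor, p=p,
        ))
    if out:
        _, q, _, _ = multipletests([g.p for g in out], method="fdr_bh")
        for g, qv in zip(out, q):
            g.q = float(qv)
            g.called = g.q <= config.q_cutoff
    return out


def call_targets(table: list[GeneContact], q_cutoff: float = 0.05) -> list[GeneContact]:
    """Called target genes: q <= cutoff, sorted by (q, genomic position)."""
    hits = [g for g in table if g.q <= q_cutoff]
    return sorted(hits, key=lambda g: (g.q, g.chrom, g.tss))


def contacts_to_frame(table: list[GeneContact]) -> pd.DataFrame:
    return pd.DataFrame(
        [(g.bait_name, g.gene, g.chrom, g.tss, g.rpm, g.p, g.q, g.called) for g in table],
        columns=["bait", "gene", "chrom", "tss", "rpm", "p", "q", "called"],
    )
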