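"""Colocalization enrichment and knockdown-disruption statistics.

Three analyses sit downstream of gene-level contact calling:

* bivalent-gene enrichment among the interaction targets of each bait —
  the expected bivalent target count comes from the bivalent proportion of
  genes on the bait's own chromosome, and the summary statistic is
  log2(observed frequency / expected frequency);
* exact 2x2 association tests (Fisher's exact, computed from the
  hypergeometric distribution) for colocalization contingency tables;
* knockdown reduction: the RPM interaction signal in TSS +/- 25 kb under
  shNegative vs two independent shRNAs; a target is "disrupted" when the
  reduction rate sh/shNeg is <= 0.7 in both shRNAs, and disruption is
  compared between bivalent and nonbivalent targets by ECDF, Mann-Whitney,
  and Fisher's exact test.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .lads import GroupComparison, compare_groups_ecdf
from .readproc import SiteCounts


@dataclass
class EnrichmentRecord:
    bait: str
    bait_class: str
    n_targets: int
    observed_bivalent: int
    expected_bivalent: float
    log2_oe: float


@dataclass
class FisherResult:
    table: tuple[tuple[int, int], tuple[int, int]]
    odds_ratio: float  # NaN when undefined (zero margin or zero cell)
    p: float


@dataclass
class ReductionRecord:
    bait: str
    gene: str
    target_class: str  # "bivalent" or "nonbivalent"
    rpm_neg: float
    rpm_sh1: float
    rpm_sh2: float
    rate_sh1: float
    rate_sh2: float
    disrupted: bool


def fisher_colocalization(table) -> FisherResult:
    """Two-sided Fisher's exact test on a 2x2 table.

    The p-value sums hypergeometric probabilities of all tables with the
    observed margins whose probability does not exceed the observed
    table's (with a 1e-7 relative tolerance for floating-point ties).  A
    zero margin makes every table with those margins identical: p = 1 and
    the odds ratio is undefined (NaN).
    """
    (a, b), (c, d) = table
    if min(a, b, c, d) < 0 or any(x != int(x) for x in (a, b, c, d)):
        raise ValueError("2x2 table must hold non-negative integers")
    a, b, c, d = int(a), int(b), int(c), int(d)
    n = a + b + c + d
    r1, c1 = a + b, a + c
    if r1 == 0 or c1 == 0 or r1 == n or c1 == n:
        return FisherResult(((a, b), (c, d)), float("nan"), 1.0)
    lo = max(0, r1 + c1 - n)
    hi = min(r1, c1)
    support = np.arange(lo, hi + 1)
    pmf = stats.hypergeom.pmf(support, n, r1, c1)
    p_obs = pmf[a - lo]
    p = float(pmf[pmf <= p_obs * (1 + 1e-7)].sum())
    odds = (a * d) / (b * c) if b * c > 0 else float("nan")
    return FisherResult(((a, b), (c, d)), odds, min(p, 1.0))


def log2_observed_expected(observed: int, expected: float) -> float:
    """log2(O/E) with a 0.5 pseudocount on both counts when observed = 0,
    so the ratio stays finite for empty target sets."""
    if expected <= 0:
        return float("nan")
    if observed == 0:
        return float(np.log2(0.5 / (expected + 0.5)))
    return float(np.log2(observed / expected))


def bivalent_enrichment(
    targets_per_bait: dict[str, set[str]],
    gene_classes: dict[str, str],
    genes: pd.DataFrame,
    bait_genes: dict[str, str],
    bait_classes: dict[str, str],
    tally: dict | None = None,
) -> tuple[list[EnrichmentRecord], dict[str, float | None]]:
    """Observed vs expected bivalent genes among each bait's targets.

    Expected = (targets tested) x (bivalent genes on the bait chromosome /
    genes on the bait chromosome), the bait gene itself excluded from the
    denominator.  Baits are grouped by their own class and the bivalent
    group's log2(O/E) values are compared against every other class by a
    two-sided Mann-Whitney test (None when a group is too small).
    """
    tally = tally if tally is not None else {}
    tally.setdefault("no_chromosome_genes", 0)
    gene_chrom = dict(zip(genes["gene"], genes["chrom"]))
    records: list[EnrichmentRecord] = []
    for bait, targets in targets_per_bait.items():
        bait_gene = bait_genes[bait]
        chrom = gene_chrom.get(bait_gene)
        chrom_genes = [
            g for g in genes.loc[genes["chrom"] == chrom, "gene"] if g != bait_gene
        ]
        if not chrom_genes:
            tally["no_chromosome_genes"] += 1
            continue
        biv_fraction = float(
            np.mean([gene_classes.get(g) == "bivalent" for g in chrom_genes])
        )
        observed = sum(1 for g in targets if gene_classes.get(g) == "bivalent")
        expected = len(targets) * biv_fraction
        records.append(EnrichmentRecord(
            bait=bait, bait_class=bait_classes.get(bait, "other"),
            n_targets=len(targets), observed_bivalent=observed,
            expected_bivalent=expected,
            log2_oe=log2_observed_expected(observed, expected),
        ))
    by_class: dict[str, list[float]] = {}
    for r in records:
        if np.isfinite(r.log2_oe):
            by_class.setdefault(r.bait_class, []).append(r.log2_oe)
    comparisons: dict[str, float | None] = {}
    biv = by_class.get("bivalent", [])
    for cls, vals in by_class.items():
        if cls == "bivalent":
            continue
        if len(biv) < 2 or len(vals) < 2:
            comparisons[cls] = None
        else:
            comparisons[cls] = float(
                stats.mannwhitneyu(biv, vals, alternative="two-sided").pvalue
            )
    return records, comparisons


def _window_rpm(counts: SiteCounts, chrom: str, tss: int, halfwidth: int) -> float:
    sites = counts.restriction_map[chrom]
    lo = int(np.searchsorted(sites, tss - halfwidth, side="left"))
    hi = int(np.searchsorted(sites, tss + halfwidth, side="right"))
    return float(counts.stat_counts(chrom)[lo:hi].sum() * counts.rpm_factor)


def knockdown_reduction(
    counts_neg: SiteCounts,
    counts_sh1: SiteCounts,
    counts_sh2: SiteCounts,
    targets: pd.DataFrame,
    window_halfwidth: int = 25_000,
    disruption_rate: float = 0.7,
    tally: dict | None = None,
) -> tuple[list[ReductionRecord], GroupComparison, FisherResult]:
    """Knockdown effect on the called targets of one bait.

    ``targets`` needs columns gene, chrom, tss, target_class ("bivalent" /
    "nonbivalent").  Per gene the RPM in TSS +/- window_halfwidth is read
    from each condition's track; reduction rates are sh/shNegative and a
    gene is disrupted when both rates are <= disruption_rate (reduction
    "to at least 30%" read as rate <= 0.7, inclusive).  Genes with zero
    shNegative RPM have undefined rates and are excluded.  Returns the
    per-gene records, the bivalent-vs-nonbivalent ECDF comparison of the
    pooled sh1+sh2 rates, and the disrupted x class Fisher table.
    """
    tally = tally if tally is not None else {}
    tally.setdefault("zero_reference", 0)
    records: list[ReductionRecord] = []
    for row in targets.itertuples(index=False):
        rpm_neg = _window_rpm(counts_neg, row.chrom, int(row.tss), window_halfwidth)
        rpm1 = _window_rpm(counts_sh1, row.chrom, int(row.tss), window_halfwidth)
        rpm2 = _window_rpm(counts_sh2, row.chrom, int(row.tss), window_halfwidth)
        if rpm_neg == 0:
            tally["zero_reference"] += 1
            continue
        r1, r2 = rpm1 / rpm_neg, rpm2 / rpm_neg
        records.append(ReductionRecord(
            bait=counts_neg.bait_name, gene=row.gene, target_class=row.target_class,
            rpm_neg=rpm_neg, rpm_sh1=rpm1, rpm_sh2=rpm2,
            rate_sh1=r1, rate_sh2=r2,
            disrupted=(r1 <= disruption_rate and r2 <= disruption_rate),
        ))
    rates_by_class: dict[str, list[float]] = {"bivalent": [], "nonbivalent": []}
    for r in records:
        rates_by_class.setdefault(r.target_class, []).extend([r.rate_sh1, r.rate_sh2])
    comparison = compare_groups_ecdf(
        {k: v for k, v in rates_by_class.items() if v} or {"all": []},
        reference="nonbivalent" if rates_by_class.get("nonbivalent") else None,
    )
    biv_dis = sum(1 for r in records if r.target_class == "bivalent" and r.disrupted)
    biv_not = sum(1 for r in records if r.target_class == "bivalent" and not r.disrupted)
    non_dis = sum(1 for r in records if r.target_class != "bivalent" and r.disrupted)
    non_not = sum(1 for r in records if r.target_class != "bivalent" and not r.disrupted)
    fisher = fisher_colocalization(((biv_dis, biv_not), (non_dis, non_not)))
    return records, comparison, fisher


def reductions_to_frame(records: list[ReductionRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [(r.bait, r.gene, r.target_class, r.rpm_neg, r.rpm_sh1, r.rpm_sh2,
          r.rate_sh1, r.rate_sh2, r.disrupted) for r in records],
        columns=["bait", "gene", "target_class", "rpm_neg", "rpm_sh1", "rpm_sh2",
                 "rate_sh1", "rate_sh2", "disrupted"],
    )


def enrichment_to_frame(records: list[EnrichmentRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [(r.bait, r.bait_class, r.n_targets, r.observed_bivalent,
          r.expected_bivalent, r.log2_oe) for r in records],
        columns=["bait", "bait_class", "n_targets", "observed_bivalent",
                 "expected_bivalent", "log2_oe"],
    )
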