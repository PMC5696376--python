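"""Raw read pairs -> deduplicated per-restriction-site count tracks.

The processing chain mirrors how a multiplexed 4C library is structured:
R1 runs from a bait-specific primer across the reconstituted HindIII
junction (AAGCTT) into the ligated partner fragment, R2 reads back from the
sonication breakpoint.  Stages:

1. split R1 at the first AAGCTT and assign the bait-side prefix to a bait
   (paralogous baits separated by discriminating SNP bases);
2. map the motif-bearing target part (exact match on a synthetic genome, or
   accept a pre-mapped pairs table) and flag self-ligation / undigested
   artifacts by fragment adjacency;
3. remove PCR duplicates keyed on the sonication breakpoint;
4. count each kept pair at every HindIII site within 1000 bp (inclusive) of
   the target position, yielding the wiggle-equivalent track, with cis/trans
   totals and a library-complexity QC extrapolation.

Every input pair lands in exactly one accounting category, so
``DropTally.check()`` verifies read conservation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .simulate import HINDIII, MOTIF_LEN, SyntheticGenome, revcomp


@dataclass
class BaitSpec:
    """One bait viewpoint of the multiplexed library.

    bait_side_sequence is the expected R1 prefix up to and including the
    HindIII motif; ``N`` bases match anything (used together with
    discriminating_variants to separate paralogous baits that differ only
    at a SNP).  bait_fragment = (chrom, start, end) bounded by two
    restriction sites; the junction is its right end.
    """

    name: str
    bait_side_sequence: str
    bait_fragment: tuple[str, int, int]
    discriminating_variants: list[tuple[int, str]] = field(default_factory=list)
    group: str = "other"

    def __post_init__(self) -> None:
        if not self.bait_side_sequence:
            raise ValueError("bait_side_sequence must be non-empty")
        for off, base in self.discriminating_variants:
            if not 0 <= off < len(self.bait_side_sequence):
                raise ValueError("variant offset outside bait_side_sequence")

    @property
    def chrom(self) -> str:
        return self.bait_fragment[0]

    @property
    def junction(self) -> int:
        return self.bait_fragment[2]


@dataclass
class SplitRead:
    bait_name: str
    target_part: str   # AAGCTT + suffix
    mate: str          # R2 sequence


@dataclass
class ProcessedPair:
    bait_name: str
    chrom: str
    strand: str
    site_pos: int      # junction-proximal restriction site of the target fragment
    site_index: int
    breakpoint: int
    self_ligation: bool = False
    undigested: bool = False
    duplicate: bool = False

    @property
    def kept(self) -> bool:
        return not (self.self_ligation or self.undigested or self.duplicate)

    def dedup_key(self) -> tuple:
        return (self.bait_name, self.chrom, self.site_pos, self.strand, self.breakpoint)


@dataclass
class DropTally:
    """Per-category read accounting; categories are disjoint and sum to the
    number of input pairs."""

    input_pairs: int = 0
    no_motif: int = 0
    unmatched: int = 0
    ambiguous: int = 0
    unmapped: int = 0
    multimapped: int = 0
    self_ligation: int = 0
    undigested: int = 0
    duplicate: int = 0
    kept: int = 0

    def check(self) -> bool:
        return self.input_pairs == (
            self.no_motif + self.unmatched + self.ambiguous + self.unmapped
            + self.multimapped + self.self_ligation + self.undigested
            + self.duplicate + self.kept
        )

    def as_dict(self) -> dict:
        return dict(self.__dict__)


@dataclass
class SiteCounts:
    """Per-restriction-site read counts of one bait library.

    ``counts[chrom]`` is the wiggle track (every site within 1000 bp of a
    read's target position is incremented, so closely spaced sites share
    reads); ``raw[chrom]`` assigns each read once, to the target
    fragment's junction-proximal site.  Both are aligned to
    ``restriction_map[chrom]``.  The wiggle is the published display/track
    convention; the raw counts are the statistical evidence (window read
    counts without double counting).  ``raw`` may be None for tracks from
    external wiggle files, in which case statistics fall back to the
    wiggle counts.
    """

    bait_name: str
    bait_chrom: str
    bait_pos: int
    restriction_map: dict[str, np.ndarray]
    counts: dict[str, np.ndarray]
    raw: dict[str, np.ndarray] | None = None
    total: int = 0
    cis: int = 0
    trans: int = 0

    @property
    def rpm_factor(self) -> float:
        return 1e6 / self.total if self.total else 0.0

    def stat_counts(self, chrom: str) -> np.ndarray:
        """Per-site read counts used by the contact statistics."""
        return self.raw[chrom] if self.raw is not None else self.counts[chrom]


@dataclass
class QCReport:
    bait_name: str
    total_reads: int
    cis_reads: int
    trans_reads: int
    cis_trans_ratio: float
    observed_distinct_cis: int
    estimated_total_distinct_cis: float
    percent_observed: float
    saturated: bool
    passed: bool


def _seq_match(read_part: str, bait_seq: str) -> bool:
    """Suffix-aligned comparison; N in the bait sequence matches any base."""
    m = min(len(read_part), len(bait_seq))
    if m == 0:
        return False
    r, b = read_part[-m:], bait_seq[-m:]
    return all(bb == "N" or rb == bb for rb, bb in zip(r, b))


def _variants_ok(read_part: str, bait: BaitSpec) -> bool:
    shift = len(read_part) - len(bait.bait_side_sequence)
    for off, base in bait.discriminating_variants:
        pos = shift + off
        if pos < 0:
            return False  # variant position not covered by the read
        if read_part[pos] != base:
            return False
    return True


def split_and_demultiplex(
    read_pairs, baits: list[BaitSpec], tally: DropTally | None = None
) -> tuple[list[SplitRead], DropTally]:
    """Split each R1 at the first AAGCTT and assign the prefix to a bait.

    ``read_pairs`` iterates (r1, r2) sequence strings.  The bait part is
    the prefix through the motif, the target part the motif plus suffix.
    Motif-free pairs, pairs matching no bait, and pairs matching several
    baits that the discriminating variants cannot separate are tallied and
    dropped.
    """
    tally = tally or DropTally()
    out: list[SplitRead] = []
    for r1, r2 in read_pairs:
        tally.input_pairs += 1
        i = r1.find(HINDIII)
        if i == -1:
            tally.no_motif += 1
            continue
        bait_part = r1[: i + MOTIF_LEN]
        target_part = r1[i:]
        candidates = [b for b in baits if _seq_match(bait_part, b.bait_side_sequence)]
        if len(candidates) > 1:
            candidates = [b for b in candidates if _variants_ok(bait_part, b)]
        if not candidates:
            tally.unmatched += 1
            continue
        if len(candidates) > 1:
            tally.ambiguous += 1
            continue
        out.append(SplitRead(candidates[0].name, target_part, r2))
    return out, tally


def _bait_frag_index(bait: BaitSpec, rmap: dict[str, np.ndarray]) -> int:
    sites = rmap[bait.chrom]
    idx = int(np.searchsorted(sites, bait.bait_fragment[1]))
    if idx >= len(sites) or sites[idx] != bait.bait_fragment[1]:
        raise ValueError(f"bait fragment of {bait.name} not bounded by restriction sites")
    return idx


def map_and_filter(
    split_reads: list[SplitRead],
    genome: SyntheticGenome,
    baits: list[BaitSpec],
    tally: DropTally | None = None,
    breakpoint_window: int = 700,
) -> tuple[list[ProcessedPair], DropTally]:
    """Exact-match mapping of target parts onto a sequence-bearing genome.

    Because the target part begins with AAGCTT and the synthetic genome
    carries the motif only at mapped sites, candidate alignments are
    exactly the restriction sites.  Multi-hit reads are dropped; the mate
    is located on the reverse strand within ``breakpoint_window`` bp
    downstream of the junction to recover the sonication breakpoint.
    Self-ligation (target fragment == bait fragment) and undigested
    (adjacent fragment, either side) pairs are flagged.
    """
    if genome.sequence is None:
        raise ValueError("toy mapping requires a sequence-bearing genome")
    tally = tally or DropTally()
    bait_by_name = {b.name: b for b in baits}
    bait_frag = {b.name: _bait_frag_index(b, genome.restriction_map) for b in baits}
    out: list[ProcessedPair] = []
    for sr in split_reads:
        hits: list[tuple[str, int]] = []
        for chrom, _ in genome.chromosomes:
            seq = genome.sequence[chrom]
            for idx, s in enumerate(genome.restriction_map[chrom]):
                if seq[s : s + len(sr.target_part)] == sr.target_part:
                    hits.append((chrom, idx))
        if not hits:
            tally.unmapped += 1
            continue
        if len(hits) > 1:
            tally.multimapped += 1
            continue
        chrom, idx = hits[0]
        s = int(genome.restriction_map[chrom][idx])
        window = genome.sequence[chrom][s : s + breakpoint_window + len(sr.mate)]
        off = window.find(revcomp(sr.mate))
        if off == -1 or not sr.mate:
            tally.unmapped += 1
            continue
        bp = s + off + len(sr.mate)
        bait = bait_by_name[sr.bait_name]
        pp = ProcessedPair(sr.bait_name, chrom, "+", s, idx, bp)
        if chrom == bait.chrom:
            d = idx - bait_frag[sr.bait_name]
            pp.self_ligation = d == 0
            pp.undigested = abs(d) == 1
        if pp.self_ligation:
            tally.self_ligation += 1
        elif pp.undigested:
            tally.undigested += 1
        out.append(pp)
    return out, tally


def load_premapped_pairs(
    table: pd.DataFrame,
    restriction_map: dict[str, np.ndarray],
    baits: list[BaitSpec],
    tally: DropTally | None = None,
) -> tuple[list[ProcessedPair], DropTally]:
    """Real-data path: accept a pairs table (bait, chrom, pos, strand,
    breakpoint) with target coordinates already mapped.

    Each target is assigned to the restriction site whose fragment
    contains ``pos`` (the left boundary site; positions upstream of the
    first site take the first site).  Self-ligation/undigested flags are
    derived from fragment adjacency exactly as in the toy-mapping path.
    """
    tally = tally or DropTally()
    tally.input_pairs += len(table)
    bait_by_name = {b.name: b for b in baits}
    bait_frag = {b.name: _bait_frag_index(b, restriction_map) for b in baits}
    out: list[ProcessedPair] = []
    for row in table.itertuples(index=False):
        bait = bait_by_name.get(row.bait)
        if bait is None:
            tally.unmatched += 1
            continue
        sites = restriction_map.get(row.chrom)
        if sites is None or len(sites) == 0:
            tally.unmapped += 1
            continue
        idx = max(int(np.searchsorted(sites, row.pos, side="right")) - 1, 0)
        s = int(sites[idx])
        pp = ProcessedPair(row.bait, row.chrom, row.strand, s, idx, int(row.breakpoint))
        if row.chrom == bait.chrom:
            d = idx - bait_frag[row.bait]
            pp.self_ligation = d == 0
            pp.undigested = abs(d) == 1
        if pp.self_ligation:
            tally.self_ligation += 1
        elif pp.undigested:
            tally.undigested += 1
        out.append(pp)
    return out, tally


def deduplicate(
    pairs: list[ProcessedPair], tally: DropTally | None = None
) -> list[ProcessedPair]:
    """Mark PCR duplicates: among pairs sharing (bait, chrom, site, strand,
    breakpoint) exactly one survives, in stable input order.  Pairs already
    flagged as ligation artifacts are passed through untouched so the
    accounting categories stay disjoint."""
    seen: set[tuple] = set()
    out: list[ProcessedPair] = []
    for p in pairs:
        if p.self_ligation or p.undigested:
            out.append(p)
            continue
        key = p.dedup_key()
        if key in seen:
            p.duplicate = True
            if tally is not None:
                tally.duplicate += 1
        else:
            seen.add(key)
            p.duplicate = False
        out.append(p)
    return out


def count_per_site(
    pairs: list[ProcessedPair],
    restriction_map: dict[str, np.ndarray],
    bait: BaitSpec,
    window: int = 1000,
    tally: DropTally | None = None,
) -> SiteCounts:
    """Aggregate kept pairs into the per-site wiggle track.

    A pair increments every restriction site within ``window`` bp
    (inclusive) of its target position, so a pair can hit two sites when
    sites lie closer than 2 x window.  cis/trans totals are per pair
    (against the bait chromosome), not per site increment.
    """
    counts = {c: np.zeros(len(s), dtype=np.int64) for c, s in restriction_map.items()}
    raw = {c: np.zeros(len(s), dtype=np.int64) for c, s in restriction_map.items()}
    sc = SiteCounts(
        bait_name=bait.name, bait_chrom=bait.chrom, bait_pos=bait.junction,
        restriction_map=restriction_map, counts=counts, raw=raw,
    )
    for p in pairs:
        if p.bait_name != bait.name or not p.kept:
            continue
        sites = restriction_map.get(p.chrom)
        if sites is None:
            raise ValueError(f"pair target chromosome {p.chrom} absent from restriction map")
        lo = int(np.searchsorted(sites, p.site_pos - window, side="left"))
        hi = int(np.searchsorted(sites, p.site_pos + window, side="right"))
        k = int(np.searchsorted(sites, p.site_pos))
        if not (lo <= k < hi) or sites[k] != p.site_pos:
            raise ValueError("pair target position is not a restriction-map member")
        counts[p.chrom][lo:hi] += 1
        raw[p.chrom][k] += 1
        sc.total += 1
        if p.chrom == bait.chrom:
            sc.cis += 1
        else:
            sc.trans += 1
        if tally is not None:
            tally.kept += 1
    return sc


def _chao_extrapolate(d: int, n: int, f1: int, f2: int, fold: float) -> float:
    """Good-Turing/Chao sample-coverage extrapolation (fallback)."""
    f0 = f1 * f1 / (2 * f2) if f2 > 0 else f1 * (f1 - 1) / 2
    if f0 == 0:
        return float(d)
    extra = (fold - 1.0) * n
    return float(d + f0 * (1.0 - (1.0 - f1 / (n * f0 + f1)) ** extra))


def extrapolate_distinct(multiplicities: np.ndarray, fold: float = 10.0) -> tuple[float, bool]:
    """Distinct-interaction yield at ``fold`` x the current depth.

    Models the duplicate-multiplicity histogram as a zero-truncated
    gamma-mixed Poisson (negative binomial): each distinct interaction i
    is read Poisson(lambda_i) times with gamma-distributed rates.  The
    (r, mu) maximum-likelihood fit gives the unseen fraction
    p0 = (r/(r+mu))^r, hence the interaction universe S = D/(1-p0) and the
    expected distinct count at depth fold*n, S*(1-(r/(r+fold*mu))^r).
    Falls back to the Chao sample-coverage formula when the fit fails.
    Under strongly heavy-tailed rate distributions (e.g. power-law contact
    decay) the estimate behaves as a lower bound.  Returns (estimate,
    saturated) where saturated means no singletons remain.
    """
    from scipy import optimize, special

    m = np.asarray(multiplicities, dtype=float)
    d = len(m)
    if d == 0:
        return 0.0, True
    n = int(m.sum())
    f1 = int((m == 1).sum())
    f2 = int((m == 2).sum())
    if f1 == 0:
        return float(d), True
    if f2 == 0 and (m > 2).sum() == 0:
        # essentially no collision information: linear growth regime
        return _chao_extrapolate(d, n, f1, f2, fold), False
    js, fs = np.unique(m, return_counts=True)

    def nll(params: np.ndarray) -> float:
        r, mu = np.exp(params)
        logp0 = r * (np.log(r) - np.log(r + mu))
        ll = fs * (
            special.gammaln(js + r) - special.gammaln(r) - special.gammaln(js + 1)
            + r * np.log(r / (r + mu)) + js * np.log(mu / (r + mu))
            - np.log1p(-np.exp(logp0))
        )
        return -float(ll.sum())

    best = None
    with np.errstate(all="ignore"):
        for lr0 in (-3.0, -1.0, 0.5):
            try:
                res = optimize.minimize(
                    nll, [lr0, np.log(m.mean())], method="Nelder-Mead",
                    options={"maxiter": 2000, "xatol": 1e-8, "fatol": 1e-10},
                )
            except (ValueError, FloatingPointError):
                continue
            if np.isfinite(res.fun) and (best is None or res.fun < best.fun):
                best = res
    if best is None:
        return _chao_extrapolate(d, n, f1, f2, fold), False
    r, mu = np.exp(best.x)
    p0 = (r / (r + mu)) ** r
    if not (0 <= p0 < 1):
        return _chao_extrapolate(d, n, f1, f2, fold), False
    s_universe = d / (1 - p0)
    est = s_universe * (1 - (r / (r + fold * mu)) ** r)
    return float(max(est, d)), False


def qc_report(
    counts: SiteCounts,
    pairs: list[ProcessedPair],
    extrapolation_fold: float = 10.0,
    min_total: int = 1000,
    min_cis_trans_ratio: float = 1.0,
    min_percent_observed: float = 20.0,
) -> QCReport:
    """Library QC: totals, cis:trans ratio, and complexity.

    Distinct cis interactions are the unique (site, strand, breakpoint)
    tuples among cis pairs after artifact filtering but before duplicate
    removal; their multiplicity histogram feeds the extrapolation to
    ``extrapolation_fold`` x depth, and percent_observed = 100 x observed /
    estimated total.  Threshold defaults are configurable package choices.
    """
    mult: dict[tuple, int] = {}
    for p in pairs:
        if p.bait_name != counts.bait_name or p.self_ligation or p.undigested:
            continue
        if p.chrom != counts.bait_chrom:
            continue
        key = p.dedup_key()
        mult[key] = mult.get(key, 0) + 1
    mvec = np.asarray(list(mult.values()), dtype=np.int64)
    est, saturated = extrapolate_distinct(mvec, fold=extrapolation_fold)
    observed = len(mult)
    percent = 100.0 * observed / est if est > 0 else 0.0
    ratio = counts.cis / counts.trans if counts.trans else float("inf")
    passed = (
        counts.total >= min_total
        and ratio >= min_cis_trans_ratio
        and percent >= min_percent_observed
    )
    return QCReport(
        bait_name=counts.bait_name,
        total_reads=counts.total,
        cis_reads=counts.cis,
        trans_reads=counts.trans,
        cis_trans_ratio=ratio,
        observed_distinct_cis=observed,
        estimated_total_distinct_cis=est,
        percent_observed=percent,
        saturated=saturated,
        passed=passed,
    )


def process_library(
    read_pairs,
    baits: list[BaitSpec],
    genome: SyntheticGenome,
) -> tuple[dict[str, SiteCounts], dict[str, QCReport], DropTally]:
    """Full chain: demultiplex, map, filter, deduplicate, count, QC."""
    tally = DropTally()
    split, tally = split_and_demultiplex(read_pairs, baits, tally)
    pairs, tally = map_and_filter(split, genome, baits, tally)
    pairs = deduplicate(pairs, tally)
    counts: dict[str, SiteCounts] = {}
    reports: dict[str, QCReport] = {}
    for bait in baits:
        sc = count_per_site(pairs, genome.restriction_map, bait, tally=tally)
        counts[bait.name] = sc
        reports[bait.name] = qc_report(sc, [p for p in pairs if p.bait_name == bait.name])
    return counts, reports, tally
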