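"""Synthetic data generators for every input of the ms4C pipeline.

A 4C library is, statistically, a sample of ligation partners of one bait
restriction fragment: cis partners occur with a probability that decays as a
power law of genomic distance, trans partners form a thin uniform background,
and a fixed fraction of molecules is re-sequenced as PCR duplicates sharing
the same sonication breakpoint.  The generators in this module produce

* a genome carrying HindIII (``AAGCTT``) sites at known coordinates,
* paired reads (R1 spans the bait/target ligation junction, R2 the
  sonication end) drawn from an explicit contact model with optional
  planted high-frequency interactions,
* DamID-style log2(Dam-LMNB1/Dam) probe tracks built from known
  lamina-associated intervals plus Gaussian noise, and
* gene annotations whose promoter windows sit inside chromatin-state
  segments matching a known transcriptional class.

Every generator is a pure function of its seed and writes the ground truth
alongside the data, so downstream modules can be tested against what was
actually planted rather than against a re-derivation of the simulation.

All coordinates are 0-based, half-open.  Restriction-site positions are the
left end of the AAGCTT motif.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

HINDIII = "AAGCTT"
MOTIF_LEN = len(HINDIII)

#: transcriptional class -> chromatin-state label planted at the promoter
CLASS_TO_STATE = {
    "bivalent": "Poised_Promoter",
    "active": "Active_Promoter",
    "repressive": "Repressed",
    "other": "Txn_Elongation",
}

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class SyntheticGenome:
    """A genome with a known HindIII restriction map.

    chromosomes: list of (name, length in bp).
    sequence: optional per-chromosome base string; when present, AAGCTT
        occurs exactly at the mapped positions and nowhere else.
    restriction_map: per-chromosome sorted array of motif left ends.
    """

    chromosomes: list[tuple[str, int]]
    restriction_map: dict[str, np.ndarray]
    sequence: dict[str, str] | None = None

    @property
    def lengths(self) -> dict[str, int]:
        return dict(self.chromosomes)

    def n_sites(self, chrom: str) -> int:
        return len(self.restriction_map[chrom])

    def fragment_bounds(self, chrom: str, frag_index: int) -> tuple[int, int]:
        """Bounds of fragment ``frag_index`` = [site_i, site_{i+1})."""
        sites = self.restriction_map[chrom]
        if not 0 <= frag_index < len(sites) - 1:
            raise IndexError(f"fragment {frag_index} out of range on {chrom}")
        return int(sites[frag_index]), int(sites[frag_index + 1])

    def validate(self) -> None:
        for name, length in self.chromosomes:
            if length <= 0:
                raise ValueError(f"non-positive length for {name}")
            sites = self.restriction_map[name]
            if np.any(np.diff(sites) <= 0):
                raise ValueError(f"restriction positions not strictly increasing on {name}")
            if self.sequence is not None:
                seq = self.sequence[name]
                found = _scan_motif(seq)
                if not np.array_equal(found, sites):
                    raise ValueError(f"sequence motif positions disagree with map on {name}")


@dataclass
class ContactModel:
    """Parameters of the ligation-partner sampling distribution.

    decay_exponent: power-law slope of cis contact probability vs distance
        (site-to-site, in bp).
    background_trans_fraction: probability a partner lies on another
        chromosome.
    planted_interactions: list of ((chrom, site_index), fold) enrichments
        multiplied onto the distance-decay weight of the target site.
    duplication_rate: per-molecule probability of being emitted twice with
        an identical sonication breakpoint.
    read_count: number of original (pre-duplication) pairs per bait.
    """

    decay_exponent: float = 1.0
    background_trans_fraction: float = 0.0
    planted_interactions: list[tuple[tuple[str, int], float]] = field(default_factory=list)
    duplication_rate: float = 0.0
    read_count: int = 10_000
    seed: int = 0

    def validate(self, genome: SyntheticGenome) -> None:
        if not 0.0 <= self.background_trans_fraction < 1.0:
            raise ValueError("background_trans_fraction must be in [0, 1)")
        if not 0.0 <= self.duplication_rate < 1.0:
            raise ValueError("duplication_rate must be in [0, 1)")
        if self.read_count < 0:
            raise ValueError("read_count must be non-negative")
        for (chrom, idx), fold in self.planted_interactions:
            if fold < 1.0:
                raise ValueError("fold_enrichment must be >= 1")
            if chrom not in genome.restriction_map or not (
                0 <= idx < genome.n_sites(chrom)
            ):
                raise ValueError(f"planted site ({chrom}, {idx}) absent from restriction map")


@dataclass
class SimulatedPair:
    """One read pair spanning a ligation junction.

    r1 = bait-side prefix + AAGCTT + target-side suffix; r2 reads back from
    the sonication breakpoint on the reverse strand.
    """

    pair_id: int
    bait_name: str
    r1: str
    r2: str
    truth_target: tuple[str, int]  # (chrom, site index)
    truth_breakpoint: int
    truth_duplicate_of: int | None = None


@dataclass
class SyntheticDamID:
    """Microarray-style lamina profile with known LAD intervals."""

    probes: dict[str, np.ndarray]       # per-chromosome sorted positions
    values: dict[str, np.ndarray]       # log2(Dam-LMNB1/Dam) per probe
    truth_lads: dict[str, list[tuple[int, int]]]
    noise_sd: float


def _scan_motif(seq: str) -> np.ndarray:
    """All occurrences of AAGCTT in ``seq`` (left ends, sorted)."""
    out = []
    i = seq.find(HINDIII)
    while i != -1:
        out.append(i)
        i = seq.find(HINDIII, i + 1)
    return np.asarray(out, dtype=np.int64)


def digest_genome(
    chrom_lengths: dict[str, int] | list[tuple[str, int]],
    mean_fragment: int,
    seed: int,
    with_sequence: bool = False,
    min_gap: int = 30,
) -> SyntheticGenome:
    """Draw an in-silico HindIII digest.

    Inter-site gaps are ``min_gap`` plus an exponential with mean
    ``mean_fragment - min_gap``, so gaps average the requested fragment
    size while motifs never overlap.  With ``with_sequence`` a random
    base string is emitted in which AAGCTT occurs exactly at the mapped
    positions.
    """
    chroms = list(chrom_lengths.items()) if isinstance(chrom_lengths, dict) else list(chrom_lengths)
    if mean_fragment <= min_gap:
        raise ValueError(f"mean fragment size must exceed {min_gap} bp")
    for name, length in chroms:
        if length <= 0:
            raise ValueError(f"non-positive length for chromosome {name}")
        if length < 10 * mean_fragment:
            raise ValueError(
                f"chromosome {name} ({length} bp) shorter than 10x mean fragment size"
            )
    rng = np.random.default_rng(seed)
    rmap: dict[str, np.ndarray] = {}
    seqs: dict[str, str] | None = {} if with_sequence else None
    for name, length in chroms:
        n_max = int(2 * length / mean_fragment) + 10
        gaps = min_gap + rng.exponential(mean_fragment - min_gap, size=n_max)
        pos = np.cumsum(gaps).astype(np.int64)
        pos = pos[pos + MOTIF_LEN <= length - min_gap]
        rmap[name] = pos
        if with_sequence:
            seqs[name] = _emit_sequence(length, pos, rng)
    genome = SyntheticGenome(chromosomes=chroms, restriction_map=rmap, sequence=seqs)
    genome.validate()
    return genome


def _emit_sequence(length: int, sites: np.ndarray, rng: np.random.Generator) -> str:
    bases = rng.choice(list("ACGT"), size=length)
    seq = bases
    for s in sites:
        seq[s : s + MOTIF_LEN] = list(HINDIII)
    text = "".join(seq)
    planted = set()
    for s in sites:
        planted.update(range(s, s + MOTIF_LEN))
    site_set = set(int(s) for s in sites)
    # break accidental motifs; AAGCTT is not self-overlapping, so every
    # spurious occurrence has at least one base outside planted windows
    for _ in range(20):
        spurious = [p for p in _scan_motif(text) if int(p) not in site_set]
        if not spurious:
            return text
        chars = list(text)
        for p in spurious:
            for j in range(int(p), int(p) + MOTIF_LEN):
                if j not in planted:
                    chars[j] = "C" if chars[j] != "C" else "G"
                    break
        text = "".join(chars)
    raise RuntimeError("could not scrub accidental AAGCTT motifs")


@dataclass
class SimulatedBait:
    """A bait viewpoint: fragment [site_i, site_{i+1}) read toward its
    right-end junction at site_{i+1}."""

    name: str
    chrom: str
    frag_index: int
    junction: int          # coordinate of site_{i+1}
    bait_side_sequence: str  # prefix through the motif

    @property
    def bait_fragment(self) -> tuple[str, int, int]:
        return (self.chrom, self.start, self.junction)

    start: int = 0


def make_bait(
    genome: SyntheticGenome, name: str, chrom: str, frag_index: int, prefix_len: int = 24
) -> SimulatedBait:
    """Define a bait on fragment ``frag_index``.  On a sequence-bearing
    genome the bait-side primer sequence is read off the fragment's right
    end; on a map-only genome (read-free simulations) it is empty."""
    start, junction = genome.fragment_bounds(chrom, frag_index)
    if junction - start <= prefix_len:
        raise ValueError("bait fragment shorter than requested prefix")
    if genome.sequence is None:
        bss = ""
    else:
        bss = genome.sequence[chrom][junction - prefix_len : junction + MOTIF_LEN]
    return SimulatedBait(
        name=name, chrom=chrom, frag_index=frag_index, junction=junction,
        bait_side_sequence=bss, start=start,
    )


def cis_target_weights(
    genome: SyntheticGenome, bait: SimulatedBait, model: ContactModel,
    edge_margin: int = 700,
) -> np.ndarray:
    """Unnormalized sampling weight of every site on the bait chromosome.

    Weight is distance^(-decay_exponent) from the bait junction, times any
    planted fold enrichment.  The junction site itself and sites too close
    to the chromosome end to yield a full read/breakpoint get weight 0.
    """
    sites = genome.restriction_map[bait.chrom]
    length = genome.lengths[bait.chrom]
    d = np.abs(sites - bait.junction).astype(float)
    with np.errstate(divide="ignore"):
        w = np.where(d > 0, d ** -model.decay_exponent, 0.0)
    w[sites + edge_margin > length] = 0.0
    for (chrom, idx), fold in model.planted_interactions:
        if chrom == bait.chrom:
            w[idx] *= fold
    return w


def simulate_pairs(
    genome: SyntheticGenome,
    bait: SimulatedBait,
    model: ContactModel,
    suffix_len: int = 44,
    r2_len: int = 50,
) -> tuple[list[SimulatedPair], pd.DataFrame]:
    """Sample ligation pairs for one bait.

    Returns the read pairs plus a truth sidecar table with one row per
    emitted pair (bait, target chrom/site, breakpoint, duplicate_of).
    """
    model.validate(genome)
    if genome.sequence is None:
        raise ValueError("simulate_pairs requires a sequence-bearing genome")
    rng = np.random.default_rng(model.seed)
    n = model.read_count

    w_cis = cis_target_weights(genome, bait, model)
    if w_cis.sum() <= 0:
        raise ValueError("no eligible cis target sites")
    p_cis = w_cis / w_cis.sum()

    trans_universe: list[tuple[str, int]] = []
    trans_w: list[float] = []
    for chrom, length in genome.chromosomes:
        if chrom == bait.chrom:
            continue
        for idx, s in enumerate(genome.restriction_map[chrom]):
            if s + 700 <= length:
                weight = 1.0
                for (pc, pi), fold in model.planted_interactions:
                    if pc == chrom and pi == idx:
                        weight = fold
                trans_universe.append((chrom, idx))
                trans_w.append(weight)
    if model.background_trans_fraction > 0 and not trans_universe:
        raise ValueError("trans fraction requested but genome has a single chromosome")

    is_trans = rng.random(n) < model.background_trans_fraction
    n_trans = int(is_trans.sum())
    cis_draws = rng.choice(len(p_cis), size=n - n_trans, p=p_cis)
    if n_trans:
        tw = np.asarray(trans_w, float)
        trans_draws = rng.choice(len(trans_universe), size=n_trans, p=tw / tw.sum())
    targets: list[tuple[str, int]] = []
    ci = ti = 0
    for flag in is_trans:
        if flag:
            targets.append(trans_universe[trans_draws[ti]]); ti += 1
        else:
            targets.append((bait.chrom, int(cis_draws[ci]))); ci += 1

    offsets = rng.integers(150, 601, size=n)
    pairs: list[SimulatedPair] = []
    rows = []
    for pid in range(n):
        chrom, idx = targets[pid]
        s = int(genome.restriction_map[chrom][idx])
        seq = genome.sequence[chrom]
        suffix = seq[s + MOTIF_LEN : s + MOTIF_LEN + suffix_len]
        r1 = bait.bait_side_sequence + suffix
        bp = min(s + int(offsets[pid]), genome.lengths[chrom])
        r2 = revcomp(seq[max(bp - r2_len, 0) : bp])
        pairs.append(SimulatedPair(pid, bait.name, r1, r2, (chrom, idx), bp))
        rows.append((pid, bait.name, chrom, idx, s, bp, -1))

    dup_mask = rng.random(n) < model.duplication_rate
    next_id = n
    for pid in np.nonzero(dup_mask)[0]:
        orig = pairs[int(pid)]
        dup = dataclasses.replace(orig, pair_id=next_id, truth_duplicate_of=int(pid))
        pairs.append(dup)
        chrom, idx = orig.truth_target
        rows.append((next_id, bait.name, chrom, idx,
                     int(genome.restriction_map[chrom][idx]), orig.truth_breakpoint, int(pid)))
        next_id += 1

    truth = pd.DataFrame(
        rows,
        columns=["pair_id", "bait", "chrom", "site_index", "site_pos", "breakpoint",
                 "duplicate_of"],
    )
    return pairs, truth


def simulate_site_counts(
    genome: SyntheticGenome,
    bait: SimulatedBait,
    model: ContactModel,
    count_window: int = 1000,
):
    """Read-free shortcut: sample target sites from the contact model and
    bin them straight into a per-site count track.

    Emulates the post-filter, post-dedup library (the bait's own fragment
    and both neighbours carry weight 0, duplication is ignored), which is
    what the contact statistics consume.  Orders of magnitude faster than
    generating and re-mapping read sequences; used for calibration and
    power studies over many seeds.
    """
    from .readproc import SiteCounts  # local import to avoid a cycle

    model.validate(genome)
    rng = np.random.default_rng(model.seed)
    n = model.read_count
    w_cis = cis_target_weights(genome, bait, model, edge_margin=0)
    for di in (-1, 0, 1):
        j = bait.frag_index + di
        if 0 <= j < genome.n_sites(bait.chrom):
            w_cis[j] = 0.0
    if w_cis.sum() <= 0:
        raise ValueError("no eligible cis target sites")
    p_cis = w_cis / w_cis.sum()

    counts = {c: np.zeros(len(s), dtype=np.int64) for c, s in genome.restriction_map.items()}
    raw = {c: np.zeros(len(s), dtype=np.int64) for c, s in genome.restriction_map.items()}
    sc = SiteCounts(
        bait_name=bait.name, bait_chrom=bait.chrom, bait_pos=bait.junction,
        restriction_map=genome.restriction_map, counts=counts, raw=raw,
    )
    n_trans = rng.binomial(n, model.background_trans_fraction) if \
        model.background_trans_fraction > 0 else 0
    n_cis = n - n_trans

    def bin_targets(chrom: str, draws: np.ndarray) -> None:
        sites = genome.restriction_map[chrom]
        target_pos = sites[draws]
        lo = np.searchsorted(sites, target_pos - count_window, side="left")
        hi = np.searchsorted(sites, target_pos + count_window, side="right")
        diff = np.zeros(len(sites) + 1, dtype=np.int64)
        np.add.at(diff, lo, 1)
        np.add.at(diff, hi, -1)
        counts[chrom] += np.cumsum(diff[:-1])
        raw[chrom] += np.bincount(draws, minlength=len(sites)).astype(np.int64)

    if n_cis:
        bin_targets(bait.chrom, rng.choice(len(p_cis), size=n_cis, p=p_cis))
        sc.cis = n_cis
    if n_trans:
        universe = [c for c, _ in genome.chromosomes if c != bait.chrom
                    and genome.n_sites(c) > 0]
        if not universe:
            raise ValueError("trans fraction requested but genome has a single chromosome")
        sizes = np.array([genome.n_sites(c) for c in universe], dtype=float)
        chrom_draws = rng.choice(len(universe), size=n_trans, p=sizes / sizes.sum())
        for ci, chrom in enumerate(universe):
            k = int((chrom_draws == ci).sum())
            if k:
                bin_targets(chrom, rng.integers(0, genome.n_sites(chrom), size=k))
        sc.trans = n_trans
    sc.total = n
    return sc


def simulate_damid(
    genome: SyntheticGenome,
    lad_intervals: dict[str, list[tuple[int, int]]],
    probe_spacing: int,
    noise_sd: float,
    seed: int,
    level: float = 1.0,
) -> SyntheticDamID:
    """Step-function lamina signal: +level inside the truth LADs, -level
    outside, plus N(0, noise_sd) per probe.  floor(L / spacing) probes per
    chromosome, centred on a regular grid."""
    if probe_spacing <= 0:
        raise ValueError("probe_spacing must be positive")
    if noise_sd < 0:
        raise ValueError("noise_sd must be non-negative")
    rng = np.random.default_rng(seed)
    probes: dict[str, np.ndarray] = {}
    values: dict[str, np.ndarray] = {}
    truth: dict[str, list[tuple[int, int]]] = {}
    for chrom, length in genome.chromosomes:
        ivs = sorted(lad_intervals.get(chrom, []))
        for (a, b), (c, d) in zip(ivs, ivs[1:]):
            if c < b:
                raise ValueError(f"overlapping LAD intervals on {chrom}")
        for a, b in ivs:
            if not (0 <= a < b <= length):
                raise ValueError(f"LAD interval ({a}, {b}) outside {chrom}")
        n = length // probe_spacing
        pos = np.arange(n, dtype=np.int64) * probe_spacing + probe_spacing // 2
        inside = np.zeros(n, dtype=bool)
        for a, b in ivs:
            inside |= (pos >= a) & (pos < b)
        vals = np.where(inside, level, -level) + rng.normal(0.0, noise_sd, size=n)
        probes[chrom] = pos
        values[chrom] = vals
        truth[chrom] = ivs
    return SyntheticDamID(probes=probes, values=values, truth_lads=truth, noise_sd=noise_sd)


def simulate_annotation(
    genome: SyntheticGenome,
    n_per_class: dict[str, int],
    seed: int,
    promoter_halfwidth: int = 300,
    body_length: int = 1000,
    min_separation: int = 2500,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Place genes with known transcriptional classes.

    Returns (genes, segmentation).  Each gene's TSS +/- 250 bp window lies
    wholly inside one chromatin-state segment whose label matches the
    gene's truth class (bivalent -> Poised_Promoter, active ->
    Active_Promoter, repressive -> Repressed, other -> Txn_Elongation).
    Genes carries columns gene, chrom, strand, tss, start, end,
    truth_class; segmentation carries chrom, start, end, state.
    """
    for cls in n_per_class:
        if cls not in CLASS_TO_STATE:
            raise ValueError(f"unknown gene class {cls!r}")
        if n_per_class[cls] < 0:
            raise ValueError("gene counts must be non-negative")
    rng = np.random.default_rng(seed)
    total = sum(n_per_class.values())
    gene_rows, seg_rows = [], []
    if total:
        slots: list[tuple[str, int]] = []
        margin = promoter_halfwidth + body_length + 10
        for chrom, length in genome.chromosomes:
            k = max((length - 2 * margin) // min_separation, 0)
            slots.extend((chrom, margin + i * min_separation) for i in range(k))
        if len(slots) < total:
            raise ValueError(f"cannot place {total} genes on this genome")
        chosen = rng.choice(len(slots), size=total, replace=False)
        strands = rng.choice(["+", "-"], size=total)
        i = 0
        gid = 0
        for cls in ("bivalent", "active", "repressive", "other"):
            for _ in range(n_per_class.get(cls, 0)):
                chrom, tss = slots[int(chosen[i])]
                strand = strands[i]
                start, end = (tss, tss + body_length) if strand == "+" else (tss - body_length, tss)
                gene_rows.append((f"G{gid:04d}", chrom, strand, tss, start, end, cls))
                seg_rows.append((chrom, tss - promoter_halfwidth, tss + promoter_halfwidth,
                                 CLASS_TO_STATE[cls]))
                i += 1
                gid += 1
    genes = pd.DataFrame(
        gene_rows, columns=["gene", "chrom", "strand", "tss", "start", "end", "truth_class"]
    ).sort_values(["chrom", "tss"], ignore_index=True)
    seg = pd.DataFrame(seg_rows, columns=["chrom", "start", "end", "state"]).sort_values(
        ["chrom", "start"], ignore_index=True
    )
    return genes, seg
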