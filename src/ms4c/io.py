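"""Readers and writers for the track and table formats the pipeline speaks.

Per-site count tracks travel as variableStep WIG (1-based positions, one
track per bait, zero-count sites written explicitly so the restriction-site
grid survives the round trip).  DamID probe tracks travel as bedGraph, LADs
and segmentations as BED, reads as paired FASTQ, and genes/baits/pairs as
TSV.  All writers accept ``.gz`` paths.  Internally everything is 0-based
half-open; the 1-based WIG convention is converted at this boundary only.
"""

from __future__ import annotations

import gzip
import json
from typing import Iterator

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .readproc import BaitSpec, SiteCounts
from .simulate import SimulatedPair, SyntheticGenome


def _open(path, mode: str = "rt"):
    path = str(path)
    if path.endswith(".gz"):
        return gzip.open(path, mode)
    return open(path, mode)


# ---------------------------------------------------------------- WIG tracks

def write_wig(counts: SiteCounts, path) -> None:
    """variableStep WIG, 1-based, with bait metadata in header comments.

    The wiggle values are the +/-1000 bp window counts; when the track
    also carries junction-assigned raw read counts they are appended as
    ``#rawStep`` sections (comments to standard WIG parsers) so the full
    in-memory object survives the round trip."""
    with _open(path, "wt") as fh:
        fh.write(f'track type=wiggle_0 name="{counts.bait_name}"\n')
        fh.write(f"#bait_chrom={counts.bait_chrom}\n")
        fh.write(f"#bait_pos={counts.bait_pos}\n")
        fh.write(f"#total={counts.total} cis={counts.cis} trans={counts.trans}\n")
        for chrom in counts.restriction_map:
            fh.write(f"variableStep chrom={chrom}\n")
            sites = counts.restriction_map[chrom]
            vals = counts.counts[chrom]
            for s, v in zip(sites, vals):
                fh.write(f"{s + 1}\t{v}\n")
        if counts.raw is not None:
            for chrom in counts.restriction_map:
                fh.write(f"#rawStep chrom={chrom}\n")
                for s, v in zip(counts.restriction_map[chrom], counts.raw[chrom]):
                    fh.write(f"#{s + 1}\t{v}\n")


def read_wig(path) -> SiteCounts:
    name = ""
    bait_chrom, bait_pos = "", 0
    total = cis = trans = 0
    rmap: dict[str, list[int]] = {}
    cvals: dict[str, list[int]] = {}
    rvals: dict[str, list[int]] = {}
    chrom = None
    mode = "wig"
    with _open(path, "rt") as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line.startswith("track"):
                name = line.split('name="')[1].rstrip('"')
            elif line.startswith("#bait_chrom="):
                bait_chrom = line.split("=", 1)[1]
            elif line.startswith("#bait_pos="):
                bait_pos = int(line.split("=", 1)[1])
            elif line.startswith("#total="):
                parts = dict(p.split("=") for p in line[1:].split())
                total, cis, trans = int(parts["total"]), int(parts["cis"]), int(parts["trans"])
            elif line.startswith("variableStep"):
                chrom = line.split("chrom=")[1].split()[0]
                mode = "wig"
                rmap[chrom] = []
                cvals[chrom] = []
            elif line.startswith("#rawStep"):
                chrom = line.split("chrom=")[1].split()[0]
                mode = "raw"
                rvals[chrom] = []
            elif line.startswith("#") and mode == "raw":
                _p, v = line[1:].split("\t")
                rvals[chrom].append(int(v))
            elif line:
                p, v = line.split("\t")
                rmap[chrom].append(int(p) - 1)
                cvals[chrom].append(int(v))
    return SiteCounts(
        bait_name=name, bait_chrom=bait_chrom, bait_pos=bait_pos,
        restriction_map={c: np.asarray(v, dtype=np.int64) for c, v in rmap.items()},
        counts={c: np.asarray(v, dtype=np.int64) for c, v in cvals.items()},
        raw={c: np.asarray(v, dtype=np.int64) for c, v in rvals.items()} if rvals else None,
        total=total, cis=cis, trans=trans,
    )


# -------------------------------------------------------------- BED/bedGraph

def write_bed(intervals: pd.DataFrame, path) -> None:
    """BED with whatever columns are present beyond chrom/start/end."""
    cols = ["chrom", "start", "end"] + [
        c for c in intervals.columns if c not in ("chrom", "start", "end")
    ]
    intervals[cols].to_csv(path, sep="\t", header=False, index=False)


def read_bed(path, names: list[str]) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", header=None, names=names)


def write_bedgraph(
    probes: dict[str, np.ndarray], values: dict[str, np.ndarray], path,
    probe_span: int = 1,
) -> None:
    """bedGraph of point probes; float values written with repr so they
    re-parse bit-identically."""
    with _open(path, "wt") as fh:
        for chrom in probes:
            for p, v in zip(probes[chrom], values[chrom]):
                fh.write(f"{chrom}\t{p}\t{p + probe_span}\t{float(v)!r}\n")


def read_bedgraph(path) -> tuple[dict[str, np.ndarray], dict[str, np.ndarray]]:
    probes: dict[str, list[int]] = {}
    values: dict[str, list[float]] = {}
    with _open(path, "rt") as fh:
        for line in fh:
            chrom, start, _end, val = line.rstrip("\n").split("\t")
            probes.setdefault(chrom, []).append(int(start))
            values.setdefault(chrom, []).append(float(val))
    return (
        {c: np.asarray(v, dtype=np.int64) for c, v in probes.items()},
        {c: np.asarray(v, dtype=float) for c, v in values.items()},
    )


def write_coverage_bedgraph(track, path, span: int = 1) -> None:
    from .repro import CoverageTrack  # noqa: F401  (documentation import)

    with _open(path, "wt") as fh:
        for p, v in zip(track.site_positions, track.coverage):
            fh.write(f"{track.chrom}\t{p}\t{p + span}\t{float(v)!r}\n")


# ------------------------------------------------------------- FASTA/FASTQ

def write_genome_fasta(genome: SyntheticGenome, path) -> None:
    if genome.sequence is None:
        raise ValueError("genome carries no sequence")
    records = [
        SeqRecord(Seq(genome.sequence[name]), id=name, description="")
        for name, _ in genome.chromosomes
    ]
    with _open(path, "wt") as fh:
        SeqIO.write(records, fh, "fasta")


def write_fastq_pairs(pairs: list[SimulatedPair], r1_path, r2_path) -> None:
    def rec(seq: str, pid: int, mate: int) -> SeqRecord:
        r = SeqRecord(Seq(seq), id=f"pair{pid}/{mate}", description="")
        r.letter_annotations["phred_quality"] = [40] * len(seq)
        return r

    with _open(r1_path, "wt") as f1, _open(r2_path, "wt") as f2:
        for p in pairs:
            SeqIO.write([rec(p.r1, p.pair_id, 1)], f1, "fastq")
            SeqIO.write([rec(p.r2, p.pair_id, 2)], f2, "fastq")


def read_fastq_pairs(r1_path, r2_path) -> Iterator[tuple[str, str]]:
    with _open(r1_path, "rt") as f1, _open(r2_path, "rt") as f2:
        for rec1, rec2 in zip(SeqIO.parse(f1, "fastq"), SeqIO.parse(f2, "fastq")):
            yield str(rec1.seq), str(rec2.seq)


# ------------------------------------------------------------------- tables

def write_bait_table(baits: list[BaitSpec], path) -> None:
    rows = []
    for b in baits:
        variants = ";".join(f"{o}:{base}" for o, base in b.discriminating_variants)
        rows.append((b.name, b.bait_side_sequence, *b.bait_fragment, variants, b.group))
    pd.DataFrame(
        rows, columns=["name", "bait_side_sequence", "chrom", "start", "end",
                       "variants", "group"],
    ).to_csv(path, sep="\t", index=False)


def read_bait_table(path) -> list[BaitSpec]:
    df = pd.read_csv(path, sep="\t", keep_default_na=False)
    baits = []
    for row in df.itertuples(index=False):
        variants = [
            (int(v.split(":")[0]), v.split(":")[1])
            for v in str(row.variants).split(";") if v
        ]
        baits.append(BaitSpec(
            name=row.name, bait_side_sequence=row.bait_side_sequence,
            bait_fragment=(row.chrom, int(row.start), int(row.end)),
            discriminating_variants=variants, group=row.group,
        ))
    return baits


def write_json(obj: dict, path) -> None:
    with _open(path, "wt") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True)
        fh.write("\n")
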