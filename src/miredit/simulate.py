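"""Synthetic stem-loops, genomes and small-RNA libraries with planted edits.

Structures are constructed, not folded: the duplex/bulge/loop geometry is
specified directly, so every downstream classification has an exact truth.
Simulated libraries draw reads from the annotated mature arms with
geometric end jitter (read starts pile up at the annotated 5' end, the way
real isomiR distributions concentrate at the dominant cleavage site), plant
substitutions at configured per-read rates, add uniform sequencing errors,
and append a 3' adaptor. A truth table records every planted event so
recovery can be scored exactly. All generators are seed-deterministic.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .mapping import revcomp
from .readio import Library, RawRead
from .structure import Interval, StemLoop

_BASES = "ACGT"
_OTHER = {b: [c for c in _BASES if c != b] for b in _BASES}


@dataclass(frozen=True)
class PlantedEvent:
    """One planted substitution: carried by each overlapping read with
    probability ``rate``."""

    mirna: str
    position: int  # 1-based on the stem-loop
    ref: str
    alt: str
    rate: float

    def __post_init__(self):
        if not 0 < self.rate <= 1:
            raise ValueError("planted rate must be in (0, 1]")
        if self.alt == self.ref:
            raise ValueError(f"planted alt must differ from ref ({self.ref})")


@dataclass
class TruthTable:
    """Ground truth for one simulated library."""

    events: list[PlantedEvent] = field(default_factory=list)
    library: str = ""
    depth: int = 0
    error_rate: float = 0.0
    seed: int = 0

    def to_json(self) -> str:
        return json.dumps(
            {
                "library": self.library,
                "depth": self.depth,
                "error_rate": self.error_rate,
                "seed": self.seed,
                "events": [asdict(e) for e in self.events],
            },
            indent=2,
        )


def _rand_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(rng.choice(list(_BASES), size=n))


def make_stemloop(
    stem_len: int,
    loop_len: int,
    bulges: Sequence[tuple[str, int, int]] = (),
    seed: int = 0,
    id: str = "synth-mir-1",
    flank_len: int = 0,
) -> StemLoop:
    """Construct a hairpin with the requested geometry.

    ``stem_len`` counts base pairs; ``loop_len`` the terminal-loop
    nucleotides; each bulge is (arm, offset, length) with arm in
    {"5p", "3p"} and offset in [1, stem_len-1] — the bulge is inserted
    after the ``offset``-th base pair of that arm (counting from the
    hairpin's outside). Paired positions are exactly complementary.
    The 5' and 3' arms (excluding flanks) are annotated as the 5P and 3P
    mature intervals.
    """
    if stem_len < 2 or loop_len < 3:
        raise ValueError("need stem_len >= 2 and loop_len >= 3")
    seen: set[tuple[str, int]] = set()
    for arm, offset, length in bulges:
        if arm not in ("5p", "3p"):
            raise ValueError(f"bulge arm must be '5p' or '3p', got {arm!r}")
        if not 1 <= offset <= stem_len - 1:
            raise ValueError(f"bulge offset {offset} outside 1..{stem_len - 1}")
        if length < 1:
            raise ValueError("bulge length must be >= 1")
        if (arm, offset) in seen:
            raise ValueError(f"overlapping bulges at {arm} offset {offset}")
        seen.add((arm, offset))

    rng = np.random.default_rng(seed)
    pair_bases = _rand_seq(rng, stem_len)
    bulges_5p = {o: l for a, o, l in bulges if a == "5p"}
    bulges_3p = {o: l for a, o, l in bulges if a == "3p"}

    seq5, db5 = [], []
    for i, b in enumerate(pair_bases, start=1):
        seq5.append(b)
        db5.append("(")
        if i in bulges_5p:
            seq5.append(_rand_seq(rng, bulges_5p[i]))
            db5.append("." * bulges_5p[i])
    loop = _rand_seq(rng, loop_len)
    # 3' arm mirrors the pairs in reverse; bulge after pair i (from outside)
    # sits between partners of pairs i+1 and i, i.e. before partner of pair i
    seq3, db3 = [], []
    for i in range(stem_len, 0, -1):
        if i in bulges_3p:
            seq3.append(_rand_seq(rng, bulges_3p[i]))
            db3.append("." * bulges_3p[i])
        seq3.append(revcomp(pair_bases[i - 1]))
        db3.append(")")
    flank5 = _rand_seq(rng, flank_len)
    flank3 = _rand_seq(rng, flank_len)
    sequence = flank5 + "".join(seq5) + loop + "".join(seq3) + flank3
    dotbracket = "." * flank_len + "".join(db5) + "." * loop_len + "".join(db3) + "." * flank_len

    len5 = len("".join(seq5))
    len3 = len("".join(seq3))
    arm5_start = flank_len + 1
    arm5_end = flank_len + len5
    arm3_start = flank_len + len5 + loop_len + 1
    arm3_end = arm3_start + len3 - 1
    mature = (
        Interval("5P", arm5_start, arm5_end),
        Interval("3P", arm3_start, arm3_end),
    )
    return StemLoop(
        id=id, sequence=sequence, dotbracket=dotbracket, mature_intervals=mature
    )


def simulate_library(
    stemloop: StemLoop,
    depth: int,
    planted_events: Sequence[PlantedEvent] = (),
    error_rate: float = 0.0,
    adaptor: str = "",
    seed: int = 0,
    name: str = "simlib",
    mature_intervals: Sequence[Interval] | None = None,
    jitter_p: float = 0.7,
    min_read_len: int = 16,
) -> tuple[Library, TruthTable]:
    """Simulate one small-RNA library over a stem-loop.

    Each read picks a mature interval uniformly, jitters both ends with a
    geometric(jitter_p) offset inward (5' starts concentrate at the
    annotated start), carries each overlapping planted substitution
    independently with its rate, accrues uniform sequencing errors at
    ``error_rate`` per base, and gets the adaptor appended. depth == 0
    yields an empty library and empty truth.
    """
    if not 0 <= error_rate < 0.05:
        raise ValueError("error_rate must be in [0, 0.05)")
    intervals = list(mature_intervals or stemloop.mature_intervals)
    if depth > 0 and not intervals:
        raise ValueError(f"{stemloop.id}: no mature intervals to draw reads from")
    for ev in planted_events:
        if not 1 <= ev.position <= len(stemloop):
            raise ValueError(f"planted event at {ev.position} outside {stemloop.id}")
        if stemloop.sequence[ev.position - 1] != ev.ref:
            raise ValueError(
                f"planted ref {ev.ref} != reference base "
                f"{stemloop.sequence[ev.position - 1]} at {stemloop.id}:{ev.position}"
            )
    rng = np.random.default_rng(seed)
    reads: list[RawRead] = []
    for i in range(depth):
        iv = intervals[rng.integers(len(intervals))]
        start = min(iv.start + int(rng.geometric(jitter_p)) - 1, iv.end - min_read_len + 1)
        end = max(iv.end - (int(rng.geometric(jitter_p)) - 1), start + min_read_len - 1)
        start = max(start, 1)
        end = min(end, len(stemloop))
        bases = list(stemloop.sequence[start - 1 : end])
        for ev in planted_events:
            if start <= ev.position <= end and rng.random() < ev.rate:
                bases[ev.position - start] = ev.alt
        if error_rate > 0:
            for k in range(len(bases)):
                if rng.random() < error_rate:
                    bases[k] = _OTHER[bases[k]][rng.integers(3)] if bases[k] in _OTHER else "N"
        reads.append(RawRead(id=f"r{i}", sequence="".join(bases) + adaptor, count=1))
    truth = TruthTable(
        events=list(planted_events),
        library=name,
        depth=depth,
        error_rate=error_rate,
        seed=seed,
    )
    return Library(name=name, reads=reads), truth


def collapse_library(lib: Library) -> Library:
    """Merge identical sequences into collapsed reads with summed counts."""
    counts: dict[str, int] = {}
    for r in lib.reads:
        counts[r.sequence] = counts.get(r.sequence, 0) + r.count
    reads = [
        RawRead(id=f"s{i}_x{c}", sequence=seq, count=c)
        for i, (seq, c) in enumerate(sorted(counts.items(), key=lambda kv: (-kv[1], kv[0])))
    ]
    return Library(name=lib.name, reads=reads, metadata=lib.metadata)


@dataclass(frozen=True)
class DecoyRecord:
    """A planted near-copy (1-mismatch variant) of a read sequence."""

    source_seq: str
    planted_seq: str
    chrom: str
    start: int  # 1-based


def make_genome(
    stemloops: Sequence[StemLoop],
    decoys: int = 0,
    seed: int = 0,
    decoy_sequences: Sequence[str] | None = None,
    spacer_len: int = 150,
    chrom: str = "chrS",
) -> tuple[dict[str, str], dict[str, tuple[str, int, int]], list[DecoyRecord]]:
    """Build a one-chromosome mini-genome embedding each stem-loop.

    Returns (genome, locus map ref_id -> (chrom, start, end), decoy records).
    ``decoys`` near-copies (one substitution each) of sequences drawn from
    ``decoy_sequences`` (or random 20-nt stem-loop windows) are planted in
    the spacers, giving the cross-genome filter something to catch.
    """
    if decoys < 0:
        raise ValueError("decoys must be >= 0")
    rng = np.random.default_rng(seed)
    parts: list[str] = []
    loci: dict[str, tuple[str, int, int]] = {}
    pos = 0

    def _append(seq: str):
        nonlocal pos
        parts.append(seq)
        pos += len(seq)

    for sl in stemloops:
        _append(_rand_seq(rng, spacer_len))
        loci[sl.id] = (chrom, pos + 1, pos + len(sl))
        _append(sl.sequence)
    _append(_rand_seq(rng, spacer_len))

    decoy_records: list[DecoyRecord] = []
    pool = list(decoy_sequences) if decoy_sequences else []
    if not pool and decoys > 0:
        for sl in stemloops:
            if len(sl) >= 20:
                o = int(rng.integers(0, len(sl) - 19))
                pool.append(sl.sequence[o : o + 20])
    for _ in range(decoys):
        src = pool[int(rng.integers(len(pool)))]
        mut = list(src)
        k = int(rng.integers(len(mut)))
        mut[k] = _OTHER[mut[k]][int(rng.integers(3))] if mut[k] in _OTHER else "A"
        planted = "".join(mut)
        _append(_rand_seq(rng, 30))
        decoy_records.append(DecoyRecord(src, planted, chrom, pos + 1))
        _append(planted)
    _append(_rand_seq(rng, 30))
    return {chrom: "".join(parts)}, loci, decoy_records


def write_loci_tsv(loci: Mapping[str, tuple[str, int, int]], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("ref_id\tchrom\tstart\tend\n")
        for ref_id in sorted(loci):
            c, s, e = loci[ref_id]
            fh.write(f"{ref_id}\t{c}\t{s}\t{e}\n")


def read_loci_tsv(path: str | Path) -> dict[str, tuple[str, int, int]]:
    loci = {}
    for ln_no, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip() or line.startswith("ref_id"):
            continue
        cols = line.split("\t")
        if len(cols) != 4:
            raise ValueError(f"{path}: line {ln_no}: expected 4 columns")
        loci[cols[0]] = (cols[1], int(cols[2]), int(cols[3]))
    return loci
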