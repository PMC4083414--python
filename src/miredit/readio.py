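"""Small-RNA read input/output and preprocessing.

Loads FASTQ, FASTA and collapsed-FASTA (multiplicity encoded in the header
as ``id_x42`` or ``id-42``), clips 3' adaptors, and applies the standard
small-RNA filters: minimum read length 16 nt and rejection of reads
containing ``N``.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Literal

from Bio import SeqIO

log = logging.getLogger(__name__)

_COUNT_RE = re.compile(r"(?:_x(\d+)|-(\d+))$")

ReadFormat = Literal["fastq", "fasta", "collapsed-fasta"]


@dataclass(frozen=True)
class RawRead:
    """One read (or one collapsed read group) with a multiplicity count."""

    id: str
    sequence: str
    count: int = 1

    def __post_init__(self):
        if self.count < 1:
            raise ValueError(f"read {self.id}: count must be >= 1")
        if not self.sequence:
            raise ValueError(f"read {self.id}: empty sequence")

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class Library:
    """A named collection of reads from one sequencing library."""

    name: str
    reads: list[RawRead] = field(default_factory=list)
    metadata: str = ""

    def __len__(self) -> int:
        return len(self.reads)

    def total_count(self) -> int:
        return sum(r.count for r in self.reads)


def _count_from_header(header: str) -> int:
    m = _COUNT_RE.search(header)
    return int(m.group(1) or m.group(2)) if m else 1


def _sniff_format(path: Path) -> ReadFormat:
    suffix = path.suffix.lower()
    if suffix in {".fastq", ".fq"}:
        return "fastq"
    return "fasta"


def load_reads(
    path: str | Path,
    format: ReadFormat | None = None,
    name: str | None = None,
) -> Library:
    """Load a read library.

    ``collapsed-fasta`` parses the multiplicity from the record id
    (``_xN`` or ``-N`` suffix); plain ``fasta``/``fastq`` reads default to
    count 1. An empty file yields an empty library with a warning.
    """
    path = Path(path)
    fmt = format or _sniff_format(path)
    parser_fmt = "fastq" if fmt == "fastq" else "fasta"
    reads: list[RawRead] = []
    try:
        for rec in SeqIO.parse(str(path), parser_fmt):
            count = _count_from_header(rec.id) if fmt == "collapsed-fasta" else 1
            reads.append(RawRead(id=rec.id, sequence=str(rec.seq).upper(), count=count))
    except ValueError as exc:  # Biopython reports malformed records as ValueError
        raise ValueError(f"{path}: malformed {parser_fmt} record: {exc}") from exc
    if not reads:
        log.warning("%s: no reads found (empty library)", path)
    return Library(name=name or path.stem, reads=reads, metadata=f"source={path}")


def write_collapsed_fasta(lib: Library, path: str | Path) -> None:
    """Write a library as collapsed FASTA with ``_xN`` count suffixes."""
    with open(path, "w") as fh:
        for i, r in enumerate(lib.reads):
            base = r.id or f"s{i}"
            base = _COUNT_RE.sub("", base)
            fh.write(f">{base}_x{r.count}\n{r.sequence}\n")


def write_fastq(lib: Library, path: str | Path) -> None:
    """Write a library as FASTQ (uniform placeholder qualities; one record
    per multiplicity unit is NOT expanded — counts are dropped)."""
    with open(path, "w") as fh:
        for r in lib.reads:
            fh.write(f"@{r.id}\n{r.sequence}\n+\n{'I' * len(r.sequence)}\n")


def read_fasta(path: str | Path) -> dict[str, str]:
    """Plain FASTA as an id -> sequence mapping (e.g. a mini-genome)."""
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(seqs: dict[str, str], path: str | Path) -> None:
    with open(path, "w") as fh:
        for name in seqs:
            fh.write(f">{name}\n{seqs[name]}\n")


def clip_adaptor(read: RawRead, adaptor: str, min_overlap: int = 6) -> RawRead | None:
    """Remove the 3' adaptor from a read.

    The clip point is the leftmost position where either (a) the full
    adaptor occurs, or (b) a prefix of the adaptor of at least
    ``min_overlap`` nt matches exactly and extends to the read's 3' end.
    Reads without adaptor evidence pass through unchanged; a read that is
    pure adaptor clips to nothing and is returned as None (discard).
    """
    if not adaptor:
        raise ValueError("adaptor must be non-empty")
    adaptor = adaptor.upper()
    seq = read.sequence
    clip_at = None
    full = seq.find(adaptor)
    if full != -1:
        clip_at = full
    # suffix of read == prefix of adaptor, at least min_overlap long
    max_tail = min(len(seq), len(adaptor))
    for tail_len in range(max_tail, min_overlap - 1, -1):
        i = len(seq) - tail_len
        if seq[i:] == adaptor[:tail_len]:
            if clip_at is None or i < clip_at:
                clip_at = i
            break  # longest suffix match is leftmost among suffix matches
    if clip_at is None or clip_at == len(seq):
        return read
    if clip_at == 0:
        return None  # pure-adaptor read
    return replace(read, sequence=seq[:clip_at])


def clip_library(lib: Library, adaptor: str, min_overlap: int = 6) -> Library:
    """Clip every read; reads reduced to nothing are dropped."""
    clipped = []
    dropped = 0
    for r in lib.reads:
        c = clip_adaptor(r, adaptor, min_overlap)
        if c is not None:
            clipped.append(c)
        else:
            dropped += 1
    if dropped:
        log.info("%s: %d pure-adaptor reads dropped during clipping", lib.name, dropped)
    return Library(name=lib.name, reads=clipped, metadata=lib.metadata)


@dataclass(frozen=True)
class FilterTally:
    """Discard bookkeeping for one filtering pass."""

    kept: int
    too_short: int
    with_n: int

    @property
    def discarded(self) -> int:
        return self.too_short + self.with_n


def filter_reads_tallied(
    lib: Library, min_len: int = 16, forbid_n: bool = True
) -> tuple[Library, FilterTally]:
    """Length/N filter with an explicit discard tally.

    A read passes when its length is >= ``min_len`` ("shorter than 16" is
    discarded, so exactly 16 survives) and, when ``forbid_n``, contains no
    ``N``. Order and counts are preserved.
    """
    kept: list[RawRead] = []
    too_short = with_n = 0
    for r in lib.reads:
        if len(r.sequence) < min_len:
            too_short += 1
        elif forbid_n and "N" in r.sequence:
            with_n += 1
        else:
            kept.append(r)
    tally = FilterTally(kept=len(kept), too_short=too_short, with_n=with_n)
    return Library(name=lib.name, reads=kept, metadata=lib.metadata), tally


def filter_reads(lib: Library, min_len: int = 16, forbid_n: bool = True) -> Library:
    """Length/N filter; the discard tally is logged."""
    out, tally = filter_reads_tallied(lib, min_len=min_len, forbid_n=forbid_n)
    log.info(
        "%s: kept %d reads, discarded %d too-short and %d with N",
        lib.name, tally.kept, tally.too_short, tally.with_n,
    )
    return out
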