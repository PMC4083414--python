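"""Ungapped all-hits read alignment with bounded mismatches.

Aligns preprocessed small-RNA reads end-to-end against stem-loop references,
reporting every placement with at most ``max_mm`` substitutions (all-hits
semantics, as with ``bowtie -v 1 -a``). A pigeonhole prefilter (one read
half must match exactly when max_mm <= 1) keeps the search fast; correctness
is defined by the exhaustive offset scan, which the test suite checks
against directly.

Also implements the cross-genome uniqueness filter: a read whose stem-loop
alignment carries a mismatch is discarded when it aligns (either strand,
<= max_mm mismatches) anywhere in the genome outside its own stem-loop
locus, suppressing cross-mapping artifacts.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pysam

from .readio import Library, RawRead
from .structure import StemLoop

log = logging.getLogger(__name__)

_COMP = str.maketrans("ACGTUN", "TGCAAN")


def revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


@dataclass(frozen=True)
class Mismatch:
    """One substitution in an alignment, in 1-based reference coordinates."""

    ref_pos: int
    ref_base: str
    read_base: str


@dataclass(frozen=True)
class AlignmentHit:
    """One ungapped end-to-end placement of a read on a reference."""

    read_id: str
    ref_id: str
    start: int  # 1-based on the reference
    sequence: str
    mismatches: tuple[Mismatch, ...] = ()
    count: int = 1
    strand: str = "+"
    multi_ref: bool = False  # read also hits another reference (all-hits)

    @property
    def end(self) -> int:
        return self.start + len(self.sequence) - 1

    @property
    def n_mismatches(self) -> int:
        return len(self.mismatches)


def _exact_offsets(ref: str, pattern: str) -> list[int]:
    """0-based start offsets of exact occurrences of pattern in ref."""
    out, i = [], ref.find(pattern)
    while i != -1:
        out.append(i)
        i = ref.find(pattern, i + 1)
    return out


def _candidate_offsets(ref: str, read: str, max_mm: int) -> Iterable[int]:
    n, m = len(ref), len(read)
    if max_mm == 0:
        return _exact_offsets(ref, read)
    if max_mm == 1:
        # pigeonhole: with <=1 substitution one of the two halves is exact
        half = m // 2
        left, right = read[:half], read[half:]
        cands = set()
        for o in _exact_offsets(ref, left):
            if o + m <= n:
                cands.add(o)
        for o in _exact_offsets(ref, right):
            if o - half >= 0 and o - half + m <= n:
                cands.add(o - half)
        return sorted(cands)
    return range(n - m + 1)


def _align_at(ref: str, read: str, offset: int, max_mm: int) -> tuple[Mismatch, ...] | None:
    """Verify one placement; None when it exceeds the mismatch budget."""
    mms: list[Mismatch] = []
    for k, (rb, qb) in enumerate(zip(ref[offset : offset + len(read)], read)):
        if rb != qb:
            if len(mms) == max_mm:
                return None
            mms.append(Mismatch(ref_pos=offset + k + 1, ref_base=rb, read_base=qb))
    return tuple(mms)


def scan_sequence(read: str, ref: str, max_mm: int = 1) -> list[tuple[int, tuple[Mismatch, ...]]]:
    """All placements of ``read`` in ``ref`` with <= max_mm substitutions.

    Returns (1-based start, mismatches) sorted by start.
    """
    if len(read) > len(ref):
        return []
    out = []
    for o in _candidate_offsets(ref, read, max_mm):
        mms = _align_at(ref, read, o, max_mm)
        if mms is not None:
            out.append((o + 1, mms))
    return out


def map_all(
    reads: Library | Sequence[RawRead],
    refs: Sequence[StemLoop],
    max_mm: int = 1,
) -> list[AlignmentHit]:
    """Map every read against every reference (sense strand), all hits.

    Every qualifying end-to-end placement is reported; reads hitting more
    than one reference contribute to each (flagged ``multi_ref``). Output is
    deterministically ordered by (ref_id, start, read_id).
    """
    read_list = reads.reads if isinstance(reads, Library) else list(reads)
    if not refs:
        raise ValueError("no references supplied")
    hits: list[AlignmentHit] = []
    for read in read_list:
        read_hits: list[AlignmentHit] = []
        refs_hit: set[str] = set()
        for ref in refs:
            for start, mms in scan_sequence(read.sequence, ref.sequence, max_mm):
                read_hits.append(
                    AlignmentHit(
                        read_id=read.id,
                        ref_id=ref.id,
                        start=start,
                        sequence=read.sequence,
                        mismatches=mms,
                        count=read.count,
                    )
                )
                refs_hit.add(ref.id)
        if len(refs_hit) > 1:
            read_hits = [replace(h, multi_ref=True) for h in read_hits]
        hits.extend(read_hits)
    hits.sort(key=lambda h: (h.ref_id, h.start, h.read_id))
    return hits


GenomeLoci = Mapping[str, tuple[str, int, int]]  # ref_id -> (chrom, start, end), 1-based


def _hits_elsewhere(
    seq: str,
    genome: Mapping[str, str],
    own_locus: tuple[str, int, int],
    max_mm: int,
) -> bool:
    """True when seq aligns (either strand, <= max_mm) outside its own locus."""
    own_chrom, own_start, own_end = own_locus
    for chrom, chrom_seq in genome.items():
        for query in (seq, revcomp(seq)):
            for start, _ in scan_sequence(query, chrom_seq, max_mm):
                end = start + len(seq) - 1
                if chrom == own_chrom and start <= own_end and end >= own_start:
                    continue  # overlaps its own stem-loop locus
                return True
    return False


def cross_genome_filter(
    hits: Sequence[AlignmentHit],
    genome: Mapping[str, str],
    stemloop_loci: GenomeLoci,
    max_mm: int = 1,
) -> list[AlignmentHit]:
    """Drop mismatched hits whose read also aligns elsewhere in the genome.

    0-mismatch hits always pass. A hit with a substitution is kept iff its
    read sequence has no alignment (either strand, <= max_mm mismatches) to
    the genome outside the genomic interval of its stem-loop locus. The
    first disqualifying placement short-circuits the scan.
    """
    genome = {c: s.upper() for c, s in genome.items()}
    cache: dict[tuple[str, str], bool] = {}
    kept: list[AlignmentHit] = []
    removed = 0
    for h in hits:
        if h.n_mismatches == 0:
            kept.append(h)
            continue
        if h.ref_id not in stemloop_loci:
            raise ValueError(
                f"stem-loop {h.ref_id} has no genomic locus; required for genome filtering"
            )
        key = (h.sequence, h.ref_id)
        if key not in cache:
            cache[key] = _hits_elsewhere(h.sequence, genome, stemloop_loci[h.ref_id], max_mm)
        if cache[key]:
            removed += 1
        else:
            kept.append(h)
    if removed:
        log.info("cross-genome filter removed %d mismatched hits", removed)
    return kept


def _md_tag(hit: AlignmentHit) -> str:
    """MD tag for an ungapped alignment (match lengths + reference bases)."""
    parts, prev = [], hit.start - 1
    for mm in sorted(hit.mismatches, key=lambda m: m.ref_pos):
        parts.append(str(mm.ref_pos - prev - 1))
        parts.append(mm.ref_base)
        prev = mm.ref_pos
    parts.append(str(hit.end - prev))
    return "".join(parts)


def write_sam(hits: Sequence[AlignmentHit], refs: Sequence[StemLoop], path: str | Path) -> None:
    """Export hits as SAM: one line per hit, NM/MD tags, count in the XC tag."""
    header = {
        "HD": {"VN": "1.6", "SO": "unsorted"},
        "SQ": [{"SN": r.id, "LN": len(r)} for r in refs],
    }
    with pysam.AlignmentFile(str(path), "w", header=header) as out:
        for h in hits:
            a = pysam.AlignedSegment(out.header)
            a.query_name = h.read_id
            a.query_sequence = h.sequence
            a.flag = 0
            a.reference_id = out.header.get_tid(h.ref_id)
            a.reference_start = h.start - 1
            a.mapping_quality = 255
            a.cigartuples = [(0, len(h.sequence))]
            a.set_tag("NM", h.n_mismatches)
            a.set_tag("MD", _md_tag(h))
            a.set_tag("XC", h.count)
            out.write(a)


def read_sam(path: str | Path) -> list[AlignmentHit]:
    """Import hits from SAM (e.g. produced by an external aligner).

    Mismatch descriptors are reconstructed from the MD tag and the read
    sequence; the XC tag, when present, restores the collapsed count.
    """
    hits: list[AlignmentHit] = []
    with pysam.AlignmentFile(str(path), "r", check_sq=False) as fh:
        for a in fh:
            if a.is_unmapped:
                continue
            seq = a.query_sequence or ""
            start = a.reference_start + 1
            mms: list[Mismatch] = []
            if a.has_tag("MD"):
                pos = start - 1  # last consumed ref position
                num = ""
                for ch in str(a.get_tag("MD")):
                    if ch.isdigit():
                        num += ch
                    else:
                        pos += int(num or 0)
                        pos += 1
                        num = ""
                        mms.append(
                            Mismatch(ref_pos=pos, ref_base=ch, read_base=seq[pos - start])
                        )
            count = int(a.get_tag("XC")) if a.has_tag("XC") else 1
            hits.append(
                AlignmentHit(
                    read_id=a.query_name,
                    ref_id=a.reference_name,
                    start=start,
                    sequence=seq,
                    mismatches=tuple(mms),
                    count=count,
                )
            )
    hits.sort(key=lambda h: (h.ref_id, h.start, h.read_id))
    return hits
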