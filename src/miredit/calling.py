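"""Per-position substitution profiles and editing-candidate calling.

Aggregates alignment hits into per-position coverage and substitution
counts, collapses identical reads into display groups, and emits editing
candidates under the standard thresholds: coverage strictly above 20 reads
and an editing level (percentage of covering reads carrying the dominant
substitution) strictly above 10%, per library. Levels are integer percent,
rounded half-up.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .mapping import AlignmentHit, Mismatch
from .structure import StemLoop

BASES = ("A", "C", "G", "T", "N")


class ProfileIntegrityError(ValueError):
    """A hit falls outside its reference's bounds."""


@dataclass
class PositionProfile:
    """Per-position coverage and substitution counts for one stem-loop.

    ``coverage[p]`` (1-based) is the summed multiplicity of reads overlapping
    p; ``subs[p]`` maps (ref_base, alt_base) to the summed multiplicity of
    reads substituted at p.
    """

    ref_id: str
    ref_seq: str
    coverage: np.ndarray  # int array, index 0 unused
    subs: dict[int, dict[tuple[str, str], int]] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.ref_seq)

    def mismatch_count(self, pos: int) -> int:
        return sum(self.subs.get(pos, {}).values())

    def mismatch_freq(self, pos: int, denominator: str = "coverage",
                      library_total: int | None = None) -> float:
        """Percent of reads mismatched at pos.

        The default denominator is the coverage at the position; pass
        ``denominator='library'`` with ``library_total`` to use the whole
        library's read count instead.
        """
        if denominator == "coverage":
            denom = int(self.coverage[pos])
        elif denominator == "library":
            if library_total is None:
                raise ValueError("library_total required for denominator='library'")
            denom = library_total
        else:
            raise ValueError(f"unknown denominator {denominator!r}")
        if denom == 0:
            return 0.0
        return 100.0 * self.mismatch_count(pos) / denom


def build_profile(hits: Sequence[AlignmentHit], ref: StemLoop) -> PositionProfile:
    """Tally coverage and substitutions for one reference from its hits."""
    n = len(ref)
    coverage = np.zeros(n + 1, dtype=np.int64)
    subs: dict[int, dict[tuple[str, str], int]] = {}
    for h in hits:
        if h.ref_id != ref.id:
            raise ProfileIntegrityError(f"hit on {h.ref_id} passed to profile of {ref.id}")
        if h.start < 1 or h.end > n:
            raise ProfileIntegrityError(
                f"hit {h.read_id} at {h.start}-{h.end} outside {ref.id} (len {n})"
            )
        coverage[h.start : h.end + 1] += h.count
        for mm in h.mismatches:
            key = (mm.ref_base, mm.read_base)
            pos_subs = subs.setdefault(mm.ref_pos, {})
            pos_subs[key] = pos_subs.get(key, 0) + h.count
    return PositionProfile(ref_id=ref.id, ref_seq=ref.sequence, coverage=coverage, subs=subs)


def combine_profiles(profiles: Sequence[PositionProfile]) -> PositionProfile:
    """Sum profiles of the same reference across libraries (for the display's
    total mismatch-frequency track)."""
    first = profiles[0]
    coverage = np.zeros_like(first.coverage)
    subs: dict[int, dict[tuple[str, str], int]] = {}
    for p in profiles:
        if p.ref_id != first.ref_id:
            raise ValueError("cannot combine profiles of different references")
        coverage += p.coverage
        for pos, d in p.subs.items():
            tgt = subs.setdefault(pos, {})
            for k, v in d.items():
                tgt[k] = tgt.get(k, 0) + v
    return PositionProfile(first.ref_id, first.ref_seq, coverage, subs)


@dataclass(frozen=True)
class ReadGroup:
    """Identical collapsed reads displayed as one bar."""

    sequence: str
    start: int
    end: int
    count: int
    mismatches: tuple[Mismatch, ...] = ()


def group_reads(hits: Sequence[AlignmentHit]) -> list[ReadGroup]:
    """Collapse hits on one reference into display groups.

    Groups are keyed by (sequence, start); counts are summed. Order is
    (start, descending count, sequence) for a stable display.
    """
    if hits:
        ref_ids = {h.ref_id for h in hits}
        if len(ref_ids) > 1:
            raise ValueError(f"hits span multiple references: {sorted(ref_ids)}")
    acc: dict[tuple[str, int], list] = {}
    for h in hits:
        key = (h.sequence, h.start)
        if key in acc:
            acc[key][0] += h.count
        else:
            acc[key] = [h.count, h.end, h.mismatches]
    groups = [
        ReadGroup(sequence=seq, start=start, end=end, count=count, mismatches=mms)
        for (seq, start), (count, end, mms) in acc.items()
    ]
    groups.sort(key=lambda g: (g.start, -g.count, g.sequence))
    return groups


def editing_level(mismatch_reads: int, total_reads: int) -> int:
    """Editing level as integer percent: round-half-up of 100*m/t.

    Computed in exact integer arithmetic, so 6/48 gives 13 (12.5 rounds up).
    """
    if total_reads <= 0:
        raise ValueError("editing level undefined for total_reads == 0")
    if not 0 <= mismatch_reads <= total_reads:
        raise ValueError("mismatch_reads must lie in [0, total_reads]")
    return (200 * mismatch_reads + total_reads) // (2 * total_reads)


@dataclass(frozen=True)
class EditCandidate:
    """One candidate editing site in one library."""

    mirna: str
    position: int
    mismatch_reads: int
    total_reads: int
    level: int
    type: str  # "REF>ALT"
    library: str
    dominant_tie: bool = False  # dominant alt chosen lexicographically on a tie


def call_candidates(
    profiles_by_library: Mapping[str, Iterable[PositionProfile]],
    min_total: int = 20,
    min_level_pct: int = 10,
    strict: bool = True,
) -> list[EditCandidate]:
    """Emit editing candidates per (stem-loop, position, library).

    A site qualifies when its coverage and the level of the dominant
    substitution both exceed the thresholds (strictly by default: coverage
    > 20 and level > 10%). The dominant alternative base is the one with the
    largest read count; ties break to the lexicographically smallest base
    and are flagged. Output is sorted ascending by level, then stem-loop,
    position and library.
    """
    out: list[EditCandidate] = []
    for library, profiles in profiles_by_library.items():
        for prof in profiles:
            for pos, d in prof.subs.items():
                total = int(prof.coverage[pos])
                if total <= 0:
                    continue
                if (total <= min_total) if strict else (total < min_total):
                    continue
                # dominant alt across substitution types at this position
                alt_counts: dict[str, int] = {}
                ref_base = prof.ref_seq[pos - 1]
                for (rb, alt), c in d.items():
                    alt_counts[alt] = alt_counts.get(alt, 0) + c
                best = max(alt_counts.values())
                winners = sorted(a for a, c in alt_counts.items() if c == best)
                alt = winners[0]
                level = editing_level(best, total)
                if (level <= min_level_pct) if strict else (level < min_level_pct):
                    continue
                out.append(
                    EditCandidate(
                        mirna=prof.ref_id,
                        position=pos,
                        mismatch_reads=best,
                        total_reads=total,
                        level=level,
                        type=f"{ref_base}>{alt}",
                        library=library,
                        dominant_tie=len(winners) > 1,
                    )
                )
    out.sort(key=lambda c: (c.level, c.mirna, c.position, c.library))
    return out


def multi_library_consistency(candidates: Sequence[EditCandidate]) -> pd.DataFrame:
    """Per-site library support: sites seen in >= 2 libraries are flagged
    high-confidence."""
    rows: dict[tuple[str, int], set[str]] = {}
    for c in candidates:
        rows.setdefault((c.mirna, c.position), set()).add(c.library)
    records = [
        {
            "mirna": mirna,
            "position": pos,
            "n_libraries": len(libs),
            "libraries": ",".join(sorted(libs)),
            "high_confidence": len(libs) >= 2,
        }
        for (mirna, pos), libs in sorted(rows.items())
    ]
    return pd.DataFrame.from_records(
        records, columns=["mirna", "position", "n_libraries", "libraries", "high_confidence"]
    )


def candidates_to_frame(candidates: Sequence[EditCandidate]) -> pd.DataFrame:
    return pd.DataFrame.from_records(
        [
            {
                "microRNA": c.mirna,
                "position": c.position,
                "reads (mismatch/total)": f"{c.mismatch_reads}/{c.total_reads}",
                "Level (%)": c.level,
                "type": c.type,
                "library": c.library,
            }
            for c in candidates
        ],
        columns=["microRNA", "position", "reads (mismatch/total)", "Level (%)", "type", "library"],
    )


def write_candidates_tsv(candidates: Sequence[EditCandidate], path: str | Path) -> None:
    candidates_to_frame(candidates).to_csv(path, sep="\t", index=False)


def read_candidates_tsv(path: str | Path) -> list[EditCandidate]:
    """Read a candidate table written by :func:`write_candidates_tsv`."""
    df = pd.read_csv(path, sep="\t")
    out = []
    for _, row in df.iterrows():
        mm, total = str(row["reads (mismatch/total)"]).split("/")
        out.append(
            EditCandidate(
                mirna=str(row["microRNA"]),
                position=int(row["position"]),
                mismatch_reads=int(mm),
                total_reads=int(total),
                level=int(row["Level (%)"]),
                type=str(row["type"]),
                library=str(row["library"]),
            )
        )
    return out


def write_profile_tsv(profile: PositionProfile, path: str | Path) -> None:
    """Per-position TSV: ref, pos, ref_base, coverage and per-alt counts."""
    rows = []
    for pos in range(1, len(profile) + 1):
        alt_counts = {b: 0 for b in BASES}
        for (rb, alt), c in profile.subs.get(pos, {}).items():
            alt_counts[alt] += c
        rows.append(
            {
                "ref": profile.ref_id,
                "pos": pos,
                "ref_base": profile.ref_seq[pos - 1],
                "coverage": int(profile.coverage[pos]),
                **alt_counts,
            }
        )
    pd.DataFrame.from_records(rows).to_csv(path, sep="\t", index=False)
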