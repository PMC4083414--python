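"""RNA secondary-structure model for microRNA stem-loops.

Parses Vienna dot-bracket strings into pairing tables and classifies every
position of a hairpin into structural element classes: the paired duplex,
bulges (unpaired on one strand only), internal loops (unpaired runs facing
each other), the terminal hairpin loop, and unpaired flanks outside the
outermost pair. These classes drive both the structure track of the linear
display and the single-/double-stranded editing statistic.

All user-facing coordinates are 1-based inclusive.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

UNPAIRED = 0

_NT = set("ACGTUN")
_DB = set("().")


class DotBracketError(ValueError):
    """Raised for malformed dot-bracket input; carries the offending 1-based index."""

    def __init__(self, message: str, index: int):
        super().__init__(f"{message} (at position {index})")
        self.index = index


class UnsupportedStructureError(ValueError):
    """Raised for structures with more than one terminal loop (multiloops)."""


@dataclass(frozen=True)
class Interval:
    """Closed 1-based interval with a label (e.g. '5P', '3P', 'exon')."""

    label: str
    start: int
    end: int

    def __post_init__(self):
        if self.start < 1 or self.end < self.start:
            raise ValueError(f"invalid interval {self.label}:{self.start}-{self.end}")

    def __len__(self) -> int:
        return self.end - self.start + 1

    def __contains__(self, pos: int) -> bool:
        return self.start <= pos <= self.end


class PairTable:
    """Base-pairing table over 1-based positions.

    ``partner(i)`` is the paired position of ``i`` or :data:`UNPAIRED` (0).
    Pairings parsed from dot-bracket strings are always nested (non-crossing).
    """

    def __init__(self, partners: Sequence[int]):
        # internal storage is a 1-based tuple with a dummy slot at index 0
        self._p = (UNPAIRED,) + tuple(partners)
        n = len(partners)
        for i in range(1, n + 1):
            j = self._p[i]
            if j == i:
                raise ValueError(f"position {i} pairs with itself")
            if j != UNPAIRED and (not 1 <= j <= n or self._p[j] != i):
                raise ValueError(f"pair table asymmetry at position {i}")

    def __len__(self) -> int:
        return len(self._p) - 1

    def partner(self, i: int) -> int:
        if not 1 <= i <= len(self):
            raise IndexError(f"position {i} outside 1..{len(self)}")
        return self._p[i]

    def is_paired(self, i: int) -> bool:
        return self.partner(i) != UNPAIRED

    def pairs(self) -> list[tuple[int, int]]:
        """All (i, j) pairs with i < j."""
        return [(i, self._p[i]) for i in range(1, len(self) + 1) if self._p[i] > i]

    def to_dotbracket(self) -> str:
        out = []
        for i in range(1, len(self) + 1):
            j = self._p[i]
            out.append("." if j == UNPAIRED else ("(" if j > i else ")"))
        return "".join(out)

    def __eq__(self, other) -> bool:
        return isinstance(other, PairTable) and self._p == other._p

    def __repr__(self) -> str:
        return f"PairTable({self.to_dotbracket()!r})"


def parse_dotbracket(dotbracket: str) -> PairTable:
    """Parse a balanced dot-bracket string into a :class:`PairTable`.

    Only ``(``, ``)`` and ``.`` are accepted; pseudoknot bracket alphabets
    are rejected. Raises :class:`DotBracketError` naming the first offending
    1-based index on unbalanced or illegal input.
    """
    partners = [UNPAIRED] * len(dotbracket)
    stack: list[int] = []
    for idx, ch in enumerate(dotbracket, start=1):
        if ch == "(":
            stack.append(idx)
        elif ch == ")":
            if not stack:
                raise DotBracketError("unmatched ')'", idx)
            j = stack.pop()
            partners[idx - 1] = j
            partners[j - 1] = idx
        elif ch != ".":
            raise DotBracketError(f"illegal character {ch!r}", idx)
    if stack:
        raise DotBracketError("unmatched '('", stack[-1])
    return PairTable(partners)


@dataclass
class StemLoop:
    """A reference hairpin: sequence, structure and annotations.

    mature_intervals carry the annotated 5P/3P arms (grey shading in the
    display); genomic_segments describe the genomic environment track
    (exon/intron/flank boxes).
    """

    id: str
    sequence: str
    dotbracket: str
    mature_intervals: tuple[Interval, ...] = ()
    genomic_segments: tuple[Interval, ...] = ()

    def __post_init__(self):
        self.sequence = self.sequence.upper()
        if len(self.sequence) != len(self.dotbracket):
            raise ValueError(
                f"{self.id}: sequence length {len(self.sequence)} != "
                f"dot-bracket length {len(self.dotbracket)}"
            )
        bad = set(self.sequence) - _NT
        if bad:
            raise ValueError(f"{self.id}: illegal sequence characters {sorted(bad)}")
        self.mature_intervals = tuple(self.mature_intervals)
        self.genomic_segments = tuple(self.genomic_segments)
        for iv in self.mature_intervals:
            if iv.end > len(self.sequence):
                raise ValueError(f"{self.id}: mature interval {iv} outside sequence")
        self._pair_table: PairTable | None = None

    def __len__(self) -> int:
        return len(self.sequence)

    @property
    def pair_table(self) -> PairTable:
        if self._pair_table is None:
            self._pair_table = parse_dotbracket(self.dotbracket)
        return self._pair_table


class ElementKind(enum.Enum):
    DUPLEX = "duplex"
    BULGE = "bulge"
    INTERNAL_LOOP = "internal_loop"
    HAIRPIN_LOOP = "hairpin_loop"
    FLANK = "flank"


#: element kinds counted as single-stranded by default (stem interruptions)
SS_KINDS = frozenset({ElementKind.BULGE, ElementKind.INTERNAL_LOOP})


@dataclass(frozen=True)
class StructureElement:
    """A maximal run of positions sharing one structural class.

    ``opposite_bulge_len`` is the length of the unpaired run on the opposite
    strand enclosed by the same flanking pairs: 0 for a bulge (the opposite
    strand is contiguous), the facing run's length for an internal loop.
    """

    kind: ElementKind
    start: int
    end: int
    opposite_bulge_len: int = 0

    def __len__(self) -> int:
        return self.end - self.start + 1

    def positions(self) -> range:
        return range(self.start, self.end + 1)


def _unpaired_runs(pt: PairTable) -> list[tuple[int, int]]:
    runs, i, n = [], 1, len(pt)
    while i <= n:
        if not pt.is_paired(i):
            j = i
            while j < n and not pt.is_paired(j + 1):
                j += 1
            runs.append((i, j))
            i = j + 1
        else:
            i += 1
    return runs


def classify_elements(pt: PairTable) -> list[StructureElement]:
    """Partition every position of a single-hairpin pair table into elements.

    Rejects multiloop structures (more than one terminal loop) with
    :class:`UnsupportedStructureError`. The result is sorted by start and
    covers every position exactly once.
    """
    n = len(pt)
    db = pt.to_dotbracket()
    # a second hairpin would open a '(' after some ')' has closed
    first_close = db.find(")")
    if first_close != -1 and "(" in db[first_close:]:
        raise UnsupportedStructureError("structure has more than one terminal loop")

    elements: list[StructureElement] = []
    paired = [i for i in range(1, n + 1) if pt.is_paired(i)]

    # duplex runs: maximal runs of consecutive paired positions
    i = 0
    while i < len(paired):
        j = i
        while j + 1 < len(paired) and paired[j + 1] == paired[j] + 1:
            j += 1
        elements.append(StructureElement(ElementKind.DUPLEX, paired[i], paired[j]))
        i = j + 1

    if not paired:
        if n:
            elements.append(StructureElement(ElementKind.FLANK, 1, n))
        return elements

    lo, hi = paired[0], paired[-1]
    for start, end in _unpaired_runs(pt):
        if end < lo or start > hi:
            elements.append(StructureElement(ElementKind.FLANK, start, end))
            continue
        left, right = start - 1, end + 1  # flanking paired positions
        if pt.partner(left) == right:
            elements.append(StructureElement(ElementKind.HAIRPIN_LOOP, start, end))
            continue
        # opposite-strand interval enclosed by the partners of the flanking pairs
        a, b = sorted((pt.partner(left), pt.partner(right)))
        opp_len = b - a - 1
        if any(pt.is_paired(k) for k in range(a + 1, b)):
            raise UnsupportedStructureError(
                f"branched structure opposite run {start}-{end}"
            )
        kind = ElementKind.BULGE if opp_len == 0 else ElementKind.INTERNAL_LOOP
        elements.append(StructureElement(kind, start, end, opposite_bulge_len=opp_len))

    elements.sort(key=lambda e: e.start)
    return elements


def element_at(elements: Sequence[StructureElement], pos: int) -> StructureElement:
    for e in elements:
        if e.start <= pos <= e.end:
            return e
    raise IndexError(f"position {pos} not covered by elements")


@dataclass(frozen=True)
class SsDsCounts:
    """Nucleotide counts in single- vs double-stranded regions."""

    n_ss: int
    n_ds: int


def count_ss_ds(
    elements: Iterable[StructureElement],
    include_hairpin_loop: bool = False,
    include_flanks: bool = False,
) -> SsDsCounts:
    """Count nucleotides in double-stranded (duplex) vs single-stranded regions.

    By default single-stranded counts only stem interruptions (bulges and
    internal loops); the terminal loop and flanks are excluded, matching the
    statistic's contrast between the duplex and its interruptions. Set the
    flags to fold hairpin-loop / flank nucleotides into N_ss.
    """
    ss_kinds = set(SS_KINDS)
    if include_hairpin_loop:
        ss_kinds.add(ElementKind.HAIRPIN_LOOP)
    if include_flanks:
        ss_kinds.add(ElementKind.FLANK)
    n_ss = n_ds = 0
    for e in elements:
        if e.kind is ElementKind.DUPLEX:
            n_ds += len(e)
        elif e.kind in ss_kinds:
            n_ss += len(e)
    return SsDsCounts(n_ss=n_ss, n_ds=n_ds)


def read_structures(path: str | Path) -> list[StemLoop]:
    """Load stem-loops from a structure file.

    Two dialects are accepted:

    * Vienna-style three-line records: ``>id`` / sequence / dot-bracket;
    * TSV with columns ``id``, ``sequence``, ``dotbracket`` (header optional).
    """
    path = Path(path)
    text = path.read_text()
    lines = [ln.rstrip("\n") for ln in text.splitlines() if ln.strip()]
    if not lines:
        return []
    out: list[StemLoop] = []
    if lines[0].startswith(">"):
        i = 0
        while i < len(lines):
            if not lines[i].startswith(">"):
                raise ValueError(f"{path}: expected '>' header at line {i + 1}")
            if i + 2 >= len(lines):
                raise ValueError(f"{path}: truncated record for {lines[i]}")
            sl_id = lines[i][1:].split()[0]
            out.append(StemLoop(id=sl_id, sequence=lines[i + 1], dotbracket=lines[i + 2]))
            i += 3
    else:
        for ln_no, ln in enumerate(lines, start=1):
            cols = ln.split("\t")
            if ln_no == 1 and cols[0].lower() in {"id", "name"}:
                continue
            if len(cols) < 3:
                raise ValueError(f"{path}: line {ln_no}: expected 3 tab-separated columns")
            out.append(StemLoop(id=cols[0], sequence=cols[1], dotbracket=cols[2]))
    return out


def write_structures(stemloops: Iterable[StemLoop], path: str | Path) -> None:
    """Write stem-loops as Vienna-style three-line records."""
    with open(path, "w") as fh:
        for sl in stemloops:
            fh.write(f">{sl.id}\n{sl.sequence}\n{sl.dotbracket}\n")
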