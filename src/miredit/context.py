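"""Observed vs expected editing in single- and double-stranded regions.

Under a random model in which editing is independent of secondary
structure, S observed edit sites distribute over double- and single-
stranded nucleotides in proportion to their abundance:

    E_ds = S * N_ds / (N_ds + N_ss)
    E_ss = S * N_ss / (N_ds + N_ss)

where N_ds and N_ss are the total numbers of nucleotides in double- and
single-stranded regions. The observed-over-expected ratios O_ss/E_ss and
O_ds/E_ds measure structural preference of editing; ratios near 1 indicate
that editing is indifferent to whether a site sits in the duplex or in a
bulge/internal loop.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
from typing import Iterable, Mapping, Sequence

from .calling import EditCandidate
from .structure import (
    ElementKind,
    SS_KINDS,
    StemLoop,
    StructureElement,
    classify_elements,
    count_ss_ds,
    element_at,
)


@dataclass(frozen=True)
class ContextStats:
    """Observed/expected editing by structural context.

    Ratios are reported rounded to 2 decimals; expected counts keep full
    precision (E_ss + E_ds == S exactly, by construction).
    """

    S: int
    n_ss: int
    n_ds: int
    o_ss: int
    o_ds: int
    unclassified: int
    e_ss: float
    e_ds: float
    ratio_ss: float
    ratio_ds: float

    def to_dict(self) -> dict:
        return asdict(self)


def expected_edits(S: int, n_ss: int, n_ds: int) -> tuple[float, float]:
    """Expected (E_ss, E_ds) for S sites under the structure-independent model."""
    if S < 0:
        raise ValueError("S must be >= 0")
    total = n_ss + n_ds
    if total == 0:
        raise ValueError("expected edits undefined: N_ss + N_ds == 0")
    return S * n_ss / total, S * n_ds / total


def observed_edits(
    sites: Iterable[tuple[str, int]],
    elements_by_mirna: Mapping[str, Sequence[StructureElement]],
    include_hairpin_loop: bool = False,
    include_flanks: bool = False,
) -> tuple[int, int, int]:
    """Assign unique edit sites to ss/ds by their structural element.

    Returns (O_ss, O_ds, unclassified): duplex positions count as ds;
    bulge/internal-loop positions as ss; hairpin-loop and flank positions
    are unclassified unless the corresponding flag folds them into ss.
    """
    ss_kinds = set(SS_KINDS)
    if include_hairpin_loop:
        ss_kinds.add(ElementKind.HAIRPIN_LOOP)
    if include_flanks:
        ss_kinds.add(ElementKind.FLANK)
    o_ss = o_ds = unclassified = 0
    for mirna, pos in sites:
        if mirna not in elements_by_mirna:
            raise ValueError(f"no structure for {mirna}")
        try:
            elem = element_at(elements_by_mirna[mirna], pos)
        except IndexError as exc:
            raise ValueError(f"site {mirna}:{pos} outside structure") from exc
        if elem.kind is ElementKind.DUPLEX:
            o_ds += 1
        elif elem.kind in ss_kinds:
            o_ss += 1
        else:
            unclassified += 1
    return o_ss, o_ds, unclassified


def unique_sites(candidates: Iterable[EditCandidate]) -> list[tuple[str, int]]:
    """Distinct (stem-loop, position) pairs across libraries, sorted."""
    return sorted({(c.mirna, c.position) for c in candidates})


def context_report(
    candidates: Sequence[EditCandidate],
    stemloops: Sequence[StemLoop],
    include_hairpin_loop: bool = False,
    include_flanks: bool = False,
    universe: str = "with_candidates",
    allow_empty: bool = False,
) -> ContextStats:
    """Full observed/expected report for a candidate set.

    The nucleotide universe (N_ss, N_ds) is summed over stem-loops carrying
    at least one candidate by default; ``universe='all'`` sums over every
    supplied stem-loop. S counts unique (stem-loop, position) sites.
    """
    if universe not in {"with_candidates", "all"}:
        raise ValueError(f"unknown universe {universe!r}")
    sites = unique_sites(candidates)
    if not sites and not allow_empty:
        raise ValueError("no candidate sites; pass allow_empty=True for a zero report")
    by_id = {sl.id: sl for sl in stemloops}
    elements = {sl.id: classify_elements(sl.pair_table) for sl in stemloops}
    carrying = {m for m, _ in sites}
    missing = carrying - set(by_id)
    if missing:
        raise ValueError(f"candidates without structures: {sorted(missing)}")
    scope = stemloops if universe == "all" else [by_id[m] for m in sorted(carrying)]
    n_ss = n_ds = 0
    for sl in scope:
        c = count_ss_ds(
            elements[sl.id],
            include_hairpin_loop=include_hairpin_loop,
            include_flanks=include_flanks,
        )
        n_ss += c.n_ss
        n_ds += c.n_ds
    S = len(sites)
    if S == 0:
        return ContextStats(0, n_ss, n_ds, 0, 0, 0, 0.0, 0.0, float("nan"), float("nan"))
    o_ss, o_ds, unclassified = observed_edits(
        sites, elements, include_hairpin_loop=include_hairpin_loop,
        include_flanks=include_flanks,
    )
    e_ss, e_ds = expected_edits(S, n_ss, n_ds)
    ratio_ss = round(o_ss / e_ss, 2) if e_ss > 0 else float("nan")
    ratio_ds = round(o_ds / e_ds, 2) if e_ds > 0 else float("nan")
    return ContextStats(
        S=S, n_ss=n_ss, n_ds=n_ds, o_ss=o_ss, o_ds=o_ds,
        unclassified=unclassified, e_ss=e_ss, e_ds=e_ds,
        ratio_ss=ratio_ss, ratio_ds=ratio_ds,
    )
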