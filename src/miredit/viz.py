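"""Seven-track linear SVG display of a stem-loop with its NGS evidence.

The display stacks, top to bottom: (1) per-position mismatch-frequency
stripe, (2) read-coverage histogram, (3) genomic environment boxes
(exon/intron/flank), (4) the reference sequence, (5) collapsed read-group
bars per library with colored mismatch segments and count labels, (6)
spelled-out read sequences with the same mismatch coloring, and (7) the
secondary-structure line: double-stranded runs in blue above, single-
stranded runs in magenta below, green boxes carrying bulge lengths drawn
on the strand opposite each bulge, grey shading under the annotated 5P/3P
mature forms, and an optional magenta connector joining a position to its
base-pairing partner.

Every glyph carries machine-readable ``data-*`` attributes (position,
count, alt base ...) so the display can be asserted on without pixel
comparison. Libraries are stacked and separated by a dotted divider; one
library may be highlighted in pink. Read groups below a count threshold
can be hidden (``min_group_count``; a threshold of 30 shows only groups
with more than 30 identical reads).
"""

from __future__ import annotations

import warnings
import xml.etree.ElementTree as ET
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

from .calling import PositionProfile, ReadGroup, combine_profiles
from .structure import ElementKind, StemLoop, StructureElement, classify_elements

SVG_NS = "http://www.w3.org/2000/svg"

TRACK_ORDER = (
    "mismatch_freq",
    "coverage",
    "genomic_env",
    "reference",
    "read_groups",
    "read_sequences",
    "structure",
)

DEFAULT_COLORS = {
    "ss": "#ff00ff",          # magenta single-stranded line
    "ds": "#0000cd",          # blue double-stranded line
    "bulge_box": "#228b22",   # green bulge-length boxes
    "highlight": "#ffc0cb",   # pink selected-library background
    "mature": "#c8c8c8",      # grey 5P/3P shading
    "coverage": "#d62728",    # red coverage histogram
    "freq": "#d62728",        # mismatch-frequency stripe
    "bar": "#4d4d4d",
    "exon": "#355e8d",
    "intron": "#9ecae1",
    "flank": "#bdbdbd",
    # per-alternative-base mismatch colors
    "alt_A": "#2ca02c",
    "alt_C": "#1f77b4",
    "alt_G": "#ff7f0e",
    "alt_T": "#d62728",
    "alt_N": "#7f7f7f",
}

_HEX = set("0123456789abcdefABCDEF")


def _valid_hex(c: str) -> bool:
    return c.startswith("#") and len(c) in (4, 7) and all(ch in _HEX for ch in c[1:])


@dataclass
class StyleConfig:
    """Colors, geometry and display filters for the linear display."""

    colors: dict = field(default_factory=lambda: dict(DEFAULT_COLORS))
    min_group_count: int = 1
    nt_width: float = 10.0
    margin: float = 40.0
    track_gap: float = 14.0
    freq_style: str = "stripe"  # or "line"
    tracks_on: dict = field(
        default_factory=lambda: {name: True for name in TRACK_ORDER}
    )

    def __post_init__(self):
        if self.min_group_count < 1:
            raise ValueError("min_group_count must be >= 1")
        for key, c in self.colors.items():
            if not _valid_hex(c):
                raise ValueError(f"style color {key}={c!r} is not a hex color")

    def color(self, key: str) -> str:
        return self.colors.get(key, "#000000")

    def alt_color(self, alt: str) -> str:
        return self.colors.get(f"alt_{alt}", self.colors.get("alt_N", "#7f7f7f"))


def load_style(path: str | Path) -> StyleConfig:
    """Read a ``key=value`` style file; unknown keys are rejected.

    Color keys match DEFAULT_COLORS; ``min_group_count``, ``nt_width`` and
    ``freq_style`` tune the display; ``track.<name>=off`` disables a track.
    """
    style = StyleConfig()
    for ln_no, raw in enumerate(Path(path).read_text().splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        if "=" not in line:
            raise ValueError(f"{path}: line {ln_no}: expected key=value")
        key, _, value = (p.strip() for p in line.partition("="))
        if key in DEFAULT_COLORS:
            style.colors[key] = value
        elif key == "min_group_count":
            style.min_group_count = int(value)
        elif key == "nt_width":
            style.nt_width = float(value)
        elif key == "freq_style":
            style.freq_style = value
        elif key.startswith("track.") and key[6:] in TRACK_ORDER:
            style.tracks_on[key[6:]] = value.lower() not in {"off", "false", "0"}
        else:
            raise ValueError(f"{path}: line {ln_no}: unknown style key {key!r}")
    style.__post_init__()
    return style


def _el(parent: ET.Element, tag: str, **attrs) -> ET.Element:
    e = ET.SubElement(parent, tag)
    for k, v in attrs.items():
        e.set(k.replace("_", "-") if k.startswith("data_") else k, str(v))
    return e


class _Layout:
    def __init__(self, style: StyleConfig, seq_len: int):
        self.style = style
        self.seq_len = seq_len

    def x(self, pos: int) -> float:
        """Left edge of the cell for 1-based position pos."""
        return self.style.margin + (pos - 1) * self.style.nt_width

    def xc(self, pos: int) -> float:
        return self.x(pos) + self.style.nt_width / 2

    @property
    def width(self) -> float:
        return 2 * self.style.margin + self.seq_len * self.style.nt_width


def visible_groups(groups: Sequence[ReadGroup], min_group_count: int) -> list[ReadGroup]:
    """Display filter: with a threshold above 1, only groups with strictly
    more reads than the threshold are shown; a threshold of 1 shows all."""
    if min_group_count > 1:
        return [g for g in groups if g.count > min_group_count]
    return list(groups)


def _pack_rows(groups: Sequence[ReadGroup]) -> list[int]:
    """Greedy interval packing: row index per group (input sorted by start)."""
    row_ends: list[int] = []
    rows = []
    for g in groups:
        for r, last_end in enumerate(row_ends):
            if g.start > last_end + 1:
                row_ends[r] = g.end
                rows.append(r)
                break
        else:
            row_ends.append(g.end)
            rows.append(len(row_ends) - 1)
    return rows


def render(
    stemloop: StemLoop,
    profiles: Mapping[str, PositionProfile] | PositionProfile,
    groups_by_library: Mapping[str, Sequence[ReadGroup]],
    elements: Sequence[StructureElement] | None = None,
    style: StyleConfig | None = None,
    highlight_pair: int | None = None,
    selected_library: str | None = None,
) -> str:
    """Render the seven-track display to an SVG 1.1 string."""
    style = style or StyleConfig()
    if isinstance(profiles, PositionProfile):
        profiles = {"library": profiles}
    if elements is None:
        elements = classify_elements(stemloop.pair_table)
    lay = _Layout(style, len(stemloop))
    combined = combine_profiles(list(profiles.values())) if profiles else None

    root = ET.Element("svg", {"xmlns": SVG_NS, "version": "1.1"})
    root.set("data-stemloop", stemloop.id)
    title = ET.SubElement(root, "title")
    title.text = stemloop.id
    y = 16.0

    builders = {
        "mismatch_freq": _track_freq,
        "coverage": _track_coverage,
        "genomic_env": _track_genomic,
        "reference": _track_reference,
        "read_groups": _track_groups,
        "read_sequences": _track_sequences,
        "structure": _track_structure,
    }
    ctx = dict(
        stemloop=stemloop,
        combined=combined,
        profiles=profiles,
        groups_by_library=groups_by_library,
        elements=elements,
        style=style,
        lay=lay,
        highlight_pair=highlight_pair,
        selected_library=selected_library,
    )
    for name in TRACK_ORDER:
        if not style.tracks_on.get(name, True):
            continue
        g = _el(root, "g", **{"class": "track", "id": f"track-{name}", "data-track": name})
        g.set("transform", f"translate(0,{y:.1f})")
        height = builders[name](g, **ctx)
        y += height + style.track_gap

    root.set("width", f"{lay.width:.0f}")
    root.set("height", f"{y:.0f}")
    return ET.tostring(root, encoding="unicode")


def save_svg(svg_text: str, path: str | Path) -> None:
    Path(path).write_text(svg_text)


# --- track builders (each returns its height) ---------------------------------


def _track_freq(g, *, combined, style, lay, **_) -> float:
    h = 14.0
    if combined is None:
        return h
    if style.freq_style == "line":
        pts = []
        for pos in range(1, len(combined) + 1):
            f = combined.mismatch_freq(pos)
            pts.append(f"{lay.xc(pos):.1f},{h - f / 100 * h:.1f}")
        _el(g, "polyline", points=" ".join(pts), fill="none",
            stroke=style.color("freq"), **{"class": "freq-line"})
        return h
    for pos in range(1, len(combined) + 1):
        f = combined.mismatch_freq(pos)
        if f <= 0:
            continue
        _el(
            g, "rect", x=f"{lay.x(pos):.1f}", y="0",
            width=f"{style.nt_width:.1f}", height=f"{h:.1f}",
            fill=style.color("freq"), **{"fill-opacity": f"{max(f / 100, 0.08):.3f}",
            "class": "freq-cell", "data-pos": pos, "data-freq": f"{f:.2f}"},
        )
    return h


def _track_coverage(g, *, combined, style, lay, **_) -> float:
    h = 40.0
    if combined is None:
        return h
    max_cov = int(combined.coverage.max()) if len(combined.coverage) else 0
    if max_cov == 0:
        return h
    for pos in range(1, len(combined) + 1):
        cov = int(combined.coverage[pos])
        if cov == 0:
            continue
        bar_h = h * cov / max_cov
        _el(
            g, "rect", x=f"{lay.x(pos):.1f}", y=f"{h - bar_h:.1f}",
            width=f"{style.nt_width:.1f}", height=f"{bar_h:.1f}",
            fill=style.color("coverage"),
            **{"class": "coverage-bar", "data-pos": pos, "data-coverage": cov},
        )
    return h


def _track_genomic(g, *, stemloop, style, lay, **_) -> float:
    h = 18.0
    for seg in stemloop.genomic_segments:
        x0, x1 = lay.x(seg.start), lay.x(seg.end) + style.nt_width
        _el(
            g, "rect", x=f"{x0:.1f}", y="2", width=f"{x1 - x0:.1f}", height=f"{h - 4:.1f}",
            fill=style.color(seg.label if seg.label in ("exon", "intron", "flank") else "flank"),
            **{"class": "genomic-segment", "data-label": seg.label,
               "data-start": seg.start, "data-end": seg.end},
        )
        t = _el(g, "text", x=f"{(x0 + x1) / 2:.1f}", y=f"{h - 5:.1f}",
                **{"text-anchor": "middle", "font-size": "9", "class": "genomic-label"})
        t.text = seg.label
    return h


def _track_reference(g, *, stemloop, style, lay, **_) -> float:
    h = 12.0
    for pos, base in enumerate(stemloop.sequence, start=1):
        t = _el(
            g, "text", x=f"{lay.xc(pos):.1f}", y=f"{h - 2:.1f}",
            **{"text-anchor": "middle", "font-size": "10",
               "font-family": "monospace", "class": "refbase", "data-pos": pos},
        )
        t.text = base
    return h


def _bar_with_mismatches(g, grp: ReadGroup, y0: float, bar_h: float, style, lay):
    x0 = lay.x(grp.start)
    width = (grp.end - grp.start + 1) * style.nt_width
    bar = _el(
        g, "g",
        **{"class": "read-group", "data-start": grp.start, "data-end": grp.end,
           "data-count": grp.count},
    )
    _el(bar, "rect", x=f"{x0:.1f}", y=f"{y0 + 3:.1f}",
        width=f"{width:.1f}", height=f"{bar_h - 3:.1f}", fill=style.color("bar"))
    for mm in grp.mismatches:
        _el(
            bar, "rect", x=f"{lay.x(mm.ref_pos):.1f}", y=f"{y0:.1f}",
            width=f"{style.nt_width:.1f}", height="3",
            fill=style.alt_color(mm.read_base),
            **{"class": "mismatch", "data-pos": mm.ref_pos, "data-alt": mm.read_base},
        )
    label = _el(
        bar, "text", x=f"{x0 + width + 3:.1f}", y=f"{y0 + bar_h - 1:.1f}",
        **{"font-size": "9", "class": "group-count"},
    )
    label.text = str(grp.count)


def _track_groups(g, *, groups_by_library, style, lay, selected_library, **_) -> float:
    bar_h, row_gap, lib_gap = 10.0, 3.0, 10.0
    y = 0.0
    libraries = list(groups_by_library)
    for li, lib in enumerate(libraries):
        groups = visible_groups(groups_by_library[lib], style.min_group_count)
        rows = _pack_rows(groups)
        n_rows = (max(rows) + 1) if rows else 1
        block_h = 12 + n_rows * (bar_h + row_gap)
        if lib == selected_library:
            _el(g, "rect", x="0", y=f"{y:.1f}", width=f"{lay.width:.1f}",
                height=f"{block_h:.1f}", fill=style.color("highlight"),
                **{"class": "library-highlight", "data-library": lib})
        t = _el(g, "text", x="2", y=f"{y + 9:.1f}",
                **{"font-size": "9", "class": "library-label", "data-library": lib})
        t.text = lib
        for grp, row in zip(groups, rows):
            _bar_with_mismatches(g, grp, y + 12 + row * (bar_h + row_gap), bar_h, style, lay)
        y += block_h
        if li < len(libraries) - 1:
            _el(g, "line", x1="0", x2=f"{lay.width:.1f}",
                y1=f"{y + lib_gap / 2:.1f}", y2=f"{y + lib_gap / 2:.1f}",
                stroke="#000000", **{"stroke-dasharray": "2,3", "class": "library-divider"})
            y += lib_gap
    return max(y, 12.0)


def _track_sequences(g, *, groups_by_library, style, lay, **_) -> float:
    row_h = 11.0
    y = 0.0
    for lib in groups_by_library:
        for grp in visible_groups(groups_by_library[lib], style.min_group_count):
            width = (grp.end - grp.start + 1) * style.nt_width
            t = _el(
                g, "text", x=f"{lay.x(grp.start):.1f}", y=f"{y + row_h - 2:.1f}",
                textLength=f"{width:.1f}", lengthAdjust="spacingAndGlyphs",
                **{"font-size": "9", "font-family": "monospace",
                   "class": "read-seq", "data-start": grp.start, "data-count": grp.count},
            )
            t.text = grp.sequence
            for mm in grp.mismatches:
                alt = _el(
                    g, "text", x=f"{lay.xc(mm.ref_pos):.1f}", y=f"{y + row_h - 2:.1f}",
                    fill=style.alt_color(mm.read_base),
                    **{"text-anchor": "middle", "font-size": "9",
                       "font-family": "monospace", "font-weight": "bold",
                       "class": "read-seq-mismatch", "data-pos": mm.ref_pos,
                       "data-alt": mm.read_base},
                )
                alt.text = mm.read_base
            y += row_h
    return max(y, row_h)


def _opposite_interval(pt, elem: StructureElement) -> tuple[int, int] | None:
    """Opposite-strand interval enclosed by the flanking pairs of a stem
    interruption; (a+1, b-1) may be empty (bulge)."""
    left, right = elem.start - 1, elem.end + 1
    if left < 1 or right > len(pt) or not (pt.is_paired(left) and pt.is_paired(right)):
        return None
    a, b = sorted((pt.partner(left), pt.partner(right)))
    return a + 1, b - 1


def _track_structure(g, *, stemloop, elements, style, lay, highlight_pair, **_) -> float:
    h = 46.0
    y_ds, y_ss = 16.0, 30.0
    pt = stemloop.pair_table
    # grey mature-form shading behind everything
    for iv in stemloop.mature_intervals:
        _el(
            g, "rect", x=f"{lay.x(iv.start):.1f}", y="6",
            width=f"{(iv.end - iv.start + 1) * style.nt_width:.1f}", height=f"{h - 12:.1f}",
            fill=style.color("mature"), **{"fill-opacity": "0.6",
            "class": "mature-shade", "data-label": iv.label,
            "data-start": iv.start, "data-end": iv.end},
        )
    for elem in elements:
        x0, x1 = lay.x(elem.start), lay.x(elem.end) + style.nt_width
        if elem.kind is ElementKind.DUPLEX:
            _el(g, "line", x1=f"{x0:.1f}", x2=f"{x1:.1f}", y1=f"{y_ds:.1f}", y2=f"{y_ds:.1f}",
                stroke=style.color("ds"), **{"stroke-width": "4", "class": "ds-run",
                "data-start": elem.start, "data-end": elem.end})
        else:
            _el(g, "line", x1=f"{x0:.1f}", x2=f"{x1:.1f}", y1=f"{y_ss:.1f}", y2=f"{y_ss:.1f}",
                stroke=style.color("ss"), **{"stroke-width": "4",
                "class": "ss-run", "data-kind": elem.kind.value,
                "data-start": elem.start, "data-end": elem.end})
        if elem.kind in (ElementKind.BULGE, ElementKind.INTERNAL_LOOP):
            opp = _opposite_interval(pt, elem)
            if opp is None:
                continue
            a, b = opp
            # green box on the strand opposite the bulge, labeled with its length
            box_w = max((b - a + 1), 1) * style.nt_width
            box_x = lay.x(a) if b >= a else lay.x(a) - style.nt_width / 2
            box = _el(
                g, "rect", x=f"{box_x:.1f}", y=f"{y_ds + 4:.1f}",
                width=f"{box_w:.1f}", height="10", fill=style.color("bulge_box"),
                **{"class": "bulge-box", "data-bulge-len": len(elem),
                   "data-opposite-of": elem.start},
            )
            t = _el(
                g, "text", x=f"{box_x + box_w / 2:.1f}", y=f"{y_ds + 12:.1f}",
                fill="#ffffff", **{"text-anchor": "middle", "font-size": "8",
                "class": "bulge-len"},
            )
            t.text = str(len(elem))
    if highlight_pair is not None:
        partner = pt.partner(highlight_pair)
        if partner == 0:
            warnings.warn(
                f"position {highlight_pair} of {stemloop.id} is unpaired; "
                "no pairing connector drawn"
            )
        else:
            x0, x1 = lay.xc(highlight_pair), lay.xc(partner)
            _el(
                g, "path",
                d=f"M {x0:.1f} {y_ds:.1f} Q {(x0 + x1) / 2:.1f} {y_ds - 14:.1f} {x1:.1f} {y_ds:.1f}",
                stroke=style.color("ss"), fill="none", **{"stroke-width": "1.5",
                "class": "pair-highlight", "data-pos": highlight_pair,
                "data-partner": partner},
            )
    return h
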