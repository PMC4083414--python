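"""Render the seven-track linear display for a stem-loop with reads.

Simulates two libraries over one hairpin, maps them, and writes an SVG with
the mismatch-frequency stripe, coverage histogram, genomic-environment
boxes, reference sequence, per-library read-group bars (count-labeled, with
colored mismatch segments), spelled-out read sequences and the structure
line (blue duplex runs, magenta single-stranded runs, green bulge-length
boxes, grey 5P/3P shading). Position 3's base pair is highlighted with a
magenta connector, as a click would in an interactive browser.
"""

from miredit import (
    Interval,
    PlantedEvent,
    build_profile,
    group_reads,
    make_stemloop,
    map_all,
    render,
    save_svg,
    simulate_library,
)

hairpin = make_stemloop(stem_len=25, loop_len=6, bulges=[("5p", 16, 2)], seed=4,
                        id="display-mir")
hairpin.genomic_segments = (
    Interval("exon", 1, 10),
    Interval("intron", 11, len(hairpin) - 10),
    Interval("exon", len(hairpin) - 9, len(hairpin)),
)
site = 9
ref_base = hairpin.sequence[site - 1]
alt = {"A": "G", "C": "T", "G": "T", "T": "C"}[ref_base]

profiles, groups = {}, {}
for i, name in enumerate(["ovary-like", "ago1-ip-like"]):
    lib, _ = simulate_library(
        hairpin, depth=80,
        planted_events=[PlantedEvent(hairpin.id, site, ref_base, alt, 0.4)] if i else [],
        seed=40 + i, name=name,
    )
    hits = map_all(lib, [hairpin], max_mm=1)
    profiles[name] = build_profile(hits, hairpin)
    groups[name] = group_reads(hits)

svg = render(hairpin, profiles, groups, highlight_pair=3,
             selected_library="ago1-ip-like")
save_svg(svg, "display-mir.svg")
n_groups = sum(len(g) for g in groups.values())
print(f"rendered {n_groups} read groups across {len(groups)} libraries -> display-mir.svg")
print("open the SVG in a browser; bars are labeled with collapsed read counts")
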