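"""Position profiles, read grouping, level arithmetic and candidate calling."""

import random

import pytest

from miredit import (
    AlignmentHit,
    Mismatch,
    RawRead,
    StemLoop,
    build_profile,
    call_candidates,
    combine_profiles,
    editing_level,
    group_reads,
    map_all,
    multi_library_consistency,
    read_candidates_tsv,
    write_candidates_tsv,
)
from miredit.calling import ProfileIntegrityError, write_profile_tsv


def _sl(seq, id="ref"):
    return StemLoop(id=id, sequence=seq, dotbracket="." * len(seq))


def _hit(ref_id, start, seq, count=1, mms=(), read_id="r"):
    return AlignmentHit(
        read_id=read_id, ref_id=ref_id, start=start, sequence=seq,
        mismatches=tuple(Mismatch(*m) for m in mms), count=count,
    )


class TestEditingLevel:
    # published candidate-table rows whose printed level agrees with
    # round-half-up of 100*mismatch/total (the 12.5 -> 13 row pins half-up)
    @pytest.mark.parametrize(
        "mismatch,total,level",
        [
            (3192, 32796, 10),
            (11, 101, 11),
            (880, 7625, 12),
            (203, 1751, 12),
            (6, 48, 13),
            (15, 116, 13),
            (4, 29, 14),
            (15, 95, 16),
            (2888, 17496, 17),
            (1582, 8795, 18),
            (1498, 6012, 25),
            (158, 527, 30),
            (42, 80, 53),
            (387, 599, 65),
        ],
    )
    def test_published_consistent_rows(self, mismatch, total, level):
        assert editing_level(mismatch, total) == level

    def test_zero_mismatches(self):
        assert editing_level(0, 20) == 0

    def test_all_mismatched(self):
        assert editing_level(20, 20) == 100

    def test_undefined_for_zero_total(self):
        with pytest.raises(ValueError):
            editing_level(0, 0)

    def test_bounds_enforced(self):
        with pytest.raises(ValueError):
            editing_level(5, 4)

    def test_half_up_in_exact_arithmetic(self):
        # denominators where floating 100*m/t sits exactly on .5
        assert editing_level(1, 8) == 13  # 12.5
        assert editing_level(3, 8) == 38  # 37.5
        assert editing_level(1, 200) == 1  # 0.5 rounds up


class TestBuildProfile:
    def test_no_hits_gives_zero_profile(self):
        prof = build_profile([], _sl("ACGTACGT"))
        assert prof.coverage[1:].sum() == 0 and prof.subs == {}

    def test_single_group_counts_weighted(self):
        ref = _sl("AAACCCGGGTTT")
        prof = build_profile(
            [_hit("ref", 4, "CCCGAG", count=42, mms=[(8, "G", "A")])], ref
        )
        assert int(prof.coverage[4]) == 42 and int(prof.coverage[9]) == 42
        assert int(prof.coverage[3]) == 0 and int(prof.coverage[10]) == 0
        assert prof.subs[8] == {("G", "A"): 42}
        assert prof.mismatch_count(8) == 42

    def test_out_of_bounds_hit_rejected(self):
        with pytest.raises(ProfileIntegrityError):
            build_profile([_hit("ref", 10, "ACGTACGT")], _sl("ACGTACGTACGT"))

    def test_wrong_reference_rejected(self):
        with pytest.raises(ProfileIntegrityError):
            build_profile([_hit("other", 1, "ACGT")], _sl("ACGTACGT"))

    def test_matches_brute_force_recount(self):
        rng = random.Random(7)
        ref = _sl("".join(rng.choice("ACGT") for _ in range(60)))
        reads = []
        for i in range(40):
            off = rng.randrange(40)
            frag = list(ref.sequence[off : off + 18])
            if rng.random() < 0.6:
                k = rng.randrange(18)
                frag[k] = rng.choice([b for b in "ACGT" if b != frag[k]])
            reads.append(RawRead(f"r{i}", "".join(frag), count=rng.randint(1, 9)))
        hits = [h for h in map_all(reads, [ref]) if h.ref_id == ref.id]
        prof = build_profile(hits, ref)
        for pos in range(1, 61):
            cov = sum(h.count for h in hits if h.start <= pos <= h.end)
            mm = sum(h.count for h in hits for m in h.mismatches if m.ref_pos == pos)
            assert int(prof.coverage[pos]) == cov
            assert prof.mismatch_count(pos) == mm

    def test_mismatch_freq_denominators(self):
        ref = _sl("AAACCCGGGTTT")
        prof = build_profile(
            [_hit("ref", 1, "AAACCC", count=10, mms=[(3, "A", "G")], read_id="a"),
             _hit("ref", 7, "GGGTTT", count=30, read_id="b")],
            ref,
        )
        assert prof.mismatch_freq(3) == 100.0
        assert prof.mismatch_freq(3, denominator="library", library_total=40) == 25.0

    def test_combine_profiles_sums(self):
        ref = _sl("AAACCCGGGTTT")
        p1 = build_profile([_hit("ref", 1, "AAAC", count=5)], ref)
        p2 = build_profile([_hit("ref", 1, "AAAC", count=7, mms=[(2, "A", "T")])], ref)
        comb = combine_profiles([p1, p2])
        assert int(comb.coverage[1]) == 12 and comb.subs[2] == {("A", "T"): 7}


class TestGroupReads:
    def test_identity_on_single_hit(self):
        (g,) = group_reads([_hit("ref", 3, "ACGTACGTACGTACGT", count=4)])
        assert (g.start, g.end, g.count) == (3, 18, 4)

    def test_identical_reads_merge(self):
        hits = [
            _hit("ref", 3, "ACGTACGT", count=2, read_id="a"),
            _hit("ref", 3, "ACGTACGT", count=5, read_id="b"),
            _hit("ref", 4, "ACGTACGT", count=1, read_id="c"),
        ]
        groups = group_reads(hits)
        assert [(g.start, g.count) for g in groups] == [(3, 7), (4, 1)]

    def test_counts_conserved_against_recount(self):
        rng = random.Random(11)
        seqs = ["ACGTACGTACGTACGT", "TTGGCCAATTGGCCAA", "GATTACAGATTACAGA"]
        hits = [
            _hit("ref", rng.randint(1, 3), rng.choice(seqs),
                 count=rng.randint(1, 20), read_id=f"r{i}")
            for i in range(200)
        ]
        groups = group_reads(hits)
        assert sum(g.count for g in groups) == sum(h.count for h in hits)
        recount: dict = {}
        for h in hits:
            recount[(h.sequence, h.start)] = recount.get((h.sequence, h.start), 0) + h.count
        assert {(g.sequence, g.start): g.count for g in groups} == recount

    def test_mixed_references_rejected(self):
        with pytest.raises(ValueError):
            group_reads([_hit("a", 1, "ACGT"), _hit("b", 1, "ACGT")])


def _profile_with_site(ref_id, coverage, mismatch, pos=5, alt="G", length=30):
    seq = "A" * length
    ref = StemLoop(id=ref_id, sequence=seq, dotbracket="." * length)
    hits = []
    if mismatch:
        hits.append(_hit(ref_id, 1, "A" * length, count=mismatch,
                         mms=[(pos, "A", alt)], read_id="edited"))
    if coverage - mismatch > 0:
        hits.append(_hit(ref_id, 1, "A" * length, count=coverage - mismatch, read_id="clean"))
    return build_profile(hits, ref)


class TestCallCandidates:
    def test_both_thresholds_strictly_exceeded(self):
        prof = _profile_with_site("mir", coverage=21, mismatch=3)
        (cand,) = call_candidates({"lib": [prof]})
        assert (cand.total_reads, cand.mismatch_reads, cand.level) == (21, 3, 14)
        assert cand.type == "A>G"

    def test_coverage_20_never_emitted(self):
        prof = _profile_with_site("mir", coverage=20, mismatch=19)
        assert call_candidates({"lib": [prof]}) == []

    def test_level_exactly_10_not_emitted(self):
        prof = _profile_with_site("mir", coverage=100, mismatch=10)
        assert call_candidates({"lib": [prof]}) == []

    def test_non_strict_boundaries(self):
        prof = _profile_with_site("mir", coverage=20, mismatch=2)  # level 10
        assert call_candidates({"lib": [prof]}, strict=False) != []

    def test_threshold_monotonicity(self):
        profs = {
            "lib": [
                _profile_with_site("m1", coverage=25, mismatch=4),
                _profile_with_site("m2", coverage=120, mismatch=30),
            ]
        }
        base = {(c.mirna, c.position) for c in call_candidates(profs)}
        looser = {
            (c.mirna, c.position)
            for c in call_candidates(profs, min_total=5, min_level_pct=2)
        }
        assert base <= looser

    def test_dominant_alt_and_tie_flag(self):
        ref = _sl("A" * 20, "mir")
        hits = [
            _hit("mir", 1, "A" * 20, count=15, mms=[(5, "A", "T")], read_id="t"),
            _hit("mir", 1, "A" * 20, count=15, mms=[(5, "A", "C")], read_id="c"),
            _hit("mir", 1, "A" * 20, count=70, read_id="clean"),
        ]
        prof = build_profile(hits, ref)
        (cand,) = call_candidates({"lib": [prof]})
        assert cand.type == "A>C" and cand.dominant_tie  # lexicographic tie-break
        assert cand.mismatch_reads == 15

    def test_sorted_ascending_by_level(self):
        profs = {
            "lib": [
                _profile_with_site("m-zz", coverage=100, mismatch=50),
                _profile_with_site("m-aa", coverage=100, mismatch=12),
            ]
        }
        cands = call_candidates(profs)
        assert [c.level for c in cands] == sorted(c.level for c in cands)

    def test_candidate_tsv_roundtrip(self, tmp_path):
        prof = _profile_with_site("mir", coverage=48, mismatch=6)
        cands = call_candidates({"GSM-like": [prof]})
        p = tmp_path / "candidates.tsv"
        write_candidates_tsv(cands, p)
        header = p.read_text().splitlines()[0]
        assert header.split("\t") == [
            "microRNA", "position", "reads (mismatch/total)", "Level (%)", "type", "library",
        ]
        back = read_candidates_tsv(p)
        assert [(c.mirna, c.position, c.mismatch_reads, c.total_reads, c.level, c.type, c.library)
                for c in back] == [
            (c.mirna, c.position, c.mismatch_reads, c.total_reads, c.level, c.type, c.library)
            for c in cands
        ]

    def test_profile_tsv_columns(self, tmp_path):
        prof = _profile_with_site("mir", coverage=30, mismatch=5)
        p = tmp_path / "profile.tsv"
        write_profile_tsv(prof, p)
        header = p.read_text().splitlines()[0].split("\t")
        assert header == ["ref", "pos", "ref_base", "coverage", "A", "C", "G", "T", "N"]


class TestMultiLibraryConsistency:
    def test_single_library_support_one(self):
        prof = _profile_with_site("mir", coverage=30, mismatch=6)
        cands = call_candidates({"only": [prof]})
        table = multi_library_consistency(cands)
        assert list(table["n_libraries"]) == [1]
        assert not table["high_confidence"].any()

    def test_same_site_in_two_libraries(self):
        cands = call_candidates(
            {
                "libA": [_profile_with_site("mir", coverage=30, mismatch=6)],
                "libB": [_profile_with_site("mir", coverage=50, mismatch=20)],
            }
        )
        table = multi_library_consistency(cands)
        assert list(table["n_libraries"]) == [2]
        assert table["high_confidence"].all()

    def test_six_library_site(self):
        # a strongly recurrent site: the same position called in six libraries
        profs = {
            f"lib{i}": [_profile_with_site("mir-recurrent", coverage=100, mismatch=25, pos=29)]
            for i in range(6)
        }
        table = multi_library_consistency(call_candidates(profs))
        assert list(table["n_libraries"]) == [6]
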