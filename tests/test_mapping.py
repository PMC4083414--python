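"""All-hits bounded-mismatch alignment vs the exhaustive offset-scan oracle,
the cross-genome uniqueness filter, and SAM round-tripping."""

import random

import pytest
from hypothesis import given, settings, strategies as st

from miredit import (
    AlignmentHit,
    Library,
    Mismatch,
    RawRead,
    StemLoop,
    cross_genome_filter,
    map_all,
    read_sam,
    revcomp,
    scan_sequence,
    write_sam,
)


def oracle_scan(read: str, ref: str, max_mm: int):
    """Exhaustive offset scan: every placement, every offset, no shortcuts."""
    out = []
    for off in range(len(ref) - len(read) + 1):
        mms = [
            (off + k + 1, ref[off + k], read[k])
            for k in range(len(read))
            if ref[off + k] != read[k]
        ]
        if len(mms) <= max_mm:
            out.append((off + 1, tuple(mms)))
    return out


def _as_tuples(placements):
    return [
        (s, tuple(m if isinstance(m, tuple) else (m.ref_pos, m.ref_base, m.read_base)
                  for m in mms))
        for s, mms in placements
    ]


def _sl(seq, id="ref"):
    return StemLoop(id=id, sequence=seq, dotbracket="." * len(seq))


def _rand_seq(rng, n):
    return "".join(rng.choice("ACGT") for _ in range(n))


class TestScanAndMapAll:
    def test_exact_substring_single_hit(self):
        ref = _sl("AAACGTACGTACGTACGTAAA")
        hits = map_all([RawRead("r", "ACGTACGTACGTACGT")], [ref])
        exact = [h for h in hits if h.n_mismatches == 0]
        assert [(h.start, h.end) for h in exact] == [(3, 18)]

    def test_all_hits_across_two_references(self):
        seq = "ACGTACGTACGTACGTT"
        refs = [_sl("TTT" + seq + "GGG", "a"), _sl("CC" + seq + "AA", "b")]
        hits = map_all([RawRead("r", seq)], refs)
        assert {(h.ref_id, h.start) for h in hits if h.n_mismatches == 0} == {("a", 4), ("b", 3)}
        assert all(h.multi_ref for h in hits)

    def test_read_longer_than_reference_yields_no_hits(self):
        assert map_all([RawRead("r", "A" * 50)], [_sl("A" * 20)]) == []

    def test_mismatch_descriptor(self):
        ref = _sl("AAAACCCCGGGGTTTTAAAA")
        read = "CCCCGAGGTTTT"  # G>A at read offset 5 -> ref pos 10
        (hit,) = map_all([RawRead("r", read)], [ref])
        assert hit.start == 5
        assert hit.mismatches == (Mismatch(ref_pos=10, ref_base="G", read_base="A"),)

    @pytest.mark.parametrize("max_mm", [0, 1])
    def test_matches_exhaustive_oracle(self, max_mm):
        rng = random.Random(42)
        refs = [_rand_seq(rng, 90) for _ in range(3)]
        for _ in range(50):
            read = _rand_seq(rng, 18)
            if rng.random() < 0.5:  # half the reads are plants with 0-1 errors
                ref = rng.choice(refs)
                off = rng.randrange(len(ref) - 18)
                bases = list(ref[off : off + 18])
                if rng.random() < 0.7:
                    k = rng.randrange(18)
                    bases[k] = rng.choice([b for b in "ACGT" if b != bases[k]])
                read = "".join(bases)
            for ref in refs:
                assert _as_tuples(scan_sequence(read, ref, max_mm)) == _as_tuples(
                    oracle_scan(read, ref, max_mm)
                )

    @given(st.integers(0, 10_000))
    @settings(max_examples=150, deadline=None, derandomize=True)
    def test_oracle_equivalence_property(self, seed):
        rng = random.Random(seed)
        ref = _rand_seq(rng, rng.randint(20, 200))
        read = _rand_seq(rng, rng.randint(16, 30))
        for max_mm in (0, 1):
            assert _as_tuples(scan_sequence(read, ref, max_mm)) == _as_tuples(
                oracle_scan(read, ref, max_mm)
            )

    def test_hit_set_invariant_under_read_order(self):
        rng = random.Random(1)
        refs = [_sl(_rand_seq(rng, 80), f"ref{i}") for i in range(2)]
        reads = [RawRead(f"r{i}", _rand_seq(rng, 17)) for i in range(30)]
        reads += [RawRead("p", refs[0].sequence[10:28])]
        shuffled = list(reads)
        rng.shuffle(shuffled)
        key = lambda h: (h.read_id, h.ref_id, h.start, h.mismatches)
        assert sorted(map_all(reads, refs), key=key) == sorted(map_all(shuffled, refs), key=key)


class TestCrossGenomeFilter:
    def _setup(self):
        rng = random.Random(3)
        sl_seq = _rand_seq(rng, 80)
        sl = _sl(sl_seq, "mir")
        genome_seq = _rand_seq(rng, 150) + sl_seq + _rand_seq(rng, 150)
        loci = {"mir": ("chr1", 151, 230)}
        return rng, sl, genome_seq, loci

    def test_zero_mismatch_hits_always_pass(self):
        rng, sl, genome_seq, loci = self._setup()
        read = sl.sequence[10:30]
        hits = map_all([RawRead("r", read)], [sl])
        # plant a perfect distant copy: 0-mm hits must still pass
        genome = {"chr1": genome_seq + read + "ACGT"}
        assert cross_genome_filter(hits, genome, loci) == hits

    def test_decoy_removes_mismatched_read(self):
        rng, sl, genome_seq, loci = self._setup()
        bases = list(sl.sequence[10:30])
        bases[5] = {"A": "G", "C": "T", "G": "A", "T": "C"}[bases[5]]
        edited = "".join(bases)
        hits = map_all([RawRead("r", edited)], [sl])
        assert hits and hits[0].n_mismatches == 1
        no_decoy = {"chr1": genome_seq}
        with_decoy = {"chr1": genome_seq + "TTTT" + edited}
        assert cross_genome_filter(hits, no_decoy, loci) == hits
        assert cross_genome_filter(hits, with_decoy, loci) == []

    def test_reverse_strand_decoy_also_disqualifies(self):
        rng, sl, genome_seq, loci = self._setup()
        bases = list(sl.sequence[20:40])
        bases[3] = {"A": "G", "C": "T", "G": "A", "T": "C"}[bases[3]]
        edited = "".join(bases)
        hits = map_all([RawRead("r", edited)], [sl])
        genome = {"chr1": genome_seq + "AAAA" + revcomp(edited)}
        assert cross_genome_filter(hits, genome, loci) == []

    def test_missing_locus_is_configuration_error(self):
        rng, sl, genome_seq, loci = self._setup()
        bases = list(sl.sequence[10:30])
        bases[2] = {"A": "G", "C": "T", "G": "A", "T": "C"}[bases[2]]
        hits = map_all([RawRead("r", "".join(bases))], [sl])
        with pytest.raises(ValueError, match="locus"):
            cross_genome_filter(hits, {"chr1": genome_seq}, {})

    def test_matches_brute_force_genome_scan(self):
        rng = random.Random(9)
        sl = _sl(_rand_seq(rng, 70), "mir")
        spacer = _rand_seq(rng, 100)
        # embed the stem-loop plus assorted decoys
        decoys = []
        for _ in range(4):
            off = rng.randrange(50)
            frag = list(sl.sequence[off : off + 20])
            k = rng.randrange(20)
            frag[k] = rng.choice([b for b in "ACGT" if b != frag[k]])
            decoys.append("".join(frag))
        genome = {"chr1": spacer + sl.sequence + spacer + "NN".join(decoys)}
        loci = {"mir": ("chr1", 101, 170)}
        reads = []
        for i in range(30):
            off = rng.randrange(50)
            frag = list(sl.sequence[off : off + 20])
            k = rng.randrange(20)
            frag[k] = rng.choice([b for b in "ACGT" if b != frag[k]])
            reads.append(RawRead(f"r{i}", "".join(frag)))
        hits = map_all(reads, [sl])
        kept = cross_genome_filter(hits, genome, loci)
        for h in hits:
            expected_kept = True
            if h.n_mismatches == 1:
                for query in (h.sequence, revcomp(h.sequence)):
                    for start, _ in oracle_scan(query, genome["chr1"], 1):
                        end = start + len(query) - 1
                        if not (start <= 170 and end >= 101):
                            expected_kept = False
            assert (h in kept) == expected_kept, h.read_id

    def test_output_is_subset(self):
        rng, sl, genome_seq, loci = self._setup()
        reads = [RawRead(f"r{i}", sl.sequence[i : i + 20]) for i in range(0, 40, 5)]
        hits = map_all(reads, [sl])
        kept = cross_genome_filter(hits, {"chr1": genome_seq}, loci)
        assert set(kept) <= set(hits)


class TestSamRoundTrip:
    def test_hits_survive_sam_roundtrip(self, tmp_path):
        rng = random.Random(5)
        refs = [_sl(_rand_seq(rng, 80), f"mir{i}") for i in range(2)]
        reads = []
        for i in range(20):
            ref = rng.choice(refs)
            off = rng.randrange(60)
            frag = list(ref.sequence[off : off + 18])
            if rng.random() < 0.5:
                k = rng.randrange(18)
                frag[k] = rng.choice([b for b in "ACGT" if b != frag[k]])
            reads.append(RawRead(f"r{i}", "".join(frag), count=rng.randint(1, 50)))
        hits = map_all(reads, refs)
        p = tmp_path / "hits.sam"
        write_sam(hits, refs, p)
        back = read_sam(p)
        strip = lambda h: (h.read_id, h.ref_id, h.start, h.sequence, h.mismatches, h.count)
        assert sorted(map(strip, back)) == sorted(map(strip, hits))
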