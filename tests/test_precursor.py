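import random

import pytest

from srnapipe.precursor import (
    Contig,
    ContigHit,
    call_duplex,
    find_duplexes,
    fold_hairpin,
    map_candidates_to_contigs,
    nussinov_pairs,
    screen_precursor_contigs,
)
from srnapipe.records import revcomp

from conftest import random_sequence


def enumerate_max_pairs(seq: str, min_loop: int = 3) -> int:
    """Independent oracle: maximum nested pairing by explicit enumeration.

    Recursively decides, for the first position, between leaving it unpaired
    and pairing it with every admissible partner; no DP table is shared with
    the implementation under test.
    """
    pairs = {("A", "T"), ("T", "A"), ("G", "C"), ("C", "G"), ("G", "T"), ("T", "G")}

    def best(i, j):
        if j - i <= min_loop:
            return 0
        options = [best(i + 1, j)]
        for k in range(i + min_loop + 1, j + 1):
            if (seq[i], seq[k]) in pairs:
                options.append(1 + best(i + 1, k - 1) + best(k + 1, j))
        return max(options)

    return best(0, len(seq) - 1)


class TestFolding:
    def test_simple_stem_loop(self):
        pairs = nussinov_pairs("GGGAAATCCC")
        assert len(pairs) == 3
        partner = {}
        for i, j in pairs:
            assert j - i > 3
            partner[i] = j
        # strictly nested
        sp = sorted(pairs)
        for (i1, j1), (i2, j2) in zip(sp, sp[1:]):
            assert i1 < i2 and (j2 < j1 or i2 > j1)

    def test_no_complementarity_no_pairs(self):
        fold = fold_hairpin("A" * 50)
        assert fold.n_pairs == 0
        assert fold.arm5 is None and fold.arm3 is None

    def test_perfect_inverted_repeat(self):
        # a 22-bp perfect stem is recovered in full; co-optimal pairings may
        # recruit loop bases, so arm pairedness is near (not exactly) 1
        rng = random.Random(1)
        arm = random_sequence(rng, 22)
        seq = arm + "TTCAATCG" + revcomp(arm)
        fold = fold_hairpin(seq)
        assert fold.n_pairs >= 22
        assert fold.pairedness5 >= 0.85
        assert fold.pairedness3 >= 0.85
        assert fold.loop is not None

    def test_length_bounds(self):
        with pytest.raises(ValueError):
            fold_hairpin("ACGT")
        with pytest.raises(ValueError):
            fold_hairpin("A" * 300)

    @pytest.mark.parametrize("trial", range(25))
    def test_pair_count_matches_enumeration(self, trial):
        rng = random.Random(trial)
        seq = random_sequence(rng, rng.randint(8, 16))
        assert len(nussinov_pairs(seq)) == enumerate_max_pairs(seq)

    def test_deterministic_traceback(self):
        rng = random.Random(9)
        seq = random_sequence(rng, 60)
        assert nussinov_pairs(seq) == nussinov_pairs(seq)


class TestMapping:
    def test_forward_reverse_and_absent(self):
        rng = random.Random(3)
        insert = random_sequence(rng, 22)
        contig = Contig("c1", random_sequence(rng, 30) + insert + random_sequence(rng, 30))
        hits = map_candidates_to_contigs([("m", insert)], [contig])
        assert len(hits) == 1
        h = hits[0]
        assert (h.start, h.end, h.strand) == (30, 52, "+")
        rc_hits = map_candidates_to_contigs([("m", revcomp(insert))], [contig])
        assert len(rc_hits) == 1
        assert rc_hits[0].strand == "-"
        assert (rc_hits[0].start, rc_hits[0].end) == (30, 52)
        assert map_candidates_to_contigs([("m", random_sequence(rng, 22))], [contig]) == []

    def test_strand_consistency_under_revcomp(self):
        rng = random.Random(4)
        insert = random_sequence(rng, 22)
        seq = random_sequence(rng, 25) + insert + random_sequence(rng, 25)
        fwd = map_candidates_to_contigs([("m", insert)], [Contig("c", seq)])
        rev = map_candidates_to_contigs([("m", insert)], [Contig("c", revcomp(seq))])
        assert len(fwd) == len(rev) == 1
        assert fwd[0].strand == "+" and rev[0].strand == "-"
        assert rev[0].start == len(seq) - fwd[0].end
        assert rev[0].end == len(seq) - fwd[0].start

    def test_short_contig_skipped(self, caplog):
        hits = map_candidates_to_contigs([("m", "ACGTACGTACGTACGTACGTAC")], [Contig("tiny", "ACGT" * 5)])
        assert hits == []


class TestScreen:
    def hit(self, cand, start, end):
        return ContigHit(cand, "c1", start, end, "+", 1.0)

    def test_two_distinct_regions_pass(self):
        passing = screen_precursor_contigs([self.hit("a", 5, 27), self.hit("b", 40, 62)])
        assert "c1" in passing

    def test_overlap_by_one_fails(self):
        passing = screen_precursor_contigs([self.hit("a", 5, 27), self.hit("b", 26, 48)])
        assert passing == {}

    def test_same_candidate_twice_fails(self):
        passing = screen_precursor_contigs([self.hit("a", 5, 27), self.hit("a", 40, 62)])
        assert passing == {}


class TestDuplex:
    def planted(self, seed=0):
        rng = random.Random(seed)
        arm = random_sequence(rng, 22)
        seq = "ACGTG" + arm + "ATTCGAAT" + revcomp(arm) + "CTGAC"
        fold = fold_hairpin(seq)
        m = (5, 27)
        s = (35, 57)
        return fold, m, s

    def test_opposite_arms_duplex(self):
        fold, m, s = self.planted()
        hits = [ContigHit("m", "c", *m, "+", 1.0), ContigHit("s", "c", *s, "+", 1.0)]
        call = call_duplex(fold, hits)
        assert call.verdict == "duplex"
        assert call.n_pairs_between >= 0.6 * 22

    def test_same_arm_rejected(self):
        fold, m, s = self.planted()
        hits = [ContigHit("m", "c", *m, "+", 1.0), ContigHit("x", "c", m[0], m[0] + 10, "+", 1.0)]
        call = call_duplex(fold, hits)
        assert call.verdict == "rejected"
        assert call.reason in ("same arm", "no hit in arm")

    def test_insufficient_pairing_rejected(self):
        # hand-built structure: hits sit on opposite arms but only 6/22
        # positions of each hit pair with the other (~27% < 60%)
        from srnapipe.precursor import HairpinFold

        rng = random.Random(5)
        seq = random_sequence(rng, 62)
        pairs = {(5 + i, 56 - i) for i in range(6)}
        fold = HairpinFold(
            sequence=seq, pairs=pairs,
            arm5=(5, 27), arm3=(35, 57), loop=(27, 35),
            pairedness5=6 / 22, pairedness3=6 / 22,
        )
        hits = [
            ContigHit("m", "c", 5, 27, "+", 1.0),
            ContigHit("s", "c", 35, 57, "+", 1.0),
        ]
        call = call_duplex(fold, hits)
        assert call.verdict == "rejected"
        assert call.reason == "insufficient pairing"

    def test_planted_contig_recovered_end_to_end(self, tiny_dataset):
        ds = tiny_dataset
        cand = [(hp.id + "_m", hp.mature_seq) for hp in ds.planted_novel()] + [
            (hp.id + "_s", hp.star_seq) for hp in ds.planted_novel()
        ]
        real = [c for c in ds.contigs if c.source_tags]
        hits = map_candidates_to_contigs(cand, real)
        calls = find_duplexes(real, hits)
        assert len(calls) == len(real)
        assert all(c.verdict == "duplex" for c in calls.values())

    def test_no_duplex_on_dinucleotide_shuffled_decoys(self, tiny_dataset):
        ds = tiny_dataset
        cand = [(hp.id + "_m", hp.mature_seq) for hp in ds.planted_novel()] + [
            (hp.id + "_s", hp.star_seq) for hp in ds.planted_novel()
        ]
        decoys = [c for c in ds.contigs if not c.source_tags]
        assert decoys
        hits = map_candidates_to_contigs(cand, decoys)
        calls = find_duplexes(decoys, hits)
        assert all(c.verdict != "duplex" for c in calls.values())
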