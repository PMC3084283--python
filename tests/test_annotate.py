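import math
import random

import pytest

from srnapipe.annotate import (
    annotate_contaminants,
    annotate_reads,
    build_pssm,
    mask_mature,
    scan_profiles,
    scan_star,
)
from srnapipe.records import ReadRecord, ReferenceSet, revcomp

from conftest import random_sequence


def mk_read(seq, rid="r", n=10):
    return ReadRecord(rid, seq, {"lib": n})


class TestBuildPssm:
    def test_single_sequence_consensus(self):
        prof = build_pssm("fam", ["TGAGGTAGTAGGTTGTATAGTT"])
        assert prof.consensus == "TGAGGTAGTAGGTTGTATAGTT"
        assert len(prof.matrix) == 22

    def test_column_score_formula(self):
        prof = build_pssm("fam", ["AG", "AG", "CG"])
        # column 0: {A:2, C:1}; score(A) = log2((2.25/4)/0.25) = log2(2.25)
        assert prof.matrix[0]["A"] == pytest.approx(math.log2(2.25))
        assert prof.matrix[0]["C"] == pytest.approx(math.log2(1.25))
        assert prof.matrix[0]["G"] == pytest.approx(math.log2(0.25))

    def test_empty_and_ragged_errors(self):
        with pytest.raises(ValueError):
            build_pssm("fam", [])
        with pytest.raises(ValueError):
            build_pssm("fam", ["ACGT", "ACG"])

    def test_rna_and_gaps_accepted(self):
        prof = build_pssm("fam", ["UGAGG", "TG-GG"])
        assert prof.consensus.startswith("TG")


class TestScanProfiles:
    def setup_method(self):
        rng = random.Random(4)
        self.families = {f"fam{i}": random_sequence(rng, 22) for i in range(5)}
        self.profiles = [build_pssm(f, [s]) for f, s in self.families.items()]

    def test_exact_read_is_assigned(self):
        fam, cons = next(iter(self.families.items()))
        labels = scan_profiles([mk_read(cons)], self.profiles)
        assert labels[0].category == f"known:{fam}"
        assert labels[0].identity == 1.0

    def test_three_mismatches_unassigned(self):
        fam, cons = next(iter(self.families.items()))
        mutated = "".join(
            ("A" if c != "A" else "C") if i in (3, 10, 17) else c
            for i, c in enumerate(cons)
        )
        labels = scan_profiles([mk_read(mutated)], self.profiles)
        assert labels[0].category == "unassigned"  # 19/22 < 0.9

    def test_shifted_read_with_untemplated_tail_assigned(self):
        fam, cons = next(iter(self.families.items()))
        read = cons[2:] + "A"  # shifted by 2 with one untemplated 3' base
        labels = scan_profiles([mk_read(read)], self.profiles)
        assert labels[0].category == f"known:{fam}"

    def test_exact_scan_equals_string_comparison(self):
        """At min_identity 1.0 a hit means literal equality over the overlap."""
        rng = random.Random(8)
        reads = [mk_read(random_sequence(rng, 22), rid=f"r{i}") for i in range(30)]
        fam, cons = next(iter(self.families.items()))
        reads.append(mk_read(cons, rid="hit"))
        labels = scan_profiles(reads, self.profiles, min_identity=1.0)
        for rec, lab in zip(reads, labels):
            expected = any(
                all(
                    rec.sequence[i] == c.consensus[i + off]
                    for i in range(max(0, -off), min(len(rec.sequence), len(c.consensus) - off))
                )
                and min(len(rec.sequence), len(c.consensus) - off) - max(0, -off) > 0
                for c in self.profiles
                for off in range(-3, 4)
            )
            assert (lab.category != "unassigned") == expected


class TestMaskAndStar:
    def test_mask_replaces_interval(self):
        mh = mask_mature("h1", "A" * 80, (10, 32))
        assert mh.sequence[10:32] == "N" * 22
        assert len(mh.sequence) == 80
        assert mh.sequence[:10] == "A" * 10

    def test_mask_idempotent_and_degenerate(self, caplog):
        mh = mask_mature("h1", "ACGT" * 20, (10, 32))
        again = mask_mature("h1", mh.sequence, (10, 32))
        assert again.sequence == mh.sequence
        full = mask_mature("h2", "ACGT" * 10, (0, 40))
        assert set(full.sequence) == {"N"}

    def test_mask_errors(self):
        with pytest.raises(ValueError):
            mask_mature("h1", "ACGT", (2, 10))

    def test_star_found_on_opposite_arm(self):
        rng = random.Random(2)
        mature = random_sequence(rng, 22)
        star = revcomp(mature)
        hairpin = "ACGTA" + mature + "GTTCAAGT" + star + "TCAGG"
        lo = 5
        mh = mask_mature("mir-x", hairpin, (lo, lo + 22))
        labels = scan_star([mk_read(star)], [mh])
        assert labels[0].category == "star:mir-x"

    def test_read_inside_mask_unassigned(self):
        rng = random.Random(2)
        mature = random_sequence(rng, 22)
        hairpin = "ACGTA" + mature + "GTTCAAGT" + revcomp(mature) + "TCAGG"
        mh = mask_mature("mir-x", hairpin, (5, 27))
        labels = scan_star([mk_read(mature)], [mh])
        assert labels[0].category == "unassigned"

    def test_read_straddling_mask_unassigned(self):
        rng = random.Random(6)
        mature = random_sequence(rng, 22)
        star = revcomp(mature)
        hairpin = "ACGTA" + mature + "GTTCAAGT" + star + "TCAGG"
        mh = mask_mature("mir-x", hairpin, (5, 27))
        straddle = hairpin[16:38]  # half inside the mask
        labels = scan_star([mk_read(straddle)], [mh])
        assert labels[0].category == "unassigned"


class TestContaminants:
    def make_refs(self):
        rng = random.Random(5)
        self.genome = random_sequence(rng, 500)
        self.rrna = random_sequence(rng, 120)
        return {
            "rRNA": ReferenceSet("rRNA", [("r1", self.rrna)]),
            "endosymbiont": ReferenceSet("endosymbiont", [("g", self.genome)]),
        }

    def test_exact_substring_hits(self):
        refs = self.make_refs()
        frag = self.genome[100:122]
        labels = annotate_contaminants([mk_read(frag)], refs)
        assert labels[0].category == "endosymbiont"
        assert labels[0].identity == 1.0

    def test_precedence_order(self):
        refs = self.make_refs()
        shared = self.rrna[10:32]
        refs["endosymbiont"] = ReferenceSet("endosymbiont", [("g", self.genome + shared)])
        labels = annotate_contaminants([mk_read(shared)], refs)
        assert labels[0].category == "rRNA"

    def test_one_mismatch_misses_at_full_identity(self):
        refs = self.make_refs()
        frag = self.genome[100:122]
        mutated = frag[:10] + ("A" if frag[10] != "A" else "C") + frag[11:]
        labels = annotate_contaminants([mk_read(mutated)], refs)
        assert labels[0].category == "unassigned"

    def test_partial_coverage_hit(self):
        refs = self.make_refs()
        frag = self.genome[100:121] + "A"  # 21/22 exact = 95.45% coverage
        labels = annotate_contaminants([mk_read(frag)], refs)
        assert labels[0].category == "endosymbiont"
        assert labels[0].coverage >= 0.95


def test_every_read_gets_exactly_one_category():
    rng = random.Random(12)
    fam_seq = random_sequence(rng, 22)
    profiles_src = {"famA": [fam_seq]}
    genome = random_sequence(rng, 300)
    refs = {"endosymbiont": ReferenceSet("endosymbiont", [("g", genome)])}
    reads = [
        mk_read(fam_seq, "known_hit"),
        mk_read(genome[50:72], "cont_hit"),
        mk_read(random_sequence(rng, 22), "nohit"),
    ]
    from srnapipe.annotate import build_pssm

    labels = annotate_reads(reads, [build_pssm("famA", profiles_src["famA"])], [], refs)
    assert set(labels) == {"known_hit", "cont_hit", "nohit"}
    assert labels["known_hit"].category == "known:famA"
    assert labels["cont_hit"].category == "endosymbiont"
    assert labels["nohit"].category == "unassigned"
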