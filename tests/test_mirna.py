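"""Known-miRNA matching, hairpin folding and novel-locus evaluation."""

from __future__ import annotations

import pytest

from _oracles import interval_union, nussinov_max_pairs, rc
from srnaome import mirna
from srnaome.align import AlignmentHit
from srnaome.sio import ReadTag


def hit(seq, start, count=1, ref="g", strand="+"):
    return AlignmentHit(seq, ref, start, strand, 0, count)


def build_hairpin_genome(mature, arm=None, loop="GAACAGUUCUC".replace("U", "T"),
                         pad=60, rng=None):
    """Genome with one planted perfect-stem hairpin; returns (genome, hp_start)."""
    arm = arm if arm is not None else mature
    precursor = arm + loop + rc(arm)
    left = "".join(rng.choice(list("ACGT"), pad)) if rng is not None else "A" * pad
    right = "".join(rng.choice(list("ACGT"), pad)) if rng is not None else "C" * pad
    return {"g": left + precursor + right}, pad


class TestMatchKnown:
    REFS = [
        mirna.MatureReference("mdm-miR1a", "ACGTACGTACGTACGTACGTA", "miR1", "mdm"),
        mirna.MatureReference("mdm-miR1b", "ACGTACGTACGTACGTACGTA", "miR1", "mdm"),
        mirna.MatureReference("mdm-miR2", "TTTTACGTACGTACGTACGTA", "miR2", "mdm"),
    ]

    def test_exact_match_counts_to_entry_and_family(self):
        df = mirna.match_known([ReadTag("TTTTACGTACGTACGTACGTA", 7)], self.REFS)
        assert df.mirna_id.tolist() == ["mdm-miR2"]
        assert mirna.family_counts(df).iloc[0].tolist() == ["miR2", 7]

    def test_single_substitution_is_no_match(self):
        df = mirna.match_known([ReadTag("TTTTACGTACGTACGTACGTC", 7)], self.REFS)
        assert df.empty

    def test_tag_matching_several_entries_reported_for_each(self):
        df = mirna.match_known([ReadTag("ACGTACGTACGTACGTACGTA", 3)], self.REFS)
        assert sorted(df.mirna_id) == ["mdm-miR1a", "mdm-miR1b"]

    def test_totals_equal_dictionary_join_oracle(self, rng):
        refs = [
            mirna.MatureReference(f"mdm-miR{i}", "".join(rng.choice(list("ACGT"), 21)),
                                  f"miR{i}", "mdm")
            for i in range(50)
        ]
        tags = [ReadTag(refs[int(i)].seq, int(c))
                for i, c in zip(rng.integers(0, 50, 120), rng.integers(1, 90, 120))]
        tags = [ReadTag(s, sum(t.count for t in tags if t.seq == s))
                for s in {t.seq for t in tags}]
        tags += [ReadTag("".join(rng.choice(list("ACGT"), 21)), 5) for _ in range(80)]
        df = mirna.match_known(tags, refs)
        oracle = {}
        by_seq = {}
        for r in refs:
            by_seq.setdefault(r.seq, []).append(r.mirna_id)
        for t in tags:
            for mid in by_seq.get(t.seq, []):
                oracle[mid] = oracle.get(mid, 0) + t.count
        got = df.groupby("mirna_id")["count"].sum().to_dict()
        assert got == oracle

    def test_mirbase_header_parsing(self):
        r = mirna.MatureReference.from_header("mdm-miR166a MIMAT000 Malus", "ucgga")
        assert (r.family, r.species_tag, r.seq) == ("miR166", "mdm", "TCGGA")


class TestClusterLoci:
    def test_distant_hits_separate(self):
        cands = mirna.cluster_loci([hit("A" * 21, 0), hit("A" * 21, 521)], max_gap=100)
        assert [(c.start, c.end) for c in cands] == [(0, 21), (521, 542)]

    def test_overlapping_hits_merge_to_union(self):
        cands = mirna.cluster_loci([hit("A" * 21, 0), hit("A" * 21, 10)], max_gap=100)
        assert [(c.start, c.end) for c in cands] == [(0, 31)]

    def test_matches_sweep_line_oracle(self, rng):
        for _ in range(20):
            starts = sorted(int(s) for s in rng.integers(0, 5000, 60))
            hits = [hit("A" * 21, s) for s in starts]
            gap = int(rng.integers(10, 300))
            cands = mirna.cluster_loci(hits, max_gap=gap)
            want = interval_union([(s, s + 21) for s in starts], gap)
            assert [(c.start, c.end) for c in cands] == want
            assert sum(len(c.hits) for c in cands) == len(hits)


class TestFoldHairpin:
    def test_perfect_complement_stem(self):
        seq = "GGCGGCGGCGAAAACGCCGCCGCC" * 2
        structure, energy = mirna.fold_hairpin(seq[:48].ljust(48, "A"))
        assert energy < 0 and "(" in structure

    def test_poly_a_has_no_stable_stem(self):
        structure, energy = mirna.fold_hairpin("A" * 60)
        assert energy >= 0
        assert set(structure) == {"."}

    @pytest.mark.parametrize("n", [39, 301])
    def test_length_limits(self, n):
        with pytest.raises(ValueError):
            mirna.fold_hairpin("A" * n)

    def test_pair_count_near_nussinov_on_planted_stems(self, rng):
        """MFE recovers close to the pairing-maximization optimum on
        GC-containing planted stems (tolerance 4 pairs)."""
        for _ in range(20):
            arm = "".join(rng.choice(list("ACGT"), int(rng.integers(15, 26))))
            seq = arm + "".join(rng.choice(list("ACGT"), 5)) + rc(arm)
            structure, _ = mirna.fold_hairpin(seq.ljust(40, "A"))
            mfe_pairs = structure.count("(")
            assert mfe_pairs >= nussinov_max_pairs(seq.ljust(40, "A")) - 4


class TestDuplexGeometry:
    def build_structure(self, unpaired: int, mlen: int = 21) -> str:
        """Mature at [0, mlen); ``unpaired`` of its 19 duplex positions open."""
        core = mlen - 2
        s = "(" * (core - unpaired) + "." * unpaired + ".."  # mature + 3' overhang
        return s + "..." + ")" * (core - unpaired) + "." * (unpaired + 4)

    def test_boundary_five_accepted_six_rejected(self):
        assert mirna.duplex_unpaired(self.build_structure(5), 0, 21) == 5
        assert mirna.duplex_ok(self.build_structure(5), 0, 21, max_unpaired=5)
        assert mirna.duplex_unpaired(self.build_structure(6), 0, 21) == 6
        assert not mirna.duplex_ok(self.build_structure(6), 0, 21, max_unpaired=5)

    def test_three_prime_overhang_excluded_from_count(self):
        assert mirna.duplex_unpaired(self.build_structure(0), 0, 21) == 0


class TestEvaluateLocus:
    def setup_locus(self, rng, mature_count=100, star_count=10):
        mature = "".join(rng.choice(list("ACGT"), 21))
        genome, hp = build_hairpin_genome(mature, rng=rng)
        hits = [
            hit(mature, hp, count=mature_count),
            hit(rc(mature), hp + 32, count=star_count),
        ]
        cand = mirna.Candidate("g", hp, hp + 53, hits)
        return mature, genome, cand

    def test_planted_hairpin_accepted(self, rng):
        mature, genome, cand = self.setup_locus(rng)
        locus = mirna.evaluate_mirna_locus(cand, genome)
        assert isinstance(locus, mirna.MirnaLocus)
        assert locus.mature_seq == mature
        assert locus.mature_count == 100
        assert locus.dicer_fraction == 1.0

    def test_mature_below_ten_reads_rejected(self, rng):
        _, genome, cand = self.setup_locus(rng, mature_count=9, star_count=5)
        res = mirna.evaluate_mirna_locus(cand, genome)
        assert isinstance(res, mirna.Rejection)
        assert res.reason == "min_mature_reads"

    def test_dicer_fraction_boundary_080(self, rng):
        """79% of read count in 20-24 nt rejects; exactly 80% accepts."""
        mature = "".join(rng.choice(list("ACGT"), 21))
        genome, hp = build_hairpin_genome(mature, rng=rng)
        oversize = genome["g"][hp + 40 : hp + 66]  # 26-mer inside the window
        for mcount, ocount, ok in ((80, 20, True), (79, 21, False)):
            cand = mirna.Candidate("g", hp, hp + 66, [
                hit(mature, hp, count=mcount), hit(oversize, hp + 40, count=ocount)])
            res = mirna.evaluate_mirna_locus(cand, genome)
            if ok:
                assert isinstance(res, mirna.MirnaLocus)
                assert res.dicer_fraction == pytest.approx(0.8)
            else:
                assert isinstance(res, mirna.Rejection)
                assert res.reason == "dicer_fraction"

    def test_hairpin_span_boundary_150(self, rng):
        """Reads spanning exactly 150 nt can still fold; 151 nt cannot."""
        arm = "".join(rng.choice(list("ACGT"), 70))
        mature = arm[:21]
        genome, hp = build_hairpin_genome(mature, arm=arm, loop="GGAAACAGTC", rng=rng)
        far_ok = hit(rc(arm)[-21:], hp + 129, count=10)  # ends at hp+150
        res = mirna.evaluate_mirna_locus(
            mirna.Candidate("g", hp, hp + 150, [hit(mature, hp, count=100), far_ok]),
            genome,
        )
        assert isinstance(res, mirna.MirnaLocus)
        far_bad = hit(genome["g"][hp + 130 : hp + 151], hp + 130, count=10)
        res = mirna.evaluate_mirna_locus(
            mirna.Candidate("g", hp, hp + 151, [hit(mature, hp, count=100), far_bad]),
            genome,
        )
        assert isinstance(res, mirna.Rejection)
        assert res.reason == "hairpin_span"

    def test_no_hairpin_in_random_sequence_rejected(self, rng):
        seq = "".join(rng.choice(list("AC"), 200))  # AC-only: no WC pairing
        genome = {"g": seq}
        cand = mirna.Candidate("g", 50, 71, [hit(seq[50:71], 50, count=50)])
        res = mirna.evaluate_mirna_locus(cand, genome)
        assert isinstance(res, mirna.Rejection)
        assert res.reason == "star_duplex"

    def test_loosening_thresholds_never_shrinks_accepted_set(self, rng):
        """Criterion monotonicity for the read floor and Dicer fraction."""
        candidates = []
        for mc in (5, 9, 15, 100):
            _, genome, cand = self.setup_locus(rng, mature_count=mc)
            candidates.append((genome, cand))
        strict = mirna.LocusConfig()
        loose = mirna.LocusConfig(min_mature_reads=5, min_dicer_fraction=0.5)
        accepted_strict = {
            id(c) for g, c in candidates
            if isinstance(mirna.evaluate_mirna_locus(c, g, strict), mirna.MirnaLocus)
        }
        accepted_loose = {
            id(c) for g, c in candidates
            if isinstance(mirna.evaluate_mirna_locus(c, g, loose), mirna.MirnaLocus)
        }
        assert accepted_strict <= accepted_loose

    def test_mature_and_star_map_back_into_precursor(self, clean_run1):
        _, result = clean_run1
        for locus in result.novel_loci:
            assert locus.mature_seq in locus.precursor_seq
            assert locus.star_seq in locus.precursor_seq
            assert locus.end - locus.start <= 150


class TestClassifyMature:
    SPECIES = [mirna.MatureReference("mdm-miR9x", "ACGGTACGTTACGTACGGTCA", "miR9", "mdm")]
    PLANT = [mirna.MatureReference("ath-miR8y", "TTGGTACGTTACGTACGGTCA", "miR8", "ath")]

    def make_locus(self, mature):
        return mirna.MirnaLocus(
            ref_id="g", start=0, end=100, strand="+", precursor_seq=mature,
            structure="." * len(mature), energy=-10.0, mature_seq=mature,
            mature_arm="5p", mature_count=50, star_seq=rc(mature), star_arm="3p",
            star_count=5, dicer_fraction=1.0,
        )

    def test_exact_species_match(self):
        locus = self.make_locus(self.SPECIES[0].seq)
        assert mirna.classify_mature(locus, self.SPECIES, self.PLANT) == "known_same_species"

    def test_plant_homolog(self):
        locus = self.make_locus(self.PLANT[0].seq)
        assert mirna.classify_mature(locus, self.SPECIES, self.PLANT) == "plant_homolog"

    def test_antisense_of_known(self):
        locus = self.make_locus(rc(self.SPECIES[0].seq))
        assert mirna.classify_mature(locus, self.SPECIES, self.PLANT) == "antisense_of_known"

    def test_novel(self):
        locus = self.make_locus("GATTACAGATTACAGATTACA")
        assert mirna.classify_mature(locus, self.SPECIES, self.PLANT) == "novel"

    def test_family_member_at_new_locus(self):
        locus = self.make_locus(self.SPECIES[0].seq)
        cls = mirna.classify_mature(
            locus, self.SPECIES, self.PLANT, known_loci=[("g", 5000, 5100)]
        )
        assert cls == "novel_family_member"

    def test_isomir_annotation_within_three_nt(self):
        shifted = self.SPECIES[0].seq[2:] + "GT"  # 2-nt end shift
        locus = self.make_locus(shifted)
        mirna.classify_mature(locus, self.SPECIES, self.PLANT)
        assert locus.isomir_of == ["mdm-miR9x"]
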