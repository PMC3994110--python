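"""NAT pair discovery, duplex validation, densities, enrichment, bias."""

from __future__ import annotations

import warnings

import numpy as np
import pytest

from _oracles import antisense_runs_dp, ranksum_permutation_p, rc
from srnaome import nat
from srnaome.align import AlignmentHit


def tmodel(tid, seq, chrom="chr1", start=None, strand="+"):
    if start is None:
        return nat.TranscriptModel(tid, seq)
    return nat.TranscriptModel(tid, seq, chrom, start, start + len(seq), strand)


def genome_pair(rng, a_span, b_span, chrom="chr1"):
    g = "".join(rng.choice(list("ACGT"), max(a_span[1], b_span[1]) + 50))
    a = tmodel("tA", g[a_span[0]:a_span[1]], chrom, a_span[0], "+")
    b = tmodel("tB", rc(g[b_span[0]:b_span[1]]), chrom, b_span[0], "-")
    return a, b


class TestCisPairs:
    def test_basic_overlap(self, rng):
        a, b = genome_pair(rng, (0, 500), (400, 900))
        pairs = nat.find_cis_pairs([a, b])
        assert len(pairs) == 1
        assert pairs[0].pair_type == "cis"
        assert pairs[0].overlaps[0].length == 100
        assert pairs[0].overlaps[0].genomic_interval == (400, 500)
        # transcript-local: last 100 nt of A, last 100 nt of B (both 5'->3')
        assert pairs[0].overlaps[0].t1_interval == (400, 500)
        assert pairs[0].overlaps[0].t2_interval == (400, 500)

    def test_same_strand_is_not_cis(self, rng):
        g = "".join(rng.choice(list("ACGT"), 900))
        a = tmodel("tA", g[0:500], "chr1", 0, "+")
        b = tmodel("tB", g[400:900], "chr1", 400, "+")
        assert nat.find_cis_pairs([a, b]) == []

    def test_overlap_boundary_strictly_greater_than_50(self, rng):
        a50, b50 = genome_pair(rng, (0, 500), (450, 950))
        assert nat.find_cis_pairs([a50, b50], min_overlap=50) == []
        a51, b51 = genome_pair(rng, (0, 501), (450, 950))
        assert len(nat.find_cis_pairs([a51, b51], min_overlap=50)) == 1

    def test_malformed_coordinates_name_the_transcript(self):
        with pytest.raises(ValueError, match="tBad"):
            nat.TranscriptModel("tBad", "ACGT" * 10, "chr1", 10, 20, "+")

    def test_random_intervals_match_quadratic_oracle(self, rng):
        for _ in range(10):
            n = 20
            g = "".join(rng.choice(list("ACGT"), 4000))
            ts = []
            for i in range(n):
                s = int(rng.integers(0, 3000))
                e = s + int(rng.integers(100, 800))
                strand = "+-"[int(rng.integers(2))]
                seq = g[s:e] if strand == "+" else rc(g[s:e])
                ts.append(nat.TranscriptModel(f"t{i:02d}", seq, "chr1", s, e, strand))
            got = {(p.t1, p.t2) for p in nat.find_cis_pairs(ts)}
            want = set()
            for i in range(n):
                for j in range(i + 1, n):
                    a, b = ts[i], ts[j]
                    if a.strand == b.strand:
                        continue
                    ov = min(a.g_end, b.g_end) - max(a.g_start, b.g_start)
                    if ov > 50:
                        want.add(tuple(sorted((a.transcript_id, b.transcript_id))))
            assert got == want


class TestTransPairs:
    def plant(self, rng, run_len, unplaced=False):
        a_seq = "".join(rng.choice(list("ACGT"), 500))
        segment = a_seq[100 : 100 + run_len]
        b_seq = "".join(rng.choice(list("ACGT"), 500))
        b_seq = b_seq[:200] + rc(segment) + b_seq[200 + run_len :]
        a = tmodel("tA", a_seq, "chr1", 0, "+")
        b = tmodel("tB", b_seq) if unplaced else tmodel("tB", b_seq, "chr2", 0, "+")
        return a, b

    def test_planted_150_run_found(self, rng):
        a, b = self.plant(rng, 150)
        pairs = nat.find_trans_pairs([a, b])
        assert len(pairs) == 1
        p = pairs[0]
        assert p.pair_type == "trans"
        assert p.overlaps[0].length >= 150  # random flanks may extend the run

    def test_sense_sense_shared_segment_is_not_a_pair(self, rng):
        a_seq = "".join(rng.choice(list("ACGT"), 500))
        b_seq = "".join(rng.choice(list("ACGT"), 500))
        b_seq = b_seq[:200] + a_seq[100:250] + b_seq[350:]
        pairs = nat.find_trans_pairs(
            [tmodel("tA", a_seq, "chr1", 0), tmodel("tB", b_seq, "chr2", 0)]
        )
        assert pairs == []

    def test_run_boundary_strictly_greater_than_100(self, rng):
        # flank the planted run with mismatching bases so it cannot extend
        core = "".join(rng.choice(list("ACGT"), 101))
        for run_len, expected in ((100, 0), (101, 1)):
            seg = core[:run_len]
            a_seq = "C" * 150 + "A" + seg + "A" + "C" * 150
            b_mid = rc("G" + seg + "G")
            b_seq = "T" * 150 + b_mid + "T" * 150
            a = tmodel("tA", a_seq, "chr1", 0)
            b = tmodel("tB", b_seq, "chr2", 0)
            assert len(nat.find_trans_pairs([a, b], min_run=100)) == expected

    def test_unplaced_transcript_gives_unclassified(self, rng):
        a, b = self.plant(rng, 150, unplaced=True)
        pairs = nat.find_trans_pairs([a, b])
        assert pairs[0].pair_type == "unclassified"

    def test_genomically_overlapping_transcripts_skipped(self, rng):
        a, b = genome_pair(rng, (0, 500), (200, 700))
        assert nat.find_trans_pairs([a, b], min_run=100) == []

    def test_runs_match_full_dp_oracle(self, rng):
        for _ in range(5):
            s1 = "".join(rng.choice(list("ACGT"), 400))
            s2 = "".join(rng.choice(list("ACGT"), 400))
            seg = s1[50:200]
            s2 = s2[:100] + rc(seg) + s2[250:]
            got = nat._antisense_runs(s1, s2, min_run=100)
            want = [r for r in antisense_runs_dp(s1, s2) if r[2] > 100]
            assert sorted(got) == sorted(want)


class TestValidateDuplex:
    def test_perfect_complement_valid(self, rng):
        a, b = genome_pair(rng, (0, 500), (400, 900))
        pair = nat.find_cis_pairs([a, b])[0]
        tx = {t.transcript_id: t for t in (a, b)}
        assert nat.validate_duplex(pair, tx) is True

    def test_unrelated_random_overlaps_invalid(self, rng):
        """Unrelated random 200-mers fail hybridization over 50 seeds."""
        invalid = 0
        for _ in range(50):
            s1 = "".join(rng.choice(list("ACGT"), 200))
            s2 = "".join(rng.choice(list("ACGT"), 200))
            frac, mfe = nat.duplex_paired_fraction(s1, s2)
            invalid += frac < 0.5
        assert invalid == 50

    def test_zero_threshold_warns_and_accepts(self, rng):
        a, b = genome_pair(rng, (0, 500), (400, 900))
        pair = nat.find_cis_pairs([a, b])[0]
        with pytest.warns(UserWarning):
            assert nat.validate_duplex(pair, {}, min_paired_fraction=0.0)


class TestRelationships:
    def mkpair(self, a, b, kind="cis"):
        return nat.NatPair(a, b, kind, [nat.OverlapRegion((0, 60), (0, 60), 60)])

    def test_single_pair_is_one_to_one(self):
        _, summary = nat.classify_relationships([self.mkpair("A", "B")])
        assert summary.set_index("relationship").loc["one_to_one", "pct"] == 100.0

    def test_shared_endpoint_makes_one_to_many(self):
        per_pair, _ = nat.classify_relationships(
            [self.mkpair("A", "B"), self.mkpair("A", "C")]
        )
        assert set(per_pair.relationship) == {"one_to_many"}

    def test_triangle_is_many_to_many(self):
        per_pair, _ = nat.classify_relationships(
            [self.mkpair("A", "B"), self.mkpair("A", "C"), self.mkpair("B", "C")]
        )
        assert set(per_pair.relationship) == {"many_to_many"}

    def test_random_graphs_match_degree_oracle(self, rng):
        for _ in range(100):
            n_nodes = int(rng.integers(4, 12))
            edges = set()
            for _ in range(int(rng.integers(1, 12))):
                i, j = rng.choice(n_nodes, 2, replace=False)
                edges.add((f"n{min(i, j)}", f"n{max(i, j)}"))
            pairs = [self.mkpair(a, b) for a, b in sorted(edges)]
            per_pair, summary = nat.classify_relationships(pairs)
            deg = {}
            for a, b in edges:
                deg[a] = deg.get(a, 0) + 1
                deg[b] = deg.get(b, 0) + 1
            for row in per_pair.itertuples():
                d1, d2 = deg[row.t1], deg[row.t2]
                want = ("one_to_one" if d1 == d2 == 1
                        else "many_to_many" if d1 > 1 and d2 > 1 else "one_to_many")
                assert row.relationship == want
            assert summary.pct.sum() == pytest.approx(100.0)


def thit(tid, start, count=1, strand="+", L=21):
    return AlignmentHit("A" * L, tid, start, strand, 0, count)


class TestDensity:
    def setup_pair(self, rng):
        a, b = genome_pair(rng, (0, 1000), (500, 1500))  # 500-nt overlap
        pair = nat.find_cis_pairs([a, b])[0]
        return pair, {t.transcript_id: t for t in (a, b)}

    def test_overlap_density_arithmetic(self, rng):
        pair, tx = self.setup_pair(rng)
        hits = [thit("tA", 600 + i * 10) for i in range(10)]  # inside overlap
        stats = nat.compute_density(hits, [pair], tx)
        assert stats[0].overlap_density == pytest.approx(20.0)  # 10 / 0.5 kb

    def test_no_hits_zero_densities(self, rng):
        pair, tx = self.setup_pair(rng)
        s = nat.compute_density([], [pair], tx)[0]
        assert s.overlap_density == 0 and s.nonoverlap_density == 0

    def test_read_conservation_over_regions(self, rng):
        pair, tx = self.setup_pair(rng)
        hits = [thit("tA", int(p)) for p in rng.integers(0, 950, 200)]
        hits += [thit("tB", int(p)) for p in rng.integers(0, 950, 200)]
        s = nat.compute_density(hits, [pair], tx)[0]
        ov_reads = s.overlap_density * 0.5
        non_reads = s.nonoverlap_density * 1.0
        assert ov_reads + non_reads == pytest.approx(400)

    def test_pair_order_symmetry(self, rng):
        pair, tx = self.setup_pair(rng)
        flipped = nat.NatPair(pair.t2, pair.t1, pair.pair_type, [
            nat.OverlapRegion(o.t2_interval, o.t1_interval, o.length, o.genomic_interval)
            for o in pair.overlaps
        ])
        hits = [thit("tA", int(p)) for p in rng.integers(0, 950, 100)]
        s1 = nat.compute_density(hits, [pair], tx)[0]
        s2 = nat.compute_density(hits, [flipped], tx)[0]
        assert s1.overlap_density == s2.overlap_density
        assert s1.nonoverlap_density == s2.nonoverlap_density
        assert s1.bias_fold == s2.bias_fold


class TestStrandBias:
    @pytest.mark.parametrize(
        "c1,c2,fold,biased",
        [(30, 10, 3.0, True), (10, 10, 1.0, False), (40, 0, 41.0, True)],
    )
    def test_fold_and_flag(self, c1, c2, fold, biased):
        got_fold, got_biased = nat.strand_bias_counts(c1, c2)
        assert got_fold == pytest.approx(fold)
        assert got_biased == biased

    def test_two_fold_inclusive_boundary(self):
        assert nat.strand_bias_counts(19, 10)[1] is False  # 1.9-fold
        assert nat.strand_bias_counts(20, 10)[1] is True  # 2.0-fold

    def test_min_reads_floor(self):
        assert nat.strand_bias_counts(6, 3)[1] is False  # 9 reads < 10


class TestEnrichment:
    def test_maximal_separation(self):
        p, direction = nat.enrichment_test([100.0] * 10, [1.0] * 10)
        assert p < 0.001 and direction == "enriched"

    def test_identical_cohorts_p_one(self):
        p, direction = nat.enrichment_test([5.0, 5.0, 5.0], [5.0, 5.0, 5.0])
        assert p == 1.0 and direction == "none"

    def test_reduction_direction(self):
        p, direction = nat.enrichment_test([1.0] * 8, [50.0] * 8)
        assert direction == "reduced" and p < 0.01

    def test_small_n_matches_permutation_enumeration(self, rng):
        """Exact rank-sum p at n1=n2=5 equals full permutation enumeration."""
        for _ in range(10):
            x = [float(v) for v in rng.uniform(0, 100, 5)]
            y = [float(v) for v in rng.uniform(0, 100, 5)]
            p, _ = nat.enrichment_test(x, y)
            assert p == pytest.approx(ranksum_permutation_p(x, y), abs=1e-9)

    def test_needs_two_pairs(self):
        with pytest.raises(ValueError):
            nat.enrichment_test([1.0], [2.0])
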