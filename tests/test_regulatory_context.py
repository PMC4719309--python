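import numpy as np
import pandas as pd
import pytest

from roxevol.model import Genome, GenomicInterval, reverse_complement
from roxevol.motif import PWM
from roxevol.regulatory_context import (
    binomial_two_sided,
    classify_summit,
    enumerate_ppt_candidates,
    feature_assignment,
    find_and_select_ppt,
    ks_two_sample,
    orientation_bias,
    peak_ppt_proximity,
    penalty,
    select_ppts,
)
from roxevol.synthetic_data import child_rng, random_sequence
from conftest import make_gene, make_peak
import oracles


class TestPenalty:
    def test_free_zone_convention(self):
        assert penalty(0) == 0.0
        assert penalty(39) == 0.0
        assert penalty(40) == 0.0  # d=40 itself penalty-free
        assert penalty(41) == pytest.approx(0.02)
        assert penalty(140) == pytest.approx(2.0)

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            penalty(-1)

    def test_nondecreasing(self):
        values = [penalty(d) for d in range(0, 200)]
        assert all(b >= a for a, b in zip(values, values[1:]))


class TestPPTSelection:
    def test_tract_near_3ss_selected_with_zero_penalty(self):
        # "…AAAA|TTTTCTTTTC|AA(3'ss)": tract ends 2 bp from the splice site
        best = find_and_select_ppt("AAAATTTTCTTTTCAA")
        assert (best.start, best.end) == (4, 14)
        assert best.raw_score == 10.0
        assert best.distance_to_3ss == 2
        assert best.penalized_score == 10.0

    def test_equal_tracts_distance_break(self):
        # equal 10-pyrimidine tracts at distances 100 and 10: penalties 1.2 vs 0
        seq = "A" * 20 + "T" * 10 + "A" * 80 + "T" * 10 + "A" * 10
        candidates = enumerate_ppt_candidates(seq)
        far = max(
            (c for c in candidates if (c.start, c.end) == (20, 30)),
            key=lambda c: c.penalized_score,
        )
        near = max(
            (c for c in candidates if (c.start, c.end) == (110, 120)),
            key=lambda c: c.penalized_score,
        )
        assert near.penalized_score - far.penalized_score == pytest.approx(1.2)
        best = find_and_select_ppt(seq)
        assert (best.start, best.end) == (110, 120)

    def test_too_short_returns_none(self):
        assert find_and_select_ppt("TTTTT") is None

    def test_no_candidate_returns_none(self):
        assert find_and_select_ppt("A" * 50) is None

    def test_matches_oracle(self, rng):
        for _ in range(60):
            # pyrimidine-biased so tracts actually occur
            seq = random_sequence(int(rng.integers(15, 70)), rng,
                                  p=[0.2, 0.3, 0.2, 0.3])
            got = find_and_select_ppt(seq)
            expected = oracles.naive_select_ppt(seq)
            if expected is None:
                assert got is None
            else:
                start, end, raw, dist, pen = expected
                assert (got.start, got.end) == (start, end)
                assert got.raw_score == pytest.approx(raw)
                assert got.distance_to_3ss == dist
                assert got.penalized_score == pytest.approx(pen)

    def test_never_dominated(self, rng):
        """Selection never prefers a candidate strictly worse in both raw
        score and distance to the splice site."""
        for _ in range(20):
            seq = random_sequence(60, rng, p=[0.2, 0.3, 0.2, 0.3])
            best = find_and_select_ppt(seq)
            if best is None:
                continue
            for c in enumerate_ppt_candidates(seq):
                assert not (
                    c.raw_score > best.raw_score
                    and c.distance_to_3ss < best.distance_to_3ss
                    and c.penalized_score > best.penalized_score
                )


class TestSelectPPTsGenomic:
    def test_minus_strand_coordinates(self):
        # transcribed-strand intron: 40 G, 12 T (the tract), 8 G
        transcribed = "G" * 40 + "T" * 12 + "G" * 8
        intron_genomic = reverse_complement(transcribed)
        seq = "C" * 50 + intron_genomic + "C" * 50
        genome = Genome({"chr1": seq})
        gene = make_gene("g", "chr1", [(0, 50), (110, 160)], "-")
        table = select_ppts([gene], genome)
        assert len(table) == 1
        row = table.iloc[0]
        assert (row["start"], row["end"]) == (58, 70)
        assert row["strand"] == "-"
        assert row["distance_to_3ss"] == 8
        # the tract reads as A-run on the genomic plus strand
        assert seq[58:70] == "A" * 12

    def test_plus_strand_coordinates(self):
        intron = "G" * 30 + "C" * 10 + "G" * 20
        seq = "A" * 50 + intron + "A" * 50
        genome = Genome({"chr1": seq})
        gene = make_gene("g", "chr1", [(0, 50), (110, 160)], "+")
        row = select_ppts([gene], genome).iloc[0]
        assert (row["start"], row["end"]) == (80, 90)
        assert row["distance_to_3ss"] == 20

    def test_empty_when_no_introns(self, toy_genome):
        gene = make_gene("g", "chr1", [(0, 100)], "+")
        assert select_ppts([gene], toy_genome).empty


class TestKS:
    def test_identical_samples(self):
        d, p = ks_two_sample([1, 2, 3], [1, 2, 3])
        assert d == 0.0 and p == 1.0

    def test_disjoint_supports(self):
        d, _p = ks_two_sample([1, 2, 3], [4, 5, 6])
        assert d == 1.0

    def test_d_matches_oracle(self, rng):
        for _ in range(20):
            x = rng.normal(size=int(rng.integers(2, 10)))
            y = rng.normal(size=int(rng.integers(2, 10)))
            d, _ = ks_two_sample(x, y)
            assert d == pytest.approx(oracles.ks_d(list(x), list(y)))

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            ks_two_sample([], [1.0])


class TestBinomial:
    def test_closed_form_ten_zero(self):
        assert binomial_two_sided(0, 10) == pytest.approx(2 * 0.5**10)
        assert binomial_two_sided(0, 10) == pytest.approx(0.001953125)

    def test_symmetry(self):
        assert binomial_two_sided(2, 10) == pytest.approx(binomial_two_sided(8, 10))

    def test_cap_at_one(self):
        assert binomial_two_sided(5, 10) == 1.0

    def test_matches_naive(self, rng):
        for _ in range(30):
            n = int(rng.integers(1, 40))
            k = int(rng.integers(0, n + 1))
            p0 = float(rng.uniform(0.1, 0.9))
            assert binomial_two_sided(k, n, p0) == pytest.approx(
                oracles.naive_binomial_two_sided(k, n, p0), rel=1e-9
            )


def ppt_frame(rows):
    return pd.DataFrame(rows, columns=["scaffold", "midpoint", "strand"])


class TestProximity:
    def test_summits_on_midpoints(self):
        ppts = ppt_frame([("chrX", 1_000, "+"), ("chrX", 5_000, "+")])
        peaks = [make_peak("chrX", 900, 1100, summit=1_000),
                 make_peak("chrX", 4_900, 5_100, summit=5_000)]
        result = peak_ppt_proximity(peaks, ppts, {"chrX": 10_000}, n_perm=10, seed=0)
        assert result.observed_fraction_within == 1.0
        np.testing.assert_array_equal(result.signed_distances, [0.0, 0.0])

    def test_sign_flips_on_minus_host(self):
        plus = ppt_frame([("chrX", 1_000, "+")])
        minus = ppt_frame([("chrX", 1_000, "-")])
        peak = [make_peak("chrX", 950, 1100, summit=1_010)]
        r_plus = peak_ppt_proximity(peak, plus, {"chrX": 10_000}, n_perm=5, seed=0)
        r_minus = peak_ppt_proximity(peak, minus, {"chrX": 10_000}, n_perm=5, seed=0)
        assert r_plus.signed_distances[0] == 10.0
        assert r_minus.signed_distances[0] == -10.0

    def test_no_ppts_rejected(self):
        with pytest.raises(ValueError):
            peak_ppt_proximity([make_peak("chrX", 0, 10)], ppt_frame([]),
                               {"chrX": 100})

    def test_deterministic(self):
        ppts = ppt_frame([("chrX", 1_000, "+")])
        peaks = [make_peak("chrX", 900, 1100)]
        a = peak_ppt_proximity(peaks, ppts, {"chrX": 10_000}, n_perm=20, seed=3)
        b = peak_ppt_proximity(peaks, ppts, {"chrX": 10_000}, n_perm=20, seed=3)
        np.testing.assert_array_equal(a.permuted_distances, b.permuted_distances)


class TestClassifySummit:
    def _gene(self):
        return make_gene(
            "g", "chr1", [(0, 100), (200, 300)], "+",
            cds_bounds=[(20, 100), (200, 280)],
            utr5=[(0, 20)], utr3=[(280, 300)],
        )

    def test_classes(self):
        gene = self._gene()
        assert classify_summit(10, "chr1", [gene]) == (["5UTR"], "+")
        assert classify_summit(50, "chr1", [gene]) == (["CDS"], "+")
        assert classify_summit(150, "chr1", [gene]) == (["intron"], "+")
        assert classify_summit(290, "chr1", [gene]) == (["3UTR"], "+")
        assert classify_summit(500, "chr1", [gene]) == (["intergenic"], None)
        assert classify_summit(10, "chr2", [gene]) == (["intergenic"], None)

    def test_double_counting_across_transcripts(self):
        a = self._gene()
        b = make_gene("h", "chr1", [(100, 260)], "-")
        classes, strand = classify_summit(150, "chr1", [a, b])
        assert sorted(classes) == ["CDS", "intron"]
        assert strand == "+"  # first host transcript wins

    def test_exon_without_finer_annotation_is_cds(self):
        gene = make_gene("g", "chr1", [(0, 100)], "+", cds_bounds=[])
        gene.transcripts[0].cds = []
        assert classify_summit(50, "chr1", [gene])[0] == ["CDS"]


class TestFeatureAssignment:
    def test_toy_arithmetic(self):
        gene = make_gene("g", "chr1", [(0, 40), (60, 100)], "+")
        peaks = [make_peak("chr1", 10, 30, summit=20),
                 make_peak("chr1", 45, 55, summit=50),
                 make_peak("chr1", 140, 160, summit=150)]
        frame = feature_assignment(peaks, [gene], {"chr1": 200}).set_index("feature")
        assert frame.loc["CDS", "n_summits"] == 1
        assert frame.loc["intron", "n_summits"] == 1
        assert frame.loc["intergenic", "n_summits"] == 1
        assert frame.loc["CDS", "genome_fraction"] == pytest.approx(80 / 200)
        assert frame.loc["intron", "genome_fraction"] == pytest.approx(20 / 200)
        assert frame.loc["intergenic", "genome_fraction"] == pytest.approx(100 / 200)
        assert frame.loc["intron", "fold_enrichment"] == pytest.approx(
            (1 / 3) / (20 / 200)
        )


class TestOrientationBias:
    def _setup(self, rng):
        length = 600
        seq = list(random_sequence(length, rng, p=[0.4, 0.1, 0.1, 0.4]))
        gene = make_gene("g", "chr1", [(50, 200), (320, 500)], "+")
        motif = "GAGAGAGAGA"
        plants = [(100, motif), (250, reverse_complement(motif)), (400, motif)]
        for pos, inst in plants:
            seq[pos : pos + len(inst)] = list(inst)
        genome = Genome({"chr1": "".join(seq)})
        peaks = [make_peak("chr1", p - 30, p + 40, summit=p + 5, name=f"p{p}")
                 for p, _ in plants]
        return genome, [gene], peaks, PWM.from_instances([motif])

    def test_counts_and_orientation(self, rng):
        genome, genes, peaks, pwm = self._setup(rng)
        result = orientation_bias(peaks, pwm, genes, genome)
        counts = result.counts.set_index("feature")
        assert counts.loc["CDS", "n_forward"] == 2  # summits 105 and 405
        assert counts.loc["intron", "n_reverse"] == 1  # summit 255
        assert result.n_unscorable == 0

    def test_reverse_complement_invariance(self, rng):
        """Mirroring the genome and flipping gene strands leaves the
        orientation counts unchanged."""
        genome, genes, peaks, pwm = self._setup(rng)
        direct = orientation_bias(peaks, pwm, genes, genome).counts

        length = genome.length("chr1")
        mirrored_genome = Genome(
            {"chr1": reverse_complement(genome.scaffolds["chr1"])}
        )
        mirrored_genes = [
            make_gene(
                "g", "chr1",
                [(length - e.end, length - e.start)
                 for e in reversed(genes[0].transcripts[0].exons)],
                "-",
            )
        ]
        mirrored_peaks = [
            make_peak("chr1", length - p.interval.end, length - p.interval.start,
                      summit=length - 1 - p.summit, name=p.name)
            for p in peaks
        ]
        mirrored = orientation_bias(
            mirrored_peaks, pwm, mirrored_genes, mirrored_genome
        ).counts
        pd.testing.assert_frame_equal(
            direct.sort_values("feature").reset_index(drop=True),
            mirrored.sort_values("feature").reset_index(drop=True),
        )

    def test_unscorable_counted(self):
        genome = Genome({"chr1": "N" * 100})
        peaks = [make_peak("chr1", 10, 40)]
        result = orientation_bias(peaks, PWM.from_instances(["GAGA"]), [], genome)
        assert result.n_unscorable == 1
        assert result.counts.empty
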