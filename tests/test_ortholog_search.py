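import numpy as np
import pytest
from Bio.Align import substitution_matrices

from roxevol.model import Genome, GenomicInterval, reverse_complement
from roxevol.motif import PWM, MotifHit
from roxevol.ortholog_search import (
    AnchorHit,
    ReferenceLocus,
    SearchConfig,
    SearchState,
    define_synteny_window,
    elect_candidate_window,
    find_anchor_locus,
    refine_pwm,
    run_bootstrap_search,
    score_stem_loop,
)
from roxevol.synthetic_data import (
    SimulationConfig,
    _encode_protein,
    _protein,
    child_rng,
    generate_species_set,
    random_sequence,
)
import oracles

BLOSUM62 = substitution_matrices.load("BLOSUM62")


class TestAnchorSearch:
    def test_recovers_planted_cds_forward(self, rng):
        protein = _protein(rng, 40)
        cds = _encode_protein(protein, rng)
        seq = random_sequence(500, rng) + cds + random_sequence(500, rng)
        genome = Genome({"s": seq})
        hit = find_anchor_locus(genome, protein, gene_id="g")
        assert hit is not None
        assert hit.interval.strand == "+"
        assert hit.interval.start <= 500 and hit.interval.end >= 500 + len(cds)
        # self-alignment score covers at least the full BLOSUM62 diagonal
        assert hit.score >= sum(BLOSUM62[a, a] for a in protein)

    def test_recovers_planted_cds_reverse(self, rng):
        protein = _protein(rng, 40)
        cds = _encode_protein(protein, rng)
        seq = random_sequence(301, rng) + reverse_complement(cds) + \
            random_sequence(200, rng)
        genome = Genome({"s": seq})
        hit = find_anchor_locus(genome, protein)
        assert hit is not None and hit.interval.strand == "-"
        assert hit.interval.start <= 301
        assert hit.interval.end >= 301 + len(cds)

    def test_absent_protein_returns_none(self, rng):
        genome = Genome({"s": random_sequence(2000, rng)})
        protein = "WWWWWCCCCCWWWWWCCCCC"  # rare residues, no planted copy
        assert find_anchor_locus(genome, protein) is None

    def test_short_protein_rejected(self):
        with pytest.raises(ValueError):
            find_anchor_locus(Genome({"s": "ACGTACGT"}), "MK", k=5)


def anchor(scaffold, start, end, score=50.0, gene="g"):
    return AnchorHit(gene, GenomicInterval(scaffold, start, end, "+"), score, 0)


class TestSyntenyWindow:
    def test_two_anchor_window(self):
        w = define_synteny_window([anchor("s", 100, 200), anchor("s", 700, 800)], 10_000)
        assert (w.interval.start, w.interval.end) == (200, 700)
        assert not w.disrupted

    def test_gap_above_max_span(self):
        assert define_synteny_window(
            [anchor("s", 0, 100), anchor("s", 20_000, 20_100)], 10_000
        ) is None

    def test_abutting_anchors(self):
        assert define_synteny_window(
            [anchor("s", 0, 100), anchor("s", 90, 200)], 10_000
        ) is None

    def test_single_anchor_clipped(self):
        w = define_synteny_window([anchor("s", 100, 200)], 1_000, scaffold_length=500)
        assert (w.interval.start, w.interval.end) == (0, 500)

    def test_different_scaffolds_disrupted(self):
        w = define_synteny_window([anchor("s", 0, 100), anchor("t", 0, 100)], 10_000)
        assert w.disrupted

    def test_no_anchors_rejected(self):
        with pytest.raises(ValueError):
            define_synteny_window([], 10_000)


def make_hits(rng, n, span=1000, width=8):
    starts = sorted(int(s) for s in rng.integers(0, span, size=n))
    hits = []
    for s in starts:
        hits.append(
            MotifHit(
                interval=GenomicInterval("s", s, s + width, "+"),
                score=float(np.round(rng.uniform(1, 10), 3)),
                p_value=1e-5,
                sequence="A" * width,
            )
        )
    return hits


class TestClusterElection:
    def test_below_min_hits(self, rng):
        assert elect_candidate_window(make_hits(rng, 2), min_hits=3) is None

    def test_matches_oracle(self, rng):
        for _ in range(60):
            hits = make_hits(rng, int(rng.integers(3, 12)), span=800)
            span = int(rng.integers(50, 400))
            got = elect_candidate_window(hits, cluster_span=span, min_hits=3)
            expected = oracles.naive_elect(
                [(h.start, h.interval.end, h.score) for h in hits], span, 3
            )
            if expected is None:
                assert got is None
            else:
                n, total, w_start, w_end = expected
                assert got is not None
                assert got.n_hits == n
                assert got.total_score == pytest.approx(total)
                assert (got.interval.start, got.interval.end) == (w_start, w_end)


class TestStemLoop:
    def test_perfect_hairpin(self):
        arm = "GGGCCATTAC"
        seq = "AAA" + arm + "TTTT" + reverse_complement(arm) + "AAA"
        score, coords = score_stem_loop(seq, 3, 3 + len(arm))
        assert score == len(arm)
        assert coords == (3, 13, 17, 27)

    def test_wobble_gt_pairs(self):
        # arm GGGGG pairs TTTTT only through G-T wobble
        seq = "GGGGG" + "AAA" + "TTTTT"
        score, coords = score_stem_loop(seq, 0, 5)
        assert score == 5.0

    def test_no_pairing_returns_zero(self):
        score, coords = score_stem_loop("AAAAACCCAAAAA", 0, 5)
        assert score == 0.0 and coords is None

    def test_matches_oracle(self, rng):
        for _ in range(50):
            seq = random_sequence(int(rng.integers(20, 45)), rng)
            f0 = int(rng.integers(0, len(seq) - 5))
            f1 = f0 + int(rng.integers(3, 8))
            got, _coords = score_stem_loop(seq, f0, f1, min_loop=3, max_loop=10,
                                           max_arm=8)
            expected = oracles.naive_stem_score(seq, f0, f1, 3, 10, 8)
            assert got == pytest.approx(expected)


class TestRefinePWM:
    def _state(self):
        pwm = PWM.from_instances(["GCTTGTGA"])
        return SearchState(pwm=pwm, instances=["GCTTGTGA"])

    def test_width_mismatch_rejected(self):
        with pytest.raises(ValueError):
            refine_pwm(self._state(), ["GCTT"])

    def test_n_rejected(self):
        with pytest.raises(ValueError):
            refine_pwm(self._state(), ["GCTTGTGN"])

    def test_counts_accumulate(self):
        state = self._state()
        pwm = refine_pwm(state, ["GCTTGTGA", "GCTTGAGA"])
        assert pwm.counts.sum() == 3 * 8
        assert state.instances == ["GCTTGTGA", "GCTTGTGA", "GCTTGAGA"]

    def test_background_from_searched_windows(self):
        state = self._state()
        state.searched_windows = ["AAAAAAAACC"]  # 80% A, 20% C
        pwm = refine_pwm(state, ["GCTTGTGA"])
        np.testing.assert_allclose(pwm.background, [0.8, 0.2, 0.0, 0.0])


class TestBootstrapSearch:
    def test_full_recall_on_default_fixture(self):
        species_set = generate_species_set(SimulationConfig(seed=0))
        truth = species_set.truth.set_index("species")
        ref = truth.loc["sp0"]
        reference = ReferenceLocus(
            species="sp0",
            interval=GenomicInterval(
                ref["scaffold"], int(ref["locus_start"]), int(ref["locus_end"])
            ),
            motif_instances=species_set.motif_instances,
            primary_anchors=species_set.anchors,
        )
        state = run_bootstrap_search(
            reference, species_set.genomes, species_set.phylogeny
        )
        assert len(state.results) == 8
        for species, cand in state.results.items():
            assert cand.accepted, (species, cand.reason)
            row = truth.loc[species]
            assert cand.interval.start < row["locus_end"]
            assert cand.interval.end > row["locus_start"]

    def test_missing_genome_reported(self):
        species_set = generate_species_set(SimulationConfig(seed=0))
        truth = species_set.truth.set_index("species")
        ref = truth.loc["sp0"]
        reference = ReferenceLocus(
            species="sp0",
            interval=GenomicInterval(
                ref["scaffold"], int(ref["locus_start"]), int(ref["locus_end"])
            ),
            motif_instances=species_set.motif_instances,
            primary_anchors=species_set.anchors,
        )
        genomes = {sp: g for sp, g in species_set.genomes.items() if sp != "sp7"}
        state = run_bootstrap_search(reference, genomes, species_set.phylogeny)
        assert not state.results["sp7"].accepted
        assert state.results["sp7"].reason == "no_assembly_window"

    def test_reference_validation(self):
        with pytest.raises(ValueError):
            ReferenceLocus(
                "sp0", GenomicInterval("s", 0, 10), [], {"a": "MKV"}
            ).validate()
        with pytest.raises(ValueError):
            ReferenceLocus(
                "sp0", GenomicInterval("s", 0, 10), ["ACGT", "ACG"], {"a": "MKV"}
            ).validate()
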