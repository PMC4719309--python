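import numpy as np
import pytest

from roxevol.model import reverse_complement
from roxevol.synthetic_data import (
    AnnotationPlan,
    ConservationPlan,
    LncRNAPlan,
    PeakPlan,
    SimulationConfig,
    child_rng,
    generate_annotated_scaffold,
    generate_chirp_experiment,
    generate_conservation_set,
    generate_species_set,
    random_sequence,
    scramble_sequence,
)


class TestDeterminism:
    def test_child_rng_reproducible_and_label_separated(self):
        a = child_rng(5, "x").integers(0, 1_000_000, size=10)
        b = child_rng(5, "x").integers(0, 1_000_000, size=10)
        c = child_rng(5, "y").integers(0, 1_000_000, size=10)
        np.testing.assert_array_equal(a, b)
        assert not np.array_equal(a, c)

    def test_scramble_preserves_composition(self):
        seq = "AAACCCGGGTTTTTT"
        (scrambled,) = scramble_sequence(seq, 1, seed=3)
        assert sorted(scrambled) == sorted(seq)
        assert scramble_sequence(seq, 2, seed=3) == scramble_sequence(seq, 2, seed=3)

    def test_scramble_empty_rejected(self):
        with pytest.raises(ValueError):
            scramble_sequence("", 1, 0)


@pytest.fixture(scope="module")
def species_set():
    return generate_species_set(SimulationConfig(seed=0))


class TestSpeciesSet:
    def test_truth_motifs_present_in_reference(self, species_set):
        cfg = species_set.config
        row = species_set.truth.set_index("species").loc[cfg.reference]
        seq = species_set.genomes[cfg.reference].scaffolds[row["scaffold"]]
        motif = cfg.lncrna.motif_consensus
        starts = [int(s) for s in row["motif_starts"].split(";")]
        assert len(starts) == cfg.lncrna.n_motifs
        for start in starts:
            assert seq[start : start + len(motif)] == motif

    def test_motif_units_fold_into_hairpins(self, species_set):
        cfg = species_set.config
        row = species_set.truth.set_index("species").loc[cfg.reference]
        seq = species_set.genomes[cfg.reference].scaffolds[row["scaffold"]]
        arm = cfg.lncrna.stem_arm
        loop = cfg.lncrna.loop_length
        start = int(row["motif_starts"].split(";")[0])
        arm5 = seq[start : start + arm]
        arm3 = seq[start + arm + loop : start + 2 * arm + loop]
        assert arm3 == reverse_complement(arm5)

    def test_cds_divergence_third_position_only(self, species_set):
        cfg = species_set.config
        ref = np.array(list(species_set.genomes[cfg.reference].scaffolds["scf1"]))
        far = np.array(list(species_set.genomes["sp7"].scaffolds["scf1"]))
        diff = np.flatnonzero(ref != far)
        gene = species_set.gene_models["sp7"][0]
        cds = gene.transcripts[0].cds[0]
        inside = diff[(diff >= cds.start) & (diff < cds.end)]
        assert inside.size > 0  # divergence did touch the CDS
        # CDS starts are phase-0 relative to the scaffold origin
        assert ((inside % 3) == 2).all()

    def test_noncoding_divergence_near_nominal_rate(self, species_set):
        cfg = species_set.config
        ref = np.array(list(species_set.genomes[cfg.reference].scaffolds["scf1"]))
        far = np.array(list(species_set.genomes["sp7"].scaffolds["scf1"]))
        genes = species_set.gene_models["sp7"]
        mask = np.ones(len(ref), dtype=bool)
        for g in genes:
            span = g.span
            mask[span.start : span.end] = False
        rate = (ref != far)[mask].mean()
        nominal = cfg.substitution_rates["sp7"]
        se = np.sqrt(nominal * (1 - nominal) / mask.sum())
        assert abs(rate - nominal) < 4 * se

    def test_decoy_locus_scrambled_but_anchors_intact(self):
        cfg = SimulationConfig(seed=0, decoy_species=["sp3"])
        ss = generate_species_set(cfg)
        row = ss.truth.set_index("species").loc["sp3"]
        assert bool(row["decoy"])
        motif = cfg.lncrna.motif_consensus
        seq = ss.genomes["sp3"].scaffolds["scf1"]
        starts = [int(s) for s in row["motif_starts"].split(";")]
        assert any(seq[s : s + len(motif)] != motif for s in starts)
        # anchors still findable: CDS intervals unchanged
        gene = ss.gene_models["sp3"][0]
        assert gene.gene_id == "anchorA"

    def test_identity_maps_and_chains(self, species_set):
        cmap = species_set.coordinate_maps["sp4"]
        assert cmap.map_point("scf1", 1234) == ("scf1", 1234)
        row = species_set.chain_tables["sp4"].row("scf1")
        assert row["A"] > row["B"]

    def test_validation_errors(self):
        with pytest.raises(ValueError):
            generate_species_set(SimulationConfig(reference="nope", seed=0))
        with pytest.raises(ValueError):
            generate_species_set(SimulationConfig(scaffold_length=100, seed=0))


class TestAnnotatedScaffold:
    def test_structure_and_planted_ppts(self):
        plan = AnnotationPlan()
        sc = generate_annotated_scaffold("chrT", 60_000, plan, child_rng(0, "t"))
        assert 0 < len(sc.genes) <= plan.n_genes
        strands = [g.strand for g in sc.genes]
        assert strands[:2] == ["+", "-"]
        assert len(sc.ppts) == len(sc.genes) * plan.n_introns
        seq = "".join(sc.sequence)
        d_lo, d_hi = plan.ppt_end_distance_range
        pyr_count = base_count = 0
        for _, row in sc.ppts.iterrows():
            tract = seq[row["start"] : row["end"]]
            if row["strand"] == "-":
                tract = reverse_complement(tract)
            pyr_count += sum(c in "CT" for c in tract)
            base_count += len(tract)
            gene = next(g for g in sc.genes if g.gene_id == row["gene_id"])
            intron = gene.transcripts[0].introns()[row["intron_index"]]
            # distance from the tract to the 3' splice site, in gene orientation
            if row["strand"] == "+":
                dist = intron.end - row["end"]
            else:
                dist = row["start"] - intron.start
            assert d_lo <= dist <= d_hi
        # per-base Bernoulli planting at 0.9: check the aggregate fraction
        frac = pyr_count / base_count
        se = np.sqrt(0.9 * 0.1 / base_count)
        assert abs(frac - 0.9) < 4 * se


@pytest.fixture(scope="module")
def experiment():
    return generate_chirp_experiment(
        {"chrX": 300_000, "chr2": 100_000}, {"chrX": "A", "chr2": "B"},
        PeakPlan(), seed=0,
    )


class TestChirpExperiment:
    def test_deterministic(self):
        kwargs = dict(me_labels={"chrX": "A"}, plan=PeakPlan(n_peaks={"chrX": 10}),
                      seed=9)
        a = generate_chirp_experiment({"chrX": 300_000}, **kwargs)
        b = generate_chirp_experiment({"chrX": 300_000}, **kwargs)
        assert [p.summit for p in a.peaks] == [p.summit for p in b.peaks]
        np.testing.assert_array_equal(a.input_track.values["chrX"],
                                      b.input_track.values["chrX"])

    def test_peak_counts(self, experiment):
        plan = PeakPlan()
        assert len(experiment.peaks) == sum(plan.n_peaks.values())

    def test_proximal_summits_near_planted_ppts(self, experiment):
        plan = PeakPlan()
        mids = experiment.ppts.groupby("scaffold")["midpoint"]
        for _, row in experiment.truth.iterrows():
            dist = (mids.get_group(row["scaffold"]) - row["summit"]).abs().min()
            if row["ppt_proximal"]:
                assert dist <= plan.proximity_window
            else:
                assert dist > plan.proximity_window

    def test_mre_planted_at_summits(self, experiment):
        plan = PeakPlan()
        motif = plan.mre_consensus
        for _, row in experiment.truth.iterrows():
            seq = experiment.genome.scaffolds[row["scaffold"]]
            start = row["summit"] - len(motif) // 2
            window = seq[start : start + len(motif)]
            expected = motif if row["motif_genomic_strand"] == "+" else \
                reverse_complement(motif)
            assert window == expected

    def test_realized_enrichment_near_planned_fold(self, experiment):
        med = experiment.truth["enrichment"].median()
        assert 15.0 < med < 25.0

    def test_feature_peaks_forced_into_class(self):
        plan = PeakPlan(n_peaks={}, ppt_proximal_fraction=0.0,
                        feature_peaks={"chrX": {"intron": 20, "CDS": 20}})
        exp = generate_chirp_experiment({"chrX": 300_000}, {"chrX": "A"}, plan,
                                        seed=4)
        counts = exp.truth["feature"].value_counts()
        assert counts.get("intron", 0) == 20
        assert counts.get("CDS", 0) == 20

    def test_signal_tracks_cover_scaffolds(self, experiment):
        assert set(experiment.chirp) == {"roX1", "roX2"}
        for track in experiment.chirp.values():
            assert set(track.values) == {"chrX", "chr2"}


class TestConservationSet:
    def test_universal_genes_bound_everywhere(self):
        plan = ConservationPlan()
        cons = generate_conservation_set(plan, seed=0)
        truth = cons.truth
        universal_groups = truth[truth["universal"]]["group"].unique()
        for g in universal_groups:
            species_bound = set(truth[truth["group"] == g]["species"])
            assert species_bound == set(plan.species)

    def test_exact_position_peaks_colocate(self):
        plan = ConservationPlan(exact_position_fraction=1.0,
                                species_specific_rate=0.0)
        cons = generate_conservation_set(plan, seed=1)
        truth = cons.truth
        for g, grp in truth.groupby("group"):
            assert grp["summit"].nunique() == 1

    def test_orthology_table_shape(self):
        plan = ConservationPlan()
        cons = generate_conservation_set(plan, seed=0)
        assert list(cons.orthology.columns) == plan.species
        assert len(cons.orthology) == plan.n_genes
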