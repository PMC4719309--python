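"""End-to-end orchestration of the synthetic study.

``run_pipeline`` drives: simulate -> ortholog search -> sequence
conservation -> windowed enrichment + ME assignment -> peak filtering and
RNA bias -> cross-species conservation and turnover -> PPT proximity ->
motif orientation bias -> spacing, writing a tab table per stage plus a run
manifest (config hash, seed, stage outputs with checksums). Every
stochastic stage derives its generator from the single configured seed, so
a rerun with the same config is byte-identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .chirp_enrichment import (
    assign_all_scaffolds,
    filter_peaks,
    rox_bias,
    window_enrichment,
)
from .conservation_seq import identity_matrix
from .has_conservation import (
    associate_genes,
    classify_gene_conservation,
    turnover_null,
)
from .motif import PWM
from .ortholog_search import ReferenceLocus, SearchConfig, run_bootstrap_search
from .regulatory_context import (
    feature_assignment,
    orientation_bias,
    peak_ppt_proximity,
    select_ppts,
)
from .spacing import evenness_score, nearest_neighbor_distances
from .synthetic_data import (
    ConservationPlan,
    PeakPlan,
    SimulationConfig,
    generate_chirp_experiment,
    generate_conservation_set,
    generate_species_set,
)
from .model import GenomicInterval

logger = logging.getLogger(__name__)

DEFAULT_CONFIG: dict = {
    "seed": 0,
    "enrichment_window_bp": 1000,
    "me_cutoff": 0.85,
    "gene_distance_bp": 1000,
    "utr5_extension_bp": 200,
    "utr3_extension_bp": 500,
    "ppt_free_zone_bp": 40,
    "ppt_penalty_per_base": 0.02,
    "ppt_window_bp": 100,
    "cluster_span_bp": 500,
    "min_cluster_hits": 3,
    "stem_threshold": 6.0,
    "peak_q_min": 3000.0,
    "peak_enrichment_min": 20.0,
    "strong_q_min": 10000.0,
    "strong_enrichment_min": 50.0,
    "n_permutations": 50,
    "ppt_proximal_fraction": 0.20,
    "orientation_bias_probability": 0.8,
    "n_x_peaks": 50,
    "n_autosome_peaks": 2,
    "enrichment_fold": 20.0,
}

_FRACTION_FIELDS = ("ppt_proximal_fraction", "orientation_bias_probability")


def validate_config(config: dict) -> dict:
    """Merge with defaults and check field ranges; errors name the field."""
    merged = dict(DEFAULT_CONFIG)
    for key, value in config.items():
        if key not in DEFAULT_CONFIG:
            raise ValueError(f"unknown config field: {key}")
        merged[key] = value
    for key in _FRACTION_FIELDS:
        if not 0.0 <= merged[key] <= 1.0:
            raise ValueError(f"config field {key}: value {merged[key]} outside [0, 1]")
    for key, value in merged.items():
        if key in _FRACTION_FIELDS or key == "seed":
            continue
        if isinstance(value, (int, float)) and value < 0:
            raise ValueError(f"config field {key}: must be non-negative")
    return merged


def _config_hash(config: dict) -> str:
    return hashlib.sha256(
        json.dumps(config, sort_keys=True).encode()
    ).hexdigest()[:16]


def _write(out_dir: Path, name: str, frame: pd.DataFrame) -> Path:
    path = out_dir / name
    frame.to_csv(path, sep="\t", index=False)
    return path


def run_pipeline(config: dict | None = None, out_dir: str | Path = "results") -> dict:
    """Run every stage on the synthetic study set; returns the manifest dict."""
    config = validate_config(config or {})
    seed = int(config["seed"])
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "version": __version__,
        "seed": seed,
        "config_hash": _config_hash(config),
        "config": config,
        "stages": {},
    }

    def record(stage: str, started: float, paths: list[Path], **metrics):
        manifest["stages"][stage] = {
            "seconds": round(time.time() - started, 2),
            "outputs": {
                p.name: hashlib.sha256(p.read_bytes()).hexdigest()[:16] for p in paths
            },
            **metrics,
        }
        logger.info("stage %s done (%.1fs)", stage, time.time() - started)

    # ---- simulate -------------------------------------------------------
    t0 = time.time()
    sim_config = SimulationConfig(seed=seed)
    species_set = generate_species_set(sim_config)
    plan = PeakPlan(
        n_peaks={"chrX": config["n_x_peaks"], "chr2": config["n_autosome_peaks"]},
        rna_folds={"roX1": config["enrichment_fold"], "roX2": config["enrichment_fold"]},
        ppt_proximal_fraction=config["ppt_proximal_fraction"],
        orientation_bias={
            "intron": ("-", config["orientation_bias_probability"]),
            "CDS": ("+", config["orientation_bias_probability"]),
        },
    )
    experiment = generate_chirp_experiment(
        {"chrX": 300_000, "chr2": 100_000},
        {"chrX": "A", "chr2": "B"},
        plan,
        seed=seed,
    )
    paths = [
        _write(out, "simulated_loci.tsv", species_set.truth),
        _write(out, "simulated_peaks.tsv", experiment.truth),
    ]
    record("simulate", t0, paths, n_species=len(sim_config.species))

    # ---- ortholog search ------------------------------------------------
    t0 = time.time()
    ref_row = species_set.truth[
        species_set.truth["species"] == sim_config.reference
    ].iloc[0]
    reference = ReferenceLocus(
        species=sim_config.reference,
        interval=GenomicInterval(
            ref_row["scaffold"], int(ref_row["locus_start"]), int(ref_row["locus_end"])
        ),
        motif_instances=species_set.motif_instances,
        primary_anchors=species_set.anchors,
    )
    search_cfg = SearchConfig(
        cluster_span=config["cluster_span_bp"],
        min_hits=config["min_cluster_hits"],
        stem_threshold=config["stem_threshold"],
    )
    state = run_bootstrap_search(
        reference, species_set.genomes, species_set.phylogeny, search_cfg
    )
    search_table = pd.DataFrame(
        [
            {
                "species": sp,
                "accepted": c.accepted,
                "reason": c.reason,
                "start": c.interval.start if c.interval else -1,
                "end": c.interval.end if c.interval else -1,
                "n_hits": len(c.motif_hits),
                "stem_score": c.stem_score,
            }
            for sp, c in state.results.items()
        ]
    )
    paths = [_write(out, "ortholog_search.tsv", search_table)]
    record(
        "search", t0, paths,
        n_accepted=int(search_table["accepted"].sum()),
    )

    # ---- sequence conservation -----------------------------------------
    t0 = time.time()
    locus_seqs = {
        row["species"]: species_set.genomes[row["species"]].scaffolds[row["scaffold"]][
            int(row["locus_start"]) : int(row["locus_end"])
        ]
        for _, row in species_set.truth.iterrows()
    }
    matrix = identity_matrix(locus_seqs, sim_config.reference, n_scrambles=2, seed=seed)
    conservation_table = pd.DataFrame(
        matrix.values, index=matrix.species, columns=matrix.species
    ).reset_index(names="species")
    paths = [_write(out, "identity_matrix.tsv", conservation_table)]
    record("conserve", t0, paths, homology_floor=round(matrix.floor, 2))

    # ---- enrichment + ME assignment ------------------------------------
    t0 = time.time()
    enrich = window_enrichment(
        experiment.chirp["roX2"],
        experiment.input_track,
        window_bp=config["enrichment_window_bp"],
    )
    assignments = {
        sp: assign_all_scaffolds(table, config["me_cutoff"])
        for sp, table in species_set.chain_tables.items()
    }
    me_table = pd.DataFrame(
        [
            {"species": sp, "scaffold": scaffold, "me": a.label, "best": a.best_score}
            for sp, per in assignments.items()
            for scaffold, a in per.items()
        ]
    )
    paths = [
        _write(out, "window_enrichment.tsv", enrich),
        _write(out, "me_assignments.tsv", me_table),
    ]
    record("enrich", t0, paths)

    # ---- filtering + RNA bias ------------------------------------------
    t0 = time.time()
    kept = filter_peaks(
        experiment.peaks, config["peak_q_min"], config["peak_enrichment_min"]
    )
    bias = rox_bias(experiment.peaks, "roX1", "roX2")
    bias_table = pd.DataFrame(
        [{"percentile": q, "log2_ratio": v} for q, v in bias.percentiles.items()]
    )
    paths = [_write(out, "rox_bias.tsv", bias_table)]
    record(
        "filter", t0, paths,
        n_peaks=len(experiment.peaks), n_kept=len(kept),
        median_fraction=round(bias.median_fraction, 3),
    )

    # ---- gene conservation + turnover ----------------------------------
    t0 = time.time()
    conservation = generate_conservation_set(ConservationPlan(), seed=seed)
    associations = {
        sp: associate_genes(
            conservation.peaks[sp],
            conservation.gene_models[sp],
            config["gene_distance_bp"],
            config["utr5_extension_bp"],
            config["utr3_extension_bp"],
            species=sp,
        )
        for sp in conservation.gene_models
    }
    gene_cons = classify_gene_conservation(associations, conservation.orthology)
    sp_a, sp_b = list(conservation.gene_models)[:2]
    null = turnover_null(
        conservation.peaks[sp_a],
        conservation.coordinate_maps[(sp_a, sp_b)],
        conservation.peaks[sp_b],
        {"chrX": conservation.scaffold_length},
        n_perm=config["n_permutations"],
        seed=seed,
    )
    turnover_table = pd.DataFrame(
        {
            "distance": null.d_grid,
            "observed": null.observed_fraction,
            "null": null.null_fraction,
            "ratio": null.ratio,
        }
    )
    paths = [_write(out, "turnover.tsv", turnover_table)]
    record(
        "evolve", t0, paths,
        shared_all_genes=gene_cons.shared_all_count,
        ratio_at_0=round(float(null.ratio[0]), 2) if np.isfinite(null.ratio[0]) else None,
    )

    # ---- PPT proximity --------------------------------------------------
    t0 = time.time()
    ppts = select_ppts(experiment.gene_models, experiment.genome)
    lengths = {s: experiment.genome.length(s) for s in experiment.genome.scaffolds}
    proximity = peak_ppt_proximity(
        experiment.peaks, ppts, lengths,
        n_perm=config["n_permutations"], seed=seed,
        window=config["ppt_window_bp"],
    )
    ppt_table = pd.DataFrame(
        [
            {
                "observed_fraction": proximity.observed_fraction_within,
                "permuted_fraction": proximity.permuted_fraction_within,
                "ks_statistic": proximity.ks_statistic,
                "ks_p": proximity.ks_p_value,
            }
        ]
    )
    paths = [_write(out, "ppt_proximity.tsv", ppt_table), _write(out, "ppts.tsv", ppts)]
    record("ppt", t0, paths,
           observed=round(proximity.observed_fraction_within, 3),
           permuted=round(proximity.permuted_fraction_within, 3))

    # ---- orientation bias + features ------------------------------------
    t0 = time.time()
    mre = PWM.from_instances([PeakPlan().mre_consensus])
    bias_result = orientation_bias(
        experiment.peaks, mre, experiment.gene_models, experiment.genome
    )
    features = feature_assignment(experiment.peaks, experiment.gene_models, lengths)
    paths = [
        _write(out, "orientation_bias.tsv", bias_result.counts),
        _write(out, "feature_enrichment.tsv", features),
    ]
    record("motif_bias", t0, paths)

    # ---- spacing --------------------------------------------------------
    t0 = time.time()
    rows = []
    for regime in ("even", "random", "clustered"):
        regime_plan = PeakPlan(
            n_peaks={"chrX": 72}, spacing_regime=regime, ppt_proximal_fraction=0.0
        )
        exp = generate_chirp_experiment(
            {"chrX": 400_000}, {"chrX": "A"}, regime_plan, seed=seed,
        )
        summits = [p.summit for p in exp.peaks]
        rows.append(
            {
                "regime": regime,
                "n_peaks": len(summits),
                "evenness": evenness_score(summits, 400_000, n_perm=50, seed=seed),
                "mean_nn": float(np.mean(nearest_neighbor_distances(summits))),
            }
        )
    spacing_table = pd.DataFrame(rows)
    paths = [_write(out, "spacing.tsv", spacing_table)]
    record("spacing", t0, paths)

    manifest_path = out / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2, default=str))
    return manifest
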