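"""Synthetic multi-species fixtures with the structure the pipeline assumes.

Emulated regimes: multi-species genomes whose single study scaffold carries
two anchor protein-coding genes flanking a planted lncRNA locus built from
motif-bearing stem-loops; X-enriched ChIRP-style experiments with planted
GA-repeat motifs, intronic polypyrimidine tracts (PPTs), configurable
summit-to-PPT proximity, per-feature motif orientation biases, and
clustered/random/even peak spacing regimes; and multi-species peak sets
with a planted fraction of universally bound orthologous genes.

Everything is deterministic under a fixed seed: submodules derive child
generators by hashing a label into the root seed.

Limits by construction: species diverge by substitutions only (no indels),
so the cross-species coordinate maps are exact whole-scaffold identity
blocks; input coverage is flat-plus-Poisson; ChIRP coverage is background
plus a triangular bump over each planted peak.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .model import (
    ChainScoreTable,
    CoordinateMap,
    GeneModel,
    Genome,
    GenomicInterval,
    MapBlock,
    Peak,
    Phylogeny,
    SignalTrack,
    Transcript,
    reverse_complement,
)

_BASES = np.array(list("ACGT"))

# standard codon table, one deterministic codon list per amino acid
_CODONS: dict[str, list[str]] = {}
_TABLE = {
    "TTT": "F", "TTC": "F", "TTA": "L", "TTG": "L", "CTT": "L", "CTC": "L",
    "CTA": "L", "CTG": "L", "ATT": "I", "ATC": "I", "ATA": "I", "ATG": "M",
    "GTT": "V", "GTC": "V", "GTA": "V", "GTG": "V", "TCT": "S", "TCC": "S",
    "TCA": "S", "TCG": "S", "CCT": "P", "CCC": "P", "CCA": "P", "CCG": "P",
    "ACT": "T", "ACC": "T", "ACA": "T", "ACG": "T", "GCT": "A", "GCC": "A",
    "GCA": "A", "GCG": "A", "TAT": "Y", "TAC": "Y", "CAT": "H", "CAC": "H",
    "CAA": "Q", "CAG": "Q", "AAT": "N", "AAC": "N", "AAA": "K", "AAG": "K",
    "GAT": "D", "GAC": "D", "GAA": "E", "GAG": "E", "TGT": "C", "TGC": "C",
    "TGG": "W", "CGT": "R", "CGC": "R", "CGA": "R", "CGG": "R", "AGT": "S",
    "AGC": "S", "AGA": "R", "AGG": "R", "GGT": "G", "GGC": "G", "GGA": "G",
    "GGG": "G",
}
for codon, aa in _TABLE.items():
    _CODONS.setdefault(aa, []).append(codon)


def child_rng(seed: int, label: str) -> np.random.Generator:
    """Deterministic child generator derived from a root seed and a label."""
    return np.random.default_rng(
        np.random.SeedSequence([int(seed) % (2**31), zlib.crc32(label.encode())])
    )


def random_sequence(length: int, rng: np.random.Generator, p=None) -> str:
    return "".join(rng.choice(_BASES, size=length, p=p))


def scramble_sequence(sequence: str, n_copies: int, seed: int) -> list[str]:
    """Uniform random permutations of the input letters (composition preserved)."""
    if not sequence:
        raise ValueError("sequence must be non-empty")
    rng = child_rng(seed, "scramble")
    letters = np.array(list(sequence))
    return ["".join(rng.permutation(letters)) for _ in range(n_copies)]


# ---------------------------------------------------------------------------
# Species set for the ortholog search


@dataclass
class LncRNAPlan:
    motif_consensus: str = "GCTTGTGA"  # roXbox-like 8-mer
    n_motifs: int = 6
    stem_arm: int = 12
    loop_length: int = 6
    spacer_length: int = 25


@dataclass
class SimulationConfig:
    """Study conditions for the multi-species ortholog-search fixture.

    The default emulates an eight-species clade at increasing noncoding
    divergence from the reference (per-base substitution rates up to 6%),
    within which motif clusters remain detectable — the regime the
    clade-by-clade bootstrap search is designed for.
    """

    species: list[str] = field(
        default_factory=lambda: [f"sp{i}" for i in range(8)]
    )
    newick: str = (
        "((((sp0:0.01,sp1:0.01):0.01,(sp2:0.01,sp3:0.02):0.01):0.02,"
        "(sp4:0.02,sp5:0.03):0.02):0.02,(sp6:0.04,sp7:0.05):0.03);"
    )
    reference: str = "sp0"
    scaffold_length: int = 20_000
    me_label: str = "A"
    substitution_rates: dict[str, float] = field(
        default_factory=lambda: {
            "sp0": 0.0, "sp1": 0.01, "sp2": 0.02, "sp3": 0.03,
            "sp4": 0.04, "sp5": 0.05, "sp6": 0.05, "sp7": 0.06,
        }
    )
    anchor_length_aa: int = 60
    anchor_gap: int = 2_000
    lncrna: LncRNAPlan = field(default_factory=LncRNAPlan)
    decoy_species: list[str] = field(default_factory=list)
    seed: int = 0

    def validate(self) -> None:
        for s in self.species:
            if s not in self.substitution_rates:
                raise ValueError(f"no substitution rate for species {s}")
            if not 0.0 <= self.substitution_rates[s] <= 1.0:
                raise ValueError(f"substitution rate for {s} out of [0,1]")
        if self.reference not in self.species:
            raise ValueError("reference species missing from species list")


@dataclass
class SpeciesSet:
    genomes: dict[str, Genome]
    gene_models: dict[str, list[GeneModel]]
    coordinate_maps: dict[str, CoordinateMap]  # species -> map species->reference
    chain_tables: dict[str, ChainScoreTable]
    phylogeny: Phylogeny
    truth: pd.DataFrame  # species, scaffold, locus_start, locus_end, motif_starts
    anchors: dict[str, str]  # gene_id -> protein sequence
    motif_instances: list[str]
    config: SimulationConfig


def _protein(rng: np.random.Generator, length: int) -> str:
    aas = np.array(sorted(_CODONS))
    return "".join(rng.choice(aas, size=length))


def _encode_protein(protein: str, rng: np.random.Generator) -> str:
    return "".join(rng.choice(_CODONS[aa]) for aa in protein)


def _build_lncrna_locus(plan: LncRNAPlan, rng: np.random.Generator):
    """Stem-loop units whose 5' arms carry the motif; returns (seq, motif offsets)."""
    motif = plan.motif_consensus.upper()
    if plan.stem_arm < len(motif):
        raise ValueError("stem arm shorter than motif")
    parts, offsets, pos = [], [], 0
    for _ in range(plan.n_motifs):
        pad = plan.stem_arm - len(motif)
        arm5 = motif + random_sequence(pad, rng)
        loop = random_sequence(plan.loop_length, rng)
        unit = arm5 + loop + reverse_complement(arm5)
        spacer = random_sequence(plan.spacer_length, rng)
        offsets.append(pos)
        parts.append(unit + spacer)
        pos += len(unit) + len(spacer)
    return "".join(parts), offsets


def _mutate(
    seq: np.ndarray,
    rate: float,
    cds_mask: np.ndarray,
    rng: np.random.Generator,
) -> np.ndarray:
    """Substitute bases at ``rate``; inside CDS only third-codon positions
    (synonymous-biased) so the translated anchor search stays solvable."""
    out = seq.copy()
    n = len(seq)
    hit = rng.random(n) < rate
    third = np.zeros(n, dtype=bool)
    third[2::3] = True  # phase fixed at scaffold origin; CDS starts are phase-0
    hit &= ~cds_mask | (cds_mask & third)
    for i in np.flatnonzero(hit):
        choices = [b for b in "ACGT" if b != out[i]]
        out[i] = choices[rng.integers(3)]
    return out


def generate_species_set(config: SimulationConfig | None = None) -> SpeciesSet:
    """Reference genome plus diverged copies with exact truth tables.

    Layout per scaffold: background — anchor A CDS — gap — lncRNA locus —
    gap — anchor B CDS — background. Coordinate maps are exact identity
    blocks (divergence is substitution-only). Decoy species get their lncRNA
    locus scrambled after divergence (anchors intact).
    """
    config = config or SimulationConfig()
    config.validate()
    cfg = config
    rng = child_rng(cfg.seed, "species_set")

    anchors = {
        "anchorA": _protein(child_rng(cfg.seed, "anchorA"), cfg.anchor_length_aa),
        "anchorB": _protein(child_rng(cfg.seed, "anchorB"), cfg.anchor_length_aa),
    }
    cds_a = _encode_protein(anchors["anchorA"], rng)
    cds_b = _encode_protein(anchors["anchorB"], rng)
    locus_seq, motif_offsets = _build_lncrna_locus(cfg.lncrna, rng)

    layout_len = len(cds_a) + cfg.anchor_gap + len(locus_seq) + cfg.anchor_gap + len(cds_b)
    margin = cfg.scaffold_length - layout_len
    if margin < 2:
        raise ValueError(
            f"scaffold scf1 too short for layout ({layout_len} bp needed)"
        )
    left = margin // 2
    # keep CDS in phase 0 relative to the scaffold for the synonymous mask
    left -= left % 3

    a_start = left
    a_end = a_start + len(cds_a)
    locus_start = a_end + cfg.anchor_gap
    locus_end = locus_start + len(locus_seq)
    b_start = locus_end + cfg.anchor_gap
    b_start -= (b_start - a_start) % 3  # phase 0 too
    b_end = b_start + len(cds_b)

    background = random_sequence(cfg.scaffold_length, rng)
    ref = np.array(list(background))
    ref[a_start:a_end] = list(cds_a)
    ref[locus_start:locus_end] = list(locus_seq)
    ref[b_start:b_end] = list(cds_b)

    cds_mask = np.zeros(cfg.scaffold_length, dtype=bool)
    cds_mask[a_start:a_end] = True
    cds_mask[b_start:b_end] = True

    scaffold = "scf1"
    genomes: dict[str, Genome] = {}
    gene_models: dict[str, list[GeneModel]] = {}
    coordinate_maps: dict[str, CoordinateMap] = {}
    chain_tables: dict[str, ChainScoreTable] = {}
    rows = []

    for species in cfg.species:
        rate = cfg.substitution_rates[species]
        srng = child_rng(cfg.seed, f"mutate:{species}")
        seq = _mutate(ref, rate, cds_mask, srng)
        if species in cfg.decoy_species:
            region = "".join(seq[locus_start:locus_end])
            scrambled = scramble_sequence(
                region, 1, cfg.seed + zlib.crc32(species.encode()) % 10_000
            )[0]
            seq[locus_start:locus_end] = list(scrambled)
        genomes[species] = Genome({scaffold: "".join(seq)}, {scaffold: cfg.me_label})
        gene_models[species] = [
            _single_exon_gene("anchorA", scaffold, a_start, a_end, "+"),
            _single_exon_gene("anchorB", scaffold, b_start, b_end, "+"),
        ]
        coordinate_maps[species] = CoordinateMap(
            [
                MapBlock(
                    source=GenomicInterval(scaffold, 0, cfg.scaffold_length),
                    target=GenomicInterval(scaffold, 0, cfg.scaffold_length),
                    orientation="+",
                )
            ]
        )
        chain_tables[species] = ChainScoreTable(
            {scaffold: {me: (1000.0 if me == cfg.me_label else 10.0) for me in "ABCDEF"}}
        )
        rows.append(
            {
                "species": species,
                "scaffold": scaffold,
                "locus_start": locus_start,
                "locus_end": locus_end,
                "decoy": species in cfg.decoy_species,
                "motif_starts": ";".join(
                    str(locus_start + off) for off in motif_offsets
                ),
            }
        )

    from .io_formats import load_phylogeny

    return SpeciesSet(
        genomes=genomes,
        gene_models=gene_models,
        coordinate_maps=coordinate_maps,
        chain_tables=chain_tables,
        phylogeny=load_phylogeny(cfg.newick),
        truth=pd.DataFrame(rows),
        anchors=anchors,
        motif_instances=[cfg.lncrna.motif_consensus] * cfg.lncrna.n_motifs,
        config=cfg,
    )


def _single_exon_gene(
    gene_id: str, scaffold: str, start: int, end: int, strand: str
) -> GeneModel:
    exon = GenomicInterval(scaffold, start, end, strand)
    return GeneModel(
        gene_id=gene_id,
        transcripts=[Transcript(transcript_id=f"{gene_id}.t1", exons=[exon], cds=[exon])],
    )


# ---------------------------------------------------------------------------
# Annotated scaffolds with intronic PPTs


@dataclass
class AnnotationPlan:
    n_genes: int = 30
    exon_length: int = 300
    intron_length: int = 600
    n_introns: int = 2
    intergenic_length: int = 700
    ppt_length_range: tuple[int, int] = (12, 25)
    ppt_pyrimidine_fraction: float = 0.9
    ppt_end_distance_range: tuple[int, int] = (5, 40)
    annotate_utrs: bool = False
    utr_length: int = 150


@dataclass
class AnnotatedScaffold:
    name: str
    sequence: np.ndarray  # mutable character array
    genes: list[GeneModel]
    ppts: pd.DataFrame  # gene_id, intron index, start, end, strand, midpoint

    @property
    def length(self) -> int:
        return len(self.sequence)


def generate_annotated_scaffold(
    name: str,
    length: int,
    plan: AnnotationPlan,
    rng: np.random.Generator,
) -> AnnotatedScaffold:
    """Tile genes (alternating strand) with introns carrying planted PPTs.

    Each intron receives one C/T-rich tract (pyrimidine fraction per plan)
    on the transcribed strand, ending 5-40 bp upstream of the intron's 3'
    splice site — the penalty-free zone of the PPT selector.
    """
    seq = np.array(list(random_sequence(length, rng)))
    genes: list[GeneModel] = []
    ppt_rows = []
    gene_span = plan.n_introns * plan.intron_length + (plan.n_introns + 1) * plan.exon_length
    pos = plan.intergenic_length
    i = 0
    while pos + gene_span + plan.intergenic_length <= length and i < plan.n_genes:
        strand = "+" if i % 2 == 0 else "-"
        gene_id = f"{name}_g{i}"
        exons, cds, utr5, utr3 = [], [], [], []
        cursor = pos
        for e in range(plan.n_introns + 1):
            exon = GenomicInterval(name, cursor, cursor + plan.exon_length, strand)
            exons.append(exon)
            cursor = exon.end + (plan.intron_length if e < plan.n_introns else 0)
        if plan.annotate_utrs:
            first, last = exons[0], exons[-1]
            lo_utr = GenomicInterval(name, first.start, first.start + plan.utr_length, strand)
            hi_utr = GenomicInterval(name, last.end - plan.utr_length, last.end, strand)
            utr5, utr3 = ([lo_utr], [hi_utr]) if strand == "+" else ([hi_utr], [lo_utr])
            cds = [GenomicInterval(name, lo_utr.end, exons[0].end, strand)] + [
                GenomicInterval(name, e.start, e.end, strand) for e in exons[1:-1]
            ] + [GenomicInterval(name, exons[-1].start, hi_utr.start, strand)]
        else:
            cds = list(exons)
        tx = Transcript(
            transcript_id=f"{gene_id}.t1", exons=exons, cds=cds, utr5=utr5, utr3=utr3
        )
        gene = GeneModel(gene_id=gene_id, transcripts=[tx])
        genes.append(gene)
        for k, intron in enumerate(tx.introns()):
            row = _plant_ppt(seq, intron, strand, plan, rng)
            row.update({"gene_id": gene_id, "intron_index": k})
            ppt_rows.append(row)
        pos = cursor + plan.intergenic_length
        i += 1
    ppts = pd.DataFrame(
        ppt_rows,
        columns=["gene_id", "intron_index", "scaffold", "start", "end", "strand", "midpoint"],
    )
    return AnnotatedScaffold(name=name, sequence=seq, genes=genes, ppts=ppts)


def _plant_ppt(seq, intron, strand, plan, rng) -> dict:
    lo, hi = plan.ppt_length_range
    tract_len = int(rng.integers(lo, hi + 1))
    d_lo, d_hi = plan.ppt_end_distance_range
    dist = int(rng.integers(d_lo, d_hi + 1))
    pyr = plan.ppt_pyrimidine_fraction
    tract = "".join(
        rng.choice(["C", "T"]) if rng.random() < pyr else rng.choice(["A", "G"])
        for _ in range(tract_len)
    )
    if strand == "+":
        end = intron.end - dist
        start = end - tract_len
        seq[start:end] = list(tract)
    else:
        start = intron.start + dist
        end = start + tract_len
        seq[start:end] = list(reverse_complement(tract))
    return {
        "scaffold": intron.scaffold,
        "start": start,
        "end": end,
        "strand": strand,
        "midpoint": (start + end) // 2,
    }


# ---------------------------------------------------------------------------
# ChIRP-style experiments


@dataclass
class PeakPlan:
    """Planted-peak regime for one experiment.

    ``rna_folds`` gives per-RNA ChIRP enrichment folds (signal bias between
    the two lncRNAs is their ratio); ``ppt_proximal_fraction`` is the
    fraction of summits placed within 100 bp of a planted PPT midpoint;
    ``orientation_bias`` maps a feature class to (preferred orientation
    relative to the host gene, probability); spacing_regime is one of
    clustered / random / even.
    """

    n_peaks: dict[str, int] = field(default_factory=lambda: {"chrX": 50, "chr2": 2})
    #: extra peaks forced inside intervals of a feature class, per scaffold:
    #: {scaffold: {"intron": 100, "CDS": 100}}
    feature_peaks: dict[str, dict[str, int]] = field(default_factory=dict)
    peak_width: int = 200
    rna_folds: dict[str, float] = field(
        default_factory=lambda: {"roX1": 20.0, "roX2": 20.0}
    )
    ppt_proximal_fraction: float = 0.20
    proximity_window: int = 100
    orientation_bias: dict[str, tuple[str, float]] = field(
        default_factory=lambda: {"intron": ("-", 0.8), "CDS": ("+", 0.8)}
    )
    mre_consensus: str = "GAGAGAGAGA"
    spacing_regime: str = "random"
    background_mean: float = 10.0
    q_score_range: tuple[float, float] = (500.0, 30_000.0)
    enrichment_window: int = 1_000


@dataclass
class ChirpExperiment:
    genome: Genome
    gene_models: list[GeneModel]
    chirp: dict[str, SignalTrack]  # per RNA
    input_track: SignalTrack
    peaks: list[Peak]
    truth: pd.DataFrame
    ppts: pd.DataFrame


def _spacing_positions(
    n: int, length: int, regime: str, width: int, rng: np.random.Generator
) -> np.ndarray:
    margin = width // 2 + 1
    usable = length - 2 * margin
    if regime == "random":
        pos = rng.integers(margin, length - margin, size=n)
    elif regime == "even":
        step = usable / n
        jitter = rng.uniform(-0.05 * step, 0.05 * step, size=n)
        pos = margin + (np.arange(n) + 0.5) * step + jitter
    elif regime == "clustered":
        n_clusters = max(1, n // 10)
        centers = rng.integers(margin, length - margin, size=n_clusters)
        pos = rng.choice(centers, size=n) + rng.normal(0, width * 2, size=n)
        pos = np.clip(pos, margin, length - margin - 1)
    else:
        raise ValueError(f"unknown spacing regime {regime!r}")
    return np.sort(pos.astype(int))


def generate_chirp_experiment(
    scaffold_lengths: dict[str, int],
    me_labels: dict[str, str],
    plan: PeakPlan,
    seed: int,
    annotation_plan: AnnotationPlan | None = None,
) -> ChirpExperiment:
    """Annotated genome + paired ChIRP/input tracks + truth peaks.

    Input coverage is flat Poisson; each RNA's ChIRP coverage adds a
    triangular bump over every planted peak scaled so that the
    ``enrichment_window``-wide window holding the peak reaches the planned
    fold. Summits of the PPT-proximal subset land within ``proximity_window``
    bp of a planted PPT midpoint; every summit receives an MRE motif
    instance whose orientation follows the per-feature bias.
    """
    annotation_plan = annotation_plan or AnnotationPlan()
    rng = child_rng(seed, "chirp")
    scaffolds: dict[str, AnnotatedScaffold] = {}
    for name, length in scaffold_lengths.items():
        scaffolds[name] = generate_annotated_scaffold(
            name, length, annotation_plan, child_rng(seed, f"annot:{name}")
        )

    # ---- choose summit positions
    # summits of distinct peaks are kept at least one motif length apart so
    # that planted MREs never overwrite each other
    sep = len(plan.mre_consensus) + 2
    taken: dict[str, list[int]] = {}
    peak_rows = []
    for name, n in plan.n_peaks.items():
        if n == 0:
            continue
        sc = scaffolds[name]
        occupied = taken.setdefault(name, [])
        positions = _spacing_positions(
            n, sc.length, plan.spacing_regime, plan.peak_width, rng
        )
        n_prox = int(round(plan.ppt_proximal_fraction * n))
        if n_prox > 0 and sc.ppts.empty:
            raise ValueError(
                f"PPT-proximal peaks requested but scaffold {name} has no introns"
            )
        prox_idx = set(rng.choice(n, size=n_prox, replace=False)) if n_prox else set()
        margin = plan.peak_width // 2 + 1
        mids = sc.ppts["midpoint"].to_numpy() if not sc.ppts.empty else np.array([])

        def _avoid_ppt_windows(pos: int) -> int:
            # keep non-proximal summits out of the proximity window so the
            # realized proximal fraction matches the plan
            if mids.size:
                nearest = int(mids[np.argmin(np.abs(mids - pos))])
                if abs(nearest - pos) <= plan.proximity_window:
                    shift = plan.proximity_window + 50
                    pos = nearest + (shift if pos >= nearest else -shift)
            return int(np.clip(pos, margin, sc.length - margin - 1))

        for i, pos in enumerate(positions):
            if i in prox_idx:
                for _ in range(100):
                    mid = int(rng.choice(mids))
                    # offset magnitude kept in [20, window-5] so the MRE planted
                    # at the summit cannot overwrite the tract it is proximal to
                    magnitude = int(rng.integers(20, plan.proximity_window - 4))
                    offset = magnitude * (1 if rng.random() < 0.5 else -1)
                    pos = int(np.clip(mid + offset, margin, sc.length - margin - 1))
                    if all(abs(pos - t) >= sep for t in occupied):
                        break
                else:
                    raise ValueError(
                        f"could not place a PPT-proximal summit on {name}"
                    )
            else:
                pos = _avoid_ppt_windows(int(pos))
                attempts = 0
                while any(abs(pos - t) < sep for t in occupied):
                    conflict = min(occupied, key=lambda t: abs(pos - t))
                    pos = _avoid_ppt_windows(
                        conflict + (sep if pos >= conflict else -sep)
                    )
                    attempts += 1
                    if attempts > 100:
                        raise ValueError(f"could not separate summits on {name}")
            occupied.append(int(pos))
            peak_rows.append({"scaffold": name, "summit": int(pos), "ppt_proximal": i in prox_idx})

    # extra peaks forced inside intervals of a requested feature class
    motif_len = len(plan.mre_consensus)
    for name, per_class in plan.feature_peaks.items():
        sc = scaffolds[name]
        pools: dict[str, list[GenomicInterval]] = {"intron": [], "CDS": []}
        for gene in sc.genes:
            for tx in gene.transcripts:
                pools["intron"].extend(tx.introns())
                pools["CDS"].extend(tx.cds)
        occupied = taken.setdefault(name, [])
        for cls, count in per_class.items():
            pool = [iv for iv in pools.get(cls, []) if len(iv) > 2 * motif_len + 4]
            if not pool:
                raise ValueError(f"no {cls} intervals on scaffold {name}")
            for _ in range(count):
                for _ in range(100):
                    iv = pool[rng.integers(len(pool))]
                    pos = int(rng.integers(iv.start + motif_len, iv.end - motif_len))
                    if all(abs(pos - t) >= sep for t in occupied):
                        break
                else:
                    raise ValueError(f"could not separate {cls} summits on {name}")
                occupied.append(pos)
                peak_rows.append(
                    {"scaffold": name, "summit": pos, "ppt_proximal": False}
                )

    # ---- plant MRE motifs with per-feature orientation bias
    from .regulatory_context import classify_summit  # late import avoids a cycle

    motif = plan.mre_consensus.upper()
    for row in peak_rows:
        sc = scaffolds[row["scaffold"]]
        genes = sc.genes
        classes, gene_strand = classify_summit(row["summit"], row["scaffold"], genes)
        feature = sorted(classes)[0] if classes else "intergenic"
        pref, prob = plan.orientation_bias.get(feature, (".", 0.5))
        if pref == ".":
            orient_tx = "+" if rng.random() < 0.5 else "-"
        else:
            orient_tx = pref if rng.random() < prob else ("-" if pref == "+" else "+")
        host = gene_strand or "+"
        genomic_strand = "+" if orient_tx == "+" else "-"
        if host == "-":
            genomic_strand = "-" if genomic_strand == "+" else "+"
        inst = motif if genomic_strand == "+" else reverse_complement(motif)
        start = row["summit"] - len(motif) // 2
        sc.sequence[start : start + len(motif)] = list(inst)
        row.update(
            {
                "feature": feature,
                "host_strand": gene_strand or ".",
                "orientation_tx": orient_tx,
                "motif_genomic_strand": genomic_strand,
            }
        )

    # ---- build tracks
    input_track = SignalTrack(bin_size=1)
    chirp = {rna: SignalTrack(bin_size=1) for rna in plan.rna_folds}
    half = plan.peak_width // 2
    window = plan.enrichment_window
    for name, sc in scaffolds.items():
        base = rng.poisson(plan.background_mean, size=sc.length).astype(float)
        input_track.set_scaffold(name, base)
        summits = [r["summit"] for r in peak_rows if r["scaffold"] == name]
        for rna, fold in plan.rna_folds.items():
            arr = rng.poisson(plan.background_mean, size=sc.length).astype(float)
            bump = np.zeros(sc.length)
            # triangle integrating to half*amp; amp chosen so the 1-kb window
            # enrichment over a planted peak equals the planned fold
            amp = 2.0 * window * (fold - 1.0) / plan.peak_width
            for s in summits:
                lo, hi = max(0, s - half), min(sc.length, s + half)
                x = np.arange(lo, hi)
                tri = 1.0 - np.abs(x - s) / half
                bump[lo:hi] += plan.background_mean * amp * np.clip(tri, 0, 1)
            arr += rng.poisson(bump)
            chirp[rna].set_scaffold(name, arr)

    # ---- peak objects with realized enrichment and per-RNA signal
    first_rna = next(iter(plan.rna_folds))
    peaks = []
    for i, row in enumerate(peak_rows):
        name, s = row["scaffold"], row["summit"]
        sc = scaffolds[name]
        lo, hi = max(0, s - half), min(sc.length, s + half)
        wlo = max(0, s - window // 2)
        whi = min(sc.length, s + window // 2)
        input_sum = input_track.window_sum(name, wlo, whi)
        enr = (
            chirp[first_rna].window_sum(name, wlo, whi) / input_sum
            if input_sum > 0
            else 0.0
        )
        signal = {
            rna: track.window_sum(name, lo, hi) for rna, track in chirp.items()
        }
        q = float(rng.uniform(*plan.q_score_range))
        peaks.append(
            Peak(
                interval=GenomicInterval(name, lo, hi),
                summit=s,
                q_score=q,
                enrichment=float(enr),
                name=f"peak{i}",
                signal=signal,
            )
        )
        row.update({"start": lo, "end": hi, "q_score": q, "enrichment": float(enr)})

    genome = Genome(
        {name: "".join(sc.sequence) for name, sc in scaffolds.items()}, me_labels
    )
    gene_models = [g for sc in scaffolds.values() for g in sc.genes]
    ppts = pd.concat([sc.ppts for sc in scaffolds.values()], ignore_index=True)
    return ChirpExperiment(
        genome=genome,
        gene_models=gene_models,
        chirp=chirp,
        input_track=input_track,
        peaks=peaks,
        truth=pd.DataFrame(peak_rows),
        ppts=ppts,
    )


# ---------------------------------------------------------------------------
# Multi-species binding conservation


@dataclass
class ConservationPlan:
    species: list[str] = field(default_factory=lambda: ["A", "B", "C", "D"])
    n_genes: int = 50
    universal_fraction: float = 0.4
    species_specific_rate: float = 0.3
    scaffold: str = "chrX"
    gene_spacing: int = 2_000
    gene_length: int = 1_000
    peak_width: int = 200
    exact_position_fraction: float = 0.6  # of conserved peaks, same lifted spot


@dataclass
class ConservationSet:
    gene_models: dict[str, list[GeneModel]]
    peaks: dict[str, list[Peak]]
    orthology: pd.DataFrame  # columns = species, one row per ortholog group
    coordinate_maps: dict[tuple[str, str], CoordinateMap]
    scaffold_length: int
    truth: pd.DataFrame


def generate_conservation_set(
    plan: ConservationPlan | None = None, seed: int = 0
) -> ConservationSet:
    """Orthologous gene rows across species with planted binding patterns.

    A ``universal_fraction`` of gene groups is bound in every species; other
    genes are bound independently per species at ``species_specific_rate``.
    For universally bound genes, a ``exact_position_fraction`` of peaks sit
    at the identical lifted position (identity maps), the rest at a shifted
    position within the gene.
    """
    plan = plan or ConservationPlan()
    rng = child_rng(seed, "conservation")
    n = plan.n_genes
    length = plan.gene_spacing * (n + 1)
    universal = rng.random(n) < plan.universal_fraction

    gene_models: dict[str, list[GeneModel]] = {}
    peaks: dict[str, list[Peak]] = {}
    rows = []
    for species in plan.species:
        genes, sp_peaks = [], []
        for g in range(n):
            start = plan.gene_spacing * g + 500
            gid = f"{species}_g{g}"
            genes.append(
                _single_exon_gene(gid, plan.scaffold, start, start + plan.gene_length, "+")
            )
            bound = False
            if universal[g]:
                bound = True
                exact = rng.random() < plan.exact_position_fraction
                # deterministic per-group position so 'exact' peaks co-locate
                group_rng = child_rng(seed, f"grouppos:{g}")
                base_summit = start + int(group_rng.integers(100, plan.gene_length - 100))
                summit = base_summit if exact else start + int(
                    rng.integers(100, plan.gene_length - 100)
                )
            elif rng.random() < plan.species_specific_rate:
                bound = True
                summit = start + int(rng.integers(100, plan.gene_length - 100))
            if bound:
                half = plan.peak_width // 2
                sp_peaks.append(
                    Peak(
                        interval=GenomicInterval(plan.scaffold, summit - half, summit + half),
                        summit=summit,
                        q_score=float(rng.uniform(1_000, 30_000)),
                        enrichment=float(rng.uniform(20, 200)),
                        name=f"{species}_p{g}",
                    )
                )
                rows.append({"species": species, "group": g, "summit": summit,
                             "universal": bool(universal[g])})
        gene_models[species] = genes
        peaks[species] = sp_peaks

    orthology = pd.DataFrame(
        {sp: [f"{sp}_g{g}" for g in range(n)] for sp in plan.species}
    )
    identity = CoordinateMap(
        [
            MapBlock(
                GenomicInterval(plan.scaffold, 0, length),
                GenomicInterval(plan.scaffold, 0, length),
                "+",
            )
        ]
    )
    maps = {
        (a, b): identity
        for a in plan.species
        for b in plan.species
        if a != b
    }
    return ConservationSet(
        gene_models=gene_models,
        peaks=peaks,
        orthology=orthology,
        coordinate_maps=maps,
        scaffold_length=length,
        truth=pd.DataFrame(rows),
    )
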