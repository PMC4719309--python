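"""Nested-homology lncRNA ortholog search.

Locates candidate loci by synteny (anchor protein-coding genes found via
translated k-mer seeding + ungapped extension), microhomology (clusters of
PWM motif hits), and secondary structure (a hairpin base-pair-maximisation
score), iterating species in order of phylogenetic distance from the
reference and refining the motif with each accepted ortholog.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from Bio.Align import substitution_matrices
from Bio.Seq import Seq

from .model import Genome, GenomicInterval, Phylogeny, reverse_complement
from .motif import PWM, MotifHit, scan_pwm

_BLOSUM62 = substitution_matrices.load("BLOSUM62")


# ---------------------------------------------------------------------------
# Anchor location (tBLASTn-style: translated seeding + ungapped extension)


@dataclass(frozen=True)
class AnchorHit:
    gene_id: str
    interval: GenomicInterval  # nucleotide coordinates of the aligned block
    score: float
    frame: int  # 0..2 on the hit strand

    @property
    def midpoint(self) -> int:
        return (self.interval.start + self.interval.end) // 2


def _aa_score(a: str, b: str) -> float:
    try:
        return float(_BLOSUM62[a, b])
    except (KeyError, IndexError):
        return -4.0


def _six_frames(sequence: str):
    """Yield (strand, frame, protein) for all six reading frames."""
    for strand, seq in (("+", sequence), ("-", reverse_complement(sequence))):
        for frame in range(3):
            sub = seq[frame:]
            sub = sub[: len(sub) - len(sub) % 3]
            if not sub:
                continue
            protein = str(Seq(sub).translate())
            yield strand, frame, protein


def find_anchor_locus(
    genome: Genome,
    anchor_protein: str,
    k: int = 5,
    min_extension_score: float = 40.0,
    gene_id: str = "anchor",
) -> AnchorHit | None:
    """Best-scoring locus of an anchor protein, or None if below threshold.

    Seeds exact length-``k`` amino-acid matches in all six reading frames and
    extends each seed without gaps under BLOSUM62, keeping the maximal-scoring
    extension.
    """
    if len(anchor_protein) < k:
        raise ValueError("protein shorter than seed length k")
    protein = anchor_protein.upper()
    kmers: dict[str, list[int]] = {}
    for i in range(len(protein) - k + 1):
        kmers.setdefault(protein[i : i + k], []).append(i)

    best: AnchorHit | None = None
    for scaffold, seq in genome.scaffolds.items():
        n = len(seq)
        for strand, frame, translated in _six_frames(seq):
            for j in range(len(translated) - k + 1):
                word = translated[j : j + k]
                if "*" in word or word not in kmers:
                    continue
                for qpos in kmers[word]:
                    score, qlo, qhi = _extend(protein, translated, qpos, j, k)
                    if score < min_extension_score:
                        continue
                    # subject aa range [j - (qpos - qlo), j + (qhi - qpos))
                    slo = j - (qpos - qlo)
                    shi = j + (qhi - qpos)
                    if strand == "+":
                        nt_start = frame + 3 * slo
                        nt_end = frame + 3 * shi
                    else:
                        nt_end = n - (frame + 3 * slo)
                        nt_start = n - (frame + 3 * shi)
                    hit = AnchorHit(
                        gene_id=gene_id,
                        interval=GenomicInterval(scaffold, nt_start, nt_end, strand),
                        score=score,
                        frame=frame,
                    )
                    if best is None or hit.score > best.score:
                        best = hit
    return best


def _extend(query: str, subject: str, qpos: int, spos: int, k: int):
    """Ungapped extension of an exact seed; returns (score, q_lo, q_hi)."""
    score = sum(_aa_score(query[qpos + i], subject[spos + i]) for i in range(k))
    # extend right
    best_right, run = 0.0, 0.0
    hi = qpos + k
    i = 0
    while qpos + k + i < len(query) and spos + k + i < len(subject):
        a, b = query[qpos + k + i], subject[spos + k + i]
        if a == "*" or b == "*":
            break
        run += _aa_score(a, b)
        if run > best_right:
            best_right, hi = run, qpos + k + i + 1
        i += 1
    # extend left
    best_left, run = 0.0, 0.0
    lo = qpos
    i = 1
    while qpos - i >= 0 and spos - i >= 0:
        a, b = query[qpos - i], subject[spos - i]
        if a == "*" or b == "*":
            break
        run += _aa_score(a, b)
        if run > best_left:
            best_left, lo = run, qpos - i
        i += 1
    return score + best_right + best_left, lo, hi


# ---------------------------------------------------------------------------
# Synteny windows


@dataclass
class SyntenyWindow:
    interval: GenomicInterval
    anchors: list[AnchorHit]
    species: str = ""
    disrupted: bool = False


def define_synteny_window(
    anchor_hits: list[AnchorHit],
    max_span: int,
    scaffold_length: int | None = None,
    species: str = "",
) -> SyntenyWindow | None:
    """Interval between two same-scaffold anchors, or ±max_span/2 around one.

    Anchors on different scaffolds signal syntenic disruption: returns a
    window flagged ``disrupted`` with a zero-length placeholder interval
    replaced by None interval semantics (interval is None-like via the flag).
    """
    if not anchor_hits:
        raise ValueError("need at least one anchor hit")
    scaffolds = {h.interval.scaffold for h in anchor_hits}
    if len(scaffolds) > 1:
        return SyntenyWindow(
            interval=anchor_hits[0].interval,
            anchors=list(anchor_hits),
            species=species,
            disrupted=True,
        )
    scaffold = anchor_hits[0].interval.scaffold
    if len(anchor_hits) >= 2:
        ordered = sorted(anchor_hits, key=lambda h: h.interval.start)
        left, right = ordered[0], ordered[-1]
        if right.interval.start - left.interval.end > max_span:
            return None
        start, end = left.interval.end, right.interval.start
        if start >= end:  # anchors abut or overlap: no interior window
            return None
    else:
        mid = anchor_hits[0].midpoint
        start, end = mid - max_span // 2, mid + max_span // 2
    start = max(0, start)
    if scaffold_length is not None:
        end = min(end, scaffold_length)
    if start >= end:
        return None
    return SyntenyWindow(
        interval=GenomicInterval(scaffold, start, end),
        anchors=list(anchor_hits),
        species=species,
    )


# ---------------------------------------------------------------------------
# Motif-cluster election


@dataclass
class ClusterWindow:
    interval: GenomicInterval
    hits: list[MotifHit]

    @property
    def n_hits(self) -> int:
        return len(self.hits)

    @property
    def total_score(self) -> float:
        return sum(h.score for h in self.hits)


def elect_candidate_window(
    hits: list[MotifHit],
    cluster_span: int = 500,
    min_hits: int = 3,
) -> ClusterWindow | None:
    """Densest cluster_span-wide window with >= min_hits hits.

    Ties break by (more hits, higher summed score, leftmost start).
    """
    if len(hits) < min_hits:
        return None
    hits = sorted(hits, key=lambda h: h.start)
    best: ClusterWindow | None = None
    for anchor in hits:
        start = anchor.start
        inside = [h for h in hits if start <= h.start and h.interval.end <= start + cluster_span]
        if len(inside) < min_hits:
            continue
        window = ClusterWindow(
            interval=GenomicInterval(
                anchor.interval.scaffold,
                inside[0].start,
                inside[-1].interval.end,
            ),
            hits=inside,
        )
        if (
            best is None
            or (window.n_hits, window.total_score, -window.interval.start)
            > (best.n_hits, best.total_score, -best.interval.start)
        ):
            best = window
    return best


# ---------------------------------------------------------------------------
# Hairpin (stem-loop) scoring

_PAIRS = {("A", "T"), ("T", "A"), ("C", "G"), ("G", "C"), ("G", "T"), ("T", "G")}


def score_stem_loop(
    sequence: str,
    focus_start: int,
    focus_end: int,
    min_loop: int = 3,
    max_loop: int = 50,
    max_arm: int = 20,
    mismatch_penalty: float = 1.0,
) -> tuple[float, tuple[int, int, int, int] | None]:
    """Best single ungapped-arm hairpin whose 5' arm overlaps the focus.

    Pairs counted are Watson–Crick plus G·T wobble (the stems are RNA
    structures read from DNA). Returns (score, (arm5_start, arm5_end,
    arm3_start, arm3_end)) with score = paired bases − mismatch_penalty ×
    internal mismatches; (0, None) when nothing pairs.
    """
    seq = sequence.upper()
    n = len(seq)
    best_score, best_coords = 0.0, None
    for i in range(max(0, focus_start - max_arm + 1), min(focus_end, n)):
        for arm in range(2, max_arm + 1):
            a5_end = i + arm
            if a5_end > n or a5_end <= focus_start or i >= focus_end:
                continue
            for loop in range(min_loop, max_loop + 1):
                a3_start = a5_end + loop
                a3_end = a3_start + arm
                if a3_end > n:
                    break
                pairs = mismatches = 0
                for j in range(arm):
                    a = seq[i + j]
                    b = seq[a3_end - 1 - j]
                    if (a, b) in _PAIRS:
                        pairs += 1
                    else:
                        mismatches += 1
                score = pairs - mismatch_penalty * mismatches
                if score > best_score:
                    best_score = score
                    best_coords = (i, a5_end, a3_start, a3_end)
    return best_score, best_coords


# ---------------------------------------------------------------------------
# Iterative bootstrap search


@dataclass
class OrthologCandidate:
    species: str
    interval: GenomicInterval | None
    motif_hits: list[MotifHit] = field(default_factory=list)
    stem_score: float = 0.0
    window_score: float = 0.0
    accepted: bool = False
    reason: str = ""  # no_assembly_window | syntenic_disruption | no_motif_cluster | no_stem


@dataclass
class SearchState:
    pwm: PWM
    instances: list[str]
    searched_windows: list[str] = field(default_factory=list)
    results: dict[str, OrthologCandidate] = field(default_factory=dict)


@dataclass
class SearchConfig:
    anchor_k: int = 5
    min_extension_score: float = 40.0
    max_span: int = 10_000
    p_threshold: float = 1e-4
    cluster_span: int = 500
    min_hits: int = 3
    stem_threshold: float = 6.0
    min_loop: int = 3
    max_loop: int = 50
    max_arm: int = 20
    pseudocount: float = 0.5
    refine_background: bool = True


@dataclass
class ReferenceLocus:
    """What the search needs to know about the lncRNA in the reference species."""

    species: str
    interval: GenomicInterval
    motif_instances: list[str]  # aligned roXbox-like instances, equal width
    primary_anchors: dict[str, str]  # gene_id -> protein sequence
    secondary_anchors: dict[str, str] = field(default_factory=dict)

    def validate(self) -> None:
        if not self.motif_instances:
            raise ValueError("reference locus needs motif instances")
        widths = {len(m) for m in self.motif_instances}
        if len(widths) != 1:
            raise ValueError("motif instances must share one width")
        if not self.primary_anchors:
            raise ValueError("reference locus needs at least one primary anchor")


def refine_pwm(state: SearchState, new_instances: list[str]) -> PWM:
    """Rebuild the PWM from all accepted instances (old + new).

    Background is re-estimated from the composition of every synteny window
    searched so far; falls back to uniform when no window has been recorded.
    """
    width = state.pwm.width
    for inst in new_instances:
        if len(inst) != width:
            raise ValueError(f"instance {inst!r} does not match PWM width {width}")
        if "N" in inst.upper():
            raise ValueError(f"instance {inst!r} contains N")
    instances = state.instances + list(new_instances)
    background = None
    if state.searched_windows:
        pooled = "".join(state.searched_windows).upper()
        counts = np.array([pooled.count(c) for c in "ACGT"], dtype=float)
        if counts.sum() > 0:
            background = counts / counts.sum()
    pwm = PWM.from_instances(
        instances, pseudocount=state.pwm.pseudocount, background=background
    )
    state.instances = instances
    state.pwm = pwm
    return pwm


def _search_one_species(
    species: str,
    genome: Genome,
    anchors: dict[str, str],
    fallback_anchors: dict[str, str],
    state: SearchState,
    config: SearchConfig,
) -> OrthologCandidate:
    hits: list[AnchorHit] = []
    for gene_id, protein in anchors.items():
        hit = find_anchor_locus(
            genome, protein, config.anchor_k, config.min_extension_score, gene_id
        )
        if hit is not None:
            hits.append(hit)
    if not hits and fallback_anchors:
        for gene_id, protein in fallback_anchors.items():
            hit = find_anchor_locus(
                genome, protein, config.anchor_k, config.min_extension_score, gene_id
            )
            if hit is not None:
                hits.append(hit)
    if not hits:
        return OrthologCandidate(species, None, reason="no_assembly_window")

    scaffold_len = genome.length(hits[0].interval.scaffold)
    window = define_synteny_window(hits, config.max_span, scaffold_len, species)
    if window is not None and window.disrupted:
        return OrthologCandidate(species, None, reason="syntenic_disruption")
    if window is None:
        return OrthologCandidate(species, None, reason="no_assembly_window")

    window_seq = genome.fetch(window.interval)
    state.searched_windows.append(window_seq)
    motif_hits = scan_pwm(
        window_seq,
        state.pwm,
        config.p_threshold,
        scaffold=window.interval.scaffold,
        offset=window.interval.start,
    )
    cluster = elect_candidate_window(motif_hits, config.cluster_span, config.min_hits)
    if cluster is None:
        return OrthologCandidate(species, None, motif_hits=motif_hits, reason="no_motif_cluster")

    focus_start = cluster.interval.start - window.interval.start
    focus_end = cluster.interval.end - window.interval.start
    stem_score, _ = score_stem_loop(
        window_seq,
        focus_start,
        focus_end,
        config.min_loop,
        config.max_loop,
        config.max_arm,
    )
    if stem_score < config.stem_threshold:
        return OrthologCandidate(
            species, cluster.interval, motif_hits=cluster.hits,
            stem_score=stem_score, reason="no_stem",
        )
    return OrthologCandidate(
        species,
        cluster.interval,
        motif_hits=cluster.hits,
        stem_score=stem_score,
        window_score=cluster.total_score,
        accepted=True,
    )


def run_bootstrap_search(
    reference: ReferenceLocus,
    genomes: dict[str, Genome],
    phylogeny: Phylogeny,
    config: SearchConfig | None = None,
) -> SearchState:
    """Iterative search over species ordered by distance from the reference.

    The reference species' locus is accepted as given and seeds the PWM; each
    accepted ortholog's clustered motif hits are folded back into the PWM
    before more distant species are searched. Primary anchors are tried
    first, the secondary list on primary failure (anchor replacement).
    """
    if config is None:
        config = SearchConfig()
    reference.validate()
    pwm = PWM.from_instances(reference.motif_instances, pseudocount=config.pseudocount)
    state = SearchState(pwm=pwm, instances=list(reference.motif_instances))

    order = phylogeny.leaves_by_distance(reference.species)
    for species in order:
        if species == reference.species:
            state.results[species] = OrthologCandidate(
                species, reference.interval, accepted=True,
            )
            continue
        if species not in genomes:
            state.results[species] = OrthologCandidate(
                species, None, reason="no_assembly_window"
            )
            continue
        candidate = _search_one_species(
            species,
            genomes[species],
            reference.primary_anchors,
            reference.secondary_anchors,
            state,
            config,
        )
        state.results[species] = candidate
        if candidate.accepted and candidate.motif_hits:
            new = [
                h.sequence for h in candidate.motif_hits
                if len(h.sequence) == state.pwm.width and "N" not in h.sequence
            ]
            if new:
                refine_pwm(state, new)
    return state
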