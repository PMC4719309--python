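"""Gene-level and element-level conservation of binding sites across species.

Gene-level: a peak is conserved between species A and B when one of its
associated genes (summit within 1 kb of the UTR-extended gene span) has an
ortholog that is itself peak-associated in B. Element-level: the peak summit
is lifted through a coordinate map and its distance to the nearest peak in
the other species is measured, against permutation nulls that reshuffle the
other species' peaks within chromosomes or genome-wide.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from .model import CoordinateMap, GeneModel, GenomicInterval, Peak
from .synthetic_data import child_rng


@dataclass
class PeakGeneAssociation:
    peak: Peak
    gene_ids: list[str]
    species: str = ""


def _extended_span(gene: GeneModel, utr5_ext: int, utr3_ext: int) -> GenomicInterval:
    span = gene.span
    if gene.has_annotated_utrs():
        return span
    if gene.strand == "-":
        start, end = span.start - utr3_ext, span.end + utr5_ext
    else:
        start, end = span.start - utr5_ext, span.end + utr3_ext
    return GenomicInterval(span.scaffold, max(0, start), end, gene.strand)


def associate_genes(
    peaks: list[Peak],
    genes: list[GeneModel],
    max_distance: int = 1_000,
    utr5_ext: int = 200,
    utr3_ext: int = 500,
    species: str = "",
) -> list[PeakGeneAssociation]:
    """Genes whose UTR-extended span lies within max_distance of each summit.

    The UTR extensions stand in for unannotated UTRs and are applied only to
    genes without annotated ones, upstream/downstream in gene orientation.
    """
    trees: dict[str, IntervalTree] = {}
    for gene in genes:
        span = _extended_span(gene, utr5_ext, utr3_ext)
        trees.setdefault(span.scaffold, IntervalTree()).addi(
            span.start - max_distance, span.end + max_distance, gene.gene_id
        )
    out = []
    for peak in peaks:
        tree = trees.get(peak.scaffold)
        hits = sorted(iv.data for iv in tree[peak.summit]) if tree else []
        out.append(PeakGeneAssociation(peak=peak, gene_ids=hits, species=species))
    return out


@dataclass
class ConservationCall:
    peak: Peak
    species: str
    status: dict[str, str]  # other species -> gene_conserved | species_specific
    element_distance: dict[str, float | None] = field(default_factory=dict)

    def conserved_in_any(self) -> bool:
        return any(s == "gene_conserved" for s in self.status.values()) or any(
            d == 0 for d in self.element_distance.values() if d is not None
        )


@dataclass
class GeneConservationResult:
    calls: dict[str, list[ConservationCall]]  # per species
    subset_counts: dict[frozenset, int]  # bound-species subset -> n ortholog groups
    shared_all_count: int
    shared_gene_peak_counts: dict[str, int]  # peaks per species within shared genes


def classify_gene_conservation(
    associations: dict[str, list[PeakGeneAssociation]],
    orthology: pd.DataFrame,
) -> GeneConservationResult:
    """Per-peak conservation statuses plus Venn-style shared-gene counts.

    ``orthology`` has one column per species and one row per ortholog group
    (one-to-many groups may repeat a gene). Genes absent from the table are
    treated as having no ortholog, so they can only support species-specific
    calls. Counting in the shared sets is over ortholog groups (genes), not
    peaks.
    """
    species = list(associations)
    bound_genes = {
        sp: {g for a in assoc for g in a.gene_ids}
        for sp, assoc in associations.items()
    }
    gene_to_group: dict[str, dict[str, int]] = {sp: {} for sp in species}
    for idx, row in orthology.iterrows():
        for sp in species:
            if sp in orthology.columns:
                gene_to_group[sp].setdefault(row[sp], idx)

    group_bound: dict[int, set[str]] = {}
    for sp in species:
        for gene in bound_genes[sp]:
            group = gene_to_group[sp].get(gene)
            if group is not None:
                group_bound.setdefault(group, set()).add(sp)

    subset_counts: dict[frozenset, int] = {}
    for group, members in group_bound.items():
        key = frozenset(members)
        subset_counts[key] = subset_counts.get(key, 0) + 1
    shared_all = {
        g for g, members in group_bound.items() if members == set(species)
    }

    calls: dict[str, list[ConservationCall]] = {}
    shared_gene_peak_counts = {sp: 0 for sp in species}
    for sp, assoc in associations.items():
        sp_calls = []
        for a in assoc:
            groups = {
                gene_to_group[sp][g] for g in a.gene_ids if g in gene_to_group[sp]
            }
            status = {}
            for other in species:
                if other == sp:
                    continue
                conserved = any(
                    other in group_bound.get(g, set()) for g in groups
                )
                status[other] = "gene_conserved" if conserved else "species_specific"
            sp_calls.append(ConservationCall(peak=a.peak, species=sp, status=status))
            if groups & shared_all:
                shared_gene_peak_counts[sp] += 1
        calls[sp] = sp_calls
    return GeneConservationResult(
        calls=calls,
        subset_counts=subset_counts,
        shared_all_count=len(shared_all),
        shared_gene_peak_counts=shared_gene_peak_counts,
    )


# ---------------------------------------------------------------------------
# Element-level turnover


def element_turnover(
    peaks_a: list[Peak],
    coord_map: CoordinateMap,
    peaks_b: list[Peak],
) -> pd.DataFrame:
    """Lift each A summit into B coordinates and measure the distance to the
    nearest B peak (0 = inside a peak; NaN = unmappable or peak-free scaffold)."""
    by_scaffold: dict[str, list[Peak]] = {}
    for p in peaks_b:
        by_scaffold.setdefault(p.scaffold, []).append(p)
    rows = []
    for p in peaks_a:
        lifted = coord_map.map_point(p.scaffold, p.summit)
        if lifted is None:
            rows.append({"peak": p.name, "mapped": False, "distance": np.nan})
            continue
        scaffold, pos = lifted
        candidates = by_scaffold.get(scaffold, [])
        if not candidates:
            rows.append({"peak": p.name, "mapped": True, "distance": np.nan})
            continue
        dist = min(q.interval.distance_to(pos) for q in candidates)
        rows.append({"peak": p.name, "mapped": True, "distance": float(dist)})
    return pd.DataFrame(rows)


def _permute_peaks(
    peaks: list[Peak],
    scaffold_lengths: dict[str, int],
    mode: str,
    rng: np.random.Generator,
    max_tries: int = 1_000,
) -> list[Peak]:
    """Place peaks uniformly at random, lengths preserved, without mutual
    overlap; within their own chromosome or anywhere in the genome."""
    if mode not in ("within_chromosome", "genome_wide"):
        raise ValueError(f"unknown mode {mode!r}")
    names = list(scaffold_lengths)
    lengths = np.array([scaffold_lengths[n] for n in names], dtype=float)
    placed: dict[str, list[tuple[int, int]]] = {n: [] for n in names}
    out = []
    for p in peaks:
        size = len(p.interval)
        for _ in range(max_tries):
            if mode == "within_chromosome":
                scaffold = p.scaffold
            else:
                scaffold = names[rng.choice(len(names), p=lengths / lengths.sum())]
            limit = scaffold_lengths[scaffold] - size
            if limit < 0:
                raise ValueError(
                    f"peak {p.name} ({size} bp) exceeds scaffold {scaffold}"
                )
            start = int(rng.integers(0, limit + 1))
            end = start + size
            if all(e <= start or end <= s for s, e in placed[scaffold]):
                placed[scaffold].append((start, end))
                out.append(
                    Peak(
                        interval=GenomicInterval(scaffold, start, end),
                        summit=start + (p.summit - p.interval.start),
                        q_score=p.q_score,
                        enrichment=p.enrichment,
                        name=p.name,
                    )
                )
                break
        else:
            raise RuntimeError("could not place peak without overlap")
    return out


@dataclass
class TurnoverNull:
    d_grid: np.ndarray
    observed_fraction: np.ndarray  # P(distance <= d), observed
    null_fraction: np.ndarray  # mean over permutations
    ratio: np.ndarray  # observed / null (NaN where null is 0)
    null_distances: list[np.ndarray]  # per permutation


def turnover_null(
    peaks_a: list[Peak],
    coord_map: CoordinateMap,
    peaks_b: list[Peak],
    scaffold_lengths: dict[str, int],
    mode: str = "within_chromosome",
    n_perm: int = 100,
    seed: int = 0,
    d_grid: np.ndarray | None = None,
) -> TurnoverNull:
    """Observed vs permuted cumulative fraction-within-d turnover curves.

    Unmappable summits are excluded from both the observed and null curves.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    if d_grid is None:
        d_grid = np.array([0, 1_000, 5_000, 10_000, 30_000, 100_000], dtype=float)
    rng = child_rng(seed, "turnover_null")
    observed = element_turnover(peaks_a, coord_map, peaks_b)
    obs = observed["distance"].dropna().to_numpy()
    if obs.size == 0:
        raise ValueError("no mappable peak had a measurable distance")
    observed_fraction = np.array([(obs <= d).mean() for d in d_grid])
    null_curves = []
    null_distances = []
    for _ in range(n_perm):
        permuted = _permute_peaks(peaks_b, scaffold_lengths, mode, rng)
        dist = element_turnover(peaks_a, coord_map, permuted)["distance"].dropna().to_numpy()
        null_distances.append(dist)
        null_curves.append([(dist <= d).mean() if dist.size else np.nan for d in d_grid])
    null_fraction = np.nanmean(np.array(null_curves), axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(null_fraction > 0, observed_fraction / null_fraction, np.nan)
    return TurnoverNull(
        d_grid=d_grid,
        observed_fraction=observed_fraction,
        null_fraction=null_fraction,
        ratio=ratio,
        null_distances=null_distances,
    )
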