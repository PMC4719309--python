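"""Nearest-neighbour spacing of peak summits against permuted nulls.

Perfectly even placement of n peaks on a chromosome of length L gives a
nearest-neighbour distance of D* = L/n; clustering pushes distances toward
0. The departure statistic contrasts the observed nearest-neighbour
histogram with a uniform-placement null on a shared bin grid.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .has_conservation import ConservationCall
from .model import Peak
from .synthetic_data import child_rng


@dataclass
class PeakSubsets:
    strong: list[Peak]
    conserved: list[Peak]
    strong_conserved: list[Peak]


def subset_peaks(
    peaks: list[Peak],
    conservation: dict[str, ConservationCall] | None = None,
    strong_enrichment_min: float = 50.0,
    strong_q_min: float = 10_000.0,
) -> PeakSubsets:
    """Strong (strict >, both thresholds), conserved (shared with at least
    one other species), and their intersection."""
    strong = [
        p
        for p in peaks
        if p.enrichment > strong_enrichment_min and p.q_score > strong_q_min
    ]
    conserved = []
    if conservation is not None:
        for p in peaks:
            call = conservation.get(p.name)
            if call is not None and call.conserved_in_any():
                conserved.append(p)
    conserved_names = {p.name for p in conserved}
    return PeakSubsets(
        strong=strong,
        conserved=conserved,
        strong_conserved=[p for p in strong if p.name in conserved_names],
    )


def nearest_neighbor_distances(summits) -> np.ndarray:
    """Distance from each summit to its nearest other summit (one chromosome)."""
    summits = np.sort(np.asarray(summits, dtype=float))
    if summits.size < 2:
        raise ValueError("need at least 2 peaks")
    gaps = np.diff(summits)
    left = np.concatenate([[np.inf], gaps])
    right = np.concatenate([gaps, [np.inf]])
    return np.minimum(left, right)


def spacing_null(
    chromosome_length: int,
    n_peaks: int,
    n_perm: int = 1_000,
    seed: int = 0,
) -> np.ndarray:
    """Pooled nearest-neighbour distances of n uniform summits per permutation."""
    if n_peaks < 2:
        raise ValueError("n_peaks must be >= 2")
    rng = child_rng(seed, "spacing_null")
    pooled = []
    for _ in range(n_perm):
        summits = rng.uniform(0, chromosome_length, size=n_peaks)
        pooled.append(nearest_neighbor_distances(summits))
    return np.concatenate(pooled)


@dataclass
class SpacingDeparture:
    perfect_distance: float  # D* = L / n
    bin_edges: np.ndarray
    observed_density: np.ndarray
    null_density: np.ndarray
    difference: np.ndarray  # observed − null density per bin
    evenness_summary: float  # excess observed mass within ±25% of D*
    clustering_summary: float  # excess observed mass below 0.1 D*


def spacing_departure(
    observed_distances: np.ndarray,
    null_distances: np.ndarray,
    chromosome_length: float,
    n_peaks: int,
    bin_width: float | None = None,
) -> SpacingDeparture:
    """Observed-minus-null nearest-neighbour histogram difference.

    Densities are normalised per distribution, so the difference curve
    integrates to ~0. The evenness summary is the observed-minus-null
    probability mass within ±25% of D*; the clustering summary the same
    below 0.1 D*.
    """
    observed = np.asarray(observed_distances, dtype=float)
    null = np.asarray(null_distances, dtype=float)
    if observed.size == 0 or null.size == 0:
        raise ValueError("distributions must be non-empty")
    d_star = chromosome_length / n_peaks
    if bin_width is None:
        bin_width = d_star / 10.0
    top = max(observed.max(), null.max()) + bin_width
    edges = np.arange(0.0, top + bin_width, bin_width)
    obs_density, _ = np.histogram(observed, bins=edges, density=True)
    null_density, _ = np.histogram(null, bins=edges, density=True)

    def mass(values: np.ndarray, lo: float, hi: float) -> float:
        return float(((values >= lo) & (values < hi)).mean())

    evenness = mass(observed, 0.75 * d_star, 1.25 * d_star) - mass(
        null, 0.75 * d_star, 1.25 * d_star
    )
    clustering = mass(observed, 0.0, 0.1 * d_star) - mass(null, 0.0, 0.1 * d_star)
    return SpacingDeparture(
        perfect_distance=d_star,
        bin_edges=edges,
        observed_density=obs_density,
        null_density=null_density,
        difference=obs_density - null_density,
        evenness_summary=evenness,
        clustering_summary=clustering,
    )


def evenness_score(
    summits,
    chromosome_length: float,
    n_perm: int = 200,
    seed: int = 0,
) -> float:
    """Convenience: evenness summary of a summit set against its own null."""
    summits = np.asarray(summits, dtype=float)
    observed = nearest_neighbor_distances(summits)
    null = spacing_null(int(chromosome_length), summits.size, n_perm, seed)
    departure = spacing_departure(observed, null, chromosome_length, summits.size)
    return departure.evenness_summary
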