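"""Windowed ChIRP/input enrichment, Müller-element assignment, peak
filtering, and roX1-vs-roX2 signal bias."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .model import ChainScoreTable, GenomicInterval, Peak, SignalTrack, UNASSIGNED


def window_enrichment(
    chirp: SignalTrack,
    input_track: SignalTrack,
    window_bp: int = 1_000,
    exclusion_zones: list[GenomicInterval] | None = None,
) -> pd.DataFrame:
    """Per-window enrichment = sum(chirp) / sum(input) over fixed windows.

    Windows intersecting an exclusion zone (e.g. the 5-kb neighbourhoods of
    the lncRNA loci themselves) are dropped; windows with zero input are
    flagged (``zero_input``) rather than divided.
    """
    chirp_names = set(chirp.scaffolds())
    input_names = set(input_track.scaffolds())
    if chirp_names != input_names:
        raise ValueError(
            f"scaffold sets differ: {sorted(chirp_names ^ input_names)}"
        )
    exclusion_zones = exclusion_zones or []
    rows = []
    for scaffold in sorted(chirp_names):
        length = len(chirp.values[scaffold]) * chirp.bin_size
        for start in range(0, length, window_bp):
            end = min(start + window_bp, length)
            window = GenomicInterval(scaffold, start, end)
            if any(window.overlaps(z) for z in exclusion_zones):
                continue
            c = chirp.window_sum(scaffold, start, end)
            i = input_track.window_sum(scaffold, start, end)
            rows.append(
                {
                    "scaffold": scaffold,
                    "start": start,
                    "end": end,
                    "chirp": c,
                    "input": i,
                    "enrichment": c / i if i > 0 else np.nan,
                    "zero_input": i == 0,
                }
            )
    return pd.DataFrame(rows)


@dataclass
class MEAssignment:
    scaffold: str
    label: str  # an ME letter or 'unassigned'
    similarity: dict[str, float]  # per-ME score/rowsum, for manual review

    @property
    def best_score(self) -> float:
        return max(self.similarity.values()) if self.similarity else 0.0


def assign_scaffold_to_me(
    scaffold: str, row: dict[str, float], cutoff: float = 0.85
) -> MEAssignment:
    """Assign a scaffold to the argmax ME when its similarity >= cutoff.

    Similarity per ME is that ME's chain score divided by the scaffold's
    total chain score. Rows below the cutoff — or with tied maxima, or a
    zero total — stay unassigned, with all similarity scores reported for
    review in place of the manual-inspection rescue step.
    """
    total = sum(row.values())
    if total <= 0:
        return MEAssignment(scaffold, UNASSIGNED, {})
    similarity = {me: s / total for me, s in row.items()}
    best = max(similarity.values())
    winners = [me for me, s in similarity.items() if s == best]
    if len(winners) > 1 or best < cutoff:
        return MEAssignment(scaffold, UNASSIGNED, similarity)
    return MEAssignment(scaffold, winners[0], similarity)


def assign_all_scaffolds(
    table: ChainScoreTable, cutoff: float = 0.85
) -> dict[str, MEAssignment]:
    return {
        scaffold: assign_scaffold_to_me(scaffold, table.row(scaffold), cutoff)
        for scaffold in table.scaffolds()
    }


def filter_peaks(
    peaks: list[Peak], q_min: float = 3_000.0, enrichment_min: float = 20.0
) -> list[Peak]:
    """Keep peaks with q_score >= q_min and enrichment >= enrichment_min
    (boundary inclusive)."""
    return [p for p in peaks if p.q_score >= q_min and p.enrichment >= enrichment_min]


@dataclass
class RoxBias:
    log2_ratios: np.ndarray  # per-peak log2(s1/s2)
    percentiles: dict[int, float]  # 5/25/50/75/95 of the log2 ratios
    median_fraction: float  # median of s1/s2
    n_excluded: int  # peaks with zero signal in either channel


def rox_bias(peaks: list[Peak], rna1: str, rna2: str) -> RoxBias:
    """Per-peak log2 signal ratio between two RNAs plus percentile summary."""
    ratios, excluded = [], 0
    for p in peaks:
        s1, s2 = p.signal.get(rna1, 0.0), p.signal.get(rna2, 0.0)
        if s1 <= 0 or s2 <= 0:
            excluded += 1
            continue
        ratios.append(s1 / s2)
    if not ratios:
        raise ValueError("no peak has positive signal in both channels")
    ratios = np.array(ratios)
    log2r = np.log2(ratios)
    percentiles = {q: float(np.percentile(log2r, q)) for q in (5, 25, 50, 75, 95)}
    return RoxBias(
        log2_ratios=log2r,
        percentiles=percentiles,
        median_fraction=float(np.median(ratios)),
        n_excluded=excluded,
    )
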