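"""Polypyrimidine-tract selection, peak-PPT proximity statistics, genomic
feature assignment, and motif orientation-bias tests.

PPT selection works on the transcribed strand of each intron: candidate
C/T-rich tracts are scored and the winner maximises raw score minus a
penalty that grows with distance from the 3' splice site (0 inside the
first 40 bp, then 0.02 per base). Proximity of peak summits to selected
PPTs is compared against within-chromosome permutation nulls with a
two-tailed Kolmogorov–Smirnov test.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import kolmogorov
from scipy.stats import binom

from .model import GeneModel, Genome, Peak, reverse_complement
from .motif import PWM, best_hit
from .synthetic_data import child_rng

FEATURE_CLASSES = ("CDS", "intron", "5UTR", "3UTR", "intergenic")


# ---------------------------------------------------------------------------
# PPT selection


def penalty(distance_to_3ss: int, free_zone: int = 40, per_base: float = 0.02) -> float:
    """0 below ``free_zone`` bp from the 3' splice site, then per_base per bp.

    Convention: base ``free_zone`` itself is penalty-free (0.02 x (d - 40)
    for d >= 40), so d=40 -> 0.0 and d=41 -> 0.02.
    """
    if distance_to_3ss < 0:
        raise ValueError("distance must be non-negative")
    if distance_to_3ss < free_zone:
        return 0.0
    return per_base * (distance_to_3ss - free_zone)


@dataclass(frozen=True)
class PPTCandidate:
    start: int  # within the intron, transcribed-strand coordinates
    end: int
    raw_score: float
    distance_to_3ss: int
    penalized_score: float

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class PPTScorerParams:
    min_length: int = 9
    min_pyrimidine_fraction: float = 0.85
    max_purines_per_10nt: int = 1
    purine_penalty: float = 2.0
    free_zone: int = 40
    distance_penalty_per_base: float = 0.02


def enumerate_ppt_candidates(
    intron_sequence: str, params: PPTScorerParams | None = None
) -> list[PPTCandidate]:
    """All substrings qualifying as pyrimidine tracts, scored and penalised.

    Qualification: length >= min_length, pyrimidine fraction >= 0.85, and at
    most ``max_purines_per_10nt`` purines per 10 nt (floor(len/10) allowed).
    Raw score = #pyrimidines − purine_penalty x #purines. The 3' splice site
    is the right end of the sequence.
    """
    params = params or PPTScorerParams()
    seq = intron_sequence.upper()
    n = len(seq)
    is_pyr = np.array([c in "CT" for c in seq], dtype=int)
    pyr_prefix = np.concatenate([[0], np.cumsum(is_pyr)])
    out = []
    for i in range(n - params.min_length + 1):
        ends = np.arange(i + params.min_length, n + 1)
        lengths = ends - i
        n_pyr = pyr_prefix[ends] - pyr_prefix[i]
        n_pur = lengths - n_pyr
        ok = (n_pyr / lengths >= params.min_pyrimidine_fraction) & (
            n_pur <= params.max_purines_per_10nt * (lengths // 10)
        )
        for j, npy, npu in zip(ends[ok], n_pyr[ok], n_pur[ok]):
            raw = float(npy - params.purine_penalty * npu)
            dist = n - int(j)
            out.append(
                PPTCandidate(
                    start=i,
                    end=int(j),
                    raw_score=raw,
                    distance_to_3ss=dist,
                    penalized_score=raw
                    - penalty(dist, params.free_zone, params.distance_penalty_per_base),
                )
            )
    return out


def find_and_select_ppt(
    intron_sequence: str, params: PPTScorerParams | None = None
) -> PPTCandidate | None:
    """The most likely PPT of an intron: maximal penalised score; ties break
    toward the 3' splice site, then toward the longer tract."""
    params = params or PPTScorerParams()
    if len(intron_sequence) < params.min_length:
        return None
    candidates = enumerate_ppt_candidates(intron_sequence, params)
    if not candidates:
        return None
    return max(
        candidates,
        key=lambda c: (c.penalized_score, -c.distance_to_3ss, c.length),
    )


def select_ppts(
    genes: list[GeneModel],
    genome: Genome,
    params: PPTScorerParams | None = None,
) -> pd.DataFrame:
    """Selected PPT per intron, in genomic coordinates.

    Columns: gene_id, transcript_id, intron_index, scaffold, start, end,
    strand, midpoint, raw_score, distance_to_3ss, penalized_score.
    """
    rows = []
    for gene in genes:
        for tx in gene.transcripts:
            for k, intron in enumerate(tx.introns()):
                seq = genome.fetch(
                    type(intron)(intron.scaffold, intron.start, intron.end, tx.strand)
                )
                best = find_and_select_ppt(seq, params)
                if best is None:
                    continue
                if tx.strand == "-":
                    g_start = intron.end - best.end
                    g_end = intron.end - best.start
                else:
                    g_start = intron.start + best.start
                    g_end = intron.start + best.end
                rows.append(
                    {
                        "gene_id": gene.gene_id,
                        "transcript_id": tx.transcript_id,
                        "intron_index": k,
                        "scaffold": intron.scaffold,
                        "start": g_start,
                        "end": g_end,
                        "strand": tx.strand,
                        "midpoint": (g_start + g_end) // 2,
                        "raw_score": best.raw_score,
                        "distance_to_3ss": best.distance_to_3ss,
                        "penalized_score": best.penalized_score,
                    }
                )
    return pd.DataFrame(
        rows,
        columns=[
            "gene_id", "transcript_id", "intron_index", "scaffold", "start",
            "end", "strand", "midpoint", "raw_score", "distance_to_3ss",
            "penalized_score",
        ],
    )


# ---------------------------------------------------------------------------
# KS test


def ks_two_sample(x, y) -> tuple[float, float]:
    """Two-sample two-tailed KS test: D = sup|ECDF_x − ECDF_y|, p from the
    asymptotic Kolmogorov distribution at effective n = |x||y|/(|x|+|y|)."""
    x = np.sort(np.asarray(x, dtype=float))
    y = np.sort(np.asarray(y, dtype=float))
    if x.size == 0 or y.size == 0:
        raise ValueError("samples must be non-empty")
    grid = np.concatenate([x, y])
    cdf_x = np.searchsorted(x, grid, side="right") / x.size
    cdf_y = np.searchsorted(y, grid, side="right") / y.size
    d = float(np.abs(cdf_x - cdf_y).max())
    en = x.size * y.size / (x.size + y.size)
    p = float(kolmogorov(np.sqrt(en) * d))
    return d, min(1.0, p)


# ---------------------------------------------------------------------------
# Peak-PPT proximity


@dataclass
class ProximityResult:
    signed_distances: np.ndarray  # observed, host-gene-oriented sign
    permuted_distances: np.ndarray  # pooled over permutations
    observed_fraction_within: float
    permuted_fraction_within: float
    ks_statistic: float
    ks_p_value: float
    window: int


def _signed_distance(summit: int, ppts: pd.DataFrame) -> float:
    """Signed bp distance to the nearest PPT midpoint (positive = summit 3'
    of the PPT in the host gene's orientation)."""
    mids = ppts["midpoint"].to_numpy()
    idx = int(np.argmin(np.abs(mids - summit)))
    delta = summit - int(mids[idx])
    if ppts.iloc[idx]["strand"] == "-":
        delta = -delta
    return float(delta)


def peak_ppt_proximity(
    peaks: list[Peak],
    ppts: pd.DataFrame,
    scaffold_lengths: dict[str, int],
    n_perm: int = 100,
    seed: int = 0,
    window: int = 100,
) -> ProximityResult:
    """Directional summit-to-PPT distances vs within-chromosome permutations.

    The within-``window`` fraction uses the absolute distance to the PPT
    midpoint; the KS test compares the signed observed and permuted
    distributions.
    """
    if ppts.empty:
        raise ValueError("no PPTs supplied")
    by_scaffold = {name: grp for name, grp in ppts.groupby("scaffold")}
    observed = []
    for p in peaks:
        grp = by_scaffold.get(p.scaffold)
        if grp is None:
            continue
        observed.append(_signed_distance(p.summit, grp))
    if not observed:
        raise ValueError("no peak shares a scaffold with a PPT")
    observed = np.array(observed)

    rng = child_rng(seed, "ppt_proximity")
    permuted = []
    for _ in range(n_perm):
        for p in peaks:
            grp = by_scaffold.get(p.scaffold)
            if grp is None:
                continue
            pos = int(rng.integers(0, scaffold_lengths[p.scaffold]))
            permuted.append(_signed_distance(pos, grp))
    permuted = np.array(permuted)

    d, p_value = ks_two_sample(observed, permuted)
    return ProximityResult(
        signed_distances=observed,
        permuted_distances=permuted,
        observed_fraction_within=float((np.abs(observed) <= window).mean()),
        permuted_fraction_within=float((np.abs(permuted) <= window).mean()),
        ks_statistic=d,
        ks_p_value=p_value,
        window=window,
    )


# ---------------------------------------------------------------------------
# Feature assignment


def classify_summit(
    summit: int, scaffold: str, genes: list[GeneModel]
) -> tuple[list[str], str | None]:
    """Feature classes of a position across all overlapping transcripts
    (double counting allowed) plus the host gene's strand (None if intergenic)."""
    classes: list[str] = []
    host_strand: str | None = None
    for gene in genes:
        if gene.scaffold != scaffold:
            continue
        for tx in gene.transcripts:
            span = tx.span
            if not (span.start <= summit < span.end):
                continue
            if host_strand is None:
                host_strand = tx.strand
            assigned = None
            for iv in tx.cds:
                if iv.contains(summit):
                    assigned = "CDS"
            for iv in tx.utr5:
                if iv.contains(summit):
                    assigned = "5UTR"
            for iv in tx.utr3:
                if iv.contains(summit):
                    assigned = "3UTR"
            if assigned is None:
                for iv in tx.introns():
                    if iv.contains(summit):
                        assigned = "intron"
            if assigned is None and any(e.contains(summit) for e in tx.exons):
                assigned = "CDS"  # exonic without finer annotation
            if assigned is not None:
                classes.append(assigned)
    if not classes:
        classes = ["intergenic"]
    return classes, host_strand


def _class_coverage(
    genes: list[GeneModel], scaffold_lengths: dict[str, int]
) -> dict[str, float]:
    """Fraction of the genome covered by each class (transcript union)."""
    total = sum(scaffold_lengths.values())
    union: dict[str, dict[str, set]] = {c: {} for c in FEATURE_CLASSES}

    def add(cls: str, iv):
        union[cls].setdefault(iv.scaffold, set()).update(range(iv.start, iv.end))

    genic: dict[str, set] = {}
    for gene in genes:
        for tx in gene.transcripts:
            genic.setdefault(tx.scaffold, set()).update(
                range(tx.span.start, tx.span.end)
            )
            for iv in tx.cds:
                add("CDS", iv)
            for iv in tx.utr5:
                add("5UTR", iv)
            for iv in tx.utr3:
                add("3UTR", iv)
            for iv in tx.introns():
                add("intron", iv)
    coverage = {
        cls: sum(len(s) for s in per.values()) / total
        for cls, per in union.items()
        if cls != "intergenic"
    }
    genic_total = sum(len(s) for s in genic.values())
    coverage["intergenic"] = (total - genic_total) / total
    return coverage


def feature_assignment(
    peaks: list[Peak],
    genes: list[GeneModel],
    scaffold_lengths: dict[str, int],
) -> pd.DataFrame:
    """Per-class summit counts and fold enrichment over the genomic
    distribution of each class."""
    counts = {c: 0 for c in FEATURE_CLASSES}
    for p in peaks:
        classes, _ = classify_summit(p.summit, p.scaffold, genes)
        for c in classes:
            counts[c] += 1
    total_assignments = sum(counts.values())
    coverage = _class_coverage(genes, scaffold_lengths)
    rows = []
    for cls in FEATURE_CLASSES:
        frac = counts[cls] / total_assignments if total_assignments else 0.0
        cov = coverage.get(cls, 0.0)
        rows.append(
            {
                "feature": cls,
                "n_summits": counts[cls],
                "summit_fraction": frac,
                "genome_fraction": cov,
                "fold_enrichment": frac / cov if cov > 0 else np.nan,
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Orientation bias


def binomial_two_sided(k: int, n: int, p0: float = 0.5) -> float:
    """Two-sided binomial p by doubling the smaller one-sided tail, capped at 1."""
    lower = binom.cdf(k, n, p0)
    upper = binom.sf(k - 1, n, p0)  # P(X >= k)
    return float(min(1.0, 2.0 * min(lower, upper)))


@dataclass
class OrientationBiasResult:
    counts: pd.DataFrame  # feature, n_forward, n_reverse, p_value
    n_unscorable: int
    per_peak: pd.DataFrame = field(default_factory=pd.DataFrame)


def orientation_bias(
    peaks: list[Peak],
    pwm: PWM,
    genes: list[GeneModel],
    genome: Genome,
) -> OrientationBiasResult:
    """Orientation of the best motif hit per peak, relative to host-gene
    transcription, counted per feature class with an exact binomial test.

    The best hit is the maximal log-odds window over both strands of the
    peak interval (ties go forward). Intergenic peaks are oriented on the
    genomic plus strand. Peaks with no scorable window are excluded and
    counted.
    """
    per_feature: dict[str, list[str]] = {}
    per_peak_rows = []
    unscorable = 0
    for p in peaks:
        seq = genome.fetch(p.interval)
        hit = best_hit(seq, pwm)
        if hit is None:
            unscorable += 1
            continue
        classes, host_strand = classify_summit(p.summit, p.scaffold, genes)
        motif_strand = hit.strand
        for cls in classes:
            if cls == "intergenic" or host_strand is None:
                orient = motif_strand
            else:
                orient = "+" if motif_strand == host_strand else "-"
            per_feature.setdefault(cls, []).append(orient)
            per_peak_rows.append(
                {
                    "peak": p.name,
                    "feature": cls,
                    "motif_strand": motif_strand,
                    "host_strand": host_strand or ".",
                    "orientation": orient,
                }
            )
    rows = []
    for cls, orients in sorted(per_feature.items()):
        n_fwd = sum(o == "+" for o in orients)
        n_rev = len(orients) - n_fwd
        rows.append(
            {
                "feature": cls,
                "n_forward": n_fwd,
                "n_reverse": n_rev,
                "p_value": binomial_two_sided(n_fwd, len(orients)),
            }
        )
    return OrientationBiasResult(
        counts=pd.DataFrame(rows, columns=["feature", "n_forward", "n_reverse", "p_value"]),
        n_unscorable=unscorable,
        per_peak=pd.DataFrame(per_peak_rows),
    )
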