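"""Independent brute-force implementations used as test oracles.

Each function re-derives a result with the most naive method available,
sharing no algorithmic code with the package (only plain data types cross
the boundary). They are intentionally slow and simple.
"""

from __future__ import annotations

import math
from itertools import combinations

import numpy as np

_COMP = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}


def revcomp(seq: str) -> str:
    return "".join(_COMP[c] for c in reversed(seq.upper()))


# ---------------------------------------------------------------------------
# PWM scanning


def pwm_log_odds(counts, pseudocount, background):
    """Per-column log2 odds computed with plain Python arithmetic."""
    counts = np.asarray(counts, dtype=float)
    width = counts.shape[1]
    table = []
    for base_idx in range(4):
        row = []
        for j in range(width):
            colsum = counts[:, j].sum() + 4 * pseudocount
            p = (counts[base_idx, j] + pseudocount) / colsum
            row.append(math.log2(p / background[base_idx]))
        table.append(row)
    return table


def naive_scan(sequence, counts, pseudocount, background):
    """All windows on both strands with their log-odds scores.

    Returns [(start, strand, score, window)] for scorable (N-free) windows,
    '-' windows scored on the reverse complement of the forward window.
    """
    lo = pwm_log_odds(counts, pseudocount, background)
    idx = {"A": 0, "C": 1, "G": 2, "T": 3}
    seq = sequence.upper()
    width = np.asarray(counts).shape[1]
    out = []
    for start in range(len(seq) - width + 1):
        fwd = seq[start : start + width]
        for strand, window in (("+", fwd), ("-", revcomp(fwd))):
            if any(c not in idx for c in window):
                continue
            score = sum(lo[idx[c]][j] for j, c in enumerate(window))
            out.append((start, strand, score, window))
    return out


def pwm_exact_tail(counts, pseudocount, background, score, scale=100):
    """P(integer score >= rint(score * scale)) by enumerating all windows.

    Mirrors the documented integer-rescaled contract: per-column log-odds
    rounded to 1/scale bits, summed, weighed by the background model.
    """
    lo = pwm_log_odds(counts, pseudocount, background)
    width = np.asarray(counts).shape[1]
    ints = [[int(np.rint(lo[i][j] * scale)) for j in range(width)] for i in range(4)]
    target = int(np.rint(score * scale))
    total = 0.0
    stack = [(0, 0, 1.0)]
    while stack:
        j, s, p = stack.pop()
        if j == width:
            if s >= target:
                total += p
            continue
        for i in range(4):
            stack.append((j + 1, s + ints[i][j], p * background[i]))
    return total


# ---------------------------------------------------------------------------
# Global alignment identity (tiny instances, full enumeration)


def enumerate_alignments(a: str, b: str):
    """All monotone global alignments of a and b as lists of column pairs.

    Columns are (char or None, char or None); None marks a gap.
    """
    if not a and not b:
        yield []
        return
    if a:
        for rest in enumerate_alignments(a[1:], b):
            yield [(a[0], None)] + rest
    if b:
        for rest in enumerate_alignments(a, b[1:]):
            yield [(None, b[0])] + rest
    if a and b:
        for rest in enumerate_alignments(a[1:], b[1:]):
            yield [(a[0], b[0])] + rest


def optimal_alignment_identities(a, b, match=1.0, mismatch=-1.0, gap=-2.0):
    """(best score, set of percent identities over all optimal alignments)."""
    best_score = None
    identities: set[float] = set()
    for aln in enumerate_alignments(a.upper(), b.upper()):
        score = 0.0
        n_match = 0
        for x, y in aln:
            if x is None or y is None:
                score += gap
            elif x == y:
                score += match
                n_match += 1
            else:
                score += mismatch
        if best_score is None or score > best_score + 1e-9:
            best_score = score
            identities = {100.0 * n_match / len(aln)}
        elif abs(score - best_score) <= 1e-9:
            identities.add(100.0 * n_match / len(aln))
    return best_score, identities


# ---------------------------------------------------------------------------
# Cluster election


def naive_elect(hits, cluster_span, min_hits):
    """Best window over every integer start position.

    ``hits`` are (start, end, score) triples; returns (n, total, window_start,
    window_end) of the winner under the (more hits, higher score, leftmost)
    tie-break, or None.
    """
    if not hits:
        return None
    positions = range(min(h[0] for h in hits), max(h[0] for h in hits) + 1)
    best = None
    for s in positions:
        inside = [h for h in hits if h[0] >= s and h[1] <= s + cluster_span]
        if len(inside) < min_hits:
            continue
        inside.sort(key=lambda h: h[0])
        key = (len(inside), sum(h[2] for h in inside), -inside[0][0])
        if best is None or key > best[0]:
            best = (key, (len(inside), sum(h[2] for h in inside),
                          inside[0][0], max(h[1] for h in inside)))
    return None if best is None else best[1]


# ---------------------------------------------------------------------------
# Hairpin scoring

_PAIRED = {("A", "T"), ("T", "A"), ("C", "G"), ("G", "C"), ("G", "T"), ("T", "G")}


def naive_stem_score(seq, focus_start, focus_end, min_loop, max_loop, max_arm,
                     mismatch_penalty=1.0):
    """Maximum hairpin score by trying every (arm5 start, arm length, loop)."""
    seq = seq.upper()
    n = len(seq)
    best = 0.0
    for i in range(n):
        for arm in range(2, max_arm + 1):
            a5_end = i + arm
            if a5_end > n:
                break
            # 5' arm must overlap [focus_start, focus_end)
            if a5_end <= focus_start or i >= focus_end:
                continue
            for loop in range(min_loop, max_loop + 1):
                a3_end = a5_end + loop + arm
                if a3_end > n:
                    break
                score = 0.0
                for j in range(arm):
                    pair = (seq[i + j], seq[a3_end - 1 - j])
                    score += 1.0 if pair in _PAIRED else -mismatch_penalty
                best = max(best, score)
    return best


# ---------------------------------------------------------------------------
# PPT selection


def naive_select_ppt(seq, min_length=9, min_pyr_frac=0.85, max_pur_per_10=1,
                     purine_penalty=2.0, free_zone=40, per_base=0.02):
    """Best tract by checking every substring with plain string counting.

    Returns (start, end, raw, distance, penalized) or None.
    """
    seq = seq.upper()
    n = len(seq)
    best = None
    for start in range(n):
        for end in range(start + min_length, n + 1):
            sub = seq[start:end]
            n_pyr = sum(c in "CT" for c in sub)
            n_pur = len(sub) - n_pyr
            if n_pyr / len(sub) < min_pyr_frac:
                continue
            if n_pur > max_pur_per_10 * (len(sub) // 10):
                continue
            raw = n_pyr - purine_penalty * n_pur
            dist = n - end
            pen = raw - (0.0 if dist < free_zone else per_base * (dist - free_zone))
            key = (pen, -dist, end - start)
            if best is None or key > best[0]:
                best = (key, (start, end, raw, dist, pen))
    return None if best is None else best[1]


# ---------------------------------------------------------------------------
# Element turnover


def naive_lift(blocks, scaffold, pos):
    """blocks: (src_scaffold, src_start, src_end, tgt_scaffold, tgt_start,
    tgt_end, orientation)."""
    for ss, s0, s1, ts, t0, t1, orient in blocks:
        if ss == scaffold and s0 <= pos < s1:
            if orient == "+":
                return ts, t0 + (pos - s0)
            return ts, t1 - 1 - (pos - s0)
    return None


def naive_turnover_distance(summit_scaffold, summit, blocks, peaks_b):
    """Distance from a lifted summit to the nearest B peak interval.

    peaks_b: (scaffold, start, end) triples. Returns None when unmappable or
    when no B peak shares the lifted scaffold.
    """
    lifted = naive_lift(blocks, summit_scaffold, summit)
    if lifted is None:
        return None
    scaffold, pos = lifted
    dists = []
    for ps, p0, p1 in peaks_b:
        if ps != scaffold:
            continue
        if p0 <= pos < p1:
            dists.append(0)
        elif pos < p0:
            dists.append(p0 - pos)
        else:
            dists.append(pos - (p1 - 1))
    return min(dists) if dists else None


# ---------------------------------------------------------------------------
# Nearest-neighbour distances


def naive_nearest_neighbor(summits):
    summits = list(summits)
    out = []
    for i, s in enumerate(summits):
        out.append(min(abs(s - t) for j, t in enumerate(summits) if j != i))
    return out


# ---------------------------------------------------------------------------
# KS exhaustive permutation (small equal samples, no ties)


def ks_d(x, y):
    x, y = sorted(x), sorted(y)
    grid = sorted(set(x) | set(y))
    d = 0.0
    for g in grid:
        fx = sum(v <= g for v in x) / len(x)
        fy = sum(v <= g for v in y) / len(y)
        d = max(d, abs(fx - fy))
    return d


def ks_exhaustive_p(x, y):
    """Exact permutation p of the two-sample KS D for small samples."""
    pooled = list(x) + list(y)
    n = len(x)
    d_obs = ks_d(x, y)
    count = total = 0
    for pick in combinations(range(len(pooled)), n):
        a = [pooled[i] for i in pick]
        b = [pooled[i] for i in range(len(pooled)) if i not in pick]
        total += 1
        if ks_d(a, b) >= d_obs - 1e-12:
            count += 1
    return count / total


# ---------------------------------------------------------------------------
# Binomial


def naive_binomial_two_sided(k, n, p0=0.5):
    def pmf(i):
        return math.comb(n, i) * p0**i * (1 - p0) ** (n - i)

    lower = sum(pmf(i) for i in range(0, k + 1))
    upper = sum(pmf(i) for i in range(k, n + 1))
    return min(1.0, 2.0 * min(lower, upper))
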