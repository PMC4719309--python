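"""Position weight matrices and FIMO-style scanning with exact p-values.

Log-odds scores are in bits. P-values are computed from the exact
distribution of integer-rescaled column scores under the background model
(dynamic programming over columns); the rescaling granularity is 1/100 bit,
so reported p-values carry a bounded discretisation error of at most
``width`` hundredths of a bit in the score threshold.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .model import GenomicInterval, reverse_complement

ALPHABET = "ACGT"
_INDEX = {c: i for i, c in enumerate(ALPHABET)}

#: integer score units per bit for the exact p-value DP
SCALE = 100


class PWM:
    """Position weight matrix: 4×width counts + pseudocount + background."""

    def __init__(
        self,
        counts: np.ndarray,
        pseudocount: float = 0.5,
        background: np.ndarray | None = None,
    ) -> None:
        counts = np.asarray(counts, dtype=float)
        if counts.ndim != 2 or counts.shape[0] != 4:
            raise ValueError("counts must be a 4 x width matrix")
        if (counts < 0).any():
            raise ValueError("counts must be non-negative")
        if background is None:
            background = np.full(4, 0.25)
        background = np.asarray(background, dtype=float)
        if background.shape != (4,) or not np.isclose(background.sum(), 1.0):
            raise ValueError("background must be 4 frequencies summing to 1")
        colsums = counts.sum(axis=0) + 4 * pseudocount
        if (colsums <= 0).any():
            raise ValueError("zero column sum after pseudocount")
        self.counts = counts
        self.pseudocount = pseudocount
        self.background = background
        probs = (counts + pseudocount) / colsums
        with np.errstate(divide="ignore"):
            self.log_odds = np.log2(probs / background[:, None])
        self._pvalue_cache: tuple[np.ndarray, np.ndarray] | None = None

    @property
    def width(self) -> int:
        return self.counts.shape[1]

    @classmethod
    def from_instances(
        cls,
        instances: list[str],
        pseudocount: float = 0.5,
        background: np.ndarray | None = None,
    ) -> "PWM":
        if not instances:
            raise ValueError("need at least one instance")
        width = len(instances[0])
        counts = np.zeros((4, width))
        for inst in instances:
            if len(inst) != width:
                raise ValueError(f"instance {inst!r} has width {len(inst)} != {width}")
            for j, c in enumerate(inst.upper()):
                if c not in _INDEX:
                    raise ValueError(f"instance {inst!r} contains non-ACGT letter")
                counts[_INDEX[c], j] += 1
        return cls(counts, pseudocount, background)

    def consensus(self) -> str:
        return "".join(ALPHABET[i] for i in self.counts.argmax(axis=0))

    def score(self, window: str) -> float:
        """Log-odds score of one width-long window; NaN if it contains N."""
        total = 0.0
        for j, c in enumerate(window.upper()):
            idx = _INDEX.get(c)
            if idx is None:
                return float("nan")
            total += self.log_odds[idx, j]
        return total

    # -- exact p-values ----------------------------------------------------

    def _integer_scores(self) -> np.ndarray:
        scaled = self.log_odds * SCALE
        # -inf columns (zero count, zero pseudocount) get a sentinel far below
        # every achievable score so they zero the tail correctly
        floor = -SCALE * 1000
        return np.where(np.isfinite(scaled), np.rint(scaled), floor).astype(int)

    def _score_distribution(self) -> tuple[np.ndarray, np.ndarray]:
        """(sorted integer scores, P(S >= score)) under the background model."""
        if self._pvalue_cache is not None:
            return self._pvalue_cache
        ints = self._integer_scores()
        dist: dict[int, float] = {0: 1.0}
        for j in range(self.width):
            nxt: dict[int, float] = {}
            for s, p in dist.items():
                for i in range(4):
                    key = s + ints[i, j]
                    nxt[key] = nxt.get(key, 0.0) + p * self.background[i]
            dist = nxt
        scores = np.array(sorted(dist))
        probs = np.array([dist[s] for s in scores])
        # clip: cumulative float error can push the total mass above 1
        tail = np.minimum(probs[::-1].cumsum()[::-1], 1.0)  # P(S >= score)
        self._pvalue_cache = (scores, tail)
        return self._pvalue_cache

    def pvalue(self, score: float) -> float:
        """P(score' >= score) for a background window; in (0, 1]."""
        if np.isnan(score) or score == float("-inf"):
            return 1.0
        if score == float("inf"):
            score = 1e6  # above any achievable score
        scores, tail = self._score_distribution()
        target = int(np.rint(score * SCALE))
        idx = np.searchsorted(scores, target, side="left")
        if idx >= len(scores):
            return float(tail[-1])  # above max achievable: smallest tail
        return float(tail[idx])


@dataclass(frozen=True)
class MotifHit:
    """A scored, stranded PWM match."""

    interval: GenomicInterval
    score: float
    p_value: float
    sequence: str

    @property
    def strand(self) -> str:
        return self.interval.strand

    @property
    def start(self) -> int:
        return self.interval.start


def scan_pwm(
    sequence: str,
    pwm: PWM,
    p_threshold: float = 1e-4,
    scaffold: str = "seq",
    offset: int = 0,
) -> list[MotifHit]:
    """Scan both strands; return hits with p <= threshold sorted by position.

    Windows containing N are unscorable and skipped. Coordinates are relative
    to ``offset`` on ``scaffold`` (forward-strand coordinates for both
    strands; a '-' hit covers the same bases, scored on the complement).
    """
    sequence = sequence.upper()
    w = pwm.width
    if len(sequence) < w:
        return []
    hits = []
    rc = reverse_complement(sequence)
    n = len(sequence)
    for i in range(n - w + 1):
        for strand, window in (
            ("+", sequence[i : i + w]),
            ("-", rc[n - w - i : n - i]),
        ):
            score = pwm.score(window)
            if np.isnan(score):
                continue
            p = pwm.pvalue(score)
            if p <= p_threshold:
                hits.append(
                    MotifHit(
                        interval=GenomicInterval(scaffold, offset + i, offset + i + w, strand),
                        score=score,
                        p_value=p,
                        sequence=window,
                    )
                )
    hits.sort(key=lambda h: (h.start, h.strand))
    return hits


def best_hit(sequence: str, pwm: PWM) -> MotifHit | None:
    """Maximal-scoring hit over both strands; ties go to the forward strand."""
    hits = scan_pwm(sequence, pwm, p_threshold=1.0)
    if not hits:
        return None
    return max(hits, key=lambda h: (h.score, h.strand == "+", -h.start))
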