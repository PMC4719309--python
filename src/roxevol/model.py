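"""Shared genomic data model.

All coordinates are 0-based, half-open ``[start, end)``; BED-style on disk.
GFF-style 1-based inclusive input is converted on read. Summits are stored as
absolute genomic positions, not offsets into their peak.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np

MULLER_ELEMENTS = ("A", "B", "C", "D", "E", "F")
UNASSIGNED = "unassigned"


@dataclass(frozen=True)
class GenomicInterval:
    """Half-open interval on a scaffold, optionally stranded.

    ``strand`` is ``'+'``, ``'-'`` or ``'.'`` (unstranded).
    """

    scaffold: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.scaffold}:{self.start}-{self.end}"
            )
        if self.strand not in ("+", "-", "."):
            raise ValueError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def contains(self, position: int) -> bool:
        return self.start <= position < self.end

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.scaffold == other.scaffold
            and self.start < other.end
            and other.start < self.end
        )

    def distance_to(self, position: int) -> int:
        """Base-pair distance from ``position`` to the interval (0 if inside)."""
        if position < self.start:
            return self.start - position
        if position >= self.end:
            return position - (self.end - 1)
        return 0


class Genome:
    """Scaffold sequences (uppercase A/C/G/T/N) plus optional Müller-element labels."""

    def __init__(
        self,
        scaffolds: Mapping[str, str],
        me_label: Mapping[str, str] | None = None,
    ) -> None:
        self.scaffolds: dict[str, str] = {}
        for name, seq in scaffolds.items():
            if name in self.scaffolds:
                raise ValueError(f"duplicate scaffold {name}")
            seq = seq.upper()
            if set(seq) - set("ACGTN"):
                raise ValueError(f"non-ACGTN characters in scaffold {name}")
            self.scaffolds[name] = seq
        self.me_label: dict[str, str] = dict(me_label or {})
        for name, label in self.me_label.items():
            if label not in MULLER_ELEMENTS and label != UNASSIGNED:
                raise ValueError(f"invalid ME label {label!r} for {name}")

    def __contains__(self, name: str) -> bool:
        return name in self.scaffolds

    def __getitem__(self, name: str) -> str:
        return self.scaffolds[name]

    def length(self, name: str) -> int:
        return len(self.scaffolds[name])

    def fetch(self, interval: GenomicInterval) -> str:
        """Sequence of an interval, reverse-complemented for '-' strand."""
        seq = self.scaffolds[interval.scaffold][interval.start : interval.end]
        if interval.strand == "-":
            seq = reverse_complement(seq)
        return seq


_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class Transcript:
    transcript_id: str
    exons: list[GenomicInterval]
    cds: list[GenomicInterval] = field(default_factory=list)
    utr5: list[GenomicInterval] = field(default_factory=list)
    utr3: list[GenomicInterval] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.exons = sorted(self.exons, key=lambda e: e.start)
        for a, b in zip(self.exons, self.exons[1:]):
            if b.start < a.end:
                raise ValueError(
                    f"overlapping exons in transcript {self.transcript_id}"
                )

    @property
    def scaffold(self) -> str:
        return self.exons[0].scaffold

    @property
    def strand(self) -> str:
        return self.exons[0].strand

    @property
    def span(self) -> GenomicInterval:
        return GenomicInterval(
            self.scaffold, self.exons[0].start, self.exons[-1].end, self.strand
        )

    def introns(self) -> list[GenomicInterval]:
        """Gaps between consecutive exons, in genomic order."""
        out = []
        for a, b in zip(self.exons, self.exons[1:]):
            if b.start > a.end:
                out.append(
                    GenomicInterval(self.scaffold, a.end, b.start, self.strand)
                )
        return out


@dataclass
class GeneModel:
    gene_id: str
    transcripts: list[Transcript]

    @property
    def strand(self) -> str:
        return self.transcripts[0].strand

    @property
    def scaffold(self) -> str:
        return self.transcripts[0].scaffold

    @property
    def span(self) -> GenomicInterval:
        start = min(t.span.start for t in self.transcripts)
        end = max(t.span.end for t in self.transcripts)
        return GenomicInterval(self.scaffold, start, end, self.strand)

    def has_annotated_utrs(self) -> bool:
        return any(t.utr5 or t.utr3 for t in self.transcripts)


@dataclass
class Peak:
    """A called binding-site peak; the unit of all evolutionary analyses.

    ``q_score`` is −log10 of the peak q-value; ``enrichment`` the ChIRP/input
    ratio; ``signal`` optional per-RNA summed coverage.
    """

    interval: GenomicInterval
    summit: int
    q_score: float
    enrichment: float
    name: str = ""
    signal: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.interval.contains(self.summit):
            raise ValueError(
                f"summit {self.summit} outside {self.interval.scaffold}:"
                f"{self.interval.start}-{self.interval.end}"
            )
        if self.q_score < 0 or self.enrichment < 0:
            raise ValueError("q_score and enrichment must be non-negative")

    @property
    def scaffold(self) -> str:
        return self.interval.scaffold


class SignalTrack:
    """Per-scaffold step vectors of non-negative coverage at a fixed bin size."""

    def __init__(self, bin_size: int = 1) -> None:
        if bin_size < 1:
            raise ValueError("bin_size must be >= 1")
        self.bin_size = bin_size
        self.values: dict[str, np.ndarray] = {}

    @classmethod
    def from_arrays(
        cls, values: Mapping[str, np.ndarray], bin_size: int = 1
    ) -> "SignalTrack":
        track = cls(bin_size)
        for name, arr in values.items():
            track.set_scaffold(name, arr)
        return track

    def set_scaffold(self, name: str, values: np.ndarray) -> None:
        arr = np.asarray(values, dtype=float)
        if (arr < 0).any():
            raise ValueError(f"negative coverage on {name}")
        self.values[name] = arr

    def scaffolds(self) -> list[str]:
        return list(self.values)

    def window_sum(self, scaffold: str, start: int, end: int) -> float:
        """Sum of coverage over base range [start, end)."""
        arr = self.values[scaffold]
        b0 = start // self.bin_size
        b1 = -(-end // self.bin_size)
        sub = arr[b0:b1]
        if self.bin_size == 1:
            return float(sub.sum())
        # partial bins at the edges weight by overlap fraction
        total = float(sub.sum()) * self.bin_size
        total -= (start - b0 * self.bin_size) * (arr[b0] if b0 < len(arr) else 0.0)
        over = b1 * self.bin_size - end
        if over and b1 - 1 < len(arr):
            total -= over * arr[b1 - 1]
        return total


@dataclass(frozen=True)
class MapBlock:
    source: GenomicInterval
    target: GenomicInterval
    orientation: str  # '+' or '-'

    def __post_init__(self) -> None:
        if len(self.source) != len(self.target):
            raise ValueError("source/target block lengths differ")
        if self.orientation not in ("+", "-"):
            raise ValueError(f"invalid orientation {self.orientation!r}")


class CoordinateMap:
    """Strand-aware piecewise interval map between two assemblies.

    Reverse-orientation convention: target = target.end − 1 − (pos − source.start).
    """

    def __init__(self, blocks: Iterable[MapBlock]) -> None:
        self.blocks = sorted(blocks, key=lambda b: (b.source.scaffold, b.source.start))
        prev: MapBlock | None = None
        for b in self.blocks:
            if (
                prev is not None
                and prev.source.scaffold == b.source.scaffold
                and b.source.start < prev.source.end
            ):
                raise ValueError("overlapping source blocks")
            prev = b

    def map_point(self, scaffold: str, position: int) -> tuple[str, int] | None:
        """Map a point; None when it falls outside all source blocks."""
        for b in self.blocks:
            if b.source.scaffold == scaffold and b.source.contains(position):
                off = position - b.source.start
                if b.orientation == "+":
                    return b.target.scaffold, b.target.start + off
                return b.target.scaffold, b.target.end - 1 - off
        return None

    def inverse(self) -> "CoordinateMap":
        return CoordinateMap(
            MapBlock(b.target, b.source, b.orientation) for b in self.blocks
        )


class ChainScoreTable:
    """Chain scores per (scaffold, Müller element)."""

    def __init__(self, scores: Mapping[str, Mapping[str, float]]) -> None:
        self.scores: dict[str, dict[str, float]] = {}
        for scaffold, row in scores.items():
            clean = {me: float(s) for me, s in row.items()}
            if not clean:
                raise ValueError(f"no ME columns for scaffold {scaffold}")
            for me, s in clean.items():
                if me not in MULLER_ELEMENTS:
                    raise ValueError(f"unknown ME {me!r}")
                if not np.isfinite(s) or s < 0:
                    raise ValueError(f"invalid chain score for {scaffold}/{me}")
            self.scores[scaffold] = clean

    def row(self, scaffold: str) -> dict[str, float]:
        return self.scores[scaffold]

    def scaffolds(self) -> list[str]:
        return list(self.scores)


class Phylogeny:
    """Rooted species tree with patristic-distance ordering of leaves."""

    def __init__(self, tree) -> None:  # dendropy.Tree
        self.tree = tree
        labels = [leaf.taxon.label for leaf in tree.leaf_node_iter()]
        if len(labels) != len(set(labels)):
            raise ValueError("duplicate species in phylogeny")
        self.species = labels

    def leaves_by_distance(self, reference: str) -> list[str]:
        """All species ordered by patristic distance from ``reference``.

        The reference comes first (distance 0); ties break alphabetically.
        """
        import dendropy

        if reference not in self.species:
            raise KeyError(f"species {reference!r} not in phylogeny")
        pdm = self.tree.phylogenetic_distance_matrix()
        taxa = {t.label: t for t in self.tree.taxon_namespace if t.label in self.species}
        ref = taxa[reference]
        dist = {
            label: (0.0 if label == reference else pdm.patristic_distance(ref, tax))
            for label, tax in taxa.items()
        }
        return sorted(self.species, key=lambda s: (dist[s], s))

    def patristic_distance(self, a: str, b: str) -> float:
        pdm = self.tree.phylogenetic_distance_matrix()
        taxa = {t.label: t for t in self.tree.taxon_namespace}
        return 0.0 if a == b else pdm.patristic_distance(taxa[a], taxa[b])
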