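"""Readers and writers for the external text formats the pipeline touches.

Formats: FASTA (genomes, RNA sequences), GFF3-style annotation (1-based
inclusive on disk, converted to 0-based half-open on read), BED peaks
(6 columns + summit-offset + enrichment), bedGraph signal, tab tables for
chain scores and coordinate-map blocks, and Newick phylogenies.
"""

from __future__ import annotations

import io
import logging
from typing import Iterable

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

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
)

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# FASTA


def load_fasta(text: str) -> dict[str, str]:
    return {
        rec.id: str(rec.seq).upper()
        for rec in SeqIO.parse(io.StringIO(text), "fasta")
    }


def dump_fasta(sequences: dict[str, str]) -> str:
    out = io.StringIO()
    records = [
        SeqRecord(Seq(seq), id=name, description="") for name, seq in sequences.items()
    ]
    SeqIO.write(records, out, "fasta")
    return out.getvalue()


def load_genome(fasta_text: str, me_table_text: str | None = None) -> Genome:
    me = None
    if me_table_text is not None:
        me = {}
        for line in me_table_text.splitlines():
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            scaffold, label = line.split("\t")[:2]
            me[scaffold] = label
    return Genome(load_fasta(fasta_text), me)


# ---------------------------------------------------------------------------
# Annotation (GFF3-style)

_FEATURE_KINDS = {"exon", "CDS", "five_prime_UTR", "three_prime_UTR"}


def _gff_attributes(field: str) -> dict[str, str]:
    out = {}
    for item in field.split(";"):
        item = item.strip()
        if item and "=" in item:
            key, value = item.split("=", 1)
            out[key] = value
    return out


def load_annotation(annotation_text: str) -> list[GeneModel]:
    """Parse GFF3-style feature lines into gene models.

    Exon/CDS/UTR features must carry ``Parent=<transcript>``; transcripts carry
    ``Parent=<gene>``. Transcripts with overlapping exons and records with an
    unknown strand are rejected with a logged warning. Introns are derivable as
    the gaps between a transcript's sorted exons.
    """
    tx_gene: dict[str, str] = {}
    tx_parts: dict[str, dict[str, list[GenomicInterval]]] = {}
    gene_order: list[str] = []

    for lineno, line in enumerate(annotation_text.splitlines(), 1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        fields = line.split("\t")
        if len(fields) < 9:
            logger.warning("annotation line %d: fewer than 9 columns, skipped", lineno)
            continue
        scaffold, _src, kind, start, end, _score, strand, _frame, attrs = fields[:9]
        attributes = _gff_attributes(attrs)
        if kind == "gene":
            gene_id = attributes.get("ID", "")
            if gene_id and gene_id not in gene_order:
                gene_order.append(gene_id)
            continue
        if kind in ("mRNA", "transcript", "ncRNA"):
            tid = attributes.get("ID", "")
            gid = attributes.get("Parent", tid)
            tx_gene[tid] = gid
            if gid not in gene_order:
                gene_order.append(gid)
            continue
        if kind not in _FEATURE_KINDS:
            continue
        if strand not in ("+", "-"):
            logger.warning("annotation line %d: unknown strand %r, rejected", lineno, strand)
            continue
        parent = attributes.get("Parent")
        if parent is None:
            logger.warning("annotation line %d: %s without Parent, rejected", lineno, kind)
            continue
        # GFF is 1-based inclusive; convert to 0-based half-open
        interval = GenomicInterval(scaffold, int(start) - 1, int(end), strand)
        tx_parts.setdefault(parent, {}).setdefault(kind, []).append(interval)

    genes: dict[str, list[Transcript]] = {}
    for tid, parts in tx_parts.items():
        exons = parts.get("exon", [])
        if not exons:
            continue
        try:
            transcript = Transcript(
                transcript_id=tid,
                exons=exons,
                cds=sorted(parts.get("CDS", []), key=lambda i: i.start),
                utr5=sorted(parts.get("five_prime_UTR", []), key=lambda i: i.start),
                utr3=sorted(parts.get("three_prime_UTR", []), key=lambda i: i.start),
            )
        except ValueError as exc:
            logger.warning("transcript %s rejected: %s", tid, exc)
            continue
        gid = tx_gene.get(tid, tid)
        genes.setdefault(gid, []).append(transcript)

    ordered = [g for g in gene_order if g in genes]
    ordered += [g for g in genes if g not in ordered]
    return [GeneModel(gene_id=g, transcripts=genes[g]) for g in ordered]


def dump_annotation(genes: list[GeneModel]) -> str:
    """Serialize gene models back to the GFF3-style dialect read by load_annotation."""
    lines = ["##gff-version 3"]
    kinds = [("exons", "exon"), ("cds", "CDS"), ("utr5", "five_prime_UTR"), ("utr3", "three_prime_UTR")]
    for gene in genes:
        span = gene.span
        lines.append(
            "\t".join(
                [span.scaffold, "roxevol", "gene", str(span.start + 1), str(span.end),
                 ".", gene.strand, ".", f"ID={gene.gene_id}"]
            )
        )
        for tx in gene.transcripts:
            ts = tx.span
            lines.append(
                "\t".join(
                    [ts.scaffold, "roxevol", "mRNA", str(ts.start + 1), str(ts.end),
                     ".", tx.strand, ".", f"ID={tx.transcript_id};Parent={gene.gene_id}"]
                )
            )
            for attr, kind in kinds:
                for iv in getattr(tx, attr):
                    lines.append(
                        "\t".join(
                            [iv.scaffold, "roxevol", kind, str(iv.start + 1), str(iv.end),
                             ".", iv.strand, ".", f"Parent={tx.transcript_id}"]
                        )
                    )
    return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# Peaks (BED-style)
#
# Columns: scaffold, start, end, name, q_score, strand, summit_offset,
# enrichment[, signal as "rna=value,..."]. Coordinates 0-based half-open;
# summit_offset is relative to start (summit stored absolute in memory).


def load_peaks(bed_text: str) -> list[Peak]:
    peaks = []
    for lineno, line in enumerate(bed_text.splitlines(), 1):
        line = line.strip()
        if not line or line.startswith(("#", "track")):
            continue
        fields = line.split()
        scaffold, start, end = fields[0], int(fields[1]), int(fields[2])
        if start >= end:
            logger.warning("peak line %d: start >= end, rejected", lineno)
            continue
        name = fields[3] if len(fields) > 3 else f"peak{lineno}"
        q_score = float(fields[4]) if len(fields) > 4 else 0.0
        strand = fields[5] if len(fields) > 5 else "."
        summit_offset = int(fields[6]) if len(fields) > 6 else (end - start) // 2
        enrichment = float(fields[7]) if len(fields) > 7 else 0.0
        summit = start + summit_offset
        if not (start <= summit < end):
            logger.warning("peak line %d: summit outside interval, rejected", lineno)
            continue
        signal = {}
        if len(fields) > 8 and fields[8] != ".":
            for item in fields[8].split(","):
                rna, value = item.split("=")
                signal[rna] = float(value)
        peaks.append(
            Peak(
                interval=GenomicInterval(scaffold, start, end, strand),
                summit=summit,
                q_score=q_score,
                enrichment=enrichment,
                name=name,
                signal=signal,
            )
        )
    return peaks


def dump_peaks(peaks: Iterable[Peak]) -> str:
    lines = []
    for p in peaks:
        iv = p.interval
        signal = ",".join(f"{k}={v:g}" for k, v in sorted(p.signal.items())) or "."
        lines.append(
            "\t".join(
                [iv.scaffold, str(iv.start), str(iv.end), p.name or ".",
                 f"{p.q_score:g}", iv.strand, str(p.summit - iv.start),
                 f"{p.enrichment:g}", signal]
            )
        )
    return "\n".join(lines) + ("\n" if lines else "")


# ---------------------------------------------------------------------------
# Signal (bedGraph)


def load_bedgraph(text: str, scaffold_lengths: dict[str, int]) -> SignalTrack:
    track = SignalTrack(bin_size=1)
    arrays = {
        name: np.zeros(length, dtype=float)
        for name, length in scaffold_lengths.items()
    }
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith(("#", "track")):
            continue
        scaffold, start, end, value = line.split()[:4]
        arrays[scaffold][int(start) : int(end)] = float(value)
    for name, arr in arrays.items():
        track.set_scaffold(name, arr)
    return track


def dump_bedgraph(track: SignalTrack) -> str:
    if track.bin_size != 1:
        raise ValueError("bedGraph writer requires per-base tracks")
    lines = []
    for scaffold in track.scaffolds():
        arr = track.values[scaffold]
        # run-length encode constant stretches
        change = np.flatnonzero(np.diff(arr)) + 1
        starts = np.concatenate([[0], change])
        ends = np.concatenate([change, [len(arr)]])
        for s, e in zip(starts, ends):
            v = arr[s]
            if v != 0:
                lines.append(f"{scaffold}\t{s}\t{e}\t{v:g}")
    return "\n".join(lines) + ("\n" if lines else "")


# ---------------------------------------------------------------------------
# Chain scores, coordinate maps, phylogeny


def load_chain_scores(text: str) -> ChainScoreTable:
    scores: dict[str, dict[str, float]] = {}
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        scaffold, me, score = line.split("\t")[:3]
        scores.setdefault(scaffold, {})[me] = float(score)
    return ChainScoreTable(scores)


def dump_chain_scores(table: ChainScoreTable) -> str:
    lines = []
    for scaffold in table.scaffolds():
        for me, score in sorted(table.row(scaffold).items()):
            lines.append(f"{scaffold}\t{me}\t{score:g}")
    return "\n".join(lines) + ("\n" if lines else "")


def load_coordinate_map(text: str) -> CoordinateMap:
    blocks = []
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        f = line.split("\t")
        blocks.append(
            MapBlock(
                source=GenomicInterval(f[0], int(f[1]), int(f[2])),
                target=GenomicInterval(f[3], int(f[4]), int(f[5])),
                orientation=f[6],
            )
        )
    return CoordinateMap(blocks)


def dump_coordinate_map(cmap: CoordinateMap) -> str:
    lines = []
    for b in cmap.blocks:
        lines.append(
            "\t".join(
                [b.source.scaffold, str(b.source.start), str(b.source.end),
                 b.target.scaffold, str(b.target.start), str(b.target.end),
                 b.orientation]
            )
        )
    return "\n".join(lines) + ("\n" if lines else "")


def load_phylogeny(newick_text: str) -> Phylogeny:
    import dendropy

    tree = dendropy.Tree.get(data=newick_text, schema="newick")
    return Phylogeny(tree)


def dump_phylogeny(phylogeny: Phylogeny) -> str:
    return phylogeny.tree.as_string(schema="newick")
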