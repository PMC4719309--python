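import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from roxevol.model import GeneModel, GenomicInterval, Genome, Peak, Transcript

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(20160101)


@pytest.fixture
def toy_genome():
    """Two scaffolds: chr1 is genic, chr2 plain background."""
    seq1 = ("ACGT" * 300)[:1000]
    seq2 = ("GGCA" * 100)[:400]
    return Genome({"chr1": seq1, "chr2": seq2}, {"chr1": "A", "chr2": "B"})


def make_gene(gene_id, scaffold, exon_bounds, strand, cds_bounds=None,
              utr5=None, utr3=None):
    exons = [GenomicInterval(scaffold, s, e, strand) for s, e in exon_bounds]
    cds = [GenomicInterval(scaffold, s, e, strand) for s, e in (cds_bounds or exon_bounds)]
    u5 = [GenomicInterval(scaffold, s, e, strand) for s, e in (utr5 or [])]
    u3 = [GenomicInterval(scaffold, s, e, strand) for s, e in (utr3 or [])]
    tx = Transcript(
        transcript_id=f"{gene_id}.t1", exons=exons, cds=cds, utr5=u5, utr3=u3
    )
    return GeneModel(gene_id=gene_id, transcripts=[tx])


@pytest.fixture
def toy_genes():
    """A '+' gene with one intron and a '-' gene with one intron on chr1."""
    plus = make_gene("gplus", "chr1", [(100, 200), (300, 400)], "+")
    minus = make_gene("gminus", "chr1", [(500, 600), (700, 800)], "-")
    return [plus, minus]


def make_peak(scaffold, start, end, summit=None, q=5000.0, enr=30.0,
              name="p", signal=None):
    return Peak(
        interval=GenomicInterval(scaffold, start, end),
        summit=(start + end) // 2 if summit is None else summit,
        q_score=q,
        enrichment=enr,
        name=name,
        signal=signal or {},
    )
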