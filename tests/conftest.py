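import numpy as np
import pytest

from nmdtools.annotation import AnnotationSet, GeneModel, GenomicInterval, TranscriptModel


def make_transcript(
    tid="t1",
    gid="g1",
    strand="+",
    exon_bounds=((0, 100), (200, 300)),
    cds=None,
    chrom="chr1",
):
    """Build a TranscriptModel from genomic exon bounds (left-to-right)."""
    bounds = sorted(exon_bounds)
    if strand == "-":
        bounds = bounds[::-1]
    exons = [GenomicInterval(chrom, s, e, strand) for s, e in bounds]
    cds_start, cds_end = cds if cds else (None, None)
    return TranscriptModel(
        transcript_id=tid,
        gene_id=gid,
        strand=strand,
        exons=exons,
        cds_start=cds_start,
        cds_end=cds_end,
    )


def make_annotation(transcripts):
    genes = {}
    for t in transcripts:
        genes.setdefault(t.gene_id, GeneModel(gene_id=t.gene_id)).transcripts.append(t)
    return AnnotationSet(genes=genes)


def mirror_transcript(model, chrom_length):
    """Mirror all coordinates (pos -> L - pos) and flip the strand."""
    new_strand = "-" if model.strand == "+" else "+"
    exons = [
        GenomicInterval(
            e.chrom, chrom_length - e.end, chrom_length - e.start, new_strand
        )
        for e in model.exons
    ]
    # mirrored exons keep transcript order under strand flip
    return TranscriptModel(
        transcript_id=model.transcript_id,
        gene_id=model.gene_id,
        strand=new_strand,
        exons=exons,
        cds_start=chrom_length - model.cds_end if model.is_coding else None,
        cds_end=chrom_length - model.cds_start if model.is_coding else None,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)
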