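"""Transcript annotation models and genomic <-> spliced-mRNA coordinate maps.

All internal coordinates are 0-based half-open; GTF input/output converts at
the boundary (GTF is 1-based inclusive). Exons of a transcript are stored in
transcript orientation: 5'->3' of the mRNA, i.e. in reverse genomic order on
the minus strand.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Optional

from gffutils.feature import feature_from_line

logger = logging.getLogger(__name__)

__all__ = [
    "GenomicInterval",
    "TranscriptModel",
    "GeneModel",
    "AnnotationSet",
    "GtfParseError",
    "read_gtf",
    "write_gtf",
    "genomic_to_mrna",
    "mrna_junctions",
    "three_prime_utr_start",
]


class GtfParseError(ValueError):
    """Raised for malformed GTF lines or inconsistent transcript models."""


@dataclass(frozen=True)
class GenomicInterval:
    """A stranded genomic interval, 0-based half-open."""

    chrom: str
    start: int
    end: int
    strand: str

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval [{self.start}, {self.end}) on {self.chrom}"
            )
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )


@dataclass
class TranscriptModel:
    """Exon/CDS structure of one transcript.

    ``exons`` are in transcript orientation (first element is the 5'-most
    exon of the mRNA). ``cds_start``/``cds_end`` are genomic 0-based
    half-open bounds of the coding region including the stop codon, or
    ``None`` for non-coding transcripts.
    """

    transcript_id: str
    gene_id: str
    strand: str
    exons: list[GenomicInterval]
    cds_start: Optional[int] = None
    cds_end: Optional[int] = None

    def __post_init__(self) -> None:
        if not self.exons:
            raise ValueError(f"{self.transcript_id}: transcript has no exons")
        chroms = {e.chrom for e in self.exons}
        if len(chroms) != 1:
            raise ValueError(f"{self.transcript_id}: exons on multiple chromosomes")
        if any(e.strand != self.strand for e in self.exons):
            raise ValueError(f"{self.transcript_id}: exon strand mismatch")
        genomic = sorted(self.exons, key=lambda e: e.start)
        for a, b in zip(genomic, genomic[1:]):
            if a.end > b.start:
                raise ValueError(f"{self.transcript_id}: overlapping exons")
        expected = genomic if self.strand == "+" else genomic[::-1]
        if list(self.exons) != expected:
            raise ValueError(
                f"{self.transcript_id}: exons not in transcript orientation"
            )
        if (self.cds_start is None) != (self.cds_end is None):
            raise ValueError(f"{self.transcript_id}: partial CDS bounds")
        if self.cds_start is not None:
            if not self._covered(self.cds_start) or not self._covered(self.cds_end - 1):
                raise GtfParseError(
                    f"{self.transcript_id}: CDS [{self.cds_start}, {self.cds_end}) "
                    "not contained in the exon union"
                )

    def _covered(self, pos: int) -> bool:
        return any(e.start <= pos < e.end for e in self.exons)

    @property
    def chrom(self) -> str:
        return self.exons[0].chrom

    @property
    def is_coding(self) -> bool:
        return self.cds_start is not None

    @property
    def spliced_length(self) -> int:
        return sum(len(e) for e in self.exons)

    @property
    def n_exons(self) -> int:
        return len(self.exons)


@dataclass
class GeneModel:
    """All annotated isoforms of one gene."""

    gene_id: str
    transcripts: list[TranscriptModel] = field(default_factory=list)

    def __post_init__(self) -> None:
        if any(t.gene_id != self.gene_id for t in self.transcripts):
            raise ValueError(f"{self.gene_id}: member transcript gene_id mismatch")
        chroms = {t.chrom for t in self.transcripts}
        if len(chroms) > 1:
            raise ValueError(f"{self.gene_id}: transcripts on multiple chromosomes")

    @property
    def chrom(self) -> str:
        return self.transcripts[0].chrom

    @property
    def strand(self) -> str:
        return self.transcripts[0].strand

    @property
    def span(self) -> tuple[int, int]:
        starts = [e.start for t in self.transcripts for e in t.exons]
        ends = [e.end for t in self.transcripts for e in t.exons]
        return min(starts), max(ends)


@dataclass
class AnnotationSet:
    """A set of gene models keyed by gene id; transcript ids are unique."""

    genes: dict[str, GeneModel]
    source_tag: str = ""

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for gene in self.genes.values():
            for t in gene.transcripts:
                if t.transcript_id in seen:
                    raise ValueError(f"duplicate transcript id {t.transcript_id}")
                seen.add(t.transcript_id)

    def transcripts(self) -> Iterable[TranscriptModel]:
        for gene in self.genes.values():
            yield from gene.transcripts

    def get_transcript(self, transcript_id: str) -> TranscriptModel:
        for t in self.transcripts():
            if t.transcript_id == transcript_id:
                return t
        raise KeyError(transcript_id)

    @property
    def n_transcripts(self) -> int:
        return sum(len(g.transcripts) for g in self.genes.values())


# ---------------------------------------------------------------------------
# GTF I/O
# ---------------------------------------------------------------------------

def _single_attr(feature, key: str, lineno: int):
    try:
        return feature.attributes[key][0]
    except (KeyError, IndexError):
        raise GtfParseError(
            f"GTF line {lineno}: missing required attribute {key!r}"
        ) from None


def read_gtf(path: str, source_tag: str = "") -> AnnotationSet:
    """Read exon/CDS (and optional stop_codon) features into an AnnotationSet.

    GTF 1-based inclusive coordinates are converted to 0-based half-open.
    Ensembl-style GTFs exclude the stop codon from CDS lines; when
    ``stop_codon`` features are present they are appended to the CDS so that
    the internal CDS always includes the stop. Duplicate transcript records
    are resolved last-wins with a warning.
    """
    exons: dict[str, list[GenomicInterval]] = {}
    cds: dict[str, list[tuple[int, int]]] = {}
    stops: dict[str, list[tuple[int, int]]] = {}
    meta: dict[str, tuple[str, str]] = {}  # tid -> (gene_id, strand)

    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            try:
                feat = feature_from_line(line)
            except Exception as exc:
                raise GtfParseError(f"GTF line {lineno}: {exc}") from exc
            if feat.featuretype not in ("exon", "CDS", "stop_codon"):
                continue
            tid = _single_attr(feat, "transcript_id", lineno)
            gid = _single_attr(feat, "gene_id", lineno)
            if feat.strand not in ("+", "-"):
                raise GtfParseError(f"GTF line {lineno}: bad strand {feat.strand!r}")
            if tid in meta and meta[tid] != (gid, feat.strand):
                raise GtfParseError(
                    f"GTF line {lineno}: transcript {tid} changes gene/strand"
                )
            meta[tid] = (gid, feat.strand)
            start0, end0 = feat.start - 1, feat.end  # to 0-based half-open
            if feat.featuretype == "exon":
                iv = GenomicInterval(feat.seqid, start0, end0, feat.strand)
                prior = exons.setdefault(tid, [])
                if any(iv.start == p.start and iv.end == p.end for p in prior):
                    warnings.warn(
                        f"duplicate exon record for {tid} at line {lineno}; last wins"
                    )
                    continue
                prior.append(iv)
            elif feat.featuretype == "CDS":
                cds.setdefault(tid, []).append((start0, end0))
            else:
                stops.setdefault(tid, []).append((start0, end0))

    genes: dict[str, GeneModel] = {}
    for tid, (gid, strand) in meta.items():
        if tid not in exons:
            raise GtfParseError(f"transcript {tid} has CDS/stop features but no exons")
        exon_list = sorted(exons[tid], key=lambda e: e.start, reverse=(strand == "-"))
        cds_start = cds_end = None
        segs = list(cds.get(tid, [])) + list(stops.get(tid, []))
        if segs:
            cds_start = min(s for s, _ in segs)
            cds_end = max(e for _, e in segs)
        model = TranscriptModel(
            transcript_id=tid,
            gene_id=gid,
            strand=strand,
            exons=exon_list,
            cds_start=cds_start,
            cds_end=cds_end,
        )
        genes.setdefault(gid, GeneModel(gene_id=gid)).transcripts.append(model)

    return AnnotationSet(genes=genes, source_tag=source_tag or path)


def write_gtf(annotation: AnnotationSet, path: str, source: str = "nmdtools") -> None:
    """Write exon and CDS features (internal dialect: CDS includes the stop)."""
    with open(path, "w") as fh:
        for gene in annotation.genes.values():
            for t in gene.transcripts:
                attrs = f'gene_id "{t.gene_id}"; transcript_id "{t.transcript_id}";'
                for e in t.exons:
                    fh.write(
                        f"{e.chrom}\t{source}\texon\t{e.start + 1}\t{e.end}\t.\t"
                        f"{e.strand}\t.\t{attrs}\n"
                    )
                if t.is_coding:
                    for e in sorted(t.exons, key=lambda x: x.start):
                        s = max(e.start, t.cds_start)
                        en = min(e.end, t.cds_end)
                        if s < en:
                            fh.write(
                                f"{e.chrom}\t{source}\tCDS\t{s + 1}\t{en}\t.\t"
                                f"{e.strand}\t0\t{attrs}\n"
                            )


# ---------------------------------------------------------------------------
# Coordinate conversion
# ---------------------------------------------------------------------------

def genomic_to_mrna(model: TranscriptModel, pos: int) -> int:
    """Map a genomic position (0-based) to its offset along the spliced mRNA.

    Raises ValueError for intronic or out-of-transcript positions.
    """
    offset = 0
    for exon in model.exons:
        if exon.start <= pos < exon.end:
            within = (pos - exon.start) if model.strand == "+" else (exon.end - 1 - pos)
            return offset + within
        offset += len(exon)
    raise ValueError(
        f"position {pos} is not exonic in transcript {model.transcript_id}"
    )


def mrna_to_genomic(model: TranscriptModel, mpos: int) -> int:
    """Inverse of :func:`genomic_to_mrna` (0 <= mpos < spliced length)."""
    if not 0 <= mpos < model.spliced_length:
        raise ValueError(f"mRNA position {mpos} outside transcript")
    offset = 0
    for exon in model.exons:
        if mpos < offset + len(exon):
            within = mpos - offset
            return (
                exon.start + within if model.strand == "+" else exon.end - 1 - within
            )
        offset += len(exon)
    raise AssertionError("unreachable")


def mrna_junctions(model: TranscriptModel) -> list[int]:
    """mRNA coordinates of exon-exon junctions.

    For n exons, returns n-1 positions; junction i is the coordinate of the
    first base of exon i+1 (immediately 3' of the junction). Single-exon
    transcripts give an empty list.
    """
    out: list[int] = []
    total = 0
    for exon in model.exons[:-1]:
        total += len(exon)
        out.append(total)
    return out


def three_prime_utr_start(model: TranscriptModel) -> Optional[int]:
    """mRNA coordinate of the first base after the stop codon.

    None for non-coding transcripts. Equals the spliced length when the CDS
    (incl. stop) ends at the transcript's last base (empty 3'UTR).
    """
    if not model.is_coding:
        return None
    last_cds_base = model.cds_end - 1 if model.strand == "+" else model.cds_start
    return genomic_to_mrna(model, last_cds_base) + 1


def exonic_positions(model: TranscriptModel) -> list[int]:
    """All genomic positions of the transcript, in transcript order."""
    out: list[int] = []
    for exon in model.exons:
        rng = range(exon.start, exon.end)
        out.extend(rng if model.strand == "+" else reversed(rng))
    return out
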