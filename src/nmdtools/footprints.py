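"""Canonical EJC-site derivation and footprint quantification.

The exon junction complex is deposited ~24 nt upstream of exon-exon
junctions; its protected footprints accumulate in a canonical window spanning
-39 to -9 nt from the 3' end of each non-last exon (offset -1 is the exon's
final base, so the window covers 31 nt inclusive). Gene-level signal counts
reads overlapping the union of canonical windows from all of the gene's
transcripts, averaged over the number of merged windows ("intron count").
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from .annotation import AnnotationSet, GenomicInterval, TranscriptModel
from .expression import CountMatrix, DeTable, simple_de

logger = logging.getLogger(__name__)

__all__ = [
    "FootprintRead",
    "CanonicalSite",
    "GeneFootprintSignal",
    "MetaExonProfile",
    "derive_canonical_sites",
    "count_footprints",
    "rpkm_filter",
    "differential_occupancy",
    "enrichment_overlap",
    "expression_normalized_occupancy",
    "meta_exon_profile",
    "read_bed",
    "write_sites_bed",
    "signals_to_frame",
]

CANONICAL_UPSTREAM = 39  # window 5' bound: -39 nt from the exon's last base
CANONICAL_DOWNSTREAM = 9  # window 3' bound: -9 nt from the exon's last base


@dataclass(frozen=True)
class FootprintRead:
    """One aligned footprint, 0-based half-open genomic coordinates."""

    chrom: str
    start: int
    end: int
    strand: str

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError("read start must precede end")


@dataclass(frozen=True)
class CanonicalSite:
    gene_id: str
    interval: GenomicInterval


@dataclass
class GeneFootprintSignal:
    gene_id: str
    raw_count: int
    n_sites: int
    total_region_length: int
    rpkm: Optional[float] = None

    @property
    def per_site_signal(self) -> float:
        return self.raw_count / self.n_sites


def _canonical_window(exon: GenomicInterval) -> tuple[int, int]:
    """0-based half-open canonical window of one non-last exon.

    Offset -k maps to genomic (end - k) on + and (start + k - 1) on -;
    windows are truncated at the exon 5' boundary for exons < 39 nt.
    """
    if exon.strand == "+":
        lo = max(exon.start, exon.end - CANONICAL_UPSTREAM)
        hi = exon.end - CANONICAL_DOWNSTREAM + 1
    else:
        lo = exon.start + CANONICAL_DOWNSTREAM - 1
        hi = min(exon.end, exon.start + CANONICAL_UPSTREAM)
    return lo, hi


def _merge(intervals: list[tuple[int, int]]) -> list[tuple[int, int]]:
    merged: list[list[int]] = []
    for lo, hi in sorted(intervals):
        if merged and lo <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], hi)
        else:
            merged.append([lo, hi])
    return [(lo, hi) for lo, hi in merged]


def derive_canonical_sites(
    annotation: AnnotationSet,
    representative_transcript: bool = False,
) -> dict[str, list[CanonicalSite]]:
    """Canonical EJC windows per gene, merged across isoforms.

    Every non-last exon (in transcript orientation) contributes a window; per
    gene the windows of all transcripts are unioned and overlapping ones
    merged, so ``n_sites`` counts merged regions. With
    ``representative_transcript=True`` only the isoform with the longest CDS
    (ties: longest spliced length, then id) is used.
    """
    out: dict[str, list[CanonicalSite]] = {}
    for gid, gene in annotation.genes.items():
        transcripts: Sequence[TranscriptModel] = gene.transcripts
        if representative_transcript:
            transcripts = [
                max(
                    gene.transcripts,
                    key=lambda t: (
                        (t.cds_end - t.cds_start) if t.is_coding else 0,
                        t.spliced_length,
                        t.transcript_id,
                    ),
                )
            ]
        raw: list[tuple[int, int]] = []
        for t in transcripts:
            for exon in t.exons[:-1]:  # last exon contributes no site
                lo, hi = _canonical_window(exon)
                if hi > lo:
                    raw.append((lo, hi))
        if not raw:
            continue
        out[gid] = [
            CanonicalSite(
                gene_id=gid,
                interval=GenomicInterval(gene.chrom, lo, hi, gene.strand),
            )
            for lo, hi in _merge(raw)
        ]
    return out


def count_footprints(
    reads: Iterable[FootprintRead],
    sites: dict[str, list[CanonicalSite]],
    strand_matched: bool = True,
) -> dict[str, GeneFootprintSignal]:
    """Count reads overlapping each gene's merged canonical windows.

    A read counts once per gene when it overlaps >= 1 nt of any of that
    gene's windows (half-open convention: an abutting read does not count).
    """
    trees: dict[tuple[str, str], IntervalTree] = {}
    for gid, site_list in sites.items():
        for site in site_list:
            iv = site.interval
            key = (iv.chrom, iv.strand if strand_matched else ".")
            trees.setdefault(key, IntervalTree()).addi(iv.start, iv.end, gid)

    counts: dict[str, int] = {gid: 0 for gid in sites}
    multi_gene_hits = 0
    for read in reads:
        key = (read.chrom, read.strand if strand_matched else ".")
        tree = trees.get(key)
        if tree is None:
            continue
        genes_hit = {hit.data for hit in tree.overlap(read.start, read.end)}
        if len(genes_hit) > 1:
            multi_gene_hits += 1
        for gid in genes_hit:
            counts[gid] += 1
    if multi_gene_hits:
        logger.info(
            "%d reads overlapped canonical regions of more than one gene",
            multi_gene_hits,
        )

    return {
        gid: GeneFootprintSignal(
            gene_id=gid,
            raw_count=counts[gid],
            n_sites=len(site_list),
            total_region_length=sum(len(s.interval) for s in site_list),
        )
        for gid, site_list in sites.items()
    }


def rpkm_filter(
    signals: dict[str, GeneFootprintSignal],
    library_size: int,
    min_rpkm: float = 5.0,
) -> dict[str, GeneFootprintSignal]:
    """Drop genes with canonical-region RPKM <= min_rpkm (boundary removed).

    rpkm = raw_count / (region_kb * library_millions); ``library_size`` is
    the sample's total mapped reads.
    """
    if library_size <= 0:
        raise ValueError("library_size must be positive")
    kept: dict[str, GeneFootprintSignal] = {}
    for gid, sig in signals.items():
        rpkm = sig.raw_count / (
            (sig.total_region_length / 1e3) * (library_size / 1e6)
        )
        if rpkm > min_rpkm:
            kept[gid] = GeneFootprintSignal(
                gene_id=sig.gene_id,
                raw_count=sig.raw_count,
                n_sites=sig.n_sites,
                total_region_length=sig.total_region_length,
                rpkm=rpkm,
            )
    return kept


def differential_occupancy(
    gene_counts: CountMatrix, contrast: tuple[str, str]
) -> DeTable:
    """Differential EJC occupancy between two RIPiT compositions.

    Gene-level canonical-site counts across samples are compared with the
    package's simplified differential-expression model.
    """
    return simple_de(gene_counts, contrast)


def enrichment_overlap(
    de_a: DeTable,
    de_b: DeTable,
    alpha: float = 0.05,
    fc: float = 1.0,
) -> dict:
    """Overlap of enriched gene sets from two occupancy contrasts.

    Enriched: adjusted p < alpha and fold change > fc. Also reports the
    discordant sets (enriched in one, depleted in the other).
    """
    log_fc = np.log2(fc)

    def _sets(t: DeTable) -> tuple[set[str], set[str]]:
        tab = t.table
        sig = tab["adjusted_p"] < alpha
        up = set(t.ids[(sig & (tab["log2_fold_change"] > log_fc)).fillna(False)])
        down = set(t.ids[(sig & (tab["log2_fold_change"] < -log_fc)).fillna(False)])
        return up, down

    up_a, down_a = _sets(de_a)
    up_b, down_b = _sets(de_b)
    union = up_a | up_b
    return {
        "enriched_a": up_a,
        "enriched_b": up_b,
        "intersection": up_a & up_b,
        "jaccard": (len(up_a & up_b) / len(union)) if union else 0.0,
        "a_up_b_down": up_a & down_b,
        "b_up_a_down": up_b & down_a,
    }


def expression_normalized_occupancy(
    signals: dict[str, GeneFootprintSignal],
    rna_rpkm: pd.Series,
) -> pd.Series:
    """Length-normalized EJC signal divided by the gene's RNA-seq RPKM.

    Genes with zero/absent RNA RPKM are excluded (logged). Doubling both the
    footprint counts and the RNA RPKM leaves the value unchanged.
    """
    vals: dict[str, float] = {}
    skipped = 0
    for gid, sig in signals.items():
        rpkm = rna_rpkm.get(gid)
        if rpkm is None or not np.isfinite(rpkm) or rpkm <= 0:
            skipped += 1
            continue
        vals[gid] = (sig.raw_count / sig.total_region_length) / float(rpkm)
    if skipped:
        logger.info("%d genes excluded for zero/missing RNA RPKM", skipped)
    return pd.Series(vals, name="expression_normalized_occupancy")


@dataclass
class MetaExonProfile:
    """Averaged normalized read 5'-end density around exon boundaries.

    ``five_prime[k]`` is the density at offset +k from exon starts
    (k = 0..window-1); ``three_prime[k]`` is the density at offset
    -(window-k) from exon 3' ends, i.e. the last array element is offset -1.
    """

    window: int
    five_prime: np.ndarray
    three_prime: np.ndarray
    n_genes: int

    def three_prime_offsets(self) -> np.ndarray:
        return np.arange(-self.window, 0)

    def argmax_three_prime_offset(self) -> int:
        """Offset (negative) of the 3'-anchored density maximum."""
        return int(self.three_prime_offsets()[int(np.argmax(self.three_prime))])


def _read_five_prime_end(read: FootprintRead) -> int:
    return read.start if read.strand == "+" else read.end - 1


def meta_exon_profile(
    reads: Iterable[FootprintRead],
    annotation: AnnotationSet,
    window: int = 100,
    min_gene_reads: int = 10,
    strand_matched: bool = True,
) -> MetaExonProfile:
    """Meta-exon read distribution anchored at exon starts and 3' ends.

    Read positions (5' ends) falling within ``window`` nt of an exon boundary
    are histogrammed per gene, normalized by the gene's total read count, and
    averaged across genes with at least ``min_gene_reads`` reads.
    """
    # assign reads to genes by 5'-end position within any exon
    trees: dict[tuple[str, str], IntervalTree] = {}
    for gid, gene in annotation.genes.items():
        exon_union = _merge(
            [(e.start, e.end) for t in gene.transcripts for e in t.exons]
        )
        for lo, hi in exon_union:
            key = (gene.chrom, gene.strand if strand_matched else ".")
            trees.setdefault(key, IntervalTree()).addi(lo, hi, gid)

    gene_positions: dict[str, list[int]] = {}
    for read in reads:
        pos = _read_five_prime_end(read)
        key = (read.chrom, read.strand if strand_matched else ".")
        tree = trees.get(key)
        if tree is None:
            continue
        for hit in tree.at(pos):
            gene_positions.setdefault(hit.data, []).append(pos)

    five_acc = np.zeros(window)
    three_acc = np.zeros(window)
    n_genes = 0
    for gid, positions in gene_positions.items():
        if len(positions) < min_gene_reads:
            continue
        gene = annotation.genes[gid]
        exons = {
            (e.start, e.end)
            for t in gene.transcripts
            for e in t.exons
        }
        five = np.zeros(window)
        three = np.zeros(window)
        pos_arr = np.asarray(positions)
        for lo, hi in exons:
            if gene.strand == "+":
                off5 = pos_arr - lo
                off3 = pos_arr - hi  # -1 is the exon's last base
            else:
                off5 = hi - 1 - pos_arr
                off3 = lo - 1 - pos_arr
            in5 = (off5 >= 0) & (off5 < window)
            in3 = (off3 >= -window) & (off3 < 0)
            np.add.at(five, off5[in5], 1)
            np.add.at(three, off3[in3] + window, 1)
        total = len(positions)
        five_acc += five / total
        three_acc += three / total
        n_genes += 1

    if n_genes == 0:
        warnings.warn("no gene passed the minimum read filter: empty profile")
        return MetaExonProfile(
            window=window,
            five_prime=np.zeros(window),
            three_prime=np.zeros(window),
            n_genes=0,
        )
    return MetaExonProfile(
        window=window,
        five_prime=five_acc / n_genes,
        three_prime=three_acc / n_genes,
        n_genes=n_genes,
    )


# ---------------------------------------------------------------------------
# BED / TSV I/O
# ---------------------------------------------------------------------------

def read_bed(path: str) -> list[FootprintRead]:
    """Read BED6 footprint reads (chrom, start, end, name, score, strand)."""
    df = pd.read_csv(
        path,
        sep="\t",
        header=None,
        usecols=[0, 1, 2, 5],
        names=["chrom", "start", "end", "strand"],
        comment="#",
    )
    return [
        FootprintRead(chrom=r.chrom, start=int(r.start), end=int(r.end), strand=r.strand)
        for r in df.itertuples(index=False)
    ]


def write_sites_bed(sites: dict[str, list[CanonicalSite]], path: str) -> None:
    with open(path, "w") as fh:
        for gid in sorted(sites):
            for i, site in enumerate(sites[gid]):
                iv = site.interval
                fh.write(
                    f"{iv.chrom}\t{iv.start}\t{iv.end}\t{gid}.site{i}\t0\t{iv.strand}\n"
                )


def signals_to_frame(signals: dict[str, GeneFootprintSignal]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "gene_id": s.gene_id,
                "raw_count": s.raw_count,
                "n_sites": s.n_sites,
                "per_site_signal": s.per_site_signal,
                "total_region_length": s.total_region_length,
                "rpkm": s.rpkm,
            }
            for s in signals.values()
        ]
    ).set_index("gene_id")
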