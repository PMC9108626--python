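"""Synthetic data with known ground truth for every pipeline stage.

The generator emulates the statistical structure the analysis assumes:
multi-exon coding transcripts with and without NMD-inducing splice-junction
configurations, negative-binomial replicate count matrices with
condition-specific fold-change injections on the PTC+ group, footprint reads
peaked ~24 nt upstream of non-last exon 3' ends, and exponential reporter
decay courses. Every artifact is a pure function of (config, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .annotation import AnnotationSet, GeneModel, GenomicInterval, TranscriptModel
from .footprints import FootprintRead
from .expression import CountMatrix

__all__ = [
    "SimConfig",
    "SimTruth",
    "simulate_annotation",
    "simulate_counts",
    "simulate_footprints",
    "simulate_decay_course",
]


@dataclass(frozen=True)
class SimConfig:
    """Study-condition parameters of the synthetic generator.

    Defaults mirror the analysis conditions: ~1.5-fold NMD effects injected
    into PTC+ transcripts of a knockout-like condition, negative-binomial
    counts with moderate dispersion, four replicates per condition, and EJC
    footprints peaked at -24 nt from exon 3' ends with a small uniform
    background. The deposition offset is fixed by splicing geometry, so its
    default jitter (s.d. 2 nt) is small relative to the 31-nt canonical
    window; both are configurable.
    """

    n_genes: int = 100
    isoforms_per_gene: tuple[int, int] = (1, 3)
    exons_per_transcript: tuple[int, int] = (2, 8)
    exon_length: tuple[int, int] = (120, 600)
    intron_length: tuple[int, int] = (80, 400)
    fraction_ptc_plus: float = 0.4
    nb_mean: tuple[float, float] = (50.0, 500.0)
    nb_dispersion: float = 0.05
    # condition -> fold change applied to true-PTC+ transcripts
    effects: dict = field(
        default_factory=lambda: {"control": 1.0, "knockout": 1.5}
    )
    n_replicates: int = 4
    peak_offset: int = -24
    peak_sd: float = 2.0
    read_length: int = 35
    background_fraction: float = 0.05
    n_footprint_reads: int = 10_000
    library_jitter_sd: float = 0.1
    chrom: str = "chrSim"

    def __post_init__(self) -> None:
        if not 0.0 <= self.fraction_ptc_plus <= 1.0:
            raise ValueError("fraction_ptc_plus must lie in [0, 1]")
        if not 0.0 <= self.background_fraction <= 1.0:
            raise ValueError("background_fraction must lie in [0, 1]")
        if any(fc <= 0 for fc in self.effects.values()):
            raise ValueError("effect fold changes must be positive")
        if self.exons_per_transcript[0] < 2:
            raise ValueError("transcripts need >= 2 exons for junction placement")


@dataclass
class SimTruth:
    """Ground truth of one simulated annotation."""

    ptc_status: dict[str, bool]  # transcript -> true PTC+ label
    gene_of: dict[str, str]
    fold_changes: dict[str, dict[str, float]] = field(default_factory=dict)
    gene_intensity: dict[str, float] = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for tid, is_plus in self.ptc_status.items():
            row = {
                "transcript_id": tid,
                "gene_id": self.gene_of[tid],
                "true_ptc_plus": is_plus,
            }
            for cond, fc in self.fold_changes.get(tid, {}).items():
                row[f"fc_{cond}"] = fc
            rows.append(row)
        return pd.DataFrame(rows).set_index("transcript_id")


def _rand_int(rng: np.random.Generator, lo: int, hi: int) -> int:
    return int(rng.integers(lo, hi + 1))


def _place_stop(
    rng: np.random.Generator,
    exon_lengths: list[int],
    want_ptc_plus: bool,
) -> Optional[int]:
    """Choose the mRNA coordinate of the 3'UTR start for one transcript.

    Junction coordinates are the cumulative exon lengths. For PTC+ truth the
    stop is placed so that the distance rule holds with a >= 2 nt margin
    (distance to the most 3' downstream junction sampled in [52, 500]) or so
    that >= 2 junctions fall downstream; for PTC- truth the stop lands in the
    last exon or close enough (distance <= 48) to the single downstream
    junction. Returns None when the geometry cannot honor the request.
    """
    junctions = list(np.cumsum(exon_lengths[:-1]))
    total = int(np.sum(exon_lengths))
    last_j = junctions[-1]
    if want_ptc_plus:
        if len(junctions) >= 2 and rng.random() < 0.5:
            # >= 2 downstream junctions: utr start at or before junction[-2]
            hi = junctions[-2]
            lo = max(4, hi - 300)
            if hi < lo:
                return None
            return _rand_int(rng, lo, hi)
        # single downstream junction at distance d = last_j - u + 1 in [52, 500]
        d = _rand_int(rng, 52, 500)
        u = last_j - d + 1
        floor = junctions[-2] + 1 if len(junctions) >= 2 else 4
        if u < floor:
            return None
        return u
    # PTC-: stop in last exon (u > last_j) or distance <= 48 to the final junction
    if rng.random() < 0.7:
        lo, hi = last_j + 1, total - 1
        if hi < lo:
            return None
        return _rand_int(rng, lo, hi)
    d = _rand_int(rng, 1, 48)
    u = last_j - d + 1
    floor = junctions[-2] + 1 if len(junctions) >= 2 else 4
    if u < floor:
        return None
    return u


def simulate_annotation(
    cfg: SimConfig = SimConfig(), seed: int = 0
) -> tuple[AnnotationSet, SimTruth]:
    """Simulate an annotation of multi-exon coding transcripts with known
    PTC truth labels.

    Genes are laid out along one chromosome with alternating strands; each
    isoform of a gene draws its own exon chain within the gene's territory.
    Infeasible stop placements are resampled (bounded retries).
    """
    rng = np.random.default_rng(seed)
    genes: dict[str, GeneModel] = {}
    truth = SimTruth(ptc_status={}, gene_of={})
    cursor = 1000

    for g in range(cfg.n_genes):
        gid = f"G{g:05d}"
        strand = "+" if g % 2 == 0 else "-"
        n_iso = _rand_int(rng, *cfg.isoforms_per_gene)
        gene = GeneModel(gene_id=gid)
        gene_start = cursor
        gene_end = cursor
        for i in range(n_iso):
            tid = f"{gid}.T{i}"
            want_plus = bool(rng.random() < cfg.fraction_ptc_plus)
            for _attempt in range(50):
                n_exons = _rand_int(rng, *cfg.exons_per_transcript)
                exon_lengths = [
                    _rand_int(rng, *cfg.exon_length) for _ in range(n_exons)
                ]
                utr_start = _place_stop(rng, exon_lengths, want_plus)
                if utr_start is not None:
                    break
            else:
                raise RuntimeError(
                    f"could not place a stop codon for {tid} after 50 retries"
                )
            intron_lengths = [
                _rand_int(rng, *cfg.intron_length) for _ in range(n_exons - 1)
            ]
            # genomic layout left to right; on the minus strand the
            # transcript's first exon is the genomically rightmost one
            layout = exon_lengths if strand == "+" else exon_lengths[::-1]
            start = gene_start + _rand_int(rng, 0, 200)
            bounds: list[tuple[int, int]] = []
            pos = start
            for k, length in enumerate(layout):
                bounds.append((pos, pos + length))
                pos += length
                if k < n_exons - 1:
                    pos += intron_lengths[k]
            gene_end = max(gene_end, pos)

            if strand == "+":
                exons = [
                    GenomicInterval(cfg.chrom, s, e, strand) for s, e in bounds
                ]
            else:
                exons = [
                    GenomicInterval(cfg.chrom, s, e, strand)
                    for s, e in reversed(bounds)
                ]
            # map mRNA coordinates (transcript order) back to genomic CDS bounds
            cds_m_start = 3  # short 5'UTR
            cds_m_end = utr_start  # CDS incl. stop occupies [3, utr_start)
            model = TranscriptModel(
                transcript_id=tid,
                gene_id=gid,
                strand=strand,
                exons=exons,
                cds_start=None,
                cds_end=None,
            )
            g_first = _mrna_to_genomic(model, cds_m_start)
            g_last = _mrna_to_genomic(model, cds_m_end - 1)
            model.cds_start = min(g_first, g_last)
            model.cds_end = max(g_first, g_last) + 1
            # re-validate CDS containment
            model.__post_init__()

            gene.transcripts.append(model)
            truth.ptc_status[tid] = want_plus
            truth.gene_of[tid] = gid
            truth.fold_changes[tid] = {
                cond: (fc if want_plus else 1.0)
                for cond, fc in cfg.effects.items()
            }
        genes[gid] = gene
        truth.gene_intensity[gid] = float(rng.lognormal(0.0, 0.5))
        cursor = gene_end + 5000

    return AnnotationSet(genes=genes, source_tag=f"sim(seed={seed})"), truth


def _mrna_to_genomic(model: TranscriptModel, mpos: int) -> int:
    from .annotation import mrna_to_genomic

    return mrna_to_genomic(model, mpos)


def simulate_counts(
    annotation: AnnotationSet,
    truth: SimTruth,
    cfg: SimConfig = SimConfig(),
    seed: int = 0,
) -> CountMatrix:
    """Negative-binomial transcript counts for every condition and replicate.

    Per-transcript baseline means are log-uniform over ``cfg.nb_mean``;
    condition fold changes from the truth table multiply the mean; per-sample
    library-size factors are log-normal(0, cfg.library_jitter_sd) so the
    normalization step has signal to recover. NB parameterized by mean mu and
    dispersion a (variance mu + a mu^2); dispersion 0 degenerates to Poisson.
    """
    rng = np.random.default_rng(seed)
    tids = [t.transcript_id for t in annotation.transcripts()]
    lengths = pd.Series(
        {t.transcript_id: t.spliced_length for t in annotation.transcripts()}
    )
    lo, hi = cfg.nb_mean
    base = np.exp(rng.uniform(np.log(lo), np.log(hi), size=len(tids)))
    base_mu = pd.Series(base, index=tids)

    columns: dict[str, np.ndarray] = {}
    conditions: dict[str, str] = {}
    for cond in cfg.effects:
        fc = np.array(
            [truth.fold_changes[tid].get(cond, 1.0) for tid in tids]
        )
        for r in range(cfg.n_replicates):
            sample = f"{cond}_rep{r + 1}"
            lib = float(np.exp(rng.normal(0.0, cfg.library_jitter_sd)))
            mu = base_mu.to_numpy() * fc * lib
            if cfg.nb_dispersion > 0:
                n_param = 1.0 / cfg.nb_dispersion
                p_param = n_param / (n_param + mu)
                columns[sample] = rng.negative_binomial(n_param, p_param)
            else:
                columns[sample] = rng.poisson(mu)
            conditions[sample] = cond
    counts = pd.DataFrame(columns, index=tids)
    return CountMatrix(counts=counts, conditions=conditions, lengths=lengths)


def simulate_footprints(
    annotation: AnnotationSet,
    cfg: SimConfig = SimConfig(),
    seed: int = 0,
    truth: Optional[SimTruth] = None,
) -> list[FootprintRead]:
    """Footprint reads peaked at ``cfg.peak_offset`` from non-last exon 3' ends.

    Signal reads pick a gene (weights: truth intensities when supplied), a
    non-last exon of one of its isoforms, then a 5' end at a normal offset
    around the peak; reads run 3' from there in transcript orientation.
    Background reads are uniform over gene spans (including last exons).
    """
    rng = np.random.default_rng(seed)
    genes = list(annotation.genes.values())
    weights = np.array(
        [
            truth.gene_intensity.get(g.gene_id, 1.0) if truth else 1.0
            for g in genes
        ]
    )
    weights = weights / weights.sum()

    # collect (strand, exon bounds) of non-last exons per gene
    gene_nonlast: list[list[GenomicInterval]] = []
    for g in genes:
        nonlast = [e for t in g.transcripts for e in t.exons[:-1]]
        gene_nonlast.append(nonlast)

    n_bg = int(round(cfg.n_footprint_reads * cfg.background_fraction))
    n_signal = cfg.n_footprint_reads - n_bg
    reads: list[FootprintRead] = []

    eligible = [i for i, nl in enumerate(gene_nonlast) if nl]
    if not eligible:
        raise ValueError("annotation has no multi-exon transcripts")
    w_eligible = weights[eligible] / weights[eligible].sum()
    choices = rng.choice(len(eligible), size=n_signal, p=w_eligible)
    for idx in choices:
        g = genes[eligible[idx]]
        exon = gene_nonlast[eligible[idx]][
            int(rng.integers(len(gene_nonlast[eligible[idx]])))
        ]
        offset = int(round(rng.normal(cfg.peak_offset, cfg.peak_sd)))
        offset = min(offset, -1)
        if exon.strand == "+":
            five = exon.end + offset
            start, end = five, five + cfg.read_length
        else:
            five = exon.start - offset - 1
            start, end = five - cfg.read_length + 1, five + 1
        if start < 0:
            continue
        reads.append(
            FootprintRead(chrom=exon.chrom, start=start, end=end, strand=exon.strand)
        )

    bg_choices = rng.choice(len(genes), size=n_bg, p=weights)
    for idx in bg_choices:
        g = genes[idx]
        lo, hi = g.span
        five = int(rng.integers(lo, hi))
        if g.strand == "+":
            start, end = five, five + cfg.read_length
        else:
            start, end = max(0, five - cfg.read_length + 1), five + 1
        reads.append(
            FootprintRead(chrom=g.chrom, start=start, end=end, strand=g.strand)
        )
    return reads


def simulate_decay_course(
    t_half: float,
    times: list[float],
    noise_sd: float = 0.0,
    n_replicates: int = 1,
    seed: int = 0,
) -> pd.DataFrame:
    """Exponential decay courses: fraction = exp(-ln2 t / t_half) with
    multiplicative log-normal noise; the t = 0 point is fixed at 1.

    Returns a frame with one row per replicate, columns = time points.
    """
    if t_half <= 0:
        raise ValueError("t_half must be positive")
    rng = np.random.default_rng(seed)
    times_arr = np.asarray(times, dtype=float)
    ideal = np.exp(-np.log(2) * times_arr / t_half)
    rows = []
    for _ in range(n_replicates):
        noise = (
            np.exp(rng.normal(0.0, noise_sd, size=times_arr.size))
            if noise_sd > 0
            else np.ones_like(times_arr)
        )
        course = ideal * noise
        course[times_arr == 0] = 1.0
        rows.append(course)
    return pd.DataFrame(rows, columns=[f"t{t:g}" for t in times_arr])


def write_reads_bed(reads: list[FootprintRead], path: str) -> None:
    """Write footprint reads as BED6."""
    with open(path, "w") as fh:
        for i, r in enumerate(reads):
            fh.write(f"{r.chrom}\t{r.start}\t{r.end}\tread{i}\t0\t{r.strand}\n")
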