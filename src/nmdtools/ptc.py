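"""50-nt-rule classification of transcripts as PTC+ / PTC- and group building.

A transcript is PTC+ (carries an NMD-inducing splice-junction configuration)
if the 3'UTR begins more than ``min_distance_nt`` (default 50) nt upstream of
an exon-exon junction, or if there are at least
``min_downstream_junctions_alt`` (default 2) junctions downstream of the stop
codon. PTC- transcripts lack both features but come from genes that express
at least one PTC+ isoform. Non-coding transcripts are unclassifiable.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Optional

import pandas as pd

from .annotation import (
    AnnotationSet,
    TranscriptModel,
    mrna_junctions,
    three_prime_utr_start,
)

logger = logging.getLogger(__name__)

__all__ = [
    "PtcStatus",
    "PtcRuleParams",
    "PtcCall",
    "PtcGrouping",
    "classify_transcript",
    "classify_annotation",
    "build_grouping",
    "calls_to_frame",
]


class PtcStatus(str, Enum):
    PTC_PLUS = "PTC_plus"
    PTC_MINUS = "PTC_minus"
    UNCLASSIFIABLE = "unclassifiable"


@dataclass(frozen=True)
class PtcRuleParams:
    """Thresholds of the 50-nt rule.

    ``strict_greater=True`` applies the "more than 50 nt" reading; False makes
    the distance test inclusive (">= 50 nt").
    """

    min_distance_nt: int = 50
    min_downstream_junctions_alt: int = 2
    strict_greater: bool = True

    def __post_init__(self) -> None:
        if self.min_distance_nt < 0:
            raise ValueError("min_distance_nt must be >= 0")
        if self.min_downstream_junctions_alt < 1:
            raise ValueError("min_downstream_junctions_alt must be >= 1")


@dataclass(frozen=True)
class PtcCall:
    transcript_id: str
    gene_id: str
    status: PtcStatus
    n_downstream_junctions: int
    max_junction_distance_nt: Optional[int]


def classify_transcript(
    model: TranscriptModel, params: PtcRuleParams = PtcRuleParams()
) -> PtcCall:
    """Classify one transcript by the 50-nt rule.

    Downstream junctions are those lying within the 3'UTR (mRNA coordinate
    >= 3'UTR start). The distance to a junction is
    ``junction_coord - utr_start + 1`` nt of 3'UTR sequence; the test applies
    to the most 3' downstream junction (equivalent to any-junction semantics
    given the OR with the junction-count clause).
    """
    if not model.is_coding:
        return PtcCall(
            transcript_id=model.transcript_id,
            gene_id=model.gene_id,
            status=PtcStatus.UNCLASSIFIABLE,
            n_downstream_junctions=0,
            max_junction_distance_nt=None,
        )
    utr_start = three_prime_utr_start(model)
    downstream = [j for j in mrna_junctions(model) if j >= utr_start]
    max_distance = max(downstream) - utr_start + 1 if downstream else None

    is_plus = len(downstream) >= params.min_downstream_junctions_alt
    if not is_plus and downstream:
        if params.strict_greater:
            is_plus = max_distance > params.min_distance_nt
        else:
            is_plus = max_distance >= params.min_distance_nt
    return PtcCall(
        transcript_id=model.transcript_id,
        gene_id=model.gene_id,
        status=PtcStatus.PTC_PLUS if is_plus else PtcStatus.PTC_MINUS,
        n_downstream_junctions=len(downstream),
        max_junction_distance_nt=max_distance,
    )


def classify_annotation(
    annotation: AnnotationSet, params: PtcRuleParams = PtcRuleParams()
) -> list[PtcCall]:
    return [classify_transcript(t, params) for t in annotation.transcripts()]


@dataclass
class PtcGrouping:
    """Paired PTC+/PTC- analysis groups restricted to expressed transcripts."""

    ptc_plus: set[str]
    ptc_minus: set[str]
    gene_index: dict[str, tuple[set[str], set[str]]] = field(default_factory=dict)

    @property
    def n_genes(self) -> int:
        return len(self.gene_index)


def build_grouping(
    annotation: AnnotationSet,
    calls: Iterable[PtcCall],
    expressed: set[str],
) -> PtcGrouping:
    """Build the PTC+/PTC- grouping from per-transcript calls.

    Both sets are intersected with ``expressed``; PTC- transcripts are kept
    only when their gene has at least one expressed PTC+ isoform (the paired
    within-gene control design).
    """
    calls = list(calls)
    call_ids = {c.transcript_id for c in calls}
    annot_ids = {t.transcript_id for t in annotation.transcripts()}
    missing = annot_ids - call_ids
    if missing:
        raise ValueError(f"calls missing for {len(missing)} transcripts")
    if not expressed:
        warnings.warn("empty expressed set: grouping is empty")

    by_gene: dict[str, tuple[set[str], set[str]]] = {}
    for c in calls:
        if c.transcript_id not in expressed:
            continue
        plus, minus = by_gene.setdefault(c.gene_id, (set(), set()))
        if c.status is PtcStatus.PTC_PLUS:
            plus.add(c.transcript_id)
        elif c.status is PtcStatus.PTC_MINUS:
            minus.add(c.transcript_id)

    gene_index = {g: pm for g, pm in by_gene.items() if pm[0]}
    ptc_plus = set().union(*(pm[0] for pm in gene_index.values())) if gene_index else set()
    ptc_minus = set().union(*(pm[1] for pm in gene_index.values())) if gene_index else set()
    logger.info(
        "PTC grouping: %d PTC+ / %d PTC- transcripts across %d genes",
        len(ptc_plus), len(ptc_minus), len(gene_index),
    )
    return PtcGrouping(ptc_plus=ptc_plus, ptc_minus=ptc_minus, gene_index=gene_index)


def calls_to_frame(calls: Iterable[PtcCall]) -> pd.DataFrame:
    """Tabulate calls for TSV output."""
    return pd.DataFrame(
        [
            {
                "transcript_id": c.transcript_id,
                "gene_id": c.gene_id,
                "status": c.status.value,
                "n_downstream_junctions": c.n_downstream_junctions,
                "max_junction_distance_nt": c.max_junction_distance_nt,
            }
            for c in calls
        ]
    )
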