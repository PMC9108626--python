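"""Expression filtering, a simplified differential-expression model, and the
NMD target-calling rules.

The differential-expression step here is deliberately lightweight: median-of-
ratios size factors, pseudocounted fold changes, and a Wald test with a
method-of-moments negative-binomial dispersion, followed by Benjamini-
Hochberg adjustment. It provides the fold-change/adjusted-p interface the
target-calling rules consume; externally computed tables (e.g. from DESeq2)
can be ingested instead via :func:`read_de_table`.

Target-calling rules implemented:

* NMD+/NMD-: adjusted p < 0.05 and fold change > 1.2 in at least two of three
  knockdown conditions (NMD+); |fold change| < 1.2 in either direction in at
  least two of three (NMD-).
* dependence groups: significant and >= 1.5-fold up (dependent) vs <= 1.2-fold
  change in either direction (independent) in a single contrast.
* per-gene NMD efficiency: the highest fold change of any PTC+ isoform of a
  gene, binned up / no-change / down.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .ptc import PtcGrouping

logger = logging.getLogger(__name__)

__all__ = [
    "CountMatrix",
    "DeTable",
    "NmdCallConfig",
    "DependenceConfig",
    "compute_tpm",
    "filter_expressed",
    "size_factors",
    "simple_de",
    "bh_adjust",
    "call_nmd_targets",
    "call_dependence_groups",
    "select_stringent_set",
    "nmd_efficiency_per_gene",
    "read_count_matrix",
    "read_de_table",
    "write_de_table",
]


@dataclass
class CountMatrix:
    """Counts (rows: transcript/gene ids, columns: samples) with metadata.

    ``conditions`` maps each sample to its experimental condition label;
    ``lengths`` holds per-row effective lengths in nt (required for TPM).
    """

    counts: pd.DataFrame
    conditions: dict[str, str]
    lengths: Optional[pd.Series] = None

    def __post_init__(self) -> None:
        if (self.counts.values < 0).any():
            raise ValueError("counts must be non-negative")
        missing = set(self.counts.columns) - set(self.conditions)
        if missing:
            raise ValueError(f"samples without condition label: {sorted(missing)}")
        if self.lengths is not None:
            self.lengths = self.lengths.reindex(self.counts.index)
            if self.lengths.isna().any() or (self.lengths <= 0).any():
                raise ValueError("lengths must be positive for every row")

    @property
    def ids(self) -> pd.Index:
        return self.counts.index

    def samples_of(self, condition: str) -> list[str]:
        cols = [s for s in self.counts.columns if self.conditions[s] == condition]
        if not cols:
            raise ValueError(f"condition {condition!r} absent from matrix")
        return cols

    @property
    def condition_labels(self) -> list[str]:
        seen: list[str] = []
        for s in self.counts.columns:
            c = self.conditions[s]
            if c not in seen:
                seen.append(c)
        return seen


@dataclass
class DeTable:
    """Per-row fold change and significance for one contrast."""

    table: pd.DataFrame  # columns: log2_fold_change, p_value, adjusted_p
    contrast: tuple[str, str]  # (test, reference)

    REQUIRED = ("log2_fold_change", "p_value", "adjusted_p")

    def __post_init__(self) -> None:
        for col in self.REQUIRED:
            if col not in self.table.columns:
                raise ValueError(f"DeTable missing column {col!r}")

    @property
    def ids(self) -> pd.Index:
        return self.table.index

    def fold_change(self) -> pd.Series:
        """Linear-scale fold change (test / reference)."""
        return np.exp2(self.table["log2_fold_change"])


# ---------------------------------------------------------------------------
# Normalization and filtering
# ---------------------------------------------------------------------------

def compute_tpm(counts: CountMatrix) -> pd.DataFrame:
    """Transcripts-per-million per sample: (c/l) scaled to 1e6 per column."""
    if counts.lengths is None:
        raise ValueError("TPM requires per-row lengths")
    rate = counts.counts.div(counts.lengths, axis=0)
    totals = rate.sum(axis=0)
    zero_cols = totals[totals == 0].index
    if len(zero_cols):
        warnings.warn(f"all-zero columns in TPM computation: {list(zero_cols)}")
        totals = totals.replace(0, np.nan)
    tpm = rate.div(totals, axis=1) * 1e6
    return tpm.fillna(0.0)


def filter_expressed(
    tpm: pd.DataFrame,
    conditions: dict[str, str],
    threshold: float = 1.0,
) -> set[str]:
    """Ids with condition-mean TPM >= threshold in at least one condition.

    Mirrors the expression filter "TPM less than 1 in all experimental
    conditions" applied to condition-averaged TPM.
    """
    groups: dict[str, list[str]] = {}
    for sample in tpm.columns:
        groups.setdefault(conditions[sample], []).append(sample)
    cond_means = pd.DataFrame(
        {cond: tpm[cols].mean(axis=1) for cond, cols in groups.items()}
    )
    keep = (cond_means >= threshold).any(axis=1)
    return set(tpm.index[keep])


def size_factors(counts: pd.DataFrame) -> pd.Series:
    """Median-of-ratios size factors (the standard count-normalization).

    factor_j = median over rows with positive geometric mean of
    counts_ij / geometric_mean_i.
    """
    log_counts = np.log(counts.where(counts > 0))
    log_geomean = log_counts.mean(axis=1, skipna=False)
    usable = log_geomean.notna() & np.isfinite(log_geomean)
    if not usable.any():
        raise ValueError(
            "no row has all-positive counts; add a pseudocount or prefilter"
        )
    ratios = counts.loc[usable].div(np.exp(log_geomean[usable]), axis=0)
    return ratios.median(axis=0).rename("size_factor")


# ---------------------------------------------------------------------------
# Simplified differential expression
# ---------------------------------------------------------------------------

_EPSILON = 0.5  # pseudocount on normalized means; bounds FC for zero rows


def simple_de(
    counts: CountMatrix,
    contrast: tuple[str, str],
) -> DeTable:
    """Fold change + Wald p-value for ``contrast = (test, reference)``.

    Counts are normalized by median-of-ratios size factors;
    log2FC = log2((mean_test + eps) / (mean_ref + eps)) with eps = 0.5.
    The p-value is a two-sided Wald test on the difference of log means with
    a method-of-moments negative-binomial dispersion (pooled within
    conditions); it requires >= 2 replicates per condition, otherwise only
    fold changes are reported.
    """
    test, ref = contrast
    test_cols = counts.samples_of(test)
    ref_cols = counts.samples_of(ref)
    sub = counts.counts[test_cols + ref_cols]
    sf = size_factors(sub)
    norm = sub.div(sf, axis=1)

    mu_t = norm[test_cols].mean(axis=1)
    mu_r = norm[ref_cols].mean(axis=1)
    log2fc = np.log2((mu_t + _EPSILON) / (mu_r + _EPSILON))

    n_t, n_r = len(test_cols), len(ref_cols)
    if min(n_t, n_r) >= 2:
        var_t = norm[test_cols].var(axis=1, ddof=1)
        var_r = norm[ref_cols].var(axis=1, ddof=1)
        # method-of-moments NB dispersion alpha: var = mu + alpha mu^2,
        # pooled across the two conditions; the per-row estimate at small n
        # is very noisy, so it is moderated toward the across-row median
        with np.errstate(divide="ignore", invalid="ignore"):
            alpha_t = (var_t - mu_t) / mu_t**2
            alpha_r = (var_r - mu_r) / mu_r**2
        alpha_row = (
            pd.concat([alpha_t, alpha_r], axis=1).mean(axis=1).clip(lower=0.0)
        ).fillna(0.0)
        alpha = 0.5 * alpha_row + 0.5 * float(alpha_row.median())
        # delta method: Var(log mu_hat) ~ (mu + alpha mu^2) / (n mu^2)
        se2 = (mu_t + alpha * mu_t**2) / (n_t * (mu_t + _EPSILON) ** 2) + (
            mu_r + alpha * mu_r**2
        ) / (n_r * (mu_r + _EPSILON) ** 2)
        z = np.log((mu_t + _EPSILON) / (mu_r + _EPSILON)) / np.sqrt(se2)
        p = pd.Series(
            2.0 * stats.norm.sf(np.abs(z.to_numpy())), index=sub.index
        )
        p[~np.isfinite(z)] = np.nan
        padj = bh_adjust(p)
    else:
        p = pd.Series(np.nan, index=sub.index)
        padj = pd.Series(np.nan, index=sub.index)

    table = pd.DataFrame(
        {"log2_fold_change": log2fc, "p_value": p, "adjusted_p": padj}
    )
    return DeTable(table=table, contrast=contrast)


def bh_adjust(p: Sequence[float] | pd.Series) -> pd.Series:
    """Benjamini-Hochberg step-up adjustment; NaNs propagate and are not
    counted in m."""
    p = pd.Series(p, dtype=float)
    valid = p.dropna()
    if ((valid < 0) | (valid > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    m = len(valid)
    out = pd.Series(np.nan, index=p.index)
    if m == 0:
        return out
    order = np.argsort(valid.to_numpy(), kind="mergesort")
    ranked = valid.to_numpy()[order] * m / (np.arange(m) + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    adj = np.empty(m)
    adj[order] = np.minimum(ranked, 1.0)
    out[valid.index] = adj
    return out


# ---------------------------------------------------------------------------
# Target calling
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class NmdCallConfig:
    """Thresholds of the 2-of-3-knockdowns NMD target rule."""

    fc_threshold: float = 1.2
    alpha: float = 0.05
    min_supporting_conditions: int = 2
    n_conditions: int = 3

    def __post_init__(self) -> None:
        if self.fc_threshold <= 1:
            raise ValueError("fc_threshold must exceed 1")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie in (0, 1)")
        if self.min_supporting_conditions > self.n_conditions:
            raise ValueError("min_supporting_conditions exceeds n_conditions")


def call_nmd_targets(
    tables: Sequence[DeTable], cfg: NmdCallConfig = NmdCallConfig()
) -> tuple[set[str], set[str]]:
    """Call NMD+ / NMD- transcripts from knockdown contrasts.

    NMD+: adjusted p < alpha and fold change > fc_threshold in at least
    ``min_supporting_conditions`` tables. NMD-: |log2FC| < log2(fc_threshold)
    (magnitude only) in at least that many tables. Rows absent from a table
    do not support either rule there. A row qualifying for both is assigned
    NMD+ with a warning.
    """
    if len(tables) < cfg.n_conditions:
        raise ValueError(
            f"need {cfg.n_conditions} condition tables, got {len(tables)}"
        )
    universe = pd.Index(sorted(set().union(*(set(t.ids) for t in tables))))
    up_support = pd.Series(0, index=universe)
    flat_support = pd.Series(0, index=universe)
    log_thr = np.log2(cfg.fc_threshold)
    for t in tables:
        tab = t.table.reindex(universe)
        up = (tab["adjusted_p"] < cfg.alpha) & (
            tab["log2_fold_change"] > log_thr
        )
        flat = tab["log2_fold_change"].abs() < log_thr
        up_support += up.fillna(False).astype(int)
        flat_support += flat.fillna(False).astype(int)

    nmd_plus = set(universe[up_support >= cfg.min_supporting_conditions])
    nmd_minus = set(universe[flat_support >= cfg.min_supporting_conditions])
    both = nmd_plus & nmd_minus
    if both:
        warnings.warn(
            f"{len(both)} rows satisfy both NMD+ and NMD- rules; assigned NMD+"
        )
        nmd_minus -= both
    return nmd_plus, nmd_minus


@dataclass(frozen=True)
class DependenceConfig:
    """Thresholds of the dependent/independent split for one contrast."""

    up_fc: float = 1.5
    neutral_fc: float = 1.2
    alpha: float = 0.05
    require_significance_up: bool = True
    up_inclusive: bool = True  # ">= 1.5-fold" vs "> 1.5-fold"

    def __post_init__(self) -> None:
        if not self.up_fc > self.neutral_fc > 1:
            raise ValueError("require up_fc > neutral_fc > 1")


def call_dependence_groups(
    table: DeTable, cfg: DependenceConfig = DependenceConfig()
) -> tuple[set[str], set[str]]:
    """Split rows into (dependent, independent) for one knockout contrast.

    Dependent: significant (adjusted p < alpha when required) and fold change
    >= up_fc. Independent: |log2FC| <= log2(neutral_fc), magnitude only.
    Rows between the thresholds belong to neither group.
    """
    log_up = np.log2(cfg.up_fc)
    log_neutral = np.log2(cfg.neutral_fc)
    lfc = table.table["log2_fold_change"]
    padj = table.table["adjusted_p"]

    up = lfc >= log_up if cfg.up_inclusive else lfc > log_up
    if cfg.require_significance_up:
        up &= padj < cfg.alpha
    independent = lfc.abs() <= log_neutral
    return set(table.ids[up.fillna(False)]), set(table.ids[independent.fillna(False)])


def select_stringent_set(
    nmd_plus: set[str],
    external_gene_list: set[str],
    gene_of: dict[str, str],
    mean_tpm: Optional[pd.Series] = None,
) -> set[str]:
    """NMD+ transcripts from an externally curated gene list, one per gene.

    When multiple NMD+ isoforms of a listed gene qualify, the one with the
    highest mean TPM is kept (ties broken lexicographically by id).
    """
    if not external_gene_list:
        warnings.warn("empty external gene list: stringent set is empty")
        return set()
    by_gene: dict[str, list[str]] = {}
    for tid in nmd_plus:
        gid = gene_of.get(tid)
        if gid in external_gene_list:
            by_gene.setdefault(gid, []).append(tid)
    chosen: set[str] = set()
    for gid, tids in by_gene.items():
        if mean_tpm is not None:
            tids.sort(key=lambda t: (-float(mean_tpm.get(t, 0.0)), t))
        else:
            tids.sort()
        chosen.add(tids[0])
    return chosen


def nmd_efficiency_per_gene(
    table: DeTable,
    grouping: PtcGrouping,
    up_fc: float = 1.5,
    neutral_fc: float = 1.2,
) -> pd.DataFrame:
    """Per-gene NMD efficiency: max fold change over the gene's PTC+ isoforms.

    Only genes with at least one PTC+ and one PTC- isoform are considered.
    Genes are binned "up" (FC > up_fc), "no_change" (<= neutral_fc-fold change
    in either direction), else "down". Returns a frame indexed by gene_id
    with columns fold_change and bin.
    """
    fc = table.fold_change()
    rows = []
    for gid, (plus, minus) in grouping.gene_index.items():
        if not plus or not minus:
            continue
        fcs = fc.reindex(sorted(plus)).dropna()
        if fcs.empty:
            logger.info("gene %s: no PTC+ fold change in table; omitted", gid)
            continue
        best = float(fcs.max())
        if best > up_fc:
            label = "up"
        elif 1.0 / neutral_fc <= best <= neutral_fc:
            label = "no_change"
        else:
            label = "down"
        rows.append({"gene_id": gid, "fold_change": best, "bin": label})
    return pd.DataFrame(rows).set_index("gene_id") if rows else pd.DataFrame(
        columns=["fold_change", "bin"]
    )


# ---------------------------------------------------------------------------
# TSV I/O
# ---------------------------------------------------------------------------

def read_count_matrix(
    counts_path: str,
    conditions: dict[str, str],
    lengths_path: Optional[str] = None,
) -> CountMatrix:
    """Read a counts TSV (first column: id) and optional lengths TSV."""
    counts = pd.read_csv(counts_path, sep="\t", index_col=0)
    lengths = None
    if lengths_path:
        lengths = pd.read_csv(lengths_path, sep="\t", index_col=0).iloc[:, 0]
    return CountMatrix(counts=counts, conditions=conditions, lengths=lengths)


def read_de_table(path: str, contrast: tuple[str, str] = ("test", "reference")) -> DeTable:
    """Ingest an external differential-expression TSV.

    Expected columns: id (index), log2FC (or log2_fold_change), pvalue, padj.
    """
    df = pd.read_csv(path, sep="\t", index_col=0)
    rename = {
        "log2FC": "log2_fold_change",
        "log2FoldChange": "log2_fold_change",
        "pvalue": "p_value",
        "padj": "adjusted_p",
    }
    df = df.rename(columns=rename)
    return DeTable(table=df[list(DeTable.REQUIRED)], contrast=contrast)


def write_de_table(de: DeTable, path: str) -> None:
    out = de.table.rename(
        columns={
            "log2_fold_change": "log2FC",
            "p_value": "pvalue",
            "adjusted_p": "padj",
        }
    )
    out.to_csv(path, sep="\t", index_label="id")
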