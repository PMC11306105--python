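"""Downstream expression-table rules: TPM, top-k ranking and DE/abundance filters.

These operations curate an already-quantified feature table (gene lengths,
per-sample counts, and externally computed differential-expression statistics
log2 fold change and adjusted p).  Count modelling and shrinkage estimation
are deliberately out of scope — ``log2fc`` and ``padj`` are input columns.

Conventions:

* TPM (transcripts per kilobase million): per sample, rate_g = count_g /
  length_g, TPM_g = 1e6 * rate_g / sum(rates); each sample's TPM column sums
  to 1e6.
* DE filter: keep genes with padj <= 0.05 AND |log2fc| >= 0.585 (inclusive;
  0.585 = log2(1.5)); genes with missing statistics are excluded.
* Abundance floor: keep genes reaching >= 50 mean TPM in at least one sample
  group (e.g. one time point).
* Top-k ranking: restrict to a tagged gene set, rank by mean TPM over the
  named samples, descending, ties broken by gene_id so output is
  deterministic.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import DataError, ParameterError

DEFAULT_PADJ_MAX = 0.05
DEFAULT_ABS_LOG2FC_MIN = 0.585
DEFAULT_MIN_MEAN_TPM = 50.0

__all__ = [
    "FeatureTable",
    "remove_rrna",
    "tpm",
    "top_metabolic_genes",
    "de_filter",
    "abundance_floor",
    "DEFAULT_PADJ_MAX",
    "DEFAULT_ABS_LOG2FC_MIN",
    "DEFAULT_MIN_MEAN_TPM",
]


@dataclass(frozen=True)
class FeatureTable:
    """A per-gene expression table.

    ``df`` holds one row per gene with columns ``gene_id``, ``length`` (bp),
    one count column per sample (named after the sample), and optionally
    ``log2fc``, ``padj``, ``is_rrna`` and boolean gene-set tag columns.
    After :func:`tpm`, per-sample TPM columns ``tpm_<sample>`` are present.
    """

    df: pd.DataFrame
    samples: tuple[str, ...]

    def __post_init__(self) -> None:
        df = self.df
        if "gene_id" not in df.columns or "length" not in df.columns:
            raise DataError("feature table needs gene_id and length columns")
        if df["gene_id"].duplicated().any():
            dup = df.loc[df["gene_id"].duplicated(), "gene_id"].iloc[0]
            raise DataError(f"duplicate gene_id {dup!r}")
        if (df["length"] <= 0).any():
            raise DataError("gene lengths must be positive")
        missing = [s for s in self.samples if s not in df.columns]
        if missing:
            raise DataError(f"count columns missing for samples {missing}")
        for s in self.samples:
            if (df[s] < 0).any():
                raise DataError(f"negative counts in sample {s!r}")
        object.__setattr__(self, "samples", tuple(self.samples))
        object.__setattr__(self, "df", df.reset_index(drop=True))

    def __len__(self) -> int:
        return len(self.df)

    @property
    def has_tpm(self) -> bool:
        return all(f"tpm_{s}" in self.df.columns for s in self.samples)

    def gene_ids(self) -> list[str]:
        return self.df["gene_id"].tolist()


def remove_rrna(table: FeatureTable) -> FeatureTable:
    """Drop genes flagged as rRNA (``is_rrna`` column); samples unchanged.

    rRNA features are removed before any abundance comparison because
    sample-specific rRNA depletion efficiencies would otherwise skew TPM.
    """
    if "is_rrna" not in table.df.columns:
        raise DataError("remove_rrna requires an is_rrna column")
    kept = table.df.loc[~table.df["is_rrna"].astype(bool)].reset_index(drop=True)
    if kept.empty:
        warnings.warn("all genes were flagged rRNA; table is now empty", stacklevel=2)
    return replace(table, df=kept)


def tpm(table: FeatureTable) -> FeatureTable:
    """Add per-sample TPM columns (``tpm_<sample>``), each summing to 1e6."""
    df = table.df.copy()
    lengths = df["length"].to_numpy(float)
    for s in table.samples:
        rates = df[s].to_numpy(float) / lengths
        total = rates.sum()
        if not total > 0:
            raise DataError(f"sample {s!r}: total length-normalized rate is zero")
        df[f"tpm_{s}"] = 1e6 * rates / total
    return replace(table, df=df)


def _mean_tpm(table: FeatureTable, samples: Sequence[str]) -> np.ndarray:
    cols = [f"tpm_{s}" for s in samples]
    missing = [c for c in cols if c not in table.df.columns]
    if missing:
        raise DataError(f"TPM not computed for {missing}; call tpm() first")
    return table.df[cols].to_numpy(float).mean(axis=1)


def top_metabolic_genes(
    table: FeatureTable,
    gene_set: str,
    samples: Sequence[str],
    k: int = 20,
) -> pd.DataFrame:
    """The k most abundant genes of a tagged set, by mean TPM over ``samples``.

    ``gene_set`` names a boolean tag column (e.g. KEGG metabolic membership).
    Returns a DataFrame sorted by descending mean TPM (ties broken by
    gene_id), truncated to ``k`` rows, with a ``mean_tpm`` column appended.
    """
    if gene_set not in table.df.columns:
        raise ParameterError(f"unknown gene set {gene_set!r}")
    if not samples:
        raise ParameterError("samples must be non-empty")
    if k < 1:
        raise ParameterError("k must be >= 1")
    sub = table.df.loc[table.df[gene_set].astype(bool)].copy()
    means = _mean_tpm(replace(table, df=sub), samples)
    sub["mean_tpm"] = means
    sub = sub.sort_values(
        ["mean_tpm", "gene_id"], ascending=[False, True], kind="mergesort"
    )
    return sub.head(k).reset_index(drop=True)


def de_filter(
    table: FeatureTable,
    padj_max: float = DEFAULT_PADJ_MAX,
    abs_log2fc_min: float = DEFAULT_ABS_LOG2FC_MIN,
) -> FeatureTable:
    """Keep genes with padj <= ``padj_max`` and |log2fc| >= ``abs_log2fc_min``.

    Both thresholds are inclusive.  Genes with missing log2fc or padj are
    excluded (they were not tested).
    """
    df = table.df
    if "log2fc" not in df.columns or "padj" not in df.columns:
        raise DataError("de_filter requires log2fc and padj columns")
    keep = (
        df["padj"].notna()
        & df["log2fc"].notna()
        & (df["padj"] <= padj_max)
        & (df["log2fc"].abs() >= abs_log2fc_min)
    )
    return replace(table, df=df.loc[keep].reset_index(drop=True))


def abundance_floor(
    table: FeatureTable,
    sample_groups: Sequence[Sequence[str]],
    min_mean_tpm: float = DEFAULT_MIN_MEAN_TPM,
) -> FeatureTable:
    """Keep genes reaching ``min_mean_tpm`` mean TPM in at least one group.

    ``sample_groups`` partitions (or subsets) the samples, typically one
    group per sampling time point.
    """
    if not sample_groups:
        raise ParameterError("sample_groups must be non-empty")
    for group in sample_groups:
        if not group:
            raise ParameterError("empty sample group")
    keep = np.zeros(len(table), dtype=bool)
    for group in sample_groups:
        keep |= _mean_tpm(table, list(group)) >= min_mean_tpm
    return replace(table, df=table.df.loc[keep].reset_index(drop=True))
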