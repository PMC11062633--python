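"""Differential-expression integration.

Consumes DESeq2-style result tables for the two mutants (*parp-1* and
*pr-set7*), applies the significance rule |log2FC| >= 1 (inclusive) at
FDR < 0.05 (strict), quantifies concordance of the two transcriptomes,
and summarizes how co-enriched genes (PARP-1 AND H4K20me1) respond in
each mutant: differentially expressed in both, only in mutant A, or only
in mutant B, each split into up- and down-regulated.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence, Union

import numpy as np
import pandas as pd
from scipy import stats

from .coenrichment import CoEnrichmentCall
from .errors import CorrelationError, FormatError, InputError

STATUS_UP = "up"
STATUS_DOWN = "down"
STATUS_NS = "ns"

_GENE_ALIASES = ("gene", "gene_id", "id", "name")
_LFC_ALIASES = ("log2FoldChange", "log2fc", "lfc")
_PADJ_ALIASES = ("padj", "qvalue", "fdr", "adj_p")


def _find_column(df: pd.DataFrame, aliases: Sequence[str], what: str) -> str:
    lower = {c.lower(): c for c in df.columns}
    for alias in aliases:
        if alias.lower() in lower:
            return lower[alias.lower()]
    raise FormatError(f"no {what} column found (tried {list(aliases)})")


def load_deg_table(path: Union[str, Path]) -> pd.DataFrame:
    """Read a DE result TSV into a frame with gene, log2fc, padj columns.

    Accepts the usual column spellings (gene/gene_id, log2FoldChange,
    padj); missing adjusted p-values ("NA" or blank) become NaN and are
    classified non-significant later.  Duplicate gene ids are rejected.
    """
    df = pd.read_csv(path, sep="\t")
    gene_col = _find_column(df, _GENE_ALIASES, "gene id")
    lfc_col = _find_column(df, _LFC_ALIASES, "log2 fold change")
    padj_col = _find_column(df, _PADJ_ALIASES, "adjusted p-value")
    out = pd.DataFrame(
        {
            "gene": df[gene_col].astype(str),
            "log2fc": pd.to_numeric(df[lfc_col], errors="raise"),
            "padj": pd.to_numeric(df[padj_col], errors="coerce"),
        }
    )
    if not np.isfinite(out["log2fc"]).all():
        raise FormatError("non-numeric log2 fold change")
    dup = out["gene"][out["gene"].duplicated()]
    if len(dup):
        raise InputError(f"duplicated gene ids: {sorted(set(dup))[:5]}")
    return out


def _canonical(records: pd.DataFrame) -> pd.DataFrame:
    """Rename gene / log2 fold change / padj columns to canonical names."""
    out = records.copy()
    renames = {}
    for canon, aliases in (
        ("gene", _GENE_ALIASES), ("log2fc", _LFC_ALIASES), ("padj", _PADJ_ALIASES)
    ):
        if canon not in out.columns:
            renames[_find_column(out, aliases, canon)] = canon
    return out.rename(columns=renames)


def classify_deg(
    records: pd.DataFrame,
    lfc_threshold: float = 1.0,
    fdr: float = 0.05,
) -> pd.DataFrame:
    """Assign up/down/ns status: |log2FC| >= threshold (inclusive) and
    padj < fdr (strict); missing padj is never significant."""
    if lfc_threshold <= 0 or fdr <= 0:
        raise ValueError("thresholds must be positive")
    out = _canonical(records)
    sig = (out["padj"] < fdr) & out["padj"].notna()
    out["status"] = STATUS_NS
    out.loc[sig & (out["log2fc"] >= lfc_threshold), "status"] = STATUS_UP
    out.loc[sig & (out["log2fc"] <= -lfc_threshold), "status"] = STATUS_DOWN
    return out


def deg_concordance(
    a: pd.DataFrame,
    b: pd.DataFrame,
    gene_universe: str = "union_DE",
) -> tuple[float, pd.DataFrame]:
    """Pearson r of paired log2 fold changes across the two tables.

    ``gene_universe="union_DE"`` (default) keeps genes present in both
    tables and significant in at least one (tables must be classified);
    ``"intersection_all"`` keeps every shared gene.  Returns the
    correlation and the paired table used to compute it.
    """
    merged = a.merge(b, on="gene", suffixes=("_a", "_b"))
    if gene_universe == "union_DE":
        if "status_a" not in merged or "status_b" not in merged:
            raise InputError("union_DE universe needs classified tables")
        merged = merged[
            (merged["status_a"] != STATUS_NS) | (merged["status_b"] != STATUS_NS)
        ]
    elif gene_universe != "intersection_all":
        raise ValueError(f"unknown gene universe {gene_universe!r}")
    if len(merged) < 3:
        raise CorrelationError("fewer than 3 shared genes in the chosen universe")
    x, y = merged["log2fc_a"].to_numpy(), merged["log2fc_b"].to_numpy()
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise CorrelationError("constant fold-change vector")
    r = float(stats.pearsonr(x, y).statistic)
    return r, merged.reset_index(drop=True)


def row_zscore(matrix: pd.DataFrame) -> pd.DataFrame:
    """Row-wise z-scores (population sd); constant rows become zeros."""
    if matrix.empty:
        raise InputError("empty matrix")
    values = matrix.to_numpy(dtype=float)
    mean = values.mean(axis=1, keepdims=True)
    sd = values.std(axis=1, ddof=0, keepdims=True)
    constant = (sd == 0).ravel()
    if constant.any():
        warnings.warn(f"{int(constant.sum())} constant row(s) set to zero", stacklevel=2)
    sd[sd == 0] = 1.0
    z = (values - mean) / sd
    z[constant, :] = 0.0
    return pd.DataFrame(z, index=matrix.index, columns=matrix.columns)


@dataclass
class CoEnrichedDEGSummary:
    """Counts/percentages of co-enriched DEGs by mutant partition.

    Partitions: significant in both mutants, only in A, only in B.  The
    "both" partition reports direction by mutant A's sign, with genes of
    opposite sign counted separately as discordant; ``pct_up`` uses all
    genes of the partition as denominator and ``pct_up_concordant``
    restricts to direction-concordant genes.
    """

    both_n: int
    both_up: int
    both_down: int
    both_discordant: int
    only_a_n: int
    only_a_up: int
    only_a_down: int
    only_b_n: int
    only_b_up: int
    only_b_down: int

    @staticmethod
    def _pct(num: int, den: int) -> float:
        return 100.0 * num / den if den else 0.0

    def to_frame(self) -> pd.DataFrame:
        rows = [
            (
                "both", self.both_n, self.both_up, self.both_down, self.both_discordant,
                self._pct(self.both_up, self.both_n),
                self._pct(self.both_up, self.both_up + self.both_down),
            ),
            (
                "only_a", self.only_a_n, self.only_a_up, self.only_a_down, 0,
                self._pct(self.only_a_up, self.only_a_n),
                self._pct(self.only_a_up, self.only_a_n),
            ),
            (
                "only_b", self.only_b_n, self.only_b_up, self.only_b_down, 0,
                self._pct(self.only_b_up, self.only_b_n),
                self._pct(self.only_b_up, self.only_b_n),
            ),
        ]
        return pd.DataFrame(
            rows,
            columns=["partition", "n", "up", "down", "discordant",
                     "pct_up", "pct_up_concordant"],
        )


def summarize_coenriched_degs(
    calls: Union[Sequence[CoEnrichmentCall], pd.DataFrame],
    a: pd.DataFrame,
    b: pd.DataFrame,
) -> CoEnrichedDEGSummary:
    """Partition co-enriched genes by which mutant they respond in.

    ``calls`` is either a list of :class:`CoEnrichmentCall` or a frame
    with gene_id and co_enriched columns; ``a`` and ``b`` are classified
    DE tables (mutant A drives the direction of the "both" partition).
    """
    if isinstance(calls, pd.DataFrame):
        coe = set(calls.loc[calls["co_enriched"], "gene_id"].astype(str))
    else:
        coe = {c.gene_id for c in calls if c.co_enriched}
    status_a = a.set_index("gene")["status"]
    status_b = b.set_index("gene")["status"]

    both_up = both_down = both_disc = 0
    only_a_up = only_a_down = only_b_up = only_b_down = 0
    for gene in coe:
        sa = status_a.get(gene, STATUS_NS)
        sb = status_b.get(gene, STATUS_NS)
        if sa != STATUS_NS and sb != STATUS_NS:
            if sa != sb:
                both_disc += 1
            elif sa == STATUS_UP:
                both_up += 1
            else:
                both_down += 1
        elif sa != STATUS_NS:
            if sa == STATUS_UP:
                only_a_up += 1
            else:
                only_a_down += 1
        elif sb != STATUS_NS:
            if sb == STATUS_UP:
                only_b_up += 1
            else:
                only_b_down += 1
    return CoEnrichedDEGSummary(
        both_n=both_up + both_down + both_disc,
        both_up=both_up,
        both_down=both_down,
        both_discordant=both_disc,
        only_a_n=only_a_up + only_a_down,
        only_a_up=only_a_up,
        only_a_down=only_a_down,
        only_b_n=only_b_up + only_b_down,
        only_b_up=only_b_up,
        only_b_down=only_b_down,
    )
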