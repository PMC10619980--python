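"""Post-fit differential-expression filtering, set overlap, and qPCR expression.

Operates on gene-level DE result tables (gene_id, log2fc, fdr, per-group
mean CPM). Lowly expressed genes — mean CPM below 5 in *both* groups — are
removed first; significance then requires FDR < 0.05 and |log2FC| > 0.58
(fold change > 1.5), all comparisons strict. Gene sets are compared with
Venn semantics. qPCR relative expression follows the 2^-ΔΔCq method with
Cq values normalized to the arithmetic mean of the housekeeping genes'
Cq (the geometric mean on the linear scale).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd

MIN_MEAN_CPM = 5.0
MAX_FDR = 0.05
MIN_ABS_LOG2FC = 0.58

DE_COLUMNS = ["gene_id", "log2fc", "fdr", "mean_cpm_group1", "mean_cpm_group2"]


def _check_de_table(table: pd.DataFrame, columns=DE_COLUMNS) -> None:
    if missing := set(columns) - set(table.columns):
        raise ValueError(f"DE table missing columns: {sorted(missing)}")
    if table["gene_id"].duplicated().any():
        raise ValueError("gene_ids must be unique")


def cpm_filter(table: pd.DataFrame, min_mean_cpm: float = MIN_MEAN_CPM) -> pd.DataFrame:
    """Drop genes whose mean CPM is below threshold in BOTH groups (strict <).

    A gene well expressed in either group survives. Genes with missing CPM
    cannot be judged; they are retained with a warning.
    """
    _check_de_table(table)
    cpm1, cpm2 = table["mean_cpm_group1"], table["mean_cpm_group2"]
    has_na = cpm1.isna() | cpm2.isna()
    if has_na.any():
        warnings.warn(f"{int(has_na.sum())} gene(s) with missing CPM retained unjudged")
    low_both = (cpm1 < min_mean_cpm) & (cpm2 < min_mean_cpm)
    return table[~low_both.fillna(False)].reset_index(drop=True)


def significance_filter(
    table: pd.DataFrame,
    max_fdr: float = MAX_FDR,
    min_abs_log2fc: float = MIN_ABS_LOG2FC,
) -> tuple[list[str], list[str]]:
    """Significant genes: fdr < max_fdr AND |log2fc| > min_abs_log2fc, both strict.

    Returns (upregulated ids, downregulated ids) split by the sign of
    log2fc; a gene at exactly the fold-change threshold is excluded.
    """
    _check_de_table(table, columns=["gene_id", "log2fc", "fdr"])
    sig = (table["fdr"] < max_fdr) & (table["log2fc"].abs() > min_abs_log2fc)
    up = table.loc[sig & (table["log2fc"] > 0), "gene_id"].tolist()
    down = table.loc[sig & (table["log2fc"] < 0), "gene_id"].tolist()
    return up, down


@dataclass
class GeneSetComparison:
    """Venn-style comparison of named gene sets."""

    set_names: list[str]
    sets: dict[str, set] = field(repr=False)
    intersections: dict[tuple[str, ...], set] = field(repr=False)
    exclusives: dict[str, set] = field(repr=False)

    @property
    def counts(self) -> dict:
        out = {name: len(s) for name, s in self.sets.items()}
        out.update({" & ".join(k): len(v) for k, v in self.intersections.items()})
        out.update({f"{k} only": len(v) for k, v in self.exclusives.items()})
        return out


def set_overlap(sets: dict[str, list | set]) -> GeneSetComparison:
    """Pairwise (and higher-order) intersections and exclusive regions of gene lists."""
    if len(sets) < 2:
        raise ValueError("need at least 2 sets")
    clean = {name: set(s) for name, s in sets.items()}
    names = list(clean)
    inter: dict[tuple[str, ...], set] = {}
    for k in range(2, len(names) + 1):
        for combo in combinations(names, k):
            inter[combo] = set.intersection(*(clean[n] for n in combo))
    exclusives = {
        n: clean[n] - set.union(*(clean[m] for m in names if m != n)) for n in names
    }
    return GeneSetComparison(set_names=names, sets=clean, intersections=inter, exclusives=exclusives)


def qpcr_relative_expression(
    records: pd.DataFrame,
    reference_genes: list[str],
) -> pd.DataFrame:
    """Relative expression by the 2^-ΔΔCq method.

    ``records`` holds one row per (sample, gene) with columns sample,
    condition ('control'/'treatment'), gene, cq. Per sample, ΔCq =
    Cq_target − mean(reference-gene Cq); per target gene, ΔΔCq = mean
    ΔCq(treatment) − mean ΔCq(control). Output columns: gene, ddcq,
    fold_change = 2^-ΔΔCq, log2_fold_change = −ΔΔCq. Samples missing a
    reference gene are excluded with a warning. PCR efficiency is assumed
    to be exactly 2.
    """
    required = {"sample", "condition", "gene", "cq"}
    if missing := required - set(records.columns):
        raise ValueError(f"qPCR records missing columns: {sorted(missing)}")
    if not reference_genes:
        raise ValueError("need at least one reference gene")
    if (records["cq"] <= 0).any():
        raise ValueError("Cq values must be positive")

    ref = records[records["gene"].isin(reference_genes)]
    ref_mean = ref.groupby("sample")["cq"].mean()
    complete = ref.groupby("sample")["gene"].nunique() == len(reference_genes)
    good_samples = set(complete[complete].index)
    dropped = set(records["sample"]) - good_samples
    if dropped:
        warnings.warn(f"samples missing reference gene(s), excluded: {sorted(dropped)}")

    targets = records[
        ~records["gene"].isin(reference_genes) & records["sample"].isin(good_samples)
    ].copy()
    if targets.empty:
        raise ValueError("no target-gene measurements in usable samples")
    targets["dcq"] = targets["cq"] - targets["sample"].map(ref_mean)

    rows = []
    for gene, sub in targets.groupby("gene", sort=False):
        means = sub.groupby("condition")["dcq"].mean()
        if not {"control", "treatment"} <= set(means.index):
            warnings.warn(f"gene {gene} lacks control or treatment samples; skipped")
            continue
        ddcq = float(means["treatment"] - means["control"])
        rows.append(
            {
                "gene": gene,
                "ddcq": ddcq,
                "fold_change": 2.0 ** (-ddcq),
                "log2_fold_change": -ddcq,
            }
        )
    return pd.DataFrame(rows)
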