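"""Multilayer gene screens over rate tables and differential expression.

The screens reproduce the selection logic used to nominate rapidly
evolving candidate genes:

* fold-over-genome-median thresholds on M0 (or maximum per-branch) dN/dS;
* a per-branch screen for distant clades combining an absolute cut with
  per-branch fold-over-median cuts;
* branch-maximum attribution (which species branch carries the highest
  omega, ``>1`` sentinels outranking any numeric value);
* saturation and low-divergence filtering of branch records;
* top-N upregulation ranking and cross-dataset overlap;
* exclusive upregulation within pooled cell-type groups.

Comparison conventions: fold screens use ``>=`` (a gene at exactly
fold x median passes); the absolute branch cut is strict ``>``.  GT1
sentinels (dN/dS > 1) pass any finite omega threshold; LOWDIV records
never pass.  All screens are monotone in their thresholds and invariant
to input row order; ties break lexicographically by gene id.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .ratetable import BranchRateRecord, GenomeRateTable, OmegaCode

logger = logging.getLogger("ovorate")

__all__ = [
    "fold_screen",
    "fold_screen_with_trace",
    "hawaiian_branch_screen",
    "branch_max",
    "saturation_filter",
    "rank_top_upregulated",
    "overlap_screen",
    "exclusive_upregulation",
    "ScreenResult",
    "SaturationResult",
]


class ConfigError(KeyError):
    pass


class UndefinedMaxError(ValueError):
    pass


@dataclass
class ScreenResult:
    """Auditable screen outcome: pass/fail plus an ordered criteria trace
    of (criterion name, value, threshold, passed)."""

    gene_id: str
    passed: bool
    criteria_trace: list[tuple[str, float, float, bool]]

    def reevaluate(self) -> bool:
        return all(p for _, _, _, p in self.criteria_trace)


def _genome_median(table: GenomeRateTable) -> float:
    vals = table.m0[table.m0["code"] == OmegaCode.VALUE.value]["omega"].dropna()
    if vals.empty:
        raise ValueError("no numeric M0 values in table")
    return float(np.median(vals))


def _gene_stat(table: GenomeRateTable, scope: str) -> pd.Series:
    """Per-gene statistic; GT1 anywhere maps to +inf."""
    if scope == "m0":
        m0 = table.m0.set_index("gene_id")
        stat = m0["omega"].copy()
        stat[m0["code"] == OmegaCode.GT1.value] = np.inf
        stat[m0["code"] == OmegaCode.LOWDIV.value] = -np.inf
        return stat
    if scope == "any_branch":
        br = table.branches.copy()
        br["stat"] = br["omega"]
        br.loc[br["code"] == OmegaCode.GT1.value, "stat"] = np.inf
        br.loc[br["code"] == OmegaCode.LOWDIV.value, "stat"] = -np.inf
        return br.groupby("gene_id")["stat"].max()
    raise ValueError(f"unknown scope {scope!r}")


def fold_screen(table: GenomeRateTable, fold: float, scope: str = "m0") -> set[str]:
    """Genes whose statistic is >= fold x genome-wide median M0 omega."""
    return {r.gene_id for r in fold_screen_with_trace(table, fold, scope) if r.passed}


def fold_screen_with_trace(
    table: GenomeRateTable, fold: float, scope: str = "m0"
) -> list[ScreenResult]:
    if fold <= 0:
        raise ValueError("fold must be > 0")
    if table.m0.empty:
        raise ValueError("empty rate table")
    median = _genome_median(table)
    threshold = fold * median
    stat = _gene_stat(table, scope)
    results = []
    for gene in sorted(stat.index):
        value = float(stat[gene])
        ok = bool(value >= threshold) if not np.isnan(value) else False
        results.append(
            ScreenResult(gene, ok, [(f"{scope}_omega_ge_fold_median", value, threshold, ok)])
        )
    n_pass = sum(r.passed for r in results)
    logger.info(
        "fold_screen(scope=%s, fold=%.3g): median=%.4g threshold=%.4g, %d/%d genes pass",
        scope, fold, median, threshold, n_pass, len(results),
    )
    return results


def hawaiian_branch_screen(
    table: GenomeRateTable,
    absolute_cut: float = 0.33,
    fold_cut: float = 1.5,
    per_branch_medians: "dict[str, float] | None" = None,
) -> set[str]:
    """Genes with any branch omega strictly above ``absolute_cut``, or at
    least ``fold_cut`` x that branch's genome-wide median."""
    if per_branch_medians is None:
        raise ConfigError("per_branch_medians is required")
    passed = set()
    for row in table.branches.itertuples():
        code = OmegaCode(row.code)
        if code is OmegaCode.LOWDIV:
            continue
        if row.branch not in per_branch_medians:
            raise ConfigError(f"no genome median supplied for branch {row.branch!r}")
        if code is OmegaCode.GT1:
            passed.add(row.gene_id)
            continue
        w = float(row.omega)
        if w > absolute_cut or w >= fold_cut * per_branch_medians[row.branch]:
            passed.add(row.gene_id)
    logger.info(
        "hawaiian_branch_screen(abs>%.3g, fold>=%.3g): %d genes pass",
        absolute_cut, fold_cut, len(passed),
    )
    return passed


def branch_max(records: "list[BranchRateRecord]") -> set[str]:
    """Branch label(s) with the maximal omega; GT1 outranks any number."""
    gt1 = {r.branch for r in records if r.code is OmegaCode.GT1}
    if gt1:
        return gt1
    values = [(r.branch, r.omega) for r in records if r.code is OmegaCode.VALUE]
    if not values:
        raise UndefinedMaxError("all records are LOWDIV; branch maximum undefined")
    top = max(w for _, w in values)
    return {b for b, w in values if w == top}


@dataclass
class SaturationResult:
    kept: list[BranchRateRecord]
    saturated: list[BranchRateRecord]
    low_divergence: list[BranchRateRecord]


def saturation_filter(
    records: "list[BranchRateRecord]",
    cap: float = 1.5,
    low_div_threshold: float = 0.001,
) -> SaturationResult:
    """Split records into kept / saturated (dN or dS >= cap) / excluded by
    the low-divergence inclusion rule (neither dN nor dS > threshold)."""
    if cap <= 0:
        raise ValueError("cap must be > 0")
    kept, saturated, lowdiv = [], [], []
    for r in records:
        if r.dN >= cap or r.dS >= cap:
            saturated.append(r)
        elif not (r.dN > low_div_threshold or r.dS > low_div_threshold):
            lowdiv.append(r)
        else:
            kept.append(r)
    logger.info(
        "saturation_filter(cap=%.3g): kept=%d saturated=%d low_divergence=%d",
        cap, len(kept), len(saturated), len(lowdiv),
    )
    return SaturationResult(kept, saturated, lowdiv)


def _check_de(de: pd.DataFrame) -> pd.DataFrame:
    required = {"gene_id", "context", "log2_fold_change", "p_value", "direction"}
    missing = required - set(de.columns)
    if missing:
        raise ValueError(f"differential-expression table lacks columns {sorted(missing)}")
    return de


def rank_top_upregulated(
    de: pd.DataFrame, context: str, n: int, p_threshold: float = 0.01
) -> list[str]:
    """Top-n genes by log2 fold change among significant upregulations in
    one context; ties break by gene id."""
    _check_de(de)
    if n < 1:
        raise ValueError("n must be >= 1")
    if context not in set(de["context"]):
        raise KeyError(f"unknown context {context!r}")
    sub = de[
        (de["context"] == context)
        & (de["direction"] == "up")
        & (de["p_value"] < p_threshold)
    ]
    ordered = sub.sort_values(
        ["log2_fold_change", "gene_id"], ascending=[False, True], kind="mergesort"
    )
    return list(ordered["gene_id"].head(n))


def overlap_screen(
    bulk_top: "dict[str, list[str]]",
    singlec_up: pd.DataFrame,
    rates: GenomeRateTable,
    omega_cut: float = 0.20,
    p_threshold: float = 0.05,
) -> set[str]:
    """Genes present in the per-stage bulk top lists AND upregulated in at
    least one single-cell type (P < threshold) AND with M0 omega strictly
    above ``omega_cut``."""
    if omega_cut <= 0:
        raise ValueError("omega_cut must be > 0")
    _check_de(singlec_up)
    bulk = set().union(*bulk_top.values()) if bulk_top else set()
    sc = set(
        singlec_up[
            (singlec_up["direction"] == "up") & (singlec_up["p_value"] < p_threshold)
        ]["gene_id"]
    )
    m0 = rates.m0.set_index("gene_id")
    rapid = set(
        m0[
            (m0["code"] == OmegaCode.GT1.value)
            | ((m0["code"] == OmegaCode.VALUE.value) & (m0["omega"] > omega_cut))
        ].index
    )
    out = bulk & sc & rapid
    logger.info(
        "overlap_screen: bulk=%d singlec=%d rapid=%d -> overlap=%d",
        len(bulk), len(sc), len(rapid), len(out),
    )
    return out


def exclusive_upregulation(
    de: pd.DataFrame,
    pooling: "dict[str, str]",
    p_threshold: float = 0.05,
) -> dict[str, set[str]]:
    """Assign genes to pooled groups when *all* their significant
    upregulation contexts fall within a single group."""
    _check_de(de)
    up = de[(de["direction"] == "up") & (de["p_value"] < p_threshold)]
    unknown = set(up["context"]) - set(pooling)
    if unknown:
        raise ConfigError(f"pooling does not cover cell types {sorted(unknown)}")
    groups: dict[str, set[str]] = {g: set() for g in set(pooling.values())}
    for gene, sub in up.groupby("gene_id"):
        gene_groups = {pooling[c] for c in sub["context"]}
        if len(gene_groups) == 1:
            groups[gene_groups.pop()].add(gene)
    return groups
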