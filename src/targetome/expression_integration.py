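"""Fold-change classification of WT-vs-knockout expression and direct targets.

A gene is "changed" when its fold change between condition means reaches the
threshold (default 1.5, with the boundary counting as changed: "at least
1.5-fold").  A direct target is a gene that is both peak-associated and
changed in the knockout; down-regulated targets are the factor-activated
class and up-regulated targets the factor-repressed class.

Fold changes are computed on linear-scale condition means by default; a
log2-mean alternative is available via ``log_scale_means``.  An optional
two-sample t-test gate (off by default) can additionally require nominal
significance for noisy data sets.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .interval_analytics import GeneAssignment

__all__ = [
    "ExpressionRecord",
    "TargetRecord",
    "compute_fold_changes",
    "define_direct_targets",
    "de_set_overlap",
]


@dataclass(frozen=True)
class ExpressionRecord:
    """Per-gene WT/KO means, fold change and direction of change in the KO."""

    gene_id: str
    wt_mean: float
    ko_mean: float
    fc: float  # max(wt, ko) / min(wt, ko); >= 1 (inf when one mean is zero)
    direction: str  # down | up | unchanged (in the knockout)
    flagged: bool = False  # degenerate input (all-zero in both conditions)


@dataclass(frozen=True)
class TargetRecord:
    """Joint peak/expression evidence for one gene."""

    gene_id: str
    has_peak: bool
    direction: str
    is_direct_target: bool
    cofactor_cobound: bool = False


def compute_fold_changes(
    expr_table: pd.DataFrame,
    threshold: float = 1.5,
    log_scale_means: bool = False,
    ttest_alpha: float | None = None,
) -> list[ExpressionRecord]:
    """Classify each gene as down / up / unchanged in the knockout.

    ``expr_table`` is indexed by gene_id with WT_* and KO_* replicate
    columns (linear scale, non-negative).  Direction is down when
    ``wt_mean / ko_mean >= threshold`` and up when
    ``ko_mean / wt_mean >= threshold`` — a fold change exactly equal to the
    threshold counts as changed.  A zero mean in one condition with a
    nonzero mean in the other is changed with ``fc = inf``; all-zero genes
    are unchanged with ``fc = 1`` and flagged.

    When ``ttest_alpha`` is set, a two-sample Welch t-test on log2 replicate
    values additionally gates the changed call at that alpha.
    """
    if threshold < 1.0:
        raise ValueError("threshold must be >= 1")
    wt_cols = [c for c in expr_table.columns if c.startswith("WT_")]
    ko_cols = [c for c in expr_table.columns if c.startswith("KO_")]
    if not wt_cols or not ko_cols:
        raise ValueError("expression table needs >=1 WT_* and >=1 KO_* column")
    if (expr_table[wt_cols + ko_cols].values < 0).any():
        raise ValueError("expression values must be non-negative")

    if log_scale_means:
        wt_mean = 2.0 ** np.log2(expr_table[wt_cols].clip(lower=1e-12)).mean(axis=1)
        ko_mean = 2.0 ** np.log2(expr_table[ko_cols].clip(lower=1e-12)).mean(axis=1)
    else:
        wt_mean = expr_table[wt_cols].mean(axis=1)
        ko_mean = expr_table[ko_cols].mean(axis=1)

    records: list[ExpressionRecord] = []
    for gene_id, wt, ko in zip(expr_table.index, wt_mean.values, ko_mean.values):
        flagged = False
        if wt == 0.0 and ko == 0.0:
            fc, direction, flagged = 1.0, "unchanged", True
        elif ko == 0.0:
            fc, direction = np.inf, "down"
        elif wt == 0.0:
            fc, direction = np.inf, "up"
        else:
            fc = max(wt, ko) / min(wt, ko)
            if wt / ko >= threshold:
                direction = "down"
            elif ko / wt >= threshold:
                direction = "up"
            else:
                direction = "unchanged"
        if ttest_alpha is not None and direction != "unchanged" and not flagged:
            a = np.log2(np.clip(expr_table.loc[gene_id, wt_cols].values.astype(float), 1e-12, None))
            b = np.log2(np.clip(expr_table.loc[gene_id, ko_cols].values.astype(float), 1e-12, None))
            pval = stats.ttest_ind(a, b, equal_var=False).pvalue
            if not np.isfinite(pval) or pval >= ttest_alpha:
                direction = "unchanged"
        records.append(
            ExpressionRecord(str(gene_id), float(wt), float(ko), float(fc), direction, flagged)
        )
    return records


def define_direct_targets(
    assignments: Sequence[GeneAssignment],
    expression_records: Sequence[ExpressionRecord],
    cobound_gene_ids: set[str] | None = None,
) -> list[TargetRecord]:
    """Join peak assignments with expression calls into target records.

    A direct target is a gene with at least one assigned peak AND a changed
    direction.  Peak-associated genes missing from the expression table are
    treated as unchanged with a warning.  ``cobound_gene_ids`` optionally
    marks genes whose peaks are co-occupied by a second factor.
    """
    by_gene = {r.gene_id: r for r in expression_records}
    peak_genes = {a.gene_id for a in assignments if a.gene_id is not None}
    missing = sorted(peak_genes - set(by_gene))
    if missing:
        warnings.warn(
            f"{len(missing)} peak-associated gene(s) absent from the expression "
            f"table; treated as unchanged: {missing[:5]}{'...' if len(missing) > 5 else ''}"
        )
    cobound = cobound_gene_ids or set()
    records: list[TargetRecord] = []
    for gene_id in sorted(peak_genes | set(by_gene)):
        has_peak = gene_id in peak_genes
        direction = by_gene[gene_id].direction if gene_id in by_gene else "unchanged"
        records.append(
            TargetRecord(
                gene_id=gene_id,
                has_peak=has_peak,
                direction=direction,
                is_direct_target=has_peak and direction != "unchanged",
                cofactor_cobound=gene_id in cobound,
            )
        )
    return records


def de_set_overlap(
    set_a_up: Iterable[str],
    set_a_down: Iterable[str],
    set_b_up: Iterable[str],
    set_b_down: Iterable[str],
) -> dict[str, int]:
    """2x2 overlap counts between two differential-expression gene sets."""
    a_up, a_down = set(set_a_up), set(set_a_down)
    b_up, b_down = set(set_b_up), set(set_b_down)
    return {
        "down_down": len(a_down & b_down),
        "up_up": len(a_up & b_up),
        "down_up": len(a_down & b_up),
        "up_down": len(a_up & b_down),
    }
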