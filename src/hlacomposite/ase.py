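"""Allele-specific expression (ASE) effect sizes from per-cell counts.

Individual cells yield noisy allelic ratios, and cells with few reads
should not bias the sample-level picture. Each cell's observed biallelic
counts are compared to the balanced expectation (total reads split
equally between the two alleles) as a 2x2 odds ratio, which reduces to
the ratio of the two observed counts; the log-odds is weighted by its
inverse variance (the standard 2x2 log-odds variance, continuity-
corrected when a count is zero) and pooled across cells with a
DerSimonian-Laird random-effects model. The between-cell variance tau^2
absorbs genuine cell-to-cell heterogeneity in allelic imbalance.

Two reference-allele conventions are available when pooling a group of
cells: ``"group"`` (default) measures every cell against the allele with
the higher total count in the group, preserving the direction of the
imbalance; ``"cell"`` uses each cell's own dominant allele, yielding a
pure imbalance magnitude (every per-cell log-odds >= 0).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "CellEffect",
    "AseSummary",
    "cell_log_odds",
    "pool_random_effects",
    "summarize_groups",
    "compare_ase_to_truth",
]


@dataclass(frozen=True)
class CellEffect:
    """One cell's ASE effect: natural-log odds and its variance."""

    cell_id: str
    log_odds: float
    variance: float
    reference_allele: int  # 0 or 1: which input allele was the reference


@dataclass(frozen=True)
class AseSummary:
    """Random-effects pooled ASE effect for a set of cells."""

    summary_log_odds: float
    standard_error: float
    tau2: float
    n_cells: int


def cell_log_odds(
    count_allele1: float,
    count_allele2: float,
    *,
    cell_id: str = "",
    continuity: float = 0.5,
    reference: str | int = "dominant",
) -> CellEffect:
    """Log-odds of observed vs expected (balanced) allele counts for one cell.

    With observed counts (a, b) for (reference, other) and total T = a+b,
    the expected table splits T equally (e = T/2 per allele); the odds
    ratio (a*e)/(b*e) reduces to a/b. The variance is the 2x2 log-odds
    variance 1/a + 1/b + 1/e + 1/e. When any table cell is zero the
    continuity increment (default 0.5, Haldane-Anscombe) is added to all
    four cells first.

    ``reference`` is ``"dominant"`` (the higher count; ties pick allele
    1) or an explicit allele index 0/1.
    """
    if count_allele1 < 0 or count_allele2 < 0:
        raise ValueError("allele counts must be nonnegative")
    total = count_allele1 + count_allele2
    if total < 1:
        raise ValueError("cell has no reads; exclude before computing effects")
    if reference == "dominant":
        ref = 0 if count_allele1 >= count_allele2 else 1
    elif reference in (0, 1):
        ref = int(reference)
    else:
        raise ValueError("reference must be 'dominant', 0, or 1")
    a, b = (count_allele1, count_allele2) if ref == 0 else (count_allele2, count_allele1)
    e = total / 2.0
    if min(a, b, e) == 0:
        a, b, e = a + continuity, b + continuity, e + continuity
    log_odds = math.log((a * e) / (b * e))
    variance = 1.0 / a + 1.0 / b + 2.0 / e
    return CellEffect(cell_id=cell_id, log_odds=log_odds, variance=variance,
                      reference_allele=ref)


def pool_random_effects(effects: list[CellEffect]) -> AseSummary:
    """DerSimonian-Laird random-effects pooling of per-cell log-odds.

    Fixed-effect weights w_i = 1/v_i give the heterogeneity statistic
    Q = sum w_i (y_i - y_FE)^2; the method-of-moments between-cell
    variance is tau^2 = max(0, (Q - (n-1)) / (sum w - sum w^2 / sum w)),
    and the summary is the tau^2-adjusted inverse-variance average with
    SE = 1/sqrt(sum 1/(v_i + tau^2)).
    """
    if not effects:
        raise ValueError("cannot pool an empty list of effects")
    y = np.array([e.log_odds for e in effects])
    v = np.array([e.variance for e in effects])
    if np.any(v <= 0):
        raise ValueError("variances must be positive")
    n = len(y)
    if n == 1:
        return AseSummary(float(y[0]), float(math.sqrt(v[0])), 0.0, 1)
    w = 1.0 / v
    y_fe = float((w * y).sum() / w.sum())
    q = float((w * (y - y_fe) ** 2).sum())
    c = float(w.sum() - (w**2).sum() / w.sum())
    tau2 = max(0.0, (q - (n - 1)) / c) if c > 0 else 0.0
    w_star = 1.0 / (v + tau2)
    summary = float((w_star * y).sum() / w_star.sum())
    se = float(1.0 / math.sqrt(w_star.sum()))
    return AseSummary(summary, se, tau2, n)


def summarize_groups(
    cells: pd.DataFrame,
    *,
    group_col: str = "group",
    count_cols: tuple[str, str] = ("count_allele1", "count_allele2"),
    cell_col: str = "cell_id",
    continuity: float = 0.5,
    convention: str = "group",
) -> pd.DataFrame:
    """Pooled ASE summary per cell group (e.g. per annotated cell type).

    Cells with zero total reads are excluded. ``convention="group"``
    references every cell against the allele with the higher total count
    across the group; ``"cell"`` uses each cell's own dominant allele.
    Empty groups (all cells read-free) are skipped.

    Returns a table with one row per group: summary_log_odds, se, tau2,
    n_cells, reference_allele (group convention; -1 under "cell").
    """
    if convention not in ("group", "cell"):
        raise ValueError("convention must be 'group' or 'cell'")
    c1, c2 = count_cols
    rows = []
    for group, sub in cells.groupby(group_col, sort=True):
        sub = sub[(sub[c1] + sub[c2]) >= 1]
        if sub.empty:
            continue
        if convention == "group":
            ref = 0 if sub[c1].sum() >= sub[c2].sum() else 1
            ref_arg: str | int = ref
        else:
            ref, ref_arg = -1, "dominant"
        effects = [
            cell_log_odds(
                row[c1],
                row[c2],
                cell_id=str(row[cell_col]) if cell_col in sub.columns else "",
                continuity=continuity,
                reference=ref_arg,
            )
            for _, row in sub.iterrows()
        ]
        pooled = pool_random_effects(effects)
        rows.append(
            {
                group_col: group,
                "summary_log_odds": pooled.summary_log_odds,
                "se": pooled.standard_error,
                "tau2": pooled.tau2,
                "n_cells": pooled.n_cells,
                "reference_allele": ref,
            }
        )
    return pd.DataFrame(rows)


def compare_ase_to_truth(
    summary_genotyper: "pd.Series | list[float]",
    summary_truth: "pd.Series | list[float]",
) -> float:
    """Squared Pearson correlation between paired pooled log-odds.

    Quantifies how well genotyper-derived ASE summaries track those from
    gold-standard genotypes over the same samples x groups. Requires at
    least 3 pairs.
    """
    x = np.asarray(summary_genotyper, dtype=float)
    y = np.asarray(summary_truth, dtype=float)
    if x.shape != y.shape:
        raise ValueError("paired summaries must have equal length")
    if len(x) < 3:
        raise ValueError("need at least 3 paired summaries for a correlation")
    r = stats.pearsonr(x, y).statistic
    return float(r * r)
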