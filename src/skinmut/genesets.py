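"""Gene-set ANOVA with mutation and arsenic-exposure interaction terms.

The set-level model is Y = mu + T + G + TxG + TxMut + e fit as fixed-effects
OLS: every member gene keeps its own cell means (gene main effect and
gene-specific tissue pattern), the residual variance is pooled across member
genes, and the set-level effect for a tumor subgroup is the unweighted
average over member genes of the gene's subgroup-vs-healthy log2 difference.
The TxMut interaction p is the F test that the set-level effects are equal
across mutation-defined (or mutation x exposure) tumor subgroups.  With large
pooled residual degrees of freedom (sum over genes of per-gene df) this test
can produce extremely small p-values for modest effect differences; that is a
property of the fixed-effects estimator, documented rather than hidden.

The exposure stratification dichotomizes the baseline urinary
arsenic-to-creatinine ratio (UACR, ug As per g creatinine) at 192, with the
boundary value assigned to the low stratum.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import logging

import numpy as np
import pandas as pd

from .expression import (
    ExpressionMatrix,
    GroupDesign,
    HEALTHY,
    fit_subgroup_effects,
    signed_fold_change,
)

logger = logging.getLogger(__name__)

UACR_CUT_DEFAULT = 192.0


@dataclass
class GeneSetCollection:
    """Named gene sets (e.g. KEGG pathways or GO categories)."""

    sets: dict[str, list[str]]
    source: str = "synthetic"

    def __post_init__(self) -> None:
        for name, members in self.sets.items():
            if not members:
                raise ValueError(f"gene set {name!r} is empty")

    def restricted_to(self, genes: Sequence[str]) -> "GeneSetCollection":
        """Intersect every set with the expression gene universe."""
        universe = set(genes)
        out = {}
        for name, members in self.sets.items():
            kept = [g for g in members if g in universe]
            dropped = len(members) - len(kept)
            if dropped:
                logger.info(
                    "gene set %s: dropped %d member(s) absent from matrix",
                    name,
                    dropped,
                )
            if kept:
                out[name] = kept
        return GeneSetCollection(sets=out, source=self.source)


@dataclass
class GeneSetEffect:
    """Set-level fold changes vs healthy with the interaction test."""

    name: str
    fc_by_group: dict[str, float]
    ci_by_group: dict[str, tuple[float, float]]
    log2_by_group: dict[str, float]
    p_interaction: float
    n_genes: int
    df_resid: int


def fit_geneset_model(
    expr: ExpressionMatrix,
    gene_set: Sequence[str],
    groups: Mapping[str, str] | pd.Series,
    *,
    healthy: str = HEALTHY,
    name: str = "",
    alpha: float = 0.05,
) -> GeneSetEffect:
    """Fit the set-level model for one gene set.

    The set effect per subgroup is the mean over member genes of the gene's
    (subgroup mean - healthy mean) on the log2 scale; SE uses the residual
    variance pooled over member genes with sum-over-genes residual df.  A
    single-gene set therefore reproduces the gene-level fit exactly.
    """
    groups = pd.Series(groups)
    members = [g for g in gene_set if g in expr.values.index]
    if not members:
        raise ValueError(f"gene set {name or gene_set!r}: no member genes in matrix")
    if len(members) < len(gene_set):
        logger.info(
            "gene set %s: %d of %d members in matrix",
            name,
            len(members),
            len(gene_set),
        )
    Y = expr.values.loc[members, groups.index].to_numpy(dtype=float)
    design = GroupDesign.from_labels(list(groups), healthy=healthy)
    fit = fit_subgroup_effects(Y, design)
    ci = fit.ci(alpha)
    return GeneSetEffect(
        name=name,
        fc_by_group={
            lev: float(signed_fold_change(fit.d[i]))
            for i, lev in enumerate(fit.levels[1:])
        },
        ci_by_group={
            lev: (
                float(signed_fold_change(ci[i, 0])),
                float(signed_fold_change(ci[i, 1])),
            )
            for i, lev in enumerate(fit.levels[1:])
        },
        log2_by_group={
            lev: float(fit.d[i]) for i, lev in enumerate(fit.levels[1:])
        },
        p_interaction=fit.p_interaction,
        n_genes=len(members),
        df_resid=fit.df_resid,
    )


def stratification_labels(
    samples: Sequence[str],
    mutation_status: Mapping[str, int] | pd.Series,
    uacr: Mapping[str, float] | pd.Series,
    uacr_cut: float = UACR_CUT_DEFAULT,
    *,
    healthy: str = HEALTHY,
) -> pd.Series:
    """Per-sample subgroup labels: healthy reference + mut x exposure cells.

    Samples absent from ``mutation_status`` are the healthy reference.  The
    exposure stratum is low when UACR <= cut (boundary inclusive), else high.
    """
    mutation_status = pd.Series(mutation_status)
    uacr = pd.Series(uacr)
    labels = {}
    for s in samples:
        if s not in mutation_status.index:
            labels[s] = healthy
            continue
        if s not in uacr.index or pd.isna(uacr[s]):
            raise ValueError(f"tumor sample {s} lacks a UACR value")
        stratum = "low" if uacr[s] <= uacr_cut else "high"
        labels[s] = f"mut{int(mutation_status[s])}_{stratum}"
    return pd.Series(labels)


def stratified_geneset_analysis(
    expr: ExpressionMatrix,
    sets: GeneSetCollection,
    mutation_status: Mapping[str, int] | pd.Series,
    uacr: Mapping[str, float] | pd.Series,
    uacr_cut: float = UACR_CUT_DEFAULT,
    *,
    healthy: str = HEALTHY,
    alpha: float = 0.05,
) -> list[GeneSetEffect]:
    """Gene-set ANOVA over the four mutation x exposure tumor subgroups.

    Subgroups are mut0_low, mut0_high, mut1_low, mut1_high against the common
    healthy reference; every subgroup must contain >=2 samples.
    """
    labels = stratification_labels(
        expr.samples, mutation_status, uacr, uacr_cut, healthy=healthy
    )
    expected = {healthy, "mut0_low", "mut0_high", "mut1_low", "mut1_high"}
    counts = labels.value_counts()
    empty = sorted(expected - set(counts.index))
    if empty:
        raise ValueError(f"empty subgroup(s): {empty}")
    restricted = sets.restricted_to(expr.genes)
    return [
        fit_geneset_model(
            expr, members, labels, healthy=healthy, name=name, alpha=alpha
        )
        for name, members in restricted.sets.items()
    ]


def geneset_report(
    effects: Sequence[GeneSetEffect], sort_key: str = "p_interaction"
) -> pd.DataFrame:
    """Tabulate set-level effects, ranked by ``sort_key`` (ties by name)."""
    if not effects:
        raise ValueError("no gene-set effects to report")
    rows = []
    for e in effects:
        row: dict[str, object] = {
            "set": e.name,
            "n_genes": e.n_genes,
            "p_interaction": e.p_interaction,
        }
        for lev, fc in e.fc_by_group.items():
            lo, hi = e.ci_by_group[lev]
            row[f"fc_{lev}"] = fc
            row[f"ci_lo_{lev}"] = lo
            row[f"ci_hi_{lev}"] = hi
        rows.append(row)
    table = pd.DataFrame(rows)
    table = table.sort_values(
        [sort_key, "set"], kind="mergesort", na_position="last"
    ).reset_index(drop=True)
    return table
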