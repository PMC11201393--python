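"""Gene-level differential expression with a tissue x mutation interaction.

Expression values are log2(CPM + offset).  Each gene is fit with a one-way
fixed-effects (pooled-variance) linear model over the group factor
``healthy`` + K tumor subgroups (e.g. tumor without / with a non-synonymous
driver mutation).  The per-subgroup effect is the subgroup mean minus the
healthy mean on the log2 scale; confidence intervals use the Student t
quantile with the pooled residual degrees of freedom and are transformed
endpoint-wise to the signed fold-change scale.  The interaction p-value is
the F test that all tumor-subgroup effects are equal (K-1 numerator df) —
the question "does mutation status change the magnitude of the tumor vs
healthy difference?".  The combined p-value comes from collapsing all tumor
subgroups into one level, which for two groups is exactly the pooled-variance
two-sample t test.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

HEALTHY = "healthy"


@dataclass
class ExpressionMatrix:
    """log2(CPM + offset) values, genes x samples."""

    values: pd.DataFrame
    offset: float = 1.0

    def __post_init__(self) -> None:
        if self.values.index.has_duplicates:
            raise ValueError("duplicate gene ids")
        if self.values.columns.has_duplicates:
            raise ValueError("duplicate sample ids")

    @property
    def genes(self) -> list[str]:
        return list(self.values.index)

    @property
    def samples(self) -> list[str]:
        return list(self.values.columns)


def cpm(counts: pd.DataFrame) -> pd.DataFrame:
    """Counts-per-million normalization (each sample column sums to 1e6)."""
    totals = counts.sum(axis=0)
    zero = totals[totals <= 0]
    if len(zero):
        raise ValueError(f"sample(s) with zero total counts: {list(zero.index)}")
    return counts * (1e6 / totals)


def cpm_log2(counts: pd.DataFrame, offset: float = 1.0) -> ExpressionMatrix:
    """log2(CPM + offset); the default offset of 1 maps zero counts to 0."""
    return ExpressionMatrix(values=np.log2(cpm(counts) + offset), offset=offset)


def signed_fold_change(d):
    """Signed fold change from a log2 difference.

    ``d >= 0 -> 2**d``; ``d < 0 -> -(2**-d)``.  The magnitude is always >= 1
    and the value is 1 exactly when the log2 difference is zero.
    """
    d = np.asarray(d, dtype=float)
    out = np.where(d >= 0, np.exp2(d), -np.exp2(-d))
    return out if out.ndim else float(out)


def signed_fc_to_log2(fc):
    """Inverse of :func:`signed_fold_change`."""
    fc = np.asarray(fc, dtype=float)
    if np.any(np.abs(fc) < 1):
        raise ValueError("signed fold changes have magnitude >= 1")
    out = np.where(fc >= 0, np.log2(fc), -np.log2(-fc))
    return out if out.ndim else float(out)


@dataclass
class GroupDesign:
    """Encoded group factor: healthy reference + ordered tumor subgroups."""

    levels: list[str]  # levels[0] is the healthy reference
    codes: np.ndarray  # per-sample level index
    counts: np.ndarray  # per-level sample counts

    @classmethod
    def from_labels(
        cls, labels: Sequence[str], healthy: str = HEALTHY
    ) -> "GroupDesign":
        uniq = sorted(set(labels))
        if healthy not in uniq:
            raise ValueError(f"reference level {healthy!r} absent from labels")
        levels = [healthy] + [u for u in uniq if u != healthy]
        index = {lev: i for i, lev in enumerate(levels)}
        codes = np.array([index[l] for l in labels])
        counts = np.bincount(codes, minlength=len(levels))
        small = [levels[i] for i in range(len(levels)) if counts[i] < 2]
        if small:
            raise ValueError(f"subgroup(s) with <2 samples: {small}")
        return cls(levels=levels, codes=codes, counts=counts)

    @property
    def n_subgroups(self) -> int:
        return len(self.levels) - 1


@dataclass
class SubgroupFit:
    """Pooled inference for subgroup-vs-healthy log2 effects.

    Produced by :func:`fit_subgroup_effects` for a block of member genes
    (``m = 1`` for a single gene).  ``d`` holds the set-level (gene-averaged)
    log2 effects per tumor subgroup, in the order of ``levels[1:]``.
    """

    levels: list[str]
    d: np.ndarray  # (K,) log2 effects vs healthy
    se: np.ndarray  # (K,)
    df_resid: int
    s2: float  # pooled residual variance
    p_interaction: float  # nan when K < 2 or variance degenerate
    f_interaction: float
    m_genes: int
    gene_means: np.ndarray = field(repr=False, default=None)  # (m, G)

    def ci(self, alpha: float = 0.05) -> np.ndarray:
        """(K, 2) confidence bounds on the log2 scale."""
        t = stats.t.ppf(1 - alpha / 2, self.df_resid)
        return np.column_stack((self.d - t * self.se, self.d + t * self.se))


def _group_means_sse(Y: np.ndarray, design: GroupDesign):
    """Per-gene group means (m, G) and residual SSE (m,) for Y (m, n)."""
    G = len(design.levels)
    sums = np.zeros((Y.shape[0], G))
    for g in range(G):
        sums[:, g] = Y[:, design.codes == g].sum(axis=1)
    means = sums / design.counts
    sse = (Y**2).sum(axis=1) - (means**2 * design.counts).sum(axis=1)
    return means, np.maximum(sse, 0.0)


def fit_subgroup_effects(Y: np.ndarray, design: GroupDesign) -> SubgroupFit:
    """Fixed-effects fit of ``Y`` (m genes x n samples) on the group factor.

    Every gene gets its own cell means (gene and gene-by-group terms are
    saturated); the residual variance is pooled across genes with
    ``m * (n - G)`` degrees of freedom.  The subgroup effect is the unweighted
    mean over genes of (subgroup mean - healthy mean); its variance follows
    from independence of genes given the pooled variance.  The interaction F
    statistic is the Wald test of equal subgroup effects, identical to the
    nested-model comparison for a single gene.
    """
    Y = np.atleast_2d(np.asarray(Y, dtype=float))
    m, n = Y.shape
    G = len(design.levels)
    K = G - 1
    means, sse = _group_means_sse(Y, design)
    df = m * (n - G)
    if df <= 0:
        raise ValueError("no residual degrees of freedom")
    s2 = float(sse.sum() / df)
    diffs = means[:, 1:] - means[:, :1]
    d = diffs.mean(axis=0)
    n0 = design.counts[0]
    nk = design.counts[1:]
    # Cov(d) = (s2/m) * (diag(1/nk) + J/n0): the healthy mean is shared.
    v0 = np.diag(1.0 / nk) + 1.0 / n0
    V = (s2 / m) * v0
    se = np.sqrt(np.diag(V))
    f = np.nan
    p_int = np.nan
    if K >= 2:
        if s2 <= 0:
            warnings.warn(
                "zero residual variance; interaction p undefined", stacklevel=2
            )
        else:
            C = np.diff(np.eye(K), axis=0)  # (K-1, K) successive differences
            cd = C @ d
            stat = cd @ np.linalg.solve(C @ V @ C.T, cd)
            f = float(stat / (K - 1))
            p_int = float(stats.f.sf(f, K - 1, df))
    return SubgroupFit(
        levels=list(design.levels),
        d=d,
        se=se,
        df_resid=df,
        s2=s2,
        p_interaction=p_int,
        f_interaction=f,
        m_genes=m,
        gene_means=means,
    )


@dataclass
class GeneEffect:
    """Per-gene differential-expression result vs healthy skin."""

    gene: str
    fc_by_group: dict[str, float]
    ci_by_group: dict[str, tuple[float, float]]
    fc_combined: float
    ci_combined: tuple[float, float]
    p_combined: float
    p_interaction: float
    fdr: float | None = None


def _combined_design(design: GroupDesign) -> GroupDesign:
    """Collapse all tumor subgroups into a single 'tumor' level."""
    codes = (design.codes > 0).astype(int)
    return GroupDesign(
        levels=[design.levels[0], "tumor"],
        codes=codes,
        counts=np.bincount(codes, minlength=2),
    )


def fit_gene_interaction(
    expr: ExpressionMatrix,
    groups: Mapping[str, str] | pd.Series,
    gene: str,
    *,
    healthy: str = HEALTHY,
    alpha: float = 0.05,
) -> GeneEffect:
    """Fit one gene: subgroup fold changes, CIs, combined and interaction p."""
    groups = pd.Series(groups)
    y = expr.values.loc[gene, groups.index].to_numpy(dtype=float)[None, :]
    design = GroupDesign.from_labels(list(groups), healthy=healthy)
    fit = fit_subgroup_effects(y, design)
    ci = fit.ci(alpha)
    comb_design = _combined_design(design)
    comb = fit_subgroup_effects(y, comb_design)
    if comb.s2 <= 0:
        warnings.warn("zero residual variance; combined p undefined", stacklevel=2)
        p_comb = np.nan
    else:
        tstat = comb.d[0] / comb.se[0]
        p_comb = float(2 * stats.t.sf(abs(tstat), comb.df_resid))
    comb_ci = comb.ci(alpha)[0]
    return GeneEffect(
        gene=gene,
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
        fc_combined=float(signed_fold_change(comb.d[0])),
        ci_combined=(
            float(signed_fold_change(comb_ci[0])),
            float(signed_fold_change(comb_ci[1])),
        ),
        p_combined=p_comb,
        p_interaction=fit.p_interaction,
    )


def fit_all_genes(
    expr: ExpressionMatrix,
    groups: Mapping[str, str] | pd.Series,
    *,
    healthy: str = HEALTHY,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Vectorized per-gene fits over the whole matrix.

    Returns one row per gene with the combined tumor-vs-healthy fold change
    and CI, BH-adjusted q-value of the combined p, per-subgroup fold changes
    and CIs, and the interaction p.
    """
    groups = pd.Series(groups)
    Y = expr.values.loc[:, groups.index].to_numpy(dtype=float)
    design = GroupDesign.from_labels(list(groups), healthy=healthy)
    m, n = Y.shape
    G = len(design.levels)
    K = G - 1
    means, sse = _group_means_sse(Y, design)
    df = n - G
    s2 = sse / df  # per-gene residual variance
    n0 = design.counts[0]
    nk = design.counts[1:]
    diffs = means[:, 1:] - means[:, :1]  # (m, K)
    v0 = np.diag(1.0 / nk) + 1.0 / n0
    tq = stats.t.ppf(1 - alpha / 2, df)
    se = np.sqrt(np.outer(s2, np.diag(v0)))
    # interaction: Wald quadratic form with per-gene s2
    if K >= 2:
        C = np.diff(np.eye(K), axis=0)
        A = C.T @ np.linalg.solve(C @ v0 @ C.T, C)
        quad = np.einsum("mi,ij,mj->m", diffs, A, diffs)
        with np.errstate(divide="ignore", invalid="ignore"):
            fstat = quad / s2 / (K - 1)
        p_int = stats.f.sf(fstat, K - 1, df * np.ones(m))
    else:
        p_int = np.full(m, np.nan)
    # combined two-level model
    cdesign = _combined_design(design)
    cmeans, csse = _group_means_sse(Y, cdesign)
    cdf = n - 2
    cs2 = csse / cdf
    cd = cmeans[:, 1] - cmeans[:, 0]
    cse = np.sqrt(cs2 * (1.0 / cdesign.counts[0] + 1.0 / cdesign.counts[1]))
    with np.errstate(divide="ignore", invalid="ignore"):
        tstat = cd / cse
    p_comb = 2 * stats.t.sf(np.abs(tstat), cdf)
    ctq = stats.t.ppf(1 - alpha / 2, cdf)
    out = pd.DataFrame(index=expr.values.index)
    out.index.name = "gene"
    out["fc_combined"] = signed_fold_change(cd)
    out["ci_lo_combined"] = signed_fold_change(cd - ctq * cse)
    out["ci_hi_combined"] = signed_fold_change(cd + ctq * cse)
    out["p_combined"] = p_comb
    out["fdr"] = bh_fdr(p_comb)
    for i, lev in enumerate(design.levels[1:]):
        out[f"fc_{lev}"] = signed_fold_change(diffs[:, i])
        out[f"ci_lo_{lev}"] = signed_fold_change(diffs[:, i] - tq * se[:, i])
        out[f"ci_hi_{lev}"] = signed_fold_change(diffs[:, i] + tq * se[:, i])
    out["p_interaction"] = p_int
    return out


def bh_fdr(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted q-values (monotone, q >= p)."""
    p = np.asarray(p_values, dtype=float)
    flat = p.ravel()
    mask = ~np.isnan(flat)
    if np.any((flat[mask] < 0) | (flat[mask] > 1)):
        raise ValueError("p-values must be in [0, 1]")
    q = np.full(flat.shape, np.nan)
    if mask.sum():
        q[mask] = multipletests(flat[mask], method="fdr_bh")[1]
    return q.reshape(p.shape)


def select_de_genes(
    effects: pd.DataFrame, fc_min: float = 3.0, fdr_max: float = 0.05
) -> list[str]:
    """Genes with |combined signed FC| >= fc_min and q <= fdr_max (inclusive)."""
    keep = (effects["fc_combined"].abs() >= fc_min) & (
        effects["fdr"] <= fdr_max
    )
    return list(effects.index[keep.fillna(False)])
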