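"""Methylation-expression association: deciles, regression, delta-delta,
overlap partitions, and the relative-expression heatmap matrix.

These are the headline analyses relating a gene's CG methylation (status,
level, or level change under knockdown) to its expression (level, log2
fold-change, or DEG status). Expression enters on a log2 scale with a
pseudo-value so zero-FPKM genes stay finite.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from scipy.cluster.hierarchy import leaves_list, linkage

from .caller import CLASS_DMG, CLASS_SMG, CLASS_UMG, STATUS_METH, STATUS_UNMETH


def _log2_expression(expr: pd.Series) -> pd.Series:
    """log2(FPKM + pseudo), pseudo = half the smallest nonzero value."""
    nz = expr[expr > 0]
    pseudo = 0.5 * float(nz.min()) if len(nz) else 1.0
    return np.log2(expr + pseudo)


def decile_analysis(
    calls: pd.DataFrame, expression: pd.Series, n_bins: int = 10
) -> pd.DataFrame:
    """Mean expression per methylation decile, plus the unmethylated bin.

    Methylated genes are ranked by weighted mCG level (ties broken by gene
    id for stability) and cut into ``n_bins`` near-equal quantile bins,
    bin 1 = least methylated. The UM bin holds unmethylated genes. Per bin:
    gene count, mean log2 expression, and a t-based 95% CI of the mean.
    """
    meth = calls[calls["status"] == STATUS_METH].copy()
    if len(meth) < n_bins:
        raise ValueError(
            f"only {len(meth)} methylated genes; need >= {n_bins} — use fewer bins"
        )
    expr = _log2_expression(expression)
    meth = meth.sort_values(["level", "gene"], kind="stable")
    chunks = np.array_split(np.arange(len(meth)), n_bins)
    rows = []
    unmeth = calls[calls["status"] == STATUS_UNMETH]
    groups = [("UM", expr.reindex(unmeth["gene"]).dropna())]
    for i, idx in enumerate(chunks, start=1):
        groups.append((str(i), expr.reindex(meth["gene"].iloc[idx]).dropna()))
    for label, vals in groups:
        n = len(vals)
        mean = float(vals.mean()) if n else math.nan
        if n >= 2:
            half = stats.t.ppf(0.975, n - 1) * vals.std(ddof=1) / math.sqrt(n)
        else:
            half = math.nan
        rows.append(
            {"bin": label, "n": n, "mean": mean, "ci_low": mean - half, "ci_high": mean + half}
        )
    return pd.DataFrame(rows)


@dataclass
class RegressionResult:
    slope: float
    intercept: float
    p: float
    r_squared: float
    n: int
    m_tests: int
    significant: bool   # Bonferroni: p < 0.05 / m_tests
    degenerate: bool    # zero variance in the methylation predictor


def level_regression(
    calls: pd.DataFrame, fpkm_mean: pd.Series, m_tests: int = 1, alpha: float = 0.05
) -> RegressionResult:
    """OLS of log2 expression on continuous weighted mCG level.

    Uses genes with FPKM > 0 and a defined level. ``m_tests`` is the number
    of regressions in the analysis run; the Bonferroni flag compares the raw
    slope p-value with alpha / m_tests. Zero variance in the predictor
    yields a flagged degenerate result, not an exception.
    """
    df = calls.set_index("gene")[["level"]].join(fpkm_mean.rename("fpkm"), how="inner")
    df = df[(df["fpkm"] > 0) & df["level"].notna()]
    if len(df) < 3:
        raise ValueError("need at least 3 genes with positive expression")
    x = df["level"].to_numpy()
    if np.ptp(x) == 0:
        return RegressionResult(
            slope=math.nan, intercept=math.nan, p=math.nan, r_squared=math.nan,
            n=len(df), m_tests=m_tests, significant=False, degenerate=True,
        )
    y = np.log2(df["fpkm"].to_numpy())
    fit = sm.OLS(y, sm.add_constant(x)).fit()
    p = float(fit.pvalues[1])
    return RegressionResult(
        slope=float(fit.params[1]), intercept=float(fit.params[0]), p=p,
        r_squared=float(fit.rsquared), n=len(df), m_tests=m_tests,
        significant=p < alpha / m_tests, degenerate=False,
    )


@dataclass
class DeltaDelta:
    """Per-gene methylation change vs expression change, with 2-D binning."""

    table: pd.DataFrame      # gene, delta_mcg, log2fc
    grid_counts: np.ndarray  # 2-D histogram over the fixed grid
    x_edges: np.ndarray
    y_edges: np.ndarray
    spearman_rho: float
    spearman_p: float


def delta_delta(
    comparison: pd.DataFrame,
    log2fc: pd.Series,
    retained: pd.Series | None = None,
    x_range: tuple[float, float] = (-1.0, 1.0),
    y_range: tuple[float, float] = (-10.0, 10.0),
    bins: int = 40,
) -> DeltaDelta:
    """Relate per-gene mCG change (condition B - A) to expression log2FC.

    Uses genes with determinate levels in both conditions (and passing the
    expression filter when ``retained`` is given). Counts are accumulated on
    a fixed grid for density plotting; Spearman correlation quantifies any
    monotone relationship.
    """
    df = comparison.set_index("gene")[["delta_level"]].join(
        log2fc.rename("log2fc"), how="inner"
    )
    df = df[df["delta_level"].notna() & df["log2fc"].notna()]
    if retained is not None:
        df = df[retained.reindex(df.index).fillna(False)]
    x = df["delta_level"].to_numpy()
    y = df["log2fc"].to_numpy()
    counts, xe, ye = np.histogram2d(
        x, y, bins=bins, range=[list(x_range), list(y_range)]
    )
    if len(df) >= 3 and np.ptp(x) > 0 and np.ptp(y) > 0:
        rho, p = stats.spearmanr(x, y)
    else:
        rho, p = math.nan, math.nan
    out = df.reset_index().rename(columns={"delta_level": "delta_mcg"})
    return DeltaDelta(
        table=out, grid_counts=counts, x_edges=xe, y_edges=ye,
        spearman_rho=float(rho), spearman_p=float(p),
    )


@dataclass
class OverlapTable:
    """2x2 partition {DMG, SMG+UMG} x {DEG, non-DEG} with row percentages."""

    counts: pd.DataFrame
    row_percent: pd.DataFrame

    @classmethod
    def from_counts(
        cls, dmg_deg: int, dmg_nondeg: int, other_deg: int, other_nondeg: int
    ) -> "OverlapTable":
        counts = pd.DataFrame(
            {"DEG": [dmg_deg, other_deg], "non-DEG": [dmg_nondeg, other_nondeg]},
            index=pd.Index(["DMG", "SMG+UMG"], name="methylation"),
        )
        totals = counts.sum(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            pct = counts.div(totals, axis=0) * 100.0
        return cls(counts=counts, row_percent=pct)


def overlap_analysis(comparison: pd.DataFrame, deg_flags: pd.Series) -> OverlapTable:
    """Cross-tabulate methylation-change class against DEG status.

    Rows: DMG vs SMG+UMG (unclassified genes are excluded — they have no
    determinate methylation contrast). Columns: DEG vs non-DEG; genes
    missing a flag count as non-DEG. Row percentages are NaN for an empty
    row rather than an error.
    """
    cls = comparison.set_index("gene")["class"]
    keep = cls.isin([CLASS_DMG, CLASS_SMG, CLASS_UMG])
    cls = cls[keep]
    flags = deg_flags.reindex(cls.index).fillna(False).astype(bool)
    is_dmg = cls == CLASS_DMG
    return OverlapTable.from_counts(
        dmg_deg=int((is_dmg & flags).sum()),
        dmg_nondeg=int((is_dmg & ~flags).sum()),
        other_deg=int((~is_dmg & flags).sum()),
        other_nondeg=int((~is_dmg & ~flags).sum()),
    )


def relative_expression_heatmap_matrix(
    fpkm: pd.DataFrame, gene_set
) -> tuple[pd.DataFrame, list, list]:
    """Row-standardised (divide-by-row-max) expression with clustered ordering.

    Each selected gene's FPKM row is divided by its own maximum across
    libraries (relative FPKM). All-zero rows are left as zeros and returned
    in the flagged list. Rows are ordered by average-linkage hierarchical
    clustering on Euclidean distance; returns (matrix in leaf order,
    leaf-ordered gene list, flagged all-zero genes).
    """
    genes = [g for g in gene_set if g in fpkm.index]
    if not genes:
        raise ValueError("gene set is empty or disjoint from the matrix")
    mat = fpkm.loc[genes].astype(float).copy()
    maxima = mat.max(axis=1)
    zero_rows = list(mat.index[maxima == 0])
    safe = maxima.where(maxima > 0, 1.0)
    rel = mat.div(safe, axis=0)
    if len(rel) > 2:
        order = leaves_list(linkage(rel.to_numpy(), method="average", metric="euclidean"))
    else:
        order = np.arange(len(rel))
    ordered = rel.iloc[order]
    return ordered, list(ordered.index), zero_rows
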