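"""Expression summaries and TE expression: CPM filtering, FPKM, group-mean
log2 fold-changes, TE locus collapsing, RPKM, and the one-sided rank test.

Differential-expression significance is normally consumed from an external
results table (gene, log2FC, FDR). A clearly-labelled synthetic stand-in
two-group test (:func:`nb_moment_de_test`) is provided for self-contained
pipelines on simulated counts; it is a moment-based approximation, not a
re-implementation of quasi-likelihood DE machinery.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests


def cpm(counts: pd.DataFrame) -> pd.DataFrame:
    """Counts per million per library: count * 1e6 / library total."""
    totals = counts.sum(axis=0)
    if (totals <= 0).any():
        bad = list(totals.index[totals <= 0])
        raise ValueError(f"libraries with zero total counts: {bad}")
    return counts * 1e6 / totals


def cpm_filter(counts: pd.DataFrame, min_cpm: float = 1.0, min_libraries: int = 2) -> pd.Series:
    """Retain genes with CPM >= min_cpm in at least min_libraries libraries."""
    if counts.shape[1] < 2:
        raise ValueError("need at least two libraries")
    return (cpm(counts) >= min_cpm).sum(axis=1) >= min_libraries


@dataclass
class ExpressionSummary:
    """Per-gene FPKM, group means, log2 fold-change and the CPM-filter flag."""

    fpkm: pd.DataFrame          # genes x libraries
    group_means: pd.DataFrame   # genes x groups
    log2fc: pd.Series           # log2(mean_kd / mean_control), pseudo-handled
    retained: pd.Series         # CPM filter verdict
    pseudo: float               # value added to zero group means


def fpkm(
    counts: pd.DataFrame,
    lengths: pd.Series,
    groups: dict[str, str],
    control: str = "control",
    treatment: str = "kd",
) -> ExpressionSummary:
    """FPKM = count * 1e9 / (gene length in bp * library total).

    Group means average FPKM across each group's libraries; log2FC compares
    treatment to control group means, with half the smallest nonzero group
    mean added to zero means so the ratio stays finite.
    """
    lengths = lengths.reindex(counts.index)
    if lengths.isna().any():
        missing = list(counts.index[lengths.isna()])[:5]
        raise ValueError(f"genes without length: {missing} ...")
    if (lengths <= 0).any():
        raise ValueError("gene lengths must be positive")
    totals = counts.sum(axis=0)
    if (totals <= 0).any():
        raise ValueError("libraries with zero total counts")
    fp = counts * 1e9
    fp = fp.div(totals, axis=1).div(lengths, axis=0)
    glabels = pd.Series(groups)
    means = {
        g: fp.loc[:, glabels.index[glabels == g]].mean(axis=1)
        for g in sorted(set(groups.values()))
    }
    gm = pd.DataFrame(means)
    nonzero = gm.to_numpy()[gm.to_numpy() > 0]
    pseudo = 0.5 * float(nonzero.min()) if nonzero.size else 1.0
    mt = gm[treatment].where(gm[treatment] > 0, pseudo)
    mm = gm[control].where(gm[control] > 0, pseudo)
    log2fc = np.log2(mt / mm).rename("log2fc")
    return ExpressionSummary(
        fpkm=fp, group_means=gm, log2fc=log2fc,
        retained=cpm_filter(counts), pseudo=pseudo,
    )


def collapse_te_gff(tes: pd.DataFrame) -> pd.DataFrame:
    """Merge neighbouring (overlapping or bookended) same-family TE records.

    Returns one row per collapsed locus: chrom, start, end, family, length.
    Records of different families never merge, however interleaved.
    """
    loci = []
    for (chrom, fam), sub in tes.groupby(["chrom", "family"], sort=True):
        sub = sub.sort_values("start", kind="stable")
        cur_s = cur_e = None
        for s, e in zip(sub["start"], sub["end"]):
            if cur_s is None:
                cur_s, cur_e = s, e
            elif s <= cur_e:  # overlap or touching
                cur_e = max(cur_e, e)
            else:
                loci.append((chrom, cur_s, cur_e, fam))
                cur_s, cur_e = s, e
        if cur_s is not None:
            loci.append((chrom, cur_s, cur_e, fam))
    out = pd.DataFrame(loci, columns=["chrom", "start", "end", "family"])
    out["length"] = out["end"] - out["start"]
    return out.sort_values(["chrom", "start"], kind="stable").reset_index(drop=True)


def select_top_te(loci: pd.DataFrame, min_len: int = 500, top: int = 10) -> list[str]:
    """The ``top`` most abundant families among loci of length >= min_len.

    Abundance is the number of qualifying collapsed loci; ties break
    alphabetically for determinism.
    """
    big = loci[loci["length"] >= min_len]
    ranked = (
        big.groupby("family").size().rename("n_loci").reset_index()
        .sort_values(["n_loci", "family"], ascending=[False, True], kind="stable")
    )
    return list(ranked["family"].head(top))


def te_rpkm(
    locus_counts: pd.DataFrame, mapped_total: int
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-locus and per-family TE expression for one library.

    ``locus_counts`` needs columns (family, length, count). Per locus:
    RPKM = count * 1e9 / (length * mapped_total) and the length-free
    reads-per-million variant RPM = count * 1e6 / mapped_total. Per family,
    both a pooled RPKM (summed counts over summed length) and the per-locus
    RPKM distribution's mean are reported, so either aggregation convention
    can be used downstream.
    """
    if mapped_total <= 0:
        raise ValueError("mapped_total must be positive")
    out = locus_counts.copy()
    out["rpkm"] = out["count"] * 1e9 / (out["length"] * mapped_total)
    out["rpm"] = out["count"] * 1e6 / mapped_total
    fam = (
        out.groupby("family")
        .agg(count=("count", "sum"), length=("length", "sum"),
             mean_locus_rpkm=("rpkm", "mean"), n_loci=("rpkm", "size"))
        .reset_index()
    )
    fam["pooled_rpkm"] = fam["count"] * 1e9 / (fam["length"] * mapped_total)
    return out, fam


@dataclass
class RankTestResult:
    u: float
    p: float
    n_kd: int
    n_control: int


def te_rank_test(rpkm_kd, rpkm_ctrl) -> RankTestResult:
    """One-sided Mann-Whitney U: alternative = knockdown greater than control.

    A fully tied (zero-spread) input is degenerate: p = 1 with a warning,
    matching the convention that no evidence of elevation exists.
    """
    kd = np.asarray(rpkm_kd, float)
    ct = np.asarray(rpkm_ctrl, float)
    if kd.size == 0 or ct.size == 0:
        raise ValueError("need at least one locus per condition")
    pooled = np.concatenate([kd, ct])
    if np.all(pooled == pooled[0]):
        warnings.warn("all TE expression values tied; rank test degenerate")
        return RankTestResult(u=kd.size * ct.size / 2.0, p=1.0, n_kd=kd.size, n_control=ct.size)
    res = stats.mannwhitneyu(kd, ct, alternative="greater")
    return RankTestResult(u=float(res.statistic), p=float(res.pvalue), n_kd=kd.size, n_control=ct.size)


def load_deg_table(
    path, alpha: float = 0.05, universe: pd.Index | None = None
) -> pd.Series:
    """DEG flags from a differential-expression results table.

    The table must carry ``gene``, ``log2FC`` and ``FDR`` columns (case
    insensitive). A gene is a DEG iff FDR < alpha. When a ``universe`` is
    given, genes absent from the table are flagged non-DEG (and counted in a
    warning) so the flag series covers the whole analysis set.
    """
    df = pd.read_csv(path, sep="\t")
    cols = {c.lower(): c for c in df.columns}
    for want in ("gene", "log2fc", "fdr"):
        if want not in cols:
            raise ValueError(f"DEG table missing required column {want!r}")
    flags = pd.Series(
        (df[cols["fdr"]] < alpha).to_numpy(), index=df[cols["gene"]], name="deg"
    )
    if universe is not None:
        missing = universe.difference(flags.index)
        if len(missing):
            warnings.warn(f"{len(missing)} genes absent from DEG table; flagged non-DEG")
        flags = flags.reindex(universe, fill_value=False)
    return flags


def nb_moment_de_test(
    counts: pd.DataFrame, groups: dict[str, str], alpha: float = 0.05,
    control: str = "control", treatment: str = "kd",
) -> pd.DataFrame:
    """Synthetic stand-in two-group differential-expression test.

    A moment-based negative-binomial Wald test on CPM-normalised group means:
    per gene, the log-ratio of group means is compared to its delta-method
    standard error under NB(mu, phi) with a method-of-moments dispersion
    pooled across genes; BH correction yields the FDR column. This is a
    deliberately simple substitute for the external quasi-likelihood DE
    results the pipeline normally consumes, adequate for calibration checks
    on simulated counts.
    """
    glabels = pd.Series(groups)
    norm = cpm(counts)
    a = norm.loc[:, glabels.index[glabels == control]]
    b = norm.loc[:, glabels.index[glabels == treatment]]
    ma, mb = a.mean(axis=1), b.mean(axis=1)
    # pooled MoM dispersion: Var = mu + phi mu^2 within groups, on CPM scale
    resid = np.concatenate(
        [(a.sub(ma, axis=0)).to_numpy().ravel(), (b.sub(mb, axis=0)).to_numpy().ravel()]
    )
    mus = np.concatenate(
        [np.repeat(ma.to_numpy(), a.shape[1]), np.repeat(mb.to_numpy(), b.shape[1])]
    )
    ok = mus > 0
    phi = max(
        float(np.sum(resid[ok] ** 2 - mus[ok]) / np.sum(mus[ok] ** 2)), 0.0
    )
    eps = 0.5
    va = (1.0 / ma.clip(lower=eps) + phi) / a.shape[1]
    vb = (1.0 / mb.clip(lower=eps) + phi) / b.shape[1]
    z = (np.log(mb.clip(lower=eps)) - np.log(ma.clip(lower=eps))) / np.sqrt(va + vb)
    p = 2.0 * stats.norm.sf(np.abs(z))
    fdr = multipletests(p, method="fdr_bh")[1]
    return pd.DataFrame(
        {
            "gene": counts.index,
            "log2FC": np.log2(mb.clip(lower=eps) / ma.clip(lower=eps)),
            "pvalue": p,
            "FDR": fdr,
            "deg": fdr < alpha,
        }
    ).set_index("gene")
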