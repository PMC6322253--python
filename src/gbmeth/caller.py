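"""Binomial classification of genes as CG-methylated vs unmethylated.

Per gene, methylated and total read counts are pooled over its CG sites and
tested one-sided against a background level p0 estimated from all coding
sequence; Benjamini-Hochberg correction runs across the determinate genes.
A gene is called methylated when q < alpha and its coverage meets the
"at least 20 reads over at least 20 covered CG sites" threshold; genes
failing the threshold are indeterminate. Because the pooled binomial can
leave highly methylated genes unmethylated (false negatives), unmethylated
genes whose level exceeds the lowest methylated gene's level are dropped
from downstream analyses.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .quant import CG_PREFIX, filter_context, weighted_level, _sites_in

STATUS_METH = "methylated"
STATUS_UNMETH = "unmethylated"
STATUS_INDET = "indeterminate"
STATUS_DROPPED = "dropped"


def background_level(
    sites: pd.DataFrame,
    coding: pd.DataFrame,
    floor: float | None = None,
    context: str | None = CG_PREFIX,
) -> float:
    """Background mCG level p0: weighted level over all coding-sequence sites.

    ``floor`` (typically the estimated non-conversion rate) guards against a
    degenerate p0 of exactly 0, under which every methylated read would be
    infinitely surprising.
    """
    if coding is None or len(coding) == 0:
        raise ValueError("coding annotation is empty")
    s = filter_context(sites, context)
    s = s[_sites_in(s.reset_index(drop=True), coding)]
    if int(s["n"].sum()) == 0:
        raise ValueError("zero read coverage over coding regions")
    p0 = weighted_level(s)
    if floor is not None:
        p0 = max(p0, floor)
    return p0


def aggregate_gene_counts(
    sites: pd.DataFrame, genes: pd.DataFrame, context: str | None = CG_PREFIX
) -> pd.DataFrame:
    """Pool mc/n and count covered CG sites per gene interval.

    Sites inside overlapping genes contribute to every gene containing them.
    """
    s = filter_context(sites, context)
    out = []
    for chrom, g in genes.groupby("chrom"):
        sub = s[s["chrom"] == chrom].sort_values("pos")
        pos0 = sub["pos"].to_numpy() - 1
        cmc = np.concatenate([[0], np.cumsum(sub["mc"].to_numpy())])
        cn = np.concatenate([[0], np.cumsum(sub["n"].to_numpy())])
        ccov = np.concatenate([[0], np.cumsum((sub["n"].to_numpy() > 0).astype(int))])
        lo = np.searchsorted(pos0, g["start"].to_numpy(), side="left")
        hi = np.searchsorted(pos0, g["end"].to_numpy(), side="left")
        out.append(
            pd.DataFrame(
                {
                    "gene": g["name"].to_numpy(),
                    "mc": cmc[hi] - cmc[lo],
                    "n": cn[hi] - cn[lo],
                    "sites": ccov[hi] - ccov[lo],
                }
            )
        )
    agg = (
        pd.concat(out, ignore_index=True)
        if out
        else pd.DataFrame(columns=["gene", "mc", "n", "sites"])
    )
    missing = genes.loc[~genes["name"].isin(agg["gene"]), "name"]
    if len(missing):
        agg = pd.concat(
            [agg, pd.DataFrame({"gene": missing, "mc": 0, "n": 0, "sites": 0})],
            ignore_index=True,
        )
    return agg.set_index("gene").loc[genes["name"]].reset_index()


def classify_genes(
    sites: pd.DataFrame,
    genes: pd.DataFrame,
    p0: float,
    min_reads: int = 20,
    min_sites: int = 20,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """One-sided binomial test of each gene's pooled counts against p0.

    p = P[Binomial(n, p0) >= mc]; BH correction is applied over determinate
    genes only (those meeting both coverage thresholds). Genes with too few
    reads or covered sites are ``indeterminate``, never an exception.
    """
    if not (0.0 < p0 < 1.0):
        raise ValueError(f"p0={p0} must lie strictly inside (0, 1)")
    agg = aggregate_gene_counts(sites, genes)
    mc = agg["mc"].to_numpy()
    n = agg["n"].to_numpy()
    with np.errstate(divide="ignore", invalid="ignore"):
        level = np.where(n > 0, mc / np.maximum(n, 1), np.nan)
    p = stats.binom.sf(mc - 1, n, p0)  # upper tail including mc
    determinate = (n >= min_reads) & (agg["sites"].to_numpy() >= min_sites)
    q = np.full(len(agg), np.nan)
    if determinate.any():
        q[determinate] = multipletests(p[determinate], method="fdr_bh")[1]
    status = np.full(len(agg), STATUS_INDET, dtype=object)
    status[determinate] = np.where(
        q[determinate] < alpha, STATUS_METH, STATUS_UNMETH
    )
    calls = agg.copy()
    calls["level"] = level
    calls["p"] = p
    calls["q"] = q
    calls["status"] = status
    return calls


def drop_false_negatives(calls: pd.DataFrame) -> pd.DataFrame:
    """Drop unmethylated genes whose level exceeds the lowest methylated gene.

    No-op when no gene is methylated. Methylated statuses never change.
    """
    meth = calls[calls["status"] == STATUS_METH]
    if meth.empty:
        return calls.copy()
    t = float(meth["level"].min())
    out = calls.copy()
    to_drop = (out["status"] == STATUS_UNMETH) & (out["level"] > t)
    out.loc[to_drop, "status"] = STATUS_DROPPED
    return out


CLASS_DMG = "DMG"
CLASS_SMG = "SMG"
CLASS_UMG = "UMG"
CLASS_UNCLASSIFIED = "unclassified"


def compare_status(
    calls_a: pd.DataFrame, calls_b: pd.DataFrame
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Cross-condition methylation-status comparison and DMG/SMG/UMG partition.

    DMG: statuses differ and both are determinate (methylated/unmethylated).
    SMG: methylated in both. UMG: unmethylated in both. Everything else —
    indeterminate, dropped, or present in only one call set — is
    unclassified. Also reports the per-gene level change (condition B minus
    condition A).
    """
    a = calls_a.set_index("gene")[["status", "level"]].rename(
        columns={"status": "status_a", "level": "level_a"}
    )
    b = calls_b.set_index("gene")[["status", "level"]].rename(
        columns={"status": "status_b", "level": "level_b"}
    )
    m = a.join(b, how="outer")
    sa, sb = m["status_a"], m["status_b"]
    determinate = sa.isin([STATUS_METH, STATUS_UNMETH]) & sb.isin(
        [STATUS_METH, STATUS_UNMETH]
    )
    cls = np.full(len(m), CLASS_UNCLASSIFIED, dtype=object)
    cls[(determinate & (sa != sb)).to_numpy()] = CLASS_DMG
    cls[(determinate & (sa == STATUS_METH) & (sb == STATUS_METH)).to_numpy()] = CLASS_SMG
    cls[
        (determinate & (sa == STATUS_UNMETH) & (sb == STATUS_UNMETH)).to_numpy()
    ] = CLASS_UMG
    m = m.reset_index()
    m["class"] = cls
    m["delta_level"] = m["level_b"] - m["level_a"]
    counts = m["class"].value_counts().to_dict()
    for k in (CLASS_DMG, CLASS_SMG, CLASS_UMG, CLASS_UNCLASSIFIED):
        counts.setdefault(k, 0)
    return m, counts
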