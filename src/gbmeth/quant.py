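"""Weighted methylation levels, spike-in non-conversion, dyad symmetry,
and genomic-compartment summaries from allc-style count tables.

The weighted level of a site set is the Schultz-style metric: the sum of
methylated read counts divided by the sum of total read counts. A region
with zero total reads has an *undefined* level, represented as NaN and kept
distinct from a genuine 0.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .io import merge_intervals

CG_PREFIX = "CG"


def filter_context(sites: pd.DataFrame, context: str | None = CG_PREFIX) -> pd.DataFrame:
    """Subset an allc frame to contexts starting with ``context`` (None = all)."""
    if context is None:
        return sites
    return sites[sites["context"].str.startswith(context)]


def weighted_level(sites: pd.DataFrame, context: str | None = None) -> float:
    """Sum(mc) / Sum(n) over the (optionally context-filtered) sites.

    Returns NaN — undefined, not zero — when no reads cover the set.
    """
    s = filter_context(sites, context)
    total = int(s["n"].sum())
    if total == 0:
        return math.nan
    return float(s["mc"].sum()) / total


@dataclass
class NonconversionEstimate:
    rate: float
    ci_low: float
    ci_high: float
    mc_reads: int
    total_reads: int


def estimate_nonconversion(
    sites: pd.DataFrame, spikein_chrom: str, confidence: float = 0.95
) -> NonconversionEstimate:
    """Bisulfite non-conversion rate from the unmethylated spike-in contig.

    The rate is the weighted level over all spike-in sites; the interval is
    an exact (Clopper-Pearson) binomial CI on the pooled read counts.
    """
    s = sites[sites["chrom"] == spikein_chrom]
    if s.empty:
        raise ValueError(f"no sites on spike-in contig {spikein_chrom!r}")
    mc, n = int(s["mc"].sum()), int(s["n"].sum())
    if n == 0:
        raise ValueError(f"spike-in contig {spikein_chrom!r} has zero coverage")
    ci = stats.binomtest(mc, n).proportion_ci(confidence_level=confidence, method="exact")
    return NonconversionEstimate(
        rate=mc / n, ci_low=ci.low, ci_high=ci.high, mc_reads=mc, total_reads=n
    )


def pair_dyads(sites: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Pair plus-strand CG sites at pos p with minus-strand partners at p+1.

    Returns ``(dyads, orphans)``: dyads carry both strands' counts keyed by
    the plus-strand C position; orphans are CG sites without a covered
    partner record (kept for pooled levels, excluded from symmetry).
    """
    cg = filter_context(sites, CG_PREFIX)
    plus = cg[cg["strand"] == "+"][["chrom", "pos", "mc", "n"]]
    minus = cg[cg["strand"] == "-"][["chrom", "pos", "mc", "n"]].copy()
    minus["pos"] = minus["pos"] - 1  # key by the plus-strand C of the dyad
    merged = plus.merge(
        minus, on=["chrom", "pos"], how="outer", suffixes=("_plus", "_minus"),
        indicator=True,
    )
    both = merged["_merge"] == "both"
    dyads = merged[both].drop(columns="_merge").reset_index(drop=True)
    dyads = dyads.astype(
        {"mc_plus": int, "n_plus": int, "mc_minus": int, "n_minus": int}
    )
    orphans = merged[~both].drop(columns="_merge").reset_index(drop=True)
    return dyads, orphans


@dataclass
class DyadSymmetry:
    """Per-strand level pairs at covered dyads plus their concordance."""

    levels_plus: np.ndarray
    levels_minus: np.ndarray
    correlation: float          # Pearson r across dyads; NaN when undefined
    n_dyads: int
    site_level_hist: np.ndarray  # per-site (both strands) level histogram
    dyad_level_hist: np.ndarray  # per-dyad pooled-level histogram
    bin_edges: np.ndarray


def dyad_symmetry_summary(
    dyads: pd.DataFrame, min_cov: int = 3, bins: int = 20
) -> DyadSymmetry:
    """Strand-resolved methylation concordance at CpG dyads.

    Only dyads with at least ``min_cov`` reads on each strand qualify.
    Pearson correlation is NaN (flagged, not an error) with fewer than two
    qualifying dyads or zero variance on either strand. Histograms of both
    per-site and per-dyad levels are produced for density plotting.
    """
    q = dyads[(dyads["n_plus"] >= min_cov) & (dyads["n_minus"] >= min_cov)]
    lp = (q["mc_plus"] / q["n_plus"]).to_numpy(float)
    lm = (q["mc_minus"] / q["n_minus"]).to_numpy(float)
    if len(q) < 2 or lp.std() == 0 or lm.std() == 0:
        r = math.nan
    else:
        r = float(stats.pearsonr(lp, lm).statistic)
    edges = np.linspace(0.0, 1.0, bins + 1)
    site_hist = np.histogram(np.concatenate([lp, lm]), bins=edges)[0]
    pooled = (
        (q["mc_plus"] + q["mc_minus"]) / (q["n_plus"] + q["n_minus"])
    ).to_numpy(float)
    dyad_hist = np.histogram(pooled, bins=edges)[0]
    return DyadSymmetry(
        levels_plus=lp, levels_minus=lm, correlation=r, n_dyads=len(q),
        site_level_hist=site_hist, dyad_level_hist=dyad_hist, bin_edges=edges,
    )


def _sites_in(sites: pd.DataFrame, annot: pd.DataFrame) -> np.ndarray:
    """Boolean mask: site cytosine position falls inside any annot interval."""
    mask = np.zeros(len(sites), dtype=bool)
    if annot is None or len(annot) == 0:
        return mask
    pos0_all = sites["pos"].to_numpy() - 1
    for chrom, sub in annot.groupby("chrom"):
        sel = (sites["chrom"] == chrom).to_numpy()
        if not sel.any():
            continue
        s, e = merge_intervals(sub["start"].to_numpy(), sub["end"].to_numpy())
        pos0 = pos0_all[sel]
        idx = np.searchsorted(s, pos0, side="right") - 1
        ok = (idx >= 0) & (pos0 < e[np.clip(idx, 0, None)])
        mask[sel] = ok
    return mask


def _check_contigs(annot: pd.DataFrame | None, known: set[str], label: str) -> None:
    if annot is None or len(annot) == 0:
        return
    unknown = sorted(set(annot["chrom"]) - known)
    if unknown:
        raise ValueError(f"{label} annotation names unknown contigs: {unknown}")


def compartment_levels(
    sites: pd.DataFrame,
    genes: pd.DataFrame | None = None,
    tes: pd.DataFrame | None = None,
    exons: pd.DataFrame | None = None,
    context: str | None = CG_PREFIX,
) -> pd.DataFrame:
    """Weighted level per genomic compartment {genic, te, intergenic, genome_wide}.

    Each site belongs to exactly one compartment with precedence
    gene > TE > intergenic, so read counts are conserved: the three
    compartments sum to the genome-wide totals. An ``exonic`` overlay row is
    added when an exon annotation is supplied (it is a subset of genic and
    excluded from the conservation identity). Annotations naming contigs
    absent from the site table raise with the offending names.
    """
    s = filter_context(sites, context).reset_index(drop=True)
    known = set(s["chrom"].unique()) | ({} if sites.empty else set(sites["chrom"]))
    _check_contigs(genes, known, "gene")
    _check_contigs(tes, known, "TE")
    _check_contigs(exons, known, "exon")
    in_gene = _sites_in(s, genes)
    in_te = _sites_in(s, tes) & ~in_gene
    inter = ~in_gene & ~in_te
    rows = []
    for name, mask in (
        ("genic", in_gene), ("te", in_te), ("intergenic", inter),
        ("genome_wide", np.ones(len(s), bool)),
    ):
        sub = s[mask]
        rows.append(
            {
                "compartment": name,
                "mc": int(sub["mc"].sum()),
                "n": int(sub["n"].sum()),
                "level": weighted_level(sub),
                "covered_sites": int((sub["n"] > 0).sum()),
            }
        )
    if exons is not None and len(exons):
        sub = s[_sites_in(s, exons)]
        rows.append(
            {
                "compartment": "exonic",
                "mc": int(sub["mc"].sum()),
                "n": int(sub["n"].sum()),
                "level": weighted_level(sub),
                "covered_sites": int((sub["n"] > 0).sum()),
            }
        )
    return pd.DataFrame(rows).set_index("compartment")
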