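"""Strand-aware proportional-window methylation profiles (metaplots).

Each feature body (start to stop codon for genes, the full interval for TEs)
is divided into k proportional windows and each fixed-length flank into k
equal windows; window levels are pooled (read-weighted) across features, so
the profile obeys the same weighted-methylation convention as every other
summary. Window 1 is always the biologically upstream end: minus-strand
features are reversed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .quant import CG_PREFIX, filter_context


def _split_widths(length: int, k: int) -> np.ndarray:
    """k near-equal widths summing to length; remainder goes to the first
    ``length % k`` windows (in feature 5'->3' orientation)."""
    base, rem = divmod(length, k)
    return np.array([base + 1] * rem + [base] * (k - rem))


def proportional_windows(
    start: int,
    end: int,
    strand: str,
    k: int = 20,
    flank: int = 1000,
    contig_len: int | None = None,
) -> pd.DataFrame:
    """3k half-open genomic sub-intervals for one feature.

    Rows are ordered by global window index 0..3k-1: upstream flank
    (k windows), body (k), downstream flank (k), all in the feature's
    5'->3' orientation. Windows running past a contig end are truncated
    (possibly to empty). Features shorter than k bp cannot be windowed and
    raise ValueError (callers skip and count them).
    """
    length = end - start
    if length < k:
        raise ValueError(f"feature length {length} < k={k}")
    segs = []
    body_w = _split_widths(length, k)
    flank_w = _split_widths(flank, k)
    if strand == "-":
        # 5'->3' runs right-to-left: upstream flank sits after `end`.
        up = _lay_windows(end, end + flank, flank_w, right_to_left=True)
        body = _lay_windows(start, end, body_w, right_to_left=True)
        down = _lay_windows(start - flank, start, flank_w, right_to_left=True)
    else:
        up = _lay_windows(start - flank, start, flank_w, right_to_left=False)
        body = _lay_windows(start, end, body_w, right_to_left=False)
        down = _lay_windows(end, end + flank, flank_w, right_to_left=False)
    for seg_name, wins in (("upstream", up), ("body", body), ("downstream", down)):
        for s, e in wins:
            s = max(s, 0)
            e = max(e, 0)
            if contig_len is not None:
                s, e = min(s, contig_len), min(e, contig_len)
            segs.append({"segment": seg_name, "start": s, "end": max(s, e)})
    out = pd.DataFrame(segs)
    out.index.name = "window"
    return out


def _lay_windows(lo, hi, widths, right_to_left):
    """Tile [lo, hi) with the given 5'->3' widths."""
    bounds = []
    if right_to_left:
        cur = hi
        for w in widths:
            bounds.append((cur - w, cur))
            cur -= w
    else:
        cur = lo
        for w in widths:
            bounds.append((cur, cur + w))
            cur += w
    return bounds


@dataclass
class MetaProfile:
    """Pooled windowed methylation profile across a feature set."""

    table: pd.DataFrame  # window, segment, mc, n, level
    n_features: int
    n_skipped: int  # features shorter than k bp
    k: int
    flank: int


def profile(
    sites: pd.DataFrame,
    features: pd.DataFrame,
    k: int = 20,
    flank: int = 1000,
    contig_lengths: dict[str, int] | None = None,
    context: str | None = CG_PREFIX,
    weighted: bool = True,
) -> MetaProfile:
    """Metaplot over features: per-window pooled weighted level.

    ``weighted=True`` (default) pools reads across features per window
    (Sum mc / Sum n); ``weighted=False`` instead averages each feature's own
    window level, ignoring uncovered windows.
    """
    s = filter_context(sites, context)
    by_chrom = {}
    for chrom, sub in s.groupby("chrom"):
        sub = sub.sort_values("pos")
        by_chrom[chrom] = (
            sub["pos"].to_numpy() - 1,
            np.concatenate([[0], np.cumsum(sub["mc"].to_numpy())]),
            np.concatenate([[0], np.cumsum(sub["n"].to_numpy())]),
        )
    nwin = 3 * k
    mc_tot = np.zeros(nwin)
    n_tot = np.zeros(nwin)
    lvl_sum = np.zeros(nwin)
    lvl_cnt = np.zeros(nwin)
    n_used = n_skipped = 0
    for _, f in features.iterrows():
        try:
            wins = proportional_windows(
                int(f["start"]), int(f["end"]), f["strand"], k=k, flank=flank,
                contig_len=(contig_lengths or {}).get(f["chrom"]),
            )
        except ValueError:
            n_skipped += 1
            continue
        n_used += 1
        if f["chrom"] not in by_chrom:
            continue
        pos0, cmc, cn = by_chrom[f["chrom"]]
        lo = np.searchsorted(pos0, wins["start"].to_numpy(), side="left")
        hi = np.searchsorted(pos0, wins["end"].to_numpy(), side="left")
        w_mc = cmc[hi] - cmc[lo]
        w_n = cn[hi] - cn[lo]
        mc_tot += w_mc
        n_tot += w_n
        cov = w_n > 0
        lvl_sum[cov] += w_mc[cov] / w_n[cov]
        lvl_cnt[cov] += 1
    with np.errstate(divide="ignore", invalid="ignore"):
        if weighted:
            level = np.where(n_tot > 0, mc_tot / np.maximum(n_tot, 1), np.nan)
        else:
            level = np.where(lvl_cnt > 0, lvl_sum / np.maximum(lvl_cnt, 1), np.nan)
    seg = ["upstream"] * k + ["body"] * k + ["downstream"] * k
    table = pd.DataFrame(
        {
            "window": np.arange(nwin),
            "segment": seg,
            "mc": mc_tot.astype(int),
            "n": n_tot.astype(int),
            "level": level,
        }
    )
    return MetaProfile(table=table, n_features=n_used, n_skipped=n_skipped, k=k, flank=flank)
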