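"""Independent brute-force oracles the tests check the implementation against.

Everything here is deliberately naive — exact rational arithmetic,
quadratic scans, explicit enumeration — and shares no code with the package.
"""

from __future__ import annotations

import itertools
from fractions import Fraction

import numpy as np


def exact_binomial_upper_tail(mc: int, n: int, p0: Fraction) -> Fraction:
    """P[Bin(n, p0) >= mc] by exact rational summation."""
    p0 = Fraction(p0)
    q0 = 1 - p0
    total = Fraction(0)
    # C(n, k) built incrementally to keep it exact and O(n)
    comb = 1
    for k in range(0, n + 1):
        if k >= mc:
            total += comb * p0**k * q0 ** (n - k)
        comb = comb * (n - k) // (k + 1)
    return total


def bh_adjust(pvals):
    """Benjamini-Hochberg adjusted p-values, straight from the definition."""
    p = np.asarray(pvals, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    adj = np.empty(m)
    running_min = 1.0
    for rank_from_top in range(m - 1, -1, -1):
        i = order[rank_from_top]
        val = p[i] * m / (rank_from_top + 1)
        running_min = min(running_min, val)
        adj[i] = min(running_min, 1.0)
    return adj


def cpm_retained(counts: np.ndarray, min_cpm=1.0, min_libraries=2):
    """CPM filter by explicit double loop over genes and libraries."""
    totals = counts.sum(axis=0)
    keep = []
    for g in range(counts.shape[0]):
        hits = 0
        for j in range(counts.shape[1]):
            if counts[g, j] * 1e6 / totals[j] >= min_cpm:
                hits += 1
        keep.append(hits >= min_libraries)
    return np.array(keep)


def merge_family_intervals(records):
    """Per-(chrom, family) interval union via a boolean sweep over positions.

    records: iterable of (chrom, start, end, family). Returns a sorted set of
    (chrom, start, end, family) merged loci (bookended intervals merge).
    """
    out = set()
    by_key = {}
    for chrom, s, e, fam in records:
        by_key.setdefault((chrom, fam), []).append((s, e))
    for (chrom, fam), ivals in by_key.items():
        lo = min(s for s, _ in ivals)
        hi = max(e for _, e in ivals)
        covered = np.zeros(hi - lo, dtype=bool)
        for s, e in ivals:
            covered[s - lo : e - lo] = True
        in_run = False
        start = None
        runs = []
        for i, c in enumerate(covered):
            if c and not in_run:
                in_run, start = True, i
            elif not c and in_run:
                runs.append((start, i))
                in_run = False
        if in_run:
            runs.append((start, len(covered)))
        # bookended (touching) runs are already contiguous in the mask,
        # so runs are the merged loci
        for s, e in runs:
            out.add((chrom, s + lo, e + lo, fam))
    return out


def mannwhitney_greater_exact(x, y):
    """Exact one-sided Mann-Whitney p by enumerating all group assignments.

    P[U >= u_obs] under the permutation null. Feasible for n+m <= 12.
    """
    x, y = list(x), list(y)
    pooled = x + y
    n = len(x)

    def u_stat(xs, ys):
        u = 0.0
        for a in xs:
            for b in ys:
                if a > b:
                    u += 1.0
                elif a == b:
                    u += 0.5
        return u

    u_obs = u_stat(x, y)
    hits = total = 0
    idx = range(len(pooled))
    for combo in itertools.combinations(idx, n):
        xs = [pooled[i] for i in combo]
        ys = [pooled[i] for i in idx if i not in combo]
        total += 1
        if u_stat(xs, ys) >= u_obs - 1e-12:
            hits += 1
    return hits / total


def window_assignment(feature_start, feature_end, strand, k, flank, positions):
    """Map each 0-based position to its global window index, by direct scan.

    Re-derives the proportional-window layout from first principles: list the
    3k windows as (index, lo, hi) in genomic coordinates, then linearly scan.
    Returns dict pos -> window index (absent if in no window).
    """

    def widths(length):
        base, rem = divmod(length, k)
        return [base + 1] * rem + [base] * (k - rem)

    length = feature_end - feature_start
    wins = []
    if strand == "+":
        cur = feature_start - flank
        for i, w in enumerate(widths(flank)):
            wins.append((i, cur, cur + w))
            cur += w
        cur = feature_start
        for i, w in enumerate(widths(length)):
            wins.append((k + i, cur, cur + w))
            cur += w
        cur = feature_end
        for i, w in enumerate(widths(flank)):
            wins.append((2 * k + i, cur, cur + w))
            cur += w
    else:
        cur = feature_end + flank
        for i, w in enumerate(widths(flank)):
            wins.append((i, cur - w, cur))
            cur -= w
        cur = feature_end
        for i, w in enumerate(widths(length)):
            wins.append((k + i, cur - w, cur))
            cur -= w
        cur = feature_start
        for i, w in enumerate(widths(flank)):
            wins.append((2 * k + i, cur - w, cur))
            cur -= w
    out = {}
    for pos in positions:
        for i, lo, hi in wins:
            if lo <= pos < hi:
                out[pos] = i
                break
    return out


def average_linkage_topology(points: np.ndarray):
    """Set of frozensets of leaf indices merged by naive average linkage.

    Unweighted average linkage (UPGMA on Euclidean distances between
    cluster members), merging the globally closest pair each step.
    """
    n = len(points)
    clusters = {i: [i] for i in range(n)}
    merges = set()
    next_id = n
    while len(clusters) > 1:
        best = None
        for a, b in itertools.combinations(sorted(clusters), 2):
            d = np.mean(
                [
                    np.linalg.norm(points[i] - points[j])
                    for i in clusters[a]
                    for j in clusters[b]
                ]
            )
            if best is None or d < best[0]:
                best = (d, a, b)
        _, a, b = best
        merged = clusters.pop(a) + clusters.pop(b)
        clusters[next_id] = merged
        merges.add(frozenset(merged))
        next_id += 1
    return merges
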