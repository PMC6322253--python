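"""Decile binning, level regression, delta-delta, overlap partitions and the
relative-expression heatmap, against closed forms and naive oracles."""

import math

import numpy as np
import pandas as pd
import pytest

from gbmeth import association
from gbmeth.simulate import SimConfig, simulate_all
from gbmeth import workflows

import oracles


def _calls(levels, status="methylated"):
    n = len(levels)
    st = [status] * n if isinstance(status, str) else status
    return pd.DataFrame(
        {
            "gene": [f"g{i:04d}" for i in range(n)],
            "mc": 0, "n": 100, "sites": 25,
            "level": levels, "p": 0.5, "q": 0.5, "status": st,
        }
    )


# ------------------------------------------------------------ deciles


def test_deciles_partition_evenly():
    calls = _calls(np.linspace(0.1, 0.9, 100))
    expr = pd.Series(np.ones(100), index=calls["gene"])
    out = association.decile_analysis(calls, expr)
    binned = out[out["bin"] != "UM"]
    assert list(binned["n"]) == [10] * 10


def test_deciles_sizes_differ_by_at_most_one():
    calls = _calls(np.linspace(0, 1, 103))
    expr = pd.Series(np.ones(103), index=calls["gene"])
    out = association.decile_analysis(calls, expr)
    sizes = out[out["bin"] != "UM"]["n"].to_numpy()
    assert sizes.sum() == 103
    assert sizes.max() - sizes.min() <= 1


def test_deciles_order_by_level():
    rng = np.random.default_rng(0)
    levels = rng.random(200)
    calls = _calls(levels)
    # expression equal to the methylation level: bin means must increase
    expr = pd.Series(2.0 ** levels, index=calls["gene"])
    out = association.decile_analysis(calls, expr)
    means = out[out["bin"] != "UM"]["mean"].to_numpy()
    assert (np.diff(means) > 0).all()


def test_deciles_require_enough_methylated_genes():
    calls = _calls([0.5] * 9)
    expr = pd.Series(np.ones(9), index=calls["gene"])
    with pytest.raises(ValueError, match="fewer bins"):
        association.decile_analysis(calls, expr)


def test_decile_ci_is_t_based():
    calls = _calls(np.linspace(0.1, 0.9, 10))
    vals = np.array([1.0, 2.0, 4.0, 8.0, 1.0, 2.0, 4.0, 8.0, 1.0, 16.0])
    expr = pd.Series(vals, index=calls["gene"])
    out = association.decile_analysis(calls, expr, n_bins=1)
    row = out[out["bin"] == "1"].iloc[0]
    from scipy import stats

    logged = np.log2(vals + 0.5 * vals[vals > 0].min())
    half = stats.t.ppf(0.975, 9) * logged.std(ddof=1) / math.sqrt(10)
    assert row["mean"] == pytest.approx(logged.mean())
    assert row["ci_high"] - row["mean"] == pytest.approx(half)


# ---------------------------------------------------------- regression


def test_regression_matches_closed_form_ols():
    levels = np.array([0.1, 0.3, 0.5, 0.9])
    fpkm = pd.Series([2.0, 3.0, 5.0, 16.0], index=[f"g{i:04d}" for i in range(4)])
    calls = _calls(levels)
    res = association.level_regression(calls, fpkm)
    x, y = levels, np.log2(fpkm.to_numpy())
    slope = ((x - x.mean()) * (y - y.mean())).sum() / ((x - x.mean()) ** 2).sum()
    intercept = y.mean() - slope * x.mean()
    assert res.slope == pytest.approx(slope, abs=1e-10)
    assert res.intercept == pytest.approx(intercept, abs=1e-10)
    from scipy import stats

    resid = y - (intercept + slope * x)
    s2 = (resid**2).sum() / 2
    se = math.sqrt(s2 / ((x - x.mean()) ** 2).sum())
    t = slope / se
    p = 2 * stats.t.sf(abs(t), 2)
    assert res.p == pytest.approx(p, abs=1e-10)


def test_regression_bonferroni_flag():
    rng = np.random.default_rng(1)
    levels = rng.random(100)
    fpkm = pd.Series(2.0 ** (5 * levels), index=[f"g{i:04d}" for i in range(100)])
    calls = _calls(levels)
    strong = association.level_regression(calls, fpkm, m_tests=1)
    assert strong.significant
    weak = association.level_regression(calls, fpkm, m_tests=10)
    assert weak.significant == (weak.p < 0.005)


def test_regression_degenerate_zero_variance():
    calls = _calls([0.5] * 10)
    fpkm = pd.Series(np.arange(1.0, 11.0), index=calls["gene"])
    res = association.level_regression(calls, fpkm)
    assert res.degenerate and math.isnan(res.slope)


def test_regression_needs_three_positive_genes():
    calls = _calls([0.1, 0.9])
    fpkm = pd.Series([1.0, 2.0], index=calls["gene"])
    with pytest.raises(ValueError):
        association.level_regression(calls, fpkm)


# ---------------------------------------------------------- delta-delta


def _comparison(deltas, classes):
    return pd.DataFrame(
        {
            "gene": [f"g{i:04d}" for i in range(len(deltas))],
            "status_a": "methylated", "status_b": "unmethylated",
            "level_a": 0.5, "level_b": 0.5,
            "class": classes, "delta_level": deltas,
        }
    )


def test_delta_delta_identical_conditions_collapse_to_origin():
    comp = _comparison([0.0] * 20, ["SMG"] * 20)
    fc = pd.Series(np.zeros(20), index=comp["gene"])
    dd = association.delta_delta(comp, fc)
    assert np.allclose(dd.table["delta_mcg"], 0)
    assert np.allclose(dd.table["log2fc"], 0)
    # all mass in the central grid cell
    assert dd.grid_counts.sum() == 20


def test_delta_delta_spearman_sign_tracks_planted_coupling():
    rng = np.random.default_rng(2)
    deltas = -rng.random(300)
    fc = pd.Series(2.0 * deltas + rng.normal(0, 0.1, 300),
                   index=[f"g{i:04d}" for i in range(300)])
    comp = _comparison(deltas, ["DMG"] * 300)
    dd = association.delta_delta(comp, fc)
    assert dd.spearman_rho > 0.9  # more loss -> more downregulation, rho > 0


# ---------------------------------------------------------- overlap


def test_overlap_printed_worked_example():
    t = association.OverlapTable.from_counts(
        dmg_deg=106, dmg_nondeg=6484, other_deg=0, other_nondeg=6003
    )
    assert t.counts.loc["DMG"].sum() == 6590
    assert t.row_percent.loc["DMG", "non-DEG"] == pytest.approx(98.39, abs=0.005)


def test_overlap_all_nondeg_row():
    t = association.OverlapTable.from_counts(10, 0, 0, 0)  # 10 DMGs all DEG
    assert t.row_percent.loc["DMG", "DEG"] == 100.0
    assert math.isnan(t.row_percent.loc["SMG+UMG", "DEG"])  # empty row flagged


def test_overlap_matches_crosstab_oracle(rng):
    n = 500
    classes = rng.choice(["DMG", "SMG", "UMG", "unclassified"], size=n)
    comp = _comparison(rng.normal(size=n), classes)
    flags = pd.Series(rng.random(n) < 0.3, index=comp["gene"])
    t = association.overlap_analysis(comp, flags)
    # brute force
    cells = {("DMG", True): 0, ("DMG", False): 0, ("other", True): 0, ("other", False): 0}
    for g, c in zip(comp["gene"], classes):
        if c == "unclassified":
            continue
        key = "DMG" if c == "DMG" else "other"
        cells[(key, bool(flags[g]))] += 1
    assert t.counts.loc["DMG", "DEG"] == cells[("DMG", True)]
    assert t.counts.loc["DMG", "non-DEG"] == cells[("DMG", False)]
    assert t.counts.loc["SMG+UMG", "DEG"] == cells[("other", True)]
    assert t.counts.loc["SMG+UMG", "non-DEG"] == cells[("other", False)]
    assert t.counts.to_numpy().sum() == (classes != "unclassified").sum()


# ---------------------------------------------------------- heatmap


def test_heatmap_single_row_scaling():
    fp = pd.DataFrame([[2.0, 4.0, 8.0]], index=["g"], columns=["a", "b", "c"])
    mat, order, zeros = association.relative_expression_heatmap_matrix(fp, ["g"])
    assert np.allclose(mat.loc["g"], [0.25, 0.5, 1.0])
    assert zeros == []


def test_heatmap_column_permutation_only_permutes_columns():
    rng = np.random.default_rng(3)
    fp = pd.DataFrame(rng.random((6, 4)), index=list("abcdef"),
                      columns=["r1", "r2", "r3", "r4"])
    m1, o1, _ = association.relative_expression_heatmap_matrix(fp, list("abcdef"))
    perm = ["r3", "r1", "r4", "r2"]
    m2, o2, _ = association.relative_expression_heatmap_matrix(fp[perm], list("abcdef"))
    assert o1 == o2  # Euclidean distances, hence ordering, unchanged
    pd.testing.assert_frame_equal(m2, m1[perm])


def test_heatmap_zero_row_flagged_not_dropped():
    fp = pd.DataFrame([[0.0, 0.0], [1.0, 2.0], [4.0, 1.0]], index=["z", "a", "b"],
                      columns=["x", "y"])
    mat, order, zeros = association.relative_expression_heatmap_matrix(fp, ["z", "a", "b"])
    assert zeros == ["z"]
    assert np.allclose(mat.loc["z"], 0.0)


def test_heatmap_topology_matches_naive_average_linkage(rng):
    fp = pd.DataFrame(rng.random((10, 6)),
                      index=[f"g{i}" for i in range(10)],
                      columns=[f"r{j}" for j in range(6)])
    mat, order, _ = association.relative_expression_heatmap_matrix(fp, list(fp.index))
    from scipy.cluster.hierarchy import linkage

    # re-derive the merge topology from the oracle on the same standardized rows
    rel = fp.div(fp.max(axis=1), axis=0).to_numpy()
    expected = oracles.average_linkage_topology(rel)
    Z = linkage(rel, method="average", metric="euclidean")
    got = set()
    members = {i: frozenset([i]) for i in range(10)}
    for step, (a, b, _, _) in enumerate(Z):
        merged = members[int(a)] | members[int(b)]
        members[10 + step] = merged
        got.add(merged)
    assert got == expected
    # and the returned order is a valid leaf order of that topology
    position = {g: i for i, g in enumerate(order)}
    for clust in expected:
        pos = sorted(position[f"g{i}"] for i in clust)
        assert pos == list(range(pos[0], pos[0] + len(pos)))  # contiguous block


# ---------------------------------------------------------- end-to-end


def test_null_pipeline_shows_no_association():
    cfg = SimConfig(seed=31, n_chrom=2, chrom_len=400_000, n_genes=200,
                    gene_len_range=(1_000, 2_200))
    suite = workflows.run_association_suite(simulate_all(cfg))
    assert abs(suite.dd.spearman_rho) <= 0.15
    nondeg = suite.overlap.row_percent.loc["DMG", "non-DEG"]
    assert nondeg >= 90.0


def test_planted_coupling_is_detected():
    cfg = SimConfig(seed=31, n_chrom=2, chrom_len=400_000, n_genes=200,
                    gene_len_range=(1_000, 2_200), coupling_effect=2.0)
    suite = workflows.run_association_suite(simulate_all(cfg))
    # methylated genes lose mCG (delta < 0) and are downregulated -> rho > 0
    assert suite.dd.spearman_rho > 0.3
    assert suite.de["deg"].sum() > 20
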