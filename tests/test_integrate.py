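"""Cross-level integration: direction calls, discordance, enrichment, clustering."""

import itertools
from math import comb

import numpy as np
import pandas as pd
import pytest

from polystress import (
    call_mrna_direction,
    classify_discordance,
    cluster_genes,
    combine_mrna_translation,
    correlate,
    hypergeom_enrichment,
    max_change,
    tree_to_newick,
)
from polystress.integrate import DISCORDANCE_CLASSES


def _mrna_table(rows: dict, times=(0, 15, 30, 45, 60, 90, 120, 180)):
    return pd.DataFrame(
        {f"stress:{t}": [v[i] for v in rows.values()] for i, t in enumerate(times)},
        index=list(rows),
    )


# --- mRNA direction calls -----------------------------------------------

def test_direction_call_rules():
    log2_15 = np.log2(1.5)
    table = _mrna_table(
        {
            "boundary": [0] + [log2_15] * 7,       # exactly 1.5-fold: strict >
            "up4": [0, 1, 1, 1, 1, 0, 0, 0],       # 4 of 7 pass
            "up3": [0, 1, 1, 1, 0, 0, 0, 0],       # only 3 pass
            "down": [0, -1, -1, -1, -1, -1, 0, 0],
            "flat": [0] * 8,
        }
    )
    calls = call_mrna_direction(table)
    assert calls.loc["boundary", "direction"] == "none"
    assert calls.loc["up4", "direction"] == "up"
    assert calls.loc["up3", "direction"] == "none"
    assert calls.loc["down", "direction"] == "down"
    assert calls.loc["flat", "direction"] == "none"
    assert (calls["n_timepoints"] == 7).all()  # 0-min column ignored


def test_direction_call_monotone_in_cutoffs():
    """Raising fold_cutoff or min_timepoints never adds called genes."""
    rng = np.random.default_rng(3)
    values = rng.normal(0, 1, size=(100, 8))
    values[:, 0] = 0
    table = pd.DataFrame(
        values, columns=[f"s:{t}" for t in (0, 15, 30, 45, 60, 90, 120, 180)],
        index=[f"g{i}" for i in range(100)],
    )
    called = {}
    for fc, mt in [(1.5, 4), (2.0, 4), (1.5, 5), (2.0, 5)]:
        c = call_mrna_direction(table, fold_cutoff=fc, min_timepoints=mt)
        called[(fc, mt)] = set(c.index[c["direction"] != "none"])
    assert called[(2.0, 4)] <= called[(1.5, 4)]
    assert called[(1.5, 5)] <= called[(1.5, 4)]
    assert called[(2.0, 5)] <= called[(1.5, 4)]


def test_direction_call_pools_experiments():
    t1 = _mrna_table({"g": [0, 1, 1, 0, 0, 0, 0, 0]}, times=(0, 15, 30, 45, 60, 90, 120, 180))
    t2 = _mrna_table({"g": [0, 1, 1, 0, 0, 0, 0, 0]}, times=(0, 15, 30, 45, 60, 90, 120, 180))
    single = call_mrna_direction(t1)
    pooled = call_mrna_direction([t1, t2])
    assert single.loc["g", "direction"] == "none"   # 2 of 7
    assert pooled.loc["g", "direction"] == "up"     # 4 of 14 pooled


def test_missing_values_do_not_pass():
    table = _mrna_table({"g": [0, np.nan, np.nan, np.nan, np.nan, 1, 1, 1]})
    assert call_mrna_direction(table).loc["g", "direction"] == "none"


# --- discordance classification -----------------------------------------

def test_discordance_rule_table():
    mrna = pd.Series(
        {"c1": "down", "c2": "up", "pflat_up": "none", "pflat_dn": "none",
         "anti_up": "down", "anti_dn": "up", "conc": "up", "nothing": "none"}
    )
    trans = pd.Series(
        {"c1": "up", "c2": "down", "pflat_up": "none", "pflat_dn": "none",
         "anti_up": "none", "anti_dn": "none", "conc": "up", "nothing": "none"}
    )
    prot = pd.Series(
        {"c1": "unchanged", "c2": "unchanged", "pflat_up": "linear_up",
         "pflat_dn": "linear_down", "anti_up": "linear_up",
         "anti_dn": "linear_down", "conc": "linear_up", "nothing": "unchanged"}
    )
    out = classify_discordance(mrna, trans, prot)
    assert out.loc["c1", "class"] == "mRNA_down_translation_up"
    assert out.loc["c2", "class"] == "mRNA_up_translation_down"
    assert out.loc["pflat_up", "class"] == "protein_up_mRNA_flat"
    assert out.loc["pflat_dn", "class"] == "protein_down_mRNA_flat"
    assert out.loc["anti_up", "class"] == "protein_up_mRNA_down"
    assert out.loc["anti_dn", "class"] == "protein_down_mRNA_up"
    assert out.loc["conc", "class"] == "concordant"
    assert out.loc["nothing", "class"] == "unclassified"


def test_discordance_partitions_universe():
    """Every (mRNA, translation, protein) combination maps to exactly one class."""
    dirs = ["up", "down", "none"]
    cats = ["linear_up", "linear_down", "quadratic_convex",
            "quadratic_concave", "unchanged"]
    combos = list(itertools.product(dirs, dirs, cats))
    idx = [f"g{i}" for i in range(len(combos))]
    m = pd.Series([c[0] for c in combos], index=idx)
    t = pd.Series([c[1] for c in combos], index=idx)
    p = pd.Series([c[2] for c in combos], index=idx)
    out = classify_discordance(m, t, p)
    assert out["class"].isin(DISCORDANCE_CLASSES).all()
    assert len(out) == len(combos)


def test_discordance_missing_level_flagged():
    m = pd.Series({"a": "up", "b": "up"})
    t = pd.Series({"a": "up"})
    p = pd.Series({"a": "unchanged"})
    out = classify_discordance(m, t, p)
    assert bool(out.loc["b", "missing_level"])
    assert out.loc["b", "class"] == "concordant"  # treated as none elsewhere


# --- correlations and combined changes ----------------------------------

def test_correlate_trivial_cases(rng):
    x = rng.normal(size=50)
    r, p = correlate(x, 2 * x + 1, "pearson")
    assert r == pytest.approx(1.0)
    r_s, _ = correlate(x, -x, "spearman")
    assert r_s == pytest.approx(-1.0)
    with pytest.raises(ValueError):
        correlate(x, np.zeros_like(x))
    with pytest.raises(ValueError):
        correlate([1.0, 2.0], [1.0, 2.0])


def test_correlate_recovers_planted_rho(rng):
    """Mean sample correlation over many draws approaches the true rho."""
    rho, n, sims = 0.6, 500, 200
    cov = np.array([[1, rho], [rho, 1]])
    rs = []
    L = np.linalg.cholesky(cov)
    for _ in range(sims):
        xy = rng.normal(size=(n, 2)) @ L.T
        rs.append(correlate(xy[:, 0], xy[:, 1], "pearson")[0])
    assert np.mean(rs) == pytest.approx(rho, abs=0.02)


def test_combine_mrna_translation():
    out = combine_mrna_translation([2.0, 2.0], [1.0, 1.5])
    np.testing.assert_allclose(out, [2.0, 3.0])
    with pytest.raises(ValueError):
        combine_mrna_translation([2.0], [-1.0])


def test_max_change_keeps_sign():
    assert max_change([0.2, 1.0, 0.5]) == 1.0
    assert max_change([-1.2, 0.8]) == -1.2
    assert max_change([0.0, 0.0]) == 0.0
    with pytest.raises(ValueError):
        max_change([])


# --- hypergeometric enrichment ------------------------------------------

def brute_force_tail(N, K, n, k):
    """P(X >= k) by exhaustive counting of draws."""
    total = comb(N, n)
    return sum(comb(K, j) * comb(N - K, n - j)
               for j in range(k, min(K, n) + 1)) / total


def test_enrichment_exact_example():
    universe = {f"g{i}" for i in range(10)}
    query = {f"g{i}" for i in range(5)}
    sets = {"hit": set(query), "all": set(universe)}
    out = hypergeom_enrichment(query, sets, universe)
    assert out.loc["hit", "p"] == pytest.approx(1 / comb(10, 5), abs=1e-12)
    assert out.loc["all", "p"] == pytest.approx(1.0)


def test_enrichment_matches_enumeration():
    """Tail probability equals brute-force enumeration for all N <= 20."""
    for N in (5, 8, 13, 20):
        universe = {f"g{i}" for i in range(N)}
        for K in (1, N // 2, N - 1):
            members = {f"g{i}" for i in range(K)}
            for n in (1, N // 3 + 1, N):
                query = {f"g{i}" for i in range(N - n, N)}
                k = len(query & members)
                out = hypergeom_enrichment(query, {"s": members}, universe)
                assert out.loc["s", "p"] == pytest.approx(
                    brute_force_tail(N, K, n, k), abs=1e-12
                ), (N, K, n, k)


def test_enrichment_edge_cases():
    universe = {"a", "b", "c"}
    out = hypergeom_enrichment(set(), {"s": {"a"}}, universe)
    assert out.loc["s", "p"] == 1.0  # empty query: tail includes X >= 0
    with pytest.raises(ValueError):
        hypergeom_enrichment({"a"}, {"s": {"a"}}, set())


def test_enrichment_bh_adjustment_monotone():
    universe = {f"g{i}" for i in range(100)}
    query = {f"g{i}" for i in range(20)}
    sets = {f"s{j}": {f"g{i}" for i in range(j, j + 30)} for j in range(5)}
    out = hypergeom_enrichment(query, sets, universe, adjust=True)
    assert (out["p_adjusted"] >= out["p"] - 1e-12).all()
    assert (out["p_adjusted"] <= 1.0).all()


# --- clustering ----------------------------------------------------------

def _ratio_matrix():
    return pd.DataFrame(
        {
            "a": [1.0, 2.0, 3.0, 4.0],
            "b": [2.0, 4.0, 6.0, 8.0],      # rank-identical to a
            "c": [4.0, 3.0, 2.0, 1.0],      # rank-reversed
        },
        index=["t1", "t2", "t3", "t4"],
    ).T


def test_identical_ranks_merge_first():
    Z, leaves, kept, dropped = cluster_genes(_ratio_matrix())
    # first merge joins rows 0 and 1 (a, b) at distance 0
    assert {int(Z[0, 0]), int(Z[0, 1])} == {0, 1}
    assert Z[0, 2] == pytest.approx(0.0)
    assert len(dropped) == 0
    assert set(leaves) == {"a", "b", "c"}


def test_clustering_invariant_to_row_order_and_monotone_transform():
    m = _ratio_matrix()
    Z1, leaves1, _, _ = cluster_genes(m)
    Z2, leaves2, _, _ = cluster_genes(m.iloc[[2, 0, 1]])
    # same topology: the (a, b) pair still merges first at distance 0
    assert Z2[0, 2] == pytest.approx(0.0)
    transformed = m.copy()
    transformed.loc["a"] = np.exp(m.loc["a"])  # monotone transform of one row
    Z3, leaves3, _, _ = cluster_genes(transformed)
    np.testing.assert_allclose(Z1[:, 2], Z3[:, 2], atol=1e-12)
    assert leaves1 == leaves3


def test_constant_rows_dropped_with_warning():
    m = _ratio_matrix()
    m.loc["flat"] = 1.0
    with pytest.warns(UserWarning):
        Z, leaves, kept, dropped = cluster_genes(m)
    assert list(dropped) == ["flat"]
    assert "flat" not in leaves


def test_newick_output_contains_all_leaves():
    Z, leaves, kept, _ = cluster_genes(_ratio_matrix())
    nwk = tree_to_newick(Z, kept)
    assert nwk.endswith(";")
    for name in ("a", "b", "c"):
        assert name in nwk
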