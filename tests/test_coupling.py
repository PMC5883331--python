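import numpy as np
import pandas as pd
import pytest
from scipy import stats

import transcortex as tx
from transcortex import coupling as cp
from transcortex.genesets import GeneSet
from transcortex.networks import WeightedNetwork, coexpression_network
from transcortex.spatial import NullPartitionSet


def _weighted(w):
    return WeightedNetwork(weights=np.asarray(w, float))


# -------------------------------------------------------------- edge table

def test_edge_table_row_count_and_distances(atlas60):
    left = atlas60.left()
    rng = np.random.default_rng(0)
    n = left.n_regions
    w = rng.uniform(0.01, 1, (n, n))
    w = (w + w.T) / 2
    np.fill_diagonal(w, 1.0)
    scn = _weighted(w)
    table = cp.build_edge_table(scn, {"genome": _weighted(w)}, left, 0.10)
    assert len(table) == n * (n - 1) // 2
    d = left.distances()
    for _, row in table.head(30).iterrows():
        i = np.flatnonzero(left.region_id == row["region_i"])[0]
        j = np.flatnonzero(left.region_id == row["region_j"])[0]
        assert row["distance_mm"] == pytest.approx(d[i, j], abs=1e-12)


def test_edge_table_symmetry_guard(atlas60):
    left = atlas60.left()
    n = left.n_regions
    w = np.random.default_rng(1).uniform(0.01, 1, (n, n))
    np.fill_diagonal(w, 1.0)   # asymmetric
    with pytest.raises(ValueError, match="symmetric"):
        cp.build_edge_table(_weighted((w + w.T) / 2), {"bad": _weighted(w)},
                            left, 0.10)


# ---------------------------------------------------------- distance decay

def test_linear_generating_form_wins():
    d = np.linspace(5, 120, 300)
    y = 2.0 - 0.01 * d
    lin = cp.distance_decay_fit(y, d, "linear")
    exp = cp.distance_decay_fit(y, d, "exponential")
    assert lin.r2 == pytest.approx(1.0)
    assert lin.aic < exp.aic


def test_exponential_generating_form_fits_exactly():
    d = np.linspace(5, 120, 300)
    y = np.exp(-d / 30)
    fit = cp.distance_decay_fit(y, d, "exponential")
    assert fit.r2 == pytest.approx(1.0)
    assert fit.coefficients["decay_mm"] == pytest.approx(30.0, rel=1e-6)


def test_exponential_model_recovery_under_noise():
    wins = 0
    for seed in range(20):
        rng = np.random.default_rng(seed)
        d = rng.uniform(5, 150, 500)
        y = np.exp(-d / 30) + rng.normal(0, 0.05, 500)
        lin = cp.distance_decay_fit(y, d, "linear")
        exp = cp.distance_decay_fit(y, d, "exponential")
        wins += exp.aic < lin.aic
    assert wins >= 18


# ------------------------------------------------------- partial correlation

def test_partial_r2_is_one_for_identical_variables():
    rng = np.random.default_rng(2)
    x = rng.normal(size=200)
    ctrl = rng.normal(size=200)
    fit = cp.partial_edge_correlation(x, x, ctrl)
    assert fit.r2 == pytest.approx(1.0)


def test_partial_correlation_calibrated_under_null():
    # x and y both functions of the control plus independent noise
    rng = np.random.default_rng(0)
    ps = []
    for _ in range(200):
        ctrl = rng.normal(size=120)
        x = 0.8 * ctrl + rng.normal(size=120)
        y = -0.5 * ctrl + rng.normal(size=120)
        ps.append(cp.partial_edge_correlation(x, y, ctrl).p_value)
    ps = np.array(ps)
    assert abs((ps < 0.05).mean() - 0.05) < 0.05
    assert stats.kstest(ps, "uniform").pvalue > 0.01


def test_partial_correlation_recovers_planted_coupling():
    rs = []
    for seed in range(10):
        rng = np.random.default_rng(100 + seed)
        n = 1000
        ctrl = rng.normal(size=n)
        shared = rng.normal(size=n)
        rho = 0.3
        x = 0.7 * ctrl + np.sqrt(rho) * shared \
            + np.sqrt(1 - rho) * rng.normal(size=n)
        y = -0.4 * ctrl + np.sqrt(rho) * shared \
            + np.sqrt(1 - rho) * rng.normal(size=n)
        rs.append(cp.partial_edge_correlation(x, y, ctrl).coefficients["r"])
    assert np.mean(rs) == pytest.approx(0.30, abs=0.06)


# ------------------------------------------------- intramodule permutation

def _null_set(labels_list):
    return NullPartitionSet(labels=np.array(labels_list), seed=0,
                            n_rejected=0)


def test_constant_coexpression_gives_p_one():
    n = 10
    w = np.full((n, n), 0.4)
    np.fill_diagonal(w, 1.0)
    labels = np.array([1] * 5 + [2] * 5)
    nulls = _null_set([np.roll(labels, k) for k in range(8)])
    res = cp.intramodule_coexpression_test(w, labels, nulls)
    assert res.p_value == 1.0
    assert res.observed == pytest.approx(0.4)


def test_observed_mean_matches_double_loop(rng):
    n = 14
    w = rng.normal(size=(n, n))
    w = (w + w.T) / 2
    labels = rng.integers(1, 4, n)
    nulls = _null_set([rng.permutation(labels) for _ in range(5)])
    res = cp.intramodule_coexpression_test(w, labels, nulls)
    tot, cnt = 0.0, 0
    for i in range(n):
        for j in range(i + 1, n):
            if labels[i] == labels[j]:
                tot += w[i, j]
                cnt += 1
    assert res.observed == pytest.approx(tot / cnt, abs=1e-12)


def test_permutation_p_value_convention():
    n = 6
    w = np.eye(n) + 0.5
    labels = np.array([1, 1, 1, 2, 2, 2])
    nulls = _null_set([labels] * 9)     # every null ties the observed
    res = cp.intramodule_coexpression_test(w, labels, nulls)
    assert res.p_value == pytest.approx(1.0)
    assert res.p_value > 0              # never exactly zero by construction


# ------------------------------------------------------------- gene sets

def test_single_gene_set_index_is_z_profile():
    rng = np.random.default_rng(5)
    regional = pd.DataFrame({"A": rng.normal(2, 3, 15),
                             "B": rng.normal(size=15)},
                            index=np.arange(1, 16))
    index, missing = cp.gene_set_index(regional, GeneSet("s", ("A",)))
    z = (regional["A"] - regional["A"].mean()) / regional["A"].std(ddof=0)
    np.testing.assert_allclose(index.to_numpy(), z.to_numpy(), atol=1e-12)
    assert missing == []


def test_gene_set_index_mean_zero_and_hand_computation():
    regional = pd.DataFrame({"A": [1.0, 2.0, 3.0], "B": [2.0, 2.0, 5.0],
                             "C": [0.0, 1.0, -1.0]}, index=[1, 2, 3])
    index, _ = cp.gene_set_index(regional, GeneSet("s", ("A", "B", "C")))
    assert abs(index.mean()) < 1e-10
    za = (np.array([1, 2, 3]) - 2) / np.std([1, 2, 3])
    zb = (np.array([2, 2, 5]) - 3) / np.std([2, 2, 5])
    zc = (np.array([0, 1, -1]) - 0) / np.std([0, 1, -1])
    np.testing.assert_allclose(index.to_numpy(), (za + zb + zc) / 3,
                               atol=1e-12)


def test_missing_genes_reported():
    regional = pd.DataFrame({"A": [1.0, 2.0, 3.0]}, index=[1, 2, 3])
    index, missing = cp.gene_set_index(regional, GeneSet("s", ("A", "ZZZ")))
    assert missing == ["ZZZ"]
    with pytest.raises(ValueError):
        cp.gene_set_index(regional, GeneSet("s", ("NOPE",)))


def test_screen_degenerate_all_gene_set_equals_genome(reduced_regional,
                                                      reduced_dataset):
    regional = reduced_regional.values
    left = reduced_dataset.atlas.left()
    scn = tx.pearson_network(reduced_dataset.thickness)
    all_set = GeneSet("all", tuple(regional.columns))
    screen = cp.set_coexpression_screen(regional, [all_set], scn,
                                        left.distances())
    genome = coexpression_network(regional)
    iu = np.triu_indices(left.n_regions, 1)
    r = np.corrcoef(genome.weights[iu], scn.weights[iu])[0, 1]
    assert screen["r2"].iloc[0] == pytest.approx(r * r, abs=1e-12)


def test_screen_r2_matches_independent_recomputation(reduced_regional,
                                                     reduced_dataset, rng):
    regional = reduced_regional.values
    left = reduced_dataset.atlas.left()
    scn = tx.pearson_network(reduced_dataset.thickness)
    sets = []
    for i in range(5):
        genes = tuple(rng.choice(regional.columns, 8, replace=False))
        sets.append(GeneSet(f"s{i}", genes))
    screen = cp.set_coexpression_screen(regional, sets, scn,
                                        left.distances())
    iu = np.triu_indices(left.n_regions, 1)
    for _, row in screen.iterrows():
        genes = [s for s in sets if s.name == row["set"]][0].genes
        x = regional[list(genes)].to_numpy(float)
        z = (x - x.mean(0)) / x.std(0)
        vals = np.corrcoef(z)[iu]
        r = np.corrcoef(vals, scn.weights[iu])[0, 1]
        assert row["r2"] == pytest.approx(r * r, abs=1e-10)


# ------------------------------------------------------------- nested F

def test_nested_f_zero_when_a_equals_b(rng):
    n = 100
    d = rng.uniform(5, 100, n)
    b = rng.normal(size=n)
    y = 0.5 * b + rng.normal(size=n)
    f, df1, df2, p = cp.nested_coupling_F(y, b, b, d)
    assert f == pytest.approx(0.0, abs=1e-9)


def test_nested_f_matches_hand_rolled_rss():
    rng = np.random.default_rng(8)
    n = 20
    d = rng.uniform(5, 100, n)
    a = rng.normal(size=n)
    b = rng.normal(size=n)
    y = 0.3 * a + 0.2 * b + rng.normal(size=n)
    f, df1, df2, p = cp.nested_coupling_F(y, a, b, d)
    logd = np.log(d)

    def resid(v):
        x = np.column_stack([np.ones(n), logd])
        beta = np.linalg.lstsq(x, v, rcond=None)[0]
        return v - x @ beta

    yr, ar, br = resid(y), resid(a), resid(b)

    def rss(design):
        beta = np.linalg.lstsq(design, yr, rcond=None)[0]
        return ((yr - design @ beta) ** 2).sum()

    rss0 = rss(np.column_stack([np.ones(n), br]))
    rss1 = rss(np.column_stack([np.ones(n), br, ar]))
    expect = (rss0 - rss1) / (rss1 / (n - 3))
    assert f == pytest.approx(expect, abs=1e-10)
    assert df2 == n - 3


def test_nested_f_power_for_planted_extra_signal():
    hits = 0
    for seed in range(10):
        rng = np.random.default_rng(seed)
        n = 500
        d = rng.uniform(5, 100, n)
        b = rng.normal(size=n)
        extra = rng.normal(size=n)
        a = 0.7 * b + 0.7 * extra
        y = 0.5 * b + 0.2 * extra + rng.normal(size=n)
        f, _, _, p = cp.nested_coupling_F(y, a, b, d)
        hits += p < 0.05
    assert hits >= 9


# ---------------------------------------------------- contrasts & classes

def test_edge_nonedge_guard_and_oracle(rng):
    table = pd.DataFrame({
        "is_edge": [True, True, False, False, False],
        "coexpr_genome": [0.5, 0.7, 0.1, -0.1, 0.0]})
    res = cp.edge_nonedge_contrast(table, "coexpr_genome")
    assert res.mean_edges == pytest.approx(0.6)
    assert res.mean_nonedges == pytest.approx(0.0)
    all_edges = table.assign(is_edge=True)
    with pytest.raises(ValueError):
        cp.edge_nonedge_contrast(all_edges, "coexpr_genome")


def test_class_test_null_and_recovery(atlas60, rng):
    left = atlas60.left()
    zero = pd.Series(np.zeros(left.n_regions) + rng.normal(0, 1e-6,
                                                           left.n_regions),
                     index=left.region_id)
    res = cp.class_expression_test(zero, left.ve_class)
    assert not (res["p_fdr"] < 0.05).any()
    # shift class 1 regions by +1 sd
    shifted = pd.Series(rng.normal(0, 0.2, left.n_regions),
                        index=left.region_id)
    shifted[left.ve_class == 1] += 1.0
    res = cp.class_expression_test(shifted, left.ve_class)
    row = res[res["ve_class"] == 1].iloc[0]
    assert row["p_fdr"] < 0.05
    assert row["mean_index"] > 0


def test_bh_adjustment_matches_hand_computation():
    ps = np.array([0.001, 0.008, 0.039, 0.041, 0.042, 0.06, 0.074])
    from statsmodels.stats.multitest import multipletests

    adj = multipletests(ps, method="fdr_bh")[1]
    m = len(ps)
    order = np.argsort(ps)
    raw = ps[order] * m / (np.arange(m) + 1)
    stepped = np.minimum.accumulate(raw[::-1])[::-1]
    expect = np.empty(m)
    expect[order] = np.minimum(stepped, 1.0)
    np.testing.assert_allclose(adj, expect, atol=1e-12)


# ------------------------------------------------------ variance partition

def test_variance_partition_orthogonal_and_exact(rng):
    n = 400
    x1 = np.tile([1.0, -1.0], n // 2)
    x2 = np.repeat([1.0, -1.0], n // 2)    # orthogonal to x1 and centered
    y = 0.6 * x1 + 0.3 * x2
    out = cp.variance_partition(y, x1, x2, np.zeros(n))
    assert out["distance_plus_coexpression"] == pytest.approx(
        out["log_distance"] + out["set_coexpression"], abs=1e-8)
    exact = cp.variance_partition(x1, x1, x2, x2)
    assert exact["log_distance"] == pytest.approx(1.0)


def test_variance_partition_matches_normal_equations(rng):
    n = 50
    x1 = rng.normal(size=n)
    x2 = rng.normal(size=n)
    y = 0.4 * x1 - 0.2 * x2 + rng.normal(size=n)
    out = cp.variance_partition(y, x1, x2, np.zeros(n) + rng.normal(size=n))
    design = np.column_stack([np.ones(n), x1, x2])
    beta = np.linalg.solve(design.T @ design, design.T @ y)
    yhat = design @ beta
    expect = 1 - ((y - yhat) ** 2).sum() / ((y - y.mean()) ** 2).sum()
    assert out["distance_plus_coexpression"] == pytest.approx(expect,
                                                              abs=1e-10)
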