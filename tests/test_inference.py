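"""Per-method scorer contracts and brute-force oracle equivalence."""
import numpy as np
import pandas as pd
import pytest
import scipy.stats as st

import ponet
from ponet.errors import ConfigError
from conftest import make_expression


def _po_of(values, stages=None, n_rep=1, genes=None):
    values = np.asarray(values, dtype=float)
    if stages is None:
        stages = tuple(f"t{i}" for i in range(values.shape[1] // n_rep))
    t = make_expression(np.zeros_like(values), stages, "T", n_rep, genes)
    p = make_expression(values, stages, "P", n_rep, genes)
    return ponet.compute_po(t, p)


@pytest.fixture(scope="module")
def random_po():
    rng = np.random.default_rng(13)
    return _po_of(rng.normal(size=(15, 18)), n_rep=2)


# ---------------------------------------------------------------------------
# correlation
# ---------------------------------------------------------------------------

def test_duplicated_gene_scores_one():
    rng = np.random.default_rng(0)
    x = rng.normal(size=(1, 12))
    po = _po_of(np.vstack([x, x, rng.normal(size=(1, 12))]), n_rep=2)
    table = ponet.correlation_scores(po)
    g = list(po.genes)
    assert table.scores.loc[g[0], g[1]] == pytest.approx(1.0)


def test_negated_gene_scores_one_with_negative_sign():
    rng = np.random.default_rng(1)
    x = rng.normal(size=(1, 12))
    po = _po_of(np.vstack([x, -x, rng.normal(size=(1, 12))]), n_rep=2)
    table = ponet.correlation_scores(po)
    g = list(po.genes)
    assert table.scores.loc[g[0], g[1]] == pytest.approx(1.0)
    assert table.sign.loc[g[0], g[1]] == -1


def test_spearman_equals_pearson_on_ranks(random_po):
    spear = ponet.correlation_scores(random_po, "spearman")
    x = random_po.sample_matrix()
    ranks = st.rankdata(x, axis=1)
    oracle = np.abs(np.corrcoef(ranks))
    np.fill_diagonal(oracle, 0.0)
    assert np.allclose(spear.scores.to_numpy(), oracle, atol=1e-12)


def test_zero_variance_gene_scores_zero():
    rng = np.random.default_rng(2)
    vals = np.vstack([np.full((1, 12), 2.0), rng.normal(size=(2, 12))])
    po = _po_of(vals, n_rep=2)
    with pytest.warns(UserWarning, match="zero-variance"):
        table = ponet.correlation_scores(po)
    g = list(po.genes)
    assert (table.scores.loc[g[0]] == 0).all()


# ---------------------------------------------------------------------------
# eta-squared
# ---------------------------------------------------------------------------

def test_eta2_near_one_for_monotone_function():
    """Noiseless monotone dependence on a well-spread predictor scores >=0.9."""
    rng = np.random.default_rng(3)
    x = np.linspace(-2, 2, 18)
    vals = np.vstack([x, 2 * x + 1, rng.normal(size=18)])
    po = _po_of(vals, n_rep=2)
    table = ponet.anova_eta_scores(po, n_bins=4)
    g = list(po.genes)
    assert table.scores.loc[g[0], g[1]] >= 0.9


def test_eta2_null_mean_matches_closed_form():
    """Independent Gaussians: E[eta^2] = (k-1)/(n-1)."""
    rng = np.random.default_rng(4)
    n, k = 20, 4
    vals = []
    for _ in range(1000):
        vals.append(rng.normal(size=n))
    po = _po_of(np.vstack([rng.normal(size=n), *vals]), n_rep=2)
    table = ponet.anova_eta_scores(po, n_bins=k)
    g = list(po.genes)
    etas = table.scores.loc[g[0], g[1:]].to_numpy()
    expected = (k - 1) / (n - 1)
    se = etas.std(ddof=1) / np.sqrt(len(etas))
    assert abs(etas.mean() - expected) < 2 * se + 1e-3


def test_eta2_constant_target_zero():
    rng = np.random.default_rng(5)
    vals = np.vstack([rng.normal(size=16), np.full(16, 1.5), rng.normal(size=16)])
    po = _po_of(vals, n_rep=2)
    table = ponet.anova_eta_scores(po, n_bins=4)
    g = list(po.genes)
    assert table.scores.loc[g[0], g[1]] == 0.0


# ---------------------------------------------------------------------------
# mutual information
# ---------------------------------------------------------------------------

def test_mi_diagonal_is_marginal_entropy(random_po):
    mi = ponet.mutual_information(random_po, n_bins=4)
    x = random_po.sample_matrix()
    n = x.shape[1]
    for gi, row in zip(random_po.genes, x):
        # equal-frequency bins of n samples into 4 bins
        order = np.argsort(row, kind="mergesort")
        ids = np.empty(n, dtype=int)
        ids[order] = np.minimum((np.arange(n) * 4) // n, 3)
        p = np.bincount(ids, minlength=4) / n
        h = -(p[p > 0] * np.log2(p[p > 0])).sum()
        assert mi.mi.loc[gi, gi] == pytest.approx(h, abs=1e-12)


def test_mi_matches_naive_double_loop_oracle():
    rng = np.random.default_rng(6)
    po = _po_of(rng.normal(size=(10, 16)), n_rep=2)
    n_bins = 4
    mi = ponet.mutual_information(po, n_bins=n_bins)
    x = po.sample_matrix()
    n = x.shape[1]

    def bins(row):
        order = np.argsort(row, kind="mergesort")
        ids = np.empty(n, dtype=int)
        ids[order] = np.minimum((np.arange(n) * n_bins) // n, n_bins - 1)
        return ids

    for i in range(10):
        for j in range(i + 1, 10):
            bi, bj = bins(x[i]), bins(x[j])
            joint = np.zeros((n_bins, n_bins))
            for a, b in zip(bi, bj):
                joint[a, b] += 1
            joint /= n
            pi, pj = joint.sum(axis=1), joint.sum(axis=0)
            expect = 0.0
            for a in range(n_bins):
                for b in range(n_bins):
                    if joint[a, b] > 0:
                        expect += joint[a, b] * np.log2(joint[a, b] / (pi[a] * pj[b]))
            assert mi.mi.iloc[i, j] == pytest.approx(expect, abs=1e-10)


def test_mi_independent_below_shuffle_null():
    rng = np.random.default_rng(7)
    x = rng.normal(size=24)
    y = rng.normal(size=24)
    po = _po_of(np.vstack([x, y]), n_rep=2)
    observed = ponet.mutual_information(po, n_bins=4).mi.iloc[0, 1]
    null = []
    for _ in range(200):
        po_s = _po_of(np.vstack([x, rng.permutation(y)]), n_rep=2)
        null.append(ponet.mutual_information(po_s, n_bins=4).mi.iloc[0, 1])
    assert observed <= np.percentile(null, 95)


def test_mi_too_many_bins_rejected(random_po):
    with pytest.raises(ConfigError):
        ponet.mutual_information(random_po, n_bins=100)


# ---------------------------------------------------------------------------
# CLR
# ---------------------------------------------------------------------------

def _mi_from(matrix, genes=None):
    genes = genes or [f"g{i}" for i in range(matrix.shape[0])]
    df = pd.DataFrame(matrix, index=genes, columns=genes)
    return ponet.MIMatrix(df, n_bins=4)


def test_clr_flat_matrix_all_zero():
    m = np.full((5, 5), 0.3)
    np.fill_diagonal(m, 1.0)
    table = ponet.clr_transform(_mi_from(m))
    assert np.allclose(table.scores.to_numpy(), 0.0)


def test_clr_single_elevated_pair_is_maximal():
    m = np.full((6, 6), 0.2)
    rng = np.random.default_rng(8)
    m += rng.normal(0, 0.001, m.shape)
    m = (m + m.T) / 2
    m[1, 4] = m[4, 1] = 0.9
    np.fill_diagonal(m, 1.0)
    table = ponet.clr_transform(_mi_from(m))
    sc = table.scores.to_numpy()
    assert sc[1, 4] == sc.max()


def test_clr_matches_row_z_recomputation():
    rng = np.random.default_rng(9)
    m = np.abs(rng.normal(0.3, 0.1, size=(15, 15)))
    m = (m + m.T) / 2
    np.fill_diagonal(m, 1.0)
    table = ponet.clr_transform(_mi_from(m))
    n = 15
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            off_i = [m[i, k] for k in range(n) if k != i]
            off_j = [m[j, k] for k in range(n) if k != j]
            zi = (m[i, j] - np.mean(off_i)) / np.std(off_i)
            zj = (m[i, j] - np.mean(off_j)) / np.std(off_j)
            expect = np.sqrt(max(zi, 0) ** 2 + max(zj, 0) ** 2)
            assert table.scores.iloc[i, j] == pytest.approx(expect, abs=1e-10)


# ---------------------------------------------------------------------------
# ARACNE
# ---------------------------------------------------------------------------

def test_aracne_triangle_weakest_edge_removed():
    m = np.zeros((3, 3))
    m[0, 1] = m[1, 0] = 0.5
    m[0, 2] = m[2, 0] = 0.4
    m[1, 2] = m[2, 1] = 0.1
    table = ponet.aracne_prune(_mi_from(m))
    assert table.scores.iloc[1, 2] == 0.0
    assert table.scores.iloc[0, 1] == 0.5
    assert table.scores.iloc[0, 2] == 0.4


def test_aracne_chain_not_pruned():
    m = np.zeros((3, 3))
    m[0, 1] = m[1, 0] = 0.5
    m[1, 2] = m[2, 1] = 0.4
    table = ponet.aracne_prune(_mi_from(m))
    assert table.scores.iloc[0, 1] == 0.5
    assert table.scores.iloc[1, 2] == 0.4


def test_aracne_matches_all_triangles_brute_force():
    rng = np.random.default_rng(10)
    n = 12
    m = np.abs(rng.normal(0.3, 0.15, size=(n, n)))
    m = (m + m.T) / 2
    np.fill_diagonal(m, 0.0)
    eps = 0.05
    table = ponet.aracne_prune(_mi_from(m), epsilon=eps)
    removed = np.zeros((n, n), dtype=bool)
    for i in range(n):
        for j in range(n):
            for k in range(n):
                if len({i, j, k}) < 3:
                    continue
                if m[i, j] < min(m[i, k], m[j, k]) * (1 - eps):
                    removed[i, j] = removed[j, i] = True
    expect = np.where(removed, 0.0, m)
    assert np.allclose(table.scores.to_numpy(), expect)


def test_aracne_bad_epsilon_rejected():
    with pytest.raises(ConfigError):
        ponet.aracne_prune(_mi_from(np.zeros((3, 3))), epsilon=1.5)


# ---------------------------------------------------------------------------
# partial correlation
# ---------------------------------------------------------------------------

def test_two_gene_pcor_equals_marginal_correlation():
    rng = np.random.default_rng(11)
    x = rng.normal(size=20)
    y = 0.6 * x + rng.normal(0, 0.5, size=20)
    po = _po_of(np.vstack([x, y]), n_rep=2)
    table = ponet.partial_correlation_shrinkage(po, shrinkage=0.0)
    r = abs(np.corrcoef(x, y)[0, 1])
    assert table.scores.iloc[0, 1] == pytest.approx(r, abs=1e-9)


def test_pcor_zero_shrinkage_matches_precision_oracle():
    rng = np.random.default_rng(12)
    x = rng.normal(size=(5, 100))
    po = _po_of(x, n_rep=2)
    table = ponet.partial_correlation_shrinkage(po, shrinkage=0.0)
    r = np.corrcoef(x)
    prec = np.linalg.pinv(r)
    d = np.sqrt(np.diag(prec))
    expect = np.abs(-prec / np.outer(d, d))
    np.fill_diagonal(expect, 0.0)
    assert np.allclose(table.scores.to_numpy(), expect, atol=1e-8)


def test_pcor_suppresses_indirect_chain_link():
    rng = np.random.default_rng(13)
    hits = 0
    for trial in range(100):
        x = rng.normal(size=500)
        y = x + rng.normal(0, 0.5, size=500)
        z = y + rng.normal(0, 0.5, size=500)
        po = _po_of(np.vstack([x, y, z]), n_rep=2)
        table = ponet.partial_correlation_shrinkage(po)
        if table.scores.iloc[0, 2] < table.scores.iloc[0, 1]:
            hits += 1
    assert hits >= 95


# ---------------------------------------------------------------------------
# tree ensemble
# ---------------------------------------------------------------------------

def test_tree_importance_seeded_determinism(random_po):
    a = ponet.tree_ensemble_importance(random_po, n_trees=20, seed=5)
    b = ponet.tree_ensemble_importance(random_po, n_trees=20, seed=5)
    pd.testing.assert_frame_equal(a.scores, b.scores)


def test_tree_importance_sums_to_one(random_po):
    table = ponet.tree_ensemble_importance(random_po, n_trees=20, seed=5)
    sums = table.scores.sum(axis=0).to_numpy()
    assert np.allclose(sums, 1.0, atol=1e-9)


def test_tree_importance_recovers_planted_regulator():
    hits = 0
    for seed in range(20):
        rng = np.random.default_rng(100 + seed)
        x = rng.normal(size=(21, 60))
        x[1] = 2 * x[0] + rng.normal(0, 0.3, size=60)
        po = _po_of(x, n_rep=2)
        table = ponet.tree_ensemble_importance(po, n_trees=50, seed=seed)
        target = list(po.genes)[1]
        top = table.scores[target].idxmax()
        if top == list(po.genes)[0]:
            hits += 1
    assert hits >= 18


# ---------------------------------------------------------------------------
# cross-cutting properties
# ---------------------------------------------------------------------------

def test_symmetry_and_finiteness_audit(random_po):
    for table in ponet.inference.run_methods(random_po, seed=1):
        m = table.scores.to_numpy()
        assert np.isfinite(m).all()
        assert np.all(np.diag(m) == 0)
        if table.symmetric:
            assert np.allclose(m, m.T)


def test_gene_permutation_equivariance():
    rng = np.random.default_rng(14)
    vals = rng.normal(size=(8, 18))
    po = _po_of(vals, n_rep=2)
    perm = rng.permutation(8)
    po_p = ponet.POProfile(po.data.iloc[perm], po.stage_order)
    for method in ("pearson", "anova", "clr", "pcor"):
        a = ponet.inference.METHODS[method](po, 0)
        b = ponet.inference.METHODS[method](po_p, 0)
        realigned = b.scores.loc[a.scores.index, a.scores.columns]
        assert np.allclose(a.scores.to_numpy(), realigned.to_numpy(), atol=1e-10)
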