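"""Alpha diversity, UniFrac (vs branch-enumeration oracle and scikit-bio)
and PERMANOVA (vs algebraic identities and exact enumeration)."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from skbio import DistanceMatrix
from skbio.stats.distance import permanova as skbio_permanova

from eimbiome.containers import CountTable
from eimbiome.diversity import (
    alpha_diversity,
    beta_distance_matrix,
    kruskal_compare,
    permanova,
    rank_compare,
    unweighted_unifrac,
    weighted_unifrac,
)
from eimbiome.synthetic import generate_random_tree


# --------------------------------------------------------------------
# alpha
# --------------------------------------------------------------------

def test_alpha_hand_values():
    counts = CountTable(
        pd.DataFrame(
            [[5, 5, 5, 5], [9, 0, 0, 0], [8, 4, 4, 0]],
            index=["uniform", "single", "mixed"],
            columns=list("abcd"),
        )
    )
    out = alpha_diversity(counts)
    assert out.loc["uniform", "observed_richness"] == 4
    assert out.loc["uniform", "shannon"] == pytest.approx(math.log(4), abs=1e-12)
    assert out.loc["uniform", "pielou_evenness"] == pytest.approx(1.0, abs=1e-12)
    assert out.loc["single", "shannon"] == 0.0
    assert np.isnan(out.loc["single", "pielou_evenness"])
    # fractions (0.5, 0.25, 0.25): direct evaluation of -sum p ln p
    assert out.loc["mixed", "shannon"] == pytest.approx(1.039721, abs=1e-6)
    assert out.loc["mixed", "pielou_evenness"] == pytest.approx(0.946395, abs=1e-6)


def test_shannon_maximal_at_uniform():
    rng = np.random.default_rng(1)
    for _ in range(10):
        k = rng.integers(2, 10)
        skew = rng.integers(1, 100, size=k)
        counts = CountTable(
            pd.DataFrame([np.full(k, 10), skew], index=["u", "s"],
                         columns=[f"a{i}" for i in range(k)])
        )
        out = alpha_diversity(counts)
        assert out.loc["u", "shannon"] >= out.loc["s", "shannon"] - 1e-12


# --------------------------------------------------------------------
# UniFrac oracles
# --------------------------------------------------------------------

def _branch_sets(tree):
    """(length, descendant-tip frozenset) for every non-root branch."""
    out = []
    for node in tree.traverse(include_self=False):
        tips = frozenset(t.name for t in node.tips()) or frozenset([node.name])
        out.append((node.length, tips))
    return out


def oracle_unweighted(a, b, tree):
    shared = unique = 0.0
    pa = {k for k, v in a.items() if v > 0}
    pb = {k for k, v in b.items() if v > 0}
    for length, tips in _branch_sets(tree):
        in_a = bool(tips & pa)
        in_b = bool(tips & pb)
        if in_a and in_b:
            shared += length
        elif in_a or in_b:
            unique += length
    return unique / (unique + shared)


def oracle_weighted(a, b, tree, normalized=True):
    ta, tb = sum(a.values()), sum(b.values())
    num = den = 0.0
    for length, tips in _branch_sets(tree):
        fa = sum(a.get(t, 0) for t in tips) / ta
        fb = sum(b.get(t, 0) for t in tips) / tb
        num += length * abs(fa - fb)
        den += length * (fa + fb)
    return num / den if normalized else num


def _random_communities(rng, ids):
    a = {i: int(rng.integers(0, 5)) for i in ids}
    b = {i: int(rng.integers(0, 5)) for i in ids}
    if sum(a.values()) == 0:
        a[ids[0]] = 1
    if sum(b.values()) == 0:
        b[ids[-1]] = 1
    return a, b


def test_unifrac_identity_and_disjoint_extremes():
    tree = generate_random_tree(list("abcd"), seed=2)
    comm = {"a": 3, "b": 1, "c": 0, "d": 0}
    assert unweighted_unifrac(comm, comm, tree) == 0.0
    assert weighted_unifrac(comm, comm, tree) == pytest.approx(0.0, abs=1e-12)
    # 2-leaf tree with disjoint mass
    two = generate_random_tree(["x", "y"], seed=0)
    assert unweighted_unifrac({"x": 1}, {"y": 1}, two) == 1.0
    assert weighted_unifrac({"x": 1, "y": 0}, {"x": 0, "y": 1}, two) == pytest.approx(1.0)


@pytest.mark.parametrize("seed", range(8))
def test_unifrac_matches_branch_enumeration_oracle(seed):
    rng = np.random.default_rng(seed)
    ids = [f"t{i}" for i in range(5)]
    tree = generate_random_tree(ids, seed=seed + 100)
    a, b = _random_communities(rng, ids)
    assert unweighted_unifrac(a, b, tree) == pytest.approx(
        oracle_unweighted(a, b, tree), abs=1e-12
    )
    assert weighted_unifrac(a, b, tree) == pytest.approx(
        oracle_weighted(a, b, tree), abs=1e-12
    )
    assert weighted_unifrac(a, b, tree, normalized=False) == pytest.approx(
        oracle_weighted(a, b, tree, normalized=False), abs=1e-12
    )


def test_unweighted_unifrac_metric_axioms():
    rng = np.random.default_rng(77)
    ids = [f"t{i}" for i in range(5)]
    tree = generate_random_tree(ids, seed=7)
    comms = []
    while len(comms) < 4:
        c, _ = _random_communities(rng, ids)
        if sum(c.values()) > 0:
            comms.append(c)
    d = {}
    for i, j in itertools.combinations(range(4), 2):
        dij = unweighted_unifrac(comms[i], comms[j], tree)
        dji = unweighted_unifrac(comms[j], comms[i], tree)
        assert dij == pytest.approx(dji, abs=1e-12)  # symmetry
        d[(i, j)] = d[(j, i)] = dij
    for i in range(4):
        d[(i, i)] = unweighted_unifrac(comms[i], comms[i], tree)
        assert d[(i, i)] == 0.0
    for i, j, k in itertools.permutations(range(4), 3):
        assert d[(i, k)] <= d[(i, j)] + d[(j, k)] + 1e-12


def test_weighted_unifrac_scale_invariance_and_bounds():
    rng = np.random.default_rng(5)
    ids = [f"t{i}" for i in range(6)]
    tree = generate_random_tree(ids, seed=9)
    a, b = _random_communities(rng, ids)
    d1 = weighted_unifrac(a, b, tree)
    scaled = {k: 7 * v for k, v in a.items()}
    assert weighted_unifrac(scaled, b, tree) == pytest.approx(d1, abs=1e-12)
    assert 0.0 <= d1 <= 1.0


def test_distance_matrix_agrees_with_skbio():
    from skbio.diversity import beta_diversity

    rng = np.random.default_rng(3)
    ids = [f"t{i}" for i in range(8)]
    tree = generate_random_tree(ids, seed=31)
    mat = rng.integers(0, 20, size=(5, 8))
    mat[mat.sum(axis=1) == 0, 0] = 1
    counts = CountTable(pd.DataFrame(mat, index=[f"S{i}" for i in range(5)], columns=ids))

    ours_u = beta_distance_matrix(counts, "unweighted_unifrac", tree=tree)
    ref_u = beta_diversity("unweighted_unifrac", mat, ids=counts.sample_ids,
                           taxa=ids, tree=tree)
    np.testing.assert_allclose(ours_u.data, ref_u.data, atol=1e-10)

    ours_w = beta_distance_matrix(counts, "weighted_unifrac", tree=tree)
    ref_w = beta_diversity("weighted_unifrac", mat, ids=counts.sample_ids,
                           taxa=ids, tree=tree, normalized=True)
    np.testing.assert_allclose(ours_w.data, ref_w.data, atol=1e-10)


def test_distance_matrix_duplicate_rows_give_zero():
    counts = CountTable(
        pd.DataFrame([[3, 1], [3, 1]], index=["S1", "S2"], columns=["a", "b"])
    )
    tree = generate_random_tree(["a", "b"], seed=1)
    for metric in ("unweighted_unifrac", "weighted_unifrac"):
        dm = beta_distance_matrix(counts, metric, tree=tree)
        assert dm[("S1", "S2")] == pytest.approx(0.0, abs=1e-12)
    with pytest.raises(ValueError, match="tree"):
        beta_distance_matrix(counts, "weighted_unifrac")


# --------------------------------------------------------------------
# PERMANOVA
# --------------------------------------------------------------------

def _random_euclidean_dm(rng, n):
    pts = rng.normal(size=(n, 3))
    d = np.sqrt(((pts[:, None, :] - pts[None, :, :]) ** 2).sum(-1))
    return DistanceMatrix(d, [f"S{i}" for i in range(n)])


def _meta(groups):
    return pd.DataFrame({"group": groups}, index=[f"S{i}" for i in range(len(groups))])


def test_single_factor_ss_matches_direct_formula():
    """SS decomposition equals the pairwise within/total d^2 formulas."""
    rng = np.random.default_rng(12)
    for _ in range(5):
        dm = _random_euclidean_dm(rng, 8)
        groups = ["a"] * 4 + ["b"] * 4
        res = permanova(dm, _meta(groups), ["group"], n_permutations=9, seed=0)[0]
        d2 = np.asarray(dm.data) ** 2
        n = 8
        ss_total = d2[np.triu_indices(n, 1)].sum() / n
        ss_within = 0.0
        for g in ("a", "b"):
            idx = [i for i, x in enumerate(groups) if x == g]
            sub = d2[np.ix_(idx, idx)]
            ss_within += sub[np.triu_indices(len(idx), 1)].sum() / len(idx)
        assert res.ss == pytest.approx(ss_total - ss_within, abs=1e-10)
        assert res.R2 == pytest.approx((ss_total - ss_within) / ss_total, abs=1e-10)


def test_sequential_ss_plus_residual_equals_total():
    rng = np.random.default_rng(8)
    dm = _random_euclidean_dm(rng, 12)
    meta = pd.DataFrame(
        {
            "group": rng.choice(["a", "b"], 12),
            "covar": rng.normal(size=12),
            "cat3": rng.choice(["x", "y", "z"], 12),
        },
        index=list(dm.ids),
    )
    res = permanova(dm, meta, ["cat3", "covar", "group"], n_permutations=9, seed=0)
    G_trace = sum(r.ss for r in res) / sum(r.R2 for r in res)
    ss_resid = G_trace - sum(r.ss for r in res)
    # recompute residual directly from F and df
    df_resid = 12 - 1 - sum(r.df for r in res)
    for r in res:
        assert r.pseudo_F == pytest.approx((r.ss / r.df) / (ss_resid / df_resid), rel=1e-8)
    assert sum(r.R2 for r in res) <= 1.0 + 1e-8


def test_exact_permutation_p_matches_group_relabel_enumeration():
    """n=6, 3+3: sampler in exact mode equals enumeration over the 20 labelings."""
    rng = np.random.default_rng(42)
    dm = _random_euclidean_dm(rng, 6)
    groups = ["a", "a", "a", "b", "b", "b"]
    obs = permanova(dm, _meta(groups), ["group"], permutations="exact")[0]

    f_values = []
    for idx_a in itertools.combinations(range(6), 3):
        labels = ["b"] * 6
        for i in idx_a:
            labels[i] = "a"
        f = permanova(dm, _meta(labels), ["group"], n_permutations=1, seed=0)[0].pseudo_F
        f_values.append(f)
    p_exact = np.mean([f >= obs.pseudo_F - 1e-12 for f in f_values])
    assert obs.p == pytest.approx(p_exact, abs=1e-12)


def test_permanova_agrees_with_skbio_single_factor():
    rng = np.random.default_rng(23)
    dm = _random_euclidean_dm(rng, 10)
    groups = ["a"] * 5 + ["b"] * 5
    ours = permanova(dm, _meta(groups), ["group"], n_permutations=99, seed=1)[0]
    grouping = pd.DataFrame({"group": groups}, index=list(dm.ids))
    ref = skbio_permanova(dm, grouping, column="group", permutations=99)
    assert ours.pseudo_F == pytest.approx(ref["test statistic"], rel=1e-10)


def test_permanova_null_labels_near_uniform_p():
    rng = np.random.default_rng(6)
    dm = _random_euclidean_dm(rng, 20)
    groups = rng.permutation(["a"] * 10 + ["b"] * 10)
    res = permanova(dm, _meta(list(groups)), ["group"], n_permutations=199, seed=3)[0]
    assert res.R2 < 0.25
    assert res.p > 0.05


# --------------------------------------------------------------------
# rank comparisons
# --------------------------------------------------------------------

def test_rank_compare_examples():
    u, p = rank_compare([1, 2], [3, 4])
    assert min(u, 4 - u) == 0.0  # all y exceed all x
    u, p = rank_compare([1.0, 1.0], [1.0, 1.0])
    assert u == 2.0 and p == 1.0
    x = [1, 2, 3, 4, 5]
    u, p = rank_compare(x, x)
    assert u == pytest.approx(len(x) ** 2 / 2)
    assert p > 0.9
    h, p = kruskal_compare([1, 2], [1, 2], [1, 2])
    assert h == pytest.approx(0.0, abs=1e-12)
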