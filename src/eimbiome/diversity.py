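"""Alpha diversity, UniFrac beta diversity and PERMANOVA.

UniFrac and the PERMANOVA sum-of-squares machinery are computed
directly from their definitions (per-branch summation over the
phylogeny; Gower-centred inner-product partitioning with sequential
hat-matrix projections) rather than delegated, so every quantity can be
audited against brute-force oracles on small trees and designs.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.stats
from scipy.spatial.distance import pdist, squareform
from skbio import DistanceMatrix, TreeNode

from .containers import CountTable

__all__ = [
    "alpha_diversity",
    "unweighted_unifrac",
    "weighted_unifrac",
    "beta_distance_matrix",
    "permanova",
    "PermanovaResult",
    "rank_compare",
    "kruskal_compare",
]


# --------------------------------------------------------------------
# alpha diversity
# --------------------------------------------------------------------

def alpha_diversity(counts: CountTable) -> pd.DataFrame:
    """Observed richness, Shannon entropy (nats) and Pielou's evenness.

    Shannon uses the natural log so that J = H / ln(S) exactly; J is
    reported as NaN for single-ASV samples, where evenness is undefined.
    """
    frac = counts.relative_abundance().to_numpy()
    observed = (frac > 0).sum(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        plogp = np.where(frac > 0, frac * np.log(frac), 0.0)
    shannon = -plogp.sum(axis=1)
    pielou = np.where(observed > 1, shannon / np.log(np.maximum(observed, 2)), np.nan)
    return pd.DataFrame(
        {"observed_richness": observed, "shannon": shannon, "pielou_evenness": pielou},
        index=counts.data.index,
    )


# --------------------------------------------------------------------
# UniFrac
# --------------------------------------------------------------------

def _branch_profile(tree: TreeNode, table: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
    """Per-branch descendant mass for every sample.

    Returns ``(lengths, mass)`` where ``lengths`` has one entry per
    non-root branch and ``mass[b, i]`` is the total count in sample
    ``i`` descending through branch ``b``.  ASVs with any count must be
    tips of the tree; extra tips carry zero mass and are harmless.
    """
    tip_names = {t.name for t in tree.tips()}
    present = table.columns[(table > 0).any(axis=0)]
    missing = set(present) - tip_names
    if missing:
        raise ValueError(f"ASV(s) present in counts but absent from tree: {sorted(missing)[:5]}")

    col_index = {c: j for j, c in enumerate(table.columns)}
    values = table.to_numpy(float)
    n = values.shape[0]
    lengths: list[float] = []
    masses: list[np.ndarray] = []
    node_mass: dict[int, np.ndarray] = {}
    for node in tree.postorder(include_self=True):
        if node.is_tip():
            j = col_index.get(node.name)
            vec = values[:, j].copy() if j is not None else np.zeros(n)
        else:
            vec = np.zeros(n)
            for child in node.children:
                vec += node_mass.pop(id(child))
        node_mass[id(node)] = vec
        if node is not tree:
            lengths.append(float(node.length or 0.0))
            masses.append(vec)
    return np.asarray(lengths), np.asarray(masses)


def _pair_table(a, b, tree: TreeNode) -> pd.DataFrame:
    names = [t.name for t in tree.tips()]
    df = pd.DataFrame(0.0, index=["a", "b"], columns=names)
    for row, comm in (("a", a), ("b", b)):
        comm = pd.Series(comm, dtype=float)
        extra = set(comm.index[comm > 0]) - set(names)
        if extra:
            raise ValueError(f"community ASV(s) not in tree: {sorted(extra)[:5]}")
        df.loc[row, comm.index.intersection(names)] = comm.reindex(names).fillna(0.0)
    return df


def unweighted_unifrac(a, b, tree: TreeNode) -> float:
    """Fraction of branch length leading to ASVs unique to one community.

    ``a`` and ``b`` are count vectors indexed by ASV id (dict, Series).
    Presence is count > 0.
    """
    table = _pair_table(a, b, tree)
    lengths, mass = _branch_profile(tree, table)
    pa, pb = mass[:, 0] > 0, mass[:, 1] > 0
    union = lengths[pa | pb].sum()
    if union == 0:
        raise ValueError("both communities are empty")
    unique = lengths[pa ^ pb].sum()
    return float(unique / union)


def weighted_unifrac(a, b, tree: TreeNode, normalized: bool = True) -> float:
    """Abundance-weighted UniFrac: sum over branches of l_b * |p_a - p_b|.

    ``p_x`` is the fraction of community ``x`` descending through the
    branch.  The normalized variant divides by sum of l_b * (p_a + p_b)
    and lies in [0, 1].
    """
    table = _pair_table(a, b, tree)
    totals = table.sum(axis=1)
    if (totals == 0).any():
        raise ValueError("zero-total community")
    lengths, mass = _branch_profile(tree, table)
    fa = mass[:, 0] / totals.iloc[0]
    fb = mass[:, 1] / totals.iloc[1]
    raw = float((lengths * np.abs(fa - fb)).sum())
    if not normalized:
        return raw
    denom = float((lengths * (fa + fb)).sum())
    return raw / denom if denom > 0 else 0.0


def beta_distance_matrix(
    counts: CountTable,
    metric: str = "weighted_unifrac",
    tree: TreeNode | None = None,
    normalized: bool = True,
) -> DistanceMatrix:
    """All-pairs distance matrix for a count table.

    ``metric`` is one of ``unweighted_unifrac``, ``weighted_unifrac``
    or ``bray_curtis``; the UniFrac metrics require ``tree``.
    """
    ids = counts.sample_ids
    if metric == "bray_curtis":
        dm = squareform(pdist(counts.data.to_numpy(float), metric="braycurtis"))
        return DistanceMatrix(dm, ids)
    if metric not in ("unweighted_unifrac", "weighted_unifrac"):
        raise ValueError(f"unknown metric {metric!r}")
    if tree is None:
        raise ValueError("UniFrac metrics require a phylogenetic tree")
    lengths, mass = _branch_profile(tree, counts.data)
    n = len(ids)
    out = np.zeros((n, n))
    if metric == "unweighted_unifrac":
        present = mass > 0
        for i, j in itertools.combinations(range(n), 2):
            pa, pb = present[:, i], present[:, j]
            union = lengths[pa | pb].sum()
            out[i, j] = out[j, i] = lengths[pa ^ pb].sum() / union if union > 0 else 0.0
    else:
        totals = counts.data.sum(axis=1).to_numpy(float)
        if np.any(totals == 0):
            raise ValueError("zero-total community in weighted UniFrac")
        frac = mass / totals
        for i, j in itertools.combinations(range(n), 2):
            diff = float((lengths * np.abs(frac[:, i] - frac[:, j])).sum())
            if normalized:
                denom = float((lengths * (frac[:, i] + frac[:, j])).sum())
                diff = diff / denom if denom > 0 else 0.0
            out[i, j] = out[j, i] = diff
    return DistanceMatrix(out, ids)


# --------------------------------------------------------------------
# PERMANOVA
# --------------------------------------------------------------------

@dataclass
class PermanovaResult:
    term: str
    df: int
    ss: float
    pseudo_F: float
    R2: float
    p: float
    n_permutations: int
    negative_eigenvalue_warning: bool = False


def _design_columns(meta: pd.DataFrame, term: str) -> np.ndarray:
    col = meta[term]
    if col.dtype == bool:
        return col.to_numpy(float).reshape(-1, 1)
    if col.dtype.kind in "ifu":
        return col.to_numpy(float).reshape(-1, 1)
    dummies = pd.get_dummies(col.astype("category"), drop_first=True)
    return dummies.to_numpy(float)


def _hat_traces(G: np.ndarray, qs: list[np.ndarray]) -> list[float]:
    """tr(H_k G) for each nested design's orthonormal basis Q_k."""
    return [float(np.sum(q * (G @ q))) for q in qs]


def permanova(
    dm: DistanceMatrix,
    meta: pd.DataFrame,
    terms: list[str],
    n_permutations: int = 999,
    seed: int = 0,
    permutations: str = "sample",
) -> list[PermanovaResult]:
    """Sequential (Type-I) PERMANOVA of a distance matrix on metadata terms.

    The squared distances are Gower-centred, G = -1/2 * C D^2 C, and the
    sum of squares of each term is the increment in tr(H G) between
    nested hat matrices built in the order the terms are given; the
    residual is tr(G) - tr(H_full G).  p-values permute raw sample
    identities, p = (1 + #{F >= F_obs}) / (1 + n_permutations).  With
    ``permutations="exact"`` every permutation is enumerated (small n
    only) and p = #{F >= F_obs} / n! with the identity included.
    """
    ids = list(dm.ids)
    if set(ids) != set(meta.index):
        raise ValueError("distance matrix and metadata sample sets differ")
    meta = meta.loc[ids]
    n = len(ids)
    D2 = np.asarray(dm.data, float) ** 2
    C = np.eye(n) - np.ones((n, n)) / n
    G = -0.5 * C @ D2 @ C

    blocks = [np.ones((n, 1))]
    dfs: list[int] = []
    for term in terms:
        if term not in meta.columns:
            raise ValueError(f"term {term!r} not in metadata")
        cols = _design_columns(meta, term)
        blocks.append(cols)
        dfs.append(cols.shape[1])
    X_parts = [np.hstack(blocks[: k + 2]) for k in range(len(terms))]
    qs = []
    for X in X_parts:
        q, r = np.linalg.qr(X)
        rank = int(np.sum(np.abs(np.diag(r)) > 1e-10 * max(1.0, np.abs(r).max())))
        if rank < X.shape[1]:
            raise ValueError("singular design matrix (collinear terms)")
        qs.append(q)
    df_model = sum(dfs)
    df_resid = n - 1 - df_model
    if df_resid <= 0:
        raise ValueError("no residual degrees of freedom")

    def stats(Gmat: np.ndarray):
        traces = _hat_traces(Gmat, qs)
        ss_terms = []
        prev = float(np.ones(n) @ Gmat @ np.ones(n)) / n
        for t in traces:
            ss_terms.append(t - prev)
            prev = t
        ss_resid = float(np.trace(Gmat)) - traces[-1]
        fs = [
            (ss / df) / (ss_resid / df_resid) if ss_resid > 0 else np.inf
            for ss, df in zip(ss_terms, dfs)
        ]
        return ss_terms, ss_resid, fs

    ss_terms, ss_resid, f_obs = stats(G)
    total = float(np.trace(G))

    if permutations == "exact":
        if n > 8:
            raise ValueError("exact enumeration limited to n <= 8")
        counts_ge = [0] * len(terms)
        n_perm = 0
        for perm in itertools.permutations(range(n)):
            idx = np.asarray(perm)
            _, _, f_perm = stats(G[np.ix_(idx, idx)])
            for k, (fp, fo) in enumerate(zip(f_perm, f_obs)):
                if fp >= fo - 1e-12:
                    counts_ge[k] += 1
            n_perm += 1
        pvals = [c / n_perm for c in counts_ge]
    else:
        rng = np.random.default_rng(seed)
        counts_ge = [0] * len(terms)
        for _ in range(n_permutations):
            idx = rng.permutation(n)
            _, _, f_perm = stats(G[np.ix_(idx, idx)])
            for k, (fp, fo) in enumerate(zip(f_perm, f_obs)):
                if fp >= fo:
                    counts_ge[k] += 1
        pvals = [(1 + c) / (1 + n_permutations) for c in counts_ge]
        n_perm = n_permutations

    neg_warn = total < 0 or any(ss < -1e-8 for ss in ss_terms)
    return [
        PermanovaResult(
            term=term,
            df=df,
            ss=float(ss),
            pseudo_F=float(f),
            R2=float(ss / total) if total != 0 else np.nan,
            p=float(p),
            n_permutations=n_perm,
            negative_eigenvalue_warning=neg_warn,
        )
        for term, df, ss, f, p in zip(terms, dfs, ss_terms, f_obs, pvals)
    ]


# --------------------------------------------------------------------
# rank comparisons
# --------------------------------------------------------------------

def rank_compare(x, y) -> tuple[float, float]:
    """Two-sided Mann-Whitney U with tie-corrected normal approximation."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if len(x) == 0 or len(y) == 0:
        raise ValueError("both groups must be non-empty")
    combined = np.concatenate([x, y])
    if np.all(combined == combined[0]):
        return len(x) * len(y) / 2.0, 1.0
    res = scipy.stats.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic")
    return float(res.statistic), float(res.pvalue)


def kruskal_compare(*groups) -> tuple[float, float]:
    """Kruskal-Wallis H with chi-square p for k groups."""
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    combined = np.concatenate([np.asarray(g, float) for g in groups])
    if np.all(combined == combined[0]):
        return 0.0, 1.0
    res = scipy.stats.kruskal(*groups)
    return float(res.statistic), float(res.pvalue)
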