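"""SparCC compositional correlations, co-association modules and
module-phenotype logistic association.

Sequencing counts are compositional: only relative abundances are
observed, so naive Pearson correlations between fractions are biased.
SparCC estimates the linear correlations of the unobserved "basis"
abundances from the variation matrix T (pairwise variances of
log-ratios) under a sparsity assumption: most pairs are uncorrelated,
so the basis variances solve the linear system

    t = G w,   t_i = sum_{j != i} T_ij,   G = (D - 2) I + 1 1',

and rho_ij = (w_i + w_j - T_ij) / (2 sqrt(w_i w_j)).  Strongly
correlated pairs violate the assumption, so the pair with the largest
|rho| above an exclusion threshold is iteratively removed from the
system and the basis re-solved.

Modules are the connected components (size >= 2) of the graph with an
edge wherever rho >= 0.5 (signed by default).  Each module's summed
relative abundance is related to the binary EIM phenotype with a
logistic regression on the standardised log10 abundance.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from scipy.stats import norm

from .containers import GROUP_CASE, CountTable, validate_metadata

__all__ = [
    "estimate_fractions",
    "variation_matrix",
    "sparcc",
    "ModuleSet",
    "detect_modules",
    "module_abundance",
    "logistic_fit",
    "ModuleAssociation",
    "associate_modules",
]


def estimate_fractions(counts: CountTable, method: str = "mean",
                       seed: int | None = None) -> pd.DataFrame:
    """Per-sample component fractions with a uniform Dirichlet prior.

    The default is the deterministic posterior mean
    (count + 1) / (depth + D); ``method="draw"`` samples one Dirichlet
    realisation instead (seeded), matching the original stochastic
    procedure.
    """
    depths = counts.depths()
    if (depths == 0).any():
        raise ValueError(f"zero-depth sample(s): {list(depths.index[depths == 0])}")
    d = counts.n_asvs
    if method == "mean":
        frac = (counts.data + 1).div(depths + d, axis=0)
    elif method == "draw":
        rng = np.random.default_rng(seed)
        frac = pd.DataFrame(
            np.vstack([rng.dirichlet(row + 1) for row in counts.data.to_numpy()]),
            index=counts.data.index, columns=counts.data.columns,
        )
    else:
        raise ValueError(f"unknown method {method!r}")
    return frac


def variation_matrix(fractions: pd.DataFrame) -> pd.DataFrame:
    """T_ij = sample variance (ddof=1) of log(f_i / f_j)."""
    if len(fractions) < 3:
        raise ValueError("need at least 3 samples for the variation matrix")
    vals = fractions.to_numpy(float)
    if np.any(vals <= 0):
        raise ValueError("fractions must be strictly positive (apply pseudocount upstream)")
    logf = np.log(vals)
    n, d = logf.shape
    # var(x_i - x_j) = var_i + var_j - 2 cov_ij
    cov = np.cov(logf, rowvar=False, ddof=1).reshape(d, d)
    v = np.diag(cov)
    T = v[:, None] + v[None, :] - 2.0 * cov
    np.fill_diagonal(T, 0.0)
    T = np.maximum(T, 0.0)
    return pd.DataFrame(T, index=fractions.columns, columns=fractions.columns)


def sparcc(
    counts: CountTable,
    exclusion_threshold: float = 0.1,
    max_exclusions: int = 10,
    fraction_method: str = "mean",
    seed: int | None = None,
) -> pd.DataFrame:
    """Basis correlation matrix rho (ASV x ASV) via SparCC.

    ``exclusion_threshold`` and ``max_exclusions`` control the
    iterative removal of strongly correlated pairs from the sparsity
    system.  Requires at least 4 ASVs (the basis system is
    underdetermined below that).
    """
    d = counts.n_asvs
    if d < 4:
        raise ValueError("basis system underdetermined: need >= 4 ASVs")
    frac = estimate_fractions(counts, method=fraction_method, seed=seed)
    Tdf = variation_matrix(frac)
    T = Tdf.to_numpy()

    # mask of pairs still inside the sparsity system (off-diagonal)
    inside = ~np.eye(d, dtype=bool)
    excluded: set[tuple[int, int]] = set()
    warn_clamped = False

    def solve(inside_mask: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        nonlocal warn_clamped
        counts_in = inside_mask.sum(axis=1).astype(float)
        M = np.ones((d, d)) * inside_mask  # off-diagonal 1s where pair in system
        # t_i ~ counts_in * w_i + sum_{j in system} w_j, i.e. (D-2)I + 11'
        # when nothing is excluded; exclusions decrement the entries
        np.fill_diagonal(M, counts_in)
        t = (T * inside_mask).sum(axis=1)
        w = np.linalg.solve(M, t)
        if np.any(w <= 0):
            warn_clamped = True
            w = np.maximum(w, 1e-10)
        sw = np.sqrt(w)
        rho = (w[:, None] + w[None, :] - T) / (2.0 * np.outer(sw, sw))
        rho = np.clip(rho, -1.0, 1.0)
        np.fill_diagonal(rho, 1.0)
        return w, rho

    _, rho = solve(inside)
    for _ in range(max_exclusions):
        cand = np.abs(rho).copy()
        cand[~inside] = 0.0
        np.fill_diagonal(cand, 0.0)
        for i, j in excluded:
            cand[i, j] = cand[j, i] = 0.0
        i, j = np.unravel_index(np.argmax(cand), cand.shape)
        if cand[i, j] < exclusion_threshold:
            break
        excluded.add((min(i, j), max(i, j)))
        inside[i, j] = inside[j, i] = False
        _, rho = solve(inside)

    out = pd.DataFrame(rho, index=Tdf.index, columns=Tdf.columns)
    out.attrs["excluded_pairs"] = sorted(excluded)
    out.attrs["clamped_variance"] = warn_clamped
    return out


@dataclass
class ModuleSet:
    """Disjoint sets of co-associated ASVs found at a threshold."""

    modules: list[set[str]]
    threshold: float

    def __len__(self) -> int:
        return len(self.modules)

    def membership(self) -> dict[str, int]:
        return {a: k for k, mod in enumerate(self.modules) for a in mod}


def detect_modules(
    rho: pd.DataFrame, threshold: float = 0.5, absolute: bool = False
) -> ModuleSet:
    """Connected components (size >= 2) of the thresholded correlation graph.

    An edge joins i and j when rho_ij >= threshold (or
    |rho_ij| >= threshold with ``absolute=True``).  Components are
    returned largest-first, ties broken by first member id.
    """
    ids = list(rho.index)
    vals = rho.to_numpy()
    adj = (np.abs(vals) if absolute else vals) >= threshold
    np.fill_diagonal(adj, False)
    g = nx.from_numpy_array(adj)
    comps = [
        {ids[i] for i in comp}
        for comp in nx.connected_components(g)
        if len(comp) >= 2
    ]
    comps.sort(key=lambda c: (-len(c), min(c)))
    return ModuleSet(comps, threshold)


def module_abundance(counts: CountTable, modules: ModuleSet) -> pd.DataFrame:
    """Sample x module matrix of summed member relative abundances."""
    if len(modules) == 0:
        return pd.DataFrame(index=counts.data.index)
    frac = counts.relative_abundance()
    cols = {}
    for k, members in enumerate(modules.modules):
        unknown = members - set(counts.asv_ids)
        if unknown:
            raise ValueError(f"module member(s) not in counts: {sorted(unknown)[:5]}")
        cols[f"module_{k + 1}"] = frac[sorted(members)].sum(axis=1)
    return pd.DataFrame(cols, index=counts.data.index)


def logistic_fit(y, x, tol: float = 1e-10, max_iter: int = 100):
    """Intercept + slope logistic regression by IRLS.

    Returns ``(slope, se, p)``; on complete separation (diverging
    slope) the fit is flagged by returning ``p = nan``.
    """
    y = np.asarray(y, float)
    x = np.asarray(x, float)
    classes = np.unique(y)
    if not np.all(np.isin(classes, [0.0, 1.0])) or len(classes) < 2:
        raise ValueError("outcome must contain both classes coded 0/1")
    X = np.column_stack([np.ones_like(x), x])
    if np.allclose(x, x[0]):
        # constant predictor: slope is exactly 0, no information
        return 0.0, np.inf, 1.0
    beta = np.zeros(2)
    separated = False
    for _ in range(max_iter):
        eta = np.clip(X @ beta, -35, 35)
        p_hat = 1.0 / (1.0 + np.exp(-eta))
        W = p_hat * (1.0 - p_hat)
        grad = X.T @ (y - p_hat)
        H = (X * W[:, None]).T @ X
        try:
            step = np.linalg.solve(H, grad)
        except np.linalg.LinAlgError:
            separated = True
            break
        beta = beta + step
        if abs(beta[1]) > 30:
            separated = True
            break
        p_new = 1.0 / (1.0 + np.exp(-np.clip(X @ beta, -35, 35)))
        if np.all(np.abs(y - p_new) < 1e-6):
            # fitted probabilities are exactly the outcomes: separation
            separated = True
            break
        if np.linalg.norm(X.T @ (y - p_new)) < tol:
            break
    else:
        separated = abs(beta[1]) > 15
    eta = np.clip(X @ beta, -35, 35)
    p_hat = 1.0 / (1.0 + np.exp(-eta))
    W = p_hat * (1.0 - p_hat)
    H = (X * W[:, None]).T @ X
    try:
        cov = np.linalg.inv(H)
        se = float(np.sqrt(max(cov[1, 1], 0.0)))
    except np.linalg.LinAlgError:
        se = np.nan
    slope = float(beta[1])
    if separated or not np.isfinite(se) or se == 0:
        return slope, np.nan, np.nan
    p = float(2.0 * norm.sf(abs(slope) / se))
    return slope, se, p


@dataclass
class ModuleAssociation:
    module_id: str
    size: int
    slope: float
    se: float
    p: float
    direction: str  # enriched | depleted


def associate_modules(
    module_abund: pd.DataFrame, meta: pd.DataFrame
) -> list[ModuleAssociation]:
    """Logistic association of each module with the EIM phenotype.

    The predictor is log10(module abundance + half the module's
    smallest nonzero abundance), standardised to unit variance, so
    slopes are log-odds per SD of log abundance.  Results are sorted by
    ascending p.
    """
    meta = validate_metadata(meta)
    meta = meta.loc[module_abund.index]
    if meta["is_negative_control"].any():
        raise ValueError("module association expects biological samples only")
    y = (meta["group"] == GROUP_CASE).to_numpy(float)
    out: list[ModuleAssociation] = []
    sizes = module_abund.attrs.get("module_sizes", {})
    for col in module_abund.columns:
        ab = module_abund[col].to_numpy(float)
        nonzero = ab[ab > 0]
        pseudo = nonzero.min() / 2.0 if len(nonzero) else 1e-6
        x = np.log10(ab + pseudo)
        sd = x.std(ddof=1)
        if sd > 0:
            x = (x - x.mean()) / sd
        slope, se, p = logistic_fit(y, x)
        out.append(
            ModuleAssociation(
                module_id=col,
                size=int(sizes.get(col, 0)),
                slope=slope,
                se=se,
                p=p,
                direction="depleted" if slope < 0 else "enriched",
            )
        )
    out.sort(key=lambda r: (np.isnan(r.p), r.p))
    return out
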