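"""Multi-model differential abundance with AIC selection.

Each ASV's counts are fit with four candidate models on the *same*
response (raw counts), so their AIC values are directly comparable:

* gaussian identity-link linear model (no library-size term),
* Poisson log-link GLM with a log-depth offset,
* negative binomial (NB2) log-link GLM with offset, dispersion by
  profiled maximum likelihood,
* zero-inflated negative binomial: NB count part with offset plus an
  intercept-only logit zero part, fit by expectation-maximization.

The converged fit with minimal AIC supplies the group-effect estimate
and a two-sided Wald p-value; p-values are Benjamini-Hochberg adjusted
across ASVs and results are filtered on q < 0.05 and |log2 FC| > 1.

AIC = -2*loglik + 2*n_params, where n_params counts every estimated
quantity (gaussian: p+1 incl. the variance; poisson: p; negbin: p+1
incl. dispersion; zinb: p+2 incl. dispersion and the zero-inflation
intercept).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar
from scipy.special import gammaln
from scipy.stats import norm
from scipy.stats import t as scipy_t

from .containers import GROUP_CASE, CountTable, validate_metadata

__all__ = [
    "ModelFit",
    "fit_candidate_models",
    "select_model",
    "differential_abundance",
    "bh_adjust",
    "effect_filter",
]

_MODEL_ORDER = ("poisson", "negbin", "zinb", "gaussian")  # tie-break order
_ETA_MAX = 30.0
_ALPHA_LOG_BOUNDS = (-12.0, 8.0)


@dataclass
class ModelFit:
    """One candidate model's fit for a single ASV."""

    model: str
    coefficients: dict[str, float]
    se: dict[str, float]
    loglik: float
    n_params: int
    converged: bool
    extra: dict[str, float] = field(default_factory=dict)
    #: sandwich (robust) standard errors; calibrated under variance
    #: misspecification, used for the reported Wald tests
    robust_se: dict[str, float] = field(default_factory=dict)
    #: residual degrees of freedom for the t reference of Wald tests
    df_resid: int = 0
    #: per-term Satterthwaite df of the sandwich variance estimate
    robust_df: dict[str, float] = field(default_factory=dict)

    @property
    def aic(self) -> float:
        return -2.0 * self.loglik + 2.0 * self.n_params

    def wald_p(self, term: str, robust: bool = True) -> float:
        if term not in self.coefficients:
            return np.nan
        source = self.robust_se if robust and self.robust_se else self.se
        se = source.get(term, np.nan)
        if not np.isfinite(se) or se <= 0:
            return np.nan
        z = self.coefficients[term] / se
        if robust and term in self.robust_df:
            df = self.robust_df[term]
        else:
            df = self.df_resid
        if df > 0:
            return float(2.0 * scipy_t.sf(abs(z), df))
        return float(2.0 * norm.sf(abs(z)))


# --------------------------------------------------------------------
# likelihoods
# --------------------------------------------------------------------

def _poisson_loglik(y: np.ndarray, mu: np.ndarray) -> float:
    return float(np.sum(y * np.log(mu) - mu - gammaln(y + 1)))


def _nb_loglik_terms(y: np.ndarray, mu: np.ndarray, alpha: float) -> np.ndarray:
    k = 1.0 / alpha
    return (
        gammaln(y + k)
        - gammaln(k)
        - gammaln(y + 1)
        + k * np.log(k / (k + mu))
        + y * np.log(mu / (k + mu))
    )


def _nb_zero_prob(mu: np.ndarray, alpha: float) -> np.ndarray:
    k = 1.0 / alpha
    return np.exp(k * np.log(k / (k + mu)))


# --------------------------------------------------------------------
# individual fitters
# --------------------------------------------------------------------

def _sandwich_se(
    X: np.ndarray, A: np.ndarray, s: np.ndarray, w: np.ndarray | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """HC3 sandwich SEs with Satterthwaite df, per coefficient.

    Per-observation scores are x_i s_i; ``w`` are the IRLS working
    weights defining the hat values h_i = w_i x_i' A^-1 x_i (w = 1 for
    least squares).  Scores are leverage-adjusted (HC3).  The variance
    of coefficient j is the sum of squared per-observation influences
    g_ji; its Satterthwaite degrees of freedom,
    (sum g^2)^2 / sum g^4, shrink when a few heavy-tailed observations
    dominate the variance estimate, widening the t reference
    accordingly.  Returns ``(se, df)`` arrays.
    """
    a_inv = np.linalg.pinv(A)
    if w is None:
        w = np.ones(len(s))
    h = np.clip(np.sum((X @ a_inv) * X, axis=1) * w, 0.0, 0.99)
    s_adj = s / (1.0 - h)
    influence = (X @ a_inv) * s_adj[:, None]  # n x p, per-obs effect on beta
    u = influence**2
    var = u.sum(axis=0)
    se = np.sqrt(np.maximum(var, 0.0))
    # Satterthwaite df of the variance estimate, moment-corrected by 3
    # (E[u^2] = 3 sigma^4 for Gaussian influences, so the raw ratio
    # underestimates df threefold on well-behaved data); capped at the
    # residual df
    n, p = X.shape
    with np.errstate(divide="ignore", invalid="ignore"):
        df = 3.0 * var**2 / (u**2).sum(axis=0)
    df = np.where(np.isfinite(df) & (df >= 1.0), df, 1.0)
    df = np.minimum(df, max(n - p, 1))
    return se, df


def _fit_gaussian(y: np.ndarray, X: np.ndarray, names: list[str]) -> ModelFit:
    n, p = X.shape
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    rss = float(resid @ resid)
    sigma2_mle = max(rss / n, 1e-12)
    loglik = -0.5 * n * (np.log(2.0 * np.pi * sigma2_mle) + 1.0)
    sigma2_ub = rss / max(n - p, 1)
    xtx_inv = np.linalg.pinv(X.T @ X)
    se = np.sqrt(np.maximum(sigma2_ub * np.diag(xtx_inv), 0.0))
    rse, rdf = _sandwich_se(X, X.T @ X, resid)
    return ModelFit(
        "gaussian", dict(zip(names, beta)), dict(zip(names, se)),
        loglik, p + 1, True, robust_se=dict(zip(names, rse)),
        df_resid=max(n - p, 1), robust_df=dict(zip(names, rdf)),
    )


def _irls_poisson(
    y: np.ndarray, X: np.ndarray, offset: np.ndarray,
    prior_weights: np.ndarray | None = None,
    beta0: np.ndarray | None = None,
    tol: float = 1e-10, max_iter: int = 50,
) -> tuple[np.ndarray, np.ndarray, bool]:
    """Weighted Poisson IRLS; returns (beta, mu, converged)."""
    n, p = X.shape
    w0 = np.ones(n) if prior_weights is None else prior_weights
    if beta0 is None:
        beta = np.zeros(p)
        base = np.average(y, weights=np.maximum(w0, 1e-12))
        beta[0] = np.log(max(base, 0.1)) - np.average(offset, weights=np.maximum(w0, 1e-12))
    else:
        beta = beta0.copy()
    ll_old = -np.inf
    converged = False
    for _ in range(max_iter):
        eta = np.clip(X @ beta + offset, -_ETA_MAX, _ETA_MAX)
        mu = np.exp(eta)
        W = w0 * mu
        z = eta - offset + (y - mu) / mu
        sw = np.sqrt(W)
        beta_new, *_ = np.linalg.lstsq(X * sw[:, None], z * sw, rcond=None)
        beta = beta_new
        eta = np.clip(X @ beta + offset, -_ETA_MAX, _ETA_MAX)
        mu = np.exp(eta)
        ll = float(np.sum(w0 * (y * np.log(mu) - mu)))
        if abs(ll - ll_old) < tol * (1.0 + abs(ll)):
            converged = True
            break
        ll_old = ll
    return beta, mu, converged


def _fit_poisson(
    y: np.ndarray, X: np.ndarray, offset: np.ndarray, names: list[str]
) -> ModelFit:
    beta, mu, converged = _irls_poisson(y, X, offset)
    A = (X * mu[:, None]).T @ X
    cov = np.linalg.pinv(A)
    se = np.sqrt(np.maximum(np.diag(cov), 0.0))
    rse, rdf = _sandwich_se(X, A, y - mu, w=mu)
    loglik = _poisson_loglik(y, mu)
    return ModelFit(
        "poisson", dict(zip(names, beta)), dict(zip(names, se)),
        loglik, X.shape[1], converged, robust_se=dict(zip(names, rse)),
        df_resid=max(len(y) - X.shape[1], 1), robust_df=dict(zip(names, rdf)),
    )


def _nb_irls(
    y: np.ndarray, X: np.ndarray, offset: np.ndarray, alpha: float,
    beta0: np.ndarray, prior_weights: np.ndarray | None = None,
    max_iter: int = 25, tol: float = 1e-10,
) -> tuple[np.ndarray, np.ndarray]:
    """IRLS for NB2 mean given dispersion; returns (beta, mu)."""
    w0 = np.ones(len(y)) if prior_weights is None else prior_weights
    beta = beta0.copy()
    ll_old = -np.inf
    for _ in range(max_iter):
        eta = np.clip(X @ beta + offset, -_ETA_MAX, _ETA_MAX)
        mu = np.exp(eta)
        W = w0 * mu / (1.0 + alpha * mu)
        z = eta - offset + (y - mu) / mu
        sw = np.sqrt(np.maximum(W, 1e-12))
        beta, *_ = np.linalg.lstsq(X * sw[:, None], z * sw, rcond=None)
        eta = np.clip(X @ beta + offset, -_ETA_MAX, _ETA_MAX)
        mu = np.exp(eta)
        ll = float(np.sum(w0 * _nb_loglik_terms(y, mu, alpha)))
        if abs(ll - ll_old) < tol * (1.0 + abs(ll)):
            break
        ll_old = ll
    return beta, mu


def _profile_alpha(
    y: np.ndarray, mu: np.ndarray, prior_weights: np.ndarray | None = None
) -> float:
    """Maximise the NB2 log-likelihood over dispersion at fixed mean."""
    w0 = np.ones(len(y)) if prior_weights is None else prior_weights

    def neg_ll(log_alpha: float) -> float:
        return -float(np.sum(w0 * _nb_loglik_terms(y, mu, np.exp(log_alpha))))

    res = minimize_scalar(neg_ll, bounds=_ALPHA_LOG_BOUNDS, method="bounded",
                          options={"xatol": 1e-6})
    return float(np.exp(res.x))


def _fit_negbin(
    y: np.ndarray, X: np.ndarray, offset: np.ndarray, names: list[str]
) -> ModelFit:
    beta, mu, _ = _irls_poisson(y, X, offset)
    m, v = float(np.mean(y)), float(np.var(y))
    alpha = max((v - m) / max(m, 1e-8) ** 2, 1e-4) if v > m else 1e-4
    ll_old = -np.inf
    converged = False
    for _ in range(50):
        alpha = _profile_alpha(y, mu)
        beta, mu = _nb_irls(y, X, offset, alpha, beta)
        ll = float(np.sum(_nb_loglik_terms(y, mu, alpha)))
        if abs(ll - ll_old) < 1e-8 * (1.0 + abs(ll)):
            converged = True
            break
        ll_old = ll
    ll = float(np.sum(_nb_loglik_terms(y, mu, alpha)))
    # the dispersion MLE can sit on the alpha -> 0 boundary, where the
    # NB collapses to the Poisson; the profile evaluated at a tiny
    # positive alpha underestimates that supremum, so compare directly
    beta_p, mu_p, conv_p = _irls_poisson(y, X, offset)
    ll_p = _poisson_loglik(y, mu_p)
    if ll_p > ll:
        beta, mu, alpha, ll = beta_p, mu_p, 0.0, ll_p
        converged = converged or conv_p
    W = mu / (1.0 + alpha * mu)
    A = (X * W[:, None]).T @ X
    cov = np.linalg.pinv(A)
    se = np.sqrt(np.maximum(np.diag(cov), 0.0))
    rse, rdf = _sandwich_se(X, A, (y - mu) / (1.0 + alpha * mu), w=W)
    return ModelFit(
        "negbin", dict(zip(names, beta)), dict(zip(names, se)),
        ll, X.shape[1] + 1, converged, extra={"alpha": alpha},
        robust_se=dict(zip(names, rse)),
        df_resid=max(len(y) - X.shape[1], 1), robust_df=dict(zip(names, rdf)),
    )


def _zinb_obs_loglik(
    y: np.ndarray, mu: np.ndarray, alpha: float, pi: float
) -> float:
    ll_nb = _nb_loglik_terms(y, mu, alpha)
    zero = y == 0
    out = np.empty_like(mu)
    out[zero] = np.log(pi + (1.0 - pi) * np.exp(ll_nb[zero]))
    out[~zero] = np.log1p(-pi) + ll_nb[~zero]
    return float(np.sum(out))


def _fit_zinb(
    y: np.ndarray, X: np.ndarray, offset: np.ndarray, names: list[str],
    tol: float = 1e-8, max_iter: int = 500,
) -> ModelFit:
    n, p = X.shape
    nb = _fit_negbin(y, X, offset, names)
    beta = np.array([nb.coefficients[c] for c in names])
    alpha = max(nb.extra["alpha"], 1e-8)  # EM needs alpha > 0
    eta = np.clip(X @ beta + offset, -_ETA_MAX, _ETA_MAX)
    mu = np.exp(eta)
    obs_zero = float(np.mean(y == 0))
    exp_zero = float(np.mean(_nb_zero_prob(mu, alpha)))
    pi = min(max(obs_zero - exp_zero, 0.01), 0.9)

    zero = y == 0
    ll_old = -np.inf
    converged = False
    for it in range(max_iter):
        # E-step: posterior probability a zero is structural
        f0 = _nb_zero_prob(mu, alpha)
        z = np.zeros(n)
        z[zero] = pi / (pi + (1.0 - pi) * f0[zero])
        # M-step
        pi = float(np.clip(np.mean(z), 1e-10, 1.0 - 1e-10))
        w = 1.0 - z
        beta, mu = _nb_irls(y, X, offset, alpha, beta, prior_weights=w, max_iter=3)
        if it % 3 == 0 or it < 5:
            alpha = _profile_alpha(y, mu, prior_weights=w)
        ll = _zinb_obs_loglik(y, mu, alpha, pi)
        if abs(ll - ll_old) < tol * (1.0 + abs(ll)):
            converged = True
            break
        ll_old = ll
    ll = _zinb_obs_loglik(y, mu, alpha, pi)

    se, rse, rdf = _zinb_covariances(y, X, offset, beta, alpha, pi, names)
    return ModelFit(
        "zinb", dict(zip(names, beta)), se,
        ll, p + 2, converged, extra={"alpha": alpha, "pi": pi},
        robust_se=rse, df_resid=max(n - p - 2, 1), robust_df=rdf,
    )


def _zinb_loglik_vector(
    y: np.ndarray, X: np.ndarray, offset: np.ndarray, theta: np.ndarray, p: int
) -> np.ndarray:
    b = theta[:p]
    a = np.exp(theta[p])
    q = 1.0 / (1.0 + np.exp(-theta[p + 1]))
    mu = np.exp(np.clip(X @ b + offset, -_ETA_MAX, _ETA_MAX))
    ll_nb = _nb_loglik_terms(y, mu, a)
    zero = y == 0
    out = np.empty_like(mu)
    out[zero] = np.log(q + (1.0 - q) * np.exp(ll_nb[zero]))
    out[~zero] = np.log1p(-q) + ll_nb[~zero]
    return out


def _zinb_covariances(
    y: np.ndarray, X: np.ndarray, offset: np.ndarray,
    beta: np.ndarray, alpha: float, pi: float, names: list[str],
) -> tuple[dict[str, float], dict[str, float], dict[str, float]]:
    """Model-based and sandwich SEs (with df) for the ZINB mean coefficients.

    The observed information is a finite-difference Hessian on the
    unconstrained scale (beta, log alpha, logit pi); the sandwich
    bread is that Hessian and the meat is the outer product of
    finite-difference per-observation scores.  Near the pi -> 0
    boundary the mixture collapses to the NB, whose formulas apply.
    """
    p = X.shape[1]
    if pi < 1e-6:
        mu = np.exp(np.clip(X @ beta + offset, -_ETA_MAX, _ETA_MAX))
        W = mu / (1.0 + alpha * mu)
        A = (X * W[:, None]).T @ X
        cov = np.linalg.pinv(A)
        se = np.sqrt(np.maximum(np.diag(cov), 0.0))
        rse, rdf = _sandwich_se(X, A, (y - mu) / (1.0 + alpha * mu), w=W)
        return dict(zip(names, se)), dict(zip(names, rse)), dict(zip(names, rdf))

    theta0 = np.concatenate([beta, [np.log(alpha), np.log(pi / (1.0 - pi))]])
    d = len(theta0)
    n = len(y)
    h = 1e-4 * np.maximum(np.abs(theta0), 1.0)

    def llv(theta):
        return _zinb_loglik_vector(y, X, offset, theta, p)

    # per-observation scores by central differences (n x d)
    scores = np.empty((n, d))
    for i in range(d):
        e = np.zeros(d); e[i] = h[i]
        scores[:, i] = (llv(theta0 + e) - llv(theta0 - e)) / (2.0 * h[i])

    # observed information by finite differences of the summed loglik
    def ll(theta):
        return float(np.sum(llv(theta)))

    H = np.zeros((d, d))
    f0 = ll(theta0)
    fp = np.empty(d)
    for i in range(d):
        e = np.zeros(d); e[i] = h[i]
        fp[i] = ll(theta0 + e)
    for i in range(d):
        for j in range(i, d):
            e = np.zeros(d); e[i] += h[i]; e[j] += h[j]
            fij = ll(theta0 + e)
            H[i, j] = H[j, i] = (fij - fp[i] - fp[j] + f0) / (h[i] * h[j])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            a_inv = np.linalg.pinv(-H)
            se = np.sqrt(np.maximum(np.diag(a_inv)[:p], 0.0))
            # HC1-style small-sample factor for the numerical sandwich
            influence = scores @ a_inv * np.sqrt(n / max(n - d, 1))
            u = influence**2
            var = u.sum(axis=0)
            rse = np.sqrt(np.maximum(var[:p], 0.0))
            with np.errstate(divide="ignore", invalid="ignore"):
                rdf = 3.0 * var**2 / (u**2).sum(axis=0)
            rdf = np.where(np.isfinite(rdf) & (rdf >= 1.0), rdf, 1.0)[:p]
            rdf = np.minimum(rdf, max(n - d, 1))
        except np.linalg.LinAlgError:
            se = rse = np.full(p, np.nan)
            rdf = np.full(p, 1.0)
    return dict(zip(names, se)), dict(zip(names, rse)), dict(zip(names, rdf))


# --------------------------------------------------------------------
# public surface
# --------------------------------------------------------------------

def fit_candidate_models(
    y: np.ndarray, X: np.ndarray, offset: np.ndarray,
    names: list[str] | None = None,
) -> list[ModelFit]:
    """Fit all four candidate models to one ASV's counts.

    ``X`` must contain an intercept column first; ``offset`` is the log
    library size (used by the count models, not the gaussian one).
    Fits that raise or fail to converge are flagged, not fatal.
    """
    y = np.asarray(y, float)
    X = np.asarray(X, float)
    offset = np.asarray(offset, float)
    if len(y) != X.shape[0] or len(y) != len(offset):
        raise ValueError("y, X and offset lengths differ")
    if np.any(y < 0) or not np.allclose(y, np.round(y)):
        raise ValueError("response must be non-negative integer counts")
    if np.all(y == 0):
        raise ValueError("degenerate response: all counts are zero")
    if names is None:
        names = [f"x{j}" for j in range(X.shape[1])]

    fits: list[ModelFit] = []
    for fitter, args in (
        (_fit_gaussian, (y, X, names)),
        (_fit_poisson, (y, X, offset, names)),
        (_fit_negbin, (y, X, offset, names)),
        (_fit_zinb, (y, X, offset, names)),
    ):
        model = {"_fit_gaussian": "gaussian", "_fit_poisson": "poisson",
                 "_fit_negbin": "negbin", "_fit_zinb": "zinb"}[fitter.__name__]
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                fits.append(fitter(*args))
        except Exception:
            fits.append(ModelFit(model, {}, {}, -np.inf, 0, False))
    return fits


def select_model(fits: list[ModelFit]) -> ModelFit:
    """Converged fit with minimal AIC.

    Ties go to the fit with fewer parameters, then to the fixed order
    poisson, negbin, zinb, gaussian.
    """
    ok = [f for f in fits if f.converged and np.isfinite(f.aic)]
    if not ok:
        raise ValueError("no converged fit available")
    return min(ok, key=lambda f: (f.aic, f.n_params, _MODEL_ORDER.index(f.model)))


def bh_adjust(p) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted q-values, in input order."""
    p = np.asarray(p, float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = len(p)
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q_sorted = np.minimum(q_sorted, 1.0)
    q = np.empty(m)
    q[order] = q_sorted
    return q


def _design_matrix(
    meta: pd.DataFrame, sample_ids: list[str], covariates: list[str]
) -> tuple[np.ndarray, list[str]]:
    meta = meta.loc[sample_ids]
    cols = [np.ones(len(sample_ids))]
    names = ["const"]
    cols.append((meta["group"] == GROUP_CASE).to_numpy(float))
    names.append("group")
    for cov in covariates:
        if cov not in meta.columns:
            raise ValueError(f"covariate {cov!r} missing from metadata")
        col = meta[cov]
        if col.dtype == bool or col.dtype.kind in "ifu":
            cols.append(col.to_numpy(float))
            names.append(cov)
        else:
            dummies = pd.get_dummies(col.astype("category"), drop_first=True)
            for lvl in dummies.columns:
                cols.append(dummies[lvl].to_numpy(float))
                names.append(f"{cov}[{lvl}]")
    X = np.column_stack(cols)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("design matrix is rank deficient")
    return X, names


def differential_abundance(
    counts: CountTable,
    meta: pd.DataFrame,
    covariates: list[str] | None = None,
) -> pd.DataFrame:
    """Per-ASV multi-model test of the EIM-vs-control group effect.

    ``counts`` should already be prevalence-filtered (>=10% of
    samples).  Returns a DataFrame indexed by ASV id with columns
    ``chosen_model, log2_fc, mean_diff, p, q``; ASVs for which no model
    converged are listed in ``result.attrs["skipped"]``.

    log2 FC is the group coefficient divided by ln 2 for the log-link
    models and log2 of the (+0.5 smoothed) group-mean ratio for the
    gaussian fit; the mean difference is on raw counts.
    """
    covariates = list(covariates or [])
    meta = validate_metadata(meta, counts)
    bio = meta.loc[counts.sample_ids]
    if bio["is_negative_control"].any():
        raise ValueError("decontaminate before differential abundance")
    X, names = _design_matrix(meta, counts.sample_ids, covariates)
    offset = np.log(counts.depths().to_numpy(float))
    is_case = (bio["group"] == GROUP_CASE).to_numpy()

    rows, skipped = [], []
    for asv in counts.asv_ids:
        y = counts.data[asv].to_numpy(float)
        mean_case = float(y[is_case].mean())
        mean_ctrl = float(y[~is_case].mean())
        try:
            fits = fit_candidate_models(y, X, offset, names)
            best = select_model(fits)
        except ValueError:
            skipped.append(asv)
            continue
        if best.model == "gaussian":
            lfc = float(np.log2((mean_case + 0.5) / (mean_ctrl + 0.5)))
        else:
            lfc = best.coefficients["group"] / np.log(2.0)
        rows.append(
            {
                "asv_id": asv,
                "chosen_model": best.model,
                "log2_fc": lfc,
                "mean_diff": mean_case - mean_ctrl,
                "p": best.wald_p("group"),
            }
        )
    out = pd.DataFrame(rows).set_index("asv_id") if rows else pd.DataFrame(
        columns=["chosen_model", "log2_fc", "mean_diff", "p", "q"]
    )
    if len(out):
        valid = out["p"].notna()
        q = np.full(len(out), np.nan)
        if valid.any():
            q[valid.to_numpy()] = bh_adjust(out.loc[valid, "p"].to_numpy())
        out["q"] = q
    out.attrs["skipped"] = skipped
    return out


def effect_filter(
    records: pd.DataFrame, q_threshold: float = 0.05, lfc_threshold: float = 1.0
) -> pd.DataFrame:
    """Keep ASVs with q < threshold and |log2 FC| strictly > threshold."""
    if len(records) == 0:
        return records.copy()
    keep = (records["q"] < q_threshold) & (records["log2_fc"].abs() > lfc_threshold)
    return records.loc[keep.fillna(False)]
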