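"""Bayesian Best Subset Regression (BBSR) with a per-predictor Zellner g-prior.

For each gene, every subset of its candidate regulators is scored.  The
coefficient prior is a Zellner-style g-prior centred at a guess ``beta0``
(zero by default: the network is believed sparse), extended so that each
predictor j carries its own weight g_j — large for predictors backed by a
structure prior, ``g = 1`` for the rest ("no priors" treats everyone equally).

For a subset with design X_m, OLS solution b_hat and n observations:

    posterior mean   b_tilde_j = beta0_j + g_j/(g_j+1) * (b_hat_j - beta0_j)
    sigma^2 ~ Inverse-Gamma(shape = n/2,
                            scale = 1/2 * [SSR + (b_hat-beta0)' W (b_hat-beta0)])
    with W = G^{1/2} (X_m' X_m) G^{1/2},  G = diag(1/(g_j+1))

so g -> infinity recovers OLS with scale -> SSR/2, and g -> 0 pins the
solution at beta0 and charges the full unexplained variance.  Model selection
minimises BIC = n * ln E[sigma^2] + k * ln n using the posterior mean of
sigma^2 (scale/(shape-1)); ties prefer fewer predictors, then lexicographic
subset order.  When more than ten candidates survive upstream filtering, an
initial filtration keeps the ten with the best single-predictor BIC, never
dropping prior predictors.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import combinations

import numpy as np

from .design import DesignResponse
from .regression import RegressionResult

__all__ = [
    "GPriorSpec",
    "SubsetModel",
    "posterior",
    "expected_sigma2",
    "bic_score",
    "best_subset",
    "initial_filtration",
    "bbsr_fit",
]

log = logging.getLogger(__name__)

MAX_SUBSET_PREDICTORS = 10
NEG_INF = float("-inf")
# posterior scales below this fraction of y'y are treated as an exact fit
# (sigma2 = 0 -> BIC = -inf sentinel); log(SSR) is floating-point noise there
_EXACT_FIT_RTOL = 1e-9


@dataclass
class GPriorSpec:
    """Per-predictor g weights: ``g_prior`` on prior edges, ``g_no_prior`` else.

    ``g = inf`` is the analytic no-shrinkage limit (treated exactly, no
    overflow).  ``g_no_prior = 1`` with no prior edges is the "no priors" mode.
    """

    g_prior: float = 1.0
    g_no_prior: float = 1.0
    beta0: float = 0.0

    def __post_init__(self) -> None:
        for g in (self.g_prior, self.g_no_prior):
            if not g > 0:
                raise ValueError(f"g weights must be positive, got {g}")

    def g_vector(self, predictor_ids: list[str], prior_predictors: set[str]) -> np.ndarray:
        return np.asarray([self.g_prior if t in prior_predictors else self.g_no_prior
                           for t in predictor_ids])


@dataclass
class SubsetModel:
    subset: tuple[int, ...]
    beta_hat: np.ndarray
    beta_tilde: np.ndarray
    ssr: float
    shape: float
    scale: float
    sigma2_expected: float
    bic: float


def _shrink_factor(g: np.ndarray) -> np.ndarray:
    """g/(g+1), exact at g = inf."""
    g = np.asarray(g, dtype=float)
    with np.errstate(invalid="ignore"):
        return np.where(np.isinf(g), 1.0, g / (g + 1.0))


def _penalty_weight(g: np.ndarray) -> np.ndarray:
    """1/(g+1), exact at g = inf."""
    g = np.asarray(g, dtype=float)
    return 1.0 / (g + 1.0)


def expected_sigma2(shape: float, scale: float) -> float:
    """Posterior mean of sigma^2 under Inverse-Gamma(shape, scale).

    The mean scale/(shape-1) needs shape > 1; for degenerate tiny samples the
    mode scale/(shape+1) is used instead (with a warning).
    """
    if shape > 1:
        return scale / (shape - 1.0)
    log.warning("IG shape %.3g <= 1; falling back to posterior mode", shape)
    return scale / (shape + 1.0)


def bic_score(sigma2: float, n: int, k: int) -> float:
    """BIC = n*ln(sigma2) + k*ln(n); sigma2 = 0 maps to the -inf sentinel."""
    if sigma2 <= 0:
        return NEG_INF
    return n * float(np.log(sigma2)) + k * float(np.log(n))


def posterior(X_m: np.ndarray, y: np.ndarray, g: np.ndarray,
              beta0: np.ndarray | None = None,
              subset: tuple[int, ...] | None = None) -> SubsetModel:
    """Closed-form posterior and BIC for a single predictor subset."""
    n, k = X_m.shape
    if n <= k + 1:
        raise ValueError(f"insufficient observations: n={n}, k={k}")
    b0 = np.zeros(k) if beta0 is None else np.asarray(beta0, dtype=float)
    g = np.broadcast_to(np.asarray(g, dtype=float), (k,))

    if k == 0:
        beta_hat = np.empty(0)
        ssr = float(y @ y)
        pen = 0.0
    else:
        gram = X_m.T @ X_m
        beta_hat = np.linalg.solve(gram, X_m.T @ y)
        resid = y - X_m @ beta_hat
        ssr = float(resid @ resid)
        d = beta_hat - b0
        w = np.sqrt(_penalty_weight(g)) * d
        pen = float(w @ gram @ w)

    beta_tilde = b0 + _shrink_factor(g) * (beta_hat - b0)
    shape = n / 2.0
    scale = 0.5 * (ssr + pen)
    if scale <= _EXACT_FIT_RTOL * float(y @ y):
        scale = 0.0
    sigma2 = expected_sigma2(shape, scale)
    return SubsetModel(
        subset=subset if subset is not None else tuple(range(k)),
        beta_hat=beta_hat, beta_tilde=beta_tilde, ssr=max(ssr, 0.0),
        shape=shape, scale=scale, sigma2_expected=sigma2,
        bic=bic_score(sigma2, n, k),
    )


def _score_size_k(gram, xty, yty, sqrt_w, n, combos):
    """Vectorised scoring of all size-k subsets. Returns (bic, sigma2, betas).

    ``combos`` is an (m, k) integer array of predictor index tuples; singular
    subsets get bic = +inf.
    """
    m, k = combos.shape
    sub_gram = gram[combos[:, :, None], combos[:, None, :]]    # (m, k, k)
    sub_xty = xty[combos]                                       # (m, k)
    try:
        beta = np.linalg.solve(sub_gram, sub_xty[..., None])[..., 0]
        bad = ~np.all(np.isfinite(beta), axis=1)
    except np.linalg.LinAlgError:
        beta = np.full((m, k), np.nan)
        bad = np.ones(m, dtype=bool)
        for r in range(m):
            try:
                beta[r] = np.linalg.solve(sub_gram[r], sub_xty[r])
                bad[r] = not np.all(np.isfinite(beta[r]))
            except np.linalg.LinAlgError:
                pass
    ssr = np.maximum(yty - np.einsum("mk,mk->m", beta, sub_xty), 0.0)
    w = sqrt_w[combos] * beta                                   # beta0 = 0 here
    pen = np.einsum("mk,mkl,ml->m", w, sub_gram, w)
    shape = n / 2.0
    scale = 0.5 * (ssr + pen)
    scale[scale <= _EXACT_FIT_RTOL * yty] = 0.0
    denom = (shape - 1.0) if shape > 1 else (shape + 1.0)
    sigma2 = scale / denom
    with np.errstate(divide="ignore"):
        bic = np.where(sigma2 > 0,
                       n * np.log(np.maximum(sigma2, 1e-300)) + k * np.log(n),
                       NEG_INF)
    bic[bad] = np.inf
    return bic, sigma2, beta


def best_subset(dr: DesignResponse, g: np.ndarray,
                beta0: np.ndarray | None = None) -> RegressionResult:
    """Enumerate all predictor subsets and return the minimum-BIC model.

    Requires at most ``MAX_SUBSET_PREDICTORS`` candidates (apply
    :func:`initial_filtration` first).  Subsets with too few observations or a
    rank-deficient design are skipped.  Ties prefer fewer predictors, then the
    lexicographically first subset.
    """
    X, y = dr.design, dr.response
    n, p = X.shape
    if p > MAX_SUBSET_PREDICTORS:
        raise ValueError(f"{p} candidates exceed the subset-enumeration limit; "
                         "apply initial_filtration first")
    if beta0 is not None and np.any(np.asarray(beta0) != 0):
        # general beta0 falls back to the per-subset closed form
        return _best_subset_general(dr, g, np.asarray(beta0, dtype=float))

    gram = X.T @ X
    xty = X.T @ y
    yty = float(y @ y)
    g = np.broadcast_to(np.asarray(g, dtype=float), (p,))
    sqrt_w = np.sqrt(_penalty_weight(g))

    best_key = None
    best_model = None  # (subset, beta_tilde, sigma2, bic)
    shape = n / 2.0
    empty_sigma2 = expected_sigma2(shape, 0.5 * yty)
    best_key = (bic_score(empty_sigma2, n, 0), 0, ())
    best_model = ((), np.empty(0), empty_sigma2, best_key[0])

    shrink = _shrink_factor(g)
    for k in range(1, p + 1):
        if n <= k + 1:
            break
        combos = np.asarray(list(combinations(range(p), k)), dtype=int)
        bic, sigma2, betas = _score_size_k(gram, xty, yty, sqrt_w, n, combos)
        i = int(np.lexsort((np.arange(len(bic)), bic))[0])  # first index at min
        key = (bic[i], k, tuple(combos[i]))
        if key < best_key:
            best_key = key
            subset = tuple(int(j) for j in combos[i])
            beta_tilde = shrink[combos[i]] * betas[i]
            best_model = (subset, beta_tilde, float(sigma2[i]), float(bic[i]))

    if best_model is None:  # pragma: no cover
        log.warning("no valid subset for gene %s; returning empty model", dr.gene_id)
        return RegressionResult(dr.gene_id, [], np.empty(0), float(yty / n), np.inf)

    subset, beta_tilde, sigma2, bic_val = best_model
    return RegressionResult(
        gene_id=dr.gene_id,
        selected=[dr.predictor_ids[j] for j in subset],
        betas=beta_tilde,
        residual_variance=sigma2,
        model_score=bic_val,
    )


def _best_subset_general(dr: DesignResponse, g: np.ndarray, beta0: np.ndarray) -> RegressionResult:
    X, y = dr.design, dr.response
    n, p = X.shape
    g = np.broadcast_to(np.asarray(g, dtype=float), (p,))
    best_key = None
    best = None
    for k in range(0, p + 1):
        if k > 0 and n <= k + 1:
            break
        for subset in combinations(range(p), k):
            idx = list(subset)
            try:
                model = posterior(X[:, idx], y, g[idx], beta0[idx], subset=subset)
            except (ValueError, np.linalg.LinAlgError):
                continue
            key = (model.bic, k, subset)
            if best_key is None or key < best_key:
                best_key, best = key, model
    if best is None:
        log.warning("no valid subset for gene %s; returning empty model", dr.gene_id)
        return RegressionResult(dr.gene_id, [], np.empty(0), float(y @ y / n), np.inf)
    return RegressionResult(
        gene_id=dr.gene_id,
        selected=[dr.predictor_ids[j] for j in best.subset],
        betas=best.beta_tilde,
        residual_variance=best.sigma2_expected,
        model_score=best.bic,
    )


def initial_filtration(dr: DesignResponse, prior_predictors: set[str],
                       g: np.ndarray, limit: int = MAX_SUBSET_PREDICTORS) -> list[str]:
    """Reduce candidates to ``limit`` by marginal single-predictor BIC.

    Prior predictors are always retained; if priors alone exceed the limit, the
    best-fitting ``limit`` among them are kept.
    """
    ids = dr.predictor_ids
    if len(ids) <= limit:
        return list(ids)
    X, y = dr.design, dr.response
    g = np.broadcast_to(np.asarray(g, dtype=float), (len(ids),))
    marginal = {}
    for j, t in enumerate(ids):
        try:
            marginal[t] = posterior(X[:, [j]], y, g[[j]]).bic
        except (ValueError, np.linalg.LinAlgError):
            marginal[t] = np.inf
    priors = [t for t in ids if t in prior_predictors]
    others = [t for t in ids if t not in prior_predictors]
    if len(priors) >= limit:
        keep = sorted(priors, key=lambda t: (marginal[t], t))[:limit]
    else:
        room = limit - len(priors)
        keep = priors + sorted(others, key=lambda t: (marginal[t], t))[:room]
    return [t for t in ids if t in set(keep)]


def bbsr_fit(dr: DesignResponse, prior_predictors: set[str] | None,
             gprior: GPriorSpec | None = None) -> RegressionResult:
    """Full BBSR step for one gene: filtration (if needed) then best subset."""
    gprior = gprior or GPriorSpec()
    prior_predictors = prior_predictors or set()
    if len(dr.predictor_ids) > MAX_SUBSET_PREDICTORS:
        g_all = gprior.g_vector(dr.predictor_ids, prior_predictors)
        keep = initial_filtration(dr, prior_predictors, g_all)
        dr = _restrict(dr, keep)
    g = gprior.g_vector(dr.predictor_ids, prior_predictors)
    beta0 = np.full(len(dr.predictor_ids), gprior.beta0)
    return best_subset(dr, g, beta0=beta0)


def _restrict(dr: DesignResponse, keep: list[str]) -> DesignResponse:
    idx = [dr.predictor_ids.index(t) for t in keep]
    return DesignResponse(
        gene_id=dr.gene_id, response=dr.response, design=dr.design[:, idx],
        predictor_ids=list(keep), alpha=dr.alpha, raw_response=dr.raw_response,
        condition_index=dr.condition_index,
    )
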