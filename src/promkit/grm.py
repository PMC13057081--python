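"""Samejima's graded response model: calibration, scoring, information.

The GRM models the probability that a person with latent trait ``theta``
responds in ordered category k of an item with discrimination ``alpha`` and
strictly increasing thresholds ``beta_1 < ... < beta_{K-1}``::

    P*_k(theta) = 1 / (1 + exp(-alpha * (theta - beta_k)))     k = 1..K-1
    P_k(theta)  = P*_k(theta) - P*_{k+1}(theta)                P*_0 = 1, P*_K = 0

Calibration is marginal maximum likelihood by EM under a N(0,1) latent
prior (the latent scale is identified by fixing the prior variance to 1);
scoring is expected a posteriori (EAP) with the posterior SD reported as
SE(theta).  T-scores are the linear transform T = 50 + 10*theta.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit, logsumexp
from scipy.stats import norm
from sklearn.base import BaseEstimator, TransformerMixin

from ._quad import QuadratureGrid, default_grid

__all__ = [
    "ItemParameters",
    "InformationProfile",
    "GradedResponseModel",
    "category_probabilities",
    "fit_grm",
    "eap_score",
    "score_table",
    "information_profile",
    "marginal_reliabilities",
    "t_transform",
    "t_inverse",
    "se_to_reliability",
]

MISSING = -1  # sentinel for a skipped response in integer matrices


# ---------------------------------------------------------------------------
# parameters container
# ---------------------------------------------------------------------------


@dataclass
class ItemParameters:
    """Per-item discrimination and ordered thresholds.

    ``alphas`` is a length-p array; ``betas`` is a list of length-(K_j - 1)
    strictly increasing arrays, so items may differ in category count.
    """

    alphas: np.ndarray
    betas: list[np.ndarray]
    item_names: list[str] | None = None

    def __post_init__(self) -> None:
        self.alphas = np.asarray(self.alphas, dtype=float).ravel()
        self.betas = [np.asarray(b, dtype=float).ravel() for b in self.betas]
        if len(self.betas) != self.alphas.size:
            raise ValueError("alphas and betas must describe the same items")
        if np.any(self.alphas <= 0):
            raise ValueError("discriminations must be strictly positive")
        for j, b in enumerate(self.betas):
            if b.size < 1:
                raise ValueError(f"item {j}: needs at least one threshold")
            if np.any(np.diff(b) <= 0):
                raise ValueError(f"item {j}: thresholds must be strictly increasing")
        if self.item_names is None:
            self.item_names = [f"item{j}" for j in range(self.n_items)]
        elif len(self.item_names) != self.n_items:
            raise ValueError("item_names length mismatch")

    @property
    def n_items(self) -> int:
        return int(self.alphas.size)

    @property
    def n_categories(self) -> np.ndarray:
        return np.array([b.size + 1 for b in self.betas])

    def subset(self, indices) -> "ItemParameters":
        indices = list(indices)
        return ItemParameters(
            self.alphas[indices],
            [self.betas[j] for j in indices],
            [self.item_names[j] for j in indices],
        )

    # --- JSON round-trip ---------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "items": [
                {"name": n, "alpha": float(a), "betas": [float(x) for x in b]}
                for n, a, b in zip(self.item_names, self.alphas, self.betas)
            ]
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ItemParameters":
        items = d["items"]
        return cls(
            np.array([it["alpha"] for it in items]),
            [np.array(it["betas"]) for it in items],
            [it.get("name", f"item{j}") for j, it in enumerate(items)],
        )

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "ItemParameters":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


@dataclass
class InformationProfile:
    """Item/test information and the test characteristic curve on a theta grid."""

    theta: np.ndarray
    item_information: np.ndarray  # (p, G)
    test_information: np.ndarray  # (G,)
    tcc: np.ndarray  # expected summed score per theta, (G,)


# ---------------------------------------------------------------------------
# probabilities
# ---------------------------------------------------------------------------


def _cat_probs_grid(alpha: float, betas: np.ndarray, theta: np.ndarray) -> np.ndarray:
    """(len(theta), K) category probabilities for one item."""
    theta = np.asarray(theta, dtype=float)
    z = alpha * (theta[:, None] - betas[None, :])  # (T, K-1)
    pstar = expit(z)
    upper = np.concatenate([np.ones((theta.size, 1)), pstar], axis=1)
    lower = np.concatenate([pstar, np.zeros((theta.size, 1))], axis=1)
    p = upper - lower
    return np.clip(p, 1e-300, 1.0)


def category_probabilities(alpha: float, betas, theta) -> np.ndarray:
    """GRM category probabilities ``P_k(theta)``.

    ``theta`` may be scalar (returns a length-K vector) or an array
    (returns (len(theta), K)).  Raises on non-increasing thresholds.
    """
    betas = np.asarray(betas, dtype=float).ravel()
    if alpha <= 0:
        raise ValueError("alpha must be positive")
    if np.any(np.diff(betas) <= 0):
        raise ValueError("thresholds must be strictly increasing")
    theta_arr = np.atleast_1d(np.asarray(theta, dtype=float))
    if not np.all(np.isfinite(theta_arr)):
        raise ValueError("theta must be finite")
    p = _cat_probs_grid(float(alpha), betas, theta_arr)
    return p[0] if np.isscalar(theta) or np.ndim(theta) == 0 else p


def _log_prob_tables(params: ItemParameters, nodes: np.ndarray) -> list[np.ndarray]:
    """Per item: (K, Q) log category probabilities at the quadrature nodes."""
    return [
        np.log(_cat_probs_grid(params.alphas[j], params.betas[j], nodes).T)
        for j in range(params.n_items)
    ]


def _pattern_loglik(X: np.ndarray, logp: list[np.ndarray]) -> np.ndarray:
    """(n, Q) log-likelihood of each response row at each node; missing skipped."""
    n = X.shape[0]
    Q = logp[0].shape[1]
    L = np.zeros((n, Q))
    for j, lp in enumerate(logp):
        x = X[:, j]
        obs = x >= 0
        if obs.all():
            L += lp[x, :]
        else:
            L[obs] += lp[x[obs], :]
    return L


# ---------------------------------------------------------------------------
# EAP scoring
# ---------------------------------------------------------------------------


def eap_score(
    X: np.ndarray,
    params: ItemParameters,
    grid: QuadratureGrid | None = None,
):
    """EAP trait estimates and posterior-SD standard errors.

    Parameters
    ----------
    X : (n, p) integer matrix, categories 0..K_j-1; ``-1`` marks missing.
    params : item parameters used for scoring.
    grid : quadrature grid (default 61 nodes on [-6, 6]).

    Returns
    -------
    theta_hat, se : (n,) arrays.  An all-missing row returns the prior
    mean 0 and prior SD 1 (the posterior equals the prior).
    """
    grid = grid or default_grid()
    X = np.atleast_2d(np.asarray(X, dtype=int))
    if X.shape[1] != params.n_items:
        raise ValueError("response matrix width does not match parameter set")
    for j, K in enumerate(params.n_categories):
        bad = X[:, j] >= K
        if np.any(bad):
            raise ValueError(f"item {j}: category out of range in rows {np.where(bad)[0][:5]}")
    logp = _log_prob_tables(params, grid.nodes)
    L = _pattern_loglik(X, logp) + np.log(grid.weights)[None, :]
    L -= L.max(axis=1, keepdims=True)
    post = np.exp(L)
    post /= post.sum(axis=1, keepdims=True)
    theta_hat = post @ grid.nodes
    second = post @ (grid.nodes**2)
    se = np.sqrt(np.maximum(second - theta_hat**2, 1e-12))
    return theta_hat, se


def t_transform(theta_hat):
    """T = 50 + 10*theta."""
    return 50.0 + 10.0 * np.asarray(theta_hat, dtype=float)


def t_inverse(t_score):
    """theta = (T - 50) / 10."""
    return (np.asarray(t_score, dtype=float) - 50.0) / 10.0


def se_to_reliability(se):
    """IRT reliability implied by a standard error on the theta scale: 1 - SE^2."""
    return 1.0 - np.asarray(se, dtype=float) ** 2


def score_table(
    X: np.ndarray,
    params: ItemParameters,
    grid: QuadratureGrid | None = None,
    person_id=None,
) -> pd.DataFrame:
    """Score a response matrix into a per-person table.

    Columns: person_id, theta_hat, se_theta, t_score, raw_sum.
    """
    X = np.atleast_2d(np.asarray(X, dtype=int))
    theta_hat, se = eap_score(X, params, grid)
    raw = np.where(X >= 0, X, 0).sum(axis=1)
    if person_id is None:
        person_id = np.arange(X.shape[0])
    return pd.DataFrame(
        {
            "person_id": person_id,
            "theta_hat": theta_hat,
            "se_theta": se,
            "t_score": t_transform(theta_hat),
            "raw_sum": raw,
        }
    )


# ---------------------------------------------------------------------------
# information / TCC
# ---------------------------------------------------------------------------


def information_profile(params: ItemParameters, theta_grid=None) -> InformationProfile:
    """Item information, test information and TCC on a theta grid.

    Item information uses the GRM category response derivatives:
    I_j = sum_k (P'_k)^2 / P_k with P'_k = alpha*(s_k - s_{k+1}) and
    s_k = P*_k (1 - P*_k) (s_0 = s_K = 0).
    """
    if theta_grid is None:
        theta_grid = np.linspace(-4.5, 4.5, 181)
    theta_grid = np.asarray(theta_grid, dtype=float)
    G = theta_grid.size
    p_items = params.n_items
    item_info = np.zeros((p_items, G))
    tcc = np.zeros(G)
    for j in range(p_items):
        a, b = params.alphas[j], params.betas[j]
        z = a * (theta_grid[:, None] - b[None, :])
        pstar = expit(z)
        s = pstar * (1 - pstar)  # (G, K-1)
        s_pad = np.concatenate([np.zeros((G, 1)), s, np.zeros((G, 1))], axis=1)
        dP = a * (s_pad[:, :-1] - s_pad[:, 1:])  # (G, K)
        P = _cat_probs_grid(a, b, theta_grid)
        item_info[j] = np.sum(dP**2 / P, axis=1)
        tcc += P @ np.arange(P.shape[1])
    return InformationProfile(theta_grid, item_info, item_info.sum(axis=0), tcc)


def marginal_reliabilities(
    params: ItemParameters,
    scores: pd.DataFrame,
    grid: QuadratureGrid | None = None,
):
    """Theoretical and empirical marginal reliability of a calibrated bank.

    Theoretical: rho_T = 1 - integral of the posterior variance
    v(theta) ~= 1/(1 + I(theta)) against the N(0,1) prior (quadrature).
    Empirical: rho_E = Var(theta_hat) / (Var(theta_hat) + mean(SE^2)) over
    the observed score table.  Both lie in [0, 1].
    """
    if scores is None or len(scores) == 0:
        raise ValueError("empty score table")
    grid = grid or default_grid()
    info = information_profile(params, grid.nodes)
    v = 1.0 / (1.0 + info.test_information)
    rho_t = 1.0 - float(np.sum(grid.weights * v))
    var_hat = float(np.var(scores["theta_hat"], ddof=1)) if len(scores) > 1 else 0.0
    mean_se2 = float(np.mean(scores["se_theta"] ** 2))
    rho_e = var_hat / (var_hat + mean_se2) if (var_hat + mean_se2) > 0 else 0.0
    return float(np.clip(rho_t, 0, 1)), float(np.clip(rho_e, 0, 1))


def reliability_band(rho: float) -> str:
    """Qualitative band: 0.70-0.80 acceptable, 0.81-0.90 good, >0.90 excellent."""
    if rho > 0.90:
        return "excellent"
    if rho > 0.80:
        return "good"
    if rho >= 0.70:
        return "acceptable"
    return "insufficient"


# ---------------------------------------------------------------------------
# EM calibration
# ---------------------------------------------------------------------------


def _mstep_objective(alpha, betas, nodes, r):
    P = _cat_probs_grid(alpha, betas, nodes)  # (Q, K)
    return float(np.sum(r.T * np.log(P)))


def _mstep_gradient(alpha, betas, nodes, r):
    """Analytic gradient of the expected complete-data log-likelihood.

    Returns gradient w.r.t. (alpha, beta_1..beta_{K-1}).
    """
    Q = nodes.size
    K = betas.size + 1
    z = alpha * (nodes[:, None] - betas[None, :])  # (Q, K-1)
    pstar = expit(z)
    s = pstar * (1 - pstar)
    P = _cat_probs_grid(alpha, betas, nodes)  # (Q, K)
    w = r.T / P  # (Q, K) expected count over probability
    D = w[:, 1:] - w[:, :-1]  # (Q, K-1): dQ/dP*_m weight
    g_alpha = float(np.sum(D * (nodes[:, None] - betas[None, :]) * s))
    g_beta = -alpha * np.sum(D * s, axis=0)
    return np.concatenate([[g_alpha], g_beta])


def _to_unconstrained(alpha, betas):
    u = np.empty(betas.size + 1)
    u[0] = np.log(alpha)
    u[1] = betas[0]
    if betas.size > 1:
        u[2:] = np.log(np.diff(betas))
    return u


def _from_unconstrained(u):
    alpha = float(np.exp(np.clip(u[0], -3.0, 2.2)))
    incr = np.exp(np.clip(u[2:], -12.0, 2.5)) if u.size > 2 else np.empty(0)
    betas = np.concatenate([[u[1]], u[1] + np.cumsum(incr)]) if u.size > 2 else np.array([u[1]])
    betas = np.clip(betas, -8.0, 8.0)
    # clipping can create ties at the boundary; restore strict ordering
    for k in range(1, betas.size):
        if betas[k] <= betas[k - 1]:
            betas[k] = betas[k - 1] + 1e-6
    return alpha, betas


def _grad_unconstrained(u, nodes, r):
    alpha, betas = _from_unconstrained(u)
    g = _mstep_gradient(alpha, betas, nodes, r)
    gu = np.empty_like(u)
    gu[0] = g[0] * alpha
    gu[1] = g[1:].sum()
    if u.size > 2:
        incr = np.diff(betas)
        # d beta_m / d u_k = incr_{k-1} for m >= k
        tail = np.cumsum(g[1:][::-1])[::-1]  # tail sums of beta-gradient
        gu[2:] = tail[1:] * incr
    return gu


def _newton_mstep(alpha, betas, nodes, r, n_steps=3):
    """A few guarded Newton steps in the unconstrained parametrization.

    The Hessian is a forward difference of the analytic gradient; steps are
    halved until the expected log-likelihood does not decrease (GEM).
    """
    u = _to_unconstrained(alpha, betas)
    q0 = _mstep_objective(alpha, betas, nodes, r)
    for _ in range(n_steps):
        g = _grad_unconstrained(u, nodes, r)
        if np.max(np.abs(g)) < 1e-8:
            break
        eps = 1e-5
        H = np.empty((u.size, u.size))
        for k in range(u.size):
            up = u.copy()
            up[k] += eps
            H[:, k] = (_grad_unconstrained(up, nodes, r) - g) / eps
        H = 0.5 * (H + H.T)
        try:
            step = np.linalg.solve(H - 1e-8 * np.eye(u.size), -g)
        except np.linalg.LinAlgError:
            step = g / max(np.max(np.abs(g)), 1.0)
        if not np.all(np.isfinite(step)) or float(step @ g) < 0:
            step = g / max(np.max(np.abs(g)), 1.0)  # fall back to gradient ascent
        scale = 1.0
        improved = False
        for _ in range(12):
            a_new, b_new = _from_unconstrained(u + scale * step)
            q_new = _mstep_objective(a_new, b_new, nodes, r)
            if q_new >= q0 - 1e-10:
                u = u + scale * step
                q0 = q_new
                improved = True
                break
            scale *= 0.5
        if not improved:
            break
    return _from_unconstrained(u)


def _collapse_categories(X: np.ndarray):
    """Recode each item's observed categories to consecutive 0..K-1.

    Returns the recoded matrix and, per item, the mapping old->new for the
    observed categories.  Items with a single observed category are rejected.
    """
    X = np.asarray(X, dtype=int).copy()
    maps = []
    for j in range(X.shape[1]):
        col = X[:, j]
        observed = np.unique(col[col >= 0])
        if observed.size < 2:
            raise ValueError(f"item {j}: fewer than 2 observed categories")
        mapping = {int(c): k for k, c in enumerate(observed)}
        if observed.size != observed.max() + 1 or observed.min() != 0:
            newcol = col.copy()
            for old, new in mapping.items():
                newcol[col == old] = new
            X[:, j] = newcol
        maps.append(mapping)
    return X, maps


def apply_category_maps(X: np.ndarray, maps) -> np.ndarray:
    """Recode a response matrix with the category maps recorded by ``fit``."""
    X = np.asarray(X, dtype=int).copy()
    out = X.copy()
    for j, mapping in enumerate(maps):
        col = X[:, j]
        newcol = col.copy()
        for old, new in mapping.items():
            newcol[col == old] = new
        # unmapped observed categories collapse to the nearest mapped one
        keys = np.array(sorted(mapping))
        unmapped = (col >= 0) & ~np.isin(col, keys)
        if np.any(unmapped):
            nearest = keys[np.argmin(np.abs(col[unmapped, None] - keys[None, :]), axis=1)]
            newcol[unmapped] = [mapping[int(k)] for k in nearest]
        out[:, j] = newcol
    return out


class GradedResponseModel(BaseEstimator, TransformerMixin):
    """Graded response model calibrated by EM marginal maximum likelihood.

    Parameters
    ----------
    n_quadrature : number of equally spaced quadrature nodes.
    quadrature_span : half-width of the node range.
    tol : EM convergence criterion, max absolute parameter change.
    max_iter : maximum EM cycles; non-convergence is flagged, not raised.
    newton_steps : guarded Newton iterations per item per M-step.

    Fitted attributes
    -----------------
    params_ : :class:`ItemParameters`
    loglik_path_ : marginal log-likelihood per EM cycle (non-decreasing).
    converged_ : bool
    n_iter_ : int
    category_maps_ : per-item recoding of observed categories.
    """

    def __init__(
        self,
        n_quadrature: int = 61,
        quadrature_span: float = 6.0,
        tol: float = 1e-4,
        max_iter: int = 500,
        newton_steps: int = 3,
    ):
        self.n_quadrature = n_quadrature
        self.quadrature_span = quadrature_span
        self.tol = tol
        self.max_iter = max_iter
        self.newton_steps = newton_steps

    # -- construction from known parameters (anchor scoring) ---------------
    @classmethod
    def from_parameters(cls, params: ItemParameters, **kwargs) -> "GradedResponseModel":
        model = cls(**kwargs)
        model.params_ = params
        model.category_maps_ = [
            {k: k for k in range(K)} for K in params.n_categories
        ]
        model.converged_ = True
        model.n_iter_ = 0
        model.loglik_path_ = np.empty(0)
        return model

    @property
    def grid_(self) -> QuadratureGrid:
        return default_grid(self.n_quadrature, self.quadrature_span)

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=int)
        if X.ndim != 2:
            raise ValueError("X must be a persons x items integer matrix")
        n, p = X.shape
        if n < p:
            raise ValueError("need at least as many persons as items")
        X, maps = _collapse_categories(X)
        grid = self.grid_
        nodes, logw = grid.nodes, np.log(grid.weights)

        # starting values: alpha = 1, thresholds from probit marginals
        alphas = np.ones(p)
        betas = []
        for j in range(p):
            col = X[:, j]
            obs = col[col >= 0]
            K = obs.max() + 1
            cum = np.array([(obs < k).mean() for k in range(1, K)])
            b = norm.ppf(np.clip(cum, 1e-3, 1 - 1e-3))
            b = np.maximum.accumulate(b + 1e-6 * np.arange(K - 1))
            betas.append(b)

        loglik_path = []
        converged = False
        onehots = []
        for j in range(p):
            K = betas[j].size + 1
            col = X[:, j]
            oh = np.zeros((n, K))
            obs = col >= 0
            oh[np.where(obs)[0], col[obs]] = 1.0
            onehots.append(oh)

        for it in range(self.max_iter):
            params = ItemParameters(alphas.copy(), [b.copy() for b in betas])
            logp = _log_prob_tables(params, nodes)
            L = _pattern_loglik(X, logp) + logw[None, :]
            ll = float(logsumexp(L, axis=1).sum())
            loglik_path.append(ll)
            Lmax = L.max(axis=1, keepdims=True)
            post = np.exp(L - Lmax)
            post /= post.sum(axis=1, keepdims=True)  # (n, Q)

            max_change = 0.0
            for j in range(p):
                r = (post.T @ onehots[j]).T  # (K, Q): expected counts per category/node
                a_new, b_new = _newton_mstep(
                    alphas[j], betas[j], nodes, r, self.newton_steps
                )
                max_change = max(
                    max_change,
                    abs(a_new - alphas[j]),
                    float(np.max(np.abs(b_new - betas[j]))),
                )
                alphas[j], betas[j] = a_new, b_new
            if max_change < self.tol:
                converged = True
                break

        self.params_ = ItemParameters(alphas, betas)
        self.category_maps_ = maps
        self.loglik_path_ = np.asarray(loglik_path)
        self.converged_ = converged
        self.n_iter_ = len(loglik_path)
        return self

    def transform(self, X):
        """EAP scores: columns (theta_hat, se_theta)."""
        X = apply_category_maps(np.asarray(X, dtype=int), self.category_maps_)
        theta, se = eap_score(X, self.params_, self.grid_)
        return np.column_stack([theta, se])

    def score_table(self, X, person_id=None) -> pd.DataFrame:
        X = apply_category_maps(np.asarray(X, dtype=int), self.category_maps_)
        return score_table(X, self.params_, self.grid_, person_id=person_id)


def fit_grm(
    responses,
    grid: QuadratureGrid | None = None,
    tol: float = 1e-4,
    max_iter: int = 500,
):
    """Functional wrapper over :class:`GradedResponseModel`.

    Returns (params, loglik, converged).
    """
    kwargs = {"tol": tol, "max_iter": max_iter}
    if grid is not None:
        kwargs["n_quadrature"] = grid.size
        kwargs["quadrature_span"] = float(grid.nodes.max())
    model = GradedResponseModel(**kwargs).fit(np.asarray(responses, dtype=int))
    return model.params_, float(model.loglik_path_[-1]), model.converged_
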