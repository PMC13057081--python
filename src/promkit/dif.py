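"""Differential item functioning: ordinal-logistic scan and impact analysis.

For each item, three nested proportional-odds models are fitted on the
observed categories: M1 (trait only), M2 (trait + group) and M3
(trait + group + trait x group).  McFadden pseudo-R2 differences between
the nested models quantify uniform (M2 - M1) and non-uniform (M3 - M2)
DIF; a difference above 0.02 flags the item.  The matching trait is the
EAP estimate from all items (single pass; iterative purification is
available but off by default).  Impact is assessed by re-estimating the
model without flagged items and comparing T-scores, reliability and test
characteristic curves.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize
from scipy.special import expit

from ._quad import QuadratureGrid, default_grid
from .grm import (
    GradedResponseModel,
    ItemParameters,
    eap_score,
    information_profile,
    t_transform,
)

__all__ = [
    "DIFResult",
    "DIFImpact",
    "proportional_odds_loglik",
    "fit_proportional_odds",
    "mcfadden_r2",
    "dif_scan",
    "dif_impact",
]

DIF_THRESHOLD = 0.02  # McFadden pseudo-R2 difference indicative of DIF
SE_RELIABLE = 0.32  # SE(theta) at or below this corresponds to reliability >= 0.90


# ---------------------------------------------------------------------------
# proportional-odds (cumulative logit) model
# ---------------------------------------------------------------------------


def _po_unpack(params: np.ndarray, K: int):
    """Unconstrained params -> (increasing cutpoints, slopes)."""
    t0 = params[0]
    if K > 2:
        cuts = np.concatenate([[t0], t0 + np.cumsum(np.exp(params[1 : K - 1]))])
    else:
        cuts = np.array([t0])
    beta = params[K - 1 :]
    return cuts, beta


def proportional_odds_loglik(params: np.ndarray, y: np.ndarray, X: np.ndarray, K: int):
    """Negative log-likelihood and gradient of the cumulative-logit model.

    P(Y <= k | x) = sigmoid(cut_k - x @ beta); parameters are the first
    cutpoint, log-increments of the remaining cutpoints, and the slopes.
    """
    n, d = X.shape
    cuts, beta = _po_unpack(params, K)
    eta = X @ beta
    # upper and lower cumulative logits per person
    upper = np.where(y < K - 1, cuts[np.minimum(y, K - 2)] - eta, np.inf)
    lower = np.where(y > 0, cuts[np.maximum(y - 1, 0)] - eta, -np.inf)
    Fu = expit(upper)
    Fl = expit(lower)
    prob = np.clip(Fu - Fl, 1e-12, 1.0)
    nll = -np.sum(np.log(prob))

    # gradient
    du = np.where(np.isfinite(upper), Fu * (1 - Fu), 0.0) / prob  # d prob / d upper
    dl = -np.where(np.isfinite(lower), Fl * (1 - Fl), 0.0) / prob
    grad = np.zeros_like(params)
    # slopes: d upper/d beta = -x, d lower/d beta = -x
    grad[K - 1 :] = (X * (du + dl)[:, None]).sum(axis=0)
    # cutpoints (raw): cut_k appears in upper when y == k, in lower when y == k+1
    gcut = np.zeros(K - 1)
    np.add.at(gcut, np.minimum(y, K - 2), np.where(y < K - 1, -du, 0.0))
    np.add.at(gcut, np.maximum(y - 1, 0), np.where(y > 0, -dl, 0.0))
    # chain rule to unconstrained parametrization
    grad[0] = gcut.sum()
    if K > 2:
        incr = np.exp(params[1 : K - 1])
        tails = np.cumsum(gcut[::-1])[::-1]
        grad[1 : K - 1] = tails[1:] * incr
    return nll, grad


def fit_proportional_odds(y: np.ndarray, X: np.ndarray):
    """Fit the cumulative-logit model; returns (loglik, cutpoints, slopes, converged).

    BFGS on the unconstrained parametrization with an analytic gradient; a
    non-convergent fit (separation) falls back to a slightly ridged
    refit and is flagged.
    """
    y = np.asarray(y, dtype=int)
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[0] != y.size:
        X = X.T
    cats = np.unique(y)
    K = int(cats.max() + 1)
    # compress to observed categories for stability
    if cats.size != K:
        remap = {c: i for i, c in enumerate(cats)}
        y = np.array([remap[c] for c in y])
        K = cats.size
    n, d = X.shape
    freq = np.bincount(y, minlength=K) / n
    cum = np.clip(np.cumsum(freq)[:-1], 1e-4, 1 - 1e-4)
    cuts0 = np.log(cum / (1 - cum))
    x0 = np.zeros(K - 1 + d)
    x0[0] = cuts0[0]
    if K > 2:
        x0[1 : K - 1] = np.log(np.maximum(np.diff(cuts0), 1e-3))
    res = optimize.minimize(
        proportional_odds_loglik, x0, args=(y, X, K), jac=True, method="BFGS",
        options={"maxiter": 200, "gtol": 1e-6},
    )
    converged = bool(res.success or np.max(np.abs(res.jac)) < 1e-3)
    params = res.x
    if not converged:
        # penalized refit: small ridge on slopes guards against separation
        def ridged(p, *a):
            nll, g = proportional_odds_loglik(p, *a)
            pen = 1e-3 * np.sum(p[K - 1 :] ** 2)
            g = g.copy()
            g[K - 1 :] += 2e-3 * p[K - 1 :]
            return nll + pen, g

        res = optimize.minimize(ridged, x0, args=(y, X, K), jac=True, method="BFGS",
                                options={"maxiter": 300})
        params = res.x
    cuts, beta = _po_unpack(params, K)
    ll = -proportional_odds_loglik(params, y, X, K)[0]
    return float(ll), cuts, beta, converged


def _null_loglik(y: np.ndarray) -> float:
    """Intercept-only cumulative model: closed form from marginal frequencies."""
    counts = np.bincount(y)
    counts = counts[counts > 0]
    n = counts.sum()
    return float(np.sum(counts * np.log(counts / n)))


def mcfadden_r2(ll_model: float, ll_null: float) -> float:
    """McFadden pseudo-R2 = 1 - ll_model / ll_null."""
    if ll_null == 0:
        return 0.0
    return 1.0 - ll_model / ll_null


# ---------------------------------------------------------------------------
# scan
# ---------------------------------------------------------------------------


@dataclass
class DIFResult:
    """Per item x pairwise-comparison pseudo-R2 differences and flags."""

    table: pd.DataFrame  # item, comparison, r2_uniform, r2_nonuniform, r2_total, flags
    covariate: str
    threshold: float

    def mean_by_item(self) -> pd.DataFrame:
        """Mean pseudo-R2 across pairwise comparisons, with flags at threshold."""
        g = self.table.groupby("item")[["r2_uniform", "r2_nonuniform", "r2_total"]].mean()
        g["flag_uniform"] = g["r2_uniform"] > self.threshold
        g["flag_nonuniform"] = g["r2_nonuniform"] > self.threshold
        g["flag_any"] = g["flag_uniform"] | g["flag_nonuniform"]
        return g.reset_index()

    def flagged_items(self) -> list[int]:
        m = self.mean_by_item()
        return sorted(m.loc[m.flag_any, "item"].astype(int))


def dif_scan(
    responses: np.ndarray,
    theta_hat: np.ndarray,
    covariate: np.ndarray,
    threshold: float = DIF_THRESHOLD,
    min_per_level: int = 25,
    covariate_name: str = "group",
) -> DIFResult:
    """Uniform/non-uniform DIF scan of every item against one covariate.

    Levels with fewer than ``min_per_level`` persons are dropped.  For
    covariates with more than two levels all pairwise comparisons are
    computed; ``mean_by_item`` aggregates them.
    """
    X = np.asarray(responses, dtype=int)
    theta = np.asarray(theta_hat, dtype=float)
    g = pd.Series(covariate).astype(str).to_numpy()
    levels, counts = np.unique(g, return_counts=True)
    levels = [l for l, c in zip(levels, counts) if c >= min_per_level]
    if len(levels) < 2:
        raise ValueError("covariate needs at least 2 levels with enough persons")
    rows = []
    for la, lb in itertools.combinations(levels, 2):
        mask = (g == la) | (g == lb)
        gb = (g[mask] == lb).astype(float)
        th = theta[mask]
        for j in range(X.shape[1]):
            y = X[mask, j]
            if np.unique(y).size < 2:
                continue
            ll_null = _null_loglik(y)
            ll1, *_ , c1 = fit_proportional_odds(y, th[:, None])
            ll2, *_, c2 = fit_proportional_odds(y, np.column_stack([th, gb]))
            ll3, *_, c3 = fit_proportional_odds(y, np.column_stack([th, gb, th * gb]))
            r1, r2_, r3 = (mcfadden_r2(l, ll_null) for l in (ll1, ll2, ll3))
            rows.append(
                {
                    "item": j,
                    "comparison": f"{la} vs {lb}",
                    "r2_uniform": max(r2_ - r1, 0.0),
                    "r2_nonuniform": max(r3 - r2_, 0.0),
                    "r2_total": max(r3 - r1, 0.0),
                    "flag_uniform": (r2_ - r1) > threshold,
                    "flag_nonuniform": (r3 - r2_) > threshold,
                    "converged": bool(c1 and c2 and c3),
                }
            )
    return DIFResult(pd.DataFrame(rows), covariate_name, threshold)


# ---------------------------------------------------------------------------
# impact
# ---------------------------------------------------------------------------


@dataclass
class DIFImpact:
    mean_abs_tdiff: float
    max_tdiff: float
    pct_ge1: float
    se_before: float
    se_after: float
    pct_reliable_before: float
    pct_reliable_after: float
    tcc_theta: np.ndarray
    tcc_before: np.ndarray
    tcc_after: np.ndarray
    cat_never_administered: bool | None = None
    cat_info_rank_summary: dict | None = None


def dif_impact(
    responses: np.ndarray,
    dif_items,
    application_items=None,
    grid: QuadratureGrid | None = None,
    cat_config=None,
) -> DIFImpact:
    """Impact of removing DIF item(s): refit, rescore, compare.

    ``application_items`` restricts the analysis to a short form or other
    subset (default: full bank).  The model is re-estimated from the data
    without the flagged items, all persons are re-scored and the T-score
    and reliability changes are summarized.  With ``cat_config`` a post-hoc
    CAT is replayed before removal and the administration/information rank
    of the flagged items is reported.
    """
    X = np.asarray(responses, dtype=int)
    grid = grid or default_grid()
    items = list(application_items) if application_items is not None else list(range(X.shape[1]))
    dif_items = [j for j in dif_items if j in items]
    keep = [j for j in items if j not in dif_items]
    if len(keep) < 3:
        raise ValueError("removal would leave fewer than 3 items")

    model_before = GradedResponseModel(n_quadrature=grid.size).fit(X[:, items])
    out_b = model_before.transform(X[:, items])
    th_b, se_b = out_b[:, 0], out_b[:, 1]

    if dif_items:
        model_after = GradedResponseModel(n_quadrature=grid.size).fit(X[:, keep])
        out = model_after.transform(X[:, keep])
        th_a, se_a = out[:, 0], out[:, 1]
        params_after = model_after.params_
    else:
        th_a, se_a = th_b, se_b
        params_after = model_before.params_

    t_b, t_a = t_transform(th_b), t_transform(th_a)
    d = np.abs(t_a - t_b)
    theta_grid = np.linspace(-4, 4, 161)
    tcc_b = information_profile(model_before.params_, theta_grid).tcc
    tcc_a = information_profile(params_after, theta_grid).tcc

    cat_never = None
    rank_summary = None
    if cat_config is not None and dif_items:
        from .cat import batch_cat  # local import to avoid a cycle

        traces, _ = batch_cat(X[:, items], model_before.params_, cat_config, grid)
        local_dif = [items.index(j) for j in dif_items]
        administered = [set(t.administered) for t in traces]
        cat_never = all(not (set(local_dif) & a) for a in administered)
        info = information_profile(model_before.params_, theta_grid)
        ranks = []
        for t in traces:
            gi = int(np.argmin(np.abs(theta_grid - t.final_theta)))
            order = np.argsort(info.item_information[:, gi])[::-1]
            ranks.append(min(int(np.where(order == j)[0][0]) + 1 for j in local_dif))
        ranks = np.array(ranks)
        rank_summary = {
            "pct_most_informative": float(100 * np.mean(ranks == 1)),
            "pct_top3": float(100 * np.mean(ranks <= 3)),
        }

    return DIFImpact(
        mean_abs_tdiff=float(d.mean()),
        max_tdiff=float(d.max()),
        pct_ge1=float(100 * np.mean(d >= 1.0)),
        se_before=float(se_b.mean()),
        se_after=float(se_a.mean()),
        pct_reliable_before=float(100 * np.mean(se_b <= SE_RELIABLE)),
        pct_reliable_after=float(100 * np.mean(se_a <= SE_RELIABLE)),
        tcc_theta=theta_grid,
        tcc_before=tcc_b,
        tcc_after=tcc_a,
        cat_never_administered=cat_never,
        cat_info_rank_summary=rank_summary,
    )
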