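"""IRT assumption checks: unidimensionality, local independence, monotonicity.

Unidimensionality is checked twice: a single-factor least-squares solution
on the polychoric correlation matrix with ML-discrepancy fit indices
(reported as unscaled CFI/TLI/RMSEA plus SRMR), and an exploratory
bifactor analysis (minres extraction, promax rotation, Schmid-Leiman
orthogonalization) summarized by ECV and omega-hierarchical.  Local
independence is screened through residual correlations of the one-factor
solution; monotonicity and invariant item ordering use Mokken-style
nonparametric scalability coefficients.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize
from scipy.stats import norm

__all__ = [
    "AssumptionReport",
    "bvn_cdf",
    "polychoric_pair",
    "polychoric_matrix",
    "single_factor_fit",
    "residual_correlations",
    "bifactor_indices",
    "bifactor_indices_from_loadings",
    "mokken_coefficients",
    "monotonicity_check",
    "iio_ht",
    "run_assumptions",
]

RESIDUAL_FLAG = 0.20  # residual correlation above this suggests local dependence


@dataclass
class AssumptionReport:
    """One measure's assumption summary (the shape of a results-table row)."""

    cfi: float
    tli: float
    rmsea: float
    srmr: float
    loadings: np.ndarray
    ecv: float
    omega_h: float
    residual_pairs: list[tuple[int, int, float]]
    n_pairs: int
    H: float
    Hi: np.ndarray
    monotonicity_violations: np.ndarray
    HT: float
    notes: dict = field(default_factory=dict)

    @property
    def residual_flag_summary(self) -> str:
        """Count (percentage) of flagged pairs, e.g. ``"1 (3.6)"``."""
        k = len(self.residual_pairs)
        pct = 100.0 * k / self.n_pairs if self.n_pairs else 0.0
        return f"{k} ({pct:.1f})"

    def verdicts(self) -> dict:
        return {
            "cfi_good": self.cfi >= 0.95,
            "tli_good": self.tli >= 0.95,
            "rmsea_good": self.rmsea <= 0.06,
            "srmr_good": self.srmr <= 0.08,
            "ecv_supportive": self.ecv >= 0.70,
            "omega_h_supportive": self.omega_h >= 0.80,
            "H_acceptable": self.H >= 0.50,
            "Hi_acceptable": bool(np.all(self.Hi >= 0.30)),
            "iio_band": ht_band(self.HT),
        }


def ht_band(ht: float) -> str:
    """Accuracy band for the item-ordering coefficient HT."""
    if not np.isfinite(ht):
        return "undefined"
    if ht < 0.30:
        return "inaccurate ordering"
    if ht < 0.40:
        return "low accuracy"
    if ht < 0.50:
        return "medium accuracy"
    return "high accuracy"


# ---------------------------------------------------------------------------
# bivariate normal CDF (Drezner-Wesolowsky single-integral form)
# ---------------------------------------------------------------------------

_GL_NODES, _GL_WEIGHTS = np.polynomial.legendre.leggauss(24)


def bvn_cdf(x, y, rho: float) -> np.ndarray:
    """Standard bivariate normal CDF P(X<=x, Y<=y) with correlation rho.

    Uses the single-integral representation
    Phi2(x,y,rho) = Phi(x)Phi(y) + (1/2pi) * int_0^rho
    exp(-(x^2 - 2txy + y^2)/(2(1-t^2))) / sqrt(1-t^2) dt,
    evaluated by 24-point Gauss-Legendre; vectorized over x, y.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    x, y = np.broadcast_arrays(x, y)
    out = norm.cdf(x) * norm.cdf(y)
    if rho == 0:
        return out
    t = 0.5 * rho * (_GL_NODES + 1.0)  # map [-1,1] -> [0, rho]
    w = 0.5 * abs(rho) * _GL_WEIGHTS * np.sign(rho)
    xx = x[..., None]
    yy = y[..., None]
    with np.errstate(over="ignore", invalid="ignore"):
        integrand = np.exp(
            -(xx**2 - 2 * t * xx * yy + yy**2) / (2 * (1 - t**2))
        ) / np.sqrt(1 - t**2)
    integrand = np.nan_to_num(integrand)
    out = out + (integrand @ w) / (2 * np.pi)
    return np.clip(out, 0.0, 1.0)


# ---------------------------------------------------------------------------
# polychoric correlations
# ---------------------------------------------------------------------------


def _thresholds(col: np.ndarray) -> np.ndarray:
    """Interior inverse-normal thresholds from cumulative marginals."""
    K = col.max() + 1
    cum = np.array([(col < k).mean() for k in range(1, K)])
    return norm.ppf(np.clip(cum, 1e-6, 1 - 1e-6))


def polychoric_pair(x: np.ndarray, y: np.ndarray) -> float:
    """ML polychoric correlation for two ordinal variables (given thresholds)."""
    x = np.asarray(x, dtype=int)
    y = np.asarray(y, dtype=int)
    Kx, Ky = x.max() + 1, y.max() + 1
    table = np.zeros((Kx, Ky))
    np.add.at(table, (x, y), 1.0)
    tx = np.concatenate([[-np.inf], _thresholds(x), [np.inf]])
    ty = np.concatenate([[-np.inf], _thresholds(y), [np.inf]])
    gx, gy = np.meshgrid(tx, ty, indexing="ij")

    def negll(rho):
        F = bvn_cdf(gx, gy, rho)
        cells = F[1:, 1:] - F[:-1, 1:] - F[1:, :-1] + F[:-1, :-1]
        return -np.sum(table * np.log(np.clip(cells, 1e-300, None)))

    res = optimize.minimize_scalar(negll, bounds=(-0.999, 0.999), method="bounded")
    return float(res.x)


def polychoric_matrix(responses: np.ndarray):
    """Pairwise ML polychoric correlation matrix plus per-item thresholds.

    Items with empty interior categories are collapsed to observed
    categories first (mapping is implicit in the thresholds).
    """
    X = np.asarray(responses, dtype=int)
    n, p = X.shape
    # collapse to observed categories per item
    Xc = np.empty_like(X)
    for j in range(p):
        _, Xc[:, j] = np.unique(X[:, j], return_inverse=True)
        if Xc[:, j].max() == 0:
            raise ValueError(f"item {j}: single observed category")
    R = np.eye(p)
    for i in range(p):
        for j in range(i + 1, p):
            R[i, j] = R[j, i] = polychoric_pair(Xc[:, i], Xc[:, j])
    thresholds = [_thresholds(Xc[:, j]) for j in range(p)]
    return R, thresholds


def nearest_psd(R: np.ndarray, eps: float = 1e-8) -> np.ndarray:
    """Project a symmetric matrix to the nearest PSD correlation matrix."""
    vals, vecs = np.linalg.eigh((R + R.T) / 2)
    if vals.min() >= eps:
        return R
    vals = np.clip(vals, eps, None)
    S = vecs @ np.diag(vals) @ vecs.T
    d = np.sqrt(np.diag(S))
    return S / np.outer(d, d)


# ---------------------------------------------------------------------------
# factor analysis machinery (minres)
# ---------------------------------------------------------------------------


def _minres_loadings(R: np.ndarray, m: int, seed: int = 0) -> np.ndarray:
    """Least-squares m-factor loadings: minimize off-diagonal residual SS."""
    p = R.shape[0]
    off = ~np.eye(p, dtype=bool)
    vals, vecs = np.linalg.eigh(R)
    order = np.argsort(vals)[::-1][:m]
    L0 = vecs[:, order] * np.sqrt(np.clip(vals[order], 1e-6, None))

    def loss_grad(flat):
        L = flat.reshape(p, m)
        E = (R - L @ L.T) * off
        return float(np.sum(E**2)), (-4.0 * E @ L).ravel()

    res = optimize.minimize(loss_grad, L0.ravel(), jac=True, method="L-BFGS-B")
    L = res.x.reshape(p, m)
    # sign convention: positive column sums
    L *= np.where(L.sum(axis=0) < 0, -1.0, 1.0)
    return L


def single_factor_fit(polychoric: np.ndarray, n_persons: int, n_items: int | None = None):
    """One-factor solution with unscaled ML-discrepancy fit indices.

    Returns (loadings, fit) where fit has keys cfi, tli, rmsea, srmr,
    chi2, df and the threshold verdicts.  The chi-square uses the ML
    discrepancy F = log|Sigma| - log|S| + tr(S Sigma^-1) - p evaluated on
    the (smoothed) polychoric matrix, scaled by (n-1); the baseline is the
    zero-correlation model.
    """
    R = np.asarray(polychoric, dtype=float)
    p = R.shape[0]
    if n_items is None:
        n_items = p
    if p < 3:
        raise ValueError("a one-factor model needs at least 3 items")
    smoothed = False
    Rs = nearest_psd(R)
    if not np.allclose(Rs, R):
        smoothed = True
    lam = _minres_loadings(Rs, 1)[:, 0]
    lam = np.clip(lam, -0.999, 0.999)
    sigma = np.outer(lam, lam)
    np.fill_diagonal(sigma, 1.0)

    def f_ml(S, Sig):
        sign, logdet_sig = np.linalg.slogdet(Sig)
        _, logdet_s = np.linalg.slogdet(S)
        return logdet_sig - logdet_s + np.trace(S @ np.linalg.inv(Sig)) - p

    n1 = max(n_persons - 1, 1)
    chi2 = n1 * max(f_ml(Rs, sigma), 0.0)
    df = p * (p - 3) // 2
    chi2_b = n1 * max(f_ml(Rs, np.eye(p)), 0.0)
    df_b = p * (p - 1) // 2
    if df > 0:
        num = max(chi2 - df, 0.0)
        den = max(chi2_b - df_b, num, 1e-12)
        cfi = 1.0 - num / den
        base_ratio = chi2_b / df_b if df_b else 0.0
        tli = (base_ratio - chi2 / df) / (base_ratio - 1.0) if base_ratio > 1 else 1.0
        tli = min(tli, 1.0)
        rmsea = np.sqrt(max(chi2 - df, 0.0) / (df * n1))
    else:  # just-identified: exact fit by construction
        cfi, tli, rmsea = 1.0, 1.0, 0.0
    resid = (R - sigma)[np.triu_indices(p, 1)]
    srmr = float(np.sqrt(np.mean(resid**2)))
    fit = {
        "chi2": float(chi2),
        "df": int(df),
        "cfi": float(cfi),
        "tli": float(tli),
        "rmsea": float(rmsea),
        "srmr": srmr,
        "smoothed": smoothed,
        "scaled": False,  # unscaled analogues of the robust indices
        "cfi_good": cfi >= 0.95,
        "tli_good": tli >= 0.95,
        "rmsea_good": rmsea <= 0.06,
        "srmr_good": srmr <= 0.08,
    }
    return lam, fit


def residual_correlations(polychoric: np.ndarray, loadings: np.ndarray, flag: float = RESIDUAL_FLAG):
    """Pairs whose one-factor residual correlation exceeds the flag value.

    Returns (list of (i, j, residual), n_pairs).
    """
    R = np.asarray(polychoric, dtype=float)
    lam = np.asarray(loadings, dtype=float).ravel()
    p = R.shape[0]
    flagged = []
    for i in range(p):
        for j in range(i + 1, p):
            resid = R[i, j] - lam[i] * lam[j]
            if resid > flag:
                flagged.append((i, j, float(resid)))
    return flagged, p * (p - 1) // 2


# ---------------------------------------------------------------------------
# exploratory bifactor (Schmid-Leiman)
# ---------------------------------------------------------------------------


def _varimax(L: np.ndarray, max_iter: int = 100, tol: float = 1e-8) -> np.ndarray:
    """Varimax by Kaiser's pairwise planar rotations, with row normalization.

    The pairwise form converges from symmetric configurations where
    gradient-style updates stall.
    """
    p, m = L.shape
    h = np.sqrt(np.sum(L**2, axis=1))
    h = np.where(h < 1e-12, 1.0, h)
    A = L / h[:, None]
    for _ in range(max_iter):
        total_rotation = 0.0
        for i in range(m - 1):
            for j in range(i + 1, m):
                a, b = A[:, i], A[:, j]
                u = a**2 - b**2
                v = 2 * a * b
                num = 2 * (np.sum(u * v) - np.sum(u) * np.sum(v) / p)
                den = np.sum(u**2 - v**2) - (np.sum(u) ** 2 - np.sum(v) ** 2) / p
                phi = 0.25 * np.arctan2(num, den)
                if abs(phi) < 1e-12:
                    continue
                c, s = np.cos(phi), np.sin(phi)
                A[:, i], A[:, j] = c * a + s * b, -s * a + c * b
                total_rotation += abs(phi)
        if total_rotation < tol:
            break
    return A * h[:, None]


def _promax(L: np.ndarray, power: int = 4):
    """Promax oblique rotation; returns (pattern, factor correlation matrix).

    Follows the classic construction: varimax, power-4 target, least-squares
    transformation normalized so that factors have unit variance.
    """
    V = _varimax(L)
    Q = V * np.abs(V) ** (power - 1)  # signed power target
    U = np.linalg.lstsq(V, Q, rcond=None)[0]
    d = np.diag(np.linalg.inv(U.T @ U))
    U = U @ np.diag(np.sqrt(d))
    pattern = V @ U
    Ui = np.linalg.inv(U)
    phi = Ui @ Ui.T
    # reflect factors with negative orientation so loadings are mostly positive
    signs = np.where(pattern.sum(axis=0) < 0, -1.0, 1.0)
    pattern = pattern * signs[None, :]
    phi = phi * np.outer(signs, signs)
    return pattern, phi


def bifactor_indices_from_loadings(general: np.ndarray, group: np.ndarray):
    """Exact ECV and omega-hierarchical from a known bifactor loading matrix.

    ``general`` is (p,), ``group`` is (p, m) with zeros off the item's
    group factor.  ECV = sum(g^2) / (sum(g^2) + sum(s^2)); omega_h uses the
    summed-scale decomposition on the correlation metric.
    """
    g = np.asarray(general, dtype=float).ravel()
    S = np.atleast_2d(np.asarray(group, dtype=float))
    if S.shape[0] != g.size:
        S = S.T
    ecv = float(np.sum(g**2) / (np.sum(g**2) + np.sum(S**2)))
    uniq = np.clip(1.0 - g**2 - np.sum(S**2, axis=1), 0.0, None)
    total = g.sum() ** 2 + np.sum(S.sum(axis=0) ** 2) + uniq.sum()
    omega_h = float(g.sum() ** 2 / total)
    return ecv, omega_h


def bifactor_indices(responses=None, polychoric=None, n_group_factors: int = 2):
    """Exploratory bifactor ECV and omega-h from data or a polychoric matrix.

    minres extraction of ``n_group_factors`` oblique factors, promax
    rotation, a second-order general factor on the factor correlations,
    then Schmid-Leiman orthogonalization.
    """
    if polychoric is None:
        if responses is None:
            raise ValueError("provide responses or a polychoric matrix")
        polychoric, _ = polychoric_matrix(responses)
    R = nearest_psd(np.asarray(polychoric, dtype=float))
    p = R.shape[0]
    m = n_group_factors
    if p < 3 * m:
        m = max(p // 3, 1)
    if m < 2:
        # with a single group factor the SL general factor is the factor itself
        lam = _minres_loadings(R, 1)[:, 0]
        return bifactor_indices_from_loadings(lam, np.zeros((p, 1)))
    L = _minres_loadings(R, m)
    pattern, phi = _promax(L)
    # second-order general factor on the factor correlation matrix
    if m == 2:
        g2 = np.sqrt(np.clip(abs(phi[0, 1]), 1e-6, 1.0))
        gload = np.array([g2, g2])
    else:
        gload = np.clip(_minres_loadings(nearest_psd(phi), 1)[:, 0], 1e-6, 0.999)
    general = pattern @ gload
    group = pattern * np.sqrt(np.clip(1.0 - gload**2, 0.0, None))[None, :]
    return bifactor_indices_from_loadings(general, group)


# ---------------------------------------------------------------------------
# Mokken scalability, monotonicity, invariant item ordering
# ---------------------------------------------------------------------------


def mokken_coefficients(responses: np.ndarray):
    """Scalability coefficients: H (scale), Hi (items), Hij (pairs).

    H_ij = cov(X_i, X_j) / cov_max(X_i, X_j), where cov_max is attained by
    the comonotone coupling of the two observed marginals (sorted-sample
    matching).  Hi and H are ratio-of-sums aggregates.  Zero-variance items
    are excluded with a note.
    """
    X = np.asarray(responses, dtype=float)
    n, p = X.shape
    keep = X.std(axis=0) > 0
    excluded = list(np.where(~keep)[0])
    X = X[:, keep]
    p_eff = X.shape[1]
    if p_eff < 2:
        raise ValueError("need at least 2 items with variance")
    means = X.mean(axis=0)
    cov = np.cov(X, rowvar=False, ddof=0)
    Xs = np.sort(X, axis=0)
    emax = (Xs.T @ Xs) / n
    covmax = emax - np.outer(means, means)
    np.fill_diagonal(covmax, 1.0)  # unused diagonal
    np.fill_diagonal(cov, 1.0)
    off = ~np.eye(p_eff, dtype=bool)
    hij = np.where(off, cov / np.where(np.abs(covmax) < 1e-12, np.nan, covmax), np.nan)
    hi = np.nansum(np.where(off, cov, 0.0), axis=1) / np.nansum(np.where(off, covmax, 0.0), axis=1)
    iu = np.triu_indices(p_eff, 1)
    H = float(np.sum(cov[iu]) / np.sum(covmax[iu]))
    return {"H": H, "Hi": hi, "Hij": hij, "excluded_items": excluded}


def monotonicity_check(
    responses: np.ndarray,
    min_group_size: int | None = None,
    alpha: float = 0.05,
    min_violation: float = 0.03,
):
    """Rest-score-based monotonicity check per item.

    Persons are grouped by the rest score (sum excluding the item) into
    adjacent groups of at least ``min_group_size`` (default: n/10, at
    least 50, the usual sample-size-based rule); for each category step k,
    decreases of P(X_i >= k) across adjacent groups are counted as
    violations when they both exceed ``min_violation`` and are significant
    by a one-sided two-proportion z-test at level ``alpha``.

    Returns a dict with per-item violation counts and the number of
    checkable comparisons (zero comparisons => not checkable).
    """
    X = np.asarray(responses, dtype=int)
    n, p = X.shape
    if min_group_size is None:
        min_group_size = max(min(n // 10, n), 50)
    zcrit = norm.ppf(1 - alpha)
    violations = np.zeros(p, dtype=int)
    comparisons = np.zeros(p, dtype=int)
    total = X.sum(axis=1)
    for j in range(p):
        rest = total - X[:, j]
        order = np.argsort(rest, kind="stable")
        # split into contiguous groups of >= min_group_size
        groups = []
        start = 0
        while start < n:
            end = min(start + min_group_size, n)
            # extend so equal rest scores stay together
            while end < n and rest[order[end]] == rest[order[end - 1]]:
                end += 1
            groups.append(order[start:end])
            start = end
        if len(groups) > 1 and len(groups[-1]) < min_group_size:
            groups[-2] = np.concatenate([groups[-2], groups[-1]])
            groups.pop()
        if len(groups) < 2:
            continue
        K = X[:, j].max() + 1
        for k in range(1, K):
            ge = X[:, j] >= k
            props = [ge[g].mean() for g in groups]
            sizes = [len(g) for g in groups]
            for a in range(len(groups) - 1):
                comparisons[j] += 1
                p1, p2 = props[a], props[a + 1]
                if p1 - p2 <= min_violation:
                    continue
                pool = (p1 * sizes[a] + p2 * sizes[a + 1]) / (sizes[a] + sizes[a + 1])
                se = np.sqrt(pool * (1 - pool) * (1 / sizes[a] + 1 / sizes[a + 1]))
                if se > 0 and (p1 - p2) / se > zcrit:
                    violations[j] += 1
    return {"violations": violations, "comparisons": comparisons,
            "checkable": bool(comparisons.sum() > 0)}


def iio_ht(responses: np.ndarray) -> float:
    """Invariant-item-ordering coefficient HT.

    The H coefficient of the transposed matrix (persons as items),
    restricted to person pairs with distinct total scores; pairs with zero
    maximum covariance are excluded.  Undefined (NaN) when all persons are
    identical.
    """
    X = np.asarray(responses, dtype=float)
    n, p = X.shape
    if p < 3:
        raise ValueError("HT needs at least 3 items")
    totals = X.sum(axis=1)
    means = X.mean(axis=1)
    cov = (X @ X.T) / p - np.outer(means, means)
    Xs = np.sort(X, axis=1)
    covmax = (Xs @ Xs.T) / p - np.outer(means, means)
    distinct = np.abs(totals[:, None] - totals[None, :]) > 1e-12
    valid = distinct & (np.abs(covmax) > 1e-12)
    iu = np.triu_indices(n, 1)
    mask = valid[iu]
    if not mask.any():
        return float("nan")
    num = np.sum(cov[iu][mask])
    den = np.sum(covmax[iu][mask])
    return float(num / den) if den != 0 else float("nan")


# ---------------------------------------------------------------------------
# bundled report
# ---------------------------------------------------------------------------


def run_assumptions(
    responses: np.ndarray,
    n_group_factors: int = 2,
    min_group_size: int | None = None,
) -> AssumptionReport:
    """All assumption checks for one measure's response matrix."""
    X = np.asarray(responses, dtype=int)
    n = X.shape[0]
    R, _ = polychoric_matrix(X)
    lam, fit = single_factor_fit(R, n)
    flagged, n_pairs = residual_correlations(R, lam)
    ecv, omega_h = bifactor_indices(polychoric=R, n_group_factors=n_group_factors)
    mok = mokken_coefficients(X)
    mono = monotonicity_check(X, min_group_size=min_group_size)
    ht = iio_ht(X)
    return AssumptionReport(
        cfi=fit["cfi"], tli=fit["tli"], rmsea=fit["rmsea"], srmr=fit["srmr"],
        loadings=lam, ecv=ecv, omega_h=omega_h,
        residual_pairs=flagged, n_pairs=n_pairs,
        H=mok["H"], Hi=mok["Hi"],
        monotonicity_violations=mono["violations"], HT=ht,
        notes={"smoothed": fit["smoothed"], "scaled": fit["scaled"],
               "chi2": fit["chi2"], "df": fit["df"],
               "mokken_excluded": mok["excluded_items"],
               "monotonicity_checkable": mono["checkable"]},
    )
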