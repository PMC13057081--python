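"""Generalized Orlando-Thissen S-X2 item fit for polytomous items.

The statistic compares observed and model-implied response frequencies
conditional on the rest score (the summed score excluding the studied
item).  The model-implied joint distribution of (rest score, category) is
obtained by convolving the remaining items' category probability vectors
at each quadrature node and marginalizing against the N(0,1) prior.
Adjacent cells are collapsed until every expected count is at least 1
(from the distribution tails inward, categories before scores).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import chi2 as chi2_dist

from ._quad import QuadratureGrid, default_grid
from .grm import ItemParameters, _cat_probs_grid, eap_score, information_profile

__all__ = ["ItemFitResult", "sx2_item_fit", "rest_score_distribution", "fit_plot_data"]

MISFIT_P = 0.001  # p below this flags item misfit


@dataclass
class ItemFitResult:
    item: int
    name: str
    sx2: float
    df: int
    p_value: float
    collapsed_cells: int
    misfit: bool
    testable: bool


def _convolve_items(prob_tables: list[np.ndarray]) -> np.ndarray:
    """Distribution of the summed score across items, per quadrature node.

    ``prob_tables[j]`` is (Q, K_j); returns (Q, max_score + 1).
    """
    Q = prob_tables[0].shape[0]
    dist = np.ones((Q, 1))
    for P in prob_tables:
        K = P.shape[1]
        L = dist.shape[1]
        new = np.zeros((Q, L + K - 1))
        for k in range(K):
            new[:, k : k + L] += dist * P[:, k][:, None]
        dist = new
    return dist


def rest_score_distribution(
    params: ItemParameters, item: int, grid: QuadratureGrid | None = None
) -> np.ndarray:
    """(Q, S+1) conditional rest-score distribution f_{-j}(s | theta_q)."""
    grid = grid or default_grid()
    tables = [
        _cat_probs_grid(params.alphas[j], params.betas[j], grid.nodes)
        for j in range(params.n_items)
        if j != item
    ]
    if not tables:
        return np.ones((grid.size, 1))
    return _convolve_items(tables)


def _collapse_expected(O: np.ndarray, E: np.ndarray, min_expected: float = 1.0):
    """Collapse cells until all expected counts >= min_expected.

    Tail-inward, categories before scores: within each score row, merge the
    outermost offending category cell toward the centre; when a row cannot
    be fixed (single cell), merge the row with its neighbour toward the
    centre of the score distribution.  Rows/cells are kept as lists so the
    table may become ragged.  Totals are preserved exactly.
    """
    rows_o = [list(row) for row in O]
    rows_e = [list(row) for row in E]
    row_ids = list(range(len(rows_o)))

    def merge_cats(ro, re):
        # merge outermost low-expected cell inward; repeat until fine or single
        while len(re) > 1 and min(re) < min_expected:
            # pick offending cell closest to a tail; merge toward centre
            idx = min(range(len(re)), key=lambda i: (re[i], -min(i, len(re) - 1 - i)))
            if idx <= len(re) // 2 and idx + 1 < len(re):
                tgt = idx + 1
            else:
                tgt = idx - 1
            re[tgt] += re[idx]
            ro[tgt] += ro[idx]
            del re[idx], ro[idx]
        return ro, re

    changed = True
    while changed:
        changed = False
        for i in range(len(rows_o)):
            rows_o[i], rows_e[i] = merge_cats(rows_o[i], rows_e[i])
        bad = [i for i, re in enumerate(rows_e) if min(re) < min_expected]
        if bad and len(rows_o) > 1:
            centre = len(rows_o) / 2
            i = min(bad, key=lambda i: -abs(i - centre))  # most tail-ward row
            tgt = i + 1 if i < centre else i - 1
            tgt = max(0, min(tgt, len(rows_o) - 1))
            if tgt == i:
                break
            # merge rows cell-wise after padding to common length
            la, lb = len(rows_o[i]), len(rows_o[tgt])
            if la != lb:  # ragged: just concatenate masses into the larger row
                rows_o[tgt] = [a + b for a, b in zip(rows_o[tgt], rows_o[i][:lb])] if la >= lb else rows_o[tgt]
                if la < lb:
                    for k in range(la):
                        rows_o[tgt][k] += rows_o[i][k]
                        rows_e[tgt][k] += rows_e[i][k]
                else:
                    rest_o = sum(rows_o[i][lb:])
                    rest_e = sum(rows_e[i][lb:])
                    for k in range(lb):
                        rows_o[tgt][k] += rows_o[i][k]
                        rows_e[tgt][k] += rows_e[i][k]
                    rows_o[tgt][-1] += rest_o
                    rows_e[tgt][-1] += rest_e
            else:
                rows_o[tgt] = [a + b for a, b in zip(rows_o[tgt], rows_o[i])]
                rows_e[tgt] = [a + b for a, b in zip(rows_e[tgt], rows_e[i])]
            del rows_o[i], rows_e[i], row_ids[i]
            changed = True
        elif bad:
            break
    return rows_o, rows_e


def sx2_item_fit(
    params: ItemParameters,
    responses: np.ndarray,
    grid: QuadratureGrid | None = None,
    min_expected: float = 1.0,
) -> pd.DataFrame:
    """S-X2 statistic, df and p-value for every item of a fitted bank.

    df = (number of cells after collapsing) - (number of rows) - (number of
    free parameters of the item); items with df < 1 or a degenerate
    observed distribution are reported untestable rather than given
    p-values.  Misfit is flagged at p < 0.001.
    """
    grid = grid or default_grid()
    X = np.asarray(responses, dtype=int)
    n, p = X.shape
    if p != params.n_items:
        raise ValueError("response matrix width does not match parameter set")
    total = X.sum(axis=1)
    results = []
    for j in range(p):
        K = params.n_categories[j]
        if np.unique(X[:, j]).size < 2:
            results.append(
                ItemFitResult(j, params.item_names[j], np.nan, 0, np.nan, 0, False, False)
            )
            continue
        rest = total - X[:, j]
        S = int(sum(params.n_categories) - params.n_categories[j] - (p - 1))
        # observed counts
        O = np.zeros((S + 1, K))
        np.add.at(O, (rest, X[:, j]), 1.0)
        # model-implied joint p(s, k) by quadrature
        f_rest = rest_score_distribution(params, j, grid)  # (Q, S+1)
        P_item = _cat_probs_grid(params.alphas[j], params.betas[j], grid.nodes)  # (Q, K)
        joint = np.einsum("q,qs,qk->sk", grid.weights, f_rest, P_item)
        p_s = joint.sum(axis=1, keepdims=True)
        with np.errstate(invalid="ignore", divide="ignore"):
            cond = np.where(p_s > 0, joint / p_s, 1.0 / K)
        E = O.sum(axis=1, keepdims=True) * cond
        # drop empty score rows (no observations)
        keep = O.sum(axis=1) > 0
        rows_o, rows_e = _collapse_expected(O[keep], E[keep], min_expected)
        n_cells = sum(len(r) for r in rows_o)
        n_rows = len(rows_o)
        n_params = K  # one discrimination + K-1 thresholds
        df = n_cells - n_rows - n_params
        chi2 = float(
            sum(
                (o - e) ** 2 / e
                for ro, re in zip(rows_o, rows_e)
                for o, e in zip(ro, re)
            )
        )
        collapsed = int(O[keep].size - n_cells)
        if df < 1:
            results.append(
                ItemFitResult(j, params.item_names[j], chi2, 0, np.nan, collapsed, False, False)
            )
        else:
            pval = float(chi2_dist.sf(chi2, df))
            results.append(
                ItemFitResult(
                    j, params.item_names[j], chi2, df, pval, collapsed, pval < MISFIT_P, True
                )
            )
    return pd.DataFrame([r.__dict__ for r in results])


def fit_plot_data(
    params: ItemParameters,
    responses: np.ndarray,
    item: int,
    n_groups: int = 10,
    grid: QuadratureGrid | None = None,
    negligible_bound: float = 0.10,
):
    """Observed vs expected category proportions across theta-score bins.

    Persons are binned into ``n_groups`` by their EAP theta (empty bins are
    merged, recorded in the output); per bin the observed category
    proportions are compared with the model-expected proportions at the
    bin mean theta.  The item's information curve is attached, plus a
    "negligible misfit" heuristic: max |obs - exp| below
    ``negligible_bound`` with logically ordered expected curves.

    Returns a dict with a per-bin DataFrame, the information curve and the
    heuristic flag.
    """
    grid = grid or default_grid()
    X = np.asarray(responses, dtype=int)
    theta, _ = eap_score(X, params, grid)
    edges = np.quantile(theta, np.linspace(0, 1, n_groups + 1))
    edges[0] -= 1e-9
    bins = np.clip(np.searchsorted(edges, theta, side="right") - 1, 0, n_groups - 1)
    K = params.n_categories[item]
    rows = []
    merged = 0
    for b in range(n_groups):
        mask = bins == b
        if mask.sum() == 0:
            merged += 1
            continue
        tmean = float(theta[mask].mean())
        obs = np.bincount(X[mask, item], minlength=K) / mask.sum()
        exp = _cat_probs_grid(params.alphas[item], params.betas[item], np.array([tmean]))[0]
        rows.append(
            {
                "bin": b,
                "n": int(mask.sum()),
                "theta_mean": tmean,
                **{f"obs_{k}": obs[k] for k in range(K)},
                **{f"exp_{k}": exp[k] for k in range(K)},
            }
        )
    table = pd.DataFrame(rows)
    max_dev = float(
        max(
            abs(table[f"obs_{k}"] - table[f"exp_{k}"]).max()
            for k in range(K)
        )
    )
    info = information_profile(params.subset([item]))
    return {
        "table": table,
        "max_abs_deviation": max_dev,
        "negligible": max_dev < negligible_bound,
        "merged_bins": merged,
        "information_theta": info.theta,
        "information": info.test_information,
    }
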