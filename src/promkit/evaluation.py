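"""Reliability, efficiency, construct validity and reference-value tables.

Reliability summaries count persons whose SE(theta) is at or below 0.32
(reliability >= 0.90), in the total sample and after excluding persons at
the best-possible-functioning raw-score extreme (ceiling).  Efficiency is
information per item, E = (1 - SE^2) / n_items; relative efficiency is a
ratio of mean efficiencies with percentile bootstrap confidence
intervals.  Construct validity checks observed Pearson correlations
against hypothesized bounds; reference values are mean (SD) T-scores per
demographic subgroup, with a version crosswalk that re-scores the same
responses under a second anchor parameter set / item subset.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._quad import QuadratureGrid, default_grid
from .grm import ItemParameters, eap_score, score_table, t_transform

__all__ = [
    "ReliabilitySummary",
    "EfficiencyComparison",
    "reliability_summary",
    "efficiency",
    "relative_efficiency",
    "construct_validity",
    "reference_values",
    "version_crosswalk",
]

SE_RELIABLE = 0.32


@dataclass
class ReliabilitySummary:
    mean_se: float
    pct_reliable: float
    n_items: float
    n_persons: int
    subgroup: str  # "total" | "ceiling_excluded"


@dataclass
class EfficiencyComparison:
    ratio: float
    ci_low: float
    ci_high: float
    theta_range_a: tuple[float, float]
    theta_range_b: tuple[float, float]


def _ceiling_mask(raw_sum: np.ndarray, max_raw: int, direction: str) -> np.ndarray:
    """True for persons at the best-possible-functioning raw extreme.

    For symptom-coded measures (higher theta = worse) the best functioning
    is the minimum raw score; for function-coded measures the maximum.
    """
    raw = np.asarray(raw_sum)
    if direction == "symptom":
        return raw == 0
    if direction == "function":
        return raw == max_raw
    raise ValueError("direction must be 'symptom' or 'function'")


def reliability_summary(
    scores: pd.DataFrame,
    n_items: float,
    direction: str = "symptom",
    exclude_ceiling: bool = False,
    max_raw: int | None = None,
) -> ReliabilitySummary:
    """Mean SE(theta) and % of reliable scores, optionally without ceiling.

    ``scores`` must carry ``se_theta`` and ``raw_sum`` columns; ``max_raw``
    is the bank's maximum possible raw sum (required for function-coded
    ceiling exclusion).
    """
    if len(scores) == 0:
        raise ValueError("empty score table")
    sub = "total"
    df = scores
    if exclude_ceiling:
        if max_raw is None:
            max_raw = int(scores["raw_sum"].max())
        mask = _ceiling_mask(scores["raw_sum"].to_numpy(), max_raw, direction)
        df = scores.loc[~mask]
        sub = "ceiling_excluded"
        if len(df) == 0:
            raise ValueError("no persons left after ceiling exclusion")
    se = df["se_theta"].to_numpy()
    return ReliabilitySummary(
        mean_se=float(se.mean()),
        pct_reliable=float(100 * np.mean(se <= SE_RELIABLE)),
        n_items=float(n_items),
        n_persons=int(len(df)),
        subgroup=sub,
    )


def efficiency(se, n_items) -> np.ndarray:
    """Per-person information per item: E = (1 - SE^2) / n_items.

    SEs above 1 (prior-dominated scores) are floored at efficiency 0.
    """
    se = np.asarray(se, dtype=float)
    n_items = np.asarray(n_items, dtype=float)
    if np.any(n_items < 1):
        raise ValueError("n_items must be >= 1")
    if np.any(se <= 0):
        raise ValueError("se must be positive")
    return np.clip((1.0 - se**2), 0.0, None) / n_items


def relative_efficiency(
    se_a,
    n_items_a,
    se_b,
    n_items_b,
    theta_a=None,
    theta_b=None,
    n_boot: int = 1000,
    seed: int = 0,
) -> EfficiencyComparison:
    """Ratio of mean efficiencies (b over a) with bootstrap 95% CI.

    A ratio above 1 means application b extracts more information per item
    than a.  The percentile bootstrap resamples persons (paired across
    both applications, 1,000 resamples by default).
    """
    e_a = efficiency(se_a, n_items_a)
    e_b = efficiency(se_b, n_items_b)
    if e_a.shape != e_b.shape:
        raise ValueError("applications must cover the same persons")
    n = e_a.size
    ratio = float(e_b.mean() / e_a.mean())
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, n, size=(n_boot, n))
    boots = e_b[idx].mean(axis=1) / e_a[idx].mean(axis=1)
    lo, hi = np.percentile(boots, [2.5, 97.5])
    rng_a = (float(np.min(theta_a)), float(np.max(theta_a))) if theta_a is not None else (np.nan, np.nan)
    rng_b = (float(np.min(theta_b)), float(np.max(theta_b))) if theta_b is not None else (np.nan, np.nan)
    return EfficiencyComparison(ratio, float(lo), float(hi), rng_a, rng_b)


def construct_validity(
    t_scores: dict | pd.DataFrame,
    legacy_scores: dict | pd.DataFrame,
    hypotheses: list[dict],
) -> pd.DataFrame:
    """Check hypothesized correlation strengths against observed |r|.

    ``hypotheses`` rows: {"measure": ..., "legacy": ..., "expected_threshold":
    0.50, "expected_strength": "strong"}.  A hypothesis is met when the
    observed |r| exceeds its bound; mismatches are marked.
    """
    t_scores = pd.DataFrame(t_scores)
    legacy_scores = pd.DataFrame(legacy_scores)
    rows = []
    for h in hypotheses:
        x = t_scores[h["measure"]].to_numpy(dtype=float)
        y = legacy_scores[h["legacy"]].to_numpy(dtype=float)
        if x.size < 3:
            raise ValueError("need at least 3 paired scores")
        if np.std(x) == 0 or np.std(y) == 0:
            r = np.nan
            met = False
            note = "zero variance"
        else:
            r = abs(float(np.corrcoef(x, y)[0, 1]))
            met = r > h["expected_threshold"]
            note = "" if met else "mismatch"
        rows.append(
            {
                "measure": h["measure"],
                "legacy": h["legacy"],
                "expected_threshold": h["expected_threshold"],
                "expected_strength": h.get("expected_strength", ""),
                "observed_r": r,
                "met": met,
                "note": note,
            }
        )
    return pd.DataFrame(rows)


def reference_values(
    scores: pd.DataFrame,
    covariates: pd.DataFrame,
    groupings: dict[str, str] | None = None,
    value_col: str = "t_score",
) -> pd.DataFrame:
    """Mean (SD) scores per demographic subgroup plus the total sample.

    ``groupings`` maps output labels to covariate columns, e.g.
    {"child_sex": "child_sex", "parent_sex": "parent_sex"}.  Subgroups with
    no members are omitted with a note row.  Works for T-scores and, for
    single-item measures, for raw scores via ``value_col``.
    """
    groupings = groupings or {}
    v = scores[value_col].to_numpy(dtype=float)
    se = scores["se_theta"].to_numpy(dtype=float) if "se_theta" in scores else None
    rows = [
        {
            "grouping": "total",
            "level": "all",
            "n": v.size,
            "mean": float(v.mean()),
            "sd": float(v.std(ddof=1)) if v.size > 1 else 0.0,
            "mean_se_theta": float(se.mean()) if se is not None else np.nan,
        }
    ]
    for label, col in groupings.items():
        for level, idx in covariates.groupby(covariates[col].astype(str)).groups.items():
            pos = covariates.index.get_indexer(idx)
            sub = v[pos]
            rows.append(
                {
                    "grouping": label,
                    "level": str(level),
                    "n": sub.size,
                    "mean": float(sub.mean()) if sub.size else np.nan,
                    "sd": float(sub.std(ddof=1)) if sub.size > 1 else 0.0,
                    "mean_se_theta": float(se[pos].mean()) if se is not None and sub.size else np.nan,
                }
            )
    return pd.DataFrame(rows)


def version_crosswalk(
    responses: np.ndarray,
    anchor_a: ItemParameters,
    items_a,
    anchor_b: ItemParameters,
    items_b,
    grid: QuadratureGrid | None = None,
):
    """Score the same persons under two anchor sets / item subsets.

    ``items_a``/``items_b`` index columns of ``responses``; ``anchor_a``
    and ``anchor_b`` must match those subsets.  Returns paired score
    tables and a comparison row with mean (SD) T and mean SE(theta) per
    version (SE also displayed in T units, 10 x SE(theta)); the b-version
    is flagged provisional when its subset omits items of a.
    """
    if len(list(items_a)) == 0 or len(list(items_b)) == 0:
        raise ValueError("empty item subset")
    grid = grid or default_grid()
    X = np.asarray(responses, dtype=int)
    tab_a = score_table(X[:, list(items_a)], anchor_a, grid)
    tab_b = score_table(X[:, list(items_b)], anchor_b, grid)
    provisional = len(set(items_a) - set(items_b)) > 0
    comparison = {
        "mean_t_a": float(tab_a.t_score.mean()),
        "sd_t_a": float(tab_a.t_score.std(ddof=1)),
        "mean_se_theta_a": float(tab_a.se_theta.mean()),
        "mean_se_t_units_a": float(10 * tab_a.se_theta.mean()),
        "mean_t_b": float(tab_b.t_score.mean()),
        "sd_t_b": float(tab_b.t_score.std(ddof=1)),
        "mean_se_theta_b": float(tab_b.se_theta.mean()),
        "mean_se_t_units_b": float(10 * tab_b.se_theta.mean()),
        "provisional_b": provisional,
    }
    return tab_a, tab_b, comparison
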