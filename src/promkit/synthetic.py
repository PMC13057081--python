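"""Synthetic study generator: item banks, traits, responses, DIF, legacy scale.

This module produces every input the evaluation pipeline needs with known
ground truth: calibrated-looking item banks for parent-proxy measures,
latent traits with an optional excess of respondents at the best-possible
functioning extreme (ceiling), GRM responses with injected group-specific
DIF, a correlated 0-100 legacy instrument, and a demographically stratified
reference subsample.  A single study seed fans out to independent
per-operation child seeds.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .grm import ItemParameters, _cat_probs_grid

__all__ = [
    "BankSpec",
    "PopulationSpec",
    "DIFSpec",
    "ResponseMatrix",
    "generate_item_bank",
    "simulate_thetas",
    "simulate_responses",
    "simulate_legacy_scale",
    "draw_reference_sample",
    "child_seed",
    "default_covariate_margins",
    "study_measures",
]


def child_seed(seed: int, stage: str) -> int:
    """Derive a stable per-stage child seed (< 2^31) from a study seed."""
    tag = zlib.crc32(stage.encode()) % (2**31)
    ss = np.random.SeedSequence([int(seed) % (2**31), tag])
    return int(ss.generate_state(1)[0] % (2**31))


# ---------------------------------------------------------------------------
# specifications
# ---------------------------------------------------------------------------


@dataclass
class BankSpec:
    """Structure of one synthetic item bank.

    ``direction`` follows PROM conventions: for a "symptom" measure a higher
    trait means worse health (best functioning = minimum raw score), for a
    "function" measure a higher trait means better health (best functioning
    = maximum raw score).
    """

    n_items: int
    n_categories: int = 5
    alpha_range: tuple[float, float] = (0.9, 3.0)
    threshold_span: tuple[float, float] = (-2.5, 2.5)
    short_form_items: tuple[int, ...] | None = None
    version_subsets: dict[str, tuple[int, ...]] = field(default_factory=dict)
    direction: str = "symptom"
    name: str = "measure"

    def __post_init__(self) -> None:
        if self.n_categories < 2:
            raise ValueError("n_categories must be >= 2")
        lo, hi = self.alpha_range
        if lo <= 0 or hi <= 0 or hi < lo:
            raise ValueError("alpha_range must be positive with lo <= hi")
        if self.direction not in ("symptom", "function"):
            raise ValueError("direction must be 'symptom' or 'function'")
        for name, subset in {"short_form": self.short_form_items or (), **self.version_subsets}.items():
            if any(i < 0 or i >= self.n_items for i in subset):
                raise ValueError(f"subset {name!r} references items outside the bank")


@dataclass
class PopulationSpec:
    """Latent-trait population and demographic margins.

    ``ceiling_mass`` is the proportion of persons relocated into a narrow
    component beyond the best-functioning end of the bank's informative
    range, emulating the excess of best-possible scores seen in
    general-population parent-proxy data.
    """

    n_persons: int = 529
    theta_mean: float = 0.0
    theta_sd: float = 1.0
    skew_shape: float = 0.0  # skew-normal shape; 0 = normal
    ceiling_mass: float = 0.0
    ceiling_direction: str = "symptom"  # which extreme is "best functioning"
    covariate_margins: dict[str, dict[str, float]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.n_persons < 1:
            raise ValueError("n_persons must be >= 1")
        if not 0 <= self.ceiling_mass <= 1:
            raise ValueError("ceiling_mass must be in [0, 1]")
        for cov, margins in self.covariate_margins.items():
            total = sum(margins.values())
            if any(p < 0 or p > 1 for p in margins.values()) or abs(total - 1) > 1e-8:
                raise ValueError(f"margins for {cov!r} must be in [0,1] and sum to 1")


@dataclass
class DIFSpec:
    """Group-specific distortion of one item.

    ``uniform_shift`` is added to every threshold for persons at
    ``affected_level`` of ``group_covariate`` (uniform DIF);
    ``alpha_multiplier`` rescales the discrimination (non-uniform DIF).
    """

    item_index: int
    group_covariate: str
    affected_level: str
    uniform_shift: float = 0.0
    alpha_multiplier: float = 1.0

    def __post_init__(self) -> None:
        if self.alpha_multiplier <= 0:
            raise ValueError("alpha_multiplier must be positive")


@dataclass
class ResponseMatrix:
    """Persons x items integer category table plus covariates.

    Categories are coded 0..K-1 internally; file readers accept 1-based
    data and re-base (recorded in metadata).
    """

    data: np.ndarray
    item_names: list[str]
    covariates: pd.DataFrame | None = None
    person_id: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=int)
        if self.person_id is None:
            self.person_id = np.arange(self.data.shape[0])
        if self.covariates is not None and len(self.covariates) != self.data.shape[0]:
            raise ValueError("covariates must have one row per person")

    @property
    def n_persons(self) -> int:
        return self.data.shape[0]

    @property
    def n_items(self) -> int:
        return self.data.shape[1]

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.data, columns=self.item_names)
        df.insert(0, "person_id", self.person_id)
        if self.covariates is not None:
            df = pd.concat([df, self.covariates.reset_index(drop=True)], axis=1)
        return df


# ---------------------------------------------------------------------------
# generators
# ---------------------------------------------------------------------------


def generate_item_bank(spec: BankSpec, seed: int) -> ItemParameters:
    """Draw a bank of GRM item parameters.

    Discriminations are uniform on ``alpha_range``.  Each item's K-1
    thresholds are strictly increasing and the bank spans
    ``threshold_span``: item threshold centres are spread over the span and
    within-item steps are jittered around an equal spacing.
    """
    rng = np.random.default_rng(seed)
    p, K = spec.n_items, spec.n_categories
    lo, hi = spec.threshold_span
    alphas = rng.uniform(*spec.alpha_range, size=p)
    betas = []
    span = max(hi - lo, 1e-9)
    centers = rng.uniform(lo + 0.15 * span, hi - 0.15 * span, size=p) if span > 1e-9 else np.full(p, lo)
    for j in range(p):
        if K == 2:
            b = np.array([centers[j]])
        else:
            width = span * rng.uniform(0.35, 0.7) if span > 1e-9 else 0.0
            steps = rng.uniform(0.5, 1.5, size=K - 2)
            steps = steps / steps.sum() * width if width > 0 else steps * 0.0
            b = centers[j] - width / 2 + np.concatenate([[0.0], np.cumsum(steps)])
            if width == 0.0:
                b = b + 1e-9 * np.arange(K - 1) if span < 1e-9 else b
        # degenerate span: force exact values but keep strict ordering
        if span <= 1e-9:
            b = lo + 1e-9 * np.arange(K - 1)
        b = np.maximum.accumulate(b + 1e-9 * np.arange(K - 1))
        for k in range(1, b.size):
            if b[k] <= b[k - 1]:
                b[k] = b[k - 1] + 1e-9
        betas.append(b)
    names = [f"{spec.name}_i{j+1}" for j in range(p)]
    return ItemParameters(alphas, betas, names)


def default_covariate_margins() -> dict[str, dict[str, float]]:
    """Demographic margins emulating the Dutch general-population targets."""
    return {
        "child_age": {"5": 1 / 3, "6": 1 / 3, "7": 1 / 3},
        "child_sex": {"male": 0.513, "female": 0.487},
        "child_ethnicity": {"dutch": 0.65, "western": 0.10, "non_western": 0.25},
        "parent_sex": {"male": 0.44, "female": 0.56},
        "parent_education": {"low": 0.135, "middle": 0.36, "high": 0.505},
    }


def simulate_thetas(pop: PopulationSpec, seed: int) -> pd.DataFrame:
    """Person table with true theta and covariates.

    The latent trait is a mixture: with probability 1-ceiling_mass a
    (skew-)normal draw, otherwise a narrow N(mu_extreme, 0.25^2) component
    placed 2.5 SD toward the best-functioning extreme (lower theta for
    symptom measures, higher for function measures).
    """
    rng = np.random.default_rng(seed)
    n = pop.n_persons
    if pop.skew_shape == 0.0:
        theta = rng.normal(pop.theta_mean, pop.theta_sd, size=n)
    else:
        # skew-normal via the delta representation
        a = pop.skew_shape
        d = a / np.sqrt(1 + a**2)
        u0, u1 = rng.normal(size=n), rng.normal(size=n)
        z = d * np.abs(u0) + np.sqrt(1 - d**2) * u1
        z = (z - d * np.sqrt(2 / np.pi)) / np.sqrt(1 - 2 * d**2 / np.pi)
        theta = pop.theta_mean + pop.theta_sd * z
    if pop.ceiling_mass > 0:
        sign = -1.0 if pop.ceiling_direction == "symptom" else 1.0
        mu_extreme = pop.theta_mean + sign * 2.5 * pop.theta_sd
        at_ceiling = rng.random(n) < pop.ceiling_mass
        theta[at_ceiling] = rng.normal(mu_extreme, 0.25, size=at_ceiling.sum())
    out = {"theta": theta}
    for cov, margins in pop.covariate_margins.items():
        levels = list(margins)
        out[cov] = rng.choice(levels, size=n, p=[margins[l] for l in levels])
    df = pd.DataFrame(out)
    df.insert(0, "person_id", np.arange(n))
    return df


def simulate_responses(
    params: ItemParameters,
    persons: pd.DataFrame | np.ndarray,
    dif: list[DIFSpec] | None = None,
    seed: int = 0,
) -> ResponseMatrix:
    """Draw GRM category responses for every person x item cell.

    ``persons`` is either a theta vector or a frame with a ``theta`` column
    plus covariates (required when DIF specs reference covariates).  Forced
    completion: no missing cells are generated.
    """
    if isinstance(persons, pd.DataFrame):
        theta = persons["theta"].to_numpy(dtype=float)
        covs = persons
    else:
        theta = np.asarray(persons, dtype=float).ravel()
        covs = None
    if not np.all(np.isfinite(theta)):
        raise ValueError("theta must be finite")
    dif = dif or []
    for spec in dif:
        if spec.item_index < 0 or spec.item_index >= params.n_items:
            raise ValueError("DIF spec references an item outside the bank")
        if covs is None or spec.group_covariate not in covs.columns:
            raise ValueError(f"DIF covariate {spec.group_covariate!r} not available")
    rng = np.random.default_rng(seed)
    n, p = theta.size, params.n_items
    X = np.empty((n, p), dtype=int)
    u = rng.random((n, p))
    for j in range(p):
        alpha_j = np.full(n, params.alphas[j])
        beta_j = np.tile(params.betas[j], (n, 1))
        for spec in dif:
            if spec.item_index != j:
                continue
            mask = covs[spec.group_covariate].astype(str).to_numpy() == str(spec.affected_level)
            beta_j[mask] += spec.uniform_shift
            alpha_j[mask] *= spec.alpha_multiplier
        z = alpha_j[:, None] * (theta[:, None] - beta_j)
        pstar = 1.0 / (1.0 + np.exp(-z))
        cum = np.concatenate([np.ones((n, 1)), pstar], axis=1)  # P(X >= k)
        # X = max k such that u < P(X >= k)  <=>  count of cum[:,1:] > u
        X[:, j] = np.sum(u[:, j][:, None] < cum[:, 1:], axis=1)
    covariates = None
    if covs is not None:
        keep = [c for c in covs.columns if c not in ("theta", "person_id")]
        covariates = covs[keep].reset_index(drop=True) if keep else None
    pid = covs["person_id"].to_numpy() if covs is not None and "person_id" in covs else None
    return ResponseMatrix(X, list(params.item_names), covariates, pid)


def marginal_category_probabilities(params: ItemParameters, item: int, n_nodes: int = 201) -> np.ndarray:
    """Quadrature oracle: P(X_j = k) under theta ~ N(0,1)."""
    from scipy.stats import norm

    nodes = np.linspace(-6, 6, n_nodes)
    w = norm.pdf(nodes)
    w /= w.sum()
    P = _cat_probs_grid(params.alphas[item], params.betas[item], nodes)
    return w @ P


def simulate_legacy_scale(
    theta: np.ndarray,
    target_r: float,
    n_items: int,
    seed: int,
    n_categories: int = 5,
):
    """A legacy instrument with latent correlation ``target_r`` to theta.

    The legacy latent trait is bivariate-normal with the study trait.  Items
    are 5-category GRM responses; following classical scoring, each item is
    reverse-scored and linearly transformed to 0-100
    (score = (K-1 - response) * 100/(K-1)), higher = better functioning.

    Returns (item table DataFrame, 0-100 scale scores, legacy latent trait).
    """
    if abs(target_r) > 1:
        raise ValueError("|target_r| must be <= 1")
    theta = np.asarray(theta, dtype=float).ravel()
    rng = np.random.default_rng(seed)
    if abs(target_r) == 1.0:
        eta = np.sign(target_r) * theta
    else:
        eta = target_r * theta + np.sqrt(1 - target_r**2) * rng.normal(size=theta.size)
    bank = generate_item_bank(
        BankSpec(n_items=n_items, n_categories=n_categories, name="legacy",
                 alpha_range=(1.0, 2.2), threshold_span=(-2.0, 2.0)),
        seed=child_seed(seed, "legacy_bank"),
    )
    resp = simulate_responses(bank, eta, seed=child_seed(seed, "legacy_resp"))
    K = n_categories
    item_scores = (K - 1 - resp.data) * (100.0 / (K - 1))
    scale_scores = item_scores.mean(axis=1)
    items = pd.DataFrame(resp.data, columns=bank.item_names)
    return items, scale_scores, eta


def draw_reference_sample(
    persons: pd.DataFrame,
    population_margins: dict[str, dict[str, float]],
    max_deviation: float = 0.025,
    n_target: int | None = None,
    seed: int = 0,
):
    """Two-phase stratified subsample matching population margins.

    Phase 1 fills under-represented strata relative to the target margins;
    phase 2 fills remaining strata until ``n_target`` persons are selected.
    A covariate whose achieved proportion deviates more than
    ``max_deviation`` from its margin for any level is flagged as
    infeasible (the report mirrors the over-representation flag real panel
    samples can show).

    Returns (subsample DataFrame, deviation report DataFrame with a
    ``flagged`` column).
    """
    if len(persons) == 0:
        raise ValueError("empty person pool")
    covs = list(population_margins)
    for cov in covs:
        if cov not in persons.columns:
            raise ValueError(f"covariate {cov!r} missing from pool")
    n_target = n_target or min(len(persons), 370)
    rng = np.random.default_rng(seed)

    labels = {cov: persons[cov].astype(str).to_numpy() for cov in covs}
    counts = {(cov, str(l)): 0 for cov in covs for l in population_margins[cov]}
    # candidate indices per stratum, pre-shuffled for random within-stratum picks
    candidates = {}
    for cov in covs:
        for level in population_margins[cov]:
            idx = np.where(labels[cov] == str(level))[0]
            rng.shuffle(idx)
            candidates[(cov, str(level))] = list(idx)
    taken = np.zeros(len(persons), dtype=bool)
    selected: list[int] = []
    exhausted: set = set()

    def deficits():
        # shortfall in *counts* against the final subsample's target counts
        return {
            (cov, str(l)): pi * n_target - counts[(cov, str(l))]
            for cov in covs
            for l, pi in population_margins[cov].items()
        }

    def take(i: int) -> None:
        taken[i] = True
        selected.append(i)
        for cov in covs:
            counts[(cov, labels[cov][i])] += 1

    # phase 1: repeatedly draw from the most under-represented stratum
    while len(selected) < n_target:
        open_deficits = {k: v for k, v in deficits().items() if k not in exhausted}
        if not open_deficits or max(open_deficits.values()) <= 0:
            break  # nothing under-represented; proceed to phase 2
        key, _ = max(open_deficits.items(), key=lambda kv: kv[1])
        pool = candidates[key]
        while pool and taken[pool[-1]]:
            pool.pop()
        if not pool:
            exhausted.add(key)
            continue
        take(pool.pop())
    # phase 2: fill from the remaining pool at random
    remaining = np.where(~taken)[0]
    rng.shuffle(remaining)
    for i in remaining[: max(n_target - len(selected), 0)]:
        take(int(i))
    selected = [int(persons.index[i]) for i in selected]

    sub = persons.loc[selected]
    rows = []
    for cov in covs:
        achieved = sub[cov].astype(str).value_counts(normalize=True)
        worst = 0.0
        for level, pi in population_margins[cov].items():
            worst = max(worst, abs(achieved.get(str(level), 0.0) - pi))
        rows.append({"covariate": cov, "max_abs_deviation": worst,
                     "flagged": worst > max_deviation})
    report = pd.DataFrame(rows)
    return sub.reset_index(drop=True), report


# ---------------------------------------------------------------------------
# the emulated study conditions
# ---------------------------------------------------------------------------


def study_measures() -> dict[str, dict]:
    """Bank structure and ceiling mass for the eight emulated measures.

    Sizes mirror the published parent-proxy banks and short forms; ceiling
    masses reproduce each measure's share of best-possible raw scores
    (derived from the reported subgroup sizes after ceiling exclusion at
    n = 529).  All measures are symptom-coded except mobility, which is
    function-coded and carries the heavy ceiling that limits its precision
    at high functioning.
    """
    def sf(n):
        return tuple(range(n))

    return {
        "global_health": {"spec": BankSpec(8, short_form_items=None, direction="function",
                                           name="global_health"), "ceiling_mass": 0.017},
        "anxiety": {"spec": BankSpec(13, short_form_items=sf(8),
                                     version_subsets={"v2.0": tuple(range(13))},
                                     name="anxiety"), "ceiling_mass": 0.113},
        "depressive_symptoms": {"spec": BankSpec(13, short_form_items=sf(6),
                                                 version_subsets={"v2.0": tuple(range(13))},
                                                 name="depressive_symptoms"), "ceiling_mass": 0.197},
        "anger": {"spec": BankSpec(5, name="anger"), "ceiling_mass": 0.091},
        "peer_relationships": {"spec": BankSpec(14, short_form_items=sf(7),
                                                version_subsets={"v2.0": tuple(range(13))},
                                                direction="function",
                                                name="peer_relationships"), "ceiling_mass": 0.100},
        "mobility": {"spec": BankSpec(20, short_form_items=sf(7),
                                      version_subsets={"v2.0": tuple(range(17))},
                                      direction="function",
                                      threshold_span=(-3.0, 0.5),
                                      name="mobility"), "ceiling_mass": 0.371},
        "fatigue": {"spec": BankSpec(23, short_form_items=sf(10),
                                     version_subsets={"v2.0": tuple(range(23))},
                                     name="fatigue"), "ceiling_mass": 0.229},
        "sleep_disturbance": {"spec": BankSpec(15, short_form_items=sf(8),
                                               name="sleep_disturbance"), "ceiling_mass": 0.070},
    }
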