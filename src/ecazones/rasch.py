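"""Polytomous Rasch (rating-scale) measurement of soil fertility.

Nine heterogeneous soil properties (sand, clay, silt, OM, pH, P2O5, K2O,
SEB, CEC) measured at each sampling location are first recoded to a
common 1..m ordinal rating (category 1 = lowest contribution to soil
fertility). The rating-scale model then places samples ("persons",
fertility measure B_n) and properties ("items", difficulty d_i) on one
logit scale with a single set of category thresholds tau_k shared across
items:

    P(X_ni = k) ∝ exp( sum_{j<k} (B_n − d_i − tau_j) ),   k = 1..m,

which reduces at m = 2 to the dichotomous form
P = exp(B−d) / (1 + exp(B−d)). Estimation is joint maximum likelihood
(JMLE): Newton updates of each B_n equating observed and expected raw
scores, alternated with quasi-Newton updates of the item difficulties
and thresholds. Identification: mean(d_i) = 0 and sum(tau_k) = 0 (without
the threshold constraint the likelihood is invariant to shifting all B
and tau_1 together). Extreme raw scores, which have no finite ML
measure, are pulled 0.3 score points inward and solved, flagged as
extrapolated.

Fit is diagnosed with the information-weighted (Infit) and unweighted
(Outfit) mean-square residual statistics; values near 1 indicate data
consistent with the model, with 0.6–1.5 the conventional acceptance
band.
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np
import pandas as pd
from scipy import optimize, special

__all__ = [
    "SOIL_PROPERTIES",
    "DEFAULT_POLARITY",
    "CategoryMatrix",
    "RaschFit",
    "categorize",
    "dichotomous_probability",
    "category_probabilities",
    "fit_rating_scale",
    "fit_statistics",
    "measures_by_zone",
]

SOIL_PROPERTIES = [
    "sand", "clay", "silt", "om", "ph", "p2o5", "k2o", "seb", "cec",
]

# High sand = coarse texture = low water/nutrient holding, so sand is
# reverse-scored; every other property contributes positively.
DEFAULT_POLARITY = {name: (name != "sand") for name in SOIL_PROPERTIES}

MNSQ_ACCEPT_LOW = 0.6
MNSQ_ACCEPT_HIGH = 1.5


@dataclasses.dataclass
class CategoryMatrix:
    """N×I ordinal ratings in 1..m with the recoding metadata."""

    X: np.ndarray
    m: int
    item_names: list[str]
    sample_ids: list
    polarity: dict[str, bool]
    cut_points: dict[str, np.ndarray] | None = None  # recoding table

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X)
        valid = ~np.isnan(self.X.astype(float))
        vals = self.X.astype(float)[valid]
        if vals.size and (np.any(vals < 1) or np.any(vals > self.m)
                          or np.any(vals != np.round(vals))):
            raise ValueError(f"ratings must be integers in 1..{self.m}")

    @property
    def n_samples(self) -> int:
        return self.X.shape[0]

    @property
    def n_items(self) -> int:
        return self.X.shape[1]


@dataclasses.dataclass
class RaschFit:
    """Joint maximum-likelihood estimates and diagnostics."""

    person_measures: np.ndarray
    person_se: np.ndarray
    item_difficulties: np.ndarray
    item_se: np.ndarray
    thresholds: np.ndarray
    person_scores: np.ndarray
    item_scores: np.ndarray
    person_extreme: np.ndarray       # True where the measure is extrapolated
    infit_person: np.ndarray | None = None
    outfit_person: np.ndarray | None = None
    infit_item: np.ndarray | None = None
    outfit_item: np.ndarray | None = None
    item_names: list[str] | None = None
    sample_ids: list | None = None
    n_iterations: int = 0
    max_score_residual: float = np.nan
    converged: bool = False
    dropped_items: list[str] = dataclasses.field(default_factory=list)

    @property
    def thresholds_ordered(self) -> bool:
        """Whether the category thresholds are strictly increasing."""
        return bool(np.all(np.diff(self.thresholds) > 0))

    def item_acceptable(self) -> np.ndarray:
        """Conventional 0.6–1.5 MNSQ acceptance flag per item."""
        return ((self.infit_item >= MNSQ_ACCEPT_LOW)
                & (self.infit_item <= MNSQ_ACCEPT_HIGH)
                & (self.outfit_item >= MNSQ_ACCEPT_LOW)
                & (self.outfit_item <= MNSQ_ACCEPT_HIGH))


def categorize(
    table: pd.DataFrame,
    m: int = 5,
    scheme: str = "equal_interval",
    polarity: dict[str, bool] | None = None,
    items: list[str] | None = None,
    cut_points: dict[str, np.ndarray] | None = None,
) -> CategoryMatrix:
    """Recode continuous soil properties to 1..m ordinal ratings.

    ``equal_interval`` splits each item's observed range into m equal
    bins; ``quantile`` uses m equal-probability bins. Items flagged
    False in ``polarity`` (high raw value = low fertility, e.g. sand)
    are reverse-scored after binning. Pre-computed ``cut_points``
    (m−1 interior boundaries per item) override the scheme, letting an
    external categorisation be injected. The applied cut points travel
    with the matrix so the recoding is reproducible.
    """
    items = items or [c for c in SOIL_PROPERTIES if c in table.columns]
    if not items:
        raise ValueError("no recognised soil-property columns")
    pol = dict(DEFAULT_POLARITY)
    if polarity:
        pol.update(polarity)

    X = np.empty((len(table), len(items)), dtype=float)
    cuts_out: dict[str, np.ndarray] = {}
    for j, item in enumerate(items):
        vals = table[item].to_numpy(dtype=float)
        if cut_points is not None and item in cut_points:
            cuts = np.asarray(cut_points[item], dtype=float)
        elif scheme == "equal_interval":
            lo, hi = np.nanmin(vals), np.nanmax(vals)
            if hi == lo:
                raise ValueError(f"item {item!r} is constant (zero range)")
            cuts = lo + (hi - lo) * np.arange(1, m) / m
        elif scheme == "quantile":
            cuts = np.nanquantile(vals, np.arange(1, m) / m)
        else:
            raise ValueError(f"unknown scheme {scheme!r}")
        if len(np.unique(vals[~np.isnan(vals)])) < m:
            warnings.warn(f"item {item!r} has fewer than {m} distinct "
                          "values; categories will be degenerate")
        cat = np.searchsorted(cuts, vals, side="right") + 1.0
        cat[np.isnan(vals)] = np.nan
        if not pol.get(item, True):
            cat = np.where(np.isnan(cat), np.nan, m + 1 - cat)
        X[:, j] = cat
        cuts_out[item] = cuts

    ids = (table["id"].tolist() if "id" in table.columns
           else list(range(len(table))))
    return CategoryMatrix(X, m, list(items), ids, pol, cuts_out)


def dichotomous_probability(B, d):
    """P(X = 1 | B, d) = e^(B−d) / (1 + e^(B−d)); the logit of P is B − d."""
    return special.expit(np.asarray(B, dtype=float) - np.asarray(d, dtype=float))


def category_probabilities(B, d, tau) -> np.ndarray:
    """Rating-scale category probabilities over categories 1..m.

    P(X = k) ∝ exp( Σ_{j≤k−1} (B − d − τ_j) ), the empty sum for k = 1.
    Computed in log space for stability; the returned vector sums to 1.
    """
    tau = np.asarray(tau, dtype=float)
    m = len(tau) + 1
    z = float(B) - float(d)
    steps = np.arange(m)  # 0-based category score
    log_num = steps * z - np.concatenate([[0.0], np.cumsum(tau)])
    return special.softmax(log_num)


def _log_numerators(B: np.ndarray, d: np.ndarray,
                    tau: np.ndarray) -> np.ndarray:
    """(N, I, m) log numerators for the rating-scale probabilities."""
    m = len(tau) + 1
    z = B[:, None] - d[None, :]
    steps = np.arange(m)
    ctau = np.concatenate([[0.0], np.cumsum(tau)])
    return steps[None, None, :] * z[:, :, None] - ctau[None, None, :]


def _probs(B: np.ndarray, d: np.ndarray, tau: np.ndarray) -> np.ndarray:
    return special.softmax(_log_numerators(B, d, tau), axis=2)


def expected_and_variance(B: np.ndarray, d: np.ndarray, tau: np.ndarray):
    """Model mean and variance of the 0-based category score per cell."""
    P = _probs(B, d, tau)
    steps = np.arange(len(tau) + 1)
    E = P @ steps
    E2 = P @ steps**2
    return E, E2 - E**2


def _person_newton(scores, obs_mask, d, tau, B0, tol=1e-8, max_iter=100):
    """Per-person Newton solve of observed score = expected score."""
    B = B0.copy()
    for _ in range(max_iter):
        E, W = expected_and_variance(B, d, tau)
        E = np.where(obs_mask, E, 0.0).sum(axis=1)
        W = np.where(obs_mask, W, 0.0).sum(axis=1)
        resid = scores - E
        step = resid / np.maximum(W, 1e-10)
        step = np.clip(step, -1.0, 1.0)
        B = B + step
        if np.max(np.abs(step)) < tol:
            break
    return B


def _item_negloglik(theta, B, X0, obs_mask, n_items, m):
    """Joint NLL in the free item/threshold parametrisation.

    theta = (d_1..d_{I−1}, τ_1..τ_{m−2}); d_I and τ_{m−1} complete the
    zero-sum constraints.
    """
    d = np.concatenate([theta[:n_items - 1],
                        [-np.sum(theta[:n_items - 1])]])
    tau_free = theta[n_items - 1:]
    tau = np.concatenate([tau_free, [-np.sum(tau_free)]])
    log_num = _log_numerators(B, d, tau)
    log_norm = special.logsumexp(log_num, axis=2)
    idx = np.where(obs_mask, X0, 0)
    chosen = np.take_along_axis(log_num, idx[:, :, None], axis=2)[:, :, 0]
    ll = np.where(obs_mask, chosen - log_norm, 0.0).sum()
    return -ll


def fit_rating_scale(
    cm: CategoryMatrix,
    max_cycles: int = 200,
    score_tol: float = 0.01,
    change_tol: float = 0.001,
    extreme_adjust: float = 0.3,
    compute_fit: bool = True,
) -> RaschFit:
    """Fit the rating-scale model by joint maximum likelihood.

    Alternates Newton updates of the person measures with bounded
    quasi-Newton updates of the (zero-sum constrained) item difficulties
    and thresholds until the largest observed-minus-expected raw score
    is below ``score_tol`` and the largest parameter change is below
    ``change_tol`` logits. Items observed in a single category are
    dropped with a warning; persons with extreme (minimum or maximum
    possible) scores are excluded from calibration and measured
    afterwards from scores shifted ``extreme_adjust`` points inward.
    """
    X = cm.X.astype(float)
    if cm.n_samples < 3 or cm.n_items < 2:
        raise ValueError("need at least 3 samples and 2 items")
    obs = ~np.isnan(X)
    X0 = np.where(obs, X - 1, 0).astype(int)  # 0-based category scores
    m = cm.m

    # drop items that never vary
    keep_items, dropped = [], []
    for j in range(X0.shape[1]):
        cats = np.unique(X0[obs[:, j], j])
        if len(cats) < 2:
            dropped.append(cm.item_names[j])
            warnings.warn(f"item {cm.item_names[j]!r} observed in a single "
                          "category; dropped from calibration")
        else:
            keep_items.append(j)
    if len(keep_items) < 2:
        raise ValueError("fewer than 2 informative items")
    X0 = X0[:, keep_items]
    obs = obs[:, keep_items]
    item_names = [cm.item_names[j] for j in keep_items]
    n_items = len(keep_items)

    scores = np.where(obs, X0, 0).sum(axis=1).astype(float)
    max_scores = (obs * (m - 1)).sum(axis=1).astype(float)
    extreme = (scores == 0) | (scores == max_scores)
    if extreme.all():
        raise ValueError("every response string is extreme; no calibration "
                         "is possible")

    core = ~extreme
    Xc, obs_c = X0[core], obs[core]
    scores_c = scores[core]

    # logit-of-proportion starting values
    p_person = (scores_c + 0.5) / (max_scores[core] + 1.0)
    B = np.log(p_person / (1 - p_person))
    item_scores = np.where(obs_c, Xc, 0).sum(axis=0).astype(float)
    item_max = (obs_c * (m - 1)).sum(axis=0).astype(float)
    p_item = (item_scores + 0.5) / (item_max + 1.0)
    d = -np.log(p_item / (1 - p_item))
    d -= d.mean()
    tau = np.zeros(m - 1)

    n_cycles = 0
    max_resid = np.inf
    for n_cycles in range(1, max_cycles + 1):
        B_old, d_old, tau_old = B.copy(), d.copy(), tau.copy()
        B = _person_newton(scores_c, obs_c, d, tau, B)
        if m > 2 or n_items > 1:
            theta0 = np.concatenate([d[:-1], tau[:-1]])
            res = optimize.minimize(
                _item_negloglik, theta0,
                args=(B, Xc, obs_c, n_items, m),
                method="L-BFGS-B",
                bounds=[(-30, 30)] * len(theta0),
            )
            d = np.concatenate([res.x[:n_items - 1],
                                [-np.sum(res.x[:n_items - 1])]])
            tau_free = res.x[n_items - 1:]
            tau = np.concatenate([tau_free, [-np.sum(tau_free)]])

        E, _ = expected_and_variance(B, d, tau)
        exp_scores = np.where(obs_c, E, 0.0).sum(axis=1)
        max_resid = float(np.max(np.abs(scores_c - exp_scores)))
        max_change = max(
            float(np.max(np.abs(B - B_old))),
            float(np.max(np.abs(d - d_old))),
            float(np.max(np.abs(tau - tau_old))),
        )
        if max_resid < score_tol and max_change < change_tol:
            break
    converged = max_resid < score_tol

    # measures for extreme persons: pull scores inward and solve
    B_all = np.full(cm.n_samples, np.nan)
    B_all[core] = B
    if extreme.any():
        adj_scores = scores[extreme].copy()
        at_min = adj_scores == 0
        adj_scores[at_min] += extreme_adjust
        adj_scores[~at_min] = (max_scores[extreme][~at_min]
                               - extreme_adjust)
        B_ext = _person_newton(adj_scores, obs[extreme], d, tau,
                               np.zeros(int(extreme.sum())))
        B_all[extreme] = B_ext

    # standard errors from the score-information (sum of model variances)
    _, W_all = expected_and_variance(B_all, d, tau)
    W_all = np.where(obs, W_all, 0.0)
    person_se = 1.0 / np.sqrt(np.maximum(W_all.sum(axis=1), 1e-10))
    item_se = 1.0 / np.sqrt(np.maximum(W_all[core].sum(axis=0), 1e-10))

    if not np.all(np.diff(tau) > 0):
        warnings.warn("category thresholds are disordered (not forced)")

    fit = RaschFit(
        person_measures=B_all,
        person_se=person_se,
        item_difficulties=d,
        item_se=item_se,
        thresholds=tau,
        person_scores=scores,
        item_scores=np.where(obs, X0, 0).sum(axis=0).astype(float),
        person_extreme=extreme,
        item_names=item_names,
        sample_ids=cm.sample_ids,
        n_iterations=n_cycles,
        max_score_residual=max_resid,
        converged=converged,
        dropped_items=dropped,
    )
    if compute_fit:
        trimmed = CategoryMatrix(
            np.where(obs, X0 + 1, np.nan), m, item_names,
            cm.sample_ids, cm.polarity)
        infit_p, outfit_p, infit_i, outfit_i = fit_statistics(trimmed, fit)
        fit.infit_person, fit.outfit_person = infit_p, outfit_p
        fit.infit_item, fit.outfit_item = infit_i, outfit_i
    return fit


def fit_statistics(cm: CategoryMatrix, fit: RaschFit):
    """Infit/Outfit mean squares per person and per item.

    With standardised residuals z_ni = (X_ni − E_ni)/√W_ni, Outfit is
    the plain mean of z² and Infit the information-weighted mean
    Σ W z² / Σ W. Extreme response strings carry no information and are
    excluded from the item statistics; zero-variance cells are excluded
    from all sums.
    """
    X = cm.X.astype(float)
    obs = ~np.isnan(X)
    X0 = np.where(obs, X - 1, 0)
    E, W = expected_and_variance(
        fit.person_measures, fit.item_difficulties, fit.thresholds)
    usable = obs & (W > 1e-10)
    resid2 = np.where(usable, (X0 - E) ** 2, 0.0)
    z2 = np.where(usable, resid2 / np.maximum(W, 1e-10), 0.0)
    Wm = np.where(usable, W, 0.0)

    n_p = usable.sum(axis=1)
    outfit_person = z2.sum(axis=1) / np.maximum(n_p, 1)
    infit_person = resid2.sum(axis=1) / np.maximum(Wm.sum(axis=1), 1e-10)

    core = ~fit.person_extreme
    n_i = (usable & core[:, None]).sum(axis=0)
    outfit_item = (z2 * core[:, None]).sum(axis=0) / np.maximum(n_i, 1)
    infit_item = ((resid2 * core[:, None]).sum(axis=0)
                  / np.maximum((Wm * core[:, None]).sum(axis=0), 1e-10))
    return infit_person, outfit_person, infit_item, outfit_item


def measures_by_zone(fit: RaschFit, zones: np.ndarray | pd.Series) -> pd.DataFrame:
    """Mean soil-fertility measure per management zone.

    Returns a table indexed by zone with the arithmetic mean of the
    person measures and the sample count; the most productive zone is
    expected to carry the highest mean measure.
    """
    zones = np.asarray(zones)
    if len(zones) != len(fit.person_measures):
        raise ValueError("one zone label per sample is required")
    if pd.isna(zones.astype(object)).any():
        raise ValueError("every sample needs a zone label")
    df = pd.DataFrame({"zone": zones, "measure": fit.person_measures})
    out = df.groupby("zone")["measure"].agg(["mean", "count"])
    out.columns = ["mean_measure", "n_samples"]
    if (out["n_samples"] == 0).any():
        raise ValueError("empty zone")
    return out
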