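"""ABC rejection, model choice and regression-adjusted estimation.

The rejection step standardizes every summary statistic by its median
absolute deviation over the reference table (normal-consistent scaling;
columns with zero spread are dropped from the distance with a warning),
measures Euclidean distance to the observed vector, and retains the
``round(tolerance * N)`` closest rows.  Retained rows carry
Epanechnikov kernel weights ``1 - (d / d_max)^2``.

Model choice is either the share of each model among retained rows
(simple rejection) or a weighted multinomial logistic regression of the
model label on the standardized statistics over the retained rows,
evaluated at the observed vector.

Parameter estimation uses a nonlinear heteroscedastic regression
adjustment: parameters (transformed to an unbounded scale) are
regressed on the standardized statistics with a small ensemble of
feed-forward networks, a second ensemble models the log squared
residuals, and each retained draw is adjusted as

    theta* = m(s_obs) + (theta - m(s)) * sigma(s_obs) / sigma(s)

before back-transformation, which guarantees adjusted draws stay inside
the prior support.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from scipy.stats import median_abs_deviation
from sklearn.exceptions import ConvergenceWarning
from sklearn.linear_model import LogisticRegression
from sklearn.neural_network import MLPRegressor

from .models import ModelSpec, Priors, param_names
from .simulate import ReferenceTable

BF_CAP = 1e6  # reported Bayes factor when the best competitor has zero mass


@dataclass
class AcceptedSet:
    """Rows retained by rejection, with distances and kernel weights."""

    indices: np.ndarray
    distances: np.ndarray
    weights: np.ndarray
    scale: np.ndarray         # per-statistic MAD over the table
    kept_columns: np.ndarray  # boolean mask of columns used in the distance
    tolerance: float

    def __len__(self):
        return len(self.indices)


@dataclass
class ModelPosterior:
    probs: dict
    method: str
    tolerance: float

    def __post_init__(self):
        total = sum(self.probs.values())
        if not np.isfinite(total) or abs(total - 1.0) > 1e-9:
            raise ValueError("model probabilities must sum to 1")
        if any(p < 0 for p in self.probs.values()):
            raise ValueError("model probabilities must be nonnegative")

    def best(self) -> str:
        return max(self.probs, key=self.probs.get)


@dataclass
class ParameterPosterior:
    """Weighted, regression-adjusted posterior sample for one model."""

    samples: pd.DataFrame
    weights: np.ndarray
    point: dict = field(init=False)
    hpd: dict = field(init=False)
    model: str = ""
    tolerance: float = float("nan")
    mass: float = 0.95

    def __post_init__(self):
        self.point = {
            c: weighted_median(self.samples[c].to_numpy(), self.weights)
            for c in self.samples.columns
        }
        self.hpd = {
            c: hpd_interval(self.samples[c].to_numpy(), self.weights, self.mass)
            for c in self.samples.columns
        }


def _standardize(table_stats: np.ndarray, observed: np.ndarray):
    scale = median_abs_deviation(table_stats, axis=0, scale="normal")
    keep = scale > 0
    if not keep.all():
        warnings.warn(
            f"{(~keep).sum()} constant statistic column(s) dropped from distance",
            stacklevel=3,
        )
    if not keep.any():
        raise ValueError("all statistic columns are constant")
    return table_stats[:, keep] / scale[keep], observed[keep] / scale[keep], scale, keep


def abc_reject(
    observed: np.ndarray, table: ReferenceTable, tolerance: float
) -> AcceptedSet:
    """Retain the ``round(tolerance * N)`` rows closest to ``observed``.

    Distances are Euclidean on MAD-standardized statistics; ties are
    broken deterministically by row index.
    """
    if not (0 < tolerance <= 1):
        raise ValueError("tolerance must be in (0, 1]")
    stats = table.stats_matrix()
    n = stats.shape[0]
    if n == 0:
        raise ValueError("empty reference table")
    obs = np.asarray(observed, dtype=float)
    if obs.shape != (stats.shape[1],):
        raise ValueError(
            f"observed vector length {obs.shape} does not match table "
            f"statistic configuration ({stats.shape[1]} columns)"
        )
    X, o, scale, keep = _standardize(stats, obs)
    d = np.sqrt(((X - o) ** 2).sum(axis=1))
    n_keep = int(round(tolerance * n))
    if n_keep < 1:
        raise ValueError("tolerance retains no rows")
    order = np.lexsort((np.arange(n), d))
    idx = order[:n_keep]
    dist = d[idx]
    dmax = dist.max()
    weights = 1.0 - (dist / dmax) ** 2 if dmax > 0 else np.ones_like(dist)
    if weights.sum() <= 0:
        weights = np.ones_like(dist)
    return AcceptedSet(
        indices=idx,
        distances=dist,
        weights=weights,
        scale=scale,
        kept_columns=keep,
        tolerance=tolerance,
    )


def model_posterior_rejection(
    accepted: AcceptedSet, table: ReferenceTable
) -> ModelPosterior:
    """Each model's posterior probability = its share of retained rows."""
    if len(accepted) == 0:
        raise ValueError("empty accepted set")
    labels = table.df["model"].to_numpy()[accepted.indices]
    probs = {m: float((labels == m).mean()) for m in table.models}
    return ModelPosterior(probs=probs, method="rejection", tolerance=accepted.tolerance)


def model_posterior_mnlogistic(
    observed: np.ndarray,
    table: ReferenceTable,
    tolerance: float,
    ridge: float = 1e-6,
    eps: float = 1e-8,
    max_iter: int = 500,
) -> ModelPosterior:
    """Weighted multinomial logistic regression model choice.

    Fit over the accepted rows with Epanechnikov weights and a small
    ridge penalty (the 52 moment statistics are strongly collinear);
    probabilities are evaluated at the observed vector, clipped to
    [eps, 1-eps] and renormalized.  Models absent from the accepted set
    receive the floor probability.
    """
    accepted = abc_reject(observed, table, tolerance)
    labels = table.df["model"].to_numpy()[accepted.indices]
    present = pd.unique(labels)
    if len(present) < 2:
        raise ValueError("fewer than two models among accepted rows")
    X = table.stats_matrix()[np.ix_(accepted.indices, accepted.kept_columns)]
    X = X / accepted.scale[accepted.kept_columns]
    obs = np.asarray(observed, dtype=float)[accepted.kept_columns]
    obs = obs / accepted.scale[accepted.kept_columns]
    clf = LogisticRegression(C=1.0 / ridge, max_iter=max_iter, tol=1e-6)
    with warnings.catch_warnings():
        warnings.filterwarnings("ignore", category=ConvergenceWarning)
        clf.fit(X - obs, labels, sample_weight=accepted.weights)
    raw = dict(zip(clf.classes_, clf.predict_proba(np.zeros((1, X.shape[1])))[0]))
    probs = np.array([raw.get(m, 0.0) for m in table.models])
    probs = np.clip(probs, eps, 1 - eps)
    probs = probs / probs.sum()
    return ModelPosterior(
        probs=dict(zip(table.models, map(float, probs))),
        method="mnlogistic",
        tolerance=tolerance,
    )


def bayes_factor_min(posterior: ModelPosterior, true_model: str) -> float:
    """P(true model) over the strongest remaining candidate."""
    if true_model not in posterior.probs:
        raise KeyError(f"unknown model id {true_model!r}")
    if len(posterior.probs) < 2:
        raise ValueError("need at least two models")
    p_true = posterior.probs[true_model]
    p_best = max(v for k, v in posterior.probs.items() if k != true_model)
    if p_best <= 0:
        return BF_CAP
    return min(p_true / p_best, BF_CAP)


# ---------------------------------------------------------------------------
# Weighted quantities
# ---------------------------------------------------------------------------

def weighted_median(values: np.ndarray, weights: Optional[np.ndarray] = None) -> float:
    values = np.asarray(values, dtype=float)
    if weights is None:
        return float(np.median(values))
    w = np.asarray(weights, dtype=float)
    order = np.argsort(values, kind="stable")
    v, w = values[order], w[order]
    cw = np.cumsum(w)
    return float(v[np.searchsorted(cw, 0.5 * cw[-1])])


def hpd_interval(
    values: np.ndarray, weights: Optional[np.ndarray] = None, mass: float = 0.95
) -> tuple:
    """Shortest contiguous interval holding >= ``mass`` of the weighted
    empirical distribution.  A point mass yields a zero-width interval."""
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise ValueError("empty sample")
    if not (0 < mass <= 1):
        raise ValueError("mass must be in (0, 1]")
    if weights is None:
        weights = np.ones_like(values)
    w = np.asarray(weights, dtype=float)
    if w.sum() <= 0:
        raise ValueError("weights must have positive sum")
    order = np.argsort(values, kind="stable")
    v, w = values[order], w[order]
    if v[0] == v[-1]:
        return (float(v[0]), float(v[0]))
    cw = np.concatenate([[0.0], np.cumsum(w)])
    target = mass * cw[-1]
    best = (v[0], v[-1])
    best_width = v[-1] - v[0]
    j = 0
    for i in range(len(v)):
        if j < i:
            j = i
        while j < len(v) and cw[j + 1] - cw[i] < target:
            j += 1
        if j == len(v):
            break
        width = v[j] - v[i]
        if width < best_width:
            best_width = width
            best = (v[i], v[j])
    return (float(best[0]), float(best[1]))


# ---------------------------------------------------------------------------
# Parameter transforms
# ---------------------------------------------------------------------------

_LOGIT_EPS = 1e-12


def _make_transforms(priors: Priors, model: ModelSpec):
    """(forward, inverse) pairs keeping draws inside the prior support:
    logit for bounded-uniform parameters, log for positive ones."""
    spec = priors.for_model(model.model_id)
    transforms = {}
    for name in param_names(model):
        lo, hi = spec.support(name)
        if np.isfinite(hi):
            def fwd(x, lo=lo, hi=hi):
                p = np.clip((np.asarray(x) - lo) / (hi - lo), _LOGIT_EPS, 1 - _LOGIT_EPS)
                return np.log(p / (1 - p))

            def inv(y, lo=lo, hi=hi):
                return lo + (hi - lo) / (1.0 + np.exp(-np.asarray(y)))

        else:
            def fwd(x, lo=lo, hi=hi):
                return np.log(np.maximum(np.asarray(x), 1e-300))

            def inv(y, lo=lo, hi=hi):
                return np.exp(np.asarray(y))

        transforms[name] = (fwd, inv)
    return transforms


@dataclass(frozen=True)
class NNSettings:
    """Hyperparameters of the regression-adjustment ensemble.

    ``decay`` is the grid of weight-decay strengths from which one is
    chosen by held-out validation error before the ensemble is fit.
    The grid deliberately extends to very strong penalties: when the
    statistics carry no information about a parameter, the selected
    regression collapses toward a constant and the adjustment leaves
    the accepted sample (hence the prior) essentially untouched.
    """

    n_networks: int = 10
    hidden_units: int = 5
    decay: tuple = (1e-4, 1e-3, 1e-2, 1.0, 100.0)
    max_iter: int = 500
    min_accepted: int = 50
    sigma_clip: float = 1e3
    val_fraction: float = 0.25


def _mlp(settings: NNSettings, decay: float, seed: int) -> MLPRegressor:
    return MLPRegressor(
        hidden_layer_sizes=(settings.hidden_units,),
        solver="lbfgs",
        alpha=decay,
        max_iter=settings.max_iter,
        random_state=seed,
    )


def _fit_ensemble(X, Y, weights, settings: NNSettings, rng: np.random.Generator, x_obs):
    """Median prediction across a bootstrap ensemble of small MLPs.

    Targets are z-scored before fitting (so the decay penalty is
    scale-meaningful) and predictions mapped back.  The decay strength
    is selected once by mean squared error on a held-out validation
    split, then the ensemble is fit on kernel-weighted bootstrap
    resamples (the regressor has no native observation weights).
    Returns (fitted values on X, prediction at x_obs).
    """
    n = X.shape[0]
    mu, sd = Y.mean(axis=0), Y.std(axis=0)
    sd = np.where(sd > 0, sd, 1.0)
    Z = (Y - mu) / sd

    with warnings.catch_warnings():
        warnings.filterwarnings("ignore", category=ConvergenceWarning)
        # held-out selection of the decay strength
        perm = rng.permutation(n)
        n_val = max(int(settings.val_fraction * n), 1)
        val, train = perm[:n_val], perm[n_val:]
        losses = []
        for decay in settings.decay:
            net = _mlp(settings, float(decay), int(rng.integers(0, 2**31 - 1)))
            net.fit(X[train], Z[train])
            pred = np.atleast_2d(net.predict(X[val]))
            if pred.shape != Z[val].shape:
                pred = pred.reshape(Z[val].shape)
            losses.append(((pred - Z[val]) ** 2).mean())
        decay = float(settings.decay[int(np.argmin(losses))])

        p = weights / weights.sum()
        preds_eval, preds_obs = [], []
        for _ in range(settings.n_networks):
            idx = rng.choice(n, size=n, replace=True, p=p)
            net = _mlp(settings, decay, int(rng.integers(0, 2**31 - 1)))
            net.fit(X[idx], Z[idx])
            preds_eval.append(np.atleast_2d(net.predict(X)).reshape(Z.shape))
            preds_obs.append(np.atleast_1d(net.predict(x_obs[None, :])).ravel())
    m_eval = np.median(np.stack(preds_eval), axis=0) * sd + mu
    m_obs = np.median(np.stack(preds_obs), axis=0) * sd + mu
    return m_eval, m_obs


def estimate_parameters_nn(
    observed: np.ndarray,
    table: ReferenceTable,
    tolerance: float,
    priors: Priors,
    model: Optional[ModelSpec] = None,
    settings: Optional[NNSettings] = None,
    seed: int = 0,
) -> ParameterPosterior:
    """Regression-adjusted posterior for a single-model reference table.

    Parameters are mapped to an unbounded scale (logit for bounded
    priors, log for positive ones), regressed on the standardized
    statistics over the accepted set with a network ensemble, adjusted
    with the heteroscedastic correction, and back-transformed, so the
    output sample always lies inside the prior support.  Reproducible
    bit-for-bit given (table, observed, seed).
    """
    settings = settings or NNSettings()
    if model is None:
        ids = table.models
        if len(ids) != 1:
            raise ValueError("table must be restricted to a single model")
        mode = priors.admixture_mode
        model = ModelSpec(ids[0], admixture_mode=mode)
    names = param_names(model)
    accepted = abc_reject(observed, table, tolerance)
    if len(accepted) < settings.min_accepted:
        raise ValueError(
            f"only {len(accepted)} accepted rows; floor is {settings.min_accepted}"
        )
    X = table.stats_matrix()[np.ix_(accepted.indices, accepted.kept_columns)]
    X = X / accepted.scale[accepted.kept_columns]
    obs = np.asarray(observed, dtype=float)[accepted.kept_columns]
    obs = obs / accepted.scale[accepted.kept_columns]

    transforms = _make_transforms(priors, model)
    theta = np.column_stack(
        [transforms[n][0](table.df[n].to_numpy()[accepted.indices]) for n in names]
    )
    rng = np.random.Generator(np.random.PCG64(np.random.SeedSequence(seed)))

    m_acc, m_obs = _fit_ensemble(X, theta, accepted.weights, settings, rng, obs)
    resid = theta - m_acc
    log_r2 = np.log(resid**2 + 1e-10)
    s_acc, s_obs = _fit_ensemble(X, log_r2, accepted.weights, settings, rng, obs)
    ratio = np.exp(0.5 * (s_obs[None, :] - s_acc))
    ratio = np.clip(ratio, 1.0 / settings.sigma_clip, settings.sigma_clip)
    adjusted = m_obs[None, :] + resid * ratio
    if not np.isfinite(adjusted).all():
        raise FloatingPointError("non-finite regression adjustment")

    samples = pd.DataFrame(
        {n: transforms[n][1](adjusted[:, k]) for k, n in enumerate(names)}
    )
    return ParameterPosterior(
        samples=samples,
        weights=accepted.weights.copy(),
        model=model.model_id,
        tolerance=tolerance,
    )
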