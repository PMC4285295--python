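"""Prior- and posterior-predictive adequacy checks via PCA.

Before inference, the observed summary statistics should fall inside
the cloud of statistics the priors can generate ("could the model have
produced data like this at all?").  After model selection, statistics
re-simulated at accepted (model, parameter) combinations should again
surround the observation.  The original check is graphical; here it is
operationalized two ways on the leading principal components of the
z-scored statistics: convex-hull membership of the observed score on
the first two components, and the percentile of its Mahalanobis
distance among the simulated scores.  Both are reported per model and
pooled.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np
import pandas as pd
from scipy.spatial import Delaunay, QhullError
from sklearn.decomposition import PCA

from .inference import AcceptedSet
from .simulate import ReferenceTable


@dataclass
class PCACheckResult:
    loadings: np.ndarray            # components x statistics (orthonormal rows)
    scores: pd.DataFrame            # per-simulation scores + model label
    observed_score: np.ndarray
    inside_cloud: dict              # group -> bool (convex hull, 2 components)
    mahalanobis_percentile: dict    # group -> percentile in [0, 100]

    @property
    def pooled_inside(self) -> bool:
        return self.inside_cloud["pooled"]


def _zscore(stats: np.ndarray, observed: np.ndarray):
    mu = stats.mean(axis=0)
    sd = stats.std(axis=0)
    keep = sd > 0
    return (stats[:, keep] - mu[keep]) / sd[keep], (observed[keep] - mu[keep]) / sd[keep]


def _inside_hull(points: np.ndarray, x: np.ndarray) -> bool:
    if len(points) < 4:
        return False
    try:
        return bool(Delaunay(points).find_simplex(x) >= 0)
    except QhullError:  # degenerate (collinear) score cloud
        return False


def _mahal_percentile(scores: np.ndarray, x: np.ndarray) -> float:
    mu = scores.mean(axis=0)
    cov = np.cov(scores, rowvar=False)
    cov = np.atleast_2d(cov)
    inv = np.linalg.pinv(cov)
    d_obs = float((x - mu) @ inv @ (x - mu))
    delta = scores - mu
    d = np.einsum("ij,jk,ik->i", delta, inv, delta)
    return float(100.0 * (d <= d_obs).mean())


def _check(stat_matrix, labels, observed, n_components):
    Z, z_obs = _zscore(stat_matrix, np.asarray(observed, dtype=float))
    k = int(min(n_components, Z.shape[1], max(1, Z.shape[0] - 1)))
    pca = PCA(n_components=k)
    scores = pca.fit_transform(Z)
    obs_score = pca.transform(z_obs[None, :])[0]
    df = pd.DataFrame(scores, columns=[f"PC{i + 1}" for i in range(k)])
    df.insert(0, "model", labels)
    inside, percentile = {}, {}
    groups = {"pooled": np.ones(len(df), dtype=bool)}
    for m in pd.unique(labels):
        groups[m] = np.asarray(labels) == m
    hull_dim = min(2, k)
    for name, mask in groups.items():
        pts = scores[mask][:, :hull_dim]
        inside[name] = _inside_hull(pts, obs_score[:hull_dim])
        percentile[name] = _mahal_percentile(scores[mask], obs_score)
    return PCACheckResult(
        loadings=pca.components_,
        scores=df,
        observed_score=obs_score,
        inside_cloud=inside,
        mahalanobis_percentile=percentile,
    )


def prior_predictive_check(
    table: ReferenceTable, observed: np.ndarray, n_components: int = 2
) -> PCACheckResult:
    """Does the observation cluster with the prior-predictive cloud?"""
    if table.n_rows == 0:
        raise ValueError("empty reference table")
    labels = table.df["model"].to_numpy()
    return _check(table.stats_matrix(), labels, observed, n_components)


def posterior_predictive_check(
    accepted: AcceptedSet,
    table: ReferenceTable,
    observed: np.ndarray,
    simulate_fn: Callable,
    n_sims: int = 1001,
    seed: int = 0,
    n_components: int = 2,
) -> PCACheckResult:
    """Re-simulate at accepted (model, parameters) and re-check fit.

    Accepted rows are resampled with their kernel weights (with
    replacement) up to ``n_sims``; ``simulate_fn(model_id, params_dict,
    seed)`` must return a statistic vector in the table's configuration.
    """
    if len(accepted) == 0:
        raise ValueError("empty accepted set")
    rng = np.random.Generator(np.random.PCG64(np.random.SeedSequence(seed)))
    p = accepted.weights / accepted.weights.sum()
    picks = rng.choice(len(accepted), size=n_sims, replace=True, p=p)
    rows = table.df.iloc[accepted.indices[picks]]
    sims = np.empty((n_sims, len(table.stat_names)))
    labels = []
    for i, (_, row) in enumerate(rows.iterrows()):
        params = {
            k: float(row[k]) for k in table.param_names if pd.notna(row.get(k))
        }
        sims[i] = simulate_fn(
            row["model"], params, int(rng.integers(1, 2**31 - 1))
        )
        labels.append(row["model"])
    return _check(sims, np.asarray(labels), observed, n_components)


def make_resimulator(config, stat_config, admixture_mode: str) -> Callable:
    """Default simulate_fn for posterior-predictive checks."""
    from .models import ModelParameters, ModelSpec, build_demography
    from .simulate import simulate_stat_row

    def fn(model_id, params, seed):
        model = ModelSpec(model_id, admixture_mode=admixture_mode)
        mp = ModelParameters(**params)
        plan = build_demography(model, mp)
        return simulate_stat_row(plan, config, mp.theta_S, seed, stat_config)

    return fn
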