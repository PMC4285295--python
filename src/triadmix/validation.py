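"""Pseudo-observed-dataset (PODS) cross-validation machinery.

Model selection is validated leave-one-out: a simulated row is removed
from the reference table, treated as observed data, and classified with
the multinomial-logistic posterior; we record the posterior probability
of the true model and whether its minimum pairwise Bayes factor clears
a strong-support threshold (10 by convention).

Parameter estimation is validated on fresh PODS drawn from the same
priors as the table: per parameter we report the prediction error

    epsilon = sum_i (theta_hat_i - theta_i)^2 / (n * Var_prior(theta)),

normalized so that an estimator stuck at the prior mean has expected
error 1 (the prior-baseline reference line), together with the
coverage and mean width of 95% highest-posterior-density intervals.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional

import numpy as np
import pandas as pd

from . import sumstats
from .inference import (
    NNSettings,
    ParameterPosterior,
    bayes_factor_min,
    estimate_parameters_nn,
    model_posterior_mnlogistic,
)
from .models import (
    ModelParameters,
    ModelSpec,
    Priors,
    build_demography,
    param_names,
    sample_prior_n,
)
from .simulate import (
    ReferenceTable,
    SampleConfig,
    build_reference_table,
    row_seed,
    simulate_stat_row,
)


@dataclass
class ModelCVResult:
    """Leave-one-out model-selection cross-validation summary."""

    confusion: pd.DataFrame          # true model x assigned model, mean posterior
    mean_true_posterior: dict        # true model -> mean P(true)
    strong_support: dict             # true model -> replicates with min BF > threshold
    replicates: int
    tolerance: float
    bf_threshold: float

    def to_json_dict(self) -> dict:
        return {
            "confusion": self.confusion.to_dict(),
            "mean_true_posterior": self.mean_true_posterior,
            "strong_support": self.strong_support,
            "replicates": self.replicates,
            "tolerance": self.tolerance,
            "bf_threshold": self.bf_threshold,
        }


@dataclass
class ParamCVResult:
    """Per-parameter PODS validation summary for one model."""

    model: str
    epsilon: dict                    # parameter -> prediction error
    prior_epsilon: float             # baseline (1.0 by construction)
    coverage: dict                   # parameter -> fraction of PODS covered
    mean_hpd_width: dict             # parameter -> mean 95% HPD width
    prior_width: dict                # parameter -> width of the prior range
    n_pods: int
    mass: float = 0.95

    def to_json_dict(self) -> dict:
        return {
            "model": self.model,
            "epsilon": self.epsilon,
            "prior_epsilon": self.prior_epsilon,
            "coverage": self.coverage,
            "mean_hpd_width": self.mean_hpd_width,
            "prior_width": self.prior_width,
            "n_pods": self.n_pods,
            "mass": self.mass,
        }


def leave_one_out_model_cv(
    table: ReferenceTable,
    replicates_per_model: int,
    tolerance: float,
    bf_threshold: float = 10.0,
    seed: int = 0,
) -> ModelCVResult:
    """Leave-one-out model-selection cross-validation.

    For each model, ``replicates_per_model`` rows are sampled without
    replacement (seeded); each is removed from the table, used as the
    observed vector, and classified with the multinomial-logistic
    posterior at ``tolerance``.
    """
    models = table.models
    counts = table.rows_per_model()
    for m in models:
        if counts[m] <= replicates_per_model:
            raise ValueError(
                f"model {m} has {counts[m]} rows; need more than "
                f"{replicates_per_model} for leave-one-out replication"
            )
    rng = np.random.Generator(np.random.PCG64(np.random.SeedSequence(seed)))
    confusion = pd.DataFrame(0.0, index=list(models), columns=list(models))
    strong = {m: 0 for m in models}
    stats = table.stats_matrix()
    for m in models:
        rows = np.flatnonzero(table.df["model"].to_numpy() == m)
        chosen = rng.choice(rows, size=replicates_per_model, replace=False)
        for row in chosen:
            observed = stats[row]
            reduced = table.drop_row(int(row))
            post = model_posterior_mnlogistic(observed, reduced, tolerance)
            for k, v in post.probs.items():
                confusion.loc[m, k] += v
            if bayes_factor_min(post, m) > bf_threshold:
                strong[m] += 1
    confusion /= replicates_per_model
    return ModelCVResult(
        confusion=confusion,
        mean_true_posterior={m: float(confusion.loc[m, m]) for m in models},
        strong_support=strong,
        replicates=replicates_per_model,
        tolerance=tolerance,
        bf_threshold=bf_threshold,
    )


def generate_pods(
    model: ModelSpec,
    priors: Priors,
    config: SampleConfig,
    stat_config: sumstats.StatConfig,
    n: int = 100,
    seed: int = 0,
) -> tuple:
    """Simulate ``n`` PODS: returns (truths DataFrame, stats matrix).

    Truths are drawn from the same priors used for the reference table;
    per-PODS seeds derive from (seed, PODS index) so the set is
    reproducible and independent of table seeds.
    """
    rng = np.random.Generator(np.random.PCG64(np.random.SeedSequence([seed, 2**20])))
    truths = sample_prior_n(model, priors, n, rng)
    stats = np.empty((n, stat_config.length))
    for i in range(n):
        params = ModelParameters(**{k: float(v) for k, v in truths.iloc[i].items()})
        plan = build_demography(model, params)
        stats[i] = simulate_stat_row(
            plan, config, params.theta_S, row_seed(seed, 2**20, i), stat_config
        )
    return truths, stats


def prior_moments(
    priors: Priors, model: ModelSpec, n: int = 100_000, seed: int = 12345
) -> pd.DataFrame:
    """Monte-Carlo mean and variance of each parameter's prior.

    A simulation-free, seeded large-sample estimate; used to normalize
    prediction errors (conditional priors make closed forms clumsy).
    """
    rng = np.random.Generator(np.random.PCG64(np.random.SeedSequence(seed)))
    draws = sample_prior_n(model, priors, n, rng)
    return pd.DataFrame({"mean": draws.mean(), "var": draws.var(ddof=1)})


def prediction_error(
    estimates: pd.DataFrame,
    truths: pd.DataFrame,
    priors: Priors,
    model: ModelSpec,
    prior_var: Optional[pd.Series] = None,
) -> dict:
    """Prior-variance-normalized mean squared error per parameter."""
    if len(estimates) != len(truths):
        raise ValueError("estimate and truth lists must have equal length")
    if prior_var is None:
        prior_var = prior_moments(priors, model)["var"]
    out = {}
    for name in param_names(model):
        v = float(prior_var[name])
        if v <= 0:
            raise ValueError(f"zero prior variance for {name}")
        resid = estimates[name].to_numpy() - truths[name].to_numpy()
        out[name] = float((resid**2).mean() / v)
    return out


def coverage_and_width(
    posteriors: Iterable[ParameterPosterior],
    truths: pd.DataFrame,
    mass: float = 0.95,
) -> tuple:
    """(coverage, mean HPD width) per parameter over matched PODS."""
    posteriors = list(posteriors)
    if len(posteriors) != len(truths):
        raise ValueError("posterior and truth lists must have equal length")
    names = list(truths.columns)
    hit = {n: 0 for n in names}
    width = {n: 0.0 for n in names}
    for post, (_, row) in zip(posteriors, truths.iterrows()):
        for n in names:
            lo, hi = post.hpd[n]
            width[n] += hi - lo
            if lo <= row[n] <= hi:
                hit[n] += 1
    n_pods = len(posteriors)
    coverage = {n: hit[n] / n_pods for n in names}
    mean_width = {n: width[n] / n_pods for n in names}
    return coverage, mean_width


def parameter_estimation_cv(
    model: ModelSpec,
    priors: Priors,
    config: SampleConfig,
    stat_config: sumstats.StatConfig,
    n_table: int = 5000,
    n_pods: int = 100,
    retained: int = 1000,
    settings: Optional[NNSettings] = None,
    seed: int = 0,
    table: Optional[ReferenceTable] = None,
    progress: bool = False,
) -> ParamCVResult:
    """End-to-end PODS parameter-estimation experiment for one model.

    Builds (or reuses) a single-model reference table, draws ``n_pods``
    PODS from the same priors, estimates each posterior with the
    regression-adjusted method retaining ``retained`` rows, and
    aggregates prediction error, HPD coverage and width.
    """
    if table is None:
        table = build_reference_table(
            [model], priors, config, n_table, stat_config, seed, progress=progress
        )
    tolerance = retained / table.n_rows
    truths, stats = generate_pods(model, priors, config, stat_config, n_pods, seed + 1)
    posteriors = []
    for i in range(n_pods):
        posteriors.append(
            estimate_parameters_nn(
                stats[i],
                table,
                tolerance,
                priors,
                model=model,
                settings=settings,
                seed=row_seed(seed, 2**21, i),
            )
        )
    estimates = pd.DataFrame([p.point for p in posteriors])
    moments = prior_moments(priors, model)
    eps = prediction_error(estimates, truths, priors, model, prior_var=moments["var"])
    coverage, mean_width = coverage_and_width(posteriors, truths)
    spec = priors.for_model(model.model_id)
    prior_width = {}
    for name in param_names(model):
        lo, hi = spec.support(name)
        prior_width[name] = (hi - lo) if np.isfinite(hi) else float("nan")
    return ParamCVResult(
        model=model.model_id,
        epsilon=eps,
        prior_epsilon=1.0,
        coverage=coverage,
        mean_hpd_width=mean_width,
        prior_width=prior_width,
        n_pods=n_pods,
    )
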