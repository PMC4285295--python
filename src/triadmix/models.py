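"""Candidate demographic histories, their priors, and demography plans.

Seven three-population divergence histories are compared: an isolation
model (``ISO``) and six divergence-with-admixture models (``A``–``F``).
The fixed topology is ((pop2, pop3), pop1): pop2 and pop3 are sister
populations splitting at time ``T1`` and their ancestor splits from pop1
at the deeper time ``T2``.  Admixture is either "recent" (after the
sister split, models A, B, D, E) or "ancient" (between the two splits,
models C and F), and is modelled either as a continuous migration window
of duration ``Tdur`` at rate ``4Nm``, or as an instantaneous pulse
moving a proportion ``F`` of lineages.

All times are in coalescent units of 4·Ne generations and ``theta_S`` is
the per-locus scaled mutation rate 4·Ne·mu·L (the ms convention).

Forward-in-time admixture direction conventions (held fixed; the model
pairs (A,B), (D,E) and (C,F) are label-symmetric, so any fixed
assignment defines the same candidate set):

=====  ==========================  =========================
model  migrant source (forward)    migrant destination
=====  ==========================  =========================
A      pop2                        pop1
B      pop3                        pop1
D      pop1                        pop2
E      pop1                        pop3
C      ancestor of (pop2, pop3)    pop1
F      pop1                        ancestor of (pop2, pop3)
=====  ==========================  =========================
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

MODEL_IDS = ("A", "B", "C", "D", "E", "F", "ISO")
RECENT_MODELS = frozenset({"A", "B", "D", "E"})
ANCIENT_MODELS = frozenset({"C", "F"})

CONTINUOUS = "continuous_window"
PULSE = "pulse"

#: forward-in-time (source, destination) of migrants during admixture.
#: "anc23" denotes the common ancestor of pop2 and pop3 (which only
#: exists between T1 and T2, hence only for the ancient models C/F).
ADMIXTURE_DIRECTIONS = {
    "A": ("pop2", "pop1"),
    "B": ("pop3", "pop1"),
    "D": ("pop1", "pop2"),
    "E": ("pop1", "pop3"),
    "C": ("anc23", "pop1"),
    "F": ("pop1", "anc23"),
}

_EPS = 1e-12


@dataclass(frozen=True)
class ModelSpec:
    """Identity and wiring of one candidate demographic history.

    Parameters
    ----------
    model_id:
        One of ``A``–``F`` or ``ISO``.
    admixture_mode:
        ``"continuous_window"`` (gene flow at rate 4Nm over a window of
        duration Tdur) or ``"pulse"`` (a single event moving a
        proportion F of lineages).  Irrelevant for ``ISO``.
    population_labels:
        Ordered labels; element 0 is the first-diverging population,
        elements 1 and 2 the sister pair splitting at T1.
    """

    model_id: str
    admixture_mode: str = CONTINUOUS
    population_labels: tuple = ("pop1", "pop2", "pop3")

    def __post_init__(self):
        if self.model_id not in MODEL_IDS:
            raise ValueError(f"unknown model id {self.model_id!r}")
        if self.admixture_mode not in (CONTINUOUS, PULSE):
            raise ValueError(f"unknown admixture mode {self.admixture_mode!r}")
        if len(self.population_labels) != 3:
            raise ValueError("exactly three population labels required")

    @property
    def has_admixture(self) -> bool:
        return self.model_id != "ISO"

    @property
    def is_recent(self) -> bool:
        return self.model_id in RECENT_MODELS

    @property
    def is_ancient(self) -> bool:
        return self.model_id in ANCIENT_MODELS


@dataclass(frozen=True)
class ModelParameters:
    """Coalescent-scaled parameter vector for one history.

    ``theta_S`` is 4·Ne·mu·L per locus; all times are in units of 4·Ne
    generations.  ``Tgf`` is the time (looking backward) at which gene
    flow ceased; for continuous admixture the window is
    [Tgf, Tgf+Tdur] backward in time at rate ``Nm4`` (=4Nm); for pulse
    admixture a proportion ``F`` of the destination population's
    lineages derive from the source at time ``Tgf``.
    """

    theta_S: float
    T1: float
    T2: float
    Tgf: Optional[float] = None
    Tdur: Optional[float] = None
    Nm4: Optional[float] = None
    F: Optional[float] = None

    def as_dict(self) -> dict:
        return {
            k: v
            for k, v in self.__dict__.items()
            if v is not None
        }


def param_names(model: ModelSpec) -> list:
    """Ordered parameter names for ``model`` under its admixture mode."""
    if not model.has_admixture:
        return ["theta_S", "T1", "T2"]
    if model.admixture_mode == CONTINUOUS:
        return ["theta_S", "T1", "T2", "Tgf", "Tdur", "Nm4"]
    return ["theta_S", "T1", "T2", "Tgf", "F"]


def validate_parameters(model: ModelSpec, params: ModelParameters) -> None:
    """Raise ``ValueError`` if ``params`` violate ``model``'s invariants."""
    p = params
    if not (p.theta_S > 0):
        raise ValueError("theta_S must be positive")
    if not (0 < p.T1 < p.T2):
        raise ValueError("need 0 < T1 < T2")
    if not model.has_admixture:
        return
    if p.Tgf is None or not (p.Tgf > 0):
        raise ValueError("admixture models need Tgf > 0")
    if model.admixture_mode == CONTINUOUS:
        if p.Tdur is None or p.Nm4 is None or p.Tdur <= 0 or p.Nm4 < 0:
            raise ValueError("continuous admixture needs Tdur > 0 and Nm4 >= 0")
        window_end = p.Tgf + p.Tdur
    else:
        if p.F is None or not (0.0 <= p.F <= 1.0):
            raise ValueError("pulse admixture needs F in [0, 1]")
        window_end = p.Tgf
    if model.is_recent:
        if not (p.Tgf < p.T1) or window_end > p.T1 + _EPS:
            raise ValueError(
                f"recent model {model.model_id}: admixture window "
                f"[{p.Tgf}, {window_end}] must precede T1={p.T1}"
            )
    else:  # ancient
        if not (p.T1 <= p.Tgf + _EPS) or window_end > p.T2 + _EPS:
            raise ValueError(
                f"ancient model {model.model_id}: admixture window "
                f"[{p.Tgf}, {window_end}] must lie within [T1={p.T1}, T2={p.T2}]"
            )


# ---------------------------------------------------------------------------
# Priors
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ParamPrior:
    """Marginal prior for one parameter, optionally truncated by others.

    ``dist`` is ``"uniform"`` (args = (low, high)) or ``"exponential"``
    (args = (scale,), i.e. the mean; see ``PriorSpec.exp_parameterization``).
    ``low``/``high`` name previously sampled parameters whose values
    truncate this parameter's range (pairwise order constraints only).
    """

    name: str
    dist: str
    args: tuple
    low: Optional[str] = None
    high: Optional[str] = None

    def to_dict(self) -> dict:
        d = {"name": self.name, "dist": self.dist, "args": list(self.args)}
        if self.low:
            d["low"] = self.low
        if self.high:
            d["high"] = self.high
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ParamPrior":
        return cls(
            name=d["name"],
            dist=d["dist"],
            args=tuple(d["args"]),
            low=d.get("low"),
            high=d.get("high"),
        )


@dataclass(frozen=True)
class PriorSpec:
    """Joint prior for one model: ordered marginals plus constraints.

    Parameters are sampled in declaration order; truncation bounds that
    reference earlier parameters are applied as exact truncated-uniform
    draws (so the printed marginals of unconditioned parameters are
    preserved).  ``window`` optionally names ``(duration, start, bound)``
    parameters enforcing ``start + duration <= bound`` by a truncated
    redraw of the duration (whole-row redraw in the rare case where the
    window is narrower than the duration's lower bound).

    ``exp_parameterization`` records whether exponential ``args[0]`` is
    the distribution's mean or its rate.
    """

    params: tuple  # of ParamPrior, ordered
    window: Optional[tuple] = None  # (dur_name, start_name, bound_name)
    exp_parameterization: str = "mean"

    def names(self) -> list:
        return [p.name for p in self.params]

    def _by_name(self, name: str) -> ParamPrior:
        for p in self.params:
            if p.name == name:
                return p
        raise KeyError(name)

    def support(self, name: str) -> tuple:
        """Global support of one parameter's marginal distribution."""
        p = self._by_name(name)
        if p.dist == "exponential":
            return (0.0, math.inf)
        lo, hi = p.args
        # truncation by another parameter can only raise the effective
        # lower bound to at least that parameter's own minimum (and
        # symmetrically for the upper bound); it never extends the box.
        if p.low is not None:
            lo = max(lo, self.support(p.low)[0])
        if p.high is not None:
            hi = min(hi, self.support(p.high)[1])
        return (lo, hi)

    def sample_n(self, n: int, rng: np.random.Generator) -> pd.DataFrame:
        """Draw ``n`` joint prior vectors satisfying all constraints."""
        out = self._sample_block(n, rng)
        if self.window is not None:
            dur, start, bound = self.window
            dlo, dhi = self._by_name(dur).args
            for _ in range(1000):
                gap = out[bound].to_numpy() - out[start].to_numpy()
                bad = gap <= dlo  # window cannot fit the minimum duration
                if not bad.any():
                    break
                redraw = self._sample_block(int(bad.sum()), rng)
                out.loc[bad, :] = redraw.to_numpy()
            else:  # pragma: no cover - presets never reach this
                raise RuntimeError("window constraint unsatisfiable under prior")
            gap = out[bound].to_numpy() - out[start].to_numpy()
            hi = np.minimum(dhi, gap)
            viol = out[dur].to_numpy() > hi
            if viol.any():
                out.loc[viol, dur] = rng.uniform(dlo, hi[viol])
        return out

    def _sample_block(self, n: int, rng: np.random.Generator) -> pd.DataFrame:
        out = {}
        for p in self.params:
            if p.dist == "uniform":
                lo = np.full(n, p.args[0])
                hi = np.full(n, p.args[1])
                if p.low is not None:
                    lo = np.maximum(lo, out[p.low])
                if p.high is not None:
                    hi = np.minimum(hi, out[p.high])
                if np.any(hi <= lo):
                    raise ValueError(f"empty truncated range for {p.name}")
                out[p.name] = rng.uniform(lo, hi)
            elif p.dist == "exponential":
                scale = (
                    p.args[0]
                    if self.exp_parameterization == "mean"
                    else 1.0 / p.args[0]
                )
                out[p.name] = rng.exponential(scale, size=n)
            else:
                raise ValueError(f"unknown distribution {p.dist!r}")
        return pd.DataFrame(out)

    def to_dict(self) -> dict:
        d = {
            "params": [p.to_dict() for p in self.params],
            "exp_parameterization": self.exp_parameterization,
        }
        if self.window is not None:
            d["window"] = list(self.window)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PriorSpec":
        return cls(
            params=tuple(ParamPrior.from_dict(p) for p in d["params"]),
            window=tuple(d["window"]) if d.get("window") else None,
            exp_parameterization=d.get("exp_parameterization", "mean"),
        )


@dataclass(frozen=True)
class Priors:
    """A named preset: one PriorSpec per model id."""

    name: str
    admixture_mode: str
    specs: dict  # model_id -> PriorSpec

    def for_model(self, model_id: str) -> PriorSpec:
        if model_id not in self.specs:
            raise KeyError(f"no prior defined for model {model_id!r}")
        return self.specs[model_id]

    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "admixture_mode": self.admixture_mode,
            "specs": {m: s.to_dict() for m, s in self.specs.items()},
        }

    @classmethod
    def from_dict(cls, d: dict) -> "Priors":
        return cls(
            name=d["name"],
            admixture_mode=d["admixture_mode"],
            specs={m: PriorSpec.from_dict(s) for m, s in d["specs"].items()},
        )


def _u(name, lo, hi, low=None, high=None):
    return ParamPrior(name, "uniform", (lo, hi), low=low, high=high)


def simulation_priors() -> Priors:
    """Preset for the simulation study (continuous admixture window).

    theta ~ U(0.007, 0.35) — the endpoints are 4·Ne·mu·L for
    Ne ∈ {2000, 100000}, mu = 1.75e-9 and L = 500 bp.  Recent models use
    the printed marginals with T1 truncated above Tgf; the ancient
    models C and F, whose window must fall between the splits, draw
    Tgf ~ U(T1, T2) conditionally.  The gene-flow magnitude prior
    "E(0.1)" is read as exponential with RATE 0.1 (mean 4Nm = 10):
    under the mean-0.1 reading the expected number of migrant lineages
    over the short admixture window is ~0.005 and all six admixture
    models collapse onto isolation, so only the rate reading yields a
    candidate set whose members are distinguishable at all.  The
    parameterization is a config field (``exp_parameterization``) and
    can be flipped.
    """
    theta = _u("theta_S", 0.007, 0.35)
    nm = ParamPrior("Nm4", "exponential", (0.1,))
    recent = PriorSpec(
        params=(
            theta,
            _u("Tgf", 0.1, 0.5),
            _u("T1", 0.4, 1.0, low="Tgf"),
            _u("T2", 1.0, 4.0),
            _u("Tdur", 0.01, 0.1),
            nm,
        ),
        window=("Tdur", "Tgf", "T1"),
        exp_parameterization="rate",
    )
    ancient = PriorSpec(
        params=(
            theta,
            _u("T1", 0.4, 1.0),
            _u("T2", 1.0, 4.0),
            _u("Tgf", 0.1, 4.0, low="T1", high="T2"),
            _u("Tdur", 0.01, 0.1),
            nm,
        ),
        window=("Tdur", "Tgf", "T2"),
        exp_parameterization="rate",
    )
    iso = PriorSpec(params=(theta, _u("T1", 0.4, 1.0), _u("T2", 1.0, 4.0)))
    specs = {m: recent for m in RECENT_MODELS}
    specs.update({m: ancient for m in ANCIENT_MODELS})
    specs["ISO"] = iso
    return Priors("simulation", CONTINUOUS, specs)


def empirical_priors() -> Priors:
    """Preset for empirical-style analyses (pulse admixture).

    theta ~ U(0.01, 1.4) (a 1 kb locus over the same Ne/mu range),
    admixture proportion F ~ U(0, 1); split and gene-flow times on
    (0.1, 4) with the order constraints Tgf < T1 < T2 for recent models
    and T1 < Tgf < T2 for ancient ones, each imposed as conditional
    uniforms.
    """
    theta = _u("theta_S", 0.01, 1.4)
    f = _u("F", 0.0, 1.0)
    recent = PriorSpec(
        params=(
            theta,
            _u("Tgf", 0.1, 2.0),
            _u("T1", 0.1, 4.0, low="Tgf"),
            _u("T2", 0.1, 4.0, low="T1"),
            f,
        )
    )
    ancient = PriorSpec(
        params=(
            theta,
            _u("T1", 0.1, 4.0),
            _u("T2", 0.1, 4.0, low="T1"),
            _u("Tgf", 0.1, 4.0, low="T1", high="T2"),
            f,
        )
    )
    iso = PriorSpec(params=(theta, _u("T1", 0.1, 4.0), _u("T2", 0.1, 4.0, low="T1")))
    specs = {m: recent for m in RECENT_MODELS}
    specs.update({m: ancient for m in ANCIENT_MODELS})
    specs["ISO"] = iso
    return Priors("empirical", PULSE, specs)


PRESETS = {"simulation": simulation_priors, "empirical": empirical_priors}


def get_priors(name: str) -> Priors:
    try:
        return PRESETS[name]()
    except KeyError:
        raise KeyError(f"unknown prior preset {name!r}") from None


def sample_prior(
    model: ModelSpec, priors: Priors, rng: np.random.Generator
) -> ModelParameters:
    """Draw one parameter vector for ``model`` from ``priors``."""
    df = sample_prior_n(model, priors, 1, rng)
    return ModelParameters(**{k: float(v) for k, v in df.iloc[0].items()})


def sample_prior_n(
    model: ModelSpec, priors: Priors, n: int, rng: np.random.Generator
) -> pd.DataFrame:
    """Draw ``n`` parameter vectors; columns follow ``param_names(model)``."""
    if model.has_admixture and priors.admixture_mode != model.admixture_mode:
        raise ValueError(
            f"priors preset {priors.name!r} is for "
            f"{priors.admixture_mode} admixture, model uses {model.admixture_mode}"
        )
    spec = priors.for_model(model.model_id)
    df = spec.sample_n(n, rng)
    return df[param_names(model)]


# ---------------------------------------------------------------------------
# Demography plans
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MergeEvent:
    """Backward-in-time lineage movement of an entire population."""

    time: float
    derived: str   # population whose lineages move (the more recent one)
    ancestral: str  # population they join


@dataclass(frozen=True)
class MigrationEpoch:
    """Continuous gene flow over [start, end] backward in time.

    ``forward_source``/``forward_dest`` give the forward-in-time
    direction of migrant movement; rate is 4Nm.
    """

    start: float
    end: float
    rate: float
    forward_source: str
    forward_dest: str


@dataclass(frozen=True)
class PulseAdmixture:
    """Instantaneous admixture: proportion F of forward_dest's lineages
    derive from forward_source at ``time``."""

    time: float
    proportion: float
    forward_source: str
    forward_dest: str


@dataclass(frozen=True)
class DemographyPlan:
    """Ordered backward-in-time event list for the coalescent engine.

    All populations have relative size 1.  Merges implement the fixed
    topology: (pop2, pop3) join at T1, the pair joins pop1 at T2.
    """

    model_id: str
    events: tuple

    @property
    def merges(self):
        return [e for e in self.events if isinstance(e, MergeEvent)]

    @property
    def migrations(self):
        return [e for e in self.events if isinstance(e, MigrationEpoch)]

    @property
    def pulses(self):
        return [e for e in self.events if isinstance(e, PulseAdmixture)]


def build_demography(model: ModelSpec, params: ModelParameters) -> DemographyPlan:
    """Translate (model, parameters) into a backward-in-time event plan."""
    validate_parameters(model, params)
    events = []
    if model.has_admixture:
        src, dst = ADMIXTURE_DIRECTIONS[model.model_id]
        if model.admixture_mode == CONTINUOUS:
            events.append(
                MigrationEpoch(
                    start=params.Tgf,
                    end=params.Tgf + params.Tdur,
                    rate=params.Nm4,
                    forward_source=src,
                    forward_dest=dst,
                )
            )
        else:
            events.append(
                PulseAdmixture(
                    time=params.Tgf,
                    proportion=params.F,
                    forward_source=src,
                    forward_dest=dst,
                )
            )
    events.append(MergeEvent(time=params.T1, derived="pop3", ancestral="pop2"))
    events.append(MergeEvent(time=params.T2, derived="pop2", ancestral="pop1"))
    events.sort(key=lambda e: (getattr(e, "time", getattr(e, "start", 0.0))))
    return DemographyPlan(model_id=model.model_id, events=tuple(events))
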