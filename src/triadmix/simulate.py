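"""Coalescent simulation of multi-locus datasets and reference tables.

Genealogy and mutation generation are delegated to msprime behind a
thin adapter that consumes a :class:`~triadmix.models.DemographyPlan`.
Times in the plan are in units of 4·Ne generations (the ms convention);
the adapter realizes this by simulating haploid lineages in
populations of size 1/2 (pairwise coalescence rate 2 per time unit),
so that one unit of msprime time equals 4·Ne generations, a
continuous-window migration rate of ``4Nm`` maps directly onto the
migration-matrix entry, and a per-locus mutation rate of ``theta_S``
per time unit gives Watterson's E[S] = theta·a_{n-1}.  Mutations follow an infinite-sites
biallelic model (binary alleles at continuous positions), so every
stored site is segregating in the total sample.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional

import msprime
import numpy as np
import pandas as pd

from . import sumstats
from .models import (
    DemographyPlan,
    MergeEvent,
    MigrationEpoch,
    ModelSpec,
    Priors,
    PulseAdmixture,
    build_demography,
    param_names,
    sample_prior_n,
)

_POP_INDEX = {"pop1": 0, "pop2": 1, "pop3": 2, "anc23": 1}
_SEED_MOD = 2**31 - 2


@dataclass(frozen=True)
class SampleConfig:
    """Sampling design: sequences per population, locus number/length.

    Sample sizes are in sequences: a diploid individual contributes 2,
    a single haploid contributes 1.
    """

    n_seq: tuple
    n_loci: int
    locus_length: int

    def __post_init__(self):
        if len(self.n_seq) != 3 or any(n < 1 for n in self.n_seq):
            raise ValueError("three populations with >= 1 sequence each required")
        if self.n_loci < 1 or self.locus_length < 1:
            raise ValueError("need n_loci >= 1 and locus_length >= 1")

    @classmethod
    def diploid(cls, individuals_per_pop: int, n_loci: int, locus_length: int):
        n = 2 * individuals_per_pop
        return cls((n, n, n), n_loci, locus_length)

    @property
    def total_sequences(self) -> int:
        return int(sum(self.n_seq))


@dataclass
class LocusData:
    """One locus: biallelic 0/1 site matrix plus sample labels.

    ``genotypes`` is sites x sequences with arbitrary 0/1 allele labels
    (no polarization).  Only sites segregating in the total sample are
    stored.  ``individuals`` pairs sequences into diploids where that
    pairing is known (phase never matters downstream).
    """

    genotypes: np.ndarray
    populations: np.ndarray
    length: int
    individuals: Optional[np.ndarray] = None
    positions: Optional[np.ndarray] = None  # relative in [0, 1)


@dataclass
class Dataset:
    """An ordered multi-locus collection sharing one SampleConfig."""

    loci: list
    config: SampleConfig
    provenance: dict = field(default_factory=dict)

    def __len__(self):
        return len(self.loci)


def to_msprime_demography(plan: DemographyPlan) -> msprime.Demography:
    """Translate a DemographyPlan into an msprime Demography.

    msprime's migration matrix and mass migrations are expressed
    backward in time: migrants moving forward from A into B correspond
    to lineages in B tracing back into A.
    """
    dem = msprime.Demography()
    # haploid lineages (ploidy=1) coalesce pairwise at rate 1/N per
    # generation; N = 1/2 makes that rate 2 per unit time, the ms
    # convention where one unit is 4*Ne generations.
    for name in ("pop1", "pop2", "pop3"):
        dem.add_population(name=name, initial_size=0.5)
    for ev in plan.events:
        if isinstance(ev, MergeEvent):
            dem.add_mass_migration(
                time=ev.time,
                source=_POP_INDEX[ev.derived],
                dest=_POP_INDEX[ev.ancestral],
                proportion=1.0,
            )
        elif isinstance(ev, MigrationEpoch):
            src = _POP_INDEX[ev.forward_source]
            dst = _POP_INDEX[ev.forward_dest]
            dem.add_migration_rate_change(
                time=ev.start, rate=ev.rate, source=dst, dest=src
            )
            dem.add_migration_rate_change(time=ev.end, rate=0.0, source=dst, dest=src)
        elif isinstance(ev, PulseAdmixture):
            dem.add_mass_migration(
                time=ev.time,
                source=_POP_INDEX[ev.forward_dest],
                dest=_POP_INDEX[ev.forward_source],
                proportion=ev.proportion,
            )
        else:  # pragma: no cover
            raise TypeError(f"unknown plan event {ev!r}")
    dem.sort_events()
    return dem


def _seeds_for(seed: int):
    ss = np.random.SeedSequence(seed)
    s_anc, s_mut = ss.spawn(2)
    anc_seed = int(np.random.Generator(np.random.PCG64(s_anc)).integers(1, _SEED_MOD))
    mut_rng = np.random.Generator(np.random.PCG64(s_mut))
    return anc_seed, mut_rng


def _ancestries(plan: DemographyPlan, config: SampleConfig, seed: int):
    dem = to_msprime_demography(plan)
    anc_seed, mut_rng = _seeds_for(seed)
    samples = [
        msprime.SampleSet(int(n), population=i, ploidy=1)
        for i, n in enumerate(config.n_seq)
    ]
    reps = msprime.sim_ancestry(
        samples=samples,
        demography=dem,
        sequence_length=config.locus_length,
        ploidy=1,
        num_replicates=config.n_loci,
        random_seed=anc_seed,
    )
    return reps, mut_rng


def _drop_mutations(ts, theta_S: float, rng: np.random.Generator):
    """Infinite-sites mutations on a single non-recombining genealogy.

    The mutation count is Poisson(theta * total branch length in
    4Ne-generation units) and each mutation lands on an edge with
    probability proportional to its branch length, at a fresh uniform
    position — exactly the ms model.  Returns (mutated edge children,
    sorted relative positions, site order); the alleles derived at a
    site are the samples below the mutated edge.
    """
    tables = ts.tables
    child = tables.edges.child
    parent = tables.edges.parent
    time = tables.nodes.time
    blen = time[parent] - time[child]
    total = blen.sum()
    k = int(rng.poisson(theta_S * total))
    if k == 0:
        return child[:0], np.empty(0), np.empty(0, dtype=int)
    cum = np.cumsum(blen)
    edge_idx = np.searchsorted(cum, rng.random(k) * total)
    pos = rng.random(k)
    order = np.argsort(pos, kind="stable")
    return child[edge_idx], pos, order


def _subtree_pop_counts(ts, pops: np.ndarray):
    """Per-node count of sample leaves in each population.

    Edges are sorted by parent time, and node times are distinct in a
    coalescent tree, so a single pass accumulates every subtree.
    """
    tables = ts.tables
    child = tables.edges.child
    parent = tables.edges.parent
    counts = np.zeros((ts.num_nodes, 3), dtype=np.int32)
    counts[np.arange(len(pops)), pops] = 1
    for c, p in zip(child, parent):
        counts[p] += counts[c]
    return counts


def _subtree_masks(ts, nsam: int):
    """Per-node boolean mask of the sample leaves below it."""
    tables = ts.tables
    child = tables.edges.child
    parent = tables.edges.parent
    masks = np.zeros((ts.num_nodes, nsam), dtype=bool)
    masks[np.arange(nsam), np.arange(nsam)] = True
    for c, p in zip(child, parent):
        masks[p] |= masks[c]
    return masks


def simulate_dataset(
    plan: DemographyPlan, config: SampleConfig, theta_S: float, seed: int
) -> Dataset:
    """Simulate ``config.n_loci`` independent loci under ``plan``.

    Identical (plan, config, theta_S, seed) yield bitwise-identical
    datasets.  Loci with no mutations are retained with empty site
    matrices (their per-locus statistics are all zero).
    """
    if theta_S <= 0:
        raise ValueError("theta_S must be positive")
    pops = np.repeat(np.arange(3), config.n_seq)
    nsam = config.total_sequences
    inds = np.arange(nsam) // 2
    loci = []
    reps, mut_rng = _ancestries(plan, config, seed)
    for ts in reps:
        mut_children, pos, order = _drop_mutations(ts, theta_S, mut_rng)
        if len(mut_children):
            masks = _subtree_masks(ts, nsam)
            G = masks[mut_children][order].astype(np.uint8)
            positions = pos[order]
        else:
            G = np.zeros((0, nsam), dtype=np.uint8)
            positions = pos
        loci.append(
            LocusData(
                genotypes=G,
                populations=pops,
                length=config.locus_length,
                individuals=inds,
                positions=positions,
            )
        )
    return Dataset(
        loci=loci,
        config=config,
        provenance={"model": plan.model_id, "theta_S": theta_S, "seed": seed},
    )


def simulate_stat_row(
    plan: DemographyPlan,
    config: SampleConfig,
    theta_S: float,
    seed: int,
    stat_config: sumstats.StatConfig,
) -> np.ndarray:
    """Summary-statistic vector of a simulated dataset (fast path).

    Skips genotype matrices entirely — the statistics only need the
    per-population derived-allele count at each site, which is the
    per-population subtree leaf count below each mutated edge.
    Numerically identical to
    ``sumstats.dataset_stats(simulate_dataset(...), stat_config)`` at
    the same seed.
    """
    if theta_S <= 0:
        raise ValueError("theta_S must be positive")
    n_seq = np.asarray(config.n_seq)
    stat_config.validate_sample_sizes(n_seq)
    pops = np.repeat(np.arange(3), n_seq)
    rows = np.empty((config.n_loci, len(stat_config.per_locus_names)))
    reps, mut_rng = _ancestries(plan, config, seed)
    for i, ts in enumerate(reps):
        mut_children, _, _ = _drop_mutations(ts, theta_S, mut_rng)
        if len(mut_children):
            counts = _subtree_pop_counts(ts, pops)
            derived = counts[mut_children]
        else:
            derived = np.zeros((0, 3), dtype=int)
        rows[i] = sumstats.locus_stats_from_counts(derived, n_seq, stat_config)
    return sumstats.compress_moments(rows, stat_config)


# ---------------------------------------------------------------------------
# Reference tables
# ---------------------------------------------------------------------------

@dataclass
class ReferenceTable:
    """Rows of (model label, parameters, summary statistics).

    ``df`` holds a ``model`` column, parameter columns (union across
    models, NaN where a model lacks a parameter) and the statistic
    columns named by ``stat_config.names``.
    """

    df: pd.DataFrame
    stat_config: sumstats.StatConfig
    param_names: tuple
    metadata: dict = field(default_factory=dict)

    @property
    def stat_names(self) -> tuple:
        return self.stat_config.names

    @property
    def models(self) -> tuple:
        return tuple(pd.unique(self.df["model"]))

    @property
    def n_rows(self) -> int:
        return len(self.df)

    def rows_per_model(self) -> dict:
        return self.df["model"].value_counts().to_dict()

    def stats_matrix(self) -> np.ndarray:
        return self.df[list(self.stat_names)].to_numpy(dtype=float)

    def restrict_to_model(self, model_id: str) -> "ReferenceTable":
        sub = self.df[self.df["model"] == model_id].reset_index(drop=True)
        return ReferenceTable(sub, self.stat_config, self.param_names, self.metadata)

    def drop_row(self, index: int) -> "ReferenceTable":
        sub = self.df.drop(index=index).reset_index(drop=True)
        return ReferenceTable(sub, self.stat_config, self.param_names, self.metadata)

    # -- persistence --------------------------------------------------------

    def save(self, path) -> None:
        """Columnar store (parquet) plus a JSON metadata sidecar."""
        path = Path(path)
        self.df.to_parquet(path)
        meta = {
            "stat_config": {
                "identifier": self.stat_config.identifier,
                "singleton_pop": self.stat_config.singleton_pop,
                "standardized_moments": self.stat_config.standardized_moments,
            },
            "param_names": list(self.param_names),
            "metadata": self.metadata,
        }
        path.with_suffix(path.suffix + ".meta.json").write_text(
            json.dumps(meta, indent=1)
        )

    @classmethod
    def load(cls, path) -> "ReferenceTable":
        path = Path(path)
        df = pd.read_parquet(path)
        meta = json.loads(path.with_suffix(path.suffix + ".meta.json").read_text())
        return cls(
            df=df,
            stat_config=sumstats.StatConfig(**meta["stat_config"]),
            param_names=tuple(meta["param_names"]),
            metadata=meta["metadata"],
        )

    def to_tsv(self, path) -> None:
        self.df.to_csv(path, sep="\t", index=False)


def row_seed(master_seed: int, model_index: int, row_index: int) -> int:
    """Deterministic per-row seed, independent of execution order."""
    ss = np.random.SeedSequence([int(master_seed), int(model_index), int(row_index)])
    return int(ss.generate_state(1)[0] % _SEED_MOD) + 1


def build_reference_table(
    models: Iterable[ModelSpec],
    priors: Priors,
    config: SampleConfig,
    n_per_model: int,
    stat_config: sumstats.StatConfig,
    seed: int,
    progress: bool = False,
) -> ReferenceTable:
    """Simulate ``n_per_model`` prior draws per model and summarize each.

    Per-row seeds derive from (master seed, model index, row index), so
    the table is reproducible regardless of how rows are scheduled.
    """
    models = list(models)
    stat_config.validate_sample_sizes(config.n_seq)
    all_params = sorted(
        {n for m in models for n in param_names(m)},
        key="theta_S T1 T2 Tgf Tdur Nm4 F".split().index,
    )
    records = []
    stat_cols = list(stat_config.names)
    for m_idx, model in enumerate(models):
        prior_rng = np.random.Generator(
            np.random.PCG64(np.random.SeedSequence([int(seed), m_idx, 10**6]))
        )
        draws = sample_prior_n(model, priors, n_per_model, prior_rng)
        iterator = range(n_per_model)
        if progress:  # pragma: no cover - cosmetic
            import sys

            print(f"model {model.model_id}: {n_per_model} rows", file=sys.stderr)
        for r in iterator:
            row = draws.iloc[r]
            from .models import ModelParameters

            params = ModelParameters(**{k: float(v) for k, v in row.items()})
            plan = build_demography(model, params)
            vec = simulate_stat_row(
                plan, config, params.theta_S, row_seed(seed, m_idx, r), stat_config
            )
            rec = {"model": model.model_id}
            rec.update({k: float(row[k]) for k in draws.columns})
            rec.update(dict(zip(stat_cols, vec)))
            records.append(rec)
    df = pd.DataFrame.from_records(
        records, columns=["model"] + all_params + stat_cols
    )
    meta = {
        "priors": priors.to_dict(),
        "sample_config": {
            "n_seq": list(config.n_seq),
            "n_loci": config.n_loci,
            "locus_length": config.locus_length,
        },
        "n_per_model": n_per_model,
        "seed": int(seed),
        "models": [m.model_id for m in models],
    }
    return ReferenceTable(df, stat_config, tuple(all_params), meta)
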