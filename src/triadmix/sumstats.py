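"""Wakeley–Hey site-category statistics and their moment compression.

For each ordered pair of populations, every biallelic segregating site
falls in exactly one of four categories: a *fixed difference* (each
population monomorphic, for different alleles), a *shared polymorphism*
(both polymorphic), or a polymorphism *private* to one population.
These categories need neither ancestral-state polarization nor phased
haplotypes: they depend only on the per-population allele counts, which
is what makes them usable on unphased diploid data without an outgroup.

Per locus we record 13 statistics under the full three-population
configuration: for each of the three population pairs the proportions
of pair-informative sites that are fixed differences, shared
polymorphisms, and private polymorphisms (the two private categories
pooled); the number of sites segregating within each population; and
the number segregating in the total sample.  Across loci each per-locus
statistic is compressed to its first four distribution moments (mean,
variance, skewness and kurtosis), giving 52 summary statistics.  When
one population is represented by a single haploid sequence, its own
segregating-site count and the shared-polymorphism proportions of its
two pairs carry no information and are dropped, leaving 10 per-locus
statistics and 40 summaries.  A means-only variant keeps just the 13
per-locus means.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from typing import Optional

import numpy as np
from scipy import stats as sps

FULL_3POP = "full_3pop"
REDUCED_SINGLE_HAPLOID = "reduced_single_haploid"
MEANS_ONLY = "means_only"

_PAIRS = ((0, 1), (0, 2), (1, 2))
_MOMENT_SUFFIXES = ("mean", "var", "skew", "kurt")


class SiteCategory(Enum):
    FIXED_DIFFERENCE = "fixed_difference"
    SHARED_POLYMORPHISM = "shared_polymorphism"
    PRIVATE_POP_I = "private_pop_i"
    PRIVATE_POP_J = "private_pop_j"
    UNINFORMATIVE = "uninformative"


def classify_site(alleles_pop_i, alleles_pop_j) -> SiteCategory:
    """Classify one biallelic site for an ordered population pair.

    Arguments are iterables of 0/1 allele observations (labels
    arbitrary — the classification is invariant under simultaneous
    0<->1 relabeling).  A site monomorphic for the same allele in both
    populations is uninformative.
    """
    ai = np.asarray(list(alleles_pop_i))
    aj = np.asarray(list(alleles_pop_j))
    if ai.size == 0 or aj.size == 0:
        raise ValueError("empty population sample at site")
    poly_i = ai.min() != ai.max()
    poly_j = aj.min() != aj.max()
    if poly_i and poly_j:
        return SiteCategory.SHARED_POLYMORPHISM
    if poly_i:
        return SiteCategory.PRIVATE_POP_I
    if poly_j:
        return SiteCategory.PRIVATE_POP_J
    if ai[0] != aj[0]:
        return SiteCategory.FIXED_DIFFERENCE
    return SiteCategory.UNINFORMATIVE


@dataclass(frozen=True)
class StatConfig:
    """Which per-locus statistics and which moments are used.

    ``singleton_pop`` (0-based) names the single-sequence population in
    the reduced configuration; ignored otherwise.
    """

    identifier: str = FULL_3POP
    singleton_pop: int = 2
    standardized_moments: bool = True

    def __post_init__(self):
        if self.identifier not in (FULL_3POP, REDUCED_SINGLE_HAPLOID, MEANS_ONLY):
            raise ValueError(f"unknown statistic configuration {self.identifier!r}")
        if self.singleton_pop not in (0, 1, 2):
            raise ValueError("singleton_pop must be 0, 1 or 2")

    @property
    def per_locus_names(self) -> tuple:
        names = []
        for i, j in _PAIRS:
            tag = f"pair{i + 1}{j + 1}"
            names += [f"{tag}_fixed", f"{tag}_shared", f"{tag}_private"]
        names += [f"S_pop{i + 1}" for i in range(3)] + ["S_total"]
        if self.identifier == REDUCED_SINGLE_HAPLOID:
            s = self.singleton_pop
            drop = {f"S_pop{s + 1}"}
            for i, j in _PAIRS:
                if s in (i, j):
                    drop.add(f"pair{i + 1}{j + 1}_shared")
            names = [n for n in names if n not in drop]
        return tuple(names)

    @property
    def n_moments(self) -> int:
        return 1 if self.identifier == MEANS_ONLY else 4

    @property
    def names(self) -> tuple:
        if self.n_moments == 1:
            return tuple(f"{n}_mean" for n in self.per_locus_names)
        return tuple(
            f"{n}_{m}" for n in self.per_locus_names for m in _MOMENT_SUFFIXES
        )

    @property
    def length(self) -> int:
        return len(self.names)

    def validate_sample_sizes(self, n_seq) -> None:
        if self.identifier == REDUCED_SINGLE_HAPLOID:
            if n_seq[self.singleton_pop] != 1:
                raise ValueError(
                    "reduced_single_haploid requires exactly one sequence in "
                    f"population {self.singleton_pop + 1}, got {n_seq}"
                )


def locus_stats_from_counts(
    derived: np.ndarray, n_seq, config: StatConfig
) -> np.ndarray:
    """Per-locus statistic vector from per-population allele-1 counts.

    ``derived`` has shape (sites, 3): the count of the (arbitrarily
    labelled) 1 allele in each population at each segregating site.
    Sites monomorphic in the total sample contribute nothing and may be
    present or absent.  Returns the per-locus vector in the order of
    ``config.per_locus_names``.
    """
    n_seq = np.asarray(n_seq)
    c = np.asarray(derived)
    full = np.zeros(13)
    if c.size:
        seg = (c > 0) & (c < n_seq)  # sites x 3, segregating within pop
        ctot = c.sum(axis=1)
        pos = 0
        for i, j in _PAIRS:
            cc = c[:, i] + c[:, j]
            informative = (cc > 0) & (cc < n_seq[i] + n_seq[j])
            k = informative.sum()
            if k:
                shared = informative & seg[:, i] & seg[:, j]
                private = informative & (seg[:, i] ^ seg[:, j])
                fixed = informative & ~seg[:, i] & ~seg[:, j]
                full[pos : pos + 3] = (
                    fixed.sum() / k,
                    shared.sum() / k,
                    private.sum() / k,
                )
            pos += 3
        full[9:12] = seg.sum(axis=0)
        full[12] = ((ctot > 0) & (ctot < n_seq.sum())).sum()
    if config.identifier != REDUCED_SINGLE_HAPLOID:
        return full
    keep = [
        FULL_PER_LOCUS_NAMES.index(n) for n in config.per_locus_names
    ]
    return full[keep]


FULL_PER_LOCUS_NAMES = StatConfig(FULL_3POP).per_locus_names


def locus_stats(locus, config: StatConfig) -> np.ndarray:
    """Per-locus statistics for a ``LocusData`` (see ``triadmix.simulate``)."""
    pops = np.asarray(locus.populations)
    n_seq = np.array([(pops == p).sum() for p in range(3)])
    if (n_seq == 0).any():
        raise ValueError("all three populations need at least one sequence")
    config.validate_sample_sizes(n_seq)
    G = np.asarray(locus.genotypes)
    if G.size == 0:
        derived = np.zeros((0, 3), dtype=int)
    else:
        derived = np.stack([G[:, pops == p].sum(axis=1) for p in range(3)], axis=1)
    return locus_stats_from_counts(derived, n_seq, config)


def compress_moments(per_locus: np.ndarray, config: StatConfig) -> np.ndarray:
    """Across-locus moment compression of a loci x statistics matrix.

    Emits, per statistic, the sample mean and (unless means-only) the
    sample variance, skewness (g1) and kurtosis (the fourth
    standardized moment m4/m2^2).  Statistics that are constant across
    loci have zero variance; their skewness and kurtosis are reported
    as 0 so the vector stays finite.  ``standardized_moments=False``
    replaces the scale-free moments 3–4 with raw central moments.
    """
    X = np.asarray(per_locus, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2:
        raise ValueError("need a loci x statistics matrix with >= 2 loci")
    mean = X.mean(axis=0)
    var = X.var(axis=0, ddof=1)
    if config.n_moments == 1:
        return mean
    degenerate = X.var(axis=0) <= 0
    if config.standardized_moments:
        import warnings

        with np.errstate(invalid="ignore", divide="ignore"), warnings.catch_warnings():
            # constant columns are handled explicitly below
            warnings.filterwarnings("ignore", message=".*catastrophic cancellation.*")
            skew = sps.skew(X, axis=0)
            kurt = sps.kurtosis(X, axis=0, fisher=False)
    else:
        d = X - mean
        skew = (d**3).mean(axis=0)
        kurt = (d**4).mean(axis=0)
    skew = np.where(degenerate, 0.0, skew)
    kurt = np.where(degenerate, 0.0, kurt)
    out = np.column_stack([mean, var, skew, kurt]).ravel()
    out = np.nan_to_num(out, nan=0.0, posinf=0.0, neginf=0.0)
    assert out.size == config.length
    return out


def dataset_stats(dataset, config: StatConfig) -> np.ndarray:
    """Full summary-statistic vector for a multi-locus dataset."""
    rows = [locus_stats(locus, config) for locus in dataset.loci]
    return compress_moments(np.asarray(rows), config)


def per_locus_matrix(dataset, config: StatConfig) -> np.ndarray:
    """Loci x statistics matrix (for audit dumps and tests)."""
    return np.asarray([locus_stats(locus, config) for locus in dataset.loci])


def stats_from_alignments(
    alignments, popmap, config: StatConfig, pairing=None
) -> np.ndarray:
    """Summary statistics from per-locus multiple sequence alignments.

    ``alignments`` is a list of FASTA paths (one per locus) or a
    directory; ``popmap`` a TSV mapping sample -> population (optional
    third column: ploidy, default 1).  Diploids may be encoded either
    as one IUPAC-ambiguity sequence (ploidy 2) or as two haplotype
    records; the statistics are identical either way because they only
    depend on population allele counts.  Sites with gaps, Ns or more
    than two alleles are dropped per site.
    """
    from .alignments import read_alignments

    dataset = read_alignments(alignments, popmap)
    return dataset_stats(dataset, config)


def stats_to_tsv(vector: np.ndarray, config: StatConfig, path) -> None:
    """Write a one-row TSV with the documented statistic header."""
    import pandas as pd

    pd.DataFrame([np.asarray(vector)], columns=list(config.names)).to_csv(
        path, sep="\t", index=False
    )


def stats_from_tsv(path, config: Optional[StatConfig] = None):
    """Read a one-row statistic TSV; returns (vector, names)."""
    import pandas as pd

    df = pd.read_csv(path, sep="\t")
    vec = df.iloc[0].to_numpy(dtype=float)
    if config is not None and list(df.columns) != list(config.names):
        raise ValueError("statistic TSV header does not match configuration")
    return vec, tuple(df.columns)
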