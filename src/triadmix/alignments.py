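"""Empirical input: per-locus FASTA alignments plus a population map.

Diploid individuals may be encoded either as a single sequence with
IUPAC ambiguity codes at heterozygous sites (ploidy 2 in the popmap)
or as two separate haplotype records; the downstream statistics depend
only on population allele counts, so the two encodings are equivalent
and phase is never needed.

Per-site filters (applied per locus, counts logged): sites containing
gaps, Ns or any character outside {A, C, G, T} + the biallelic
heterozygote codes {R, Y, S, W, K, M} are dropped, as are sites with
more than two alleles.  Monomorphic sites carry no information and are
not stored.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Iterable, Union

import numpy as np
import pandas as pd
from Bio import SeqIO

from .simulate import Dataset, LocusData, SampleConfig

logger = logging.getLogger(__name__)

IUPAC_HET = {
    "R": ("A", "G"),
    "Y": ("C", "T"),
    "S": ("C", "G"),
    "W": ("A", "T"),
    "K": ("G", "T"),
    "M": ("A", "C"),
}
BASES = {"A", "C", "G", "T"}


def read_popmap(path) -> pd.DataFrame:
    """TSV: sample <TAB> population [<TAB> ploidy]; ploidy defaults to 1."""
    df = pd.read_csv(
        path, sep="\t", header=None, comment="#", dtype=str
    ).iloc[:, :3]
    df.columns = ["sample", "population", "ploidy"][: df.shape[1]]
    if "ploidy" not in df:
        df["ploidy"] = "1"
    df["ploidy"] = df["ploidy"].fillna("1").astype(int)
    if not df["ploidy"].isin((1, 2)).all():
        raise ValueError("ploidy must be 1 or 2")
    if df["sample"].duplicated().any():
        raise ValueError("duplicate sample in population map")
    return df


def _expand(seqs: dict, popmap: pd.DataFrame):
    """Split records into per-haplotype allele columns.

    Returns (columns, pops) where columns is a list of per-haplotype
    base lists and pops the matching population indices.
    """
    pop_order = list(dict.fromkeys(popmap["population"]))
    if len(pop_order) != 3:
        raise ValueError(f"exactly three populations required, got {pop_order}")
    pop_idx = {p: i for i, p in enumerate(pop_order)}
    by_sample = popmap.set_index("sample")
    length = None
    cols, pops, inds = [], [], []
    for ind, (name, seq) in enumerate(seqs.items()):
        if name not in by_sample.index:
            raise KeyError(f"sample {name!r} missing from population map")
        row = by_sample.loc[name]
        s = str(seq).upper()
        if length is None:
            length = len(s)
        elif len(s) != length:
            raise ValueError(f"length mismatch for {name!r} within locus")
        ploidy = int(row["ploidy"])
        if ploidy == 1:
            hap_sets = [[(c,) for c in s]]
        else:
            h1, h2 = [], []
            for c in s:
                if c in IUPAC_HET:
                    a, b = IUPAC_HET[c]
                elif c in BASES:
                    a = b = c
                else:
                    a = b = c  # filtered later
                h1.append((a,))
                h2.append((b,))
            hap_sets = [h1, h2]
        for h in hap_sets:
            cols.append([x[0] for x in h])
            pops.append(pop_idx[row["population"]])
            inds.append(ind)
    return cols, np.array(pops), np.array(inds), pop_order, length


def _locus_from_records(seqs: dict, popmap: pd.DataFrame) -> tuple:
    cols, pops, inds, pop_order, length = _expand(seqs, popmap)
    M = np.array([list(c) for c in cols]).T  # sites x haplotypes
    keep_rows = []
    allele_maps = []
    n_filtered = 0
    for site in M:
        alleles = set(site)
        if alleles - BASES:
            n_filtered += 1
            continue
        if len(alleles) > 2:
            n_filtered += 1
            continue
        if len(alleles) < 2:
            continue  # monomorphic: uninformative, not stored
        a0 = sorted(alleles)[0]
        keep_rows.append((site != a0).astype(np.uint8))
        allele_maps.append(tuple(sorted(alleles)))
    G = (
        np.array(keep_rows, dtype=np.uint8)
        if keep_rows
        else np.zeros((0, len(cols)), dtype=np.uint8)
    )
    if n_filtered:
        logger.info("locus: %d site(s) dropped by biallelic/ungapped filter", n_filtered)
    locus = LocusData(
        genotypes=G, populations=pops, length=length, individuals=inds
    )
    return locus, pop_order, n_filtered


def read_alignments(
    fastas: Union[str, Path, Iterable], popmap_path
) -> Dataset:
    """Read per-locus FASTA alignments into a Dataset.

    ``fastas`` is a directory (all ``*.fa``/``*.fasta`` files, sorted)
    or an iterable of paths, one alignment per locus.  All loci must
    cover the same samples.
    """
    popmap = read_popmap(popmap_path)
    if isinstance(fastas, (str, Path)) and Path(fastas).is_dir():
        paths = sorted(
            p for p in Path(fastas).iterdir() if p.suffix in (".fa", ".fasta")
        )
    else:
        paths = [Path(p) for p in fastas]
    if not paths:
        raise ValueError("no FASTA inputs")
    loci = []
    pop_order = None
    total_filtered = 0
    for p in paths:
        seqs = {rec.id: rec.seq for rec in SeqIO.parse(str(p), "fasta")}
        locus, order, nf = _locus_from_records(seqs, popmap)
        total_filtered += nf
        if pop_order is None:
            pop_order = order
        loci.append(locus)
    n_seq = tuple(int((loci[0].populations == i).sum()) for i in range(3))
    config = SampleConfig(n_seq, n_loci=len(loci), locus_length=loci[0].length)
    logger.info(
        "read %d loci (%d filtered sites total); populations %s with %s sequences",
        len(loci), total_filtered, pop_order, n_seq,
    )
    return Dataset(
        loci=loci,
        config=config,
        provenance={"source": "alignments", "populations": pop_order,
                    "filtered_sites": total_filtered},
    )


def write_alignments(
    dataset: Dataset,
    outdir,
    alleles: tuple = ("A", "G"),
    diploid_iupac: bool = False,
) -> tuple:
    """Encode a (typically simulated) Dataset as per-locus FASTA files.

    Allele 0/1 labels map to ``alleles``.  With ``diploid_iupac`` the
    two haplotypes of each individual collapse into one IUPAC sequence.
    Only segregating sites are written, so these are variable-column
    alignments meant for round-trip testing, not full sequences.
    Returns (fasta paths, popmap path).
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rev = {tuple(sorted(v)): k for k, v in IUPAC_HET.items()}
    paths = []
    popmap_rows = []
    for li, locus in enumerate(dataset.loci):
        G = np.asarray(locus.genotypes)
        path = outdir / f"locus{li:05d}.fa"
        with open(path, "w") as fh:
            if diploid_iupac:
                if locus.individuals is None:
                    raise ValueError("diploid output needs individual pairing")
                for ind in np.unique(locus.individuals):
                    cols = np.flatnonzero(locus.individuals == ind)
                    if len(cols) != 2:
                        raise ValueError("diploid output needs paired sequences")
                    a = [alleles[x] for x in G[:, cols[0]]]
                    b = [alleles[x] for x in G[:, cols[1]]]
                    seq = "".join(
                        x if x == y else rev[tuple(sorted((x, y)))]
                        for x, y in zip(a, b)
                    )
                    name = f"ind{ind}"
                    fh.write(f">{name}\n{seq}\n")
                    if li == 0:
                        popmap_rows.append(
                            (name, f"pop{locus.populations[cols[0]] + 1}", 2)
                        )
            else:
                for s in range(G.shape[1]):
                    seq = "".join(alleles[x] for x in G[:, s])
                    name = f"seq{s}"
                    fh.write(f">{name}\n{seq}\n")
                    if li == 0:
                        popmap_rows.append(
                            (name, f"pop{locus.populations[s] + 1}", 1)
                        )
        paths.append(path)
    popmap_path = outdir / "popmap.tsv"
    pd.DataFrame(popmap_rows).to_csv(
        popmap_path, sep="\t", header=False, index=False
    )
    return paths, popmap_path
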