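"""Reader/writer for ms-style simulator text output.

Canonical layout: a command line whose ``-I 3 n1 n2 n3`` clause
declares population sample sizes, a seed line, then one ``//`` block
per locus with ``segsites:``, ``positions:`` and 0/1 haplotype rows.
``write_ms_text(read_ms_text(f))`` is the identity on canonical files.
"""

from __future__ import annotations

import io
from pathlib import Path
from typing import Optional

import numpy as np

from .simulate import Dataset, LocusData, SampleConfig


def write_ms_text(dataset: Dataset, path_or_stream) -> None:
    close = False
    if isinstance(path_or_stream, (str, Path)):
        stream = open(path_or_stream, "w")
        close = True
    else:
        stream = path_or_stream
    try:
        cfg = dataset.config
        n1, n2, n3 = cfg.n_seq
        nsam = cfg.total_sequences
        seed = dataset.provenance.get("seed", 0)
        stream.write(f"ms {nsam} {cfg.n_loci} -I 3 {n1} {n2} {n3}\n{seed}\n")
        for locus in dataset.loci:
            G = np.asarray(locus.genotypes)
            k = G.shape[0]
            stream.write(f"\n//\nsegsites: {k}\n")
            if k:
                pos = locus.positions
                if pos is None:
                    pos = (np.arange(k) + 0.5) / k
                stream.write(
                    "positions: " + " ".join(f"{p:.5f}" for p in pos) + "\n"
                )
                for hap in G.T:
                    stream.write("".join("1" if a else "0" for a in hap) + "\n")
    finally:
        if close:
            stream.close()


def read_ms_text(path_or_stream, pop_sizes: Optional[tuple] = None) -> Dataset:
    """Parse ms text output into a Dataset.

    Population sizes come from the command line's ``-I`` clause unless
    overridden with ``pop_sizes`` (required when the producing command
    simulated a single panmictic sample).
    """
    if isinstance(path_or_stream, (str, Path)):
        text = Path(path_or_stream).read_text()
    else:
        text = path_or_stream.read()
    lines = text.splitlines()
    if not lines:
        raise ValueError("empty ms stream")
    cmd = lines[0].split()
    if len(cmd) < 3:
        raise ValueError(f"malformed ms command line: {lines[0]!r}")
    nsam = int(cmd[1])
    if pop_sizes is None:
        if "-I" in cmd:
            i = cmd.index("-I")
            npop = int(cmd[i + 1])
            if npop != 3:
                raise ValueError("exactly three populations expected")
            pop_sizes = tuple(int(x) for x in cmd[i + 2 : i + 5])
        else:
            raise ValueError("no -I clause and no pop_sizes override")
    if sum(pop_sizes) != nsam:
        raise ValueError("population sizes do not sum to the sample size")
    seed = 0
    if len(lines) > 1 and lines[1].strip().lstrip("-").isdigit():
        seed = int(lines[1].strip())

    pops = np.repeat(np.arange(3), pop_sizes)
    loci = []
    i = 0
    while i < len(lines):
        if lines[i].strip() != "//":
            i += 1
            continue
        i += 1
        if i >= len(lines) or not lines[i].startswith("segsites:"):
            raise ValueError(f"expected 'segsites:' after '//' near line {i + 1}")
        k = int(lines[i].split(":", 1)[1])
        i += 1
        positions = None
        if k > 0:
            if i >= len(lines) or not lines[i].startswith("positions:"):
                raise ValueError(f"expected 'positions:' near line {i + 1}")
            positions = np.array(
                [float(x) for x in lines[i].split(":", 1)[1].split()]
            )
            if positions.size != k:
                raise ValueError("positions count does not match segsites")
            i += 1
            haps = []
            for _ in range(nsam):
                if i >= len(lines):
                    raise ValueError("truncated haplotype block")
                row = lines[i].strip()
                if len(row) != k or set(row) - {"0", "1"}:
                    raise ValueError(f"bad haplotype row at line {i + 1}")
                haps.append([int(c) for c in row])
                i += 1
            G = np.array(haps, dtype=np.uint8).T
        else:
            G = np.zeros((0, nsam), dtype=np.uint8)
        loci.append(
            LocusData(
                genotypes=G,
                populations=pops,
                length=1,
                positions=positions,
            )
        )
    config = SampleConfig(tuple(pop_sizes), n_loci=max(len(loci), 1), locus_length=1)
    if not loci:
        raise ValueError("no '//' locus blocks found")
    return Dataset(loci=loci, config=config, provenance={"seed": seed, "source": "ms"})


def ms_roundtrip_text(dataset: Dataset) -> str:
    buf = io.StringIO()
    write_ms_text(dataset, buf)
    return buf.getvalue()
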