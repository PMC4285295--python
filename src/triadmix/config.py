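"""Run configuration, prior-config files, seeds and manifests."""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from . import __version__
from .models import PRESETS, Priors, get_priors
from .simulate import SampleConfig
from .sumstats import StatConfig


def load_priors(source) -> Priors:
    """A preset name, or a YAML file with a serialized prior preset.

    Custom files use the documented schema: ``name``,
    ``admixture_mode`` and per-model ``specs`` whose parameters carry a
    distribution (uniform/exponential), its arguments and optional
    pairwise order constraints (``low``/``high`` naming an earlier
    parameter).
    """
    if isinstance(source, Priors):
        return source
    if source in PRESETS:
        return get_priors(source)
    with open(source) as fh:
        return Priors.from_dict(yaml.safe_load(fh))


def save_priors(priors: Priors, path) -> None:
    Path(path).write_text(yaml.safe_dump(priors.to_dict(), sort_keys=False))


@dataclass
class RunConfig:
    """Everything needed to reproduce a run bit-for-bit."""

    models: list = field(default_factory=lambda: list("ABCDEF") + ["ISO"])
    priors: str = "simulation"
    individuals_per_pop: int = 1
    n_loci: int = 1000
    locus_length: int = 500
    stat_config: str = "full_3pop"
    singleton_pop: int = 2
    n_per_model: int = 1000
    tolerance: float = 0.001
    nn_tolerance: float = 0.005
    seed: int = 1
    workers: int = 1
    outdir: str = "triadmix_out"

    def sample_config(self) -> SampleConfig:
        return SampleConfig.diploid(
            self.individuals_per_pop, self.n_loci, self.locus_length
        )

    def stat_configuration(self) -> StatConfig:
        return StatConfig(self.stat_config, singleton_pop=self.singleton_pop)

    @classmethod
    def load(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls(**(yaml.safe_load(fh) or {}))

    def save(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=False))

    def digest(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:16]


def write_manifest(outdir, config, extra=None) -> Path:
    """JSON manifest binding outputs to config hash, seed and version."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = {
        "version": __version__,
        "config": asdict(config) if isinstance(config, RunConfig) else dict(config),
        "config_hash": config.digest() if isinstance(config, RunConfig) else None,
    }
    if extra:
        manifest.update(extra)
    path = outdir / "manifest.json"
    path.write_text(json.dumps(manifest, indent=1, default=str))
    return path
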