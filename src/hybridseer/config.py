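"""Configuration objects shared by the simulator, the pipeline, and the CLI.

All randomness in the package flows from a single integer seed carried by
these objects; sub-streams are derived with :func:`substream` so that each
stage draws from an independent, reproducible generator.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Any

import numpy as np
import yaml


class ConfigError(ValueError):
    """Raised when a configuration file or object violates its schema."""


# Stable stream ids so adding a stage never shifts another stage's draws.
STREAMS = {
    "ancestral": 1,
    "variants": 2,
    "genes": 3,
    "offspring": 4,
    "reads": 5,
    "slocus": 6,
    "panel": 7,
    "assembly": 8,
}


def substream(seed: int, name: str, extra: int = 0) -> np.random.Generator:
    """Return the dedicated RNG for stage *name* under global *seed*."""
    return np.random.default_rng([int(seed), STREAMS[name], int(extra)])


@dataclass
class SimulationConfig:
    """Parameters of the synthetic hybrid cross.

    The defaults describe the study conditions the analyses are validated
    under: two parental species ~1% diverged at the sequence level, 0.2%
    within-species heterozygosity, and uniform 150-bp single-end reads with a
    0.5% per-base error rate.

    Parameters
    ----------
    genome_length : int
        Haploid (per-haplotype) genome length in bases.
    n_genes : int
        Number of non-overlapping gene models to annotate.
    gene_length_mean : int
        Mean gene length in bases.
    interspecies_divergence : float
        Per-base substitution rate separating the two parental species
        (sites where the species consensus sequences differ).
    intraspecies_heterozygosity : float
        Per-base rate at which each parent's two haplotypes differ.
    indel_fraction : float
        Fraction of variant sites realised as 1-10 bp InDels rather than
        substitutions.
    read_length : int
        Read length in bases (single-end).
    coverage : float
        Per-haplotype fold coverage; total emitted bases are
        ``coverage * 2 * genome_length``.
    error_rate : float
        Per-base substitution error rate of the read simulator.
    offspring_type : str
        ``"F1"`` (one haplotype from each parent) or ``"BC1"`` (backcross of
        an F1 gamete to the maternal recurrent parent).
    bc_recomb_rate : float
        Mean crossovers per chromosome in the BC1 gamete (Poisson).
    rng_seed : int
        Global seed; identical configs produce byte-identical outputs.
    """

    genome_length: int = 1_000_000
    n_genes: int = 500
    gene_length_mean: int = 1_000
    interspecies_divergence: float = 0.01
    intraspecies_heterozygosity: float = 0.002
    indel_fraction: float = 0.15
    read_length: int = 150
    coverage: float = 30.0
    error_rate: float = 0.005
    offspring_type: str = "F1"
    bc_recomb_rate: float = 2.0
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.genome_length < self.n_genes * self.gene_length_mean:
            raise ConfigError(
                "genome_length must be at least n_genes * gene_length_mean "
                f"({self.genome_length} < {self.n_genes * self.gene_length_mean})"
            )
        for name in (
            "interspecies_divergence",
            "intraspecies_heterozygosity",
            "indel_fraction",
            "error_rate",
        ):
            v = getattr(self, name)
            if not 0.0 <= v < 1.0:
                raise ConfigError(f"{name} must be in [0, 1), got {v}")
        if self.interspecies_divergence + self.intraspecies_heterozygosity >= 0.5:
            raise ConfigError(
                "interspecies_divergence + intraspecies_heterozygosity >= 0.5: "
                "alleles are no longer identifiable"
            )
        if self.coverage <= 0:
            raise ConfigError("coverage must be positive")
        if self.read_length < 20:
            raise ConfigError("read_length must be >= 20")
        if self.read_length > self.genome_length:
            raise ConfigError("read_length exceeds genome length")
        if self.offspring_type not in ("F1", "BC1"):
            raise ConfigError("offspring_type must be 'F1' or 'BC1'")
        if self.bc_recomb_rate < 0:
            raise ConfigError("bc_recomb_rate must be non-negative")

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "SimulationConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ConfigError(f"unknown simulate keys: {sorted(unknown)}")
        return cls(**d)

    def to_dict(self) -> dict[str, Any]:
        return dataclasses.asdict(self)

    def rng(self, stream: str, extra: int = 0) -> np.random.Generator:
        return substream(self.rng_seed, stream, extra)


@dataclass
class PipelineConfig:
    """Resolved configuration of a full ``hybridseer run``.

    Each stage owns a parameter block; unknown keys anywhere are rejected so
    that typos never silently fall back to defaults.
    """

    simulate: SimulationConfig = field(default_factory=SimulationConfig)
    kmer: dict[str, Any] = field(default_factory=dict)
    phase: dict[str, Any] = field(default_factory=dict)
    variome: dict[str, Any] = field(default_factory=dict)
    slocus: dict[str, Any] = field(default_factory=dict)
    rng_seed: int = 0
    out_dir: str = "hybridseer_out"
    log_level: str = "INFO"

    _KNOWN_KMER = {"k", "max_multiplicity", "basis"}
    _KNOWN_PHASE = {"min_depth", "fold", "min_support", "min_breadth"}
    _KNOWN_VARIOME = {"snps_only", "normalize", "n_per_group", "panel_sites"}
    _KNOWN_SLOCUS = {"identity_threshold", "n_accessions", "pool_size", "n_trios"}

    def __post_init__(self) -> None:
        for name, known in (
            ("kmer", self._KNOWN_KMER),
            ("phase", self._KNOWN_PHASE),
            ("variome", self._KNOWN_VARIOME),
            ("slocus", self._KNOWN_SLOCUS),
        ):
            block = getattr(self, name)
            unknown = set(block) - known
            if unknown:
                raise ConfigError(f"unknown {name} keys: {sorted(unknown)}")
        if self.log_level not in ("DEBUG", "INFO", "WARNING", "ERROR"):
            raise ConfigError(f"bad log_level {self.log_level!r}")

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "PipelineConfig":
        d = dict(d)
        known = {
            "simulate", "kmer", "phase", "variome", "slocus",
            "rng_seed", "out_dir", "log_level",
        }
        unknown = set(d) - known
        if unknown:
            raise ConfigError(f"unknown pipeline keys: {sorted(unknown)}")
        sim = dict(d.pop("simulate", {}))
        seed = d.get("rng_seed", 0)
        sim.setdefault("rng_seed", seed)
        return cls(simulate=SimulationConfig.from_dict(sim), **d)

    @classmethod
    def from_yaml(cls, path: str) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if not isinstance(raw, dict):
            raise ConfigError(f"{path}: top level must be a mapping")
        return cls.from_dict(raw)

    def to_dict(self) -> dict[str, Any]:
        d = dataclasses.asdict(self)
        d["simulate"] = self.simulate.to_dict()
        return d

    def to_yaml(self, path: str) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)
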