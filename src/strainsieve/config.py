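"""Configuration objects, thresholds and logging for the strainsieve pipeline.

All analysis-defining cutoffs live in :class:`Thresholds`; the defaults are the
published values of the workflow this package implements (10x site depth,
3 reads / 10% depth for allele presence, 90% fixation for consensus building,
20-mers with a 90% match fraction for the gene screen). Everything that drives
the synthetic-data generator lives in :class:`SimulationConfig`, and a full
end-to-end run is described by :class:`RunConfig`, which round-trips through
YAML losslessly.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping

import yaml

logger = logging.getLogger("strainsieve")

# Exit codes used by the CLI: 0 ok, 2 config error, 3 data error.
EXIT_OK = 0
EXIT_CONFIG_ERROR = 2
EXIT_DATA_ERROR = 3


class ConfigError(ValueError):
    """Invalid configuration (missing inputs, inconsistent parameters)."""


class DataError(ValueError):
    """Invalid or degenerate data encountered at run time."""


def setup_logging(level: str = "INFO", logfile: str | Path | None = None) -> None:
    """Configure the package logger to stderr and, optionally, a logfile."""
    logger.setLevel(level.upper())
    logger.handlers.clear()
    fmt = logging.Formatter("%(asctime)s %(levelname)s %(name)s: %(message)s")
    sh = logging.StreamHandler()
    sh.setFormatter(fmt)
    logger.addHandler(sh)
    if logfile is not None:
        fh = logging.FileHandler(logfile)
        fh.setFormatter(fmt)
        logger.addHandler(fh)


@dataclass(frozen=True)
class Thresholds:
    """Analysis cutoffs.

    min_depth
        Minimum read depth (DP) for a site to be analysed at all, in reads.
    min_allele_reads, min_allele_frac
        An allele is *present* in a sample iff supported by at least
        ``min_allele_reads`` reads **and** at least ``min_allele_frac`` of the
        site's read depth.
    fixation_frac
        A mapped site is *nearly fixed* iff its major allele accounts for at
        least this fraction of read depth; only such sites contribute a base
        to the masked consensus.
    kmer_k, min_kmer_frac
        Gene-screen parameters: k-mer size and the minimum fraction of a
        read's k-mers that must match a gene for assignment.
    """

    min_depth: int = 10
    min_allele_reads: int = 3
    min_allele_frac: float = 0.10
    fixation_frac: float = 0.90
    kmer_k: int = 20
    min_kmer_frac: float = 0.90

    def __post_init__(self) -> None:
        if self.min_depth < 1 or self.min_allele_reads < 1 or self.kmer_k < 1:
            raise ConfigError("integer thresholds must be >= 1")
        for name in ("min_allele_frac", "fixation_frac", "min_kmer_frac"):
            v = getattr(self, name)
            if not 0.0 < v <= 1.0:
                raise ConfigError(f"{name} must be in (0, 1], got {v}")


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of the synthetic-data generator.

    The defaults reproduce the study conditions the downstream analyses were
    designed around: four samples, a sharing design with 6/7/24/176 alleles
    present in 4/3/2/1 samples (213 planted alleles in total), allele
    fractions spanning the polymorphic-to-fixed range, and per-site depth
    comfortably above the 10x analysis threshold.
    """

    seed: int = 0
    n_samples: int = 4
    genome_length: int = 50_000
    n_variant_sites: int = 213
    depth: int = 100
    fraction_grid: tuple[float, ...] = (0.2, 0.3, 0.4, 0.5, 0.6, 0.7, 0.8, 0.9, 1.0)
    sharing_spec: Mapping[int, int] = field(
        default_factory=lambda: {4: 6, 3: 7, 2: 24, 1: 176}
    )
    unmapped_fraction: float = 0.05
    gene_db_size: int = 12
    gene_length: int = 600
    read_length: int = 150
    n_reads: int = 500
    read_identity: float = 1.0
    n_taxa: int = 30
    library_size: int = 100_000
    dominance: float = 0.3

    def __post_init__(self) -> None:
        if self.n_samples < 1:
            raise ConfigError("n_samples must be >= 1")
        if self.depth < 10:
            raise ConfigError("mean depth must be >= 10 so sites pass the depth filter")
        if self.n_variant_sites > self.genome_length:
            raise ConfigError("n_variant_sites cannot exceed genome_length")
        if sum(self.sharing_spec.values()) != self.n_variant_sites:
            raise ConfigError(
                "sharing_spec counts must sum to n_variant_sites "
                f"({sum(self.sharing_spec.values())} != {self.n_variant_sites})"
            )
        if any(s < 1 or s > self.n_samples for s in self.sharing_spec):
            raise ConfigError("sharing classes must be in [1, n_samples]")
        if not 0.0 <= self.unmapped_fraction < 1.0:
            raise ConfigError("unmapped_fraction must be in [0, 1)")
        for f in self.fraction_grid:
            if not 0.0 < f <= 1.0:
                raise ConfigError("true allele fractions must be in (0, 1]")


#: Stage names in dependency order; genescreen and community are independent
#: of the variant branch.
STAGES = ("simulate", "variants", "alleles", "consensus", "genescreen", "community")


@dataclass
class RunConfig:
    """Full pipeline configuration (YAML-serialisable)."""

    outdir: str = "strainsieve_out"
    seed: int = 0
    log_level: str = "INFO"
    stages: tuple[str, ...] = STAGES
    thresholds: Thresholds = field(default_factory=Thresholds)
    simulation: SimulationConfig | None = field(default_factory=SimulationConfig)
    # Explicit input paths; filled in from the simulate stage when present.
    reference_fasta: str | None = None
    vcf_paths: Mapping[str, str] = field(default_factory=dict)  # sample -> vcf
    mapped_regions_tsv: str | None = None
    gene_fasta: str | None = None
    category_map_tsv: str | None = None
    reads_fastq: str | None = None
    abundance_tsv: str | None = None
    sample_metadata_tsv: str | None = None

    def validate(self) -> None:
        unknown = set(self.stages) - set(STAGES)
        if unknown:
            raise ConfigError(f"unknown stages: {sorted(unknown)}")
        simulated = "simulate" in self.stages and self.simulation is not None
        if not simulated:
            need = {
                "variants": ["vcf_paths"],
                "alleles": ["vcf_paths", "mapped_regions_tsv"],
                "consensus": ["vcf_paths", "mapped_regions_tsv", "reference_fasta"],
                "genescreen": ["gene_fasta", "category_map_tsv", "reads_fastq"],
                "community": ["abundance_tsv"],
            }
            for stage in self.stages:
                for attr in need.get(stage, []):
                    if not getattr(self, attr):
                        raise ConfigError(
                            f"stage '{stage}' requires '{attr}' when not simulating"
                        )

    # -- YAML round-trip ----------------------------------------------------

    def to_dict(self) -> dict[str, Any]:
        d = dataclasses.asdict(self)
        d["stages"] = list(self.stages)
        d["thresholds"] = dataclasses.asdict(self.thresholds)
        if self.simulation is not None:
            sim = dataclasses.asdict(self.simulation)
            sim["fraction_grid"] = list(self.simulation.fraction_grid)
            sim["sharing_spec"] = dict(self.simulation.sharing_spec)
            d["simulation"] = sim
        d["vcf_paths"] = dict(self.vcf_paths)
        return d

    @classmethod
    def from_dict(cls, d: Mapping[str, Any]) -> "RunConfig":
        d = dict(d)
        if "thresholds" in d and isinstance(d["thresholds"], Mapping):
            d["thresholds"] = Thresholds(**d["thresholds"])
        sim = d.get("simulation")
        if isinstance(sim, Mapping):
            sim = dict(sim)
            if "fraction_grid" in sim:
                sim["fraction_grid"] = tuple(sim["fraction_grid"])
            if "sharing_spec" in sim:
                sim["sharing_spec"] = {int(k): int(v) for k, v in sim["sharing_spec"].items()}
            d["simulation"] = SimulationConfig(**sim)
        if "stages" in d:
            d["stages"] = tuple(d["stages"])
        allowed = {f.name for f in dataclasses.fields(cls)}
        extra = set(d) - allowed
        if extra:
            raise ConfigError(f"unknown config keys: {sorted(extra)}")
        return cls(**d)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text())
        if not isinstance(data, Mapping):
            raise ConfigError(f"config file {path} did not parse to a mapping")
        return cls.from_dict(data)
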