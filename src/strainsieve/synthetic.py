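"""Synthetic data generator for every pipeline input.

Emulates the statistical structure the downstream analyses assume: a
reference genome; planted non-reference alleles with a controlled
cross-sample sharing design (how many alleles are present in exactly s of S
samples) and true within-sample fractions drawn from a grid spanning
polymorphic to fixed; per-site read counts binomially sampled at a fixed
depth; reads generated from a gene database at a controlled per-read
identity; and dominance-skewed species abundance profiles with a paired
viable ("PMA") subsample. Coverage is modelled as uniform per-site depth
with per-sample contiguous unmapped blocks — the downstream analyses consume
only counts and depths, so no read placement is simulated.

Every generator is a pure function of its arguments and seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .config import DataError, SimulationConfig, logger
from .community import AbundanceTable
from .variants import VariantRecord, write_vcf

BASES = np.array(list("ACGT"))


def simulate_reference(length: int, gc: float = 0.5, seed: int = 0) -> str:
    """Random reference sequence with the requested GC content."""
    if length < 1:
        raise DataError(f"reference length must be positive, got {length}")
    if not 0.0 < gc < 1.0:
        raise DataError("gc must be in (0, 1)")
    rng = np.random.default_rng(seed)
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return "".join(rng.choice(BASES, size=length, p=p))


@dataclass
class StrainTruth:
    """Ground truth of a planted multi-sample variant dataset."""

    reference_id: str
    reference_seq: str
    #: sample -> {position -> (alt base, true allele fraction in (0, 1])}
    planted: dict[str, dict[int, tuple[str, float]]]
    #: s -> number of alleles present in exactly s samples
    sharing_design: dict[int, int]
    #: sample -> positions with simulated coverage
    mapped: dict[str, frozenset[int]]

    @property
    def sample_ids(self) -> list[str]:
        return sorted(self.planted)

    def n_planted_alleles(self) -> int:
        return len({(pos, alt) for m in self.planted.values()
                    for pos, (alt, _f) in m.items()})


def _unmapped_blocks(rng: np.random.Generator, length: int, fraction: float,
                     n_blocks: int = 3) -> set[int]:
    """Contiguous unmapped blocks covering ~``fraction`` of the genome."""
    total = int(round(fraction * length))
    if total == 0:
        return set()
    sizes = [total // n_blocks] * n_blocks
    sizes[0] += total - sum(sizes)
    unmapped: set[int] = set()
    for size in sizes:
        if size == 0:
            continue
        for _ in range(100):
            start = int(rng.integers(1, length - size + 2))
            block = set(range(start, start + size))
            if not block & unmapped:
                unmapped |= block
                break
    return unmapped


def plant_variants(ref: str, config: SimulationConfig) -> StrainTruth:
    """Plant non-reference alleles according to the sharing design.

    Positions are sampled without replacement from the region mapped in all
    samples; each planted allele differs from the reference base and is
    assigned to exactly the number of samples its sharing class dictates,
    with per-sample true fractions drawn from the fraction grid.
    """
    if sum(config.sharing_spec.values()) != config.n_variant_sites:
        raise DataError("sharing_spec inconsistent with n_variant_sites")
    rng = np.random.default_rng(config.seed)
    length = len(ref)
    samples = [f"S{i + 1}" for i in range(config.n_samples)]
    mapped = {
        s: frozenset(range(1, length + 1))
        - frozenset(_unmapped_blocks(rng, length, config.unmapped_fraction))
        for s in samples
    }
    core = sorted(frozenset.intersection(*mapped.values()))
    if len(core) < config.n_variant_sites:
        raise DataError("jointly mapped region too small for requested variant sites")
    positions = rng.choice(core, size=config.n_variant_sites, replace=False)
    planted: dict[str, dict[int, tuple[str, float]]] = {s: {} for s in samples}
    grid = np.asarray(config.fraction_grid)
    classes = [s for s, n in sorted(config.sharing_spec.items()) for _ in range(n)]
    for pos, n_shared in zip(positions.tolist(), classes):
        ref_base = ref[pos - 1]
        alt = str(rng.choice([b for b in "ACGT" if b != ref_base]))
        carriers = rng.choice(samples, size=n_shared, replace=False)
        for s in carriers:
            planted[s][pos] = (alt, float(rng.choice(grid)))
    return StrainTruth(
        reference_id="ref",
        reference_seq=ref,
        planted=planted,
        sharing_design=dict(config.sharing_spec),
        mapped=mapped,
    )


def simulate_read_counts(
    truth: StrainTruth, depth: int, seed: int = 0
) -> dict[str, list[VariantRecord]]:
    """Binomially sample per-site read counts for every planted allele.

    At each planted site in a carrying sample the alternate count is drawn
    Binomial(depth, true fraction); the reference count is the remainder and
    the record carries the total depth.
    """
    if depth < 1:
        raise DataError("depth must be >= 1")
    rng = np.random.default_rng(seed)
    records: dict[str, list[VariantRecord]] = {}
    for s in truth.sample_ids:
        recs = []
        for pos in sorted(truth.planted[s]):
            alt, frac = truth.planted[s][pos]
            alt_n = int(rng.binomial(depth, frac))
            recs.append(
                VariantRecord(
                    chrom=truth.reference_id,
                    pos=pos,
                    ref_allele=truth.reference_seq[pos - 1],
                    alt_alleles=(alt,),
                    ref_obs=depth - alt_n,
                    alt_obs=(alt_n,),
                    depth=depth,
                )
            )
        records[s] = recs
    return records


# -- gene database and reads -------------------------------------------------

_DEFAULT_CATEGORIES = (
    "beta_lactam", "aminoglycoside", "tetracycline", "macrolide", "efflux_pump",
    "adhesin", "toxin", "iron_uptake", "secretion_system", "capsule",
)


def simulate_gene_db(
    n_genes: int, gene_length: int = 600, seed: int = 0,
    categories: Sequence[str] = _DEFAULT_CATEGORIES,
) -> tuple[list[tuple[str, str]], dict[str, tuple[str, ...]]]:
    """Random gene sequences with a cyclic gene -> category map."""
    rng = np.random.default_rng(seed)
    genes = [
        (f"gene{i + 1:03d}", "".join(rng.choice(BASES, size=gene_length)))
        for i in range(n_genes)
    ]
    catmap = {gid: (categories[i % len(categories)],) for i, (gid, _) in enumerate(genes)}
    return genes, catmap


@dataclass(frozen=True)
class SimulatedRead:
    read_id: str
    seq: str
    source_gene: str
    strand: str  # '+' or '-'
    n_mutations: int


_COMPLEMENT = str.maketrans("ACGT", "TGCA")


def simulate_gene_reads(
    genes: Sequence[tuple[str, str]],
    identity: float = 1.0,
    n_reads: int = 100,
    read_length: int = 150,
    seed: int = 0,
) -> list[SimulatedRead]:
    """Reads drawn as gene substrings mutated to a controlled identity.

    The number of substitutions per read is round((1 - identity) * length),
    placed uniformly, never twice at the same position, so per-read identity
    is exact (up to rounding). Half the reads are reverse-complemented.
    """
    if not 0.0 < identity <= 1.0:
        raise DataError("identity must be in (0, 1]")
    min_len = min(len(seq) for _gid, seq in genes)
    if read_length > min_len:
        raise DataError(f"read_length {read_length} exceeds shortest gene ({min_len})")
    rng = np.random.default_rng(seed)
    n_mut = int(round((1.0 - identity) * read_length))
    reads = []
    for i in range(n_reads):
        gid, gseq = genes[int(rng.integers(len(genes)))]
        start = int(rng.integers(0, len(gseq) - read_length + 1))
        seq = list(gseq[start : start + read_length])
        for p in rng.choice(read_length, size=n_mut, replace=False):
            seq[p] = str(rng.choice([b for b in "ACGT" if b != seq[p]]))
        out = "".join(seq)
        strand = "+" if rng.random() < 0.5 else "-"
        if strand == "-":
            out = out.translate(_COMPLEMENT)[::-1]
        reads.append(SimulatedRead(f"read{i + 1:05d}", out, gid, strand, n_mut))
    return reads


# -- community abundance -----------------------------------------------------

def simulate_abundance(
    n_taxa: int = 30,
    n_samples: int = 3,
    dominance: float = 0.3,
    seed: int = 0,
    library_size: int = 100_000,
    pma_dropout: float = 0.3,
    pma_subsample: float = 0.5,
) -> AbundanceTable:
    """Dirichlet-multinomial species profiles with paired PMA subsamples.

    ``dominance`` is the symmetric Dirichlet concentration: smaller values
    give more dominance-skewed profiles (larger expected top-1 share). Each
    untreated sample gets a paired "PMA" sample formed by zeroing a random
    taxon subset (dropout probability ``pma_dropout``) and multinomially
    subsampling ``pma_subsample`` of its reads — a viability stand-in, not a
    chemistry model.
    """
    if n_taxa < 2:
        raise DataError("n_taxa must be >= 2")
    if dominance <= 0:
        raise DataError("dominance (Dirichlet concentration) must be positive")
    rng = np.random.default_rng(seed)
    taxa = [f"taxon_{i + 1:02d}" for i in range(n_taxa)]
    locations = ["ISS", "ISS", "SAF"]
    materials = ["dust", "filter", "dust"]
    cols: dict[str, np.ndarray] = {}
    meta_rows = []
    for j in range(n_samples):
        name = f"{locations[j % 3]}_{materials[j % 3]}_{j + 1}"
        p = rng.dirichlet(np.full(n_taxa, dominance))
        counts = rng.multinomial(library_size, p)
        cols[name] = counts
        meta_rows.append((name, locations[j % 3], materials[j % 3], False))
        keep = rng.random(n_taxa) >= pma_dropout
        viable = counts * keep
        if viable.sum() == 0:  # keep at least the most abundant taxon viable
            viable = counts * (counts == counts.max())
        sub = rng.multinomial(int(round(pma_subsample * viable.sum())),
                              viable / viable.sum())
        cols[name + "_PMA"] = sub
        meta_rows.append((name + "_PMA", locations[j % 3], materials[j % 3], True))
    counts_df = pd.DataFrame(cols, index=pd.Index(taxa, name="taxon"))
    meta = pd.DataFrame(
        meta_rows, columns=["sample", "location", "material", "pma_treated"]
    ).set_index("sample")
    return AbundanceTable(counts=counts_df, metadata=meta)


# -- writers -----------------------------------------------------------------

def write_fasta(records: Sequence[tuple[str, str]], path: str | Path) -> None:
    with open(path, "w") as fh:
        for rid, seq in records:
            fh.write(f">{rid}\n")
            for i in range(0, len(seq), 80):
                fh.write(seq[i : i + 80] + "\n")


def write_reads_fastq(reads: Sequence[SimulatedRead], path: str | Path) -> None:
    with open(path, "w") as fh:
        for r in reads:
            fh.write(f"@{r.read_id} source={r.source_gene} strand={r.strand}\n"
                     f"{r.seq}\n+\n{'I' * len(r.seq)}\n")


def write_truth_tsv(truth: StrainTruth, path: str | Path) -> None:
    rows = [
        (s, pos, truth.reference_seq[pos - 1], alt, frac)
        for s in truth.sample_ids
        for pos, (alt, frac) in sorted(truth.planted[s].items())
    ]
    pd.DataFrame(rows, columns=["sample", "pos", "ref", "alt", "true_fraction"]
                 ).to_csv(path, sep="\t", index=False)


def _to_intervals(positions: frozenset[int]) -> list[tuple[int, int]]:
    out = []
    for p in sorted(positions):
        if out and p == out[-1][1] + 1:
            out[-1] = (out[-1][0], p)
        else:
            out.append((p, p))
    return out


def write_mapped_regions_tsv(truth: StrainTruth, path: str | Path) -> None:
    """1-based inclusive mapped intervals per sample."""
    rows = [
        (s, start, end)
        for s in truth.sample_ids
        for start, end in _to_intervals(truth.mapped[s])
    ]
    pd.DataFrame(rows, columns=["sample", "start", "end"]).to_csv(
        path, sep="\t", index=False)


def read_mapped_regions_tsv(path: str | Path) -> dict[str, frozenset[int]]:
    df = pd.read_csv(path, sep="\t")
    out: dict[str, set[int]] = {}
    for _, row in df.iterrows():
        out.setdefault(str(row["sample"]), set()).update(
            range(int(row["start"]), int(row["end"]) + 1))
    return {s: frozenset(v) for s, v in out.items()}


def write_sample_vcfs(
    truth: StrainTruth,
    records: Mapping[str, Sequence[VariantRecord]],
    outdir: str | Path,
) -> dict[str, str]:
    """One minimal-dialect VCF per sample; returns sample -> path."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    contigs = {truth.reference_id: len(truth.reference_seq)}
    paths = {}
    for s, recs in records.items():
        p = outdir / f"{s}.vcf"
        write_vcf(list(recs), p, contigs=contigs)
        paths[s] = str(p)
    return paths


def write_category_map_tsv(catmap: Mapping[str, Sequence[str]], path: str | Path,
                           database: str = "synthetic") -> None:
    rows = [(g, c, database) for g, cats in sorted(catmap.items()) for c in cats]
    pd.DataFrame(rows, columns=["gene_id", "category", "database"]).to_csv(
        path, sep="\t", index=False)
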