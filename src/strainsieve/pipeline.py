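"""Config-driven orchestration of all analysis stages.

Stages run in dependency order (simulate -> variants -> alleles -> consensus;
genescreen and community are independent branches); a failure in one branch
does not abort independent branches. Stages communicate via files only, so
every intermediate is re-runnable and inspectable, and the run manifest
records stage statuses, output paths with checksums, the seed and warning
counts.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from pathlib import Path
from typing import Any

import pandas as pd
from Bio import SeqIO

from . import __version__
from .config import ConfigError, DataError, RunConfig, logger
from . import alleles as am
from . import community as cm
from . import consensus as cs
from . import genescreen as gs
from . import synthetic as syn
from . import variants as vio


def _sha256(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


class _Manifest:
    def __init__(self, config: RunConfig):
        self.data: dict[str, Any] = {
            "version": __version__,
            "seed": config.seed,
            "config": config.to_dict(),
            "stages": {},
            "inputs": {},
        }

    def record(self, stage: str, status: str, outputs: dict[str, str],
               counts: dict[str, Any] | None = None, error: str | None = None,
               elapsed: float = 0.0) -> None:
        entry: dict[str, Any] = {
            "status": status,
            "elapsed_s": round(elapsed, 3),
            "outputs": {k: {"path": p, "sha256": _sha256(p)}
                        for k, p in outputs.items() if Path(p).exists()},
        }
        if counts:
            entry["counts"] = counts
        if error:
            entry["error"] = error
        self.data["stages"][stage] = entry

    def write(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.data, indent=2, sort_keys=True) + "\n")


def _stage_simulate(config: RunConfig, outdir: Path) -> tuple[dict[str, str], dict]:
    sim = config.simulation
    assert sim is not None
    sim = dataclasses.replace(sim, seed=config.seed)
    ref = syn.simulate_reference(sim.genome_length, 0.5, seed=sim.seed)
    truth = syn.plant_variants(ref, sim)
    records = syn.simulate_read_counts(truth, sim.depth, seed=sim.seed + 1)
    simdir = outdir / "simulated"
    simdir.mkdir(parents=True, exist_ok=True)
    syn.write_fasta([(truth.reference_id, ref)], simdir / "reference.fasta")
    vcf_paths = syn.write_sample_vcfs(truth, records, simdir / "vcf")
    syn.write_truth_tsv(truth, simdir / "truth.tsv")
    syn.write_mapped_regions_tsv(truth, simdir / "mapped_regions.tsv")
    genes, catmap = syn.simulate_gene_db(sim.gene_db_size, sim.gene_length,
                                         seed=sim.seed + 2)
    syn.write_fasta(genes, simdir / "genes.fasta")
    syn.write_category_map_tsv(catmap, simdir / "categories.tsv")
    reads = syn.simulate_gene_reads(genes, sim.read_identity, sim.n_reads,
                                    sim.read_length, seed=sim.seed + 3)
    syn.write_reads_fastq(reads, simdir / "reads.fastq")
    abund = syn.simulate_abundance(sim.n_taxa, 3, sim.dominance,
                                   seed=sim.seed + 4, library_size=sim.library_size)
    abund.to_tsv(simdir / "abundance.tsv", simdir / "sample_metadata.tsv")
    # Wire simulated outputs in as the downstream inputs.
    config.reference_fasta = str(simdir / "reference.fasta")
    config.vcf_paths = vcf_paths
    config.mapped_regions_tsv = str(simdir / "mapped_regions.tsv")
    config.gene_fasta = str(simdir / "genes.fasta")
    config.category_map_tsv = str(simdir / "categories.tsv")
    config.reads_fastq = str(simdir / "reads.fastq")
    config.abundance_tsv = str(simdir / "abundance.tsv")
    config.sample_metadata_tsv = str(simdir / "sample_metadata.tsv")
    outputs = {
        "reference": str(simdir / "reference.fasta"),
        "truth": str(simdir / "truth.tsv"),
        "mapped_regions": str(simdir / "mapped_regions.tsv"),
        "genes": str(simdir / "genes.fasta"),
        "categories": str(simdir / "categories.tsv"),
        "reads": str(simdir / "reads.fastq"),
        "abundance": str(simdir / "abundance.tsv"),
        **{f"vcf_{s}": p for s, p in vcf_paths.items()},
    }
    return outputs, {"n_planted_alleles": truth.n_planted_alleles(),
                     "n_samples": len(truth.sample_ids)}


def _stage_variants(config: RunConfig, outdir: Path) -> tuple[dict[str, str], dict]:
    rows, n_parsed = [], 0
    n_rejected = n_retained = 0
    for sample, vcf in sorted(config.vcf_paths.items()):
        result = vio.parse_variants(vcf)
        n_parsed += len(result.records)
        n_rejected += result.n_rejected
        prims = [p for r in result.records for p in vio.decompose_to_primitives(r)]
        kept = vio.filter_sites(prims, config.thresholds)
        n_retained += len(kept)
        rows += [(sample, p.chrom, p.pos, p.ref_base, p.alt_base, p.ref_obs,
                  p.alt_obs, p.depth) for p in kept]
    out = outdir / "primitives.tsv"
    pd.DataFrame(rows, columns=["sample", "chrom", "pos", "ref", "alt",
                                "ref_obs", "alt_obs", "depth"]
                 ).to_csv(out, sep="\t", index=False)
    return {"primitives": str(out)}, {
        "records_parsed": n_parsed, "records_rejected": n_rejected,
        "snp_primitives_retained": n_retained}


def _load_tables(config: RunConfig) -> list[am.SampleAlleleTable]:
    mapped = syn.read_mapped_regions_tsv(config.mapped_regions_tsv)
    tables = []
    for sample, vcf in sorted(config.vcf_paths.items()):
        result = vio.parse_variants(vcf)
        prims = vio.filter_sites(
            [p for r in result.records for p in vio.decompose_to_primitives(r)],
            config.thresholds)
        if sample not in mapped:
            raise DataError(f"no mapped regions for sample {sample!r}")
        tables.append(am.build_sample_table(sample, prims, mapped[sample],
                                            config.thresholds))
    return tables


def _stage_alleles(config: RunConfig, outdir: Path) -> tuple[dict[str, str], dict]:
    tables = _load_tables(config)
    call_rows, allelism_rows = [], []
    for t in tables:
        for pos in sorted(t.calls):
            for c in t.calls[pos]:
                call_rows.append((t.sample_id, c.chrom, c.pos, c.allele, c.obs,
                                  c.depth, round(c.fraction, 6),
                                  c.is_reference, c.present))
        s = am.classify_allelism(t)
        allelism_rows.append((t.sample_id, s.n_variant_positions, s.n_mono,
                              s.n_bi, s.n_multi,
                              round(s.prop_mono, 6) if s.n_variant_positions else ""))
        spec = am.fraction_spectrum(t)
        spec.to_csv(outdir / f"fraction_spectrum_{t.sample_id}.tsv", sep="\t")
    calls_path = outdir / "allele_calls.tsv"
    pd.DataFrame(call_rows, columns=["sample", "chrom", "pos", "allele", "obs",
                                     "depth", "fraction", "is_reference", "present"]
                 ).to_csv(calls_path, sep="\t", index=False)
    allelism_path = outdir / "allelism.tsv"
    pd.DataFrame(allelism_rows, columns=["sample", "n_variant_positions", "n_mono",
                                         "n_bi", "n_multi", "prop_mono"]
                 ).to_csv(allelism_path, sep="\t", index=False)
    outputs = {"allele_calls": str(calls_path), "allelism": str(allelism_path)}
    counts: dict[str, Any] = {
        "alleles_present": sum(1 for r in call_rows if r[8] and not r[7])}
    if len(tables) >= 2:
        spectrum = am.sharing_spectrum(tables)
        hist = pd.DataFrame(sorted(spectrum.histogram.items()),
                            columns=["n_samples_present", "n_alleles"])
        hist_path = outdir / "sharing_histogram.tsv"
        hist.to_csv(hist_path, sep="\t", index=False)
        mat_path = outdir / "sharing_matrix.tsv"
        spectrum.fraction_matrix.to_csv(mat_path, sep="\t")
        outputs["sharing_histogram"] = str(hist_path)
        outputs["sharing_matrix"] = str(mat_path)
        counts["sharing_total_alleles"] = spectrum.n_alleles
        counts["sharing_histogram"] = {str(k): v for k, v in spectrum.histogram.items()}
    return outputs, counts


def _stage_consensus(config: RunConfig, outdir: Path) -> tuple[dict[str, str], dict]:
    tables = _load_tables(config)
    ref = str(next(SeqIO.parse(config.reference_fasta, "fasta")).seq)
    consensi = [cs.build_consensus(t, ref, config.thresholds) for t in tables]
    fasta_path = outdir / "consensus.fasta"
    cs.write_consensus_fasta(consensi, fasta_path)
    outputs = {"consensus": str(fasta_path)}
    counts: dict[str, Any] = {
        "masked_positions": {c.sample_id: c.n_masked() for c in consensi}}
    if len(consensi) >= 2:
        dm = cs.distance_matrix(consensi)
        dist_path = outdir / "hamming_distances.tsv"
        cs.write_distance_tsv(dm, dist_path)
        newick = cs.cluster_samples(dm)
        tree_path = outdir / "dendrogram.nwk"
        Path(tree_path).write_text(newick + "\n")
        outputs["distances"] = str(dist_path)
        outputs["dendrogram"] = str(tree_path)
        counts["comparable_sites"] = int(dm.comparable_sites.iloc[0, 1])
    return outputs, counts


def _stage_genescreen(config: RunConfig, outdir: Path) -> tuple[dict[str, str], dict]:
    genes = [(r.id, str(r.seq)) for r in SeqIO.parse(config.gene_fasta, "fasta")]
    catmap = gs.read_category_map(config.category_map_tsv)
    index = gs.build_index(genes, catmap, k=config.thresholds.kmer_k)
    fmt = "fastq" if str(config.reads_fastq).endswith(("fastq", "fq")) else "fasta"
    assignments = [
        gs.assign_read((r.id, str(r.seq)), index, config.thresholds)
        for r in SeqIO.parse(config.reads_fastq, fmt)
    ]
    assign_path = outdir / "assignments.tsv"
    pd.DataFrame(
        [(a.read_id, a.gene_id or "", round(a.matched_fraction, 6),
          a.n_query_kmers, a.reason) for a in assignments],
        columns=["read_id", "gene_id", "matched_fraction", "n_query_kmers", "reason"],
    ).to_csv(assign_path, sep="\t", index=False)
    table = gs.bin_categories(assignments, index, sample_id="all_reads")
    cat_path = outdir / "category_counts.tsv"
    pd.DataFrame(sorted(table.counts.items()), columns=["category", "read_count"]
                 ).to_csv(cat_path, sep="\t", index=False)
    n_assigned = sum(1 for a in assignments if a.gene_id is not None)
    return ({"assignments": str(assign_path), "categories": str(cat_path)},
            {"reads": len(assignments), "assigned": n_assigned,
             "categories_detected": len(table.detected())})


def _stage_community(config: RunConfig, outdir: Path) -> tuple[dict[str, str], dict]:
    table = cm.AbundanceTable.from_tsv(config.abundance_tsv,
                                       config.sample_metadata_tsv)
    div = cm.diversity_table(table)
    div_path = outdir / "diversity.tsv"
    div.to_csv(div_path, sep="\t", index_label="sample")
    props, coverage = cm.relative_abundance(table, top_n=min(30, table.counts.shape[0]))
    cov_path = outdir / "top_coverage.tsv"
    coverage.to_frame().to_csv(cov_path, sep="\t", index_label="sample")
    bc = cm.bray_curtis(table)
    bc_path = outdir / "bray_curtis.tsv"
    bc.to_csv(bc_path, sep="\t", index_label="sample")
    ord_res = cm.pcoa(bc)
    coords_path = outdir / "pcoa_coordinates.tsv"
    ord_res.coordinates.to_csv(coords_path, sep="\t", index_label="sample")
    return ({"diversity": str(div_path), "top_coverage": str(cov_path),
             "bray_curtis": str(bc_path), "pcoa": str(coords_path)},
            {"n_samples": table.counts.shape[1], "n_taxa": table.counts.shape[0],
             "pcoa_axes": ord_res.coordinates.shape[1]})


_STAGE_FUNCS = {
    "simulate": _stage_simulate,
    "variants": _stage_variants,
    "alleles": _stage_alleles,
    "consensus": _stage_consensus,
    "genescreen": _stage_genescreen,
    "community": _stage_community,
}

# Stages whose failure poisons later stages in the same branch.
_BRANCH = {
    "variants": ("simulate",),
    "alleles": ("simulate", "variants"),
    "consensus": ("simulate", "variants", "alleles"),
    "genescreen": ("simulate",),
    "community": ("simulate",),
}


def run_pipeline(config: RunConfig) -> dict[str, Any]:
    """Run the configured stages; returns (and writes) the run manifest."""
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = _Manifest(config)
    failed: set[str] = set()
    for stage in (s for s in _STAGE_FUNCS if s in config.stages):
        upstream_failed = failed & set(_BRANCH.get(stage, ()))
        if upstream_failed:
            manifest.record(stage, "skipped", {},
                            error=f"upstream failure: {sorted(upstream_failed)}")
            failed.add(stage)
            continue
        t0 = time.monotonic()
        try:
            outputs, counts = _STAGE_FUNCS[stage](config, outdir)
            manifest.record(stage, "ok", outputs, counts,
                            elapsed=time.monotonic() - t0)
            logger.info("stage %s ok (%.2fs)", stage, time.monotonic() - t0)
        except Exception as exc:  # independent branches must keep running
            failed.add(stage)
            manifest.record(stage, "failed", {}, error=str(exc),
                            elapsed=time.monotonic() - t0)
            logger.error("stage %s failed: %s", stage, exc)
    for name in ("reference_fasta", "mapped_regions_tsv", "gene_fasta",
                 "category_map_tsv", "reads_fastq", "abundance_tsv"):
        p = getattr(config, name)
        if p and Path(p).exists():
            manifest.data["inputs"][name] = {"path": p, "sha256": _sha256(p)}
    manifest.write(outdir / "manifest.json")
    return manifest.data


def report(manifest: dict[str, Any] | str | Path) -> str:
    """Human-readable run summary; every number is recomputable from the TSVs."""
    if not isinstance(manifest, dict):
        manifest = json.loads(Path(manifest).read_text())
    lines = [f"strainsieve {manifest.get('version', '?')} run report",
             f"seed: {manifest.get('seed')}"]
    stages = manifest.get("stages", {})
    ordered = [s for s in _STAGE_FUNCS if s in stages]
    ordered += [s for s in stages if s not in ordered]
    for stage in ordered:
        entry = stages[stage]
        lines.append(f"[{stage}] {entry['status']} ({entry.get('elapsed_s', 0)}s)")
        for key in sorted(entry.get("counts", {})):
            if key == "sharing_histogram":
                continue
            lines.append(f"  {key}: {entry['counts'][key]}")
    alle = stages.get("alleles", {}).get("counts", {})
    hist = alle.get("sharing_histogram")
    if hist:
        total = sum(hist.values())
        parts = " + ".join(str(v) for _k, v in sorted(hist.items(), reverse=True))
        lines.append(f"sharing spectrum accounting: {total} non-reference alleles"
                     f" = {parts} (alleles present in"
                     f" {', '.join(k for k, _ in sorted(hist.items(), reverse=True))}"
                     " sample(s))")
    return "\n".join(lines) + "\n"
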