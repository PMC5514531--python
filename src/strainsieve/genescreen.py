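"""20-mer read-to-gene screening and functional category binning.

Each reference gene is stored as its set of constituent canonical 20-mers
(lexicographic minimum of a k-mer and its reverse complement, so read strand
is irrelevant). A query read is greedily assigned to the gene with the
highest fraction of matching 20-mers — matched distinct query k-mers over
total distinct query k-mers — requiring at least 90% to match. Detected
genes are binned into functional categories (CARD/VFDB/KO-style maps
supplied as TSV), and presence/absence of categories between two samples is
compared with a two-sided Fisher's exact test.
"""

from __future__ import annotations

import csv
from collections import defaultdict
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from scipy.stats import fisher_exact

from .config import DataError, Thresholds, logger

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def canonical_kmers(seq: str, k: int) -> frozenset[str]:
    """Distinct canonical k-mers of a sequence; k-mers containing N skipped."""
    seq = seq.upper()
    out = set()
    for i in range(len(seq) - k + 1):
        kmer = seq[i : i + k]
        if "N" in kmer:
            continue
        rc = reverse_complement(kmer)
        out.add(min(kmer, rc))
    return frozenset(out)


@dataclass
class GeneKmerIndex:
    """Gene id -> canonical k-mer set, plus category map and gene lengths."""

    k: int
    kmers: dict[str, frozenset[str]]
    categories: dict[str, tuple[str, ...]]
    lengths: dict[str, int]


def read_category_map(path: str | Path) -> dict[str, tuple[str, ...]]:
    """Read a TSV of (gene_id, category[, database]); one row per pairing."""
    cats: dict[str, list[str]] = defaultdict(list)
    with open(path, newline="") as fh:
        for row in csv.reader(fh, delimiter="\t"):
            if not row or row[0].startswith("#") or row[0] == "gene_id":
                continue
            if len(row) < 2:
                raise DataError(f"category map row needs >= 2 columns: {row!r}")
            gene, cat = row[0].strip(), row[1].strip()
            if cat not in cats[gene]:
                cats[gene].append(cat)
    return {g: tuple(c) for g, c in cats.items()}


def build_index(
    genes: Iterable[tuple[str, str]],
    categories: Mapping[str, Sequence[str]] | None = None,
    k: int = 20,
) -> GeneKmerIndex:
    """Index gene sequences as canonical k-mer sets.

    ``genes`` yields (gene_id, sequence) pairs; genes shorter than k are
    excluded with a warning, duplicate ids are an error.
    """
    kmers: dict[str, frozenset[str]] = {}
    lengths: dict[str, int] = {}
    for gene_id, seq in genes:
        if gene_id in kmers:
            raise DataError(f"duplicate gene id {gene_id!r}")
        if len(seq) < k:
            logger.warning("gene %s shorter than k=%d, excluded", gene_id, k)
            continue
        kmers[gene_id] = canonical_kmers(seq, k)
        lengths[gene_id] = len(seq)
    cats = {g: tuple(c) for g, c in (categories or {}).items()}
    return GeneKmerIndex(k=k, kmers=kmers, categories=cats, lengths=lengths)


@dataclass(frozen=True)
class ReadAssignment:
    read_id: str
    gene_id: str | None
    matched_fraction: float
    n_query_kmers: int
    reason: str = ""  # why unassigned, when gene_id is None


def _assign_kmers(
    read_id: str, query: frozenset[str], index: GeneKmerIndex, thr: Thresholds
) -> ReadAssignment:
    if not query:
        return ReadAssignment(read_id, None, 0.0, 0, reason="no usable k-mers")
    best_gene: str | None = None
    best_frac = -1.0
    for gene_id in sorted(index.kmers):  # lexicographic tie-break via stable scan
        frac = len(query & index.kmers[gene_id]) / len(query)
        if frac > best_frac:
            best_gene, best_frac = gene_id, frac
    if best_gene is not None and best_frac >= thr.min_kmer_frac - 1e-9:
        return ReadAssignment(read_id, best_gene, best_frac, len(query))
    return ReadAssignment(read_id, None, max(best_frac, 0.0), len(query),
                          reason="best match below k-mer fraction threshold")


def assign_read(
    read: tuple[str, str] | str,
    index: GeneKmerIndex,
    thresholds: Thresholds | None = None,
) -> ReadAssignment:
    """Greedily assign one read to the best-matching gene, or leave unassigned.

    ``read`` is (read_id, sequence) or a bare sequence. Reads shorter than k
    are unassigned with the reason recorded.
    """
    thr = thresholds or Thresholds()
    read_id, seq = read if isinstance(read, tuple) else ("read", read)
    if len(seq) < index.k:
        return ReadAssignment(read_id, None, 0.0, 0, reason="read shorter than k")
    return _assign_kmers(read_id, canonical_kmers(seq, index.k), index, thr)


def assign_read_pair(
    read_id: str,
    seq1: str,
    seq2: str,
    index: GeneKmerIndex,
    thresholds: Thresholds | None = None,
) -> ReadAssignment:
    """Score mates jointly: the union of both mates' canonical k-mers."""
    thr = thresholds or Thresholds()
    query = canonical_kmers(seq1, index.k) | canonical_kmers(seq2, index.k)
    return _assign_kmers(read_id, query, index, thr)


UNCATEGORIZED = "uncategorized"


@dataclass
class CategoryTable:
    """Per-sample category support: read counts and detected gene sets."""

    sample_id: str
    counts: dict[str, int] = field(default_factory=dict)
    genes: dict[str, set[str]] = field(default_factory=dict)

    def detected(self) -> set[str]:
        return {c for c, n in self.counts.items() if n > 0}


def bin_categories(
    assignments: Iterable[ReadAssignment],
    index: GeneKmerIndex,
    sample_id: str = "sample",
) -> CategoryTable:
    """Accumulate assigned read counts per functional category.

    A gene in several categories counts once per category (documented
    double-binning); genes missing from the map fall under "uncategorized";
    unassigned reads are ignored.
    """
    table = CategoryTable(sample_id=sample_id)
    for a in assignments:
        if a.gene_id is None:
            continue
        cats = index.categories.get(a.gene_id) or (UNCATEGORIZED,)
        for c in cats:
            table.counts[c] = table.counts.get(c, 0) + 1
            table.genes.setdefault(c, set()).add(a.gene_id)
    return table


def compare_category_presence(a: CategoryTable, b: CategoryTable) -> float:
    """Two-sided Fisher's exact p on category presence/absence in two samples.

    The 2x2 table counts, over the union of categories seen in either sample,
    how many are detected vs not detected in each sample.
    """
    union = sorted(a.detected() | b.detected() | set(a.counts) | set(b.counts))
    if not union:
        raise DataError("no categories to compare")
    da, db = a.detected(), b.detected()
    table = [
        [sum(c in da for c in union), sum(c not in da for c in union)],
        [sum(c in db for c in union), sum(c not in db for c in union)],
    ]
    return float(fisher_exact(table, alternative="two-sided").pvalue)
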