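"""Masked consensus sequences and Hamming-distance clustering of samples.

A per-sample consensus over the mapped reference carries the major allele at
*nearly fixed* sites (major allele >= 90% of read depth), the reference base
at mapped sites with no variant record, and a mask everywhere else: positions
below the depth threshold are masked as ``unmapped``, mapped-but-polymorphic
positions as ``polymorphic``. Pairwise Hamming distances count differing
bases over jointly unmasked positions only, and samples are clustered by
average linkage (UPGMA) on the raw mismatch counts.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import linkage
from scipy.spatial.distance import squareform
from skbio import TreeNode

from .config import DataError, Thresholds, logger
from .alleles import SampleAlleleTable

MASK = "N"
MASK_UNMAPPED = "unmapped"
MASK_POLYMORPHIC = "polymorphic"


@dataclass
class ConsensusSequence:
    """Masked consensus over the reference for one sample."""

    sample_id: str
    seq: str  # over {A,C,G,T,N}; N marks masked positions
    mask_reasons: dict[int, str] = field(default_factory=dict)  # 1-based pos -> reason

    def __len__(self) -> int:
        return len(self.seq)

    def n_masked(self) -> int:
        return len(self.mask_reasons)


@dataclass
class DistanceMatrix:
    """Symmetric pairwise distances with per-pair comparable-site counts."""

    ids: tuple[str, ...]
    distances: pd.DataFrame
    comparable_sites: pd.DataFrame

    def __post_init__(self) -> None:
        d = self.distances.to_numpy(dtype=float)
        if not np.allclose(d, d.T, equal_nan=True):
            raise DataError("distance matrix is not symmetric")
        if not np.allclose(np.nan_to_num(np.diag(d)), 0.0):
            raise DataError("distance matrix diagonal is not zero")


def nearly_fixed_sites(
    table: SampleAlleleTable, thresholds: Thresholds | None = None
) -> set[int]:
    """Variant positions whose single most-supported allele has >=90% of depth."""
    thr = thresholds or Thresholds()
    fixed: set[int] = set()
    for pos, calls in table.calls.items():
        major = max(calls, key=lambda c: (c.obs, c.is_reference, c.allele))
        if major.obs / major.depth >= thr.fixation_frac - 1e-9:
            fixed.add(pos)
    return fixed


def build_consensus(
    table: SampleAlleleTable,
    reference: str,
    thresholds: Thresholds | None = None,
) -> ConsensusSequence:
    """Build the masked consensus of one sample over the full reference.

    Mapped positions without a variant record carry the reference base
    (variant callers emit only non-reference evidence); nearly fixed variant
    positions carry the major allele; everything else is masked.
    """
    thr = thresholds or Thresholds()
    if any(p > len(reference) for p in table.calls):
        raise DataError("variant position beyond reference length")
    fixed = nearly_fixed_sites(table, thr)
    seq = list(reference.upper())
    reasons: dict[int, str] = {}
    for pos0 in range(len(seq)):
        pos = pos0 + 1
        if pos not in table.mapped_positions:
            seq[pos0] = MASK
            reasons[pos] = MASK_UNMAPPED
        elif pos in table.calls:
            if pos in fixed:
                calls = table.calls[pos]
                major = max(calls, key=lambda c: (c.obs, c.is_reference, c.allele))
                seq[pos0] = major.allele
            else:
                seq[pos0] = MASK
                reasons[pos] = MASK_POLYMORPHIC
    return ConsensusSequence(table.sample_id, "".join(seq), reasons)


def hamming(c1: ConsensusSequence, c2: ConsensusSequence) -> tuple[int, int]:
    """(mismatch count, comparable sites) over jointly unmasked positions."""
    if len(c1) != len(c2):
        raise DataError("consensus length mismatch")
    dist = comparable = 0
    for a, b in zip(c1.seq, c2.seq):
        if a == MASK or b == MASK:
            continue
        comparable += 1
        if a != b:
            dist += 1
    if comparable == 0:
        logger.warning("samples %s/%s share no unmasked positions",
                       c1.sample_id, c2.sample_id)
    return dist, comparable


def distance_matrix(consensi: Sequence[ConsensusSequence]) -> DistanceMatrix:
    """All-pairs Hamming distances restricted to globally unmasked positions.

    The clustering matrix uses the global intersection of unmasked positions
    across all samples, so every pair is compared on the same site set.
    """
    if len(consensi) < 2:
        raise DataError("need >= 2 samples for a distance matrix")
    ids = tuple(c.sample_id for c in consensi)
    if len(set(ids)) != len(ids):
        raise DataError("duplicate sample ids")
    arr = np.array([list(c.seq) for c in consensi])
    unmasked = (arr != MASK).all(axis=0)
    n_sites = int(unmasked.sum())
    if n_sites == 0:
        logger.warning("no position is unmasked in all samples")
    core = arr[:, unmasked]
    n = len(ids)
    d = np.zeros((n, n), dtype=float)
    for i in range(n):
        for j in range(i + 1, n):
            d[i, j] = d[j, i] = int((core[i] != core[j]).sum())
    comp = pd.DataFrame(np.full((n, n), n_sites, dtype=int), index=ids, columns=ids)
    np.fill_diagonal(comp.values, n_sites)
    return DistanceMatrix(
        ids=ids,
        distances=pd.DataFrame(d, index=ids, columns=ids),
        comparable_sites=comp,
    )


def cluster_samples(dm: DistanceMatrix, method: str = "average") -> str:
    """Agglomerative clustering of samples; returns a Newick string.

    Samples are ordered lexicographically before linkage so ties break
    deterministically regardless of input order.
    """
    if len(dm.ids) < 2:
        raise DataError("need >= 2 samples to cluster")
    d = dm.distances.to_numpy(dtype=float)
    if np.isnan(d).any():
        raise DataError("NaN distances (no comparable sites for some pair)")
    order = sorted(range(len(dm.ids)), key=lambda i: dm.ids[i])
    ids = [dm.ids[i] for i in order]
    d = d[np.ix_(order, order)]
    z = linkage(squareform(d, checks=False), method=method)
    tree = TreeNode.from_linkage_matrix(z, ids)
    buf = io.StringIO()
    tree.write(buf, format="newick")
    return buf.getvalue().strip()


def write_consensus_fasta(consensi: Sequence[ConsensusSequence], path: str | Path) -> None:
    with open(path, "w") as fh:
        for c in consensi:
            fh.write(f">{c.sample_id}\n")
            for i in range(0, len(c.seq), 80):
                fh.write(c.seq[i : i + 80] + "\n")


def write_distance_tsv(dm: DistanceMatrix, path: str | Path) -> None:
    dm.distances.to_csv(path, sep="\t", index_label="sample")
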