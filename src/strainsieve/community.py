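"""Community composition, alpha diversity, Bray-Curtis distance and PCoA.

Diversity is computed on absolute read counts, without rarefying: Chao1
richness (bias-corrected form), Shannon entropy (natural log) and the
Gini-Simpson index. Sample ordination uses the Bray-Curtis distance on raw
counts followed by classical principal-coordinate analysis (double-centering
and eigendecomposition); axes with negative eigenvalues are reported but
dropped from the coordinates.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import NamedTuple

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from skbio.diversity.alpha import chao1 as _chao1, shannon as _shannon, simpson as _simpson

from .config import DataError, logger


@dataclass
class AbundanceTable:
    """Taxon x sample absolute read counts plus sample metadata.

    ``counts`` has taxa as rows and samples as columns; ``metadata`` is
    indexed by sample id with columns location, material and pma_treated.
    """

    counts: pd.DataFrame
    metadata: pd.DataFrame = field(default_factory=pd.DataFrame)

    def __post_init__(self) -> None:
        c = self.counts.to_numpy()
        if (c < 0).any():
            raise DataError("abundance counts must be nonnegative")

    @classmethod
    def from_tsv(cls, counts_path: str | Path, metadata_path: str | Path | None = None):
        counts = pd.read_csv(counts_path, sep="\t", index_col=0, comment="#")
        meta = pd.DataFrame()
        if metadata_path is not None:
            meta = pd.read_csv(metadata_path, sep="\t", index_col=0, comment="#")
        return cls(counts=counts, metadata=meta)

    def to_tsv(self, counts_path: str | Path, metadata_path: str | Path | None = None) -> None:
        self.counts.to_csv(counts_path, sep="\t", index_label="taxon")
        if metadata_path is not None and not self.metadata.empty:
            self.metadata.to_csv(metadata_path, sep="\t", index_label="sample")


def relative_abundance(
    table: AbundanceTable, top_n: int = 30
) -> tuple[pd.DataFrame, pd.Series]:
    """Per-sample proportions and top-N coverage.

    The top-N taxon set is global — selected by summed relative abundance
    across samples so all samples share one species axis; coverage is each
    sample's share of reads falling in that set. All-zero samples are
    excluded with a warning.
    """
    if top_n < 1:
        raise DataError("top_n must be >= 1")
    counts = table.counts
    totals = counts.sum(axis=0)
    zero = totals[totals == 0].index
    if len(zero):
        logger.warning("excluding all-zero samples: %s", list(zero))
        counts = counts.drop(columns=zero)
        totals = totals.drop(zero)
    if counts.shape[1] == 0:
        raise DataError("no samples with positive counts")
    props = counts / totals
    top = props.sum(axis=1).sort_values(ascending=False).index[:top_n]
    coverage = props.loc[top].sum(axis=0)
    coverage.name = f"top{top_n}_coverage"
    return props, coverage


class AlphaDiversity(NamedTuple):
    chao1: float
    shannon: float
    gini_simpson: float


def alpha_diversity(counts) -> AlphaDiversity:
    """Chao1 (bias-corrected), Shannon entropy (nats), Gini-Simpson index."""
    c = np.asarray(counts)
    if c.size == 0 or (c < 0).any() or not (c > 0).any():
        raise DataError("counts must be nonnegative with >= 1 positive entry")
    c = c[c > 0].astype(int)
    return AlphaDiversity(
        chao1=float(_chao1(c, bias_corrected=True)),
        shannon=float(_shannon(c)),  # skbio default base: natural log
        gini_simpson=float(_simpson(c)),
    )


def diversity_table(table: AbundanceTable) -> pd.DataFrame:
    """Per-sample alpha diversity on absolute read counts."""
    rows = {s: alpha_diversity(table.counts[s].to_numpy()) for s in table.counts.columns}
    return pd.DataFrame.from_dict(rows, orient="index",
                                  columns=["chao1", "shannon", "gini_simpson"])


def bray_curtis(table: AbundanceTable) -> pd.DataFrame:
    """Pairwise Bray-Curtis distances on raw counts (sum|x-y| / sum(x+y))."""
    counts = table.counts
    if counts.shape[1] < 2:
        raise DataError("need >= 2 samples")
    totals = counts.sum(axis=0).to_numpy()
    if (totals == 0).sum() >= 2:
        raise DataError("Bray-Curtis undefined between two all-zero samples")
    d = squareform(pdist(counts.T.to_numpy(dtype=float), metric="braycurtis"))
    return pd.DataFrame(d, index=counts.columns, columns=counts.columns)


@dataclass
class PCoAResult:
    coordinates: pd.DataFrame  # samples x retained axes (PC1, PC2, ...)
    eigenvalues: np.ndarray  # all eigenvalues, descending (negatives included)
    proportion_explained: np.ndarray  # per retained axis


def pcoa(distances: pd.DataFrame, atol: float = 1e-9) -> PCoAResult:
    """Classical scaling (principal coordinates) of a distance matrix.

    Double-centers -0.5 * D^2, eigendecomposes, and builds coordinates from
    the nonnegative-eigenvalue axes sorted by eigenvalue. Negative
    eigenvalues (non-Euclidean distances) are reported but their axes
    dropped. Percent explained is relative to the sum of positive
    eigenvalues.
    """
    d = distances.to_numpy(dtype=float)
    if d.shape[0] != d.shape[1]:
        raise DataError("distance matrix must be square")
    if np.abs(d - d.T).max() > atol:
        raise DataError("distance matrix asymmetry exceeds tolerance")
    if np.abs(np.diag(d)).max() > atol:
        raise DataError("distance matrix diagonal must be zero")
    n = d.shape[0]
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ (d ** 2) @ j
    evals, evecs = np.linalg.eigh((b + b.T) / 2)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    pos = evals > atol
    coords = evecs[:, pos] * np.sqrt(evals[pos])
    pos_sum = evals[pos].sum()
    prop = evals[pos] / pos_sum if pos_sum > 0 else np.zeros(pos.sum())
    cols = [f"PC{i + 1}" for i in range(int(pos.sum()))]
    return PCoAResult(
        coordinates=pd.DataFrame(coords, index=distances.index, columns=cols),
        eigenvalues=evals,
        proportion_explained=prop,
    )
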