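"""Within-sample allele presence, fraction spectra and cross-sample sharing.

An allele (reference or alternate) is *present* in a sample iff it is
supported by at least 3 reads and at least 10% of the site's read depth; its
within-sample fraction is supporting reads / total depth (DP), not the sum of
present-allele observations. Variant positions are classified as mono-allelic
(a single present allele which is non-reference — i.e. 100% of observed
supporting reads back a non-reference base), bi-allelic (two present alleles)
or multi-allelic. Fraction histograms use left-open/right-closed bins so that
a fully fixed allele (fraction exactly 1.0) falls in the top bin (0.9, 1.0].

The sharing spectrum counts each distinct non-reference (position, allele)
by the number of samples in which it is present, restricted to positions
mapped (depth >= 10) in every sample.
"""

from __future__ import annotations

import math
from collections import defaultdict
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .config import DataError, Thresholds, logger
from .variants import PrimitiveVariant


@dataclass(frozen=True)
class AlleleCall:
    """One evaluated allele at one position in one sample."""

    chrom: str
    pos: int
    allele: str  # single base
    obs: int
    depth: int
    is_reference: bool
    present: bool

    @property
    def fraction(self) -> float:
        return self.obs / self.depth


@dataclass
class SampleAlleleTable:
    """All allele calls of one sample over its mapped positions."""

    sample_id: str
    mapped_positions: frozenset[int]
    calls: dict[int, list[AlleleCall]] = field(default_factory=dict)
    pma_treated: bool = False

    def present_calls(self, pos: int) -> list[AlleleCall]:
        return [c for c in self.calls.get(pos, []) if c.present]

    def variant_positions(self) -> list[int]:
        """Positions with at least one present non-reference allele."""
        return sorted(
            p for p, cs in self.calls.items()
            if any(c.present and not c.is_reference for c in cs)
        )


def is_present(obs: int, depth: int, thresholds: Thresholds) -> bool:
    """The allele-presence rule: >=3 reads and >=10% of read depth.

    The fraction comparison uses a tiny epsilon so that exact boundary cases
    (e.g. 3 of 30 reads at a 10% cutoff) are judged present regardless of
    binary rounding of the threshold.
    """
    return (
        obs >= thresholds.min_allele_reads
        and obs / depth >= thresholds.min_allele_frac - 1e-9
    )


def call_alleles(
    primitives: Sequence[PrimitiveVariant], thresholds: Thresholds | None = None
) -> list[AlleleCall]:
    """Evaluate reference and alternate alleles at one position.

    ``primitives`` must all be SNPs at the same (chrom, pos) from one record,
    sharing RO and DP. Every allele is evaluated independently against both
    presence criteria; absent alleles are returned with ``present=False`` so
    downstream consumers (e.g. the major-allele rule) can see raw support.
    """
    thr = thresholds or Thresholds()
    if not primitives:
        return []
    first = primitives[0]
    if any((p.chrom, p.pos) != (first.chrom, first.pos) for p in primitives):
        raise DataError("call_alleles expects primitives at a single position")
    depth = first.depth
    if depth <= 0:
        raise DataError(f"non-positive depth at {first.chrom}:{first.pos}")
    calls = [
        AlleleCall(first.chrom, first.pos, first.ref_base, first.ref_obs, depth,
                   is_reference=True, present=is_present(first.ref_obs, depth, thr))
    ]
    seen: dict[str, int] = {}
    for p in primitives:
        if p.kind != "snp":
            raise DataError("call_alleles expects SNP primitives only")
        # Distinct alternate bases; duplicated base keeps the larger support.
        seen[p.alt_base] = max(seen.get(p.alt_base, 0), p.alt_obs)
    for base in sorted(seen):
        obs = seen[base]
        calls.append(
            AlleleCall(first.chrom, first.pos, base, obs, depth,
                       is_reference=False, present=is_present(obs, depth, thr))
        )
    return calls


def build_sample_table(
    sample_id: str,
    primitives: Iterable[PrimitiveVariant],
    mapped_positions: Iterable[int],
    thresholds: Thresholds | None = None,
    pma_treated: bool = False,
) -> SampleAlleleTable:
    """Group filtered SNP primitives by position and call alleles."""
    thr = thresholds or Thresholds()
    mapped = frozenset(mapped_positions)
    by_pos: dict[int, list[PrimitiveVariant]] = defaultdict(list)
    for p in primitives:
        by_pos[p.pos].append(p)
    table = SampleAlleleTable(sample_id=sample_id, mapped_positions=mapped,
                              pma_treated=pma_treated)
    for pos in sorted(by_pos):
        if pos not in mapped:
            logger.warning("sample %s: variant at unmapped position %d skipped",
                           sample_id, pos)
            continue
        table.calls[pos] = call_alleles(by_pos[pos], thr)
    return table


@dataclass(frozen=True)
class AllelismSummary:
    n_variant_positions: int
    n_mono: int
    n_bi: int
    n_multi: int

    @property
    def prop_mono(self) -> float:
        return self.n_mono / self.n_variant_positions if self.n_variant_positions else math.nan

    @property
    def prop_bi(self) -> float:
        return self.n_bi / self.n_variant_positions if self.n_variant_positions else math.nan


def classify_allelism(table: SampleAlleleTable) -> AllelismSummary:
    """Count mono-/bi-/multi-allelic variant positions in one sample.

    A variant position has >=1 present non-reference allele. It is
    mono-allelic iff exactly one allele is present and that allele is
    non-reference (all observed supporting reads back a non-reference call);
    bi-allelic iff exactly two alleles are present; multi-allelic otherwise.
    """
    n_mono = n_bi = n_multi = n_var = 0
    for pos in table.variant_positions():
        present = table.present_calls(pos)
        n_var += 1
        if len(present) == 1 and not present[0].is_reference:
            n_mono += 1
        elif len(present) == 2:
            n_bi += 1
        elif len(present) > 2:
            n_multi += 1
    return AllelismSummary(n_var, n_mono, n_bi, n_multi)


def _bin_index(fraction: float, bin_width: float, n_bins: int) -> int:
    # left-open right-closed (x, x+w]: fraction exactly on an edge goes left.
    idx = int(math.ceil(fraction / bin_width - 1e-9)) - 1
    return min(max(idx, 0), n_bins - 1)


def fraction_spectrum(
    table: SampleAlleleTable, bin_width: float = 0.1
) -> pd.DataFrame:
    """Histogram of present non-reference allele fractions, stratified.

    Rows are (x, x+bin_width] bins over (0, 1]; columns are the number of
    present alleles (reference included) at the contributing position. Each
    present non-reference allele contributes exactly once.
    """
    n_bins = round(1.0 / bin_width)
    if abs(n_bins * bin_width - 1.0) > 1e-9:
        raise DataError(f"bin_width {bin_width} does not divide 1.0")
    strata: dict[int, np.ndarray] = {}
    for pos, calls in table.calls.items():
        present = [c for c in calls if c.present]
        n_present = len(present)
        for c in present:
            if c.is_reference:
                continue
            strata.setdefault(n_present, np.zeros(n_bins, dtype=int))
            strata[n_present][_bin_index(c.fraction, bin_width, n_bins)] += 1
    edges = [round((i + 1) * bin_width, 10) for i in range(n_bins)]
    index = pd.Index(edges, name="bin_upper")
    df = pd.DataFrame(
        {k: strata[k] for k in sorted(strata)}, index=index, dtype=int
    )
    df.columns.name = "n_present_alleles"
    return df


@dataclass
class SharingSpectrum:
    """Cross-sample sharing of non-reference alleles on jointly mapped sites."""

    restricted_positions: frozenset[int]
    entries: dict[tuple[int, str], int]  # (pos, allele) -> n samples present
    histogram: dict[int, int]  # s -> count of alleles present in s samples
    fraction_matrix: pd.DataFrame  # rows (pos, allele), columns samples

    @property
    def n_alleles(self) -> int:
        return len(self.entries)


def sharing_spectrum(tables: Sequence[SampleAlleleTable]) -> SharingSpectrum:
    """Build the allele-sharing spectrum across samples.

    Restricted to positions mapped in every sample; each distinct present
    non-reference (position, allele) is counted by the number of samples in
    which it is present. The fraction matrix gives within-sample fractions
    (zero where absent), rows sorted by samples-present descending, then by
    mean within-sample fraction descending.
    """
    if len(tables) < 2:
        raise DataError("sharing spectrum needs >= 2 samples")
    restricted = frozenset.intersection(*(t.mapped_positions for t in tables))
    if not restricted:
        logger.warning("no positions mapped in all samples; empty sharing spectrum")
    counts: dict[tuple[int, str], int] = defaultdict(int)
    fracs: dict[tuple[int, str], dict[str, float]] = defaultdict(dict)
    for t in tables:
        for pos in t.variant_positions():
            if pos not in restricted:
                continue
            for c in t.present_calls(pos):
                if c.is_reference:
                    continue
                key = (pos, c.allele)
                counts[key] += 1
                fracs[key][t.sample_id] = c.fraction
    histogram: dict[int, int] = defaultdict(int)
    for s in counts.values():
        histogram[s] += 1
    sample_ids = [t.sample_id for t in tables]
    rows = sorted(
        counts,
        key=lambda k: (-counts[k], -float(np.mean(list(fracs[k].values()))), k),
    )
    mat = pd.DataFrame(
        [[fracs[k].get(s, 0.0) for s in sample_ids] for k in rows],
        index=pd.MultiIndex.from_tuples(rows, names=["pos", "allele"]) if rows
        else pd.MultiIndex.from_arrays([[], []], names=["pos", "allele"]),
        columns=sample_ids,
        dtype=float,
    )
    return SharingSpectrum(
        restricted_positions=restricted,
        entries=dict(counts),
        histogram=dict(sorted(histogram.items())),
        fraction_matrix=mat,
    )


# -- printed-accounting helpers ---------------------------------------------

def allele_accounting(multiplicity: Mapping[int, int]) -> tuple[int, int]:
    """Total (variant positions, non-reference alleles) from multiplicities.

    ``multiplicity`` maps "number of non-reference alleles at a position" to
    "number of such positions"; e.g. {1: 207, 2: 3} -> (210, 213).
    """
    if any(k < 1 or v < 0 for k, v in multiplicity.items()):
        raise DataError("invalid multiplicity map")
    n_positions = sum(multiplicity.values())
    n_alleles = sum(k * v for k, v in multiplicity.items())
    return n_positions, n_alleles


def sharing_accounting(total_alleles: int, shared: Mapping[int, int]) -> int:
    """Alleles unique to one sample, given totals for the shared classes.

    ``shared`` maps s (>1) to the number of alleles present in exactly s
    samples; the remainder of ``total_alleles`` is the s=1 class.
    """
    if any(s < 2 for s in shared):
        raise DataError("shared classes must have s >= 2")
    n_shared = sum(shared.values())
    if n_shared > total_alleles:
        raise DataError("shared classes exceed the total allele count")
    return total_alleles - n_shared
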