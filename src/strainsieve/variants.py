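"""Variant record parsing, decomposition to allelic primitives, site filters.

Consumes freebayes-style VCF in which per-allele supporting read counts travel
in the RO (reference observations) and AO (alternate observations) fields and
total depth in DP. Complex variants are decomposed to allelic primitives —
single-base mismatches (SNPs) and 1-bp gaps — after which only substitutions
at sites of depth >= 10 are analysed; indels and complex variants are ignored
downstream, so the decomposition only needs SNP-exact behaviour.

Coordinates are 1-based inclusive throughout, matching VCF.
"""

from __future__ import annotations

import contextlib
import os
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import pysam

from .config import DataError, Thresholds, logger

GAP = "-"
_DNA = frozenset("ACGT")


@dataclass(frozen=True)
class VariantRecord:
    """One variant locus in one sample, with per-allele read support."""

    chrom: str
    pos: int  # 1-based
    ref_allele: str
    alt_alleles: tuple[str, ...]
    ref_obs: int  # RO
    alt_obs: tuple[int, ...]  # AO, one per alternate
    depth: int  # DP

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise DataError(f"position must be >= 1, got {self.pos}")
        if not self.ref_allele or any(not a for a in self.alt_alleles):
            raise DataError("alleles must be non-empty")
        if len(self.alt_obs) != len(self.alt_alleles):
            raise DataError("AO count does not match number of alternate alleles")
        if self.ref_obs + sum(self.alt_obs) > self.depth:
            raise DataError("allele observations exceed total depth")


@dataclass(frozen=True)
class PrimitiveVariant:
    """A 1-bp unit of a variant: a SNP or a gap, with inherited counts."""

    chrom: str
    pos: int  # 1-based
    ref_base: str
    alt_base: str  # single base for SNPs; inserted base or '-' for gaps
    kind: str  # 'snp' | 'gap'
    ref_obs: int
    alt_obs: int
    depth: int

    def __post_init__(self) -> None:
        if len(self.ref_base) != 1:
            raise DataError("primitive ref_base must be a single base")
        if self.kind == "snp":
            if self.alt_base not in _DNA or self.alt_base == self.ref_base:
                raise DataError(f"invalid SNP {self.ref_base}->{self.alt_base}")
        elif self.kind != "gap":
            raise DataError(f"unknown primitive kind {self.kind!r}")


@dataclass
class ParseResult:
    """Parsed records plus rejection accounting."""

    records: list[VariantRecord] = field(default_factory=list)
    n_rejected: int = 0

    def __iter__(self):
        return iter(self.records)

    def __len__(self) -> int:
        return len(self.records)


def _record_from_pysam(rec: "pysam.VariantRecord") -> VariantRecord:
    info = rec.info
    if "DP" not in info or "RO" not in info or "AO" not in info:
        raise KeyError("missing DP/RO/AO")
    ao = info["AO"]
    if not isinstance(ao, tuple):
        ao = (ao,)
    ro = info["RO"]
    if isinstance(ro, tuple):
        ro = ro[0]
    dp = info["DP"]
    if isinstance(dp, tuple):
        dp = dp[0]
    return VariantRecord(
        chrom=rec.chrom,
        pos=rec.pos,  # pysam exposes 1-based .pos for VCF records
        ref_allele=rec.ref,
        alt_alleles=tuple(rec.alts or ()),
        ref_obs=int(ro),
        alt_obs=tuple(int(a) for a in ao),
        depth=int(dp),
    )


def parse_variants(path: str | Path) -> ParseResult:
    """Parse a VCF file into :class:`VariantRecord` objects.

    Records missing any of DP/RO/AO are rejected with a logged warning and
    counted in ``n_rejected``; a structurally malformed file raises
    :class:`DataError`. Output is sorted by (chrom, pos).
    """
    result = ParseResult()
    try:
        with contextlib.redirect_stderr(open(os.devnull, "w")):
            vf = pysam.VariantFile(str(path))
    except (OSError, ValueError) as exc:
        raise DataError(f"cannot parse VCF {path}: {exc}") from exc
    with vf:
        for i, rec in enumerate(vf.fetch() if vf.index else vf):
            try:
                result.records.append(_record_from_pysam(rec))
            except (KeyError, DataError) as exc:
                result.n_rejected += 1
                logger.warning("rejected VCF record %s:%s (#%d): %s", rec.chrom, rec.pos, i + 1, exc)
    result.records.sort(key=lambda r: (r.chrom, r.pos))
    return result


def _common_prefix_len(a: str, b: str) -> int:
    n = 0
    for x, y in zip(a, b):
        if x != y:
            break
        n += 1
    return n


def _decompose_pair(
    chrom: str, pos: int, ref: str, alt: str, ref_obs: int, alt_obs: int, depth: int
) -> list[PrimitiveVariant]:
    # Prefix/suffix trimming then positionwise comparison. Gap primitives are
    # anchored but never analysed downstream (substitutions only).
    p = _common_prefix_len(ref, alt)
    max_s = min(len(ref), len(alt)) - p
    s = 0
    while s < max_s and ref[len(ref) - 1 - s] == alt[len(alt) - 1 - s]:
        s += 1
    rcore = ref[p : len(ref) - s]
    acore = alt[p : len(alt) - s]
    prims: list[PrimitiveVariant] = []
    m = min(len(rcore), len(acore))
    for i in range(m):
        if rcore[i] != acore[i]:
            prims.append(
                PrimitiveVariant(chrom, pos + p + i, rcore[i], acore[i], "snp",
                                 ref_obs, alt_obs, depth)
            )
    for i in range(m, len(rcore)):  # deletion: each deleted ref base is a gap
        prims.append(
            PrimitiveVariant(chrom, pos + p + i, rcore[i], GAP, "gap",
                             ref_obs, alt_obs, depth)
        )
    if len(acore) > m:  # insertion: anchored at the base before the insertion
        anchor = pos + p - 1 if p > 0 else pos
        anchor_base = ref[p - 1] if p > 0 else ref[0]
        for i in range(m, len(acore)):
            prims.append(
                PrimitiveVariant(chrom, anchor, anchor_base, acore[i], "gap",
                                 ref_obs, alt_obs, depth)
            )
    return prims


def decompose_to_primitives(rec: VariantRecord) -> list[PrimitiveVariant]:
    """Decompose a (possibly multi-allelic, complex) record into 1-bp primitives.

    For equal-length REF/ALT pairs this emits one SNP per mismatching offset;
    for unequal lengths the common prefix/suffix is trimmed, mismatches over
    the aligned overlap become SNPs and each unaligned base a gap primitive.
    Every primitive inherits its source allele's RO/AO/DP unchanged.
    """
    prims: list[PrimitiveVariant] = []
    for alt, ao in zip(rec.alt_alleles, rec.alt_obs):
        prims.extend(
            _decompose_pair(rec.chrom, rec.pos, rec.ref_allele, alt,
                            rec.ref_obs, ao, rec.depth)
        )
    return prims


def filter_sites(
    primitives: Iterable[PrimitiveVariant], thresholds: Thresholds | None = None
) -> list[PrimitiveVariant]:
    """Retain SNP primitives at sites with depth >= ``min_depth``; order kept."""
    thr = thresholds or Thresholds()
    return [p for p in primitives if p.kind == "snp" and p.depth >= thr.min_depth]


# -- minimal VCF dialect writer (round-trips through parse_variants) --------

_VCF_HEADER = """\
##fileformat=VCFv4.2
##INFO=<ID=DP,Number=1,Type=Integer,Description="Total read depth">
##INFO=<ID=RO,Number=1,Type=Integer,Description="Reference allele observation count">
##INFO=<ID=AO,Number=A,Type=Integer,Description="Alternate allele observation count">
"""


def write_vcf(
    records: Sequence[VariantRecord],
    path: str | Path,
    contigs: dict[str, int] | None = None,
) -> None:
    """Write records in the minimal freebayes-like dialect (DP/RO/AO in INFO)."""
    if contigs is None:
        contigs = {}
        for r in records:
            contigs[r.chrom] = max(contigs.get(r.chrom, 0), r.pos + len(r.ref_allele))
    lines = [_VCF_HEADER]
    for chrom, length in contigs.items():
        lines.append(f"##contig=<ID={chrom},length={length}>\n")
    lines.append("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
    for r in sorted(records, key=lambda r: (r.chrom, r.pos)):
        ao = ",".join(str(a) for a in r.alt_obs)
        alt = ",".join(r.alt_alleles)
        lines.append(
            f"{r.chrom}\t{r.pos}\t.\t{r.ref_allele}\t{alt}\t.\t.\t"
            f"DP={r.depth};RO={r.ref_obs};AO={ao}\n"
        )
    Path(path).write_text("".join(lines))


def effective_depth(rec: VariantRecord) -> int:
    """DP when present and positive, else the allele-count sum."""
    return rec.depth if rec.depth > 0 else rec.ref_obs + sum(rec.alt_obs)
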