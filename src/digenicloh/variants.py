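"""Somatic variant I/O and consensus filtering.

Tumor variant calls from two independent somatic callers are reconciled
into a single high-confidence set: a variant is retained only if both
callers report it (matched on normalized chrom/pos/ref/alt), both mark it
PASS, and the tumor sample shows a variant allele fraction (VAF) and read
depth above configurable minima.  Thresholds are inclusive ("minimum of
0.1" means vaf >= 0.1).

Coordinates: :class:`VariantSite.pos` is the 1-based VCF position;
capture regions use 0-based half-open (BED) intervals internally, and VCF
positions are converted on comparison.
"""

from __future__ import annotations

import bisect
import enum
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
from cyvcf2 import VCF


class VcfParseError(ValueError):
    """A VCF record could not be interpreted (missing sample/fields)."""


class ChromosomeDialectError(ValueError):
    """Chromosome naming styles of two inputs do not match."""


class VariantClass(str, enum.Enum):
    SNV = "SNV"
    INSERTION = "insertion"
    DELETION = "deletion"
    OTHER = "other"


def _variant_class(ref: str, alt: str) -> VariantClass:
    if len(ref) == 1 and len(alt) == 1:
        return VariantClass.SNV
    if len(alt) > len(ref):
        return VariantClass.INSERTION
    if len(alt) < len(ref):
        return VariantClass.DELETION
    return VariantClass.OTHER


@dataclass
class VariantSite:
    """One called variant (one ALT allele) with per-sample read support."""

    chrom: str
    pos: int  # 1-based
    ref: str
    alt: str
    filter: str = "PASS"
    depth: int = 0
    alt_depth: int = 0

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"pos must be >= 1, got {self.pos}")
        if not (0 <= self.alt_depth <= self.depth):
            raise ValueError(
                f"{self.chrom}:{self.pos}: require 0 <= alt_depth <= depth, "
                f"got alt_depth={self.alt_depth}, depth={self.depth}"
            )

    @property
    def vaf(self) -> float:
        """Variant allele fraction computed from allele depths."""
        return self.alt_depth / self.depth if self.depth > 0 else 0.0

    @property
    def variant_class(self) -> VariantClass:
        return _variant_class(self.ref, self.alt)

    @property
    def key(self) -> tuple[str, int, str, str]:
        return (self.chrom, self.pos, self.ref, self.alt)


@dataclass
class FilterConfig:
    """Consensus somatic filter thresholds (inclusive minima)."""

    min_vaf: float = 0.1
    min_depth: int = 50
    require_pass: bool = True
    require_both_callers: bool = True

    def __post_init__(self) -> None:
        if not 0.0 <= self.min_vaf <= 1.0:
            raise ValueError(f"min_vaf must be in [0,1], got {self.min_vaf}")
        if self.min_depth < 0:
            raise ValueError(f"min_depth must be >= 0, got {self.min_depth}")


@dataclass
class CaptureRegionSet:
    """Genomic intervals, 0-based half-open, as in BED."""

    intervals: list[tuple[str, int, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        for chrom, start, end in self.intervals:
            if not start < end:
                raise ValueError(f"empty interval {chrom}:{start}-{end}")
        self.intervals = sorted(self.intervals)
        # per chrom: sorted starts + running max of ends, for O(log n) lookup
        self._by_chrom: dict[str, tuple[list[int], list[int]]] = {}
        for chrom, start, end in self.intervals:
            starts, maxends = self._by_chrom.setdefault(chrom, ([], []))
            starts.append(start)
            maxends.append(max(end, maxends[-1]) if maxends else end)

    @classmethod
    def from_bed(cls, path: str | Path) -> "CaptureRegionSet":
        df = pd.read_csv(
            path, sep="\t", comment="#", header=None, usecols=[0, 1, 2],
            names=["chrom", "start", "end"], dtype={"chrom": str},
        )
        return cls([tuple(r) for r in df.itertuples(index=False)])

    @property
    def chroms(self) -> set[str]:
        return set(self._by_chrom)

    def contains(self, chrom: str, pos: int) -> bool:
        """Membership of a 1-based position (end coordinate exclusive)."""
        if chrom not in self._by_chrom:
            return False
        starts, maxends = self._by_chrom[chrom]
        p0 = pos - 1
        i = bisect.bisect_right(starts, p0) - 1
        return i >= 0 and maxends[i] > p0


def read_vcf(path: str | Path, sample: str | None = None) -> list[VariantSite]:
    """Read per-sample variant calls, decomposing multi-allelic records.

    One :class:`VariantSite` is produced per ALT allele; depth is the sum of
    the sample's allele depths (AD) and VAF follows from them.
    """
    vcf = VCF(str(path))
    samples = list(vcf.samples)
    if not samples:
        raise VcfParseError(f"{path}: VCF has no sample columns")
    if sample is None:
        if len(samples) > 1:
            raise VcfParseError(
                f"{path}: multiple samples {samples}; specify one"
            )
        sample = samples[0]
    if sample not in samples:
        raise VcfParseError(f"{path}: sample {sample!r} not in {samples}")
    si = samples.index(sample)

    out: list[VariantSite] = []
    for rec in vcf:
        ad = rec.format("AD")
        if ad is None:
            raise VcfParseError(
                f"{rec.CHROM}:{rec.POS}: record lacks FORMAT/AD allele depths"
            )
        row = [int(x) for x in ad[si]]
        if any(x < 0 for x in row):  # cyvcf2 encodes missing AD as negative
            raise VcfParseError(
                f"{rec.CHROM}:{rec.POS}: missing AD values for sample {sample}"
            )
        depth = sum(row)
        filt = rec.FILTER or "PASS"
        for j, alt in enumerate(rec.ALT):
            out.append(
                VariantSite(
                    chrom=rec.CHROM,
                    pos=rec.POS,
                    ref=rec.REF,
                    alt=alt,
                    filter=filt,
                    depth=depth,
                    alt_depth=row[j + 1],
                )
            )
    return out


def write_vcf(
    calls: Iterable[VariantSite],
    path: str | Path,
    sample: str = "SAMPLE",
) -> None:
    """Write calls as a minimal single-sample VCF 4.2 with GT/AD/DP.

    Decomposed multi-allelic sites are written as separate biallelic
    records, which round-trips the per-allele fields this package uses.
    """
    calls = list(calls)
    chroms = list(dict.fromkeys(s.chrom for s in calls))
    lines = [
        "##fileformat=VCFv4.2",
        '##FILTER=<ID=PASS,Description="All filters passed">',
        *[f"##contig=<ID={c}>" for c in chroms],
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
        '##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allele depths">',
        '##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">',
        f"#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t{sample}",
    ]
    for s in calls:
        ref_depth = s.depth - s.alt_depth
        lines.append(
            f"{s.chrom}\t{s.pos}\t.\t{s.ref}\t{s.alt}\t.\t{s.filter}\t.\t"
            f"GT:AD:DP\t0/1:{ref_depth},{s.alt_depth}:{s.depth}"
        )
    Path(path).write_text("\n".join(lines) + "\n")


def consensus_filter(
    calls_a: Sequence[VariantSite],
    calls_b: Sequence[VariantSite],
    cfg: FilterConfig | None = None,
) -> list[VariantSite]:
    """Variants reported by both callers, PASS in both, above VAF/depth minima.

    Read support (depth, VAF) of the retained variant is taken from
    ``calls_a``, the primary caller; matching is on (chrom, pos, ref, alt).
    """
    cfg = cfg or FilterConfig()
    b_index = {s.key: s for s in calls_b}
    out: list[VariantSite] = []
    for s in calls_a:
        other = b_index.get(s.key)
        if cfg.require_both_callers and other is None:
            continue
        if cfg.require_pass:
            if s.filter != "PASS":
                continue
            if other is not None and other.filter != "PASS":
                continue
        if s.vaf < cfg.min_vaf or s.depth < cfg.min_depth:
            continue
        out.append(s)
    return out


def _dialect(chroms: Iterable[str]) -> str | None:
    cs = set(chroms)
    if not cs:
        return None
    if all(c.startswith("chr") for c in cs):
        return "chr"
    if not any(c.startswith("chr") for c in cs):
        return "plain"
    return "mixed"


def restrict_to_capture(
    calls: Sequence[VariantSite], regions: CaptureRegionSet
) -> list[VariantSite]:
    """Retain variants whose position falls inside a capture interval."""
    if not regions.intervals:
        raise ValueError("capture region set is empty")
    call_chroms = {s.chrom for s in calls}
    if call_chroms and not (call_chroms & regions.chroms):
        d_calls, d_reg = _dialect(call_chroms), _dialect(regions.chroms)
        if d_calls != d_reg and "mixed" not in (d_calls, d_reg):
            raise ChromosomeDialectError(
                f"variant chromosomes use the {d_calls!r} naming style but "
                f"capture regions use {d_reg!r} (e.g. 'chr1' vs '1'); rename "
                "one input so the styles match"
            )
    return [s for s in calls if regions.contains(s.chrom, s.pos)]


def write_variants_tsv(calls: Sequence[VariantSite], path: str | Path) -> None:
    df = pd.DataFrame(
        [
            {
                "chrom": s.chrom, "pos": s.pos, "ref": s.ref, "alt": s.alt,
                "filter": s.filter, "depth": s.depth,
                "alt_depth": s.alt_depth, "vaf": round(s.vaf, 6),
                "variant_class": s.variant_class.value,
            }
            for s in calls
        ],
        columns=[
            "chrom", "pos", "ref", "alt", "filter", "depth", "alt_depth",
            "vaf", "variant_class",
        ],
    )
    df.to_csv(path, sep="\t", index=False)
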