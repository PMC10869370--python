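"""Loss-of-heterozygosity (LOH) detection from paired germline/tumor calls.

A locus heterozygous in the germline (allele fraction near 0.5) whose tumor
allele fraction shifts toward 0 or 1 is evidence that one parental allele
was lost somatically.  The detector works site by site:

* a germline site is *informative* when its allele fraction lies inside the
  heterozygosity window (default [0.4, 0.6], inclusive) and both depth
  gates pass (germline depth >= 10, tumor depth >= 30 by default);
* the tumor allele fraction is corrected for tumor cellularity *p* (the
  fraction of sampled cells that are neoplastic) before thresholding:
  ``adjusted = clamp((tumor_vaf - (1 - p) * 0.5) / p, 0, 1)`` — the
  contaminating normal cells contribute allele fraction 0.5 at a
  heterozygous site, diluting the somatic shift;
* a site supports LOH when ``|adjusted - germline_vaf| >= min_shift``
  (default 0.3, inclusive), with the direction of the shift recorded.

Supporting sites are then aggregated along each chromosome into maximal
runs (tolerating a configurable number of intervening non-supporting
sites; uninformative sites are transparent) and emitted as LOH regions
when they contain enough supporting sites.  Per-gene verdicts and an
allele-fraction plot over a chromosome complete the module.

Region and gene coordinates are 0-based half-open (BED convention); site
positions are 1-based.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import matplotlib
import pandas as pd

from .variants import VariantSite

matplotlib.use("Agg")

import matplotlib.pyplot as plt  # noqa: E402


class SiteStatus(str, enum.Enum):
    SUPPORTS_LOH = "SUPPORTS_LOH"
    NO_SUPPORT = "NO_SUPPORT"
    UNINFORMATIVE = "UNINFORMATIVE"


class ShiftDirection(str, enum.Enum):
    TOWARD_REF = "TOWARD_REF"
    TOWARD_ALT = "TOWARD_ALT"
    NA = "NA"


class GeneVerdict(str, enum.Enum):
    LOH = "LOH"
    NO_LOH = "NO_LOH"
    UNINFORMATIVE = "UNINFORMATIVE"


@dataclass(frozen=True)
class PairedSite:
    """A germline-heterozygous candidate locus observed in both samples."""

    chrom: str
    pos: int
    germline_vaf: float
    germline_depth: int
    tumor_vaf: float
    tumor_depth: int

    def __post_init__(self) -> None:
        for name in ("germline_vaf", "tumor_vaf"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0,1], got {v}")
        if self.germline_depth < 0 or self.tumor_depth < 0:
            raise ValueError("depths must be >= 0")


@dataclass
class LOHConfig:
    """Thresholds of the site classifier and the region aggregator."""

    het_low: float = 0.4
    het_high: float = 0.6
    min_germline_depth: int = 10
    min_tumor_depth: int = 30
    min_shift: float = 0.3
    cellularity: float = 0.8
    region_min_sites: int = 3
    region_max_gap_sites: int = 1
    purity_correction: bool = True

    def __post_init__(self) -> None:
        if not 0.0 <= self.het_low < self.het_high <= 1.0:
            raise ValueError("require 0 <= het_low < het_high <= 1")
        if not 0.0 < self.min_shift <= 1.0:
            raise ValueError("min_shift must be in (0,1]")
        if not 0.0 < self.cellularity <= 1.0:
            raise ValueError("cellularity must be in (0,1]")
        if self.region_min_sites < 1 or self.region_max_gap_sites < 0:
            raise ValueError("invalid region aggregation parameters")


@dataclass(frozen=True)
class LOHSiteCall:
    site: PairedSite
    status: SiteStatus
    direction: ShiftDirection
    adjusted_tumor_vaf: float

    def __post_init__(self) -> None:
        has_dir = self.direction is not ShiftDirection.NA
        if has_dir != (self.status is SiteStatus.SUPPORTS_LOH):
            raise ValueError("direction set iff status is SUPPORTS_LOH")


@dataclass
class LOHRegion:
    """A genomic segment supported by a run of LOH-consistent sites."""

    chrom: str
    start: int  # 0-based, inclusive
    end: int  # exclusive
    n_support: int
    n_no_support: int = 0
    genes_overlapped: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError("require start <= end")


def adjusted_tumor_vaf(tumor_vaf: float, cellularity: float) -> float:
    """Cellularity-corrected tumor allele fraction, clamped to [0, 1].

    Inverts the mixture ``observed = p * somatic + (1 - p) * 0.5`` at a
    germline-heterozygous site, where p is the tumor cell fraction.
    """
    adj = (tumor_vaf - (1.0 - cellularity) * 0.5) / cellularity
    return min(1.0, max(0.0, adj))


def classify_site(site: PairedSite, cfg: LOHConfig | None = None) -> LOHSiteCall:
    """Per-site LOH evidence from the paired allele fractions."""
    cfg = cfg or LOHConfig()
    adj = (
        adjusted_tumor_vaf(site.tumor_vaf, cfg.cellularity)
        if cfg.purity_correction
        else site.tumor_vaf
    )
    informative = (
        cfg.het_low <= site.germline_vaf <= cfg.het_high
        and site.germline_depth >= cfg.min_germline_depth
        and site.tumor_depth >= cfg.min_tumor_depth
    )
    if not informative:
        return LOHSiteCall(site, SiteStatus.UNINFORMATIVE, ShiftDirection.NA, adj)
    shift = adj - site.germline_vaf
    if abs(shift) >= cfg.min_shift:
        direction = (
            ShiftDirection.TOWARD_ALT if shift > 0 else ShiftDirection.TOWARD_REF
        )
        return LOHSiteCall(site, SiteStatus.SUPPORTS_LOH, direction, adj)
    return LOHSiteCall(site, SiteStatus.NO_SUPPORT, ShiftDirection.NA, adj)


def pair_sites(
    germline_calls: Sequence[VariantSite],
    tumor_calls: Sequence[VariantSite],
) -> list[PairedSite]:
    """Join germline calls with the tumor's observation at the same allele.

    Candidate loci come from the germline calls only; a locus absent from
    the tumor calls gets tumor depth 0 and is later uninformative.
    """
    tumor_index = {s.key: s for s in tumor_calls}
    out = []
    for g in germline_calls:
        t = tumor_index.get(g.key)
        out.append(
            PairedSite(
                chrom=g.chrom,
                pos=g.pos,
                germline_vaf=g.vaf,
                germline_depth=g.depth,
                tumor_vaf=t.vaf if t is not None else 0.0,
                tumor_depth=t.depth if t is not None else 0,
            )
        )
    out.sort(key=lambda s: (s.chrom, s.pos))
    return out


def classify_sites(
    paired: Sequence[PairedSite], cfg: LOHConfig | None = None
) -> list[LOHSiteCall]:
    cfg = cfg or LOHConfig()
    return [classify_site(s, cfg) for s in paired]


def _check_sorted(calls: Sequence[LOHSiteCall]) -> None:
    seen: set[str] = set()
    prev_chrom: str | None = None
    prev_pos = -1
    for c in calls:
        chrom, pos = c.site.chrom, c.site.pos
        if chrom != prev_chrom:
            if chrom in seen:
                raise ValueError(
                    f"calls not grouped by chromosome ({chrom} revisited)"
                )
            seen.add(chrom)
            prev_chrom, prev_pos = chrom, pos
        elif pos < prev_pos:
            raise ValueError(
                f"calls not sorted by position at {chrom}:{pos} after {prev_pos}"
            )
        else:
            prev_pos = pos


def aggregate_regions(
    calls: Sequence[LOHSiteCall], cfg: LOHConfig | None = None
) -> list[LOHRegion]:
    """Collapse supporting sites into maximal LOH regions.

    A run grows over consecutive informative sites; up to
    ``region_max_gap_sites`` NO_SUPPORT sites may sit between two
    supporting sites, and UNINFORMATIVE sites never break or extend a run.
    A run is emitted when it holds at least ``region_min_sites`` supporting
    sites; its span is the first to last supporting site.
    """
    cfg = cfg or LOHConfig()
    _check_sorted(calls)
    regions: list[LOHRegion] = []

    def close(run: list[LOHSiteCall], internal_gaps: int) -> None:
        if len(run) >= cfg.region_min_sites:
            regions.append(
                LOHRegion(
                    chrom=run[0].site.chrom,
                    start=run[0].site.pos - 1,
                    end=run[-1].site.pos,
                    n_support=len(run),
                    n_no_support=internal_gaps,
                )
            )

    run: list[LOHSiteCall] = []
    pending_gap = 0
    internal_gaps = 0
    cur_chrom: str | None = None
    for c in calls:
        if c.site.chrom != cur_chrom:
            close(run, internal_gaps)
            run, pending_gap, internal_gaps = [], 0, 0
            cur_chrom = c.site.chrom
        if c.status is SiteStatus.UNINFORMATIVE:
            continue
        if c.status is SiteStatus.SUPPORTS_LOH:
            if run:
                internal_gaps += pending_gap
            run.append(c)
            pending_gap = 0
        else:  # NO_SUPPORT
            if run:
                pending_gap += 1
                if pending_gap > cfg.region_max_gap_sites:
                    close(run, internal_gaps)
                    run, pending_gap, internal_gaps = [], 0, 0
    close(run, internal_gaps)
    return regions


def genes_from_bed(path: str | Path) -> dict[str, tuple[str, int, int]]:
    """Gene intervals from a 4-column BED (chrom, start, end, name)."""
    df = pd.read_csv(
        path, sep="\t", comment="#", header=None, usecols=[0, 1, 2, 3],
        names=["chrom", "start", "end", "name"], dtype={"chrom": str},
    )
    return {
        r.name: (r.chrom, int(r.start), int(r.end))
        for r in df.itertuples(index=False)
    }


def gene_loh_status(
    regions: Sequence[LOHRegion],
    calls: Sequence[LOHSiteCall],
    gene_intervals: Mapping[str, tuple[str, int, int]],
    genes: Iterable[str] | None = None,
) -> dict[str, GeneVerdict]:
    """Per-gene LOH verdicts.

    LOH when the gene overlaps an emitted region or contains at least one
    supporting site; UNINFORMATIVE when it contains no informative site;
    NO_LOH otherwise.  ``genes`` restricts evaluation to named genes and
    raises on a label missing from ``gene_intervals``.
    """
    if genes is None:
        targets = list(gene_intervals)
    else:
        targets = list(genes)
        unknown = [g for g in targets if g not in gene_intervals]
        if unknown:
            raise ValueError(f"unknown gene label(s): {unknown}")

    verdicts: dict[str, GeneVerdict] = {}
    for name in targets:
        chrom, start, end = gene_intervals[name]
        in_gene = [
            c for c in calls
            if c.site.chrom == chrom and start <= c.site.pos - 1 < end
        ]
        overlaps_region = any(
            r.chrom == chrom and r.start < end and start < r.end
            for r in regions
        )
        supports = any(c.status is SiteStatus.SUPPORTS_LOH for c in in_gene)
        informative = [
            c for c in in_gene if c.status is not SiteStatus.UNINFORMATIVE
        ]
        if overlaps_region or supports:
            verdicts[name] = GeneVerdict.LOH
        elif not informative:
            verdicts[name] = GeneVerdict.UNINFORMATIVE
        else:
            verdicts[name] = GeneVerdict.NO_LOH
    return verdicts


def allele_frequency_plot(
    calls: Sequence[LOHSiteCall],
    regions: Sequence[LOHRegion] = (),
    focus_intervals: Sequence[tuple[int, int]] = (),
    chrom: str | None = None,
    path: str | Path | None = None,
) -> "plt.Figure":
    """Tumor allele fractions of germline-het sites along one chromosome.

    One whole-chromosome panel plus a zoom panel per focus interval
    (0-based half-open); emitted LOH regions are shaded.
    """
    if chrom is None:
        informative = [
            c for c in calls if c.status is not SiteStatus.UNINFORMATIVE
        ]
        if not informative:
            raise ValueError("no informative sites to plot")
        chrom = informative[0].site.chrom
    chrom_calls = [
        c for c in calls
        if c.site.chrom == chrom and c.status is not SiteStatus.UNINFORMATIVE
    ]
    n_panels = 1 + len(focus_intervals)
    fig, axes = plt.subplots(
        n_panels, 1, figsize=(9, 2.6 * n_panels), squeeze=False
    )
    axes_flat = [ax for row in axes for ax in row]
    pos = [c.site.pos for c in chrom_calls]
    vaf = [c.site.tumor_vaf for c in chrom_calls]
    colors = [
        "#c0392b" if c.status is SiteStatus.SUPPORTS_LOH else "#2c3e50"
        for c in chrom_calls
    ]
    for k, ax in enumerate(axes_flat):
        ax.scatter(pos, vaf, s=8, c=colors, linewidths=0)
        for r in regions:
            if r.chrom == chrom:
                ax.axvspan(r.start, r.end, color="#f6c5a9", alpha=0.5, zorder=0)
        ax.axhline(0.5, color="grey", lw=0.6, ls=":")
        ax.set_ylim(-0.02, 1.02)
        ax.set_ylabel("tumor allele fraction")
        if k == 0:
            ax.set_title(f"{chrom}: germline-heterozygous sites")
        else:
            start, end = focus_intervals[k - 1]
            ax.set_xlim(start, end)
            ax.set_title(f"{chrom}:{start:,}-{end:,}")
    axes_flat[-1].set_xlabel(f"position on {chrom}")
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
    return fig


def regions_to_bed(regions: Sequence[LOHRegion], path: str | Path) -> None:
    with open(path, "w") as fh:
        for r in regions:
            fh.write(
                f"{r.chrom}\t{r.start}\t{r.end}\t"
                f"support={r.n_support};no_support={r.n_no_support}\n"
            )


def site_calls_to_tsv(calls: Sequence[LOHSiteCall], path: str | Path) -> None:
    df = pd.DataFrame(
        [
            {
                "chrom": c.site.chrom, "pos": c.site.pos,
                "germline_vaf": round(c.site.germline_vaf, 6),
                "germline_depth": c.site.germline_depth,
                "tumor_vaf": round(c.site.tumor_vaf, 6),
                "tumor_depth": c.site.tumor_depth,
                "adjusted_tumor_vaf": round(c.adjusted_tumor_vaf, 6),
                "status": c.status.value, "direction": c.direction.value,
            }
            for c in calls
        ]
    )
    df.to_csv(path, sep="\t", index=False)
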