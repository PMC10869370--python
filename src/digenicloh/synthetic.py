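"""Seeded generators for every input the pipeline consumes.

The generators emulate the study's (non-deposited) inputs with known
ground truth:

* paired germline/tumor allele-fraction data with planted copy-neutral
  LOH segments at a stated tumor cellularity — germline alternate reads
  are Binomial(depth, 0.5) at heterozygous sites, and inside an LOH
  segment the expected tumor alternate fraction is
  ``p * a + (1 - p) * 0.5`` where ``p`` is the cellularity and ``a`` is 0
  or 1 depending on which allele the tumor lost;
* mutation catalogues drawn multinomially from a known mixture of
  reference signatures (real or synthetic random-simplex matrices);
* family/phenotype tables with planted genotypes for round-trip testing.

Everything is bit-reproducible given (config, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .loh import PairedSite
from .pedigree import SCHEMA_COLUMNS
from .signatures import ALPHABETS, MutationCatalogue, SignatureMatrix
from .variants import VariantSite, write_vcf


@dataclass(frozen=True)
class PlantedSegment:
    start: int  # 0-based half-open, like BED
    end: int
    mode: str = "copy_neutral_loh"  # or "none"

    def __post_init__(self) -> None:
        if self.mode not in ("copy_neutral_loh", "none"):
            raise ValueError(f"unknown segment mode {self.mode!r}")
        if not 0 <= self.start < self.end:
            raise ValueError("require 0 <= start < end")


@dataclass
class LOHSimulationConfig:
    n_sites: int = 500
    chrom: str = "17"
    chrom_length: int = 60_000_000
    planted_segments: list[PlantedSegment] = field(default_factory=list)
    cellularity: float = 0.8
    germline_depth_mean: float = 30.0
    tumor_depth_mean: float = 60.0
    seed: int = 0

    def __post_init__(self) -> None:
        self.planted_segments = [
            s if isinstance(s, PlantedSegment) else PlantedSegment(*s)
            for s in self.planted_segments
        ]
        for s in self.planted_segments:
            if s.end > self.chrom_length:
                raise ValueError(
                    f"segment {s} extends past chromosome length "
                    f"{self.chrom_length}"
                )
        if not 0.0 < self.cellularity <= 1.0:
            raise ValueError("cellularity must be in (0,1]")
        if self.germline_depth_mean <= 0 or self.tumor_depth_mean <= 0:
            raise ValueError("depth means must be > 0")


def expected_tumor_vaf(mode: str, a: int, cellularity: float) -> float:
    """Expected tumor alternate-allele fraction at a germline-het site.

    ``a`` is the alternate fraction of the pure tumor cells: 1 when the
    reference allele was lost, 0 when the alternate allele was lost.
    """
    if mode == "none":
        return 0.5
    return cellularity * float(a) + (1.0 - cellularity) * 0.5


@dataclass(frozen=True)
class SegmentTruth:
    start: int
    end: int
    a: int  # pure-tumor alternate fraction the segment drifts toward


def simulate_paired_sites(
    cfg: LOHSimulationConfig,
) -> tuple[list[PairedSite], list[SegmentTruth]]:
    """Paired allele-fraction observations with planted LOH segments."""
    rng = np.random.default_rng(cfg.seed)
    positions = np.sort(
        rng.choice(np.arange(1, cfg.chrom_length + 1), size=cfg.n_sites,
                   replace=False)
    )
    g_depth = np.maximum(1, rng.poisson(cfg.germline_depth_mean, cfg.n_sites))
    t_depth = np.maximum(1, rng.poisson(cfg.tumor_depth_mean, cfg.n_sites))
    g_alt = rng.binomial(g_depth, 0.5)

    truth: list[SegmentTruth] = []
    expectation = np.full(cfg.n_sites, 0.5)
    for seg in cfg.planted_segments:
        if seg.mode == "none":
            continue
        a = int(rng.integers(0, 2))
        inside = (positions > seg.start) & (positions <= seg.end)
        expectation[inside] = expected_tumor_vaf(
            "copy_neutral_loh", a, cfg.cellularity
        )
        truth.append(SegmentTruth(seg.start, seg.end, a))
    t_alt = rng.binomial(t_depth, expectation)

    sites = [
        PairedSite(
            chrom=cfg.chrom,
            pos=int(p),
            germline_vaf=float(ga) / float(gd),
            germline_depth=int(gd),
            tumor_vaf=float(ta) / float(td),
            tumor_depth=int(td),
        )
        for p, ga, gd, ta, td in zip(positions, g_alt, g_depth, t_alt, t_depth)
    ]
    return sites, truth


def paired_sites_to_vcfs(
    sites: Sequence[PairedSite],
    germline_path: str | Path,
    tumor_path: str | Path,
) -> None:
    """Emit a synthetic germline/tumor VCF pair (A>G at every site)."""
    germline = [
        VariantSite(
            chrom=s.chrom, pos=s.pos, ref="A", alt="G",
            depth=s.germline_depth,
            alt_depth=round(s.germline_vaf * s.germline_depth),
        )
        for s in sites
    ]
    tumor = [
        VariantSite(
            chrom=s.chrom, pos=s.pos, ref="A", alt="G",
            depth=s.tumor_depth,
            alt_depth=round(s.tumor_vaf * s.tumor_depth),
        )
        for s in sites
    ]
    write_vcf(germline, germline_path, sample="GERMLINE")
    write_vcf(tumor, tumor_path, sample="TUMOR")


def segments_to_bed(
    truth: Sequence[SegmentTruth], chrom: str, path: str | Path
) -> None:
    with open(path, "w") as fh:
        for seg in truth:
            fh.write(f"{chrom}\t{seg.start}\t{seg.end}\ta={seg.a}\n")


def _segment_recovered(regions, segment: SegmentTruth, calls) -> bool:
    """Was a planted segment recovered with edge error within the local
    spacing of informative sites?

    The best-overlapping region must exist and each recovered edge must lie
    within the gap between the two informative sites straddling the true
    edge — the finest localization the site density permits.
    """
    from bisect import bisect_left

    positions = sorted(
        c.site.pos for c in calls if c.status.value != "UNINFORMATIVE"
    )
    if not positions:
        return False
    overlapping = [
        r for r in regions
        if r.start < segment.end and segment.start < r.end
    ]
    if not overlapping:
        return False
    region = max(
        overlapping,
        key=lambda r: min(r.end, segment.end) - max(r.start, segment.start),
    )

    def local_spacing(edge0: int) -> float:
        i = bisect_left(positions, edge0 + 1)  # first pos > edge (1-based)
        left = positions[i - 1] if i > 0 else 0
        right = positions[i] if i < len(positions) else positions[-1] + (
            positions[-1] - left
        )
        return float(max(right - left, 1))

    return (
        abs(region.start - segment.start) <= local_spacing(segment.start)
        and abs(region.end - segment.end) <= local_spacing(segment.end)
    )


def loh_recovery_experiment(
    n_replicates: int = 100,
    seed: int = 0,
    n_sites: int = 500,
    chrom_length: int = 60_000_000,
    segment: tuple[int, int] = (20_000_000, 40_000_000),
    cellularity: float = 0.8,
    germline_depth: float = 30.0,
    tumor_depth: float = 60.0,
):
    """Sensitivity/specificity of the LOH detector on seeded replicates.

    Each replicate simulates one chromosome with a single planted
    copy-neutral LOH segment (sensitivity arm) and one neutral chromosome
    (specificity arm), runs the detector at matching cellularity, and
    scores recovery with boundary error bounded by the local inter-site
    spacing.  Returns a dict with ``recovery_rate`` and
    ``false_region_rate`` in [0, 1].
    """
    from . import loh as loh_mod

    rng = np.random.default_rng(seed)
    child_seeds = rng.integers(0, 2**31 - 1, size=2 * n_replicates)
    detector = loh_mod.LOHConfig(cellularity=cellularity)
    recovered = 0
    false_positive = 0
    for i in range(n_replicates):
        planted_cfg = LOHSimulationConfig(
            n_sites=n_sites, chrom_length=chrom_length,
            planted_segments=[PlantedSegment(*segment)],
            cellularity=cellularity,
            germline_depth_mean=germline_depth,
            tumor_depth_mean=tumor_depth,
            seed=int(child_seeds[i]),
        )
        sites, truth = simulate_paired_sites(planted_cfg)
        calls = loh_mod.classify_sites(sites, detector)
        regions = loh_mod.aggregate_regions(calls, detector)
        if _segment_recovered(regions, truth[0], calls):
            recovered += 1

        neutral_cfg = LOHSimulationConfig(
            n_sites=n_sites, chrom_length=chrom_length,
            planted_segments=[],
            cellularity=cellularity,
            germline_depth_mean=germline_depth,
            tumor_depth_mean=tumor_depth,
            seed=int(child_seeds[n_replicates + i]),
        )
        neutral_sites, _ = simulate_paired_sites(neutral_cfg)
        neutral_calls = loh_mod.classify_sites(neutral_sites, detector)
        if loh_mod.aggregate_regions(neutral_calls, detector):
            false_positive += 1
    return {
        "recovery_rate": recovered / n_replicates,
        "false_region_rate": false_positive / n_replicates,
    }


# ---------------------------------------------------------------------------
# catalogues


def random_signature_matrix(
    alphabet: str,
    n_signatures: int,
    seed: int,
    names: Sequence[str] | None = None,
    concentration: float = 0.5,
    max_pairwise_cosine: float = 0.7,
    max_tries: int = 1000,
) -> SignatureMatrix:
    """Random simplex columns with bounded pairwise cosine similarity.

    The similarity bound keeps synthetic refitting problems
    well-conditioned so exposure recovery is attributable to the solver,
    not to luck with the draw.
    """
    rng = np.random.default_rng(seed)
    n_ch = len(ALPHABETS[alphabet])
    cols: list[np.ndarray] = []
    tries = 0
    while len(cols) < n_signatures:
        col = rng.dirichlet(np.full(n_ch, concentration))
        ok = all(
            float(col @ c / (np.linalg.norm(col) * np.linalg.norm(c)))
            <= max_pairwise_cosine
            for c in cols
        )
        if ok:
            cols.append(col)
        tries += 1
        if tries > max_tries:
            raise RuntimeError(
                "could not draw signatures under the similarity bound; "
                "raise max_pairwise_cosine or lower n_signatures"
            )
    if names is None:
        prefix = "SBS" if alphabet == "SBS96" else "ID"
        names = tuple(f"{prefix}_syn{i + 1}" for i in range(n_signatures))
    return SignatureMatrix(alphabet, tuple(names), np.column_stack(cols))


@dataclass
class CatalogueSimulationConfig:
    signature_matrix: SignatureMatrix
    true_exposures: dict[str, float]
    n_mutations: int
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_mutations <= 0:
            raise ValueError("n_mutations must be > 0")
        unknown = set(self.true_exposures) - set(self.signature_matrix.names)
        if unknown:
            raise ValueError(
                f"exposure names not in signature matrix: {sorted(unknown)}"
            )
        total = sum(self.true_exposures.values())
        if abs(total - 1.0) > 1e-6 or any(
            v < 0 for v in self.true_exposures.values()
        ):
            raise ValueError("true_exposures must lie on the simplex")


def simulate_catalogue(cfg: CatalogueSimulationConfig) -> MutationCatalogue:
    """Multinomial draw of ``n_mutations`` from the mixture S @ e_true."""
    rng = np.random.default_rng(cfg.seed)
    sig = cfg.signature_matrix
    e = np.array([cfg.true_exposures.get(n, 0.0) for n in sig.names])
    p = sig.matrix @ e
    p = p / p.sum()  # guard against rounding drift
    counts = rng.multinomial(cfg.n_mutations, p)
    return MutationCatalogue(sig.alphabet, counts)


# ---------------------------------------------------------------------------
# families


def simulate_family(
    n_members: int,
    planted_genotypes: Sequence[tuple[str, str]] = (),
    n_crc_in_dual: int = 0,
    seed: int = 0,
) -> pd.DataFrame:
    """A family table in the pedigree CSV schema with planted genotypes.

    ``planted_genotypes`` assigns (brca1, rnf43) tokens to the first
    members; the rest are wildtype/wildtype.  ``n_crc_in_dual`` plants a
    CRC diagnosis in that many of the leading dual carriers.
    """
    if len(planted_genotypes) > n_members:
        raise ValueError("more planted genotypes than members")
    rng = np.random.default_rng(seed)
    rows: list[dict] = []
    crc_left = n_crc_in_dual
    for i in range(n_members):
        g1, g2 = (
            planted_genotypes[i] if i < len(planted_genotypes)
            else ("wildtype", "wildtype")
        )
        pid = f"{i + 1:03d}"
        base = {
            "person_id": pid,
            "sex": rng.choice(["F", "M"]),
            "genotype_brca1": g1,
            "genotype_rnf43": g2,
            "age_last_contact": int(rng.integers(30, 85)),
            "event_type": "none",
            "age": "", "tumor_type": "", "location": "", "histology": "",
            "size_min_mm": "", "size_max_mm": "", "count": "",
            "background_lesion": "",
        }
        is_dual = g1 in ("carrier", "obligate_carrier") and g2 in (
            "carrier", "obligate_carrier"
        )
        if is_dual and crc_left > 0:
            crc_left -= 1
            base.update(
                event_type="cancer", age=int(rng.integers(40, 70)),
                tumor_type="CRC", location="Colon",
                histology="Adenocarcinoma",
            )
        rows.append(base)
    return pd.DataFrame(rows, columns=SCHEMA_COLUMNS)


def write_family_csv(table: pd.DataFrame, path: str | Path) -> None:
    table.to_csv(path, index=False)
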