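"""End-to-end case analysis: filter -> capture-restrict -> catalogue ->
refit -> HRD, plus paired LOH detection with per-gene verdicts.

The configuration is a YAML file mirroring :class:`PipelineConfig`.
Inputs may enter at two levels: raw tumor VCFs from two callers plus a
reference sequence (catalogues are then built in-pipeline), or
pre-computed catalogue TSVs.  Reports are JSON with a one-row TSV
companion laid out like a per-tumor molecular summary table (LOH per
gene, top signature proportions, HRD verdict).
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import yaml

from . import loh as loh_mod
from . import signatures as sig_mod
from . import variants as var_mod

log = logging.getLogger("digenicloh")

REPORT_SCHEMA_VERSION = "1.0"


@dataclass
class PathsConfig:
    """Input/output file locations; unset inputs disable their stage."""

    tumor_vcf_a: str | None = None
    tumor_vcf_b: str | None = None
    tumor_sample: str | None = None
    germline_vcf: str | None = None
    germline_sample: str | None = None
    capture_bed: str | None = None
    genes_bed: str | None = None
    reference_fasta: str | None = None
    sbs_catalogue: str | None = None
    id_catalogue: str | None = None
    sbs_signatures: str | None = None
    id_signatures: str | None = None
    out_dir: str | None = None


@dataclass
class PipelineConfig:
    paths: PathsConfig = field(default_factory=PathsConfig)
    filter: var_mod.FilterConfig = field(default_factory=var_mod.FilterConfig)
    loh: loh_mod.LOHConfig = field(default_factory=loh_mod.LOHConfig)
    hrd: sig_mod.HRDRuleConfig = field(default_factory=sig_mod.HRDRuleConfig)
    sbs_subset: list[str] | None = None
    id_subset: list[str] | None = None
    sample_id: str = "case"
    seed: int = 0


def _build_dataclass(cls, obj: dict[str, Any], context: str):
    field_names = {f.name for f in dataclasses.fields(cls)}
    unknown = set(obj) - field_names
    if unknown:
        raise ValueError(f"unknown key(s) in {context}: {sorted(unknown)}")
    return cls(**obj)


def load_config(path: str | Path) -> PipelineConfig:
    """Parse a YAML pipeline config, rejecting unknown keys."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(raw, dict):
        raise ValueError(f"{path}: config must be a mapping")
    nested = {
        "paths": PathsConfig,
        "filter": var_mod.FilterConfig,
        "loh": loh_mod.LOHConfig,
        "hrd": sig_mod.HRDRuleConfig,
    }
    kwargs: dict[str, Any] = {}
    for key, value in raw.items():
        if key in nested:
            if not isinstance(value, dict):
                raise ValueError(f"config section {key!r} must be a mapping")
            kwargs[key] = _build_dataclass(nested[key], value, key)
        else:
            kwargs[key] = value
    return _build_dataclass(PipelineConfig, kwargs, "pipeline config")


def dump_config(cfg: PipelineConfig, path: str | Path | None = None) -> str:
    text = yaml.safe_dump(dataclasses.asdict(cfg), sort_keys=True)
    if path is not None:
        Path(path).write_text(text)
    return text


@dataclass
class CaseReport:
    data: dict[str, Any]

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps(self.data, indent=2, sort_keys=True) + "\n"
        )

    def to_tsv(self, path: str | Path) -> None:
        """One-row molecular summary, one column per headline result."""
        row: dict[str, Any] = {"sample": self.data["sample_id"]}
        for gene, verdict in sorted(
            self.data.get("gene_loh", {}).items()
        ):
            row[f"LOH_{gene}"] = verdict
        for kind in ("sbs", "id"):
            exp = self.data.get("exposures", {}).get(kind)
            if exp:
                top = sorted(
                    exp["proportions"].items(), key=lambda kv: -kv[1]
                )[:3]
                row[f"{kind}_signatures"] = "; ".join(
                    f"{n} ({100 * p:.1f}%)" for n, p in top if p >= 1e-4
                )
        if "hrd" in self.data:
            row["HRD"] = self.data["hrd"]["status"]
        header = "\t".join(row)
        values = "\t".join(str(v) for v in row.values())
        Path(path).write_text(header + "\n" + values + "\n")


def _stage(name: str):
    log.info("stage: %s", name)


def run_case_analysis(cfg: PipelineConfig) -> CaseReport:
    """Run every stage enabled by the configuration and assemble a report."""
    p = cfg.paths
    report: dict[str, Any] = {
        "schema_version": REPORT_SCHEMA_VERSION,
        "sample_id": cfg.sample_id,
        "counts": {},
    }
    out_dir = Path(p.out_dir) if p.out_dir else None
    if out_dir:
        out_dir.mkdir(parents=True, exist_ok=True)

    # --- somatic consensus filtering ------------------------------------
    retained = None
    if p.tumor_vcf_a and p.tumor_vcf_b:
        _stage("consensus filter")
        calls_a = var_mod.read_vcf(p.tumor_vcf_a, p.tumor_sample)
        calls_b = var_mod.read_vcf(p.tumor_vcf_b, p.tumor_sample)
        report["counts"]["caller_a"] = len(calls_a)
        report["counts"]["caller_b"] = len(calls_b)
        retained = var_mod.consensus_filter(calls_a, calls_b, cfg.filter)
        report["counts"]["consensus"] = len(retained)
        if p.capture_bed:
            regions = var_mod.CaptureRegionSet.from_bed(p.capture_bed)
            retained = var_mod.restrict_to_capture(retained, regions)
            report["counts"]["in_capture"] = len(retained)
        log.info("retained %d somatic variants", len(retained))
        if out_dir:
            var_mod.write_variants_tsv(retained, out_dir / "somatic_retained.tsv")

    # --- catalogues ------------------------------------------------------
    catalogues: dict[str, sig_mod.MutationCatalogue] = {}
    if retained is not None and p.reference_fasta:
        _stage("catalogue construction")
        import pyfaidx

        ref = pyfaidx.Fasta(p.reference_fasta)
        for kind, alphabet in (("sbs", "SBS96"), ("id", "ID83")):
            cat, skipped = sig_mod.build_catalogue(retained, ref, alphabet)
            catalogues[kind] = cat
            report["counts"][f"{kind}_catalogue_total"] = int(cat.total)
            report["counts"][f"{kind}_skipped"] = len(skipped)
    for kind, path in (("sbs", p.sbs_catalogue), ("id", p.id_catalogue)):
        if kind not in catalogues and path:
            alphabet = "SBS96" if kind == "sbs" else "ID83"
            catalogues[kind] = sig_mod.MutationCatalogue.from_tsv(path, alphabet)
            report["counts"][f"{kind}_catalogue_total"] = int(
                catalogues[kind].total
            )
    if out_dir:
        for kind, cat in catalogues.items():
            cat.to_tsv(out_dir / f"{kind}_catalogue.tsv")

    # --- signature refitting and HRD -------------------------------------
    exposures: dict[str, sig_mod.ExposureVector] = {}
    sig_paths = {"sbs": p.sbs_signatures, "id": p.id_signatures}
    subsets = {"sbs": cfg.sbs_subset, "id": cfg.id_subset}
    for kind, cat in catalogues.items():
        if not sig_paths[kind]:
            continue
        _stage(f"{kind} signature refit")
        matrix = sig_mod.SignatureMatrix.from_tsv(
            sig_paths[kind], cat.alphabet
        )
        exposures[kind] = sig_mod.refit_exposures(cat, matrix, subsets[kind])
    if exposures:
        report["exposures"] = {
            kind: {
                "proportions": e.as_dict(),
                "residual_norm": e.residual_norm,
            }
            for kind, e in exposures.items()
        }
    if "sbs" in exposures and "id" in exposures:
        _stage("HRD classification")
        call = sig_mod.hrd_classify(exposures["sbs"], exposures["id"], cfg.hrd)
        report["hrd"] = {
            "status": call.status,
            "reasons": call.reasons,
            "sbs3": call.sbs3,
            "id6": call.id6,
        }

    # --- LOH --------------------------------------------------------------
    if p.germline_vcf and (p.tumor_vcf_a or p.tumor_vcf_b):
        _stage("LOH detection")
        germline = var_mod.read_vcf(p.germline_vcf, p.germline_sample)
        tumor = var_mod.read_vcf(p.tumor_vcf_a or p.tumor_vcf_b, p.tumor_sample)
        paired = loh_mod.pair_sites(germline, tumor)
        calls = loh_mod.classify_sites(paired, cfg.loh)
        regions = loh_mod.aggregate_regions(calls, cfg.loh)
        report["counts"]["paired_sites"] = len(paired)
        report["counts"]["loh_supporting_sites"] = sum(
            c.status is loh_mod.SiteStatus.SUPPORTS_LOH for c in calls
        )
        report["loh_regions"] = [
            {
                "chrom": r.chrom, "start": r.start, "end": r.end,
                "n_support": r.n_support, "n_no_support": r.n_no_support,
            }
            for r in regions
        ]
        if p.genes_bed:
            genes = loh_mod.genes_from_bed(p.genes_bed)
            verdicts = loh_mod.gene_loh_status(regions, calls, genes)
            report["gene_loh"] = {
                g: v.value for g, v in sorted(verdicts.items())
            }
        if out_dir:
            loh_mod.site_calls_to_tsv(calls, out_dir / "loh_sites.tsv")
            loh_mod.regions_to_bed(regions, out_dir / "loh_regions.bed")

    case = CaseReport(report)
    if out_dir:
        case.to_json(out_dir / "report.json")
        case.to_tsv(out_dir / "report.tsv")
    return case
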