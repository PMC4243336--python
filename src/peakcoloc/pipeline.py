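"""End-to-end orchestration: sizes -> overlap -> OCV sweep -> spatial tests
-> region-gene association, emitting one machine-readable run report."""

from __future__ import annotations

import dataclasses
import json
import math
import sys
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import yaml

from . import __version__
from .domains import GeneAnnotation, WindowSpec, associate_regions, build_tss_domain
from .intervals import (
    GenomeLayout,
    IntervalSet,
    read_bed,
    read_chrom_sizes,
    size_summary,
    write_bed,
)
from .overlap import common_sections, venn_counts
from .proximity import DomainSet, ocv_domain_sweep
from .spatial import run_all_spatial_tests


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        self.stage = stage
        self.cause = cause
        super().__init__(f"stage {stage!r} failed: {cause}")


def _log(stage: str, message: str) -> None:
    print(f"[{stage}] {message}", file=sys.stderr)


def _jsonable(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return _jsonable(dataclasses.asdict(obj))
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        v = float(obj)
        return None if math.isnan(v) else v
    if isinstance(obj, float) and math.isnan(obj):
        return None
    return obj


@dataclass
class RunReport:
    inputs: dict
    size_summaries: dict
    overlap: dict
    ocv_sweep: list
    spatial_tests: list
    association: Optional[dict]
    version: str = __version__
    seed: Optional[int] = None
    timestamp: str = ""

    def to_dict(self) -> dict:
        return _jsonable(dataclasses.asdict(self))


def load_domains_config(path, genes: Optional[GeneAnnotation], layout: GenomeLayout):
    """YAML schema: {domains: [{name: str, windows: [[rel_start, rel_end], ...]}]}"""
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    domains = []
    for entry in cfg.get("domains", []):
        name = entry["name"]
        windows = tuple(tuple(int(x) for x in w) for w in entry["windows"])
        if genes is None:
            raise ValueError(f"domain {name!r} needs a gene table for TSS windows")
        domains.append((name, build_tss_domain(genes, WindowSpec(windows), layout, name)))
    return domains


def run_pipeline(
    query_bed,
    reference_bed,
    chrom_sizes,
    gene_table=None,
    domains_config=None,
    n_perm: int = 1_000,
    seed: Optional[int] = None,
    out_dir=".",
    alpha: float = 0.05,
) -> RunReport:
    """Run every stage in order and write report.json / report.txt to out_dir.

    Gene-dependent stages are skipped when no gene table is given.  Any stage
    failure raises :class:`StageError`; partial outputs are retained.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    stage = "parse"
    try:
        layout = read_chrom_sizes(chrom_sizes)
        query = read_bed(query_bed, layout)
        reference = read_bed(reference_bed, layout)
        genes = (
            GeneAnnotation.read_tss_table(gene_table, layout) if gene_table else None
        )
        _log(stage, f"{len(query)} query, {len(reference)} reference regions")
    except Exception as exc:
        raise StageError(stage, exc) from exc

    stage = "summarize"
    try:
        sizes = {
            "query": dataclasses.asdict(size_summary(query)),
            "reference": dataclasses.asdict(size_summary(reference)),
        }
        _log(stage, "size summaries computed")
    except Exception as exc:
        raise StageError(stage, exc) from exc

    stage = "overlap"
    try:
        summary = venn_counts(query, reference)
        sections = common_sections(query, reference)
        write_bed(sections, out / "sections.bed")
        _log(stage, f"{summary.n_sections} common sections")
    except Exception as exc:
        raise StageError(stage, exc) from exc

    stage = "ocv"
    try:
        domains = [("whole_genome", DomainSet.whole_genome(layout))]
        if domains_config:
            domains += load_domains_config(domains_config, genes, layout)
        sweep = ocv_domain_sweep(query, reference, domains, layout, alpha)
        _log(stage, f"{len(sweep)} domain row(s)")
    except Exception as exc:
        raise StageError(stage, exc) from exc

    stage = "spatial"
    try:
        spatial = run_all_spatial_tests(query, reference, layout, n_perm, seed)
        _log(stage, f"{len(spatial)} tests run")
    except Exception as exc:
        raise StageError(stage, exc) from exc

    stage = "annotate"
    association = None
    if genes is not None:
        try:
            assoc = associate_regions(common_sections(query, reference), genes, layout)
            association = {
                "genes_per_region": assoc.genes_per_region,
                "distance_bins": assoc.distance_bins,
                "orientation_counts": assoc.orientation_counts,
                "n_regions": assoc.n_regions,
                "n_associations": len(assoc.associations),
            }
            _log(stage, f"{len(assoc.associations)} associations")
        except Exception as exc:
            raise StageError(stage, exc) from exc
    else:
        _log(stage, "skipped (no gene table)")

    report = RunReport(
        inputs={
            "query_bed": str(query_bed),
            "reference_bed": str(reference_bed),
            "chrom_sizes": str(chrom_sizes),
            "gene_table": str(gene_table) if gene_table else None,
            "n_query": len(query),
            "n_reference": len(reference),
            "n_perm": n_perm,
        },
        size_summaries=sizes,
        overlap=dataclasses.asdict(summary),
        ocv_sweep=[dataclasses.asdict(row) for row in sweep],
        spatial_tests=[dataclasses.asdict(t) for t in spatial],
        association=association,
        seed=seed,
        timestamp=time.strftime("%Y-%m-%dT%H:%M:%S"),
    )

    stage = "report"
    try:
        machine = report.to_dict()
        with open(out / "report.json", "w") as fh:
            json.dump(machine, fh, indent=2, sort_keys=True)
            fh.write("\n")
        with open(out / "report.txt", "w") as fh:
            fh.write(render_text_report(report))
        _log(stage, f"written to {out}")
    except Exception as exc:
        raise StageError(stage, exc) from exc
    return report


def render_text_report(report: RunReport) -> str:
    lines = [f"peakcoloc run report (v{report.version}, seed={report.seed})", ""]
    ov = report.overlap
    lines.append("Overlap")
    lines.append(
        f"  {ov['n_query_overlapped']}/{ov['n_query']} query regions overlap "
        f"{ov['n_reference_overlapped']}/{ov['n_reference']} reference regions "
        f"in {ov['n_sections']} sections "
        f"(query fraction {ov['query_overlap_fraction']:.3f})"
    )
    lines.append("")
    lines.append("OCV sweep")
    for row in report.ocv_sweep:
        if not row["applicable"]:
            lines.append(f"  {row['domain_name']}: not applicable ({row['note']})")
            continue
        rev = row["ocv_reference_vs_query"]
        rev_s = f"{rev:.3f}" if rev is not None else "n/a"
        lines.append(
            f"  {row['domain_name']}: OCV {row['ocv_query_vs_reference']:.3f} "
            f"(reverse {rev_s}); overlaps {row['n_overlapping']}"
            f"/{row['n_query_in_domain']}"
        )
    lines.append("")
    lines.append("Spatial tests")
    for t in report.spatial_tests:
        if t["error"]:
            lines.append(f"  {t['test_name']}: ERROR {t['error']}")
        else:
            lines.append(
                f"  {t['test_name']}: stat={t['observed_statistic']:.6g} "
                f"p={t['p_value']:.4g} ({t['direction']})"
            )
    if report.association:
        lines.append("")
        lines.append("Region-gene association")
        lines.append(f"  genes per region: {report.association['genes_per_region']}")
    lines.append("")
    return "\n".join(lines)
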