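"""End-to-end orchestration: filter -> statistics -> smoothing -> thresholds
-> region calling -> intersection, with file outputs and a run log.

Intermediate files (association TSV, window TSV, per-method BED) are the
contract between stages, so every stage can also be re-run standalone from
the CLI. Output is a pure function of (input sites, config).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import io
from .association import (
    AssociationResult,
    attach_window_delta,
    compute_statistics,
    window_profile,
)
from .filtering import FilterConfig, FilterStats, filter_snps
from .loess import loess_fit_aicc
from .model import CandidateRegion, ConfigurationError, DataError, SnpSite, is_unknown_chrom
from .regions import ThresholdRule, call_regions, compute_threshold, intersect_regions

log = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    out_dir: str | Path = "bsamap_out"
    filter: FilterConfig = field(default_factory=FilterConfig)
    ed_mode: str = "frequency"
    window_n: int = 200
    window_step: int = 1
    span_grid: tuple[float, ...] | None = None
    delta_threshold: ThresholdRule = field(
        default_factory=lambda: ThresholdRule(mode="explicit", explicit_value=0.26)
    )
    ed5_threshold: ThresholdRule = field(
        default_factory=lambda: ThresholdRule(mode="explicit", explicit_value=0.15)
    )
    #: which smoothed delta series feeds region calling: "loess" or "window"
    delta_source: str = "loess"
    run_snp_index: bool = True
    run_ed: bool = True

    def __post_init__(self) -> None:
        if not (self.run_snp_index or self.run_ed):
            raise ConfigurationError("at least one statistic must be enabled")
        if self.delta_source not in ("loess", "window"):
            raise ConfigurationError(f"unknown delta_source {self.delta_source!r}")


@dataclass
class RunSummary:
    filter_stats: FilterStats
    thresholds: dict[str, float]
    regions: dict[str, list[CandidateRegion]]
    files: dict[str, str]

    def as_dict(self) -> dict:
        return {
            "filter_stats": self.filter_stats.as_dict(),
            "thresholds": self.thresholds,
            "regions": {
                method: [
                    {
                        "chrom": r.chrom,
                        "start_bp": r.start_bp,
                        "end_bp": r.end_bp,
                        "size_mb": r.size_mb,
                    }
                    for r in regs
                ]
                for method, regs in self.regions.items()
            },
            "files": self.files,
        }


def attach_loess(
    results: list[AssociationResult],
    source: str,
    target: str,
    span_grid: tuple[float, ...] | None = None,
) -> None:
    """Per-chromosome AICc loess of ``source``, written to ``target``.

    Missing source values are excluded from the fit and keep a missing
    fitted value; chromosomes with fewer than 10 usable points are skipped.
    """
    by_chrom: dict[str, list[AssociationResult]] = {}
    for r in results:
        by_chrom.setdefault(r.chrom, []).append(r)
    for chrom, group in by_chrom.items():
        if is_unknown_chrom(chrom):
            continue
        group.sort(key=lambda r: r.pos)
        usable = [r for r in group if getattr(r, source) is not None]
        if len(usable) < 10:
            log.warning("chrom %s: %d usable points < 10, loess skipped", chrom, len(usable))
            continue
        x = np.array([r.pos for r in usable], dtype=float)
        y = np.array([getattr(r, source) for r in usable], dtype=float)
        fit = loess_fit_aicc(x, y, span_grid=span_grid)
        for r, value in zip(usable, fit.fitted):
            setattr(r, target, float(value))


def _snp_profile(results: list[AssociationResult], stat: str) -> list[tuple[str, float, float]]:
    profile = [
        (r.chrom, float(r.pos), getattr(r, stat))
        for r in sorted(results, key=lambda r: (r.chrom, r.pos))
        if getattr(r, stat) is not None and not is_unknown_chrom(r.chrom)
    ]
    return profile


def run_pipeline(
    config: PipelineConfig,
    sites: list[SnpSite] | None = None,
    input_path: str | Path | None = None,
) -> RunSummary:
    """Execute the full association pipeline and write all artifacts."""
    if sites is None:
        if input_path is None:
            raise ConfigurationError("provide sites or input_path")
        sites = io.read_depth_table(input_path)
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    filtered, fstats = filter_snps(sites, config.filter)
    log.info("filter: %d -> %d sites", fstats.n_input, fstats.n_passed)
    if not filtered:
        raise DataError("no SNP sites survive filtering")

    filtered = sorted(filtered, key=lambda s: (s.chrom, s.pos))
    results = compute_statistics(filtered, ed_mode=config.ed_mode)

    files: dict[str, str] = {}
    thresholds: dict[str, float] = {}
    regions: dict[str, list[CandidateRegion]] = {}

    if config.run_snp_index:
        attach_window_delta(results, window_n=config.window_n, step=config.window_step)
        attach_loess(results, "delta", "loess_delta", span_grid=config.span_grid)
        if config.delta_source == "window":
            profile = window_profile(
                results, stat="delta", window_n=config.window_n, step=config.window_step
            )
        else:
            profile = _snp_profile(results, "loess_delta")
        thr = compute_threshold([p[2] for p in profile], config.delta_threshold)
        thresholds["snp_index"] = thr
        regions["snp_index"] = call_regions(profile, thr, method="snp_index")
        log.info("snp_index: threshold %.4f, %d region(s)", thr, len(regions["snp_index"]))

    if config.run_ed:
        attach_loess(results, "ed5", "loess_ed5", span_grid=config.span_grid)
        profile = _snp_profile(results, "loess_ed5")
        thr = compute_threshold([p[2] for p in profile], config.ed5_threshold)
        thresholds["euclidean"] = thr
        regions["euclidean"] = call_regions(profile, thr, method="euclidean")
        log.info("euclidean: threshold %.4f, %d region(s)", thr, len(regions["euclidean"]))

    if config.run_snp_index and config.run_ed:
        inter = intersect_regions(regions["snp_index"], regions["euclidean"])
        if not inter and (regions["snp_index"] or regions["euclidean"]):
            log.warning("methods do not overlap: empty intersection")
        regions["intersection"] = inter

    assoc_path = out_dir / "association.tsv"
    io.write_association_table(results, assoc_path)
    files["association"] = str(assoc_path)
    for method, regs in regions.items():
        bed_path = out_dir / f"regions_{method}.bed"
        io.write_regions_bed(regs, bed_path)
        files[f"regions_{method}"] = str(bed_path)

    summary = RunSummary(
        filter_stats=fstats, thresholds=thresholds, regions=regions, files=files
    )
    log_path = out_dir / "run_log.json"
    log_path.write_text(json.dumps(summary.as_dict(), indent=2) + "\n")
    files["run_log"] = str(log_path)
    return summary
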