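"""Threshold computation, candidate-region calling, and region set algebra."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .model import CandidateRegion, DataError, round_half_up


@dataclass
class ThresholdRule:
    """Either an explicit cutoff or median + k * SD of the fitted profile."""

    mode: str = "explicit"  # "explicit" | "median_plus_k_sd"
    explicit_value: float | None = None
    k_sd: float = 3.0

    def __post_init__(self) -> None:
        if self.mode not in ("explicit", "median_plus_k_sd"):
            raise ValueError(f"unknown threshold mode {self.mode!r}")
        if self.mode == "explicit" and self.explicit_value is None:
            raise ValueError("explicit mode requires explicit_value")
        if self.k_sd <= 0:
            raise ValueError("k_sd must be > 0")


def compute_threshold(fitted_values: Iterable[float], rule: ThresholdRule) -> float:
    """Genome-wide threshold from the fitted profile under ``rule``.

    SD mode uses the sample standard deviation (ddof=1) over all finite
    values; requires at least 2 of them.
    """
    if rule.mode == "explicit":
        return float(rule.explicit_value)
    values = np.asarray(
        [v for v in fitted_values if v is not None and np.isfinite(v)], dtype=float
    )
    if len(values) < 2:
        raise DataError("median_plus_k_sd threshold needs >= 2 finite values")
    return float(np.median(values) + rule.k_sd * values.std(ddof=1))


def call_regions(
    profile: Sequence[tuple[str, float, float]],
    threshold: float,
    method: str = "unknown",
) -> list[CandidateRegion]:
    """Maximal runs of consecutive profile points strictly above threshold.

    ``profile`` is a (chrom, position, fitted) series sorted by chromosome
    then position; runs never span chromosomes. Region bounds are the first
    and last profile positions of the run (no extrapolation).
    """
    regions: list[CandidateRegion] = []
    run_chrom: str | None = None
    run_start = run_end = 0.0

    def close_run() -> None:
        if run_chrom is not None:
            regions.append(
                CandidateRegion(
                    chrom=run_chrom,
                    start_bp=int(round(run_start)),
                    end_bp=int(round(run_end)),
                    method=method,
                )
            )

    for chrom, pos, fitted in profile:
        above = fitted is not None and np.isfinite(fitted) and fitted > threshold
        if above and chrom == run_chrom:
            run_end = pos
        elif above:
            close_run()
            run_chrom, run_start, run_end = chrom, pos, pos
        else:
            close_run()
            run_chrom = None
    close_run()
    return regions


def intersect_regions(
    a: Sequence[CandidateRegion],
    b: Sequence[CandidateRegion],
    method: str = "intersection",
) -> list[CandidateRegion]:
    """Pairwise same-chromosome overlaps [max(starts), min(ends)]."""
    out = []
    for ra in a:
        for rb in b:
            if ra.chrom != rb.chrom:
                continue
            start = max(ra.start_bp, rb.start_bp)
            end = min(ra.end_bp, rb.end_bp)
            if start <= end:
                out.append(
                    CandidateRegion(chrom=ra.chrom, start_bp=start, end_bp=end, method=method)
                )
    return out


def region_size_mb(region: CandidateRegion) -> float:
    """(end_bp - start_bp) / 1e6, rounded half-up to 2 decimals."""
    return region.size_mb


def region_size_mb_from_coords(start_bp: int, end_bp: int) -> float:
    from decimal import Decimal

    return round_half_up(Decimal(end_bp - start_bp) / Decimal(1_000_000), 2)
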