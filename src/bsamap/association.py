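"""Per-SNP association statistics and sliding-window smoothing.

Two statistics contrast the bulks at each SNP:

* SNP index — the fraction of a bulk's reads carrying the dominant parent's
  allele: index = M / (M + P) per bulk, with delta = index_dom - index_rec.
* Euclidean distance — root-sum-of-squares difference of the within-bulk
  base-frequency vectors, ed in [0, sqrt(2)]; ed5 = ed**5 sharpens peaks.

Undefined statistics (zero usable depth) propagate as None/NaN and are
excluded from smoothing, never imputed as zero.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np

from .model import BASES, DataError, SnpSite, is_unknown_chrom

log = logging.getLogger(__name__)

MAX_ED = math.sqrt(2.0)


@dataclass
class AssociationResult:
    chrom: str
    pos: int
    snp_index_dom: float | None = None
    snp_index_rec: float | None = None
    delta: float | None = None
    ed: float | None = None
    ed5: float | None = None
    window_delta: float | None = None
    loess_delta: float | None = None
    loess_ed5: float | None = None


def snp_index(site: SnpSite) -> tuple[float | None, float | None, float | None]:
    """(index_dom, index_rec, delta) for one site.

    M/P depths are the depths of the parent1/parent2 allele bases in each
    bulk. A bulk with M + P = 0 yields an undefined index, and delta is
    undefined if either index is.
    """
    m, p = site.parent1_allele, site.parent2_allele
    if m not in BASES or p not in BASES:
        raise DataError(
            f"site {site.chrom}:{site.pos}: parental alleles must be single "
            f"bases in {BASES}, got {m!r}/{p!r}"
        )

    def index(depths) -> float | None:
        m_depth = depths.depth_of(m)
        p_depth = depths.depth_of(p)
        if m_depth + p_depth == 0:
            return None
        return m_depth / (m_depth + p_depth)

    idx_dom = index(site.bulk_dom)
    idx_rec = index(site.bulk_rec)
    delta = None if idx_dom is None or idx_rec is None else idx_dom - idx_rec
    return idx_dom, idx_rec, delta


def euclidean_distance(
    site: SnpSite, mode: str = "frequency"
) -> tuple[float | None, float | None]:
    """(ed, ed5) for one site.

    ``mode="frequency"`` (default) compares within-bulk base frequencies,
    bounding ed by sqrt(2); ``mode="raw"`` compares raw depths (unbounded,
    provided for completeness). A bulk with zero total depth yields an
    undefined ed, never 0.
    """
    if mode not in ("frequency", "raw"):
        raise ValueError(f"unknown ed mode {mode!r}")
    if mode == "raw":
        dom = np.asarray(site.bulk_dom.as_tuple(), dtype=float)
        rec = np.asarray(site.bulk_rec.as_tuple(), dtype=float)
    else:
        dom = site.bulk_dom.frequencies()
        rec = site.bulk_rec.frequencies()
        if dom is None or rec is None:
            return None, None
    ed = float(np.sqrt(np.sum((dom - rec) ** 2)))
    return ed, ed**5


def compute_statistics(
    sites: list[SnpSite], ed_mode: str = "frequency"
) -> list[AssociationResult]:
    """Per-SNP statistics for all sites, in input order."""
    results = []
    for site in sites:
        idx_dom, idx_rec, delta = snp_index(site)
        ed, ed5 = euclidean_distance(site, mode=ed_mode)
        results.append(
            AssociationResult(
                chrom=site.chrom, pos=site.pos,
                snp_index_dom=idx_dom, snp_index_rec=idx_rec, delta=delta,
                ed=ed, ed5=ed5,
            )
        )
    return results


def sliding_window_mean(
    values: np.ndarray,
    positions: np.ndarray,
    window_n: int = 200,
    step: int = 1,
) -> tuple[np.ndarray, np.ndarray]:
    """Sliding mean over one chromosome's SNP statistics.

    Missing values (NaN) are dropped before windowing, so every window
    averages exactly ``window_n`` observed statistics. The reported
    position is the median position of the window's SNPs. A chromosome
    with fewer than ``window_n`` usable SNPs collapses to a single
    whole-chromosome window (logged).

    Returns (window positions, window means); empty arrays if no usable SNP.
    """
    if window_n < 1 or step < 1:
        raise ValueError("window_n and step must be >= 1")
    values = np.asarray(values, dtype=float)
    positions = np.asarray(positions, dtype=float)
    if values.shape != positions.shape:
        raise ValueError("values and positions must have equal length")
    keep = ~np.isnan(values)
    values, positions = values[keep], positions[keep]
    n = len(values)
    if n == 0:
        return np.array([]), np.array([])
    if n < window_n:
        log.info("only %d usable SNPs (< window_n=%d): single window", n, window_n)
        return np.array([np.median(positions)]), np.array([values.mean()])
    starts = np.arange(0, n - window_n + 1, step)
    means = np.array([values[s : s + window_n].mean() for s in starts])
    med_pos = np.array([np.median(positions[s : s + window_n]) for s in starts])
    return med_pos, means


def window_profile(
    results: list[AssociationResult],
    stat: str = "delta",
    window_n: int = 200,
    step: int = 1,
) -> list[tuple[str, float, float]]:
    """Genome-wide window series as (chrom, position, mean) tuples.

    Windows never span chromosomes; placeholder ("unknown") chromosomes are
    skipped. Results must already be sorted by (chrom, pos).
    """
    profile: list[tuple[str, float, float]] = []
    for chrom, group in _group_by_chrom(results):
        if is_unknown_chrom(chrom):
            continue
        vals = np.array(
            [getattr(r, stat) if getattr(r, stat) is not None else np.nan for r in group]
        )
        pos = np.array([r.pos for r in group], dtype=float)
        wpos, wmean = sliding_window_mean(vals, pos, window_n=window_n, step=step)
        profile.extend((chrom, p, m) for p, m in zip(wpos, wmean))
    return profile


def _group_by_chrom(results: list[AssociationResult]):
    groups: dict[str, list[AssociationResult]] = {}
    for r in results:
        groups.setdefault(r.chrom, []).append(r)
    return groups.items()


def attach_window_delta(
    results: list[AssociationResult], window_n: int = 200, step: int = 1
) -> None:
    """Annotate each result with the mean of the window centred nearest it.

    Convenience for the per-SNP output table; region calling consumes the
    full window series from :func:`window_profile` instead.
    """
    for chrom, group in _group_by_chrom(results):
        if is_unknown_chrom(chrom):
            continue
        vals = np.array([r.delta if r.delta is not None else np.nan for r in group])
        pos = np.array([r.pos for r in group], dtype=float)
        wpos, wmean = sliding_window_mean(vals, pos, window_n=window_n, step=step)
        if len(wpos) == 0:
            continue
        for r in group:
            i = int(np.argmin(np.abs(wpos - r.pos)))
            r.window_delta = float(wmean[i])
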