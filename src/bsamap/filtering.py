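"""Marker screening: reduce raw SNP sites to the polymorphic set used for
association.

Rules are applied in a fixed order so the removal counters are
deterministic: bulk depth -> parental polymorphism -> multiallelic ->
between-pool monomorphism. A site is counted once, under the first rule it
fails.

Note on the depth cutoff: the source protocol quotes both "fewer than four
reads" and "depth less than 5x" at different stages; the default here is
``min_bulk_depth=5`` (the SNP-calling-stage value) and it is configurable.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

from .model import BASES, SnpSite

log = logging.getLogger(__name__)


@dataclass
class FilterConfig:
    min_bulk_depth: int = 5
    #: if True, each bulk must reach min_bulk_depth; if False, either bulk
    depth_in_both_pools: bool = True
    require_parent_polymorphism: bool = True
    drop_multiallelic: bool = True
    drop_pool_monomorphic: bool = True

    def __post_init__(self) -> None:
        if self.min_bulk_depth < 0:
            raise ValueError("min_bulk_depth must be >= 0")


@dataclass
class FilterStats:
    """Removal counters; n_input == n_passed + sum of removals."""

    n_input: int = 0
    n_removed_depth: int = 0
    n_removed_parent_monomorphic: int = 0
    n_removed_multiallelic: int = 0
    n_removed_pool_monomorphic: int = 0
    n_passed: int = 0

    @property
    def n_removed(self) -> int:
        return (
            self.n_removed_depth
            + self.n_removed_parent_monomorphic
            + self.n_removed_multiallelic
            + self.n_removed_pool_monomorphic
        )

    def as_dict(self) -> dict[str, int]:
        return {
            "n_input": self.n_input,
            "n_removed_depth": self.n_removed_depth,
            "n_removed_parent_monomorphic": self.n_removed_parent_monomorphic,
            "n_removed_multiallelic": self.n_removed_multiallelic,
            "n_removed_pool_monomorphic": self.n_removed_pool_monomorphic,
            "n_passed": self.n_passed,
        }


def _fails_depth(site: SnpSite, config: FilterConfig) -> bool:
    dom_ok = site.bulk_dom.total >= config.min_bulk_depth
    rec_ok = site.bulk_rec.total >= config.min_bulk_depth
    if config.depth_in_both_pools:
        return not (dom_ok and rec_ok)
    return not (dom_ok or rec_ok)


def _fails_parent_polymorphism(site: SnpSite) -> bool:
    p1, p2 = site.parent1_allele, site.parent2_allele
    if p1 is None or p2 is None or p1 not in BASES or p2 not in BASES:
        # unknown parental genotype: not usable as a polymorphic marker
        return True
    return p1 == p2


def _fails_pool_monomorphism(site: SnpSite) -> bool:
    """Both bulks fixed for the same single base -> no signal between pools."""

    def fixed_base(depths) -> str | None:
        nz = [b for b, d in zip(BASES, depths.as_tuple()) if d > 0]
        return nz[0] if len(nz) == 1 else None

    dom = fixed_base(site.bulk_dom)
    rec = fixed_base(site.bulk_rec)
    return dom is not None and dom == rec


def filter_snps(
    sites: list[SnpSite], config: FilterConfig | None = None
) -> tuple[list[SnpSite], FilterStats]:
    """Apply the screening rules; returns surviving sites and counters."""
    config = config or FilterConfig()
    stats = FilterStats(n_input=len(sites))
    passed: list[SnpSite] = []
    for site in sites:
        if _fails_depth(site, config):
            stats.n_removed_depth += 1
            continue
        if config.require_parent_polymorphism and _fails_parent_polymorphism(site):
            if site.parent1_allele is None or site.parent2_allele is None:
                log.debug(
                    "site %s:%d has unknown parental allele; removed as "
                    "parent-monomorphic", site.chrom, site.pos,
                )
            stats.n_removed_parent_monomorphic += 1
            continue
        if config.drop_multiallelic and not site.is_biallelic:
            stats.n_removed_multiallelic += 1
            continue
        if config.drop_pool_monomorphic and _fails_pool_monomorphism(site):
            stats.n_removed_pool_monomorphic += 1
            continue
        passed.append(site)
    stats.n_passed = len(passed)
    return passed, stats
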