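"""Recombinant analysis on the homozygous-recessive F2 class, map-distance
utilities, and the Mendelian segregation check.

Plants in this class carry two recessive-parent gametes at the trait locus,
so at a linked marker a "0/1" call means one recombinant gamete and "1/1"
means two. Markers with zero recombinants co-segregate with the trait; the
flanking markers with recombinants delimit the interval.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from scipy import stats as _st

from .model import DataError, GenotypeMatrix, GenotypingError


@dataclass
class RecombinantSummary:
    marker_id: str
    n_single: int  # plants coded 0/1
    n_double: int  # plants coded 1/1
    n_missing: int
    n_plants: int

    @property
    def n_recombinant(self) -> int:
        return self.n_single + self.n_double


@dataclass
class DelimitedInterval:
    left_marker: str | None  # None = open boundary
    right_marker: str | None
    co_segregating: list[str]


def count_recombinants(gm: GenotypeMatrix) -> list[RecombinantSummary]:
    """Per-marker counts of single (0/1) and double (1/1) recombinants.

    If the matrix declares a population size larger than the listed plants,
    the unlisted plants count as non-recombinant everywhere.
    """
    summaries = []
    for marker, row in zip(gm.marker_ids, gm.calls):
        n_single = sum(1 for c in row if c == "0/1")
        n_double = sum(1 for c in row if c == "1/1")
        n_missing = sum(1 for c in row if c == "NA")
        summaries.append(
            RecombinantSummary(
                marker_id=marker,
                n_single=n_single,
                n_double=n_double,
                n_missing=n_missing,
                n_plants=gm.n_plants,
            )
        )
    return summaries


def delimit_interval(gm: GenotypeMatrix) -> DelimitedInterval:
    """Locate the trait-containing marker block and its flanking markers.

    The co-segregating set is the longest run of zero-recombinant markers
    (matrix rows are assumed to be in physical order); the boundaries are
    the nearest markers with >= 1 recombinant on each side, or open when a
    side has none. Two equally long zero-recombinant runs are ambiguous and
    raise GenotypingError.
    """
    summaries = count_recombinants(gm)
    zero = [s.n_recombinant == 0 for s in summaries]
    if not any(zero):
        raise DataError("no co-segregating block: every marker has recombinants")

    runs: list[tuple[int, int]] = []  # [start, end] inclusive marker indices
    start = None
    for i, z in enumerate(zero):
        if z and start is None:
            start = i
        elif not z and start is not None:
            runs.append((start, i - 1))
            start = None
    if start is not None:
        runs.append((start, len(zero) - 1))

    longest = max(r[1] - r[0] for r in runs)
    best = [r for r in runs if r[1] - r[0] == longest]
    if len(best) > 1:
        raise GenotypingError(
            "ambiguous co-segregating block: multiple equally long "
            "zero-recombinant runs (possible genotyping error)"
        )
    lo, hi = best[0]
    left = gm.marker_ids[lo - 1] if lo > 0 else None
    right = gm.marker_ids[hi + 1] if hi < len(zero) - 1 else None
    return DelimitedInterval(
        left_marker=left,
        right_marker=right,
        co_segregating=gm.marker_ids[lo : hi + 1],
    )


def recomb_fraction_recessive_class(summary: RecombinantSummary) -> float:
    """Recombination fraction from gamete counts within the recessive class.

    r = (n_single + 2 * n_double) / (2 * (n_plants - n_missing)); every
    scored plant contributes two gametes.
    """
    n_scored = summary.n_plants - summary.n_missing
    if n_scored <= 0:
        raise DataError(f"marker {summary.marker_id}: no scored plants")
    r = (summary.n_single + 2 * summary.n_double) / (2 * n_scored)
    if r >= 0.5:
        raise DataError(
            f"marker {summary.marker_id}: recombination fraction {r:.3f} >= 0.5 "
            "(unlinked)"
        )
    return r


def kosambi_cm(r: float) -> float:
    """Kosambi map distance in cM: d = 25 * ln((1 + 2r) / (1 - 2r))."""
    if not 0.0 <= r < 0.5:
        raise DataError(f"recombination fraction must be in [0, 0.5), got {r}")
    return 25.0 * math.log((1.0 + 2.0 * r) / (1.0 - 2.0 * r))


def kosambi_r(d_cm: float) -> float:
    """Inverse Kosambi: r = tanh(2d / 100) / 2."""
    if d_cm < 0:
        raise DataError(f"map distance must be >= 0, got {d_cm}")
    return math.tanh(2.0 * d_cm / 100.0) / 2.0


def segregation_chi_square(
    n_dominant: int,
    n_recessive: int,
    ratio: tuple[float, float] = (3.0, 1.0),
) -> tuple[float, float]:
    """1-df goodness-of-fit chi-square of observed counts against a ratio."""
    if n_dominant < 0 or n_recessive < 0:
        raise DataError("counts must be >= 0")
    total = n_dominant + n_recessive
    if total == 0:
        raise DataError("total count must be > 0")
    w = ratio[0] + ratio[1]
    expected = (total * ratio[0] / w, total * ratio[1] / w)
    chi2 = sum(
        (obs - exp) ** 2 / exp
        for obs, exp in zip((n_dominant, n_recessive), expected)
    )
    p = float(_st.chi2.sf(chi2, df=1))
    return float(chi2), p
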