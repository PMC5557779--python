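"""Shared domain types and exceptions.

Coordinates are 1-based inclusive everywhere inside the package; conversion
to BED's 0-based half-open convention happens only in the BED writer.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal

import numpy as np

BASES = ("A", "C", "G", "T")
_BASE_INDEX = {b: i for i, b in enumerate(BASES)}

GENOTYPE_CODES = ("0/0", "0/1", "1/1")
MISSING_CODE = "NA"


class BsamapError(Exception):
    """Base class for all package errors."""


class SchemaError(BsamapError):
    """A file does not match the expected tabular schema."""


class RowParseError(BsamapError):
    """A data row could not be parsed; carries the 1-based line number."""

    def __init__(self, message: str, line: int):
        super().__init__(f"line {line}: {message}")
        self.line = line


class ConfigurationError(BsamapError):
    """Invalid user-supplied configuration (bad sample map, flags, ...)."""


class DataError(BsamapError):
    """Input data violates a precondition of an analysis step."""


class GenotypingError(DataError):
    """Genotype matrix is internally inconsistent (suspect genotyping error)."""


def is_unknown_chrom(label: str) -> bool:
    """True for placeholder chromosome labels ("chrUn", "unknown", ...).

    Sites on such labels keep their per-SNP statistics but are excluded
    from windowing, smoothing and region calling.
    """
    norm = label.strip().lower().replace(" ", "").replace("_", "")
    return norm in {"chrun", "un", "unknown", "chrunknown"} or "unknown" in norm


@dataclass(frozen=True)
class BaseDepths:
    """Read counts supporting each nucleotide in one bulk at one site."""

    a: int = 0
    c: int = 0
    g: int = 0
    t: int = 0

    def __post_init__(self) -> None:
        for name in ("a", "c", "g", "t"):
            v = getattr(self, name)
            if not isinstance(v, (int, np.integer)) or isinstance(v, bool):
                raise ValueError(f"depth_{name.upper()} must be an integer, got {v!r}")
            if v < 0:
                raise ValueError(f"depth_{name.upper()} must be >= 0, got {v}")

    @property
    def total(self) -> int:
        return self.a + self.c + self.g + self.t

    def depth_of(self, base: str) -> int:
        if base not in _BASE_INDEX:
            raise ValueError(f"unknown base {base!r}")
        return self.as_tuple()[_BASE_INDEX[base]]

    def as_tuple(self) -> tuple[int, int, int, int]:
        return (self.a, self.c, self.g, self.t)

    def frequencies(self) -> np.ndarray | None:
        """Within-bulk base frequencies (A, C, G, T), or None at zero depth."""
        tot = self.total
        if tot == 0:
            return None
        return np.asarray(self.as_tuple(), dtype=float) / tot


@dataclass
class SnpSite:
    """One SNP site with parental alleles and per-bulk base depths.

    ``parent1`` is the dominant-phenotype parent (allele written M below),
    ``parent2`` the recessive-phenotype parent (allele P). ``bulk_dom`` and
    ``bulk_rec`` are the dominant- and recessive-phenotype bulks.
    """

    chrom: str
    pos: int
    ref: str
    alts: tuple[str, ...]
    parent1_allele: str | None
    parent2_allele: str | None
    bulk_dom: BaseDepths
    bulk_rec: BaseDepths
    parent1_depth: int | None = None
    parent2_depth: int | None = None
    flagged: bool = False

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"pos must be >= 1, got {self.pos}")
        if self.ref not in BASES:
            raise ValueError(f"ref_base must be one of {BASES}, got {self.ref!r}")
        self.alts = tuple(self.alts)

    @property
    def is_biallelic(self) -> bool:
        return len(self.alts) == 1


def round_half_up(value: Decimal | int | float, ndigits: int = 2) -> float:
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(str(value)).quantize(q, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class CandidateRegion:
    """A chromosome interval called above threshold (1-based inclusive)."""

    chrom: str
    start_bp: int
    end_bp: int
    method: str = "unknown"

    def __post_init__(self) -> None:
        if self.start_bp > self.end_bp:
            raise ValueError(
                f"start_bp {self.start_bp} > end_bp {self.end_bp} on {self.chrom}"
            )

    @property
    def size_mb(self) -> float:
        """Interval length in Mb, (end - start)/1e6 rounded half-up to 2 dp."""
        exact = Decimal(self.end_bp - self.start_bp) / Decimal(1_000_000)
        return round_half_up(exact, 2)


@dataclass
class GenotypeMatrix:
    """Markers x plants matrix of recombination codes for recessive-class F2s.

    Codes: "0/0" non-recombinant, "0/1" single recombinant, "1/1" double
    recombinant, "NA" missing. Marker order is physical order along the
    chromosome. ``n_population`` may declare a total population size larger
    than the listed plants; unlisted plants are treated as non-recombinant
    ("0/0") everywhere.
    """

    marker_ids: list[str]
    plant_ids: list[str]
    calls: list[list[str]]  # rows = markers, columns = plants
    marker_positions: list[int] | None = None
    n_population: int | None = None

    def __post_init__(self) -> None:
        if len(self.calls) != len(self.marker_ids):
            raise ValueError("calls row count does not match marker_ids")
        for marker, row in zip(self.marker_ids, self.calls):
            if len(row) != len(self.plant_ids):
                raise ValueError(f"marker {marker}: row length != number of plants")
            for plant, code in zip(self.plant_ids, row):
                if code not in GENOTYPE_CODES and code != MISSING_CODE:
                    raise GenotypingError(
                        f"invalid genotype code {code!r} at marker {marker}, "
                        f"plant {plant}"
                    )
        if self.marker_positions is not None and len(self.marker_positions) != len(
            self.marker_ids
        ):
            raise ValueError("marker_positions length does not match marker_ids")
        if self.n_population is not None and self.n_population < len(self.plant_ids):
            raise ValueError("n_population smaller than number of listed plants")

    @property
    def n_plants(self) -> int:
        """Effective population size (declared total, else listed plants)."""
        return self.n_population if self.n_population is not None else len(self.plant_ids)

    def row(self, marker_id: str) -> list[str]:
        return self.calls[self.marker_ids.index(marker_id)]
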