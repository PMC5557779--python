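"""Readers and writers for the tabular, VCF and BED interfaces.

The canonical depth table is a TSV with one row per SNP site:

    chrom  pos  ref  alt  p1_allele  p2_allele
    dom_A  dom_C  dom_G  dom_T  rec_A  rec_C  rec_G  rec_T
    p1_depth  p2_depth

``alt`` may hold comma-separated bases; ``p1_depth``/``p2_depth`` and the
parental alleles may be "NA". Statistics are written with 6 decimals and
missing values as "NA".
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .model import (
    BaseDepths,
    CandidateRegion,
    GenotypeMatrix,
    ConfigurationError,
    RowParseError,
    SchemaError,
    SnpSite,
)

DEPTH_COLUMNS = [
    "chrom", "pos", "ref", "alt", "p1_allele", "p2_allele",
    "dom_A", "dom_C", "dom_G", "dom_T",
    "rec_A", "rec_C", "rec_G", "rec_T",
    "p1_depth", "p2_depth",
]

ASSOC_COLUMNS = [
    "chrom", "pos", "snp_index_dom", "snp_index_rec", "delta",
    "ed", "ed5", "window_delta", "loess_delta", "loess_ed5",
]

_NA = "NA"


def _parse_depth(token: str, line: int, column: str) -> int:
    try:
        value = int(token)
    except (TypeError, ValueError):
        raise RowParseError(f"column {column}: non-integer depth {token!r}", line)
    if value < 0:
        raise RowParseError(f"column {column}: negative depth {value}", line)
    return value


def _parse_optional_int(token: str, line: int, column: str) -> int | None:
    if token in ("", _NA, "."):
        return None
    return _parse_depth(token, line, column)


def read_depth_table(path: str | Path) -> list[SnpSite]:
    """Read the canonical depth TSV into SnpSites, preserving file order."""
    path = Path(path)
    sites: list[SnpSite] = []
    with path.open(newline="") as handle:
        reader = csv.reader(handle, delimiter="\t")
        try:
            header = next(reader)
        except StopIteration:
            raise SchemaError(f"{path}: empty file, expected a header row")
        missing = [col for col in DEPTH_COLUMNS if col not in header]
        if missing:
            raise SchemaError(f"{path}: missing column(s) {', '.join(missing)}")
        idx = {col: header.index(col) for col in DEPTH_COLUMNS}
        for lineno, row in enumerate(reader, start=2):
            if not row or (len(row) == 1 and not row[0].strip()):
                continue
            if len(row) < len(header):
                raise RowParseError(f"expected {len(header)} fields, got {len(row)}", lineno)

            def get(col: str) -> str:
                return row[idx[col]].strip()

            try:
                pos = int(get("pos"))
            except ValueError:
                raise RowParseError(f"column pos: non-integer {get('pos')!r}", lineno)
            alts = tuple(b for b in get("alt").split(",") if b)
            p1 = get("p1_allele") or None
            p2 = get("p2_allele") or None
            site = SnpSite(
                chrom=get("chrom"),
                pos=pos,
                ref=get("ref"),
                alts=alts,
                parent1_allele=None if p1 in (None, _NA, ".") else p1,
                parent2_allele=None if p2 in (None, _NA, ".") else p2,
                bulk_dom=BaseDepths(
                    a=_parse_depth(get("dom_A"), lineno, "dom_A"),
                    c=_parse_depth(get("dom_C"), lineno, "dom_C"),
                    g=_parse_depth(get("dom_G"), lineno, "dom_G"),
                    t=_parse_depth(get("dom_T"), lineno, "dom_T"),
                ),
                bulk_rec=BaseDepths(
                    a=_parse_depth(get("rec_A"), lineno, "rec_A"),
                    c=_parse_depth(get("rec_C"), lineno, "rec_C"),
                    g=_parse_depth(get("rec_G"), lineno, "rec_G"),
                    t=_parse_depth(get("rec_T"), lineno, "rec_T"),
                ),
                parent1_depth=_parse_optional_int(get("p1_depth"), lineno, "p1_depth"),
                parent2_depth=_parse_optional_int(get("p2_depth"), lineno, "p2_depth"),
            )
            sites.append(site)
    return sites


def write_depth_table(sites: Iterable[SnpSite], path: str | Path) -> None:
    """Write SnpSites as the canonical depth TSV (inverse of the reader)."""
    with Path(path).open("w", newline="") as handle:
        writer = csv.writer(handle, delimiter="\t", lineterminator="\n")
        writer.writerow(DEPTH_COLUMNS)
        for s in sites:
            writer.writerow([
                s.chrom, s.pos, s.ref, ",".join(s.alts),
                s.parent1_allele or _NA, s.parent2_allele or _NA,
                *s.bulk_dom.as_tuple(), *s.bulk_rec.as_tuple(),
                _NA if s.parent1_depth is None else s.parent1_depth,
                _NA if s.parent2_depth is None else s.parent2_depth,
            ])


@dataclass
class VcfReadStats:
    n_records: int = 0
    n_sites: int = 0
    n_skipped_indel: int = 0
    n_flagged_no_depth: int = 0


_VCF_ROLES = ("parent_dom", "parent_rec", "bulk_dom", "bulk_rec")


def read_vcf_bulks(
    path: str | Path, sample_map: dict[str, str]
) -> tuple[list[SnpSite], VcfReadStats]:
    """Read a 4-sample VCF with per-sample allele depths (AD) into SnpSites.

    ``sample_map`` maps the roles parent_dom, parent_rec, bulk_dom, bulk_rec
    to VCF sample names. Per-base depths are reconstructed by assigning each
    REF/ALT allele's AD entry to its base. Records with any allele longer
    than 1 bp (indels) are skipped and counted. Sites where a bulk lacks
    depth annotations are emitted with zero depths and ``flagged=True``.
    Parental alleles are taken from the parent genotypes when homozygous.
    """
    from cyvcf2 import VCF  # deferred: cyvcf2 import is comparatively slow

    for role in _VCF_ROLES:
        if role not in sample_map:
            raise ConfigurationError(f"sample_map is missing role {role!r}")
    vcf = VCF(str(path))
    samples = list(vcf.samples)
    for role, name in sample_map.items():
        if name not in samples:
            raise ConfigurationError(
                f"sample {name!r} (role {role}) not present in VCF; "
                f"available: {', '.join(samples)}"
            )
    col = {role: samples.index(sample_map[role]) for role in _VCF_ROLES}

    stats = VcfReadStats()
    sites: list[SnpSite] = []
    for rec in vcf:
        stats.n_records += 1
        alleles = [rec.REF] + list(rec.ALT)
        if any(len(a) != 1 for a in alleles):
            stats.n_skipped_indel += 1
            continue
        ad = rec.format("AD")  # shape (n_samples, n_alleles), -1 = missing

        def bulk_depths(sample_idx: int) -> tuple[BaseDepths, bool]:
            counts = {b: 0 for b in "ACGT"}
            ok = ad is not None
            if ok:
                row = ad[sample_idx]
                for allele, depth in zip(alleles, row):
                    if depth < 0:
                        ok = False
                        break
                    counts[allele] = counts.get(allele, 0) + int(depth)
            if not ok:
                counts = {b: 0 for b in "ACGT"}
            return (
                BaseDepths(a=counts["A"], c=counts["C"], g=counts["G"], t=counts["T"]),
                not ok,
            )

        def parent_allele(sample_idx: int) -> str | None:
            gt = rec.genotypes[sample_idx][:-1]  # last entry is phasedness
            called = [g for g in gt if g is not None and g >= 0]
            if not called or len(set(called)) != 1:
                return None  # missing or heterozygous parent call
            return alleles[called[0]]

        dom, dom_flag = bulk_depths(col["bulk_dom"])
        rec_bd, rec_flag = bulk_depths(col["bulk_rec"])
        flagged = dom_flag or rec_flag
        if flagged:
            stats.n_flagged_no_depth += 1
        p1_ad = ad[col["parent_dom"]] if ad is not None else None
        p2_ad = ad[col["parent_rec"]] if ad is not None else None
        sites.append(
            SnpSite(
                chrom=rec.CHROM,
                pos=rec.POS,
                ref=rec.REF,
                alts=tuple(rec.ALT),
                parent1_allele=parent_allele(col["parent_dom"]),
                parent2_allele=parent_allele(col["parent_rec"]),
                bulk_dom=dom,
                bulk_rec=rec_bd,
                parent1_depth=int(p1_ad.sum()) if p1_ad is not None and p1_ad.min() >= 0 else None,
                parent2_depth=int(p2_ad.sum()) if p2_ad is not None and p2_ad.min() >= 0 else None,
                flagged=flagged,
            )
        )
        stats.n_sites += 1
    return sites, stats


def write_regions_bed(regions: Sequence[CandidateRegion], path: str | Path) -> None:
    """Write regions as BED (0-based half-open), method label in the name column."""
    with Path(path).open("w") as handle:
        for r in regions:
            handle.write(f"{r.chrom}\t{r.start_bp - 1}\t{r.end_bp}\t{r.method}\n")


def read_regions_bed(path: str | Path, method: str | None = None) -> list[CandidateRegion]:
    regions = []
    with Path(path).open() as handle:
        for line in handle:
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            regions.append(
                CandidateRegion(
                    chrom=fields[0],
                    start_bp=int(fields[1]) + 1,
                    end_bp=int(fields[2]),
                    method=method or (fields[3] if len(fields) > 3 else "unknown"),
                )
            )
    return regions


def _fmt(value: float | None) -> str:
    return _NA if value is None else f"{value:.6f}"


def write_association_table(results: Iterable, path: str | Path) -> None:
    """One row per SNP; statistics at 6 decimals, missing values as NA."""
    with Path(path).open("w", newline="") as handle:
        writer = csv.writer(handle, delimiter="\t", lineterminator="\n")
        writer.writerow(ASSOC_COLUMNS)
        for r in results:
            writer.writerow([
                r.chrom, r.pos,
                _fmt(r.snp_index_dom), _fmt(r.snp_index_rec), _fmt(r.delta),
                _fmt(r.ed), _fmt(r.ed5),
                _fmt(r.window_delta), _fmt(r.loess_delta), _fmt(r.loess_ed5),
            ])


def read_association_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", na_values=[_NA], dtype={"chrom": str})
    missing = [c for c in ASSOC_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing column(s) {', '.join(missing)}")
    return df


def read_genotype_matrix(
    path: str | Path,
    n_population: int | None = None,
    marker_positions: dict[str, int] | None = None,
) -> GenotypeMatrix:
    """Read a markers-x-plants genotype TSV (first column = marker id)."""
    path = Path(path)
    with path.open(newline="") as handle:
        reader = csv.reader(handle, delimiter="\t")
        try:
            header = next(reader)
        except StopIteration:
            raise SchemaError(f"{path}: empty file, expected a header row")
        plant_ids = [h.strip() for h in header[1:]]
        marker_ids: list[str] = []
        calls: list[list[str]] = []
        for lineno, row in enumerate(reader, start=2):
            if not row or not row[0].strip():
                continue
            if len(row) != len(header):
                raise RowParseError(f"expected {len(header)} fields, got {len(row)}", lineno)
            marker_ids.append(row[0].strip())
            calls.append([c.strip() for c in row[1:]])
    positions = None
    if marker_positions is not None:
        positions = [marker_positions[m] for m in marker_ids]
    return GenotypeMatrix(
        marker_ids=marker_ids,
        plant_ids=plant_ids,
        calls=calls,
        marker_positions=positions,
        n_population=n_population,
    )


def write_genotype_matrix(gm: GenotypeMatrix, path: str | Path) -> None:
    with Path(path).open("w", newline="") as handle:
        writer = csv.writer(handle, delimiter="\t", lineterminator="\n")
        writer.writerow(["marker", *gm.plant_ids])
        for marker, row in zip(gm.marker_ids, gm.calls):
            writer.writerow([marker, *row])
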