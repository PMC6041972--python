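"""Readers, writers and core record types for genetic maps and QTL tables.

The native on-disk dialect is UTF-8 TSV with a one-line header:

* map TSV: ``map_id  chromosome  marker  position_cM``
* QTL TSV: ``qtl_id  study_id  trait  tissue_class  trait_category  chromosome
  position_cM  ci_start_cM  ci_end_cM  lod  lrs  r2  population_size
  population_type``
* physical anchor TSV: ``marker  chromosome  position_bp``

Missing statistics are encoded as empty cells, never as 0.  Positions are
stored at full floating precision; two-decimal rounding (half-up) is applied
only when reports are written.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .errors import ParseError, ValidationError

log = logging.getLogger(__name__)

TISSUE_CLASSES = frozenset({"leaf", "stem", "kernel"})
TRAIT_CATEGORIES = frozenset({"insect_resistance", "CWC"})
POPULATION_TYPES = frozenset({"F2", "F3", "RIL", "IRIL", "reference"})

MAP_COLUMNS = ["map_id", "chromosome", "marker", "position_cM"]
QTL_COLUMNS = [
    "qtl_id", "study_id", "trait", "tissue_class", "trait_category",
    "chromosome", "position_cM", "ci_start_cM", "ci_end_cM",
    "lod", "lrs", "r2", "population_size", "population_type",
]
ANCHOR_COLUMNS = ["marker", "chromosome", "position_bp"]


def round_half_up(x: float, ndigits: int = 2) -> float:
    """Round half away from zero at ``ndigits`` decimals (report precision)."""
    q = Decimal(10) ** -ndigits
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


def natural_chrom_key(label: str):
    """Sort chromosome labels numerically when possible, else lexically."""
    try:
        return (0, float(label), "")
    except (TypeError, ValueError):
        return (1, 0.0, str(label))


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MarkerLocus:
    """A marker with a genetic position (cM) on one chromosome."""

    name: str
    chromosome: str
    position: float

    def __post_init__(self):
        if not self.name:
            raise ValidationError("marker name must be non-empty")
        if not math.isfinite(self.position) or self.position < 0:
            raise ValidationError(
                f"marker {self.name!r}: position must be finite and >= 0, "
                f"got {self.position}"
            )


@dataclass
class GeneticMap:
    """Ordered markers with cM positions per chromosome.

    ``markers`` maps a chromosome label to its loci sorted by position.
    ``population_size``/``population_type`` describe the mapping population
    for component (study) maps and are absent/"reference" for the reference.
    """

    map_id: str
    markers: dict[str, list[MarkerLocus]] = field(default_factory=dict)
    population_size: int | None = None
    population_type: str = "reference"
    mapping_function: str | None = None

    @classmethod
    def from_loci(cls, map_id: str, loci: Iterable[MarkerLocus], **kw) -> "GeneticMap":
        by_chrom: dict[str, list[MarkerLocus]] = {}
        for locus in loci:
            by_chrom.setdefault(locus.chromosome, []).append(locus)
        for chrom, items in by_chrom.items():
            items.sort(key=lambda m: (m.position, m.name))
            names = [m.name for m in items]
            if len(names) != len(set(names)):
                dup = sorted({n for n in names if names.count(n) > 1})
                raise ValidationError(
                    f"map {map_id!r} chromosome {chrom}: duplicate marker "
                    f"name(s) {dup}"
                )
        ordered = dict(sorted(by_chrom.items(), key=lambda kv: natural_chrom_key(kv[0])))
        return cls(map_id=map_id, markers=ordered, **kw)

    @property
    def chromosomes(self) -> list[str]:
        return list(self.markers)

    def loci(self, chromosome: str) -> list[MarkerLocus]:
        return self.markers[chromosome]

    def positions(self, chromosome: str) -> list[float]:
        return [m.position for m in self.markers[chromosome]]

    def marker_names(self, chromosome: str) -> list[str]:
        return [m.name for m in self.markers[chromosome]]

    def chromosome_length(self, chromosome: str) -> float:
        loci = self.markers[chromosome]
        return loci[-1].position if loci else 0.0

    def total_length(self) -> float:
        return sum(self.chromosome_length(c) for c in self.markers)

    def n_markers(self) -> int:
        return sum(len(v) for v in self.markers.values())

    def position_of(self, name: str, chromosome: str) -> float | None:
        for m in self.markers.get(chromosome, []):
            if m.name == name:
                return m.position
        return None


@dataclass
class QTLRecord:
    """One reported QTL with its study and population metadata.

    ``lod``, ``lrs`` and ``r2`` are the statistics as published; at least one
    must be present.  ``ci_start``/``ci_end`` hold the reported support
    interval (cM) when the publication gave one.
    """

    qtl_id: str
    study_id: str
    trait: str
    tissue_class: str
    trait_category: str
    chromosome: str
    position: float
    ci_start: float | None = None
    ci_end: float | None = None
    lod: float | None = None
    lrs: float | None = None
    r2: float | None = None
    population_size: int = 0
    population_type: str = "F2"
    species_or_compound: str = ""

    def validate(self) -> None:
        if not self.qtl_id:
            raise ValidationError("qtl_id must be non-empty")
        if self.tissue_class not in TISSUE_CLASSES:
            raise ValidationError(
                f"{self.qtl_id}: unknown tissue_class {self.tissue_class!r}"
            )
        if self.trait_category not in TRAIT_CATEGORIES:
            raise ValidationError(
                f"{self.qtl_id}: unknown trait_category {self.trait_category!r}"
            )
        if not math.isfinite(self.position):
            raise ValidationError(f"{self.qtl_id}: non-finite position")
        if self.ci_start is not None and self.ci_end is not None:
            if self.ci_start > self.ci_end:
                raise ValidationError(
                    f"{self.qtl_id}: ci_start {self.ci_start} > ci_end {self.ci_end}"
                )
            if not (self.ci_start <= self.position <= self.ci_end):
                raise ValidationError(
                    f"{self.qtl_id}: position {self.position} outside reported "
                    f"CI [{self.ci_start}, {self.ci_end}]"
                )
        if self.lod is None and self.lrs is None and self.r2 is None:
            raise ValidationError(
                f"{self.qtl_id}: at least one of lod, lrs, r2 must be present"
            )
        if self.r2 is not None and not (0 < self.r2 <= 1):
            raise ValidationError(f"{self.qtl_id}: r2 must be in (0, 1], got {self.r2}")
        if self.population_size <= 0:
            raise ValidationError(
                f"{self.qtl_id}: population_size must be positive"
            )


@dataclass(frozen=True)
class PhysicalAnchor:
    """A marker's physical position (bp) on the genome assembly."""

    marker_name: str
    chromosome: str
    position_bp: int

    def __post_init__(self):
        if self.position_bp < 0:
            raise ValidationError(
                f"anchor {self.marker_name!r}: position_bp must be >= 0"
            )


@dataclass
class QTLTableResult:
    """Outcome of reading a QTL table: records plus per-row diagnostics."""

    records: list[QTLRecord]
    diagnostics: list[tuple[int, str]]  # (1-based data row number, message)
    n_rows: int


# ---------------------------------------------------------------------------
# Readers
# ---------------------------------------------------------------------------

def _read_tsv(path: str | Path, required: Sequence[str]) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise ParseError(f"no such file: {path}")
    try:
        df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    except Exception as exc:  # pragma: no cover - pandas error text varies
        raise ParseError(f"{path}: {exc}") from exc
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: missing column(s) {missing}")
    return df


def _float_cell(value: str, column: str, line: int) -> float | None:
    value = value.strip()
    if value == "" or value.upper() in {"NA", "NAN"}:
        return None
    try:
        return float(value)
    except ValueError:
        raise ParseError(f"non-numeric {column}: {value!r}", line=line)


def read_map(path: str | Path, dialect: str = "tsv", *,
             population_size: int | None = None,
             population_type: str = "reference",
             mapping_function: str | None = None) -> GeneticMap:
    """Read a genetic map TSV into a :class:`GeneticMap`.

    Rows may appear in any order; markers are sorted per chromosome.  A
    duplicated marker name within a chromosome is rejected.
    """
    if dialect != "tsv":
        raise ValueError(f"unknown map dialect {dialect!r}")
    df = _read_tsv(path, MAP_COLUMNS)
    map_ids = sorted(set(df["map_id"]))
    if len(map_ids) > 1:
        raise ParseError(f"{path}: multiple map_id values {map_ids}")
    map_id = map_ids[0] if map_ids else Path(path).stem
    loci = []
    for i, row in enumerate(df.itertuples(index=False), start=2):
        pos = _float_cell(row.position_cM, "position_cM", i)
        if pos is None:
            raise ParseError("empty position_cM", line=i)
        loci.append(MarkerLocus(name=row.marker, chromosome=str(row.chromosome),
                                position=pos))
    return GeneticMap.from_loci(
        map_id, loci, population_size=population_size,
        population_type=population_type, mapping_function=mapping_function,
    )


def load_qtl_table(path: str | Path, strict: bool = False) -> QTLTableResult:
    """Read a QTL TSV, validating every row.

    Validation is total: every data row is either converted to a
    :class:`QTLRecord` or attached to a diagnostic, so
    ``len(records) + len(diagnostics) == n_rows``.  In strict mode the first
    invalid row aborts with :class:`ValidationError`.
    """
    df = _read_tsv(path, QTL_COLUMNS)
    records: list[QTLRecord] = []
    diagnostics: list[tuple[int, str]] = []
    for i, row in enumerate(df.itertuples(index=False), start=1):
        line = i + 1  # header is line 1
        try:
            n_raw = _float_cell(row.population_size, "population_size", line)
            rec = QTLRecord(
                qtl_id=row.qtl_id,
                study_id=row.study_id,
                trait=row.trait,
                tissue_class=row.tissue_class,
                trait_category=row.trait_category,
                chromosome=str(row.chromosome),
                position=_float_cell(row.position_cM, "position_cM", line),
                ci_start=_float_cell(row.ci_start_cM, "ci_start_cM", line),
                ci_end=_float_cell(row.ci_end_cM, "ci_end_cM", line),
                lod=_float_cell(row.lod, "lod", line),
                lrs=_float_cell(row.lrs, "lrs", line),
                r2=_float_cell(row.r2, "r2", line),
                population_size=int(n_raw) if n_raw is not None else 0,
                population_type=row.population_type,
            )
            rec.validate()
            records.append(rec)
        except (ParseError, ValidationError) as exc:
            if strict:
                raise ValidationError(f"row {i}: {exc}") from exc
            diagnostics.append((i, str(exc)))
    if len(df) == 0:
        log.warning("QTL table %s is empty", path)
    return QTLTableResult(records=records, diagnostics=diagnostics, n_rows=len(df))


def read_qtl_table(path: str | Path, strict: bool = False) -> list[QTLRecord]:
    """Read a QTL TSV and return the valid records (see :func:`load_qtl_table`)."""
    result = load_qtl_table(path, strict=strict)
    for row, message in result.diagnostics:
        log.warning("QTL table %s row %d rejected: %s", path, row, message)
    return result.records


def read_physical_anchors(path: str | Path) -> list[PhysicalAnchor]:
    """Read a marker -> physical position (bp) table."""
    df = _read_tsv(path, ANCHOR_COLUMNS)
    anchors = []
    for i, row in enumerate(df.itertuples(index=False), start=2):
        bp = _float_cell(row.position_bp, "position_bp", i)
        if bp is None:
            raise ParseError("empty position_bp", line=i)
        anchors.append(PhysicalAnchor(marker_name=row.marker,
                                      chromosome=str(row.chromosome),
                                      position_bp=int(bp)))
    return anchors


# ---------------------------------------------------------------------------
# Writers
# ---------------------------------------------------------------------------

def write_map(gmap: GeneticMap, path: str | Path) -> None:
    rows = [
        {"map_id": gmap.map_id, "chromosome": c, "marker": m.name,
         "position_cM": repr(m.position)}
        for c in gmap.chromosomes for m in gmap.loci(c)
    ]
    pd.DataFrame(rows, columns=MAP_COLUMNS).to_csv(path, sep="\t", index=False)


def _fmt(value) -> str:
    return "" if value is None else repr(value) if isinstance(value, float) else str(value)


def write_qtl_table(records: Sequence[QTLRecord], path: str | Path) -> None:
    rows = []
    for q in records:
        rows.append({
            "qtl_id": q.qtl_id, "study_id": q.study_id, "trait": q.trait,
            "tissue_class": q.tissue_class, "trait_category": q.trait_category,
            "chromosome": q.chromosome, "position_cM": _fmt(q.position),
            "ci_start_cM": _fmt(q.ci_start), "ci_end_cM": _fmt(q.ci_end),
            "lod": _fmt(q.lod), "lrs": _fmt(q.lrs), "r2": _fmt(q.r2),
            "population_size": q.population_size,
            "population_type": q.population_type,
        })
    pd.DataFrame(rows, columns=QTL_COLUMNS).to_csv(path, sep="\t", index=False)


def write_mqtl_report(mqtls: Sequence, path: str | Path) -> None:
    """Write the declared-MQTL report TSV (2-decimal genetic coordinates).

    Physical columns are emitted as NA when an MQTL carries no physical
    interval; an open-ended physical interval end is written as END.
    """
    if not mqtls:
        raise ValueError("cannot write an empty MQTL report")
    rows = []
    for m in mqtls:
        if m.phys_start_bp is None:
            phys_start = "NA"
        else:
            phys_start = str(int(m.phys_start_bp))
        if getattr(m, "phys_end_open", False):
            phys_end = "END"
        elif m.phys_end_bp is None:
            phys_end = "NA"
        else:
            phys_end = str(int(m.phys_end_bp))
        rows.append({
            "mqtl_id": m.mqtl_id,
            "tissue_class": m.tissue_class,
            "chromosome": m.chromosome,
            "ci_start_cM": round_half_up(m.ci95_start),
            "position_cM": round_half_up(m.position),
            "ci_end_cM": round_half_up(m.ci95_end),
            "ci_width_cM": round_half_up(m.ci_width),
            "flank_left": m.flank_left or "NA",
            "flank_right": m.flank_right or "NA",
            "phys_start_bp": phys_start,
            "phys_end_bp": phys_end,
        })
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
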