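"""siRNA library handling, randomized 384-well layouts and dispenser picklists.

The layout model: candidate genes are partitioned into *plate sets*. Each set
is one randomized 384-well layout holding every one of its genes in
``replicates`` wells plus reserved non-targeting (NT) and control-gene wells.
The layout is physically replicated once per assay condition, so a set with
three conditions occupies three destination plates sharing identical well
assignments.
"""

from __future__ import annotations

import csv
import math
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from gsis_screen.errors import (
    ConfigurationError,
    LibraryLookupError,
    LibraryParseError,
)

ROWS = "ABCDEFGHIJKLMNOP"
N_COLS = 24
N_WELLS = len(ROWS) * N_COLS

#: Canonical condition labels, in assay order.
DEFAULT_CONDITIONS: tuple[str, ...] = ("0mM", "20mM", "20mM+IBMX")

NT_GENE = "NT"
CONTROL_GENES: tuple[str, ...] = ("INSULIN", "PLK1", "ZMIZ1", "HNF4A")

_WELL_RE = re.compile(r"^([A-P])0*([1-9][0-9]?)$")


def parse_well(label: str) -> tuple[int, int]:
    """Parse a 384-well label into 0-based ``(row, column)`` indices.

    Accepts both plain ("A1") and zero-padded ("A01") dialects.
    """
    m = _WELL_RE.match(str(label).strip().upper())
    if not m:
        raise ValueError(f"not a valid 384-well label: {label!r}")
    row = ROWS.index(m.group(1))
    col = int(m.group(2)) - 1
    if col >= N_COLS:
        raise ValueError(f"column out of range in well label {label!r}")
    return row, col


def format_well(row: int, col: int, zero_pad: bool = False) -> str:
    """Format 0-based ``(row, column)`` indices as a well label."""
    if not (0 <= row < len(ROWS) and 0 <= col < N_COLS):
        raise ValueError(f"well indices out of range: ({row}, {col})")
    return f"{ROWS[row]}{col + 1:02d}" if zero_pad else f"{ROWS[row]}{col + 1}"


def all_wells() -> list[str]:
    """All 384 well labels in row-major order (A1..A24, B1..., P24)."""
    return [format_well(r, c) for r in range(len(ROWS)) for c in range(N_COLS)]


def well_sort_key(label: str) -> tuple[int, int]:
    return parse_well(label)


@dataclass(frozen=True)
class SirnaLibraryEntry:
    """One library siRNA with its source-plate coordinates."""

    uniprot_id: str
    gene_symbol: str
    source_plate: str
    source_well: str
    catalog_id: str | None = None

    def __post_init__(self) -> None:
        parse_well(self.source_well)  # raises on bad grammar


@dataclass(frozen=True)
class WellAssignment:
    """One destination well of one plate-set layout."""

    destination_plate: str
    well: str
    role: str  # candidate | control | nt | empty
    gene_symbol: str | None
    replicate_index: int

    def __post_init__(self) -> None:
        if self.role not in ("candidate", "control", "nt", "empty"):
            raise ValueError(f"unknown well role: {self.role!r}")
        if self.role in ("candidate", "control") and not self.gene_symbol:
            raise ValueError(f"role {self.role!r} requires a gene symbol")
        if self.role in ("nt", "empty") and self.gene_symbol is not None:
            raise ValueError(f"role {self.role!r} must not carry a gene symbol")


@dataclass
class PlateSet:
    """One randomized layout shared by its per-condition plate replicas."""

    set_id: int
    layout: list[WellAssignment]
    condition_plates: dict[str, str]

    @property
    def barcode(self) -> str:
        return f"SET{self.set_id}"

    def non_empty(self) -> list[WellAssignment]:
        return [a for a in self.layout if a.role != "empty"]

    def genes(self, roles: tuple[str, ...] = ("candidate",)) -> list[str]:
        seen: dict[str, None] = {}
        for a in self.layout:
            if a.role in roles and a.gene_symbol is not None:
                seen.setdefault(a.gene_symbol)
        return list(seen)


@dataclass(frozen=True)
class PicklistRow:
    source_plate: str
    source_well: str
    destination_plate: str
    destination_well: str
    volume_nl: float = 100.0

    def __post_init__(self) -> None:
        if self.volume_nl <= 0:
            raise ValueError("transfer volume must be positive")


@dataclass
class ControlSpec:
    """How many wells each control reagent gets on every plate set.

    Counts default to 33 NT wells and 8 wells per control gene; positions are
    randomized together with candidate wells unless ``fixed_positions`` maps
    each control reagent to an explicit well list.
    """

    nt_gene: str = NT_GENE
    nt_wells: int = 33
    control_wells: dict[str, int] = field(
        default_factory=lambda: {g: 8 for g in CONTROL_GENES}
    )
    fixed_positions: dict[str, list[str]] | None = None

    @property
    def total_wells(self) -> int:
        return self.nt_wells + sum(self.control_wells.values())

    def validate(self) -> None:
        if self.nt_wells < 2:
            raise ConfigurationError("need at least 2 NT wells per plate for SSMD")
        if any(n < 1 for n in self.control_wells.values()):
            raise ConfigurationError("control well counts must be >= 1")
        if self.fixed_positions is not None:
            expected = {self.nt_gene: self.nt_wells, **self.control_wells}
            flat: list[str] = []
            for reagent, count in expected.items():
                wells = self.fixed_positions.get(reagent, [])
                if len(wells) != count:
                    raise ConfigurationError(
                        f"fixed_positions for {reagent} must list {count} wells"
                    )
                flat.extend(wells)
            if len(set(flat)) != len(flat):
                raise ConfigurationError("fixed control positions overlap")


# ---------------------------------------------------------------------------
# Library I/O


def load_library(path: str | Path) -> list[SirnaLibraryEntry]:
    """Load a siRNA library CSV.

    Required columns: uniprot_id, gene_symbol, source_plate, source_well;
    catalog_id is optional. Rows with malformed well labels or duplicated
    UniProt IDs are rejected.
    """
    df = pd.read_csv(path, dtype=str)
    required = {"uniprot_id", "gene_symbol", "source_plate", "source_well"}
    missing = required - set(df.columns)
    if missing:
        raise LibraryParseError(f"library CSV missing columns: {sorted(missing)}")
    entries: list[SirnaLibraryEntry] = []
    for i, row in enumerate(df.itertuples(index=False), start=2):
        try:
            entries.append(
                SirnaLibraryEntry(
                    uniprot_id=str(row.uniprot_id),
                    gene_symbol=str(row.gene_symbol),
                    source_plate=str(row.source_plate),
                    source_well=str(row.source_well),
                    catalog_id=(
                        str(row.catalog_id)
                        if "catalog_id" in df.columns and pd.notna(row.catalog_id)
                        else None
                    ),
                )
            )
        except ValueError as exc:
            raise LibraryParseError(f"library row {i}: {exc}") from exc
    ids = [e.uniprot_id for e in entries]
    dupes = sorted({u for u in ids if ids.count(u) > 1})
    if dupes:
        raise LibraryParseError(f"duplicate uniprot_id in library: {dupes}")
    return entries


def write_library(entries: Iterable[SirnaLibraryEntry], path: str | Path) -> None:
    pd.DataFrame(
        [
            {
                "uniprot_id": e.uniprot_id,
                "gene_symbol": e.gene_symbol,
                "catalog_id": e.catalog_id or "",
                "source_plate": e.source_plate,
                "source_well": e.source_well,
            }
            for e in entries
        ]
    ).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Layout construction


def assign_wells(
    library: Sequence[SirnaLibraryEntry],
    replicates: int = 3,
    capacity: int = 75,
    controls: ControlSpec | None = None,
    seed: int = 0,
    conditions: Sequence[str] = DEFAULT_CONDITIONS,
) -> list[PlateSet]:
    """Partition the library into randomized plate-set layouts.

    Genes are split into ``ceil(N / capacity)`` sets in library order; within
    each set every gene receives ``replicates`` wells drawn uniformly at
    random without replacement from the wells left after control reservation.
    Control reagents (NT plus each control gene) are placed on every set,
    randomized by default. A fixed ``seed`` reproduces the layout exactly.
    """
    controls = controls or ControlSpec()
    controls.validate()
    if replicates < 1:
        raise ConfigurationError("replicates must be >= 1")
    if capacity < 1:
        raise ConfigurationError("capacity must be >= 1")
    needed = capacity * replicates + controls.total_wells
    if needed > N_WELLS:
        raise ConfigurationError(
            f"capacity {capacity} x {replicates} replicates + "
            f"{controls.total_wells} control wells = {needed} > {N_WELLS} wells"
        )
    if len(set(conditions)) != len(conditions):
        raise ConfigurationError("condition labels must be distinct")

    reserved_symbols = {controls.nt_gene, *controls.control_wells}
    candidates = [e for e in library if e.gene_symbol not in reserved_symbols]
    n_sets = max(1, math.ceil(len(candidates) / capacity)) if candidates else 1
    rng = np.random.default_rng(seed)
    wells = all_wells()

    plate_sets: list[PlateSet] = []
    for set_idx in range(n_sets):
        set_id = set_idx + 1
        barcode = f"SET{set_id}"
        genes = [
            e.gene_symbol
            for e in candidates[set_idx * capacity : (set_idx + 1) * capacity]
        ]

        assignments: list[WellAssignment] = []
        free = list(wells)
        if controls.fixed_positions is not None:
            fixed = controls.fixed_positions
            for rep, w in enumerate(fixed[controls.nt_gene], start=1):
                assignments.append(WellAssignment(barcode, w, "nt", None, rep))
            for gene in controls.control_wells:
                for rep, w in enumerate(fixed[gene], start=1):
                    assignments.append(WellAssignment(barcode, w, "control", gene, rep))
            used = {a.well for a in assignments}
            free = [w for w in wells if w not in used]
            n_random = len(genes) * replicates
        else:
            n_random = (
                controls.nt_wells
                + sum(controls.control_wells.values())
                + len(genes) * replicates
            )

        pick = rng.choice(len(free), size=n_random, replace=False)
        drawn = iter(free[i] for i in pick)
        if controls.fixed_positions is None:
            for rep in range(1, controls.nt_wells + 1):
                assignments.append(WellAssignment(barcode, next(drawn), "nt", None, rep))
            for gene, count in controls.control_wells.items():
                for rep in range(1, count + 1):
                    assignments.append(
                        WellAssignment(barcode, next(drawn), "control", gene, rep)
                    )
        for gene in genes:
            for rep in range(1, replicates + 1):
                assignments.append(
                    WellAssignment(barcode, next(drawn), "candidate", gene, rep)
                )

        used = {a.well for a in assignments}
        for w in wells:
            if w not in used:
                assignments.append(WellAssignment(barcode, w, "empty", None, 1))
        assignments.sort(key=lambda a: well_sort_key(a.well))

        plate_sets.append(
            PlateSet(
                set_id=set_id,
                layout=assignments,
                condition_plates={c: f"SET{set_id}_{c}" for c in conditions},
            )
        )
    return plate_sets


# ---------------------------------------------------------------------------
# Picklist


def generate_picklist(
    plate_sets: Sequence[PlateSet],
    library: Sequence[SirnaLibraryEntry],
    volume_nl: float = 100.0,
) -> list[PicklistRow]:
    """Emit one transfer per non-empty well per condition-replica plate.

    Rows are ordered by (source plate, source well) so that each source plate
    is visited in a single contiguous block — the siRNA stocks are thawed
    once per plate.
    """
    by_symbol: dict[str, SirnaLibraryEntry] = {}
    for e in library:
        by_symbol.setdefault(e.gene_symbol, e)

    rows: list[PicklistRow] = []
    for ps in plate_sets:
        for condition, dest_plate in ps.condition_plates.items():
            for a in ps.non_empty():
                symbol = a.gene_symbol if a.gene_symbol is not None else NT_GENE
                entry = by_symbol.get(symbol)
                if entry is None:
                    raise LibraryLookupError(
                        f"gene {symbol!r} (set {ps.set_id}, well {a.well}) "
                        "not found in library"
                    )
                rows.append(
                    PicklistRow(
                        source_plate=entry.source_plate,
                        source_well=entry.source_well,
                        destination_plate=dest_plate,
                        destination_well=a.well,
                        volume_nl=volume_nl,
                    )
                )
    rows.sort(key=lambda r: (r.source_plate, well_sort_key(r.source_well)))
    return rows


# ---------------------------------------------------------------------------
# Validation


@dataclass
class ValidationReport:
    violations: list[str] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.violations


def validate_layout(
    plate_sets: Sequence[PlateSet],
    replicates: int = 3,
    controls: ControlSpec | None = None,
) -> ValidationReport:
    """Check a layout for replicate completeness, well reuse, missing control
    roles and genes split across sets. Empty report iff the layout is valid."""
    controls = controls or ControlSpec()
    report = ValidationReport()
    gene_sets: dict[str, set[int]] = {}
    for ps in plate_sets:
        seen_wells: dict[str, int] = {}
        per_gene: dict[str, int] = {}
        nt_count = 0
        control_counts: dict[str, int] = {}
        for a in ps.layout:
            try:
                parse_well(a.well)
            except ValueError:
                report.violations.append(f"set {ps.set_id}: bad well label {a.well!r}")
            seen_wells[a.well] = seen_wells.get(a.well, 0) + 1
            if a.role == "candidate":
                assert a.gene_symbol is not None
                per_gene[a.gene_symbol] = per_gene.get(a.gene_symbol, 0) + 1
                gene_sets.setdefault(a.gene_symbol, set()).add(ps.set_id)
            elif a.role == "nt":
                nt_count += 1
            elif a.role == "control":
                assert a.gene_symbol is not None
                control_counts[a.gene_symbol] = control_counts.get(a.gene_symbol, 0) + 1
        for w, n in seen_wells.items():
            if n > 1:
                report.violations.append(
                    f"set {ps.set_id}: duplicate well {w} used {n} times"
                )
        for gene, n in per_gene.items():
            if n != replicates:
                report.violations.append(
                    f"set {ps.set_id}: incomplete replicates for {gene} "
                    f"({n} of {replicates})"
                )
        if nt_count < controls.nt_wells:
            report.violations.append(
                f"set {ps.set_id}: missing NT wells ({nt_count} of {controls.nt_wells})"
            )
        for gene in controls.control_wells:
            if gene not in control_counts:
                report.violations.append(f"set {ps.set_id}: missing control {gene}")
        if len(ps.condition_plates) != len(set(ps.condition_plates.values())):
            report.violations.append(
                f"set {ps.set_id}: condition plate barcodes not distinct"
            )
    for gene, sets in gene_sets.items():
        if len(sets) > 1:
            report.violations.append(f"gene {gene} split across sets {sorted(sets)}")
    return report


# ---------------------------------------------------------------------------
# Tabular I/O


def layout_to_frame(plate_sets: Sequence[PlateSet]) -> pd.DataFrame:
    records = []
    for ps in plate_sets:
        for a in ps.layout:
            records.append(
                {
                    "set_id": ps.set_id,
                    "destination_plate": a.destination_plate,
                    "well": a.well,
                    "role": a.role,
                    "gene_symbol": a.gene_symbol if a.gene_symbol is not None else "",
                    "replicate_index": a.replicate_index,
                }
            )
    return pd.DataFrame.from_records(records)


def frame_to_plate_sets(
    df: pd.DataFrame, conditions: Sequence[str] = DEFAULT_CONDITIONS
) -> list[PlateSet]:
    plate_sets = []
    for set_id, grp in df.groupby("set_id", sort=True):
        layout = [
            WellAssignment(
                destination_plate=str(r.destination_plate),
                well=str(r.well),
                role=str(r.role),
                gene_symbol=(
                    str(r.gene_symbol)
                    if isinstance(r.gene_symbol, str) and r.gene_symbol
                    else None
                ),
                replicate_index=int(r.replicate_index),
            )
            for r in grp.itertuples(index=False)
        ]
        plate_sets.append(
            PlateSet(
                set_id=int(set_id),
                layout=layout,
                condition_plates={c: f"SET{int(set_id)}_{c}" for c in conditions},
            )
        )
    return plate_sets


def write_layout(plate_sets: Sequence[PlateSet], path: str | Path) -> None:
    layout_to_frame(plate_sets).to_csv(path, index=False)


def read_layout(
    path: str | Path, conditions: Sequence[str] = DEFAULT_CONDITIONS
) -> list[PlateSet]:
    df = pd.read_csv(path, keep_default_na=False)
    return frame_to_plate_sets(df, conditions=conditions)


ECHO_HEADER = (
    "Source Plate Barcode",
    "Source Well",
    "Destination Plate Barcode",
    "Destination Well",
    "Transfer Volume",
)


def write_picklist(
    rows: Iterable[PicklistRow], path: str | Path, zero_pad: bool = False
) -> None:
    """Write a picklist in the ECHO Cherry Pick CSV dialect."""

    def fmt(label: str) -> str:
        return format_well(*parse_well(label), zero_pad=zero_pad)

    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(ECHO_HEADER)
        for r in rows:
            writer.writerow(
                [
                    r.source_plate,
                    fmt(r.source_well),
                    r.destination_plate,
                    fmt(r.destination_well),
                    f"{r.volume_nl:g}",
                ]
            )
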