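"""Readers and writers for every on-disk format the screening pipeline touches.

Colony-size tables use a gitter-style tab-delimited dialect: comment lines
start with ``#``, an optional header row names the columns, and data rows
carry ``row``, ``col``, ``size`` (in that order) plus optional trailing
columns such as circularity and a flag string.  Plate layouts and result
tables are plain TSV; genome annotation is GFF3 (1-based, inclusive); gene
lists are one systematic ID per line.

Conventions: plate rows count from the top, columns from the left, both
1-based.  An absent colony is encoded as size 0, an empty size field, ``NA``,
or a missing line relative to the declared plate format.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger("sgascreen")

#: Sentinel gene ID for library positions that carry no strain.
EMPTY = "EMPTY"

#: Mask-reason codes, in the order the pipeline assigns them.
REASON_NONE = "none"
REASON_ABSENT = "absent"
REASON_SMALL = "small"
REASON_FLAGGED = "flagged"
REASON_LINKED = "linked"

_FLOAT_FMT = "%.6g"


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass(eq=False)
class PlateGrid:
    """One replicate plate of colony sizes on a fixed row x column grid.

    Parameters
    ----------
    plate_id : str
        Library plate identifier (shared across replicates and backgrounds).
    condition : str
        Growth condition, e.g. ``"untreated"`` or ``"CAP"``.
    background : str
        ``"query"`` (double mutant) or ``"control"`` (marker-only wild type).
    replicate : int
        Biological replicate number, 1-based.
    n_rows, n_cols : int
        Plate format, e.g. 32 x 48 (1536 density) or 16 x 24 (384 density).
    size : ndarray of float, shape (n_rows, n_cols)
        Colony areas in pixels; 0 marks an absent colony.
    mask : ndarray of bool
        True = excluded from all downstream computation.
    mask_reason : ndarray of str
        Per-position code: none | absent | small | flagged | linked.
        ``none`` iff the position is unmasked.
    """

    plate_id: str
    condition: str
    background: str
    replicate: int
    n_rows: int
    n_cols: int
    size: np.ndarray
    mask: np.ndarray
    mask_reason: np.ndarray

    def __post_init__(self) -> None:
        self.size = np.asarray(self.size, dtype=float)
        self.mask = np.asarray(self.mask, dtype=bool)
        self.mask_reason = np.asarray(self.mask_reason, dtype="<U8")
        shape = (self.n_rows, self.n_cols)
        if self.size.shape != shape or self.mask.shape != shape:
            raise ValueError(
                f"plate {self.plate_id}: array shape does not match declared "
                f"format {self.n_rows}x{self.n_cols}"
            )
        if self.replicate < 1:
            raise ValueError("replicate must be a positive integer")
        self.validate()

    def validate(self) -> None:
        """Check the structural invariants; raise ValueError on violation."""
        if np.any(self.size[~self.mask] <= 0):
            raise ValueError(
                f"plate {self.plate_id}: unmasked position with size <= 0"
            )
        reason_none = self.mask_reason == REASON_NONE
        if np.any(reason_none == self.mask):
            raise ValueError(
                f"plate {self.plate_id}: mask_reason inconsistent with mask"
            )

    @property
    def shape(self) -> tuple[int, int]:
        return (self.n_rows, self.n_cols)

    def unmasked_values(self) -> np.ndarray:
        """Sizes at unmasked positions, as a flat array."""
        return self.size[~self.mask]

    def n_unmasked(self) -> int:
        return int((~self.mask).sum())

    def copy(self) -> "PlateGrid":
        return replace(
            self,
            size=self.size.copy(),
            mask=self.mask.copy(),
            mask_reason=self.mask_reason.copy(),
        )

    def with_sizes(self, size: np.ndarray) -> "PlateGrid":
        """New grid with replaced sizes, same masks and metadata."""
        return replace(
            self, size=np.asarray(size, float), mask=self.mask.copy(),
            mask_reason=self.mask_reason.copy(),
        )


def make_grid(
    size: np.ndarray,
    *,
    plate_id: str = "P01",
    condition: str = "untreated",
    background: str = "control",
    replicate: int = 1,
    absent_value: float = 0.0,
) -> PlateGrid:
    """Build a PlateGrid from a size matrix, masking absent positions.

    Positions equal to ``absent_value`` (or NaN) are masked ``absent``.
    """
    size = np.asarray(size, dtype=float)
    absent = np.isnan(size) | (size == absent_value)
    reason = np.full(size.shape, REASON_NONE, dtype="<U8")
    reason[absent] = REASON_ABSENT
    clean = np.where(absent, 0.0, size)
    return PlateGrid(
        plate_id=plate_id,
        condition=condition,
        background=background,
        replicate=replicate,
        n_rows=size.shape[0],
        n_cols=size.shape[1],
        size=clean,
        mask=absent,
        mask_reason=reason,
    )


def grids_equal(a: PlateGrid, b: PlateGrid) -> bool:
    """Field-by-field equality of two plates (exact float comparison)."""
    return (
        a.plate_id == b.plate_id
        and a.condition == b.condition
        and a.background == b.background
        and a.replicate == b.replicate
        and a.shape == b.shape
        and np.array_equal(a.size, b.size)
        and np.array_equal(a.mask, b.mask)
        and np.array_equal(a.mask_reason, b.mask_reason)
    )


@dataclass
class LibraryLayout:
    """Mapping from (plate_id, row, col) to systematic gene ID.

    One gene may occupy multiple positions (replicate spots); positions with
    no strain carry the sentinel :data:`EMPTY`.
    """

    entries: dict[tuple[str, int, int], str] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.entries)

    def gene_at(self, plate_id: str, row: int, col: int) -> str | None:
        return self.entries.get((plate_id, row, col))

    def genes(self) -> set[str]:
        """All gene IDs in the layout (EMPTY excluded)."""
        return {g for g in self.entries.values() if g != EMPTY}

    def positions_of(self, gene_id: str) -> list[tuple[str, int, int]]:
        return sorted(k for k, v in self.entries.items() if v == gene_id)

    def plate_ids(self) -> list[str]:
        return sorted({p for p, _, _ in self.entries})


@dataclass
class GeneAnnotation:
    """Gene ID -> (chromosome, start, end), 1-based inclusive coordinates."""

    records: dict[str, tuple[str, int, int]] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.records)

    def __contains__(self, gene_id: str) -> bool:
        return gene_id in self.records

    def locus(self, gene_id: str) -> tuple[str, int, int]:
        return self.records[gene_id]


@dataclass
class ColonyDialect:
    """How to interpret a colony-size table.

    ``n_rows``/``n_cols`` declare the plate format; when None the format is
    inferred as max(row) x max(col).  ``flag_exclusions`` lists flag-column
    strings whose positions are masked with reason ``flagged`` (off by
    default).
    """

    n_rows: int | None = None
    n_cols: int | None = None
    flag_exclusions: tuple[str, ...] = ()


# ---------------------------------------------------------------------------
# Colony-size tables (gitter-style .dat)
# ---------------------------------------------------------------------------

_META_RE = re.compile(r"(\w+)=(\S+)")
_NA_TOKENS = {"", "NA", "NaN", "nan", "na"}


def read_colony_table(
    path: str | Path,
    dialect: ColonyDialect | None = None,
    **metadata,
) -> PlateGrid:
    """Parse a gitter-style colony-size table into a :class:`PlateGrid`.

    Comment lines (``#``) may carry ``key=value`` metadata (plate_id,
    condition, background, replicate, n_rows, n_cols) which explicit
    ``metadata`` keyword arguments override.  Positions with size 0, an
    empty field, or NA are masked ``absent``; positions whose flag column
    matches ``dialect.flag_exclusions`` are masked ``flagged``.  Missing
    positions relative to the declared format are filled as absent, with a
    warning count in the log.

    Raises
    ------
    ValueError
        On a duplicate (row, col) position or a non-numeric size field
        (reported with its line number).
    """
    path = Path(path)
    dialect = dialect or ColonyDialect()
    meta: dict[str, str] = {}
    cells: dict[tuple[int, int], tuple[float, str]] = {}

    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            if line.lstrip().startswith("#"):
                for m in _META_RE.finditer(line):
                    meta[m.group(1)] = m.group(2)
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}:{lineno}: expected >= 3 columns")
            # Tolerate a single header row naming the columns.
            if not _is_int(fields[0]):
                if cells:
                    raise ValueError(
                        f"{path}:{lineno}: non-numeric row field {fields[0]!r}"
                    )
                continue
            row, col = int(fields[0]), int(fields[1])
            if row < 1 or col < 1:
                raise ValueError(f"{path}:{lineno}: positions are 1-based")
            if (row, col) in cells:
                raise ValueError(f"{path}:{lineno}: duplicate position ({row},{col})")
            tok = fields[2].strip()
            if tok in _NA_TOKENS:
                size = 0.0
            else:
                try:
                    size = float(tok)
                except ValueError as exc:
                    raise ValueError(
                        f"{path}:{lineno}: non-numeric size {tok!r}"
                    ) from exc
            flag = fields[4].strip() if len(fields) > 4 else ""
            cells[(row, col)] = (size, flag)

    if not cells:
        raise ValueError(f"{path}: no data rows")

    n_rows = _pick_int(metadata, meta, "n_rows", dialect.n_rows)
    n_cols = _pick_int(metadata, meta, "n_cols", dialect.n_cols)
    if n_rows is None:
        n_rows = max(r for r, _ in cells)
    if n_cols is None:
        n_cols = max(c for _, c in cells)

    size = np.zeros((n_rows, n_cols))
    mask = np.ones((n_rows, n_cols), dtype=bool)
    reason = np.full((n_rows, n_cols), REASON_ABSENT, dtype="<U8")
    n_missing = n_rows * n_cols - len(cells)
    for (r, c), (val, flag) in cells.items():
        if r > n_rows or c > n_cols:
            raise ValueError(
                f"{path}: position ({r},{c}) outside declared "
                f"{n_rows}x{n_cols} format"
            )
        if flag and flag in dialect.flag_exclusions:
            size[r - 1, c - 1] = val
            reason[r - 1, c - 1] = REASON_FLAGGED
        elif val > 0:
            size[r - 1, c - 1] = val
            mask[r - 1, c - 1] = False
            reason[r - 1, c - 1] = REASON_NONE
        # else: stays absent
    if n_missing > 0:
        logger.warning(
            "%s: %d positions missing from the declared %dx%d format, "
            "filled as absent", path.name, n_missing, n_rows, n_cols,
        )

    return PlateGrid(
        plate_id=str(metadata.get("plate_id", meta.get("plate_id", path.stem))),
        condition=str(metadata.get("condition", meta.get("condition", ""))),
        background=str(metadata.get("background", meta.get("background", ""))),
        replicate=int(metadata.get("replicate", meta.get("replicate", 1))),
        n_rows=n_rows,
        n_cols=n_cols,
        size=size,
        mask=mask,
        mask_reason=reason,
    )


def write_colony_table(grid: PlateGrid, path: str | Path) -> None:
    """Write a plate back to the gitter-style dialect.

    Metadata goes into ``#`` comment lines so a round trip through
    :func:`read_colony_table` recovers the plate.  Absent positions are
    written with size 0; positions masked ``flagged`` carry the literal
    token ``flagged`` in the flags column (re-read with a dialect listing
    it to restore the mask).
    """
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("# sgascreen colony table\n")
        fh.write(
            f"# plate_id={grid.plate_id} condition={grid.condition} "
            f"background={grid.background} replicate={grid.replicate} "
            f"n_rows={grid.n_rows} n_cols={grid.n_cols}\n"
        )
        fh.write("row\tcol\tsize\tcircularity\tflags\n")
        for r in range(grid.n_rows):
            for c in range(grid.n_cols):
                if grid.mask_reason[r, c] == REASON_ABSENT:
                    val = "0"
                else:
                    val = _FLOAT_FMT % grid.size[r, c]
                flag = "flagged" if grid.mask_reason[r, c] == REASON_FLAGGED else ""
                fh.write(f"{r + 1}\t{c + 1}\t{val}\t\t{flag}\n")


def _is_int(tok: str) -> bool:
    try:
        int(tok)
        return True
    except ValueError:
        return False


def _pick_int(kw: Mapping, meta: Mapping, key: str, fallback) -> int | None:
    for src in (kw, meta):
        if key in src:
            return int(src[key])
    return fallback


# ---------------------------------------------------------------------------
# Plate layouts
# ---------------------------------------------------------------------------

_LAYOUT_COLUMNS = ["plate_id", "row", "col", "gene_id"]


def read_layout(path: str | Path) -> LibraryLayout:
    """Read a TSV layout (columns plate_id, row, col, gene_id).

    Unknown columns are ignored with a warning; a missing required column or
    a duplicate position is a hard error.
    """
    df = pd.read_csv(path, sep="\t", dtype={"plate_id": str, "gene_id": str})
    missing = [c for c in _LAYOUT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: layout missing required columns {missing}")
    extra = [c for c in df.columns if c not in _LAYOUT_COLUMNS]
    if extra:
        logger.warning("%s: ignoring unknown layout columns %s", path, extra)
    entries: dict[tuple[str, int, int], str] = {}
    for plate, row, col, gene in df[_LAYOUT_COLUMNS].itertuples(index=False):
        row, col = int(row), int(col)
        if row < 1 or col < 1:
            raise ValueError(f"{path}: layout positions are 1-based")
        key = (str(plate), row, col)
        if key in entries:
            raise ValueError(f"{path}: duplicate layout position {key}")
        entries[key] = str(gene)
    return LibraryLayout(entries=entries)


def write_layout(layout: LibraryLayout, path: str | Path) -> None:
    rows = [
        {"plate_id": p, "row": r, "col": c, "gene_id": g}
        for (p, r, c), g in sorted(layout.entries.items())
    ]
    pd.DataFrame(rows, columns=_LAYOUT_COLUMNS).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Genome annotation (GFF3)
# ---------------------------------------------------------------------------


def read_gff3(path: str | Path, feature_type: str = "gene") -> GeneAnnotation:
    """Read gene intervals from a GFF3 file.

    One record per feature of ``feature_type``; the gene ID is taken from
    the ``ID=`` attribute.  Coordinates are 1-based inclusive; strand is
    ignored (linkage distance is strand-agnostic).
    """
    path = Path(path)
    records: dict[str, tuple[str, int, int]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise ValueError(f"{path}:{lineno}: expected 9 GFF3 columns")
            seqid, _source, ftype, start, end, _score, _strand, _phase, attrs = fields
            if ftype != feature_type:
                continue
            start_i, end_i = int(start), int(end)
            if start_i > end_i:
                raise ValueError(f"{path}:{lineno}: start > end")
            gene_id = None
            for item in attrs.split(";"):
                if item.startswith("ID="):
                    gene_id = item[3:]
                    break
            if gene_id is None:
                raise ValueError(f"{path}:{lineno}: feature without ID= attribute")
            if gene_id in records:
                raise ValueError(f"{path}:{lineno}: duplicate gene ID {gene_id!r}")
            records[gene_id] = (seqid, start_i, end_i)
    if not records:
        logger.warning("%s: no %r features found", path, feature_type)
    return GeneAnnotation(records=records)


def write_gff3(annotation: GeneAnnotation, path: str | Path,
               feature_type: str = "gene") -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for gene_id, (chrom, start, end) in sorted(annotation.records.items()):
            fh.write(
                f"{chrom}\t.\t{feature_type}\t{start}\t{end}\t.\t+\t.\tID={gene_id}\n"
            )


# ---------------------------------------------------------------------------
# Gene lists
# ---------------------------------------------------------------------------


def read_gene_list(path: str | Path) -> list[str]:
    """One gene ID per line; '#' comments and blank lines skipped."""
    out: list[str] = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if line and not line.startswith("#"):
                out.append(line)
    return out


def write_gene_list(genes: Iterable[str], path: str | Path) -> None:
    with open(path, "w") as fh:
        for g in genes:
            fh.write(f"{g}\n")


# ---------------------------------------------------------------------------
# Interaction result tables
# ---------------------------------------------------------------------------

_RESULT_COLUMNS = [
    "gene_id", "condition", "gis", "p_value", "n_query_reps",
    "n_control_reps", "excluded", "exclusion_reason", "hit_class",
]


def write_interaction_table(records: Sequence, path: str | Path) -> None:
    """Write interaction records as TSV, gene_id ascending, floats at 6
    significant digits.  An empty record list yields a header-only file."""
    rows = []
    for rec in sorted(records, key=lambda r: (r.gene_id, r.condition)):
        rows.append({
            "gene_id": rec.gene_id,
            "condition": rec.condition,
            "gis": "" if rec.gis is None else _FLOAT_FMT % rec.gis,
            "p_value": "" if rec.p_value is None else _FLOAT_FMT % rec.p_value,
            "n_query_reps": rec.n_query_reps,
            "n_control_reps": rec.n_control_reps,
            "excluded": rec.excluded,
            "exclusion_reason": rec.exclusion_reason,
            "hit_class": rec.hit_class,
        })
    df = pd.DataFrame(rows, columns=_RESULT_COLUMNS)
    df.to_csv(path, sep="\t", index=False)


def read_interaction_table(path: str | Path) -> list:
    """Read back a table written by :func:`write_interaction_table`."""
    from .interaction import InteractionRecord  # local import: avoid cycle

    df = pd.read_csv(path, sep="\t", dtype={"gene_id": str, "condition": str})
    records = []
    for row in df.itertuples(index=False):
        records.append(InteractionRecord(
            gene_id=row.gene_id,
            condition=row.condition,
            gis=None if pd.isna(row.gis) else float(row.gis),
            p_value=None if pd.isna(row.p_value) else float(row.p_value),
            n_query_reps=int(row.n_query_reps),
            n_control_reps=int(row.n_control_reps),
            excluded=bool(row.excluded),
            exclusion_reason=str(row.exclusion_reason),
            hit_class=str(row.hit_class),
        ))
    return records
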