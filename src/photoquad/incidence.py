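"""Quadrat incidence data model, validation, I/O and taxon-rule application.

The universal input of the toolkit is a grid of contiguous photoquadrats
covering a rectangular plot, scored for presence/absence of sessile
macrobenthic taxa.  Each quadrat carries integer grid coordinates
(0-based, row-major within the plot) and an acquisition index recording
the order in which the quadrats were photographed; spatially explicit
species-area curves depend on that order, so it is stored explicitly
rather than inferred.

The canonical on-disk format is a wide CSV: reserved columns
``index,row,col`` followed by one 0/1 column per taxon.  Plot-level
metadata (plot id, site, region, assemblage, quadrat edge length) lives
in a key/value sidecar CSV or is supplied by the caller.  A long
(quadrat, taxon) reader is provided for convenience and converted on
read.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

RESERVED_COLUMNS = ("index", "row", "col")
METADATA_FIELDS = ("plot_id", "site", "region", "assemblage", "side_cm")


class ValidationError(ValueError):
    """Raised when incidence data violate the domain contract."""


def _as_binary(values: np.ndarray, context: str) -> np.ndarray:
    arr = np.asarray(values)
    if arr.dtype == object or arr.dtype.kind == "f":
        if np.any(pd.isna(arr)):
            raise ValidationError(f"{context}: missing (NaN) incidence cell")
    arr = arr.astype(float)
    if not np.all(np.isin(arr, (0.0, 1.0))):
        bad = np.argwhere(~np.isin(arr, (0.0, 1.0)))
        r, c = bad[0]
        raise ValidationError(
            f"{context}: non-binary cell value {arr[r, c]!r} at data row {r}, column {c}"
        )
    return arr.astype(np.uint8)


@dataclass(frozen=True)
class TaxonRules:
    """Grouping map and seasonal-exclusion list for taxa.

    ``groups`` maps a group label to the set of member taxa that are
    pooled into one column (visually similar taxa that cannot be told
    apart reliably on photographs).  ``exclusions`` lists taxa dropped
    from analysis (markedly seasonal taxa whose presence depends on the
    time of sampling).
    """

    groups: Mapping[str, frozenset[str]] = field(default_factory=dict)
    exclusions: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        groups = {k: frozenset(v) for k, v in dict(self.groups).items()}
        object.__setattr__(self, "groups", groups)
        object.__setattr__(self, "exclusions", frozenset(self.exclusions))
        seen: dict[str, str] = {}
        for label, members in groups.items():
            for taxon in members:
                if taxon in seen:
                    raise ValidationError(
                        f"taxon {taxon!r} appears in groups {seen[taxon]!r} and {label!r}"
                    )
                seen[taxon] = label
        overlap = self.exclusions & set(seen)
        if overlap:
            raise ValidationError(
                f"excluded taxa may not also be group members: {sorted(overlap)}"
            )

    @classmethod
    def from_files(
        cls,
        groups_csv: str | Path | None = None,
        exclusions_file: str | Path | None = None,
    ) -> "TaxonRules":
        """Read rules from a two-column ``taxon,group`` CSV and a one-taxon-per-line list."""
        groups: dict[str, set[str]] = {}
        if groups_csv is not None:
            table = pd.read_csv(groups_csv)
            cols = [c.strip().lower() for c in table.columns]
            if cols[:2] != ["taxon", "group"]:
                raise ValidationError(
                    f"group table must have columns 'taxon,group', got {list(table.columns)}"
                )
            for taxon, label in zip(table.iloc[:, 0], table.iloc[:, 1]):
                groups.setdefault(str(label), set()).add(str(taxon))
        exclusions: set[str] = set()
        if exclusions_file is not None:
            text = Path(exclusions_file).read_text()
            exclusions = {line.strip() for line in text.splitlines() if line.strip()}
        return cls(groups={k: frozenset(v) for k, v in groups.items()}, exclusions=frozenset(exclusions))

    @classmethod
    def from_config(cls, mapping: Mapping) -> "TaxonRules":
        """Build rules from one structured config block (``groups``/``exclusions`` keys)."""
        groups = {str(k): frozenset(map(str, v)) for k, v in dict(mapping.get("groups", {})).items()}
        exclusions = frozenset(map(str, mapping.get("exclusions", ())))
        return cls(groups=groups, exclusions=exclusions)


@dataclass
class IncidenceGrid:
    """Ordered binary quadrat-by-taxon matrix with coordinates and survey metadata.

    Rows of ``incidence`` follow acquisition order: row ``i`` is the
    ``i``-th quadrat photographed.  ``row``/``col`` give the grid
    position of each quadrat; ``side_cm`` is the quadrat edge length
    (25 cm and 20 cm are the sizes used for the two gorgonian
    assemblages this toolkit was designed around).
    """

    incidence: np.ndarray
    taxa: tuple[str, ...]
    row: np.ndarray
    col: np.ndarray
    side_cm: float
    plot_id: str = ""
    site: str = ""
    region: str = ""
    assemblage: str = ""

    def __post_init__(self) -> None:
        self.incidence = _as_binary(np.atleast_2d(self.incidence), f"plot {self.plot_id or '?'}")
        self.taxa = tuple(str(t) for t in self.taxa)
        self.row = np.asarray(self.row, dtype=int)
        self.col = np.asarray(self.col, dtype=int)
        n, s = self.incidence.shape
        if s != len(self.taxa):
            raise ValidationError(
                f"incidence has {s} columns but {len(self.taxa)} taxon names"
            )
        if len(set(self.taxa)) != len(self.taxa):
            raise ValidationError("duplicate taxon names")
        if self.row.shape != (n,) or self.col.shape != (n,):
            raise ValidationError("row/col coordinate arrays must match quadrat count")
        if self.side_cm <= 0:
            raise ValidationError(f"side_cm must be positive, got {self.side_cm}")
        coords = list(zip(self.row.tolist(), self.col.tolist()))
        if len(set(coords)) != n:
            raise ValidationError("duplicate (row, col) quadrat coordinates")

    # -- basic geometry -------------------------------------------------
    @property
    def n_quadrats(self) -> int:
        return self.incidence.shape[0]

    @property
    def n_taxa(self) -> int:
        return self.incidence.shape[1]

    @property
    def quadrat_area_cm2(self) -> float:
        return float(self.side_cm) ** 2

    @property
    def n_rows(self) -> int:
        return int(self.row.max()) + 1 if self.n_quadrats else 0

    @property
    def n_cols(self) -> int:
        return int(self.col.max()) + 1 if self.n_quadrats else 0

    # -- views ----------------------------------------------------------
    def subset(self, indices: Sequence[int]) -> "IncidenceGrid":
        idx = np.asarray(indices, dtype=int)
        return replace(
            self,
            incidence=self.incidence[idx],
            row=self.row[idx],
            col=self.col[idx],
        )

    def to_frame(self) -> pd.DataFrame:
        frame = pd.DataFrame(self.incidence, columns=list(self.taxa))
        frame.insert(0, "col", self.col)
        frame.insert(0, "row", self.row)
        frame.insert(0, "index", np.arange(self.n_quadrats))
        return frame

    def metadata(self) -> dict:
        return {f: getattr(self, f) for f in METADATA_FIELDS}


def richness(grid: IncidenceGrid, indices: Sequence[int] | None = None) -> int:
    """Number of taxa present in the union of the selected quadrats.

    Monotone non-decreasing under supersets; the empty selection is a
    domain error rather than zero because an empty sample says nothing
    about the community.
    """
    if indices is None:
        indices = np.arange(grid.n_quadrats)
    idx = np.asarray(indices, dtype=int)
    if idx.size == 0:
        raise ValidationError("richness of an empty quadrat set is undefined")
    return int(grid.incidence[idx].any(axis=0).sum())


def apply_taxon_rules(grid: IncidenceGrid, rules: TaxonRules, strict: bool = True) -> IncidenceGrid:
    """Pool grouped taxa (logical OR) and drop excluded taxa.

    The grouped column takes the position of the group's first member in
    the original taxon order; quadrat order and count never change.
    With ``strict`` (default) any rule naming a taxon absent from the
    grid is an error — silent fuzzy matching hides data errors.
    """
    known = set(grid.taxa)
    named = set().union(*rules.groups.values()) | set(rules.exclusions) if (rules.groups or rules.exclusions) else set()
    unknown = named - known
    if unknown and strict:
        raise ValidationError(f"rules name taxa absent from grid: {sorted(unknown)}")

    member_of: dict[str, str] = {}
    for label, members in rules.groups.items():
        for taxon in members:
            member_of[taxon] = label

    new_taxa: list[str] = []
    columns: list[np.ndarray] = []
    done_groups: set[str] = set()
    for j, taxon in enumerate(grid.taxa):
        if taxon in rules.exclusions:
            continue
        label = member_of.get(taxon)
        if label is None:
            new_taxa.append(taxon)
            columns.append(grid.incidence[:, j])
        elif label not in done_groups:
            member_cols = [k for k, t in enumerate(grid.taxa) if member_of.get(t) == label]
            new_taxa.append(label)
            columns.append(grid.incidence[:, member_cols].max(axis=1))
            done_groups.add(label)
    if not new_taxa:
        raise ValidationError("rules removed every taxon")
    return replace(grid, incidence=np.column_stack(columns), taxa=tuple(new_taxa))


def boustrophedon_order(row: np.ndarray, col: np.ndarray) -> np.ndarray:
    """Serpentine acquisition order over the grid: even rows left-to-right, odd rows right-to-left."""
    row = np.asarray(row)
    col = np.asarray(col)
    key = np.where(row % 2 == 0, col, -col)
    return np.lexsort((key, row))


def read_incidence(
    path: str | Path,
    metadata: Mapping | None = None,
    sidecar: str | Path | None = None,
) -> IncidenceGrid:
    """Read a wide-CSV incidence table into a validated :class:`IncidenceGrid`.

    An ``index`` column, when present, is the authoritative acquisition
    order; otherwise a boustrophedon path over (row, col) is assumed.
    Metadata comes from ``metadata`` and/or a key/value ``sidecar`` CSV
    (explicit ``metadata`` wins).
    """
    path = Path(path)
    table = pd.read_csv(path)
    if table.isna().any().any():
        bad = table.columns[table.isna().any()][0]
        raise ValidationError(f"{path.name}: ragged or missing values in column {bad!r}")
    cols = list(table.columns)
    if "row" not in cols or "col" not in cols:
        raise ValidationError(f"{path.name}: required columns 'row' and 'col' missing")
    taxa = [c for c in cols if c not in RESERVED_COLUMNS]
    if not taxa:
        raise ValidationError(f"{path.name}: no taxon columns found")

    if "index" in cols:
        order = table["index"].to_numpy()
        if sorted(order.tolist()) != list(range(len(table))):
            raise ValidationError(
                f"{path.name}: 'index' must be a permutation of 0..N-1 (duplicate or missing index)"
            )
        table = table.iloc[np.argsort(order)].reset_index(drop=True)
    else:
        order = boustrophedon_order(table["row"].to_numpy(), table["col"].to_numpy())
        table = table.iloc[order].reset_index(drop=True)

    meta: dict = {"plot_id": path.stem, "side_cm": 25.0}
    if sidecar is not None:
        meta.update(read_metadata_sidecar(sidecar))
    if metadata:
        meta.update(metadata)
    meta = {k: v for k, v in meta.items() if k in METADATA_FIELDS}
    meta["side_cm"] = float(meta["side_cm"])

    incidence = _as_binary(table[taxa].to_numpy(), path.name)
    return IncidenceGrid(
        incidence=incidence,
        taxa=tuple(taxa),
        row=table["row"].to_numpy(dtype=int),
        col=table["col"].to_numpy(dtype=int),
        **meta,
    )


def read_incidence_long(
    path: str | Path,
    metadata: Mapping | None = None,
    sidecar: str | Path | None = None,
) -> IncidenceGrid:
    """Read a long-format table (columns ``index,row,col,taxon``, one row per presence)."""
    path = Path(path)
    long = pd.read_csv(path)
    needed = {"index", "row", "col", "taxon"}
    if not needed.issubset(long.columns):
        raise ValidationError(f"{path.name}: long format needs columns {sorted(needed)}")
    quadrats = (
        long[["index", "row", "col"]].drop_duplicates().sort_values("index").reset_index(drop=True)
    )
    if quadrats["index"].duplicated().any():
        raise ValidationError(f"{path.name}: conflicting coordinates for one quadrat index")
    taxa = sorted(long["taxon"].astype(str).unique())
    wide = pd.DataFrame(0, index=quadrats["index"], columns=taxa)
    for q, t in zip(long["index"], long["taxon"]):
        wide.at[q, str(t)] = 1
    meta: dict = {"plot_id": path.stem, "side_cm": 25.0}
    if sidecar is not None:
        meta.update(read_metadata_sidecar(sidecar))
    if metadata:
        meta.update(metadata)
    meta = {k: v for k, v in meta.items() if k in METADATA_FIELDS}
    meta["side_cm"] = float(meta["side_cm"])
    return IncidenceGrid(
        incidence=_as_binary(wide.to_numpy(), path.name),
        taxa=tuple(taxa),
        row=quadrats["row"].to_numpy(dtype=int),
        col=quadrats["col"].to_numpy(dtype=int),
        **meta,
    )


def write_incidence(grid: IncidenceGrid, path: str | Path, sidecar: str | Path | None = None) -> None:
    """Write the wide CSV; optionally a key/value metadata sidecar alongside."""
    grid.to_frame().to_csv(path, index=False)
    if sidecar is not None:
        write_metadata_sidecar(grid.metadata(), sidecar)


def read_metadata_sidecar(path: str | Path) -> dict:
    meta: dict = {}
    with open(path, newline="") as handle:
        for rec in csv.reader(handle):
            if not rec or rec[0] == "key":
                continue
            meta[rec[0]] = rec[1]
    if "side_cm" in meta:
        meta["side_cm"] = float(meta["side_cm"])
    return meta


def write_metadata_sidecar(meta: Mapping, path: str | Path) -> None:
    with open(path, "w", newline="") as handle:
        writer = csv.writer(handle)
        writer.writerow(["key", "value"])
        for key, value in meta.items():
            writer.writerow([key, value])
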