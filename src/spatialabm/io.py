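"""Readers and writers for measured cell tables and simulation artifacts.

Measured data enter as a :class:`CellTable` — an id / (x, y) / type-label
record per cell, coordinates in µm — read either from a user-mapped CSV or
from an AnnData ``.h5ad`` container (per-cell label column in ``obs``,
coordinates in an ``obsm`` matrix). Model-facing output formats are a
minimal PhysiCell-style ``cells.csv`` (``x,y,z,type`` with z = 0 for this 2D
model), a long-format population time-series CSV, and per-snapshot agent
tables.
"""
from __future__ import annotations

import re
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .errors import FormatError, ParseError, ValidationError

#: Sentinel mapping target meaning "discard this measured label".
DROP = "DROP"

_TYPE_NAME_RE = re.compile(r"^[A-Za-z0-9_]+$")


@dataclass
class CellTable:
    """Measured cells: unique string ids, type labels, optional coordinates.

    Coordinates are table-level: either every record carries an (x, y) in µm
    or none does (``xy is None``).
    """

    cell_ids: np.ndarray  # shape (n,), str
    type_labels: np.ndarray  # shape (n,), str
    xy: Optional[np.ndarray] = None  # shape (n, 2), float µm, or None

    def __post_init__(self) -> None:
        self.cell_ids = np.asarray(self.cell_ids, dtype=object)
        self.type_labels = np.asarray(self.type_labels, dtype=object)
        if len(self.cell_ids) != len(self.type_labels):
            raise ValidationError("cell_ids and type_labels length mismatch")
        if len(np.unique(self.cell_ids)) != len(self.cell_ids):
            dup = pd.Series(self.cell_ids).loc[
                pd.Series(self.cell_ids).duplicated()
            ]
            raise ValidationError(f"duplicate cell ids: {sorted(set(dup))[:5]}")
        if self.xy is not None:
            self.xy = np.asarray(self.xy, dtype=float)
            if self.xy.shape != (len(self.cell_ids), 2):
                raise ValidationError(
                    f"coordinate array has shape {self.xy.shape}, expected "
                    f"({len(self.cell_ids)}, 2)"
                )
            if not np.all(np.isfinite(self.xy)):
                raise ValidationError("non-finite coordinates in cell table")

    def __len__(self) -> int:
        return len(self.cell_ids)

    @property
    def is_spatial(self) -> bool:
        return self.xy is not None

    def abundances(self) -> dict[str, int]:
        """Counts per type label."""
        labels, counts = np.unique(self.type_labels.astype(str), return_counts=True)
        return dict(zip(labels.tolist(), counts.tolist()))


@dataclass
class TypeMapping:
    """Measured label -> model type name (or :data:`DROP`).

    ``default`` applies to labels absent from ``entries``; leaving it None
    makes unmapped labels an error, the safe default.
    """

    entries: Mapping[str, str]
    default: Optional[str] = None

    def resolve(self, label: str) -> str:
        if label in self.entries:
            return self.entries[label]
        if self.default is not None:
            return self.default
        raise ValidationError(f"unmapped cell type label: {label!r}")


def read_cell_table_csv(
    path: str | Path, column_map: Mapping[str, str]
) -> CellTable:
    """Read a CellTable from CSV with user-supplied column names.

    ``column_map`` maps the roles ``id`` and ``type`` (required) and ``x``,
    ``y`` (optional, both or neither) to column names in the file.
    Coordinates are parsed as µm; the table is spatial iff both coordinate
    columns are mapped.
    """
    path = Path(path)
    for role in ("id", "type"):
        if role not in column_map:
            raise FormatError(f"column_map must map role {role!r}")
    has_x, has_y = "x" in column_map, "y" in column_map
    if has_x != has_y:
        raise FormatError("map both coordinate columns 'x' and 'y', or neither")

    df = pd.read_csv(path, dtype=str)
    for role in ("id", "type") + (("x", "y") if has_x else ()):
        col = column_map[role]
        if col not in df.columns:
            raise FormatError(
                f"mapped column {col!r} (role {role!r}) not in {path.name}; "
                f"available: {list(df.columns)}"
            )

    ids = df[column_map["id"]].to_numpy(dtype=object)
    labels = df[column_map["type"]].to_numpy(dtype=object)
    xy = None
    if has_x:
        coords = np.empty((len(df), 2), dtype=float)
        for k, role in enumerate(("x", "y")):
            parsed = pd.to_numeric(df[column_map[role]], errors="coerce")
            bad = parsed.isna() | ~np.isfinite(parsed.fillna(np.inf))
            if bad.any():
                row = int(np.flatnonzero(bad.to_numpy())[0])
                raise ParseError(
                    f"non-numeric coordinate in column "
                    f"{column_map[role]!r} at data row {row} of {path.name}: "
                    f"{df[column_map[role]].iloc[row]!r}"
                )
            coords[:, k] = parsed.to_numpy(dtype=float)
        xy = coords
    return CellTable(ids, labels, xy)


def read_cell_table_h5ad(
    path: str | Path, type_key: str, spatial_key: str = "spatial"
) -> CellTable:
    """Read a CellTable from an AnnData container.

    ``type_key`` names the per-cell annotation column holding type labels;
    ``spatial_key`` names the per-cell coordinate matrix (first two columns
    used as x, y in µm; "spatial" is the dominant convention). A container
    without that matrix yields a non-spatial table. Cell ids come from the
    per-cell index.
    """
    import anndata  # deferred: heavy import

    adata = anndata.read_h5ad(path)
    if type_key not in adata.obs.columns:
        raise KeyError(
            f"type_key {type_key!r} not found in per-cell annotations; "
            f"available keys: {list(adata.obs.columns)}"
        )
    ids = np.asarray(adata.obs_names, dtype=object)
    labels = adata.obs[type_key].astype(str).to_numpy(dtype=object)
    xy = None
    if spatial_key in adata.obsm:
        mat = np.asarray(adata.obsm[spatial_key], dtype=float)
        if mat.ndim != 2 or mat.shape[1] < 2:
            raise FormatError(
                f"spatial matrix {spatial_key!r} must have >= 2 columns, "
                f"got shape {mat.shape}"
            )
        xy = mat[:, :2].copy()
    return CellTable(ids, labels, xy)


def select_and_relabel(table: CellTable, mapping: TypeMapping) -> CellTable:
    """Apply a type mapping: drop DROP-mapped cells, rename the rest.

    Coordinates are carried through untouched; model type names are
    restricted to ``[A-Za-z0-9_]`` so downstream CSVs stay unambiguous.
    """
    resolved = np.array(
        [mapping.resolve(str(lbl)) for lbl in table.type_labels], dtype=object
    )
    keep = resolved != DROP
    new_labels = resolved[keep]
    for name in set(new_labels.tolist()):
        if not _TYPE_NAME_RE.match(name):
            raise ValidationError(
                f"model type name {name!r} not of the form [A-Za-z0-9_]+"
            )
    return CellTable(
        table.cell_ids[keep],
        new_labels,
        table.xy[keep] if table.xy is not None else None,
    )


def write_physicell_cells_csv(state, path: str | Path) -> None:
    """Write an initial state as a PhysiCell-style ``cells.csv``.

    Fixed dialect: header ``x,y,z,type``, comma separator, ``.`` decimal,
    z always 0 (2D model). Floats are printed with Python's shortest
    round-trip repr so a read-back reproduces positions exactly.
    """
    path = Path(path)
    lines = ["x,y,z,type"]
    for (x, y), t in zip(state.xy, state.types):
        lines.append(f"{float(x)!r},{float(y)!r},0,{t}")
    path.write_text("\n".join(lines) + "\n", encoding="utf-8")


def read_physicell_cells_csv(path: str | Path, domain=None):
    """Read a ``cells.csv`` back into an :class:`~spatialabm.initialize.InitialState`.

    ``domain`` defaults to the bounding box of the cells padded by 50 µm.
    """
    from .initialize import InitialState, _domain_from_points

    df = pd.read_csv(path, float_precision="round_trip")
    for col in ("x", "y", "type"):
        if col not in df.columns:
            raise FormatError(f"cells.csv missing column {col!r}")
    xy = df[["x", "y"]].to_numpy(dtype=float)
    types = df["type"].to_numpy(dtype=object)
    if domain is None:
        domain = _domain_from_points(xy, padding=50.0)
    return InitialState(xy=xy, types=types, domain=domain)


_TS_COLUMNS = [
    "time_min",
    "replicate",
    "cancer_count",
    "healthy_count",
    "tcell_count",
    "ongoing_attacks",
]

# Canonical model type names feeding the fixed time-series columns.
_TS_TYPE_FOR_COLUMN = {
    "cancer_count": "cancer",
    "healthy_count": "healthy",
    "tcell_count": "CD8",
}


def write_timeseries_csv(summaries: Sequence[pd.DataFrame], path: str | Path) -> None:
    """Write replicate summary series as one long-format CSV.

    Each summary is a trajectory's per-save-point table (``time_min``,
    ``count_<type>`` columns, ``ongoing_attacks``); all replicates must share
    the same time grid.
    """
    path = Path(path)
    if len(summaries) == 0:
        pd.DataFrame(columns=_TS_COLUMNS).to_csv(path, index=False)
        return
    grid = summaries[0]["time_min"].to_numpy()
    rows = []
    for rep, summary in enumerate(summaries):
        t = summary["time_min"].to_numpy()
        if len(t) != len(grid) or not np.array_equal(t, grid):
            raise ValidationError(
                f"replicate {rep} time grid differs from replicate 0"
            )
        out = pd.DataFrame({"time_min": t, "replicate": rep})
        for col, typ in _TS_TYPE_FOR_COLUMN.items():
            key = f"count_{typ}"
            out[col] = summary[key].to_numpy() if key in summary else 0
        out["ongoing_attacks"] = summary["ongoing_attacks"].to_numpy()
        rows.append(out)
    pd.concat(rows, ignore_index=True)[_TS_COLUMNS].to_csv(path, index=False)


def read_timeseries_csv(path: str | Path) -> pd.DataFrame:
    """Read back a long-format time-series CSV."""
    return pd.read_csv(path)


def write_snapshot_csv(snapshots, path: str | Path) -> None:
    """Write one or more snapshots as a tidy agent table.

    Columns: time, id, x, y, type, attack_state — attack_state holds the
    partner's agent id, or -1 for a free cell.
    """
    if not isinstance(snapshots, (list, tuple)):
        snapshots = [snapshots]
    frames = []
    for snap in snapshots:
        frames.append(
            pd.DataFrame(
                {
                    "time": snap.time,
                    "id": snap.ids,
                    "x": snap.xy[:, 0],
                    "y": snap.xy[:, 1],
                    "type": snap.types,
                    "attack_state": snap.partner,
                }
            )
        )
    cols = ["time", "id", "x", "y", "type", "attack_state"]
    if frames:
        pd.concat(frames, ignore_index=True)[cols].to_csv(path, index=False)
    else:
        pd.DataFrame(columns=cols).to_csv(path, index=False)
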