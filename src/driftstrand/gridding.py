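"""Quadrat gridding of drifter deployment and recovery logs.

Drifter release positions are grouped into square lat/lon quadrats
(0.01°-0.05° per side, roughly 1.1-5.6 km at these latitudes) so that each
quadrat j yields a binomial observation: N_j drifters deployed, m_j of them
later found stranded on the monitored shoreline.  Quadrats are plain
latitude/longitude boxes; no projection or geodesic correction is applied.

Cells are half-open, ``[lo, hi)`` on both axes, so a point exactly on a seam
belongs to the north/east cell and every point maps to exactly one quadrat.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

#: drifter codes that became illegible during drift are recorded with this id
UNREADABLE_ID = "unreadable"

MIN_CELL_DEG = 0.01
MAX_CELL_DEG = 0.05


@dataclass(frozen=True)
class QuadratGrid:
    """A square lat/lon grid anchored at (origin_lat, origin_lon).

    Parameters
    ----------
    cell_size_deg
        Side length of each quadrat in decimal degrees, within [0.01, 0.05].
    origin_lat, origin_lon
        South-west anchor of cell (0, 0).
    grouping_mode
        ``"deployment"`` groups a recovered drifter into the quadrat of its
        release position (the default); ``"retrieval"`` groups by recovery
        position and requires recovery coordinates.
    """

    cell_size_deg: float
    origin_lat: float = 0.0
    origin_lon: float = 0.0
    grouping_mode: str = "deployment"

    def __post_init__(self) -> None:
        if not (MIN_CELL_DEG <= self.cell_size_deg <= MAX_CELL_DEG):
            raise ValueError(
                f"cell_size_deg must lie in [{MIN_CELL_DEG}, {MAX_CELL_DEG}] "
                f"degrees, got {self.cell_size_deg}"
            )
        if self.grouping_mode not in ("deployment", "retrieval"):
            raise ValueError(f"unknown grouping_mode {self.grouping_mode!r}")
        if not (-90 <= self.origin_lat <= 90) or not (-180 <= self.origin_lon <= 180):
            raise ValueError("grid origin outside valid coordinate range")

    @classmethod
    def from_points(
        cls,
        lat: np.ndarray | pd.Series,
        lon: np.ndarray | pd.Series,
        cell_size_deg: float,
        grouping_mode: str = "deployment",
    ) -> "QuadratGrid":
        """Anchor the grid at the integer-degree corner south-west of the data."""
        lat = np.asarray(lat, dtype=float)
        lon = np.asarray(lon, dtype=float)
        if lat.size == 0:
            raise ValueError("cannot anchor a grid on an empty point set")
        return cls(
            cell_size_deg=cell_size_deg,
            origin_lat=math.floor(np.min(lat)),
            origin_lon=math.floor(np.min(lon)),
            grouping_mode=grouping_mode,
        )

    def with_cell_size(self, cell_size_deg: float) -> "QuadratGrid":
        return replace(self, cell_size_deg=cell_size_deg)

    def cell_bounds(self, row: int, col: int) -> tuple[float, float, float, float]:
        """(south, west, north, east) bounds of quadrat (row, col)."""
        s = self.origin_lat + row * self.cell_size_deg
        w = self.origin_lon + col * self.cell_size_deg
        return s, w, s + self.cell_size_deg, w + self.cell_size_deg

    def cell_center(self, row: int, col: int) -> tuple[float, float]:
        s, w, n, e = self.cell_bounds(row, col)
        return (s + n) / 2.0, (w + e) / 2.0


def assign_quadrat(lat, lon, grid: QuadratGrid):
    """Map coordinates to (row, col) quadrat indices.

    Accepts scalars or arrays.  Cells are half-open, so a point exactly on
    the shared edge of two cells belongs to the cell to the north/east.

    Raises
    ------
    ValueError
        If any coordinate is NaN or infinite; the message identifies the
        offending record positions.
    """
    lat_a = np.asarray(lat, dtype=float)
    lon_a = np.asarray(lon, dtype=float)
    bad = ~(np.isfinite(lat_a) & np.isfinite(lon_a))
    if np.any(bad):
        idx = np.flatnonzero(np.atleast_1d(bad))
        raise ValueError(
            f"non-finite coordinates at record positions {idx.tolist()[:10]}"
        )
    def _index(x: np.ndarray, origin: float) -> np.ndarray:
        frac = (x - origin) / grid.cell_size_deg
        # snap float round-off at cell seams so the half-open convention is
        # exact: a point computing to 0.999999999 of a cell sits on the seam
        # and belongs to the upper cell
        nearest = np.round(frac)
        snapped = np.where(np.abs(frac - nearest) < 1e-9 * np.maximum(1.0, np.abs(frac)),
                           nearest, np.floor(frac))
        return snapped.astype(int)

    row = _index(lat_a, grid.origin_lat)
    col = _index(lon_a, grid.origin_lon)
    if np.ndim(lat) == 0 and np.ndim(lon) == 0:
        return int(row), int(col)
    return row, col


def _readable(ids: pd.Series) -> pd.Series:
    return ids.astype(str).str.lower() != UNREADABLE_ID


def tabulate_counts(
    deployments: pd.DataFrame,
    recoveries: pd.DataFrame,
    grid: QuadratGrid,
) -> pd.DataFrame:
    """Tally quadrat-level binomial counts (N_j deployed, m_j stranded).

    Parameters
    ----------
    deployments
        One row per released drifter with columns ``drifter_id``, ``site_id``,
        ``release_date``, ``release_lat``, ``release_lon``.
    recoveries
        One row per drifter found stranded, columns ``drifter_id`` and
        ``recovery_date`` (``recovery_lat``/``recovery_lon`` required only in
        retrieval grouping mode).  Drifters whose code became illegible carry
        the id ``"unreadable"``; they are excluded from every m_j (their
        source quadrat is unknown) but counted in the trial-level
        ``retrieved_total`` attribute used for recovery-rate summaries.

    Returns
    -------
    DataFrame with one row per non-empty quadrat: ``row``, ``col``,
    ``center_lat``, ``center_lon``, ``N``, ``m``; sorted by (row, col).
    ``df.attrs`` carries ``deployed_total``, ``retrieved_total``,
    ``retrieved_readable`` and the grid parameters.
    """
    dep = deployments.copy()
    if dep["drifter_id"].duplicated().any():
        dups = dep.loc[dep["drifter_id"].duplicated(), "drifter_id"].unique()
        raise ValueError(f"duplicate drifter ids in deployments: {list(dups)[:10]}")

    rec = recoveries.copy()
    rec_readable = rec[_readable(rec["drifter_id"])]
    orphans = set(rec_readable["drifter_id"]) - set(dep["drifter_id"])
    if orphans:
        raise ValueError(
            f"recovery ids with no matching deployment: {sorted(orphans)[:20]}"
        )

    rows, cols = assign_quadrat(
        dep["release_lat"].to_numpy(), dep["release_lon"].to_numpy(), grid
    )
    dep["_row"], dep["_col"] = rows, cols

    stranded_ids = set(rec_readable["drifter_id"])
    dep["_stranded"] = dep["drifter_id"].isin(stranded_ids)

    if grid.grouping_mode == "deployment":
        grouped = dep.groupby(["_row", "_col"]).agg(
            N=("drifter_id", "size"), m=("_stranded", "sum")
        )
    else:
        # retrieval grouping: m_j counts recoveries whose stranding position
        # fell in the box; N_j still counts releases from the box.  m <= N is
        # not guaranteed in this mode and the hierarchical model does not
        # accept such tables.
        if rec_readable[["recovery_lat", "recovery_lon"]].isna().any().any():
            raise ValueError(
                "retrieval grouping requires recovery coordinates on every "
                "readable recovery"
            )
        rrow, rcol = assign_quadrat(
            rec_readable["recovery_lat"].to_numpy(),
            rec_readable["recovery_lon"].to_numpy(),
            grid,
        )
        m_tab = (
            pd.DataFrame({"_row": rrow, "_col": rcol})
            .groupby(["_row", "_col"])
            .size()
            .rename("m")
        )
        n_tab = dep.groupby(["_row", "_col"]).size().rename("N")
        grouped = pd.concat([n_tab, m_tab], axis=1).fillna(0).astype(int)

    out = grouped.reset_index().rename(columns={"_row": "row", "_col": "col"})
    centers = [grid.cell_center(r, c) for r, c in zip(out["row"], out["col"])]
    out["center_lat"] = [c[0] for c in centers]
    out["center_lon"] = [c[1] for c in centers]
    out = out[["row", "col", "center_lat", "center_lon", "N", "m"]]
    out = out.sort_values(["row", "col"]).reset_index(drop=True)
    out["N"] = out["N"].astype(int)
    out["m"] = out["m"].astype(int)

    out.attrs["deployed_total"] = int(len(dep))
    out.attrs["retrieved_total"] = int(len(rec))
    out.attrs["retrieved_readable"] = int(len(rec_readable))
    out.attrs["cell_size_deg"] = grid.cell_size_deg
    out.attrs["origin_lat"] = grid.origin_lat
    out.attrs["origin_lon"] = grid.origin_lon
    out.attrs["grouping_mode"] = grid.grouping_mode
    return out


@dataclass
class CellSizeSelection:
    """Outcome of the occupancy-driven cell-size search."""

    cell_size_deg: float
    satisfied: bool
    occupancy: pd.DataFrame = field(repr=False)


def choose_cell_size(
    deployments: pd.DataFrame,
    recoveries: pd.DataFrame,
    candidate_sizes: list[float],
    min_per_quadrat: int,
    grouping_mode: str = "deployment",
) -> CellSizeSelection:
    """Pick the smallest cell size giving enough deployments per quadrat.

    Mirrors the field practice of growing the quadrat until every occupied
    cell holds at least ``min_per_quadrat`` releases.  Returns the smallest
    satisfying candidate; if none satisfies the rule, the largest candidate
    is returned with ``satisfied=False``.  The per-candidate occupancy table
    (number of quadrats, min/median N) is always attached.
    """
    if not candidate_sizes:
        raise ValueError("candidate_sizes is empty")
    for s in candidate_sizes:
        if not (MIN_CELL_DEG <= s <= MAX_CELL_DEG):
            raise ValueError(f"candidate size {s} outside [{MIN_CELL_DEG}, {MAX_CELL_DEG}]")

    rows = []
    chosen = None
    for s in sorted(candidate_sizes):
        grid = QuadratGrid.from_points(
            deployments["release_lat"],
            deployments["release_lon"],
            s,
            grouping_mode=grouping_mode,
        )
        counts = tabulate_counts(deployments, recoveries, grid)
        min_n = int(counts["N"].min())
        ok = min_n >= min_per_quadrat
        rows.append(
            {
                "cell_size_deg": s,
                "n_quadrats": len(counts),
                "min_N": min_n,
                "median_N": float(counts["N"].median()),
                "satisfies": ok,
            }
        )
        if ok and chosen is None:
            chosen = s
    table = pd.DataFrame(rows)
    if chosen is None:
        return CellSizeSelection(max(candidate_sizes), False, table)
    return CellSizeSelection(chosen, True, table)


def counts_to_geojson(
    counts: pd.DataFrame,
    grid: QuadratGrid,
    extra: pd.DataFrame | None = None,
) -> dict:
    """Build a GeoJSON FeatureCollection of quadrat polygons.

    Each feature carries N and m; columns of ``extra`` (indexed like
    ``counts``, e.g. posterior mean p_j and CV) are merged into the
    properties.  Coordinates follow the GeoJSON (lon, lat) order.
    """
    features = []
    for i, rec in counts.iterrows():
        s, w, n, e = grid.cell_bounds(int(rec["row"]), int(rec["col"]))
        props = {"row": int(rec["row"]), "col": int(rec["col"]),
                 "N": int(rec["N"]), "m": int(rec["m"])}
        if extra is not None:
            for k, v in extra.loc[i].items():
                props[k] = None if pd.isna(v) else float(v)
        features.append(
            {
                "type": "Feature",
                "geometry": {
                    "type": "Polygon",
                    "coordinates": [[[w, s], [e, s], [e, n], [w, n], [w, s]]],
                },
                "properties": props,
            }
        )
    return {"type": "FeatureCollection", "features": features}


def write_geojson(obj: dict, path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=1)
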