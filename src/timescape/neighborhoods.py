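"""Inflammatory neighborhoods: disc unions around marker-combination anchors.

A neighborhood is anchored on cells positive for every marker of an
inflammatory combination (e.g. CD74 & MIF); any cell within radius R (µm) of
its nearest anchor belongs to the neighborhood (anchors trivially belong,
distance 0). Neighborhoods may overlap and a cell may hold several
memberships. Membership is computed per sample, never across cores.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .phenotyping import threshold_positive, default_thresholds

__all__ = [
    "NeighborhoodSpec",
    "DEFAULT_COMBOS",
    "default_specs",
    "anchor_cells",
    "assign_neighborhoods",
    "neighborhood_proportions",
    "celltype_within_neighborhood",
    "neighborhood_within_celltype",
]

#: The seven inflammatory marker combinations defining the default neighborhoods.
DEFAULT_COMBOS: dict[str, tuple[str, ...]] = {
    "CD74_CD44": ("CD74", "CD44"),
    "CD74_MIF": ("CD74", "MIF"),
    "MIF_CD44": ("MIF", "CD44"),
    "CD74_CD44_MIF": ("CD74", "CD44", "MIF"),
    "iNOS_mPGES": ("iNOS", "mPGES1"),
    "iNOS_mPGES_NT": ("iNOS", "mPGES1", "NT"),
    "iNOS_NT": ("iNOS", "NT"),
}


@dataclass(frozen=True)
class NeighborhoodSpec:
    """Name, anchor marker combination (all required positive), radius R in µm.

    The biologically motivated neighborhood scale is 20–80 µm; radii outside
    that span are allowed but warned against in the docs, not rejected.
    """

    name: str
    markers: tuple
    radius: float = 40.0

    def __post_init__(self) -> None:
        if len(self.markers) == 0:
            raise ValueError("anchor marker combination must be nonempty")
        if self.radius <= 0:
            raise ValueError("radius must be positive")


def default_specs(radius: float = 40.0) -> list[NeighborhoodSpec]:
    return [NeighborhoodSpec(name, markers, radius) for name, markers in DEFAULT_COMBOS.items()]


def anchor_cells(
    cells: pd.DataFrame, combo, thresholds: dict | None = None
) -> pd.Series:
    """Boolean mask of cells positive for every marker in the combination."""
    combo = tuple(combo)
    if len(combo) == 0:
        raise ValueError("anchor combination must be nonempty")
    if thresholds is None:
        thresholds = default_thresholds()
    mask = np.ones(len(cells), dtype=bool)
    for m in combo:
        if m not in cells.columns:
            raise KeyError(f"marker {m!r} has no intensity column")
        if m not in thresholds:
            raise KeyError(f"marker {m!r} has no threshold")
        mask &= threshold_positive(cells[m].to_numpy(), thresholds[m])
    return pd.Series(mask, index=cells.index, name="anchor")


def assign_neighborhoods(
    cells: pd.DataFrame,
    specs: list[NeighborhoodSpec] | None = None,
    thresholds: dict | None = None,
) -> pd.DataFrame:
    """Per-cell boolean membership for each neighborhood spec.

    A cell is a member iff the Euclidean distance to the nearest anchor of
    the spec, within the same sample, is <= R (closed bound). A spec with no
    anchors in a sample has no members there. Nearest-anchor distances use a
    k-d tree; tests validate against the all-pairs brute-force oracle.
    """
    if specs is None:
        specs = default_specs()
    if thresholds is None:
        thresholds = default_thresholds()
    names = [s.name for s in specs]
    if len(set(names)) != len(names):
        raise ValueError("neighborhood names must be unique")
    out = pd.DataFrame(False, index=cells.index, columns=names)
    anchors = {s.name: anchor_cells(cells, s.markers, thresholds) for s in specs}
    for _, sub in cells.groupby("sample_id", sort=False):
        xy = sub[["x_um", "y_um"]].to_numpy(dtype=float)
        for s in specs:
            a = anchors[s.name].loc[sub.index].to_numpy()
            if not a.any():
                continue
            tree = cKDTree(xy[a])
            d, _ = tree.query(xy, k=1)
            out.loc[sub.index[d <= s.radius], s.name] = True
    return out


def neighborhood_proportions(
    cells: pd.DataFrame, membership: pd.DataFrame
) -> pd.DataFrame:
    """Per-sample fraction of all cells belonging to each neighborhood."""
    joined = membership.reindex(cells.index)
    grouped = joined.groupby(cells["sample_id"], sort=True)
    out = grouped.mean()
    out.index.name = "sample_id"
    return out


def _type_mask(cells: pd.DataFrame, cell_type: str) -> pd.Series:
    col = f"is_{cell_type}"
    if col in cells.columns:
        return cells[col].astype(bool)
    return cells["phenotype"] == cell_type


def celltype_within_neighborhood(
    cells: pd.DataFrame,
    membership: pd.DataFrame,
    types: list[str] | None = None,
) -> pd.DataFrame:
    """Fraction of each cell type among the members of each neighborhood.

    Tidy output: one row per (sample_id, neighborhood) with one column per
    type, count(type & member) / count(member). Rows where a neighborhood has
    zero members in a sample are excluded (undefined denominator), echoing
    the zero-variance exclusion used downstream.
    """
    if types is None:
        from .phenotyping import CELL_TYPES

        types = CELL_TYPES
    rows = []
    for sid, sub in cells.groupby("sample_id", sort=True):
        mem = membership.reindex(sub.index)
        for nb in membership.columns:
            inside = mem[nb].to_numpy(dtype=bool)
            denom = int(inside.sum())
            if denom == 0:
                continue
            rec = {"sample_id": sid, "neighborhood": nb}
            for t in types:
                tmask = _type_mask(sub, t).to_numpy()
                rec[t] = int((tmask & inside).sum()) / denom
            rows.append(rec)
    return pd.DataFrame(rows)


def neighborhood_within_celltype(
    cells: pd.DataFrame,
    membership: pd.DataFrame,
    types: list[str] | None = None,
) -> pd.DataFrame:
    """Fraction of each cell type's population residing in each neighborhood.

    Tidy output: one row per (sample_id, cell type) with one column per
    neighborhood, count(type & member) / count(type). Rows where the type is
    absent from the sample are excluded.
    """
    if types is None:
        from .phenotyping import CELL_TYPES

        types = CELL_TYPES
    rows = []
    for sid, sub in cells.groupby("sample_id", sort=True):
        mem = membership.reindex(sub.index)
        for t in types:
            tmask = _type_mask(sub, t).to_numpy()
            denom = int(tmask.sum())
            if denom == 0:
                continue
            rec = {"sample_id": sid, "cell_type": t}
            for nb in membership.columns:
                inside = mem[nb].to_numpy(dtype=bool)
                rec[nb] = int((tmask & inside).sum()) / denom
            rows.append(rec)
    return pd.DataFrame(rows)
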