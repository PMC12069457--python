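"""Cross-type nearest-neighbor distance functions (G-cross) for planar cell patterns.

The G-cross function ``G_{i,j}(r)`` is the cumulative distribution of the
distance from a typical cell of type *i* to its nearest neighbor of type *j*.
For a homogeneous Poisson target process of intensity ``alpha_j`` (cells per
µm²) it has the closed form ``1 - exp(-alpha_j * pi * r**2)``, which serves as
the independence baseline: empirical curves above it indicate cross-type
attraction (clustering), curves below it dispersion.

Two estimators are provided:

* ``raw`` — the plain empirical CDF of nearest-neighbor distances. Slightly
  biased near the window boundary (a reference cell close to the edge sees a
  truncated disc), but always defined.
* ``border`` — the reduced-sample (border) correction: at each radius *r* the
  reference set is restricted to cells at least *r* from the window boundary,
  so nearest-neighbor distances are never censored by the window. Undefined
  (NaN) at radii where the restricted set is empty.

All distances and coordinates are in µm.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

__all__ = [
    "Window",
    "GCrossCurve",
    "EmptyTypeError",
    "gcross_theoretical",
    "gcross_empirical",
    "gcross_arrays",
    "gcross_at",
    "gcross_auc",
    "gcross_within_neighborhood",
    "gcross_feature_table",
    "default_radii",
]


@dataclass(frozen=True)
class Window:
    """Rectangular observation window, origin at the lower-left corner.

    Defaults to the 1 × 1 mm region-of-interest of a tissue-microarray core.
    """

    width: float = 1000.0
    height: float = 1000.0

    def __post_init__(self) -> None:
        if not (self.width > 0 and self.height > 0):
            raise ValueError("window dimensions must be positive")

    @property
    def area(self) -> float:
        return self.width * self.height

    def boundary_distance(self, x: np.ndarray, y: np.ndarray) -> np.ndarray:
        """Distance from each point to the nearest window edge."""
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        return np.minimum.reduce([x, y, self.width - x, self.height - y])

    def contains(self, x: np.ndarray, y: np.ndarray) -> np.ndarray:
        return (x >= 0) & (x <= self.width) & (y >= 0) & (y <= self.height)


class EmptyTypeError(ValueError):
    """Raised when a sample has no cells of a type required for a G-cross pair."""


def default_radii(r_max: float = 80.0, step: float = 1.0) -> np.ndarray:
    """Radius grid 0..r_max (µm), ascending, starting at 0."""
    return np.arange(0.0, r_max + 0.5 * step, step)


@dataclass
class GCrossCurve:
    """An estimated G-cross curve for one (reference, target) type pair.

    ``values`` may contain NaN for border-corrected radii where no reference
    cell is far enough from the boundary.
    """

    type_i: str
    type_j: str
    radii: np.ndarray
    values: np.ndarray
    correction: str
    n_i: int
    n_j: int
    alpha_j: float
    sample_id: object = None
    neighborhood: str | None = None

    def __post_init__(self) -> None:
        self.radii = np.asarray(self.radii, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.radii.shape != self.values.shape:
            raise ValueError("radii and values must have equal length")

    def at(self, r: float) -> float:
        return gcross_at(self, r)

    def auc(self, r_max: float | None = None) -> float:
        return gcross_auc(self, r_max)


def gcross_theoretical(alpha_j: float, r) -> np.ndarray | float:
    """Poisson-baseline G-cross: ``1 - exp(-alpha_j * pi * r**2)``.

    Parameters
    ----------
    alpha_j : intensity of the target type (cells per µm²), >= 0.
    r : radius or array of radii (µm), >= 0.
    """
    r = np.asarray(r, dtype=float)
    if alpha_j < 0:
        raise ValueError("alpha_j must be nonnegative")
    if np.any(r < 0):
        raise ValueError("radii must be nonnegative")
    out = 1.0 - np.exp(-alpha_j * np.pi * r**2)
    return float(out) if out.ndim == 0 else out


def _nearest_distances(
    xy_i: np.ndarray, xy_j: np.ndarray, same_type: bool
) -> np.ndarray:
    """Distance from each reference point to its nearest target point.

    When the reference and target sets are the same point set, the self-point
    is excluded from its own search.
    """
    tree = cKDTree(xy_j)
    if same_type:
        if len(xy_j) < 2:
            raise EmptyTypeError("need at least 2 points for same-type G-cross")
        d, _ = tree.query(xy_i, k=2)
        return d[:, 1]
    d, _ = tree.query(xy_i, k=1)
    return d


def gcross_arrays(
    xy_i: np.ndarray,
    xy_j: np.ndarray,
    radii: np.ndarray,
    window: Window,
    correction: str = "border",
    same_type: bool = False,
) -> np.ndarray:
    """Estimate Ĝ(r) on a radius grid from raw coordinate arrays.

    Fast array-level core used by :func:`gcross_empirical`, the cohort
    simulator and the acceptance checks. Coincident points (distance 0) count
    as satisfied at every r >= 0 (comparisons are ``<=``).
    """
    xy_i = np.asarray(xy_i, dtype=float)
    xy_j = np.asarray(xy_j, dtype=float)
    radii = np.asarray(radii, dtype=float)
    if correction not in ("raw", "border"):
        raise ValueError(f"unknown correction {correction!r}")
    if len(xy_i) == 0 or len(xy_j) == 0:
        raise EmptyTypeError("empty reference or target point set")
    nn = _nearest_distances(xy_i, xy_j, same_type)
    if correction == "raw":
        return (nn[:, None] <= radii[None, :]).mean(axis=0)
    bdist = window.boundary_distance(xy_i[:, 0], xy_i[:, 1])
    values = np.full(radii.shape, np.nan)
    hit = nn[:, None] <= radii[None, :]
    keep = bdist[:, None] >= radii[None, :]
    counts = keep.sum(axis=0)
    ok = counts > 0
    values[ok] = (hit & keep).sum(axis=0)[ok] / counts[ok]
    return values


def gcross_empirical(
    cells: pd.DataFrame,
    type_i: str,
    type_j: str,
    radii: np.ndarray | None = None,
    window: Window | None = None,
    correction: str = "border",
    *,
    sample_id=None,
    type_col: str = "phenotype",
    x_col: str = "x_um",
    y_col: str = "y_um",
) -> GCrossCurve:
    """Estimate the G-cross curve for one type pair within one sample.

    ``cells`` is a per-cell table; if ``sample_id`` is given the table is
    first restricted to that sample (a core/ROI) — spatial statistics are
    never computed across samples. ``type_i == type_j`` is allowed: the
    nearest *other* point of the same type is used.

    Raises
    ------
    EmptyTypeError
        If either type has no cells in the sample; callers treating many
        samples should catch this and exclude the sample for the pair.
    """
    if window is None:
        window = Window()
    if radii is None:
        radii = default_radii()
    if sample_id is not None:
        cells = cells[cells["sample_id"] == sample_id]
    same = type_i == type_j
    mask_i = cells[type_col] == type_i
    mask_j = cells[type_col] == type_j if not same else mask_i
    xy_i = cells.loc[mask_i, [x_col, y_col]].to_numpy(dtype=float)
    xy_j = cells.loc[mask_j, [x_col, y_col]].to_numpy(dtype=float)
    if len(xy_i) == 0 or len(xy_j) == 0 or (same and len(xy_j) < 2):
        raise EmptyTypeError(
            f"sample has {len(xy_i)} cells of {type_i!r} and {len(xy_j)} of {type_j!r}"
        )
    values = gcross_arrays(xy_i, xy_j, np.asarray(radii, float), window, correction, same)
    return GCrossCurve(
        type_i=type_i,
        type_j=type_j,
        radii=np.asarray(radii, float),
        values=values,
        correction=correction,
        n_i=len(xy_i),
        n_j=len(xy_j),
        alpha_j=len(xy_j) / window.area,
        sample_id=sample_id,
    )


def gcross_within_neighborhood(
    cells: pd.DataFrame,
    membership: pd.DataFrame,
    neighborhood: str,
    type_i: str,
    type_j: str,
    radii: np.ndarray | None = None,
    window: Window | None = None,
    correction: str = "border",
    *,
    sample_id=None,
    type_col: str = "phenotype",
) -> GCrossCurve:
    """G-cross with the reference set restricted to neighborhood members.

    Reference points are type-*i* cells belonging to the named inflammatory
    neighborhood; target points are *all* type-*j* cells in the sample. The
    restriction conditions the focal cell on residing in the neighborhood
    without truncating the target process.
    """
    if window is None:
        window = Window()
    if radii is None:
        radii = default_radii()
    member = membership[neighborhood].reindex(cells.index).fillna(False).astype(bool)
    if sample_id is not None:
        in_sample = cells["sample_id"] == sample_id
        cells = cells[in_sample]
        member = member[in_sample]
    same = type_i == type_j
    mask_i = (cells[type_col] == type_i) & member
    mask_j = cells[type_col] == type_j
    xy_i = cells.loc[mask_i, ["x_um", "y_um"]].to_numpy(dtype=float)
    xy_j = cells.loc[mask_j, ["x_um", "y_um"]].to_numpy(dtype=float)
    if len(xy_i) == 0 or len(xy_j) == 0 or (same and len(xy_j) < 2):
        raise EmptyTypeError(
            f"no {type_i!r} members of {neighborhood!r} or no {type_j!r} targets"
        )
    # same-type: self-exclusion applies only when the reference point is
    # itself in the target set, which holds here since targets are all type-j
    values = gcross_arrays(xy_i, xy_j, np.asarray(radii, float), window, correction, same)
    return GCrossCurve(
        type_i=type_i,
        type_j=type_j,
        radii=np.asarray(radii, float),
        values=values,
        correction=correction,
        n_i=len(xy_i),
        n_j=len(xy_j),
        alpha_j=len(xy_j) / window.area,
        sample_id=sample_id,
        neighborhood=neighborhood,
    )


def gcross_at(curve: GCrossCurve, r: float) -> float:
    """Evaluate a curve at radius r by linear interpolation (exact at grid points)."""
    valid = ~np.isnan(curve.values)
    radii, values = curve.radii[valid], curve.values[valid]
    if len(radii) == 0:
        raise ValueError("curve has no defined values")
    if r < radii[0] or r > radii[-1]:
        raise ValueError(f"r={r} outside defined grid [{radii[0]}, {radii[-1]}]")
    return float(np.interp(r, radii, values))


def gcross_auc(curve: GCrossCurve, r_max: float | None = None) -> float:
    """Trapezoidal area under Ĝ over [grid min, r_max] (µm units).

    Border-corrected NaN grid points are dropped and the trapezoid re-spanned
    across the gap. The value at ``r_max`` itself is obtained by linear
    interpolation when it falls between grid points.
    """
    valid = ~np.isnan(curve.values)
    radii, values = curve.radii[valid], curve.values[valid]
    if len(radii) == 0:
        raise ValueError("curve has no defined values to integrate")
    if r_max is None:
        r_max = float(radii[-1])
    if r_max > radii[-1] + 1e-9:
        raise ValueError(f"r_max={r_max} beyond defined grid maximum {radii[-1]}")
    keep = radii <= r_max
    rr, vv = radii[keep], values[keep]
    if rr[-1] < r_max:
        rr = np.append(rr, r_max)
        vv = np.append(vv, np.interp(r_max, radii, values))
    return float(np.trapezoid(vv, rr))


def gcross_feature_table(
    cells: pd.DataFrame,
    pairs: list[tuple[str, str]],
    radii_report=(20.0, 40.0, 60.0, 80.0),
    window: Window | None = None,
    correction: str = "border",
    *,
    type_col: str = "phenotype",
    radii: np.ndarray | None = None,
    membership: pd.DataFrame | None = None,
    neighborhoods: list[str] | None = None,
    auc_rmax: float | None = None,
) -> pd.DataFrame:
    """Per-sample scalar G-cross features: fixed-radius values and AUC.

    Returns a wide table indexed by (sample_id[, patient_id]) with one column
    per feature, named ``gcross_<i>_<j>_<r>`` and ``gcross_<i>_<j>_auc`` (with
    a ``<neighborhood>_`` prefix for within-neighborhood runs). Samples where
    a pair is undefined (a type absent) get NaN for that pair's features —
    mirroring the zero-variance exclusion philosophy; downstream fits drop
    them per-feature.
    """
    if window is None:
        window = Window()
    if radii is None:
        radii = default_radii(max(radii_report))
    rows: dict = {}
    has_patient = "patient_id" in cells.columns
    contexts: list[str | None] = [None]
    if neighborhoods:
        if membership is None:
            raise ValueError("membership table required for neighborhood-restricted features")
        contexts = list(neighborhoods)
    for sid, sub in cells.groupby("sample_id", sort=True):
        rec: dict = {}
        if has_patient:
            rec["patient_id"] = sub["patient_id"].iloc[0]
        for ctx in contexts:
            prefix = f"{ctx}_" if ctx is not None else ""
            for ti, tj in pairs:
                stem = f"{prefix}gcross_{ti}_{tj}"
                try:
                    if ctx is None:
                        curve = gcross_empirical(
                            sub, ti, tj, radii, window, correction, type_col=type_col
                        )
                    else:
                        curve = gcross_within_neighborhood(
                            sub, membership, ctx, ti, tj, radii, window,
                            correction, type_col=type_col,
                        )
                    for r in radii_report:
                        rec[f"{stem}_{r:g}"] = curve.at(r)
                    rec[f"{stem}_auc"] = curve.auc(auc_rmax)
                except (EmptyTypeError, ValueError):
                    for r in radii_report:
                        rec[f"{stem}_{r:g}"] = np.nan
                    rec[f"{stem}_auc"] = np.nan
        rows[sid] = rec
    out = pd.DataFrame.from_dict(rows, orient="index")
    out.index.name = "sample_id"
    return out
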