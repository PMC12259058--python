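"""Single-cell spatial neighborhood quantification.

The neighborhood of a focal cell is the set of cells whose centers lie
within a fixed radius (default 55 µm) of the focal cell's center,
Euclidean, boundary inclusive, self excluded.  Focal cells closer than the
radius to the ROI boundary are excluded from analysis because their
neighborhood is truncated by the image edge; excluded cells still count as
neighbors and as nearest-of-type targets of retained focal cells (the
truncation argument concerns the focal neighborhood only).

On top of the radius query the module computes, per focal cell:

* neighborhood composition — neighbor counts and fractions by phenotype;
* nearest-of-type distance — distance to the closest cell of a target
  phenotype (unbounded search by default; an optional policy restricts it
  to the neighborhood radius);
* mean k-nearest-of-type distance (default k = 10); focal cells with
  fewer than k available targets get a missing value rather than a
  partial mean, which would silently bias low;
* lipid-neighbor metrics — fraction of neighbors that are lipid-loaded
  macrophages, fraction of neighbor macrophages that are lipid-loaded,
  and distance to the closest lipid-loaded macrophage.

Neighbor queries use a k-d tree; unit tests hold every query to exact
agreement with an exhaustive O(n²) scan.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .errors import ConfigurationError, FrameError, StateError
from .tissue_io import ROIGeometry

BORDER_POLICIES = ("exclude_focal_within_radius", "none")
RADIUS_POLICIES = ("unbounded", "within_radius")


@dataclass
class NeighborhoodParams:
    """Tunable parameters of the neighborhood analysis.

    radius_um
        Maximum center-to-center distance for two cells to be neighbors
        (inclusive).  Default 55 µm.
    k
        Number of nearest target cells averaged by
        :func:`mean_k_nearest`.  Default 10.
    border_policy
        ``exclude_focal_within_radius`` (default) drops focal cells whose
        distance to the ROI boundary is below ``radius_um``; ``none``
        retains all focal cells.
    """

    radius_um: float = 55.0
    k: int = 10
    border_policy: str = "exclude_focal_within_radius"

    def __post_init__(self):
        if not self.radius_um > 0:
            raise ConfigurationError("radius_um must be > 0")
        if not (isinstance(self.k, (int, np.integer)) and self.k >= 1):
            raise ConfigurationError("k must be a positive integer")
        if self.border_policy not in BORDER_POLICIES:
            raise ConfigurationError(f"border_policy must be one of {BORDER_POLICIES}")


@dataclass
class PerFocalMetric:
    """A per-focal-cell metric with its group aggregate.

    per_focal
        pandas Series indexed by focal ``cell_id`` (NaN = missing).
    group_mean
        Mean over focal cells with a defined value (NaN if none).
    n_missing
        Number of focal cells with a missing value.
    """

    per_focal: pd.Series
    group_mean: float
    n_missing: int


def _require_single_frame(cells: pd.DataFrame) -> None:
    if "roi_id" in cells.columns:
        frames = cells["roi_id"].unique()
        if len(frames) > 1:
            raise FrameError(
                f"cells span {len(frames)} ROIs ({list(frames)[:5]}...); neighborhood "
                "operations require a single coordinate frame — analyze per ROI"
            )


def _positions(cells: pd.DataFrame) -> np.ndarray:
    return np.column_stack(
        [cells["x_um"].to_numpy(dtype=float), cells["y_um"].to_numpy(dtype=float)]
    )


def _require_phenotyped(cells: pd.DataFrame) -> None:
    if "phenotype" not in cells.columns:
        raise StateError("cells carry no phenotype column; run classify_cells first")


# ---------------------------------------------------------------------------
# Primitive queries
# ---------------------------------------------------------------------------

def all_pairs_within(cells: pd.DataFrame, radius_um: float) -> pd.DataFrame:
    """All neighbor pairs at or below ``radius_um`` (Euclidean, boundary inclusive).

    Returns a DataFrame with columns ``cell_i, cell_j, distance`` holding
    the symmetric relation: every unordered neighbor pair appears in both
    orientations; self-pairs are excluded.

    Raises :class:`FrameError` when cells from more than one ROI are mixed.
    """
    if len(cells) == 0:
        raise ConfigurationError("all_pairs_within requires at least one cell")
    if not radius_um > 0:
        raise ConfigurationError("radius_um must be > 0")
    _require_single_frame(cells)
    pos = _positions(cells)
    tree = cKDTree(pos)
    pairs = tree.query_pairs(r=radius_um, output_type="ndarray")
    ids = cells["cell_id"].to_numpy()
    if len(pairs) == 0:
        return pd.DataFrame({"cell_i": [], "cell_j": [], "distance": []})
    d = np.linalg.norm(pos[pairs[:, 0]] - pos[pairs[:, 1]], axis=1)
    return pd.DataFrame(
        {
            "cell_i": np.concatenate([ids[pairs[:, 0]], ids[pairs[:, 1]]]),
            "cell_j": np.concatenate([ids[pairs[:, 1]], ids[pairs[:, 0]]]),
            "distance": np.concatenate([d, d]),
        }
    )


def exclude_border_focal(
    cells: pd.DataFrame, roi: ROIGeometry, radius_um: float
) -> pd.DataFrame:
    """Focal subset with a full neighborhood: boundary distance >= ``radius_um``.

    On a W x H rectangle this retains exactly the cells in the inset
    rectangle ``[r, W-r] x [r, H-r]`` (boundary inclusive).  Excluded
    cells remain available as neighbors/targets of retained cells — the
    caller keeps the full table for that purpose.

    Emits a warning (not an error) and returns an empty subset when the
    ROI is smaller than ``2 * radius_um`` in either dimension.
    """
    if not radius_um > 0:
        raise ConfigurationError("radius_um must be > 0")
    xmin, ymin, xmax, ymax = roi.extent
    if (xmax - xmin) < 2 * radius_um or (ymax - ymin) < 2 * radius_um:
        warnings.warn(
            f"ROI {roi.roi_id!r} is smaller than 2*radius ({radius_um} um) in at "
            "least one dimension; no focal cell has a full neighborhood",
            stacklevel=2,
        )
    d = roi.signed_boundary_distance(
        cells["x_um"].to_numpy(dtype=float), cells["y_um"].to_numpy(dtype=float)
    )
    return cells[d >= radius_um]


def _focal_subset(
    cells: pd.DataFrame,
    focal_type: str | None,
    roi: ROIGeometry,
    params: NeighborhoodParams,
) -> pd.DataFrame:
    focal = cells
    if focal_type is not None:
        focal = focal[focal["phenotype"] == focal_type]
        if len(focal) == 0:
            warnings.warn(
                f"focal type {focal_type!r} absent from the data; empty result",
                stacklevel=3,
            )
    if params.border_policy == "exclude_focal_within_radius" and len(focal) > 0:
        focal = exclude_border_focal(focal, roi, params.radius_um)
    return focal


# ---------------------------------------------------------------------------
# Composition
# ---------------------------------------------------------------------------

def neighborhood_composition(
    cells: pd.DataFrame,
    focal_type: str,
    params: NeighborhoodParams,
    roi: ROIGeometry,
    *,
    labels: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Neighbor counts and fractions by phenotype, per retained focal cell.

    Returns a DataFrame indexed by focal ``cell_id`` with columns
    ``n_neighbors``, ``empty_neighborhood``, ``count_<label>`` and
    ``frac_<label>`` for every label in the universe (all observed
    phenotypes by default).  Fractions sum to 1 whenever
    ``n_neighbors > 0`` and are NaN for empty neighborhoods, which are
    flagged rather than dropped.
    """
    _require_single_frame(cells)
    _require_phenotyped(cells)
    if labels is None:
        labels = sorted(cells["phenotype"].unique())
    focal = _focal_subset(cells, focal_type, roi, params)
    pos_all = _positions(cells)
    tree = cKDTree(pos_all)
    phen = cells["phenotype"].to_numpy()
    label_idx = {lab: i for i, lab in enumerate(labels)}
    phen_codes = np.array([label_idx.get(p, -1) for p in phen])

    focal_pos = _positions(focal)
    focal_iloc = cells.index.get_indexer(focal.index)
    rows = []
    neighbor_lists = tree.query_ball_point(focal_pos, r=params.radius_um) if len(focal) else []
    for fi, neigh in zip(focal_iloc, neighbor_lists):
        neigh = [j for j in neigh if j != fi]
        counts = np.zeros(len(labels), dtype=int)
        for j in neigh:
            c = phen_codes[j]
            if c >= 0:
                counts[c] += 1
        total = len(neigh)
        row = {"n_neighbors": total, "empty_neighborhood": total == 0}
        for lab, c in zip(labels, counts):
            row[f"count_{lab}"] = int(c)
            row[f"frac_{lab}"] = c / total if total > 0 else np.nan
        rows.append(row)
    out = pd.DataFrame(rows, index=pd.Index(focal["cell_id"], name="cell_id"))
    if len(rows) == 0:
        cols = ["n_neighbors", "empty_neighborhood"]
        for lab in labels:
            cols += [f"count_{lab}", f"frac_{lab}"]
        out = pd.DataFrame(columns=cols, index=pd.Index([], name="cell_id"))
    return out


# ---------------------------------------------------------------------------
# Nearest-of-type distances
# ---------------------------------------------------------------------------

def _nearest_distances(
    cells: pd.DataFrame,
    focal: pd.DataFrame,
    target_mask: np.ndarray,
    k: int,
) -> np.ndarray:
    """Distances from each focal cell to its k nearest targets (self excluded).

    Returns an (n_focal, k) array padded with inf where fewer than k
    targets exist.
    """
    targets = cells[target_mask]
    n_focal = len(focal)
    out = np.full((n_focal, k), np.inf)
    if len(targets) == 0 or n_focal == 0:
        return out
    tree = cKDTree(_positions(targets))
    # query one extra neighbor so a focal cell that is itself a target can
    # drop its self-match (identified by cell id, not by zero distance —
    # distinct cells may share coordinates)
    kq = min(k + 1, len(targets))
    dist, idx = tree.query(_positions(focal), k=kq)
    if kq == 1:
        dist = dist[:, None]
        idx = idx[:, None]
    target_ids = targets["cell_id"].to_numpy()
    focal_ids = focal["cell_id"].to_numpy()
    for i in range(n_focal):
        ds = [
            dist[i, m]
            for m in range(kq)
            if np.isfinite(dist[i, m]) and target_ids[idx[i, m]] != focal_ids[i]
        ]
        out[i, : min(k, len(ds))] = ds[:k]
    return out


def nearest_of_type(
    cells: pd.DataFrame,
    focal_type: str,
    target_type: str,
    roi: ROIGeometry,
    *,
    radius_policy: str = "unbounded",
    params: NeighborhoodParams | None = None,
) -> PerFocalMetric:
    """Distance from each retained focal cell to the closest target-type cell.

    The focal cell itself is excluded even when it is of the target type.
    ``radius_policy='unbounded'`` (default) searches the whole ROI;
    ``'within_radius'`` reports a missing value when the nearest target
    lies beyond ``params.radius_um``.  When no target cells exist all
    distances are missing and the group mean is NaN.
    """
    if radius_policy not in RADIUS_POLICIES:
        raise ConfigurationError(f"radius_policy must be one of {RADIUS_POLICIES}")
    params = params or NeighborhoodParams()
    _require_single_frame(cells)
    _require_phenotyped(cells)
    focal = _focal_subset(cells, focal_type, roi, params)
    target_mask = (cells["phenotype"] == target_type).to_numpy()
    d = _nearest_distances(cells, focal, target_mask, k=1)[:, 0]
    if radius_policy == "within_radius":
        d = np.where(d <= params.radius_um, d, np.inf)
    vals = pd.Series(np.where(np.isfinite(d), d, np.nan), index=pd.Index(focal["cell_id"], name="cell_id"))
    n_missing = int(vals.isna().sum())
    mean = float(vals.mean()) if vals.notna().any() else float("nan")
    return PerFocalMetric(vals, mean, n_missing)


def mean_k_nearest(
    cells: pd.DataFrame,
    focal_type: str,
    target_type: str,
    k: int,
    roi: ROIGeometry,
    *,
    params: NeighborhoodParams | None = None,
) -> PerFocalMetric:
    """Mean distance from each retained focal cell to its k closest targets.

    With fewer than k available targets (self excluded) the value is
    missing and excluded from the group mean — a partial mean over fewer
    cells would be biased low.  ``k = 1`` coincides with
    :func:`nearest_of_type` under the unbounded policy.
    """
    if not (isinstance(k, (int, np.integer)) and k >= 1):
        raise ConfigurationError("k must be a positive integer")
    params = params or NeighborhoodParams()
    _require_single_frame(cells)
    _require_phenotyped(cells)
    focal = _focal_subset(cells, focal_type, roi, params)
    target_mask = (cells["phenotype"] == target_type).to_numpy()
    d = _nearest_distances(cells, focal, target_mask, k=k)
    complete = np.all(np.isfinite(d), axis=1)
    means = np.where(complete, d.mean(axis=1), np.nan)
    vals = pd.Series(means, index=pd.Index(focal["cell_id"], name="cell_id"))
    n_missing = int(vals.isna().sum())
    mean = float(vals.mean()) if vals.notna().any() else float("nan")
    return PerFocalMetric(vals, mean, n_missing)


# ---------------------------------------------------------------------------
# Lipid-neighbor metrics
# ---------------------------------------------------------------------------

@dataclass
class LipidNeighborhoodResult:
    """Output of :func:`lipid_neighborhood_metrics`.

    per_focal
        DataFrame indexed by focal ``cell_id`` with columns
        ``frac_neighbors_lipid_tam`` (lipid+ macrophage neighbors over all
        neighbors; NaN for empty neighborhoods),
        ``frac_tam_neighbors_lipid`` (lipid+ macrophage neighbors over
        macrophage neighbors; NaN when there are none) and
        ``nearest_lipid_tam`` (distance to the closest lipid+ macrophage).
    group_means
        Mapping metric name -> mean over focal cells with defined values.
    lipid_fraction_by_phenotype
        Series: fraction of all cells of each phenotype that are lipid+.
    """

    per_focal: pd.DataFrame
    group_means: dict[str, float]
    lipid_fraction_by_phenotype: pd.Series


def lipid_fraction_by_phenotype(cells: pd.DataFrame) -> pd.Series:
    """Fraction of cells of each phenotype flagged lipid-positive."""
    _require_phenotyped(cells)
    if "lipid_positive" not in cells.columns or cells["lipid_positive"].isna().any():
        raise StateError("lipid flags unset; run assign_lipid_flag first")
    return cells.groupby("phenotype")["lipid_positive"].mean()


def lipid_neighborhood_metrics(
    cells: pd.DataFrame,
    focal_type: str,
    tam_label: str,
    params: NeighborhoodParams,
    roi: ROIGeometry,
) -> LipidNeighborhoodResult:
    """Lipid-loaded-macrophage metrics around each retained focal cell.

    Requires both phenotype labels and lipid flags to be set.
    """
    _require_single_frame(cells)
    _require_phenotyped(cells)
    if "lipid_positive" not in cells.columns or cells["lipid_positive"].isna().any():
        raise StateError("lipid flags unset; run assign_lipid_flag first")

    focal = _focal_subset(cells, focal_type, roi, params)
    pos_all = _positions(cells)
    tree = cKDTree(pos_all)
    is_tam = (cells["phenotype"] == tam_label).to_numpy()
    is_lipid = cells["lipid_positive"].to_numpy(dtype=bool)
    is_lipid_tam = is_tam & is_lipid

    focal_iloc = cells.index.get_indexer(focal.index)
    neighbor_lists = (
        tree.query_ball_point(_positions(focal), r=params.radius_um) if len(focal) else []
    )
    m1 = np.full(len(focal), np.nan)
    m2 = np.full(len(focal), np.nan)
    for i, (fi, neigh) in enumerate(zip(focal_iloc, neighbor_lists)):
        neigh = np.array([j for j in neigh if j != fi], dtype=int)
        if len(neigh) == 0:
            continue
        n_lt = int(is_lipid_tam[neigh].sum())
        n_t = int(is_tam[neigh].sum())
        m1[i] = n_lt / len(neigh)
        if n_t > 0:
            m2[i] = n_lt / n_t
    d3 = _nearest_distances(cells, focal, is_lipid_tam, k=1)[:, 0]
    d3 = np.where(np.isfinite(d3), d3, np.nan)

    idx = pd.Index(focal["cell_id"], name="cell_id")
    per_focal = pd.DataFrame(
        {
            "frac_neighbors_lipid_tam": m1,
            "frac_tam_neighbors_lipid": m2,
            "nearest_lipid_tam": d3,
        },
        index=idx,
    )
    group_means = {
        c: (float(per_focal[c].mean()) if per_focal[c].notna().any() else float("nan"))
        for c in per_focal.columns
    }
    return LipidNeighborhoodResult(per_focal, group_means, lipid_fraction_by_phenotype(cells))


# ---------------------------------------------------------------------------
# Region tagging and per-ROI record assembly
# ---------------------------------------------------------------------------

def classify_points_by_region(
    cells: pd.DataFrame,
    regions: Sequence[ROIGeometry],
    *,
    margin_um: float = 0.0,
    background_class: str = "other",
    ambiguous_class: str = "boundary",
) -> pd.Series:
    """Tag each cell with the region class of the region it falls in.

    ``margin_um`` applies the border-exclusion logic at region boundaries:
    a cell is tagged with a region's class only when it lies at least
    ``margin_um`` inside it, and with ``background_class`` only when it is
    at least ``margin_um`` outside every region; cells in between get
    ``ambiguous_class``.  With the default margin of 0 every cell receives
    either a region class or the background class.
    """
    x = cells["x_um"].to_numpy(dtype=float)
    y = cells["y_um"].to_numpy(dtype=float)
    label = np.full(len(cells), background_class, dtype=object)
    min_outside = np.full(len(cells), np.inf)
    for reg in regions:
        d = reg.signed_boundary_distance(x, y)
        label = np.where(d >= margin_um, reg.region_class, label)
        min_outside = np.minimum(min_outside, -d)
    # not deep inside any region, and not far enough outside all of them
    ambiguous = (label == background_class) & (min_outside < margin_um)
    label[ambiguous] = ambiguous_class
    return pd.Series(label, index=cells.index, name="region_class")


def neighborhood_table(
    cells: pd.DataFrame,
    roi: ROIGeometry,
    *,
    focal_types: Sequence[str],
    target_types: Sequence[str],
    params: NeighborhoodParams | None = None,
    tam_label: str | None = None,
) -> pd.DataFrame:
    """Assemble per-focal-cell records for one ROI.

    For every focal cell of any type in ``focal_types`` (border-retained
    per ``params.border_policy``) the record carries the neighborhood
    composition, ``nearest_<target>`` and ``mean{k}nn_<target>`` for every
    target type, and — when ``tam_label`` is given and lipid flags are set
    — the lipid-neighbor metrics.  Output columns include ``cell_id``,
    ``roi_id`` and ``phenotype`` so records from many ROIs can be
    concatenated and summarized by region.
    """
    params = params or NeighborhoodParams()
    _require_single_frame(cells)
    _require_phenotyped(cells)
    blocks = []
    for ftype in focal_types:
        comp = neighborhood_composition(cells, ftype, params, roi)
        block = comp.reset_index()
        block.insert(1, "roi_id", roi.roi_id)
        block.insert(2, "phenotype", ftype)
        for ttype in target_types:
            nres = nearest_of_type(cells, ftype, ttype, roi, params=params)
            kres = mean_k_nearest(cells, ftype, ttype, params.k, roi, params=params)
            block[f"nearest_{ttype}"] = nres.per_focal.reindex(block["cell_id"]).to_numpy()
            block[f"mean{params.k}nn_{ttype}"] = kres.per_focal.reindex(block["cell_id"]).to_numpy()
        if tam_label is not None:
            lres = lipid_neighborhood_metrics(cells, ftype, tam_label, params, roi)
            for c in lres.per_focal.columns:
                block[c] = lres.per_focal[c].reindex(block["cell_id"]).to_numpy()
        blocks.append(block)
    if not blocks:
        return pd.DataFrame()
    return pd.concat(blocks, ignore_index=True)
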