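"""Shared fixtures and independent brute-force oracles.

The oracles recompute every spatial quantity with plain vectorized
numpy (O(n²) distance matrices), never touching the tree-based code
paths they check.
"""

import numpy as np
import pandas as pd
import pytest

from cellhood.tissue_io import ROIGeometry


# ---------------------------------------------------------------------------
# Builders
# ---------------------------------------------------------------------------

def make_cells(x, y, phenotype=None, lipid=None, roi_id="roi", markers=None):
    """Build a canonical cell table from coordinate arrays."""
    n = len(x)
    df = pd.DataFrame(
        {
            "cell_id": [f"c{i}" for i in range(n)],
            "roi_id": roi_id,
            "x_um": np.asarray(x, dtype=float),
            "y_um": np.asarray(y, dtype=float),
        }
    )
    if markers:
        for name, vals in markers.items():
            df[name] = np.asarray(vals, dtype=float)
    if phenotype is not None:
        df["phenotype"] = list(phenotype)
    if lipid is not None:
        df["lipid_positive"] = np.asarray(lipid, dtype=bool)
    return df


def random_cells(rng, n, size=500.0, labels=("TRPC", "TSC", "M2-TAM"), p=None, lipid_p=None):
    """Uniform random cells on [0, size]^2 with random phenotype labels."""
    x = rng.uniform(0, size, n)
    y = rng.uniform(0, size, n)
    phen = rng.choice(labels, size=n, p=p)
    lipid = rng.uniform(size=n) < lipid_p if lipid_p is not None else None
    return make_cells(x, y, phenotype=phen, lipid=lipid)


@pytest.fixture
def rng():
    return np.random.default_rng(2024)


@pytest.fixture
def square_roi():
    return ROIGeometry(roi_id="roi", bounds=(0.0, 0.0, 500.0, 500.0))


# ---------------------------------------------------------------------------
# Brute-force oracles
# ---------------------------------------------------------------------------

def dist_matrix(cells_a, cells_b=None):
    a = np.column_stack([cells_a["x_um"], cells_a["y_um"]]).astype(float)
    b = a if cells_b is None else np.column_stack([cells_b["x_um"], cells_b["y_um"]]).astype(float)
    return np.sqrt(((a[:, None, :] - b[None, :, :]) ** 2).sum(axis=2))


def brute_pair_set(cells, radius):
    """Unordered neighbor-pair id set by exhaustive scan (self excluded)."""
    D = dist_matrix(cells)
    ids = cells["cell_id"].to_numpy()
    n = len(ids)
    return {
        frozenset((ids[i], ids[j]))
        for i in range(n)
        for j in range(i + 1, n)
        if D[i, j] <= radius
    }


def brute_border_retained(cells, bounds, radius):
    xmin, ymin, xmax, ymax = bounds
    x = cells["x_um"].to_numpy()
    y = cells["y_um"].to_numpy()
    keep = (
        (x - xmin >= radius) & (xmax - x >= radius)
        & (y - ymin >= radius) & (ymax - y >= radius)
    )
    return set(cells.loc[keep, "cell_id"])


def brute_composition(cells, focal_ids, radius):
    """Per-focal phenotype counts among radius-neighbors, by recount."""
    D = dist_matrix(cells)
    ids = cells["cell_id"].to_numpy()
    phen = cells["phenotype"].to_numpy()
    pos = {cid: i for i, cid in enumerate(ids)}
    out = {}
    for fid in focal_ids:
        i = pos[fid]
        neigh = [j for j in range(len(ids)) if j != i and D[i, j] <= radius]
        counts = {}
        for j in neigh:
            counts[phen[j]] = counts.get(phen[j], 0) + 1
        out[fid] = counts
    return out


def brute_knearest(cells, focal_ids, target_type, k):
    """Mean of the k smallest focal->target distances (self excluded);
    NaN when fewer than k targets exist."""
    D = dist_matrix(cells)
    ids = cells["cell_id"].to_numpy()
    phen = cells["phenotype"].to_numpy()
    pos = {cid: i for i, cid in enumerate(ids)}
    out = {}
    for fid in focal_ids:
        i = pos[fid]
        ds = sorted(D[i, j] for j in range(len(ids)) if j != i and phen[j] == target_type)
        out[fid] = float(np.mean(ds[:k])) if len(ds) >= k else float("nan")
    return out
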