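"""Synthetic marked point-pattern tissues with niche structure.

The generator emulates the spatial statistics the neighborhood analysis
assumes in resistant-tumor tissue: circular tumor niches in which the
persister tumor lineage (TRPC) resides and macrophages (M2-TAMs) are
enriched by a density multiplier, over a background of sensitive tumor
cells (TSC) at baseline macrophage density.  Each cell carries a true
type, a region label, a Bernoulli lipid flag with per-(type, region)
probability, and marker mean intensities drawn from a two-component
(positive/negative) Gaussian model so threshold gating is exercised
non-trivially.  Output is a canonical cell table plus ground truth, so
the full pipeline (classify -> neighborhood -> summarize) can be tested
for parameter recovery without any external data.

Sampling model
--------------
Cell counts are Poisson (area x density), making density-based
expectations exact; positions are uniform within their region.  The
enriched macrophage field is realized by superposition/thinning: a
baseline uniform field over the whole frame plus, per niche, an
independent excess field at density ``(rho - 1) * lambda_TAM`` when
``rho >= 1`` (or binomial thinning inside niches when ``rho < 1``).
This is distributionally identical to drawing each region separately.

Randomness is organized as keyed substreams of the single user seed
(one stream per region x cell type for positions, plus dedicated streams
for type assignment, lipid flags and each marker), drawn in a documented
fixed order, so adding a cell type or marker cannot perturb earlier
draws and identical seeds give byte-identical tables.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigurationError
from .tissue_io import ROIGeometry, validate_cell_table

#: Substream keys: rng = default_rng([seed, REGION_KEY, TYPE_KEY]).
#: Background regions use region key 0; niche i uses i + 1.
_TYPE_KEYS = {"tumor": 0, "tam": 1}
_ASSIGN_KEY = 1_000_000   # TRPC-vs-TSC assignment inside niches
_LIPID_KEY = 1_000_001
_MARKER_KEY0 = 2_000_000  # marker m uses 2_000_000 + its index


#: Default two-component intensity model: per marker, per true type,
#: (mean, sd) of a Gaussian truncated at zero.  Positive populations sit
#: well above the default gate threshold of 4, negatives well below, with
#: enough spread that gating is exercised rather than trivial.
DEFAULT_INTENSITY_MODEL: dict[str, dict[str, tuple[float, float]]] = {
    "FABP7": {"TRPC": (8.0, 1.0), "TSC": (1.0, 0.5), "M2-TAM": (1.0, 0.5)},
    "CD163": {"TRPC": (1.0, 0.5), "TSC": (1.0, 0.5), "M2-TAM": (8.0, 1.0)},
}

#: Default gate thresholds matching the intensity model.
DEFAULT_THRESHOLDS = {"FABP7": 4.0, "CD163": 4.0, "LipidSpot": 4.0}

#: Default lipid-positivity probabilities per (type, region).  The tumor
#: and macrophage values reproduce the lipid-loaded fractions reported in
#: resistant vs sensitive tumor regions (74.6%/30% for tumor cells,
#: 77.4%/58.6% for macrophages), so simulated tissues occupy a realistic
#: regime.
DEFAULT_LIPID_PROB: dict[tuple[str, str], float] = {
    ("TRPC", "niche"): 0.746,
    ("TRPC", "background"): 0.746,
    ("TSC", "niche"): 0.30,
    ("TSC", "background"): 0.30,
    ("M2-TAM", "niche"): 0.774,
    ("M2-TAM", "background"): 0.586,
}


@dataclass
class SyntheticTissueConfig:
    """Parameters of one synthetic tissue.

    Defaults describe a 1500 x 1000 µm field with three non-overlapping
    200 µm niches (~25% of the field), uniform tumor density 0.0025
    cells/µm² and background macrophage density 0.001 cells/µm²
    (≈ 3500 cells/mm² total, a realistic solid-tissue value, ≈ 5000–6000
    cells per field), macrophage enrichment rho = 2.5 inside niches, and
    90% of niche tumor cells belonging to the persister lineage.
    """

    width_um: float = 1500.0
    height_um: float = 1000.0
    niche_centers: Sequence[tuple[float, float]] = ((300.0, 300.0), (750.0, 700.0), (1200.0, 300.0))
    niche_radius_um: float = 200.0
    tumor_density: float = 0.0025
    tam_density: float = 0.001
    tam_enrichment: float = 2.5
    trpc_in_niche_fraction: float = 0.9
    lipid_prob: Mapping[tuple[str, str], float] = field(
        default_factory=lambda: dict(DEFAULT_LIPID_PROB)
    )
    intensity_model: Mapping[str, Mapping[str, tuple[float, float]]] = field(
        default_factory=lambda: {m: dict(v) for m, v in DEFAULT_INTENSITY_MODEL.items()}
    )
    lipid_marker: str = "LipidSpot"
    lipid_intensity: tuple[tuple[float, float], tuple[float, float]] = ((8.0, 1.0), (1.0, 0.5))
    tumor_label_niche: str = "TRPC"
    tumor_label_background: str = "TSC"
    tam_label: str = "M2-TAM"
    poisson_counts: bool = True
    seed: int = 0

    def __post_init__(self):
        if not (self.width_um > 0 and self.height_um > 0):
            raise ConfigurationError("field dimensions must be positive")
        if not self.niche_radius_um > 0:
            raise ConfigurationError("niche_radius_um must be > 0")
        r = self.niche_radius_um
        for cx, cy in self.niche_centers:
            if cx - r < 0 or cy - r < 0 or cx + r > self.width_um or cy + r > self.height_um:
                raise ConfigurationError(
                    f"niche at ({cx}, {cy}) with radius {r} extends outside the field"
                )
        for name, v in (("tumor_density", self.tumor_density),
                        ("tam_density", self.tam_density),
                        ("tam_enrichment", self.tam_enrichment)):
            if v < 0:
                raise ConfigurationError(f"{name} must be >= 0")
        if not 0 <= self.trpc_in_niche_fraction <= 1:
            raise ConfigurationError("trpc_in_niche_fraction must lie in [0, 1]")
        for key, p in self.lipid_prob.items():
            if not 0 <= p <= 1:
                raise ConfigurationError(f"lipid_prob{key} = {p} outside [0, 1]")

    @property
    def niches_overlap(self) -> bool:
        cs = list(self.niche_centers)
        r = self.niche_radius_um
        for i in range(len(cs)):
            for j in range(i + 1, len(cs)):
                if math.hypot(cs[i][0] - cs[j][0], cs[i][1] - cs[j][1]) < 2 * r:
                    return True
        return False

    @property
    def field_area(self) -> float:
        return self.width_um * self.height_um

    @property
    def niche_area(self) -> float:
        """Total niche area (exact only for non-overlapping niches)."""
        return len(self.niche_centers) * math.pi * self.niche_radius_um ** 2


@dataclass
class TissueSample:
    """One generated tissue.

    cells
        Canonical cell table (``cell_id, roi_id, x_um, y_um`` + marker
        intensities).  Phenotype and lipid columns are deliberately
        absent: the pipeline must recover them from intensities.
    frame
        Rectangular ROI covering the whole field (``region_class='other'``).
    niches
        One circular :class:`ROIGeometry` per niche, region class
        ``TRPC`` — the analogue of pathologist-drawn resistant-region ROIs.
    truth
        Ground truth per cell: ``true_type``, ``region``
        (niche/background), ``niche_index`` (-1 outside), ``lipid_true``.
    """

    cells: pd.DataFrame
    frame: ROIGeometry
    niches: list[ROIGeometry]
    truth: pd.DataFrame
    config: SyntheticTissueConfig


def _rng(seed: int, *keys: int) -> np.random.Generator:
    return np.random.default_rng([int(seed)] + [int(k) for k in keys])


def _count(rng: np.random.Generator, expected: float, poisson: bool) -> int:
    if expected < 0:
        raise ConfigurationError("negative expected count")
    return int(rng.poisson(expected)) if poisson else int(round(expected))


def generate_tissue(config: SyntheticTissueConfig, seed: int | None = None) -> TissueSample:
    """Generate one tissue; fully reproducible from ``seed`` (default: config.seed)."""
    seed = config.seed if seed is None else seed
    W, H, r = config.width_um, config.height_um, config.niche_radius_um
    centers = [(float(cx), float(cy)) for cx, cy in config.niche_centers]

    def in_any_niche(x, y):
        idx = np.full(len(x), -1)
        for i, (cx, cy) in enumerate(centers):
            hit = (x - cx) ** 2 + (y - cy) ** 2 <= r * r
            idx = np.where((idx == -1) & hit, i, idx)
        return idx

    # -- tumor cells: uniform over the field ------------------------------
    rng_t = _rng(seed, 0, _TYPE_KEYS["tumor"])
    n_tumor = _count(rng_t, config.tumor_density * config.field_area, config.poisson_counts)
    tx = rng_t.uniform(0, W, n_tumor)
    ty = rng_t.uniform(0, H, n_tumor)
    t_niche = in_any_niche(tx, ty)
    rng_assign = _rng(seed, _ASSIGN_KEY)
    is_trpc = (t_niche >= 0) & (rng_assign.uniform(size=n_tumor) < config.trpc_in_niche_fraction)
    t_type = np.where(is_trpc, config.tumor_label_niche, config.tumor_label_background)

    # -- macrophages: baseline field + per-niche excess / thinning --------
    rng_m = _rng(seed, 0, _TYPE_KEYS["tam"])
    n_base = _count(rng_m, config.tam_density * config.field_area, config.poisson_counts)
    mx = rng_m.uniform(0, W, n_base)
    my = rng_m.uniform(0, H, n_base)
    rho = config.tam_enrichment
    if rho < 1:
        inside = in_any_niche(mx, my) >= 0
        keep = ~inside | (rng_m.uniform(size=n_base) < rho)
        mx, my = mx[keep], my[keep]
    xs_extra, ys_extra = [], []
    if rho > 1:
        excess = (rho - 1) * config.tam_density * math.pi * r * r
        for i, (cx, cy) in enumerate(centers):
            rng_n = _rng(seed, i + 1, _TYPE_KEYS["tam"])
            n_ex = _count(rng_n, excess, config.poisson_counts)
            rad = r * np.sqrt(rng_n.uniform(size=n_ex))
            ang = rng_n.uniform(0, 2 * math.pi, n_ex)
            xs_extra.append(cx + rad * np.cos(ang))
            ys_extra.append(cy + rad * np.sin(ang))
    mx = np.concatenate([mx] + xs_extra) if xs_extra else mx
    my = np.concatenate([my] + ys_extra) if ys_extra else my

    x = np.concatenate([tx, mx])
    y = np.concatenate([ty, my])
    true_type = np.concatenate([t_type, np.full(len(mx), config.tam_label, dtype=object)])
    niche_idx = in_any_niche(x, y)
    region = np.where(niche_idx >= 0, "niche", "background")
    n = len(x)

    # -- lipid flags -------------------------------------------------------
    rng_l = _rng(seed, _LIPID_KEY)
    u = rng_l.uniform(size=n)
    p = np.empty(n)
    for i in range(n):
        key = (str(true_type[i]), str(region[i]))
        if key not in config.lipid_prob:
            raise ConfigurationError(f"lipid_prob missing entry for {key}")
        p[i] = config.lipid_prob[key]
    lipid = u < p

    # -- marker intensities ------------------------------------------------
    cells = pd.DataFrame(
        {
            "cell_id": [f"c{i:06d}" for i in range(n)],
            "roi_id": "sim",
            "x_um": x,
            "y_um": y,
        }
    )
    for mi, (marker, per_type) in enumerate(config.intensity_model.items()):
        rng_mk = _rng(seed, _MARKER_KEY0 + mi)
        vals = np.empty(n)
        for t, (mu, sd) in per_type.items():
            mask = true_type == t
            vals[mask] = rng_mk.normal(mu, sd, int(mask.sum()))
        known = np.isin(true_type, list(per_type))
        if not known.all():
            missing = sorted(set(true_type[~known]))
            raise ConfigurationError(
                f"intensity_model[{marker!r}] lacks entries for type(s) {missing}"
            )
        cells[marker] = np.clip(vals, 0.0, None)
    rng_ls = _rng(seed, _MARKER_KEY0 + len(config.intensity_model))
    (mu_p, sd_p), (mu_n, sd_n) = config.lipid_intensity
    ls = np.where(
        lipid,
        rng_ls.normal(mu_p, sd_p, n),
        rng_ls.normal(mu_n, sd_n, n),
    )
    cells[config.lipid_marker] = np.clip(ls, 0.0, None)

    validate_cell_table(cells)
    frame = ROIGeometry(roi_id="sim", bounds=(0.0, 0.0, W, H), region_class="other")
    niches = [
        ROIGeometry(roi_id=f"niche_{i}", circle=(cx, cy, r), region_class="TRPC")
        for i, (cx, cy) in enumerate(centers)
    ]
    truth = pd.DataFrame(
        {
            "cell_id": cells["cell_id"],
            "true_type": true_type,
            "region": region,
            "niche_index": niche_idx,
            "lipid_true": lipid,
        }
    )
    return TissueSample(cells=cells, frame=frame, niches=niches, truth=truth, config=config)


@dataclass
class ExpectedMetrics:
    """Closed-form expectations for a config (non-overlapping niches).

    ``tam_neighbor_fraction_*`` are the expected macrophage fractions
    among the neighbors of a focal cell whose full neighborhood lies in
    the stated region (deep-interior approximation — the reason the
    analysis excludes region-boundary focal cells when recovering these).
    """

    analytic: bool
    reason: str
    lipid_fraction: dict[tuple[str, str], float]
    tam_density_ratio: float
    tam_neighbor_fraction_niche: float
    tam_neighbor_fraction_background: float
    tam_neighbor_fraction_ratio: float
    expected_counts: dict[str, float]


def expected_metrics(config: SyntheticTissueConfig) -> ExpectedMetrics:
    """Analytic expectations; flagged non-analytic when niches overlap."""
    analytic = not config.niches_overlap
    reason = "" if analytic else "niches overlap; region areas are not closed-form"
    lam_t, lam_m, rho = config.tumor_density, config.tam_density, config.tam_enrichment
    f_in = rho * lam_m / (lam_t + rho * lam_m) if (lam_t + rho * lam_m) > 0 else float("nan")
    f_out = lam_m / (lam_t + lam_m) if (lam_t + lam_m) > 0 else float("nan")
    ratio = f_in / f_out if f_out and not np.isnan(f_out) and f_out > 0 else float("nan")
    a_niche = config.niche_area
    a_bg = config.field_area - a_niche
    n_tumor_niche = lam_t * a_niche
    counts = {
        config.tumor_label_niche: n_tumor_niche * config.trpc_in_niche_fraction,
        config.tumor_label_background: lam_t * a_bg
        + n_tumor_niche * (1 - config.trpc_in_niche_fraction),
        config.tam_label: lam_m * a_bg + rho * lam_m * a_niche,
    }
    return ExpectedMetrics(
        analytic=analytic,
        reason=reason,
        lipid_fraction=dict(config.lipid_prob),
        tam_density_ratio=rho,
        tam_neighbor_fraction_niche=f_in,
        tam_neighbor_fraction_background=f_out,
        tam_neighbor_fraction_ratio=ratio,
        expected_counts=counts,
    )
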