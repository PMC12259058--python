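"""End-to-end convenience glue: classify -> neighborhood -> region summary.

Thin composition of the other modules used by the recovery tests, the
acceptance script and the CLI; no science of its own lives here.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import pandas as pd

from . import group_stats, neighborhood, phenotyping, synthetic_tissue
from .neighborhood import NeighborhoodParams
from .phenotyping import PhenotypeRuleSet
from .synthetic_tissue import DEFAULT_THRESHOLDS, TissueSample


@dataclass
class SampleAnalysis:
    """Per-focal-cell records plus classified cells for one tissue."""

    cells: pd.DataFrame          # classified + lipid-flagged cell table
    records: pd.DataFrame        # neighborhood_table output + region_class
    lipid_fraction: pd.DataFrame  # lipid+ fraction per (phenotype, region_class)


def analyze_sample(
    sample: TissueSample,
    *,
    rules: PhenotypeRuleSet | None = None,
    params: NeighborhoodParams | None = None,
    thresholds: Mapping[str, float] | None = None,
    focal_types: Sequence[str] = ("TRPC", "TSC"),
    target_types: Sequence[str] = ("M2-TAM",),
    tam_label: str = "M2-TAM",
    region_margin_um: float | None = None,
) -> SampleAnalysis:
    """Run the full pipeline on a synthetic tissue.

    Phenotypes and lipid flags are recovered from intensities (ground
    truth is never consulted); focal cells are then tagged with the
    region class of the niche geometry, applying border-exclusion logic
    at region boundaries with margin ``region_margin_um`` (default: the
    neighborhood radius), with ambiguous cells excluded from summaries.
    """
    params = params or NeighborhoodParams()
    thresholds = dict(thresholds or DEFAULT_THRESHOLDS)
    if rules is None:
        rules = phenotyping.human_tumor_rules(thresholds)
    margin = params.radius_um if region_margin_um is None else region_margin_um

    cells = phenotyping.classify_cells(sample.cells, rules)
    cells = phenotyping.assign_lipid_flag(
        cells, sample.config.lipid_marker, thresholds[sample.config.lipid_marker]
    )
    records = neighborhood.neighborhood_table(
        cells,
        sample.frame,
        focal_types=list(focal_types),
        target_types=list(target_types),
        params=params,
        tam_label=tam_label,
    )
    region = neighborhood.classify_points_by_region(
        cells, sample.niches, margin_um=margin, background_class="TSC"
    )
    cells = cells.assign(region_class=region)
    records = records.merge(
        cells[["cell_id", "region_class"]], on="cell_id", how="left"
    )
    records = records[records["region_class"] != "boundary"].reset_index(drop=True)

    lipid_fraction = (
        cells[cells["region_class"] != "boundary"]
        .groupby(["phenotype", "region_class"])["lipid_positive"]
        .agg(["mean", "size"])
        .rename(columns={"mean": "lipid_fraction", "size": "n_cells"})
        .reset_index()
    )
    return SampleAnalysis(cells=cells, records=records, lipid_fraction=lipid_fraction)


def recover_tam_fraction_ratio(
    config: synthetic_tissue.SyntheticTissueConfig,
    seed: int,
    *,
    tam_label: str = "M2-TAM",
    params: NeighborhoodParams | None = None,
) -> dict[str, float]:
    """Generate one tissue and measure the niche/background macrophage metrics.

    Returns the mean macrophage neighbor fraction of focal tumor cells in
    the niche interior (region class ``TRPC``) and background interior
    (``TSC``), their ratio, and the mean nearest-macrophage distances —
    the quantities whose expectations :func:`~cellhood.synthetic_tissue.
    expected_metrics` provides in closed form.
    """
    sample = synthetic_tissue.generate_tissue(config, seed=seed)
    analysis = analyze_sample(sample, params=params, tam_label=tam_label)
    summaries = group_stats.summarize_by_region(
        analysis.records, level="pooled_cells",
        metrics=[f"frac_{tam_label}", f"nearest_{tam_label}"],
    )
    out: dict[str, float] = {}
    for cls, key in (("TRPC", "niche"), ("TSC", "background")):
        if cls in summaries:
            out[f"tam_fraction_{key}"] = summaries[cls].mean(f"frac_{tam_label}")
            out[f"nearest_tam_{key}"] = summaries[cls].mean(f"nearest_{tam_label}")
        else:
            out[f"tam_fraction_{key}"] = float("nan")
            out[f"nearest_tam_{key}"] = float("nan")
    f_in, f_out = out["tam_fraction_niche"], out["tam_fraction_background"]
    out["tam_fraction_ratio"] = f_in / f_out if f_out and f_out > 0 else float("nan")
    return out
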