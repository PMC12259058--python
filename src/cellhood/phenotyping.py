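"""Phenotype assignment from marker mean intensities.

Cells are classified by ordered marker-predicate rules: each rule is a
label plus a conjunction of ``marker relation threshold`` predicates, where
``relation`` is ``positive`` (intensity strictly above the threshold) or
``negative`` (at or below).  Rules are evaluated in order and the first
match wins, which is how hierarchical panel definitions are expressed —
e.g. a cytotoxic T cell requires CD68−, so macrophage rules are listed
first.  Cells matching no rule receive the fallback label ("double
negative" cells, i.e. the treatment-sensitive background population in the
tumor panels shipped here).

Thresholds are user-defined per marker and per dataset; no automatic
threshold learning is attempted.  Positivity is strict ``>`` so that a
zero threshold has well-defined behavior (intensity 0 is negative).

The module also provides quantile gating (top/bottom fraction of a
marker's intensity distribution, the chip-cytometry FABP7-high/low gate)
and lipid-positivity flagging against a neutral-lipid stain threshold.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .errors import (
    ConfigurationError,
    DegenerateDataError,
    InsufficientDataError,
)
from .tissue_io import marker_columns

RELATIONS = ("positive", "negative")


@dataclass(frozen=True)
class MarkerPredicate:
    """One ``marker relation threshold`` clause."""

    marker: str
    relation: str
    threshold: float

    def __post_init__(self):
        if self.relation not in RELATIONS:
            raise ConfigurationError(
                f"relation must be one of {RELATIONS}, got {self.relation!r}"
            )

    def evaluate(self, intensities: np.ndarray) -> np.ndarray:
        """Vectorized predicate over an intensity array (strict > for positive)."""
        if self.relation == "positive":
            return intensities > self.threshold
        return intensities <= self.threshold


@dataclass(frozen=True)
class PhenotypeRule:
    label: str
    predicates: tuple[MarkerPredicate, ...]


@dataclass
class PhenotypeRuleSet:
    """Ordered first-match-wins phenotype rules with a fallback label.

    Labels must be unique; the fallback label must not collide with a rule
    label.  Marker availability is checked at classify time against the
    actual cell table.
    """

    rules: Sequence[PhenotypeRule]
    fallback_label: str = "other"

    def __post_init__(self):
        labels = [r.label for r in self.rules]
        if len(set(labels)) != len(labels):
            raise ConfigurationError(f"rule labels must be unique, got {labels}")
        if self.fallback_label in labels:
            raise ConfigurationError(
                f"fallback label {self.fallback_label!r} collides with a rule label"
            )

    @property
    def labels(self) -> list[str]:
        """All labels this rule set can assign, fallback last."""
        return [r.label for r in self.rules] + [self.fallback_label]

    @property
    def markers(self) -> list[str]:
        seen: list[str] = []
        for r in self.rules:
            for p in r.predicates:
                if p.marker not in seen:
                    seen.append(p.marker)
        return seen

    # -- (de)serialization --------------------------------------------------

    @classmethod
    def from_dict(cls, data: Mapping) -> "PhenotypeRuleSet":
        rules = []
        for entry in data["rules"]:
            preds = tuple(
                MarkerPredicate(str(p["marker"]), str(p["relation"]), float(p["threshold"]))
                for p in entry["all"]
            )
            rules.append(PhenotypeRule(str(entry["label"]), preds))
        return cls(rules=rules, fallback_label=str(data.get("fallback", "other")))

    @classmethod
    def from_yaml(cls, path) -> "PhenotypeRuleSet":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def to_dict(self) -> dict:
        return {
            "fallback": self.fallback_label,
            "rules": [
                {
                    "label": r.label,
                    "all": [
                        {"marker": p.marker, "relation": p.relation, "threshold": p.threshold}
                        for p in r.predicates
                    ],
                }
                for r in self.rules
            ],
        }

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)


# ---------------------------------------------------------------------------
# Shipped rule sets
# ---------------------------------------------------------------------------

def human_tumor_rules(
    thresholds: Mapping[str, float],
    *,
    tumor_marker: str = "FABP7",
    tam_marker: str = "CD163",
) -> PhenotypeRuleSet:
    """Three-way human tumor labeling: TRPC (FABP7+), M2-TAM (CD163+), TSC fallback.

    TRPC = treatment-resistant persister cell (lipid-metabolic lineage,
    FABP7-high); M2-TAM = CD163+ tumor-associated macrophage; everything
    double-negative is a treatment-sensitive cell (TSC).
    """
    return PhenotypeRuleSet(
        rules=[
            PhenotypeRule("TRPC", (MarkerPredicate(tumor_marker, "positive", thresholds[tumor_marker]),)),
            PhenotypeRule("M2-TAM", (MarkerPredicate(tam_marker, "positive", thresholds[tam_marker]),)),
        ],
        fallback_label="TSC",
    )


def mouse_tumor_rules(
    thresholds: Mapping[str, float],
    *,
    tumor_marker: str = "RFP",
    tam_marker: str = "CD68",
) -> PhenotypeRuleSet:
    """Mouse labeling: cancer cell (RFP+), TAM (CD68+), 'other' fallback."""
    return PhenotypeRuleSet(
        rules=[
            PhenotypeRule("cancer", (MarkerPredicate(tumor_marker, "positive", thresholds[tumor_marker]),)),
            PhenotypeRule("TAM", (MarkerPredicate(tam_marker, "positive", thresholds[tam_marker]),)),
        ],
        fallback_label="other",
    )


def immune_panel_rules(thresholds: Mapping[str, float]) -> PhenotypeRuleSet:
    """Hierarchical immune-contexture panel for high-plex immunofluorescence.

    Definitions (CD31− excludes endothelium throughout):

    * MDSC — CD31−/CD68+/CD11b+/HLA-DR−
    * TAM — CD31−/CD68+
    * CTL — CD31−/CD68−/CD4−/CD8+
    * Th — CD31−/CD68−/CD4+
    * T lymphocyte — CD31−/CD3+
    * APC — CD31−/HLA-DR+

    First-match ordering runs from the most to the least specific
    definition so each cell receives its most informative single label;
    a cell matching none is labeled ``other``.  ``thresholds`` must cover
    CD31, CD68, CD11b, HLA-DR, CD4, CD8 and CD3.
    """
    t = thresholds

    def pos(m):
        return MarkerPredicate(m, "positive", t[m])

    def neg(m):
        return MarkerPredicate(m, "negative", t[m])

    return PhenotypeRuleSet(
        rules=[
            PhenotypeRule("MDSC", (neg("CD31"), pos("CD68"), pos("CD11b"), neg("HLA-DR"))),
            PhenotypeRule("TAM", (neg("CD31"), pos("CD68"))),
            PhenotypeRule("CTL", (neg("CD31"), neg("CD68"), neg("CD4"), pos("CD8"))),
            PhenotypeRule("Th", (neg("CD31"), neg("CD68"), pos("CD4"))),
            PhenotypeRule("T lymphocyte", (neg("CD31"), pos("CD3"))),
            PhenotypeRule("APC", (neg("CD31"), pos("HLA-DR"))),
        ],
        fallback_label="other",
    )


# ---------------------------------------------------------------------------
# Operations
# ---------------------------------------------------------------------------

def classify_cells(cells: pd.DataFrame, rules: PhenotypeRuleSet) -> pd.DataFrame:
    """Assign each cell exactly one phenotype label.

    Returns a copy of ``cells`` with a ``phenotype`` column.  Deterministic,
    order-dependent (first matching rule wins), and a pure function of the
    intensity columns and the rule set — reclassifying an already
    classified table gives the same answer.

    Raises
    ------
    ConfigurationError
        A rule references a marker absent from the cell table; the message
        names the marker and the rule.
    """
    for rule in rules.rules:
        for p in rule.predicates:
            if p.marker not in cells.columns:
                raise ConfigurationError(
                    f"rule {rule.label!r} references marker {p.marker!r} "
                    "absent from the cell table"
                )
    n = len(cells)
    label = np.full(n, rules.fallback_label, dtype=object)
    unassigned = np.ones(n, dtype=bool)
    for rule in rules.rules:
        mask = np.ones(n, dtype=bool)
        for p in rule.predicates:
            mask &= p.evaluate(cells[p.marker].to_numpy(dtype=float))
        take = mask & unassigned
        label[take] = rule.label
        unassigned &= ~take
    out = cells.copy()
    out["phenotype"] = label
    return out


@dataclass
class QuantileGateResult:
    """Partition produced by :func:`quantile_gate`.

    ``high``/``low``/``unassigned`` are pandas Index objects of cell ids;
    ``high_threshold``/``low_threshold`` are the empirical quantile values
    used as gate boundaries (ties at a boundary are included in the set).
    """

    high: pd.Index
    low: pd.Index
    unassigned: pd.Index
    high_threshold: float
    low_threshold: float


def quantile_gate(
    cells: pd.DataFrame,
    marker: str,
    top_frac: float,
    bottom_frac: float,
) -> QuantileGateResult:
    """Split cells into marker-high / marker-low sets by empirical quantiles.

    The high set is the cells with intensity at or above the
    ``1 - top_frac`` empirical quantile; the low set those at or below the
    ``bottom_frac`` quantile.  With distinct intensities the set sizes are
    ``ceil(top_frac * n)`` and ``ceil(bottom_frac * n)``.  Cells tied
    exactly at a gate boundary are all included (the set may then exceed
    the nominal size; a warning is issued).  The two sets are kept
    disjoint: in the rare odd-``n`` case where both nominal sizes cannot
    be honored simultaneously, the low set yields (with a warning).

    The top/bottom 10% MFI gate used to call marker-high vs marker-low
    populations is ``top_frac = bottom_frac = 0.1``.
    """
    if not (0 < top_frac < 1 and 0 < bottom_frac < 1):
        raise ConfigurationError("top_frac and bottom_frac must lie in (0, 1)")
    if top_frac + bottom_frac > 1 + 1e-12:
        raise ConfigurationError("top_frac + bottom_frac must be <= 1")
    if marker not in cells.columns:
        raise ConfigurationError(f"marker {marker!r} absent from the cell table")
    n = len(cells)
    if n == 0:
        raise InsufficientDataError("quantile_gate called on an empty cell table")
    v = cells[marker].to_numpy(dtype=float)
    if np.nanmax(v) == np.nanmin(v):
        raise DegenerateDataError(
            f"all {marker!r} intensities are tied; the gate is undefined"
        )
    order = np.sort(v)
    k_high = math.ceil(top_frac * n)
    k_low = math.ceil(bottom_frac * n)
    hi_thr = order[n - k_high]
    lo_thr = order[k_low - 1]
    ids = cells["cell_id"] if "cell_id" in cells.columns else pd.Series(cells.index, index=cells.index)
    high_mask = v >= hi_thr
    low_mask = (v <= lo_thr) & ~high_mask
    if high_mask.sum() > k_high or (v <= lo_thr).sum() > k_low:
        warnings.warn(
            f"ties at the {marker!r} gate boundary: all tied cells included",
            stacklevel=2,
        )
    if ((v <= lo_thr) & high_mask).any():
        warnings.warn(
            "high and low gates overlap; overlapping cells kept in the high set",
            stacklevel=2,
        )
    high = pd.Index(ids[high_mask])
    low = pd.Index(ids[low_mask])
    unassigned = pd.Index(ids[~high_mask & ~low_mask])
    return QuantileGateResult(high, low, unassigned, float(hi_thr), float(lo_thr))


def assign_lipid_flag(cells: pd.DataFrame, marker: str, threshold: float) -> pd.DataFrame:
    """Flag cells as lipid-loaded: ``lipid_positive = intensity > threshold``.

    Strict inequality, independent of any phenotype label.  Returns a copy
    with a boolean ``lipid_positive`` column.
    """
    if marker not in cells.columns:
        raise ConfigurationError(f"lipid marker {marker!r} absent from the cell table")
    out = cells.copy()
    out["lipid_positive"] = cells[marker].to_numpy(dtype=float) > threshold
    return out
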