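"""Digital-spatial-profiler probe QC and normalization math.

Works on a segment x probe count table from a spatial profiler run, where
probes are annotated as targets, IgG negative controls, or housekeeping
genes, and each segment carries its area and nuclei count.  Implements:

* signal-to-background — each probe's count divided by the geometric mean
  of the IgG negative-control counts of the same segment;
* background-probe filtering — a target hovering at background in
  (almost) all segments is excluded, but near-background targets with a
  few clearly elevated segments are kept;
* the four per-segment normalization factors: housekeeping geomean, IgG
  (Neg) geomean, area, nuclei;
* factor concordance — the sample standard deviation of the log2 ratio
  between two factors across segments.  Stable factors that both track
  true signal have low SD (the geNorm stability idea); the statistic is
  invariant to rescaling either factor;
* normalization — dividing counts by a factor, multiplied back by the
  factor's across-segment geomean so normalized counts stay on the raw
  count scale.  Recomputing the same factor on normalized counts gives a
  constant across segments (fixed point).

Counts must be strictly positive before any log/geomean operation; a
configurable pseudocount can be added for tables containing zeros, but
the default is to refuse rather than silently floor.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import ConfigurationError, InsufficientDataError, SchemaError

PROBE_CLASSES = ("target", "IgG", "housekeeping")
FACTOR_METHODS = ("HK_geomean", "Neg_geomean", "area", "nuclei")


def geometric_mean(values) -> float:
    """Geometric mean ``exp(mean(log v))`` of strictly positive values."""
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise InsufficientDataError("geometric mean of an empty collection")
    if np.any(~np.isfinite(v)) or np.any(v <= 0):
        raise ConfigurationError("geometric mean requires strictly positive finite values")
    return float(np.exp(np.mean(np.log(v))))


@dataclass
class DSPSegmentTable:
    """Counts plus annotations for one profiler run.

    counts
        DataFrame, probes as rows (index = probe ids), segments as
        columns, strictly positive after the optional pseudocount.
    probe_class
        Series probe id -> one of ``target, IgG, housekeeping``.
    area, nuclei
        Series segment id -> surface area (> 0) / nuclei count (>= 0).
    pseudocount
        Added to every count on construction (default 0; the raw counts
        must then already be positive).
    """

    counts: pd.DataFrame
    probe_class: pd.Series
    area: pd.Series | None = None
    nuclei: pd.Series | None = None
    pseudocount: float = 0.0

    def __post_init__(self):
        self.counts = pd.DataFrame(self.counts).astype(float) + self.pseudocount
        self.probe_class = pd.Series(self.probe_class)
        bad = set(self.probe_class.unique()) - set(PROBE_CLASSES)
        if bad:
            raise SchemaError(f"unknown probe class(es) {sorted(bad)}; allowed: {PROBE_CLASSES}")
        missing = [p for p in self.counts.index if p not in self.probe_class.index]
        if missing:
            raise SchemaError(f"probes without class annotation: {missing[:10]}")
        vals = self.counts.to_numpy()
        if np.any(~np.isfinite(vals)) or np.any(vals <= 0):
            raise SchemaError(
                "counts must be finite and strictly positive (set pseudocount "
                "to floor zero counts explicitly)"
            )
        for name, s, strict in (("area", self.area, True), ("nuclei", self.nuclei, False)):
            if s is None:
                continue
            s = pd.Series(s).astype(float)
            missing_seg = [c for c in self.counts.columns if c not in s.index]
            if missing_seg:
                raise SchemaError(f"{name} missing for segment(s): {missing_seg[:10]}")
            v = s.loc[list(self.counts.columns)].to_numpy()
            if (strict and np.any(v <= 0)) or (not strict and np.any(v < 0)):
                raise SchemaError(f"{name} must be {'> 0' if strict else '>= 0'}")
            setattr(self, name, s)

    @property
    def segments(self) -> list:
        return list(self.counts.columns)

    def probes_of_class(self, cls: str) -> list:
        return [p for p in self.counts.index if self.probe_class[p] == cls]


def read_dsp_tables(
    counts_path, probe_meta_path, segment_meta_path=None, *, pseudocount: float = 0.0
) -> DSPSegmentTable:
    """Assemble a :class:`DSPSegmentTable` from three CSVs.

    ``counts_path``: probes as rows, first column the probe id, one
    column per segment.  ``probe_meta_path``: columns ``probe_id, class``.
    ``segment_meta_path`` (optional): columns ``segment_id, area, nuclei``.
    """
    counts = pd.read_csv(counts_path, index_col=0)
    probes = pd.read_csv(probe_meta_path)
    probe_class = pd.Series(
        probes["class"].to_numpy(), index=probes["probe_id"].astype(str)
    )
    counts.index = counts.index.astype(str)
    area = nuclei = None
    if segment_meta_path is not None:
        seg = pd.read_csv(segment_meta_path)
        seg_id = seg["segment_id"].astype(str)
        if "area" in seg.columns:
            area = pd.Series(seg["area"].to_numpy(dtype=float), index=seg_id)
        if "nuclei" in seg.columns:
            nuclei = pd.Series(seg["nuclei"].to_numpy(dtype=float), index=seg_id)
    return DSPSegmentTable(
        counts=counts, probe_class=probe_class, area=area, nuclei=nuclei,
        pseudocount=pseudocount,
    )


def signal_to_background(table: DSPSegmentTable, *, probes: str = "all") -> pd.DataFrame:
    """Count divided by the segment's IgG geomean, per probe and segment.

    ``probes='all'`` returns ratios for every probe (the IgG probes' own
    ratios then have geomean exactly 1 within each segment — a useful
    self-check); ``'target'`` restricts the rows to target probes.
    """
    igg = table.probes_of_class("IgG")
    if not igg:
        raise ConfigurationError("signal_to_background requires at least one IgG probe")
    bg = table.counts.loc[igg].apply(geometric_mean, axis=0)
    ratios = table.counts.div(bg, axis=1)
    if probes == "target":
        return ratios.loc[table.probes_of_class("target")]
    if probes == "all":
        return ratios
    raise ConfigurationError("probes must be 'all' or 'target'")


def filter_probes(
    ratios: pd.DataFrame,
    background_band: float = 1.5,
    min_high_segments: int = 1,
) -> tuple[pd.Index, pd.Index]:
    """Partition targets into (kept, excluded) by signal-to-background.

    A target is kept iff its ratio exceeds ``background_band`` in at
    least ``min_high_segments`` segments — i.e. probes hovering around
    background everywhere are excluded, while near-background probes with
    a few clearly elevated segments are retained.  The two index sets
    partition the rows of ``ratios``.

    The band and segment count are qualitative choices; the defaults
    (ratio 1.5, one elevated segment) are deliberately permissive and
    should be reviewed per dataset.
    """
    if background_band < 0:
        raise ConfigurationError("background_band must be >= 0")
    if min_high_segments < 1:
        raise ConfigurationError("min_high_segments must be >= 1")
    n_high = (ratios > background_band).sum(axis=1)
    keep = n_high >= min_high_segments
    return ratios.index[keep], ratios.index[~keep]


def normalization_factors(
    table: DSPSegmentTable, methods: Sequence[str] | None = None
) -> pd.DataFrame:
    """Per-segment normalization factors, one column per method.

    ``HK_geomean``/``Neg_geomean`` are the per-segment geometric means of
    the housekeeping / IgG counts; ``area`` and ``nuclei`` are passed
    through verbatim.  Requesting a method whose inputs are absent raises
    :class:`ConfigurationError`.
    """
    methods = list(methods) if methods is not None else list(FACTOR_METHODS)
    out = {}
    for m in methods:
        if m == "HK_geomean":
            hk = table.probes_of_class("housekeeping")
            if not hk:
                raise ConfigurationError("HK_geomean requested but no housekeeping probes")
            out[m] = table.counts.loc[hk].apply(geometric_mean, axis=0)
        elif m == "Neg_geomean":
            igg = table.probes_of_class("IgG")
            if not igg:
                raise ConfigurationError("Neg_geomean requested but no IgG probes")
            out[m] = table.counts.loc[igg].apply(geometric_mean, axis=0)
        elif m == "area":
            if table.area is None:
                raise ConfigurationError("area normalization requested but no area metadata")
            out[m] = table.area.loc[table.segments]
        elif m == "nuclei":
            if table.nuclei is None:
                raise ConfigurationError("nuclei normalization requested but no nuclei metadata")
            out[m] = table.nuclei.loc[table.segments]
        else:
            raise ConfigurationError(f"unknown factor method {m!r}; allowed: {FACTOR_METHODS}")
    return pd.DataFrame(out, index=pd.Index(table.segments))


def factor_concordance(factor_a, factor_b) -> float:
    """Sample SD (n-1 denominator) of log2(a/b) across segments.

    0 means the factors are proportional; symmetric in its arguments and
    invariant to multiplying either factor by a positive constant.
    """
    a = np.asarray(factor_a, dtype=float)
    b = np.asarray(factor_b, dtype=float)
    if a.shape != b.shape:
        raise ConfigurationError("factors must cover the same segments")
    if a.size < 2:
        raise InsufficientDataError("factor concordance needs at least 2 segments")
    if np.any(a <= 0) or np.any(b <= 0):
        raise ConfigurationError("factors must be strictly positive")
    return float(np.std(np.log2(a / b), ddof=1))


def apply_normalization(
    table: DSPSegmentTable, factor_method: str, *, preserve_scale: bool = True
) -> pd.DataFrame:
    """Normalize counts by a per-segment factor.

    ``normalized(probe, segment) = count / factor(segment) * G`` where
    ``G`` is the geometric mean of the factor across segments when
    ``preserve_scale`` (default) — keeping normalized counts on the raw
    count scale — and 1 otherwise.  Recomputing the same factor on the
    normalized table yields a constant across segments.
    """
    factors = normalization_factors(table, [factor_method])[factor_method]
    if np.any(factors.to_numpy() <= 0):
        raise ConfigurationError(f"{factor_method} factor is non-positive for some segment")
    scale = geometric_mean(factors.to_numpy()) if preserve_scale else 1.0
    return table.counts.div(factors, axis=1) * scale
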