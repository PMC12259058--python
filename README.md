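# cellhood

Single-cell spatial neighborhood quantification for multiplexed
immunofluorescence tissue images.

## The problem

Multiplexed imaging of solid tumors (glioblastoma in particular) produces
segmented-cell tables: one row per cell with its centroid and the mean
intensity of each marker.  A recurring question is how cell types arrange
themselves around one another — for instance, whether the
treatment-resistant, lipid-metabolic tumor lineage (TRPC, FABP7-high)
lives in niches densely infiltrated by immunosuppressive M2-like
tumor-associated macrophages (CD163⁺ M2-TAMs), while the
treatment-sensitive, glycolytic lineage (TSC, double-negative) occupies a
macrophage-poor background.  `cellhood` answers this class of question
with per-cell neighborhood statistics, and ships a synthetic tissue
generator so the whole pipeline is testable end to end without imaging
data.  A companion module implements the probe-QC and normalization math
for digital-spatial-profiler count tables from the same kind of study.

## The statistics

For a focal cell $i$ at position $x_i$, its neighborhood is
$N(i) = \{j \ne i : \lVert x_j - x_i \rVert \le r\}$ with $r = 55\,\mu m$
by default (Euclidean, center to center, boundary inclusive).  Focal
cells closer than $r$ to the image border are excluded — their
neighborhoods are truncated — but still count as neighbors of retained
cells.  Per retained focal cell the package computes

- **composition**: $n_t(i)/|N(i)|$, the fraction of neighbors of each
  phenotype $t$;
- **nearest of type**: $d_t(i) = \min_{j \ne i,\; \text{type}(j)=t} \lVert x_j - x_i\rVert$;
- **mean k-nearest of type** (default $k=10$); missing rather than a
  partial mean when fewer than $k$ targets exist;
- **lipid metrics**: fraction of neighbors that are lipid-loaded (e.g.
  LipidSpot⁺) macrophages, fraction of neighbor macrophages that are
  lipid-loaded, and distance to the closest lipid-loaded macrophage.

Phenotypes come from ordered first-match marker rules
(e.g. TRPC: FABP7 > threshold; M2-TAM: CD163 > threshold; else TSC), or
from top/bottom quantile gates.  Per-cell metrics are aggregated into
region-class summaries (per-ROI-then-pool or pooled-cells), with fold
changes and Welch t-tests between classes.

The DSP module computes signal-to-background (count / per-segment IgG
geomean), background-probe filtering, the four normalization factors
(housekeeping geomean, IgG geomean, area, nuclei), their concordance
(SD of log₂ factor ratios, the geNorm stability idea), and
scale-preserving normalization.

## Worked example

Generate a tissue with macrophage enrichment ρ = 2.5 inside tumor
niches, recover phenotypes from intensities, and quantify neighborhoods:

```python
from cellhood import SyntheticTissueConfig, generate_tissue, pipeline, group_stats

cfg = SyntheticTissueConfig(tam_enrichment=2.5)
sample = generate_tissue(cfg, seed=7)
analysis = pipeline.analyze_sample(sample)
summaries = group_stats.summarize_by_region(analysis.records, level="pooled_cells")
for cls, region in (("TRPC", "niche"), ("TSC", "background")):
    s = summaries[cls]
    print(f"{region}: TAM neighbor fraction {s.mean('frac_M2-TAM'):.3f}, "
          f"nearest TAM {s.mean('nearest_M2-TAM'):.2f} um (n={s.n_focal_cells})")
```

prints

```
niche: TAM neighbor fraction 0.485, nearest TAM 10.06 um (n=531)
background: TAM neighbor fraction 0.269, nearest TAM 16.94 um (n=1595)
```

The niche/background ratio of macrophage neighbor fractions, 1.806 here,
recovers the closed-form expectation
ρλ_TAM/(λ_tumor+ρλ_TAM) ÷ λ_TAM/(λ_tumor+λ_TAM) = 1.750 for this
configuration; nearest-macrophage distances are correspondingly shorter
inside niches (10.06 vs 16.94 µm).  The per-phenotype lipid-loaded
fractions in `analysis.lipid_fraction` land on the generator's
probabilities (e.g. 0.758 measured for niche tumor cells configured at
0.746).

The same stages are available from the shell:

```bash
cellhood simulate --seed 7 --out cells.csv --roi-out rois.csv
cellhood classify --cells cells.csv --rules rules.yaml --pixel-size-um 1.0 \
    --lipid-marker LipidSpot --lipid-threshold 4 --out classified.csv
cellhood neighborhood --cells classified.csv --rois rois.csv \
    --focal TRPC,TSC --targets M2-TAM --lipid-tam-label M2-TAM \
    --out-cells records.csv --out-summary summary.csv
cellhood dsp-qc --counts counts.csv --probe-meta probes.csv \
    --segment-meta segments.csv --out-prefix qc
```

## Layout

- `src/cellhood/tissue_io.py` — cell-table / ROI / summary I/O, unit and
  coordinate conventions
- `src/cellhood/phenotyping.py` — marker rules, quantile gate, lipid flag
- `src/cellhood/neighborhood.py` — radius queries, border exclusion,
  composition, nearest / k-nearest-of-type, lipid-neighbor metrics
- `src/cellhood/group_stats.py` — region summaries, fold changes, t-test
- `src/cellhood/synthetic_tissue.py` — niche-structured generator with
  ground truth and closed-form expectations
- `src/cellhood/dsp_qc.py` — profiler probe QC and normalization
- `docs/methods.md` — model, assumptions, parameter choices, limitations
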