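# polefrac

Quantification of polar fluorescent protein clusters and single-cell
motility metrics in rod-shaped bacteria.

Many rod-shaped bacteria — *Myxococcus xanthus* being the classic example —
polarize their motility machinery: regulators of type IVa pili accumulate
in clusters at the cell poles, and the asymmetry of that accumulation
determines which pole leads during movement and inverts when the cell
reverses.  Microscopy studies of these systems quantify, for hundreds of
segmented cells per strain, how much of the total cellular fluorescence
sits in clusters at each pole, and complement this with single-cell
motility assays (speed per frame interval, reversals per recording window).
`polefrac` is a tested, reusable implementation of that analysis for anyone
with labelled cell masks (e.g. from Oufti or MicrobeJ) and matching
single-channel fluorescence images, or with single-cell trajectory tables.

## The model

For each segmented cell the pipeline derives a medial axis running pole tip
to pole tip, defines two polar caps (by default the outer 1/6 of the axis
at each end), and estimates the cytoplasmic fluorescence level from the
mid-cell pixels.  A **polar cluster** is an 8-connected group of at least
3 pixels inside a cap whose mean background-subtracted fluorescence is at
least 2 SD above the mean cytoplasmic fluorescence.  Pole 1 is, by
definition, the pole with the higher total cluster fluorescence.  For every
cell with at least one cluster the **asymmetry index**

    ω = (pole1 − pole2) / (pole1 + pole2)

is computed from the total cluster fluorescence at the two poles, and cells
are binned as

| category           | rule        |
|--------------------|-------------|
| unipolar           | ω > 0.9     |
| bipolar asymmetric | 0.9 ≥ ω ≥ 0.2 |
| bipolar symmetric  | ω < 0.2     |
| diffuse            | no polar cluster detected |

Population summaries report the percentage of cells per category and the
mean polar / cytoplasmic fluorescence fractions over all cells (with and
without clusters), per replicate and pooled as the mean of replicate means.
Significance testing uses the two-tailed Student's t-test for samples with
equal variances.

Motility metrics follow the standard assay conventions: speed per 20-s or
30-s frame interval in µm/min, reversals (direction changes > 120° that
persist ≥ 2 intervals) per 15-min window, and the inclusion filter that
keeps only cells that moved in every interval of the recording.

A ground-truthed synthetic generator (`polefrac.simulate`) renders
spherocylindrical rod cells (~0.5 × 5–7 µm at 0.06 µm/px) with diffuse
cytoplasmic signal, zero/one/two polar Gaussian spots of exact intensity
fractions, Poisson shot noise and Gaussian read noise, plus constant-speed
trajectories with programmed reversals — so every pipeline stage can be
validated against exact truth without microscope data.

## Worked example

`examples/01_simulate_and_quantify.py` simulates 40 cells carrying 35% of
their fluorescence at one pole and 15% at the other (true ω = 0.4) and
quantifies them:

```
quantified 40 cells (0 excluded)
 cell_label     total  pole1_pct  pole2_pct  cytoplasmic_pct  omega           category
          1 50032.343     37.531     16.896           45.573  0.379 bipolar_asymmetric
          2 49798.271     37.872     17.360           44.768  0.371 bipolar_asymmetric
...
category counts (true pattern is bipolar asymmetric, omega = 0.4):
bipolar_asymmetric    40

mean omega           : 0.378   (truth 0.400)
mean % at both poles : 54.5   (truth 50.0 plus the diffuse signal under the cluster footprint)
```

All 40 cells land in the true category; the polar percentages are a few
points above the spot fractions because, by default, cluster totals are raw
background-subtracted sums and therefore include the diffuse signal lying
under the cluster footprint (pass `subtract_cytoplasm=True` to remove it).
The other examples cover population aggregation with the t-test
(`02_population_summary.py`) and motility metrics
(`03_motility_metrics.py`).

Real data enters through the same functions:

```python
import polefrac as pf

mask  = pf.read_labeled_mask("cells_mask.tif")   # 0 = background
image = pf.read_image("gfp_channel.tif")
cells, skipped = pf.quantify_image(image, mask)  # one row per cell
```

or through the CLI (`polefrac simulate | quantify | aggregate | tracks`),
which writes CSV tables plus a manifest with the configuration, seed and
input hashes for reproducibility.

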