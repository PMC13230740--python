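# fishflow

Sequential smFISH multiplexes RNA species over time: each hybridization
round binds a fluorescent readout probe against one gene, images every
field of view, and strips the signal before the next round. Automating
this demands two things working together — a fluidic controller that
exchanges buffers and hands off to the microscope round after round, and
an analysis pipeline that turns the resulting multi-round image stacks
into registered, quality-controlled spot tables and cell-level expression
profiles.

`fishflow` implements both halves against **fully simulated** hardware
and data, for people building or validating such platforms: the fluidic
run engine executes declarative run specifications on a simulated rig
(valve, peristaltic pump, flow sensor, 96-well plate robot) with
file-based or TTL acquisition handshakes, and the analysis side provides
the round-wise pipeline — spot detection, drift registration, cross-round
colocalization, focus scoring, and cell typing — scored end-to-end
against the synthetic generator's ground truth.

## The core computations

- **Spot detection.** RNAs appear as diffraction-limited spots. Stacks
  are filtered with a negated Laplacian-of-Gaussian at the PSF scale
  σ = (σ_lat, σ_ax); spots are local maxima of the response above a
  threshold chosen automatically from the stable plateau of the
  count-vs-threshold curve, refined to subpixel precision by 3-point
  parabolic fits. Per spot, the background mean μ_bg and SD σ_bg come
  from an annulus (3σ–5σ) on the spot's central plane, and
  SNR = (I_peak − μ_bg) / σ_bg.
- **Drift registration.** Stage drift between rounds is a global lateral
  translation (ΔX, ΔY), estimated by phase cross-correlation on binary
  spot maps or maximum-intensity projections, with upsampled subpixel
  refinement and a peak-ratio confidence score.
- **Colocalization.** Registered spot sets from two rounds are matched
  one-to-one by the Hungarian algorithm on 2D Euclidean distances (pairs
  beyond 4× the threshold forbidden); pairs closer than the threshold
  (default 0.5 µm) count as colocalized, reported as a percentage of the
  query round's spots. Cross-gene matching is the specificity control.
- **Focus scoring.** Per-nucleus sharpness uses the Helmli–Scherer
  mean-ratio contrast R = max(I/μ, μ/I) with a local mean μ over a 7 px
  window; the z-plane maximizing the mean R over the nucleus bounding box
  is its focal plane, and a composite image stitches best planes together.
- **Cell typing.** Spots are assigned to their nearest nucleus (≤ 5 µm)
  to build a gene-by-cell count matrix; cells are typed by cosine
  distance d(x, c) = 1 − x·c / (‖x‖‖c‖) to reference centroids, accepting
  a call only when d < 0.8 and the cell has > 10 RNAs.
- **Fluidics.** A YAML run spec declares buffers (syringe ports or plate
  wells, capacity 2 mL, optionally templated per round), flush / incubate
  / image steps, and per-round conditions. The simulated rig executes it
  in simulated time, monitors flow for anomalies, and logs every event.

## Worked example

Simulate a 6-round, 2-gene experiment (genes alternate rounds, 90%
re-detection probability, up to 4 px drift per round) and run the QC
pipeline on the rendered TIFFs:

```python
from fishflow import simkit, pipeline

cfg = simkit.SimConfig(
    n_rounds=6, n_cells=6, field_shape=(9, 256, 256), seed=0,
    genes={"XPO1": {"hela": 15.0}, "KIF1C": {"hela": 15.0}},
    redetect_prob=0.9, drift_per_round_px=4.0,
)
stacks, truth = simkit.generate_experiment(cfg)
simkit.write_dataset("demo/data", stacks, truth, cfg)

report = pipeline.run_qc(pipeline.AnalysisConfig(data_dir="demo/data", out_dir="demo/qc"))
print(report.round_summary[["gene", "round", "n_spots", "intensity_median", "snr_median"]])
print(report.coloc[["gene", "round", "n_query", "n_matched", "percent"]].dropna())
```

```
 gene  round  n_spots  intensity_median  snr_median
KIF1C      2       75             136.9        12.6
KIF1C      4       76             131.0        12.2
KIF1C      6       78             128.6        12.1
 XPO1      1       79             141.4        13.3
 XPO1      3       74             129.0        11.9
 XPO1      5       78             120.0        11.6

 gene  round  n_query  n_matched  percent
KIF1C      2       75         75    100.0
KIF1C      4       76         68     89.5
KIF1C      6       78         70     89.7
 XPO1      1       79         79    100.0
 XPO1      3       74         67     90.5
 XPO1      5       78         70     89.7
```

Spot counts are stable across rounds while the median intensity decays
slowly (the generator's 2%/round probe loss); each gene's later rounds
colocalize with its first round at roughly the configured 90%
re-detection rate, and the cross-gene control sits at the chance level
for this density (`report.cross_gene` prints 7.6% here) — the signature
of a healthy sequential run. A fluidic run is executed the same way from
the CLI:

```sh
fishflow run-experiment --spec run.yaml --trigger ttl --seed 3 --log run.jsonl
```

The remaining subcommands (`simulate`, `reformat`, `detect`, `register`,
`coloc`, `focus`, `type`, `qc`) wrap the corresponding library modules.

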