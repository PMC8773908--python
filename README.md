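# circfish

A Python toolkit for the computational side of **circFISH** — two-channel
single-molecule FISH that images circular RNAs distinctly from their linear
isoforms in the same cell.

Exonic circRNAs share their entire sequence with the linear transcript, so no
single probe can tell the isoforms apart. circFISH resolves them with two
probe sets: **PC** probes tile the exon(s) retained in the circle (binding
both isoforms) and **PL** probes tile exons found only in the linear
transcript. After hybridization every full-length linear molecule emits in
both channels; a circRNA emits only in the PC channel; a degraded linear
fragment that kept only the PL region emits only in the PL channel. The
analysis is therefore geometric: detect diffraction-limited spots in 3D in
each channel, and call a PL–PC pair within **250 nm** one linear molecule, an
unpaired PC spot a circRNA, and an unpaired PL spot a fragment.

The package provides, as importable modules and a `circfish` CLI:

* **probes** — partition a transcript into PC / PL target regions and
  greedily tile 18–20 nt antisense probes under the smFISH design rules
  (GC in [35%, 55%], ≥ 2 nt between binding sites, ≥ 15 probes per set,
  closed-form capacity `floor((L + g) / (l + g))` for target length *L*,
  probe length *l*, gap *g*).
* **simulate** — synthetic two-channel z-stacks (16 slices, 200 nm apart,
  130 nm pixels by default) with exact ground truth: elliptical DAPI nuclei,
  per-cell Poisson molecule counts with class-specific nuclear fractions,
  anisotropic 3D Gaussian PSFs, channel co-emission for linear molecules,
  Poisson + read noise, plus in-silico RNase R digestion (exponential decay,
  circles long-lived) and shRNA knockdown scenarios.
* **detect** — scale-normalized anisotropic Laplacian-of-Gaussian spot
  detection with plateau-based automatic thresholding and subpixel 3D
  localization in nm.
* **classify** — greedy one-to-one nearest-pair matching within 250 nm and
  linear / circular / fragment calls; independent per-channel counting for
  RNase-R multiplexed samples.
* **quantify** — DAPI nuclear segmentation (Otsu + watershed), nearest-nucleus
  cell territories, per-cell counts, nuclear/cytoplasmic fractions, 95%
  confidence intervals (1.96 × SEM) and pooled-variance Student's t-tests
  with `***` / `*` / `ns` calls.

## Worked example

```python
import circfish as cf
from circfish.detect import spots_to_frame

cfg = cf.SimulationConfig(field_shape=(16, 512, 512), n_cells=6, rng_seed=42)
nuclear, cells = cf.generate_cells(cfg)
gt = cf.sample_molecules(cfg, nuclear, cells)
stack = cf.render(gt, cfg)

params = cf.DetectionParams(threshold="auto")
pl = spots_to_frame(cf.detect_spots(stack["PL"], params, cfg.voxel_size_nm, "PL"))
pc = spots_to_frame(cf.detect_spots(stack["PC"], params, cfg.voxel_size_nm, "PC"))
result = cf.classify(cf.match_spots(pl, pc), pl, pc)
print("truth:     ", gt.class_counts())
print("classified:", result.counts)
```

prints

```
truth:      {'linear': 165, 'circular': 59, 'fragment': 17}
classified: {'linear': 164, 'circular': 57, 'fragment': 17}
```

i.e. 241 molecules across 6 cells recovered with three errors, all from
molecules lying closer than the optical resolution. Quantification and a
scenario comparison continue from the same objects:

```python
maps = cf.segment_nuclei(stack["DAPI"])
annotated = cf.assign_spots(result.to_frame(), maps, cfg.voxel_size_nm)
counts = cf.per_cell_counts(annotated, maps)
print(cf.localization_fractions(counts).round(3).to_string(index=False))

gt4 = cf.apply_rnase_r(gt, 4.0)   # 4 h in-silico RNase R digestion
stats = cf.summarize({"control": cf.counts_from_ground_truth(gt),
                      "rnase_r_4h": cf.counts_from_ground_truth(gt4)}, min_cells=1)
print(stats.summary())
```

```
   class  n_cells  nuclear_fraction  ci95_halfwidth  cytoplasmic_fraction
  linear        5             0.260           0.075                 0.740
circular        5             0.443           0.124                 0.557
fragment        5             0.240           0.220                 0.760
Per-condition mean molecules per cell (95% CI half-width):
  control        linear    n=6        27.50 ± 4.69
  control        circular  n=6         9.83 ± 3.48
  ...
Pairwise Student's t-tests (pooled variance, two-sided):
  control vs rnase_r_4h     linear    t=  10.987  p=6.66e-07  ***
  control vs rnase_r_4h     circular  t=   0.137  p=0.894  ns
  control vs rnase_r_4h     fragment  t=   3.639  p=0.00454  *
```

The linear isoform is mostly cytoplasmic while the circle splits between
compartments, and digestion wipes out linear molecules (`***`) while leaving
circles unchanged (`ns`) — the behaviour the two-probe design exists to
demonstrate.

The same stages are available from the shell:

```sh
circfish design-probes --fasta t.fasta --exons exons.tsv
circfish simulate --out scene/ --seed 7
circfish detect --stack scene/stack.tif --channel PC --out pc.csv
circfish classify --pl pl.csv --pc pc.csv --out classified.csv
circfish quantify --classified classified.csv --dapi scene/stack.tif --out out/
circfish run-all --config pipeline.yaml
```

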