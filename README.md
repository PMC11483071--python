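# planeye

Image-quantification and spatial-mapping tools for planarian eye biology.

Planarian eyes sit close together and their cells pack tightly, so counting
differentiated photoreceptor neurons (*opsin*⁺ cells) by hand is
impractical, and because planarians lack a fixed body size, positions of
ectopic eyes and migratory eye progenitors cannot be compared across
animals in raw pixels. `planeye` addresses both problems for researchers
quantifying eye-patterning phenotypes (e.g. after RNAi):

1. **Counting.** From a two-channel confocal z-stack (nuclear stain +
   marker FISH), slices are sampled every Δz = 5 µm, nuclei are segmented
   in 2D per slice, and a nucleus is called positive when its median
   marker intensity exceeds a global Otsu-derived threshold T:

   N = Σₖ #{ ROI on slice zₖ : median(I_marker | ROI) > T },  zₖ = k·Δz.

   N is an abundance index summed across the stack; treatment groups are
   compared with an unpaired two-tailed Student t-test, and a robustness
   sweep over T·{0.9, 1.0, 1.1} and Δz ∈ {2.5, 5, 7.5, 10} µm verifies the
   sign of the group difference is parameter-independent.

2. **QC.** Detections are matched to annotations within a radius and
   scored with the cell-level Jaccard similarity index
   JSI = TP/(TP+FN+FP), compared between treatments.

3. **Mapping.** Each animal's left/right eye landmarks define a similarity
   transform sending them to (−1, 0) and (1, 0), so any point is expressed
   in units of one-half the inter-eye distance with y > 0 anterior. This
   common frame supports scatter overlays, counts of anterior ectopic
   eyes, and dose-response comparisons of the posterior-most ectopic eye
   position.

A synthetic-data module generates ground-truthed confocal-like stacks and
landmark populations with known spatial distributions, which is how the
whole pipeline is validated end to end.

## Worked example

Simulate a two-group experiment (8 control vs 8 treated animals whose true
positive-cell numbers differ by 1.5×), count, and compare:

```bash
planeye simulate --out fixtures --seed 1
planeye count --fixtures fixtures --out counts
planeye sweep --fixtures fixtures --out sweep
planeye map --landmarks fixtures/landmarks.csv --out mapped
```

The `count` step prints

```
control mean 8.62 vs rnai mean 12.38: t=-5.530, p=7.413e-05
```

i.e. the per-sample summed positive counts average 8.62 in the control
group and 12.38 in the treated group, and the pooled t-test rejects
equality (t = −5.53, 14 df). The `sweep` step prints

```
sweep signs across grid: [-1]
```

meaning the control-minus-treated difference is negative in every one of
the 12 grid cells (3 threshold multipliers × 4 sampling intervals) — the
detected increase is not an artifact of the chosen threshold or slice
width. `mapped/summary.json` contains the per-condition normalized point
summaries and the posterior-most-eye comparison; `counts/manifest.json`
and each `run_manifest.json` record every parameter, seed and file hash
that produced the outputs.

The same operations are available as a library (`planeye.marker_quant`,
`planeye.qc`, `planeye.spatial_mapping`, `planeye.synthetic_data`,
`planeye.io_formats`, `planeye.segmentation`); see `docs/methods.md` for
the models, conventions and defaults.

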