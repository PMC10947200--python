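# skinquant

Quantitative immunohistochemistry (IHC) analysis of inflammatory skin
disease biopsies. Brightfield DAB-stained sections are analysed with two
semantic-segmentation models applied in sequence — one labelling skin
tissue compartments (epidermis, dermis, follicle/artefact, background),
one labelling positively and negatively immunostained cells — followed
by artefact-aware post-processing and per-compartment quantification of
the primary endpoints: the percentage of positive cells and the average
stain signal inside and outside the epidermis.

The package is for dermatology researchers who quantify protein markers
(Ki67, γ-H2AX, cyclin B1/D1, filaggrin, loricrin, …) in skin biopsy
sections and want the counting to be automated, deterministic and
auditable, rather than done slide by slide in a viewer.

## What it computes

For each section image the pipeline runs:

1. **Tiling & preprocessing** — the slide is traversed region by region
   (700×700 px tiles for tissue, 300×300 px for cells) from top left to
   bottom right; tiles of bare glass are skipped; tiles are
   colour-normalized by Reinhard mean/std transfer in CIELAB.
2. **Tissue segmentation** — per-pixel classes 1=epidermis, 2=dermal
   papilla/dermis, 3=follicle/gland/artefact, 4=background; binarized to
   an epidermis mask.
3. **Cell segmentation** — classes 1/2 positive/negative membrane,
   3/4 positive/negative nucleus, 5 other.
4. **Stain thresholding & fusion** — an adaptive (local-mean) threshold
   on the grayscale image marks dark DAB pixels; the cell and stain
   masks are fused into a {0,1,2} raster (1=positive, 2=negative cell),
   where the stain mask may promote a model-detected cell to positive
   but never invents cells.
5. **Post-processing** — connected objects ≤ 100 px are removed as
   noise; touching cells are split by marker-controlled watershed on the
   negated distance transform.
6. **Quantification** — instances are assigned to epidermis or dermis by
   their centroid; the endpoints are

   pct_positive = 100 · n_pos / (n_pos + n_neg)   (per compartment)
   avg_signal  = mean(255 − grayscale)  over positive-cell pixels

   with cohort summaries as medians and interquartile ranges.

Validation mirrors standard segmentation practice: GlobalAccuracy,
MeanAccuracy, MeanIoU, WeightedIoU and Mean Boundary-F1 from a pooled
confusion matrix, under repeated random 60/20/20 (or 70/25/5)
train/test/left-out splits.

Two segmentation backends are provided behind one interface: a
deterministic colour-rule oracle (exact on the synthetic generator's
sections — the reference for tests) and a trainable multi-scale pixel
classifier (Gaussian context features at several scales feeding a small
MLP) that learns the task from annotated tiles on a CPU in seconds.
Because no annotated slides are publicly deposited, a synthetic-section
generator with pixel-exact ground truth (nuclear / cytoplasmic /
membrane staining patterns, follicle-like artefacts, configurable
positive fraction) stands in for real data throughout the test suite.

## Worked example

`examples/oracle_pipeline.py` generates a noise-free synthetic section
and runs the full pipeline with the oracle backend:

```
                 pipeline   ground truth
pos in epidermis        4             4
neg in epidermis        8             8
pos in dermis          10            10
neg in dermis          18            18
pct positive epi    33.33         33.33
avg signal          186.0         186.0
```

The pipeline's per-compartment counts equal the generator's ground
truth exactly: 4 of 12 epidermal cells are DAB-positive (33.33 %), and
the mean stain darkness over positive-cell pixels is 186 on the 0–255
scale. `examples/train_pixel_classifier.py` trains the learnable
backend on 40 synthetic tiles and prints

```
training loss: 0.5769 -> 0.0027
held-out GlobalAccuracy = 99.92%  MeanIoU = 99.90%
```

i.e. the trained model transfers almost perfectly to fresh synthetic
sections. The other examples cover the generator, repeated-split
validation and cohort aggregation. A thin CLI wraps the same library
calls: `skinquant synth | train | segment | quantify | validate | run`.

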