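# Methods

This note records the scientific and numerical choices behind
`skinquant`: what the pipeline assumes, which parameters matter, what
the synthetic generator does and does not emulate, and where the design
was genuinely open.

## Pipeline model

The analysis treats a brightfield DAB/haematoxylin section as a
composition of four tissue compartments (epidermis, dermis including
papillae, follicle/gland artefacts, glass background) containing
elliptical cells that are either DAB-positive (brown) or
counterstain-negative (blue-gray). Two per-pixel classifiers are
applied in sequence — tissue first, then cells — because compartment
membership is a property of context (a nucleus looks the same in
epidermis and dermis) while stain polarity is a property of local
colour. All coordinates are 0-based row-major with half-open windows
[x, x+w) × [y, y+h).

**Tiling.** Whole slides are processed as square tiles in strict
row-major order. Edge windows are clamped so they fit inside the slide
(the last column/row overlaps its neighbour), which is standard
whole-slide practice; on re-assembly the later tile in row-major order
wins in overlap zones, so every pixel gets exactly one code. A slide
smaller than the tile yields one window equal to the slide.

**Specimen filter.** A tile is "glass" when more than 95 % of its
pixels exceed luminance 240. These defaults encode the intent of
skipping empty regions; both are configurable since scanners differ in
background brightness.

**Colour normalization.** Per-tile Reinhard mean/std transfer in
CIELAB: each channel is centred, scaled by ref_std/src_std, shifted to
the reference mean and converted back to clipped 8-bit RGB. Channels
with source std < 1e-6 are set flat to the reference mean, which keeps
constant tiles defined and avoids division blow-up. The method is a
pluggable callable so a stain-vector (Macenko-style) normalizer can be
substituted; mean/std transfer was chosen as the common default for
per-block histology normalization. Idempotence holds to within half an
intensity level on channel means.

**Grayscale and stain threshold.** Luminance is ITU-R BT.601
(0.299 R + 0.587 G + 0.114 B, rounded). The stain mask is a
Bradley-style adaptive threshold: pixel < local window mean − offset,
with replicate-padded borders; the window defaults to the nearest odd
integer to tile_size/8. DAB is dark on a light background, so the dark
phase is foreground. Two offsets are used deliberately:

* generic dark-object detection: offset 10 (the package-wide default of
  `adaptive_threshold`);
* the *stain-fusion* step of the pipeline: offset 60.

The larger fusion offset reflects the chromogen physics: DAB product
sits far below the local mean (luminance ≈ 70–105 in our palette, and
similarly deep in real sections) while the haematoxylin counterstain is
a light blue (≈ 180–220). An offset midway between those contrasts
marks DAB while leaving counterstained nuclei unmarked, so fusion can
rescue genuinely stained cells the cell model missed without promoting
negative cells wholesale. With offset 10 essentially every visible
nucleus falls below the local mean and the promotion rule would erase
the positive/negative distinction.

**Fusion.** Cell-model codes {1,3} map to positive, {2,4} to negative
unless the stain mask promotes them to positive; code 5 (non-cell) is
never promoted — the threshold alone cannot create cells. This
one-way-promotion reading keeps the cell model authoritative for cell
*existence* and the stain mask authoritative only for *polarity*
upgrades.

**Noise removal and instance splitting.** 8-connected components with
area ≤ 100 px are removed (the cutoff is inclusive at exactly 100);
8-connectivity is the standard choice for nuclei. Touching cells are
split by marker-controlled watershed on the negated Euclidean distance
transform; markers are distance-transform maxima at least 5 px apart
within each component, and a component whose peak detection returns no
marker is kept whole rather than dropped, so foreground is conserved
exactly. Labels are relabelled contiguously.

**Quantification.** An instance belongs to the epidermis iff its
centroid pixel lies in the epidermis mask — cheap, deterministic and
unambiguous for convex nuclei; "dermal" means everything outside the
epidermis. An optional band-depth parameter restricts the dermal
compartment to a literal upper-dermis band (pixels within a given
Euclidean distance of the epidermis) for users who want that stricter
reading; by default the whole non-epidermal specimen is used because no
pixel definition of "upper dermis" is otherwise available. *Average
signal* is defined as the mean of (255 − grayscale) over all pixels of
positive instances — stain darkness on a 0–255 scale; this is an
interpretation (per-pixel, both compartments pooled) and is recorded as
such. Ratios over zero cells are reported as missing, never as zero,
and excluded from cohort order statistics with their exclusion count
reported. Cohort summaries are medians and IQRs (linear-interpolation
percentiles). An optional user-supplied exclusion mask (nonzero =
excluded) stands in for manual removal of residual artefacts: instances
touching it are dropped and counted.

## Segmentation backends

**Colour-rule oracle.** Nearest-palette-colour classification over the
synthetic generator's eight colours. Cell-coloured pixels carry no
tissue class; for the tissue task they inherit the class of the nearest
non-cell pixel (exact because generated cells sit wholly inside one
compartment with a clear margin). On noise-free synthetic sections the
oracle reproduces ground truth bit-exactly, which is what makes it the
reference predictor for the metric and pipeline tests.

**Trainable backend.** A multi-scale pixel classifier: per-pixel
features are raw RGB, Gaussian-smoothed RGB at σ = 1, 2, 4, 8 px
(growing receptive fields, the same multi-scale idea dilated
convolutions serve in encoder–decoder segmentation networks) and
gradient magnitude at σ = 1, 2 — 17 features — standardized and fed to
a small MLP (48, 24 hidden units). Training subsamples pixels with an
equal per-class cap (12 000 by default), which implements
inverse-frequency balancing of the heavily skewed class areas
(epidermis ≪ background). Epochs (default 15), learning rate (1e-3),
batch size (512) and the seed live in `TrainConfig`; the per-epoch loss
curve is kept on the model and decreases over training. Given a fixed
seed, training and prediction are bit-reproducible. Checkpoints are a
directory with a JSON config and a weights blob. The backend interface
is minimal (`predict_codes` on a tile) so a full encoder–decoder
network can be plugged in where GPUs are available.

## Synthetic sections

The generator emulates the geometry and chromatics the pipeline must
handle: a glass strip above an epidermal band whose lower boundary
undulates sinusoidally (dermal papillae; amplitude 0.07 and ~2.5 cycles
per width by default), dermis below, follicle-like elliptical artefact
blobs, and non-overlapping elliptical cells with configurable count
(40 per 300×300 section by default; 7 for 128×128 training tiles,
scaled by area), positive fraction (0.3 default) and staining pattern
(nuclear: stained nucleus; cytoplasmic: nucleus + touching halo;
membrane: detached ring). Additive Gaussian pixel noise (σ = 4 by
default) is applied after mask generation; masks are therefore exact by
construction. One seeded random stream is consumed in a fixed order
(layout, artefacts, cell geometry, polarity, noise), so identical
parameters give bit-identical sections.

Two geometric guarantees make end-to-end ground truth unambiguous and
are deliberate idealizations: cells keep a 3 px margin from compartment
boundaries, artefacts and each other (so each cell is one 8-connected
component in exactly one compartment), and nucleus semi-axes default to
6.5–9 px with a 110 px minimum footprint so genuine nuclei always
survive the 100-px noise cutoff. Real sections violate all of this —
cells touch, straddle the basement membrane, and small or cut nuclei
fall under the noise threshold — so passing the oracle-identity tests
demonstrates the correctness of the *computation*, not field accuracy
on real slides. Likewise the palette (background 245-ish, negative
blue-gray, positive brown, every pair ≥ 30 levels apart in some
channel) is far cleaner than scanner output; the trainable backend's
near-perfect held-out scores on synthetic tiles should be read as a
learning sanity check, not an accuracy claim for real IHC.

## Numerical choices

* Split arithmetic uses floor sizes with the left-out set absorbing the
  remainder — n_train = ⌊n·f⌋ etc. — which reproduces the published
  5009 → 3005/1001/1003 pattern; a 1e-6 epsilon inside the floor guards
  against float artefacts such as 560 × 0.7 = 391.99999999999994.
* Metrics: classes absent from both truth and prediction are excluded
  from class means (prevents 0/0); a class present only in the
  prediction contributes recall 0. Accuracy/IoU pool one confusion
  matrix across a test set; BF is averaged per image then over images,
  matching its per-image normalization. Which of pooled vs per-image
  averaging the convention "should" be is genuinely open; pooled is the
  default and the harness takes a tolerance/bf switch.
* Boundary pixels are class pixels with a 4-neighbour of a different
  class; the image border is not a boundary. Two empty boundaries score
  BF 1 (vacuous match — identical masks must score 100), one empty
  boundary against a non-empty one scores 0. The BF tolerance defaults
  to ⌈0.75 % of the image diagonal⌉, the conventional choice.
* The fold table's average row is the plain arithmetic mean of the fold
  rows (documented because published fold tables do not always average
  exactly).
* Degenerate inputs: empty masks quantify to all-missing endpoints;
  empty training sets, mixed vocabularies, out-of-vocabulary mask
  values (reported with value and first coordinate), non-odd threshold
  windows and zero-pixel confusion matrices all raise typed errors.

## Problem sizes in tests

The test suite and acceptance script run at desk scale: 300×300
synthetic sections (40 cells), 128×128 training tiles (7 cells), 40
training / 10 held-out tiles for the learning check, 12 tiles × 10
repeated splits for the harness. These sizes were chosen so the whole
suite exercises every code path in a few minutes on one CPU; the
pipeline itself takes 700/300 px tiles and arbitrary slide sizes.

## Known limitations

* No stain deconvolution into H/DAB channels; polarity rests on the
  cell model plus a grayscale threshold.
* Centroid-based compartment assignment can misassign a crescent-shaped
  instance whose centroid falls outside its own pixels; irrelevant for
  convex nuclei.
* The watershed can over-split strongly elongated objects (ridge-shaped
  distance transforms produce multiple seeds); the generator's mild
  ellipse eccentricity avoids this, real elongated cells may not.
* The trainable backend is a pixel classifier: it has no shape prior,
  and its context is capped by the largest feature scale (σ = 8 px).
* Proprietary scanner formats are rejected by design; convert to plain
  TIFF/PNG first.
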