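# Methods

## Foci quantification

The estimator treats staining, not spots, as the primitive. A red-plane
intensity threshold (absolute, on the [0, 1] normalized scale) defines
stained area; connected components (8-connected by default, matching
the common default of image-analysis environments) are measured, and
the foci count is AreaTotal divided by a trimmed mean of single-object
areas with floor(0.10·n) values removed from each tail. The trimmed
mean is insensitive to a minority of merged objects (which inflate the
upper tail) and single-pixel debris (lower tail); the quotient is
real-valued and is used as such in all averaging. Lists with fewer than
three objects cannot be trimmed and fall back to the plain mean; an
empty image has count 0 by definition.

Threshold comparison is `>=` so boundary pixels are kept — stated for
bit-exact reproducibility. Both defaults (red and blue threshold 0.1)
are exposed in `ThresholdConfig`.

Blue gating is object-level: a red object is kept in full if any of its
pixels overlaps blue staining, else removed in full. Pixel-level
intersection would truncate object areas and change AreaTotal
semantics; whole-object removal matches the intent of discarding
staining that lies outside nuclei/DAPI-positive regions. Consequence:
gating is monotone — enlarging the blue mask never removes objects.

Cell number is the count of blue connected objects of at least
20 µm² (configurable); a `cells.csv` override is supported for
manually counted images. Per-cell values are undefined, not zero, when
no cells are found.

Integer images are normalized by the dtype's full-scale value (255,
65535), never the observed maximum: an absolute threshold presumes a
fixed scale, and per-image max-scaling would make thresholds
incomparable across images. The acquired bit depth of the original
microscope images is not documented anywhere we could rely on, so
fixed-full-scale normalization is this package's assumption.

## Colocalization

An event is a connected component of (red ≥ t_r) ∩ (green ≥ t_g) with
area at least `min_coloc_area_um2` (default 0.25 µm², suppressing
single-pixel chance overlaps; no overlap-fraction rule is imposed).
Compartment is decided by the event centroid: nuclear if it falls in a
min-area-filtered DAPI nucleus, cytoplasmic if it falls in dim
DAPI-positive cytoplasm (`cytoplasm_threshold`, default 0.02 — any
appreciable DAPI signal — minus nuclei), else unassigned. Centroid
membership rather than full containment makes the call robust to
one-pixel boundary crossings.

Two incidence metrics are reported because they answer different
questions and differ whenever events co-occur in a cell: events per 100
cells, and percent of cells containing at least one event (events are
attributed to the nearest nucleus for the latter). The large-focus
criterion used for tissue sections — longest dimension ≥ 0.5 µm — is
implemented as the longer bounding-box side times the pixel size.

## Group statistics

Within each staining experiment every line's per-cell value is divided
by the experiment's average-control-cell value, computed by pooling all
control cells (cell-count-weighted mean over control lines), not by
averaging line means — "average control cell" refers to cells. After
normalization the cell-weighted control mean is exactly 1 per
experiment, and the statistic is invariant to any per-experiment
intensity scale. Normalized replicates from all experiments are
compared with an unpaired Student (pooled-variance) t-test by default;
Welch is available by flag since the original choice is not
documented. Zero-variance degenerate inputs are resolved by the means
(equal → p = 1, different → p = 0). Significance stars follow the
0.05/0.01/0.001/0.0001 convention; Benjamini–Hochberg adjustment across
metrics is offered separately and clearly labelled — raw p-values are
always reported.

RNAse arithmetic: percent reduction per group is
(untreated − treated)/untreated; the implied untreated case:control
ratio is [treated_case/(1−red_case)] / [treated_ctrl/(1−red_ctrl)].

## Splicing PSI

PSI = 100·incl/(incl+excl) per lane — invariant to lane loading. An
optional labeled-nucleotide correction (divide each band by its
product's labeled-site count) is off by default, since raw densitometry
proportions are the conventional readout. Lanes with both bands zero
are unquantifiable and dropped with a log message; an exclusion list
(sample, gene, replicate) supports omitting artifact lanes.
Single-isoform exons are representable as PSI 0/100 but should be
excluded from group tests by the caller.

Per-exon tests use per-patient replicate means. The severity regression
takes case patients only, computes each patient's unweighted mean PSI
over the significant-exon set, orders patients by it, and regresses
each gene's PSI on it by OLS; genes tracking overall severity get
positive slopes, anti-coupled genes negative. On complete data the
equal-weight average of slopes is exactly 1 (x is the mean of the
regressed variables). Disease-duration association uses Spearman rank
correlation (mid-ranks for ties, missing durations excluded).

## Fractionation and binding

Percent insoluble = 100·insol/(sol + sark_sol + insol), cancelling
loading; replicates are averaged per sample before group comparison.
Co-IP values subtract matched beads-alone background when provided,
flooring at zero (negative corrected signal is noise).

Gel shifts are fit to f = Bmax·P/(K_D + P) by nonlinear least squares.
The model treats total protein as free protein, valid when probe
concentration ≪ K_D (0.3 nM probe vs tens of nM K_D). Bmax is free
rather than fixed at 1 because shifts rarely reach completion; no Hill
coefficient is fit (no cooperativity is modelled). Initialization: K_D
at the concentration nearest half the maximal observed fraction bound,
Bmax at the observed maximum; up to five jittered restarts with a fixed
restart seed; optimizer tolerances are tightened to 1e-12 so noiseless
data invert to ~1e-7. Supershifted multimeric complexes are summed into
"bound" before computing fraction bound. Standard errors come from the
Jacobian covariance.

## Synthetic data

The generator emulates confocal fields of cultured cells: elliptical
DAPI nuclei (radius 3.1–3.9 µm for fibroblast-like cells, 3.8–5 µm for
astrocyte-like, intensity 0.5–0.9) surrounded by a dim DAPI-positive
cytoplasm ring (width 1.8 µm, intensity 0.04–0.06, above the 0.02
cytoplasm threshold and below the 0.1 nucleus threshold); red and green
foci as disks with Poisson per-cell counts and lognormal radii (CV
0.15 — heavy-tailed enough to exercise the trimmed mean); Gaussian
background noise (sd 0.01) clipped to [0, 1] and snapped to the uint16
grid so that written TIFFs round-trip bit-exactly. All rendered disks
are kept disjoint by rejection sampling; when a crowded cell exceeds
its overlap budget the focus is dropped, a warning is emitted, and the
truth tables reflect only placed objects. Foci intensities (0.3–0.8)
sit strictly above the 0.1 threshold so that recovery failures indict
the measurement, not the rendering; the `dim` preset deliberately
straddles the threshold.

Preset effect sizes are the study conditions the package is calibrated
to: fibroblast cohorts plant a case:control foci-per-cell ratio of 1.8
and stained-area ratio of 2.8 (7 patient and 5 control lines, 4
experiments, 112 cells per line per experiment); astrocyte cohorts
plant 2.0 and 2.3 (one line per group, 3 experiments); the rnase preset
plants untreated means in ratio 2.7 with RNA-removable fractions 0.27
(control) and 0.76 (case), generating pixel-matched treated/untreated
pairs from the same random stream. Absolute per-cell rates (7, 12 and
20 foci per control cell respectively) are chosen so that nuclei hold
their foci without exceeding the non-overlap budget at realistic focus
sizes; the case focus radius is scaled by sqrt(area ratio / count
ratio) so both planted ratios hold simultaneously. A lognormal
per-(experiment, line) rate factor (CV 0.05) models staining-batch ×
line interaction; it is sized so the planted ratios remain identifiable
at the presets' cohort sizes. A persistent per-line biological factor
is deliberately not modelled: with one line per group it would be
confounded with the group effect and the planted ratio would be
unrecoverable by any analysis.

Randomness: one run seed; per-image substreams are derived from (seed,
experiment, line, image) indices, so generation is order-independent
and bit-reproducible.

What the generator does **not** emulate: optics (PSF blur, chromatic
shift), z-structure (inputs are assumed max-projected), autofluorescence
gradients, touching nuclei, partial cells at field edges, and spot
merging. Passing recovery tests therefore shows the algorithms are
correct on well-separated, well-focused specimens; they do not certify
performance on crowded or low-contrast real images, where the threshold
and the trimmed-mean assumptions do the real work.

Tabular generators mirror the densitometry workflows: band pairs are
(PSI, 100−PSI) scaled by a lognormal lane factor with multiplicative
noise; fraction tables plant per-sample percent insoluble with
between-sample and replicate noise under lognormal loading; binding
tables follow the one-site model over a 2-fold dilution series (to
640 nM for the lower-affinity preset, 160 nM for the higher-affinity
one) with Gaussian noise (sd 0.03) on fraction bound.

## Problem sizes

The recovery suites use the preset cohort sizes above (≈5400 cells for
the fibroblast cohort, ≈500 for the astrocyte cohort, ≈480 paired cells
for the rnase preset), 100 seeded titrations for the K_D bias check,
and 50 seeded cohorts for the splicing slope-sign check — sizes at
which the planted parameters are estimated with standard errors several
times smaller than the tolerances being checked.

## Known limitations

- The foci count is a ratio estimator; with heavy-tailed area
  distributions the trimmed mean sits below the untrimmed mean, so
  absolute counts run a few percent high. Group ratios are unaffected
  because the bias factor is common to both groups.
- Compartment classification is 2-D and centroid-based; genuinely
  overlapping nuclear/cytoplasmic signal in z cannot be resolved.
- The one-site fit reports Jacobian standard errors, which understate
  uncertainty when residuals are correlated across a titration.
- CSV schemas are fixed; arbitrary column mapping is out of scope.
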