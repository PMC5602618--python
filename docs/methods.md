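# Methods

`fundus-cdr` implements an automatic glaucoma-screening pipeline for color
fundus photographs of the optic nerve head: it segments the optic disc and
the optic cup, computes the horizontal and vertical cup-to-disc ratios
(HCDR/VCDR), and evaluates automated readings against panels of manual
graders with an outlier-filtering protocol. This note documents the model
and procedure choices, their parameters, and what the synthetic test bed
does and does not show.

## Pipeline

### Vessel extraction and inpainting

Blood vessels are thin, dark, curvilinear occluders; left in place they trap
the disc contour and distort the cup's intensity classes. The green channel
(highest retinal contrast) is smoothed with a Gaussian of σ = 1 px and a
black top-hat (morphological closing minus image) with a disk structuring
element responds to structures darker and thinner than the element. The
element radius is 7 px at a 512-px frame width and scales linearly with
width, tracking apparent vessel caliber across camera resolutions. The
response is binarized at a fixed 15 gray levels, which sits between the
smoothed noise residue and the response of a vessel of typical contrast
(≈40 gray levels below its surround). Otsu's rule remains available
(`threshold_rule: otsu`) but is bistable on the top-hat's long-tailed
response histogram — it either floods or keeps only vessel cores — and is
not the default.

Vessel pixels are then filled by iterated 3×3 diffusion: each pass convolves
with a normalized kernel (4-neighbours 0.1875, diagonals 0.0625, centre 0)
and resets unmasked pixels, so the hole converges to the kernel-harmonic
fill of its boundary values. The iteration cap is 100 passes or a maximum
per-pass change below 0.1 gray level; unmasked pixels are bit-identical to
the input, and filled values obey the discrete maximum principle. The test
suite checks the fill against a directly solved discrete Laplace system on a
5×5 hole (agreement within 2 gray levels).

### Disc localization and level-set segmentation

The inpainted green channel is multilevel-thresholded (k = 2) and the
largest connected component of the brightest class marks the optic nerve
head; components smaller than 0.05 % of the frame mean no localization —
a reported failure state, not an exception, matching the clinical reality
that a fraction of images cannot be processed. A square region of interest
(side = 0.25 × frame width) is centered on that component.

The disc boundary evolves under a morphological geodesic active contour on
the inverse-gradient edge indicator g = 1/√(1 + α|∇G_σ I|) with α = 100,
σ = 2 px, curvature smoothing 2, and an outward balloon force. The contour
starts from a circle inscribed at 60 % of the ROI half-side and stops at 300
iterations or when the fraction of sign changes per iteration drops below
10⁻³. The balloon stalls where the edge indicator falls below a threshold;
the adaptive default suits textured clinical images, and an explicit level
(≈0.3) is appropriate for flat synthetic scenes where the adaptive rule
degenerates.

Low-quality (nonmydriatic-class) frames take a second pass: the window is
re-centered on the first contour, split into left/right (nasal/temporal)
halves, each half re-evolved from the first contour's restriction, and the
union's largest component kept. The split axis is a design choice: disc
asymmetries are predominantly nasal/temporal.

### Cup segmentation: the four-loop cascade

Inside the disc ROI the cup is found by multilevel thresholding with an
interval Type-II fuzzy-entropy criterion optimized by Differential
Evolution, in a cascade of four loops with fixed settings — number of
thresholds k = 3, 2, 4, 3, with linear contrast enhancement (percentiles
1–99 stretched to full range) in the first two loops only. Each loop:

1. thresholds the (optionally enhanced) ROI and takes the brightest class;
2. discards bright spots below 50 px and keeps the largest surviving
   component (ties go to the component nearest the ROI centre);
3. restores vessel pixels that lie inside the spot's internal gaps (the
   region added by a morphological closing with a 6-px disk) — bridging cup
   parts split by a crossing vessel without following the vessel track
   outward — then closes residual pinholes (3-px disk) and fills holes;
4. fits a circle to the candidate's boundary by circular Hough voting over
   radii in [0.15, 0.6] × the disc-equivalent radius (anatomically plausible
   cup sizes). The accumulator is rescaled from per-circumference
   completeness to absolute votes so a short dense arc cannot outvote the
   true, larger circle. The circle's filled interior replaces the raw mask
   for all downstream area/centroid/extent computations.

A loop's result is rejected — triggering the next loop — when the candidate
area is at or below a floor, or the candidate touches the disc boundary
(8-adjacency to a non-disc pixel). The floor is 3000 px in the 2376-px-wide
reference frame and scales with relative frame area (an unscaled mode keeps
the literal constant). Both error conditions are checked on the pre-fit
candidate by default: the bounded Hough radius means a fitted circle can
never reach the disc rim, so checking the fitted circle (available as
`area_test_after_hough: true`) would disable the cascade's fall-through
behaviour. Exhausting all four loops is the cup-failure state.

### The entropy criterion

`k` thresholds partition the gray axis into `k+1` classes. Each class gets a
triangular primary membership (1 at the class centre, 0 at its boundaries)
whose half-width is widened/narrowed by a footprint-of-uncertainty width
(default 10 gray levels) into upper/lower memberships; the interval
membership is their average, normalized across classes at each gray level.

Two members of the family are implemented:

* **within-class form (default)** — the Kapur-type criterion: the sum over
  classes of the Shannon entropy of the class's membership-weighted
  within-class gray-level distribution. Its optimum separates intensity
  modes, which is what allows the brightest class to isolate the cup.
* **mass form** — the Shannon entropy of the normalized class masses. Its
  optimum balances class masses irrespective of valleys; on optic-nerve-head
  windows this provably drags the top threshold into the disc plateau (the
  cup holds ~12 % of ROI mass, far below any balanced share), inflating the
  brightest class to a near-disc-sized region for every k. It is retained
  (`form="mass"`) for comparison and for delta-histogram analyses, where it
  is better behaved than the within-class form.

The optimizer is DE/rand/1/bin (population 30, 100 generations, F = 0.5,
CR = 0.9, explicit seed) over real threshold vectors in [1, 254], sorted and
rounded at evaluation. An exhaustive integer search is the oracle: DE
matches it exactly for k ≤ 3 in the test suite. Label assignment counts
thresholds ≤ pixel value, so a pixel equal to a threshold joins the upper
class.

### CDR computation

The horizontal (vertical) extent of a mask is the inclusive pixel distance
between its furthest two member pixels along the column (row) axis; HCDR
and VCDR are cup-to-disc extent ratios. Ratios are not clipped at 1 — a cup
wider than the disc is a segmentation failure that the evaluation protocol
is designed to catch, not to hide. Areas are pixel counts; centroids are
arithmetic means of member-pixel coordinates.

## Evaluation protocol

Six per-image parameters are compared across graders: disc area, disc
centroid, cup area, cup centroid, HCDR, VCDR. All statistics use the
unbiased (n−1) sample SD — the convention validated against every
reproducible published worked example; centroid spread is the Euclidean norm
of the two per-coordinate SDs.

Per parameter, the outlier threshold is the mean over images of the
per-image SD among the six manual graders; the two CDR thresholds default to
the protocol constant 0.075. A marking is an outlier when its presence keeps
the per-image SD above threshold: while the SD exceeds the threshold and
more than three markings remain, the marking whose removal most reduces the
SD is flagged (ties: larger deviation from the mean, then lower grader id).
The remaining set never shrinks below three.

Images are eliminated when outliers concentrate: at least three flags on one
parameter, or at least four flags overall with at least two sharing a
parameter; three flags spread over three parameters keep the image. Four
flags on four distinct parameters — a case the published rules do not cover
— keep the image by the nearest rule. The HCDR analysis uses five parameters
(disc area/centroid, cup area/centroid, HCDR), the VCDR analysis swaps the
ratio, and the final analysis uses all six.

The automated reading is evaluated as a seventh marking joining the six
manual ones, and its flags count toward the elimination rules in its own
evaluation; manual graders are evaluated against the six-grader panel. An
entity is accurate on a tested (non-eliminated, localized) image when it is
flagged on no analysis parameter. Percentages are rounded half-up to one
decimal — the only rounding rule consistent with the published tables.
Pairwise agreement counts images co-accepted by both entities; the matrix is
symmetric with the total image count on the diagonal. A single image-level
elimination set per entity evaluation is computed; exact reproduction of the
published per-grader removal counts is not claimed, since those imply an
undocumented grader-dependent elimination rule.

## Synthetic test bed

The phantom renders what the pipeline actually relies on: a bright
elliptical disc (default semi-axes 52 × 48 px in a 512×512 frame,
brightness 150) containing a brighter concentric elliptical cup (brightness
200, axes set by the target CDRs), dark random-walk vessels (width 3 px,
darkness 40 below background) seeded at the disc centre, radial background
vignetting (level 60, 25 % falloff), Gaussian optics blur (σ = 1.5 px), then
additive Gaussian sensor noise, clipped to 8 bits. Three profiles mirror the
clinical frame sizes (2240×1488, 2376×1584 low-quality, 2743×1936) plus the
small test profile. Ground truth comes from the noiseless masks; everything
is bit-reproducible from the seed.

The grader simulator perturbs truth records per grader: multiplicative
log-normal jitter for areas (CV 0.05 — keeps areas positive, scale
proportional), additive Gaussian jitter for centroid coordinates (SD 2 px)
and CDRs (SD 0.03, matching the 0.02–0.06 inter-grader SD range of the
published worked examples). With a configurable probability per (image,
grader, parameter), the perturbation is replaced by a gross blunder of
magnitude `outlier_scale · jitter · (1 + |z|)` with random sign: bounded
away from zero, because a blunder indistinguishable from nominal jitter is
not a recoverable outlier, and an injected-outlier ledger is returned as the
recovery target.

Standard experiments (`fundus_cdr.experiments`):

* **Phantom suite** — twenty 512×512 phantoms, noise σ = 8, per-image CDR
  drawn uniformly from 0.35–0.65 (a clinically typical span within the
  cascade's anatomical Hough prior), generator seeds `base_seed + i`. The
  suite measures disc Dice, cup-cascade success, and median absolute
  HCDR/VCDR error.
* **Outlier recovery** — 500 analytic truth records, six graders, 10 %
  injection at scale 10. Mean-SD thresholds are calibrated on an
  outlier-free table drawn with the same jitters, so they reflect nominal
  inter-grader variability; the detector is then scored against the ledger.
  Self-calibration on the contaminated table is also available
  (`calibration="self"`): the gross contamination inflates the mean-SD
  thresholds severalfold, which raises specificity to ≈1 but hides outliers
  on small-area images (measured sensitivity ≈0.88 vs ≈0.99 under clean
  calibration). The clean-calibrated sensitivity and specificity are both
  reported. Note the protocol by construction flags the most deviant
  markings of any above-mean-SD image, so against an injected-blunder ledger
  its specificity is bounded well below 1 even with perfect behaviour.

What passing on phantoms does not show: real fundus images have textured
retinal background, peripapillary atrophy, uneven illumination and gentler
cup/rim transitions than the rendered plateau-and-ramp geometry, and real
grader error is not independent across parameters. Phantom results validate
the machinery and its contracts, not clinical accuracy; the published
clinical accuracies depend on the original image sets and manual markings
and are outside this package's reach.

## Numerical and degenerate-input choices

* Coordinates are 0-based (row, col); ROI windows half-open; extents
  inclusive.
* 16-bit rasters are rescaled by integer division of the full range
  (//257); single-channel images are replicated to three channels with a
  warning.
* A constant image cannot be localized (returned as failure); an all-true
  inpainting mask is an error (no boundary information); an empty mask has
  no extent or centroid (errors), while an empty cup yields a record with
  the ratios flagged absent.
* Hough radii are swept over integers; the reported circle is the absolute
  vote maximum; the filled interior uses radius + 0.5 so a fitted radius r
  reproduces the extent of a rasterized disk of the same radius.
* DE seeds derive from the pipeline seed (localization uses it directly;
  cup loop i uses seed + i), making every run reproducible end to end.

## Known limitations

* The cup boundary inherits an upward bias of a few pixels from the
  threshold landing on the cup-rim intensity ramp; on the standard suite the
  median HCDR error is ≈+0.06.
* The double level-set path assumes the first contour lands near the disc;
  a grossly wrong first pass is not detected before splitting.
* Vessel extraction targets occlusion removal, not vessel-tree morphometry;
  its mask is deliberately permissive near the disc.
* The evaluation protocol treats parameters as independent when counting
  outliers, as the published rules do; correlated failures (a bad disc
  contaminating both CDRs) are counted per parameter.
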