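# Methods

## The measurement problem

A pulse of a thymidine analogue (BrdU, EdU or TFdU) marks nuclei that were
synthesising DNA during the pulse. After detection chemistry and staining,
each nucleus yields a label-channel signal and a DNA-content signal (DAPI or
propidium iodide), measured either per segmented nucleus in micrographs
(image cytometry) or per event on a flow cytometer. The analysis questions
are always the same: how well do labelled and unlabelled nuclei separate,
what fraction of cells is replicating, and how do cells distribute over
G1/S/G2M.

## The R/non-R statistic

For N nuclei with labelled fraction F, the statistic divides the mean
signal of the (F − 0.1)·N most-labelled nuclei (the "R" trim set) by the
mean of the (0.9 − F)·N least-labelled ("non-R"). Trim-set sizes use
`max(1, floor(p·N))`; because the two trimmed fractions sum to 0.8, the
floor guarantees disjoint sets for every F ∈ (0.1, 0.9). F outside that
open interval is a hard error (the sets would be empty or overlap) rather
than being clamped. Sorting is descending and stable, so ties at a trim
boundary are resolved by original order — documented because it makes
results bit-reproducible. The floor is computed as `floor(p·N + 1e-9)`:
binary floats make e.g. (0.9 − 0.44)·100 = 45.999…986, which must count
as 46 nuclei. A zero non-R mean reports an infinite ratio with a flag
instead of raising.

Properties relied on by the tests: scale invariance (c·x gives the same
ratio), and an additive offset pulls any ratio > 1 toward 1 — which is why
the image branch subtracts the camera offset before computing statistics.

Separability uses a single documented constant: ratio ≥ 3 (the lower end of
the empirical 3–4 range) flags a population as cleanly separable. The
constant is a per-call parameter.

## Labelled-fraction estimation

`estimate_labelled_fraction` fits a two-component Gaussian mixture to
log1p(signal) (or applies Otsu on the same scale) and returns the fraction
of nuclei above the equal-posterior decision boundary. The mixture uses
k-means initialisation with a fixed seed, making the fit deterministic;
quantile-based starts were observed to split the dominant component into a
spurious local optimum when F is far from 0.5. If the standardised distance
between fitted component means is below 2 (or a component collapses), the
estimate carries a `low_separation` flag — weakly separated input (e.g. a
ratio-2 condition) is an unreliable-estimate situation, not an error.

## Cell-cycle profiling

S phase = label-positive events (threshold from the mixture boundary unless
supplied). Among label-negative events the two highest peaks of a smoothed
DNA histogram (96 bins, Gaussian kernel of 1.5 bins, zero-padded so edge
bins can peak) give the G1 and G2/M modes; the gate is the midpoint between
them. No Gaussian deconvolution of the DNA histogram is attempted — the
midpoint gate mirrors how such bivariate plots are gated in practice, and
deconvolution (Watson / Dean–Jett–Fox) is an explicit non-goal. Fractions
are event counts over N and therefore sum to 1 exactly. Fewer than two DNA
modes raises a `ProfileError` carrying the diagnostic histogram; an
all-positive population returns S = 1 with a warning instead.

## The population generator

The generator is the study-condition model, not a tuning dial:

- `n_cells` defaults to 10,000 (nuclei analysed per experiment) and
  replicate aggregation defaults to 3 independent seeded experiments,
  summarised as mean ± sample SD (n − 1).
- `f_labelled` defaults to 0.44, the labelled fraction after a 30-minute
  pulse; phase fractions default to (G1, S, G2M) = (0.40, 0.44, 0.16).
- Label–phase coupling (default on): labelled cells are S-phase and
  unlabelled cells draw from the renormalised (G1, G2M) mass, since only
  S-phase cells incorporate the analogue during a pulse. The switch
  `couple_label_to_s_phase=False` gives independent draws for studying
  mislabelling scenarios.
- DNA content = `dna_g1_mean` × ploidy × (1 + N(0, dna_cv)), with ploidy 1
  in G1, 2 in G2/M, uniform(1, 2) in S (no empirical intra-S distribution
  is assumed). Default CV 0.05; flow acquisition adds its own CV in
  quadrature (default 0.03).
- Label signals are lognormal: background in every nucleus (default mean
  100 AU, log-SD 0.35) plus, in labelled nuclei only, a specific signal
  (log-SD 0.5). Lognormality is a modelling assumption — the field does not
  report the intensity distribution family of real labelled nuclei; the
  log-SDs are fixed at values typical of immunofluorescence CVs (~36% and
  ~53%) and are not adjusted per condition.
- Nuclear radius ~ N(12, 1) px, scaled by √ploidy so nuclear area tracks
  DNA content and per-pixel DNA-stain brightness is roughly phase-independent
  (as for real chromatin); without this coupling a global threshold
  systematically truncates large dim nuclei.
- Geometry: the default jittered-grid layout guarantees non-overlapping
  discs (segmentation of overlaps is exercised separately with constructed
  fixtures); `layout="random"` allows overlap.

Protein channels (e.g. FUCCI-G1 Orange marking G1, FUCCI-S/G2/M Green) have
per-phase mean intensities with unit-mean lognormal cell-to-cell noise
(CV 0.25).

### Protocol effects and presets

Wet-lab protocol variants are represented purely multiplicatively:
`specific_scale`, `background_scale`, per-channel `protein_retention`, and
an exponential wash-decay `exp(−rate·time)` on the specific signal. The
observation behind the wash term is an inverse relation between signal and
washing time; the exponential form is chosen for positivity and
composability (applying two effects equals one effect with element-wise
multiplied scales), with the rate a free preset parameter (default preset
uses 0.02/min). Identity effects leave populations numerically unchanged.

Each preset names a documented condition and carries a target R/non-R
(e.g. B44/formaldehyde/20 mM HCl → 4.4; Bu20a/formaldehyde → 3.8;
B44/ethanol at 5 and 10 mM → 4.6 and 5.0; Bu20a/ethanol → ~6; 5-minute
BrdU pulse → ~4; 5-minute EdU → ~2; FUCCI acid treatment → green 60% /
orange 45% retention). Calibration is analytic: the measured label signal
is a two-component mixture — background lognormal, and specific+background
for labelled cells, the latter approximated by a moment-matched
(Fenton–Wilkinson) lognormal. The expected trimmed R and non-R means are
then closed-form partial expectations of the mixture above/below numerically
inverted quantiles, and the specific-signal mean is solved (Brent) so the
expected trimmed ratio equals the target. Simulated statistics at n = 20,000
match this expectation within a few tenths of a percent.
`params_for_separation` instead fixes the component-level mean ratio
(labelled measured mean / background mean), the quantity used in the
parameter-recovery grid.

## Image formation and quantification

Nuclei render as hard discs whose pixel sum equals `pixel_scale` × signal
exactly (per-pixel value divides by the disc's actual pixel count), followed
by Gaussian PSF blur, constant camera offset, optional Poisson shot noise
and Gaussian read noise, rounding to uint16 with clipping at 2¹⁶ − 1.
Analytically summable shapes are the point: every downstream tolerance can
be derived.

Segmentation is deliberately standard: Gaussian smoothing, Otsu (or fixed)
global threshold, 8-connected components, optional distance-transform
watershed split, minimum-area filter, consecutive relabelling. Quantification
reports mean and integrated intensity over all member pixels (no erosion)
and never subtracts the camera offset — offset handling is a statistics-layer
choice, and both corrected paths are exposed. The pipeline's default
image-branch replication signal is background-corrected **integrated**
intensity, the per-nucleus total directly comparable with a flow event;
mean intensity is available via `signal_measure="mean"` but divides by the
ploidy-coupled area, which deflates ratios relative to the flow branch.

Coordinates: origin at the top-left pixel centre, x = column, y = row.

## Numerical and reproducibility choices

- All randomness flows from explicit integer seeds; the pipeline derives
  per-stage child seeds from one config seed via `SeedSequence`, so a run
  re-executed from its saved YAML config is byte-identical (manifests record
  checksums, never timestamps).
- uint16 quantisation matters for fidelity checks: per-pixel signals of a
  few counts quantise visibly, so analytic-recovery tests render at a pixel
  scale giving ≥ 100 counts/pixel.
- Degenerate inputs: constant images under Otsu warn and return an empty
  segmentation; constant signal vectors give ratio 1; empty populations
  render to a constant-offset image and produce empty, schema-complete
  tables.

## Problem sizes

Simulation-based checks run at the documented condition sizes: 10,000
nuclei for statistics-only checks (recovery grid: 3 × 2 × 20 runs),
1,000–2,000 nuclei for rendered-image checks, 20 seeded runs for the
separability dichotomy, three replicates per condition for aggregation.

## Limitations

The simulator emulates the statistical structure the analysis assumes, not
microscopy realism: no chromatin texture, illumination gradients, optical
aberrations, 3D effects, doublets, debris, or spectral spillover; protocol
chemistry is collapsed into multiplicative attenuation. Passing tests
therefore demonstrate the correctness and calibration of the analysis
pipeline on data with known structure — not the performance of any wet-lab
protocol on real micrographs. Flow-specific artefacts (doublet
discrimination, compensation) are out of scope, as is DNA-histogram
deconvolution.
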