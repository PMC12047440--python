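# Methods

`rnpq` quantifies how LINE-1 ORF1p ribonucleoprotein (RNP) condensates
assemble on RNA and acquire DNA-binding activity. It implements the five
quantitative analyses such a study rests on — mass-photometry oligomer
deconvolution, cooperative hexamer-dissociation modeling, equilibrium
binding and competition, DNA-curtains event statistics, and a
randomized-spot 3D colocalization test — together with synthetic-data
generators that provide known ground truth for every stage. This note
records the models, their assumptions, the defaults, and the design
decisions taken where more than one reasonable choice existed.

## Mass photometry (`rnpq.massphot`)

**Calibration.** Landing-event contrasts are converted to masses by a
least-squares line through (median contrast, known mass) pairs of at least
two standard proteins. Default standard masses are configuration values,
not constants: BSA 66.5 kDa, ovalbumin 44 kDa, aldolase (tetramer)
158 kDa, the species in common gel-filtration HMW calibration kits. The
median is used rather than the mean so occasional aggregate landings do
not skew the line; a crude mode-count check warns when a standard's
contrast distribution looks multimodal.

**Histogram.** Masses are binned into exactly 100 bins of 8 kDa. The lower
edge defaults to 0 kDa (masses are nonnegative and the instrument floor is
near 40 kDa) and is configurable; out-of-range events are counted and
reported, never silently dropped. Savitzky–Golay smoothing (order 2,
9-bin span) is provided for visualization of low-abundance high-mass
species; peak fitting always runs on raw counts, because smoothing
correlates neighbouring bins and would bias fitted areas.

**Oligomer deconvolution.** The species grid is monomer / trimer /
hexamer / ">6": Gaussians initialized at 1, 3 and 6 times the monomer mass
(default 40 kDa) plus one unconstrained high-mass component for unresolved
higher-order oligomers. Peak means may move ±25% from initialization —
enough to absorb the mass shift of RNA-bound trimers and hexamers without
modeling the nucleic-acid mass explicitly. Species fractions are fitted
Gaussian areas over total area; fractions below a configurable floor
(default 1%) are reported as zero and the rest renormalized, so a
two-species sample cleanly reports two species. Fitting uses bounded
trust-region least squares; a warning fires when events are scarce
relative to the parameter count.

**Cooperative hexamer dissociation.** The trimer fraction versus RNA
concentration is fitted with the four-parameter Hill form
p₃(c) = f_min + (f_max − f_min)·cʰ/(K_halfʰ + cʰ), with free floor and
ceiling since neither endpoint is exactly 0 or 1 in practice. h > 1
captures cooperativity: RNA binding to one trimer of a hexamer promotes
dissociation and exposes the second trimer's binding site. The fit
requires a protein-only (c = 0) anchor and at least 5 points; h is bounded
to (0.1, 10) with a warning when it saturates.

**Footprint occupancy model.** One trimer occupies a 30-nt RNA footprint;
successive trimers repeat every 45 nt (a 15-nt linker). Capacity is
`0` below one footprint, else `floor((L − 30)/45) + 1`: 1 trimer at
30–74 nt, 2 from 75 nt — hence, among the tested 30/60/90/120-nt oligos,
90 nt is the first with room for two — and 44 on the 1970-nt curtain RNA.
The saturating monomer:RNA ratio is 3 × capacity (132 for 1970 nt; also
reported rounded to two significant figures, 130, the form such ratios are
usually quoted in).

## Equilibrium binding (`rnpq.binding`)

**Normalization.** Titrations are blank-subtracted (protein-free control)
and min–max scaled so the smallest value maps to exactly 0 and the largest
to exactly 1. The procedure is invariant to positive affine transforms of
the raw signal.

**Hill fit.** The fitted model is y = y0 + a·Pʰ/(K_dʰ + Pʰ). The free
baseline and amplitude absorb exactly the affine distortion that min–max
normalization introduces when a titration does not fully span the
transition; with a bare two-parameter Hill the top-of-curve pinning would
bias K_d low on under-saturated grids. Protein is treated as total, not
free: with 1 nM labeled oligo, depletion is negligible over the fitted
range. A depletion-aware quadratic isotherm
(`bound_fraction_depletion`, the stable root of
(P_T − PL)(L_T − PL) = K_d·PL) is available when the trace-ligand
assumption fails. h is fitted freely; concentrations keep the unit of the
input table (nM throughout), and K_d inherits it.

**Competition.** Two nucleic acids competing for one shared site are
solved exactly: conservation of P, L and C with mass-action complexes
reduces to one monotone equation in free protein, solved by bracketed
Brent iteration (relative tolerance 1e-13). With no competitor this is the
single-site isotherm to machine precision. The familiar closed form
K_d,app = K_d·(1 + C/K_dC) holds only in the negligible-depletion limit —
competitor abundant *and* weakly bound (K_dC much larger than free protein
at half-saturation). At the experimental concentrations (100 nM competitor
of K_d 3.9 nM), the titrated protein consumes the competitor
stoichiometrically and the exact half-saturation is ≈102 nM, roughly
K_d + bound competitor, far below the closed form's ≈503 nM. The package
reports both; the ideal-model fold change (1 + C/K_dC ≈ 26.6×) is a model
property, and the larger fold change observed in real competition
experiments is an empirical quantity the single-site model does not
predict — multivalent trimer binding is deliberately out of scope.

## DNA curtains (`rnpq.curtains`)

Event tables arrive with one row per binding event (upstream particle
detection is out of scope). Conventions: positions in kbp from the barrier
anchor, half-open bins [lo, hi), bin 0 at 0; sequence coordinates 1-based
inclusive in reports.

- **Events per DNA**: per experiment, total events over total DNA strands;
  mean ± SEM across experiments (≥3 in practice). Splitting an
  experiment's events across fields of view leaves the estimate unchanged
  when the strand counts are split accordingly.
- **Per-nM normalization and weighted averaging**: events/DNA divided by
  the labeled-RNA concentration in nM; the cross-experiment weighted
  average weights by the number of DNA strands observed per experiment,
  since the precision of each experiment's estimate scales with its
  observation count.
- **Two-color colocalization**: cross-channel events on the same DNA are
  greedily paired nearest-first within a position threshold (default
  1 kbp) and a start-time threshold (default 1 s ≈ one frame); both are
  configurable since they depend on optics and frame rate. A paired pair
  counts as one condensate; the fraction is symmetric under channel swap.
- **Position histogram**: fixed 24 bins × 2 kbp, matching the λ substrate
  (48.5 kbp); out-of-range positions counted and excluded.
- **Motif scan**: exact, overlapping occurrences, 1-based. Default strand
  policy is `both` (the endonuclease target is strand-defined, but
  curtains cannot distinguish strands); forward-only is available and the
  per-strand breakdown is always reported.
- **A/T enrichment**: the score is the mean windowed A/T fraction at the
  observed positions; the null redraws the same number of positions
  uniformly; p = (1 + #null ≥ obs)/(1 + N). Power requires genuine
  A/T-content structure along the substrate — on a homogeneous random
  sequence, base-level binding bias barely moves window-level scores.
- **Dwell-time survival**: product-limit (Kaplan–Meier) estimator with
  events persisting at movie end right-censored; the movie length is a
  required table attribute. Confidence bands are percentile bootstrap
  (default 1000 resamples, seeded), resampling events with replacement;
  the band always contains the point estimate. An independent
  implementation (lifelines) serves as a cross-check in the test suite,
  not as the estimator.
- **Kymograms** rasterize per-DNA traces into a position × time matrix;
  missing frames are background-filled and flagged.

## 3D puncta analysis (`rnpq.spots`)

**Detection** uses multiscale 3D Laplacian-of-Gaussian blob detection
(scikit-image) over a sigma range of the configured PSF sigma ±50%. The
image is centered and scaled by its robust noise (1.4826 × MAD) first, so
the threshold — a scale-normalized LoG response in noise-sd units, default
2.2 — transfers across intensity scales. A spot of peak SNR S responds at
roughly 0.25·S, so the default passes SNR ≳ 10 spots while staying above
the noise floor; detections closer than one blob radius merge (two spots
2 voxels apart at sigma 2 become one detection, by design).

**ROI assignment and compartments.** Spots take the label of the 2D cell
mask at their (y, x); label-0 spots are dropped and counted. Nuclear
versus cytoplasmic classification thresholds the per-spot mean
DNA-channel intensity over the measurement aperture, by default with
Otsu's method over all spot values in the image (the classification rule
is standard; the threshold value is not, so it is data-driven and
overridable). Nuclear spots are excluded from the colocalization
normalization, which targets cytoplasmic (cotranslational) RNP assembly.

**Randomized-spot null.** Per ROI, exactly as many random (y, x) positions
as detected spots are drawn uniformly from that ROI's pixel set; each
random z is drawn from the multiset of detected-spot z values *image-wide*
(the ROI is 2D, the detection 3D; the image-level draw follows the
procedure's wording). Intensities are measured over a spherical aperture
(radius 2 voxels — the measurement radius is a documented default, not a
derived quantity) and normalized per ROI by the median random-spot
intensity of the same ROI, making "1.0" mean "typical for this cell".
Detected and random distributions are compared with a two-sided
Mann–Whitney U test, pooled across cells.

**Chromatin colocalization** is the per-cell fraction of puncta whose
center falls inside a binary chromatin mask (configurable dilation,
default 0); cells with zero puncta are excluded and counted.

## Synthetic data (`rnpq.simulate`)

The generators emulate the measurement process of each stage with the
simplest noise models consistent with it: Gaussian mass noise on mixture
draws (with a matching standards set so the calibration round-trip is
exercised); Gaussian anisotropy noise over Hill or exact-competition
structure; Poisson per-DNA event counts, sequence-biased positions
(uniform, A/T-weighted, or motif-weighted), exponential dwell times
right-censored at movie end, and independent Bernoulli dual-color
labeling (no co-assembly model is assumed — the two-color fraction is a
free simulation parameter, not a prediction); and 3D Gaussian puncta of
configurable peak intensity over Gaussian background in disjoint
elliptical cells with rendered nuclei. One seeded generator drives each
dataset, with sub-streams spawned per cell/DNA so enlarging a dataset
never perturbs earlier entries; identical configuration and seed give
byte-identical outputs. Every generator emits a ground-truth record, and
all recovery tests read truth only from that record.

What the generators deliberately do not model: photophysics beyond
PSF + background (no bleaching, drift, or z-anisotropic PSF), condensate
fusion kinetics, cotranslational assembly, cell-shape irregularity, or
autofluorescence structure. Passing recovery tests therefore demonstrate
estimator correctness under the stated stochastic models, not robustness
to every artifact of real microscopy data.

The curtain substrate for full-scale runs is a *synthetic* λ-length
genome: 48,502 bp of random sequence at λ-like GC content, scrubbed of
spontaneous TTTTTAA occurrences and planted with exactly 12 target sites
(7 forward, 5 reverse-complement) at known positions. It matches the real
substrate in length, GC content and target-site count — not in sequence —
and exists so the motif scan and position analyses have exact ground
truth without any external download.

## Problem sizes and statistical conditions

Monte-Carlo recovery studies use 200 replicates (titration fits), 300
dwell times (survival), and 20,000 landing events (deconvolution) — the
scales at which the estimators' medians stabilize well inside the
tolerances asserted in the tests. The null calibration of the full
colocalization pipeline uses 200 seeded runs of 4-cell, 16×96×96-voxel
images with 10 spots per cell at peak SNR 10; this size keeps each run's
detection unambiguous while the per-run spot count (~40) leaves the
Mann–Whitney test enough resolution for a meaningful 5%-level calibration.
Anisotropy noise (sd 0.05) is quoted on the normalized signal scale.

## Known limitations

- The oligomer fit assumes Gaussian peaks on a linear mass axis; strongly
  overlapping species below one bin width apart are not resolvable.
- The competition module models one shared site per binding unit;
  multivalent trimers with three cleft sites are out of scope.
- The colocalization pipeline requires the 2D ROI mask as input; cell
  segmentation quality is the caller's responsibility.
- Sub-voxel spot localization is not attempted; position error is
  bounded by one voxel at adequate SNR.
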