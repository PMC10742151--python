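# Methods

This note documents the models, estimators and numerical choices behind
`aptaprobe`, and what the synthetic data do and do not emulate.

## Scattering model

Conformers are sets of point scatterers with positive weights
(coordinates in nm). The calculated intensity is the exact Debye sum
over unique pairs, `I(s) = Σ w_i² + 2 Σ_{i<j} w_i w_j sinc(s d_ij)`,
evaluated in pair chunks to bound memory; `sinc` switches to a 3-term
Taylor series for |x| < 1e-4 to avoid 0/0 cancellation. No atomic form
factors and no hydration shell are modeled: the χ²-ranking logic is
form-factor-agnostic, and unit point scatterers keep the oracle (an
O(n²) double loop) exact. Consequences: absolute intensities are in
arbitrary units, and high-angle detail beyond the bead resolution is
not meaningful — the optional `s_max` truncation in the fit options
exists for exactly that reason.

Structural parameters from coordinates are the weighted radius of
gyration about the weighted centroid and the maximum pairwise distance
(all pairs up to 2000 points, convex-hull reduction — still exact —
above).

## Fitting a model to a curve

The scale factor minimizing the reduced discrepancy χ² is
`c = Σ(I_exp·I_calc/σ²)/Σ(I_calc²/σ²)`; χ² divides by N−1. Identical s
grids are required everywhere — background subtraction refuses to
interpolate, because silent regridding changes σ and therefore every
downstream χ². A variant scale formula with first-power σ weighting and
I_exp² in the denominator circulates in print; it is implemented behind
`use_printed_formula=True` for comparison only and is not a
least-squares minimizer. No constant background term is fitted by
default. Ties in the per-conformer ranking go to the lowest model
label, which makes reports deterministic. Conformers that fail to fit
become flagged NaN rows rather than aborting the table.

## Experimental Rg and Dmax from a curve

* **Guinier fit**: weighted linear fit of ln I vs s² iterated to
  self-consistency with the window s·Rg ≤ 1.3 (at least 5 points).
  Weights are the delta-method (I/σ)². A positive low-angle slope
  raises an error; a flat curve yields Rg = 0.
* **Indirect transform**: p(r) on a fixed r grid (101 points) solving
  `I(s) = 4π ∫ p(r) sinc(sr) dr` by σ-weighted bounded least squares
  with endpoint constraints p(0) = p(Dmax) = 0, non-negativity, and a
  second-difference smoothness penalty of weight α. The penalty matrix
  is norm-scaled against the data matrix so α ≈ 1 balances misfit
  against curvature. α defaults to the elbow (maximum discrete
  curvature) of a 10-point logarithmic L-curve scan; the support scan
  below instead fixes α = 1, since only the χ² plateau is read off
  there and the elbow estimate is jittery under replication.
* **Dmax support scan**: candidate supports between 1.5× and 5× the
  Guinier Rg (12 candidates). Supports below the true Dmax truncate
  p(r) and fit poorly; the estimate is the smallest candidate inside
  the χ² plateau. Two refinements make the onset robust. First, the
  plateau band is the larger of 10% of the scan minimum and an additive
  2·√(2/(N−1)) — the standard deviation of a reduced χ² with N−1
  degrees of freedom — because the scan minimum is itself noise-biased
  low and a purely relative band can exclude the true support. Second,
  a candidate is vetoed when its p(r) piles more than 10% of its peak
  (mean over the outer tenth of the support) against the endpoint: the
  signature of truncation. If the estimate lands near the scan cap the
  cap is extended ×1.6 and the scan repeated (up to 4 times), which
  handles aggregates much larger than the Guinier window can resolve.
* **Reported Rg**: the real-space second-moment value
  `Rg² = ∫ r² p(r) dr / 2`, averaged over the accepted scan candidates.
  The Guinier estimate saturates once s_min·Rg exceeds the window limit
  (at s_min = 0.2 nm⁻¹ that is Rg ≈ 6.5 nm), while the real-space value
  stays accurate for larger particles; both are logged.

## Oligomeric-state call

Verdict `aggregation-suspected` iff the experimental Dmax exceeds
1.3 × the ensemble-mean Dmax, or the experimental Rg exceeds 1.3 × the
ensemble-mean Rg; otherwise `monomer-compatible`. The 1.3 default
separates a monomer-consistent ratio (≈1.0–1.15) from a genuinely
oligomeric one (≈1.9) with margin on both sides. The ensemble summary
uses unweighted means and sample standard deviations.

## Detector images and radial averaging

Pixels map to s through the flat-detector geometry (radial distance →
2θ → s = 4π sinθ/λ). Radial averaging bins pixels uniformly in s,
reports the plain bin mean with the standard error of the mean (floored
at machine epsilon), drops empty bins, and uses the mean pixel-s of the
bin as its abscissa. Polarization, solid-angle and flux corrections are
out of scope; the 2-D → 1-D round trip on a noiseless frame is accurate
to <1% with ~60 bins over the default geometry, limited by the
curvature of I(s) within a bin.

## AFM statistics

* **Flattening**: least-squares plane fitted to pixels below the 70th
  height percentile (objects sit above it), iterated with its mask to a
  fixed point so the operation is idempotent; the result is shifted to
  zero median. Scanner drift and line noise beyond a plane are not
  modeled or corrected.
* **Detection**: the threshold is k·(MAD×1.4826) of the raw flattened
  frame (k = 3), applied to a 3×3 box-mean copy. Smoothing suppresses
  single-pixel noise roughly threefold, so pure-roughness control
  frames produce empty object lists while real objects — wider than
  the filter — keep their mask connected and their height. 8-connected
  components with area ≥ 800 nm² become objects; height is the peak of
  the smoothed frame inside the component (a raw per-pixel maximum
  would be biased upward by roughness); components covering >5% of the
  frame are classified layered, the rest compact. For the default
  pixel size (≈20 nm) the 3×3 smoothing biases peak heights down by
  ~3–7% for objects of ≥80 nm lateral scale — negligible against the
  0.2 nm binning of ρ(h).
* **Statistics**: N400 = N·400/(n·S_fr); ρ(h) uses 0.2 nm bins (the
  reporting granularity of AFM height histograms) and always sums to
  100% on non-empty input; fractions above a threshold are computed
  from raw object heights, never from bins. The complex-formation call
  requires the above-threshold fraction to grow by ≥20 percentage
  points, far below a genuine complexation shift (≈80–95 points on the
  synthetic scenes) and far above control drift (≈0).

## Synthetic data: what it emulates, what it does not

* **Conformers** are semi-flexible self-avoiding bead chains (80 beads,
  0.4 nm bonds, directional stiffness 1.2, self-avoidance at ≥0.2 nm),
  sized so monomer Dmax falls in the ~7–19 nm range;
  `generate_sized_chain` narrows to the 9–11.5 nm study scale used by
  the recovery experiments, emulating a ~10 nm nucleic-acid monomer.
  Ensembles perturb the base chain with smooth random displacement
  fields (RMS 0.5 nm by default, 1.0 nm in the recovery experiments)
  and restore bond lengths by projection. There is no force field, no
  base pairing, no excluded-volume realism beyond the hard-core
  distance — these chains stand in for molecular-dynamics conformers
  only in their downstream role.
* **Scattering noise** is Gaussian with σ(s) = f·I(s)·(1 + s/s_max),
  f = 0.02 by default, mimicking the worse signal-to-noise at high
  angle; the σ column stores the model σ exactly, so the standardized
  residuals are N(0,1) by construction and the χ² calibration
  (mean ≈ 1 over replicates) is a genuine check of the fitting chain,
  not of the generator. Counting statistics, detector artifacts and
  buffer-subtraction systematics are not emulated.
* **Topography** frames are Gaussian roughness (0.2 nm RMS on chips,
  0.1 nm for controls) plus optional plane tilt, with compact objects
  as Gaussian caps truncated at 4σ and layered patches as
  cosine-edged plateaus. Tip convolution, scanner drift and line noise
  are not modeled, so passing detection tests bounds algorithmic
  errors, not instrument systematics.
* One integer seed drives every generator through named
  `numpy.random.Generator` instances; no global random state. The
  pipeline derives per-frame seeds from the master seed, and two runs
  with the same config are byte-identical.

## Problem sizes in the test suite and acceptance script

Monte-Carlo oracles use 4000-point sphere clouds (closed-form Rg and
p(r) to <1% and <2% relative RMS); calibration uses 500 noisy
replicates; recovery experiments use 100 replicates with 18–20-model
ensembles of 80-bead chains on 120-point s grids; AFM scenes use
256–512 px frames with 30–120 objects. These sizes keep the full suite
under two minutes while leaving each statistical assertion at least a
~2σ margin; they are choices of the package, documented here so larger
reruns are a one-line change.

## Known limitations

* Point-scatterer intensities cannot reproduce atomic-resolution χ²
  values from form-factor-based tools; rankings, not absolute χ², are
  the transferable quantity.
* Dmax from a curve is information-limited by s_min: distances beyond
  ≈ π/s_min (~16 nm at s_min = 0.2 nm⁻¹) are constrained only weakly,
  which is why the oligomer call uses Rg and Dmax in disjunction.
* The layered/compact cutoff (5% of frame area) is a pragmatic rule;
  morphologies near the cutoff are sensitive to it.
* The indirect transform reports the regularized point estimate of
  p(r) without error bands.
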