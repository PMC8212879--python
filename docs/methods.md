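# Methods

## The angular model and its assumptions

The P-SHG fit assumes each pixel contains an effectively cylindrically
symmetric (C∞v) distribution of harmonophores lying in the image plane, probed
under Kleinman symmetry (χ_XZX = χ_ZXX). The detected SHG intensity as the
excitation linear polarization angle θ rotates is then

    I(θ) = A · { sin²[2(θ−φ)] + [ sin²(θ−φ) + b·cos²(θ−φ) ]² } + c

with two independent tensor elements entering only through their ratio
b = χ_ZZZ/χ_ZXX, an in-plane fiber orientation φ, an amplitude A and an
additive background c. This is the canonical single-ratio angular response for
collagen; it is the single most consequential modeling choice in the package,
and everything downstream (pitch angles in particular) inherits it. Out-of-
plane fiber tilt, non-Kleinman (complex) tensor components and polarization
distortion by the optics are not modeled.

Useful analytic consequences, all exercised by the tests: I(φ)/I(φ+90°) = b²
when c = 0; the response is 180°-periodic; and at b = 1 the cos2(θ−φ) harmonic
vanishes, leaving a 90°-periodic signal in which φ is identifiable only modulo
90° (the fitter may legitimately return φ ± 90° there).

The effective α-helical pitch angle of the emitting peptide dipoles follows
from the single-axis molecular picture as θ_p = arctan√(2/b), strictly
decreasing in b, with θ_p(2) = 45°.

## Per-pixel fitting

Each pixel's angular response is fitted by bounded nonlinear least squares
(`scipy.optimize.least_squares`, b ∈ [0.05, 10], A ≥ 0, c ≥ 0, φ free and
wrapped to [0°, 180°)). The orientation is initialized from the discrete
cos 2θ Fourier phase of the response, which locates φ up to a 90° branch; both
branches are fitted and the lower-cost solution kept, because the two are
near-degenerate under the b ↔ 1/b mapping and a single start can stall on the
wrong one. b is initialized from the max/min intensity-ratio heuristic
b ≈ √(I_max/I_min).

A pixel is masked invalid if its mean intensity over angles is below the
caller's threshold (a background mean + 3·SD rule is the recommended
data-driven choice; the darkest-decile estimator in `shgmetrics._util`
implements it), if the fit explains less than r² = 0.5 of the angular
variance, or if the response has no angular modulation at all — a constant
response carries no orientation information and is rejected rather than
assigned an arbitrary φ. All summaries (mean ± SEM) are over valid pixels
only. Whether the offset c is free or pinned to zero is a caller option;
background-subtracted data warrant pinning, and the default keeps it free.

## Anisotropy and SHG-CD statistics

Both polarimetric scalars are computed per pixel first and aggregated as
mask-means, not as ratios of summed intensities; with heterogeneous fields the
two differ, and the per-pixel form is the one that matches a pixel-based
acquisition. For the anisotropy the validity mask at each excitation angle
keeps pixels with denominator I∥ + 2·I⊥ above the noise background
(independently per angle); negative per-pixel β values — subtraction errors at
low counts — are reported, never clipped, since their presence is itself
informative. For SHG-CD the absolute value is taken per pixel (the raw sign
depends on fiber orientation) and both the mask-mean (primary,
intensity-independent) and the mask-sum are emitted, so either convention of
"summed across the field of view" is available without re-running.

The CD statistic has a shot-noise floor: |L − R| of two equal-rate Poisson
variates is positively biased, so at ε = 0 the measured mean CD is positive
and decreases as counts grow (≈ 0.035 at 1000 counts, ≈ 0.011 at 10⁴). Tests
compare noisy CD recovery against a direct Monte-Carlo simulation of this
bias, not against the injected ε.

## Attenuation normalization

Each optical section is reduced to a foreground-masked mean; the profile is
self-normalized to its peak section. The peak is *located* on a 3-point moving
average of the section means, which makes the choice robust to a single
spuriously bright section, but the normalization constant is the raw mean of
that section — dividing by the moving-average value itself would bias every
normalized value up by the smoothing factor and break the identity
normalized(z) = exp(−µz) on clean monotone data, which the tests require to
1e-6. Both a linear slope of the normalized curve (for conventional
slope-of-attenuation comparisons) and a single-exponential coefficient µ (the
primary recovery target in simulation) are fitted on the window from the peak
section to the last section. Scattering corrections (Monte-Carlo photon
transport) are deliberately out of scope: the intended samples are thinner
than one scattering length.

## Fiber extraction

The extractor is a fully specified ridge/skeleton pipeline rather than a
curvelet-based tool: median-filter background subtraction → multiscale
principal-curvature ridge enhancement (Sato tubeness, maximum over scales) →
hysteresis binarization → skeletonization → spur pruning → decomposition at
junction pixels (≥ 3 skeleton neighbors) into branches, each branch one fiber
candidate, with no merging across junctions (conservative by design; crossing
or bundled fibers are split, not disambiguated).

Numerical choices that matter for metric fidelity:

* skeleton pixel chains are smoothed with a 5-point moving average before
  arc-length computation (the raw 8-connected chain inflates diagonal lengths
  by up to ~8%);
* skeleton endpoints retract inside rounded fiber tips by roughly the local
  half-width; each end is extended along its tangent by the endpoint's
  distance-transform value before lengths are measured;
* geometry (skeleton, widths) is measured on the intensity half-max footprint
  connected to ridge evidence, not on the ridge mask, which overshoots the
  fiber boundary; widths use the identity EDT(p+n̂/2) + EDT(p−n̂/2) = W across
  a band of width W, which is exact for both odd and even pixel widths and
  sampled along the middle 80% of the centerline to avoid cap bias;
* straightness is chord/arc of the same polyline, so the triangle inequality
  guarantees it never exceeds 1.

## Synthetic scenes

The generator produces every geometry the pipeline reads, with closed-form
ground truth: polarization sweeps evaluating the angular model exactly;
channel pairs solving (I∥ − I⊥)/(I∥ + 2 I⊥) = β with I∥ + I⊥ equal to the
total response (I∥ = T(1+2β)/(2+β), I⊥ = T(1−β)/(2+β)); chiral pairs with
symmetric multiplicative asymmetry ±ε/2 so the normalized CD is exactly ε;
z-series with single-exponential mean decay; and constant-width fiber
phantoms from three curve families (segments, circular arcs with closed-form
straightness, smoothed random walks whose realized straightness is measured
from the rendered centerline). Phantom fibers are placed without overlap so
that ground truth and extractable structure coincide.

Defaults describe the acquisition the pipeline targets: a 10°-step sweep
through 180° (18 frames, 0–170°; the reader accepts any strictly increasing
angle list, including 19-frame sweeps closing both endpoints), photon-count
intensities with Poisson noise as the default noise model (photon-counting
detection) and ~10³ peak counts (amplitude 250 with b = 2), pixel size
0.332 µm. Optional additive Gaussian noise supports read-noise studies. These
are configuration defaults, not claims about any particular instrument's
noise floor.

What the synthetic data does *not* emulate: focal-volume polarization mixing
at high NA, scattering-induced depolarization, out-of-plane fibers,
instrument drift, and registration error between channels or polarization
frames (frames are generated co-registered, and the pipeline assumes
sequential acquisitions are aligned). Passing tests therefore demonstrate
correctness of the estimators under the stated forward models, not robustness
to those instrument effects.

## Group statistics

The comparison protocol is one-way ANOVA (F from sums of squares on
(k−1, N−k) degrees of freedom) followed by post hoc two-tailed two-sample
Student's t-tests with pooled variance, significant at α = 0.05, with
configurable star thresholds (default * < 0.05, ** < 0.01, *** < 0.001,
**** < 10⁻⁴). "Two-way" t-tests are read as two-tailed two-sample tests. No
multiple-testing correction is applied by default, matching the protocol the
pipeline mirrors; Holm step-down adjustment is available behind a flag.
Welch's correction is likewise opt-in — the default is the classical pooled
test. Degenerate cases are defined, not errors: zero pooled variance with
equal means gives t = 0, p = 1; with unequal means the pair is flagged as an
infinite-t case. Statistics are computed from sums of squares directly and
cross-checked in the tests against independent library implementations.

The built-in study configuration constructs the control group as the most
ordered (largest b, highest β and CD, flattest attenuation) with three samples
per group over 16×16-pixel fields — deliberately small problem sizes chosen so
the full simulate-measure-compare loop stays cheap while per-sample SEMs
remain far below the constructed group separations, which is what makes the
expected significance pattern recoverable in essentially every seeded
replicate.

## Known limitations

* The angular model is the package's reconstruction choice; data from fibers
  with strong out-of-plane tilt or non-Kleinman response will fit poorly
  (visible as low r², not silently wrong b).
* Fiber metrics are defined on branches between junctions; absolute fiber
  counts and length distributions in dense crossing networks depend on that
  convention and are not comparable across extractors.
* The attenuation coefficient is an effective single-exponential summary; no
  absolute (calibrated) conversion efficiency is produced.
* ELISA/hydroxyproline assays themselves are out of scope; only their unit
  conversions (300 Hyp per triple helix, 300 kDa per triple helix) are
  implemented.
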