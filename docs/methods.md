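# Methods

`blebmech` quantifies the mechanics and signaling of confined, non-adherent
blebbing cells — the "leader bleb" migration mode in which a single large,
stable, sausage-shaped bleb at the cell front drives adhesion-independent
motility. This note documents the models, the estimators, their tunable
parameters, and the assumptions behind the synthetic benchmarks.

## 1. AFM force-curve inversion (`blebmech.afm`)

### Model

A rounded cell gently compressed by a soft, tipless cantilever is treated as
a pressurised liquid drop bounded by a cortex under uniform in-plane tension
*T* (N/m). Balancing the vertical cantilever load against cortical tension
and intracellular pressure gives, for Z-piezo extension *Z* beyond the
contact point Z₀ and cantilever deflection *d*,

    T = k_c / (π (Z/d − 1))

with *k_c* the cantilever spring constant (N/m). Post-contact the
deflection is therefore linear in extension with dimensionless slope

    s = d/(Z − Z₀) = πT / (πT + k_c),    T = k_c·s / (π(1 − s)).

Laplace's law converts tension to the excess hydrostatic pressure of a cell
of radius *R* (measured from bright-field images):

    P = 2T / R    (Pa).

Assumptions: quasi-static, small deformation; uniform isotropic tension; the
cell is round (no adhesion); *Z* is measured from contact — using the raw
piezo coordinate would make *T* depend on an arbitrary origin. The slope
singularity at *s* → 1 corresponds to a rigid sample; slopes above
1 − 10⁻⁶ raise `RigidContact`.

### Pipeline and parameters

1. **Contact detection** (`detect_contact_point`). The baseline is the mean
   μ and SD σ of the first `noise_window = 64` samples. The coarse contact
   is the first run of `persistence = 8` samples exceeding μ + `k_sigma`·σ
   (`k_sigma = 3`). Because at shallow slopes the threshold is crossed only
   ~3σ/s beyond true contact (50–160 nm at tensions of 0.3–1 mN/m), the
   estimate is refined: a line is fitted to the rising segment and
   extrapolated back to the baseline level, and the fit window is
   re-anchored at the refined estimate for three iterations. On noiseless
   piecewise-linear curves this recovers the breakpoint exactly; at 0.5 nm
   deflection noise it keeps the median tension error at 0.3 mN/m
   below 3% (vs ~8% for a single pass). Automating this step replaces a
   manual judgement ("the curve rises substantially from zero") that cannot
   be reproduced across analysts.
2. **Slope fit** (`fit_deflection_slope`). Ordinary least squares of *d* on
   (z − Z₀), constrained through the origin (the force balance has no
   intercept), over 0 < z − Z₀ ≤ `fit_window_nm = 400`. R² is the
   through-origin coefficient of determination 1 − SS_res/Σd². At least 8
   in-window samples are required.
3. **Quality gate**. Curves are rejected (not errored) when contact is not
   found, the window is underpopulated, R² < `r2_min = 0.9`, or the slope is
   negative or rigid; each rejection carries a machine-readable reason code.
4. **Aggregation** (`summarize_cell`). Repeat curves of one cell (typically
   ~10) are summarised by the arithmetic mean and SD over accepted curves
   only; a median would also be defensible, the mean was chosen so that the
   per-cell SD is interpretable alongside it.

Internal units are SI; file I/O uses nm for curve coordinates and mN/m /
Pa in result tables, converted only at the boundary.

## 2. Cortex and bleb morphometrics (`blebmech.morphometry`)

**Cortical density** is the mean stain intensity over a 5-pixel-wide line
traced along a bleb-free stretch of cortex, minus the mean over a
cytoplasmic background ROI. The subtraction makes the measure invariant
under any constant offset; negative values are reported as-is.

**Cortex thickness** comes from a dual-channel line scan across the cell
edge: the separation between the membrane-stain and actin-stain peaks.
Profiles are smoothed with a Gaussian of `smooth_sigma_px = 2` (below the
optical PSF; smoothing a Gaussian-shaped peak does not move its centre) and
each peak is localised by 3-point quadratic interpolation around the argmax
(ties toward the smaller coordinate). On noiseless Gaussian pairs the bias
is < 0.01 px across sub-pixel placements; at peak SNR 10 the median
separation error is ~0.15 px. Without pre-smoothing the same interpolator
degrades to ~0.5 px at SNR 10, which motivated the smoothing default. The
default thickness mapping is `2 × separation` (the actin peak is taken to
sit at the cortex midline, half a thickness inside the membrane peak); a
`correction` hook accepts any other separation→thickness model, e.g. a
PSF-aware calibration.

**Segmentation.** The canonical mode packages user-drawn body/bleb masks
(mirroring manual outlining) and derives what is missing: the neck point
(centroid of bleb pixels bordering the body) and the bleb axis (geodesic
path inside the bleb from neck to the farthest bleb pixel, via
`skimage.graph.MCP_Geometric`). The automated mode — explicitly
non-canonical — Otsu-thresholds the image, keeps the largest connected
component, erodes with growing disks until the shape splits at its
narrowest constriction, seeds a watershed on the distance transform, and
labels lobes. The **body is the lobe with the largest inscribed disk**
(maximum of the distance transform), not the largest lobe: a leader bleb
can exceed the body in area, but it is always the narrower structure.
Degenerate shapes that never split raise `NoBleb`; downstream the bleb area
is then 0.

**Leader-bleb area** is 100 × bleb px / body px — exact integer-pixel
arithmetic; time series are summarised by the per-cell maximum (the single
largest bleb the cell makes) with the full series also exported.

**Migration fraction** operationalises a manual moving/stationary count: a
cell "moves" when its net centroid displacement over a 60-min window
exceeds 10 µm. Both numbers are parameters; the defaults are deliberate,
conservative choices for confined cells that migrate at ~1 µm/min when they
do move.

**Regional profiles.** The bleb axis arclength is divided into five equal
bins (bin 0 at the neck). Each axis sample owns one arclength cell and its
bin index comes from the cell-centred fraction (s + h/2)/(S + h); each bleb
pixel is assigned to the bin of its nearest axis point. The bins therefore
tile the bleb exactly — no pixel is counted twice or dropped. Per-bin
channel means are reported raw and normalised to the maximum bin. On a
linear neck-to-tip ramp the five means are analytically
[0.9, 0.7, 0.5, 0.3, 0.1], which the estimator reproduces to ~10⁻¹³ on a
flat-capped synthetic bleb.

**Fibril anisotropy** uses the nematic-tensor construction: unit intensity
gradients (central differences) are accumulated into the mean outer-product
tensor; the score is the eigenvalue gap λ₁ − λ₂ ∈ [0, 1] (eigenvalues sum
to 1) and the fibril orientation is the dominant gradient direction rotated
90° (fibrils lie along iso-intensity lines). The score is invariant under
affine intensity maps and under 90° rotation (orientation shifts by exactly
π/2). One numerical caveat: central differences of a plane wave point along
(sin k_x, sin k_y) rather than (k_x, k_y), so short-wavelength textures
bias the orientation — ~1.2° at an 8 px stripe period and 30°, ~0.3° at
16 px. The synthetic texture default is 16 px for this reason; real
bundles imaged near Nyquist carry the same caveat.

**Contrast gating** (`contrast_index`, SD/mean over the ROI) reproduces the
practice of only comparing anisotropy between images of similar contrast.

**Arrival timing**: time 0 is the frame of maximal bleb protrusion; arrival
is the first frame whose rim intensity exceeds the stated background level;
the signed time is a multiple of the frame interval (default 5 s).

## 3. Ratiometric imaging (`blebmech.ratiometric`)

The FRET pipeline order is fixed and enforced by `fret_pipeline`:

1. **Background subtraction** — per-frame, per-channel scalar (background
   ROI mean); negative pixels are clipped to 0 and counted.
2. **Bleach correction** — the mean in-mask intensity per frame (mask from
   an Otsu threshold of the first donor frame) is fitted to I₀e^(−kt),
   log-linear initialisation then nonlinear refinement; each frame is
   divided by e^(−kt), per channel by default. A failed fit leaves the
   channel uncorrected and flagged (rate NaN). Correction is idempotent
   (re-fitting a corrected series gives k ≈ 0).
3. **Masking** — recomputed per frame from the donor channel (cells move);
   only strictly positive donor pixels enter, so no division by zero.
4. **Ratio** — pixelwise acceptor/donor inside the mask, NaN outside, with
   a provenance record of the corrections applied.

The order matters: an additive background offset corrupts a multiplicative
bleach fit, and bleach bias inflates late-frame ratios. A test asserts the
reordered pipeline gives a different answer, guarding against silent
refactors.

**Enrichment** is mean(bleb)/mean(body) over the segmentation masks.
Because "X% enrichment" is ambiguous between a ratio of X/100 and an
increase of X/100, both the plain ratio and the percent increase
100·(ratio − 1) are reported side by side.

**Photoconversion.** After a conversion pulse confined to the bleb, the
bleb's share of the converted signal relaxes toward the bleb's volume
fraction as molecules exchange through the neck. The simplest model
consistent with that observation — two well-mixed compartments with
first-order exchange — gives

    r(t) = r_eq + (r₀ − r_eq) e^(−kt),

with r₀ fixed at the first post-conversion observation and (k, r_eq)
fitted (k ≥ 0, 0 ≤ r_eq ≤ 1). The rate k measures neck-barrier
permeability; a sealed neck gives a flat series and k = 0 without entering
the nonlinear fit. This quantitative model is an extension beyond the
qualitative retention observation it formalises: real blebs are neither
well-mixed nor constant-volume, so k should be read as an effective
exchange rate.

## 4. Synthetic ground truth (`blebmech.synthetic`)

Every estimator is benchmarked against a seeded forward model of the data
it inverts; the generator returns the truth record alongside the data, and
tests consume only that record.

* **Force curves**: d = s·(z − Z₀) for z > Z₀ with s = πT/(πT + k_c), plus
  additive Gaussian deflection noise (default 0.5 nm), optional baseline
  tilt, and an optional slip artifact. Defaults mirror the instrument's
  regime: k_c = 0.1 N/m (levers 0.08–0.11), 4 µm ramps, contact at
  3.6 µm so the peak force stays of order 1 nN, 2048 samples. The slip is
  modelled as a sudden deflection *drop* of 0.5 × the maximal in-window
  deflection at a uniform position in the middle half of the fit window:
  through-origin R² is surprisingly tolerant of positive jumps but a drop
  reliably drives R² below 0.9, matching how slip curves are discarded in
  practice.
* **Cell images**: disk body (radius 60 px), narrow neck, sausage bleb
  (200 × 70 px, flat or round caps) at 0.1 µm/px, with a configurable
  axial intensity profile (linear 1→0 or uniform), a bright cortical rim
  channel, a binary-ish silhouette channel for segmentation tests, and an
  optional oriented stripe texture. For the linear gradient the analytic
  per-bin means are exact by construction (the profile is a function of
  the same pixel-centre arclength fraction the binning uses).
* **Line scans**: two Gaussians (PSF σ = 0.1 µm, 0.04 µm sampling)
  separated by the true cortex offset, with optional iid noise.
* **FRET stacks**: donor = morphology·e^(−k_d t) + background(t) + noise;
  acceptor = morphology·activity·e^(−k_a t) + background(t) + noise, with
  activity 1 in the body and 2.5 in the bleb by default, k_d = 0.01 s⁻¹,
  k_a = 0.005 s⁻¹, optional linear background drift.
* **Photoconversion**: exact two-compartment exponential with signal
  conservation, r_eq = bleb area/(bleb + body area), default k = 0.02 s⁻¹,
  130 ms frames.

All randomness flows from one `numpy.random.Generator` per call; identical
configuration and seed give bit-identical arrays. What the generators do
**not** emulate: optical blur of the 2-D scenes, shot-noise statistics
(Gaussian approximations only), cell movement between frames, spectral
bleed-through, out-of-focus light, or spatially varying background. Passing
tests therefore demonstrate correctness of the estimators under their own
model assumptions, not robustness to every artifact of real microscopy.

## 5. Problem sizes and numerical choices

The verification suite uses 200 curves per tension level for noisy AFM
recovery, a 10×10 noiseless (T, k_c) grid, 200 + 200 curves for the
clean/slip filter check, 100 line scans at SNR 10, 100 FRET stacks at 2%
multiplicative noise, and 512² iid-noise fields for the isotropy check —
sizes at which the medians and rates being asserted are stable across
seeds while the whole suite stays fast.

Degenerate inputs are first-class: flat traces raise `NoContact` (its
noiseless special case `DegenerateBaseline` subclasses it), monotone line
scans raise `NoPeak`, constant images score anisotropy 0 with undefined
orientation, empty thresholds raise `EmptyMask`, a zero-signal conversion
series raises `NoSignal`. Curves with non-monotone z are re-sorted and
exact duplicates averaged on construction.

## 6. Known limitations

* The force balance is the small-deformation drop model; no Hertzian or
  viscoelastic corrections, no retract-curve adhesion analysis, and the
  spring constant is an input (thermal calibration is out of scope).
* The thickness→separation mapping defaults to a pure geometric factor of
  2; the hook exists because published PSF-aware calibrations are
  instrument-specific.
* Automated segmentation assumes one cell with one dominant bleb in view;
  it is a convenience, not a replacement for curated masks.
* The two-compartment exchange model ignores intra-bleb gradients; on
  short series (k·T ≲ 1) the fitted r_eq is weakly constrained and the
  fitted k correspondingly less certain.
* Emission ratios are raw acceptor/donor values: no bleed-through or
  stoichiometry correction, so ratios are comparable within an experiment,
  not across instruments.
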