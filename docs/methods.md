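# Methods

This note records the models implemented in `dvhkit`, the numerical
choices made where the underlying conventions are genuinely open, and
what the synthetic phantoms do and do not demonstrate.

## Coordinate and binning conventions

Patient coordinates are millimetres, dose is cGy, volumes are cc. The
dose array is slice-major `[z, y, x]`; voxel indices are 0-based and the
grid origin is the *centre* of voxel (0, 0, 0). Contour slices are
matched to the nearest grid slice within half a slice spacing.

Differential DVH bins are uniform and **centre-aligned**: bin *k* covers
`[k·w − w/2, k·w + w/2)` and is represented by the dose `k·w`. The
default width is `max(grid dose)/500`, so the cumulative curve has 501
evenly spaced points spanning `[0, max dose]` — the conventional sampling
density for clinical DVH export. Centre alignment means a voxel
population at a dose that is an exact multiple of the width (a uniform
plateau at the prescription dose, for instance) sits exactly on a dose
point: the cumulative curve evaluated at the prescription dose returns
the full covered volume with no half-bin offset, and plateau phantoms
score their indices exactly rather than to within half a bin.

Cumulative values between dose points are linear interpolations; below
the first point the curve equals the total volume, beyond the last it is
zero. Inverse lookups (`dose_at_volume`) return the highest dose of a
flat segment, so `Dmax` of a plateau is the plateau dose.

## Rasterization

Membership is decided per voxel sample point by the even-odd rule over
all rings of a slice (an inner ring carves a hole); points on a ring
boundary count inside. With `supersample = k` each voxel is probed at a
k × k stratified grid of in-plane sub-centres and carries the inside
fraction as partial volume. Sub-sampling is in-plane only: contours are
planar per slice, so additional z sub-points would re-probe the same
polygon and change nothing. `supersample = 1` reproduces pure
voxel-centre counting, which is what the exhaustive point-in-polygon
oracle in the test suite checks; the default analyses use 2, which
roughly quarters the surface-voxel discretization error of volume
estimates at ~4× the rasterization cost.

## Curve smoothing and Dx extraction

The cumulative curve is modelled piecewise. For each inter-sample
interval a virtual midpoint is synthesized by cosine interpolation with
weight 0.5 — blend fraction `(1 − cos(π·0.5))/2 = 0.5` — and a
least-squares polynomial is fitted through that midpoint plus the six
nearest samples. "Six nearest" is realized as the contiguous run of six
samples centred on the interval (clamped at the curve ends), which makes
the window a function of the interval alone and the fit cacheable. The
polynomial degree is selected per window from {2, 3, 4, 5} by minimal
leave-one-out RMSE with ties to the lowest degree: a reproducible
criterion standing in for "optimal" degree selection.

Raw window polynomials can overshoot, so evaluation returns the
running-minimum envelope of the polynomial over `[xⱼ, d]` (computed from
the polynomial's real critical points), clipped to the bracketing sample
values and to `[0, total volume]`. The modelled curve is therefore
monotone non-increasing *everywhere*, not just at the samples, and
reproduces each sample exactly. Dose-at-volume queries invert the
smoothed model by bracketed root finding, falling back to linear
inversion on flat windows; curves shorter than 7 points skip smoothing
entirely.

## Comparison metrics

NRMSD between two cumulative curves is `100 × RMS(f_a − f_b)` at the
probe doses, where each curve is normalized by **its own total volume**.
Published NRMSD conventions differ (per-point range, maximum value,
total volume); the total-volume normalization is stated here prominently
because reported percentages are not comparable across conventions.
DTA is evaluated on the dose axis at a fixed volume fraction (default
50%) and normalized to the prescription dose.

## Spatial histograms

zDVH entries share the whole-structure bin edges, so the slice-sum
identity holds bin-by-bin to floating-point addition error only. The
DSH "surface" is the 6-connectivity boundary: member voxels with at
least one face neighbour outside the mask or outside the grid (one-voxel
binary erosion). A contour-based surface (in-plane ring voxels per
slice) is a documented alternative that was not implemented; the
erosion definition is the simplest reproducible choice and makes the
`DSH ⊆ DVH` containment exact by construction. Hot/cold slice flags use
1.05·PD and 0.95·PD — reporting conveniences, not clinical thresholds.

## Plan indices

COSI is computed as `1 − [Σ wᵢ·V(OARᵢ ≥ TOLᵢ)]/TCI` with default weights
`wᵢ = 1/N`; the formula's precedence is ambiguous as usually typeset and
this reading (the overdose sum divided by TCI) is the one consistent
with an ideal score of unity. PIV is taken over the whole dose grid, not
the target, preserving the PIV/PTV distinction. CI and TR are exposed as
auxiliaries but are not members of the scored ten-index set. The QF base
constant is kept at the printed value 2.718 rather than *e*; the
relative deviation is below 4×10⁻⁴, and the ideal-plan test uses a 10⁻³
tolerance accordingly. No clinical tolerance-dose table is bundled:
organ tolerances are always user input.

## Outcome models

Fractional DVHs take bin doses at differential-bin centres (midpoint
rather than edge — unstated in most formulations, chosen here once).
Zero-dose bins are kept: they contribute `exp(2γ₅₀ ln2)` per unit volume
to the Poisson exponent and zero to the generalized mean dose, so
unirradiated volume is never silently dropped. The probit Φ is
`erfc(−x/√2)/2`; the generalized mean dose is evaluated in log space
(log-sum-exp), which stays finite for small volume exponents *n* where
`D^{1/n}` overflows double precision. The shipped parameter values
(TCD₅₀ = 4180 cGy, γ₅₀ = 0.6; TD₅₀ = 8190 cGy, m = 0.19, n = 0.23) are
illustrative prostate-study examples, not clinical recommendations.

## Synthetic phantoms

The generator emulates a conformal plan at study scale: a spherical (or
box) target of radius 20 mm centred in a 68³ voxel, 1 mm lattice, an
optional concentric shell OAR out to 30 mm, prescription 3900 cGy, and
three dose models. The plateau model assigns D0 to exactly the voxels
the rasterizer would select (membership-consistent), making the "ideal
plan" exactly ideal; the linear-falloff model is
`D(r) = D0·min(1, max(0, 1 − (r−R)/L))` with L = 10 mm, a penumbra-like
gradient of 10%/mm used to stress the high-gradient behaviour of the
DVH chain; the two-level model gives step DVHs. Circular rings are
64-gons, so rasterization oracles see the same polygons; the closed-form
curves use ideal spheres — the in-plane polygon area deficit
(`(n/2π)·sin(2π/n) ≈ 0.16%` for n = 64) is a constant factor that
cancels in volume-normalized comparisons. Noise is additive Gaussian on
the dose grid, clipped at 0 cGy, driven by one integer seed; noisy
phantoms have no closed form and say so.

What phantom tests demonstrate: correctness of the geometric,
histogramming, smoothing, index and model arithmetic against exact
expectations. What they do not demonstrate: fidelity to any treatment
planning system's own DVH algorithm, behaviour on irregular clinical
anatomy, multi-isocentre dose grids, or contours finer than the dose
lattice. Agreement thresholds (NRMSD < 1%, DTA at half volume < 0.5% of
PD at 1 mm spacing / 501 bins) are the package's acceptance envelope on
these phantoms, achieved with margin (measured ≈ 0.26% / 0.30%).

## Degenerate inputs and errors

Contours with fewer than three vertices, structures that overlap no grid
slice, empty masks, curves too short to smooth, and unparseable query
tokens all raise typed exceptions rather than returning sentinel values;
indices with vanishing denominators are reported as undefined with a
reason, never ±∞. DVH queries outside a curve's dose range are clamped
and flagged, never silently extrapolated.

## Problem sizes

Default test and validation problems use the 68³ 1 mm phantom
(~315k voxels, 501-point curves), which the full pipeline processes in
well under a second per structure; rasterization oracles run on ≤ 50²
slices where exhaustive pure-Python sweeps remain cheap.
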