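# Methods

`tfmuq` implements uncertainty-aware traction force microscopy (TFM):
it measures substrate deformation from fluorescent-bead image pairs
with a bootstrap estimate of the per-vector measurement uncertainty,
and propagates that spatially varying uncertainty through a
hierarchical Bayesian elastostatic inversion to pointwise error maps
of the recovered traction stresses. This note records the models, the
numerical choices, and what the synthetic validation does and does not
demonstrate.

## Elastostatic model

The substrate is a flat, inertia-less, linearly elastic layer of
Young's modulus `E` (Pa), Poisson ratio `ν ∈ [0, 0.5)` and thickness
`h` (μm), bonded to a rigid support at its base and loaded by
tangential tractions `t(x, y)` on its free surface. Per wavenumber
`k = (kx, ky)` the surface displacement responds through a 2×2 block

    M̃(k) = g1(k)·I + g2(k)·[[kx², kx·ky], [kx·ky, ky²]],

where `g1` is the transverse (antiplane-shear) compliance and
`g1 + g2·k²` the longitudinal one. Solving the plane-strain Navier
equations for a single Fourier mode with a clamped base (`u = w = 0`)
and a traction-loaded, normal-stress-free surface gives, with
`s = sinh kh`, `c = cosh kh` and shear modulus `μ = E/(2(1+ν))`:

    g1         = tanh(kh) / (μ k)
    g1 + g2 k² = (1−ν)[(3−4ν)·s·c + kh] /
                 (μ k [(3−4ν)·s² + (kh)² + 4(1−ν)²])

The derivation was performed symbolically (sympy) and the resulting
closed forms are validated in the test suite against the two analytic
limits that bracket them: the pure-shear membrane `M̃ → (h/μ)·I` as
`kh → 0` and the Boussinesq half-space kernel
`g1 = 2(1+ν)/(Ek)`, `g2 = −2ν(1+ν)/(Ek³)` as `kh → ∞`, both to 0.1 %.
This two-limit validation is the module's central correctness
contract. An alternative surface condition (zero vertical surface
displacement) was considered and rejected because its half-space limit
deviates from the Boussinesq kernel by ≈0.8 % at ν = 0.45.

Numerical details:

* Periodic boundary conditions (Fourier method) on the analysis grid.
* The DC (`k = 0`) block uses the pure-shear limit `(h/μ)·I`.
* The off-diagonal coupling `g2·kx·ky` is odd in each wavenumber
  component; on Nyquist rows/columns of an even grid the sign of `k`
  is ambiguous and conjugate symmetry of a real field would break, so
  the coupling is zeroed there. This makes the forward operator
  exactly real and self-adjoint, and forward→inverse round-trips exact
  to machine precision.
* The dense operator `M` (2N_w × 2N_w, μm/Pa, ordering
  `(ux…, uy…)` row-major) is assembled from two FFT impulse responses
  using the block-circulant structure, then symmetrized; a guard
  rejects grids above 4000 windows. Its condition number grows ∝ h at
  fixed grid, as expected from the `kh` scaling of the eigenvalues.
* `ν = 0.5` is rejected (the `1−2ν` factors in the underlying solution
  degenerate).
* The mean of the measured displacement field is removed before
  inversion by default: the DC traction mode is weakly constrained and
  rigid drift between the image pair is not traction.
* Beads are treated as lying exactly at the surface; the depth
  amplification factor for beads below the surface is out of scope.

## PIV engine

Single-pass FFT cross-correlation on overlapping square interrogation
windows of side `WL` px spaced `WS = WL/2` (the Nyquist-style
trade-off between resolution and cost). The sign convention: `u` maps
reference coordinates to session coordinates.

* Correlation estimator: windows are mean-subtracted, zero-padded by
  the search range, and the correlation is divided by the per-lag
  overlap area. This unbiased ("linear") estimator was chosen after
  measuring the classic pair-loss bias of plain circular correlation:
  ~0.07 px toward zero at a 2 px shift with `WL = 64`, scaling as
  `1/WL` — far above the 0.1 px accuracy this package targets for the
  uniform-shift regime. The unbiased estimator measures ~0.003 px
  under the same conditions. Circular correlation remains available
  (`PIVConfig(correlation="circular")`).
* Search range: `|lag| ≤ WL/4` per component by default (the standard
  quarter rule). Overlap normalization amplifies noise at extreme
  lags, and in sparse windows (few beads) spurious matches at large
  lags otherwise contaminate the field with wild vectors.
* Sub-pixel peak: three-point Gaussian (log-parabolic) fit per axis,
  exact for a Gaussian-shaped peak; the integer peak is kept when a
  stencil value is non-positive. Border peaks flag the window invalid.
* Windows with zero contrast (bead-free at zero noise) are flagged
  degenerate.

The engine is deliberately single-pass and swappable; iterative
window-deformation schemes can replace `run_piv` without touching the
uncertainty machinery.

## Bootstrap uncertainty quantification (PIV-UQ)

For each window pair, `n²` pixel indices are drawn uniformly with
replacement; a pixel's contribution is weighted by its sampled
multiplicity (unsampled pixels drop out) and the same index multiset
perturbs both windows, so the perturbation acts on the correlation
functional rather than on the imaged scene. PIV on `n_B` such
perturbed pairs yields an empirical distribution of displacement draws
per window; its componentwise standard deviation is the reported
`σ_u,PIV`, and the circular standard deviation `sqrt(−2 ln R̄)` of the
draw directions the angular uncertainty.

Two details matter in practice:

* Weights are applied to the *mean-centered* windows. Because the
  weight pattern is shared by both windows of a pair, weighting raw
  intensities lets that pattern correlate with itself at zero lag
  through the image's nonzero mean (clipped noise has positive mean),
  which gives even bead-free windows a tight, confident `u* ≈ 0`
  cluster. Centering first makes the resampled quantity each pixel's
  contribution to the mean-subtracted correlation metric and restores
  the intended behavior: fully bead-free windows fail validation. A
  binary-mask variant (membership instead of multiplicity) is kept as
  a sensitivity option.
* Validation: DBSCAN on the 2-D draws with `eps = WS/5` and
  `minPts = ⌈n_B/10⌉`. Noise points are outliers; a window is invalid
  when no cluster forms or when two clusters come no closer than 20 %
  of the window spacing (a multi-modal distribution: more than one
  registration is plausible). Statistics use the largest cluster.
  Invalid windows get their vector filled by iterated 3×3 median
  filtering of valid neighbors and their σ set to 5× the maximum valid
  σ (configurable), keeping the grid complete while carrying almost no
  weight in the inversion.

Convergence of the σ estimator with `n_B` is monitored by the
coefficient of variation of repeated estimates; noisier images need
larger `n_B` to reach a given CoV.

## Hierarchical Bayesian inversion

The stacked displacement observation `u_h` (μm) is modeled as
`M t + ε_β + ε_m` with `ε_m ~ N(0, Σ_PIV)` (diagonal, from the
bootstrap, converted px → μm) and `ε_β ~ N(0, β⁻¹ I)` a global model
error of unknown precision `β`. The smoothness prior on `t` uses the
5-point discrete Laplacian `L` per component with mirror boundaries
(annihilates constants, hence never penalizes — and therefore
conserves — the total traction force); the prior energy is `|L t|²`,
i.e. precision `α LᵀL`. The quadratic form `tᵀLt` reading is exposed
via configuration, but `LᵀL` is the default because it makes the Gamma
conditional for α exact and the prior proper on the non-constant
subspace. Both hyperparameters carry weakly informative Gamma(1, 1e-5)
hyperpriors.

The hybrid Gibbs sampler cycles:

1. `t | α, β` — Gaussian with precision `Mᵀ Λ⁻¹ M + α LᵀL`,
   `Λ = β⁻¹ I + Σ_PIV`; sampled exactly through a Cholesky
   factorization of the precision.
2. `α | t` — Gamma(N_w + θ_α, |Lt|²/2 + φ_α).
3. `β | t` — no closed form when Σ_PIV is non-uniform; sampled by
   numerical inverse transform: a coarse log-grid brackets the
   conditional MAP, a 400-point log-grid spanning 4 decades around it
   resolves the density, and the trapezoid CDF is inverted against a
   uniform draw. The grid widens once if mass piles on an edge. When
   Σ_PIV = 0 the conditional is an analytic Gamma, which the test
   suite uses as the sampler's oracle (moments to ~1 %).

Defaults: 300 draws, 50 burn-in. Posterior summaries (mean traction,
componentwise/total std, angular circular std) are accumulated over
post-burn-in draws. With Σ_PIV = 0 and clamped hyperparameters the
conditional mean reproduces the Tikhonov solution at `λ = α/β` to
1e-8, which ties the sampler to the classical baseline.

Initialization: `α0, β0` are free in the formulation ("reasonable
maximum-likelihood estimates"); the package initializes from the
Tikhonov fit at a reference weight `λ0` (by default the L-curve
corner): `β0` moment-matches that fit's residual and `α0 = λ0·β0`.
This choice is load-bearing. Initializing `β0` from the PIV variance
floor instead overweights high-quality data by orders of magnitude;
the first `t` draw then overfits wildly, `|Lt|²` explodes, α collapses,
and the chain enters a long-lived metastable state in which β absorbs
the entire signal as noise. Chain traces confirmed both the trap and
that the residual-matched start avoids it; with it, 600-draw runs show
the chain stationary well within the default budget.

A heteroskedastic prior variant rescales the prior precision by
`Σ_PIV^{-1/2} LᵀL Σ_PIV^{-1/2}`, giving weaker effective
regularization (and a σ floor that tracks the local noise) in
high-noise regions.

## Tikhonov baseline and L-curve

The classical baseline solves
`(MᵀM + λ LᵀL) t = Mᵀ u_h` (or ridge, `L = I`), with λ chosen at the
corner of the L-curve: the log-log trade-off of the seminorm `|tᵀLt|`
against the residual `‖u_h − Mt‖²` over a 40-point λ grid spanning 8
decades around the scale heuristic `tr(MMᵀ)/tr(LᵀL)`.

Corner finding required care. Because the discretized response matrix
here is square and only mildly ill-conditioned (κ ~ h/WS), λ → 0
attains an exact data fit with *finite* seminorm, so the sampled curve
is S-shaped rather than L-shaped: an overfit-side clockwise bend joins
the noise-tracking counterclockwise corner. The corner is therefore
selected as the maximum of the signed curvature (cubic-spline
smoothed, parameterized by log λ), restricted to interior grid points
whose residual has risen at least 10 % (in log span) above the
exact-fit floor; a chord-distance fallback covers curves with no
resolved counterclockwise bend. On full-scale synthetic data this rule
tracks the noise level correctly — the corner of a low-noise
(dense-bead) data set sits well below that of a high-noise (sparse)
one, each within about 2× of the λ that minimizes the true error —
whereas unsigned curvature maxima and chord rules were observed to
lock onto the overfit bend regardless of noise.

`λ_L` and `λ_H` for the benchmark comparisons are the corners of
spatially uniform low-noise and high-noise companion data sets (bead
densities of the heteroskedastic image's left and right edges). The
ridge variants are matched to the Laplacian solutions at equal 95th
percentile traction magnitude by bisection.

## Synthetic benchmark

`synthetic` image pairs contain Gaussian-profile beads (default
σ_bead = 1.5 px, peak 1000 a.u., saturating clip at 1000) placed by a
Poisson process whose density may vary with x; pixel noise is additive
Gaussian with `SNR = 20·log10(1000/σ_px)` dB; bead centroids are
displaced by a prescribed field evaluated at their pre-displacement
positions (out-of-frame beads are dropped, no wrap).

The heteroskedastic four-island benchmark: four Gaussian traction
islands (peak 500 Pa, width 15 μm, one per quadrant at (±L/4, ±L/4),
pointing toward the vertical midline so the net force vanishes) on a
substrate with E = 5 kPa, ν = 0.45, h = 50 μm; 1024² px images at
SNR = 50 with a linear bead-density ramp from 8×10⁻³ (left) to 8×10⁻⁴
(right) beads/px². The pixel size, 0.34618 μm/px, is calibrated so
that the RMS magnitude of the island truth over the domain is exactly
75 Pa — the threshold separating foreground (|t| ≥ RMS) from
background in the evaluation metrics. This is a calibration, not a
prediction. The displacement field is generated by a forward solve on
the 1024² pixel grid, while inversion operates on the 31×31 window
grid (WL = 64, WS = 32; N_w = 961), so the benchmark does not commit
the inverse crime. On the window grid (which does not tile the full
domain) the truth's RMS evaluates to ≈77 Pa; the 75 Pa figure refers
to the calibrated continuous domain.

What the generator emulates: spatially varying information content
(bead density), uniform sensor noise, saturation clipping, and
deformation-gradient-induced PIV uncertainty at the islands. What it
does not: optical PSF and defocus blur, shot noise, bead brightness
variation, bead depth below the surface, drift, or temporally
correlated noise. Passing benchmarks here therefore demonstrate the
statistical machinery — uncertainty tracking, adaptive regularization,
error-map calibration — under controlled conditions, not photometric
realism.

## Observed behavior on the benchmark, and limitations

With the default conditions the pipeline recovers the four-island
field with TFM-UQ RMS error ≈ 23 Pa, and the λ ordering
`λ_L < λ_D < λ_H` emerges with the expected qualitative behavior
(λ_H over-smooths severely; λ_L carries the strongest foreground and
dirtiest background). Two honest caveats, both traceable to this
implementation's comparatively clean PIV front end (unbiased
correlation, quarter-rule search, sub-0.01 px bootstrap floor at
SNR 50):

* The well-placed L-curve corner gives the global Tikhonov baseline an
  RMS error similar to or slightly better than the hierarchical
  posterior mean on this benchmark. The hierarchical model prefers
  weaker smoothing than the corner (its effective λ = α/β settles
  ~1.5 decades lower), consistent with PIV errors that are spatially
  correlated across overlapping windows while the likelihood assumes
  independence.
* The absolute posterior uncertainty scale (σ_t ≈ 6–22 Pa across the
  map) and the uniform-λ failure magnitudes are smaller than they
  would be with a noisier front end; the σ_t map shows clear maxima at
  the traction islands (where deformation gradients inflate the
  bootstrap spread) and a left-right asymmetry that follows the
  density ramp, saturated by the global smoothing prior exactly as the
  `S_post` analysis predicts (pointwise variance bounded by the local
  measurement term and the α-floor).

Sizes used in the shipped validation runs were chosen to keep the full
suite in the minutes range on a single core: the benchmark itself runs
at full scale (1024², N_w = 961, 300 draws), while ensemble studies
(uniform-shift recovery, bootstrap-vs-ensemble scatter) use 320–384 px
images and 8–50 realizations.
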