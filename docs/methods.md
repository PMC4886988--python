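# Methods

## Truncation mechanism and scope

Detector calibration (dark-frame subtraction followed by gain
multiplication) can turn weak raw counts into slightly negative
calibrated values. When the storage format is unsigned 16-bit, those
values are clamped to zero and the information is lost. `detrunc`
operates strictly downstream of calibration and upstream of
integration: it reads calibrated SMV frames, models the censored zero
bin, reassigns negative counts, and writes SMV frames back with a
storage offset. Dark/gain correction, indexing, integration and scaling
are out of scope.

## Noise model

Within one resolution annulus, pixel counts are modeled as independent,
identically distributed draws from a shifted (three-parameter)
lognormal: location μ (log-ADU), scale σ > 0, shift τ (ADU, typically
negative) moving the support to (τ, ∞). The lognormal is an empirical
choice: it is flexible enough for the heavy-tailed, skewed background
of diffraction images and admits negative values through τ. Integer
counts use half-integer binning, P(I) = F(I+½) − F(I−½), which
telescopes to exactly 1 over the integers and makes the censored zero
bin the natural left tail F(½).

### Likelihood

    ℓ(μ,σ,τ) = N₀ ln F(½) + Σ_{I=1}^{I_max} N_I ln P(I)
               + N_over ln[1 − F(I_max+½)]

The fit range [0, I_max] deliberately excludes Bragg-peak tails: by
default I_max is the 95th percentile of the positive valid pixel values
in the annulus, capped at 2000 ADU (both configurable). The N_over
pixels above the range enter as a single right-censored term, the
mirror image of the left-censored zero bin. This term matters: dropping
the overflow pixels entirely (a plain partial sum over the in-range
bins) makes the estimator inconsistent — in simulations with 1% of the
mass above I_max the plain sum biased σ̂ by ~20% regardless of sample
size, while the right-censored form recovers the generating parameters
to well under 1% at 10⁶ draws. A conditional variant (renormalizing by
F(I_max+½) and discarding the overflow) is available via
`conditional=True` and behaves equivalently; the right-censored form is
the default because it reduces exactly to the plain sum whenever no
pixel exceeds I_max.

Saturated pixels (65535 ADU) are excluded from modeling altogether:
they carry the same clamping pathology at the opposite extreme.

### Optimization

The likelihood is maximized with BFGS using the analytic gradient
(chain rule through Φ at the half-integer edges) over the
reparameterized space (μ, ln σ, t) with τ = U − exp(t), where
U = min(½, I_min_pos − ½) is the largest shift that leaves positive
probability in every occupied bin and in the censored bin. This keeps
the search unconstrained while guaranteeing feasibility. Start values
are method-of-moments: τ₀ = −(weighted std of the positive bins), then
μ₀, σ₀ from the weighted mean and variance of ln(I − τ₀); at least 3
distinct occupied positive bins are required. Convergence is declared
at gradient tolerance 1e−6 (scaled by the likelihood magnitude, since ℓ
grows linearly with pixel count), with up to 500 iterations per start
and up to 3 restarts to absorb line-search precision stalls; a
non-converged fit is reported, never silently accepted. Identical
inputs give bitwise-identical results.

Fit quality is summarized as the r.m.s. deviation between observed and
predicted histogram counts over [0, I_max] (the zero-bin prediction
being n·F(½)). The r.m.s.d. is reported in histogram counts; no
particular absolute value is claimed for real data.

## Resolution shells

Pixels map to d-spacing via the flat-detector small-angle geometry:
2θ = atan(r/D), d = λ/(2 sin θ), with λ from the relativistic
de Broglie relation at the given acceleration voltage (0.02508 Å at
200 kV). Obliquity and Ewald-curvature corrections are ignored — at
MicroED scattering angles (2θ ≲ 1.2°) they are far below the model's
other approximations. "Approximately equal area" annuli are realized as
equal valid-pixel count via radius quantiles rather than analytic
√(k/n) rings: this stays balanced in the square detector's corners and
under beam-stop masks without special cases. On an integer pixel grid,
radius ties (symmetry orbits of 4–8 pixels) prevent exactly equal
counts; the observed relative spread is far below 1%. Pixel coordinates
are 0-based with centers at integer positions; header beam centers
(BEAM_CENTER_X/Y, millimeters, the dominant SMV convention) are
converted to pixels on load and can be overridden in the config.

## Correction

Per annulus with N₀ > 0, the fitted model fixes the expected
frequencies of the true counts I ≤ 0: e_I = N₀·P(I)/F(½) for
I = 0, −1, −2, …, truncated where the remaining left tail holds fewer
than half an expected pixel (the tail is infinite; some cut is
required, and half a pixel is below the resolution of the integer
histogram). The e_I are integerized by largest-remainder rounding so
they sum to exactly N₀ — the value frequencies are deterministic and
conform to the fitted distribution by construction; only the assignment
of values to pixels is a seeded random permutation. A value of 0 may be
re-assigned, since an observed zero can be a true zero. This
deterministic-frequencies reading minimizes the footprint of the random
number generator: two runs with the same seed are bitwise identical,
and runs with different seeds differ only in arrangement.

Consequences, all tested: positive pixels are bitwise unchanged;
zero-free images are returned identical; the correction never increases
a pixel value; per-annulus assigned counts sum to N₀ exactly.

Seed policy: one master seed per sweep; frame k uses seed + k, and
annulus j within a frame uses the stream (seed+k, j), so results do not
depend on processing order.

### Storage offset

Corrected frames are signed in memory. At write time a single
sweep-wide offset — max(0, −min corrected valid count over all frames)
— is added and recorded as `ADCOFFSET` in the SMV header. A per-frame
offset would break relative scaling across the sweep. The SMV dialect
is the 512-byte ADSC-style header of `KEY=value;` lines framed by
`{`/`}` and zero-padded, with unsigned 16-bit row-major payload in the
declared byte order; unknown header keys round-trip untouched.

## Synthetic data

The simulator draws per-annulus backgrounds i.i.d. from specified
shifted lognormals (rounded to integers), optionally adds
integer-rounded isotropic 2-D Gaussian Bragg spots, then clamps
negatives to zero for the "observed" frame while keeping the signed
truth. Defaults describe a 200 kV camera at 2.2 m virtual distance with
10 annuli whose modes decay geometrically from 600 to 50 ADU, σ from
0.55 to 0.35 and τ from −140 to −45 ADU inward→outward, so mode and
variance fall with resolution and the outer shells are censored.

What the simulation does *not* emulate: pixel-to-pixel correlation,
solvent rings and ice artifacts, rolling-shutter temporal structure,
per-pixel gain variation, and physically faithful spot profiles.
Passing tests therefore demonstrate correctness of the procedure under
its own i.i.d.-per-annulus assumptions, not the adequacy of the
lognormal for any particular real detector.

## Problem sizes and numerical choices

Tests run at desk scale: parameter-recovery checks use 2×10⁵–10⁶ draws
per histogram (recovering μ, σ within 2% and τ within 5 ADU at ~20%
censoring; the near-Gaussian regime of small σ with deep τ is weakly
identified and needs the larger sample), bias-restoration checks use
ten 96×96 single-annulus replicates at 20% censoring, and frame-level
tests use 32–320 pixel grids scaled from the 4096² physical camera
while preserving its angular extent. Degenerate inputs are rejected
loudly: empty annuli, histograms with fewer than 3 distinct positive
bins, models with no censored mass despite observed zeros, and offsets
that would leave the unsigned 16-bit range.

## Known limitations

- Truncated values are modeled, not recovered; accuracy is bounded by
  the adequacy of the lognormal fit in each annulus.
- Fits share no information across annuli or frames; very small annuli
  (≲ a few hundred pixels) can fail the distinct-bin requirement.
- Only concentric annuli are supported as correction regions.
- Only the SMV unsigned-short dialect described above is read/written.
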