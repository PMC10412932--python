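# Methods

## Biological setting and model structure

A tamoxifen pulse (days 0–4; t = 0 at the first injection) induces permanent
YFP expression in cells that divide during the pulse, with low per-division
efficiency.  Thymocytes divide extensively during development, peripheral
naive T cells rarely, so YFP enters the naive CD4/CD8 pools almost entirely
via export of labeled mature single-positive (mSP) thymocytes.  The naive
pools are treated as homogeneous and at steady state (dN/dt = 0; the
generator's near-constant pool sizes reflect the same assumption), host age
effects are neglected over the 42–110-day age range, and self-renewal is
modeled as single divisions at a low daily rate p rather than bursts.

Rather than modeling the intrathymic chain of labeled precursors, the label
content of the source is described empirically:

* counts: Y(t) = Y0 − a·t^b·e^(−ct).  Y(0) = Y(∞) = Y0; with a < 0 the curve
  rises above the plateau and returns.  The printed sign convention is kept
  and `a` left unconstrained, so the fit decides the orientation.  The
  nonzero plateau encodes residual label influx from heritably labeled
  progenitors, which visibly sustains labeled mSP numbers months after the
  pulse and must be present for the chase-phase decay to be interpreted
  correctly.
* normalized counts: Z(t) = k·e^(at)·(1 + e^(v(t−τ)))^(−(a+b)/v), an
  exponential rise at rate a switching smoothly (sharpness v, time τ) to
  decay at rate b.  Evaluated in log space; its a, b are a separate parameter
  set from the bump curve's.
* the YFP+Ki67+ mSP curve K+(t) takes the bump form with its own parameters;
  K−(t) = max(Y − K+, 0), with clamping logged, because the two curves are
  fitted independently and may cross slightly.

The peripheral models (counts, frequency, Ki67-stratified; see README for
the equations) are linear time-invariant ODEs driven by these sources.  The
Ki67-stratified observables are fitted as the recast pair (L, ℓ+) because
the measured Ki67+ and Ki67− labeled counts derive from one cell-counter
reading times flow fractions and therefore share their count error, whereas
L (counts) and ℓ+ (a flow fraction) are statistically independent.  The
recast system is integrated in the (L+, L−) variables and transformed on
output, which is algebraically identical and avoids the 0/0 singularity of
dℓ+/dt at L(0) = 0; the equivalence of the two forms is enforced by a
100-draw property test at 1e−6 relative tolerance against an independent
adaptive solver.

Initial conditions are L(0) = L+(0) = L−(0) = 0 at the first injection
(peripheral label is negligible at day 4); nonzero initial states are
supported for property tests and for fits anchored at the first sampling
time.

## Numerics

The forward models are solved with an exact exponential propagator:
eigendecompose the constant system matrix, then advance each eigenchannel
with φ-function quadrature of the forcing, interpolated quadratically within
grid steps (default h = 0.05 d).  This is exact for constant or linear
forcing — so the constant-source closed forms hold to machine precision —
and accurate to ~1e−7 relative for the empirical sources, whose t^b terms
(b < 2) have unbounded derivatives at t = 0; a 32-fold-refined startup
segment over the first day handles that.  Halving h changes solutions by
< 1e−6 relative.  Nearly defective system matrices (a measure-zero parameter
set) are nudged by 1e−9 before decomposition.  Monte-Carlo-heavy routines
(bootstrap replicates, calibration suites) use h = 0.25 d, whose ~1e−6
relative error is far below measurement noise.

Fitting minimizes unweighted sums of squared residuals on transformed
observations: log for counts, logit for fractions and ratios.  The
transforms approximately variance-stabilize flow-derived data, which is what
justifies unit stream weights in the simultaneous objective; degrees of
freedom are total residuals minus free parameters.  Fractions are clamped to
[ε, 1−ε] with ε = half the smallest nonzero value of the stream before
logit.  Optimization is a seeded Latin-hypercube search over the kinetic
parameters (default 200 points; recovery studies use 40–60, which suffices
because stage-one source fits center the source block) followed by bounded
trust-region least-squares refinement of the best five starts.  Search
bounds: Θ ∈ [0.05, 5], μ ∈ [1/500, 0.5], β ∈ [0.02, 5] (log scale),
p ∈ [−0.05, 0.1] (linear).  Sources are reparametrized for search as
(plateau, peak height, b, c) — log scale on the two amplitudes — making the
box constraints meaningful at any b, c.

The division-rate lower bound deliberately extends below zero so that the
p = 0 null lies in the interior of the parameter space: with p clamped at
zero the nested F-test is conservative by the usual boundary argument
(roughly half the null fits would sit exactly at the boundary), whereas with
the interior null its type-I error is nominal — the calibration suite
measures 0.053 at α = 0.05 over 1000 null cohorts.  Negative p is a fitting
device, not a biological claim; predictions are clipped into (0, 1) before
transforms.

Bootstrap uncertainty is case resampling of mice with replacement —
preserving within-mouse coupling across streams — with the full pipeline
rerun per replicate: source curves that were fitted from data are refitted
on each resample (warm-started from the base solution), so source
uncertainty propagates into the intervals; sources the caller froze stay
frozen.  Intervals are percentile 95%.  Replicates are warm-started at the
base estimates; more than 20% replicate failures aborts with diagnostics.

## Synthetic cohorts

The generator emulates the study design: 61 mice, ages uniform on [42, 110]
days (metadata only), one sacrifice per mouse on integer days spread over
4–66, thymic mSP and spleen+LN naive records per lineage.  Default pools:
naive CD4 2×10⁷, naive CD8 1×10⁷, mSP4 10⁶, mSP8 3×10⁵ cells.  Default
ground-truth kinetics are the simultaneous-fit point estimates per model
family (e.g. frequency model: Θ = 0.59/d, 1/μ = 35 d for CD4; full model:
Θ = 0.84/d, 1/μ = 21 d, 1/p = 300 d, 1/β = 1.7 d).  Source-shape defaults
put the Y peak near day 10 with a plateau about a tenth of the peak;
frequency-model truths drive the generator with the logistic Z form directly
so that generation and fitting share a source family.

Noise: counts are multiplicative lognormal (CV 0.2), fractions carry
Gaussian noise on the logit scale (SD 0.3) — reproducing the observation
that frequencies are less noisy than counts — and both are centered to be
mean-preserving on the natural scale (the lognormal's −σ²/2 shift; a
second-order correction for the logit), so generator noise introduces no
systematic bias into unbiasedness checks.  Spleen and LN records of a mouse
derive from a single noisy pooled count split 45/55, so all labeled subset
counts of that mouse share one count error; organ-level fractions equal the
noisy pooled value, so weighted pooling recovers it exactly.  Each mouse's
bulk naive Ki67 fraction is generated from the quasi-steady-state relation
at its own realized thymic Ki67+ count and naive pool, reflecting the
within-mouse pairing the validation analysis exploits.

What the generator does **not** emulate: flow-cytometer acquisition and
gating noise, per-cell label-induction stochasticity, host/cell-age
structure in the rates, intrathymic development dynamics (bulk mSP Ki67 is a
constant 35%), or any drift in pool sizes.  Passing recovery tests therefore
demonstrates estimator correctness under the stated noise model and design,
not robustness to those unmodeled features of real data.

## Study sizes and calibration suites

Recovery studies use 25 replicate cohorts per target (seeds 1–25 under the
default base seed) — enough to pin medians to a few percent while keeping a
full study under a minute.  The F-test calibration uses 1000 null cohorts
with sources frozen at truth; bootstrap coverage uses 100 experiments of 200
replicates on the frequency model with the separate strategy.  Replicate
counts and search sizes are the package's own accuracy/effort trade-off and
are set in one place (`recovery.py`, the test fixtures).

## Known limitations

* The inter-mouse variance components of the real experiment are unknown;
  the defaults are calibrated qualitatively to the published scatter, so
  absolute CI widths on real data may differ.
* The 62-day chase cannot resolve interdivision times of hundreds of days —
  the F-test decides whether p is resolvable, and the CD8 recovery medians
  for p are essentially bound-limited, mirroring the published uncertainty.
* Whether the original analysis excluded any mice is unrecorded; the
  pipeline keeps every row and logs observables it must drop (e.g. ℓ+ of a
  mouse with no labeled naive cells).
* Only the two printed empirical source forms are implemented; the analysis
  is reported to be insensitive to that choice, but alternatives are not
  explored here.
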