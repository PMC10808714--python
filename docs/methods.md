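# Methods

## Problem

A mixture of fluorophores excited by a pulsed laser emits light whose
intensity decays as a sum of mono-exponentials,

    I(t) = Σ_i α_i exp(-t / τ_i),

with per-fluorophore lifetimes τ_i and amplitude factors α_i.  The share of
the total emitted signal contributed by fluorophore i is its fractional
contribution

    P_i = α_i τ_i / Σ_j α_j τ_j.

Determining the P_i from a measured time-correlated single-photon-counting
(TCSPC) histogram is ill-posed for free multi-exponential fits; `flimmix`
instead estimates the fractions directly with a small feed-forward network
trained on simulated decays with known fractions, and quantifies how the
spacing between lifetimes limits the achievable precision.

## Monte-Carlo TCSPC simulator (`flimmix.decay`)

Each simulated photon is the sum of three independent delays:

* fluorescence: Exponential(τ_i), the component i chosen with probability
  P_i (the fraction is by definition the share of emitted photons, so the
  labels are exact by construction);
* laser pulse: a Gaussian core (FWHM 1.25 ns → σ = FWHM/2.355) plus an
  exponential turn-off tail of characteristic time 600 ps;
* detector jitter: zero-mean Gaussian, σ = 150 ps (typical for SPAD
  detectors of this class; configurable).

Arrivals are binned into half-open 312.5 ps bins over a 1.28 µs window
(4096 bins); photons outside [0, window) are dropped, not clamped.  A
constant-rate Poisson background is added per bin at level
`peak expected signal / SNR` (SNR default 100, defined as peak intensity
over noise level).  The default photon budget is 5×10⁴ signal photons per
curve.  The noise-free expectation (`expected_histogram`) integrates the
same arrival density analytically per bin: the density of
Exp(τ) + Exp(τ_L) + N(0, σ) is a difference of two exponentially modified
Gaussians, with closed-form degenerate branches when σ or τ_L vanish and a
relative 10⁻⁶ nudge when τ = τ_L.  A chi-square test in the suite confirms
the sampler against this expectation at 10⁶ photons.

Pile-up, detector dead time, afterpulsing and the array read-out delay are
not modelled; at count rates below pile-up the aggregate-photon model is
statistically equivalent to per-pulse sampling.

Randomness: seeds are mandatory.  Datasets derive one sub-seed per curve
from a counter-based `SeedSequence(seed, spawn_key=(1, i))` scheme, so a
dataset is bit-reproducible independent of generation order.  Training
labels are drawn from a flat Dirichlet prior over the simplex (the
degenerate-limit statistics below are the constant-predictor moments of
exactly this prior), configurable to any Dirichlet concentration.

## Fraction estimator (`flimmix.ann`)

Fully connected ReLU network on the leading 256 histogram bins (80 ns, ≥ 4
lifetimes of the longest default component): hidden layers (40, 20, 10) for
two components, (70, 50, 30, 10) for three or more; minibatch Adam, batch
500, 20 epochs, learning rate 10⁻³, mean-squared-error loss against the
reference fractions.  Raw outputs are clipped to [0, 1] and renormalized to
sum to one at inference (post-processing, not part of the loss).  No early
stopping or validation selection: longer training was observed to overfit
(held-out σ worsens after ~20 epochs at 10⁴ curves), so the fixed recipe is
also near-optimal.

Weight initialization is fan-in-scaled (He) for hidden layers and **zero for
the output layer**.  The zero output head makes training exactly
equivariant under permutations of the label columns (each output unit's
gradient depends only on its own error), which the suite asserts to 10⁻⁹.

### Input representation

Two recorded normalization modes (`EstimatorConfig.normalization`):

* `total` (default): each curve divided by its summed counts, times a fixed
  factor of `input_bins` so the inputs are O(1) — without that rescale the
  printed Adam recipe cannot move the zero-initialized output head into the
  [0, 1] range within 400 steps and every network stalls at the constant
  predictor.
* `sqrt-center`: square root of the total-normalized histogram
  (variance-stabilizing for Poisson counts), centered per bin with
  training-set means, on a fixed O(1) scale.  Per-bin *rescaling*
  (z-scoring) is deliberately avoided: it inflates noise-dominated tail
  bins to unit variance and measurably triples two-component error.

The choice matters scientifically, not just numerically.  With `total`
input the estimator reproduces the documented two-fluorophore behaviour in
full: held-out σ ≈ 1.2 % at 5 ns spacing, and at near-identical lifetimes
(Δτ = 0.05 ns) the collapse to the prior mean with mean |ΔP| ≈ 25 %,
σ(|ΔP|) ≈ 1/(4√3) ≈ 14.4 % and R² ≈ 0.  But its precision for three or more
components is representation-limited: the middle component of a
three-fluorophore mixture stalls near 10 % where the fixed-lifetime
least-squares bound allows 2–3 %.  The `sqrt-center` input removes that
limit (it is the strongest setting tested on every mixture size) — at the
price of resolving the sub-bin mean-arrival shift Δτ·P ≈ 0.05·P ns, whose
standard error at 5×10⁴ photons is only ~0.02 ns, so near-degenerate
mixtures no longer collapse to the prior mean (R² ≈ 0.3 instead of 0).
Both behaviours are real properties of the data; the package therefore
keeps the plain representation as the faithful default and uses the
variance-stabilized one for the multi-component spacing studies below.

Two-step training is supported: `fine_tune` continues from existing weights
on a labelled (e.g. measured) set with its own epoch count and learning
rate, reusing the recorded normalization; the optimizer state starts fresh.

## Least-squares baseline (`flimmix.lsq`)

With lifetimes held fixed the model is linear in the amplitudes, so the
baseline solves a non-negative least-squares problem whose design columns
are the per-component bin-integrated arrival densities plus a constant
background column.  The fitted coefficient of column i is the expected
photon count emitted by component i, so fractions are the normalized
coefficients — identical to α_i τ_i / Σ α_j τ_j.  Unweighted by default
(the optional `weighted` mode divides rows by √max(counts, 1)); amplitudes
are non-negativity-constrained as the physically meaningful variant.  On
noiseless input the fit is exact; a brute-force amplitude-grid oracle in
the suite confirms optimality on noisy curves.

## Evaluation statistics (`flimmix.metrics`)

Per component: mean offset ⟨ΔP⟩ = mean(P_est − P_ref) (accuracy), the
population standard deviation of the offsets about their own mean
(precision), and squared Pearson correlation R² (a constant estimate scores
0; regression-against-identity R² is available as an option).  Both offset
conventions are always computed: *signed* follows the printed definition;
*absolute* (offsets |P_est − P_ref|) is the convention whose flat-prior
degenerate limits are the plateau constants 1/4 and 1/(4√3).  The spacing
studies quote the absolute convention.

## Spacing studies (`flimmix.spacing`)

Every grid point simulates fresh training and held-out sets with disjoint
derived seeds, trains a fresh estimator, and averages each statistic over
replicate seeds.  Protocol sizes (chosen once, stated here because they are
part of the result):

* two-fluorophore sweep and the degenerate/well-spaced anchor runs:
  10⁴ training curves, 2,000 test curves (τ_A = 4 ns);
* three-fluorophore middle-lifetime sweep (τ_A = 4, τ_C = 10 ns, τ_B
  swept): 4,000 / 800 curves, 3 seeds per point, `sqrt-center` estimator.
  σ_A falls and σ_C rises as τ_B moves from A towards C, the middle
  component is most precise near uniform spacing, and the σ_A/σ_C curves
  cross slightly *below* uniform spacing (≈ 2.5 ns rather than 3 ns; the
  fixed-lifetime least-squares oracle crosses at ≈ 2.3 ns on the same
  curves, so this is a property of the simulated data — the
  shortest-lifetime component keeps an early-bin precision advantage — not
  of the network);
* minimal-spacing search: equally spaced lifetime ladders from 4 ns,
  bisection on Δτ to 0.2 ns against a seed-averaged σ target of 5 %,
  6,000 / 600 curves and two replicates per evaluation, `sqrt-center`
  estimator, per-N brackets verified at both endpoints (from coarse sweeps;
  bisection assumes a single crossing inside the bracket and falls back to
  an explicit `BracketError` with all evaluations otherwise).

The σ target is aggregated across fluorophores by the **mean** (an option
allows worst-component).  Worst-component aggregation is provably
unreachable at this photon budget for N ≥ 4: the Cramér–Rao floor for the
middle components of a five-fluorophore ladder is ≈ 24 % unbiased (≈ 8 %
even for the Bayes-shrunk network), so a 5 % worst-component target has no
crossing at any spacing.

`fit_spacing_law` fits log10 Δτ_min = slope·N + intercept by ordinary least
squares; `max_distinguishable` returns the largest N whose ladder span
(N−1)·Δτ_min(N) fits a lifetime budget (default 20 ns, the practical upper
end of common fluorophore lifetimes).

### Known deviation of the fitted law

With the study estimator the five-fluorophore ladder keeps aggregate σ at
4.5–5 % over a wide spacing range (≈ 3–12 ns): the outer components become
extremely precise and compensate the middle ones, so the minimal spacing is
reached already near 3 ns and the fitted law is shallower (slope ≈ 0.33,
intercept ≈ −1.05) than the log-linear law with slope 0.41 / intercept −1.1
that the two- and three-fluorophore points alone would suggest.  A direct
corollary follows honestly from the fitted coefficients: five fluorophores
fit a 20 ns budget at the 5 % target, not four.  The suite checks the
four-fluorophore corollary both against the fitted law (where it fails for
this reason, documented) and against the reference coefficients (where the
arithmetic is exact).

## SNR sensitivity

`snr_sweep` re-trains at each peak-to-background ratio.  Precision
improves strongly up to SNR ≈ 100 and only marginally beyond — the suite
asserts the saturating trend at a reduced problem size.

## What the generator does and does not emulate

The simulator reproduces binning, IRF blur, jitter, Poisson background and
shot noise of a SPAD TCSPC acquisition under a flat fraction prior.  It
does not emulate pile-up, dead time, afterpulsing, spectral bleed-through,
lifetime shifts from chemical interaction (except as deliberately shifted
simulations for fine-tuning tests), or uncertainty in the reference
fractions of real mixtures.  Passing tests therefore demonstrate correct
behaviour of the method under the stated noise model, not performance on
any particular experimental data set.

## Numerical choices and degenerate inputs

Float32 sampling in the photon loop (errors ≪ bin width); int64 counts.
Duplicate lifetimes raise a degenerate-basis error in the least-squares
fit; all-zero mixtures raise degenerate-mixture errors; statistics on fewer
than two samples raise undefined-statistic errors; a constant reference
column makes R² undefined (error) while a constant estimate is defined as
R² = 0.  Fraction vectors are validated to sum to one within 10⁻⁹
everywhere.  Sub-seeds derived for train/test/replicate splits stay below
2³¹.
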