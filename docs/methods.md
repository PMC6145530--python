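# Methods

## Signal model and conventions

A record `y_1..y_N` (uniform grid, `dt` hours per sample) is modeled as a sum
of exponential modes plus noise,

```
y[n] = Σ_i P_i λ_i^(n-1) + w[n],    λ_i = e^(σ_i + j ω_i),
```

with complex residues `P_i`. Sample indices enter with exponent `n−1`
(equivalently, components are evaluated on `m = 0..N−1`), so the first sample
carries weight `Σ_i P_i`. For real records poles occur in conjugate pairs;
one pair collapses to a real damped cosine
`A·e^(−σm)·cos(2π·m·dt/T + θ)` with

* **amplitude** `A = 2|P|` per conjugate pair (so `A` is the peak amplitude
  of the cosine; a real pole contributes `|P|`),
* **decay** `σ = −ln|λ|` per sample (positive = decaying, negative =
  growing),
* **period** `T = 2π·dt/|arg λ|` hours,
* **phase** `θ = arg P`, normalized to `(−π, π]`.

A pole with `|Im λ| < 1e−6` and `Re λ > 0` is the **dc** (trend) term and
prints as period `"dc"`. A complex pole whose conjugate is missing from the
estimated set (tolerance `1e−6·max(1,|λ|)`) is kept as a single component and
flagged `paired=False` with a warning. The dc term is deliberately *modeled*
(as a pole near +1) rather than removed by centering; `decompose(...,
center=True)` is available but off by default.

## The matrix-pencil estimator

1. `k = ⌊N/2⌋`; Hankel matrix `H[i,j] = y[i+j−1]` (1-based), shape
   `k×(k+1)`, from the first `2k` samples. With `N` odd the last sample does
   not enter the model but does enter the reported approximation error,
   which is always computed over all `N` samples.
2. Raw quadruple (1-based slices) `E = H(1:k, 1:k)`, `A = H(1:k, 2:k+1)`,
   `B = H(1:k, 1)`, `C = H(1, 1:k)`; singular spectra `s1 = svd([E; A])`,
   `s2 = svd([E, A])`.
3. **Order rule**: `r` = number of values of `s2` with `s_i/s_1 ≥ ε`
   (default `ε = 0.01`; `ε = 0` keeps everything). The rule is applied to
   `s2` because the column space of the pencil `[E, A]` drives the left
   projector; `s1` is computed and reported alongside. If the retained
   spectrum would split a conjugate pole pair (detected after the
   eigen-decomposition), `r` is incremented by one.
4. Projection `X = u2[:, :r]`, `Y = v1[:, :r]`; reduced quadruple
   `E_r = XᵀEY` etc.
5. Poles = generalized eigenvalues of `(A_r, E_r)`, solved by the
   QZ-based generalized solver rather than by forming `E_r⁻¹A_r`, so a
   nearly singular `E_r` degrades gracefully (infinite eigenvalues are
   dropped with a warning). Residues `P_i = (C_r v_i)(v̂_i E_r⁻¹B_r)` with
   `v_i` the right eigenvectors and `v̂_i` the rows of the inverse
   eigenvector matrix; `E_r⁻¹B_r` is computed by least squares. A
   numerically defective eigenvector basis (condition number above 1e14)
   raises an error naming the failure.

On noiseless sums of `m` damped cosines with `2m+1 ≤ k`, decomposition at
the true order is exact to ~1e−12; this round trip against the simulator is
the package's central test oracle.

## Comparison methods

All subspace baselines share the Hankel snapshot convention: snapshot
covariance `R = HHᵀ/M` over the `M = k+1` Hankel columns (configurable).

* **ESPRIT**: poles from the shift invariance `S₂ = S₁Ψ` of the `K`
  principal eigenvectors of `R`; estimates frequency *and* decay; exact on
  noiseless exact-rank data.
* **Spectral MUSIC**: pseudospectrum `1/‖Gᴴe(ω)‖²` over a 4096-point grid on
  `[0, 2π)` (steering vectors have snapshot length; the grid is circular for
  peak picking). Poles are reported as `e^(jω)` — magnitude exactly 1 by
  construction; MUSIC cannot estimate decay. The written description of the
  steering-vector length is internally inconsistent in places in the
  literature; snapshot-length steering vectors are the dimensionally
  consistent choice.
* **Root MUSIC**: roots of the null-spectrum polynomial `pᴴ(1/z)GGᴴp(z)`;
  the `K` roots inside the closed unit disk nearest the circle are projected
  onto it.
* **Prony LS**: autoregressive coefficients by least squares over all
  shifts, poles as characteristic roots. Noise biases these poles toward
  the interior of the unit disk — the package's cohort scan makes this
  damping bias visible against the pencil.
* **DFT**: the plain decomposition on the rigid period grid `N·dt/k`; used
  to demonstrate leakage when the true period (e.g. 24.8 h at `N = 48`)
  falls between grid points. Off-grid leakage is real but mild when the
  true frequency is close to a bin: a 24.8 h cosine on 48 hourly samples
  still concentrates ≈98% of its energy in the 24 h bin.
* **Complex-Morlet CWT** (`cmorB-fc`, defaults `B = 1.5`, `fc = 1.0`,
  both configurable; defaults chosen as a middling trade-off between time
  and frequency resolution since no canonical value exists): scalogram on a
  requested period grid with `scale = fc·T/dt`. Boundaries use zero padding
  and the cone of influence is reported explicitly (e-folding half-width
  `√B·scale` samples, growing linearly with period) instead of being hidden
  by reflection padding.

Amplitudes for all pole-only estimators come from a Vandermonde
least-squares fit; near-coincident poles trigger an ill-conditioning warning
with the condition number.

## Statistical rhythm tests

### ARSER

Pipeline per record: linear detrend → Savitzky–Golay smoothing (polynomial
order 4; window = largest odd integer ≤ N/4, never below 5) → AR spectrum
`s(ω) = σ²/|1 − Σ α_k e^(−iωk)|²` for each of three estimators
(Yule–Walker, conditional MLE = OLS, Burg) → candidate periods = local
spectral maxima inside the search window (default [20, 28] h; set e.g.
[10, 14] for 12 h rhythms) → harmonic regression → AIC picks the estimator →
F statistic with `(r−1, N−r)` degrees of freedom, `r` = number of regression
coefficients.

Two design choices matter for calibration and deviate from a literal reading
of the published pipeline description:

* The smoothing feeds *only* the period search. The regression and F test
  use the detrended, unsmoothed record; fitting the smoothed record tests
  against autocorrelation the smoother itself created and inflates the null
  rejection rate from ~0.05 to ~0.44.
* When no spectral peak lies in the window, the regression falls back to
  the window-midpoint period (the original tool's default-period behavior)
  instead of returning p = 1; otherwise nearly half of all null records
  carry an atom at p = 1 and the null p-distribution is far from uniform.
  `fallback_period=None` restores the strict behavior.
* The AR order defaults to `min(round(24/dt), ⌊N/3⌋)`; the naive
  "record length / sampling interval" choice equals `N` at `dt = 1`, which
  is degenerate.

Measured under white noise (N = 48): rejection rate 0.054 at α = 0.05,
Kolmogorov–Smirnov distance to uniform 0.047 over 500 replicates.

### JTK and RAIN: exact nulls by generating functions

Records are folded into `n = T/dt` phase groups per cycle. With
`U_ij = #{(x ∈ group i, y ∈ group j) : x ≤ y}` (Mann–Whitney counts; ties
count 1, or ½ with the optional midrank flag):

* **JTK** (monotone): `s = Σ_{i<j} U_ij`, two-sided via the more extreme of
  the increasing/decreasing tails with a factor-2 cap.
* **RAIN** (umbrella with wrap, peak group `e`): rising comparisons
  `Σ_{i<j≤e} U_ij`, falling comparisons with the direction reversed
  `Σ_{e≤i<j} U_ji`, plus wrap comparisons `Σ_{i>e} U_1i` of the trough
  group against every post-peak group (the next cycle's descent toward the
  trough).

Under the null (exchangeability, continuous data) the JTK statistic's
distribution is the Gaussian `q`-multinomial
`Π_{u=1}^{N}(1−z^u) / Π_d Π_{v=1}^{m_d}(1−z^v)`.

For RAIN the key observation is that the set of counted comparisons is the
comparability graph of a **series-parallel partial order**: trough group 1
at the bottom, then the rising chain (groups 2..e−1) *in parallel with* the
reversed falling chain (groups n..e+1), then peak group `e` on top. The
exact null pmf of a concordance count over a series-parallel poset
factorizes: a parallel composition convolves the two sub-distributions, and
a series composition additionally convolves a two-sample Mann–Whitney
`q`-binomial for the cross-block comparisons. Every factor is a ratio of
`(1−z^a)` terms, so the pmf is assembled by exact integer polynomial
multiplication and synthetic division and is *identical to brute-force
enumeration* (verified exhaustively for all group-size vectors with
Σm ≤ 8). A naive product of independent per-segment nulls is *not* exact —
the segments share the trough and peak groups — and measurably disagrees
with enumeration already for three singleton groups.

Peak positions: `e = n` degenerates to the pure rising chain; `e = 1` makes
the wrap term contradict the falling chain (the comparison structure becomes
cyclic, not a poset), so the exact null accepts `2 ≤ e ≤ n` and the scan
covers that range. The scan evaluates every cyclic phase rotation (and for
RAIN every peak position) and Bonferroni-corrects the best raw p-value by
the number of tests (`n` for JTK, `n(n−1)` for RAIN) — deliberately
conservative; measured null rejection at α = 0.05 over 2000 white-noise
records: ≈0.03 (JTK), ≈0.01 (RAIN). Exact arithmetic is budgeted at
Σm ≤ 60 observations; longer records must be subsampled or pooled first.

## Simulator

`simulate.generate` emits `Σ_i A_i e^(−σ_i m) cos(2π m dt/T_i + θ_i) + w[m]`
with i.i.d. Gaussian noise (the noise family is a modeling choice; only mean
zero and variance σ² are prescribed). The standard preset is

| i | A   | σ      | θ        | T    |
|---|-----|--------|----------|------|
| 1 | 1   | 0.005  | 0        | ∞    |
| 2 | 1   | 0.004  | π/2 − 6  | 24.8 |
| 3 | 0.3 | −0.002 | π/2      | 11.8 |
| 4 | 0.1 | 0.005  | π/2 + 1  | 7.5  |

implying true poles `0.995`, `0.964 ± 0.250i`, `0.863 ± 0.509i`,
`0.666 ± 0.739i`. Phases only shift the cosines and do not affect the pole
targets. `subsample` and `split_parts` (first/second half, odd/even
positions) support the sampling-rate studies.

The generator emulates additive-noise damped-cosine records on a uniform
grid. It does **not** emulate heteroskedastic measurement error, missing
samples, non-uniform sampling, heavy-tailed biological outliers, or
between-replicate variability — passing tests on it demonstrate correctness
of the estimators under the stated model, not robustness to every
real-data pathology.

## Problem sizes and study conditions used by the checks

* Exact-recovery oracles: N = 50–80, noiseless, order 7.
* Noisy recovery: N ∈ {100, 200}, noise sd 0.05, 25 seeds, medians of the
  pole real parts.
* Trend-test level: 2000 white-noise records of N = 48, hourly, period 24.
* RAIN-vs-JTK power: amplitude-1 sawtooth (18 h rise, 6 h fall), noise
  sd 0.2 — a clearly detectable but non-trivial signal-to-noise ratio —
  100 replicates.
* Cohort ordering: 100 synthetic two-rhythm profiles (24 h + 12 h cosines,
  amplitudes 0.5–1.5 and 0.3–0.8, noise sd 0.05) over 48 hourly samples.

## Numerical notes

* Angles between signals use `arccos` of the real part of the normalized
  inner product, clipped to [−1, 1]; near ±1 (collinear signals, real
  inputs) the chord formula `2·arcsin(‖u − v‖/2)` is used instead because
  `arccos` loses half the significant digits there.
* `select_order` returns at least 1; an all-zero spectrum is rejected.
* Vandermonde systems and the Prony normal equations use `lstsq`
  (minimum-norm under rank deficiency, with a warning).
* All stochastic experiments take explicit integer seeds
  (`numpy.random.default_rng`); every routine is deterministic given
  (data, order, ε).

## Known limitations

* Non-uniform sampling and missing values are out of scope; series must be
  resampled upstream.
* Each row of a matrix is decomposed independently — no multichannel joint
  fit, no recursive/online updating.
* The trend tests' exact arithmetic caps total observations at 60 per fold;
  no asymptotic approximation is provided beyond that.
* MUSIC reports frequencies only (poles pinned to the unit circle); decay
  must come from the pencil, ESPRIT, or Prony.
* Forward–backward averaging, spatial smoothing and TLS-ESPRIT variants are
  deliberately not implemented (only the plain LS forms are compared).
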