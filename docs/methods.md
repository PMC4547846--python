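# Methods

## Models

All models live on a 1-D cortex arclength x ≥ 0 from the pole tip, with
concentrations in arbitrary fluorescence-intensity units (fluorescence is
linear in concentration, so no molar calibration is attached anywhere).

**Detailed cascade.** P_i(x,t) is the concentration of kinase carrying i
phosphorylations (i = 0…N, biological default N = 6, the number of sites
controlling membrane affinity). Unphosphorylated kinase arrives through the
source S(x); every state diffuses with the same D; intermolecular
phosphorylation moves mass up the ladder at rate βP (P = ΣP_i, the
encounter rate with any neighbour); state i detaches at κ_i:

    ∂P_0/∂t = D ∂²P_0 + S(x) − βP·P_0 − κ_0 P_0
    ∂P_i/∂t = D ∂²P_i + βP·P_{i−1} − βP·P_i − κ_i P_i      (0 < i < N)
    ∂P_N/∂t = D ∂²P_N + βP·P_{N−1} − κ_N P_N

The β terms cancel in the sum, so ∂P/∂t = D∂²P + S − Σκ_iP_i exactly (this
identity is asserted numerically in the tests). Placing the β-loss term
only on states below N is a modelling choice: the top state has no further
site to phosphorylate; its trans-encounters still count in P. κ_0 = 0 by
default (fully dephosphorylated kinase does not detach), κ non-decreasing
and strictly increasing once positive; the default shape is linear,
κ_i = i·κ, with a superlinear i²·κ option.

**Simplified models.** Summing the cascade and approximating the
detachment density by a power law gives D∂²P − α_γ P^γ + S with
1 < γ ≤ 2. The package's working models are the two ends and two rivals:

* trans: D∂²P − αP² + S — the γ = 2 limit; analytic steady state
  P = C/(x+x₀)², C = 6D/α, x₀ = (12D²/αS)^(1/3) (re-derived from the flux
  condition −DP'(0) = S and verified against the solver to < 1 %);
* cis: D∂²P − αP + S — exponential, λ = √(D/α), no buffering;
* cluster: flux-form diffusion ∂x(D(P)∂xP) − αP + S with Hill-type
  D(P) = D₀/(1+(P/P*)^h), default h = 2 (the functional form of the
  concentration-dependent-diffusion hypothesis is not canonical; only the
  *sign* of its ratio-vs-source prediction is relied upon);
* combined: cluster diffusion with the quadratic trans decay.

**Threshold-shift bound.** For the trans model the position where P crosses
a fixed threshold moves by Δx = x₀(1 − k^(−1/3)) under a k-fold source
change — bounded by x₀ for arbitrarily large k. This is the positional
statement of buffering.

## Numerics

Finite differences on a uniform grid (default half-cell L = 7 µm,
dx = 0.01 µm), zero-flux boundaries at both ends. The source is a
half-Gaussian band at the pole of width w (default 0.3 µm, the Tea4 cap
scale) normalized so its trapezoidal integral equals S. Time stepping is
either explicit Euler (dt bounded by dx²/2D; the simple reference scheme)
or the default semi-implicit scheme (implicit diffusion via a banded
solve, explicit reactions, dt = 5·10⁻³ min); both agree within tolerance
in tests. Convergence is declared when max|∂P/∂t| / max P < 10⁻⁶ min⁻¹;
non-convergence raises an error carrying the residual, instability (NaN or
negative blow-up) raises an error advising a smaller dt, and sweep drivers
retry with halved dt.

Three numerical facts shape the defaults used for measuring model
predictions:

1. **Finite source band.** With a band of width w the node value at x = 0
   underestimates the point-flux amplitude (mass enters distributed, and
   roughly 3w/x₀ of the detachment happens inside the band). Steady-state
   pole quantities of trans-type profiles are therefore extracted by
   least-squares fitting C/(x+x₀)² to the profile interior (0.15–3 µm) and
   reporting A = C/x₀², λ = x₀(√2−1), P_tot = C/x₀; prediction sweeps use
   a narrow band (w = 0.05 µm). Pointwise agreement with the analytic
   oracle is verified separately (band ≤ 0.05 µm, long domains: < 1 %
   beyond 5w) and narrowing the band converges monotonically to the
   analytic profile.
2. **Domain truncation.** The power-law tail is heavy: P(L)/P(0) =
   (x₀/(L+x₀))² never reaches the 10⁻³ of a comfortable truncation at
   half-cell length, and the zero-flux far boundary inflates the tail by a
   perturbation growing like (x/L)⁶/2. Quantities read from the interior
   fit window are unaffected at L = 7; oracle-equivalence tests use L = 30.
3. **Effective exponent γ.** The fit regresses log₁₀(Σκ_iP_i) on log₁₀ P
   over nodes with P > 1 % of the amplitude, excluding the source band
   (x < 5w, where the summed equation is dominated by S(x) rather than the
   decay law). The slow unphosphorylated tail (κ_0 = 0) makes the fit
   domain-sensitive at L = 7 (the 1 % cutoff never engages); it is
   domain-converged by L = 21 µm (γ changes < 0.02 going to L = 28), which
   is the γ-study default. In the calibrated strong-phosphorylation regime
   (N = 6, κ_i = i·0.5 min⁻¹, β·A ≈ 5κ reached by fixed-point iteration on
   β) the result is γ ≈ 1.88 with R² ≈ 0.98 — inside the theoretical
   (1.5, 2] band, with γ = 2 as the upper bound realized by the simplified
   quadratic model and γ = 1 by the rate-uniform (constant-κ) control.
   Empirically γ *decreases* when β is pushed far beyond the calibrated
   regime (state occupancy saturates at the top of the ladder, making
   detachment nearly linear in P); the γ study therefore asserts the
   bounds, not a trend in β.

## Synthetic populations

The generator emulates the *output* of cortical-profile quantification
(tidy per-position intensity tables), not images: 97 cells × 4 profiles
(two poles × two cortex sides) = 388 pole profiles sampled every 0.1 µm
over 0–4 µm. Per cell a Tea4 source strength is drawn log-normally
(SD of ln S = 0.35, several-fold 95 % spread); secondary profiles are
scaled by a uniform-in-log factor in [1/2, 1] (within-cell two- to
four-fold source asymmetry). The Tea4 profile is the half-Gaussian cap;
the noiseless Pom1 profile is the generative model's steady state for that
pole's S (analytic for trans/cis, solver otherwise). Both channels then
receive independent mean-one log-normal noise per position (CV 0.1; shot
and speckle noise is scale-dependent, hence multiplicative; no spatial
autocorrelation in this version) and a constant additive background
(0.05). Per-cell cytoplasmic levels (log-normal, ~two-fold population
range, uncorrelated with pole source) and cell lengths are carried as
metadata.

The default trans parameters are D = 1 µm²/min, α = 0.45, median S = 2,
i.e. median x₀ ≈ 2.4 µm, half-max decay length ≈ 1 µm and amplitude ≈ 2.4
against a 0.05 background. The scale was chosen to match measured cortical
kinase gradients (decay lengths of order 1 µm), which also places the
profiles in the regime the 0.1 µm sampling and 0.3 µm analysis windows are
sized for; all scaling exponents are independent of this scale. What the
generator does *not* emulate: optical blurring and spatially correlated
speckle, cell-to-cell variation in geometry or background, segmentation
artefacts, and any coupling of the source to the cytoplasmic pool — so
passing recovery tests demonstrate estimator consistency under the model's
own assumptions, not robustness to every property of real images.

## Measurement pipeline

Per pole: centered moving average (window 0.3 µm, edge-truncated),
background subtraction, amplitude = mean of the first 0.3 µm, decay
length = interpolated first crossing of fraction × amplitude (default
fraction 0.5; exponent predictions are fraction-independent), cortical
total = trapezoidal integral. Censored decay lengths (no crossing in
range) are excluded from regressions and counted. The default background
estimate is the per-cell minimum of the smoothed *source-channel* (Tea4)
profile: the compact source cap genuinely reaches baseline inside the
sampled range, whereas the minimum of the heavy-tailed gradient channel
sits on signal proportional to that cell's amplitude and demonstrably
attenuates the λ-vs-A slope (from ≈ −0.44 to ≈ −0.32 on default
populations). A constant override and a Pom1-channel option remain
available. Exponent estimates move < 0.05 across smoothing windows
0.1–0.5 µm.

Poles are sorted by Tea4 amplitude and partitioned into ⌈1/batch-fraction⌉
contiguous batches differing in size by at most one (larger first; 388
poles at 5 % → 8×20 + 12×19). Regressions are weighted least squares of
log₁₀ y on log₁₀ x with inverse-variance-of-the-mean weights propagated to
log scale, var(log₁₀ y) ≈ (sem/(y ln 10))²; zero/undefined SEMs fall back
to equal weights with a warning. The ratio regression
log₁₀(Pom1/Tea4) vs log₁₀ Tea4 equals the amplitude regression minus one
in slope (identity asserted to 10⁻¹⁰); its sign is the model discriminant.
The per-pole regressions reported alongside use the slope conventions:
decay length on amplitude (prediction −1/2), Pom1 on Tea4 amplitude (2/3),
cortical total on amplitude (1/2, equivalently amplitude on total = 2).

Known limitations: the amplitude-band mean is a mildly biased estimator of
the extrapolated pole amplitude (bias ~ band/x₀ and amplitude-dependent),
which is the main reason population recoveries sit at −0.45 rather than
−0.50; batch means regress seed-stably but per-pole regressions are offered
only unweighted; Bartlett's test assumes log-normal amplitudes (exact here
by construction, approximate for real data).
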