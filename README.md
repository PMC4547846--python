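# pom1grad

Reaction–diffusion modelling and statistical analysis of **buffered cortical
protein gradients**, built around the Pom1 kinase gradient of fission yeast.

Pom1 is a membrane-associated DYRK-family kinase deposited at the cell pole
(by the microtubule-delivered Tea4–phosphatase complex), which then diffuses
along the cortex and detaches after auto-phosphorylation. If
auto-phosphorylation is *intermolecular* (trans), the detachment rate grows
with the local Pom1 concentration itself, and the steady-state gradient obeys

```
D ∂²P/∂x² − α P² + S(x) = 0
```

on the half-line from the pole tip (concentrations in fluorescence-intensity
units). With a point influx S at the pole the solution is the power law

```
P(x) = C / (x + x₀)²,   C = 6D/α,   x₀ = (12 D² / (α S))^(1/3)
```

with amplitude A = C/x₀², decay length λ = x₀(f^(−1/2) − 1) at amplitude
fraction f, and cortical total P_tot = C/x₀. Two sub-linear power laws follow
and constitute the gradient's *buffering* against source fluctuations:

* **λ ∝ A^(−1/2)** — brighter poles make *steeper* gradients (log–log slope −1/2),
* **A ∝ S^(2/3)** — the amplitude under-responds to the Tea4 source (slope 2/3),

and a position read out at a fixed concentration threshold shifts by
Δx = x₀(1 − k^(−1/3)) < x₀ for any k-fold source change. By contrast,
*cis*(intramolecular)-phosphorylation gives an exponential gradient whose
decay length √(D/α) ignores the source entirely (no buffering), and a
cluster-based alternative (diffusion decreasing with concentration,
D(P) = D₀/(1+(P/P*)^h)) predicts the *opposite* sign for the
gradient/source-ratio-vs-source relationship.

The package provides:

* `model_core` — closed forms for the trans/cis models (steady states,
  amplitude, decay length, cortical total, threshold-shift bound);
* `pde_solver` — finite-difference steady states of all model variants,
  including the detailed N-state phosphorylation cascade, and the fitted
  effective decay exponent γ of its coarse-grained decay law α_γ P^γ;
* `synthetic_profiles` — a generator of realistic paired Pom1/Tea4 cortical
  intensity populations (97 cells × 4 profiles, log-normal source spread,
  within-cell pole asymmetry, multiplicative noise, background);
* `profile_analysis` — the measurement pipeline: smoothing, background
  subtraction, amplitude/decay-length extraction, 5 %-batch averaging by
  Tea4 level, inverse-variance-weighted log–log regressions (base 10),
  ratio analysis, CV-vs-distance, exponential-vs-power-law comparison,
  Bartlett's variance test;
* `pipeline` / `pom1grad` CLI — one-command reproduction runs and the
  detailed-model γ study.

## Worked example

```
$ pom1grad reproduce --seed 1 --out run1 --check
sweep_decay_length_vs_amplitude: -0.5014 (target -0.5000 +/- 0.02) [ok]
sweep_amplitude_vs_source: 0.6746 (target 0.6667 +/- 0.02) [ok]
sweep_amplitude_vs_total: 2.0056 (target 2.0000 +/- 0.08) [ok]
population_decay_length_vs_amplitude: -0.4506 (target -0.5000 +/- 0.08) [ok]
population_pom1_vs_tea4: 0.6291 (target 0.6667 +/- 0.08) [ok]
population_cis_decay_length_vs_amplitude: -0.0041 (target 0.0000 +/- 0.08) [ok]
```

The first three lines are numerical steady states of the trans model
(15 source strengths over two decades, D = 1 µm²/min, α = 6) reproducing the
analytic exponents −1/2 (decay length vs amplitude), 2/3 (amplitude vs
source) and 2 (amplitude vs cortical total, i.e. P_tot ∝ √A). The last three
are the full measurement pipeline run on synthetic populations
(388 noisy profiles, 10 seeds): the trans-generated population recovers both
buffering exponents, while a cis-generated control shows the
amplitude-independent decay length of an unbuffered gradient. `run1/`
contains the model-prediction curves, the population and its per-pole fits,
20-batch summaries, `regressions.json` and `report.md`; the report also
shows that Pom1 pole amplitudes vary less than the Tea4 source driving them
(CV 0.33 vs 0.45, Bartlett p ≈ 5e−9) — buffering seen as variance
compression — and that the ratio-slope signs separate the trans (−),
combined (−) and pure cluster (+) hypotheses.

Library use mirrors the CLI:

```python
from pom1grad import ModelParams, steady_state_summary

s = steady_state_summary(ModelParams(D=1.0, alpha=6.0, source_strength=2.0))
print(s.amplitude, s.x0, s.total_cortical)   # 1.0 1.0 1.0
```

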