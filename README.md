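# sibcm — stable individualized brain computing models

`sibcm` builds a personalized whole-brain simulation from nothing but a
parcellated resting-state BOLD matrix. It is aimed at computational
neuroscientists who want subject-specific mean-field models without
diffusion imaging: instead of a tractography-derived structural connectome,
the model's coupling matrix is a *stable spatiotemporal co-activity
pattern* inferred from the functional data themselves.

The pipeline:

1. **Pattern inference.** Sliding-window correlation matrices Σ(n)
   (window 30 samples, step 10) are stacked edge-by-window and decomposed
   by a fused robust-PCA program solved with ADMM,

       min ‖L‖\* + λ₁‖S‖₁ + λ₂‖B vec(L)‖₁   s.t.  L + S = X,

   separating a low-rank component shared across windows from sparse
   per-window excursions. The across-window mean of the low-rank part,
   symmetrized and normalized, is the coupling matrix W_L.

2. **Forward model.** A one-population dynamic mean-field model per region,

       dS_i = [ −S_i/τ_s + r (1 − S_i) H(z_i) ] dt + σ dW_i,
       z_i = ω J S_i + G J Σ_j ζ(W_L)_ij S_j + I₀,

   with the Balloon–Windkessel hemodynamic cascade producing TR-sampled
   BOLD.

3. **Inversion.** The four free parameters (ω, G, I₀, σ) are fitted by a
   genetic algorithm maximizing PSAC — the correlation between empirical
   and simulated phase-space association (PSA) matrices, an SSIM-form
   similarity of 3-D delay-embedded regional trajectories. The first half
   of the data builds the pattern, the second half is the fitting target.

4. **Evaluation.** Static/dynamic FC similarity, FCD and its KS distance,
   Welch spectra, DFA Hurst exponents, Kuramoto synchrony/metastability,
   integration/segregation/ISOR, binary graph topology, RSN block FC and
   test–retest ICC.

See `docs/methods.md` for model details, parameter defaults and known
limitations.

## Worked example

Everything below runs on synthetic data generated by the package itself
(no external dataset needed):

```python
import numpy as np
from sibcm import (DMFParameters, GAConfig, SimConfig, extract_pattern,
                   fit_parameters, make_modular_pattern,
                   make_synthetic_subject, pattern_correlation, split_half)

# a synthetic subject: 20 regions, modular coupling, HCP-like TR
pattern = make_modular_pattern(m=20, n_modules=4, seed=1)
bold, truth = make_synthetic_subject(pattern, DMFParameters(),
                                     duration_seconds=600 * 0.72, seed=0)

# split-half pattern stability
first, second = split_half(bold)
p1, _ = extract_pattern(first)
p2, _ = extract_pattern(second)
print(f"split-half pattern r = {pattern_correlation(p1, p2):.3f}")
print(f"pattern vs generating truth r = {pattern_correlation(p1, pattern):.3f}")

# reduced GA inversion against the second half
model = fit_parameters(
    bold,
    GAConfig(population_size=24, generations=15, n_reps=2, master_seed=1),
    sim=SimConfig(duration_seconds=300 * 0.72, tr_out_seconds=0.72,
                  dt_seconds=0.002),
)
print(f"best PSAC = {model.best_psac:.3f}")
print(f"fitted G  = {model.best_params.coupling_G:.2f}")
```

Output:

```
split-half pattern r = 0.920
pattern vs generating truth r = 0.957
best PSAC = 0.878
fitted G  = 2.93
```

The two half-series yield nearly the same coupling pattern (r = 0.92), and
both closely match the matrix that actually generated the data (r = 0.96) —
the pattern is a stable, recoverable object, not a noise artifact. The
fitted simulation reproduces the target's phase-space association structure
at PSAC 0.88. The fitted G lands near the generating value of 4.0 on the
model's flat (ω, G, I₀) fitness ridge; see `docs/methods.md` on why these
parameters are identifiable jointly rather than marginally.

A command-line interface mirrors the library:

```bash
sibcm make-fixture --m 20 --duration 300 --out-dir demo
sibcm extract demo/synthetic_bold.tsv --tr 0.72 --out-dir demo
sibcm simulate demo/pattern.tsv --duration 200 --seed 3 --out demo/sim.tsv
sibcm evaluate demo/sim.tsv --tr 0.72 --reference demo/synthetic_bold.tsv
sibcm fit demo/synthetic_bold.tsv --tr 0.72 --population 24 --generations 15
sibcm sweep-omega demo/pattern.tsv --omega 0.9 --omega 1.2 --seed 0 --seed 1
```

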