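# Methods

This note documents the models implemented in `sibcm`, the choices made
where the design was genuinely open, and what the synthetic test conditions
do and do not establish.

## Co-activity pattern inference

The observed parcellated BOLD series `x_i(t)` (T time points, M regions) is
cut into overlapping windows (default length 30 samples, step 10, matching
common sliding-window connectivity practice) and a Pearson correlation
matrix Σ(n) is computed per window. The upper triangles of the N window
matrices are stacked as columns of an edge-by-window matrix X ∈
R^{E×N}, E = M(M−1)/2, which is decomposed by

    min ‖L‖* + λ₁‖S‖₁ + λ₂‖B vec(L)‖₁   s.t.  L + S = X,

where ‖·‖* is the nuclear norm, ‖·‖₁ the elementwise ℓ₁ norm, and B the
first-order difference operator across consecutive windows, i.e. a fused
(total-variation) penalty per edge. The low-rank term asks that a few
shared edge-patterns explain every window; the sparse term absorbs
transient, window-specific excursions; the fusion term additionally pulls
each edge's profile toward a constant across windows. Penalizing the rank
of the *stacked* matrix is essential: a per-window rank penalty decouples
the program into N independent robust-PCA problems and discards exactly the
across-window sharing the method is built on (we verified that per-window
decomposition fails to recover planted shared structure at M = 20 while the
stacked form recovers it exactly). Stacking the upper triangle also keeps
the enforced unit diagonal of a correlation matrix — which carries no
coupling information — out of the decomposition entirely.

Solver: two-block ADMM. The L-update is singular-value soft-thresholding
of the E×N matrix; the S-update is elementwise soft-thresholding; the
fusion term is carried by an auxiliary copy Z = L whose update is an exact
1-D total-variation prox per edge across the window index (Condat's direct
algorithm, validated in the tests against a box-constrained dual QP solved
with L-BFGS-B). Defaults: ρ = 1, tolerance 1e-6 on the scaled primal/dual
residual, 1500 iterations. The returned per-window components are the
re-symmetrized columns with the diagonal assigned to the low-rank side, so
L_n + S_n = Σ(n) holds exactly and S's support is purely off-diagonal.

Regularization defaults: λ₁ = 1/√N. For the tall edge-by-window matrix the
window axis carries the random-sign corruption, and the dual certificate
for exact recovery requires λ₁ ≥ max_e |u_e|/√N for the normalized shared
edge profile u; both sides scale as 1/√N, so the calibration is stable in
the number of windows. (The more familiar 1/√max-dimension rule, derived
for square incoherent matrices, sits below the certificate here and
produces systematic singular-value shrinkage.) λ₂ = 0.1·λ₁; the fusion
penalty mainly accelerates agreement across windows — the stacked rank
penalty already pools them.

The stable pattern W_L is the across-window mean of the low-rank
components, symmetrized, diagonal zeroed (self-coupling is an explicit
model parameter, below), and scaled to unit maximum absolute off-diagonal
weight. Signed entries are retained: anti-correlated region pairs yield
negative coupling weights.

## Dynamic mean-field model

Each region carries one synaptic gating variable S_i ∈ [0, 1]:

    dS_i = [ −S_i/τ_s + r (1 − S_i) H(z_i) ] dt + σ dW_i
    z_i  = ω J S_i + G J Σ_j ζ(W)_ij S_j + I₀
    H(z) = (a z − b) / (1 − exp(−d (a z − b)))

with transfer-function constants a = 270 n/C, b = 108 Hz, d = 0.154 s and
synaptic constants J = 0.2609 nA, τ_s = 0.1 s, r = 0.641 from the reduced
mean-field literature. The four free parameters are the recurrent strength
ω, global coupling G, background input I₀ (nA) and noise amplitude σ.

ζ(W) normalizes the coupling matrix by its spectral radius, ζ(W) = W/ρ(W).
G and the pattern's weight scale enter the dynamics only through their
product, so some scale convention is required for G to be comparable across
subjects; normalizing by the spectral radius pins the dynamically relevant
quantity — the gain G·J·λ_max of the most amplified network mode — rather
than the size of the single largest weight, which depends on how an
estimate distributes mass across edges.

Integration is Euler–Maruyama at dt = 1 ms (dt ≤ τ_s/10 enforced), noise
increments σ√dt·N(0,1), gating clamped to [0, 1], initial state
S_i(0) = 0.1 + 0.01·U(0,1) from the run seed. One numpy Generator per
simulation, seeded explicitly, makes trajectories bitwise reproducible.
Halving dt changes deterministic endpoints by < 1e-4.

Operating point. With these constants the per-region dynamics are
bistable. Defaults ω = 0.9, G = 4.0 (spectral scale), I₀ = 0.28 nA,
σ = 0.005 place the network in the subcritical low-activity state close to
— but a finite margin below — the jump to the saturated branch. This is
the regime in which these models are normally operated and the only one in
which the coupling structure expresses itself in simulated FC (measured
FC–pattern correlation ≈ 0.95 near the edge vs ≈ 0.05 in the frozen or
saturated regimes). σ = 0.005 keeps noise-assisted escapes from the
metastable low state unobservable at the run lengths used (the escape rate
is exponential in 1/σ²) while leaving correlation structure unchanged.

## Hemodynamics

The Balloon–Windkessel model maps gating to BOLD per region: vasodilatory
signal Ż = S − κZ − γ(f−1), inflow ḟ = Z, volume τv̇ = f − v^{1/α},
deoxyhemoglobin τq̇ = f[1−(1−ρ)^{1/f}]/ρ − q v^{1/α−1}, and
BOLD = V₀[k₁(1−q) + k₂(1−q/v) + k₃(1−v)]. Constants: κ = 0.65 s⁻¹,
γ = 0.41 s⁻¹, τ = 0.98 s, α = 0.32, ρ = 0.34, V₀ = 0.02, k₁ = 7ρ, k₂ = 2,
k₃ = 2ρ−0.2. Integration shares the neural Euler step from rest
(Z = 0, f = v = q = 1); zero input keeps BOLD at exactly 0.

Burn-in default is 60 s. The startup transient (identical across regions
because all regions leave rest together) decays below 1e-4 only after tens
of seconds; at a 10 s burn-in it dominates every pairwise correlation in
coupled regimes (measured mean FC ≈ 1.0 vs ≈ 0.005 at 60 s). Decimation to
the acquisition TR is plain subsampling of every round(TR/dt)-th point —
the hemodynamic kernel is already a strong low-pass, and subsampling keeps
the output bit-reproducible.

## Phase-space association (PSA) and the fitting cost

Each region's signal (after per-region z-scoring) is delay-embedded in 3-D:
PS_i(t) = (x_i(t), x_i(t+τ), x_i(t+2τ)). One global τ per subject is the
median of per-region delays, each chosen to precede the first local
minimum of the autocorrelation function. For a region pair, PSA is an
SSIM-form similarity pooled over all 3(T−2τ) scalar entries of the two
embeddings:

    PSA_ij = (2μ_iμ_j + c₁)(2σ_ij + c₂) / ((μ_i² + μ_j² + c₁)(σ_i² + σ_j² + c₂)).

Defaults c₁ = (0.01R)², c₂ = (0.03R)² with R the dynamic range of the
standardized signals, the SSIM convention. The printed pooled-statistic
form is symmetric in i and j; a `directional` variant whose
cross-covariance pairs PS_i(t) with PS_j(t+τ) is provided as well and is
genuinely asymmetric on lead–lag structured signals. The fitting default is
the literal (symmetric) form. The scalar cost PSAC is the Pearson
correlation of off-diagonal PSA entries between the empirical and
simulated matrices (upper triangle for the literal variant).

## Genetic-algorithm inversion

To avoid overfitting, the series is split in half: the first half yields
the co-activity pattern (model construction), the second half the PSA
target (model fitting). Candidates (ω, G, I₀, σ) are scored by averaging
the PSA matrices of n_reps simulations (duration matched to the fitting
half) and correlating with the target. The GA uses tournament selection
(size 3), uniform blend crossover (rate 0.8), per-gene Gaussian mutation
(rate 0.2, sd 10% of range) and single-individual elitism; defaults
population 50, 30 generations, n_reps 3. Bounds: ω ∈ [0.5, 1.5],
G ∈ [0, 6] (spectral scale), I₀ ∈ [0.25, 0.45] nA, σ ∈ [0.001, 0.02].

All candidates share one simulation seed set derived from the master seed
(common random numbers). Near the optimum the fitness surface is flatter
than the per-candidate evaluation noise, so independent seeds make
selection chase lucky draws; CRN makes the surface deterministic and the
fit exactly reproducible from the master seed.

Known limitation — parameter identifiability. The fitted parameters enter
the subcritical dynamics largely through a single effective quantity, the
proximity of the low-activity state to its instability. (ω, G, I₀)
therefore compensate along a ridge on which PSAC is flat to within
evaluation noise: on synthetic subjects the generating point and ridge
points with G off by 30–40% differ by < 0.01 in PSAC even at
1200-sample fitting halves. G is identifiable jointly with (ω, I₀) —
and the attained PSAC is high and reproducible — but its marginal value
should not be over-interpreted. Self-consistency of the whole loop is
instead established by the split-half pattern stability and the
FC/PSA-level agreement between fitted simulations and the target.

## Evaluation metrics

Static FC is full-series Pearson correlation; similarity is reported as
the correlation of Fisher-z upper triangles (edge level) and of per-region
mean FC (node level). Dynamic FC reuses the sliding-window protocol
(30/10); σ-dFC is each edge's across-window standard deviation, the FCD
matrix correlates upper-triangle window-FC vectors, and FCD distributions
are compared by the two-sample KS statistic. Spectra are Welch
periodograms (Hann, nperseg ≤ 256, 50% overlap) compared by cosine
distance of region-mean spectra. The Hurst exponent is estimated by
detrended fluctuation analysis (box sizes log-spaced in [4, T/4], linear
detrend, least-squares slope). Phase metrics band-pass 0.01–0.1 Hz
(Butterworth order 2, zero-phase) and take Hilbert phases; synchrony and
metastability are the time-mean and time-std of the Kuramoto order
parameter. Integration is the weighted global efficiency of each window's
absolute FC, segregation the Newman modularity of the positive window FC
under the RSN partition (greedy modularity communities when no partition
is supplied), ISOR the fraction of windows whose integration exceeds the
median of a reference. Graph metrics binarize |FC| at a proportional
density (default 0.15, zero entries never become edges) and report global
and local efficiency, characteristic path length (finite distances only
on disconnected graphs, flagged), clustering, mean participation
coefficient and modularity. RSN block FC averages within-block
off-diagonal and between-block entries over the seven canonical networks.
Test–retest reliability is the consistency ICC, (MSR − MSE)/(MSR +
(k−1)MSE) from the two-way ANOVA decomposition (matches pingouin's
ICC(C,1) to 1e-10 in the tests).

## Synthetic data

`fixtures` generates every input the tests and the acceptance script use:

- `make_planted_stack`: a shared symmetric rank-r component (Gaussian
  factors, peak magnitude 0.35) plus per-window symmetric outliers
  (uniform magnitude 0.45–0.6, random sign, 5% of edges by default,
  support disjoint from the diagonal), symmetrized, unit diagonal, clipped
  to [−1, 1] — magnitudes are chosen so clipping never bites and the
  ground truth stays exact. Positive semidefiniteness is deliberately not
  enforced.
- `make_modular_pattern`: block-modular coupling with jitter; the default
  between-module weight is −0.15 (signed, like real co-activity patterns,
  which resemble FC with anti-correlated systems). All-positive max-abs-one
  patterns drive the mean-field network into saturation at any appreciable
  coupling because their leading mode is the global mode.
- `make_synthetic_subject`: closes the loop — simulates the mean-field +
  Balloon model from a known pattern and parameters and returns TR-sampled
  BOLD with the generating truth.
- `fractional_gaussian_noise`: exact circulant-embedding fGn, the
  known-exponent signal for the DFA estimator.

What the synthetic conditions do not emulate: scanner/physiological noise
structure, motion, spatial autocorrelation of parcels, inter-subject
variability, or the empirical spectral content of HCP/ADNI acquisitions.
Passing tests establish internal consistency of the pipeline and
recoverability under the model's own assumptions, not performance on real
cohorts.

## Problem sizes

Desk-scale defaults used throughout the tests and the acceptance script:
M = 20 regions, 600–1200 samples at TR 0.72 s, windows of 30 samples at
step 10, GA with population 24 and 15 generations at n_reps 2 and dt 2 ms
for fitting runs, dt 1 ms elsewhere. These sizes keep every decomposition
instance comfortably inside the exact-recovery regime and every
statistical check well-powered while remaining quick to run.
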