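# Methods

This note documents the generative model, the inversion scheme, the
synthetic-data generator and the numerical choices made in `nfdcm`, at the
level of detail a user needs to interpret its outputs and its tests.

## Generative model

### Neural field dynamics

A single cortical source is a one-dimensional patch of normalized radius
ℓ = 1 carrying three layers: excitatory spiny stellate input cells (1),
inhibitory interneurons (2) and excitatory pyramidal output cells (3).
Mean depolarizations V(x, t) ∈ R³ obey second-order synaptic dynamics

    V̈ + 2B V̇ + B² V = A B (D ⊗ σ∘V) + G U

with A = diag(mₑ, mᵢ, mₑ), B = diag(κₑ, κᵢ, κₑ), input vector
G = (κₑ mₑ, 0, 0)ᵀ (exogenous fluctuations enter the stellate layer only),
and logistic firing function σ(v) = 1 / (1 + e^{r(η − v)}).  The wiring
follows the classical three-population microcircuit: pyramidal → stellate
(13), pyramidal → interneuron (23), stellate → pyramidal (31) and
interneuron ⊣ pyramidal (32, the one inhibitory connection).

Connectivity kernels are exponential in distance with a
distance-proportional conduction delay,

    d_ij(x, t) = (α_ij / 2) e^{−c_ij |x|} δ(t − υ |x|),

so their spatiotemporal Fourier transform is

    D_ij(k, ω) = α_ij (c_ij + iυω) / ((c_ij + iυω)² + k²).

υ is the transit time from patch centre to boundary; υ = 0 makes every
delay vanish and reduces the field to a point-source (neural mass) model.
The two connections onto pyramidal cells share a decay constant
(c₃₂ = c₃₁).

### Linearization and transfer function

The dynamics are linearized around the resting state V₀ = 0, with scalar
gain γ = σ′(0) = r e^{rη} / (1 + e^{rη})².  (At the default r = 0.54,
η = 0 this is r/4 = 0.135.)  The working point is taken at v = 0 by
construction, not solved self-consistently; the gain is therefore exact at
the stated priors and approximate away from them.  Per spatial frequency
k the perturbation transfer function is

    T(k, ω) = (2iωB + B² − ω²I₃ − J(k, ω))⁻¹ G,   J = A B D(k, ω) γ,

and the observed (pyramidal) component has the closed form, derived by
cofactor expansion of the 3×3 system matrix,

    T₃(k, ω) = D₃₁ γ κₑ² mₑ² (κᵢ + iω)² / R(k, ω)
    R = (κₑ+iω)⁴ (κᵢ+iω)²
        + (κₑ+iω)² κₑ κᵢ mₑ mᵢ D₂₃ D₃₂ γ²
        − (κᵢ+iω)² κₑ² mₑ² D₁₃ D₃₁ γ².

The closed form and the generic complex linear solve are independent code
paths, verified against each other to 1e-9 relative error in the tests.

### Predicted sensor spectrum

Under periodic boundary conditions the patch supports standing waves at
k_j = jπ/ℓ; the predicted single-channel auto-spectrum is

    g_Y(ω, θ) = (π/ℓ) Σ_{j=1..n_modes} |L_j|² |T₃(k_j, ω)|² g_U(ω)

with n_modes = 32 by default (the modal sum is converged: 64 vs 32 modes
change integrated power by far less than 1%), spatially white input with
white + pink temporal spectrum g_U(ω) = α_U + β_U/ω, and a Gaussian
lead-field weight.

**Lead-field convention.** The sensor's spatial sensitivity profile is
L(x) = φ₁ exp(−x²/φ₂).  Its transform in the cycles-per-length convention
is a Gaussian ∝ exp(−φ₂ π² ν²); the modal weight is therefore evaluated at
ν_j = k_j / 2π, i.e. L_j = φ₁ exp(−φ₂ π² j² / 4), while the connectivity
transfer functions use angular wavenumber k_j = jπ.  With the default
φ₂ = 0.01 (an LFP-like, spatially narrow sensor) roughly ten modes
contribute appreciably.  Evaluating the same Gaussian at angular k instead
would suppress every mode above j = 1 and make the 32-mode sum (and the
field/mass distinction) vacuous, so the cycles convention is the one
consistent with the model's intent.

**Observed data model.** Observed cross-spectra are

    g_obs(ω) = g_Y(ω, θ) + g_N(ω, θ) + ε(ω),
    g_N(ω) = α_N + β_N/ω,   Re ε, Im ε ~ N(0, Σ(ω, λ)),

with channel noise g_N again white + pink.  "Pink" throughout means a
1/ω density.

### Parameters, units, defaults

All internal computation is in SI units (s, s⁻¹, rad/s) on the normalized
patch; configuration files use the printed field units and are converted
exactly once at load time.

| parameter | meaning | default (internal) | from printed units |
|---|---|---|---|
| mₑ, mᵢ | max postsynaptic depolarization | 8, 32 mV | — |
| κₑ, κᵢ | postsynaptic rate constants | 250, 35.71 s⁻¹ | 1/4, 1/28 ms⁻¹ |
| α₁₃, α₂₃, α₃₁, α₃₂ | kernel amplitudes | 2000, 8000, 2000, 1000 | — |
| c_ij | kernel decay | 16 /radius | 0.32 mm⁻¹ × 50 mm |
| υ | transit time | 16.7 ms | 50 mm ÷ 3 m/s |
| r, η | sigmoid slope, inflection | 0.54 mV⁻¹, 0 mV | — |
| φ₁, φ₂ | lead-field gain, width² | 1, 0.01 | — |
| α_U, β_U | input white/pink | 1, 1 | chosen; see below |
| α_N, β_N | channel-noise white/pink | 1e-7, 1e-7 | chosen; see below |
| n_modes | standing-wave modes | 32 | — |

The four kernel amplitudes keep their distinct tabulated defaults (2000,
8000, 2000, 1000); only the decay constants of the two connections onto
pyramidal cells are tied.  The tabulated gain value 0.135 is exactly
σ′(0) at the prior (r, η) and is treated as derived, never as a free
parameter.  Input-spectrum coefficients default to α_U = β_U = 1 (a mild
1/ω tilt on top of white drive); channel-noise coefficients default to
1e-7, placing the noise floor about an order of magnitude below the tail
of the prior source spectrum so that it is present but not dominant.
Both are estimated during inversion, so only their priors matter.

### Stability screen

The spectral model is well defined whenever no characteristic root of any
retained mode sits on the real-frequency axis.  A parameter set is flagged
unstable when, for any mode k_j, either

1. the DC characteristic determinant det(B² − J(k_j, 0)) is nonpositive —
   its sign flip is the zero-frequency bifurcation produced by, e.g.,
   scaling up the excitatory loop gain α₁₃ α₃₁; or
2. the smallest singular value of the system matrix dips below 1e-8 times
   its median over the frequency grid (a resonance at a sampled
   frequency).

This is deliberately a *spectral-domain* criterion.  The linearized fixed
point at the default parameters in fact carries a weakly unstable complex
pair (real part ≈ +18 s⁻¹, from the inhibitory loop whose DC gain is
≈ 15): a strict Hurwitz criterion would reject the default priors
themselves, while the steady-state spectrum remains finite, smooth and
physiologically shaped.  The screen therefore rejects only parameter
regions where predicted spectra genuinely blow up; during inversion any
candidate step into such a region is rejected and the previous estimate
retained.

## Spectral data features

Raw recordings are summarized by a vector autoregression of order 8
(channel means removed; ordinary least squares on lagged regressors, with
a small ridge fallback if the design is numerically rank deficient).  The
package-wide spectral convention is a **one-sided, per-Hz density**:
g(f) = (2/fs) H(f) Σ_innov H(f)*, H(f) = (I − Σ_m A_m e^{−2πi f m/fs})⁻¹.
Only relative spectral shape matters to the inversion, since the input and
noise amplitudes are free parameters.  No windowing or detrending beyond
mean removal is applied before the fit.  A band-pass + resampling helper
(`preprocess`) covers the usual acquisition chain (e.g. 0.6–60 Hz,
down-sampling to 125 Hz).

## Variational-Laplace inversion

Each physical parameter is estimated through a log-scale deviation,
θᵢ = Pᵢ e^{μᵢ}, with independent Gaussian priors μᵢ ~ N(0, 1/16).  The
free set for the field model is (mₑ, mᵢ, κₑ, κᵢ, α₁₃, α₂₃, α₃₁, α₃₂, c,
υ, r, φ₁, φ₂, α_U, β_U, α_N, β_N) — 17 parameters, where `c` scales all
decay constants jointly (one lateral-extent scaling).  η stays fixed: a
log-scaling cannot move a zero prior.  The mass variant removes υ from the
free set and forces it structurally to zero — 16 parameters.  The
structural route is the default because υ = P e^μ can never reach zero
under log-scaling; an extreme shrinkage prior on the υ scaling is
available (`PriorDensity.shrink`) as the alternative framing of the same
nesting.

The observation-error covariance is Σ(ω, λ) = e^{−λ} I over frequency
bins — a single log-precision hyperparameter.  The Gibbs energy

    G = −½ Re(ε)ᵀ Σ⁻¹ Re(ε) − ½ Im(ε)ᵀ Σ⁻¹ Im(ε) − ½ ρᵀ Ω⁻¹ ρ
        − ½ ln|Σ| − ½ ln|Ω|,     ε = g_pred(μ) − g_obs,  ρ = μ − φ,

treats real and imaginary parts of complex residuals separately; for real
single-channel auto-spectra the imaginary terms are identically zero.
The reported free energy is the Laplace bound

    F = G(μ) − ½ ln|−∂²G/∂μ²| + (p/2) ln 2π,

whose log-determinant is computed by symmetric eigendecomposition.

Optimization is Gauss–Newton coordinate ascent:

- **Jacobian** ∂ε/∂μ by central finite differences with step 1e-3 on the
  log-scalings (predictions are smooth in log-parameters); the step is
  halved and retried if a perturbed prediction lands on an unstable set.
- **λ update** in closed form, e^{−λ} = (‖Re ε‖² + ‖Im ε‖²)/n, capped at
  |λ| ≤ 40.  The cap matters: some parameter pairs (lead-field gain vs
  input amplitude) are exactly confounded, so the Gauss–Newton Gram is
  singular and only the prior precision regularizes the curvature; an
  unbounded precision would amplify roundoff past that regularization
  when residuals vanish.
- **μ step** with Levenberg–Marquardt damping on the Gauss–Newton step
  (damping ×10 on rejection, ÷10 on acceptance).  A candidate is accepted
  only if it passes the stability screen and does not lower F; the F trace
  over accepted iterations is therefore nondecreasing by construction.
- **Convergence** when ΔF < 1e-3 nats on three consecutive accepted
  iterations, or after 128 iterations, or when damping exceeds 1e10.

The posterior is q(μ) = N(μ*, C) with C the negative inverse curvature at
convergence.  These are declared defaults of this implementation, not
reconstructions of any particular historical setting.

## Model comparison

Fitted variants are ranked by F; pairwise differences are log Bayes
factors, with ΔF ≥ 3 nats labeled strong evidence.  Posteriors carry a
hash of the data they were fitted to, and comparison refuses to mix
hashes.  On data generated from the field model at its default parameters
the field model wins by a margin of order 200 nats; on mass-generated
data the mass model wins by a smaller margin, as expected when the
loser *nests* the generating model and pays mostly the complexity and
near-nesting misfit costs.

## Synthetic-data generator

`simulate_observed_spectrum` draws g_Y + g_N + ε with iid Gaussian ε of
standard deviation `noise_sd` on the 1–60 Hz, 0.5 Hz grid (119 bins — the
empirical LFP band).  The default `noise_sd` is **1e-4 of the peak** of
the noiseless spectrum.  Rationale: ε stands for the *estimation error of
spectral data features*, not channel noise (which is g_N).  Steady-state
spectra summarized from minutes of recording are very precise, and the
informative regime for field-vs-mass selection requires that precision:
the best mass-model fit to a noiseless field spectrum leaves an rms error
of only ~7e-4 of the peak, so at peak SNR of order 10–100 the two models
are indistinguishable (log-evidence margins of order 1 nat, selection
outcomes dominated by noise), while at 1e4 the generating model is
selected decisively and transit-time recovery is tight with credible
intervals that still cover the truth.  The level is a config knob on
every entry point and is recorded in every experiment output.

The generator emulates *data features* (spectra) directly; it does not
emulate the telemetric acquisition chain, raw time-series generation from
the field equations (which would require PDE integration), estimator bias
of the VAR summary, or heteroscedastic estimation error (real VAR errors
scale roughly with the local spectrum value, whereas ε here is iid across
bins to match the fitted Σ = e^{−λ}I).  Passing tests therefore
demonstrate internal consistency of model, inversion and selection under
the stated error model — not robustness to the mismatches of real
recordings.

Experiments:

- `recovery_experiment` — sweep the true υ log-scaling (default 9 steps
  over [−1, 1], i.e. 36–272%), simulate, invert the field model, report
  conditional mean and 90% credible interval (μ ± 1.645 sd).  At the
  default noise level the interval covers the truth at all but the most
  extreme scalings.
- `sensitivity_scan` — predicted spectra over a log-scaling sweep
  (default [−2.5, 2.5], i.e. 8–1200%) of one parameter; unstable rows are
  recorded as such (NaN spectra), never dropped.  Slowing conduction
  (larger υ) shifts power below 15 Hz; slowing excitatory kinetics
  (smaller κₑ) moves the spectral peak into the alpha band.
- `model_selection_2x2` — field- and mass-generated data each inverted
  with both variants.

All experiments are seeded and run from a single entry point with no
external data.

## Numerical choices and edge cases

- Conjugate symmetry T(k, −ω) = conj T(k, ω) holds analytically; predicted
  auto-spectra are computed as |T₃|² and are real and nonnegative by
  construction.
- ω = 0 is rejected when a pink (1/ω) term is active; the default grid
  starts at 1 Hz.
- Kernel transfer raises a singular-kernel error when its denominator
  vanishes (c = 0 with k = 0).
- Spectra CSV round trips are value-identical (17-significant-digit
  formatting, round-trip float parsing).
- Ill-conditioned VAR designs fall back to a ridge of 1e-8 × mean Gram
  diagonal.

## Known limitations

- Single source, single channel: multi-channel inversion of complex
  cross-spectra is structurally supported by the data containers but the
  inversion currently handles one-channel auto-spectra.
- The linearization point is fixed at V₀ = 0; strongly depolarized
  operating points are outside the model.
- One-dimensional patch with periodic boundary conditions; no 2-D cortical
  sheets, no extrinsic (between-source) coupling kernels.
- Time-domain integration of the field equations is out of scope; the
  model lives entirely in the spectral domain.
- The error model is homoscedastic across frequency bins (single λ); a
  frequency-correlated Σ basis is a natural extension but is not enabled.
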