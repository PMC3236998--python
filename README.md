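# nfdcm — neural-field dynamic causal modeling of steady-state spectra

`nfdcm` is a Python package for estimating the *spatial* parameters of a
cortical source — lateral-connection extent and conduction (transit) time —
from purely temporal data: the steady-state power spectrum recorded by a
single LFP/EEG channel.  It implements a Jansen–Rit neural **field** model as
a generative model of observed cross-spectra, inverts it with Variational
Laplace, and compares it against its nested neural **mass** homologue by
Bayesian model selection.  It is aimed at computational neuroscientists and
electrophysiologists who want to ask whether spatially extended dynamics
leave a measurable signature in single-channel spectra.

## The model

A cortical patch of normalized radius ℓ = 1 carries three interacting layers
(excitatory stellate cells, inhibitory interneurons, pyramidal output
cells) with second-order synaptic dynamics

    V̈ + 2B V̇ + B² V = A B (D ⊗ σ(V)) + G U,

where A = diag(mₑ, mᵢ, mₑ) and B = diag(κₑ, κᵢ, κₑ) hold the maximum
postsynaptic depolarizations and rate constants, σ is a logistic
depolarization-to-firing function with slope r, and D ⊗ · is a spatial
convolution with delayed exponential connectivity kernels

    d(x, t) = (α/2) e^{−c|x|} δ(t − υ|x|),

whose Fourier transform is D(k, ω) = α (c + iυω) / ((c + iυω)² + k²).
Here α is the connection strength, c the inverse lateral extent and υ the
centre-to-boundary transit time (inverse conduction velocity).  Linearizing
at the resting state (gain γ = σ′(0) = r e^{rη} / (1 + e^{rη})²) gives a
per-mode transfer function, and under periodic boundary
conditions the predicted sensor auto-spectrum is a standing-wave sum

    g_Y(ω, θ) = (π/ℓ) Σⱼ |L(kⱼ)|² |T₃(kⱼ, ω)|² g_U(ω),   kⱼ = jπ/ℓ,

with a Gaussian lead field L, the pyramidal transfer component T₃ in closed
form, and a white + pink input spectrum g_U(ω) = α_U + β_U/ω.  Setting
υ = 0 collapses all conduction delays and recovers the classical neural
mass model exactly — the mass model is a nested special case.

Observed spectra are modeled as g_Y(ω, θ) + channel noise + Gaussian error.
All physical parameters are estimated as log-scale deviations from their
prior expectations (θᵢ = Pᵢ e^{μᵢ}, μᵢ ~ N(0, 1/16)); inversion maximizes a
free-energy bound F on the log model evidence (Gauss–Newton with
Levenberg–Marquardt damping and coordinate ascent on the noise precision).
F differences between fitted models are log Bayes factors: ΔF ≥ 3 nats is
conventionally strong evidence.

## Worked example

Simulate a spectrum from the field model at its prior expectations, then
invert it with both variants and compare:

```python
import numpy as np
from nfdcm import (ModelParams, ParameterMap, PriorDensity, invert_model,
                   simulate_observed_spectrum, compare_models)

params = ModelParams()                       # standard prior expectations
data = simulate_observed_spectrum(params, seed=1)

posts = {}
for variant in ("field", "mass"):
    pmap = ParameterMap.for_variant(params, variant)
    posts[variant] = invert_model(data, PriorDensity.default(pmap.n_params),
                                  pmap)

table = compare_models(posts)
print(table.table.to_string(index=False))
print("dF =", round(table.delta("field", "mass"), 2), "nats")
post = posts["field"]
print("upsilon log-scaling: %.4f  90%% CI (%.4f, %.4f)"
      % (post.mean("upsilon"), *post.credible_interval("upsilon")))
```

prints

```
model           F
field 1506.343714
 mass 1255.182676
dF = 251.16 nats
upsilon log-scaling: 0.0022  90% CI (-0.0174, 0.0218)
```

The field model beats its mass variant by ~251 nats on field-generated
data — overwhelming evidence for spatial dynamics — and the transit-time
log-scaling is recovered near its true value of 0 with a tight 90%
credible interval.

The same workflow is available from the shell:

```bash
nfdcm simulate --seed 1 --out field.csv
nfdcm invert --data field.csv --variant field --out post_field.json
nfdcm invert --data field.csv --variant mass  --out post_mass.json
nfdcm compare post_field.json post_mass.json --out table.csv
nfdcm recover --seed 1 --out recovery.csv      # transit-time sweep
nfdcm scan --param upsilon --out scan.csv      # sensitivity scan
```

Raw time series can be summarized into spectra first with
`nfdcm estimate-spectrum` (order-8 vector autoregression), and every
command writes a JSON provenance record next to its output.

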