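# Methods

## Field model and conventions

All fields are complex phasors with the e^{+jωt} convention, stored per
unit channel drive on a regular grid in SI units (tesla, V/m, S/m). The
transverse RF magnetic field decomposes into circularly polarized
components taken literally as

    B1+ = (Bx + j·By)/2,    B1− = (Bx − j·By)/2,

with no rotating-frame conjugation; a conjugate-B1− convention would swap
the roles of the two components but leaves every downstream quantity
unchanged. The electric field inside the lossy phantom follows Ampere's
law,

    E = (∇×B) / (μ0·(σ + jωε0εr)),

evaluated with second-order central differences. The evaluation mask is
eroded by one voxel so no one-sided stencil ever enters a result; the
admittance is applied voxelwise, so uniform and voxelwise material maps
share one code path. An equivalent expanded form — three fixed derivative
patterns acting on B1+, B1− and B1z — is implemented as an independent
route and agrees with the direct curl to ~1e-15 relative, which is the
identity that justifies propagating B1+ errors (not full-B errors) into
E-field and SAR errors.

Discrete-operator exactness is the backbone of the package's guarantees:
the curl, the circular decomposition and the admittance division are all
exactly linear, so the superposition identity ΔE = Σ λk·Ek holds to
rounding error whenever E was produced from B by the same operator, and
the Monte-Carlo propagation introduces no discretization bias of its own.

## SAR and Q-matrices

Voxel SAR uses the time-averaged peak-phasor convention,
SAR = σ|E|²/(2ρ). The regulated quantity averages SAR over contiguous
10 g regions; here the region is a cube centered on each voxel, grown
symmetrically (clipped at the grid edge) until the enclosed masked mass
reaches 10 g, with the outermost shell weighted fractionally so every
region averages over exactly 10 g. Voxels that cannot gather 10 g of
masked material are excluded. This mask-aware cube scheme is the standard
simplification for uniform phantoms; it does not implement the
surface-correction rules needed for heterogeneous body models. Averaging
is evaluated with 3D integral images, so building the full Q-matrix set
(the Hermitian matrices Q(r) with w†Q(r)w the 10 g-averaged SAR of weight
vector w) costs Nc(Nc+1)/2 volume passes rather than one pass per
location. Because Q-matrices and the voxel-SAR→averaging pipeline share
the same weights, the quadratic form reproduces the pipeline to ~1e-14
relative — an internal consistency check, not an approximation.

Phantom density defaults to 1000 kg/m³ (configurable); material presets
cover the torso (σ=0.61 S/m, εr=45.7), jar (0.5, 78) and lightbulb
(0.65, 47.2) phantoms at 447 MHz.

## Monte-Carlo error propagation

NRMSE between complex maps is ‖a−b‖/‖b‖ over the evaluation mask, with
the reference map b. Two reference conventions coexist deliberately: the
mode-level NRMSE0 is referenced to the *measured* map (the ground truth
of the comparison), while per-channel errors and the perturbed-mode
NRMSEi are referenced to the *simulated* maps (the quantity being
perturbed). Voxels whose reference magnitude falls below 1% of the
mask-median are excluded so noise-dominated voxels cannot inflate the
metric; a magnitude-only variant and an optional global phase alignment
exist for sensitivity analysis and are off by default.

Perturbations are applied as w_k → w_k + λk·s_k with s_k = |w_k| (median
|w| for switched-off channels), so the uniform box bounds ±eps_k act as
relative errors; for unit-magnitude modes this is plain additive λ.
Draws are channel-major from one seeded generator, making runs bitwise
reproducible. NRMSEi is evaluated through the channel Gram matrix over
the evaluation mask — algebraically identical to synthesizing each
perturbed map voxelwise but O(Nc²) per sample — and pSAR10g through the
Q-matrix quadratic forms, so 10^5 iterations take seconds.

The relative pSAR deviation is kept *signed* and the eEMM is the 99.9th
percentile (linear interpolation between order statistics) of the signed
distribution over the selected region, floored at zero: the eEMM scales
pSAR upward as a margin, and a negative deviation cannot serve as one.
The selection keeps the full sub-level set NRMSEi ≤ NRMSE0, not only the
boundary. Degenerate inputs are handled explicitly: identical measured
and simulated maps define eEMM = 0 with a warning; a nonzero NRMSE0 that
no draw can reach (possible only for inconsistent inputs, e.g. an error
pattern that cancels in the mode map while the per-channel bounds are
large) raises an error rather than returning an empty-region percentile.

Mode sweeps reuse the same seed for every mode, so the overall maximum is
idempotent under duplicated modes, and the per-mode runs are individually
reproducible. An optional accelerator prunes the pSAR search to the
locations in the top spectral-norm quantile (default top 5%) and
re-evaluates the most extreme selected sample on the full set, recording
the relative discrepancy in the result metadata; the pruned search can
miss the true peak location by a few percent, which shifts pSAR_0 and
pSAR_i consistently and leaves the deviation ratio nearly unchanged.

The safety budget combines uncorrelated uncertainties root-sum-square,
eSAR = √(ePM² + eISV² + eEMM²), SF = 1 + eSAR, with defaults
ePM = 0.15 and eISV = 0.50. The mode-count heuristic
n = ⌈(z·σ/(e·μ))²⌉ estimates how many modes a sweep needs to represent
the B1+ error space (it is a sampling heuristic, not a coverage proof).

## Temperature-probe validation

Probe SAR is cρ·(dT/dt) with the slope fit by least squares over the
initial window of the heating curve (default 0–60 s; cρ default
3500 J/kg/K). The validation report scales simulated probe SAR by
(1 + eEMM) and flags any probe/mode pair where the scaled value still
falls below the measurement.

## Synthetic data: what it emulates and what it does not

Each channel's B field is the discrete curl of a smooth random complex
vector potential (Gaussian-windowed low-order harmonics centered between
the channel position and the phantom), so B is exactly divergence-free
under the same central-difference operators and E follows by the same
curl used on real data. The construction is quasi-static: it does not
solve a boundary-value problem, carries no wave propagation, standing-wave
or coil-geometry physics, and its SAR patterns are not those of any real
coil. That is sufficient because every operation under test depends only
on field linearity and the curl relation — but it also means passing
tests certify the propagation machinery, not the accuracy of any
particular coil model.

"Measured" maps are the simulated ones mixed by (I+Γ) — diagonal
gain/phase errors of scale 0.08 (real and imaginary parts uniform),
ring-neighbor coupling of scale 0.015, defaults chosen as a plausible
residual-modeling-error structure with coupling well below the diagonal —
plus multiplicative complex Gaussian noise of relative scale 0.02
emulating B1+ mapping noise. The evaluation mask defaults to three
central axial slices, mimicking slice-limited experimental mapping.
Because the mixing lives inside the channel span, the ground-truth field
of any mode is the weight transform w → (I+Γ)ᵀw, giving an exact oracle
for the realized pSAR10g error.

The conservativeness guarantee applies to mixings whose implied channel
perturbation lies within ± the observed per-channel error in both
quadratures — the regime in which the per-channel NRMSE genuinely bounds
the coefficient error. `draw_truth_within_bounds` draws truths from that
population by rejection; mixings outside it (strong unmodeled coupling)
can defeat the bound, which mirrors the method's stated applicability
limit rather than a defect of the implementation. Probe fixtures place
probes at locations in the top 20% of CP-mode SAR: temperature probes
only produce usable heating slopes where SAR is appreciable, and at
near-null locations the *relative* per-probe error is unbounded for any
method.

## Problem sizes and numerical choices

The default study configuration is an 8-channel, 32³-voxel (4 mm) fixture
with ~11 600 phantom voxels; eEMM runs use N = 10^5 iterations at the
99.9th percentile, and conservativeness is assessed over 200 trials of
N = 10^4. With the Gram/Q-matrix fast paths the full acceptance run
completes in about a minute on one CPU. Percentiles use numpy's linear
interpolation; peak-location ties break at the lowest linear voxel index;
seeds are plain integers fed to `numpy.random.default_rng`, with
sub-streams derived via `SeedSequence.spawn` where one seed feeds several
generators.

## Known limitations

- The cube 10 g average is adequate for uniform phantoms only.
- The eEMM is an upper bound *within the channel span*; resonant or
  strongly coupled structures introduce unrepresented field components
  that the per-channel error cannot capture.
- eISV and ePM are scalar inputs from literature or vendor data; the
  package does not estimate them.
- No VOP compression: pSAR is evaluated directly over Q-matrix sets
  (optionally pruned), which is fine at desk scale but not at
  scanner-watchdog scale.
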