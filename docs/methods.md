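# Methods

## Problem and model

`gaitdistill` estimates mass-normalized lower-limb joint torques (N·m/kg) from
six-axis IMU signals, one gait cycle at a time (cycles resampled to 101 steps,
0–100 % of the stride). Two models solve the same regression task from very
different observations:

* **Teacher.** Each IMU channel is expanded into a continuous-wavelet-transform
  magnitude scalogram (complex Morlet `cmor1.5-1.0`, log-spaced scales covering
  ≈0.5 Hz to a quarter of the sampling rate). A convolutional backbone
  (stride 2 along the frequency axis, stride 1 along time) followed by
  multi-head self-attention over time yields per-timestep features; a linear
  projection W_T maps them into a `D_anchor`-dimensional *anchor space*, from
  which a linear head reads out the torque trajectory.
* **Student.** A small stacked GRU consumes the raw 1-D channels with a
  per-timestep linear torque head. A linear *dimensional adapter* W_S maps the
  final hidden state into the same anchor space.

The published scale (`paper` preset) instantiates ≈32.2 M teacher and ≈0.47 M
student parameters (a ≥98 % reduction); the `test` preset keeps the identical
layer plan at ≤0.1 M parameters for desk-scale experiments.

## Distillation with two consistency pathways

The student minimizes

L_total = L_data + α·L_KD + β·L_Fisher + δ·L_subspace + γ·L_phy

with L_data and L_KD the (1/BT)-normalized squared errors against labels and
frozen-teacher predictions. Default weights α = 0.5, β = 0.1, δ = 0.1,
γ = 0.05: chosen once so the weighted components start at comparable
magnitudes on synthetic data. Ablation presets: M0 (all zero — a plain
supervised run, bit-identical to one), M1 (+KD), M2 (+anchor alignment),
M3 (+physics).

**Pathway I — parameter-manifold alignment.** The Gram images
G = WᵀW ∈ R^{D_anchor×D_anchor} of W_T and W_S live in a common space although
the feature widths differ. Teacher-side artifacts are computed once from the
frozen teacher and cached: G_T; the diagonal Fisher information
F_kk = E[(∂L/∂z_k)²] of the anchor activations (the expectation runs over the
training split and over timesteps, since the prediction flows through the
per-timestep anchor activations); and the projector P = U_k U_kᵀ onto the
top-k eigenvectors of G_T. The rank k defaults to the smallest k capturing
95 % of G_T's eigenvalue mass, capped at D_anchor/2. Eigenvectors are made
deterministic by descending-eigenvalue order (ties broken by index) and a sign
convention (largest-magnitude component positive). L_Fisher weights the rows
of the Gram difference (rows ≡ columns by symmetry); the plain unweighted
distance ‖G_S − G_T‖²_F is kept as a diagnostic only, since the training
objective uses the Fisher-weighted and subspace terms. Fisher weights are used
raw; a unit-mean normalization is available as an option.

**Pathway II — physics consistency.** For a single rigid segment,
τ = I_eff ω̇ + ω × (I_eff ω) + G(θ). `I_eff` is an *equivalent* inertia in
sensor coordinates — it absorbs the unknown sensor-to-segment rotation and is
learned jointly with the network, not measured. It is parameterized through
its Cholesky factor L (softplus-positive diagonal, ε = 1e−6), so I_eff = L·Lᵀ
is symmetric positive definite for every unconstrained parameter value and the
map is smooth. The gravity term — whose functional form is a modelling choice
here — is pendulum-like and linear in its coefficients:
G(θ) = a_sin·sin θ + a_cos·cos θ per axis, with learnable 3-vectors. The
residual loss filters the measured angular velocity with a Savitzky–Golay
smoother and differentiates it with the same filter, then averages the squared
sagittal residual over interior samples, excluding half a filter window at
each cycle edge where the fit extrapolates. Torque labels are scalar
(sagittal, axis index 2 by convention); the physics model is evaluated as a
full 3-vector and its sagittal component is compared.

**Stabilizers.** AdamW (weight decay 0 by default), linear learning-rate
warm-up over 5 epochs, global gradient clipping at norm 1.0. Model selection
is by validation data loss. Physics parameters join the optimizer only when
γ > 0, which keeps the γ = 0 presets bitwise identical to runs that never
construct the physics pathway.

## Savitzky–Golay settings

Window 11 (110 ms at 100 Hz) with polyorder 5, configurable. A cubic fit over
the same window — the textbook choice for broadband noise — measurably
attenuates the 3–4 Hz harmonics that dominate gait kinematics at this sampling
rate, biasing the differentiated angular acceleration enough that forward
labels and the inverse residual no longer agree (squared residual ~1e−3).
Polyorder 5 keeps the same support, is exact for quintic polynomials, and is
transparent to the simulator's band-limited signal (worst squared residual
1.5e−7 over 120 cycles). The cost is weaker attenuation of high-frequency
noise, acceptable at the noise scales studied here.

## Synthetic gait simulator

The generator emulates the *structure* of open lower-limb biomechanics
datasets: per-joint cycles (hip/knee/ankle), six-axis IMU per segment, scalar
torque labels, 7:2:1 cycle-level train/val/test splits, 101-step
normalization, fixed seeds throughout (all randomness flows from one config
seed; rebuilds are file-identical).

Per joint, the segment orientation is a truncated Fourier series (order 4,
period = cycle duration, default 1.1 s at 100 Hz) with subject-specific random
coefficients and a 5 % per-cycle jitter; ω and ω̇ are its exact analytic
derivatives, so no numerical differentiation touches the ground truth. Two
excitation profiles: `sagittal_dominant` (≈0.45 rad sagittal, 0.05 rad
off-axis — gait-like) and `full_3d` (0.3–0.4 rad on all axes), the latter
giving a well-conditioned inertia-identification problem. Torque labels are
the exact forward Newton–Euler evaluation with the configured true inertia
(default diag(0.12, 0.10, 0.05) + 0.01 off-diagonals, shank-like and
mass-normalized) and gravity coefficients — so the labels are dynamically
consistent with the physics module by construction, which is what makes
inertia recovery and the γ-ablation assertable. The IMU model: gyroscope = ω
(+ optional bias and noise); accelerometer = gravity rotated into the moving
sensor frame plus tangential/centripetal terms at a 10 cm lever arm. Noise is
relative: σ multiplies each channel's clean standard deviation.

What the simulator does *not* emulate: soft-tissue artifact, sensor-to-segment
misalignment, multi-segment coupling, terrain/activity variation, or the
OpenSim inverse-dynamics label pipeline of real datasets. Passing tests
therefore demonstrate internal correctness and the mechanisms of the method
under controlled conditions, not performance on real recordings.

## Evaluation

R², RMSE, NRMSE (RMSE as % of the ground-truth range — the normalizer is a
convention choice), Pearson correlation; per-cycle physical-consistency error
(PCE: root-mean-square Newton–Euler residual over interior samples) and Peak
Error (absolute deviation at the torque extrema, located on the ground-truth
trajectory by default, prediction-anchored as an option). PCE defaults to the
model's own learned inertia/gravity parameters — the learned tensor is an
engineering surrogate, typically far from the generating inertia when labels
are sagittal-only, so a known-truth audit mode exists separately for synthetic
studies. Run-to-run stability is the coefficient of variation (population
std/mean). The noise sweep perturbs held-out inputs channel-wise at
σ ∈ {0, 0.1, 0.2, 0.5, 1.0} (relative scale, seeded) and recomputes all
metrics; the σ = 0 row is the clean evaluation exactly.

## Numerical core

All differentiable computation (networks, alignment losses, physics residual)
runs on a compact reverse-mode automatic-differentiation engine over NumPy
float64 arrays (`gaitdistill.autodiff`), with the layer library in
`gaitdistill.nn` (linear, im2col convolution, layer norm, multi-head
attention, GRU, AdamW, gradient clipping). Gradients are exact and verified
against central finite differences in the test suite. Inertia identification
(`fit_inertia`) minimizes the mean physics residual with L-BFGS using these
exact gradients. Eigen-quantities of I_eff are computed from the factor
(σ_min(L)²) rather than from the product L·Lᵀ, whose eigensolver round-off
can dip below zero for near-singular factors.

## Study conditions for tests and the acceptance script

Desk-scale sizes, chosen once: 2 subjects × 24 cycles (33–34 train / 9–10 val
/ 4–5 test cycles), hip joint, test-preset models; teacher 150 epochs and
students 60 epochs at learning rate 2e−3, batch 8. The physics-pathway
comparison trains M3 against its γ = 0 counterpart at three seeds on data with
σ = 0.1 input noise (a mid-range level of the noise sweep) and compares final
validation PCE under each run's own physics parameters; the PCE-convergence
trajectory is read from the clean-data M3 run. Forward–inverse consistency is
checked on native-rate cycles: the 101-step resampling adds linear-
interpolation distortion (~3e−3 squared residual) that belongs to resampling,
not to the operator pair.

## Known limitations

Single-segment rigid-body dynamics per joint; scalar sagittal supervision
leaves the off-sagittal structure of I_eff weakly identified under gait-like
excitation (by design — the tensor is a compensation variable); the gravity
form is a modelling choice, not identified from first principles; training is
CPU-bound NumPy and sized for small studies, not for large datasets.
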