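# Methods

This note records the models, numerical choices and known limitations
behind `dwssfp`.

## The DW-SSFP steady state

The sequence applies an RF pulse of flip angle α every TR, with a
diffusion gradient of amplitude G and duration δ in each repetition.  Its
spatial modulation frequency is q = (γ/2π)·G·δ (in cm⁻¹; γ/2π =
42.577 MHz/T), and the measured echo mixes coherence pathways whose
diffusion weighting grows with the number of TRs spent dephased, which is
what makes the effective diffusion weighting depend on α, T1 and T2.

`dwssfp.epg` solves the steady state exactly: the configuration-state
(partition) recursion over transverse harmonics u_k and longitudinal
harmonics Z_k is assembled as a sparse linear system — transverse
intervals k → k+1 attenuate by exp(−D·m²·[δ(k² + k + ⅓) + (TR−δ)(k+1)²])
with m = 2πq, longitudinal states by exp(−D·m²·TR·k²) — and solved
directly, truncated at harmonic order 60 (far beyond the attenuation
horizon of any setting used here).  At D = 0 this reproduces the classical
Freeman–Hill SSFP echo to machine precision, which pins down every sign
and convention.

`dwssfp.signals.buxton_signal` is the fast closed form used everywhere
else.  It closes the same recursion analytically: the three-term
continued fraction in the state ratio ρ_k = u_{−k}/u_k is peeled exactly
for the first `depth` levels and closed beyond with the constant-
coefficient geometric root ρ = K − sign(K)·√(K² − 1) — the construction
underlying the classic Buxton approximate solution, which corresponds to
depth 1.  Accuracy against the exact solver over α ∈ [10°, 120°],
D ∈ [5·10⁻⁵, 5·10⁻⁴] mm²/s at protocol settings: ≈4.9% worst-case at
depth 1, 0.11% at depth 2, <0.002% at depth 3 (the default).  At D = 0
every depth is exact.  The signal is returned as a magnitude (fraction of
S0), matching magnitude MR data; gradient placement within the TR does not
affect the echo amplitude (only attenuation-factor loop products enter).

Model extensions: the tensor form evaluates the scalar model at the
projected diffusivity ĝᵀDĝ; ball & sticks mixes an isotropic compartment
at diffusivity d with sticks at d·(ĝ·v̂_j)², weighted (1 − Σf_j) and f_j;
the noise floor enters as S = √(S_SSFP² + S_nf²).

Units: interfaces take ms, cm⁻¹, mT/m and mm²/s; everything is converted
once to an internal s / mm / mm²/s system.  The "non-DW" volumes carry a
small spoiler gradient (q = 20 cm⁻¹); they are *simulated* at their true q
but *fitted* as q = 0 by default (`spoiler_as_q0`), since their diffusion
weighting is negligible; exact-q fitting is a switch.

## Gamma-distributed diffusivities and the effective b-value

Restriction makes a voxel's diffusion non-Gaussian.  The parsimonious
model used here is a gamma PDF of diffusivities ρ(D; Dm, Ds) with mean Dm
and standard deviation Ds (shape Dm²/Ds², scale Ds²/Dm), integrated
against the steady-state signal.  The scalar integral is evaluated by
adaptive quadrature in CDF space (∫₀¹ S(Q(u)) du), which is robust for
arbitrarily narrow distributions; the voxelwise batch path uses fixed
48-node Gauss–Legendre quadrature in the same variable (≈10⁻⁵ relative
agreement), grouping inverse-CDF evaluations over unique shape values so
homogeneous regions cost almost nothing.  Ds < 10⁻⁷·Dm collapses to the
single-diffusivity branch to avoid a 0/0 shape parameter.

Under the same PDF the diffusion-weighted spin-echo signal is analytic,
S = S0·(Dm/(Dm + b·Ds²))^(Dm²/Ds²), and the ADC that a spin-echo
measurement at b-value b_eff would report is

    ADC(b_eff) = (Dm²/Ds²) · ln(1 + b_eff·Ds²/Dm) / b_eff,

implemented with log1p and returning Dm in the limits b_eff → 0 or
Ds → 0.  It is strictly decreasing in b_eff, so its inverse
(`solve_beff`) is a bracketing Brent search on [0, 10⁶] s/mm² (expanded if
needed); observed diffusivities outside (0, Dm] have no solution and raise
a range error that map-level wrappers convert to a per-voxel flag.  When
Ds ≫ Dm (shape < 1) the same formulas apply — the PDF is then monotone
decreasing with a heavy tail and the ADC drops steeply with b_eff; no
physical cut-off is imposed.

## Flip-pair optimisation

Contrast at a nominal angle α is S(q=0) − S(q_diff) evaluated at the
actual angle B1·α across a B1 grid.  For every pair on a 1° grid
(1–180°), the two curves are combined pointwise and μ/σ of the combined
curve over B1 ∈ [0.30, 1.00] (0.005 steps, uniform weights, population σ)
is maximised; ties break toward smaller angles.  The default combination
is the pointwise **mean** — the contrast of the averaged pair of
acquisitions — selected because among the candidate rules (mean, pointwise
max, root-sum-of-squares) it is the one whose optimum reproduces the
published pair's neighbourhood; max yields (33°, 60°) and RSS (27°, 75°)
under the same model.  With the exact steady-state model and the stated
tissue parameters the mean-rule optimum is (24°, 91°); the μ/σ ridge runs
from (23°, 88°) to (25°, 95°) and its peak is sensitive at the
few-degree level to the signal approximation and tissue parameters
(e.g. T2 = 35 ms or T1 = 450 ms move it to (24°, 94°) / (25°, 95°)).

## Voxelwise fitting

**Tensor.**  Eigenvalue ordering L1 > L2 > L3 > 0 is built into the
parameterisation (L1 = eᵃ, L2 = L1·σ(b), L3 = L2·σ(c) with logistic σ),
eigenvectors are a rotation-vector; dual mode shares one rotation across
both flips' predictions (11 parameters: 2 × (ln S0 + 3 eigenvalues) + one
rotation), so the shared-eigenvector constraint holds by construction,
not by penalty.  T1, T2, B1 and S_nf are fixed per voxel.
Initialisation inverts each DW volume's attenuation on a log-spaced D
grid (using the high-flip data, which keeps SNR at low B1) followed by a
linear six-component tensor fit; the nonlinear refinement is
Levenberg–Marquardt on the noise-floored forward model.  Voxels whose
mean signal is below 2 × S_nf are excluded (flagged, not raised), and
eigenvalues outside the box [10⁻⁶, 3·10⁻³] mm²/s are flagged — together
these play the role of the low-signal constraint needed at the sample
rind.  Optimiser failures flag the voxel rather than aborting a map.

**Eigenvalue-gamma fit.**  For each eigenvector the pair of per-flip
eigenvalues is explained by (Dm_i, Ds_i) through the three-term objective
(data terms at both flips plus the prior λ‖Dm_i − L_exp,high‖², λ = 1
default).  L_sim is the single diffusivity whose steady-state attenuation
matches the gamma-averaged attenuation at the voxel's actual flip angle;
because the q = 0 signal carries no diffusion weighting, matching
attenuation ratios and matching raw q-weighted signals at a shared S0 are
the same criterion, so no separate mode is needed.  The solver is a
vectorised 2-parameter Levenberg–Marquardt in (ln Dm, ln Ds) across all
voxels and eigenvectors simultaneously (closed-form 2×2 normal
equations, forward-difference Jacobians, per-element damping), with
L_sim computed by vectorised bisection of the monotone scalar model onto
the batch gamma signal.  Initialisation: Dm = L_exp,high (consistent with
the prior), Ds = √(|ΔL|·Dm).

The λ = 1 prior deliberately anchors Dm to the high-flip eigenvalue; since
L_exp,high < Dm in restricted tissue, recovery of Dm carries a small
systematic underestimate that grows as both actual flip angles collapse
at very low B1 (≈2.6% at B1 = 0.95, ≈4.5% at 0.65, ≈9.5% at 0.35 in the
noiseless forward chain).  This mirrors the method's intrinsic bias, not
an implementation artefact; it is the reason analyses restrict to the
interior white-matter-like region (below).

**Mapping to b_eff.**  Each (Dm_i, Ds_i) is converted to
L_i = ADC(b_eff; Dm_i, Ds_i) at a common target (default 4000 s/mm², the
value at which the high-flip acquisition's low-B1 regions need no
extrapolation).  Ordering violations after mapping are flagged in a QC
volume, never silently reordered, to keep eigenvalue–eigenvector pairing
intact.

**Ball & sticks.**  Shared stick orientations (spherical angles) and
stick-breaking fractions, with one diffusivity per flip-angle dataset;
three seeded Levenberg–Marquardt starts guard against local minima and
sticks are sorted by fraction to resolve label switching.

**Orientation uncertainty.**  A random-walk Metropolis chain around the
point fit under the Gaussian likelihood of the same forward model (noise
variance from the point fit's residuals), 2·n_samples iterations with the
first half as burn-in, step scale adapted toward 0.3 acceptance during
burn-in, fixed seeds giving bit-identical chains.  The summary is the
dyadic dispersion 1 − λ_max(mean v vᵀ) ∈ [0, 1]: antipodally invariant, 0
for a point mass, 2/3 for uniform orientations.  With noiseless data the
chain collapses onto the point estimate (the acceptance-rate warning flag
is expected there).

## The synthetic phantom

The generator emulates a fixed whole-brain sample at 7T: an ellipsoidal
mask (default 32³ voxels, 0.85 mm), transmit field falling as a cosine of
normalised radius from 1.0 at the centroid to 0.3 at the mask boundary,
uniform T1 = 500 ms / T2 = 30 ms, and per-flip acquisitions of 120
diffusion directions (q = 300 cm⁻¹, electrostatic-repulsion scheme with
antipodal symmetry) plus six spoiled non-DW volumes (q = 20 cm⁻¹) at
nominal 24° and 94°.  Ground truth is exact (region parameters are
written into the truth maps without sampling): default eigenvalue means
(1.7, 0.8, 0.5)·10⁻⁴ mm²/s (mean diffusivity 10⁻⁴, FA ≈ 0.56) with
Ds_i = 0.5·Dm_i (gamma shape 4) — restriction strong enough that the two
flips see clearly distinct apparent eigenvalues, matching the magnitudes
used throughout the signal-model examples.  Signals along a direction ĝ
use the projected distribution (Dm(ĝ) = Σ(ĝ·V_i)²·Dm_i and likewise for
Ds); noise is stationary Rician from two-channel Gaussian noise, and the
noise floor handed to fitting is the analytic background mean σ√(π/2).
The "white-matter-like" evaluation region is the interior 80% of the mask
radius: white matter occupies the interior of a real sample, and the
outermost shell — where B1 ≈ 0.3 makes the low-flip data unreliable —
plays the role of cortex/rind that the low-signal constraint excludes in
practice.  SNR 20 means σ = (mean WM non-DW signal at the high flip)/20.

What passing phantom tests do *not* show about real data: the phantom has
no anatomy, banding, eddy currents, slice profiles, coregistration error
or spatially varying T1/T2, and its diffusion truly follows the gamma
model, so recovery accuracy here bounds only the estimation chain, not
model mismatch in tissue.

The direction-subset selection for time-matched comparisons (60 of 120)
is greedy removal of the most crowded vector under the antipodal Coulomb
energy — a documented stand-in for "maximally even coverage", not a claim
of equivalence to any particular published scheme.

## Numerical defaults

| quantity | default | note |
| --- | --- | --- |
| closure depth | 3 | <0.002% vs exact steady state |
| scalar gamma quadrature | adaptive, rel err ≤ 1e-8 | CDF-space |
| batch gamma quadrature | 48-node Gauss–Legendre | ~1e-5 relative |
| λ (eigenvalue-gamma prior) | 1 | matching the published configuration |
| b_eff target | 4000 s/mm² | configurable |
| diffusivity box | [1e-6, 3e-3] mm²/s | flagged, not clipped |
| low-signal exclusion | mean signal < 2·S_nf | flagged |
| posterior sampler | RW-Metropolis, 0.3 target acceptance | 50% burn-in |
| global seed default | 42 | all randomness flows from one seed |

## Known limitations

- The Freed continued-fraction signal model is not implemented; the
  model interface (a scalar `D → signal` closed form) is designed so it
  can be slotted in.
- The λ = 1 prior's Dm underestimate at very low B1 (above) is inherited
  from the method; reporting it per-voxel would require propagating the
  eigenvalue covariance, which is out of scope.
- Tractography itself is out of scope: the artifact stops at the
  voxelwise orientation model (and its uncertainty) that a tractography
  engine would consume.
- Voxelwise fitting is plain Python/NumPy per voxel; whole-brain maps at
  full resolution are practical but not fast (no GPU path).
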