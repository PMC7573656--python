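# dwssfp — dual-flip-angle DW-SSFP quantification

Diffusion-weighted steady-state free precession (DW-SSFP) is the
SNR-efficient sequence of choice for diffusion imaging of fixed
post-mortem brains, whose short T2 and low diffusivity defeat conventional
spin-echo protocols.  At 7T, however, the transmit field B1 varies strongly
across a whole-brain sample, and in DW-SSFP the flip angle controls not
only the signal level but also the *effective diffusion weighting*: in
restricted (non-Gaussian) tissue, different parts of the brain are
effectively imaged at different b-values, so diffusivity maps inherit the
B1 pattern.

This package implements the dual-flip-angle remedy end to end:

1. **Protocol design** — choose a pair of nominal flip angles that jointly
   maximise diffusion contrast-to-noise over the B1 range found in the
   sample, by maximising the mean/standard-deviation ratio μ/σ of the
   pair's combined contrast curve.
2. **Signal modelling** — the Buxton-type closed form of the DW-SSFP echo
   `S_SSFP(α, T1, T2, TR, q, D)` (a continued-fraction truncation of the
   configuration-state steady state, validated to <2% against an exact
   extended-phase-graph solver shipped in `dwssfp.epg`), its diffusion-
   tensor and ball & sticks extensions, and the magnitude noise floor
   `S = sqrt(S_SSFP² + S_nf²)`.
3. **Non-Gaussian diffusion** — a gamma distribution of diffusivities
   ρ(D; Dm, Ds) integrated against the steady-state signal, the analytic
   DW-SE counterpart `S = S0·(Dm/(Dm + b·Ds²))^(Dm²/Ds²)`, and the ADC a
   spin-echo measurement at b-value `b_eff` would report,
   `ADC(b_eff) = (Dm²/Ds²)·ln(1 + b_eff·Ds²/Dm)/b_eff`.
4. **Fitting** — voxelwise tensor fits to one flip or to both flips
   simultaneously (shared eigenvectors `V1,2,3`, per-flip eigenvalues
   `L1 > L2 > L3 > 0`, fixed voxelwise T1/T2/B1 and noise floor); a
   regularised per-eigenvector gamma fit of the eigenvalue pairs
   (`min ‖L_sim(α_low) − L_exp,low‖² + ‖L_sim(α_high) − L_exp,high‖² +
   λ‖Dm − L_exp,high‖²`, λ = 1); interpolation of all eigenvalues to one
   effective b-value (default 4000 s/mm²); dual-flip ball & sticks with
   shared stick orientations; and PDD angular uncertainty from
   Metropolis posterior orientation samples (dyadic dispersion in [0, 1]).
5. **Synthetic phantoms** — brain-like digital phantoms (radially decaying
   B1, gamma-distributed anisotropic diffusion, Rician noise) so every
   stage is testable without scanner data.

## Worked example

Interpolating a restricted white-matter voxel's flip-angle-dependent
eigenvalues to a single effective b-value:

```python
import numpy as np
from dwssfp import (
    GammaDiffusivity, SequenceParams, TissueParams,
    apparent_diffusivity_at_flip, adc_at_beff, fit_gamma_eigenvalues,
    map_eigenvalues_to_beff,
)

tissue = TissueParams(T1=500.0, T2=30.0)          # fixed post-mortem tissue, ms
seq = SequenceParams(TR=30.0, alpha_nominal=24.0, delta=13.56, G=52.0)
print(f"protocol q-value: {seq.q:.1f} cm^-1")

# ground truth: gamma-distributed diffusivity along each eigenvector
Dm_true = np.array([1.7e-4, 0.8e-4, 0.5e-4])       # mm^2/s
Ds_true = 0.5 * Dm_true
B1 = 0.8                                           # relative transmit scale

L_low = [apparent_diffusivity_at_flip(GammaDiffusivity(dm, ds), 24.0 * B1, tissue, seq)
         for dm, ds in zip(Dm_true, Ds_true)]
L_high = [apparent_diffusivity_at_flip(GammaDiffusivity(dm, ds), 94.0 * B1, tissue, seq)
          for dm, ds in zip(Dm_true, Ds_true)]
print("apparent L at 24 deg x B1:", np.round(L_low, 9))
print("apparent L at 94 deg x B1:", np.round(L_high, 9))

eig = fit_gamma_eigenvalues(np.array([L_low]), np.array([L_high]),
                            np.array([24.0 * B1]), np.array([94.0 * B1]),
                            tissue, seq, seq, lambda_reg=1.0)
print("recovered Dm:", np.round(eig.Dm[0], 9))
L4000, flags = map_eigenvalues_to_beff(eig, beff_target=4000.0)
print("L at beff=4000 s/mm^2:", np.round(L4000[0], 9))
print("ground-truth ADC at 4000:",
      np.round([adc_at_beff(4000.0, GammaDiffusivity(dm, ds))
                for dm, ds in zip(Dm_true, Ds_true)], 9))
```

which prints

```
protocol q-value: 300.2 cm^-1
apparent L at 24 deg x B1: [1.46349e-04 7.22870e-05 4.63530e-05]
apparent L at 94 deg x B1: [1.62169e-04 7.81060e-05 4.92340e-05]
recovered Dm: [1.64303e-04 7.87460e-05 4.95150e-05]
L at beff=4000 s/mm^2: [1.55269e-04 7.63330e-05 4.85060e-05]
ground-truth ADC at 4000: [1.57004e-04 7.69610e-05 4.87900e-05]
```

The two flips see ~11% different apparent eigenvalues (the restriction
signature); after the gamma fit, eigenvalues interpolated to
b_eff = 4000 s/mm² agree with the ground-truth ADC at that b-value to ~1%,
independent of B1.

## Command line

```bash
dwssfp optimize-flips --t1 500 --t2 30 --adc 1e-4 --tr 30 --grad 52 --dur 14 \
    --b1-min 0.30 --b1-max 1.00            # CNR-optimal flip pair + CSV surface
dwssfp simulate --config phantom.yaml --out study/   # synthetic dual-flip study
dwssfp fit-tensor --config study/study.yaml --out tensor/
dwssfp fit-gamma  --config study/study.yaml --tensor-dir tensor/ --out gamma/
dwssfp map-beff   --gamma-dir gamma/ --out beff/
dwssfp fit-ballsticks --config study/study.yaml --out bs/
dwssfp dispersion --config study/study.yaml --out disp/
```

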