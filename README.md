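# grappa2d

2D-GRAPPA reconstruction of 3D MRI k-space data undersampled along **both**
phase-encoding directions, for people studying parallel-imaging kernel
design: it implements the classical lowest-dimensional (LK), extended (EX)
and square (SK) kernel families together with the boomerang kernel (BK),
plus everything needed to compare them — a Biot–Savart coil/phantom
simulator, retrospective 2D undersampling with a centred ACS block, an
exact memory/arithmetic cost model and complex-nRMSE evaluation over whole
volumes and undersampled edges.

## The method

A 3D acquisition accelerated by `R_y × R_z` leaves `R_y R_z − 1` missing
samples per acquired-lattice block. GRAPPA estimates each missing sample as
a learned linear combination of acquired neighbours over all `J` coils,

```
S_i(k + r) = Σ_j Σ_{(s,p,q) ∈ Ω} W_{i,r}(j,s,p,q) · S_j(k_x + sΔk_x, k_y + pR_yΔk_y, k_z + qR_zΔk_z)
```

with weights `W` fitted on the autocalibration block by least squares
(`S_tgt = S_src W`) and then slid across k-space. The kernel families
differ in the source set Ω: the square kernel is the **intersection** of
the per-target extended-kernel footprints (a 2×2 lattice square) and the
boomerang kernel is their **union** (the 3×3 lattice neighbourhood minus
one corner), reconstructing all block targets simultaneously. Each family
exists in a basis (`n_x = 1`) and readout-expanded (`n_x = 3`) form.

The reconstruction is exposed as a scikit-learn-style estimator —
calibration is `fit`, synthesis is `transform`:

```python
from grappa2d import (GrappaReconstructor, SamplingScheme, apply_mask,
                      make_mask, simulate_dataset)

kspace, sens, phantom = simulate_dataset(grid=64, n_channels=8)
scheme = SamplingScheme(R_y=2, R_z=2, acs_y=16, acs_z=16,
                        grid_shape=kspace.grid_shape)
undersampled = apply_mask(kspace, make_mask(scheme))

recon = GrappaReconstructor(algorithm="BK").fit(undersampled).transform(undersampled)
```

## Worked example

Comparing the four algorithms on the desk-scale simulation (64³ grid,
8 channels, R = 2×2, 16×16 ACS, reference lines excluded from the final
k-space):

```python
from grappa2d import SamplingScheme, evaluate_algorithms, simulate_dataset

kspace, _, _ = simulate_dataset(grid=64, n_channels=8)
scheme = SamplingScheme(2, 2, 16, 16, kspace.grid_shape)
report = evaluate_algorithms(kspace, [scheme])
for e in report.entries:
    print(f"{e['algorithm']}: nRMSE = {e['nrmse_full']:.5f}")
```

```
LK: nRMSE = 0.07213
EX: nRMSE = 0.06888
SK: nRMSE = 0.06945
BK: nRMSE = 0.04628
```

The boomerang kernel resolves aliasing best because each weight fit sees
the most acquired data; expanding it along the readout (`n_x=3`) lowers its
nRMSE further (0.02747 on the same data). The cost model quantifies what
that costs — at the reference operating point `J = 12`, `N_f = 12`,
`N_rec = 250,000` (`grappa2d complexity`):

```
algorithm     calib memory       calib arith      synth memory       synth arith
--------------------------------------------------------------------------------
LK                   3,888           187,776        24,001,152       567,000,000
EX                   7,344           646,272        48,002,304     1,143,000,000
SK                   1,872           256,896        12,000,576       855,000,000
BK                   3,600           951,552        24,001,152     1,719,000,000
```

BK needs the most arithmetic but only the second-smallest memory, since a
whole block of missing samples shares one gathered source matrix.

A CLI covers the same workflow from the shell: `grappa2d simulate`,
`undersample`, `reconstruct`, `evaluate`, `complexity` and
`kernels show`, driven by a validated YAML config with a single seed.

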