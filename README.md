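# isingtcp

Tumor control probability (TCP) modelling with voxel–voxel **bystander
interactions**, built on an exact correspondence between the logistic TCP
model and a two-state lattice (Ising-type) model.

## The problem

Biologically driven radiotherapy planning scores dose distributions by the
probability that *every* clonogenic tumor cell is sterilized. Standard TCP
models treat voxels as independent: the logistic model assigns voxel *i*

```
TCP_i = 1 / (1 + exp[-(4 γ₅₀ / D₅₀) (D_i − D₅₀)])
```

with `D₅₀` the 50%-control dose and `γ₅₀` the normalized slope at `D₅₀`.
Experimentally, however, irradiated regions can radio-sensitize their
neighborhood (the *bystander effect*), which breaks the independence
assumption. Writing each voxel's state as a binary variable `σ_i ∈ {0, 1}`
(1 = sterilized), the logistic model is *exactly* a non-interacting
two-state lattice model with external field `B_i = D_i − D₅₀` and tumor
temperature `k_B T = D₅₀ / 4γ₅₀` (in Gy). Bystander sensitization then
enters naturally as a short-range directed coupling

```
J_ij = J₀ · TCP_i · exp(−|r_i − r_j| / λ)
```

(strength `J₀` in Gy, diffusion length `λ` in cm; in practice the linearized
form with the non-interacting `TCP_i⁰(D_i)` as source factor), giving the
configuration energy

```
E({σ}) = Σ_i (D₅₀ − D_i) σ_i − Σ_{i≠j} J_ij σ_i σ_j        [Gy]
```

sampled from the Boltzmann distribution `P({σ}) ∝ exp(−E/k_B T)`. Small
systems (≤ 20 voxels) are solved by exact enumeration; realistic (~10³
voxel) grids by single-flip Metropolis Monte Carlo. The package is aimed at
radiotherapy-physics researchers who want to quantify *when* voxel
independence is a safe assumption and what interactions do to dose-response
curves, dose boosting and partial-coverage plans.

## Worked example

```python
import numpy as np
from isingtcp import (TumorControlModel, RegionParams, BystanderParams,
                      BoostPhantomSpec, boost_phantom)

params = RegionParams(d50=72.8, gamma50=5.0)          # intermediate/high risk
grid, mask = boost_phantom(BoostPhantomSpec(          # 57 Gy base, 25% at 97 Gy
    base_dose=57.0, boost_delta=40.0, boost_fraction=0.25))

model = TumorControlModel(grid, params, bystander=BystanderParams(j0=2.0, lam=0.30))
res = model.fit(n_sweeps=10_000, seed=1)
print(res.summary())
print("unboosted-region TCP:", res.tcp_map[~mask].mean().round(4))
```

prints

```
Tumor Control Model Results
==============================================
Voxels                      1000
Voxel edge (cm)             0.127
Dose range (Gy)             [57.00, 97.00]
D50 (Gy)                    72.8
gamma50                     5
Tumor temperature kT (Gy)   3.6400
Hot / cold voxels           250 / 750
Bystander J0 (Gy)           2
Diffusion length (cm)       0.3
Couplings (nnz)             985896
----------------------------------------------
Method                      mcmc
Sweeps (burn-in)            10000 (2000)
Retained samples            8000
Acceptance rate             0.1639
Seed                        1
TCP_avg                     0.852527 +/- 0.000059
Voxel TCP range             [0.064625, 1.000000]
==============================================
unboosted-region TCP: 0.8034
```

Reading: a quarter of the structure is boosted to 97 Gy (those voxels are
"hot", TCP ≈ 1 on their own), the rest sits at 57 Gy where the independent
logistic TCP is only 0.013. With `λ = 0.30 cm` bystander couplings, the
average TCP of the *unboosted* region rises from 0.013 to ≈ 0.80 — the
"biological penumbra" of indirect cell kill spreading from the boosted slab.
Setting `lam=0` (or `bystander=None`) recovers the independent model, where
the whole-structure average saturates at `0.25 + 0.75·TCP(57 Gy) ≈ 0.26`.

Experiment drivers reproduce full sweeps
(`dose_response_sweep`, `phase_diagram`, `boost_dose_sweep`,
`boost_volume_sweep`), and a CLI wraps them:

```bash
isingtcp dose-response --lam 0 --lam 0.30 --out sweep.tsv
isingtcp check-bystander --dose 97 --d50 72.8 --gamma50 5 --j0 2 --lam 0.15 --a 0.127
```

The second command evaluates the neglectability criterion
`|D − D₅₀| ≫ 8π J₀ (λ/a)³` for a near-homogeneous dose.

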