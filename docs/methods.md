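# Methods

## Model

Each tumor voxel carries a binary sterilization variable `σ_i ∈ {0, 1}`
(clonogen hypothesis: a voxel is controlled iff all of its clonogens are
inactivated). The joint distribution over configurations is Boltzmann,

```
P({σ}) = Z⁻¹ exp(−β E({σ})),
E({σ}) = Σ_i (D₅₀ − D_i) σ_i − Σ_{i≠j} J_ij σ_i σ_j,
```

with energies in Gy and inverse temperature `β = 4γ₅₀/D₅₀` (per Gy). The
non-interacting marginal of this distribution is exactly the logistic voxel
TCP, which fixes the parameter mapping: the external field is `D_i − D₅₀`
and the tumor temperature `k_B T = D₅₀/4γ₅₀`. Boltzmann's constant never
appears on its own — only the product `k_B T` is defined, so temperatures
are carried in Gy and `β` multiplies energies exclusively inside Boltzmann
weights.

Key consequences used throughout:

- per-voxel TCP = one-point correlation `⟨σ_i⟩`;
- whole-structure (N-voxel) TCP = `⟨Π σ_i⟩^(1/N)`, which factorizes into the
  geometric mean of voxel TCPs only when couplings vanish;
- the order parameter is the average TCP per voxel, `TCP_avg = mean ⟨σ_i⟩`,
  separating an uncontrolled phase (≈0), a disordered phase of partial
  sterilization, and a controlled phase (≈1);
- a steep dose response (large `γ₅₀`) is a *cold* tumor: the minimum-energy
  configuration (sterilized wherever `D_i > D₅₀`) dominates.

### Bystander coupling

Radio-sensitization of voxel *j* by voxel *i* is modeled as
`J_ij = J₀ · TCP_i · exp(−d_ij/λ)`: damaged cells release a diffusible
mediator in proportion to their kill probability, decaying over a single
characteristic length λ. Because `TCP_i` itself depends on the couplings,
the kernel is non-linear; the **linearized** kernel substitutes the
non-interacting logistic `TCP⁰(D_i)` and is the default everywhere (the
non-linear fixed point is available via `build_interaction_selfconsistent`,
which iterates kernel → marginals → kernel and *flags* rather than raises on
non-convergence, since the non-linear form is numerically less stable).

The interaction double sum runs over **ordered pairs** `i ≠ j` with no ½
factor: the coupling is directional (source × target), and `J_ij ≠ J_ji`
whenever the two doses differ. An `unordered` pair mode (entries halved) is
provided for sensitivity analysis. Self-terms are excluded — on {0,1}
variables `σ_i² = σ_i`, so a diagonal entry would silently shift the
external field.

Matrices are sparse, truncated at a cutoff radius (default `5λ`). Note the
truncated mass is *not* tiny: the continuum kernel mass beyond radius `c` is
`Q(3, c/λ)` (regularized upper incomplete gamma), ≈ 12.5% at `5λ` because
the `r²` volume factor dominates the exponential; it drops below 1% only
beyond `≈ 9λ`. The default keeps the matrix at `O(N·(λ/a)³)` entries; on the
reference 10×10×10 phantom the cutoff barely truncates anyway (the grid is
only ~4λ across at λ = 0.30 cm). `kernel_tail_fraction` quantifies the
truncation for any choice. Boundaries are open (no periodicity): voxels at
the surface of the structure genuinely receive fewer couplings, which is the
mechanism behind the finite-size lag of complete sterilization.

For near-homogeneous doses, couplings are negligible when
`|D − D₅₀| ≫ 8π J₀ (λ/a)³`; the "≫" is operationalized as a configurable
factor (default 10), and `(λ/a)³` is the number of voxels sensitized around
a single sterilized voxel.

## Solvers

**Exact enumeration** (≤ 20 voxels, ~10⁶ states): all `2^N` bit-encoded
configurations are evaluated in vectorized chunks of 2¹⁴ states; weights are
accumulated with log-sum-exp and the post-hoc normalization is asserted to
1e−12. This replaces a Gray-code incremental scan — same complexity, simpler
and faster in vectorized form. Enumeration supplies the partition function,
free energy `F = −logZ/β`, one- and two-point correlations and the N-voxel
TCP, and serves as the oracle for the sampler.

**Metropolis MCMC** (arbitrary N): single-voxel flips proposed in a fresh
random order each sweep; flipping voxel m changes the energy by
`Δσ·[(D₅₀ − D_m) − h_m]` with the local field `h = (J + Jᵀ)σ` cached and
updated incrementally on acceptance (O(1) per proposal, O(degree) per
acceptance; the kernel is numba-compiled). Defaults: burn-in = 20% of
sweeps, thinning 1, 20 batches. Initialization draws each voxel
independently from its non-interacting logistic marginal — starting near the
target distribution equilibrates fastest; `all-zero`/`all-one` starts are
available for hysteresis probes near the sharp interacting transition.
Standard errors use batch means (valid under autocorrelation); per-voxel
comparisons in tests floor the batch-means estimate at the iid binomial
value `√(p(1−p)/n)`, a lower bound on the true Monte-Carlo error for
positively autocorrelated chains. One seedable generator drives everything;
the seed is recorded in every result, and identical inputs + seed give
bitwise-identical output. The correlated N-voxel TCP is deliberately *not*
estimated by sampling: the all-sterilized indicator has vanishing
signal-to-noise unless the tumor is essentially controlled.

## Synthetic phantoms (study conditions)

No clinical dose matrix ships with the package; phantoms reproduce the
reference conditions of the modeled scenario:

- 10×10×10 cubic lattice (1000 voxels ≈ the 1004-voxel clinical structure),
  voxel edge 0.1270 cm;
- biological parameters `D₅₀ = 72.8 Gy`, `γ₅₀ = 5` (intermediate/high-risk
  prostate region; `k_B T = 3.64 Gy`);
- homogeneous experiments parameterized by `ΔD` with absolute dose
  `87 Gy + ΔD` (87 Gy is where the non-interacting `TCP_avg` first
  saturates at ≈1);
- boost experiments: 57 Gy base, boost doses 0–45 Gy (57→102 Gy in the
  boosted region), boost fractions 0–1;
- bystander strength fixed at `J₀ = 2 Gy`, diffusion lengths
  λ ∈ {0, 0.15, 0.30} cm (≈ 0, 1.2 and 2.4 voxel spacings).

The boost geometry is a contiguous **slab** filled plane-by-plane from one
lattice face, so the boosted/unboosted interface is a single plane; a
`centered-box` alternative exists for sensitivity checks. λ = 0 rows of
every sweep are computed in closed form from the logistic model (stderr 0)
and double as an engine cross-check against explicit non-interacting MCMC.

What the phantoms do **not** emulate: the irregular shape and
surface-to-volume ratio of a clinical target, dose heterogeneity inside
regions, and fractionation. Quantities tied to geometry — e.g. the exact
boost fraction at which partial coverage sterilizes the whole structure, or
the precise interacting transition dose — are therefore reproduced as
qualitative signatures (left shift, steepening, penumbra, coverage sparing
below 80%) rather than point values. The homogeneous-phantom transition for
λ = 0.30 cm sits near ΔD ≈ −22 Gy, and the compact cube geometry makes the
biological penumbra comparatively strong: full-structure control is reached
at ~45% slab coverage.

## Numerical and design choices

- `hot`/`cold` voxel classification threshold: `T_i/T ≥ 3` (voxel TCP
  ≈ 0.95); the underlying notion is only "local temperature much larger
  than tumor temperature", so the ratio is configurable.
- Geometric means and enumeration run in log space; a TCP of exactly 0
  short-circuits products to 0.
- Phase classification tolerance ε = 0.02: `TCP_avg ≤ ε` uncontrolled,
  `≥ 1 − ε` controlled, else disordered.
- Enumeration refuses `N > 20` with an explicit message instead of
  attempting `2^N` states.
- Sweep tables are long-format TSV (control parameter, λ, J₀, region,
  tcp_avg, stderr, seed), sorted by control parameter; MCMC rows always
  record seed and stderr, closed-form rows carry stderr 0 and seed −1.
- Test problem sizes: driver tests use 5³ phantoms and a few thousand
  sweeps; oracle-equivalence tests use 100 random ≤ 10-voxel instances at
  25 000 sweeps; the stationarity check uses 10⁵ retained samples on an
  8-voxel system. These sizes make the statistical assertions sharp while
  keeping the default suite fast.

## Known limitations

- The linearized kernel underestimates sensitization cascades: voxels
  sterilized *through* bystander effects do not themselves emit stronger
  couplings. The self-consistent solver exists but is only exercised on
  small systems.
- No mechanistic diffusion model for the mediator; `J₀` and λ are free
  parameters (λ ≈ 0.1 cm is the experimentally motivated scale).
- Single risk region in the interacting engines; multi-region combination
  is available only in the closed-form (non-interacting) layer.
- Metropolis single-flip dynamics mix slowly near the sharp interacting
  transition; results there carry visible seed-to-seed variability, and the
  chain-diagnostics helper (two chains, 5× pooled stderr) should be used
  before trusting a single run.
- No linear-quadratic/Poisson TCP, fractionation, α/β conversion, NTCP
  models or DICOM-RT import.
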