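# Methods

## Model and procedure

`chromofold` reconstructs a chromosome's 3D organization in three stages.

**Backbone (TAD level).** The global arrangement of TADs is found by
minimizing `C_g = C1 + λE·C2 + λF·C3` over one 3D point per TAD. `C1` is
a stochastic-neighbor objective: contact counts are normalized into a
single probability distribution over ordered locus pairs
(`p_ij = f_ij/Σ_{k≠l} f_kl`), the embedding induces a matching
distribution through the heavy-tailed proximity kernel
`q_ij ∝ (1+‖s_i−s_j‖)⁻¹`, and the KL divergence `Σ p log(p/q)` is
minimized. This makes no assumption about the functional form of the
contact–distance relation. `C3` is a direct least-squares fit to the FISH
mean distances in µm; because `q` is scale-sensitive only through its
fixed ~1 µm kernel length, `C3` (not `C1`) is what pins the metric scale
of the model. `C2` is a polymer prior (below).

A normalization subtlety: the objective is written as a sum of per-locus
KL divergences, but the printed definitions of `p` and `q` normalize over
all ordered pairs jointly, and the two readings are incompatible. The
global reading is implemented, since it matches the printed denominators.
All pair sums (C1, C3, RE averaging) run over ordered pairs — each
unordered pair counts twice — so reported cost values are reproducible
bit for bit; gradients are the exact derivatives of these double-counted
sums.

**Intra-TAD models.** Each TAD's internal structure is fit at bin
resolution (default 5000 bp) from its intra-TAD contact submatrix by
minimizing `C_t = C1 + λE·C2 + λR·C4`. FISH does not resolve loci inside
a TAD, but the chromosome-wide power law `d ≈ c·g^β` fitted to the FISH
matrix (OLS of log distance on log genomic separation, center-to-center)
gives a size prior: the TAD's genomic length `L` maps to a spatial span
`c·L^β`, converted to a target radius of gyration by the ideal-chain
relation `R̂g = c·L^β/√6`. `C4 = |R_g² − R̂g²|` pins the model to that
size with the subgradient `(2/N)·sign(R_g²−R̂g²)(y_i−ȳ)`, `sign(0)=0`.
The √6 conversion is this package's own estimator (the original
derivation it stands in for is not public); per-TAD overrides are
accepted. Bins with zero contact marginal are retained and positioned by
chain connectivity alone, so the first/last points every TAD contributes
to assembly always exist.

**Assembly.** TAD models are rigid bodies: each is translated so its
centroid (the "center" of a TAD, by this package's definition) coincides
with its backbone point, then oriented by sweeps in genomic order. For
each TAD the more-strained endpoint (larger junction-cost gradient) is
moved one gradient step toward its target, and that displacement is
converted to a rotation about the TAD center — axis perpendicular to the
endpoint's current and target radius vectors, angle capped at π/2 to
prevent overshoot oscillation. An update is accepted only if the global
junction cost does not increase (angle halved up to 12 times otherwise),
so the cost history is monotone non-increasing. With reflections enabled,
each TAD's mirror image through the center-passing plane perpendicular to
the current rotation axis is also evaluated once per sweep and kept if
strictly better; when the rotation axis is undefined (endpoint exactly
antipodal to its target), the plane normal falls back to the
endpoint-to-center direction, which resolves that stuck case. Junction
targets are `d = f^α` with `α = −0.25` from the contact count between the
last bin of TAD i and the first bin of TAD i+1, falling back to `c·g^β`
when the count is zero; the genomic distance `g` is center-to-center of
those two bins, which stays positive for abutting TADs. An optional
`rescale_linkers` switch rescales the `f^α` distances so their median
matches the median power-law estimate, for contact counts on an arbitrary
scale (off by default; the synthetic counts are on the natural scale).

**Polymer prior (C2).** Harmonic stretching of consecutive beads plus a
soft-sphere repulsion between non-adjacent beads:
`Σ k_s(‖Δ‖−b)² + Σ_{|i−j|>1} k_r·max(0, r_c−‖Δ‖)²`. This is the minimal
standard prior giving connectivity and non-self-intersection; it is
deliberately isolated behind one interface (`polymer.conf_energy_and_grad`)
so a richer form (bending, torsion) can be swapped in. Defaults: `b` =
median FISH-implied neighbor distance (backbone) or `R̂g·√(6/N)`
(intra-TAD), `r_c = b/2`, `k_s = k_r = 1` (dimensionless; the overall
weight is λE's job).

## Parameters

| parameter | default | units | role |
|---|---|---|---|
| λE (backbone) | 5e12 | – | weight of C2 in C_g |
| λF | 1e-8 | – | weight of C3 in C_g |
| λE (intra-TAD) | 5e11 | – | weight of C2 in C_t |
| λR | 1e-7 | – | weight of C4 in C_t |
| α | −0.25 | – | contact→distance exponent for linkers |
| learning rate | 0.05 × data scale | µm | gradient-descent step |
| max_iter | 20000 | – | iteration cap |
| rel_tol | 1e-7 | – | relative cost-change stop |
| init_scale | mean(F)/2 or R̂g | µm | s.d. of the Gaussian start |

The λ defaults are the published grid-search selections for raw
(count-scale) Hi-C matrices and are kept as the configuration defaults.
Their magnitudes are tied to that data scale: C1 is scale-free, but C2
and C3/C4 carry the units of the coordinates, so λ must be re-selected
when the inputs change scale or normalization. That selection is part of
the method — the `tune` subcommand / `paramsearch.grid_search` maximize
`S = (1 − C1)·v / |v − v′|` with `C1` clamped to [0, 1] (the
globally-normalized KL can exceed 1) and the denominator regularized as
`max(|v−v′|, 1e-3·v)` so the score stays finite at `v′ = v`. `v` is a
prior volume (user input, or the fallback `(4/3)π(1.29·R_g)³` with `R_g`
from the FISH power law applied to the chromosome length); `v′` is the
convex-hull volume of the model. Joint selection across datasets
averages `S`; ties break toward smaller λ, deterministically.

For the µm-scale synthetic benchmarks the frozen profile is
`(λE, λF) = (1e-3, 1.0)` for backbones — selected by the package's own
grid search under the default generator conditions — and
`(λE, λR) = (1e-3, 100)` for TADs. λR follows a constraint-dominance
rule rather than the score: the proximity kernel's fixed ~1 µm length
scale makes `C1` push sub-µm models to inflate (its gradient is O(1) at
TAD scale), so λR·‖∇C4‖ must exceed ‖∇C1‖ with a margin; 100 is the
smallest decade that does. Under the steep `d⁻⁴` synthetic contact law
the clamped score saturates (C1 > 1 even at the truth), so it cannot
arbitrate there; the grid-search benchmark therefore uses a gentler
`d⁻²` law, where `C1(truth) ≈ 0.56` and the score is informative — a
legitimate condition, since the embedding assumes no particular law.

## Optimization

Plain gradient descent with backtracking halving: each iteration starts
from the configured learning rate and halves the step (≤ 30 times) until
the cost does not increase, giving a monotone trajectory by construction;
termination on relative cost change < rel_tol or the iteration cap.
Coordinates initialize from a seeded isotropic Gaussian at the data's
length scale. All randomness flows from explicit seeds
(`numpy.random.default_rng`); per-TAD problems seed with
(global seed + 1 + TAD ordinal), so parallel and sequential execution are
result-identical. Degenerate inputs are handled with explicit
conventions: coincident points contribute zero-direction gradients;
`0·log 0 = 0` in the KL sum; the C4 kink has `sign(0) = 0`; an all-zero
contact map is rejected; coplanar point sets get hull volume 0 with a
warning; compartment sign ties go to +1 and the eigenvector sign is fixed
so the first nonzero score is positive.

## Synthetic data

The generator emulates the study's two observables on one ground truth.
TAD centers follow a confined self-avoiding random walk (spacing 0.4 µm,
territory radius 1.5 µm, self-avoidance 0.25 µm — multiplexed-FISH scales
for mid-size human chromosomes); each TAD's loci are threaded as a
Brownian bridge between junction anchors midway to its neighbors, so the
chain is continuous and genomically adjacent loci of consecutive TADs sit
one bead step (0.05 µm) apart, matching the short linkers the assembly
stage presumes. Contacts follow `f = scale·d⁻⁴` (the exact inverse of the
α = −0.25 rule), optionally Poisson-sampled; FISH matrices are the true
TAD-center distances with optional truncated Gaussian noise and missing
entries (masked, never imputed, excluded from C3 and RE). Polarized mode
splits the TADs into two contiguous blocks biased into opposite
half-spaces with planted ±1 labels; the single block-boundary linker is
drawn fresh in the new half-space, since a polarized boundary genuinely
spans the territory.

What passing on this generator does and does not show: it validates the
estimators and optimizers under the method's own generative assumptions —
exact power-law contacts, unbiased FISH means, one conformation per
population. Real data violate all three (normalization artifacts,
cell-to-cell variability, ensemble averaging of incompatible geometries),
so synthetic recovery rates are upper bounds, not forecasts. Benchmark
problem sizes — 20 TADs × 25 beads, 5-kb bins, 10–20 replicate seeds —
were chosen so the whole suite exercises every stage at the scale of the
imaged chromosomes' TAD counts.

## Known limitations

- **Assembly identifiability.** The junction cost supplies n−1 scalars
  against the 3n orientation DOF it optimizes. End TADs (one junction)
  keep a two-parameter orientation freedom; interior TADs keep a
  one-parameter spin family plus a chirality branch the cost cannot see
  (the center/endpoint triangle is planar, so its mirror image is
  rotation-reachable). Residual full-model RMSD after assembly therefore
  scales with the intra-TAD radius of gyration rather than converging to
  zero — ~0.2·R_g of the chromosome under the default generator, where
  TAD-to-chromosome R_g ratios match imaged chromosomes. Assembly
  reliably restores junction geometry (and hence adjacent-TAD distances),
  not per-TAD orientation; metrics that average over loci (RE,
  compartments, density) are insensitive to this freedom.
- The ensemble extension (mixtures of conformations) is out of scope: the
  rigid assembly step has no counterpart for mixture components.
- The score `S` saturates when `C1 ≥ 1`; on data in that regime λ
  selection needs either the volume term alone or an external prior.
- `.hic`/`.cool` binary inputs are not parsed; matrices are exchanged as
  text (dense or triplet).
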