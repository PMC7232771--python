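# Methods

This note records the models implemented in `seaconn`, the assumptions they
make, the defaults and why, and what the synthetic world does and does not
establish.

## Seascape and velocity fields

The domain is an abstract planar grid (no spherical correction): `ny × nx`
square cells of side `cell_size_km`, row-major, with cell centers at
`(i + 0.5, j + 0.5) · cell_size`. Habitat is hydrographic: sea cells with
mean depth strictly below the habitat limit (default 30 m), emulating the
shallow photic band where macrophyte-associated invertebrates live. A
seascape with no habitat cell is an error, not an empty result.

Velocity fields are sums of analytic components evaluated on cell centers:

- **Solid-body gyre** — evaluated directly (`u = -ω(y−c_y)`,
  `v = ω(x−c_x)`); exactly linear, so bilinear interpolation is exact and
  the component doubles as an integrator test case.
- **Gaussian gyre, coastal current, eddy noise** — defined through a
  streamfunction ψ and differentiated by central differences
  (`u = −∂ψ/∂y`, `v = ∂ψ/∂x`). Because the divergence oracle uses the same
  central differences, these components are divergence-free to machine
  precision on interior cells; this is a discrete identity, not an
  approximation. The coastal current uses
  `ψ = s·w·exp(−d/w)` with `d` the distance to the nearest land cell, which
  makes flow follow the coastline (the dominant transport mode for coastal
  species); noise smooths a white streamfunction with a Gaussian spectral
  kernel. Velocities are zeroed on land cells, which locally breaks the
  divergence identity in the one-cell fringe — tests therefore check
  interior cells only.

## Particle tracking

Fixed-step RK4 (default `dt = 3600 s`) with bilinear velocity
interpolation; particles are passive (no diffusion term, behavior, or
mortality). The dispersive-phase duration defaults to 5 days, and releases
occur monthly April–September (six releases), `particles_per_cell = 50` by
default (`20` in the demo config) — a desk-scale stand-in for the tens of
millions of particles an operational run would use. The vertical dimension
is collapsed to the single surface layer.

Boundary rules, chosen as the simplest particle-conserving set:

- a step whose endpoint lands on a land cell is cancelled and the particle
  holds position for that step (stick-in-place; unlike reflection it
  introduces no directional bias);
- a step crossing the open domain boundary marks the particle LOST at its
  last in-domain position;
- settlement: the habitat cell containing the end position; otherwise the
  nearest habitat cell within a one-cell radius (ties to the smaller cell
  id); otherwise LOST.

Settled + lost = released holds exactly, per source cell. Element `(i, j)`
of the connectivity matrix is the settled fraction `i → j`; row sums are
≤ 1 with the deficit equal to the lost fraction.

## Connectivity algebra

Multigeneration stepping-stone connectivity is the sum of matrix powers
`S_G = Σ_{g=1..G} M^g` computed by iterated multiplication (default
`G = 64`, enough for basin-scale chains at tens of km per generation). The
sum counts every route and can exceed 1; both the raw sum and the
elementwise cap at 1 are produced, and the capped form is the downstream
default because the quantity is read as a dispersal probability. Whether
to renormalize instead is genuinely open; the flag is recorded in every
output so either convention can be recovered.

Symmetrization (needed because F_ST is symmetric) combines `(i, j)` with
`(j, i)` by min, max or mean — mean is the default used in the headline
comparison — and the log transform is `log10(x + 1e−50)`, mapping zero
connectivity to −50. Site-level matrices average the cell matrix over the
habitat-cell patches representing each site; in the demo each site is the
patch of habitat cells within 35 km of its anchor cell, because a
one-generation matrix between isolated single cells ~100 km apart is
unresolvably sparse at desk-scale particle counts.

## Barrier clustering

A deterministic greedy agglomeration stands in for the eigenvector-based
minimization used in the literature: starting from singletons, repeatedly
merge the cluster pair with the largest mean crossing probability (mean of
the symmetrized matrix over the cross block) while that maximum exceeds θ;
ties break on the smallest cluster ids. On return every inter-cluster mean
is ≤ θ, so cluster boundaries are barriers by construction.

The implied objective is the *finest* partition whose inter-cluster
crossings are all ≤ θ ("minimize clusters" is degenerate — one big cluster
has no inter-cluster pairs and is always feasible). The greedy result is
validated against an exhaustive search over all set partitions on ≤ 8
nodes. Because the merge sequence does not depend on θ (only the stopping
point does), the cluster count is exactly monotone non-decreasing in θ.

## Genotype simulation

Wright–Fisher demes of constant size `N`, biallelic loci, no mutation,
selection or linkage. Per generation, deme `j`'s gamete pool is
`(1 − m) p_j + m Σ_i W_ij p_i`, followed by binomial drift
(`p' = Bin(2N, ·)/2N`). `W` is the column-normalized incoming
connectivity with the diagonal removed: the dispersal matrix is a
source→destination probability whose rows lose mass to open boundaries, so
it must be converted to an immigration mixture, and self-recruitment is
excluded because local retention is already the `1 − m` share. A deme with
no incoming connectivity is treated as isolated, with a warning.

All demes start from shared ancestral frequencies drawn uniformly in
[0.1, 0.9] (avoiding immediate fixation; configurable). Individuals are
sampled as `Bin(2, p)` dosages (within-deme random mating); missing data is
optional uniform masking (0.2 mimics a RAD-style 80% call-rate floor).
One RNG stream per simulation, seeded from the config; every stage seed is
derived from the global run seed by hashing and logged in the manifest.

The serial-founder option colonizes demes in a stated order, each through a
bottleneck of `founder_size` diploids drawn from its predecessor, with
inactive demes excluded from donor pools. Two opposing clocks act on
diversity: the cumulative founder loss (~`1/(2N_f)` per step) and the
*residence-time* drift loss (~`t/(2N)`), which is larger for
earlier-colonized demes and therefore runs against the front signature.
The canonical founder regime (N = 500, founder size 8, colonization
interval 4 generations, m ≤ 0.02) keeps residence drift an order of
magnitude below the bottleneck loss, giving a robustly monotone He decline;
at small N (≈100) the residence effect dominates and the gradient inverts —
that regime is a stated limitation, not a bug.

None of the demographic values are estimates; they are free parameters of
the synthetic world.

## Statistics

- **F_ST** — Weir–Cockerham (1984) variance components per locus,
  multilocus ratio of averages `Σa / Σ(a+b+c)` over loci genotyped in both
  samples (pairwise-complete; per-pair locus counts reported). Estimates
  are not clamped — small negatives are a property of the estimator —
  except inside metric MDS, where distances must be nonnegative.
- **He / F_IS** — unbiased expected heterozygosity
  `(2n/(2n−1))(1 − p² − q²)` averaged over loci with data (monomorphic loci
  contribute 0); `F_IS = 1 − Ho/He` averaged over polymorphic loci. With
  unbiased He, exact Hardy–Weinberg proportions leave a residual F_IS of
  `1/(2n)`, so "≈ 0 at HWE" is true only to that order.
- **Genic differentiation** — per-locus two-sided Fisher exact test on the
  2×2 allele-count table (fully enumerable for biallelic loci, so no Markov
  chain is needed), combined across loci by Fisher's method
  (`−2Σ ln p ~ χ²(2L)`); independence across loci is assumed.
- **IBS** — per-locus identity-by-state `1 − |d₁ − d₂|/2`, pairwise
  distance `1 − mean(IBS)` over shared loci.
- **Metric MDS** — classical scaling (double-centering +
  eigen-decomposition); variance explained is each retained positive
  eigenvalue's share of the positive spectrum; coordinates are unique up to
  axis sign.
- **Mantel** — Pearson correlation of upper-triangle vectors; null by
  jointly permuting rows and columns of the second matrix;
  `p = (1 + #{|r_perm| ≥ |r_obs|})/(n_perm + 1)`, two-sided, default
  `n_perm = 9999` (999 in the pipeline default for speed), seeded. Whether
  the original analyses were one- or two-sided is not stated anywhere
  authoritative; two-sided is the conservative declared choice. An exact
  variant enumerates all `n!` relabelings for small matrices.
- **IBD split regression** — pairs partitioned by whether they touch a
  flagged site (the demo flags the divergent SBO region); OLS of F_ST on
  log connectivity per group; groups under 3 pairs are skipped with a
  warning.
- **He ~ environment** — predictors screened by variance inflation factor
  (iteratively dropping the worst ≥ 3), then OLS with sequential (type I)
  ANOVA, matching the R `anova(lm(...))` convention. Collinear seasonal
  salinity is meant to drop out here as an emergent outcome rather than by
  fiat; in the demo world coastline distance is also near-collinear with
  salinity (both are linear in the along-path coordinate), so the screen
  removes it too — an artifact of the perfectly linear synthetic gradient.

## What the synthetic world does and does not establish

The generator emulates: a multi-basin coastal domain with a monotone
salinity gradient, alongshore-dominated dispersal with seasonal releases,
connectivity-structured migration, and founder effects along a colonization
front; sample sizes mirror a typical survey (31 sites, ~20 diploids/site,
10³–10⁴ loci available). It does not emulate: mesoscale variability or
tides, vertical behavior, mutation, selection, linkage, or genotyping
error beyond uniform missingness. A green test therefore establishes that
the estimators and the inference chain behave correctly under the stated
model — not that any particular empirical system satisfies that model.

Known limitations: the greedy clusterer is validated exhaustively only to
8 nodes; the dispersal matrix at desk-scale particle counts carries
Monte-Carlo noise of order `1/√(particles per cell)`; strongly directional
(one-way) circulation can leave upstream demes with zero incoming
connectivity, which the simulator treats as isolated with a warning.
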