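# Methods

## Continuum electrostatics

The package treats a protein (or synthetic charge arrangement) as a set of
point charges qᵢ at positions rᵢ with van der Waals radii, immersed in a
1:1 salt solution described by the linearized Poisson–Boltzmann (LPB)
model. Potentials are expressed in kT/e throughout (1 kT/e ≈ 25.7 mV at
298.15 K), which makes the Bjerrum length

l_B = e² / (4π ε₀ ε_s k_B T)

the natural conversion constant: a unit charge in a uniform dielectric ε_s
produces φ(r) = l_B/r kT/e. At the default solvent conditions —
ionic strength 150 mM, temperature 298.15 K, ε_solvent 78.54 — l_B ≈
7.136 Å and the inverse Debye length κ = √(8π l_B n) ≈ 0.1273 Å⁻¹
(n is the per-species ion number density in Å⁻³; Debye length ≈ 7.86 Å).

Two field modes share one grid geometry (isotropic spacing, default 0.8 Å,
default padding 12 Å around the structure):

* **DH mode** evaluates the screened-Coulomb superposition
  φ = Σ qᵢ l_B e^(−κd)/d analytically at every node. It is exact for point
  charges in a *uniform* dielectric and is the fast path used by the
  similarity pipeline for desk-scale work. Node-atom distances below half
  a spacing are clamped to half a spacing (the number of clamped pairs is
  recorded in grid metadata).
* **LPB mode** solves ∇·(ε∇φ) − ε_s κ²(r) φ = −4π l_B ε_s ρ by finite
  differences: ε is ε_solute (default 2.0; the solvent constant is the
  physically established one, the solute value is conventional and
  configurable) inside atom radii and ε_solvent outside, with
  harmonic-mean face dielectrics; κ² acts only beyond radius +
  ion-exclusion shell (default 2 Å); boundary values are Dirichlet from
  the DH field; red–black successive over-relaxation (ω = 1.8) iterates
  until the maximum update falls below 1e-4 kT/e.

Charges are spread onto the grid over a Gaussian of width σ = one grid
spacing (truncated at 4σ, renormalized on the grid). A Gaussian source
removes most of the near-source anisotropy of the 7-point stencil — against
the analytic Coulomb/DH oracles the maximum relative error beyond three
spacings drops from ≈5–6% (8-node trilinear spreading) to ≈1–2% — while
the field beyond ~3σ remains point-like to well under 1%. Trilinear
spreading remains available (`charge_spread="trilinear"`).

The SOR residual is the maximum Gauss–Seidel update per sweep, in kT/e; it
decays geometrically but not strictly monotonically sweep-to-sweep, so the
tests assert decay on a five-sweep stride. Linearity in the charges holds
exactly for the discrete operator at fixed coefficient maps; note that the
dielectric cavity and ion-exclusion maps themselves depend on the atom
set, so superposition across *structures* only holds in a uniform medium.

## Isosurfaces and surface sampling

The compared shape is the pair of level sets φ = +1 and φ = −1 kT/e,
triangulated by marching cubes in grid world coordinates with all
disconnected components pooled into one mesh per sign. If a sign is empty
at the requested level the pipeline retries once at half the level, then
raises — a structure whose field never reaches ±0.5 kT/e has no meaningful
signed shape to compare (a monopole, for instance, has no negative surface
at any level; the synthetic clustering studies therefore use the dipole,
split-patch and quadrupole archetypes).

Points are drawn on a mesh area-weighted: a triangle is chosen with
probability proportional to its area, then a point is placed uniformly by
barycentric sampling. Sampling is reproducible from a generator seed.

Solvent-accessible surface areas use Shrake–Rupley with a deterministic
golden-spiral lattice (default 960 points) and probe 1.4 Å. Test points
landing exactly on a neighbor's expanded sphere are assigned to the
lower-index atom so that exactly coincident atoms split their shared
surface instead of double- or zero-counting it. The buried interface area
of a two-chain complex is (SASA_A + SASA_B − SASA_AB)/2 — the per-side
convention of Chimera-style "buriedArea" reports; if the summed-both-sides
convention were intended the value would double, which is why the
reference comparison for the reductase–thioredoxin interface carries a
±15% tolerance.

## Gromov–Wasserstein lower bounds

Two surfaces are compared as metric measure spaces: n sampled points with
uniform mass 1/n and Euclidean pairwise distances. The exact GW distance
is NP-hard; three classical polynomial-time lower bounds are implemented.
All distributions exclude the self-distance: the distance distribution of
a cloud is its n(n−1) off-diagonal entries, the eccentricity of a point is
its mean distance to the *other* n−1 points, and the coupling upper bound
averages over ordered pairs i ≠ j. With this convention the worked
two-point example (1 Å vs 2 Å separation) gives SLB = UB = 0.5 Å.

* SLB = ½·W₁(distance distribution X, distance distribution Y)
* FLB = ½·W₁(eccentricities X, eccentricities Y)
* TLB = ½·OT(c), c(i,j) = W₁(row distances of i, row distances of j)

W₁ between 1D samples is computed exactly by sorted-quantile integration.
The optimal transport in the TLB reduces to a linear assignment for equal
cloud sizes (a permutation is an optimal extreme point by Birkhoff's
theorem) and to the transportation LP otherwise. TLB dominates SLB and FLB
(convexity of W₁ over mixtures, and the mean-contraction bound on the
ground cost, respectively), and every admissible coupling dominates TLB —
these are the inequalities the tests verify on random clouds. SLB and FLB
are *not* mutually ordered: simple numerical experiments produce violations
in both directions, so no such chain is asserted. TLB, the tightest of the
three, is the default. Bounds are made exactly symmetric by canonicalizing
the argument order internally (the assignment sum would otherwise differ
in the last float bits).

## Repeated subsampling and histograms

One protein pair is compared by repetition: per repetition, 100 points are
drawn from each protein's + surface and the bound L⁺ computed, likewise L⁻
from the − surfaces, and the sample (L⁺+L⁻)/2 recorded; 500 repetitions
form the pair's histogram. How the original protocol merged the two signs
is not documented; the arithmetic mean is this package's choice, made once
and kept. RNG streams are derived by hashing the sorted pair labels plus
side, sign and repetition index, so results are independent of pair
evaluation order, exactly symmetric in the pair, and the two sides of a
self-comparison still draw independently — the self-pair histogram is
therefore a pure subsampling-noise baseline whose mean shrinks as the
sample size grows.

Histograms are binned on one shared edge set (64 equal-width bins spanning
zero to the largest sample in the run) because the earth-mover's distance
between histograms needs a common support.

## From histograms to a tree

The EMD between two binned histograms is W₁ of the normalized counts:
Σ|CDF_A − CDF_B|·bin width. The scalar distance between proteins i and j
is the baseline-corrected ½·[W₁(h_ij, h_ii) + W₁(h_ij, h_jj)] when
self-comparison histograms are available (the pipeline always computes
them); it vanishes exactly when the pair histogram is indistinguishable
from the noise baselines. Without self-pairs the fallback is W₁(h_ij, δ₀),
the histogram mean.

UPGMA merges the closest pair of clusters under the arithmetic mean of all
cross-pair distances (maintained by the Lance–Williams size-weighted
update, and cross-checked against a brute-force reference that recomputes
every cross-pair mean). Ties break on the smallest pair of
smallest-member leaf indices, making the tree deterministic across
platforms. Newick export uses the ultrametric half-distance convention
(node height = merge distance/2); flat clusters at level k drop the k−1
highest merges, with cluster ids assigned in leaf order. No attempt is
made to hard-code the cut heights behind any published subgroup count;
k is always an explicit parameter.

## Interactome analysis

Partner identity is exact string match on UniProtKB accessions after
trimming isoform suffixes ("-1", "-2", …) by default, since curated tables
mix isoform and canonical ids; trimming can be disabled. Venn regions are
the 2^k−1 exclusive intersection counts for 2–5 selected proteins and
always partition the union. The catalog's per-protein interaction column
and the overlap analysis count different things (raw table rows vs
deduplicated accession sets), which is why the two can legitimately differ
for the same protein; both are reported.

## Synthetic data: what it emulates and what it does not

The structure archetypes reproduce the qualitative potential-surface
classes observed on redoxin active-site faces — a predominantly one-signed
potential (monopole), a split positive/negative pattern (dipole,
split-patch shell), and an alternating pattern (quadrupole) — at a 10 Å
scale where ±1 kT/e surfaces are well resolved on a 0.8 Å grid. Families
jitter atom positions (σ 0.3 Å) and charges (σ 0.02 e) around an
archetype; generators are pure functions of their seed. The planted
interactome realizes exact exclusive and pairwise-shared counts with
synthetic accessions; the five-redoxin configuration plants the reported
per-protein totals (30/45/70/75/97) and the three reported overlaps
(24/7/5).

Passing the planted-recovery tests shows that the pipeline separates
shape families whose differences exceed the subsampling noise — it does
not show that real redoxins cluster as published, which would require the
homology models and curated structure sets that are outside this
package's scope. Synthetic structures also lack protein-like geometry
(no fold, no sequence, uniform radii), so absolute distances are not
comparable to protein values.

Reference quantities checked at desk scale (test suite sizes, chosen to
keep the default run in minutes): electrostatics oracles on a 64³ grid;
GW inequalities on 200 random cloud pairs; UPGMA against brute force on 50
random 6×6 matrices; end-to-end recovery over 10 seeds with 3 families ×
4 members, 100 points and 100 repetitions (scaled down from the
production 500).

## Known limitations

* The LPB solver is a plain SOR relaxation on a single regular grid — no
  multigrid, no nonlinear term, no focusing; it is built for ≤64³
  desk-scale grids, not production protein electrostatics, and is not
  expected to match APBS bit-for-bit.
* "150 mM mobile ions" is interpreted as a 1:1 salt; ion valencies are not
  modeled.
* The catalog transcription carries 31 Grx and 35 Trx rows; the published
  tally of 37 Trxs does not match the table rows available to this
  package, and the discrepancy is surfaced rather than resolved.
* Exact GW distances, entropic solvers and GPU transport are out of scope;
  the bounds are the analysis tool, as in the protocol they implement.
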