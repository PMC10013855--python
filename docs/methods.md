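# Methods

This note records the models, conventions and numerical choices behind
each analysis stage, what the synthetic-data generators do and do not
emulate, and the design decisions taken where the underlying procedure was
genuinely open.

## Geometry conventions

All distances and angles are measured between *geometric centers* —
unweighted arithmetic means of atom coordinates, no mass weighting. The
default atom subset is heavy atoms: hydrogen placement varies between
force fields and reconstruction protocols, and heavy-atom centers are
insensitive to it. The subset rule (`all_atoms`, `heavy_atoms`, `c_alpha`)
is part of every `ResidueGroup`, because the convention used upstream is
not always recorded alongside published measurements.

The interdomain orientation angle uses two vectors, each running from a
domain's center to a single anchor residue's center (helical domain →
A161, Ras-like domain → E299 for Gsα), and is reported in [0°, 180°] via
the arccosine of the normalised dot product.

Superposition is least-squares rigid-body alignment (Kabsch, via
`scipy.spatial.transform.Rotation.align_vectors`) of a fit group to a
reference frame, applied to all atoms; internal geometry is preserved to
machine precision and the operation refuses degenerate (collinear, < 3
atoms) fit selections. Residue groups are declared in YAML using PDB
author numbering per chain; mapping to internal 0-based indices happens in
the config layer, so selections like "receptor without intracellular loop
3" are plain residue-range exclusions.

## Opening-state classification

The Gsα opening coordinate is the A161–E299 center distance. Boundaries:
open [55 Å, ∞), semi-open [45, 55), semi-closed (35, 45), closed (0, 35].
The source convention is explicit only at the outer bounds (≥ 55 and
≤ 35); we resolve the interior boundary by assigning 45.0 Å to semi-open,
keeping all four intervals disjoint while preserving the outer ≥/≤. The
classifier is deliberately a raw per-frame threshold — no hidden-Markov or
dwell-time smoothing — so occupancies are exactly histogram fractions.
Known limitation: a flipped-up helical-domain geometry can yield an
intermediate A161–E299 distance while the domain is actually packed closed;
the distance CV alone cannot detect this, and no corrected classifier is
attempted. Users should corroborate with the interdomain angle and
domain–domain distance CVs.

## Contacts

A target residue is in contact in a frame when the minimum heavy-atom pair
distance to the probe group is ≤ the cutoff (default 3.0 Å; the boundary
counts as "within"). Persistence means contact in *strictly more than*
half of the analysed frames (6/10 qualifies, 5/10 does not). Residues
belonging to the probe are never reported as targets (self-contact
exclusion). The average percentage interaction time of an interface is
100 × the mean contact fraction over its persistent residues. No
minimum-image treatment is applied by default — analyses assume a whole,
wrapped complex — and no angular hydrogen-bond criteria are implemented:
contacts are proximity only. Nearest-neighbour queries use a k-d tree; an
O(N²) brute-force oracle in the test suite pins the semantics.

## Pose clustering

Frames are first aligned on the receptor (frame-0 reference); the ligand
RMSD between every frame pair is then computed *without further fitting*,
so poses are compared within the receptor frame. Ward minimum-variance
linkage on that matrix (SciPy) provides a partition at every k; the
within-cluster sum of squares is evaluated from the distance matrix as
Σ_c (1/2n_c) Σ_{i,j∈c} d²_ij. The cluster count is the point of maximum
perpendicular distance to the chord joining (1, WSS₁) and (k_max, WSS_kmax)
after normalising both axes — deterministic, no RNG. Because that chord
criterion always has *some* maximum, the elbow is accepted only when
demarcated (WSS drops by more than half at the elbow step); otherwise the
data are treated as a single cluster. The hierarchical/elbow combination
follows the behaviour of the commonly used trajectory-clustering tools
that mix Ward linkage with an elbow rule; a pure K-means mode on ligand
coordinates is available for sensitivity checks. Populations are reported
over all supplied frames; the medoid (lowest mean RMSD to its cluster
mates) represents each cluster, ties broken by lowest frame index.

## Free-energy surfaces

PMFs are histogram estimates, W(bin) = −k_B·T·ln(count/count_max),
anchored at the most probable bin and shifted so the minimum over retained
bins is exactly zero (only relative values are meaningful). Conventional
bin widths are 0.5 Å for distances and 5° for angles; 2D grids mask bins
with fewer than 10 configurations (1D grids default to masking empty bins
only). Grids span [floor(min), ceil(max)] in whole bin widths.
T = 310 K and k_B = 0.0019872041 kcal/mol/K throughout.

GaMD-boosted samples are reweighted per bin by the second-order cumulant
expansion: each bin's probability is multiplied by
exp(β·c₁ + β²·c₂/2), with c₁ the mean and c₂ the (unbiased) variance of
the boost ΔV in that bin. Higher orders are not used: with realistic
sample counts they are dominated by noise. Bins with fewer than two
samples cannot estimate c₂ and are masked. The boost exponents are
centred on their maximum before exponentiation, which both conditions the
arithmetic and makes a constant (or zero) boost reduce *bit-identically*
to the unbiased estimator. Entropy-like quantities are never reweighted
(the exponential averages diverge in practice); for energies, only the
enthalpic term is reweighted (below).

Minima are grid bins strictly below all unmasked axis-neighbours. Barriers
are exact on the grid graph: the bottleneck (minimax-over-path) free
energy between two minima via a Dijkstra variant, minus the origin
minimum. An optional prominence filter removes statistical dimples — a
minimum is kept only if every route to a deeper minimum climbs at least
`min_prominence` above it (0.5 kcal/mol is a reasonable setting for
well-sampled 0.5 Å grids).

## MM–PBSA assembly

Per-frame electrostatic, van der Waals, polar- and nonpolar-solvation
components are *inputs* (CSV), produced by an external implicit-solvent
pipeline; this package never solves the Poisson–Boltzmann equation. ΔH is
the window mean of the component sum. The entropic term uses the
interaction-entropy estimator, −TΔS = k_B·T·ln⟨e^{β(E_int−⟨E_int⟩)}⟩,
evaluated with log-sum-exp so large fluctuations cannot overflow; by
Jensen's inequality it is non-negative, and exactly zero for constant
interaction energy. ΔG = ΔH + (−TΔS) is exact addition. SEMs come from
block averages: the window is split into n_blocks contiguous equal blocks
(default 5 — over a 2 μs analysis window that gives 400 ns blocks, long
relative to the autocorrelation of the collective variables) and
SEM = SD(block means)/√n_blocks.

GaMD-biased energies are reweighted by histogramming the energy with
0.5 kcal/mol bins, computing the reweighted PMF W on that energy
coordinate, and averaging bin energies with probabilities e^{−βW}. With
zero boost this reduces to the plain mean, up to the loss of
singleton-count bins.

A toy gas-phase evaluator (Coulomb k·q_iq_j/r with k = 332.0637
kcal·Å/(mol·e²), plus 12-6 Lennard-Jones with Lorentz–Berthelot
combination, no cutoffs) exists purely so the energy chain can be tested
end-to-end on synthetic complexes.

## Correlations

Pearson coefficients are the standard product-moment statistic; zero
variance raises rather than returning NaN. The lag convention is
r(τ) = corr(x(t), y(t+τ)) for τ ≥ 0 — positive lag reads the second series
later — computed on the overlapping samples only (no padding), with τ up
to half the series duration. Cross-run summaries average each run's
trailing window (default 2000 ns) per CV and correlate the per-run means;
with fewer than three runs only the means are reported. No significance
testing is attached to r.

## Synthetic data: what it emulates, and what it does not

The generators provide data with the statistical structure each estimator
assumes, plus exact ground truth, so every stage has a parameter-recovery
test with no external download.

**Langevin CVs.** Overdamped (Brownian) Euler–Maruyama dynamics,
dx = −βD·U′(x)dt + √(2Ddt)·ξ, defaults D = 100 Å²/ns and dt = 0.005 ns.
Overdamped rather than inertial dynamics: only equilibrium distributions
and correlation structure matter for testing the estimators, not kinetic
prefactors. The step bound dt < 2/(βD·max|U″|) is enforced with the
suggested maximum in the error. Plain Euler carries an O(dt) sampling
bias (a few percent in well variance at the defaults); an optional
Metropolis correction (MALA) makes the stationary distribution exact
regardless of dt and is used wherever a test compares occupancies against
analytic Boltzmann weights. Identical seeds give bit-identical
trajectories.

**Calibrated double well.** A quartic with derivative k(x−a)(x−c)(x−b):
minima land *exactly* at the requested closed (34 Å) and open (62 Å)
positions; the saddle position c and scale k are solved (Brent root
finding on the analytic polynomial integrals) so the barrier above the
lower minimum and the well-depth difference take the requested values.
Defaults: barrier 2.5 kcal/mol (the observed scale of the opening
barrier), asymmetry 1.0 kcal/mol with the open well deeper, reflecting
the open state's greater stability on the opening free-energy surface.
The barrier must exceed |asymmetry| or no double well exists (raises).

**GaMD boost.** ΔV(x) = ½k(E−V(x))² below the threshold E, zero above,
with E at the potential's domain maximum (the lower-bound convention, so
wells are filled and barrier tops are untouched). k is reduced by
fixed-point iteration until the boosted-ensemble SD of ΔV is at most
σ₀ = 6.0 kcal/mol, mirroring the boost-SD cap used when such simulations
are parameterised.

**Correlated pairs.** Either i.i.d. bivariate Gaussians at exactly the
requested ρ, or a stationary Ornstein–Uhlenbeck pair (exact AR(1)
discretisation, correlation time τ default 20 ns) in which y echoes x
after a prescribed lag, so the lag-correlation profile peaks at that lag
with height ≈ ρ and decays as exp(−|τ−lag|/τ_c).

**Toy complexes.** A row of two-atom receptor residues plus a small-
molecule ligand hopping between pockets placed at near-equidistant
directions on a sphere (triangular bipyramid for five) — equidistant
pockets make the WSS curve decay evenly to the planted k, giving the
elbow a single clean kink. Intra-pose jitter (0.05 Å) is far below the
inter-pocket spacing (12 Å). A contact script rigidly displaces chosen
residues to within the cutoff of the ligand in chosen frames; the
generator brute-force-verifies the resulting geometry against the script
and refuses infeasible scripts. Ground truth (pose labels, pocket
centers, contact tables) is returned alongside.

None of this emulates real atomistic data: there is no solvent, membrane
or force field; CV dynamics are 1D and memoryless; pose clusters are far
better separated than real ligand poses; contacts are scripted rather
than emergent. Passing tests therefore demonstrate *estimator
correctness* — that each stage recovers the known truth of data with the
assumed structure at the stated tolerance — not robustness to the
ambiguities of real trajectories (overlapping pose clusters, broken
ergodicity, correlated multi-dimensional CVs).

## Problem sizes used in tests and the acceptance script

PMF-recovery runs use 10⁶ Langevin steps (unbiased RMSE tolerance 0.3
kcal/mol, GaMD-reweighted 0.5, over bins with ≥ 100 counts); occupancy
checks use 4–6 independent runs of 1.2–3×10⁵ Metropolis-corrected steps
compared within three standard errors (with a floor on the SE estimate,
since run-to-run spread over ~10² barrier crossings is itself noisy);
correlation recovery uses n = 10⁵ (±0.01 on ρ) and n = 4×10⁴ for the
50 ns lag peak; clustering toys use 100–200 frames. These sizes give
comfortable statistical margins for the stated tolerances while keeping
the whole suite fast on a single CPU.

## Known limitations

- The A161–E299 distance mislabels flip-up helical-domain geometries (see
  above); the angle CV must be consulted alongside it.
- Helix unwinding has no quantitative metric here (none is defined for
  the α5 partial unwinding observation); secondary-structure analysis is
  out of scope.
- Cluster populations are computed over all supplied frames; window
  restriction must be done upstream by slicing the trajectory.
- The MM–PBSA chain trusts its input tables; no screened-electrostatics
  variant and no normal-mode entropy are provided.
- 2D synthetic CVs are built from 1D processes (independent or linearly
  mixed); there are no bespoke 2D potentials.
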