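# ternary

Trajectory analysis for GPCR–G-protein ternary complexes.

`ternary` implements the full analysis chain used to characterise the
conformational dynamics and energetics of an agonist-bound receptor coupled
to its G protein — prototypically norepinephrine-bound β2-adrenergic
receptor in complex with Gs — from multi-microsecond molecular-dynamics
trajectories (conventional or Gaussian-accelerated):

- **Collective variables** — geometric-center distances and interdomain
  angles between named residue groups (Gsα helical vs Ras-like domain,
  α1/α5 helices, the receptor NPxxY motif, the ligand), plus fitted RMSD
  series and trailing-window averages.
- **Opening-state classification** — the Gsα opening coordinate (the
  A161–E299 center-to-center distance, Å) is mapped to four states:
  open (≥ 55), semi-open ([45, 55)), semi-closed ((35, 45)) and
  closed (≤ 35), with occupancies and transition counts.
- **Persistent contacts** — a residue is in contact when any heavy atom
  comes within 3 Å of the probe group, and persistent when that holds in
  more than half of the frames; interface residue counts and average
  percentage interaction times follow.
- **Pose clustering** — pairwise ligand RMSD in the receptor frame → Ward
  minimum-variance linkage → elbow selection of the cluster count →
  populations and medoid representative poses.
- **Free-energy surfaces** — 1D/2D potentials of mean force,
  W = −k_B·T·ln p, with 0.5 Å / 5° bins and low-count masking, and GaMD
  reweighting by the second-order cumulant expansion
  ln⟨e^{βΔV}⟩ ≈ β·c₁ + β²·c₂/2 per bin; exact bottleneck-path barriers
  between minima.
- **MM–PBSA assembly** — ΔG = ΔH + (−TΔS) from per-frame component
  tables, with the interaction-entropy estimator
  −TΔS = k_B·T·ln⟨e^{βΔE_int}⟩, block-average SEMs, and canonical-ensemble
  reweighting of GaMD-biased energies on a 0.5 kcal/mol energy histogram.
- **Correlations** — Pearson coefficients across runs and time-lagged
  correlation profiles r(τ) = corr(x(t), y(t+τ)) for τ from 0 to half the
  trajectory length.
- **Synthetic data** — seed-deterministic generators with exact ground
  truth: overdamped Langevin dynamics on calibrated double-well potentials
  (minima at the closed ~34 Å and open ~62 Å endpoints), GaMD-style
  harmonic boosts, CV pairs with prescribed correlation and lag, and toy
  receptor–ligand complexes with scripted poses and contacts.

## Worked example

Simulate the calibrated opening coordinate, estimate its free-energy
profile, classify states, and assemble a binding energy:

```python
from ternary import (assemble_dG, classify_series, minima_and_barrier,
                     occupancy, pmf_unbiased)
from ternary.synthetic import make_opening_double_well, simulate_langevin

well = make_opening_double_well(barrier=2.5, asymmetry=1.0)
run = simulate_langevin(well, n_steps=200_000, seed=42, x0=62.0)

grid = pmf_unbiased(run.series.values, bin_width=0.5)
res = minima_and_barrier(grid, min_prominence=0.5)
for loc, depth in res.minima:
    print(f"minimum at {loc[0]:.2f} A, depth {depth:.2f} kcal/mol")
print(f"barrier: {res.barrier:.2f} kcal/mol")

for state, frac in occupancy(classify_series(run.series)).items():
    print(f"{state.value}: {frac:.3f}")

be = assemble_dG(-21.61, 6.88, sem=0.92)
print(f"dG = {be.dG:.2f} +/- {be.sem:.2f} kcal/mol")
```

prints

```
minimum at 61.75 A, depth 0.00 kcal/mol
minimum at 34.75 A, depth 1.09 kcal/mol
barrier: 2.56 kcal/mol
closed: 0.081
semi_closed: 0.078
semi_open: 0.049
open: 0.792
dG = -14.73 +/- 0.92 kcal/mol
```

The two PMF minima sit at the open (~62 Å) and closed (~34 Å) endpoints of
the generating double well, separated by the calibrated ~2.5 kcal/mol
barrier; the open state dominates because the well was built 1 kcal/mol
deeper there. The last line reassembles a published-style MM–PBSA row:
enthalpy −21.61 plus entropic penalty +6.88 gives ΔG = −14.73 kcal/mol.

A command-line interface mirrors the library
(`ternary simulate|extract|states|contacts|cluster|pmf|energy|correlate`),
reading PDB/DCD/XTC trajectories, YAML residue-group definitions and CSV
tables, and writing CSV/JSON.

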