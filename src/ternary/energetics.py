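"""MM-PBSA binding free-energy assembly.

Per-frame energy components (gas-phase electrostatics, van der Waals, polar
and nonpolar solvation, all kcal/mol) are consumed from tables produced by
an external implicit-solvent pipeline; this module averages them into an
enthalpy dH, estimates the entropic term -T*dS from gas-phase
interaction-energy fluctuations (interaction entropy), attaches a
block-average standard error, and assembles dG = dH + (-T*dS).

For GaMD trajectories the biased-ensemble energy is reweighted back to the
canonical ensemble by histogramming the energy (0.5 kcal/mol bins), turning
the boost statistics of each bin into a PMF W, and averaging bin energies
with probabilities exp(-beta*W).

A toy gas-phase Coulomb + Lennard-Jones evaluator is included so the whole
chain can be exercised end-to-end on synthetic complexes without any
external energy pipeline.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence, Tuple

import numpy as np
from scipy.special import logsumexp

from .core import DEFAULT_TEMPERATURE, KB
from .pmf import BoostedSamples, pmf_reweighted

__all__ = ["EnergySeries", "BindingEnergy", "mean_enthalpy",
           "interaction_entropy", "assemble_dG", "block_sem",
           "reweight_energy", "toy_interaction_energy", "read_energy_csv"]

#: Coulomb constant in kcal*A/(mol*e^2).
COULOMB_K = 332.0637


@dataclass(frozen=True)
class EnergySeries:
    """Per-frame MM-PBSA energy components (kcal/mol)."""

    electrostatic: np.ndarray
    van_der_waals: np.ndarray
    polar_solvation: np.ndarray
    nonpolar_solvation: np.ndarray
    timestep: float = 1.0
    gas_interaction: Optional[np.ndarray] = None
    deltaV: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        arrays = {}
        n = None
        for name in ("electrostatic", "van_der_waals", "polar_solvation",
                     "nonpolar_solvation", "gas_interaction", "deltaV"):
            a = getattr(self, name)
            if a is None:
                continue
            a = np.asarray(a, dtype=float)
            if not np.all(np.isfinite(a)):
                raise ValueError(f"{name} contains non-finite values")
            if n is None:
                n = a.size
            elif a.size != n:
                raise ValueError("all component arrays must have equal length")
            arrays[name] = a
        for name, a in arrays.items():
            object.__setattr__(self, name, a)

    @property
    def n_frames(self) -> int:
        return self.electrostatic.size

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.n_frames) * self.timestep

    def total(self) -> np.ndarray:
        """Per-frame sum of all four components."""
        return (self.electrostatic + self.van_der_waals
                + self.polar_solvation + self.nonpolar_solvation)


@dataclass(frozen=True)
class BindingEnergy:
    """dG = dH + (-T*dS), all kcal/mol, with a block-average SEM on dG."""

    dH: float
    minus_TdS: float
    dG: float
    sem: float = 0.0

    def __post_init__(self) -> None:
        if self.dG != self.dH + self.minus_TdS:
            raise ValueError("dG must equal dH + (-T dS) exactly")


def _window_mask(times: np.ndarray, window: Optional[Tuple[float, float]]) -> np.ndarray:
    if window is None:
        return np.ones(times.size, dtype=bool)
    t0, t1 = window
    mask = (times >= t0 - 1e-12) & (times <= t1 + 1e-12)
    if not mask.any():
        raise ValueError("window contains no frames")
    return mask


def mean_enthalpy(series: EnergySeries,
                  window: Optional[Tuple[float, float]] = None) -> float:
    """Mean total energy (dH, kcal/mol) over an inclusive ns window."""
    mask = _window_mask(series.times, window)
    return float(np.mean(series.total()[mask]))


def interaction_entropy(gas_phase_interaction: np.ndarray,
                        temperature: float = DEFAULT_TEMPERATURE) -> float:
    """Entropic penalty -T*dS = kB*T * ln< exp(beta * dE) > (kcal/mol).

    dE are the fluctuations of the gas-phase interaction energy about its
    mean. The exponential average is evaluated with log-sum-exp, so large
    fluctuations cannot overflow. By Jensen's inequality the result is
    always >= 0, and exactly 0 for a constant series.
    """
    e = np.asarray(gas_phase_interaction, dtype=float)
    if e.size < 2:
        raise ValueError("interaction entropy needs at least 2 frames")
    if not np.all(np.isfinite(e)):
        raise ValueError("interaction energies must be finite")
    kT = KB * temperature
    beta = 1.0 / kT
    fluct = e - e.mean()
    log_avg = logsumexp(beta * fluct) - np.log(e.size)
    return max(float(kT * log_avg), 0.0)


def assemble_dG(dH: float, minus_TdS: float, sem: float = 0.0) -> BindingEnergy:
    """Assemble a binding free energy: dG = dH + (-T*dS), exact addition."""
    if not (np.isfinite(dH) and np.isfinite(minus_TdS)):
        raise ValueError("dH and -T dS must be finite")
    return BindingEnergy(dH=float(dH), minus_TdS=float(minus_TdS),
                         dG=float(dH) + float(minus_TdS), sem=float(sem))


def block_sem(series: np.ndarray, n_blocks: int = 5) -> float:
    """Standard error of the mean from contiguous block averages.

    The series is split into ``n_blocks`` equal contiguous blocks (surplus
    frames are dropped from the end); SEM = SD(block means)/sqrt(n_blocks).
    Five blocks over a 2-us analysis window give 400-ns blocks, long
    relative to the autocorrelation of the collective variables.
    """
    x = np.asarray(series, dtype=float)
    if n_blocks < 2:
        raise ValueError("need at least 2 blocks")
    if x.size < n_blocks:
        raise ValueError(f"series of {x.size} frames cannot form {n_blocks} blocks")
    per = x.size // n_blocks
    means = x[: per * n_blocks].reshape(n_blocks, per).mean(axis=1)
    return float(np.std(means, ddof=1) / np.sqrt(n_blocks))


def reweight_energy(energies: np.ndarray, deltaV: np.ndarray,
                    temperature: float = DEFAULT_TEMPERATURE,
                    bin_width: float = 0.5) -> float:
    """Canonical-ensemble mean energy from GaMD-biased samples.

    Energies are histogrammed with ``bin_width`` (default 0.5 kcal/mol); the
    cumulant-expansion reweighted PMF W on the energy coordinate gives bin
    probabilities P = exp(-beta*W), and the returned value is
    sum(P * E*_bin) / sum(P) with E*_bin the biased-ensemble mean energy of
    each bin. With dV identically zero this reduces to the plain arithmetic
    mean, up to the loss of bins masked for being too sparse to estimate
    the boost variance.
    """
    e = np.asarray(energies, dtype=float)
    dv = np.asarray(deltaV, dtype=float)
    if e.shape != dv.shape or e.ndim != 1 or e.size == 0:
        raise ValueError("energies and deltaV must be equal-length 1D arrays")
    grid = pmf_reweighted(
        BoostedSamples(cv=e, deltaV=dv, temperature=temperature),
        bin_width=bin_width, count_cutoff=1, order=2,
    )
    edges = grid.bin_edges[0]
    shape = len(edges) - 1
    idx = np.clip(np.searchsorted(edges, e, side="right") - 1, 0, shape - 1)
    sums = np.bincount(idx, weights=e, minlength=shape)
    counts = np.bincount(idx, minlength=shape)
    keep = ~grid.mask & (counts > 0)
    if not keep.any():
        raise ValueError("no populated energy bins after masking")
    ebin = sums[keep] / counts[keep]
    beta = 1.0 / (KB * temperature)
    p = np.exp(-beta * grid.free_energy[keep])
    return float(np.sum(p * ebin) / np.sum(p))


def toy_interaction_energy(coords_a: np.ndarray, coords_b: np.ndarray,
                           charges_a: Sequence[float], charges_b: Sequence[float],
                           lj_sigma_a: Sequence[float], lj_sigma_b: Sequence[float],
                           lj_eps_a: Sequence[float], lj_eps_b: Sequence[float],
                           ) -> Tuple[float, float]:
    """Gas-phase Coulomb and 12-6 Lennard-Jones inter-group energies.

    Coulomb: sum of k*qi*qj/rij (kcal/mol, charges in e, r in A, vacuum
    dielectric). LJ: 4*eps*((s/r)^12 - (s/r)^6) with Lorentz-Berthelot
    combination (arithmetic sigma, geometric epsilon). No cutoffs. A test
    stand-in for an external Poisson-Boltzmann pipeline's gas-phase terms.
    """
    A = np.asarray(coords_a, dtype=float)
    B = np.asarray(coords_b, dtype=float)
    qa = np.asarray(charges_a, dtype=float)
    qb = np.asarray(charges_b, dtype=float)
    sa = np.asarray(lj_sigma_a, dtype=float)
    sb = np.asarray(lj_sigma_b, dtype=float)
    ea = np.asarray(lj_eps_a, dtype=float)
    eb = np.asarray(lj_eps_b, dtype=float)
    for arr, n in ((qa, len(A)), (sa, len(A)), (ea, len(A)),
                   (qb, len(B)), (sb, len(B)), (eb, len(B))):
        if arr.size != n:
            raise ValueError("parameter tables must cover every atom")
    diff = A[:, None, :] - B[None, :, :]
    r = np.sqrt(np.sum(diff**2, axis=2))
    if np.any(r < 0.01):
        raise ValueError("overlapping atoms (r < 0.01 A)")
    elec = float(np.sum(COULOMB_K * np.outer(qa, qb) / r))
    sigma = (sa[:, None] + sb[None, :]) / 2.0
    eps = np.sqrt(np.outer(ea, eb))
    sr6 = (sigma / r) ** 6
    vdw = float(np.sum(4.0 * eps * (sr6**2 - sr6)))
    return elec, vdw


def read_energy_csv(path, timestep: Optional[float] = None) -> EnergySeries:
    """Read a per-frame component table.

    Expected columns: ``frame,time_ns,elec,vdw,polar,nonpolar`` with optional
    ``gas_interaction`` and ``deltaV``.
    """
    import pandas as pd

    df = pd.read_csv(path)
    required = ["elec", "vdw", "polar", "nonpolar"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"energy table missing columns {missing}")
    if timestep is None:
        if "time_ns" in df.columns and len(df) > 1:
            timestep = float(df["time_ns"].iloc[1] - df["time_ns"].iloc[0])
        else:
            timestep = 1.0
    return EnergySeries(
        electrostatic=df["elec"].to_numpy(),
        van_der_waals=df["vdw"].to_numpy(),
        polar_solvation=df["polar"].to_numpy(),
        nonpolar_solvation=df["nonpolar"].to_numpy(),
        timestep=timestep,
        gas_interaction=df["gas_interaction"].to_numpy() if "gas_interaction" in df else None,
        deltaV=df["deltaV"].to_numpy() if "deltaV" in df else None,
    )
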