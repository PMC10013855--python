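"""Synthetic-data generators with exact ground truth.

Every downstream stage of the package is exercised against data generated
here: overdamped Langevin dynamics on analytically known 1D potentials
(optionally under a GaMD-style harmonic boost), CV pairs with prescribed
Pearson correlation and time lag, and toy receptor-ligand coordinate sets
with scripted binding poses and contacts. Each generator is deterministic
under a seed and emits the ground truth needed for parameter-recovery
tests.

The calibrated opening double-well places its minima at the closed (~34 A)
and open (~62 A) endpoints of the Gs-alpha opening coordinate with a small
(2-3 kcal/mol) barrier, emulating the two-state character of the
interdomain distance.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Dict, Iterable, List, Optional, Sequence, Set, Tuple

import numpy as np
from scipy.optimize import brentq

from .core import (
    DEFAULT_TEMPERATURE,
    KB,
    CVSeries,
    ResidueGroup,
    Topology,
    Trajectory,
)

__all__ = ["Potential1D", "Harmonic", "DoubleWell", "Tabulated", "BoostSpec",
           "LangevinRun", "simulate_langevin", "make_opening_double_well",
           "correlated_cv_pair", "make_toy_complex", "ToyComplex",
           "boltzmann_weights"]


# ---------------------------------------------------------------------------
# Potentials
# ---------------------------------------------------------------------------


class Potential1D:
    """Evaluable, differentiable 1D potential (kcal/mol over Angstrom)."""

    domain: Tuple[float, float]

    def value(self, x: float) -> float:  # pragma: no cover - interface
        raise NotImplementedError

    def derivative(self, x: float) -> float:  # pragma: no cover - interface
        raise NotImplementedError

    def values(self, x: np.ndarray) -> np.ndarray:
        return np.asarray([self.value(float(v)) for v in np.asarray(x).ravel()])

    def max_curvature(self, n_grid: int = 2001) -> float:
        xs = np.linspace(self.domain[0], self.domain[1], n_grid)
        h = (self.domain[1] - self.domain[0]) / (n_grid - 1)
        d = np.asarray([self.derivative(float(v)) for v in xs])
        return float(np.max(np.abs(np.gradient(d, h))))


@dataclass(frozen=True)
class Harmonic(Potential1D):
    """V(x) = k/2 (x - x0)^2."""

    k: float
    x0: float = 0.0
    half_width: float = 20.0

    @property
    def domain(self) -> Tuple[float, float]:
        return (self.x0 - self.half_width, self.x0 + self.half_width)

    def value(self, x: float) -> float:
        return 0.5 * self.k * (x - self.x0) ** 2

    def derivative(self, x: float) -> float:
        return self.k * (x - self.x0)


@dataclass(frozen=True)
class DoubleWell(Potential1D):
    """Quartic double well with derivative k (x-a)(x-c)(x-b).

    a < c < b: a and b are the minima, c the saddle. The absolute offset is
    chosen so that the lower minimum sits at zero.
    """

    k: float
    a: float
    c: float
    b: float
    offset: float = 0.0

    @property
    def domain(self) -> Tuple[float, float]:
        span = self.b - self.a
        return (self.a - 0.35 * span, self.b + 0.35 * span)

    @property
    def minima(self) -> Tuple[float, float]:
        return (self.a, self.b)

    @property
    def saddle(self) -> float:
        return self.c

    def _raw(self, x: float) -> float:
        # antiderivative of k (x-a)(x-c)(x-b)
        a, b, c = self.a, self.b, self.c
        s2 = a + b + c
        s1 = a * b + a * c + b * c
        s0 = a * b * c
        return self.k * (x**4 / 4.0 - s2 * x**3 / 3.0 + s1 * x**2 / 2.0 - s0 * x)

    def value(self, x: float) -> float:
        return self._raw(x) + self.offset

    def derivative(self, x: float) -> float:
        return self.k * (x - self.a) * (x - self.c) * (x - self.b)

    def barrier(self) -> float:
        """Saddle height above the lower minimum (kcal/mol)."""
        return self.value(self.c) - min(self.value(self.a), self.value(self.b))

    def asymmetry(self) -> float:
        """V(closed minimum) - V(open minimum)."""
        return self.value(self.a) - self.value(self.b)


@dataclass(frozen=True)
class Tabulated(Potential1D):
    """Cubic-spline interpolated potential from (x, V) tables."""

    x: np.ndarray
    v: np.ndarray

    def __post_init__(self) -> None:
        from scipy.interpolate import CubicSpline

        x = np.asarray(self.x, dtype=float)
        v = np.asarray(self.v, dtype=float)
        if x.ndim != 1 or x.size < 4 or x.shape != v.shape:
            raise ValueError("need matching 1D tables with >= 4 points")
        object.__setattr__(self, "x", x)
        object.__setattr__(self, "v", v)
        object.__setattr__(self, "_spline", CubicSpline(x, v))

    @property
    def domain(self) -> Tuple[float, float]:
        return (float(self.x[0]), float(self.x[-1]))

    def value(self, x: float) -> float:
        return float(self._spline(np.clip(x, *self.domain)))

    def derivative(self, x: float) -> float:
        return float(self._spline(np.clip(x, *self.domain), 1))


def make_opening_double_well(closed_pos: float = 34.0, open_pos: float = 62.0,
                             barrier: float = 2.5,
                             asymmetry: float = 1.0) -> DoubleWell:
    """Double well calibrated to the Gs-alpha opening coordinate.

    Minima sit exactly at ``closed_pos`` and ``open_pos``; the saddle lies
    ``barrier`` kcal/mol above the lower minimum; ``asymmetry`` is
    V(closed) - V(open), positive when the open state is the more stable
    one (the default, matching the relative stability seen on the opening
    free-energy surface).
    """
    a, b = float(closed_pos), float(open_pos)
    if not b > a:
        raise ValueError("open_pos must exceed closed_pos")
    if barrier <= 0:
        raise ValueError("barrier must be positive")
    if barrier <= abs(asymmetry):
        raise ValueError("barrier must exceed |asymmetry| for two minima to exist")

    def va_vc(c: float) -> Tuple[float, float]:
        dw = DoubleWell(k=1.0, a=a, c=c, b=b)
        return dw._raw(a) - dw._raw(b), dw._raw(c) - dw._raw(b)

    def f(c: float) -> float:
        v_a, v_c = va_vc(c)  # with V(b) = 0 and k = 1
        return barrier * v_a - asymmetry * (v_c - min(v_a, 0.0))

    eps = 1e-6 * (b - a)
    c = brentq(f, a + eps, b - eps)
    v_a, v_c = va_vc(c)
    denom = v_c - min(v_a, 0.0)
    if denom <= 0:
        raise ValueError("infeasible double-well parameters")
    k = barrier / denom
    dw = DoubleWell(k=k, a=a, c=c, b=b)
    low = min(dw._raw(a), dw._raw(b))
    return DoubleWell(k=k, a=a, c=c, b=b, offset=-low)


def boltzmann_weights(potential: Potential1D, boundaries: Sequence[float],
                      temperature: float = DEFAULT_TEMPERATURE,
                      n_grid: int = 20001) -> np.ndarray:
    """Exact-region Boltzmann probabilities between the given boundaries.

    ``boundaries`` are interior cut points; the regions are
    (domain_lo, b1], (b1, b2], ..., (bk, domain_hi). Used as the analytic
    oracle for state-occupancy tests.
    """
    lo, hi = potential.domain
    xs = np.linspace(lo, hi, n_grid)
    beta = 1.0 / (KB * temperature)
    v = potential.values(xs)
    p = np.exp(-beta * (v - v.min()))
    cuts = [lo] + [float(b) for b in boundaries] + [hi]
    weights = []
    for x0, x1 in zip(cuts[:-1], cuts[1:]):
        mask = (xs > x0) & (xs <= x1)
        weights.append(np.trapezoid(p[mask], xs[mask]) if mask.sum() > 1 else 0.0)
    w = np.asarray(weights)
    return w / w.sum()


# ---------------------------------------------------------------------------
# GaMD-style boost
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class BoostSpec:
    """Harmonic GaMD boost: dV(x) = k/2 (E - V(x))^2 for V(x) < E, else 0.

    ``threshold_E`` follows the lower-bound convention (E at the maximum of
    the potential over its domain), so the boost fills wells and vanishes on
    top of barriers.
    """

    threshold_E: float
    k: float

    def __post_init__(self) -> None:
        if self.k <= 0:
            raise ValueError("boost force constant must be positive")

    def deltaV(self, potential: Potential1D, x: float) -> float:
        v = potential.value(x)
        if v >= self.threshold_E:
            return 0.0
        return 0.5 * self.k * (self.threshold_E - v) ** 2

    def deltaV_derivative(self, potential: Potential1D, x: float) -> float:
        v = potential.value(x)
        if v >= self.threshold_E:
            return 0.0
        return -self.k * (self.threshold_E - v) * potential.derivative(x)

    @classmethod
    def from_potential(cls, potential: Potential1D, sigma0: float = 6.0,
                       temperature: float = DEFAULT_TEMPERATURE,
                       n_grid: int = 4001) -> "BoostSpec":
        """Lower-bound boost with k scaled so std(dV) <= sigma0 (kcal/mol).

        The standard deviation is evaluated over the boosted-ensemble
        distribution on a grid and k is reduced by fixed-point iteration
        until the sigma0 cap is met (mirroring the role of the boost-SD
        upper limit in GaMD parameter selection).
        """
        lo, hi = potential.domain
        xs = np.linspace(lo, hi, n_grid)
        v = potential.values(xs)
        vmin, vmax = float(v.min()), float(v.max())
        if vmax <= vmin:
            raise ValueError("potential is flat; boost is undefined")
        E = vmax
        k = 1.0 / (vmax - vmin)
        beta = 1.0 / (KB * temperature)
        for _ in range(25):
            dv = 0.5 * k * np.clip(E - v, 0.0, None) ** 2
            p = np.exp(-beta * (v + dv - (v + dv).min()))
            p /= p.sum()
            mean = float(np.sum(p * dv))
            std = math.sqrt(max(float(np.sum(p * dv**2)) - mean**2, 0.0))
            if std <= sigma0 * (1 + 1e-6):
                break
            k *= sigma0 / std
        return cls(threshold_E=E, k=k)


# ---------------------------------------------------------------------------
# Overdamped Langevin dynamics
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class LangevinRun:
    """A simulated CV trajectory plus its generating ground truth."""

    series: CVSeries
    deltaV: Optional[np.ndarray]
    potential: Potential1D
    boost: Optional[BoostSpec]
    acceptance_rate: Optional[float] = None


def simulate_langevin(potential: Potential1D,
                      temperature: float = DEFAULT_TEMPERATURE,
                      diffusion: float = 100.0, dt: float = 0.005,
                      n_steps: int = 100_000, x0: Optional[float] = None,
                      seed: int = 0, boost: Optional[BoostSpec] = None,
                      stride: int = 1, burn_in: int = 0,
                      metropolis: bool = False, name: str = "cv",
                      units: str = "A") -> LangevinRun:
    """Overdamped (Brownian) Euler-Maruyama dynamics on a 1D potential.

    dx = -beta*D*U'(x) dt + sqrt(2 D dt) xi, with U = V (+ dV when a
    :class:`BoostSpec` is given; the recorded deltaV then reports the boost
    at every kept frame). ``diffusion`` D is in A^2/ns, ``dt`` in ns.

    ``metropolis=True`` adds a Metropolis-Hastings accept/reject step
    (MALA), making the stationary distribution exactly exp(-beta*U)
    regardless of dt; plain Euler carries an O(dt) discretisation bias.

    The step size must satisfy dt < 2/(beta*D*max|U''|); violating it makes
    the Euler update unstable and raises with the suggested maximum.
    Identical seeds give bit-identical trajectories.
    """
    if n_steps < 1:
        raise ValueError("n_steps must be >= 1")
    if stride < 1:
        raise ValueError("stride must be >= 1")
    beta = 1.0 / (KB * temperature)
    curv = potential.max_curvature()
    if boost is not None:
        # the boost adds curvature up to k*(E - Vmin)*|V''| + k*V'^2 scale;
        # estimate on a grid
        lo, hi = potential.domain
        xs = np.linspace(lo, hi, 2001)
        u = np.asarray([potential.value(float(v)) + boost.deltaV(potential, float(v))
                        for v in xs])
        h = (hi - lo) / 2000
        curv = float(np.max(np.abs(np.gradient(np.gradient(u, h), h))))
    dt_max = 2.0 / (beta * diffusion * curv) if curv > 0 else np.inf
    if dt >= dt_max:
        raise ValueError(
            f"dt={dt} ns unstable for this potential; use dt < {dt_max:.3g} ns"
        )

    rng = np.random.default_rng(seed)
    if x0 is None:
        lo, hi = potential.domain
        x0 = 0.5 * (lo + hi)
    x = float(x0)
    mobility = beta * diffusion * dt
    sigma = math.sqrt(2.0 * diffusion * dt)
    total = burn_in + n_steps
    noise = rng.standard_normal(total)
    if metropolis:
        accept_u = rng.random(total)

    value = potential.value
    deriv = potential.derivative
    if boost is not None:
        b_dv = boost.deltaV
        b_dd = boost.deltaV_derivative

        def U(z: float) -> float:
            return value(z) + b_dv(potential, z)

        def dU(z: float) -> float:
            return deriv(z) + b_dd(potential, z)
    else:
        U, dU = value, deriv

    out = np.empty((n_steps + stride - 1) // stride)
    dv_out = np.empty_like(out) if boost is not None else None
    n_acc = 0
    j = 0
    fx = dU(x)
    ux = U(x)
    for i in range(total):
        prop = x - mobility * fx + sigma * noise[i]
        if metropolis:
            up = U(prop)
            fp = dU(prop)
            # MALA acceptance with asymmetric drift proposal
            fwd = (prop - x + mobility * fx) ** 2
            bwd = (x - prop + mobility * fp) ** 2
            log_alpha = -beta * (up - ux) - (bwd - fwd) / (2.0 * sigma * sigma)
            if math.log(accept_u[i] + 1e-300) < log_alpha:
                x, ux, fx = prop, up, fp
                n_acc += 1
        else:
            x = prop
            fx = dU(x)
        k = i - burn_in
        if k >= 0 and k % stride == 0:
            out[j] = x
            if dv_out is not None:
                dv_out[j] = b_dv(potential, x)
            j += 1
    series = CVSeries(name=name, values=out[:j], units=units, timestep=dt * stride)
    rate = n_acc / total if metropolis else None
    return LangevinRun(series=series, deltaV=None if dv_out is None else dv_out[:j],
                       potential=potential, boost=boost, acceptance_rate=rate)


# ---------------------------------------------------------------------------
# Correlated CV pairs
# ---------------------------------------------------------------------------


def correlated_cv_pair(rho: float, n: int, process: str = "gaussian_iid",
                       lag: float = 0.0, seed: int = 0, timestep: float = 1.0,
                       tau: float = 20.0, name_x: str = "cv_x",
                       name_y: str = "cv_y") -> Tuple[CVSeries, CVSeries]:
    """Two unit-variance CV series with population correlation ``rho``.

    ``process='gaussian_iid'`` draws i.i.d. bivariate normals;
    ``process='OU'`` draws a stationary Ornstein-Uhlenbeck pair (correlation
    time ``tau`` ns) in which y echoes x after ``lag`` ns, so the
    time-lagged correlation profile peaks at the requested lag with height
    ~rho.
    """
    if not -1.0 < rho < 1.0:
        raise ValueError("rho must lie strictly inside (-1, 1)")
    if n < 2:
        raise ValueError("n must be >= 2")
    rng = np.random.default_rng(seed)
    mix = math.sqrt(1.0 - rho * rho)
    if process == "gaussian_iid":
        if lag:
            raise ValueError("lag is only meaningful for the OU process")
        z1 = rng.standard_normal(n)
        z2 = rng.standard_normal(n)
        x, y = z1, rho * z1 + mix * z2
    elif process == "OU":
        lag_frames = int(round(lag / timestep))
        if lag_frames < 0 or (lag_frames and lag_frames >= n // 2):
            raise ValueError("lag must be non-negative and below half the duration")
        m = n + lag_frames
        phi = math.exp(-timestep / tau)
        innov = math.sqrt(1.0 - phi * phi)
        u = _ou(rng, m, phi, innov)
        w = _ou(rng, n, phi, innov)
        x = u[lag_frames:]
        y = rho * u[:n] + mix * w
    else:
        raise ValueError("process must be 'gaussian_iid' or 'OU'")
    return (
        CVSeries(name=name_x, values=x, units="A", timestep=timestep),
        CVSeries(name=name_y, values=y, units="A", timestep=timestep),
    )


def _ou(rng: np.random.Generator, n: int, phi: float, innov: float) -> np.ndarray:
    out = np.empty(n)
    out[0] = rng.standard_normal()
    eps = rng.standard_normal(n - 1)
    for i in range(1, n):
        out[i] = phi * out[i - 1] + innov * eps[i - 1]
    return out


# ---------------------------------------------------------------------------
# Toy receptor-ligand complexes
# ---------------------------------------------------------------------------


def _pocket_directions(n: int) -> np.ndarray:
    """Near-equidistant unit directions for the pose pockets.

    Keeping inter-pocket distances comparable makes the within-cluster
    variance curve decay evenly down to the planted cluster count, so the
    elbow criterion sees a single clean kink.
    """
    s = 1.0 / math.sqrt(3.0)
    fixed = {
        1: [(0.0, 0.0, 1.0)],
        2: [(0.0, 0.0, 1.0), (0.0, 0.0, -1.0)],
        3: [(1.0, 0.0, 0.0), (-0.5, math.sqrt(3) / 2, 0.0),
            (-0.5, -math.sqrt(3) / 2, 0.0)],
        4: [(s, s, s), (s, -s, -s), (-s, s, -s), (-s, -s, s)],
        5: [(0.0, 0.0, 1.0), (0.0, 0.0, -1.0), (1.0, 0.0, 0.0),
            (-0.5, math.sqrt(3) / 2, 0.0), (-0.5, -math.sqrt(3) / 2, 0.0)],
        6: [(1.0, 0.0, 0.0), (-1.0, 0.0, 0.0), (0.0, 1.0, 0.0),
            (0.0, -1.0, 0.0), (0.0, 0.0, 1.0), (0.0, 0.0, -1.0)],
    }
    if n in fixed:
        return np.asarray(fixed[n])
    # Fibonacci sphere for larger counts
    i = np.arange(n)
    phi = math.pi * (3.0 - math.sqrt(5.0)) * i
    z = 1.0 - 2.0 * (i + 0.5) / n
    r = np.sqrt(1.0 - z**2)
    return np.column_stack([r * np.cos(phi), r * np.sin(phi), z])


@dataclass(frozen=True)
class ToyComplex:
    """A scripted receptor-ligand trajectory with exact ground truth.

    ``pose_labels`` are the planted cluster memberships; ``contact_truth``
    maps internal residue index -> the set of frames in which the residue
    was placed within the contact cutoff of the ligand. Construction
    verifies the tables against the generated geometry and raises on any
    inconsistency.
    """

    trajectory: Trajectory
    receptor: ResidueGroup
    ligand: ResidueGroup
    pose_labels: np.ndarray
    pocket_centers: np.ndarray
    contact_truth: Dict[int, Set[int]]
    cutoff: float


def make_toy_complex(n_receptor_residues: int = 10, n_pose_clusters: int = 5,
                     frames_per_pose=20,
                     contact_script: Optional[Dict[int, Iterable[int]]] = None,
                     seed: int = 0, jitter: float = 0.05,
                     pocket_spacing: float = 12.0,
                     cutoff: float = 3.0) -> ToyComplex:
    """Build a toy complex with planted pose clusters and scripted contacts.

    The receptor is a row of two-atom residues; the ligand hops between
    ``n_pose_clusters`` pockets, well separated relative to the intra-pose
    coordinate jitter. ``frames_per_pose`` is an int (equal populations) or
    one count per cluster. ``contact_script`` maps a receptor residue (internal
    index) to the frames in which it must touch the ligand; in those frames
    the residue is rigidly displaced to within the cutoff of the ligand's
    central atom. Ground-truth tables are validated against the generated
    geometry before returning.
    """
    if np.isscalar(frames_per_pose):
        frame_counts = [int(frames_per_pose)] * n_pose_clusters
    else:
        frame_counts = [int(c) for c in frames_per_pose]
        if len(frame_counts) != n_pose_clusters:
            raise ValueError("need one frame count per pose cluster")
    if min([n_receptor_residues, n_pose_clusters] + frame_counts) < 1:
        raise ValueError("all size parameters must be positive")
    rng = np.random.default_rng(seed)
    n_frames = int(sum(frame_counts))
    script: Dict[int, Set[int]] = {}
    for res, frames in (contact_script or {}).items():
        fr = {int(f) for f in frames}
        if not 0 <= res < n_receptor_residues:
            raise ValueError(f"scripted residue {res} outside receptor")
        if any(f < 0 or f >= n_frames for f in fr):
            raise ValueError("scripted frame outside trajectory")
        script[int(res)] = fr

    # topology: receptor residues with CA+CB, ligand residue with 4 atoms
    atom_names: List[str] = []
    elements: List[str] = []
    residue_index: List[int] = []
    res_names: List[str] = []
    res_ids: List[int] = []
    res_chains: List[str] = []
    base = np.zeros((n_receptor_residues * 2 + 4, 3))
    for r in range(n_receptor_residues):
        res_names.append("ALA")
        res_ids.append(r + 1)
        res_chains.append("R")
        for name, el, off in (("CA", "C", (0.0, 0.0, 0.0)), ("CB", "C", (0.0, 1.5, 0.0))):
            atom_names.append(name)
            elements.append(el)
            residue_index.append(r)
            base[len(atom_names) - 1] = np.array([8.0 * r, 0.0, 0.0]) + off
    lig_res = n_receptor_residues
    res_names.append("LIG")
    res_ids.append(1)
    res_chains.append("L")
    lig_offsets = np.array([[0.0, 0.0, 0.0], [1.0, 0.0, 0.0],
                            [0.0, 1.0, 0.0], [0.0, 0.0, 1.0]])
    for i in range(4):
        atom_names.append(f"C{i + 1}")
        elements.append("C")
        residue_index.append(lig_res)
    topology = Topology(
        atom_ids=np.arange(len(atom_names)) + 1,
        atom_names=np.asarray(atom_names),
        elements=np.asarray(elements),
        residue_index=np.asarray(residue_index),
        residue_names=np.asarray(res_names),
        residue_ids=np.asarray(res_ids),
        residue_chains=np.asarray(res_chains),
    )

    hub = np.array([4.0 * (n_receptor_residues - 1), 0.0,
                    pocket_spacing + 6.0])
    pockets = hub + pocket_spacing * _pocket_directions(n_pose_clusters)
    pose_labels = np.repeat(np.arange(n_pose_clusters), frame_counts)
    coords = np.empty((n_frames, topology.n_atoms, 3))
    contact_truth: Dict[int, Set[int]] = {r: set() for r in script}
    for f in range(n_frames):
        coords[f, : n_receptor_residues * 2] = base[: n_receptor_residues * 2]
        center = pockets[pose_labels[f]] + rng.normal(0.0, jitter, 3)
        coords[f, n_receptor_residues * 2:] = center + lig_offsets
        touching = sorted(r for r, fr in script.items() if f in fr)
        for slot, r in enumerate(touching):
            theta = 2.0 * math.pi * slot / max(len(touching), 1)
            direction = np.array([math.cos(theta), math.sin(theta), -0.4])
            direction /= np.linalg.norm(direction)
            ca = center + direction * (cutoff * 0.8)
            shift = ca - base[2 * r]
            coords[f, 2 * r] = ca
            coords[f, 2 * r + 1] = base[2 * r + 1] + shift
            contact_truth[r].add(f)

    traj = Trajectory(topology=topology, coordinates=coords, timestep=1.0)
    receptor = ResidueGroup(name="receptor",
                            residue_indices=tuple(range(n_receptor_residues)),
                            atom_subset_rule="heavy_atoms")
    ligand = ResidueGroup(name="ligand", residue_indices=(lig_res,),
                          atom_subset_rule="heavy_atoms")
    _validate_toy(traj, n_receptor_residues, contact_truth, cutoff)
    return ToyComplex(trajectory=traj, receptor=receptor, ligand=ligand,
                      pose_labels=pose_labels, pocket_centers=pockets,
                      contact_truth=contact_truth, cutoff=cutoff)


def _validate_toy(traj: Trajectory, n_res: int,
                  truth: Dict[int, Set[int]], cutoff: float) -> None:
    """Brute-force check that the scripted contact table matches geometry."""
    lig = traj.coordinates[:, n_res * 2:]
    for r in range(n_res):
        res_xyz = traj.coordinates[:, 2 * r: 2 * r + 2]
        d = np.min(
            np.linalg.norm(res_xyz[:, :, None, :] - lig[:, None, :, :], axis=3),
            axis=(1, 2),
        )
        expected = truth.get(r, set())
        actual = set(np.nonzero(d <= cutoff)[0].tolist())
        if actual != expected:
            raise ValueError(
                f"contact script infeasible for residue {r}: "
                f"expected frames {sorted(expected)}, geometry gives {sorted(actual)}"
            )
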