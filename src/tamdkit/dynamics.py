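"""Langevin dynamics for the physical coordinates, with the restraint
potentials used around the channel filter: smooth flat-bottom exclusion
volumes, one-sided harmonic walls, and soft positional restraints.

The integrator is a BAOAB splitting scheme (position/velocity half-steps
with an exact Ornstein-Uhlenbeck velocity update), which is exact for the
harmonic thermostat limit and reduces to velocity Verlet at zero friction.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np

from . import _kernels
from .units import ACC, KB

logger = logging.getLogger(__name__)

_AXIS_OFFSET = {"x": 0, "y": 1, "z": 2}


@dataclass
class LangevinParams:
    """Thermostat settings: K, ps^-1, ps, amu."""

    temperature: float = 310.0
    friction: float = 1.0
    timestep: float = 0.002
    mass: float | np.ndarray | None = None  # per particle; None -> potential default
    seed: int = 0

    def __post_init__(self):
        if self.temperature < 0:
            raise ValueError("temperature must be >= 0")
        if self.timestep <= 0:
            raise ValueError("timestep must be positive")
        if self.friction < 0:
            raise ValueError("friction must be >= 0")


@dataclass
class HalfHarmonicWall:
    """One-sided quadratic confinement: E = (kappa/2)(c - bound)^2 beyond it.

    ``side='above'`` penalizes coordinates above the bound.
    """

    axis: str
    bound: float
    side: str
    kappa: float
    selection: tuple = (0,)

    def __post_init__(self):
        if self.kappa <= 0:
            raise ValueError("kappa must be positive")
        if self.side not in ("above", "below"):
            raise ValueError("side must be 'above' or 'below'")
        if self.axis not in _AXIS_OFFSET:
            raise ValueError("axis must be one of x, y, z")


@dataclass
class PositionalRestraint:
    """Soft isotropic harmonic tether of selected particles to references."""

    selection: tuple
    reference: np.ndarray  # (n_selected, dim) A
    kappa: float

    def __post_init__(self):
        if self.kappa < 0:
            raise ValueError("kappa must be >= 0")
        self.reference = np.atleast_2d(np.asarray(self.reference, dtype=float))


@dataclass
class FlatBottomExclusion:
    """Smooth flat-bottom exclusion bias over a rectangular box.

    Each excluded particle contributes k * S(x) S(y) S(z), where S is a C1
    plateau function equal to 1 on the box interior (inset by
    ``ramp_width``), 0 outside, with a cubic smoothstep ramp.  The plateau
    value k (600 kcal/mol in the filter setups) is a prohibitive barrier at
    physiological temperature.  With an empty selection the bias is a no-op.
    """

    x_min: float = -6.0
    x_max: float = 6.0
    y_min: float = -6.0
    y_max: float = 6.0
    z_min: float = -4.0
    z_max: float = 18.0
    k: float = 600.0
    ramp_width: float = 1.0
    excluded_selection: tuple = ()

    def __post_init__(self):
        for lo, hi, ax in ((self.x_min, self.x_max, "x"),
                           (self.y_min, self.y_max, "y"),
                           (self.z_min, self.z_max, "z")):
            if lo >= hi:
                raise ValueError(f"{ax}_min must be < {ax}_max")
        if self.k <= 0:
            raise ValueError("k must be positive")
        smallest = min(self.x_max - self.x_min, self.y_max - self.y_min,
                       self.z_max - self.z_min)
        if not 0 < self.ramp_width < smallest / 2:
            raise ValueError("ramp_width must be positive and smaller than "
                             "half the smallest box extent")

    @classmethod
    def tamd_box(cls, excluded_selection=()):
        """Filter exclusion volume of the accelerated runs: +-6 A in x, y
        and z in [-4, 18] A, k = 600 kcal/mol."""
        return cls(-6, 6, -6, 6, -4, 18, 600.0,
                   excluded_selection=tuple(excluded_selection))

    @classmethod
    def two_ion_md_box(cls, excluded_selection=()):
        """Exclusion volume of the two-ion confined runs: +-10 A in x, y and
        z in [-20, 25] A, k = 600 kcal/mol."""
        return cls(-10, 10, -10, 10, -20, 25, 600.0,
                   excluded_selection=tuple(excluded_selection))

    def bounds(self, axis: str):
        return {"x": (self.x_min, self.x_max), "y": (self.y_min, self.y_max),
                "z": (self.z_min, self.z_max)}[axis]


@dataclass
class Trajectory:
    """Time series of coordinates and, optionally, auxiliary/instantaneous CVs."""

    times: np.ndarray                 # (n_frames,) ps, strictly increasing
    x_frames: np.ndarray              # (n_frames, n_coords) A
    z_frames: np.ndarray | None = None      # (n_frames, M) A
    theta_frames: np.ndarray | None = None  # (n_frames, M) A
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.x_frames = np.atleast_2d(np.asarray(self.x_frames, dtype=float))
        n = len(self.times)
        if self.x_frames.shape[0] != n:
            raise ValueError("frame count mismatch between times and coordinates")
        for name in ("z_frames", "theta_frames"):
            arr = getattr(self, name)
            if arr is not None:
                arr = np.atleast_2d(np.asarray(arr, dtype=float))
                if arr.shape[0] != n:
                    raise ValueError(f"frame count mismatch in {name}")
                setattr(self, name, arr)
        if n > 1 and not np.all(np.diff(self.times) > 0):
            raise ValueError("times must be strictly increasing")

    @property
    def n_frames(self) -> int:
        return len(self.times)

    def particle_xyz(self, particle: int) -> np.ndarray:
        """(n_frames, 3) coordinates of one particle (3D layouts)."""
        return self.x_frames[:, 3 * particle:3 * particle + 3]

    def write(self, path):
        ncv = 0 if self.z_frames is None else self.z_frames.shape[1]
        cols = [self.times[:, None], self.x_frames]
        if ncv:
            cols += [self.z_frames, self.theta_frames]
        meta = json.dumps(self.metadata, default=str)
        header = (f"tamdkit trajectory\nn_coords={self.x_frames.shape[1]} "
                  f"n_cv={ncv}\nmetadata={meta}\n"
                  "columns: time_ps coords... [z... theta...]")
        np.savetxt(path, np.hstack(cols), header=header)

    @classmethod
    def read(cls, path):
        meta = {}
        ncv = 0
        with open(path) as fh:
            for line in fh:
                if not line.startswith("#"):
                    break
                body = line[1:].strip()
                if body.startswith("n_coords="):
                    parts = dict(p.split("=") for p in body.split())
                    ncv = int(parts["n_cv"])
                elif body.startswith("metadata="):
                    meta = json.loads(body[len("metadata="):])
        data = np.atleast_2d(np.loadtxt(path))
        ncoord = data.shape[1] - 1 - 2 * ncv
        return cls(times=data[:, 0], x_frames=data[:, 1:1 + ncoord],
                   z_frames=data[:, 1 + ncoord:1 + ncoord + ncv] if ncv else None,
                   theta_frames=data[:, 1 + ncoord + ncv:] if ncv else None,
                   metadata=meta)


# ----------------------------------------------------------------------
# standalone restraint energy/force operations
# ----------------------------------------------------------------------

def _as_xyz(coords) -> np.ndarray:
    arr = np.asarray(coords, dtype=float)
    if arr.ndim == 1:
        arr = arr.reshape(-1, 3)
    return arr


def exclusion_energy(coords, restraint: FlatBottomExclusion):
    """Energy and per-coordinate forces of the flat-bottom exclusion bias.

    ``coords`` is (n_particles, 3) or a flat xyz vector; the bias applies to
    ``restraint.excluded_selection``.
    """
    xyz = _as_xyz(coords)
    flat = np.ascontiguousarray(xyz.ravel())
    rows = np.array([[3.0 * p, restraint.x_min, restraint.x_max,
                      restraint.y_min, restraint.y_max,
                      restraint.z_min, restraint.z_max,
                      restraint.k, restraint.ramp_width]
                     for p in restraint.excluded_selection], dtype=float)
    rows = rows.reshape(-1, 9)
    g = np.zeros_like(flat)
    e = _kernels.restraints_eg(np.zeros((0, 4)), np.zeros((0, 3)), rows,
                               flat, g)
    return float(e), -g.reshape(xyz.shape)


def wall_energy(coords, wall: HalfHarmonicWall):
    """Energy and per-coordinate forces of a half-harmonic wall (3D layout)."""
    xyz = _as_xyz(coords)
    flat = np.ascontiguousarray(xyz.ravel())
    side = 1.0 if wall.side == "above" else -1.0
    rows = np.array([[3.0 * p + _AXIS_OFFSET[wall.axis], wall.bound, side,
                      wall.kappa] for p in wall.selection], dtype=float)
    rows = rows.reshape(-1, 4)
    g = np.zeros_like(flat)
    e = _kernels.restraints_eg(rows, np.zeros((0, 3)), np.zeros((0, 9)),
                               flat, g)
    return float(e), -g.reshape(xyz.shape)


# ----------------------------------------------------------------------
# restraint compilation against a potential's coordinate layout
# ----------------------------------------------------------------------

def _coord_index(potential, particle: int, axis: str) -> int:
    stride = potential.meta.get("stride", potential.dim_per_particle)
    if "gate_index" in potential.meta and particle == potential.n_particles - 1:
        if axis != "z":
            raise ValueError("the gate particle only has a z coordinate")
        return potential.meta["gate_index"]
    off = _AXIS_OFFSET[axis]
    if stride == 1:
        if axis != "z":
            raise ValueError("1D particles only have a z coordinate")
        return particle
    if off >= stride:
        # 2D layouts: x, y only
        raise ValueError(f"axis {axis} not present in a {stride}D layout")
    zoff = potential.meta.get("z_offset", stride - 1)
    if axis == "z":
        off = zoff
    return particle * stride + off


def compile_restraints(potential, restraints):
    """Lower restraint objects to the flat arrays the kernels consume."""
    walls, posres, excl = [], [], []
    for r in restraints or ():
        if isinstance(r, HalfHarmonicWall):
            side = 1.0 if r.side == "above" else -1.0
            for p in r.selection:
                walls.append([_coord_index(potential, p, r.axis),
                              r.bound, side, r.kappa])
        elif isinstance(r, PositionalRestraint):
            for i, p in enumerate(r.selection):
                for ax, ref in zip("xyz", r.reference[i]):
                    posres.append([_coord_index(potential, p, ax), ref,
                                   r.kappa])
        elif isinstance(r, FlatBottomExclusion):
            for p in r.excluded_selection:
                base = _coord_index(potential, p, "x")
                excl.append([base, r.x_min, r.x_max, r.y_min, r.y_max,
                             r.z_min, r.z_max, r.k, r.ramp_width])
        else:
            raise TypeError(f"unknown restraint type {type(r).__name__}")
    return (np.array(walls, dtype=float).reshape(-1, 4),
            np.array(posres, dtype=float).reshape(-1, 3),
            np.array(excl, dtype=float).reshape(-1, 9))


def _plateau_np(u, lo, hi, w):
    t_lo = np.clip((u - lo) / w, 0.0, 1.0)
    t_hi = np.clip((hi - u) / w, 0.0, 1.0)
    s = np.where(u <= lo, 0.0, np.where(u >= hi, 0.0, 1.0))
    ramp = lambda t: 3 * t ** 2 - 2 * t ** 3  # noqa: E731
    return s * ramp(t_lo) * ramp(t_hi)


def restraint_energy_batch(walls, posres, excl, X) -> np.ndarray:
    """Vectorized restraint energies for (n, n_coords) batches."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    e = np.zeros(X.shape[0])
    for i, bound, side, kap in walls:
        d = (X[:, int(i)] - bound) * side
        e += 0.5 * kap * np.maximum(d, 0.0) ** 2
    for i, ref, kap in posres:
        e += 0.5 * kap * (X[:, int(i)] - ref) ** 2
    for row in excl:
        b = int(row[0])
        k, w = row[7], row[8]
        e += k * (_plateau_np(X[:, b], row[1], row[2], w)
                  * _plateau_np(X[:, b + 1], row[3], row[4], w)
                  * _plateau_np(X[:, b + 2], row[5], row[6], w))
    return e


def _coordinate_masses(potential, params: LangevinParams) -> np.ndarray:
    if params.mass is None:
        return potential.masses()
    m = np.asarray(params.mass, dtype=float)
    if m.ndim == 0:
        return np.full(potential.n_coords, float(m))
    stride = potential.meta.get("stride", potential.dim_per_particle)
    return np.repeat(m, stride)[:potential.n_coords]


def integrate(potential, restraints, params: LangevinParams, n_steps: int,
              save_every: int = 1, x0=None, v0=None) -> Trajectory:
    """Evolve coordinates under potential + restraints with a Langevin
    thermostat.  Identical inputs and seed give bit-identical trajectories.
    """
    n = potential.n_coords
    x0 = np.zeros(n) if x0 is None else np.asarray(x0, dtype=float).ravel().copy()
    v0 = np.zeros(n) if v0 is None else np.asarray(v0, dtype=float).ravel().copy()
    walls, posres, excl = compile_restraints(potential, restraints)
    mass = _coordinate_masses(potential, params)
    kT = KB * params.temperature

    if potential.kind is not None:
        W = np.zeros((0, n))
        times, xs, zs, thetas, status, n_saved = _kernels.run_dynamics(
            potential.kind, potential.params, x0, v0, mass, kT,
            params.friction, params.timestep, n_steps, save_every,
            walls, posres, excl,
            False, W, np.zeros(0), 0.0, 1.0, 0.0, np.inf, params.seed)
        _raise_on_status(status, times)
    else:
        times, xs, _, _ = _python_loop(
            potential, walls, posres, excl, x0, v0, mass, kT, params,
            n_steps, save_every)
        status = _kernels.STATUS_OK
    meta = {"temperature_K": params.temperature, "friction_per_ps":
            params.friction, "timestep_ps": params.timestep,
            "seed": params.seed, "potential": potential.label}
    logger.info("integrate: %d steps of %s, %d frames saved", n_steps,
                potential.label, len(times))
    return Trajectory(times=times, x_frames=xs, metadata=meta)


def _raise_on_status(status, times):
    if status == _kernels.STATUS_ENERGY_OVERFLOW:
        t = times[-1] if len(times) else 0.0
        raise RuntimeError(f"energy exceeded 1e8 kcal/mol near t={t} ps; "
                           "check the timestep and restraint stiffness")
    if status == _kernels.STATUS_CV_DIVERGENCE:
        t = times[-1] if len(times) else 0.0
        raise RuntimeError(f"auxiliary variable diverged from its CV near "
                           f"t={t} ps")


def _python_loop(potential, walls, posres, excl, x, v, mass, kT, params,
                 n_steps, save_every, theta_fn=None, jac_fn=None, z=None,
                 kappa=0.0, gamma_bar=1.0, kT_bar=0.0):
    """Pure-Python BAOAB loop for custom potentials or custom CVs."""
    rng = np.random.default_rng(params.seed)
    dt = params.timestep
    c1 = np.exp(-params.friction * dt)
    sig = np.sqrt(kT * ACC / mass) * np.sqrt(max(0.0, 1.0 - c1 * c1))
    tamd_on = theta_fn is not None
    if tamd_on:
        z = np.asarray(z, dtype=float).copy()
        z_step = dt / gamma_bar
        z_noise = np.sqrt(2.0 * kT_bar * dt / gamma_bar)

    def total_grad(x):
        g = potential.gradient(x).astype(float).copy()
        gr = np.zeros_like(g)
        _kernels.restraints_eg(walls, posres, excl, x, gr)
        g += gr
        if tamd_on:
            th = np.asarray(theta_fn(x), dtype=float)
            J = np.asarray(jac_fn(x), dtype=float)
            g += kappa * (th - z) @ J
        return g

    g = total_grad(x)
    n_saved = n_steps // save_every
    times = np.empty(n_saved)
    xs = np.empty((n_saved, len(x)))
    M = len(z) if tamd_on else 0
    zs = np.empty((n_saved, M))
    thetas = np.empty((n_saved, M))
    frame = 0
    for step in range(n_steps):
        v -= 0.5 * dt * g * ACC / mass
        x += 0.5 * dt * v
        v = c1 * v + sig * rng.standard_normal(len(x))
        x += 0.5 * dt * v
        if tamd_on:
            th = np.asarray(theta_fn(x), dtype=float)
            z += z_step * kappa * (th - z) + z_noise * rng.standard_normal(M)
        g = total_grad(x)
        v -= 0.5 * dt * g * ACC / mass
        if (step + 1) % save_every == 0:
            times[frame] = (step + 1) * dt
            xs[frame] = x
            if tamd_on:
                zs[frame] = z
                thetas[frame] = theta_fn(x)
            frame += 1
    return times, xs, zs, thetas
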