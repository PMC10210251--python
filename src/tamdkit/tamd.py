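"""Temperature-accelerated molecular dynamics (TAMD).

Auxiliary variables z are tethered by springs of stiffness kappa to the
collective variables theta(x) and evolve overdamped at an artificial
temperature 1/beta_bar:

    gamma_bar dz_j/dt = kappa (theta_j(x) - z_j) + sqrt(2 gamma_bar / beta_bar) eta_j

With kappa large enough that z tracks theta and gamma_bar large enough that
z is slow, z moves at the artificial temperature on the free-energy surface
computed at the *physical* temperature, and the instantaneous spring forces
kappa (theta - z) are the samples from which the surface is reconstructed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from . import _kernels
from .dynamics import (LangevinParams, Trajectory, _coordinate_masses,
                       _python_loop, _raise_on_status, compile_restraints)
from .units import KB

logger = logging.getLogger(__name__)


@dataclass
class CollectiveVariableMap:
    """Linear (or custom) map from full coordinates to M CV values.

    For the built-in kinds the map is theta(x) = W x with a constant sparse
    weight matrix W, which is also the linear response used to project
    spring forces back onto the particles.
    """

    kind: str                     # coordinate_z | com_z | custom
    selections: tuple = ()        # per CV: tuple of flat coordinate indices
    M: int = 1
    theta_fn: object = None
    jacobian_fn: object = None

    @classmethod
    def coordinate_z(cls, potential, particles):
        """One CV per particle: its z coordinate (the gate particle's only
        coordinate counts as z)."""
        idx = tuple((_z_index(potential, p),) for p in particles)
        return cls(kind="coordinate_z", selections=idx, M=len(idx))

    @classmethod
    def com_z(cls, potential, particles):
        """Single CV: equal-weight z center of mass of the selection."""
        idx = tuple(_z_index(potential, p) for p in particles)
        return cls(kind="com_z", selections=(idx,), M=1)

    @classmethod
    def custom(cls, theta_fn, jacobian_fn=None, M=1):
        return cls(kind="custom", theta_fn=theta_fn, jacobian_fn=jacobian_fn,
                   M=M)

    @property
    def is_linear(self) -> bool:
        return self.kind in ("coordinate_z", "com_z")

    def weight_matrix(self, n_coords: int) -> np.ndarray:
        if not self.is_linear:
            raise ValueError("custom CVs have no constant weight matrix")
        W = np.zeros((self.M, n_coords))
        for j, sel in enumerate(self.selections):
            for i in sel:
                W[j, i] = 1.0 / len(sel)  # com weights sum to 1
        return W

    def theta(self, x) -> np.ndarray:
        x = np.asarray(x, dtype=float).ravel()
        if self.is_linear:
            return self.weight_matrix(len(x)) @ x
        return np.atleast_1d(np.asarray(self.theta_fn(x), dtype=float))

    def jacobian(self, x) -> np.ndarray:
        x = np.asarray(x, dtype=float).ravel()
        if self.is_linear:
            return self.weight_matrix(len(x))
        if self.jacobian_fn is not None:
            return np.atleast_2d(np.asarray(self.jacobian_fn(x), dtype=float))
        J = np.empty((self.M, len(x)))
        h = 1e-7
        for i in range(len(x)):
            xp, xm = x.copy(), x.copy()
            xp[i] += h
            xm[i] -= h
            J[:, i] = (self.theta(xp) - self.theta(xm)) / (2 * h)
        return J


def _z_index(potential, particle: int) -> int:
    if "gate_index" in potential.meta and particle == potential.n_particles - 1:
        return potential.meta["gate_index"]
    return potential.z_index(particle)


@dataclass
class TamdParams:
    """Extended-system settings.

    Defaults follow the accelerated filter runs: spring 1500 kcal/mol/A^2,
    auxiliary friction 800 (kcal/mol) ps/A^2, auxiliary temperature 6000 K.
    """

    kappa: float = 1500.0
    gamma_bar: float = 800.0
    T_bar: float = 6000.0
    physical: LangevinParams = field(default_factory=LangevinParams)
    z_init: np.ndarray | None = None
    z_walls: tuple = ()  # HalfHarmonicWall applied to the confined particles
    seed: int | None = None

    def __post_init__(self):
        if self.kappa <= 0:
            raise ValueError("kappa must be positive")
        if self.gamma_bar <= 0:
            raise ValueError("gamma_bar must be positive")
        if self.T_bar < self.physical.temperature:
            raise ValueError("T_bar must be >= the physical temperature")
        if self.seed is None:
            self.seed = self.physical.seed


def extended_energy(x, z, potential, cv: CollectiveVariableMap,
                    kappa: float) -> float:
    """V(x) + (kappa/2) sum_j (theta_j(x) - z_j)^2."""
    z = np.atleast_1d(np.asarray(z, dtype=float))
    d = cv.theta(x) - z
    return potential.energy(x) + 0.5 * kappa * float(d @ d)


def tamd_run(potential, cv: CollectiveVariableMap, params: TamdParams,
             restraints=(), n_steps: int = 100000, save_every: int = 1,
             x0=None, v0=None) -> Trajectory:
    """Run the coupled extended dynamics; the trajectory stores x, z and
    theta(x) per saved frame.

    z is initialized at theta(x0) unless ``params.z_init`` is given.  The
    confinement walls in ``params.z_walls`` act on the physical particles
    defining the CVs (z then stays in range by tethering).
    """
    n = potential.n_coords
    x0 = np.zeros(n) if x0 is None else np.asarray(x0, dtype=float).ravel().copy()
    v0 = np.zeros(n) if v0 is None else np.asarray(v0, dtype=float).ravel().copy()
    all_restraints = tuple(restraints or ()) + tuple(params.z_walls)
    walls, posres, excl = compile_restraints(potential, all_restraints)
    phys = params.physical
    mass = _coordinate_masses(potential, phys)
    kT = KB * phys.temperature
    kT_bar = KB * params.T_bar
    z0 = cv.theta(x0) if params.z_init is None else \
        np.atleast_1d(np.asarray(params.z_init, dtype=float)).copy()
    extent = float(np.max(potential.quad_bounds[:, 1]
                          - potential.quad_bounds[:, 0]))
    z_div_limit = 10.0 * extent

    if potential.kind is not None and cv.is_linear:
        W = np.ascontiguousarray(cv.weight_matrix(n))
        times, xs, zs, thetas, status, n_saved = _kernels.run_dynamics(
            potential.kind, potential.params, x0, v0, mass, kT,
            phys.friction, phys.timestep, n_steps, save_every,
            walls, posres, excl,
            True, W, z0, params.kappa, params.gamma_bar, kT_bar,
            z_div_limit, params.seed)
        _raise_on_status(status, times)
    else:
        seeded = LangevinParams(phys.temperature, phys.friction,
                                phys.timestep, phys.mass, params.seed)
        times, xs, zs, thetas = _python_loop(
            potential, walls, posres, excl, x0, v0, mass, kT, seeded,
            n_steps, save_every, theta_fn=cv.theta, jac_fn=cv.jacobian,
            z=z0, kappa=params.kappa, gamma_bar=params.gamma_bar,
            kT_bar=kT_bar)
    meta = {"kappa": params.kappa, "gamma_bar": params.gamma_bar,
            "T_bar_K": params.T_bar, "temperature_K": phys.temperature,
            "timestep_ps": phys.timestep, "seed": params.seed,
            "potential": potential.label, "cv_kind": cv.kind}
    logger.info("tamd_run: %d steps, %d frames, kappa=%g T_bar=%g",
                n_steps, len(times), params.kappa, params.T_bar)
    return Trajectory(times=times, x_frames=xs, z_frames=zs,
                      theta_frames=thetas, metadata=meta)


def mean_force_samples(traj: Trajectory, kappa: float) -> np.ndarray:
    """Instantaneous spring-force samples kappa (theta(x_t) - z_t).

    Their conditional average at fixed z converges to -grad G(z) as
    kappa -> infinity; they point from z toward theta(x).
    """
    if traj.z_frames is None or traj.theta_frames is None:
        raise ValueError("trajectory lacks auxiliary (z) or instantaneous "
                         "(theta) CV frames")
    return kappa * (traj.theta_frames - traj.z_frames)
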