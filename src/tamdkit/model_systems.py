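"""Synthetic model systems with known free-energy structure.

Every downstream stage (Langevin dynamics, TAMD, OTFP reconstruction, the
string method, occupancy analyses) is exercised against the potentials
defined here, whose marginal free energies are available either in closed
form or by deterministic quadrature.  Energies are kcal/mol, lengths are
Angstrom throughout.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import null_space
from scipy.special import logsumexp

from . import _kernels
from .units import KB

logger = logging.getLogger(__name__)

MASS_SODIUM = 22.989769  # amu
MASS_GATE = 14.007       # amu, nitrogen-like gate particle


@dataclass
class ModelPotential:
    """Differentiable energy over a flat coordinate vector.

    ``kind``/``params`` select a compiled kernel; custom potentials instead
    provide ``energy_fn``/``gradient_fn`` (the latter may be ``None`` to fall
    back on central finite differences).  ``quad_bounds`` declares, per
    coordinate, the domain on which the Boltzmann weight is negligible
    outside — the quadrature oracle integrates over these boxes.
    """

    label: str
    n_particles: int
    dim_per_particle: int
    n_coords: int
    kind: int | None = None
    params: np.ndarray | None = None
    energy_fn: object = None
    gradient_fn: object = None
    quad_bounds: np.ndarray | None = None
    default_masses: np.ndarray | None = None
    meta: dict = field(default_factory=dict)

    def energy(self, x) -> float:
        x = np.asarray(x, dtype=float).ravel()
        if self.kind is not None:
            g = np.empty(self.n_coords)
            return float(_kernels.pot_eg(self.kind, self.params, x, g))
        return float(self.energy_fn(x))

    def gradient(self, x) -> np.ndarray:
        x = np.asarray(x, dtype=float).ravel()
        if self.kind is not None:
            g = np.empty(self.n_coords)
            _kernels.pot_eg(self.kind, self.params, x, g)
            return g
        if self.gradient_fn is not None:
            return np.asarray(self.gradient_fn(x), dtype=float)
        return _fd_gradient(self.energy, x)

    def energy_batch(self, X) -> np.ndarray:
        X = np.ascontiguousarray(X, dtype=float)
        if "energy_batch_fn" in self.meta:
            return self.meta["energy_batch_fn"](X)
        if self.kind is not None:
            return _kernels.pot_energy_batch(self.kind, self.params, X)
        return np.array([self.energy_fn(row) for row in X])

    # --- coordinate layout helpers -------------------------------------
    def z_index(self, particle: int = 0) -> int:
        """Flat index of the z coordinate of a particle."""
        if self.dim_per_particle == 3:
            return 3 * particle + 2
        return particle * self.dim_per_particle

    @property
    def gate_index(self) -> int:
        if "gate_index" not in self.meta:
            raise AttributeError(f"{self.label} has no gate particle")
        return self.meta["gate_index"]

    def masses(self) -> np.ndarray:
        if self.default_masses is not None:
            return self.default_masses.copy()
        return np.full(self.n_coords, MASS_SODIUM)


@dataclass
class MarginalFEOracle:
    """Reference marginal free energy G(z) along a CV, min-shifted to zero."""

    cv_grid: tuple  # tuple of per-CV node arrays (len 1 or 2)
    fe_values: np.ndarray  # (n1,) or (n1, n2), kcal/mol
    beta: float  # mol/kcal
    method: str  # analytic | quadrature | histogram
    converged: bool = True

    def minima(self):
        """Grid-local minima as (coords, value) sorted by value."""
        fe = self.fe_values
        out = []
        if fe.ndim == 1:
            for i in range(1, fe.shape[0] - 1):
                if fe[i] <= fe[i - 1] and fe[i] <= fe[i + 1] and (
                        fe[i] < fe[i - 1] or fe[i] < fe[i + 1]):
                    out.append((np.array([self.cv_grid[0][i]]), fe[i]))
        else:
            for i in range(1, fe.shape[0] - 1):
                for j in range(1, fe.shape[1] - 1):
                    v = fe[i, j]
                    if (v < fe[i - 1, j] and v < fe[i + 1, j]
                            and v < fe[i, j - 1] and v < fe[i, j + 1]):
                        out.append((np.array([self.cv_grid[0][i],
                                              self.cv_grid[1][j]]), v))
        return sorted(out, key=lambda t: t[1])

    def with_spring_tether(self, kappa: float) -> "MarginalFEOracle":
        """Free energy of an auxiliary variable tethered to the CV.

        A harmonic tether of stiffness kappa samples the marginal of the
        auxiliary z, exp(-beta G_z) = exp(-beta G) * N(0, 1/(beta kappa))
        (a Gaussian convolution of the Boltzmann factor; for a quadratic G
        of curvature k this is exactly the softened curvature
        k*kappa/(k+kappa)).  This is the reference against which a
        spring-coupled estimate of G should be compared.
        """
        from scipy.interpolate import CubicSpline

        sigma = np.sqrt(1.0 / (self.beta * kappa))
        fine_step = sigma / 4.0
        fe = self.fe_values.copy()
        axes = [np.asarray(a) for a in self.cv_grid]
        # blur each CV axis in turn: dense quadrature of the convolution on
        # a spline-refined axis (a truncated filter would miss the shifted
        # integrand peak where the surface is much stiffer than the tether)
        for d in range(fe.ndim):
            ax = axes[d]
            pad = 8.0 * sigma
            fine = np.arange(ax[0] - pad, ax[-1] + pad + fine_step / 2,
                             fine_step)
            kernel = np.exp(-0.5 * ((ax[:, None] - fine[None, :]) / sigma) ** 2)
            kernel *= fine_step / (sigma * np.sqrt(2 * np.pi))
            fe = np.moveaxis(fe, d, -1)
            shape = fe.shape
            flat = fe.reshape(-1, shape[-1])
            out = np.empty_like(flat)
            for r in range(flat.shape[0]):
                spl = CubicSpline(ax, flat[r])
                ref = flat[r].min()
                w = np.exp(-self.beta * (spl(fine) - ref))
                out[r] = -np.log(np.maximum(kernel @ w, 1e-300)) \
                    / self.beta + ref
            fe = np.moveaxis(out.reshape(shape), -1, d)
        fe -= fe.min()
        return MarginalFEOracle(cv_grid=self.cv_grid, fe_values=fe,
                                beta=self.beta, method=self.method + "+tether",
                                converged=self.converged)

    def write(self, path):
        """2-column (1D) or 3-column (2D) delimited table with a comment header."""
        with open(path, "w") as fh:
            fh.write(f"# marginal free energy table (kcal/mol)\n"
                     f"# beta = {self.beta!r} mol/kcal\n"
                     f"# method = {self.method}\n")
            if self.fe_values.ndim == 1:
                for zv, fv in zip(self.cv_grid[0], self.fe_values):
                    fh.write(f"{zv:.8g}\t{fv:.8g}\n")
            else:
                for i, zx in enumerate(self.cv_grid[0]):
                    for j, zy in enumerate(self.cv_grid[1]):
                        fh.write(f"{zx:.8g}\t{zy:.8g}\t{self.fe_values[i, j]:.8g}\n")


def _fd_gradient(fn, x, h=1e-5):
    g = np.empty(x.shape[0])
    for i in range(x.shape[0]):
        xp = x.copy()
        xm = x.copy()
        xp[i] += h
        xm[i] -= h
        g[i] = (fn(xp) - fn(xm)) / (2 * h)
    return g


def check_gradient(potential: ModelPotential, n_points: int = 20,
                   rtol: float = 1e-5, seed: int = 0) -> float:
    """Max relative deviation between analytic gradient and central FD."""
    rng = np.random.default_rng(seed)
    lo = potential.quad_bounds[:, 0]
    hi = potential.quad_bounds[:, 1]
    worst = 0.0
    for _ in range(n_points):
        x = lo + (hi - lo) * rng.random(potential.n_coords)
        ga = potential.gradient(x)
        gf = _fd_gradient(potential.energy, x)
        scale = max(np.max(np.abs(ga)), 1.0)
        worst = max(worst, float(np.max(np.abs(ga - gf)) / scale))
    if worst > rtol:
        raise ValueError(
            f"gradient/finite-difference mismatch {worst:.2e} for {potential.label}")
    return worst


# ----------------------------------------------------------------------
# factory operations
# ----------------------------------------------------------------------

def make_harmonic(k: float = 2.0) -> ModelPotential:
    """1-particle 1D harmonic well V = (k/2) x^2."""
    if k <= 0:
        raise ValueError("k must be positive")
    span = 8.0 / np.sqrt(k)
    return ModelPotential(
        label=f"harmonic(k={k:g})", n_particles=1, dim_per_particle=1,
        n_coords=1, kind=_kernels.KIND_HARMONIC, params=np.array([k]),
        quad_bounds=np.array([[-span, span]]),
        default_masses=np.array([MASS_SODIUM]))


def make_double_well(height: float = 6.0, half_separation: float = 2.0,
                     transverse_stiffness: float = 1.0) -> ModelPotential:
    """Quartic double well with a harmonic transverse coordinate.

    V(x, y) = height * ((x/half_separation)^2 - 1)^2
              + (transverse_stiffness/2) * y^2

    The marginal free energy along x equals the x-term up to an additive
    constant at any temperature, because y integrates out independently.
    """
    if height <= 0 or half_separation <= 0 or transverse_stiffness <= 0:
        raise ValueError("height, half_separation and transverse_stiffness "
                         "must be positive")
    a = half_separation
    return ModelPotential(
        label=f"double_well(h={height:g},a={a:g})", n_particles=1,
        dim_per_particle=2, n_coords=2, kind=_kernels.KIND_DOUBLE_WELL,
        params=np.array([height, a, transverse_stiffness]),
        quad_bounds=np.array([[-3.0 * a, 3.0 * a],
                              [-8.0 / np.sqrt(transverse_stiffness),
                               8.0 / np.sqrt(transverse_stiffness)]]),
        default_masses=np.full(2, MASS_SODIUM),
        meta={"barrier": height, "minima": (-a, a)})


#: Constants of the standard four-Gaussian 2D benchmark surface.
BENCHMARK_CONSTANTS = {
    "A": (-200.0, -100.0, -170.0, 15.0),
    "a": (-1.0, -1.0, -6.5, 0.7),
    "b": (0.0, 0.0, 11.0, 0.6),
    "c": (-10.0, -10.0, -6.5, 0.7),
    "x0": (1.0, 0.0, -0.5, -1.0),
    "y0": (0.0, 0.5, 1.5, 1.0),
}

#: Domain on which the benchmark surface is conventionally studied.
BENCHMARK_BOUNDS = np.array([[-1.7, 1.3], [-0.5, 2.2]])


def make_benchmark_surface() -> ModelPotential:
    """The conventional four-Gaussian 2D benchmark potential.

    Three minima and two saddles; the standard published constants are
    echoed in ``meta['constants']`` for config/log output.  (Energy units
    follow the published convention; lengths are treated as Angstrom.)
    """
    return ModelPotential(
        label="benchmark_surface", n_particles=1, dim_per_particle=2,
        n_coords=2, kind=_kernels.KIND_MUELLER_BROWN, params=np.zeros(1),
        quad_bounds=BENCHMARK_BOUNDS.copy(),
        default_masses=np.full(2, MASS_SODIUM),
        meta={"constants": BENCHMARK_CONSTANTS})


def make_toy_filter(n_ions: int = 1,
                    well_centers=(5.0, 12.0),
                    well_depths=3.0,
                    radius: float = 3.0,
                    gate_coupling: float = 1.5,
                    *,
                    well_sigma: float = 1.0,
                    gate_height: float = 2.0,
                    gate_half_width: float = 1.0,
                    repulsion: float = 20.0,
                    repulsion_width: float = 2.0,
                    z_domain=(-2.0, 22.0),
                    domain_k: float = 10.0,
                    radial_k: float = 10.0,
                    axial: bool = False) -> ModelPotential:
    """Toy conductivity/selectivity-filter surrogate.

    ``n_ions`` ions move in a cylinder of the given radius with Gaussian
    wells at ``well_centers`` along z (the metastable binding sites), an
    axial pairwise repulsion, and a 1D "gate" particle — a stand-in for a
    charged side chain reaching into the pore — whose double-well coordinate
    is bilinearly coupled to the mean ion z.  With ``gate_coupling = 0`` the
    joint (ion-z, gate) free energy factorizes exactly.

    ``axial=True`` restricts ions to their z coordinate (quasi-1D channel),
    which keeps the quadrature oracle feasible for two-ion CVs.
    """
    centers = np.atleast_1d(np.asarray(well_centers, dtype=float))
    depths = np.broadcast_to(np.asarray(well_depths, dtype=float),
                             centers.shape).astype(float)
    if n_ions not in (1, 2):
        raise ValueError("n_ions must be 1 or 2")
    z_lo, z_hi = float(z_domain[0]), float(z_domain[1])
    if np.any(centers < z_lo) or np.any(centers > z_hi):
        raise ValueError("well centers must lie inside the z domain")
    if np.any(depths <= 0):
        raise ValueError("well depths must be positive")
    sep = np.abs(np.subtract.outer(centers, centers))
    iu = np.triu_indices(len(centers), k=1)
    if len(centers) > 1 and np.min(sep[iu]) < 0.5:
        raise ValueError("well centers closer than 0.5 A are rejected")

    z_mid = float(np.mean(centers))
    z_scale = max(1.0, (np.max(centers) - np.min(centers)) / 2.0)
    params = np.concatenate([
        [n_ions, len(centers), radius, radial_k, gate_coupling,
         gate_height, gate_half_width, z_mid, z_scale, well_sigma,
         repulsion, repulsion_width, z_lo, z_hi, domain_k],
        centers, depths])

    stride = 1 if axial else 3
    n_coords = n_ions * stride + 1
    kind = _kernels.KIND_TOY_FILTER_AXIAL if axial else _kernels.KIND_TOY_FILTER
    bounds = []
    masses = []
    for _ in range(n_ions):
        if not axial:
            bounds += [[-radius - 3, radius + 3], [-radius - 3, radius + 3]]
            masses += [MASS_SODIUM, MASS_SODIUM]
        bounds += [[z_lo - 2, z_hi + 2]]
        masses += [MASS_SODIUM]
    gspan = 3.0 * gate_half_width
    bounds += [[-gspan, gspan]]
    masses += [MASS_GATE]

    return ModelPotential(
        label=f"toy_filter(n_ions={n_ions}{',axial' if axial else ''})",
        n_particles=n_ions + 1,
        dim_per_particle=1 if axial else 3,
        n_coords=n_coords, kind=kind, params=params,
        quad_bounds=np.array(bounds, dtype=float),
        default_masses=np.array(masses),
        meta={"gate_index": n_ions * stride, "axial": axial,
              "well_centers": centers, "well_depths": depths,
              "z_domain": (z_lo, z_hi), "stride": stride, "z_offset":
              0 if axial else 2})


# ----------------------------------------------------------------------
# quadrature marginal free-energy oracle
# ----------------------------------------------------------------------

def _as_weight_matrix(cv, n_coords: int) -> np.ndarray:
    if hasattr(cv, "weight_matrix"):
        return np.asarray(cv.weight_matrix(n_coords), dtype=float)
    W = np.atleast_2d(np.asarray(cv, dtype=float))
    if W.shape[1] != n_coords:
        raise ValueError("CV weight matrix has wrong coordinate count")
    return W


def _trapz_logweights(axes):
    """Log of the product-trapezoid weights on a tensor grid."""
    logw = np.zeros([len(ax) for ax in axes])
    for d, ax in enumerate(axes):
        w = np.full(len(ax), ax[1] - ax[0] if len(ax) > 1 else 1.0)
        if len(ax) > 1:
            w[0] *= 0.5
            w[-1] *= 0.5
        shape = [1] * len(axes)
        shape[d] = len(ax)
        logw = logw + np.log(w).reshape(shape)
    return logw.ravel()


def _fe_on_grid(potential, W, beta, cv_points, n_quad):
    """-1/beta log integral over the affine subspace {x : Wx = z}."""
    n = potential.n_coords
    M = W.shape[0]
    coord_aligned = all(
        np.count_nonzero(W[j]) == 1 and
        np.isclose(W[j][np.nonzero(W[j])[0][0]], 1.0)
        for j in range(M))
    if coord_aligned:
        fixed = [int(np.nonzero(W[j])[0][0]) for j in range(M)]
        free = [i for i in range(n) if i not in fixed]
        if len(free) > 3:
            raise ValueError("quadrature needs <= 3 non-CV coordinates")
        axes = [np.linspace(*potential.quad_bounds[i], n_quad) for i in free]
        mesh = np.meshgrid(*axes, indexing="ij") if axes else []
        base = np.empty((int(np.prod([len(a) for a in axes])) or 1, n))
        for d, i in enumerate(free):
            base[:, i] = mesh[d].ravel()
        logw = _trapz_logweights(axes) if axes else np.zeros(1)
        out = np.empty(cv_points.shape[0])
        for p, zv in enumerate(cv_points):
            X = base.copy()
            for j, i in enumerate(fixed):
                X[:, i] = zv[j]
            E = potential.energy_batch(X)
            out[p] = -logsumexp(-beta * E + logw) / beta
        return out
    # general linear CV: parametrize the null space of W; the u-box is the
    # projection (support function) of the coordinate-bounds box
    N = null_space(W)
    if N.shape[1] > 3:
        raise ValueError("quadrature needs <= 3 non-CV coordinates")
    Wp = np.linalg.pinv(W)
    lo = potential.quad_bounds[:, 0]
    hi = potential.quad_bounds[:, 1]
    u_lo_box = np.where(N > 0, lo[:, None], hi[:, None])
    u_hi_box = np.where(N > 0, hi[:, None], lo[:, None])
    out = np.empty(cv_points.shape[0])
    for p, zv in enumerate(cv_points):
        base = Wp @ zv
        axes = [np.linspace(np.sum(N[:, i] * (u_lo_box[:, i])) - N[:, i] @ base,
                            np.sum(N[:, i] * (u_hi_box[:, i])) - N[:, i] @ base,
                            n_quad)
                for i in range(N.shape[1])]
        mesh = np.meshgrid(*axes, indexing="ij")
        U = np.stack([m.ravel() for m in mesh], axis=1)
        logw = _trapz_logweights(axes)
        X = base[None, :] + U @ N.T
        E = potential.energy_batch(X)
        out[p] = -logsumexp(-beta * E + logw) / beta
    return out


def marginal_fe_oracle(potential: ModelPotential, cv, beta: float, grid,
                       n_quad: int = 41,
                       refine_tol: float = 1e-3) -> MarginalFEOracle:
    """Deterministic-quadrature marginal free energy along a linear CV.

    G(z) = -(1/beta) ln integral exp(-beta U(x)) delta(theta(x) - z) dx,
    min-shifted to zero.  ``cv`` is a CollectiveVariableMap or a weight
    matrix; the non-CV coordinate count must be at most 3.  Convergence is
    verified by doubling the quadrature resolution; non-convergence is
    reported via a warning and ``converged=False``.
    """
    W = _as_weight_matrix(cv, potential.n_coords)
    if isinstance(grid, (tuple, list)) and np.ndim(grid[0]) >= 1:
        axes = [np.asarray(g, dtype=float) for g in grid]
    else:
        axes = [np.asarray(grid, dtype=float)]
    if len(axes) != W.shape[0]:
        raise ValueError("grid dimensionality must match the number of CVs")
    mesh = np.meshgrid(*axes, indexing="ij")
    cv_points = np.stack([m.ravel() for m in mesh], axis=1)

    fe = _fe_on_grid(potential, W, beta, cv_points, n_quad)
    fe_ref = _fe_on_grid(potential, W, beta, cv_points, 2 * n_quad - 1)
    shift = lambda v: v - np.min(v)  # noqa: E731
    drift = float(np.max(np.abs(shift(fe) - shift(fe_ref))))
    converged = drift < refine_tol
    if not converged:
        warnings.warn(f"quadrature not converged: refinement changed the "
                      f"profile by {drift:.3g} kcal/mol")
    fe = shift(fe_ref).reshape([len(a) for a in axes])
    if fe.ndim == 1:
        fe = fe.ravel()
    return MarginalFEOracle(cv_grid=tuple(axes), fe_values=fe, beta=beta,
                            method="quadrature", converged=converged)


# ----------------------------------------------------------------------
# dense-grid search oracles (used to validate the string method)
# ----------------------------------------------------------------------

def grid_energies(potential: ModelPotential, bounds=None, n: int = 1000):
    """Energies of a 2D potential on an n x n grid; returns (gx, gy, E)."""
    if bounds is None:
        bounds = potential.quad_bounds
    gx = np.linspace(bounds[0][0], bounds[0][1], n)
    gy = np.linspace(bounds[1][0], bounds[1][1], n)
    X, Y = np.meshgrid(gx, gy, indexing="ij")
    pts = np.stack([X.ravel(), Y.ravel()], axis=1)
    E = potential.energy_batch(pts).reshape(n, n)
    return gx, gy, E


def grid_minima(potential: ModelPotential, bounds=None, n: int = 1000,
                min_separation: float | None = None):
    """Local minima of a 2D potential on a dense grid, sorted by energy.

    Candidates closer than ``min_separation`` (default: 10 grid cells) are
    merged onto the lowest one, which suppresses float-level plateau
    duplicates around each true minimum.
    """
    gx, gy, E = grid_energies(potential, bounds, n)
    if min_separation is None:
        min_separation = 10.0 * max(gx[1] - gx[0], gy[1] - gy[0])
    interior = E[1:-1, 1:-1]
    is_min = ((interior <= E[:-2, 1:-1]) & (interior <= E[2:, 1:-1])
              & (interior <= E[1:-1, :-2]) & (interior <= E[1:-1, 2:]))
    ii, jj = np.nonzero(is_min)
    cands = sorted(((np.array([gx[i + 1], gy[j + 1]]),
                     float(E[i + 1, j + 1])) for i, j in zip(ii, jj)),
                   key=lambda t: t[1])
    out = []
    for xy, e in cands:
        if all(np.linalg.norm(xy - kept_xy) > min_separation
               for kept_xy, _ in out):
            out.append((xy, e))
    return out


def grid_minimax_saddle(potential: ModelPotential, point_a, point_b,
                        bounds=None, n: int = 1000):
    """Bottleneck saddle between two basins, by grid flooding (minimax).

    Returns (saddle_xy, saddle_energy): the highest point of the best
    (lowest-maximum) 4-connected grid path between the cells containing
    ``point_a`` and ``point_b``.
    """
    gx, gy, E = grid_energies(potential, bounds, n)

    def flat(p):
        i = int(np.clip(np.searchsorted(gx, p[0]), 1, n - 1))
        j = int(np.clip(np.searchsorted(gy, p[1]), 1, n - 1))
        if abs(gx[i - 1] - p[0]) < abs(gx[i] - p[0]):
            i -= 1
        if abs(gy[j - 1] - p[1]) < abs(gy[j] - p[1]):
            j -= 1
        return i * n + j

    Ef = np.ascontiguousarray(E.ravel())
    order = np.argsort(Ef, kind="stable")
    idx, e = _kernels.minimax_saddle(Ef, n, n, order, flat(point_a),
                                     flat(point_b))
    if idx < 0:
        raise RuntimeError("flooding failed to connect the two basins")
    return np.array([gx[idx // n], gy[idx % n]]), float(e)


# ----------------------------------------------------------------------
# plain-text configuration
# ----------------------------------------------------------------------

_FACTORIES = {
    "harmonic": make_harmonic,
    "double_well": make_double_well,
    "benchmark_surface": make_benchmark_surface,
    "toy_filter": make_toy_filter,
}


def parse_config(text: str) -> dict:
    """Parse a plain-text ``key = value`` config (``#`` starts a comment).

    Values are parsed as int, float, bool, comma-separated number lists, or
    left as strings.
    """
    out = {}
    for raw in text.splitlines():
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise ValueError(f"malformed config line: {raw!r}")
        key, val = (s.strip() for s in line.split("=", 1))
        if "," in val:
            out[key] = tuple(float(v) for v in val.split(","))
            continue
        for cast in (int, float):
            try:
                out[key] = cast(val)
                break
            except ValueError:
                continue
        else:
            out[key] = {"true": True, "false": False}.get(val.lower(), val)
    return out


def potential_from_config(source) -> ModelPotential:
    """Build a ModelPotential from a config file path or config text."""
    try:
        text = open(source).read()
    except (OSError, TypeError):
        text = str(source)
    cfg = parse_config(text)
    kind = cfg.pop("kind", None)
    if kind not in _FACTORIES:
        raise ValueError(f"unknown potential kind {kind!r}; "
                         f"choose from {sorted(_FACTORIES)}")
    pot = _FACTORIES[kind](**cfg)
    logger.info("potential %s built from config; meta=%s", pot.label, pot.meta)
    return pot


# ----------------------------------------------------------------------
# programmable-occupancy trajectories
# ----------------------------------------------------------------------

def make_occupancy_trajectory(counts, n_particles: int, *, radius: float = 7.0,
                              z_lower: float = 4.0, z_upper: float = 17.0,
                              dt: float = 1.0, seed: int = 0):
    """Synthetic 3D trajectory with a programmed per-frame occupancy.

    ``counts[t]`` particles are placed uniformly inside the cylinder
    (radius, [z_lower, z_upper]) at frame ``t``; the rest are parked well
    outside.  Used to validate the occupancy and histogram operations
    against their design values.
    """
    from .dynamics import Trajectory

    counts = np.asarray(counts, dtype=int)
    if np.any(counts < 0) or np.any(counts > n_particles):
        raise ValueError("counts must lie in [0, n_particles]")
    rng = np.random.default_rng(seed)
    n_frames = len(counts)
    xs = np.empty((n_frames, 3 * n_particles))
    for t, c in enumerate(counts):
        inside = rng.permutation(n_particles)[:c]
        for p in range(n_particles):
            if p in inside:
                r = radius * np.sqrt(rng.random())
                phi = 2 * np.pi * rng.random()
                zc = z_lower + (z_upper - z_lower) * rng.random()
                xs[t, 3 * p:3 * p + 3] = (r * np.cos(phi), r * np.sin(phi), zc)
            else:
                xs[t, 3 * p:3 * p + 3] = (3 * radius, 3 * radius,
                                          z_upper + 20.0)
    return Trajectory(times=dt * np.arange(1, n_frames + 1), x_frames=xs,
                      metadata={"programmed": True, "seed": seed,
                                "radius": radius,
                                "z_bounds": (z_lower, z_upper)})


def restrained_potential(potential: ModelPotential, restraints) -> ModelPotential:
    """Potential-plus-restraints composite (for oracles of restrained runs).

    The sampled free energy of a wall-confined run is that of the total
    energy including the walls; this wrapper exposes exactly that total to
    the quadrature oracle.
    """
    from .dynamics import compile_restraints, restraint_energy_batch

    walls, posres, excl = compile_restraints(potential, restraints)

    def e_batch(X):
        return (potential.energy_batch(X)
                + restraint_energy_batch(walls, posres, excl, X))

    def e_one(x):
        return float(e_batch(np.atleast_2d(x))[0])

    def g_one(x):
        g = potential.gradient(x).copy()
        _kernels.restraints_eg(walls, posres, excl,
                               np.asarray(x, dtype=float).ravel(), g)
        return g

    meta = dict(potential.meta)
    meta["energy_batch_fn"] = e_batch
    return ModelPotential(
        label=f"{potential.label}+restraints", n_particles=potential.n_particles,
        dim_per_particle=potential.dim_per_particle,
        n_coords=potential.n_coords, kind=None, energy_fn=e_one,
        gradient_fn=g_one, quad_bounds=potential.quad_bounds.copy(),
        default_masses=potential.masses(), meta=meta)


def boltzmann_beta(temperature: float) -> float:
    """1/(k_B T) in mol/kcal."""
    return 1.0 / (KB * temperature)
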