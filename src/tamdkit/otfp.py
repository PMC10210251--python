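"""On-the-fly free-energy parametrization (OTFP).

The free energy over the CVs is expanded in piecewise-linear finite-element
("chapeau") bases, G_lambda(z) = sum_m lambda_m phi_m(z), and the
coefficients are obtained by least-squares matching of grad G_lambda to the
negated instantaneous spring-force samples f_t = kappa (theta(x_t) - z_t)
from a TAMD run:

    E(lambda) = 1/2 < | grad G_lambda(z_t) + f_t |^2 >
    =>  A lambda = b,   A_mn = <grad phi_m . grad phi_n>,
                        b_m  = -<grad phi_m . f_t>

Since the conditional mean of f at fixed z estimates -grad G(z), the
solution reproduces G up to one gauge constant, fixed by min-shifting to
zero.  In 2D the grid is triangulated (lower-left diagonal) so that basis
gradients are element-wise constant and the assembly is exact.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
from scipy.sparse.csgraph import connected_components

from . import _kernels

logger = logging.getLogger(__name__)

#: a node is "defined" once this many samples touched its support
DEFAULT_MIN_SUPPORT = 10


class OutOfGridError(ValueError):
    """CV value outside the grid (caller clips or discards the sample)."""


class OutOfDomainError(ValueError):
    """Lookup at a point whose interpolation stencil is not fully defined."""


def _axes(mins, maxs, n_nodes):
    return [np.linspace(mins[d], maxs[d], n_nodes[d])
            for d in range(len(n_nodes))]


@dataclass
class ChapeauGrid:
    """Regular chapeau-basis grid accumulating the normal equations."""

    mins: np.ndarray
    maxs: np.ndarray
    n_nodes: np.ndarray
    accum_A: np.ndarray = None
    accum_b: np.ndarray = None
    counts: np.ndarray = None
    n_samples: int = 0
    n_discarded: int = 0

    def __post_init__(self):
        self.mins = np.atleast_1d(np.asarray(self.mins, dtype=float))
        self.maxs = np.atleast_1d(np.asarray(self.maxs, dtype=float))
        self.n_nodes = np.atleast_1d(np.asarray(self.n_nodes, dtype=np.int64))
        if self.dim not in (1, 2):
            raise ValueError("only 1D and 2D grids are supported")
        if np.any(self.maxs <= self.mins) or np.any(self.n_nodes < 2):
            raise ValueError("grid needs mins < maxs and >= 2 nodes per dim")
        N = self.total_nodes
        if self.accum_A is None:
            self.accum_A = np.zeros((N, N))
            self.accum_b = np.zeros(N)
            self.counts = np.zeros(N, dtype=np.int64)

    @classmethod
    def from_spacing(cls, mins, maxs, spacing):
        mins = np.atleast_1d(np.asarray(mins, dtype=float))
        maxs = np.atleast_1d(np.asarray(maxs, dtype=float))
        spacing = np.broadcast_to(np.asarray(spacing, dtype=float), mins.shape)
        n_nodes = np.rint((maxs - mins) / spacing).astype(np.int64) + 1
        return cls(mins=mins, maxs=maxs, n_nodes=n_nodes)

    @property
    def dim(self) -> int:
        return len(self.n_nodes)

    @property
    def total_nodes(self) -> int:
        return int(np.prod(self.n_nodes))

    @property
    def spacing(self) -> np.ndarray:
        return (self.maxs - self.mins) / (self.n_nodes - 1)

    def node_axes(self):
        return _axes(self.mins, self.maxs, self.n_nodes)

    def basis_eval(self, z):
        """Nonzero basis values and gradients at one CV point.

        Returns (node_ids, values, gradients): 2 nonzero hats in 1D, 3 in 2D
        (linear elements on the triangulated grid, piecewise-constant
        gradients per element).
        """
        z = np.atleast_1d(np.asarray(z, dtype=float))
        if np.any(z < self.mins) or np.any(z > self.maxs):
            raise OutOfGridError(f"CV value {z} outside grid bounds")
        h = self.spacing
        if self.dim == 1:
            i = min(int((z[0] - self.mins[0]) / h[0]), self.n_nodes[0] - 2)
            s = (z[0] - (self.mins[0] + i * h[0])) / h[0]
            return (np.array([i, i + 1]),
                    np.array([1.0 - s, s]),
                    np.array([[-1.0 / h[0]], [1.0 / h[0]]]))
        nx, ny = self.n_nodes
        i = min(int((z[0] - self.mins[0]) / h[0]), nx - 2)
        j = min(int((z[1] - self.mins[1]) / h[1]), ny - 2)
        s = (z[0] - (self.mins[0] + i * h[0])) / h[0]
        t = (z[1] - (self.mins[1] + j * h[1])) / h[1]
        if s + t <= 1.0:
            ids = np.array([i * ny + j, (i + 1) * ny + j, i * ny + j + 1])
            vals = np.array([1.0 - s - t, s, t])
            grads = np.array([[-1.0 / h[0], -1.0 / h[1]],
                              [1.0 / h[0], 0.0], [0.0, 1.0 / h[1]]])
        else:
            ids = np.array([(i + 1) * ny + j + 1, (i + 1) * ny + j,
                            i * ny + j + 1])
            vals = np.array([s + t - 1.0, 1.0 - t, 1.0 - s])
            grads = np.array([[1.0 / h[0], 1.0 / h[1]],
                              [0.0, -1.0 / h[1]], [-1.0 / h[0], 0.0]])
        return ids, vals, grads


def accumulate(grid: ChapeauGrid, z_t, force_samples) -> ChapeauGrid:
    """Add force samples kappa(theta - z) to the running A, b sums.

    ``z_t``: (n, dim) CV positions; ``force_samples``: matching (n, dim)
    spring forces.  Out-of-range samples are discarded and counted.
    """
    z_t = np.atleast_2d(np.asarray(z_t, dtype=float))
    f = np.atleast_2d(np.asarray(force_samples, dtype=float))
    if z_t.shape != f.shape or z_t.shape[1] != grid.dim:
        raise ValueError("sample arrays must be (n, dim) with the grid's dim")
    h = grid.spacing
    if grid.dim == 1:
        n_out = _kernels.accumulate_1d(
            grid.accum_A, grid.accum_b, grid.counts, grid.mins[0], h[0],
            grid.n_nodes[0], np.ascontiguousarray(z_t[:, 0]),
            np.ascontiguousarray(f[:, 0]))
    else:
        n_out = _kernels.accumulate_2d(
            grid.accum_A, grid.accum_b, grid.counts, grid.mins[0],
            grid.mins[1], h[0], h[1], grid.n_nodes[0], grid.n_nodes[1],
            np.ascontiguousarray(z_t[:, 0]), np.ascontiguousarray(z_t[:, 1]),
            np.ascontiguousarray(f[:, 0]), np.ascontiguousarray(f[:, 1]))
    grid.n_samples += z_t.shape[0] - n_out
    grid.n_discarded += n_out
    return grid


@dataclass
class FreeEnergySurface:
    """Node values of G over a chapeau grid, with a defined-node mask.

    Values are stored flat in C order (node id = ix*ny + iy in 2D) and are
    min-shifted so the lowest defined node is zero.
    """

    mins: np.ndarray
    maxs: np.ndarray
    n_nodes: np.ndarray
    values: np.ndarray
    defined_mask: np.ndarray
    provenance: dict = field(default_factory=dict)

    def __post_init__(self):
        self.mins = np.atleast_1d(np.asarray(self.mins, dtype=float))
        self.maxs = np.atleast_1d(np.asarray(self.maxs, dtype=float))
        self.n_nodes = np.atleast_1d(np.asarray(self.n_nodes, dtype=np.int64))
        self.values = np.asarray(self.values, dtype=float).ravel().copy()
        self.defined_mask = np.asarray(self.defined_mask, dtype=bool).ravel()
        if not np.any(self.defined_mask):
            raise ValueError("surface has no defined nodes")
        if np.any(~np.isfinite(self.values[self.defined_mask])):
            raise ValueError("non-finite values on defined nodes")
        self.values[self.defined_mask] -= \
            np.min(self.values[self.defined_mask])
        self.values[~self.defined_mask] = np.nan

    @property
    def dim(self) -> int:
        return len(self.n_nodes)

    @property
    def spacing(self) -> np.ndarray:
        return (self.maxs - self.mins) / (self.n_nodes - 1)

    def node_axes(self):
        return _axes(self.mins, self.maxs, self.n_nodes)

    def values_grid(self) -> np.ndarray:
        return self.values.reshape(tuple(self.n_nodes))

    def mask_grid(self) -> np.ndarray:
        return self.defined_mask.reshape(tuple(self.n_nodes))

    @classmethod
    def from_callable(cls, fn, mins, maxs, spacing, provenance=None):
        """Tabulate an energy function on a grid (fully defined surface)."""
        mins = np.atleast_1d(np.asarray(mins, dtype=float))
        maxs = np.atleast_1d(np.asarray(maxs, dtype=float))
        spacing = np.broadcast_to(np.asarray(spacing, dtype=float), mins.shape)
        n_nodes = np.rint((maxs - mins) / spacing).astype(np.int64) + 1
        axes = _axes(mins, maxs, n_nodes)
        mesh = np.meshgrid(*axes, indexing="ij")
        pts = np.stack([m.ravel() for m in mesh], axis=1)
        vals = np.array([fn(p) for p in pts]) if not hasattr(fn, "energy_batch") \
            else fn.energy_batch(pts)
        return cls(mins=mins, maxs=maxs, n_nodes=n_nodes, values=vals,
                   defined_mask=np.ones(len(vals), dtype=bool),
                   provenance=provenance or {"source": "tabulated"})

    def write(self, path):
        header = (f"tamdkit free-energy surface\n"
                  f"dim={self.dim}\n"
                  f"mins={' '.join(repr(float(v)) for v in self.mins)}\n"
                  f"maxs={' '.join(repr(float(v)) for v in self.maxs)}\n"
                  f"n_nodes={' '.join(str(v) for v in self.n_nodes)}\n"
                  f"provenance={json.dumps(self.provenance, default=str)}\n"
                  "columns: node coords..., value_kcal_mol, defined")
        axes = self.node_axes()
        mesh = np.meshgrid(*axes, indexing="ij")
        coords = np.stack([m.ravel() for m in mesh], axis=1)
        vals = np.where(self.defined_mask, self.values, 0.0)
        body = np.hstack([coords, vals[:, None],
                          self.defined_mask.astype(float)[:, None]])
        np.savetxt(path, body, header=header, fmt="%.10g")

    @classmethod
    def read(cls, path):
        info = {}
        with open(path) as fh:
            for line in fh:
                if not line.startswith("#"):
                    break
                body = line[1:].strip()
                if "=" in body:
                    key, val = body.split("=", 1)
                    info[key.strip()] = val.strip()
        mins = np.array([float(v) for v in info["mins"].split()])
        maxs = np.array([float(v) for v in info["maxs"].split()])
        n_nodes = np.array([int(v) for v in info["n_nodes"].split()])
        prov = json.loads(info.get("provenance", "{}"))
        data = np.atleast_2d(np.loadtxt(path))
        vals = data[:, -2].copy()
        mask = data[:, -1] > 0.5
        vals[~mask] = np.nan
        return cls(mins=mins, maxs=maxs, n_nodes=n_nodes, values=vals,
                   defined_mask=mask, provenance=prov)


def solve_fes(grid: ChapeauGrid, min_support: int = DEFAULT_MIN_SUPPORT,
              provenance=None) -> FreeEnergySurface:
    """Solve A lambda = b on the sampled nodes.

    Nodes whose support saw fewer than ``min_support`` samples are left
    undefined.  The gauge constant (one per connected sampled component) is
    fixed by pinning, and the result is min-shifted to zero.  A singular
    restricted system falls back to the smallest-norm solution with a
    logged warning.
    """
    if grid.n_samples <= 0:
        raise ValueError("no samples accumulated")
    keep = np.nonzero(grid.counts >= min_support)[0]
    if len(keep) == 0:
        raise ValueError(f"no node has >= {min_support} supporting samples")
    A = grid.accum_A[np.ix_(keep, keep)]
    b = grid.accum_b[keep]
    As = sp.csr_matrix(A)
    n_comp, labels = connected_components(As != 0, directed=False)
    Ap = As.tolil()
    bp = b.copy()
    for c in range(n_comp):
        pin = int(np.nonzero(labels == c)[0][0])
        Ap.rows[pin] = [pin]
        Ap.data[pin] = [1.0]
        bp[pin] = 0.0
    try:
        lam = sp.linalg.spsolve(Ap.tocsr(), bp)
        if not np.all(np.isfinite(lam)):
            raise RuntimeError("non-finite solution")
    except Exception:
        logger.warning("restricted OTFP system singular; using the "
                       "smallest-norm least-squares solution")
        lam = np.linalg.lstsq(A, b, rcond=None)[0]
    values = np.full(grid.total_nodes, np.nan)
    values[keep] = lam
    mask = np.zeros(grid.total_nodes, dtype=bool)
    mask[keep] = True
    prov = dict(provenance or {})
    prov.setdefault("n_samples", grid.n_samples)
    prov.setdefault("n_discarded", grid.n_discarded)
    prov.setdefault("min_support", min_support)
    return FreeEnergySurface(mins=grid.mins, maxs=grid.maxs,
                             n_nodes=grid.n_nodes, values=values,
                             defined_mask=mask, provenance=prov)


def average_fes(surfaces) -> FreeEnergySurface:
    """Pointwise mean over nodes defined in *every* replica (mask
    intersection), re-min-shifted."""
    surfaces = list(surfaces)
    if not surfaces:
        raise ValueError("no surfaces to average")
    ref = surfaces[0]
    for s in surfaces[1:]:
        if (not np.array_equal(s.n_nodes, ref.n_nodes)
                or not np.allclose(s.mins, ref.mins)
                or not np.allclose(s.maxs, ref.maxs)):
            raise ValueError("replica grids do not match")
    mask = np.logical_and.reduce([s.defined_mask for s in surfaces])
    if not np.any(mask):
        raise ValueError("replica defined regions do not overlap")
    stack = np.stack([np.where(s.defined_mask, s.values, 0.0)
                      for s in surfaces])
    values = np.where(mask, stack.mean(axis=0), np.nan)
    prov = {"replicas": [s.provenance for s in surfaces],
            "n_replicas": len(surfaces)}
    return FreeEnergySurface(mins=ref.mins, maxs=ref.maxs,
                             n_nodes=ref.n_nodes, values=values,
                             defined_mask=mask, provenance=prov)


def _interp_values(fes: FreeEnergySurface, pts: np.ndarray) -> np.ndarray:
    h = fes.spacing
    idx = np.minimum(((pts - fes.mins) / h).astype(int), fes.n_nodes - 2)
    frac = (pts - (fes.mins + idx * h)) / h
    V = fes.values_grid()
    if fes.dim == 1:
        i = idx[:, 0]
        s = frac[:, 0]
        vals = (1 - s) * V[i] + s * V[i + 1]
    else:
        i, j = idx[:, 0], idx[:, 1]
        s, t = frac[:, 0], frac[:, 1]
        vals = (V[i, j] * (1 - s) * (1 - t) + V[i + 1, j] * s * (1 - t)
                + V[i, j + 1] * (1 - s) * t + V[i + 1, j + 1] * s * t)
    if np.any(~np.isfinite(vals)):
        raise OutOfDomainError("lookup in an undefined region")
    return vals


def fes_lookup(fes: FreeEnergySurface, z, with_gradient: bool = True):
    """(Bi)linear interpolation of node values; gradient by central finite
    differences of node values taken through the interpolant.

    The gradient stencil is half a grid spacing, centered at the query and
    clipped (one-sided) at the grid boundary.  ``z`` may be a single point
    or an (n, dim) array.  Lookups whose interpolation stencil contains
    undefined nodes raise OutOfDomainError.
    """
    pts = np.atleast_2d(np.asarray(z, dtype=float))
    single = np.asarray(z).ndim <= 1
    if pts.shape[1] != fes.dim:
        raise ValueError("query dimensionality mismatch")
    eps = 1e-9 * np.maximum(1.0, np.abs(fes.maxs - fes.mins))
    if np.any(pts < fes.mins - eps) or np.any(pts > fes.maxs + eps):
        raise OutOfDomainError("lookup outside the grid bounds")
    pts = np.clip(pts, fes.mins, fes.maxs)
    vals = _interp_values(fes, pts)
    if not with_gradient:
        return (float(vals[0]) if single else vals)
    grads = np.empty_like(pts)
    for d in range(fes.dim):
        e = np.zeros(fes.dim)
        e[d] = 0.5 * fes.spacing[d]
        up = np.clip(pts + e, fes.mins, fes.maxs)
        dn = np.clip(pts - e, fes.mins, fes.maxs)
        grads[:, d] = (_interp_values(fes, up) - _interp_values(fes, dn)) \
            / (up[:, d] - dn[:, d])
    if single:
        return float(vals[0]), grads[0]
    return vals, grads


def fes_rms_deviation(fes: FreeEnergySurface, oracle_values: np.ndarray,
                      oracle_mask=None) -> float:
    """RMS difference to a reference tabulated on the same nodes.

    Free energies are defined up to an additive constant; the gauge is
    fixed by least squares (mean alignment over the common defined
    region), so the deviation is not pinned to any single node."""
    ref = np.asarray(oracle_values, dtype=float).ravel()
    mask = fes.defined_mask & np.isfinite(ref)
    if oracle_mask is not None:
        mask &= np.asarray(oracle_mask, dtype=bool).ravel()
    d = fes.values[mask] - ref[mask]
    d -= d.mean()
    return float(np.sqrt(np.mean(d * d)))
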