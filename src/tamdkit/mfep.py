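"""Zero-temperature string method over a gridded free-energy surface.

A discretized curve is relaxed by alternating steepest-descent displacement
of every point along -grad G (forces from finite differences of the FES
node values, projected through the interpolant) with reparametrization to
equal arclength.  The converged curve is the minimum free energy path
(MFEP); the free-energy profile along it is read off the FES at the path
points.  Endpoints evolve freely and slide into the basin minima.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .otfp import FreeEnergySurface, OutOfDomainError, fes_lookup

logger = logging.getLogger(__name__)


@dataclass
class StringPath:
    """Ordered points in CV space with equal-arclength parametrization."""

    points: np.ndarray        # (n_points, dim) A
    arclengths: np.ndarray    # normalized 0..1, strictly increasing
    iteration: int = 0
    converged: bool = False
    mean_displacement: float = np.inf

    @property
    def n_points(self) -> int:
        return self.points.shape[0]

    def write(self, path):
        body = np.hstack([self.arclengths[:, None], self.points])
        np.savetxt(path, body, header=(
            "tamdkit string path\n"
            f"iteration={self.iteration} converged={self.converged} "
            f"mean_displacement={self.mean_displacement!r}\n"
            "columns: arclength coords..."))


def _arclengths(points: np.ndarray) -> np.ndarray:
    seg = np.linalg.norm(np.diff(points, axis=0), axis=1)
    s = np.concatenate([[0.0], np.cumsum(seg)])
    if s[-1] <= 0:
        raise ValueError("degenerate string: zero total length")
    return s / s[-1]


def _reparametrize(points: np.ndarray) -> np.ndarray:
    """Piecewise-linear resampling to equal arclength."""
    s = _arclengths(points)
    target = np.linspace(0.0, 1.0, len(points))
    out = np.empty_like(points)
    for d in range(points.shape[1]):
        out[:, d] = np.interp(target, s, points[:, d])
    return out


def init_string(segments) -> StringPath:
    """Concatenated linear interpolations.

    ``segments`` is a list of (start, end, n_points) with n_points >= 2
    each; a junction point shared (within 1e-6 A) by consecutive segments
    is kept once.
    """
    segments = list(segments)
    if not segments:
        raise ValueError("empty segment list")
    pts = []
    for start, end, n in segments:
        start = np.atleast_1d(np.asarray(start, dtype=float))
        end = np.atleast_1d(np.asarray(end, dtype=float))
        if n < 2:
            raise ValueError("each segment needs at least 2 points")
        if np.allclose(start, end, atol=1e-12):
            raise ValueError("degenerate segment: start equals end")
        seg = start[None, :] + np.linspace(0, 1, int(n))[:, None] \
            * (end - start)[None, :]
        if pts and np.linalg.norm(pts[-1] - seg[0]) < 1e-6:
            seg = seg[1:]  # de-duplicate the shared junction
        pts.extend(seg)
    points = np.asarray(pts)
    return StringPath(points=points, arclengths=_arclengths(points))


def evolve_string(fes: FreeEnergySurface, path: StringPath,
                  step_size: float = 1e-3, tol: float = 1e-7,
                  max_iter: int = 200000) -> StringPath:
    """Relax a string to the MFEP of a gridded surface.

    Each iteration displaces every point by ``-step_size * grad G`` (from
    the FES interpolant) and reparametrizes to equal arclength; convergence
    is declared when the mean per-point Euclidean displacement between two
    consecutive parametrized strings drops below ``tol`` (A).  The step is
    halved when the summed path energy rises for 5 consecutive iterations,
    or when a single proposed move exceeds one grid cell (overshoot guard).
    A point leaving the defined region aborts with the iteration logged.
    """
    pts = _reparametrize(np.array(path.points, dtype=float))
    step = float(step_size)
    max_move = float(np.max(fes.spacing))
    prev_energy = np.inf
    n_increase = 0
    mean_disp = np.inf
    it = 0
    while it < max_iter:
        it += 1
        try:
            vals, grads = fes_lookup(fes, pts)
        except OutOfDomainError as err:
            raise RuntimeError(
                f"string point left the defined region at iteration {it}: "
                f"{err}") from err
        move = -step * grads
        worst = float(np.max(np.linalg.norm(move, axis=1)))
        if worst > max_move:
            step *= 0.5
            logger.debug("iteration %d: overshoot (%.3g A), step -> %g",
                         it, worst, step)
            continue
        total = float(np.sum(vals))
        if total > prev_energy:
            n_increase += 1
            if n_increase >= 5:
                step *= 0.5
                n_increase = 0
                logger.debug("iteration %d: energy rising, step -> %g",
                             it, step)
        else:
            n_increase = 0
            # regrow toward the nominal step so halvings cannot collapse
            # the step and fake convergence of the displacement metric
            step = min(step * 1.05, step_size)
        prev_energy = total
        new_pts = _reparametrize(pts + move)
        mean_disp = float(np.mean(np.linalg.norm(new_pts - pts, axis=1)))
        pts = new_pts
        if mean_disp < tol:
            logger.info("string converged at iteration %d "
                        "(mean displacement %.3g A)", it, mean_disp)
            return StringPath(points=pts, arclengths=_arclengths(pts),
                              iteration=it, converged=True,
                              mean_displacement=mean_disp)
    logger.warning("string not converged after %d iterations "
                   "(mean displacement %.3g A)", max_iter, mean_disp)
    return StringPath(points=pts, arclengths=_arclengths(pts),
                      iteration=max_iter, converged=False,
                      mean_displacement=mean_disp)


def profile_along_path(fes: FreeEnergySurface, path: StringPath):
    """Free-energy profile along the string: (arclength, G) pairs.

    G is the FES value at each path point via the interpolant.
    """
    vals = fes_lookup(fes, path.points, with_gradient=False)
    return np.asarray(path.arclengths), np.asarray(vals)
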