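"""Chapeau-basis free-energy reconstruction."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import tamdkit as tk
from tamdkit.otfp import OutOfGridError


@pytest.fixture
def grid1d():
    return tk.ChapeauGrid.from_spacing([-4.0], [4.0], 0.25)


@pytest.fixture
def grid2d():
    return tk.ChapeauGrid.from_spacing([0.0, 0.0], [2.0, 1.0], 0.25)


# ----------------------------------------------------------------------
# basis
# ----------------------------------------------------------------------

@given(z=st.floats(-3.999, 3.999))
@settings(max_examples=200, deadline=None)
def test_basis_partition_of_unity_1d(z):
    grid = tk.ChapeauGrid.from_spacing([-4.0], [4.0], 0.25)
    _, vals, _ = grid.basis_eval(z)
    assert len(vals) == 2
    assert abs(vals.sum() - 1.0) < 1e-12


@given(zx=st.floats(0.001, 1.999), zy=st.floats(0.001, 0.999))
@settings(max_examples=200, deadline=None)
def test_basis_partition_of_unity_2d(zx, zy):
    grid = tk.ChapeauGrid.from_spacing([0.0, 0.0], [2.0, 1.0], 0.25)
    _, vals, _ = grid.basis_eval((zx, zy))
    assert len(vals) == 3
    assert abs(vals.sum() - 1.0) < 1e-12


def test_basis_interpolation_property(grid1d, grid2d):
    ids, vals, _ = grid1d.basis_eval(-4.0 + 5 * 0.25)  # exactly node 5
    assert vals[np.argwhere(ids == 5)[0, 0]] == pytest.approx(1.0)
    assert vals.sum() == pytest.approx(1.0)
    ids, vals, _ = grid1d.basis_eval(-4.0 + 5.5 * 0.25)  # cell midpoint
    assert np.allclose(sorted(vals), [0.5, 0.5])
    ids, vals, grads = grid2d.basis_eval((0.5, 0.5))
    node = 2 * grid2d.n_nodes[1] + 2
    assert vals[np.argwhere(ids == node)[0, 0]] == pytest.approx(1.0)


def test_basis_gradients_are_constant_per_element(grid2d):
    ids_a, _, grads_a = grid2d.basis_eval((0.26, 0.01))
    ids_b, _, grads_b = grid2d.basis_eval((0.30, 0.05))
    assert np.array_equal(ids_a, ids_b)
    assert np.allclose(grads_a, grads_b)


def test_basis_out_of_range(grid1d):
    with pytest.raises(OutOfGridError):
        grid1d.basis_eval(4.5)


# ----------------------------------------------------------------------
# accumulation
# ----------------------------------------------------------------------

def test_single_sample_touches_one_cell_block(grid1d):
    tk.accumulate(grid1d, [[0.1]], [[1.0]])
    nz = np.argwhere(grid1d.accum_A != 0)
    touched = np.unique(nz)
    assert len(touched) == 2 and touched[1] == touched[0] + 1
    assert grid1d.n_samples == 1


def test_accumulation_is_linear(grid1d):
    rng = np.random.default_rng(0)
    z = rng.uniform(-4, 4, (100, 1))
    f = rng.normal(size=(100, 1))
    tk.accumulate(grid1d, z, f)
    A1, b1 = grid1d.accum_A.copy(), grid1d.accum_b.copy()
    tk.accumulate(grid1d, z, f)
    assert np.allclose(grid1d.accum_A, 2 * A1)
    assert np.allclose(grid1d.accum_b, 2 * b1)


def test_out_of_range_samples_discarded_with_counter(grid1d):
    tk.accumulate(grid1d, [[0.0], [9.0]], [[1.0], [1.0]])
    assert grid1d.n_samples == 1
    assert grid1d.n_discarded == 1


def test_quadratic_gradient_recovered_to_machine_precision(grid1d):
    """Programmed samples f = -G'(z) of a quadratic G solve back to G
    exactly: for cell-centered samples the hat-gradient match equals the
    midpoint rule, which is exact for the linear integrand G'."""
    z = (np.arange(-4.0 + 0.125, 4.0, 0.25))[:, None]  # cell centers
    f = -2.0 * 1.3 * z  # G = 1.3 z^2
    tk.accumulate(grid1d, z, f)
    fes = tk.solve_fes(grid1d, min_support=1)
    nodes = fes.node_axes()[0]
    ref = 1.3 * nodes ** 2
    defined = fes.defined_mask
    assert np.allclose(fes.values[defined],
                       (ref - ref[defined].min())[defined], atol=1e-9)


def test_doubling_sample_stream_leaves_solution_unchanged(grid1d):
    rng = np.random.default_rng(1)
    z = rng.uniform(-3.9, 3.9, (5000, 1))
    f = -2.0 * z + rng.normal(0, 5.0, (5000, 1))
    tk.accumulate(grid1d, z, f)
    lam1 = tk.solve_fes(grid1d).values
    tk.accumulate(grid1d, z, f)
    lam2 = tk.solve_fes(grid1d).values
    assert np.allclose(lam1, lam2, equal_nan=True)


def test_unsampled_nodes_are_undefined(grid1d):
    z = np.full((500, 1), 2.1)  # all samples in one cell
    tk.accumulate(grid1d, z, np.zeros((500, 1)))
    fes = tk.solve_fes(grid1d)
    assert fes.defined_mask.sum() == 2
    nodes = fes.node_axes()[0]
    assert np.all(np.abs(nodes[fes.defined_mask] - 2.1) < 0.3)


def test_solve_requires_samples(grid1d):
    with pytest.raises(ValueError):
        tk.solve_fes(grid1d)


# ----------------------------------------------------------------------
# averaging
# ----------------------------------------------------------------------

def _surface(values, mask=None):
    values = np.asarray(values, dtype=float)
    mask = np.ones_like(values, bool) if mask is None else np.asarray(mask)
    return tk.FreeEnergySurface(mins=[0.0], maxs=[float(len(values) - 1)],
                                n_nodes=[len(values)], values=values,
                                defined_mask=mask)


def test_average_is_idempotent():
    s = _surface([0.0, 1.0, 2.0])
    avg = tk.average_fes([s, s])
    assert np.allclose(avg.values, s.values)


def test_average_mask_is_intersection():
    a = _surface([0.0, 1.0, 2.0], [True, True, False])
    b = _surface([0.0, 2.0, 1.0], [True, False, True])
    avg = tk.average_fes([a, b])
    assert list(avg.defined_mask) == [True, False, False]


def test_average_is_gauge_invariant():
    base = np.array([3.0, 0.0, 1.0])
    avg = tk.average_fes([_surface(base), _surface(base + 7.5)])
    assert np.allclose(avg.values, base - base.min())


def test_average_rejects_mismatched_grids():
    a = _surface([0.0, 1.0, 2.0])
    b = tk.FreeEnergySurface(mins=[0.0], maxs=[1.0], n_nodes=[3],
                             values=[0, 1, 2],
                             defined_mask=[True] * 3)
    with pytest.raises(ValueError):
        tk.average_fes([a, b])


# ----------------------------------------------------------------------
# lookup and I/O
# ----------------------------------------------------------------------

def test_lookup_exact_at_nodes_and_linear_fields():
    fes = tk.FreeEnergySurface.from_callable(lambda p: 3.0 * p[0] + 1.0,
                                             [0.0], [2.0], 0.25)
    nodes = fes.node_axes()[0]
    for i, node in enumerate(nodes):
        assert tk.fes_lookup(fes, [node], with_gradient=False) == \
            pytest.approx(fes.values[i])
    v, g = tk.fes_lookup(fes, [0.37])
    assert g[0] == pytest.approx(3.0)
    fes2 = tk.FreeEnergySurface.from_callable(
        lambda p: 2.0 * p[0] - 1.0 * p[1], [0, 0], [1, 1], 0.25)
    v, g = tk.fes_lookup(fes2, (0.4, 0.7))
    assert np.allclose(g, (2.0, -1.0))


def test_lookup_outside_defined_region_raises():
    fes = _surface([0.0, 1.0, 2.0, 3.0], [True, True, False, True])
    with pytest.raises(tk.OutOfDomainError):
        tk.fes_lookup(fes, [2.5])
    with pytest.raises(tk.OutOfDomainError):
        tk.fes_lookup(fes, [-1.0])


def test_fes_text_roundtrip_is_lossless(tmp_path, filter2d):
    fes = filter2d["replicas"][0][2]
    path = tmp_path / "fes.tsv"
    fes.write(path)
    back = tk.FreeEnergySurface.read(path)
    assert np.array_equal(back.n_nodes, fes.n_nodes)
    assert np.allclose(back.mins, fes.mins)
    assert np.array_equal(back.defined_mask, fes.defined_mask)
    assert np.allclose(back.values[back.defined_mask],
                       fes.values[fes.defined_mask], atol=1e-8)
    assert back.provenance["seed"] == 11


# ----------------------------------------------------------------------
# end-to-end recovery (shares the session fixtures with acceptance)
# ----------------------------------------------------------------------

def test_2d_recovery_convergence_is_monotone(filter2d):
    """More sampling does not worsen the surface: RMS at the full sample
    stream <= RMS at a quarter of it."""
    traj, _, _ = filter2d["replicas"][0]
    oracle = filter2d["oracle"].fe_values.ravel()
    f = tk.mean_force_samples(traj, filter2d["kappa"])
    rms = {}
    for n in (len(traj.z_frames) // 4, len(traj.z_frames)):
        grid = tk.ChapeauGrid.from_spacing([3.0, -1.5], [18.0, 1.5], 0.25)
        tk.accumulate(grid, traj.z_frames[:n], f[:n])
        rms[n] = tk.fes_rms_deviation(tk.solve_fes(grid), oracle)
    ns = sorted(rms)
    assert rms[ns[1]] <= rms[ns[0]]


def test_interpolated_minimum_matches_oracle_minimum(filter2d):
    fes = filter2d["replicas"][0][2]
    oracle = filter2d["oracle"]
    node_id = np.nanargmin(np.where(fes.defined_mask, fes.values, np.nan))
    axes = fes.node_axes()
    est = np.array([axes[0][node_id // fes.n_nodes[1]],
                    axes[1][node_id % fes.n_nodes[1]]])
    # the two wells are degenerate by symmetry: compare to the nearest of
    # the lowest oracle minima
    lowest = [m[0] for m in oracle.minima() if m[1] < 0.1]
    err = min(np.max(np.abs(est - ref)) for ref in lowest)
    assert err <= 0.25 + 1e-9
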