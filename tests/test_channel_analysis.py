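"""Occupancy, histograms, cross distances, superposition."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import biotite.structure as struc
import tamdkit as tk


# ----------------------------------------------------------------------
# occupancy
# ----------------------------------------------------------------------

def _traj_from_xyz(frames):
    """frames: list of per-frame lists of (x, y, z) per particle."""
    arr = np.array([[c for p in frame for c in p] for frame in frames])
    return tk.Trajectory(times=np.arange(1.0, len(frames) + 1),
                         x_frames=arr)


def test_count_occupancy_constructed_frames():
    region = tk.OccupancyRegion(radius=7.0, z_lower=4.0, z_upper=17.0)
    traj = _traj_from_xyz([
        [(30, 0, 10), (0, 30, 10)],   # none inside
        [(0, 0, 10), (30, 0, 10)],    # one inside
        [(0, 0, 5), (1, 1, 16)],      # both inside
    ])
    series = tk.count_occupancy(traj, region, [0, 1])
    assert list(series.counts) == [0, 1, 2]


def test_occupancy_boundary_is_inclusive():
    region = tk.OccupancyRegion(radius=7.0, z_lower=4.0, z_upper=17.0)
    traj = _traj_from_xyz([[(7.0, 0.0, 4.0)], [(7.0001, 0.0, 10.0)],
                           [(0.0, 0.0, 17.0)]])
    series = tk.count_occupancy(traj, region, [0])
    assert list(series.counts) == [1, 0, 1]


def test_count_occupancy_rejects_empty_selection():
    traj = _traj_from_xyz([[(0, 0, 10)]])
    with pytest.raises(ValueError):
        tk.count_occupancy(traj, tk.OccupancyRegion(), [])


def test_occupancy_table_examples():
    series = tk.OccupancySeries(counts=np.array([0, 1, 1, 2]),
                                times=np.arange(4.0))
    table = tk.occupancy_table(series)
    assert np.allclose(table["percent"], [25, 50, 25, 0, 0])
    assert table["mean"] == pytest.approx(1.0)
    assert table["sd_population"] == pytest.approx(np.sqrt(0.5), abs=1e-9)
    zeros = tk.occupancy_table(tk.OccupancySeries(
        counts=np.zeros(10, dtype=int), times=np.arange(10.0)))
    assert zeros["percent"][0] == 100.0
    assert zeros["mean"] == 0.0 and zeros["sd_population"] == 0.0


def test_occupancy_table_pools_counts_above_top_bin():
    series = tk.OccupancySeries(counts=np.array([4, 5, 6, 0]),
                                times=np.arange(4.0))
    table = tk.occupancy_table(series, max_count=4)
    assert table["percent"][4] == pytest.approx(75.0)
    assert table["percent"].sum() == pytest.approx(100.0)


@given(counts=st.lists(st.integers(0, 8), min_size=1, max_size=300))
@settings(max_examples=100, deadline=None)
def test_occupancy_percentages_always_sum_to_100(counts):
    series = tk.OccupancySeries(counts=np.array(counts, dtype=int),
                                times=np.arange(1.0, len(counts) + 1))
    table = tk.occupancy_table(series)
    assert table["percent"].sum() == pytest.approx(100.0, abs=0.01)


def test_region_bounds_from_reference_atoms(synthetic_structure):
    region = tk.OccupancyRegion.from_reference_atoms(
        synthetic_structure, upper_atom=("A", 940, "CA"),
        lower_atom=("A", 940, "CA"), lower_offset=-4.0)
    z940 = synthetic_structure.get_coord(940, "CA")[2]
    assert region.z_upper == pytest.approx(z940)
    assert region.z_lower == pytest.approx(z940 - 4.0)
    assert "reference atoms" in region.provenance


# ----------------------------------------------------------------------
# histograms
# ----------------------------------------------------------------------

def test_z_histogram_single_bin_and_conditions():
    traj = _traj_from_xyz([[(0, 0, 10.0)]] * 8)
    counts, edges = tk.z_histogram(traj, 0, (3.0, 18.0), 15)
    assert counts.sum() == 8
    assert counts[np.digitize(10.0, edges) - 1] == 8
    with pytest.warns(UserWarning):
        counts, _ = tk.z_histogram(traj, 0, (3.0, 18.0), 15,
                                   condition=np.zeros(8, bool))
    assert not counts.any()


def test_z_histogram_integrates_to_conditional_frame_count():
    rng = np.random.default_rng(0)
    traj = _traj_from_xyz([[(0, 0, z)] for z in rng.uniform(4, 17, 200)])
    cond = np.arange(200) % 2 == 0
    counts, _ = tk.z_histogram(traj, 0, (3.0, 18.0), 30, condition=cond)
    assert counts.sum() == cond.sum()


def test_z_histogram_com_variant():
    traj = _traj_from_xyz([[(0, 0, 6.0), (0, 0, 10.0)]] * 4)
    counts, edges = tk.z_histogram(traj, ("com", (0, 1)), (3.0, 18.0), 30)
    center_bin = np.digitize(8.0, edges) - 1
    assert counts[center_bin] == 4


def test_pool_trajectories_concatenates_frames():
    a = _traj_from_xyz([[(0, 0, 5.0)]] * 3)
    b = _traj_from_xyz([[(0, 0, 12.0)]] * 5)
    pooled = tk.pool_trajectories([a, b])
    assert pooled.n_frames == 8
    assert np.all(np.diff(pooled.times) > 0)
    assert "pooled_from" in pooled.metadata
    with pytest.raises(ValueError):
        tk.pool_trajectories([a, _traj_from_xyz([[(0, 0, 1), (0, 0, 2)]])])


# ----------------------------------------------------------------------
# structures: cross distances
# ----------------------------------------------------------------------

def test_cross_distance_three_four_five():
    atoms = struc.AtomArray(2)
    atoms.coord[0] = (0, 0, 0)
    atoms.coord[1] = (3, 4, 0)
    atoms.chain_id[:] = "A"
    atoms.res_id[:] = (387, 1426)
    atoms.res_name[:] = ("GLU", "ASP")
    atoms.atom_name[:] = ("CA", "CA")
    atoms.element[:] = "C"
    model = tk.StructureModel(atoms=atoms, default_chain="A")
    assert tk.cross_distance(model, tk.CROSS_DISTANCES["d1A"]) == 5.00


def test_cross_distance_symmetric_and_rigid_invariant(synthetic_structure):
    from scipy.spatial.transform import Rotation

    d = tk.cross_distance_table(synthetic_structure)
    flipped = tk.CrossDistanceDef("d1A*", (1426, "CA"), (387, "CA"))
    assert tk.cross_distance(synthetic_structure, flipped) == d["d1A"]

    rot = Rotation.from_euler("zyx", [31.0, -12.0, 55.0], degrees=True)
    moved = synthetic_structure.atoms.copy()
    moved.coord = rot.apply(moved.coord) + np.array([5.0, -3.0, 11.0])
    model2 = tk.StructureModel(atoms=moved, default_chain="A")
    for label, value in tk.cross_distance_table(model2).items():
        assert value == pytest.approx(d[label], abs=0.01)


def test_cross_distance_table_matches_coordinate_arithmetic(
        synthetic_structure):
    for label, cdef in tk.CROSS_DISTANCES.items():
        a = synthetic_structure.get_coord(*cdef.atom_a)
        b = synthetic_structure.get_coord(*cdef.atom_b)
        expected = round(float(np.linalg.norm(a - b)), 2)
        assert tk.cross_distance(synthetic_structure, cdef) == expected


def test_missing_atom_names_the_address(synthetic_structure):
    bad = tk.CrossDistanceDef("dX", (387, "CA"), (999, "CB"))
    with pytest.raises(KeyError, match="999"):
        tk.cross_distance(synthetic_structure, bad)


def test_pdb_roundtrip_preserves_addressing(tmp_path, synthetic_structure):
    path = tmp_path / "synthetic_filter.pdb"
    synthetic_structure.to_pdb(path)
    back = tk.StructureModel.from_pdb(path)
    assert back.default_chain == "A"
    for label, value in tk.cross_distance_table(synthetic_structure).items():
        assert tk.cross_distance(back, tk.CROSS_DISTANCES[label]) == \
            pytest.approx(value, abs=0.01)


# ----------------------------------------------------------------------
# superposition RMSD
# ----------------------------------------------------------------------

def test_superpose_structure_onto_itself(synthetic_structure):
    assert tk.superpose_rmsd(synthetic_structure, synthetic_structure) == \
        pytest.approx(0.0, abs=1e-6)


def test_superpose_removes_rigid_motion(synthetic_structure):
    from scipy.spatial.transform import Rotation

    moved = synthetic_structure.atoms.copy()
    moved.coord = Rotation.from_euler("z", 90, degrees=True).apply(
        moved.coord) + np.array([10.0, 0.0, -4.0])
    model2 = tk.StructureModel(atoms=moved, default_chain="A")
    assert tk.superpose_rmsd(model2, synthetic_structure) == \
        pytest.approx(0.0, abs=1e-6)


def test_superpose_agrees_with_independent_superimposition(
        synthetic_structure):
    """Cross-check against biotite's Kabsch superimposition on a perturbed
    copy of the synthetic structure."""
    rng = np.random.default_rng(5)
    moved = synthetic_structure.atoms.copy()
    moved.coord = moved.coord + rng.normal(0, 0.4, moved.coord.shape)
    model2 = tk.StructureModel(atoms=moved, default_chain="A")
    ours = tk.superpose_rmsd(model2, synthetic_structure)
    fitted, _ = struc.superimpose(synthetic_structure.atoms, moved)
    theirs = float(struc.rmsd(synthetic_structure.atoms, fitted))
    assert ours == pytest.approx(theirs, abs=1e-6)


def test_superpose_single_displaced_atom(synthetic_structure):
    n = synthetic_structure.atoms.array_length()
    moved = synthetic_structure.atoms.copy()
    moved.coord[0] = moved.coord[0] + np.array([1.0, 0.0, 0.0])
    model2 = tk.StructureModel(atoms=moved, default_chain="A")
    rmsd = tk.superpose_rmsd(model2, synthetic_structure)
    # approx sqrt(1/N), reduced slightly by the optimal re-alignment
    assert rmsd <= np.sqrt(1.0 / n) + 1e-9
    assert rmsd >= 0.8 * np.sqrt(1.0 / n)


def test_superposed_never_exceeds_unaligned_rmsd(synthetic_structure):
    rng = np.random.default_rng(7)
    moved = synthetic_structure.atoms.copy()
    moved.coord = moved.coord + rng.normal(0, 1.0, moved.coord.shape) \
        + np.array([2.0, 2.0, 2.0])
    model2 = tk.StructureModel(atoms=moved, default_chain="A")
    aligned = tk.superpose_rmsd(model2, synthetic_structure)
    unaligned = np.sqrt(np.mean(np.sum(
        (moved.coord - synthetic_structure.atoms.coord) ** 2, axis=1)))
    assert aligned <= unaligned + 1e-12


def test_backbone_selection_and_ploop_presets():
    atoms = struc.AtomArray(8)
    rng = np.random.default_rng(11)
    atoms.coord = rng.normal(0.0, 3.0, (8, 3))
    atoms.chain_id[:] = "A"
    atoms.res_id[:] = np.repeat([370, 371], 4)
    atoms.res_name[:] = "ALA"
    atoms.atom_name[:] = ["N", "CA", "C", "O"] * 2
    atoms.element[:] = ["N", "C", "C", "O"] * 2
    model = tk.StructureModel(atoms=atoms, default_chain="A")
    sel = model.backbone_selection(((370, 371),))
    assert len(sel) == 8
    assert tk.superpose_rmsd(model, model, sel) == pytest.approx(0.0,
                                                                 abs=1e-6)
    assert set(tk.P_LOOP_RANGES) == {"nav1.1", "nav1.2", "nav1.6"}
    assert tk.P_LOOP_RANGES["nav1.2"][0] == (370, 397)
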