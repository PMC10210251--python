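"""Trajectory and structure analyses around the channel filter.

Covers the conductivity/selectivity-filter (C/SF) bookkeeping used for
voltage-gated sodium channels: per-frame ion occupancy of a cylindrical
filter region, z-coordinate histograms conditioned on occupancy,
cross distances between atoms of opposite pore repeats (the d1A..d4B set),
and rigid-body superposition RMSD over P-loop selections.

Structures are read from standard PDB files through biotite; the filter
region can be bounded either explicitly or by the z coordinates of named
reference atoms.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import biotite.structure as struc
from biotite.structure.io.pdb import PDBFile
from scipy.spatial.transform import Rotation

from .dynamics import Trajectory

logger = logging.getLogger(__name__)


# ----------------------------------------------------------------------
# structures
# ----------------------------------------------------------------------

@dataclass
class StructureModel:
    """Parsed atomic structure with (chain, residue number, atom name)
    addressing.

    The first model is used and alternate locations are resolved to the
    highest occupancy, so addressing is deterministic.  ``default_chain``
    is the longest amino-acid chain unless set explicitly.
    """

    atoms: struc.AtomArray
    source: str = ""
    default_chain: str | None = None

    def __post_init__(self):
        if self.default_chain is None:
            aa = self.atoms[struc.filter_amino_acids(self.atoms)]
            if len(aa):
                chains, counts = np.unique(aa.chain_id, return_counts=True)
                self.default_chain = str(chains[np.argmax(counts)])
                logger.info("%s: default chain = %r (longest protein chain)",
                            self.source or "structure", self.default_chain)

    @classmethod
    def from_pdb(cls, path, chain=None):
        pdb = PDBFile.read(str(path))
        atoms = pdb.get_structure(model=1, altloc="occupancy")
        return cls(atoms=atoms, source=str(path), default_chain=chain)

    def to_pdb(self, path):
        pdb = PDBFile()
        pdb.set_structure(self.atoms)
        pdb.write(str(path))

    def _mask(self, res_id, atom_name=None, chain=None, ins_code=None):
        chain = self.default_chain if chain is None else chain
        m = (self.atoms.res_id == res_id)
        if chain is not None:
            m &= self.atoms.chain_id == chain
        if atom_name is not None:
            m &= self.atoms.atom_name == atom_name
        if ins_code is not None and "ins_code" in \
                self.atoms.get_annotation_categories():
            m &= self.atoms.ins_code == ins_code
        return m

    def get_coord(self, res_id, atom_name, chain=None, ins_code=None):
        m = self._mask(res_id, atom_name, chain, ins_code)
        n = int(np.count_nonzero(m))
        if n == 0:
            raise KeyError(f"atom not found: chain "
                           f"{chain or self.default_chain!r}, residue "
                           f"{res_id}, atom {atom_name!r}")
        if n > 1:
            raise KeyError(f"ambiguous address: chain "
                           f"{chain or self.default_chain!r}, residue "
                           f"{res_id}, atom {atom_name!r} matches {n} atoms")
        return self.atoms.coord[m][0].astype(float)

    def select(self, triples):
        """Coordinates (n, 3) for a list of (chain, res_id, atom_name);
        chain None uses the default chain."""
        return np.array([self.get_coord(r, a, chain=c)
                         for c, r, a in triples])

    def backbone_selection(self, res_ranges, chain=None):
        """(chain, res_id, atom_name) triples of backbone N, CA, C, O atoms
        in the given inclusive residue ranges, ordered by residue."""
        chain = self.default_chain if chain is None else chain
        triples = []
        for lo, hi in res_ranges:
            for res in range(lo, hi + 1):
                for name in ("N", "CA", "C", "O"):
                    if np.any(self._mask(res, name, chain)):
                        triples.append((chain, res, name))
        return triples


def make_synthetic_filter_structure() -> StructureModel:
    """Synthetic miniature stand-in for a Nav selectivity-filter structure.

    Places the CA and side-chain tip atoms of the DEKA (D384, E942, K1422,
    A1714) and EEDD (E387, E945, D1426, D1717) residues of the four repeats
    around a pore axis at plausible filter-like radii, plus the CA atoms of
    residues 939/940 used by the region-bound rule.  This is *synthetic*
    geometry for exercising the analysis operations; it is not derived from
    any deposited structure.
    """
    spec = [  # (res_id, res_name, atom_name, radius A, z A, azimuth deg)
        (384, "ASP", "CA", 5.4, 10.0, 0), (384, "ASP", "CG", 4.0, 10.4, 0),
        (942, "GLU", "CA", 6.0, 11.0, 90), (942, "GLU", "CD", 4.4, 11.3, 90),
        (1422, "LYS", "CA", 5.4, 10.2, 180), (1422, "LYS", "CE", 3.2, 10.8, 180),
        (1422, "LYS", "NZ", 2.6, 11.2, 180),
        (1714, "ALA", "CA", 6.0, 10.8, 270), (1714, "ALA", "CB", 5.1, 11.1, 270),
        (387, "GLU", "CA", 9.0, 15.0, 10), (387, "GLU", "CD", 6.6, 15.5, 10),
        (945, "GLU", "CA", 8.8, 15.4, 100), (945, "GLU", "CD", 6.9, 15.8, 100),
        (1426, "ASP", "CA", 8.9, 15.2, 190), (1426, "ASP", "CG", 6.5, 15.6, 190),
        (1717, "ASP", "CA", 8.7, 15.3, 280), (1717, "ASP", "CG", 6.8, 15.7, 280),
        (939, "GLU", "CA", 8.0, 17.0, 45), (940, "GLY", "CA", 7.8, 16.0, 135),
    ]
    atoms = struc.AtomArray(len(spec))
    for i, (rid, rname, aname, rad, zz, az) in enumerate(spec):
        phi = np.deg2rad(az)
        atoms.coord[i] = (rad * np.cos(phi), rad * np.sin(phi), zz)
        atoms.chain_id[i] = "A"
        atoms.res_id[i] = rid
        atoms.res_name[i] = rname
        atoms.atom_name[i] = aname
        atoms.element[i] = aname[0]
        atoms.hetero[i] = False
    return StructureModel(atoms=atoms, source="synthetic_filter",
                          default_chain="A")


# ----------------------------------------------------------------------
# cross distances
# ----------------------------------------------------------------------

@dataclass
class CrossDistanceDef:
    """A labelled atom-pair distance, e.g. d1A: E387 CA vs D1426 CA."""

    label: str
    atom_a: tuple  # (res_id, atom_name)
    atom_b: tuple

#: Cross distances between opposite repeats of the C/SF: the EEDD pairs
#: (d1, d2) and the DEKA pairs (d3, d4); "A" variants use backbone CA
#: atoms, "B" variants the outermost side-chain carbons.
CROSS_DISTANCES = {
    "d1A": CrossDistanceDef("d1A", (387, "CA"), (1426, "CA")),
    "d1B": CrossDistanceDef("d1B", (387, "CD"), (1426, "CG")),
    "d2A": CrossDistanceDef("d2A", (945, "CA"), (1717, "CA")),
    "d2B": CrossDistanceDef("d2B", (945, "CD"), (1717, "CG")),
    "d3A": CrossDistanceDef("d3A", (384, "CA"), (1422, "CA")),
    "d3B": CrossDistanceDef("d3B", (384, "CG"), (1422, "CE")),
    "d4A": CrossDistanceDef("d4A", (942, "CA"), (1714, "CA")),
    "d4B": CrossDistanceDef("d4B", (942, "CD"), (1714, "CB")),
}

#: P-loop residue ranges per repeat (inclusive), by channel isoform.
P_LOOP_RANGES = {
    "nav1.1": ((368, 395), (938, 962), (1417, 1443), (1710, 1734)),
    "nav1.2": ((370, 397), (929, 955), (1408, 1434), (1700, 1724)),
    "nav1.6": ((354, 383), (922, 947), (1399, 1424), (1690, 1714)),
}


def cross_distance(structure: StructureModel, cdef: CrossDistanceDef,
                   chain=None) -> float:
    """Euclidean distance between the two addressed atoms, in A to 0.01."""
    a = structure.get_coord(*cdef.atom_a, chain=chain)
    b = structure.get_coord(*cdef.atom_b, chain=chain)
    return round(float(np.linalg.norm(a - b)), 2)


def cross_distance_table(structure: StructureModel, chain=None) -> dict:
    """All preset cross distances d1A..d4B on one structure."""
    return {label: cross_distance(structure, cdef, chain=chain)
            for label, cdef in CROSS_DISTANCES.items()}


# ----------------------------------------------------------------------
# superposition RMSD
# ----------------------------------------------------------------------

def superpose_rmsd(mobile: StructureModel, reference: StructureModel,
                   selection=None, return_transform: bool = False):
    """Least-squares rigid-body superposition RMSD over a selection.

    ``selection`` is a list of (chain, res_id, atom_name) triples resolved
    in both structures in the same order (all atoms of the mobile structure
    if omitted, which then requires matching addresses).  Returns the RMSD
    in A, optionally with the (rotation_matrix, translation) that maps the
    centered mobile onto the centered reference.
    """
    if selection is None:
        a = mobile.atoms
        selection = [(c, int(r), n) for c, r, n in
                     zip(a.chain_id, a.res_id, a.atom_name)]
    try:
        X = mobile.select(selection)
        Y = reference.select(selection)
    except KeyError as err:
        raise KeyError(f"selection not resolvable in both structures: "
                       f"{err}") from err
    if X.shape != Y.shape:
        raise ValueError("selected atom counts differ between structures")
    xc = X - X.mean(axis=0)
    yc = Y - Y.mean(axis=0)
    rot, rssd = Rotation.align_vectors(yc, xc)
    rmsd = float(rssd / np.sqrt(len(X)))
    if return_transform:
        t = Y.mean(axis=0) - rot.apply(X.mean(axis=0))
        return rmsd, (rot.as_matrix(), t)
    return rmsd


# ----------------------------------------------------------------------
# occupancy
# ----------------------------------------------------------------------

@dataclass
class OccupancyRegion:
    """Cylindrical C/SF region around the z axis; bounds inclusive."""

    radius: float = 7.0
    z_lower: float = 4.0
    z_upper: float = 17.0
    axis_xy: tuple = (0.0, 0.0)
    provenance: str = "explicit"

    def __post_init__(self):
        if self.z_lower >= self.z_upper:
            raise ValueError("z_lower must be < z_upper")
        if self.radius <= 0:
            raise ValueError("radius must be positive")

    @classmethod
    def from_reference_atoms(cls, structure: StructureModel, upper_atom,
                             lower_atom, upper_offset: float = 0.0,
                             lower_offset: float = -4.0,
                             radius: float = 7.0):
        """Bounds from reference-atom z coordinates.

        ``upper_atom``/``lower_atom`` are (chain, res_id, atom_name);
        offsets are added to the respective z values (the filter convention
        reduces the lower reference by 4 A).
        """
        cu, ru, au = upper_atom
        cl, rl, al = lower_atom
        zu = structure.get_coord(ru, au, chain=cu)[2] + upper_offset
        zl = structure.get_coord(rl, al, chain=cl)[2] + lower_offset
        return cls(radius=radius, z_lower=float(zl), z_upper=float(zu),
                   provenance=f"reference atoms {upper_atom}/{lower_atom}")

    def contains(self, xyz: np.ndarray) -> np.ndarray:
        """Boolean mask for points (..., 3); boundary inclusive."""
        xyz = np.asarray(xyz, dtype=float)
        dx = xyz[..., 0] - self.axis_xy[0]
        dy = xyz[..., 1] - self.axis_xy[1]
        r2 = dx * dx + dy * dy
        return ((r2 <= self.radius ** 2)
                & (xyz[..., 2] >= self.z_lower)
                & (xyz[..., 2] <= self.z_upper))


@dataclass
class OccupancySeries:
    """Per-frame counts of tracked species inside a region."""

    counts: np.ndarray
    times: np.ndarray

    def __post_init__(self):
        self.counts = np.asarray(self.counts)
        if np.any(self.counts < 0) or not np.issubdtype(self.counts.dtype,
                                                        np.integer):
            raise ValueError("counts must be non-negative integers")


def count_occupancy(traj: Trajectory, region: OccupancyRegion,
                    species) -> OccupancySeries:
    """Per-frame occupancy of the region by the selected particles."""
    species = tuple(species)
    if not species:
        raise ValueError("empty species selection")
    inside = np.zeros(traj.n_frames, dtype=int)
    for p in species:
        inside += region.contains(traj.particle_xyz(p)).astype(int)
    return OccupancySeries(counts=inside, times=traj.times)


def occupancy_table(series: OccupancySeries, max_count: int = 4) -> dict:
    """Occupancy statistics: percentage of frames at 0..max_count ions
    (counts above are pooled into the top bin), plus mean +- sd.

    The headline sd is the population one; the sample sd is also reported.
    """
    c = series.counts
    if len(c) == 0:
        raise ValueError("empty occupancy series")
    pooled = np.minimum(c, max_count)
    if np.any(c > max_count):
        logger.info("%d frames above occupancy %d pooled into the top bin",
                    int(np.sum(c > max_count)), max_count)
    percent = np.bincount(pooled, minlength=max_count + 1) / len(c) * 100.0
    return {
        "percent": percent,
        "mean": float(np.mean(c)),
        "sd_population": float(np.std(c)),
        "sd_sample": float(np.std(c, ddof=1)) if len(c) > 1 else 0.0,
        "n_frames": int(len(c)),
    }


def z_histogram(traj: Trajectory, selection, z_range=(3.0, 18.0),
                n_bins: int = 60, condition=None, density: bool = False):
    """Histogram of a selection's z coordinate over conditioned frames.

    ``selection`` is a particle index, a sequence of particle indices
    (pooled), or ``("com", indices)`` for their equal-weight center of
    mass.  ``condition`` is an optional boolean mask per frame (e.g. built
    from an occupancy predicate).  Returns (counts, bin_edges).
    """
    if n_bins < 1:
        raise ValueError("n_bins must be >= 1")
    mask = np.ones(traj.n_frames, dtype=bool) if condition is None \
        else np.asarray(condition, dtype=bool)
    if mask.shape != (traj.n_frames,):
        raise ValueError("condition mask must have one entry per frame")
    if not np.any(mask):
        warnings.warn("condition excludes every frame; empty histogram")
        return (np.zeros(n_bins, dtype=float),
                np.linspace(z_range[0], z_range[1], n_bins + 1))
    if isinstance(selection, tuple) and len(selection) == 2 \
            and selection[0] == "com":
        zvals = np.mean([traj.particle_xyz(p)[mask, 2]
                         for p in selection[1]], axis=0)
    elif np.ndim(selection) == 0:
        zvals = traj.particle_xyz(int(selection))[mask, 2]
    else:
        zvals = np.concatenate([traj.particle_xyz(int(p))[mask, 2]
                                for p in selection])
    counts, edges = np.histogram(zvals, bins=n_bins, range=tuple(z_range),
                                 density=density)
    return counts.astype(float), edges


def pool_trajectories(trajs) -> Trajectory:
    """Concatenate frames of runs with identical layouts (explicit pooling,
    provenance recorded), for aggregate histograms."""
    trajs = list(trajs)
    widths = {t.x_frames.shape[1] for t in trajs}
    if len(widths) != 1:
        raise ValueError("cannot pool trajectories with different layouts")
    offset = 0.0
    times = []
    for t in trajs:
        times.append(t.times + offset)
        offset = times[-1][-1] + (t.times[0] if len(t.times) else 1.0)
    return Trajectory(
        times=np.concatenate(times),
        x_frames=np.vstack([t.x_frames for t in trajs]),
        metadata={"pooled_from": [t.metadata for t in trajs]})
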