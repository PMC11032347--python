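"""Grid-based pocket detection with buriedness ray-casting and probe typing.

The detector lays a cubic lattice over a box centred on a reference (the
ligand for protein-ligand entries, the partner chain for heterodimers),
prunes points that clash with the target or drift into bulk solvent, and
scores each survivor by *buriedness*: the number of rays, out of a fixed
near-uniform spherical set, that hit a target heavy atom (van der Waals
sphere) within a finite range.  Retained buried points are eroded by a
minimum-neighbour rule, split into 26-connected components, and components
below the minimum size are dropped.  Each pocket point finally inherits a
pharmacophoric probe type from its nearest protein heavy atom.

Default parameters (1 A step, 20 A box, buriedness >= 65, >= 12 retained
neighbours, >= 20 points per cavity) target the shallow pockets typical of
protein-protein interfaces.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import ndimage
from scipy.spatial import cKDTree

from .models import AtomRecord, Cavity, ChainRecord, GridPoint, as_coord_array

__all__ = [
    "CavityParams",
    "VDW_RADII",
    "ray_directions",
    "build_grid",
    "buriedness",
    "buriedness_many",
    "detect_cavities",
    "assign_probes",
    "detect_pockets",
]

logger = logging.getLogger(__name__)

#: Van der Waals radii (A) by element; unknown elements default to 1.7 A.
VDW_RADII: dict[str, float] = {
    "H": 1.20, "D": 1.20, "C": 1.70, "N": 1.55, "O": 1.52, "S": 1.80,
    "P": 1.80, "F": 1.47, "Cl": 1.75, "Br": 1.85, "I": 1.98, "B": 1.92,
    "Se": 1.90,
}
DEFAULT_VDW = 1.70


@dataclass
class CavityParams:
    """Detection parameters.

    ``step`` and ``boxS`` are the lattice spacing and main-box edge (A);
    ``b`` the minimal buriedness (blocked-ray count) to retain a point;
    ``n`` the minimal number of retained 26-neighbours; ``nPTS`` the
    minimal component size; ``n_rays`` the size of the spherical ray set
    (120 so the burial scale runs 0..120); ``ray_range`` the maximal ray
    length and bulk-solvent distance (A); ``clash_distance`` the minimal
    allowed point-to-atom distance (A).
    """

    step: float = 1.0
    boxS: float = 20.0
    b: int = 65
    n: int = 12
    nPTS: int = 20
    n_rays: int = 120
    ray_range: float = 8.0
    clash_distance: float = 2.5

    def __post_init__(self) -> None:
        if self.step <= 0:
            raise ValueError("step must be > 0")
        if self.boxS < self.step:
            raise ValueError("boxS must be >= step")
        if not 0 <= self.b <= self.n_rays:
            raise ValueError("b must be in [0, n_rays]")
        if not 0 <= self.n <= 26:
            raise ValueError("n must be in [0, 26]")
        if self.nPTS < 1:
            raise ValueError("nPTS must be >= 1")


def ray_directions(n_rays: int = 120) -> np.ndarray:
    """Deterministic near-uniform unit directions (spherical Fibonacci set)."""
    i = np.arange(n_rays, dtype=float)
    golden = (1.0 + np.sqrt(5.0)) / 2.0
    z = 1.0 - (2.0 * i + 1.0) / n_rays
    theta = 2.0 * np.pi * i / golden
    r = np.sqrt(np.maximum(0.0, 1.0 - z * z))
    return np.column_stack([r * np.cos(theta), r * np.sin(theta), z])


def _target_coords(target: ChainRecord | Sequence[AtomRecord]) -> np.ndarray:
    if isinstance(target, ChainRecord):
        return target.heavy_coords()
    return as_coord_array([a for a in target if a.is_heavy])


@dataclass
class GridCandidates:
    """Candidate lattice points with their integer lattice indices."""

    coords: np.ndarray                 # (m, 3) in A
    indices: np.ndarray                # (m, 3) integer lattice offsets
    origin: np.ndarray                 # lattice origin (A)
    params: CavityParams
    buriedness: Optional[np.ndarray] = field(default=None)

    def __len__(self) -> int:
        return len(self.coords)


def build_grid(
    target: ChainRecord | Sequence[AtomRecord],
    reference: Sequence[AtomRecord] | np.ndarray,
    params: CavityParams | None = None,
) -> GridCandidates:
    """Candidate grid points in a box centred on the reference centroid.

    Points closer than ``clash_distance`` to any target heavy atom are
    removed, as are bulk-solvent points farther than ``ray_range`` from
    every target heavy atom.
    """
    params = params or CavityParams()
    ref = np.asarray(reference, dtype=float) if isinstance(reference, np.ndarray) \
        else as_coord_array(list(reference))
    if ref.size == 0:
        raise ValueError("empty reference atom set")
    center = ref.reshape(-1, 3).mean(axis=0)

    half = params.boxS / 2.0
    n_side = int(np.floor(half / params.step))
    offsets = np.arange(-n_side, n_side + 1)
    ii, jj, kk = np.meshgrid(offsets, offsets, offsets, indexing="ij")
    indices = np.column_stack([ii.ravel(), jj.ravel(), kk.ravel()])
    origin = center
    coords = origin + indices * params.step

    tcoords = _target_coords(target)
    if len(tcoords):
        tree = cKDTree(tcoords)
        dmin, _ = tree.query(coords, k=1)
        keep = (dmin > params.clash_distance) & (dmin <= params.ray_range)
        coords, indices = coords[keep], indices[keep]
    return GridCandidates(coords=coords, indices=indices, origin=origin,
                          params=params)


def _blocked_ray_count(point: np.ndarray, centers: np.ndarray, radii: np.ndarray,
                       dirs: np.ndarray, ray_range: float) -> int:
    """Rays from *point* that hit a sphere within [0, ray_range]."""
    if len(centers) == 0:
        return 0
    v = centers - point                      # (m, 3)
    d2 = np.einsum("ij,ij->i", v, v)
    inside = d2 <= radii**2
    if np.any(inside):
        return len(dirs)
    proj = dirs @ v.T                        # (n_rays, m)
    perp2 = d2[None, :] - proj**2
    disc = radii[None, :] ** 2 - perp2
    ok = disc >= 0
    t_hit = np.where(ok, proj - np.sqrt(np.maximum(disc, 0.0)), np.inf)
    hit = ok & (proj >= 0) & (t_hit <= ray_range)
    return int(np.count_nonzero(hit.any(axis=1)))


def buriedness(
    point: np.ndarray,
    target_atoms: Sequence[AtomRecord] | ChainRecord,
    params: CavityParams | None = None,
) -> int:
    """Buriedness of one point: blocked rays out of ``n_rays``."""
    params = params or CavityParams()
    atoms = target_atoms.heavy_atoms() if isinstance(target_atoms, ChainRecord) \
        else [a for a in target_atoms if a.is_heavy]
    centers = as_coord_array(atoms)
    radii = np.array([VDW_RADII.get(a.element, DEFAULT_VDW) for a in atoms])
    dirs = ray_directions(params.n_rays)
    return _blocked_ray_count(np.asarray(point, float), centers, radii, dirs,
                              params.ray_range)


def buriedness_many(
    grid: GridCandidates,
    target: ChainRecord | Sequence[AtomRecord],
) -> GridCandidates:
    """Score every candidate point, storing results on the grid (in place)."""
    params = grid.params
    atoms = target.heavy_atoms() if isinstance(target, ChainRecord) \
        else [a for a in target if a.is_heavy]
    centers = as_coord_array(atoms)
    radii = np.array([VDW_RADII.get(a.element, DEFAULT_VDW) for a in atoms])
    dirs = ray_directions(params.n_rays)
    scores = np.zeros(len(grid), dtype=int)
    if len(centers):
        # only atoms within ray_range + vdW of the point can block a ray
        tree = cKDTree(centers)
        reach = params.ray_range + float(radii.max(initial=DEFAULT_VDW))
        neighbours = tree.query_ball_point(grid.coords, reach)
        for i, (pt, idx) in enumerate(zip(grid.coords, neighbours)):
            if idx:
                sel = np.asarray(idx)
                scores[i] = _blocked_ray_count(pt, centers[sel], radii[sel],
                                               dirs, params.ray_range)
    grid.buriedness = scores
    return grid


_CONN26 = np.ones((3, 3, 3), dtype=int)


def _dense_mask(indices: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    lo = indices.min(axis=0)
    shape = indices.max(axis=0) - lo + 1
    mask = np.zeros(shape, dtype=bool)
    shifted = indices - lo
    mask[tuple(shifted.T)] = True
    return mask, lo


def detect_cavities(grid: GridCandidates,
                    params: CavityParams | None = None) -> list[Cavity]:
    """Cluster buried grid points into ranked cavities.

    Points with buriedness below ``b`` are discarded; the survivors are
    iteratively eroded until every point keeps at least ``n`` retained
    26-neighbours; 26-connected components smaller than ``nPTS`` are
    dropped and the rest are ranked by size (ties by centroid x, y, z) as
    CAVITY_N1, CAVITY_N2, ...
    """
    params = params or grid.params
    if grid.buriedness is None:
        raise ValueError("buriedness not computed for the candidate grid")
    keep = grid.buriedness >= params.b
    coords = grid.coords[keep]
    indices = grid.indices[keep]
    scores = grid.buriedness[keep]
    if len(coords) == 0:
        return []

    mask, lo = _dense_mask(indices)
    while True:
        neigh = ndimage.convolve(mask.astype(np.int8), _CONN26, mode="constant") \
            - mask.astype(np.int8)
        new_mask = mask & (neigh >= params.n)
        if np.array_equal(new_mask, mask):
            break
        mask = new_mask
    if not mask.any():
        return []

    labels, n_comp = ndimage.label(mask, structure=_CONN26)
    shifted = indices - lo
    point_labels = labels[tuple(shifted.T)]

    cavities = []
    for comp in range(1, n_comp + 1):
        sel = point_labels == comp
        if int(sel.sum()) < params.nPTS:
            continue
        c_coords = coords[sel]
        c_scores = scores[sel]
        order = np.lexsort((c_coords[:, 2], c_coords[:, 1], c_coords[:, 0]))
        points = [GridPoint(coords=c_coords[i], buriedness=int(c_scores[i]))
                  for i in order]
        cavities.append((len(points), tuple(c_coords.mean(axis=0)), points))
    # largest first; centroid x, y, z breaks ties reproducibly
    cavities.sort(key=lambda t: (-t[0], t[1]))
    return [
        Cavity(cavity_id=f"CAVITY_N{k}", points=points, step=params.step)
        for k, (_, _, points) in enumerate(cavities, start=1)
    ]


# ---------------------------------------------------------------------------
# pharmacophoric probe typing


def _pharmacophore_table() -> dict[tuple[str, str], str]:
    """(residue, atom name) -> probe label for the 20 standard residues."""
    table: dict[tuple[str, str], str] = {}
    residues = ["ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS",
                "ILE", "LEU", "LYS", "MET", "PHE", "PRO", "SER", "THR", "TRP",
                "TYR", "VAL"]
    backbone = {"N": "N", "O": "O", "OXT": "OD1", "C": "CA", "CA": "CA"}
    for res in residues:
        for at, probe in backbone.items():
            table[(res, at)] = probe
    aromatic = {
        "PHE": ["CG", "CD1", "CD2", "CE1", "CE2", "CZ"],
        "TYR": ["CG", "CD1", "CD2", "CE1", "CE2", "CZ"],
        "TRP": ["CG", "CD1", "CD2", "NE1", "CE2", "CE3", "CZ2", "CZ3", "CH2"],
        "HIS": ["CG", "CD2", "CE1"],
    }
    for res, names in aromatic.items():
        for at in names:
            table[(res, at)] = "CZ"
    table[("TRP", "NE1")] = "N"          # indole NH donates
    side = {
        ("ASP", "OD1"): "OD1", ("ASP", "OD2"): "OD1",
        ("GLU", "OE1"): "OD1", ("GLU", "OE2"): "OD1",
        ("ASN", "OD1"): "O", ("ASN", "ND2"): "N",
        ("GLN", "OE1"): "O", ("GLN", "NE2"): "N",
        ("SER", "OG"): "OG", ("THR", "OG1"): "OG", ("TYR", "OH"): "OG",
        ("LYS", "NZ"): "NZ",
        ("ARG", "NE"): "NZ", ("ARG", "NH1"): "NZ", ("ARG", "NH2"): "NZ",
        ("HIS", "ND1"): "NZ", ("HIS", "NE2"): "NZ",
        ("CYS", "SG"): "CA", ("MET", "SD"): "CA",
    }
    table.update(side)
    return table


_PHARMACOPHORES = _pharmacophore_table()


def _probe_for_atom(resname: str, atom: AtomRecord) -> str:
    probe = _PHARMACOPHORES.get((resname, atom.name))
    if probe is not None:
        return probe
    # side-chain carbons and anything aliphatic default to hydrophobic
    if atom.element == "C":
        return "CA"
    logger.warning("no pharmacophore rule for %s/%s; typing as DU",
                   resname, atom.name)
    return "DU"


def assign_probes(cavity: Cavity, target: ChainRecord,
                  max_distance: float = 4.0) -> Cavity:
    """Type each cavity point from its nearest target heavy atom.

    Points with no protein heavy atom within ``max_distance`` (A) become
    dummy (DU) probes.  Modifies the cavity in place and returns it.
    """
    atoms = target.heavy_atoms()
    resnames = [r.name for r in target.residues for a in r.atoms if a.is_heavy]
    coords = as_coord_array(atoms)
    if len(coords) == 0:
        for p in cavity.points:
            p.probe = "DU"
        return cavity
    tree = cKDTree(coords)
    dmin, nearest = tree.query(cavity.coords(), k=1)
    for point, d, j in zip(cavity.points, dmin, nearest):
        point.probe = _probe_for_atom(resnames[j], atoms[j]) if d <= max_distance \
            else "DU"
    return cavity


def detect_pockets(
    target: ChainRecord,
    reference: Sequence[AtomRecord] | np.ndarray,
    params: CavityParams | None = None,
) -> list[Cavity]:
    """Full detection: grid, buriedness, clustering and probe typing."""
    params = params or CavityParams()
    grid = build_grid(target, reference, params)
    buriedness_many(grid, target)
    cavities = detect_cavities(grid, params)
    for cav in cavities:
        assign_probes(cav, target)
    return cavities
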