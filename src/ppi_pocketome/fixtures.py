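"""Synthetic toy structures and descriptor tables with known ground truth.

Real curated structures cannot ship with the package, so every pipeline
stage is exercised on geometrically controlled fixtures:

* a *toy heterodimer* — chain A is a spherical shell of pseudo-atoms with a
  conical aperture forming a concave pocket, chain B a convex plug seated
  in the pocket mouth.  Chain A also carries a second, outward-facing bowl
  on the far side of the shell, so liganded fixtures can place a ligand in
  a genuinely non-interface (allosteric) site.
* a *toy liganded monomer* — chain A alone plus a rigid six-carbon ring
  whose closest approach to the partner epitope is calibrated to a
  requested offset, for exercising the competitive / non-competitive /
  allosteric classification.
* a *descriptor sample* — Gaussian clusters in descriptor space with
  planted per-column zero fractions, for the descriptor-processing and
  similarity stages.

All generators are pure functions of their spec (seed included).
Pseudo-atoms are carbon in ALA residues on Fibonacci-sphere lattices:
the fixtures favour geometric controllability over chemical realism.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .models import (
    AtomRecord,
    ChainRecord,
    ExperimentalMethod,
    LigandRecord,
    ResidueRecord,
    StructureEntry,
)

__all__ = [
    "ToyComplexSpec",
    "DescriptorSampleSpec",
    "make_toy_heterodimer",
    "make_toy_liganded",
    "make_descriptor_sample",
]

#: Synthetic accessions for the two toy chains.
TOY_UNIPROT_A = "Q99901"
TOY_UNIPROT_B = "Q99902"
#: Half-angle (degrees) of the pocket aperture cone.
APERTURE_DEG = 60.0


@dataclass
class ToyComplexSpec:
    """Geometry of the toy complex.

    ``pocket_radius`` is the inner shell radius (A); ``wall_thickness`` the
    radial separation of the two shell layers (A); ``ligand_offset`` the
    requested closest approach between ligand and partner epitope (A);
    ``n_wall_atoms`` the atom count of the inner shell layer.
    """

    pocket_radius: float = 6.0
    wall_thickness: float = 2.0
    ligand_offset: float = 0.5
    n_wall_atoms: int = 350
    seed: int = 0

    def __post_init__(self) -> None:
        if self.pocket_radius <= 0:
            raise ValueError("pocket_radius must be > 0")
        if self.wall_thickness >= self.pocket_radius:
            raise ValueError("wall_thickness must be < pocket_radius")
        if self.n_wall_atoms < 50:
            raise ValueError("n_wall_atoms must be >= 50")


@dataclass
class DescriptorSampleSpec:
    """Planted-cluster descriptor sample.

    ``cluster_separation`` and ``noise_sd`` are in standardized descriptor
    units; ``zero_fraction_per_column`` gives, per leading column, the
    exact fraction of rows forced to zero.
    """

    n_pockets: int = 60
    n_descriptors: int = 20
    n_clusters: int = 2
    cluster_separation: float = 6.0
    noise_sd: float = 1.0
    zero_fraction_per_column: list[float] = field(default_factory=list)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_clusters < 1:
            raise ValueError("n_clusters must be >= 1")
        if self.cluster_separation < 0:
            raise ValueError("cluster_separation must be >= 0")
        if self.n_descriptors < self.n_clusters:
            raise ValueError("need n_descriptors >= n_clusters")
        if any(not 0 <= p <= 1 for p in self.zero_fraction_per_column):
            raise ValueError("zero fractions must be in [0, 1]")


def _fibonacci_sphere(n: int) -> np.ndarray:
    i = np.arange(n, dtype=float)
    golden = (1.0 + np.sqrt(5.0)) / 2.0
    z = 1.0 - (2.0 * i + 1.0) / n
    theta = 2.0 * np.pi * i / golden
    r = np.sqrt(np.maximum(0.0, 1.0 - z * z))
    return np.column_stack([r * np.cos(theta), r * np.sin(theta), z])


def _bowl_coords(radius: float, wall: float, n_atoms: int, axis_sign: float,
                 center: np.ndarray) -> np.ndarray:
    """Two concentric shell layers minus an aperture cone around +-z."""
    cos_ap = np.cos(np.deg2rad(APERTURE_DEG))
    layers = []
    for r, n in ((radius, n_atoms), (radius + wall, int(n_atoms * 1.4))):
        dirs = _fibonacci_sphere(n)
        keep = axis_sign * dirs[:, 2] < cos_ap   # outside the aperture cone
        layers.append(center + r * dirs[keep])
    return np.vstack(layers)


def _make_chain(chain_id: str, uniprot: str, coords: np.ndarray,
                atoms_per_residue: int = 4) -> ChainRecord:
    chain = ChainRecord(chain_id=chain_id, uniprot_id=uniprot)
    for start in range(0, len(coords), atoms_per_residue):
        resnum = start // atoms_per_residue + 1
        residue = ResidueRecord(name="ALA", number=resnum)
        for j, xyz in enumerate(coords[start:start + atoms_per_residue]):
            residue.atoms.append(
                AtomRecord(name="CA" if j == 0 else f"CB{j}"[:4], element="C",
                           coords=xyz)
            )
        chain.residues.append(residue)
    return chain


def _toy_coords(spec: ToyComplexSpec) -> tuple[np.ndarray, np.ndarray]:
    """Chain A (pocket bowl + far-face allosteric bowl) and chain B plug."""
    rng = np.random.default_rng(spec.seed)
    R = spec.pocket_radius
    bowl_main = _bowl_coords(R, spec.wall_thickness, spec.n_wall_atoms,
                             axis_sign=+1.0, center=np.zeros(3))
    allo_center = np.array([0.0, 0.0, -(2 * R + spec.wall_thickness + 2.0)])
    bowl_allo = _bowl_coords(R, spec.wall_thickness, spec.n_wall_atoms,
                             axis_sign=-1.0, center=allo_center)
    chain_a = np.vstack([bowl_main, bowl_allo])
    # small deterministic jitter breaks lattice symmetry
    chain_a = chain_a + rng.normal(scale=0.05, size=chain_a.shape)

    plug_center = np.array([0.0, 0.0, 0.9 * R])
    plug = np.vstack([
        plug_center + 0.6 * R * _fibonacci_sphere(max(60, spec.n_wall_atoms // 4)),
        plug_center + 0.3 * R * _fibonacci_sphere(30),
        plug_center[None, :],
    ])
    plug = plug + rng.normal(scale=0.05, size=plug.shape)
    return chain_a, plug


def make_toy_heterodimer(spec: ToyComplexSpec) -> StructureEntry:
    """Two-chain complex with a concave interface pocket of known centre.

    Chain A is the shell (pocket centred at the origin, opening towards
    +z); chain B is the plug occupying the pocket mouth.  The chains carry
    distinct synthetic UniProt accessions and X-ray-like metadata that
    passes the quality filters.
    """
    chain_a_coords, plug_coords = _toy_coords(spec)
    entry = StructureEntry(
        entry_id="9hda",
        method=ExperimentalMethod.XRAY,
        resolution=2.0,
        r_free_minus_r_factor=0.03,
        chains=[
            _make_chain("A", TOY_UNIPROT_A, chain_a_coords),
            _make_chain("B", TOY_UNIPROT_B, plug_coords),
        ],
    )
    return entry


def _hexagon_ring(bond: float = 1.39) -> np.ndarray:
    ang = np.deg2rad(np.arange(6) * 60.0)
    return np.column_stack([bond * np.cos(ang), bond * np.sin(ang),
                            np.zeros(6)])


def _epitope_coords(partner: StructureEntry, threshold: float = 6.0) -> np.ndarray:
    """Partner (chain B) heavy atoms within *threshold* of chain A."""
    from scipy.spatial import cKDTree

    a = partner.chain("A").heavy_coords()
    b = partner.chain("B").heavy_coords()
    dmin, _ = cKDTree(a).query(b, k=1)
    epi = b[dmin <= threshold]
    return epi if len(epi) else b


def make_toy_liganded(
    spec: ToyComplexSpec,
    partner: StructureEntry,
    site: str = "orthosteric",
) -> StructureEntry:
    """Monomer copy of chain A plus a rigid six-carbon ring ligand.

    For ``site="orthosteric"`` the ring is slid down the pocket axis until
    its closest approach to the partner epitope (chain B atoms within 6 A
    of chain A) equals ``spec.ligand_offset`` to within 0.05 A.  For
    ``site="allosteric"`` the ring is placed in the far-face bowl, well
    away from the interface.
    """
    if spec.ligand_offset < 0:
        raise ValueError("ligand_offset must be >= 0")
    if site not in ("orthosteric", "allosteric"):
        raise ValueError(f"unknown site {site!r}")

    chain_a = partner.chain("A")
    ring = _hexagon_ring()
    if site == "orthosteric":
        epitope = _epitope_coords(partner)

        def min_dist(z: float) -> float:
            pts = ring + np.array([0.0, 0.0, z])
            d = np.linalg.norm(epitope[:, None, :] - pts[None, :, :], axis=2)
            return float(d.min())

        # slide the ring down the pocket axis from inside the plug until the
        # closest approach to the epitope first exceeds the requested offset,
        # then refine the crossing
        f = lambda z: min_dist(z) - spec.ligand_offset
        z_top = float(epitope[:, 2].min()) + 2.0
        zs = z_top - np.arange(0.0, 20.0, 0.1)
        z_star = None
        for z_prev, z_next in zip(zs[:-1], zs[1:]):
            if f(z_prev) < 0 <= f(z_next):
                z_star = brentq(f, z_prev, z_next, xtol=1e-4)
                break
        if z_star is None:
            raise ValueError(
                f"could not place ligand at offset {spec.ligand_offset} A"
            )
        ring = ring + np.array([0.0, 0.0, z_star])
    else:
        allo_center = np.array(
            [0.0, 0.0, -(2 * spec.pocket_radius + spec.wall_thickness + 2.0)]
        )
        ring = ring + allo_center

    ligand = LigandRecord(
        het_code="TOY",
        residue_number=500,
        chain_id="A",
        atoms=[AtomRecord(name=f"C{i + 1}", element="C", coords=xyz,
                          is_hetero=True)
               for i, xyz in enumerate(ring)],
    )
    entry = StructureEntry(
        entry_id="9pla" if site == "allosteric" else "9plo",
        method=ExperimentalMethod.XRAY,
        resolution=2.0,
        r_free_minus_r_factor=0.03,
        chains=[ChainRecord(chain_id="A", uniprot_id=chain_a.uniprot_id,
                            residues=[ResidueRecord(r.name, r.number,
                                                    list(r.atoms))
                                      for r in chain_a.residues])],
        ligands=[ligand],
    )
    return entry


def make_descriptor_sample(
    spec: DescriptorSampleSpec,
) -> tuple[pd.DataFrame, np.ndarray]:
    """Gaussian planted clusters with exact per-column zero fractions.

    Returns a (pockets x descriptors) table and the true cluster label of
    each row.  Cluster centres sit at ``separation / sqrt(2)`` along
    orthogonal axes, so every pair of centres is ``separation`` apart.
    Column ``j`` listed in ``zero_fraction_per_column`` has exactly
    ``round(fraction * n_pockets)`` of its entries forced to zero.
    """
    rng = np.random.default_rng(spec.seed)
    centers = np.zeros((spec.n_clusters, spec.n_descriptors))
    for k in range(spec.n_clusters):
        centers[k, k] = spec.cluster_separation / np.sqrt(2.0)
    labels = np.arange(spec.n_pockets) % spec.n_clusters
    x = centers[labels] + rng.normal(scale=spec.noise_sd,
                                     size=(spec.n_pockets, spec.n_descriptors))
    for j, frac in enumerate(spec.zero_fraction_per_column):
        n_zero = int(round(frac * spec.n_pockets))
        rows = rng.choice(spec.n_pockets, size=n_zero, replace=False)
        x[rows, j] = 0.0
    cols = [f"D{j + 1:03d}" for j in range(spec.n_descriptors)]
    ids = [f"pocket{(i + 1):04d}" for i in range(spec.n_pockets)]
    return pd.DataFrame(x, index=ids, columns=cols), labels
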