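"""Interface patches and pocket/ligand classification.

The interaction patch between two chains is the set of target heavy atoms
within a Euclidean distance threshold (6 A by default) of any partner
heavy atom.  A detected cavity is *orthosteric* when at least half of its
grid points lie within that threshold of the partner.  Liganded pockets
are classified against the partner epitope of the aligned heterodimer:
competitive (PLOC) when the ligand's closest approach to the epitope is
within 1 A, non-competitive (PLONC) when it is farther, and allosteric
(PLA) when the pocket is not orthosteric at all.

Distances use heavy atoms only, keeping heterodimer and protein-ligand
entries on the same footing regardless of protonation state.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.spatial import cKDTree
from scipy.spatial.transform import Rotation

from .models import (
    AtomRecord,
    Cavity,
    ChainRecord,
    LigandRecord,
    PocketClass,
    ResidueRecord,
    StructureEntry,
    as_coord_array,
)

__all__ = [
    "InterfacePatch",
    "interface_patch",
    "ligand_interface_residues",
    "is_orthosteric",
    "classify_ligand_pocket",
    "superpose_pl_on_hd",
]

DEFAULT_THRESHOLD = 6.0
OCCUPANCY_DISTANCE = 2.0  # ligand heavy atom to cavity point (A)


@dataclass
class InterfacePatch:
    """Target-chain atoms in contact with the partner chain."""

    target_chain: str
    partner_chain: str
    threshold: float
    atoms: list[AtomRecord] = field(default_factory=list)
    residues: list[ResidueRecord] = field(default_factory=list)


def interface_patch(
    target: ChainRecord,
    partner: ChainRecord,
    threshold: float = DEFAULT_THRESHOLD,
) -> InterfacePatch:
    """Target heavy atoms within *threshold* of any partner heavy atom."""
    partner_coords = partner.heavy_coords()
    target_atoms = target.heavy_atoms()
    if not target_atoms or not len(partner_coords):
        raise ValueError("interface_patch requires heavy atoms on both chains")
    tree = cKDTree(partner_coords)
    dmin, _ = tree.query(as_coord_array(target_atoms), k=1)
    keep = dmin <= threshold

    patch = InterfacePatch(target_chain=target.chain_id,
                           partner_chain=partner.chain_id,
                           threshold=threshold)
    selected = {id(a) for a, k in zip(target_atoms, keep) if k}
    for res in target.residues:
        hit = [a for a in res.atoms if id(a) in selected]
        if hit:
            patch.atoms.extend(hit)
            patch.residues.append(res)
    return patch


def ligand_interface_residues(
    protein: ChainRecord,
    lig: LigandRecord,
    threshold: float = DEFAULT_THRESHOLD,
) -> list[ResidueRecord]:
    """Residues with a heavy atom within *threshold* of a ligand heavy atom."""
    lig_coords = lig.heavy_coords()
    if not len(lig_coords):
        raise ValueError("ligand has no heavy atoms")
    tree = cKDTree(lig_coords)
    residues = []
    for res in protein.residues:
        coords = as_coord_array(res.heavy_atoms())
        if len(coords):
            dmin, _ = tree.query(coords, k=1)
            if np.any(dmin <= threshold):
                residues.append(res)
    return residues


def is_orthosteric(
    cavity: Cavity,
    partner: ChainRecord | Sequence[AtomRecord] | np.ndarray,
    threshold: float = DEFAULT_THRESHOLD,
    min_fraction: float = 0.5,
) -> bool:
    """True iff at least *min_fraction* of cavity points lie within
    *threshold* of a partner heavy atom."""
    if len(cavity) == 0:
        raise ValueError("empty cavity")
    if isinstance(partner, ChainRecord):
        coords = partner.heavy_coords()
    elif isinstance(partner, np.ndarray):
        coords = partner.reshape(-1, 3)
    else:
        coords = as_coord_array([a for a in partner if a.is_heavy])
    if not len(coords):
        raise ValueError("partner has no heavy atoms")
    dmin, _ = cKDTree(coords).query(cavity.coords(), k=1)
    return float(np.mean(dmin <= threshold)) >= min_fraction


def classify_ligand_pocket(
    cavity: Cavity,
    lig: LigandRecord,
    partner_epitope: Sequence[AtomRecord] | np.ndarray,
    ortho: bool,
    cutoff: float = 1.0,
) -> PocketClass:
    """PLOC / PLONC / PLA classification of a liganded pocket.

    The ligand must occupy the cavity (some heavy atom within 2 A of a
    cavity point).  An orthosteric pocket is competitive when the minimal
    ligand-to-epitope heavy-atom distance is within *cutoff* (1 A),
    non-competitive otherwise; a non-orthosteric pocket is allosteric.
    """
    lig_coords = lig.heavy_coords()
    if not len(lig_coords):
        raise ValueError("ligand has no heavy atoms")
    dmin, _ = cKDTree(cavity.coords()).query(lig_coords, k=1)
    if not np.any(dmin <= OCCUPANCY_DISTANCE):
        raise ValueError("ligand/cavity mismatch: ligand does not occupy cavity")
    if not ortho:
        return PocketClass.PLA
    if isinstance(partner_epitope, np.ndarray):
        epi = partner_epitope.reshape(-1, 3)
    else:
        epi = as_coord_array([a for a in partner_epitope if a.is_heavy])
    if not len(epi):
        raise ValueError("empty partner epitope")
    d = cKDTree(epi).query(lig_coords, k=1)[0]
    return PocketClass.PLOC if float(d.min()) <= cutoff else PocketClass.PLONC


def _common_ca(chain_a: ChainRecord, chain_b: ChainRecord) -> tuple[np.ndarray, np.ndarray]:
    def ca_map(chain: ChainRecord) -> dict[int, np.ndarray]:
        out = {}
        for res in chain.residues:
            for atom in res.atoms:
                if atom.name == "CA" and atom.is_heavy:
                    out[res.number] = atom.coords
                    break
        return out

    ca_a, ca_b = ca_map(chain_a), ca_map(chain_b)
    shared = sorted(set(ca_a) & set(ca_b))
    if len(shared) < 3:
        raise ValueError("fewer than 3 common CA residues for superposition")
    return (np.array([ca_a[i] for i in shared]),
            np.array([ca_b[i] for i in shared]))


def superpose_pl_on_hd(
    pl: StructureEntry,
    hd: StructureEntry,
    shared_uniprot: str,
) -> tuple[StructureEntry, float]:
    """Least-squares superposition of the shared chain's CA atoms.

    Transforms every PL coordinate (in place on a copy) into the HD frame
    and returns the transformed entry with the CA RMSD.
    """
    def chain_for(entry: StructureEntry) -> ChainRecord:
        for ch in entry.chains:
            if ch.uniprot_id == shared_uniprot:
                return ch
        raise ValueError(
            f"{entry.entry_id}: no chain mapped to {shared_uniprot}")

    mobile_chain = chain_for(pl)
    fixed_chain = chain_for(hd)
    mobile, fixed = _common_ca(mobile_chain, fixed_chain)

    mob_c, fix_c = mobile.mean(axis=0), fixed.mean(axis=0)
    rot, _ = Rotation.align_vectors(fixed - fix_c, mobile - mob_c)

    def transform(x: np.ndarray) -> np.ndarray:
        return rot.apply(x - mob_c) + fix_c

    rmsd = float(np.sqrt(np.mean(
        np.sum((transform(mobile) - fixed) ** 2, axis=1))))

    moved = StructureEntry(
        entry_id=pl.entry_id, method=pl.method, resolution=pl.resolution,
        r_free_minus_r_factor=pl.r_free_minus_r_factor, fsc=pl.fsc,
        chains=[
            ChainRecord(ch.chain_id, ch.uniprot_id, [
                ResidueRecord(r.name, r.number, [
                    AtomRecord(a.name, a.element, transform(a.coords),
                               a.altloc, a.is_hetero)
                    for a in r.atoms
                ]) for r in ch.residues
            ]) for ch in pl.chains
        ],
        ligands=[
            LigandRecord(lg.het_code, lg.residue_number, lg.chain_id, [
                AtomRecord(a.name, a.element, transform(a.coords),
                           a.altloc, a.is_hetero)
                for a in lg.atoms
            ], lg.pdb_occurrence) for lg in pl.ligands
        ],
    )
    return moved, rmsd
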