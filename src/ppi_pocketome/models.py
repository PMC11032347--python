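"""Core in-memory containers for structures, cavities and pockets.

The unit of curation is a :class:`StructureEntry`: one PDB entry with its
chains, ligands and the experimental metadata the quality filters need
(method, resolution, R-free minus R-factor, Fourier shell correlation).
Pockets are represented as :class:`Cavity` objects — sets of cubic-grid
points ("negative image" pseudo-atoms) with a per-point buriedness score
and a pharmacophoric probe label inherited from the nearest protein atom.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Iterator, Optional, Sequence

import numpy as np

__all__ = [
    "ExperimentalMethod",
    "AtomRecord",
    "ResidueRecord",
    "ChainRecord",
    "LigandRecord",
    "StructureEntry",
    "GridPoint",
    "Cavity",
    "PROBE_TYPES",
    "HYDROGEN_ELEMENTS",
    "PocketClass",
]

#: Pharmacophoric probe vocabulary, in canonical column order.
#: CA hydrophobic, CZ aromatic, O H-bond acceptor, OD1 anionic acceptor,
#: OG donor/acceptor, N donor, NZ cationic, DU dummy (no protein contact).
PROBE_TYPES: tuple[str, ...] = ("CA", "CZ", "O", "OD1", "OG", "N", "NZ", "DU")

#: Elements treated as hydrogen for heavy-atom logic (deuterium included).
HYDROGEN_ELEMENTS = frozenset({"H", "D"})


class ExperimentalMethod(enum.Enum):
    """Structure determination technique, as reported in entry metadata."""

    XRAY = "XRAY"
    CRYOEM = "CRYOEM"
    NMR = "NMR"
    OTHER = "OTHER"


class PocketClass(enum.Enum):
    """Pocket class vocabulary.

    Heterodimer pockets are orthosteric (at the partner interface) or not;
    liganded pockets are competitive-orthosteric (PLOC, ligand within 1 A of
    the partner epitope), non-competitive orthosteric (PLONC) or allosteric
    (PLA, outside the interface pocket).
    """

    HD_ORTHOSTERIC = "orthosteric"
    HD_NONORTHOSTERIC = "nonorthosteric"
    PLOC = "liganded_orthosteric_competitive"
    PLONC = "liganded_orthosteric_noncompetitive"
    PLA = "liganded_allosteric"
    UNLIGANDED = "unliganded"


@dataclass
class AtomRecord:
    """One ATOM/HETATM record."""

    name: str
    element: str
    coords: np.ndarray
    altloc: str = ""
    is_hetero: bool = False

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.shape != (3,):
            raise ValueError(f"atom {self.name!r}: coords must be a 3-vector")
        if not np.all(np.isfinite(self.coords)):
            raise ValueError(f"atom {self.name!r}: non-finite coordinates")
        self.element = self.element.strip().capitalize()
        if not self.element or not self.element[0].isalpha():
            raise ValueError(f"atom {self.name!r}: bad element {self.element!r}")

    @property
    def is_heavy(self) -> bool:
        return self.element not in HYDROGEN_ELEMENTS


@dataclass
class ResidueRecord:
    """A residue: named, numbered group of atoms within one chain."""

    name: str
    number: int
    atoms: list[AtomRecord] = field(default_factory=list)

    def heavy_atoms(self) -> list[AtomRecord]:
        return [a for a in self.atoms if a.is_heavy]


@dataclass
class ChainRecord:
    """One polymer chain with an optional UniProt mapping."""

    chain_id: str
    uniprot_id: Optional[str] = None
    residues: list[ResidueRecord] = field(default_factory=list)

    @property
    def atoms(self) -> list[AtomRecord]:
        return [a for r in self.residues for a in r.atoms]

    def heavy_atoms(self) -> list[AtomRecord]:
        return [a for r in self.residues for a in r.atoms if a.is_heavy]

    def heavy_coords(self) -> np.ndarray:
        atoms = self.heavy_atoms()
        if not atoms:
            return np.empty((0, 3))
        return np.array([a.coords for a in atoms])

    def __len__(self) -> int:
        return len(self.residues)


@dataclass
class LigandRecord:
    """A small-molecule component (one HET residue)."""

    het_code: str
    residue_number: int
    chain_id: str
    atoms: list[AtomRecord] = field(default_factory=list)
    pdb_occurrence: Optional[int] = None

    def heavy_atoms(self) -> list[AtomRecord]:
        return [a for a in self.atoms if a.is_heavy]

    @property
    def heavy_atom_count(self) -> int:
        return len(self.heavy_atoms())

    def heavy_coords(self) -> np.ndarray:
        atoms = self.heavy_atoms()
        if not atoms:
            return np.empty((0, 3))
        return np.array([a.coords for a in atoms])


@dataclass
class StructureEntry:
    """One PDB entry: chains, ligands and experimental metadata.

    ``resolution`` is in angstroms; ``r_free_minus_r_factor`` applies to
    X-ray entries and ``fsc`` (Fourier shell correlation criterion value)
    to cryo-EM entries.  Any metadata field may be absent (``None``).
    """

    entry_id: str
    method: ExperimentalMethod = ExperimentalMethod.OTHER
    resolution: Optional[float] = None
    r_free_minus_r_factor: Optional[float] = None
    fsc: Optional[float] = None
    chains: list[ChainRecord] = field(default_factory=list)
    ligands: list[LigandRecord] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.entry_id:
            raise ValueError("entry_id must be non-empty")
        if self.resolution is not None and self.resolution <= 0:
            raise ValueError("resolution must be positive when present")

    def chain(self, chain_id: str) -> ChainRecord:
        for ch in self.chains:
            if ch.chain_id == chain_id:
                return ch
        raise KeyError(f"no chain {chain_id!r} in entry {self.entry_id}")

    def all_atoms(self) -> Iterator[AtomRecord]:
        for ch in self.chains:
            yield from ch.atoms
        for lig in self.ligands:
            yield from lig.atoms


@dataclass
class GridPoint:
    """One cavity grid point with buriedness and probe type."""

    coords: np.ndarray
    buriedness: int = 0
    probe: str = "DU"

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.probe not in PROBE_TYPES:
            raise ValueError(f"unknown probe label {self.probe!r}")


@dataclass
class Cavity:
    """A detected pocket: one 26-connected set of grid points.

    The negative image of the pocket; ``volume`` is point count times the
    grid step cubed.
    """

    cavity_id: str
    points: list[GridPoint]
    step: float = 1.0
    source: str = ""

    @property
    def volume(self) -> float:
        return len(self.points) * self.step**3

    def coords(self) -> np.ndarray:
        if not self.points:
            return np.empty((0, 3))
        return np.array([p.coords for p in self.points])

    def buriedness_values(self) -> np.ndarray:
        return np.array([p.buriedness for p in self.points], dtype=int)

    def probes(self) -> list[str]:
        return [p.probe for p in self.points]

    def __len__(self) -> int:
        return len(self.points)


def as_coord_array(atoms: Sequence[AtomRecord]) -> np.ndarray:
    """Stack atom coordinates into an (n, 3) array."""
    if not atoms:
        return np.empty((0, 3))
    return np.array([a.coords for a in atoms])
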