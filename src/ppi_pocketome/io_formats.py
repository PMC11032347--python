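"""Readers and writers for every external representation the pipeline touches.

PDB coordinate files are parsed with :mod:`gemmi` into the package's own
records; pocket negative images are written as Mol2 pseudo-atom blocks;
descriptor tables follow a fixed CSV schema whose row identifiers encode
the pocket provenance (PDB code, chain, UniProt accession, optional ligand,
cavity rank and pocket class); entry metadata is accepted as PDBe-style
JSON objects.

File naming follows the published pattern::

    <pdb>-<chains>-<uniprots>[-<lig>-<resnum>]_CAVITY_N<k>_ALL_<annotation>.mol2

e.g. ``1bxl-AB-Q07817-Q16611_CAVITY_N1_ALL_orthosteric.mol2`` for a
heterodimer pocket and
``1t4e-A-Q00987-DIZ-112_CAVITY_N1_ALL_liganded_orthosteric_competitive.mol2``
for a liganded one.
"""

from __future__ import annotations

import json
import re
from pathlib import Path
from typing import Optional, Sequence

import gemmi
import numpy as np
import pandas as pd

from .models import (
    PROBE_TYPES,
    AtomRecord,
    Cavity,
    ChainRecord,
    ExperimentalMethod,
    GridPoint,
    LigandRecord,
    PocketClass,
    ResidueRecord,
    StructureEntry,
)

__all__ = [
    "PdbParseError",
    "read_pdb",
    "write_pdb",
    "write_pocket_mol2",
    "read_pocket_mol2",
    "pocket_file_name",
    "pocket_row_id",
    "validate_pocket_filename",
    "DESCRIPTOR_COLUMNS",
    "BURIAL_BIN_LABELS",
    "GEOMETRIC_COLUMNS",
    "write_descriptor_csv",
    "read_descriptor_csv",
    "read_metadata_json",
    "apply_metadata",
    "write_interface_residues",
]

WATER_CODES = {"HOH", "DOD", "WAT"}

#: Burial bin labels: "40" is buriedness <= 40 (exposed), "x.y" is
#: x < buriedness <= y, "120" is fully buried (all rays blocked).
BURIAL_BIN_LABELS: tuple[str, ...] = (
    "40", "40.50", "50.60", "60.70", "70.80",
    "80.90", "90.100", "100.110", "110.120", "120",
)

GEOMETRIC_COLUMNS: tuple[str, ...] = (
    "PMI1", "PMI2", "PMI3", "NPR1", "NPR2", "Rgyr",
    "Asphericity", "SpherocityIndex", "Eccentricity", "InertialShapeFactor",
)

#: The 109 descriptor columns in canonical order: volume, 8 probe totals,
#: 80 probe x burial-bin counts, 10 aggregated T bins, 10 geometric.
DESCRIPTOR_COLUMNS: tuple[str, ...] = (
    ("Volume",)
    + PROBE_TYPES
    + tuple(f"{p}{b}" for p in PROBE_TYPES for b in BURIAL_BIN_LABELS)
    + tuple(f"T{b}" for b in BURIAL_BIN_LABELS)
    + GEOMETRIC_COLUMNS
)


class PdbParseError(ValueError):
    """Raised on a malformed PDB coordinate file."""


def _validate_pdb_text(path: Path) -> None:
    n_coord = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if line.startswith(("ATOM  ", "HETATM")):
                if len(line.rstrip("\n")) < 54:
                    raise PdbParseError(
                        f"{path}: malformed coordinate line {lineno} (too short)"
                    )
                try:
                    for lo, hi in ((30, 38), (38, 46), (46, 54)):
                        float(line[lo:hi])
                except ValueError as exc:
                    raise PdbParseError(
                        f"{path}: malformed coordinate line {lineno}: {exc}"
                    ) from None
                n_coord += 1
    if n_coord == 0:
        raise PdbParseError(f"{path}: no ATOM/HETATM records")


def read_pdb(path: str | Path) -> StructureEntry:
    """Parse a PDB-format file into a :class:`StructureEntry`.

    Alternate-location indicators are preserved verbatim; HETATM residues
    other than water become :class:`LigandRecord` entries.  Only the first
    model of multi-model files is read.  Experimental metadata (method,
    resolution, ...) is not taken from the coordinate file; attach it with
    :func:`apply_metadata`.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    _validate_pdb_text(path)
    st = gemmi.read_pdb(str(path))
    entry_id = ""
    with open(path) as fh:
        for line in fh:
            if line.startswith("HEADER"):
                # idCode lives in columns 63-66; minimal fixture files may
                # carry the code right after the record name instead
                entry_id = line[62:66].strip()
                if not entry_id and line[10:].strip():
                    entry_id = line[10:].split()[0]
                break
    entry_id = (entry_id or st.name or path.stem)[:4].lower()
    entry = StructureEntry(entry_id=entry_id)
    if len(st) == 0:
        raise PdbParseError(f"{path}: no models")
    model = st[0]
    for ch in model:
        chain_rec = ChainRecord(chain_id=ch.name)
        for res in ch:
            hetero = res.het_flag == "H"
            atoms = [
                AtomRecord(
                    name=at.name,
                    element=at.element.name,
                    coords=np.array([at.pos.x, at.pos.y, at.pos.z]),
                    altloc="" if at.altloc == "\x00" else at.altloc,
                    is_hetero=hetero,
                )
                for at in res
            ]
            if hetero and res.name not in WATER_CODES:
                entry.ligands.append(
                    LigandRecord(
                        het_code=res.name,
                        residue_number=res.seqid.num,
                        chain_id=ch.name,
                        atoms=atoms,
                    )
                )
            else:
                chain_rec.residues.append(
                    ResidueRecord(name=res.name, number=res.seqid.num, atoms=atoms)
                )
        if chain_rec.residues:
            entry.chains.append(chain_rec)
    return entry


def _pdb_atom_line(serial: int, atom: AtomRecord, resname: str, chain_id: str,
                   resnum: int) -> str:
    record = "HETATM" if atom.is_hetero else "ATOM  "
    name = atom.name
    if len(name) < 4 and len(atom.element) == 1:
        name = " " + name
    x, y, z = atom.coords
    elem = atom.element.upper()
    return (
        f"{record}{serial:>5} {name:<4}{atom.altloc or ' '}{resname:<3} "
        f"{chain_id[:1]}{resnum:>4}    {x:8.3f}{y:8.3f}{z:8.3f}"
        f"{1.00:6.2f}{0.00:6.2f}          {elem:>2}"
    )


def write_pdb(entry: StructureEntry, path: str | Path) -> Path:
    """Write a :class:`StructureEntry` as PDB-format text (3-decimal coords)."""
    path = Path(path)
    lines = [f"HEADER    {entry.entry_id.upper()}"]
    serial = 0
    for ch in entry.chains:
        for res in ch.residues:
            for atom in res.atoms:
                serial += 1
                lines.append(_pdb_atom_line(serial, atom, res.name, ch.chain_id,
                                            res.number))
        lines.append(f"TER   {serial + 1:>5}")
        serial += 1
    for lig in entry.ligands:
        for atom in lig.atoms:
            serial += 1
            lines.append(_pdb_atom_line(serial, atom, lig.het_code, lig.chain_id,
                                        lig.residue_number))
    lines.append("END")
    path.write_text("\n".join(lines) + "\n")
    return path


# ---------------------------------------------------------------------------
# pocket naming


_ANNOTATIONS = tuple(c.value for c in PocketClass)

_FILENAME_RE = re.compile(
    r"^[0-9a-zA-Z]{4}"          # PDB code
    r"(-[A-Za-z0-9]+)+"         # chains, uniprots, optional ligand and resnum
    r"_CAVITY_N\d+_ALL_"
    r"(" + "|".join(_ANNOTATIONS) + r")\.mol2$"
)


def pocket_file_name(
    entry_id: str,
    chain_ids: Sequence[str],
    uniprot_ids: Sequence[str],
    cavity_index: int,
    annotation: str | PocketClass,
    ligand: Optional[LigandRecord] = None,
) -> str:
    """Build the canonical Mol2 file name for one pocket."""
    if isinstance(annotation, PocketClass):
        annotation = annotation.value
    if annotation not in _ANNOTATIONS:
        raise ValueError(f"unknown pocket annotation {annotation!r}")
    parts = [entry_id.lower(), "".join(chain_ids)] + [u for u in uniprot_ids]
    if ligand is not None:
        parts += [ligand.het_code, str(ligand.residue_number)]
    return "-".join(parts) + f"_CAVITY_N{cavity_index}_ALL_{annotation}.mol2"


def pocket_row_id(
    entry_id: str,
    chain_id: str,
    uniprot_id: str,
    cavity_index: int,
    pocket_class: str | PocketClass,
    ligand: Optional[LigandRecord] = None,
) -> str:
    """Row identifier used in descriptor tables.

    e.g. ``4lgu-A-Q13490-1YH-402_CAVITY_N2_liganded_orthosteric_competitive``.
    """
    if isinstance(pocket_class, PocketClass):
        pocket_class = pocket_class.value
    parts = [entry_id.lower(), chain_id, uniprot_id]
    if ligand is not None:
        parts += [ligand.het_code, str(ligand.residue_number)]
    return "-".join(parts) + f"_CAVITY_N{cavity_index}_{pocket_class}"


def validate_pocket_filename(name: str) -> bool:
    """True iff *name* matches the documented pocket Mol2 naming pattern."""
    return _FILENAME_RE.match(name) is not None


# ---------------------------------------------------------------------------
# Mol2 negative images


def write_pocket_mol2(cavity: Cavity, path: str | Path,
                      annotation: str = "") -> Path:
    """Write a cavity as a Mol2 pseudo-atom block (the negative image).

    One atom record per grid point; the atom name is the pharmacophoric
    probe label.  Probe pseudo-atoms carry zero charge in a single residue
    named CAV1.  Buriedness is not stored in Mol2.
    """
    if len(cavity) == 0:
        raise ValueError("cannot write an empty cavity")
    for p in cavity.points:
        if p.probe not in PROBE_TYPES:
            raise ValueError(f"unknown probe label {p.probe!r}")
    path = Path(path)
    name = path.stem
    lines = [
        "@<TRIPOS>MOLECULE",
        name if not annotation else f"{name} {annotation}",
        f"{len(cavity)} 0 1 0 0",
        "SMALL",
        "NO_CHARGES",
        "",
        "@<TRIPOS>ATOM",
    ]
    for i, pt in enumerate(cavity.points, start=1):
        x, y, z = pt.coords
        lines.append(
            f"{i:>7} {pt.probe:<4} {x:>12.4f} {y:>12.4f} {z:>12.4f} "
            f"{pt.probe:<5} 1 CAV1 {0.0:>10.4f}"
        )
    path.write_text("\n".join(lines) + "\n")
    return path


def read_pocket_mol2(path: str | Path) -> Cavity:
    """Read a cavity negative image written by :func:`write_pocket_mol2`."""
    path = Path(path)
    lines = path.read_text().splitlines()
    try:
        start = lines.index("@<TRIPOS>ATOM") + 1
    except ValueError:
        raise ValueError(f"{path}: no @<TRIPOS>ATOM block") from None
    points = []
    for line in lines[start:]:
        if line.startswith("@<TRIPOS>"):
            break
        if not line.strip():
            continue
        fields = line.split()
        probe = fields[1]
        if probe not in PROBE_TYPES:
            raise ValueError(f"{path}: unknown probe label {probe!r}")
        coords = np.array([float(v) for v in fields[2:5]])
        points.append(GridPoint(coords=coords, probe=probe))
    if not points:
        raise ValueError(f"{path}: empty cavity")
    m = re.search(r"CAVITY_N\d+", path.stem)
    return Cavity(cavity_id=m.group(0) if m else path.stem, points=points)


# ---------------------------------------------------------------------------
# descriptor CSV


def write_descriptor_csv(table: pd.DataFrame, path: str | Path) -> Path:
    """Write a pocket-descriptor matrix in the published CSV schema.

    *table* is indexed by pocket row IDs (see :func:`pocket_row_id`) with
    the 109 :data:`DESCRIPTOR_COLUMNS`.  The output prepends the
    ``pdb.chain`` and ``Cavity`` identifier columns.  Floats are written
    with 6 significant digits.
    """
    missing = [c for c in DESCRIPTOR_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"descriptor table missing columns: {missing}")
    ids = table.index.astype(str)
    pdb_chain = []
    for rid in ids:
        parts = rid.split("-")
        pdb_chain.append(f"{parts[0]}_{parts[1]}" if len(parts) >= 2 else rid)
    out = pd.concat(
        [pd.DataFrame({"pdb.chain": pdb_chain, "Cavity": ids},
                      index=table.index),
         table[list(DESCRIPTOR_COLUMNS)]],
        axis=1,
    )
    out.to_csv(path, index=False, float_format="%.6g")
    return Path(path)


def read_descriptor_csv(path: str | Path) -> pd.DataFrame:
    """Read a descriptor CSV back into a matrix indexed by the Cavity ID."""
    df = pd.read_csv(path)
    missing = [c for c in ("pdb.chain", "Cavity") if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing identifier columns {missing}")
    df = df.set_index("Cavity")
    keep = [c for c in df.columns if c != "pdb.chain"]
    return df[keep]


# ---------------------------------------------------------------------------
# metadata


_METHOD_PATTERNS = (
    ("XRAY", ExperimentalMethod.XRAY),
    ("X-RAY", ExperimentalMethod.XRAY),
    ("DIFFRACTION", ExperimentalMethod.XRAY),
    ("EM", ExperimentalMethod.CRYOEM),
    ("MICROSCOPY", ExperimentalMethod.CRYOEM),
    ("NMR", ExperimentalMethod.NMR),
)


def _parse_method(raw: str) -> ExperimentalMethod:
    up = raw.upper()
    for token, method in _METHOD_PATTERNS:
        if token in up:
            return method
    return ExperimentalMethod.OTHER


def read_metadata_json(path: str | Path) -> dict[str, dict]:
    """Load PDBe-style metadata: a JSON object keyed by entry ID.

    Each record may carry ``method``, ``resolution``, ``r_free``/``r_factor``
    (or ``r_free_minus_r_factor`` directly), ``fsc``, a ``chain_uniprot``
    chain-to-accession map, and a ``ligand_occurrence`` het-code count map.
    """
    with open(path) as fh:
        raw = json.load(fh)
    if not isinstance(raw, dict):
        raise ValueError(f"{path}: metadata must be a JSON object keyed by entry")
    return {k.lower(): v for k, v in raw.items()}


def apply_metadata(entry: StructureEntry, record: dict) -> StructureEntry:
    """Attach a metadata record to an entry (in place) and return it."""
    if "method" in record:
        entry.method = _parse_method(str(record["method"]))
    if record.get("resolution") is not None:
        entry.resolution = float(record["resolution"])
    if record.get("r_free_minus_r_factor") is not None:
        entry.r_free_minus_r_factor = float(record["r_free_minus_r_factor"])
    elif record.get("r_free") is not None and record.get("r_factor") is not None:
        entry.r_free_minus_r_factor = float(record["r_free"]) - float(record["r_factor"])
    if record.get("fsc") is not None:
        entry.fsc = float(record["fsc"])
    for ch in entry.chains:
        acc = record.get("chain_uniprot", {}).get(ch.chain_id)
        if acc is not None:
            ch.uniprot_id = acc
    occ = record.get("ligand_occurrence", {})
    for lig in entry.ligands:
        if lig.het_code in occ:
            lig.pdb_occurrence = int(occ[lig.het_code])
    return entry


def write_interface_residues(residues, path: str | Path) -> Path:
    """Write a ligand-contact residue list (the ``__interface-residues_6A.txt``
    format): one ``<resname> <resnum>`` line per residue."""
    path = Path(path)
    path.write_text("".join(f"{r.name} {r.number}\n" for r in residues))
    return path
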