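"""Structure- and ligand-level filters for the HD and PL candidate sets.

Heterodimer (HD) candidates must be two-chain complexes of distinct
UniProt proteins with more than three residues each; protein-ligand (PL)
candidates are single-chain entries whose protein also occurs in at least
one HD complex.  Experimental-quality rules: X-ray entries need resolution
<= 3.5 A and R-free - R-factor <= 0.07; cryo-EM entries resolution
<= 3.0 A and FSC <= 0.143; NMR entries pass without a resolution test;
anything else is rejected.  Ligands must have at least five heavy atoms of
drug-like elements (C, N, O, S, P, B and the halogens) and must not be
ubiquitous crystallization additives or co-factors — modelled by excluding
het codes whose PDB-wide occurrence count is below 10, minus a
user-curated whitelist standing in for manual inspection.

Every rejection names the rules that failed, so per-rule rejection
reports can be produced.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional

from .models import (
    ChainRecord,
    ExperimentalMethod,
    LigandRecord,
    StructureEntry,
)

__all__ = [
    "FilterReport",
    "CurationConfig",
    "filter_structure_quality",
    "select_heterodimers",
    "filter_ligand",
    "build_occurrence_exclusions",
    "check_interface_altlocs",
    "cross_reference_pl",
    "strip_for_detection",
]


@dataclass
class FilterReport:
    """Outcome of a filter: ACCEPT, or REJECT with the named failed rules."""

    entry_id: str
    failed_rules: list[str] = field(default_factory=list)
    thresholds: dict[str, float] = field(default_factory=dict)

    @property
    def verdict(self) -> str:
        return "REJECT" if self.failed_rules else "ACCEPT"

    @property
    def accepted(self) -> bool:
        return not self.failed_rules


@dataclass
class CurationConfig:
    """Thresholds for every curation rule."""

    max_res_xray: float = 3.5
    max_res_cryoem: float = 3.0
    max_rfree_minus_rfactor: float = 0.07
    max_fsc: float = 0.143
    min_ligand_heavy_atoms: int = 5
    allowed_elements: frozenset[str] = frozenset(
        {"C", "N", "O", "S", "P", "I", "Br", "Cl", "F", "B"}
    )
    ligand_occurrence_exclusion_threshold: int = 10
    exclusion_list: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        for name in ("max_res_xray", "max_res_cryoem", "max_rfree_minus_rfactor",
                     "max_fsc", "min_ligand_heavy_atoms",
                     "ligand_occurrence_exclusion_threshold"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not self.allowed_elements:
            raise ValueError("allowed_elements must be non-empty")


def filter_structure_quality(entry: StructureEntry,
                             cfg: CurationConfig | None = None) -> FilterReport:
    """Experimental-method and quality-statistic filter for one entry."""
    cfg = cfg or CurationConfig()
    report = FilterReport(entry_id=entry.entry_id)
    if entry.method is ExperimentalMethod.XRAY:
        report.thresholds = {"max_res_xray": cfg.max_res_xray,
                             "max_rfree_minus_rfactor": cfg.max_rfree_minus_rfactor}
        if entry.resolution is None or entry.r_free_minus_r_factor is None:
            report.failed_rules.append("missing_metadata")
        else:
            if entry.resolution > cfg.max_res_xray:
                report.failed_rules.append("resolution")
            if entry.r_free_minus_r_factor > cfg.max_rfree_minus_rfactor:
                report.failed_rules.append("r_free_minus_r_factor")
    elif entry.method is ExperimentalMethod.CRYOEM:
        report.thresholds = {"max_res_cryoem": cfg.max_res_cryoem,
                             "max_fsc": cfg.max_fsc}
        if entry.resolution is None or entry.fsc is None:
            report.failed_rules.append("missing_metadata")
        else:
            if entry.resolution > cfg.max_res_cryoem:
                report.failed_rules.append("resolution")
            if entry.fsc > cfg.max_fsc:
                report.failed_rules.append("fsc")
    elif entry.method is ExperimentalMethod.NMR:
        pass  # accepted with no resolution test
    else:
        report.failed_rules.append("method")
    return report


def select_heterodimers(
    entries: Iterable[StructureEntry],
) -> tuple[list[StructureEntry], list[FilterReport]]:
    """Keep entries with exactly two protein chains, distinct UniProt IDs
    and more than three residues per chain."""
    accepted: list[StructureEntry] = []
    reports: list[FilterReport] = []
    for entry in entries:
        report = FilterReport(entry_id=entry.entry_id)
        if len(entry.chains) != 2:
            report.failed_rules.append("chain_count")
        else:
            a, b = entry.chains
            if a.uniprot_id is None or b.uniprot_id is None:
                report.failed_rules.append("unmapped_chain")
            elif a.uniprot_id == b.uniprot_id:
                report.failed_rules.append("homodimer")
            if any(len(ch.residues) < 4 for ch in entry.chains):
                report.failed_rules.append("short_chain")
        reports.append(report)
        if report.accepted:
            accepted.append(entry)
    return accepted, reports


def filter_ligand(lig: LigandRecord,
                  cfg: CurationConfig | None = None) -> FilterReport:
    """Heavy-atom count, element and exclusion-list filter for one ligand."""
    cfg = cfg or CurationConfig()
    report = FilterReport(
        entry_id=f"{lig.het_code}-{lig.residue_number}",
        thresholds={"min_ligand_heavy_atoms": cfg.min_ligand_heavy_atoms},
    )
    if lig.heavy_atom_count < cfg.min_ligand_heavy_atoms:
        report.failed_rules.append("min_heavy_atoms")
    bad = {a.element for a in lig.heavy_atoms()} - cfg.allowed_elements
    if bad:
        report.failed_rules.append("element")
    if lig.het_code in cfg.exclusion_list:
        report.failed_rules.append("excluded_het_code")
    return report


def build_occurrence_exclusions(
    occurrence_table: Mapping[str, int],
    cfg: CurationConfig | None = None,
    whitelist: Optional[Iterable[str]] = None,
) -> set[str]:
    """Het codes to exclude: PDB-wide occurrence below the threshold.

    ``whitelist`` removes codes judged pertinent on inspection from the
    automatic exclusion set.
    """
    cfg = cfg or CurationConfig()
    for code, count in occurrence_table.items():
        if count < 0:
            raise ValueError(f"negative occurrence count for {code!r}")
    excluded = {
        code
        for code, count in occurrence_table.items()
        if count < cfg.ligand_occurrence_exclusion_threshold
    }
    return excluded - set(whitelist or ())


def check_interface_altlocs(entry: StructureEntry, interface) -> FilterReport:
    """Reject entries with alternate-location atoms at the interface.

    ``interface`` is an :class:`~ppi_pocketome.interfaces.InterfacePatch`
    (or any object with an ``atoms`` iterable of atom records).
    """
    report = FilterReport(entry_id=entry.entry_id)
    if any(atom.altloc for atom in interface.atoms):
        report.failed_rules.append("altloc")
    return report


def cross_reference_pl(
    pl_entries: Iterable[StructureEntry],
    hd_entries: Iterable[StructureEntry],
) -> tuple[list[tuple[StructureEntry, list[StructureEntry]]], list[FilterReport]]:
    """Link each single-chain PL entry to the HD entries sharing its UniProt.

    Returns retained ``(pl, [matching HDs])`` pairs plus one report per PL
    entry; PL entries with more than one protein chain are rejected, and
    those whose protein occurs in no HD are dropped with rule
    ``no_hd_partner``.
    """
    hd_list = list(hd_entries)
    by_uniprot: dict[str, list[StructureEntry]] = {}
    for hd in hd_list:
        for ch in hd.chains:
            if ch.uniprot_id:
                by_uniprot.setdefault(ch.uniprot_id, []).append(hd)

    retained = []
    reports = []
    for pl in pl_entries:
        report = FilterReport(entry_id=pl.entry_id)
        if len(pl.chains) != 1:
            report.failed_rules.append("monomer_rule")
        else:
            acc = pl.chains[0].uniprot_id
            if acc is None:
                report.failed_rules.append("unmapped_chain")
            elif acc not in by_uniprot:
                report.failed_rules.append("no_hd_partner")
            else:
                retained.append((pl, by_uniprot[acc]))
        reports.append(report)
    return retained, reports


def strip_for_detection(entry: StructureEntry, is_hd: bool) -> StructureEntry:
    """Remove waters always, and all heteroatom components for HD entries.

    Returns a shallow-modified copy suitable for pocket detection.
    """
    stripped = StructureEntry(
        entry_id=entry.entry_id,
        method=entry.method,
        resolution=entry.resolution,
        r_free_minus_r_factor=entry.r_free_minus_r_factor,
        fsc=entry.fsc,
        chains=[
            ChainRecord(ch.chain_id, ch.uniprot_id,
                        [r for r in ch.residues
                         if r.name not in ("HOH", "DOD", "WAT")])
            for ch in entry.chains
        ],
        ligands=[] if is_hd else list(entry.ligands),
    )
    return stripped
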