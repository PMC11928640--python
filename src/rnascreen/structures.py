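"""Narrow structure-parsing contract and the optional mmCIF/PDB adapter.

Binding-site extraction only needs residues with atom coordinates, a chain
and numbering for backbone order, and a coarse polymer classification.
This module defines that contract as plain dataclasses and provides an
optional adapter reading mmCIF/PDB through gemmi.  Base-pair geometry is
never computed here: Leontis-Westhof annotations are taken from the input
(``StructureModel.base_pairs``) or produced by the synthetic generator.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "Residue",
    "StructureModel",
    "DEFAULT_LIGAND_EXCLUSIONS",
    "is_admissible_ligand",
    "from_mmcif",
]

#: Residue names treated as ions or crystallization artefacts rather than
#: candidate ligands (configurable, mirroring common RNA-ligand curation).
DEFAULT_LIGAND_EXCLUSIONS = frozenset(
    {
        "HOH", "DOD", "MG", "NA", "K", "CL", "ZN", "MN", "CA", "SR", "BA",
        "CD", "NI", "CO", "FE", "CU", "IR", "CS", "BR", "IOD", "F",
        "SO4", "PO4", "GOL", "EDO", "PEG", "PG4", "MPD", "ACT", "DMS",
        "FMT", "TRS", "EPE", "MES", "NH4", "NO3", "BME", "SPM", "SPD",
    }
)

_RNA_NAMES = {"A", "C", "G", "U"}


@dataclass
class Residue:
    """One residue with its atom coordinates.

    ``kind`` is one of ``rna``, ``protein``, ``ligand``, ``ion``, ``water``,
    ``other``; ``coords`` is an (n_atoms, 3) array in angstroms.
    """

    chain: str
    number: int
    name: str
    kind: str
    coords: np.ndarray
    insertion: str = ""

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float).reshape(-1, 3)

    @property
    def key(self) -> str:
        base = f"{self.chain}.{self.number}"
        return f"{base}.{self.insertion}" if self.insertion else base


@dataclass
class StructureModel:
    structure_id: str
    residues: list[Residue]
    base_pairs: list[tuple[str, str, str]] = field(default_factory=list)

    def ligand_candidates(
        self,
        exclusions: frozenset[str] = DEFAULT_LIGAND_EXCLUSIONS,
        min_heavy_atoms: int = 8,
        max_heavy_atoms: int = 200,
    ) -> list[Residue]:
        return [
            r
            for r in self.residues
            if r.kind == "ligand"
            and is_admissible_ligand(r, exclusions, min_heavy_atoms, max_heavy_atoms)
        ]


def is_admissible_ligand(
    res: Residue,
    exclusions: frozenset[str] = DEFAULT_LIGAND_EXCLUSIONS,
    min_heavy_atoms: int = 8,
    max_heavy_atoms: int = 200,
) -> bool:
    """Exclusion-list + size rules for candidate small-molecule ligands."""
    if res.name.upper() in exclusions:
        return False
    return min_heavy_atoms <= len(res.coords) <= max_heavy_atoms


def from_mmcif(path: str) -> StructureModel:
    """Read an mmCIF/PDB file into the adapter contract (requires gemmi)."""
    try:
        import gemmi
    except ImportError as exc:  # pragma: no cover - optional dependency
        raise ImportError(
            "reading mmCIF/PDB requires the optional 'structures' extra (gemmi)"
        ) from exc

    st = gemmi.read_structure(str(path))
    st.setup_entities()
    model = st[0]
    residues: list[Residue] = []
    for chain in model:
        for res in chain:
            coords = np.array([[a.pos.x, a.pos.y, a.pos.z] for a in res if a.element.name != "H"])
            if coords.size == 0:
                continue
            info = gemmi.find_tabulated_residue(res.name)
            if res.is_water():
                kind = "water"
            elif info is not None and info.is_metal():
                kind = "ion"
            elif res.name.strip() in _RNA_NAMES or (info is not None and info.is_nucleic_acid()):
                kind = "rna"
            elif info is not None and info.is_amino_acid():
                kind = "protein"
            elif len(coords) <= 1:
                kind = "ion"
            else:
                kind = "ligand"
            residues.append(
                Residue(
                    chain=chain.name,
                    number=res.seqid.num,
                    insertion=(res.seqid.icode or "").strip(),
                    name=res.name.strip(),
                    kind=kind,
                    coords=coords,
                )
            )
    return StructureModel(structure_id=st.name or "structure", residues=residues)
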