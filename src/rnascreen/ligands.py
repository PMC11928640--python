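"""Compound handling: molecular graphs, drug-likeness, diversity, decoys.

Compounds enter as SMILES and are held as :class:`LigandRecord` objects
carrying the RDKit molecule, a node/edge-labelled molecular graph (atom
type, formal charge, aromaticity; bond class on edges), a folded circular
fingerprint (Morgan radius 2, 2048 bits by default) and a small property
vector.  On top of that the module implements the screening-library
curation steps: a strict drug-likeness filter (MW < 400 Da, at least one
ring, fewer than 5 rotatable bonds and H-bond donors, fewer than 10
H-bond acceptors, logP < 5), Tanimoto similarity, seeded MaxMin diversity
picking, and property-matched decoy-set construction in which at most a
capped number of decoys may resemble the native ligand.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
from rdkit import Chem, RDLogger
from rdkit.Chem import Crippen, Descriptors, rdFingerprintGenerator, rdMolDescriptors

RDLogger.DisableLog("rdApp.*")

__all__ = [
    "PropertyVector",
    "LigandRecord",
    "smiles_to_ligand",
    "druglike_filter",
    "tanimoto",
    "maxmin_pick",
    "build_decoy_set",
    "read_smi",
    "write_smi",
]

DEFAULT_FP_RADIUS = 2
DEFAULT_FP_BITS = 2048


@dataclass(frozen=True)
class PropertyVector:
    mol_weight: float
    n_rings: int
    n_rotatable: int
    n_hbd: int
    n_hba: int
    logp: float


@dataclass
class LigandRecord:
    ligand_id: str
    smiles: str  # canonical
    mol: Chem.Mol
    mol_graph: nx.Graph
    fingerprint: np.ndarray  # uint8 bit vector
    properties: PropertyVector

    @property
    def n_heavy_atoms(self) -> int:
        return self.mol.GetNumAtoms()


def _mol_to_graph(mol: Chem.Mol) -> nx.Graph:
    g = nx.Graph()
    for atom in mol.GetAtoms():
        g.add_node(
            atom.GetIdx(),
            element=atom.GetSymbol(),
            formal_charge=atom.GetFormalCharge(),
            aromatic=atom.GetIsAromatic(),
        )
    for bond in mol.GetBonds():
        g.add_edge(
            bond.GetBeginAtomIdx(),
            bond.GetEndAtomIdx(),
            bond_type=str(bond.GetBondType()),
        )
    return g


def smiles_to_ligand(
    smiles: str,
    ligand_id: str,
    fp_radius: int = DEFAULT_FP_RADIUS,
    fp_bits: int = DEFAULT_FP_BITS,
) -> LigandRecord:
    """Parse a SMILES string into a fully populated :class:`LigandRecord`."""
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise ValueError(f"unparsable SMILES: {smiles!r}")
    if mol.GetNumAtoms() == 0:
        raise ValueError(f"empty molecule: {smiles!r}")
    gen = rdFingerprintGenerator.GetMorganGenerator(radius=fp_radius, fpSize=fp_bits)
    fp = np.array(gen.GetFingerprintAsNumPy(mol), dtype=np.uint8)
    props = PropertyVector(
        mol_weight=Descriptors.MolWt(mol),
        n_rings=rdMolDescriptors.CalcNumRings(mol),
        n_rotatable=rdMolDescriptors.CalcNumRotatableBonds(mol),
        n_hbd=rdMolDescriptors.CalcNumHBD(mol),
        n_hba=rdMolDescriptors.CalcNumHBA(mol),
        logp=Crippen.MolLogP(mol),
    )
    return LigandRecord(
        ligand_id=ligand_id,
        smiles=Chem.MolToSmiles(mol),
        mol=mol,
        mol_graph=_mol_to_graph(mol),
        fingerprint=fp,
        properties=props,
    )


def druglike_filter(lig: LigandRecord) -> tuple[bool, list[str]]:
    """Strict drug-likeness rules; returns (passes, violated-rule names).

    Pass requires MW < 400, >= 1 ring, < 5 rotatable bonds, < 5 H-bond
    donors, < 10 H-bond acceptors and logP < 5.  All inequalities strict
    except the ring requirement.
    """
    p = lig.properties
    reasons = []
    if not p.mol_weight < 400:
        reasons.append("mol_weight")
    if not p.n_rings >= 1:
        reasons.append("n_rings")
    if not p.n_rotatable < 5:
        reasons.append("n_rotatable")
    if not p.n_hbd < 5:
        reasons.append("n_hbd")
    if not p.n_hba < 10:
        reasons.append("n_hba")
    if not p.logp < 5:
        reasons.append("logp")
    return (not reasons), reasons


def tanimoto(a: np.ndarray, b: np.ndarray) -> float:
    """Tanimoto similarity |a AND b| / |a OR b| of two equal-length bit vectors.

    Both-empty fingerprints count as identical (similarity 1).
    """
    a = np.asarray(a)
    b = np.asarray(b)
    if a.shape != b.shape:
        raise ValueError(f"fingerprint length mismatch: {a.shape} vs {b.shape}")
    a = a.astype(bool)
    b = b.astype(bool)
    union = int(np.count_nonzero(a | b))
    if union == 0:
        return 1.0
    return int(np.count_nonzero(a & b)) / union


def maxmin_pick(library: list[LigandRecord], n: int, seed: int = 0) -> list[LigandRecord]:
    """Greedy MaxMin diversity selection on Tanimoto distance.

    The first pick is a seeded uniform choice; each following pick
    maximizes the minimum Tanimoto distance (1 - similarity) to the
    already-selected set, breaking ties by lowest ``ligand_id``.  Output
    order is pick order and is deterministic given the seed.
    """
    if n > len(library):
        raise ValueError(f"cannot pick {n} from a library of {len(library)}")
    if n == 0:
        return []
    rng = np.random.default_rng(seed)
    order = sorted(range(len(library)), key=lambda i: library[i].ligand_id)
    first = order[rng.integers(len(order))]
    selected = [first]
    remaining = [i for i in range(len(library)) if i != first]
    # min distance of each remaining item to the selected set
    min_dist = np.array(
        [1.0 - tanimoto(library[i].fingerprint, library[first].fingerprint) for i in remaining]
    )
    while len(selected) < n:
        best_d = min_dist.max()
        cands = [k for k in range(len(remaining)) if min_dist[k] == best_d]
        best = min(cands, key=lambda k: library[remaining[k]].ligand_id)
        idx = remaining.pop(best)
        min_dist = np.delete(min_dist, best)
        selected.append(idx)
        if remaining:
            d_new = np.array(
                [1.0 - tanimoto(library[i].fingerprint, library[idx].fingerprint) for i in remaining]
            )
            min_dist = np.minimum(min_dist, d_new)
    return [library[i] for i in selected]


class DecoyPoolError(ValueError):
    """Pool cannot satisfy the decoy constraints; carries achievable size."""

    def __init__(self, achievable: int, requested: int):
        self.achievable = achievable
        self.requested = requested
        super().__init__(
            f"decoy constraints allow at most {achievable} decoys "
            f"({requested} requested); pass allow_relax=True to accept fewer"
        )


def build_decoy_set(
    native: LigandRecord,
    pool: list[LigandRecord],
    size: int,
    sim_cap_count: int = 100,
    sim_threshold: float = 0.6,
    seed: int = 0,
    allow_relax: bool = False,
) -> list[LigandRecord]:
    """Build a decoy set of ``size`` compounds around a native ligand.

    At most ``sim_cap_count`` decoys may have Tanimoto similarity >=
    ``sim_threshold`` to the native (the most similar are kept, giving the
    property-matched fraction); the remaining slots are filled from the
    dissimilar part of the pool by seeded MaxMin picking for diversity.
    The native is never returned.  If the constraints make ``size``
    unreachable, a :class:`DecoyPoolError` reporting the achievable size is
    raised unless ``allow_relax`` is set, in which case the achievable set
    is returned.
    """
    pool = [p for p in pool if p.ligand_id != native.ligand_id]
    sims = [(tanimoto(native.fingerprint, p.fingerprint), p) for p in pool]
    near = sorted(
        (sp for sp in sims if sp[0] >= sim_threshold),
        key=lambda sp: (-sp[0], sp[1].ligand_id),
    )
    far = [p for s, p in sims if s < sim_threshold]
    n_near = min(len(near), sim_cap_count, size)
    chosen = [p for _, p in near[:n_near]]
    n_far = size - len(chosen)
    if n_far > len(far):
        achievable = len(chosen) + len(far)
        if not allow_relax:
            raise DecoyPoolError(achievable, size)
        n_far = len(far)
    if n_far > 0:
        chosen.extend(maxmin_pick(far, n_far, seed=seed))
    return chosen


def read_smi(path) -> list[LigandRecord]:
    """Read a ``.smi`` file (SMILES, whitespace, identifier per line)."""
    records = []
    with open(path, encoding="utf-8") as fh:
        for i, line in enumerate(fh):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            smiles = parts[0]
            lig_id = parts[1] if len(parts) > 1 else f"mol{i}"
            records.append(smiles_to_ligand(smiles, lig_id))
    return records


def write_smi(records: list[LigandRecord], path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for rec in records:
            fh.write(f"{rec.smiles}\t{rec.ligand_id}\n")
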