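"""Molecular graphs, extended-connectivity fingerprints and Tanimoto similarity.

Molecules are parsed with RDKit from SMILES, InChI or MDL Molfile text.
Fingerprints are 1024-bit binary ECFPs at radius 3 by default (Morgan
algorithm, structure-only invariants, implicit hydrogens); a path-based
topological fingerprint is available as an alternative similarity input.
:class:`MolGraph` exposes the atom/bond feature tensors consumed by the
directed message-passing network in :mod:`esp.gnn_fingerprints`.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from rdkit import Chem, RDLogger
from rdkit.Chem import AllChem, rdFingerprintGenerator

from esp.data_io import MoleculeRecord

RDLogger.DisableLog("rdApp.*")

__all__ = [
    "MolGraph",
    "parse_structure",
    "mol_to_graph",
    "compute_ecfp",
    "compute_path_fingerprint",
    "fingerprint_collisions",
    "tanimoto",
    "pairwise_similarity",
    "SimilarityMatrix",
]

# categorical vocabularies for one-hot atom/bond feature blocks
_HYBRIDIZATIONS = [
    Chem.HybridizationType.SP,
    Chem.HybridizationType.SP2,
    Chem.HybridizationType.SP3,
    Chem.HybridizationType.SP3D,
    Chem.HybridizationType.SP3D2,
]
_CHIRALITY = [
    Chem.ChiralType.CHI_UNSPECIFIED,
    Chem.ChiralType.CHI_TETRAHEDRAL_CW,
    Chem.ChiralType.CHI_TETRAHEDRAL_CCW,
    Chem.ChiralType.CHI_OTHER,
]
_BOND_TYPES = [
    Chem.BondType.SINGLE,
    Chem.BondType.DOUBLE,
    Chem.BondType.TRIPLE,
    Chem.BondType.AROMATIC,
]
_STEREO = [
    Chem.BondStereo.STEREONONE,
    Chem.BondStereo.STEREOZ,
    Chem.BondStereo.STEREOE,
    Chem.BondStereo.STEREOCIS,
    Chem.BondStereo.STEREOTRANS,
    Chem.BondStereo.STEREOANY,
]

# scalar block: atomic number, degree, charge, H count, scaled mass, aromatic
ATOM_FDIM = 6 + len(_HYBRIDIZATIONS) + len(_CHIRALITY)
BOND_FDIM = len(_BOND_TYPES) + 2 + len(_STEREO)


def parse_structure(record: MoleculeRecord) -> Chem.Mol:
    """Parse a molecule record into an RDKit Mol (sanitized, ≥1 heavy atom)."""
    src, text = record.structure_source, record.structure_text
    if src == "smiles":
        mol = Chem.MolFromSmiles(text)
    elif src == "inchi":
        mol = Chem.MolFromInchi(text)
    else:
        mol = Chem.MolFromMolBlock(text)
    if mol is None:
        raise ValueError(
            f"molecule {record.molecule_id!r}: could not parse {src} structure"
        )
    if mol.GetNumHeavyAtoms() < 1:
        raise ValueError(f"molecule {record.molecule_id!r}: no heavy atoms")
    return mol


def _mol_of(molecule: MoleculeRecord | Chem.Mol) -> Chem.Mol:
    if isinstance(molecule, Chem.Mol):
        return molecule
    if molecule.parsed is None:
        molecule.parsed = parse_structure(molecule)
    return molecule.parsed


@dataclass
class MolGraph:
    """Directed molecular graph with per-atom and per-bond feature vectors.

    ``directed_edges`` lists (source atom, target atom, bond index) with both
    directions per bond, so its length is exactly twice the bond count.
    ``reverse_edge[k]`` is the index of edge k's opposite direction; the
    directed message-passing update excludes it.
    """

    atom_features: np.ndarray  # (n_atoms, ATOM_FDIM)
    bond_features: np.ndarray  # (n_bonds, BOND_FDIM)
    directed_edges: list[tuple[int, int, int]]
    reverse_edge: np.ndarray  # (2*n_bonds,)

    @property
    def n_atoms(self) -> int:
        return self.atom_features.shape[0]

    @property
    def n_bonds(self) -> int:
        return self.bond_features.shape[0]


def _one_hot(value, vocab) -> list[float]:
    return [1.0 if value == v else 0.0 for v in vocab]


def _atom_features(atom: Chem.Atom) -> list[float]:
    return [
        float(atom.GetAtomicNum()),
        float(atom.GetDegree()),
        float(atom.GetFormalCharge()),
        float(atom.GetTotalNumHs()),
        atom.GetMass() / 100.0,  # unit-scaled
        1.0 if atom.GetIsAromatic() else 0.0,
        *_one_hot(atom.GetHybridization(), _HYBRIDIZATIONS),
        *_one_hot(atom.GetChiralTag(), _CHIRALITY),
    ]


def _bond_features(bond: Chem.Bond) -> list[float]:
    return [
        *_one_hot(bond.GetBondType(), _BOND_TYPES),
        1.0 if bond.IsInRing() else 0.0,
        1.0 if bond.GetIsAromatic() else 0.0,
        *_one_hot(bond.GetStereo(), _STEREO),
    ]


def mol_to_graph(molecule: MoleculeRecord | Chem.Mol) -> MolGraph:
    """Build the directed graph a message-passing network consumes.

    Hydrogens stay implicit: they contribute to the per-atom hydrogen count
    but are not nodes.
    """
    mol = _mol_of(molecule)
    atoms = np.array([_atom_features(a) for a in mol.GetAtoms()], dtype=np.float64)
    if mol.GetNumBonds() == 0:
        return MolGraph(atoms, np.zeros((0, BOND_FDIM)), [], np.zeros(0, dtype=int))
    bonds = np.array([_bond_features(b) for b in mol.GetBonds()], dtype=np.float64)
    edges: list[tuple[int, int, int]] = []
    for b in mol.GetBonds():
        i, j = b.GetBeginAtomIdx(), b.GetEndAtomIdx()
        edges.append((i, j, b.GetIdx()))
        edges.append((j, i, b.GetIdx()))
    reverse = np.array([k + 1 if k % 2 == 0 else k - 1 for k in range(len(edges))])
    return MolGraph(atoms, bonds, edges, reverse)


def compute_ecfp(molecule: MoleculeRecord | Chem.Mol, n_bits: int = 1024,
                 radius: int = 3) -> np.ndarray:
    """Binary extended-connectivity fingerprint (Morgan), default 1024 bits, radius 3.

    Deterministic and invariant to the input representation (the same
    structure given as SMILES, InChI or Molfile hashes to the same bits).
    Chirality is not folded into the hashing.
    """
    mol = _mol_of(molecule)
    gen = rdFingerprintGenerator.GetMorganGenerator(radius=radius, fpSize=n_bits)
    fp = gen.GetFingerprint(mol)
    arr = np.zeros(n_bits, dtype=np.uint8)
    for bit in fp.GetOnBits():
        arr[bit] = 1
    return arr


def compute_path_fingerprint(molecule: MoleculeRecord | Chem.Mol,
                             n_bits: int = 1024) -> np.ndarray:
    """Path-based (topological) fingerprint, the RDKit default similarity input."""
    mol = _mol_of(molecule)
    fp = Chem.RDKFingerprint(mol, fpSize=n_bits)
    arr = np.zeros(n_bits, dtype=np.uint8)
    for bit in fp.GetOnBits():
        arr[bit] = 1
    return arr


def fingerprints_for(molecules: list[MoleculeRecord], kind: str = "ecfp",
                     n_bits: int = 1024, radius: int = 3
                     ) -> dict[str, np.ndarray]:
    """Fingerprint every molecule; ``kind`` in {ecfp, path}."""
    if kind == "ecfp":
        return {m.molecule_id: compute_ecfp(m, n_bits, radius) for m in molecules}
    if kind == "path":
        return {m.molecule_id: compute_path_fingerprint(m, n_bits) for m in molecules}
    raise ValueError(f"unknown fingerprint kind {kind!r}")


def fingerprint_collisions(fingerprints: dict[str, np.ndarray]
                           ) -> list[list[str]]:
    """Groups of distinct molecule ids sharing an identical fingerprint.

    Collisions arise when structures differ only beyond the fingerprint
    radius (e.g. long-chain homologs); the report surfaces them so users
    know which molecules the model cannot tell apart.
    """
    groups: dict[bytes, list[str]] = {}
    for mid, fp in fingerprints.items():
        groups.setdefault(np.asarray(fp, dtype=np.uint8).tobytes(), []).append(mid)
    return sorted([sorted(g) for g in groups.values() if len(g) >= 2])


def tanimoto(a: np.ndarray, b: np.ndarray) -> float:
    """|a AND b| / |a OR b| over binary fingerprints.

    Both-empty fingerprints return 1.0 by convention; such molecules are
    rejected upstream (every accepted molecule has ≥1 heavy atom).
    """
    a = np.asarray(a, dtype=bool)
    b = np.asarray(b, dtype=bool)
    if a.shape != b.shape:
        raise ValueError(f"fingerprint length mismatch: {a.shape} vs {b.shape}")
    union = np.logical_or(a, b).sum()
    if union == 0:
        return 1.0
    return float(np.logical_and(a, b).sum() / union)


@dataclass
class SimilarityMatrix:
    """Symmetric unit-interval molecule similarity with an id index."""

    ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self._index = {mid: i for i, mid in enumerate(self.ids)}

    def sim(self, a: str, b: str) -> float:
        return float(self.values[self._index[a], self._index[b]])

    def __contains__(self, mid: str) -> bool:
        return mid in self._index

    def row(self, mid: str) -> np.ndarray:
        return self.values[self._index[mid]]


def pairwise_similarity(fingerprints: dict[str, np.ndarray]) -> SimilarityMatrix:
    """All-vs-all Tanimoto similarity over a fingerprint table.

    Computed with one intersection/union matrix product rather than a double
    loop; tests check exact agreement with the brute-force oracle.
    """
    ids = list(fingerprints.keys())
    if not ids:
        return SimilarityMatrix(ids=[], values=np.zeros((0, 0)))
    mat = np.array([np.asarray(fingerprints[m], dtype=np.float64) for m in ids])
    inter = mat @ mat.T
    counts = mat.sum(axis=1)
    union = counts[:, None] + counts[None, :] - inter
    with np.errstate(invalid="ignore"):
        values = np.where(union > 0, inter / np.maximum(union, 1e-300), 1.0)
    np.fill_diagonal(values, 1.0)
    return SimilarityMatrix(ids=ids, values=values)
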