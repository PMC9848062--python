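"""Featurization of compounds and proteins.

Compounds are represented in two complementary views: a directed-bond
molecular graph (for message passing) and a Morgan/circular fingerprint (for
the substructure-presence view).  Proteins are tokenized to fixed-length
integer arrays over a 26-symbol amino-acid vocabulary and zero-padded.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from rdkit import Chem
from rdkit.Chem import rdFingerprintGenerator


class SmilesParseError(ValueError):
    """Raised when a SMILES string cannot be parsed into a molecule."""


# ---------------------------------------------------------------------------
# Atom / bond feature layout (D-MPNN reference layout).
# Each categorical feature is one-hot with a trailing "other" bucket so the
# vector length is fixed regardless of the molecule.
# ---------------------------------------------------------------------------

MAX_ATOMIC_NUM = 100
_DEGREES = [0, 1, 2, 3, 4, 5]
_FORMAL_CHARGES = [-2, -1, 0, 1, 2]
_CHIRAL_TAGS = [0, 1, 2, 3]  # CHI_UNSPECIFIED, CHI_TETRAHEDRAL_CW/CCW, CHI_OTHER
_NUM_HS = [0, 1, 2, 3, 4]
_HYBRIDIZATIONS = [
    Chem.rdchem.HybridizationType.SP,
    Chem.rdchem.HybridizationType.SP2,
    Chem.rdchem.HybridizationType.SP3,
    Chem.rdchem.HybridizationType.SP3D,
    Chem.rdchem.HybridizationType.SP3D2,
]

ATOM_FDIM = (
    (MAX_ATOMIC_NUM + 1)
    + (len(_DEGREES) + 1)
    + (len(_FORMAL_CHARGES) + 1)
    + (len(_CHIRAL_TAGS) + 1)
    + (len(_NUM_HS) + 1)
    + (len(_HYBRIDIZATIONS) + 1)
    + 1  # aromaticity flag
    + 1  # atomic mass * 0.01
)

_BOND_TYPES = [
    Chem.rdchem.BondType.SINGLE,
    Chem.rdchem.BondType.DOUBLE,
    Chem.rdchem.BondType.TRIPLE,
    Chem.rdchem.BondType.AROMATIC,
]
_BOND_STEREO = [0, 1, 2, 3, 4, 5]  # STEREONONE..STEREOTRANS

BOND_FDIM = (len(_BOND_TYPES) + 1) + 1 + 1 + (len(_BOND_STEREO) + 1)


def _onehot(value, choices) -> list[float]:
    vec = [0.0] * (len(choices) + 1)
    try:
        vec[choices.index(value)] = 1.0
    except ValueError:
        vec[-1] = 1.0
    return vec


def atom_features(atom: Chem.Atom) -> np.ndarray:
    feats = (
        _onehot(atom.GetAtomicNum(), list(range(1, MAX_ATOMIC_NUM + 1)))
        + _onehot(atom.GetTotalDegree(), _DEGREES)
        + _onehot(atom.GetFormalCharge(), _FORMAL_CHARGES)
        + _onehot(int(atom.GetChiralTag()), _CHIRAL_TAGS)
        + _onehot(int(atom.GetTotalNumHs()), _NUM_HS)
        + _onehot(atom.GetHybridization(), _HYBRIDIZATIONS)
        + [1.0 if atom.GetIsAromatic() else 0.0]
        + [atom.GetMass() * 0.01]
    )
    return np.asarray(feats, dtype=np.float64)


def bond_features(bond: Chem.Bond) -> np.ndarray:
    feats = (
        _onehot(bond.GetBondType(), _BOND_TYPES)
        + [1.0 if bond.GetIsConjugated() else 0.0]
        + [1.0 if bond.IsInRing() else 0.0]
        + _onehot(int(bond.GetStereo()), _BOND_STEREO)
    )
    return np.asarray(feats, dtype=np.float64)


@dataclass
class MolGraph:
    """Directed-bond molecular graph.

    Every chemical bond v-w contributes two directed bonds v->w and w->v with
    identical bond feature vectors.  ``rev`` maps each directed bond to its
    reverse; ``incoming[a]`` lists the directed bonds ending at atom ``a``.
    """

    n_atoms: int
    n_directed_bonds: int
    atom_feats: np.ndarray  # (n_atoms, ATOM_FDIM)
    bond_feats: np.ndarray  # (n_directed_bonds, BOND_FDIM)
    src: np.ndarray  # (n_directed_bonds,) int
    dst: np.ndarray  # (n_directed_bonds,) int
    rev: np.ndarray  # (n_directed_bonds,) int
    incoming: list = field(repr=False, default_factory=list)


def smiles_to_molgraph(smiles: str) -> MolGraph:
    """Build the directed molecular graph for a SMILES string.

    Hydrogens stay implicit; only heavy atoms become graph nodes.  Raises
    :class:`SmilesParseError` for unparsable or empty input.
    """
    if not smiles or not smiles.strip():
        raise SmilesParseError("empty SMILES string")
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise SmilesParseError(f"could not parse SMILES: {smiles!r}")

    n_atoms = mol.GetNumAtoms()
    afeats = np.zeros((n_atoms, ATOM_FDIM))
    for atom in mol.GetAtoms():
        afeats[atom.GetIdx()] = atom_features(atom)

    src, dst, rev, bfeats = [], [], [], []
    for bond in mol.GetBonds():
        v, w = bond.GetBeginAtomIdx(), bond.GetEndAtomIdx()
        bf = bond_features(bond)
        i = len(src)
        src += [v, w]
        dst += [w, v]
        rev += [i + 1, i]
        bfeats += [bf, bf]

    n_bonds = len(src)
    incoming = [[] for _ in range(n_atoms)]
    for b, a in enumerate(dst):
        incoming[a].append(b)

    return MolGraph(
        n_atoms=n_atoms,
        n_directed_bonds=n_bonds,
        atom_feats=afeats,
        bond_feats=(
            np.asarray(bfeats) if bfeats else np.zeros((0, BOND_FDIM))
        ),
        src=np.asarray(src, dtype=np.intp),
        dst=np.asarray(dst, dtype=np.intp),
        rev=np.asarray(rev, dtype=np.intp),
        incoming=incoming,
    )


@dataclass
class MorganFingerprint:
    """Binary circular-substructure fingerprint (ECFP-style)."""

    bits: np.ndarray
    radius: int

    @property
    def n_bits(self) -> int:
        return self.bits.shape[0]


def smiles_to_fingerprint(
    smiles: str, radius: int = 2, n_bits: int = 2048
) -> MorganFingerprint:
    """Hash circular substructures up to ``radius`` into an ``n_bits`` vector.

    Defaults (radius 2, 2048 bits) are the community-standard ECFP4 settings.
    """
    if radius < 0:
        raise ValueError("radius must be >= 0")
    if n_bits < 1:
        raise ValueError("n_bits must be >= 1")
    if not smiles or not smiles.strip():
        raise SmilesParseError("empty SMILES string")
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise SmilesParseError(f"could not parse SMILES: {smiles!r}")
    gen = rdFingerprintGenerator.GetMorganGenerator(radius=radius, fpSize=n_bits)
    bits = gen.GetFingerprintAsNumPy(mol).astype(np.float64)
    return MorganFingerprint(bits=bits, radius=radius)


# ---------------------------------------------------------------------------
# Protein tokenization: 26-symbol vocabulary (pad, 20 canonical residues,
# B/Z/X/U ambiguity codes, unknown).  Any stable bijective table works since
# the embedding is learned; this one is fixed and documented here.
# ---------------------------------------------------------------------------

PAD_ID = 0
_RESIDUE_ORDER = "ACDEFGHIKLMNPQRSTVWYBZXU"
VOCAB: dict[str, int] = {aa: i + 1 for i, aa in enumerate(_RESIDUE_ORDER)}
UNK_ID = len(_RESIDUE_ORDER) + 1  # 25
VOCAB_SIZE = UNK_ID + 1  # 26
_ID_TO_RESIDUE = {v: k for k, v in VOCAB.items()}

DEFAULT_MAX_LEN = 500


@dataclass
class ProteinTokens:
    """Fixed-length integer encoding of an amino-acid sequence."""

    ids: np.ndarray  # (max_len,) int
    true_length: int

    @property
    def max_len(self) -> int:
        return self.ids.shape[0]


def tokenize_protein(sequence: str, max_len: int = DEFAULT_MAX_LEN) -> ProteinTokens:
    """Encode a one-letter sequence to exactly ``max_len`` integer ids.

    Longer sequences are right-truncated; shorter ones right-padded with the
    pad id 0.  Characters outside the vocabulary map to the unknown token
    rather than being rejected.
    """
    seq = sequence.strip().upper()[:max_len]
    ids = np.full(max_len, PAD_ID, dtype=np.intp)
    for i, ch in enumerate(seq):
        ids[i] = VOCAB.get(ch, UNK_ID)
    return ProteinTokens(ids=ids, true_length=len(seq))


def detokenize_protein(tokens: ProteinTokens) -> str:
    """Recover the residue string of the non-pad prefix ('?' for unknown)."""
    out = []
    for t in tokens.ids[: tokens.true_length]:
        out.append(_ID_TO_RESIDUE.get(int(t), "?"))
    return "".join(out)
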