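"""Molecular graph featurization for the drug branch.

Each drug is a graph whose nodes are heavy atoms and whose edges are bonds
(binary, bond order ignored). Every atom carries a 75-dimensional feature
vector laid out as fixed one-hot blocks plus two scalars:

====================  ======  ==========================================
block                 width   columns
====================  ======  ==========================================
atom symbol           44      0–43   (last slot = "other"/unknown element)
heavy-atom degree     11      44–54  (0–10)
implicit valence      7       55–61  (0–6)
formal charge         1       62
radical electrons     1       63
hybridization         5       64–68  (SP, SP2, SP3, SP3D, SP3D2)
aromaticity flag      1       69
total hydrogen count  5       70–74  (0–4)
====================  ======  ==========================================

Hydrogens are implicit — encoded through the H-count block, never as nodes.
Graphs of varying size are embedded into a fixed 100-node zero-padded
template (:func:`pad_drug_graph`) so one network serves all drugs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

N_ATOM_FEATURES = 75
DEFAULT_MAX_NODES = 100

#: Frozen element vocabulary for the symbol one-hot; the trailing slot
#: absorbs any element not listed, so rare elements never error.
ATOM_VOCAB: tuple[str, ...] = (
    "C", "N", "O", "S", "F", "Si", "P", "Cl", "Br", "Mg", "Na", "Ca", "Fe",
    "As", "Al", "I", "B", "V", "K", "Tl", "Yb", "Sb", "Sn", "Ag", "Pd", "Co",
    "Se", "Ti", "Zn", "H", "Li", "Ge", "Cu", "Au", "Ni", "Cd", "In", "Mn",
    "Zr", "Cr", "Pt", "Hg", "Pb", "other",
)
_HYBRIDIZATIONS = ("SP", "SP2", "SP3", "SP3D", "SP3D2")

# column offsets of each block
SYMBOL_SLICE = slice(0, 44)
DEGREE_SLICE = slice(44, 55)
VALENCE_SLICE = slice(55, 62)
CHARGE_COL = 62
RADICAL_COL = 63
HYBRID_SLICE = slice(64, 69)
AROMATIC_COL = 69
HCOUNT_SLICE = slice(70, 75)


class MoleculeParseError(ValueError):
    """The structure input could not be parsed."""


class InvalidMoleculeError(ValueError):
    """The molecule has no heavy atoms."""


class CapacityError(ValueError):
    """A molecule exceeds the fixed padding template."""


class DuplicateIdError(ValueError):
    """Two input rows share a drug identifier."""


@dataclass
class DrugGraph:
    """Raw (native-size) molecular graph: features ``X_raw``, adjacency ``A_raw``."""

    drug_id: str
    X_raw: np.ndarray = field(repr=False)
    A_raw: np.ndarray = field(repr=False)

    @property
    def n_atoms(self) -> int:
        return self.A_raw.shape[0]

    def validate(self) -> None:
        X, A = self.X_raw, self.A_raw
        if X.shape != (self.n_atoms, N_ATOM_FEATURES):
            raise ValueError(f"{self.drug_id}: feature matrix shape {X.shape}")
        if not np.array_equal(A, A.T) or np.any(np.diagonal(A) != 0):
            raise ValueError(f"{self.drug_id}: adjacency not symmetric/zero-diagonal")
        if not np.isin(A, (0, 1)).all():
            raise ValueError(f"{self.drug_id}: adjacency entries must be 0/1")
        for name, sl in (("symbol", SYMBOL_SLICE), ("degree", DEGREE_SLICE),
                         ("valence", VALENCE_SLICE), ("hybridization", HYBRID_SLICE),
                         ("h-count", HCOUNT_SLICE)):
            if not np.all(X[:, sl].sum(axis=1) == 1):
                raise ValueError(f"{self.drug_id}: {name} block is not one-hot")
        if not np.isin(X[:, AROMATIC_COL], (0, 1)).all():
            raise ValueError(f"{self.drug_id}: aromatic flag must be 0/1")


@dataclass
class PaddedDrugGraph:
    """A drug graph embedded top-left into the fixed-scale zero template."""

    drug_id: str
    X: np.ndarray = field(repr=False)
    A: np.ndarray = field(repr=False)
    node_mask: np.ndarray = field(repr=False)

    @property
    def n_atoms(self) -> int:
        return int(self.node_mask.sum())


def _one_hot(value, choices, clamp: bool = True) -> np.ndarray:
    vec = np.zeros(len(choices))
    if value in choices:
        vec[choices.index(value)] = 1.0
    elif clamp and isinstance(value, (int, np.integer)):
        vec[-1 if value > max(choices) else 0] = 1.0
    else:
        vec[-1] = 1.0
    return vec


def featurize_molecule(mol, drug_id: str = "") -> DrugGraph:
    """Featurize a parsed RDKit molecule into a :class:`DrugGraph`.

    Hybridizations outside {SP, SP2, SP3, SP3D, SP3D2} (e.g. the S state of
    an isolated ion) fall back to the SP slot; degree, valence and H-count
    clamp to their final slot. Adjacency records a 1 for every bonded pair of
    heavy atoms regardless of bond order.
    """
    if mol is None:
        raise MoleculeParseError(f"could not parse structure for '{drug_id}'")
    n = mol.GetNumAtoms()
    if n == 0:
        raise InvalidMoleculeError(f"'{drug_id}' has no heavy atoms")
    X = np.zeros((n, N_ATOM_FEATURES))
    for atom in mol.GetAtoms():
        i = atom.GetIdx()
        sym = atom.GetSymbol()
        X[i, SYMBOL_SLICE] = _one_hot(
            sym if sym in ATOM_VOCAB[:-1] else "other", list(ATOM_VOCAB), clamp=False)
        X[i, DEGREE_SLICE] = _one_hot(atom.GetDegree(), list(range(11)))
        X[i, VALENCE_SLICE] = _one_hot(atom.GetImplicitValence(), list(range(7)))
        X[i, CHARGE_COL] = atom.GetFormalCharge()
        X[i, RADICAL_COL] = atom.GetNumRadicalElectrons()
        hyb = str(atom.GetHybridization())
        hyb_vec = np.zeros(5)
        hyb_vec[_HYBRIDIZATIONS.index(hyb) if hyb in _HYBRIDIZATIONS else 0] = 1.0
        X[i, HYBRID_SLICE] = hyb_vec
        X[i, AROMATIC_COL] = float(atom.GetIsAromatic())
        X[i, HCOUNT_SLICE] = _one_hot(atom.GetTotalNumHs(), list(range(5)))
    A = np.zeros((n, n))
    for bond in mol.GetBonds():
        a, b = bond.GetBeginAtomIdx(), bond.GetEndAtomIdx()
        A[a, b] = A[b, a] = 1.0
    g = DrugGraph(drug_id=drug_id, X_raw=X, A_raw=A)
    g.validate()
    return g


def featurize_smiles(smiles: str, drug_id: str = "") -> DrugGraph:
    """Parse a SMILES string with RDKit and featurize it."""
    from rdkit import Chem

    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise MoleculeParseError(f"could not parse SMILES for '{drug_id or smiles}'")
    return featurize_molecule(mol, drug_id=drug_id)


def pad_drug_graph(g: DrugGraph, n_nodes: int = DEFAULT_MAX_NODES) -> PaddedDrugGraph:
    """Embed ``g`` top-left into an ``n_nodes``-node zero template.

    ``X = [X_raw; 0]`` and ``A = [[A_raw, 0], [0, 0]]``; the node mask marks
    the first ``g.n_atoms`` positions.
    """
    n = g.n_atoms
    if n > n_nodes:
        raise CapacityError(
            f"'{g.drug_id}' has {n} atoms, exceeding the {n_nodes}-node template")
    X = np.zeros((n_nodes, g.X_raw.shape[1]))
    X[:n] = g.X_raw
    A = np.zeros((n_nodes, n_nodes))
    A[:n, :n] = g.A_raw
    mask = np.zeros(n_nodes)
    mask[:n] = 1.0
    return PaddedDrugGraph(drug_id=g.drug_id, X=X, A=A, node_mask=mask)


def read_graph_text(path: str | Path, drug_id: str | None = None) -> DrugGraph:
    """Read the plain-text graph format.

    Layout: a header line ``n_atoms l_d``; then ``n_atoms`` whitespace-
    separated feature rows of ``l_d`` values; then a line ``edges:`` followed
    by 0-based ``i j`` pairs, one per line.
    """
    path = Path(path)
    if drug_id is None:
        drug_id = path.name.split(".")[0]
    lines = [ln.strip() for ln in path.read_text().splitlines() if ln.strip()]
    try:
        n_atoms, l_d = (int(tok) for tok in lines[0].split())
    except (ValueError, IndexError) as exc:
        raise MoleculeParseError(f"{path}: bad header line: {lines[0]!r}") from exc
    X = np.array([[float(v) for v in lines[1 + i].split()] for i in range(n_atoms)])
    if X.shape != (n_atoms, l_d):
        raise MoleculeParseError(f"{path}: expected {n_atoms}x{l_d} feature block")
    if lines[1 + n_atoms] != "edges:":
        raise MoleculeParseError(f"{path}: missing 'edges:' separator")
    A = np.zeros((n_atoms, n_atoms))
    for ln in lines[2 + n_atoms:]:
        i, j = (int(tok) for tok in ln.split())
        A[i, j] = A[j, i] = 1.0
    g = DrugGraph(drug_id=drug_id, X_raw=X, A_raw=A)
    g.validate()
    return g


def write_graph_text(g: DrugGraph, path: str | Path) -> None:
    """Write a :class:`DrugGraph` in the plain-text format of :func:`read_graph_text`."""
    out = [f"{g.n_atoms} {g.X_raw.shape[1]}"]
    for row in g.X_raw:
        out.append(" ".join(repr(float(v)) for v in row))
    out.append("edges:")
    ii, jj = np.nonzero(np.triu(g.A_raw))
    out.extend(f"{i} {j}" for i, j in zip(ii, jj))
    Path(path).write_text("\n".join(out) + "\n")


def read_smiles_table(path: str | Path) -> list[DrugGraph]:
    """Read drugs from a TSV with header columns ``id`` and ``smiles``.

    A file whose first line is two integers is interpreted as the alternate
    single-graph text format instead (see :func:`read_graph_text`), so tests
    and downstream tools can exchange graphs without a chemistry toolkit.
    """
    path = Path(path)
    first = path.read_text().splitlines()[0].split()
    if len(first) == 2 and all(tok.isdigit() for tok in first):
        return [read_graph_text(path)]
    graphs: list[DrugGraph] = []
    seen: set[str] = set()
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        try:
            id_col, smi_col = header.index("id"), header.index("smiles")
        except ValueError as exc:
            raise MoleculeParseError(
                f"{path}: header must contain 'id' and 'smiles'") from exc
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) <= max(id_col, smi_col):
                raise MoleculeParseError(f"{path}:{lineno}: malformed row")
            drug_id, smiles = fields[id_col], fields[smi_col]
            if drug_id in seen:
                raise DuplicateIdError(f"{path}: duplicate drug id '{drug_id}'")
            seen.add(drug_id)
            graphs.append(featurize_smiles(smiles, drug_id=drug_id))
    return graphs
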