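"""Reading and writing molecule tables; SMILES -> featurized graph.

Input tables are comma-separated UTF-8 files with a header row, as exported
by common benchmark collections.  Rows whose SMILES fail RDKit sanitization
are skipped with a logged warning, never silently retained.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from rdkit import Chem
from rdkit import RDLogger

logger = logging.getLogger(__name__)
RDLogger.DisableLog("rdApp.*")

#: elements receiving a one-hot slot; anything else maps to the final slot
ATOM_ELEMENTS = ["C", "N", "O", "F", "P", "S", "Cl", "Br", "I"]
_MAX_DEGREE = 5

PREDICTION_COLUMNS = ["mol_id", "smiles", "alpha0", "alpha1", "p_mean", "evidence", "entropy"]


class FeaturizationError(ValueError):
    """Raised when a SMILES cannot be sanitized/featurized."""


@dataclass(frozen=True)
class LabeledMolecule:
    """A SMILES record with an optional binary label."""

    smiles: str
    label: int | None
    mol_id: str

    def __post_init__(self):
        if self.label is not None and self.label not in (0, 1):
            raise ValueError(f"label must be 0 or 1, got {self.label!r}")


@dataclass(frozen=True)
class ClassCounts:
    n_negative: int
    n_positive: int

    def __post_init__(self):
        if self.n_negative < 0 or self.n_positive < 0:
            raise ValueError("class counts must be non-negative")

    @property
    def total(self) -> int:
        return self.n_negative + self.n_positive


@dataclass
class LabeledDataset:
    """A named collection of molecules with tallied class counts."""

    molecules: list[LabeledMolecule]
    name: str = "dataset"
    class_counts: ClassCounts = field(init=False)

    def __post_init__(self):
        self.class_counts = tally(self.molecules)

    def __len__(self) -> int:
        return len(self.molecules)

    def __iter__(self):
        return iter(self.molecules)

    @property
    def labels(self) -> np.ndarray:
        """Labels of the labeled subset, in order (unlabeled rows excluded)."""
        return np.array([m.label for m in self.molecules if m.label is not None])

    def subset(self, indices: Sequence[int], name: str | None = None) -> "LabeledDataset":
        return LabeledDataset([self.molecules[i] for i in indices],
                              name=name or self.name)


def tally(molecules: Iterable[LabeledMolecule]) -> ClassCounts:
    neg = pos = 0
    for m in molecules:
        if m.label == 0:
            neg += 1
        elif m.label == 1:
            pos += 1
    return ClassCounts(neg, pos)


@dataclass(frozen=True)
class MolecularGraph:
    """Directed-edge representation of a molecule for message passing.

    ``bond_index`` has shape (2, n_edges) with both (i, j) and (j, i)
    present for every bond; ``atom_features`` is (n_atoms, n_atom_features).
    """

    atom_features: np.ndarray
    bond_index: np.ndarray
    bond_features: np.ndarray

    @property
    def n_atoms(self) -> int:
        return self.atom_features.shape[0]

    @property
    def n_edges(self) -> int:
        return self.bond_index.shape[1]


def _atom_features(atom: Chem.Atom) -> np.ndarray:
    onehot = [0.0] * (len(ATOM_ELEMENTS) + 1)
    try:
        onehot[ATOM_ELEMENTS.index(atom.GetSymbol())] = 1.0
    except ValueError:
        onehot[-1] = 1.0
    degree = [0.0] * (_MAX_DEGREE + 1)
    degree[min(atom.GetDegree(), _MAX_DEGREE)] = 1.0
    return np.array(
        onehot
        + degree
        + [
            float(atom.GetFormalCharge()),
            float(atom.GetIsAromatic()),
            float(atom.GetTotalNumHs()),
        ]
    )


_BOND_TYPES = [
    Chem.BondType.SINGLE,
    Chem.BondType.DOUBLE,
    Chem.BondType.TRIPLE,
    Chem.BondType.AROMATIC,
]


def _bond_features(bond: Chem.Bond) -> np.ndarray:
    onehot = [0.0] * (len(_BOND_TYPES) + 1)
    try:
        onehot[_BOND_TYPES.index(bond.GetBondType())] = 1.0
    except ValueError:
        onehot[-1] = 1.0
    return np.array(onehot + [float(bond.IsInRing())])


N_ATOM_FEATURES = len(ATOM_ELEMENTS) + 1 + _MAX_DEGREE + 1 + 3
N_BOND_FEATURES = len(_BOND_TYPES) + 1 + 1


def featurize(mol: LabeledMolecule | str) -> MolecularGraph:
    """Parse a SMILES into a directed molecular graph with atom/bond features."""
    smiles = mol.smiles if isinstance(mol, LabeledMolecule) else mol
    rdmol = Chem.MolFromSmiles(smiles)
    if rdmol is None:
        raise FeaturizationError(f"cannot sanitize SMILES {smiles!r}")
    atoms = np.array([_atom_features(a) for a in rdmol.GetAtoms()])
    src, dst, bfeat = [], [], []
    for bond in rdmol.GetBonds():
        i, j = bond.GetBeginAtomIdx(), bond.GetEndAtomIdx()
        f = _bond_features(bond)
        src += [i, j]
        dst += [j, i]
        bfeat += [f, f]
    bond_index = np.array([src, dst], dtype=np.int64).reshape(2, -1)
    bond_features = (np.array(bfeat) if bfeat
                     else np.zeros((0, N_BOND_FEATURES)))
    return MolecularGraph(atoms, bond_index, bond_features)


def read_labeled_smiles(path: str | Path, smiles_col: str = "smiles",
                        label_col: str | None = "label",
                        name: str | None = None) -> LabeledDataset:
    """Read a CSV of SMILES (and optional 0/1 labels) into a dataset.

    Unparseable SMILES are skipped with a warning; a non-{0,1} label is a
    fatal error; zero parseable rows is a fatal error.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path)
    if smiles_col not in df.columns:
        raise KeyError(f"column {smiles_col!r} not found in {path}")
    if label_col is not None and label_col not in df.columns:
        raise KeyError(f"column {label_col!r} not found in {path}")

    molecules: list[LabeledMolecule] = []
    skipped: list[str] = []
    for idx, row in df.iterrows():
        smiles = str(row[smiles_col])
        if Chem.MolFromSmiles(smiles) is None:
            skipped.append(smiles)
            continue
        if label_col is None or (isinstance(row[label_col], float)
                                 and math.isnan(row[label_col])):
            label = None
        else:
            raw = row[label_col]
            if float(raw) not in (0.0, 1.0):
                raise ValueError(f"label {raw!r} at row {idx} is not 0 or 1")
            label = int(float(raw))
        mol_id = str(row["mol_id"]) if "mol_id" in df.columns else str(idx)
        molecules.append(LabeledMolecule(smiles, label, mol_id))
    if skipped:
        logger.warning("skipped %d unparseable SMILES in %s", len(skipped), path)
    if not molecules:
        raise ValueError(f"no parseable SMILES rows in {path}")
    ds = LabeledDataset(molecules, name=name or path.stem)
    ds.skip_log = skipped  # type: ignore[attr-defined]
    return ds


def write_predictions(rows: Iterable, path: str | Path) -> None:
    """Write prediction records to CSV with the fixed column layout.

    Each row must expose ``mol_id, smiles, alpha0, alpha1, p_mean, evidence,
    entropy`` (attributes or mapping keys).  Floats are written at full
    precision so a round-trip read is lossless.
    """
    records = []
    for r in rows:
        get = r.get if isinstance(r, dict) else lambda k, rr=r: getattr(rr, k)
        records.append({c: get(c) for c in PREDICTION_COLUMNS})
    df = pd.DataFrame.from_records(records, columns=PREDICTION_COLUMNS)
    df.to_csv(path, index=False, float_format="%.17g")


def read_predictions(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in PREDICTION_COLUMNS if c not in df.columns]
    if missing:
        raise KeyError(f"prediction file {path} missing columns {missing}")
    return df
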