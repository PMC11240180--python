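"""Synthetic four-category molecule benchmark for uncertainty analysis.

The task: molecules containing nitrogen but no fluorine (``Nmol``) are
negatives; fluorine but no nitrogen (``Fmol``) are positives; molecules with
both elements (``N_Fmol``) get a fair-coin label — irreducible (aleatoric)
noise; molecules with neither (``NULLmol``) appear only in the test split and
are out-of-distribution — no similar training molecule exists, so any label
is unpredictable (epistemic uncertainty).  ``NULLmol`` records carry a
fair-coin *dummy* label purely so metric code runs; it is not ground truth.

Molecules are assembled from a random carbon/oxygen fragment grammar
(chains and rings built atom-by-atom with valence bookkeeping, optionally
decorated with N and/or F).  The experiment depends only on the
element-content categories, not on any particular molecular library.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from rdkit import Chem

from .mol_io import LabeledDataset, LabeledMolecule

CATEGORIES = ("Nmol", "Fmol", "N_Fmol", "NULLmol")
TRAIN_CATEGORIES = ("Nmol", "Fmol", "N_Fmol")


class GenerationError(RuntimeError):
    """Raised when the grammar fails to produce a valid molecule."""


@dataclass
class SyntheticSpec:
    """Per-category sample counts and generation settings.

    ``n_train`` covers the three in-distribution categories; ``n_test``
    additionally includes NULLmol, which never enters the training split.
    """

    n_train: dict = field(default_factory=lambda: {
        "Nmol": 500, "Fmol": 500, "N_Fmol": 500})
    n_test: dict = field(default_factory=lambda: {
        "Nmol": 200, "Fmol": 200, "N_Fmol": 200, "NULLmol": 200})
    seed: int = 0
    max_heavy_atoms: int = 17

    def __post_init__(self):
        if "NULLmol" in self.n_train and self.n_train["NULLmol"] > 0:
            raise ValueError("NULLmol may only appear in the test split")
        for counts in (self.n_train, self.n_test):
            for cat, n in counts.items():
                if cat not in CATEGORIES:
                    raise ValueError(f"unknown category {cat!r}")
                if n < 0:
                    raise ValueError("counts must be >= 0")


def _category_elements(smiles: str) -> tuple[bool, bool]:
    mol = Chem.MolFromSmiles(smiles)
    symbols = {a.GetSymbol() for a in mol.GetAtoms()}
    return "N" in symbols, "F" in symbols


def category_predicate(smiles: str, category: str) -> bool:
    """True iff the molecule's N/F content matches its category."""
    has_n, has_f = _category_elements(smiles)
    return {
        "Nmol": has_n and not has_f,
        "Fmol": has_f and not has_n,
        "N_Fmol": has_n and has_f,
        "NULLmol": not has_n and not has_f,
    }[category]


_VALENCE = {"C": 4, "O": 2, "N": 3, "F": 1}


def _random_skeleton(rng: np.random.Generator, n_atoms: int) -> Chem.RWMol:
    """Random C/O tree, optionally with one ring closure."""
    mol = Chem.RWMol()
    mol.AddAtom(Chem.Atom("C"))
    free = {0: _VALENCE["C"]}
    for _ in range(n_atoms - 1):
        symbol = "O" if rng.random() < 0.2 else "C"
        attach_candidates = [i for i, v in free.items() if v >= 1]
        if not attach_candidates:
            break
        parent = int(rng.choice(attach_candidates))
        idx = mol.AddAtom(Chem.Atom(symbol))
        mol.AddBond(parent, idx, Chem.BondType.SINGLE)
        free[parent] -= 1
        free[idx] = _VALENCE[symbol] - 1
    if rng.random() < 0.5 and mol.GetNumAtoms() >= 4:
        open_atoms = [i for i, v in free.items() if v >= 1]
        rng.shuffle(open_atoms)
        for a in open_atoms:
            partners = [b for b in open_atoms
                        if b != a and free[b] >= 1
                        and mol.GetBondBetweenAtoms(a, b) is None
                        and abs(a - b) >= 2]
            if partners:
                b = int(rng.choice(partners))
                mol.AddBond(a, b, Chem.BondType.SINGLE)
                free[a] -= 1
                free[b] -= 1
                break
    mol._free_valence = free  # noqa: SLF001 - internal bookkeeping
    return mol


def _decorate(mol: Chem.RWMol, rng: np.random.Generator,
              add_n: int, add_f: int) -> bool:
    free = mol._free_valence
    for symbol, count in (("N", add_n), ("F", add_f)):
        for _ in range(count):
            hosts = [i for i, v in free.items()
                     if v >= 1 and mol.GetAtomWithIdx(i).GetSymbol() == "C"]
            if not hosts:
                return False
            host = int(rng.choice(hosts))
            idx = mol.AddAtom(Chem.Atom(symbol))
            mol.AddBond(host, idx, Chem.BondType.SINGLE)
            free[host] -= 1
            free[idx] = _VALENCE[symbol] - 1
    return True


def generate_molecule(category: str, rng: np.random.Generator,
                      max_heavy_atoms: int = 17,
                      max_attempts: int = 100) -> LabeledMolecule:
    """Generate one valid molecule of the requested category.

    Labels: Nmol -> 0, Fmol -> 1, N_Fmol -> fair coin, NULLmol -> fair-coin
    dummy (its true label is taken to be unpredictable).  Category membership
    is re-verified by an element scan before returning.
    """
    if category not in CATEGORIES:
        raise ValueError(f"unknown category {category!r}")
    has_n = category in ("Nmol", "N_Fmol")
    has_f = category in ("Fmol", "N_Fmol")
    for _ in range(max_attempts):
        # 1-3 atoms of each required element, echoing the variable polar-atom
        # counts of molecules drawn from an enumerated library
        add_n = int(rng.integers(1, 4)) if has_n else 0
        add_f = int(rng.integers(1, 4)) if has_f else 0
        budget = max_heavy_atoms - add_n - add_f
        n_skel = int(rng.integers(5, max(6, budget + 1)))
        mol = _random_skeleton(rng, n_skel)
        if not _decorate(mol, rng, add_n, add_f):
            continue
        try:
            Chem.SanitizeMol(mol)
        except Exception:
            continue
        smiles = Chem.MolToSmiles(mol)
        if Chem.MolFromSmiles(smiles) is None:
            continue
        if not category_predicate(smiles, category):
            continue
        if category == "Nmol":
            label = 0
        elif category == "Fmol":
            label = 1
        else:  # N_Fmol true coin flip; NULLmol dummy coin flip
            label = int(rng.random() < 0.5)
        return LabeledMolecule(smiles, label, mol_id=f"{category}")
    raise GenerationError(
        f"failed to generate a valid {category} molecule in {max_attempts} attempts")


def _generate_unique(category: str, n: int, rng: np.random.Generator,
                     max_heavy_atoms: int, seen: set) -> list[LabeledMolecule]:
    out: list[LabeledMolecule] = []
    while len(out) < n:
        m = generate_molecule(category, rng, max_heavy_atoms)
        canonical = Chem.MolToSmiles(Chem.MolFromSmiles(m.smiles))
        if canonical in seen:
            continue
        seen.add(canonical)
        out.append(LabeledMolecule(canonical, m.label,
                                   mol_id=f"{category}_{len(out)}"))
    return out


def build_synthetic_splits(spec: SyntheticSpec) -> tuple[LabeledDataset, LabeledDataset]:
    """Build disjoint train/test splits, fully determined by ``spec.seed``.

    The train split holds only Nmol/Fmol/N_Fmol; the test split additionally
    holds NULLmol.  No canonical SMILES appears in both splits.
    """
    rng = np.random.default_rng(spec.seed)
    train_mols: list[LabeledMolecule] = []
    test_mols: list[LabeledMolecule] = []
    for cat in CATEGORIES:
        n_tr = spec.n_train.get(cat, 0)
        n_te = spec.n_test.get(cat, 0)
        if n_tr + n_te == 0:
            continue
        seen: set = set()
        pool = _generate_unique(cat, n_tr + n_te, rng, spec.max_heavy_atoms, seen)
        train_mols.extend(pool[:n_tr])
        test_mols.extend(pool[n_tr:])
    overlap = {m.smiles for m in train_mols} & {m.smiles for m in test_mols}
    assert not overlap, f"train/test SMILES overlap: {sorted(overlap)[:3]}"
    train = LabeledDataset(train_mols, name="synthetic-train")
    test = LabeledDataset(test_mols, name="synthetic-test")
    return train, test


def category_of(mol: LabeledMolecule) -> str:
    """Recover the category of a generated molecule from its mol_id prefix."""
    return mol.mol_id.rsplit("_", 1)[0]
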