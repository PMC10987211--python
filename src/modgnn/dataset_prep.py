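"""Cleaning rules for labeled SMILES datasets and the 9:1 train/test split.

Four rules are applied in order: (1) canonicalize every SMILES and drop
duplicates (first occurrence in input order wins; a molecule that appears
with conflicting labels is dropped entirely and counted separately);
(2) drop molecules containing metal atoms; (3) drop molecules with fewer
than 2 heavy atoms; (4) molecules the parser cannot read are removals, not
failures. Rule 4 is detected first in practice — an unreadable record can
be neither canonicalized nor inspected — but is reported as its own
category so the counts always add up to the input size.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from rdkit import Chem

from .featurization import SmilesParseError

#: Elements treated as metals: alkali, alkaline-earth, transition,
#: post-transition metals, lanthanides and actinides. Metalloids
#: (B, Si, Ge, As, Sb, Te) are deliberately excluded.
METALS = frozenset({
    "Li", "Na", "K", "Rb", "Cs", "Fr",
    "Be", "Mg", "Ca", "Sr", "Ba", "Ra",
    "Sc", "Ti", "V", "Cr", "Mn", "Fe", "Co", "Ni", "Cu", "Zn",
    "Y", "Zr", "Nb", "Mo", "Tc", "Ru", "Rh", "Pd", "Ag", "Cd",
    "Hf", "Ta", "W", "Re", "Os", "Ir", "Pt", "Au", "Hg",
    "Rf", "Db", "Sg", "Bh", "Hs",
    "Al", "Ga", "In", "Sn", "Tl", "Pb", "Bi", "Po",
    "La", "Ce", "Pr", "Nd", "Pm", "Sm", "Eu", "Gd", "Tb", "Dy",
    "Ho", "Er", "Tm", "Yb", "Lu",
    "Ac", "Th", "Pa", "U", "Np", "Pu", "Am", "Cm", "Bk", "Cf",
})


@dataclass
class CleaningReport:
    """Outcome of the four-rule cleaning pass over one dataset."""

    n_input: int
    n_unparseable: int
    n_duplicate: int
    n_conflicting: int  # same canonical molecule with contradictory labels
    n_metal: int
    n_too_small: int
    survivors: list[tuple[str, float]] = field(default_factory=list)

    @property
    def n_removed(self) -> int:
        return (self.n_unparseable + self.n_duplicate + self.n_conflicting
                + self.n_metal + self.n_too_small)

    def to_dict(self) -> dict:
        return {
            "n_input": self.n_input, "n_unparseable": self.n_unparseable,
            "n_duplicate": self.n_duplicate, "n_conflicting": self.n_conflicting,
            "n_metal": self.n_metal, "n_too_small": self.n_too_small,
            "n_survivors": len(self.survivors),
        }


def contains_metal(mol: Chem.Mol) -> bool:
    return any(atom.GetSymbol() in METALS for atom in mol.GetAtoms())


def clean_dataset(records: list[tuple[str, float]],
                  metals: frozenset[str] = METALS) -> CleaningReport:
    """Apply the four cleaning rules; counts always sum to the input size."""
    n_unparseable = n_duplicate = n_conflicting = n_metal = n_too_small = 0
    parsed: list[tuple[str, Chem.Mol, float]] = []
    for smiles, label in records:
        mol = Chem.MolFromSmiles(smiles) if smiles else None
        if mol is None:
            n_unparseable += 1
            continue
        parsed.append((Chem.MolToSmiles(mol), mol, label))

    # canonical-SMILES dedup, first occurrence kept; conflicting labels drop all
    label_sets: dict[str, set[float]] = {}
    for canon, _, label in parsed:
        label_sets.setdefault(canon, set()).add(label)
    seen: set[str] = set()
    survivors: list[tuple[str, float]] = []
    for canon, mol, label in parsed:
        if len(label_sets[canon]) > 1:
            n_conflicting += 1
            continue
        if canon in seen:
            n_duplicate += 1
            continue
        seen.add(canon)
        if any(atom.GetSymbol() in metals for atom in mol.GetAtoms()):
            n_metal += 1
            continue
        if mol.GetNumHeavyAtoms() < 2:
            n_too_small += 1
            continue
        survivors.append((canon, label))

    return CleaningReport(
        n_input=len(records), n_unparseable=n_unparseable,
        n_duplicate=n_duplicate, n_conflicting=n_conflicting,
        n_metal=n_metal, n_too_small=n_too_small, survivors=survivors,
    )


def split_train_test(records: list, ratio: float = 0.9, seed: int = 0,
                     stratify: bool = True):
    """Random 9:1 (by default) train/test split, reproducible from the seed.

    The test set holds ``round((1 - ratio) * n)`` records; with
    ``stratify=True`` the split preserves the label proportions.
    """
    from sklearn.model_selection import train_test_split

    if not 0.0 < ratio < 1.0:
        raise ValueError(f"ratio must be in (0, 1), got {ratio}")
    n = len(records)
    n_test = int(round((1.0 - ratio) * n))
    if n_test == 0 or n_test == n:
        raise ValueError(f"split of {n} records at ratio {ratio} is degenerate")
    labels = [lab for _, lab in records] if stratify else None
    train, test = train_test_split(records, test_size=n_test,
                                   random_state=seed, stratify=labels)
    return train, test
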