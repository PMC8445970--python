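"""Seven-rule drug-likeness pre-filter for docking libraries.

Before docking a multi-million-compound library against a large binding
pocket, molecules with extreme physicochemical properties are removed.
A molecule is eliminated iff any of these holds:

* more than 7 hydrogen-bond donors
* more than 12 hydrogen-bond acceptors
* molecular weight above 600 Da
* logP above 7
* more than 8 rotatable bonds
* fewer than 3 aromatic rings
* fewer than 4 rings in total

The inequalities are strict: a molecule exactly at a bound (e.g. 600 Da,
logP 7) is kept.  The ring minima reflect that the targeted pockets are
large and favor multi-ring scaffolds.

The filter consumes a property table.  Computing the properties from
SMILES is available as an optional adapter (requires RDKit) but is off
the core path.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

__all__ = [
    "MoleculeProperties",
    "FilterReport",
    "RULES",
    "apply_druglikeness_filter",
    "read_property_table",
    "properties_from_smiles",
]

#: rule name -> (property, direction of violation, bound)
RULES: dict[str, tuple[str, str, float]] = {
    "hbd>7": ("hbd", "gt", 7),
    "hba>12": ("hba", "gt", 12),
    "mw>600": ("mw", "gt", 600.0),
    "logp>7": ("logp", "gt", 7.0),
    "rotatable_bonds>8": ("rotatable_bonds", "gt", 8),
    "aromatic_rings<3": ("aromatic_rings", "lt", 3),
    "total_rings<4": ("total_rings", "lt", 4),
}

_COUNT_FIELDS = ("hbd", "hba", "rotatable_bonds", "aromatic_rings", "total_rings")


@dataclass(frozen=True)
class MoleculeProperties:
    """Physicochemical properties of one molecule."""

    id: str
    hbd: int
    hba: int
    mw: float
    logp: float
    rotatable_bonds: int
    aromatic_rings: int
    total_rings: int

    def validate(self) -> list[str]:
        """Return a list of property problems (empty if none)."""
        problems = []
        for name in _COUNT_FIELDS:
            v = getattr(self, name)
            if v is None or (isinstance(v, float) and math.isnan(v)):
                problems.append(f"missing {name}")
            elif v < 0 or int(v) != v:
                problems.append(f"{name} must be a non-negative integer, got {v}")
        if self.mw is None or math.isnan(self.mw) or self.mw <= 0:
            problems.append(f"mw must be positive, got {self.mw}")
        if self.logp is None or math.isnan(self.logp):
            problems.append("missing logp")
        return problems

    def violated_rules(self) -> list[str]:
        out = []
        for rule, (attr, op, bound) in RULES.items():
            v = getattr(self, attr)
            if (op == "gt" and v > bound) or (op == "lt" and v < bound):
                out.append(rule)
        return out


@dataclass
class FilterReport:
    kept: list[str] = field(default_factory=list)
    discarded: dict[str, list[str]] = field(default_factory=dict)
    errors: dict[str, list[str]] = field(default_factory=dict)
    rule_counts: dict[str, int] = field(default_factory=dict)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps({
            "n_input": len(self.kept) + len(self.discarded) + len(self.errors),
            "n_kept": len(self.kept),
            "kept": self.kept,
            "discarded": self.discarded,
            "errors": self.errors,
            "rule_counts": self.rule_counts,
        }, indent=2))


def apply_druglikeness_filter(
    molecules: Iterable[MoleculeProperties],
) -> FilterReport:
    """Partition molecules into kept / discarded under the seven rules.

    Molecules with missing or invalid properties are recorded under
    ``errors`` (never silently kept).  Every violated rule is listed for
    each discarded molecule, and per-rule elimination tallies reported.
    """
    report = FilterReport(rule_counts={rule: 0 for rule in RULES})
    for mol in molecules:
        problems = mol.validate()
        if problems:
            report.errors[mol.id] = problems
            continue
        violated = mol.violated_rules()
        if violated:
            report.discarded[mol.id] = violated
            for rule in violated:
                report.rule_counts[rule] += 1
        else:
            report.kept.append(mol.id)
    return report


def read_property_table(path: str | Path, *, delimiter: str = ",") -> list[MoleculeProperties]:
    """Read a CSV property table (id plus the seven property columns)."""
    df = pd.read_csv(path, sep=delimiter)
    required = ["id", "hbd", "hba", "mw", "logp", "rotatable_bonds",
                "aromatic_rings", "total_rings"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    out = []
    for row in df.itertuples(index=False):
        out.append(MoleculeProperties(
            id=str(row.id),
            hbd=int(row.hbd), hba=int(row.hba),
            mw=float(row.mw), logp=float(row.logp),
            rotatable_bonds=int(row.rotatable_bonds),
            aromatic_rings=int(row.aromatic_rings),
            total_rings=int(row.total_rings),
        ))
    return out


def properties_from_smiles(
    smiles: Sequence[str], ids: Sequence[str] | None = None
) -> list[MoleculeProperties]:
    """Compute the seven filter properties from SMILES via RDKit.

    Optional adapter; raises ImportError when RDKit is unavailable and
    ValueError on unparseable SMILES.
    """
    from rdkit import Chem
    from rdkit.Chem import Crippen, Descriptors, Lipinski, rdMolDescriptors

    ids = list(ids) if ids is not None else [f"mol{i}" for i in range(len(smiles))]
    out = []
    for mol_id, smi in zip(ids, smiles):
        mol = Chem.MolFromSmiles(smi)
        if mol is None:
            raise ValueError(f"unparseable SMILES for {mol_id}: {smi!r}")
        out.append(MoleculeProperties(
            id=mol_id,
            hbd=Lipinski.NumHDonors(mol),
            hba=Lipinski.NumHAcceptors(mol),
            mw=Descriptors.MolWt(mol),
            logp=Crippen.MolLogP(mol),
            rotatable_bonds=Lipinski.NumRotatableBonds(mol),
            aromatic_rings=rdMolDescriptors.CalcNumAromaticRings(mol),
            total_rings=rdMolDescriptors.CalcNumRings(mol),
        ))
    return out
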