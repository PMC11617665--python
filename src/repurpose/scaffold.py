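"""Murcko-style chemotype extraction and scaffold-overlap selection.

A molecule's chemotype here is its ring systems plus the linkers
connecting them, with side chains removed, under two preservation rules:

* bond orders, atom types and ring-ring connectors are preserved;
* atoms double-bonded to a ring or linker atom (exocyclic C=O, C=S, C=N,
  sulfone/sulfoxide S=O, and any other exocyclic double bond) stay part of
  the scaffold, together with their double bond -- but not their own
  substituents.

A side-chain carbonyl (e.g. the acetyl group of acetophenone) is *not*
retained, because its carbon is neither a ring nor a linker atom; the
benzophenone carbonyl *is*, because its carbon bridges two rings.

Scaffold keys are canonical SMILES with stereochemistry stripped: the
chemotype is a constitution-level concept.  Acyclic molecules have no
scaffold and never participate in overlap selection.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

from rdkit import Chem

from .errors import StructureError
from .library import CuratedLibrary


@dataclass(frozen=True)
class Scaffold:
    """A pruned scaffold: canonical key plus ring/atom counts."""

    key: str
    n_rings: int
    n_atoms: int


def _framework_atoms(mol: Chem.Mol) -> set[int]:
    """Ring plus linker atoms: iteratively strip terminal non-ring atoms.

    Linker atoms (atoms on acyclic paths between ring systems) survive
    because they never reach degree <= 1 while both ring systems remain.
    """
    ring_atoms = {
        i for i in range(mol.GetNumAtoms()) if mol.GetAtomWithIdx(i).IsInRing()
    }
    kept = set(range(mol.GetNumAtoms()))
    adjacency = {
        a.GetIdx(): {n.GetIdx() for n in a.GetNeighbors()} for a in mol.GetAtoms()
    }
    while True:
        terminal = [
            i
            for i in kept
            if i not in ring_atoms and len(adjacency[i] & kept) <= 1
        ]
        if not terminal:
            return kept
        kept -= set(terminal)


def _retained_partners(mol: Chem.Mol, framework: set[int]) -> set[int]:
    """Side-chain atoms double-bonded directly to a framework atom."""
    extra = set()
    for bond in mol.GetBonds():
        if bond.GetBondType() != Chem.BondType.DOUBLE:
            continue
        a, b = bond.GetBeginAtomIdx(), bond.GetEndAtomIdx()
        if (a in framework) != (b in framework):
            extra.add(b if a in framework else a)
    return extra


def _extract_submol(mol: Chem.Mol, keep: set[int]) -> Chem.Mol:
    rw = Chem.RWMol(mol)
    # aromatic heteroatoms that lose their only substituent need an H back
    needs_h = set()
    for idx in keep:
        atom = mol.GetAtomWithIdx(idx)
        if (
            atom.GetIsAromatic()
            and atom.GetAtomicNum() in (7, 15)
            and atom.GetTotalNumHs() == 0
            and any(n.GetIdx() not in keep for n in atom.GetNeighbors())
        ):
            needs_h.add(idx)
    for idx in sorted(set(range(mol.GetNumAtoms())) - keep, reverse=True):
        rw.RemoveAtom(idx)
    # indices shifted; match by original mapping
    if needs_h:
        old_to_new = {}
        new = 0
        for old in range(mol.GetNumAtoms()):
            if old in keep:
                old_to_new[old] = new
                new += 1
        for old in needs_h:
            atom = rw.GetAtomWithIdx(old_to_new[old])
            if atom.GetTotalNumHs() == 0:
                atom.SetNumExplicitHs(1)
    # ex-stereocenter carbons keep a stale explicit-H count after neighbor
    # removal; clear it so implicit valence is recomputed
    for atom in rw.GetAtoms():
        if atom.GetAtomicNum() == 6 and not atom.GetIsAromatic():
            atom.SetNumExplicitHs(0)
            atom.SetNoImplicit(False)
    sub = rw.GetMol()
    Chem.SanitizeMol(sub)
    return sub


def extract_scaffold(mol: Chem.Mol) -> Optional[Scaffold]:
    """Return the molecule's scaffold, or ``None`` for acyclic molecules.

    Raises :class:`StructureError` if ``mol`` is missing or unprocessable.
    """
    if mol is None:
        raise StructureError("cannot extract scaffold from unparsable structure")
    if not any(a.IsInRing() for a in mol.GetAtoms()):
        return None
    framework = _framework_atoms(mol)
    keep = framework | _retained_partners(mol, framework)
    try:
        sub = _extract_submol(mol, keep)
    except Exception as exc:  # pragma: no cover - defensive
        raise StructureError(f"scaffold extraction failed: {exc}") from exc
    Chem.RemoveStereochemistry(sub)
    key = Chem.MolToSmiles(sub)
    return Scaffold(
        key=key,
        n_rings=sub.GetRingInfo().NumRings(),
        n_atoms=sub.GetNumAtoms(),
    )


def scaffold_key(smiles: str) -> Optional[str]:
    """Convenience: scaffold key straight from a SMILES string."""
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise StructureError(f"unparsable SMILES {smiles!r}")
    scaf = extract_scaffold(mol)
    return None if scaf is None else scaf.key


@dataclass
class ChemotypeTable:
    """Scaffold key -> member compound ids, plus the acyclic remainder."""

    entries: dict[str, list[str]] = field(default_factory=dict)
    acyclic_ids: list[str] = field(default_factory=list)
    assignments: list[tuple[str, Optional[str]]] = field(default_factory=list)

    @property
    def n_chemotypes(self) -> int:
        return len(self.entries)

    def add(self, compound_id: str, key: Optional[str]) -> None:
        self.assignments.append((compound_id, key))
        if key is None:
            self.acyclic_ids.append(compound_id)
        else:
            self.entries.setdefault(key, []).append(compound_id)


def classify_chemotypes(lib: CuratedLibrary) -> ChemotypeTable:
    """Bucket every library compound by its scaffold key."""
    table = ChemotypeTable()
    for rec in lib.records:
        scaf = extract_scaffold(rec.structure)
        table.add(rec.id, None if scaf is None else scaf.key)
    return table


def chemotype_overlap(reference: ChemotypeTable, search: ChemotypeTable) -> list[str]:
    """Search-library compound ids whose chemotype occurs in the reference.

    Returned in stable search-input order; acyclic compounds never match.
    """
    ref_keys = set(reference.entries)
    return [
        cid for cid, key in search.assignments if key is not None and key in ref_keys
    ]


def write_chemotype_csv(table: ChemotypeTable, path) -> None:
    import csv

    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["scaffold_smiles", "n_members", "member_ids"])
        for key, members in table.entries.items():
            writer.writerow([key, len(members), ";".join(members)])
        if table.acyclic_ids:
            writer.writerow(["<acyclic>", len(table.acyclic_ids), ";".join(table.acyclic_ids)])
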