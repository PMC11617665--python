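"""Independent brute-force oracles used to cross-check the implementation.

These deliberately take different algorithmic routes from the package:
the scaffold oracle prunes one terminal atom per pass with ring/linker
status recomputed on the current graph each time (the package computes a
keep-set in two phases); the superposition oracle uses Horn's closed-form
quaternion solution (the package uses the SVD-based Kabsch construction);
the consensus oracle recomputes normalized means spreadsheet-style.
"""

from __future__ import annotations

import numpy as np
from rdkit import Chem


# ---------------------------------------------------------------------------
# scaffold pruning oracle
# ---------------------------------------------------------------------------

def _is_linker(alive: set[int], adjacency: dict[int, set[int]], ring: set[int], u: int) -> bool:
    """u (non-ring) is a linker iff >= 2 of its branches reach ring atoms."""
    branches_with_ring = 0
    for v in adjacency[u] & alive:
        # BFS in alive graph with u removed, starting at v
        seen = {u, v}
        stack = [v]
        found = v in ring
        while stack and not found:
            w = stack.pop()
            for x in adjacency[w] & alive:
                if x not in seen:
                    seen.add(x)
                    if x in ring:
                        found = True
                        break
                    stack.append(x)
        if found:
            branches_with_ring += 1
    return branches_with_ring >= 2


def murcko_pruning_oracle(smiles: str) -> str | None:
    """Scaffold key by one-atom-per-pass terminal pruning.

    Eligible for removal: a terminal (alive-degree <= 1) non-ring heavy
    atom that is not double-bonded to a ring or linker atom.  Returns the
    canonical stereo-stripped SMILES of what remains, or None if the
    molecule is acyclic.
    """
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise ValueError(f"unparsable SMILES {smiles!r}")
    ring = {a.GetIdx() for a in mol.GetAtoms() if a.IsInRing()}
    if not ring:
        return None
    adjacency = {
        a.GetIdx(): {n.GetIdx() for n in a.GetNeighbors()} for a in mol.GetAtoms()
    }
    double = {
        frozenset((b.GetBeginAtomIdx(), b.GetEndAtomIdx()))
        for b in mol.GetBonds()
        if b.GetBondType() == Chem.BondType.DOUBLE
    }
    alive = set(adjacency)
    while True:
        removed = False
        for u in sorted(alive):
            if u in ring:
                continue
            neighbors = adjacency[u] & alive
            if len(neighbors) > 1:
                continue
            protected = False
            for v in neighbors:
                if frozenset((u, v)) in double and (
                    v in ring or _is_linker(alive, adjacency, ring, v)
                ):
                    protected = True
            if not protected:
                alive.remove(u)
                removed = True
                break
        if not removed:
            break
    return _submol_smiles(mol, alive)


def _submol_smiles(mol: Chem.Mol, keep: set[int]) -> str:
    rw = Chem.RWMol(mol)
    aromatic_n = {
        a.GetIdx()
        for a in mol.GetAtoms()
        if a.GetIsAromatic()
        and a.GetAtomicNum() == 7
        and a.GetTotalNumHs() == 0
        and any(n.GetIdx() not in keep for n in a.GetNeighbors())
    }
    old_to_new = {}
    new = 0
    for old in range(mol.GetNumAtoms()):
        if old in keep:
            old_to_new[old] = new
            new += 1
    for idx in sorted(set(range(mol.GetNumAtoms())) - keep, reverse=True):
        rw.RemoveAtom(idx)
    for old in aromatic_n & keep:
        atom = rw.GetAtomWithIdx(old_to_new[old])
        if atom.GetTotalNumHs() == 0:
            atom.SetNumExplicitHs(1)
    for atom in rw.GetAtoms():
        if atom.GetAtomicNum() == 6 and not atom.GetIsAromatic():
            atom.SetNumExplicitHs(0)
            atom.SetNoImplicit(False)
    sub = rw.GetMol()
    Chem.SanitizeMol(sub)
    Chem.RemoveStereochemistry(sub)
    return Chem.MolToSmiles(sub)


# ---------------------------------------------------------------------------
# quaternion superposition oracle (Horn 1987 closed form)
# ---------------------------------------------------------------------------

def quaternion_rmsd_oracle(x: np.ndarray, y: np.ndarray) -> float:
    """Minimal RMSD between point sets after optimal proper rotation."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    xc = x - x.mean(axis=0)
    yc = y - y.mean(axis=0)
    m = xc.T @ yc
    sxx, sxy, sxz = m[0]
    syx, syy, syz = m[1]
    szx, szy, szz = m[2]
    k = np.array(
        [
            [sxx + syy + szz, syz - szy, szx - sxz, sxy - syx],
            [syz - szy, sxx - syy - szz, sxy + syx, szx + sxz],
            [szx - sxz, sxy + syx, -sxx + syy - szz, syz + szy],
            [sxy - syx, szx + sxz, syz + szy, -sxx - syy + szz],
        ]
    )
    lam = np.linalg.eigvalsh(k)[-1]
    n = x.shape[0]
    msd = (np.sum(xc**2) + np.sum(yc**2) - 2.0 * lam) / n
    return float(np.sqrt(max(msd, 0.0)))


# ---------------------------------------------------------------------------
# consensus ranking oracle
# ---------------------------------------------------------------------------

def consensus_oracle(tables: dict[str, dict[str, float]], orientations: dict[str, str]):
    """Spreadsheet-style recomputation: normalize, average, sort."""
    normalized = {}
    for program, scores in tables.items():
        values = list(scores.values())
        lo, hi = min(values), max(values)
        if orientations[program] == "lower_is_better":
            normalized[program] = {c: (hi - s) / (hi - lo) for c, s in scores.items()}
        else:
            normalized[program] = {c: (s - lo) / (hi - lo) for c, s in scores.items()}
    ids = set.intersection(*(set(t) for t in tables.values()))
    consensus = {
        c: sum(normalized[p][c] for p in tables) / len(tables) for c in ids
    }
    vina = normalized.get("vina", {})
    order = sorted(ids, key=lambda c: (-consensus[c], -vina.get(c, 0.0), c))
    return consensus, order
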