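"""Structure and trajectory post-processing, plus MM/PBSA aggregation.

Engines (docking, MD) are consumed as coordinates and energy tables.
This module provides least-squares rigid superposition (Kabsch, proper
rotation only), pose and trajectory RMSD, per-residue RMSF, residue
contact occupancy at a distance cutoff, and the combination of per-frame
molecular-mechanics / Poisson-Boltzmann surface-area energy components
into a binding free energy:

    dG_bind = dH - T dS ~ dE_MM + dG_solv - T dS
    dE_MM   = dE_internal + dE_electrostatic + dE_vdw
    dG_solv = dG_PB + dG_SA

where each delta is complex - receptor - ligand per frame.  The entropy
term is accepted as a precomputed scalar or per-frame column; without it
the result is flagged as an enthalpy-only estimate.

Conventions: coordinates in Angstrom; trajectory RMSD/RMSF defaults to
the backbone atom names C, CA and N; pose RMSD for docking validation
uses identity atom correspondence by input order without superposition.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist

from .errors import ParameterError

BACKBONE_NAMES = ("C", "CA", "N")


# ---------------------------------------------------------------------------
# coordinate containers
# ---------------------------------------------------------------------------

@dataclass
class CoordinateSet:
    """Atom records with coordinates (Angstrom) and selection helpers."""

    coords: np.ndarray
    atom_names: np.ndarray
    res_ids: np.ndarray
    res_names: np.ndarray
    elements: np.ndarray

    def __post_init__(self):
        self.coords = np.asarray(self.coords, dtype=float)
        self.atom_names = np.asarray(self.atom_names, dtype=object)
        self.res_ids = np.asarray(self.res_ids, dtype=int)
        self.res_names = np.asarray(self.res_names, dtype=object)
        self.elements = np.asarray(self.elements, dtype=object)
        if self.coords.ndim != 2 or self.coords.shape[1] != 3:
            raise ParameterError("coords must be (n, 3)")
        if self.coords.shape[0] == 0:
            raise ParameterError("empty coordinate set")
        if not np.all(np.isfinite(self.coords)):
            raise ParameterError("non-finite coordinates")

    def __len__(self) -> int:
        return self.coords.shape[0]

    def mask_by_name(self, names: Sequence[str]) -> np.ndarray:
        return np.isin(self.atom_names.astype(str), list(names))

    def backbone_mask(self) -> np.ndarray:
        return self.mask_by_name(BACKBONE_NAMES)

    def heavy_mask(self) -> np.ndarray:
        return self.elements.astype(str) != "H"

    def mask_by_residue_name(self, res_names: Sequence[str]) -> np.ndarray:
        return np.isin(self.res_names.astype(str), list(res_names))

    def with_coords(self, coords: np.ndarray) -> "CoordinateSet":
        return CoordinateSet(
            coords, self.atom_names, self.res_ids, self.res_names, self.elements
        )


@dataclass
class Trajectory:
    """Frame-indexed coordinates sharing one atom table."""

    coords: np.ndarray  # (n_frames, n_atoms, 3)
    template: CoordinateSet
    timestep_ns: float = 1.0

    def __post_init__(self):
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 3 or self.coords.shape[2] != 3:
            raise ParameterError("trajectory coords must be (frames, atoms, 3)")
        if self.coords.shape[0] == 0:
            raise ParameterError("empty trajectory")
        if self.coords.shape[1] != len(self.template):
            raise ParameterError("frame atom count does not match template")

    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]

    def frame(self, i: int) -> CoordinateSet:
        return self.template.with_coords(self.coords[i])

    def times(self) -> np.ndarray:
        return np.arange(self.n_frames) * self.timestep_ns


# ---------------------------------------------------------------------------
# PDB input/output (via biotite; element inferred from atom name if absent)
# ---------------------------------------------------------------------------

def _infer_elements(atom_names: np.ndarray, elements: np.ndarray) -> np.ndarray:
    out = elements.astype(str).copy().astype(object)
    for i, (el, name) in enumerate(zip(out, atom_names.astype(str))):
        if not el.strip():
            stripped = name.strip().lstrip("0123456789")
            out[i] = stripped[:1].upper() if stripped else "C"
    return out


def _from_atom_array(arr) -> CoordinateSet:
    return CoordinateSet(
        coords=np.asarray(arr.coord, dtype=float),
        atom_names=np.asarray(arr.atom_name, dtype=object),
        res_ids=np.asarray(arr.res_id, dtype=int),
        res_names=np.asarray(arr.res_name, dtype=object),
        elements=_infer_elements(
            np.asarray(arr.atom_name, dtype=object), np.asarray(arr.element)
        ),
    )


def read_pdb(path: str | Path) -> Trajectory:
    """Read a (possibly multi-MODEL) PDB file into a :class:`Trajectory`."""
    from biotite.structure.io.pdb import PDBFile

    pdb = PDBFile.read(str(path))
    stack = pdb.get_structure()
    template = _from_atom_array(stack[0])
    return Trajectory(np.asarray(stack.coord, dtype=float), template)


def read_pdb_frame(path: str | Path, model: int = 1) -> CoordinateSet:
    traj = read_pdb(path)
    return traj.frame(model - 1)


def write_pdb(path: str | Path, obj: "CoordinateSet | Trajectory") -> None:
    import biotite.structure as struc
    from biotite.structure.io.pdb import PDBFile

    if isinstance(obj, CoordinateSet):
        traj = Trajectory(obj.coords[None, :, :], obj)
    else:
        traj = obj
    template = traj.template
    arr = struc.AtomArray(len(template))
    arr.coord = traj.coords[0].astype(np.float32)
    arr.atom_name = template.atom_names.astype(str)
    arr.res_id = template.res_ids
    arr.res_name = template.res_names.astype(str)
    arr.chain_id = np.full(len(template), "A")
    arr.element = template.elements.astype(str)
    arr.hetero = np.isin(template.res_names.astype(str), ["LIG"])
    stack = struc.stack([arr] * traj.n_frames)
    stack.coord = traj.coords.astype(np.float32)
    pdb = PDBFile()
    pdb.set_structure(stack)
    pdb.write(str(path))


# ---------------------------------------------------------------------------
# superposition and RMSD
# ---------------------------------------------------------------------------

@dataclass
class Superposition:
    rotation: np.ndarray
    translation: np.ndarray
    rmsd: float

    def apply(self, coords: np.ndarray) -> np.ndarray:
        return coords @ self.rotation.T + self.translation


def _coords_of(obj, selection=None) -> np.ndarray:
    xyz = obj.coords if isinstance(obj, CoordinateSet) else np.asarray(obj, dtype=float)
    if selection is not None:
        xyz = xyz[np.asarray(selection)]
    return xyz


def kabsch_superpose(mobile, reference, selection=None) -> Superposition:
    """Least-squares rigid superposition (proper rotation, det = +1).

    ``selection`` (a boolean mask or index array) restricts the atoms used
    to determine the transform and to compute the post-fit RMSD.
    """
    x = _coords_of(mobile, selection)
    y = _coords_of(reference, selection)
    if x.shape != y.shape:
        raise ParameterError("mobile and reference selections differ in size")
    if x.shape[0] < 3:
        raise ParameterError("need >= 3 atoms for superposition")
    xc, yc = x.mean(axis=0), y.mean(axis=0)
    h = (x - xc).T @ (y - yc)
    u, s, vt = np.linalg.svd(h)
    if s[1] < 1e-10 * max(s[0], 1.0):
        warnings.warn("nearly collinear selection; superposition is ill-conditioned")
    d = np.sign(np.linalg.det(vt.T @ u.T))
    rot = vt.T @ np.diag([1.0, 1.0, d]) @ u.T
    trans = yc - rot @ xc
    fitted = x @ rot.T + trans
    value = float(np.sqrt(np.mean(np.sum((fitted - y) ** 2, axis=1))))
    return Superposition(rot, trans, value)


def rmsd(a, b, selection=None, superpose: bool = False) -> float:
    """Root-mean-square deviation over the selected atoms (Angstrom).

    With ``superpose=True`` the optimal rigid fit is applied first; pose
    comparison against a crystallographic reference keeps the frame fixed
    (``superpose=False``) because both poses live in the same site.
    """
    x = _coords_of(a, selection)
    y = _coords_of(b, selection)
    if x.shape != y.shape:
        raise ParameterError("mismatched atom counts")
    if superpose:
        return kabsch_superpose(x, y).rmsd
    return float(np.sqrt(np.mean(np.sum((x - y) ** 2, axis=1))))


def rmsd_series(
    traj: Trajectory, reference: CoordinateSet, selection=None
) -> list[tuple[float, float]]:
    """Per-frame superposed RMSD against a reference structure.

    Defaults to the backbone C/CA/N selection.
    """
    if selection is None:
        selection = traj.template.backbone_mask()
    times = traj.times()
    out = []
    ref = reference.coords
    for i in range(traj.n_frames):
        sup = kabsch_superpose(traj.coords[i], ref, selection)
        out.append((float(times[i]), sup.rmsd))
    return out


def _align_frames(coords: np.ndarray, selection, n_passes: int = 2) -> np.ndarray:
    """Align every frame to the evolving mean structure (2 passes)."""
    aligned = coords.copy()
    reference = aligned[0]
    for _ in range(n_passes):
        for i in range(aligned.shape[0]):
            sup = kabsch_superpose(aligned[i], reference, selection)
            aligned[i] = sup.apply(aligned[i])
        reference = aligned.mean(axis=0)
    return aligned


def rmsf(
    traj: Trajectory, selection=None, by_residue: bool = True, align_selection=None
):
    """Per-residue (or per-atom) RMS fluctuation about the time mean.

    Frames are first aligned to their mean structure (two alignment
    passes) so rigid-body motion does not inflate the fluctuation.
    ``align_selection`` restricts the atoms that determine the alignment
    (e.g. a stable core, so a mobile tail cannot drag the fit); it
    defaults to ``selection``.
    """
    if traj.n_frames < 2:
        raise ParameterError("need >= 2 frames for RMSF")
    if selection is None:
        selection = traj.template.backbone_mask()
    selection = np.asarray(selection)
    if align_selection is None:
        align_selection = selection
    aligned = _align_frames(traj.coords, np.asarray(align_selection))
    sub = aligned[:, selection if selection.dtype == bool else selection, :]
    mean = sub.mean(axis=0)
    per_atom = np.sqrt(np.mean(np.sum((sub - mean) ** 2, axis=2), axis=0))
    if not by_residue:
        return per_atom
    res_ids = traj.template.res_ids[selection]
    out = []
    for rid in np.unique(res_ids):
        out.append((int(rid), float(per_atom[res_ids == rid].mean())))
    return out


def contact_residues(
    traj: Trajectory,
    ligand_selection,
    cutoff: float = 4.0,
    frame_range: Optional[tuple[int, int]] = None,
    protein_selection=None,
) -> dict[int, float]:
    """Residue -> fraction of frames with any heavy-atom contact <= cutoff.

    ``frame_range`` restricts the analysis window as (start, stop)
    frame indices, stop exclusive (e.g. to split a trajectory into an
    early and a late binding mode).
    """
    template = traj.template
    lig = np.asarray(ligand_selection)
    if lig.dtype != bool:
        mask = np.zeros(len(template), dtype=bool)
        mask[lig] = True
        lig = mask
    heavy = template.heavy_mask()
    lig_mask = lig & heavy
    if protein_selection is None:
        prot_mask = ~lig & heavy
    else:
        prot_mask = np.asarray(protein_selection) & heavy
        if np.any(prot_mask & lig_mask):
            raise ParameterError("ligand and protein selections overlap")
    if not lig_mask.any() or not prot_mask.any():
        raise ParameterError("empty ligand or protein selection")
    start, stop = (0, traj.n_frames) if frame_range is None else frame_range
    frames = range(start, stop)
    n_frames = len(frames)
    if n_frames == 0:
        raise ParameterError("empty frame window")
    prot_res = template.res_ids[prot_mask]
    counts: dict[int, int] = {}
    for f in frames:
        dists = cdist(traj.coords[f][lig_mask], traj.coords[f][prot_mask])
        contact_atoms = np.any(dists <= cutoff, axis=0)
        for rid in np.unique(prot_res[contact_atoms]):
            counts[int(rid)] = counts.get(int(rid), 0) + 1
    return {rid: c / n_frames for rid, c in sorted(counts.items())}


# ---------------------------------------------------------------------------
# MM/PBSA aggregation
# ---------------------------------------------------------------------------

COMPONENTS = ("E_internal", "E_elec", "E_vdw", "G_PB", "G_SA")
SYSTEMS = ("complex", "receptor", "ligand")


@dataclass
class EnergyComponentTable:
    """Per-frame MM/PBSA components for complex, receptor and ligand."""

    frame: pd.DataFrame

    def __post_init__(self):
        required = {"frame", "system", *COMPONENTS}
        missing = required - set(self.frame.columns)
        if missing:
            raise ParameterError(f"missing energy columns {sorted(missing)}")
        if not np.all(np.isfinite(self.frame[list(COMPONENTS)].to_numpy())):
            raise ParameterError("non-finite energy components")

    @classmethod
    def from_csv(cls, path: str | Path) -> "EnergyComponentTable":
        return cls(pd.read_csv(path))


@dataclass
class MMPBSASummary:
    """Mean +/- sd (over frames) of the binding energy and its breakdown."""

    dg_bind: float
    dg_bind_sd: float
    components: dict[str, tuple[float, float]]
    entropy_included: bool
    n_frames: int
    per_frame: pd.DataFrame = field(repr=False, default=None)


def mmpbsa_combine(
    table: EnergyComponentTable, minus_TdS: Optional[float] = None
) -> MMPBSASummary:
    """Combine per-frame components into a binding free energy.

    Per frame each component delta is complex - receptor - ligand; the
    gas-phase, solvation and total terms follow the standard MM/PBSA
    decomposition.  ``minus_TdS`` (scalar, kcal/mol) or a per-frame
    ``minus_TdS`` column supplies the entropy term; absent both, the
    summary is an enthalpy-only estimate (``entropy_included=False``).
    """
    df = table.frame
    pivot = df.pivot_table(
        index="frame", columns="system", values=list(COMPONENTS), sort=True
    )
    for sysname in SYSTEMS:
        for comp in COMPONENTS:
            if (comp, sysname) not in pivot.columns or pivot[(comp, sysname)].isna().any():
                raise ParameterError(f"incomplete {sysname} rows for {comp}")
    delta = pd.DataFrame(index=pivot.index)
    for comp in COMPONENTS:
        delta["d" + comp] = (
            pivot[(comp, "complex")]
            - pivot[(comp, "receptor")]
            - pivot[(comp, "ligand")]
        )
    delta["dE_MM"] = delta["dE_internal"] + delta["dE_elec"] + delta["dE_vdw"]
    delta["dG_solv"] = delta["dG_PB"] + delta["dG_SA"]
    delta["dH"] = delta["dE_MM"] + delta["dG_solv"]

    entropy_included = False
    if minus_TdS is not None:
        delta["minus_TdS"] = float(minus_TdS)
        entropy_included = True
    elif "minus_TdS" in df.columns and df["minus_TdS"].notna().any():
        per_frame_tds = df.dropna(subset=["minus_TdS"]).groupby("frame")["minus_TdS"].first()
        delta["minus_TdS"] = per_frame_tds.reindex(delta.index)
        if delta["minus_TdS"].isna().any():
            raise ParameterError("per-frame minus_TdS column is incomplete")
        entropy_included = True
    delta["dG_bind"] = delta["dH"] + (delta["minus_TdS"] if entropy_included else 0.0)

    components = {
        name: (float(delta[name].mean()), float(delta[name].std(ddof=0)))
        for name in delta.columns
        if name != "dG_bind"
    }
    return MMPBSASummary(
        dg_bind=float(delta["dG_bind"].mean()),
        dg_bind_sd=float(delta["dG_bind"].std(ddof=0)),
        components=components,
        entropy_included=entropy_included,
        n_frames=len(delta),
        per_frame=delta.reset_index(),
    )
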