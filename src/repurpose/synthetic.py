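"""Synthetic inputs for every pipeline stage.

Each generator emulates the structure of one real input — scaffold-
decorated compound libraries, correlated three-program docking score
tables, dose-response and inhibition-rate datasets, harmonic toy
trajectories, and Gaussian MM/PBSA component tables — and records the
planted ground truth alongside, so every downstream stage can be tested
for exact recovery with no external data.

Defaults mirror the study conditions the pipeline targets: the kinetics
generators default to Vmax = 36.06 mM/min, Km = 25.71 mM, Ki = 0.0234 mM
on inhibitor grid {0, 0.005, 0.040, 0.060} mM and substrate grid
{0.10 ... 0.50} mM, the dose-response generator to IC50 = 0.044 mM with
A100 = 100 and s = 1, and the docking generator to 1075 compounds.  Noise
on kinetic data is multiplicative Gaussian (CV-parameterized), the
standard error model for absorbance-derived rates.  Same seed, same
bytes: every generator is driven by a single ``numpy`` Generator.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from rdkit import Chem
from rdkit.Chem import Descriptors

from .funnel import ScoreTable
from .kinetics import (
    DoseResponseDataset,
    RateDataset,
    competitive_rate,
    dose_response_model,
    mixed_rate,
    noncompetitive_rate,
    uncompetitive_rate,
)
from .structural import CoordinateSet, EnergyComponentTable, Trajectory
from .errors import ParameterError

# scaffold templates are emitted verbatim (canonicalized) as ground truth
SCAFFOLD_POOL = (
    "c1ccc2ccccc2c1",               # naphthalene
    "c1ccc(-c2ccccc2)cc1",          # biphenyl
    "c1ccc2ncccc2c1",               # quinoline
    "O=C(c1ccccc1)c1ccccc1",        # benzophenone (keto on the linker)
    "c1ccc2c(c1)oc1ccccc12",        # dibenzofuran
    "c1ccc2c(c1)[nH]c1ccccc12",     # carbazole
    "c1ccc(Oc2ccccc2)cc1",          # diphenyl ether
    "C1CCN(c2ccccc2)CC1",           # N-phenylpiperidine
)

SIDE_CHAINS = ("C", "CC", "CCC", "CCCC", "CCCCC", "Cl", "Br", "F", "OC", "C(C)C")


@dataclass
class LibraryConfig:
    n_scaffolds: int = 5
    decorations_per_scaffold: int = 6
    mw_range: tuple[float, float] = (160.0, 1000.0)
    duplicate_fraction: float = 0.0
    mw_violation_fraction: float = 0.0
    activity_violation_fraction: float = 0.0
    source_class: str = "PTP1B"
    with_activities: bool = True
    scaffold_indices: Optional[tuple[int, ...]] = None  # pool subset override


@dataclass
class DockingConfig:
    n_compounds: int = 1075
    rank_correlation: float = 0.85
    program_offsets: dict = field(
        default_factory=lambda: {"vina": -8.0, "autodock42": -9.0, "gold": 50.0}
    )
    program_scales: dict = field(
        default_factory=lambda: {"vina": -1.2, "autodock42": -1.5, "gold": 12.0}
    )


@dataclass
class KineticsConfig:
    Vmax: float = 36.06       # mM/min
    Km: float = 25.71         # mM
    Ki: float = 0.0234        # mM
    Ki_prime: float = 0.0234  # mM, mixed mechanism only
    substrate_grid: tuple = (0.10, 0.20, 0.30, 0.40, 0.50)   # mM
    inhibitor_grid: tuple = (0.0, 0.005, 0.040, 0.060)       # mM
    noise_cv: float = 0.02
    n_replicates: int = 3
    mechanism: str = "competitive"


@dataclass
class DoseResponseConfig:
    A100: float = 100.0
    IC50: float = 0.044       # mM
    s: float = 1.0
    conc_grid: tuple = tuple(np.geomspace(0.005, 0.5, 8).round(6))
    noise_cv: float = 0.02
    n_replicates: int = 3


@dataclass
class TrajectoryConfig:
    n_frames: int = 100
    n_residues: int = 20
    amplitudes: Optional[Sequence[float]] = None  # per-residue, Angstrom
    mobile_tail: int = 5          # residues at the C-terminus
    tail_amplitude: float = 2.0
    base_amplitude: float = 0.3
    include_ligand: bool = False
    ligand_contact_frames: int = 0
    contact_residue: int = 10     # 1-based residue id the ligand touches
    contact_distance: float = 3.5
    far_distance: float = 15.0


@dataclass
class EnergyConfig:
    n_frames: int = 200
    delta_means: dict = field(
        default_factory=lambda: {
            "E_internal": 0.0,
            "E_elec": -25.0,
            "E_vdw": -35.0,
            "G_PB": 20.0,
            "G_SA": -5.11,
        }
    )
    component_sd: float = 1.6     # per system-component, kcal/mol
    minus_TdS: Optional[float] = None


@dataclass
class GeneratorConfig:
    seed: int = 0
    library: LibraryConfig = field(default_factory=LibraryConfig)
    docking: DockingConfig = field(default_factory=DockingConfig)
    kinetics: KineticsConfig = field(default_factory=KineticsConfig)
    dose_response: DoseResponseConfig = field(default_factory=DoseResponseConfig)
    trajectory: TrajectoryConfig = field(default_factory=TrajectoryConfig)
    energies: EnergyConfig = field(default_factory=EnergyConfig)


# ---------------------------------------------------------------------------
# compound library
# ---------------------------------------------------------------------------

def _attach_chain(mol: Chem.Mol, chain_smiles: str, rng: np.random.Generator):
    """Attach a side chain at a random substitutable heavy atom."""
    chain = Chem.MolFromSmiles(chain_smiles)
    combined = Chem.RWMol(Chem.CombineMols(mol, chain))
    candidates = [
        a.GetIdx()
        for a in mol.GetAtoms()
        if a.GetTotalNumHs() > 0 and a.GetAtomicNum() in (6, 7)
    ]
    if not candidates:
        return mol
    site = int(rng.choice(candidates))
    combined.AddBond(site, mol.GetNumAtoms(), Chem.BondType.SINGLE)
    out = combined.GetMol()
    try:
        Chem.SanitizeMol(out)
    except Exception:
        return mol
    return out


def gen_library(
    config: LibraryConfig, seed: int = 0
) -> tuple[pd.DataFrame, dict]:
    """Scaffold-decorated compound library with planted curation violations.

    Returns the library table (columns id, smiles, activity_um,
    activity_type, source_class) and a ground-truth dict mapping compound
    id to its scaffold key and any planted violation.
    """
    rng = np.random.default_rng(seed)
    if config.scaffold_indices is not None:
        if any(i >= len(SCAFFOLD_POOL) for i in config.scaffold_indices):
            raise ParameterError(f"scaffold index out of range (pool size {len(SCAFFOLD_POOL)})")
        scaffolds = tuple(SCAFFOLD_POOL[i] for i in config.scaffold_indices)
    elif config.n_scaffolds > len(SCAFFOLD_POOL):
        raise ParameterError(f"at most {len(SCAFFOLD_POOL)} scaffolds available")
    else:
        scaffolds = SCAFFOLD_POOL[: config.n_scaffolds]
    rows, truth = [], {}
    seen_smiles = set()
    counter = 0
    for scaffold_smiles in scaffolds:
        scaffold_key = Chem.MolToSmiles(Chem.MolFromSmiles(scaffold_smiles))
        for _ in range(config.decorations_per_scaffold):
            mol = Chem.MolFromSmiles(scaffold_smiles)
            for attempt in range(30):
                trial = mol
                for _ in range(int(rng.integers(1, 4))):
                    trial = _attach_chain(
                        trial, SIDE_CHAINS[int(rng.integers(len(SIDE_CHAINS)))], rng
                    )
                # top up with butyl chains until inside the MW window
                guard = 0
                while Descriptors.MolWt(trial) < config.mw_range[0] and guard < 20:
                    trial = _attach_chain(trial, "CCCC", rng)
                    guard += 1
                smi = Chem.MolToSmiles(trial)
                if smi not in seen_smiles:
                    break
            seen_smiles.add(smi)
            counter += 1
            cid = f"SYN{counter:04d}"
            activity = (
                float(10 ** rng.uniform(-2, 2)) if config.with_activities else None
            )
            rows.append(
                {
                    "id": cid,
                    "smiles": smi,
                    "activity_um": activity,
                    "activity_type": "IC50" if activity is not None else "none",
                    "source_class": config.source_class,
                }
            )
            truth[cid] = {"scaffold_key": scaffold_key, "violation": "none"}

    n = len(rows)

    def _planted(fraction: float) -> int:
        return int(round(fraction * n))

    for j in range(_planted(config.mw_violation_fraction)):
        counter += 1
        cid = f"SYN{counter:04d}"
        if j % 2 == 0:  # below the window
            smi, tag = "Cc1ccccc1", "mw_low"
        else:           # above the window
            smi, tag = "C" * 70 + "c1ccc2ccccc2c1", "mw_high"
        rows.append(
            {
                "id": cid,
                "smiles": smi,
                "activity_um": 10.0 if config.with_activities else None,
                "activity_type": "IC50" if config.with_activities else "none",
                "source_class": config.source_class,
            }
        )
        truth[cid] = {"scaffold_key": None, "violation": tag}

    originals = [r for r in rows if truth[r["id"]]["violation"] == "none"]
    for j in range(_planted(config.duplicate_fraction)):
        src = originals[int(rng.integers(len(originals)))]
        counter += 1
        cid = f"SYN{counter:04d}"
        mol = Chem.MolFromSmiles(src["smiles"])
        variant = Chem.MolToSmiles(
            mol, canonical=False, rootedAtAtom=int(rng.integers(mol.GetNumAtoms()))
        )
        activity = (
            None
            if src["activity_um"] is None
            else float(src["activity_um"]) * float(rng.uniform(1.5, 4.0))
        )
        rows.append(
            {
                "id": cid,
                "smiles": variant,
                "activity_um": activity,
                "activity_type": src["activity_type"],
                "source_class": src["source_class"],
            }
        )
        truth[cid] = {
            "scaffold_key": truth[src["id"]]["scaffold_key"],
            "violation": f"duplicate_of:{src['id']}",
        }

    if config.with_activities:
        for j in range(_planted(config.activity_violation_fraction)):
            counter += 1
            cid = f"SYN{counter:04d}"
            mol = Chem.MolFromSmiles(SCAFFOLD_POOL[0])
            trial = _attach_chain(mol, "CCCC", rng)
            trial = _attach_chain(trial, SIDE_CHAINS[int(rng.integers(len(SIDE_CHAINS)))], rng)
            smi = Chem.MolToSmiles(trial)
            rows.append(
                {
                    "id": cid,
                    "smiles": smi,
                    "activity_um": float(rng.uniform(101.0, 900.0)),
                    "activity_type": "IC50",
                    "source_class": config.source_class,
                }
            )
            truth[cid] = {
                "scaffold_key": Chem.MolToSmiles(Chem.MolFromSmiles(SCAFFOLD_POOL[0])),
                "violation": "activity",
            }

    return pd.DataFrame(rows), truth


# ---------------------------------------------------------------------------
# docking scores
# ---------------------------------------------------------------------------

def gen_docking_scores(
    config: DockingConfig, seed: int = 0
) -> tuple[dict[str, ScoreTable], dict]:
    """Three correlated score tables driven by one latent affinity.

    The latent->score correlation is calibrated so the pairwise Spearman
    rank correlation between programs matches ``rank_correlation``
    (Pearson rho = 2 sin(pi r_s / 6) for bivariate normal scores).
    Vina/AutoDock scores are emitted as negative kcal/mol (lower is
    better), GOLD as positive fitness (higher is better).
    """
    if not 0.0 <= config.rank_correlation <= 1.0:
        raise ParameterError("rank_correlation must be in [0, 1]")
    rng = np.random.default_rng(seed)
    n = config.n_compounds
    ids = [f"C{i + 1:05d}" for i in range(n)]
    latent = rng.normal(size=n)
    rho = 2.0 * np.sin(np.pi * config.rank_correlation / 6.0)
    tables = {}
    for program in ("vina", "autodock42", "gold"):
        eps = rng.normal(size=n)
        z = np.sqrt(rho) * latent + np.sqrt(1.0 - rho) * eps
        raw = config.program_offsets[program] + config.program_scales[program] * z
        tables[program] = ScoreTable(program, dict(zip(ids, raw.tolist())))
    truth = {
        "latent_order_best_first": [
            ids[i] for i in np.argsort(-latent)
        ],
        "rank_correlation": config.rank_correlation,
    }
    return tables, truth


# ---------------------------------------------------------------------------
# kinetics
# ---------------------------------------------------------------------------

def gen_dose_response(
    config: DoseResponseConfig, seed: int = 0
) -> tuple[DoseResponseDataset, dict]:
    """Dose-response data from the Hill model with multiplicative noise."""
    rng = np.random.default_rng(seed)
    conc = np.tile(np.asarray(config.conc_grid, dtype=float), config.n_replicates)
    replicate = np.repeat(
        np.arange(1, config.n_replicates + 1), len(config.conc_grid)
    )
    clean = dose_response_model(conc, config.A100, config.IC50, config.s)
    noisy = clean * (1.0 + rng.normal(0.0, config.noise_cv, conc.size))
    truth = {"A100": config.A100, "IC50": config.IC50, "s": config.s}
    return DoseResponseDataset(conc, noisy, replicate), truth


_MECHANISM_LAWS = {
    "competitive": competitive_rate,
    "uncompetitive": uncompetitive_rate,
    "noncompetitive": noncompetitive_rate,
    "mixed": mixed_rate,
}


def gen_rate_data(
    config: KineticsConfig, seed: int = 0
) -> tuple[RateDataset, dict]:
    """Full-factorial substrate x inhibitor x replicate rate data."""
    if config.mechanism not in _MECHANISM_LAWS:
        raise ParameterError(f"unknown mechanism {config.mechanism!r}")
    rng = np.random.default_rng(seed)
    S_grid = np.asarray(config.substrate_grid, dtype=float)
    I_grid = np.asarray(config.inhibitor_grid, dtype=float)
    S, I = np.meshgrid(S_grid, I_grid)
    S = np.tile(S.ravel(), config.n_replicates)
    I = np.tile(I.ravel(), config.n_replicates)
    law = _MECHANISM_LAWS[config.mechanism]
    args = [config.Vmax, config.Km, config.Ki]
    if config.mechanism == "mixed":
        args.append(config.Ki_prime)
    clean = law(S, I, *args)
    noisy = clean * (1.0 + rng.normal(0.0, config.noise_cv, S.size))
    truth = {
        "Vmax": config.Vmax,
        "Km": config.Km,
        "Ki": config.Ki,
        "mechanism": config.mechanism,
    }
    if config.mechanism == "mixed":
        truth["Ki_prime"] = config.Ki_prime
    return RateDataset(S, I, noisy), truth


# ---------------------------------------------------------------------------
# trajectories
# ---------------------------------------------------------------------------

def _toy_backbone(n_residues: int, include_ligand: bool) -> CoordinateSet:
    """Extended zig-zag toy backbone: N/CA/C per residue, 3.8 A spacing.

    The transverse offsets keep the chain non-collinear so rigid
    superposition is well conditioned.
    """
    names, res_ids, res_names, elements, coords = [], [], [], [], []
    offsets = {"N": (-1.2, 0.5, -0.3), "CA": (0.0, -0.5, 0.4), "C": (1.2, 0.3, -0.2)}
    for i in range(n_residues):
        for name in ("N", "CA", "C"):
            dx, dy, dz = offsets[name]
            names.append(name)
            res_ids.append(i + 1)
            res_names.append("GLY")
            elements.append(name[0])
            coords.append([3.8 * i + dx, dy, dz])
    if include_ligand:
        names.append("C1")
        res_ids.append(n_residues + 1)
        res_names.append("LIG")
        elements.append("C")
        coords.append([0.0, 0.0, 0.0])  # placed per frame
    return CoordinateSet(
        np.asarray(coords), np.asarray(names), np.asarray(res_ids),
        np.asarray(res_names), np.asarray(elements),
    )


def gen_trajectory(
    config: TrajectoryConfig, seed: int = 0
) -> tuple[Trajectory, CoordinateSet, dict]:
    """Toy trajectory with per-residue two-state wobble and optional ligand.

    Each residue hops between +A and -A along y with an independent,
    exactly balanced random sign sequence (equal dwell), so every atom's
    time mean is its base position and its fluctuation is exactly A when
    frames are aligned on the static core.  A mobile tail with a larger
    amplitude emulates an intrinsically disordered terminus.  With a
    ligand, the single ligand atom sits ``contact_distance`` above the
    contact residue's CA for the first ``ligand_contact_frames`` frames
    and ``far_distance`` afterwards, planting an exact occupancy.
    """
    rng = np.random.default_rng(seed)
    if config.n_frames % 2:
        raise ParameterError("n_frames must be even for exactly balanced dwell")
    template = _toy_backbone(config.n_residues, config.include_ligand)
    if config.amplitudes is not None:
        amplitudes = np.asarray(config.amplitudes, dtype=float)
        if amplitudes.size != config.n_residues:
            raise ParameterError("amplitude profile length != n_residues")
    else:
        amplitudes = np.full(config.n_residues, config.base_amplitude)
        if config.mobile_tail:
            amplitudes[-config.mobile_tail:] = config.tail_amplitude
    base = template.coords
    frames = np.repeat(base[None, :, :], config.n_frames, axis=0)
    half = config.n_frames // 2
    balanced = np.array([1.0] * half + [-1.0] * half)
    for i in range(config.n_residues):
        signs = rng.permutation(balanced)
        atom_mask = template.res_ids == i + 1
        frames[:, atom_mask, 1] += signs[:, None] * amplitudes[i]
    if config.include_ligand:
        lig_idx = len(template) - 1
        ca_pos = base[
            (template.res_ids == config.contact_residue)
            & (template.atom_names.astype(str) == "CA")
        ][0]
        for f in range(config.n_frames):
            z = (
                config.contact_distance
                if f < config.ligand_contact_frames
                else config.far_distance
            )
            frames[f, lig_idx] = [ca_pos[0], ca_pos[1], ca_pos[2] + z]
    truth = {
        "amplitudes": amplitudes.tolist(),
        "contact_residue": config.contact_residue if config.include_ligand else None,
        "contact_occupancy": (
            config.ligand_contact_frames / config.n_frames
            if config.include_ligand
            else None
        ),
    }
    return Trajectory(frames, template), template, truth


# ---------------------------------------------------------------------------
# MM/PBSA components
# ---------------------------------------------------------------------------

_SYSTEM_BASES = {
    "receptor": {"E_internal": 5000.0, "E_elec": -9000.0, "E_vdw": -800.0,
                 "G_PB": -2500.0, "G_SA": 90.0},
    "ligand": {"E_internal": 50.0, "E_elec": -30.0, "E_vdw": -5.0,
               "G_PB": -20.0, "G_SA": 5.0},
}


def gen_energy_components(
    config: EnergyConfig, seed: int = 0
) -> tuple[EnergyComponentTable, dict]:
    """Gaussian per-frame MM/PBSA component tables for the three systems.

    Complex means equal receptor + ligand + configured delta, so the
    ground-truth binding enthalpy is the sum of ``delta_means``.
    """
    rng = np.random.default_rng(seed)
    comps = list(config.delta_means)
    rows = []
    for system in ("complex", "receptor", "ligand"):
        means = dict(_SYSTEM_BASES.get(system, {}))
        if system == "complex":
            means = {
                c: _SYSTEM_BASES["receptor"][c]
                + _SYSTEM_BASES["ligand"][c]
                + config.delta_means[c]
                for c in comps
            }
        noise = rng.normal(0.0, config.component_sd, size=(config.n_frames, len(comps)))
        for f in range(config.n_frames):
            row = {"frame": f, "system": system}
            for j, c in enumerate(comps):
                row[c] = means[c] + noise[f, j]
            if config.minus_TdS is not None and system == "complex":
                row["minus_TdS"] = config.minus_TdS
            rows.append(row)
    df = pd.DataFrame(rows)
    df = df.rename(columns={"E_internal": "E_internal", "E_elec": "E_elec"})
    dH = float(sum(config.delta_means.values()))
    truth = {
        "dH": dH,
        "dG_bind": dH + (config.minus_TdS or 0.0),
        "delta_means": dict(config.delta_means),
        "delta_sd_theoretical": config.component_sd * np.sqrt(3.0),
    }
    return EnergyComponentTable(df), truth


# ---------------------------------------------------------------------------
# persistence helpers
# ---------------------------------------------------------------------------

def write_truth(truth: dict, path: str | Path) -> None:
    Path(path).write_text(json.dumps(truth, indent=2, sort_keys=True) + "\n")


def write_score_tables(tables: dict[str, ScoreTable], out_dir: str | Path) -> list[Path]:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = []
    for program, table in tables.items():
        df = pd.DataFrame(
            {
                "compound_id": list(table.scores),
                "program": program,
                "score": list(table.scores.values()),
            }
        )
        p = out_dir / f"scores_{program}.csv"
        df.to_csv(p, index=False, float_format="%.8g")
        paths.append(p)
    return paths
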