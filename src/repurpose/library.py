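"""Compound-library parsing and curation.

A screening campaign starts from annotated compound collections (actives
against the target, ligands of related anti-diabetic targets, approved
drugs).  Before any structure-based step the collections are curated with
three criteria: a molecular-weight window (160-1000 g/mol by default),
removal of duplicate structures, and removal of weak actives (reported
potency above 100 uM).  Drug entries carry no potency annotation and are
exempt from the activity criterion.

Structures are standardized before comparison: the largest organic fragment
is kept (salts and counter-ions stripped) and charges are neutralized where
valence-legal; the canonical SMILES of that parent structure is the
identity key used for deduplication, and molecular weight is computed from
the same parent with average atomic weights.
"""

from __future__ import annotations

import csv
import json
import logging
from dataclasses import dataclass, field, replace
from enum import Enum
from pathlib import Path
from typing import Optional

from rdkit import Chem, RDLogger
from rdkit.Chem import Descriptors
from rdkit.Chem.MolStandardize import rdMolStandardize

from .errors import EmptyLibraryError, ParameterError, StructureError

logger = logging.getLogger(__name__)

RDLogger.DisableLog("rdApp.*")


class ActivityType(str, Enum):
    IC50 = "IC50"
    KI = "Ki"
    EC50 = "EC50"
    NONE = "none"


class SourceClass(str, Enum):
    PTP1B = "PTP1B"
    ALPHA_GLUCOSIDASE = "alpha_glucosidase"
    PPAR_GAMMA = "PPAR_gamma"
    DRUG = "drug"


_LARGEST_FRAGMENT = rdMolStandardize.LargestFragmentChooser()
_UNCHARGER = rdMolStandardize.Uncharger()


def standardize_mol(mol: Chem.Mol) -> Chem.Mol:
    """Return the desalted, charge-neutralized parent structure."""
    parent = _LARGEST_FRAGMENT.choose(mol)
    parent = _UNCHARGER.uncharge(parent)
    Chem.SanitizeMol(parent)
    return parent


def canonical_key(mol: Chem.Mol) -> str:
    """Canonical SMILES of the standardized parent; the dedup identity."""
    return Chem.MolToSmiles(standardize_mol(mol))


@dataclass
class CompoundRecord:
    """One library entry.

    ``activity_value`` is a potency in uM; ``None`` for entries (drugs)
    with no annotation.  ``mw`` is computed from the desalted parent.
    """

    id: str
    structure: Chem.Mol
    canonical_key: str
    mw: float
    activity_value: Optional[float] = None
    activity_type: ActivityType = ActivityType.NONE
    source_class: SourceClass = SourceClass.DRUG
    smiles: str = ""

    def __post_init__(self):
        if self.structure is not None and self.mw <= 0:
            raise StructureError(f"record {self.id}: non-positive MW {self.mw}")
        if self.activity_value is not None and self.activity_value < 0:
            raise StructureError(
                f"record {self.id}: negative activity {self.activity_value}"
            )


@dataclass
class CuratedLibrary:
    """A list of records plus the per-step curation report.

    ``report`` maps step name to surviving record count, in application
    order; counts are monotonically non-increasing along the filter chain.
    """

    records: list[CompoundRecord]
    report: dict[str, int] = field(default_factory=dict)
    n_rejected_parse: int = 0

    def __len__(self) -> int:
        return len(self.records)

    def ids(self) -> list[str]:
        return [r.id for r in self.records]

    def with_step(self, step: str, records: list[CompoundRecord]) -> "CuratedLibrary":
        report = dict(self.report)
        report[step] = len(records)
        return CuratedLibrary(records, report, self.n_rejected_parse)


def _record_from_mol(
    mol: Chem.Mol,
    rec_id: str,
    activity_value: Optional[float] = None,
    activity_type: ActivityType = ActivityType.NONE,
    source_class: SourceClass = SourceClass.DRUG,
    smiles: str = "",
) -> CompoundRecord:
    parent = standardize_mol(mol)
    return CompoundRecord(
        id=rec_id,
        structure=parent,
        canonical_key=Chem.MolToSmiles(parent),
        mw=Descriptors.MolWt(parent),
        activity_value=activity_value,
        activity_type=activity_type,
        source_class=source_class,
        smiles=smiles or Chem.MolToSmiles(mol),
    )


def _parse_smiles_file(path: Path) -> tuple[list[CompoundRecord], int]:
    n_bad = 0
    records = []
    for i, line in enumerate(path.read_text().splitlines()):
        line = line.strip()
        if not line:
            continue
        parts = line.split()
        smi = parts[0]
        rec_id = parts[1] if len(parts) > 1 else f"mol{i + 1}"
        mol = Chem.MolFromSmiles(smi)
        if mol is None:
            logger.warning("unparsable SMILES at line %d: %s", i + 1, smi)
            n_bad += 1
            continue
        records.append(_record_from_mol(mol, rec_id, smiles=smi))
    return records, n_bad


def _parse_sdf(path: Path) -> tuple[list[CompoundRecord], int]:
    supplier = Chem.SDMolSupplier(str(path), sanitize=True)
    records, n_bad = [], 0
    for i, mol in enumerate(supplier):
        if mol is None:
            logger.warning("unparsable SDF entry %d", i + 1)
            n_bad += 1
            continue
        if mol.HasProp("id"):
            rec_id = mol.GetProp("id")
        elif mol.HasProp("_Name") and mol.GetProp("_Name").strip():
            rec_id = mol.GetProp("_Name").strip()
        else:
            rec_id = f"mol{i + 1}"
        records.append(_record_from_mol(mol, rec_id))
    return records, n_bad


def _parse_csv(path: Path) -> tuple[list[CompoundRecord], int]:
    records, n_bad = [], 0
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None or not {"id", "smiles"} <= set(reader.fieldnames):
            raise ParameterError(f"{path}: CSV needs columns 'id' and 'smiles'")
        for i, row in enumerate(reader):
            mol = Chem.MolFromSmiles(row["smiles"])
            if mol is None:
                logger.warning("row %d: unparsable SMILES %r", i + 1, row["smiles"])
                n_bad += 1
                continue
            raw_act = (row.get("activity_um") or "").strip()
            activity = float(raw_act) if raw_act else None
            act_type = ActivityType((row.get("activity_type") or "none").strip() or "none")
            src = SourceClass((row.get("source_class") or "drug").strip() or "drug")
            records.append(
                _record_from_mol(
                    mol, row["id"], activity, act_type, src, smiles=row["smiles"]
                )
            )
    return records, n_bad


def parse_library(path: str | Path, format: str = "csv") -> CuratedLibrary:
    """Parse a compound library file into an uncurated :class:`CuratedLibrary`.

    Unparsable entries are logged and counted, not fatal; a file with zero
    parsable records raises :class:`EmptyLibraryError`.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    parsers = {"smiles": _parse_smiles_file, "sdf": _parse_sdf, "csv": _parse_csv}
    if format not in parsers:
        raise ParameterError(f"unknown format {format!r}")
    records, n_bad = parsers[format](path)
    if not records:
        raise EmptyLibraryError(f"{path}: no parsable records")
    lib = CuratedLibrary(list(records), {"input": len(records)}, n_bad)
    return lib


def filter_molecular_weight(
    lib: CuratedLibrary, min_mw: float = 160.0, max_mw: float = 1000.0
) -> CuratedLibrary:
    """Keep records with ``min_mw <= mw <= max_mw`` (inclusive window)."""
    if min_mw > max_mw:
        raise ParameterError(f"min_mw {min_mw} > max_mw {max_mw}")
    kept = [r for r in lib.records if min_mw <= r.mw <= max_mw]
    return lib.with_step("mw_filter", kept)


def deduplicate(lib: CuratedLibrary) -> CuratedLibrary:
    """Collapse records sharing a canonical key to a single record.

    Among duplicates with activity annotations the most potent (lowest
    value) wins; otherwise the first by input order.  Survivor order
    follows the input order of each group's first occurrence.
    """
    best: dict[str, CompoundRecord] = {}
    order: list[str] = []
    for rec in lib.records:
        key = rec.canonical_key
        if key not in best:
            best[key] = rec
            order.append(key)
        else:
            cur = best[key]
            if rec.activity_value is not None and (
                cur.activity_value is None or rec.activity_value < cur.activity_value
            ):
                best[key] = replace(rec)
    return lib.with_step("dedup", [best[k] for k in order])


def filter_activity(lib: CuratedLibrary, threshold: float = 100.0) -> CuratedLibrary:
    """Drop records whose potency is strictly above ``threshold`` uM.

    Records without an activity annotation (the drug class) pass untouched.
    """
    if threshold < 0:
        raise ParameterError(f"negative activity threshold {threshold}")
    kept = [
        r
        for r in lib.records
        if r.activity_value is None or r.activity_value <= threshold
    ]
    return lib.with_step("activity_filter", kept)


def curate(
    lib: CuratedLibrary,
    min_mw: float = 160.0,
    max_mw: float = 1000.0,
    max_activity_um: Optional[float] = 100.0,
) -> CuratedLibrary:
    """Run the full curation chain: MW window, dedup, activity threshold."""
    out = filter_molecular_weight(lib, min_mw, max_mw)
    out = deduplicate(out)
    if max_activity_um is not None:
        out = filter_activity(out, max_activity_um)
    return out


def write_library_csv(lib: CuratedLibrary, path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(
            ["id", "smiles", "canonical_smiles", "mw", "activity_um", "activity_type", "source_class"]
        )
        for r in lib.records:
            writer.writerow(
                [
                    r.id,
                    r.smiles,
                    r.canonical_key,
                    f"{r.mw:.3f}",
                    "" if r.activity_value is None else f"{r.activity_value:g}",
                    r.activity_type.value,
                    r.source_class.value,
                ]
            )


def write_report_json(lib: CuratedLibrary, path: str | Path) -> None:
    payload = dict(lib.report)
    payload["rejected_parse"] = lib.n_rejected_parse
    Path(path).write_text(json.dumps(payload, indent=2) + "\n")
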