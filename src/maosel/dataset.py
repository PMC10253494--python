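"""Compound-table handling for dual-target inhibitor datasets.

A dataset row carries a structure (SMILES) and half-maximal inhibitory
concentrations against two targets, canonically MAO-A (``ic50_a``) and
MAO-B (``ic50_b``).  From those this module derives

* ``pic50_b`` = -log10(IC50 against target B, in molar),
* the selectivity index ``si`` = IC50_A / IC50_B (large values mean
  B-selective), and
* a binary selectivity class at a configurable SI threshold,

together with drug-likeness descriptors (Lipinski counts, molecular
weight, rotatable bonds, TPSA) and Bemis-Murcko frameworks used to
summarise the chemical space.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import pandas as pd
from rdkit import Chem
from rdkit.Chem import Crippen, Descriptors, Lipinski, rdMolDescriptors
from rdkit.Chem.Scaffolds import MurckoScaffold

logger = logging.getLogger(__name__)

SELECTIVE = "selective"
NON_SELECTIVE = "non_selective"
UNKNOWN = "unknown"

#: multiplicative factors taking a declared unit to molar
_UNIT_TO_MOLAR = {"M": 1.0, "mM": 1e-3, "uM": 1e-6, "µM": 1e-6, "nM": 1e-9, "pM": 1e-12}

#: default SI threshold separating selective from non-selective compounds;
#: strictly between the observed non-selective maximum (~49) and the
#: selective minimum (~57) in the reference dataset.
DEFAULT_SI_THRESHOLD = 50.0


@dataclass
class CompoundRecord:
    """One molecule with its two-target potencies and derived quantities."""

    id: str
    smiles: str  # canonical SMILES
    ic50_b: float  # molar, > 0
    ic50_a: float | None = None  # molar, > 0, or None when not measured
    pic50_b: float = field(init=False)
    si: float | None = field(init=False)
    selectivity_class: str = UNKNOWN

    def __post_init__(self) -> None:
        if self.ic50_b <= 0 or not math.isfinite(self.ic50_b):
            raise ValueError(f"compound {self.id!r}: IC50 (target B) must be positive, got {self.ic50_b}")
        if self.ic50_a is not None and (self.ic50_a <= 0 or not math.isfinite(self.ic50_a)):
            raise ValueError(f"compound {self.id!r}: IC50 (target A) must be positive, got {self.ic50_a}")
        self.pic50_b = -math.log10(self.ic50_b)
        self.si = self.ic50_a / self.ic50_b if self.ic50_a is not None else None


@dataclass(frozen=True)
class DruglikeProfile:
    """Lipinski-style descriptor block for one compound."""

    hba: int
    hbd: int
    mw: float  # average molecular weight, Da
    rbn: int
    tpsa: float  # A^2
    xlogp: float | None = None


@dataclass(frozen=True)
class Framework:
    """Bemis-Murcko framework (ring systems + linkers) of a molecule.

    ``framework_smiles`` is canonical so equal frameworks compare equal as
    strings; it is empty for acyclic molecules.  Exocyclic atoms attached
    to the framework by multiple bonds are retained (the common
    "framework" variant) — unique-framework counts depend on this
    convention.
    """

    parent_id: str
    framework_smiles: str


@dataclass
class LoadResult:
    records: list["CompoundRecord"]
    rejects: pd.DataFrame  # columns: row, id, smiles, reason
    duplicates: list[str]  # ids of rows dropped as duplicate canonical SMILES


def _mol_from_smiles(smiles: str) -> Chem.Mol | None:
    if not isinstance(smiles, str) or not smiles.strip():
        return None
    return Chem.MolFromSmiles(smiles)


def load_dataset(
    path: str,
    column_map: Mapping[str, str] | None = None,
    ic50_unit: str = "nM",
) -> LoadResult:
    """Read a compound table (CSV) into validated :class:`CompoundRecord` s.

    Parameters
    ----------
    path:
        CSV file with at least an id, a SMILES and an IC50 column for
        target B; an IC50 column for target A is optional.
    column_map:
        Mapping from the roles ``id``, ``smiles``, ``ic50_a``, ``ic50_b``
        to the actual column names.  Defaults to those literal names.
    ic50_unit:
        Concentration unit of both IC50 columns, declared once per file
        (one of M, mM, uM/µM, nM, pM).

    Rows whose SMILES fail to parse are skipped and reported in
    ``rejects``; a non-positive IC50 is a hard error naming the row.
    Duplicate canonical SMILES keep the first occurrence.
    """
    if ic50_unit not in _UNIT_TO_MOLAR:
        raise ValueError(f"unknown IC50 unit {ic50_unit!r}; expected one of {sorted(_UNIT_TO_MOLAR)}")
    to_molar = _UNIT_TO_MOLAR[ic50_unit]
    cmap = {"id": "id", "smiles": "smiles", "ic50_a": "ic50_a", "ic50_b": "ic50_b"}
    if column_map:
        cmap.update(column_map)

    df = pd.read_csv(path)
    for role in ("smiles", "ic50_b"):
        if cmap[role] not in df.columns:
            raise ValueError(f"required column {cmap[role]!r} (role {role!r}) missing from {path}")
    has_id = cmap["id"] in df.columns
    has_a = cmap["ic50_a"] in df.columns

    records: list[CompoundRecord] = []
    rejects: list[dict] = []
    duplicates: list[str] = []
    seen: set[str] = set()
    for row_idx, row in df.iterrows():
        cid = str(row[cmap["id"]]) if has_id else f"row{row_idx}"
        raw_smiles = row[cmap["smiles"]]
        mol = _mol_from_smiles(raw_smiles)
        if mol is None:
            logger.warning("row %s (%s): unparseable SMILES %r — skipped", row_idx, cid, raw_smiles)
            rejects.append({"row": row_idx, "id": cid, "smiles": raw_smiles, "reason": "unparseable SMILES"})
            continue
        canonical = Chem.MolToSmiles(mol)
        if canonical in seen:
            logger.warning("row %s (%s): duplicate canonical SMILES %s — keeping first occurrence", row_idx, cid, canonical)
            duplicates.append(cid)
            continue
        ic50_b = float(row[cmap["ic50_b"]]) * to_molar
        if not ic50_b > 0:
            raise ValueError(f"row {row_idx} (compound {cid!r}): non-positive IC50 (target B)")
        ic50_a = None
        if has_a and pd.notna(row[cmap["ic50_a"]]):
            ic50_a = float(row[cmap["ic50_a"]]) * to_molar
            if not ic50_a > 0:
                raise ValueError(f"row {row_idx} (compound {cid!r}): non-positive IC50 (target A)")
        seen.add(canonical)
        records.append(CompoundRecord(id=cid, smiles=canonical, ic50_b=ic50_b, ic50_a=ic50_a))
    rejects_df = pd.DataFrame(rejects, columns=["row", "id", "smiles", "reason"])
    return LoadResult(records=records, rejects=rejects_df, duplicates=duplicates)


def load_sdf(
    path: str,
    ic50_b_prop: str = "ic50_b",
    ic50_a_prop: str = "ic50_a",
    id_prop: str | None = None,
    ic50_unit: str = "nM",
) -> LoadResult:
    """Read an SDF (V2000) whose records carry IC50 values as properties.

    Falls back to the molecule title (or a running index) for ids when
    ``id_prop`` is not given.  Same validation/deduplication semantics as
    :func:`load_dataset`.
    """
    if ic50_unit not in _UNIT_TO_MOLAR:
        raise ValueError(f"unknown IC50 unit {ic50_unit!r}; expected one of {sorted(_UNIT_TO_MOLAR)}")
    to_molar = _UNIT_TO_MOLAR[ic50_unit]
    records: list[CompoundRecord] = []
    rejects: list[dict] = []
    duplicates: list[str] = []
    seen: set[str] = set()
    supplier = Chem.SDMolSupplier(str(path))
    for idx, mol in enumerate(supplier):
        if mol is None:
            logger.warning("SDF record %d: unparseable — skipped", idx)
            rejects.append({"row": idx, "id": f"rec{idx}", "smiles": None, "reason": "unparseable SDF record"})
            continue
        if id_prop and mol.HasProp(id_prop):
            cid = mol.GetProp(id_prop)
        else:
            cid = mol.GetProp("_Name") if mol.GetProp("_Name") else f"rec{idx}"
        if not mol.HasProp(ic50_b_prop):
            rejects.append({"row": idx, "id": cid, "smiles": Chem.MolToSmiles(mol), "reason": f"missing {ic50_b_prop}"})
            continue
        canonical = Chem.MolToSmiles(mol)
        if canonical in seen:
            logger.warning("SDF record %d (%s): duplicate canonical SMILES — keeping first", idx, cid)
            duplicates.append(cid)
            continue
        ic50_b = float(mol.GetProp(ic50_b_prop)) * to_molar
        if not ic50_b > 0:
            raise ValueError(f"SDF record {idx} (compound {cid!r}): non-positive IC50 (target B)")
        ic50_a = float(mol.GetProp(ic50_a_prop)) * to_molar if mol.HasProp(ic50_a_prop) else None
        if ic50_a is not None and not ic50_a > 0:
            raise ValueError(f"SDF record {idx} (compound {cid!r}): non-positive IC50 (target A)")
        seen.add(canonical)
        records.append(CompoundRecord(id=cid, smiles=canonical, ic50_b=ic50_b, ic50_a=ic50_a))
    return LoadResult(records=records, rejects=pd.DataFrame(rejects, columns=["row", "id", "smiles", "reason"]), duplicates=duplicates)


def classify_selectivity(
    records: Iterable[CompoundRecord], si_threshold: float = DEFAULT_SI_THRESHOLD
) -> list[CompoundRecord]:
    """Label each record selective (si >= threshold) / non-selective / unknown.

    Deterministic and order-preserving; records lacking an SI value (no
    target-A potency) are labelled ``unknown``.
    """
    if not si_threshold > 0:
        raise ValueError("si_threshold must be positive")
    out = []
    for rec in records:
        if rec.si is None:
            cls = UNKNOWN
        elif rec.si >= si_threshold:
            cls = SELECTIVE
        else:
            cls = NON_SELECTIVE
        rec.selectivity_class = cls
        out.append(rec)
    return out


def druglike_descriptors(record: CompoundRecord | str, include_logp: bool = False) -> DruglikeProfile:
    """Compute the Lipinski descriptor block for one compound.

    Definitions: HBA = Lipinski N+O count; HBD = NH+OH count; MW uses
    average atomic weights; RBN = rotatable (non-ring single, non-terminal)
    bonds; TPSA = Ertl topological polar surface area.  Input must be a
    single neutral fragment (salt-stripped); multi-fragment or net-charged
    input is rejected.
    """
    smiles = record.smiles if isinstance(record, CompoundRecord) else record
    mol = _mol_from_smiles(smiles)
    if mol is None:
        raise ValueError(f"invalid SMILES: {smiles!r}")
    if len(Chem.GetMolFrags(mol)) > 1:
        raise ValueError(f"multi-fragment input (salt-stripped input required): {smiles!r}")
    if Chem.GetFormalCharge(mol) != 0:
        raise ValueError(f"net-charged input (neutralised input required): {smiles!r}")
    return DruglikeProfile(
        hba=Lipinski.NOCount(mol),
        hbd=Lipinski.NHOHCount(mol),
        mw=Descriptors.MolWt(mol),
        rbn=Lipinski.NumRotatableBonds(mol),
        tpsa=rdMolDescriptors.CalcTPSA(mol),
        xlogp=Crippen.MolLogP(mol) if include_logp else None,
    )


def bemis_murcko_framework(record: CompoundRecord | str) -> Framework:
    smiles = record.smiles if isinstance(record, CompoundRecord) else record
    parent_id = record.id if isinstance(record, CompoundRecord) else smiles
    mol = _mol_from_smiles(smiles)
    if mol is None:
        raise ValueError(f"invalid SMILES: {smiles!r}")
    scaffold = MurckoScaffold.GetScaffoldForMol(mol)
    return Framework(parent_id=parent_id, framework_smiles=Chem.MolToSmiles(scaffold))


def dataset_summary(records: Sequence[CompoundRecord]) -> dict:
    """Per-class potency/selectivity ranges and framework diversity.

    Returns a JSON-serialisable dict with n, class counts, per-class pIC50
    and SI ranges, the global pIC50 span (max - min) and the number of
    unique Bemis-Murcko frameworks per class.  Counts are permutation
    invariant and sum to n.
    """
    if not records:
        raise ValueError("dataset_summary requires at least one record")
    by_class: dict[str, list[CompoundRecord]] = {}
    for rec in records:
        by_class.setdefault(rec.selectivity_class, []).append(rec)

    def _rng(vals):
        return [min(vals), max(vals)] if vals else None

    classes = {}
    for cls, recs in sorted(by_class.items()):
        pic50s = [r.pic50_b for r in recs]
        sis = [r.si for r in recs if r.si is not None]
        frameworks = {bemis_murcko_framework(r).framework_smiles for r in recs}
        classes[cls] = {
            "n": len(recs),
            "pic50_range": _rng(pic50s),
            "si_range": _rng(sis),
            "n_unique_frameworks": len(frameworks),
        }
    all_pic50 = [r.pic50_b for r in records]
    return {
        "n": len(records),
        "class_counts": {cls: info["n"] for cls, info in classes.items()},
        "classes": classes,
        "pic50_span": max(all_pic50) - min(all_pic50),
    }


def records_to_frame(records: Sequence[CompoundRecord]) -> pd.DataFrame:
    """Normalised dataset table (id, canonical smiles, potencies, class)."""
    return pd.DataFrame(
        {
            "id": [r.id for r in records],
            "smiles": [r.smiles for r in records],
            "ic50_a": [r.ic50_a for r in records],
            "ic50_b": [r.ic50_b for r in records],
            "pic50_b": [r.pic50_b for r in records],
            "si": [r.si for r in records],
            "selectivity_class": [r.selectivity_class for r in records],
        }
    )


def records_from_frame(df: pd.DataFrame) -> list[CompoundRecord]:
    """Inverse of :func:`records_to_frame` (classes are preserved)."""
    out = []
    for _, row in df.iterrows():
        rec = CompoundRecord(
            id=str(row["id"]),
            smiles=row["smiles"],
            ic50_b=float(row["ic50_b"]),
            ic50_a=float(row["ic50_a"]) if pd.notna(row.get("ic50_a")) else None,
        )
        rec.selectivity_class = row.get("selectivity_class", UNKNOWN)
        out.append(rec)
    return out
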