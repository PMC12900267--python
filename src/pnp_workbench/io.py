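"""Compound and feature-table I/O.

Owns the on-disk formats used by every other module:

* compound collections — SMILES lists (one structure per line, optional
  tab-separated id), SDF (v2000/v3000) and CSV with a SMILES column;
* plate feature tables — CSV with the fixed metadata columns
  ``plate_id, well_id, compound_id, concentration_um, is_control`` followed
  by an arbitrary number of numeric feature columns.

Structures are canonicalized on read: the largest covalent fragment is kept
(salt/counterion stripping) and the toolkit's canonical SMILES with
stereochemistry is stored.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator

import numpy as np
import pandas as pd
from rdkit import Chem
from rdkit import RDLogger

logger = logging.getLogger(__name__)

RDLogger.DisableLog("rdApp.error")

#: Metadata columns of a plate feature table, in canonical order.
METADATA_COLUMNS = ("plate_id", "well_id", "compound_id", "concentration_um", "is_control")


# ---------------------------------------------------------------------------
# compound records
# ---------------------------------------------------------------------------

def canonicalize_smiles(smiles: str) -> str | None:
    """Canonical SMILES of the largest covalent fragment, or None if unparseable.

    Stereochemistry is retained. Applying the function to its own output is a
    no-op (canonicalization is idempotent).
    """
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        return None
    frags = Chem.GetMolFrags(mol, asMols=True, sanitizeFrags=False)
    if len(frags) > 1:
        mol = max(frags, key=lambda m: m.GetNumHeavyAtoms())
    return Chem.MolToSmiles(mol)


@dataclass(frozen=True)
class CompoundRecord:
    """One molecule: unique id, canonical structure, class label, optional name."""

    compound_id: str
    structure: str  # canonical SMILES
    class_label: str = "unlabeled"
    name: str | None = None

    def mol(self) -> Chem.Mol:
        m = Chem.MolFromSmiles(self.structure)
        if m is None:  # pragma: no cover - guarded at construction time
            raise ValueError(f"invalid stored structure for {self.compound_id!r}")
        return m


@dataclass
class CompoundSet:
    """Ordered collection of compound records with provenance.

    Duplicate canonical structures are allowed across class labels (a molecule
    may legitimately be both a natural product and a drug) but are dropped,
    with a warning, within one label. Duplicate ids are an error.
    """

    records: list[CompoundRecord]
    provenance: str = ""
    n_skipped: int = 0

    def __post_init__(self) -> None:
        ids = [r.compound_id for r in self.records]
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        if dupes:
            raise ValueError(f"duplicate compound ids: {dupes}")
        seen: set[tuple[str, str]] = set()
        kept = []
        for r in self.records:
            key = (r.class_label, r.structure)
            if key in seen:
                warnings.warn(
                    f"dropping duplicate structure within label {r.class_label!r}: "
                    f"{r.compound_id}",
                    stacklevel=2,
                )
                continue
            seen.add(key)
            kept.append(r)
        self.records = kept

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[CompoundRecord]:
        return iter(self.records)

    def __getitem__(self, i: int) -> CompoundRecord:
        return self.records[i]

    @property
    def labels(self) -> list[str]:
        out: list[str] = []
        for r in self.records:
            if r.class_label not in out:
                out.append(r.class_label)
        return out

    def subset(self, label: str) -> "CompoundSet":
        return CompoundSet(
            [r for r in self.records if r.class_label == label],
            provenance=f"{self.provenance}[{label}]",
        )


def read_compounds(
    path: str | Path,
    format: str = "smiles_list",
    *,
    smiles_column: str = "smiles",
    id_column: str = "compound_id",
    label_column: str | None = "class_label",
    default_label: str = "unlabeled",
) -> CompoundSet:
    """Read a compound collection, canonicalizing structures.

    Unparseable structures are skipped and counted in ``CompoundSet.n_skipped``.
    A file yielding zero parseable structures is an error.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format not in ("smiles_list", "sdf", "csv"):
        raise ValueError(f"unknown format {format!r}; expected smiles_list, sdf or csv")

    raw: list[tuple[str, str, str, str | None]] = []  # (id, smiles, label, name)
    if format == "smiles_list":
        for i, line in enumerate(path.read_text().splitlines()):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            smi = parts[0].strip()
            cid = parts[1].strip() if len(parts) > 1 else f"cpd_{i + 1:04d}"
            raw.append((cid, smi, default_label, None))
    elif format == "sdf":
        supplier = Chem.SDMolSupplier(str(path), sanitize=True)
        for i, mol in enumerate(supplier):
            if mol is None:
                raw.append((f"cpd_{i + 1:04d}", "", default_label, None))
                continue
            cid = mol.GetProp("_Name") if mol.HasProp("_Name") and mol.GetProp("_Name") else f"cpd_{i + 1:04d}"
            label = mol.GetProp("class_label") if mol.HasProp("class_label") else default_label
            raw.append((cid, Chem.MolToSmiles(mol), label, None))
    else:  # csv
        df = pd.read_csv(path, dtype=str)
        if smiles_column not in df.columns:
            raise ValueError(f"csv is missing the structure column {smiles_column!r}")
        for i, row in df.iterrows():
            cid = str(row[id_column]) if id_column in df.columns and pd.notna(row.get(id_column)) else f"cpd_{i + 1:04d}"
            label = (
                str(row[label_column])
                if label_column and label_column in df.columns and pd.notna(row.get(label_column))
                else default_label
            )
            name = str(row["name"]) if "name" in df.columns and pd.notna(row.get("name")) else None
            raw.append((cid, str(row[smiles_column]), label, name))

    records: list[CompoundRecord] = []
    n_skipped = 0
    for cid, smi, label, name in raw:
        canon = canonicalize_smiles(smi) if smi else None
        if canon is None:
            n_skipped += 1
            logger.warning("skipping unparseable structure %r (id %s)", smi, cid)
            continue
        records.append(CompoundRecord(cid, canon, label, name))
    if not records:
        raise ValueError(f"zero parseable structures in {path}")
    return CompoundSet(records, provenance=str(path), n_skipped=n_skipped)


def write_compounds(compounds: CompoundSet, path: str | Path) -> None:
    """Write a compound set as CSV (compound_id, smiles, class_label, name)."""
    df = pd.DataFrame(
        {
            "compound_id": [r.compound_id for r in compounds],
            "smiles": [r.structure for r in compounds],
            "class_label": [r.class_label for r in compounds],
            "name": [r.name for r in compounds],
        }
    )
    df.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# feature tables
# ---------------------------------------------------------------------------

@dataclass
class FeatureTable:
    """Plate-level morphological feature table: wells x (metadata + features).

    The underlying frame carries the five metadata columns of
    :data:`METADATA_COLUMNS` followed by numeric feature columns. Row order is
    preserved from the source file; each row is either a treatment well
    (``compound_id`` set, positive concentration) or a control well
    (``is_control`` true).
    """

    data: pd.DataFrame
    feature_columns: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        missing = [c for c in METADATA_COLUMNS if c not in self.data.columns]
        if missing:
            raise ValueError(f"feature table is missing metadata columns {missing}")
        if not self.feature_columns:
            self.feature_columns = [c for c in self.data.columns if c not in METADATA_COLUMNS]
        if not self.feature_columns:
            raise ValueError("feature table has no feature columns")
        for col in self.feature_columns:
            vals = self.data[col]
            if not pd.api.types.is_numeric_dtype(vals):
                for idx, v in vals.items():
                    try:
                        float(v)
                    except (TypeError, ValueError):
                        raise ValueError(
                            f"non-numeric feature value at row {idx!r}, column {col!r}: {v!r}"
                        ) from None
            bad = vals.index[vals.isna()]
            if len(bad):
                raise ValueError(f"missing feature value at row {bad[0]!r}, column {col!r}")
        ctrl = self.data["is_control"].astype(bool)
        no_id = self.data["compound_id"].isna() | (self.data["compound_id"].astype(str) == "")
        orphans = self.data.index[~ctrl & no_id]
        if len(orphans):
            raise ValueError(f"row {orphans[0]!r} has neither a compound_id nor a control flag")
        conc = pd.to_numeric(self.data.loc[~ctrl, "concentration_um"], errors="coerce")
        if (conc <= 0).any() or conc.isna().any():
            raise ValueError("treatment wells must have positive concentration_um")

    @property
    def n_features(self) -> int:
        return len(self.feature_columns)

    @property
    def features(self) -> pd.DataFrame:
        return self.data[self.feature_columns]

    @property
    def control_mask(self) -> np.ndarray:
        return self.data["is_control"].astype(bool).to_numpy()


def read_feature_table(path: str | Path) -> FeatureTable:
    """Read a plate CSV into a validated :class:`FeatureTable`."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, float_precision="round_trip")
    if "is_control" in df.columns:
        df["is_control"] = df["is_control"].astype(bool)
    if "compound_id" in df.columns:
        df["compound_id"] = df["compound_id"].fillna("").astype(str)
    return FeatureTable(df)


def write_feature_table(table: FeatureTable, path: str | Path) -> None:
    """Write a feature table as CSV, re-readable with full value precision."""
    if len(table.data) == 0:
        raise ValueError("refusing to write an empty feature table")
    out = table.data[list(METADATA_COLUMNS) + table.feature_columns]
    out.to_csv(path, index=False)
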