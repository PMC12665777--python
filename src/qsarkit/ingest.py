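"""Compound-table and descriptor-matrix I/O.

Activity data arrive as delimited text with an id column, an optional SMILES
column and an IC50 column in nanomolar units.  IC50 values are converted to
pIC50 = -log10(IC50 in mol/L), the scale on which all regression modelling is
done.  Descriptor matrices are plain CSV: first column the compound id, every
remaining column a named numeric descriptor.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "CompoundRecord",
    "ic50_to_pic50",
    "read_compound_table",
    "deduplicate",
    "read_descriptor_matrix",
    "write_descriptor_matrix",
]

#: multiplier converting the supplied IC50 unit to nanomolar
_UNIT_TO_NM = {"nM": 1.0, "uM": 1e3, "mM": 1e6, "M": 1e9, "pM": 1e-3}


@dataclass(frozen=True)
class CompoundRecord:
    """A single assayed compound.

    Attributes
    ----------
    id : str
        Unique identifier within a dataset.
    smiles : str
        Structure string, carried verbatim; may be empty when only a
        descriptor matrix is supplied.
    ic50_nM : float
        Half-maximal inhibitory concentration in nanomolar; strictly positive.
    pic50 : float
        ``-log10(ic50_nM * 1e-9)``, i.e. ``9 - log10(ic50_nM)``.
    """

    id: str
    smiles: str
    ic50_nM: float
    pic50: float = field(default=math.nan)

    def __post_init__(self) -> None:
        if not (self.ic50_nM > 0 and math.isfinite(self.ic50_nM)):
            raise ValueError(
                f"compound {self.id!r}: IC50 must be positive and finite, "
                f"got {self.ic50_nM!r}"
            )
        if math.isnan(self.pic50):
            object.__setattr__(self, "pic50", ic50_to_pic50(self.ic50_nM))


def ic50_to_pic50(ic50_nM: float) -> float:
    """Convert an IC50 in nanomolar to pIC50 (``-log10`` of the molar value).

    Raises
    ------
    ValueError
        If ``ic50_nM`` is non-positive or non-finite.
    """
    ic50_nM = float(ic50_nM)
    if not (ic50_nM > 0 and math.isfinite(ic50_nM)):
        raise ValueError(f"IC50 must be positive and finite, got {ic50_nM!r}")
    return -math.log10(ic50_nM * 1e-9)


def read_compound_table(
    path: str | Path,
    column_map: Mapping[str, str] | None = None,
) -> list[CompoundRecord]:
    """Read a compound activity table from CSV.

    ``column_map`` remaps the logical names ``id``, ``smiles`` and ``ic50``
    onto the file's actual headers and may carry an ``ic50_unit`` entry
    (default ``"nM"``).  Rows whose IC50 cell cannot be parsed as a positive
    number are dropped with a log message; a duplicated id is an error.
    """
    cmap = dict(column_map or {})
    id_col = cmap.get("id", "id")
    smiles_col = cmap.get("smiles", "smiles")
    ic50_col = cmap.get("ic50", "ic50_nM")
    unit = cmap.get("ic50_unit", "nM")
    if unit not in _UNIT_TO_NM:
        raise ValueError(f"unknown IC50 unit {unit!r}; expected one of {sorted(_UNIT_TO_NM)}")

    df = pd.read_csv(path, dtype=str)
    for col in (id_col, ic50_col):
        if col not in df.columns:
            raise ValueError(f"{path}: missing mandatory column {col!r}")

    ids = df[id_col].astype(str)
    dup = ids[ids.duplicated()].unique().tolist()
    if dup:
        raise ValueError(f"{path}: duplicated compound id(s): {dup}")

    records: list[CompoundRecord] = []
    n_dropped = 0
    for _, row in df.iterrows():
        raw = row[ic50_col]
        try:
            ic50 = float(raw) * _UNIT_TO_NM[unit]
            if not (ic50 > 0 and math.isfinite(ic50)):
                raise ValueError
        except (TypeError, ValueError):
            n_dropped += 1
            logger.warning("dropping compound %r: unparseable IC50 %r", row[id_col], raw)
            continue
        smiles = row[smiles_col] if smiles_col in df.columns else ""
        if pd.isna(smiles):
            smiles = ""
        records.append(CompoundRecord(id=str(row[id_col]), smiles=str(smiles), ic50_nM=ic50))
    if n_dropped:
        logger.info("read_compound_table: dropped %d row(s) with invalid IC50", n_dropped)
    return records


def _structure_key(record: CompoundRecord) -> str:
    """Canonical duplicate key: RDKit canonical SMILES when available and
    parseable, else the stripped structure string, else the id."""
    smi = record.smiles.strip()
    if not smi:
        return f"id:{record.id}"
    try:  # optional chem dependency
        from rdkit import Chem  # type: ignore
        from rdkit import RDLogger  # type: ignore

        RDLogger.DisableLog("rdApp.*")
        mol = Chem.MolFromSmiles(smi)
        if mol is not None:
            return "smi:" + Chem.MolToSmiles(mol)
    except ImportError:
        pass
    return "smi:" + smi


def deduplicate(records: Sequence[CompoundRecord]) -> list[CompoundRecord]:
    """Collapse duplicate structures to one record carrying the median pIC50.

    The key is the canonical form of the structure string when a structure is
    present, else the id.  The surviving record keeps the first duplicate's id
    and structure; its IC50 is back-computed from the median pIC50 so the
    record stays internally consistent.  Idempotent.
    """
    groups: dict[str, list[CompoundRecord]] = {}
    order: list[str] = []
    for rec in records:
        key = _structure_key(rec)
        if key not in groups:
            groups[key] = []
            order.append(key)
        groups[key].append(rec)

    out: list[CompoundRecord] = []
    for key in order:
        group = groups[key]
        if len(group) == 1:
            out.append(group[0])
            continue
        med = float(np.median([r.pic50 for r in group]))
        first = group[0]
        out.append(
            replace(first, ic50_nM=10.0 ** (9.0 - med), pic50=med)
        )
        logger.info(
            "deduplicate: %d records collapsed to %r (median pIC50 %.4f)",
            len(group), first.id, med,
        )
    return out


def read_descriptor_matrix(path: str | Path) -> pd.DataFrame:
    """Read a descriptor matrix (CSV, first column = row id).

    Columns containing any missing value are dropped with a log message.
    A non-numeric cell in a retained column is a parse error identifying the
    row and column; an empty file is an error.
    """
    df = pd.read_csv(path, index_col=0, float_precision="round_trip")
    if df.shape[0] == 0 or df.shape[1] == 0:
        raise ValueError(f"{path}: empty descriptor matrix")
    df.index = df.index.astype(str)

    with_missing = [c for c in df.columns if df[c].isna().any()]
    if with_missing:
        logger.info("read_descriptor_matrix: dropping %d column(s) with missing values: %s",
                    len(with_missing), with_missing)
        df = df.drop(columns=with_missing)
    if df.shape[1] == 0:
        raise ValueError(f"{path}: no descriptor columns survive missing-value filtering")

    for col in df.columns:
        coerced = pd.to_numeric(df[col], errors="coerce")
        if coerced.isna().any():
            bad = df.index[coerced.isna()][0]
            raise ValueError(f"{path}: non-numeric value in column {col!r}, row {bad!r}")
        df[col] = coerced.astype(float)
    return df


def write_descriptor_matrix(X: pd.DataFrame, path: str | Path) -> None:
    """Write a descriptor matrix in the same dialect ``read_descriptor_matrix``
    expects; round-trips finite values bit-exactly (17 significant digits)."""
    X.to_csv(path, index=True, index_label=X.index.name or "id",
             float_format="%.17g")
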