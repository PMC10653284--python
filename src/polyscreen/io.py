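"""Dataset and result I/O.

Training CSV schema (version 1): columns ``smiles_1..smiles_k``,
``ratio_1..ratio_k`` (optional), ``chemistry``, ``polymer_class``, then the
8 property columns ``tg_c, tm_c, density_g_cm3, modulus, perm_o2, perm_n2,
perm_co2, perm_h2o``.  Blank property cells mean "not observed" (mask bit
0).  Monomer lists are CSV (``smiles`` plus optional ``name`` and
``ratio``) or plain SMILES files, one per line.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .builder import BuilderError, PolymerSpec, PolymerStructure, polymerize
from .model import PROPERTY_NAMES, PropertyRecord, TrainingRecord
from .monomers import MonomerError, classify_monomer

log = logging.getLogger(__name__)

SCHEMA_VERSION = 1


class DatasetError(ValueError):
    pass


@dataclass(frozen=True)
class RowError:
    row: int
    message: str


def _row_spec(row: pd.Series, dp: int, seed: int) -> PolymerSpec:
    smiles_cols = sorted(
        (c for c in row.index if c.startswith("smiles_")),
        key=lambda c: int(c.split("_")[1]),
    )
    monomers = []
    ratios = []
    for c in smiles_cols:
        if pd.isna(row[c]) or not str(row[c]).strip():
            continue
        monomers.append(classify_monomer(str(row[c]).strip()))
        rc = c.replace("smiles_", "ratio_")
        ratios.append(float(row[rc]) if rc in row.index and not pd.isna(row[rc]) else np.nan)
    if not monomers:
        raise DatasetError("row has no monomer SMILES")
    molar_ratios = None
    if not any(np.isnan(r) for r in ratios):
        total = sum(ratios)
        molar_ratios = tuple(r / total for r in ratios)
    return PolymerSpec(
        monomers=tuple(monomers),
        chemistry=str(row["chemistry"]),
        degree_of_polymerization=dp,
        molar_ratios=molar_ratios,
        rng_seed=seed,
    )


def read_dataset(
    path: str | Path,
    dp_train: int = 12,
    seed: int = 0,
    max_failure_rate: float = 0.05,
) -> tuple[list[TrainingRecord], list[RowError]]:
    """Read a labeled training table and build one chain per row.

    Malformed rows are reported with their (1-based data) row number; the
    run aborts if more than ``max_failure_rate`` of rows fail.
    """
    df = pd.read_csv(path)
    required = {"chemistry", "polymer_class"}
    if missing := required - set(df.columns):
        raise DatasetError(f"dataset is missing columns: {sorted(missing)}")

    records: list[TrainingRecord] = []
    errors: list[RowError] = []
    for i, row in df.iterrows():
        try:
            spec = _row_spec(row, dp_train, seed=seed + int(i))
            structure = polymerize(spec)
            prop = PropertyRecord.from_dict(
                {k: row[k] for k in PROPERTY_NAMES if k in row.index and not pd.isna(row[k])}
            )
            if not prop.mask.any():
                raise DatasetError("row has no observed property")
            records.append(
                TrainingRecord(
                    structure=structure,
                    record=prop,
                    polymer_class=str(row["polymer_class"]),
                )
            )
        except (DatasetError, MonomerError, BuilderError, ValueError) as e:
            errors.append(RowError(row=int(i) + 1, message=str(e)))
            log.warning("row %d: %s", int(i) + 1, e)

    if len(df) and len(errors) / len(df) > max_failure_rate:
        raise DatasetError(
            f"{len(errors)}/{len(df)} rows failed to parse; first: "
            f"row {errors[0].row}: {errors[0].message}"
        )
    return records, errors


def write_dataset(path: str | Path, records: list[TrainingRecord], specs=None) -> None:
    """Write training records with their built chain SMILES as ``smiles_1``.

    Chains cannot be decomposed back into monomers; for a table that
    :func:`read_dataset` can rebuild, use :func:`write_fixture_csv` with the
    generating specs.
    """
    rows = []
    for rec in records:
        row = {
            "smiles_1": rec.structure.smiles,
            "chemistry": rec.structure.chemistry,
            "polymer_class": rec.polymer_class,
        }
        for j, name in enumerate(PROPERTY_NAMES):
            row[name] = rec.record.values[j] if rec.record.mask[j] else np.nan
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)


def write_fixture_csv(path: str | Path, specs, records: list[TrainingRecord]) -> None:
    """Write a fixture dataset as (monomer SMILES, labels) rows, the format
    :func:`read_dataset` consumes."""
    rows = []
    for spec, rec in zip(specs, records):
        row: dict = {}
        for j, m in enumerate(spec.monomers, start=1):
            row[f"smiles_{j}"] = m.smiles
        row["chemistry"] = spec.chemistry
        row["polymer_class"] = rec.polymer_class
        for j, name in enumerate(PROPERTY_NAMES):
            row[name] = rec.record.values[j] if rec.record.mask[j] else np.nan
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)


def read_monomer_list(path: str | Path) -> list[str]:
    """Monomer SMILES from CSV (``smiles`` column) or a plain list file."""
    path = Path(path)
    text = path.read_text().strip()
    if not text:
        return []
    first = text.splitlines()[0]
    if "," in first or first.strip().lower() == "smiles":
        df = pd.read_csv(path)
        if "smiles" not in df.columns:
            raise DatasetError("monomer CSV needs a 'smiles' column")
        return [str(s).strip() for s in df["smiles"].dropna()]
    return [line.strip() for line in text.splitlines() if line.strip()]


def write_structures(path: str | Path, spec_id: str, structures: list[PolymerStructure]) -> None:
    """Polymer structures as CSV: spec id, replicate id, chain SMILES,
    residue-sequence encoding (monomer index:orientation, ';'-joined)."""
    rows = [
        {
            "spec_id": spec_id,
            "replicate": k,
            "smiles": s.smiles,
            "residues": ";".join(f"{i}:{int(f)}" for i, f in s.residue_sequence),
        }
        for k, s in enumerate(structures)
    ]
    pd.DataFrame(rows).to_csv(path, index=False)


def write_predictions(path: str | Path, results: list[dict]) -> None:
    pd.DataFrame(results).to_csv(path, index=False)
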