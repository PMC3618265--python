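"""Readers and writers for the pipeline's file formats.

Inputs: multi-record FASTA (protein targets), SMILES lists (.smi lines
``SMILES id`` or CSV with ``id,smiles`` columns) and Ki interaction
tables (CSV/TSV with ``drug_id``, ``target_id`` and either ``ki_nM`` or
``ki`` + ``unit`` columns).  All Ki values are canonicalized to nM;
unit conversion is explicit, never guessed.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO

from dtiscreen.fingerprints import DrugRecord, SmilesParseError, parse_molecule

logger = logging.getLogger(__name__)

_UNIT_TO_NM = {"nm": 1.0, "um": 1e3, "µm": 1e3, "mm": 1e6, "m": 1e9, "pm": 1e-3}


def read_fasta(path: str | Path) -> dict[str, str]:
    """Read a FASTA file into an ordered {id: sequence} mapping.

    Ids are the first whitespace token of each header; wrapped sequence
    lines are concatenated; duplicate ids are rejected.
    """
    path = Path(path)
    sequences: dict[str, str] = {}
    for record in SeqIO.parse(str(path), "fasta"):
        if record.id in sequences:
            raise ValueError(f"duplicate FASTA id {record.id!r} in {path}")
        sequences[record.id] = str(record.seq).upper()
    if not sequences:
        logger.warning("no FASTA records found in %s", path)
    return sequences


def read_smiles(path: str | Path, strict: bool = False) -> tuple[dict[str, DrugRecord], list[dict]]:
    """Read drugs from a .smi or CSV file, auto-detected by content.

    Returns ``(records, errors)`` where ``errors`` collects line-level
    parse failures; in strict mode any invalid SMILES raises instead.
    """
    path = Path(path)
    first = ""
    with open(path) as fh:
        for line in fh:
            if line.strip():
                first = line
                break
    entries: list[tuple[int, str, str]] = []  # (lineno, id, smiles)
    if "," in first and "smiles" in first.lower():
        df = pd.read_csv(path)
        cols = {c.lower(): c for c in df.columns}
        if "id" not in cols or "smiles" not in cols:
            raise ValueError(f"{path}: CSV needs 'id' and 'smiles' columns")
        for i, row in df.iterrows():
            entries.append((i + 2, str(row[cols["id"]]), str(row[cols["smiles"]])))
    else:
        with open(path) as fh:
            for lineno, line in enumerate(fh, start=1):
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                parts = line.split()
                smiles = parts[0]
                drug_id = parts[1] if len(parts) > 1 else f"mol{lineno}"
                entries.append((lineno, drug_id, smiles))
    records: dict[str, DrugRecord] = {}
    errors: list[dict] = []
    for lineno, drug_id, smiles in entries:
        try:
            records[drug_id] = parse_molecule(smiles, id=drug_id)
        except SmilesParseError as exc:
            if strict:
                raise SmilesParseError(f"{path}:{lineno}: {exc}") from exc
            errors.append({"line": lineno, "id": drug_id, "smiles": smiles, "error": str(exc)})
    if strict is False and not records and entries:
        raise SmilesParseError(f"{path}: no valid SMILES records")
    return records, errors


def read_interactions(path: str | Path) -> pd.DataFrame:
    """Read a Ki table, canonicalizing Ki to the ``ki_nM`` column.

    Accepts CSV or TSV (sniffed by the header line).  Either a ``ki_nM``
    column or ``ki`` plus ``unit`` (nM/uM/mM/M/pM per row) is required;
    non-positive Ki values are rejected with their row numbers.
    """
    path = Path(path)
    with open(path) as fh:
        header = fh.readline()
    sep = "\t" if "\t" in header else ","
    df = pd.read_csv(path, sep=sep)
    required = {"drug_id", "target_id"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing required columns {sorted(missing)}")
    if "ki_nM" not in df.columns:
        if "ki" not in df.columns or "unit" not in df.columns:
            raise ValueError(f"{path}: need a 'ki_nM' column or 'ki' + 'unit' columns")
        units = df["unit"].astype(str).str.strip().str.lower()
        unknown = sorted(set(units) - set(_UNIT_TO_NM))
        if unknown:
            raise ValueError(f"{path}: unknown Ki units {unknown}")
        df["ki_nM"] = df["ki"].astype(float) * units.map(_UNIT_TO_NM)
    bad = df.index[~(df["ki_nM"] > 0)].tolist()
    if bad:
        raise ValueError(f"{path}: non-positive Ki at rows {[i + 2 for i in bad]}")
    return df


def write_protein_features(sequences: dict[str, str], path: str | Path) -> pd.DataFrame:
    """Featurize sequences and write the 167-column descriptor table."""
    from dtiscreen.protein import protein_feature_names, protein_features

    rows = {sid: protein_features(seq).values for sid, seq in sequences.items()}
    df = pd.DataFrame.from_dict(rows, orient="index", columns=protein_feature_names())
    df.index.name = "target_id"
    df.to_csv(path, float_format="%.10g")
    return df


def write_fingerprints(records: dict[str, DrugRecord], path: str | Path, **fp_kwargs) -> pd.DataFrame:
    """Fingerprint drugs and write the bit table (one 0/1 column per bit)."""
    from dtiscreen.fingerprints import path_fingerprint

    rows = {did: path_fingerprint(rec, **fp_kwargs) for did, rec in records.items()}
    nbits = len(next(iter(rows.values()))) if rows else 1024
    df = pd.DataFrame.from_dict(rows, orient="index", columns=[f"fp.{i}" for i in range(nbits)])
    df.index.name = "drug_id"
    df.to_csv(path)
    return df


def read_feature_table(path: str | Path) -> tuple[np.ndarray, list[str], list[str]]:
    """Read a feature CSV back into (matrix, row ids, column names)."""
    df = pd.read_csv(path, index_col=0)
    return df.to_numpy(dtype=float), list(df.index.astype(str)), list(df.columns)
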