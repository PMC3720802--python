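"""Readers and writers for scale tables, property tables, peptide datasets
and fitted models.

All tabular formats are plain CSV/TSV (delimiter inferred from the file
extension); model files are JSON with named axes.  Writes are atomic
(temporary file + rename) so a crashed run never leaves a half-written
output.
"""

from __future__ import annotations

import json
import os
import tempfile
from pathlib import Path

import numpy as np
import pandas as pd

from .encoding import Peptide, parse_sequence
from .lda import LDAModel
from .pls import PLSModel
from .scales import FactorModel, PropertyTable, ScaleTable

__all__ = [
    "read_scales",
    "write_scales",
    "read_property_table",
    "write_property_table",
    "read_peptide_dataset",
    "write_peptide_dataset",
    "save_model",
    "load_model",
    "atomic_write_text",
]


def _sep_for(path) -> str:
    return "\t" if str(path).endswith((".tsv", ".tab")) else ","


def atomic_write_text(path, text: str) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    fd, tmp = tempfile.mkstemp(dir=path.parent, prefix=f".{path.name}.")
    try:
        with os.fdopen(fd, "w") as fh:
            fh.write(text)
        os.replace(tmp, path)
    except BaseException:
        if os.path.exists(tmp):
            os.unlink(tmp)
        raise


def _read_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep=_sep_for(path), dtype={0: str})
    if df.shape[1] < 2:
        raise ValueError(f"{path}: expected an id column plus data columns")
    df = df.set_index(df.columns[0])
    df.index = df.index.map(str)
    return df


def _check_numeric(df: pd.DataFrame, path) -> pd.DataFrame:
    try:
        return df.astype(float)
    except (TypeError, ValueError):
        for col in df.columns:
            bad = pd.to_numeric(df[col], errors="coerce").isna() & df[col].notna()
            if bad.any():
                row = df.index[bad][0]
                raise ValueError(
                    f"{path}: non-numeric cell at row {row!r}, column {col!r}"
                ) from None
        raise


def read_scales(path) -> ScaleTable:
    """Read a scale table CSV/TSV: id column followed by m factor columns."""
    df = _read_table(path)
    if df.index.duplicated().any():
        dup = df.index[df.index.duplicated()][0]
        raise ValueError(f"{path}: duplicate residue id {dup!r}")
    return ScaleTable(_check_numeric(df, path))


def write_scales(scales: ScaleTable, path) -> None:
    df = scales.data.copy()
    df.index.name = "id"
    atomic_write_text(
        path, df.to_csv(sep=_sep_for(path), float_format="%.17g")
    )


def read_property_table(path) -> PropertyTable:
    df = _read_table(path)
    return PropertyTable(_check_numeric(df, path))


def write_property_table(table: PropertyTable, path) -> None:
    df = table.data.copy()
    df.index.name = "id"
    atomic_write_text(
        path, df.to_csv(sep=_sep_for(path), float_format="%.17g")
    )


def read_peptide_dataset(path) -> list[Peptide]:
    """Read a peptide dataset CSV/TSV with columns id, sequence and either
    a numeric ``activity`` or a categorical ``class``."""
    df = pd.read_csv(path, sep=_sep_for(path), dtype=str)
    cols = {c.lower(): c for c in df.columns}
    if "id" not in cols or "sequence" not in cols:
        raise ValueError(f"{path}: need columns id, sequence, activity|class")
    if df.empty:
        raise ValueError(f"{path}: dataset is empty")
    if "activity" in cols:
        target, numeric = cols["activity"], True
    elif "class" in cols:
        target, numeric = cols["class"], False
    else:
        raise ValueError(f"{path}: need an activity or class column")

    peptides = []
    for _, row in df.iterrows():
        sid = str(row[cols["id"]])
        try:
            pep = parse_sequence(str(row[cols["sequence"]]))
        except ValueError as exc:
            raise ValueError(f"{path}: sample {sid!r}: {exc}") from None
        raw = row[target]
        if numeric:
            try:
                pep.activity = float(raw)
            except (TypeError, ValueError):
                raise ValueError(
                    f"{path}: sample {sid!r}: non-numeric activity {raw!r}"
                ) from None
        else:
            pep.activity = str(raw)
        pep.sample_id = sid
        peptides.append(pep)
    return peptides


def write_peptide_dataset(peptides: list[Peptide], path,
                          target: str = "activity") -> None:
    rows = [
        {"id": p.sample_id, "sequence": p.sequence, target: p.activity}
        for p in peptides
    ]
    atomic_write_text(
        path, pd.DataFrame(rows).to_csv(index=False, sep=_sep_for(path))
    )


_MODEL_KINDS = {"pls": PLSModel, "lda": LDAModel, "factor": FactorModel}


def save_model(model, path) -> None:
    d = model.to_dict()
    if isinstance(model, FactorModel):
        d.setdefault("kind", "factor")
    atomic_write_text(path, json.dumps(d, indent=1))


def load_model(path):
    with open(path) as fh:
        d = json.load(fh)
    kind = d.get("kind")
    if kind not in _MODEL_KINDS:
        raise ValueError(f"{path}: unknown model kind {kind!r}")
    return _MODEL_KINDS[kind].from_dict(d)
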