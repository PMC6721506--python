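"""Readers and writers for the pipeline's plain-text formats.

All tabular data travel as tab-separated UTF-8 text with ``NA`` for missing
values.  An expression matrix has genes (or probes) as rows, samples as
columns, and the row-identifier column as the first column.  The clinical
table uses a fixed column vocabulary so downstream stages can rely on it.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import pandas as pd

#: Required columns of a clinical table, in canonical order.
CLINICAL_COLUMNS = [
    "sample_id", "dataset_id", "platform", "age_years", "grade",
    "pT", "pN", "histotype",
    "dfs_months", "dfs_event", "os_months", "os_event",
]

_NA = "NA"


def write_matrix_tsv(matrix: pd.DataFrame, path: str | Path, index_name: str = "gene_id") -> None:
    """Write a gene × sample matrix as TSV (first column = row identifier)."""
    out = matrix.copy()
    out.index.name = index_name
    out.to_csv(path, sep="\t", na_rep=_NA)


def read_matrix_tsv(path: str | Path) -> pd.DataFrame:
    """Read a gene × sample TSV matrix; returns float values, gene index."""
    df = pd.read_csv(path, sep="\t", index_col=0, na_values=[_NA], keep_default_na=False)
    df.index.name = None
    return df.astype(float)


def write_clinical_tsv(clinical: pd.DataFrame, path: str | Path) -> None:
    missing = [c for c in CLINICAL_COLUMNS if c not in clinical.columns]
    if missing:
        raise ValueError(f"clinical table lacks required columns: {missing}")
    extra = [c for c in clinical.columns if c not in CLINICAL_COLUMNS]
    clinical[CLINICAL_COLUMNS + extra].to_csv(path, sep="\t", index=False, na_rep=_NA)


def read_clinical_tsv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", na_values=[_NA], keep_default_na=False)
    missing = [c for c in CLINICAL_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"clinical table lacks required columns: {missing}")
    return df


def write_table_tsv(table: pd.DataFrame, path: str | Path, index: bool = False) -> None:
    table.to_csv(path, sep="\t", index=index, na_rep=_NA)


def read_table_tsv(path: str | Path, index_col=None) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=index_col, na_values=[_NA], keep_default_na=False)


def read_gmt(path: str | Path) -> dict[str, list[str]]:
    """Read gene sets from a GMT file: name <tab> description <tab> genes...

    Returns a mapping name -> member gene list (order preserved, duplicates
    dropped).  Blank lines are skipped; malformed lines (< 3 fields) raise.
    """
    sets: dict[str, list[str]] = {}
    for lineno, line in enumerate(Path(path).read_text(encoding="utf-8").splitlines(), 1):
        if not line.strip():
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) < 3:
            raise ValueError(f"{path}:{lineno}: GMT line needs name, description and >=1 gene")
        name, genes = fields[0], fields[2:]
        seen: list[str] = []
        for g in genes:
            if g and g not in seen:
                seen.append(g)
        sets[name] = seen
    return sets


def sha256_file(path: str | Path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


def write_json(obj, path: str | Path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n", encoding="utf-8")


def read_json(path: str | Path):
    return json.loads(Path(path).read_text(encoding="utf-8"))
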