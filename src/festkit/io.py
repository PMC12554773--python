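"""Reading and writing clonotype tables and study manifests.

Two tab-separated dialects are supported:

* ``airr`` -- AIRR Rearrangement columns ``junction_aa``,
  ``duplicate_count``, ``productive`` (plus optional ``v_call``/``j_call``).
* ``immunoseq`` -- Adaptive immunoSEQ export columns ``aminoAcid``,
  ``count (templates/estTemplates)`` (or ``count``/``templates``) and
  ``sequenceStatus`` (plus optional ``vGeneName``/``jGeneName``).

Frequencies are never stored at parse time; they are computed downstream
over each well's productive templates.
"""

from __future__ import annotations

import os
from pathlib import Path

import pandas as pd

from .model import (
    ClonotypeRecord,
    Condition,
    EmptyInputError,
    FormatError,
    ManifestEntry,
    StudyManifest,
    ValidationError,
    WellSample,
    parse_condition,
)

_AIRR_TRUE = {"t", "true", "1", "yes"}
_AIRR_FALSE = {"f", "false", "0", "no"}

_IMMUNOSEQ_COUNT_COLUMNS = (
    "count (templates/estTemplates)",
    "count",
    "templates",
)


def _read_tsv(path: str | os.PathLike) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"clonotype table not found: {path}")
    df = pd.read_csv(path, sep="\t", dtype=str, comment="#")
    if df.empty:
        raise EmptyInputError(f"clonotype table {path} contains no data rows")
    return df


def _parse_count(value: str, row: int, column: str) -> int:
    try:
        as_float = float(value)
    except (TypeError, ValueError):
        raise ValidationError(
            f"row {row}: column {column!r} value {value!r} is not a number"
        ) from None
    if as_float != int(as_float):
        raise ValidationError(
            f"row {row}: column {column!r} value {value!r} is not an integer count"
        )
    n = int(as_float)
    if n < 0:
        raise ValidationError(f"row {row}: column {column!r} value {n} is negative")
    return n


def _parse_airr(df: pd.DataFrame, path: Path) -> list[ClonotypeRecord]:
    for col in ("junction_aa", "duplicate_count", "productive"):
        if col not in df.columns:
            raise FormatError(f"{path}: missing mandatory airr column {col!r}")
    records = []
    for i, row in enumerate(df.itertuples(index=False), start=1):
        n = _parse_count(getattr(row, "duplicate_count"), i, "duplicate_count")
        if n == 0:
            continue
        raw_prod = str(getattr(row, "productive")).strip().lower()
        if raw_prod in _AIRR_TRUE:
            productive = True
        elif raw_prod in _AIRR_FALSE:
            productive = False
        else:
            raise ValidationError(
                f"row {i}: unrecognized 'productive' value {raw_prod!r}"
            )
        records.append(
            ClonotypeRecord(
                cdr3_aa=str(getattr(row, "junction_aa")).strip(),
                templates=n,
                productive=productive,
                v_gene=str(getattr(row, "v_call", "") or ""),
                j_gene=str(getattr(row, "j_call", "") or ""),
            )
        )
    return records


def _parse_immunoseq(df: pd.DataFrame, path: Path) -> list[ClonotypeRecord]:
    if "aminoAcid" not in df.columns:
        raise FormatError(f"{path}: missing mandatory immunoseq column 'aminoAcid'")
    count_col = next((c for c in _IMMUNOSEQ_COUNT_COLUMNS if c in df.columns), None)
    if count_col is None:
        raise FormatError(
            f"{path}: missing mandatory immunoseq count column "
            f"(one of {list(_IMMUNOSEQ_COUNT_COLUMNS)})"
        )
    if "sequenceStatus" not in df.columns:
        raise FormatError(f"{path}: missing mandatory immunoseq column 'sequenceStatus'")
    records = []
    for i, (_, row) in enumerate(df.iterrows(), start=1):
        n = _parse_count(row[count_col], i, count_col)
        if n == 0:
            continue
        status = str(row["sequenceStatus"]).strip().lower()
        records.append(
            ClonotypeRecord(
                cdr3_aa=str(row["aminoAcid"]).strip(),
                templates=n,
                productive=status == "in",
                v_gene=str(row["vGeneName"]).strip() if "vGeneName" in df.columns else "",
                j_gene=str(row["jGeneName"]).strip() if "jGeneName" in df.columns else "",
            )
        )
    return records


def read_rearrangement_table(
    path: str | os.PathLike,
    dialect: str = "airr",
    *,
    participant: str = "",
    condition: Condition = Condition.DMSO,
    replicate: int = 1,
    assay_batch: str = "batch1",
    key_mode: str = "cdr3",
) -> WellSample:
    """Parse one per-well clonotype table into a :class:`WellSample`.

    Metadata (participant/condition/replicate/batch) is normally supplied by
    the manifest; the keyword arguments default to placeholders so the
    records can be parsed standalone.  Duplicate identity keys are merged by
    summing templates; non-productive records are retained but flagged.
    """
    df = _read_tsv(path)
    if dialect == "airr":
        records = _parse_airr(df, Path(path))
    elif dialect == "immunoseq":
        records = _parse_immunoseq(df, Path(path))
    else:
        raise ValueError(f"unknown dialect {dialect!r}; expected 'airr' or 'immunoseq'")
    return WellSample(
        participant=participant,
        condition=condition,
        replicate=replicate,
        assay_batch=assay_batch,
        records=records,
        key_mode=key_mode,
    )


def write_rearrangement_table(well: WellSample, path: str | os.PathLike) -> None:
    """Write a well in the airr dialect (round-trips with
    :func:`read_rearrangement_table`)."""
    rows = [
        {
            "junction_aa": r.cdr3_aa,
            "v_call": r.v_gene,
            "j_call": r.j_gene,
            "duplicate_count": r.templates,
            "productive": "T" if r.productive else "F",
        }
        for r in sorted(well.records, key=lambda r: (r.cdr3_aa, r.v_gene, not r.productive))
    ]
    pd.DataFrame(rows, columns=["junction_aa", "v_call", "j_call",
                                "duplicate_count", "productive"]).to_csv(
        path, sep="\t", index=False
    )


_MANIFEST_REQUIRED = ("file", "participant", "condition", "replicate", "assay_batch")


def read_manifest(path: str | os.PathLike) -> StudyManifest:
    """Read a CSV/TSV manifest with columns
    (file, participant, condition, replicate, assay_batch[, group]).

    Condition labels are normalized case-insensitively; relative file paths
    are resolved against the manifest's own directory.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"manifest not found: {path}")
    df = pd.read_csv(path, sep=None, engine="python", dtype=str)
    for col in _MANIFEST_REQUIRED:
        if col not in df.columns:
            raise FormatError(f"{path}: missing manifest column {col!r}")
    if df.empty:
        raise EmptyInputError(f"manifest {path} contains no entries")
    entries = []
    for i, row in df.iterrows():
        file = str(row["file"])
        if not os.path.isabs(file):
            file = str(path.parent / file)
        try:
            replicate = int(row["replicate"])
        except ValueError:
            raise ValidationError(
                f"manifest row {i + 1}: replicate {row['replicate']!r} is not an integer"
            ) from None
        entries.append(
            ManifestEntry(
                file=file,
                participant=str(row["participant"]),
                condition=parse_condition(row["condition"]),
                replicate=replicate,
                assay_batch=str(row["assay_batch"]),
                group=str(row["group"]) if "group" in df.columns and pd.notna(row.get("group")) else "",
            )
        )
    return StudyManifest(entries=entries)


def load_study(
    manifest: StudyManifest, dialect: str = "airr", key_mode: str = "cdr3"
) -> list[WellSample]:
    """Load every well referenced by the manifest.

    All files are checked for existence first so a dangling reference aborts
    the run before any table is parsed.
    """
    missing = [e.file for e in manifest.entries if not Path(e.file).exists()]
    if missing:
        raise FileNotFoundError(f"manifest references missing files: {missing}")
    wells = []
    for e in manifest.entries:
        wells.append(
            read_rearrangement_table(
                e.file,
                dialect=dialect,
                participant=e.participant,
                condition=e.condition,
                replicate=e.replicate,
                assay_batch=e.assay_batch,
                key_mode=key_mode,
            )
        )
    return wells
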