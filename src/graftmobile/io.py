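"""Count-table reading/writing and schema validation.

The on-disk format is delimited text (tab by default, comma auto-detected)
with a header row and optional ``#``-prefixed provenance comment lines:

    transcript_id  snp_id  replicate_id  tissue  genotype_sampled  total_reads  distal_reads

Extra columns are preserved untouched as ride-along metadata.
"""

from __future__ import annotations

import hashlib
import logging
import warnings
from pathlib import Path

import pandas as pd

__all__ = [
    "REQUIRED_COLUMNS",
    "read_count_table",
    "write_count_table",
    "read_label_table",
    "write_label_table",
    "validate_count_table",
]

logger = logging.getLogger(__name__)

REQUIRED_COLUMNS = [
    "transcript_id",
    "snp_id",
    "replicate_id",
    "tissue",
    "genotype_sampled",
    "total_reads",
    "distal_reads",
]

KEY_COLUMNS = ["transcript_id", "snp_id", "replicate_id"]

_DIALECTS = {"tsv": "\t", "csv": ","}


def _sniff_delimiter(path: Path) -> str:
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            return "\t" if "\t" in line else ","
    return "\t"


def validate_count_table(df: pd.DataFrame, source: str = "<table>") -> pd.DataFrame:
    """Validate schema and row invariants; raise with offending row numbers."""
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{source}: missing required columns {missing}")
    if df.empty:
        warnings.warn(f"{source}: table is empty", UserWarning, stacklevel=2)
        return df
    problems = []
    for col in ("total_reads", "distal_reads"):
        numeric = pd.to_numeric(df[col], errors="coerce")
        bad = df.index[numeric.isna() | (numeric != numeric.round()) | (numeric < 0)]
        problems.extend((int(i), f"non-integer or negative {col}") for i in bad)
    if not problems:
        df = df.assign(
            total_reads=df["total_reads"].astype(int), distal_reads=df["distal_reads"].astype(int)
        )
        over = df.index[df["distal_reads"] > df["total_reads"]]
        problems.extend((int(i), "distal_reads > total_reads") for i in over)
    dup = df.index[df.duplicated(subset=KEY_COLUMNS, keep=False)]
    problems.extend(
        (int(i), "duplicate (transcript_id, snp_id, replicate_id) key") for i in dup
    )
    if problems:
        listing = "; ".join(f"row {i}: {msg}" for i, msg in sorted(problems)[:20])
        raise ValueError(f"{source}: {len(problems)} invalid rows — {listing}")
    return df


def read_count_table(path, dialect: str | None = None) -> pd.DataFrame:
    """Read and validate a count table; delimiter auto-detected unless forced."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if dialect is not None and dialect not in _DIALECTS:
        raise ValueError(f"dialect must be one of {sorted(_DIALECTS)}, got {dialect!r}")
    sep = _DIALECTS[dialect] if dialect else _sniff_delimiter(path)
    df = pd.read_csv(path, sep=sep, comment="#", dtype={"transcript_id": str, "snp_id": str,
                                                        "replicate_id": str})
    df = validate_count_table(df, source=str(path))
    logger.debug("read %d rows from %s", len(df), path)
    return df


def write_count_table(
    df: pd.DataFrame, path, dialect: str = "tsv", metadata: dict | None = None
) -> None:
    """Write a count table with ``#`` provenance header lines (source, seed, config hash)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    sep = _DIALECTS[dialect]
    with open(path, "w") as fh:
        if metadata:
            digest = hashlib.md5(
                repr(sorted(metadata.items())).encode()
            ).hexdigest()[:12]
            for key, value in sorted(metadata.items()):
                fh.write(f"# {key}: {value}\n")
            fh.write(f"# config_hash: {digest}\n")
        df.to_csv(fh, sep=sep, index=False)


def read_label_table(path, dialect: str | None = None) -> pd.DataFrame:
    """Read a per-transcript label table (transcript_id, label[, ...])."""
    path = Path(path)
    sep = _DIALECTS[dialect] if dialect else _sniff_delimiter(path)
    df = pd.read_csv(path, sep=sep, comment="#", dtype={"transcript_id": str})
    for col in ("transcript_id", "label"):
        if col not in df.columns:
            raise ValueError(f"{path}: label table missing column {col!r}")
    return df


def write_label_table(df: pd.DataFrame, path, dialect: str = "tsv", metadata: dict | None = None) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        if metadata:
            for key, value in sorted(metadata.items()):
                fh.write(f"# {key}: {value}\n")
        df.to_csv(fh, sep=_DIALECTS[dialect], index=False)
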