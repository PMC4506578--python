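"""Tabular readers/writers and run configuration.

All tables are headered TSV.  Writers prefix provenance comment lines with
``#`` (including the resolved config hash when available); readers skip them.
Readers validate types and invariants and report the offending row number.
"""

from __future__ import annotations

import hashlib
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

import pandas as pd
import yaml
from Bio import SeqIO

from .annotate import AnnotatedRead, airr_table
from .errors import InputFormatError
from .flow import validate_flow_table

AIRR_COLUMNS = [
    "sequence_id",
    "v_call",
    "d_call",
    "j_call",
    "cdr3",
    "cdr3_aa",
    "productive",
    "duplicate_count",
    "v_score",
    "j_score",
    "fail_reason",
]


def write_tsv(df: pd.DataFrame, path: str | Path, meta: dict | None = None) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        for k, v in (meta or {}).items():
            fh.write(f"# {k}={v}\n")
        df.to_csv(fh, sep="\t", index=False, float_format="%.10g")


def read_tsv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#")


# -- AIRR-style rearrangements ----------------------------------------------

def write_airr(
    annotated: Iterable[tuple[AnnotatedRead, int]],
    path: str | Path,
    meta: dict | None = None,
) -> None:
    df = airr_table(annotated)
    if df.empty:
        df = pd.DataFrame(columns=AIRR_COLUMNS)
    write_tsv(df[AIRR_COLUMNS], path, meta)


def read_airr(path: str | Path) -> pd.DataFrame:
    df = read_tsv(path)
    missing = set(AIRR_COLUMNS) - set(df.columns)
    if missing:
        raise InputFormatError(f"{path}: missing AIRR columns {sorted(missing)}")
    return df


# -- peak / flow tables ------------------------------------------------------

def read_peaks(path: str | Path) -> pd.DataFrame:
    df = read_tsv(path)
    required = {"sample", "chain", "fragment_bp", "area"}
    if not required <= set(df.columns):
        raise InputFormatError(f"{path}: peak TSV needs columns {sorted(required)}")
    for i, row in df.iterrows():
        if row["area"] < 0:
            raise InputFormatError(f"{path}: negative area at row {i}")
        if int(row["fragment_bp"]) != row["fragment_bp"] or row["fragment_bp"] <= 0:
            raise InputFormatError(f"{path}: bad fragment length at row {i}")
    dup = df.duplicated(subset=["sample", "chain", "fragment_bp"])
    if dup.any():
        raise InputFormatError(f"{path}: duplicate peak at rows {list(df.index[dup])}")
    return df


def read_flow(path: str | Path) -> pd.DataFrame:
    return validate_flow_table(read_tsv(path))


# -- sequence files ----------------------------------------------------------

def iter_reads(path: str | Path) -> Iterator[tuple[str, str]]:
    """Yield (read_id, sequence) from FASTQ or FASTA (by extension)."""
    path = Path(path)
    fmt = "fastq" if path.suffix.lower() in (".fastq", ".fq") else "fasta"
    for rec in SeqIO.parse(str(path), fmt):
        yield rec.id, str(rec.seq).upper()


def read_counts_from_file(path: str | Path) -> dict[str, int]:
    """Deduplicated sequence multiset from a FASTQ/FASTA file."""
    counts: dict[str, int] = {}
    for _, seq in iter_reads(path):
        counts[seq] = counts.get(seq, 0) + 1
    return counts


# -- run configuration -------------------------------------------------------

@dataclass
class RunConfig:
    """Declarative run configuration; round-trips losslessly through YAML."""

    seed: int = 0
    outdir: str = "trdrep_out"
    dominance_threshold: float = 0.01
    min_d_match: int = 5
    min_v_score: float = 20.0
    min_j_score: float = 10.0
    min_support: int = 1
    max_mismatch: int = 0
    germline_fasta: str | None = None  # None -> built-in default reference
    germline_anchors: str | None = None
    germline_primers: str | None = None
    sim: dict = field(default_factory=dict)  # SimParams overrides
    flow: dict = field(default_factory=dict)  # FlowParams top-level overrides

    def __post_init__(self) -> None:
        if not (0.0 <= self.dominance_threshold < 1.0):
            raise InputFormatError("dominance_threshold must be in [0, 1)")
        if self.min_d_match < 1 or self.min_support < 1 or self.max_mismatch < 0:
            raise InputFormatError("bad threshold in config")

    def hash(self) -> str:
        """Provenance hash over everything that affects results (the output
        location does not)."""
        data = asdict(self)
        data.pop("outdir")
        blob = yaml.safe_dump(data, sort_keys=True).encode()
        return hashlib.sha1(blob).hexdigest()[:12]


def load_config(path: str | Path) -> RunConfig:
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    return RunConfig(**data)


def save_config(config: RunConfig, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(asdict(config), fh, sort_keys=True)
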