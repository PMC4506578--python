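"""Three-criterion clonotype assignment and cross-sample comparison.

A delta-1 clonotype is defined by (1) the amino acids the V segment
contributes to the CDR3 (IMGT positions 105-108, i.e. the first four CDR3
residues), (2) the number and identity of D segments in the junction, and
(3) the J segment.  Nucleotide-level junction diversity within a clonotype is
retained as per-clonotype CDR3 spectra, so a clonotype typically spans many
distinct nucleotide (and several amino-acid) junction sequences.

Criterion 1 is keyed at the amino-acid level; the nucleotide spectra are kept
per clonotype so a nucleotide-level re-keying remains a one-flag reanalysis.
Frequencies are read-level fractions of productive, successfully annotated
reads.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, NamedTuple

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist

from .annotate import AnnotatedRead
from .errors import EmptyTableError, TrdrepError


class ClonotypeKey(NamedTuple):
    v_call: str
    v_tail_aa: str  # IMGT 105-108 (shorter if junctional editing removed V residues)
    d_calls: tuple[str, ...]
    j_call: str

    def label(self) -> str:
        d = "+".join(self.d_calls) if self.d_calls else "-"
        return f"{self.v_call}|{self.v_tail_aa}|{d}|{self.j_call}"


def make_key(read: AnnotatedRead) -> ClonotypeKey:
    """Clonotype key of a productive annotated read."""
    if not read.productive or not read.cdr3_aa:
        raise TrdrepError(f"read {read.read_id}: clonotype key requires a productive CDR3")
    assert read.v_call is not None and read.j_call is not None
    return ClonotypeKey(
        read.v_call.segment_id,
        read.cdr3_aa[: min(4, len(read.cdr3_aa))],
        read.d_calls,
        read.j_call.segment_id,
    )


@dataclass
class ClonotypeTable:
    """Per-sample clonotype enumeration with junction spectra."""

    sample_id: str
    counts: dict[ClonotypeKey, int] = field(default_factory=dict)
    aa_spectra: dict[ClonotypeKey, Counter] = field(default_factory=dict)
    nt_spectra: dict[ClonotypeKey, Counter] = field(default_factory=dict)

    @property
    def total_reads(self) -> int:
        return sum(self.counts.values())

    def frequency(self, key: ClonotypeKey) -> float:
        return self.counts.get(key, 0) / self.total_reads

    def frequencies(self) -> dict[ClonotypeKey, float]:
        tot = self.total_reads
        return {k: c / tot for k, c in self.counts.items()}

    def to_frame(self) -> pd.DataFrame:
        tot = self.total_reads
        rows = []
        for key, c in sorted(self.counts.items(), key=lambda kv: (-kv[1], kv[0].label())):
            top_aa, top_n = _modal(self.aa_spectra[key])
            rows.append(
                {
                    "sample": self.sample_id,
                    "v_call": key.v_call,
                    "v_tail_aa": key.v_tail_aa,
                    "d_calls": "+".join(key.d_calls) if key.d_calls else "",
                    "j_call": key.j_call,
                    "read_count": c,
                    "frequency": c / tot,
                    "top_cdr3_aa": top_aa,
                    "top_cdr3_aa_count": top_n,
                }
            )
        return pd.DataFrame(rows)


def _modal(spectrum: Counter) -> tuple[str, int]:
    """Most frequent entry; ties break lexicographically."""
    best = min(spectrum.items(), key=lambda kv: (-kv[1], kv[0]))
    return best[0], best[1]


def enumerate_clonotypes(
    annotated: Iterable[tuple[AnnotatedRead, int]],
    sample_id: str,
) -> ClonotypeTable:
    """Group productive annotated reads by clonotype key.

    Frequencies use productive reads with an extracted CDR3 as denominator;
    unproductive and failed reads contribute nothing.
    """
    table = ClonotypeTable(sample_id)
    for read, count in annotated:
        if not read.productive or not read.cdr3_aa:
            continue
        key = make_key(read)
        table.counts[key] = table.counts.get(key, 0) + count
        table.aa_spectra.setdefault(key, Counter())[read.cdr3_aa] += count
        table.nt_spectra.setdefault(key, Counter())[read.cdr3_nt] += count
    if not table.counts:
        raise EmptyTableError(f"{sample_id}: no productive reads")
    return table


def dominant_clonotypes(
    table: ClonotypeTable, threshold: float = 0.01
) -> tuple[list[ClonotypeKey], int, float]:
    """Keys strictly above ``threshold`` frequency, their count, and their
    summed frequency in percent (the 'percent of total' summary)."""
    freqs = table.frequencies()
    keys = sorted((k for k, f in freqs.items() if f > threshold), key=lambda k: -freqs[k])
    summed_pct = 100.0 * sum(freqs[k] for k in keys)
    return keys, len(keys), summed_pct


@dataclass
class PublicMatrix:
    """Clonotype-by-sample frequency matrix over the union of per-sample
    dominant clonotypes, with average-linkage/Euclidean clustering orders."""

    data: pd.DataFrame  # index: key labels; columns: sample ids; values: frequency
    keys: list[ClonotypeKey]
    threshold: float
    row_order: list[int]
    col_order: list[int]

    def clustered(self) -> pd.DataFrame:
        return self.data.iloc[self.row_order, self.col_order]


def _leaf_order(mat: np.ndarray) -> list[int]:
    if mat.shape[0] < 2:
        return list(range(mat.shape[0]))
    link = hierarchy.linkage(pdist(mat, metric="euclidean"), method="average")
    return list(hierarchy.leaves_list(link))


def build_public_matrix(
    tables: Iterable[ClonotypeTable], threshold: float = 0.01
) -> PublicMatrix:
    """Union of per-sample dominant keys x samples -> frequency.

    An entry is the key's true frequency in that sample whenever the key is
    present at all (including below threshold); 0 only when absent.
    """
    tables = list(tables)
    if len(tables) < 2:
        raise TrdrepError("public matrix requires at least two samples")
    union: list[ClonotypeKey] = []
    seen = set()
    for t in tables:
        for k in dominant_clonotypes(t, threshold)[0]:
            if k not in seen:
                seen.add(k)
                union.append(k)
    union.sort(key=lambda k: k.label())
    mat = np.array([[t.frequency(k) for t in tables] for k in union])
    data = pd.DataFrame(mat, index=[k.label() for k in union], columns=[t.sample_id for t in tables])
    return PublicMatrix(
        data=data,
        keys=union,
        threshold=threshold,
        row_order=_leaf_order(mat),
        col_order=_leaf_order(mat.T),
    )


def top_cdr3(table: ClonotypeTable, key: ClonotypeKey) -> tuple[str, int, float]:
    """Modal CDR3 amino-acid sequence of a clonotype (ties break
    lexicographically), its count, and its within-clonotype frequency."""
    if key not in table.counts:
        raise KeyError(f"clonotype {key.label()} absent from {table.sample_id}")
    aa, n = _modal(table.aa_spectra[key])
    return aa, n, n / table.counts[key]


def shared_cdr3(
    tables: Iterable[ClonotypeTable],
    dominant_only: bool = False,
    threshold: float = 0.01,
) -> pd.DataFrame:
    """CDR3 amino-acid sequences present in every sample.

    Returns per-sample read-level frequencies of each universal sequence,
    sorted by minimum frequency descending.  With ``dominant_only`` the
    search is restricted to CDR3s of dominant clonotypes.
    """
    tables = list(tables)
    if len(tables) < 2:
        raise TrdrepError("shared-CDR3 detection requires at least two samples")
    per_sample: list[dict[str, float]] = []
    for t in tables:
        keys = set(dominant_clonotypes(t, threshold)[0]) if dominant_only else set(t.counts)
        agg: Counter = Counter()
        for k in keys:
            agg.update(t.aa_spectra[k])
        tot = t.total_reads
        per_sample.append({aa: c / tot for aa, c in agg.items()})
    universal = set(per_sample[0])
    for d in per_sample[1:]:
        universal &= set(d)
    rows = [
        {"cdr3_aa": aa, **{t.sample_id: d[aa] for t, d in zip(tables, per_sample)}}
        for aa in universal
    ]
    df = pd.DataFrame(rows)
    if df.empty:
        return pd.DataFrame(columns=["cdr3_aa", "min_frequency"] + [t.sample_id for t in tables])
    df["min_frequency"] = df[[t.sample_id for t in tables]].min(axis=1)
    return df.sort_values(["min_frequency", "cdr3_aa"], ascending=[False, True]).reset_index(
        drop=True
    )
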