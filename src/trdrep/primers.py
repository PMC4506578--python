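"""Clone-specific CDR3 primer derivation and presence/absence screening.

For a CDR3 peptide of interest, the nucleotide encodings observed across
samples are ranked per sample by read frequency; the primer is the encoding
that ranks first in the most samples, spanning the full CDR3 (IMGT position
105 through the J-encoded junction end).  Screening is a substring scan over
reads or junction spectra — the wet-lab readout this emulates is qualitative
present/absent, so the headline output is binary while supporting read counts
are retained.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Mapping

import pandas as pd

from ._seq import translate_nt
from .clonotype import ClonotypeTable
from .errors import TieError, TrdrepError

#: Recurrent ("public") delta-1 CDR3 peptides reported across encephalitic
#: brain specimens, with the clone-specific forward primer sequences that
#: exactly encode them.  These double as worked-example fixtures.
PUBLIC_DELTA1_CDR3_PRIMERS: dict[str, str] = {
    "ALGDSIPRRIAYTDKLI": "GCTCTTGGGGATTCCATTCCTAGGAGGATAGCGTACACCGATAAACTCATC",
    "ALGGLGTGGYAYTDKLI": "GCTCTTGGGGGGCTAGGTACTGGGGGATACGCCTACACCGATAAACTCATC",
    "ALGVPPRPSLYWGIGSLGSYTDKLI": "GCTCTTGGGGTCCCGCCTCGACCTTCCCTCTACTGGGGGATAGGAAGCTTGGGCTCGTACACCGATAAACTCATC",
}


@dataclass(frozen=True)
class PrimerSpec:
    """A clone-specific CDR3 primer: named by its target peptide, with the
    per-sample rank evidence that selected this DNA variant."""

    name: str  # target cdr3_aa
    primer_nt: str
    source_ranks: pd.DataFrame  # variant x sample rank table

    def __post_init__(self) -> None:
        if translate_nt(self.primer_nt) != self.name:
            raise TrdrepError(f"primer for {self.name} does not encode its target peptide")


def _nt_spectrum_of_aa(table: ClonotypeTable, cdr3_aa: str) -> Counter:
    """Read counts of each nucleotide encoding of ``cdr3_aa`` in one sample,
    pooled over clonotypes."""
    agg: Counter = Counter()
    for key, nt_counter in table.nt_spectra.items():
        for nt, c in nt_counter.items():
            if len(nt) == 3 * len(cdr3_aa) and translate_nt(nt) == cdr3_aa:
                agg[nt] += c
    return agg


def rank_cdr3_dna_variants(tables: Iterable[ClonotypeTable], cdr3_aa: str) -> pd.DataFrame:
    """Rank the DNA encodings of a CDR3 peptide within each carrying sample.

    Returns one row per variant with per-sample ranks (1 = most frequent in
    that sample, NaN = absent) and ``n_top`` = number of samples where the
    variant ranks first; sorted by ``n_top`` descending.
    """
    tables = list(tables)
    spectra = {t.sample_id: _nt_spectrum_of_aa(t, cdr3_aa) for t in tables}
    variants = sorted({nt for spec in spectra.values() for nt in spec})
    if not variants:
        raise TrdrepError(f"CDR3 {cdr3_aa!r} absent from every sample")
    rows = []
    for nt in variants:
        row: dict[str, object] = {"variant_nt": nt}
        n_top = 0
        for sid, spec in spectra.items():
            if nt not in spec:
                row[sid] = float("nan")
                continue
            # dense rank by count descending, ties broken lexicographically
            ordered = sorted(spec.items(), key=lambda kv: (-kv[1], kv[0]))
            rank = next(i for i, (v, _) in enumerate(ordered, 1) if v == nt)
            row[sid] = rank
            if rank == 1:
                n_top += 1
        row["n_top"] = n_top
        rows.append(row)
    df = pd.DataFrame(rows).sort_values(["n_top", "variant_nt"], ascending=[False, True])
    return df.reset_index(drop=True)


def build_clone_primer(ranked: pd.DataFrame, cdr3_aa: str) -> PrimerSpec:
    """Primer = the DNA variant that is most-frequent in the majority of the
    samples; an outright tie is surfaced for the caller to resolve."""
    if ranked.empty:
        raise TrdrepError("no ranked variants")
    top = ranked["n_top"].iloc[0]
    contenders = ranked[ranked["n_top"] == top]
    if len(contenders) > 1:
        raise TieError(
            f"{len(contenders)} variants tied at rank-1 in {top} samples for {cdr3_aa}"
        )
    return PrimerSpec(name=cdr3_aa, primer_nt=str(ranked["variant_nt"].iloc[0]), source_ranks=ranked)


def _count_with_mismatches(primer: str, seq: str, max_mismatch: int) -> bool:
    """Does ``primer`` occur in ``seq`` with at most ``max_mismatch``
    substitutions (Hamming scan)?"""
    if max_mismatch == 0:
        return primer in seq
    m = len(primer)
    for start in range(len(seq) - m + 1):
        mm = 0
        for a, b in zip(primer, seq[start : start + m]):
            if a != b:
                mm += 1
                if mm > max_mismatch:
                    break
        if mm <= max_mismatch:
            return True
    return False


def match_primer(
    primer: PrimerSpec,
    sequences: Mapping[str, int],
    max_mismatch: int = 0,
    min_support: int = 1,
) -> tuple[bool, int]:
    """Screen a sample for a clone-specific primer site.

    ``sequences`` maps read (or junction) sequences to read counts.  Returns
    (detected, supporting read count); detected requires ``min_support``.
    """
    count = 0
    for seq, c in sequences.items():
        if _count_with_mismatches(primer.primer_nt, seq, max_mismatch):
            count += c
    return count >= min_support, count


def sample_nt_sequences(table: ClonotypeTable) -> dict[str, int]:
    """Pooled junction-sequence multiset of one sample (screening substrate)."""
    agg: Counter = Counter()
    for nt_counter in table.nt_spectra.values():
        agg.update(nt_counter)
    return dict(agg)


def presence_matrix(
    primers: Iterable[PrimerSpec],
    samples: Mapping[str, Mapping[str, int]],
    max_mismatch: int = 0,
    min_support: int = 1,
) -> pd.DataFrame:
    """Full primer x sample screen.

    ``samples`` maps sample id to its sequence multiset.  Returns a tidy frame
    (primer, sample, detected, read_count).
    """
    primers = list(primers)
    if not primers or not samples:
        raise TrdrepError("presence matrix requires >= 1 primer and >= 1 sample")
    rows = []
    for p in primers:
        for sid, seqs in samples.items():
            detected, count = match_primer(p, seqs, max_mismatch, min_support)
            rows.append(
                {"primer": p.name, "sample": sid, "detected": detected, "read_count": count}
            )
    return pd.DataFrame(rows)
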