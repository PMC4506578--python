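"""In-silico and empirical spectratyping.

Spectratyping profiles a repertoire by the lengths of fluorescently labelled
PCR fragments spanning the CDR3: each distinct junction length is one peak,
and an oligoclonal repertoire collapses to a few discrete peaks.  Fragment
lengths run from the chain-specific forward primer's 5' end to the labelled
constant-region reverse primer's 5' end, inclusive of both footprints, so
productive (in-frame) junctions differ by whole codons and the lengths form
a 3-bp ladder.

Fragment lengths are integer bp (capillary sizing treated as exact); a +/-1 bp
binning tolerance for real electropherograms is available in the readers only.
"""

from __future__ import annotations

from typing import TYPE_CHECKING, Iterable

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist

from ._seq import revcomp
from .errors import InputFormatError, TrdrepError
from .germline import CHAIN_OF_V, GermlineReference

if TYPE_CHECKING:  # only for typing; simulate imports this module at run time
    from .simulate import CloneTable, TrueRearrangement


def amplicon_bounds(
    transcript_nt: str,
    ref: GermlineReference,
    chain: str,
    rev_primer: str = "Cd1.2",
) -> tuple[int, int]:
    """Half-open amplicon span on a transcript: forward primer start through
    the last base of the reverse primer's plus-strand footprint."""
    fwd = ref.primers[chain]
    rev = ref.primers[rev_primer]
    i = transcript_nt.find(fwd.seq)
    if i < 0:
        raise TrdrepError(f"forward primer {chain} site missing from transcript")
    site = revcomp(rev.seq)
    j = transcript_nt.find(site, i)
    if j < 0:
        raise TrdrepError(f"reverse primer {rev_primer} site missing from transcript")
    return i, j + len(site)


def fragment_length(rearrangement: "TrueRearrangement", ref: GermlineReference) -> int:
    """Labelled-fragment length in bp for one rearrangement."""
    chain = CHAIN_OF_V[rearrangement.v_id]
    start, end = amplicon_bounds(rearrangement.transcript_nt, ref, chain)
    return end - start


def normalize_peaks(peaks: pd.DataFrame) -> pd.DataFrame:
    """Normalize peak areas within each (sample, chain) to fractions of the
    total area; idempotent on already-normalized input."""
    if peaks.empty:
        raise InputFormatError("empty peak table")
    if (peaks["area"] < 0).any():
        raise InputFormatError("negative peak area")
    out = peaks.copy()
    totals = out.groupby(["sample", "chain"])["area"].transform("sum")
    if (totals == 0).any():
        raise InputFormatError("all-zero peak areas for a sample/chain")
    out["fraction"] = out["area"] / totals
    return out


def insilico_spectratype(clone_table: "CloneTable", ref: GermlineReference) -> pd.DataFrame:
    """Noise-free spectratype directly from ground-truth clone frequencies
    (the two-path check against simulate_peak_table + normalize_peaks)."""
    rows = []
    for sid, recs in clone_table.samples.items():
        agg: dict[tuple[str, int], float] = {}
        for rec in recs:
            ch = CHAIN_OF_V[rec.rearrangement.v_id]
            bp = fragment_length(rec.rearrangement, ref)
            agg[(ch, bp)] = agg.get((ch, bp), 0.0) + rec.frequency
        tot_by_chain: dict[str, float] = {}
        for (ch, _), f in agg.items():
            tot_by_chain[ch] = tot_by_chain.get(ch, 0.0) + f
        for (ch, bp), f in sorted(agg.items()):
            rows.append(
                {"sample": sid, "chain": ch, "fragment_bp": bp, "fraction": f / tot_by_chain[ch]}
            )
    return pd.DataFrame(rows)


class SpectratypeMatrix:
    """Samples x fragment-length fraction matrix for one chain, with an
    average-linkage/Euclidean clustering order over samples."""

    def __init__(self, chain: str, data: pd.DataFrame, row_order: list[int]):
        self.chain = chain
        self.data = data  # index: sample ids; columns: fragment lengths (ascending)
        self.row_order = row_order

    def clustered(self) -> pd.DataFrame:
        return self.data.iloc[self.row_order]


def build_matrix(peaks: pd.DataFrame, chain: str) -> SpectratypeMatrix:
    """Cross-sample fragment-length matrix for one chain.

    Columns are the union of observed lengths (ascending); a sample lacking a
    length gets 0 there.  Rows are normalized to sum to 1.
    """
    sub = peaks[peaks["chain"] == chain]
    if sub["sample"].nunique() < 2:
        raise TrdrepError(f"chain {chain}: need >= 2 samples to build a matrix")
    wide = (
        sub.pivot_table(index="sample", columns="fragment_bp", values="area", aggfunc="sum")
        .fillna(0.0)
        .sort_index(axis=1)
    )
    wide = wide.div(wide.sum(axis=1), axis=0)
    mat = wide.to_numpy()
    if mat.shape[0] < 2:
        order = list(range(mat.shape[0]))
    else:
        link = hierarchy.linkage(pdist(mat, metric="euclidean"), method="average")
        order = list(hierarchy.leaves_list(link))
    return SpectratypeMatrix(chain, wide, order)


def frame_ladder_check(matrix: SpectratypeMatrix) -> pd.DataFrame:
    """QC for the in-frame 3-bp ladder: flags fragment lengths not congruent
    to the modal residue class mod 3, with their fraction mass per sample."""
    lengths = np.asarray(matrix.data.columns, dtype=int)
    if lengths.size == 0:
        raise TrdrepError("empty spectratype matrix")
    residues = lengths % 3
    mass = matrix.data.to_numpy().sum(axis=0)
    modal = int(
        min(
            np.unique(residues),
            key=lambda r: (-mass[residues == r].sum(), r),
        )
    )
    bad = lengths[residues != modal]
    rows = []
    for sid in matrix.data.index:
        row = matrix.data.loc[sid]
        for bp in bad:
            if row[bp] > 0:
                rows.append({"sample": sid, "fragment_bp": int(bp), "fraction": float(row[bp])})
    return pd.DataFrame(rows, columns=["sample", "fragment_bp", "fraction"])


def spectratype_from_clones(
    clone_table: "CloneTable", ref: GermlineReference, chain: str
) -> SpectratypeMatrix:
    """Convenience: ground-truth in-silico matrix for one chain."""
    df = insilico_spectratype(clone_table, ref).rename(columns={"fraction": "area"})
    return build_matrix(df, chain)
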