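"""Germline TRD segment model and I/O.

The T-cell receptor delta locus rearranges one variable (V), up to three
diversity (D), and one joining (J) segment; the junction between the conserved
cysteine at IMGT position 104 (last V-framework codon) and the conserved
phenylalanine/tryptophan at position 118 (first J-framework codon) is the CDR3.
This module holds the segment sequences, their anchor codon offsets, and the
PCR primer geometry that defines amplicon fragment lengths downstream.

Coordinates are 0-based half-open throughout; anchors point at codon starts.
Reverse primers are stored 5'->3' as synthesized and matched by reverse
complement on the plus strand.

The built-in default reference is a compact synthetic scaffold: the three real
TRDD segment sequences and the published spectratyping primer sequences are
embedded in invented-but-realistic V/J/C context, sized so that a 51-nt
(17-residue) CDR3 yields a 183 bp Vd1 amplicon — the bottom rung of the
in-frame fragment ladder seen in oligoclonal delta-1 repertoires.  Users with
IMGT-derived references can load them from FASTA/TSV at run time.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from ._seq import is_valid_nt, revcomp, translate_nt
from .errors import AnchorError, GermlineFormatError, PrimerSiteError

VALID_KINDS = {"V", "D", "J", "C"}

#: Spectratyping / sequencing primers (5'->3' as synthesized).
PRIMER_SEQS: dict[str, str] = {
    "Vd1": "CTGTCAACTTCAAGAAAGCAGCGAAATC",
    "Vd2": "TACCGAGAAAAGGACATCTATGGC",
    "Vd3": "GGGGATAACAGCAGATCAGAAGGT",
    "Cd1.1": "TGGGAGAGATGCAATAGCAGGATC",
    "Cd1.2": "ACGGATGGTTTGGTAGAGGCTGA",
}

#: Forward chain primer name for each V segment.
CHAIN_OF_V: dict[str, str] = {"TRDV1": "Vd1", "TRDV2": "Vd2", "TRDV3": "Vd3"}
V_OF_CHAIN: dict[str, str] = {v: k for k, v in CHAIN_OF_V.items()}


@dataclass(frozen=True)
class GermlineSegment:
    """One germline segment.

    ``anchor`` is the 0-based offset of the first nucleotide of the C104 codon
    (V segments) or of the F/W118 codon (J segments); absent for D and C.
    """

    id: str
    kind: str
    seq: str
    anchor: int | None = None

    def __post_init__(self) -> None:
        if self.kind not in VALID_KINDS:
            raise GermlineFormatError(f"{self.id}: unknown kind {self.kind!r}")
        if not is_valid_nt(self.seq):
            raise GermlineFormatError(f"{self.id}: sequence must be non-empty uppercase ACGT")
        if self.kind in ("V", "J"):
            if self.anchor is None:
                raise AnchorError(f"{self.id}: {self.kind} segment requires an anchor")
            if not (0 <= self.anchor and self.anchor + 3 <= len(self.seq)):
                raise AnchorError(f"{self.id}: anchor {self.anchor} out of range")
            codon_aa = translate_nt(self.anchor_codon)
            if self.kind == "V" and codon_aa != "C":
                raise AnchorError(f"{self.id}: anchor codon {self.anchor_codon} is not cysteine")
            if self.kind == "J" and codon_aa not in ("F", "W"):
                raise AnchorError(f"{self.id}: anchor codon {self.anchor_codon} is not F/W")
        else:
            if self.anchor is not None:
                raise AnchorError(f"{self.id}: {self.kind} segment must not carry an anchor")
            if self.kind == "D" and len(self.seq) < 5:
                raise GermlineFormatError(f"{self.id}: D segment shorter than 5 nt")

    @property
    def anchor_codon(self) -> str:
        assert self.anchor is not None
        return self.seq[self.anchor : self.anchor + 3]

    @property
    def post_anchor(self) -> str:
        """V: CDR3-contributing tail after the C104 codon. J: F118 codon onward."""
        assert self.anchor is not None
        if self.kind == "V":
            return self.seq[self.anchor + 3 :]
        return self.seq[self.anchor :]

    @property
    def pre_anchor(self) -> str:
        """J: CDR3-contributing head before the F/W118 codon."""
        assert self.anchor is not None
        return self.seq[: self.anchor]


@dataclass(frozen=True)
class Primer:
    """A PCR primer and its declared binding site.

    ``offset`` is the 0-based start of the binding footprint on the plus
    strand of ``segment``; reverse primers bind as their reverse complement.
    """

    name: str
    seq: str
    segment: str
    offset: int
    orientation: str  # "forward" | "reverse"

    def __post_init__(self) -> None:
        if self.orientation not in ("forward", "reverse"):
            raise GermlineFormatError(f"primer {self.name}: bad orientation {self.orientation!r}")
        if not is_valid_nt(self.seq):
            raise GermlineFormatError(f"primer {self.name}: invalid sequence")

    @property
    def site_seq(self) -> str:
        """Plus-strand footprint sequence at the binding site."""
        return self.seq if self.orientation == "forward" else revcomp(self.seq)


@dataclass(frozen=True)
class PrimerReport:
    name: str
    bound: bool
    offset: int


@dataclass
class GermlineReference:
    """Validated collection of germline segments plus primer geometry."""

    segments: dict[str, GermlineSegment] = field(default_factory=dict)
    primers: dict[str, Primer] = field(default_factory=dict)

    def __post_init__(self) -> None:
        kinds = {k: [s for s in self.segments.values() if s.kind == k] for k in VALID_KINDS}
        if not kinds["V"] or not kinds["J"]:
            raise GermlineFormatError("reference requires at least one V and one J segment")
        if self.primers:
            validate_primers(self)

    # -- accessors -------------------------------------------------------
    def by_kind(self, kind: str) -> list[GermlineSegment]:
        return sorted((s for s in self.segments.values() if s.kind == kind), key=lambda s: s.id)

    @property
    def v_segments(self) -> list[GermlineSegment]:
        return self.by_kind("V")

    @property
    def d_segments(self) -> list[GermlineSegment]:
        return self.by_kind("D")

    @property
    def j_segments(self) -> list[GermlineSegment]:
        return self.by_kind("J")

    @property
    def c_segment(self) -> GermlineSegment:
        cs = self.by_kind("C")
        if not cs:
            raise GermlineFormatError("reference has no constant segment")
        return cs[0]

    def __getitem__(self, seg_id: str) -> GermlineSegment:
        try:
            return self.segments[seg_id]
        except KeyError:
            raise GermlineFormatError(f"unknown segment id {seg_id!r}") from None


def validate_primers(ref: GermlineReference) -> list[PrimerReport]:
    """Check that every declared primer binds exactly once at its declared site.

    Returns one report row per primer; raises :class:`PrimerSiteError` on a
    missing or multiply-occurring site.
    """
    reports = []
    for primer in ref.primers.values():
        seg = ref[primer.segment]
        site = primer.site_seq
        hits = _find_all(site, seg.seq)
        if len(hits) == 0:
            raise PrimerSiteError(f"primer {primer.name}: site not found in {seg.id}")
        if len(hits) > 1:
            raise PrimerSiteError(f"primer {primer.name}: site occurs {len(hits)}x in {seg.id}")
        if hits[0] != primer.offset:
            raise PrimerSiteError(
                f"primer {primer.name}: site at offset {hits[0]}, declared {primer.offset}"
            )
        reports.append(PrimerReport(primer.name, True, hits[0]))
    return reports


def _find_all(needle: str, haystack: str) -> list[int]:
    hits, start = [], 0
    while True:
        i = haystack.find(needle, start)
        if i < 0:
            return hits
        hits.append(i)
        start = i + 1


# ---------------------------------------------------------------------------
# FASTA / TSV I/O
# ---------------------------------------------------------------------------

def load_germline(
    segment_file: str | Path,
    anchor_file: str | Path,
    primer_file: str | Path | None = None,
) -> GermlineReference:
    """Load a reference from a segment FASTA plus an anchor TSV.

    The anchor TSV has columns ``id``, ``kind``, ``anchor`` (empty anchor for
    D/C).  An optional primer TSV has columns ``name``, ``seq``, ``segment``,
    ``offset``, ``orientation``.
    """
    records = list(SeqIO.parse(str(segment_file), "fasta"))
    seqs: dict[str, str] = {}
    for rec in records:
        if rec.id in seqs:
            raise GermlineFormatError(f"duplicate segment id {rec.id!r} in FASTA")
        seqs[rec.id] = str(rec.seq).upper()

    anchors = pd.read_csv(anchor_file, sep="\t", dtype={"id": str, "kind": str})
    if not {"id", "kind", "anchor"} <= set(anchors.columns):
        raise GermlineFormatError("anchor TSV must have columns id, kind, anchor")
    segments: dict[str, GermlineSegment] = {}
    for row in anchors.itertuples(index=False):
        if row.id not in seqs:
            raise GermlineFormatError(f"anchor TSV lists {row.id!r}, absent from FASTA")
        if row.id in segments:
            raise GermlineFormatError(f"duplicate segment id {row.id!r} in anchor TSV")
        anchor = None if pd.isna(row.anchor) else int(row.anchor)
        segments[row.id] = GermlineSegment(row.id, row.kind, seqs[row.id], anchor)
    missing = set(seqs) - set(segments)
    if missing:
        raise GermlineFormatError(f"FASTA records without anchor rows: {sorted(missing)}")

    primers: dict[str, Primer] = {}
    if primer_file is not None:
        ptab = pd.read_csv(primer_file, sep="\t")
        for row in ptab.itertuples(index=False):
            primers[row.name] = Primer(
                row.name, row.seq, row.segment, int(row.offset), row.orientation
            )
    return GermlineReference(segments, primers)


def write_germline(
    ref: GermlineReference,
    segment_file: str | Path,
    anchor_file: str | Path,
    primer_file: str | Path | None = None,
) -> None:
    """Inverse of :func:`load_germline`; round-trips byte-identically."""
    ordered = sorted(ref.segments.values(), key=lambda s: s.id)
    SeqIO.write(
        [SeqRecord(Seq(s.seq), id=s.id, description="") for s in ordered],
        str(segment_file),
        "fasta",
    )
    pd.DataFrame(
        {
            "id": [s.id for s in ordered],
            "kind": [s.kind for s in ordered],
            "anchor": [s.anchor if s.anchor is not None else pd.NA for s in ordered],
        }
    ).to_csv(anchor_file, sep="\t", index=False)
    if primer_file is not None:
        ps = sorted(ref.primers.values(), key=lambda p: p.name)
        pd.DataFrame(
            {
                "name": [p.name for p in ps],
                "seq": [p.seq for p in ps],
                "segment": [p.segment for p in ps],
                "offset": [p.offset for p in ps],
                "orientation": [p.orientation for p in ps],
            }
        ).to_csv(primer_file, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Built-in default reference (synthetic scaffold; see module docstring)
# ---------------------------------------------------------------------------

_DEFAULT_SEGMENTS: list[tuple[str, str, str, int | None]] = [
    # V segments: chain primer at offset 0, C104 anchor, CDR3-contributing tail.
    (
        "TRDV1",
        "V",
        PRIMER_SEQS["Vd1"] + "CTTCCAGTTCTGGGACTCAGGAAGAGACAAGTGACAGTGGCCTTTAT" + "TGT" + "GCTCTTGGGG",
        75,
    ),
    (
        "TRDV2",
        "V",
        PRIMER_SEQS["Vd2"] + "TCATCGGATACAGTGTCTCTCGGAAGAACCTGGGAA" + "TGT" + "GCCTGTGACACC",
        60,
    ),
    (
        "TRDV3",
        "V",
        PRIMER_SEQS["Vd3"] + "GGCTTCTCACCTCAGCCTTGAGAGTCTATT" + "TGT" + "GCCTTT",
        54,
    ),
    # D segments (real IMGT TRDD1/2/3 core sequences).
    ("TRDD1", "D", "GAAATAGT", None),
    ("TRDD2", "D", "CCTTCCTAC", None),
    ("TRDD3", "D", "ACTGGGGGATACG", None),
    # J segments: CDR3-contributing head, F/W118 anchor codon, 12 nt framework.
    ("TRDJ1", "J", "ACACCGATAAACTCATC" + "TTT" + "GGAAAAGGAACC", 17),
    ("TRDJ2", "J", "GACACCGTCAAGCT" + "TTC" + "GGCAAAGGAACC", 14),
    ("TRDJ3", "J", "TCGGACAAGCTCAT" + "TGG" + "GGAACCGACCTG", 14),
    ("TRDJ4", "J", "AGCCGAACTCATCA" + "TTT" + "GGCAGAGGAACC", 14),
    # Constant region: nested reverse primer sites (Cd1.2 inner, Cd1.1 outer).
    (
        "TRDC1",
        "C",
        "AGTCAACCGAATCCTT"
        + revcomp(PRIMER_SEQS["Cd1.2"])
        + "CACCAGTTGA"
        + revcomp(PRIMER_SEQS["Cd1.1"])
        + "GGACTTCAGC",
        None,
    ),
]

_DEFAULT_PRIMERS: list[tuple[str, str, int, str]] = [
    ("Vd1", "TRDV1", 0, "forward"),
    ("Vd2", "TRDV2", 0, "forward"),
    ("Vd3", "TRDV3", 0, "forward"),
    ("Cd1.2", "TRDC1", 16, "reverse"),
    ("Cd1.1", "TRDC1", 16 + 23 + 10, "reverse"),
]


def default_reference() -> GermlineReference:
    """The built-in synthetic TRD reference (3 V, 3 D, 4 J, 1 C, 5 primers)."""
    segments = {sid: GermlineSegment(sid, kind, seq, anchor) for sid, kind, seq, anchor in _DEFAULT_SEGMENTS}
    primers = {
        name: Primer(name, PRIMER_SEQS[name], seg, offset, orient)
        for name, seg, offset, orient in _DEFAULT_PRIMERS
    }
    return GermlineReference(segments, primers)


def segments_from_iterable(segments: Iterable[GermlineSegment]) -> dict[str, GermlineSegment]:
    out: dict[str, GermlineSegment] = {}
    for seg in segments:
        if seg.id in out:
            raise GermlineFormatError(f"duplicate segment id {seg.id!r}")
        out[seg.id] = seg
    return out
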