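"""Read annotation: segment calls, CDR3 extraction, D identification,
translation, productivity."""

import numpy as np
import pytest
from Bio.Seq import Seq

import trdrep as t
from trdrep._seq import CODON_TABLE
from trdrep.annotate import (
    AnnotateConfig,
    SegmentCall,
    annotate_read,
    assign_segment,
    classify_productivity,
    extract_cdr3,
    find_d_segments,
)
from trdrep.align import semiglobal
from trdrep.errors import AnnotationError, FrameError
from trdrep.primers import PUBLIC_DELTA1_CDR3_PRIMERS
from trdrep.simulate import rearrangement_from_cdr3, amplicon_nt

CLONE1 = "GCTCTTGGGGATTCCATTCCTAGGAGGATAGCGTACACCGATAAACTCATC"


def build_read(ref, cdr3_nt, v_id="TRDV1", j_id="TRDJ1"):
    v, j = ref[v_id], ref[j_id]
    return v.seq[: v.anchor + 3] + cdr3_nt + j.post_anchor + ref.c_segment.seq


# -- translation -------------------------------------------------------------

@pytest.mark.parametrize("aa,nt", sorted(PUBLIC_DELTA1_CDR3_PRIMERS.items()))
def test_clone_specific_primers_translate_to_their_peptides(aa, nt):
    assert t.translate_nt(nt) == aa


def test_codon_table_matches_independent_translator():
    for codon, aa in CODON_TABLE.items():
        assert aa == str(Seq(codon).translate())
    assert len(CODON_TABLE) == 64


def test_out_of_frame_translation_raises():
    with pytest.raises(FrameError):
        t.translate_nt("ACGTA")


# -- segment assignment ------------------------------------------------------

def test_exact_v_read_assigns_with_correct_anchor(ref):
    read = build_read(ref, CLONE1)
    call = assign_segment(read, ref.v_segments)
    assert call.segment_id == "TRDV1"
    assert call.score == len(ref["TRDV1"].seq)  # full-length exact match
    assert call.anchor_offset == ref["TRDV1"].anchor


def test_substitutions_reduce_score_by_two_each(ref):
    read = build_read(ref, CLONE1)
    mutated = list(read)
    mutated[10] = "A" if read[10] != "A" else "C"
    mutated[40] = "A" if read[40] != "A" else "C"
    call = assign_segment("".join(mutated), ref.v_segments)
    assert call.segment_id == "TRDV1"
    assert call.score == len(ref["TRDV1"].seq) - 4


def test_all_n_read_is_unassigned(ref):
    assert assign_segment("N" * 120, ref.v_segments, min_score=20.0) is None


def test_pruned_assignment_equals_exhaustive_evaluation(ref, rng):
    """The score-bound prune never changes the winner or the tie-break."""
    segs = ref.v_segments + ref.j_segments
    for _ in range(30):
        n = int(rng.integers(30, 150))
        read = "".join("ACGT"[b] for b in rng.integers(4, size=n))
        for cands in (ref.v_segments, ref.j_segments):
            got = assign_segment(read, cands, min_score=float("-inf"))
            scores = {s.id: semiglobal(s.seq, read).score for s in cands}
            want = min(scores.items(), key=lambda kv: (-kv[1], kv[0]))
            assert got.segment_id == want[0] and got.score == want[1]


# -- CDR3 extraction ---------------------------------------------------------

def test_extract_cdr3_recovers_printed_clone(ref):
    """Read carries the 51-nt public junction; slicing at the known anchor
    offsets is the oracle."""
    read = build_read(ref, CLONE1)
    v_off = ref["TRDV1"].anchor
    j_off = read.find(ref["TRDJ1"].post_anchor)
    assert read[v_off + 3 : j_off] == CLONE1  # oracle: direct slice
    rec = annotate_read("r1", read, ref)
    assert rec.cdr3_nt == CLONE1
    assert rec.cdr3_aa == "ALGDSIPRRIAYTDKLI"


def test_anchor_order_violation_is_an_extraction_error():
    with pytest.raises(AnnotationError):
        extract_cdr3("ACGT" * 10, SegmentCall("V", 0, 30), SegmentCall("J", 0, 10))


def test_zero_length_cdr3_is_valid():
    assert extract_cdr3("ACGTACGT", SegmentCall("V", 0, 1), SegmentCall("J", 0, 4)) == ""


@pytest.mark.parametrize("length", list(range(0, 61)))
def test_extraction_is_identity_on_constructed_junctions(ref, length):
    """Extraction returns exactly the junction for lengths 0-60.

    Junctions of >= 9 nt (the generator's support: at least 9 J-head
    nucleotides are always retained) go through full annotation; shorter ones
    carry no alignable J evidence and are checked via direct extraction at
    the known anchors.
    """
    rng = np.random.default_rng(length)
    j_head = ref["TRDJ1"].pre_anchor
    if length >= 9:
        cdr3 = (
            "".join("ACGT"[b] for b in rng.integers(4, size=length - 9)) + j_head[-9:]
        )
        read = build_read(ref, cdr3)
        rec = annotate_read(f"len{length}", read, ref)
        assert rec.fail_reason is None
        assert rec.cdr3_nt == cdr3
    else:
        cdr3 = "".join("ACGT"[b] for b in rng.integers(4, size=length))
        read = build_read(ref, cdr3)
        v_anchor = ref["TRDV1"].anchor
        j_anchor = v_anchor + 3 + length
        got = extract_cdr3(read, SegmentCall("TRDV1", 0, v_anchor), SegmentCall("TRDJ1", 0, j_anchor))
        assert got == cdr3


def test_read_without_j_region_fails_no_j(ref):
    v = ref["TRDV1"]
    rec = annotate_read("short", v.seq[: v.anchor + 3] + "ACGTAC", ref)
    assert rec.fail_reason == "no_j"


# -- D identification --------------------------------------------------------

def oracle_d_positions(cdr3, d_segs, min_len):
    """Exhaustive substring-position oracle: all (start, length, d_id) hits."""
    hits = []
    for d in d_segs:
        for ds in range(len(d.seq)):
            for de in range(ds + min_len, len(d.seq) + 1):
                sub = d.seq[ds:de]
                start = cdr3.find(sub)
                while start >= 0:
                    hits.append((start, de - ds, d.id))
                    start = cdr3.find(sub, start + 1)
    return hits


def test_full_d3_containment(ref):
    cdr3 = "GCA" + ref["TRDD3"].seq + "TAC"
    assert find_d_segments(cdr3, ref.d_segments) == ["TRDD3"]


def test_short_d_fragments_below_threshold_are_ignored(ref):
    cdr3 = "GCAGAAACCGTGGC"  # max 3-4 nt of any D (checked by the oracle)
    assert oracle_d_positions(cdr3, ref.d_segments, 5) == []
    assert find_d_segments(cdr3, ref.d_segments, min_d_match=5) == []


def test_two_d_segments_ordered_by_position(ref):
    d2 = ref["TRDD2"].seq[:6]  # 6 nt retained
    d3 = ref["TRDD3"].seq[3:10]  # 7 nt retained
    cdr3 = "GCAA" + d2 + "TT" + d3 + "CAA"
    got = find_d_segments(cdr3, ref.d_segments, min_d_match=5)
    hits = oracle_d_positions(cdr3, ref.d_segments, 5)
    # oracle confirms both Ds have >= 5 nt evidence, D2 before D3
    assert {h[2] for h in hits} >= {"TRDD2", "TRDD3"}
    d2_first = min(h[0] for h in hits if h[2] == "TRDD2")
    d3_first = min(h[0] for h in hits if h[2] == "TRDD3")
    assert d2_first < d3_first
    assert got == ["TRDD2", "TRDD3"]


from hypothesis import given, settings
from hypothesis import strategies as st


@settings(max_examples=60, derandomize=True)
@given(st.text(alphabet="ACGT", min_size=0, max_size=60))
def test_d_identification_is_sound_on_arbitrary_junctions(cdr3):
    """Soundness property: every reported D is backed by a >= 5 nt germline
    substring at a position in the junction, reports are ordered and each D
    appears at most once."""
    ref = __import__("trdrep").default_reference()
    got = find_d_segments(cdr3, ref.d_segments, min_d_match=5)
    assert len(got) == len(set(got))
    hits = oracle_d_positions(cdr3, ref.d_segments, 5)
    backed = {h[2] for h in hits}
    assert set(got) <= backed


def test_each_d_reported_at_most_once(ref):
    d3 = ref["TRDD3"].seq
    cdr3 = d3 + "AA" + d3
    assert find_d_segments(cdr3, ref.d_segments).count("TRDD3") == 1


# -- productivity ------------------------------------------------------------

def test_productivity_classification(ref):
    assert classify_productivity(CLONE1)  # expressed public junction
    assert not classify_productivity(CLONE1[:-1])  # frameshift
    assert not classify_productivity("TGATAAACG")  # in-frame stop


def test_unproductive_read_is_annotated_but_flagged(ref):
    rec = annotate_read("fs", build_read(ref, CLONE1[:-1]), ref)
    assert rec.fail_reason is None
    assert not rec.productive
    assert rec.cdr3_nt == CLONE1[:-1]


# -- whole-read concordance with simulator truth -----------------------------

def _concordance(ref, tmp_path, error_rate, n_reads, seed):
    """Fraction of simulated reads whose annotation matches the per-read
    truth: correct V and J call, the junction window cut at exactly the true
    coordinates (substitution errors inside the window stay in the window),
    and productivity classified from that window."""
    params = t.SimParams(
        seed=seed, n_samples=1, depth=n_reads, n_background_clones=150,
        error_rate=error_rate,
        dominant_clones=(t.DominantClone(name="A", freq=0.3, samples=(0,)),),
    )
    table = t.simulate_repertoire(params)
    t.emit_reads(table, tmp_path, ref)
    clones = {r.clone_id: r.rearrangement for r in table.samples["S01"]}
    truth_of = dict(
        line.split("\t")
        for line in (tmp_path / "S01.truth.tsv").read_text().splitlines()[1:]
    )
    ok = tot = 0
    fq = (tmp_path / "S01.fastq").read_text().splitlines()
    for rid_line, seq in zip(fq[0::4], fq[1::4]):
        rid = rid_line[1:]
        truth = clones[truth_of[rid]]
        v = ref[truth.v_id]
        start = v.anchor + 3 - ref.primers["Vd1" if truth.v_id == "TRDV1" else
                                          "Vd2" if truth.v_id == "TRDV2" else "Vd3"].offset
        expected_cdr3 = seq[start : start + len(truth.cdr3_nt)]
        ann = annotate_read(rid, seq, ref)
        tot += 1
        if (
            ann.v_call is not None and ann.v_call.segment_id == truth.v_id
            and ann.j_call is not None and ann.j_call.segment_id == truth.j_id
            and ann.cdr3_nt == expected_cdr3
            and ann.productive == classify_productivity(expected_cdr3)
        ):
            ok += 1
    return ok / tot


def test_error_free_reads_match_truth_exactly(ref, tmp_path):
    assert _concordance(ref, tmp_path, 0.0, 500, seed=3) == 1.0


def test_low_error_reads_concordant_above_98pct(ref, tmp_path):
    # errors may hit the anchors or segment cores; those reads may mis-extract
    assert _concordance(ref, tmp_path, 0.005, 500, seed=4) >= 0.98
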