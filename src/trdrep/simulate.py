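"""V(D)J rearrangement and study-scale repertoire simulation.

No delta-chain sequencing data from encephalitic brain tissue are publicly
deposited, so this module is a first-class generative stand-in: it produces
TRD rearrangements with junctional diversity (geometric exonucleolytic
trimming per junction end, Poisson-length uniform N-additions), multi-sample
repertoires with implanted dominant and public clones (public clones may be
encoded by several distinct nucleotide rearrangements — convergent
recombination), amplicon reads with substitution errors, capillary-
electrophoresis-style peak tables, and flow-cytometry subset tables shaped
like a per-sample BIL/PBMC summary.

Default parameters encode the study conditions this package analyses:
14 brain samples, ~2000 background clonotypes per sample on a power-law tail,
12 dominant clones per sample summing to 79 % of reads (three of them public
across all samples, carrying the recurrent delta-1 CDR3 peptides), and
100,000 reads per sample.

Reproducibility: one integer seed drives everything.  Independent streams are
derived as ``SeedSequence([seed, stage, index])`` where stage is 0 for shared
(public-clone) construction, 1 for per-sample repertoires, 2 for read
emission, 3 for peak tables, and 4 for flow tables.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from ._seq import CODON_TABLE, translate_nt
from .annotate import find_d_segments
from .errors import ParameterError, SimulationError
from .germline import CHAIN_OF_V, GermlineReference, default_reference
from .primers import PUBLIC_DELTA1_CDR3_PRIMERS

_NT = "ACGT"

#: deepest J-head trim the generator emits (see simulate_rearrangement)
MAX_J_TRIM = 8

#: codons per amino acid, for reverse translation of requested CDR3 peptides
_CODONS_OF: dict[str, list[str]] = {}
for _codon, _aa in CODON_TABLE.items():
    _CODONS_OF.setdefault(_aa, []).append(_codon)


def stream_rng(seed: int, stage: int, index: int = 0) -> np.random.Generator:
    """Documented stream-splitting scheme (see module docstring)."""
    return np.random.default_rng(np.random.SeedSequence([seed, stage, index]))


# ---------------------------------------------------------------------------
# Parameter containers
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DominantClone:
    """One implanted dominant clone.

    ``samples`` lists the 0-based sample indices carrying the clone; ``None``
    means all samples (a public clone).  ``cdr3_aa=None`` requests a random
    junction.  ``n_encodings > 1`` asks for that many distinct nucleotide
    encodings of the same peptide (convergent recombination); their within-
    clone proportions are ``encoding_weights`` (default 0.7, 0.3, ...).
    """

    name: str
    freq: float
    samples: tuple[int, ...] | None = None
    cdr3_aa: str | None = None
    cdr3_nt: str | None = None
    n_encodings: int = 1
    encoding_weights: tuple[float, ...] | None = None
    v_id: str = "TRDV1"
    j_id: str = "TRDJ1"

    def weights(self) -> np.ndarray:
        if self.encoding_weights is not None:
            w = np.asarray(self.encoding_weights, dtype=float)
        else:
            w = 0.7 ** np.arange(self.n_encodings)
        if len(w) != self.n_encodings or (w <= 0).any():
            raise ParameterError(f"clone {self.name}: bad encoding weights")
        return w / w.sum()


def default_dominant_clones(n_samples: int) -> tuple[DominantClone, ...]:
    """Study-shaped implantation: 3 public clones (the recurrent delta-1 CDR3
    peptides, two nucleotide encodings each) plus 9 private dominants per
    sample; per-sample dominant mass 79 % across 12 clones."""
    public_aa = sorted(PUBLIC_DELTA1_CDR3_PRIMERS)
    public_freqs = (0.08, 0.06, 0.05)
    clones = [
        DominantClone(
            name=f"PUB{i}",
            freq=f,
            samples=None,
            cdr3_aa=aa,
            cdr3_nt=PUBLIC_DELTA1_CDR3_PRIMERS[aa],
            n_encodings=2,
        )
        for i, (aa, f) in enumerate(zip(public_aa, public_freqs))
    ]
    private_freqs = (0.10, 0.09, 0.08, 0.07, 0.065, 0.06, 0.05, 0.045, 0.04)
    for s in range(n_samples):
        for k, f in enumerate(private_freqs):
            clones.append(DominantClone(name=f"S{s:02d}PRIV{k}", freq=f, samples=(s,)))
    return tuple(clones)


@dataclass
class SimParams:
    """Repertoire simulation parameters (defaults = study conditions)."""

    seed: int = 0
    n_samples: int = 14
    v_weights: dict[str, float] = field(
        default_factory=lambda: {"TRDV1": 0.90, "TRDV2": 0.05, "TRDV3": 0.05}
    )
    d_count_dist: tuple[float, ...] = (0.1, 0.6, 0.2, 0.1)
    trim_geom_p: float = 0.25
    n_ins_lambda: float = 4.0
    clone_tail_alpha: float = 3.0
    n_background_clones: int = 2000
    dominant_clones: tuple[DominantClone, ...] | None = None
    depth: int = 100_000
    error_rate: float = 0.0
    productive_only: bool = True
    min_d_match: int = 5
    peak_noise_sigma: float = 0.1
    read_qual: str = "I"

    def __post_init__(self) -> None:
        if self.dominant_clones is None:
            self.dominant_clones = default_dominant_clones(self.n_samples)
        if abs(sum(self.v_weights.values()) - 1.0) > 1e-9 or min(self.v_weights.values()) < 0:
            raise ParameterError("v_weights must be a probability distribution")
        if abs(sum(self.d_count_dist) - 1.0) > 1e-9 or min(self.d_count_dist) < 0:
            raise ParameterError("d_count_dist must be a probability distribution")
        if not (0.0 < self.trim_geom_p <= 1.0):
            raise ParameterError("trim_geom_p must be in (0, 1]")
        if self.n_ins_lambda < 0 or not (0.0 <= self.error_rate < 1.0):
            raise ParameterError("bad n_ins_lambda / error_rate")
        if self.clone_tail_alpha <= 1.0:
            raise ParameterError("clone_tail_alpha must exceed 1")
        if self.depth < 1:
            raise ParameterError("depth must be >= 1")
        for s in range(self.n_samples):
            tot = sum(c.freq for c in self.dominant_clones if c.samples is None or s in c.samples)
            if tot >= 1.0:
                raise ParameterError(f"dominant clone frequencies sum to {tot:.3f} >= 1 in sample {s}")

    def dominant_in_sample(self, s: int) -> list[DominantClone]:
        return [c for c in self.dominant_clones if c.samples is None or s in c.samples]


# ---------------------------------------------------------------------------
# Rearrangement model
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TrueRearrangement:
    """Ground truth for one simulated rearrangement.

    ``d_ids`` are the D segments identifiable in the junction under the same
    substring rule the annotator uses (a retained run of >= ``min_d_match``
    nt); ``d_used`` records which segments the generative process actually
    recombined, which can differ when trimming leaves too little evidence or
    a germline V-tail suffix mimics a D.
    """

    v_id: str
    d_ids: tuple[str, ...]
    j_id: str
    v_trim: int
    d_trims: tuple[tuple[int, int], ...]
    j_trim: int
    inserts: tuple[str, ...]
    d_used: tuple[str, ...]
    transcript_nt: str
    cdr3_nt: str
    cdr3_aa: str | None
    productive: bool

    def truth_key(self) -> tuple[str, str, tuple[str, ...], str] | None:
        """Clonotype key this rearrangement maps to (productive only)."""
        if not self.productive or not self.cdr3_aa:
            return None
        return (self.v_id, self.cdr3_aa[:4], self.d_ids, self.j_id)


def _geom_trim(rng: np.random.Generator, p: float) -> int:
    return int(rng.geometric(p) - 1)  # support starts at 0


def _geom_trim_capped(rng: np.random.Generator, p: float, cap: int) -> int:
    """Geometric trim, resampled until feasible.

    Resampling only the offending trim (rather than the whole rearrangement)
    keeps segment-usage statistics at their configured distributions: a
    whole-draw rejection would select against rearrangements with more
    trimmable junction ends.
    """
    for _ in range(1000):
        trim = _geom_trim(rng, p)
        if trim <= cap:
            return trim
    raise SimulationError("1000 consecutive infeasible trim draws")


def _assemble(
    ref: GermlineReference,
    v_id: str,
    j_id: str,
    cdr3_nt: str,
    v_trim: int,
    j_trim: int,
    d_used: Sequence[str],
    d_trims: Sequence[tuple[int, int]],
    inserts: Sequence[str],
    min_d_match: int,
) -> TrueRearrangement:
    v, j = ref[v_id], ref[j_id]
    transcript = v.seq[: v.anchor + 3] + cdr3_nt + j.post_anchor + ref.c_segment.seq
    if len(cdr3_nt) % 3 == 0:
        cdr3_aa = translate_nt(cdr3_nt)
        productive = "*" not in cdr3_aa
    else:
        cdr3_aa, productive = None, False
    return TrueRearrangement(
        v_id=v_id,
        d_ids=tuple(find_d_segments(cdr3_nt, ref.d_segments, min_d_match)),
        j_id=j_id,
        v_trim=v_trim,
        d_trims=tuple(d_trims),
        j_trim=j_trim,
        inserts=tuple(inserts),
        d_used=tuple(d_used),
        transcript_nt=transcript,
        cdr3_nt=cdr3_nt,
        cdr3_aa=cdr3_aa,
        productive=productive,
    )


def simulate_rearrangement(
    params: SimParams,
    rng: np.random.Generator,
    ref: GermlineReference | None = None,
    v_id: str | None = None,
    j_id: str | None = None,
) -> TrueRearrangement:
    """Draw one rearrangement; resamples internally on trimming exhaustion
    (and on unproductive junctions when ``productive_only``)."""
    ref = ref or default_reference()
    v_ids = sorted(params.v_weights)
    v_probs = np.array([params.v_weights[k] for k in v_ids])
    j_ids = [s.id for s in ref.j_segments]
    d_segs = ref.d_segments

    for _ in range(1000):
        vi = v_id or v_ids[rng.choice(len(v_ids), p=v_probs)]
        ji = j_id or j_ids[rng.integers(len(j_ids))]
        v, j = ref[vi], ref[ji]
        d_count = min(int(rng.choice(len(params.d_count_dist), p=np.asarray(params.d_count_dist))), len(d_segs))
        d_idx = sorted(rng.choice(len(d_segs), size=d_count, replace=False))
        d_used = [d_segs[i].id for i in d_idx]  # genomic order

        v_avail, j_avail = len(v.post_anchor), len(j.pre_anchor)
        v_trim = _geom_trim_capped(rng, params.trim_geom_p, v_avail)
        # J trims beyond MAX_J_TRIM would erase the germline evidence that
        # anchors the J call; they are vanishingly rare in expressed TRD
        # junctions and are resampled like exhausted segments.
        j_trim = _geom_trim_capped(rng, params.trim_geom_p, min(j_avail, MAX_J_TRIM))
        d_trims, d_parts = [], []
        for di in d_idx:
            dseq = d_segs[di].seq
            while True:
                lt = _geom_trim(rng, params.trim_geom_p)
                rt = _geom_trim(rng, params.trim_geom_p)
                if lt + rt <= len(dseq):
                    break
            d_trims.append((lt, rt))
            d_parts.append(dseq[lt : len(dseq) - rt])
        inserts = [
            "".join(_NT[b] for b in rng.integers(4, size=int(rng.poisson(params.n_ins_lambda))))
            for _ in range(d_count + 1)
        ]
        middle = inserts[0]
        for part, ins in zip(d_parts, inserts[1:]):
            middle += part + ins
        cdr3 = v.post_anchor[: v_avail - v_trim] + middle + j.pre_anchor[j_trim:]
        rearr = _assemble(ref, vi, ji, cdr3, v_trim, j_trim, d_used, d_trims, inserts, params.min_d_match)
        if params.productive_only and not rearr.productive:
            continue
        return rearr
    raise SimulationError("1000 consecutive rejected rearrangement draws")


def rearrangement_from_cdr3(
    ref: GermlineReference,
    cdr3_nt: str,
    v_id: str = "TRDV1",
    j_id: str = "TRDJ1",
    min_d_match: int = 5,
) -> TrueRearrangement:
    """Build the ground-truth record for an explicitly specified junction.

    Trim lengths are inferred from the longest germline-matching V prefix and
    J suffix of the junction; everything between counts as junction-derived.
    """
    v, j = ref[v_id], ref[j_id]
    vt = v.post_anchor
    keep_v = 0
    while keep_v < min(len(vt), len(cdr3_nt)) and cdr3_nt[keep_v] == vt[keep_v]:
        keep_v += 1
    jh = j.pre_anchor
    keep_j = 0
    while (
        keep_j < min(len(jh), len(cdr3_nt) - keep_v)
        and cdr3_nt[len(cdr3_nt) - 1 - keep_j] == jh[len(jh) - 1 - keep_j]
    ):
        keep_j += 1
    middle = cdr3_nt[keep_v : len(cdr3_nt) - keep_j]
    return _assemble(
        ref, v_id, j_id, cdr3_nt,
        v_trim=len(vt) - keep_v, j_trim=len(jh) - keep_j,
        d_used=(), d_trims=(), inserts=(middle,), min_d_match=min_d_match,
    )


def _reverse_translate(aa: str, rng: np.random.Generator) -> str:
    return "".join(_CODONS_OF[a][rng.integers(len(_CODONS_OF[a]))] for a in aa)


def synonymous_variants(
    cdr3_nt: str,
    n_variants: int,
    rng: np.random.Generator,
    ref: GermlineReference,
    min_d_match: int = 5,
) -> list[str]:
    """Distinct nucleotide encodings of the same peptide (convergent
    recombination), preserving the D-segment content of the junction so that
    all encodings fall in the same clonotype."""
    if len(cdr3_nt) % 3 != 0:
        raise ParameterError("synonymous variants need an in-frame junction")
    base_d = find_d_segments(cdr3_nt, ref.d_segments, min_d_match)
    out = [cdr3_nt]
    for _ in range(500):
        if len(out) >= n_variants:
            break
        var = list(out[0])
        ci = int(rng.integers(len(cdr3_nt) // 3))
        codon = out[0][3 * ci : 3 * ci + 3]
        alts = [c for c in _CODONS_OF[CODON_TABLE[codon]] if c != codon]
        if not alts:
            continue
        var[3 * ci : 3 * ci + 3] = alts[rng.integers(len(alts))]
        cand = "".join(var)
        if cand in out:
            continue
        if find_d_segments(cand, ref.d_segments, min_d_match) != base_d:
            continue
        out.append(cand)
    if len(out) < n_variants:
        raise SimulationError(f"could not generate {n_variants} synonymous encodings")
    return out


# ---------------------------------------------------------------------------
# Repertoire assembly
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CloneRecord:
    clone_id: str  # e.g. "PUB0.e1", "S03PRIV2", "S03.B0417"
    rearrangement: TrueRearrangement
    frequency: float
    read_count: int
    dominant: bool


@dataclass
class CloneTable:
    """Ground-truth repertoire: per sample, clones with frequencies/counts."""

    samples: dict[str, list[CloneRecord]]
    params: SimParams

    @property
    def sample_ids(self) -> list[str]:
        return list(self.samples)

    def check(self) -> None:
        for sid, recs in self.samples.items():
            tot_f = sum(r.frequency for r in recs)
            tot_n = sum(r.read_count for r in recs)
            if abs(tot_f - 1.0) > 1e-9:
                raise SimulationError(f"{sid}: frequencies sum to {tot_f}")
            if tot_n != self.params.depth:
                raise SimulationError(f"{sid}: read counts sum to {tot_n}")


def sample_name(i: int) -> str:
    return f"S{i + 1:02d}"


def _build_dominant_rearrangements(
    params: SimParams, ref: GermlineReference
) -> dict[str, list[TrueRearrangement]]:
    """One encoding list per dominant clone; shared clones use the shared
    stream so every carrying sample sees identical encodings."""
    rng = stream_rng(params.seed, 0)
    out: dict[str, list[TrueRearrangement]] = {}
    for clone in params.dominant_clones:
        if clone.cdr3_nt is not None:
            base = clone.cdr3_nt
        elif clone.cdr3_aa is not None:
            base = _reverse_translate(clone.cdr3_aa, rng)
        else:
            base = None
        if base is not None:
            if clone.cdr3_aa is not None and translate_nt(base) != clone.cdr3_aa:
                raise ParameterError(f"clone {clone.name}: cdr3_nt does not encode cdr3_aa")
            encodings = synonymous_variants(base, clone.n_encodings, rng, ref, params.min_d_match)
            out[clone.name] = [
                rearrangement_from_cdr3(ref, nt, clone.v_id, clone.j_id, params.min_d_match)
                for nt in encodings
            ]
        else:
            # random junction; encodings are synonymous variants of one draw
            rearr = simulate_rearrangement(params, rng, ref, clone.v_id, clone.j_id)
            encodings = synonymous_variants(
                rearr.cdr3_nt, clone.n_encodings, rng, ref, params.min_d_match
            )
            out[clone.name] = [rearr] + [
                rearrangement_from_cdr3(ref, nt, clone.v_id, clone.j_id, params.min_d_match)
                for nt in encodings[1:]
            ]
    return out


def simulate_repertoire(params: SimParams, ref: GermlineReference | None = None) -> CloneTable:
    """Simulate the full multi-sample repertoire with implanted clones."""
    ref = ref or default_reference()
    dominant = _build_dominant_rearrangements(params, ref)
    # distinct truth keys among dominants (re-derive random private clones on collision)
    samples: dict[str, list[CloneRecord]] = {}
    for s in range(params.n_samples):
        rng = stream_rng(params.seed, 1, s)
        sid = sample_name(s)
        recs: list[CloneRecord] = []
        keys_seen: set = set()
        for clone in params.dominant_in_sample(s):
            rearrs = dominant[clone.name]
            key = rearrs[0].truth_key()
            if key in keys_seen and clone.samples is not None and clone.cdr3_aa is None:
                for _ in range(50):  # private clone colliding with an earlier key
                    rearr = simulate_rearrangement(params, rng, ref, clone.v_id, clone.j_id)
                    if rearr.truth_key() not in keys_seen:
                        rearrs = [rearr]
                        key = rearr.truth_key()
                        break
                else:
                    raise SimulationError(f"cannot find distinct key for {clone.name}")
                dominant[clone.name] = rearrs
            keys_seen.add(key)
            for e, (rearr, w) in enumerate(zip(rearrs, clone.weights())):
                recs.append(
                    CloneRecord(f"{clone.name}.e{e}", rearr, clone.freq * float(w), 0, True)
                )
        dom_mass = sum(r.frequency for r in recs)
        n_bg = params.n_background_clones
        if n_bg > 0:
            slope = -1.0 / (params.clone_tail_alpha - 1.0)
            w = np.arange(1, n_bg + 1, dtype=float) ** slope
            w *= (1.0 - dom_mass) / w.sum()
            for i in range(n_bg):
                rearr = simulate_rearrangement(params, rng, ref)
                recs.append(CloneRecord(f"{sid}.B{i:05d}", rearr, float(w[i]), 0, False))
        freqs = np.array([r.frequency for r in recs])
        freqs = freqs / freqs.sum()  # guard rounding
        counts = rng.multinomial(params.depth, freqs)
        samples[sid] = [
            replace(r, frequency=float(f), read_count=int(c))
            for r, f, c in zip(recs, freqs, counts)
        ]
    table = CloneTable(samples, params)
    table.check()
    return table


# ---------------------------------------------------------------------------
# Read emission
# ---------------------------------------------------------------------------

def amplicon_nt(rearr: TrueRearrangement, ref: GermlineReference) -> str:
    """Second-round amplicon: chain forward primer 5' end through the labelled
    constant-region reverse primer site, inclusive of both footprints.

    Amplicons here (~180-210 bp for delta-1) fit within one 250 bp read, so
    reads are emitted pre-merged rather than as overlapping pairs.
    """
    from .spectratype import amplicon_bounds  # local import avoids a cycle

    start, end = amplicon_bounds(rearr.transcript_nt, ref, CHAIN_OF_V[rearr.v_id])
    return rearr.transcript_nt[start:end]


def _mutate(seq: str, n_err: int, rng: np.random.Generator) -> str:
    pos = rng.choice(len(seq), size=n_err, replace=False)
    out = list(seq)
    for p in pos:
        choices = [b for b in _NT if b != out[p]]
        out[p] = choices[rng.integers(3)]
    return "".join(out)


def read_counter(
    clone_table: CloneTable,
    sample_id: str,
    ref: GermlineReference | None = None,
    rng: np.random.Generator | None = None,
) -> Counter[str]:
    """Multiset of read sequences for one sample (deduplicated).

    Substitution errors are applied by binomial thinning: the number of
    error-free copies of each amplicon is Binomial(k, (1-e)^L) and each
    remaining read receives a conditional-positive Binomial(L, e) error count.
    """
    params = clone_table.params
    ref = ref or default_reference()
    if rng is None:
        rng = stream_rng(params.seed, 2, clone_table.sample_ids.index(sample_id))
    counter: Counter[str] = Counter()
    for rec in clone_table.samples[sample_id]:
        if rec.read_count == 0:
            continue
        amp = amplicon_nt(rec.rearrangement, ref)
        if params.error_rate == 0.0:
            counter[amp] += rec.read_count
            continue
        L = len(amp)
        p_clean = (1.0 - params.error_rate) ** L
        n_clean = int(rng.binomial(rec.read_count, p_clean))
        if n_clean:
            counter[amp] += n_clean
        for _ in range(rec.read_count - n_clean):
            n_err = 0
            while n_err == 0:
                n_err = int(rng.binomial(L, params.error_rate))
            counter[_mutate(amp, n_err, rng)] += 1
    return counter


def emit_reads(
    clone_table: CloneTable,
    outdir: str | Path,
    ref: GermlineReference | None = None,
) -> dict[str, Path]:
    """Write per-sample FASTQ (Sanger Phred+33, constant quality) plus a truth
    TSV mapping read id -> clone id.  Returns the written paths."""
    params = clone_table.params
    ref = ref or default_reference()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    for si, sid in enumerate(clone_table.sample_ids):
        rng = stream_rng(params.seed, 2, si)
        fq = outdir / f"{sid}.fastq"
        truth = outdir / f"{sid}.truth.tsv"
        with open(fq, "w") as fh, open(truth, "w") as th:
            th.write("read_id\tclone_id\n")
            ridx = 0
            for rec in clone_table.samples[sid]:
                if rec.read_count == 0:
                    continue
                amp = amplicon_nt(rec.rearrangement, ref)
                L = len(amp)
                for _ in range(rec.read_count):
                    seq = amp
                    if params.error_rate > 0.0:
                        n_err = int(rng.binomial(L, params.error_rate))
                        if n_err:
                            seq = _mutate(amp, n_err, rng)
                    rid = f"{sid}.r{ridx:07d}"
                    fh.write(f"@{rid}\n{seq}\n+\n{params.read_qual * len(seq)}\n")
                    th.write(f"{rid}\t{rec.clone_id}\n")
                    ridx += 1
        paths[sid] = fq
    return paths


# ---------------------------------------------------------------------------
# Peak tables (in-silico capillary electrophoresis)
# ---------------------------------------------------------------------------

def simulate_peak_table(
    clone_table: CloneTable,
    ref: GermlineReference | None = None,
    chain: str | None = None,
    noise_sigma: float | None = None,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Peak table (sample, chain, fragment_bp, area) emulating sizing-software
    exports: area proportional to summed clone frequency per fragment length,
    times multiplicative log-normal noise."""
    from .spectratype import fragment_length

    params = clone_table.params
    ref = ref or default_reference()
    sigma = params.peak_noise_sigma if noise_sigma is None else noise_sigma
    if rng is None:
        rng = stream_rng(params.seed, 3)
    rows = []
    for sid, recs in clone_table.samples.items():
        agg: dict[tuple[str, int], float] = {}
        for rec in recs:
            ch = CHAIN_OF_V[rec.rearrangement.v_id]
            if chain is not None and ch != chain:
                continue
            bp = fragment_length(rec.rearrangement, ref)
            agg[(ch, bp)] = agg.get((ch, bp), 0.0) + rec.frequency
        for (ch, bp), freq in sorted(agg.items()):
            noise = math.exp(rng.normal(0.0, sigma)) if sigma > 0 else 1.0
            rows.append({"sample": sid, "chain": ch, "fragment_bp": bp, "area": 1e4 * freq * noise})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Flow-cytometry subset tables
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CompartmentTargets:
    """Target distributions for one compartment (percentages of gated CD3+;
    CD69 fields are percentages of the respective subset)."""

    gd_mean: float
    gd_sd: float
    gd_lo: float
    gd_hi: float
    cd4_frac_mean: float
    cd4_frac_sd: float
    cd4_frac_lo: float
    cd4_frac_hi: float
    cd69_ab_mean: float
    cd69_ab_sd: float
    cd69_ab_lo: float
    cd69_ab_hi: float
    cd69_gd_mean: float
    cd69_gd_sd: float
    cd69_gd_lo: float
    cd69_gd_hi: float
    cd69_rho: float
    other_mean: float = 2.0  # CD3+ cells neither ab nor gd
    other_sd: float = 1.0
    other_lo: float = 0.0
    other_hi: float = 5.0

    def __post_init__(self) -> None:
        for v in (self.gd_mean, self.cd69_ab_mean, self.cd69_gd_mean):
            if not (0.0 <= v <= 100.0):
                raise ParameterError("flow targets must be percentages in [0, 100]")
        if not (-1.0 <= self.cd69_rho <= 1.0):
            raise ParameterError("cd69_rho must be a correlation")


@dataclass(frozen=True)
class FlowParams:
    """Flow-table generator settings (defaults emulate the study cohort:
    brain infiltrates enriched for gd T cells relative to blood, CD8-dominant
    ab infiltrates, and strongly co-varying CD69 activation)."""

    n_samples: int = 20
    n_cd69: int = 14  # CD69 staining available for a subset of samples
    noise: float = 1.0  # 0 collapses every sample onto the targets
    bil: CompartmentTargets = field(
        default_factory=lambda: CompartmentTargets(
            gd_mean=34.0, gd_sd=12.0, gd_lo=10.0, gd_hi=70.0,
            cd4_frac_mean=0.26, cd4_frac_sd=0.10, cd4_frac_lo=0.05, cd4_frac_hi=0.60,
            cd69_ab_mean=40.5, cd69_ab_sd=20.0, cd69_ab_lo=13.0, cd69_ab_hi=91.0,
            cd69_gd_mean=46.2, cd69_gd_sd=21.0, cd69_gd_lo=14.0, cd69_gd_hi=99.0,
            cd69_rho=0.96,
        )
    )
    pbmc: CompartmentTargets = field(
        default_factory=lambda: CompartmentTargets(
            gd_mean=11.05, gd_sd=6.0, gd_lo=2.4, gd_hi=27.0,
            cd4_frac_mean=0.60, cd4_frac_sd=0.10, cd4_frac_lo=0.30, cd4_frac_hi=0.85,
            cd69_ab_mean=8.0, cd69_ab_sd=4.0, cd69_ab_lo=1.0, cd69_ab_hi=25.0,
            cd69_gd_mean=10.0, cd69_gd_sd=5.0, cd69_gd_lo=1.0, cd69_gd_hi=30.0,
            cd69_rho=0.30,
        )
    )


def _truncnorm(
    rng: np.random.Generator, n: int, mean: float, sd: float, lo: float, hi: float, noise: float
) -> np.ndarray:
    s = sd * noise
    if s == 0:
        return np.full(n, mean)
    a, b = (lo - mean) / s, (hi - mean) / s
    return stats.truncnorm.rvs(a, b, loc=mean, scale=s, size=n, random_state=rng)


def _truncnorm_pair(
    rng: np.random.Generator,
    n: int,
    t: CompartmentTargets,
    noise: float,
) -> tuple[np.ndarray, np.ndarray]:
    """Correlated CD69 pair via a Gaussian copula with truncated-normal
    marginals."""
    if t.cd69_ab_sd * noise == 0 or t.cd69_gd_sd * noise == 0:
        return np.full(n, t.cd69_ab_mean), np.full(n, t.cd69_gd_mean)
    z1 = rng.standard_normal(n)
    z2 = t.cd69_rho * z1 + math.sqrt(1.0 - t.cd69_rho**2) * rng.standard_normal(n)
    u1, u2 = stats.norm.cdf(z1), stats.norm.cdf(z2)

    def marginal(u, mean, sd, lo, hi):
        s = sd * noise
        a, b = (lo - mean) / s, (hi - mean) / s
        return stats.truncnorm.ppf(u, a, b, loc=mean, scale=s)

    return (
        marginal(u1, t.cd69_ab_mean, t.cd69_ab_sd, t.cd69_ab_lo, t.cd69_ab_hi),
        marginal(u2, t.cd69_gd_mean, t.cd69_gd_sd, t.cd69_gd_lo, t.cd69_gd_hi),
    )


def simulate_flow_table(
    params: FlowParams = FlowParams(),
    seed: int = 0,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Per-sample BIL/PBMC CD3+ subset table.

    Columns: sample, compartment, pct_ab, pct_gd, pct_cd4_ab, pct_cd8_ab,
    pct_cd69_ab, pct_cd69_gd.  CD69 fields are NaN for samples beyond
    ``n_cd69`` (emulating markers measured on a cohort subset).
    """
    if rng is None:
        rng = stream_rng(seed, 4)
    n = params.n_samples
    rows = []
    for comp, t in (("BIL", params.bil), ("PBMC", params.pbmc)):
        gd = _truncnorm(rng, n, t.gd_mean, t.gd_sd, t.gd_lo, t.gd_hi, params.noise)
        other = _truncnorm(rng, n, t.other_mean, t.other_sd, t.other_lo, t.other_hi, params.noise)
        ab = 100.0 - gd - other
        cd4f = _truncnorm(
            rng, n, t.cd4_frac_mean, t.cd4_frac_sd, t.cd4_frac_lo, t.cd4_frac_hi, params.noise
        )
        cd69_ab, cd69_gd = _truncnorm_pair(rng, n, t, params.noise)
        for i in range(n):
            has69 = i < params.n_cd69
            rows.append(
                {
                    "sample": sample_name(i),
                    "compartment": comp,
                    "pct_ab": ab[i],
                    "pct_gd": gd[i],
                    "pct_cd4_ab": ab[i] * cd4f[i],
                    "pct_cd8_ab": ab[i] * (0.97 - cd4f[i]),
                    "pct_cd69_ab": cd69_ab[i] if has69 else np.nan,
                    "pct_cd69_gd": cd69_gd[i] if has69 else np.nan,
                }
            )
    return pd.DataFrame(rows)
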