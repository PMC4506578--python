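"""Generative model: junctional statistics, clone structure, read emission,
peak and flow tables."""

import numpy as np
import pytest
from scipy import stats

import trdrep as t
from trdrep.errors import ParameterError
from trdrep.simulate import (
    CloneRecord,
    CloneTable,
    CompartmentTargets,
    DominantClone,
    FlowParams,
    SimParams,
    rearrangement_from_cdr3,
    amplicon_nt,
    read_counter,
    simulate_flow_table,
    simulate_peak_table,
    simulate_rearrangement,
    stream_rng,
    synonymous_variants,
)
from dataclasses import replace

from conftest import make_private_params


# -- single rearrangements ---------------------------------------------------

def test_no_diversity_limit_is_fully_determined(ref, rng):
    """With zero trimming/insertion and exactly one D, the junction is the
    exact germline concatenation."""
    params = SimParams(
        n_samples=1, trim_geom_p=1.0, n_ins_lambda=0.0, d_count_dist=(0.0, 1.0, 0.0, 0.0),
        dominant_clones=(), productive_only=False,
    )
    r = simulate_rearrangement(params, rng, ref)
    v, j = ref[r.v_id], ref[r.j_id]
    (d_id,) = r.d_used
    assert r.cdr3_nt == v.post_anchor + ref[d_id].seq + j.pre_anchor
    assert r.v_trim == 0 and r.j_trim == 0 and r.inserts == ("", "")


def test_same_seed_reproduces_rearrangement(ref):
    params = SimParams(n_samples=1, dominant_clones=())
    r1 = simulate_rearrangement(params, np.random.default_rng(42), ref)
    r2 = simulate_rearrangement(params, np.random.default_rng(42), ref)
    assert r1 == r2


def test_d_count_distribution_recovered(ref):
    """Empirical D-count frequencies over 10,000 draws within +/-0.02 of the
    target distribution (law of large numbers; chi-square sanity check)."""
    target = (0.1, 0.6, 0.2, 0.1)
    params = SimParams(
        n_samples=1, d_count_dist=target, dominant_clones=(), productive_only=False,
    )
    rng = np.random.default_rng(2024)
    counts = np.zeros(4)
    n = 10_000
    for _ in range(n):
        counts[len(simulate_rearrangement(params, rng, ref).d_used)] += 1
    emp = counts / n
    assert np.all(np.abs(emp - np.array(target)) <= 0.02)
    chi2 = ((counts - n * np.array(target)) ** 2 / (n * np.array(target))).sum()
    assert chi2 < stats.chi2.ppf(0.999, df=3)


def test_productive_only_draws_are_in_frame_and_stop_free():
    params = SimParams(n_samples=1, dominant_clones=(), productive_only=True)
    rng = np.random.default_rng(5)
    for _ in range(50):
        r = simulate_rearrangement(params, rng)
        assert r.productive and len(r.cdr3_nt) % 3 == 0 and "*" not in r.cdr3_aa


def test_truth_d_ids_are_substrings_of_the_junction(ref, rng):
    params = SimParams(n_samples=1, dominant_clones=(), productive_only=False)
    for _ in range(100):
        r = simulate_rearrangement(params, rng, ref)
        for d_id in r.d_ids:
            found = any(
                ref[d_id].seq[i:j] in r.cdr3_nt
                for i in range(len(ref[d_id].seq))
                for j in range(i + 5, len(ref[d_id].seq) + 1)
            )
            assert found


# -- repertoire structure ----------------------------------------------------

def test_dominant_frequencies_exceeding_one_rejected():
    clones = tuple(
        DominantClone(name=f"C{i}", freq=0.4, samples=(0,)) for i in range(3)
    )  # sums to 1.2
    with pytest.raises(ParameterError):
        SimParams(n_samples=1, dominant_clones=clones)


def test_public_clone_present_in_every_sample(small_study):
    aa = sorted(t.PUBLIC_DELTA1_CDR3_PRIMERS)[0]
    for recs in small_study.clone_table.samples.values():
        assert any(r.rearrangement.cdr3_aa == aa for r in recs)


def test_convergent_public_clone_has_two_distinct_encodings(small_study):
    aa = sorted(t.PUBLIC_DELTA1_CDR3_PRIMERS)[0]
    for recs in small_study.clone_table.samples.values():
        encodings = {r.rearrangement.cdr3_nt for r in recs if r.rearrangement.cdr3_aa == aa and r.dominant}
        assert len(encodings) >= 2


def test_frequencies_and_counts_conserved(small_study):
    small_study.clone_table.check()  # sums to 1 and to depth


def test_background_rank_frequency_follows_power_law(ref):
    """Configured tail: frequency ~ rank^(-1/(alpha-1)); the generative law is
    the oracle for the fitted slope."""
    alpha = 2.0
    params = SimParams(
        seed=9, n_samples=1, depth=1000, n_background_clones=5000,
        clone_tail_alpha=alpha, dominant_clones=(),
    )
    table = t.simulate_repertoire(params, ref)
    freqs = sorted((r.frequency for r in table.samples["S01"] if not r.dominant), reverse=True)
    ranks = np.arange(1, len(freqs) + 1)
    slope = stats.linregress(np.log(ranks), np.log(freqs)).slope
    assert abs(slope - (-1.0 / (alpha - 1.0))) <= 0.3


def test_multinomial_counts_sum_to_depth(ref):
    params = make_private_params(seed=3, n_samples=1, depth=100, n_background=0)
    table = t.simulate_repertoire(params, ref)
    assert sum(r.read_count for r in table.samples["S01"]) == 100


def test_repertoire_deterministic_under_seed(ref):
    p = make_private_params(seed=21, n_samples=2, depth=500, n_background=20)
    t1 = t.simulate_repertoire(p, ref)
    t2 = t.simulate_repertoire(p, ref)
    for sid in t1.sample_ids:
        assert [(r.clone_id, r.rearrangement.cdr3_nt, r.read_count) for r in t1.samples[sid]] == [
            (r.clone_id, r.rearrangement.cdr3_nt, r.read_count) for r in t2.samples[sid]
        ]


def test_synonymous_variants_preserve_peptide_and_d_content(ref, rng):
    nt = t.PUBLIC_DELTA1_CDR3_PRIMERS["ALGDSIPRRIAYTDKLI"]
    variants = synonymous_variants(nt, 3, rng, ref)
    from trdrep.annotate import find_d_segments

    base_d = find_d_segments(nt, ref.d_segments)
    assert len(set(variants)) == 3
    for v in variants:
        assert t.translate_nt(v) == "ALGDSIPRRIAYTDKLI"
        assert find_d_segments(v, ref.d_segments) == base_d


# -- read emission -----------------------------------------------------------

def test_error_free_reads_equal_amplicons(ref):
    params = make_private_params(seed=13, n_samples=1, depth=300, n_background=10)
    table = t.simulate_repertoire(params, ref)
    amps = {amplicon_nt(r.rearrangement, ref) for r in table.samples["S01"]}
    counter = read_counter(table, "S01", ref)
    assert set(counter) <= amps
    assert sum(counter.values()) == 300


def test_substitution_error_rate_matches_binomial(ref):
    """>= 100k sequenced bases at e=0.01: observed mismatches within 3 sigma
    of Binomial(n_bases, 0.01)."""
    clone = DominantClone(name="X", freq=0.999, samples=(0,), cdr3_aa="ALGDSIPRRIAYTDKLI",
                          cdr3_nt=t.PUBLIC_DELTA1_CDR3_PRIMERS["ALGDSIPRRIAYTDKLI"])
    params = SimParams(seed=17, n_samples=1, depth=600, n_background_clones=1,
                       error_rate=0.01, dominant_clones=(clone,))
    table = t.simulate_repertoire(params, ref)
    amp_of = {amplicon_nt(r.rearrangement, ref): r for r in table.samples["S01"]}
    counter = read_counter(table, "S01", ref)
    # attribute each read to the closest amplicon (errors are sparse)
    import edlib

    n_bases = mismatches = 0
    for seq, count in counter.items():
        best = min(amp_of, key=lambda a: edlib.align(seq, a)["editDistance"])
        d = sum(1 for x, y in zip(seq, best) if x != y)
        mismatches += d * count
        n_bases += len(seq) * count
    assert n_bases >= 100_000
    expect = n_bases * 0.01
    sigma = np.sqrt(n_bases * 0.01 * 0.99)
    assert abs(mismatches - expect) <= 3 * sigma


def test_fastq_and_truth_roundtrip(tmp_path, ref):
    params = make_private_params(seed=19, n_samples=1, depth=50, n_background=5)
    table = t.simulate_repertoire(params, ref)
    paths = t.emit_reads(table, tmp_path, ref)
    lines = paths["S01"].read_text().splitlines()
    assert len(lines) == 4 * 50
    truth = (tmp_path / "S01.truth.tsv").read_text().splitlines()
    assert truth[0] == "read_id\tclone_id"
    assert len(truth) == 51


# -- peak tables -------------------------------------------------------------

def _tiny_clone_table(ref, freqs, cdr3s, depth=100):
    params = make_private_params(n_samples=1, depth=depth, n_background=0)
    recs = [
        CloneRecord(f"C{i}", rearrangement_from_cdr3(ref, nt), f, int(round(f * depth)), True)
        for i, (f, nt) in enumerate(zip(freqs, cdr3s))
    ]
    return CloneTable({"S01": recs}, params)


def test_same_length_clones_aggregate_to_one_peak(ref, rng):
    nt = t.PUBLIC_DELTA1_CDR3_PRIMERS["ALGDSIPRRIAYTDKLI"]
    var = synonymous_variants(nt, 2, rng, ref)[1]
    table = _tiny_clone_table(ref, [0.3, 0.2, 0.5], [nt, var, nt[:-6] + nt[-3:]])
    peaks = simulate_peak_table(table, ref, noise_sigma=0.0)
    vd1 = peaks[peaks["chain"] == "Vd1"].set_index("fragment_bp")["area"]
    assert vd1.loc[183] == pytest.approx(0.5 * 1e4)  # two clones, same length
    assert vd1.loc[180] == pytest.approx(0.5 * 1e4)


def test_noise_free_areas_proportional_to_frequencies(ref):
    nt = t.PUBLIC_DELTA1_CDR3_PRIMERS["ALGGLGTGGYAYTDKLI"]
    table = _tiny_clone_table(ref, [0.7, 0.3], [nt, nt[:-9] + nt[-3:]])
    peaks = simulate_peak_table(table, ref, noise_sigma=0.0)
    areas = peaks.sort_values("fragment_bp")["area"].to_numpy()
    assert areas[0] / areas.sum() == pytest.approx(0.3)


def test_productive_only_fragments_form_3bp_ladder(small_study, ref):
    peaks = simulate_peak_table(small_study.clone_table, ref, noise_sigma=0.0)
    for chain, sub in peaks.groupby("chain"):
        assert len(set(sub["fragment_bp"] % 3)) == 1


# -- flow tables -------------------------------------------------------------

def test_zero_noise_collapses_onto_targets():
    fp = FlowParams(noise=0.0, n_samples=6, n_cd69=6)
    df = simulate_flow_table(fp, seed=1)
    bil = df[df["compartment"] == "BIL"]
    assert np.allclose(bil["pct_gd"], fp.bil.gd_mean)
    assert np.allclose(bil["pct_ab"], 100.0 - fp.bil.gd_mean - fp.bil.other_mean)
    assert np.allclose(bil["pct_cd69_ab"], fp.bil.cd69_ab_mean)


def test_bil_ratio_below_pbmc_ratio_by_construction():
    df = simulate_flow_table(FlowParams(), seed=3)
    from trdrep.flow import ratio_summary

    bil = ratio_summary(df, "pct_ab", "pct_gd", "BIL")
    pb = ratio_summary(df, "pct_ab", "pct_gd", "PBMC")
    assert bil.median < pb.median


def test_percentages_within_bounds_and_cd69_missing_pattern():
    fp = FlowParams(n_samples=10, n_cd69=6)
    df = simulate_flow_table(fp, seed=5)
    assert ((df["pct_ab"] >= 0) & (df["pct_ab"] <= 100)).all()
    assert (df["pct_ab"] + df["pct_gd"] <= 100).all()
    assert df["pct_cd69_ab"].isna().sum() == 2 * 4  # both compartments


def test_flow_targets_outside_range_rejected():
    with pytest.raises(ParameterError):
        CompartmentTargets(
            gd_mean=120.0, gd_sd=1.0, gd_lo=0, gd_hi=100,
            cd4_frac_mean=0.5, cd4_frac_sd=0.1, cd4_frac_lo=0, cd4_frac_hi=1,
            cd69_ab_mean=50, cd69_ab_sd=1, cd69_ab_lo=0, cd69_ab_hi=100,
            cd69_gd_mean=50, cd69_gd_sd=1, cd69_gd_lo=0, cd69_gd_hi=100,
            cd69_rho=0.5,
        )


def test_induced_cd69_correlation_recovered():
    """Latent rho=0.95, n=14: sample r within 0.15 in >= 90% of 200 cohorts
    (bivariate-copula oracle)."""
    base = FlowParams()
    fp = replace(base, bil=replace(base.bil, cd69_rho=0.95))
    hits = 0
    for s in range(200):
        df = simulate_flow_table(fp, seed=s)
        bil = df[df["compartment"] == "BIL"].dropna(subset=["pct_cd69_ab"])
        r = np.corrcoef(bil["pct_cd69_ab"], bil["pct_cd69_gd"])[0, 1]
        hits += abs(r - 0.95) <= 0.15
    assert hits >= 180


def test_stream_splitting_gives_independent_reproducible_streams():
    a = stream_rng(1, 1, 0).integers(1 << 30, size=5)
    b = stream_rng(1, 1, 1).integers(1 << 30, size=5)
    a2 = stream_rng(1, 1, 0).integers(1 << 30, size=5)
    assert np.array_equal(a, a2)
    assert not np.array_equal(a, b)
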