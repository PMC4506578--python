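"""Derive a clone-specific CDR3 primer and screen samples for the clone.

Ranks the nucleotide encodings of a public CDR3 peptide across samples,
builds the primer from the majority-top encoding, and screens each sample's
junction sequences for it — emulating a presence/absence PCR readout.
"""

import trdrep as t
from trdrep.primers import rank_cdr3_dna_variants, build_clone_primer, match_primer, sample_nt_sequences

study = t.run_study(t.SimParams(seed=3, n_samples=4, depth=20_000, n_background_clones=500))
tables = list(study.clonotypes.values())

aa = "ALGDSIPRRIAYTDKLI"
ranked = rank_cdr3_dna_variants(tables, aa)
print(f"{len(ranked)} DNA encodings of {aa}; top is rank-1 in {ranked['n_top'].iloc[0]} samples")

spec = build_clone_primer(ranked, aa)
print(f"primer: 5' {spec.primer_nt} 3'")

for table in tables:
    detected, count = match_primer(spec, sample_nt_sequences(table))
    print(f"  {table.sample_id}: {'present' if detected else 'absent'} ({count} supporting reads)")

# The derived primer is the most frequent encoding in the majority of samples
# and detects the clone in every sample that carries it.
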