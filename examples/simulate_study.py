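"""Simulate a small multi-sample TRD repertoire and inspect its structure.

Builds a 4-sample cohort with three public delta-1 clones implanted in every
sample plus per-sample private dominants, then prints the per-sample count of
clonotypes above 1% frequency and their summed mass — the oligoclonality
summary a repertoire study tabulates per specimen.
"""

import trdrep as t

params = t.SimParams(seed=7, n_samples=4, depth=20_000, n_background_clones=500)
study = t.run_study(params)

print("sample  clonotypes  n>1%  summed%")
for sid, table in study.clonotypes.items():
    _, n_dom, pct = t.dominant_clonotypes(table, threshold=0.01)
    print(f"{sid:6s}  {len(table.counts):10d}  {n_dom:4d}  {pct:6.1f}")

# n>1% ~ 12 and summed% ~ 79 reflect the implanted dominant-clone structure;
# the remaining ~21% of reads spread over hundreds of background clonotypes.
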