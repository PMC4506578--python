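"""Annotate a single amplicon read: V/J calls, CDR3, D content, productivity.

Constructs the amplicon of a known public delta-1 clone from the built-in
germline reference and pushes it through the annotator; the printed junction
should reproduce the clone's CDR3 exactly.
"""

import trdrep as t
from trdrep.simulate import amplicon_nt, rearrangement_from_cdr3

ref = t.default_reference()
aa = "ALGDSIPRRIAYTDKLI"
clone = rearrangement_from_cdr3(ref, t.PUBLIC_DELTA1_CDR3_PRIMERS[aa])
read = amplicon_nt(clone, ref)

rec = t.annotate_read("example", read, ref)
print(f"read length : {len(read)} bp (fragment size)")
print(f"V call      : {rec.v_call.segment_id} (score {rec.v_call.score:.0f})")
print(f"J call      : {rec.j_call.segment_id} (score {rec.j_call.score:.0f})")
print(f"D content   : {', '.join(rec.d_calls) or '-'}")
print(f"CDR3 nt     : {rec.cdr3_nt}")
print(f"CDR3 aa     : {rec.cdr3_aa}")
print(f"productive  : {rec.productive}")

# The CDR3 runs strictly between the conserved C104 and F118 anchor codons;
# residues 105-108 (here ALGD) plus the D and J identities define the
# clonotype this read belongs to.
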