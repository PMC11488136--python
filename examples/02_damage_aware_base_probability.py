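"""The damage-aware base probability, channel by channel.

An observed fragment base is explained by three chained channels: HKY
mutation over the branch distance t, terminal deamination (C->T near the
5' end, G->A near the 3' end), and sequencing error from the base quality.
The per-base probability marginalises over all 16 intermediate states.
"""

import branchmix as bm
from branchmix.graphalign import AlignedBase
from branchmix.likelihood import base_prob_aligned

model = bm.HkyModel(kappa=2.0)          # mitochondrial transition bias
profile = bm.default_damage_profile()   # ~30% terminal C->T / G->A, decaying

# a T observed at the very 5' end of a fragment where the reference has C
ab = AlignedBase(b="T", eps=0.001, event="mismatch", node=1, offset=0,
                 pos5=0, pos3=39)
for t in (0.0, 0.01, 0.05, 0.2):
    p = base_prob_aligned(model, profile, t, ab, bg="C")
    print(f"P(obs T | ref C, t={t:<5}) = {p:.4f}")
print("-> at t=0 the mismatch is explained almost entirely by deamination "
      f"(terminal rate {profile.rate_ct(0):.2f})")

# the same mismatch deep inside the fragment is much less plausible
ab_interior = AlignedBase("T", 0.001, "mismatch", 1, 0, pos5=20, pos3=19)
p0 = base_prob_aligned(model, profile, 0.0, ab_interior, bg="C")
print(f"P(obs T | ref C, t=0, interior) = {p0:.4f} "
      "(residual damage + sequencing error only)")

# a base on a graph node the evaluated path does not traverse
print(f"P(unsupported base | eps=0.001)  = {bm.base_prob_unsupported(0.001):.4f}")
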