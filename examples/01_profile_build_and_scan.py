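"""Build a family profile HMM, calibrate it, and score sequences.

A profile is estimated from a toy 3-member seed alignment of a 40-residue
domain, its E-value null is fitted on random background sequences, and
then a true (slightly diverged) family member is scored against a shuffled
decoy of itself.  The bit scores are log2-odds of the best local path
versus an i.i.d. background null; the E-values say how many hits that
strong one would expect by chance in a 50-sequence database.
"""

import numpy as np

from zfscan.formats_io import FamilyAlignment, PipelineConfig
from zfscan.profile_hmm import build_profile, calibrate, evalue, viterbi_score

rng = np.random.default_rng(0)
AA = list("ACDEFGHIKLMNPQRSTVWY")

consensus = "".join(rng.choice(AA, 40))
rows = tuple((f"seed{i}", consensus) for i in range(3))
hmm = build_profile(FamilyAlignment("DEMO", rows), PipelineConfig())
hmm = calibrate(hmm, n_shuffles=500, seed=0, length=100)

member = list(consensus)
for pos in rng.choice(40, size=6, replace=False):  # ~15% divergence
    member[pos] = AA[rng.integers(20)]
member = "".join(member)
decoy = "".join(rng.permutation(list(member)))

print(f"profile: {hmm.M} match states; null mu={hmm.calibration.mu:.2f} "
      f"lambda={hmm.calibration.lam:.3f}")
for name, seq in [("diverged member", member), ("shuffled decoy", decoy)]:
    full, envelopes, best = viterbi_score(hmm, seq)
    e = evalue(hmm, full, database_size=50)
    print(f"{name:16s} full={full:7.2f} bits  best_domain={best:7.2f}  "
          f"E={e:.3g}  envelopes={envelopes}")
print("\nA real member scores tens of bits above the calibrated null "
      "(E << 0.001); its own shuffle is indistinguishable from noise.")
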