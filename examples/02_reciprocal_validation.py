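"""Reciprocal master-list validation of candidate family members.

A candidate picked up by a profile scan is aligned against the whole
reference database (Smith-Waterman, BLOSUM62, affine gaps).  It is
accepted as a family member only if one of its top-3 reference hits is on
the family's master list - the list of reference-genome accessions known
to belong to that family.  A candidate whose best friends are another
family's genes is rejected, however good its profile score was.
"""

import numpy as np

from zfscan.formats_io import MasterList, PipelineConfig, SequenceRecord
from zfscan.local_align import rank_reference_hits, validate_candidate

rng = np.random.default_rng(1)
AA = list("ACDEFGHIKLMNPQRSTVWY")


def mutate(seq, n):
    out = list(seq)
    for pos in rng.choice(len(seq), size=n, replace=False):
        out[pos] = AA[rng.integers(20)]
    return "".join(out)


fam_a = "".join(rng.choice(AA, 60))
fam_b = "".join(rng.choice(AA, 60))
reference_db = [
    SequenceRecord("humA1", mutate(fam_a, 4), "ref"),
    SequenceRecord("flyA1", mutate(fam_a, 6), "ref"),
    SequenceRecord("wrmA1", mutate(fam_a, 7), "ref"),
    SequenceRecord("humB1", mutate(fam_b, 4), "ref"),
    SequenceRecord("flyB1", mutate(fam_b, 6), "ref"),
    SequenceRecord("wrmB1", mutate(fam_b, 7), "ref"),
]
master = MasterList({"FAMA": frozenset({"humA1", "flyA1", "wrmA1"}),
                     "FAMB": frozenset({"humB1", "flyB1", "wrmB1"})})
cfg = PipelineConfig()

candidate = SequenceRecord("sp9_gene12", mutate(fam_a, 10), "sp9")
print("top reference hits for", candidate.accession)
for rank, hit in enumerate(rank_reference_hits(candidate, reference_db, cfg), 1):
    print(f"  {rank}. {hit.subject:6s} score={hit.score:6.1f} identity={hit.identity:.2f}")

for fam in ("FAMA", "FAMB"):
    ok, support = validate_candidate(candidate, fam, reference_db, master, cfg)
    verdict = f"ACCEPTED via {support.subject}" if ok else "rejected"
    print(f"validation for {fam}: {verdict}")
print("\nThe candidate descends from family A, so only the FAMA search "
      "finds a master-list gene among its top hits.")
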