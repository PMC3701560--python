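"""Smith-Waterman local alignment and the focused reference-database search.

This is the reciprocal-validation arm of the pipeline: a candidate family
member is aligned against the complete reference database (exhaustively -
the database is three well-annotated proteomes, small enough that no
seeding heuristic is needed), and is accepted iff one of its top-ranked
subjects appears in the family's master list.

Scoring uses BLOSUM62 with affine gaps (defaults open 11, extend 1; a gap
of length g costs open + (g-1)*extend).  Traceback tie-breaks prefer
diagonal over up (gap in subject) over left (gap in query) so results are
deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np
from Bio.Align import substitution_matrices

from . import _kernels
from .formats_io import AMINO_ACIDS, MasterList, PipelineConfig, SequenceRecord
from .profile_hmm import encode

_ALPHABET21 = AMINO_ACIDS + "X"


@lru_cache(maxsize=8)
def load_matrix(name: str = "BLOSUM62") -> np.ndarray:
    """A 21x21 substitution matrix (20 AA + X) in this package's residue order."""
    try:
        m = substitution_matrices.load(name)
    except FileNotFoundError:
        raise ValueError(f"unknown substitution matrix {name!r}") from None
    out = np.zeros((21, 21))
    for i, a in enumerate(_ALPHABET21):
        for j, b in enumerate(_ALPHABET21):
            out[i, j] = m[a][b]
    return out


@dataclass(frozen=True)
class AlignmentHit:
    """One local alignment between a query and a subject sequence."""

    query: str
    subject: str
    score: float
    identity: float
    query_span: tuple[int, int]  # 1-based inclusive; (0, 0) for empty alignments
    subject_span: tuple[int, int]
    aligned_columns: int = 0

    def __post_init__(self) -> None:
        if self.score < 0:
            raise ValueError("negative local-alignment score")
        if not 0.0 <= self.identity <= 1.0:
            raise ValueError("identity outside [0, 1]")


def _residues(seq: SequenceRecord | str) -> str:
    return seq.residues if isinstance(seq, SequenceRecord) else seq


def _name(seq: SequenceRecord | str, default: str) -> str:
    return seq.accession if isinstance(seq, SequenceRecord) else default


def sw_align(
    query: SequenceRecord | str,
    subject: SequenceRecord | str,
    matrix_name: str = "BLOSUM62",
    gap_open: float = 11.0,
    gap_extend: float = 1.0,
) -> AlignmentHit:
    """Optimal affine-gap Smith-Waterman alignment of two sequences."""
    q = _residues(query)
    s = _residues(subject)
    if not q or not s:
        raise ValueError("cannot align empty sequences")
    sub = load_matrix(matrix_name)
    a = encode(q)
    b = encode(s)
    score, end_i, end_j, H, E, F = _kernels.sw_full(a, b, sub, gap_open, gap_extend)
    qname = _name(query, "query")
    sname = _name(subject, "subject")
    if score <= 0.0:
        return AlignmentHit(qname, sname, 0.0, 0.0, (0, 0), (0, 0), 0)

    # deterministic traceback: diagonal > up (gap in subject) > left
    i, j = end_i, end_j
    matches = 0
    columns = 0
    tol = 1e-9
    state = "H"
    while True:
        if state == "H":
            if i == 0 or j == 0 or H[i, j] <= 0.0:
                break
            h = H[i, j]
            if abs(H[i - 1, j - 1] + sub[a[i - 1], b[j - 1]] - h) < tol:
                columns += 1
                if a[i - 1] == b[j - 1]:
                    matches += 1
                i, j = i - 1, j - 1
            elif abs(E[i, j] - h) < tol:
                state = "E"
            else:
                state = "F"
        elif state == "E":  # vertical gap run: consumes query residues
            columns += 1
            opened = abs(H[i - 1, j] - gap_open - E[i, j]) < tol
            i -= 1
            state = "H" if opened else "E"
        else:  # horizontal gap run: consumes subject residues
            columns += 1
            opened = abs(H[i, j - 1] - gap_open - F[i, j]) < tol
            j -= 1
            state = "H" if opened else "F"
    qspan = (i + 1, end_i)
    sspan = (j + 1, end_j)
    identity = matches / columns if columns else 0.0
    return AlignmentHit(qname, sname, float(score), identity, qspan, sspan, columns)


def sw_score(
    query: SequenceRecord | str,
    subject: SequenceRecord | str,
    matrix_name: str = "BLOSUM62",
    gap_open: float = 11.0,
    gap_extend: float = 1.0,
) -> float:
    """Score-only Smith-Waterman (no traceback; faster for ranking)."""
    sub = load_matrix(matrix_name)
    return float(
        _kernels.sw_score(encode(_residues(query)), encode(_residues(subject)), sub, gap_open, gap_extend)
    )


def rank_reference_hits(
    query: SequenceRecord | str,
    reference_db: list[SequenceRecord],
    cfg: PipelineConfig | None = None,
) -> list[AlignmentHit]:
    """Rank all positive-scoring reference subjects, truncated to the top N.

    Subjects are ordered by score descending, ties broken by subject
    accession ascending; at most ``cfg.max_reference_hits`` are returned.
    """
    cfg = cfg or PipelineConfig()
    scored: list[tuple[float, str, SequenceRecord]] = []
    for ref in reference_db:
        s = sw_score(query, ref)
        if s > 0.0:
            scored.append((s, ref.accession, ref))
    scored.sort(key=lambda t: (-t[0], t[1]))
    return [sw_align(query, ref) for _, _, ref in scored[: cfg.max_reference_hits]]


def validate_candidate(
    candidate: SequenceRecord | str,
    family_id: str,
    reference_db: list[SequenceRecord],
    master: MasterList,
    cfg: PipelineConfig | None = None,
) -> tuple[bool, AlignmentHit | None]:
    """Reciprocal master-list validation of a candidate family member.

    Accepted iff any of the candidate's top reference hits carries an
    accession in the family's master list; the supporting hit is the
    highest-ranked such subject.
    """
    if family_id not in master:
        raise KeyError(f"family {family_id!r} not in master list")
    cfg = cfg or PipelineConfig()
    members = master[family_id]
    for hit in rank_reference_hits(candidate, reference_db, cfg):
        if hit.subject in members:
            return True, hit
    return False, None
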