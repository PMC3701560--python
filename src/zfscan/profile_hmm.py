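"""Simplified Plan-7-style profile HMMs: construction, Viterbi scoring,
Gumbel E-value calibration.

The model is a local-alignment profile with match, insert and delete
states per node.  Entry is uniform over match states, exit is uniform per
match state (total exit mass 1), and insert emissions are tied to the
background, so only match emissions and transitions carry information.
Scores are log2-odds (bits) of the best state path against an i.i.d.
background null over the same residues.  Bit scores from this model are
on their own scale and are not comparable to other software's scores;
statistical significance comes from per-profile Gumbel calibration on
background-sampled random sequences.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from . import _kernels
from .formats_io import AMINO_ACIDS, GAP, FamilyAlignment, PipelineConfig, SequenceRecord

_AA_INDEX = {a: i for i, a in enumerate(AMINO_ACIDS)}
_AA_INDEX["X"] = 20
#: Euler-Mascheroni constant, used by the method-of-moments Gumbel fit.
_EULER_GAMMA = 0.5772156649015329


class CalibrationError(RuntimeError):
    pass


def encode(residues: str) -> np.ndarray:
    """Encode residues as int codes 0..19 (alphabetical AA order), 20 = X."""
    try:
        return np.array([_AA_INDEX[c] for c in residues], dtype=np.int64)
    except KeyError as exc:
        raise ValueError(f"residue {exc.args[0]!r} outside amino-acid alphabet") from None


@dataclass(frozen=True)
class Calibration:
    mu: float
    lam: float
    n: int
    seed: int
    length: int


@dataclass
class ProfileHMM:
    """A calibratable profile HMM over the 20-letter amino-acid alphabet.

    Transition arrays are indexed by source node k (0-based): ``tMM[k]`` is
    M_k -> M_{k+1}, ``tMI[k]`` is M_k -> I_k, ``tMD[k]`` is M_k -> D_{k+1},
    ``tIM``/``tII`` leave I_k, ``tDM``/``tDD`` leave D_k.  Entries for
    transitions that would leave the model (k = M-1) are zero probability.
    """

    family_id: str
    clade_tag: str
    M: int
    match_emissions: np.ndarray  # (M, 20)
    insert_emissions: np.ndarray  # (20,), background-tied
    background: np.ndarray  # (20,)
    tMM: np.ndarray
    tMI: np.ndarray
    tMD: np.ndarray
    tIM: np.ndarray
    tII: np.ndarray
    tDM: np.ndarray
    tDD: np.ndarray
    entry: np.ndarray  # (M,)
    exit: np.ndarray  # (M,)
    #: source-alignment column index of each match state (for augmentation)
    match_cols: tuple[int, ...] | None = None
    calibration: Calibration | None = None
    _log_cache: dict = field(default_factory=dict, repr=False, compare=False)

    # -- log-space views used by the kernels ------------------------------
    def _logs(self):
        if "lo" not in self._log_cache:
            with np.errstate(divide="ignore"):
                lo = np.full((self.M, 21), 0.0)
                lo[:, :20] = np.log2(self.match_emissions) - np.log2(self.background)[None, :]
                c = {
                    "lo": lo,
                    "lentry": np.log2(self.entry),
                    "lexit": np.log2(self.exit),
                }
                for name in ("tMM", "tMI", "tMD", "tIM", "tII", "tDM", "tDD"):
                    c["l" + name] = np.log2(getattr(self, name))
            self._log_cache.update(c)
        return self._log_cache


def assign_match_columns(aln: FamilyAlignment, gap_threshold: float) -> tuple[bool, ...]:
    """Mark alignment columns as match columns.

    A column is a match column iff its gap fraction is strictly below
    ``gap_threshold`` (a column exactly at the threshold is an insert
    column).  An explicit RF mask on the alignment overrides the rule.
    """
    if aln.rf_mask is not None:
        mask = aln.rf_mask
    else:
        n = len(aln.rows)
        mask = tuple(
            sum(1 for _, g in aln.rows if g[j] == GAP) / n < gap_threshold
            for j in range(aln.width)
        )
    if not any(mask):
        raise ValueError(f"family {aln.family_id!r}: no match columns; profile would be empty")
    return mask


def _estimate_background(aln: FamilyAlignment) -> np.ndarray:
    """Amino-acid frequencies of the alignment's ungapped residues.

    Always smoothed with one pseudocount per residue so every letter has
    non-zero background probability (log-odds stay finite); with no
    countable residues this degenerates to the uniform 1/20.
    """
    counts = np.zeros(20)
    for _, gapped in aln.rows:
        for c in gapped:
            i = _AA_INDEX.get(c)
            if i is not None and i < 20:
                counts[i] += 1
    counts += 1.0
    return counts / counts.sum()


def build_profile(
    aln: FamilyAlignment, cfg: PipelineConfig | None = None, clade_tag: str = "general"
) -> ProfileHMM:
    """Estimate a profile HMM from a family alignment.

    Match emissions use Laplace pseudocounts, p(a) = (n_a + alpha) /
    (n + 20 * alpha); transitions are estimated from the observed
    column-to-column state paths with the same alpha spread over each
    state's outgoing fan.  Entry and exit are uniform over match states.
    """
    cfg = cfg or PipelineConfig()
    if len(aln.rows) < 2:
        raise ValueError(f"family {aln.family_id!r}: need >= 2 rows to build a profile")
    alpha = cfg.pseudocount_alpha
    mask = assign_match_columns(aln, cfg.match_column_gap_threshold)
    match_cols = [j for j, m in enumerate(mask) if m]
    M = len(match_cols)
    background = _estimate_background(aln)

    # --- match emissions
    em = np.zeros((M, 20))
    for k, j in enumerate(match_cols):
        counts = np.zeros(20)
        for _, gapped in aln.rows:
            i = _AA_INDEX.get(gapped[j])
            if i is not None and i < 20:
                counts[i] += 1
        tot = counts.sum()
        denom = tot + 20 * alpha
        if denom == 0:
            em[k] = 1.0 / 20
        else:
            em[k] = (counts + alpha) / denom

    # --- transition counts from per-row state paths
    # events per row: (node k 0-based, kind) with kind in {M, D, I}; insert
    # residues attach to the preceding match node.
    cMM = np.zeros(M)
    cMI = np.zeros(M)
    cMD = np.zeros(M)
    cIM = np.zeros(M)
    cII = np.zeros(M)
    cDM = np.zeros(M)
    cDD = np.zeros(M)
    node_of_col = {}
    k = -1
    for j in range(aln.width):
        if mask[j]:
            k += 1
        node_of_col[j] = k
    for _, gapped in aln.rows:
        events: list[tuple[int, str]] = []
        for j in range(aln.width):
            if mask[j]:
                events.append((node_of_col[j], "M" if gapped[j] != GAP else "D"))
            elif gapped[j] != GAP:
                events.append((node_of_col[j], "I"))
        # trim to the local span: first to last M event (paths enter and
        # leave at match states; leading/trailing D/I are outside the model)
        m_idx = [i for i, (_, kind) in enumerate(events) if kind == "M"]
        if not m_idx:
            continue
        events = events[m_idx[0] : m_idx[-1] + 1]
        for (k1, kind1), (k2, kind2) in zip(events, events[1:]):
            pair = kind1 + kind2
            if pair == "MM" and k2 == k1 + 1:
                cMM[k1] += 1
            elif pair == "MI" and k2 == k1:
                cMI[k1] += 1
            elif pair == "MD" and k2 == k1 + 1:
                cMD[k1] += 1
            elif pair == "IM" and k2 == k1 + 1:
                cIM[k1] += 1
            elif pair == "II" and k2 == k1:
                cII[k1] += 1
            elif pair == "DM" and k2 == k1 + 1:
                cDM[k1] += 1
            elif pair == "DD" and k2 == k1 + 1:
                cDD[k1] += 1
            # other combinations (I->D, D->I, long skips from partial rows)
            # have no edge in the model and contribute no counts

    def _fan(counts_list, k_valid):
        """Normalise a fan of outgoing counts with alpha pseudocounts."""
        fan = len(counts_list)
        out = [np.zeros(M) for _ in counts_list]
        for k in range(M):
            if not k_valid(k):
                continue
            tot = sum(c[k] for c in counts_list) + fan * alpha
            if tot == 0:
                for o in out:
                    o[k] = 1.0 / fan
            else:
                for o, c in zip(out, counts_list):
                    o[k] = (c[k] + alpha) / tot
        return out

    last = M - 1
    tMM, tMI, tMD = _fan([cMM, cMI, cMD], lambda k: k < last)
    tIM, tII = _fan([cIM, cII], lambda k: k < last)
    tDM, tDD = _fan([cDM, cDD], lambda k: 0 < k < last)

    entry = np.full(M, 1.0 / M)
    exit_ = np.full(M, 1.0 / M)

    return ProfileHMM(
        family_id=aln.family_id,
        clade_tag=clade_tag,
        M=M,
        match_emissions=em,
        insert_emissions=background.copy(),
        background=background,
        tMM=tMM,
        tMI=tMI,
        tMD=tMD,
        tIM=tIM,
        tII=tII,
        tDM=tDM,
        tDD=tDD,
        entry=entry,
        exit=exit_,
        match_cols=tuple(match_cols),
    )


# ---------------------------------------------------------------------------
# Scoring


def _kernel_args(hmm: ProfileHMM):
    c = hmm._logs()
    return (
        c["lo"],
        c["ltMM"],
        c["ltMI"],
        c["ltMD"],
        c["ltIM"],
        c["ltII"],
        c["ltDM"],
        c["ltDD"],
        c["lentry"],
        c["lexit"],
    )


def viterbi_best_path(hmm: ProfileHMM, residues: str) -> tuple[float, int, int]:
    """Best single local path: (bits, start, end) with 1-based inclusive span."""
    codes = encode(residues)
    score, s, e = _kernels.viterbi_local(codes, *_kernel_args(hmm))
    return float(score), s + 1, e + 1


def viterbi_score(
    hmm: ProfileHMM, seq: SequenceRecord | str
) -> tuple[float, list[tuple[int, int]], float]:
    """Score a sequence: (full_score, envelopes, best_domain_score).

    The full score is the sum of per-domain scores found by greedy
    iterated local alignment: the best-scoring path is taken as a domain,
    its residues are masked, and the search repeats on the remaining
    segments while the best remaining domain scores above 0 bits.
    Envelopes are 1-based inclusive and sorted.
    """
    residues = seq.residues if isinstance(seq, SequenceRecord) else seq
    if not residues:
        raise ValueError("cannot score an empty sequence")
    codes = encode(residues)
    args = _kernel_args(hmm)

    # segment -> (score, abs_start, abs_end), scored lazily
    cache: dict[tuple[int, int], tuple[float, int, int]] = {}

    def seg_best(lo: int, hi: int) -> tuple[float, int, int]:
        if (lo, hi) not in cache:
            s, a, b = _kernels.viterbi_local(codes[lo:hi], *args)
            cache[(lo, hi)] = (float(s), lo + a, lo + b)
        return cache[(lo, hi)]

    segments = [(0, len(codes))]
    domains: list[tuple[float, int, int]] = []
    first_best: tuple[float, int, int] | None = None
    while segments:
        scored = [(seg_best(lo, hi), (lo, hi)) for lo, hi in segments]
        (score, a, b), seg = max(scored, key=lambda t: t[0][0])
        if first_best is None:
            first_best = (score, a, b)
        if score <= 0.0:
            break
        domains.append((score, a, b))
        lo, hi = seg
        segments.remove(seg)
        if a - lo >= 1:
            segments.append((lo, a))
        if hi - (b + 1) >= 1:
            segments.append((b + 1, hi))

    if not domains:
        score, a, b = first_best
        return score, [(a + 1, b + 1)] if b >= a else [], score

    domains.sort(key=lambda d: d[1])
    full = sum(d[0] for d in domains)
    best = max(d[0] for d in domains)
    envelopes = [(a + 1, b + 1) for _, a, b in domains]
    return full, envelopes, best


@dataclass(frozen=True)
class HmmHit:
    """One profile-vs-sequence match."""

    family_id: str
    clade_tag: str
    species_id: str
    accession: str
    full_score: float
    best_domain_score: float
    evalue: float
    envelopes: tuple[tuple[int, int], ...]
    #: full score above the forwarding bit-score threshold
    forwarded: bool = False

    def __post_init__(self) -> None:
        if self.best_domain_score > self.full_score + 1e-6:
            raise ValueError("best_domain_score exceeds full_score")
        if self.evalue < 0:
            raise ValueError("negative E-value")
        prev_end = 0
        for s, e in self.envelopes:
            if s <= prev_end or e < s:
                raise ValueError(f"envelopes not sorted/disjoint: {self.envelopes}")
            prev_end = e


# ---------------------------------------------------------------------------
# Calibration / E-values


def fit_gumbel(scores: np.ndarray) -> tuple[float, float]:
    """Method-of-moments Gumbel fit: returns (mu, lambda)."""
    scores = np.asarray(scores, dtype=float)
    sd = scores.std(ddof=1)
    if not np.isfinite(sd) or sd < 1e-9:
        raise CalibrationError("degenerate score variance; cannot fit Gumbel")
    beta = sd * math.sqrt(6.0) / math.pi
    mu = scores.mean() - _EULER_GAMMA * beta
    return mu, 1.0 / beta


def calibrate(
    hmm: ProfileHMM, n_shuffles: int = 1000, seed: int = 0, length: int = 400
) -> ProfileHMM:
    """Fit the Gumbel null by scoring random background-sampled sequences.

    Sequences are drawn i.i.d. from the profile's background composition
    at the calibration length and scored exactly as real sequences are
    (multi-domain full score); location/scale come from a moments fit.
    A random sequence can have no admissible path at all when the profile
    carries zero-probability emissions (pseudocount alpha 0); such -inf
    scores carry no information about the high-score tail and are dropped,
    provided at least half the sample remains.
    """
    if n_shuffles < 100:
        raise ValueError("n_shuffles must be >= 100")
    rng = np.random.default_rng(seed)
    draws = rng.choice(20, size=(n_shuffles, length), p=hmm.background)
    letters = np.array(list(AMINO_ACIDS))
    scores = np.empty(n_shuffles)
    for i in range(n_shuffles):
        residues = "".join(letters[draws[i]])
        scores[i], _, _ = viterbi_score(hmm, residues)
    finite = scores[np.isfinite(scores)]
    if finite.size < max(50, n_shuffles // 2):
        raise CalibrationError(
            "too few random sequences had an admissible path to calibrate"
        )
    mu, lam = fit_gumbel(finite)
    out = replace(hmm, calibration=Calibration(mu=mu, lam=lam, n=n_shuffles, seed=seed, length=length))
    out._log_cache = hmm._log_cache  # share kernel arrays
    return out


def evalue(hmm: ProfileHMM, score: float, database_size: int) -> float:
    """Expected hits >= score in ``database_size`` sequences under the null."""
    if hmm.calibration is None:
        raise CalibrationError(f"profile {hmm.family_id!r} is not calibrated")
    cal = hmm.calibration
    x = cal.lam * (score - cal.mu)
    # P(S >= s) = 1 - exp(-exp(-x)), computed stably
    if x > 700:
        p = math.exp(-x)  # tail expansion of -expm1(-exp(-x))
    else:
        p = -math.expm1(-math.exp(-x))
    return database_size * p


# ---------------------------------------------------------------------------
# Plain-text serialization


def save_profile(hmm: ProfileHMM, path) -> None:
    """Serialize a profile to a documented plain-text format."""
    lines = [f"zfscan-profile 1\t{hmm.family_id}\t{hmm.clade_tag}\t{hmm.M}"]
    if hmm.calibration:
        c = hmm.calibration
        lines.append(f"calibration\t{c.mu:.10g}\t{c.lam:.10g}\t{c.n}\t{c.seed}\t{c.length}")
    lines.append("background\t" + "\t".join(f"{p:.10g}" for p in hmm.background))
    for k in range(hmm.M):
        em = "\t".join(f"{p:.10g}" for p in hmm.match_emissions[k])
        tr = "\t".join(
            f"{getattr(hmm, t)[k]:.10g}" for t in ("tMM", "tMI", "tMD", "tIM", "tII", "tDM", "tDD")
        )
        lines.append(f"node\t{k}\t{em}\t{tr}")
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def load_profile(path) -> ProfileHMM:
    lines = [l for l in open(path).read().splitlines() if l.strip()]
    head = lines[0].split("\t")
    if not head[0].startswith("zfscan-profile"):
        raise ValueError(f"{path} is not a zfscan profile file")
    family_id, clade_tag, M = head[1], head[2], int(head[3])
    cal = None
    background = None
    em = np.zeros((M, 20))
    tr = {t: np.zeros(M) for t in ("tMM", "tMI", "tMD", "tIM", "tII", "tDM", "tDD")}
    for line in lines[1:]:
        parts = line.split("\t")
        if parts[0] == "calibration":
            cal = Calibration(
                mu=float(parts[1]), lam=float(parts[2]), n=int(parts[3]),
                seed=int(parts[4]), length=int(parts[5]),
            )
        elif parts[0] == "background":
            background = np.array([float(x) for x in parts[1:21]])
        elif parts[0] == "node":
            k = int(parts[1])
            em[k] = [float(x) for x in parts[2:22]]
            for i, t in enumerate(("tMM", "tMI", "tMD", "tIM", "tII", "tDM", "tDD")):
                tr[t][k] = float(parts[22 + i])
    return ProfileHMM(
        family_id=family_id,
        clade_tag=clade_tag,
        M=M,
        match_emissions=em,
        insert_emissions=background.copy(),
        background=background,
        entry=np.full(M, 1.0 / M),
        exit=np.full(M, 1.0 / M),
        calibration=cal,
        **tr,
    )


# ---------------------------------------------------------------------------
# Alignment of a sequence to a profile (used when augmenting alignments)


def align_to_profile(hmm: ProfileHMM, residues: str) -> tuple[float, list[tuple[str, int, int]]]:
    """Trace the best local path of ``residues`` through the profile.

    Returns (score, path) where path is a list of (state, node_k, res_i)
    steps with 0-based indices; delete states carry res_i = -1.
    """
    codes = encode(residues)
    score, end_i, end_k, bpM, bpI, bpD = _kernels.viterbi_local_traceback(
        codes, *_kernel_args(hmm)
    )
    path: list[tuple[str, int, int]] = []
    state, i, k = "M", end_i, end_k
    while True:
        if state == "M":
            path.append(("M", k, i))
            p = bpM[i, k]
            if p == 0:
                break
            state = {1: "M", 2: "I", 3: "D"}[int(p)]
            if p in (1, 2):
                i, k = i - 1, k - 1
            else:
                i, k = i - 1, k - 1
        elif state == "I":
            path.append(("I", k, i))
            p = bpI[i, k]
            state = "M" if p == 0 else "I"
            i = i - 1
        else:  # D
            path.append(("D", k, -1))
            p = bpD[i, k]
            state = "M" if p == 0 else "D"
            k = k - 1
    path.reverse()
    return float(score), path
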