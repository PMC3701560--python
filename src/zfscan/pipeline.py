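"""Orchestration of the hybrid detection method.

Per round, every proteome is scanned with each family's profile; hits
passing the E-value and bit-score thresholds are validated reciprocally
against the reference database and the master list; accepted members are
appended to the family alignment (aligned through the profile itself, no
external aligner) and the profiles rebuilt for the next round.  From the
second round on, clade-specific profiles are built for taxonomic groups
that have contributed enough members.  After the final round, a
two-stage re-check (profile re-scan, then focused alignment search with
donor sequences from the same group) decides whether a family absent
from a species is truly missing or merely hard to detect.

Accepted member sets only ever grow across rounds: each round's
acceptances are merged into the running state, so refinement cannot drop
a previously validated member.
"""

from __future__ import annotations

import logging
import zlib
from dataclasses import dataclass, field
from pathlib import Path

from .formats_io import (
    FamilyAlignment,
    GAP,
    MasterList,
    PipelineConfig,
    SequenceRecord,
    Taxonomy,
)
from .local_align import sw_score, validate_candidate
from .profile_hmm import (
    HmmHit,
    ProfileHMM,
    align_to_profile,
    build_profile,
    calibrate,
    evalue,
    viterbi_score,
)

logger = logging.getLogger(__name__)


class AssignmentConflictError(RuntimeError):
    """A candidate validated reciprocally for two different families."""


@dataclass(frozen=True)
class AuditEntry:
    round_number: int
    family_id: str
    clade_tag: str
    species_id: str
    accession: str
    full_score: float
    best_domain_score: float
    evalue: float
    forwarded: bool
    validated: bool | None  # None = not forwarded
    supporting_subject: str | None


@dataclass
class RoundResult:
    """Acceptances and the per-candidate audit trail of one round."""

    round_number: int
    accepted: dict[str, dict[str, tuple[str, ...]]]  # family -> species -> accessions
    audit: tuple[AuditEntry, ...]


@dataclass
class FamilyCallTable:
    """Final calls: member records per (species, family) plus a status."""

    families: tuple[str, ...]
    species: tuple[str, ...]
    members: dict[tuple[str, str], tuple[SequenceRecord, ...]]  # (species, family)
    status: dict[tuple[str, str], str]  # "present(n)" | "missing" | "not_assessed"
    found_in_round: dict[str, int | str]  # accession -> round number or "focused"
    clade_tag: dict[str, str]  # accession -> profile tag that found it
    audit: tuple[AuditEntry, ...]

    def accessions(self, species: str, family: str) -> tuple[str, ...]:
        return tuple(r.accession for r in self.members.get((species, family), ()))

    def all_assignments(self) -> dict[str, str]:
        """accession -> family over all final members."""
        out: dict[str, str] = {}
        for (sp, fam), recs in self.members.items():
            for r in recs:
                out[r.accession] = fam
        return out

    def to_tsv(self, path: str | Path) -> None:
        """Deterministic export: one row per member plus non-present statuses."""
        lines = ["species_id\tfamily_id\taccession\tstatus\tround\tclade_tag"]
        for sp in self.species:
            for fam in self.families:
                recs = self.members.get((sp, fam), ())
                if recs:
                    for r in recs:
                        lines.append(
                            f"{sp}\t{fam}\t{r.accession}\tpresent({len(recs)})\t"
                            f"{self.found_in_round.get(r.accession, '')}\t"
                            f"{self.clade_tag.get(r.accession, '')}"
                        )
                else:
                    lines.append(f"{sp}\t{fam}\t\t{self.status[(sp, fam)]}\t\t")
        Path(path).write_text("\n".join(lines) + "\n")

    def save(self, outdir: str | Path) -> None:
        """Write calls.tsv plus members.fasta so the table can be reloaded."""
        from .formats_io import write_fasta

        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        self.to_tsv(out / "calls.tsv")
        recs = sorted(
            {r.accession: r for rs in self.members.values() for r in rs}.values(),
            key=lambda r: r.accession,
        )
        write_fasta(recs, out / "members.fasta")

    @classmethod
    def load(cls, outdir: str | Path) -> "FamilyCallTable":
        """Reload a table written by :meth:`save` (audit trail not restored)."""
        from .formats_io import read_fasta

        out = Path(outdir)
        by_acc = {r.accession: r for r in read_fasta(out / "members.fasta")}
        members: dict[tuple[str, str], list[SequenceRecord]] = {}
        status: dict[tuple[str, str], str] = {}
        found: dict[str, int | str] = {}
        clade: dict[str, str] = {}
        species: list[str] = []
        families: list[str] = []
        for line in (out / "calls.tsv").read_text().splitlines()[1:]:
            sp, fam, acc, st, rnd, tag = line.split("\t")
            if sp not in species:
                species.append(sp)
            if fam not in families:
                families.append(fam)
            status[(sp, fam)] = st
            if acc:
                rec = by_acc[acc]
                rec = SequenceRecord(accession=acc, residues=rec.residues, species_id=sp)
                members.setdefault((sp, fam), []).append(rec)
                found[acc] = int(rnd) if rnd.isdigit() else rnd
                clade[acc] = tag
        return cls(
            families=tuple(sorted(families)),
            species=tuple(sorted(species)),
            members={k: tuple(v) for k, v in members.items()},
            status=status,
            found_in_round=found,
            clade_tag=clade,
            audit=(),
        )


# ---------------------------------------------------------------------------
# Scanning


def search_proteome(
    hmm: ProfileHMM, proteome: list[SequenceRecord], cfg: PipelineConfig | None = None
) -> list[HmmHit]:
    """Scan one proteome with one calibrated profile.

    Returns hits with E-value at or below the threshold, sorted by full
    score descending, then best domain score descending, then accession;
    hits whose full score exceeds the bit-score threshold carry
    ``forwarded=True`` and proceed to reciprocal validation.
    """
    cfg = cfg or PipelineConfig()
    db_size = len(proteome)
    hits: list[HmmHit] = []
    for rec in proteome:
        full, envelopes, best = viterbi_score(hmm, rec)
        ev = evalue(hmm, full, db_size)
        if ev <= cfg.evalue_threshold:
            hits.append(
                HmmHit(
                    family_id=hmm.family_id,
                    clade_tag=hmm.clade_tag,
                    species_id=rec.species_id,
                    accession=rec.accession,
                    full_score=full,
                    best_domain_score=best,
                    evalue=ev,
                    envelopes=tuple(envelopes),
                    forwarded=full > cfg.score_threshold,
                )
            )
    hits.sort(key=lambda h: (-h.full_score, -h.best_domain_score, h.accession))
    return hits


def _calibration_seed(cfg: PipelineConfig, family_id: str, clade_tag: str, round_number: int) -> int:
    tag = f"{family_id}:{clade_tag}:{round_number}".encode()
    return (cfg.rng_seed * 1000003 + zlib.crc32(tag)) % (2**31)


def _build_calibrated(
    aln: FamilyAlignment, cfg: PipelineConfig, clade_tag: str, round_number: int
) -> ProfileHMM:
    hmm = build_profile(aln, cfg, clade_tag=clade_tag)
    return calibrate(
        hmm,
        n_shuffles=cfg.calibration_n,
        seed=_calibration_seed(cfg, aln.family_id, clade_tag, round_number),
        length=cfg.calibration_length,
    )


def _clade_subalignment(
    aln: FamilyAlignment, group: str, taxonomy: Taxonomy, species_of: dict[str, str]
) -> FamilyAlignment | None:
    rows = tuple(
        (acc, g)
        for acc, g in aln.rows
        if species_of.get(acc) is not None and taxonomy.group_of(species_of[acc]) == group
    )
    if len(rows) < 2:
        return None
    return FamilyAlignment(family_id=aln.family_id, rows=rows, rf_mask=aln.rf_mask)


# ---------------------------------------------------------------------------
# Profile-guided alignment augmentation


def augment_family(
    aln: FamilyAlignment, new_members: list[SequenceRecord], profile: ProfileHMM
) -> FamilyAlignment:
    """Insert validated members into the family alignment via the profile.

    Each new member is threaded through the profile by Viterbi traceback;
    its match/delete states land in the existing match columns, while
    insert-state residues (and unaligned flanks) open fresh all-gap
    columns for the old rows.  Members sharing an insertion anchor share
    the new columns (left-aligned), keeping growth modest.  A member whose
    accession is already a row is skipped with a log entry.
    """
    if profile.match_cols is None:
        raise ValueError("profile does not record its source match columns")
    match_cols = profile.match_cols
    existing = set(aln.accessions)
    todo = []
    for rec in sorted(new_members, key=lambda r: r.accession):
        if rec.accession in existing:
            logger.info("augment %s: member %s already in alignment, skipped",
                        aln.family_id, rec.accession)
            continue
        todo.append(rec)
    if not todo:
        return aln

    # per-member layout: column index -> residue, plus insert runs keyed by
    # the original column after which they sit (-1 = before everything)
    layouts: list[tuple[str, dict[int, str], dict[int, list[str]]]] = []
    for rec in todo:
        score, path = align_to_profile(profile, rec.residues)
        cells: dict[int, str] = {}
        inserts: dict[int, list[str]] = {}
        first_i = min(i for _, _, i in path if i >= 0)
        last_i = max(i for _, _, i in path if i >= 0)
        first_k = path[0][1]
        last_k = path[-1][1]
        # unaligned flanks become insert runs outside the matched span
        lead = list(rec.residues[:first_i])
        if lead:
            anchor = match_cols[first_k] - 1
            inserts.setdefault(anchor if anchor >= 0 else -1, []).extend(lead)
        for state, k, i in path:
            if state == "M":
                cells[match_cols[k]] = rec.residues[i]
            elif state == "I":
                inserts.setdefault(match_cols[k], []).append(rec.residues[i])
            # deletes need no action: default is a gap
        tail = list(rec.residues[last_i + 1 :])
        if tail:
            inserts.setdefault(match_cols[last_k], []).extend(tail)
        layouts.append((rec.accession, cells, inserts))

    n_new: dict[int, int] = {}
    for _, _, inserts in layouts:
        for anchor, run in inserts.items():
            n_new[anchor] = max(n_new.get(anchor, 0), len(run))

    def render(row_cells: dict[int, str], row_inserts: dict[int, list[str]]) -> str:
        out: list[str] = []
        for pad in range(n_new.get(-1, 0)):
            run = row_inserts.get(-1, [])
            out.append(run[pad] if pad < len(run) else GAP)
        for j in range(aln.width):
            out.append(row_cells.get(j, GAP))
            for pad in range(n_new.get(j, 0)):
                run = row_inserts.get(j, [])
                out.append(run[pad] if pad < len(run) else GAP)
        return "".join(out)

    new_rows = [
        (acc, render({j: c for j, c in enumerate(gapped)}, {}))
        for acc, gapped in aln.rows
    ]
    for acc, cells, inserts in layouts:
        new_rows.append((acc, render(cells, inserts)))

    rf_mask = None
    if aln.rf_mask is not None:
        mask: list[bool] = [False] * n_new.get(-1, 0)
        for j in range(aln.width):
            mask.append(aln.rf_mask[j])
            mask.extend([False] * n_new.get(j, 0))
        rf_mask = tuple(mask)
    return FamilyAlignment(family_id=aln.family_id, rows=tuple(new_rows), rf_mask=rf_mask)


# ---------------------------------------------------------------------------
# Rounds


@dataclass
class _PipelineState:
    accepted: dict[str, dict[str, set[str]]] = field(default_factory=dict)
    validation_cache: dict[tuple[str, str], tuple[bool, str | None]] = field(default_factory=dict)

    def accept(self, family: str, species: str, accession: str) -> None:
        self.accepted.setdefault(family, {}).setdefault(species, set()).add(accession)

    def is_accepted(self, family: str, species: str, accession: str) -> bool:
        return accession in self.accepted.get(family, {}).get(species, set())

    def accepted_view(self) -> dict[str, dict[str, tuple[str, ...]]]:
        return {
            fam: {sp: tuple(sorted(accs)) for sp, accs in sorted(by_sp.items()) if accs}
            for fam, by_sp in sorted(self.accepted.items())
        }


def _check_conflicts(state: _PipelineState) -> None:
    owner: dict[str, str] = {}
    for fam, by_sp in sorted(state.accepted.items()):
        for sp, accs in sorted(by_sp.items()):
            for acc in sorted(accs):
                if acc in owner and owner[acc] != fam:
                    raise AssignmentConflictError(
                        f"accession {acc} validated for both {owner[acc]} and {fam}; "
                        "master list families are expected to be disjoint"
                    )
                owner[acc] = fam


def run_round(
    families: dict[str, FamilyAlignment],
    proteomes: dict[str, list[SequenceRecord]],
    reference_db: list[SequenceRecord],
    master: MasterList,
    taxonomy: Taxonomy,
    cfg: PipelineConfig,
    round_number: int,
    state: _PipelineState | None = None,
) -> RoundResult:
    """One scan/validate round over all families and species.

    From round 2 on, a clade-specific profile is used for species of a
    group that has contributed at least ``cfg.min_clade_seqs`` alignment
    rows; other species fall back to the general profile.
    """
    if round_number > cfg.total_rounds:
        raise ValueError(f"round {round_number} exceeds total_rounds={cfg.total_rounds}")
    state = state if state is not None else _PipelineState()
    species_of = {
        rec.accession: sp for sp, recs in proteomes.items() for rec in recs
    }
    audit: list[AuditEntry] = []

    for fam in sorted(families):
        aln = families[fam]
        general = _build_calibrated(aln, cfg, "general", round_number)
        profile_for_group: dict[str, ProfileHMM] = {}
        if round_number >= 2:
            for group in taxonomy.group_order:
                rows = [
                    acc for acc in aln.accessions
                    if species_of.get(acc) is not None
                    and taxonomy.group_of(species_of[acc]) == group
                ]
                if len(rows) >= cfg.min_clade_seqs:
                    sub = _clade_subalignment(aln, group, taxonomy, species_of)
                    if sub is not None:
                        profile_for_group[group] = _build_calibrated(
                            sub, cfg, group, round_number
                        )

        for sp in sorted(proteomes):
            hmm = profile_for_group.get(taxonomy.group_of(sp), general)
            for hit in search_proteome(hmm, proteomes[sp], cfg):
                validated: bool | None = None
                subject: str | None = None
                if hit.forwarded:
                    key = (fam, hit.accession)
                    if state.is_accepted(fam, sp, hit.accession):
                        validated, subject = True, state.validation_cache.get(key, (True, None))[1]
                    else:
                        if key not in state.validation_cache:
                            rec = next(r for r in proteomes[sp] if r.accession == hit.accession)
                            ok, support = validate_candidate(rec, fam, reference_db, master, cfg)
                            state.validation_cache[key] = (ok, support.subject if support else None)
                        validated, subject = state.validation_cache[key]
                        if validated:
                            state.accept(fam, sp, hit.accession)
                audit.append(
                    AuditEntry(
                        round_number=round_number,
                        family_id=fam,
                        clade_tag=hmm.clade_tag,
                        species_id=sp,
                        accession=hit.accession,
                        full_score=hit.full_score,
                        best_domain_score=hit.best_domain_score,
                        evalue=hit.evalue,
                        forwarded=hit.forwarded,
                        validated=validated,
                        supporting_subject=subject,
                    )
                )
    _check_conflicts(state)
    return RoundResult(
        round_number=round_number,
        accepted=state.accepted_view(),
        audit=tuple(audit),
    )


# ---------------------------------------------------------------------------
# Missing-family re-check


def focused_missing_search(
    species: str,
    family_id: str,
    donor_sequences: list[SequenceRecord],
    proteome: list[SequenceRecord],
    cfg: PipelineConfig,
    reference_db: list[SequenceRecord],
    master: MasterList,
) -> tuple[str, list[str]]:
    """Focused alignment search of one proteome with same-group donors.

    Each donor is aligned against every proteome sequence; the top
    ``cfg.max_reference_hits`` subjects per donor that score at least
    ``cfg.focused_min_score_ratio`` of the donor's self-alignment score
    are validated reciprocally, and any that validate are family members.
    Returns ("found", accessions), ("missing", []) or ("not_assessed", [])
    when no donors are available.
    """
    if not donor_sequences:
        return "not_assessed", []
    candidates: set[str] = set()
    by_acc = {rec.accession: rec for rec in proteome}
    for donor in donor_sequences:
        floor = cfg.focused_min_score_ratio * sw_score(donor, donor)
        scored = [
            (sw_score(donor, rec), rec.accession)
            for rec in proteome
        ]
        scored = [(s, acc) for s, acc in scored if s > 0.0 and s >= floor]
        scored.sort(key=lambda t: (-t[0], t[1]))
        candidates.update(acc for _, acc in scored[: cfg.max_reference_hits])
    found: list[str] = []
    for acc in sorted(candidates):
        ok, _ = validate_candidate(by_acc[acc], family_id, reference_db, master, cfg)
        if ok:
            found.append(acc)
    return ("found", found) if found else ("missing", [])


# ---------------------------------------------------------------------------
# The full pipeline


def run_pipeline(
    families: dict[str, FamilyAlignment],
    proteomes: dict[str, list[SequenceRecord]],
    reference_db: list[SequenceRecord],
    master: MasterList,
    taxonomy: Taxonomy,
    cfg: PipelineConfig | None = None,
) -> FamilyCallTable:
    """Run all rounds plus the final missing-family re-check."""
    cfg = cfg or PipelineConfig()
    state = _PipelineState()
    alignments = dict(families)
    species_of = {rec.accession: sp for sp, recs in proteomes.items() for rec in recs}
    record_of = {rec.accession: rec for recs in proteomes.values() for rec in recs}
    found_in_round: dict[str, int | str] = {}
    clade_tag: dict[str, str] = {}
    audit: list[AuditEntry] = []

    def _augment_all(round_number: int) -> None:
        for fam in sorted(alignments):
            accepted = state.accepted.get(fam, {})
            new = [
                record_of[acc]
                for sp in sorted(accepted)
                for acc in sorted(accepted[sp])
                if acc not in set(alignments[fam].accessions)
            ]
            if new:
                profile = build_profile(alignments[fam], cfg, clade_tag="general")
                alignments[fam] = augment_family(alignments[fam], new, profile)

    for r in range(1, cfg.total_rounds + 1):
        rr = run_round(
            alignments, proteomes, reference_db, master, taxonomy, cfg, r, state
        )
        audit.extend(rr.audit)
        for e in rr.audit:
            if e.validated and e.accession not in found_in_round:
                found_in_round[e.accession] = r
                clade_tag[e.accession] = e.clade_tag
        if r < cfg.total_rounds:
            _augment_all(r)

    # final profiles (post last round) for stage 1 of the missing check
    _augment_all(cfg.total_rounds)
    final_general: dict[str, ProfileHMM] = {}
    final_clade: dict[tuple[str, str], ProfileHMM | None] = {}

    def _final_profile(fam: str, group: str) -> ProfileHMM:
        key = (fam, group)
        if key not in final_clade:
            sub = _clade_subalignment(alignments[fam], group, taxonomy, species_of)
            if sub is not None and len(sub.rows) >= cfg.min_clade_seqs:
                final_clade[key] = _build_calibrated(sub, cfg, group, cfg.total_rounds + 1)
            else:
                final_clade[key] = None
        if final_clade[key] is not None:
            return final_clade[key]
        if fam not in final_general:
            final_general[fam] = _build_calibrated(
                alignments[fam], cfg, "general", cfg.total_rounds + 1
            )
        return final_general[fam]

    fam_list = tuple(sorted(families))
    sp_list = tuple(sorted(proteomes))
    status: dict[tuple[str, str], str] = {}

    for fam in fam_list:
        accepted = state.accepted.get(fam, {})
        group_members: dict[str, list[str]] = {}
        for sp, accs in accepted.items():
            if accs:
                group_members.setdefault(taxonomy.group_of(sp), []).extend(sorted(accs))
        for sp in sp_list:
            if accepted.get(sp):
                continue
            group = taxonomy.group_of(sp)
            donors_accs = [
                acc for acc in group_members.get(group, [])
                if species_of[acc] != sp
            ]
            if not donors_accs:
                status[(sp, fam)] = "not_assessed"
                continue
            # stage 1: re-scan with the final profile
            hmm = _final_profile(fam, group)
            rescued = False
            for hit in search_proteome(hmm, proteomes[sp], cfg):
                if not hit.forwarded:
                    continue
                key = (fam, hit.accession)
                if key not in state.validation_cache:
                    ok, support = validate_candidate(
                        record_of[hit.accession], fam, reference_db, master, cfg
                    )
                    state.validation_cache[key] = (ok, support.subject if support else None)
                if state.validation_cache[key][0]:
                    state.accept(fam, sp, hit.accession)
                    found_in_round.setdefault(hit.accession, "focused")
                    clade_tag.setdefault(hit.accession, hmm.clade_tag)
                    rescued = True
            if rescued:
                continue
            # stage 2: focused alignment search with same-group donors
            phylum = taxonomy.phylum_of(sp)
            donors_accs.sort(
                key=lambda a: (taxonomy.phylum_of(species_of[a]) != phylum, a)
            )
            donors = [record_of[a] for a in donors_accs[: cfg.max_reference_hits]]
            verdict, accs = focused_missing_search(
                sp, fam, donors, proteomes[sp], cfg, reference_db, master
            )
            if verdict == "found":
                for acc in accs:
                    state.accept(fam, sp, acc)
                    found_in_round.setdefault(acc, "focused")
                    clade_tag.setdefault(acc, "focused")
            else:
                status[(sp, fam)] = "missing"

    _check_conflicts(state)
    members: dict[tuple[str, str], tuple[SequenceRecord, ...]] = {}
    for fam in fam_list:
        for sp in sp_list:
            accs = sorted(state.accepted.get(fam, {}).get(sp, set()))
            if accs:
                members[(sp, fam)] = tuple(record_of[a] for a in accs)
                status[(sp, fam)] = f"present({len(accs)})"
            else:
                status.setdefault((sp, fam), "not_assessed")
    return FamilyCallTable(
        families=fam_list,
        species=sp_list,
        members=members,
        status=status,
        found_in_round=found_in_round,
        clade_tag=clade_tag,
        audit=tuple(audit),
    )
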