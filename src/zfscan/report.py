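"""Comparative products: presence/absence matrix, gene blocks, holes, loners.

The species-by-family member counts (after duplicate collapsing) roll up
to phylum-level presence under an any-species rule: a phylum possesses a
family if at least one of its species does, so a single missing gene
model does not erase a phylum's presence.  Each family's "block" is the
most basal taxonomic group in which it appears; holes are isolated
absences inside an otherwise well-populated phylum, loners isolated
presences inside a group that otherwise lacks the family.
"""

from __future__ import annotations

import logging

import pandas as pd
from dataclasses import dataclass

from .formats_io import PipelineConfig, SequenceRecord, Taxonomy
from .local_align import sw_align
from .pipeline import FamilyCallTable

logger = logging.getLogger(__name__)


@dataclass
class PresenceMatrix:
    """Species x family member counts plus the derived comparative layers."""

    counts: pd.DataFrame  # species rows, family columns, int
    phylum_presence: pd.DataFrame  # phylum rows, family columns, bool
    taxonomy: Taxonomy
    duplicates: dict[tuple[str, str], tuple[str, ...]]  # collapsed accessions
    blocks: dict[str, str] | None = None
    holes: frozenset[tuple[str, str]] | None = None
    loners: frozenset[tuple[str, str]] | None = None


def dedupe_paralogs(
    members: list[SequenceRecord], cfg: PipelineConfig | None = None
) -> tuple[list[SequenceRecord], list[tuple[str, ...]]]:
    """Split one species' family members into paralogs and duplicate groups.

    Two members are duplicates when their local alignment covers at least
    95% of the shorter sequence at identity >= cfg.duplicate_identity;
    duplicate groups keep the lexicographically smallest accession as the
    representative.  Returns (retained members, duplicate groups).
    """
    cfg = cfg or PipelineConfig()
    if len(members) <= 1:
        return list(members), []
    members = sorted(members, key=lambda r: r.accession)
    parent = {r.accession: r.accession for r in members}

    def find(a: str) -> str:
        while parent[a] != a:
            parent[a] = parent[parent[a]]
            a = parent[a]
        return a

    for i, a in enumerate(members):
        for b in members[i + 1 :]:
            hit = sw_align(a, b)
            if hit.aligned_columns == 0:
                continue
            shorter = min(len(a.residues), len(b.residues))
            qcov = hit.query_span[1] - hit.query_span[0] + 1
            scov = hit.subject_span[1] - hit.subject_span[0] + 1
            coverage = min(qcov, scov) / shorter
            if coverage >= 0.95 and hit.identity >= cfg.duplicate_identity:
                parent[find(b.accession)] = find(a.accession)

    groups: dict[str, list[str]] = {}
    for r in members:
        groups.setdefault(find(r.accession), []).append(r.accession)
    retained_accs = {min(accs) for accs in groups.values()}
    retained = [r for r in members if r.accession in retained_accs]
    dup_groups = [tuple(sorted(accs)) for accs in groups.values() if len(accs) > 1]
    return retained, sorted(dup_groups)


def build_matrix(
    calls: FamilyCallTable, taxonomy: Taxonomy, cfg: PipelineConfig | None = None
) -> PresenceMatrix:
    """Count non-duplicate members per species and family."""
    cfg = cfg or PipelineConfig()
    unknown = sorted(set(calls.species) - set(taxonomy.species))
    if unknown:
        raise KeyError(f"species {unknown} not in taxonomy")
    counts = pd.DataFrame(
        0, index=list(calls.species), columns=list(calls.families), dtype=int
    )
    duplicates: dict[tuple[str, str], tuple[str, ...]] = {}
    for (sp, fam), recs in sorted(calls.members.items()):
        retained, dup_groups = dedupe_paralogs(list(recs), cfg)
        counts.loc[sp, fam] = len(retained)
        if dup_groups:
            collapsed = tuple(a for g in dup_groups for a in g[1:])
            duplicates[(sp, fam)] = collapsed
    phyla = taxonomy.phyla
    presence = pd.DataFrame(False, index=phyla, columns=list(calls.families))
    for phylum in phyla:
        sps = [s for s in taxonomy.species_in_phylum(phylum) if s in counts.index]
        if sps:
            presence.loc[phylum] = (counts.loc[sps] >= 1).any(axis=0)
    return PresenceMatrix(
        counts=counts, phylum_presence=presence, taxonomy=taxonomy, duplicates=duplicates
    )


def detect_blocks(matrix: PresenceMatrix, group_order: tuple[str, ...] | None = None) -> dict[str, str]:
    """Assign each family to the most basal group where it is present.

    A family present in exactly one species overall is labelled "none"
    (it is a loner candidate, not a block member).
    """
    tax = matrix.taxonomy
    group_order = group_order or tax.group_order
    group_of_phylum = {p: tax.species[tax.species_in_phylum(p)[0]][1] for p in tax.phyla}
    blocks: dict[str, str] = {}
    for fam in matrix.counts.columns:
        n_species = int((matrix.counts[fam] >= 1).sum())
        if n_species <= 1:
            blocks[fam] = "none"
            continue
        label = "none"
        for group in group_order:
            phyla = [p for p in matrix.phylum_presence.index if group_of_phylum[p] == group]
            if any(matrix.phylum_presence.loc[p, fam] for p in phyla):
                label = group
                break
        blocks[fam] = label
    matrix.blocks = blocks
    return blocks


def flag_holes_loners(
    matrix: PresenceMatrix, taxonomy: Taxonomy | None = None, cfg: PipelineConfig | None = None
) -> tuple[frozenset[tuple[str, str]], frozenset[tuple[str, str]]]:
    """Flag isolated absences (holes) and isolated presences (loners).

    A hole needs a phylum of >= 3 species in which at least
    ``hole_majority`` of the species' peers have the family; a loner
    needs a group of >= 5 species in which at most
    ``loner_max_other_frequency`` of the peers have it.
    """
    tax = taxonomy or matrix.taxonomy
    cfg = cfg or PipelineConfig()
    counts = matrix.counts
    holes: set[tuple[str, str]] = set()
    loners: set[tuple[str, str]] = set()
    for sp in counts.index:
        phylum_peers = [s for s in tax.species_in_phylum(tax.phylum_of(sp)) if s != sp and s in counts.index]
        group_peers = [s for s in tax.species_in_group(tax.group_of(sp)) if s != sp and s in counts.index]
        for fam in counts.columns:
            c = counts.loc[sp, fam]
            if c == 0:
                if len(phylum_peers) + 1 >= 3 and phylum_peers:
                    frac = sum(counts.loc[p, fam] >= 1 for p in phylum_peers) / len(phylum_peers)
                    if frac >= cfg.hole_majority:
                        holes.add((sp, fam))
            else:
                if len(group_peers) + 1 >= 5 and group_peers:
                    frac = sum(counts.loc[p, fam] >= 1 for p in group_peers) / len(group_peers)
                    if frac <= cfg.loner_max_other_frequency:
                        loners.add((sp, fam))
    matrix.holes = frozenset(holes)
    matrix.loners = frozenset(loners)
    return matrix.holes, matrix.loners


def render_summary(matrix: PresenceMatrix, fmt: str = "tsv") -> str:
    """Render the phylum x family table with block/hole/loner annotations.

    Rows are phyla in basal-to-derived group order; columns are families
    ordered by block (basal first, "none" last) then name.  Output is
    byte-stable across reruns for identical inputs.
    """
    if fmt not in ("tsv", "markdown"):
        raise ValueError(f"unknown format {fmt!r}")
    tax = matrix.taxonomy
    blocks = matrix.blocks if matrix.blocks is not None else detect_blocks(matrix)
    if matrix.holes is None or matrix.loners is None:
        flag_holes_loners(matrix)
    rank = {g: i for i, g in enumerate(tax.group_order)}
    fams = sorted(
        matrix.counts.columns,
        key=lambda f: (rank.get(blocks.get(f, "none"), len(rank)), f),
    )
    if matrix.counts.values.sum() == 0:
        logger.warning("presence matrix is empty; rendering header-only report")

    phyla = [p for p in tax.phyla if any(s in matrix.counts.index for s in tax.species_in_phylum(p))]
    rows: list[list[str]] = []
    header = ["phylum_class", "group", "n_species"] + list(fams)
    rows.append(header)
    rows.append(["(block)", "", ""] + [blocks.get(f, "none") for f in fams])
    for p in phyla:
        sps = [s for s in tax.species_in_phylum(p) if s in matrix.counts.index]
        group = tax.species[sps[0]][1]
        cells = [str(int(matrix.counts.loc[sps, f].sum())) for f in fams]
        rows.append([p, group, str(len(sps))] + cells)

    notes: list[str] = []
    for sp, fam in sorted(matrix.holes or ()):
        notes.append(f"hole\t{sp}\t{fam}")
    for sp, fam in sorted(matrix.loners or ()):
        notes.append(f"loner\t{sp}\t{fam}")

    if fmt == "tsv":
        out = "\n".join("\t".join(r) for r in rows)
        if notes:
            out += "\n\n#flags\n" + "\n".join(notes)
        return out + "\n"
    # markdown
    md = ["| " + " | ".join(rows[0]) + " |", "|" + "---|" * len(rows[0])]
    for r in rows[1:]:
        md.append("| " + " | ".join(r) + " |")
    if notes:
        md.append("")
        md.append("Flags:")
        for n in notes:
            md.append("- " + n.replace("\t", " "))
    return "\n".join(md) + "\n"
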