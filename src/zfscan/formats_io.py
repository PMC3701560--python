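"""On-disk artifacts: FASTA / Stockholm parsing, TSV tables, run configuration.

All readers go through Biopython for the sequence formats and return the
small typed containers the rest of the package works with.  Coordinates in
every report produced downstream are 1-based inclusive, matching the
conventions of the search tools this package stands in for.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, fields, replace
from pathlib import Path
from typing import Iterable, Sequence

import yaml
from Bio import AlignIO, SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord as _BioSeqRecord

logger = logging.getLogger(__name__)

#: The 20 canonical amino acids, in alphabetical one-letter order.
AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
#: 'X' (unknown residue) is accepted everywhere and scored as background.
ALPHABET = set(AMINO_ACIDS) | {"X"}
GAP = "-"


class FormatError(ValueError):
    """Raised when an input file violates the documented contracts."""


@dataclass(frozen=True)
class SequenceRecord:
    """One protein sequence: unique accession, owning species, residues.

    Residues are upper-case, gap-free, drawn from the 20-letter amino-acid
    alphabet plus ``X``.
    """

    accession: str
    residues: str
    species_id: str = ""

    def __post_init__(self) -> None:
        if not self.residues:
            raise FormatError(f"empty sequence for accession {self.accession!r}")
        bad = set(self.residues) - ALPHABET
        if bad:
            raise FormatError(
                f"accession {self.accession!r}: residues outside the amino-acid "
                f"alphabet: {sorted(bad)}"
            )

    def __len__(self) -> int:
        return len(self.residues)


@dataclass(frozen=True)
class FamilyAlignment:
    """A gapped, equal-width multiple alignment of one family's members.

    ``rf_mask`` is an optional explicit match-column annotation (True =
    match column), e.g. from a Stockholm ``#=GC RF`` line; when present it
    overrides the gap-fraction rule during profile construction.
    """

    family_id: str
    rows: tuple[tuple[str, str], ...]
    rf_mask: tuple[bool, ...] | None = None

    def __post_init__(self) -> None:
        if not self.rows:
            raise FormatError(f"family {self.family_id!r}: alignment has no rows")
        w = len(self.rows[0][1])
        for acc, gapped in self.rows:
            if len(gapped) != w:
                raise FormatError(
                    f"family {self.family_id!r}: row {acc!r} has length "
                    f"{len(gapped)}, expected {w}"
                )
            bad = set(gapped) - ALPHABET - {GAP}
            if bad:
                raise FormatError(
                    f"family {self.family_id!r}: row {acc!r} has characters "
                    f"outside alphabet+gap: {sorted(bad)}"
                )
        accs = [a for a, _ in self.rows]
        if len(set(accs)) != len(accs):
            dup = sorted({a for a in accs if accs.count(a) > 1})
            raise FormatError(f"family {self.family_id!r}: duplicate row accession(s) {dup}")
        if self.rf_mask is not None and len(self.rf_mask) != w:
            raise FormatError(
                f"family {self.family_id!r}: RF mask length {len(self.rf_mask)} != width {w}"
            )

    @property
    def width(self) -> int:
        return len(self.rows[0][1])

    @property
    def accessions(self) -> tuple[str, ...]:
        return tuple(a for a, _ in self.rows)

    def ungapped(self, accession: str) -> str:
        for acc, gapped in self.rows:
            if acc == accession:
                return gapped.replace(GAP, "")
        raise KeyError(accession)


@dataclass(frozen=True)
class Taxonomy:
    """Species -> (phylum/class, group) plus an explicit basal-to-derived group order."""

    species: dict[str, tuple[str, str]]
    group_order: tuple[str, ...]

    def __post_init__(self) -> None:
        groups_present = {g for _, g in self.species.values()}
        missing = groups_present - set(self.group_order)
        if missing:
            raise FormatError(f"groups {sorted(missing)} not in group_order {self.group_order}")

    def group_of(self, species_id: str) -> str:
        return self.species[species_id][1]

    def phylum_of(self, species_id: str) -> str:
        return self.species[species_id][0]

    def species_in_group(self, group: str) -> list[str]:
        return sorted(s for s, (_, g) in self.species.items() if g == group)

    def species_in_phylum(self, phylum: str) -> list[str]:
        return sorted(s for s, (p, _) in self.species.items() if p == phylum)

    @property
    def phyla(self) -> list[str]:
        """Phyla ordered by group order, then name."""
        rank = {g: i for i, g in enumerate(self.group_order)}
        seen: dict[str, str] = {}
        for p, g in self.species.values():
            seen[p] = g
        return sorted(seen, key=lambda p: (rank[seen[p]], p))


@dataclass(frozen=True)
class MasterList:
    """family_id -> set of reference accessions; each accession in exactly one family."""

    families: dict[str, frozenset[str]]

    def __post_init__(self) -> None:
        seen: dict[str, str] = {}
        for fam in sorted(self.families):
            for acc in sorted(self.families[fam]):
                if acc in seen:
                    raise FormatError(
                        f"accession {acc!r} listed under families "
                        f"{seen[acc]!r} and {fam!r}"
                    )
                seen[acc] = fam

    def family_of(self, accession: str) -> str | None:
        for fam, accs in self.families.items():
            if accession in accs:
                return fam
        return None

    def __getitem__(self, family_id: str) -> frozenset[str]:
        return self.families[family_id]

    def __contains__(self, family_id: str) -> bool:
        return family_id in self.families


@dataclass(frozen=True)
class PipelineConfig:
    """All pipeline thresholds in one place.

    evalue_threshold
        Maximum E-value for a profile hit to be reported (default 0.001).
    score_threshold
        Minimum full-sequence bit score for a hit to be forwarded to
        reciprocal validation (default 100 bits).
    max_reference_hits
        Top-N reference subjects inspected during validation (default 3).
    total_rounds
        Scan/validate/refine iterations (default 3: one initial round plus
        two refinement rounds).
    min_clade_seqs
        Minimum accepted members from one taxonomic group before a
        clade-specific profile is built for that group (default 4).
    match_column_gap_threshold
        An alignment column is a match column iff its gap fraction is
        strictly below this value (default 0.5).
    pseudocount_alpha
        Laplace pseudocount added per residue/transition (default 1.0).
    duplicate_identity
        Pairwise identity at or above which two within-species members are
        collapsed as duplicates rather than kept as paralogs (default 0.99).
    hole_majority
        Fraction of a species' phylum peers that must possess a family for
        the species' absence to be flagged a hole (default 0.8).
    loner_max_other_frequency
        Maximum fraction of group peers possessing a family for a presence
        to be flagged a loner (default 0.1).
    focused_min_score_ratio
        In the focused missing-family search, a proteome sequence only
        becomes a candidate if its alignment to a donor scores at least
        this fraction of the donor's self-alignment score (default 0.2).
        The main rounds need no such guard because the bit-score filter
        precedes validation; the focused search queries with donors
        directly, and without a floor a compositionally biased decoy can
        reach reciprocal validation on a noise-level hit.
    """

    evalue_threshold: float = 0.001
    score_threshold: float = 100.0
    max_reference_hits: int = 3
    total_rounds: int = 3
    min_clade_seqs: int = 4
    match_column_gap_threshold: float = 0.5
    pseudocount_alpha: float = 1.0
    duplicate_identity: float = 0.99
    hole_majority: float = 0.8
    loner_max_other_frequency: float = 0.1
    focused_min_score_ratio: float = 0.2
    rng_seed: int = 0
    calibration_n: int = 500
    calibration_length: int = 400

    def __post_init__(self) -> None:
        if self.evalue_threshold <= 0 or self.score_threshold <= 0:
            raise ValueError("thresholds must be positive")
        if self.total_rounds < 1:
            raise ValueError("total_rounds must be >= 1")
        if self.max_reference_hits < 1:
            raise ValueError("max_reference_hits must be >= 1")
        for name in (
            "match_column_gap_threshold",
            "duplicate_identity",
            "hole_majority",
            "loner_max_other_frequency",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if self.pseudocount_alpha < 0:
            raise ValueError("pseudocount_alpha must be >= 0")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        """Load from a plain ``key: value`` (YAML mapping) file."""
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise FormatError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        data = {f.name: getattr(self, f.name) for f in fields(self)}
        Path(path).write_text(yaml.safe_dump(data, sort_keys=True))

    def with_(self, **kwargs) -> "PipelineConfig":
        return replace(self, **kwargs)


# ---------------------------------------------------------------------------
# FASTA


def read_fasta(path: str | Path, species_id: str = "") -> list[SequenceRecord]:
    """Parse a protein FASTA file.

    The accession is the header token before the first whitespace; residues
    are upper-cased and trailing/internal ``*`` stop symbols are stripped.
    Duplicate accessions and empty sequences are errors.
    """
    records: list[SequenceRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        acc = rec.id
        if acc in seen:
            raise FormatError(f"duplicate accession {acc!r} in {path}")
        seen.add(acc)
        residues = str(rec.seq).upper().replace("*", "")
        if not residues:
            raise FormatError(f"empty sequence for accession {acc!r} in {path}")
        records.append(SequenceRecord(accession=acc, residues=residues, species_id=species_id))
    return records


def write_fasta(records: Iterable[SequenceRecord], path: str | Path, width: int = 60) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.accession}\n")
            for i in range(0, len(rec.residues), width):
                fh.write(rec.residues[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# Alignments


def read_alignment(
    path: str | Path, dialect: str = "fasta", family_id: str | None = None
) -> FamilyAlignment:
    """Read an aligned FASTA or Stockholm file into a FamilyAlignment.

    For Stockholm input a ``#=GC RF`` line, when present, is kept as an
    explicit match-column mask (non-gap RF characters mark match columns).
    ``.`` gaps are normalised to ``-``.
    """
    if dialect not in ("fasta", "stockholm"):
        raise ValueError(f"unknown alignment dialect {dialect!r}")
    if family_id is None:
        family_id = Path(path).stem.split(".")[0]
    try:
        aln = AlignIO.read(str(path), dialect)
    except ValueError as exc:
        # AlignIO reports ragged rows with an unhelpful message; re-check
        # row lengths ourselves for the FASTA case to name the offender.
        if dialect == "fasta":
            lengths = [(rec.id, len(rec.seq)) for rec in SeqIO.parse(str(path), "fasta")]
            if len({l for _, l in lengths}) > 1:
                w = lengths[0][1]  # first row defines the width
                bad = sorted(a for a, l in lengths if l != w)
                raise FormatError(
                    f"family {family_id!r}: rows {bad} differ in length from width {w}"
                ) from exc
        raise
    rows = tuple(
        (rec.id, str(rec.seq).upper().replace(".", GAP)) for rec in aln
    )
    rf_mask = None
    rf = aln.column_annotations.get("reference_annotation")
    if rf is not None:
        rf_mask = tuple(c not in ".-~" for c in rf)
    return FamilyAlignment(family_id=family_id, rows=rows, rf_mask=rf_mask)


def write_alignment(aln: FamilyAlignment, path: str | Path, dialect: str = "fasta") -> None:
    recs = [
        _BioSeqRecord(Seq(gapped), id=acc, description="") for acc, gapped in aln.rows
    ]
    AlignIO.write(AlignIO.MultipleSeqAlignment(recs), str(path), dialect)


# ---------------------------------------------------------------------------
# TSV tables


def read_master_list(path: str | Path) -> MasterList:
    """Read a two-column TSV (family_id, accession) into a MasterList."""
    families: dict[str, set[str]] = {}
    n = 0
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t")
        if parts[0] == "family_id":  # optional header
            continue
        if len(parts) < 2:
            raise FormatError(f"master list line has fewer than 2 columns: {line!r}")
        fam, acc = parts[0], parts[1]
        families.setdefault(fam, set()).add(acc)
        n += 1
    if n == 0:
        logger.warning("master list %s is empty", path)
    return MasterList(families={f: frozenset(a) for f, a in families.items()})


def write_master_list(master: MasterList, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("family_id\taccession\n")
        for fam in sorted(master.families):
            for acc in sorted(master.families[fam]):
                fh.write(f"{fam}\t{acc}\n")


def read_taxonomy(path: str | Path) -> Taxonomy:
    """Read a species taxonomy TSV: species_id, phylum_class, group.

    The basal-to-derived group ordering is taken from a
    ``#group_order=a,b,c`` comment line when present, otherwise from the
    order of first appearance in the file.
    """
    species: dict[str, tuple[str, str]] = {}
    order: list[str] = []
    explicit: tuple[str, ...] | None = None
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line:
            continue
        if line.startswith("#"):
            if line.startswith("#group_order="):
                explicit = tuple(
                    g.strip() for g in line.split("=", 1)[1].split(",") if g.strip()
                )
            continue
        parts = line.split("\t")
        if parts[0] == "species_id":
            continue
        if len(parts) < 3:
            raise FormatError(f"taxonomy line has fewer than 3 columns: {line!r}")
        sp, phylum, group = parts[0], parts[1], parts[2]
        if sp in species:
            raise FormatError(f"species {sp!r} listed twice in taxonomy")
        species[sp] = (phylum, group)
        if group not in order:
            order.append(group)
    return Taxonomy(species=species, group_order=explicit or tuple(order))


def write_taxonomy(tax: Taxonomy, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("#group_order=" + ",".join(tax.group_order) + "\n")
        fh.write("species_id\tphylum_class\tgroup\n")
        for sp in sorted(tax.species):
            phylum, group = tax.species[sp]
            fh.write(f"{sp}\t{phylum}\t{group}\n")


def read_proteome_dir(path: str | Path) -> dict[str, list[SequenceRecord]]:
    """Load every ``<species_id>.fasta`` in a directory as that species' proteome."""
    proteomes: dict[str, list[SequenceRecord]] = {}
    for f in sorted(Path(path).glob("*.fasta")):
        sp = f.stem
        proteomes[sp] = read_fasta(f, species_id=sp)
    return proteomes
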