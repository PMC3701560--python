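"""Synthetic multi-species proteomes with planted gene-family members.

The simulator evolves each family's root protein down a fixed species
topology (root -> group ancestor -> phylum ancestor -> species) that
mirrors a four-group eukaryote taxonomy at desk scale.  Families are
introduced at a chosen group and exist only in that group and the more
derived ones; members can be lost per species, duplicated within a
species, and are surrounded by decoys (shuffled members plus random
background proteins).  Column homology is tracked through every indel,
so true multiple alignments of any member subset come for free - the
seed alignments handed to the pipeline are exactly the reference
species' members projected onto their shared columns.

Substitutions are sampled from a BLOSUM62-derived conditional model so
diverged members stay detectable the way real homologs are; each root
carries a 28-residue low-entropy signature core (anchored by two Cys and
two His, echoing a C2H2-type zinc finger) that mutates at a quarter of
the global rate and never takes indels.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from Bio.Align import substitution_matrices

from .formats_io import (
    AMINO_ACIDS,
    GAP,
    FamilyAlignment,
    MasterList,
    SequenceRecord,
    Taxonomy,
    write_alignment,
    write_fasta,
    write_master_list,
    write_taxonomy,
)

_AA = np.array(list(AMINO_ACIDS))
_AA_INDEX = {a: i for i, a in enumerate(AMINO_ACIDS)}


def default_taxonomy() -> Taxonomy:
    """20 species in 8 phyla across the four canonical groups."""
    species: dict[str, tuple[str, str]] = {}
    layout = [
        ("protist", [("P_alpha", 3), ("P_beta", 2)]),
        ("plant", [("L_alpha", 3), ("L_beta", 2)]),
        ("fungus", [("F_alpha", 3), ("F_beta", 2)]),
        ("metazoan", [("M_alpha", 3), ("M_beta", 2)]),
    ]
    i = 0
    for group, phyla in layout:
        for phylum, n in phyla:
            for _ in range(n):
                i += 1
                species[f"SP{i:02d}"] = (phylum, group)
    return Taxonomy(species=species, group_order=("protist", "plant", "fungus", "metazoan"))


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for one synthetic corpus.

    Defaults describe the standard benchmark: 20 species in 4 groups and
    8 phyla, 6 families of length 300 introduced at staggered groups,
    per-branch substitution probability 0.15/site (core at a quarter of
    that), indels at 0.01/site with geometric mean length 2, per-species
    loss probability 0.1, within-species duplication probability 0.1, and
    50 decoys per species.  The three metazoan species of phylum M_alpha
    serve as the reference proteomes whose members seed the master list.
    """

    rng_seed: int = 0
    n_families: int = 6
    family_length: int = 300
    substitution_prob: float = 0.15
    core_length: int = 28
    core_rate_factor: float = 0.25
    indel_prob: float = 0.01
    indel_mean_length: float = 2.0
    loss_prob: float = 0.1
    duplication_prob: float = 0.1
    dup_divergence: float = 0.02
    n_decoys: int = 50
    taxonomy: Taxonomy = field(default_factory=default_taxonomy)
    reference_species: tuple[str, ...] = ("SP16", "SP17", "SP18")
    introduction_groups: tuple[str, ...] | None = None
    forced_losses: tuple[tuple[str, str], ...] = ()
    loner_family: bool = False

    def __post_init__(self) -> None:
        for name in ("substitution_prob", "indel_prob", "loss_prob", "duplication_prob"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.n_families < 1 or self.family_length < 1:
            raise ValueError("counts must be >= 1")
        missing = set(self.reference_species) - set(self.taxonomy.species)
        if missing:
            raise ValueError(f"reference species {sorted(missing)} not in taxonomy")

    def family_ids(self) -> list[str]:
        fams = [f"FAM{i + 1}" for i in range(self.n_families)]
        if self.loner_family:
            fams.append("FAMLONER")
        return fams

    def introduction_group_of(self, family_id: str) -> str:
        order = self.taxonomy.group_order
        if family_id == "FAMLONER":
            return order[-1]
        i = int(family_id[3:]) - 1
        if self.introduction_groups is not None:
            return self.introduction_groups[i]
        return order[(i * len(order)) // self.n_families]


@dataclass(frozen=True)
class TruthTable:
    """Ground truth for one simulated corpus."""

    members: dict[tuple[str, str], tuple[str, ...]]  # (species, family) -> accessions
    losses: tuple[tuple[str, str], ...]
    duplications: tuple[tuple[str, str, str], ...]  # (species, family, accession)
    decoys: frozenset[str]

    def __post_init__(self) -> None:
        fam_of: dict[str, str] = {}
        for (sp, fam), accs in self.members.items():
            for acc in accs:
                if acc in self.decoys:
                    raise ValueError(f"accession {acc} is both member and decoy")
                if acc in fam_of and fam_of[acc] != fam:
                    raise ValueError(f"accession {acc} planted in two families")
                fam_of[acc] = fam

    def member_accessions(self) -> frozenset[str]:
        return frozenset(a for accs in self.members.values() for a in accs)

    def family_of(self, accession: str) -> str | None:
        for (sp, fam), accs in self.members.items():
            if accession in accs:
                return fam
        return None


@dataclass
class SimulatedCorpus:
    proteomes: dict[str, list[SequenceRecord]]
    seed_alignments: dict[str, FamilyAlignment]
    reference_db: list[SequenceRecord]
    master: MasterList
    taxonomy: Taxonomy
    truth: TruthTable
    #: full true alignments (all members) per family, for diagnostics
    full_alignments: dict[str, FamilyAlignment]


# ---------------------------------------------------------------------------
# BLOSUM62-conditional substitution model


def _conditional_substitution_matrix() -> np.ndarray:
    """P(b | a, b != a) derived from BLOSUM62 target frequencies.

    BLOSUM62 half-bit scores satisfy s_ab = 2*log2(q_ab / (p_a p_b));
    inverting with the matrix's marginal frequencies gives the joint
    q_ab, whose off-diagonal rows normalise to the conditional mutation
    distribution.
    """
    m = substitution_matrices.load("BLOSUM62")
    s = np.array([[m[a][b] for b in AMINO_ACIDS] for a in AMINO_ACIDS])
    # marginals: solve q row sums iteratively is overkill; use the
    # standard BLOSUM62 background frequencies shipped as half-bit priors
    q = np.power(2.0, s / 2.0)
    p = _background()
    q = q * p[:, None] * p[None, :]
    np.fill_diagonal(q, 0.0)
    return q / q.sum(axis=1, keepdims=True)


def _background() -> np.ndarray:
    """Robinson-Robinson style amino-acid frequencies (normalised)."""
    freqs = {
        "A": 0.078, "C": 0.019, "D": 0.053, "E": 0.063, "F": 0.039,
        "G": 0.072, "H": 0.023, "I": 0.053, "K": 0.059, "L": 0.091,
        "M": 0.022, "N": 0.045, "P": 0.052, "Q": 0.042, "R": 0.051,
        "S": 0.068, "T": 0.059, "V": 0.066, "W": 0.014, "Y": 0.032,
    }
    p = np.array([freqs[a] for a in AMINO_ACIDS])
    return p / p.sum()


# ---------------------------------------------------------------------------
# Column-tracked sequences


class _ColumnRegistry:
    """Allocates alignment columns and keeps their global order."""

    def __init__(self, n: int) -> None:
        self.order: list[int] = list(range(n))
        self._next = n

    def new_after(self, anchor: int | None, count: int) -> list[int]:
        """Insert ``count`` fresh columns right after ``anchor`` (None = front)."""
        ids = list(range(self._next, self._next + count))
        self._next += count
        pos = 0 if anchor is None else self.order.index(anchor) + 1
        self.order[pos:pos] = ids
        return ids


@dataclass
class _TrackedSeq:
    cols: list[int]  # column ids in order
    residues: list[str]

    def copy(self) -> "_TrackedSeq":
        return _TrackedSeq(list(self.cols), list(self.residues))

    def to_string(self) -> str:
        return "".join(self.residues)


def _evolve(
    seq: _TrackedSeq,
    registry: _ColumnRegistry,
    core_cols: frozenset[int],
    cfg: SimConfig,
    rng: np.random.Generator,
    sub_matrix: np.ndarray,
    background: np.ndarray,
    sub_prob: float | None = None,
    allow_indels: bool = True,
) -> _TrackedSeq:
    """One branch of evolution: substitutions then indels."""
    p = cfg.substitution_prob if sub_prob is None else sub_prob
    child = seq.copy()
    # substitutions
    for i, (col, res) in enumerate(zip(child.cols, child.residues)):
        rate = p * cfg.core_rate_factor if col in core_cols else p
        if rng.random() < rate:
            a = _AA_INDEX[res]
            child.residues[i] = str(rng.choice(_AA, p=sub_matrix[a]))
    if not allow_indels or cfg.indel_prob == 0.0:
        return child
    # indels: scan a snapshot of positions; geometric lengths, mean as configured
    geom_p = min(1.0, 1.0 / cfg.indel_mean_length)
    i = 0
    while i < len(child.cols):
        col = child.cols[i]
        if col not in core_cols and rng.random() < cfg.indel_prob:
            length = int(rng.geometric(geom_p))
            if rng.random() < 0.5 and len(child.cols) > length + 10:
                # deletion of up to `length` columns (core columns stop it)
                end = i
                while (
                    end < len(child.cols)
                    and end - i < length
                    and child.cols[end] not in core_cols
                ):
                    end += 1
                del child.cols[i:end]
                del child.residues[i:end]
                continue  # do not advance; next column now at i
            else:
                new_ids = registry.new_after(col, length)
                new_res = [str(a) for a in rng.choice(_AA, size=length, p=background)]
                child.cols[i + 1 : i + 1] = new_ids
                child.residues[i + 1 : i + 1] = new_res
                i += length
        i += 1
    return child


def _project(rows: list[tuple[str, _TrackedSeq]], registry: _ColumnRegistry, family_id: str) -> FamilyAlignment:
    """Project tracked sequences onto their jointly occupied columns."""
    used = set()
    for _, ts in rows:
        used.update(ts.cols)
    cols = [c for c in registry.order if c in used]
    index = {c: i for i, c in enumerate(cols)}
    out_rows = []
    for acc, ts in rows:
        row = [GAP] * len(cols)
        for c, r in zip(ts.cols, ts.residues):
            row[index[c]] = r
        out_rows.append((acc, "".join(row)))
    return FamilyAlignment(family_id=family_id, rows=tuple(out_rows))


# ---------------------------------------------------------------------------
# Decoys


def shuffle_decoy(seq: SequenceRecord, seed: int) -> SequenceRecord:
    """A uniform random permutation of the residues (same composition).

    For sequences of length >= 10 the permutation is resampled in the
    (astronomically rare) event that it reproduces the source.
    """
    rng = np.random.default_rng(seed)
    res = list(seq.residues)
    while True:
        perm = rng.permutation(len(res))
        shuffled = "".join(res[i] for i in perm)
        if shuffled != seq.residues or len(res) < 10:
            break
    return SequenceRecord(
        accession=f"{seq.accession}_shuf", residues=shuffled, species_id=seq.species_id
    )


# ---------------------------------------------------------------------------
# The generator


def simulate(cfg: SimConfig) -> SimulatedCorpus:
    """Generate a corpus: proteomes, seed alignments, master list, truth."""
    rng = np.random.default_rng(cfg.rng_seed)
    tax = cfg.taxonomy
    order = tax.group_order
    rank = {g: i for i, g in enumerate(order)}
    sub_matrix = _conditional_substitution_matrix()
    background = _background()

    members: dict[tuple[str, str], list[SequenceRecord]] = {}
    losses: list[tuple[str, str]] = []
    duplications: list[tuple[str, str, str]] = []
    full_alignments: dict[str, FamilyAlignment] = {}
    seed_alignments: dict[str, FamilyAlignment] = {}

    forced_by_family: dict[str, list[str]] = {}
    for sp, fam in cfg.forced_losses:
        forced_by_family.setdefault(fam, []).append(sp)

    for fam in cfg.family_ids():
        intro = cfg.introduction_group_of(fam)
        L = cfg.family_length
        registry = _ColumnRegistry(L)
        # root: background residues with a low-entropy C2H2-like core
        root_res = [str(a) for a in rng.choice(_AA, size=L, p=background)]
        core_start = (L - cfg.core_length) // 2
        core_ids = list(range(core_start, core_start + cfg.core_length))
        # low-entropy signature: each core position strongly prefers one residue
        sig = [str(a) for a in rng.choice(_AA, size=cfg.core_length)]
        if cfg.core_length >= 24:
            sig[2], sig[5], sig[18], sig[22] = "C", "C", "H", "H"
        for i, c in enumerate(core_ids):
            root_res[c] = sig[i]
        root = _TrackedSeq(cols=list(range(L)), residues=root_res)
        core_cols = frozenset(core_ids)

        def branch(s: _TrackedSeq) -> _TrackedSeq:
            return _evolve(s, registry, core_cols, cfg, rng, sub_matrix, background)

        if fam == "FAMLONER":
            # present in exactly one (reference) species, as two
            # near-identical copies so a seed alignment exists
            sp = cfg.reference_species[0]
            m1 = branch(root)
            m2 = _evolve(
                m1, registry, core_cols, cfg, rng, sub_matrix, background,
                sub_prob=cfg.dup_divergence, allow_indels=False,
            )
            rows = [(f"{sp}_{fam}_m1", m1), (f"{sp}_{fam}_m2", m2)]
            for acc, ts in rows:
                members.setdefault((sp, fam), []).append(
                    SequenceRecord(accession=acc, residues=ts.to_string(), species_id=sp)
                )
            duplications.append((sp, fam, rows[1][0]))
            full_alignments[fam] = _project(rows, registry, fam)
            seed_alignments[fam] = full_alignments[fam]
            continue

        eligible_groups = [g for g in order if rank[g] >= rank[intro]]
        # random losses, skipping reference species, forced-loss targets and
        # the forced targets' phylum peers (so forced holes stay clean)
        forced_sps = forced_by_family.get(fam, [])
        protected = set(cfg.reference_species) | set(forced_sps)
        for sp in forced_sps:
            protected.update(tax.species_in_phylum(tax.phylum_of(sp)))

        tracked_rows: list[tuple[str, _TrackedSeq]] = []
        for group in eligible_groups:
            g_anc = branch(root)
            for phylum in sorted(
                {tax.phylum_of(sp) for sp in tax.species_in_group(group)}
            ):
                p_anc = branch(g_anc)
                for sp in tax.species_in_phylum(phylum):
                    lost = (sp, fam) in cfg.forced_losses or (
                        sp not in protected and rng.random() < cfg.loss_prob
                    )
                    if lost:
                        losses.append((sp, fam))
                        continue
                    tip = branch(p_anc)
                    acc = f"{sp}_{fam}_m1"
                    tracked_rows.append((acc, tip))
                    members.setdefault((sp, fam), []).append(
                        SequenceRecord(accession=acc, residues=tip.to_string(), species_id=sp)
                    )
                    if rng.random() < cfg.duplication_prob:
                        dup = _evolve(
                            tip, registry, core_cols, cfg, rng, sub_matrix, background,
                            sub_prob=cfg.dup_divergence, allow_indels=False,
                        )
                        dacc = f"{sp}_{fam}_m2"
                        tracked_rows.append((dacc, dup))
                        members[(sp, fam)].append(
                            SequenceRecord(accession=dacc, residues=dup.to_string(), species_id=sp)
                        )
                        duplications.append((sp, fam, dacc))

        full_alignments[fam] = _project(tracked_rows, registry, fam)
        ref_rows = [
            (acc, ts) for acc, ts in tracked_rows if acc.split("_")[0] in cfg.reference_species
        ]
        if len(ref_rows) < 2:
            raise RuntimeError(
                f"family {fam}: fewer than 2 reference members; cannot seed an alignment"
            )
        seed_alignments[fam] = _project(ref_rows, registry, fam)

    # --- decoys
    decoys: set[str] = set()
    proteomes: dict[str, list[SequenceRecord]] = {}
    for sp in sorted(tax.species):
        prot = []
        own_members = [
            rec for (s, f), recs in sorted(members.items()) if s == sp for rec in recs
        ]
        prot.extend(own_members)
        n_shuf = cfg.n_decoys // 2
        for i in range(cfg.n_decoys):
            if i < n_shuf and own_members:
                src = own_members[i % len(own_members)]
                d = shuffle_decoy(src, seed=int(rng.integers(2**31)))
                rec = SequenceRecord(
                    accession=f"{sp}_DS{i:02d}", residues=d.residues, species_id=sp
                )
            else:
                L = int(rng.integers(150, 451))
                res = "".join(str(a) for a in rng.choice(_AA, size=L, p=background))
                rec = SequenceRecord(accession=f"{sp}_DR{i:02d}", residues=res, species_id=sp)
            decoys.add(rec.accession)
            prot.append(rec)
        proteomes[sp] = prot

    reference_db = [
        rec for sp in cfg.reference_species for rec in proteomes[sp]
    ]
    master = MasterList(
        families={
            fam: frozenset(
                rec.accession
                for sp in cfg.reference_species
                for rec in members.get((sp, fam), [])
            )
            for fam in cfg.family_ids()
            if any(members.get((sp, fam)) for sp in cfg.reference_species)
        }
    )

    truth = TruthTable(
        members={k: tuple(r.accession for r in v) for k, v in sorted(members.items())},
        losses=tuple(sorted(losses)),
        duplications=tuple(sorted(duplications)),
        decoys=frozenset(decoys),
    )
    return SimulatedCorpus(
        proteomes=proteomes,
        seed_alignments=seed_alignments,
        reference_db=reference_db,
        master=master,
        taxonomy=tax,
        truth=truth,
        full_alignments=full_alignments,
    )


def write_corpus(corpus: SimulatedCorpus, outdir: str | Path) -> None:
    """Write a corpus in the directory layout the pipeline CLI expects."""
    out = Path(outdir)
    (out / "proteomes").mkdir(parents=True, exist_ok=True)
    (out / "families").mkdir(exist_ok=True)
    for sp, recs in sorted(corpus.proteomes.items()):
        write_fasta(recs, out / "proteomes" / f"{sp}.fasta")
    for fam, aln in sorted(corpus.seed_alignments.items()):
        write_alignment(aln, out / "families" / f"{fam}.fasta")
    write_fasta(corpus.reference_db, out / "refdb.fasta")
    write_master_list(corpus.master, out / "master.tsv")
    write_taxonomy(corpus.taxonomy, out / "taxonomy.tsv")
    with open(out / "truth_members.tsv", "w") as fh:
        fh.write("species_id\tfamily_id\taccession\n")
        for (sp, fam), accs in sorted(corpus.truth.members.items()):
            for acc in accs:
                fh.write(f"{sp}\t{fam}\t{acc}\n")
    with open(out / "truth_losses.tsv", "w") as fh:
        fh.write("species_id\tfamily_id\n")
        for sp, fam in corpus.truth.losses:
            fh.write(f"{sp}\t{fam}\n")
    with open(out / "truth_decoys.tsv", "w") as fh:
        fh.write("accession\n")
        for acc in sorted(corpus.truth.decoys):
            fh.write(acc + "\n")
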