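"""Curated gene-block metadata for the 37 deeply conserved C2H2
zinc-finger families.

These lists transcribe the published block structure of the 37 families
across 124 eukaryotic genomes: which families are present in essentially
all eukaryotes, which were added with plants, amoebozoans, fungi, and
the successive metazoan additions (choanozoans, poriferans, cnidarians,
bilaterians).  They serve as reference inputs for counting summaries and
as a realistic template for block-structured simulations; the package
never treats them as something it can rediscover from sequence data it
does not ship.
"""

from __future__ import annotations

#: Present in (almost) all eukaryotes: the most basal block.
UNIVERSAL_FAMILIES: tuple[str, ...] = (
    "SF3A2",
    "SF3A3",
    "KIN17",
    "ZNF598",
    "ZNF622",
    "ZMAT2",
    "ZNF207",
)

#: Added with the plants (Streptophyta; absent from green algae).
PLANT_ADDITIONS: tuple[str, ...] = ("TFIIIA", "YY1")

#: Present additionally in Amoebozoa (and again in lower metazoans),
#: though absent from plants and fungi.
AMOEBOZOA_ADDITIONS: tuple[str, ...] = ("ZNF277", "ZIC")

#: The fungal block: TFIIIA shared with plants, GLI new.
FUNGI_FAMILIES: tuple[str, ...] = ("TFIIIA", "GLI")

#: Metazoan additions, by the lineage where each first appears.
CHOANOZOA_ADDITIONS: tuple[str, ...] = ("KLF", "JAZ", "BLIMP", "EVI1")
PORIFERA_ADDITIONS: tuple[str, ...] = ("SP", "EGR", "ZXD", "MTF1")
CNIDARIA_ADDITIONS: tuple[str, ...] = ("SNAIL", "OVO", "GFI", "IA1", "FEZ", "PRDM13")
BILATERIA_ADDITIONS: tuple[str, ...] = (
    "ZNF384",
    "ZNF362",
    "ZEP",
    "DISCO",
    "RREB",
    "OAZ",
    "CTCF",
    "OSR",
    "SPALT",
    "ZFHX1",
    "ZEB",
)

#: Number of genomes surveyed per taxonomic group.
GROUP_GENOME_COUNTS: dict[str, int] = {
    "protists": 30,
    "plants": 16,
    "fungi": 28,
    "metazoans": 50,
}


def metazoan_block_families() -> tuple[str, ...]:
    """The families first appearing within the metazoans."""
    return (
        CHOANOZOA_ADDITIONS
        + PORIFERA_ADDITIONS
        + CNIDARIA_ADDITIONS
        + BILATERIA_ADDITIONS
    )


def all_families() -> frozenset[str]:
    """The full set of distinct conserved families across all blocks."""
    return frozenset(
        UNIVERSAL_FAMILIES
        + PLANT_ADDITIONS
        + AMOEBOZOA_ADDITIONS
        + FUNGI_FAMILIES
        + metazoan_block_families()
    )


def family_block_table() -> dict[str, str]:
    """family -> most basal block where it appears."""
    table: dict[str, str] = {}
    for fams, block in (
        (UNIVERSAL_FAMILIES, "protists"),
        (PLANT_ADDITIONS, "plants"),
        (AMOEBOZOA_ADDITIONS, "amoebozoa"),
        (FUNGI_FAMILIES, "fungi"),
        (metazoan_block_families(), "metazoans"),
    ):
        for f in fams:
            table.setdefault(f, block)
    return table


def total_genomes() -> int:
    return sum(GROUP_GENOME_COUNTS.values())
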