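"""Taxon codes and clade structure for the five-proboscidean study design.

The analysis samples four elephantid taxa — African forest (F) and savanna (S)
elephants, Asian elephant (A) and woolly mammoth (M) — each as one diploid
individual (two chromosomes), plus a single haploid American mastodon (O)
consensus sequence used exclusively as the outgroup for polarizing alleles.
The species topology is fixed throughout: (((F,S),(A,M)),O), with F+S forming
the African (Loxodonta) clade and A+M the "Eurasian" clade.
"""

from __future__ import annotations

from enum import Enum


class Taxon(str, Enum):
    """Single-letter taxon codes used in site tables and reports."""

    FOREST = "F"
    SAVANNA = "S"
    ASIAN = "A"
    MAMMOTH = "M"
    MASTODON = "O"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


#: The four ingroup taxa, sampled as diploids (two chromosomes each).
ELEPHANTIDS: tuple[Taxon, ...] = (
    Taxon.FOREST,
    Taxon.SAVANNA,
    Taxon.ASIAN,
    Taxon.MAMMOTH,
)

#: African side of the deepest ingroup split (genus Loxodonta).
AFRICAN: frozenset[Taxon] = frozenset({Taxon.FOREST, Taxon.SAVANNA})

#: "Eurasian" side (Elephas + Mammuthus; the ancestral ranges included Africa).
EURASIAN: frozenset[Taxon] = frozenset({Taxon.ASIAN, Taxon.MAMMOTH})

#: Haploid outgroup.
OUTGROUP: Taxon = Taxon.MASTODON

#: Number of chromosomes sampled per taxon.
PLOIDY: dict[Taxon, int] = {
    Taxon.FOREST: 2,
    Taxon.SAVANNA: 2,
    Taxon.ASIAN: 2,
    Taxon.MAMMOTH: 2,
    Taxon.MASTODON: 1,
}

LONG_NAMES: dict[Taxon, str] = {
    Taxon.FOREST: "Forest",
    Taxon.SAVANNA: "Savanna",
    Taxon.ASIAN: "Asian",
    Taxon.MAMMOTH: "Mammoth",
    Taxon.MASTODON: "Mastodon",
}


def clade_of(taxon: Taxon) -> str:
    """Return 'African', 'Eurasian' or 'outgroup' for a taxon code."""
    if taxon in AFRICAN:
        return "African"
    if taxon in EURASIAN:
        return "Eurasian"
    return "outgroup"


def parse_taxon(code: str) -> Taxon:
    try:
        return Taxon(code)
    except ValueError as exc:
        raise ValueError(f"unknown taxon code {code!r}; expected one of F,S,A,M,O") from exc
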