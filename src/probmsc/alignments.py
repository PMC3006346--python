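"""Per-locus sequence alignments and the multilocus sequential-PHYLIP dialect.

The multilocus format is the one consumed by coalescent inference programs in
the MCMCcoal/BPP family: many sequential-PHYLIP blocks concatenated in one
file, each block holding one anonymous amplicon locus.  A block starts with a
``n_sequences  length`` header line followed by one line per sequence
(label, whitespace, bases).  Loci are short (~106 bp on average) anonymous
amplicons; positions are 1-based within a locus and carry no genome
coordinates.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

from .taxa import ELEPHANTIDS, LONG_NAMES, OUTGROUP, Taxon

VALID_BASES = frozenset("ACGTN")


class PhylipFormatError(ValueError):
    """Raised for malformed multilocus PHYLIP input, naming the bad block."""


@dataclass
class LocusAlignment:
    """Aligned sequences for one locus, keyed by sample label.

    Invariants: all sequences have equal length matching ``length``; bases are
    A/C/G/T/N.  ``sample_to_taxon`` maps each sample label to its taxon code.
    """

    locus_id: str
    sequences: dict[str, str]
    sample_to_taxon: dict[str, Taxon]
    length: int = field(default=0)

    def __post_init__(self) -> None:
        if not self.sequences:
            raise ValueError(f"locus {self.locus_id}: no sequences")
        lengths = {len(s) for s in self.sequences.values()}
        if len(lengths) != 1:
            raise ValueError(f"locus {self.locus_id}: unequal sequence lengths {sorted(lengths)}")
        (n,) = lengths
        if self.length == 0:
            self.length = n
        elif self.length != n:
            raise ValueError(
                f"locus {self.locus_id}: declared length {self.length} != sequence length {n}"
            )
        for label, seq in self.sequences.items():
            bad = set(seq.upper()) - VALID_BASES
            if bad:
                raise ValueError(f"locus {self.locus_id}, sample {label}: invalid bases {sorted(bad)}")
            self.sequences[label] = seq.upper()

    def samples_for(self, taxon: Taxon) -> list[str]:
        return [s for s, t in self.sample_to_taxon.items() if t == taxon and s in self.sequences]

    def column(self, pos: int) -> dict[str, str]:
        """1-based alignment column as sample -> base."""
        return {s: seq[pos - 1] for s, seq in self.sequences.items()}


def infer_taxon(label: str) -> Taxon:
    """Map a sample label to a taxon: long-name prefix first, then the
    leading single-letter code ('Mastodon' must not collapse onto M)."""
    low = label.lower()
    for taxon, name in LONG_NAMES.items():
        if low.startswith(name.lower()):
            return taxon
    try:
        return Taxon(label[0].upper())
    except (ValueError, IndexError):
        raise ValueError(f"cannot infer taxon from sample label {label!r}")


def default_sample_map(labels: Iterable[str]) -> dict[str, Taxon]:
    return {label: infer_taxon(label) for label in labels}


_HEADER_RE = re.compile(r"^\s*(\d+)\s+(\d+)\s*$")


def read_phylip_multilocus(
    path: str | Path,
    sample_map: Mapping[str, Taxon] | None = None,
) -> list[LocusAlignment]:
    """Read concatenated sequential-PHYLIP blocks into LocusAlignments.

    ``sample_map`` maps sample labels to taxa; labels absent from the map are
    resolved with :func:`infer_taxon` and reported in the error if that fails.
    Loci are numbered ``L001`` ... in file order.
    """
    text = Path(path).read_text()
    lines = text.splitlines()
    loci: list[LocusAlignment] = []
    i = 0
    block = 0
    # skip leading blank lines
    while i < len(lines) and not lines[i].strip():
        i += 1
    if i >= len(lines):
        raise PhylipFormatError(f"{path}: empty file")
    while i < len(lines):
        if not lines[i].strip():
            i += 1
            continue
        block += 1
        m = _HEADER_RE.match(lines[i])
        if not m:
            raise PhylipFormatError(
                f"{path}: block {block}: expected 'n_seqs length' header, got {lines[i]!r}"
            )
        nseq, length = int(m.group(1)), int(m.group(2))
        i += 1
        sequences: dict[str, str] = {}
        for _ in range(nseq):
            # a sequence may span several lines until `length` bases are read
            while i < len(lines) and not lines[i].strip():
                i += 1
            if i >= len(lines):
                raise PhylipFormatError(f"{path}: block {block}: truncated (missing sequences)")
            parts = lines[i].split(None, 1)
            label = parts[0]
            seq = re.sub(r"\s+", "", parts[1]) if len(parts) > 1 else ""
            i += 1
            while len(seq) < length and i < len(lines):
                nxt = lines[i].strip()
                if not nxt:
                    break
                chunk = re.sub(r"\s+", "", nxt)
                if set(chunk.upper()) - VALID_BASES:
                    break  # next label line, not sequence continuation
                seq += chunk
                i += 1
            if len(seq) != length:
                raise PhylipFormatError(
                    f"{path}: block {block}: sample {label!r} has {len(seq)} bases, "
                    f"header declares {length}"
                )
            if label in sequences:
                raise PhylipFormatError(f"{path}: block {block}: duplicate sample label {label!r}")
            sequences[label] = seq.upper()
        locus_id = f"L{block:03d}"
        smap: dict[str, Taxon] = {}
        unknown: list[str] = []
        for label in sequences:
            if sample_map is not None and label in sample_map:
                smap[label] = Taxon(sample_map[label])
            else:
                try:
                    smap[label] = infer_taxon(label)
                except ValueError:
                    unknown.append(label)
        if unknown:
            raise PhylipFormatError(
                f"{path}: block {block}: unknown sample labels {unknown}; supply a sample_map"
            )
        try:
            loci.append(LocusAlignment(locus_id, sequences, smap, length))
        except ValueError as exc:
            raise PhylipFormatError(f"{path}: block {block}: {exc}") from exc
    return loci


def write_phylip_multilocus(loci: Iterable[LocusAlignment], path: str | Path) -> None:
    """Write LocusAlignments as concatenated sequential-PHYLIP blocks.

    Sample labels are truncated to 10 characters (the dialect's limit).
    """
    out = []
    for locus in loci:
        out.append(f"{len(locus.sequences)}  {locus.length}")
        for label, seq in locus.sequences.items():
            out.append(f"{label[:10]:<10}  {seq}")
        out.append("")
    Path(path).write_text("\n".join(out) + "\n")


def total_alignment_bp(loci: Iterable[LocusAlignment]) -> int:
    return sum(l.length for l in loci)


def check_site_calling_ready(locus: LocusAlignment) -> None:
    """Site calling needs >=1 sequence per elephantid taxon and a mastodon."""
    for taxon in (*ELEPHANTIDS, OUTGROUP):
        if not locus.samples_for(taxon):
            raise ValueError(f"locus {locus.locus_id}: no sequence for taxon {taxon.value}")
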