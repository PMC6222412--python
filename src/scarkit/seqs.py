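"""Sequence records, FASTA I/O, IUPAC semantics and primer physical properties.

Coordinates are 0-based half-open internally; anything user-facing
(reports, error messages) is 1-based inclusive.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

from Bio import SeqIO

#: Expansion sets of the IUPAC nucleotide codes.
IUPAC_SETS: dict[str, frozenset[str]] = {
    "A": frozenset("A"),
    "C": frozenset("C"),
    "G": frozenset("G"),
    "T": frozenset("T"),
    "R": frozenset("AG"),
    "Y": frozenset("CT"),
    "S": frozenset("GC"),
    "W": frozenset("AT"),
    "K": frozenset("GT"),
    "M": frozenset("AC"),
    "B": frozenset("CGT"),
    "D": frozenset("AGT"),
    "H": frozenset("ACT"),
    "V": frozenset("ACG"),
    "N": frozenset("ACGT"),
}

IUPAC_CODES = frozenset(IUPAC_SETS)
GAP = "-"
VALID_CHARS = IUPAC_CODES | {GAP}

_COMPLEMENT = {
    "A": "T", "T": "A", "G": "C", "C": "G",
    "R": "Y", "Y": "R", "S": "S", "W": "W",
    "K": "M", "M": "K", "B": "V", "V": "B",
    "D": "H", "H": "D", "N": "N",
}


class SequenceError(ValueError):
    """Raised for malformed sequences or files."""


@dataclass
class SeqRecord:
    """A single DNA sequence with a species label.

    ``bases`` is the uppercase sequence over the IUPAC alphabet; the gap
    character ``-`` is only meaningful inside an :class:`Alignment`.
    """

    id: str
    bases: str
    species: str = "unknown"
    description: str = ""

    def __post_init__(self) -> None:
        self.bases = self.bases.upper().replace("U", "T")
        if not self.bases:
            raise SequenceError(f"record {self.id!r}: empty sequence")
        for pos, ch in enumerate(self.bases):
            if ch not in VALID_CHARS:
                raise SequenceError(
                    f"record {self.id!r}: non-IUPAC character {ch!r} at position {pos + 1}"
                )

    def __len__(self) -> int:
        return len(self.bases)

    @property
    def ungapped(self) -> str:
        return self.bases.replace(GAP, "")


@dataclass
class Alignment:
    """An ordered multiple alignment; all records share one length."""

    records: list[SeqRecord]

    def __post_init__(self) -> None:
        if len(self.records) < 2:
            raise SequenceError("alignment needs at least 2 records")
        lengths = {len(r) for r in self.records}
        if len(lengths) != 1:
            raise SequenceError(f"unequal aligned lengths: {sorted(lengths)}")

    @property
    def aligned_length(self) -> int:
        return len(self.records[0])

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def column(self, i: int) -> str:
        return "".join(r.bases[i] for r in self.records)


@dataclass
class SpeciesPanel:
    """A reference alignment whose records are grouped by species label."""

    alignment: Alignment
    species_map: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.species_map:
            self.species_map = {r.id: r.species for r in self.alignment}
        missing = [r.id for r in self.alignment if r.id not in self.species_map]
        if missing:
            raise SequenceError(f"records without species label: {missing}")
        for rec in self.alignment:
            rec.species = self.species_map[rec.id]
        if len(self.species) < 2:
            raise SequenceError("panel needs at least 2 distinct species")

    @property
    def species(self) -> list[str]:
        seen: dict[str, None] = {}
        for rec in self.alignment:
            seen.setdefault(rec.species, None)
        return list(seen)

    def records_of(self, species: str) -> list[SeqRecord]:
        return [r for r in self.alignment if r.species == species]

    def reference_of(self, species: str) -> SeqRecord:
        """First record of a species, used as the design reference."""
        recs = self.records_of(species)
        if not recs:
            raise SequenceError(f"species {species!r} not in panel")
        return recs[0]


def _parse_species(header_id: str, description: str, delimiter: str, field_index: int) -> tuple[str, str]:
    parts = header_id.split(delimiter)
    if len(parts) > field_index:
        return parts[0], parts[field_index]
    return header_id, "unknown"


def read_fasta(path: str | os.PathLike, delimiter: str = "|", species_field: int = 1) -> list[SeqRecord]:
    """Read a (multi-)FASTA into :class:`SeqRecord` objects.

    The species label is taken from the header ID split on ``delimiter``
    (default: second ``|``-delimited field), falling back to ``"unknown"``.
    ``U`` is normalised to ``T`` and case to upper.
    """
    records = []
    for rec in SeqIO.parse(os.fspath(path), "fasta"):
        rid, species = _parse_species(rec.id, rec.description, delimiter, species_field)
        records.append(SeqRecord(id=rid, bases=str(rec.seq), species=species, description=rec.description))
    if not records:
        raise SequenceError(f"{path}: no FASTA records found")
    return records


def write_fasta(records: list[SeqRecord], path: str | os.PathLike, delimiter: str = "|", width: int = 70) -> None:
    """Write records as FASTA, encoding species into the header as ``id|species``."""
    with open(path, "w") as fh:
        for rec in records:
            header = rec.id if rec.species == "unknown" else f"{rec.id}{delimiter}{rec.species}"
            fh.write(f">{header}\n")
            for i in range(0, len(rec.bases), width):
                fh.write(rec.bases[i : i + width] + "\n")


def read_panel(path: str | os.PathLike, delimiter: str = "|", species_field: int = 1) -> SpeciesPanel:
    """Read an aligned FASTA with ``id|species`` headers as a SpeciesPanel."""
    return SpeciesPanel(Alignment(read_fasta(path, delimiter, species_field)))


def revcomp(bases: str) -> str:
    """IUPAC-aware reverse complement; gaps are not allowed."""
    if GAP in bases:
        raise SequenceError("revcomp of gapped sequence is undefined")
    try:
        return "".join(_COMPLEMENT[b] for b in reversed(bases.upper()))
    except KeyError as exc:
        raise SequenceError(f"cannot complement {exc.args[0]!r}") from None


def gc_content(bases: str) -> float:
    """G+C fraction over unambiguous bases (gaps, N and most ambiguity
    codes excluded; S counts as G/C, W as A/T)."""
    bases = bases.upper()
    gc = sum(bases.count(c) for c in "GCS")
    at = sum(bases.count(c) for c in "ATW")
    if gc + at == 0:
        raise SequenceError("GC content undefined: no unambiguous bases")
    return gc / (gc + at)


def tm_wallace(primer: str) -> float:
    """Wallace-rule melting temperature 2(A+T) + 4(G+C), for 8-36 nt
    unambiguous primers."""
    primer = primer.upper()
    if not 8 <= len(primer) <= 36:
        raise SequenceError(f"Wallace rule valid for 8-36 nt, got {len(primer)}")
    if any(b not in "ACGT" for b in primer):
        raise SequenceError("Wallace Tm undefined for ambiguity codes")
    at = primer.count("A") + primer.count("T")
    gc = primer.count("G") + primer.count("C")
    return 2.0 * at + 4.0 * gc


def iupac_match(primer_base: str, template_base: str) -> bool:
    """True iff the IUPAC expansion sets of the two codes intersect.

    A gap on either side never matches (returns False, not an error).
    """
    p = IUPAC_SETS.get(primer_base.upper())
    t = IUPAC_SETS.get(template_base.upper())
    if p is None or t is None:
        return False
    return not p.isdisjoint(t)


def reverse_complement_record(rec: SeqRecord) -> SeqRecord:
    return SeqRecord(id=rec.id, bases=revcomp(rec.bases), species=rec.species, description=rec.description)
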