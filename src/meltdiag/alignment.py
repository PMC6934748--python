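"""Species-labelled multiple sequence alignments of mitochondrial mini-barcodes.

The unit of input for the whole toolkit is a pre-aligned, equal-length FASTA of
COI (or any protein-coding) fragments in which every record carries a species
label, by convention embedded in the header after a delimiter
(``>specimen07|marginata-like``). This module reads and validates such
alignments, translates codons under a selectable genetic code, and collapses
records to haplotypes — distinct sequence/species combinations with their
specimen membership.

Coordinates are 0-based half-open throughout; codon positions are reported as
1/2/3. ``N`` and ``-`` are treated as missing data, never as character states.
"""

from __future__ import annotations

import collections
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from Bio import SeqIO
from Bio.Data import CodonTable
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .errors import AlignmentError, AlphabetError, ConfigError, InputError

ALPHABET = frozenset("ACGTN-")
#: Value used for records whose species cannot be determined.
UNKNOWN_LABEL = "unknown"


@dataclass(frozen=True)
class AlignedRecord:
    specimen_id: str
    species_label: str
    sequence: str


@dataclass(frozen=True)
class LabelledAlignment:
    """Equal-length DNA alignment with one species label per record.

    Parameters
    ----------
    records
        One :class:`AlignedRecord` per specimen; ids must be unique, sequences
        equal length over the A/C/G/T/N/- alphabet.
    frame_offset
        0-based position of the first complete codon (0, 1 or 2).
    """

    records: tuple[AlignedRecord, ...]
    frame_offset: int = 0

    def __post_init__(self):
        if not self.records:
            raise InputError("alignment has no records")
        if self.frame_offset not in (0, 1, 2):
            raise ConfigError(f"frame_offset must be 0-2, got {self.frame_offset}")
        length = len(self.records[0].sequence)
        ids = set()
        for rec in self.records:
            if len(rec.sequence) != length:
                raise AlignmentError(
                    f"record {rec.specimen_id!r} has length {len(rec.sequence)}, "
                    f"expected {length}"
                )
            bad = set(rec.sequence) - ALPHABET
            if bad:
                raise AlphabetError(
                    f"record {rec.specimen_id!r} contains non-IUPAC "
                    f"characters {sorted(bad)}"
                )
            if rec.specimen_id in ids:
                raise InputError(f"duplicate specimen id {rec.specimen_id!r}")
            ids.add(rec.specimen_id)

    @property
    def length(self) -> int:
        return len(self.records[0].sequence)

    @property
    def species_labels(self) -> tuple[str, ...]:
        seen = dict.fromkeys(r.species_label for r in self.records)
        return tuple(seen)

    def records_for(self, species_label: str) -> tuple[AlignedRecord, ...]:
        recs = tuple(r for r in self.records if r.species_label == species_label)
        if not recs:
            raise InputError(f"no records labelled {species_label!r}")
        return recs

    def sequences_for(self, species_label: str) -> tuple[str, ...]:
        return tuple(r.sequence for r in self.records_for(species_label))

    def codon_position(self, column: int) -> int:
        """1-based codon position of an alignment column (1, 2 or 3)."""
        return (column - self.frame_offset) % 3 + 1


@dataclass(frozen=True)
class Haplotype:
    """A distinct sequence within one species, with its specimen membership."""

    sequence: str
    species_label: str
    members: tuple[str, ...] = field(default_factory=tuple)

    @property
    def count(self) -> int:
        return len(self.members)


def read_alignment(
    path: str | Path,
    labels: Mapping[str, str] | None = None,
    label_delimiter: str = "|",
    frame_offset: int = 0,
) -> LabelledAlignment:
    """Read a species-labelled FASTA alignment.

    The species label is taken from ``labels[specimen_id]`` when a mapping is
    given, otherwise parsed from the header as the text after the *last*
    ``label_delimiter`` (the remainder becomes the specimen id). Headers
    without the delimiter are labelled :data:`UNKNOWN_LABEL`.
    """
    path = Path(path)
    if not path.exists():
        raise InputError(f"no such file: {path}")
    seq_records = list(SeqIO.parse(str(path), "fasta"))
    if not seq_records:
        raise InputError(f"no FASTA records in {path}")
    records = []
    for sr in seq_records:
        header = sr.id
        if labels is not None:
            specimen_id, species = header, labels.get(header, UNKNOWN_LABEL)
        elif label_delimiter in header:
            specimen_id, _, species = header.rpartition(label_delimiter)
        else:
            specimen_id, species = header, UNKNOWN_LABEL
        records.append(
            AlignedRecord(specimen_id, species, str(sr.seq).upper())
        )
    return LabelledAlignment(tuple(records), frame_offset=frame_offset)


def write_alignment(
    aln: LabelledAlignment, path: str | Path, label_delimiter: str = "|"
) -> None:
    """Write the alignment back to FASTA with ``id|species`` headers."""
    recs = [
        SeqRecord(
            Seq(r.sequence),
            id=f"{r.specimen_id}{label_delimiter}{r.species_label}",
            description="",
        )
        for r in aln.records
    ]
    SeqIO.write(recs, str(Path(path)), "fasta-2line")


def translate_codons(
    sequence: str, frame_offset: int = 0, code_table: int = 1
) -> str:
    """Translate complete codons of ``sequence`` starting at ``frame_offset``.

    One amino-acid letter per complete codon; codons containing gaps, ``N`` or
    any other non-ACGT character translate to ``X``; stop codons to ``*``.
    ``code_table`` is an NCBI genetic-code id — 1 (standard, the default) or
    e.g. 5 (invertebrate mitochondrial).
    """
    try:
        table = CodonTable.unambiguous_dna_by_id[code_table]
    except KeyError:
        raise ConfigError(f"unknown genetic code table id {code_table!r}") from None
    seq = sequence.upper()
    out = []
    for i in range(frame_offset, len(seq) - 2, 3):
        codon = seq[i : i + 3]
        if set(codon) <= set("ACGT"):
            out.append(table.forward_table.get(codon, "*"))
        else:
            out.append("X")
    return "".join(out)


def collapse_haplotypes(aln: LabelledAlignment) -> list[Haplotype]:
    """Collapse records into one haplotype per distinct (sequence, species).

    Deterministic order: descending count, then lexicographic sequence, then
    species label. The result partitions the specimen ids of ``aln``.
    """
    groups: dict[tuple[str, str], list[str]] = collections.defaultdict(list)
    for rec in aln.records:
        groups[(rec.sequence, rec.species_label)].append(rec.specimen_id)
    haps = [
        Haplotype(seq, species, tuple(members))
        for (seq, species), members in groups.items()
    ]
    haps.sort(key=lambda h: (-h.count, h.sequence, h.species_label))
    return haps


def majority_consensus(sequences: Iterable[str]) -> str:
    """Column-wise majority base, ignoring N and gaps; ties break to the
    lexicographically smallest base. Columns with no called base become N."""
    seqs = list(sequences)
    if not seqs:
        raise InputError("no sequences for consensus")
    length = len(seqs[0])
    cols = []
    for i in range(length):
        counts = collections.Counter(
            s[i] for s in seqs if s[i] in "ACGT"
        )
        if not counts:
            cols.append("N")
            continue
        best = max(counts.items(), key=lambda kv: (kv[1], -ord(kv[0])))
        cols.append(best[0])
    return "".join(cols)


_COMPLEMENT = str.maketrans("ACGTN-", "TGCAN-")


def reverse_complement(sequence: str) -> str:
    return sequence.translate(_COMPLEMENT)[::-1]
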