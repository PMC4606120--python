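"""Protein sequence I/O with organism and pathogen metadata.

Sequences are held as plain upper-case strings over the 20 standard amino
acids plus the ambiguity codes B, Z, X and the rare translated residues
U (selenocysteine) and O (pyrrolysine).  ``J`` (I/L ambiguity) and stop
markers (``*``) are rejected, as are gap characters: the pipeline scores
compositions of real translated sequences, not alignments.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

STANDARD_AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
AMBIGUITY_CODES = "BZXUO"
ALLOWED_ALPHABET = frozenset(STANDARD_AMINO_ACIDS + AMBIGUITY_CODES)

_FASTA_WRAP = 60


class FastaFormatError(ValueError):
    """Raised for malformed FASTA input (empty records, illegal residues)."""


@dataclass
class ProteinRecord:
    """A single identified protein sequence.

    Parameters
    ----------
    accession : str
        Unique identifier; the first whitespace-delimited token of a FASTA
        header.
    sequence : str
        Amino-acid sequence, case-normalised to upper.
    organism : str
        Free-text organism tag; empty string when untagged.
    is_pathogen : bool
        Whether the organism is on the user-supplied pathogen list.
    description : str
        Remainder of the FASTA header after the accession token.
    """

    accession: str
    sequence: str
    organism: str = ""
    is_pathogen: bool = False
    description: str = ""

    def __post_init__(self) -> None:
        if not self.accession:
            raise FastaFormatError("record with empty accession")
        self.sequence = self.sequence.upper()
        if not self.sequence:
            raise FastaFormatError(
                f"record {self.accession!r} has an empty sequence"
            )
        for pos, ch in enumerate(self.sequence, start=1):
            if ch not in ALLOWED_ALPHABET:
                raise FastaFormatError(
                    f"record {self.accession!r}: illegal character {ch!r} "
                    f"at position {pos}"
                )

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class ProteomeSet:
    """An ordered collection of :class:`ProteinRecord` with unique accessions."""

    records: list[ProteinRecord] = field(default_factory=list)

    def __post_init__(self) -> None:
        self._index: dict[str, ProteinRecord] = {}
        for rec in self.records:
            if rec.accession in self._index:
                raise ValueError(f"duplicate accession {rec.accession!r}")
            self._index[rec.accession] = rec

    @property
    def n_proteins(self) -> int:
        return len(self.records)

    @property
    def n_proteomes(self) -> int:
        return len({rec.organism for rec in self.records})

    @property
    def organisms(self) -> list[str]:
        seen: dict[str, None] = {}
        for rec in self.records:
            seen.setdefault(rec.organism)
        return list(seen)

    def add(self, record: ProteinRecord) -> None:
        if record.accession in self._index:
            raise ValueError(f"duplicate accession {record.accession!r}")
        self.records.append(record)
        self._index[record.accession] = record

    def get(self, accession: str) -> ProteinRecord:
        return self._index[accession]

    def __contains__(self, accession: str) -> bool:
        return accession in self._index

    def __iter__(self) -> Iterator[ProteinRecord]:
        return iter(self.records)

    def __len__(self) -> int:
        return len(self.records)

    def extend(self, records: Iterable[ProteinRecord]) -> None:
        for rec in records:
            self.add(rec)


def read_fasta(
    path: str | Path,
    organism: str = "",
    is_pathogen: bool = False,
) -> ProteomeSet:
    """Read a protein FASTA file into a :class:`ProteomeSet`.

    The first whitespace-delimited header token becomes the accession; the
    remainder is kept as the record description.  Duplicate accessions are
    dropped after the first occurrence (deduplication is by accession only).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    proteome = ProteomeSet()
    n_seen = 0
    for entry in SeqIO.parse(str(path), "fasta"):
        n_seen += 1
        accession = entry.id
        description = entry.description[len(entry.id):].strip()
        seq = str(entry.seq).strip()
        if any(g in seq for g in "-."):
            raise FastaFormatError(
                f"record {accession!r} contains gap characters"
            )
        record = ProteinRecord(
            accession=accession,
            sequence=seq,
            organism=organism,
            is_pathogen=is_pathogen,
            description=description,
        )
        if accession not in proteome:
            proteome.add(record)
    if n_seen == 0:
        raise FastaFormatError(f"no FASTA records found in {path}")
    return proteome


def write_fasta(proteome: ProteomeSet, path: str | Path) -> None:
    """Write a ProteomeSet as FASTA with 60-column sequence wrapping.

    The header is ``>accession organism`` (organism omitted when empty).
    """
    path = Path(path)
    with path.open("w") as handle:
        for rec in proteome:
            header = rec.accession
            if rec.organism:
                header += f" {rec.organism}"
            handle.write(f">{header}\n")
            for i in range(0, len(rec.sequence), _FASTA_WRAP):
                handle.write(rec.sequence[i : i + _FASTA_WRAP] + "\n")


def _parse_bool(value: str) -> bool:
    value = value.strip().lower()
    if value in {"1", "true", "yes", "y"}:
        return True
    if value in {"0", "false", "no", "n", ""}:
        return False
    raise ValueError(f"cannot interpret {value!r} as a boolean flag")


def read_metadata(path: str | Path) -> dict[str, tuple[str, bool]]:
    """Read a sidecar metadata TSV mapping accession -> (organism, is_pathogen).

    The file must have header columns ``accession``, ``organism``,
    ``is_pathogen``.
    """
    path = Path(path)
    with path.open() as handle:
        reader = csv.DictReader(handle, delimiter="\t")
        required = {"accession", "organism", "is_pathogen"}
        missing = required - set(reader.fieldnames or ())
        if missing:
            raise FastaFormatError(
                f"metadata file {path} missing columns: {sorted(missing)}"
            )
        table: dict[str, tuple[str, bool]] = {}
        for row in reader:
            table[row["accession"]] = (
                row["organism"],
                _parse_bool(row["is_pathogen"]),
            )
    return table


def apply_metadata(
    proteome: ProteomeSet, metadata: dict[str, tuple[str, bool]]
) -> int:
    """Apply sidecar organism/pathogen tags in place; returns records tagged."""
    n = 0
    for rec in proteome:
        if rec.accession in metadata:
            rec.organism, rec.is_pathogen = metadata[rec.accession]
            n += 1
    return n


def as_seqrecords(proteome: ProteomeSet) -> list[SeqRecord]:
    """View a ProteomeSet as Biopython SeqRecords (for interop)."""
    return [
        SeqRecord(Seq(rec.sequence), id=rec.accession, description=rec.description)
        for rec in proteome
    ]
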