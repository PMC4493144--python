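"""Aligned-sequence and taxonomy I/O.

This module owns the coordinate convention used by the whole package: column
positions are **1-based and inclusive** on the trimmed alignment frame (the
barcode key quotes positions "in relation to the 612 bp alignment", which is a
1-based biologist's convention).  Every other module accepts and reports
positions in this frame.

It also owns the character-class rules: sequences are uppercased on input, RNA
``U`` is mapped to ``T``, and the alphabet is restricted to ``A C G T``, the
gap ``-`` and the IUPAC ambiguity codes.  Gaps and all ambiguity codes
(including ``N``) are *non-informative* for every downstream computation:
they are excluded pairwise from distances and disqualify or neutralise
character-attribute positions.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord as _BioSeqRecord

#: Unambiguous nucleotide states (the only states a character attribute may take).
INFORMATIVE_STATES = "ACGT"

#: Full accepted alphabet: unambiguous states, gap, and IUPAC ambiguity codes.
ALPHABET = frozenset("ACGT-" + "RYSWKMBDHVN")

# Integer codes used throughout the package: A=0 C=1 G=2 T=3; anything
# non-informative gets a code >= 4.  With this ordering a mismatch between two
# codes < 4 is a transition iff the codes have equal parity (A,G even; C,T odd).
_CODE_TABLE = np.full(256, 255, dtype=np.uint8)
for _i, _c in enumerate("ACGT"):
    _CODE_TABLE[ord(_c)] = _i
for _i, _c in enumerate("-RYSWKMBDHVN"):
    _CODE_TABLE[ord(_c)] = 4 + _i

GAP_CODE = 4  # code of '-'


class AlignmentError(ValueError):
    """Malformed alignment input (ragged rows, bad characters, duplicate ids)."""


class TaxonomyError(ValueError):
    """Malformed taxonomy table."""


def is_informative(ch: str) -> bool:
    """True if *ch* is an unambiguous nucleotide (A/C/G/T)."""
    return ch in INFORMATIVE_STATES


def normalize_sequence(seq_id: str, raw: str) -> str:
    """Uppercase, map U->T, and validate against the accepted alphabet.

    Raises :class:`AlignmentError` naming the offending 1-based position.
    """
    seq = raw.upper().replace("U", "T")
    for pos, ch in enumerate(seq, start=1):
        if ch not in ALPHABET:
            raise AlignmentError(
                f"sequence {seq_id!r}: invalid character {ch!r} at position {pos}"
            )
    return seq


@dataclass(frozen=True)
class SequenceRecord:
    """A single labelled, aligned nucleotide sequence."""

    id: str
    seq: str

    def __post_init__(self) -> None:
        if not self.id:
            raise AlignmentError("sequence id must be non-empty")
        if not self.seq:
            raise AlignmentError(f"sequence {self.id!r} is empty")

    def __len__(self) -> int:
        return len(self.seq)


@dataclass
class Alignment:
    """An ordered collection of equal-length sequence records.

    The alignment defines the shared coordinate frame: position ``p`` (1-based)
    of every record refers to the same homologous column.
    """

    records: list[SequenceRecord]
    _codes: np.ndarray | None = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        if not self.records:
            raise AlignmentError("alignment must contain at least one record")
        length = len(self.records[0].seq)
        if length < 1:
            raise AlignmentError("alignment length must be >= 1")
        ragged = [r.id for r in self.records if len(r.seq) != length]
        if ragged:
            raise AlignmentError(
                f"ragged alignment: records {ragged} differ in length from "
                f"{self.records[0].id!r} (length {length})"
            )
        seen: set[str] = set()
        for r in self.records:
            if r.id in seen:
                raise AlignmentError(f"duplicate sequence id {r.id!r}")
            seen.add(r.id)

    @property
    def length(self) -> int:
        return len(self.records[0].seq)

    @property
    def ids(self) -> list[str]:
        return [r.id for r in self.records]

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[SequenceRecord]:
        return iter(self.records)

    def __getitem__(self, seq_id: str) -> SequenceRecord:
        for r in self.records:
            if r.id == seq_id:
                return r
        raise KeyError(seq_id)

    def to_codes(self) -> np.ndarray:
        """Integer-coded matrix, shape (n_records, length), dtype uint8."""
        if self._codes is None:
            buf = np.frombuffer(
                "".join(r.seq for r in self.records).encode("ascii"), dtype=np.uint8
            )
            self._codes = _CODE_TABLE[buf].reshape(len(self.records), self.length)
        return self._codes

    def subset(self, ids: Iterable[str]) -> "Alignment":
        wanted = set(ids)
        missing = wanted - set(self.ids)
        if missing:
            raise KeyError(f"ids not in alignment: {sorted(missing)}")
        return Alignment([r for r in self.records if r.id in wanted])

    def content_hash(self) -> str:
        """Stable hash of ids + sequences (used as key provenance)."""
        h = hashlib.sha256()
        for r in self.records:
            h.update(r.id.encode())
            h.update(b"\x00")
            h.update(r.seq.encode())
            h.update(b"\x00")
        return h.hexdigest()[:16]


def encode_sequence(seq: str) -> np.ndarray:
    """Integer-code a single (already normalised) sequence string."""
    buf = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    return _CODE_TABLE[buf]


def read_fasta_alignment(path: str | Path) -> Alignment:
    """Read a multi-FASTA file as an alignment.

    Sequences are uppercased, ``U`` is mapped to ``T`` and the alphabet is
    validated.  Ragged lengths and duplicate ids raise :class:`AlignmentError`
    naming the offending records.
    """
    path = Path(path)
    records = [
        SequenceRecord(rec.id, normalize_sequence(rec.id, str(rec.seq)))
        for rec in SeqIO.parse(str(path), "fasta")
    ]
    if not records:
        raise AlignmentError(f"no FASTA records found in {path}")
    return Alignment(records)


def write_fasta_alignment(alignment: Alignment, path: str | Path) -> None:
    """Write an alignment as multi-FASTA (one line per sequence)."""
    bio = [
        _BioSeqRecord(Seq(r.seq), id=r.id, description="") for r in alignment.records
    ]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=None)
        writer.write_file(bio)


def trim_alignment(alignment: Alignment, start: int, end: int) -> Alignment:
    """Cut every record to the 1-based inclusive column window [start, end]."""
    if not (1 <= start <= end <= alignment.length):
        raise AlignmentError(
            f"trim window [{start}, {end}] out of range for alignment of "
            f"length {alignment.length}"
        )
    return Alignment(
        [SequenceRecord(r.id, r.seq[start - 1 : end]) for r in alignment.records]
    )


@dataclass
class TaxonomyTable:
    """Mapping of sequence id -> species -> genus (optional higher group).

    Backed by a DataFrame with columns ``id``, ``species``, ``genus`` and
    optionally ``group``.  Every id is unique and every species maps to
    exactly one genus.
    """

    frame: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"id", "species", "genus"}
        missing = required - set(self.frame.columns)
        if missing:
            raise TaxonomyError(f"taxonomy table missing columns: {sorted(missing)}")
        dupes = self.frame["id"][self.frame["id"].duplicated()].tolist()
        if dupes:
            raise TaxonomyError(f"duplicate ids in taxonomy table: {sorted(set(dupes))}")
        genus_per_species = self.frame.groupby("species")["genus"].nunique()
        bad = genus_per_species[genus_per_species > 1].index.tolist()
        if bad:
            raise TaxonomyError(f"species mapped to multiple genera: {bad}")
        self.frame = self.frame.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.frame)

    @property
    def species(self) -> list[str]:
        """Distinct species, in first-appearance order."""
        return list(dict.fromkeys(self.frame["species"]))

    @property
    def genera(self) -> list[str]:
        return list(dict.fromkeys(self.frame["genus"]))

    def species_of(self, seq_id: str) -> str:
        hit = self.frame.loc[self.frame["id"] == seq_id, "species"]
        if hit.empty:
            raise TaxonomyError(f"id {seq_id!r} absent from taxonomy table")
        return hit.iloc[0]

    def genus_of_species(self, species: str) -> str:
        hit = self.frame.loc[self.frame["species"] == species, "genus"]
        if hit.empty:
            raise TaxonomyError(f"species {species!r} absent from taxonomy table")
        return hit.iloc[0]

    def ids_of_species(self, species: str | Iterable[str]) -> list[str]:
        if isinstance(species, str):
            species = [species]
        wanted = set(species)
        return self.frame.loc[self.frame["species"].isin(wanted), "id"].tolist()

    def species_by_genus(self) -> dict[str, list[str]]:
        out: dict[str, list[str]] = {}
        for sp in self.species:
            out.setdefault(self.genus_of_species(sp), []).append(sp)
        return out

    def species_map(self) -> dict[str, str]:
        """id -> species over the whole table."""
        return dict(zip(self.frame["id"], self.frame["species"]))

    @classmethod
    def from_rows(
        cls, rows: Sequence[tuple[str, str, str]] | Sequence[tuple[str, str, str, str]]
    ) -> "TaxonomyTable":
        cols = ["id", "species", "genus", "group"][: len(rows[0])]
        return cls(pd.DataFrame(list(rows), columns=cols))


def read_taxonomy(path: str | Path) -> TaxonomyTable:
    """Read a tab-separated taxonomy table (header ``id/species/genus[/group]``)."""
    frame = pd.read_csv(path, sep="\t", dtype=str)
    return TaxonomyTable(frame)


def write_taxonomy(table: TaxonomyTable, path: str | Path) -> None:
    table.frame.to_csv(path, sep="\t", index=False)
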