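"""Sequence records, FASTA/TSV I/O and IUPAC nucleotide semantics.

All other modules consume :class:`SequenceRecord` and :class:`Alignment`.
Metadata (species, strain, phylum) travels in a TSV sidecar keyed by record
id, never in FASTA headers.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord as _BioRecord

PROTEIN_ALPHABET = frozenset("ACDEFGHIKLMNPQRSTVWYX")
GAP = "-"

#: IUPAC nucleotide one-letter codes mapped to the base sets they denote.
IUPAC_SETS: dict[str, frozenset[str]] = {
    "A": frozenset("A"),
    "C": frozenset("C"),
    "G": frozenset("G"),
    "T": frozenset("T"),
    "R": frozenset("AG"),
    "Y": frozenset("CT"),
    "S": frozenset("CG"),
    "W": frozenset("AT"),
    "K": frozenset("GT"),
    "M": frozenset("AC"),
    "B": frozenset("CGT"),
    "D": frozenset("AGT"),
    "H": frozenset("ACT"),
    "V": frozenset("ACG"),
    "N": frozenset("ACGT"),
}

NUCLEOTIDE_ALPHABET = frozenset(IUPAC_SETS)

_COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN")


class SequenceError(ValueError):
    """Malformed sequence input (bad characters, duplicate ids, empty files)."""


@dataclass(frozen=True)
class SequenceRecord:
    """One protein or nucleotide sequence with taxon metadata."""

    id: str
    residues: str
    alphabet: str = "protein"  # {"protein", "nucleotide"}
    description: str = ""
    species: str = ""
    strain: str = ""
    phylum: str = ""
    source: str = "real"  # {"real", "synthetic"}

    def __post_init__(self) -> None:
        if not self.residues:
            raise SequenceError(f"record {self.id!r}: empty sequence")
        if self.alphabet not in ("protein", "nucleotide"):
            raise SequenceError(f"record {self.id!r}: unknown alphabet {self.alphabet!r}")
        residues = self.residues.upper()
        object.__setattr__(self, "residues", residues)
        allowed = PROTEIN_ALPHABET if self.alphabet == "protein" else NUCLEOTIDE_ALPHABET
        for pos, ch in enumerate(residues, start=1):
            if ch not in allowed:
                raise SequenceError(
                    f"record {self.id!r}: illegal {self.alphabet} character "
                    f"{ch!r} at position {pos}"
                )

    def __len__(self) -> int:
        return len(self.residues)

    def with_residues(self, residues: str) -> "SequenceRecord":
        return replace(self, residues=residues)


@dataclass
class Alignment:
    """Rows of gapped sequences of equal length; gap symbol is ``-``.

    Degapping row *i* reproduces the residues of the source record with
    id ``ids[i]``.
    """

    ids: list[str]
    rows: list[str]

    def __post_init__(self) -> None:
        if len(self.ids) != len(self.rows):
            raise SequenceError("ids and rows differ in length")
        if self.rows:
            width = len(self.rows[0])
            for rid, row in zip(self.ids, self.rows):
                if len(row) != width:
                    raise SequenceError(f"row {rid!r} has ragged length")
                if "." in row:
                    raise SequenceError(f"row {rid!r} uses '.' as gap; only '-' accepted")

    @property
    def length(self) -> int:
        return len(self.rows[0]) if self.rows else 0

    def __len__(self) -> int:
        return len(self.rows)

    def degapped(self, i: int) -> str:
        return self.rows[i].replace(GAP, "")

    def columns(self) -> Iterable[tuple[str, ...]]:
        return zip(*self.rows)


def _check_unique(ids: Sequence[str]) -> None:
    seen: set[str] = set()
    for rid in ids:
        if rid in seen:
            raise SequenceError(f"duplicate id {rid!r}")
        seen.add(rid)


def read_metadata(path: str | Path) -> pd.DataFrame:
    """Read the TSV metadata sidecar (columns: id, species, strain, phylum)."""
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    if "id" not in df.columns:
        raise SequenceError(f"metadata {path}: missing 'id' column")
    return df.set_index("id")


def read_fasta(
    path: str | Path,
    alphabet: str = "protein",
    metadata: str | Path | pd.DataFrame | None = None,
) -> list[SequenceRecord]:
    """Read a FASTA file into :class:`SequenceRecord` objects.

    The first whitespace-delimited header token is the record id; the rest is
    kept as the description.  ``metadata`` (TSV path or DataFrame indexed by
    id) merges species/strain/phylum by id.  Characters are upper-cased and
    validated against the declared alphabet; an illegal character is reported
    with the offending record id and position.
    """
    path = Path(path)
    entries = list(SeqIO.parse(str(path), "fasta"))
    if not entries:
        raise SequenceError(f"{path}: empty or non-FASTA file")
    if metadata is not None and not isinstance(metadata, pd.DataFrame):
        metadata = read_metadata(metadata)
    records = []
    for entry in entries:
        meta = {}
        if metadata is not None and entry.id in metadata.index:
            row = metadata.loc[entry.id]
            meta = {
                "species": row.get("species", ""),
                "strain": row.get("strain", ""),
                "phylum": row.get("phylum", ""),
            }
        desc = entry.description[len(entry.id):].strip()
        records.append(
            SequenceRecord(
                id=entry.id, residues=str(entry.seq), alphabet=alphabet,
                description=desc, **meta,
            )
        )
    _check_unique([r.id for r in records])
    return records


def write_fasta(records: Iterable[SequenceRecord], path: str | Path, wrap: int = 60) -> None:
    """Write records as wrapped FASTA (UTF-8)."""
    bio = [
        _BioRecord(Seq(r.residues), id=r.id, description=r.description)
        for r in records
    ]
    with open(path, "w", encoding="utf-8") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=wrap)
        writer.write_file(bio)


def write_metadata(records: Iterable[SequenceRecord], path: str | Path) -> None:
    rows = [
        {"id": r.id, "species": r.species, "strain": r.strain, "phylum": r.phylum}
        for r in records
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def iupac_compatible(a: str, b: str) -> bool:
    """True iff the base sets denoted by IUPAC symbols ``a`` and ``b`` intersect.

    E.g. R={A,G} is compatible with A; S={C,G} is not compatible with A.
    Symmetric and reflexive over the 15-letter code.
    """
    try:
        sa, sb = IUPAC_SETS[a.upper()], IUPAC_SETS[b.upper()]
    except KeyError as exc:
        raise SequenceError(f"non-IUPAC nucleotide symbol {exc.args[0]!r}") from None
    return bool(sa & sb)


def reverse_complement(seq: str) -> str:
    """IUPAC-aware reverse complement."""
    return seq.upper().translate(_COMPLEMENT)[::-1]
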