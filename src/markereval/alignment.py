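"""Alignment, strain-metadata and coordinate primitives.

The central objects are :class:`Alignment` (an equal-length, gapped,
IUPAC-nucleotide multiple alignment keyed by strain id), :class:`StrainTable`
(strain → species label, plus optional accession and type-strain flag) and
:class:`CoordinateMap`, which relates alignment columns to positions in the
ungapped sequenced fragment, to positions in the full-length gene, and to
codon coordinates.

All coordinates are 1-based and inclusive throughout the package, matching
the way positions are conventionally reported for marker-gene alignments
(e.g. "alignment column 225", "gene position 561", "third position of the
187th codon").
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Union

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq

GAP = "-"

#: IUPAC nucleotide one-letter codes → the set of concrete bases they stand for.
#: The gap character expands to the empty set.
IUPAC_EXPANSION: Mapping[str, frozenset] = {
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
    GAP: frozenset(),
}

BASES = ("A", "C", "G", "T")
AMBIGUITY_CODES = frozenset("RYSWKMBDHVN")
ALPHABET = frozenset(IUPAC_EXPANSION) | {"U"}

# Integer encoding used by the numeric kernels: bases 0-3, ambiguity codes
# 4-14, gap 15.  Anything < 4 is a concrete base.
_CODE_OF = {c: i for i, c in enumerate("ACGTRYSWKMBDHVN-")}
GAP_CODE = _CODE_OF[GAP]
_CHAR_OF = np.array(list("ACGTRYSWKMBDHVN-"))


class AlignmentError(ValueError):
    """Malformed alignment input (ragged rows, illegal characters, bad ids)."""


class StrainTableError(ValueError):
    """Malformed strain metadata table."""


#: Reserved species label for strains without an assignment; such strains are
#: excluded from intra/inter identity partitions and from diagnostic target
#: or background groups.
UNASSIGNED = "unassigned"


def _normalize_sequence(strain_id: str, raw: str) -> str:
    seq = raw.upper().replace("U", "T")
    for col, ch in enumerate(seq, start=1):
        if ch not in IUPAC_EXPANSION:
            raise AlignmentError(
                f"illegal character {ch!r} in record {strain_id!r} at column {col}"
            )
    return seq


@dataclass
class Alignment:
    """An equal-length gapped IUPAC nucleotide multiple alignment.

    Parameters
    ----------
    records
        Ordered ``(strain_id, sequence)`` pairs.  Sequences are upper-cased
        and U is normalized to T on construction; '-' is the only gap
        character ('.' is rejected).
    descriptions
        Optional map of strain id → FASTA description text (everything after
        the first whitespace on the header line); carried but never used as
        a key.
    """

    records: list
    descriptions: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.records:
            raise AlignmentError("alignment has no records")
        normalized = []
        seen = set()
        length = None
        for strain_id, seq in self.records:
            if not strain_id:
                raise AlignmentError("empty strain id")
            if strain_id in seen:
                raise AlignmentError(f"duplicate strain id {strain_id!r}")
            seen.add(strain_id)
            seq = _normalize_sequence(strain_id, str(seq))
            if length is None:
                length = len(seq)
                if length < 1:
                    raise AlignmentError(f"record {strain_id!r} is empty")
            elif len(seq) != length:
                raise AlignmentError(
                    f"ragged alignment: record {strain_id!r} has length "
                    f"{len(seq)}, expected {length}"
                )
            normalized.append((strain_id, seq))
        self.records = normalized
        self._codes: Optional[np.ndarray] = None

    @property
    def length(self) -> int:
        """Number of alignment columns."""
        return len(self.records[0][1])

    @property
    def n_sequences(self) -> int:
        return len(self.records)

    @property
    def ids(self) -> list:
        return [sid for sid, _ in self.records]

    def sequence(self, strain_id: str) -> str:
        for sid, seq in self.records:
            if sid == strain_id:
                return seq
        raise KeyError(strain_id)

    def __contains__(self, strain_id: str) -> bool:
        return any(sid == strain_id for sid, _ in self.records)

    def column(self, column: int) -> str:
        """Characters of 1-based `column`, in record order."""
        if not 1 <= column <= self.length:
            raise IndexError(
                f"column {column} out of range 1..{self.length}"
            )
        return "".join(seq[column - 1] for _, seq in self.records)

    def to_codes(self) -> np.ndarray:
        """Integer-encoded matrix (n_sequences × length, uint8).

        Bases A,C,G,T map to 0–3, ambiguity codes to 4–14, gap to 15.
        Cached; treat as read-only.
        """
        if self._codes is None:
            lut = np.full(128, 255, dtype=np.uint8)
            for ch, code in _CODE_OF.items():
                lut[ord(ch)] = code
            rows = [
                lut[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]
                for _, seq in self.records
            ]
            self._codes = np.vstack(rows)
        return self._codes


def read_alignment(path: Union[str, Path]) -> Alignment:
    """Read a FASTA multiple alignment.

    The token before the first whitespace on each header line is the strain
    id; the remainder is stored as the record description.  Raises
    :class:`AlignmentError` for ragged rows or non-IUPAC characters.
    """
    records = []
    descriptions = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        records.append((rec.id, str(rec.seq)))
        desc = rec.description
        if desc.startswith(rec.id):
            desc = desc[len(rec.id):].strip()
        if desc:
            descriptions[rec.id] = desc
    if not records:
        raise AlignmentError(f"no FASTA records in {path}")
    return Alignment(records, descriptions)


def write_alignment(aln: Alignment, path: Union[str, Path], wrap: int = 60) -> None:
    """Write FASTA, uppercase, wrapped at `wrap` columns."""
    with open(path, "w") as fh:
        for sid, seq in aln.records:
            desc = aln.descriptions.get(sid, "")
            header = f">{sid} {desc}".rstrip()
            fh.write(header + "\n")
            for i in range(0, len(seq), wrap):
                fh.write(seq[i:i + wrap] + "\n")


@dataclass(frozen=True)
class StrainEntry:
    species: str
    accession: Optional[str] = None
    is_type_strain: bool = False


class StrainTable:
    """Strain id → species label (plus accession and type-strain flag).

    Strains carrying the reserved label ``"unassigned"`` are considered
    unlabeled and are left out of intra/inter partitions and diagnostic
    groups.
    """

    def __init__(self, entries: Mapping[str, StrainEntry]):
        for sid, entry in entries.items():
            if not sid:
                raise StrainTableError("empty strain id")
            if not entry.species:
                raise StrainTableError(f"empty species label for strain {sid!r}")
        self.entries = dict(entries)

    def __len__(self) -> int:
        return len(self.entries)

    def __contains__(self, strain_id: str) -> bool:
        return strain_id in self.entries

    def species_of(self, strain_id: str) -> str:
        return self.entries[strain_id].species

    def is_labeled(self, strain_id: str) -> bool:
        entry = self.entries.get(strain_id)
        return entry is not None and entry.species != UNASSIGNED

    def species_labels(self) -> list:
        """Distinct species labels (excluding 'unassigned'), insertion order."""
        seen = []
        for entry in self.entries.values():
            if entry.species != UNASSIGNED and entry.species not in seen:
                seen.append(entry.species)
        return seen

    def strains_of(self, species: str) -> list:
        return [s for s, e in self.entries.items() if e.species == species]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "strain": list(self.entries),
                "species": [e.species for e in self.entries.values()],
                "accession": [e.accession or "" for e in self.entries.values()],
                "type_strain": [
                    "yes" if e.is_type_strain else "no"
                    for e in self.entries.values()
                ],
            }
        )


_TRUTHY = {"1", "true", "yes", "y", "t"}
_FALSY = {"", "0", "false", "no", "n", "f", "na", "nan"}


def read_strain_table(path: Union[str, Path]) -> StrainTable:
    """Read a tab-separated strain table.

    Expected header: ``strain  species  accession  type_strain`` — the last
    two columns optional.  Duplicate strain ids and empty species labels are
    errors.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    cols = [c.strip().lower() for c in df.columns]
    df.columns = cols
    if "strain" not in cols or "species" not in cols:
        raise StrainTableError(
            f"strain table needs 'strain' and 'species' columns, got {cols}"
        )
    entries: dict = {}
    for _, row in df.iterrows():
        sid = row["strain"].strip()
        if sid in entries:
            raise StrainTableError(f"duplicate strain id {sid!r}")
        species = row["species"].strip()
        if not species:
            raise StrainTableError(f"empty species for strain {sid!r}")
        accession = row.get("accession", "").strip() or None
        flag_raw = str(row.get("type_strain", "")).strip().lower()
        if flag_raw in _TRUTHY:
            flag = True
        elif flag_raw in _FALSY:
            flag = False
        else:
            raise StrainTableError(
                f"unrecognized type_strain value {flag_raw!r} for {sid!r}"
            )
        entries[sid] = StrainEntry(species, accession, flag)
    return StrainTable(entries)


def write_strain_table(table: StrainTable, path: Union[str, Path]) -> None:
    table.to_frame().to_csv(path, sep="\t", index=False)


@dataclass(frozen=True)
class CoordinateMap:
    """Relates alignment columns to full-gene and codon coordinates.

    Parameters
    ----------
    reference_strain
        Strain whose (ungapped) row anchors the mapping.
    gene_offset
        Number of full-gene nucleotides preceding ungapped position 1 of the
        aligned fragment.  For a fragment whose first base is gene position
        337, ``gene_offset = 336``.
    frame_start
        Full-gene position of the first base of the start codon (default 1,
        i.e. the gene coordinate system starts at the reading frame).
    """

    reference_strain: str
    gene_offset: int = 0
    frame_start: int = 1

    def __post_init__(self) -> None:
        if self.gene_offset < 0:
            raise ValueError("gene_offset must be >= 0")
        if self.frame_start < 1:
            raise ValueError("frame_start must be >= 1")


def column_to_gene_position(aln: Alignment, cmap: CoordinateMap, column: int) -> int:
    """Map a 1-based alignment column to a 1-based full-gene position.

    The gene position is ``gene_offset`` plus the number of non-gap
    characters in the reference row from column 1 through `column`.  Raises
    if the reference row is gapped at `column` (no base maps there).
    """
    if not 1 <= column <= aln.length:
        raise IndexError(f"column {column} out of range 1..{aln.length}")
    ref = aln.sequence(cmap.reference_strain)
    if ref[column - 1] == GAP:
        raise ValueError(
            f"unmappable column {column}: reference {cmap.reference_strain!r} "
            "is gapped there"
        )
    ungapped = sum(1 for ch in ref[:column] if ch != GAP)
    return cmap.gene_offset + ungapped


def column_to_fragment_position(aln: Alignment, cmap: CoordinateMap, column: int) -> int:
    """Map an alignment column to the 1-based position in the reference's
    ungapped fragment."""
    return column_to_gene_position(aln, cmap, column) - cmap.gene_offset


def codon_context(gene_position: int, frame_start: int = 1) -> tuple:
    """Codon index and within-codon position of a full-gene position.

    With ``p = gene_position − frame_start + 1``, returns
    ``(ceil(p/3), ((p−1) mod 3) + 1)``.  E.g. gene position 561 in frame 1 is
    the third position of codon 187.
    """
    if gene_position < frame_start:
        raise ValueError(
            f"gene position {gene_position} precedes frame start {frame_start}"
        )
    p = gene_position - frame_start + 1
    return math.ceil(p / 3), (p - 1) % 3 + 1


def gene_position_of_codon(codon_index: int, codon_position: int, frame_start: int = 1) -> int:
    """Inverse of :func:`codon_context`."""
    return frame_start + 3 * (codon_index - 1) + (codon_position - 1)


def translate_codon(codon: str) -> str:
    """Standard-genetic-code translation of a gap-free codon."""
    if len(codon) != 3 or any(c not in BASES for c in codon):
        raise ValueError(f"not a concrete codon: {codon!r}")
    return str(Seq(codon).translate())
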