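"""Sequence primitives and the TSS-relative coordinate system.

All promoter positions in reports and saRNA names use the genomics
convention in which the transcription start site (TSS) base is +1, the
base immediately upstream is -1, and position 0 does not exist.
Internally every module works with plain 0-based Python string offsets;
:func:`to_tss_coordinate` / :func:`from_tss_coordinate` convert losslessly
between the two.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

from Bio import SeqIO

DNA_BASES = frozenset("ACGTN")
RNA_BASES = frozenset("ACGUN")

_DNA_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")
_RNA_COMPLEMENT = str.maketrans("ACGUN", "UGCAN")


class AlphabetError(ValueError):
    """Sequence contains characters outside the declared alphabet."""


@dataclass(frozen=True)
class PromoterRecord:
    """A promoter sequence anchored at its transcription start site.

    Parameters
    ----------
    id
        Short label used in saRNA names (e.g. ``"P21"`` yields names like
        ``dsP21-322``).
    sequence
        Upper-case DNA over ``{A, C, G, T, N}``. Lower-case input is
        normalised at construction; any other character is rejected.
    tss_index
        1-based index within ``sequence`` of the TSS (+1) base.
    species_tag
        Optional free-text species label (e.g. ``"PT"``, ``"CA"``).
    """

    id: str
    sequence: str
    tss_index: int
    species_tag: str | None = None

    def __post_init__(self) -> None:
        seq = self.sequence.upper()
        object.__setattr__(self, "sequence", seq)
        bad = set(seq) - DNA_BASES
        if bad:
            raise AlphabetError(
                f"record {self.id!r}: invalid DNA characters {sorted(bad)}"
            )
        if not seq:
            raise ValueError(f"record {self.id!r}: empty sequence")
        if not 1 <= self.tss_index <= len(seq):
            raise ValueError(
                f"record {self.id!r}: tss_index {self.tss_index} outside "
                f"[1, {len(seq)}]"
            )

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class TssCoordinate:
    """Signed TSS-relative position; +1 is the TSS base, 0 does not exist."""

    value: int

    def __post_init__(self) -> None:
        if self.value == 0:
            raise ValueError("TSS-relative position 0 does not exist")

    def __int__(self) -> int:
        return self.value

    def __str__(self) -> str:
        return f"{self.value:+d}"


def to_tss_coordinate(record: PromoterRecord, offset: int) -> TssCoordinate:
    """Convert a 0-based sequence offset to a TSS-relative coordinate.

    The base at ``offset == tss_index - 1`` is +1; the base immediately
    upstream is -1 (there is no 0).
    """
    if not 0 <= offset < len(record.sequence):
        raise IndexError(
            f"offset {offset} outside sequence of length {len(record.sequence)}"
        )
    anchor = record.tss_index - 1  # 0-based offset of the +1 base
    if offset < anchor:
        return TssCoordinate(offset - anchor)
    return TssCoordinate(offset - anchor + 1)


def from_tss_coordinate(record: PromoterRecord, pos: TssCoordinate | int) -> int:
    """Inverse of :func:`to_tss_coordinate`; returns the 0-based offset."""
    value = int(pos)
    if value == 0:
        raise ValueError("TSS-relative position 0 does not exist")
    anchor = record.tss_index - 1
    offset = anchor + value if value < 0 else anchor + value - 1
    if not 0 <= offset < len(record.sequence):
        raise IndexError(f"TSS position {value:+d} outside record {record.id!r}")
    return offset


def _check_alphabet(seq: str, alphabet: str) -> None:
    allowed = DNA_BASES if alphabet == "dna" else RNA_BASES
    bad = set(seq) - allowed
    if bad:
        raise AlphabetError(f"invalid {alphabet.upper()} characters {sorted(bad)}")


def reverse_complement(seq: str, alphabet: str = "dna") -> str:
    """Reverse complement of a DNA or RNA sequence (N maps to N).

    ``alphabet`` must be ``"dna"`` or ``"rna"``; mixed T/U input is
    rejected via the alphabet check.
    """
    if alphabet not in ("dna", "rna"):
        raise ValueError(f"alphabet must be 'dna' or 'rna', got {alphabet!r}")
    seq = seq.upper()
    _check_alphabet(seq, alphabet)
    table = _DNA_COMPLEMENT if alphabet == "dna" else _RNA_COMPLEMENT
    return seq.translate(table)[::-1]


def dna_to_rna(seq: str) -> str:
    """Transcribe-in-place: T -> U, everything else unchanged."""
    seq = seq.upper()
    _check_alphabet(seq, "dna")
    return seq.replace("T", "U")


def gc_content(seq: str) -> float:
    """G+C percentage of a sequence.

    N counts toward the length but not toward GC, so draft sequence with
    ambiguity codes is penalised rather than inflated.
    """
    if not seq:
        raise ValueError("gc_content of empty sequence is undefined")
    seq = seq.upper()
    return 100.0 * (seq.count("G") + seq.count("C")) / len(seq)


def max_homopolymer_run(seq: str) -> int:
    """Length of the longest run of a single repeated base."""
    if not seq:
        raise ValueError("max_homopolymer_run of empty sequence is undefined")
    seq = seq.upper()
    best = run = 1
    for prev, cur in zip(seq, seq[1:]):
        run = run + 1 if cur == prev else 1
        if run > best:
            best = run
    return best


# ---------------------------------------------------------------------------
# FASTA + TSS sidecar I/O


def read_tss_table(path: str | Path) -> dict[str, int]:
    """Read a ``record_id <TAB> tss_index`` sidecar file."""
    table: dict[str, int] = {}
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        fields = line.split("\t")
        if len(fields) != 2:
            raise ValueError(f"malformed TSS table line: {line!r}")
        table[fields[0]] = int(fields[1])
    return table


def read_promoters(
    fasta_path: str | Path,
    tss: int | None = None,
    tss_table: dict[str, int] | None = None,
    tss_at_end: bool = False,
    species_tag: str | None = None,
) -> list[PromoterRecord]:
    """Load promoter records from FASTA with their TSS anchors.

    Exactly one TSS source must be supplied: a single 1-based ``tss``
    applied to all records, a per-record ``tss_table``, or ``tss_at_end``
    (the last base is the TSS — the common case for upstream-only
    promoter extracts).
    """
    if sum(x is not None and x is not False for x in (tss, tss_table, tss_at_end)) != 1:
        raise ValueError("supply exactly one of tss, tss_table, tss_at_end")
    records = []
    for rec in SeqIO.parse(str(fasta_path), "fasta"):
        seq = str(rec.seq)
        if tss_at_end:
            idx = len(seq)
        elif tss_table is not None:
            if rec.id not in tss_table:
                raise KeyError(f"record {rec.id!r} missing from TSS table")
            idx = tss_table[rec.id]
        else:
            assert tss is not None
            idx = tss
        records.append(
            PromoterRecord(id=rec.id, sequence=seq, tss_index=idx, species_tag=species_tag)
        )
    return records


def write_fasta(records: Iterable[PromoterRecord], path: str | Path) -> None:
    """Write records as plain multi-record FASTA (60-column wrap)."""
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.id}\n")
            for i in range(0, len(rec.sequence), 60):
                fh.write(rec.sequence[i : i + 60] + "\n")
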