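"""Family-tagged TE reference library built from a genome FASTA and a TE BED.

The library holds the extracted member sequences of each retrotransposon
family (e.g. *ji*, *opie* for Copia; *huck*, *cinful-zeon* for Gypsy).
Families smaller than ``min_members`` (default 20 members, the conventional
sub-family size cut-off for maize LTR annotation) are dropped before any
read is aligned.
"""

from __future__ import annotations

import collections
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

SUPERFAMILIES = ("Copia", "Gypsy")

#: separator used in library FASTA headers: ``family|superfamily|index``
HEADER_SEP = "|"


class BedParseError(ValueError):
    """A TE annotation record could not be parsed."""


class SuperfamilyError(ValueError):
    """The superfamily token is not one of the recognised labels."""


@dataclass(frozen=True)
class TEInterval:
    """One annotated TE copy, BED-style 0-based half-open coordinates."""

    chrom: str
    start: int
    end: int
    family: str
    superfamily: str

    def __post_init__(self) -> None:
        if self.start < 0 or self.start >= self.end:
            raise BedParseError(
                f"invalid interval [{self.start}, {self.end}) on {self.chrom}"
            )
        if not self.family:
            raise BedParseError("empty family label")
        if self.superfamily not in SUPERFAMILIES:
            raise SuperfamilyError(
                f"unknown superfamily {self.superfamily!r}; expected one of {SUPERFAMILIES}"
            )

    def __len__(self) -> int:
        return self.end - self.start


@dataclass
class TEFamilyLibrary:
    """Member sequences per retained family, plus superfamily labels."""

    families: dict[str, list[str]] = field(default_factory=dict)
    superfamily_of: dict[str, str] = field(default_factory=dict)

    @property
    def member_count(self) -> dict[str, int]:
        return {f: len(seqs) for f, seqs in self.families.items()}

    def total_members(self) -> int:
        return sum(len(s) for s in self.families.values())

    def iter_records(self) -> Iterable[tuple[str, str]]:
        """Yield ``(header, sequence)`` with ``family|superfamily|i`` headers."""
        for family in sorted(self.families):
            sf = self.superfamily_of[family]
            for i, seq in enumerate(self.families[family]):
                yield f"{family}{HEADER_SEP}{sf}{HEADER_SEP}{i}", seq

    def write_fasta(self, path: str | Path) -> None:
        records = [
            SeqRecord(Seq(seq), id=name, description="")
            for name, seq in self.iter_records()
        ]
        SeqIO.write(records, str(path), "fasta")

    @classmethod
    def from_fasta(cls, path: str | Path) -> "TEFamilyLibrary":
        lib = cls()
        for rec in SeqIO.parse(str(path), "fasta"):
            family, superfamily = parse_member_name(rec.id)[:2]
            lib.families.setdefault(family, []).append(str(rec.seq).upper())
            lib.superfamily_of[family] = superfamily
        return lib

    def summary(self) -> pd.DataFrame:
        rows = [
            {
                "family": f,
                "superfamily": self.superfamily_of[f],
                "member_count": len(seqs),
                "total_bp": sum(len(s) for s in seqs),
            }
            for f, seqs in sorted(self.families.items())
        ]
        return pd.DataFrame(rows, columns=["family", "superfamily", "member_count", "total_bp"])


def parse_member_name(name: str) -> tuple[str, str, int]:
    """Split a ``family|superfamily|index`` library member name."""
    parts = name.split(HEADER_SEP)
    if len(parts) != 3:
        raise ValueError(
            f"library member name {name!r} does not follow 'family{HEADER_SEP}superfamily{HEADER_SEP}index'"
        )
    family, superfamily, idx = parts
    if superfamily not in SUPERFAMILIES:
        raise SuperfamilyError(f"unknown superfamily in member name {name!r}")
    return family, superfamily, int(idx)


def load_te_annotation(bed_path: str | Path, family_delim: str = "#") -> list[TEInterval]:
    """Parse a BED4+ TE annotation whose name column is ``family<delim>superfamily``."""
    intervals: list[TEInterval] = []
    with open(bed_path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 4:
                raise BedParseError(f"{bed_path}:{lineno}: expected >=4 columns, got {len(fields)}")
            chrom, start_s, end_s, name = fields[:4]
            try:
                start, end = int(start_s), int(end_s)
            except ValueError as exc:
                raise BedParseError(f"{bed_path}:{lineno}: non-integer coordinates") from exc
            if family_delim not in name:
                raise BedParseError(
                    f"{bed_path}:{lineno}: name {name!r} lacks family delimiter {family_delim!r}"
                )
            family, superfamily = name.split(family_delim, 1)
            try:
                intervals.append(TEInterval(chrom, start, end, family, superfamily))
            except ValueError as exc:
                raise type(exc)(f"{bed_path}:{lineno}: {exc}") from exc
    return intervals


def family_member_counts(intervals: Iterable[TEInterval]) -> dict[str, int]:
    counts: collections.Counter[str] = collections.Counter()
    for iv in intervals:
        counts[iv.family] += 1
    return dict(counts)


def filter_families(intervals: Iterable[TEInterval], min_members: int = 20) -> list[str]:
    """Families with at least ``min_members`` annotated copies (inclusive), sorted."""
    if min_members < 1:
        raise ValueError("min_members must be >= 1")
    counts = family_member_counts(intervals)
    return sorted(f for f, n in counts.items() if n >= min_members)


def _load_genome(genome: str | Path | Mapping[str, str]) -> Mapping[str, str]:
    if isinstance(genome, Mapping):
        return genome
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(genome), "fasta")}


def extract_family_sequences(
    genome: str | Path | Mapping[str, str],
    intervals: Iterable[TEInterval],
    retained: Iterable[str],
) -> TEFamilyLibrary:
    """Extract the genome substring of every interval of a retained family.

    Sequences are uppercased and used verbatim (no consensus building, no
    strand handling — the mapper searches both strands).
    """
    seqs = _load_genome(genome)
    keep = set(retained)
    lib = TEFamilyLibrary()
    for iv in intervals:
        if iv.family not in keep:
            continue
        if iv.chrom not in seqs:
            raise KeyError(f"chromosome {iv.chrom!r} absent from genome")
        chrom_seq = seqs[iv.chrom]
        if iv.end > len(chrom_seq):
            raise IndexError(
                f"interval {iv.chrom}:{iv.start}-{iv.end} exceeds chromosome length {len(chrom_seq)}"
            )
        lib.families.setdefault(iv.family, []).append(chrom_seq[iv.start : iv.end].upper())
        lib.superfamily_of[iv.family] = iv.superfamily
    return lib


def build_library(
    genome: str | Path | Mapping[str, str],
    bed_path: str | Path,
    min_members: int = 20,
    family_delim: str = "#",
) -> TEFamilyLibrary:
    """Convenience: annotation → family filter → sequence extraction."""
    intervals = load_te_annotation(bed_path, family_delim=family_delim)
    retained = filter_families(intervals, min_members=min_members)
    return extract_family_sequences(genome, intervals, retained)
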