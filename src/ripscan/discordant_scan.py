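"""Discordant read-pair evidence for TE insertions.

A pair supports an insertion when exactly one mate maps to the TE family
library (any hit counts — TE families are internally repetitive, so
uniqueness cannot be required there) and the other mate maps *uniquely*
to the reference genome. The unique genomic mate anchors the insertion;
the family label comes from the TE-mapped mate.

Two entry points produce the same :class:`AnchorEvidence` records:
``scan_pairs`` (built-in mapper, desk mode) and ``import_sam_evidence``
(real data aligned externally: one SAM of both mates vs the TE reference,
one SAM of the TE-unmapped mates vs the genome).
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from ._mapper import (
    ClippedHit,
    MappingResult,
    SeedIndex,
    batch_seed_code_matrix,
    build_seed_index,
    clipped_map_encoded,
    encode,
    map_read,
    revcomp,
    _seed_positions,
)
from .te_library import TEFamilyLibrary, parse_member_name

__all__ = [
    "AnchorEvidence",
    "MappingResult",
    "SeedIndex",
    "build_seed_index",
    "map_read",
    "scan_pairs",
    "import_sam_evidence",
    "write_evidence",
    "read_evidence",
]


@dataclass
class AnchorEvidence:
    """One read pair's proof of a family insertion at a genomic anchor."""

    accession: str
    family: str
    chrom: str
    anchor_pos: int  # 0-based leftmost aligned base of the genomic mate
    pair_id: str
    te_mate_seq: str = ""
    anchor_mate_seq: str = ""


def _iter_fastq(path: str | Path) -> Iterable[tuple[str, str]]:
    from Bio import SeqIO

    path = str(path)
    if path.endswith(".gz"):
        with gzip.open(path, "rt") as fh:
            for rec in SeqIO.parse(fh, "fastq"):
                yield rec.id, str(rec.seq).upper()
    else:
        for rec in SeqIO.parse(path, "fastq"):
            yield rec.id, str(rec.seq).upper()


def _load_reads(source) -> tuple[list[str], list[str]]:
    """Accept a FASTQ path or an iterable of (name, seq) pairs."""
    if isinstance(source, (str, Path)):
        pairs = list(_iter_fastq(source))
    else:
        pairs = [(n, s.upper()) for n, s in source]
    return [n for n, _ in pairs], [s for _, s in pairs]


def _te_index(te_library, k: int) -> SeedIndex:
    if isinstance(te_library, SeedIndex):
        return te_library
    if isinstance(te_library, TEFamilyLibrary):
        items = list(te_library.iter_records())
    elif isinstance(te_library, (str, Path)):
        items = list(TEFamilyLibrary.from_fasta(te_library).iter_records())
    else:
        items = list(te_library.items())
    return SeedIndex([n for n, _ in items], [s for _, s in items], k=k)


def _genome_index(genome, k: int) -> SeedIndex:
    if isinstance(genome, SeedIndex):
        return genome
    if isinstance(genome, (str, Path)):
        from Bio import SeqIO

        genome = {r.id: str(r.seq).upper() for r in SeqIO.parse(str(genome), "fasta")}
    return build_seed_index(genome, k=k)


def _batch_te_hits(
    seqs: Sequence[str],
    index: SeedIndex,
    min_aligned: int,
    max_mismatch_frac: float,
    n_seeds: int,
) -> list[Optional[ClippedHit]]:
    """TE-library hit per read; vectorised seed prefilter, lazy extension."""
    out: list[Optional[ClippedHit]] = [None] * len(seqs)
    if not seqs:
        return out
    by_len: dict[int, list[int]] = {}
    for i, s in enumerate(seqs):
        by_len.setdefault(len(s), []).append(i)
    for L, idxs in by_len.items():
        if L < index.k:
            continue
        mat = np.empty((len(idxs), L), dtype=np.uint8)
        for row, i in enumerate(idxs):
            mat[row] = encode(seqs[i])
        positions = _seed_positions(L, index.k, n_seeds)
        codes = batch_seed_code_matrix(mat, index.k, positions)
        flagged = np.nonzero(index.contains_batch(codes).any(axis=1))[0]
        for row in flagged.tolist():
            out[idxs[row]] = clipped_map_encoded(
                mat[row], index, min_aligned=min_aligned,
                max_mismatch_frac=max_mismatch_frac, n_seeds=n_seeds,
            )
    return out


def scan_pairs(
    fastq1,
    fastq2,
    te_library,
    genome,
    accession: str,
    *,
    te_k: int = 17,
    genome_k: int = 31,
    min_te_aligned: int = 30,
    max_mismatch_frac: float = 0.05,
    min_seed_hits: int = 2,
    te_n_seeds: int = 10,
    dedup: bool = False,
    sam_out: Optional[tuple[str | Path, str | Path]] = None,
) -> list[AnchorEvidence]:
    """Scan paired reads for discordant TE evidence with the built-in mapper.

    ``fastq1``/``fastq2`` may be FASTQ(.gz) paths or in-memory
    ``(name, sequence)`` iterables. ``te_library``/``genome`` may be paths,
    dict-like sequence maps, a :class:`TEFamilyLibrary`, or prebuilt
    :class:`SeedIndex` objects (pass indexes to amortise across accessions).
    """
    names1, seqs1 = _load_reads(fastq1)
    names2, seqs2 = _load_reads(fastq2)
    if len(seqs1) != len(seqs2):
        raise ValueError(
            f"mismatched pair counts: {len(seqs1)} vs {len(seqs2)} reads"
        )
    for n1, n2 in zip(names1[:1], names2[:1]):
        if n1.split("/")[0] != n2.split("/")[0]:
            raise ValueError(f"FASTQ files look out of sync: {n1!r} vs {n2!r}")

    te_idx = _te_index(te_library, te_k)
    g_idx = _genome_index(genome, genome_k)

    hits1 = _batch_te_hits(seqs1, te_idx, min_te_aligned, max_mismatch_frac, te_n_seeds)
    hits2 = _batch_te_hits(seqs2, te_idx, min_te_aligned, max_mismatch_frac, te_n_seeds)

    evidence: list[AnchorEvidence] = []
    sam_te_rows: list[tuple] = []
    sam_g_rows: list[tuple] = []
    seen: set[tuple] = set()
    for i, name in enumerate(names1):
        h1, h2 = hits1[i], hits2[i]
        if sam_out is not None:
            sam_te_rows.append((name, seqs1[i], seqs2[i], h1, h2))
        if (h1 is None) == (h2 is None):
            continue  # both TE-mapped (inside the element) or neither: no evidence
        te_hit, te_seq = (h1, seqs1[i]) if h1 is not None else (h2, seqs2[i])
        anchor_seq = seqs2[i] if h1 is not None else seqs1[i]
        m = map_read(
            anchor_seq, g_idx, min_seed_hits=min_seed_hits,
            max_mismatch_frac=max_mismatch_frac,
        )
        if sam_out is not None:
            # the anchor is mate 2 exactly when mate 1 was the TE hit
            sam_g_rows.append((name, h1 is not None, anchor_seq, m))
        if m.status != "unique":
            continue
        family = parse_member_name(te_hit.target)[0]
        if dedup:
            key = (m.chrom, m.pos, m.strand, te_seq)
            if key in seen:
                continue
            seen.add(key)
        evidence.append(
            AnchorEvidence(
                accession=accession, family=family, chrom=m.chrom,
                anchor_pos=int(m.pos), pair_id=name,
                te_mate_seq=te_seq, anchor_mate_seq=anchor_seq,
            )
        )
    if sam_out is not None:
        _write_te_sam(sam_out[0], te_idx, sam_te_rows)
        _write_genome_sam(sam_out[1], g_idx, sam_g_rows)
    return evidence


# --- SAM export (so the import path can be exercised on scan output) ---

_FLAG_PAIRED = 0x1
_FLAG_UNMAPPED = 0x4
_FLAG_REVERSE = 0x10
_FLAG_FIRST = 0x40
_FLAG_SECOND = 0x80


def _sam_header(index: SeedIndex) -> str:
    lines = ["@HD\tVN:1.6\tSO:unsorted"]
    for name, seq in zip(index.names, index.seqs):
        lines.append(f"@SQ\tSN:{name}\tLN:{len(seq)}")
    return "\n".join(lines) + "\n"


def _te_record(name: str, seq: str, hit: Optional[ClippedHit], mate_flag: int) -> str:
    flag = _FLAG_PAIRED | mate_flag
    if hit is None:
        return f"{name}\t{flag | _FLAG_UNMAPPED}\t*\t0\t0\t*\t*\t0\t0\t{seq}\tI" + "I" * (len(seq) - 1)
    out_seq = seq if hit.is_forward else revcomp(seq)
    if not hit.is_forward:
        flag |= _FLAG_REVERSE
    a, b, L = hit.aligned_start, hit.aligned_end, len(seq)
    cigar = (f"{a}S" if a else "") + f"{b - a}M" + (f"{L - b}S" if b < L else "")
    pos = hit.read_start + a + 1  # SAM 1-based
    return (
        f"{name}\t{flag}\t{hit.target}\t{pos}\t255\t{cigar}\t*\t0\t0\t{out_seq}\t"
        + "I" * L
    )


def _write_te_sam(path, index: SeedIndex, rows) -> None:
    with open(path, "w") as fh:
        fh.write(_sam_header(index))
        for name, s1, s2, h1, h2 in rows:
            fh.write(_te_record(name, s1, h1, _FLAG_FIRST) + "\n")
            fh.write(_te_record(name, s2, h2, _FLAG_SECOND) + "\n")


def _write_genome_sam(path, index: SeedIndex, rows) -> None:
    with open(path, "w") as fh:
        fh.write(_sam_header(index))
        for name, anchor_is_mate2, seq, m in rows:
            mate_flag = _FLAG_SECOND if anchor_is_mate2 else _FLAG_FIRST
            flag = _FLAG_PAIRED | mate_flag
            L = len(seq)
            if m.status == "unique":
                if m.strand == "-":
                    flag |= _FLAG_REVERSE
                    seq = revcomp(seq)
                fh.write(
                    f"{name}\t{flag}\t{m.chrom}\t{m.pos + 1}\t60\t{L}M\t*\t0\t0\t{seq}\t"
                    + "I" * L + "\n"
                )
            else:
                # multi-mappers carry no reported position here; both multi and
                # unmapped anchors are written unmapped and fail the import
                # filter exactly as they fail the scan filter
                fh.write(
                    f"{name}\t{flag | _FLAG_UNMAPPED}\t*\t0\t0\t*\t*\t0\t0\t{seq}\t"
                    + "I" * L + "\n"
                )


def import_sam_evidence(
    sam_vs_te: str | Path,
    sam_vs_genome: str | Path,
    accession: str,
    min_mapq: int = 20,
) -> list[AnchorEvidence]:
    """Build evidence from externally aligned SAM files.

    ``sam_vs_te``: both mates aligned to the TE reference (members named
    ``family|superfamily|index``). ``sam_vs_genome``: the TE-unmapped mates
    aligned to the genome. "Unique" in the genome SAM means a primary,
    non-secondary/supplementary alignment with MAPQ >= ``min_mapq``.
    """
    import pysam

    te_status: dict[tuple[str, int], tuple[bool, Optional[str], Optional[str]]] = {}
    with pysam.AlignmentFile(str(sam_vs_te), "r", check_sq=False) as sam:
        for rec in sam:
            if rec.is_secondary or rec.is_supplementary:
                continue
            mate = 2 if rec.is_read2 else 1
            mapped = not rec.is_unmapped
            family = None
            if mapped:
                family = parse_member_name(rec.reference_name)[0]
            seq = rec.query_sequence or ""
            if mapped and rec.is_reverse:
                seq = revcomp(seq)
            te_status[(rec.query_name, mate)] = (mapped, family, seq)

    evidence: list[AnchorEvidence] = []
    with pysam.AlignmentFile(str(sam_vs_genome), "r", check_sq=False) as sam:
        for rec in sam:
            if rec.is_secondary or rec.is_supplementary:
                continue
            if rec.is_unmapped or rec.mapping_quality < min_mapq:
                continue
            mate = 2 if rec.is_read2 else 1
            other = 1 if mate == 2 else 2
            self_te = te_status.get((rec.query_name, mate))
            other_te = te_status.get((rec.query_name, other))
            if other_te is None:
                continue
            # retention: this mate must be TE-unmapped, the other TE-mapped
            if self_te is not None and self_te[0]:
                continue
            if not other_te[0]:
                continue
            family = other_te[1]
            if family is None:
                raise ValueError(
                    f"pair {rec.query_name}: TE-mapped mate lacks a parseable family"
                )
            seq = rec.query_sequence or ""
            if rec.is_reverse:
                seq = revcomp(seq)
            evidence.append(
                AnchorEvidence(
                    accession=accession, family=family,
                    chrom=rec.reference_name, anchor_pos=int(rec.reference_start),
                    pair_id=rec.query_name,
                    te_mate_seq=other_te[2], anchor_mate_seq=seq,
                )
            )
    return evidence


EVIDENCE_COLUMNS = [
    "accession", "family", "chrom", "anchor_pos", "pair_id",
    "te_mate_seq", "anchor_mate_seq",
]


def write_evidence(evidence: Sequence[AnchorEvidence], path: str | Path) -> None:
    pd.DataFrame(
        [[getattr(e, c) for c in EVIDENCE_COLUMNS] for e in evidence],
        columns=EVIDENCE_COLUMNS,
    ).to_csv(path, sep="\t", index=False)


def read_evidence(path: str | Path) -> list[AnchorEvidence]:
    df = pd.read_csv(path, sep="\t", dtype={"anchor_pos": int}, keep_default_na=False)
    return [AnchorEvidence(**row) for row in df.to_dict(orient="records")]
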