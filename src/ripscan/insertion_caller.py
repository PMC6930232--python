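"""Windowed insertion calling, copy number, and assembly-based validation.

Anchors are tallied into fixed, non-overlapping 10 kb windows tiled from
coordinate 0. A (family, chrom, window) locus is *called* when it collects
more than three supporting pairs (>3, i.e. >=4); *copy number* counts
windows with at least three supporting pairs (>=3). The two thresholds are
deliberately kept as separate defaults — they are defined differently and
both definitions are honoured.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, NamedTuple, Optional, Sequence

import numpy as np
import pandas as pd

from ._mapper import SeedIndex, build_seed_index, encode, map_read
from .discordant_scan import AnchorEvidence
from .te_library import TEInterval

DEFAULT_WINDOW = 10_000
CALL_MIN_READS = 4  # realizes the ">3 reads" call rule
COPY_MIN_READS = 3  # realizes the "at least three reads" copy-number rule


class WindowKey(NamedTuple):
    family: str
    chrom: str
    window_index: int


def assign_window(pos: int, window_size: int = DEFAULT_WINDOW) -> int:
    """Window index of a position: floor(pos / window_size)."""
    if pos < 0:
        raise ValueError("position must be >= 0")
    if window_size <= 0:
        raise ValueError("window_size must be > 0")
    return pos // window_size


@dataclass
class InsertionCallSet:
    """Per-accession windowed anchor counts and called insertion loci."""

    accession: str
    window_size: int = DEFAULT_WINDOW
    counts: dict[WindowKey, int] = field(default_factory=dict)
    calls: set[WindowKey] = field(default_factory=set)
    insertion_point: dict[WindowKey, int] = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "accession": self.accession,
                "family": k.family,
                "chrom": k.chrom,
                "window_start": k.window_index * self.window_size,
                "window_end": (k.window_index + 1) * self.window_size,
                "read_count": c,
                "insertion_point": self.insertion_point.get(k, -1),
                "called": int(k in self.calls),
            }
            for k, c in sorted(self.counts.items())
        ]
        return pd.DataFrame(
            rows,
            columns=[
                "accession", "family", "chrom", "window_start", "window_end",
                "read_count", "insertion_point", "called",
            ],
        )


def call_insertions(
    evidence: Sequence[AnchorEvidence],
    window_size: int = DEFAULT_WINDOW,
    min_reads: int = CALL_MIN_READS,
) -> InsertionCallSet:
    """Tally evidence into windows and call loci with >= ``min_reads`` support.

    The representative insertion point of a window is the lower median of
    its contributing anchor positions.
    """
    accessions = {e.accession for e in evidence}
    if len(accessions) > 1:
        raise ValueError(f"evidence mixes accessions: {sorted(accessions)}")
    acc = accessions.pop() if accessions else ""
    positions: dict[WindowKey, list[int]] = {}
    for e in evidence:
        key = WindowKey(e.family, e.chrom, assign_window(e.anchor_pos, window_size))
        positions.setdefault(key, []).append(e.anchor_pos)
    counts = {k: len(v) for k, v in positions.items()}
    calls = {k for k, c in counts.items() if c >= min_reads}
    ipoint = {
        k: sorted(v)[(len(v) - 1) // 2] for k, v in positions.items()
    }
    return InsertionCallSet(acc, window_size, counts, calls, ipoint)


def copy_number(callset: InsertionCallSet, min_reads: int = COPY_MIN_READS) -> int:
    """Number of windows covered by at least ``min_reads`` supporting pairs."""
    return sum(1 for c in callset.counts.values() if c >= min_reads)


def copy_number_by_family(
    callset: InsertionCallSet, min_reads: int = COPY_MIN_READS
) -> dict[str, int]:
    out: dict[str, int] = {}
    for k, c in callset.counts.items():
        if c >= min_reads:
            out[k.family] = out.get(k.family, 0) + 1
    return out


def mask_reference_windows(
    callset: InsertionCallSet,
    te_intervals: Iterable[TEInterval],
    pad: int = 0,
) -> InsertionCallSet:
    """Drop windows overlapping same-family annotated reference TE copies.

    Evidence at reference-resident elements is genuine TE presence shared by
    every accession; masking it isolates the polymorphic component. ``pad``
    widens each annotated interval (anchors scatter a fragment-length around
    element boundaries).
    """
    masked: set[WindowKey] = set()
    ws = callset.window_size
    for iv in te_intervals:
        w0 = max(0, iv.start - pad) // ws
        w1 = (iv.end + pad - 1) // ws
        for w in range(w0, w1 + 1):
            masked.add(WindowKey(iv.family, iv.chrom, w))
    keep = [k for k in callset.counts if k not in masked]
    return InsertionCallSet(
        callset.accession,
        ws,
        {k: callset.counts[k] for k in keep},
        {k for k in callset.calls if k not in masked},
        {k: callset.insertion_point[k] for k in keep if k in callset.insertion_point},
    )


def _sliding_min_mismatch(region_codes: np.ndarray, read_codes: np.ndarray) -> int:
    """Minimum mismatch count of a read against every offset of a region."""
    L = read_codes.size
    if region_codes.size < L:
        return L
    win = np.lib.stride_tricks.sliding_window_view(region_codes, L)
    return int((win != read_codes).sum(axis=1).min())


def validate_against_assembly(
    callset: InsertionCallSet,
    evidence: Sequence[AnchorEvidence],
    alt_genome: Mapping[str, str] | str | Path,
    flank: int = 2000,
    restrict: Optional[set[WindowKey]] = None,
    max_mismatch_frac: float = 0.05,
    alt_index: Optional[SeedIndex] = None,
) -> Optional[float]:
    """Fraction of TE-mate reads that land near their anchor in an assembly.

    For every supporting pair of a called window, the genomic (anchor) mate
    is mapped uniquely to ``alt_genome``; its TE mate is then searched,
    mismatch-tolerantly on both strands, within ``flank`` bp of that located
    position. An assembly that truly carries the insertions validates almost
    all TE mates; an insertion-free assembly validates almost none.
    """
    if flank <= 0:
        warnings.warn("flank must be positive; validation skipped")
        return None
    calls = callset.calls if restrict is None else (callset.calls & restrict)
    if not calls:
        warnings.warn("no called windows to validate")
        return None
    if alt_index is None:
        if isinstance(alt_genome, (str, Path)):
            from Bio import SeqIO

            alt_genome = {
                r.id: str(r.seq).upper() for r in SeqIO.parse(str(alt_genome), "fasta")
            }
        if not alt_genome or all(len(s) == 0 for s in alt_genome.values()):
            raise ValueError("alternate genome is empty")
        alt_index = build_seed_index(alt_genome, k=31)
    alt_codes = {n: enc for n, enc in zip(alt_index.names, alt_index.encoded)}

    tested = 0
    validated = 0
    ws = callset.window_size
    for e in evidence:
        key = WindowKey(e.family, e.chrom, assign_window(e.anchor_pos, ws))
        if key not in calls:
            continue
        if not e.te_mate_seq or not e.anchor_mate_seq:
            continue
        tested += 1
        m = map_read(e.anchor_mate_seq, alt_index, max_mismatch_frac=max_mismatch_frac)
        if m.status != "unique":
            continue
        codes = alt_codes[m.chrom]
        lo = max(0, m.pos - flank)
        hi = min(codes.size, m.pos + len(e.anchor_mate_seq) + flank)
        region = codes[lo:hi]
        te = encode(e.te_mate_seq)
        te_rc = np.uint8(3) - te[::-1] if te.max() <= 3 else None
        budget = int(max_mismatch_frac * te.size)
        mm = _sliding_min_mismatch(region, te)
        if mm > budget and te_rc is not None:
            mm = min(mm, _sliding_min_mismatch(region, te_rc))
        if mm <= budget:
            validated += 1
    if tested == 0:
        warnings.warn("no testable pairs in called windows")
        return None
    return validated / tested


def write_calls(callset: InsertionCallSet, path: str | Path) -> None:
    callset.to_frame().to_csv(path, sep="\t", index=False)


def write_calls_bed(callset: InsertionCallSet, path: str | Path) -> None:
    """Called windows as BED6 (name = family, score = read count)."""
    with open(path, "w") as fh:
        for k in sorted(callset.calls):
            fh.write(
                f"{k.chrom}\t{k.window_index * callset.window_size}\t"
                f"{(k.window_index + 1) * callset.window_size}\t{k.family}\t"
                f"{callset.counts[k]}\t.\n"
            )


def read_calls(path: str | Path, min_reads: int = CALL_MIN_READS) -> InsertionCallSet:
    df = pd.read_csv(path, sep="\t", keep_default_na=False)
    accs = set(df["accession"]) if len(df) else {""}
    if len(accs) > 1:
        raise ValueError(f"calls file mixes accessions: {sorted(accs)}")
    acc = accs.pop()
    if len(df):
        ws = int(df["window_end"].iloc[0] - df["window_start"].iloc[0])
    else:
        ws = DEFAULT_WINDOW
    cs = InsertionCallSet(acc, ws)
    for row in df.itertuples(index=False):
        k = WindowKey(row.family, row.chrom, row.window_start // ws)
        cs.counts[k] = int(row.read_count)
        cs.insertion_point[k] = int(row.insertion_point)
        if row.called:
            cs.calls.add(k)
    return cs
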