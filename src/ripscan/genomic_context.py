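"""Relate insertion calls to gene annotation.

Feature classification (exon > intron > up2kb > down2kb > intergenic),
distance to the transcription start site, 1 Mb insertion-density vs
gene-density correlation, a metagene profile of anchor reads around gene
bodies, and the landrace/teosinte upstream read-depth enrichment screen.

Calls enter these statistics as points (their representative insertion
position), not as 10 kb windows; bp-scale summaries such as mean TSS
distance are meaningless at window resolution.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from intervaltree import IntervalTree
from scipy import stats

FEATURE_CLASSES = ("exon", "intron", "up2kb", "down2kb", "intergenic")


@dataclass
class GeneModel:
    """One gene, 0-based half-open, with sorted non-overlapping exons."""

    gene_id: str
    chrom: str
    strand: str
    start: int
    end: int
    exons: list[tuple[int, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError(f"gene {self.gene_id}: missing/invalid strand {self.strand!r}")
        if not self.exons:
            self.exons = [(self.start, self.end)]
        self.exons = _merge_intervals(self.exons)
        for s, e in self.exons:
            if s < self.start or e > self.end:
                raise ValueError(f"gene {self.gene_id}: exon ({s},{e}) outside gene body")

    @property
    def tss(self) -> int:
        return self.start if self.strand == "+" else self.end - 1

    def upstream(self, flank: int) -> tuple[int, int]:
        if self.strand == "+":
            return max(0, self.start - flank), self.start
        return self.end, self.end + flank

    def downstream(self, flank: int) -> tuple[int, int]:
        if self.strand == "+":
            return self.end, self.end + flank
        return max(0, self.start - flank), self.start


def _merge_intervals(intervals: Iterable[tuple[int, int]]) -> list[tuple[int, int]]:
    ivs = sorted(intervals)
    merged: list[tuple[int, int]] = []
    for s, e in ivs:
        if merged and s <= merged[-1][1]:
            merged[-1] = (merged[-1][0], max(merged[-1][1], e))
        else:
            merged.append((s, e))
    return merged


def load_genes(gff3: str | Path) -> list[GeneModel]:
    """Parse gene + exon features from GFF3 (1-based inclusive -> 0-based half-open)."""
    import gffutils

    db = gffutils.create_db(
        str(gff3), ":memory:", force=True, keep_order=True,
        merge_strategy="create_unique",
    )
    genes: list[GeneModel] = []
    for g in db.features_of_type("gene"):
        if g.strand not in "+-":
            raise ValueError(f"gene {g.id}: missing strand")
        exons = [(e.start - 1, e.end) for e in db.children(g, featuretype="exon")]
        for s, e in exons:
            if s < g.start - 1 or e > g.end:
                raise ValueError(f"gene {g.id}: exon ({s},{e}) outside gene")
        genes.append(
            GeneModel(
                gene_id=g.id, chrom=g.seqid, strand=g.strand,
                start=g.start - 1, end=g.end, exons=exons,
            )
        )
    return genes


def write_gff3(genes: Sequence[GeneModel], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in genes:
            fh.write(
                f"{g.chrom}\tripscan\tgene\t{g.start + 1}\t{g.end}\t.\t{g.strand}\t.\tID={g.gene_id}\n"
            )
            for i, (s, e) in enumerate(g.exons, start=1):
                fh.write(
                    f"{g.chrom}\tripscan\texon\t{s + 1}\t{e}\t.\t{g.strand}\t.\t"
                    f"ID={g.gene_id}.exon{i};Parent={g.gene_id}\n"
                )


class GeneContext:
    """Interval-tree wrapper over a gene set for point queries."""

    def __init__(self, genes: Sequence[GeneModel], flank: int = 2000):
        self.genes = list(genes)
        self.flank = flank
        self._exon: dict[str, IntervalTree] = {}
        self._body: dict[str, IntervalTree] = {}
        self._up: dict[str, IntervalTree] = {}
        self._down: dict[str, IntervalTree] = {}
        self._span: dict[str, IntervalTree] = {}
        self._tss: dict[str, np.ndarray] = {}
        by_chrom: dict[str, list[int]] = {}
        for g in self.genes:
            for s, e in g.exons:
                self._exon.setdefault(g.chrom, IntervalTree()).addi(s, e, g)
            self._body.setdefault(g.chrom, IntervalTree()).addi(g.start, g.end, g)
            for tree, (s, e) in (
                (self._up, g.upstream(flank)),
                (self._down, g.downstream(flank)),
            ):
                if s < e:
                    tree.setdefault(g.chrom, IntervalTree()).addi(s, e, g)
            s = max(0, g.start - flank)
            self._span.setdefault(g.chrom, IntervalTree()).addi(s, g.end + flank, g)
            by_chrom.setdefault(g.chrom, []).append(g.tss)
        self._tss = {c: np.sort(np.array(p, dtype=np.int64)) for c, p in by_chrom.items()}

    def classify(self, point: int, chrom: str) -> str:
        if point < 0:
            raise ValueError("point must be >= 0")
        for name, trees in (
            ("exon", self._exon), ("intron", self._body),
            ("up2kb", self._up), ("down2kb", self._down),
        ):
            t = trees.get(chrom)
            if t is not None and t.overlaps_point(point):
                return name
        return "intergenic"

    def distance_to_tss(self, point: int, chrom: str) -> Optional[int]:
        tss = self._tss.get(chrom)
        if tss is None or tss.size == 0:
            warnings.warn(f"no genes on {chrom}; TSS distance undefined")
            return None
        i = int(np.searchsorted(tss, point))
        best = min(
            (abs(point - int(tss[j])) for j in (i - 1, i) if 0 <= j < tss.size)
        )
        return best

    def genes_overlapping_span(self, point: int, chrom: str):
        t = self._span.get(chrom)
        if t is None:
            return []
        return [iv.data for iv in t.at(point)]


def classify_feature(point: int, chrom: str, genes: Sequence[GeneModel] | GeneContext) -> str:
    ctx = genes if isinstance(genes, GeneContext) else GeneContext(genes)
    return ctx.classify(point, chrom)


def distance_to_tss(point: int, chrom: str, genes: Sequence[GeneModel] | GeneContext) -> Optional[int]:
    ctx = genes if isinstance(genes, GeneContext) else GeneContext(genes)
    return ctx.distance_to_tss(point, chrom)


def feature_class_percentages(
    points: Iterable[tuple[str, int]], genes: Sequence[GeneModel] | GeneContext
) -> dict[str, float]:
    """Percentage of points per feature class (sums to 100 over nonempty input)."""
    ctx = genes if isinstance(genes, GeneContext) else GeneContext(genes)
    counts = {c: 0 for c in FEATURE_CLASSES}
    n = 0
    for chrom, p in points:
        counts[ctx.classify(p, chrom)] += 1
        n += 1
    if n == 0:
        warnings.warn("no points to classify")
        return {c: 0.0 for c in FEATURE_CLASSES}
    return {c: 100.0 * v / n for c, v in counts.items()}


def megabase_density_correlation(
    points: Iterable[tuple[str, int]],
    genes: Sequence[GeneModel],
    chrom_lengths: Mapping[str, int],
    bin_size: int = 1_000_000,
) -> Optional[float]:
    """Pearson r between per-bin insertion counts and per-bin gene-start counts."""
    edges: dict[str, int] = {}
    offset = 0
    nbins_total = 0
    for chrom, L in chrom_lengths.items():
        edges[chrom] = offset
        offset += -(-L // bin_size)
        nbins_total = offset
    if nbins_total < 3:
        raise ValueError("need >= 3 bins; shrink bin_size or provide longer chromosomes")
    ins = np.zeros(nbins_total)
    gen = np.zeros(nbins_total)
    for chrom, p in points:
        ins[edges[chrom] + p // bin_size] += 1
    for g in genes:
        gen[edges[g.chrom] + g.start // bin_size] += 1
    if np.ptp(ins) == 0 or np.ptp(gen) == 0:
        warnings.warn("zero-variance bin vector; correlation undefined")
        return None
    return float(stats.pearsonr(ins, gen)[0])


def metagene_profile(
    anchors: Iterable[tuple[str, int]],
    genes: Sequence[GeneModel] | GeneContext,
    flank: int = 2000,
    body_bins: int = 100,
    flank_bin: int = 50,
) -> np.ndarray:
    """Normalized anchor-density profile over (5' flank, body, 3' flank).

    The body is rescaled to ``body_bins`` bins; each flank has
    ``flank // flank_bin`` fixed-width bins; minus-strand genes are flipped
    so bin 0 is always the far 5' end. The profile sums to 1 (all-zero with
    a warning if nothing falls near a gene). Flipping every gene's strand
    reverses the profile exactly.
    """
    ctx = genes if isinstance(genes, GeneContext) else GeneContext(genes, flank=flank)
    n_flank = flank // flank_bin
    B = 2 * n_flank + body_bins
    prof = np.zeros(B)
    any_anchor = False
    for chrom, x in anchors:
        any_anchor = True
        for g in ctx.genes_overlapping_span(x, chrom):
            lo = g.start - flank
            if not (lo <= x < g.end + flank):
                continue
            # genomic-layout bin, then flip for minus-strand genes
            if x < g.start:
                raw = (x - lo) // flank_bin
            elif x < g.end:
                raw = n_flank + (x - g.start) * body_bins // (g.end - g.start)
            else:
                raw = n_flank + body_bins + (x - g.end) // flank_bin
            bin_ = raw if g.strand == "+" else B - 1 - raw
            prof[int(bin_)] += 1
    if not any_anchor:
        warnings.warn("empty anchor set; metagene profile is all-zero")
        return prof
    total = prof.sum()
    return prof / total if total > 0 else prof


def distance_summary_by_group(
    points_by_group: Mapping[str, Sequence[tuple[str, int]]],
    genes: Sequence[GeneModel] | GeneContext,
) -> tuple[dict[str, float], dict[tuple[str, str], Optional[float]]]:
    """Mean TSS distance per group + Welch-test p-value per group pair."""
    ctx = genes if isinstance(genes, GeneContext) else GeneContext(genes)
    dists = {
        g: [d for c, p in pts if (d := ctx.distance_to_tss(p, c)) is not None]
        for g, pts in points_by_group.items()
    }
    means = {g: float(np.mean(v)) if v else float("nan") for g, v in dists.items()}
    pvals: dict[tuple[str, str], Optional[float]] = {}
    names = sorted(dists)
    for i, a in enumerate(names):
        for b in names[i + 1 :]:
            if len(dists[a]) < 2 or len(dists[b]) < 2:
                pvals[(a, b)] = None
                continue
            pvals[(a, b)] = float(stats.ttest_ind(dists[a], dists[b], equal_var=False)[1])
    return means, pvals


def upstream_depth_by_gene(
    anchors: Iterable[tuple[str, int]],
    genes: Sequence[GeneModel],
    flank: int = 2000,
) -> dict[str, int]:
    """Raw anchor count in each gene's strand-aware upstream ``flank``."""
    trees: dict[str, IntervalTree] = {}
    for g in genes:
        s, e = g.upstream(flank)
        if s < e:
            trees.setdefault(g.chrom, IntervalTree()).addi(s, e, g.gene_id)
    counts = {g.gene_id: 0 for g in genes}
    for chrom, p in anchors:
        t = trees.get(chrom)
        if t is None:
            continue
        for iv in t.at(p):
            counts[iv.data] += 1
    return counts


def upstream_enrichment(
    depth_by_group: Mapping[str, Mapping[str, int]],
    group_sizes: Mapping[str, int],
    numerator: str = "landrace",
    denominator: str = "teosinte",
    ratio: float = 5.0,
) -> list[str]:
    """Genes whose per-accession-normalized upstream depth ratio is >= ``ratio``.

    Depths are divided by group size before the ratio (unequal cohorts would
    otherwise bias toward the larger group); a pseudocount of one read in the
    denominator group avoids division by zero.
    """
    for g in (numerator, denominator):
        if g not in depth_by_group:
            raise KeyError(f"group {g!r} missing from depth_by_group")
    num_size = group_sizes[numerator]
    den_size = group_sizes[denominator]
    num = depth_by_group[numerator]
    den = depth_by_group[denominator]
    out = []
    for gene in sorted(set(num) | set(den)):
        n = num.get(gene, 0) / num_size
        d = den.get(gene, 0) / den_size + 1.0 / den_size
        if n > 0 and n / d >= ratio:
            out.append(gene)
    return out
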