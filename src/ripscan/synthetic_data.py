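"""Desk-scale synthetic cohort with known TE-insertion ground truth.

The generator emulates the statistical structure the analysis assumes:
a reference genome carrying annotated full-length TE copies (so the family
filter has members to count), a cohort of accessions in three germplasm
groups (teosinte / landrace / improved) whose donor genomes carry shared,
group-specific and private insertions of those families, and paired-end
reads at a few-fold coverage. Landrace accessions draw more group-specific
insertions than teosinte, improved fewer — the amplification-then-
contraction pattern the population statistics are meant to recover.

Truth positions are in *reference* coordinates (the coordinate system
calls are made in), so recovery tests need no lift-over.
"""

from __future__ import annotations

import gzip
import zlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, NamedTuple, Sequence

import numpy as np
import pandas as pd

from .genomic_context import GeneModel, write_gff3
from .te_library import TEFamilyLibrary, TEInterval

# real maize LTR family names, alternating Copia/Gypsy
_FAMILY_NAMES = [
    ("ji", "Copia"), ("huck", "Gypsy"), ("opie", "Copia"), ("cinful-zeon", "Gypsy"),
    ("giepum", "Copia"), ("grande", "Gypsy"), ("ruda", "Copia"), ("tekay", "Gypsy"),
    ("wiwa", "Copia"), ("doke", "Gypsy"), ("ebel", "Copia"), ("gyma", "Gypsy"),
]

_DECODE = np.frombuffer(b"ACGT", dtype=np.uint8)


class PlacementError(RuntimeError):
    """Requested insertions cannot be placed under the spacing constraint."""


class TruthRecord(NamedTuple):
    accession: str
    group: str
    family: str
    chrom: str
    position: int  # 0-based bp, reference coordinates


@dataclass
class SyntheticTruth:
    records: list[TruthRecord] = field(default_factory=list)

    def __post_init__(self) -> None:
        seen = set()
        for r in self.records:
            key = (r.accession, r.chrom, r.position)
            if key in seen:
                raise ValueError(f"duplicate truth record {key}")
            seen.add(key)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.records, columns=TruthRecord._fields)
        return df.sort_values(["accession", "chrom", "position"]).reset_index(drop=True)


@dataclass
class CohortSpec:
    """Cohort design. Defaults are the package's standard desk-scale study.

    3 groups x 4 accessions on one 2 Mb chromosome; 3 TE families of 5 kb
    with 25 planted reference copies each; insertion pools shared=10,
    per-group teosinte=15 / landrace=30 / improved=5, private=5 per
    accession; 5X 2x100 bp reads, 300+-30 bp fragments, 0.5% substitution
    error.
    """

    genome_length: int = 2_000_000
    n_chroms: int = 1
    n_families: int = 3
    te_length: int = 5_000
    groups: dict[str, int] = field(
        default_factory=lambda: {"teosinte": 4, "landrace": 4, "improved": 4}
    )
    pool_sizes: dict = field(
        default_factory=lambda: {
            "shared": 10,
            "per_group": {"teosinte": 15, "landrace": 30, "improved": 5},
            "private": 5,
        }
    )
    coverage: float = 5.0
    read_length: int = 100
    fragment_mean: int = 300
    fragment_sd: float = 30.0
    error_rate: float = 0.005
    seed: int = 7
    n_ref_copies: int = 25
    divergence: float = 0.01  # per-copy divergence from the family prototype
    te_clearance: int = 2_500  # min distance of polymorphic sites from reference copies
    # polymorphic sites sit at least a 10 kb window away from same-family
    # reference copies, so reference-resident and polymorphic signals occupy
    # distinct (family, window) loci — the identifiability condition the
    # window-based locus definition assumes
    same_family_clearance: int = 11_500
    n_genes_per_chrom: int = 40

    def __post_init__(self) -> None:
        if self.coverage <= 0:
            raise ValueError("coverage must be > 0")
        if self.read_length >= self.fragment_mean:
            raise ValueError("read_length must be < fragment_mean")
        if not (0 <= self.error_rate < 1):
            raise ValueError("error_rate must be in [0, 1)")
        if any(n < 0 for n in self.groups.values()):
            raise ValueError("group sizes must be >= 0")
        if self.pool_sizes.get("shared", 0) < 0 or self.pool_sizes.get("private", 0) < 0:
            raise ValueError("pool sizes must be >= 0")

    def per_group_pool(self, group: str) -> int:
        pg = self.pool_sizes.get("per_group", 0)
        if isinstance(pg, dict):
            return int(pg.get(group, 0))
        return int(pg)

    @property
    def accessions(self) -> list[str]:
        return [f"{g}_{i + 1}" for g in self.groups for i in range(self.groups[g])]

    @property
    def group_of(self) -> dict[str, str]:
        return {f"{g}_{i + 1}": g for g in self.groups for i in range(self.groups[g])}


class InsertionLocus(NamedTuple):
    chrom: str
    position: int
    family: str
    sequence: str  # the (diverged) TE copy inserted at this locus


@dataclass
class Cohort:
    spec: CohortSpec
    reference: dict[str, str]
    te_intervals: list[TEInterval]
    library: TEFamilyLibrary
    truth: SyntheticTruth
    donors: dict[str, dict[str, str]]
    genes: list[GeneModel]

    @property
    def accessions(self) -> list[str]:
        return self.spec.accessions

    @property
    def group_of(self) -> dict[str, str]:
        return self.spec.group_of


def _mutate(seq_codes: np.ndarray, rate: float, rng: np.random.Generator) -> np.ndarray:
    out = seq_codes.copy()
    mask = rng.random(out.size) < rate
    if mask.any():
        out[mask] = (out[mask] + rng.integers(1, 4, int(mask.sum()))) % 4
    return out


def _decode(codes: np.ndarray) -> str:
    return _DECODE[codes].tobytes().decode()


def _place_intervals(
    rng: np.random.Generator,
    n: int,
    length: int,
    genome_length: int,
    blocked: list[tuple[int, int]],
    gap: int,
    max_tries: int = 20_000,
) -> list[int]:
    """Sample ``n`` starts of ``length``-bp intervals avoiding blocked+-gap."""
    starts: list[int] = []
    tries = 0
    while len(starts) < n:
        if tries >= max_tries:
            raise PlacementError(
                f"could not place {n} intervals of {length} bp with gap {gap}; "
                "reduce pool sizes or copy numbers"
            )
        tries += 1
        s = int(rng.integers(gap, genome_length - length - gap))
        e = s + length
        if any(s - gap < be and bs < e + gap for bs, be in blocked):
            continue
        blocked.append((s, e))
        starts.append(s)
    return starts


def generate_cohort(spec: CohortSpec) -> Cohort:
    """Build reference, TE annotation/library, truth table and donor genomes."""
    rng = np.random.default_rng(spec.seed)
    chrom_names = [f"chr{i + 1}" for i in range(spec.n_chroms)]

    ref_codes = {c: rng.integers(0, 4, spec.genome_length, dtype=np.uint8) for c in chrom_names}

    fam_info = [_FAMILY_NAMES[i % len(_FAMILY_NAMES)] for i in range(spec.n_families)]
    fam_names = [
        n if i < len(_FAMILY_NAMES) else f"{n}{i // len(_FAMILY_NAMES) + 1}"
        for i, (n, _) in enumerate(fam_info)
    ]
    superfam = {fam_names[i]: fam_info[i][1] for i in range(spec.n_families)}
    prototypes = {f: rng.integers(0, 4, spec.te_length, dtype=np.uint8) for f in fam_names}

    # plant reference copies (slice replacement keeps coordinates stable)
    te_intervals: list[TEInterval] = []
    blocked: dict[str, list[tuple[int, int]]] = {c: [] for c in chrom_names}
    for fam in fam_names:
        for ci, chrom in enumerate(chrom_names):
            n_here = spec.n_ref_copies // spec.n_chroms + (
                1 if ci < spec.n_ref_copies % spec.n_chroms else 0
            )
            starts = _place_intervals(
                rng, n_here, spec.te_length, spec.genome_length, blocked[chrom],
                gap=2 * spec.fragment_mean,
            )
            for s in starts:
                copy = _mutate(prototypes[fam], spec.divergence, rng)
                ref_codes[chrom][s : s + spec.te_length] = copy
                te_intervals.append(
                    TEInterval(chrom, s, s + spec.te_length, fam, superfam[fam])
                )
    te_intervals.sort(key=lambda iv: (iv.chrom, iv.start))

    reference = {c: _decode(codes) for c, codes in ref_codes.items()}
    library = TEFamilyLibrary(
        families={
            fam: [reference[iv.chrom][iv.start : iv.end] for iv in te_intervals if iv.family == fam]
            for fam in fam_names
        },
        superfamily_of=dict(superfam),
    )

    # polymorphic insertion loci: clear of reference copies and of each other
    copies_by_family: dict[tuple[str, str], list[tuple[int, int]]] = {}
    for iv in te_intervals:
        copies_by_family.setdefault((iv.chrom, iv.family), []).append((iv.start, iv.end))
    locus_gap = max(2 * spec.fragment_mean, spec.te_clearance)

    def sample_loci(n: int, start_index: int) -> list[InsertionLocus]:
        loci = []
        for j in range(n):
            fam = fam_names[(start_index + j) % spec.n_families]  # balanced across families
            pos = None
            for _ in range(20_000):
                chrom = chrom_names[int(rng.integers(0, spec.n_chroms))]
                cand = int(rng.integers(locus_gap, spec.genome_length - locus_gap))
                if any(
                    cand - locus_gap < be and bs < cand + locus_gap
                    for bs, be in blocked[chrom]
                ):
                    continue
                gap_sf = spec.same_family_clearance
                if any(
                    cand - gap_sf < be and bs < cand + gap_sf
                    for bs, be in copies_by_family.get((chrom, fam), [])
                ):
                    continue
                blocked[chrom].append((cand, cand + 1))
                pos = cand
                break
            if pos is None:
                raise PlacementError(
                    "could not place insertion loci under the spacing constraints; "
                    "reduce pool sizes or copy numbers"
                )
            seq = _decode(_mutate(prototypes[fam], spec.divergence, rng))
            loci.append(InsertionLocus(chrom, pos, fam, seq))
        return loci

    shared = sample_loci(int(spec.pool_sizes.get("shared", 0)), 0)
    group_pools = {g: sample_loci(spec.per_group_pool(g), 0) for g in spec.groups}
    private = {
        acc: sample_loci(int(spec.pool_sizes.get("private", 0)), 0)
        for acc in spec.accessions
    }

    records: list[TruthRecord] = []
    donor_loci: dict[str, list[InsertionLocus]] = {}
    for acc in spec.accessions:
        grp = spec.group_of[acc]
        loci = shared + group_pools[grp] + private[acc]
        donor_loci[acc] = loci
        records.extend(
            TruthRecord(acc, grp, l.family, l.chrom, l.position) for l in loci
        )
    truth = SyntheticTruth(records)

    donors: dict[str, dict[str, str]] = {}
    for acc, loci in donor_loci.items():
        genome = {}
        for chrom in chrom_names:
            pieces: list[str] = []
            prev = 0
            for l in sorted((l for l in loci if l.chrom == chrom), key=lambda l: l.position):
                pieces.append(reference[chrom][prev : l.position])
                pieces.append(l.sequence)
                prev = l.position
            pieces.append(reference[chrom][prev:])
            genome[chrom] = "".join(pieces)
        donors[acc] = genome

    genes = generate_gene_annotation(spec, chrom_names)
    return Cohort(spec, reference, te_intervals, library, truth, donors, genes)


def generate_gene_annotation(spec: CohortSpec, chrom_names: Sequence[str]) -> list[GeneModel]:
    """Uniformly spaced toy genes with a 3-exon structure, alternating strand."""
    genes: list[GeneModel] = []
    n = spec.n_genes_per_chrom
    if n <= 0:
        return genes
    spacing = spec.genome_length // (n + 1)
    exon, intron = 600, 600
    glen = 3 * exon + 2 * intron
    for chrom in chrom_names:
        for i in range(n):
            start = spacing * (i + 1)
            end = start + glen
            if end >= spec.genome_length:
                continue
            exons = [
                (start, start + exon),
                (start + exon + intron, start + 2 * exon + intron),
                (start + 2 * (exon + intron), end),
            ]
            genes.append(
                GeneModel(
                    gene_id=f"gene_{chrom}_{i + 1:03d}",
                    chrom=chrom,
                    strand="+" if i % 2 == 0 else "-",
                    start=start,
                    end=end,
                    exons=exons,
                )
            )
    return genes


def _accession_rng(spec_seed: int, accession: str) -> np.random.Generator:
    # salt by accession so per-accession streams are order-independent
    return np.random.default_rng([spec_seed, zlib.crc32(accession.encode()) & 0x7FFFFFFF])


class ReadPairs(NamedTuple):
    names: list[str]
    r1: list[str]
    r2: list[str]


def simulate_paired_reads(
    donor: dict[str, str], spec: CohortSpec, accession: str
) -> ReadPairs:
    """Simulate paired-end reads from a donor genome.

    Pair count is exactly ``floor(coverage * genome_length / (2 * read_length))``.
    Fragments start uniformly; lengths ~ Normal(fragment_mean, fragment_sd)
    truncated to [read_length, 3*fragment_mean]; the second sequenced mate is
    the reverse complement of the fragment's far end; substitution errors are
    i.i.d. per base. Deterministic given (seed, accession).
    """
    if not donor or all(len(s) == 0 for s in donor.values()):
        raise ValueError("donor genome is empty")
    rng = _accession_rng(spec.seed, accession)
    rl = spec.read_length
    total_len = sum(len(s) for s in donor.values())
    n_pairs = int(spec.coverage * total_len / (2 * rl))

    # largest-remainder apportionment across chromosomes
    chroms = sorted(donor)
    quotas = [n_pairs * len(donor[c]) / total_len for c in chroms]
    counts = [int(q) for q in quotas]
    for i in sorted(range(len(chroms)), key=lambda i: quotas[i] - counts[i], reverse=True)[
        : n_pairs - sum(counts)
    ]:
        counts[i] += 1

    names: list[str] = []
    r1_all: list[str] = []
    r2_all: list[str] = []
    for chrom, n in zip(chroms, counts):
        if n == 0:
            continue
        codes = np.frombuffer(donor[chrom].encode(), dtype=np.uint8)
        codes = np.searchsorted(np.frombuffer(b"ACGT", dtype=np.uint8), codes).astype(np.uint8)
        L = codes.size
        flen = np.clip(
            np.rint(rng.normal(spec.fragment_mean, spec.fragment_sd, n)).astype(np.int64),
            rl,
            3 * spec.fragment_mean,
        )
        flen = np.minimum(flen, L)
        starts = (rng.random(n) * (L - flen + 1)).astype(np.int64)
        col = np.arange(rl)
        left = codes[starts[:, None] + col]
        right = codes[(starts + flen - rl)[:, None] + col]
        right_rc = (np.uint8(3) - right)[:, ::-1]
        plus = rng.random(n) < 0.5
        r1 = np.where(plus[:, None], left, right_rc)
        r2 = np.where(plus[:, None], right_rc, left)
        if spec.error_rate > 0:
            for m in (r1, r2):
                mask = rng.random(m.shape) < spec.error_rate
                shift = rng.integers(1, 4, m.shape, dtype=np.uint8)
                m[mask] = (m[mask] + shift[mask]) % 4
        a1 = _DECODE[r1]
        a2 = _DECODE[r2]
        for i in range(n):
            names.append(
                f"{accession}:{chrom}:{int(starts[i])}:{int(flen[i])}:{'+' if plus[i] else '-'}:{i}"
            )
            r1_all.append(a1[i].tobytes().decode())
            r2_all.append(a2[i].tobytes().decode())
    return ReadPairs(names, r1_all, r2_all)


def write_fastq(path: str | Path, names: Sequence[str], seqs: Sequence[str]) -> None:
    path = str(path)
    opener = gzip.open if path.endswith(".gz") else open
    with opener(path, "wt") as fh:
        for name, seq in zip(names, seqs):
            fh.write(f"@{name}\n{seq}\n+\n{'I' * len(seq)}\n")


def write_truth(truth: SyntheticTruth, out: str | Path) -> None:
    truth.to_frame().to_csv(out, sep="\t", index=False)


def read_truth(path: str | Path) -> SyntheticTruth:
    df = pd.read_csv(path, sep="\t", dtype={"position": int})
    return SyntheticTruth([TruthRecord(*row) for row in df.itertuples(index=False)])


def write_cohort(cohort: Cohort, outdir: str | Path, gzip_reads: bool = True) -> dict[str, Path]:
    """Write every cohort artifact; returns a name -> path map."""
    from Bio import SeqIO
    from Bio.Seq import Seq
    from Bio.SeqRecord import SeqRecord

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    def fasta(path: Path, seqs: dict[str, str]) -> None:
        SeqIO.write(
            [SeqRecord(Seq(s), id=n, description="") for n, s in seqs.items()],
            str(path),
            "fasta",
        )

    paths["reference"] = outdir / "reference.fa"
    fasta(paths["reference"], cohort.reference)

    paths["te_bed"] = outdir / "te_annotation.bed"
    with open(paths["te_bed"], "w") as fh:
        for iv in cohort.te_intervals:
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{iv.family}#{iv.superfamily}\n")

    paths["library"] = outdir / "te_library.fa"
    cohort.library.write_fasta(paths["library"])

    paths["truth"] = outdir / "truth.tsv"
    write_truth(cohort.truth, paths["truth"])

    paths["groups"] = outdir / "groups.tsv"
    pd.DataFrame(
        {"accession": cohort.accessions, "group": [cohort.group_of[a] for a in cohort.accessions]}
    ).to_csv(paths["groups"], sep="\t", index=False)

    paths["genes"] = outdir / "genes.gff3"
    write_gff3(cohort.genes, paths["genes"])

    donors_dir = outdir / "donors"
    donors_dir.mkdir(exist_ok=True)
    reads_dir = outdir / "reads"
    reads_dir.mkdir(exist_ok=True)
    ext = ".fastq.gz" if gzip_reads else ".fastq"
    for acc in cohort.accessions:
        dpath = donors_dir / f"{acc}.fa"
        fasta(dpath, cohort.donors[acc])
        paths[f"donor:{acc}"] = dpath
        pairs = simulate_paired_reads(cohort.donors[acc], cohort.spec, acc)
        p1 = reads_dir / f"{acc}_1{ext}"
        p2 = reads_dir / f"{acc}_2{ext}"
        write_fastq(p1, pairs.names, pairs.r1)
        write_fastq(p2, pairs.names, pairs.r2)
        paths[f"reads1:{acc}"] = p1
        paths[f"reads2:{acc}"] = p2
    return paths
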