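"""End-to-end pipeline runner: simulate -> library -> scan -> call -> stats.

Stages communicate through files under ``out_dir``; a JSON manifest records
config, seed, per-stage outputs and checksums. A rerun skips stages whose
outputs all exist with matching checksums, so deleting one accession's
evidence file recomputes only that accession. Per-accession stages are
independent and order-invariant.
"""

from __future__ import annotations

import datetime
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml
from pydantic import BaseModel, Field, ValidationError, field_validator

from . import __version__
from ._mapper import SeedIndex, build_seed_index
from .discordant_scan import read_evidence, scan_pairs, write_evidence
from .genomic_context import (
    GeneContext,
    distance_summary_by_group,
    feature_class_percentages,
    load_genes,
    megabase_density_correlation,
    metagene_profile,
    upstream_depth_by_gene,
    upstream_enrichment,
)
from .insertion_caller import (
    call_insertions,
    copy_number_by_family,
    mask_reference_windows,
    read_calls,
    write_calls,
)
from .population_stats import (
    build_rip_matrix,
    common_rip_fraction,
    family_copy_number_summary,
    group_rip_sets,
    insertion_frequency,
    mean_family_frequency,
    venn_counts,
    write_venn,
)
from .pca_structure import encode_genotypes, compute_grm, pca, pcs_table
from .synthetic_data import CohortSpec, generate_cohort, write_cohort
from .te_library import TEFamilyLibrary, build_library, load_te_annotation


class ConfigError(ValueError):
    """The pipeline configuration is invalid."""


class ThresholdConfig(BaseModel):
    window_size: int = Field(10_000, gt=0)
    call_min_reads: int = Field(4, ge=1)  # ">3 reads" call rule
    copy_min_reads: int = Field(3, ge=1)  # "at least three reads" copy-number rule
    common_threshold: float = Field(0.2, ge=0, le=1)
    min_members: int = Field(20, ge=1)
    validation_flank: int = Field(2_000, gt=0)
    enrichment_ratio: float = Field(5.0, gt=0)
    upstream_flank: int = Field(2_000, gt=0)
    mask_reference: bool = True
    mask_pad: int = Field(300, ge=0)
    density_bin: int = Field(1_000_000, gt=0)


class SimulateConfig(BaseModel):
    genome_length: int = Field(2_000_000, gt=0)
    n_chroms: int = Field(1, gt=0)
    n_families: int = Field(3, gt=0)
    te_length: int = Field(5_000, gt=0)
    groups: dict[str, int] = {"teosinte": 4, "landrace": 4, "improved": 4}
    pool_sizes: dict = {
        "shared": 10,
        "per_group": {"teosinte": 15, "landrace": 30, "improved": 5},
        "private": 5,
    }
    coverage: float = Field(5.0, gt=0)
    read_length: int = Field(100, gt=0)
    fragment_mean: int = Field(300, gt=0)
    fragment_sd: float = Field(30.0, ge=0)
    error_rate: float = Field(0.005, ge=0, lt=1)
    n_ref_copies: int = Field(25, ge=0)


class PipelineConfig(BaseModel):
    out_dir: str
    seed: int = 7
    simulate: SimulateConfig = SimulateConfig()
    thresholds: ThresholdConfig = ThresholdConfig()

    @field_validator("out_dir")
    @classmethod
    def _nonempty(cls, v: str) -> str:
        if not v:
            raise ValueError("out_dir must be set")
        return v


def load_config(source: str | Path | dict) -> PipelineConfig:
    if isinstance(source, (str, Path)):
        with open(source) as fh:
            source = yaml.safe_load(fh)
    try:
        return PipelineConfig(**source)
    except ValidationError as exc:
        keys = ", ".join(".".join(str(p) for p in e["loc"]) for e in exc.errors())
        raise ConfigError(f"invalid configuration keys: {keys}") from exc


def _md5(path: Path) -> str:
    h = hashlib.md5()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


@dataclass
class RunManifest:
    config: dict
    version: str = __version__
    seed: int = 0
    stages: dict = field(default_factory=dict)

    def stage_complete(self, name: str) -> bool:
        info = self.stages.get(name)
        if not info:
            return False
        for path, digest in info["outputs"].items():
            p = Path(path)
            if not p.exists() or _md5(p) != digest:
                return False
        return True

    def record(self, name: str, outputs: list[Path]) -> None:
        self.stages[name] = {
            "outputs": {str(p): _md5(p) for p in outputs},
            "completed_at": datetime.datetime.now().isoformat(timespec="seconds"),
        }

    def save(self, path: Path) -> None:
        with open(path, "w") as fh:
            json.dump(
                {
                    "version": self.version,
                    "seed": self.seed,
                    "config": self.config,
                    "stages": self.stages,
                },
                fh,
                indent=2,
            )

    @classmethod
    def load(cls, path: Path) -> "RunManifest":
        with open(path) as fh:
            d = json.load(fh)
        return cls(config=d["config"], version=d["version"], seed=d["seed"], stages=d["stages"])


def _cohort_spec(cfg: PipelineConfig) -> CohortSpec:
    return CohortSpec(seed=cfg.seed, **cfg.simulate.model_dump())


def run_pipeline(config: str | Path | dict, log=print) -> RunManifest:
    cfg = load_config(config)
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest_path = out / "manifest.json"
    if manifest_path.exists():
        manifest = RunManifest.load(manifest_path)
        manifest.config = cfg.model_dump()
    else:
        manifest = RunManifest(config=cfg.model_dump())
    manifest.seed = cfg.seed
    th = cfg.thresholds
    spec = _cohort_spec(cfg)
    accessions = spec.accessions

    sim_dir = out / "sim"
    # --- simulate ---
    if manifest.stage_complete("simulate"):
        log("[simulate] up to date, skipped")
    else:
        log("[simulate] generating cohort and reads")
        cohort = generate_cohort(spec)
        paths = write_cohort(cohort, sim_dir)
        manifest.record("simulate", sorted(paths.values()))
        manifest.save(manifest_path)

    # --- TE library ---
    lib_fa = out / "te_library.fa"
    lib_summary = out / "family_summary.tsv"
    if manifest.stage_complete("library"):
        log("[library] up to date, skipped")
    else:
        log("[library] building family library")
        lib = build_library(sim_dir / "reference.fa", sim_dir / "te_annotation.bed", th.min_members)
        lib.write_fasta(lib_fa)
        lib.summary().to_csv(lib_summary, sep="\t", index=False)
        manifest.record("library", [lib_fa, lib_summary])
        manifest.save(manifest_path)

    # --- scan (per accession) ---
    ev_dir = out / "evidence"
    ev_dir.mkdir(exist_ok=True)
    te_idx: Optional[SeedIndex] = None
    g_idx: Optional[SeedIndex] = None
    for acc in accessions:
        stage = f"scan:{acc}"
        ev_path = ev_dir / f"{acc}.evidence.tsv"
        if manifest.stage_complete(stage):
            log(f"[{stage}] up to date, skipped")
            continue
        if te_idx is None:
            from Bio import SeqIO

            lib = TEFamilyLibrary.from_fasta(lib_fa)
            items = list(lib.iter_records())
            te_idx = SeedIndex([n for n, _ in items], [s for _, s in items], k=17)
            genome = {
                r.id: str(r.seq).upper()
                for r in SeqIO.parse(str(sim_dir / "reference.fa"), "fasta")
            }
            g_idx = build_seed_index(genome, k=31)
        ext = ".fastq.gz"
        evidence = scan_pairs(
            sim_dir / "reads" / f"{acc}_1{ext}",
            sim_dir / "reads" / f"{acc}_2{ext}",
            te_idx,
            g_idx,
            acc,
        )
        write_evidence(evidence, ev_path)
        log(f"[{stage}] {len(evidence)} evidence pairs")
        manifest.record(stage, [ev_path])
        manifest.save(manifest_path)

    # --- call (per accession) ---
    calls_dir = out / "calls"
    calls_dir.mkdir(exist_ok=True)
    for acc in accessions:
        stage = f"call:{acc}"
        calls_path = calls_dir / f"{acc}.calls.tsv"
        if manifest.stage_complete(stage):
            log(f"[{stage}] up to date, skipped")
            continue
        evidence = read_evidence(ev_dir / f"{acc}.evidence.tsv")
        cs = call_insertions(evidence, th.window_size, th.call_min_reads)
        write_calls(cs, calls_path)
        log(f"[{stage}] {len(cs.calls)} called windows")
        manifest.record(stage, [calls_path])
        manifest.save(manifest_path)

    groups = dict(
        pd.read_csv(sim_dir / "groups.tsv", sep="\t").itertuples(index=False, name=None)
    )
    te_intervals = load_te_annotation(sim_dir / "te_annotation.bed")

    def load_callsets(mask: bool):
        out_cs = []
        for acc in accessions:
            cs = read_calls(calls_dir / f"{acc}.calls.tsv")
            if mask:
                cs = mask_reference_windows(cs, te_intervals, pad=th.mask_pad)
            out_cs.append(cs)
        return out_cs

    # --- stats ---
    stats_dir = out / "stats"
    stats_dir.mkdir(exist_ok=True)
    stats_outputs = [stats_dir / "rip_matrix.tsv", stats_dir / "venn.tsv",
                     stats_dir / "family_copy_number.tsv", stats_dir / "common_rip.tsv"] + [
        stats_dir / f"frequency_{g}.tsv" for g in spec.groups
    ]
    if manifest.stage_complete("stats"):
        log("[stats] up to date, skipped")
    else:
        log("[stats] building RIP matrix and group statistics")
        callsets = load_callsets(th.mask_reference)
        matrix = build_rip_matrix(callsets, groups)
        matrix.to_frame().to_csv(stats_dir / "rip_matrix.tsv", sep="\t")
        write_venn(venn_counts(group_rip_sets(matrix)), stats_dir / "venn.tsv")
        common_rows = []
        for g in spec.groups:
            freqs = insertion_frequency(matrix, g)
            detected = group_rip_sets(matrix)[g]
            pd.DataFrame(
                [
                    {"locus": f"{k.family}:{k.chrom}:{k.window_index}", "frequency": v}
                    for k, v in sorted(freqs.items())
                ]
            ).to_csv(stats_dir / f"frequency_{g}.tsv", sep="\t", index=False)
            common_rows.append(
                {
                    "group": g,
                    "common_rip_fraction": common_rip_fraction(
                        {k: freqs[k] for k in detected}, th.common_threshold
                    ),
                    "mean_frequency": float(np.mean([freqs[k] for k in detected]))
                    if detected
                    else float("nan"),
                }
            )
        pd.DataFrame(common_rows).to_csv(stats_dir / "common_rip.tsv", sep="\t", index=False)
        unmasked = load_callsets(False)
        cn = {
            (cs.accession, fam): n
            for cs in unmasked
            for fam, n in copy_number_by_family(cs, th.copy_min_reads).items()
        }
        family_copy_number_summary(cn, groups).to_csv(
            stats_dir / "family_copy_number.tsv", sep="\t"
        )
        manifest.record("stats", stats_outputs)
        manifest.save(manifest_path)

    # --- pca ---
    pca_path = out / "pca.tsv"
    if manifest.stage_complete("pca"):
        log("[pca] up to date, skipped")
    else:
        log("[pca] GRM + eigendecomposition")
        matrix = build_rip_matrix(load_callsets(th.mask_reference), groups)
        G = encode_genotypes(matrix)
        res = pca(compute_grm(G), n_components=2, accessions=G.accessions)
        table = pcs_table(res, groups)
        header = "# variance_explained: " + ",".join(
            f"{v:.4f}" for v in res.variance_explained
        )
        with open(pca_path, "w") as fh:
            fh.write(header + "\n")
            table.to_csv(fh, sep="\t", index=False)
        manifest.record("pca", [pca_path])
        manifest.save(manifest_path)

    # --- genomic context ---
    ctx_dir = out / "context"
    ctx_dir.mkdir(exist_ok=True)
    ctx_outputs = [
        ctx_dir / "feature_percentages.tsv", ctx_dir / "tss_distance.tsv",
        ctx_dir / "density_correlation.tsv", ctx_dir / "metagene.tsv",
        ctx_dir / "enriched_genes.tsv",
    ]
    if manifest.stage_complete("context"):
        log("[context] up to date, skipped")
    else:
        log("[context] feature classes, TSS distances, metagene, enrichment")
        genes = load_genes(sim_dir / "genes.gff3")
        ctx = GeneContext(genes, flank=th.upstream_flank)
        callsets = load_callsets(th.mask_reference)
        points_by_group: dict[str, list[tuple[str, int]]] = {g: [] for g in spec.groups}
        for cs in callsets:
            g = groups[cs.accession]
            points_by_group[g].extend(
                (k.chrom, cs.insertion_point[k]) for k in cs.calls
            )
        pd.DataFrame(
            [
                {"group": g, **feature_class_percentages(pts, ctx)}
                for g, pts in points_by_group.items()
            ]
        ).to_csv(ctx_dir / "feature_percentages.tsv", sep="\t", index=False)

        means, pvals = distance_summary_by_group(points_by_group, ctx)
        rows = [{"group": g, "mean_tss_distance": m} for g, m in means.items()]
        pd.DataFrame(rows).to_csv(ctx_dir / "tss_distance.tsv", sep="\t", index=False)

        from Bio import SeqIO

        chrom_lengths = {
            r.id: len(r.seq) for r in SeqIO.parse(str(sim_dir / "reference.fa"), "fasta")
        }
        bin_size = min(th.density_bin, max(l // 3 for l in chrom_lengths.values()))
        superfam = {iv.family: iv.superfamily for iv in te_intervals}
        corr_rows = []
        for g, pts in points_by_group.items():
            for sf in sorted(set(superfam.values())):
                sub_pts = []
                for cs in callsets:
                    if groups[cs.accession] != g:
                        continue
                    sub_pts.extend(
                        (k.chrom, cs.insertion_point[k])
                        for k in cs.calls
                        if superfam.get(k.family) == sf
                    )
                r = megabase_density_correlation(sub_pts, genes, chrom_lengths, bin_size)
                corr_rows.append({"group": g, "superfamily": sf, "pearson_r": r})
        pd.DataFrame(corr_rows).to_csv(
            ctx_dir / "density_correlation.tsv", sep="\t", index=False
        )

        anchors_by_group: dict[str, list[tuple[str, int]]] = {g: [] for g in spec.groups}
        for acc in accessions:
            evidence = read_evidence(ev_dir / f"{acc}.evidence.tsv")
            anchors_by_group[groups[acc]].extend(
                (e.chrom, e.anchor_pos) for e in evidence
            )
        prof_rows = {}
        for g, anchors in anchors_by_group.items():
            prof_rows[g] = metagene_profile(anchors, ctx, flank=th.upstream_flank)
        pd.DataFrame(prof_rows).to_csv(ctx_dir / "metagene.tsv", sep="\t", index_label="bin")

        depth_by_group = {
            g: upstream_depth_by_gene(anchors, genes, th.upstream_flank)
            for g, anchors in anchors_by_group.items()
        }
        group_sizes = {g: n for g, n in spec.groups.items()}
        if "landrace" in depth_by_group and "teosinte" in depth_by_group:
            enriched = upstream_enrichment(
                depth_by_group, group_sizes, ratio=th.enrichment_ratio
            )
        else:
            enriched = []
        pd.DataFrame({"gene_id": enriched}).to_csv(
            ctx_dir / "enriched_genes.tsv", sep="\t", index=False
        )
        manifest.record("context", ctx_outputs)
        manifest.save(manifest_path)

    manifest.save(manifest_path)
    return manifest
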