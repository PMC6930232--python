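"""Run the standard desk-scale study end-to-end and score it against truth.

This is the package's self-evaluation harness: it generates the default
synthetic cohort, runs the scan -> call -> stats -> PCA chain in memory,
and measures window-level recovery against the generator's truth table,
group-level copy-number/frequency ordering, PCA group separation and
assembly-based validation.

Reference-resident TE copies are genuine presences in every donor genome;
recovery precision and the population statistics are therefore computed on
reference-masked calls, while copy number (a per-accession census of all
detected elements) uses unmasked counts.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from ._mapper import SeedIndex, build_seed_index
from .discordant_scan import AnchorEvidence, scan_pairs
from .insertion_caller import (
    InsertionCallSet,
    assign_window,
    call_insertions,
    copy_number_by_family,
    mask_reference_windows,
    validate_against_assembly,
)
from .pca_structure import compute_grm, encode_genotypes, pca
from .population_stats import (
    RIPMatrix,
    build_rip_matrix,
    common_rip_fraction,
    group_rip_sets,
    insertion_frequency,
    venn_counts,
)
from .synthetic_data import Cohort, CohortSpec, generate_cohort, simulate_paired_reads

MASK_PAD = 300  # anchors scatter ~a fragment length around element boundaries


@dataclass
class AnalysisRun:
    """Everything the desk-scale study produces, kept in memory."""

    spec: CohortSpec
    cohort: Cohort
    evidence: dict[str, list[AnchorEvidence]]
    callsets: dict[str, InsertionCallSet]  # unmasked
    masked: dict[str, InsertionCallSet]  # reference windows removed
    matrix: RIPMatrix  # built from masked calls
    genome_index: SeedIndex = field(repr=False, default=None)


def run_cohort_analysis(spec: Optional[CohortSpec] = None, log=None) -> AnalysisRun:
    """Simulate, scan, call and matrix-build the cohort defined by ``spec``."""
    spec = spec or CohortSpec()
    cohort = generate_cohort(spec)
    items = list(cohort.library.iter_records())
    te_idx = SeedIndex([n for n, _ in items], [s for _, s in items], k=17)
    g_idx = build_seed_index(cohort.reference, k=31)
    evidence: dict[str, list[AnchorEvidence]] = {}
    callsets: dict[str, InsertionCallSet] = {}
    masked: dict[str, InsertionCallSet] = {}
    for acc in cohort.accessions:
        pairs = simulate_paired_reads(cohort.donors[acc], spec, acc)
        ev = scan_pairs(
            list(zip(pairs.names, pairs.r1)),
            list(zip(pairs.names, pairs.r2)),
            te_idx,
            g_idx,
            acc,
        )
        evidence[acc] = ev
        cs = call_insertions(ev)
        callsets[acc] = cs
        masked[acc] = mask_reference_windows(cs, cohort.te_intervals, pad=MASK_PAD)
        if log:
            log(f"{acc}: {len(ev)} evidence pairs, {len(masked[acc].calls)} polymorphic calls")
    matrix = build_rip_matrix(list(masked.values()), cohort.group_of)
    return AnalysisRun(spec, cohort, evidence, callsets, masked, matrix, g_idx)


def recovery(run: AnalysisRun, window_tol: int = 1) -> dict[str, float]:
    """Window-level recall/precision of masked calls against the truth table.

    A truth record is recovered when its accession calls the same
    (family, chrom) within ``window_tol`` windows; a call is correct when it
    matches a truth record the same way.
    """
    n_truth = n_recovered = n_calls = n_correct = 0
    for acc in run.cohort.accessions:
        truth = {
            (r.family, r.chrom, assign_window(r.position, run.masked[acc].window_size))
            for r in run.cohort.truth.records
            if r.accession == acc
        }
        calls = {(k.family, k.chrom, k.window_index) for k in run.masked[acc].calls}
        n_truth += len(truth)
        n_calls += len(calls)
        n_recovered += sum(
            1
            for f, c, w in truth
            if any((f, c, w + d) in calls for d in range(-window_tol, window_tol + 1))
        )
        n_correct += sum(
            1
            for f, c, w in calls
            if any((f, c, w + d) in truth for d in range(-window_tol, window_tol + 1))
        )
    return {
        "recall": n_recovered / n_truth if n_truth else float("nan"),
        "precision": n_correct / n_calls if n_calls else float("nan"),
        "n_truth": n_truth,
        "n_calls": n_calls,
    }


def group_copy_number_means(run: AnalysisRun, masked: bool = True) -> pd.DataFrame:
    """Mean per-family copy number per group (windows >= 3 reads).

    By default the polymorphic copy number (reference-masked) is reported:
    in the synthetic cohort every accession carries the same reference
    copies, so unmasked counts add identical-mean counting noise across
    groups and carry no group signal.
    """
    rows = []
    source = run.masked if masked else run.callsets
    for acc, cs in source.items():
        for fam, n in copy_number_by_family(cs).items():
            rows.append({"group": run.cohort.group_of[acc], "family": fam, "n": n})
    return pd.DataFrame(rows).pivot_table(
        index="family", columns="group", values="n", aggfunc="mean"
    )


def group_frequency_means(run: AnalysisRun) -> dict[str, float]:
    """Mean insertion frequency over each group's detected polymorphic loci."""
    sets = group_rip_sets(run.matrix)
    out = {}
    for g, detected in sets.items():
        freqs = insertion_frequency(run.matrix, g)
        out[g] = float(np.mean([freqs[k] for k in detected])) if detected else float("nan")
    return out


def group_common_fractions(run: AnalysisRun, threshold: float = 0.2) -> dict[str, float]:
    sets = group_rip_sets(run.matrix)
    out = {}
    for g, detected in sets.items():
        freqs = insertion_frequency(run.matrix, g)
        frac = common_rip_fraction({k: freqs[k] for k in detected}, threshold)
        out[g] = float("nan") if frac is None else frac
    return out


def venn_triple_fraction(run: AnalysisRun) -> float:
    return venn_counts(group_rip_sets(run.matrix)).triple_fraction


def pca_coordinates(run: AnalysisRun):
    G = encode_genotypes(run.matrix)
    return pca(compute_grm(G), n_components=2, accessions=G.accessions)


def pca_group_purity(run: AnalysisRun, random_state: int = 0) -> float:
    """k-means (k = #groups) purity of PC1/PC2 against the true group labels."""
    from sklearn.cluster import KMeans

    res = pca_coordinates(run)
    accs = list(res.coordinates)
    X = np.array([res.coordinates[a] for a in accs])
    labels = [run.cohort.group_of[a] for a in accs]
    k = len(set(labels))
    km = KMeans(n_clusters=k, n_init=10, random_state=random_state).fit(X)
    correct = 0
    for c in range(k):
        members = [labels[i] for i in range(len(accs)) if km.labels_[i] == c]
        if members:
            correct += max(members.count(g) for g in set(members))
    return correct / len(accs)


def validation_fractions(
    run: AnalysisRun, flank: int = 2000
) -> tuple[float, float]:
    """Mean validated fraction of polymorphic calls against (a) each
    accession's own donor genome and (b) the insertion-free reference."""
    donor_fracs, ref_fracs = [], []
    ref_index = run.genome_index
    for acc in run.cohort.accessions:
        cs, ev = run.masked[acc], run.evidence[acc]
        if not cs.calls:
            continue
        fd = validate_against_assembly(cs, ev, run.cohort.donors[acc], flank=flank)
        fr = validate_against_assembly(
            cs, ev, run.cohort.reference, flank=flank, alt_index=ref_index
        )
        if fd is not None:
            donor_fracs.append(fd)
        if fr is not None:
            ref_fracs.append(fr)
    return float(np.mean(donor_fracs)), float(np.mean(ref_fracs))
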