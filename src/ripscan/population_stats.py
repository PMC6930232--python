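"""Cohort-level RIP statistics: presence/absence matrix, Venn partition,
insertion frequency, common-RIP fraction, and per-family copy-number means.

A RIP locus is a (family, chrom, 10 kb window) triple; two families in one
window are two distinct loci. A locus belongs to a group when at least one
accession of that group carries it (union semantics). Insertion frequency
is carriers / group size, like an allele frequency.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .insertion_caller import InsertionCallSet, WindowKey


@dataclass
class RIPMatrix:
    """Accessions x loci binary presence matrix with group labels."""

    accessions: list[str]
    groups: dict[str, str]
    loci: list[WindowKey]
    presence: np.ndarray  # shape (n_accessions, n_loci), entries in {0, 1}

    def __post_init__(self) -> None:
        self.presence = np.asarray(self.presence, dtype=np.int8)
        if self.presence.shape != (len(self.accessions), len(self.loci)):
            raise ValueError("presence shape does not match accessions x loci")
        if not set(np.unique(self.presence)) <= {0, 1}:
            raise ValueError("presence entries must be 0/1")
        missing = [a for a in self.accessions if a not in self.groups]
        if missing:
            raise ValueError(f"accessions without group labels: {missing}")

    def to_frame(self) -> pd.DataFrame:
        cols = [f"{k.family}:{k.chrom}:{k.window_index}" for k in self.loci]
        return pd.DataFrame(self.presence, index=self.accessions, columns=cols)

    def group_members(self, group: str) -> list[int]:
        return [i for i, a in enumerate(self.accessions) if self.groups[a] == group]

    @property
    def group_names(self) -> list[str]:
        seen: dict[str, None] = {}
        for a in self.accessions:
            seen.setdefault(self.groups[a])
        return list(seen)


def build_rip_matrix(
    callsets: Sequence[InsertionCallSet], groups: Mapping[str, str]
) -> RIPMatrix:
    """Union of called loci over accessions as a binary matrix."""
    accessions = [cs.accession for cs in callsets]
    if len(set(accessions)) != len(accessions):
        raise ValueError("duplicate accession names in callsets")
    loci = sorted(set().union(*[cs.calls for cs in callsets]) if callsets else set())
    index = {k: j for j, k in enumerate(loci)}
    presence = np.zeros((len(accessions), len(loci)), dtype=np.int8)
    for i, cs in enumerate(callsets):
        for k in cs.calls:
            presence[i, index[k]] = 1
    return RIPMatrix(accessions, dict(groups), loci, presence)


def group_rip_sets(matrix: RIPMatrix) -> dict[str, set[WindowKey]]:
    """Loci carried by at least one accession of each group."""
    out: dict[str, set[WindowKey]] = {}
    for g in matrix.group_names:
        rows = matrix.group_members(g)
        if not rows:
            out[g] = set()
            continue
        mask = matrix.presence[rows].any(axis=0)
        out[g] = {matrix.loci[j] for j in np.nonzero(mask)[0]}
    return out


@dataclass
class GroupVenn:
    """Counts over the 7 disjoint regions of a 3-set Venn partition."""

    region_counts: dict[frozenset, int]
    group_names: tuple[str, str, str]

    @property
    def union_size(self) -> int:
        return sum(self.region_counts.values())

    def unique_count(self, group: str) -> int:
        return self.region_counts[frozenset([group])]

    @property
    def triple_count(self) -> int:
        return self.region_counts[frozenset(self.group_names)]

    def unique_fraction(self, group: str) -> float:
        return self.unique_count(group) / self.union_size if self.union_size else 0.0

    @property
    def triple_fraction(self) -> float:
        return self.triple_count / self.union_size if self.union_size else 0.0


def venn_counts(sets: Mapping[str, set]) -> GroupVenn:
    """Disjoint 7-region partition of three group locus sets."""
    if len(sets) != 3:
        raise ValueError(f"expected exactly 3 groups, got {len(sets)}")
    names = tuple(sets)
    regions: dict[frozenset, int] = {}
    for r in range(1, 4):
        for combo in itertools.combinations(names, r):
            inside = set.intersection(*[sets[g] for g in combo])
            outside = set().union(*[sets[g] for g in names if g not in combo]) if r < 3 else set()
            regions[frozenset(combo)] = len(inside - outside)
    return GroupVenn(regions, names)


def insertion_frequency(matrix: RIPMatrix, group: str) -> dict[WindowKey, float]:
    """Carrier fraction of every locus within one group."""
    rows = matrix.group_members(group)
    if not rows:
        raise ValueError(f"group {group!r} has no accessions")
    carriers = matrix.presence[rows].sum(axis=0)
    return {k: float(c) / len(rows) for k, c in zip(matrix.loci, carriers)}


def mean_family_frequency(
    matrix: RIPMatrix,
    group: str,
    denominator: str = "group-detected",
) -> dict[str, float]:
    """Per-family mean insertion frequency for one group.

    ``denominator`` selects the averaging set: loci detected in this group
    (default) or all cohort-detected loci of the family.
    """
    freqs = insertion_frequency(matrix, group)
    if denominator == "group-detected":
        keep = group_rip_sets(matrix)[group]
    elif denominator == "cohort-detected":
        keep = set(matrix.loci)
    else:
        raise ValueError("denominator must be 'group-detected' or 'cohort-detected'")
    by_family: dict[str, list[float]] = {}
    for k in keep:
        by_family.setdefault(k.family, []).append(freqs[k])
    return {f: float(np.mean(v)) for f, v in by_family.items()}


def common_rip_fraction(
    freqs: Mapping, threshold: float = 0.2
) -> Optional[float]:
    """Fraction of loci with frequency strictly above ``threshold``."""
    if not freqs:
        warnings.warn("empty frequency map; common-RIP fraction undefined")
        return None
    vals = np.fromiter(freqs.values(), dtype=float)
    return float((vals > threshold).mean())


def family_copy_number_summary(
    copy_numbers: Mapping[tuple[str, str], int], groups: Mapping[str, str]
) -> pd.DataFrame:
    """Mean copy number per family per group (families x groups table)."""
    rows = []
    for (acc, family), n in copy_numbers.items():
        if acc not in groups:
            raise ValueError(f"accession {acc!r} has no group label")
        rows.append({"accession": acc, "group": groups[acc], "family": family, "n": n})
    df = pd.DataFrame(rows)
    if df.empty:
        return pd.DataFrame()
    return df.pivot_table(index="family", columns="group", values="n", aggfunc="mean")


def copy_number_distributions(
    copy_numbers: Mapping[tuple[str, str], int], groups: Mapping[str, str]
) -> dict[str, dict[str, list[int]]]:
    """family -> group -> list of per-accession copy numbers (for plotting)."""
    out: dict[str, dict[str, list[int]]] = {}
    for (acc, family), n in copy_numbers.items():
        out.setdefault(family, {}).setdefault(groups[acc], []).append(n)
    return out


def compare_group_distributions(
    values_by_group: Mapping[str, Sequence[float]],
    test: str = "wilcoxon",
    alpha: float = 0.05,
) -> dict[tuple[str, str], Optional[float]]:
    """Two-sided p-value per group pair (rank-sum by default, t-test by flag)."""
    out: dict[tuple[str, str], Optional[float]] = {}
    names = list(values_by_group)
    for a, b in itertools.combinations(names, 2):
        x, y = list(values_by_group[a]), list(values_by_group[b])
        if len(x) < 2 or len(y) < 2 or len(set(x) | set(y)) < 2:
            warnings.warn(f"degenerate comparison {a} vs {b}; p-value undefined")
            out[(a, b)] = None
            continue
        if test == "wilcoxon":
            combined = x + y
            no_ties = len(set(combined)) == len(combined)
            method = "exact" if no_ties and len(combined) <= 40 else "auto"
            p = float(stats.mannwhitneyu(x, y, alternative="two-sided", method=method)[1])
        elif test == "ttest":
            p = float(stats.ttest_ind(x, y, equal_var=False)[1])
        else:
            raise ValueError("test must be 'wilcoxon' or 'ttest'")
        out[(a, b)] = p
    return out


def significance_marker(p: Optional[float], alpha: float = 0.05) -> str:
    return "*" if p is not None and p <= alpha else ""


def write_venn(venn: GroupVenn, path: str | Path) -> None:
    rows = [
        {
            "region": "&".join(sorted(region)),
            "count": count,
            "fraction_of_union": count / venn.union_size if venn.union_size else 0.0,
        }
        for region, count in sorted(venn.region_counts.items(), key=lambda kv: sorted(kv[0]))
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
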