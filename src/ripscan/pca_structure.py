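"""Population structure from the RIP matrix.

The binary presence/absence matrix is encoded as homozygous allele dosages
(0/2) — what a ped-file conversion of dominant markers feeds PLINK — and a
GCTA-style genetic relationship matrix is formed from standardized
genotypes:

    w_ij = (x_ij - 2 p_j) / sqrt(2 p_j (1 - p_j)),    A = W W' / m

where p_j is the allele frequency of locus j and m the locus count. The
top eigenpairs of A give the principal-component coordinates (eigenvector
scaled by sqrt(eigenvalue)), with a deterministic sign convention.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .insertion_caller import WindowKey
from .population_stats import RIPMatrix


@dataclass
class GenotypeMatrix:
    accessions: list[str]
    loci: list[WindowKey]
    dosage: np.ndarray  # entries in {0, 2}

    @property
    def allele_freq(self) -> np.ndarray:
        return self.dosage.mean(axis=0) / 2.0


@dataclass
class PCAResult:
    coordinates: dict[str, tuple[float, ...]]
    eigenvalues: np.ndarray
    variance_explained: np.ndarray
    degenerate: bool = False


def encode_genotypes(matrix: RIPMatrix) -> GenotypeMatrix:
    """Presence 1 -> dosage 2, absence -> 0; monomorphic loci removed.

    Monomorphic columns carry no relationship information and would divide
    by zero in the standardization, so they are dropped here.
    """
    dosage = 2 * matrix.presence.astype(np.float64)
    poly = (dosage.std(axis=0) > 0) if dosage.size else np.array([], dtype=bool)
    if dosage.size == 0 or not poly.any():
        raise ValueError("no polymorphic loci; genotype matrix is degenerate")
    keep = np.nonzero(poly)[0]
    return GenotypeMatrix(
        list(matrix.accessions),
        [matrix.loci[j] for j in keep],
        dosage[:, keep],
    )


def compute_grm(G: GenotypeMatrix) -> np.ndarray:
    """GCTA-convention genetic relationship matrix A = W W' / m."""
    if len(G.accessions) < 2:
        raise ValueError("need at least 2 accessions")
    p = G.allele_freq
    if np.any((p <= 0) | (p >= 1)):
        raise AssertionError("monomorphic locus survived encoding")
    W = (G.dosage - 2 * p) / np.sqrt(2 * p * (1 - p))
    return W @ W.T / W.shape[1]


def pca(
    A: np.ndarray,
    n_components: int = 2,
    accessions: Sequence[str] | None = None,
    sym_tol: float = 1e-8,
) -> PCAResult:
    """Top eigenpairs of a relationship matrix as PC coordinates."""
    A = np.asarray(A, dtype=float)
    if A.ndim != 2 or A.shape[0] != A.shape[1]:
        raise ValueError("relationship matrix must be square")
    if np.abs(A - A.T).max() > sym_tol:
        raise ValueError("relationship matrix is not symmetric")
    n = A.shape[0]
    if accessions is None:
        accessions = [str(i) for i in range(n)]
    evals, evecs = np.linalg.eigh(A)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    top = evals[:n_components]
    vecs = evecs[:, :n_components].copy()
    # deterministic sign: largest-magnitude entry of each eigenvector positive
    for j in range(vecs.shape[1]):
        i = int(np.abs(vecs[:, j]).argmax())
        if vecs[i, j] < 0:
            vecs[:, j] = -vecs[:, j]
    coords = vecs * np.sqrt(np.clip(top, 0.0, None))
    pos = np.clip(evals, 0.0, None)
    total = pos.sum()
    var = np.clip(top, 0.0, None) / total if total > 0 else np.zeros_like(top)
    # an (almost) flat spectrum means the leading axes are arbitrary
    degenerate = bool(
        n > n_components and top[-1] - evals[n_components] <= 1e-9 * max(1.0, abs(top[0]))
    )
    return PCAResult(
        coordinates={a: tuple(coords[i]) for i, a in enumerate(accessions)},
        eigenvalues=top,
        variance_explained=var,
        degenerate=degenerate,
    )


def rip_pca(matrix: RIPMatrix, n_components: int = 2) -> PCAResult:
    """Convenience: RIP matrix -> dosages -> GRM -> PCA."""
    G = encode_genotypes(matrix)
    A = compute_grm(G)
    return pca(A, n_components=n_components, accessions=G.accessions)


def pcs_table(result: PCAResult, groups: Mapping[str, str]) -> pd.DataFrame:
    rows = [
        {
            "accession": a,
            "group": groups.get(a, ""),
            **{f"PC{i + 1}": c for i, c in enumerate(coords)},
        }
        for a, coords in result.coordinates.items()
    ]
    return pd.DataFrame(rows)


def write_ped_map(G: GenotypeMatrix, prefix: str | Path, window_size: int = 10_000) -> None:
    """PLINK-compatible .ped/.map export for external cross-checks.

    Dosage 2 is written as the 'A A' genotype, dosage 0 as 'T T'.
    """
    prefix = str(prefix)
    with open(prefix + ".map", "w") as fh:
        for k in G.loci:
            chrom_num = "".join(c for c in k.chrom if c.isdigit()) or "1"
            pos = k.window_index * window_size + window_size // 2
            fh.write(f"{chrom_num}\t{k.family}:{k.chrom}:{k.window_index}\t0\t{pos}\n")
    with open(prefix + ".ped", "w") as fh:
        for i, acc in enumerate(G.accessions):
            geno = " ".join("A A" if d == 2 else "T T" for d in G.dosage[i])
            fh.write(f"{acc} {acc} 0 0 0 -9 {geno}\n")
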