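"""Shared fixtures: a small synthetic cohort scanned end-to-end."""

from __future__ import annotations

import numpy as np
import pytest

from ripscan._mapper import SeedIndex, build_seed_index
from ripscan.discordant_scan import scan_pairs
from ripscan.insertion_caller import call_insertions, mask_reference_windows
from ripscan.synthetic_data import CohortSpec, generate_cohort, simulate_paired_reads


SMALL_SPEC = dict(
    genome_length=300_000,
    n_ref_copies=4,
    te_length=2_000,
    groups={"teosinte": 2, "landrace": 2, "improved": 2},
    pool_sizes={
        "shared": 3,
        "per_group": {"teosinte": 4, "landrace": 8, "improved": 2},
        "private": 2,
    },
    te_clearance=1_500,
    seed=11,
)


@pytest.fixture(scope="session")
def small_spec() -> CohortSpec:
    return CohortSpec(**SMALL_SPEC)


@pytest.fixture(scope="session")
def small_cohort(small_spec):
    return generate_cohort(small_spec)


@pytest.fixture(scope="session")
def small_indexes(small_cohort):
    items = list(small_cohort.library.iter_records())
    te_idx = SeedIndex([n for n, _ in items], [s for _, s in items], k=17)
    g_idx = build_seed_index(small_cohort.reference, k=31)
    return te_idx, g_idx


@pytest.fixture(scope="session")
def small_evidence(small_cohort, small_indexes):
    """Evidence per accession for the small cohort (in-memory reads)."""
    te_idx, g_idx = small_indexes
    out = {}
    for acc in small_cohort.accessions:
        pairs = simulate_paired_reads(small_cohort.donors[acc], small_cohort.spec, acc)
        out[acc] = scan_pairs(
            list(zip(pairs.names, pairs.r1)),
            list(zip(pairs.names, pairs.r2)),
            te_idx,
            g_idx,
            acc,
        )
    return out


@pytest.fixture(scope="session")
def small_callsets(small_cohort, small_evidence):
    """(unmasked, reference-masked) callsets per accession."""
    unmasked = {acc: call_insertions(ev) for acc, ev in small_evidence.items()}
    masked = {
        acc: mask_reference_windows(cs, small_cohort.te_intervals, pad=300)
        for acc, cs in unmasked.items()
    }
    return unmasked, masked


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
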