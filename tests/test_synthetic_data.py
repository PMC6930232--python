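"""Synthetic cohort generator: determinism, pool structure, read model."""

import numpy as np
import pytest

from ripscan.insertion_caller import assign_window
from ripscan.synthetic_data import (
    CohortSpec,
    PlacementError,
    generate_cohort,
    read_truth,
    simulate_paired_reads,
    write_truth,
)

TINY = dict(
    genome_length=120_000,
    n_ref_copies=2,
    te_length=1_000,
    groups={"teosinte": 2, "landrace": 2, "improved": 2},
    pool_sizes={"shared": 2, "per_group": 3, "private": 1},
    te_clearance=800,
    same_family_clearance=5_000,
    seed=3,
)


class TestSpecValidation:
    def test_rejects_bad_coverage(self):
        with pytest.raises(ValueError):
            CohortSpec(coverage=0)

    def test_rejects_read_longer_than_fragment(self):
        with pytest.raises(ValueError):
            CohortSpec(read_length=400, fragment_mean=300)

    def test_rejects_error_rate_one(self):
        with pytest.raises(ValueError):
            CohortSpec(error_rate=1.0)

    def test_impossible_placement_raises(self):
        with pytest.raises(PlacementError):
            generate_cohort(CohortSpec(**{**TINY, "genome_length": 30_000, "n_ref_copies": 30}))


class TestCohortStructure:
    def test_no_insertions_means_identical_donors(self):
        spec = CohortSpec(**{**TINY, "pool_sizes": {"shared": 0, "per_group": 0, "private": 0}})
        cohort = generate_cohort(spec)
        assert cohort.truth.records == []
        for acc in cohort.accessions:
            assert cohort.donors[acc] == cohort.reference

    def test_determinism_same_seed(self):
        a = generate_cohort(CohortSpec(**TINY))
        b = generate_cohort(CohortSpec(**TINY))
        assert a.reference == b.reference
        assert a.truth.records == b.truth.records
        assert a.donors == b.donors
        ra = simulate_paired_reads(a.donors["teosinte_1"], a.spec, "teosinte_1")
        rb = simulate_paired_reads(b.donors["teosinte_1"], b.spec, "teosinte_1")
        assert ra == rb

    def test_group_pool_shared_within_group_only(self):
        spec = CohortSpec(
            **{**TINY, "pool_sizes": {"shared": 0, "per_group": 10, "private": 0},
               "genome_length": 400_000}
        )
        cohort = generate_cohort(spec)
        by_acc = {}
        for r in cohort.truth.records:
            by_acc.setdefault(r.accession, set()).add((r.chrom, r.position))
        for grp, size in spec.groups.items():
            members = [a for a in cohort.accessions if cohort.group_of[a] == grp]
            sets = [by_acc[a] for a in members]
            assert all(s == sets[0] for s in sets)
            assert len(sets[0]) == 10
            for other in cohort.accessions:
                if cohort.group_of[other] != grp:
                    assert not (sets[0] & by_acc[other])

    def test_shared_pool_nested_in_every_accession(self, small_cohort):
        spec = small_cohort.spec
        by_acc = {}
        for r in small_cohort.truth.records:
            by_acc.setdefault(r.accession, set()).add((r.chrom, r.position))
        shared = set.intersection(*by_acc.values())
        assert len(shared) >= spec.pool_sizes["shared"]

    def test_reference_carries_annotated_copies(self, small_cohort):
        for iv in small_cohort.te_intervals[:5]:
            seg = small_cohort.reference[iv.chrom][iv.start : iv.end]
            assert seg in small_cohort.library.families[iv.family]

    def test_truth_positions_in_bounds_and_unique(self, small_cohort):
        seen = set()
        for r in small_cohort.truth.records:
            assert 0 <= r.position < small_cohort.spec.genome_length
            key = (r.accession, r.chrom, r.position)
            assert key not in seen
            seen.add(key)

    def test_insertions_clear_of_same_family_windows(self, small_cohort):
        # identifiability: the windows a polymorphic locus' anchors can touch
        # (+-300 bp) never coincide with the padded windows of a same-family
        # reference copy, so masking reference windows cannot hide truth
        pad = 300
        for r in small_cohort.truth.records:
            wins = set(range(assign_window(max(0, r.position - pad)),
                             assign_window(r.position + pad) + 1))
            for iv in small_cohort.te_intervals:
                if iv.family != r.family or iv.chrom != r.chrom:
                    continue
                copy_wins = set(range(assign_window(max(0, iv.start - pad)),
                                      assign_window(iv.end + pad - 1) + 1))
                assert not (wins & copy_wins)


class TestReadSimulation:
    def test_pair_count_formula(self):
        spec = CohortSpec(**{**TINY, "coverage": 5.0, "read_length": 100})
        donor = {"chr1": "ACGT" * 25_000}  # 100 kb
        pairs = simulate_paired_reads(donor, spec, "x")
        assert len(pairs.names) == int(5.0 * 100_000 / (2 * 100))

    def test_error_free_reads_are_donor_substrings(self):
        spec = CohortSpec(**{**TINY, "error_rate": 0.0})
        cohort = generate_cohort(spec)
        acc = cohort.accessions[0]
        donor = cohort.donors[acc]["chr1"]
        rc = str.maketrans("ACGT", "TGCA")
        pairs = simulate_paired_reads(cohort.donors[acc], spec, acc)
        for name, r1, r2 in list(zip(pairs.names, pairs.r1, pairs.r2))[:200]:
            _, chrom, start, flen, strand, _ = name.split(":")
            s, f = int(start), int(flen)
            left, right = donor[s : s + 100], donor[s + f - 100 : s + f]
            right_rc = right.translate(rc)[::-1]
            if strand == "+":
                assert (r1, r2) == (left, right_rc)
            else:
                assert (r1, r2) == (right_rc, left)

    def test_accession_salting_gives_different_reads(self, small_cohort):
        spec = small_cohort.spec
        donor = small_cohort.donors["teosinte_1"]
        a = simulate_paired_reads(donor, spec, "teosinte_1")
        b = simulate_paired_reads(donor, spec, "other_name")
        assert a.r1 != b.r1

    def test_empty_donor_rejected(self, small_spec):
        with pytest.raises(ValueError):
            simulate_paired_reads({}, small_spec, "x")


class TestTruthIO:
    def test_round_trip(self, tmp_path, small_cohort):
        p = tmp_path / "truth.tsv"
        write_truth(small_cohort.truth, p)
        back = read_truth(p)
        assert sorted(back.records) == sorted(small_cohort.truth.records)

    def test_empty_truth_writes_header_only(self, tmp_path):
        from ripscan.synthetic_data import SyntheticTruth

        p = tmp_path / "empty.tsv"
        write_truth(SyntheticTruth([]), p)
        lines = p.read_text().strip().splitlines()
        assert len(lines) == 1
        assert lines[0].split("\t") == ["accession", "group", "family", "chrom", "position"]


class TestGeneAnnotation:
    def test_gff3_round_trip(self, tmp_path, small_cohort):
        from ripscan.genomic_context import load_genes, write_gff3

        p = tmp_path / "genes.gff3"
        write_gff3(small_cohort.genes, p)
        back = load_genes(p)
        assert len(back) == len(small_cohort.genes)
        for a, b in zip(sorted(back, key=lambda g: g.start),
                        sorted(small_cohort.genes, key=lambda g: g.start)):
            assert (a.chrom, a.strand, a.start, a.end, a.exons) == (
                b.chrom, b.strand, b.start, b.end, b.exons)
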