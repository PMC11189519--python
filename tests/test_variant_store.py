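"""Unit tests for the data model, VCF I/O, and site-set operations."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from relictpop.variant_store import (
    CohortMatrix,
    FilterParams,
    GenomicIntervals,
    SiteRecord,
    UnsupportedPloidyError,
    VcfParseError,
    concat_sites,
    filter_sites,
    intersect_genic,
    merge_cohorts,
    read_bed,
    read_groups,
    read_vcf,
    split_sites,
    write_bed,
    write_groups,
    write_vcf,
)
from tests.conftest import make_cohort, random_cohort

VCF_HEADER = (
    "##fileformat=VCFv4.2\n"
    '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n'
    "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t{samples}\n"
)


def write_text_vcf(path, body: str, samples=("a", "b", "c")) -> str:
    path.write_text(VCF_HEADER.format(samples="\t".join(samples)) + body)
    return str(path)


class TestReadVcf:
    def test_empty_body(self, tmp_path):
        m = read_vcf(write_text_vcf(tmp_path / "e.vcf", ""))
        assert m.n_sites == 0
        assert m.samples == ["a", "b", "c"]

    def test_dosage_mapping(self, tmp_path):
        body = "A01\t5\t.\tA\tT\t.\t.\t.\tGT\t0/1\t1/1\t./.\n"
        m = read_vcf(write_text_vcf(tmp_path / "d.vcf", body))
        assert m.dosages[:, 0].tolist() == [1, 2, -1]

    def test_half_call_is_missing(self, tmp_path):
        body = "A01\t5\t.\tA\tT\t.\t.\t.\tGT\t0/.\t1/1\t0/0\n"
        m = read_vcf(write_text_vcf(tmp_path / "h.vcf", body))
        assert m.dosages[:, 0].tolist() == [-1, 2, 0]

    def test_site_classes(self, tmp_path):
        body = (
            "A01\t1\t.\tA\tT\t.\t.\t.\tGT\t0/0\t0/0\t0/0\n"  # alt never observed
            "A01\t2\t.\tA\tT\t.\t.\t.\tGT\t0/1\t0/0\t0/0\n"
            "A01\t3\t.\tA\tT,G\t.\t.\t.\tGT\t0/1\t1/2\t0/0\n"
            "A01\t4\t.\tAT\tA\t.\t.\t.\tGT\t0/1\t0/0\t0/0\n"
            "A01\t5\t.\tA\t.\t.\t.\t.\tGT\t0/0\t0/0\t./.\n"
        )
        m = read_vcf(write_text_vcf(tmp_path / "c.vcf", body))
        assert [s.site_class for s in m.sites] == [
            "invariant", "snp", "multiallelic", "indel", "invariant",
        ]

    def test_multiallelic_dosage_counts_nonref(self, tmp_path):
        body = "A01\t3\t.\tA\tT,G\t.\t.\t.\tGT\t0/1\t1/2\t2/2\n"
        m = read_vcf(write_text_vcf(tmp_path / "m.vcf", body))
        assert m.dosages[:, 0].tolist() == [1, 2, 2]

    def test_malformed_line_names_line_number(self, tmp_path):
        body = "A01\t5\t.\tA\tT\t.\t.\t.\tGT\t0/1\t1/1\n"  # one sample short
        with pytest.raises(VcfParseError, match="line 4"):
            read_vcf(write_text_vcf(tmp_path / "bad.vcf", body))

    def test_non_integer_pos(self, tmp_path):
        body = "A01\tXX\t.\tA\tT\t.\t.\t.\tGT\t0/1\t1/1\t0/0\n"
        with pytest.raises(VcfParseError, match="line 4"):
            read_vcf(write_text_vcf(tmp_path / "bad2.vcf", body))

    def test_haploid_rejected(self, tmp_path):
        body = "A01\t5\t.\tA\tT\t.\t.\t.\tGT\t0\t1\t0\n"
        with pytest.raises(UnsupportedPloidyError):
            read_vcf(write_text_vcf(tmp_path / "hap.vcf", body))

    def test_depth_from_format_dp(self, tmp_path):
        path = tmp_path / "dp.vcf"
        path.write_text(
            "##fileformat=VCFv4.2\n"
            '##FORMAT=<ID=GT,Number=1,Type=String,Description="g">\n'
            '##FORMAT=<ID=DP,Number=1,Type=Integer,Description="d">\n'
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\ta\tb\n"
            "A01\t5\t.\tA\tT\t.\t.\t.\tGT:DP\t0/1:10\t1/1:30\n"
        )
        m = read_vcf(str(path))
        assert m.sites[0].mean_depth == pytest.approx(20.0)


class TestWriteVcf:
    def test_round_trip(self, tmp_path, rng):
        m = random_cohort(rng, 5, 40, missing_rate=0.2)
        path = tmp_path / "rt.vcf"
        write_vcf(m, path)
        back = read_vcf(path)
        assert back.equals(m)
        np.testing.assert_allclose(back.mean_depths(), m.mean_depths(), rtol=1e-9)

    def test_round_trip_gz(self, tmp_path, rng):
        m = random_cohort(rng, 4, 20)
        path = tmp_path / "rt.vcf.gz"
        write_vcf(m, path)
        assert read_vcf(path).equals(m)

    def test_zero_sites_header_only(self, tmp_path):
        m = make_cohort(np.zeros((3, 0)))
        path = tmp_path / "empty.vcf"
        write_vcf(m, path)
        lines = path.read_text().splitlines()
        assert all(line.startswith("#") for line in lines)
        assert read_vcf(path).n_sites == 0

    def test_missing_serialized_as_dots(self, tmp_path):
        m = make_cohort([[1], [-1]])
        path = tmp_path / "miss.vcf"
        write_vcf(m, path)
        data = [line for line in path.read_text().splitlines() if not line.startswith("#")]
        assert data[0].split("\t")[-1] == "./."

    def test_invariant_written_with_dot_alt(self, tmp_path):
        m = make_cohort([[0], [0]])
        path = tmp_path / "inv.vcf"
        write_vcf(m, path)
        data = [line for line in path.read_text().splitlines() if not line.startswith("#")]
        assert data[0].split("\t")[4] == "."


class TestSplitConcat:
    def test_split_counts(self):
        d = np.zeros((3, 10), dtype=np.int8)
        d[0, 4] = 1
        m = make_cohort(d)
        invariant, variable = split_sites(m)
        assert (invariant.n_sites, variable.n_sites) == (9, 1)

    def test_all_invariant(self):
        m = make_cohort(np.zeros((3, 6), dtype=np.int8))
        _, variable = split_sites(m)
        assert variable.n_sites == 0

    def test_partition_round_trip(self, rng):
        for _ in range(20):
            m = random_cohort(rng, 4, 30, missing_rate=0.1)
            invariant, variable = split_sites(m)
            assert invariant.n_sites + variable.n_sites == m.n_sites
            back = concat_sites(invariant, variable)
            assert back.equals(m.sorted_by_position())

    def test_concat_sorted(self):
        a = make_cohort([[0, 1]], positions=[10, 30])
        b = make_cohort([[2]], positions=[20])
        c = concat_sites(a, b)
        assert c.positions().tolist() == [10, 20, 30]
        assert c.dosages[0].tolist() == [0, 2, 1]

    def test_concat_identity_element(self):
        a = make_cohort([[0, 1, 2]])
        empty = make_cohort(np.zeros((1, 0)))
        assert concat_sites(a, empty).equals(a)

    def test_concat_errors(self):
        a = make_cohort([[0]], sample_names=["x"])
        b = make_cohort([[0]], sample_names=["y"])
        with pytest.raises(ValueError, match="identical sample"):
            concat_sites(a, b)
        c = make_cohort([[0]])
        with pytest.raises(ValueError, match="duplicate"):
            concat_sites(c, c)


def eight_record_toy() -> CohortMatrix:
    """1 passing SNP; 1 indel; 1 triallelic; maf=0.02 SNP; SNP with one
    missing call; SNP meanDP=5; SNP meanDP=150; 1 passing SNP."""
    n = 25
    d = np.zeros((n, 8), dtype=np.int8)
    d[:5, [0, 1, 2, 4, 5, 6, 7]] = 1  # maf 5/50 = 0.1 at these sites
    d[0, 3] = 1  # maf 1/50 = 0.02
    d[6, 4] = -1  # one missing genotype
    sites = [
        SiteRecord("A01", 10, "A", ("T",), "r1", 30.0, "snp"),
        SiteRecord("A01", 20, "AT", ("A",), "r2", 30.0, "indel"),
        SiteRecord("A01", 30, "A", ("T", "G"), "r3", 30.0, "multiallelic"),
        SiteRecord("A01", 40, "A", ("T",), "r4", 30.0, "snp"),
        SiteRecord("A01", 50, "A", ("T",), "r5", 30.0, "snp"),
        SiteRecord("A01", 60, "A", ("T",), "r6", 5.0, "snp"),
        SiteRecord("A01", 70, "A", ("T",), "r7", 150.0, "snp"),
        SiteRecord("A01", 80, "A", ("T",), "r8", 30.0, "snp"),
    ]
    return CohortMatrix([f"s{i}" for i in range(n)], sites, d)


class TestFilterSites:
    def _eight_record_toy(self) -> CohortMatrix:
        return eight_record_toy()

    def test_snp_preset_keeps_two(self):
        m = self._eight_record_toy()
        kept = filter_sites(m, FilterParams.snp_preset())
        assert kept.n_sites == 2
        assert [s.site_id for s in kept.sites] == ["r1", "r8"]

    def test_each_clause_individually(self):
        m = self._eight_record_toy()
        n = m.n_samples
        base = FilterParams.disabled(n)
        from dataclasses import replace

        assert filter_sites(m, replace(base, drop_indels=True)).n_sites == 7
        assert filter_sites(m, replace(base, max_alleles=2)).n_sites == 7
        assert filter_sites(m, replace(base, min_maf=0.05)).n_sites == 7
        assert filter_sites(m, replace(base, max_missing_count=0)).n_sites == 7
        assert filter_sites(m, replace(base, min_mean_depth=10.0)).n_sites == 7
        assert filter_sites(m, replace(base, max_mean_depth=100.0)).n_sites == 7

    def test_disabled_is_identity(self, rng):
        m = random_cohort(rng, 6, 30, missing_rate=0.3)
        assert filter_sites(m, FilterParams.disabled(m.n_samples)).equals(m)

    def test_idempotent(self, rng):
        m = random_cohort(rng, 8, 50, missing_rate=0.2)
        p = FilterParams(min_maf=0.1, max_missing_count=1, min_mean_depth=0,
                        max_mean_depth=1e9)
        once = filter_sites(m, p)
        assert filter_sites(once, p).equals(once)

    def test_unknown_depth_passes(self):
        m = make_cohort([[1, 0], [1, 0]], mean_depth=float("nan"))
        p = FilterParams(min_maf=0.0, min_mac=0, max_missing_count=2)
        assert filter_sites(m, p).n_sites == 2

    def test_alt_fixed_site_fails_mac(self):
        # minor allele is REF with count 0 -> mac 1 drops it
        m = make_cohort([[2], [2]])
        p = FilterParams(min_maf=0.0, min_mean_depth=0, max_mean_depth=1e9)
        assert filter_sites(m, p).n_sites == 0

    @given(st.integers(0, 2**32 - 1))
    @settings(max_examples=15, deadline=None)
    def test_retained_sites_satisfy_all_clauses(self, seed):
        r = np.random.default_rng(seed)
        m = random_cohort(r, 6, 40, missing_rate=0.25)
        p = FilterParams(max_missing_count=1, min_maf=0.1, min_mean_depth=0,
                        max_mean_depth=1e9)
        kept = filter_sites(m, p)
        # independent re-check of every clause
        for j in range(kept.n_sites):
            col = kept.dosages[:, j]
            called = col[col >= 0]
            assert (col < 0).sum() <= p.max_missing_count
            alt = called.sum()
            mac = min(alt, 2 * len(called) - alt)
            assert mac >= p.min_mac
            assert mac / (2 * len(called)) >= p.min_maf


class TestMergeCohorts:
    def test_sample_union(self, rng):
        a = random_cohort(rng, 5, 20, chrom="A01")
        b = make_cohort(
            rng.integers(0, 3, (2, 20)).astype(np.int8),
            positions=a.positions(),
            sample_names=["o1", "o2"],
        )
        merged = merge_cohorts(a, b)
        assert merged.n_samples == 7
        assert merged.n_sites == 20

    def test_merge_empty_is_identity(self, rng):
        a = random_cohort(rng, 3, 10)
        empty = CohortMatrix([], [], np.zeros((0, 0), dtype=np.int8))
        merged = merge_cohorts(a, empty)
        assert merged.equals(a.reclassified())

    def test_private_position_missing_in_other(self):
        a = make_cohort([[1, 0]], positions=[10, 20], sample_names=["x"])
        b = make_cohort([[2]], positions=[10], sample_names=["y"])
        merged = merge_cohorts(a, b)
        assert merged.positions().tolist() == [10, 20]
        col20 = merged.dosages[:, 1]
        assert col20.tolist() == [0, -1]

    def test_conflicting_ref_rejected(self):
        a = make_cohort([[1]], sample_names=["x"])
        b = make_cohort([[1]], sample_names=["y"])
        b.sites[0].ref_allele = "G"
        with pytest.raises(ValueError, match="conflicting REF"):
            merge_cohorts(a, b)

    def test_overlapping_samples_rejected(self):
        a = make_cohort([[1]])
        with pytest.raises(ValueError, match="disjoint"):
            merge_cohorts(a, a)


class TestIntersectGenic:
    def test_half_open_boundary(self):
        m = make_cohort([[1]], positions=[100])
        kept = intersect_genic(m, GenomicIntervals.from_tuples([("A01", 99, 100)]))
        assert kept.n_sites == 1
        dropped = intersect_genic(m, GenomicIntervals.from_tuples([("A01", 100, 101)]))
        assert dropped.n_sites == 0

    def test_empty_intervals(self, rng):
        m = random_cohort(rng, 3, 10)
        assert intersect_genic(m, GenomicIntervals({})).n_sites == 0

    def test_brute_force_oracle(self, rng):
        positions = [5, 17, 30, 42, 55, 70]
        m = make_cohort(np.ones((2, 6), dtype=np.int8), positions=positions)
        intervals = [("A01", 10, 31), ("A01", 54, 70)]
        g = GenomicIntervals.from_tuples(intervals)
        kept = intersect_genic(m, g)
        expected = [
            p for p in positions
            if any(c == "A01" and s <= p - 1 < e for c, s, e in intervals)
        ]
        assert kept.positions().tolist() == expected

    def test_normalization_merges_overlaps(self):
        g = GenomicIntervals.from_tuples([("A01", 0, 10), ("A01", 5, 20), ("A01", 30, 40)])
        assert g.by_chrom["A01"].tolist() == [[0, 20], [30, 40]]

    def test_invalid_interval(self):
        with pytest.raises(ValueError):
            GenomicIntervals.from_tuples([("A01", 10, 10)])


class TestTables:
    def test_bed_round_trip(self, tmp_path):
        g = GenomicIntervals.from_tuples([("A01", 0, 100), ("D01", 50, 80)])
        path = tmp_path / "x.bed"
        write_bed(g, path)
        back = read_bed(path)
        assert {c: a.tolist() for c, a in back.by_chrom.items()} == {
            c: a.tolist() for c, a in g.by_chrom.items()
        }

    def test_groups_round_trip(self, tmp_path):
        from relictpop.variant_store import GroupAssignment

        ga = GroupAssignment({"s1": "MK", "s2": "wild"})
        path = tmp_path / "g.tsv"
        write_groups(ga, path)
        assert read_groups(path).assignment == ga.assignment


class TestModelInvariants:
    def test_validate_detects_unsorted(self):
        m = make_cohort([[0, 1]], positions=[20, 10])
        with pytest.raises(ValueError, match="sorted"):
            m.validate()

    def test_validate_detects_phantom_alt(self):
        m = make_cohort([[1]])
        m.sites[0].alt_alleles = ()
        with pytest.raises(ValueError, match="alternate"):
            m.validate()

    def test_position_must_be_positive(self):
        with pytest.raises(ValueError):
            SiteRecord("A01", 0)
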