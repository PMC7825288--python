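import warnings
from pathlib import Path

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from mirsnp_rewire import annotation
from mirsnp_rewire.annotation import (
    MatureMirna,
    classify_region,
    compute_maf,
    cpm,
    filter_expressed_mirnas,
    filter_maf,
    position_in_mature,
)
from mirsnp_rewire.datagen import simulate_mirna_locus
from mirsnp_rewire.datagen.io import write_gff3, write_vcf


def _mirna(strand: str = "+") -> MatureMirna:
    # 1-based inclusive [100, 121] -> internal [99, 121), length 22
    return MatureMirna(
        name="mir-x", chrom="chr1", start=99, end=121, strand=strand,
        sequence="ACGUACGUACGUACGUACGUAC",
    )


class TestPositionInMature:
    def test_plus_strand_offset(self):
        assert position_in_mature(104, _mirna("+")) == 6  # VCF POS 105

    def test_minus_strand_mirror(self):
        assert position_in_mature(115, _mirna("-")) == 6  # VCF POS 116

    def test_outside_interval_is_none(self):
        assert position_in_mature(98, _mirna()) is None
        assert position_in_mature(121, _mirna()) is None

    def test_strand_mirror_exhaustive(self):
        """Reflecting a position through the interval midpoint and flipping
        the strand leaves the mature offset unchanged."""
        plus, minus = _mirna("+"), _mirna("-")
        for pos in range(99, 121):
            mirrored = 99 + 121 - 1 - pos
            assert position_in_mature(pos, plus) == position_in_mature(mirrored, minus)


class TestClassifyRegion:
    @pytest.mark.parametrize(
        "pos,region",
        [(1, "mature"), (2, "seed"), (6, "seed"), (7, "seed"),
         (8, "mature"), (10, "mature"), (13, "mature"), (22, "mature")],
    )
    def test_seed_boundaries(self, pos, region):
        assert classify_region(pos) == region

    def test_position_below_one_rejected(self):
        with pytest.raises(ValueError):
            classify_region(0)


class TestComputeMaf:
    @pytest.mark.parametrize(
        "hom_major,het,hom_minor,expected",
        [(326, 46, 2, 0.07), (130, 182, 62, 0.41), (345, 29, 0, 0.04)],
    )
    def test_genotype_count_arithmetic(self, hom_major, het, hom_minor, expected):
        """The three cohort genotype distributions reproduce the reported
        frequencies at two decimals."""
        g = np.repeat([0, 1, 2], [hom_major, het, hom_minor])
        minor, maf = compute_maf(g)
        assert minor == "alt"
        assert round(maf, 2) == expected

    def test_all_heterozygous_ties_report_alt(self):
        minor, maf = compute_maf(np.ones(10))
        assert (minor, maf) == ("alt", 0.5)

    def test_all_missing_rejected(self):
        with pytest.raises(ValueError):
            compute_maf(np.array([np.nan, np.nan]))

    @given(st.lists(st.integers(0, 2), min_size=1, max_size=60))
    def test_invariant_under_allele_label_swap(self, geno):
        g = np.array(geno, float)
        _, maf = compute_maf(g)
        _, maf_swapped = compute_maf(2 - g)
        assert maf == pytest.approx(maf_swapped)


class TestFilters:
    def _snp(self, maf: float):
        return annotation.MiRSNP(
            variant_id=f"rs_{maf}", chrom="chr1", pos=104, ref="C", alt="T",
            mirna=_mirna(), position_in_mature=6, region="seed",
            minor_allele="T", maf=maf,
        )

    def test_maf_boundary_is_kept(self):
        kept = filter_maf([self._snp(0.009), self._snp(0.01), self._snp(0.0)])
        assert [s.maf for s in kept] == [0.01]

    def test_maf_filter_matches_direct_scan(self, rng):
        snps = [self._snp(round(m, 4)) for m in rng.uniform(0, 0.5, 100)]
        kept = filter_maf(snps, threshold=0.05)
        assert len(kept) == sum(1 for s in snps if s.maf >= 0.05)

    def test_cpm_definition(self, rng):
        counts = pd.DataFrame(rng.integers(0, 1000, (20, 8)))
        lib = counts.sum(axis=0)
        out = cpm(counts)
        for i in range(20):
            for j in range(8):
                assert out.iloc[i, j] == pytest.approx(
                    counts.iloc[i, j] * 1e6 / lib.iloc[j]
                )

    def test_cpm_simple_values(self):
        counts = pd.DataFrame({"s1": [10, 0]}, index=["a", "b"])
        out = cpm(counts, pd.Series({"s1": 1_000_000}))
        assert out.loc["a", "s1"] == 10.0 and out.loc["b", "s1"] == 0.0

    def test_cpm_zero_library_rejected(self):
        with pytest.raises(ValueError):
            cpm(pd.DataFrame({"s1": [0, 0]}), pd.Series({"s1": 0}))

    def test_expression_filter_boundary_half_of_samples(self):
        mat = pd.DataFrame(
            [[0.5, 0.5, 0.1, 0.1], [0.4, 0.4, 0.4, 0.4]],
            index=["kept", "removed"],
        )
        assert filter_expressed_mirnas(mat) == ["kept"]

    def test_expression_filter_planted_funnel(self):
        """25 miRNAs of which exactly 5 are expressed leaves an analysis set
        of 5, mirroring the study's filter funnel."""
        rng = np.random.default_rng(0)
        expressed = rng.uniform(5, 50, (5, 10))
        silent = rng.uniform(0, 0.4, (20, 10))
        mat = pd.DataFrame(
            np.vstack([expressed, silent]),
            index=[f"mir{i}" for i in range(25)],
        )
        assert len(filter_expressed_mirnas(mat)) == 5

    def test_filters_commute_and_are_idempotent(self, rng):
        snps = [self._snp(round(m, 4)) for m in rng.uniform(0, 0.5, 50)]
        once = filter_maf(snps, 0.05)
        assert filter_maf(once, 0.05) == once


class TestFileRoundTrip:
    @pytest.mark.parametrize("strand", ["+", "-"])
    def test_simulated_locus_position_recovered(self, strand, tmp_path):
        """Loci written as VCF+GFF3 come back with the exact planted mature
        position and region, on both strands (spot positions incl. bounds)."""
        mature = "UCGACACGGUAGCAUGUCGAAU"
        positions = [1, 2, 6, 7, 8, 13, 22]
        loci = []
        for i, pos in enumerate(positions):
            major = mature[pos - 1]
            minor = {"A": "C", "C": "A", "G": "U", "U": "G"}[major]
            loci.append(
                simulate_mirna_locus(
                    mature, pos, (major, minor),
                    name=f"mir{i}", chrom=f"chr{i}", strand=strand,
                )
            )
        geno = np.tile([0, 1, 2, 1], (len(loci), 1)).T
        write_vcf(tmp_path / "x.vcf", loci, geno, [f"s{i}" for i in range(4)])
        write_gff3(tmp_path / "x.gff3", loci)
        counts = pd.DataFrame(
            np.full((len(loci), 4), 100),
            index=[l.name for l in loci],
            columns=[f"s{i}" for i in range(4)],
        )
        snps, dosages, funnel = annotation.select_analysis_set(
            tmp_path / "x.vcf", tmp_path / "x.gff3", counts
        )
        assert funnel["n_variants"] == len(positions)
        recovered = {s.mirna.name: (s.position_in_mature, s.region) for s in snps}
        for i, pos in enumerate(positions):
            assert recovered[f"mir{i}"] == (pos, classify_region(pos))

    def test_in_memory_round_trip_exhaustive(self):
        """Every mature position 1..22 on both strands maps back exactly."""
        mature = "UGCAGCUAAGCUCGGACUGCAU"
        for strand in "+-":
            for pos in range(1, 23):
                major = mature[pos - 1]
                minor = {"A": "C", "C": "A", "G": "U", "U": "G"}[major]
                loc = simulate_mirna_locus(mature, pos, (major, minor), strand=strand)
                mir = MatureMirna(
                    name=loc.name, chrom=loc.chrom,
                    start=loc.mature_start, end=loc.mature_end,
                    strand=strand, sequence=loc.mature_major,
                )
                assert position_in_mature(loc.snp_pos, mir) == pos

    def test_variant_outside_mature_excluded(self, tmp_path):
        loc = simulate_mirna_locus(
            "UCGACACGGUAGCAUGUCGAAU", 6, ("A", "C"), chrom="chr1"
        )
        mir = MatureMirna(
            name=loc.name, chrom="chr1", start=loc.mature_start,
            end=loc.mature_end, strand="+",
        )
        # a precursor position downstream of the mature interval
        assert position_in_mature(loc.mature_end + 3, mir) is None

    def test_multiallelic_records_split(self, tmp_path):
        vcf = tmp_path / "m.vcf"
        vcf.write_text(
            "##fileformat=VCFv4.2\n"
            '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n'
            "##contig=<ID=chr1,length=1000>\n"
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\ts1\ts2\n"
            "chr1\t10\trs1\tA\tC,G\t.\tPASS\t.\tGT\t0/1\t0/2\n"
        )
        variants, dosages = annotation.read_genotype_matrix(vcf)
        assert len(variants) == 2
        assert list(variants["alt"]) == ["C", "G"]
        assert dosages.iloc[0].tolist() == [1.0, 0.0]
        assert dosages.iloc[1].tolist() == [0.0, 1.0]

    def test_orphan_mature_feature_warns(self, tmp_path):
        gff = tmp_path / "o.gff3"
        gff.write_text(
            "##gff-version 3\n"
            "chr1\t.\tmiRNA\t100\t121\t.\t+\t.\tID=MIMAT_x;Name=mir-orphan\n"
        )
        with warnings.catch_warnings(record=True) as caught:
            warnings.simplefilter("always")
            matures = annotation.read_mature_mirnas(gff)
        assert len(matures) == 1
        assert any("parent" in str(w.message) for w in caught)
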