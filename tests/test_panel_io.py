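import numpy as np
import pandas as pd
import pytest

import lanccsv as lc
from lanccsv.panel import (MISSING, GenotypeMatrix, HaplotypePanel,
                           filter_strand_ambiguous, harmonize, read_genotypes,
                           read_panel, write_genotypes_vcf, write_panel,
                           read_read_counts, write_read_counts)
from lanccsv.tracks import from_segments, read_tracks, write_tracks

VCF_PHASED = """##fileformat=VCFv4.2
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\ts1\ts2
1\t100\t.\tA\tG\t.\tPASS\t.\tGT\t0|1\t1|1
1\t200\t.\tC\tT\t.\tPASS\t.\tGT\t0|0\t0|1
1\t300\t.\tG\tA\t.\tPASS\t.\tGT\t1|0\t0|0
"""

VCF_UNPHASED = VCF_PHASED.replace("0|1\t1|1", "0/1\t1|1")

VCF_MULTIALLELIC = """##fileformat=VCFv4.2
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\ts1
1\t100\t.\tA\tG\t.\tPASS\t.\tGT\t0|1
1\t150\t.\tA\tG,T\t.\tPASS\t.\tGT\t0|2
1\t200\t.\tC\tT\t.\tPASS\t.\tGT\t1|1
1\t250\t.\tCA\tC\t.\tPASS\t.\tGT\t0|1
1\t300\t.\tG\tA\t.\tPASS\t.\tGT\t0|0
"""


@pytest.fixture
def labels_file(tmp_path):
    p = tmp_path / "labels.tsv"
    p.write_text("s1\tCEU\tEUR\ns2\tYRI\tAFR\n")
    return p


class TestReadPanel:
    def test_phased_vcf_parses_to_haplotypes(self, tmp_path, labels_file):
        vcf = tmp_path / "p.vcf"
        vcf.write_text(VCF_PHASED)
        panel = read_panel(vcf, labels_file)
        assert panel.n_haplotypes == 4
        assert panel.n_sites == 3
        assert list(panel.labels) == ["CEU", "CEU", "YRI", "YRI"]
        assert panel.group_map["CEU"] == "EUR"
        # site 0: s1 = 0|1, s2 = 1|1
        assert list(panel.haplotypes[0]) == [0, 1, 1, 1]

    def test_unphased_record_is_an_error(self, tmp_path, labels_file):
        vcf = tmp_path / "p.vcf"
        vcf.write_text(VCF_UNPHASED)
        with pytest.raises(ValueError, match="unphased.*1:100"):
            read_panel(vcf, labels_file)

    def test_multiallelic_and_indel_records_skipped(self, tmp_path, tmp_path_factory):
        vcf = tmp_path / "p.vcf"
        vcf.write_text(VCF_MULTIALLELIC)
        labels = tmp_path / "l.tsv"
        labels.write_text("s1\tCEU\tEUR\n")
        panel = read_panel(vcf, labels)
        assert panel.n_sites == 3  # 2 of 5 records skipped

    def test_unknown_sample_is_an_error(self, tmp_path):
        vcf = tmp_path / "p.vcf"
        vcf.write_text(VCF_PHASED)
        labels = tmp_path / "l.tsv"
        labels.write_text("s1\tCEU\tEUR\n")
        with pytest.raises(ValueError, match="s2"):
            read_panel(vcf, labels)

    def test_matrix_dialect_round_trip(self, tmp_path, small_spec):
        panel, _ = lc.generate_synthetic_panel(small_spec, 0)
        write_panel(panel, tmp_path / "p.txt", tmp_path / "l.tsv")
        p2 = read_panel(tmp_path / "p.txt", tmp_path / "l.tsv")
        assert np.array_equal(p2.haplotypes, panel.haplotypes)
        assert p2.sites.equals(panel.sites)
        assert p2.group_map == panel.group_map


class TestStrandAmbiguousFilter:
    def test_rule_application(self):
        sites = pd.DataFrame({"chrom": "1", "pos": [1, 2, 3, 4],
                              "ref": ["A", "A", "C", "C"],
                              "alt": ["T", "G", "G", "T"]})
        hap = np.zeros((4, 2), dtype=np.uint8)
        panel = HaplotypePanel(sites, hap, np.array(["p", "p"]))
        out = filter_strand_ambiguous(panel)
        assert list(out.sites["pos"]) == [2, 4]

    def test_orientation_insensitive(self):
        sites = pd.DataFrame({"chrom": "1", "pos": [1], "ref": ["G"], "alt": ["C"]})
        panel = HaplotypePanel(sites, np.zeros((1, 2), np.uint8),
                               np.array(["p", "p"]))
        assert filter_strand_ambiguous(panel).n_sites == 0

    def test_clean_panel_unchanged(self, toy_panel):
        out = filter_strand_ambiguous(toy_panel)
        assert out.n_sites == toy_panel.n_sites


class TestPanelInvariants:
    def test_positions_must_increase(self):
        sites = pd.DataFrame({"chrom": "1", "pos": [5, 5], "ref": "A", "alt": "G"})
        with pytest.raises(ValueError, match="increasing"):
            HaplotypePanel(sites, np.zeros((2, 2), np.uint8), np.array(["p", "p"]))

    def test_non_binary_entries_rejected(self, toy_panel):
        with pytest.raises(ValueError, match="0/1"):
            HaplotypePanel(toy_panel.sites, toy_panel.haplotypes * 2,
                           toy_panel.labels, toy_panel.group_map)

    def test_genotypes_missing_sentinel_distinct(self):
        sites = pd.DataFrame({"chrom": "1", "pos": [1], "ref": ["A"], "alt": ["G"]})
        gm = GenotypeMatrix(sites, np.array([[MISSING, 0]], np.int8), ["i1", "i2"])
        assert gm.genotypes[0, 0] == MISSING != 0
        with pytest.raises(ValueError):
            GenotypeMatrix(sites, np.array([[3, 0]], np.int8), ["i1", "i2"])


class TestTracks:
    def test_round_trip_identity(self, tmp_path):
        track = from_segments([
            ("i1", "1", 1, 100, "EUR", "AFR"),
            ("i1", "1", 101, 500, "AFR", "AFR"),
            ("i2", "1", 1, 500, "EUR", "EUR"),
        ])
        write_tracks(track, tmp_path / "t.bed")
        assert read_tracks(tmp_path / "t.bed") == track

    def test_bed_coordinates_half_open(self, tmp_path):
        track = from_segments([("i1", "1", 1, 100, "A", "A")])
        write_tracks(track, tmp_path / "t.bed")
        line = (tmp_path / "t.bed").read_text().splitlines()[1]
        assert line.split("\t")[1:3] == ["0", "100"]

    def test_overlap_on_read_is_an_error(self, tmp_path):
        p = tmp_path / "t.bed"
        p.write_text("1\t0\t100\ti1\tA,A\n1\t50\t150\ti1\tA,B\n")
        with pytest.raises(ValueError, match="overlap"):
            read_tracks(p)

    def test_adjacent_equal_states_merge(self):
        track = from_segments([("i1", "1", 1, 100, "A", "B"),
                               ("i1", "1", 101, 200, "B", "A")])
        assert len(track.df) == 1
        assert track.df.loc[0, "end"] == 200


class TestHarmonize:
    def _pair(self):
        sites = pd.DataFrame({"chrom": "1", "pos": [10, 20, 30],
                              "ref": ["A", "C", "G"], "alt": ["G", "T", "A"]})
        panel = HaplotypePanel(sites, np.zeros((3, 2), np.uint8),
                               np.array(["p", "p"]))
        gsites = pd.DataFrame({"chrom": "1", "pos": [10, 20, 40],
                               "ref": ["A", "T", "G"], "alt": ["G", "C", "A"]})
        gm = GenotypeMatrix(gsites, np.array([[2], [2], [1]], np.int8), ["i1"])
        return panel, gm

    def test_swapped_alleles_flipped_and_extras_dropped(self):
        panel, gm = self._pair()
        out = harmonize(panel, gm, on_swap="flip")
        assert out.sites.equals(panel.sites)
        assert out.genotypes[0, 0] == 2        # exact match
        assert out.genotypes[1, 0] == 0        # flipped 2 -> 0
        assert out.genotypes[2, 0] == MISSING  # panel site absent from input

    def test_swapped_alleles_dropped_when_configured(self):
        panel, gm = self._pair()
        out = harmonize(panel, gm, on_swap="drop")
        assert out.genotypes[1, 0] == MISSING


class TestGenotypeVcf:
    def test_vcf_round_trip_with_missing(self, tmp_path):
        sites = pd.DataFrame({"chrom": "1", "pos": [10, 20],
                              "ref": ["A", "C"], "alt": ["G", "T"]})
        gm = GenotypeMatrix(sites, np.array([[0, 2], [MISSING, 1]], np.int8),
                            ["i1", "i2"])
        write_genotypes_vcf(gm, tmp_path / "g.vcf")
        g2 = read_genotypes(tmp_path / "g.vcf")
        assert np.array_equal(g2.genotypes, gm.genotypes)
        assert g2.samples == gm.samples


def test_read_counts_round_trip(tmp_path):
    sites = pd.DataFrame({"chrom": "1", "pos": [10, 20],
                          "ref": ["A", "C"], "alt": ["G", "T"]})
    ref = np.array([[3, 0], [1, 5]])
    alt = np.array([[0, 2], [4, 0]])
    write_read_counts(sites, ["i1", "i2"], ref, alt, tmp_path / "r.tsv")
    r2, a2 = read_read_counts(tmp_path / "r.tsv", sites, ["i1", "i2"])
    assert np.array_equal(r2, ref) and np.array_equal(a2, alt)
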