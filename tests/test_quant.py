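"""Gene-body counting, exclusion rules, TPM, and track normalization."""

import numpy as np
import pandas as pd
import pytest

from conftest import (
    brute_force_gene_counts,
    brute_force_mirna_counts,
    random_genome_instance,
)
from ptreg.quant import (
    QuantParams,
    count_gene_body,
    count_mirna_locus,
    normalize_track,
    tpm_normalize,
)


def make_gene(gene_id="gA", strand="+", start=1000, end=3000, chrom="chr1"):
    tss = start if strand == "+" else end - 1
    return pd.DataFrame(
        [{"gene_id": gene_id, "chrom": chrom, "strand": strand, "start": start, "end": end, "tss": tss}]
    )


def make_reads(rows):
    return pd.DataFrame(rows, columns=["chrom", "strand", "position", "count"])


class TestCountGeneBody:
    def test_worked_example_with_all_exclusions(self):
        # + strand gene [1000,3000): TSS window kills 1050, antisense kills
        # one of the 1200s, the TRE kills 1550 -> one read survives
        genes = make_gene()
        tres = pd.DataFrame([{"tre_id": "t1", "chrom": "chr1", "start": 1500, "end": 1600}])
        reads = make_reads(
            [
                ("chr1", "+", 1050, 1),
                ("chr1", "+", 1200, 1),
                ("chr1", "-", 1200, 1),
                ("chr1", "+", 1550, 1),
            ]
        )
        counts = count_gene_body(reads, genes, tres)
        assert counts["gA"] == 1

    def test_short_gene_absent_from_output(self):
        genes = make_gene(end=1900)  # 900 bp body
        counts = count_gene_body(make_reads([("chr1", "+", 1500, 5)]), genes, None)
        assert "gA" not in counts.index

    def test_no_reads_gives_zero(self):
        counts = count_gene_body(make_reads([]), make_gene(), None)
        assert counts["gA"] == 0

    def test_minus_strand_tss_window_points_into_the_gene(self):
        # - strand gene: TSS = end-1; window covers the last 150 bases
        genes = make_gene(strand="-")
        reads = make_reads([("chr1", "-", 2950, 1), ("chr1", "-", 2849, 1)])
        counts = count_gene_body(reads, genes, None)
        assert counts["gA"] == 1  # 2950 excluded, 2849 kept

    def test_tss_outside_body_raises(self):
        genes = make_gene()
        genes.loc[0, "tss"] = 5000
        with pytest.raises(ValueError, match="TSS"):
            count_gene_body(make_reads([]), genes, None)

    def test_unknown_chromosome_reads_skipped(self, caplog):
        reads = make_reads([("chrUn", "+", 1500, 3), ("chr1", "+", 2500, 2)])
        with caplog.at_level("WARNING"):
            counts = count_gene_body(reads, make_gene(), None)
        assert counts["gA"] == 2
        assert "unknown chromosome" in caplog.text

    def test_non_overlapping_tre_changes_nothing(self):
        genes = make_gene()
        reads = make_reads([("chr1", "+", 2500, 4)])
        far_tre = pd.DataFrame([{"tre_id": "t", "chrom": "chr1", "start": 9000, "end": 9200}])
        assert count_gene_body(reads, genes, far_tre).equals(count_gene_body(reads, genes, None))

    def test_invariant_to_record_order_and_splitting(self):
        rng = np.random.default_rng(5)
        genes, tres, reads = random_genome_instance(rng)
        shuffled = reads.sample(frac=1.0, random_state=1).reset_index(drop=True)
        split = reads.loc[reads.index.repeat(reads["count"])].assign(count=1).reset_index(drop=True)
        base = count_gene_body(reads, genes, tres)
        pd.testing.assert_series_equal(base, count_gene_body(shuffled, genes, tres))
        pd.testing.assert_series_equal(base, count_gene_body(split, genes, tres))

    @pytest.mark.parametrize("seed", range(25))
    def test_matches_brute_force_on_random_genomes(self, seed):
        rng = np.random.default_rng(seed)
        genes, tres, reads = random_genome_instance(rng)
        fast = count_gene_body(reads, genes, tres)
        slow = brute_force_gene_counts(reads, genes, tres)
        pd.testing.assert_series_equal(fast.sort_index(), slow.sort_index(), check_names=False)


class TestTPM:
    def test_single_gene_gets_the_whole_million(self):
        genes = make_gene()
        tpm = tpm_normalize(pd.Series({"gA": 7.0}), genes)
        assert tpm["gA"] == pytest.approx(1e6)

    def test_hand_computed_two_gene_example(self):
        genes = pd.concat(
            [make_gene("g1", start=0, end=1000), make_gene("g2", start=5000, end=7000)],
            ignore_index=True,
        )
        tpm = tpm_normalize(pd.Series({"g1": 10.0, "g2": 10.0}), genes)
        assert tpm["g1"] == pytest.approx(666666.6667, rel=1e-6)
        assert tpm["g2"] == pytest.approx(333333.3333, rel=1e-6)

    def test_scale_invariance(self):
        genes = pd.concat(
            [make_gene("g1", start=0, end=1500), make_gene("g2", start=5000, end=9000)],
            ignore_index=True,
        )
        counts = pd.Series({"g1": 12.0, "g2": 30.0})
        pd.testing.assert_series_equal(tpm_normalize(counts, genes), tpm_normalize(2 * counts, genes))

    def test_all_zero_column_stays_zero(self):
        genes = make_gene()
        mat = pd.DataFrame({"s1": [0.0], "s2": [5.0]}, index=["gA"])
        tpm = tpm_normalize(mat, genes)
        assert tpm["s1"].eq(0).all()
        assert tpm["s2"]["gA"] == pytest.approx(1e6)

    def test_matrix_columns_sum_to_one_million(self):
        genes = pd.concat(
            [make_gene(f"g{i}", start=i * 10_000, end=i * 10_000 + 1000 * (i + 1)) for i in range(4)],
            ignore_index=True,
        )
        rng = np.random.default_rng(0)
        mat = pd.DataFrame(
            rng.integers(1, 100, size=(4, 3)).astype(float),
            index=genes["gene_id"],
            columns=["a", "b", "c"],
        )
        sums = tpm_normalize(mat, genes).sum(axis=0)
        assert np.allclose(sums, 1e6, rtol=1e-9)


class TestMirnaLocus:
    def test_flank_window_boundaries(self):
        coords = pd.DataFrame(
            [{"mirna_id": "miR-1", "chrom": "chr1", "strand": "+", "start": 10_000, "end": 10_022}]
        )
        reads = make_reads([("chr1", "+", 5500, 1), ("chr1", "+", 4999, 1)])
        counts = count_mirna_locus(reads, coords)
        assert counts["miR-1"] == 1  # 5500 in [5000, 15022); 4999 outside

    def test_antisense_read_not_counted(self):
        coords = pd.DataFrame(
            [{"mirna_id": "miR-1", "chrom": "chr1", "strand": "+", "start": 10_000, "end": 10_022}]
        )
        assert count_mirna_locus(make_reads([("chr1", "-", 10_010, 3)]), coords)["miR-1"] == 0

    def test_flank_clipped_at_chromosome_start(self):
        coords = pd.DataFrame(
            [{"mirna_id": "miR-1", "chrom": "chr1", "strand": "+", "start": 100, "end": 122}]
        )
        counts = count_mirna_locus(make_reads([("chr1", "+", 0, 2)]), coords)
        assert counts["miR-1"] == 2

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_brute_force(self, seed):
        rng = np.random.default_rng(1000 + seed)
        genes, _, reads = random_genome_instance(rng)
        coords = genes.rename(columns={"gene_id": "mirna_id"})[
            ["mirna_id", "chrom", "strand", "start", "end"]
        ]
        fast = count_mirna_locus(reads, coords)
        slow = brute_force_mirna_counts(reads, coords)
        pd.testing.assert_series_equal(fast.sort_index(), slow.sort_index(), check_names=False)


class TestNormalizeTrack:
    def test_total_two_million_halves_every_value(self):
        reads = make_reads([("chr1", "+", 100, 1_500_000), ("chr1", "-", 200, 500_000)])
        track = normalize_track(reads)
        plus = track[track["value"] > 0]["value"].iloc[0]
        minus = track[track["value"] < 0]["value"].iloc[0]
        assert plus == pytest.approx(750_000.0)
        assert minus == pytest.approx(-250_000.0)
        assert track["value"].abs().sum() == pytest.approx(1e6)

    def test_empty_track(self):
        assert len(normalize_track(make_reads([]))) == 0

    def test_minus_strand_is_negative(self):
        track = normalize_track(make_reads([("chr1", "-", 5, 10)]))
        assert (track["value"] < 0).all()
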