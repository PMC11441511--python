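"""Amplicon read processing, clustering, retention filters and metrics."""

from collections import Counter

import numpy as np
import pytest

from ecmevolve.barcodes import (
    BARCODE_LEN,
    FLANK3,
    FLANK5,
    BarcodeCountTable,
    MergedRead,
    ReadPair,
    apply_lineage_filters,
    build_lineage_table,
    cluster_barcodes,
    count_sample,
    display_barcode,
    diversity_summary,
    extract_barcode,
    log2_fold_change,
    merge_read_pair,
    preference_score,
    quality_filter,
    reverse_complement,
)
from ecmevolve.simulate import generate_reads, random_barcodes


def _pair_from_template(template, read_len, overlap_start, q1=38, q2=38):
    """Mates as exact prefix/suffix windows of one template."""
    mate1 = template[:read_len]
    mate2 = reverse_complement(template[overlap_start:])
    return ReadPair("r1", mate1, (q1,) * len(mate1), mate2, (q2,) * len(mate2))


class TestMergeReadPair:
    TEMPLATE = "".join(
        "ACGT"[i % 4] if i % 7 else "G" for i in range(120))  # aperiodic-ish

    def test_perfect_overlap_reconstructs_template(self, rng):
        template = "".join(rng.choice(list("ACGT"), size=120))
        pair = _pair_from_template(template, 80, 40)  # 40-base overlap
        merged = merge_read_pair(pair)
        assert merged is not None
        assert merged.seq == template

    def test_disagreement_resolved_by_higher_quality(self, rng):
        template = "".join(rng.choice(list("ACGT"), size=120))
        mate1 = list(template[:80])
        pos = 60  # inside the overlap [40, 80)
        orig = mate1[pos]
        mate1[pos] = {"A": "C", "C": "G", "G": "T", "T": "A"}[orig]
        pair = ReadPair("r", "".join(mate1), (40,) * 80,
                        reverse_complement(template[40:]), (10,) * 80)
        merged = merge_read_pair(pair)
        assert merged.seq[pos] == mate1[pos]  # mate 1 wins at Phred 40 vs 10
        # with qualities swapped, mate 2's (template) base wins
        pair2 = ReadPair("r", "".join(mate1), (10,) * 80,
                         reverse_complement(template[40:]), (40,) * 80)
        assert merge_read_pair(pair2).seq == template

    def test_unrelated_reads_fail_to_merge(self, rng):
        s1 = "".join(rng.choice(list("ACGT"), size=70))
        s2 = "".join(rng.choice(list("ACGT"), size=70))
        pair = ReadPair("r", s1, (38,) * 70, s2, (38,) * 70)
        assert merge_read_pair(pair) is None

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            ReadPair("r", "ACGT", (30, 30), "ACGT", (30,) * 4)


class TestQualityFilter:
    @pytest.mark.parametrize("quals,expected", [
        ((35,) * 50, True),
        ((20,) * 50, False),
        ((40,) * 25 + (22,) * 25, True),  # mean 31
    ])
    def test_mean_phred_threshold(self, quals, expected):
        read = MergedRead("r", "A" * len(quals), tuple(quals))
        assert quality_filter(read) is expected

    def test_optional_per_base_minimum(self):
        read = MergedRead("r", "A" * 10, (40,) * 9 + (2,))
        assert quality_filter(read)
        assert not quality_filter(read, min_base_phred=3)


class TestExtractBarcode:
    BARCODE = "ACGTACGTACGTACGTACGT"
    READ = "AA" + FLANK5 + BARCODE + FLANK3 + "CC"

    def test_extracts_between_flanks(self):
        assert extract_barcode(self.READ) == self.BARCODE

    def test_one_substitution_in_flank_tolerated(self):
        # floor(0.1 * 18) = 1 substitution allowed in the 5' flank
        mutated = self.READ.replace(FLANK5, "T" + FLANK5[1:])
        assert extract_barcode(mutated) == self.BARCODE

    def test_two_substitutions_in_flank_rejected(self):
        mutated = self.READ.replace(FLANK5, "TT" + FLANK5[2:])
        assert extract_barcode(mutated) is None

    def test_ambiguous_base_in_barcode_rejected(self):
        read = "AA" + FLANK5 + "N" + self.BARCODE[1:] + FLANK3 + "CC"
        assert extract_barcode(read) is None

    def test_missing_3prime_flank_rejected(self):
        read = "AA" + FLANK5 + self.BARCODE + "GGGGGGGGGGGGGGGGGGGG"
        assert extract_barcode(read) is None

    def test_leftmost_qualifying_match_wins(self):
        other = "TGCATGCATGCATGCATGCA"
        double = ("AA" + FLANK5 + self.BARCODE + FLANK3
                  + FLANK5 + other + FLANK3 + "CC")
        assert extract_barcode(double) == self.BARCODE


class TestClusterBarcodes:
    def test_one_edit_minor_variant_absorbed(self):
        a = "A" * BARCODE_LEN
        a1 = "A" * (BARCODE_LEN - 1) + "T"
        assert cluster_barcodes({a: 1000, a1: 10}) == {a: 1010}

    def test_count_ratio_below_three_keeps_both(self):
        x = "ACGT" * 5
        y = "ACGT" * 4 + "ACGA"  # distance 1
        out = cluster_barcodes({x: 900, y: 850})
        assert out == {x: 900, y: 850}

    def test_distance_two_never_merged(self):
        x = "ACGT" * 5
        z = "ACGT" * 4 + "AAGA"  # distance 2
        out = cluster_barcodes({x: 900, z: 1})
        assert set(out) == {x, z}

    def test_conserves_reads_and_never_adds_barcodes(self, rng):
        true = random_barcodes(8, rng)
        raw = Counter()
        for bc in true:
            raw[bc] += int(rng.integers(50, 500))
            for _ in range(int(rng.integers(0, 6))):
                pos = int(rng.integers(BARCODE_LEN))
                sub = rng.choice([b for b in "ACGT" if b != bc[pos]])
                raw[bc[:pos] + sub + bc[pos + 1:]] += int(rng.integers(1, 5))
        out = cluster_barcodes(raw)
        assert sum(out.values()) == sum(raw.values())
        assert len(out) <= len(raw)
        assert set(out) <= set(raw)

    def test_recovers_true_lineages_from_error_reads(self, rng):
        """1e5 reads over 20 lineages >= 3 edits apart, substitution rate
        0.005/base: every true lineage comes back as a cluster and >= 99% of
        erroneous reads are funnelled to their parent."""
        true = random_barcodes(20, rng, min_dist=3)
        draws = rng.multinomial(100_000, np.full(20, 1 / 20))
        raw = Counter()
        n_err = 0
        bases = np.array(list("ACGT"))
        for bc, c in zip(true, draws):
            n_errors = rng.binomial(BARCODE_LEN, 0.005, size=c)
            raw[bc] += int((n_errors == 0).sum())
            for k in n_errors[n_errors > 0]:
                n_err += 1
                b = list(bc)
                for pos in rng.choice(BARCODE_LEN, size=k, replace=False):
                    b[pos] = rng.choice(bases[bases != b[pos]])
                raw["".join(b)] += 1
        out = cluster_barcodes(raw)
        assert set(true) <= set(out)
        stray = sum(c for b, c in out.items() if b not in true)
        assert stray <= 0.01 * n_err
        assert sum(out.values()) == 100_000

    def test_empty_input(self):
        assert cluster_barcodes({}) == {}


class TestLineageFilters:
    def test_rule_truth_table(self, toy_count_table):
        out = apply_lineage_filters(toy_count_table)
        expect = {
            "AAAAAAAAAAAAAAAAAAAA": (True, False, False, True),
            "CCCCCCCCCCCCCCCCCCCC": (False, True, False, True),
            "GGGGGGGGGGGGGGGGGGGG": (False, False, False, False),
            "TTTTTTTTTTTTTTTTTTTT": (False, True, False, True),
            "ACACACACACACACACACAC": (False, False, True, True),
            "AGAGAGAGAGAGAGAGAGAG": (True, True, True, True),
        }
        for bc, (r1, r2, r3, kept) in expect.items():
            row = out.loc[bc]
            assert (row.rule1, row.rule2, row.rule3, row.retained) == \
                (r1, r2, r3, kept), bc

    def test_missing_ancestral_sample_is_an_error(self, toy_count_table):
        counts = toy_count_table.counts.drop(columns="anc")
        groups = {s: g for s, g in toy_count_table.groups.items() if s != "anc"}
        with pytest.raises(ValueError):
            apply_lineage_filters(BarcodeCountTable(counts, groups))

    def test_retention_monotone_in_own_count(self, toy_count_table):
        base = apply_lineage_filters(toy_count_table)
        for bc in toy_count_table.counts.index:
            if not base.loc[bc, "retained"]:
                continue
            boosted = toy_count_table.counts.copy()
            boosted.loc[bc] = boosted.loc[bc] * 10 + 5
            out = apply_lineage_filters(
                BarcodeCountTable(boosted, dict(toy_count_table.groups)))
            assert out.loc[bc, "retained"]


class TestMetrics:
    def test_log2_fold_change_examples(self):
        assert log2_fold_change(0.08, 0.01, 1e-12) == pytest.approx(3.0, abs=1e-6)
        assert log2_fold_change(0.37, 0.37, 0.01) == 0.0
        assert log2_fold_change(0.10, 0.0, 1e-4) == pytest.approx(
            np.log2(0.1001 / 1e-4), rel=1e-9)  # ~9.97
        with pytest.raises(ValueError):
            log2_fold_change(0.1, 0.1, 0.0)

    def test_preference_score_examples_and_antisymmetry(self):
        assert preference_score([3, 3], [1, 1]) == pytest.approx(2.0)
        assert preference_score([0.5, 0.7], [0.5, 0.7]) == pytest.approx(0.0)
        s = preference_score([1.2, 0.3], [0.4, -0.1])
        assert preference_score([0.4, -0.1], [1.2, 0.3]) == pytest.approx(-s)

    def test_diversity_collapse_arithmetic(self):
        import itertools

        n = 220
        tails = itertools.product("ACGT", repeat=4)  # 256 distinct tails
        barcodes = ["A" * 16 + "".join(t) for t in itertools.islice(tails, n)]
        anc = {bc: 100 for bc in barcodes}
        survivors = barcodes[:44]
        per_sample = {"anc": anc,
                      "soft1": {bc: 500 for bc in survivors[:30]},
                      "stiff1": {bc: 500 for bc in survivors[20:]}}
        table = BarcodeCountTable.from_sample_counts(
            per_sample, {"anc": "ancestral", "soft1": "soft", "stiff1": "stiff"})
        d = diversity_summary(table)
        assert d["ancestral"] == 220
        assert d["selected_union"] == 44
        assert d["percent_decrease"] == pytest.approx(80.0)

    def test_no_collapse_and_single_survivor_limits(self, toy_count_table):
        freq = toy_count_table.frequencies()
        assert np.allclose(freq.sum(axis=0), 1.0, atol=1e-12)
        # selected identical to ancestral -> 0% decrease
        anc = {f"{'A' * 19}{b}": 10 for b in "CGT"}
        table = BarcodeCountTable.from_sample_counts(
            {"anc": anc, "s": anc, "t": anc},
            {"anc": "ancestral", "s": "soft", "t": "stiff"})
        assert diversity_summary(table)["percent_decrease"] == 0.0
        # one survivor of 220 -> ~99.5%
        assert 100 * (1 - 1 / 220) == pytest.approx(99.5455, abs=1e-3)

    def test_lineage_table_columns_and_preference(self, toy_count_table):
        out = build_lineage_table(toy_count_table)
        assert {"n_samples_detected", "preference_score", "retained"} <= set(out.columns)
        pct_cols = [c for c in out.columns if c.startswith("pct_")]
        assert ((out[pct_cols] >= 0) & (out[pct_cols] <= 100)).all().all()
        assert np.allclose(out["preference_score"],
                           out["log2fc_soft"] - out["log2fc_stiff"])

    def test_display_truncation(self):
        assert display_barcode("TTTCTTCATTTCTTCATTTC") == "TTTCTTCA..."


class TestFastqRoundTrip:
    def test_zero_error_pipeline_recovers_truth_exactly(self, rng, tmp_path):
        barcodes = random_barcodes(12, rng, min_dist=3)
        freqs = dict(zip(barcodes, np.full(12, 1 / 12)))
        fq1, fq2 = tmp_path / "s_1.fq", tmp_path / "s_2.fq"
        truth = generate_reads(freqs, 1500, 0.0, rng, fq1, fq2)
        counts, stats = count_sample(fq1, fq2)
        assert stats["merge_failed"] == 0
        assert stats["low_quality"] == 0
        assert counts == truth["reads_per_barcode"]

    def test_noisy_pipeline_clusters_to_truth_within_double_error_loss(
            self, rng, tmp_path):
        barcodes = random_barcodes(6, rng, min_dist=3)
        freqs = dict(zip(barcodes, np.full(6, 1 / 6)))
        fq1, fq2 = tmp_path / "s_1.fq", tmp_path / "s_2.fq"
        truth = generate_reads(freqs, 4000, 0.005, rng, fq1, fq2)
        counts, stats = count_sample(fq1, fq2)
        assert set(barcodes) <= set(counts)
        recovered = sum(counts.get(b, 0) for b in barcodes)
        assert recovered >= 0.99 * stats["extracted"]
        for b in barcodes:
            assert counts[b] == pytest.approx(truth["reads_per_barcode"][b],
                                              rel=0.05)

    def test_low_quality_reads_removed_exactly(self, rng, tmp_path):
        barcodes = random_barcodes(4, rng)
        freqs = dict(zip(barcodes, np.full(4, 0.25)))
        fq1, fq2 = tmp_path / "s_1.fq", tmp_path / "s_2.fq"
        truth = generate_reads(freqs, 800, 0.0, rng, fq1, fq2,
                               low_quality_frac=0.1)
        counts, stats = count_sample(fq1, fq2)
        assert stats["low_quality"] == truth["n_low_quality"]
        assert stats["extracted"] == 800 - truth["n_low_quality"]
        assert sum(counts.values()) == 800 - truth["n_low_quality"]
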