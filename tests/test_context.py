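"""Cytosine-context counting and the analytic expectation model."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from methylspread.context_freq import (
    ContextCounts,
    count_contexts,
    expected_frequencies,
    frequency_table,
    ltr_similarity_frequencies,
    printed_frequency,
)
from methylspread.simulate import write_genome_fasta

from oracles import brute_context_counts

COMPLEMENT = str.maketrans("ACGT", "TGCA")


def random_seq(rng, n, p=(0.25, 0.25, 0.25, 0.25)):
    return "".join(np.array(list("ACGT"))[rng.choice(4, size=n, p=list(p))])


class TestCountContexts:
    @pytest.mark.parametrize(
        "seq, cg, chg, chh",
        [
            ("ACGT", 1, 0, 0),   # palindromic CG counted once
            ("CAG", 0, 1, 0),    # CHG palindrome counted once
            ("CAA", 0, 0, 1),    # reverse strand TTG contributes nothing
            ("CCG", 1, 1, 0),    # first C is CHG (H=C), second C is CG
            ("TTG", 0, 0, 1),    # reverse-strand CAA
        ],
    )
    def test_hand_checked_examples(self, seq, cg, chg, chh):
        counts = count_contexts(seq)
        assert (counts.n_cg, counts.n_chg, counts.n_chh) == (cg, chg, chh)

    def test_empty_sequence_raises(self):
        with pytest.raises(ValueError):
            count_contexts("")

    def test_n_bases_contribute_no_context(self):
        assert count_contexts("CNN").n_chh == 0
        assert count_contexts("CNG").n_chg == 0

    @settings(derandomize=True, max_examples=60, deadline=None)
    @given(seed=st.integers(0, 10_000), n=st.integers(3, 60))
    def test_matches_pure_python_oracle(self, seed, n):
        rng = np.random.default_rng(seed)
        seq = random_seq(rng, n)
        counts = count_contexts(seq)
        assert (counts.n_cg, counts.n_chg, counts.n_chh) == \
            brute_context_counts(seq)

    @settings(derandomize=True, max_examples=40, deadline=None)
    @given(seed=st.integers(0, 10_000))
    def test_reverse_complement_symmetry(self, seed):
        rng = np.random.default_rng(seed)
        seq = random_seq(rng, 50)
        rc = seq.translate(COMPLEMENT)[::-1]
        a = count_contexts(seq)
        b = count_contexts(rc)
        # CG is palindromic and CHH counts both strands: fully symmetric.
        assert (a.n_cg, a.n_chh) == (b.n_cg, b.n_chh)
        # CHG is symmetric except for H=C: a CCG is CHG on its own strand but
        # its opposite-strand cytosine sits in CG context, so the per-strand
        # CHG counts differ by exactly the CCG imbalance.
        def ccg(s):
            return sum(1 for i in range(len(s) - 2) if s[i:i + 3] == "CCG")

        assert a.n_chg - b.n_chg == ccg(seq) - ccg(rc)

    def test_every_forward_cytosine_in_exactly_one_context(self):
        rng = np.random.default_rng(77)
        seq = random_seq(rng, 2_000)
        counts = count_contexts(seq)
        fwd_chh = sum(
            1 for i in range(len(seq) - 2)
            if seq[i] == "C" and seq[i + 1] in "ACT" and seq[i + 2] in "ACT"
        )
        n_c_with_context = sum(
            1 for i in range(len(seq) - 2) if seq[i] == "C"
        ) + (1 if seq[-2] == "C" and seq[-1] == "G" else 0)
        assert counts.n_cg + counts.n_chg + fwd_chh == n_c_with_context


class TestExpectedFrequencies:
    def test_uniform_composition_rounds_to_printed_values(self):
        exp = expected_frequencies()
        assert exp["CG"] == pytest.approx(0.0625)
        assert exp["CHG"] == pytest.approx(0.046875)
        assert exp["CHH"] == pytest.approx(0.28125)
        assert printed_frequency(exp["CG"], 3) == 0.063
        assert printed_frequency(exp["CHG"], 3) == 0.047
        assert printed_frequency(exp["CHH"], 2) == 0.28

    def test_no_forward_cytosines(self):
        # no C on the forward strand: CG and CHG vanish, but reverse-strand
        # CHH contexts (D-D-G on the forward strand) remain with rate p(G)
        exp = expected_frequencies({"A": 0.4, "C": 0.0, "G": 0.3, "T": 0.3})
        assert exp["CG"] == 0.0 and exp["CHG"] == 0.0
        assert exp["CHH"] == pytest.approx(0.3)
        # and the counter agrees: a C-free sequence still has CHH contexts
        assert count_contexts("AAG").n_chh == 1

    def test_no_cytosines_on_either_strand_all_zero(self):
        exp = expected_frequencies({"A": 0.6, "C": 0.0, "G": 0.0, "T": 0.4})
        assert exp == {"CG": 0.0, "CHG": 0.0, "CHH": 0.0}

    def test_probabilities_must_sum_to_one(self):
        with pytest.raises(ValueError):
            expected_frequencies({"A": 0.5, "C": 0.5, "G": 0.5, "T": 0.5})

    def test_matches_empirical_frequencies_of_biased_sequence(self):
        p = {"A": 0.4, "C": 0.15, "G": 0.35, "T": 0.10}
        rng = np.random.default_rng(31)
        seq = random_seq(rng, 200_000, p=[p[b] for b in "ACGT"])
        counts = count_contexts(seq)
        exp = expected_frequencies(p)
        freqs = counts.frequencies
        for ctx in ("CG", "CHG", "CHH"):
            # 4 binomial SDs of the per-bp rate
            sd = np.sqrt(exp[ctx] * (1 - min(exp[ctx], 1)) / len(seq))
            assert abs(freqs[ctx] - exp[ctx]) < 4 * sd + 1e-4


class TestFrequencyTable:
    def _write_genome(self, tmp_path, seqs):
        path = tmp_path / "g.fa"
        write_genome_fasta(seqs, path)
        return path

    def test_repeated_acgt_gives_quarter_cg(self, tmp_path):
        fasta = self._write_genome(tmp_path, {"Chr1": "ACGT" * 250})
        tes = pd.DataFrame(
            [{"chrom": "Chr1", "start": 0, "end": 1000, "te_id": "TE0",
              "superfamily": "Gypsy", "dmr_class": "cCMT2"}]
        )
        table = frequency_table(tes, fasta)
        row = table[(table["dmr_class"] == "cCMT2")
                    & (table["superfamily"] == "Gypsy")].iloc[0]
        assert row["CG"] == pytest.approx(0.25)

    def test_class_equal_to_reference_flags_reference(self, tmp_path):
        rng = np.random.default_rng(3)
        seq = random_seq(rng, 3_000)
        fasta = self._write_genome(tmp_path, {"Chr1": seq})
        tes = pd.DataFrame(
            [{"chrom": "Chr1", "start": i * 300, "end": i * 300 + 200,
              "te_id": f"TE{i}", "superfamily": "Copia",
              "dmr_class": "cRdDM"} for i in range(5)]
        )
        table = frequency_table(tes, fasta)
        cls_row = table[table["dmr_class"] == "cRdDM"].iloc[0]
        assert (cls_row["flag_CG"], cls_row["flag_CHG"],
                cls_row["flag_CHH"]) == ("reference",) * 3

    def test_injected_composition_bias_flags_direction(self, tmp_path):
        rng = np.random.default_rng(9)
        gc_rich = random_seq(rng, 4_000, p=(0.15, 0.35, 0.35, 0.15))
        at_rich = random_seq(rng, 4_000, p=(0.35, 0.15, 0.15, 0.35))
        fasta = self._write_genome(
            tmp_path, {"Chr1": gc_rich + at_rich}
        )
        tes = pd.DataFrame(
            [{"chrom": "Chr1", "start": i * 400, "end": i * 400 + 300,
              "te_id": f"G{i}", "superfamily": "Gypsy",
              "dmr_class": "cCMT2"} for i in range(10)]
            + [{"chrom": "Chr1", "start": 4_000 + i * 400,
                "end": 4_000 + i * 400 + 300, "te_id": f"A{i}",
                "superfamily": "Gypsy", "dmr_class": "eRdDM"}
               for i in range(10)]
        )
        table = frequency_table(tes, fasta)
        cc = table[table["dmr_class"] == "cCMT2"].iloc[0]
        er = table[table["dmr_class"] == "eRdDM"].iloc[0]
        assert cc["flag_CG"] == "higher" and er["flag_CG"] == "lower"

    def test_pooling_is_length_weighted(self, tmp_path):
        fasta = self._write_genome(
            tmp_path, {"Chr1": "ACGT" * 250 + "AAAA" * 250}
        )
        tes = pd.DataFrame(
            [{"chrom": "Chr1", "start": 0, "end": 1000, "te_id": "TE0",
              "superfamily": "Gypsy", "dmr_class": "cCMT2"},
             {"chrom": "Chr1", "start": 1000, "end": 1200, "te_id": "TE1",
              "superfamily": "Gypsy", "dmr_class": "cCMT2"}]
        )
        pooled = frequency_table(tes, fasta, mode="pooled")
        mean = frequency_table(tes, fasta, mode="mean")
        cc_pooled = pooled[pooled["dmr_class"] == "cCMT2"].iloc[0]["CG"]
        cc_mean = mean[mean["dmr_class"] == "cCMT2"].iloc[0]["CG"]
        assert cc_pooled == pytest.approx(250 / 1200)
        assert cc_mean == pytest.approx(0.125)

    def test_te_without_sequence_skipped_with_warning(self, tmp_path):
        fasta = self._write_genome(tmp_path, {"Chr1": "ACGT" * 100})
        tes = pd.DataFrame(
            [{"chrom": "ChrMissing", "start": 0, "end": 10, "te_id": "TE0",
              "superfamily": "Gypsy", "dmr_class": "cCMT2"},
             {"chrom": "Chr1", "start": 0, "end": 100, "te_id": "TE1",
              "superfamily": "Gypsy", "dmr_class": "cCMT2"}]
        )
        with pytest.warns(UserWarning, match="skipped"):
            table = frequency_table(tes, fasta)
        assert table[table["dmr_class"] == "cCMT2"].iloc[0]["n"] == 1


class TestLTRFrequencies:
    def test_single_bin_matches_direct_count(self, tmp_path):
        rng = np.random.default_rng(13)
        seq = random_seq(rng, 2_000)
        fasta = tmp_path / "g.fa"
        write_genome_fasta({"Chr1": seq}, fasta)
        ltrs = pd.DataFrame(
            [{"chrom": "Chr1", "start": 0, "end": 500, "similarity": 90.0},
             {"chrom": "Chr1", "start": 600, "end": 1_000, "similarity": 95.0}]
        )
        out = ltr_similarity_frequencies(ltrs, fasta, [80, 100])
        assert len(out) == 1
        total = ContextCounts(0, 0, 0, 0)
        for s, e in ((0, 500), (600, 1000)):
            c = count_contexts(seq[s:e])
            total = total + c
        assert out.iloc[0]["CG"] == pytest.approx(total.frequencies["CG"])
        assert out.iloc[0]["n"] == 2

    def test_empty_bin_omitted(self, tmp_path):
        fasta = tmp_path / "g.fa"
        write_genome_fasta({"Chr1": "ACGT" * 100}, fasta)
        ltrs = pd.DataFrame(
            [{"chrom": "Chr1", "start": 0, "end": 100, "similarity": 95.0}]
        )
        out = ltr_similarity_frequencies(ltrs, fasta, [0, 50, 90, 100])
        assert list(out["bin_low"]) == [90.0]

    def test_similarity_out_of_range_raises(self, tmp_path):
        fasta = tmp_path / "g.fa"
        write_genome_fasta({"Chr1": "ACGT" * 10}, fasta)
        ltrs = pd.DataFrame(
            [{"chrom": "Chr1", "start": 0, "end": 10, "similarity": 120.0}]
        )
        with pytest.raises(ValueError):
            ltr_similarity_frequencies(ltrs, fasta, [0, 100])
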