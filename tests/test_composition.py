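"""Composition module: counting, frequencies, DL background, X vectors."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import dlphylo as dl
from dlphylo.errors import (
    DegenerateProfileError,
    InvalidParameterError,
    RecordTooShortError,
)

from conftest import dense_dl_vector, naive_count_kmers, random_record


class TestCountKmers:
    def test_mama_counts(self, mama):
        c = dl.count_kmers(mama, 2)
        assert c.counts == {"MA": 2, "AM": 1}
        assert c.valid_windows == 3

    def test_single_symbols(self):
        rec = dl.GenomeRecord("r", ("ACGT",), dl.DNA)
        c = dl.count_kmers(rec, 1)
        assert c.counts == {"A": 1, "C": 1, "G": 1, "T": 1}
        assert c.valid_windows == 4

    def test_ambiguity_windows_dropped(self):
        rec = dl.GenomeRecord("r", ("AANA",), dl.DNA)
        c = dl.count_kmers(rec, 2)
        assert c.counts == {"AA": 1}
        assert c.valid_windows == 1

    def test_multi_gene_pooling(self):
        rec = dl.GenomeRecord("r", ("AAA", "AA"), dl.DNA)
        c = dl.count_kmers(rec, 2)
        assert c.counts == {"AA": 3}
        assert c.valid_windows == 3  # per-gene windows 2 and 1, pooled

    def test_case_insensitive(self):
        lo = dl.GenomeRecord("r", ("acgtacgt",), dl.DNA)
        up = dl.GenomeRecord("r", ("ACGTACGT",), dl.DNA)
        assert dl.count_kmers(lo, 3).counts == dl.count_kmers(up, 3).counts

    def test_short_sequence_contributes_nothing(self):
        rec = dl.GenomeRecord("r", ("AC", "ACGTACGT"), dl.DNA)
        only_long = dl.GenomeRecord("r", ("ACGTACGT",), dl.DNA)
        assert dl.count_kmers(rec, 4).counts == dl.count_kmers(only_long, 4).counts

    def test_record_too_short_rejected(self):
        rec = dl.GenomeRecord("r", ("ACG",), dl.DNA)
        with pytest.raises(RecordTooShortError, match="too short"):
            dl.count_kmers(rec, 5)

    def test_invalid_k(self, mama):
        with pytest.raises(InvalidParameterError):
            dl.count_kmers(mama, 0)

    @pytest.mark.parametrize("alphabet", [dl.DNA, dl.PROTEIN], ids=["dna", "protein"])
    def test_matches_naive_oracle(self, alphabet):
        """200 random strings (length <= 50, k <= 5): exact oracle agreement."""
        rng = np.random.default_rng(7)
        extra = "NX-*"  # ambiguity characters sprinkled in
        for trial in range(200):
            k = int(rng.integers(1, 6))
            length = int(rng.integers(k, 51))
            pool = list(alphabet.symbols) + list(extra)
            seq = "".join(rng.choice(pool, size=length))
            rec = dl.GenomeRecord("r", (seq,), alphabet)
            expected, windows = naive_count_kmers((seq,), k, alphabet)
            got = dl.count_kmers(rec, k)
            assert got.counts == expected
            assert got.valid_windows == windows

    @settings(max_examples=50, derandomize=True, deadline=None)
    @given(
        seq=st.text(alphabet="ACGTn-", min_size=3, max_size=40),
        k=st.integers(min_value=1, max_value=3),
    )
    def test_counts_sum_to_windows(self, seq, k):
        """Invariant: counts always sum to the valid-window total."""
        rec = dl.GenomeRecord("r", (seq,), dl.DNA)
        try:
            c = dl.count_kmers(rec, k)
        except RecordTooShortError:
            return
        assert int(c.values.sum()) == c.valid_windows


class TestFrequencyProfile:
    def test_mama_frequencies(self, mama):
        p = dl.frequency_profile(dl.count_kmers(mama, 2))
        assert p.freqs["MA"] == pytest.approx(2 / 3, abs=1e-15)
        assert p.freqs["AM"] == pytest.approx(1 / 3, abs=1e-15)

    def test_pooled_two_genes(self):
        rec = dl.GenomeRecord("r", ("AAA", "AA"), dl.DNA)
        p = dl.frequency_profile(dl.count_kmers(rec, 2))
        assert p.freqs == {"AA": 1.0}

    def test_degenerate_profile_signal(self):
        rec = dl.GenomeRecord("r", ("NNNN",), dl.DNA)
        with pytest.raises(DegenerateProfileError):
            dl.frequency_profile(dl.count_kmers(rec, 2))

    @pytest.mark.parametrize("alphabet", [dl.DNA, dl.PROTEIN], ids=["dna", "protein"])
    def test_sums_to_one(self, rng, alphabet):
        for _ in range(20):
            rec = random_record(rng, alphabet, n_seqs=int(rng.integers(1, 4)))
            p = dl.frequency_profile(dl.count_kmers(rec, 3))
            assert p.total() == pytest.approx(1.0, abs=1e-12)
            assert np.all(p.values > 0)


class TestExpectedProfile:
    def test_mama_background(self, mama):
        p1 = dl.frequency_profile(dl.count_kmers(mama, 1))
        q = dl.expected_profile(p1, p1)
        assert q.freqs == pytest.approx(
            {"MA": 0.25, "AM": 0.25, "AA": 0.25, "MM": 0.25}, abs=1e-15
        )

    def test_mismatched_k_rejected(self, mama):
        p2 = dl.frequency_profile(dl.count_kmers(mama, 2))
        with pytest.raises(InvalidParameterError):
            dl.expected_profile(p2, p2)  # second argument must be a letter profile

    def test_sums_to_one(self, rng):
        for _ in range(20):
            rec = random_record(rng, dl.PROTEIN, n_seqs=2)
            p2 = dl.frequency_profile(dl.count_kmers(rec, 2))
            p1 = dl.frequency_profile(dl.count_kmers(rec, 1))
            q = dl.expected_profile(p2, p1)
            assert q.total() == pytest.approx(1.0, abs=1e-12)

    def test_iid_uniform_limit(self):
        """For long i.i.d. uniform DNA, q(s) -> 4^-3 for every 3-mer."""
        rng = np.random.default_rng(123)
        seq = "".join(rng.choice(list("ACGT"), size=10**6))
        rec = dl.GenomeRecord("r", (seq,), dl.DNA)
        p2 = dl.frequency_profile(dl.count_kmers(rec, 2))
        p1 = dl.frequency_profile(dl.count_kmers(rec, 1))
        q = dl.expected_profile(p2, p1)
        vals = np.array(list(q.freqs.values()))
        assert vals.size == 64
        # q is a product of two near-uniform estimates; 3 SE of a 2-mer
        # frequency at L=1e6 is ~2.4e-4, propagated ~6e-5 on q
        assert np.allclose(vals, 4.0**-3, atol=1e-4)


class TestCompositionVector:
    def test_mama_worked_example(self, mama):
        x = dl.dl_vector(mama, 2).entries
        assert x["MA"] == pytest.approx(5 / 3, abs=1e-12)
        assert x["AM"] == pytest.approx(1 / 3, abs=1e-12)
        assert x["AA"] == -1.0
        assert x["MM"] == -1.0

    def test_identity_case_x_zero(self):
        """p == q on the support (i.i.d.-like single-letter run) gives X == 0."""
        rec = dl.GenomeRecord("r", ("AAAAAAAA",), dl.DNA)
        v = dl.dl_vector(rec, 2)
        assert v.entries == {"AA": 0.0}

    def test_component_space_size(self):
        rec = dl.GenomeRecord("r", ("ACDEFGHIKL" * 3,), dl.PROTEIN)
        v = dl.dl_vector(rec, 5)
        assert v.n_total == 20**5

    def test_k_below_two_rejected(self, mama):
        with pytest.raises(InvalidParameterError):
            dl.dl_vector(mama, 1)

    @pytest.mark.parametrize("alphabet", [dl.DNA, dl.PROTEIN], ids=["dna", "protein"])
    def test_conservation_identities(self, rng, alphabet):
        """Sum p = 1, sum q = 1 and sum q_i X_i = 0 on random records."""
        for _ in range(50):
            rec = random_record(rng, alphabet, n_seqs=int(rng.integers(1, 4)))
            k = int(rng.integers(2, 5))
            p_k = dl.frequency_profile(dl.count_kmers(rec, k))
            p_km1 = dl.frequency_profile(dl.count_kmers(rec, k - 1))
            p_1 = dl.frequency_profile(dl.count_kmers(rec, 1))
            q = dl.expected_profile(p_km1, p_1)
            v = dl.composition_vector(p_k, q, rec.taxon_id)
            assert p_k.total() == pytest.approx(1.0, abs=1e-12)
            assert q.total() == pytest.approx(1.0, abs=1e-12)
            assert float(np.dot(q.values, v.values)) == pytest.approx(0.0, abs=1e-10)
            assert np.all(v.values >= -1.0)

    def test_x_minus_one_iff_unobserved(self, rng):
        rec = random_record(rng, dl.DNA, min_len=30, max_len=40)
        v = dl.dl_vector(rec, 3)
        p = dl.frequency_profile(dl.count_kmers(rec, 3))
        observed = set(p.freqs)
        for mer, x in v.entries.items():
            assert (x == -1.0) == (mer not in observed)

    def test_matches_dense_oracle(self, rng):
        """Sparse X equals the dense dictionary-and-loop oracle at DNA k=3."""
        for _ in range(10):
            rec = random_record(rng, dl.DNA, min_len=50, max_len=120)
            v = dl.dl_vector(rec, 3)
            dense = np.zeros(64)
            # decode sparse into dense component order
            dense[v.codes] = v.values
            np.testing.assert_allclose(dense, dense_dl_vector(rec, 3), atol=1e-13)

    def test_tsv_export_roundtrip_values(self, mama):
        tsv = dl.dl_vector(mama, 2).to_tsv()
        rows = dict(line.split("\t") for line in tsv.strip().splitlines())
        assert float(rows["MA"]) == pytest.approx(5 / 3, abs=1e-12)
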