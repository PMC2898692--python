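"""Distance module: sparse correlation/chord algebra, matrices, PHYLIP I/O."""

import numpy as np
import pytest

import dlphylo as dl
from dlphylo.errors import (
    DuplicateTaxonError,
    InvalidParameterError,
    PhylipFormatError,
    UndefinedCorrelationError,
    UndefinedDistanceError,
)

from conftest import dense_chord, dense_dl_vector, dense_pearson, random_record


def _dense(v):
    out = np.zeros(v.n_total)
    out[v.codes] = v.values
    return out


class TestPairwise:
    def test_self_correlation_is_one(self, mama):
        v = dl.dl_vector(mama, 2)
        assert dl.pearson_correlation(v, v) == pytest.approx(1.0, abs=1e-12)
        assert dl.correlation_distance(v, v) == 0.0
        assert dl.chord_distance(v, v) == 0.0

    def test_negated_vector(self, mama):
        v = dl.dl_vector(mama, 2)
        neg = dl.CompositionVector(
            "neg", v.k, v.alphabet, v.codes, -v.values, v.n_total
        )
        assert dl.pearson_correlation(v, neg) == pytest.approx(-1.0, abs=1e-12)
        assert dl.correlation_distance(v, neg) == pytest.approx(1.0, abs=1e-12)
        assert dl.chord_distance(v, neg) == pytest.approx(2.0, abs=1e-12)

    def test_mama_vs_amam_matches_dense(self):
        a = dl.dl_vector(dl.GenomeRecord("a", ("MAMA",), dl.PROTEIN), 2)
        b = dl.dl_vector(dl.GenomeRecord("b", ("AMAM",), dl.PROTEIN), 2)
        d_sparse = dl.correlation_distance(a, b)
        d_dense = (1 - dense_pearson(_dense(a), _dense(b))) / 2
        assert d_sparse == pytest.approx(d_dense, abs=1e-15)
        assert d_sparse == pytest.approx(2 / 11, abs=1e-12)  # C = 7/11 by hand

    def test_sparse_equals_dense_oracle_50_pairs(self, rng):
        """Core correctness: full-N sparse algebra == dense numpy at DNA k=3."""
        for _ in range(50):
            ra = random_record(rng, dl.DNA, "a", min_len=60, max_len=150)
            rb = random_record(rng, dl.DNA, "b", min_len=60, max_len=150)
            va, vb = dl.dl_vector(ra, 3), dl.dl_vector(rb, 3)
            da, db = dense_dl_vector(ra, 3), dense_dl_vector(rb, 3)
            assert dl.pearson_correlation(va, vb) == pytest.approx(
                dense_pearson(da, db), abs=1e-12
            )
            assert dl.chord_distance(va, vb) == pytest.approx(
                dense_chord(da, db), abs=1e-12
            )

    def test_bounds_and_symmetry(self, rng):
        for _ in range(20):
            va = dl.dl_vector(random_record(rng, dl.PROTEIN, "a", n_seqs=2), 3)
            vb = dl.dl_vector(random_record(rng, dl.PROTEIN, "b", n_seqs=2), 3)
            dc = dl.correlation_distance(va, vb)
            ch = dl.chord_distance(va, vb)
            assert 0.0 <= dc <= 1.0
            assert 0.0 <= ch <= 2.0
            assert dc == pytest.approx(dl.correlation_distance(vb, va), abs=1e-12)
            assert ch == pytest.approx(dl.chord_distance(vb, va), abs=1e-12)

    def test_chord_triangle_inequality(self, rng):
        for _ in range(200):
            vs = [
                dl.dl_vector(random_record(rng, dl.DNA, t, min_len=40, max_len=100), 3)
                for t in "abc"
            ]
            dab = dl.chord_distance(vs[0], vs[1])
            dbc = dl.chord_distance(vs[1], vs[2])
            dac = dl.chord_distance(vs[0], vs[2])
            assert dac <= dab + dbc + 1e-9

    def test_zero_variance_signals(self):
        # constant-zero vector: single-letter run has X == 0 everywhere
        rec = dl.GenomeRecord("z", ("AAAAAAAA",), dl.DNA)
        vz = dl.dl_vector(rec, 2)
        v = dl.dl_vector(dl.GenomeRecord("m", ("MAMA",), dl.PROTEIN), 2)
        vz = dl.CompositionVector("z", 2, dl.PROTEIN, vz.codes, vz.values, 400)
        with pytest.raises(UndefinedCorrelationError):
            dl.pearson_correlation(v, vz)
        with pytest.raises(UndefinedDistanceError):
            dl.chord_distance(v, vz)

    def test_incompatible_vectors_rejected(self, mama):
        v2 = dl.dl_vector(mama, 2)
        v3 = dl.dl_vector(mama, 3)
        with pytest.raises(InvalidParameterError):
            dl.pearson_correlation(v2, v3)

    def test_uncentered_flag(self, mama):
        """centered=False substitutes the cosine kernel for Pearson."""
        a = dl.dl_vector(dl.GenomeRecord("a", ("MAMA",), dl.PROTEIN), 2)
        b = dl.dl_vector(dl.GenomeRecord("b", ("AMAM",), dl.PROTEIN), 2)
        expected = (1 - dl.cosine_similarity(a, b)) / 2
        assert dl.correlation_distance(a, b, centered=False) == pytest.approx(expected)


class TestDistanceMatrix:
    def test_identical_records_zero_offdiag(self):
        recs = [
            dl.GenomeRecord(t, ("ACGTACGTAAGG",), dl.DNA) for t in ("x", "y", "z")
        ]
        dm = dl.distance_matrix(recs, 3)
        assert np.allclose(dm.values, 0.0, atol=1e-12)

    def test_permutation_equivariance(self, dna_records):
        dm = dl.distance_matrix(dna_records, 3)
        perm = [dna_records[i] for i in (2, 0, 1)]
        dm_p = dl.distance_matrix(perm, 3)
        assert dm_p.labels == ("g2", "g0", "g1")
        np.testing.assert_allclose(
            dm_p.values, dm.reordered(dm_p.labels).values, atol=0
        )

    def test_equals_pairwise_recomputation(self, dna_records):
        vs = [dl.dl_vector(r, 3) for r in dna_records]
        for method, fn in (
            ("correlation", dl.correlation_distance),
            ("chord", dl.chord_distance),
        ):
            dm = dl.distance_matrix(dna_records, 3, method)
            for i in range(3):
                for j in range(3):
                    expected = 0.0 if i == j else fn(vs[i], vs[j])
                    assert dm.values[i, j] == expected  # bitwise: same code path

    def test_duplicate_taxa_rejected(self, dna_records):
        recs = dna_records + [dna_records[0]]
        with pytest.raises(DuplicateTaxonError, match="g0"):
            dl.distance_matrix(recs, 3)

    def test_too_few_records(self, dna_records):
        with pytest.raises(InvalidParameterError):
            dl.distance_matrix(dna_records[:2], 3)

    def test_matrix_contracts(self, dna_records):
        for method, hi in (("correlation", 1.0), ("chord", 2.0)):
            dm = dl.distance_matrix(dna_records, 3, method)
            assert np.allclose(dm.values, dm.values.T, atol=1e-12)
            assert np.all(np.diag(dm.values) == 0)
            assert np.all(dm.values >= 0) and np.all(dm.values <= hi)


class TestPhylipIO:
    def test_roundtrip(self, dna_records):
        dm = dl.distance_matrix(dna_records, 3)
        back = dl.read_phylip(dl.write_phylip(dm))
        assert back.labels == dm.labels
        np.testing.assert_allclose(back.values, dm.values, atol=1e-6)

    def test_header_and_shape(self, dna_records):
        text = dl.write_phylip(dl.distance_matrix(dna_records, 3))
        lines = text.strip().splitlines()
        assert lines[0].strip() == "3"
        assert len(lines) == 4

    def test_padded_dialect(self, dna_records):
        text = dl.write_phylip(dl.distance_matrix(dna_records, 3), pad_names=True)
        body = text.splitlines()[1]
        assert body[:10].rstrip() == "g0"

    @pytest.mark.parametrize(
        "bad",
        [
            "3\na 0 1\nb 1 0\n",  # 3-header with 2 rows
            "notanumber\na 0\n",  # malformed header
            "2\na 0.0 0.1 0.3\nb 0.1 0.0 0.2\n",  # non-square body
            "",  # empty
        ],
    )
    def test_malformed_rejected(self, bad):
        with pytest.raises(PhylipFormatError):
            dl.read_phylip(bad)
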