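"""Feature encoder unit and property tests.

Hand-computed oracles for the small worked examples; seeded random
sequences for the sum-to-one and reduction-consistency invariants.
"""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from druggability.alphabets import (
    ALL_SCHEMES,
    CANONICAL_RESIDUES,
    GDPC_SCHEME,
    RAAA_SCHEMES,
    standardized_properties,
)
from druggability.encoders import (
    EncoderSpec,
    PseAACParams,
    SegmentationScheme,
    aac,
    encode_dataset,
    gdpc,
    pseaac,
    raaa,
    reduce_sequence,
    s_pseaac,
    theta_correlations,
)

sequences = st.text(alphabet=CANONICAL_RESIDUES, min_size=2, max_size=80)


def vec(fv):
    return dict(zip(fv.names, fv.values))


class TestSchemes:
    def test_every_scheme_partitions_the_alphabet(self):
        # construction would have raised otherwise; assert the structure anyway
        for scheme in ALL_SCHEMES:
            residues = [r for g in scheme.groups for r in g]
            assert sorted(residues) == sorted(CANONICAL_RESIDUES)

    def test_cluster_counts_match_scheme_names(self):
        assert {k: s.n_groups for k, s in RAAA_SCHEMES.items()} == {
            5: 5, 8: 8, 9: 9, 11: 11, 13: 13
        }

    def test_property_table_standardized(self):
        props = standardized_properties()
        assert props.shape == (3, 20)
        assert np.allclose(props.mean(axis=1), 0, atol=1e-9)
        assert np.allclose(props.std(axis=1), 1, atol=1e-9)


class TestAAC:
    @pytest.mark.parametrize(
        "seq,expected",
        [
            ("AAAA", {"A": 1.0}),
            ("ACAC", {"A": 0.5, "C": 0.5}),
            ("MKVMK", {"M": 0.4, "K": 0.4, "V": 0.2}),
        ],
    )
    def test_hand_counts(self, seq, expected):
        got = vec(aac(seq))
        for r in CANONICAL_RESIDUES:
            assert got[f"AAC|{r}"] == pytest.approx(expected.get(r, 0.0))

    def test_empty_sequence_rejected(self):
        with pytest.raises(ValueError):
            aac("")

    def test_shuffle_invariance(self):
        rng = np.random.default_rng(3)
        seq = "MKVLWQRACDEF"
        shuffled = "".join(rng.permutation(list(seq)))
        assert np.allclose(aac(seq).values, aac(shuffled).values)


class TestGDPC:
    def test_single_dipeptide_homogroup(self):
        got = vec(gdpc("AA"))
        assert got["GDPC|aliphatic>aliphatic"] == 1.0
        assert vec(gdpc("WY"))["GDPC|aromatic>aromatic"] == 1.0

    def test_two_dipeptides_hand_enumerated(self):
        got = vec(gdpc("WKA"))
        assert got["GDPC|aromatic>positive"] == pytest.approx(0.5)
        assert got["GDPC|positive>aliphatic"] == pytest.approx(0.5)
        assert sum(got.values()) == pytest.approx(1.0)

    def test_length_one_rejected(self):
        with pytest.raises(ValueError, match="dipeptide"):
            gdpc("A")

    def test_dimension(self):
        assert len(gdpc("MKVLWQR")) == 25

    @settings(max_examples=200, derandomize=True)
    @given(seq=sequences)
    def test_matches_reduced_pair_counting_oracle(self, seq):
        """gdpc must equal counting adjacent pairs on the 5-group
        reduced sequence (independent route via reduce_sequence)."""
        reduced = reduce_sequence(seq, GDPC_SCHEME)
        counts = np.zeros((5, 5))
        for a, b in zip(reduced, reduced[1:]):
            counts[a - 1, b - 1] += 1
        assert np.allclose(gdpc(seq).values, counts.ravel() / (len(seq) - 1))


class TestReduceSequence:
    def test_c5_mapping(self):
        assert reduce_sequence("GIVP", RAAA_SCHEMES[5]) == [1, 2, 2, 4]

    def test_c13_single_residue(self):
        assert reduce_sequence("G", RAAA_SCHEMES[13]) == [1]

    def test_c8_places_cysteine_in_last_cluster(self):
        assert reduce_sequence("CC", RAAA_SCHEMES[8]) == [8, 8]

    def test_length_preserved(self):
        seq = "MKVLWQRACDEF"
        for scheme in RAAA_SCHEMES.values():
            assert len(reduce_sequence(seq, scheme)) == len(seq)


class TestRAAA:
    def test_dimension_is_506(self):
        assert len(raaa("MKVLWQR")) == 506
        assert sum(k + k * k for k in (5, 8, 9, 11, 13)) == 506

    def test_homopolymer_concentrates_mass(self):
        got = vec(raaa("GG"))
        for k in RAAA_SCHEMES:
            assert got[f"RAAA|C{k}|comp|1"] == 1.0  # G is cluster 1 everywhere
            assert got[f"RAAA|C{k}|dp|1>1"] == 1.0

    def test_gp_under_c5(self):
        got = vec(raaa("GP"))
        assert got["RAAA|C5|comp|1"] == pytest.approx(0.5)
        assert got["RAAA|C5|comp|4"] == pytest.approx(0.5)
        assert got["RAAA|C5|dp|1>4"] == 1.0

    @settings(max_examples=100, derandomize=True)
    @given(seq=sequences)
    def test_each_block_sums_to_one(self, seq):
        got = vec(raaa(seq))
        for k in RAAA_SCHEMES:
            comp = sum(v for n, v in got.items() if n.startswith(f"RAAA|C{k}|comp|"))
            dp = sum(v for n, v in got.items() if n.startswith(f"RAAA|C{k}|dp|"))
            assert comp == pytest.approx(1.0, abs=1e-9)
            assert dp == pytest.approx(1.0, abs=1e-9)


def theta_oracle(seq: str, lam: int) -> np.ndarray:
    """Brute-force correlation factors straight from the raw property
    table, standardizing by hand."""
    from druggability.alphabets import _RAW_PROPERTIES

    tables = []
    for prop in _RAW_PROPERTIES.values():
        vals = np.array([prop[r] for r in CANONICAL_RESIDUES])
        std = (vals - vals.mean()) / vals.std()
        tables.append(dict(zip(CANONICAL_RESIDUES, std)))

    def big_theta(a, b):
        return np.mean([(t[a] - t[b]) ** 2 for t in tables])

    out = []
    for j in range(1, lam + 1):
        pairs = [(seq[i], seq[i + j]) for i in range(len(seq) - j)]
        out.append(np.mean([big_theta(a, b) for a, b in pairs]))
    return np.array(out)


class TestPseAAC:
    def test_homopolymer_thetas_vanish(self):
        assert np.allclose(theta_correlations("AAAAAA", PseAACParams(lam=2)), 0)

    def test_lam_zero_gives_empty_thetas_and_plain_aac(self):
        params = PseAACParams(lam=0)
        assert theta_correlations("MKVL", params).size == 0
        assert np.allclose(pseaac("MKVL", params).values, aac("MKVL").values)

    def test_alternating_sequence_matches_brute_force(self):
        params = PseAACParams(lam=1, w=0.05)
        theta = theta_correlations("ACACA", params)
        expected = theta_oracle("ACACA", 1)
        assert np.allclose(theta, expected)
        # every adjacent pair is (A,C) or (C,A): one constant value
        fv = pseaac("ACACA", params)
        denom = 1 + 0.05 * expected[0]
        got = vec(fv)
        assert got["PseAAC|aac|A"] == pytest.approx(0.6 / denom)
        assert got["PseAAC|aac|C"] == pytest.approx(0.4 / denom)
        assert got["PseAAC|lam1"] == pytest.approx(0.05 * expected[0] / denom)
        assert fv.values.sum() == pytest.approx(1.0, abs=1e-12)

    def test_sequence_shorter_than_lambda_rejected(self):
        with pytest.raises(ValueError, match="lambda"):
            theta_correlations("MK", PseAACParams(lam=5))

    @settings(max_examples=100, derandomize=True)
    @given(seq=st.text(alphabet=CANONICAL_RESIDUES, min_size=6, max_size=60))
    def test_sums_to_one_and_thetas_nonnegative(self, seq):
        params = PseAACParams(lam=5)
        assert (theta_correlations(seq, params) >= 0).all()
        assert pseaac(seq, params).values.sum() == pytest.approx(1.0, abs=1e-9)


class TestSegmentation:
    def test_boundaries_cover_without_overlap(self):
        seq = "MKVLWQR"  # length 7, two segments: floor(7/2)=3
        seg = SegmentationScheme(n_seg=2)
        assert seg.segments(seq) == ["MKV", "LWQR"]

    def test_even_split(self):
        assert SegmentationScheme(n_seg=2).segments("AAAACCCC") == ["AAAA", "CCCC"]

    @settings(max_examples=100, derandomize=True)
    @given(
        seq=st.text(alphabet=CANONICAL_RESIDUES, min_size=4, max_size=100),
        n_seg=st.integers(min_value=1, max_value=4),
    )
    def test_segments_reassemble_to_sequence(self, seq, n_seg):
        if len(seq) < n_seg:
            return
        parts = SegmentationScheme(n_seg=n_seg).segments(seq)
        assert "".join(parts) == seq
        assert all(parts)


class TestSPseAAC:
    def test_single_segment_equals_pseaac(self):
        params = PseAACParams(lam=3)
        whole = pseaac("MKVLWQRACDEF", params)
        seg = s_pseaac("MKVLWQRACDEF", params, SegmentationScheme(n_seg=1))
        assert np.allclose(seg.values, whole.values)

    def test_two_segments_localize_composition(self):
        fv = s_pseaac("AAAACCCC", PseAACParams(lam=0), SegmentationScheme(n_seg=2))
        got = vec(fv)
        assert got["SPseAAC|seg1|aac|A"] == 1.0
        assert got["SPseAAC|seg2|aac|C"] == 1.0

    def test_dimension(self):
        fv = s_pseaac("M" * 40, PseAACParams(lam=5), SegmentationScheme(n_seg=2))
        assert len(fv) == 2 * (20 + 5)

    def test_short_segment_rejected_with_segment_named(self):
        with pytest.raises(ValueError, match="segment"):
            s_pseaac("MKVLWQ", PseAACParams(lam=3), SegmentationScheme(n_seg=2))


class TestEncodeDataset:
    def test_block_widths(self, tiny_dataset):
        fm = encode_dataset(tiny_dataset, [EncoderSpec.make("gdpc")])
        assert fm.shape == (5, 25)
        fm = encode_dataset(
            tiny_dataset, [EncoderSpec.make("gdpc"), EncoderSpec.make("raaa")]
        )
        assert fm.shape == (5, 531)
        fm = encode_dataset(
            tiny_dataset,
            [
                EncoderSpec.make("gdpc"),
                EncoderSpec.make("raaa"),
                EncoderSpec.make("s_pseaac", lam=5, n_seg=2),
            ],
        )
        assert fm.shape == (5, 581)
        assert len(set(fm.feature_names)) == 581

    def test_labels_carried_through(self, tiny_dataset):
        fm = encode_dataset(tiny_dataset, [EncoderSpec.make("aac")])
        assert list(fm.labels) == [1, 1, 1, 0, 0]

    def test_encoder_error_names_the_record(self, tiny_dataset):
        tiny_dataset.records[2] = type(tiny_dataset.records[2])("pos3", "MK")
        with pytest.raises(ValueError, match="pos3"):
            encode_dataset(tiny_dataset, [EncoderSpec.make("s_pseaac", lam=5)])

    def test_determinism(self, tiny_dataset):
        a = encode_dataset(tiny_dataset, [EncoderSpec.make("raaa")])
        b = encode_dataset(tiny_dataset, [EncoderSpec.make("raaa")])
        assert (a.X.to_numpy() == b.X.to_numpy()).all()
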