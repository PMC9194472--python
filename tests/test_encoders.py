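import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import _oracles as oracle
from glutarkit.encoders import (
    CTD_ATTRIBUTES, BlockSpec, EncoderSpec, FeatureVector, concat_features,
    encode_aac, encode_apaac, encode_ctdc, encode_ctdd, encode_ctdt,
    encode_eaac, encode_paac, encode_peptide,
)
from glutarkit.peptide_io import ALPHABET, Peptide

from conftest import random_sequences

peptide_text = st.text(alphabet=ALPHABET + "X", min_size=2, max_size=23).filter(
    lambda s: len(s.replace("X", "")) >= 2)


class TestAAC:
    def test_direct_counting(self):
        fv = encode_aac("AKAKA")
        d = dict(zip(fv.names, fv.values))
        assert d["aac.A"] == pytest.approx(0.6)
        assert d["aac.K"] == pytest.approx(0.4)
        assert sum(v for k, v in d.items() if k not in ("aac.A", "aac.K")) == 0

    def test_x_excluded_from_both_counts(self):
        fv = encode_aac("XXAXX")
        assert dict(zip(fv.names, fv.values))["aac.A"] == 1.0

    def test_all_x_raises(self):
        with pytest.raises(ValueError, match="all 'X'"):
            encode_aac("XXXX")

    @settings(deadline=None, derandomize=True)
    @given(peptide_text)
    def test_sums_to_one(self, seq):
        assert encode_aac(seq).values.sum() == pytest.approx(1.0, abs=1e-9)


class TestEAAC:
    def test_width_formula_on_23mer(self, window23):
        assert len(encode_eaac(window23, window=5)) == 19 * 20

    def test_window_block_counting(self):
        fv = encode_eaac("AAAKK", window=5)
        d = dict(zip(fv.names, fv.values))
        assert d["eaac.w1.A"] == pytest.approx(0.6)
        assert d["eaac.w1.K"] == pytest.approx(0.4)

    def test_homopolymer_every_window_pure(self):
        fv = encode_eaac("K" * 23)
        mat = fv.values.reshape(19, 20)
        k_col = ALPHABET.index("K")
        assert (mat[:, k_col] == 1.0).all()
        assert mat.sum() == pytest.approx(19.0)

    def test_all_x_window_yields_zeros(self):
        fv = encode_eaac("XXXXXAK", window=5)
        assert fv.values[:20].sum() == 0.0

    @pytest.mark.parametrize("window", [0, 24])
    def test_invalid_window_raises(self, window23, window):
        with pytest.raises(ValueError, match="window"):
            encode_eaac(window23, window=window)

    @settings(deadline=None, derandomize=True)
    @given(peptide_text, st.integers(min_value=1, max_value=5))
    def test_each_nonempty_window_sums_to_one(self, seq, window):
        if window > len(seq):
            return
        mat = encode_eaac(seq, window=window).values.reshape(-1, 20)
        for start, row in enumerate(mat):
            has_residue = any(c != "X" for c in seq[start:start + window])
            assert row.sum() == pytest.approx(1.0 if has_residue else 0.0, abs=1e-9)


class TestCTD:
    def test_property_table_partitions_alphabet(self):
        for attr, groups in CTD_ATTRIBUTES.items():
            assert sorted("".join(groups)) == sorted(ALPHABET), attr

    def test_ctdc_homopolymer_hits_single_group(self):
        fv = encode_ctdc("A" * 23)
        d = dict(zip(fv.names, fv.values))
        assert d["ctdc.Hydrophobicity_PRAM900101.g1"] == 0.0
        assert d["ctdc.Hydrophobicity_PRAM900101.g2"] == 1.0  # A is neutral
        assert d["ctdc.Hydrophobicity_PRAM900101.g3"] == 0.0

    def test_ctdc_each_attribute_sums_to_one(self, window23):
        mat = encode_ctdc(window23).values.reshape(13, 3)
        np.testing.assert_allclose(mat.sum(axis=1), 1.0, atol=1e-9)

    def test_ctdt_homopolymer_is_all_zero(self):
        assert encode_ctdt("A" * 23).values.sum() == 0.0

    def test_ctdt_single_transition(self):
        # R polar, A neutral under PRAM900101: one switch over N-1 = 1 pair
        fv = encode_ctdt("RA")
        d = dict(zip(fv.names, fv.values))
        assert d["ctdt.Hydrophobicity_PRAM900101.g12"] == 1.0

    def test_ctdt_values_bounded(self, rng):
        for seq in random_sequences(rng, 20):
            v = encode_ctdt(seq).values
            assert ((v >= 0) & (v <= 1)).all()

    def test_ctdd_single_occurrence_all_five_equal(self):
        fv = encode_ctdd("R" + "A" * 22)
        d = dict(zip(fv.names, fv.values))
        for q in ("first", "q25", "q50", "q75", "q100"):
            assert d[f"ctdd.Hydrophobicity_PRAM900101.g1.{q}"] == pytest.approx(1 / 23)

    def test_ctdd_absent_group_is_five_zeros(self):
        fv = encode_ctdd("A" * 23)
        d = dict(zip(fv.names, fv.values))
        assert all(d[f"ctdd.Hydrophobicity_PRAM900101.g1.{q}"] == 0.0
                   for q in ("first", "q25", "q50", "q75", "q100"))

    def test_widths(self, window23):
        assert len(encode_ctdc(window23)) == 39
        assert len(encode_ctdt(window23)) == 39
        assert len(encode_ctdd(window23)) == 195


class TestOracleEquivalence:
    """Package encoders vs naive loop-based recounting, X-salted inputs."""

    @pytest.mark.parametrize("encode,ref", [
        (encode_aac, oracle.aac_oracle),
        (encode_eaac, oracle.eaac_oracle),
        (encode_ctdc, oracle.ctdc_oracle),
        (encode_ctdt, oracle.ctdt_oracle),
        (encode_ctdd, oracle.ctdd_oracle),
    ], ids=["aac", "eaac", "ctdc", "ctdt", "ctdd"])
    def test_counting_encoders_match_brute_force(self, rng, encode, ref):
        for seq in random_sequences(rng, 50, min_len=5, max_len=23):
            got = encode(seq).values
            want = np.array(ref(seq))
            assert np.abs(got - want).max() < 1e-12

    @pytest.mark.parametrize("encode,ref", [
        (encode_paac, oracle.paac_oracle),
        (encode_apaac, oracle.apaac_oracle),
    ], ids=["paac", "apaac"])
    def test_pseudo_composition_matches_brute_force(self, rng, encode, ref):
        for seq in random_sequences(rng, 30, min_len=6, max_len=23):
            lam = min(4, len(seq.replace("X", "")) - 1)
            got = encode(seq, lam=lam).values
            want = np.array(ref(seq, lam=lam))
            assert np.abs(got - want).max() < 1e-10


class TestPAAC:
    def test_width(self, window23):
        assert len(encode_paac(window23, lam=15)) == 35
        assert len(encode_apaac(window23, lam=15)) == 50

    def test_sums_to_one(self, window23):
        assert encode_paac(window23).values.sum() == pytest.approx(1.0, abs=1e-9)
        assert encode_apaac(window23).values.sum() == pytest.approx(1.0, abs=1e-9)

    def test_lam_zero_reduces_to_aac(self, window23):
        np.testing.assert_allclose(encode_paac(window23, lam=0).values,
                                   encode_aac(window23).values, atol=1e-12)

    def test_weight_zero_first_20_equal_aac(self, window23):
        np.testing.assert_allclose(encode_paac(window23, weight=0.0).values[:20],
                                   encode_aac(window23).values, atol=1e-12)

    def test_lam_too_large_raises(self, window23):
        with pytest.raises(ValueError, match="lambda"):
            encode_paac(window23, lam=23)
        with pytest.raises(ValueError, match="lambda"):
            encode_paac(window23, lam=-1)

    def test_apaac_homopolymer_odd_taus_constant(self):
        # all H1 products equal h1(A)^2, so every hydrophobicity tau is equal
        fv = encode_apaac("A" * 23, lam=5)
        odd = [v for n, v in zip(fv.names, fv.values) if n.endswith(".h1")]
        np.testing.assert_allclose(odd, odd[0])

    def test_metadata_invariance(self, window23):
        relabeled = Peptide(window23.sequence, label=0, center_index=11,
                            source_id="other")
        for enc in (encode_aac, encode_eaac, encode_ctdc, encode_ctdt,
                    encode_ctdd, encode_paac, encode_apaac):
            np.testing.assert_array_equal(enc(window23).values,
                                          enc(relabeled).values)


class TestSpecAndConcat:
    def test_parse_with_params(self):
        spec = EncoderSpec.parse("aac+eaac:window=5+paac:lam=10")
        assert [b.name for b in spec.blocks] == ["aac", "eaac", "paac"]
        assert spec.blocks[2].params["lam"] == 10

    @pytest.mark.parametrize("L,window,lam", [(23, 5, 15), (23, 3, 7), (15, 5, 10)])
    def test_width_formulas(self, L, window, lam):
        assert BlockSpec("eaac", {"window": window}).width(L) == (L - window + 1) * 20
        assert BlockSpec("paac", {"lam": lam}).width(L) == 20 + lam
        assert BlockSpec("apaac", {"lam": lam}).width(L) == 20 + 2 * lam

    def test_aac_plus_eaac_is_400(self, window23):
        spec = EncoderSpec.parse("aac+eaac")
        fv = encode_peptide(window23, spec)
        assert len(fv) == 400
        assert fv.names[0].startswith("aac.") and fv.names[-1].startswith("eaac.")

    def test_empty_block_list_gives_empty_vector(self):
        assert len(concat_features([])) == 0

    def test_block_count_mismatch_raises(self, window23):
        spec = EncoderSpec.parse("aac+eaac")
        with pytest.raises(ValueError, match="blocks"):
            concat_features([encode_aac(window23)], spec)

    def test_unresolved_embedding_block_raises(self, window23):
        spec = EncoderSpec.parse("aac+prott5-xl-uniref50")
        with pytest.raises(ValueError, match="embedding resolver"):
            encode_peptide(window23, spec)
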