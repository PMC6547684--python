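"""The seven window encodings: printed dimensions, oracles, invariants."""

import numpy as np
import pandas as pd
import pytest

from phosforest.encoders import (
    AFC_ALPHABET,
    DEFAULT_K_VALUES,
    encode_aac,
    encode_afc,
    encode_aip,
    encode_be,
    encode_combined,
    encode_pka,
    encode_pssm,
    encode_ssf,
    load_aaindex,
    make_encoder,
    read_feature_matrix,
    standardize_aaindex,
    write_feature_matrix,
)
from phosforest.fragments import AMINO_ACIDS, PeptideFragment, extract_window
from phosforest.profiles import PSSM_ALPHABET, PSSMProfile
from phosforest.synthetic import SynthConfig, generate_pssm, generate_struct_profile
from tests.conftest import random_fragment


def _frag(window: str, protein_id: str = "p") -> PeptideFragment:
    hw = len(window) // 2
    return PeptideFragment(protein_id, hw + 1, window[hw], window, 1, hw)


@pytest.fixture(scope="module")
def toy_profiles():
    cfg = SynthConfig(seed=3)
    rng = np.random.default_rng(3)
    seq = "".join(rng.choice(list(AMINO_ACIDS), size=60))
    seq = seq[:29] + "S" + seq[30:57] + "T" + seq[58:]
    return {
        "seq": seq,
        "pssm": {"p": generate_pssm(seq, cfg, "p", rng)},
        "struct": {"p": generate_struct_profile(seq, cfg, "p", rng)},
    }


class TestDimensionContracts:
    """Each encoder's output length at W=21 equals its published dimension."""

    @pytest.mark.parametrize(
        "tag,dim",
        [
            ("aac", 20),
            ("afc", 2205),
            ("be", 420),
            ("aip", 315),
            ("ssf", 168),
            ("pssm", 420),
            ("pka", 2000),
            ("combined", 4940),
        ],
    )
    def test_dimension(self, tag, dim, toy_profiles):
        frag = extract_window(toy_profiles["seq"], 30, 10, protein_id="p")
        enc = make_encoder(
            tag,
            pssm_profiles=toy_profiles["pssm"],
            struct_profiles=toy_profiles["struct"],
        )
        enc.fit([frag])
        X = enc.transform([frag])
        assert X.shape == (1, dim)
        assert len(set(enc.get_feature_names_out())) == dim  # names unique


class TestAAC:
    def test_homopolymer(self):
        v = encode_aac(_frag("A" * 10 + "S" + "A" * 10))
        d = dict(zip(v.names, v.values))
        assert d["AAC|A"] == pytest.approx(20 / 21)
        assert d["AAC|S"] == pytest.approx(1 / 21)

    def test_pads_excluded_from_denominator(self):
        v = encode_aac(_frag("XXXXX" + "AAAAA" + "S" + "AAAAA" + "XXXXX"))
        d = dict(zip(v.names, v.values))
        assert d["AAC|A"] == pytest.approx(10 / 11)
        assert d["AAC|S"] == pytest.approx(1 / 11)

    def test_counting_oracle_and_sum(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            frag = random_fragment(rng)
            v = encode_aac(frag)
            non_pad = [c for c in frag.window if c != "X"]
            for name, val in zip(v.names, v.values):
                aa = name.split("|")[1]
                assert val == pytest.approx(non_pad.count(aa) / len(non_pad))
            assert v.values.sum() == pytest.approx(1.0)


def afc_oracle(window: str, k: int) -> dict[tuple[str, str], float]:
    """Exhaustive pair enumeration, independent of the encoder."""
    counts: dict[tuple[str, str], float] = {}
    for i in range(len(window) - k - 1):
        pair = (window[i], window[i + k + 1])
        counts[pair] = counts.get(pair, 0) + 1
    return {p: c / (len(window) - k - 1) for p, c in counts.items()}


class TestAFC:
    def test_homopolymer_k0(self):
        v = encode_afc(_frag("A" * 10 + "S" + "A" * 10))
        d = dict(zip(v.names, v.values))
        # 18 of 20 adjacent pairs are (A,A); (A,S) and (S,A) once each
        assert d["AFC|k=0|A_A"] == pytest.approx(18 / 20)
        assert d["AFC|k=0|A_S"] == pytest.approx(1 / 20)

    def test_within_k_normalization(self):
        rng = np.random.default_rng(1)
        frag = random_fragment(rng)
        v = encode_afc(frag)
        vals = v.values.reshape(len(DEFAULT_K_VALUES), 21 * 21)
        np.testing.assert_allclose(vals.sum(axis=1), 1.0)

    def test_brute_force_oracle_100_fragments(self):
        rng = np.random.default_rng(2)
        for _ in range(100):
            frag = random_fragment(rng)
            v = encode_afc(frag)
            d = dict(zip(v.names, v.values))
            for k in DEFAULT_K_VALUES:
                expected = afc_oracle(frag.window, k)
                for a in AFC_ALPHABET:
                    for b in AFC_ALPHABET:
                        assert d[f"AFC|k={k}|{a}_{b}"] == pytest.approx(
                            expected.get((a, b), 0.0)
                        )

    def test_k_too_large(self):
        with pytest.raises(ValueError):
            encode_afc(_frag("ASA"), k_values=[5])


class TestBE:
    def test_blocks_sum_to_zero_or_one_and_decode(self):
        rng = np.random.default_rng(3)
        for _ in range(30):
            frag = random_fragment(rng)
            v = encode_be(frag)
            blocks = v.values.reshape(frag.width, 20)
            decoded = []
            for i, block in enumerate(blocks):
                s = block.sum()
                assert s in (0.0, 1.0)
                decoded.append("X" if s == 0 else AMINO_ACIDS[int(block.argmax())])
            assert "".join(decoded) == frag.window


class TestAIP:
    def test_table_shape_and_standardization(self):
        table = standardize_aaindex(load_aaindex())
        assert table.shape == (15, 20)
        np.testing.assert_allclose(table.mean(axis=1), 0.0, atol=1e-12)
        np.testing.assert_allclose(table.std(axis=1, ddof=0), 1.0)

    def test_pad_positions_are_zero(self):
        v = encode_aip(_frag("XXXXXXXXXX" + "S" + "AAAAAAAAAA"))
        vals = v.values.reshape(21, 15)
        assert np.all(vals[:10] == 0)
        assert np.all(vals[10:] != 0)

    def test_single_position_perturbation_changes_15_coords(self):
        rng = np.random.default_rng(4)
        table = standardize_aaindex(load_aaindex())
        for _ in range(20):
            frag = random_fragment(rng)
            i = int(rng.integers(0, frag.width))
            if i == frag.half_width or frag.window[i] == "X":
                continue
            other = next(a for a in AMINO_ACIDS if a != frag.window[i])
            mutated = PeptideFragment(
                frag.protein_id,
                frag.center_pos,
                frag.residue,
                frag.window[:i] + other + frag.window[i + 1 :],
                frag.label,
                frag.half_width,
            )
            diff = encode_aip(frag, table).values != encode_aip(mutated, table).values
            # coordinates change exactly where the two residues' index
            # values differ (some scales assign equal values to both)
            expected = int((table[frag.window[i]] != table[other]).sum())
            assert diff.sum() == expected
            assert expected > 0


class TestProfileEncoders:
    def test_ssf_matches_window_slice(self, toy_profiles):
        from phosforest.profiles import window_profile

        frag = extract_window(toy_profiles["seq"], 30, 10, protein_id="p")
        v = encode_ssf(frag, toy_profiles["struct"]["p"])
        expected = window_profile(toy_profiles["struct"]["p"], 30, 10).ravel()
        np.testing.assert_array_equal(v.values, expected)

    def test_pssm_interior_values_verbatim(self, toy_profiles):
        frag = extract_window(toy_profiles["seq"], 30, 10, protein_id="p")
        v = encode_pssm(frag, toy_profiles["pssm"]["p"])
        expected = toy_profiles["pssm"]["p"].scores[19:40].ravel()
        np.testing.assert_array_equal(v.values, expected)

    def test_all_zero_pssm_gives_zero_vector(self):
        prof = PSSMProfile("p", np.zeros((21, 20)))
        frag = _frag("A" * 10 + "S" + "A" * 10)
        assert np.all(encode_pssm(frag, prof).values == 0)

    def test_missing_profile_error_names_protein(self, toy_profiles):
        frag = extract_window(toy_profiles["seq"], 30, 10, protein_id="absent")
        enc = make_encoder("pssm", pssm_profiles=toy_profiles["pssm"])
        with pytest.raises(KeyError, match="absent"):
            enc.fit([frag])


def pka_oracle(frag, profile, k):
    """Hand-expanded sum of products over k-spaced positions."""
    width = frag.width
    lo = frag.center_pos - 1 - frag.half_width
    rescaled = np.zeros((width, 20))
    for w in range(width):
        src = lo + w
        if 0 <= src < len(profile):
            rescaled[w] = 1.0 / (1.0 + np.exp(-profile.scores[src]))
    out = {}
    for ai, a in enumerate(PSSM_ALPHABET):
        for bi, b in enumerate(PSSM_ALPHABET):
            total = sum(
                rescaled[i, ai] * rescaled[i + k + 1, bi] for i in range(width - k - 1)
            )
            out[(a, b)] = total / (width - k - 1)
    return out


class TestPKA:
    def test_small_profile_oracle(self):
        rng = np.random.default_rng(5)
        prof = PSSMProfile("p", rng.integers(-5, 6, size=(5, 20)).astype(float))
        frag = extract_window("AKSKA", 3, 2, protein_id="p")
        v = encode_pka(frag, prof, k_values=[0])
        d = dict(zip(v.names, v.values))
        expected = pka_oracle(frag, prof, 0)
        for (a, b), val in expected.items():
            assert d[f"PKA|k=0|{a}_{b}"] == pytest.approx(val)

    def test_brute_force_oracle_terminal_fragment(self, toy_profiles):
        """Pad rows contribute zero even though sigmoid(0) would be 0.5."""
        frag = extract_window(toy_profiles["seq"], 30, 10, protein_id="p")
        near_end = extract_window(toy_profiles["seq"], 58, 10, protein_id="p")
        prof = toy_profiles["pssm"]["p"]
        for f in (frag, near_end):
            v = encode_pka(f, prof)
            d = dict(zip(v.names, v.values))
            for k in DEFAULT_K_VALUES:
                expected = pka_oracle(f, prof, k)
                for (a, b), val in expected.items():
                    assert d[f"PKA|k={k}|{a}_{b}"] == pytest.approx(val)


class TestCombined:
    def test_concatenation_contract(self, toy_profiles):
        frag = extract_window(toy_profiles["seq"], 30, 10, protein_id="p")
        prof = toy_profiles["pssm"]["p"]
        v = encode_combined(frag, prof)
        assert len(v) == 4940
        np.testing.assert_array_equal(v.values[:2205], encode_afc(frag).values)
        np.testing.assert_array_equal(v.values[2205:2520], encode_aip(frag).values)
        np.testing.assert_array_equal(v.values[2520:2940], encode_be(frag).values)
        np.testing.assert_array_equal(v.values[2940:], encode_pka(frag, prof).values)
        assert len(set(v.names)) == 4940

    def test_deterministic(self, toy_profiles):
        frag = extract_window(toy_profiles["seq"], 30, 10, protein_id="p")
        prof = toy_profiles["pssm"]["p"]
        a = encode_combined(frag, prof).values
        b = encode_combined(frag, prof).values
        assert np.array_equal(a, b)


def test_feature_matrix_roundtrip(tmp_path, toy_profiles):
    frag = extract_window(toy_profiles["seq"], 30, 10, protein_id="p")
    enc = make_encoder("aac")
    enc.fit([frag])
    X = pd.DataFrame(enc.transform([frag]), columns=list(enc.get_feature_names_out()))
    path = tmp_path / "fm.tsv"
    write_feature_matrix(X, [frag], path)
    meta, feats = read_feature_matrix(path)
    assert list(meta.columns) == ["protein_id", "position", "label"]
    np.testing.assert_allclose(feats.to_numpy(), X.to_numpy())
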