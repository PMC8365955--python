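"""Shape, determinism and content contracts of the five featurizers."""

import numpy as np
import pytest
from rdkit import Chem
from rdkit.Chem import rdFingerprintGenerator

from hergstack import featurize as fz
from hergstack.dataio import SmilesParseError


class TestDescriptorNormalizer:
    def test_minmax_transform(self):
        mat = np.tile([[0.0], [10.0]], (1, fz.N_DESCRIPTORS))
        norm = fz.fit_descriptor_normalizer(mat)
        out = norm.transform(np.full(fz.N_DESCRIPTORS, 5.0))
        assert np.allclose(out, 0.5)

    def test_constant_column_maps_to_zero(self):
        mat = np.full((3, fz.N_DESCRIPTORS), 3.0)
        norm = fz.fit_descriptor_normalizer(mat)
        assert np.allclose(norm.transform(np.full(fz.N_DESCRIPTORS, 3.0)), 0.0)

    def test_held_out_values_clip_to_unit_interval(self):
        mat = np.tile([[0.0], [10.0]], (1, fz.N_DESCRIPTORS))
        norm = fz.fit_descriptor_normalizer(mat)
        assert np.allclose(norm.transform(np.full(fz.N_DESCRIPTORS, 20.0)), 1.0)
        assert np.allclose(norm.transform(np.full(fz.N_DESCRIPTORS, -5.0)), 0.0)

    def test_requires_two_rows(self):
        with pytest.raises(ValueError):
            fz.fit_descriptor_normalizer(np.zeros((1, fz.N_DESCRIPTORS)))

    def test_json_roundtrip(self, tmp_path):
        mat = np.vstack([np.zeros(fz.N_DESCRIPTORS), np.arange(fz.N_DESCRIPTORS)])
        norm = fz.fit_descriptor_normalizer(mat)
        norm.to_json(tmp_path / "norm.json")
        back = fz.DescriptorNormalizer.from_json(tmp_path / "norm.json")
        assert np.allclose(back.mins, norm.mins)
        assert np.allclose(back.maxs, norm.maxs)


class TestDescriptors:
    def test_deterministic(self):
        a = fz.compute_raw_descriptors("CC(=O)Nc1ccc(O)cc1")
        b = fz.compute_raw_descriptors("CC(=O)Nc1ccc(O)cc1")
        assert np.array_equal(a, b)

    def test_ethane_heavy_atom_count(self):
        # ethane has exactly 2 heavy atoms
        idx = fz.DESCRIPTOR_NAMES.index("HeavyAtomCount")
        assert fz.compute_raw_descriptors("CC")[idx] == 2

    def test_fixed_length_and_normalized_range(self):
        mat = np.stack([fz.compute_raw_descriptors(s) for s in ("CCO", "c1ccccc1", "CCN")])
        norm = fz.fit_descriptor_normalizer(mat)
        vec = fz.compute_descriptor_vector("CCOC", norm)
        assert vec.shape == (fz.N_DESCRIPTORS,)
        assert (vec >= 0).all() and (vec <= 1).all()


class TestGraphFeaturizer:
    def test_shapes(self):
        g = fz.featurize_graph("CCO")
        assert g.nodes.shape == (50, 65)
        assert g.adjacency.shape == (50, 50)

    def test_benzene_topology(self):
        g = fz.featurize_graph("c1ccccc1")
        assert g.n_atoms == 6
        assert (np.abs(g.nodes[:6]).sum(axis=1) > 0).all()
        assert np.abs(g.nodes[6:]).sum() == 0
        assert g.adjacency.sum() == 12  # 6 ring bonds, symmetric

    def test_methane_is_isolated_node(self):
        g = fz.featurize_graph("C")
        assert g.n_atoms == 1
        assert g.adjacency.sum() == 0

    def test_adjacency_symmetric_and_padded(self, small_dataset):
        for smiles in small_dataset.smiles[:30]:
            g = fz.featurize_graph(smiles)
            assert np.array_equal(g.adjacency, g.adjacency.T)
            assert g.adjacency[g.n_atoms:, :].sum() == 0
            assert g.adjacency[:, g.n_atoms:].sum() == 0
            assert np.abs(g.nodes[g.n_atoms:]).sum() == 0

    def test_oversize_molecule_rejected(self):
        with pytest.raises(fz.OversizeMoleculeError):
            fz.featurize_graph("C" * 60)


class TestCombinedFingerprints:
    def test_length_and_binary(self):
        bits = fz.compute_combined_fingerprints("CC(=O)Nc1ccc(O)cc1")
        assert bits.shape == (1905,)
        assert set(np.unique(bits)) <= {0, 1}

    def test_invariant_to_smiles_form(self):
        assert np.array_equal(
            fz.compute_combined_fingerprints("OCC"),
            fz.compute_combined_fingerprints("CCO"),
        )

    def test_ecfp_block_matches_rdkit_oracle(self):
        gen = rdFingerprintGenerator.GetMorganGenerator(radius=1, fpSize=1024)
        mol = Chem.MolFromSmiles("c1ccncc1")
        expected = np.zeros(1024)
        expected[list(gen.GetFingerprint(mol).GetOnBits())] = 1
        assert np.array_equal(fz.compute_combined_fingerprints("c1ccncc1")[:1024], expected)


class TestTokenizer:
    def test_small_corpus_vocabulary(self):
        vocab = fz.build_token_vocabulary(["CCO", "CCN"])
        assert set(vocab.index) == {"C", "O", "N"}
        assert len(vocab) == 4  # three tokens + pad

    def test_multichar_tokens(self):
        assert fz.tokenize_smiles("Clc1ccccc1") == ["Cl", "c", "1", "c", "c", "c", "c", "c", "1"]
        assert fz.tokenize_smiles("[nH]1cccc1")[0] == "[nH]"
        assert "%12" in fz.tokenize_smiles("C%12CCCC%12")

    def test_encode_pads_and_roundtrips(self):
        vocab = fz.build_token_vocabulary(["CCO"])
        ids = fz.encode_smiles_tokens("CCO", vocab)
        assert ids.shape == (97,)
        assert (ids[:3] > 0).all() and (ids[3:] == 0).all()
        assert fz.decode_token_ids(ids, vocab) == "CCO"

    def test_overlength_rejected(self):
        vocab = fz.build_token_vocabulary(["C"])
        with pytest.raises(fz.OverlengthError):
            fz.encode_smiles_tokens("C" * 98, vocab)

    def test_unknown_token_modes(self):
        vocab = fz.build_token_vocabulary(["CC"])
        lenient = fz.encode_smiles_tokens("CO", vocab)
        assert lenient[1] == fz.TokenVocabulary.PAD
        with pytest.raises(KeyError):
            fz.encode_smiles_tokens("CO", vocab, strict=True)

    def test_vocab_json_roundtrip(self, tmp_path):
        vocab = fz.build_token_vocabulary(["Clc1ccccc1", "CCO"])
        vocab.to_json(tmp_path / "vocab.json")
        back = fz.TokenVocabulary.from_json(tmp_path / "vocab.json")
        assert back.index == vocab.index


class TestFpIndexVector:
    def test_matches_on_bit_oracle(self):
        gen = rdFingerprintGenerator.GetMorganGenerator(radius=2, fpSize=1024)
        mol = Chem.MolFromSmiles("CC(=O)Nc1ccc(O)cc1")
        on_bits = sorted(gen.GetFingerprint(mol).GetOnBits())
        vec = fz.compute_fp_index_vector("CC(=O)Nc1ccc(O)cc1")
        assert vec.shape == (93,)
        nonzero = vec[vec > 0]
        assert list(nonzero - 1) == on_bits  # 1-based offset convention
        assert (vec[len(on_bits):] == 0).all()

    def test_strictly_increasing_nonsentinel(self, small_dataset):
        for smiles in small_dataset.smiles[:25]:
            vec = fz.compute_fp_index_vector(smiles)
            nz = vec[vec > 0]
            assert (np.diff(nz) > 0).all()
            assert nz.min() >= 1 and nz.max() <= 1024

    def test_overflow_truncates_with_warning(self):
        big = "CC(C)(C)c1ccc(C(=O)NC2CCC(N3CCN(Cc4ccccc4)CC3)CC2)cc1"
        with pytest.warns(UserWarning):
            vec = fz.compute_fp_index_vector(big, max_len=10)
        assert vec.shape == (10,)
        assert (vec > 0).all()


def test_all_featurizers_deterministic_on_batch(small_dataset):
    """Every view is a pure function of the canonical SMILES."""
    for smiles in small_dataset.smiles[:10]:
        assert np.array_equal(
            fz.compute_combined_fingerprints(smiles),
            fz.compute_combined_fingerprints(smiles),
        )
        assert np.array_equal(
            fz.compute_fp_index_vector(smiles), fz.compute_fp_index_vector(smiles)
        )
        g1, g2 = fz.featurize_graph(smiles), fz.featurize_graph(smiles)
        assert np.array_equal(g1.nodes, g2.nodes)
        assert np.array_equal(g1.adjacency, g2.adjacency)
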