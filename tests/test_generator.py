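"""Generator model: invariances, temperature sampling, training behaviour."""

import math

import numpy as np
import pytest

from molcraft.alphabet import build_alphabet
from molcraft.generator import (
    GeneratorConfig,
    GeneratorModel,
    PropertyWishlist,
    count_parameters,
    greedy_decode,
    load_model,
    sample,
    save_model,
    temperature_probs,
    train_generator,
)
from molcraft.molgraph import (
    ProteinAtom,
    extract_pocket,
    featurize_ligand_2d,
    featurize_pocket,
    read_pdb,
)
from molcraft.nn import LSTMCell


@pytest.fixture(scope="module")
def alpha(tiny_corpus=None):
    return build_alphabet(["CCO", "CCN", "c1ccccc1O", "CC(=O)O"], seed=0)


def _small_model(alpha, conditioned=False, mode="ligand", seed=0):
    cfg = GeneratorConfig(
        mode=mode, node_dim=8, hidden_dim=16, latent_dim=24,
        token_emb_dim=8, n_seeds=2, conditioned=conditioned,
    )
    return GeneratorModel(cfg, alpha, seed=seed)


class TestEncoder:
    def test_permutation_invariance(self, alpha):
        from molcraft.chem import randomized_smiles

        model = _small_model(alpha)
        smi = "CC(=O)Oc1ccccc1"
        l1, l2 = model.encode(featurize_ligand_2d(smi))
        for r in randomized_smiles(smi, 4, seed=2):
            l1r, l2r = model.encode(featurize_ligand_2d(r))
            np.testing.assert_allclose(l1r.data, l1.data, atol=1e-6)
            np.testing.assert_allclose(l2r.data, l2.data, atol=1e-6)

    def test_rigid_motion_invariance_3d(self, alpha, toy_pocket):
        model = _small_model(alpha, mode="structure")
        atoms, lig = read_pdb(toy_pocket.pdb_text, ligand_resname="LIG")
        pg = featurize_pocket(extract_pocket(atoms, lig), lig)
        l1, l2 = model.encode(pg)

        rng = np.random.default_rng(4)
        Q, _ = np.linalg.qr(rng.normal(size=(3, 3)))
        t = rng.uniform(-10, 10, 3)
        rot_atoms = [
            ProteinAtom(a.element, a.res_name, a.atom_name,
                        tuple(Q @ np.array(a.coord) + t), a.b_factor)
            for a in atoms
        ]
        rot_lig = lig @ Q.T + t
        pg2 = featurize_pocket(extract_pocket(rot_atoms, rot_lig), rot_lig)
        l1r, l2r = model.encode(pg2)
        np.testing.assert_allclose(l1r.data, l1.data, atol=1e-6)
        np.testing.assert_allclose(l2r.data, l2.data, atol=1e-6)

    def test_deterministic_latents(self, alpha):
        model = _small_model(alpha)
        g = featurize_ligand_2d("CCO")
        a = model.encode(g)[0].data
        b = model.encode(g)[0].data
        np.testing.assert_array_equal(a, b)

    def test_empty_graph_rejected(self, alpha):
        import molcraft.molgraph as mg

        model = _small_model(alpha)
        empty = mg.LigandGraph2D(
            atom_type_idx=np.array([], dtype=int),
            ring_flag=np.array([], dtype=int),
            aromatic_flag=np.array([], dtype=int),
            hybridization_idx=np.array([], dtype=int),
            edges=np.zeros((0, 2), dtype=int),
        )
        with pytest.raises(ValueError):
            model.encode(empty)


class TestConditioning:
    def test_different_wishlists_different_latents(self, alpha):
        model = _small_model(alpha, conditioned=True)
        model.prop_std = np.array([50.0, 2.0, 1.0, 1.0, 20.0, 1.0])
        g = featurize_ligand_2d("CCO")
        w1 = PropertyWishlist(300, 3, 2, 1, 60, 2.5)
        w2 = PropertyWishlist(120, 1, 1, 0, 20, 0.5)
        l1a, _ = model.encode(g, [w1])
        l1b, _ = model.encode(g, [w2])
        assert np.abs(l1a.data - l1b.data).max() > 1e-8

    def test_wishlist_at_training_mean_standardizes_to_zero(self, alpha):
        model = _small_model(alpha, conditioned=True)
        model.prop_mean = np.array([250.0, 3, 2, 1, 50, 2])
        model.prop_std = np.array([50.0, 2, 1, 1, 20, 1])
        z = model.standardize_properties(model.prop_mean)
        np.testing.assert_allclose(z, 0.0)

    def test_standardize_round_trip(self, alpha):
        model = _small_model(alpha, conditioned=True)
        model.prop_mean = np.array([250.0, 3, 2, 1, 50, 2])
        model.prop_std = np.array([50.0, 2, 1, 1, 20, 1])
        x = np.array([321.0, 5, 4, 2, 77, 3.3])
        np.testing.assert_allclose(
            model.destandardize_properties(model.standardize_properties(x)), x
        )

    def test_missing_wishlist_raises_in_conditioned_mode(self, alpha):
        model = _small_model(alpha, conditioned=True)
        with pytest.raises(ValueError):
            model.encode(featurize_ligand_2d("CCO"))


class TestDecodeStep:
    def test_softmax_of_logits_normalizes(self, alpha):
        model = _small_model(alpha)
        d = model.config.latent_dim
        state = np.zeros((3, d))
        _, _, _, _, logits = model.decode_step(state, state, state, state, np.array([3, 4, 5]))
        p = temperature_probs(logits, 1.0)
        np.testing.assert_allclose(p.sum(axis=1), 1.0, atol=1e-9)

    def test_zero_weights_give_uniform_distribution(self, alpha):
        model = _small_model(alpha)
        for p in model.parameters():
            p.data[:] = 0.0
        d = model.config.latent_dim
        z = np.zeros((1, d))
        _, _, _, _, logits = model.decode_step(z, z, z, z, np.array([3]))
        p = temperature_probs(logits, 1.0)
        np.testing.assert_allclose(p, 1.0 / alpha.size, atol=1e-12)

    def test_forced_gates_preserve_cell_state(self):
        # saturate: forget gate -> 1, input gate -> 0 => c_t = c_{t-1}
        rng = np.random.default_rng(0)
        cell = LSTMCell(4, 6, rng)
        for p in (cell.wx, cell.wl):
            p.data[:] = 0.0
        H = 6
        cell.bx.data[:] = 0.0
        cell.bl.data[:] = 0.0
        cell.bx.data[0 * H:1 * H] = -60.0  # input gate ~ 0
        cell.bx.data[1 * H:2 * H] = +60.0  # forget gate ~ 1
        c_prev = rng.normal(size=(2, H))
        _, c_t = cell.step_numpy(rng.normal(size=(2, 4)), np.zeros((2, H)), c_prev)
        np.testing.assert_allclose(c_t, c_prev, atol=1e-12)


class TestTemperature:
    def test_equal_logits_uniform_at_any_temperature(self):
        for T in (0.2, 0.5, 0.8, 1.1):
            p = temperature_probs(np.zeros(7), T)
            np.testing.assert_allclose(p, 1 / 7)

    def test_direct_softmax_value(self):
        p = temperature_probs(np.array([1.0, 0.0]), 1.0)
        np.testing.assert_allclose(p, [0.7311, 0.2689], atol=1e-4)

    def test_low_temperature_approaches_argmax(self):
        p = temperature_probs(np.array([1.0, 0.0]), 0.01)
        assert p[0] > 1 - 1e-10

    def test_shift_invariance(self):
        logits = np.array([0.3, -1.2, 2.0])
        np.testing.assert_allclose(
            temperature_probs(logits, 0.7), temperature_probs(logits + 123.4, 0.7), atol=1e-12
        )

    def test_monotone_sharpening(self):
        logits = np.array([1.0, 0.2, -0.5])
        pm = [temperature_probs(logits, T).max() for T in (0.2, 0.5, 0.8, 1.1)]
        assert pm == sorted(pm, reverse=True)

    def test_nonpositive_temperature_rejected(self):
        with pytest.raises(ValueError):
            temperature_probs(np.zeros(3), 0.0)


class TestTraining:
    def test_initial_loss_near_log_vocab(self, alpha):
        model = _small_model(alpha, seed=5)
        g = featurize_ligand_2d("CCO")
        trace = train_generator(model, [(g, "CCO", None)], epochs=1, lr=0.0, batch_size=1, seed=0)
        assert abs(trace[0] - math.log(alpha.size)) < 0.3

    def test_same_seed_identical_traces(self, alpha):
        g = featurize_ligand_2d("CCO")
        examples = [(g, "CCO", None), (g, "CCN", None)]
        t1 = train_generator(_small_model(alpha, seed=2), examples, epochs=3, seed=9)
        t2 = train_generator(_small_model(alpha, seed=2), examples, epochs=3, seed=9)
        assert t1 == t2

    def test_memorization_single_pair(self, alpha):
        model = _small_model(alpha, seed=1)
        target = "c1ccccc1O"
        g = featurize_ligand_2d(target)
        trace = train_generator(model, [(g, target, None)], epochs=250, lr=5e-3, batch_size=1, seed=0)
        assert trace[-1] < 0.05
        assert greedy_decode(model, g) == target

    def test_sampling_reproducible_and_counts(self, alpha):
        model = _small_model(alpha, seed=1)
        g = featurize_ligand_2d("CCO")
        train_generator(model, [(g, "CCO", None)], epochs=60, lr=5e-3, batch_size=1, seed=0)
        s1 = sample(model, g, T=0.5, n=25, seed=3)
        s2 = sample(model, g, T=0.5, n=25, seed=3)
        assert len(s1) == 25
        assert [x.string for x in s1] == [x.string for x in s2]

    def test_overfit_sampling_recovers_target_at_low_temperature(self, alpha):
        model = _small_model(alpha, seed=1)
        g = featurize_ligand_2d("CCO")
        train_generator(model, [(g, "CCO", None)], epochs=200, lr=5e-3, batch_size=1, seed=0)
        out = sample(model, g, T=0.2, n=50, seed=7)
        frac = np.mean([s.canonical == "CCO" for s in out])
        assert frac >= 0.9


class TestParameterCount:
    def test_counts_match_hand_algebra(self, alpha):
        cfg = GeneratorConfig(
            mode="ligand", node_dim=4, hidden_dim=8, latent_dim=8,
            token_emb_dim=4, n_seeds=2,
        )
        model = GeneratorModel(cfg, alpha, seed=0)
        enc, dec, total = count_parameters(model)
        V = alpha.size
        mlp = lambda i, h, o: (i * h + h) + (h * o + o)
        exp_enc = (
            (10 + 2 + 2 + 4) * 4          # feature embeddings
            + mlp(16, 8, 8)               # node MLP
            + 3 * mlp(16, 8, 8)           # psi per layer
            + 3 * mlp(16, 8, 8)           # phi per layer
            + mlp(24, 8, 8)               # concat projection
            + 2 * 8                       # pooling seeds
            + 2 * mlp(16, 8, 8)           # two latent MLPs
        )
        exp_dec = (
            V * 4
            + (4 * 4 * 8 + 8 * 4 * 8 + 2 * 4 * 8)   # LSTM layer 1
            + (8 * 4 * 8 + 8 * 4 * 8 + 2 * 4 * 8)   # LSTM layer 2
            + (8 * V + V)                            # output projection
        )
        assert enc == exp_enc and dec == exp_dec and total == enc + dec

    def test_doubling_hidden_dim_changes_only_predicted_layers(self, alpha):
        c1 = GeneratorConfig(mode="ligand", node_dim=4, hidden_dim=8, latent_dim=8, token_emb_dim=4, n_seeds=2)
        c2 = GeneratorConfig(mode="ligand", node_dim=4, hidden_dim=16, latent_dim=8, token_emb_dim=4, n_seeds=2)
        e1, d1, _ = count_parameters(GeneratorModel(c1, alpha, seed=0))
        e2, d2, _ = count_parameters(GeneratorModel(c2, alpha, seed=0))
        assert d1 == d2  # decoder untouched by encoder width
        assert e2 > e1


def test_save_load_round_trip(tmp_path, alpha):
    model = _small_model(alpha, conditioned=True, seed=8)
    model.prop_mean = np.arange(6.0)
    model.prop_std = np.arange(1.0, 7.0)
    path = tmp_path / "model.npz"
    save_model(model, path)
    loaded = load_model(path)
    g = featurize_ligand_2d("CCO")
    w = [PropertyWishlist(300, 3, 2, 1, 60, 2.5)]
    np.testing.assert_array_equal(model.encode(g, w)[0].data, loaded.encode(g, w)[0].data)
    assert loaded.alphabet.tokens == model.alphabet.tokens
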