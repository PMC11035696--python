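"""Descriptors, KRR QSAR (with sklearn as independent oracle), novelty scheme."""

import math

import numpy as np
import pytest

from molcraft.chem import ecfp4_512, mol_from_smiles
from molcraft.scoring import (
    NoveltyIndex,
    atom_scaffold,
    carbon_scaffold,
    compute_descriptor,
    jaccard_distance,
    krr_fit,
    krr_predict,
    laplacian_kernel,
    novelty_score,
    qsar_ensemble_score,
    synthesizability,
)
from molcraft.synthetic import gen_qsar_dataset


class TestDescriptors:
    def test_ecfp_is_binary_512(self):
        v = compute_descriptor("CC(=O)Oc1ccccc1C(=O)O", "ECFP4_512").values
        assert v.shape == (512,) and set(np.unique(v)) <= {0.0, 1.0}

    def test_identical_canonical_smiles_identical_vectors(self):
        a = compute_descriptor("OCC", "CATS_abs").values
        b = compute_descriptor("CCO", "CATS_abs").values
        np.testing.assert_array_equal(a, b)

    def test_cats_ethane_all_zero(self):
        # no pharmacophoric atoms on a two-carbon alkane under the frozen typing
        v = compute_descriptor("CC", "CATS_abs").values
        assert v.shape == (210,) and v.sum() == 0

    def test_cats_ethylene_glycol_hand_enumeration(self):
        # two O atoms, each donor+acceptor, topological distance 3:
        # per-atom (D,A)@0 twice; cross pairs: DD@3, AA@3, and DA@3 twice
        from molcraft.scoring import CATS_N_BINS, _CATS_PAIRS

        v = compute_descriptor("OCCO", "CATS_abs").values
        by_pair = {p: v[i * CATS_N_BINS:(i + 1) * CATS_N_BINS] for i, p in enumerate(_CATS_PAIRS)}
        assert by_pair[("D", "A")][0] == 2
        assert by_pair[("D", "D")][3] == 1
        assert by_pair[("A", "A")][3] == 1
        assert by_pair[("D", "A")][3] == 2
        assert v.sum() == 6

    def test_usrcat_deterministic_with_seed(self):
        a = compute_descriptor("CC(=O)Oc1ccccc1", "USRCAT").values
        b = compute_descriptor("CC(=O)Oc1ccccc1", "USRCAT").values
        np.testing.assert_array_equal(a, b)
        assert a.shape == (60,)


class TestLaplacianKernel:
    def test_self_similarity_is_one(self):
        x = np.array([1.0, 2.0, 3.0])
        assert laplacian_kernel(x, x) == 1.0

    def test_known_values(self):
        x = np.zeros(4)
        y = np.array([51.2, 0, 0, 0])
        assert laplacian_kernel(x, y, sigma=51.2) == pytest.approx(math.exp(-1), abs=1e-10)
        assert laplacian_kernel(x, 2 * y, sigma=51.2) == pytest.approx(math.exp(-2), abs=1e-10)

    def test_length_mismatch_raises(self):
        with pytest.raises(ValueError):
            laplacian_kernel(np.zeros(3), np.zeros(4))

    def test_kernel_matrix_symmetric_unit_diagonal(self):
        rng = np.random.default_rng(0)
        X = rng.integers(0, 2, size=(20, 64)).astype(float)
        from molcraft.scoring import _kernel_matrix

        K = _kernel_matrix(X, X, 51.2)
        np.testing.assert_allclose(K, K.T)
        np.testing.assert_allclose(np.diag(K), 1.0)


class TestKRR:
    def test_single_point_interpolates_at_lambda_zero(self):
        m = krr_fit(np.array([[1.0, 2.0]]), np.array([5.0]), lam=0.0)
        assert krr_predict(m, np.array([1.0, 2.0])) == pytest.approx(5.0)

    def test_single_point_closed_form_with_ridge(self):
        m = krr_fit(np.array([[1.0, 2.0]]), np.array([5.0]), lam=1e-7)
        assert m.alpha[0] == pytest.approx(5.0 / (1 + 1e-7), rel=1e-12)

    def test_two_point_manual_solve(self):
        X = np.array([[0.0], [51.2]])
        y = np.array([4.0, 8.0])
        m = krr_fit(X, y, sigma=51.2, lam=0.0)
        k = math.exp(-1)
        # solve [[1, k], [k, 1]] alpha = y by hand
        det = 1 - k * k
        expected = np.array([(4.0 - k * 8.0) / det, (8.0 - k * 4.0) / det])
        np.testing.assert_allclose(m.alpha, expected, atol=1e-10)

    def test_interpolation_of_distinct_points(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(25, 8)) * 10
        y = rng.normal(size=25)
        m = krr_fit(X, y, lam=0.0)
        np.testing.assert_allclose(krr_predict(m, X), y, atol=1e-6)

    def test_duplicated_rows_at_lambda_zero_raise_advice(self):
        X = np.array([[1.0, 1.0], [1.0, 1.0]])
        with pytest.raises(np.linalg.LinAlgError, match="lambda"):
            krr_fit(X, np.array([1.0, 2.0]), lam=0.0)

    def test_far_query_predicts_zero(self):
        m = krr_fit(np.array([[0.0]]), np.array([7.0]), lam=0.0)
        assert abs(krr_predict(m, np.array([1e6]))) < 1e-12

    def test_vectorized_prediction_equals_brute_force(self):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(50, 16)) * 5
        y = rng.normal(size=50)
        m = krr_fit(X, y)
        q = rng.normal(size=16) * 5
        brute = sum(
            m.alpha[i] * laplacian_kernel(X[i], q, m.sigma) for i in range(50)
        )
        assert krr_predict(m, q) == pytest.approx(brute, rel=1e-10)

    def test_matches_sklearn_kernel_ridge(self):
        sklearn = pytest.importorskip("sklearn.kernel_ridge")
        rng = np.random.default_rng(3)
        X = rng.integers(0, 2, size=(40, 64)).astype(float)
        y = rng.normal(size=40)
        sigma, lam = 51.2, 1e-7
        m = krr_fit(X, y, sigma=sigma, lam=lam)
        sk = sklearn.KernelRidge(kernel="laplacian", gamma=1.0 / sigma, alpha=lam)
        sk.fit(X, y)
        Q = rng.integers(0, 2, size=(10, 64)).astype(float)
        np.testing.assert_allclose(krr_predict(m, Q), sk.predict(Q), atol=1e-6)

    def test_learning_curve_mae_below_twice_noise(self):
        noise_sd = 0.2
        smiles, X, y = gen_qsar_dataset(260, seed=4, noise_sd=noise_sd)
        train, test = slice(0, 200), slice(200, 260)
        m = krr_fit(X[train], y[train])
        mae = np.abs(krr_predict(m, X[test]) - y[test]).mean()
        assert mae < 2 * noise_sd

    def test_mae_improves_with_training_size(self):
        smiles, X, y = gen_qsar_dataset(300, seed=5, noise_sd=0.2)
        test = slice(240, 300)
        maes = []
        for n in (20, 80, 240):
            m = krr_fit(X[:n], y[:n])
            maes.append(np.abs(krr_predict(m, X[test]) - y[test]).mean())
        assert maes[-1] < maes[0]


class TestJaccard:
    def test_identical_nonzero_is_zero(self):
        fp = np.zeros(16)
        fp[[1, 5]] = 1
        assert jaccard_distance(fp, fp) == 0.0

    def test_disjoint_is_one(self):
        a = np.zeros(16)
        b = np.zeros(16)
        a[0] = b[1] = 1
        assert jaccard_distance(a, b) == 1.0

    def test_partial_overlap(self):
        a = np.zeros(16)
        b = np.zeros(16)
        a[[1, 2]] = 1
        b[[2, 3]] = 1
        assert jaccard_distance(a, b) == pytest.approx(2 / 3)

    def test_both_all_zero_undefined(self):
        with pytest.raises(ValueError):
            jaccard_distance(np.zeros(8), np.zeros(8))

    def test_metric_properties_on_random_vectors(self):
        rng = np.random.default_rng(6)
        vs = rng.integers(0, 2, size=(12, 32)).astype(float)
        vs[:, 0] = 1  # avoid all-zero rows
        for a in vs:
            for b in vs:
                assert jaccard_distance(a, b) == pytest.approx(jaccard_distance(b, a))
        for a in vs[:6]:
            for b in vs[:6]:
                for c in vs[:6]:
                    assert (
                        jaccard_distance(a, c)
                        <= jaccard_distance(a, b) + jaccard_distance(b, c) + 1e-12
                    )


class TestScaffolds:
    def test_toluene_atom_scaffold_is_benzene(self):
        assert atom_scaffold("Cc1ccccc1") == "c1ccccc1"

    def test_pyridine_carbon_scaffold_is_cyclohexane(self):
        assert carbon_scaffold("c1ccncc1") == "C1CCCCC1"

    def test_acyclic_molecule_has_empty_scaffold(self):
        assert atom_scaffold("CCO") == ""
        assert carbon_scaffold("CCO") == ""


class TestNovelty:
    def test_training_member_scores_zero(self):
        idx = NoveltyIndex(["Cc1ccccc1", "CCO"])
        r = novelty_score("Cc1ccccc1", idx)
        assert r.s_novelty == 0.0

    def test_component_sum_mid_case(self):
        idx = NoveltyIndex(["Cc1ccccc1", "CCO"])
        r = novelty_score("c1ccncc1", idx)  # pyridine: benzene-free ring, new atom scaffold
        assert r.s_novelty == pytest.approx(r.s_ecfp + r.s_atom + r.s_carbon)
        assert 0.0 <= r.s_novelty <= 1.2 + 1e-12

    def test_ceiling_reached_for_disjoint_fingerprint_and_unseen_scaffolds(self):
        idx = NoveltyIndex(["CCCC", "CCO"])
        r = novelty_score("c1ccsc1", idx)
        assert r.s_ecfp == 1.0 and r.s_atom == 0.1 and r.s_carbon == 0.1
        assert r.s_novelty == pytest.approx(1.2, abs=1e-12)

    def test_acyclic_query_sees_acyclic_training_scaffold(self):
        idx = NoveltyIndex(["CCCC"])
        r = novelty_score("CCOCC", idx)
        assert r.s_atom == 0.0 and r.s_carbon == 0.0  # empty scaffold shared

    def test_nearest_neighbor_matches_exhaustive_scan(self):
        train = ["CCO", "CCN", "c1ccccc1", "Cc1ccccc1O", "CCCC(=O)O"]
        idx = NoveltyIndex(train)
        q = ecfp4_512(mol_from_smiles("CCOC"))
        d, i = idx.nearest(q)
        brute = min(
            jaccard_distance(q, ecfp4_512(mol_from_smiles(s))) for s in train
        )
        assert d == pytest.approx(brute)

    def test_empty_index_rejected(self):
        with pytest.raises(ValueError):
            NoveltyIndex([])


class TestEnsembleAndSynthesizability:
    def _models(self, preds):
        class Fixed:
            def __init__(self, v):
                self.v = v

        # fabricate one-point models whose prediction is a constant
        models = {}
        for kind, v in preds.items():
            m = krr_fit(np.array([[0.0]]), np.array([v]), lam=0.0, kind=kind)
            models[kind] = m
        return models

    def test_equal_predictions_pass_through(self, monkeypatch):
        import molcraft.scoring as sc

        models = self._models({"ECFP4_512": 5.0, "CATS_abs": 5.0, "USRCAT": 5.0})
        monkeypatch.setattr(sc, "krr_predict", lambda m, x: m.y[0])
        assert sc.qsar_ensemble_score("CCO", models) == pytest.approx(5.0)

    def test_double_weighted_ecfp(self, monkeypatch):
        import molcraft.scoring as sc

        models = self._models({"ECFP4_512": 6.0, "CATS_abs": 5.0, "USRCAT": 5.0})
        monkeypatch.setattr(sc, "krr_predict", lambda m, x: m.y[0])
        assert sc.qsar_ensemble_score("CCO", models) == pytest.approx(5.5)

    def test_uniform_weights_give_arithmetic_mean(self, monkeypatch):
        import molcraft.scoring as sc

        models = self._models({"ECFP4_512": 6.0, "CATS_abs": 5.0, "USRCAT": 4.0})
        monkeypatch.setattr(sc, "krr_predict", lambda m, x: m.y[0])
        w = {"ECFP4_512": 1.0, "CATS_abs": 1.0, "USRCAT": 1.0}
        assert sc.qsar_ensemble_score("CCO", models, weights=w) == pytest.approx(5.0)

    def test_missing_model_raises(self):
        models = self._models({"ECFP4_512": 6.0})
        with pytest.raises(ValueError):
            qsar_ensemble_score("CCO", models)

    def test_stub_range_and_determinism(self):
        v1 = synthesizability("CCO")
        v2 = synthesizability("CCO")
        assert 0.0 <= v1 <= 1.0 and v1 == v2

    def test_plugin_passthrough(self):
        assert synthesizability("CCO", scorer=lambda m: 0.42) == 0.42

    def test_no_scorer_no_stub_raises(self):
        with pytest.raises(ValueError):
            synthesizability("CCO", scorer=None, use_stub=False)
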