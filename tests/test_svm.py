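import numpy as np
import pytest
from sklearn.svm import SVC

from nirselect import (
    BinaryRBFSVM,
    SVMParams,
    TreeSVM,
    build_tree,
    rbf_kernel,
    train_binary,
)
from ._oracles import dual_objective, svm_dual_bruteforce


class TestRBFKernel:
    def test_self_similarity_is_one(self):
        x = np.array([1.0, -2.0, 0.5])
        assert rbf_kernel(x, x, sigma=1.7) == 1.0

    def test_closed_form_value(self):
        # ||x-y||^2 = 2 sigma^2  ->  exp(-1)
        sigma = 1.3
        x = np.zeros(2)
        y = np.array([sigma * np.sqrt(2.0), 0.0])
        assert np.isclose(rbf_kernel(x, y, sigma=sigma), np.exp(-1.0))

    def test_gram_symmetric_psd(self, rng):
        x = rng.standard_normal((10, 4))
        gram = rbf_kernel(x, sigma=0.9)
        assert np.allclose(gram, gram.T)
        assert np.linalg.eigvalsh(gram).min() >= -1e-10
        assert gram.max() <= 1.0 and gram.min() > 0.0

    def test_invalid_sigma(self):
        with pytest.raises(ValueError, match="sigma"):
            rbf_kernel(np.zeros(2), np.ones(2), sigma=0.0)

    def test_dimension_mismatch(self):
        with pytest.raises(ValueError, match="mismatch"):
            rbf_kernel(np.zeros(2), np.zeros(3), sigma=1.0)


class TestSVMParams:
    @pytest.mark.parametrize("bad", [{"C": 0.0}, {"C": -1.0}, {"sigma": 0.0},
                                     {"sigma": np.inf}])
    def test_invalid(self, bad):
        with pytest.raises(ValueError):
            SVMParams(**bad)


class TestBinarySVM:
    def test_separable_clusters(self, rng):
        x = np.vstack([rng.normal(-3, 0.3, (20, 2)), rng.normal(3, 0.3, (20, 2))])
        y = np.array(["neg"] * 20 + ["pos"] * 20)
        model = train_binary(x, y, SVMParams(C=10.0, sigma=1.0))
        assert np.all(model.predict(x) == y)
        g = model.decision_function(x)
        assert np.all(g[:20] < 0) and np.all(g[20:] > 0)

    def test_xor_pattern(self):
        x = np.array([[0.0, 0.0], [1.0, 1.0], [0.0, 1.0], [1.0, 0.0]])
        y = np.array([1, 1, -1, -1])
        model = BinaryRBFSVM(C=10.0, sigma=0.5).fit(x, y)
        assert np.all(model.predict(x) == y)

    def test_single_class_rejected(self, rng):
        x = rng.standard_normal((5, 2))
        with pytest.raises(ValueError, match="2 classes"):
            BinaryRBFSVM().fit(x, np.ones(5))

    def test_matches_sklearn_svc_exactly(self, rng):
        """The low-level solver path must agree with the public SVC wrapper."""
        for _ in range(8):
            x = rng.standard_normal((40, 3))
            y = np.where(x[:, 0] + 0.3 * rng.standard_normal(40) > 0, 1, -1)
            if len(np.unique(y)) < 2:
                continue
            model = BinaryRBFSVM(C=2.0, sigma=2.0, tol=1e-8).fit(x, y)
            svc = SVC(C=2.0, gamma=1 / 8.0, tol=1e-8).fit(x, y)
            assert np.allclose(
                model.decision_function(x), svc.decision_function(x), atol=1e-9
            )

    def test_dual_feasibility(self, rng):
        x = rng.standard_normal((30, 3))
        y = np.where(x[:, 0] > 0, 1, -1)
        model = BinaryRBFSVM(C=2.0, sigma=1.0, tol=1e-8).fit(x, y)
        assert np.all(model.alpha_ >= -1e-9)
        assert np.all(model.alpha_ <= 2.0 + 1e-9)
        assert abs(model.alpha_ @ model.y_train_sign_) < 1e-6

    @pytest.mark.parametrize("seed", range(6))
    def test_objective_matches_bruteforce_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 7))
        x = rng.standard_normal((n, 2))
        y = np.where(rng.random(n) < 0.5, 1.0, -1.0)
        if len(np.unique(y)) < 2:
            y[0] = -y[1]
        C, sigma = 2.0, 1.0
        model = BinaryRBFSVM(C=C, sigma=sigma, tol=1e-10).fit(x, y)
        K = rbf_kernel(x, sigma=sigma)
        obj_impl = dual_objective(K, model.y_train_sign_, model.alpha_)
        obj_oracle, _ = svm_dual_bruteforce(K, y, C)
        assert obj_impl <= obj_oracle + 1e-4
        assert abs(obj_impl - obj_oracle) < 1e-4

    def test_serialization_round_trip(self, rng):
        x = rng.standard_normal((25, 3))
        y = np.where(x[:, 0] > 0, "a", "b")
        if len(np.unique(y)) < 2:
            y[0] = "a" if y[0] == "b" else "b"
        model = BinaryRBFSVM(C=2.0, sigma=1.0).fit(x, y)
        back = BinaryRBFSVM.from_dict(model.to_dict())
        assert np.allclose(back.decision_function(x), model.decision_function(x))
        assert np.all(back.predict(x) == model.predict(x))


class TestTreeSVM:
    def _four_class_blobs(self, rng, n=15):
        centers = np.array([[-4, -4], [-4, 4], [4, -4], [4, 4]], dtype=float)
        x = np.vstack([rng.normal(c, 0.4, (n, 2)) for c in centers])
        y = np.repeat(["c1", "c2", "c3", "c4"], n)
        return x, y

    def test_two_classes_single_node(self, rng):
        x = np.vstack([rng.normal(-2, 0.3, (10, 2)), rng.normal(2, 0.3, (10, 2))])
        y = np.array(["a"] * 10 + ["b"] * 10)
        tree = build_tree(x, y, SVMParams(C=5.0, sigma=1.0))
        assert tree.n_internal_nodes_ == 1
        binary = train_binary(x, y, SVMParams(C=5.0, sigma=1.0))
        assert np.all(tree.predict(x) == binary.predict(x))

    def test_four_classes_three_internal_nodes(self, rng):
        x, y = self._four_class_blobs(rng)
        tree = build_tree(x, y, SVMParams(C=5.0, sigma=1.0))
        assert tree.n_internal_nodes_ == 3
        assert np.mean(tree.predict(x) == y) == 1.0

    def test_ordered_policy_root_split(self, rng):
        x, y = self._four_class_blobs(rng)
        tree = TreeSVM(C=5.0, sigma=1.0, split_policy="ordered").fit(x, y)
        assert sorted(tree.tree_.left.classes) == ["c1", "c2"]
        assert sorted(tree.tree_.right.classes) == ["c3", "c4"]

    def test_prediction_permutation_invariance(self, rng):
        x, y = self._four_class_blobs(rng)
        tree = build_tree(x, y, SVMParams(C=5.0, sigma=1.0))
        perm = rng.permutation(len(y))
        assert np.all(tree.predict(x[perm]) == tree.predict(x)[perm])

    def test_single_class_rejected(self, rng):
        x = rng.standard_normal((6, 2))
        with pytest.raises(ValueError, match="2 classes"):
            TreeSVM().fit(x, np.repeat("only", 6))

    def test_dimension_mismatch(self, rng):
        x, y = self._four_class_blobs(rng)
        tree = build_tree(x, y, SVMParams(C=5.0, sigma=1.0))
        with pytest.raises(ValueError, match="features"):
            tree.predict(rng.standard_normal((3, 5)))

    def test_serialization_round_trip(self, rng):
        x, y = self._four_class_blobs(rng)
        tree = build_tree(x, y, SVMParams(C=5.0, sigma=1.0))
        back = TreeSVM.from_dict(tree.to_dict())
        probe = rng.standard_normal((50, 2)) * 4
        assert np.all(back.predict(probe) == tree.predict(probe))

    def test_deterministic_refit(self, rng):
        x, y = self._four_class_blobs(rng)
        t1 = build_tree(x, y, SVMParams())
        t2 = build_tree(x, y, SVMParams())
        probe = rng.standard_normal((80, 2)) * 4
        assert np.all(t1.predict(probe) == t2.predict(probe))
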