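"""Movement encoding over a shared vocabulary and prototype clustering."""

import numpy as np
import pytest
from sklearn.metrics import adjusted_rand_score

from armkin import (
    BehaviorVocabulary,
    GaussianUnit,
    KinematicSurface,
    MovementEncoding,
    cluster_movements,
    encode_movement,
    evaluate_mixture,
    match_movement,
    pool_encoding,
)
from armkin.exceptions import ShapeError, ValidationError
from armkin import simdata


@pytest.fixture(scope="module")
def vocab():
    return simdata.extension_vocabulary()


def _surfaces_from_weights(w, vocab, n=60, noise=0.0, seed=None):
    curv = [GaussianUnit(float(wi), u.mu, u.Sigma)
            for wi, u in zip(w[: vocab.n_C], vocab.curvature_units) if wi > 0]
    tors = [GaussianUnit(float(wi), u.mu, u.Sigma)
            for wi, u in zip(w[vocab.n_C:], vocab.torsion_units) if wi > 0]
    k = simdata.gen_surface(curv, n=n, noise_sd=noise, seed=seed)
    axis = np.linspace(0, 1, n)
    if tors:
        t = simdata.gen_surface(tors, n=n, noise_sd=noise, seed=seed, quantity="torsion")
    else:
        t = KinematicSurface(np.zeros((n, n)), "torsion", axis, axis)
    return k, t


class TestEncode:
    def test_construct_then_solve_recovery(self, vocab):
        w_true = np.array([0.7, 1.3, 0.4, 0.9, 0.2, 1.1])
        pair = _surfaces_from_weights(w_true, vocab)
        enc = encode_movement(pair, vocab)
        assert np.abs(enc.weights - w_true).max() < 1e-6
        assert enc.residuals["curvature"] < 1e-9

    def test_zero_surfaces_zero_weights(self, vocab):
        axis = np.linspace(0, 1, 40)
        zero = lambda q: KinematicSurface(np.zeros((40, 40)), q, axis, axis)
        enc = encode_movement((zero("curvature"), zero("torsion")), vocab)
        assert np.all(enc.weights == 0.0)

    def test_weights_nonnegative_for_random_surface(self, vocab, rng):
        axis = np.linspace(0, 1, 40)
        k = KinematicSurface(rng.random((40, 40)), "curvature", axis, axis)
        t = KinematicSurface(rng.random((40, 40)), "torsion", axis, axis)
        enc = encode_movement((k, t), vocab)
        assert np.all(enc.weights >= 0.0)

    def test_grid_mismatch_rejected(self, vocab):
        a40 = np.linspace(0, 1, 40)
        a50 = np.linspace(0, 1, 50)
        k = KinematicSurface(np.zeros((40, 40)), "curvature", a40, a40)
        t = KinematicSurface(np.zeros((50, 50)), "torsion", a50, a50)
        with pytest.raises(ShapeError):
            encode_movement((k, t), vocab)

    def test_pool_encoding_assigns_to_nearest(self, vocab):
        # a movement whose own Gaussians sit exactly on two centroids
        own_c = [GaussianUnit(0.8, vocab.curvature_units[1].mu, vocab.curvature_units[1].Sigma)]
        own_t = [GaussianUnit(0.5, vocab.torsion_units[2].mu, vocab.torsion_units[2].Sigma)]
        enc = pool_encoding(own_c, own_t, vocab)
        assert enc.weights[1] == pytest.approx(0.8)
        assert enc.weights[vocab.n_C + 2] == pytest.approx(0.5)
        assert enc.weights.sum() == pytest.approx(1.3)


class TestClusterMovements:
    def test_planted_patterns_recovered(self, vocab):
        pairs, labels, _ = simdata.gen_classification_set(
            per_pattern=5, noise_frac=0.1, n=60, seed=9
        )
        encs = [encode_movement(p, vocab, movement_id=str(i)) for i, p in enumerate(pairs)]
        protos = cluster_movements(encs, vocab, k=3, seed=0, grid_n=60)
        assert adjusted_rand_score(labels, protos.assignments) >= 0.9

    def test_auto_k_via_gap(self, vocab):
        pats = simdata.extension_weight_patterns()[:2]
        pairs, labels, truth = simdata.gen_classification_set(
            patterns=pats, per_pattern=10, noise_frac=0.1, n=60, seed=0
        )
        encs = [encode_movement(p, vocab) for p in pairs]
        protos = cluster_movements(encs, vocab, k="auto", seed=0, grid_n=60)
        assert protos.k == 2
        assert adjusted_rand_score(labels, protos.assignments) == 1.0

    def test_identical_encodings_single_prototype(self, vocab):
        w = np.array([1.0, 0.5, 0.2, 0.3, 0.1, 0.6])
        encs = [
            MovementEncoding(str(i), w.copy(), vocab.n_C, {}) for i in range(5)
        ]
        protos = cluster_movements(encs, vocab, k=1, seed=0, grid_n=40)
        assert protos.k == 1
        assert np.allclose(protos.prototype_weights[0], w)

    def test_prototype_surface_roundtrip(self, vocab):
        w = np.array([0.9, 0.4, 0.7, 0.2, 0.8, 0.3])
        pair = _surfaces_from_weights(w, vocab, n=60)
        enc = encode_movement(pair, vocab)
        protos = cluster_movements([enc, enc, enc], vocab, k=1, seed=0, grid_n=60)
        curv, _ = protos.prototype_surfaces[0]
        resid = np.sqrt(np.mean((curv.values - pair[0].values) ** 2))
        assert resid <= enc.residuals["curvature"] + 1e-9


class TestMatch:
    def test_exact_prototype_match(self, vocab):
        pairs, labels, _ = simdata.gen_classification_set(
            per_pattern=4, noise_frac=0.05, n=50, seed=2
        )
        encs = [encode_movement(p, vocab) for p in pairs]
        protos = cluster_movements(encs, vocab, k=3, seed=0, grid_n=50)
        for j in range(protos.k):
            e = MovementEncoding("p", protos.prototype_weights[j], vocab.n_C, {})
            assert match_movement(e, protos) == j

    def test_tie_breaks_to_lowest_label(self, vocab):
        protos_w = np.array([[1.0, 0, 0, 0, 0, 0], [0, 0, 0, 0, 0, 1.0]])
        enc = MovementEncoding("x", np.zeros(6), vocab.n_C, {})
        from armkin.classify import PrototypeSet
        ps = PrototypeSet(np.array([0, 1]), protos_w, [], vocab)
        assert match_movement(enc, ps) == 0

    def test_noisy_draws_match_generating_prototype(self, vocab):
        pairs, labels, _ = simdata.gen_classification_set(
            per_pattern=6, noise_frac=0.15, n=50, seed=21
        )
        encs = [encode_movement(p, vocab) for p in pairs]
        protos = cluster_movements(encs, vocab, k=3, seed=0, grid_n=50)
        # map planted pattern -> majority prototype label, then check assignment
        matches = np.array([match_movement(e, protos) for e in encs])
        agree = adjusted_rand_score(labels, matches)
        assert agree >= 0.9
        assert np.array_equal(matches, protos.assignments)
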