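"""Seed algebra, decoding regimes and sampling reproducibility."""

import numpy as np
import pytest

from numgen import generation
from numgen.generation import (SoSVector, conditional_generate,
                               sos_extrapolated, sos_interpolated,
                               sos_pca_reduced, sos_trained,
                               spontaneous_generate)
from numgen.model import ParameterTables, PixelTransformer

from conftest import toy_core


@pytest.fixture
def tables():
    core = toy_core(n_pixels=9, d=8, numerosities=(1, 2, 3, 4, 5))
    return ParameterTables(core)


def small_estimator(numerosities=(1, 2), vocab=2, frame=(6, 6), d=16,
                    heads=2, seed=0):
    est = PixelTransformer(n_layers=1, d_model=d, n_heads=heads,
                           vocab_size=vocab, frame_shape=frame,
                           numerosities=numerosities, ff_width=32,
                           dropout=0.0, seed=seed)
    est.core_ = est._build_core()
    return est


# ---------------------------------------------------------------------------
# seed construction


def test_trained_seed_is_a_copy(tables):
    sos = sos_trained(tables, 1)
    np.testing.assert_array_equal(sos.values, tables.Ws[0])
    sos.values[:] = 99.0
    assert not np.allclose(tables.Ws[0], 99.0)  # no aliasing into Ws
    assert sos.provenance == ("trained", 1)
    with pytest.raises(KeyError):
        sos_trained(tables, 9)


def test_interpolated_seed_is_the_midpoint():
    held_out = ParameterTables(toy_core(n_pixels=9, d=8,
                                        numerosities=(1, 3)))
    w1, w3 = held_out.Ws[0], held_out.Ws[1]
    sos = sos_interpolated(held_out, 2)
    np.testing.assert_allclose(sos.values, (w1 + w3) / 2)
    # midpoint identity: equidistant from both neighbours
    np.testing.assert_allclose(sos.values - w1, w3 - sos.values)
    assert sos.provenance == ("interpolated", 2)


def test_interpolation_warns_on_trained_target_and_needs_neighbours(tables):
    with pytest.warns(UserWarning, match="trained"):
        sos_interpolated(tables, 3)
    with pytest.raises(KeyError):
        sos_interpolated(tables, 6)  # neighbour 7 missing


def test_interpolation_degenerate_equal_neighbours(tables):
    tables.Ws[0][:] = 1.5
    tables.Ws[2][:] = 1.5
    with pytest.warns(UserWarning):
        sos = sos_interpolated(tables, 2)
    np.testing.assert_allclose(sos.values, 1.5)


def test_extrapolated_seed_vector_identities(tables):
    w5, w4 = tables.Ws[4], tables.Ws[3]
    np.testing.assert_allclose(sos_extrapolated(tables, 0.0).values, w5)
    np.testing.assert_allclose(sos_extrapolated(tables, 1.0).values,
                               2 * w5 - w4)
    # collinearity: alpha = 0.5 lies midway between alpha = 0 and alpha = 1
    mid = sos_extrapolated(tables, 0.5).values
    np.testing.assert_allclose(mid, (w5 + (2 * w5 - w4)) / 2)


def test_extrapolation_needs_two_numerosities():
    core = toy_core(numerosities=(4,), n_pixels=9)
    with pytest.raises(ValueError):
        sos_extrapolated(ParameterTables(core), 1.0)


def test_pca_reduced_seed_reconstruction(tables):
    """Full-rank reconstruction recovers the row exactly; reconstruction
    error is non-increasing in k; k = 1 displacements are collinear."""
    W = tables.Ws
    full_rank = len(W) - 1
    np.testing.assert_allclose(
        sos_pca_reduced(tables, full_rank, 3).values, W[2], atol=1e-6)
    errs = [np.linalg.norm(sos_pca_reduced(tables, k, 3).values - W[2])
            for k in range(1, full_rank + 1)]
    assert np.all(np.diff(errs) <= 1e-9)
    mean = W.mean(axis=0)
    disp = np.stack([sos_pca_reduced(tables, 1, n).values - mean
                     for n in (1, 2, 3, 4, 5)])
    assert np.linalg.matrix_rank(disp, tol=1e-8) == 1
    with pytest.raises(ValueError):
        sos_pca_reduced(tables, len(W), 1)
    with pytest.raises(ValueError):
        sos_pca_reduced(tables, 0, 1)


def test_sos_vector_validation():
    with pytest.raises(ValueError):
        SoSVector(np.zeros((2, 2)))


# ---------------------------------------------------------------------------
# conditional (teacher-forced) generation


def test_conditional_generation_uniform_pmf_is_chance(rng):
    """Zero head weights give uniform PMFs: argmax agreement with a random
    image sits at chance 1/p."""
    est = small_estimator(vocab=4)
    est.core_.head.W.value[...] = 0.0
    est.core_.head.b.value[...] = 0.0
    rates = []
    for _ in range(40):
        img = rng.integers(0, 4, size=(6, 6))
        _, agree = conditional_generate(est, img, 1)
        rates.append(agree)
    assert abs(np.mean(rates) - 0.25) < 0.05


def test_conditional_generation_confident_model_is_perfect():
    """A model whose PMFs are (near) one-hot at a constant level rebuilds a
    constant image exactly."""
    est = small_estimator(vocab=3)
    est.core_.head.W.value[...] = 0.0
    est.core_.head.b.value[...] = 0.0
    est.core_.head.b.value[2] = 50.0
    img = np.full((6, 6), 2)
    rebuilt, agree = conditional_generate(est, img, 1)
    assert agree == 1.0
    assert np.array_equal(rebuilt, img)


def test_conditional_generation_rejects_untrained_numerosity(rng):
    est = small_estimator()
    with pytest.raises(KeyError):
        conditional_generate(est, rng.integers(0, 2, (6, 6)), 5)


# ---------------------------------------------------------------------------
# spontaneous generation


def test_spontaneous_batch_size_and_determinism():
    est = small_estimator()
    sos = sos_trained(est.tables_, 1)
    b1 = spontaneous_generate(est, sos, rng=np.random.default_rng(3))
    assert len(b1) == 64  # default batch size per seed
    assert b1.images.shape == (64, 6, 6)
    b2 = spontaneous_generate(est, sos, rng=np.random.default_rng(3))
    np.testing.assert_array_equal(b1.images, b2.images)
    b3 = spontaneous_generate(est, sos, rng=np.random.default_rng(4))
    assert not np.array_equal(b1.images, b3.images)


def test_incremental_equals_full_recompute():
    """The KV-cache decoder and step-wise full-prefix recomputation follow
    identical PMFs, hence identical draws from the same stream."""
    est = small_estimator(vocab=3)
    sos = sos_trained(est.tables_, 2)
    fast = spontaneous_generate(est, sos, count=8,
                                rng=np.random.default_rng(9),
                                incremental=True)
    slow = spontaneous_generate(est, sos, count=8,
                                rng=np.random.default_rng(9),
                                incremental=False)
    np.testing.assert_array_equal(fast.images, slow.images)


def test_spontaneous_near_deterministic_model_matches_greedy():
    est = small_estimator(vocab=3)
    est.core_.head.W.value[...] = 0.0
    est.core_.head.b.value[...] = 0.0
    est.core_.head.b.value[1] = 50.0
    sos = sos_trained(est.tables_, 1)
    batch = spontaneous_generate(est, sos, count=4,
                                 rng=np.random.default_rng(0))
    assert np.all(batch.images == 1)
    greedy, _ = conditional_generate(est, np.full((6, 6), 1), 1)
    np.testing.assert_array_equal(batch.images[0], greedy)


def test_spontaneous_rejects_wrong_seed_dimension():
    est = small_estimator()
    with pytest.raises(ValueError):
        spontaneous_generate(est, SoSVector(np.zeros(5)))


def test_sample_batch_records_provenance():
    est = small_estimator()
    sos = sos_trained(est.tables_, 1)
    batch = spontaneous_generate(est, sos, count=2,
                                 rng=np.random.default_rng(1))
    assert batch.sos.provenance == ("trained", 1)
    assert "bit_generator_state" in batch.draw_log
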