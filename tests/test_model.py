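"""Architecture contracts: masking, embeddings, causality, PMF validity."""

import numpy as np
import pytest

from numgen.model import (ModelConfig, TransformerCore, causal_mask,
                          embed_sequence, encoder_forward, output_pmfs)
from numgen._nn import softmax

from conftest import toy_core


# ---------------------------------------------------------------------------
# causal mask


def test_causal_mask_structure():
    assert causal_mask(1).tolist() == [[True]]
    m3 = causal_mask(3)
    assert m3.sum() == 6  # lower triangle including the diagonal
    assert np.array_equal(m3, np.tril(np.ones((3, 3), bool)))
    assert not m3[0, 1:].any()  # the seed attends only to itself
    with pytest.raises(ValueError):
        causal_mask(0)


# ---------------------------------------------------------------------------
# embeddings


def test_embed_sequence_layout(rng):
    core = toy_core()
    h0 = embed_sequence([], 1, core)
    assert h0.shape == (1, 8)
    np.testing.assert_allclose(h0[0], core.Ws.value[0] + core.WE.value[0])

    prefix = [0, 2, 1]
    h = embed_sequence(prefix, 2, core)
    for i, v in enumerate(prefix):
        np.testing.assert_allclose(
            h[i + 1], core.Wx.value[v] + core.WE.value[i + 1])


def test_embed_sequence_zero_tables_leave_positional_rows(rng):
    core = toy_core()
    core.Wx.value[...] = 0.0
    h = embed_sequence([1, 0], np.zeros(8), core)
    np.testing.assert_allclose(h, core.WE.value[:3])


def test_embed_sequence_swap_changes_only_swapped_rows():
    core = toy_core()
    a = embed_sequence([0, 1, 2, 2], 1, core)
    b = embed_sequence([0, 2, 1, 2], 1, core)
    diff = ~np.all(np.isclose(a, b), axis=1)
    assert diff.tolist() == [False, False, True, True, False]


def test_embed_sequence_accepts_external_vector_and_validates():
    core = toy_core()
    vec = np.linspace(0, 1, 8)
    h = embed_sequence([0], vec, core)
    np.testing.assert_allclose(h[0], vec + core.WE.value[0])
    with pytest.raises(ValueError, match="8"):  # r is named in the message
        embed_sequence([0] * 20, 1, core)
    with pytest.raises(ValueError):
        embed_sequence([5], 1, core)  # intensity out of vocabulary
    with pytest.raises(KeyError):
        embed_sequence([0], 7, core)  # untrained numerosity


# ---------------------------------------------------------------------------
# encoder and output head


def test_zero_layer_stack_is_identity(rng):
    core = toy_core(layers=0)
    h0 = rng.normal(size=(4, 8))
    out = encoder_forward(h0, causal_mask(4), core)
    np.testing.assert_allclose(out, h0)


def test_output_pmfs_rows_are_distributions(rng):
    core = toy_core()
    hl = rng.normal(size=(5, 8))
    P, logits = output_pmfs(hl, core, return_logits=True)
    np.testing.assert_allclose(P.sum(axis=-1), 1.0, atol=1e-6)
    assert np.all(P >= 0)
    assert np.array_equal(P.argmax(-1), logits.argmax(-1))
    core.head.W.value[...] = 0.0
    core.head.b.value[...] = 0.0
    np.testing.assert_allclose(output_pmfs(hl, core), 1.0 / 3.0)


def test_autoregressive_causality_exhaustive():
    """Perturbing input pixel j never changes output rows 0..j: the PMF for
    pixel i depends only on the seed and pixels before i.  Exhaustive over
    all positions of a 9-pixel toy model."""
    core = toy_core(n_pixels=9, layers=2)
    rng = np.random.default_rng(0)
    prefix = rng.integers(0, 3, size=(1, 8))
    base = core.forward(prefix, core.Ws.value[[0]])[0]
    for j in range(8):
        for v in range(3):
            if v == prefix[0, j]:
                continue
            pert = prefix.copy()
            pert[0, j] = v
            out = core.forward(pert, core.Ws.value[[0]])[0]
            np.testing.assert_allclose(out[:j + 1], base[:j + 1], atol=1e-10,
                                       err_msg=f"row <= {j} changed by "
                                               f"perturbing pixel {j}")
            assert not np.allclose(out[j + 1], base[j + 1])


def test_prefix_consistency_full_vs_growing():
    """Teacher-forced rows for a prefix agree with the rows computed from
    any longer sequence sharing that prefix — the property that makes
    incremental sampling valid."""
    core = toy_core(n_pixels=12, layers=2)
    rng = np.random.default_rng(3)
    seq = rng.integers(0, 3, size=11)
    sos = core.Ws.value[[1]]
    full = core.forward(seq[None], sos)[0]
    for q in (1, 4, 8):
        part = core.forward(seq[None, :q], sos)[0]
        np.testing.assert_allclose(part, full[:q + 1], atol=1e-10)


def test_incremental_cache_matches_full_pass():
    core = toy_core(n_pixels=10, layers=2)
    rng = np.random.default_rng(4)
    seq = rng.integers(0, 3, size=(2, 9))
    sos = core.Ws.value[[0, 1]]
    full = core.forward(seq, sos)
    cache = core.start_cache(2)
    token = sos + core.WE.value[0]
    rows = [cache.step(token)]
    for i in range(9):
        token = core.Wx.value[seq[:, i]] + core.WE.value[i + 1]
        rows.append(cache.step(token))
    np.testing.assert_allclose(np.stack(rows, axis=1), full, atol=1e-10)


def test_unmasked_encoder_is_permutation_equivariant():
    """With the permission mask fully open, permuting input rows permutes
    output rows identically: the encoder itself carries no notion of
    position or scan order — order is imposed only by the causal mask and
    the learned positional table, and once fixed must be maintained."""
    core = toy_core(n_pixels=8, layers=2)
    rng = np.random.default_rng(5)
    h0 = rng.normal(size=(6, 8))
    full = np.ones((6, 6), dtype=bool)
    out = encoder_forward(h0, full, core)
    perm = rng.permutation(6)
    out_perm = encoder_forward(h0[perm], full, core)
    np.testing.assert_allclose(out_perm, out[perm], atol=1e-10)


def test_row_stochasticity_under_random_inputs():
    core = toy_core(n_pixels=16, layers=2)
    rng = np.random.default_rng(6)
    for _ in range(5):
        prefix = rng.integers(0, 3, size=(3, rng.integers(0, 16)))
        P = core.pmfs(prefix, core.Ws.value[[0, 1, 0]])
        np.testing.assert_allclose(P.sum(axis=-1), 1.0, atol=1e-6)


# ---------------------------------------------------------------------------
# config validation and checkpointing


def test_model_config_validation():
    with pytest.raises(ValueError):
        ModelConfig(d_model=30, n_heads=4)
    with pytest.raises(ValueError):
        ModelConfig(numerosities=())
    cfg = ModelConfig(numerosities=(3, 1, 2))
    assert cfg.numerosities == (1, 2, 3)  # ascending row convention


def test_checkpoint_roundtrip(tmp_path):
    core = toy_core(n_pixels=9, layers=1)
    rng = np.random.default_rng(7)
    prefix = rng.integers(0, 3, size=(2, 5))
    before = core.forward(prefix, core.Ws.value[[0, 1]])
    path = tmp_path / "ckpt.zip"
    core.save(path)
    back = TransformerCore.load(path)
    assert back.config == core.config
    np.testing.assert_allclose(
        back.forward(prefix, back.Ws.value[[0, 1]]), before)
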