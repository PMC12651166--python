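"""Cross-attention, residual mix, pooling, prediction head and loss."""

import numpy as np
import pytest

import dtifuse._autodiff as ad
from dtifuse import (DTIModel, bce_loss, cross_attend, featurize_batch,
                     pool_and_concat, predict, residual_mix)
from dtifuse.interaction_fusion import CrossAttention, PredictionHead


def _cross(rng, d_drug=4, d_prot=4, d_k=4):
    return CrossAttention(d_drug, d_prot, d_k, rng)


# -- cross-attention ------------------------------------------------------

def test_singleton_attention_weight_is_one(rng):
    ca = _cross(rng)
    out = cross_attend(rng.normal(size=(1, 1, 4)), rng.normal(size=(1, 1, 4)),
                       ca, np.ones((1, 1)), np.ones((1, 1)))
    np.testing.assert_allclose(out.attn_d.data, 1.0, atol=1e-7)
    np.testing.assert_allclose(out.attn_p.data, 1.0, atol=1e-7)


def test_identical_keys_give_uniform_attention(rng):
    ca = _cross(rng)
    f_p = np.tile(rng.normal(size=(1, 1, 4)), (1, 5, 1))  # identical rows
    out = cross_attend(rng.normal(size=(1, 3, 4)), f_p, ca,
                       np.ones((1, 3)), np.ones((1, 5)))
    np.testing.assert_allclose(out.attn_d.data, 0.2, atol=1e-6)


def test_attention_matches_bruteforce_softmax_oracle(rng):
    ca = _cross(rng)
    f_d = rng.normal(size=(1, 3, 4))
    f_p = rng.normal(size=(1, 5, 4))
    out = cross_attend(f_d, f_p, ca, np.ones((1, 3)), np.ones((1, 5)))
    q = f_d[0] @ ca.params["cross.wq_d"].data
    k = f_p[0] @ ca.params["cross.wk_p"].data
    logits = q @ k.T / np.sqrt(4)
    for i in range(3):
        row = np.array([np.exp(v) for v in logits[i]])
        row = row / row.sum()
        np.testing.assert_allclose(out.attn_d.data[0, i], row, atol=1e-6)
    v = f_p[0] @ ca.params["cross.wv_p"].data
    np.testing.assert_allclose(out.z_d.data[0], out.attn_d.data[0] @ v,
                               atol=1e-6)


def test_attention_rows_sum_to_one_under_padding(rng):
    ca = _cross(rng)
    pm = np.array([[1.0, 1.0, 1.0, 0.0, 0.0]])
    out = cross_attend(rng.normal(size=(1, 3, 4)), rng.normal(size=(1, 5, 4)),
                       ca, np.ones((1, 3)), pm)
    np.testing.assert_allclose(out.attn_d.data.sum(-1), 1.0, atol=1e-6)
    assert np.abs(out.attn_d.data[:, :, 3:]).max() < 1e-9


def test_all_masked_keys_is_an_error(rng):
    ca = _cross(rng)
    with pytest.raises(ValueError, match="valid residues"):
        cross_attend(rng.normal(size=(1, 3, 4)), rng.normal(size=(1, 5, 4)),
                     ca, np.ones((1, 3)), np.zeros((1, 5)))


# -- residual mix ---------------------------------------------------------

def test_equal_inputs_are_a_fixed_point(rng):
    f = rng.normal(size=(3, 4))
    np.testing.assert_allclose(residual_mix(f, f).data, f)


def test_zero_attention_halves_the_features(rng):
    f = rng.normal(size=(3, 4))
    np.testing.assert_allclose(residual_mix(np.zeros_like(f), f).data, 0.5 * f)


def test_mix_is_the_elementwise_average(rng):
    z, f = rng.normal(size=(4, 5)), rng.normal(size=(4, 5))
    want = np.array([[(z[i, j] + f[i, j]) / 2 for j in range(5)]
                     for i in range(4)])
    np.testing.assert_allclose(residual_mix(z, f).data, want, atol=1e-7)


def test_mix_shape_mismatch_raises(rng):
    with pytest.raises(ValueError, match="mismatch"):
        residual_mix(rng.normal(size=(3, 4)), rng.normal(size=(4, 3)))


# -- pooling and head ------------------------------------------------------

def test_single_row_pooling_concatenates_the_rows(rng):
    d = rng.normal(size=(1, 1, 3))
    p = rng.normal(size=(1, 1, 4))
    f = pool_and_concat(d, p, np.ones((1, 1)), np.ones((1, 1)))
    np.testing.assert_allclose(f.data[0], np.concatenate([d[0, 0], p[0, 0]]))


def test_masked_rows_never_reach_the_max(rng):
    d = rng.normal(size=(1, 3, 4))
    p = rng.normal(size=(1, 2, 4))
    f0 = pool_and_concat(d, p, np.ones((1, 3)), np.ones((1, 2)))
    d2 = np.concatenate([d, d.max() + 5 + rng.random((1, 2, 4))], axis=1)
    dm = np.array([[1.0, 1.0, 1.0, 0.0, 0.0]])
    f1 = pool_and_concat(d2, p, dm, np.ones((1, 2)))
    np.testing.assert_allclose(f0.data, f1.data)


def test_pooling_matches_column_max_loop(rng):
    d = rng.normal(size=(1, 5, 3))
    p = rng.normal(size=(1, 4, 2))
    f = pool_and_concat(d, p, np.ones((1, 5)), np.ones((1, 4)))
    want = ([max(d[0, i, j] for i in range(5)) for j in range(3)]
            + [max(p[0, i, j] for i in range(4)) for j in range(2)])
    np.testing.assert_allclose(f.data[0], want, atol=1e-7)


def test_zero_valid_rows_rejected(rng):
    with pytest.raises(ValueError, match="zero valid"):
        pool_and_concat(rng.normal(size=(1, 2, 3)), rng.normal(size=(1, 2, 3)),
                        np.zeros((1, 2)), np.ones((1, 2)))


def test_zero_weights_give_even_odds(rng):
    head = PredictionHead(4, hidden=(), dropout=0.0, rng=rng)
    head.params["head.fc0_w"].data[:] = 0.0
    head.params["head.fc0_b"].data[:] = 0.0
    p = predict(rng.normal(size=(3, 4)), head)
    np.testing.assert_allclose(p.data, 0.5)


def test_probability_monotone_in_bias(rng):
    head = PredictionHead(4, hidden=(), dropout=0.0, rng=rng)
    f = rng.normal(size=(1, 4))
    probs = []
    for b in (-5.0, 0.0, 5.0, 20.0):
        head.params["head.fc0_b"].data[:] = b
        probs.append(float(predict(f, head).data[0]))
    assert probs == sorted(probs)
    assert probs[-1] > 0.999
    assert all(0 < p < 1 for p in probs)


def test_single_linear_head_matches_closed_form(rng):
    head = PredictionHead(6, hidden=(), dropout=0.0, rng=rng)
    f = rng.normal(size=(2, 6))
    w = head.params["head.fc0_w"].data
    b = head.params["head.fc0_b"].data
    want = 1.0 / (1.0 + np.exp(-(f @ w + b)))
    np.testing.assert_allclose(predict(f, head).data, want[:, 0], atol=1e-6)


def test_head_dimension_mismatch_raises(rng):
    head = PredictionHead(6, hidden=(4,), dropout=0.0, rng=rng)
    with pytest.raises(ValueError, match="width"):
        predict(rng.normal(size=(2, 5)), head)


# -- loss ------------------------------------------------------------------

def test_perfect_prediction_has_near_zero_loss():
    loss = bce_loss([1, 0], [1.0 - 1e-7, 1e-7])
    assert loss.data < 1e-5


def test_even_odds_loss_is_ln2():
    loss = bce_loss([1, 0, 1], [0.5, 0.5, 0.5])
    np.testing.assert_allclose(loss.data, np.log(2.0), atol=1e-6)


def test_loss_matches_per_sample_loop(rng):
    y = rng.integers(0, 2, size=12)
    p = rng.uniform(0.01, 0.99, size=12)
    want = np.mean([-(yi * np.log(pi) + (1 - yi) * np.log(1 - pi))
                    for yi, pi in zip(y, p)])
    np.testing.assert_allclose(bce_loss(y, p).data, want, atol=1e-6)


def test_non_binary_labels_rejected():
    with pytest.raises(ValueError, match="0 or 1"):
        bce_loss([0, 2], [0.5, 0.5])


# -- end-to-end contracts --------------------------------------------------

def test_padding_growth_never_changes_the_probability(tiny_config):
    big = tiny_config.replace(n_atoms_max=32, seq_len_max=32)
    m_small = DTIModel(tiny_config)
    m_big = DTIModel(big)
    m_big.load_state(m_small.state_dict())   # same channel widths
    pairs = [("CC(N)C(=O)O", "ACDHKHMW"), ("CNC", "MKWVTFIS")]
    for smiles, seq in pairs:
        ps = m_small.predict_pairs([smiles], [seq])[0]
        pb = m_big.predict_pairs([smiles], [seq])[0]
        assert abs(ps - pb) < 1e-6


def test_nocross_has_strictly_fewer_parameters_and_skips_attention(
        tiny_config, tiny_batch):
    full = DTIModel(tiny_config)
    nocross = DTIModel(tiny_config.replace(ablation="nocross"))
    assert nocross.parameter_count() < full.parameter_count()
    nocross.forward(tiny_batch)
    assert nocross.cross_attend_calls == 0
    full.forward(tiny_batch)
    assert full.cross_attend_calls == 1


def test_every_parameter_receives_gradient_on_generic_batch(
        tiny_config, tiny_batch):
    model = DTIModel(tiny_config)
    loss = model.loss(tiny_batch, [1, 0, 1, 0], training=False)
    loss.backward()
    for name, p in model.parameters().items():
        assert p.grad is not None, f"{name} got no gradient"
        assert np.abs(p.grad).max() > 0, f"{name} gradient identically zero"
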