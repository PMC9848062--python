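"""Cross-attention contracts: softmax normalization, degenerate keys,
hand-computed scalar examples, role asymmetry and the full forward pass."""

import numpy as np
import pytest

from cpifuse.attention import (
    CrossAttention, CompoundFusion, LatentStack, InteractionAttention,
    AffinityHead,
)
from cpifuse.nn import Tensor
from cpifuse.model import AffinityModel
from cpifuse._molecules import DRUG_SMILES


def set_identity(lin):
    n = min(lin.W.shape)
    lin.W.data = np.eye(*lin.W.shape)
    lin.b.data[:] = 0.0


def test_energy_rows_sum_to_one(rng):
    att = CrossAttention(4, 4, 8, rng, heads=2)
    q = Tensor(rng.normal(size=(3, 5, 4)))
    kv = Tensor(rng.normal(size=(3, 7, 4)))
    e = att.energies(q, kv).numpy()
    assert e.shape == (3, 2, 5, 7)
    np.testing.assert_allclose(e.sum(axis=-1), np.ones((3, 2, 5)), atol=1e-6)


def test_single_key_degeneracy(rng):
    """With one key/value token the energy is identically 1 and the output
    is f_0(f_V(kv)) for any query."""
    att = CrossAttention(4, 4, 8, rng)
    q = Tensor(rng.normal(size=(2, 3, 4)))
    kv = Tensor(rng.normal(size=(2, 1, 4)))
    e = att.energies(q, kv).numpy()
    np.testing.assert_array_equal(e, np.ones_like(e))
    out = att(q, kv).numpy()
    expected = att.f_0(att.f_V(kv)).numpy()
    for t in range(3):
        np.testing.assert_allclose(out[:, t], expected[:, 0], atol=1e-10)


def test_identical_keys_uniform_energy(rng):
    att = CrossAttention(4, 4, 8, rng)
    q = Tensor(rng.normal(size=(2, 4)))
    row = rng.normal(size=4)
    kv = Tensor(np.tile(row, (5, 1)))
    e = att.energies(q, kv).numpy()
    np.testing.assert_allclose(e, np.full_like(e, 1.0 / 5), atol=1e-12)
    out = att(q, kv).numpy()
    expected = att.f_0(att.f_V(Tensor(row[None, :]))).numpy()[0]
    np.testing.assert_allclose(out, np.tile(expected, (2, 1)), atol=1e-10)


def test_hand_computed_2x2_attention():
    """1-D projections, 2 queries x 2 keys, evaluated by scalar arithmetic."""
    rng = np.random.default_rng(0)
    att = CrossAttention(1, 1, 1, rng, heads=1)
    att.f_Q.W.data = np.array([[2.0]]); att.f_Q.b.data = np.array([0.5])
    att.f_K.W.data = np.array([[1.0]]); att.f_K.b.data = np.array([-1.0])
    att.f_V.W.data = np.array([[3.0]]); att.f_V.b.data = np.array([0.0])
    att.f_0.W.data = np.array([[1.0]]); att.f_0.b.data = np.array([0.25])
    q = Tensor(np.array([[1.0], [2.0]]))
    kv = Tensor(np.array([[0.0], [1.0]]))
    # Q = [2.5, 4.5]; K = [-1, 0]; V = [0, 3]; scale = sqrt(1) = 1
    # row i energies = softmax([-Q_i, 0])
    e = att.energies(q, kv).numpy()[0]
    for i, qv in enumerate([2.5, 4.5]):
        scores = np.array([-qv, 0.0])
        expect = np.exp(scores) / np.exp(scores).sum()
        np.testing.assert_allclose(e[i], expect, atol=1e-9)
    out = att(q, kv).numpy()
    for i in range(2):
        np.testing.assert_allclose(
            out[i, 0], e[i, 1] * 3.0 + 0.25, atol=1e-9
        )


def test_literal_energy_scaling_switch(rng):
    """The alternative literal reading multiplies scores by C/d."""
    att_s = CrossAttention(2, 2, 4, rng, energy_scale="sqrt")
    att_l = CrossAttention(2, 2, 4, np.random.default_rng(0),
                           energy_scale="linear")
    att_l.load_state_dict(att_s.state_dict())
    q = Tensor(rng.normal(size=(1, 3, 2)))
    kv = Tensor(rng.normal(size=(1, 3, 2)))
    e_s = att_s.energies(q, kv).numpy()
    e_l = att_l.energies(q, kv).numpy()
    assert not np.allclose(e_s, e_l)


def test_key_permutation_equivariance(rng):
    att = CrossAttention(4, 4, 8, rng)
    q = Tensor(rng.normal(size=(2, 4)))
    kv = rng.normal(size=(6, 4))
    perm = rng.permutation(6)
    out1 = att(q, Tensor(kv)).numpy()
    out2 = att(q, Tensor(kv[perm])).numpy()
    np.testing.assert_allclose(out1, out2, atol=1e-10)
    e1 = att.energies(q, Tensor(kv)).numpy()
    e2 = att.energies(q, Tensor(kv[perm])).numpy()
    np.testing.assert_allclose(e1[..., perm], e2, atol=1e-10)


def test_nonfinite_inputs_raise(rng):
    att = CrossAttention(4, 4, 8, rng)
    bad = np.full((1, 2, 4), np.nan)
    with pytest.raises(FloatingPointError):
        att(Tensor(bad), Tensor(np.zeros((1, 2, 4))))


def test_fusion_single_token_reduces_to_one_key_case(rng):
    fus = CompoundFusion(8, 8, 1, 4, rng)
    o_ms = Tensor(rng.normal(size=(2, 8)))
    o_gs = Tensor(rng.normal(size=(2, 8)))
    out = fus(o_ms, o_gs).numpy()
    expected = fus.attn.f_0(fus.attn.f_V(o_gs.reshape(2, 1, 8))).numpy()
    np.testing.assert_allclose(out, expected.reshape(2, 4), atol=1e-10)


def test_fusion_role_asymmetry(rng):
    fus = CompoundFusion(8, 8, 2, 4, rng)
    a = Tensor(rng.normal(size=(1, 8)))
    b = Tensor(rng.normal(size=(1, 8)))
    assert not np.allclose(fus(a, b).numpy(), fus(b, a).numpy())


def test_fusion_hand_case_two_tokens():
    """n_tokens = 2, scalar token dims, hand-evaluated energies."""
    rng = np.random.default_rng(0)
    fus = CompoundFusion(2, 2, 2, 1, rng)
    for lin in (fus.attn.f_Q, fus.attn.f_K, fus.attn.f_V, fus.attn.f_0):
        set_identity(lin)
    o_ms = Tensor(np.array([[1.0, 2.0]]))
    o_gs = Tensor(np.array([[3.0, 5.0]]))
    out = fus(o_ms, o_gs).numpy()[0]
    for i, qv in enumerate([1.0, 2.0]):
        scores = np.array([qv * 3.0, qv * 5.0])
        e = np.exp(scores - scores.max())
        e = e / e.sum()
        np.testing.assert_allclose(out[i], e @ np.array([3.0, 5.0]),
                                   atol=1e-9)


def test_fusion_rejects_indivisible_lengths(rng):
    with pytest.raises(ValueError):
        CompoundFusion(9, 8, 4, 4, rng)


def test_latent_stack_zero_blocks_is_identity(rng):
    stk = LatentStack(4, 8, 0, rng)
    x = rng.normal(size=(2, 32))
    out = stk(Tensor(x)).numpy()
    np.testing.assert_array_equal(out, x.reshape(2, 4, 8))


def test_latent_stack_zero_output_projections_residual_identity(rng):
    stk = LatentStack(4, 8, 1, rng)
    blk = stk.blocks[0]
    blk.attn.f_0.W.data[:] = 0.0
    blk.attn.f_0.b.data[:] = 0.0
    blk.ff.layers[-1].W.data[:] = 0.0
    blk.ff.layers[-1].b.data[:] = 0.0
    x = rng.normal(size=(2, 32))
    np.testing.assert_allclose(stk(Tensor(x)).numpy(),
                               x.reshape(2, 4, 8), atol=1e-12)


def test_interaction_constant_protein_rows(rng):
    """If all protein rows are identical the interaction vector does not
    depend on the attention energies."""
    ia = InteractionAttention(8, 6, 8, rng)
    row = rng.normal(size=6)
    prot = Tensor(np.tile(row, (1, 9, 1)))
    lat1 = Tensor(rng.normal(size=(1, 4, 8)))
    lat2 = Tensor(rng.normal(size=(1, 4, 8)))
    np.testing.assert_allclose(ia(lat1, prot).numpy(),
                               ia(lat2, prot).numpy(), atol=1e-10)


def test_interaction_zero_latents_uniform_energy(rng):
    ia = InteractionAttention(8, 6, 8, rng)
    ia.attn.f_Q.b.data[:] = 0.0
    prot_rows = rng.normal(size=(1, 5, 6))
    lat = Tensor(np.zeros((1, 4, 8)))
    e = ia.attn.energies(lat, Tensor(prot_rows)).numpy()
    np.testing.assert_allclose(e, np.full_like(e, 0.2), atol=1e-12)
    out = ia(lat, Tensor(prot_rows)).numpy()
    mean_v = ia.attn.f_V(Tensor(prot_rows)).numpy().mean(axis=1)
    expected = ia.attn.f_0(Tensor(mean_v)).numpy()
    np.testing.assert_allclose(out, expected, atol=1e-10)


def test_affinity_head_zero_weights_gives_bias(rng):
    head = AffinityHead(8, 4, rng)
    for layer in head.mlp.layers:
        layer.W.data[:] = 0.0
    head.mlp.layers[-1].b.data[:] = 1.75
    out = head(Tensor(rng.normal(size=(3, 8)))).numpy()
    np.testing.assert_allclose(out, np.full(3, 1.75), atol=1e-12)


def test_full_forward_finite_and_deterministic(tiny_config):
    """Every fixture molecule with a random protein gives a finite,
    seed-reproducible prediction."""
    model = AffinityModel(tiny_config)
    rng = np.random.default_rng(5)
    seqs = ["".join(rng.choice(list("ACDEFGHIKLMNPQRSTVWY"), size=25))
            for _ in DRUG_SMILES]
    pred1 = model.predict(DRUG_SMILES, seqs)
    assert np.all(np.isfinite(pred1))
    pred2 = AffinityModel(tiny_config).predict(DRUG_SMILES, seqs)
    np.testing.assert_array_equal(pred1, pred2)
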