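"""Network blocks: residual identities, explicit-loop oracles, loss algebra."""

import math

import numpy as np
import pytest

from tmcontact import net as nx
from tmcontact.net import (ContactNet, ModelConfig, ResNetInceptionBlock,
                           Transition, TriangleAttention, TriangleBlock,
                           TriangleUpdate, distance_gate, focal_loss)
from tmcontact.nn.autodiff import Tensor


def rand_t(shape, seed, scale=1.0):
    return np.random.default_rng(seed).normal(0, scale, size=shape)


def sigmoid(x):
    return 1.0 / (1.0 + np.exp(-x))


def layer_norm(x, gamma, beta, eps=1e-5):
    mu = x.mean(-1, keepdims=True)
    var = ((x - mu) ** 2).mean(-1, keepdims=True)
    return gamma * (x - mu) / np.sqrt(var + eps) + beta


def apply_norm_linear(mod, x):
    return layer_norm(x, mod.norm.gamma.data, mod.norm.beta.data) \
        @ mod.lin.weight.data + mod.lin.bias.data


class TestDistanceGate:
    def test_closed_form_values(self):
        assert distance_gate(np.array(0.0)) == pytest.approx(1.0)
        assert distance_gate(np.array(8.0)) == pytest.approx(math.exp(-0.5), abs=1e-6)
        assert distance_gate(np.array(np.inf)) == 0.0


@pytest.mark.usefixtures("float64_params")
class TestTriangleUpdate:
    def test_zero_initialized_output_map_is_identity(self):
        rng = np.random.default_rng(0)
        blk = TriangleUpdate(4, rng)
        blk.out.lin.zero_init()
        z = Tensor(rand_t((3, 5, 4), 1))
        r = Tensor(rand_t((3, 3, 4), 2))
        l = Tensor(rand_t((5, 5, 4), 3))
        out = blk(z, r, l)
        np.testing.assert_array_equal(out.data, z.data)

    def test_matches_triple_loop_oracle(self):
        rng = np.random.default_rng(4)
        d, L1, L2 = 4, 3, 4
        blk = TriangleUpdate(d, rng)
        z = rand_t((L1, L2, d), 5)
        r = rand_t((L1, L1, d), 6)
        l = rand_t((L2, L2, d), 7)
        out = blk(Tensor(z), Tensor(r), Tensor(l)).data

        def gate(mod, x):
            return sigmoid(x @ mod.lin.weight.data + mod.lin.bias.data)

        def lin(mod, x):
            return x @ mod.weight.data + mod.bias.data

        zp = lin(blk.lin_z1, gate(blk.gate_z1, z))
        zpp = lin(blk.lin_z2, gate(blk.gate_z2, z))
        rp = lin(blk.lin_r, gate(blk.gate_r, r))
        lp = lin(blk.lin_l, gate(blk.gate_l, l))
        expected = np.empty_like(z)
        for i in range(L1):
            for j in range(L2):
                s = np.zeros(d)
                for m in range(L1):
                    s += rp[i, m] * zp[m, j]
                for n in range(L2):
                    s += zpp[i, n] * lp[n, j]
                phi_out = layer_norm(s, blk.out.norm.gamma.data, blk.out.norm.beta.data)
                phi_out = phi_out @ blk.out.lin.weight.data + blk.out.lin.bias.data
                g = sigmoid(z[i, j] @ blk.gate_out.lin.weight.data
                            + blk.gate_out.lin.bias.data)
                expected[i, j] = z[i, j] + phi_out * g
        np.testing.assert_allclose(out, expected, atol=1e-10)

    def test_masked_residues_excluded_from_sums(self):
        rng = np.random.default_rng(8)
        d, L = 4, 5
        blk = TriangleUpdate(d, rng)
        z, r, l = rand_t((L, L, d), 9), rand_t((L, L, d), 10), rand_t((L, L, d), 11)
        mask = np.array([True, True, False, True, True])
        out_masked = blk(Tensor(z), Tensor(r), Tensor(l), mask, mask).data
        out_unmasked = blk(Tensor(z), Tensor(r), Tensor(l)).data
        assert not np.array_equal(out_masked, out_unmasked)
        # masking is equivalent to feeding z/r/l with the buried index zeroed
        # out in the projected tensors; verify via double masking idempotence
        np.testing.assert_array_equal(
            out_masked, blk(Tensor(z), Tensor(r), Tensor(l), mask, mask).data)


@pytest.mark.usefixtures("float64_params")
class TestTriangleAttention:
    @pytest.mark.parametrize("axis", ["row", "column"])
    def test_matches_explicit_loop_oracle(self, axis):
        rng = np.random.default_rng(12)
        d, h, L1, L2 = 8, 4, 3, 4
        blk = TriangleAttention(d, h, axis, rng)
        z = rand_t((L1, L2, d), 13)
        Lm = L2 if axis == "row" else L1
        dmap = np.abs(rand_t((Lm, Lm), 14, scale=6.0))
        dmap = (dmap + dmap.T) / 2
        np.fill_diagonal(dmap, 0.0)
        out = blk(Tensor(z), dmap).data

        dh = d // h
        zn = layer_norm(z, blk.norm_in.gamma.data, blk.norm_in.beta.data)
        q = (zn @ blk.q.weight.data + blk.q.bias.data).reshape(L1, L2, h, dh)
        k = (zn @ blk.k.weight.data + blk.k.bias.data).reshape(L1, L2, h, dh)
        v = (zn @ blk.v.weight.data + blk.v.bias.data).reshape(L1, L2, h, dh)
        g = distance_gate(dmap)
        expected = np.empty_like(z)
        for i in range(L1):
            for j in range(L2):
                heads = []
                for hh in range(h):
                    if axis == "row":
                        logits = np.array([q[i, j, hh] @ k[i, m, hh] / np.sqrt(dh)
                                           for m in range(L2)])
                        w = np.exp(logits - logits.max())
                        w /= w.sum()
                        w = w * np.array([g[j, m] for m in range(L2)])
                        o = sum(w[m] * v[i, m, hh] for m in range(L2))
                    else:
                        logits = np.array([q[i, j, hh] @ k[m, j, hh] / np.sqrt(dh)
                                           for m in range(L1)])
                        w = np.exp(logits - logits.max())
                        w /= w.sum()
                        w = w * np.array([g[i, m] for m in range(L1)])
                        o = sum(w[m] * v[m, j, hh] for m in range(L1))
                    heads.append(o)
                o = np.concatenate(heads)
                gate = sigmoid(z[i, j] @ blk.gate.lin.weight.data
                               + blk.gate.lin.bias.data)
                expected[i, j] = z[i, j] + apply_norm_linear(blk.out, o * gate)
        np.testing.assert_allclose(out, expected, atol=1e-10)

    def test_softmax_weights_sum_to_one_before_gating(self):
        rng = np.random.default_rng(15)
        blk = TriangleAttention(8, 4, "row", rng)
        z = Tensor(rand_t((3, 4, 8), 16))
        dmap = np.abs(rand_t((4, 4), 17, scale=5.0))
        w_soft, _ = blk.attention_weights(z, distance_gate(dmap), None)
        np.testing.assert_allclose(w_soft.data.sum(axis=2), 1.0, atol=1e-12)

    def test_zero_initialized_output_is_identity(self):
        rng = np.random.default_rng(18)
        blk = TriangleAttention(4, 2, "column", rng)
        blk.out.lin.zero_init()
        z = Tensor(rand_t((4, 3, 4), 19))
        dmap = np.zeros((4, 4))
        np.testing.assert_array_equal(blk(z, dmap).data, z.data)

    def test_fully_masked_keys_keep_residual(self):
        rng = np.random.default_rng(20)
        blk = TriangleAttention(4, 2, "row", rng)
        z = Tensor(rand_t((3, 4, 4), 21))
        dmap = np.zeros((4, 4))
        mask = np.zeros(4, dtype=bool)  # every key buried
        out = blk(z, dmap, key_mask=mask)
        # attention contributes phi(0 * gate); finite and well-defined
        assert np.isfinite(out.data).all()


@pytest.mark.usefixtures("float64_params")
class TestTransitionAndHead:
    def test_zero_initialized_second_layer_is_identity(self):
        rng = np.random.default_rng(22)
        t = Transition(6, rng)
        t.lin2.zero_init()
        z = Tensor(rand_t((4, 5, 6), 23))
        np.testing.assert_array_equal(t(z).data, z.data)

    def test_matches_per_position_oracle(self):
        rng = np.random.default_rng(24)
        t = Transition(4, rng)
        z = rand_t((3, 4, 4), 25)
        out = t(Tensor(z)).data
        for i in range(3):
            for j in range(4):
                x = layer_norm(z[i, j], t.norm.gamma.data, t.norm.beta.data)
                hdn = x @ t.lin1.weight.data + t.lin1.bias.data
                hdn = np.where(hdn > 0, hdn, np.exp(np.minimum(hdn, 0)) - 1)
                expected = z[i, j] + hdn @ t.lin2.weight.data + t.lin2.bias.data
                np.testing.assert_allclose(out[i, j], expected, atol=1e-10)

    def test_shape_preserved(self):
        rng = np.random.default_rng(26)
        t = Transition(8, rng)
        z = Tensor(rand_t((7, 7, 8), 27))
        assert t(z).shape == (7, 7, 8)


class TestResNetInception:
    @pytest.mark.usefixtures("float64_params")
    def test_zero_initialized_fuse_is_identity(self):
        rng = np.random.default_rng(28)
        blk = ResNetInceptionBlock(8, rng)
        blk.fuse.zero_init()
        x = Tensor(rand_t((5, 6, 8), 29))
        np.testing.assert_array_equal(blk(x).data, x.data)

    @pytest.mark.usefixtures("float64_params")
    def test_shape_contract(self):
        rng = np.random.default_rng(30)
        blk = ResNetInceptionBlock(64, rng)
        x = Tensor(rand_t((7, 7, 64), 31))
        assert blk(x).shape == (7, 7, 64)

    @pytest.mark.usefixtures("float64_params")
    def test_matches_branchwise_composition_oracle(self):
        rng = np.random.default_rng(32)
        d = 8
        blk = ResNetInceptionBlock(d, rng)
        x = Tensor(rand_t((5, 5, d), 33))
        out = blk(x).data

        from tmcontact.nn import autodiff as ad

        def branch(conv, norm, inp):
            return ad.elu(norm(conv(inp))).data

        y1 = branch(blk.b1, blk.n1, x)
        y3 = branch(blk.b3, blk.n3, x)
        y5a = ad.elu(blk.n5a(blk.b5a(x)))
        y5 = ad.elu(blk.n5b(blk.b5b(y5a))).data
        cat = Tensor(np.concatenate([y1, y3, y5], axis=-1))
        expected = x.data + blk.nf(blk.fuse(cat)).data
        np.testing.assert_allclose(out, expected, atol=1e-10)


class TestFocalLoss:
    def test_gamma_zero_alpha_one_is_bce(self):
        rng = np.random.default_rng(34)
        p = Tensor(rng.uniform(0.05, 0.95, size=(6, 6)))
        y = rng.random((6, 6)) > 0.7
        loss = focal_loss(p, y, gamma=0.0, alpha=1.0).data
        pc = p.data
        bce = -np.mean(y * np.log(pc) + (~y) * np.log(1 - pc))
        assert loss == pytest.approx(bce, abs=1e-10)

    def test_hand_computed_two_by_two(self):
        p = Tensor(np.array([[0.9, 0.2], [0.6, 0.1]]))
        y = np.array([[1, 0], [1, 0]], dtype=bool)
        # p_t = [[0.9, 0.8], [0.6, 0.9]]
        pt = np.array([[0.9, 0.8], [0.6, 0.9]])
        expected = float(np.mean(-0.25 * (1 - pt) ** 2 * np.log(pt)))
        loss = focal_loss(p, y, gamma=2.0, alpha=0.25).data
        assert loss == pytest.approx(expected, abs=1e-12)

    def test_perfect_prediction_is_near_zero(self):
        y = np.array([[True, False]])
        p = Tensor(y.astype(float))
        loss = focal_loss(p, y, gamma=2.0, alpha=0.25).data
        assert 0.0 <= loss < 1e-12

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            focal_loss(Tensor(np.zeros((3, 3))), np.zeros((4, 4), dtype=bool))


@pytest.fixture(scope="module")
def small_model():
    cfg = ModelConfig(d=8, heads=2, n_res_blocks=2, n_tri_blocks=1,
                      in_channels_monomer=12, in_channels_complex=10)
    return ContactNet(cfg, seed=0)


@pytest.fixture(scope="module")
def small_inputs():
    rng = np.random.default_rng(35)
    L = 9
    rec = rng.normal(size=(L, L, 12)).astype(np.float32)
    cplx = rec[:, :, :10].copy()
    dmap = np.abs(rng.normal(0, 8, size=(L, L)))
    dmap = (dmap + dmap.T) / 2
    np.fill_diagonal(dmap, 0.0)
    surface = np.ones(L, dtype=bool)
    return rec, cplx, dmap, surface


class TestContactNet:

    def test_output_shape_and_range(self, small_model, small_inputs):
        pred = small_model.predict(*small_inputs)
        L = small_inputs[0].shape[0]
        assert pred.probabilities.shape == (L, L)
        assert np.all(pred.probabilities >= 0) and np.all(pred.probabilities <= 1)

    def test_symmetrized_output(self, small_model, small_inputs):
        pred = small_model.predict(*small_inputs)
        assert np.abs(pred.probabilities - pred.probabilities.T).max() == 0.0

    def test_eval_mode_is_deterministic(self, small_model, small_inputs):
        p1 = small_model.predict(*small_inputs)
        p2 = small_model.predict(*small_inputs)
        np.testing.assert_array_equal(p1.probabilities, p2.probabilities)

    def test_all_zero_logits_give_half(self, small_inputs):
        cfg = ModelConfig(d=8, heads=2, n_res_blocks=1, n_tri_blocks=1,
                          in_channels_monomer=12, in_channels_complex=10)
        model = ContactNet(cfg, seed=1)
        model.head.zero_init()
        pred = model.predict(*small_inputs)
        np.testing.assert_allclose(pred.probabilities, 0.5, atol=1e-7)

    def test_gradients_reach_every_parameter_group(self, small_model, small_inputs):
        rec, cplx, dmap, surface = small_inputs
        truth = np.random.default_rng(36).random((9, 9)) > 0.8
        small_model.zero_grad()
        p = small_model.forward_tensor(rec, cplx, dmap, surface)
        focal_loss(p, truth).backward()
        dead = [name for name, prm in small_model.named_parameters()
                if prm.grad is None or not np.any(prm.grad)]
        assert dead == []

    def test_masking_additional_residue_changes_only_its_queries(self, small_inputs):
        # with the network reduced to a single row attention, masking one
        # ligand residue must leave other keys' softmax unchanged only
        # where that residue was not attended; here we just assert the
        # prediction changes and stays finite under a stricter mask
        cfg = ModelConfig(d=8, heads=2, n_res_blocks=1, n_tri_blocks=1,
                          in_channels_monomer=12, in_channels_complex=10)
        model = ContactNet(cfg, seed=2)
        rec, cplx, dmap, surface = small_inputs
        p_full = model.predict(rec, cplx, dmap, surface).probabilities
        stricter = surface.copy()
        stricter[3] = False
        p_masked = model.predict(rec, cplx, dmap, stricter).probabilities
        assert np.isfinite(p_masked).all()
        assert not np.array_equal(p_full, p_masked)

    def test_checkpoint_roundtrip(self, small_model, small_inputs, tmp_path):
        p = tmp_path / "model.h5"
        nx.save_checkpoint(p, small_model)
        back = nx.load_checkpoint(p)
        p1 = small_model.predict(*small_inputs)
        p2 = back.predict(*small_inputs)
        np.testing.assert_array_equal(p1.probabilities, p2.probabilities)

    def test_config_validation(self):
        with pytest.raises(ValueError):
            ModelConfig(d=8, heads=3)
        with pytest.raises(ValueError):
            ModelConfig(dropout=1.0)
        with pytest.raises(ValueError):
            ModelConfig(mask_mode="invert")


class TestTriangleBlockComposition:
    @pytest.mark.usefixtures("float64_params")
    def test_block_equals_sequential_application(self):
        rng = np.random.default_rng(37)
        d, h, L = 4, 2, 5
        blk = TriangleBlock(d, h, rng)
        z = Tensor(rand_t((L, L, d), 38))
        r = Tensor(rand_t((L, L, d), 39))
        dmap = np.abs(rand_t((L, L), 40, scale=6))
        dmap = (dmap + dmap.T) / 2
        np.fill_diagonal(dmap, 0.0)
        mask = np.ones(L, dtype=bool)
        out = blk(z, r, r, dmap, dmap, mask, mask)
        step = blk.update(z, r, r, mask_rec=mask, mask_lig=mask)
        step = blk.attn_row(step, dmap, key_mask=mask)
        step = blk.attn_col(step, dmap, key_mask=mask)
        step = blk.transition(step)
        np.testing.assert_array_equal(out.data, step.data)
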