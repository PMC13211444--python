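"""Contrast-aware feature enhancement: calibration, selection, dual paths,
similarity feedback and the detachment contract."""

import numpy as np
import pytest

from pcrfusion.autodiff import Tensor
from pcrfusion.enhancement import MCFE
from pcrfusion.objectives import intra_class_similarity, supcon_loss

D_FUSED, D_CLIN, D_EMB = 32, 16, 8


@pytest.fixture()
def mcfe(rng):
    return MCFE(d_fused=D_FUSED, d_clin=D_CLIN, d_embed=D_EMB, rng=rng)


def random_inputs(rng, b=5):
    return (Tensor(rng.normal(size=(b, D_FUSED))),
            Tensor(rng.normal(size=(b, D_CLIN))),
            Tensor(rng.uniform(0, 1, (b, 1))),
            Tensor(rng.uniform(0, 1, (b, 1))))


class TestModalCalibration:
    def test_zero_gating_parameters_reduce_to_identity(self, mcfe, rng):
        ffused, _, amri, aclin = random_inputs(rng)
        out = mcfe.modal_calibration(ffused, amri, aclin)
        assert np.allclose(out.data, ffused.data)  # (0.5 + 0.5) * f

    def test_gates_live_in_unit_interval_and_sum_identity(self, mcfe, rng):
        mcfe.gate_w_mri.data[:] = 1.3
        mcfe.gate_b_mri.data[:] = -0.4
        mcfe.gate_w_clin.data[:] = -2.0
        ffused, _, amri, aclin = random_inputs(rng)
        out = mcfe.modal_calibration(ffused, amri, aclin)
        w_mri = 1 / (1 + np.exp(-(amri.data * 1.3 - 0.4)))
        w_clin = 1 / (1 + np.exp(-(aclin.data * -2.0)))
        assert np.all((w_mri > 0) & (w_mri < 1))
        assert np.allclose(out.data, (w_mri + w_clin) * ffused.data, atol=1e-12)


class TestSemanticSelection:
    def test_selection_weights_sum_to_one(self, mcfe, rng):
        ffused, fclin, _, _ = random_inputs(rng)
        selected = mcfe.semantic_selection(ffused, fclin)
        weights = selected.data / ffused.data
        assert np.allclose(weights.sum(axis=1), 1.0, atol=1e-6)

    def test_uniform_logits_divide_by_width(self, mcfe, rng):
        mcfe.select.weight.data[:] = 0.0
        mcfe.select.bias.data[:] = 0.0
        ffused, fclin, _, _ = random_inputs(rng)
        selected = mcfe.semantic_selection(ffused, fclin)
        assert np.allclose(selected.data, ffused.data / D_FUSED, atol=1e-12)

    def test_dominant_logit_masks_to_one_slot(self, mcfe, rng):
        mcfe.select.weight.data[:] = 0.0
        mcfe.select.bias.data[:] = 0.0
        mcfe.select.bias.data[3] = 1e4  # one dominant pre-norm logit
        mcfe.select_norm.gamma.data[:] = 10.0  # sharpen past the norm bound
        ffused, fclin, _, _ = random_inputs(rng)
        selected = mcfe.semantic_selection(ffused, fclin).data
        expected = np.zeros_like(ffused.data)
        expected[:, 3] = ffused.data[:, 3]
        assert np.allclose(selected, expected, atol=1e-8)


class TestDualPath:
    def test_beta_zero_alpha_one_is_plain_relu_path(self, rng):
        mcfe = MCFE(d_fused=D_FUSED, d_clin=D_CLIN, d_embed=D_EMB,
                    beta_init=0.0, rng=rng)
        fsel = Tensor(rng.normal(size=(4, D_FUSED)))
        f1_act, f2_act = mcfe.dual_path_refine(fsel, np.zeros((4, 1)))
        f1 = mcfe.path1_norm(mcfe.path1(fsel))
        assert np.allclose(f1_act.data, np.maximum(f1.data, 0.0), atol=1e-12)
        assert np.all(f1_act.data >= 0)
        assert not np.allclose(f1_act.data, f2_act.data)  # independent paths

    def test_activation_magnitude_nonincreasing_in_similarity(self, mcfe, rng):
        fsel = Tensor(rng.normal(size=(3, D_FUSED)))
        norms = []
        for s in [0.0, 0.5, 1.0, 2.0, 5.0]:
            f1_act, _ = mcfe.dual_path_refine(fsel, np.full((3, 1), s))
            norms.append(np.linalg.norm(f1_act.data))
        assert all(b <= a + 1e-12 for a, b in zip(norms, norms[1:]))

    def test_unclamped_modulation_can_go_negative(self, mcfe, rng):
        fsel = Tensor(rng.normal(size=(2, D_FUSED)))
        f1_act, _ = mcfe.dual_path_refine(fsel, np.full((2, 1), 100.0))
        assert f1_act.data.min() < 0  # (1 - beta*s) < 0, literal form

    def test_clamping_flag_floors_at_zero(self, rng):
        mcfe = MCFE(d_fused=D_FUSED, d_clin=D_CLIN, d_embed=D_EMB,
                    clamp_activation=True, rng=rng)
        fsel = Tensor(rng.normal(size=(2, D_FUSED)))
        f1_act, _ = mcfe.dual_path_refine(fsel, np.full((2, 1), 100.0))
        assert np.allclose(f1_act.data, 0.0)


class TestEnhancedEmbedding:
    def test_equal_paths_average_to_either(self, mcfe, rng):
        f_act = Tensor(rng.normal(size=(3, D_FUSED)))
        mcfe.proj2.weight.data = mcfe.proj1.weight.data.copy()
        mcfe.proj2.bias.data = mcfe.proj1.bias.data.copy()
        z = mcfe.enhanced_embedding(f_act, f_act)
        ref = mcfe.proj1_norm(mcfe.proj1(f_act))
        assert np.allclose(z.data, ref.data, atol=1e-12)

    def test_projection_dims_and_zero_mean(self, mcfe, rng):
        z = mcfe.enhanced_embedding(Tensor(rng.normal(size=(4, D_FUSED))),
                                    Tensor(rng.normal(size=(4, D_FUSED))))
        assert z.shape == (4, D_EMB)


class TestForward:
    def test_beta_zero_two_pass_equals_single_pass(self, rng):
        mcfe = MCFE(d_fused=D_FUSED, d_clin=D_CLIN, d_embed=D_EMB,
                    beta_init=0.0, rng=rng)
        ffused, fclin, amri, aclin = random_inputs(rng)
        labels = np.array([0, 1, 0, 1, 1])
        trained = mcfe(ffused, fclin, amri, aclin, labels=labels)
        inference = mcfe(ffused, fclin, amri, aclin, labels=None)
        assert np.allclose(trained.z_enhanced.data, inference.z_enhanced.data)

    def test_two_pass_equals_manual_chain(self, mcfe, rng):
        ffused, fclin, amri, aclin = random_inputs(rng)
        labels = np.array([0, 1, 0, 1, 1])
        out = mcfe(ffused, fclin, amri, aclin, labels=labels, tau=0.1)
        # manual: pass 1 with s=0, similarity, pass 2
        z0 = mcfe.enhanced_embedding(
            *mcfe.dual_path_refine(
                mcfe.semantic_selection(
                    mcfe.modal_calibration(ffused, amri, aclin), fclin
                ),
                np.zeros((5, 1)),
            )
        )
        s = intra_class_similarity(z0.data, labels, 0.1)
        z1 = mcfe.enhanced_embedding(
            *mcfe.dual_path_refine(
                mcfe.semantic_selection(
                    mcfe.modal_calibration(ffused, amri, aclin), fclin
                ),
                s,
            )
        )
        assert np.allclose(out.s_intra, s, atol=1e-12)
        assert np.allclose(out.z_enhanced.data, z1.data, atol=1e-12)

    def test_deterministic(self, mcfe, rng):
        ffused, fclin, amri, aclin = random_inputs(rng)
        labels = np.array([0, 1, 0, 1, 1])
        a = mcfe(ffused, fclin, amri, aclin, labels=labels).z_enhanced.data
        b = mcfe(ffused, fclin, amri, aclin, labels=labels).z_enhanced.data
        assert np.array_equal(a, b)

    def test_batch_of_one_warns_and_falls_back(self, mcfe, rng):
        ffused, fclin, amri, aclin = random_inputs(rng, b=1)
        with pytest.warns(UserWarning, match="batch"):
            out = mcfe(ffused, fclin, amri, aclin, labels=np.array([1]))
        assert np.allclose(out.s_intra, 0.0)

    def test_similarity_feedback_is_detached(self, mcfe, rng):
        """Gradients must not flow through the pass-1 similarity computation:
        supplying the same s_intra as a fixed constant yields identical
        parameter gradients."""
        ffused, fclin, amri, aclin = random_inputs(rng)
        labels = np.array([0, 1, 0, 1, 1])

        out = mcfe(ffused, fclin, amri, aclin, labels=labels, tau=0.1)
        loss = supcon_loss(out.z_enhanced, labels, tau=0.1)
        mcfe.zero_grad()
        loss.backward()
        grads_auto = {n: p.grad.copy() for n, p in mcfe.named_parameters()}

        z_fixed = mcfe._single_pass(ffused, fclin, amri, aclin, out.s_intra)
        loss_fixed = supcon_loss(z_fixed, labels, tau=0.1)
        mcfe.zero_grad()
        loss_fixed.backward()
        for name, p in mcfe.named_parameters():
            assert np.allclose(grads_auto[name], p.grad, atol=1e-10), name

    def test_conventional_cl_mode_is_plain_projection(self, rng):
        mcfe = MCFE(d_fused=D_FUSED, d_clin=D_CLIN, d_embed=D_EMB,
                    mode="conventional_cl", rng=rng)
        ffused, fclin, amri, aclin = random_inputs(rng)
        out = mcfe(ffused, fclin, amri, aclin, labels=np.array([0, 1, 0, 1, 1]))
        ref = mcfe.proj1_norm(mcfe.proj1(ffused))
        assert np.allclose(out.z_enhanced.data, ref.data)


def test_reduction_oracle_under_neutral_settings(rng):
    """With beta=0, zero gating and uniform selection, the embedding reduces
    to the average of two LayerNorm-affine maps of f_fused / width."""
    mcfe = MCFE(d_fused=D_FUSED, d_clin=D_CLIN, d_embed=D_EMB, beta_init=0.0,
                rng=rng)
    mcfe.select.weight.data[:] = 0.0
    mcfe.select.bias.data[:] = 0.0
    ffused, fclin, amri, aclin = random_inputs(rng)
    out = mcfe(ffused, fclin, amri, aclin, labels=None)

    def layer_norm_np(x):
        mu = x.mean(axis=-1, keepdims=True)
        var = x.var(axis=-1, keepdims=True)
        return (x - mu) / np.sqrt(var + 1e-5)

    f = ffused.data / D_FUSED
    halves = []
    for path, norm, proj, proj_norm in (
        (mcfe.path1, mcfe.path1_norm, mcfe.proj1, mcfe.proj1_norm),
        (mcfe.path2, mcfe.path2_norm, mcfe.proj2, mcfe.proj2_norm),
    ):
        h = np.maximum(layer_norm_np(f @ path.weight.data + path.bias.data), 0.0)
        halves.append(layer_norm_np(h @ proj.weight.data + proj.bias.data))
    expected = 0.5 * (halves[0] + halves[1])
    assert np.allclose(out.z_enhanced.data, expected, atol=1e-6)
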