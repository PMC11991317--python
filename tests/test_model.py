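import numpy as np
import pytest

from msdsanet.autodiff import Tensor
from msdsanet.model import (ABLATION_NAMES, CBAM, DSANet, ECA, ECAConfig,
                            EEGTemporalStream, MSARB, MSDSANet, ModelConfig,
                            ablation_config, cross_entropy, eca_kernel_size,
                            load_checkpoint, save_checkpoint)


# ----------------------------------------------------------- ECA kernel size
@pytest.mark.parametrize("c,expect", [(2, 1), (64, 3), (256, 5), (1152, 5)])
def test_eca_kernel_size_examples(c, expect):
    assert eca_kernel_size(c) == expect


def test_eca_kernel_size_is_odd_and_nondecreasing():
    ks = [eca_kernel_size(c) for c in range(1, 513)]
    assert all(k % 2 == 1 and k >= 1 for k in ks)
    assert all(b >= a for a, b in zip(ks, ks[1:]))
    with pytest.raises(ValueError):
        eca_kernel_size(0)
    with pytest.raises(ValueError):
        ECAConfig(t0=0)


# ------------------------------------------------------------------- ECA op
def test_eca_zero_weights_halve_and_zero_input_stays_zero(rng):
    eca = ECA(8, rng)
    eca.weight.data[:] = 0.0
    x = Tensor(rng.normal(size=(2, 8, 3, 3)))
    np.testing.assert_allclose(eca(x).data, 0.5 * x.data, atol=1e-12)
    zero = Tensor(np.zeros((2, 8, 3, 3)))
    np.testing.assert_array_equal(eca(zero).data, 0.0)


def test_eca_matches_explicit_loop_oracle(rng):
    c = 8                                     # k = 3 for 8 channels
    eca = ECA(c, rng)
    assert eca.k == 3
    w = rng.normal(size=3)
    eca.weight.data[0, 0, 0, :] = w
    x = rng.normal(size=(2, c, 4, 5))
    out = eca(Tensor(x)).data
    # oracle: GAP, zero-padded cross-correlation over channels, sigmoid, scale
    for n in range(2):
        gap = x[n].mean(axis=(1, 2))
        padded = np.concatenate([[0.0], gap, [0.0]])
        conv = np.array([padded[i:i + 3] @ w for i in range(c)])
        weights = 1.0 / (1.0 + np.exp(-conv))
        np.testing.assert_allclose(out[n], x[n] * weights[:, None, None], rtol=1e-10)


# -------------------------------------------------------------------- MSARB
def _zero(module):
    for _, p in module.named_parameters():
        p.data[:] = 0.0


def test_msarb_residual_reduces_to_stem_when_branches_zeroed(rng):
    cfg = ModelConfig.reduced(n_eeg=4, window_samples=16, grid_h=4, grid_w=4)
    block = MSARB(cfg, rng)
    for b in block.branches:
        _zero(b)
    _zero(block.bottleneck)
    block.eval()
    x = Tensor(rng.normal(size=(2, 16, 4, 4)))
    out = block(x).data
    stem = block.stem(x).data
    np.testing.assert_allclose(out, stem, atol=1e-12)


def test_msarb_preserves_spatial_shape_at_full_width(rng):
    cfg = ModelConfig()  # F0 = 64, 128 time samples as input channels
    block = MSARB(cfg, rng)
    block.eval()
    out = block(Tensor(rng.normal(size=(1, 128, 9, 9))))
    assert out.shape == (1, 64, 9, 9)
    assert np.all(np.isfinite(out.data))


def test_msarb_eval_mode_is_deterministic(rng):
    cfg = ModelConfig.reduced(n_eeg=4, window_samples=8, grid_h=3, grid_w=3)
    block = MSARB(cfg, rng)
    block.eval()
    x = Tensor(rng.normal(size=(2, 8, 3, 3)))
    np.testing.assert_array_equal(block(x).data, block(x).data)


# ---------------------------------------------------------- temporal stream
def test_temporal_stream_output_has_32_feature_maps(rng):
    cfg = ModelConfig(n_eeg=32)
    stream = EEGTemporalStream(cfg, rng)
    stream.eval()
    out = stream(Tensor(rng.normal(size=(1, 32, 128))))
    assert out.shape == (1, 32, 1, 128)     # electrode axis collapsed
    assert np.all(np.isfinite(out.data))


def test_temporal_stream_eval_repeatable_and_short_window_rejected(rng):
    cfg = ModelConfig.reduced(n_eeg=4, window_samples=32)
    stream = EEGTemporalStream(cfg, rng)
    stream.eval()
    x = Tensor(rng.normal(size=(2, 4, 32)))
    np.testing.assert_array_equal(stream(x).data, stream(x).data)
    with pytest.raises(ValueError, match="shorter than temporal kernel"):
        stream(Tensor(rng.normal(size=(2, 4, 3))))


# ------------------------------------------------------------------- DSANet
def test_dsanet_output_is_1152_units_with_default_widths(rng):
    cfg = ModelConfig(n_periph=2)
    net = DSANet(cfg, rng)
    assert net.out_channels == 768 + 384 == 1152
    assert net.eca.k == 5                    # adaptive kernel for 1152 channels
    out = net(Tensor(rng.normal(size=(1, 2, 128))))
    assert out.shape == (1, 1152)


def test_dsanet_zero_weights_zero_input_gives_zero(rng):
    cfg = ModelConfig.reduced(n_eeg=4, n_periph=1)
    net = DSANet(cfg, rng)
    _zero(net)
    out = net(Tensor(np.zeros((2, 1, 128))))
    np.testing.assert_array_equal(out.data, 0.0)


def test_dsanet_rejects_windows_shorter_than_long_kernel_chain(rng):
    net = DSANet(ModelConfig.reduced(n_eeg=4, n_periph=1), rng)
    with pytest.raises(ValueError, match="at least"):
        net(Tensor(np.zeros((1, 1, 40))))


# --------------------------------------------------------------------- CBAM
def test_cbam_zero_mlp_gives_half_channel_attention(rng):
    cfg = ModelConfig.reduced(n_eeg=4)
    cbam = CBAM(6, cfg, rng)
    _zero(cbam.mlp1)
    _zero(cbam.mlp2)
    x = Tensor(rng.normal(size=(2, 6, 3, 3)))
    np.testing.assert_allclose(cbam.channel_attention(x).data, 0.5, atol=1e-12)


def test_cbam_spatial_attention_shape_and_range(rng):
    cbam = CBAM(4, ModelConfig.reduced(n_eeg=4), rng)
    x = Tensor(rng.normal(size=(3, 4, 5, 6)))
    att = cbam.spatial_attention(x).data
    assert att.shape == (3, 1, 5, 6)
    assert np.all((att > 0) & (att < 1))
    assert cbam(x).shape == x.shape


def test_cbam_matches_explicit_loop_oracle(rng):
    cfg = ModelConfig.reduced(n_eeg=4, cbam_reduction=2)
    c, h, w = 2, 2, 2
    cbam = CBAM(c, cfg, rng)
    x = rng.normal(size=(1, c, h, w))
    out = cbam(Tensor(x)).data

    def mlp(v):
        h1 = np.maximum(v @ cbam.mlp1.weight.data + cbam.mlp1.bias.data, 0)
        return h1 @ cbam.mlp2.weight.data + cbam.mlp2.bias.data

    sig = lambda z: 1.0 / (1.0 + np.exp(-z))
    f_ca = sig(mlp(x[0].mean(axis=(1, 2))) + mlp(x[0].max(axis=(1, 2))))
    h_ca = x[0] * f_ca[:, None, None]
    pooled = np.stack([h_ca.mean(axis=0), h_ca.max(axis=0)])
    kern = cbam.spatial.weight.data[0]       # [2, 7, 7]
    pad = 3
    padded = np.pad(pooled, ((0, 0), (pad, pad), (pad, pad)))
    conv = np.zeros((h, w))
    for i in range(h):
        for j in range(w):
            conv[i, j] = (padded[:, i:i + 7, j:j + 7] * kern).sum()
    f_sa = sig(conv + cbam.spatial.bias.data[0])
    np.testing.assert_allclose(out[0], h_ca * f_sa[None], rtol=1e-10)


# -------------------------------------------------------- classifier & loss
def test_probabilities_normalize_and_zero_head_is_uniform(tiny_model_cfg, rng):
    model = MSDSANet(tiny_model_cfg)
    eeg = rng.normal(size=(3, 4, 128))
    grid = rng.normal(size=(3, 9, 9, 128))
    periph = rng.normal(size=(3, 1, 128))
    p = model.predict_proba(eeg=eeg, grid=grid, periph=periph)
    np.testing.assert_allclose(p.sum(axis=1), 1.0, atol=1e-9)
    assert np.all(p > 0)
    model.head.weight.data[:] = 0.0
    model.head.bias.data[:] = 0.0
    p = model.predict_proba(eeg=eeg, grid=grid, periph=periph)
    np.testing.assert_allclose(p, 0.5, atol=1e-12)


def test_cross_entropy_reference_values(rng):
    onehot = np.eye(2)[[0, 1]]
    assert cross_entropy(onehot, onehot) == pytest.approx(0.0, abs=1e-9)
    half = np.full((1, 2), 0.5)
    assert cross_entropy(np.eye(2)[[0]], half) == pytest.approx(np.log(2), rel=1e-9)
    probs = rng.dirichlet(np.ones(2), size=3)
    y = np.eye(2)[[1, 0, 1]]
    manual = -sum(np.log(probs[i, y[i].argmax()]) for i in range(3)) / 3
    assert cross_entropy(y, probs) == pytest.approx(manual, rel=1e-12)
    with pytest.raises(ValueError):
        cross_entropy(np.eye(2)[[0]], probs)


# ------------------------------------------------------------ full forward
def test_forward_deterministic_in_eval_mode(tiny_model_cfg, rng):
    model = MSDSANet(tiny_model_cfg)
    kw = dict(eeg=rng.normal(size=(2, 4, 128)),
              grid=rng.normal(size=(2, 9, 9, 128)),
              periph=rng.normal(size=(2, 1, 128)))
    np.testing.assert_array_equal(model.predict_proba(**kw),
                                  model.predict_proba(**kw))


def test_full_width_forward_accepts_deap_shapes(rng):
    model = MSDSANet(ModelConfig())         # paper widths: 32 EEG, 2 peripherals
    p = model.predict_proba(eeg=rng.normal(size=(1, 32, 128)),
                            grid=rng.normal(size=(1, 9, 9, 128)),
                            periph=rng.normal(size=(1, 2, 128)))
    assert p.shape == (1, 2)
    np.testing.assert_allclose(p.sum(axis=1), 1.0, atol=1e-9)


def test_checkpoint_round_trip(tiny_model_cfg, rng, tmp_path):
    model = MSDSANet(tiny_model_cfg)
    kw = dict(eeg=rng.normal(size=(2, 4, 128)),
              grid=rng.normal(size=(2, 9, 9, 128)),
              periph=rng.normal(size=(2, 1, 128)))
    save_checkpoint(model, tmp_path / "ckpt.npz")
    back = load_checkpoint(tmp_path / "ckpt.npz")
    assert back.cfg == tiny_model_cfg
    np.testing.assert_array_equal(model.predict_proba(**kw),
                                  back.predict_proba(**kw))


# ---------------------------------------------------------------- ablations
def test_ablation_flags_disable_exactly_the_stated_streams(tiny_model_cfg):
    flags = {name: ablation_config(name, tiny_model_cfg) for name in ABLATION_NAMES}
    assert not flags["Model1"].use_dsanet
    assert flags["Model1"].use_temporal_stream and flags["Model1"].use_grid_stream
    assert not flags["Model2"].use_temporal_stream
    assert not flags["Model2"].use_grid_stream and flags["Model2"].use_dsanet
    assert not flags["Model3"].use_grid_stream and flags["Model3"].use_temporal_stream
    assert not flags["Model4"].use_temporal_stream and flags["Model4"].use_grid_stream
    assert flags["Model5"].dsanet_long and not flags["Model5"].dsanet_short
    assert flags["Model6"].dsanet_short and not flags["Model6"].dsanet_long
    assert all(getattr(flags["full"], f) for f in
               ("use_temporal_stream", "use_grid_stream", "use_dsanet",
                "dsanet_long", "dsanet_short"))


def test_unknown_ablation_lists_valid_names(tiny_model_cfg):
    with pytest.raises(ValueError, match="Model1.*Model6.*full"):
        ablation_config("Model7", tiny_model_cfg)


def test_peripheral_only_model_ignores_nan_eeg(tiny_model_cfg, rng):
    cfg = ablation_config("Model2", tiny_model_cfg)
    model = MSDSANet(cfg)
    periph = rng.normal(size=(2, 1, 128))
    nan = np.full((2, 4, 128), np.nan)
    nan_grid = np.full((2, 9, 9, 128), np.nan)
    clean = model.predict_proba(periph=periph)
    with_nan = model.predict_proba(eeg=nan, grid=nan_grid, periph=periph)
    np.testing.assert_array_equal(clean, with_nan)
    assert np.all(np.isfinite(with_nan))


def test_long_branch_only_has_expected_unit_count(tiny_model_cfg):
    model5 = MSDSANet(ablation_config("Model5", tiny_model_cfg))
    assert model5.dsanet.out_channels == tiny_model_cfg.lstm_long
    model6 = MSDSANet(ablation_config("Model6", tiny_model_cfg))
    assert model6.dsanet.out_channels == tiny_model_cfg.lstm_short


def test_config_requires_at_least_one_stream():
    with pytest.raises(ValueError):
        ModelConfig(use_temporal_stream=False, use_grid_stream=False,
                    use_dsanet=False)
    with pytest.raises(ValueError):
        ModelConfig(dsanet_long=False, dsanet_short=False)
    with pytest.raises(ValueError):
        ModelConfig(temporal_kernel=4)
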