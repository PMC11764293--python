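"""Architecture contracts: the printed intermediate shapes, parameter and
MAC counts against independent hand sums, variant comparisons, checkpoints
and head/loss behaviour."""

import numpy as np
import pytest

from fnirsda import model as md
from fnirsda.autodiff import Tensor


@pytest.fixture(scope="module")
def default_net():
    return md.build_model(md.ModelConfig(), seed=0)


class TestShapes:
    def test_printed_intermediate_shapes(self, default_net, rng):
        x = rng.standard_normal((2, 40, 256)).astype(np.float32)
        default_net.eval()
        rec = {}
        feats = default_net.features(x, record=rec)
        assert rec["after_depthwise"][1:] == (128, 70)
        assert rec["after_pointwise"][1:] == (64, 70)
        assert feats.shape == (2, 128)

    def test_classifier_head_is_three_way(self, default_net, rng):
        x = rng.standard_normal((3, 40, 256)).astype(np.float32)
        default_net.eval()
        out = md.classify(default_net.features(x), default_net.classifier)
        assert out.probs.shape == (3, 3)
        assert np.allclose(out.probs.sum(axis=1), 1.0, atol=1e-6)

    def test_feature_dim_independent_of_roi_width(self, rng):
        for in_ch in (8, 16, 40):
            cfg = md.ModelConfig(in_channels=in_ch)
            net = md.build_model(cfg, seed=1)
            net.eval()
            x = rng.standard_normal((2, in_ch, 256)).astype(np.float32)
            assert net.features(x).shape == (2, 128)

    def test_eval_forward_deterministic(self, default_net, rng):
        x = rng.standard_normal((2, 40, 256)).astype(np.float32)
        default_net.eval()
        a = default_net.features(x).data
        b = default_net.features(x).data
        assert np.array_equal(a, b)

    def test_invalid_config_rejected_with_field_name(self):
        with pytest.raises(ValueError, match="gated_width"):
            md.ModelConfig(expand_width=256, gated_width=100)
        with pytest.raises(ValueError, match="dropout"):
            md.ModelConfig(dropout=1.0)
        with pytest.raises(ValueError, match="conv_variant"):
            md.ModelConfig(conv_variant="dilated")


def hand_param_count(cfg: md.ModelConfig, with_heads: bool = True) -> int:
    """Independent layer-by-layer arithmetic over the pinned dimensions."""
    n = 0
    n += cfg.in_samples * cfg.time_reduce + cfg.time_reduce      # time linear
    n += 2 * cfg.time_reduce                                     # layer norm
    n += cfg.in_channels * cfg.expand_width + cfg.expand_width   # expand pw conv
    if cfg.conv_variant == "dsc":
        n += cfg.gated_width * cfg.depthwise_kernel + cfg.gated_width
        n += cfg.gated_width * cfg.pointwise_out + cfg.pointwise_out
    else:
        n += cfg.gated_width * cfg.gated_width * cfg.depthwise_kernel + cfg.gated_width
    n += 2 * cfg.gated_width                                     # batch norm
    n += cfg.flat_dim * cfg.fc_hidden + cfg.fc_hidden            # fc1
    n += cfg.fc_hidden * cfg.feature_dim + cfg.feature_dim       # fc2
    if with_heads:
        n += cfg.feature_dim * cfg.n_classes + cfg.n_classes
        n += cfg.feature_dim * cfg.n_domains + cfg.n_domains
    return n


class TestParameterCounts:
    def test_default_extractor_matches_hand_sum(self, default_net):
        cfg = default_net.cfg
        assert md.count_parameters(default_net.extractor) == hand_param_count(cfg, False)
        assert md.count_parameters(default_net) == hand_param_count(cfg, True)

    def test_default_extractor_is_1_23M(self, default_net):
        # 256*99+99 + 2*99 + 40*256+256 + 128*30+128 + 2*128 + 128*64+64
        #   + 4480*256+256 + 256*128+128 = 1,228,649
        assert md.count_parameters(default_net.extractor) == 1_228_649

    @pytest.mark.parametrize("k", [10, 20, 30, 40, 50, 60])
    def test_dsc_fewer_parameters_than_standard(self, k):
        dsc = md.ModelConfig(depthwise_kernel=k)
        std = md.ModelConfig(depthwise_kernel=k, conv_variant="standard")
        assert (md.count_parameters(md.build_model(dsc, 0))
                < md.count_parameters(md.build_model(std, 0)))

    def test_conv_stage_weight_difference_closed_form(self):
        dsc = md.build_model(md.ModelConfig(), 0).extractor
        std = md.build_model(md.ModelConfig(conv_variant="standard"), 0).extractor
        diff = std.conv_stage_weight_count() - dsc.conv_stage_weight_count()
        assert diff == 128 * 128 * 30 - (128 * 30 + 128 * 64) == 479_488


class TestFlops:
    def test_single_linear_layer_macs(self):
        from fnirsda import nn
        layer = nn.Linear(10, 5, np.random.default_rng(0))
        assert layer.in_features * layer.out_features == 50  # 100 FLOPs at x2

    def test_depthwise_stage_macs(self, default_net):
        report = md.count_flops(default_net)
        assert report.per_layer_macs["depthwise"] == 128 * 30 * 70  # 268,800

    def test_total_macs_match_hand_sum(self, default_net):
        cfg = default_net.cfg
        expected = (cfg.in_channels * cfg.in_samples * cfg.time_reduce
                    + cfg.in_channels * cfg.expand_width * cfg.time_reduce
                    + cfg.depthwise_kernel * cfg.gated_width * cfg.conv_out_len
                    + cfg.gated_width * cfg.pointwise_out * cfg.conv_out_len
                    + cfg.flat_dim * cfg.fc_hidden
                    + cfg.fc_hidden * cfg.feature_dim
                    + cfg.feature_dim * cfg.n_classes
                    + cfg.feature_dim * cfg.n_domains)
        report = md.count_flops(default_net)
        assert report.macs == expected
        assert report.flops == 2 * expected


class TestHeads:
    def test_classification_loss_closed_forms(self):
        logits = np.log(np.array([[0.5, 0.3, 0.2], [0.25, 0.5, 0.25]]))
        loss = md.classification_loss(Tensor(logits), np.array([0, 0]))
        assert loss.item() == pytest.approx(1.0397, abs=1e-4)

    def test_domain_loss_uniform_is_ln2(self):
        logits = Tensor(np.zeros((6, 2)))
        loss = md.domain_loss(logits, np.array([0, 1, 0, 1, 0, 1]))
        assert loss.item() == pytest.approx(np.log(2), rel=1e-12)

    def test_domain_loss_matches_double_sum(self, rng):
        logits = rng.standard_normal((5, 2))
        d = np.array([0, 1, 1, 0, 1])
        loss = md.domain_loss(Tensor(logits), d)
        # literal per-sample -sum_j d_j log d'_j, averaged
        p = np.exp(logits) / np.exp(logits).sum(axis=1, keepdims=True)
        ref = 0.0
        for i in range(5):
            onehot = np.eye(2)[d[i]]
            ref += -(onehot * np.log(p[i])).sum()
        assert loss.item() == pytest.approx(ref / 5, rel=1e-6)

    def test_bad_domain_labels_rejected(self):
        with pytest.raises(ValueError, match="domain labels"):
            md.domain_loss(Tensor(np.zeros((2, 2))), np.array([0, 2]))


def test_measure_fps_basic(default_net):
    fps, cv = md.measure_fps(default_net, n_samples=8, repetitions=3)
    assert fps > 0 and cv >= 0


def test_checkpoint_round_trip(tmp_path, rng):
    cfg = md.ModelConfig(in_channels=8, in_samples=64, time_reduce=40,
                         expand_width=16, gated_width=8, depthwise_kernel=5,
                         pointwise_out=4, fc_hidden=12, feature_dim=6)
    net = md.build_model(cfg, seed=3)
    path = tmp_path / "model.npz"
    md.save_checkpoint(net, path)
    restored = md.load_checkpoint(path)
    net.eval(), restored.eval()
    x = rng.standard_normal((2, 8, 64)).astype(np.float32)
    assert np.array_equal(net.features(x).data, restored.features(x).data)
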