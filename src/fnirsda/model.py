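"""Lightweight convolutional feature extractor, task/domain heads and the
lightweighting profiler.

The extractor maps one preprocessed trial (feature-channels x 256 samples) to
a 128-dimensional embedding through four stages:

1. an affine reduction along the time axis (256 -> 99) with layer
   normalisation, keeping the tensor channel-major;
2. a gating block: pointwise convolution widening the channels to 256
   followed by a gated linear unit halving them to 128;
3. a depthwise-separable convolution block: per-channel (depthwise)
   convolution of kernel length 30 with valid padding -> (128, 70), batch
   normalisation and Swish, then a pointwise convolution to 64 channels
   -> (64, 70), dropout, flatten.  The ``standard`` variant replaces this
   separable pair with a single full 128->128 convolution of the same kernel;
4. two fully connected layers (flatten -> 256 -> 128), dropout after each.

A linear 3-way softmax head classifies motor-imagery classes; a linear 2-way
softmax head discriminates source vs target domains for adversarial training.
The profiler reports trainable-parameter counts and MAC/FLOP estimates
(multiply-accumulates over linear and convolution layers only, FLOPs = 2 x
MACs; normalisation, activations and dropout excluded by convention).
"""

from __future__ import annotations

import json
import time
from dataclasses import asdict, dataclass, field

import numpy as np

from . import nn
from .autodiff import Tensor

CONV_VARIANTS = ("dsc", "standard")


@dataclass
class ModelConfig:
    """Every architectural dimension, pinned in one place."""

    in_channels: int = 40
    in_samples: int = 256
    time_reduce: int = 99
    expand_width: int = 256
    gated_width: int = 128
    depthwise_kernel: int = 30
    pointwise_out: int = 64
    fc_hidden: int = 256
    feature_dim: int = 128
    n_classes: int = 3
    n_domains: int = 2
    dropout: float = 0.5
    conv_variant: str = "dsc"
    dtype: str = "float32"

    def __post_init__(self):
        if self.gated_width * 2 != self.expand_width:
            raise ValueError(
                f"gated_width ({self.gated_width}) must be expand_width/2 "
                f"({self.expand_width})")
        if not 0.0 <= self.dropout < 1.0:
            raise ValueError(f"dropout must be in [0, 1), got {self.dropout}")
        if self.conv_variant not in CONV_VARIANTS:
            raise ValueError(
                f"conv_variant must be one of {CONV_VARIANTS}, got {self.conv_variant!r}")
        if self.depthwise_kernel >= self.time_reduce:
            raise ValueError(
                f"depthwise_kernel ({self.depthwise_kernel}) must be shorter than "
                f"time_reduce ({self.time_reduce})")
        for name in ("in_channels", "in_samples", "time_reduce", "expand_width",
                     "pointwise_out", "fc_hidden", "feature_dim", "n_classes",
                     "n_domains"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")

    @property
    def conv_out_len(self) -> int:
        return self.time_reduce - self.depthwise_kernel + 1

    @property
    def flat_dim(self) -> int:
        width = self.pointwise_out if self.conv_variant == "dsc" else self.gated_width
        return width * self.conv_out_len

    @property
    def np_dtype(self):
        return np.dtype(self.dtype)


@dataclass
class HeadOutput:
    """Logits and softmax probabilities from a linear head."""

    logits: np.ndarray
    probs: np.ndarray


@dataclass
class ProfileReport:
    """Lightweighting numbers: parameters, MACs/FLOPs and throughput."""

    n_params: int
    macs: int
    flops: int
    fps: float | None = None
    fps_cv: float | None = None
    per_layer_macs: dict[str, int] = field(default_factory=dict)

    def to_json(self) -> str:
        d = asdict(self)
        return json.dumps(d, indent=2)


class FeatureExtractor(nn.Module):
    """Stages 1-4 above; emits ``cfg.feature_dim``-dimensional embeddings."""

    def __init__(self, cfg: ModelConfig, rng: np.random.Generator,
                 dropout_rng: np.random.Generator):
        super().__init__()
        self.cfg = cfg
        dt = cfg.np_dtype
        self.time_linear = nn.TimeLinear(cfg.in_samples, cfg.time_reduce, rng, dt)
        self.norm = nn.LayerNorm(cfg.time_reduce, dt)
        self.expand = nn.PointwiseConv1d(cfg.in_channels, cfg.expand_width, rng, dt)
        self.glu = nn.GLU(axis=1)
        if cfg.conv_variant == "dsc":
            self.depthwise = nn.DepthwiseConv1d(cfg.gated_width, cfg.depthwise_kernel,
                                                rng, dt)
            self.pointwise = nn.PointwiseConv1d(cfg.gated_width, cfg.pointwise_out,
                                                rng, dt)
        else:
            self.full_conv = nn.Conv1d(cfg.gated_width, cfg.gated_width,
                                       cfg.depthwise_kernel, rng, dt)
        self.bn = nn.BatchNorm1d(cfg.gated_width, dt)
        self.swish = nn.Swish()
        self.drop_conv = nn.Dropout(cfg.dropout, dropout_rng)
        self.fc1 = nn.Linear(cfg.flat_dim, cfg.fc_hidden, rng, dt)
        self.drop1 = nn.Dropout(cfg.dropout, dropout_rng)
        self.fc2 = nn.Linear(cfg.fc_hidden, cfg.feature_dim, rng, dt)
        self.drop2 = nn.Dropout(cfg.dropout, dropout_rng)

    def forward(self, x: Tensor, record: dict | None = None) -> Tensor:
        if not isinstance(x, Tensor):
            x = Tensor(np.asarray(x, dtype=self.cfg.np_dtype))
        if x.ndim == 2:
            x = x.reshape(1, *x.shape)
        # stage 1: time-axis reduction, layer norm; stays channel-major
        h = self.norm(self.time_linear(x))
        # stage 2: gating
        h = self.glu(self.expand(h))
        # stage 3: (separable) convolution
        if self.cfg.conv_variant == "dsc":
            h = self.depthwise(h)
            if record is not None:
                record["after_depthwise"] = h.shape
            h = self.swish(self.bn(h))
            h = self.pointwise(h)
            if record is not None:
                record["after_pointwise"] = h.shape
        else:
            h = self.full_conv(h)
            if record is not None:
                record["after_conv"] = h.shape
            h = self.swish(self.bn(h))
        h = self.drop_conv(h)
        h = h.reshape(h.shape[0], -1)
        # stage 4: fully connected embedding
        h = self.drop1(self.fc1(h))
        h = self.drop2(self.fc2(h))
        if record is not None:
            record["features"] = h.shape
        return h

    def layer_macs(self) -> dict[str, int]:
        cfg = self.cfg
        macs = {
            "time_linear": cfg.in_channels * cfg.in_samples * cfg.time_reduce,
            "expand_pointwise": cfg.in_channels * cfg.expand_width * cfg.time_reduce,
        }
        if cfg.conv_variant == "dsc":
            macs["depthwise"] = cfg.depthwise_kernel * cfg.gated_width * cfg.conv_out_len
            macs["pointwise"] = cfg.gated_width * cfg.pointwise_out * cfg.conv_out_len
        else:
            macs["full_conv"] = (cfg.depthwise_kernel * cfg.gated_width
                                 * cfg.gated_width * cfg.conv_out_len)
        macs["fc1"] = cfg.flat_dim * cfg.fc_hidden
        macs["fc2"] = cfg.fc_hidden * cfg.feature_dim
        return macs

    def conv_stage_weight_count(self) -> int:
        """Weight elements (biases excluded) of the stage-3 convolution(s)."""
        cfg = self.cfg
        if cfg.conv_variant == "dsc":
            return (cfg.gated_width * cfg.depthwise_kernel
                    + cfg.gated_width * cfg.pointwise_out)
        return cfg.gated_width * cfg.gated_width * cfg.depthwise_kernel


class LinearHead(nn.Module):
    """One fully connected layer; softmax applied by the loss/inference code."""

    def __init__(self, in_dim: int, n_out: int, rng: np.random.Generator, dtype):
        super().__init__()
        self.linear = nn.Linear(in_dim, n_out, rng, dtype)

    def forward(self, x: Tensor) -> Tensor:
        return self.linear(x)

    def layer_macs(self) -> int:
        return self.linear.in_features * self.linear.out_features


class DomainAdaptNet(nn.Module):
    """Feature extractor + classifier head + domain-discriminator head."""

    def __init__(self, cfg: ModelConfig, seed: int = 0):
        super().__init__()
        self.cfg = cfg
        ss = np.random.SeedSequence(seed)
        init_ss, head_ss, drop_ss = ss.spawn(3)
        init_rng = np.random.default_rng(init_ss)
        head_rng = np.random.default_rng(head_ss)
        self.dropout_rng = np.random.default_rng(drop_ss)
        self.extractor = FeatureExtractor(cfg, init_rng, self.dropout_rng)
        self.classifier = LinearHead(cfg.feature_dim, cfg.n_classes, head_rng, cfg.np_dtype)
        self.discriminator = LinearHead(cfg.feature_dim, cfg.n_domains, head_rng,
                                        cfg.np_dtype)

    def forward(self, x: Tensor) -> Tensor:
        return self.classifier(self.extractor(x))

    def features(self, x, record: dict | None = None) -> Tensor:
        return self.extractor(x, record=record)


def build_feature_extractor(cfg: ModelConfig | None = None, seed: int = 0) -> FeatureExtractor:
    cfg = cfg or ModelConfig()
    net = DomainAdaptNet(cfg, seed=seed)
    return net.extractor


def build_model(cfg: ModelConfig | None = None, seed: int = 0) -> DomainAdaptNet:
    return DomainAdaptNet(cfg or ModelConfig(), seed=seed)


def _head_output(logits: Tensor) -> HeadOutput:
    probs = nn.softmax(logits, axis=-1)
    return HeadOutput(logits=logits.data.copy(), probs=probs.data.copy())


def classify(features, head: LinearHead) -> HeadOutput:
    """Run the 3-way classifier head on a feature batch."""
    if not isinstance(features, Tensor):
        features = Tensor(np.asarray(features))
    return _head_output(head(features))


def discriminate(features, head: LinearHead) -> HeadOutput:
    """Run the 2-way source/target domain head on a feature batch."""
    if not isinstance(features, Tensor):
        features = Tensor(np.asarray(features))
    return _head_output(head(features))


def classification_loss(logits: Tensor, labels: np.ndarray) -> Tensor:
    """Mean cross-entropy of the true class, the classifier objective."""
    return nn.cross_entropy(logits, labels)


def domain_loss(logits: Tensor, domain_labels: np.ndarray) -> Tensor:
    """Domain-discrimination cross-entropy, -sum_j d_j log d'_j, batch-mean
    reduced; domain labels are 0 = source, 1 = target."""
    domain_labels = np.asarray(domain_labels)
    if domain_labels.size and not np.isin(domain_labels, (0, 1)).all():
        raise ValueError("domain labels must be 0 (source) or 1 (target)")
    return nn.cross_entropy(logits, domain_labels)


# ---------------------------------------------------------------------------
# profiling
# ---------------------------------------------------------------------------

def count_parameters(model: nn.Module) -> int:
    """Total size of all trainable arrays in the model."""
    return model.n_parameters()


def count_flops(model) -> ProfileReport:
    """MAC/FLOP estimate per the linear+conv convention (one input sample)."""
    if isinstance(model, DomainAdaptNet):
        per_layer = dict(model.extractor.layer_macs())
        per_layer["classifier"] = model.classifier.layer_macs()
        per_layer["discriminator"] = model.discriminator.layer_macs()
    elif isinstance(model, FeatureExtractor):
        per_layer = dict(model.layer_macs())
    else:
        raise TypeError(f"cannot profile object of type {type(model).__name__}")
    macs = int(sum(per_layer.values()))
    return ProfileReport(n_params=count_parameters(model), macs=macs,
                         flops=2 * macs, per_layer_macs=per_layer)


def measure_fps(model: nn.Module, n_samples: int = 128, repetitions: int = 5,
                rng: np.random.Generator | None = None) -> tuple[float, float]:
    """Throughput N/T in samples/s (median wall time over repetitions) and the
    coefficient of variation of the repeated measurements.

    Hardware dependent by nature; reported for information only.
    """
    if n_samples < 1:
        raise ValueError("n_samples must be >= 1")
    cfg = model.cfg
    rng = rng or np.random.default_rng(0)
    x = rng.standard_normal((n_samples, cfg.in_channels, cfg.in_samples)).astype(cfg.np_dtype)
    model.eval()
    if isinstance(model, DomainAdaptNet):
        run = lambda: model.features(Tensor(x))
    else:
        run = lambda: model(Tensor(x))
    run()  # warm-up
    times = []
    for _ in range(repetitions):
        t0 = time.perf_counter()
        run()
        times.append(time.perf_counter() - t0)
    times = np.asarray(times)
    median_t = float(np.median(times))
    fps = n_samples / median_t
    cv = float(times.std() / times.mean()) if times.mean() > 0 else 0.0
    return fps, cv


def profile_model(model: nn.Module, with_fps: bool = False) -> ProfileReport:
    report = count_flops(model)
    if with_fps:
        report.fps, report.fps_cv = measure_fps(model)
    return report


# ---------------------------------------------------------------------------
# checkpoints
# ---------------------------------------------------------------------------

def save_checkpoint(model: DomainAdaptNet, path) -> None:
    """Single-archive checkpoint: flat named arrays + the config as JSON."""
    arrays = {f"param_{i}": p.data for i, p in enumerate(model.parameters())}
    arrays["config_json"] = np.frombuffer(
        json.dumps(asdict(model.cfg)).encode(), dtype=np.uint8)
    np.savez(path, **arrays)


def load_checkpoint(path, seed: int = 0) -> DomainAdaptNet:
    with np.load(path) as archive:
        cfg = ModelConfig(**json.loads(archive["config_json"].tobytes().decode()))
        model = DomainAdaptNet(cfg, seed=seed)
        state = {k: archive[k] for k in archive.files if k != "config_json"}
    model.load_state_dict(state)
    return model
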