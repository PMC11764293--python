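"""Distribution alignment and adversarial-training machinery.

Maximum mean discrepancy (MMD) measures the distance between the source and
target feature distributions in a reproducing-kernel Hilbert space.  We use
the biased V-statistic (plug-in) estimator with a multi-bandwidth Gaussian
RBF kernel,

    MMD^2(S, T) = mean k(S, S) + mean k(T, T) - 2 mean k(S, T),

summed over bandwidths {1/4, 1/2, 1, 2, 4} x the median pairwise squared
distance of the pooled batch (the median heuristic); the V-statistic is
non-negative by construction.  A fixed bandwidth list can be supplied for
tests.

Adversarial mechanics: the minimax game between the feature extractor
and a domain discriminator is folded into a single objective through a
gradient-reversal operator (identity forward, gradient scaled by -1 going
upstream), so one optimiser minimises

    L_all = L_cls + lambda * (L_MMD + L_domin)

with the discriminator head descending L_domin on its own parameters while
the extractor ascends it.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .autodiff import Tensor, grad_reverse

__all__ = ["MmdConfig", "DomainBatch", "ObjectiveWeights", "mmd2", "mmd2_loss",
           "grad_reverse", "total_loss", "resolve_bandwidths"]

DEFAULT_BANDWIDTH_SCALES = (0.25, 0.5, 1.0, 2.0, 4.0)


@dataclass
class MmdConfig:
    """Kernel settings for the MMD estimator."""

    kernel: str = "rbf"
    bandwidths: tuple | str = "median"
    estimator: str = "biased_v"

    def __post_init__(self):
        if self.kernel != "rbf":
            raise ValueError(f"only the rbf kernel is supported, got {self.kernel!r}")
        if self.estimator != "biased_v":
            raise ValueError(f"only the biased_v estimator is supported, got {self.estimator!r}")
        if self.bandwidths != "median":
            bw = tuple(float(b) for b in self.bandwidths)
            if not bw or any(b <= 0 for b in bw):
                raise ValueError(f"bandwidths must be positive, got {self.bandwidths}")
            self.bandwidths = bw


@dataclass
class DomainBatch:
    """Paired source/target feature batches."""

    source_features: np.ndarray
    target_features: np.ndarray

    def __post_init__(self):
        self.source_features = np.asarray(self.source_features)
        self.target_features = np.asarray(self.target_features)
        s, t = self.source_features, self.target_features
        if s.ndim != 2 or t.ndim != 2 or s.shape[1] != t.shape[1]:
            raise ValueError(
                f"feature matrices must be 2-D with equal width, got {s.shape}, {t.shape}")
        if s.shape[0] < 2 or t.shape[0] < 2:
            raise ValueError(
                f"need at least 2 samples per side, got {s.shape[0]} source, "
                f"{t.shape[0]} target")


@dataclass
class ObjectiveWeights:
    """Balance factor between classification and the two adaptation losses."""

    lam: float = 0.35

    def __post_init__(self):
        if self.lam < 0:
            raise ValueError(f"lam must be >= 0, got {self.lam}")


def _pairwise_sq_dists(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    aa = (a * a).sum(axis=1)[:, None]
    bb = (b * b).sum(axis=1)[None, :]
    d = aa + bb - 2.0 * (a @ b.T)
    return np.maximum(d, 0.0)


def resolve_bandwidths(source: np.ndarray, target: np.ndarray,
                       cfg: MmdConfig) -> tuple[float, ...]:
    """Resolve the bandwidth list, applying the median heuristic if asked.

    The heuristic sets the base bandwidth to the median pairwise squared
    distance of the pooled batch and surrounds it with the scale ladder
    {1/4, 1/2, 1, 2, 4}.
    """
    if cfg.bandwidths != "median":
        return tuple(cfg.bandwidths)
    pooled = np.concatenate([source, target], axis=0).astype(np.float64)
    d = _pairwise_sq_dists(pooled, pooled)
    off_diag = d[~np.eye(d.shape[0], dtype=bool)]
    med = float(np.median(off_diag))
    if med <= 0:
        med = 1.0
    return tuple(s * med for s in DEFAULT_BANDWIDTH_SCALES)


def mmd2(batch: DomainBatch | None = None, cfg: MmdConfig | None = None, *,
         source: np.ndarray | None = None, target: np.ndarray | None = None) -> float:
    """Biased (V-statistic) squared MMD between source and target features.

    Accepts either a :class:`DomainBatch` or explicit arrays.  The Gaussian
    kernel is ``exp(-||x - y||^2 / (2 h))`` for each resolved bandwidth ``h``;
    the statistic is summed over bandwidths.  Non-negative up to floating
    error.
    """
    if batch is None:
        batch = DomainBatch(source, target)
    cfg = cfg or MmdConfig()
    s = batch.source_features.astype(np.float64)
    t = batch.target_features.astype(np.float64)
    bandwidths = resolve_bandwidths(s, t, cfg)
    d_ss = _pairwise_sq_dists(s, s)
    d_tt = _pairwise_sq_dists(t, t)
    d_st = _pairwise_sq_dists(s, t)
    out = 0.0
    for h in bandwidths:
        out += (np.exp(-d_ss / (2.0 * h)).mean()
                + np.exp(-d_tt / (2.0 * h)).mean()
                - 2.0 * np.exp(-d_st / (2.0 * h)).mean())
    return float(out)


def mmd2_loss(source: Tensor, target: Tensor, cfg: MmdConfig | None = None) -> Tensor:
    """Differentiable MMD^2 for the training objective (same estimator).

    Bandwidths resolved by the median heuristic are treated as constants
    (not differentiated through), the usual practice.
    """
    cfg = cfg or MmdConfig()
    if source.shape[0] < 2 or target.shape[0] < 2:
        raise ValueError("need at least 2 samples per side for the MMD loss")
    bandwidths = resolve_bandwidths(source.data, target.data, cfg)

    def sq_dists(a: Tensor, b: Tensor) -> Tensor:
        aa = (a * a).sum(axis=1).reshape(-1, 1)
        bb = (b * b).sum(axis=1).reshape(1, -1)
        return aa + bb - 2.0 * (a @ b.transpose(1, 0))

    d_ss, d_tt, d_st = sq_dists(source, source), sq_dists(target, target), \
        sq_dists(source, target)
    total = None
    for h in bandwidths:
        term = ((d_ss * (-1.0 / (2.0 * h))).exp().mean()
                + (d_tt * (-1.0 / (2.0 * h))).exp().mean()
                - 2.0 * (d_st * (-1.0 / (2.0 * h))).exp().mean())
        total = term if total is None else total + term
    return total


def total_loss(l_cls, l_mmd, l_domin, w: ObjectiveWeights | float = 0.35):
    """Combined objective ``L_all = L_cls + lam * (L_MMD + L_domin)``.

    Works on plain floats or on autodiff tensors (in which case the gradient
    flows to all three components; the adversarial sign on L_domin is carried
    by the gradient-reversal operator inside the discriminator branch, not
    here).
    """
    lam = w.lam if isinstance(w, ObjectiveWeights) else ObjectiveWeights(float(w)).lam
    for name, value in (("l_cls", l_cls), ("l_mmd", l_mmd), ("l_domin", l_domin)):
        v = value.item() if isinstance(value, Tensor) else float(value)
        if math.isnan(v):
            raise ValueError(f"loss component {name} is NaN")
    return l_cls + lam * (l_mmd + l_domin)
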