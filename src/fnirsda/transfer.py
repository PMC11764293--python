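"""Cross-subject transfer strategies and paradigms.

Strategies:

* **DT** (direct transfer): train on the source subjects with the
  classification loss only, apply unchanged to the held-out subject.
* **FT** (fine-tuning): a DT model whose feature extractor is then frozen
  while the classifier head is retrained on a small stratified labeled
  calibration split of the target subject (default 25%); evaluation uses the
  disjoint remainder.
* **DA** (domain adaptation): train on source labels plus *unlabeled* target
  trials with the combined objective (MMD alignment + adversarial domain
  discrimination); target labels are used for evaluation only.

Paradigms:

* **MTS** (multi-source to single-target): each subject is held out in turn;
  all remaining subjects form the source set.
* **STS** (single-source to single-target): for each target subject, every
  other subject serves as the sole source in turn and the target's score is
  the mean over those pairs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .estimators import LightConvNetClassifier
from .evaluate import MetricsReport, PredictionSet, compute_metrics

STRATEGIES = ("DT", "FT", "DA")
PARADIGMS = ("MTS", "STS")


@dataclass
class TrainConfig:
    """Training hyper-parameters (defaults = the study configuration)."""

    lr: float = 0.001
    weight_decay: float = 0.0
    dropout: float = 0.5
    iterations: int = 120
    iteration_unit: str = "epochs"
    batch_size: int = 128
    lam: float = 0.35
    ft_fraction: float = 0.25
    kernel_length: int = 30
    conv_variant: str = "dsc"
    seed: int = 0

    def __post_init__(self):
        if self.iterations < 1:
            raise ValueError("iterations must be >= 1")
        if not 0.0 < self.ft_fraction < 1.0:
            raise ValueError(f"ft_fraction must be in (0, 1), got {self.ft_fraction}")


@dataclass
class ArrayDataset:
    """Trials as stacked arrays with per-trial subject identifiers."""

    X: np.ndarray
    y: np.ndarray
    subjects: np.ndarray

    def __post_init__(self):
        self.X = np.asarray(self.X)
        self.y = np.asarray(self.y)
        self.subjects = np.asarray(self.subjects)
        if not self.X.shape[0] == self.y.shape[0] == self.subjects.shape[0]:
            raise ValueError("X, y and subjects must have equal first dimensions")

    def subject_ids(self) -> np.ndarray:
        return np.unique(self.subjects)

    def subset(self, mask: np.ndarray) -> "ArrayDataset":
        return ArrayDataset(self.X[mask], self.y[mask], self.subjects[mask])

    def __len__(self) -> int:
        return self.X.shape[0]


@dataclass
class RunResult:
    """Per-target-subject metric rows plus their mean +/- sd aggregate."""

    strategy: str
    paradigm: str
    rows: list[dict] = field(default_factory=list)
    seed: int = 0

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.rows)

    def summary(self) -> dict[str, tuple[float, float]]:
        df = self.to_dataframe()
        out = {}
        for col in ("accuracy", "precision", "recall", "f1", "kappa"):
            if col in df:
                out[col] = (float(df[col].mean()), float(df[col].std(ddof=0)))
        return out

    @property
    def mean_accuracy(self) -> float:
        return float(self.to_dataframe()["accuracy"].mean())


def split_mts(dataset: ArrayDataset, held_out_subject) -> tuple[ArrayDataset, ArrayDataset]:
    """All other subjects' trials as source, the held-out subject as target."""
    if held_out_subject not in dataset.subject_ids():
        raise ValueError(f"unknown subject {held_out_subject!r}")
    mask = dataset.subjects == held_out_subject
    return dataset.subset(~mask), dataset.subset(mask)


def split_sts(dataset: ArrayDataset, target_subject) -> list[tuple[ArrayDataset, ArrayDataset]]:
    """One (single-source, target) pair per non-target subject."""
    ids = dataset.subject_ids()
    if target_subject not in ids:
        raise ValueError(f"unknown subject {target_subject!r}")
    if ids.size < 2:
        raise ValueError("STS needs at least 2 subjects")
    target = dataset.subset(dataset.subjects == target_subject)
    return [(dataset.subset(dataset.subjects == sid), target)
            for sid in ids if sid != target_subject]


def _stratified_split(y: np.ndarray, fraction: float,
                      rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """Stratified calibration/evaluation index split (at least one per class)."""
    cal_idx = []
    for cls in np.unique(y):
        idx = np.where(y == cls)[0]
        rng.shuffle(idx)
        n_cal = max(1, int(round(fraction * idx.size)))
        if n_cal >= idx.size:
            n_cal = idx.size - 1
        cal_idx.extend(idx[:max(n_cal, 0)] if idx.size > 1 else [])
    cal = np.sort(np.asarray(cal_idx, dtype=int))
    eval_mask = np.ones(y.size, dtype=bool)
    eval_mask[cal] = False
    return cal, np.where(eval_mask)[0]


def _make_estimator(cfg: TrainConfig, lam: float, seed: int) -> LightConvNetClassifier:
    return LightConvNetClassifier(
        kernel_length=cfg.kernel_length, conv_variant=cfg.conv_variant,
        dropout=cfg.dropout, lam=lam, lr=cfg.lr, weight_decay=cfg.weight_decay,
        iterations=cfg.iterations, iteration_unit=cfg.iteration_unit,
        batch_size=cfg.batch_size, random_state=seed)


def train(strategy: str, source: ArrayDataset, target: ArrayDataset,
          cfg: TrainConfig | None = None) -> tuple[LightConvNetClassifier, MetricsReport]:
    """Train one strategy on a source/target split and evaluate on the target.

    DT and DA evaluate on all target trials; FT evaluates on the stratified
    1 - ft_fraction remainder disjoint from its calibration split.
    """
    cfg = cfg or TrainConfig()
    if strategy not in STRATEGIES:
        raise ValueError(f"strategy must be one of {STRATEGIES}, got {strategy!r}")
    if len(source) == 0 or len(target) == 0:
        raise ValueError("source and target sets must be non-empty")

    if strategy == "DA":
        est = _make_estimator(cfg, lam=cfg.lam, seed=cfg.seed)
        est.fit(source.X, source.y, X_target=target.X)
        X_eval, y_eval = target.X, target.y
    elif strategy == "DT":
        est = _make_estimator(cfg, lam=0.0, seed=cfg.seed)
        est.fit(source.X, source.y)
        X_eval, y_eval = target.X, target.y
    else:  # FT
        est = _make_estimator(cfg, lam=0.0, seed=cfg.seed)
        est.fit(source.X, source.y)
        split_rng = np.random.default_rng(
            np.random.SeedSequence([cfg.seed, 0xFE]).generate_state(1)[0])
        cal_idx, eval_idx = _stratified_split(target.y, cfg.ft_fraction, split_rng)
        est.fine_tune(target.X[cal_idx], target.y[cal_idx])
        X_eval, y_eval = target.X[eval_idx], target.y[eval_idx]

    scores = est.predict_proba(X_eval)
    y_pred = est.classes_[np.argmax(scores, axis=1)]
    preds = PredictionSet(true_labels=y_eval, predicted_labels=y_pred, scores=scores)
    return est, compute_metrics(preds)


def run_paradigm(dataset: ArrayDataset, strategy: str, paradigm: str,
                 cfg: TrainConfig | None = None,
                 targets: list | None = None) -> RunResult:
    """Iterate the chosen split over every (or the given) target subject."""
    cfg = cfg or TrainConfig()
    if paradigm not in PARADIGMS:
        raise ValueError(f"paradigm must be one of {PARADIGMS}, got {paradigm!r}")
    subjects = targets if targets is not None else list(dataset.subject_ids())
    result = RunResult(strategy=strategy, paradigm=paradigm, seed=cfg.seed)
    for sid in subjects:
        if paradigm == "MTS":
            source, target = split_mts(dataset, sid)
            _, report = train(strategy, source, target, cfg)
            row = {"subject": sid, **report.as_dict()}
        else:
            pair_reports = [train(strategy, src, tgt, cfg)[1]
                            for src, tgt in split_sts(dataset, sid)]
            row = {"subject": sid}
            for key in ("accuracy", "precision", "recall", "f1", "kappa"):
                row[key] = float(np.mean([r.as_dict()[key] for r in pair_reports]))
            row["n_pairs"] = len(pair_reports)
        result.rows.append(row)
    return result
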