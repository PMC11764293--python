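"""Synthetic multi-subject fNIRS motor-imagery data with controllable
inter-subject domain shift.

The generator emulates the structure of a 30-participant, 20-channel,
three-class (left hand / right hand / feet) motor-imagery protocol: each trial
is a 2 s introduction, a 10 s task period and a 17-19 s rest, repeated 25
times per class in randomised order.  Per channel, the continuous dHbO signal
is a sum of

* task-locked hemodynamic responses (a canonical double-gamma HRF convolved
  with the task boxcar), weighted by a class-specific channel topography and a
  per-channel subject gain, shifted by a subject latency;
* Gaussian measurement noise;
* sinusoidal physiological components (~1.1 Hz cardiac, ~0.3 Hz respiratory,
  ~0.1 Hz Mayer waves) with random phases; and
* an integrated-random-walk slow drift.

dHbR is a negatively scaled (-1/3 by default), 1 s delayed copy of the
task-locked dHbO component plus its own noise, the typical anticorrelation.
Amplitudes are in micromolar-like arbitrary concentration units.

Domain shift is parameterised *only* through :class:`SubjectProfile`
hyper-priors, so ``shift_level="none"`` gives exactly identical subjects.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import stats

from .preprocess import (CLASS_NAMES, EpochReport, HemoSignal, TrialEpoch, epoch,
                         preprocess_hemo, trials_to_arrays)

SHIFT_LEVELS = ("none", "mild", "strong")


@dataclass
class HrfParams:
    """Canonical double-gamma hemodynamic response parameters (seconds)."""

    peak_time: float = 6.0
    undershoot_time: float = 16.0
    peak_disp: float = 1.0
    under_disp: float = 1.0
    under_ratio: float = 1.0 / 6.0
    amplitude: float = 1.0

    def __post_init__(self):
        if not self.peak_time < self.undershoot_time:
            raise ValueError("peak_time must precede undershoot_time")
        if self.peak_disp <= 0 or self.under_disp <= 0:
            raise ValueError("dispersions must be > 0")
        if not np.isfinite(self.amplitude):
            raise ValueError("amplitude must be finite")


def double_gamma_hrf(t: np.ndarray, p: HrfParams | None = None) -> np.ndarray:
    """Sample the double-gamma HRF on a time grid ``t`` (seconds, t >= 0).

    The positive lobe is a gamma density with mode exactly at ``peak_time``;
    the undershoot is a second gamma density scaled by ``under_ratio``.  The
    curve is normalised so the positive lobe peaks at ``amplitude``; the value
    at t = 0 is 0.
    """
    p = p or HrfParams()
    t = np.asarray(t, dtype=float)
    shape1 = 1.0 + p.peak_time / p.peak_disp
    shape2 = 1.0 + p.undershoot_time / p.under_disp
    main = stats.gamma.pdf(t, shape1, scale=p.peak_disp)
    under = stats.gamma.pdf(t, shape2, scale=p.under_disp)
    peak_height = stats.gamma.pdf(p.peak_time, shape1, scale=p.peak_disp)
    return p.amplitude * (main - p.under_ratio * under) / peak_height


@dataclass
class SubjectProfile:
    """Everything that makes one subject's recordings look like *that* subject."""

    subject_id: str
    gain: np.ndarray  # multiplicative scale per channel, > 0
    latency_shift: float  # seconds
    noise_sd: float  # concentration units
    topography: dict[str, np.ndarray]  # class -> per-channel weights in [0, 1]
    drift_sd: float = 0.0

    def __post_init__(self):
        self.gain = np.asarray(self.gain, dtype=float)
        if np.any(self.gain <= 0):
            raise ValueError("gains must be > 0")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        for cls, w in self.topography.items():
            w = np.asarray(w, dtype=float)
            if np.any(w < 0) or np.any(w > 1):
                raise ValueError(f"topography weights for {cls} outside [0, 1]")
            self.topography[cls] = w


@dataclass
class GeneratorConfig:
    """Protocol-level generator settings (defaults mirror the study paradigm)."""

    n_subjects: int = 30
    classes: tuple[str, ...] = CLASS_NAMES
    trials_per_class: int = 25
    n_channels: int = 20
    fs: float = 10.0
    task_s: float = 10.0
    intro_s: float = 2.0
    rest_range: tuple[float, float] = (17.0, 19.0)
    seed: int = 0
    # signal-model knobs (arbitrary concentration units)
    amplitude: float = 1.0
    noise_sd: float = 1.0
    physio_amp: float = 0.5
    drift_sd: float = 0.3
    hbr_ratio: float = -1.0 / 3.0
    hbr_delay_s: float = 1.0
    hrf: HrfParams = field(default_factory=HrfParams)

    def __post_init__(self):
        for name in ("n_subjects", "trials_per_class", "n_channels"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if self.fs <= 0:
            raise ValueError("fs must be > 0")


@dataclass
class LabeledDataset:
    """Per-subject continuous signals plus their raw trial epochs."""

    trials: list[TrialEpoch]
    subjects: list[SubjectProfile]
    recordings: list[HemoSignal]
    generator_config: GeneratorConfig

    def subject_ids(self) -> list[str]:
        return [p.subject_id for p in self.subjects]


def default_topography(n_channels: int = 20) -> dict[str, np.ndarray]:
    """Class -> channel-weight maps over the bilateral 20-channel montage.

    Channels 1-10 cover the left hemisphere, 11-20 the right; hand imagery
    activates the contralateral motor cortex, foot imagery the medial
    channels of both hemispheres.  Weights are in [0, 1].
    """
    def weights(core: list[int], halo: list[int], base_idx: np.ndarray) -> np.ndarray:
        w = np.zeros(n_channels)
        w[base_idx] = 0.15
        for ch in halo:
            w[ch - 1] = 0.5
        for ch in core:
            w[ch - 1] = 1.0
        return w

    left_hemi = np.arange(0, min(10, n_channels))
    right_hemi = np.arange(min(10, n_channels), n_channels)
    return {
        "left": weights([14, 15, 16, 17], [11, 12, 13, 18], right_hemi),
        "right": weights([4, 5, 6, 7], [1, 2, 3, 8], left_hemi),
        "feet": weights([5, 6, 15, 16], [4, 7, 14, 17], np.arange(0)),
    }


#: Hyper-prior widths per shift level: (log-gain sd, log-scale sd,
#: latency sd [s], log-noise sd, topography jitter sd, montage
#: displacements).  The dominant components are covariate: per-channel
#: gains, a global amplitude scale, the noise floor, and a *montage
#: displacement* — a coherent spatial shift of every class topography
#: within each hemisphere, emulating between-subject cap/optode placement
#: differences.  Displacement moves all classes identically, so it shifts
#: the marginal feature distribution without scrambling the label-conditional
#: structure; iid topography jitter (which no marginal-alignment method can
#: repair) is kept small.
_SHIFT_PRIORS = {
    "none": (0.0, 0.0, 0.0, 0.0, 0.0, (0,)),
    "mild": (0.4, 0.3, 0.3, 0.2, 0.05, (-1, 0, 1)),
    "strong": (1.2, 1.0, 0.5, 0.4, 0.05, (-2, 2)),
}


def _displace_montage(weights: np.ndarray, offset: int) -> np.ndarray:
    """Shift channel weights by ``offset`` positions within each hemisphere."""
    if offset == 0:
        return weights
    half = weights.shape[0] // 2
    out = weights.copy()
    out[:half] = np.roll(weights[:half], offset)
    out[half:] = np.roll(weights[half:], offset)
    return out


def draw_profile(subject_id: str, cfg: GeneratorConfig, shift_level: str,
                 rng: np.random.Generator) -> SubjectProfile:
    if shift_level not in _SHIFT_PRIORS:
        raise ValueError(f"shift_level must be one of {SHIFT_LEVELS}, got {shift_level!r}")
    g_sd, scale_sd, lat_sd, n_sd, topo_sd, displacements = _SHIFT_PRIORS[shift_level]
    base = default_topography(cfg.n_channels)
    gain = np.exp(rng.normal(0.0, g_sd, size=cfg.n_channels)) if g_sd else np.ones(cfg.n_channels)
    if scale_sd:
        gain = gain * float(np.exp(rng.normal(0.0, scale_sd)))
    latency = float(np.clip(rng.normal(0.0, lat_sd), -1.5, 1.5)) if lat_sd else 0.0
    noise_sd = cfg.noise_sd * (float(np.exp(rng.normal(0.0, n_sd))) if n_sd else 1.0)
    offset = int(rng.choice(displacements))  # one cap placement per subject
    topo = {}
    for cls, w in base.items():
        w = _displace_montage(w, offset)
        if topo_sd:
            w = np.clip(w + rng.normal(0.0, topo_sd, size=w.shape), 0.0, 1.0)
        topo[cls] = w
    return SubjectProfile(subject_id=subject_id, gain=gain, latency_shift=latency,
                          noise_sd=noise_sd, topography=topo, drift_sd=cfg.drift_sd)


def _task_response(cfg: GeneratorConfig) -> np.ndarray:
    """Unit-amplitude boxcar(0..task_s) convolved with the HRF, 32 s support."""
    dt = 1.0 / cfg.fs
    t = np.arange(0.0, 32.0, dt)
    hrf = double_gamma_hrf(t, replace(cfg.hrf, amplitude=1.0))
    box = (t < cfg.task_s).astype(float)
    resp = np.convolve(box, hrf)[: t.size] * dt
    peak = np.abs(resp).max()
    return resp / peak if peak > 0 else resp


def synthesize_subject(profile: SubjectProfile, cfg: GeneratorConfig,
                       rng: np.random.Generator) -> tuple[HemoSignal, list[TrialEpoch]]:
    """Simulate one subject's continuous session and its raw trial epochs.

    Returns the continuous :class:`HemoSignal` (so the full preprocessing
    chain can be exercised on it) and the unfiltered, un-baselined epochs.
    """
    if profile.gain.shape[0] != cfg.n_channels:
        raise ValueError("profile channel count does not match config")
    fs, n_ch = cfg.fs, cfg.n_channels

    labels = np.repeat(np.arange(len(cfg.classes)), cfg.trials_per_class)
    rng.shuffle(labels)
    rests = rng.uniform(*cfg.rest_range, size=labels.size)

    onsets, t_cursor = [], 0.0
    for rest in rests:
        onsets.append(t_cursor + cfg.intro_s)
        t_cursor += cfg.intro_s + cfg.task_s + rest
    total_s = t_cursor + 32.0  # tail so the last epoch window always fits
    n_samples = int(round(total_s * fs))
    time = np.arange(n_samples) / fs

    resp = _task_response(cfg)
    delay = int(round(cfg.hbr_delay_s * fs))

    activation = np.zeros((n_ch, n_samples))
    for onset, lab in zip(onsets, labels):
        cls = cfg.classes[lab]
        start = int(round((onset + profile.latency_shift) * fs))
        start = max(start, 0)
        stop = min(start + resp.size, n_samples)
        amp = cfg.amplitude * profile.topography[cls] * profile.gain
        activation[:, start:stop] += amp[:, None] * resp[: stop - start]

    def nuisance() -> np.ndarray:
        out = rng.normal(0.0, profile.noise_sd, size=(n_ch, n_samples))
        if cfg.physio_amp > 0:
            for freq in (1.1, 0.3, 0.1):
                phases = rng.uniform(0, 2 * np.pi, size=n_ch)
                out += cfg.physio_amp * np.sin(
                    2 * np.pi * freq * time[None, :] + phases[:, None])
        if profile.drift_sd > 0:
            steps = rng.normal(0.0, profile.drift_sd / np.sqrt(fs), size=(n_ch, n_samples))
            out += np.cumsum(steps, axis=1)
        return out

    dhbo = activation + nuisance()
    hbr_act = np.zeros_like(activation)
    if delay < n_samples:
        hbr_act[:, delay:] = activation[:, : n_samples - delay]
    dhbr = cfg.hbr_ratio * hbr_act + 0.5 * nuisance()

    events = [(int(round(o * fs)), cfg.classes[lab]) for o, lab in zip(onsets, labels)]
    hemo = HemoSignal(dHbO=dhbo, dHbR=dhbr, fs=fs, events=events,
                      subject_id=profile.subject_id)
    return hemo, epoch(hemo, kind="both")


def trial_template(profile: SubjectProfile, cfg: GeneratorConfig, class_label: str,
                   pre_s: float = 2.0, post_s: float = 28.0) -> np.ndarray:
    """Deterministic noise-free epoch template for one class (HbO+HbR rows)."""
    resp = _task_response(cfg)
    fs = cfg.fs
    n = int(round((pre_s + post_s) * fs))
    n_pre = int(round(pre_s * fs))
    amp = cfg.amplitude * profile.topography[class_label] * profile.gain
    hbo = np.zeros((cfg.n_channels, n))
    start = n_pre + int(round(profile.latency_shift * fs))
    stop = min(start + resp.size, n)
    hbo[:, start:stop] = amp[:, None] * resp[: stop - start]
    delay = int(round(cfg.hbr_delay_s * fs))
    hbr = np.zeros_like(hbo)
    if delay < n:
        hbr[:, delay:] = cfg.hbr_ratio * hbo[:, : n - delay]
    return np.concatenate([hbo, hbr], axis=0)


def make_dataset(cfg: GeneratorConfig | None = None,
                 shift_level: str = "mild") -> LabeledDataset:
    """Generate a fully labelled multi-subject dataset.

    Subject profiles are drawn from hyper-priors whose widths grow with
    ``shift_level``; ``"none"`` makes every profile identical.  The config
    seed fully determines the output.
    """
    cfg = cfg or GeneratorConfig()
    ss = np.random.SeedSequence(cfg.seed)
    profile_rng = np.random.default_rng(ss.spawn(1)[0])
    subject_seeds = ss.spawn(cfg.n_subjects + 1)[1:]

    trials: list[TrialEpoch] = []
    profiles: list[SubjectProfile] = []
    recordings: list[HemoSignal] = []
    for i in range(cfg.n_subjects):
        sid = f"S{i + 1:02d}"
        profile = draw_profile(sid, cfg, shift_level, profile_rng)
        hemo, eps = synthesize_subject(profile, cfg, np.random.default_rng(subject_seeds[i]))
        profiles.append(profile)
        recordings.append(hemo)
        trials.extend(eps)
    return LabeledDataset(trials=trials, subjects=profiles, recordings=recordings,
                          generator_config=cfg)


def dataset_to_arrays(ds: LabeledDataset, roi: str | None = None,
                      filter_signal: bool = True,
                      report: EpochReport | None = None):
    """Run the standard preprocessing chain over every subject's recording and
    stack the result into (X, y, subject) training arrays."""
    trials: list[TrialEpoch] = []
    for hemo in ds.recordings:
        trials.extend(preprocess_hemo(hemo, roi=roi, filter_signal=filter_signal,
                                      report=report))
    return trials_to_arrays(trials)
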