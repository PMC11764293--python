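"""Raw-intensity to network-ready trial preprocessing for fNIRS recordings.

The chain implemented here is the standard hemodynamic pipeline:

1. light intensity -> optical-density change (relative to a reference),
2. modified Beer-Lambert law (MBLL) inversion to oxy-/deoxyhemoglobin
   concentration changes (dHbO, dHbR),
3. third-order Butterworth band-pass, 0.01-0.1 Hz, applied zero-phase,
4. epoching around task onsets (-2 s .. +28 s),
5. baseline correction against the -1..0 s pre-task mean,
6. a fixed analysis window of 256 samples (indices [20, 276)), and
7. optional region-of-interest channel selection over the 20-channel montage.

Trial epochs stack dHbO and dHbR rows per measurement channel, so the default
20-channel montage yields 40 feature channels.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import signal as sps

logger = logging.getLogger(__name__)

CLASS_NAMES = ("left", "right", "feet")
CLASS_TO_INDEX = {name: i for i, name in enumerate(CLASS_NAMES)}

#: Molar extinction coefficients [L mol^-1 cm^-1], rows = wavelengths
#: (760 nm, 850 nm), columns = (HbO, HbR).  Standard two-wavelength table;
#: overridable through MbllConfig.
DEFAULT_EXTINCTION = np.array([[1486.6, 3843.7], [2526.4, 1798.6]])
DEFAULT_WAVELENGTHS = (760.0, 850.0)

#: Region-of-interest channel table over the 20-channel bilateral motor-cortex
#: montage (1-based measurement-channel indices).
ROI_TABLE: dict[str, tuple[int, ...]] = {
    "A": (1, 2, 3, 4, 11, 12, 13, 14),
    "B": (5, 6, 15, 16),
    "C": (4, 5, 6, 7, 14, 15, 16, 17),
    "D": (8, 9, 18, 19),
    "E": (7, 8, 9, 10, 17, 18, 19, 20),
    "FULL": tuple(range(1, 21)),
}


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass
class RawRecording:
    """Two-wavelength light-intensity recording with event markers.

    ``intensity`` has shape (2, n_channels, n_samples) indexed by wavelength;
    ``events`` is a list of ``(onset_sample, class_label)`` pairs.
    """

    intensity: np.ndarray
    wavelengths: tuple[float, float]
    fs: float
    events: list[tuple[int, str]]
    subject_id: str = "S0"

    def __post_init__(self):
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.intensity.ndim != 3 or self.intensity.shape[0] != 2:
            raise ValueError(
                f"intensity must be (2, channels, samples), got {self.intensity.shape}"
            )
        if len(self.wavelengths) != 2:
            raise ValueError(f"exactly two wavelengths required, got {self.wavelengths}")
        bad = np.argwhere(self.intensity <= 0)
        if bad.size:
            w, c, s = bad[0]
            raise ValueError(
                f"non-positive intensity at wavelength {w}, channel {c}, sample {s}"
            )
        n = self.intensity.shape[2]
        for onset, label in self.events:
            if not 0 <= onset < n:
                raise ValueError(f"event onset {onset} outside recording of {n} samples")
            if label not in CLASS_TO_INDEX:
                raise ValueError(f"unknown class label {label!r}; expected {CLASS_NAMES}")


@dataclass
class OpticalDensityChange:
    """Optical-density change per wavelength, shape (2, channels, samples)."""

    dOD: np.ndarray
    fs: float
    events: list[tuple[int, str]]
    subject_id: str = "S0"


@dataclass
class HemoSignal:
    """Continuous dHbO/dHbR concentration-change signals with events."""

    dHbO: np.ndarray
    dHbR: np.ndarray
    fs: float
    events: list[tuple[int, str]]
    subject_id: str = "S0"

    def __post_init__(self):
        self.dHbO = np.asarray(self.dHbO, dtype=float)
        self.dHbR = np.asarray(self.dHbR, dtype=float)
        if self.dHbO.shape != self.dHbR.shape:
            raise ValueError(
                f"dHbO shape {self.dHbO.shape} != dHbR shape {self.dHbR.shape}"
            )

    @property
    def n_channels(self) -> int:
        return self.dHbO.shape[0]

    @property
    def n_samples(self) -> int:
        return self.dHbO.shape[1]


@dataclass
class MbllConfig:
    """MBLL constants: source-detector distance, DPFs and extinction matrix."""

    d: float = 3.0  # cm
    dpf: tuple[float, float] = (6.0, 6.0)
    eps: np.ndarray = field(default_factory=lambda: DEFAULT_EXTINCTION.copy())

    def __post_init__(self):
        self.eps = np.asarray(self.eps, dtype=float)
        if self.d <= 0:
            raise ValueError(f"source-detector distance must be > 0, got {self.d}")
        if any(v <= 0 for v in self.dpf):
            raise ValueError(f"DPF values must be > 0, got {self.dpf}")
        if self.eps.shape != (2, 2):
            raise ValueError(f"extinction matrix must be 2x2, got {self.eps.shape}")
        if np.linalg.cond(self.eps) > 1e12:
            raise ValueError("extinction matrix eps is singular")


@dataclass
class FilterConfig:
    """Butterworth band-pass specification."""

    order: int = 3
    band: tuple[float, float] = (0.01, 0.1)
    zero_phase: bool = True

    def __post_init__(self):
        low, high = self.band
        if self.order < 1:
            raise ValueError(f"filter order must be >= 1, got {self.order}")
        if not 0 < low < high:
            raise ValueError(f"band must satisfy 0 < low < high, got {self.band}")

    def sos(self, fs: float) -> np.ndarray:
        low, high = self.band
        if high >= fs / 2:
            raise ValueError(
                f"band edge {high} Hz at or above Nyquist for fs={fs} Hz"
            )
        return sps.butter(self.order, self.band, btype="bandpass", fs=fs, output="sos")


@dataclass
class TrialEpoch:
    """One trial: stacked (dHbO, dHbR) feature channels by time.

    Feature rows are ordered [HbO ch1..chN, HbR ch1..chN]; ``channels`` records
    the 1-based measurement-channel identity of each montage channel retained.
    """

    data: np.ndarray
    fs: float
    t0_offset: float
    class_label: str
    subject_id: str = "S0"
    channels: tuple[int, ...] = tuple(range(1, 21))
    signal_kind: str = "both"  # both | hbo | hbr

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        if self.class_label not in CLASS_TO_INDEX:
            raise ValueError(f"unknown class label {self.class_label!r}")

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def label_index(self) -> int:
        return CLASS_TO_INDEX[self.class_label]


@dataclass
class RoiSpec:
    """Named region of interest over the measurement-channel montage."""

    name: str
    channels: tuple[int, ...]

    @classmethod
    def from_name(cls, name: str) -> "RoiSpec":
        key = name.upper()
        if key not in ROI_TABLE:
            raise ValueError(
                f"unknown ROI {name!r}; valid names: {sorted(ROI_TABLE)}"
            )
        return cls(name=key, channels=ROI_TABLE[key])

    def __post_init__(self):
        if len(set(self.channels)) != len(self.channels):
            raise ValueError(f"duplicate channels in ROI {self.name}: {self.channels}")


@dataclass
class EpochReport:
    """Bookkeeping for epoching: kept vs dropped trial counts."""

    n_events: int = 0
    n_epochs: int = 0
    n_dropped: int = 0


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------

def intensity_to_od(raw: RawRecording, reference: str = "mean") -> OpticalDensityChange:
    """Convert light intensity to optical-density change.

    ``dOD[w, c, t] = -log10(I[w, c, t] / I_ref[w, c])`` with the reference
    intensity either the per-channel temporal mean (default, the common fNIRS
    convention) or the first sample.
    """
    if reference == "mean":
        ref = raw.intensity.mean(axis=2, keepdims=True)
    elif reference == "first_sample":
        ref = raw.intensity[:, :, :1]
    else:
        raise ValueError(f"reference must be 'mean' or 'first_sample', got {reference!r}")
    dod = -np.log10(raw.intensity / ref)
    return OpticalDensityChange(dOD=dod, fs=raw.fs, events=list(raw.events),
                                subject_id=raw.subject_id)


def mbll(od: OpticalDensityChange, cfg: MbllConfig | None = None) -> HemoSignal:
    """Invert the modified Beer-Lambert law.

    Per channel and sample::

        [dHbO, dHbR]^T = (1/d) * eps^-1 @ [dOD(l1)/DPF(l1), dOD(l2)/DPF(l2)]^T

    where ``eps`` holds the extinction coefficients (rows = wavelengths,
    columns = (HbO, HbR)) and ``d`` is the source-detector distance.
    """
    cfg = cfg or MbllConfig()
    dod = np.asarray(od.dOD, dtype=float)
    if dod.ndim != 3 or dod.shape[0] != 2:
        raise ValueError(f"dOD must be (2, channels, samples), got {dod.shape}")
    scaled = dod / np.asarray(cfg.dpf, dtype=float)[:, None, None]
    inv = np.linalg.inv(cfg.eps)
    # (2, C, S) contracted against eps^-1 on the wavelength axis
    hemo = np.einsum("ij,jcs->ics", inv, scaled) / cfg.d
    return HemoSignal(dHbO=hemo[0], dHbR=hemo[1], fs=od.fs, events=list(od.events),
                      subject_id=od.subject_id)


def mbll_forward(dhbo: np.ndarray, dhbr: np.ndarray, cfg: MbllConfig) -> np.ndarray:
    """Forward Beer-Lambert synthesis (concentrations -> dOD); test oracle."""
    conc = np.stack([np.asarray(dhbo, dtype=float), np.asarray(dhbr, dtype=float)])
    dod = np.einsum("ij,jcs->ics", cfg.eps, conc) * cfg.d
    return dod * np.asarray(cfg.dpf, dtype=float)[:, None, None]


def bandpass(sig: HemoSignal, cfg: FilterConfig | None = None) -> HemoSignal:
    """Band-pass both hemoglobin signals.

    Zero-phase by default (forward-backward second-order sections), honouring
    the distortion-free intent of the design; a causal single pass is available
    via ``FilterConfig(zero_phase=False)``.
    """
    cfg = cfg or FilterConfig()
    sos = cfg.sos(sig.fs)
    apply = (lambda x: sps.sosfiltfilt(sos, x, axis=-1)) if cfg.zero_phase else (
        lambda x: sps.sosfilt(sos, x, axis=-1))
    return HemoSignal(dHbO=apply(sig.dHbO), dHbR=apply(sig.dHbR), fs=sig.fs,
                      events=list(sig.events), subject_id=sig.subject_id)


def stack_features(sig: HemoSignal, start: int, stop: int, kind: str = "both") -> np.ndarray:
    seg_o = sig.dHbO[:, start:stop]
    seg_r = sig.dHbR[:, start:stop]
    if kind == "both":
        return np.concatenate([seg_o, seg_r], axis=0)
    if kind == "hbo":
        return seg_o
    if kind == "hbr":
        return seg_r
    raise ValueError(f"signal kind must be both|hbo|hbr, got {kind!r}")


def epoch(sig: HemoSignal, pre_s: float = 2.0, post_s: float = 28.0,
          kind: str = "both", report: EpochReport | None = None) -> list[TrialEpoch]:
    """Cut one epoch per event, ``pre_s`` before to ``post_s`` after onset.

    Events whose window would extend past either end of the recording are
    dropped with a logged warning and counted in ``report``.
    """
    n_pre = int(round(pre_s * sig.fs))
    n_post = int(round(post_s * sig.fs))
    n = sig.n_samples
    epochs: list[TrialEpoch] = []
    if report is None:
        report = EpochReport()
    report.n_events += len(sig.events)
    for onset, label in sig.events:
        start, stop = onset - n_pre, onset + n_post
        if start < 0 or stop > n:
            logger.warning(
                "dropping trial at sample %d (%s): window [%d, %d) outside recording "
                "of %d samples", onset, label, start, stop, n)
            report.n_dropped += 1
            continue
        data = stack_features(sig, start, stop, kind)
        epochs.append(TrialEpoch(data=data, fs=sig.fs, t0_offset=pre_s,
                                 class_label=label, subject_id=sig.subject_id,
                                 channels=tuple(range(1, sig.n_channels + 1)),
                                 signal_kind=kind))
        report.n_epochs += 1
    return epochs


def baseline_correct(trial: TrialEpoch, window: tuple[float, float] = (-1.0, 0.0)) -> TrialEpoch:
    """Subtract the per-channel mean of the baseline window (BC(x) = x - u0).

    ``window`` is in seconds relative to task onset; the default -1..0 s is
    the last pre-task second.
    """
    lo = int(round((window[0] + trial.t0_offset) * trial.fs))
    hi = int(round((window[1] + trial.t0_offset) * trial.fs))
    if not 0 <= lo < hi <= trial.n_samples:
        raise ValueError(
            f"baseline window {window} s maps to samples [{lo}, {hi}) outside epoch "
            f"of {trial.n_samples} samples")
    u0 = trial.data[:, lo:hi].mean(axis=1, keepdims=True)
    return replace(trial, data=trial.data - u0)


def crop_window(trial: TrialEpoch, start: int = 20, stop: int = 276) -> TrialEpoch:
    """Keep samples with 0-based index in the half-open range [start, stop)."""
    if trial.n_samples < stop:
        raise ValueError(
            f"epoch has {trial.n_samples} samples, cannot crop to [{start}, {stop})")
    new_t0 = trial.t0_offset - start / trial.fs
    return replace(trial, data=trial.data[:, start:stop], t0_offset=new_t0)


def select_roi(trial: TrialEpoch, roi: RoiSpec | str) -> TrialEpoch:
    """Retain only the ROI's measurement channels (both HbO and HbR rows)."""
    if isinstance(roi, str):
        roi = RoiSpec.from_name(roi)
    pos = {ch: i for i, ch in enumerate(trial.channels)}
    missing = [ch for ch in roi.channels if ch not in pos]
    if missing:
        raise ValueError(f"ROI {roi.name} channels {missing} absent from trial")
    idx = np.array([pos[ch] for ch in roi.channels])
    n = len(trial.channels)
    if trial.signal_kind == "both":
        rows = np.concatenate([idx, idx + n])
    else:
        rows = idx
    return replace(trial, data=trial.data[rows], channels=tuple(roi.channels))


def preprocess_recording(raw: RawRecording, mbll_cfg: MbllConfig | None = None,
                         filter_cfg: FilterConfig | None = None,
                         reference: str = "mean", pre_s: float = 2.0,
                         post_s: float = 28.0, baseline: tuple[float, float] = (-1.0, 0.0),
                         window: tuple[int, int] = (20, 276), roi: str | None = None,
                         kind: str = "both",
                         report: EpochReport | None = None) -> list[TrialEpoch]:
    """Full chain: intensity -> dOD -> MBLL -> filter -> epoch -> BC -> crop -> ROI."""
    hemo = mbll(intensity_to_od(raw, reference), mbll_cfg)
    return preprocess_hemo(hemo, filter_cfg=filter_cfg, pre_s=pre_s, post_s=post_s,
                           baseline=baseline, window=window, roi=roi, kind=kind,
                           report=report)


def preprocess_hemo(hemo: HemoSignal, filter_cfg: FilterConfig | None = None,
                    pre_s: float = 2.0, post_s: float = 28.0,
                    baseline: tuple[float, float] = (-1.0, 0.0),
                    window: tuple[int, int] = (20, 276), roi: str | None = None,
                    kind: str = "both", filter_signal: bool = True,
                    report: EpochReport | None = None) -> list[TrialEpoch]:
    """Concentration-signal entry point of the chain (for pre-converted data)."""
    if filter_signal:
        hemo = bandpass(hemo, filter_cfg)
    trials = []
    for tr in epoch(hemo, pre_s=pre_s, post_s=post_s, kind=kind, report=report):
        tr = baseline_correct(tr, baseline)
        tr = crop_window(tr, *window)
        if roi is not None:
            tr = select_roi(tr, roi)
        trials.append(tr)
    return trials


def trials_to_arrays(trials: list[TrialEpoch]) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Stack epochs into (X, y, subjects) arrays for the estimators."""
    if not trials:
        raise ValueError("no trials to stack")
    X = np.stack([t.data for t in trials])
    y = np.array([t.label_index for t in trials])
    subjects = np.array([t.subject_id for t in trials])
    return X, y, subjects
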