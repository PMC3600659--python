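"""Feedback-locked ERP scoring.

Epochs span -200..+350 ms around feedback onset at 250 Hz.  Processing:
amplitude-based artifact rejection (strict +/-100 uV), per-condition
baseline-corrected averaging, then component scores:

* FRN per condition = mean amplitude over 220-350 ms minus the positive
  peak (window maximum) over 150-220 ms; the differential FRN score is
  FRN(PF) - FRN(NF).
* P3 per condition = mean over the last 50 ms of the epoch referenced to
  the mean of the immediately preceding 100 ms; the differential P3
  score is P3(NF) - P3(PF) (note the opposite order).

All window bounds are inclusive.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "EpochSet",
    "ScoringConfig",
    "FRNScore",
    "reject_artifacts",
    "condition_average",
    "frn_component",
    "frn_score",
    "p3_score",
    "score_epochs",
]

CONDITIONS = ("PF", "NF")


@dataclass
class EpochSet:
    """Feedback-locked multichannel epochs.

    ``data`` has shape (n_epochs, n_channels, n_samples) in microvolts;
    ``times`` are milliseconds relative to feedback onset, uniformly
    spaced at ``1000 / sfreq``.
    """

    data: np.ndarray
    times: np.ndarray
    channels: list
    conditions: np.ndarray      # array of 'PF' / 'NF' per epoch
    sfreq: float

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        self.times = np.asarray(self.times, dtype=float)
        self.conditions = np.asarray(self.conditions)
        if self.data.ndim != 3:
            raise ValueError("data must be (epochs, channels, samples)")
        n_ep, n_ch, n_s = self.data.shape
        if len(self.times) != n_s:
            raise ValueError("times length mismatch")
        if len(self.channels) != n_ch:
            raise ValueError("channel list mismatch")
        if len(self.conditions) != n_ep:
            raise ValueError("conditions length mismatch")
        dt = np.diff(self.times)
        if len(dt) and (np.any(dt <= 0)
                        or not np.allclose(dt, 1000.0 / self.sfreq, atol=1e-6)):
            raise ValueError("times must increase uniformly at 1000/sfreq")

    @property
    def n_epochs(self) -> int:
        return self.data.shape[0]

    def subset(self, idx) -> "EpochSet":
        return EpochSet(data=self.data[idx], times=self.times,
                        channels=list(self.channels),
                        conditions=self.conditions[idx], sfreq=self.sfreq)

    # -- container I/O: raw .npy array + JSON sidecar -----------------
    def save(self, prefix) -> None:
        prefix = Path(prefix)
        prefix.parent.mkdir(parents=True, exist_ok=True)
        np.save(str(prefix) + ".npy", self.data)
        sidecar = {
            "channels": list(self.channels),
            "sfreq": self.sfreq,
            "times_ms": self.times.tolist(),
            "conditions": [str(c) for c in self.conditions],
        }
        with open(str(prefix) + ".json", "w") as fh:
            json.dump(sidecar, fh)

    @classmethod
    def load(cls, prefix) -> "EpochSet":
        data = np.load(str(prefix) + ".npy")
        with open(str(prefix) + ".json") as fh:
            sc = json.load(fh)
        return cls(data=data, times=np.array(sc["times_ms"]),
                   channels=sc["channels"],
                   conditions=np.array(sc["conditions"]), sfreq=sc["sfreq"])


@dataclass(frozen=True)
class ScoringConfig:
    rejection_threshold: float = 100.0           # uV, strict "outside"
    frn_mean_window: tuple = (220.0, 350.0)      # ms
    frn_peak_window: tuple = (150.0, 220.0)
    p3_late_window: tuple = (300.0, 350.0)       # last 50 ms
    p3_ref_window: tuple = (200.0, 300.0)        # preceding 100 ms
    baseline_window: tuple = (-200.0, 0.0)
    min_retained: dict = field(default_factory=lambda: {"NF": 27, "PF": 51})

    def __post_init__(self):
        if self.frn_peak_window[1] > self.frn_mean_window[0]:
            raise ValueError("peak window must precede the mean window")


@dataclass
class FRNScore:
    channel: str
    frn_pf: float
    frn_nf: float
    retained: dict | None = None

    @property
    def differential(self) -> float:
        return self.frn_pf - self.frn_nf


def _window_mask(times: np.ndarray, window) -> np.ndarray:
    lo, hi = window
    mask = (times >= lo) & (times <= hi)
    if not mask.any():
        raise ValueError(f"no samples inside window {window}")
    return mask


def reject_artifacts(epochs: EpochSet, config: ScoringConfig = ScoringConfig()):
    """Exclude epochs with any sample strictly outside the +/- threshold
    range on any channel (a sample at exactly the threshold is kept).

    Returns ``(retained_epochs, report)``; raises if a condition loses
    all epochs, warns if retained counts fall below ``min_retained``.
    """
    thr = config.rejection_threshold
    bad = np.abs(epochs.data).max(axis=(1, 2)) > thr
    keep = ~bad
    retained = epochs.subset(keep)
    report = {
        "threshold_uv": thr,
        "n_input": int(epochs.n_epochs),
        "n_excluded": int(bad.sum()),
        "excluded_indices": np.flatnonzero(bad).tolist(),
        "retained_per_condition": {},
        "warnings": [],
    }
    for cond in np.unique(epochs.conditions):
        n_kept = int(np.sum(retained.conditions == cond))
        report["retained_per_condition"][str(cond)] = n_kept
        if n_kept == 0:
            raise ValueError(f"all {cond} epochs rejected")
        floor = config.min_retained.get(str(cond))
        if floor is not None and n_kept < floor:
            msg = f"{cond}: only {n_kept} epochs retained (< {floor})"
            report["warnings"].append(msg)
            warnings.warn(msg, stacklevel=2)
    return retained, report


def condition_average(epochs: EpochSet,
                      config: ScoringConfig = ScoringConfig()) -> dict:
    """Per-condition mean waveform (channels x samples) after per-epoch,
    per-channel baseline correction to the pre-feedback mean."""
    base = _window_mask(epochs.times, config.baseline_window)
    corrected = epochs.data - epochs.data[:, :, base].mean(axis=2, keepdims=True)
    out = {}
    for cond in np.unique(epochs.conditions):
        sel = epochs.conditions == cond
        out[str(cond)] = corrected[sel].mean(axis=0)
    return out


def frn_component(waveform, times, config: ScoringConfig = ScoringConfig()) -> float:
    """Windowed-mean-minus-preceding-positive-peak FRN for one channel.

    The "positive peak" is the maximum sample in the peak window even if
    it is negative (a warning is emitted in that degenerate case).
    """
    waveform = np.asarray(waveform, dtype=float)
    mean_amp = waveform[_window_mask(times, config.frn_mean_window)].mean()
    peak = waveform[_window_mask(times, config.frn_peak_window)].max()
    if peak < 0:
        warnings.warn("positive-peak window maximum is negative", stacklevel=2)
    return float(mean_amp - peak)


def frn_score(erp_pf, erp_nf, times, config: ScoringConfig = ScoringConfig(),
              channels=None) -> pd.DataFrame:
    """Per-channel FRN for each condition and the differential PF - NF."""
    erp_pf = np.atleast_2d(np.asarray(erp_pf, dtype=float))
    erp_nf = np.atleast_2d(np.asarray(erp_nf, dtype=float))
    if channels is None:
        channels = [f"ch{i}" for i in range(erp_pf.shape[0])]
    rows = []
    for i, ch in enumerate(channels):
        f_pf = frn_component(erp_pf[i], times, config)
        f_nf = frn_component(erp_nf[i], times, config)
        rows.append({"channel": ch, "frn_pf": f_pf, "frn_nf": f_nf,
                     "frn_differential": f_pf - f_nf})
    return pd.DataFrame(rows)


def p3_score(erp_pf, erp_nf, times, config: ScoringConfig = ScoringConfig(),
             channels=None) -> pd.DataFrame:
    """Per-channel late-window P3 referenced to the preceding 100 ms;
    differential is NF - PF (opposite order to the FRN)."""
    erp_pf = np.atleast_2d(np.asarray(erp_pf, dtype=float))
    erp_nf = np.atleast_2d(np.asarray(erp_nf, dtype=float))
    if channels is None:
        channels = [f"ch{i}" for i in range(erp_pf.shape[0])]
    late = _window_mask(times, config.p3_late_window)
    ref = _window_mask(times, config.p3_ref_window)
    rows = []
    for i, ch in enumerate(channels):
        p_pf = float(erp_pf[i, late].mean() - erp_pf[i, ref].mean())
        p_nf = float(erp_nf[i, late].mean() - erp_nf[i, ref].mean())
        rows.append({"channel": ch, "p3_pf": p_pf, "p3_nf": p_nf,
                     "p3_differential": p_nf - p_pf})
    return pd.DataFrame(rows)


def score_epochs(epochs: EpochSet, config: ScoringConfig = ScoringConfig()):
    """Full pipeline: rejection -> averaging -> FRN and P3 tables.

    Returns ``(frn_table, p3_table, rejection_report)``.
    """
    retained, report = reject_artifacts(epochs, config)
    averages = condition_average(retained, config)
    if not {"PF", "NF"} <= set(averages):
        raise ValueError("both PF and NF conditions are required")
    frn = frn_score(averages["PF"], averages["NF"], retained.times, config,
                    channels=retained.channels)
    p3 = p3_score(averages["PF"], averages["NF"], retained.times, config,
                  channels=retained.channels)
    return frn, p3, report
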