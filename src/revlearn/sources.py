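"""Correlation-based identification of cortical FRN sources.

The procedure: (1) average each voxel's current density over the
220-330 ms post-feedback window; (2) correlate that average with the
per-participant FRN score across participants, voxel by voxel; (3) flag
anatomical areas in which at least ``min_voxels`` voxels correlate
significantly.  Cross-group contrasts of area-level correlations use the
independent-samples Fisher z test with Bonferroni adjustment.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "CurrentDensityMap",
    "window_average",
    "voxel_frn_correlations",
    "identify_areas",
    "compare_correlations",
]

DEFAULT_SOURCE_WINDOW = (220.0, 330.0)


@dataclass
class CurrentDensityMap:
    """Participant x voxel window-averaged current densities with
    anatomical area labels per voxel."""

    densities: np.ndarray            # (n_participants, n_voxels)
    areas: list                      # area label per voxel
    participant_ids: list = field(default_factory=list)
    voxel_ids: list = field(default_factory=list)
    window: tuple = DEFAULT_SOURCE_WINDOW

    def __post_init__(self):
        self.densities = np.asarray(self.densities, dtype=float)
        if self.densities.ndim != 2:
            raise ValueError("densities must be (participants, voxels)")
        n_p, n_v = self.densities.shape
        if len(self.areas) != n_v:
            raise ValueError("one area label per voxel required")
        if not np.all(np.isfinite(self.densities)):
            raise ValueError("densities must be finite")
        if not self.participant_ids:
            self.participant_ids = [f"P{i + 1:02d}" for i in range(n_p)]
        if not self.voxel_ids:
            self.voxel_ids = [f"v{i:04d}" for i in range(n_v)]

    def to_frame(self) -> pd.DataFrame:
        n_p, n_v = self.densities.shape
        return pd.DataFrame({
            "participant_id": np.repeat(self.participant_ids, n_v),
            "voxel_id": np.tile(self.voxel_ids, n_p),
            "area": np.tile(self.areas, n_p),
            "density": self.densities.ravel(),
        })

    @classmethod
    def from_frame(cls, frame: pd.DataFrame, window=DEFAULT_SOURCE_WINDOW):
        pids = list(pd.unique(frame["participant_id"]))
        vids = list(pd.unique(frame["voxel_id"]))
        pivot = frame.pivot(index="participant_id", columns="voxel_id",
                            values="density").loc[pids, vids]
        area_of = frame.drop_duplicates("voxel_id").set_index("voxel_id")["area"]
        return cls(densities=pivot.to_numpy(), areas=[area_of[v] for v in vids],
                   participant_ids=pids, voxel_ids=vids, window=window)


def window_average(density_series, times, window=DEFAULT_SOURCE_WINDOW,
                   areas=None, participant_ids=None) -> CurrentDensityMap:
    """Average a (participants, voxels, time) series over the inclusive
    time window, yielding a :class:`CurrentDensityMap`."""
    series = np.asarray(density_series, dtype=float)
    times = np.asarray(times, dtype=float)
    if series.ndim != 3:
        raise ValueError("density series must be (participants, voxels, time)")
    lo, hi = window
    mask = (times >= lo) & (times <= hi)
    if not mask.any():
        raise ValueError(f"no samples inside window {window}")
    mean = series[:, :, mask].mean(axis=2)
    if areas is None:
        areas = ["unlabelled"] * series.shape[1]
    return CurrentDensityMap(densities=mean, areas=list(areas),
                             participant_ids=list(participant_ids or []),
                             window=tuple(window))


def _pearson_columns(x: np.ndarray, Y: np.ndarray):
    """Pearson r of vector ``x`` against each column of ``Y``; constant
    columns yield NaN."""
    xc = x - x.mean()
    Yc = Y - Y.mean(axis=0)
    sx = np.sqrt((xc**2).sum())
    sy = np.sqrt((Yc**2).sum(axis=0))
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (xc @ Yc) / (sx * sy)
    r[sy < 1e-12 * max(1.0, np.abs(Y).max())] = np.nan
    return r


def voxel_frn_correlations(cdm: CurrentDensityMap, frn,
                           method: str = "parametric",
                           n_boot: int = 2000, seed=None) -> pd.DataFrame:
    """Across-participant Pearson correlation of every voxel's density
    with the FRN score.

    ``method='parametric'`` gives two-sided p from t with n-2 df;
    ``method='bootstrap'`` gives a two-sided percentile-bootstrap p
    (sign inversion of the resampled r distribution).  Constant voxels
    are flagged with NaN, not fatal.
    """
    frn = np.asarray(frn, dtype=float)
    n = len(frn)
    if n < 4:
        raise ValueError("need at least 4 participants")
    if cdm.densities.shape[0] != n:
        raise ValueError("FRN vector length does not match participants")
    if np.ptp(frn) == 0:
        raise ValueError("FRN scores are constant")
    r = _pearson_columns(frn, cdm.densities)
    if method == "parametric":
        rc = np.clip(r, -1 + 1e-15, 1 - 1e-15)
        t = rc * np.sqrt((n - 2) / (1.0 - rc**2))
        p = 2.0 * stats.t.sf(np.abs(t), n - 2)
        p = np.where(np.isnan(r), np.nan, p)
    elif method == "bootstrap":
        rng = np.random.default_rng(seed)
        idx = rng.integers(0, n, size=(n_boot, n))
        counts = np.zeros(cdm.densities.shape[1])
        valid = np.zeros(cdm.densities.shape[1])
        for b in range(n_boot):
            rb = _pearson_columns(frn[idx[b]], cdm.densities[idx[b]])
            ok = ~np.isnan(rb)
            counts += np.where(ok & (np.sign(rb) != np.sign(r)) | (rb == 0), 1, 0)
            valid += ok
        with np.errstate(invalid="ignore", divide="ignore"):
            p = np.minimum(1.0, 2.0 * counts / np.maximum(valid, 1))
        p = np.where(np.isnan(r), np.nan, p)
    else:
        raise ValueError(f"unknown method {method!r}")
    return pd.DataFrame({"voxel_id": cdm.voxel_ids, "area": cdm.areas,
                         "r": r, "p": p})


def identify_areas(voxel_stats: pd.DataFrame, alpha: float = 0.05,
                   min_voxels: int = 10) -> pd.DataFrame:
    """Area-level summary: an area is ``included`` iff it contains at
    least ``min_voxels`` voxels with ``p < alpha``.  Counts are reported
    for every area regardless of inclusion."""
    rows = []
    for area, sub in voxel_stats.groupby("area", sort=False):
        sig = sub[sub["p"] < alpha]
        rows.append({
            "area": area,
            "n_voxels": int(len(sub)),
            "n_significant_voxels": int(len(sig)),
            "mean_r_significant": float(sig["r"].mean()) if len(sig) else np.nan,
            "mean_r_all": float(sub["r"].mean()),
            "included": bool(len(sig) >= min_voxels),
        })
    return pd.DataFrame(rows)


def compare_correlations(r1: float, n1: int, r2: float, n2: int,
                         n_comparisons: int = 1):
    """Independent-samples Fisher z contrast of two correlations with
    Bonferroni adjustment.

    Returns ``(z, p_adjusted)`` where ``p_adjusted = min(1, raw * m)``.
    """
    for r in (r1, r2):
        if abs(r) >= 1.0:
            raise ValueError("|r| = 1: Fisher transform undefined")
    if n1 < 4 or n2 < 4:
        raise ValueError("need n >= 4 in both samples")
    z1 = np.arctanh(r1)
    z2 = np.arctanh(r2)
    z = (z1 - z2) / np.sqrt(1.0 / (n1 - 3) + 1.0 / (n2 - 3))
    p = 2.0 * stats.norm.sf(abs(z))
    return float(z), float(min(1.0, p * n_comparisons))
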