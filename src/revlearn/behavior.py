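"""Behavioral dependent measures from trial logs.

Correct choices are tabulated per 10-trial block within each phase.
First-block counts index reversal cost (phases 2+), and the collapsed
(summed) last two blocks index the asymptotic learning level.  Exposure
covariates are rank-transformed before correlation analyses.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "BlockTable",
    "tabulate_blocks",
    "reversal_cost_scores",
    "asymptote_scores",
    "rank_transform",
    "partial_correlation",
    "metrics_table",
]


@dataclass
class BlockTable:
    """Per-participant phase x block correct-choice counts and mean
    latencies."""

    counts: np.ndarray       # (n_phases, n_blocks) int
    latency: np.ndarray      # (n_phases, n_blocks) float, ms
    block_size: int
    participant_id: str | None = None

    @property
    def n_phases(self) -> int:
        return self.counts.shape[0]

    @property
    def n_blocks(self) -> int:
        return self.counts.shape[1]


def tabulate_blocks(trials: pd.DataFrame, block_size: int = 10) -> BlockTable:
    """Aggregate a complete single-participant trial log into a
    :class:`BlockTable`.

    Raises ``ValueError`` on incomplete or duplicated trials.
    """
    required = {"phase", "trial", "block", "accurate", "latency_ms"}
    missing = required - set(trials.columns)
    if missing:
        raise ValueError(f"trial log missing columns: {sorted(missing)}")
    n_phases = int(trials["phase"].max())
    trials_per_phase = int(trials["trial"].max())
    expected = n_phases * trials_per_phase
    if len(trials) != expected:
        raise ValueError(
            f"incomplete log: {len(trials)} records, expected {expected}")
    keys = trials[["phase", "trial"]].apply(tuple, axis=1)
    if keys.duplicated().any():
        raise ValueError("duplicated (phase, trial) records")
    if trials_per_phase % block_size != 0:
        raise ValueError("trials_per_phase not divisible by block_size")
    n_blocks = trials_per_phase // block_size
    counts = np.zeros((n_phases, n_blocks), dtype=int)
    latency = np.zeros((n_phases, n_blocks), dtype=float)
    for (ph, bl), sub in trials.groupby(["phase", "block"]):
        if len(sub) != block_size:
            raise ValueError(f"phase {ph} block {bl} has {len(sub)} trials")
        counts[int(ph) - 1, int(bl) - 1] = int(sub["accurate"].sum())
        latency[int(ph) - 1, int(bl) - 1] = float(sub["latency_ms"].mean())
    pid = None
    if "participant_id" in trials.columns:
        ids = trials["participant_id"].unique()
        if len(ids) > 1:
            raise ValueError("trial log mixes participants")
        pid = str(ids[0])
    return BlockTable(counts=counts, latency=latency, block_size=block_size,
                      participant_id=pid)


def reversal_cost_scores(table: BlockTable) -> np.ndarray:
    """First-block correct counts per phase.

    Only phases 2+ follow a reversal; phase 1 is retained for design
    completeness but is an acquisition score, not a reversal cost.
    """
    return table.counts[:, 0].copy()


def asymptote_scores(table: BlockTable) -> np.ndarray:
    """Collapsed (summed) correct counts of the last two blocks per
    phase; range ``0 .. 2*block_size``."""
    return table.counts[:, -2:].sum(axis=1)


def rank_transform(values) -> np.ndarray:
    """Within-design rank scores (average ranks for ties)."""
    return stats.rankdata(np.asarray(values, dtype=float))


def partial_correlation(x, y, control, ranks: bool = False):
    """Partial correlation of ``x`` and ``y`` controlling for ``control``.

    Computed as the Pearson correlation of the least-squares residuals
    of ``x`` and ``y`` on ``[1, control]``.  ``control`` may be a vector
    or an ``(n, k)`` matrix.  With ``ranks=True`` all inputs are rank
    transformed first.  Two-sided p from the t distribution with
    ``n - 2 - k`` degrees of freedom.

    Returns ``(r_partial, p_two_sided)``.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    c = np.asarray(control, dtype=float)
    if c.ndim == 1:
        c = c[:, None]
    n = len(x)
    if len(y) != n or c.shape[0] != n:
        raise ValueError("inputs must have equal length")
    k = c.shape[1]
    if n < k + 3:
        raise ValueError("too few observations for partial correlation")
    if ranks:
        x = rank_transform(x)
        y = rank_transform(y)
        c = np.column_stack([rank_transform(c[:, j]) for j in range(k)])
    X = np.column_stack([np.ones(n), c])
    rx = x - X @ np.linalg.lstsq(X, x, rcond=None)[0]
    ry = y - X @ np.linalg.lstsq(X, y, rcond=None)[0]
    sx = np.sqrt(rx @ rx)
    sy = np.sqrt(ry @ ry)
    if sx < 1e-12 * max(1.0, abs(x).max()) or sy < 1e-12 * max(1.0, abs(y).max()):
        raise ValueError("constant residuals: partial correlation undefined")
    r = float((rx @ ry) / (sx * sy))
    df = n - 2 - k
    r_c = min(max(r, -1.0), 1.0)
    if abs(r_c) >= 1.0:
        return r_c, 0.0
    t = r_c * np.sqrt(df / (1.0 - r_c**2))
    p = float(2.0 * stats.t.sf(abs(t), df))
    return r, p


def metrics_table(tables: list[BlockTable]) -> pd.DataFrame:
    """Flatten block tables into one row per participant: 16 counts, 16
    latencies, 4 reversal-cost and 4 asymptote entries."""
    rows = []
    for t in tables:
        row = {"participant_id": t.participant_id}
        for ph in range(t.n_phases):
            for bl in range(t.n_blocks):
                row[f"correct_p{ph + 1}b{bl + 1}"] = int(t.counts[ph, bl])
                row[f"latency_p{ph + 1}b{bl + 1}"] = float(t.latency[ph, bl])
        rc = reversal_cost_scores(t)
        asym = asymptote_scores(t)
        for ph in range(t.n_phases):
            row[f"reversal_cost_p{ph + 1}"] = int(rc[ph])
            row[f"asymptote_p{ph + 1}"] = int(asym[ph])
        rows.append(row)
    return pd.DataFrame(rows)
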