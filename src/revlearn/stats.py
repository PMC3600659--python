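"""Repeated-measures inference: mixed ANOVA with Greenhouse-Geisser
correction, repeated-measures ANCOVA with continuous covariates, and
pairwise post hocs (Bonferroni / uncorrected LSD).

The implementation uses the classical univariate approach on orthonormal
within-subject contrasts: for each within effect the subject x cell
matrix is projected onto the effect's contrast space, hypothesis and
error sums of squares are accumulated there, and the averaged F test is
corrected by the Greenhouse-Geisser epsilon estimated from the pooled
error covariance (applied when a Mauchly sphericity pretest rejects at
alpha = 0.05, reported always).  Between-group tests with one between
factor reduce to a one-way ANOVA on subject means.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "gg_epsilon",
    "mauchly",
    "mixed_anova",
    "ancova_rm",
    "posthoc",
]

GG_PRETEST_ALPHA = 0.05


def _orthonormal_contrasts(k: int) -> np.ndarray:
    """k x (k-1) orthonormal Helmert-style contrasts, orthogonal to the
    unit vector."""
    H = np.zeros((k, k - 1))
    for j in range(1, k):
        H[:j, j - 1] = 1.0
        H[j, j - 1] = -j
    return H / np.linalg.norm(H, axis=0)


def gg_epsilon(within_covariance) -> float:
    """Greenhouse-Geisser epsilon from a k x k within-level covariance
    matrix, clamped to ``[1/(k-1), 1]``.

    Computed from the eigenvalues of the double-centered covariance,
    which equal those of the covariance in any orthonormal contrast
    space.
    """
    S = np.asarray(within_covariance, dtype=float)
    if S.ndim != 2 or S.shape[0] != S.shape[1]:
        raise ValueError("covariance must be square")
    if not np.allclose(S, S.T, atol=1e-8 * max(1.0, np.abs(S).max())):
        raise ValueError("covariance must be symmetric")
    k = S.shape[0]
    if k < 2:
        raise ValueError("need at least two within levels")
    H = np.eye(k) - 1.0 / k
    C = H @ S @ H
    lam = np.linalg.eigvalsh(C)
    lam = np.clip(lam, 0.0, None)
    d = k - 1
    denom = d * float(lam @ lam)
    if denom <= 0:
        return 1.0
    eps = float(lam.sum()) ** 2 / denom
    return float(np.clip(eps, 1.0 / d, 1.0))


def _gg_from_contrast_cov(Sc: np.ndarray) -> float:
    d = Sc.shape[0]
    if d == 1:
        return 1.0
    tr = float(np.trace(Sc))
    tr2 = float(np.trace(Sc @ Sc))
    if tr2 <= 0:
        return 1.0
    return float(np.clip(tr**2 / (d * tr2), 1.0 / d, 1.0))


def mauchly(Sc: np.ndarray, df_error: int) -> float:
    """Mauchly sphericity test p-value on a contrast-space covariance."""
    d = Sc.shape[0]
    if d < 2:
        return 1.0
    sign, logdet = np.linalg.slogdet(Sc)
    if sign <= 0:
        return 0.0
    logW = logdet - d * np.log(np.trace(Sc) / d)
    f = 1.0 - (2.0 * d**2 + d + 2.0) / (6.0 * d * df_error)
    chi2 = -df_error * f * logW
    df = d * (d + 1) // 2 - 1
    return float(sps.chi2.sf(max(chi2, 0.0), df))


def _within_effect_basis(within_levels: dict, effect: tuple) -> np.ndarray:
    """Kronecker contrast basis (m x d) for a within effect over the cell
    ordering given by the cartesian product of sorted factor levels (first
    factor slowest)."""
    mats = []
    for f, levels in within_levels.items():
        k = len(levels)
        mats.append(_orthonormal_contrasts(k) if f in effect
                    else np.ones((k, 1)) / np.sqrt(k))
    C = mats[0]
    for M in mats[1:]:
        C = np.kron(C, M)
    return C


def _pivot_wide(data, dv, within, subject):
    """Subject x cell response matrix; raises on unbalanced cells."""
    d = data.copy()
    counts = d.groupby([subject] + within, observed=True).size()
    if (counts != 1).any():
        bad = counts[counts != 1]
        raise ValueError(f"unbalanced design cells:\n{bad.head(10)}")
    wide = d.pivot_table(index=subject, columns=within, values=dv,
                         observed=True)
    if wide.isna().any().any():
        raise ValueError("missing within-factor cells for some subjects")
    within_levels = {f: sorted(data[f].unique()) for f in within}
    # column order: cartesian product, first factor slowest
    idx = pd.MultiIndex.from_product([within_levels[f] for f in within],
                                     names=within) if len(within) > 1 else \
        pd.Index(within_levels[within[0]], name=within[0])
    wide = wide.reindex(columns=idx)
    return wide, within_levels


def _effect_rows(within) -> list:
    effects = []
    for size in range(1, len(within) + 1):
        effects.extend(combinations(within, size))
    return effects


@dataclass
class _WithinTest:
    source: str
    ss_h: float
    ss_e: float
    df1: int
    df2: int
    eps: float
    sphericity_p: float

    def row(self) -> dict:
        F = (self.ss_h / self.df1) / (self.ss_e / self.df2)
        p_unc = float(sps.f.sf(F, self.df1, self.df2))
        p_gg = float(sps.f.sf(F, self.df1 * self.eps, self.df2 * self.eps))
        corrected = self.sphericity_p < GG_PRETEST_ALPHA
        return {
            "source": self.source, "ss": self.ss_h, "df1": self.df1,
            "df2": self.df2, "F": F, "p_unc": p_unc, "eps": self.eps,
            "p_gg": p_gg, "sphericity_p": self.sphericity_p,
            "gg_applied": bool(corrected),
            "p": p_gg if corrected else p_unc,
            "np2": self.ss_h / (self.ss_h + self.ss_e),
        }


def mixed_anova(data: pd.DataFrame, dv: str, within, subject: str,
                between: str | None = None) -> pd.DataFrame:
    """Mixed ANOVA with crossed within factors and one optional between
    factor, on a balanced long-format design.

    Returns a tidy table with one row per effect: sums of squares, df,
    F, uncorrected and GG-corrected p (the ``p`` column applies the GG
    correction when Mauchly's test rejects), epsilon, and partial eta
    squared.
    """
    within = list(within)
    wide, within_levels = _pivot_wide(data, dv, within, subject)
    Y = wide.to_numpy(dtype=float)
    N, m = Y.shape

    if between is not None:
        grp = data.drop_duplicates(subject).set_index(subject)[between]
        groups = grp.loc[wide.index].to_numpy()
        labels = sorted(pd.unique(groups))
    else:
        groups = np.zeros(N, dtype=int)
        labels = [0]
    g = len(labels)
    if N - g < 1:
        raise ValueError("not enough subjects for error df")
    masks = [groups == lab for lab in labels]
    ns = np.array([mask.sum() for mask in masks])
    if (ns < 1).any():
        raise ValueError("empty group")

    rows = []

    # between-subjects stratum: one-way ANOVA on subject means (x m to
    # keep sums of squares on the cell scale)
    u = Y.mean(axis=1)
    gm = np.array([u[mask].mean() for mask in masks])
    resid = u.copy()
    for mask, mu in zip(masks, gm):
        resid[mask] -= mu
    ss_err_b = m * float(resid @ resid)
    df_err_b = N - g
    if between is not None:
        grand_w = float(u.mean())
        ss_grp = m * float(np.sum(ns * (gm - grand_w) ** 2))
        F = (ss_grp / (g - 1)) / (ss_err_b / df_err_b)
        rows.append({
            "source": between, "ss": ss_grp, "df1": g - 1, "df2": df_err_b,
            "F": F, "p_unc": float(sps.f.sf(F, g - 1, df_err_b)),
            "eps": np.nan, "p_gg": np.nan, "sphericity_p": np.nan,
            "gg_applied": False, "p": float(sps.f.sf(F, g - 1, df_err_b)),
            "np2": ss_grp / (ss_grp + ss_err_b),
        })

    # within-subject strata
    for effect in _effect_rows(within):
        C = _within_effect_basis(within_levels, effect)
        d_e = C.shape[1]
        Z = Y @ C
        Zbar = np.vstack([Z[mask].mean(axis=0) for mask in masks])
        R = Z.copy()
        for mask, mu in zip(masks, Zbar):
            R[mask] -= mu
        S = R.T @ R
        df_e = N - g
        Sc = S / df_e
        eps = _gg_from_contrast_cov(Sc)
        w_p = mauchly(Sc, df_e)

        # main within effect: Type III (unweighted) grand mean of group means
        zu = Zbar.mean(axis=0)
        scale = g**2 / float(np.sum(1.0 / ns))
        ss_main = scale * float(zu @ zu)
        name = " * ".join(effect)
        rows.append(_WithinTest(name, ss_main, float(np.trace(S)), d_e,
                                d_e * df_e, eps, w_p).row())

        if between is not None:
            zw = (ns[:, None] * Zbar).sum(axis=0) / N
            Hng = sum(n_j * np.outer(zb - zw, zb - zw)
                      for n_j, zb in zip(ns, Zbar))
            ss_int = float(np.trace(Hng))
            rows.append(_WithinTest(f"{name} * {between}", ss_int,
                                    float(np.trace(S)), d_e * (g - 1),
                                    d_e * df_e, eps, w_p).row())
    return pd.DataFrame(rows)


def ancova_rm(data: pd.DataFrame, dv: str, within, subject: str,
              covariates: dict | list) -> pd.DataFrame:
    """Repeated-measures ANCOVA for a single group with continuous
    covariates (centered before testing).

    ``covariates`` maps names to per-subject vectors, or lists columns
    of ``data`` holding subject-constant values.  Tests covariate main
    effects (on subject means), within main effects, and covariate x
    within interactions against the residual error of the covariate
    regression.  GG handling mirrors :func:`mixed_anova`.
    """
    within = list(within)
    wide, within_levels = _pivot_wide(data, dv, within, subject)
    Y = wide.to_numpy(dtype=float)
    N, m = Y.shape

    if isinstance(covariates, (list, tuple)):
        per_subject = data.drop_duplicates(subject).set_index(subject)
        covariates = {c: per_subject.loc[wide.index, c].to_numpy(dtype=float)
                      for c in covariates}
    names = list(covariates)
    Cv = np.column_stack([np.asarray(covariates[c], dtype=float)
                          for c in names])
    if Cv.shape[0] != N:
        raise ValueError("covariate length does not match subjects")
    if np.any(np.ptp(Cv, axis=0) == 0):
        raise ValueError("constant covariate")
    Cv = Cv - Cv.mean(axis=0)
    X = np.column_stack([np.ones(N), Cv])
    p = X.shape[1]
    if np.linalg.matrix_rank(X) < p:
        raise ValueError("collinear covariates")
    if N - p < 1:
        raise ValueError("not enough subjects")
    XtX_inv = np.linalg.inv(X.T @ X)
    df_e = N - p
    rows = []

    # between-subject part: covariate main effects on subject means
    u = Y.mean(axis=1)
    bu = XtX_inv @ X.T @ u
    ru = u - X @ bu
    ss_e_u = m * float(ru @ ru)
    for j, cname in enumerate(names, start=1):
        ss_h = m * float(bu[j] ** 2 / XtX_inv[j, j])
        F = (ss_h / 1) / (ss_e_u / df_e)
        rows.append({
            "source": cname, "ss": ss_h, "df1": 1, "df2": df_e, "F": F,
            "p_unc": float(sps.f.sf(F, 1, df_e)), "eps": np.nan,
            "p_gg": np.nan, "sphericity_p": np.nan, "gg_applied": False,
            "p": float(sps.f.sf(F, 1, df_e)),
            "np2": ss_h / (ss_h + ss_e_u),
        })

    # within strata: intercept -> within main effect, slopes -> interactions
    for effect in _effect_rows(within):
        C = _within_effect_basis(within_levels, effect)
        d_e = C.shape[1]
        Z = Y @ C
        B = XtX_inv @ X.T @ Z
        R = Z - X @ B
        S = R.T @ R
        Sc = S / df_e
        eps = _gg_from_contrast_cov(Sc)
        w_p = mauchly(Sc, df_e)
        name = " * ".join(effect)
        for j, src in enumerate([name] + [f"{name} * {c}" for c in names]):
            ss_h = float(B[j] @ B[j]) / XtX_inv[j, j]
            rows.append(_WithinTest(src, ss_h, float(np.trace(S)), d_e,
                                    d_e * df_e, eps, w_p).row())
    return pd.DataFrame(rows)


def posthoc(data: pd.DataFrame, dv: str, between: str, subject: str,
            method: str = "bonferroni") -> pd.DataFrame:
    """Pairwise two-sample pooled-variance t tests between groups on
    subject means.  ``method='bonferroni'`` multiplies p by the number
    of comparisons (capped at 1); ``'lsd'`` leaves p uncorrected."""
    if method not in ("bonferroni", "lsd"):
        raise ValueError(f"unknown method {method!r}")
    sub = data.groupby([subject, between], observed=True)[dv].mean().reset_index()
    labels = sorted(sub[between].unique())
    pairs = list(combinations(labels, 2))
    rows = []
    for a, b in pairs:
        xa = sub.loc[sub[between] == a, dv].to_numpy(dtype=float)
        xb = sub.loc[sub[between] == b, dv].to_numpy(dtype=float)
        na, nb = len(xa), len(xb)
        df = na + nb - 2
        sp2 = ((na - 1) * xa.var(ddof=1) + (nb - 1) * xb.var(ddof=1)) / df
        se = np.sqrt(sp2 * (1.0 / na + 1.0 / nb))
        t = (xa.mean() - xb.mean()) / se if se > 0 else 0.0
        p_raw = float(2.0 * sps.t.sf(abs(t), df)) if se > 0 else 1.0
        p_adj = min(1.0, p_raw * len(pairs)) if method == "bonferroni" else p_raw
        rows.append({"A": a, "B": b, "mean_A": xa.mean(), "mean_B": xb.mean(),
                     "t": float(t), "df": df, "p_raw": p_raw, "p": p_adj,
                     "method": method})
    return pd.DataFrame(rows)
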