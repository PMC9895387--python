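"""Within-subject (repeated-measures) statistics.

Implements the classical two-factor fully-within-subject ANOVA partition:
each effect (A, B, A x B) is tested against its own subject-by-effect
interaction error term.  Sphericity of each effect's contrast covariance
is assessed with Mauchly's W; when violated (p < .05 by default) the
degrees of freedom are deflated by the Greenhouse-Geisser epsilon.  Effect
sizes are partial eta squared.  Post hoc machinery is Bonferroni-corrected
paired t-tests.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as ss

__all__ = [
    "rm_anova_two_way",
    "mauchly_test",
    "greenhouse_geisser_epsilon",
    "eta_squared_partial",
    "bonferroni_adjust",
    "paired_t",
    "posthoc_paired",
]


def _orthonormal_contrasts(k: int) -> np.ndarray:
    """k x (k-1) orthonormal contrasts spanning the deviation space."""
    h = np.eye(k) - np.ones((k, k)) / k
    q, r = np.linalg.qr(h)
    keep = np.abs(np.diag(r)) > 1e-12
    return q[:, keep][:, : k - 1]


def _contrast_cov(x: np.ndarray, c: np.ndarray) -> np.ndarray:
    """Sample covariance (n-1 denominator) of the contrast scores."""
    y = x @ c
    return np.cov(y, rowvar=False, ddof=1).reshape(c.shape[1], c.shape[1])


def mauchly_test(x: np.ndarray) -> tuple[float, float, int, float]:
    """Mauchly's sphericity test on an n_subjects x k matrix.

    Returns (W, chi2, df, p).  With k = 2 the single contrast is trivially
    spherical (W = 1, p = 1).
    """
    x = np.asarray(x, dtype=float)
    n, k = x.shape
    if k < 2:
        raise ValueError("need >= 2 levels")
    if n <= k:
        raise ValueError("need more subjects than levels")
    p = k - 1
    if p == 1:
        return 1.0, 0.0, 0, 1.0
    s = _contrast_cov(x, _orthonormal_contrasts(k))
    det = np.linalg.det(s)
    tr = np.trace(s)
    if det <= 0 or tr <= 0:
        return 0.0, np.inf, p * (p + 1) // 2 - 1, 0.0
    w = float(det / (tr / p) ** p)
    d = 1.0 - (2.0 * p**2 + p + 2.0) / (6.0 * p * (n - 1.0))
    chi2 = -(n - 1.0) * d * np.log(w)
    df = p * (p + 1) // 2 - 1
    pval = float(ss.chi2.sf(chi2, df))
    return w, float(chi2), df, pval


def greenhouse_geisser_epsilon(x: np.ndarray) -> float:
    """Greenhouse-Geisser epsilon from the contrast covariance eigenvalues,
    in [1/(k-1), 1]."""
    x = np.asarray(x, dtype=float)
    n, k = x.shape
    if k < 2:
        raise ValueError("need >= 2 levels")
    if k == 2:
        return 1.0
    s = _contrast_cov(x, _orthonormal_contrasts(k))
    lam = np.clip(np.linalg.eigvalsh(s), 0.0, None)
    p = k - 1
    denom = p * float(np.sum(lam**2))
    if denom == 0:
        return 1.0 / p
    eps = float(np.sum(lam)) ** 2 / denom
    return float(np.clip(eps, 1.0 / p, 1.0))


def eta_squared_partial(f: float, df1: float, df2: float) -> float:
    """Partial eta squared from an F statistic: F df1 / (F df1 + df2)."""
    if f < 0 or df1 <= 0 or df2 <= 0:
        raise ValueError("need F >= 0 and positive dfs")
    return float(f * df1 / (f * df1 + df2))


def bonferroni_adjust(p_values, m: int | None = None) -> np.ndarray:
    """min(1, m * p) for each p; ``m`` defaults to the family size."""
    p = np.asarray(p_values, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    m = len(p) if m is None else int(m)
    if m < 1:
        raise ValueError("family size must be >= 1")
    return np.minimum(1.0, m * p)


def paired_t(x, y) -> tuple[float, int, float]:
    """Two-sided paired t-test; returns (t, df, p)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or len(x) < 2:
        raise ValueError("need two equal-length vectors of >= 2 observations")
    d = x - y
    if np.allclose(d.std(ddof=1), 0.0):
        if np.allclose(d, 0.0):
            return 0.0, len(x) - 1, 1.0
        raise ValueError("zero-variance nonzero differences: t undefined")
    res = ss.ttest_rel(x, y)
    return float(res.statistic), len(x) - 1, float(res.pvalue)


def posthoc_paired(
    pairs: list[tuple[str, np.ndarray, np.ndarray]],
    m: int | None = None,
) -> pd.DataFrame:
    """Bonferroni-corrected paired t-tests over a named family.

    Each entry is (name, x, y); the mean difference reported is
    ``mean(x - y)``.
    """
    rows = []
    for name, x, y in pairs:
        t, df, p = paired_t(x, y)
        rows.append({"comparison": name, "mean_diff": float(np.mean(np.asarray(x) - np.asarray(y))),
                     "t": t, "df": df, "p_raw": p})
    out = pd.DataFrame(rows)
    out["p_bonferroni"] = bonferroni_adjust(out["p_raw"].to_numpy(), m or len(pairs))
    return out


@dataclass
class _Effect:
    name: str
    ss_effect: float
    ss_error: float
    df1: int
    df2: int
    contrast_scores: np.ndarray  # n x (levels-1 per factor product)


def rm_anova_two_way(
    data: np.ndarray,
    factor_a: str = "A",
    factor_b: str = "B",
    gg_policy: str = "mauchly",  # "mauchly" | "always" | "never"
    alpha_sphericity: float = 0.05,
) -> pd.DataFrame:
    """Two-factor fully repeated-measures ANOVA.

    ``data`` is subjects x levels(A) x levels(B), complete.  Returns one
    row per effect with sums of squares, F, Mauchly W/p, Greenhouse-
    Geisser epsilon, uncorrected and corrected dfs and p-values, the
    p-value selected by ``gg_policy`` (``p_reported``), and partial eta
    squared.
    """
    y = np.asarray(data, dtype=float)
    if y.ndim != 3:
        raise ValueError("data must be subjects x levels(A) x levels(B)")
    if not np.all(np.isfinite(y)):
        raise ValueError("design must be complete (finite values)")
    n, a, b = y.shape
    if n < 2:
        raise ValueError("need >= 2 subjects")
    if np.allclose(y.std(), 0.0):
        raise ValueError("constant data: no variance to partition")

    gm = y.mean()
    mean_s = y.mean(axis=(1, 2))
    mean_a = y.mean(axis=(0, 2))
    mean_b = y.mean(axis=(0, 1))
    mean_sa = y.mean(axis=2)
    mean_sb = y.mean(axis=1)
    mean_ab = y.mean(axis=0)

    ss_a = n * b * np.sum((mean_a - gm) ** 2)
    ss_b = n * a * np.sum((mean_b - gm) ** 2)
    ss_ab = n * np.sum((mean_ab - mean_a[:, None] - mean_b[None, :] + gm) ** 2)
    ss_as = b * np.sum((mean_sa - mean_s[:, None] - mean_a[None, :] + gm) ** 2)
    ss_bs = a * np.sum((mean_sb - mean_s[:, None] - mean_b[None, :] + gm) ** 2)
    resid = (
        y
        - mean_sa[:, :, None]
        - mean_sb[:, None, :]
        - mean_ab[None, :, :]
        + mean_s[:, None, None]
        + mean_a[None, :, None]
        + mean_b[None, None, :]
        - gm
    )
    ss_abs = np.sum(resid**2)

    effects = [
        _Effect(factor_a, ss_a, ss_as, a - 1, (a - 1) * (n - 1), mean_sa),
        _Effect(factor_b, ss_b, ss_bs, b - 1, (b - 1) * (n - 1), mean_sb),
        _Effect(
            f"{factor_a} x {factor_b}",
            ss_ab,
            ss_abs,
            (a - 1) * (b - 1),
            (a - 1) * (b - 1) * (n - 1),
            y.reshape(n, a * b),
        ),
    ]

    # mean squares at round-off scale are treated as exactly zero so that
    # condition-invariant data yields F = 0 rather than a 0/0 artefact
    tiny = 1e-12 * float(np.var(y))
    rows = []
    for eff in effects:
        ms_eff = eff.ss_effect / eff.df1
        ms_err = eff.ss_error / eff.df2
        if ms_eff < tiny:
            f = 0.0
        elif ms_err < tiny:
            f = np.inf
        else:
            f = ms_eff / ms_err
        if eff.name == f"{factor_a} x {factor_b}":
            eps, w, p_mauchly = _interaction_sphericity(y)
        else:
            x = eff.contrast_scores
            eps = greenhouse_geisser_epsilon(x)
            w, _, _, p_mauchly = (
                mauchly_test(x) if x.shape[0] > x.shape[1] else (np.nan, np.nan, 0, np.nan)
            )
        df1c, df2c = eps * eff.df1, eps * eff.df2
        p_unc = float(ss.f.sf(f, eff.df1, eff.df2))
        p_gg = float(ss.f.sf(f, df1c, df2c))
        if gg_policy == "always":
            use_gg = True
        elif gg_policy == "never":
            use_gg = False
        else:
            use_gg = (not np.isnan(p_mauchly)) and p_mauchly < alpha_sphericity
        rows.append(
            {
                "effect": eff.name,
                "ss_effect": eff.ss_effect,
                "ss_error": eff.ss_error,
                "df1": eff.df1,
                "df2": eff.df2,
                "F": f,
                "mauchly_w": w,
                "p_mauchly": p_mauchly,
                "epsilon_gg": eps,
                "df1_gg": df1c,
                "df2_gg": df2c,
                "p_uncorrected": p_unc,
                "p_gg": p_gg,
                "p_reported": p_gg if use_gg else p_unc,
                "eta2p": eta_squared_partial(f, eff.df1, eff.df2),
            }
        )
    return pd.DataFrame(rows).set_index("effect")


def _interaction_sphericity(y: np.ndarray) -> tuple[float, float, float]:
    """GG epsilon and Mauchly result for the A x B interaction contrasts."""
    n, a, b = y.shape
    ca = _orthonormal_contrasts(a)
    cb = _orthonormal_contrasts(b)
    c = np.kron(ca, cb)  # (a*b, (a-1)(b-1))
    scores = y.reshape(n, a * b) @ c
    p = c.shape[1]
    if p == 1:
        return 1.0, 1.0, 1.0
    s = np.cov(scores, rowvar=False, ddof=1)
    lam = np.clip(np.linalg.eigvalsh(s), 0.0, None)
    denom = p * float(np.sum(lam**2))
    eps = float(np.clip(np.sum(lam) ** 2 / denom, 1.0 / p, 1.0)) if denom > 0 else 1.0 / p
    if n <= p:
        return eps, np.nan, np.nan
    det = np.linalg.det(s)
    tr = np.trace(s)
    if det <= 0 or tr <= 0:
        return eps, 0.0, 0.0
    w = float(det / (tr / p) ** p)
    d = 1.0 - (2.0 * p**2 + p + 2.0) / (6.0 * p * (n - 1.0))
    chi2 = -(n - 1.0) * d * np.log(w)
    df = p * (p + 1) // 2 - 1
    return eps, w, float(ss.chi2.sf(chi2, df))
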