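"""Empirical-Bayes moderated one-sample t-statistics for SILAC log-ratios.

The moderated t shrinks each feature's sample variance toward a prior
variance ``s02`` estimated across all features, gaining degrees of freedom
``d0`` from the ensemble.  Hyperparameters are estimated by moment matching
on the log sample variances: if s2 ~ s_true2 * chi2_df / df and
1/s_true2 ~ chi2_d0 / (d0 * s02), then

    E[log s2]   = log s02 + digamma(df/2) - log(df/2)
                           - digamma(d0/2) + log(d0/2)
    Var[log s2] = trigamma(df/2) + trigamma(d0/2)

so the excess of the observed variance of log(s2) over the mean
trigamma(df/2) term identifies trigamma(d0/2), inverted by Newton
iteration.  The posterior variance is the df-weighted average

    s2_tilde = (d0 * s02 + df * s2) / (d0 + df)

and t_mod = mean / sqrt(s2_tilde / n) is referred to a Student t with
d0 + df degrees of freedom.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import special, stats

__all__ = ["EBayesFit", "fit_ebayes", "moderated_one_sample_test", "bh_adjust"]

#: variance floor applied before taking logs, avoids log(0) for ties
VAR_FLOOR = 1e-8


@dataclass
class EBayesFit:
    """Fitted moderated-t model for one contrast.

    Per-feature arrays are aligned with ``index``.  ``d0`` may be
    ``np.inf`` when no between-feature variance heterogeneity is left
    after accounting for chi-square sampling noise; the moderated t then
    degenerates to a z-like statistic against ``s02``.
    """

    index: pd.Index
    n_obs: np.ndarray
    mean_log2: np.ndarray
    s2: np.ndarray
    df: np.ndarray
    d0: float
    s02: float
    s2_tilde: np.ndarray = field(repr=False, default=None)
    df_total: np.ndarray = field(repr=False, default=None)
    t_mod: np.ndarray = field(repr=False, default=None)
    p: np.ndarray = field(repr=False, default=None)

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "n_obs": self.n_obs,
                "mean_log2": self.mean_log2,
                "s2": self.s2,
                "df": self.df,
                "s2_tilde": self.s2_tilde,
                "df_total": self.df_total,
                "t_mod": self.t_mod,
                "p": self.p,
            },
            index=self.index,
        )

    def p_one_sided(self, direction: str) -> np.ndarray:
        """Lower- ('less') or upper-tail ('greater') p-values."""
        with np.errstate(invalid="ignore"):
            if direction == "less":
                p = _t_cdf(self.t_mod, self.df_total)
            elif direction == "greater":
                p = _t_sf(self.t_mod, self.df_total)
            else:
                raise ValueError(f"direction must be 'less' or 'greater', got {direction!r}")
        return p


def _t_cdf(t, df):
    df = np.asarray(df, dtype=float)
    out = np.where(np.isinf(df), stats.norm.cdf(t), stats.t.cdf(t, np.where(np.isinf(df), 1.0, df)))
    return out


def _t_sf(t, df):
    df = np.asarray(df, dtype=float)
    out = np.where(np.isinf(df), stats.norm.sf(t), stats.t.sf(t, np.where(np.isinf(df), 1.0, df)))
    return out


def trigamma_inverse(x: float, tol: float = 1e-12, max_iter: int = 100) -> float:
    """Solve trigamma(y) = x for y > 0 by Newton iteration.

    trigamma is positive, decreasing and convex on (0, inf), so the
    Newton step on 1/trigamma converges monotonically from the moment
    starting value y0 = 0.5 + 1/x.
    """
    if x <= 0:
        return np.inf
    if x > 1e7:
        return 1.0 / np.sqrt(x)
    y = 0.5 + 1.0 / x
    for _ in range(max_iter):
        tri = special.polygamma(1, y)
        dif = tri * (1.0 - tri / x) / special.polygamma(2, y)
        y += dif
        if abs(dif) < tol * y:
            break
    return float(y)


def _squeeze_var(s2: np.ndarray, df: np.ndarray) -> tuple[float, float]:
    """Moment-matching estimate of (d0, s02) from sample variances."""
    s2 = np.maximum(np.asarray(s2, dtype=float), VAR_FLOOR)
    df = np.asarray(df, dtype=float)
    z = np.log(s2)
    e = z - special.digamma(df / 2.0) + np.log(df / 2.0)
    emean = e.mean()
    evar = e.var(ddof=1) - np.mean(special.polygamma(1, df / 2.0))
    if evar > 0:
        d0 = 2.0 * trigamma_inverse(evar)
        s02 = float(np.exp(emean + special.digamma(d0 / 2.0) - np.log(d0 / 2.0)))
    else:
        d0 = np.inf
        s02 = float(np.exp(emean))
    return d0, s02


def fit_ebayes(
    log_ratios: pd.DataFrame | np.ndarray,
    d0_override: float | None = None,
    posterior_only: bool = False,
) -> EBayesFit:
    """Fit the moderated one-sample t model on a feature x replicate matrix.

    Missing values (NaN) are allowed; a feature contributes to the
    hyperparameter fit only if it has df >= 1.  Features observed in a
    single replicate get the posterior variance with df_total = d0 but
    receive no t/p unless ``posterior_only`` is set.

    ``d0_override`` forces the prior degrees of freedom (0 recovers the
    ordinary t, inf forces full shrinkage to s02).
    """
    if isinstance(log_ratios, pd.DataFrame):
        index = log_ratios.index
        X = log_ratios.to_numpy(dtype=float)
    else:
        X = np.asarray(log_ratios, dtype=float)
        index = pd.RangeIndex(X.shape[0])
    if X.ndim != 2:
        raise ValueError("log_ratios must be 2-D (features x replicates)")

    n_obs = np.sum(~np.isnan(X), axis=1)
    with np.errstate(invalid="ignore"):
        mean = np.nanmean(np.where(np.isnan(X), np.nan, X), axis=1)
        mean = np.where(n_obs > 0, mean, np.nan)
    s2 = np.full(X.shape[0], np.nan)
    has_var = n_obs >= 2
    if has_var.any():
        s2[has_var] = np.nanvar(X[has_var], axis=1, ddof=1)
    df = np.maximum(n_obs - 1, 0).astype(float)

    fit_mask = df >= 1
    if fit_mask.sum() < 2:
        raise ValueError("need at least 2 features with df >= 1 to fit hyperparameters")
    if np.all(s2[fit_mask] == 0):
        raise ValueError(
            "all sample variances are zero; the model is ill-posed — "
            "add replicate noise or apply a variance floor to the input"
        )

    if d0_override is not None:
        d0 = float(d0_override)
        # s02 still comes from the data (irrelevant when d0 == 0)
        _, s02 = _squeeze_var(s2[fit_mask], df[fit_mask])
    else:
        d0, s02 = _squeeze_var(s2[fit_mask], df[fit_mask])

    s2_eff = np.where(np.isnan(s2), 0.0, s2)
    if np.isinf(d0):
        s2_tilde = np.full_like(s2_eff, s02)
    elif d0 == 0:
        s2_tilde = np.where(df > 0, s2_eff, s02)
    else:
        s2_tilde = (d0 * s02 + df * s2_eff) / (d0 + df)
        s2_tilde = np.where(df > 0, s2_tilde, s02)
    df_total = df + d0

    testable = n_obs >= (1 if posterior_only else 2)
    with np.errstate(divide="ignore", invalid="ignore"):
        se = np.sqrt(s2_tilde / np.maximum(n_obs, 1))
        t = np.where(testable & (se > 0), mean / se, np.nan)
        # zero posterior SE with nonzero mean would be +-inf; flag as NaN
    p = np.full_like(t, np.nan)
    ok = ~np.isnan(t)
    if ok.any():
        p[ok] = np.clip(2.0 * _t_sf(np.abs(t[ok]), df_total[ok]), np.finfo(float).tiny, 1.0)

    return EBayesFit(
        index=index,
        n_obs=n_obs,
        mean_log2=mean,
        s2=s2,
        df=df,
        d0=d0,
        s02=s02,
        s2_tilde=s2_tilde,
        df_total=df_total,
        t_mod=t,
        p=p,
    )


def moderated_one_sample_test(fit: EBayesFit, alpha: float = 0.01) -> pd.DataFrame:
    """Two-sided moderated t-test results with BH q-values.

    Returns a frame with t_mod, p, q and a boolean ``significant``
    column at the raw-p threshold ``alpha`` (raw p is the calling
    criterion throughout the phospho analysis; q is reported alongside).
    """
    out = fit.as_frame()[["n_obs", "mean_log2", "t_mod", "p"]].copy()
    out["q"] = bh_adjust(out["p"].to_numpy())
    out["significant"] = out["p"] < alpha
    return out


def bh_adjust(p) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values.

    q_(i) = min over j >= i of min(1, m * p_(j) / j) on the sorted
    p-values; NaNs are ignored (and returned as NaN), m counts only
    finite p-values.  Order of the input is preserved.
    """
    p = np.asarray(p, dtype=float)
    q = np.full(p.shape, np.nan)
    ok = ~np.isnan(p)
    pv = p[ok]
    if pv.size == 0:
        return q
    if np.any((pv < 0) | (pv > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    m = pv.size
    order = np.argsort(pv, kind="mergesort")
    ranked = pv[order] * m / np.arange(1, m + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    ranked = np.minimum(ranked, 1.0)
    qv = np.empty(m)
    qv[order] = ranked
    q[ok] = qv
    return q
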