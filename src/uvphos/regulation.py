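"""Hierarchical regulation calling for UV-induced phosphorylation.

Three tiers, each a moderated one-sample t on log2 SILAC ratios:

1. UV regulation: sites up-/down-regulated after UV vs mock at raw
   p < 0.01 (two-sided), direction from the sign of the mean.
2. p38 dependency, evaluated among UV-up sites: the per-replicate
   difference of the inhibitor and UV log2 ratios (H/L - M/L =
   log2 H/M) tested significantly negative (one-sided, same alpha).
3. MK2/3/5 dependency, same construction, evaluated among
   p38-dependent sites.

Sites failing the localization-probability cutoff are excluded before
testing.  Summary fractions reproduce the printed-count arithmetic with
both truncating and half-up-rounding percentage formatters.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .ebayes import bh_adjust, fit_ebayes
from .io import SilacSiteTable
from .motifs import MOTIF_STQ, match_motif

__all__ = [
    "call_uv_regulation",
    "call_dependency",
    "flag_stq",
    "summarize_fractions",
    "percent_truncated",
    "percent_rounded",
]


def call_uv_regulation(
    table: SilacSiteTable,
    uv_contrast: str = "UV/mock",
    alpha: float = 0.01,
    localization_cutoff: float = 0.75,
    min_abs_log2: float = 0.0,
) -> pd.DataFrame:
    """Call per-site UV regulation (up / down / ns).

    Sites below the localization cutoff or with fewer than 2 ratio
    observations are not tested (direction 'ns', tested=False).  An
    optional absolute fold-change threshold can be stacked on the raw-p
    criterion.
    """
    ratios = table.condition_matrix(uv_contrast)
    try:
        fit = fit_ebayes(ratios)
        calls = pd.DataFrame(
            {
                "n_obs": fit.n_obs,
                "mean_uv": fit.mean_log2,
                "t_uv": fit.t_mod,
                "p_uv": fit.p,
            },
            index=fit.index,
        )
    except ValueError:
        # degenerate input with no replicate variance anywhere (e.g. an
        # all-zero matrix): nothing is callable, everything is 'ns'
        n_obs = ratios.notna().sum(axis=1)
        mean = ratios.mean(axis=1)
        calls = pd.DataFrame(
            {
                "n_obs": n_obs,
                "mean_uv": mean,
                "t_uv": np.where(mean == 0, 0.0, np.nan),
                "p_uv": np.where((n_obs >= 2) & (mean == 0), 1.0, np.nan),
            },
            index=ratios.index,
        )
    calls["q_uv"] = bh_adjust(calls["p_uv"].to_numpy())
    localized = table.sites["localization_prob"] >= localization_cutoff
    calls["tested"] = localized & calls["p_uv"].notna()
    sig = calls["tested"] & (calls["p_uv"] < alpha) & (calls["mean_uv"].abs() >= min_abs_log2)
    calls["uv_direction"] = np.where(
        sig & (calls["mean_uv"] > 0), "up", np.where(sig & (calls["mean_uv"] < 0), "down", "ns")
    )
    calls["is_stq"] = flag_stq(table)
    return calls


def call_dependency(
    table: SilacSiteTable,
    calls: pd.DataFrame,
    inhibitor_contrast: str,
    uv_contrast: str = "UV/mock",
    alpha: float = 0.01,
    among: str = "up",
    column: str = "dependency",
) -> pd.DataFrame:
    """Add an inhibitor-dependency column to regulation calls.

    The tested quantity is the per-replicate difference
    log2(inhibitor+UV / mock) - log2(UV / mock), i.e. log2 of the
    inhibitor-vs-UV channel ratio.  Hyperparameters are pooled over all
    sites with >= 2 paired observations; the call (dependent iff the
    one-sided lower-tail p < alpha) is made only among the sites whose
    value in the column named by ``among`` is truthy — UV-up sites for
    p38 dependency ('up' selects uv_direction == 'up'), p38-dependent
    sites for MK dependency.
    """
    inh = table.condition_matrix(inhibitor_contrast)
    uv = table.condition_matrix(uv_contrast)
    common = inh.columns.intersection(uv.columns)
    if len(common) == 0:
        raise ValueError(
            f"no shared replicates between {inhibitor_contrast!r} and {uv_contrast!r}"
        )
    diff = inh[common] - uv[common]
    try:
        fit = fit_ebayes(diff)
        p_dep = pd.Series(fit.p_one_sided("less"), index=fit.index)
        mean_diff = pd.Series(fit.mean_log2, index=fit.index)
    except ValueError:
        # identical contrasts (zero difference everywhere): nothing depends
        n_obs = diff.notna().sum(axis=1)
        mean_diff = diff.mean(axis=1)
        p_dep = pd.Series(
            np.where((n_obs >= 2) & (mean_diff == 0), 1.0, np.nan), index=diff.index
        )

    if among == "up":
        eligible = calls["uv_direction"] == "up"
    else:
        eligible = calls[among] == "dependent"
    out = calls.copy()
    out[f"p_{column}"] = p_dep
    out[f"mean_diff_{column}"] = mean_diff
    dep = eligible & (p_dep < alpha)
    indep = eligible & ~dep & p_dep.notna()
    out[column] = np.where(dep, "dependent", np.where(indep, "independent", "na"))
    return out


def flag_stq(table: SilacSiteTable) -> pd.Series:
    """True iff the window center is S/T and the +1 residue is Q."""
    return table.sites["sequence_window"].map(lambda w: match_motif(w, MOTIF_STQ))


# ---------------------------------------------------------------------------
# Printed-fraction arithmetic
# ---------------------------------------------------------------------------


def percent_truncated(k: int, n: int, decimals: int = 1) -> float:
    """Percentage truncated (floored) to the given number of decimals."""
    if n <= 0:
        raise ValueError("denominator must be positive")
    scale = 10**decimals
    return math.floor(100.0 * k / n * scale) / scale


def percent_rounded(k: int, n: int, decimals: int = 0) -> float:
    """Percentage rounded half-up to the given number of decimals."""
    if n <= 0:
        raise ValueError("denominator must be positive")
    scale = 10**decimals
    return math.floor(100.0 * k / n * scale + 0.5) / scale


@dataclass(frozen=True)
class FractionSummary:
    numerator: int
    denominator: int

    @property
    def fraction(self) -> float:
        return self.numerator / self.denominator

    @property
    def pct(self) -> float:
        return 100.0 * self.fraction

    @property
    def pct_1dp_truncated(self) -> float:
        return percent_truncated(self.numerator, self.denominator, 1)

    @property
    def pct_1dp_rounded(self) -> float:
        return percent_rounded(self.numerator, self.denominator, 1)

    @property
    def pct_int(self) -> float:
        return percent_rounded(self.numerator, self.denominator, 0)

    def as_dict(self) -> dict:
        return {
            "count": self.numerator,
            "of": self.denominator,
            "pct": self.pct,
            "pct_1dp_truncated": self.pct_1dp_truncated,
            "pct_1dp_rounded": self.pct_1dp_rounded,
            "pct_int": self.pct_int,
        }


def summarize_fractions(calls: pd.DataFrame) -> dict:
    """Counts and percentages for the regulation hierarchy.

    Reports up/down of tested, S/TQ of up, dependent of up, and (when
    present) MK-dependent of p38-dependent.  Each fraction carries the
    exact percentage plus one-decimal truncated, one-decimal rounded and
    integer (half-up) printed forms.
    """
    tested = calls[calls.get("tested", True) == True]  # noqa: E712
    total = len(tested)
    up = tested[tested["uv_direction"] == "up"]
    down = tested[tested["uv_direction"] == "down"]
    summary = {
        "n_tested": total,
        "up": FractionSummary(len(up), total).as_dict(),
        "down": FractionSummary(len(down), total).as_dict(),
    }
    if len(up):
        if "is_stq" in calls:
            summary["stq_of_up"] = FractionSummary(int(up["is_stq"].sum()), len(up)).as_dict()
        if "dependency" in calls:
            dep = up[up["dependency"] == "dependent"]
            summary["dependent_of_up"] = FractionSummary(len(dep), len(up)).as_dict()
            if "mk_dependency" in calls and len(dep):
                mk = dep[dep["mk_dependency"] == "dependent"]
                summary["mk_dependent_of_dependent"] = FractionSummary(
                    len(mk), len(dep)
                ).as_dict()
    return summary
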