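"""Pulldown interactor calling and gene-set over-representation.

Interactor calling reuses the moderated one-sample t machinery on
protein-level pulldown ratios (bait vs control at alpha = 0.05, then an
inhibitor contrast for the dependency call).  Over-representation uses
the one-sided hypergeometric tail, identical to one-sided Fisher's
exact, with BH correction across retained sets.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .ebayes import bh_adjust, fit_ebayes
from .io import GeneSetCollection, PulldownTable

__all__ = [
    "call_interactors",
    "gene_set_enrichment",
    "set_overlap_fraction",
]


def call_interactors(
    table: PulldownTable,
    bait_contrast: str,
    inhibitor_contrast: str | None = None,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Call interactors (and optionally inhibitor-dependent interactors).

    A protein is an interactor if the bait-vs-control moderated t has
    two-sided p < alpha with positive mean enrichment.  Among
    interactors, a protein is inhibitor-dependent if the inhibitor
    contrast is significantly *negative* (one-sided moderated t at the
    same alpha).
    """
    fit = fit_ebayes(table.condition_matrix(bait_contrast))
    res = pd.DataFrame(
        {
            "mean_log2": fit.mean_log2,
            "t_mod": fit.t_mod,
            "p": fit.p,
        },
        index=fit.index,
    )
    res["q"] = bh_adjust(res["p"].to_numpy())
    res["interactor"] = (res["p"] < alpha) & (res["mean_log2"] > 0)

    if inhibitor_contrast is not None:
        dep_fit = fit_ebayes(table.condition_matrix(inhibitor_contrast))
        p_dep = pd.Series(dep_fit.p_one_sided("less"), index=dep_fit.index)
        res["p_dependency"] = p_dep
        dep = res["interactor"] & (p_dep < alpha)
        res["dependency"] = np.where(
            ~res["interactor"], "na", np.where(dep, "dependent", "independent")
        )
    return res


def gene_set_enrichment(
    query,
    universe,
    sets: GeneSetCollection,
    test: str = "hypergeom",
    min_size: int = 3,
    max_size: int = 1000,
) -> pd.DataFrame:
    """One-sided over-representation of `query` within `universe` per set.

    Identifiers are uppercased and deduplicated.  Sets are intersected
    with the universe and retained if min_size <= K <= max_size.  The
    hypergeometric upper tail P(X >= k) is used; ``test='fisher'``
    routes through Fisher's exact (one-sided 'greater'), which is
    mathematically the same tail.  BH correction across retained sets.
    """
    query = {str(g).upper() for g in query}
    universe = {str(g).upper() for g in universe}
    stray = query - universe
    if stray:
        raise ValueError(f"query genes not in universe: {sorted(stray)[:10]}")
    if test not in ("hypergeom", "fisher"):
        raise ValueError(f"unknown test {test!r}")
    N, n = len(universe), len(query)
    rows = []
    for name, desc, members in sets.items():
        in_universe = members & universe
        K = len(in_universe)
        if not (min_size <= K <= max_size):
            continue
        k = len(in_universe & query)
        if test == "hypergeom":
            p = float(stats.hypergeom.sf(k - 1, N, K, n))
        else:
            table = [[k, n - k], [K - k, N - K - (n - k)]]
            _, p = stats.fisher_exact(table, alternative="greater")
        rows.append((name, desc, k, K, n, N, p))
    out = pd.DataFrame(
        rows, columns=["set_name", "description", "k", "K", "n", "N", "p"]
    ).set_index("set_name")
    if len(out):
        out["q"] = bh_adjust(out["p"].to_numpy())
        out = out.sort_values("p")
    else:
        out["q"] = pd.Series(dtype=float)
    return out


def set_overlap_fraction(a, b) -> float:
    """|a intersect b| / |a| (identifiers uppercased)."""
    a = {str(g).upper() for g in a}
    b = {str(g).upper() for g in b}
    if not a:
        raise ValueError("empty reference set")
    return len(a & b) / len(a)
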