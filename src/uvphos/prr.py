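"""RNA polymerase II promoter-release ratio (PRR) analysis.

For each gene the TSS window spans -300 to +1000 bp around the TSS and
the downstream window +1000 to +3000 bp, both in transcription
direction.  The PRR is

    PRR = log2( (E_down + eps) / (E_tss + eps) )

with E_* the mean RPKM-normalized per-base signal in each window and a
pseudocount eps (default 0.1 RPKM) guarding silent windows.  Genes must
be longer than 3 kb (so the downstream window stays inside the gene) and
pass a minimum TSS signal in the untreated condition.  Released
(elongating) polymerase raises downstream signal relative to the TSS
peak, so UV-induced pause release appears as delta PRR > 0.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .ebayes import bh_adjust, fit_ebayes
from .io import CoverageTrack, GeneModel
from .rank_tests import TestResult, wilcoxon_rank_sum

__all__ = [
    "WindowSpec",
    "compute_window_signal",
    "compute_prr",
    "differential_prr",
    "metagene_profile",
]


@dataclass(frozen=True)
class WindowSpec:
    """PRR window geometry and eligibility filters (bp, RPKM units)."""

    tss_window: tuple = (-300, 1000)
    downstream_window: tuple = (1000, 3000)
    min_gene_length: int = 3000
    tss_min_signal: float = 1.0
    epsilon: float = 0.1

    def __post_init__(self):
        a, b = self.tss_window
        c, d = self.downstream_window
        if not (a < b <= c < d):
            raise ValueError("windows must be ordered and non-overlapping")
        if self.epsilon <= 0:
            raise ValueError("epsilon must be positive")


def _project_window(gene: GeneModel, rel_start: int, rel_end: int) -> tuple[int, int]:
    """Genomic half-open interval for a TSS-relative window.

    Relative coordinates count in transcription direction with 0 at the
    TSS base; for minus-strand genes the projection mirrors around the
    TSS (relative position r maps to genomic tss - r).
    """
    if gene.strand == "+":
        return gene.tss + rel_start, gene.tss + rel_end
    # [rel_start, rel_end) maps to genomic (tss - rel_end, tss - rel_start]
    return gene.tss - rel_end + 1, gene.tss - rel_start + 1


def compute_window_signal(track: CoverageTrack, gene: GeneModel, window: tuple) -> float:
    """Mean RPKM-normalized signal over a TSS-relative window.

    Windows running off the chromosome end are truncated with a warning;
    an empty truncated window yields NaN.
    """
    start, end = _project_window(gene, window[0], window[1])
    arr = track.coverage.get(gene.chrom)
    if arr is None:
        raise KeyError(f"chromosome {gene.chrom!r} not in coverage track")
    cs, ce = max(start, 0), min(end, len(arr))
    if (cs, ce) != (start, end) and cs < ce:
        warnings.warn(f"window for gene {gene.gene_id} truncated to chromosome bounds")
    if ce <= cs:
        return np.nan
    return track.rpkm(gene.chrom, cs, ce)


def compute_prr(
    tracks: dict,
    genes: list,
    spec: WindowSpec = WindowSpec(),
    baseline_condition: str | None = None,
) -> pd.DataFrame:
    """Per-gene, per-condition PRR table.

    ``tracks`` maps condition -> list of replicate CoverageTracks.
    Replicate PRRs are computed separately and averaged.  Eligibility:
    gene length > min_gene_length AND mean TSS signal in the baseline
    (untreated) condition >= tss_min_signal.  Raises if no gene is
    eligible.
    """
    conditions = list(tracks)
    if baseline_condition is None:
        baseline_condition = conditions[0]
    rows = []
    for gene in genes:
        row = {"gene_id": gene.gene_id, "length": gene.length}
        for cond, reps in tracks.items():
            prrs, e_tss_list, e_down_list = [], [], []
            for track in reps:
                e_tss = compute_window_signal(track, gene, spec.tss_window)
                e_down = compute_window_signal(track, gene, spec.downstream_window)
                e_tss_list.append(e_tss)
                e_down_list.append(e_down)
                prrs.append(
                    np.log2((e_down + spec.epsilon) / (e_tss + spec.epsilon))
                    if np.isfinite(e_tss) and np.isfinite(e_down)
                    else np.nan
                )
            row[f"e_tss:{cond}"] = float(np.nanmean(e_tss_list))
            row[f"e_down:{cond}"] = float(np.nanmean(e_down_list))
            for i, v in enumerate(prrs, 1):
                row[f"prr:{cond}:{i}"] = v
            row[f"prr:{cond}"] = float(np.nanmean(prrs)) if np.isfinite(prrs).any() else np.nan
        long_enough = gene.length > spec.min_gene_length
        tss_ok = row.get(f"e_tss:{baseline_condition}", np.nan) >= spec.tss_min_signal
        row["eligible"] = bool(long_enough and tss_ok)
        rows.append(row)
    table = pd.DataFrame(rows).set_index("gene_id")
    if not table["eligible"].any():
        raise ValueError("no eligible genes (length/TSS-signal filters removed everything)")
    # PRR is defined only for eligible genes
    prr_cols = [c for c in table.columns if c.startswith("prr:")]
    table.loc[~table["eligible"], prr_cols] = np.nan
    return table


def differential_prr(
    prr_table: pd.DataFrame,
    mock: str,
    uv: str,
    alpha: float = 0.05,
) -> tuple[pd.DataFrame, TestResult]:
    """Per-gene delta PRR with a replicate-paired moderated t, plus the
    global mock-vs-UV Wilcoxon rank-sum on per-gene mean PRRs.

    Replicate deltas pair replicate i of the UV condition with
    replicate i of mock; replicate counts must match.  The degenerate
    all-zero-delta case (identical tracks) yields p = 1 everywhere.
    """
    reps_mock = sorted(
        int(c.split(":")[2]) for c in prr_table.columns if c.startswith(f"prr:{mock}:")
    )
    reps_uv = sorted(
        int(c.split(":")[2]) for c in prr_table.columns if c.startswith(f"prr:{uv}:")
    )
    if reps_mock != reps_uv:
        raise ValueError(f"replicate mismatch between {mock!r} and {uv!r}")
    eligible = prr_table["eligible"]
    deltas = pd.DataFrame(
        {
            i: prr_table[f"prr:{uv}:{i}"] - prr_table[f"prr:{mock}:{i}"]
            for i in reps_uv
        }
    )[eligible]

    out = prr_table.copy()
    out["delta_prr"] = (out[f"prr:{uv}"] - out[f"prr:{mock}"]).where(eligible)
    finite = deltas.dropna()
    if len(finite) and np.nanmax(np.abs(deltas.to_numpy())) == 0:
        out.loc[eligible, "p_delta"] = 1.0
    else:
        fit = fit_ebayes(deltas)
        out.loc[deltas.index, "p_delta"] = fit.p
    out["q_delta"] = bh_adjust(out["p_delta"].to_numpy()) if "p_delta" in out else np.nan
    out["prr_call"] = "ns"
    sig = (out["p_delta"] < alpha) & eligible
    out.loc[sig & (out["delta_prr"] > 0), "prr_call"] = "up"
    out.loc[sig & (out["delta_prr"] < 0), "prr_call"] = "down"

    x = prr_table.loc[eligible, f"prr:{mock}"].dropna()
    y = prr_table.loc[eligible, f"prr:{uv}"].dropna()
    global_test = wilcoxon_rank_sum(x, y, continuity=True, alternative="two-sided")
    return out, global_test


def metagene_profile(
    tracks: list,
    genes: list,
    span: int = 2000,
    bins: int = 100,
) -> pd.DataFrame:
    """Average strand-oriented normalized coverage around the TSS.

    Positions -span..+span (transcription direction) are divided into
    ``bins`` equal bins; per-base RPKM-scale signal is averaged within
    each bin, across genes, then across the given replicate tracks.
    Returns a frame indexed by bin-center offset with a 'signal' column.
    """
    edges = np.linspace(-span, span, bins + 1)
    centers = 0.5 * (edges[:-1] + edges[1:])
    per_track = []
    for track in tracks:
        total_mass = track.library_mass
        norm = 1e9 / total_mass if total_mass > 0 else 0.0
        acc = np.zeros(bins)
        n_genes = np.zeros(bins)
        for gene in genes:
            arr = track.coverage.get(gene.chrom)
            if arr is None:
                continue
            rel = np.arange(-span, span)
            gpos = gene.tss + rel if gene.strand == "+" else gene.tss - rel
            valid = (gpos >= 0) & (gpos < len(arr))
            vals = np.full(rel.shape, np.nan)
            vals[valid] = arr[gpos[valid]] * norm
            idx = np.clip(np.digitize(rel + 0.5, edges) - 1, 0, bins - 1)
            for b in range(bins):
                sel = vals[idx == b]
                sel = sel[np.isfinite(sel)]
                if sel.size:
                    acc[b] += sel.mean()
                    n_genes[b] += 1
        with np.errstate(invalid="ignore"):
            per_track.append(acc / np.where(n_genes > 0, n_genes, np.nan))
    profile = np.nanmean(per_track, axis=0)
    return pd.DataFrame({"offset": centers, "signal": profile}).set_index("offset")
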