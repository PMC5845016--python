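"""Phosphosite occupancy from the phosphatase-reference SILAC design.

Dephosphorylating one SILAC channel collapses the phosphorylated pool
into the unmodified peptide, so the unmodified-peptide ratio r between
the phosphatase-treated and untreated channels determines the fraction
of the protein pool carrying the phosphate:

    occupancy = (1 - 1/r) * 100%

r < 1 is physically impossible (dephosphorylation can only add to the
unmodified pool) and is flagged as invalid rather than clamped, so QC
can count how often measurement noise drives the estimate negative.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

__all__ = ["occupancy_from_ratio", "compute_site_occupancy"]


def occupancy_from_ratio(ratio_r: float) -> float:
    """Occupancy percentage from the unmodified-peptide ratio.

    Returns NaN (flagged invalid) for 0 < ratio_r < 1; raises for
    ratio_r <= 0.
    """
    ratio_r = float(ratio_r)
    if ratio_r <= 0:
        raise ValueError(f"ratio must be positive, got {ratio_r}")
    if ratio_r < 1:
        return np.nan
    return (1.0 - 1.0 / ratio_r) * 100.0


def compute_site_occupancy(table: pd.DataFrame) -> pd.DataFrame:
    """Per-site occupancy for each condition column of an occupancy table.

    ``table`` is indexed by site_id with one column of unmodified-peptide
    ratios per condition (e.g. 'mock', 'UV').  Sites with a missing
    ratio in a condition are skipped for that condition with a warning;
    ratios below 1 yield NaN occupancy and are counted in the warning as
    flagged-invalid.
    """
    out = {}
    for cond in table.columns:
        r = pd.to_numeric(table[cond], errors="coerce")
        missing = int(r.isna().sum())
        if missing:
            warnings.warn(f"{missing} site(s) missing unmodified-peptide ratio in {cond!r}")
        if (r <= 0).any():
            raise ValueError(f"non-positive ratio(s) in condition {cond!r}")
        occ = (1.0 - 1.0 / r) * 100.0
        invalid = r < 1
        if invalid.any():
            warnings.warn(f"{int(invalid.sum())} ratio(s) < 1 in {cond!r} flagged invalid")
        occ[invalid] = np.nan
        out[f"occupancy_pct:{cond}"] = occ
    return pd.DataFrame(out, index=table.index)
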