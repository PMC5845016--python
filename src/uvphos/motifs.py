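"""Position-specific sequence analysis around phosphosites.

Covers position frequency counting over the +-6 frame centered on the
phosphoacceptor, iceLogo-style foreground-vs-background enrichment
(per-cell z-score against binomial sampling of the background), fixed
consensus matchers (S/TQ, the MK2/3/5 motif LXRQXS/T, the downstream
effector motif RXXS/TXDXDI) and a rule-based 14-3-3 binding-motif
scorer.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "AMINO_ACIDS",
    "MotifCountMatrix",
    "MotifSpec",
    "MOTIF_STQ",
    "MOTIF_MK",
    "MOTIF_EFFECTOR",
    "count_position_frequencies",
    "icelogo_enrichment",
    "match_motif",
    "predict_14_3_3",
]

AMINO_ACIDS = tuple("ACDEFGHIKLMNPQRSTVWY")
PAD = "_"


@dataclass
class MotifCountMatrix:
    """Residue counts per flank position (phosphoacceptor at offset 0).

    ``counts`` is a (2*flank+1) x 20 frame indexed by offset; ``padding``
    counts the '_' placeholders per offset so that counts + padding sum
    to ``n_windows`` at every position.
    """

    counts: pd.DataFrame
    padding: pd.Series
    n_windows: int

    def frequencies(self) -> pd.DataFrame:
        """Per-position residue frequencies over non-padding characters."""
        occupied = self.counts.sum(axis=1)
        return self.counts.div(occupied.where(occupied > 0), axis=0)

    def occupied(self) -> pd.Series:
        """Number of non-padding characters per position."""
        return self.counts.sum(axis=1)


def _center_offsets(window: str, flank: int):
    if len(window) % 2 == 0:
        raise ValueError(f"window {window!r} has even length, no center residue")
    c = len(window) // 2
    if flank > c:
        raise ValueError(f"window too short for flank {flank}")
    return c


def count_position_frequencies(windows, flank: int = 6) -> MotifCountMatrix:
    """Tally residues in the +-flank frame around the phosphoacceptor."""
    offsets = list(range(-flank, flank + 1))
    width = 2 * flank + 1
    slices = []
    for w in windows:
        c = _center_offsets(w, flank)
        slices.append(w[c - flank : c + flank + 1])
    n = len(slices)
    counts = pd.DataFrame(0, index=offsets, columns=list(AMINO_ACIDS))
    padding = pd.Series(0, index=offsets)
    if n:
        mat = np.array(slices, dtype=f"U{width}").view("U1").reshape(n, width)
        for j, off in enumerate(offsets):
            vals, cnts = np.unique(mat[:, j], return_counts=True)
            for v, c_ in zip(vals, cnts):
                if v in counts.columns:
                    counts.loc[off, v] += int(c_)
                else:
                    padding[off] += int(c_)  # '_' and non-standard residues
    return MotifCountMatrix(counts=counts, padding=padding, n_windows=n)


def icelogo_enrichment(
    fg: MotifCountMatrix,
    bg: MotifCountMatrix,
    alpha: float = 0.05,
    bh_correct: bool = False,
) -> pd.DataFrame:
    """Per-cell foreground-vs-background enrichment, iceLogo style.

    For each (position, residue) cell the foreground frequency is
    compared with the background frequency under binomial sampling of
    n_fg windows from the background:

        z = (f_fg - f_bg) / sqrt(f_bg (1 - f_bg) / n_fg)

    Two-sided p from the normal; ``significant`` flags cells at alpha
    (no multiple-testing correction by default, matching iceLogo;
    ``bh_correct`` switches to BH-adjusted calls).
    """
    if fg.n_windows == 0:
        raise ValueError("empty foreground")
    if not fg.counts.index.equals(bg.counts.index):
        raise ValueError("foreground and background frames differ")
    f_fg = fg.frequencies()
    f_bg = bg.frequencies()
    n_fg = fg.occupied()

    rows = []
    for off in fg.counts.index:
        for aa in AMINO_ACIDS:
            pf, pb = f_fg.loc[off, aa], f_bg.loc[off, aa]
            n = n_fg[off]
            if n == 0 or np.isnan(pb):
                continue
            denom = np.sqrt(pb * (1 - pb) / n) if 0 < pb < 1 else np.nan
            diff = pf - pb
            z = diff / denom if denom and denom > 0 else np.nan
            p = 2 * stats.norm.sf(abs(z)) if np.isfinite(z) else np.nan
            rows.append((off, aa, pf, pb, diff, z, p))
    out = pd.DataFrame(
        rows, columns=["position", "residue", "freq_fg", "freq_bg", "diff", "z", "p"]
    )
    if bh_correct:
        from .ebayes import bh_adjust

        out["q"] = bh_adjust(out["p"].to_numpy())
        out["significant"] = out["q"] < alpha
    else:
        out["significant"] = out["p"] < alpha
    return out


@dataclass(frozen=True)
class MotifSpec:
    """Fixed consensus: required residue sets at offsets from the center."""

    name: str
    center: frozenset
    required: tuple  # ((offset, frozenset), ...)

    @classmethod
    def make(cls, name, center, required: dict) -> "MotifSpec":
        for off in required:
            if not -6 <= off <= 6:
                raise ValueError(f"offset {off} outside +-6")
        return cls(
            name=name,
            center=frozenset(center),
            required=tuple(sorted((o, frozenset(s)) for o, s in required.items())),
        )


#: ATM/ATR/DNA-PKcs consensus: phospho-S/T followed by Q
MOTIF_STQ = MotifSpec.make("S/TQ", "ST", {+1: "Q"})
#: MK2/3/5 substrate consensus LXRQXS/T
MOTIF_MK = MotifSpec.make("LXRQXS/T", "ST", {-5: "L", -3: "R", -2: "Q"})
#: downstream p38-effector consensus RXXS/TXDXDI
MOTIF_EFFECTOR = MotifSpec.make("RXXS/TXDXDI", "ST", {-3: "R", +2: "D", +4: "D", +5: "I"})


def match_motif(window: str, spec: MotifSpec) -> bool:
    """True iff the center residue and every required offset match the spec."""
    c = len(window) // 2
    if len(window) % 2 == 0:
        raise ValueError(f"window {window!r} has even length")
    if window[c] not in spec.center:
        return False
    for off, allowed in spec.required:
        pos = c + off
        if pos < 0 or pos >= len(window) or window[pos] not in allowed:
            return False
    return True


AROMATIC = frozenset("FWY")


def predict_14_3_3(window: str, cutoff: int = 1) -> tuple[int, bool]:
    """Rule-based 14-3-3 binding-motif score for a phospho-S/T window.

    Transparent surrogate for consensus-based 14-3-3 predictors.  Scores
    the best-matching rule:

    - mode I  (score 3): R at -3, S/T or aromatic at -2, P at +2
    - mode II (score 2): R at -4 or -3, P at +2
    - relaxed (score 1): R at -3 and S at -2 (no +2 constraint)

    ``positive`` is score >= cutoff.  Errors if the center residue is
    not S or T (14-3-3 reads phospho-Ser/Thr only).
    """
    c = len(window) // 2
    if len(window) % 2 == 0:
        raise ValueError(f"window {window!r} has even length")
    if window[c] not in "ST":
        raise ValueError(f"center residue {window[c]!r} is not S/T")

    def at(off):
        pos = c + off
        return window[pos] if 0 <= pos < len(window) else PAD

    score = 0
    if at(-3) == "R" and (at(-2) in "ST" or at(-2) in AROMATIC) and at(+2) == "P":
        score = 3
    elif (at(-4) == "R" or at(-3) == "R") and at(+2) == "P":
        score = 2
    elif at(-3) == "R" and at(-2) == "S":
        score = 1
    return score, score >= cutoff
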