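"""Synthetic datasets with planted ground truth for every pipeline stage.

Each simulator emulates one of the experimental designs the pipeline analyzes:

- ``simulate_phospho_experiment``: triple-SILAC phosphoproteomics with a
  planted UV-upregulated stratum (~4% of sites), of which ~26% are
  p38-dependent and ~60% of those MK2/3/5-dependent; replicate log2
  ratios get independent Normal noise; MK-dependent windows carry the
  LXRQXS/T consensus and a disjoint "ATR-substrate" stratum carries S/TQ.
- ``simulate_pulldown``: protein-level 14-3-3 pulldown enrichment with a
  planted interactor stratum (384 of 2000 by default) of which 28% lose
  enrichment under p38 inhibition.
- ``simulate_polii_coverage``: paused-polymerase ChIP-seq-like coverage
  (Gaussian TSS peak + uniform gene body + Poisson noise) with a planted
  gene-body release shift (delta PRR) for a gene subset.
- ``simulate_occupancy``: phosphatase-reference unmodified-peptide
  ratios r = 1/(1-o) with multiplicative log-normal noise.

The noise models are the field-standard choices (Normal in log2 space
for SILAC ratios, Poisson for read counts); every simulator returns a
truth table sufficient to score the downstream caller, and identical
seeds give byte-identical outputs (single numpy default_rng per call).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import CoverageTrack, GeneModel, PulldownTable, SilacSiteTable
from .motifs import AMINO_ACIDS

__all__ = [
    "SimConfig",
    "PulldownSimConfig",
    "CoverageSimConfig",
    "OccupancySimConfig",
    "simulate_phospho_experiment",
    "simulate_pulldown",
    "simulate_polii_coverage",
    "simulate_occupancy",
]


def _check_prob(name, value):
    if not 0 <= value <= 1:
        raise ValueError(f"{name} must lie in [0, 1], got {value}")


@dataclass(frozen=True)
class SimConfig:
    """Phosphoproteomics simulation parameters (defaults = the modeled design)."""

    seed: int = 0
    n_sites: int = 13091
    frac_uv_up: float = 0.04
    frac_p38_dep_given_up: float = 0.26
    frac_mk_dep_given_p38: float = 0.60
    frac_atr_given_up: float = 0.17
    effect_log2: float = 1.5
    sigma_rep: float = 0.35
    n_replicates: int = 2
    motif_injection: bool = True
    frac_low_localization: float = 0.05

    def __post_init__(self):
        for name in (
            "frac_uv_up",
            "frac_p38_dep_given_up",
            "frac_mk_dep_given_p38",
            "frac_atr_given_up",
            "frac_low_localization",
        ):
            _check_prob(name, getattr(self, name))
        if self.sigma_rep <= 0:
            raise ValueError("sigma_rep must be positive")
        if self.n_replicates < 2:
            raise ValueError("need at least 2 replicates")
        if self.frac_p38_dep_given_up + self.frac_atr_given_up > 1:
            raise ValueError("p38-dependent and ATR strata must be disjoint within UV-up")


UV_CONTRAST = "UV/mock"
P38_CONTRAST = "p38i+UV/mock"
MK_CONTRAST = "MKi+UV/mock"


def simulate_phospho_experiment(cfg: SimConfig) -> tuple[SilacSiteTable, pd.DataFrame]:
    """Simulate a SILAC phosphosite table plus its planted truth.

    Ratios (log2): UV/mock ~ N(effect * uv_up, sigma) per replicate;
    the p38-inhibitor (and MK-inhibitor) contrast retains the effect
    unless the site is planted dependent on that kinase.
    """
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_sites

    uv_up = rng.random(n) < cfg.frac_uv_up
    u = rng.random(n)  # single draw splits the UV-up stratum disjointly
    p38_dep = uv_up & (u < cfg.frac_p38_dep_given_up)
    atr = uv_up & (u >= cfg.frac_p38_dep_given_up) & (
        u < cfg.frac_p38_dep_given_up + cfg.frac_atr_given_up
    )
    mk_dep = p38_dep & (rng.random(n) < cfg.frac_mk_dep_given_p38)

    # windows: center mostly S, some T, few Y; motif injection per stratum
    centers = rng.choice(list("STY"), size=n, p=[0.85, 0.13, 0.02])
    centers[p38_dep | atr] = rng.choice(list("ST"), size=int((p38_dep | atr).sum()), p=[0.9, 0.1])
    flank = 15
    width = 2 * flank + 1
    chars = np.array(list(AMINO_ACIDS))[rng.integers(0, 20, size=(n, width))]
    chars[:, flank] = centers
    if cfg.motif_injection:
        chars[mk_dep, flank - 5] = "L"
        chars[mk_dep, flank - 3] = "R"
        chars[mk_dep, flank - 2] = "Q"
        chars[atr, flank + 1] = "Q"
    windows = ["".join(row) for row in chars]

    loc = rng.uniform(0.75, 1.0, size=n)
    low = rng.random(n) < cfg.frac_low_localization
    loc[low] = rng.uniform(0.0, 0.75, size=int(low.sum()))

    site_ids = [f"site{i:05d}" for i in range(n)]
    sites = pd.DataFrame(
        {
            "protein_id": [f"P{i // 4:05d}" for i in range(n)],
            "gene_name": [f"GENE{i // 4:05d}" for i in range(n)],
            "position": rng.integers(10, 900, size=n),
            "residue": centers,
            "localization_prob": loc,
            "sequence_window": windows,
        },
        index=pd.Index(site_ids, name="site_id"),
    )

    def ratios_for(effect_mask):
        mu = np.where(effect_mask, cfg.effect_log2, 0.0)
        return mu[:, None] + rng.normal(0.0, cfg.sigma_rep, size=(n, cfg.n_replicates))

    blocks = {
        UV_CONTRAST: ratios_for(uv_up),
        P38_CONTRAST: ratios_for(uv_up & ~p38_dep),
        MK_CONTRAST: ratios_for(uv_up & ~mk_dep),
    }
    cols, data = [], []
    for cond, mat in blocks.items():
        for r in range(cfg.n_replicates):
            cols.append((cond, r + 1))
            data.append(mat[:, r])
    ratios = pd.DataFrame(
        np.column_stack(data),
        index=sites.index,
        columns=pd.MultiIndex.from_tuples(cols, names=["condition", "replicate"]),
    )

    truth = pd.DataFrame(
        {
            "uv_up": uv_up,
            "p38_dep": p38_dep,
            "mk_dep": mk_dep,
            "atr_substrate": atr,
            "effect_log2": np.where(uv_up, cfg.effect_log2, 0.0),
        },
        index=sites.index,
    )
    return SilacSiteTable(sites=sites, ratios=ratios), truth


@dataclass(frozen=True)
class PulldownSimConfig:
    """14-3-3 pulldown simulation parameters."""

    seed: int = 0
    n_proteins: int = 2000
    n_interactors: int = 384
    frac_dep_given_interactor: float = 0.28
    effect_log2: float = 2.0
    sigma_rep: float = 0.35
    n_replicates: int = 2

    def __post_init__(self):
        _check_prob("frac_dep_given_interactor", self.frac_dep_given_interactor)
        if not 0 <= self.n_interactors <= self.n_proteins:
            raise ValueError("n_interactors must not exceed n_proteins")


BAIT_CONTRAST = "14-3-3/control"
PULLDOWN_INHIBITOR_CONTRAST = "p38i+UV/UV"


def simulate_pulldown(cfg: PulldownSimConfig) -> tuple[PulldownTable, pd.DataFrame]:
    """Simulate a protein-level pulldown table plus planted truth.

    Interactors get positive bait-vs-control log2 enrichment; the
    p38-dependent subset additionally loses enrichment in the
    inhibitor-vs-UV contrast (planted negative shift of the same size).
    """
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_proteins
    interactor = np.zeros(n, dtype=bool)
    int_idx = rng.choice(n, size=cfg.n_interactors, replace=False)
    interactor[int_idx] = True
    # exact-count planting (the emulated experiment has fixed counts:
    # round(0.28 * 384) = 108 dependent interactors)
    n_dep = int(round(cfg.frac_dep_given_interactor * cfg.n_interactors))
    dep = np.zeros(n, dtype=bool)
    dep[rng.choice(int_idx, size=n_dep, replace=False)] = True

    bait = np.where(interactor, cfg.effect_log2, 0.0)[:, None] + rng.normal(
        0, cfg.sigma_rep, size=(n, cfg.n_replicates)
    )
    inhib = np.where(dep, -cfg.effect_log2, 0.0)[:, None] + rng.normal(
        0, cfg.sigma_rep, size=(n, cfg.n_replicates)
    )
    ids = pd.Index([f"P{i:05d}" for i in range(n)], name="protein_id")
    proteins = pd.DataFrame({"gene_name": [f"GENE{i:05d}" for i in range(n)]}, index=ids)
    cols, data = [], []
    for cond, mat in ((BAIT_CONTRAST, bait), (PULLDOWN_INHIBITOR_CONTRAST, inhib)):
        for r in range(cfg.n_replicates):
            cols.append((cond, r + 1))
            data.append(mat[:, r])
    ratios = pd.DataFrame(
        np.column_stack(data),
        index=ids,
        columns=pd.MultiIndex.from_tuples(cols, names=["condition", "replicate"]),
    )
    truth = pd.DataFrame({"interactor": interactor, "p38_dep_interactor": dep}, index=ids)
    return PulldownTable(proteins=proteins, ratios=ratios), truth


@dataclass(frozen=True)
class CoverageSimConfig:
    """Paused-polymerase coverage simulation parameters.

    Rates are reads per base; the TSS peak is a Gaussian bump just
    downstream of the TSS on top of a uniform gene-body rate, and UV
    release multiplies the gene-body rate beyond +1000 bp by
    2**delta_prr for the released gene subset.
    """

    seed: int = 0
    n_genes: int = 500
    min_length: int = 1000
    max_length: int = 30000
    gap: int = 2000
    frac_released: float = 0.30
    delta_prr: float = 1.0
    tss_peak_height: float = 30.0
    tss_peak_sd: float = 200.0
    tss_peak_offset: int = 100
    body_rate: float = 2.0
    n_replicates: int = 2
    frac_minus_strand: float = 0.5
    release_boundary: int = 1000  # bp downstream of TSS where release starts
    chrom: str = "chrSim"
    chrom_size: int | None = None

    def __post_init__(self):
        _check_prob("frac_released", self.frac_released)
        if self.min_length <= 0 or self.max_length < self.min_length:
            raise ValueError("invalid gene length range")


def simulate_polii_coverage(
    cfg: CoverageSimConfig,
) -> tuple[list, dict, pd.DataFrame]:
    """Simulate gene models and mock/UV coverage tracks with planted release.

    Returns (genes, tracks, truth) where ``tracks`` maps condition ->
    list of replicate CoverageTracks.  Raises if the configured
    chromosome cannot hold all genes.
    """
    rng = np.random.default_rng(cfg.seed)
    lengths = rng.integers(cfg.min_length, cfg.max_length + 1, size=cfg.n_genes)
    strands = np.where(rng.random(cfg.n_genes) < cfg.frac_minus_strand, "-", "+")
    released = rng.random(cfg.n_genes) < cfg.frac_released

    needed = int(lengths.sum() + cfg.gap * (cfg.n_genes + 1))
    size = cfg.chrom_size or needed
    if size < needed:
        raise ValueError(f"chromosome size {size} too small for {cfg.n_genes} genes ({needed})")

    genes = []
    pos = cfg.gap
    for i in range(cfg.n_genes):
        start, end = pos, pos + int(lengths[i])
        genes.append(GeneModel.from_interval(f"g{i:04d}", cfg.chrom, start, end, strands[i]))
        pos = end + cfg.gap

    base_rate = np.zeros(size)
    uv_rate = None  # filled after base
    release_mask = np.zeros(size, dtype=bool)
    for gene, rel in zip(genes, released):
        L = gene.length
        d = np.arange(L)  # distance from TSS in transcription direction
        profile = cfg.body_rate + cfg.tss_peak_height * np.exp(
            -0.5 * ((d - cfg.tss_peak_offset) / cfg.tss_peak_sd) ** 2
        )
        if gene.strand == "+":
            base_rate[gene.tss : gene.tss + L] += profile
            if rel:
                release_mask[gene.tss + cfg.release_boundary : gene.tss + L] = True
        else:
            base_rate[gene.tss - L + 1 : gene.tss + 1] += profile[::-1]
            if rel:
                release_mask[gene.tss - L + 1 : gene.tss - cfg.release_boundary + 1] = True

    uv_rate = base_rate.copy()
    # release multiplies only the body signal beyond the TSS window, so the
    # planted delta PRR acts purely on the downstream window
    uv_rate[release_mask] *= 2.0**cfg.delta_prr

    tracks = {"mock": [], "UV": []}
    for cond, rate in (("mock", base_rate), ("UV", uv_rate)):
        for rep in range(1, cfg.n_replicates + 1):
            cov = rng.poisson(rate).astype(float)
            tracks[cond].append(
                CoverageTrack(condition=cond, replicate=rep, coverage={cfg.chrom: cov})
            )

    truth = pd.DataFrame(
        {
            "length": [g.length for g in genes],
            "strand": [g.strand for g in genes],
            "released": released,
            "delta_prr_planted": np.where(released, cfg.delta_prr, 0.0),
            "prr_eligible": [g.length > 3000 for g in genes],
        },
        index=pd.Index([g.gene_id for g in genes], name="gene_id"),
    )
    return genes, tracks, truth


@dataclass(frozen=True)
class OccupancySimConfig:
    """Phosphatase-reference occupancy simulation parameters."""

    seed: int = 0
    n_sites: int = 500
    occ_low: float = 0.1
    occ_high: float = 0.9
    noise_cv: float = 0.05
    conditions: tuple = ("mock", "UV")

    def __post_init__(self):
        _check_prob("occ_low", self.occ_low)
        _check_prob("occ_high", self.occ_high)
        if self.occ_high < self.occ_low:
            raise ValueError("occ_high must be >= occ_low")
        if self.noise_cv < 0:
            raise ValueError("noise_cv must be non-negative")


def simulate_occupancy(cfg: OccupancySimConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate unmodified-peptide ratio tables plus planted occupancies.

    For planted occupancy o the noise-free ratio is r = 1/(1-o);
    multiplicative log-normal noise with the configured CV is applied.
    Returns (ratio table indexed by site with one column per condition,
    truth table of planted occupancies on the same shape).
    """
    rng = np.random.default_rng(cfg.seed)
    ids = pd.Index([f"site{i:04d}" for i in range(cfg.n_sites)], name="site_id")
    ratios, truths = {}, {}
    for cond in cfg.conditions:
        o = rng.uniform(cfg.occ_low, cfg.occ_high, size=cfg.n_sites)
        r = 1.0 / (1.0 - o)
        if cfg.noise_cv > 0:
            r = r * np.exp(rng.normal(0.0, cfg.noise_cv, size=cfg.n_sites))
        ratios[cond] = r
        truths[cond] = o
    return pd.DataFrame(ratios, index=ids), pd.DataFrame(truths, index=ids)
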