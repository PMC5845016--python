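"""Config-driven end-to-end orchestration of the phospho pipeline.

A run simulates (or reads) a phosphosite table, calls UV regulation and
the p38/MK dependency tiers, runs motif enrichment on the dependent
stratum, and writes per-stage TSVs plus a machine-readable summary.json
carrying every count and fraction with the thresholds that produced
them.  Stages never mutate each other's inputs; re-running a stage from
its cached input reproduces the full-run output.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

from . import __version__
from .io import read_site_table, write_site_table
from .motifs import count_position_frequencies, icelogo_enrichment
from .regulation import call_dependency, call_uv_regulation, summarize_fractions
from .synthetic import MK_CONTRAST, P38_CONTRAST, UV_CONTRAST, SimConfig, simulate_phospho_experiment

log = logging.getLogger("uvphos")

__all__ = ["PipelineConfig", "run_pipeline"]


@dataclass
class PipelineConfig:
    """End-to-end run configuration (thresholds per the modeled experimental design)."""

    out_dir: str = "uvphos_out"
    sites_path: str | None = None  # None -> simulate
    seed: int = 0
    alpha_phospho: float = 0.01
    alpha_interactome: float = 0.05
    localization_cutoff: float = 0.75
    uv_contrast: str = UV_CONTRAST
    p38_contrast: str = P38_CONTRAST
    mk_contrast: str | None = MK_CONTRAST
    sim: dict = field(default_factory=dict)

    def __post_init__(self):
        for name in ("alpha_phospho", "alpha_interactome", "localization_cutoff"):
            v = getattr(self, name)
            if not 0 < v < 1:
                raise ValueError(f"{name} must lie in (0, 1), got {v}")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        import yaml

        with open(path) as fh:
            cfg = yaml.safe_load(fh) or {}
        return cls(**cfg)


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Run simulate/read -> classify -> motif and write stage outputs.

    Returns the summary record (also written as summary.json).
    """
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log.info("uvphos %s | seed=%d alpha=%g", __version__, cfg.seed, cfg.alpha_phospho)

    if cfg.sites_path is None:
        sim_cfg = SimConfig(seed=cfg.seed, **cfg.sim)
        table, truth = simulate_phospho_experiment(sim_cfg)
        truth.to_csv(out / "truth.tsv", sep="\t")
        write_site_table(table, out / "sites.tsv")
        log.info("simulated %d sites", len(table.sites))
    else:
        table = read_site_table(cfg.sites_path)
        truth = None
        log.info("read %d sites from %s", len(table.sites), cfg.sites_path)

    calls = call_uv_regulation(
        table,
        uv_contrast=cfg.uv_contrast,
        alpha=cfg.alpha_phospho,
        localization_cutoff=cfg.localization_cutoff,
    )
    calls = call_dependency(
        table, calls, cfg.p38_contrast, uv_contrast=cfg.uv_contrast,
        alpha=cfg.alpha_phospho, among="up", column="dependency",
    )
    if cfg.mk_contrast and cfg.mk_contrast in table.conditions:
        calls = call_dependency(
            table, calls, cfg.mk_contrast, uv_contrast=cfg.uv_contrast,
            alpha=cfg.alpha_phospho, among="dependency", column="mk_dependency",
        )
    calls.to_csv(out / "calls.tsv", sep="\t")

    dep_windows = table.sites.loc[
        calls.index[calls.get("dependency", "na") == "dependent"], "sequence_window"
    ]
    motif_table = None
    if len(dep_windows):
        fg = count_position_frequencies(dep_windows)
        bg = count_position_frequencies(table.sites["sequence_window"])
        motif_table = icelogo_enrichment(fg, bg)
        motif_table.to_csv(out / "motif_enrichment.tsv", sep="\t", index=False)

    summary = {
        "version": __version__,
        "seed": cfg.seed,
        "parameters": {
            "alpha_phospho": cfg.alpha_phospho,
            "localization_cutoff": cfg.localization_cutoff,
            "contrasts": [cfg.uv_contrast, cfg.p38_contrast, cfg.mk_contrast],
        },
        "fractions": summarize_fractions(calls),
    }
    if truth is not None:
        summary["planted"] = {
            "uv_up": int(truth["uv_up"].sum()),
            "p38_dep": int(truth["p38_dep"].sum()),
            "mk_dep": int(truth["mk_dep"].sum()),
        }
    with open(out / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return summary
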