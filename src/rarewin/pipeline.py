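"""End-to-end orchestration: simulate → QC → windows → scans → meta → report.

`run_pipeline` drives the whole analysis on synthetic cohorts (or on
matrices supplied by the caller), producing the discovery scan, the
replication scan on the mapped windows, the Fisher meta-analysis and the
top-regions report.  All randomness derives from the configured seeds, so
identical configuration yields byte-identical written reports.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import meta as meta_mod
from .casecontrol import CCTestConfig, scan_case_control
from .famtest import RegionTestConfig, scan_family_genome
from .io import Pedigree, write_results
from .popstruct import PruneConfig, rare_variant_pcs
from .qc import QCConfig, filter_variants
from .simulate import (
    SimConfig,
    simulate_case_control,
    simulate_families,
    simulate_founder_panel,
    af_reference,
)
from .windows import build_windows, map_windows_by_key, windows_table

__all__ = ["PipelineConfig", "PipelineResult", "run_pipeline"]


@dataclass
class PipelineConfig:
    sim: SimConfig = field(default_factory=SimConfig)
    qc: QCConfig = field(default_factory=QCConfig)
    fam: RegionTestConfig = field(default_factory=RegionTestConfig)
    cc: CCTestConfig = field(default_factory=CCTestConfig)
    prune: PruneConfig = field(default_factory=PruneConfig)
    window_k: int = 10
    alpha: float = 0.05
    suggestive: float = 5e-6
    use_pca: bool = True
    replication_name: str = "cc"
    comparable: tuple[str, ...] = ("cc",)

    def __post_init__(self) -> None:
        if not 0 < self.suggestive < 1 or not 0 < self.alpha < 1:
            raise ValueError("thresholds must be in (0, 1)")


@dataclass
class PipelineResult:
    discovery: pd.DataFrame
    replication: dict[str, pd.DataFrame]
    meta: pd.DataFrame
    report: pd.DataFrame
    manhattan: pd.DataFrame
    qc_reports: dict[str, pd.DataFrame]
    windows: pd.DataFrame
    bonferroni: float
    truth: dict


def run_pipeline(cfg: PipelineConfig, outdir: str | Path | None = None) -> PipelineResult:
    """Run the full synthetic-data analysis.

    Simulates the family discovery cohort and the case-control replication
    cohort from one founder panel, applies variant QC to each, windows the
    discovery variants, runs both scans (replication on each window's
    variant subset present post-QC in the replication cohort), combines
    p-values with Fisher's method, and assembles the report.  With
    ``outdir`` set, writes the result tables as TSV.
    """
    sim = cfg.sim
    panel = simulate_founder_panel(sim, np.random.default_rng(
        np.random.SeedSequence((sim.seed, 0))))
    G_fam, ped, phen_fam, truth_fam = simulate_families(
        sim, panel, np.random.default_rng(np.random.SeedSequence((sim.seed, 1)))
    )
    G_cc, phen_cc, cov_cc, truth_cc = simulate_case_control(
        sim, panel, np.random.default_rng(np.random.SeedSequence((sim.seed, 2)))
    )
    af_table = af_reference(panel)

    G_fam_qc, rep_fam = filter_variants(G_fam, ped, af_table, cfg.qc)
    empty_ped = Pedigree(
        pd.DataFrame(columns=["fid", "iid", "father", "mother", "sex", "affection"])
    )
    G_cc_qc, rep_cc = filter_variants(G_cc, empty_ped, af_table, cfg.qc)

    wins = build_windows(G_fam_qc.variants, cfg.window_k)
    discovery = scan_family_genome(G_fam_qc, ped, phen_fam, wins, cfg.fam)

    cov = cov_cc
    if cfg.use_pca and G_cc_qc.n_variants:
        pcs = rare_variant_pcs(G_cc_qc, cfg.prune, k=cfg.cc.n_pcs)
        cov = cov_cc.join(pcs)
    repl_wins = map_windows_by_key(wins, G_cc_qc.variants)
    replication = {
        cfg.replication_name: scan_case_control(
            G_cc_qc, phen_cc, cov, repl_wins, cfg.cc
        )
    }

    meta = meta_mod.combine_discovery_replication(
        discovery, replication, cfg.comparable
    )
    bonf = meta_mod.bonferroni_threshold(cfg.alpha, max(len(wins), 1))
    report = meta_mod.assemble_results(
        discovery, replication, meta, cfg.suggestive, bonf
    )
    manhattan = meta_mod.manhattan_table(discovery, suggestive=cfg.suggestive)

    result = PipelineResult(
        discovery=discovery,
        replication=replication,
        meta=meta,
        report=report,
        manhattan=manhattan,
        qc_reports={"family": rep_fam, cfg.replication_name: rep_cc},
        windows=windows_table(wins),
        bonferroni=bonf,
        truth={
            "family": truth_fam,
            cfg.replication_name: truth_cc,
        },
    )
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_results(discovery, outdir / "discovery.tsv")
        for name, t in replication.items():
            write_results(t, outdir / f"replication_{name}.tsv")
        write_results(meta, outdir / "meta.tsv")
        write_results(report, outdir / "report.tsv")
        write_results(manhattan, outdir / "manhattan.tsv")
        for name, t in result.qc_reports.items():
            t.to_csv(outdir / f"qc_{name}.tsv", sep="\t", index=False)
        result.windows.to_csv(outdir / "windows.tsv", sep="\t", index=False)
    return result
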