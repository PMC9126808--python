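"""Simulate a multiplex-family cohort and a case-control cohort.

Both cohorts are drawn from one founder haplotype panel of rare variants
(AF ≤ 1%), so the same variants appear in discovery and replication.
Families are ascertained for ≥ 2 affected siblings; disease follows a
logistic model calibrated to a population prevalence of 0.15.
"""

from pathlib import Path

from rarewin.simulate import (
    SimConfig,
    CausalWindow,
    simulate_case_control,
    simulate_families,
    simulate_founder_panel,
    write_case_control_cohort,
    write_family_cohort,
)

cfg = SimConfig(
    n_families=100,
    n_cases=300,
    n_controls=300,
    n_chrom=2,
    variants_per_chrom=50,
    causal_windows=(CausalWindow("1", 0, "unidirectional", 1.2),),
    seed=42,
)

panel = simulate_founder_panel(cfg)
G_fam, ped, phen_fam, truth = simulate_families(cfg, panel)
G_cc, phen_cc, cov, _ = simulate_case_control(cfg, panel)

outdir = Path("scratch/example_cohorts")
write_family_cohort(outdir, cfg, panel, G_fam, ped, phen_fam, truth)
write_case_control_cohort(outdir, cfg, panel, G_cc, phen_cc, cov, truth)

print(f"panel: {panel.n_variants} rare variants on {len(panel.chroms)} chromosomes")
print(f"families: {ped.n_families} sibships, {G_fam.n_samples} genotyped siblings")
print(f"  affected siblings: {int(phen_fam.sum())} "
      f"(every family has ≥ {cfg.min_affected_sibs} by ascertainment)")
print(f"case-control: {int(phen_cc.sum())} cases / {int((1 - phen_cc).sum())} controls")
print(f"planted causal window: {truth.causal_window_ids} "
      f"({len(truth.effect_per_variant)} risk variants, log-OR 1.2 per allele)")
print(f"files written to {outdir}/ (VCF, PED, phenotype/covariate TSV, truth JSON)")
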