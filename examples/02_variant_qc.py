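"""Variant quality control: the fixed-order filter cascade.

Filters: multiallelic → monomorphic → indel → singleton (dataset-wide or
single-family) → half-call → Mendel errors → call rate ≥ 95% → HWE exact
p ≥ 1e-8 (founders/unrelated only) → external AF ≤ 1% → allow-list.
The report shows per-filter attrition; only variants surviving every
stage are windowed and tested.
"""

from rarewin.qc import QCConfig, filter_variants
from rarewin.simulate import SimConfig, simulate_families, simulate_founder_panel, af_reference

cfg = SimConfig(n_families=80, n_chrom=2, variants_per_chrom=100, seed=7)
panel = simulate_founder_panel(cfg)
G, ped, phen, _ = simulate_families(cfg, panel)
af_table = af_reference(panel)

G_qc, report = filter_variants(G, ped, af_table, QCConfig())

print(report.to_string(index=False))
print()
print(f"{G.n_variants} simulated variants -> {G_qc.n_variants} pass QC.")
print("In a small cohort most removals are singletons: rare variants seen "
      "in only one family carry no between-family replication and are "
      "excluded before testing.")
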