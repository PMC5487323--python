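"""Per-site and per-tissue methylation levels, QC and band histogram.

Sites must be covered by >= 5 reads in every library; a tissue's level
is the mean of its replicates' methylated-read fractions.
"""

import methaxis as mx

sim = mx.simulate(mx.SimConfig(seed=1))
design = sim.design()

filtered = mx.filter_sites(sim.sites, min_coverage=5)
print(f"{len(filtered)} of {len(sim.sites)} sites pass the 5x everywhere filter")

levels = mx.add_levels(filtered, design)
print("\nglobal means (% methylation):")
print(mx.global_summary(levels, design).to_string(index=False))

# bisulfite conversion QC from CpH sites (expected near 100%)
qc = mx.conversion_rate(sim.sites, "ovary_1")
print(f"\novary_1 conversion efficiency: {qc['efficiency_pct']:.2f}%")

cpg = levels[levels["context"] == "CpG"]
print("\nCpG methylation band fractions (hypothalamus):")
print(mx.level_histogram(cpg["beta_hypothalamus"]).to_string())
# The low band collects island/upstream sites; the high bands collect
# gene-body and intergenic sites — the bimodal RRBS signature.
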