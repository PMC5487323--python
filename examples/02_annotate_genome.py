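"""Partition the genome into genic features and localize CpG islands.

Every base gets exactly one of five labels (upstream / exon / intron /
downstream / intergenic); islands get 2-kb shores and 2-kb shelves, and
each island is assigned to the feature covering > 50% of it.
"""

from collections import Counter

import methaxis as mx

sim = mx.simulate(mx.SimConfig(seed=1))

fmap = mx.build_genic_features(sim.genes, sim.config.chrom_sizes)
for label in ("upstream", "exon", "intron", "downstream", "intergenic"):
    bp = sum(
        int((arr[:, 1] - arr[:, 0]).sum()) for arr in fmap.features[label].values()
    )
    print(f"{label:<11} {bp/1e6:6.2f} Mb")

cgi_set = mx.build_cgi_features(sim.cgis, sim.config.chrom_sizes)
classes = mx.classify_cgis(sim.cgis, fmap)
print("\nCGI localization (>50% overlap rule):")
for feature, n in Counter(c.feature for c in classes).most_common():
    print(f"  {feature:<11} {n}")

gene_sets = mx.classify_genes_by_cgi(classes, fmap)
for name, genes in gene_sets.items():
    print(f"{name:<15} {len(genes)} genes")

# The sequence-level island predicate is also available:
verdict, diag = mx.is_cgi("CG" * 150)
print(f"\n(CG)x150 is a CGI: {verdict}, obs/exp = {diag['obs_exp_ratio']:.2f}")
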