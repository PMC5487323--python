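"""Generate a synthetic 3-tissue, 3-replicate RRBS dataset with known truth.

Sites are clustered (dense in CpG islands, fragment-like elsewhere),
counts are beta-binomial around feature-dependent means, and 60
tissue-specific differential regions are planted and recorded.
"""

import methaxis as mx

result = mx.simulate(mx.SimConfig(seed=1))

print(f"genes:            {len(result.genes)}")
print(f"CpG islands:      {len(result.cgis)}")
print(f"sites emitted:    {len(result.sites)} "
      f"({(result.sites['context'] == 'CpG').sum()} CpG, "
      f"{(result.sites['context'] == 'CpH').sum()} CpH)")
print(f"planted DMRs:     {len(result.planted)} "
      f"(first: {result.planted[0]})")

paths = result.write("scratch/simdir")
print(f"wrote {len(paths)} files, e.g. {paths['genes']}")
# Each library gets a Bismark-style coverage file (CpG) and a cytosine
# report (all contexts); truth.tsv records every site's true means.
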