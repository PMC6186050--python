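"""Estimate the empirical substitution model and simulate neutral SNVs.

Rates are estimated per 100 kb window, stratified by CpG context of the
ancestral base; CpG dinucleotides deaminate and substitute about an
order of magnitude faster. Simulated SNVs drawn from this model form
the proxy-deleterious training class.
"""

import numpy as np

from speciescadd import ancestor_diff, fixtures, mutmodel

spec = fixtures.FixtureSpec(genome_length=500_000, n_contigs=1, seed=2)
template = fixtures.generate_genome(spec)
ref, anc, _ = fixtures.evolve_ancestor(template, spec)

model = mutmodel.estimate_rates(ref, anc)
rates = model.global_rates()
B = "ACGT"
print("pooled substitution rates (ancestral base -> current base):")
print("  non-CpG C->T:", round(rates[1, B.index('C'), B.index('T')], 5))
print("  CpG     C->T:", round(rates[0, B.index('C'), B.index('T')], 5))
ratio = rates[0, 1, 3] / rates[1, 1, 3]
print(f"  CpG / non-CpG ratio: {ratio:.1f} (the generator planted 10x)")

derived = ancestor_diff.call_derived(ref, anc)
exclude = {"chr1": {v.pos for v in derived}}
sims = mutmodel.simulate_variants(
    model, ref, anc, n=len(derived), exclude=exclude,
    cfg=mutmodel.MutationModelConfig(rng_seed=2),
)
print(f"\nsimulated {len(sims)} SNVs (equal to the derived count)")
transitions = sum(
    1 for v in sims if {v.ref_allele, v.alt_allele} in ({"A", "G"}, {"C", "T"})
)
print(f"transition fraction among simulated: {transitions / len(sims):.2f}")

combined = mutmodel.build_training_set(derived, sims, n_folds=11, seed=2)
sizes = np.bincount([v.fold for v in combined])
print(f"\n11 training folds, sizes {sizes.min()}..{sizes.max()} "
      "(fold 10 is the held-out test partition)")
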