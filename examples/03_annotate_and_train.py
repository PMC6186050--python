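"""Assemble the annotation matrix and train the logistic classifier.

Features carry class tags (conservation, sequence, vep, epigenetic, ...)
so nested annotation-availability tiers can be carved out. Training
standardizes by dividing by the standard deviation only — no centering,
so sparse features stay sparse — and fits an L2-penalized logistic
regressor separating simulated (1) from derived (0) variants.
"""

import numpy as np

from speciescadd import ancestor_diff, fixtures, mutmodel, training
from speciescadd.features import apply_tier, build_feature_matrix

spec = fixtures.FixtureSpec(genome_length=300_000, n_contigs=1, seed=3)
template = fixtures.generate_genome(spec)
ref, anc, _ = fixtures.evolve_ancestor(template, spec)

derived = ancestor_diff.call_derived(ref, anc)
model_mut = mutmodel.estimate_rates(ref, anc)
sims = mutmodel.simulate_variants(
    model_mut, ref, anc, len(derived), {"chr1": {v.pos for v in derived}},
    mutmodel.MutationModelConfig(rng_seed=3),
)
combined = mutmodel.build_training_set(derived, sims, 11, seed=3)
labels = np.array([1 if v.label == "simulated" else 0 for v in combined])

bundle = fixtures.generate_feature_bundle(combined, labels, spec)
matrix = build_feature_matrix(ref, combined, bundle.tracks, bundle.csq,
                              bundle.shape_table)
print(f"feature matrix: {matrix.n_variants} variants x {len(matrix.columns)} columns")
for tier in ("all", "no_epi", "cons_vep", "seq_only"):
    print(f"  tier {tier:9s}: {len(apply_tier(matrix, tier).columns)} columns")

model = training.train_model(matrix, lam=0.1, max_iter=100, exclude_fold=10)
order = np.argsort(-np.abs(model.betas))[:5]
print("\ntop weights (|beta|, scaled feature space):")
for i in order:
    print(f"  {model.feature_names[i]:24s} {model.betas[i]:+.3f}")
print("\nthe planted informative tracks", bundle.truth["informative_features"],
      "should dominate")
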