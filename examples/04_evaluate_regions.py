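"""Region-stratified evaluation and matched negative sets.

The held-out fold is sliced into seven genomic-region subsets (all, not
transcribed, transcribed, transcribed-untranslated, translated,
synonymous, missense) and scored by ROC-AUC in each. A validation-style
negative set is sampled from high-allele-frequency candidates with
consequence strata matched exactly to the positives.
"""

from dataclasses import replace

import numpy as np

from speciescadd import ancestor_diff, evaluation, fixtures, mutmodel, training
from speciescadd.features import build_feature_matrix

spec = fixtures.FixtureSpec(genome_length=500_000, n_contigs=1, seed=4)
template = fixtures.generate_genome(spec)
ref, anc, _ = fixtures.evolve_ancestor(template, spec)
derived = ancestor_diff.call_derived(ref, anc)
sims = mutmodel.simulate_variants(
    mutmodel.estimate_rates(ref, anc), ref, anc, len(derived),
    {"chr1": {v.pos for v in derived}}, mutmodel.MutationModelConfig(rng_seed=4),
)
combined = mutmodel.build_training_set(derived, sims, 11, seed=4)
labels = np.array([1 if v.label == "simulated" else 0 for v in combined])
bundle = fixtures.generate_feature_bundle(combined, labels, spec)
matrix = build_feature_matrix(ref, combined, bundle.tracks, bundle.csq, None)

model = training.train_model(matrix, lam=0.1, max_iter=100, exclude_fold=10)
folds = matrix.folds()
keep = folds == 10
scores = training.score(model, matrix)[keep]
held = [v for v, k in zip(matrix.variants, keep) if k]
report = evaluation.stratified_report(scores, held, matrix.labels[keep])
print("held-out ROC-AUC by genomic region subset:")
print(report.to_dataframe().to_string(index=False))
print("\ncoding subsets separate best: the planted signal is strongest in "
      "translated regions, weakest outside transcripts.")

# matched negatives: derived variants play the strain-variant candidates,
# with synthetic allele frequencies; only AF >= 0.9 may be drawn
rng = np.random.default_rng(4)
positives = [v for v, l in zip(held, matrix.labels[keep]) if l == 1][:200]
candidates = [
    replace(v, af=float(rng.uniform(0.5, 1.0)))
    for v, l in zip(matrix.variants, matrix.labels) if l == 0
]
negatives = evaluation.match_negatives(positives, candidates, 0.9, seed=4)
strata = [evaluation._stratum(v) for v in negatives]
print(f"\nmatched negatives: {len(negatives)} sampled; strata "
      f"(syn/non-syn/other) = {strata.count('synonymous')}/"
      f"{strata.count('non_synonymous')}/{strata.count('other')} "
      "— identical to the positives by construction")
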