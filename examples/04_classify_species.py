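"""Classify syllables to species with a prior-weighted bagged forest.

Class imbalance is handled two ways: bootstrap sampling weighted by motif-share
priors, and SCUT resampling to a common per-class size. Permutation importance
ranks the features; the largest-gap elbow selects the informative subset.
"""

from songphylo.classification import (
    class_priors_from_motifs,
    evaluate,
    permutation_importance,
    scut_resample,
    select_features,
    train_forest,
)
from songphylo.synth import SynthSpec, synth_feature_table
from songphylo.trees import example_tree

tree = example_tree()
counts = {"ZF": 120, "LF": 300, "DF": 420, "RF": 60, "CB": 90, "GW": 180, "BF": 390}
spec = SynthSpec(syllables_per_species=counts, missing_rate=0.0, seed=6)
table = synth_feature_table(spec, tree)

priors = class_priors_from_motifs(table)
print("class priors from motif share:")
print(priors.round(3).to_string())

model = train_forest(table, priors=priors, n_trees=150, seed=7)
stats = evaluate(model)
print(f"\nOOB weighted F1 (prior-weighted forest): {stats.weighted_f1:.3f}")

balanced = scut_resample(table, seed=8)
print(f"\nSCUT-balanced table: {balanced.groupby('species').size().to_dict()}")
model_b = train_forest(balanced, n_trees=150, seed=9)
stats_b = evaluate(model_b)
print(f"OOB weighted F1 (SCUT-balanced forest): {stats_b.weighted_f1:.3f}")

imp = permutation_importance(table, n_trees=60, iterations=2, seed=10)
selected = select_features(imp)
print(f"\ntop-ranked features: {imp.rank_order[:5]}")
print(f"elbow-selected subset ({len(selected)}): {selected}")
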