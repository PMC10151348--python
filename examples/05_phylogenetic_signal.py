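"""Test acoustic distance matrices for phylogenetic signal.

Species-by-species distance matrices (sum of squared differences between
binned feature histograms) are screened with the standard Mantel test and
confirmed with the evolutionary-model Mantel test (Brownian-motion null);
dendrograms cut at k clusters are compared with the Fowlkes-Mallows index.
"""

import numpy as np

from songphylo.feature_space import pca_fit, ripca_impute
from songphylo.phylo_signal import (
    build_distance_matrices,
    cluster_dendrogram,
    em_mantel,
    fmi_test,
    inertia_percent,
    pp_mantel,
    two_step_signal,
)
from songphylo.synth import SynthSpec, species_frequency_traits, synth_feature_table, synth_morphometrics
from songphylo.trees import example_tree

tree = example_tree()
spec = SynthSpec(syllables_per_species={s: 300 for s in tree.tip_names}, seed=11)
table = synth_feature_table(spec, tree)
scores = pca_fit(ripca_impute(table)).scores[["pc1", "pc2", "pc3"]].copy()
scores.insert(0, "species", table["species"].to_numpy())

mats = build_distance_matrices(scores, ["pc1", "pc2", "pc3"])
res = two_step_signal(mats, tree, n_perm=500, n_sim=500, seed=12)
print("two-step signal test on PC distance matrices:")
print(res[["mantel_p", "em_r", "em_q", "inertia", "significant"]].round(3).to_string())

sig = res.index[res["significant"]]
for pc in sig:
    em = em_mantel(mats[pc], tree, n_sim=500, seed=13)
    print(f"\n{pc}: EM-Mantel r = {em.r:.2f}, p = {em.p:.3f}, "
          f"phylogenetic inertia = {inertia_percent(em.r)}%")

# phylogenetically permuted Mantel against morphometric distances
traits = species_frequency_traits(spec, tree, np.random.default_rng(14))
morpho = synth_morphometrics(tree, traits, seed=15)
mass = morpho["mass_g"].to_numpy()
import pandas as pd
d_mass = pd.DataFrame(np.abs(mass[:, None] - mass[None, :]),
                      index=morpho.index, columns=morpho.index)
pp = pp_mantel(mats["pc1"], d_mass, tree, k_influence=1.0, n_perm=500, seed=16)
print(f"\nppMantel pc1 vs body-mass distances: r = {pp.r:.2f}, p = {pp.p:.3f}")

# dendrogram congruence: acoustic clustering vs the phylogeny
dendro_a = cluster_dendrogram(mats["pc1"])
dendro_t = cluster_dendrogram(tree.patristic_matrix())
fmi = fmi_test(dendro_a, dendro_t, k=3)
print(f"\nFMI at k=3 (acoustic vs phylogeny): {fmi.fmi:.2f} "
      f"(null expectation {fmi.expectation:.2f}, p = {fmi.p:.3f})")
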