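"""Rank features by their ability to predict screen recovery.

Each feature gets its own ridge-stabilized logistic regression, evaluated
by ROC-AUC under stratified 5-fold cross-validation with within-fold
standardization.
"""

import binderqc as b

cfg = b.SimConfig(seed=11)
designs, truth = b.generate_designs(cfg)
results = b.test_enrichment(b.simulate_screen(designs, cfg))
features = b.compute_feature_table(designs).set_index("design_id")

ranking = b.cv_feature_ranking(
    features.loc[results.index], results["recovered"].astype(int), k=5, seed=0
)
print(ranking.head(8)[["feature", "mean_auc", "n_pos", "n_neg"]].to_string(index=False))
# The K+E-helix ratio tops the ranking because the cohort plants it as the
# dropout mechanism; the correlated DNA-level signatures (A-dinucleotide
# repeats, nucleotide entropy) follow close behind, as they do in real
# design libraries dominated by fixed-backbone sequence models.
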