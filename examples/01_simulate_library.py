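"""Generate a small competition-like binder library and pooled-screen counts.

The generator plants four design categories — functional CD20-enriched
binders, neutral designs, heavily K/E-helical dropouts, and cysteine-rich
depleting designs — and simulates NB-distributed read counts for an input
sample plus three replicates of each co-culture condition.
"""

import binderqc as b

cfg = b.SimConfig(
    n_designs={
        "functional_enriched": 15,
        "neutral": 50,
        "mpnn_ke_dropout": 30,
        "cys_depleting": 5,
    },
    depth_per_replicate=300_000,
    seed=42,
)
designs, truth = b.generate_designs(cfg)
counts = b.simulate_screen(designs, cfg)

print(f"{len(designs)} designs, classes: {truth['design_class'].value_counts().to_dict()}")
d = designs[0]
print(f"example design {d.design_id} ({d.design_class}):")
print(f"  protein: {d.protein}")
print(f"  ss:      {d.ss}")
print(f"counts table: {counts.counts.shape[0]} designs x {list(counts.counts.columns)}")
print(f"reads per replicate: {counts.library_sizes.to_dict()}")
# Library sizes sit near the configured depth; dropout-class designs carry
# near-zero counts in the six screen replicates by construction.
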