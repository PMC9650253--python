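"""Generate a synthetic multiomics fish study with known ground truth.

Builds composition tables (muscle NMR regions, gut taxa), strain-
stratified phenotypes and ecology metadata for 120 fish with three
planted metabolite clusters, then writes everything to CSV.
"""

from omnirule import SynthConfig, generate_dataset, write_dataset

config = SynthConfig(n_samples=120, k_clusters=3, seed=7)
ds = generate_dataset(config)

print("NMR table (features x samples):", ds.nmr.shape)
print("taxa table:", ds.taxa.shape)
print("phenotypes:", list(ds.phenotypes.columns))
print("metadata columns:", list(ds.metadata.columns))
print("planted cluster sizes:", ds.truth.cluster_labels.value_counts().to_dict())
print("discriminative NMR features:", ds.truth.discriminative_features["nmr"][:5], "...")

paths = write_dataset(ds, "scratch/example_dataset")
print(f"wrote {len(paths)} files to scratch/example_dataset/")
# The cluster sizes are deliberately unbalanced (like real cohorts);
# the listed features are the ones downstream methods should rediscover.
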