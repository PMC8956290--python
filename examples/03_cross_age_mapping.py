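"""Supervised cross-age cluster correspondence (ARI / NCE / OF).

Trains gradient-boosted classifiers on each older age and assigns its labels
to the preceding age's cells, then summarizes each confusion table with the
adjusted Rand index (1 = one-to-one), the normalized conditional entropy
(0 = fully specific), and the per-label occupancy fraction.
"""

import warnings

warnings.filterwarnings("ignore")

import numpy as np

from rgcfate import pipeline, synthdata, xmap
from rgcfate.benchmarks import desk_config

truth, counts = synthdata.simulate_dataset(
    n_types=10, n_subclasses=3, n_cells_per_age=400, n_genes=700, seed=2
)
config = desk_config()
_, em, hvg = pipeline.preprocess_stage(counts, config)
hvg_em, _, partitions = pipeline.cluster_stage(em, hvg, config, seed=0)
mapping = pipeline.xmap_stage(hvg_em, partitions, config, seed=0)

print(mapping[["test_age", "ref_age", "ari", "nce"]].round(3).to_string(index=False))
last = mapping.iloc[-1]["table"]
of = [xmap.occupancy_fraction(last, i) for i in range(last.N.shape[0])]
print(f"\noccupancy fractions of the last mapping: mean {np.mean(of):.2f} "
      f"(1/t = {1 / last.N.shape[1]:.2f} would be perfectly localized)")
print(
    "\nEarly mappings are diffuse (high NCE, low ARI) because early clusters"
    "\ncut a maturation continuum; correspondence sharpens as types emerge."
)
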