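"""Marginal ancestral reconstruction and recovery against ground truth.

Reconstructs every internal node of a simulated family on its true tree
and compares the root's MAP (maximum-a-posteriori) sequence with the
simulator's recorded root. Because gaps are treated as missing data, the
reconstruction covers every alignment column; the per-site maximum
posterior quantifies how confident each reconstructed residue is.
"""

import numpy as np

from lipevol import (
    SimulationConfig,
    build_wag_model,
    reconstruct_all,
    simulate_family,
)
from lipevol.io_core import GAP

family = simulate_family(SimulationConfig(n_leaves=8, seed=11))
model = build_wag_model("empirical_plus_F", family.true_alignment)
recs, posteriors = reconstruct_all(
    family.true_tree, family.true_alignment, model
)

root = family.root_label
truth = family.aligned_ancestors[root]
map_seq = recs[root].map_sequence
cols = [j for j, ch in enumerate(truth) if ch != GAP]
accuracy = np.mean([map_seq[j] == truth[j] for j in cols])

print(f"internal nodes reconstructed: {sorted(recs)}")
print(f"root node label: {root}")
print(f"root MAP accuracy vs simulated truth: {accuracy:.3f} "
      f"({len(cols)} residue-bearing columns)")
conf = recs[root].max_posterior
print(f"mean max-posterior at root: {conf.mean():.3f}")
lid = family.true_lid_columns
print(f"  over lid columns:     {conf[lid].mean():.3f}")
nonlid = [j for j in range(len(truth)) if j not in set(lid)]
print(f"  over non-lid columns: {conf[nonlid].mean():.3f}")
print("(the hypervariable lid reconstructs with visibly lower "
      "confidence — the signal the trimming step consumes)")
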