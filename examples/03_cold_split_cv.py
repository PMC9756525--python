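"""Build leakage-free cold-split cross-validation folds.

Compounds and proteins are single-linkage clustered at a distance
threshold; folds then keep whole clusters together, so test compounds
(new-compound), test proteins (new-protein) or both (both-new, a 3x3
grid giving 9 folds) are unseen during training.
"""

import warnings

warnings.filterwarnings("ignore", message=".*embedding width.*")

from cpinet import FixtureSpec, gen_dataset_in_memory, make_folds
from cpinet.cv import audit_fold_assignment

spec = FixtureSpec(n_pairs=60, d0=8, seed=11)
records, proteins, _ = gen_dataset_in_memory(spec)
sequences = {pid: e.sequence for pid, e in proteins.items()}

for setting in ("new_compound", "new_protein", "both_new"):
    fa = make_folds(records, sequences, setting, threshold=0.4, seed=1)
    comparisons = audit_fold_assignment(fa, records)  # raises on leakage
    sizes = [len(fa.train_test(f)[1]) for f in range(fa.n_folds)]
    print(f"{setting:13s}: {fa.n_folds} folds, test sizes {sizes}, "
          f"{len(set(fa.compound_cluster.values()))} compound / "
          f"{len(set(fa.protein_cluster.values()))} protein clusters, "
          f"audit passed ({comparisons} comparisons)")
# A fold's test pairs never share a compound (and/or protein) cluster
# with its training pairs; both_new discards same-row/column grid cells.
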