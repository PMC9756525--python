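"""Generate a synthetic compound-protein interaction dataset.

Writes the four dataset files (pairs.tsv, proteins.fasta, embeddings.h5,
sites.tsv) plus a manifest, then reads them back and prints summary
counts.  The generator plants a hidden rule — heteroatoms contact
residues of one hidden embedding class — so the data is learnable, and
affinities follow a*log(1 + contacts) + b with noise.
"""

from cpinet import (FixtureSpec, gen_dataset, read_pairs_table,
                    read_protein_store, read_site_labels)

spec = FixtureSpec(n_pairs=20, seed=1)
paths = gen_dataset(spec, "example_data")

records = read_pairs_table(paths["pairs"])
proteins = read_protein_store(paths["fasta"], paths["embeddings"])
sites = read_site_labels(paths["sites"])

n_labeled = sum(r.affinity is not None for r in records)
n_contacts = sum(len(s) for s in sites.values())
print(f"pairs:            {len(records)} ({n_labeled} with affinity labels)")
print(f"proteins:         {len(proteins)} "
      f"(lengths {min(len(p.sequence) for p in proteins.values())}-"
      f"{max(len(p.sequence) for p in proteins.values())}, "
      f"embeddings {next(iter(proteins.values())).embedding.shape[1]}-dim)")
print(f"planted contacts: {n_contacts} across {len(sites)} pairs")
# Each contact is one (atom index, residue index) cell of the pair's
# interaction matrix; affinities sit on the -log10 Ki/Kd scale.
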