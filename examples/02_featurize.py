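"""Compute the five molecular representations for one molecule.

Each base model of the ensemble reads one of these views; all are pure
functions of the canonical SMILES (plus state fitted on training data).
"""

import numpy as np

from hergstack import featurize as fz

smiles_corpus = ["CCO", "c1ccccc1", "CC(=O)Nc1ccc(O)cc1", "Clc1ccc(CN2CCCC2)cc1"]
query = "CC(=O)Nc1ccc(O)cc1"  # paracetamol

raw = np.stack([fz.compute_raw_descriptors(s) for s in smiles_corpus])
normalizer = fz.fit_descriptor_normalizer(raw)
vocab = fz.build_token_vocabulary(smiles_corpus)

desc = fz.compute_descriptor_vector(query, normalizer)
graph = fz.featurize_graph(query)
bits = fz.compute_combined_fingerprints(query)
tokens = fz.encode_smiles_tokens(query, vocab)
fp_idx = fz.compute_fp_index_vector(query)

print(f"descriptors: shape {desc.shape}, range [{desc.min():.2f}, {desc.max():.2f}]")
print(f"graph: nodes {graph.nodes.shape}, adjacency {graph.adjacency.shape}, "
      f"{graph.n_atoms} heavy atoms")
print(f"combined fingerprint: {bits.shape[0]} bits, {int(bits.sum())} set")
print(f"token sequence: length {tokens.shape[0]}, "
      f"{int((tokens > 0).sum())} non-pad tokens")
print(f"fingerprint indices: length {fp_idx.shape[0]}, "
      f"{int((fp_idx > 0).sum())} on bits")
# Shapes are fixed contracts: (D,), (50,65)+(50,50), (1905,), (97,), (93,).
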