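"""Build molecular-network edges from pairwise similarity scores.

Scores all spectrum pairs of a small synthetic library with a quickly
trained model, filters edges (score > 0.6, top-10 per node, families capped
at 100 nodes) and prints the resulting compound families. Analog families
of the generator should reappear as connected components.
"""

import itertools

import numpy as np
import networkx as nx

import transexion as tx
from transexion.model import predict_batch
from transexion.search_eval import network_edges
from transexion.training import PairSamplingConfig, SpectrumLibrary, TrainConfig, _EncodingCache, train

lib = tx.generate_library(n_molecules=40, seed=0)
cfg = tx.ModelConfig(embed_dim=8, heads_per_block=(50, 10), hidden_dim=64,
                     tx_ffn_dim=128, seed=0)
model = tx.init_model(cfg)
model, _ = train(
    model,
    SpectrumLibrary.from_synthetic(lib, "train"),
    TrainConfig(seed=0, max_epochs=60, patience=60),
    PairSamplingConfig(seed=0),
    validation=SpectrumLibrary.from_synthetic(lib, "validation"),
)

spectra = lib.spectra
cache = _EncodingCache(spectra)
scores = {}
batch_keys, batch_encs = [], []
for a, b in itertools.permutations(spectra, 2):
    batch_keys.append((a.spectrum_id, b.spectrum_id))
    batch_encs.append(cache.get(a.spectrum_id, b.spectrum_id))
preds = np.concatenate(
    [predict_batch(model, batch_encs[i : i + 256]) for i in range(0, len(batch_encs), 256)]
)
scores = dict(zip(batch_keys, preds.astype(float)))

edges = network_edges(scores, threshold=0.6, top_k_per_node=10, max_family_size=100)
print(f"{len(edges)} edges above threshold 0.6")

g = nx.Graph()
g.add_nodes_from(s.spectrum_id for s in spectra)
g.add_weighted_edges_from(edges)
families = [sorted(c) for c in nx.connected_components(g) if len(c) > 1]
print(f"{len(families)} molecular families:")
for fam in families:
    print("  ", fam)
# each family groups spectra the model scores as structural analogs; with
# the synthetic generator these should align with its analog families
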