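"""Estimate a sparse co-expression graph by neighborhood selection.

Simulates 20 genes from a chain-structured precision matrix (each gene
partially correlated 0.3 with its neighbors), runs the lasso
neighborhood path and picks the penalty by stability selection (StARS),
then compares the recovered edges with the generative chain.
"""

import numpy as np

import cismediator as cm
from cismediator.synthdata import make_precision_matrix, sample_background

omega, true_edges = make_precision_matrix(20, structure="chain", magnitude=0.3)
X = sample_background(500, omega, np.random.default_rng(0))

path = cm.neighborhood_selection_path(X)
print(f"penalty grid: {path.lambdas[0]:.3f} .. {path.lambdas[-1]:.3f} "
      f"({len(path.lambdas)} log-spaced values)")
print(f"edges along the path: {[len(e) for e in path.edge_sets]}")

graph = cm.select_graph(path, seed=0)
true = {tuple(sorted(e)) for e in true_edges}
est = graph.edges
tp = len(est & true)
print(f"\nStARS-selected penalty: {graph.selected_lambda:.3f}")
print(f"estimated edges: {len(est)}, true edges: {len(true)}, overlap: {tp}")
print(f"precision {tp / len(est):.2f}, recall {tp / len(true):.2f}")
print("each edge means the two genes are partially correlated given all "
      "other genes; gene 0's neighbors:", sorted(cm.neighbors(graph, 0)))
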