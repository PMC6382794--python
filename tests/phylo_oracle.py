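"""Shared oracle: direct numeric minimization of the squared-change criterion."""

import numpy as np
from scipy.optimize import minimize


def numeric_tree_length(tree, tip_values, weighted=True):
    """Oracle: direct numeric minimization over internal-node values."""
    tips = {}
    internals = []
    edges = []
    index = {}
    for node in tree.preorder_node_iter():
        if node.is_leaf():
            index[id(node)] = ("tip", node.taxon.label)
        else:
            index[id(node)] = ("int", len(internals))
            internals.append(node)
    for node in tree.preorder_node_iter():
        if node.parent_node is None:
            continue
        w = 1.0 / node.edge.length if weighted else 1.0
        edges.append((index[id(node)], index[id(node.parent_node)], w))
    dim = np.atleast_1d(next(iter(tip_values.values()))).shape[0]

    def objective(flat):
        anc = flat.reshape(len(internals), dim)
        total = 0.0
        for (ka, va), (kb, vb), w in edges:
            xa = np.atleast_1d(tip_values[va]) if ka == "tip" else anc[va]
            xb = np.atleast_1d(tip_values[vb]) if kb == "tip" else anc[vb]
            total += w * float(np.sum((xa - xb) ** 2))
        return total

    x0 = np.zeros(len(internals) * dim)
    res = minimize(objective, x0, method="L-BFGS-B", tol=1e-14,
                   options={"maxiter": 10_000, "ftol": 1e-16, "gtol": 1e-12})
    return res.fun
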