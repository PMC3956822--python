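"""Independent reference implementations used only to check the package.

These deliberately take the slow, textbook route (explicit matrix inverses,
Felsenstein's recursive contrasts) so they share no code path with the
implementations they verify.
"""

import numpy as np


def dense_gls_loglik(y, X, V):
    """Profiled GLS log-likelihood via explicit inverse and determinant."""
    n = len(y)
    Vi = np.linalg.inv(V)
    beta = np.linalg.solve(X.T @ Vi @ X, X.T @ Vi @ y)
    r = y - X @ beta
    s2 = (r @ Vi @ r) / n
    _, logdet = np.linalg.slogdet(V)
    return -0.5 * (n * np.log(2 * np.pi * s2) + n + logdet)


def independent_contrasts(phylogeny, values):
    """Felsenstein's phylogenetically independent contrasts.

    ``values`` maps tip label -> trait value; returns the standardized
    contrasts in postorder.  Tree must be bifurcating with positive branch
    lengths.
    """
    t = phylogeny._tree.clone(depth=1)
    contrasts = []
    for nd in t.postorder_node_iter():
        if nd.is_leaf():
            nd.val = values[nd.taxon.label]
            nd.blen = nd.edge.length or 0.0
            continue
        c1, c2 = nd.child_nodes()
        v1, v2 = c1.blen, c2.blen
        contrasts.append((c1.val - c2.val) / np.sqrt(v1 + v2))
        nd.val = (c1.val / v1 + c2.val / v2) / (1.0 / v1 + 1.0 / v2)
        nd.blen = (nd.edge.length or 0.0) + v1 * v2 / (v1 + v2)
    return np.array(contrasts)


def pic_regression_slope(phylogeny, x_values, y_values):
    """Regression-through-origin slope of y-contrasts on x-contrasts."""
    cx = independent_contrasts(phylogeny, x_values)
    cy = independent_contrasts(phylogeny, y_values)
    return float(cx @ cy / (cx @ cx))
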