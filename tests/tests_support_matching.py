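"""Brute-force maximum bipartite matching oracle shared by matching tests."""

import numpy as np

from hfokit import overlap_ratio


def brute_force_max_matching(a_iv, b_iv, threshold):
    """Maximum one-to-one matching size via Hopcroft-Karp (scipy)."""
    from scipy.sparse import csr_matrix
    from scipy.sparse.csgraph import maximum_bipartite_matching
    rows, cols = [], []
    for i, ia in enumerate(a_iv):
        for j, jb in enumerate(b_iv):
            if overlap_ratio(ia, jb) >= threshold:
                rows.append(i)
                cols.append(j)
    if not rows:
        return 0
    graph = csr_matrix((np.ones(len(rows)), (rows, cols)),
                       shape=(len(a_iv), len(b_iv)))
    match = maximum_bipartite_matching(graph, perm_type="column")
    return int((match >= 0).sum())
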