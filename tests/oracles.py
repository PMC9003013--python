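"""Independent brute-force reference implementations used only by tests."""

import itertools

import numpy as np


def msc_reference(x, y, fs, band_low, band_high, seg_len=1.0, overlap=0.5,
                  taper="hann"):
    """Band-averaged magnitude squared coherence via explicit per-segment DFTs.

    Deliberately naive: loops over segments and frequencies, builds the DFT
    matrix by hand, averages periodograms explicitly.
    """
    n = len(x)
    nperseg = int(round(seg_len * fs))
    step = int(round(nperseg * (1 - overlap)))
    if taper == "hann":
        w = 0.5 - 0.5 * np.cos(2 * np.pi * np.arange(nperseg) / nperseg)
    else:
        raise ValueError(taper)
    k = np.arange(nperseg // 2 + 1)
    dft = np.exp(-2j * np.pi * np.outer(k, np.arange(nperseg)) / nperseg)
    sxx = np.zeros(len(k))
    syy = np.zeros(len(k))
    sxy = np.zeros(len(k), dtype=complex)
    n_seg = 0
    start = 0
    while start + nperseg <= n:
        xs = x[start:start + nperseg]
        ys = y[start:start + nperseg]
        xs = (xs - xs.mean()) * w
        ys = (ys - ys.mean()) * w
        X = dft @ xs
        Y = dft @ ys
        sxx += np.abs(X) ** 2
        syy += np.abs(Y) ** 2
        sxy += np.conj(X) * Y
        n_seg += 1
        start += step
    sxx /= n_seg
    syy /= n_seg
    sxy /= n_seg
    freqs = k * fs / nperseg
    sel = (freqs >= band_low - 1e-9) & (freqs <= band_high + 1e-9)
    coh = np.abs(sxy[sel]) ** 2 / (sxx[sel] * syy[sel])
    return float(np.mean(coh))


def all_pairs_hop_and_weighted(weights):
    """Exhaustive shortest paths by enumerating all simple paths.

    Only feasible for tiny graphs (<= ~7 nodes).  Returns (hop_dist, w_dist)
    matrices with np.inf for unreachable pairs.
    """
    n = weights.shape[0]
    hop = np.full((n, n), np.inf)
    wd = np.full((n, n), np.inf)
    np.fill_diagonal(hop, 0.0)
    np.fill_diagonal(wd, 0.0)
    nodes = list(range(n))
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            inner = [v for v in nodes if v not in (i, j)]
            for r in range(len(inner) + 1):
                for mid in itertools.permutations(inner, r):
                    path = (i,) + mid + (j,)
                    ok = all(weights[a, b] > 0 for a, b in zip(path, path[1:]))
                    if not ok:
                        continue
                    hop[i, j] = min(hop[i, j], len(path) - 1)
                    wd[i, j] = min(wd[i, j],
                                   sum(weights[a, b] for a, b in
                                       zip(path, path[1:])))
    return hop, wd


def disconnect_grid_oracle(weights, step=0.01):
    """Test every grid proportion independently (no incremental state)."""
    import networkx as nx
    from fractions import Fraction

    n = weights.shape[0]
    edges = []
    for i in range(n):
        for j in range(i + 1, n):
            if weights[i, j] > 0:
                edges.append((weights[i, j], i, j))
    edges.sort()
    grid = round(1 / step)
    for k in range(grid + 1):
        n_remove = int(Fraction(k, grid) * len(edges))  # floor via int()
        g = nx.Graph()
        g.add_nodes_from(range(n))
        for w, i, j in edges[n_remove:]:
            g.add_edge(i, j)
        if g.number_of_edges() == 0 or not nx.is_connected(g):
            if k == 0:
                raise ValueError("disconnected at zero removal")
            return k / grid
    return 1.0
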