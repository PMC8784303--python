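"""Independent brute-force oracles used to cross-check the implementation.

Everything here is deliberately naive (explicit loops, textbook formulas)
and shares no code with the package internals it checks.
"""

from __future__ import annotations

import math
from collections import deque

import numpy as np


def pearson_two_pass(x, y) -> float:
    """Textbook two-pass Pearson correlation of two 1-D sequences."""
    x = [float(v) for v in x]
    y = [float(v) for v in y]
    n = len(x)
    mx = sum(x) / n
    my = sum(y) / n
    cov = sum((a - mx) * (b - my) for a, b in zip(x, y))
    vx = sum((a - mx) ** 2 for a in x)
    vy = sum((b - my) ** 2 for b in y)
    if vx == 0 or vy == 0:
        return 0.0
    return cov / math.sqrt(vx * vy)


def paired_t_flat(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Paired t over axis 0, computed sample-by-sample on flattened data."""
    a2 = a.reshape(a.shape[0], -1)
    b2 = b.reshape(b.shape[0], -1)
    out = np.empty(a2.shape[1])
    n = a2.shape[0]
    for j in range(a2.shape[1]):
        d = a2[:, j] - b2[:, j]
        m = d.mean()
        sd = d.std(ddof=1)
        out[j] = 0.0 if sd == 0 else m / (sd / math.sqrt(n))
    return out.reshape(a.shape[1:])


def one_sample_t_flat(a: np.ndarray) -> np.ndarray:
    return paired_t_flat(a, np.zeros_like(a))


def bfs_clusters(mask: np.ndarray, values: np.ndarray, channel_pairs) -> set:
    """Exhaustive BFS connected-component labeling of a (channel, T, T)
    boolean volume.

    Connectivity: one step in t1 OR t2 within a channel (no diagonals), or
    the same (t1, t2) in channels joined by ``channel_pairs``. Returns a
    set of (frozenset of cells, rounded mass) per component.
    """
    neighbors = {}
    for i, j in channel_pairs:
        neighbors.setdefault(i, set()).add(j)
        neighbors.setdefault(j, set()).add(i)
    seen = np.zeros(mask.shape, dtype=bool)
    comps = set()
    n_ch, T1, T2 = mask.shape
    for start in zip(*np.nonzero(mask)):
        if seen[start]:
            continue
        comp = []
        q = deque([start])
        seen[start] = True
        while q:
            c, i, j = q.popleft()
            comp.append((c, i, j))
            cand = [(c, i - 1, j), (c, i + 1, j), (c, i, j - 1), (c, i, j + 1)]
            cand += [(d, i, j) for d in neighbors.get(c, ())]
            for cell in cand:
                d, a, b = cell
                if 0 <= a < T1 and 0 <= b < T2 and mask[cell] and not seen[cell]:
                    seen[cell] = True
                    q.append(cell)
        mass = sum(values[cell] for cell in comp)
        comps.add((frozenset(comp), round(mass, 9)))
    return comps


def exhaustive_sign_flip_p(maps: np.ndarray, threshold: float, channel_pairs) -> dict:
    """Exact sign-flip permutation p-values by full 2^n enumeration.

    For every sign assignment, recompute the one-sample t-map, label
    clusters with :func:`bfs_clusters`, and record the extreme masses.
    Returns observed positive/negative cluster masses with their exact
    p-values (fraction of assignments with an extreme mass at least as
    large, the identity assignment included).
    """
    n = maps.shape[0]
    max_pos, min_neg = [], []
    for k in range(2 ** n):
        signs = np.array([1.0 if (k >> b) & 1 else -1.0 for b in range(n)])
        t = one_sample_t_flat(signs[:, None, None, None] * maps)
        pos = bfs_clusters(t > threshold, t, channel_pairs)
        neg = bfs_clusters(t < -threshold, t, channel_pairs)
        max_pos.append(max((m for _, m in pos), default=0.0))
        min_neg.append(min((m for _, m in neg), default=0.0))
    max_pos = np.array(max_pos)
    min_neg = np.array(min_neg)
    t_obs = one_sample_t_flat(maps)
    obs_pos = sorted(m for _, m in bfs_clusters(t_obs > threshold, t_obs, channel_pairs))
    obs_neg = sorted(m for _, m in bfs_clusters(t_obs < -threshold, t_obs, channel_pairs))
    return {
        "p_pos": {m: float(np.mean(max_pos >= m)) for m in obs_pos},
        "p_neg": {m: float(np.mean(min_neg <= m)) for m in obs_neg},
    }
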