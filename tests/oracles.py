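"""Independent brute-force oracles for the null-model statistics.

Everything here is written as plain loops over taxa, deliberately sharing
no code with the package implementation, so the two can be compared on
small inputs.
"""

import math

import numpy as np


def mpd_naive(abund, D, weighted):
    idx = [i for i, a in enumerate(abund) if a > 0]
    if len(idx) < 2:
        return float("nan")
    num = den = 0.0
    for i in idx:
        for j in idx:
            if i == j:
                continue
            w = abund[i] * abund[j] if weighted else 1.0
            num += w * D[i][j]
            den += w
    return num / den


def mntd_naive(abund, D, weighted):
    idx = [i for i, a in enumerate(abund) if a > 0]
    if len(idx) < 2:
        return float("nan")
    num = den = 0.0
    for i in idx:
        nearest = min(D[i][j] for j in idx if j != i)
        w = abund[i] if weighted else 1.0
        num += w * nearest
        den += w
    return num / den


def beta_mntd_naive(a, b, D, weighted):
    ia = [i for i, x in enumerate(a) if x > 0]
    ib = [i for i, x in enumerate(b) if x > 0]
    if not ia or not ib:
        return float("nan")

    def directional(src_idx, src_ab, dst_idx):
        num = den = 0.0
        for i in src_idx:
            nearest = min(D[i][j] for j in dst_idx)
            w = src_ab[i] if weighted else 1.0
            num += w * nearest
            den += w
        return num / den

    return 0.5 * (directional(ia, a, ib) + directional(ib, b, ia))


def patristic_naive(tree):
    """Tip-to-tip distances via root paths: d = depth_i + depth_j - 2*depth(MRCA)."""
    tips = list(tree.tips())
    paths = {}
    for tip in tips:
        path = []
        node = tip
        while node.parent is not None:
            path.append(node)
            node = node.parent
        paths[tip.name] = list(reversed(path))  # root-side first
    names = [t.name for t in tips]
    depth = {n: sum(nd.length for nd in paths[n]) for n in names}
    out = {}
    for x in names:
        for y in names:
            shared = 0.0
            for nx, ny in zip(paths[x], paths[y]):
                if nx is ny:
                    shared += nx.length
                else:
                    break
            out[(x, y)] = depth[x] + depth[y] - 2.0 * shared
    return names, out


def ses_naive(abund, D, metric, weighted, n_iter, rng):
    """SES with the literal shuffled-matrix loop, same permutation stream."""
    fn = mpd_naive if metric == "mpd" else mntd_naive
    T = len(D)
    obs = fn(abund, D, weighted)
    nulls = []
    for _ in range(n_iter):
        perm = rng.permutation(T)
        Dp = [[D[perm[i]][perm[j]] for j in range(T)] for i in range(T)]
        nulls.append(fn(abund, Dp, weighted))
    mean = float(np.mean(nulls))
    sd = float(np.std(nulls, ddof=1))
    return obs, mean, sd, (obs - mean) / sd


def beta_nti_naive(A, D, n_iter, rng, weighted=True):
    """Pairwise betaNTI with literal loops and a shared permutation stream."""
    S, T = len(A), len(D)
    obs = [[beta_mntd_naive(A[i], A[j], D, weighted) for j in range(S)]
           for i in range(S)]
    nulls = [[[] for _ in range(S)] for _ in range(S)]
    for _ in range(n_iter):
        perm = rng.permutation(T)
        Dp = [[D[perm[i]][perm[j]] for j in range(T)] for i in range(T)]
        for i in range(S):
            for j in range(i + 1, S):
                nulls[i][j].append(beta_mntd_naive(A[i], A[j], Dp, weighted))
    out = np.full((S, S), np.nan)
    for i in range(S):
        for j in range(i + 1, S):
            mean = float(np.mean(nulls[i][j]))
            sd = float(np.std(nulls[i][j], ddof=1))
            out[i, j] = out[j, i] = (obs[i][j] - mean) / sd
    return np.array(obs), out


def nonempty_subsets(n):
    for mask in range(1, 2 ** n):
        yield [1.0 if mask & (1 << i) else 0.0 for i in range(n)]
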