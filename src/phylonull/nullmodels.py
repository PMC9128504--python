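"""Phylogenetic and compositional null-model statistics.

This is the core of the package: abundance-weighted mean pairwise distance
(MPD) and mean nearest-taxon distance (MNTD) with their standardized effect
sizes (NRI/NTI), the between-sample nearest-taxon turnover betaMNTD and its
standardized effect size betaNTI, Bray-Curtis dissimilarity, and the
Bray-Curtis-based Raup-Crick metric RC_bray.

Null distributions follow the "taxa labels" scheme: taxon labels are
permuted uniformly at random across the pool's patristic distance matrix,
leaving the distance values unchanged as a multiset.  Nulls are built per
pool (one compartment x week group) with 999 randomizations by default, and
betaNTI uses one shared permutation stream per pool — every sample pair is
evaluated against the same shuffled matrix in a given iteration.

Sign conventions match common usage: NRI/NTI are the *negated* standardized
effect sizes of MPD/MNTD, so values > +2 indicate significantly more
phylogenetic clustering than expected by chance and values < -2 indicate
overdispersion.  betaNTI keeps the direct sign: (observed - null mean) /
null sd, so betaNTI > +2 flags more-than-random turnover.
"""

from __future__ import annotations

import warnings
import zlib
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import PatristicMatrix

DEFAULT_N_ITER = 999


def _as_array(dist) -> np.ndarray:
    if isinstance(dist, PatristicMatrix):
        return dist.data
    return np.asarray(dist, dtype=float)


def _weights(a: np.ndarray, weighted: bool) -> np.ndarray:
    """Per-taxon weights: relative abundance, or presence / richness."""
    if weighted:
        return a / a.sum()
    pres = (a > 0).astype(float)
    return pres / pres.sum()


# ---------------------------------------------------------------------------
# Alpha-scale metrics: MPD / MNTD


def mpd(abund, dist, weighted: bool = True) -> float:
    """Mean pairwise patristic distance among the taxa present in a sample.

    Unweighted: the mean of d(i, j) over unordered present pairs i != j.
    Weighted: sum_{i != j} a_i a_j d(i, j) / sum_{i != j} a_i a_j, i.e.
    abundance-product weighting with conspecific (diagonal) pairs excluded.
    Returns NaN when fewer than two taxa are present.
    """
    d = _as_array(dist)
    a = np.asarray(abund, dtype=float)
    present = a > 0
    if present.sum() < 2:
        return float("nan")
    if weighted:
        p = a / a.sum()
        num = p @ d @ p  # diagonal of d is zero
        den = 1.0 - (p ** 2).sum()
        return float(num / den)
    idx = np.flatnonzero(present)
    sub = d[np.ix_(idx, idx)]
    k = idx.size
    return float(sub.sum() / (k * (k - 1)))


def mntd(abund, dist, weighted: bool = True) -> float:
    """Mean distance from each present taxon to its nearest present relative.

    Weighted form weights each focal taxon's nearest-neighbor distance by
    that taxon's relative abundance.  NaN when fewer than two taxa present.
    """
    d = _as_array(dist)
    a = np.asarray(abund, dtype=float)
    idx = np.flatnonzero(a > 0)
    if idx.size < 2:
        return float("nan")
    sub = d[np.ix_(idx, idx)].copy()
    np.fill_diagonal(sub, np.inf)
    mins = sub.min(axis=1)
    w = _weights(a[idx], weighted)
    return float(w @ mins)


# ---------------------------------------------------------------------------
# Beta-scale metrics: betaMNTD / betaMPD / Bray-Curtis


def beta_mntd(abund_a, abund_b, dist, weighted: bool = True) -> float:
    """Between-sample nearest-taxon turnover (betaMNTD).

    For each taxon present in sample a, the patristic distance to its
    nearest taxon present in sample b (a taxon shared by both samples is
    its own nearest relative, at distance zero), and vice versa; the two
    directional (abundance-weighted) means are averaged, so the result is
    symmetric and betaMNTD(x, x) = 0.
    """
    d = _as_array(dist)
    a = np.asarray(abund_a, dtype=float)
    b = np.asarray(abund_b, dtype=float)
    ia, ib = np.flatnonzero(a > 0), np.flatnonzero(b > 0)
    if ia.size == 0 or ib.size == 0:
        return float("nan")
    cross = d[np.ix_(ia, ib)]
    wa = _weights(a[ia], weighted)
    wb = _weights(b[ib], weighted)
    return float(0.5 * (wa @ cross.min(axis=1) + wb @ cross.min(axis=0)))


def beta_mpd(abund_a, abund_b, dist, weighted: bool = True) -> float:
    """Between-sample mean pairwise distance (the ``comdist`` statistic)."""
    d = _as_array(dist)
    a = np.asarray(abund_a, dtype=float)
    b = np.asarray(abund_b, dtype=float)
    ia, ib = np.flatnonzero(a > 0), np.flatnonzero(b > 0)
    if ia.size == 0 or ib.size == 0:
        return float("nan")
    cross = d[np.ix_(ia, ib)]
    wa = _weights(a[ia], weighted)
    wb = _weights(b[ib], weighted)
    return float(wa @ cross @ wb)


def bray_curtis(abund_a, abund_b) -> float:
    """Bray-Curtis dissimilarity 1 - 2*sum(min(a, b)) / (sum a + sum b)."""
    a = np.asarray(abund_a, dtype=float)
    b = np.asarray(abund_b, dtype=float)
    tot = a.sum() + b.sum()
    if tot <= 0:
        raise ValueError("Bray-Curtis undefined for two all-zero samples")
    return float(1.0 - 2.0 * np.minimum(a, b).sum() / tot)


def bray_curtis_matrix(table: pd.DataFrame) -> pd.DataFrame:
    """All pairwise Bray-Curtis dissimilarities of a samples x taxa table."""
    vals = table.to_numpy(dtype=float)
    n = len(vals)
    out = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            out[i, j] = out[j, i] = bray_curtis(vals[i], vals[j])
    return pd.DataFrame(out, index=table.index, columns=table.index)


# ---------------------------------------------------------------------------
# Taxa-shuffle null


def taxa_shuffle(dist: PatristicMatrix, rng: np.random.Generator) -> PatristicMatrix:
    """Permute taxon labels uniformly at random across a distance matrix.

    The returned matrix carries the same taxa in the same order, but the
    distance structure is re-indexed by a uniform random permutation, so
    the multiset of distances is unchanged.
    """
    perm = rng.permutation(len(dist.taxa))
    return PatristicMatrix(dist.taxa, dist.data[np.ix_(perm, perm)])


def _null_permuted_abunds(a: np.ndarray, perm: np.ndarray) -> np.ndarray:
    # metric(a, D[perm][:, perm]) == metric(a[argsort(perm)], D): pushing the
    # label shuffle onto the abundance vector avoids copying the matrix.
    return a[..., np.argsort(perm)]


# ---------------------------------------------------------------------------
# Standardized effect sizes (NRI / NTI)


@dataclass(frozen=True)
class SESResult:
    """Standardized effect size of MPD or MNTD for one sample."""

    sample_id: str
    metric: str  # "mpd" or "mntd"
    observed: float
    null_mean: float
    null_sd: float
    ses: float
    index: float  # NRI (for mpd) or NTI (for mntd) = -ses
    n_iter: int


_METRICS = {"mpd": mpd, "mntd": mntd}


def ses_metric(abund, dist, metric: str = "mntd", weighted: bool = True,
               n_iter: int = DEFAULT_N_ITER, rng: np.random.Generator | None = None,
               sample_id: str = "") -> SESResult:
    """Standardized effect size of MPD/MNTD against the taxa-shuffle null.

    ses = (observed - null mean) / null sd over ``n_iter`` label shuffles
    of the distance matrix; the reported index negates it (NRI for MPD,
    NTI for MNTD) so that index > +2 means more phylogenetic clustering
    than expected.  A degenerate null (sd = 0) yields NaN with a warning,
    never +/-infinity.
    """
    if metric not in _METRICS:
        raise ValueError(f"metric must be one of {sorted(_METRICS)}")
    rng = np.random.default_rng(rng)
    d = _as_array(dist)
    a = np.asarray(abund, dtype=float)
    fn = _METRICS[metric]
    obs = fn(a, d, weighted)
    nulls = np.empty(n_iter)
    for k in range(n_iter):
        perm = rng.permutation(d.shape[0])
        nulls[k] = fn(_null_permuted_abunds(a, perm), d, weighted)
    return _make_ses(sample_id, metric, obs, nulls, n_iter)


def _make_ses(sample_id, metric, obs, nulls, n_iter) -> SESResult:
    mean = float(np.mean(nulls))
    sd = float(np.std(nulls, ddof=1))
    if not np.isfinite(obs) or sd == 0 or not np.isfinite(sd):
        if np.isfinite(obs) and sd == 0:
            warnings.warn(f"degenerate null (sd = 0) for {sample_id!r} {metric}")
        ses = float("nan")
    else:
        ses = (obs - mean) / sd
    return SESResult(sample_id, metric, float(obs), mean, sd, ses, -ses, n_iter)


def ses_pool(table: pd.DataFrame, dist: PatristicMatrix, metric: str = "mntd",
             weighted: bool = True, n_iter: int = DEFAULT_N_ITER,
             rng: np.random.Generator | None = None) -> pd.DataFrame:
    """Per-sample SES for every sample of one null pool.

    All samples share the pool's permutation stream: each iteration draws
    one label shuffle and evaluates every sample against it, matching the
    weekly-per-compartment pooling of the null distributions.
    """
    _check_aligned(table, dist)
    rng = np.random.default_rng(rng)
    d = dist.data
    A = table.to_numpy(dtype=float)
    fn = _METRICS[metric]
    obs = np.array([fn(a, d, weighted) for a in A])
    nulls = np.empty((n_iter, len(A)))
    for k in range(n_iter):
        perm = rng.permutation(d.shape[0])
        Ak = _null_permuted_abunds(A, perm)
        nulls[k] = [fn(a, d, weighted) for a in Ak]
    rows = [_make_ses(sid, metric, obs[i], nulls[:, i], n_iter)
            for i, sid in enumerate(table.index)]
    return pd.DataFrame([r.__dict__ for r in rows]).set_index("sample_id",
                                                              drop=False)


# ---------------------------------------------------------------------------
# betaNTI


def _beta_matrix(A: np.ndarray, d: np.ndarray, weighted: bool,
                 beta_metric: str) -> np.ndarray:
    """All pairwise betaMNTD (or betaMPD) values of an abundance matrix."""
    S, T = A.shape
    masks = A > 0
    if not masks.any(axis=1).all():
        raise ValueError("empty sample in pool")
    if weighted:
        W = A / A.sum(axis=1, keepdims=True)
    else:
        W = masks / masks.sum(axis=1, keepdims=True)
    if beta_metric == "bmpd":
        M = W @ d @ W.T
        return 0.5 * (M + M.T)
    # nearest-taxon: dmin[t, s] = distance from taxon t to its nearest taxon
    # present in sample s (zero if t itself is present in s)
    dmin = np.empty((T, S))
    for s in range(S):
        dmin[:, s] = d[:, masks[s]].min(axis=1)
    M = W @ dmin
    return 0.5 * (M + M.T)


def beta_nti_matrix(table: pd.DataFrame, dist: PatristicMatrix,
                    weighted: bool = True, n_iter: int = DEFAULT_N_ITER,
                    rng: np.random.Generator | None = None,
                    beta_metric: str = "bmntd"
                    ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Observed betaMNTD and betaNTI for all sample pairs of one pool.

    betaNTI(a, b) = (betaMNTD_obs - mean_null betaMNTD) / sd_null betaMNTD,
    with nulls from label shuffles of the pool's distance matrix.  One
    shared permutation stream per pool: in each of the ``n_iter``
    iterations a single shuffled matrix is used for every pair.  A pair
    with null sd = 0 yields NaN with a warning.

    Returns (betaMNTD observed, betaNTI) as symmetric sample x sample
    DataFrames (betaNTI diagonal is NaN).
    """
    if beta_metric not in ("bmntd", "bmpd"):
        raise ValueError("beta_metric must be 'bmntd' or 'bmpd'")
    _check_aligned(table, dist)
    if len(table) < 2:
        raise ValueError("pool needs at least two samples")
    rng = np.random.default_rng(rng)
    d = dist.data
    A = table.to_numpy(dtype=float)
    obs = _beta_matrix(A, d, weighted, beta_metric)
    S = len(A)
    acc = np.zeros((S, S))
    acc2 = np.zeros((S, S))
    for _ in range(n_iter):
        perm = rng.permutation(d.shape[0])
        nk = _beta_matrix(_null_permuted_abunds(A, perm), d, weighted, beta_metric)
        acc += nk
        acc2 += nk * nk
    mean = acc / n_iter
    var = (acc2 - n_iter * mean * mean) / (n_iter - 1)
    sd = np.sqrt(np.maximum(var, 0.0))
    with np.errstate(invalid="ignore", divide="ignore"):
        bnti = (obs - mean) / sd
    off = ~np.eye(S, dtype=bool)
    if (sd[off] == 0).any():
        warnings.warn("degenerate null (sd = 0) for some sample pairs; "
                      "betaNTI set to NaN there")
        bnti[(sd == 0) & off] = np.nan
    np.fill_diagonal(bnti, np.nan)
    ids = table.index
    return (pd.DataFrame(obs, index=ids, columns=ids),
            pd.DataFrame(bnti, index=ids, columns=ids))


# ---------------------------------------------------------------------------
# RC_bray


def discretize_counts(table: pd.DataFrame, floor: int = 1000) -> pd.DataFrame:
    """Rescale a non-integer table to integer counts for RC_bray.

    All samples are multiplied by one common factor chosen so that the
    smallest sample total reaches ``floor`` individuals, then rounded.
    Integer tables whose smallest total already meets the floor are
    returned unchanged.
    """
    vals = table.to_numpy(dtype=float)
    totals = vals.sum(axis=1)
    if (totals <= 0).any():
        raise ValueError("zero-total sample cannot be discretized")
    if np.allclose(vals, np.round(vals)) and totals.min() >= floor:
        return table.round()
    factor = floor / totals.min()
    return (table * factor).round()


def raup_crick_bray(table: pd.DataFrame, n_iter: int = DEFAULT_N_ITER,
                    rng: np.random.Generator | None = None,
                    species_weight: str = "occupancy",
                    tie_tol: float = 1e-12) -> pd.DataFrame:
    """Bray-Curtis-based Raup-Crick (RC_bray) for all pairs of one pool.

    For each sample, ``n_iter`` null communities are simulated preserving
    the sample's observed richness and total abundance: species are drawn
    without replacement with probability proportional to their occupancy
    across the pool (``species_weight="occupancy"``, the default) or to
    occupancy times pool-wide relative abundance
    (``species_weight="occupancy_abundance"``); each drawn species receives
    one individual and the remaining individuals are allocated
    multinomially with probability proportional to pool-wide relative
    abundance.  Null pairs are formed iteration-wise across samples and

        RC = 2 * [ (#(null BC < obs BC) + 0.5 * #(null BC = obs BC)) / n_iter ] - 1

    so RC is in [-1, +1]: +1 means the pair is more dissimilar than the
    stochastic null predicts, -1 less dissimilar.  Requires integer counts
    (see :func:`discretize_counts` for spike-normalized tables).
    """
    if species_weight not in ("occupancy", "occupancy_abundance"):
        raise ValueError("species_weight must be 'occupancy' or "
                         "'occupancy_abundance'")
    rng = np.random.default_rng(rng)
    vals = table.to_numpy(dtype=float)
    if not np.allclose(vals, np.round(vals)):
        raise ValueError("RC_bray requires integer counts; use "
                         "discretize_counts() on normalized tables")
    counts = np.round(vals).astype(np.int64)
    if len(counts) < 2:
        raise ValueError("pool needs at least two samples")
    occupancy = (counts > 0).sum(axis=0).astype(float)
    in_pool = occupancy > 0
    if in_pool.sum() < 2:
        raise ValueError("degenerate pool: fewer than two taxa occur")
    # restrict to taxa occurring in the pool; absent taxa can never be drawn
    counts = counts[:, in_pool]
    occupancy = occupancy[in_pool]
    pool_rel = counts.sum(axis=0).astype(float)
    pool_rel /= pool_rel.sum()
    if species_weight == "occupancy":
        draw_p = occupancy / occupancy.sum()
    else:
        dw = occupancy * pool_rel
        draw_p = dw / dw.sum()

    S, T = counts.shape
    richness = (counts > 0).sum(axis=1)
    totals = counts.sum(axis=1)
    nulls = np.zeros((S, n_iter, T), dtype=np.int64)
    for s in range(S):
        for k in range(n_iter):
            species = rng.choice(T, size=richness[s], replace=False, p=draw_p)
            alloc_p = pool_rel[species]
            alloc = rng.multinomial(totals[s] - richness[s],
                                    alloc_p / alloc_p.sum())
            nulls[s, k, species] = 1 + alloc

    out = np.zeros((S, S))
    for i in range(S):
        for j in range(i + 1, S):
            obs_bc = bray_curtis(counts[i], counts[j])
            shared = np.minimum(nulls[i], nulls[j]).sum(axis=1)
            null_bc = 1.0 - 2.0 * shared / (totals[i] + totals[j])
            less = (null_bc < obs_bc - tie_tol).sum()
            ties = (np.abs(null_bc - obs_bc) <= tie_tol).sum()
            rc = 2.0 * ((less + 0.5 * ties) / n_iter) - 1.0
            out[i, j] = out[j, i] = rc
    ids = table.index
    return pd.DataFrame(out, index=ids, columns=ids)


# ---------------------------------------------------------------------------
# Null pools


@dataclass(frozen=True)
class NullPool:
    """One unit of null-model work: the samples of one design group.

    Each pool carries a deterministic RNG substream derived from the run
    seed and the group key, so results do not depend on the order in which
    pools are processed.
    """

    key: tuple
    sample_ids: tuple[str, ...]
    root_seed: int = 0
    group_keys: tuple[str, ...] = ("compartment", "week")

    def rng(self, stream: str) -> np.random.Generator:
        """Independent generator for one analysis stream of this pool."""
        entropy = [int(self.root_seed) & 0x7FFFFFFF,
                   zlib.crc32(stream.encode())]
        entropy += [zlib.crc32(str(k).encode()) for k in self.key]
        return np.random.default_rng(np.random.SeedSequence(entropy))


def build_pools(metadata: pd.DataFrame, group_keys=("compartment", "week"),
                seed: int = 0) -> list[NullPool]:
    """Partition samples into null pools by the given metadata keys."""
    pools = []
    for key, grp in metadata.groupby(list(group_keys), sort=True):
        key = key if isinstance(key, tuple) else (key,)
        pools.append(NullPool(tuple(key), tuple(grp.index), seed,
                              tuple(group_keys)))
    return pools


def _check_aligned(table: pd.DataFrame, dist: PatristicMatrix) -> None:
    if tuple(table.columns) != dist.taxa:
        raise ValueError("table columns must match distance-matrix taxa; "
                         "align the table to the tree first")
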