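"""Self-calibration experiments: the framework run against its own null.

When observed communities are themselves generated by the taxa-shuffle
randomization, the standardized effect sizes should be centred at zero with
unit spread, and the deterministic-selection call (|betaNTI| > 2) should
fire at about its nominal 5% two-tailed rate.  These routines build such
null-drawn pools and measure both properties; they are the package's
false-positive-rate audit.

The base community profile is even across a configurable number of taxa
(default 24 of 64): the |betaNTI| > 2 = 5% reading presumes an
approximately Gaussian null, which in turn needs enough effective taxa per
sample — a handful of hyper-dominant taxa makes the null betaMNTD skewed
and the two-tailed rate conservative.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .io import PatristicMatrix, patristic_distances
from .nullmodels import DEFAULT_N_ITER, beta_nti_matrix, ses_pool
from .simulate import simulate_tree


def null_community_pool(dist: PatristicMatrix, n_samples: int = 20,
                        n_individuals: int = 1000, richness: int = 24,
                        rng: np.random.Generator | None = None
                        ) -> pd.DataFrame:
    """Draw a pool of communities from the taxa-shuffle null itself.

    Each sample distributes ``n_individuals`` evenly over ``richness``
    taxa whose identities are assigned by an independent uniform
    permutation of the taxon labels — exactly the randomization the SES
    and betaNTI statistics standardize against, so every sample is one
    draw from its own null.
    """
    rng = np.random.default_rng(rng)
    T = len(dist.taxa)
    if not 2 <= richness <= T:
        raise ValueError("richness must be between 2 and the taxon count")
    profile = np.zeros(T)
    profile[:richness] = n_individuals / richness
    rows = [profile[np.argsort(rng.permutation(T))]
            for _ in range(n_samples)]
    return pd.DataFrame(rows, index=[f"S{i:02d}" for i in range(n_samples)],
                        columns=list(dist.taxa))


def selection_false_positive_rate(seed: int = 0, n_pools: int = 20,
                                  n_tips: int = 64, n_samples: int = 20,
                                  n_individuals: int = 1000,
                                  richness: int = 24,
                                  n_iter: int = DEFAULT_N_ITER,
                                  threshold: float = 2.0,
                                  pairs_per_pool: int | None = 50) -> dict:
    """Empirical |betaNTI| > threshold rate under the taxa-shuffle null.

    Simulates ``n_pools`` independent replicates (fresh Yule tree and
    null-drawn pool each) and pools pairwise betaNTI values across them.
    Pairs within a pool share samples, a tree and a permutation stream and
    are therefore correlated; by default only ``pairs_per_pool`` randomly
    chosen pairs per pool enter the estimate, spreading a fixed comparison
    budget over more independent replicates.  Returns the exceedance rate
    as a percentage together with the number of pairs and the mean/sd of
    the pooled values.
    """
    root = np.random.SeedSequence(int(seed) & 0x7FFFFFFF)
    values = []
    for pool_ss in root.spawn(n_pools):
        tree_rng, comm_rng, null_rng, pick_rng = (
            np.random.default_rng(s) for s in pool_ss.spawn(4))
        dist = patristic_distances(simulate_tree(n_tips, seed=tree_rng))
        table = null_community_pool(dist, n_samples, n_individuals,
                                    richness, comm_rng)
        _, bnti = beta_nti_matrix(table, dist, n_iter=n_iter, rng=null_rng)
        v = bnti.to_numpy()[np.triu_indices(n_samples, 1)]
        v = v[~np.isnan(v)]
        if pairs_per_pool is not None and pairs_per_pool < v.size:
            v = pick_rng.choice(v, size=pairs_per_pool, replace=False)
        values.append(v)
    v = np.concatenate(values)
    return {
        "rate_percent": float(100.0 * (np.abs(v) > threshold).mean()),
        "n_pairs": int(v.size),
        "mean": float(v.mean()),
        "sd": float(v.std(ddof=1)),
    }


def ses_self_calibration(seed: int = 0, n_replicates: int = 1000,
                         metric: str = "mntd", n_tips: int = 64,
                         pool_size: int = 50, n_individuals: int = 1000,
                         richness: int = 24,
                         n_iter: int = DEFAULT_N_ITER) -> dict:
    """Mean and sd of SES(MPD/MNTD) for null-drawn communities.

    Replicates are batched into pools of ``pool_size`` samples sharing a
    tree; a calibrated statistic has mean near 0 and sd near 1.
    """
    root = np.random.SeedSequence([int(seed) & 0x7FFFFFFF, 911])
    n_pools = int(np.ceil(n_replicates / pool_size))
    values = []
    for pool_ss in root.spawn(n_pools):
        tree_rng, comm_rng, null_rng = (np.random.default_rng(s)
                                        for s in pool_ss.spawn(3))
        dist = patristic_distances(simulate_tree(n_tips, seed=tree_rng))
        table = null_community_pool(dist, pool_size, n_individuals,
                                    richness, comm_rng)
        ses = ses_pool(table, dist, metric=metric, n_iter=n_iter,
                       rng=null_rng)
        values.append(ses["ses"].to_numpy())
    v = np.concatenate(values)[:n_replicates]
    return {"n": int(v.size), "mean": float(v.mean()),
            "sd": float(v.std(ddof=1))}
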