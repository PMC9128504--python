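"""Synthetic communities with known assembly regimes.

Generates everything the pipeline consumes — a Yule tree, Brownian-motion
traits on its tips, multinomial community samples assembled under
configurable selection/dispersal/drift regimes, and study-shaped metadata
(compartments x weeks x lines x blocks with an internal-standard spike
taxon) — so every stage is testable without any sequencing data.

Selection is operationalized as Gaussian environmental filtering on a
heritable trait: tip traits evolve by Brownian motion along the tree, and a
sample assembled under a narrow filter draws taxa whose traits sit near an
environmental optimum.  Because the trait is phylogenetically conserved,
filtered communities are phylogenetically clustered, which is exactly the
signal the nearest-taxon null-model statistics respond to.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass

import numpy as np
import pandas as pd
from skbio import TreeNode

from .io import COMPARTMENTS, write_feature_table, write_tsv
from .regime_params import REGIME_DEFAULTS, REGIMES

SPIKE_TAXON = "Aliivibrio_fischeri_spike"

# fixed phenology label map: weeks after planting -> BBCH growth stage
BBCH_BY_WEEK = {3: 14, 4: 30, 5: 50, 6: 60, 7: 65, 8: 69, 9: 71, 10: 75,
                11: 80, 12: 89}

NAM_LINES = tuple(f"NAM{i}" for i in range(1, 9))


def _rng(seed_or_rng) -> np.random.Generator:
    if isinstance(seed_or_rng, np.random.Generator):
        return seed_or_rng
    return np.random.default_rng(seed_or_rng)


def _substream(seed: int, *keys) -> np.random.Generator:
    entropy = [int(seed) & 0x7FFFFFFF] + [zlib.crc32(str(k).encode())
                                          for k in keys]
    return np.random.default_rng(np.random.SeedSequence(entropy))


# ---------------------------------------------------------------------------
# Tree and trait simulation


def simulate_tree(n_tips: int, birth_rate: float = 1.0,
                  seed=None) -> TreeNode:
    """Simulate a pure-birth (Yule) tree with positive branch lengths.

    Lineages split after exponential waiting times (rate = birth_rate x
    number of extant lineages); after the n-th lineage appears one further
    exponential interval elapses, so every pendant edge has strictly
    positive length.  Tips are labelled ``t001 ...`` in traversal order.
    """
    if n_tips < 2:
        raise ValueError("need at least two tips")
    rng = _rng(seed)
    root = TreeNode()
    t = 0.0
    active: list[TreeNode] = []
    for _ in range(2):
        child = TreeNode(length=None)
        child._t_start = t
        root.append(child)
        active.append(child)
    while len(active) < n_tips:
        k = len(active)
        t += rng.exponential(1.0 / (birth_rate * k))
        node = active.pop(rng.integers(k))
        node._t_end = t
        for _ in range(2):
            child = TreeNode(length=None)
            child._t_start = t
            node.append(child)
            active.append(child)
    t += rng.exponential(1.0 / (birth_rate * n_tips))
    for node in active:
        node._t_end = t
    for node in root.traverse(include_self=False):
        node.length = node._t_end - node._t_start
        del node._t_start, node._t_end
    width = len(str(n_tips))
    for i, tip in enumerate(root.tips(), start=1):
        tip.name = f"t{i:0{width}d}"
    return root


def evolve_trait_bm(tree: TreeNode, trait_sigma: float, seed=None) -> pd.Series:
    """Evolve a continuous trait along the tree by Brownian motion.

    The root starts at 0 and each child adds Normal(0, trait_sigma^2 x
    branch_length); returns the tip values in tree tip order.
    """
    rng = _rng(seed)
    values = {id(tree): 0.0}
    for node in tree.preorder(include_self=False):
        step = 0.0
        if trait_sigma > 0 and node.length > 0:
            step = rng.normal(0.0, trait_sigma * np.sqrt(node.length))
        values[id(node)] = values[id(node.parent)] + step
    tips = list(tree.tips())
    return pd.Series([values[id(t)] for t in tips],
                     index=[t.name for t in tips], name="trait")


# ---------------------------------------------------------------------------
# Community assembly


def assemble_community(traits, env_optimum: float, filter_sigma: float | None,
                       n_individuals: int, migration: float,
                       metacommunity, rng, local_bias=None) -> np.ndarray:
    """Draw one community sample under trait filtering plus migration.

    Sampling weights are ``(1 - m) * local + m * metacommunity`` where the
    local term is the normalized product of Gaussian trait fitness
    ``exp(-(trait - optimum)^2 / (2 sigma_f^2))`` and an optional
    per-sample ``local_bias`` lottery (founder effects / drift);
    ``filter_sigma=None`` is the no-selection limit (flat fitness).
    ``n_individuals`` are then drawn multinomially, so sample totals are
    conserved exactly.
    """
    tr = np.asarray(traits, dtype=float)
    meta = np.asarray(metacommunity, dtype=float)
    if not np.isclose(meta.sum(), 1.0):
        raise ValueError("metacommunity must be a probability vector")
    if not 0.0 <= migration <= 1.0:
        raise ValueError("migration must be in [0, 1]")
    if filter_sigma is None or np.isinf(filter_sigma):
        fitness = np.ones_like(tr)
    else:
        if filter_sigma <= 0:
            raise ValueError("filter_sigma must be positive")
        fitness = np.exp(-((tr - env_optimum) ** 2) / (2.0 * filter_sigma ** 2))
    if local_bias is not None:
        fitness = fitness * np.asarray(local_bias, dtype=float)
    tot = fitness.sum()
    if migration < 1.0 and tot <= 0:
        raise ValueError("all local sampling weights are zero")
    local = fitness / tot if tot > 0 else np.zeros_like(fitness)
    weights = (1.0 - migration) * local + migration * meta
    return rng.multinomial(n_individuals, weights / weights.sum())


# ---------------------------------------------------------------------------
# Scenario and study generation


@dataclass(frozen=True)
class ScenarioSpec:
    """Parameters of one synthetic assembly scenario (one null pool).

    Any regime parameter left as None falls back to the calibrated default
    for the regime (see :mod:`phylonull.regime_params`).
    """

    regime: str
    n_taxa: int = 200
    n_samples: int = 10
    n_individuals: int = 1000
    trait_sigma: float = 1.0
    birth_rate: float = 1.0
    meta_lognormal_sigma: float = 1.0
    filter_sigma: float | None = None
    migration: float | None = None
    n_env_patches: int | None = None
    optimum_spread: float | None = None
    founder_alpha: float | None = None
    founder_keep: float | None = None
    trait_jump: float | None = None
    seed: int = 0

    def __post_init__(self):
        if self.regime not in REGIMES:
            raise ValueError(f"unknown regime {self.regime!r}; "
                             f"choose from {REGIMES}")
        if self.n_taxa < 2 or self.n_samples < 2 or self.n_individuals < 2:
            raise ValueError("n_taxa, n_samples and n_individuals must be >= 2")

    def resolved(self) -> dict:
        """Regime parameters with None fields replaced by regime defaults."""
        params = dict(REGIME_DEFAULTS[self.regime])
        for key in params:
            override = getattr(self, key, None)
            if override is not None:
                params[key] = override
        return params


@dataclass
class SyntheticDataset:
    """A complete simulated input bundle with known truth labels."""

    tree: TreeNode
    table: pd.DataFrame  # samples x taxa counts
    metadata: pd.DataFrame
    truth: pd.DataFrame  # one row per pool: group key columns + regime


def _standardize(traits: pd.Series) -> pd.Series:
    sd = traits.std(ddof=0)
    if sd == 0:
        return traits - traits.mean()
    return (traits - traits.mean()) / sd


def _patch_optima(params: dict, traits: pd.Series) -> np.ndarray:
    n = int(params["n_env_patches"])
    if n == 1:
        # an extreme-tail optimum selects a phylogenetically tight taxon set
        # (BM trait extremes concentrate in one wandering clade)
        return np.array([float(np.quantile(traits, 0.95))])
    return np.linspace(-params["optimum_spread"], params["optimum_spread"], n)


def _jump_clade(tree: TreeNode, rng: np.random.Generator,
                frac_range=(0.15, 0.30)) -> list[str]:
    """Pick a random internal clade holding 15-30% of the tips."""
    n = tree.count(tips=True)
    lo, hi = frac_range[0] * n, frac_range[1] * n
    cands = [nd for nd in tree.non_tips()
             if lo <= nd.count(tips=True) <= hi]
    if not cands:
        cands = sorted(tree.non_tips(),
                       key=lambda nd: abs(nd.count(tips=True) - 0.2 * n))[:1]
    node = cands[rng.integers(len(cands))]
    return [t.name for t in node.tips()]


def _assemble_pool(tree: TreeNode, traits_raw: pd.Series, meta_p: np.ndarray,
                   params: dict, n_samples: int, n_individuals: int,
                   rng: np.random.Generator) -> np.ndarray:
    """Assemble one pool of samples under a resolved regime recipe."""
    tr = traits_raw.copy()
    jump = params.get("trait_jump")
    if jump:
        clade = _jump_clade(tree, rng)
        sd = float(tr.std(ddof=0)) or 1.0
        tr.loc[clade] = tr.loc[clade] + jump * sd
        tr = _standardize(tr)
        optima = np.array([float(tr.loc[clade].mean())])
    else:
        tr = _standardize(tr)
        optima = _patch_optima(params, tr)
    alpha = params.get("founder_alpha")
    keep = params.get("founder_keep")
    n_taxa = len(tr)
    rows = []
    for s in range(n_samples):
        opt = float(optima[s % len(optima)])
        bias = None
        if alpha is not None:
            # unit-mean gamma lottery; small alpha = strong founder effects
            bias = rng.gamma(alpha, 1.0 / alpha, size=n_taxa)
        if keep is not None:
            # membership lottery: turns over which taxa are locally present
            # while keeping the survivors' weights even
            mask = (rng.random(n_taxa) < keep).astype(float)
            bias = mask if bias is None else bias * mask
        try:
            counts = assemble_community(
                tr.to_numpy(), opt, params["filter_sigma"], n_individuals,
                params["migration"], meta_p, rng, local_bias=bias)
        except ValueError:
            # lottery wiped out every locally fit taxon; retry without it
            counts = assemble_community(
                tr.to_numpy(), opt, params["filter_sigma"], n_individuals,
                params["migration"], meta_p, rng)
        rows.append(counts)
    return np.array(rows)


def simulate_scenario(spec: ScenarioSpec) -> SyntheticDataset:
    """Simulate one pool of samples under a named assembly regime.

    The tree, traits and metacommunity are drawn from seed-derived
    substreams, so identical specs give identical datasets.  Metadata
    frames the pool as one compartment x week group so it can run through
    the full pipeline unchanged.
    """
    params = spec.resolved()
    tree = simulate_tree(spec.n_taxa, spec.birth_rate,
                         _substream(spec.seed, "tree"))
    traits = evolve_trait_bm(tree, spec.trait_sigma,
                             _substream(spec.seed, "trait"))
    meta_rng = _substream(spec.seed, "meta")
    meta_p = meta_rng.lognormal(0.0, spec.meta_lognormal_sigma,
                                size=spec.n_taxa)
    meta_p /= meta_p.sum()
    counts = _assemble_pool(tree, traits, meta_p, params, spec.n_samples,
                            spec.n_individuals,
                            _substream(spec.seed, "samples"))
    sample_ids = [f"S{i:03d}" for i in range(spec.n_samples)]
    table = pd.DataFrame(counts, index=pd.Index(sample_ids, name="sample_id"),
                         columns=list(traits.index))
    metadata = pd.DataFrame({
        "sample_id": sample_ids,
        "compartment": "rhizosphere",
        "week": 3,
        "nam_line": [NAM_LINES[i % len(NAM_LINES)] for i in range(spec.n_samples)],
        "bbch": BBCH_BY_WEEK[3],
        "block": [i % 3 + 1 for i in range(spec.n_samples)],
    }).set_index("sample_id", drop=False)
    truth = pd.DataFrame([{"compartment": "rhizosphere", "week": 3,
                           "regime": spec.regime}])
    return SyntheticDataset(tree, table, metadata, truth)


def default_schedule(regime: str = "neutral_drift",
                     compartments=COMPARTMENTS,
                     weeks=tuple(range(3, 13))) -> dict:
    """A per-pool regime schedule assigning one regime everywhere."""
    return {(c, w): regime for c in compartments for w in weeks}


def simulate_study(schedule: dict | None = None, n_taxa: int = 200,
                   samples_per_pool: int = 9, n_individuals: int = 1000,
                   compartments=COMPARTMENTS, weeks=tuple(range(3, 13)),
                   trait_sigma: float = 1.0, meta_lognormal_sigma: float = 1.0,
                   spike_depth: int = 500, spike_jitter_sd: float = 0.2,
                   seed: int = 0) -> SyntheticDataset:
    """Simulate a full study-shaped dataset: compartments x weeks pools.

    One tree/trait/metacommunity backdrop is shared by all pools; each
    (compartment, week) pool assembles ``samples_per_pool`` samples under
    the regime its schedule entry names.  Root and rhizosphere samples
    carry an internal-standard spike taxon (lognormal jitter around
    ``spike_depth`` emulating extraction-efficiency variation); metadata
    assigns NAM lines, blocks and a fixed week -> BBCH stage map.
    """
    if schedule is None:
        schedule = default_schedule(compartments=compartments, weeks=weeks)
    missing = [(c, w) for c in compartments for w in weeks
               if (c, w) not in schedule]
    if missing:
        raise ValueError(f"schedule missing pools: {missing}")
    tree = simulate_tree(n_taxa, seed=_substream(seed, "tree"))
    traits = evolve_trait_bm(tree, trait_sigma, _substream(seed, "trait"))
    meta_rng = _substream(seed, "meta")
    meta_p = meta_rng.lognormal(0.0, meta_lognormal_sigma, size=n_taxa)
    meta_p /= meta_p.sum()

    tables, md_rows, truth_rows = [], [], []
    for comp in compartments:
        for week in weeks:
            regime = schedule[(comp, week)]
            params = dict(REGIME_DEFAULTS[regime])
            rng = _substream(seed, "pool", comp, week)
            counts = _assemble_pool(tree, traits, meta_p, params,
                                    samples_per_pool, n_individuals, rng)
            ids = [f"{comp[:2]}_w{week:02d}_s{i:02d}"
                   for i in range(samples_per_pool)]
            frame = pd.DataFrame(counts, index=pd.Index(ids, name="sample_id"),
                                 columns=list(traits.index))
            if comp in ("root", "rhizosphere"):
                jitter = rng.lognormal(0.0, spike_jitter_sd,
                                       size=samples_per_pool)
                frame[SPIKE_TAXON] = np.maximum(
                    1, np.round(spike_depth * jitter)).astype(int)
            tables.append(frame)
            for i, sid in enumerate(ids):
                md_rows.append({"sample_id": sid, "compartment": comp,
                                "week": week,
                                "nam_line": NAM_LINES[i % len(NAM_LINES)],
                                "bbch": BBCH_BY_WEEK.get(week, 0),
                                "block": i % 3 + 1})
            truth_rows.append({"compartment": comp, "week": week,
                               "regime": regime})
    table = pd.concat(tables).fillna(0.0)
    metadata = pd.DataFrame(md_rows).set_index("sample_id", drop=False)
    truth = pd.DataFrame(truth_rows)
    return SyntheticDataset(tree, table, metadata, truth)


def write_dataset(dataset: SyntheticDataset, outdir, seed=None) -> dict:
    """Write a synthetic dataset as Newick + TSVs; returns the paths."""
    from pathlib import Path
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "tree": outdir / "tree.nwk",
        "table": outdir / "feature_table.tsv",
        "metadata": outdir / "metadata.tsv",
        "truth": outdir / "truth.tsv",
    }
    dataset.tree.write(str(paths["tree"]))
    write_feature_table(dataset.table, paths["table"], seed=seed)
    write_tsv(dataset.metadata, paths["metadata"], seed=seed)
    write_tsv(dataset.truth, paths["truth"], seed=seed)
    return paths
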