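"""End-to-end pipeline: preprocessing -> alpha diversity -> null models ->
process classification -> grouped summaries.

All randomness flows from a single named seed; per-pool RNG substreams are
derived deterministically from (seed, group key), so outputs are
byte-identical across reruns and independent of pool execution order.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .alpha import alpha_diversity_table, summarize_by_group
from .classify import (classify_pairs, mean_index_trajectory, pairs_long_format,
                       process_fractions)
from .io import (align_table_to_tree, patristic_distances, read_feature_table,
                 read_metadata, read_newick, remove_singletons, spike_normalize,
                 write_tsv)
from .nullmodels import (DEFAULT_N_ITER, beta_nti_matrix, bray_curtis_matrix,
                         build_pools, discretize_counts, raup_crick_bray,
                         ses_pool)
from .simulate import ScenarioSpec, simulate_scenario, simulate_study

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Everything a pipeline run needs; mirrors the CLI flags.

    Either the three input paths (tree/table/metadata) or a synthetic
    ``scenario`` regime name / ``study`` flag must be given.
    """

    tree: str | None = None
    table: str | None = None
    metadata: str | None = None
    scenario: str | None = None  # synthetic single-pool regime name
    study: bool = False          # synthetic full study shape
    out_dir: str = "phylonull_out"
    seed: int = 0
    n_iter: int = DEFAULT_N_ITER
    weighted: bool = True
    beta_metric: str = "bmntd"
    group_by: tuple = ("compartment", "week")
    spike_taxon: str | None = None
    bnti_threshold: float = 2.0
    rc_threshold: float = 0.95
    rc_species_weight: str = "occupancy"
    rc_floor: int = 1000
    simpson_variant: str = "complement"
    scenario_samples: int = 10
    scenario_taxa: int = 200
    scenario_individuals: int = 1000

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "group_by" in data:
            data["group_by"] = tuple(data["group_by"])
        return cls(**data)


def _load_inputs(config: PipelineConfig):
    if config.scenario:
        spec = ScenarioSpec(regime=config.scenario,
                            n_taxa=config.scenario_taxa,
                            n_samples=config.scenario_samples,
                            n_individuals=config.scenario_individuals,
                            seed=config.seed)
        ds = simulate_scenario(spec)
        return ds.tree, ds.table, ds.metadata, ds.truth
    if config.study:
        ds = simulate_study(n_taxa=config.scenario_taxa,
                            samples_per_pool=config.scenario_samples,
                            n_individuals=config.scenario_individuals,
                            seed=config.seed)
        return ds.tree, ds.table, ds.metadata, ds.truth
    if not (config.tree and config.table and config.metadata):
        raise ValueError("config must name tree/table/metadata paths or a "
                         "synthetic scenario/study")
    tree = read_newick(config.tree)
    table = read_feature_table(config.table)
    metadata = read_metadata(config.metadata)
    return tree, table, metadata, None


def run_pipeline(config: PipelineConfig) -> dict:
    """Run all stages and write the output bundle under ``config.out_dir``.

    Writes ``alpha.tsv``, ``alpha_groups.tsv``, ``ses.tsv``,
    ``pairwise.tsv``, ``process_fractions.tsv``, ``index_trajectories.tsv``
    and ``manifest.json``.  On failure a FAILED marker file is left next to
    any partial outputs and the exception propagates.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    failed_marker = out / "FAILED"
    if failed_marker.exists():
        failed_marker.unlink()
    try:
        result = _run(config, out)
    except Exception as exc:
        failed_marker.write_text(f"{type(exc).__name__}: {exc}\n")
        raise
    return result


def _run(config: PipelineConfig, out: Path) -> dict:
    tree, table, metadata, truth = _load_inputs(config)
    warnings_log: list[str] = []
    if config.n_iter != DEFAULT_N_ITER:
        msg = (f"nonstandard iteration count n_iter={config.n_iter} "
               f"(default {DEFAULT_N_ITER})")
        warnings_log.append(msg)
        warnings.warn(msg)

    # --- preprocessing: singletons -> spike -> tree alignment
    table = remove_singletons(table)
    counts_for_alpha = table
    if config.spike_taxon:
        counts_for_alpha = table.drop(columns=[config.spike_taxon],
                                      errors="ignore")
        table = spike_normalize(table, config.spike_taxon)
    table, tree, align_report = align_table_to_tree(table, tree)
    dist_full = patristic_distances(tree)

    # --- alpha diversity (ACE needs counts, so pre-normalization abundances)
    alpha = alpha_diversity_table(counts_for_alpha.loc[table.index],
                                  simpson_variant=config.simpson_variant)
    alpha_groups = []
    for metric in ("pielou_J", "simpson", "ace", "richness"):
        g = summarize_by_group(alpha[metric], metadata, config.group_by)
        g.insert(len(config.group_by), "metric", metric)
        alpha_groups.append(g)
    alpha_groups = pd.concat(alpha_groups, ignore_index=True)

    # --- null models per pool
    pools = build_pools(metadata.loc[table.index], config.group_by,
                        config.seed)
    ses_frames, pair_frames = [], []
    for pool in pools:
        sub = table.loc[list(pool.sample_ids)]
        present = sub.columns[(sub > 0).any(axis=0)]
        sub = sub[present]
        dist = dist_full.submatrix(list(present))
        group = dict(zip(config.group_by, pool.key))

        for metric in ("mpd", "mntd"):
            ses = ses_pool(sub, dist, metric=metric, weighted=config.weighted,
                           n_iter=config.n_iter, rng=pool.rng(f"ses_{metric}"))
            for col, val in group.items():
                ses[col] = val
            ses_frames.append(ses)

        bmntd, bnti = beta_nti_matrix(sub, dist, weighted=config.weighted,
                                      n_iter=config.n_iter,
                                      rng=pool.rng("bnti"),
                                      beta_metric=config.beta_metric)
        bray = bray_curtis_matrix(sub)
        rc_table = discretize_counts(sub, config.rc_floor)
        rc = raup_crick_bray(rc_table, n_iter=config.n_iter,
                             rng=pool.rng("rc"),
                             species_weight=config.rc_species_weight)
        pair_frames.append(pairs_long_format(bnti, bmntd, bray, rc, group))

    ses_all = pd.concat(ses_frames, ignore_index=True)
    pairs = pd.concat(pair_frames, ignore_index=True)

    # --- classification and summaries
    pairs = classify_pairs(pairs, config.bnti_threshold, config.rc_threshold)
    fractions = process_fractions(pairs, config.group_by,
                                  metadata=metadata.loc[table.index])
    bnti_series = pd.Series(pairs["beta_nti"].to_numpy(),
                            index=pairs["sample_a"])  # one entry per pair
    traj_frames = []
    for metric, frame in (("nri", ses_all[ses_all["metric"] == "mpd"]),
                          ("nti", ses_all[ses_all["metric"] == "mntd"])):
        t = mean_index_trajectory(
            pd.Series(frame["index"].to_numpy(), index=frame["sample_id"]),
            metadata, config.group_by)
        if len(t):
            t.insert(len(config.group_by), "metric", metric)
            traj_frames.append(t)
    tb = mean_index_trajectory(bnti_series, metadata, config.group_by)
    if len(tb):
        tb.insert(len(config.group_by), "metric", "beta_nti")
        traj_frames.append(tb)
    trajectories = (pd.concat(traj_frames, ignore_index=True) if traj_frames
                    else pd.DataFrame(columns=[*config.group_by, "metric",
                                               "n", "mean", "se"]))

    # --- outputs
    input_paths = [p for p in (config.tree, config.table, config.metadata) if p]
    kw = dict(input_paths=input_paths, seed=config.seed)
    write_tsv(alpha.drop(columns=["sample_id"]).reset_index(),
              out / "alpha.tsv", **kw)
    write_tsv(alpha_groups, out / "alpha_groups.tsv", **kw)
    write_tsv(ses_all, out / "ses.tsv", **kw)
    write_tsv(pairs, out / "pairwise.tsv", **kw)
    write_tsv(fractions, out / "process_fractions.tsv", **kw)
    write_tsv(trajectories, out / "index_trajectories.tsv", **kw)
    if truth is not None:
        write_tsv(truth, out / "truth.tsv", **kw)

    manifest = {
        "package": "phylonull",
        "version": __version__,
        "config": {k: (list(v) if isinstance(v, tuple) else v)
                   for k, v in dataclasses.asdict(config).items()
                   if k != "out_dir"},
        "n_samples": int(len(table)),
        "n_taxa": int(table.shape[1]),
        "n_pools": len(pools),
        "n_pairs": int(len(pairs)),
        "n_pairs_excluded": int(pairs.attrs.get("n_excluded", 0)),
        "alignment": {"shared": len(align_report.shared),
                      "dropped_from_table": align_report.dropped_from_table,
                      "dropped_from_tree": len(align_report.dropped_from_tree)},
        "warnings": warnings_log,
        "outputs": ["alpha.tsv", "alpha_groups.tsv", "ses.tsv", "pairwise.tsv",
                    "process_fractions.tsv", "index_trajectories.tsv"],
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2,
                                                  sort_keys=True) + "\n")
    return {"out_dir": str(out), "manifest": manifest, "pairs": pairs,
            "fractions": fractions, "ses": ses_all, "alpha": alpha}
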