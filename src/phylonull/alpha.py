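"""Per-sample alpha diversity and grouped mean +/- standard-error summaries.

Implements the three indices commonly reported for amplicon surveys —
Pielou's evenness J = H'/ln(S), the (Gini-)Simpson index 1 - sum(p_i^2),
and the abundance-based coverage estimator (ACE) of richness — and the
per-group trajectories (mean and standard error per compartment x week)
used to track them over a growing season.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from skbio.diversity import alpha as _skalpha


def _clean(abundances) -> np.ndarray:
    a = np.asarray(abundances, dtype=float)
    if a.ndim != 1:
        raise ValueError("abundance vector must be one-dimensional")
    if (a < 0).any():
        raise ValueError("negative abundances")
    if a.sum() <= 0:
        raise ValueError("all-zero sample has no diversity")
    return a


def richness(abundances) -> int:
    """Number of taxa with abundance > 0."""
    return int((_clean(abundances) > 0).sum())


def pielou_evenness(abundances) -> float:
    """Pielou's evenness J = H'/ln(S).

    Returns NaN for a single-taxon sample, where J is 0/0; imputing 0
    there would bias grouped means downward, so undefined values are
    dropped (and counted) by :func:`summarize_by_group` instead.
    """
    a = _clean(abundances)
    if richness(a) == 1:
        return float("nan")
    return float(_skalpha.pielou_e(a))


def simpson_index(abundances, variant: str = "complement") -> float:
    """Simpson diversity.

    ``variant="complement"`` (default) returns 1 - sum(p_i^2), the
    convention of phyloseq's ``estimate_richness``; ``variant="inverse"``
    returns 1/sum(p_i^2).
    """
    a = _clean(abundances)
    if variant == "complement":
        return float(_skalpha.simpson(a))
    if variant == "inverse":
        return float(_skalpha.enspie(a))
    raise ValueError(f"unknown Simpson variant {variant!r}")


def ace_richness(counts, rare_threshold: int = 10) -> float:
    """Abundance-based coverage estimator of richness.

    Defined on integer counts only (spike-normalized tables are rejected).
    Taxa with count <= ``rare_threshold`` form the rare group; when the
    ACE sample coverage C_ace = 1 - F1/N_rare is zero (every rare taxon a
    singleton) the estimator is undefined and the bias-corrected Chao1
    estimate is returned instead, with a warning.
    """
    a = _clean(counts)
    if not np.allclose(a, np.round(a)):
        raise ValueError("ACE requires integer counts")
    a = np.round(a).astype(int)
    a = a[a > 0]
    rare = a[a <= rare_threshold]
    if rare.size == 0:
        return float(a.size)
    f1 = int((rare == 1).sum())
    if f1 == rare.sum():  # C_ace = 1 - F1/N_rare = 0
        warnings.warn("ACE coverage is zero (all rare taxa are singletons); "
                      "falling back to bias-corrected Chao1")
        return float(_skalpha.chao1(a, bias_corrected=True))
    return float(_skalpha.ace(a, rare_threshold=rare_threshold))


@dataclass(frozen=True)
class GroupSummary:
    """Mean and standard error of a metric within one design group."""

    group: tuple
    n: int
    mean: float
    se: float
    n_dropped: int = 0


def alpha_diversity_table(table: pd.DataFrame, rare_threshold: int = 10,
                          simpson_variant: str = "complement",
                          ace: bool | None = None) -> pd.DataFrame:
    """Compute all alpha metrics for every sample of a feature table.

    ACE is only computed when the table holds integer counts (``ace=None``
    auto-detects; pass ``ace=False`` to skip on count tables too).
    """
    vals = table.to_numpy(dtype=float)
    if ace is None:
        ace = bool(np.allclose(vals, np.round(vals)))
    rows = []
    for sid, row in zip(table.index, vals):
        rec = {
            "sample_id": sid,
            "richness": richness(row),
            "pielou_J": pielou_evenness(row),
            "simpson": simpson_index(row, simpson_variant),
        }
        rec["ace"] = ace_richness(row, rare_threshold) if ace else float("nan")
        rows.append(rec)
    return pd.DataFrame(rows).set_index("sample_id", drop=False)


def summarize_by_group(values: pd.Series, metadata: pd.DataFrame,
                       group_keys=("compartment", "week")) -> pd.DataFrame:
    """Per-group n, mean and standard error of a per-sample metric.

    ``se = sd / sqrt(n)`` with the n-1 denominator; NaN values are dropped
    and counted per group.  Groups with a single member report ``se`` as
    NaN (the sample standard deviation is undefined), and groups emptied
    by the NaN drop are omitted with a warning.
    """
    unknown = values.index.difference(metadata.index)
    if len(unknown):
        raise KeyError(f"samples without metadata: {list(unknown)}")
    df = metadata.loc[values.index, list(group_keys)].copy()
    df["value"] = values.to_numpy(dtype=float)
    out = []
    for key, grp in df.groupby(list(group_keys), sort=True):
        v = grp["value"].to_numpy()
        ok = v[~np.isnan(v)]
        n_dropped = v.size - ok.size
        if ok.size == 0:
            warnings.warn(f"group {key} has no defined values after NaN drop; omitted")
            continue
        mean = float(ok.mean())
        se = float(ok.std(ddof=1) / np.sqrt(ok.size)) if ok.size > 1 else float("nan")
        rec = dict(zip(group_keys, key if isinstance(key, tuple) else (key,)))
        rec.update(n=int(ok.size), mean=mean, se=se, n_dropped=int(n_dropped))
        out.append(rec)
    return pd.DataFrame(out)


def alpha_long_format(alpha: pd.DataFrame) -> pd.DataFrame:
    """Melt an alpha table to long (sample_id, metric, value) format."""
    return alpha.melt(id_vars="sample_id", var_name="metric",
                      value_name="value", value_vars=[c for c in alpha.columns
                                                      if c != "sample_id"])
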