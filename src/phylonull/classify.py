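"""Five-way classification of pairwise comparisons into assembly processes.

The decision tree asks first whether deterministic selection dominates
(|betaNTI| > 2): betaNTI > +2 is heterogeneous selection, betaNTI < -2
homogeneous selection.  Only when |betaNTI| < 2 is RC_bray consulted:
RC > +0.95 is dispersal limitation, RC < -0.95 homogenizing dispersal, and
anything within both bands is drift/diversification.  All inequalities are
strict, so boundary-exact values fall to the stochastic/drift side.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from enum import Enum

import numpy as np
import pandas as pd

from .alpha import summarize_by_group

logger = logging.getLogger(__name__)

BNTI_THRESHOLD = 2.0
RC_THRESHOLD = 0.95


class AssemblyProcess(str, Enum):
    HETEROGENEOUS_SELECTION = "heterogeneous_selection"
    HOMOGENEOUS_SELECTION = "homogeneous_selection"
    DISPERSAL_LIMITATION = "dispersal_limitation"
    HOMOGENIZING_DISPERSAL = "homogenizing_dispersal"
    DRIFT_DIVERSIFICATION = "drift_diversification"


DETERMINISTIC = (AssemblyProcess.HETEROGENEOUS_SELECTION,
                 AssemblyProcess.HOMOGENEOUS_SELECTION)

# fraction-table column order (deterministic processes first)
PROCESS_ORDER = [p.value for p in (AssemblyProcess.HETEROGENEOUS_SELECTION,
                                   AssemblyProcess.HOMOGENEOUS_SELECTION,
                                   AssemblyProcess.DISPERSAL_LIMITATION,
                                   AssemblyProcess.HOMOGENIZING_DISPERSAL,
                                   AssemblyProcess.DRIFT_DIVERSIFICATION)]


def classify_pair(beta_nti: float, rc_bray: float,
                  bnti_threshold: float = BNTI_THRESHOLD,
                  rc_threshold: float = RC_THRESHOLD) -> AssemblyProcess:
    """Assign one (betaNTI, RC_bray) pair to an assembly process.

    Raises ValueError on non-finite input; callers exclude such pairs and
    report them (see :func:`classify_pairs`).
    """
    if not (np.isfinite(beta_nti) and np.isfinite(rc_bray)):
        raise ValueError("classify_pair requires finite betaNTI and RC_bray")
    if beta_nti == bnti_threshold or beta_nti == -bnti_threshold:
        logger.info("boundary-exact betaNTI %.6g treated as stochastic", beta_nti)
    if beta_nti > bnti_threshold:
        return AssemblyProcess.HETEROGENEOUS_SELECTION
    if beta_nti < -bnti_threshold:
        return AssemblyProcess.HOMOGENEOUS_SELECTION
    if rc_bray > rc_threshold:
        return AssemblyProcess.DISPERSAL_LIMITATION
    if rc_bray < -rc_threshold:
        return AssemblyProcess.HOMOGENIZING_DISPERSAL
    return AssemblyProcess.DRIFT_DIVERSIFICATION


def classify_pairs(pairs: pd.DataFrame, bnti_threshold: float = BNTI_THRESHOLD,
                   rc_threshold: float = RC_THRESHOLD) -> pd.DataFrame:
    """Classify a long-format pair table in place.

    ``pairs`` needs columns ``beta_nti`` and ``rc_bray``; a ``process``
    column is added.  Pairs with NaN in either statistic get a missing
    process and are counted in the returned frame's ``attrs['n_excluded']``.
    """
    out = pairs.copy()
    finite = np.isfinite(out["beta_nti"]) & np.isfinite(out["rc_bray"])
    out["process"] = pd.NA
    out.loc[finite, "process"] = [
        classify_pair(b, r, bnti_threshold, rc_threshold).value
        for b, r in zip(out.loc[finite, "beta_nti"], out.loc[finite, "rc_bray"])]
    n_excluded = int((~finite).sum())
    if n_excluded:
        warnings.warn(f"{n_excluded} pair(s) excluded from classification "
                      "(non-finite betaNTI or RC_bray)")
    out.attrs["n_excluded"] = n_excluded
    return out


@dataclass(frozen=True)
class ProcessFractionSummary:
    group: tuple
    n_pairs: int
    fractions: dict
    dominant: str


def process_fractions(pairs: pd.DataFrame, group_keys=("compartment", "week"),
                      metadata: pd.DataFrame | None = None) -> pd.DataFrame:
    """Per-group fractions of pairs assigned to each of the five processes.

    ``pairs`` is a classified long-format table whose two samples share the
    same group; the group columns must already be attached (the pipeline
    attaches them when it emits within-pool pairs).  Passing ``metadata``
    additionally verifies the pooling contract — a pair whose two samples
    belong to different groups is an error.  Dominant process ties are
    broken toward the deterministic categories and logged.
    """
    group_keys = list(group_keys)
    for c in group_keys:
        if c not in pairs.columns:
            raise ValueError(f"pairs table lacks group column {c!r}")
    if metadata is not None:
        ga = metadata.loc[pairs["sample_a"], group_keys].to_numpy()
        gb = metadata.loc[pairs["sample_b"], group_keys].to_numpy()
        bad = (ga != gb).any(axis=1)
        if bad.any():
            offenders = pairs.loc[bad, ["sample_a", "sample_b"]].head()
            raise ValueError("cross-group sample pairs violate the pooling "
                             f"contract:\n{offenders}")
    rows = []
    for key, grp in pairs.groupby(group_keys, sort=True):
        key = key if isinstance(key, tuple) else (key,)
        classified = grp.dropna(subset=["process"])
        if not len(classified):
            warnings.warn(f"group {key} has no classifiable pairs; omitted")
            continue
        counts = classified["process"].value_counts()
        frac = {p: counts.get(p, 0) / len(classified) for p in PROCESS_ORDER}
        best = max(frac.values())
        winners = [p for p in PROCESS_ORDER if frac[p] == best]
        if len(winners) > 1:
            logger.info("dominant-process tie in group %s among %s; "
                        "broken toward deterministic", key, winners)
        dominant = winners[0]  # PROCESS_ORDER lists deterministic first
        rec = dict(zip(group_keys, key))
        rec["n_pairs"] = int(len(classified))
        rec.update({f"frac_{p}": frac[p] for p in PROCESS_ORDER})
        rec["dominant"] = dominant
        rows.append(rec)
    return pd.DataFrame(rows)


def mean_index_trajectory(values: pd.Series, metadata: pd.DataFrame,
                          group_keys=("compartment", "week"),
                          significance_band: float = 2.0) -> pd.DataFrame:
    """Group-wise mean +/- se of an index (NRI, NTI or betaNTI).

    Adds a ``crosses_band`` flag marking groups whose mean exceeds the
    |2| significance band.
    """
    summary = summarize_by_group(values, metadata, group_keys)
    if len(summary):
        summary["crosses_band"] = summary["mean"].abs() > significance_band
    return summary


def pairs_long_format(beta_nti: pd.DataFrame, beta_mntd: pd.DataFrame,
                      bray: pd.DataFrame, rc: pd.DataFrame,
                      group: dict | None = None) -> pd.DataFrame:
    """Flatten symmetric pair matrices into one row per unordered pair."""
    ids = list(beta_nti.index)
    rows = []
    for i in range(len(ids)):
        for j in range(i + 1, len(ids)):
            a, b = ids[i], ids[j]
            rec = {"sample_a": a, "sample_b": b,
                   "beta_mntd": beta_mntd.iloc[i, j],
                   "beta_nti": beta_nti.iloc[i, j],
                   "bray_curtis": bray.iloc[i, j],
                   "rc_bray": rc.iloc[i, j]}
            if group:
                rec.update(group)
            rows.append(rec)
    return pd.DataFrame(rows)
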