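"""Input/output and preprocessing for trees, feature tables and sample metadata.

The three standard inputs are a rooted Newick tree with branch lengths, a
sample x taxon abundance table (plain TSV or the TSV export of a BIOM table),
and a sample metadata TSV.  Preprocessing mirrors common amplicon practice:
dataset-wide singleton removal, internal-standard (spike) normalization, and
alignment of the feature table to the tree's tip set.
"""

from __future__ import annotations

import hashlib
import io as _io
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from skbio import TreeNode

from . import __version__

COMPARTMENTS = ("leaf", "root", "rhizosphere")
WEEK_RANGE = (3, 12)

REQUIRED_METADATA_COLUMNS = ("sample_id", "compartment", "week")
OPTIONAL_METADATA_COLUMNS = ("nam_line", "bbch", "block")


class NewickParseError(ValueError):
    """Raised when a Newick file cannot be parsed or fails validation."""


class ValidationError(ValueError):
    """Raised when an input violates a structural invariant."""


# ---------------------------------------------------------------------------
# Trees


def read_newick(path, default_branch_length: float | None = None) -> TreeNode:
    """Read and validate a rooted Newick tree with branch lengths.

    Parameters
    ----------
    path : str, Path or file-like
        Newick source.
    default_branch_length : float, optional
        If given, nodes lacking a branch length are assigned this value
        (the root is always allowed to lack one).  By default missing
        lengths are rejected, since silently defaulting them corrupts
        distance-based statistics.
    """
    try:
        tree = TreeNode.read(str(path) if isinstance(path, (str, Path)) else path,
                             format="newick")
    except Exception as exc:  # skbio raises NewickFormatError with position info
        raise NewickParseError(f"malformed Newick in {path!r}: {exc}") from exc
    for node in tree.traverse(include_self=False):
        if node.length is None:
            if default_branch_length is None:
                raise NewickParseError(
                    f"node {node.name!r} has no branch length; pass "
                    "default_branch_length to default missing lengths")
            node.length = float(default_branch_length)
    validate_tree(tree)
    return tree


def validate_tree(tree: TreeNode) -> None:
    """Check tip-label uniqueness and branch-length nonnegativity."""
    labels = [tip.name for tip in tree.tips()]
    if any(lbl is None or lbl == "" for lbl in labels):
        raise ValidationError("tree has unnamed tips")
    dupes = {l for l in labels if labels.count(l) > 1}
    if dupes:
        raise ValidationError(f"duplicate tip labels: {sorted(dupes)}")
    for node in tree.traverse(include_self=False):
        if node.length is not None and node.length < 0:
            raise ValidationError(
                f"negative branch length {node.length} at {node.name!r}")


def tree_tip_order(tree: TreeNode) -> list[str]:
    """Tip labels in the tree's postorder traversal order."""
    return [tip.name for tip in tree.tips()]


@dataclass(frozen=True)
class PatristicMatrix:
    """Pairwise tip-to-tip path-length (patristic) distances.

    ``data[i, j]`` is the sum of branch lengths on the unique path between
    tips ``taxa[i]`` and ``taxa[j]``.  Symmetric with a zero diagonal.
    """

    taxa: tuple[str, ...]
    data: np.ndarray

    def __post_init__(self):
        d = np.asarray(self.data, dtype=float)
        if d.ndim != 2 or d.shape[0] != d.shape[1] or d.shape[0] != len(self.taxa):
            raise ValidationError("distance matrix shape does not match taxa")
        if len(set(self.taxa)) != len(self.taxa):
            raise ValidationError("duplicate taxa in distance matrix")
        if (d < 0).any():
            raise ValidationError("negative patristic distance")
        if not np.allclose(d, d.T):
            raise ValidationError("distance matrix not symmetric")
        if not np.allclose(np.diag(d), 0):
            raise ValidationError("distance matrix diagonal not zero")
        object.__setattr__(self, "data", d)
        object.__setattr__(self, "taxa", tuple(self.taxa))

    @property
    def index(self) -> dict[str, int]:
        return {t: i for i, t in enumerate(self.taxa)}

    def submatrix(self, taxa) -> "PatristicMatrix":
        """Restrict to the given taxa, in the given order."""
        idx = self.index
        try:
            pos = [idx[t] for t in taxa]
        except KeyError as exc:
            raise KeyError(f"taxon {exc.args[0]!r} not in distance matrix") from exc
        return PatristicMatrix(tuple(taxa), self.data[np.ix_(pos, pos)])


def patristic_distances(tree: TreeNode) -> PatristicMatrix:
    """Patristic distance matrix for all tips, in tree tip order."""
    dm = tree.tip_tip_distances()
    order = tree_tip_order(tree)
    sub = dm.filter(order)
    return PatristicMatrix(tuple(sub.ids), np.asarray(sub.data, dtype=float))


# ---------------------------------------------------------------------------
# Feature tables

# CommunityTable is represented as a pandas DataFrame with samples as the row
# index and taxa as columns; all entries nonnegative.


def validate_table(table: pd.DataFrame) -> None:
    if table.index.has_duplicates:
        raise ValidationError("duplicate sample IDs in feature table")
    if table.columns.has_duplicates:
        raise ValidationError("duplicate taxon IDs in feature table")
    if (table.to_numpy() < 0).any():
        raise ValidationError("negative abundances in feature table")


def read_feature_table(path) -> pd.DataFrame:
    """Read a feature table in plain-TSV or BIOM-TSV dialect.

    Both dialects store taxa as rows and samples as columns; BIOM TSV export
    additionally carries a ``# Constructed from biom file`` banner and names
    the first header cell ``#OTU ID``.  The dialect is auto-detected.  The
    returned frame is transposed to samples x taxa.
    """
    text = Path(path).read_text()
    lines = text.splitlines()
    start = 0
    while start < len(lines) and lines[start].startswith("#") \
            and not lines[start].startswith("#OTU ID"):
        start += 1
    body = "\n".join(lines[start:])
    df = pd.read_csv(_io.StringIO(body), sep="\t", index_col=0)
    df.index.name = "taxon_id"
    table = df.T
    table.index.name = "sample_id"
    table = table.astype(float)
    validate_table(table)
    return table


def read_metadata(path, allowed_compartments=COMPARTMENTS,
                  week_range=WEEK_RANGE) -> pd.DataFrame:
    """Read the sample metadata TSV and validate the design columns."""
    md = pd.read_csv(path, sep="\t", comment="#", dtype={"sample_id": str})
    missing = [c for c in REQUIRED_METADATA_COLUMNS if c not in md.columns]
    if missing:
        raise ValidationError(f"metadata missing required columns: {missing}")
    if md["sample_id"].duplicated().any():
        raise ValidationError("duplicate sample_id in metadata")
    bad = sorted(set(md["compartment"]) - set(allowed_compartments))
    if bad:
        raise ValidationError(f"unknown compartments: {bad}")
    md["week"] = md["week"].astype(int)
    lo, hi = week_range
    out = md[(md["week"] < lo) | (md["week"] > hi)]
    if len(out):
        raise ValidationError(
            f"weeks outside declared range {week_range}: {sorted(out['week'].unique())}")
    return md.set_index("sample_id", drop=False)


# ---------------------------------------------------------------------------
# Preprocessing filters


def remove_singletons(table: pd.DataFrame) -> pd.DataFrame:
    """Drop taxa represented at most once across the whole dataset.

    A taxon whose total abundance over all samples is <= 1 (dataset-wide
    singletons and zero-sum taxa) is removed; samples are untouched.
    Idempotent.
    """
    validate_table(table)
    totals = table.sum(axis=0)
    keep = totals > 1
    if not keep.any():
        warnings.warn("all taxa are singletons or zero-sum; table is empty")
    return table.loc[:, keep]


def spike_normalize(table: pd.DataFrame, spike_taxon: str) -> pd.DataFrame:
    """Standardize each sample to its internal-standard spike abundance.

    Every abundance in a sample is divided by that sample's spike count;
    the spike taxon itself is removed from the output.  Within-sample
    ratios of the remaining taxa are preserved.
    """
    validate_table(table)
    if spike_taxon not in table.columns:
        raise ValidationError(f"spike taxon {spike_taxon!r} not in table")
    spike = table[spike_taxon]
    zero = spike[spike <= 0]
    if len(zero):
        raise ValidationError(
            f"spike count is zero in samples: {list(zero.index)}")
    out = table.drop(columns=[spike_taxon]).div(spike, axis=0)
    return out


@dataclass
class AlignmentReport:
    """Taxa dropped on each side when intersecting a table with a tree."""

    shared: list[str]
    dropped_from_table: list[str]
    dropped_from_tree: list[str]


def align_table_to_tree(table: pd.DataFrame, tree: TreeNode
                        ) -> tuple[pd.DataFrame, TreeNode, AlignmentReport]:
    """Restrict a feature table and tree to their shared taxa.

    The table's columns are reordered to the pruned tree's tip order so all
    downstream matrices share one deterministic taxon ordering.
    """
    validate_table(table)
    tips = set(tree_tip_order(tree))
    cols = set(table.columns)
    shared = tips & cols
    if not shared:
        raise ValidationError("feature table and tree share no taxa")
    report = AlignmentReport(
        shared=sorted(shared),
        dropped_from_table=sorted(cols - tips),
        dropped_from_tree=sorted(tips - cols),
    )
    pruned = tree.shear(shared) if report.dropped_from_tree else tree
    order = tree_tip_order(pruned)
    return table.loc[:, order], pruned, report


# ---------------------------------------------------------------------------
# Writers


def _hash_file(path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()[:16]


def write_tsv(df: pd.DataFrame, path, input_paths=(), seed=None,
              index: bool = False) -> None:
    """Write a TSV with a provenance header comment.

    The header records the package version, a short SHA-256 of each input
    file, and the RNG seed used for the run.
    """
    lines = [f"# phylonull {__version__}"]
    for p in input_paths:
        lines.append(f"# input {Path(p).name} sha256:{_hash_file(p)}")
    if seed is not None:
        lines.append(f"# seed {seed}")
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")
        df.to_csv(fh, sep="\t", index=index, float_format="%.10g")


def write_feature_table(table: pd.DataFrame, path, **kwargs) -> None:
    """Write a samples x taxa table in the taxa-rows TSV dialect."""
    out = table.T
    out.index.name = "#OTU ID"
    write_tsv(out, path, index=True, **kwargs)
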