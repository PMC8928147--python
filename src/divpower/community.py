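"""Data model and file IO for count tables, trees, distance matrices, groups.

The on-disk formats are deliberately plain:

* count table — TSV, first row = feature identifiers, first column = sample
  identifiers (samples as rows by default; ``features_as_rows=True``
  transposes on read, since amplicon tables circulate in both orientations);
* phylogeny — Newick with mandatory branch lengths;
* distance matrix — square labelled TSV, identical row/column labels;
* group design — two-column TSV (sample identifier, group label).
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import skbio
from skbio import TreeNode


class ValidationError(ValueError):
    """Raised when an input violates a structural invariant."""


# ---------------------------------------------------------------------------
# CountTable
# ---------------------------------------------------------------------------

class CountTable:
    """Samples x features matrix of nonnegative abundances.

    Counts are accepted as reals, not just integers: perturbed abundances
    from simulation scenarios need not be integral.  Chao1 is the only
    metric that additionally demands integer counts, and it checks for
    itself.

    Parameters
    ----------
    data : pandas.DataFrame
        One row per sample, one column per feature.  The index holds sample
        identifiers, the columns feature identifiers.
    """

    def __init__(self, data: pd.DataFrame):
        if data.index.has_duplicates:
            dups = data.index[data.index.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate sample identifiers: {dups}")
        if data.columns.has_duplicates:
            dups = data.columns[data.columns.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate feature identifiers: {dups}")
        values = data.to_numpy(dtype=float)
        if not np.all(np.isfinite(values)):
            raise ValidationError("count table contains non-finite values")
        if np.any(values < 0):
            i, j = np.argwhere(values < 0)[0]
            raise ValidationError(
                f"negative abundance at sample {data.index[i]!r}, "
                f"feature {data.columns[j]!r}"
            )
        self._data = data.astype(float)

    # -- accessors ---------------------------------------------------------
    @property
    def data(self) -> pd.DataFrame:
        return self._data

    @property
    def values(self) -> np.ndarray:
        return self._data.to_numpy()

    @property
    def sample_ids(self) -> list[str]:
        return [str(s) for s in self._data.index]

    @property
    def feature_ids(self) -> list[str]:
        return [str(f) for f in self._data.columns]

    @property
    def n_samples(self) -> int:
        return self._data.shape[0]

    @property
    def n_features(self) -> int:
        return self._data.shape[1]

    def __eq__(self, other) -> bool:
        if not isinstance(other, CountTable):
            return NotImplemented
        return self._data.equals(other._data)

    def __repr__(self) -> str:
        return f"CountTable({self.n_samples} samples x {self.n_features} features)"

    # -- IO ----------------------------------------------------------------
    def to_tsv(self, path) -> None:
        self._data.to_csv(path, sep="\t", index_label="#SampleID")

    def select_samples(self, sample_ids) -> "CountTable":
        return CountTable(self._data.loc[list(sample_ids)])

    def take(self, indices, suffix: bool = True) -> "CountTable":
        """Row-select by integer position, allowing repeats.

        With-replacement resampling duplicates rows; ``suffix=True`` makes
        the resulting sample identifiers unique by appending the draw index.
        """
        sub = self._data.iloc[list(indices)]
        if suffix:
            sub = sub.set_axis(
                [f"{s}.{k}" for k, s in enumerate(sub.index)], axis=0
            )
        return CountTable(sub)


def read_count_table(path, features_as_rows: bool = False) -> CountTable:
    """Read a TSV count table; first row and column are identifiers."""
    try:
        df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    except Exception as exc:
        raise ValidationError(f"cannot parse count table {path}: {exc}") from exc
    try:
        df = df.apply(pd.to_numeric)
    except Exception:
        # locate the offending cell for a useful message
        for col in df.columns:
            bad = pd.to_numeric(df[col], errors="coerce")
            mask = bad.isna() & df[col].notna()
            if mask.any():
                row = df.index[mask.to_numpy().nonzero()[0][0]]
                raise ValidationError(
                    f"malformed numeric cell at row {row!r}, column {col!r}"
                ) from None
        raise
    if features_as_rows:
        df = df.T
    return CountTable(df)


# ---------------------------------------------------------------------------
# PhyloTree
# ---------------------------------------------------------------------------

def _validate_tree(tree: TreeNode) -> TreeNode:
    leaves = [t.name for t in tree.tips()]
    if any(name is None for name in leaves):
        raise ValidationError("tree has an unlabelled leaf")
    if len(set(leaves)) != len(leaves):
        raise ValidationError("tree leaf labels are not unique")
    for node in tree.traverse(include_self=False):
        if node.length is None:
            where = node.name or "internal node"
            raise ValidationError(
                f"branch length missing on edge above {where}; "
                "lengths are mandatory (not treated as zero)"
            )
        if node.length < 0:
            raise ValidationError(f"negative branch length {node.length}")
    if tree.length is None:
        tree.length = 0.0  # a root stem is optional; absent means zero
    return tree


def read_tree(source) -> TreeNode:
    """Read a rooted Newick tree with mandatory branch lengths.

    ``source`` may be a path or a Newick string.
    """
    text = None
    if isinstance(source, (str, Path)):
        p = Path(source)
        # Heuristic: a Newick literal contains parentheses/semicolon
        if isinstance(source, str) and (";" in source or "(" in source):
            text = source
        else:
            text = p.read_text()
    else:
        text = source.read()
    try:
        tree = TreeNode.read(io.StringIO(text))
    except Exception as exc:
        raise ValidationError(f"cannot parse Newick tree: {exc}") from exc
    return _validate_tree(tree)


def write_tree(tree: TreeNode, path) -> None:
    tree.write(str(path))


def total_branch_length(tree: TreeNode) -> float:
    """Sum of all branch lengths including the root stem (if any)."""
    total = tree.length or 0.0
    total += sum(n.length for n in tree.traverse(include_self=False))
    return total


def check_features_in_tree(table: CountTable, tree: TreeNode,
                           prune: bool = False) -> CountTable:
    """Verify every table feature is a tree leaf.

    Silent intersection hides bugs: missing features raise unless ``prune``
    was explicitly requested, in which case they are dropped from the table.
    """
    leaf_set = {t.name for t in tree.tips()}
    missing = [f for f in table.feature_ids if f not in leaf_set]
    if not missing:
        return table
    if not prune:
        raise ValidationError(
            f"{len(missing)} features absent from tree "
            f"(e.g. {missing[:5]}); pass prune=True to drop them"
        )
    keep = [f for f in table.feature_ids if f in leaf_set]
    return CountTable(table.data[keep])


# ---------------------------------------------------------------------------
# DistanceMatrix
# ---------------------------------------------------------------------------

def as_distance_matrix(values: np.ndarray, ids) -> skbio.DistanceMatrix:
    """Build a validated skbio DistanceMatrix (symmetry tol 1e-10)."""
    values = np.asarray(values, dtype=float)
    if values.ndim != 2 or values.shape[0] != values.shape[1]:
        raise ValidationError(f"distance matrix is not square: {values.shape}")
    if not np.allclose(values, values.T, atol=1e-10, rtol=0):
        raise ValidationError("distance matrix asymmetric beyond 1e-10")
    if np.any(np.diag(values) != 0):
        raise ValidationError("distance matrix diagonal is not zero")
    if np.any(values < 0):
        raise ValidationError("negative distances")
    sym = (values + values.T) / 2.0
    np.fill_diagonal(sym, 0.0)
    return skbio.DistanceMatrix(sym, ids=[str(i) for i in ids])


def write_distance_matrix(dm: skbio.DistanceMatrix, path) -> None:
    df = pd.DataFrame(dm.data, index=dm.ids, columns=dm.ids)
    df.to_csv(path, sep="\t", index_label="")


def read_distance_matrix(path) -> skbio.DistanceMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    row_ids = [str(i) for i in df.index]
    col_ids = [str(c) for c in df.columns]
    if row_ids != col_ids:
        raise ValidationError("row and column labels differ or are reordered")
    return as_distance_matrix(df.to_numpy(dtype=float), row_ids)


# ---------------------------------------------------------------------------
# GroupDesign
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GroupDesign:
    """Mapping from sample identifier to group label."""

    mapping: dict = field(default_factory=dict)

    def __post_init__(self):
        object.__setattr__(self, "mapping", dict(self.mapping))

    @property
    def sample_ids(self) -> list[str]:
        return list(self.mapping)

    @property
    def groups(self) -> list[str]:
        seen = {}
        for g in self.mapping.values():
            seen.setdefault(g, None)
        return list(seen)

    @property
    def n_groups(self) -> int:
        return len(self.groups)

    @property
    def group_sizes(self) -> dict:
        sizes: dict = {}
        for g in self.mapping.values():
            sizes[g] = sizes.get(g, 0) + 1
        return sizes

    def labels_for(self, sample_ids) -> np.ndarray:
        missing = [s for s in sample_ids if s not in self.mapping]
        if missing:
            raise ValidationError(f"samples without group label: {missing[:5]}")
        return np.asarray([self.mapping[s] for s in sample_ids])

    def require_groups(self, minimum: int = 2) -> None:
        if self.n_groups < minimum:
            raise ValidationError(
                f"need at least {minimum} groups, found {self.n_groups}"
            )

    @classmethod
    def from_labels(cls, sample_ids, labels) -> "GroupDesign":
        if len(sample_ids) != len(labels):
            raise ValidationError("sample_ids and labels differ in length")
        return cls(dict(zip(sample_ids, labels)))

    def to_tsv(self, path) -> None:
        pd.DataFrame(
            {"sample_id": list(self.mapping), "group": list(self.mapping.values())}
        ).to_csv(path, sep="\t", index=False)


def read_group_design(path) -> GroupDesign:
    df = pd.read_csv(path, sep="\t", dtype=str)
    if df.shape[1] < 2:
        raise ValidationError("group file needs two columns: sample_id, group")
    ids = df.iloc[:, 0].tolist()
    if len(set(ids)) != len(ids):
        raise ValidationError("duplicate sample identifiers in group file")
    return GroupDesign(dict(zip(ids, df.iloc[:, 1].tolist())))
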