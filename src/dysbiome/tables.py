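"""Core containers and plain-text I/O for microbiome count data.

The in-memory orientation is samples x taxa; on disk, abundance tables use
the QIIME-classic dialect of taxa as rows and samples as columns, with an
optional trailing ``lineage`` column holding Greengenes-style semicolon
lineages (``k__Bacteria;p__Firmicutes;...``). Trees are Newick via
scikit-bio; metadata is a flat TSV keyed by ``sample_id``.
"""

from __future__ import annotations

import io
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from skbio import TreeNode

logger = logging.getLogger(__name__)

#: Canonical taxonomic ranks, outermost first.
RANKS = ("kingdom", "phylum", "class", "order", "family", "genus", "species")

_RANK_PREFIXES = ("k__", "p__", "c__", "o__", "f__", "g__", "s__")

#: Closed set of cohort groups: physiological normal, pre-cancer, tumor.
GROUPS = ("PN", "PreT", "T")

Lineage = tuple  # length-7 tuple of Optional[str], one entry per rank


class TableFormatError(ValueError):
    """Raised when an on-disk table violates the format contract."""


def parse_lineage(text: Optional[str]) -> Lineage:
    """Parse ``k__Bacteria;p__Firmicutes;...`` into a 7-tuple of rank names.

    Rank prefixes are optional and stripped; empty or missing trailing ranks
    become ``None``. More than seven fields is a format error.
    """
    if text is None or (isinstance(text, float) and np.isnan(text)) or text == "":
        return (None,) * len(RANKS)
    parts = [p.strip() for p in str(text).split(";")]
    if len(parts) > len(RANKS):
        raise TableFormatError(f"lineage has {len(parts)} fields (> {len(RANKS)}): {text!r}")
    names = []
    for i, part in enumerate(parts):
        for pref in _RANK_PREFIXES:
            if part.startswith(pref):
                part = part[len(pref):]
                break
        names.append(part if part else None)
    names.extend([None] * (len(RANKS) - len(names)))
    return tuple(names)


def format_lineage(lineage: Lineage) -> str:
    """Render a lineage tuple back to prefixed semicolon form."""
    return ";".join(p + (n or "") for p, n in zip(_RANK_PREFIXES, lineage))


def _check_unique(ids: Sequence[str], what: str) -> None:
    seen = set()
    for x in ids:
        if x in seen:
            raise TableFormatError(f"duplicate {what} id: {x!r}")
        seen.add(x)


@dataclass
class AbundanceTable:
    """Taxon read counts per sample, with a ranked lineage for every taxon.

    ``data`` is a samples x taxa integer DataFrame; ``lineages`` maps every
    taxon id to a 7-tuple over :data:`RANKS` (missing ranks are ``None``).
    """

    data: pd.DataFrame
    lineages: dict = field(default_factory=dict)

    def __post_init__(self):
        _check_unique(list(self.data.index), "sample")
        _check_unique(list(self.data.columns), "taxon")
        values = self.data.to_numpy()
        if values.size and not np.issubdtype(values.dtype, np.integer):
            if not np.all(np.equal(np.mod(values, 1), 0)):
                raise TableFormatError("counts must be integers")
            self.data = self.data.astype(np.int64)
        if values.size and (self.data.to_numpy() < 0).any():
            raise TableFormatError("counts must be non-negative")
        lineages = dict(self.lineages)
        for t in self.data.columns:
            lin = lineages.get(t)
            lineages[t] = (None,) * len(RANKS) if lin is None else tuple(lin)
        self.lineages = lineages

    # -- accessors ---------------------------------------------------------
    @property
    def sample_ids(self) -> list:
        return list(self.data.index)

    @property
    def taxon_ids(self) -> list:
        return list(self.data.columns)

    @property
    def shape(self) -> tuple:
        return self.data.shape

    # -- transforms --------------------------------------------------------
    def to_relative(self) -> "RelativeAbundanceTable":
        """Per-sample closure: counts divided by the sample total."""
        totals = self.data.sum(axis=1)
        zero = totals[totals == 0]
        if len(zero):
            raise ValueError(f"zero-total sample(s): {list(zero.index)}")
        rel = self.data.div(totals, axis=0)
        return RelativeAbundanceTable(rel, dict(self.lineages))

    def aggregate_at_rank(self, rank: str) -> "AbundanceTable":
        """Sum taxa sharing the same lineage prefix through ``rank``.

        Taxa with no assignment at ``rank`` are pooled into a single
        ``Unclassified_<rank>`` bucket. Per-sample totals are conserved
        exactly (integer arithmetic).
        """
        if rank not in RANKS:
            raise ValueError(f"unknown rank {rank!r}; expected one of {RANKS}")
        ri = RANKS.index(rank)
        keys = {}  # prefix tuple (or None bucket) -> list of taxon ids
        for t in self.taxon_ids:
            lin = self.lineages[t]
            key = None if lin[ri] is None else tuple(lin[: ri + 1])
            keys.setdefault(key, []).append(t)

        # name aggregated taxa by the rank name; disambiguate collisions by
        # the full prefix
        name_counts = {}
        for key in keys:
            name = f"Unclassified_{rank}" if key is None else key[ri]
            name_counts[name] = name_counts.get(name, 0) + 1

        cols, lineages = {}, {}
        for key, members in keys.items():
            if key is None:
                name = f"Unclassified_{rank}"
                lin = (None,) * len(RANKS)
            else:
                name = key[ri]
                if name_counts[name] > 1:
                    name = ";".join(x or "" for x in key)
                lin = tuple(key) + (None,) * (len(RANKS) - len(key))
            cols[name] = self.data[members].sum(axis=1)
            lineages[name] = lin
        out = pd.DataFrame(cols, index=self.data.index)
        return AbundanceTable(out, lineages)

    def filter_samples(self, metadata: "SampleMetadata",
                       predicate: Callable[[pd.Series], bool]) -> "AbundanceTable":
        """Keep samples whose metadata row satisfies ``predicate``.

        All-zero taxa are retained for index stability.
        """
        keep = [s for s in metadata.frame.index if predicate(metadata.frame.loc[s])]
        if not keep:
            raise ValueError("predicate retained zero samples")
        missing = [s for s in keep if s not in self.data.index]
        if missing:
            raise ValueError(f"retained samples absent from table: {missing}")
        return AbundanceTable(self.data.loc[keep].copy(), dict(self.lineages))

    def drop_zero_taxa(self) -> "AbundanceTable":
        """Drop taxa with zero total count (logged), e.g. before statistics."""
        totals = self.data.sum(axis=0)
        zero = list(totals.index[totals == 0])
        if zero:
            logger.info("dropping %d all-zero taxa: %s", len(zero), zero)
            keep = [t for t in self.taxon_ids if t not in set(zero)]
            return AbundanceTable(self.data[keep].copy(),
                                  {t: self.lineages[t] for t in keep})
        return self


@dataclass
class RelativeAbundanceTable:
    """Per-sample fractional abundances; every row sums to one."""

    data: pd.DataFrame
    lineages: dict = field(default_factory=dict)

    def __post_init__(self):
        _check_unique(list(self.data.index), "sample")
        _check_unique(list(self.data.columns), "taxon")
        values = self.data.to_numpy(dtype=float)
        if values.size:
            if (values < -1e-12).any() or (values > 1 + 1e-12).any():
                raise ValueError("relative abundances must lie in [0, 1]")
            rows = values.sum(axis=1)
            bad = np.abs(rows - 1) > 1e-9
            if bad.any():
                raise ValueError(
                    f"sample rows must sum to 1: {list(self.data.index[bad])}")
        lineages = dict(self.lineages)
        for t in self.data.columns:
            lin = lineages.get(t)
            lineages[t] = (None,) * len(RANKS) if lin is None else tuple(lin)
        self.lineages = lineages

    @property
    def sample_ids(self) -> list:
        return list(self.data.index)

    @property
    def taxon_ids(self) -> list:
        return list(self.data.columns)


@dataclass
class SampleMetadata:
    """Sample annotations: group (PN/PreT/T), optional age, sex, stage.

    Missing optional fields are stored as explicit ``"unknown"`` (age as NaN),
    never dropped.
    """

    frame: pd.DataFrame

    def __post_init__(self):
        df = self.frame.copy()
        if df.index.name != "sample_id":
            if "sample_id" in df.columns:
                df = df.set_index("sample_id")
            else:
                df.index.name = "sample_id"
        _check_unique(list(df.index), "sample")
        if "group" not in df.columns:
            raise TableFormatError("metadata requires a 'group' column")
        bad = set(df["group"]) - set(GROUPS)
        if bad:
            raise TableFormatError(f"group values outside {GROUPS}: {sorted(bad)}")
        for col in ("sex", "stage"):
            if col not in df.columns:
                df[col] = "unknown"
            df[col] = df[col].fillna("unknown").replace("", "unknown")
        if "age" not in df.columns:
            df["age"] = np.nan
        df["age"] = pd.to_numeric(df["age"], errors="coerce")
        self.frame = df[["group", "age", "sex", "stage"]]

    @property
    def sample_ids(self) -> list:
        return list(self.frame.index)

    def groups(self, sample_ids: Optional[Sequence[str]] = None) -> pd.Series:
        """Group label per sample, optionally aligned to ``sample_ids``."""
        g = self.frame["group"]
        if sample_ids is not None:
            missing = [s for s in sample_ids if s not in g.index]
            if missing:
                raise ValueError(f"samples missing from metadata: {missing}")
            g = g.loc[list(sample_ids)]
        return g


@dataclass
class PhyloTree:
    """A rooted tree whose leaf labels are taxon ids; branch lengths >= 0."""

    tree: TreeNode

    def __post_init__(self):
        leaves = [n.name for n in self.tree.tips()]
        if len(leaves) < 2:
            raise ValueError("tree must have at least 2 leaves")
        _check_unique(leaves, "leaf")
        for node in self.tree.traverse(include_self=True):
            if node.length is not None and node.length < 0:
                raise ValueError(f"negative branch length at {node.name!r}")

    @property
    def leaf_names(self) -> list:
        return [n.name for n in self.tree.tips()]

    def total_branch_length(self) -> float:
        return sum(n.length or 0.0 for n in self.tree.traverse(include_self=True))

    def to_newick(self) -> str:
        buf = io.StringIO()
        self.tree.write(buf, format="newick")
        return buf.getvalue().strip()


# -- file I/O --------------------------------------------------------------

def read_abundance_table(path) -> AbundanceTable:
    """Read a taxa-by-samples TSV (first column taxon id, optional trailing
    ``lineage`` column) into an :class:`AbundanceTable`."""
    path = Path(path)
    with path.open() as fh:
        header = fh.readline().rstrip("\n").split("\t")
    sample_cols = [c for c in header[1:] if c != "lineage"]
    _check_unique(sample_cols, "sample column")
    df = pd.read_csv(path, sep="\t", dtype=str)
    taxa = df.iloc[:, 0].tolist()
    _check_unique(taxa, "taxon")
    lineages = {}
    if "lineage" in df.columns:
        for t, lin in zip(taxa, df["lineage"]):
            lineages[t] = parse_lineage(lin)
        df = df.drop(columns=["lineage"])
    counts = df.iloc[:, 1:].apply(pd.to_numeric)
    arr = counts.to_numpy()
    if not np.all(np.equal(np.mod(arr, 1), 0)):
        raise TableFormatError("non-integer count in table")
    if (arr < 0).any():
        raise TableFormatError("negative count in table")
    data = pd.DataFrame(arr.T.astype(np.int64), index=list(counts.columns),
                        columns=taxa)
    data.index.name = None
    return AbundanceTable(data, lineages)


def write_abundance_table(table: AbundanceTable, path) -> None:
    """Write the taxa-by-samples TSV dialect read by
    :func:`read_abundance_table`; deterministic column order."""
    out = table.data.T.copy()
    out.insert(0, "#TaxonID", out.index)
    out["lineage"] = [format_lineage(table.lineages[t]) for t in out.index]
    out.to_csv(path, sep="\t", index=False)


def read_metadata(path) -> SampleMetadata:
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str})
    if "sample_id" not in df.columns:
        raise TableFormatError("metadata requires a 'sample_id' column")
    return SampleMetadata(df)


def write_metadata(metadata: SampleMetadata, path) -> None:
    metadata.frame.to_csv(path, sep="\t", index=True, float_format="%g")


def read_tree(path) -> PhyloTree:
    """Read a rooted Newick tree; unlabeled internal nodes are permitted."""
    tree = TreeNode.read(str(path), format="newick")
    for node in tree.traverse(include_self=False):
        if node.length is None:
            node.length = 0.0
    return PhyloTree(tree)


def write_tree(tree: PhyloTree, path) -> None:
    tree.tree.write(str(path), format="newick")


# module-level aliases mirroring the method surface
def to_relative(table: AbundanceTable) -> RelativeAbundanceTable:
    return table.to_relative()


def aggregate_at_rank(table: AbundanceTable, rank: str) -> AbundanceTable:
    return table.aggregate_at_rank(rank)


def filter_samples(table: AbundanceTable, metadata: SampleMetadata,
                   predicate: Callable[[pd.Series], bool]) -> AbundanceTable:
    return table.filter_samples(metadata, predicate)
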