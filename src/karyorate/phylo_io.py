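"""Reading, validating, rescaling, and pruning phylogenies and trait tables.

Trees are carried as :class:`Phylogeny` objects, thin wrappers around a rooted
:class:`dendropy.Tree`.  Trait data travel as plain :class:`pandas.DataFrame`
objects with columns ``species``, ``haploid_n`` and ``state`` (see
:func:`read_trait_table`).  Taxon matching is exact-string after whitespace /
underscore normalisation: ``"Canis lupus"`` and ``"Canis_lupus"`` refer to the
same taxon.
"""

from __future__ import annotations

import io
import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import dendropy
import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "Phylogeny",
    "TreeSet",
    "read_tree_set",
    "write_tree_set",
    "read_trait_table",
    "write_trait_table",
    "scale_to_unit_height",
    "match_and_prune",
    "prune_taxa",
    "normalize_label",
]


def normalize_label(label: str) -> str:
    """Canonical form of a taxon label: trimmed, underscores as spaces."""
    return " ".join(str(label).replace("_", " ").split())


@dataclass
class Phylogeny:
    """A rooted phylogeny with branch lengths.

    Parameters
    ----------
    tree
        The underlying dendropy tree (rooted; polytomies allowed).
    height_my
        When the tree has been rescaled to unit root-to-tip height, the
        original height in millions of years; ``None`` for trees still in
        their native units.
    """

    tree: dendropy.Tree
    height_my: float | None = None

    @property
    def tip_labels(self) -> list[str]:
        return [normalize_label(leaf.taxon.label) for leaf in self.tree.leaf_node_iter()]

    @property
    def n_tips(self) -> int:
        return sum(1 for _ in self.tree.leaf_node_iter())

    def root_height(self) -> float:
        """Maximum root-to-tip distance."""
        return max(leaf.distance_from_root() for leaf in self.tree.leaf_node_iter())

    def is_ultrametric(self, rel_tol: float = 1e-6) -> bool:
        depths = [leaf.distance_from_root() for leaf in self.tree.leaf_node_iter()]
        h = max(depths)
        if h == 0:
            return True
        return (h - min(depths)) / h <= rel_tol

    def clone(self) -> "Phylogeny":
        return Phylogeny(self.tree.clone(depth=1), self.height_my)

    def as_newick(self) -> str:
        return self.tree.as_string(schema="newick", suppress_rooting=True).strip()


@dataclass
class TreeSet:
    """An ordered collection of phylogenies sharing one tip-label set."""

    trees: list[Phylogeny] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.trees:
            raise ValueError("TreeSet must contain at least one tree")
        ref = set(self.trees[0].tip_labels)
        for i, t in enumerate(self.trees[1:], start=1):
            if set(t.tip_labels) != ref:
                raise ValueError(
                    f"tree {i} has a tip set inconsistent with tree 0 "
                    f"(symmetric difference: {sorted(set(t.tip_labels) ^ ref)[:5]} ...)"
                )

    def __len__(self) -> int:
        return len(self.trees)

    def __iter__(self):
        return iter(self.trees)

    def __getitem__(self, i: int) -> Phylogeny:
        return self.trees[i]

    @property
    def tip_labels(self) -> list[str]:
        return self.trees[0].tip_labels


def _normalize_tree_labels(tree: dendropy.Tree) -> None:
    for taxon in tree.taxon_namespace:
        taxon.label = normalize_label(taxon.label)


def read_tree_set(path: str) -> TreeSet:
    """Read one or more Newick trees from ``path`` into a :class:`TreeSet`.

    Each tree gets its own taxon namespace so label sets may be validated
    independently.  Malformed Newick raises an error naming the tree index;
    inconsistent tip sets across trees raise a validation error.
    """
    with open(path) as fh:
        text = fh.read()
    # One tree per ';' -- robust to multi-line single trees and per-line files.
    chunks = [c.strip() for c in text.split(";") if c.strip()]
    trees: list[Phylogeny] = []
    for i, chunk in enumerate(chunks):
        try:
            tree = dendropy.Tree.get(
                data=chunk + ";",
                schema="newick",
                taxon_namespace=dendropy.TaxonNamespace(),
                rooting="default-rooted",
            )
        except Exception as exc:  # dendropy raises various parse errors
            raise ValueError(f"malformed Newick for tree index {i}: {exc}") from exc
        _normalize_tree_labels(tree)
        labels = [l.taxon.label for l in tree.leaf_node_iter()]
        if len(labels) != len(set(labels)):
            raise ValueError(f"tree index {i} has duplicate tip labels")
        trees.append(Phylogeny(tree))
    if not trees:
        raise ValueError(f"no trees found in {path}")
    return TreeSet(trees)


def write_tree_set(tree_set: TreeSet | Sequence[Phylogeny], path: str) -> None:
    """Write trees as Newick, one per line."""
    trees = tree_set.trees if isinstance(tree_set, TreeSet) else list(tree_set)
    with open(path, "w") as fh:
        for phy in trees:
            fh.write(phy.as_newick() + "\n")


def _sniff_sep(path: str) -> str:
    with open(path) as fh:
        header = fh.readline()
    return "\t" if header.count("\t") >= header.count(",") and "\t" in header else ","


def read_trait_table(path: str, state_col: str = "state") -> pd.DataFrame:
    """Read a delimited trait table with columns species, haploid_n, state.

    CSV/TSV is auto-detected from the header line.  Extra columns are kept
    (they may serve as substitute binary traits).  ``haploid_n`` must be a
    positive integer; ``state`` must have exactly two levels.
    """
    sep = _sniff_sep(path)
    df = pd.read_csv(path, sep=sep)
    required = {"species", "haploid_n"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"trait table missing columns: {sorted(missing)}")
    df = df.copy()
    df["species"] = df["species"].map(normalize_label)
    if df["species"].duplicated().any():
        dups = df.loc[df["species"].duplicated(), "species"].tolist()
        raise ValueError(f"duplicate species in trait table: {dups[:5]}")
    counts = pd.to_numeric(df["haploid_n"], errors="raise")
    if (counts < 1).any() or (counts != counts.round()).any():
        raise ValueError("haploid_n must be integers >= 1")
    df["haploid_n"] = counts.astype(int)
    if state_col in df.columns and not pd.api.types.is_numeric_dtype(df[state_col]):
        levels = sorted(df[state_col].astype(str).unique())
        if len(levels) != 2:
            raise ValueError(
                f"binary state column {state_col!r} must have exactly two levels, got {levels}"
            )
    # numeric state columns pass through: they are discretized downstream
    return df


def write_trait_table(df: pd.DataFrame, path: str) -> None:
    df.to_csv(path, sep="\t", index=False)


def scale_to_unit_height(phy: Phylogeny, mode: str = "height") -> Phylogeny:
    """Rescale a tree so that its root-to-tip height (or total length) is 1.

    ``mode='height'`` (default) divides every branch by the root-to-tip
    height, the scaling under which per-unit rates back-transform to per-MY
    rates by division with the recorded ``height_my``.  ``mode='length'``
    divides by the total branch length instead.  Height scaling requires an
    ultrametric tree (relative tolerance 1e-6); otherwise rates per MY are
    undefined.
    """
    if mode not in ("height", "length"):
        raise ValueError("mode must be 'height' or 'length'")
    if mode == "height" and not phy.is_ultrametric():
        raise ValueError("tree is not ultrametric within tolerance; cannot unit-height scale")
    denom = phy.root_height() if mode == "height" else sum(
        e.length or 0.0 for e in phy.tree.preorder_edge_iter() if e.length
    )
    if denom <= 0:
        raise ValueError("tree has zero height/length; cannot rescale")
    out = phy.clone()
    for edge in out.tree.preorder_edge_iter():
        if edge.length is not None:
            edge.length = edge.length / denom
    out.height_my = denom
    return out


def prune_taxa(phy: Phylogeny, drop: Iterable[str]) -> Phylogeny:
    """Remove the named tips; remaining patristic distances are preserved."""
    drop_set = {normalize_label(d) for d in drop}
    keep = [l for l in phy.tip_labels if l not in drop_set]
    if len(keep) < 2:
        raise ValueError("pruning would leave fewer than 2 tips")
    out = phy.clone()
    taxa = [t for t in out.tree.taxon_namespace if t.label in set(keep)]
    out.tree.retain_taxa(taxa)
    # dendropy can leave a unifurcation at the root; collapse it so the tree
    # stays strictly rooted with >=2 root children where possible.
    out.tree.suppress_unifurcations()
    return out


def match_and_prune(
    tree_set: TreeSet, traits: pd.DataFrame
) -> tuple[TreeSet, pd.DataFrame]:
    """Intersect tree tips with trait species; prune and reorder both.

    Returns trees pruned to the shared species and a trait table subset and
    reordered to the (first) tree's tip order.  Dropped names on both sides
    are logged.  Fewer than 4 shared species is an error: the likelihood is
    degenerate below that.
    """
    tip_set = set(tree_set.tip_labels)
    trait_set = set(traits["species"])
    shared = tip_set & trait_set
    if not shared:
        raise ValueError("no overlap between tree tips and trait species")
    if len(shared) < 4:
        raise ValueError(f"only {len(shared)} shared species; need at least 4")
    dropped_tips = sorted(tip_set - shared)
    dropped_traits = sorted(trait_set - shared)
    if dropped_tips:
        logger.info("dropping %d tree tips without traits: %s...", len(dropped_tips), dropped_tips[:5])
    if dropped_traits:
        logger.info("dropping %d trait rows without tips: %s...", len(dropped_traits), dropped_traits[:5])

    if dropped_tips:
        pruned = [prune_taxa(phy, dropped_tips) for phy in tree_set]
    else:
        pruned = [phy for phy in tree_set]
    new_set = TreeSet(pruned)
    order = new_set.tip_labels
    sub = traits[traits["species"].isin(shared)].set_index("species").loc[order].reset_index()
    return new_set, sub
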