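"""Branch-rate heterogeneity scan with autocorrelated rate bins.

Every branch is assigned one of a small grid of multiplicative rate scalars
(default 21 bins spanning 0.5-2).  The scan walks the tree in preorder
assuming the root sits in the bin nearest scalar 1; at each branch only the
parent's bin and its two neighbours are candidates, the branch length is
multiplied by each candidate scalar and the full-tree log-likelihood (all
other branches at their current assignment) decides.  Restricting candidates
to the parental neighbourhood enforces autocorrelation of rates along the
tree and guards against overfitting.  Scalar > 1 marks an elevated branch,
< 1 a depressed one; per-family proportions are averaged across a tree set.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import chrom_markov as cm
from .phylo_io import Phylogeny, TreeSet, normalize_label

logger = logging.getLogger(__name__)

__all__ = [
    "BinGrid",
    "BranchBinAssignment",
    "make_bin_grid",
    "assign_branch_bins",
    "summarize_clades",
]


@dataclass(frozen=True)
class BinGrid:
    """Equally spaced rate scalars from ``low`` to ``high`` inclusive."""

    low: float = 0.5
    high: float = 2.0
    n_bins: int = 21

    def __post_init__(self) -> None:
        if not self.low < self.high:
            raise ValueError("low must be < high")
        if self.n_bins < 2:
            raise ValueError("need at least 2 bins")

    @property
    def scalars(self) -> np.ndarray:
        return np.linspace(self.low, self.high, self.n_bins)

    @property
    def spacing(self) -> float:
        return (self.high - self.low) / (self.n_bins - 1)

    @property
    def root_bin(self) -> int:
        """Bin nearest scalar 1.0 — the root's assumed rate category."""
        return int(np.argmin(np.abs(self.scalars - 1.0)))


def make_bin_grid(low: float = 0.5, high: float = 2.0, n: int = 21) -> BinGrid:
    return BinGrid(low, high, n)


@dataclass
class BranchBinAssignment:
    """Per-branch result of the scan for one tree.

    ``table`` has one row per non-root node with columns ``node``,
    ``parent``, ``bin``, ``scalar`` and ``loglik`` (the full-tree
    log-likelihood at the moment the branch was assigned).
    """

    tindex: cm.TreeIndex
    grid: BinGrid
    bins: np.ndarray  # per-node bin index (root carries the pseudo-bin)
    table: pd.DataFrame
    final_loglik: float


def assign_branch_bins(
    phy: Phylogeny,
    traits: pd.DataFrame,
    mean_params: cm.RateParams,
    grid: BinGrid | None = None,
    space: cm.StateSpace | None = None,
    root_mode: str = "obs_weighted",
    state_col: str = "state",
    levels: tuple | None = None,
) -> BranchBinAssignment:
    """Greedy constrained preorder assignment of rate scalars to branches.

    ``mean_params`` is the pooled posterior-mean rate matrix from the fit;
    the generator stays fixed throughout and only branch lengths are scaled.
    Not-yet-visited branches inherit their nearest assigned ancestor's bin
    (the autocorrelated default): a candidate scalar is evaluated with the
    branch's whole unvisited subtree at that scalar, and descendants are
    revisited (and re-decided) at their own turn.  Because the parent's own
    bin is always among the candidates, every accepted move compares against
    the current configuration and the full-tree log-likelihood is
    non-decreasing over the scan.  Being greedy, the scan yields a
    constrained local optimum, not necessarily the global constrained argmax.
    Ties keep the parent's bin.  ``phy`` should be on the same scale the
    rates were estimated on (unit height).
    """
    grid = grid or BinGrid()
    if space is None:
        space = cm.state_space_from_counts(traits["haploid_n"])
    ti = cm.TreeIndex(phy)
    tip_idx = cm.tip_state_indices(ti, traits, space, state_col=state_col, levels=levels)
    engine = cm.LikelihoodEngine(ti, tip_idx, space)
    Q = cm.build_rate_matrix(mean_params, space)
    scalars = grid.scalars

    # subtree node lists (node itself included) for inheritance updates
    subtree: list[list[int]] = [[] for _ in range(ti.n_nodes)]
    for node in ti.postorder:
        subtree[node] = [node] + [n for c in ti.children[node] for n in subtree[c]]

    bins = np.full(ti.n_nodes, grid.root_bin, dtype=int)
    rows = []
    last_ll = None
    for node in ti.preorder:
        if ti.parent[node] < 0:
            continue  # root has no subtending branch
        parent_bin = bins[ti.parent[node]] if ti.parent[node] != 0 else bins[0]
        candidates = [b for b in (parent_bin - 1, parent_bin, parent_bin + 1)
                      if 0 <= b < grid.n_bins]
        best_bin, best_ll = None, -np.inf
        for b in candidates:
            bins[subtree[node]] = b  # subtree inherits the candidate
            ll = engine.loglik(Q, root_mode=root_mode,
                               branch_scalars=scalars[bins])
            if ll > best_ll + 1e-12 or (
                best_bin is None and np.isfinite(ll)
            ):
                best_bin, best_ll = b, ll
            elif abs(ll - best_ll) <= 1e-12 and b == parent_bin:
                best_bin = b  # tie -> inherit the parent's bin
        if best_bin is None:
            raise FloatingPointError(f"non-finite likelihood for every candidate at branch {node}")
        bins[subtree[node]] = best_bin
        last_ll = best_ll
        rows.append(dict(node=int(node), parent=int(ti.parent[node]),
                         bin=int(best_bin), scalar=float(scalars[best_bin]),
                         loglik=float(best_ll)))
    table = pd.DataFrame(rows)
    return BranchBinAssignment(ti, grid, bins, table, float(last_ll))


def _clade_nodes(ti: cm.TreeIndex, members: set[str]) -> list[int]:
    """Non-root nodes inside the MRCA subtree of the member tips."""
    member_ids = {ti.tip_ids[m] for m in members if m in ti.tip_ids}
    if len(member_ids) < 2:
        return sorted(member_ids)
    # MRCA by intersecting root paths
    paths = []
    for nid in member_ids:
        path = []
        n = nid
        while n >= 0:
            path.append(n)
            n = ti.parent[n]
        paths.append(path[::-1])
    mrca = 0
    for level in zip(*paths):
        if len(set(level)) == 1:
            mrca = level[0]
        else:
            break
    # collect subtree below the MRCA (excluding the MRCA's own stem branch)
    out, stack = [], list(ti.children[mrca])
    while stack:
        n = stack.pop()
        out.append(n)
        stack.extend(ti.children[n])
    return out


def summarize_clades(
    assignments: list[BranchBinAssignment],
    clade_map: dict[str, str] | pd.Series,
    min_taxa: int = 5,
) -> pd.DataFrame:
    """Per-family elevated/depressed branch proportions, averaged over trees.

    ``clade_map`` maps species -> family.  Families with fewer than
    ``min_taxa`` members present on the trees are excluded (logged).  A
    branch is elevated when its scalar > 1, depressed when < 1; a scalar of
    exactly 1 (possible only on grids containing it) counts as neither.
    """
    if isinstance(clade_map, pd.Series):
        clade_map = clade_map.to_dict()
    clade_map = {normalize_label(k): v for k, v in clade_map.items()}
    families: dict[str, set[str]] = {}
    for sp, fam in clade_map.items():
        families.setdefault(str(fam), set()).add(sp)

    rows = []
    for fam, members in sorted(families.items()):
        present = members & set(assignments[0].tindex.tip_ids)
        if len(present) < min_taxa:
            logger.info("family %s has %d taxa (<%d); excluded", fam, len(present), min_taxa)
            continue
        props_up, props_down, means = [], [], []
        for asg in assignments:
            nodes = _clade_nodes(asg.tindex, present)
            sc = asg.grid.scalars[asg.bins[nodes]]
            props_up.append(float((sc > 1).mean()))
            props_down.append(float((sc < 1).mean()))
            means.append(float(sc.mean()))
        rows.append(dict(family=fam, n_taxa=len(present),
                         prop_elevated=float(np.mean(props_up)),
                         prop_depressed=float(np.mean(props_down)),
                         mean_scalar=float(np.mean(means))))
    return pd.DataFrame(rows)
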