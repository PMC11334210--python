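"""Independent reference implementations used as oracles by the test suite.

Each function here recomputes a quantity by a different route than the
package (exhaustive enumeration, brute-force search, closed forms) so the
two can be compared on tiny inputs.
"""

from __future__ import annotations

import itertools

import dendropy
import numpy as np

from karyorate import chrom_markov as cm
from karyorate.phylo_io import Phylogeny


def phylo(newick: str, height_my: float | None = None) -> Phylogeny:
    tree = dendropy.Tree.get(data=newick, schema="newick", rooting="default-rooted")
    return Phylogeny(tree, height_my)


def enumeration_loglik(
    phy: Phylogeny,
    tip_states: dict[str, int],
    Q: np.ndarray,
    space: cm.StateSpace,
    root_mode: str = "obs_weighted",
) -> float:
    """Tree log-likelihood by summing over every interior-node assignment."""
    ti = cm.TreeIndex(phy)
    S = space.size
    P = {i: cm.transition_probabilities(Q, ti.blen[i])
         for i in range(ti.n_nodes) if ti.parent[i] >= 0}
    internal = [i for i in range(ti.n_nodes) if not ti.is_tip[i]]
    non_root_internal = [i for i in internal if i != 0]
    root_partial = np.zeros(S)
    for s_root in range(S):
        total = 0.0
        for assign in itertools.product(range(S), repeat=len(non_root_internal)):
            states = {0: s_root}
            states.update(dict(zip(non_root_internal, assign)))
            for label, nid in ti.tip_ids.items():
                states[nid] = tip_states[label]
            prob = 1.0
            for i in range(ti.n_nodes):
                if ti.parent[i] >= 0:
                    prob *= P[i][states[ti.parent[i]], states[i]]
            total += prob
        root_partial[s_root] = total
    if root_mode == "obs_weighted":
        lik = (root_partial**2).sum() / root_partial.sum()
    else:
        lik = root_partial.mean()
    return float(np.log(lik))


def enumeration_node_marginal(
    phy: Phylogeny,
    tip_states: dict[str, int],
    Q: np.ndarray,
    space: cm.StateSpace,
    node: int,
    root_mode: str = "flat",
) -> np.ndarray:
    """Marginal posterior of one interior node's state by enumeration."""
    ti = cm.TreeIndex(phy)
    S = space.size
    P = {i: cm.transition_probabilities(Q, ti.blen[i])
         for i in range(ti.n_nodes) if ti.parent[i] >= 0}
    internal = [i for i in range(ti.n_nodes) if not ti.is_tip[i]]

    def joint(states: dict[int, int]) -> float:
        prob = 1.0
        for i in range(ti.n_nodes):
            if ti.parent[i] >= 0:
                prob *= P[i][states[ti.parent[i]], states[i]]
        return prob

    # root-state weights
    if root_mode == "flat":
        pi = np.full(S, 1.0 / S)
    else:  # obs_weighted: weights proportional to the per-root-state likelihood
        per_root = np.zeros(S)
        for assign in itertools.product(range(S), repeat=len(internal)):
            states = dict(zip(internal, assign))
            for label, nid in ti.tip_ids.items():
                states[nid] = tip_states[label]
            per_root[states[0]] += joint(states)
        pi = per_root / per_root.sum()

    out = np.zeros(S)
    for assign in itertools.product(range(S), repeat=len(internal)):
        states = dict(zip(internal, assign))
        for label, nid in ti.tip_ids.items():
            states[nid] = tip_states[label]
        out[states[node]] += pi[states[0]] * joint(states)
    return out / out.sum()


def brute_force_hpd(samples, mass: float) -> tuple[float, float]:
    """Try every window of ceil(mass*n) sorted points; return the narrowest."""
    x = np.sort(np.asarray(samples, dtype=float))
    n = x.size
    k = int(np.ceil(mass * n))
    best = (np.inf, None, None)
    for i in range(n - k + 1):
        w = x[i + k - 1] - x[i]
        if w < best[0]:
            best = (w, x[i], x[i + k - 1])
    return float(best[1]), float(best[2])


def lhuilier_polygon_area(lon_deg, lat_deg, radius: float) -> float:
    """Spherical polygon area by fan triangulation + l'Huilier's theorem."""
    lon = np.radians(np.asarray(lon_deg, float))
    lat = np.radians(np.asarray(lat_deg, float))
    xyz = np.column_stack(
        [np.cos(lat) * np.cos(lon), np.cos(lat) * np.sin(lon), np.sin(lat)]
    )

    def angdist(a, b):
        return np.arctan2(np.linalg.norm(np.cross(a, b)), np.dot(a, b))

    total = 0.0
    for i in range(1, len(xyz) - 1):
        a, b, c = xyz[0], xyz[i], xyz[i + 1]
        ab, bc, ca = angdist(a, b), angdist(b, c), angdist(c, a)
        s = 0.5 * (ab + bc + ca)
        t = np.tan(s / 2) * np.tan((s - ab) / 2) * np.tan((s - bc) / 2) * np.tan((s - ca) / 2)
        total += 4.0 * np.arctan(np.sqrt(max(t, 0.0)))
    return float(total * radius**2)


def exhaustive_bin_search(engine, Q, grid, root_mode="obs_weighted"):
    """Global argmax over all constraint-respecting bin configurations.

    The constraint is the same autocorrelation rule the greedy scan uses:
    every branch's bin within +-1 of its parent branch's bin, the root
    pseudo-branch pinned to ``grid.root_bin``.  Among configurations tied on
    likelihood the one agreeing with parental inheritance at the earliest
    preorder branch wins (mirroring the greedy tie rule).
    """
    ti = engine.tindex
    branches = [i for i in ti.preorder if ti.parent[i] >= 0]
    best = (-np.inf, None)
    for assign in itertools.product(range(grid.n_bins), repeat=len(branches)):
        bins = np.full(ti.n_nodes, grid.root_bin, dtype=int)
        for node, b in zip(branches, assign):
            bins[node] = b
        ok = all(
            abs(bins[node] - (bins[ti.parent[node]] if ti.parent[node] != 0 else grid.root_bin)) <= 1
            for node in branches
        )
        if not ok:
            continue
        ll = engine.loglik(Q, root_mode=root_mode, branch_scalars=grid.scalars[bins])
        if ll > best[0] + 1e-12:
            best = (ll, bins.copy())
    return best
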