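"""Combined (chromosome count x binary hyperstate) Markov model.

The model follows the chromosome-number evolution tradition: a lineage's
haploid count k changes by single steps — fusion (k -> k-1, rate delta) and
fission (k -> k+1, rate gamma) — optionally by polyploidy (k -> 2k, rate rho,
constrained to 0 by default), while a binary "hyperstate" (here small vs.
large geographic range, a proxy for effective population size) flips at rates
q_SL / q_LS.  Fusion and fission rates are conditioned on the hyperstate, so
the combined state is the pair (count, hyperstate) and the generator acts on
the product space.

The tree likelihood is computed by Felsenstein's pruning algorithm over the
combined space, with per-node rescaling against underflow.  Transition
probabilities along branches are obtained from an eigendecomposition of the
generator (cached per Q), falling back to ``scipy.linalg.expm`` when the
decomposition is ill-conditioned; the two routes agree to well below 1e-10.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numba
import numpy as np
import pandas as pd
from scipy.linalg import expm

from .phylo_io import Phylogeny, normalize_label

__all__ = [
    "StateSpace",
    "RateParams",
    "build_state_space",
    "state_space_from_counts",
    "build_rate_matrix",
    "transition_probabilities",
    "TreeIndex",
    "LikelihoodEngine",
    "NodeMarginals",
    "hyperstate_codes",
    "tip_state_indices",
    "tree_log_likelihood",
    "marginal_ancestral_states",
]

SMALL, LARGE = 0, 1  # hyperstate codes


@dataclass(frozen=True)
class StateSpace:
    """Ordered product space of (haploid count, hyperstate) pairs.

    Indexing is count-major, hyperstate-minor: state ``2*(k - k_min) + h``
    is count ``k`` in hyperstate ``h`` (0 = small, 1 = large).
    """

    k_min: int
    k_max: int

    def __post_init__(self) -> None:
        if self.k_min < 1:
            raise ValueError("k_min must be >= 1")
        if self.k_max < self.k_min:
            raise ValueError("k_max must be >= k_min")

    @property
    def n_counts(self) -> int:
        return self.k_max - self.k_min + 1

    @property
    def size(self) -> int:
        return 2 * self.n_counts

    @property
    def states(self) -> list[tuple[int, int]]:
        return [(k, h) for k in range(self.k_min, self.k_max + 1) for h in (SMALL, LARGE)]

    def index(self, count: int, hyper: int) -> int:
        if not (self.k_min <= count <= self.k_max):
            raise ValueError(
                f"count {count} outside state space [{self.k_min}, {self.k_max}]; "
                "widen the bounds"
            )
        if hyper not in (SMALL, LARGE):
            raise ValueError("hyperstate must be 0 (small) or 1 (large)")
        return 2 * (count - self.k_min) + hyper

    @property
    def counts(self) -> np.ndarray:
        """Per-state chromosome count, aligned with the state index."""
        return np.repeat(np.arange(self.k_min, self.k_max + 1), 2)

    @property
    def hypers(self) -> np.ndarray:
        return np.tile(np.array([SMALL, LARGE]), self.n_counts)


def build_state_space(k_min: int, k_max: int) -> StateSpace:
    return StateSpace(k_min, k_max)


def state_space_from_counts(counts: Sequence[int], pad: int = 1) -> StateSpace:
    """Default bounds policy: one step of headroom beyond the observed range,
    floored at count 1, so boundary species can move in both directions."""
    counts = np.asarray(counts, dtype=int)
    return StateSpace(max(1, int(counts.min()) - pad), int(counts.max()) + pad)


@dataclass(frozen=True)
class RateParams:
    """The model's rates, per unit tree height.

    delta_* are fusion rates (count decrease), gamma_* fission rates (count
    increase), rho_* polyploidy (count doubling, 0 in the constrained model),
    q_SL / q_LS the hyperstate transition rates (S = small, L = large).
    """

    delta_S: float = 0.0
    delta_L: float = 0.0
    gamma_S: float = 0.0
    gamma_L: float = 0.0
    q_SL: float = 0.0
    q_LS: float = 0.0
    rho_S: float = 0.0
    rho_L: float = 0.0

    FREE_NAMES = ("delta_S", "delta_L", "gamma_S", "gamma_L", "q_SL", "q_LS")

    def __post_init__(self) -> None:
        for name in self.FREE_NAMES + ("rho_S", "rho_L"):
            if getattr(self, name) < 0:
                raise ValueError(f"rate {name} must be >= 0")

    def free_array(self) -> np.ndarray:
        return np.array([getattr(self, n) for n in self.FREE_NAMES], dtype=float)

    @classmethod
    def from_free_array(cls, x: Sequence[float], rho_S: float = 0.0, rho_L: float = 0.0) -> "RateParams":
        return cls(**dict(zip(cls.FREE_NAMES, map(float, x))), rho_S=rho_S, rho_L=rho_L)

    def scaled(self, factor: float) -> "RateParams":
        return replace(self, **{n: getattr(self, n) * factor for n in self.FREE_NAMES + ("rho_S", "rho_L")})


def build_rate_matrix(params: RateParams, space: StateSpace) -> np.ndarray:
    """Instantaneous rate matrix on the combined space.

    Moves: count +-1 within a hyperstate (rate gamma_h / delta_h), count
    doubling within a hyperstate (rho_h, only when 2k <= k_max), hyperstate
    flip at fixed count (q_SL, q_LS).  Moves that would leave the space get
    rate 0; the diagonal makes each row sum to zero.
    """
    n = space.size
    Q = np.zeros((n, n))
    delta = (params.delta_S, params.delta_L)
    gamma = (params.gamma_S, params.gamma_L)
    rho = (params.rho_S, params.rho_L)
    for k in range(space.k_min, space.k_max + 1):
        for h in (SMALL, LARGE):
            i = space.index(k, h)
            if k > space.k_min:
                Q[i, space.index(k - 1, h)] += delta[h]
            if k < space.k_max:
                Q[i, space.index(k + 1, h)] += gamma[h]
            if 2 * k <= space.k_max and rho[h] > 0:
                Q[i, space.index(2 * k, h)] += rho[h]
            j = space.index(k, LARGE if h == SMALL else SMALL)
            Q[i, j] += params.q_SL if h == SMALL else params.q_LS
    np.fill_diagonal(Q, Q.diagonal() - Q.sum(axis=1))
    return Q


def dump_matrix(M: np.ndarray, space: StateSpace, path: str) -> None:
    """Write Q or P(t) as tab-delimited text with (count,hyper) labels."""
    labels = [f"{k}{'SL'[h]}" for k, h in space.states]
    pd.DataFrame(M, index=labels, columns=labels).to_csv(path, sep="\t")


def transition_probabilities(Q: np.ndarray, t: float) -> np.ndarray:
    """P(t) = exp(Qt) via scaling-and-squaring; rows sum to 1 within 1e-9."""
    if t < 0:
        raise ValueError("elapsed time t must be >= 0")
    P = expm(Q * t)
    rowsum = P.sum(axis=1)
    if not np.allclose(rowsum, 1.0, atol=1e-9):
        raise FloatingPointError("transition matrix rows do not sum to 1")
    return np.clip(P, 0.0, 1.0)


def uniformized_transition_matrix(Q: np.ndarray, t: float) -> np.ndarray:
    """P(t) by uniformization: e^{-qt} sum_k (qt)^k/k! (I + Q/q)^k.

    Every term is nonnegative, so unlike expm or eigendecomposition there is
    no cancellation and tiny transition probabilities keep good *relative*
    accuracy — essential when ranking ancestral states that all require
    many-step count changes.  Truncation is generous: the Poisson tail plus
    the state-space diameter, so multi-step paths are never cut off.
    """
    if t < 0:
        raise ValueError("elapsed time t must be >= 0")
    n = Q.shape[0]
    q = float(-Q.diagonal().min())
    qt = q * t
    if qt == 0.0:
        return np.eye(n)
    if qt > 500:  # uniformization impractical; relative accuracy moot here
        return np.clip(expm(Q * t), 0.0, 1.0)
    M = np.maximum(np.eye(n) + Q / q, 0.0)
    K = int(np.ceil(qt + 8.0 * np.sqrt(qt + 1.0))) + n + 10
    T = np.eye(n)
    coeff = np.exp(-qt)
    P = coeff * T
    for k in range(1, K + 1):
        T = T @ M
        coeff *= qt / k
        P += coeff * T
    return np.clip(P, 0.0, 1.0)


class TreeIndex:
    """Array view of a rooted tree for fast repeated traversals.

    Nodes are numbered in preorder (root = 0).  ``children[i]`` lists the
    child ids of node i, ``blen[i]`` the length of the edge above node i
    (0 for the root), and ``postorder`` visits children before parents.
    """

    def __init__(self, phy: Phylogeny):
        nodes = list(phy.tree.preorder_node_iter())
        self.n_nodes = len(nodes)
        ids = {id(nd): i for i, nd in enumerate(nodes)}
        self.parent = np.full(self.n_nodes, -1, dtype=int)
        self.blen = np.zeros(self.n_nodes)
        self.children: list[list[int]] = [[] for _ in range(self.n_nodes)]
        self.tip_ids: dict[str, int] = {}
        for i, nd in enumerate(nodes):
            if nd.parent_node is not None:
                p = ids[id(nd.parent_node)]
                self.parent[i] = p
                self.children[p].append(i)
                self.blen[i] = nd.edge.length if nd.edge.length is not None else 0.0
            if nd.is_leaf():
                self.tip_ids[normalize_label(nd.taxon.label)] = i
        self.preorder = np.arange(self.n_nodes)
        self.postorder = self.preorder[::-1]
        self.is_tip = np.array([len(c) == 0 for c in self.children])
        self.height_my = phy.height_my

    @property
    def tip_labels(self) -> list[str]:
        return list(self.tip_ids)


def hyperstate_codes(states: Sequence, levels: tuple | None = None) -> tuple[np.ndarray, tuple]:
    """Map a two-level factor to 0/1 hyperstate codes.

    ``levels`` gives (small_level, large_level) explicitly; otherwise the
    literal levels {'small', 'large'} are recognised, else the sorted first
    level is taken as 'small'.  A table observing only one of the two levels
    is accepted (the other level is then unobserved at the tips).
    """
    vals = pd.Series(states).astype(str)
    uniq = sorted(vals.unique())
    if len(uniq) > 2 or len(uniq) == 0:
        raise ValueError(f"binary state must have at most two levels, got {uniq}")
    if levels is None:
        if set(uniq) <= {"small", "large"}:
            levels = ("small", "large")
        elif len(uniq) == 2:
            levels = tuple(uniq)
        else:
            raise ValueError(
                f"single observed level {uniq}; pass levels=(small, large) explicitly"
            )
    if not set(uniq) <= set(levels):
        raise ValueError(f"levels {levels} do not match data levels {uniq}")
    codes = np.where(vals.values == str(levels[0]), SMALL, LARGE)
    return codes, levels


def tip_state_indices(
    tindex: TreeIndex,
    traits: pd.DataFrame,
    space: StateSpace,
    state_col: str = "state",
    levels: tuple | None = None,
) -> np.ndarray:
    """Per-node combined-state index for tips (-1 for internal nodes)."""
    codes, _ = hyperstate_codes(traits[state_col], levels)
    by_species = {
        normalize_label(sp): (int(k), int(h))
        for sp, k, h in zip(traits["species"], traits["haploid_n"], codes)
    }
    out = np.full(tindex.n_nodes, -1, dtype=int)
    for label, nid in tindex.tip_ids.items():
        if label not in by_species:
            raise ValueError(f"tip {label!r} missing from trait table")
        k, h = by_species[label]
        out[nid] = space.index(k, h)
    return out


class _Propagator:
    """exp(Q t) action on vectors via eigendecomposition, with expm fallback."""

    def __init__(self, Q: np.ndarray):
        self.Q = Q
        self.n = Q.shape[0]
        self._expm_cache: dict[float, np.ndarray] = {}
        try:
            w, V = np.linalg.eig(Q)
            Vinv = np.linalg.inv(V)
            err = np.abs((V * w) @ Vinv - Q).max()
            ok = err <= 1e-9 * (1.0 + np.abs(Q).max())
        except np.linalg.LinAlgError:
            ok = False
        if ok:
            self.w = w.astype(np.complex128)
            self.V = V.astype(np.complex128)
            self.Vinv = Vinv.astype(np.complex128)
        else:  # defective or ill-conditioned generator
            self.w = None

    def matrix(self, t: float) -> np.ndarray:
        if self.w is not None:
            P = ((self.V * np.exp(self.w * t)) @ self.Vinv).real
            return np.clip(P, 0.0, 1.0)
        if t not in self._expm_cache:
            self._expm_cache[t] = np.clip(expm(self.Q * t), 0.0, 1.0)
        return self._expm_cache[t]

    def apply(self, t: float, x: np.ndarray) -> np.ndarray:
        """Return exp(Q t) @ x (x a conditional-likelihood vector)."""
        if self.w is not None:
            y = (self.V @ (np.exp(self.w * t) * (self.Vinv @ x))).real
            return np.maximum(y, 0.0)
        return self.matrix(t) @ x


@numba.njit(cache=True)
def _prune_eigen_kernel(order, parent, is_tip, children_flat, child_start,
                        child_count, tip_idx, blen, V, Vinv, w):
    """Pruning pass with the eigen-propagator, compiled for speed.

    Returns (root partial vector, accumulated log scale); log scale is -inf
    when a partial underflows to all zeros.
    """
    n, S = order.shape[0], w.shape[0]
    partials = np.zeros((n, S))
    messages = np.zeros((n, S))
    y = np.zeros(S, dtype=np.complex128)
    log_scale = 0.0
    for oi in range(n):
        i = order[oi]
        if is_tip[i]:
            partials[i, tip_idx[i]] = 1.0
        else:
            m = 0.0
            for s in range(S):
                prod = 1.0
                for ci in range(child_count[i]):
                    prod *= messages[children_flat[child_start[i] + ci], s]
                partials[i, s] = prod
                if prod > m:
                    m = prod
            if m <= 0.0 or not np.isfinite(m):
                return partials[0], -np.inf
            for s in range(S):
                partials[i, s] /= m
            log_scale += np.log(m)
        if parent[i] >= 0:
            t = blen[i]
            for r in range(S):
                acc = 0.0 + 0.0j
                for c in range(S):
                    acc += Vinv[r, c] * partials[i, c]
                y[r] = acc * np.exp(w[r] * t)
            for r in range(S):
                acc = 0.0 + 0.0j
                for c in range(S):
                    acc += V[r, c] * y[c]
                v = acc.real
                messages[i, r] = v if v > 0.0 else 0.0
    return partials[0], log_scale


class LikelihoodEngine:
    """Pruning likelihood over the combined space for one indexed tree.

    Built once per (tree, data, space); ``loglik(Q)`` may then be called many
    times with different generators (the MCMC's inner loop), optionally with
    per-node branch scalars (the rate-bin scan).
    """

    def __init__(self, tindex: TreeIndex, tip_idx: np.ndarray, space: StateSpace):
        self.tindex = tindex
        self.space = space
        self.tip_idx = tip_idx
        self._prop: _Propagator | None = None
        self._prop_key: bytes | None = None
        # flattened child lists for the compiled pruning kernel
        counts = np.array([len(c) for c in tindex.children], dtype=np.int64)
        self._child_count = counts
        self._child_start = np.concatenate([[0], np.cumsum(counts)[:-1]]).astype(np.int64)
        self._children_flat = np.array(
            [c for kids in tindex.children for c in kids], dtype=np.int64)
        self._order = tindex.postorder.astype(np.int64)
        self._parent = tindex.parent.astype(np.int64)
        self._is_tip = tindex.is_tip.astype(np.bool_)
        self._tip_idx64 = tip_idx.astype(np.int64)

    def _propagator(self, Q: np.ndarray) -> _Propagator:
        key = Q.tobytes()
        if self._prop_key != key:
            self._prop = _Propagator(Q)
            self._prop_key = key
        return self._prop

    def _down_pass(
        self, Q: np.ndarray, branch_scalars: np.ndarray | None = None
    ) -> tuple[np.ndarray, np.ndarray, float]:
        """Return (partials, edge_messages, log_scale).

        ``partials[i]`` is the rescaled conditional likelihood of the data
        below node i given each state at i; ``edge_messages[i]`` is
        P(t_i) @ partials[i], the message node i sends to its parent.
        """
        ti, S = self.tindex, self.space.size
        prop = self._propagator(Q)
        partials = np.zeros((ti.n_nodes, S))
        messages = np.zeros((ti.n_nodes, S))
        log_scale = 0.0
        blen = ti.blen if branch_scalars is None else ti.blen * branch_scalars
        for i in ti.postorder:
            if ti.is_tip[i]:
                partials[i, self.tip_idx[i]] = 1.0
            else:
                prod = np.ones(S)
                for c in ti.children[i]:
                    prod *= messages[c]
                m = prod.max()
                if m <= 0.0 or not np.isfinite(m):
                    return partials, messages, -np.inf
                prod /= m
                log_scale += np.log(m)
                partials[i] = prod
            if ti.parent[i] >= 0:
                messages[i] = prop.apply(blen[i], partials[i])
        return partials, messages, log_scale

    def loglik(
        self,
        Q: np.ndarray,
        root_mode: str = "obs_weighted",
        branch_scalars: np.ndarray | None = None,
    ) -> float:
        prop = self._propagator(Q)
        blen = self.tindex.blen if branch_scalars is None else self.tindex.blen * branch_scalars
        if prop.w is not None:
            L, log_scale = _prune_eigen_kernel(
                self._order, self._parent, self._is_tip, self._children_flat,
                self._child_start, self._child_count, self._tip_idx64,
                blen.astype(np.float64), prop.V, prop.Vinv, prop.w)
        else:
            partials, _, log_scale = self._down_pass(Q, branch_scalars)
            L = partials[0]
        if not np.isfinite(log_scale):
            return -np.inf
        total = L.sum()
        if total <= 0:
            return -np.inf
        if root_mode == "obs_weighted":  # FitzJohn-style data-driven root weights
            lik = float((L * L).sum() / total)
        elif root_mode == "flat":
            lik = float(total / self.space.size)
        else:
            raise ValueError("root_mode must be 'obs_weighted' or 'flat'")
        if lik <= 0:
            return -np.inf
        ll = np.log(lik) + log_scale
        if not np.isfinite(ll):
            raise FloatingPointError("non-finite log-likelihood")
        return ll


@dataclass
class NodeMarginals:
    """Marginal posterior state distributions at every node of one tree."""

    tindex: TreeIndex
    space: StateSpace
    probs: np.ndarray  # (n_nodes, space.size), each row sums to 1

    def count_marginal(self, node: int) -> np.ndarray:
        """Distribution over counts, hyperstate marginalised out."""
        return self.probs[node].reshape(-1, 2).sum(axis=1)

    def most_probable_count(self, node: int) -> int:
        cm = self.count_marginal(node)
        # ties broken toward the lower count (argmax returns the first max)
        return int(self.space.k_min + int(np.argmax(cm)))


def marginal_ancestral_states(
    engine: LikelihoodEngine,
    Q: np.ndarray,
    root_mode: str = "obs_weighted",
) -> NodeMarginals:
    """Marginal ancestral state distributions by a down-pass / up-pass sweep.

    For each node the marginal combines the conditional likelihood of the
    data below it with the contribution of the rest of the tree passed down
    from the root; root state weights follow ``root_mode``.  Transition
    matrices come from uniformization so that states reachable only through
    many-step count changes are ranked by true (if tiny) probabilities
    rather than dense-exponential roundoff.
    """
    ti, space = engine.tindex, engine.space
    S = space.size
    P = {int(i): uniformized_transition_matrix(Q, float(ti.blen[i]))
         for i in range(ti.n_nodes) if ti.parent[i] >= 0}
    partials = np.zeros((ti.n_nodes, S))
    messages = np.zeros((ti.n_nodes, S))
    for i in ti.postorder:
        if ti.is_tip[i]:
            partials[i, engine.tip_idx[i]] = 1.0
        else:
            prod = np.ones(S)
            for c in ti.children[i]:
                prod *= messages[c]
            m = prod.max()
            if m <= 0:
                raise FloatingPointError("data have zero likelihood under Q")
            partials[i] = prod / m
        if ti.parent[i] >= 0:
            messages[i] = P[i] @ partials[i]
    up = np.zeros((ti.n_nodes, S))
    D = partials[0]
    pi = D / D.sum() if root_mode == "obs_weighted" else np.full(S, 1.0 / S)
    up[0] = pi
    probs = np.zeros((ti.n_nodes, S))
    for i in ti.preorder:
        post = up[i] * partials[i]
        tot = post.sum()
        if tot <= 0:
            raise FloatingPointError(f"zero marginal at node {i}")
        probs[i] = post / tot
        kids = ti.children[i]
        for c in kids:
            sib = up[i].copy()
            for b in kids:
                if b != c:
                    sib *= messages[b]
            contrib = P[c].T @ sib
            m = contrib.max()
            up[c] = contrib / m if m > 0 else contrib
    return NodeMarginals(ti, space, probs)


# -- convenience wrappers on Phylogeny + trait table ------------------------

def _engine_for(
    phy: Phylogeny,
    traits: pd.DataFrame,
    space: StateSpace,
    state_col: str = "state",
    levels: tuple | None = None,
) -> LikelihoodEngine:
    ti = TreeIndex(phy)
    tip_idx = tip_state_indices(ti, traits, space, state_col=state_col, levels=levels)
    return LikelihoodEngine(ti, tip_idx, space)


def tree_log_likelihood(
    phy: Phylogeny,
    traits: pd.DataFrame,
    Q: np.ndarray,
    space: StateSpace,
    root_mode: str = "obs_weighted",
    state_col: str = "state",
    levels: tuple | None = None,
) -> float:
    """One-shot pruning log-likelihood for a tree / trait table / generator."""
    return _engine_for(phy, traits, space, state_col, levels).loglik(Q, root_mode=root_mode)
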