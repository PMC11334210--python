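"""Synthetic data: trees, chromosome counts, binary traits, and experiments.

Everything the pipeline consumes can be generated here: ultrametric
birth-death trees (standing in for an empirical posterior tree set), joint
(count, hyperstate) chromosome-number histories simulated exactly by
Gillespie sampling with the same move set the likelihood uses, neutral binary
traits, plus the two simulation experiments built on top — the neutral-trait
false-positive experiment and the variance adequacy check.

Defaults emulate the study conditions: ~110-tip trees, root haploid count 19
(the inferred ancestral carnivoran count), root hyperstate drawn with
probability 0.5, binary traits flipping at rate 2 on unit-height trees.
Simulated counts are floored at 1 and carry no upper cap; the fitted model's
state-space bounds are an inference choice, not a biological one.
"""

from __future__ import annotations

import dataclasses
import random
from dataclasses import dataclass, field

import dendropy
import numpy as np
import pandas as pd
from dendropy.simulate import treesim

from . import chrom_markov as cm
from .bayes_fit import McmcSettings, PosteriorSet, PriorSpec, fit_tree_set
from .phylo_io import Phylogeny, TreeSet
from .rate_stats import delta_r

__all__ = [
    "SimConfig",
    "SimulatedDataset",
    "simulate_tree",
    "simulate_tree_set",
    "simulate_chromosomes",
    "simulate_binary_trait",
    "replay_events",
    "false_positive_experiment",
    "variance_adequacy",
]


@dataclass(frozen=True)
class SimConfig:
    """Generating conditions for a simulated dataset."""

    n_tips: int = 110
    birth: float = 1.0
    death: float = 0.0
    params: cm.RateParams = field(default_factory=lambda: cm.RateParams(
        delta_S=1.5, delta_L=0.25, gamma_S=1.5, gamma_L=0.25, q_SL=2.0, q_LS=2.0))
    root_count: int = 19
    root_small_prob: float = 0.5
    neutral_rate: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.root_small_prob <= 1:
            raise ValueError("root_small_prob must be in [0, 1]")
        if self.root_count < 1:
            raise ValueError("root_count must be >= 1")


@dataclass
class SimulatedDataset:
    """A simulated tree + trait table with its full event history."""

    phylogeny: Phylogeny
    traits: pd.DataFrame  # species, haploid_n, state
    events: pd.DataFrame  # node, time, kind, k_from, h_from, k_to, h_to
    root_state: tuple[int, int]  # (count, hyperstate code)
    config: SimConfig


def _rng(seed_or_rng) -> np.random.Generator:
    if isinstance(seed_or_rng, np.random.Generator):
        return seed_or_rng
    return np.random.default_rng(seed_or_rng)


def simulate_tree(
    n_tips: int, birth: float = 1.0, death: float = 0.0,
    seed: int | np.random.Generator = 0, max_retries: int = 50,
) -> Phylogeny:
    """Ultrametric birth-death tree conditioned on the number of extant tips.

    Simulated with the general sampling approach (run on to a larger tip
    count, then sample a time slice during which exactly ``n_tips`` lineages
    existed), which avoids the zero-length pendant cherries of naive
    stop-at-n simulation.  The stem edge is dropped: trees start at their
    root split.
    """
    if n_tips < 3:
        raise ValueError("need at least 3 tips")
    if not birth > death >= 0:
        raise ValueError("need birth > death >= 0")
    rng = _rng(seed)
    last = None
    for _ in range(max_retries):
        py_seed = int(rng.integers(0, 2**31 - 1))
        try:
            tree = treesim.birth_death_tree(
                birth_rate=birth, death_rate=death,
                num_extant_tips=n_tips, gsa_ntax=n_tips + max(2, n_tips // 10),
                rng=random.Random(py_seed),
            )
        except Exception as exc:  # total extinction; retry
            last = exc
            continue
        tree.seed_node.edge.length = None
        for i, leaf in enumerate(tree.leaf_node_iter()):
            leaf.taxon.label = f"sp{i + 1:04d}"
        return Phylogeny(tree)
    raise RuntimeError(f"birth-death simulation failed after {max_retries} tries: {last}")


def simulate_tree_set(
    n_trees: int, n_tips: int, birth: float = 1.0, death: float = 0.0,
    seed: int | np.random.Generator = 0,
) -> TreeSet:
    rng = _rng(seed)
    return TreeSet([simulate_tree(n_tips, birth, death, rng) for _ in range(n_trees)])


_EVENT_COLS = ["node", "time", "kind", "k_from", "h_from", "k_to", "h_to"]


def _branch_gillespie(k, h, t_total, p: cm.RateParams, rng, node, events):
    """Exact CTMC simulation of (count, hyperstate) along one branch."""
    delta = (p.delta_S, p.delta_L)
    gamma = (p.gamma_S, p.gamma_L)
    rho = (p.rho_S, p.rho_L)
    q = (p.q_SL, p.q_LS)
    t = 0.0
    while True:
        r_fus = delta[h] if k > 1 else 0.0  # counts floored at 1
        r_fis = gamma[h]
        r_rho = rho[h]
        r_flip = q[h]
        total = r_fus + r_fis + r_rho + r_flip
        if total <= 0:
            return k, h
        t += rng.exponential(1.0 / total)
        if t >= t_total:
            return k, h
        u = rng.random() * total
        k0, h0 = k, h
        if u < r_fus:
            k, kind = k - 1, "fusion"
        elif u < r_fus + r_fis:
            k, kind = k + 1, "fission"
        elif u < r_fus + r_fis + r_rho:
            k, kind = 2 * k, "polyploidy"
        else:
            h, kind = 1 - h, "flip"
        events.append((node, t, kind, k0, h0, k, h))


def simulate_chromosomes(
    phy: Phylogeny, config: SimConfig,
    rng: np.random.Generator | None = None,
) -> SimulatedDataset:
    """Simulate a joint (count, hyperstate) history down a tree.

    The tree must be on the same scale as the generating rates (unit height
    for the defaults).  The root count is fixed by the config and the root
    hyperstate drawn Bernoulli(root_small_prob) for 'small'.
    """
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    ti = cm.TreeIndex(phy)
    root_h = cm.SMALL if rng.random() < config.root_small_prob else cm.LARGE
    state = {0: (config.root_count, root_h)}
    events: list[tuple] = []
    for node in ti.preorder:
        if ti.parent[node] < 0:
            continue
        k, h = state[ti.parent[node]]
        state[node] = _branch_gillespie(k, h, ti.blen[node], config.params,
                                        rng, int(node), events)
    names = {cm.SMALL: "small", cm.LARGE: "large"}
    rows = [
        dict(species=label, haploid_n=state[nid][0], state=names[state[nid][1]])
        for label, nid in ti.tip_ids.items()
    ]
    traits = pd.DataFrame(rows)
    ev = pd.DataFrame(events, columns=_EVENT_COLS)
    return SimulatedDataset(phy, traits, ev, (config.root_count, root_h), config)


def replay_events(dataset: SimulatedDataset) -> pd.DataFrame:
    """Recompute tip states by replaying the event log from the root."""
    ti = cm.TreeIndex(dataset.phylogeny)
    state = {0: dataset.root_state}
    by_node = {n: grp.sort_values("time") for n, grp in dataset.events.groupby("node")}
    for node in ti.preorder:
        if ti.parent[node] < 0:
            continue
        k, h = state[ti.parent[node]]
        if node in by_node:
            last = by_node[node].iloc[-1]
            k, h = int(last["k_to"]), int(last["h_to"])
        state[node] = (k, h)
    names = {cm.SMALL: "small", cm.LARGE: "large"}
    rows = [dict(species=label, haploid_n=state[nid][0], state=names[state[nid][1]])
            for label, nid in ti.tip_ids.items()]
    return pd.DataFrame(rows)


def simulate_binary_trait(
    phy: Phylogeny, rate: float = 2.0,
    seed: int | np.random.Generator = 0,
    names: tuple[str, str] = ("small", "large"),
) -> pd.DataFrame:
    """Neutral symmetric two-state character; root state uniform.

    Returns a table with ``species`` and ``state``; the total number of
    state flips over the whole tree is recorded in the frame's ``n_events``
    attr (useful for checking the Poisson event-count expectation).
    """
    if rate < 0:
        raise ValueError("rate must be >= 0")
    rng = _rng(seed)
    ti = cm.TreeIndex(phy)
    state = {0: int(rng.integers(0, 2))}
    n_events = 0
    for node in ti.preorder:
        if ti.parent[node] < 0:
            continue
        s = state[ti.parent[node]]
        t_total = ti.blen[node]
        if rate > 0:
            t = 0.0
            while True:
                t += rng.exponential(1.0 / rate)
                if t >= t_total:
                    break
                s = 1 - s
                n_events += 1
        state[node] = s
    rows = [dict(species=label, state=names[state[nid]])
            for label, nid in ti.tip_ids.items()]
    out = pd.DataFrame(rows)
    out.attrs["n_events"] = n_events
    return out


def false_positive_experiment(
    tree_set: TreeSet,
    counts: pd.DataFrame,
    n_neutral: int,
    prior: PriorSpec | None = None,
    settings: McmcSettings | None = None,
    neutral_rate: float = 2.0,
    reference: dict[str, float] | None = None,
    seed: int = 0,
) -> tuple[pd.DataFrame, dict]:
    """Neutral-trait false-positive experiment.

    Chromosome counts are held fixed while ``n_neutral`` neutral binary
    traits are simulated (trait i on tree i mod n_trees, one trait per tree)
    and each is analysed exactly like an empirical trait.  Reported: the
    fraction of traits whose fusion / fission ΔR 95% HPD excludes 0 (the
    false-positive rate), and, when ``reference`` gives empirical mean ΔR
    values, the fraction whose |mean ΔR| reaches them.

    Fit failures are collected in the per-trait table, not fatal.
    """
    prior = prior or PriorSpec()
    settings = settings or McmcSettings()
    rows = []
    counts = counts.drop(columns=[c for c in ("state",) if c in counts.columns])
    for i in range(n_neutral):
        phy = tree_set[i % len(tree_set)]
        trait = simulate_binary_trait(
            phy, neutral_rate, np.random.default_rng(np.random.SeedSequence([seed, i])))
        merged = counts.merge(trait, on="species")
        rep = dict(trait=i, tree=i % len(tree_set))
        try:
            sub_settings = dataclasses.replace(settings, seed=settings.seed + i)
            post = fit_tree_set(TreeSet([phy]), merged, prior, sub_settings)
            for which in ("fusion", "fission"):
                s = delta_r(post, which)
                rep[f"{which}_mean"] = s.mean
                rep[f"{which}_hpd_low"] = s.hpd_low
                rep[f"{which}_hpd_high"] = s.hpd_high
                rep[f"{which}_excludes_zero"] = s.support != "indeterminate"
            rep["error"] = ""
        except Exception as exc:
            rep["error"] = str(exc)
        rows.append(rep)
    table = pd.DataFrame(rows)
    summary: dict = dict(n_neutral=n_neutral)
    ok = table[table.get("error", pd.Series(dtype=str)) == ""] if len(table) else table
    for which in ("fusion", "fission"):
        if len(ok):
            summary[f"fp_rate_{which}"] = float(ok[f"{which}_excludes_zero"].mean())
            summary[f"mean_delta_r_{which}"] = float(ok[f"{which}_mean"].mean())
            if reference and which in reference:
                summary[f"frac_as_extreme_{which}"] = float(
                    (ok[f"{which}_mean"].abs() >= abs(reference[which])).mean())
        else:
            summary[f"fp_rate_{which}"] = np.nan
            summary[f"mean_delta_r_{which}"] = np.nan
    summary["n_failed"] = int((table["error"] != "").sum()) if len(table) else 0
    return table, summary


def variance_adequacy(
    observed: pd.DataFrame, simulated: list[SimulatedDataset | pd.DataFrame]
) -> dict:
    """Compare tip-count variance between observed and simulated datasets.

    Uses the sample variance (n-1 denominator).  Reports the observed
    variance, the simulated min/mean/max, and the observed value's quantile
    among the simulated values.
    """
    if not simulated:
        raise ValueError("need at least one simulated dataset")

    def _var(df) -> float:
        counts = (df.traits if isinstance(df, SimulatedDataset) else df)["haploid_n"]
        return float(np.var(counts.to_numpy(float), ddof=1))

    obs = _var(observed)
    sims = np.array([_var(s) for s in simulated])
    return dict(
        observed_variance=obs,
        simulated_min=float(sims.min()),
        simulated_mean=float(sims.mean()),
        simulated_max=float(sims.max()),
        observed_quantile=float((sims <= obs).mean()),
        n_simulated=len(sims),
    )
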