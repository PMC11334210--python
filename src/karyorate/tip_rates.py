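"""Per-species ("tip") rates of chromosome number change.

A tip rate is |tip count - most probable count of the tip's immediate
ancestor| divided by the connecting branch length in MY.  Ancestral counts
come from marginal ancestral state reconstruction under the fitted model
(pooled posterior-mean rates on the unit-height tree), with the hyperstate
marginalised out before taking the most probable count.  The metric flags
whether a handful of outlier species drives clade-level rate estimates.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from . import chrom_markov as cm
from .phylo_io import Phylogeny, scale_to_unit_height

logger = logging.getLogger(__name__)

__all__ = ["get_tip_rates", "summarize_tip_rates"]


def get_tip_rates(
    phy: Phylogeny,
    traits: pd.DataFrame,
    mean_params: cm.RateParams,
    space: cm.StateSpace | None = None,
    root_mode: str = "obs_weighted",
    state_col: str = "state",
    levels: tuple | None = None,
    count_only: bool = False,
) -> pd.DataFrame:
    """Tip-rate table for one tree in MY units.

    ``phy`` must be in MY units (ultrametric); internally the tree is scaled
    to unit height for the reconstruction (matching the scale on which
    ``mean_params`` was estimated) while branch lengths in MY are used for
    the rate division.  ``count_only=True`` collapses the hyperstate by
    averaging the state-pair rates before reconstruction.

    Zero-length terminal branches with a count change yield an undefined
    rate, reported as NaN with a warning.
    """
    if space is None:
        space = cm.state_space_from_counts(traits["haploid_n"])
    if count_only:
        d = 0.5 * (mean_params.delta_S + mean_params.delta_L)
        g = 0.5 * (mean_params.gamma_S + mean_params.gamma_L)
        mean_params = cm.RateParams(d, d, g, g, mean_params.q_SL, mean_params.q_LS)
    unit = phy if phy.height_my is not None else scale_to_unit_height(phy)
    height = unit.height_my
    ti = cm.TreeIndex(unit)
    tip_idx = cm.tip_state_indices(ti, traits, space, state_col=state_col, levels=levels)
    engine = cm.LikelihoodEngine(ti, tip_idx, space)
    Q = cm.build_rate_matrix(mean_params, space)
    marg = cm.marginal_ancestral_states(engine, Q, root_mode=root_mode)

    counts_by_sp = dict(zip(traits["species"], traits["haploid_n"].astype(int)))
    states_by_sp = dict(zip(traits["species"], traits[state_col].astype(str)))
    rows = []
    for label, nid in ti.tip_ids.items():
        parent = ti.parent[nid]
        anc = marg.most_probable_count(parent)
        tip_count = counts_by_sp[label]
        blen_my = ti.blen[nid] * height  # back to MY
        diff = abs(tip_count - anc)
        if blen_my <= 0 and diff > 0:
            logger.warning("zero-length terminal branch with count change at %s", label)
            rate = np.nan
        elif blen_my <= 0:
            rate = 0.0
        else:
            rate = diff / blen_my
        rows.append(
            dict(species=label, tip_count=tip_count, ancestral_count=anc,
                 branch_length_my=blen_my, tip_rate=rate,
                 binary_state=states_by_sp[label])
        )
    return pd.DataFrame(rows)


def summarize_tip_rates(table: pd.DataFrame) -> dict:
    """Grouped summary: per-state mean rate and zero/non-zero tallies."""
    if table.empty:
        raise ValueError("tip-rate table is empty")
    by_state = {}
    for state, grp in table.groupby("binary_state"):
        rates = grp["tip_rate"].dropna()
        by_state[state] = dict(
            mean_tip_rate=float(rates.mean()) if len(rates) else np.nan,
            n_zero=int((rates == 0).sum()),
            n_nonzero=int((rates > 0).sum()),
        )
    valid = table.dropna(subset=["tip_rate"])
    max_rate = float(valid["tip_rate"].max()) if len(valid) else np.nan
    max_species = sorted(valid.loc[valid["tip_rate"] == max_rate, "species"]) if len(valid) else []
    return dict(by_state=by_state, max_tip_rate=max_rate, max_species=max_species)
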