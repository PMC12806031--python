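"""Pathway-level proton (H+) accounting.

Each reaction carries a net proton stoichiometric coefficient h_r
(positive = H+ produced per unit flux). A pathway's proton factor h_i
is the arithmetic mean of h_r over its reactions, its proton flux is
J_i = v_i * h_i, and production shares divide the positive part of J
by the total positive production (a net proton-consuming pathway
contributes a 0% share). The ledger is exactly linear in the fluxes,
so the shares are invariant to the arbitrary units of glucose uptake.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from glucoflux.errors import DomainError
from glucoflux.network import Reaction, StoichiometricNetwork


def pathway_proton_factor(reactions: list[Reaction]) -> float:
    """Mean net proton coefficient over the pathway's reactions."""
    if not reactions:
        raise DomainError("pathway has no reactions; proton factor undefined")
    return float(np.mean([r.proton_coefficient for r in reactions]))


def network_proton_factors(network: StoichiometricNetwork) -> pd.Series:
    """Proton factor per sink pathway.

    A sink pathway's reaction set is its terminal drain plus any internal
    reactions explicitly labeled with its pathway name.
    """
    return pd.Series(
        {
            p: pathway_proton_factor(network.pathway_reactions(p))
            for p in network.sink_pathways
        },
        name="h",
    )


def proton_fluxes(v: pd.Series, h: pd.Series) -> pd.Series:
    """Proton production flux J_i = v_i * h_i per pathway."""
    if set(v.index) != set(h.index):
        raise DomainError(
            f"pathway sets differ: {sorted(set(v.index) ^ set(h.index))}"
        )
    return (v * h.reindex(v.index)).rename("J")


def proton_fractions(J: pd.Series) -> pd.Series:
    """Share of total H+ production per pathway.

    Negative fluxes (net proton consumption) are clipped to zero before
    normalizing, so consuming pathways report a 0% production share.
    """
    clipped = J.clip(lower=0.0)
    total = clipped.sum()
    if total <= 0:
        raise DomainError("no pathway produces protons; shares undefined")
    return (clipped / total).rename("production_fraction")


def proton_ledger(v: pd.Series, h: pd.Series) -> pd.DataFrame:
    """Full per-pathway ledger: factor, flux, production share."""
    J = proton_fluxes(v, h)
    return pd.DataFrame(
        {"h": h.reindex(v.index), "J": J, "production_fraction": proton_fractions(J)}
    )
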