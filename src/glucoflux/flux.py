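"""Quadratic-program allocation of glucose influx across sink pathways.

Per sample, sink fluxes maximize a balanced objective

    max_v  sum_s  w_s v_s - lambda * v_s^2

subject to steady-state mass balance at every internal metabolite, the
conservation constraint sum_s v_s = v_glc_in, and capacity bounds
0 <= v_s <= B_s with B_s = G_s * (kcat/Km)_s. The linear weights pull
flux toward transcriptionally active pathways while the quadratic
penalty discourages winner-take-all allocations.

Because the objective is separable in the sink fluxes and internal
reactions are uncapacitated on an acyclic network, the optimum over the
sinks has the exact Karush-Kuhn-Tucker form

    v_s(mu) = clip((w_s - mu) / (2 lambda), 0, B_s),

with the multiplier mu chosen so the fluxes sum to the uptake. The
solver locates mu by bisection, then re-solves it exactly on the
resulting active set, giving machine-precision solutions. Internal
fluxes supporting the optimal sink allocation are recovered by linear
programming on the balance equations; if that routing step is
infeasible (possible only for non-unit internal stoichiometry), a
general SLSQP solve over all fluxes is used instead.

The same one-constraint QP structure partitions the lactate flux
between export and protein lactylation (weights from softmax-blended
transporter/lactylation activity scores).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize

from glucoflux.errors import DomainError, InfeasibleError, SolverError
from glucoflux.network import StoichiometricNetwork, build_stoichiometric_matrix


# -- bounds and weights ---------------------------------------------------

def compute_flux_bounds(
    G: pd.Series | np.ndarray, eff: pd.Series | np.ndarray
) -> np.ndarray:
    """Capacity bound per sink, B = G * eff (elementwise)."""
    G = np.asarray(G, dtype=float)
    eff = np.asarray(eff, dtype=float)
    if np.any(G < 0) or np.any(eff < 0):
        raise DomainError("activity scores and efficiencies must be nonnegative")
    return G * eff


def compute_sink_weights(
    B: np.ndarray, sqrt_normalize: bool = True
) -> np.ndarray:
    """Sink weights from capacity bounds.

    Square-root normalization (default) w_s = sqrt(B_s) / sum sqrt(B);
    the linear alternative normalizes B directly. An all-zero bound
    vector yields uniform weights with a warning.
    """
    B = np.asarray(B, dtype=float)
    if np.any(B < 0):
        raise DomainError("bounds must be nonnegative")
    base = np.sqrt(B) if sqrt_normalize else B
    total = base.sum()
    if total == 0.0:
        warnings.warn("all capacity bounds are zero; using uniform sink weights")
        return np.full(B.shape, 1.0 / B.size)
    return base / total


# -- exact one-constraint QP ----------------------------------------------

def _box_simplex_qp(
    w: np.ndarray, B: np.ndarray, total: float, lam: float
) -> np.ndarray:
    """max sum w_i v_i - lam v_i^2  s.t.  sum v_i = total, 0 <= v_i <= B_i.

    Exact solve via the KKT form v_i = clip((w_i - mu)/(2 lam), 0, B_i):
    bisection on the monotone multiplier, then an exact multiplier solve
    on the identified active set.
    """
    if lam <= 0:
        raise DomainError("lambda_qp must be positive")
    if total < 0:
        raise DomainError("total flux must be nonnegative")
    cap = B.sum()
    if total > cap * (1 + 1e-12) + 1e-300:
        raise InfeasibleError(
            f"total capacity {cap:.6g} below required flux {total:.6g} "
            f"(gap {total - cap:.6g})"
        )
    if total == 0.0:
        return np.zeros_like(B)
    if abs(cap - total) <= 1e-12 * max(cap, total):
        return B.copy()

    def v_of(mu: float) -> np.ndarray:
        return np.clip((w - mu) / (2 * lam), 0.0, B)

    lo = float(np.min(w - 2 * lam * B)) - 1.0
    hi = float(np.max(w)) + 1.0
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        if v_of(mid).sum() > total:
            lo = mid
        else:
            hi = mid
    mu = 0.5 * (lo + hi)
    v = v_of(mu)

    # exact multiplier on the active set found by bisection
    tol = 1e-9 * (1.0 + B.max())
    interior = (v > tol) & (v < B - tol)
    at_upper = v >= B - tol
    if interior.any():
        mu = (w[interior].sum() - 2 * lam * (total - B[at_upper].sum())) / (
            interior.sum()
        )
        v = v_of(mu)
    # distribute any residual rounding on the interior set
    resid = total - v.sum()
    if interior.any():
        v[interior] += resid / interior.sum()
    v = np.clip(v, 0.0, B)
    return v


# -- full flux solution ---------------------------------------------------

@dataclass
class FluxSolution:
    """Per-sample optimal fluxes with conservation diagnostics."""

    sample_id: str
    vglc_in: float
    v: pd.Series  # flux per reaction (internal + sink), reaction order
    sink_flux: pd.Series  # flux per sink pathway, sink_pathways order
    fractions: pd.Series  # sink flux / vglc_in
    residuals: pd.Series  # balance residual per internal metabolite
    objective: float


def _route_internal_fluxes(
    network: StoichiometricNetwork,
    S: np.ndarray,
    sink_flux: np.ndarray,
    vglc_in: float,
) -> np.ndarray | None:
    """Nonnegative internal fluxes satisfying balance for fixed sink fluxes.

    Minimizes total internal flux (deterministic tie-break among
    alternative routings) subject to S_internal v = 0 with the sink
    columns fixed and the uptake fixed to vglc_in. Returns None if the
    LP is infeasible.
    """
    met_role = {m.id: m.role for m in network.metabolites}
    internal_rows = [
        i for i, m in enumerate(network.metabolites) if m.role == "internal"
    ]
    sink_ids = [r.id for r in network.sink_reactions()]
    rxn_ids = network.reaction_ids
    free_cols = [j for j, rid in enumerate(rxn_ids) if rid not in sink_ids]
    sink_cols = [rxn_ids.index(rid) for rid in sink_ids]

    A_int = S[np.ix_(internal_rows, free_cols)]
    b_int = -S[np.ix_(internal_rows, sink_cols)] @ sink_flux

    # pin uptake reactions (consumers of the source metabolite) to vglc_in
    src = network.source_metabolite.id
    uptake_row = np.zeros(len(free_cols))
    for k, j in enumerate(free_cols):
        r = network.reactions[j]
        if src in r.consumed:
            uptake_row[k] = r.consumed[src]
    A_eq = np.vstack([A_int, uptake_row])
    b_eq = np.concatenate([b_int, [vglc_in]])

    res = optimize.linprog(
        c=np.ones(len(free_cols)),
        A_eq=A_eq,
        b_eq=b_eq,
        bounds=[(0, None)] * len(free_cols),
        method="highs",
    )
    if not res.success:
        return None
    v = np.zeros(len(rxn_ids))
    v[free_cols] = res.x
    v[sink_cols] = sink_flux
    return v


def _full_qp_fallback(
    network: StoichiometricNetwork,
    S: np.ndarray,
    B: np.ndarray,
    w: np.ndarray,
    vglc_in: float,
    lam: float,
) -> np.ndarray:
    """General SLSQP solve over all reaction fluxes (non-unit stoichiometry)."""
    rxn_ids = network.reaction_ids
    sink_ids = [r.id for r in network.sink_reactions()]
    sink_cols = np.array([rxn_ids.index(rid) for rid in sink_ids])
    internal_rows = [
        i for i, m in enumerate(network.metabolites) if m.role == "internal"
    ]
    n = len(rxn_ids)

    def neg_obj(v: np.ndarray) -> float:
        vs = v[sink_cols]
        return -(w @ vs - lam * vs @ vs)

    def neg_grad(v: np.ndarray) -> np.ndarray:
        g = np.zeros(n)
        g[sink_cols] = -(w - 2 * lam * v[sink_cols])
        return g

    A_bal = S[internal_rows, :]
    sum_row = np.zeros(n)
    sum_row[sink_cols] = 1.0
    A_eq = np.vstack([A_bal, sum_row])
    b_eq = np.concatenate([np.zeros(len(internal_rows)), [vglc_in]])

    ub = np.full(n, np.inf)
    ub[sink_cols] = B
    x0 = np.full(n, vglc_in / max(n, 1))
    res = optimize.minimize(
        neg_obj,
        x0,
        jac=neg_grad,
        bounds=[(0.0, u) for u in ub],
        constraints=[{"type": "eq", "fun": lambda v: A_eq @ v - b_eq,
                      "jac": lambda v: A_eq}],
        method="SLSQP",
        options={"maxiter": 500, "ftol": 1e-14},
    )
    if not res.success:
        raise SolverError(f"flux QP failed to converge: {res.message}")
    return np.clip(res.x, 0.0, None)


def solve_flux_qp(
    network: StoichiometricNetwork,
    bounds: np.ndarray | pd.Series,
    weights: np.ndarray | pd.Series,
    vglc_in: float,
    lambda_qp: float | None = None,
    sample_id: str = "sample",
    rescale_infeasible: bool = False,
) -> FluxSolution:
    """Optimal per-sample allocation of glucose influx across sinks.

    ``bounds`` and ``weights`` are per-sink (in ``network.sink_pathways``
    order). ``lambda_qp=None`` uses 1 / (2 * mean(bounds)). If the total
    capacity is below the uptake, an :class:`InfeasibleError` reporting
    the gap is raised unless ``rescale_infeasible`` is set, in which case
    the uptake is scaled down to the total capacity.
    """
    B = np.asarray(bounds, dtype=float)
    w = np.asarray(weights, dtype=float)
    n_sinks = len(network.sink_pathways)
    if B.shape != (n_sinks,) or w.shape != (n_sinks,):
        raise DomainError("bounds/weights must have one entry per sink pathway")
    if vglc_in < 0:
        raise DomainError("vglc_in must be nonnegative")
    if lambda_qp is None:
        mean_b = B.mean()
        if mean_b <= 0:
            raise DomainError("cannot derive lambda_qp from all-zero bounds")
        lambda_qp = 1.0 / (2.0 * mean_b)
    if rescale_infeasible and B.sum() < vglc_in:
        vglc_in = float(B.sum())

    sink_flux = _box_simplex_qp(w, B, vglc_in, lambda_qp)

    S = build_stoichiometric_matrix(network)
    v = _route_internal_fluxes(network, S, sink_flux, vglc_in)
    if v is None:
        v = _full_qp_fallback(network, S, B, w, vglc_in, lambda_qp)
        rxn_ids = network.reaction_ids
        sink_cols = [rxn_ids.index(r.id) for r in network.sink_reactions()]
        sink_flux = v[sink_cols]

    internal_rows = [
        i for i, m in enumerate(network.metabolites) if m.role == "internal"
    ]
    residuals = S[internal_rows, :] @ v
    fractions = sink_flux / vglc_in if vglc_in > 0 else np.zeros_like(sink_flux)
    objective = float(w @ sink_flux - lambda_qp * sink_flux @ sink_flux)
    return FluxSolution(
        sample_id=sample_id,
        vglc_in=float(vglc_in),
        v=pd.Series(v, index=network.reaction_ids, name="flux"),
        sink_flux=pd.Series(
            sink_flux, index=network.sink_pathways, name="sink_flux"
        ),
        fractions=pd.Series(
            fractions, index=network.sink_pathways, name="fraction"
        ),
        residuals=pd.Series(
            residuals,
            index=[network.metabolites[i].id for i in internal_rows],
            name="residual",
        ),
        objective=objective,
    )


def allocation_fractions(solution: FluxSolution) -> pd.Series:
    """Per-sink allocation fractions v_s / vglc_in for one sample."""
    if solution.vglc_in <= 0:
        raise DomainError("allocation fractions undefined at zero uptake")
    return solution.sink_flux / solution.vglc_in


def mean_allocation_table(
    solutions: list[FluxSolution], metadata: pd.DataFrame | None = None
) -> pd.DataFrame:
    """Mean per-sink fractions, optionally grouped by a ``stage`` column.

    ``metadata`` is indexed by sample id; without it a single overall
    mean row labeled ``all`` is returned. Per-sample fractions are
    averaged (not fractions of mean fluxes).
    """
    frac = pd.DataFrame(
        {s.sample_id: allocation_fractions(s) for s in solutions}
    ).T
    if metadata is None or "stage" not in getattr(metadata, "columns", []):
        return frac.mean(axis=0).to_frame("all").T
    stages = metadata.loc[frac.index, "stage"]
    return frac.groupby(stages).mean()


# -- lactate fate ---------------------------------------------------------

@dataclass
class LactateFateWeights:
    """Softmax-blended weights for the export/lactylation partition."""

    s_export: float
    s_lactylation: float
    z_export: float
    z_lactylation: float
    w_export: float
    w_lactylation: float


def lactate_fate_weights(
    s_export: float,
    s_lactylation: float,
    tau: float = 1.0,
    alpha: float = 0.2,
) -> LactateFateWeights:
    """Weights from activity scores: log-compress, softmax, blend with uniform.

    z_i = ln(1 + s_i); softmax at temperature tau; the softmax weights
    are mixed with a uniform prior, w_i = alpha * 0.5 + (1 - alpha) *
    softmax_i, so no fate is ever fully starved.
    """
    if tau <= 0:
        raise DomainError("tau must be positive")
    if not 0 < alpha < 1:
        raise DomainError("alpha must lie in (0, 1)")
    if s_export < 0 or s_lactylation < 0:
        raise DomainError("activity scores must be nonnegative (shift upstream)")
    z_e = np.log1p(s_export)
    z_l = np.log1p(s_lactylation)
    m = max(z_e, z_l) / tau
    e_e = np.exp(z_e / tau - m)
    e_l = np.exp(z_l / tau - m)
    soft_e = e_e / (e_e + e_l)
    w_e = alpha * 0.5 + (1 - alpha) * soft_e
    return LactateFateWeights(
        s_export=float(s_export),
        s_lactylation=float(s_lactylation),
        z_export=float(z_e),
        z_lactylation=float(z_l),
        w_export=float(w_e),
        w_lactylation=float(1.0 - w_e),
    )


@dataclass
class LactatePartition:
    v_lactate: float
    v_export: float
    v_lactylation: float


def partition_lactate(
    v_lactate: float,
    weights: LactateFateWeights,
    lambda_qp: float = 0.5,
) -> LactatePartition:
    """Split the lactate flux between export and lactylation.

    Solves max w1 v1 + w2 v2 - lambda (v1^2 + v2^2) subject to
    v1 + v2 = v_lactate, v >= 0, whose KKT solution is the clipped
    closed form v1 = clip(L/2 + (w1 - w2)/(4 lambda), 0, L).
    """
    if v_lactate < 0:
        raise DomainError("v_lactate must be nonnegative")
    if lambda_qp <= 0:
        raise DomainError("lambda_qp must be positive")
    L = float(v_lactate)
    v_exp = float(
        np.clip(L / 2 + (weights.w_export - weights.w_lactylation) / (4 * lambda_qp),
                0.0, L)
    )
    return LactatePartition(
        v_lactate=L, v_export=v_exp, v_lactylation=L - v_exp
    )
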