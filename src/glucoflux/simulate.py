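"""Synthetic networks, cohorts, and causal triples with planted truth.

The generator emulates the study's inputs at desk scale so every
downstream stage can be checked against known ground truth:

* :func:`simulate_network` builds a small acyclic glucose-rooted network
  (source -> chain of internal transit metabolites -> terminal sink
  drains) with planted, conservation-exact fluxes and planted positive
  catalytic efficiencies;
* :func:`simulate_cohort` emits a two-group log2-scale expression cohort
  whose metabolic genes carry planted fold changes and whose weighted
  activity proxy is consistent with the planted fluxes and efficiencies,
  so the efficiency-estimation and flux-allocation stages can recover
  the planted allocation;
* :func:`simulate_causal_data` draws from the linear structural model
  W -> T -> Y with W -> Y used to validate the backdoor estimator.

Planted sink efficiencies are proportional to the squared planted
allocation fractions, with the overall scale calibrated so that the
expected capacity bound (exp(z-scored enrichment) times efficiency)
averages to the glucose uptake. Under that calibration the square-root
weight normalization and the default quadratic penalty make the
expected QP allocation coincide with the planted fractions.

Latent pathway factors are centered within each sample group before
being added to expression, so a zero-noise cohort reproduces the
planted fold changes exactly.

All randomness flows from a single integer seed through independent
child generators; no global state is touched.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from glucoflux.config import AnalysisConfig
from glucoflux.errors import ConfigError
from glucoflux.network import (
    INTERNAL_PATHWAY,
    Metabolite,
    Reaction,
    StoichiometricNetwork,
    build_stoichiometric_matrix,
    validate_network,
    write_network,
)
from glucoflux.pathways import write_gmt

# canonical eight glucose sinks, in Table-style order (largest fate first)
CANONICAL_SINKS = [
    "nucleotide_synthesis",
    "lactate_production",
    "lipid_synthesis",
    "glycosylation",
    "sialic_acid",
    "ganglioside_synthesis",
    "serine_synthesis",
    "tca_entry",
]
#: planted mean allocation fractions for the canonical 8-sink network
CANONICAL_FRACTIONS = np.array([0.28, 0.18, 0.14, 0.11, 0.09, 0.08, 0.07, 0.05])

#: internal transit metabolites of the glucose-centric map
CANONICAL_INTERNAL = [
    "G6P", "F6P", "UDP_GlcNAc", "G3P", "PG3",
    "serine", "ceramide", "pyruvate", "acetyl_CoA", "citrate",
]

TRANSPORTER_GENES = ["SLC2A1", "SLC2A3", "SLC5A1", "SLC5A2", "SLC2A10"]

PLANTED_UPTAKE = 100.0  # arbitrary flux units; all reported outputs are fractions

#: E[exp(z)] for a standard normal z; calibrates the capacity-bound scale
_EXP_Z_MEAN = float(np.exp(0.5))

MKI67 = "MKI67"

#: global TPM scale of the metabolic genes; keeps planted levels far above
#: the additive noise floor of the linear back-transform (2^x - 1). The
#: balance constraints and the prior-pinned efficiencies are invariant to
#: a common activity scale, so this constant only sets realistic units.
EXPRESSION_TPM_SCALE = 1000.0

# reserved gene-set names emitted alongside the sink pathway sets
SET_LACTATE_EXPORT = "lactate_export"
SET_LACTYLATION = "lactylation"
SET_FENTON = "fenton_reaction"
SET_MIGRATION = "migration"
SET_PROLIFERATION = "proliferation_signature"


@dataclass
class SimConfig:
    """Study conditions of the synthetic cohort."""

    n_tumor: int = 50
    n_normal: int = 50
    n_genes: int = 1000
    n_internal_mets: int = 10
    n_sinks: int = 8
    planted_log2fc: float = 1.0  # fold change of metabolic genes, log2 units
    noise_sd: float = 0.5  # log2 units
    causal_beta: float = 0.5
    confounding_a: float = 0.8  # W -> T
    confounding_b: float = 0.6  # W -> Y
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_tumor", "n_normal", "n_genes", "n_internal_mets", "n_sinks"):
            v = getattr(self, name)
            if not isinstance(v, int) or v < 1:
                raise ConfigError(f"{name} must be a positive integer, got {v!r}")
        if self.noise_sd < 0:
            raise ConfigError("noise_sd must be nonnegative")
        if self.n_sinks < 2:
            raise ConfigError("need at least 2 sink pathways")


@dataclass
class SimTruth:
    """Planted ground truth for parameter-recovery tests."""

    true_eff: pd.Series | None = None  # reaction -> planted efficiency
    true_flux: pd.Series | None = None  # reaction -> planted flux
    true_fractions: pd.Series | None = None  # sink pathway -> planted fraction
    vglc_in: float | None = None
    true_log2fc: pd.Series | None = None  # gene -> planted fold change
    true_ate: float | None = None

    def to_json(self) -> str:
        def ser(s):
            return None if s is None else {k: float(v) for k, v in s.items()}

        return json.dumps(
            {
                "true_eff": ser(self.true_eff),
                "true_flux": ser(self.true_flux),
                "true_fractions": ser(self.true_fractions),
                "vglc_in": self.vglc_in,
                "true_log2fc": ser(self.true_log2fc),
                "true_ate": self.true_ate,
            },
            indent=1,
        )


def _sink_labels(n_sinks: int) -> list[str]:
    if n_sinks <= len(CANONICAL_SINKS):
        return CANONICAL_SINKS[:n_sinks]
    extra = [f"sink_{i + 1}" for i in range(len(CANONICAL_SINKS), n_sinks)]
    return CANONICAL_SINKS + extra


def _internal_names(k: int) -> list[str]:
    if k <= len(CANONICAL_INTERNAL):
        return CANONICAL_INTERNAL[:k]
    extra = [f"M{i + 1}" for i in range(len(CANONICAL_INTERNAL), k)]
    return CANONICAL_INTERNAL + extra


def _planted_fractions(n_sinks: int, rng: np.random.Generator) -> np.ndarray:
    if n_sinks == len(CANONICAL_FRACTIONS):
        return CANONICAL_FRACTIONS.copy()
    f = np.sort(rng.dirichlet(np.full(n_sinks, 5.0)))[::-1]
    return f


def _random_ec(rng: np.random.Generator) -> str:
    return ".".join(
        str(int(d))
        for d in (rng.integers(1, 7), rng.integers(1, 10),
                  rng.integers(1, 10), rng.integers(1, 200))
    )


def simulate_network(
    n_internal_mets: int, n_sinks: int, seed: int
) -> tuple[StoichiometricNetwork, SimTruth]:
    """Acyclic glucose-rooted network with planted fluxes and efficiencies.

    Topology: glucose -> m1 (uptake), a chain m_i -> m_{i+1} of internal
    conversions, and one terminal drain per sink pathway attached to an
    internal metabolite (the last internal metabolite always feeds at
    least one sink, so every internal node has a consumer). Planted sink
    fluxes follow the planted allocation fractions and satisfy every
    balance constraint exactly by construction.
    """
    if n_internal_mets < 1:
        raise ConfigError("n_internal_mets must be >= 1")
    if n_sinks < 2:
        raise ConfigError("n_sinks must be >= 2")
    rng = np.random.default_rng(seed)

    k = n_internal_mets
    internal = _internal_names(k)
    sinks = _sink_labels(n_sinks)
    fractions = _planted_fractions(n_sinks, rng)
    V = PLANTED_UPTAKE
    sink_flux = fractions * V

    # sink p drains internal metabolite attach[p]; m_{k-1} always consumed
    attach = np.concatenate(
        [[k - 1], rng.integers(0, k, size=n_sinks - 1)]
    ).astype(int)

    metabolites = [Metabolite("glucose", "imported glucose", "source")]
    metabolites += [Metabolite(m, m, "internal") for m in internal]
    metabolites += [Metabolite(f"{p}__sink", f"{p} terminal pool", "sink")
                    for p in sinks]

    reactions: list[Reaction] = []
    reactions.append(
        Reaction(
            id="R_uptake",
            stoichiometry={"glucose": -1.0, internal[0]: 1.0},
            ec_numbers=["2.7.1.1"],
            genes=frozenset(TRANSPORTER_GENES),
            proton_coefficient=0.0,
            pathway=INTERNAL_PATHWAY,
        )
    )
    flux = {"R_uptake": V}

    # chain m_i -> m_{i+1}: carries everything drained strictly downstream
    downstream = np.zeros(k)
    for p, a in enumerate(attach):
        downstream[a] += sink_flux[p]
    for i in range(k - 1):
        rid = f"R_int_{internal[i]}_{internal[i + 1]}"
        carried = float(downstream[i + 1:].sum())
        n_genes = int(rng.integers(1, 4))
        reactions.append(
            Reaction(
                id=rid,
                stoichiometry={internal[i]: -1.0, internal[i + 1]: 1.0},
                ec_numbers=[_random_ec(rng)],
                genes=frozenset(f"g_{rid}_{j}" for j in range(n_genes)),
                proton_coefficient=float(rng.integers(-1, 3)),
                pathway=INTERNAL_PATHWAY,
            )
        )
        flux[rid] = carried

    # planted efficiencies: sinks proportional to fraction^2, calibrated so
    # the expected capacity bound G * eff averages to the uptake
    c_scale = n_sinks * V / (_EXP_Z_MEAN * float((fractions**2).sum()))
    sink_eff = c_scale * fractions**2

    proton_by_sink = {
        "nucleotide_synthesis": 8.0,  # each purine yields ~8 net protons
        "lactate_production": 1.0,
        "lipid_synthesis": -2.0,  # net proton-consuming fate
    }
    for p, (label, a) in enumerate(zip(sinks, attach)):
        rid = f"R_sink_{label}"
        n_genes = int(rng.integers(1, 4))
        hr = proton_by_sink.get(label, float(rng.integers(-1, 4)))
        reactions.append(
            Reaction(
                id=rid,
                stoichiometry={internal[a]: -1.0, f"{label}__sink": 1.0},
                ec_numbers=[_random_ec(rng)],
                genes=frozenset(f"g_{rid}_{j}" for j in range(n_genes)),
                proton_coefficient=hr,
                pathway=label,
            )
        )
        flux[rid] = float(sink_flux[p])

    eff = {}
    for r in reactions:
        if r.pathway == INTERNAL_PATHWAY:
            eff[r.id] = float(np.exp(rng.normal(np.log(V), 0.3)))
    for p, label in enumerate(sinks):
        eff[f"R_sink_{label}"] = float(sink_eff[p])

    network = StoichiometricNetwork(
        metabolites=metabolites, reactions=reactions, sink_pathways=sinks
    )
    violations = validate_network(network)
    if violations:  # pragma: no cover - construction guarantees validity
        raise AssertionError(f"generated network invalid: {violations}")

    rxn_ids = network.reaction_ids
    truth = SimTruth(
        true_eff=pd.Series({r: eff[r] for r in rxn_ids}, name="eff"),
        true_flux=pd.Series({r: flux[r] for r in rxn_ids}, name="flux"),
        true_fractions=pd.Series(fractions, index=sinks, name="fraction"),
        vglc_in=V,
    )
    return network, truth


def consistent_activity(network: StoichiometricNetwork, truth: SimTruth) -> pd.Series:
    """Per-reaction activity E = v / eff exactly consistent with the truth.

    Feeding this vector to the efficiency estimator together with the
    planted priors recovers the planted efficiencies (the balance term
    vanishes at the truth).
    """
    return (truth.true_flux / truth.true_eff).rename("activity")


# -- cohort ---------------------------------------------------------------

def _group_center(x: np.ndarray, is_tumor: np.ndarray) -> np.ndarray:
    """Center a per-sample latent within each group (mean-0 per group)."""
    out = x.copy()
    for mask in (is_tumor, ~is_tumor):
        if mask.any():
            out[mask] -= out[mask].mean()
    return out


def simulate_cohort(
    network: StoichiometricNetwork,
    config: SimConfig,
    truth: SimTruth | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame, SimTruth, dict[str, set[str]]]:
    """Two-group log2 expression cohort consistent with the planted network.

    Returns (expression gene-by-sample, metadata, truth, gene_sets).
    Tumor metabolic genes are shifted by the planted fold change; the
    genes of each reaction carry linear-TPM levels chosen so that the
    pipeline's weighted activity proxy equals the planted flux divided by
    the planted efficiency (anticipating the fold-change weight the
    pipeline will assign). Latent per-sample pathway factors induce
    realistic covariance for enrichment scoring, and a linear structural
    model links a proliferation latent, the nucleotide-synthesis latent,
    and MKI67 with the planted causal effect.
    """
    if truth is None:
        raise ConfigError("simulate_cohort requires the SimTruth of the network")
    rng = np.random.default_rng(np.random.SeedSequence(config.seed).spawn(1)[0])
    gamma = AnalysisConfig().gamma
    delta = config.planted_log2fc

    n_t, n_n = config.n_tumor, config.n_normal
    samples = [f"T{i + 1:03d}" for i in range(n_t)] + [
        f"N{i + 1:03d}" for i in range(n_n)
    ]
    is_tumor = np.array([True] * n_t + [False] * n_n)

    # --- gene roster -----------------------------------------------------
    network_genes: list[str] = []
    gene_reaction: dict[str, str] = {}
    for r in network.reactions:
        for g in sorted(r.genes):
            if g not in gene_reaction:
                gene_reaction[g] = r.id
                network_genes.append(g)

    nucleotide_extra = [f"NUC_EXTRA_{j + 1}" for j in range(6)]
    proliferation = [f"PROLIF_{j + 1}" for j in range(30)]
    fenton = [f"FENTON_{j + 1}" for j in range(20)]
    migration = [f"MIG_{j + 1}" for j in range(15)]
    export_genes = [f"LACT_EXP_{j + 1}" for j in range(8)]
    lactylation_genes = [f"LACTYL_{j + 1}" for j in range(8)]
    special = (
        nucleotide_extra + proliferation + fenton + migration
        + export_genes + lactylation_genes + [MKI67]
    )
    n_needed = len(network_genes) + len(special)
    if config.n_genes < n_needed:
        raise ConfigError(
            f"n_genes = {config.n_genes} below the {n_needed} genes demanded "
            f"by the network and signature sets"
        )
    background = [f"BG_{j + 1}" for j in range(config.n_genes - n_needed)]
    genes = network_genes + special + background

    # --- baseline log2 levels and planted fold changes -------------------
    base = pd.Series(0.0, index=genes)
    lfc = pd.Series(0.0, index=genes)

    # anticipated composite gene weight for a significant gene at fold delta
    w_bar = 2.0 ** (gamma * delta)
    # mean multiplicative inflation of 2^eps for log2 noise eps
    noise_infl = float(np.exp(0.5 * (config.noise_sd * np.log(2.0)) ** 2))

    # mean of the linear back-transform: E[2^(x+eps) - 1] = tpm*infl + (infl-1)
    uptake_ids = {r.id for r in network.source_reactions()}
    true_eff = truth.true_eff.copy()
    for r in network.reactions:
        m_j = len(r.genes)
        if r.id in uptake_ids:
            # transporter linear TPM sums to the planted uptake in expectation;
            # the uptake efficiency is then fixed by activity consistency
            tpm = max(truth.vglc_in - m_j * (noise_infl - 1.0), 0.0) / (
                m_j * noise_infl
            )
            true_eff[r.id] = (
                EXPRESSION_TPM_SCALE
                * truth.true_flux[r.id] / (w_bar * truth.vglc_in)
            )
        else:
            target_e = (
                EXPRESSION_TPM_SCALE
                * truth.true_flux[r.id] / truth.true_eff[r.id]
            )
            tpm = max(target_e / w_bar - m_j * (noise_infl - 1.0), 0.0) / (
                m_j * noise_infl
            )
        for g in r.genes:
            base[g] = np.log2(1.0 + tpm) - delta  # normal-tissue level
            lfc[g] = delta

    for g in nucleotide_extra:
        base[g] = rng.uniform(3.0, 6.0)
        lfc[g] = 1.5
    for g in proliferation + fenton + migration:
        base[g] = rng.uniform(3.0, 6.0)
    for g in export_genes:
        base[g] = rng.uniform(5.0, 7.0)
        lfc[g] = 1.2  # export programme dominates lactate fate in tumors
    for g in lactylation_genes:
        base[g] = rng.uniform(2.0, 4.0)
        lfc[g] = 0.4
    base[MKI67] = 5.0
    lfc[MKI67] = 1.0
    for g in background:
        base[g] = rng.uniform(1.0, 8.0)

    # --- latent per-sample structure -------------------------------------
    n = n_t + n_n
    pathway_factor = {
        p: _group_center(rng.standard_normal(n), is_tumor)
        for p in network.sink_pathways
    }
    P = _group_center(rng.standard_normal(n), is_tumor)  # proliferation latent
    a, b, beta = config.confounding_a, config.confounding_b, config.causal_beta
    N_lat = _group_center(
        a * P + rng.standard_normal(n), is_tumor
    )  # nucleotide-synthesis latent (confounded by P)
    if "nucleotide_synthesis" in pathway_factor:
        pathway_factor["nucleotide_synthesis"] = N_lat
    fenton_mix = _group_center(
        sum(0.35 * f for f in pathway_factor.values())
        + 0.1 * rng.standard_normal(n),
        is_tumor,
    )

    expr = pd.DataFrame(
        np.tile(base.to_numpy()[:, None], (1, n)), index=genes, columns=samples
    )
    expr.loc[:, is_tumor] = expr.loc[:, is_tumor].add(lfc, axis=0)

    amp = 0.3
    for p, f in pathway_factor.items():
        rxn_genes = sorted(
            set().union(*(r.genes for r in network.pathway_reactions(p)))
        )
        expr.loc[rxn_genes] += amp * f[None, :]
    expr.loc[nucleotide_extra] += amp * N_lat[None, :]
    expr.loc[proliferation] += 0.5 * P[None, :]
    expr.loc[fenton] += 0.5 * fenton_mix[None, :]
    if "sialic_acid" in pathway_factor:
        expr.loc[migration] += 0.4 * pathway_factor["sialic_acid"][None, :]
    mki_signal = _group_center(beta * N_lat + b * P, is_tumor)
    expr.loc[MKI67] += 0.4 * mki_signal

    if config.noise_sd > 0:
        expr += rng.normal(0.0, config.noise_sd, size=expr.shape)
    expr = expr.clip(lower=0.0)

    stages = np.array(["I", "II", "III", "IV"])[np.arange(n_t) % 4]
    metadata = pd.DataFrame(
        {
            "sample_id": samples,
            "group": np.where(is_tumor, "tumor", "normal"),
            "stage": list(stages) + ["NA"] * n_n,
        }
    ).set_index("sample_id")

    gene_sets: dict[str, set[str]] = {}
    for p in network.sink_pathways:
        members = set().union(*(r.genes for r in network.pathway_reactions(p)))
        if p == "nucleotide_synthesis":
            members |= set(nucleotide_extra)
        gene_sets[p] = members
    gene_sets[SET_LACTATE_EXPORT] = set(export_genes)
    gene_sets[SET_LACTYLATION] = set(lactylation_genes)
    gene_sets[SET_FENTON] = set(fenton)
    gene_sets[SET_MIGRATION] = set(migration)
    gene_sets[SET_PROLIFERATION] = set(proliferation) | {MKI67}

    cohort_truth = SimTruth(
        true_eff=true_eff,
        true_flux=truth.true_flux,
        true_fractions=truth.true_fractions,
        vglc_in=truth.vglc_in,
        true_log2fc=lfc,
        true_ate=beta,
    )
    return expr, metadata, cohort_truth, gene_sets


# -- causal triple ---------------------------------------------------------

def simulate_causal_data(
    n: int, beta: float, a: float, b: float, seed: int
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Draw (T, Y, W) from the linear SCM W -> T -> Y with W -> Y.

    W ~ N(0,1); T = a W + e1; Y = beta T + b W + e2 with unit-variance
    Gaussian noise. The adjusted regression of Y on (T, W) is consistent
    for beta; the unadjusted Y ~ T slope carries the confounding bias
    a b Var(W) / Var(T).
    """
    if n < 10:
        raise ConfigError(f"n must be >= 10, got {n}")
    rng = np.random.default_rng(seed)
    W = rng.standard_normal(n)
    T = a * W + rng.standard_normal(n)
    Y = beta * T + b * W + rng.standard_normal(n)
    return T, Y, W


# -- file emission ---------------------------------------------------------

def write_simulation(
    out_dir: str | Path,
    network: StoichiometricNetwork,
    expr: pd.DataFrame,
    metadata: pd.DataFrame,
    truth: SimTruth,
    gene_sets: dict[str, set[str]],
) -> dict[str, Path]:
    """Write the full simulated input bundle; returns the file manifest."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = {
        "expression": out / "expression.tsv",
        "metadata": out / "metadata.tsv",
        "network": out / "network.json",
        "priors": out / "priors.tsv",
        "gene_sets": out / "gene_sets.gmt",
        "truth": out / "truth.json",
    }
    expr.to_csv(manifest["expression"], sep="\t", index_label="gene",
                float_format="%.6g")
    metadata.to_csv(manifest["metadata"], sep="\t")
    write_network(network, manifest["network"])
    pd.DataFrame(
        {
            "reaction_id": truth.true_eff.index,
            "eff0": truth.true_eff.to_numpy(),
            "source": "curated",
        }
    ).to_csv(manifest["priors"], sep="\t", index=False, float_format="%.8g")
    write_gmt(gene_sets, manifest["gene_sets"])
    manifest["truth"].write_text(truth.to_json() + "\n")
    return manifest
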