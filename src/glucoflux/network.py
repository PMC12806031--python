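"""Data model and I/O for the glucose-centric stoichiometric network.

The network is a small, acyclic, glucose-rooted map: one source metabolite
(imported glucose), a layer of internal transit metabolites (G6P, F6P,
UDP-GlcNAc, G3P, 3-phosphoglycerate, serine, ceramide, pyruvate,
acetyl-CoA, citrate in the curated fixture), and one terminal sink
metabolite per major glucose fate. Sink pathways are represented by
terminal drain reactions consuming their terminal metabolite; minor fates
(e.g. hyaluronic acid) are treated as negligible and not represented.

Each reaction carries its signed stoichiometry, EC numbers, the union of
its gene-protein-reaction gene set, and a net proton coefficient
(positive = net H+ produced per unit flux).
"""

from __future__ import annotations

import importlib.resources
import json
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np

from glucoflux.errors import SchemaError, ValidationError

ROLE_SOURCE = "source"
ROLE_INTERNAL = "internal"
ROLE_SINK = "sink"
_ROLES = (ROLE_SOURCE, ROLE_INTERNAL, ROLE_SINK)

INTERNAL_PATHWAY = "internal"


@dataclass(frozen=True)
class Metabolite:
    id: str
    name: str
    role: str

    def __post_init__(self) -> None:
        if self.role not in _ROLES:
            raise SchemaError(
                f"metabolite {self.id!r}: role must be one of {_ROLES}, "
                f"got {self.role!r}"
            )


@dataclass
class Reaction:
    """A reaction with signed stoichiometry (negative = consumed).

    ``proton_coefficient`` is the net stoichiometric coefficient of H+
    in the balanced equation; ``pathway`` is a sink-pathway label for
    drains and ``"internal"`` otherwise.
    """

    id: str
    stoichiometry: dict[str, float]
    ec_numbers: list[str] = field(default_factory=list)
    genes: frozenset[str] = frozenset()
    proton_coefficient: float = 0.0
    pathway: str = INTERNAL_PATHWAY

    def __post_init__(self) -> None:
        self.genes = frozenset(self.genes)
        if not self.stoichiometry:
            raise SchemaError(f"reaction {self.id!r}: empty stoichiometry")
        if not np.isfinite(self.proton_coefficient):
            raise SchemaError(f"reaction {self.id!r}: non-finite proton coefficient")
        has_neg = any(c < 0 for c in self.stoichiometry.values())
        if not has_neg:
            raise SchemaError(
                f"reaction {self.id!r}: must consume at least one metabolite"
            )

    @property
    def consumed(self) -> dict[str, float]:
        return {m: -c for m, c in self.stoichiometry.items() if c < 0}

    @property
    def produced(self) -> dict[str, float]:
        return {m: c for m, c in self.stoichiometry.items() if c > 0}


@dataclass
class StoichiometricNetwork:
    metabolites: list[Metabolite]
    reactions: list[Reaction]
    sink_pathways: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.sink_pathways:
            self.sink_pathways = [
                r.pathway for r in self.reactions
                if r.pathway != INTERNAL_PATHWAY
            ]

    # -- indexed views ----------------------------------------------------
    @property
    def metabolite_ids(self) -> list[str]:
        return [m.id for m in self.metabolites]

    @property
    def reaction_ids(self) -> list[str]:
        return [r.id for r in self.reactions]

    def metabolite(self, met_id: str) -> Metabolite:
        for m in self.metabolites:
            if m.id == met_id:
                return m
        raise KeyError(met_id)

    def reaction(self, rxn_id: str) -> Reaction:
        for r in self.reactions:
            if r.id == rxn_id:
                return r
        raise KeyError(rxn_id)

    @property
    def source_metabolite(self) -> Metabolite:
        sources = [m for m in self.metabolites if m.role == ROLE_SOURCE]
        if len(sources) != 1:
            raise ValidationError(
                f"network must have exactly one source metabolite, found "
                f"{[m.id for m in sources]}"
            )
        return sources[0]

    @property
    def internal_metabolite_ids(self) -> list[str]:
        return [m.id for m in self.metabolites if m.role == ROLE_INTERNAL]

    def sink_reactions(self) -> list[Reaction]:
        """Terminal drain reactions, in sink_pathways order."""
        by_pathway = {
            r.pathway: r for r in self.reactions if r.pathway != INTERNAL_PATHWAY
        }
        return [by_pathway[p] for p in self.sink_pathways]

    def internal_reactions(self) -> list[Reaction]:
        return [r for r in self.reactions if r.pathway == INTERNAL_PATHWAY]

    def pathway_reactions(self, pathway: str) -> list[Reaction]:
        return [r for r in self.reactions if r.pathway == pathway]

    def source_reactions(self) -> list[Reaction]:
        """Reactions consuming the source metabolite (glucose uptake)."""
        src = self.source_metabolite.id
        return [r for r in self.reactions if src in r.consumed]

    def reaction_graph(self) -> nx.DiGraph:
        """Bipartite-collapsed digraph: metabolite -> reaction -> metabolite."""
        g = nx.DiGraph()
        for r in self.reactions:
            for m in r.consumed:
                g.add_edge(("met", m), ("rxn", r.id))
            for m in r.produced:
                g.add_edge(("rxn", r.id), ("met", m))
        return g


def build_stoichiometric_matrix(network: StoichiometricNetwork) -> np.ndarray:
    """Dense signed matrix S, rows = metabolites, columns = reactions."""
    met_index = {m.id: i for i, m in enumerate(network.metabolites)}
    S = np.zeros((len(network.metabolites), len(network.reactions)))
    for j, r in enumerate(network.reactions):
        for met_id, coeff in r.stoichiometry.items():
            if met_id not in met_index:
                raise SchemaError(
                    f"reaction {r.id!r} references undeclared metabolite {met_id!r}"
                )
            S[met_index[met_id], j] = coeff
    return S


def internal_stoichiometric_matrix(network: StoichiometricNetwork) -> np.ndarray:
    """Rows of S restricted to internal metabolites (the balanced nodes).

    Source and sink pools exchange with the environment and are not
    mass-balanced; every steady-state constraint S v = 0 in the package
    refers to these rows only.
    """
    S = build_stoichiometric_matrix(network)
    rows = [i for i, m in enumerate(network.metabolites) if m.role == ROLE_INTERNAL]
    return S[rows, :]


def validate_network(network: StoichiometricNetwork) -> list[str]:
    """Structural validation; returns a list of violations (empty = valid).

    Checks: unique ids, exactly one source, declared metabolite
    references, every internal metabolite has a producer and a consumer,
    every sink reachable from the source, acyclicity.
    """
    violations: list[str] = []

    met_ids = network.metabolite_ids
    dup_mets = {m for m in met_ids if met_ids.count(m) > 1}
    if dup_mets:
        violations.append(f"duplicate metabolite ids: {sorted(dup_mets)}")
    rxn_ids = network.reaction_ids
    dup_rxns = {r for r in rxn_ids if rxn_ids.count(r) > 1}
    if dup_rxns:
        violations.append(f"duplicate reaction ids: {sorted(dup_rxns)}")

    n_sources = sum(1 for m in network.metabolites if m.role == ROLE_SOURCE)
    if n_sources != 1:
        violations.append(f"expected exactly 1 source metabolite, found {n_sources}")

    declared = set(met_ids)
    for r in network.reactions:
        undeclared = set(r.stoichiometry) - declared
        if undeclared:
            violations.append(
                f"reaction {r.id!r} references undeclared metabolites "
                f"{sorted(undeclared)}"
            )
    if violations:
        return violations  # graph checks need a well-formed id space

    produced: dict[str, int] = {m: 0 for m in met_ids}
    consumed: dict[str, int] = {m: 0 for m in met_ids}
    for r in network.reactions:
        for m in r.produced:
            produced[m] += 1
        for m in r.consumed:
            consumed[m] += 1
    for m in network.metabolites:
        if m.role == ROLE_INTERNAL:
            if produced[m.id] == 0:
                violations.append(f"internal metabolite {m.id!r} has no producer")
            if consumed[m.id] == 0:
                violations.append(f"internal metabolite {m.id!r} has no consumer")

    g = network.reaction_graph()
    cycles = list(nx.simple_cycles(g))
    for cyc in cycles:
        members = sorted(n[1] for n in cyc if n[0] == "rxn")
        violations.append(f"cycle through reactions {members}")

    if n_sources == 1 and not cycles:
        src_node = ("met", network.source_metabolite.id)
        reachable = (
            nx.descendants(g, src_node) | {src_node} if src_node in g else {src_node}
        )
        for m in network.metabolites:
            if m.role == ROLE_SINK and ("met", m.id) not in reachable:
                violations.append(f"sink metabolite {m.id!r} unreachable from source")

    return violations


# -- JSON dialect ---------------------------------------------------------

def _network_to_dict(network: StoichiometricNetwork) -> dict:
    return {
        "metabolites": [
            {"id": m.id, "name": m.name, "role": m.role}
            for m in network.metabolites
        ],
        "reactions": [
            {
                "id": r.id,
                "stoichiometry": dict(sorted(r.stoichiometry.items())),
                "ec": list(r.ec_numbers),
                "genes": sorted(r.genes),
                "proton_coefficient": r.proton_coefficient,
                "pathway": r.pathway,
            }
            for r in network.reactions
        ],
        "sink_pathways": list(network.sink_pathways),
    }


def write_network(network: StoichiometricNetwork, path: str | Path) -> None:
    Path(path).write_text(
        json.dumps(_network_to_dict(network), indent=1, sort_keys=False) + "\n"
    )


def load_network(path: str | Path) -> StoichiometricNetwork:
    """Load and validate a network from its JSON dialect.

    Raises :class:`~glucoflux.errors.SchemaError` naming the offending
    record on malformed input, and :class:`ValidationError` listing the
    violations if the structural checks fail.
    """
    try:
        data = json.loads(Path(path).read_text())
    except json.JSONDecodeError as exc:
        raise SchemaError(f"cannot parse network file {path}: {exc}") from exc
    try:
        mets = [
            Metabolite(id=m["id"], name=m.get("name", m["id"]), role=m["role"])
            for m in data["metabolites"]
        ]
        rxns = [
            Reaction(
                id=r["id"],
                stoichiometry={k: float(v) for k, v in r["stoichiometry"].items()},
                ec_numbers=list(r.get("ec", [])),
                genes=frozenset(r.get("genes", [])),
                proton_coefficient=float(r.get("proton_coefficient", 0.0)),
                pathway=r.get("pathway", INTERNAL_PATHWAY),
            )
            for r in data["reactions"]
        ]
    except (KeyError, TypeError) as exc:
        raise SchemaError(f"malformed network file {path}: {exc}") from exc
    net = StoichiometricNetwork(
        metabolites=mets,
        reactions=rxns,
        sink_pathways=list(data.get("sink_pathways", [])),
    )
    violations = validate_network(net)
    if violations:
        raise ValidationError(
            "network failed validation:\n  " + "\n  ".join(violations)
        )
    return net


def curated_network_path() -> Path:
    """Path of the bundled curated glucose-centric network."""
    return Path(
        importlib.resources.files("glucoflux") / "data" / "curated_network.json"
    )


def load_curated_network() -> StoichiometricNetwork:
    """The bundled 8-sink glucose map with its 10 internal transit nodes."""
    return load_network(curated_network_path())
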