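"""End-to-end orchestration: expression cohort in, flux/causal reports out.

Stage order: differential expression -> gene weights -> activity proxy ->
ssGSEA pathway scores -> regularized-NNLS efficiencies -> per-sample flux
QP -> lactate partition -> proton ledger -> causal inference -> signature
regressions. Each stage's status and outputs are recorded in a run
report; a stage failure marks later stages skipped.

Written outputs are deterministic given the same inputs, config and
seed; wall-clock timings go to the side log only.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from glucoflux.causal import (
    construct_causal_variables,
    estimate_ate,
    partial_regression_coordinates,
    permutation_test,
    refute_with_latent_confounder,
)
from glucoflux.config import AnalysisConfig, write_config
from glucoflux.efficiency import (
    assemble_priors,
    ec_class_validation,
    estimate_efficiencies,
    primary_ec_class,
)
from glucoflux.errors import GlucofluxError
from glucoflux.expression import (
    activity_matrix,
    differential_expression,
    gene_weights,
)
from glucoflux.flux import (
    compute_flux_bounds,
    compute_sink_weights,
    lactate_fate_weights,
    mean_allocation_table,
    partition_lactate,
    solve_flux_qp,
)
from glucoflux.network import (
    StoichiometricNetwork,
    internal_stoichiometric_matrix,
)
from glucoflux.pathways import pathway_activity_score, ssgsea_matrix
from glucoflux.protons import network_proton_factors, proton_fluxes
from glucoflux.signatures import (
    fenton_neutralization_fit,
    migration_outcome,
    pathway_pls_score,
    score_signature_regression,
)
from glucoflux.simulate import (
    MKI67,
    SET_FENTON,
    SET_LACTATE_EXPORT,
    SET_LACTYLATION,
    SET_MIGRATION,
    SET_PROLIFERATION,
)

REFUTATION_STRENGTHS = [0.0, 0.2, 0.4, 0.6, 0.8, 1.0]


@dataclass
class RunReport:
    stages: list[dict] = field(default_factory=list)
    manifest: list[str] = field(default_factory=list)
    input_digests: dict[str, str] = field(default_factory=dict)
    config: dict = field(default_factory=dict)
    failed: bool = False
    timings: dict[str, float] = field(default_factory=dict)  # log-only

    def to_json(self) -> str:
        return json.dumps(
            {
                "stages": self.stages,
                "manifest": sorted(self.manifest),
                "input_digests": self.input_digests,
                "config": self.config,
                "failed": self.failed,
            },
            indent=1,
            sort_keys=True,
            default=str,
        )


@dataclass
class PipelineResults:
    """In-memory results of a full run (also serialized to out_dir)."""

    de: pd.DataFrame
    efficiencies: pd.Series
    flux_solutions: list
    allocation_by_stage: pd.DataFrame
    mean_fractions: pd.Series
    proton_fractions: pd.Series
    lactate: pd.DataFrame
    causal: dict
    signatures: dict
    report: RunReport


def _digest(df: pd.DataFrame) -> str:
    return hashlib.sha256(
        df.to_csv(float_format="%.10g").encode()
    ).hexdigest()[:16]


def _vglc_in(expr: pd.DataFrame, network: StoichiometricNetwork) -> pd.Series:
    """Per-sample glucose uptake: summed linear TPM of the transporter genes."""
    transporter_genes = sorted(
        set().union(*(r.genes for r in network.source_reactions()))
    )
    present = [g for g in transporter_genes if g in expr.index]
    if not present:
        raise GlucofluxError("no glucose transporter gene in the matrix")
    linear = np.power(2.0, expr.loc[present].to_numpy(float)) - 1.0
    return pd.Series(linear.clip(0).sum(axis=0), index=expr.columns)


def run_pipeline(
    expr: pd.DataFrame,
    metadata: pd.DataFrame,
    network: StoichiometricNetwork,
    prior_table: pd.DataFrame,
    gene_sets: dict[str, set[str]],
    config: AnalysisConfig | None = None,
    out_dir: str | Path | None = None,
) -> PipelineResults:
    """Run the full analysis; optionally write all reports under out_dir."""
    if config is None:
        config = AnalysisConfig()
    report = RunReport(config=config.to_dict())
    report.input_digests = {
        "expression": _digest(expr),
        "metadata": _digest(metadata),
    }
    out = Path(out_dir) if out_dir is not None else None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)

    log_lines = list(config.provenance_lines())
    results: dict = {}

    def stage(name):
        def deco(fn):
            if report.failed:
                report.stages.append({"name": name, "status": "skipped"})
                return
            t0 = time.perf_counter()
            try:
                fn()
                report.stages.append({"name": name, "status": "ok"})
            except Exception as exc:
                report.failed = True
                report.stages.append(
                    {"name": name, "status": "failed", "error": str(exc)}
                )
            report.timings[name] = time.perf_counter() - t0
        return deco

    tumor_samples = metadata.index[metadata["group"] == "tumor"].tolist()
    tumor_expr = expr[tumor_samples]
    sink_rxns = network.sink_reactions()
    sink_labels = network.sink_pathways

    @stage("differential_expression")
    def _de():
        de = differential_expression(
            expr, metadata["group"], config.p_adj_threshold
        )
        results["de"] = de
        results["weights"] = gene_weights(de, config.gamma, config.eta)

    @stage("activity_matrix")
    def _activity():
        results["E"] = activity_matrix(
            tumor_expr, network, results["weights"],
            on_linear_tpm=config.activity_on_linear_tpm,
        )

    @stage("pathway_scores")
    def _scores():
        sink_sets = {p: gene_sets[p] for p in sink_labels}
        raw = ssgsea_matrix(tumor_expr, sink_sets, config.ssgsea_exponent)
        G = raw.copy()
        for p in sink_labels:
            G.loc[p] = pathway_activity_score(raw.loc[p])
        results["ssgsea_raw"] = raw
        results["G"] = G

    @stage("efficiency_estimation")
    def _eff():
        priors = assemble_priors(
            prior_table,
            network.reaction_ids,
            {
                "curated": config.lambda_curated,
                "predicted": config.lambda_predicted,
                "fallback": config.lambda_fallback,
            },
        )
        S_int = internal_stoichiometric_matrix(network)
        eff, obj = estimate_efficiencies(S_int, results["E"].values, priors)
        results["priors"] = priors
        results["eff"] = eff
        ec_map = {
            r.id: cls
            for r in network.reactions
            if (cls := primary_ec_class(r.ec_numbers)) is not None
        }
        try:
            h, p, med = ec_class_validation(eff, ec_map)
            results["ec_validation"] = {"H": h, "p": p}
        except GlucofluxError:
            results["ec_validation"] = None

    @stage("flux_allocation")
    def _flux():
        eff_sinks = results["eff"].loc[[r.id for r in sink_rxns]].to_numpy()
        uptake = _vglc_in(tumor_expr, network)
        solutions = []
        for s in tumor_samples:
            G_s = results["G"][s].loc[sink_labels].to_numpy(float)
            B = compute_flux_bounds(G_s, eff_sinks)
            w = compute_sink_weights(B, config.sqrt_sink_weights)
            sol = solve_flux_qp(
                network, B, w, float(uptake[s]),
                lambda_qp=config.lambda_qp, sample_id=s,
                rescale_infeasible=config.rescale_infeasible_uptake,
            )
            solutions.append(sol)
        results["flux_solutions"] = solutions
        results["allocation_by_stage"] = mean_allocation_table(solutions, metadata)
        results["mean_fractions"] = mean_allocation_table(solutions).iloc[0]

    @stage("lactate_partition")
    def _lactate():
        fate_sets = {
            SET_LACTATE_EXPORT: gene_sets[SET_LACTATE_EXPORT],
            SET_LACTYLATION: gene_sets[SET_LACTYLATION],
        }
        scores = ssgsea_matrix(tumor_expr, fate_sets, config.ssgsea_exponent)
        shift = min(0.0, float(scores.to_numpy().min()))
        rows = []
        for sol in results["flux_solutions"]:
            v_lac = float(sol.sink_flux.get("lactate_production", 0.0))
            wts = lactate_fate_weights(
                float(scores.loc[SET_LACTATE_EXPORT, sol.sample_id]) - shift,
                float(scores.loc[SET_LACTYLATION, sol.sample_id]) - shift,
                tau=config.tau, alpha=config.alpha,
            )
            lam = config.lambda_qp
            if lam is None:
                lam = 0.5 if v_lac == 0 else 1.0 / (2.0 * v_lac)
            part = partition_lactate(v_lac, wts, lam)
            rows.append(
                {
                    "sample_id": sol.sample_id,
                    "v_lactate": part.v_lactate,
                    "v_export": part.v_export,
                    "v_lactylation": part.v_lactylation,
                    "w_export": wts.w_export,
                }
            )
        results["lactate"] = pd.DataFrame(rows).set_index("sample_id")

    @stage("proton_accounting")
    def _protons():
        h = network_proton_factors(network)
        per_sample = []
        for sol in results["flux_solutions"]:
            J = proton_fluxes(sol.sink_flux, h)
            clipped = J.clip(lower=0.0)
            tot = clipped.sum()
            per_sample.append(clipped / tot if tot > 0 else clipped * 0.0)
        frac = pd.DataFrame(per_sample).mean(axis=0)
        results["proton_factors"] = h
        results["proton_fractions"] = frac.rename("production_fraction")

    @stage("causal_inference")
    def _causal():
        triple = construct_causal_variables(
            tumor_expr,
            results["de"],
            gene_sets["nucleotide_synthesis"],
            gene_sets[SET_PROLIFERATION],
            mki67=MKI67,
            ssgsea_exponent=config.ssgsea_exponent,
        )
        est = estimate_ate(triple)
        p = permutation_test(triple, config.n_perm, seed=config.seed)
        curve = refute_with_latent_confounder(
            triple, REFUTATION_STRENGTHS, seed=config.seed
        )
        results["causal_triple"] = triple
        results["causal"] = {
            "ate": est.ate,
            "beta_w": est.beta_w,
            "intercept": est.intercept,
            "permutation_p": p,
            "refutation_curve": curve,
        }

    @stage("signature_regression")
    def _signatures():
        sigs: dict = {}
        nuc_scores = pathway_pls_score(
            tumor_expr, gene_sets["nucleotide_synthesis"], k=config.pls_components
        )
        y_prolif = tumor_expr.loc[MKI67].to_numpy(float)
        fit = score_signature_regression(nuc_scores, y_prolif)
        sigs["proliferation"] = {"r2": fit.r2,
                                 "coefficients": fit.coefficients.tolist()}
        if "sialic_acid" in gene_sets:
            sial_scores = pathway_pls_score(
                tumor_expr, gene_sets["sialic_acid"], k=config.pls_components
            )
            y_mig = migration_outcome(tumor_expr, gene_sets[SET_MIGRATION])
            fit = score_signature_regression(sial_scores, y_mig)
            sigs["migration"] = {"r2": fit.r2,
                                 "coefficients": fit.coefficients.tolist()}
        pathway_sets = {p: gene_sets[p] for p in sink_labels}
        fit = fenton_neutralization_fit(
            tumor_expr, gene_sets[SET_FENTON], pathway_sets,
            k=config.pls_components,
        )
        sigs["fenton"] = {
            "r2": fit.r2,
            "coefficients": dict(
                zip(fit.predictor_names, fit.coefficients.tolist())
            ),
        }
        results["signatures"] = sigs

    # ---- write outputs ---------------------------------------------------
    if out is not None and not report.failed:
        def write(name: str, writer) -> None:
            path = out / name
            writer(path)
            report.manifest.append(name)

        write("de.tsv", lambda p: results["de"].to_csv(
            p, sep="\t", index_label="gene", float_format="%.6g"))
        write("efficiencies.tsv", lambda p: pd.DataFrame(
            {
                "eff": results["eff"],
                "source": results["priors"].source,
                "lambda": results["priors"].lambda_j,
            }
        ).to_csv(p, sep="\t", index_label="reaction_id", float_format="%.8g"))
        write("allocation_by_stage.tsv", lambda p: results[
            "allocation_by_stage"
        ].mul(100).to_csv(p, sep="\t", index_label="stage", float_format="%.4f"))
        long = pd.concat(
            [
                pd.DataFrame(
                    {
                        "sample_id": sol.sample_id,
                        "pathway": sol.sink_flux.index,
                        "flux": sol.sink_flux.to_numpy(),
                        "fraction": sol.fractions.to_numpy(),
                    }
                )
                for sol in results["flux_solutions"]
            ],
            ignore_index=True,
        )
        write("allocation_per_sample.tsv", lambda p: long.to_csv(
            p, sep="\t", index=False, float_format="%.6g"))
        write("proton_fractions.tsv", lambda p: pd.DataFrame(
            {
                "h": results["proton_factors"],
                "production_percent": results["proton_fractions"] * 100,
            }
        ).to_csv(p, sep="\t", index_label="pathway", float_format="%.4f"))
        write("lactate_partition.tsv", lambda p: results["lactate"].to_csv(
            p, sep="\t", float_format="%.6g"))
        write("causal.json", lambda p: Path(p).write_text(
            json.dumps(results["causal"], indent=1) + "\n"))
        write("partial_regression.tsv", lambda p: partial_regression_coordinates(
            results["causal_triple"]
        ).to_csv(p, sep="\t", index=False, float_format="%.6g"))
        write("signatures.json", lambda p: Path(p).write_text(
            json.dumps(results["signatures"], indent=1) + "\n"))
        write("config.yaml", lambda p: write_config(config, p))
        write("run_report.json", lambda p: Path(p).write_text(
            report.to_json() + "\n"))
        (out / "pipeline.log").write_text(
            "\n".join(
                log_lines
                + [f"{k}: {v:.3f}s" for k, v in report.timings.items()]
            )
            + "\n"
        )

    if report.failed:
        failed = [s for s in report.stages if s["status"] == "failed"]
        raise GlucofluxError(
            f"pipeline stage {failed[0]['name']!r} failed: {failed[0]['error']}"
        )

    return PipelineResults(
        de=results["de"],
        efficiencies=results["eff"],
        flux_solutions=results["flux_solutions"],
        allocation_by_stage=results["allocation_by_stage"],
        mean_fractions=results["mean_fractions"],
        proton_fractions=results["proton_fractions"],
        lactate=results["lactate"],
        causal=results["causal"],
        signatures=results["signatures"],
        report=report,
    )
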