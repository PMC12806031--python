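# glucoflux

Where does the glucose a cancer cell imports actually go?

`glucoflux` answers that question from bulk transcriptomes. Given a
gene-by-sample matrix of log2-TPM expression for tumor and matched
normal tissue, a glucose-centric stoichiometric network, prior
catalytic-efficiency estimates, and the gene sets of the major glucose
sinks, it estimates the fraction of imported glucose allocated to each
of eight terminal fates — nucleotide synthesis, lactate, lipids,
glycosylation, sialic acid, gangliosides, free serine, and TCA entry —
and then quantifies the downstream consequences: net proton
production per pathway, the split of lactate between export and
protein lactylation, the backdoor-adjusted causal effect of
nucleotide-synthesis activity on proliferation, and PLS
signature regressions for proliferation, migration, and
Fenton-reaction neutralization.

It is aimed at computational cancer-metabolism researchers who want a
tested, deterministic, desk-scale implementation of this two-step
constraint-based pipeline, with a synthetic-data generator that plants
ground truth so every stage can be validated.

## The method in brief

**Step 1 — catalytic efficiencies.** Per reaction j, an enzyme-activity
proxy is built from expression, E_ij = Σ_{g∈R_j} w_g · TPM_gi with
composite gene weights w_g = 2^(γ·log2FC) · (1 − p_adj)^η (γ = 0.75,
η = 0.7; Welch t-tests, Benjamini–Hochberg correction). Efficiencies
eff (lumped kcat/Km) are estimated under pseudo-steady-state mass
balance by regularized nonnegative least squares,

    min_{eff ≥ 0} ‖S·(eff ∘ Ē)‖² + Σ_j λ_j (eff_j − eff0_j)²,

with priors eff0 (curated / predicted / global-median fallback).

**Step 2 — flux allocation.** Per sample, sink fluxes solve the
quadratic program

    max_v Σ_s (w_s·v_s − λ·v_s²)
    s.t.  S·v = 0 at internal nodes,  Σ_s v_s = v_glc_in,
          0 ≤ v_s ≤ B_s = G_s · eff_s,

where G_s = exp(z-scored ssGSEA) is a positive pathway-capacity score
and w_s = √B_s / Σ√B. The solver uses the exact KKT form
v_s = clip((w_s − μ)/2λ, 0, B_s) and matches the analytic two-sink
closed form to machine precision. Lactate is further partitioned
between export and lactylation by the same one-constraint QP with
softmax-blended weights; proton fluxes are J_i = v_i·h_i with h_i the
mean net H⁺ coefficient of the pathway's reactions; the causal effect
of nucleotide synthesis on MKI67-measured cell-cycle activity is the
coefficient β_ATE in E[Y] = β₀ + β_ATE·T + β_W·W, with permutation and
latent-confounder refutation tests.

See `docs/methods.md` for assumptions, parameter provenance, and known
limitations.

## Worked example

Generate a synthetic cohort with planted ground truth (100 samples,
8 sinks, planted allocation 28/18/14/11/9/8/7/5 %) and run the full
pipeline:

```sh
glucoflux simulate --out demo/sim --seed 1
printf 'n_perm: 500\nseed: 1\n' > demo/cfg.yaml
glucoflux pipeline \
    --expression demo/sim/expression.tsv \
    --metadata   demo/sim/metadata.tsv \
    --network    demo/sim/network.json \
    --priors     demo/sim/priors.tsv \
    --gene-sets  demo/sim/gene_sets.gmt \
    --config     demo/cfg.yaml \
    --out        demo/out
```

which prints:

```
mean allocation fractions (%):
  nucleotide_synthesis	29.71
  lactate_production	18.23
  lipid_synthesis	13.55
  glycosylation	10.57
  sialic_acid	8.70
  ganglioside_synthesis	8.24
  serine_synthesis	7.17
  tca_entry	3.83
ATE = 0.1665 (permutation p = 0.1996)
```

Reading this: the pipeline recovered the planted allocation to within
1.7 percentage points per pathway (nucleotide synthesis planted at
28 %, recovered at 29.7 %), ranked the planted dominant pathway first,
and estimated a positive adjusted effect of nucleotide-synthesis
activity on proliferation (the cohort-level ATE is attenuated relative
to the planted structural effect of 0.5 because enrichment scores are
noisy proxies of the underlying pathway activity — see the methods
note). `demo/out/` contains the full reports: per-stage allocation
tables, estimated efficiencies, proton production shares, the lactate
export/lactylation split, causal JSON with the refutation curve, and
signature-regression fits.

The same analyses are available as a library:

```python
import glucoflux as gf

network, truth = gf.simulate_network(10, 8, seed=1)
expr, meta, truth, sets = gf.simulate_cohort(network, gf.SimConfig(seed=1), truth)
# ... or load your own expression/metadata/network/priors/gene sets
results = gf.run_pipeline(expr, meta, network, priors, sets,
                          config=gf.AnalysisConfig(seed=1))
print(results.mean_fractions)
```

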