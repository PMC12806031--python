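# Methods

## Scope and model overview

`glucoflux` estimates, from bulk log2-TPM transcriptomes of tumor and
matched normal tissue, how imported glucose is allocated across eight
terminal metabolic fates — nucleotide synthesis, lactate production,
lipid synthesis, glycosylation, sialic-acid synthesis, ganglioside
synthesis, free serine, and TCA entry — and then accounts for the
downstream consequences of that allocation: net proton production,
the export-versus-lactylation fate of lactate, the causal contribution
of nucleotide synthesis to proliferation, and signature-level
regressions linking pathway activity to proliferation, migration and
the neutralization of the cytosolic Fenton reaction.

The flux machinery is a two-step constraint-based procedure on a small
glucose-rooted stoichiometric network. The network has a single source
metabolite (imported glucose), a set of internal transit metabolites
that must be mass-balanced at pseudo-steady state, and one terminal
drain reaction per sink pathway. The bundled curated network uses the
ten internal nodes G6P, F6P, UDP-GlcNAc, G3P, 3-phosphoglycerate,
serine, ceramide, pyruvate, acetyl-CoA and citrate. Minor fates
(e.g. hyaluronic acid) are treated as negligible and omitted.

### Step 1 — catalytic efficiencies by regularized NNLS

Reaction flux is modeled as proportional to an expression-derived
enzyme-activity proxy, `v_j = eff_j * E_j`, where `eff_j` plays the
role of a lumped catalytic efficiency (kcat/Km). The activity proxy
for reaction j in sample i is

    E_ij = sum_{g in genes(j)} w_g * TPM_gi ,
    w_g  = 2^(gamma * log2FC_g) * (1 - p_adj,g)^eta ,

with gamma = 0.75 tempering extreme fold changes and eta = 0.7
down-weighting genes with weak statistical support (Welch t-test,
Benjamini–Hochberg adjusted). Expression enters on the linear TPM
scale (back-transformed as `2^x - 1` from the stored log2 values;
a config flag switches to log2 if desired), and the whole matrix is
divided by its global median over positive entries for numerical
stability. Efficiencies are then estimated by

    min_{eff >= 0}  || S_int (eff o E_bar) ||^2
                    + sum_j lambda_j (eff_j - eff0_j)^2 ,

where `S_int` is the internal-row stoichiometric matrix, `E_bar` the
per-reaction mean activity over tumor samples, and `eff0` prior
efficiencies (curated values, model predictions, or the global median
as fallback). The balance term alone fixes efficiencies only up to a
scale (and, more generally, up to the null space of `S_int diag(E_bar)`);
the priors pin both. The problem is solved exactly as a stacked
nonnegative least squares system with an active-set solver. Prior
adherence defaults to lambda = 1.0 / 0.5 / 0.1 for curated / predicted
/ fallback priors; these are implementation defaults, not literature
values. Estimated efficiencies are sanity-checked by a Kruskal–Wallis
test of median differences across primary EC classes (midranks, tie
correction).

### Step 2 — flux allocation by quadratic programming

Per tumor sample, glucose uptake `V` is the summed linear TPM of the
five glucose transporter genes (SLC2A1, SLC2A3, SLC5A1, SLC5A2,
SLC2A10); its absolute units are arbitrary because all reported
outputs are fractions of `V`. Each sink carries a capacity bound

    B_s = G_s * eff_s ,     G_s = exp(z_s) ,

where `z_s` is the across-sample z-score of the sink gene set's
single-sample enrichment score (ssGSEA, rank weight exponent 0.25 by
default; the exponential-of-z transform is this package's concrete
reading of "an exponential transform to a positive activity score").
Sink weights are square-root-normalized bounds,
`w_s = sqrt(B_s) / sum sqrt(B)` (a linear normalization is available
behind a flag). The allocation solves

    max_v  sum_s (w_s v_s - lambda v_s^2)
    s.t.   mass balance at every internal metabolite,
           sum_s v_s = V,    0 <= v_s <= B_s,   all fluxes >= 0.

Because the objective involves only sink fluxes and internal reactions
are uncapacitated on an acyclic network, the optimum over the sinks is
exactly the one-constraint box QP whose KKT solution is

    v_s(mu) = clip((w_s - mu) / (2 lambda), 0, B_s),
    with mu chosen so that sum_s v_s = V.

The solver brackets `mu` by bisection and then re-solves it exactly on
the identified active set, which gives machine-precision solutions
(verified against the two-sink closed form `v1 = clip(V/2 +
(w1-w2)/(4 lambda), bounds)` to better than 1e-12). Internal fluxes
supporting the sink optimum are recovered by a linear program (minimum
total internal flux as a deterministic tie-break among alternative
routings); if that routing is infeasible — possible only with non-unit
internal stoichiometry — a general SLSQP solve over all fluxes is used
instead. `lambda` defaults to `1/(2 * mean(B))` per sample so that the
quadratic penalty is commensurate with the linear term at typical flux
scales. A sample whose total capacity falls below its uptake raises an
infeasibility error reporting the gap; a config flag instead rescales
the uptake down to the capacity.

### Lactate fate

The lactate flux from step 2 is split between export and protein
lactylation by the same one-constraint QP. Weights come from the
ssGSEA scores of a lactate-transporter set and a lactylation-enzyme
set: scores are shifted nonnegative, log-compressed (`z = ln(1+s)`),
converted by a temperature-tau softmax, and blended with a uniform
prior (`w = alpha/2 + (1-alpha) softmax`; tau = 1.0, alpha = 0.2 by
default — implementation defaults). With the package's default
penalty `lambda = 1/(2 L)` the closed form reduces to
`v_export = w_export * L`, i.e. the export share equals its weight.

### Proton accounting

Each reaction carries the net stoichiometric proton coefficient of its
balanced equation (positive = H+ produced per unit flux). A pathway's
proton factor is the mean coefficient over its reactions; its proton
flux is `J_i = v_i * h_i`. Production shares divide the positive part
of J by total positive production: a net proton-consuming pathway
(lipid synthesis in the curated network, h = -2) contributes a 0%
share rather than a negative one. The ledger is linear in the fluxes,
so shares are invariant to the arbitrary uptake units.

### Causal inference

The effect of nucleotide-synthesis activity (T: ssGSEA of the
tumor-upregulated nucleotide genes, upregulation meaning log2FC >= 0
and BH-adjusted p < 0.05) on cell-cycle activity (Y: log2 MKI67) is
estimated with backdoor adjustment for the shared proliferative drive
(W: ssGSEA of a general proliferation signature with all nucleotide
genes removed, enforcing T/W gene disjointness). All three variables
are z-scored over tumor samples and the ATE is the coefficient of T in
the OLS fit of Y on (1, T, W). Significance uses a permutation test
(T shuffled, N = 500, add-one p-value so p >= 1/(N+1)); robustness
uses a refutation curve re-estimating the ATE after injecting a
standard-normal latent confounder into both T and Y at increasing
strength (additive on the z-scored scale; the same latent draw is
reused across strengths so the curve is smooth and equals the original
estimate exactly at strength 0).

**Known limitation of the permutation scheme.** Plainly shuffling T is
exchangeable only when T is independent of W. When the treatment is
confounded, the shuffle also destroys corr(T, W), so the permutation
null for the *adjusted* coefficient has variance smaller than the
estimator's true null sampling variance by the factor `1 - r^2`
(r = corr(T, W)), and the test is anti-conservative: at r ≈ 0.62 the
nominal 5% level rejects about 12% of the time. The package implements
the plain shuffle as specified; its type-I calibration is therefore
asserted (tests, acceptance script) on the exchangeable null where the
treatment is unconfounded while W still drives the outcome. Users who
need exact calibration under confounding should permute residualized
treatments (Freedman–Lane), which is outside this package's scope.

### Signature regressions

For a gene set with expression block X (samples x genes) and response
y, PLS1 (columns centered, not scaled) extracts components maximizing
covariance between X and y; the first X-score `t = X_c w` with
`w ∝ X_c' y_c` is the set's signature score. One component is the
default. Scores feed ordinary least squares with intercept, summarized
by R^2 = 1 - SSE/SST: proliferation (log2 MKI67 on the nucleotide
score), migration (mean log2 expression of migration genes on the
sialic-acid score), and Fenton neutralization (the Fenton-gene score
regressed jointly on the eight pathway scores, each supervised by its
own mean set expression).

## The synthetic-data generator

The generator replaces the tumor/normal compendium the method was
designed for; its defaults are the package's study conditions:
50 tumor + 50 normal samples, 1000 genes, a 10-internal-node /
8-sink network, planted metabolic fold change of 1 log2 unit,
Gaussian log2 noise with SD 0.5, and a planted causal effect
beta = 0.5 with confounding a = 0.8 (W→T) and b = 0.6 (W→Y). Planted
sink allocation fractions follow a Table-style profile with nucleotide
synthesis dominant: (28, 18, 14, 11, 9, 8, 7, 5)% of an uptake of 100
arbitrary units.

The generator is built so the planted truth is *recoverable by the
default pipeline*, i.e. the planted structure satisfies the
statistical assumptions every stage makes:

* **Flux conservation.** Sink fluxes are planted first; chain fluxes
  are their downstream sums, so `S_int v = 0` holds exactly.
* **Activity consistency.** Each reaction's genes carry linear TPM
  levels equal to `kappa * v_j / eff_j` divided by the gene count, the
  anticipated composite weight `2^(gamma * delta)` of a strongly
  significant gene at the planted fold change delta, and the noise
  inflation `E[2^eps] = exp((sigma ln 2)^2 / 2)`. The global TPM scale
  kappa = 1000 keeps planted levels far above the additive noise floor
  of the linear back-transform; the balance constraints and the
  prior-pinned efficiencies are invariant to it. The uptake reaction's
  true efficiency is derived from the realized transporter activity so
  the NNLS balance holds at the planted truth.
* **Bound calibration.** Planted sink efficiencies are proportional to
  the squared planted fractions, `eff_s = c f_s^2`, with
  `c = n V / (E[e^z] * sum f^2)` so that capacity bounds `B = e^z eff`
  average to the uptake V. Under the square-root weight normalization
  this makes `E[w_s] ≈ f_s`, and with the default penalty
  `lambda = 1/(2 mean B)` the interior KKT optimum
  `v_s = V/n + (w_s - mean w) * mean(B)` has expectation `V f_s` — the
  planted fractions are the expected QP allocation, not a lookup.
* **Exact zero-noise fold changes.** Per-sample latent pathway factors
  (which give the enrichment scores realistic covariance) are centered
  within each sample group, so a zero-noise cohort reproduces the
  planted fold changes exactly.
* **Causal structure.** A proliferation latent P drives the
  proliferation-signature genes; the nucleotide latent is a*P plus
  noise and drives the nucleotide genes; MKI67 receives
  beta*N + b*P. The pipeline's ssGSEA scores are noisy monotone
  proxies of these latents, so the cohort-level ATE is attenuated
  relative to beta (an expected property of proxy measurement, tested
  for sign, not magnitude); quantitative estimator calibration uses
  the direct structural-model generator.

What the generator does **not** emulate: batch effects, stage-specific
biology, realistic pathway gene memberships, count noise, correlated
backgrounds, or non-unit stoichiometry. Passing tests therefore
demonstrate internal consistency and estimator correctness under the
model's own assumptions, not performance on real tumor compendia.

## Numerical choices

* QP multiplier: 200 bisection steps, then an exact active-set solve;
  residual redistribution over interior sinks; tolerance on bound
  activity 1e-9 relative to the largest bound.
* NNLS: `scipy.optimize.nnls` on the stacked system; the solution is
  rejected if its objective exceeds the objective at the prior vector
  (solver sanity guard).
* Zero-variance genes in the Welch test: p = 1 if group means are
  equal, p = 0 otherwise (continuity-respecting convention).
* Upregulation filter is exactly `log2FC >= 0 and p_adj < 0.05`.
* z-scores use the population SD; a zero-variance score vector maps to
  G = 1 for all samples with a warning.
* ssGSEA ties are broken by the stable sort order of the gene index;
  if all in-set rank weights are zero the score falls back to
  unweighted counts.
* Forward selection enumerates candidate terms deterministically (raw,
  squares, interactions lexicographically) and stops at R^2 >= 0.95,
  at `n/10` terms, or when no term improves the fit while keeping at
  least one residual degree of freedom.
* All randomness flows from one integer seed through
  `numpy.random.default_rng`; no global state. Pipeline outputs are
  byte-deterministic given inputs, config and seed (wall-clock timings
  go to a side log).

## Problem sizes

Tests and the acceptance script run at desk scale by design: cohorts
of 100 samples and 1000 genes, networks of up to 10 internal nodes and
8 sinks, 1000 random QP instances, 50 efficiency-recovery networks,
200 causal replicates of n = 1000 with 500-permutation tests. These
sizes give Monte-Carlo errors comfortably inside the asserted
tolerances while keeping the full suite in the tens of seconds.

## Known limitations

* The permutation test's anti-conservativeness under confounded
  treatments (discussed above).
* Cohort-level ATE is attenuated by enrichment-score proxying; the
  package reports it but does not de-attenuate.
* Efficiencies are identified only relative to the prior scale; all
  downstream quantities are deliberately scale-free (fractions,
  shares, R^2).
* The acyclic, irreversible network excludes exchange/recycling fluxes
  and thermodynamic constraints.
* Per-sample capacity bounds can fall below the transporter-derived
  uptake in small cohorts (heavy left tail of `exp(z)`); the package
  surfaces this as an explicit infeasibility with an optional rescue
  policy rather than silently renormalizing.
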