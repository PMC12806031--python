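"""PLS signature scores and the downstream phenotype regressions.

For a gene set G with expression block X (samples x genes) and a
supervising response y (mean log2 expression of G, or a phenotype),
PLS1 extracts latent components maximizing covariance between X and y;
the first X-score t = X_c w (w proportional to X_c' y_c) is the
pathway's signature score. Scores then enter ordinary least squares:

* proliferation: log2 MKI67 regressed on the nucleotide-synthesis score;
* migration: mean log2 expression of migration genes regressed on the
  sialic-acid score;
* Fenton neutralization: the Fenton-reaction score regressed jointly on
  the eight glucose-pathway scores, with R^2 read as the fraction of
  Fenton variability the glucose sinks explain.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.cross_decomposition import PLSRegression

from glucoflux.errors import DomainError, InsufficientDataError, SchemaError


@dataclass
class PLSModel:
    """Fitted PLS1 model: weights, scores, loadings, centering offsets."""

    n_components: int
    x_weights: np.ndarray  # genes x components
    scores: np.ndarray  # samples x components (zero-mean, X-scores)
    x_loadings: np.ndarray
    y_loadings: np.ndarray
    x_mean: np.ndarray
    y_mean: float
    gene_order: list[str]

    def transform(self, X: pd.DataFrame) -> np.ndarray:
        xc = X[self.gene_order].to_numpy(float) - self.x_mean
        # sequential deflation transform, as in NIPALS
        t = np.zeros((len(X), self.n_components))
        for k in range(self.n_components):
            t[:, k] = xc @ self.x_weights[:, k]
            xc = xc - np.outer(t[:, k], self.x_loadings[:, k])
        return t


def fit_pls(X: pd.DataFrame, y: pd.Series | np.ndarray, k: int = 1) -> PLSModel:
    """PLS1 fit of k components maximizing covariance between X and y.

    X is samples-by-genes; columns are centered (not scaled) before
    extraction, so the first weight vector is proportional to the
    centered cross-covariance X_c' y_c.
    """
    y = np.asarray(y, dtype=float)
    n, p = X.shape
    if n < k + 2:
        raise InsufficientDataError(f"need >= k+2 = {k + 2} samples, got {n}")
    if k >= n - 1:
        raise DomainError(f"k = {k} too large for n = {n}")
    if np.all(y == y[0]):
        raise DomainError("response is constant; PLS direction undefined")
    k_eff = min(k, p)
    pls = PLSRegression(n_components=k_eff, scale=False)
    pls.fit(X.to_numpy(float), y)
    return PLSModel(
        n_components=k_eff,
        x_weights=pls.x_weights_,
        scores=pls.x_scores_,
        x_loadings=pls.x_loadings_,
        y_loadings=pls.y_loadings_,
        x_mean=pls._x_mean,
        y_mean=float(np.mean(y)),
        gene_order=list(X.columns),
    )


@dataclass
class SignatureFit:
    """OLS of an outcome on signature scores."""

    coefficients: np.ndarray  # per score column
    intercept: float
    r2: float
    residual_sd: float
    predictor_names: list[str]


def score_signature_regression(
    scores: np.ndarray | pd.DataFrame,
    outcome: pd.Series | np.ndarray,
    predictor_names: list[str] | None = None,
) -> SignatureFit:
    """OLS with intercept of the outcome on sample-by-k score columns."""
    if isinstance(scores, pd.DataFrame):
        if predictor_names is None:
            predictor_names = list(scores.columns)
        scores = scores.to_numpy(float)
    scores = np.asarray(scores, dtype=float)
    if scores.ndim == 1:
        scores = scores[:, None]
    y = np.asarray(outcome, dtype=float)
    n, k = scores.shape
    if len(y) != n:
        raise DomainError(f"{n} score rows vs {len(y)} outcome values")
    if n <= k + 1:
        raise InsufficientDataError(f"need n > k+1 samples (n={n}, k={k})")
    if predictor_names is None:
        predictor_names = [f"t{j + 1}" for j in range(k)]

    A = np.column_stack([np.ones(n), scores])
    beta, *_ = np.linalg.lstsq(A, y, rcond=None)
    resid = y - A @ beta
    sst = float(np.sum((y - y.mean()) ** 2))
    sse = float(np.sum(resid**2))
    r2 = 0.0 if sst == 0 else 1.0 - sse / sst
    dof = n - k - 1
    return SignatureFit(
        coefficients=beta[1:],
        intercept=float(beta[0]),
        r2=float(r2),
        residual_sd=float(np.sqrt(sse / dof)) if dof > 0 else float("nan"),
        predictor_names=predictor_names,
    )


def pathway_pls_score(
    expr: pd.DataFrame, gene_set: set[str], k: int = 1
) -> np.ndarray:
    """First-k PLS X-scores of a gene set, supervised by its mean expression.

    ``expr`` is gene-by-sample log2 TPM; the response is the per-sample
    mean log2 expression of the set's genes, so the score is the
    covariance-dominant expression axis of the pathway.
    """
    genes = sorted(set(expr.index) & gene_set)
    if not genes:
        raise SchemaError("gene set has no genes in the expression matrix")
    X = expr.loc[genes].T  # samples x genes
    y = X.mean(axis=1)
    model = fit_pls(X, y, k=k)
    return model.scores


def migration_outcome(expr: pd.DataFrame, migration_genes: set[str]) -> pd.Series:
    """Per-sample mean log2 expression over the migration gene set."""
    genes = sorted(set(expr.index) & migration_genes)
    if not genes:
        raise SchemaError("migration gene set absent from the matrix")
    return expr.loc[genes].mean(axis=0)


def fenton_neutralization_fit(
    expr: pd.DataFrame,
    fenton_genes: set[str],
    pathway_sets: dict[str, set[str]],
    k: int = 1,
) -> SignatureFit:
    """How much of the Fenton-reaction score the glucose sinks explain.

    The Fenton score is the first PLS1 X-score over the Fenton gene set
    (response: mean Fenton-gene expression); each sink pathway gets its
    analogous score; the Fenton score is regressed on the eight pathway
    scores jointly, in ``pathway_sets`` order. The fit's R^2 is the
    neutralization-explained fraction.
    """
    if not pathway_sets:
        raise SchemaError("no pathway gene sets supplied")
    t_f = pathway_pls_score(expr, fenton_genes, k=k)[:, 0]
    cols, names = [], []
    for name, gs in pathway_sets.items():
        cols.append(pathway_pls_score(expr, gs, k=k)[:, 0])
        names.append(name)
    T = np.column_stack(cols)
    return score_signature_regression(T, t_f, predictor_names=names)
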