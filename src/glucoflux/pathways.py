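"""Pathway activity scoring and the glucose-import statistical model.

Provides a Barbie-style single-sample enrichment score (ssGSEA), its
exponential transform into a strictly positive capacity score, hub-gene
pathway features from a thresholded co-expression network, and the
degree-2 polynomial forward-selection regression of glucose import on
the eight pathway features.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from glucoflux.errors import DomainError, InsufficientDataError, SchemaError


# -- GMT I/O --------------------------------------------------------------

def read_gmt(path: str | Path) -> dict[str, set[str]]:
    """Read gene sets from GMT (name, description, genes...)."""
    sets: dict[str, set[str]] = {}
    for line_no, line in enumerate(Path(path).read_text().splitlines(), 1):
        if not line.strip():
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 3:
            raise SchemaError(f"{path}:{line_no}: GMT line needs >=3 fields")
        name = parts[0]
        if name in sets:
            raise SchemaError(f"{path}:{line_no}: duplicate gene-set name {name!r}")
        genes = {g for g in parts[2:] if g}
        if not genes:
            raise SchemaError(f"{path}:{line_no}: empty gene set {name!r}")
        sets[name] = genes
    return sets


def write_gmt(sets: dict[str, set[str]], path: str | Path) -> None:
    lines = [
        "\t".join([name, name] + sorted(genes)) for name, genes in sets.items()
    ]
    Path(path).write_text("\n".join(lines) + "\n")


# -- single-sample enrichment ---------------------------------------------

def ssgsea_score(
    sample_expression: pd.Series,
    gene_set: set[str],
    exponent: float = 0.25,
) -> float:
    """Single-sample enrichment score of a gene set in one sample.

    Genes are ranked by descending expression; the score is the sum over
    all ranks of the difference between the weighted in-set ECDF (weight
    = |expression|^exponent) and the unweighted out-of-set ECDF. With
    exponent 0 this reduces to a plain ECDF-difference sum.
    """
    genes = sample_expression.index
    in_set = np.fromiter((g in gene_set for g in genes), bool, len(genes))
    n_in = int(in_set.sum())
    n_out = len(genes) - n_in
    if n_in == 0:
        raise DomainError("gene set does not intersect the expressed genes")
    if n_out == 0:
        raise DomainError("gene set covers all expressed genes; complement empty")

    x = sample_expression.to_numpy(float)
    # stable sort on descending expression keeps gene order deterministic on ties
    order = np.argsort(-x, kind="stable")
    in_sorted = in_set[order]
    w = np.abs(x[order]) ** exponent
    w_in = np.where(in_sorted, w, 0.0)
    denom_in = w_in.sum()
    if denom_in == 0.0:
        # all in-set weights zero (e.g. all-zero expression): fall back to counts
        w_in = in_sorted.astype(float)
        denom_in = float(n_in)
    p_in = np.cumsum(w_in) / denom_in
    p_out = np.cumsum(~in_sorted) / n_out
    return float(np.sum(p_in - p_out))


def ssgsea_matrix(
    expr: pd.DataFrame, gene_sets: dict[str, set[str]], exponent: float = 0.25
) -> pd.DataFrame:
    """ssGSEA scores for several gene sets, pathway-by-sample."""
    out = pd.DataFrame(
        index=list(gene_sets), columns=expr.columns, dtype=float
    )
    for name, gs in gene_sets.items():
        for s in expr.columns:
            out.loc[name, s] = ssgsea_score(expr[s], gs, exponent)
    return out


def pathway_activity_score(scores: pd.Series | np.ndarray) -> np.ndarray:
    """Positive capacity score G = exp(z) from per-sample ssGSEA values.

    z is the within-pathway z-score across samples (population SD). A
    zero-variance pathway yields z = 0, hence G = 1, for every sample.
    """
    s = np.asarray(scores, dtype=float)
    if s.size < 2:
        raise InsufficientDataError("need >=2 samples to standardize scores")
    sd = s.std()  # population SD
    z = np.zeros_like(s) if sd == 0.0 else (s - s.mean()) / sd
    return np.exp(z)


# -- co-expression hub features -------------------------------------------

def coexpression_hub_feature(
    expr: pd.DataFrame,
    pathway_genes: set[str],
    r_threshold: float = 0.8,
) -> tuple[set[str], pd.Series]:
    """Hub genes of a pathway and the per-sample pathway feature.

    Edges connect gene pairs with |Pearson r| > r_threshold over all
    expressed genes; hubs are the pathway genes whose degree is at least
    the mean degree over all genes. The feature is the mean expression of
    the hub genes per sample. With no hubs (or no edges at all) the
    feature falls back to the mean over all pathway genes.
    """
    if expr.shape[1] < 3:
        raise InsufficientDataError("need >=3 samples for correlation network")
    present = [g for g in expr.index if g in pathway_genes]
    if len(present) < 2:
        raise InsufficientDataError("need >=2 pathway genes in the matrix")

    x = expr.to_numpy(float)
    sd = x.std(axis=1)
    # zero-variance genes correlate with nothing; mask them out
    with np.errstate(invalid="ignore", divide="ignore"):
        xc = (x - x.mean(axis=1, keepdims=True)) / sd[:, None]
    xc[sd == 0] = 0.0
    r = (xc @ xc.T) / expr.shape[1]
    np.fill_diagonal(r, 0.0)
    adj = np.abs(r) > r_threshold
    degree = adj.sum(axis=1)
    mean_degree = degree.mean()

    gene_pos = {g: i for i, g in enumerate(expr.index)}
    hubs = {g for g in present if degree[gene_pos[g]] >= mean_degree}
    if not hubs or adj.sum() == 0:
        hubs = set(present)
    feature = expr.loc[sorted(hubs)].mean(axis=0)
    return hubs, feature


# -- polynomial forward selection -----------------------------------------

@dataclass
class PolynomialModel:
    """Forward-selected degree-2 polynomial OLS model of glucose import."""

    selected_terms: list[str]
    coefficients: dict[str, float]
    intercept: float
    r2: float
    f_test_p: float
    r2_trace: list[float] = field(default_factory=list)

    def predict(self, features: pd.DataFrame) -> np.ndarray:
        design = _expand_terms(features)
        y = np.full(len(features), self.intercept)
        for term in self.selected_terms:
            y = y + self.coefficients[term] * design[term].to_numpy(float)
        return y


def _expand_terms(features: pd.DataFrame) -> pd.DataFrame:
    """Degree-2 expansion in deterministic order: raw, squares, interactions."""
    cols: dict[str, np.ndarray] = {}
    names = list(features.columns)
    for c in names:
        cols[c] = features[c].to_numpy(float)
    for c in names:
        cols[f"{c}^2"] = features[c].to_numpy(float) ** 2
    for i, a in enumerate(names):
        for b in names[i + 1:]:
            cols[f"{a}*{b}"] = (features[a] * features[b]).to_numpy(float)
    return pd.DataFrame(cols, index=features.index)


def _ols_r2(X: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, float]:
    ones = np.ones((len(y), 1))
    A = np.hstack([ones, X]) if X.size else ones
    beta, *_ = np.linalg.lstsq(A, y, rcond=None)
    resid = y - A @ beta
    sst = float(np.sum((y - y.mean()) ** 2))
    if sst == 0.0:
        return beta, 0.0
    return beta, 1.0 - float(np.sum(resid**2)) / sst


def forward_polynomial_fit(
    features: pd.DataFrame,
    response: pd.Series | np.ndarray,
    degree: int = 2,
    r2_stop: float = 0.95,
    max_features: int | None = None,
) -> PolynomialModel:
    """Greedy forward selection over {x_i, x_i^2, x_i*x_j} maximizing R^2.

    Each step adds the candidate term with the largest resulting model
    R^2 (ties broken by enumeration order: raw terms, then squares, then
    interactions lexicographically); selection stops once R^2 >= r2_stop,
    at max_features terms, or when no term improves the fit. Returns the
    OLS fit with its overall F-test p-value.
    """
    if degree != 2:
        raise DomainError("only degree-2 expansion is supported")
    y = np.asarray(response, dtype=float)
    n = len(y)
    if max_features is None:
        max_features = max(1, n // 10)
    if np.all(y == y[0]):
        return PolynomialModel([], {}, float(y[0]), 0.0, 1.0, [])

    design = _expand_terms(features)
    candidates = list(design.columns)
    selected: list[str] = []
    trace: list[float] = []
    current_r2 = 0.0

    while len(selected) < max_features and current_r2 < r2_stop:
        best_term, best_r2 = None, current_r2
        for term in candidates:
            if term in selected:
                continue
            X = design[selected + [term]].to_numpy(float)
            if n <= X.shape[1] + 1:
                continue  # keep residual degrees of freedom
            _, r2 = _ols_r2(X, y)
            if r2 > best_r2 + 1e-12:
                best_term, best_r2 = term, r2
        if best_term is None:
            break
        selected.append(best_term)
        current_r2 = best_r2
        trace.append(current_r2)

    X = design[selected].to_numpy(float)
    beta, r2 = _ols_r2(X, y)
    k = len(selected)
    if k == 0 or r2 >= 1.0 or n - k - 1 <= 0:
        f_p = 1.0 if k == 0 else 0.0
    else:
        f_stat = (r2 / k) / ((1 - r2) / (n - k - 1))
        f_p = float(stats.f.sf(f_stat, k, n - k - 1))
    return PolynomialModel(
        selected_terms=selected,
        coefficients={t: float(b) for t, b in zip(selected, beta[1:])},
        intercept=float(beta[0]),
        r2=r2,
        f_test_p=f_p,
        r2_trace=trace,
    )
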