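"""Differential expression, gene weighting, and the enzyme-activity proxy.

Expression matrices are gene-by-sample pandas DataFrames of
log2-transformed TPM. Differential expression uses Welch (unequal
variance) two-sample t-tests on the log2 scale; multiple testing is
controlled by Benjamini-Hochberg. Gene weights combine a tempered
fold-change factor 2^(gamma*log2fc) with a significance factor
(1 - p_adj)^eta, and the enzyme-activity proxy for a reaction sums the
weighted linear-TPM expression of its gene set, with a global median
normalization for numerical stability downstream.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from glucoflux.errors import DomainError, InsufficientDataError, SchemaError
from glucoflux.network import StoichiometricNetwork

TUMOR = "tumor"
NORMAL = "normal"


def bh_adjust(p_values: np.ndarray | list[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, clipped at 1."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise DomainError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def _welch_row(t_vals: np.ndarray, n_vals: np.ndarray) -> tuple[float, float]:
    """Welch t statistic and p for one gene, with zero-variance conventions.

    When both groups are constant: p = 1 if the means are equal, p = 0
    otherwise (continuity-respecting limit of the test).
    """
    m1, m2 = t_vals.mean(), n_vals.mean()
    v1 = t_vals.var(ddof=1)
    v2 = n_vals.var(ddof=1)
    if v1 == 0.0 and v2 == 0.0:
        if m1 == m2:
            return 0.0, 1.0
        return np.inf if m1 > m2 else -np.inf, 0.0
    res = stats.ttest_ind(t_vals, n_vals, equal_var=False)
    return float(res.statistic), float(res.pvalue)


def differential_expression(
    expr: pd.DataFrame,
    groups: pd.Series | dict[str, str],
    p_adj_threshold: float = 0.05,
) -> pd.DataFrame:
    """Per-gene Welch t-test of tumor vs normal on log2 expression.

    Parameters
    ----------
    expr : DataFrame
        Gene-by-sample log2 TPM.
    groups : Series or mapping
        sample id -> ``"tumor"`` or ``"normal"``.

    Returns
    -------
    DataFrame indexed by gene with columns ``log2fc`` (tumor mean minus
    normal mean), ``t``, ``p_value``, ``p_adj``, ``upregulated``.
    A gene is upregulated iff log2fc >= 0 and p_adj < the threshold.
    """
    groups = pd.Series(groups)
    tumor_samples = [s for s in expr.columns if groups.get(s) == TUMOR]
    normal_samples = [s for s in expr.columns if groups.get(s) == NORMAL]
    if len(tumor_samples) < 2 or len(normal_samples) < 2:
        raise InsufficientDataError(
            f"need >=2 samples per group, got {len(tumor_samples)} tumor / "
            f"{len(normal_samples)} normal"
        )
    T = expr[tumor_samples].to_numpy(float)
    N = expr[normal_samples].to_numpy(float)
    log2fc = T.mean(axis=1) - N.mean(axis=1)
    t_stats = np.empty(len(expr))
    p_vals = np.empty(len(expr))
    for i in range(len(expr)):
        t_stats[i], p_vals[i] = _welch_row(T[i], N[i])
    p_adj = bh_adjust(p_vals)
    return pd.DataFrame(
        {
            "log2fc": log2fc,
            "t": t_stats,
            "p_value": p_vals,
            "p_adj": p_adj,
            "upregulated": (log2fc >= 0) & (p_adj < p_adj_threshold),
        },
        index=expr.index,
    )


def gene_weights(
    de: pd.DataFrame, gamma: float = 0.75, eta: float = 0.7
) -> pd.DataFrame:
    """Composite gene weights w = 2^(gamma*log2fc) * (1 - p_adj)^eta.

    The fold-change factor tempers extreme fold changes through the
    exponent gamma; the significance factor down-weights genes with weak
    statistical support (it is 0 at p_adj = 1).
    """
    if gamma <= 0 or eta <= 0:
        raise DomainError("gamma and eta must be positive")
    w_fc = np.power(2.0, gamma * de["log2fc"].to_numpy(float))
    w_fdr = np.power(1.0 - de["p_adj"].to_numpy(float), eta)
    return pd.DataFrame(
        {"w_fc": w_fc, "w_fdr": w_fdr, "w": w_fc * w_fdr}, index=de.index
    )


def activity_matrix(
    expr: pd.DataFrame,
    network: StoichiometricNetwork,
    weights: pd.DataFrame,
    on_linear_tpm: bool = True,
) -> "ActivityMatrix":
    """Reaction-by-sample enzyme-activity proxy E.

    E[j, i] = sum over genes g of reaction j of w_g * TPM_{g,i}, computed
    on the linear TPM scale (expression back-transformed as 2^x - 1 from
    the stored log2 values) unless ``on_linear_tpm`` is False. The full
    matrix is then divided by its global median over strictly positive
    entries.
    """
    if on_linear_tpm:
        values = np.power(2.0, expr.to_numpy(float)) - 1.0
        values = np.clip(values, 0.0, None)
    else:
        values = expr.to_numpy(float)
    w = weights["w"].reindex(expr.index).to_numpy(float)
    gene_index = {g: i for i, g in enumerate(expr.index)}

    rows = []
    for r in network.reactions:
        idx = [gene_index[g] for g in sorted(r.genes) if g in gene_index]
        if not idx:
            raise SchemaError(
                f"reaction {r.id!r}: none of its genes are in the expression matrix"
            )
        rows.append((w[idx, None] * values[idx, :]).sum(axis=0))
    E = np.vstack(rows) if rows else np.zeros((0, expr.shape[1]))

    positive = E[E > 0]
    if positive.size == 0:
        raise DomainError("activity matrix has no positive entries; median undefined")
    med = float(np.median(positive))
    return ActivityMatrix(
        values=pd.DataFrame(E / med, index=network.reaction_ids, columns=expr.columns),
        normalization_constant=med,
    )


@dataclass
class ActivityMatrix:
    """Median-normalized reaction-by-sample activity proxy.

    ``normalization_constant`` is the global median over positive entries
    of the raw matrix; the stored values are the raw matrix divided by it.
    """

    values: pd.DataFrame
    normalization_constant: float

    @property
    def reaction_ids(self) -> list[str]:
        return list(self.values.index)

    def mean_activity(self) -> pd.Series:
        """Per-reaction mean over samples (used for cohort-level estimates)."""
        return self.values.mean(axis=1)


def write_de_table(de: pd.DataFrame, path) -> None:
    de.to_csv(path, sep="\t", index_label="gene")
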