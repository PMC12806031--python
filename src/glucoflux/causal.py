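"""Backdoor-adjusted causal effect of nucleotide synthesis on proliferation.

The treatment T is the per-tumor-sample enrichment (ssGSEA) of the
cancer-upregulated nucleotide-synthesis genes; the outcome Y is
normalized log2 MKI67 expression; the confounder W is the enrichment of
a general proliferation signature with nucleotide genes removed, so W
blocks the backdoor path from shared proliferative drive. All three are
z-scored, and under the assumed structural model W -> T -> Y with
W -> Y, the coefficient of T in the multivariable regression

    E[Y] = b0 + b_ATE * T + b_W * W

identifies the average treatment effect. Inference uses a permutation
null (shuffle T) and a latent-confounder refutation curve (inject a
synthetic confounder of growing strength into both T and Y).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from glucoflux.errors import DomainError, InsufficientDataError, SchemaError
from glucoflux.pathways import ssgsea_score


def _zscore(x: np.ndarray) -> np.ndarray:
    sd = x.std()
    if sd == 0:
        raise DomainError("cannot z-score a constant vector")
    return (x - x.mean()) / sd


@dataclass
class CausalTriple:
    """z-scored (treatment, outcome, confounder) vectors over tumor samples."""

    T: np.ndarray
    Y: np.ndarray
    W: np.ndarray

    def __post_init__(self) -> None:
        n = len(self.T)
        if len(self.Y) != n or len(self.W) != n:
            raise DomainError("T, Y, W must have equal length")


@dataclass
class CausalEstimate:
    ate: float
    beta_w: float
    intercept: float
    permutation_p: float | None = None
    refutation_curve: list[tuple[float, float]] = field(default_factory=list)


def construct_causal_variables(
    expr: pd.DataFrame,
    de: pd.DataFrame,
    nucleotide_genes: set[str],
    proliferation_genes: set[str],
    mki67: str = "MKI67",
    ssgsea_exponent: float = 0.25,
) -> CausalTriple:
    """Build the z-scored causal triple from tumor expression.

    T scores the nucleotide-synthesis genes that pass the upregulation
    filter (log2fc >= 0 and adjusted p < 0.05 in the supplied DE table);
    W scores the proliferation signature after removing every nucleotide
    gene (set difference enforces T/W gene disjointness); Y is the log2
    MKI67 row. ``expr`` should contain tumor samples only.
    """
    if mki67 not in expr.index:
        raise SchemaError(f"proliferation marker {mki67!r} absent from matrix")
    upregulated = set(de.index[de["upregulated"]])
    t_set = (nucleotide_genes & upregulated) & set(expr.index)
    if not t_set:
        raise SchemaError(
            "no nucleotide-synthesis gene passes the upregulation filter"
        )
    w_set = (proliferation_genes - nucleotide_genes) & set(expr.index)
    if not w_set:
        raise SchemaError("proliferation signature empty after refinement")

    T = np.array([ssgsea_score(expr[s], t_set, ssgsea_exponent) for s in expr.columns])
    W = np.array([ssgsea_score(expr[s], w_set, ssgsea_exponent) for s in expr.columns])
    Y = expr.loc[mki67].to_numpy(float)
    return CausalTriple(T=_zscore(T), Y=_zscore(Y), W=_zscore(W))


def estimate_ate(triple: CausalTriple) -> CausalEstimate:
    """OLS of Y on (1, T, W); the coefficient of T is the adjusted ATE."""
    n = len(triple.T)
    if n < 10:
        raise InsufficientDataError(f"need >=10 samples, got {n}")
    t_sd, w_sd = triple.T.std(), triple.W.std()
    if t_sd > 0 and w_sd > 0:
        r = float(np.corrcoef(triple.T, triple.W)[0, 1])
        if abs(r) >= 0.999:
            raise DomainError(
                f"T and W are collinear (|r| = {abs(r):.4f}); ATE not identifiable"
            )
    X = np.column_stack([np.ones(n), triple.T, triple.W])
    beta, *_ = np.linalg.lstsq(X, triple.Y, rcond=None)
    return CausalEstimate(
        ate=float(beta[1]), beta_w=float(beta[2]), intercept=float(beta[0])
    )


def permutation_test(
    triple: CausalTriple, n_perm: int = 500, seed: int = 0
) -> float:
    """Permutation p-value for the ATE: shuffle T, re-estimate, compare |ATE|.

    Uses the add-one estimator p = (1 + #{|ate_perm| >= |ate_obs|}) /
    (n_perm + 1), so p is never exactly zero and is bounded below by
    1 / (n_perm + 1).
    """
    if n_perm < 1:
        raise DomainError("n_perm must be >= 1")
    rng = np.random.default_rng(seed)
    observed = abs(estimate_ate(triple).ate)
    exceed = 0
    for _ in range(n_perm):
        t_perm = rng.permutation(triple.T)
        est = estimate_ate(CausalTriple(T=t_perm, Y=triple.Y, W=triple.W))
        if abs(est.ate) >= observed:
            exceed += 1
    return (1 + exceed) / (n_perm + 1)


def refute_with_latent_confounder(
    triple: CausalTriple,
    strengths: list[float],
    seed: int = 0,
) -> list[tuple[float, float]]:
    """Sensitivity of the ATE to an injected latent confounder.

    For each strength c, a standard-normal latent U is added with
    coefficient c to both (z-scored) T and Y and the ATE re-estimated;
    the same U draw is reused across strengths so the curve is smooth in
    c and equals the original estimate exactly at c = 0.
    """
    if not strengths:
        raise DomainError("strengths must be non-empty")
    rng = np.random.default_rng(seed)
    U = rng.standard_normal(len(triple.T))
    curve: list[tuple[float, float]] = []
    for c in strengths:
        perturbed = CausalTriple(
            T=triple.T + c * U, Y=triple.Y + c * U, W=triple.W
        )
        curve.append((float(c), estimate_ate(perturbed).ate))
    return curve


def partial_regression_coordinates(
    triple: CausalTriple,
) -> pd.DataFrame:
    """Residuals of Y and T after removing the linear effect of W.

    The slope of y_resid on t_resid equals the adjusted ATE
    (Frisch-Waugh-Lovell); the coordinates are emitted for partial
    regression plots.
    """
    n = len(triple.T)
    Xw = np.column_stack([np.ones(n), triple.W])
    hat = Xw @ np.linalg.lstsq(Xw, np.column_stack([triple.T, triple.Y]),
                               rcond=None)[0]
    return pd.DataFrame(
        {
            "t_resid": triple.T - hat[:, 0],
            "y_resid": triple.Y - hat[:, 1],
        }
    )
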