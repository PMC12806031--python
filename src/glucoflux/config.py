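"""Central home for every tunable scalar of the analysis.

Each parameter records whether its default is stated by the published
method (``literature``) or is an implementation decision of this package
(``decision``), so sensitivity sweeps and provenance logging are
one-flag operations.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import yaml

from glucoflux.errors import ConfigError

#: provenance of each default: stated in the published method vs chosen here
PARAMETER_PROVENANCE: dict[str, str] = {
    "gamma": "literature",
    "eta": "literature",
    "r_threshold": "literature",
    "poly_degree": "literature",
    "r2_stop": "literature",
    "max_features": "decision",
    "ssgsea_exponent": "decision",
    "lambda_qp": "decision",
    "lambda_curated": "decision",
    "lambda_predicted": "decision",
    "lambda_fallback": "decision",
    "tau": "decision",
    "alpha": "decision",
    "n_perm": "literature",
    "pls_components": "literature",
    "top_proliferation_genes": "literature",
    "p_adj_threshold": "literature",
    "activity_on_linear_tpm": "decision",
    "sqrt_sink_weights": "decision",
    "rescale_infeasible_uptake": "decision",
    "seed": "decision",
}


@dataclass
class AnalysisConfig:
    """All tunable scalars of the pipeline with validated domains.

    Parameters
    ----------
    gamma : float
        Exponent tempering the fold-change factor of the gene weight,
        ``w_fc = 2 ** (gamma * log2fc)``.
    eta : float
        Exponent of the significance factor ``w_fdr = (1 - p_adj) ** eta``.
    r_threshold : float
        Absolute Pearson correlation above which a co-expression edge is
        drawn when identifying hub genes.
    poly_degree : int
        Degree of the polynomial feature expansion (raw, squared and
        pairwise-interaction terms at degree 2).
    r2_stop : float
        Forward selection stops once the model R^2 exceeds this value.
    max_features : int | None
        Cap on selected polynomial terms; ``None`` means ``n_samples // 10``.
    ssgsea_exponent : float
        Rank-weight exponent of the single-sample enrichment running sum.
    lambda_qp : float | None
        Quadratic flux penalty; ``None`` means ``1 / (2 * mean(bounds))``
        computed per sample.
    lambda_curated, lambda_predicted, lambda_fallback : float
        Prior-adherence strengths of the regularized NNLS, keyed by the
        provenance of each efficiency prior.
    tau : float
        Softmax temperature of the lactate-fate weighting.
    alpha : float
        Mixing weight of the uniform prior in the lactate-fate weights,
        in (0, 1).
    n_perm : int
        Number of treatment shuffles in the permutation test.
    pls_components : int
        Number of PLS components retained for signature regressions.
    top_proliferation_genes : int
        Size of the general proliferation signature gene list.
    p_adj_threshold : float
        BH-adjusted p-value below which a gene counts as upregulated.
    activity_on_linear_tpm : bool
        If True (default) the enzyme-activity proxy sums weighted linear
        TPM (back-transformed from log2); if False it sums log2 values.
    sqrt_sink_weights : bool
        If True (default) sink weights are square-root-normalized bounds;
        if False, linearly normalized bounds.
    rescale_infeasible_uptake : bool
        If True, a sample whose capacity bounds sum below its glucose
        uptake has the uptake rescaled down to the total capacity instead
        of raising an infeasibility error.
    seed : int
        Root seed for every stochastic component.
    """

    gamma: float = 0.75
    eta: float = 0.7
    r_threshold: float = 0.8
    poly_degree: int = 2
    r2_stop: float = 0.95
    max_features: int | None = None
    ssgsea_exponent: float = 0.25
    lambda_qp: float | None = None
    lambda_curated: float = 1.0
    lambda_predicted: float = 0.5
    lambda_fallback: float = 0.1
    tau: float = 1.0
    alpha: float = 0.2
    n_perm: int = 500
    pls_components: int = 1
    top_proliferation_genes: int = 500
    p_adj_threshold: float = 0.05
    activity_on_linear_tpm: bool = True
    sqrt_sink_weights: bool = True
    rescale_infeasible_uptake: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        def _positive(name: str, allow_none: bool = False) -> None:
            v = getattr(self, name)
            if v is None:
                if not allow_none:
                    raise ConfigError(f"{name} may not be None")
                return
            if not math.isfinite(v) or v <= 0:
                raise ConfigError(f"{name} must be finite and > 0, got {v!r}")

        for name in ("gamma", "eta", "tau", "lambda_curated",
                     "lambda_predicted", "lambda_fallback"):
            _positive(name)
        _positive("lambda_qp", allow_none=True)
        if not 0 < self.alpha < 1:
            raise ConfigError(f"alpha must lie in (0, 1), got {self.alpha!r}")
        if not 0 < self.r_threshold:
            raise ConfigError("r_threshold must be positive")
        if not 0 < self.r2_stop <= 1:
            raise ConfigError("r2_stop must lie in (0, 1]")
        if not 0 < self.p_adj_threshold <= 1:
            raise ConfigError("p_adj_threshold must lie in (0, 1]")
        if self.ssgsea_exponent < 0:
            raise ConfigError("ssgsea_exponent must be >= 0")
        for name in ("poly_degree", "n_perm", "pls_components",
                     "top_proliferation_genes"):
            v = getattr(self, name)
            if not isinstance(v, int) or v < 1:
                raise ConfigError(f"{name} must be a positive integer, got {v!r}")
        if self.max_features is not None and (
            not isinstance(self.max_features, int) or self.max_features < 1
        ):
            raise ConfigError("max_features must be a positive integer or None")
        if not isinstance(self.seed, int):
            raise ConfigError("seed must be an integer")

    def effective_max_features(self, n_samples: int) -> int:
        """Resolve the feature cap: explicit value or ``n_samples // 10``."""
        if self.max_features is not None:
            return self.max_features
        return max(1, n_samples // 10)

    def lambda_nnls(self, source: str) -> float:
        """Prior-adherence strength for a prior of the given provenance."""
        try:
            return {
                "curated": self.lambda_curated,
                "predicted": self.lambda_predicted,
                "fallback": self.lambda_fallback,
            }[source]
        except KeyError:
            raise ConfigError(f"unknown prior source {source!r}") from None

    def to_dict(self) -> dict[str, Any]:
        return dataclasses.asdict(self)

    def provenance_lines(self) -> list[str]:
        """One line per parameter stating its value and default provenance."""
        return [
            f"{name} = {getattr(self, name)!r} [{PARAMETER_PROVENANCE[name]}]"
            for name in PARAMETER_PROVENANCE
        ]


def load_config(path: str | Path | None) -> AnalysisConfig:
    """Load an :class:`AnalysisConfig` from a YAML file.

    An empty or absent file yields all defaults. Unknown keys and
    out-of-domain values raise :class:`~glucoflux.errors.ConfigError`
    naming the field.
    """
    if path is None:
        return AnalysisConfig()
    raw = Path(path).read_text()
    data = yaml.safe_load(raw) or {}
    if not isinstance(data, dict):
        raise ConfigError(f"config file {path} must contain a mapping")
    known = {f.name for f in dataclasses.fields(AnalysisConfig)}
    unknown = set(data) - known
    if unknown:
        raise ConfigError(f"unknown config keys: {sorted(unknown)}")
    try:
        return AnalysisConfig(**data)
    except TypeError as exc:  # wrong type for a field
        raise ConfigError(str(exc)) from exc


def write_config(cfg: AnalysisConfig, path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump(cfg.to_dict(), sort_keys=True))
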