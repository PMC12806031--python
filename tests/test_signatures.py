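"""PLS1 identities, signature regressions, Fenton neutralization fit."""

import numpy as np
import pandas as pd
import pytest

from glucoflux.errors import DomainError, SchemaError
from glucoflux.signatures import (
    fenton_neutralization_fit,
    fit_pls,
    migration_outcome,
    pathway_pls_score,
    score_signature_regression,
)


def _xy(n=50, p=6, seed=0):
    rng = np.random.default_rng(seed)
    X = pd.DataFrame(rng.normal(size=(n, p)),
                     columns=[f"g{i}" for i in range(p)])
    beta = rng.normal(size=p)
    y = X.to_numpy() @ beta + 0.3 * rng.normal(size=n)
    return X, y


class TestFitPls:
    def test_first_direction_proportional_to_cross_covariance(self):
        """w1 is parallel to centered X'y on random instances (oracle)."""
        for seed in range(20):
            X, y = _xy(seed=seed)
            model = fit_pls(X, y, k=1)
            xc = X.to_numpy() - X.to_numpy().mean(axis=0)
            yc = y - y.mean()
            target = xc.T @ yc
            w = model.x_weights[:, 0]
            cos = abs(w @ target) / (np.linalg.norm(w) * np.linalg.norm(target))
            assert cos == pytest.approx(1.0, abs=1e-10)

    def test_single_gene_equals_simple_regression(self):
        """With p=1 the score is the centered gene and the downstream R^2
        equals the squared Pearson correlation."""
        rng = np.random.default_rng(1)
        x = rng.normal(size=80)
        y = 2 * x + rng.normal(size=80)
        X = pd.DataFrame({"g": x})
        model = fit_pls(X, y, k=1)
        score = model.scores[:, 0]
        assert np.allclose(score / np.abs(score).max(),
                           (x - x.mean()) / np.abs(x - x.mean()).max())
        fit = score_signature_regression(model.scores, y)
        assert fit.r2 == pytest.approx(np.corrcoef(x, y)[0, 1] ** 2, abs=1e-10)

    def test_noiseless_rank_one_reaches_unit_r2(self):
        rng = np.random.default_rng(2)
        u = rng.normal(size=60)
        X = pd.DataFrame(np.outer(u, [1.0, -2.0, 0.5]),
                         columns=["a", "b", "c"])
        y = 3.0 * u
        model = fit_pls(X, y, k=1)
        fit = score_signature_regression(model.scores, y)
        assert fit.r2 == pytest.approx(1.0, abs=1e-10)

    def test_constant_response_rejected(self):
        X, _ = _xy()
        with pytest.raises(DomainError):
            fit_pls(X, np.ones(len(X)), k=1)

    def test_scores_are_centered_and_orthogonal(self):
        X, y = _xy(n=100, p=8, seed=5)
        model = fit_pls(X, y, k=3)
        assert np.allclose(model.scores.mean(axis=0), 0, atol=1e-10)
        gram = model.scores.T @ model.scores
        off = gram - np.diag(np.diag(gram))
        assert np.abs(off).max() < 1e-8 * np.diag(gram).max()


class TestScoreRegression:
    def test_r2_equals_independent_sse_sst(self):
        """Reported R^2 matches 1 - SSE/SST computed from scratch."""
        rng = np.random.default_rng(3)
        scores = rng.normal(size=(120, 3))
        y = scores @ [1.0, -0.5, 0.2] + rng.normal(size=120)
        fit = score_signature_regression(scores, y)
        A = np.column_stack([np.ones(120), scores])
        beta = np.linalg.lstsq(A, y, rcond=None)[0]
        sse = np.sum((y - A @ beta) ** 2)
        sst = np.sum((y - y.mean()) ** 2)
        assert fit.r2 == pytest.approx(1 - sse / sst, abs=1e-12)

    def test_exact_linear_outcome(self):
        rng = np.random.default_rng(4)
        scores = rng.normal(size=(40, 2))
        y = 2 + scores @ [1.0, 3.0]
        fit = score_signature_regression(scores, y)
        assert fit.r2 == pytest.approx(1.0, abs=1e-12)

    def test_null_r2_expectation(self):
        """Outcome independent of k=8 scores at n=200: E[R^2] ~ k/(n-1)."""
        rng = np.random.default_rng(5)
        r2s = []
        for _ in range(150):
            scores = rng.normal(size=(200, 8))
            y = rng.normal(size=200)
            r2s.append(score_signature_regression(scores, y).r2)
        assert np.mean(r2s) == pytest.approx(8 / 199, abs=0.01)


class TestFentonFit:
    def test_exact_linear_combination_gives_unit_r2(self):
        """A Fenton axis built from the pathway axes is fully explained."""
        rng = np.random.default_rng(6)
        n = 120
        factors = {f"p{k}": rng.normal(size=n) for k in range(8)}
        expr = {}
        sets = {}
        for name, f in factors.items():
            genes = [f"{name}_g{j}" for j in range(4)]
            sets[name] = set(genes)
            for j, g in enumerate(genes):
                expr[g] = 5 + (1 + 0.2 * j) * f
        mix = sum((k + 1) * f for k, f in enumerate(factors.values()))
        fgenes = [f"F_g{j}" for j in range(5)]
        for j, g in enumerate(fgenes):
            expr[g] = 4 + (1 + 0.1 * j) * mix
        frame = pd.DataFrame(expr, index=[f"s{i}" for i in range(n)]).T
        fit = fenton_neutralization_fit(frame, set(fgenes), sets)
        assert fit.r2 == pytest.approx(1.0, abs=1e-8)
        assert fit.predictor_names == list(sets)
        assert len(fit.coefficients) == 8

    def test_independent_pathways_explain_little(self):
        rng = np.random.default_rng(7)
        n = 300
        expr = {}
        sets = {}
        for k in range(8):
            genes = [f"p{k}_g{j}" for j in range(3)]
            sets[f"p{k}"] = set(genes)
            f = rng.normal(size=n)
            for g in genes:
                expr[g] = 5 + f + 0.1 * rng.normal(size=n)
        fgenes = [f"F_g{j}" for j in range(5)]
        f = rng.normal(size=n)
        for g in fgenes:
            expr[g] = 4 + f + 0.1 * rng.normal(size=n)
        frame = pd.DataFrame(expr, index=[f"s{i}" for i in range(n)]).T
        fit = fenton_neutralization_fit(frame, set(fgenes), sets)
        assert fit.r2 < 0.1


class TestMigrationOutcome:
    def test_single_gene_set(self):
        expr = pd.DataFrame([[1.0, 2.0], [5.0, 6.0]], index=["a", "b"],
                            columns=["s1", "s2"])
        out = migration_outcome(expr, {"a"})
        assert np.allclose(out, [1.0, 2.0])

    def test_mean_and_order_invariance(self):
        expr = pd.DataFrame([[2.0], [4.0]], index=["a", "b"], columns=["s1"])
        assert migration_outcome(expr, {"a", "b"})["s1"] == 3.0
        assert migration_outcome(expr, {"b", "a"})["s1"] == 3.0

    def test_empty_intersection_rejected(self):
        expr = pd.DataFrame([[1.0]], index=["a"], columns=["s1"])
        with pytest.raises(SchemaError):
            migration_outcome(expr, {"zz"})


def test_pathway_score_is_covariance_axis(cohort):
    """The pathway PLS score correlates with the planted pathway latent."""
    network, expr, meta, _, sets = cohort
    tumor = meta.index[meta["group"] == "tumor"].tolist()
    scores = pathway_pls_score(expr[tumor], sets["nucleotide_synthesis"], k=1)
    # the score must track the mean expression of the set (its supervisor)
    genes = sorted(sets["nucleotide_synthesis"])
    mean_expr = expr[tumor].loc[genes].mean(axis=0)
    r = abs(np.corrcoef(scores[:, 0], mean_expr)[0, 1])
    assert r > 0.95
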