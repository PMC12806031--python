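"""Differential expression, BH correction, gene weights, activity proxy."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from glucoflux.errors import DomainError, InsufficientDataError, SchemaError
from glucoflux.expression import (
    activity_matrix,
    bh_adjust,
    differential_expression,
    gene_weights,
)
from glucoflux.network import Metabolite, Reaction, StoichiometricNetwork


def brute_force_bh(p):
    """Step-up definition evaluated literally (independent oracle)."""
    p = np.asarray(p, float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    adj = np.empty(m)
    running_min = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running_min = min(running_min, p[i] * m / rank)
        adj[i] = running_min
    return np.minimum(adj, 1.0)


class TestBHAdjust:
    @pytest.mark.parametrize(
        "p,expected",
        [
            ([0.05], [0.05]),
            ([0.01, 0.02, 0.03], [0.03, 0.03, 0.03]),
            ([0.04, 0.5], [0.08, 0.5]),
        ],
    )
    def test_hand_examples(self, p, expected):
        assert np.allclose(bh_adjust(p), expected)

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(st.lists(st.floats(0, 1), min_size=1, max_size=50))
    def test_matches_brute_force_step_up(self, p):
        assert np.allclose(bh_adjust(p), brute_force_bh(p), atol=1e-12)

    def test_domain_error(self):
        with pytest.raises(DomainError):
            bh_adjust([0.5, 1.2])


def _frame(tumor, normal):
    cols = [f"T{i}" for i in range(len(tumor[0]))] + [
        f"N{i}" for i in range(len(normal[0]))
    ]
    expr = pd.DataFrame(np.hstack([tumor, normal]), index=["g1"], columns=cols)
    groups = pd.Series(
        ["tumor"] * len(tumor[0]) + ["normal"] * len(normal[0]), index=cols
    )
    return expr, groups


class TestDifferentialExpression:
    def test_welch_hand_example(self):
        """Tumor {1,2,3} vs normal {2,3,4}: t = -1.2247, p ~ 0.288."""
        expr, groups = _frame([[1.0, 2.0, 3.0]], [[2.0, 3.0, 4.0]])
        de = differential_expression(expr, groups)
        assert de.loc["g1", "log2fc"] == pytest.approx(-1.0)
        assert de.loc["g1", "t"] == pytest.approx(-1.2247, abs=1e-4)
        assert de.loc["g1", "p_value"] == pytest.approx(0.288, abs=0.002)

    def test_identical_groups(self):
        expr, groups = _frame([[2.0, 2.0, 2.0]], [[2.0, 2.0, 2.0]])
        de = differential_expression(expr, groups)
        assert de.loc["g1", "log2fc"] == 0.0
        assert de.loc["g1", "p_value"] == 1.0
        assert not de.loc["g1", "upregulated"]

    def test_zero_variance_distinct_means(self):
        expr, groups = _frame([[3.0, 3.0]], [[1.0, 1.0]])
        de = differential_expression(expr, groups)
        assert de.loc["g1", "p_value"] == 0.0

    def test_insufficient_samples(self):
        expr, groups = _frame([[1.0]], [[2.0, 3.0]])
        with pytest.raises(InsufficientDataError):
            differential_expression(expr, groups)

    def test_planted_effect_is_detected(self, cohort):
        """Planted metabolic fold changes at noise 0.5, n=50/50 are overwhelming."""
        _, expr, meta, truth, _ = cohort
        de = differential_expression(expr, meta["group"])
        strong = truth.true_log2fc.index[truth.true_log2fc >= 1.0]
        assert de.loc[strong, "upregulated"].all()
        # MKI67 carries extra latent (causal-signal) variance by design
        strong = strong.drop("MKI67")
        assert (de.loc[strong, "p_value"] < 1e-10).all()


class TestGeneWeights:
    def _de(self, log2fc, p_adj):
        return pd.DataFrame({"log2fc": log2fc, "p_adj": p_adj})

    def test_point_values(self):
        de = self._de([0.0, 2.0, 1.0], [0.0, 1.0, 0.05])
        w = gene_weights(de, gamma=0.75, eta=0.7)
        assert w["w"].iloc[0] == pytest.approx(1.0)
        assert w["w"].iloc[1] == 0.0  # p_adj = 1 kills any fold change
        assert w["w"].iloc[2] == pytest.approx(
            2**0.75 * 0.95**0.7, abs=1e-4
        )  # ~1.6225

    def test_monotone_in_fold_change_and_significance(self):
        lfc = np.linspace(-2, 2, 9)
        w1 = gene_weights(self._de(lfc, np.full(9, 0.2)))["w"].to_numpy()
        assert (np.diff(w1) > 0).all()
        p = np.linspace(0, 0.99, 9)
        w2 = gene_weights(self._de(np.ones(9), p))["w"].to_numpy()
        assert (np.diff(w2) < 0).all()


def _mini_network():
    mets = [
        Metabolite("glc", "glc", "source"),
        Metabolite("a", "a", "internal"),
        Metabolite("s", "s", "sink"),
    ]
    rxns = [
        Reaction("r1", {"glc": -1, "a": 1}, genes=frozenset({"g1"})),
        Reaction("r2", {"a": -1, "s": 1}, genes=frozenset({"g2", "g3"}),
                 pathway="p"),
    ]
    return StoichiometricNetwork(mets, rxns, ["p"])


class TestActivityMatrix:
    def _weights(self, w):
        return pd.DataFrame({"w": pd.Series(w)})

    def test_single_gene_reaction_tracks_tpm(self):
        net = _mini_network()
        # log2(TPM + 1) stored; TPM rows: g1 = (3, 7), others constant 1
        expr = pd.DataFrame(
            np.log2(np.array([[3, 7], [1, 1], [1, 1]]) + 1.0),
            index=["g1", "g2", "g3"], columns=["s1", "s2"],
        )
        E = activity_matrix(expr, net, self._weights({"g1": 1, "g2": 1, "g3": 1}))
        raw = E.values * E.normalization_constant
        assert np.allclose(raw.loc["r1"], [3, 7])
        assert np.allclose(raw.loc["r2"], [2, 2])
        assert np.median(E.values.to_numpy()[E.values.to_numpy() > 0]) == 1.0

    def test_weighted_sum_arithmetic(self):
        """Weights (1,2) on TPM (3,4) give a raw entry of 11."""
        net = _mini_network()
        expr = pd.DataFrame(
            np.log2(np.array([[5.0], [3.0], [4.0]]) + 1.0),
            index=["g1", "g2", "g3"], columns=["s1"],
        )
        E = activity_matrix(expr, net, self._weights({"g1": 1, "g2": 1, "g3": 2}))
        raw = E.values * E.normalization_constant
        assert raw.loc["r2", "s1"] == pytest.approx(11.0)

    def test_all_zero_expression_rejected(self):
        net = _mini_network()
        expr = pd.DataFrame(0.0, index=["g1", "g2", "g3"], columns=["s1", "s2"])
        with pytest.raises(DomainError):
            activity_matrix(expr, net, self._weights({"g1": 1, "g2": 1, "g3": 1}))

    def test_missing_genes_named(self):
        net = _mini_network()
        expr = pd.DataFrame([[1.0, 2.0]], index=["g1"], columns=["s1", "s2"])
        with pytest.raises(SchemaError, match="r2"):
            activity_matrix(expr, net, self._weights({"g1": 1}))

    def test_scale_equivariance(self):
        """Scaling all linear TPM by c leaves the normalized matrix unchanged."""
        net = _mini_network()
        rng = np.random.default_rng(0)
        tpm = rng.uniform(1, 50, size=(3, 4))
        w = self._weights({"g1": 1.0, "g2": 0.5, "g3": 2.0})
        cols = list("abcd")
        e1 = activity_matrix(
            pd.DataFrame(np.log2(tpm + 1), index=["g1", "g2", "g3"],
                         columns=cols), net, w)
        e2 = activity_matrix(
            pd.DataFrame(np.log2(7.3 * tpm + 1), index=["g1", "g2", "g3"],
                         columns=cols), net, w)
        pd.testing.assert_frame_equal(e1.values, e2.values)
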