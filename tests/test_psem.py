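import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from conftest import d_separated_bruteforce, random_dag
from richabund.psem import test_claim as claim_p_value
from richabund.psem import (
    RANDOM_INTERCEPT,
    DagSpec,
    EquationSpec,
    IndependenceClaim,
    basis_set,
    fisher_c,
    fit_psem,
    information_criteria,
)


class TestDagSpec:
    def test_rejects_cycle(self):
        with pytest.raises(ValueError, match="cycle"):
            DagSpec(nodes=("a", "b"), edges=(("a", "b"), ("b", "a")))

    def test_rejects_self_loop_and_duplicates(self):
        with pytest.raises(ValueError, match="self-loop"):
            DagSpec(nodes=("a",), edges=(("a", "a"),))
        with pytest.raises(ValueError, match="duplicate"):
            DagSpec(nodes=("a", "b"), edges=(("a", "b"), ("a", "b")))

    def test_exogenous_and_parents(self):
        dag = DagSpec(nodes=("e", "d", "a"), edges=(("e", "d"), ("e", "a"), ("d", "a")))
        assert dag.exogenous == ("e",)
        assert set(dag.parents("a")) == {"e", "d"}


class TestBasisSet:
    def test_fully_connected_graph_has_empty_basis(self):
        dag = DagSpec(nodes=("a", "b", "c"), edges=(("a", "b"), ("a", "c"), ("b", "c")))
        assert basis_set(dag) == []

    def test_exogenous_pairs_excluded(self):
        dag = DagSpec(nodes=("x", "y", "z"), edges=(("x", "z"), ("y", "z")))
        assert basis_set(dag) == []  # only non-adjacent pair is exogenous-exogenous

    def test_conditioning_is_union_of_parents(self):
        dag = DagSpec(
            nodes=("e", "d", "s", "a"),
            edges=(("e", "s"), ("e", "d"), ("e", "a"), ("d", "a"), ("a", "s")),
        )
        (claim,) = basis_set(dag)
        assert {claim.x, claim.y} == {"d", "s"}
        assert set(claim.conditioning_set) == {"e", "a"}

    def test_agrees_with_bruteforce_oracle_on_random_dags(self):
        """Every emitted claim is a true d-separation, and claims cover
        exactly the non-adjacent pairs that are not both exogenous."""
        rng = np.random.default_rng(2024)
        for _ in range(100):
            g = random_dag(rng)
            nodes = tuple(sorted(g.nodes))
            dag = DagSpec(nodes=nodes, edges=tuple(g.edges))
            claims = basis_set(dag)
            exo = set(dag.exogenous)
            expected_pairs = {
                frozenset((x, y))
                for i, x in enumerate(nodes)
                for y in nodes[i + 1 :]
                if not dag.adjacent(x, y) and not (x in exo and y in exo)
            }
            assert {frozenset((c.x, c.y)) for c in claims} == expected_pairs
            for c in claims:
                assert set(c.conditioning_set) == (
                    set(dag.parents(c.x)) | set(dag.parents(c.y))
                ) - {c.x, c.y}
                assert d_separated_bruteforce(g, c.x, c.y, set(c.conditioning_set)), (
                    f"claim {c.label()} not d-separated in {sorted(g.edges)}"
                )

    def test_deterministic_ordering_and_response_choice(self):
        dag = DagSpec(
            nodes=("e", "d", "s", "a"),
            edges=(("e", "s"), ("e", "d"), ("e", "a"), ("d", "a"), ("s", "a")),
        )
        c1 = basis_set(dag)
        c2 = basis_set(DagSpec(nodes=dag.nodes, edges=dag.edges))
        assert [(c.x, c.y, c.response_node) for c in c1] == [
            (c.x, c.y, c.response_node) for c in c2
        ]
        # downstream node responds when a directed path orders the pair
        chain = DagSpec(nodes=("x", "m", "y", "w"), edges=(("x", "m"), ("m", "y"), ("w", "m")))
        claims = {frozenset((c.x, c.y)): c for c in basis_set(chain)}
        assert claims[frozenset(("x", "y"))].response_node == "y"


class TestClaimTesting:
    def test_perfect_dependence(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=100)
        data = pd.DataFrame({"x": x, "y": x})
        claim = IndependenceClaim(x="x", y="y", conditioning_set=(), response_node="y")
        assert claim_p_value(claim, data) < 1e-10

    def test_matches_correlation_test_without_conditioning(self):
        rng = np.random.default_rng(2)
        data = pd.DataFrame({"x": rng.normal(size=5000), "y": rng.normal(size=5000)})
        claim = IndependenceClaim(x="x", y="y", conditioning_set=(), response_node="y")
        p_reg = claim_p_value(claim, data)
        p_cor = stats.pearsonr(data.x, data.y).pvalue
        assert p_reg == pytest.approx(p_cor, abs=1e-4)

    def test_rank_deficient_design_raises(self):
        rng = np.random.default_rng(3)
        z = rng.normal(size=50)
        data = pd.DataFrame({"x": z, "z1": z, "z2": z, "y": rng.normal(size=50)})
        claim = IndependenceClaim(x="x", y="y", conditioning_set=("z1", "z2"), response_node="y")
        with pytest.raises(ValueError, match="rank-deficient"):
            claim_p_value(claim, data)

    def test_too_few_observations(self):
        data = pd.DataFrame({"x": [1.0, 2.0], "y": [0.5, 0.1]})
        claim = IndependenceClaim(x="x", y="y", conditioning_set=(), response_node="y")
        with pytest.raises(ValueError, match="too few"):
            claim_p_value(claim, data)


class TestFisherC:
    def test_all_ones(self):
        assert fisher_c([1.0, 1.0]) == (0.0, 4, 1.0)

    def test_halves(self):
        c, df, p = fisher_c([0.5, 0.5])
        assert c == pytest.approx(4 * math.log(2), abs=1e-9)
        assert df == 4

    def test_empty(self):
        assert fisher_c([]) == (0.0, 0, 1.0)

    def test_single_claim_survival_is_exp_minus_half_c(self):
        for pv in (0.9, 0.3, 0.045224):
            c, df, p = fisher_c([pv])
            assert df == 2
            assert p == pytest.approx(math.exp(-c / 2), rel=1e-12)
        # a published single-claim C of 6.192 sits just under the 0.05 line
        assert stats.chi2.sf(6.192, 2) == pytest.approx(math.exp(-6.192 / 2), rel=1e-12)
        assert stats.chi2.sf(6.192, 2) < 0.05 < stats.chi2.sf(5.991, 2) + 1e-4

    def test_zero_p_floored_with_warning(self):
        with pytest.warns(RuntimeWarning, match="floored"):
            c, df, p = fisher_c([0.0])
        assert math.isfinite(c) and c > 0


class TestInformationCriteria:
    def test_closed_form(self):
        bic, cic = information_criteria(0.0, 8, 28)
        assert bic == pytest.approx(8 * math.log(28), rel=1e-12)
        assert cic == 16.0

    def test_preconditions(self):
        with pytest.raises(ValueError):
            information_criteria(0.0, 0, 28)
        with pytest.raises(ValueError):
            information_criteria(-1.0, 2, 28)

    @pytest.mark.parametrize("n", [3, 7, 8, 200])
    def test_bic_minus_cic_sign_flips_at_e_squared(self, n):
        bic, cic = information_criteria(1.0, 5, n)
        assert np.sign(bic - cic) == np.sign(math.log(n) - 2.0)


class TestModelFile:
    def test_yaml_roundtrip(self, tmp_path):
        from richabund.psem import load_model

        path = tmp_path / "model.yaml"
        path.write_text(
            "nodes: [e, d, s, a]\n"
            "edges:\n"
            "  - [e, s]\n  - [e, d]\n  - [e, a]\n  - [d, a]\n  - [s, a]\n"
            "estimator: ols\n"
        )
        dag, equations = load_model(path)
        assert set(dag.exogenous) == {"e"}
        assert {eq.response for eq in equations} == {"d", "s", "a"}
        by_response = {eq.response: set(eq.predictors) for eq in equations}
        assert by_response["a"] == {"e", "d", "s"}
        (claim,) = basis_set(dag)
        assert {claim.x, claim.y} == {"d", "s"}

    def test_missing_key_errors(self, tmp_path):
        from richabund.psem import load_model

        path = tmp_path / "bad.yaml"
        path.write_text("nodes: [a, b]\n")
        with pytest.raises(ValueError, match="edges"):
            load_model(path)


class TestFitPsem:
    def _msh_model(self):
        dag = DagSpec(
            nodes=("e", "d", "s", "a"),
            edges=(("e", "s"), ("e", "d"), ("e", "a"), ("d", "a"), ("s", "a")),
        )
        eqs = [
            EquationSpec("d", dag.parents("d")),
            EquationSpec("s", dag.parents("s")),
            EquationSpec("a", dag.parents("a")),
        ]
        return dag, eqs

    def _simulate(self, rng, n=400):
        e = rng.uniform(0, 1, n)
        d = 0.8 * e + rng.normal(0, 0.5, n)
        s = -0.5 * e + rng.normal(0, 0.5, n)
        a = 0.6 * s - 0.7 * d + 0.3 * e + rng.normal(0, 0.5, n)
        return pd.DataFrame({"e": e, "d": d, "s": s, "a": a})

    def test_true_graph_rarely_rejected(self):
        dag, eqs = self._msh_model()
        rng = np.random.default_rng(7)
        passes = sum(
            fit_psem(dag, eqs, self._simulate(rng)).c_p_value > 0.05 for _ in range(20)
        )
        assert passes >= 16

    def test_empty_basis_set_gives_bic_k_log_n(self):
        dag = DagSpec(nodes=("x", "y"), edges=(("x", "y"),))
        rng = np.random.default_rng(8)
        data = pd.DataFrame({"x": rng.normal(size=50)})
        data["y"] = 2 * data.x + rng.normal(size=50)
        fit = fit_psem(dag, [EquationSpec("y", ("x",))], data)
        assert fit.fisher_c == 0.0 and fit.c_p_value == 1.0
        assert fit.bic == pytest.approx(fit.K * math.log(50), rel=1e-12)

    def test_k_counts_and_shared_n(self):
        dag, eqs = self._msh_model()
        fit = fit_psem(dag, eqs, self._simulate(np.random.default_rng(9)))
        # d~e: 2 coef + 1 var; s~e: 3; a~s+d+e: 4 coef + 1 var
        assert fit.K == 3 + 3 + 5
        assert all(c.n == fit.n for c in fit.components)

    def test_equation_order_invariance(self):
        dag, eqs = self._msh_model()
        data = self._simulate(np.random.default_rng(10))
        f1 = fit_psem(dag, eqs, data)
        f2 = fit_psem(dag, list(reversed(eqs)), data)
        assert (f1.fisher_c, f1.K, f1.n, f1.bic) == (f2.fisher_c, f2.K, f2.n, f2.bic)

    def test_equations_must_match_dag(self):
        dag, eqs = self._msh_model()
        data = self._simulate(np.random.default_rng(11))
        with pytest.raises(ValueError, match="cover endogenous"):
            fit_psem(dag, eqs[:2], data)
        bad = [EquationSpec("d", ("s",)), eqs[1], eqs[2]]
        with pytest.raises(ValueError, match="parents"):
            fit_psem(dag, bad, data)

    def test_random_intercept_estimator(self):
        rng = np.random.default_rng(12)
        n, k = 300, 30
        groups = np.repeat([f"g{i}" for i in range(k)], n // k)
        u = rng.normal(0, 1.0, k)[np.arange(n) // (n // k)]
        x = rng.normal(size=n)
        y = 1.5 * x + u + rng.normal(0, 0.5, n)
        data = pd.DataFrame({"x": x, "y": y, "g": groups})
        dag = DagSpec(nodes=("x", "y"), edges=(("x", "y"),))
        eqs = [EquationSpec("y", ("x",), estimator=RANDOM_INTERCEPT, grouping="g")]
        fit = fit_psem(dag, eqs, data)
        comp = fit.components[0]
        assert comp.coefficients["x"] == pytest.approx(1.5, abs=0.15)
        assert comp.random_effect_variance == pytest.approx(1.0, rel=0.6)
        assert comp.k == 4  # intercept + slope + residual var + RI var
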