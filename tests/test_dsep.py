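"""d-separation tests and Fisher's C."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from gmlpath import (
    IndependenceClaim,
    PathDAG,
    PathEdge,
    PathNode,
    basis_set,
    claim_to_model,
    fishers_c,
)
from gmlpath.dsep import test_claim as run_claim_test
from gmlpath.dsep import test_model_fit as run_model_fit
from gmlpath.mixedfit import CategoricalTerm, QuadraticTerm


class TestFishersC:
    def test_single_p_round_trips(self):
        for p in (0.01, 0.2, 0.5, 0.97):
            res = fishers_c([p])
            assert res.C == pytest.approx(-2 * np.log(p))
            assert res.df == 2
            # chi2 with 2 df: survival(C) = exp(-C/2) = p
            assert res.p == pytest.approx(p, rel=1e-12)

    def test_two_half_pvalues(self):
        res = fishers_c([0.5, 0.5])
        assert res.C == pytest.approx(2.7726, abs=1e-4)
        assert res.df == 4
        # chi2_4 survival: e^{-x/2} (1 + x/2)
        assert res.p == pytest.approx(0.5966, abs=1e-4)

    def test_published_combined_statistic(self):
        # fifty equal claim p-values chosen so C matches the published
        # statistic: p_i = exp(-C / 2K) with C = 119.32, K = 50
        p = np.exp(-119.32 / 100)
        res = fishers_c([p] * 50)
        assert res.C == pytest.approx(119.32, abs=1e-10)
        assert res.df == 100
        assert round(res.p, 3) == 0.091

    def test_invalid_inputs_error(self):
        with pytest.raises(ValueError):
            fishers_c([])
        with pytest.raises(ValueError):
            fishers_c([0.0, 0.5])
        with pytest.raises(ValueError):
            fishers_c([1.2])
        assert np.isfinite(fishers_c([1e-300]).C)

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(st.lists(st.floats(1e-6, 1.0), min_size=2, max_size=12))
    def test_permutation_invariance(self, ps):
        a = fishers_c(ps)
        b = fishers_c(list(reversed(ps)))
        assert a.C == pytest.approx(b.C)
        assert a.p == pytest.approx(b.p)

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(
        st.lists(st.floats(1e-6, 0.99), min_size=1, max_size=8),
        st.integers(0, 7),
        st.floats(0.1, 0.9),
    )
    def test_decreasing_any_p_increases_c(self, ps, idx, shrink):
        idx = idx % len(ps)
        base = fishers_c(ps)
        smaller = list(ps)
        smaller[idx] = smaller[idx] * shrink
        res = fishers_c(smaller)
        assert res.C > base.C
        assert res.p <= base.p + 1e-12


def chain_dag(grouping=("nest",)):
    return PathDAG(
        [
            PathNode("X", grouping=grouping),
            PathNode("Y", grouping=grouping),
            PathNode("Z", grouping=grouping),
        ],
        [PathEdge("X", "Y"), PathEdge("Y", "Z")],
    )


class TestClaimToModel:
    def test_chain_claim_regresses_later_node(self):
        dag = chain_dag()
        (claim,) = basis_set(dag)
        spec = claim_to_model(claim, dag)
        assert spec.response == "Z"
        names = {getattr(t, "name", None) for t in spec.fixed_terms}
        assert names == {"X", "Y"}
        assert spec.random_nesting == ("nest",)

    def test_collider_claim_with_empty_conditioning(self):
        dag = PathDAG(
            [PathNode("X"), PathNode("Y"), PathNode("Z")],
            [PathEdge("X", "Z"), PathEdge("Y", "Z")],
        )
        (claim,) = basis_set(dag)
        spec = claim_to_model(claim, dag)
        assert spec.response == claim.response
        assert len(spec.fixed_terms) == 1

    def test_quadratic_conditioning_expands_per_structural_equation(self):
        dag = PathDAG(
            [PathNode("M"), PathNode("T"), PathNode("W")],
            [PathEdge("M", "W", "quadratic"), PathEdge("T", "M")],
        )
        # claim: T independent of W given M (quadratic parent of W)
        (claim,) = basis_set(dag)
        spec = claim_to_model(claim, dag)
        quads = [t for t in spec.fixed_terms if isinstance(t, QuadraticTerm)]
        assert [t.name for t in quads] == ["M"]

    def test_sparrow_capture_node_is_response(self, sparrow):
        claims = basis_set(sparrow)
        match = [
            c for c in claims if {c.x, c.y} == {"nestling_mass", "time_captured"}
        ]
        assert len(match) == 1
        # the repeated-capture variable, later in the nesting-aware
        # topological order, is modelled as the response
        assert match[0].response == "time_captured"
        order = sparrow.topological_order()
        assert order.index("time_captured") > order.index("nestling_mass")

    def test_categorical_tested_variable_uses_dummies(self, sparrow):
        claims = basis_set(sparrow)
        year_claims = [c for c in claims if "year" in (c.x, c.y)]
        assert year_claims
        for c in year_claims:
            assert c.response != "year"
            spec = claim_to_model(c, sparrow)
            assert any(
                isinstance(t, CategoricalTerm) and t.name == "year"
                for t in spec.fixed_terms
            )


def _simulate_chain(rng, n_groups=25, m=4, beta_xz=0.0):
    """Nested data satisfying X -> Y -> Z (optionally a direct X -> Z)."""
    g = np.repeat(np.arange(n_groups), m)
    n = len(g)
    x = rng.normal(size=n)
    y = 0.6 * x + rng.normal(0, 1.5, n_groups)[g] * 0.3 + rng.normal(0, 0.8, n)
    z = 0.6 * y + beta_xz * x + rng.normal(0, 1.5, n_groups)[g] * 0.3 + rng.normal(0, 0.8, n)
    return pd.DataFrame({"X": x, "Y": y, "Z": z, "nest": g.astype(str)})


class TestClaimTesting:
    def test_null_claim_p_values_are_approximately_uniform(self):
        dag = chain_dag()
        (claim,) = basis_set(dag)
        ps = []
        for seed in range(400):
            rng = np.random.default_rng(50_000 + seed)
            table = _simulate_chain(rng)
            ps.append(run_claim_test(claim, dag, table).p)
        ps = np.array(ps)
        rejection = np.mean(ps < 0.05)
        assert 0.02 <= rejection <= 0.09
        ks = stats.kstest(ps, "uniform").statistic
        assert ks < 0.08

    def test_strong_violation_is_detected(self):
        dag = chain_dag()
        (claim,) = basis_set(dag)
        hits = 0
        for seed in range(40):
            rng = np.random.default_rng(60_000 + seed)
            table = _simulate_chain(rng, n_groups=40, beta_xz=0.5)
            hits += run_claim_test(claim, dag, table).p < 0.05
        assert hits >= 38

    def test_predictor_in_conditioning_set_rejected(self):
        dag = chain_dag()
        claim = IndependenceClaim(
            x="X", y="Z", conditioning=frozenset(("X", "Y")), response="Z"
        )
        rng = np.random.default_rng(0)
        with pytest.raises(ValueError, match="conditioning"):
            run_claim_test(claim, dag, _simulate_chain(rng))


class TestModelFit:
    def test_data_from_the_dag_is_not_rejected(self, sparrow, std_tables):
        result = run_model_fit(sparrow, std_tables)
        assert result.df == 2 * result.K
        assert result.p > 0.01
        table = result.claim_table()
        assert len(table) == result.K
        assert set(table.columns) >= {"x", "y", "conditioning", "beta", "p"}

    def test_missing_strong_edge_is_detected(self, default_config):
        # analyse with the tarsus -> mass edge (beta 0.67) removed: the
        # basis set then claims tarsus_nest and nestling_mass independent
        from gmlpath.pipeline import prepare_path_tables, standardize_path_tables
        from gmlpath.simulate import SimulationConfig, simulate_study, sparrow_dag

        rejected = 0
        for seed in range(12):
            config = SimulationConfig(seed=7000 + seed)
            study = simulate_study(config)
            dag = sparrow_dag(config)
            slim = PathDAG(
                list(dag.nodes.values()),
                [e for e in dag.edges
                 if not (e.source == "tarsus_nest" and e.target == "nestling_mass")],
                dag.free_covariance,
            )
            tables = prepare_path_tables(study.nestlings, study.captures)
            std, _ = standardize_path_tables(slim, tables)
            rejected += run_model_fit(slim, std).p < 0.05
        assert rejected >= 10

    def test_df_always_twice_claim_count(self):
        for k in (1, 3, 10):
            res = fishers_c([0.3] * k)
            assert res.df == 2 * k
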