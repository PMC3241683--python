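"""Path enumeration and effect decomposition by the product rule."""

import numpy as np
import pandas as pd
import pytest

from gmlpath import (
    PathDAG,
    PathEdge,
    PathNode,
    enumerate_paths,
    fit_structural_equations,
    indirect_effect,
    total_effect,
)
from gmlpath.effects import PathCoefficients

from conftest import random_dag


def diamond():
    return PathDAG(
        [PathNode("X"), PathNode("A"), PathNode("B"), PathNode("Z")],
        [PathEdge("X", "A"), PathEdge("X", "B"),
         PathEdge("A", "Z"), PathEdge("B", "Z")],
    )


class TestEnumeratePaths:
    def test_diamond_has_two_length_two_paths(self):
        paths = enumerate_paths(diamond(), "X", "Z")
        assert paths == [["X", "A", "Z"], ["X", "B", "Z"]]

    def test_unreachable_gives_empty_list(self):
        paths = enumerate_paths(diamond(), "Z", "X")
        assert paths == []

    def test_count_matches_dfs_oracle_on_random_dags(self):
        rng = np.random.default_rng(11)

        def dfs_count(edges, src, dst, seen):
            if src == dst:
                return 1
            total = 0
            for a, b in edges:
                if a == src and b not in seen:
                    total += dfs_count(edges, b, dst, seen | {b})
            return total

        for _ in range(30):
            dag, nodes, edges = random_dag(rng, int(rng.integers(3, 7)))
            names = sorted(nodes)
            src, dst = names[0], names[-1]
            assert len(enumerate_paths(dag, src, dst)) == dfs_count(
                edges, src, dst, {src}
            )

    def test_categorical_control_nodes_are_excluded(self):
        dag = PathDAG(
            [PathNode("X"), PathNode("year", family="categorical-exogenous"),
             PathNode("Z")],
            [PathEdge("X", "Z"), PathEdge("year", "Z")],
        )
        # no path may route through the categorical node
        assert enumerate_paths(dag, "X", "Z") == [["X", "Z"]]


def published_coefficients():
    """The study's printed standardized coefficients as a lookup table."""
    return PathCoefficients.from_values(
        {
            ("timing", "nestling_mass"): -0.33,
            ("nestling_mass", "fat"): 0.24,
            ("fledglings", "tarsus_nest"): 0.25,
            ("tarsus_nest", "nestling_mass"): 0.67,
            ("fledglings", "nestling_mass"): -0.33,
        }
    )


class TestIndirectEffect:
    def test_product_rule_worked_example(self):
        comp = indirect_effect(
            ["timing", "nestling_mass", "fat"], published_coefficients()
        )
        assert round(comp.product, 2) == -0.08

    def test_zero_coefficient_annihilates_product(self):
        coeffs = PathCoefficients.from_values(
            {("a", "b"): 0.0, ("b", "c"): 0.9}
        )
        assert indirect_effect(["a", "b", "c"], coeffs).product == 0.0

    def test_quadratic_component_reported_separately(self, sparrow, std_tables):
        fitted = fit_structural_equations(sparrow, std_tables)
        comp = indirect_effect(["timing", "moult", "tbw"], fitted)
        # product uses only the linear moult coefficient; the squared part
        # is carried as a labelled note, never multiplied in
        lin = fitted.get("timing", "moult").linear.beta * fitted.get("moult", "tbw").linear.beta
        assert comp.product == pytest.approx(lin)
        assert comp.quadratic_note and "moult^2" in comp.quadratic_note

    def test_too_short_path_and_missing_edge_error(self):
        coeffs = published_coefficients()
        with pytest.raises(ValueError):
            indirect_effect(["timing", "nestling_mass"], coeffs)
        with pytest.raises(KeyError, match="fat.*tbw|tbw"):
            indirect_effect(["nestling_mass", "fat", "tbw"], coeffs)


class TestTotalEffect:
    def test_direct_plus_indirect_worked_example(self):
        dag = PathDAG(
            [PathNode("fledglings"), PathNode("tarsus_nest"),
             PathNode("nestling_mass")],
            [PathEdge("fledglings", "tarsus_nest"),
             PathEdge("tarsus_nest", "nestling_mass"),
             PathEdge("fledglings", "nestling_mass")],
        )
        deco = total_effect(
            "fledglings", "nestling_mass", dag, published_coefficients()
        )
        assert round(deco.total, 2) == -0.16
        assert deco.direct == -0.33
        assert len(deco.indirect_paths) == 1

    def test_single_direct_edge_total_equals_direct(self):
        dag = PathDAG(
            [PathNode("a"), PathNode("b")], [PathEdge("a", "b")]
        )
        coeffs = PathCoefficients.from_values({("a", "b"): 0.42})
        deco = total_effect("a", "b", dag, coeffs)
        assert deco.total == deco.direct == 0.42

    def test_additivity_and_multi_route_sum(self):
        dag = PathDAG(
            [PathNode("s"), PathNode("m1"), PathNode("m2"), PathNode("t")],
            [PathEdge("s", "m1"), PathEdge("m1", "m2"), PathEdge("m2", "t"),
             PathEdge("s", "m2"), PathEdge("s", "t")],
        )
        vals = {("s", "m1"): 0.5, ("m1", "m2"): 0.4, ("m2", "t"): 0.3,
                ("s", "m2"): -0.2, ("s", "t"): 0.1}
        coeffs = PathCoefficients.from_values(vals)
        deco = total_effect("s", "t", dag, coeffs)
        brute = (
            vals[("s", "t")]
            + vals[("s", "m1")] * vals[("m1", "m2")] * vals[("m2", "t")]
            + vals[("s", "m2")] * vals[("m2", "t")]
        )
        assert deco.total == pytest.approx(brute)
        assert deco.total == pytest.approx(
            deco.direct + sum(c.product for c in deco.indirect_paths)
        )

    def test_total_effect_approximates_marginal_regression_slope(self):
        # fully linear-gaussian DAG, no random effects: the total effect
        # equals the simple regression slope of target on source
        rng = np.random.default_rng(3)
        n = 10_000
        s = rng.normal(size=n)
        m = 0.5 * s + np.sqrt(1 - 0.25) * rng.normal(size=n)
        t = 0.4 * m + 0.3 * s + 0.6 * rng.normal(size=n)
        df = pd.DataFrame({"s": s, "m": m, "t": t})
        dag = PathDAG(
            [PathNode("s"), PathNode("m"), PathNode("t")],
            [PathEdge("s", "m"), PathEdge("m", "t"), PathEdge("s", "t")],
        )
        from gmlpath import standardize

        std, _ = standardize(df, ["s", "m", "t"])
        coeffs = fit_structural_equations(dag, std)
        deco = total_effect("s", "t", dag, coeffs)
        slope = np.polyfit(std["s"], std["t"], 1)[0]
        assert deco.total == pytest.approx(slope, abs=0.02)


class TestFitStructuralEquations:
    def test_noise_free_single_edge(self):
        rng = np.random.default_rng(5)
        x = rng.normal(size=50)
        df = pd.DataFrame({"x": x, "y": 0.5 * x})
        dag = PathDAG([PathNode("x"), PathNode("y")], [PathEdge("x", "y")])
        coeffs = fit_structural_equations(dag, df)
        assert coeffs.get("x", "y").linear.beta == pytest.approx(0.5, abs=1e-9)

    def test_source_nodes_have_no_equation(self, sparrow, std_tables):
        coeffs = fit_structural_equations(sparrow, std_tables)
        assert "timing" in coeffs.fits  # has parent year
        assert "date" not in coeffs.fits
        assert "year" not in coeffs.fits

    def test_every_edge_has_a_coefficient_after_fitting(self, sparrow, std_tables):
        coeffs = fit_structural_equations(sparrow, std_tables)
        for e in sparrow.edges:
            if e.form == "interaction":
                assert (f"{e.source}:{e.partner}", e.target) in coeffs
            else:
                assert (e.source, e.target) in coeffs

    def test_significant_only_drops_weak_paths(self):
        dag = PathDAG(
            [PathNode("a"), PathNode("b"), PathNode("c")],
            [PathEdge("a", "b"), PathEdge("b", "c")],
        )
        coeffs = PathCoefficients.from_values({("a", "b"): 0.5, ("b", "c"): 0.5})
        # mark b -> c as non-significant
        coeffs.get("b", "c").linear.p = 0.5
        coeffs.get("a", "b").linear.p = 0.001
        deco = total_effect("a", "c", dag, coeffs, significant_only=True)
        assert deco.total == 0.0
        deco_all = total_effect("a", "c", dag, coeffs, significant_only=False)
        assert deco_all.total == pytest.approx(0.25)
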