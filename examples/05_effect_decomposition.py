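"""Direct, indirect and total effects by the product rule.

Given fitted (or published) standardized path coefficients, the indirect
effect along a causal route is the product of its coefficients, and the
total effect of a source on a target is the direct coefficient plus the
sum over all indirect routes.
"""

from gmlpath import PathDAG, PathEdge, PathNode, indirect_effect, total_effect
from gmlpath.effects import PathCoefficients

# the study's printed standardized coefficients
coeffs = PathCoefficients.from_values(
    {
        ("timing", "nestling_mass"): -0.33,
        ("nestling_mass", "fat"): 0.24,
        ("fledglings", "tarsus_nest"): 0.25,
        ("tarsus_nest", "nestling_mass"): 0.67,
        ("fledglings", "nestling_mass"): -0.33,
    }
)

route = ["timing", "nestling_mass", "fat"]
comp = indirect_effect(route, coeffs)
print("indirect effect of timing of nesting on pre-migratory fat,")
print(f"  via nestling mass: -0.33 x 0.24 = {comp.product:.2f}")
print("  (later nests fledge lighter chicks, which carry less fat into autumn)\n")

dag = PathDAG(
    [PathNode("fledglings"), PathNode("tarsus_nest"), PathNode("nestling_mass")],
    [PathEdge("fledglings", "tarsus_nest"),
     PathEdge("tarsus_nest", "nestling_mass"),
     PathEdge("fledglings", "nestling_mass")],
)
deco = total_effect("fledglings", "nestling_mass", dag, coeffs)
r = deco.rounded()
print("total effect of brood size on nestling mass:")
print(f"  direct {r['direct']}  +  indirect via tarsus 0.25 x 0.67 = "
      f"{r['indirect'][0][1]}")
print(f"  total = {r['total']}")
print("  (bigger broods mean lighter chicks even though their tarsi run longer)")
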