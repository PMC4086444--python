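"""LP problem sizes and the payoff of redundancy pruning.

Prints variable/constraint counts at a metropolitan scale (11,740 areas)
with and without nearest-k sparsification, then shows on a synthetic city
how many risk constraints the g-function analysis removes outright.
"""

import geodeid as gd
from geodeid.model import lp_dimensions

print("metropolitan scale (11,740 areas):")
for label, k in (("full transitions", None), ("nearest 10", 10), ("nearest 30", 30)):
    n_vars, n_cons = lp_dimensions(11_740, k)
    print(f"  {label:>18}: {n_vars:>12,} variables, {n_cons:>12,} constraints")

city = gd.generate_city(gd.ottawa_like(n_areas=500, seed=1))
neighbors = gd.nearest_neighbors(city, k=30)
problem = gd.DeidProblem(city, neighbors, s=50, epsilon=0.5, variant="revised")
spec = gd.build_lp(problem, prune=True)
print(f"\nsynthetic city ({len(city)} areas, s=50, k=30, epsilon=0.5):")
print(f"  {spec.n_variables:,} variables; {spec.n_constraints_unpruned:,} constraints "
      f"before pruning, {spec.n_constraints:,} after")
print(f"  {len(spec.pruned_origins)} origins have population >= s/epsilon: their risk")
print("  rows have only non-negative coefficients and can be dropped unchanged.")
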