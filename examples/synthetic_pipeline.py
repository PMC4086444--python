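"""End-to-end de-identification of a synthetic city's patient list.

Generates an ottawa-like city (dense core, isolated rural villages,
median area population ~10), samples a patient cohort, solves the
revised LP at risk threshold 0.2 with nearest-30 transitions, audits the
solution, and relocates the patients.
"""

import numpy as np

import geodeid as gd

city = gd.generate_city(gd.ottawa_like(n_areas=400, seed=7))
patients = gd.sample_patients(city, s=120, seed=7)
print(f"city: {len(city)} areas, N={city.N} residents, "
      f"median area population {np.median(city.population):.0f}")
print(f"cohort: {patients.s} patients from {len(set(patients.area_ids))} areas")

neighbors = gd.nearest_neighbors(city, k=30)
problem = gd.DeidProblem(city, neighbors, patients.s, epsilon=0.2, variant="revised")
matrix = gd.solve(gd.build_lp(problem))
print(f"solve: {matrix.status}, expected displacement {matrix.objective_m:.1f} m")
# ^ the minimum average distance a patient's reported location moves while
#   keeping every re-identification probability at or below 0.2

report = gd.audit(matrix, problem)
print(f"audit: max re-identification risk {report.max_risk:.4f} "
      f"(threshold {report.epsilon}) -> {'PASS' if report.passed else 'FAIL'}")

relocated = gd.relocate(patients, matrix, seed=7)
moved = sum(a != b for a, b in zip(patients.area_ids, relocated.area_ids))
print(f"relocation: {moved}/{patients.s} patients reported in a new area")
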