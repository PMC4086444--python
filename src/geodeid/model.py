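"""Construction of the de-identification linear programs.

Two variants are supported.  Both minimize the expected patient
displacement  Σ_ij (n_i/N)·d_ij·P_ij  over row-stochastic transition
probabilities P_ij, subject to one re-identification risk constraint per
(i, j) pair:

    Σ_k (n_k/N)·P_kj  −  ν_i·P_ij  ≥  0

* ``wcmb`` uses  ν = s/(N·ϵ)  — the original worst-case bound, which
  becomes infeasible when many areas have population below the patient
  count s.
* ``revised`` uses  ν = min(s, n_i)/(N·ϵ)  — capping the per-area maximum
  re-identification probability s/n_i at 1, which keeps the bound exact
  while restoring feasibility for small areas.

Rewriting a risk row as  Σ_{k≠i}(n_k/N)P_kj + (n_i/N − ν_i)P_ij ≥ 0 shows
that whenever  g(n_i) = n_i/N − ν_i ≥ 0  every coefficient is
non-negative, so the row is implied by P ≥ 0 and can be pruned without
changing the model.  g crosses zero at n_i = s/ϵ.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import sparse

from .geodata import LocationTable, NeighborMap

VARIANTS = ("wcmb", "revised")

__all__ = [
    "VARIANTS",
    "DeidProblem",
    "LPSpec",
    "build_lp",
    "g_function",
    "is_redundant_risk_constraint",
    "lp_dimensions",
    "risk_coefficient",
]


def risk_coefficient(variant: str, s: float, N: float, epsilon: float, n_i: float) -> float:
    """Risk-constraint coefficient ν multiplying P_ij.

    ``wcmb``: s/(N·ϵ).  ``revised``: min(s, n_i)/(N·ϵ), which never
    exceeds the wcmb value, so every revised constraint is implied by the
    corresponding wcmb one.
    """
    if s <= 0 or N <= 0 or epsilon <= 0 or n_i <= 0:
        raise ValueError("s, N, epsilon, n_i must all be positive")
    if variant == "wcmb":
        return s / (N * epsilon)
    if variant == "revised":
        return min(s, n_i) / (N * epsilon)
    raise ValueError(f"unknown variant {variant!r}; expected one of {VARIANTS}")


def g_function(n_i: float, s: float, N: float, epsilon: float) -> float:
    """g(n_i) = n_i/N − ν  with the revised ν = min(s, n_i)/(N·ϵ).

    Piecewise: (n_i/N)(1 − 1/ϵ) for n_i ≤ s, (n_i − s/ϵ)/N for n_i > s;
    continuous at n_i = s, minimal there (value (s/N)(1 − 1/ϵ) when
    ϵ < 1), and crossing zero at n_i = s/ϵ.  Its sign decides constraint
    redundancy.
    """
    if n_i < 1:
        raise ValueError("n_i must be >= 1")
    if n_i <= s:
        return (n_i / N) * (1.0 - 1.0 / epsilon)
    return (n_i - s / epsilon) / N


def is_redundant_risk_constraint(n_i: float, s: float, epsilon: float) -> bool:
    """True iff the risk constraints of origin i can be dropped: n_i ≥ s/ϵ.

    Equivalent to g(n_i) ≥ 0.  The algebra is the same for both variants
    because the revised ν never exceeds the wcmb ν = s/(Nϵ): when the
    P_ij coefficient n_i/N − ν is non-negative, every coefficient in the
    row is, and the row follows from P ≥ 0.
    """
    if n_i <= 0 or s <= 0 or epsilon <= 0:
        raise ValueError("arguments must be positive")
    return n_i >= s / epsilon


def lp_dimensions(n_areas: int, k: int | None = None) -> tuple[int, int]:
    """(variables, constraints) of the unpruned LP for |A| areas, nearest-k.

    ``k=None`` means full transitions (k = |A|).  Variables number |A|·k;
    constraints |A|·(1 + k) — one row-sum equality per origin plus one risk
    inequality per variable, non-negativity counted as bounds.
    """
    if k is None:
        k = n_areas
    k = min(k, n_areas)
    return n_areas * k, n_areas * (1 + k)


@dataclass(frozen=True)
class DeidProblem:
    """A fully specified de-identification instance."""

    locations: LocationTable
    neighbors: NeighborMap
    s: int
    epsilon: float
    variant: str = "revised"

    def __post_init__(self) -> None:
        if self.variant not in VARIANTS:
            raise ValueError(f"variant must be one of {VARIANTS}")
        if self.s < 1:
            raise ValueError("s must be >= 1")
        if self.epsilon <= 0:
            raise ValueError("epsilon must be > 0")
        if len(self.neighbors) != len(self.locations):
            raise ValueError("neighbor map does not match location table")
        if self.epsilon > 1:
            warnings.warn(
                "epsilon > 1 is impractical: the re-identification "
                "probability bound exceeds certainty",
                stacklevel=2,
            )
        if self.variant == "revised" and self.epsilon < 1 and self.s > self.locations.N:
            warnings.warn("s exceeds the total population N", stacklevel=2)


@dataclass(frozen=True)
class LPSpec:
    """Sparse LP instance: variables are retained (origin, destination) pairs.

    ``A_eq x = 1`` enforces row-stochastic transition rows; ``A_risk x >= 0``
    holds the retained re-identification constraints (one per variable,
    minus pruned origins); ``x >= 0`` are bounds, not counted constraints.
    """

    area_ids: tuple[str, ...]
    var_origin: np.ndarray  # variable -> origin index
    var_dest: np.ndarray  # variable -> destination index
    c: np.ndarray  # objective (n_i/N)·d_ij, meters
    A_eq: sparse.csr_matrix
    A_risk: sparse.csr_matrix  # sense >=, rhs 0
    risk_var: np.ndarray  # risk row -> variable index it bounds
    pruned_origins: tuple[int, ...] = field(default=())

    @property
    def n_variables(self) -> int:
        return len(self.c)

    @property
    def n_constraints(self) -> int:
        """Retained constraints: row sums plus kept risk rows."""
        return self.A_eq.shape[0] + self.A_risk.shape[0]

    @property
    def n_constraints_unpruned(self) -> int:
        """|A| + Σ_i |B_i|: the count before redundancy pruning."""
        return self.A_eq.shape[0] + self.n_variables

    @property
    def n_pruned(self) -> int:
        return self.n_constraints_unpruned - self.n_constraints

    def export(self, directory) -> None:
        """Debug export: triplets ``row,col,coef`` and rows ``row,sense,rhs``.

        Equality rows come first, then risk rows, matching the row ids in
        the triplet file.
        """
        import pathlib

        directory = pathlib.Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        A = sparse.vstack([self.A_eq, self.A_risk]).tocoo()
        pd.DataFrame({"row": A.row, "col": A.col, "coef": A.data}).to_csv(
            directory / "lp_triplets.csv", index=False
        )
        n_eq = self.A_eq.shape[0]
        rows = pd.DataFrame(
            {
                "row": np.arange(self.n_constraints),
                "sense": ["=="] * n_eq + [">="] * self.A_risk.shape[0],
                "rhs": [1.0] * n_eq + [0.0] * self.A_risk.shape[0],
            }
        )
        rows.to_csv(directory / "lp_rows.csv", index=False)


def build_lp(problem: DeidProblem, prune: bool = True) -> LPSpec:
    """Assemble the sparse LP for a de-identification instance.

    The column sum in each risk row runs only over origins k whose
    neighbor set contains the destination j — other P_kj do not exist as
    variables under nearest-k sparsification.  With ``prune`` (default),
    risk rows of origins with n_i ≥ s/ϵ are omitted as redundant; pruned
    and unpruned instances have identical feasible regions.
    """
    loc = problem.locations
    nb = problem.neighbors
    if nb.n_pairs == 0:
        raise ValueError("neighbor map is empty")
    n_areas = len(loc)
    N = loc.N
    pop = loc.population

    # Variable index: origins in table order, destinations in B_i order.
    sizes = np.array([len(d) for d in nb.dest_idx])
    var_origin = np.repeat(np.arange(n_areas), sizes)
    var_dest = np.concatenate(nb.dest_idx)
    dist = np.concatenate(nb.dist_m)
    nv = len(var_origin)
    c = (pop[var_origin] / N) * dist

    A_eq = sparse.csr_matrix(
        (np.ones(nv), (var_origin, np.arange(nv))), shape=(n_areas, nv)
    )

    nu = np.array(
        [
            risk_coefficient(problem.variant, problem.s, N, problem.epsilon, int(n))
            for n in pop
        ]
    )
    redundant = np.array(
        [is_redundant_risk_constraint(int(n), problem.s, problem.epsilon) for n in pop]
    )

    # Variables grouped by destination column j: the incoming-mass term
    # Σ_k (n_k/N)·P_kj is shared by every risk row with that j.
    col_vars: list[list[int]] = [[] for _ in range(n_areas)]
    for v in range(nv):
        col_vars[var_dest[v]].append(v)

    keep = ~redundant if prune else np.ones(n_areas, dtype=bool)
    rows_i: list[int] = []
    rows_j: list[int] = []
    rows_v: list[float] = []
    risk_var: list[int] = []
    r = 0
    mass_coef = pop[var_origin] / N  # coefficient n_k/N of each variable
    for v in range(nv):
        i = var_origin[v]
        if not keep[i]:
            continue
        j = var_dest[v]
        for w in col_vars[j]:
            rows_i.append(r)
            rows_j.append(w)
            rows_v.append(mass_coef[w] - nu[i] if w == v else mass_coef[w])
        risk_var.append(v)
        r += 1
    A_risk = sparse.csr_matrix((rows_v, (rows_i, rows_j)), shape=(r, nv))

    return LPSpec(
        area_ids=loc.area_ids,
        var_origin=var_origin,
        var_dest=var_dest,
        c=c,
        A_eq=A_eq,
        A_risk=A_risk,
        risk_var=np.array(risk_var, dtype=np.int64),
        pruned_origins=tuple(int(i) for i in np.nonzero(~keep)[0]),
    )
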