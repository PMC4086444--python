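"""Independent verification of the re-identification bound.

The audited quantity for a pair (i, j) is

    r_ij = min(s/n_i, 1) · (n_i·P_ij) / (Σ_k n_k·P_kj)

— the probability that a record reported in area j traces back to a
specific individual of area i, with the per-area maximum s/n_i capped at
1 (the number of patients from an area cannot exceed its population).
The audit recomputes this from first principles rather than trusting LP
feasibility, so it catches solver-tolerance violations and pruning bugs.

Destinations receiving no transition mass are skipped, not scored zero:
a 0/0 ratio has no risk interpretation, and an area no one maps to poses
no risk.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .geodata import LocationTable
from .model import DeidProblem
from .solve import ROW_SUM_TOL, TransitionMatrix

RISK_TOL = 1e-6

__all__ = ["RISK_TOL", "AuditReport", "audit", "reidentification_probability"]


@dataclass(frozen=True)
class AuditReport:
    """Per-pair re-identification probabilities and the verdict vs ϵ."""

    origin_idx: np.ndarray
    dest_idx: np.ndarray
    risk: np.ndarray
    max_risk: float
    epsilon: float
    passed: bool
    zero_mass_dests: tuple[int, ...] = field(default=())
    area_ids: tuple[str, ...] = field(default=())

    def to_frame(self) -> pd.DataFrame:
        ids = np.array(self.area_ids)
        return pd.DataFrame(
            {
                "origin_id": ids[self.origin_idx],
                "dest_id": ids[self.dest_idx],
                "risk": self.risk,
            }
        )

    def summary(self) -> dict:
        return {
            "max_risk": self.max_risk,
            "epsilon": self.epsilon,
            "pass": self.passed,
            "n_zero_mass_dests": len(self.zero_mass_dests),
        }


def _column_mass(P: TransitionMatrix, population: np.ndarray) -> np.ndarray:
    mass = np.zeros(P.n_areas)
    np.add.at(mass, P.dest_idx, population[P.origin_idx] * P.prob)
    return mass


def reidentification_probability(
    P: TransitionMatrix, locations: LocationTable, s: int, i: str, j: str
) -> float:
    """Risk that a record reported in area j came from a given person of area i.

    Raises on a destination with zero incoming population mass, where the
    ratio is undefined.
    """
    pop = locations.population.astype(float)
    ii = locations.index_of(i)
    jj = locations.index_of(j)
    mass = _column_mass(P, pop)
    if mass[jj] <= 0:
        raise ValueError(f"destination {j!r} receives no transition mass")
    mask = (P.origin_idx == ii) & (P.dest_idx == jj)
    p_ij = float(P.prob[mask].sum())
    return min(s / pop[ii], 1.0) * pop[ii] * p_ij / mass[jj]


def audit(P: TransitionMatrix, problem: DeidProblem) -> AuditReport:
    """Score every stored (i, j) pair with positive column mass against ϵ.

    Requires a row-stochastic P over the problem's areas; passes iff
    max risk ≤ ϵ + 1e−6.
    """
    loc = problem.locations
    if P.area_ids != loc.area_ids:
        raise ValueError("transition matrix areas do not match the problem")
    sums = P.row_sums()
    if np.any(np.abs(sums - 1.0) > ROW_SUM_TOL):
        raise ValueError("transition matrix is not row-stochastic")
    pop = loc.population.astype(float)
    mass = _column_mass(P, pop)
    zero_dests = tuple(int(j) for j in np.nonzero(mass <= 0)[0])

    keep = mass[P.dest_idx] > 0
    oi = P.origin_idx[keep]
    dj = P.dest_idx[keep]
    cap = np.minimum(problem.s / pop[oi], 1.0)
    risk = cap * pop[oi] * P.prob[keep] / mass[dj]
    max_risk = float(risk.max()) if len(risk) else 0.0
    return AuditReport(
        origin_idx=oi,
        dest_idx=dj,
        risk=risk,
        max_risk=max_risk,
        epsilon=problem.epsilon,
        passed=max_risk <= problem.epsilon + RISK_TOL,
        zero_mass_dests=zero_dests,
        area_ids=loc.area_ids,
    )
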