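"""Solver contract: minimize an LPSpec and return a transition matrix.

The backend is scipy's HiGHS interface.  ``highs-ds`` (dual simplex) and
``highs-ipm`` (interior point) are deterministic single-threaded paths,
so repeated runs agree on the objective; degenerate optima may still
differ in P between backends — only the objective value is
contract-bound.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import sparse
from scipy.optimize import linprog

from .model import LPSpec

BACKENDS = ("highs", "highs-ds", "highs-ipm")
ROW_SUM_TOL = 1e-6

__all__ = ["BACKENDS", "ROW_SUM_TOL", "TransitionMatrix", "solve"]


@dataclass(frozen=True)
class TransitionMatrix:
    """Sparse solved transition probabilities P_ij with solve metadata.

    ``status`` is one of optimal / infeasible / unbounded /
    numeric_failure; entries and the objective are only present when
    optimal.  ``objective_m`` is the expected patient displacement
    Σ (n_i/N)·d_ij·P_ij in meters.
    """

    area_ids: tuple[str, ...]
    origin_idx: np.ndarray
    dest_idx: np.ndarray
    prob: np.ndarray
    status: str
    objective_m: float = float("nan")
    meta: dict = field(default_factory=dict)

    @property
    def n_areas(self) -> int:
        return len(self.area_ids)

    def row(self, origin_id: str) -> tuple[np.ndarray, np.ndarray]:
        """(destination indices, probabilities) of one origin, stored order."""
        i = self.area_ids.index(origin_id)
        mask = self.origin_idx == i
        return self.dest_idx[mask], self.prob[mask]

    def row_sums(self) -> np.ndarray:
        out = np.zeros(self.n_areas)
        np.add.at(out, self.origin_idx, self.prob)
        return out

    def to_sparse(self) -> sparse.csr_matrix:
        n = self.n_areas
        return sparse.csr_matrix(
            (self.prob, (self.origin_idx, self.dest_idx)), shape=(n, n)
        )

    def to_frame(self) -> pd.DataFrame:
        ids = np.array(self.area_ids)
        return pd.DataFrame(
            {
                "origin_id": ids[self.origin_idx],
                "dest_id": ids[self.dest_idx],
                "probability": self.prob,
            }
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def identity(cls, area_ids) -> "TransitionMatrix":
        n = len(area_ids)
        idx = np.arange(n)
        return cls(
            area_ids=tuple(area_ids),
            origin_idx=idx,
            dest_idx=idx.copy(),
            prob=np.ones(n),
            status="optimal",
            objective_m=0.0,
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame, area_ids) -> "TransitionMatrix":
        area_ids = tuple(area_ids)
        index = {a: i for i, a in enumerate(area_ids)}
        return cls(
            area_ids=area_ids,
            origin_idx=df["origin_id"].map(index).to_numpy(np.int64),
            dest_idx=df["dest_id"].map(index).to_numpy(np.int64),
            prob=df["probability"].to_numpy(float),
            status="optimal",
        )

    @classmethod
    def from_csv(cls, path, area_ids) -> "TransitionMatrix":
        return cls.from_frame(pd.read_csv(path, dtype={"origin_id": str, "dest_id": str}), area_ids)


_STATUS = {0: "optimal", 1: "numeric_failure", 2: "infeasible", 3: "unbounded", 4: "numeric_failure"}


def solve(spec: LPSpec, *, tolerance: float = 1e-6, backend: str = "highs-ds") -> TransitionMatrix:
    """Minimize the expected displacement subject to the LPSpec constraints.

    Infeasibility is a legitimate outcome (status ``infeasible``, no
    matrix entries), not an exception.  On an optimal solve the objective
    is recomputed independently as c·x; tiny negative entries (within
    ``tolerance``) are clipped to zero and rows renormalized.
    """
    if backend not in BACKENDS:
        raise ValueError(f"unknown backend {backend!r}; choose from {BACKENDS}")

    def _run(method):
        return linprog(
            spec.c,
            A_ub=(-spec.A_risk).tocsc() if spec.A_risk.shape[0] else None,
            b_ub=np.zeros(spec.A_risk.shape[0]) if spec.A_risk.shape[0] else None,
            A_eq=spec.A_eq.tocsc(),
            b_eq=np.ones(spec.A_eq.shape[0]),
            bounds=(0, None),
            method=method,
        )

    res = _run(backend)
    status = _STATUS.get(res.status, "numeric_failure")
    if status == "numeric_failure":
        # Simplex and interior point have complementary failure modes
        # (e.g., dual simplex stalling on an infeasible instance that
        # interior point certifies immediately); retry once.
        fallback = "highs-ipm" if backend != "highs-ipm" else "highs-ds"
        res = _run(fallback)
        status = _STATUS.get(res.status, "numeric_failure")
        backend = f"{backend}->{fallback}"
    if status != "optimal":
        return TransitionMatrix(
            area_ids=spec.area_ids,
            origin_idx=np.empty(0, np.int64),
            dest_idx=np.empty(0, np.int64),
            prob=np.empty(0),
            status=status,
            meta={"backend": backend, "message": res.message},
        )
    x = np.asarray(res.x)
    if np.any(x < -tolerance):
        raise RuntimeError("solver returned entries below -tolerance")
    # Clip tiny negatives and drop numerical-noise positives: the audited
    # risk ratio is scale-invariant within a column, so even a 1e-13 stray
    # entry into an otherwise unused destination would masquerade as a
    # high-risk pair.
    x = np.clip(x, 0.0, None)
    x[x < 1e-9] = 0.0
    # Renormalize each row to sum exactly 1 (solver feasibility slack).
    sums = np.zeros(spec.A_eq.shape[0])
    np.add.at(sums, spec.var_origin, x)
    x = x / sums[spec.var_origin]
    objective = float(spec.c @ x)
    return TransitionMatrix(
        area_ids=spec.area_ids,
        origin_idx=spec.var_origin,
        dest_idx=spec.var_dest,
        prob=x,
        status="optimal",
        objective_m=objective,
        meta={"backend": backend, "solver_objective": float(res.fun)},
    )
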