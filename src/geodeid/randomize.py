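"""Multinomial relocation of patients through a solved transition matrix.

For each origin area i holding s_i patients, destination counts are drawn
from Multinomial(s_i, {P_ij}) and the drawn counts are assigned to
individual patients by a uniform shuffle — patients within an origin are
exchangeable, no attribute drives the assignment.  A single root seed
spawns an independent substream per origin keyed by area_id, so adding or
removing one origin does not perturb the draws of the others.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .geodata import LocationTable
from .solve import TransitionMatrix

__all__ = ["PatientList", "load_patients", "relocate"]


@dataclass(frozen=True)
class PatientList:
    """Patient records: opaque id plus origin area id."""

    patient_ids: tuple[str, ...]
    area_ids: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.patient_ids) != len(self.area_ids):
            raise ValueError("patient_ids and area_ids differ in length")

    def __len__(self) -> int:
        return len(self.patient_ids)

    @property
    def s(self) -> int:
        """Total patient count."""
        return len(self)

    def counts(self) -> dict[str, int]:
        """Per-origin patient counts s_i."""
        out: dict[str, int] = {}
        for a in self.area_ids:
            out[a] = out.get(a, 0) + 1
        return out

    def validate_against(self, locations: LocationTable) -> None:
        known = set(locations.area_ids)
        unknown = sorted({a for a in self.area_ids if a not in known})
        if unknown:
            raise ValueError(f"patient origins not in location table: {unknown[:5]}")

    def to_frame(self, column: str = "area_id") -> pd.DataFrame:
        return pd.DataFrame({"patient_id": self.patient_ids, column: self.area_ids})

    def to_csv(self, path, column: str = "area_id") -> None:
        self.to_frame(column).to_csv(path, index=False)


def load_patients(path, *, sep: str = ",") -> PatientList:
    """Read a patient CSV with header ``patient_id,area_id``."""
    df = pd.read_csv(path, sep=sep, dtype=str)
    if "patient_id" not in df.columns or "area_id" not in df.columns:
        raise ValueError("patient file needs columns patient_id, area_id")
    return PatientList(tuple(df["patient_id"]), tuple(df["area_id"]))


def _origin_rng(root_seed: int, area_id: str) -> np.random.Generator:
    # Stable substream per origin: root seed combined with a hash of the
    # area id, independent of table order.
    digest = hashlib.sha256(area_id.encode()).digest()
    key = int.from_bytes(digest[:8], "big")
    return np.random.default_rng(np.random.SeedSequence([root_seed & 0x7FFFFFFF, key]))


def relocate(patients: PatientList, P: TransitionMatrix, seed: int) -> PatientList:
    """Draw randomized areas for every patient; reproducible for a fixed seed.

    Patient ids are preserved and the output has exactly the input size.
    Raises if a patient origin has no row in P.
    """
    if P.status != "optimal" and len(P.prob) == 0:
        raise ValueError("transition matrix carries no probabilities")
    index = {a: i for i, a in enumerate(P.area_ids)}
    id_arr = np.array(P.area_ids)

    # Group patient positions by origin, preserving input order.
    by_origin: dict[str, list[int]] = {}
    for pos, a in enumerate(patients.area_ids):
        by_origin.setdefault(a, []).append(pos)

    new_area = [""] * len(patients)
    for origin, positions in by_origin.items():
        if origin not in index:
            raise ValueError(f"origin {origin!r} has no row in the transition matrix")
        mask = P.origin_idx == index[origin]
        dests = P.dest_idx[mask]
        probs = P.prob[mask]
        if len(probs) == 0 or abs(probs.sum() - 1.0) > 1e-6:
            raise ValueError(f"origin {origin!r} row is not a probability vector")
        rng = _origin_rng(seed, origin)
        counts = rng.multinomial(len(positions), probs / probs.sum())
        order = rng.permutation(len(positions))
        shuffled = [positions[o] for o in order]
        # Fill destinations in the stored row order of P.
        cursor = 0
        for dest, cnt in zip(dests, counts):
            for pos in shuffled[cursor : cursor + cnt]:
                new_area[pos] = id_arr[dest]
            cursor += cnt
    return PatientList(patients.patient_ids, tuple(new_area))
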