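"""Similarity and connectivity diagnostics for assigned steps.

The similarity profile compares a step against every reference class in two
metrics at once: the scaled periodicity-aware parameter-space distance to the
class means and the Cartesian r.m.s.d. of the 18 step atoms to the class
representative.  The connectivity analysis superposes the assigned-class
representative of each of two overlapping steps onto its own experimental
atoms and measures how far apart the two superposed references place the
shared residue's C5' and O3' atoms — small values mean mutually compatible
assignments.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .classify import Assignment, DistanceProfile, _distance_matrix
from .geometry import StepParameters, superpose_rmsd
from .reference import ReferenceSet
from .structure_io import ATOM_ROLES, DinucleotideStep

__all__ = [
    "similarity_profile",
    "rmsd_band",
    "connectivity",
    "OverlapDistances",
    "ConnectivityReport",
    "suggest_alternatives",
    "RMSD_GREEN_MAX",
    "RMSD_YELLOW_MAX",
]

#: Cartesian r.m.s.d. color bands (A): green below, red above, yellow between
RMSD_GREEN_MAX = 0.5
RMSD_YELLOW_MAX = 1.0

_ROLE_INDEX = {role: i for i, role in enumerate(ATOM_ROLES)}


def rmsd_band(rmsd: float) -> str:
    if rmsd < RMSD_GREEN_MAX:
        return "green"
    if rmsd <= RMSD_YELLOW_MAX:
        return "yellow"
    return "red"


def similarity_profile(step: DinucleotideStep, params: StepParameters,
                       refset: ReferenceSet, scaling=None) -> DistanceProfile:
    """Parameter-space and Cartesian distance of one step to every class."""
    if scaling is None:
        scaling = refset.pooled_esd()
    p = params.as_array() if isinstance(params, StepParameters) else np.asarray(params, float)
    euclid = _distance_matrix(p[None, :], refset.means_matrix(), np.asarray(scaling, float))[0]
    coords = step.coords()
    profile = DistanceProfile()
    for cls, d in zip(refset, euclid):
        profile.euclid[cls.ntc] = float(d)
        if cls.representative is not None:
            profile.rmsd[cls.ntc] = superpose_rmsd(coords, cls.representative).rmsd
    return profile


@dataclass(frozen=True)
class OverlapDistances:
    """Distances between the shared residue's atoms of two superposed references."""

    c5: float
    o3: float


@dataclass
class ConnectivityReport:
    """Per-step connectivity: overlap with the previous and the next step.

    Entries are None at chain termini or next to unassigned steps.
    """

    prev_C5: float | None = None
    prev_O3: float | None = None
    next_C5: float | None = None
    next_O3: float | None = None


def _superposed_reference(step: DinucleotideStep, ntc: str, refset: ReferenceSet) -> np.ndarray:
    rep = refset.get(ntc).representative
    if rep is None:
        raise ValueError(f"class {ntc} has no representative coordinates")
    return superpose_rmsd(step.coords(), rep).transform(rep)


def connectivity(step_i: DinucleotideStep, ntc_i: str,
                 step_j: DinucleotideStep, ntc_j: str,
                 refset: ReferenceSet) -> OverlapDistances:
    """Overlap distances between two consecutive assigned steps.

    ``step_j`` must start with the residue that ends ``step_i``.  Each step's
    assigned-class representative is superposed onto that step's own 18
    experimental atoms; the report gives the distances between the two
    superposed references' copies of the shared residue's C5' and O3' atoms.
    """
    if (step_i.second.chain_id, step_i.second.res_seq, step_i.second.ins_code) != \
       (step_j.first.chain_id, step_j.first.res_seq, step_j.first.ins_code):
        raise ValueError("steps do not share a residue; connectivity undefined")
    ref_i = _superposed_reference(step_i, ntc_i, refset)
    ref_j = _superposed_reference(step_j, ntc_j, refset)
    c5 = np.linalg.norm(ref_i[_ROLE_INDEX[(2, "C5'")]] - ref_j[_ROLE_INDEX[(1, "C5'")]])
    o3 = np.linalg.norm(ref_i[_ROLE_INDEX[(2, "O3'")]] - ref_j[_ROLE_INDEX[(1, "O3'")]])
    return OverlapDistances(c5=float(c5), o3=float(o3))


def suggest_alternatives(assignment: Assignment, profile: DistanceProfile,
                         refset: ReferenceSet,
                         step: DinucleotideStep | None = None,
                         neighbors: list | None = None,
                         margin: float = 0.2,
                         max_alternatives: int = 5) -> list[str]:
    """Alternative NtC classes structurally close to the assigned one.

    Candidates are the classes whose Cartesian r.m.s.d. lies within
    ``margin`` angstroms of the assigned class's r.m.s.d.  When connectivity
    context is available (``step`` plus ``neighbors`` — a list of
    ``(neighbor_step, neighbor_ntc, position)`` with position ``"prev"`` or
    ``"next"``), candidates are re-ranked by the total overlap distance they
    would produce; otherwise by r.m.s.d.
    """
    if not assignment.assigned or assignment.ntc not in profile.rmsd:
        return []
    base = profile.rmsd[assignment.ntc]
    candidates = [code for code, r in profile.rmsd.items()
                  if code != assignment.ntc and r <= base + margin]

    def connectivity_cost(code: str) -> float:
        total = 0.0
        for nstep, nntc, position in neighbors or []:
            if position == "prev":
                ov = connectivity(nstep, nntc, step, code, refset)
            else:
                ov = connectivity(step, code, nstep, nntc, refset)
            total += ov.c5 + ov.o3
        return total

    if step is not None and neighbors:
        key = lambda code: (connectivity_cost(code), profile.rmsd[code], code)
    else:
        key = lambda code: (profile.rmsd[code], code)
    return sorted(candidates, key=key)[:max_alternatives]
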