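"""Geometric protein–ligand interaction profiling with occupancies.

Hydrogen bonds and hydrophobic contacts are detected per frame with
PLIP-style geometric criteria: a hydrogen bond is a flagged donor /
acceptor heavy-atom pair within a maximum donor–acceptor distance whose
D–H···A angle (when hydrogens are present) is at least a minimum; a
hydrophobic contact is a pair of flagged apolar carbons within a maximum
distance, collapsed to the closest atom pair per environment residue and
frame.  Occupancy of a contact is the fraction of frames in which it is
present; its reported distance is the average over those frames.

Donor / acceptor / hydrophobic roles come from the parameter sidecar, not
from on-the-fly chemical perception, which keeps detection exact on
synthetic systems and configurable on real ones.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist

from .topology import Topology, Trajectory

__all__ = [
    "InteractionCriteria",
    "InteractionEvent",
    "OccupancyReport",
    "detect_hbonds",
    "detect_hydrophobic",
    "interaction_occupancy",
    "occupancy_table",
    "format_binding_summary",
]

#: maximum covalent X–H bond length used to find a donor's hydrogens (Å)
HYDROGEN_BOND_LENGTH_MAX = 1.3


@dataclass(frozen=True)
class InteractionCriteria:
    """Geometric thresholds for contact detection (PLIP defaults)."""

    hbond_da_max: float = 4.1
    hbond_donor_angle_min: float = 100.0
    hydrophobic_max: float = 4.0
    heavy_atom_only: bool = False

    def __post_init__(self) -> None:
        if self.hbond_da_max <= 0 or self.hydrophobic_max <= 0:
            raise ValueError("distance criteria must be positive")
        if not 0 < self.hbond_donor_angle_min <= 180:
            raise ValueError("donor angle must be in (0, 180] degrees")


@dataclass(frozen=True)
class InteractionEvent:
    """One detected contact in one frame."""

    kind: str
    ligand_atom: int
    environment_atom: int
    residue: str
    distance: float
    frame_index: int
    angle: float | None = None


def _angle_deg(a: np.ndarray, b: np.ndarray, c: np.ndarray) -> float:
    """Angle at vertex b of the triangle a-b-c, in degrees."""
    u, v = a - b, c - b
    cosine = np.dot(u, v) / (np.linalg.norm(u) * np.linalg.norm(v))
    return float(np.degrees(np.arccos(np.clip(cosine, -1.0, 1.0))))


def _donor_hydrogens(frame: np.ndarray, topology: Topology,
                     donor: int) -> np.ndarray:
    """Indices of hydrogens covalently attached to a donor heavy atom.

    Attachment is inferred geometrically: hydrogens of the same residue
    within the covalent bond-length limit.
    """
    same_res = (
        (topology.res_id == topology.res_id[donor])
        & (topology.chain_id == topology.chain_id[donor])
        & (topology.element == "H")
    )
    candidates = np.flatnonzero(same_res)
    if candidates.size == 0:
        return candidates
    d = np.linalg.norm(frame[candidates] - frame[donor], axis=1)
    return candidates[d <= HYDROGEN_BOND_LENGTH_MAX]


def detect_hbonds(
    frame: np.ndarray,
    topology: Topology,
    criteria: InteractionCriteria | None = None,
    frame_index: int = 0,
) -> list[InteractionEvent]:
    """Hydrogen bonds between ligand and environment in one frame.

    Both directions are scanned (ligand donor → environment acceptor and
    environment donor → ligand acceptor).  The donor-angle test applies
    only when the donor has resolvable hydrogens and ``heavy_atom_only``
    is off; the event's distance is the donor–acceptor heavy-atom
    distance.
    """
    criteria = criteria or InteractionCriteria()
    donors = topology.flag("donor")
    acceptors = topology.flag("acceptor")
    if not donors.any() and not acceptors.any():
        warnings.warn("no donor/acceptor flags assigned; no hydrogen bonds")
        return []
    ligand = topology.ligand_mask()
    events: list[InteractionEvent] = []
    for donor_side, acceptor_side in ((ligand, ~ligand), (~ligand, ligand)):
        d_idx = np.flatnonzero(donors & donor_side)
        a_idx = np.flatnonzero(acceptors & acceptor_side)
        if d_idx.size == 0 or a_idx.size == 0:
            continue
        dist = cdist(frame[d_idx], frame[a_idx])
        for i, j in np.argwhere(dist <= criteria.hbond_da_max):
            donor, acceptor = int(d_idx[i]), int(a_idx[j])
            if donor == acceptor:
                continue
            angle = None
            if not criteria.heavy_atom_only:
                hydrogens = _donor_hydrogens(frame, topology, donor)
                if hydrogens.size:
                    angle = max(
                        _angle_deg(frame[donor], frame[h], frame[acceptor])
                        for h in hydrogens
                    )
                    if angle < criteria.hbond_donor_angle_min:
                        continue
            lig_atom, env_atom = (
                (donor, acceptor) if ligand[donor] else (acceptor, donor)
            )
            events.append(
                InteractionEvent(
                    kind="hbond",
                    ligand_atom=lig_atom,
                    environment_atom=env_atom,
                    residue=topology.residue_label(env_atom),
                    distance=float(dist[i, j]),
                    angle=angle,
                    frame_index=frame_index,
                )
            )
    return events


def detect_hydrophobic(
    frame: np.ndarray,
    topology: Topology,
    criteria: InteractionCriteria | None = None,
    frame_index: int = 0,
) -> list[InteractionEvent]:
    """Hydrophobic contacts between ligand and environment in one frame.

    All flagged-carbon pairs within the distance criterion are found, then
    collapsed to the single closest pair per environment residue.
    """
    criteria = criteria or InteractionCriteria()
    hydrophobic = topology.flag("hydrophobic")
    ligand = topology.ligand_mask()
    l_idx = np.flatnonzero(hydrophobic & ligand)
    e_idx = np.flatnonzero(hydrophobic & ~ligand)
    if l_idx.size == 0 or e_idx.size == 0:
        return []
    dist = cdist(frame[l_idx], frame[e_idx])
    best: dict[str, tuple[float, int, int]] = {}
    for i, j in np.argwhere(dist <= criteria.hydrophobic_max):
        env_atom = int(e_idx[j])
        residue = topology.residue_label(env_atom)
        d = float(dist[i, j])
        if residue not in best or d < best[residue][0]:
            best[residue] = (d, int(l_idx[i]), env_atom)
    return [
        InteractionEvent(
            kind="hydrophobic",
            ligand_atom=lig_atom,
            environment_atom=env_atom,
            residue=residue,
            distance=d,
            frame_index=frame_index,
        )
        for residue, (d, lig_atom, env_atom) in sorted(best.items())
    ]


@dataclass(frozen=True)
class OccupancyReport:
    """Presence statistics of one contact over a trajectory."""

    kind: str
    ligand_atom: int
    ligand_atom_name: str
    residue: str
    occupancy: float
    mean_distance: float
    n_present: int
    n_frames: int


def _contact_key(event: InteractionEvent) -> tuple:
    return (event.kind, event.ligand_atom, event.residue)


def interaction_occupancy(
    trajectory: Trajectory,
    topology: Topology,
    criteria: InteractionCriteria | None = None,
) -> list[OccupancyReport]:
    """Occupancy and mean distance of every contact over a trajectory.

    A contact is keyed by (kind, ligand atom, environment residue).  When
    several atom pairs realize the same contact in one frame, the closest
    one represents it.  Reports are sorted by descending occupancy, then
    by key for determinism.
    """
    trajectory.check_compatible(topology)
    criteria = criteria or InteractionCriteria()
    present: dict[tuple, list[float]] = {}
    for f in range(trajectory.n_frames):
        frame = trajectory.frame(f)
        events = detect_hbonds(frame, topology, criteria, frame_index=f)
        events += detect_hydrophobic(frame, topology, criteria, frame_index=f)
        per_frame: dict[tuple, float] = {}
        for ev in events:
            key = _contact_key(ev)
            if key not in per_frame or ev.distance < per_frame[key]:
                per_frame[key] = ev.distance
        for key, d in per_frame.items():
            present.setdefault(key, []).append(d)
    n_frames = trajectory.n_frames
    reports = [
        OccupancyReport(
            kind=kind,
            ligand_atom=lig_atom,
            ligand_atom_name=str(topology.atom_name[lig_atom]),
            residue=residue,
            occupancy=len(distances) / n_frames,
            mean_distance=float(np.mean(distances)),
            n_present=len(distances),
            n_frames=n_frames,
        )
        for (kind, lig_atom, residue), distances in present.items()
    ]
    reports.sort(key=lambda r: (-r.occupancy, r.kind, r.residue, r.ligand_atom))
    return reports


def occupancy_table(reports: list[OccupancyReport]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "kind": r.kind,
                "ligand_atom": r.ligand_atom,
                "ligand_atom_name": r.ligand_atom_name,
                "residue": r.residue,
                "occupancy": r.occupancy,
                "mean_distance": r.mean_distance,
                "n_present": r.n_present,
                "n_frames": r.n_frames,
            }
            for r in reports
        ]
    )


def format_binding_summary(reports: list[OccupancyReport]) -> str:
    """Human-readable per-residue summary: ``residue (d Å, occ%)`` lines."""
    lines = []
    for kind in ("hbond", "hydrophobic"):
        subset = [r for r in reports if r.kind == kind]
        if not subset:
            continue
        label = "Hydrogen bonds" if kind == "hbond" else "Hydrophobic contacts"
        entries = ", ".join(
            f"{r.residue} ({r.mean_distance:.2f} Å, {100 * r.occupancy:.0f}%)"
            for r in subset
        )
        lines.append(f"{label}: {entries}")
    return "\n".join(lines)
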