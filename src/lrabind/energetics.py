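"""Ligand–environment nonbonded interaction energies.

The endpoint estimator consumes ensemble averages of the intermolecular
van der Waals and electrostatic energies between the ligand and its
surroundings (solvent for the free state W, the solvated binding site for
the bound state P).  Energies are plain pairwise sums — point-charge
Coulomb and 12-6 Lennard-Jones with AMBER-convention mixing (arithmetic
Rmin, geometric ε) — evaluated without a cutoff by default, so that the
computed terms are exactly the pairwise quantities the estimator is
defined over.  A cutoff flag exists for experimentation only.

The ``charge_state`` tag of a series records how the underlying ensemble
was *sampled* (with real ligand charges, ``q``, or with them switched
off, ``zero``).  Evaluation always uses the real charges: the
preorganization average ⟨V_ele⟩₀ is the real-charge electrostatic energy
over zero-charge-sampled configurations.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist

from .topology import Topology, Trajectory

__all__ = [
    "COULOMB_CONSTANT",
    "pair_coulomb",
    "pair_lj",
    "group_interaction_energy",
    "ensemble_energy_series",
    "EnergySeries",
    "StateEnergySummary",
]

#: Coulomb constant in kcal·Å/(mol·e²)
COULOMB_CONSTANT = 332.0636

#: pair distance below which atoms are reported as overlapping (Å)
OVERLAP_DISTANCE = 0.1


def pair_coulomb(q_i: float, q_j: float, r_ij: float,
                 coulomb_constant: float = COULOMB_CONSTANT) -> float:
    """Point-charge Coulomb energy in kcal/mol (charges in e, r in Å)."""
    if r_ij <= 0:
        raise ValueError(f"pair distance must be positive, got {r_ij}")
    return coulomb_constant * q_i * q_j / r_ij


def pair_lj(rmin_half_i: float, eps_i: float, rmin_half_j: float,
            eps_j: float, r_ij: float) -> float:
    """12-6 Lennard-Jones energy with AMBER mixing, in kcal/mol.

    R_ij = Rmin/2_i + Rmin/2_j, ε_ij = sqrt(ε_i ε_j); the minimum of the
    potential is exactly −ε_ij at r = R_ij.
    """
    if r_ij <= 0:
        raise ValueError(f"pair distance must be positive, got {r_ij}")
    r_min = rmin_half_i + rmin_half_j
    eps = np.sqrt(eps_i * eps_j)
    s6 = (r_min / r_ij) ** 6
    return eps * (s6 * s6 - 2.0 * s6)


def group_interaction_energy(
    frame: np.ndarray,
    topology: Topology,
    group_a: np.ndarray,
    group_b: np.ndarray,
    charge_state: str = "q",
    cutoff: float | None = None,
    coulomb_constant: float = COULOMB_CONSTANT,
) -> tuple[float, float]:
    """Total (v_vdw, v_ele) between two disjoint atom groups, kcal/mol.

    All A×B pairs are summed (no cutoff unless one is passed explicitly).
    ``charge_state`` is metadata only — see the module docstring — so the
    electrostatic term is always evaluated with the topology's charges.
    Overlapping pairs (r < 0.1 Å) trigger a warning naming the pair but
    the energy is still returned.
    """
    del charge_state  # sampling tag; does not alter evaluation
    if not topology.is_parameterized:
        raise ValueError("topology has no nonbonded parameters")
    group_a = np.asarray(group_a, dtype=int)
    group_b = np.asarray(group_b, dtype=int)
    if np.intersect1d(group_a, group_b).size:
        raise ValueError("interaction groups must be disjoint")
    if group_a.size == 0 or group_b.size == 0:
        return 0.0, 0.0

    r = cdist(frame[group_a], frame[group_b])
    close = r < OVERLAP_DISTANCE
    if close.any():
        ia, ib = np.argwhere(close)[0]
        warnings.warn(
            "overlapping atom pair "
            f"{topology.atom(int(group_a[ia]))} / "
            f"{topology.atom(int(group_b[ib]))} at r={r[ia, ib]:.3f} Å"
        )
    mask = np.ones_like(r, dtype=bool) if cutoff is None else (r <= cutoff)

    q = topology.charge
    ele = coulomb_constant * np.outer(q[group_a], q[group_b]) / r
    r_min = topology.rmin_half[group_a][:, None] + topology.rmin_half[group_b][None, :]
    eps = np.sqrt(np.outer(topology.epsilon[group_a], topology.epsilon[group_b]))
    s6 = (r_min / r) ** 6
    vdw = eps * (s6 * s6 - 2.0 * s6)
    return float(vdw[mask].sum()), float(ele[mask].sum())


@dataclass
class EnergySeries:
    """Per-frame intermolecular energies of one production run."""

    state: str
    charge_state: str
    run_id: str
    v_vdw: np.ndarray
    v_ele: np.ndarray

    def __post_init__(self) -> None:
        self.v_vdw = np.asarray(self.v_vdw, dtype=float)
        self.v_ele = np.asarray(self.v_ele, dtype=float)
        if self.v_vdw.shape != self.v_ele.shape or self.v_vdw.ndim != 1:
            raise ValueError("v_vdw and v_ele must be 1-D and equally long")
        if not (np.isfinite(self.v_vdw).all() and np.isfinite(self.v_ele).all()):
            raise ValueError("energy series contains non-finite values")

    @property
    def n_frames(self) -> int:
        return len(self.v_vdw)

    @property
    def mean_vdw(self) -> float:
        return float(self.v_vdw.mean())

    @property
    def mean_ele(self) -> float:
        return float(self.v_ele.mean())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "frame_index": np.arange(self.n_frames),
                "v_vdw": self.v_vdw,
                "v_ele": self.v_ele,
                "state": self.state,
                "charge_state": self.charge_state,
                "run_id": self.run_id,
            }
        )

    def write_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False, float_format="%.10g")

    @classmethod
    def read_tsv(cls, path) -> "EnergySeries":
        df = pd.read_csv(path, sep="\t")
        return cls(
            state=str(df["state"].iloc[0]),
            charge_state=str(df["charge_state"].iloc[0]),
            run_id=str(df["run_id"].iloc[0]),
            v_vdw=df["v_vdw"].to_numpy(),
            v_ele=df["v_ele"].to_numpy(),
        )


def ensemble_energy_series(
    trajectory: Trajectory,
    topology: Topology,
    state: str,
    charge_state: str = "q",
    run_id: str = "",
    environment: str = "all",
    cutoff: float | None = None,
) -> EnergySeries:
    """Ligand–environment (v_vdw, v_ele) for every frame of a run.

    ``environment='all'`` (default) takes everything except the ligand —
    the solvated binding site including solvent and ions; ``'protein'``
    restricts to protein atoms.
    """
    trajectory.check_compatible(topology)
    if trajectory.n_frames < 1:
        raise ValueError("empty trajectory")
    ligand = np.flatnonzero(topology.ligand_mask())
    if ligand.size == 0:
        raise ValueError("topology has no ligand-flagged atoms")
    env = np.flatnonzero(topology.environment_mask(environment))
    v_vdw = np.empty(trajectory.n_frames)
    v_ele = np.empty(trajectory.n_frames)
    for f in range(trajectory.n_frames):
        v_vdw[f], v_ele[f] = group_interaction_energy(
            trajectory.frame(f), topology, ligand, env,
            charge_state=charge_state, cutoff=cutoff,
        )
    return EnergySeries(
        state=state, charge_state=charge_state, run_id=run_id,
        v_vdw=v_vdw, v_ele=v_ele,
    )


@dataclass(frozen=True)
class StateEnergySummary:
    """Ensemble averages of one physical state (one production run).

    ``mean_vdw_q`` / ``mean_ele_q`` are averages over the real-charge
    ensemble; ``mean_ele_0`` is the real-charge electrostatic energy
    averaged over the zero-ligand-charge ensemble (the preorganization
    term).  For the free state in solvent this term is identically zero —
    a polar solvent is not preorganized around an uncharged solute — so
    ``mean_ele_0`` may be omitted there.
    """

    state: str
    mean_vdw_q: float
    mean_ele_q: float
    mean_ele_0: float | None = None

    @classmethod
    def from_series(
        cls,
        q_series: EnergySeries,
        zero_series: EnergySeries | None = None,
    ) -> "StateEnergySummary":
        if q_series.charge_state != "q":
            raise ValueError("q_series must come from the charged ensemble")
        mean_ele_0 = None
        if zero_series is not None:
            if zero_series.charge_state != "zero":
                raise ValueError(
                    "zero_series must come from the zero-charge ensemble"
                )
            if zero_series.state != q_series.state:
                raise ValueError("ensembles belong to different states")
            mean_ele_0 = zero_series.mean_ele
        return cls(
            state=q_series.state,
            mean_vdw_q=q_series.mean_vdw,
            mean_ele_q=q_series.mean_ele,
            mean_ele_0=mean_ele_0,
        )
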