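"""Atom-level data model: parameterized topologies and coordinate trajectories.

A :class:`Topology` holds the static, per-atom description of a system —
identity (name, element, residue, chain), nonbonded parameters (partial
charge in e, Lennard-Jones Rmin/2 in Å and well depth ε in kcal/mol) and
role flags (donor / acceptor / hydrophobic / backbone / ligand).  A
:class:`Trajectory` holds per-frame Cartesian coordinates in Å for the same
ordered atom list.  Atom order is the contract between the two: frame ``i``
of a trajectory is interpreted through the topology it was read with.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable

import numpy as np

#: role flags an atom may carry
FLAG_NAMES = ("donor", "acceptor", "hydrophobic", "backbone", "ligand")

#: atom names that constitute the protein backbone (standard convention)
BACKBONE_ATOM_NAMES = ("N", "CA", "C", "O")

#: residue names treated as solvent
SOLVENT_RES_NAMES = ("HOH", "WAT", "SOL", "TIP3", "SPC")

#: residue names treated as monoatomic counterions
ION_RES_NAMES = ("NA", "CL", "K", "MG", "ZN", "CA", "NA+", "CL-")


class TopologyError(ValueError):
    """Inconsistent or incomplete topology."""


@dataclass(frozen=True)
class AtomRecord:
    """A single atom row, used for reporting and error messages."""

    atom_index: int
    atom_name: str
    element: str
    residue_name: str
    residue_number: int
    chain_id: str
    charge: float | None = None
    rmin_half: float | None = None
    epsilon: float | None = None
    flags: frozenset[str] = frozenset()

    def key(self) -> tuple[str, int, str]:
        """(chain, residue number, atom name) — the parameter-table key."""
        return (self.chain_id, self.residue_number, self.atom_name)

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return (
            f"{self.chain_id}/{self.residue_name}{self.residue_number}"
            f"/{self.atom_name}"
        )


@dataclass
class Topology:
    """Ordered per-atom annotations for one molecular system.

    Parameters (``charge``, ``rmin_half``, ``epsilon``) and ``flags`` may be
    absent on a freshly read structure; :func:`lrabind.io.read_parameters`
    merges them in from a sidecar table.  ``flags`` maps flag name to a
    boolean array over atoms.
    """

    atom_name: np.ndarray
    element: np.ndarray
    res_name: np.ndarray
    res_id: np.ndarray
    chain_id: np.ndarray
    charge: np.ndarray | None = None
    rmin_half: np.ndarray | None = None
    epsilon: np.ndarray | None = None
    flags: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        n = len(self.atom_name)
        for name in ("element", "res_name", "res_id", "chain_id"):
            if len(getattr(self, name)) != n:
                raise TopologyError(f"annotation '{name}' has wrong length")
        self.res_id = np.asarray(self.res_id, dtype=int)
        for name in ("charge", "rmin_half", "epsilon"):
            arr = getattr(self, name)
            if arr is not None:
                arr = np.asarray(arr, dtype=float)
                if len(arr) != n:
                    raise TopologyError(f"parameter '{name}' has wrong length")
                setattr(self, name, arr)
        if self.rmin_half is not None and np.any(self.rmin_half < 0):
            raise TopologyError("rmin_half must be >= 0")
        if self.epsilon is not None and np.any(self.epsilon < 0):
            raise TopologyError("epsilon must be >= 0")
        for key, mask in self.flags.items():
            if key not in FLAG_NAMES:
                raise TopologyError(f"unknown flag '{key}'")
            self.flags[key] = np.asarray(mask, dtype=bool)

    # -- basic accessors ---------------------------------------------------

    @property
    def n_atoms(self) -> int:
        return len(self.atom_name)

    def flag(self, name: str) -> np.ndarray:
        """Boolean mask for a role flag (all-False if never assigned)."""
        if name not in FLAG_NAMES:
            raise TopologyError(f"unknown flag '{name}'")
        mask = self.flags.get(name)
        if mask is None:
            return np.zeros(self.n_atoms, dtype=bool)
        return mask

    @property
    def is_parameterized(self) -> bool:
        return (
            self.charge is not None
            and self.rmin_half is not None
            and self.epsilon is not None
        )

    def atom(self, i: int) -> AtomRecord:
        flags = frozenset(k for k in self.flags if self.flags[k][i])
        return AtomRecord(
            atom_index=int(i),
            atom_name=str(self.atom_name[i]),
            element=str(self.element[i]),
            residue_name=str(self.res_name[i]),
            residue_number=int(self.res_id[i]),
            chain_id=str(self.chain_id[i]),
            charge=None if self.charge is None else float(self.charge[i]),
            rmin_half=None if self.rmin_half is None else float(self.rmin_half[i]),
            epsilon=None if self.epsilon is None else float(self.epsilon[i]),
            flags=flags,
        )

    def atoms(self) -> Iterable[AtomRecord]:
        return (self.atom(i) for i in range(self.n_atoms))

    def residue_label(self, i: int) -> str:
        """Residue identity string for atom ``i``, e.g. ``'A/SER101'``."""
        return f"{self.chain_id[i]}/{self.res_name[i]}{int(self.res_id[i])}"

    # -- named groups ------------------------------------------------------

    def ligand_mask(self) -> np.ndarray:
        return self.flag("ligand")

    def solvent_mask(self) -> np.ndarray:
        return np.isin(self.res_name, SOLVENT_RES_NAMES) & ~self.ligand_mask()

    def ion_mask(self) -> np.ndarray:
        return np.isin(self.res_name, ION_RES_NAMES) & ~self.ligand_mask()

    def protein_mask(self) -> np.ndarray:
        """Everything that is neither ligand, solvent nor ion."""
        return ~(self.ligand_mask() | self.solvent_mask() | self.ion_mask())

    def backbone_mask(self) -> np.ndarray:
        explicit = self.flags.get("backbone")
        if explicit is not None and explicit.any():
            return explicit
        return self.protein_mask() & np.isin(self.atom_name, BACKBONE_ATOM_NAMES)

    def environment_mask(self, scope: str = "all") -> np.ndarray:
        """Atoms forming the ligand's surroundings.

        ``scope='all'`` (default) is everything except the ligand — the
        solvated binding site; ``scope='protein'`` restricts to protein
        atoms only.
        """
        if scope == "all":
            return ~self.ligand_mask()
        if scope == "protein":
            return self.protein_mask()
        raise TopologyError(f"unknown environment scope '{scope}'")

    def groups(self) -> dict[str, np.ndarray]:
        """Named selections as ordered index arrays."""
        masks = {
            "ligand": self.ligand_mask(),
            "protein": self.protein_mask(),
            "backbone": self.backbone_mask(),
            "solvent": self.solvent_mask(),
            "ions": self.ion_mask(),
        }
        return {k: np.flatnonzero(v) for k, v in masks.items()}

    def validate_groups(self) -> None:
        """Ligand and environment must partition the atoms."""
        lig = self.ligand_mask()
        env = self.environment_mask("all")
        if np.any(lig & env) or not np.all(lig | env):
            raise TopologyError("ligand/environment flags do not partition atoms")


@dataclass
class Trajectory:
    """Per-frame coordinates (Å) for a fixed atom list.

    ``coords`` has shape ``(n_frames, n_atoms, 3)``; frame order is the
    order of MODEL records in the source file (or of emitted Monte-Carlo
    snapshots).
    """

    coords: np.ndarray
    run_id: str = ""

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 3 or self.coords.shape[2] != 3:
            raise TopologyError("coords must have shape (n_frames, n_atoms, 3)")
        if self.n_frames < 1:
            raise TopologyError("trajectory must contain at least one frame")

    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.coords.shape[1]

    def frame(self, i: int) -> np.ndarray:
        return self.coords[i]

    def check_compatible(self, topology: Topology) -> None:
        if self.n_atoms != topology.n_atoms:
            raise TopologyError(
                f"trajectory has {self.n_atoms} atoms, topology has "
                f"{topology.n_atoms}"
            )
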