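"""Structure, trajectory, parameter-table and run-manifest I/O.

Trajectories travel as multi-model PDB files (one MODEL per frame), read
and written through biotite so coordinate formatting follows the PDB
standard (0.001 Å precision).  Nonbonded parameters and role flags live in
a flat tab-separated sidecar keyed by (chain, residue number, atom name),
and run manifests are small YAML documents grouping the independent
production runs of one (state, charge-state) condition.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
import biotite.structure as struc
from biotite.structure.io.pdb import PDBFile

from .topology import Topology, Trajectory, FLAG_NAMES

__all__ = [
    "read_structure",
    "write_structure",
    "read_parameters",
    "write_parameters",
    "RunEntry",
    "RunManifest",
    "StructureParseError",
    "ParameterError",
]

PARAMETER_COLUMNS = [
    "chain_id",
    "res_id",
    "atom_name",
    "charge",
    "rmin_half",
    "epsilon",
    "flags",
]


class StructureParseError(ValueError):
    """Malformed or internally inconsistent structure file."""


class ParameterError(ValueError):
    """Parameter sidecar does not cover the topology (or is ambiguous)."""


def _check_model_consistency(path: Path) -> None:
    """Require every MODEL to carry the same number of atom records.

    biotite raises on such files too, but without naming the offending
    model; trajectories are long so the model index matters to the user.
    """
    counts: list[int] = []
    current: int | None = None
    with open(path) as fh:
        for line in fh:
            record = line[:6].strip()
            if record == "MODEL":
                current = 0
            elif record in ("ATOM", "HETATM"):
                if current is None:  # implicit single model
                    current = 0
                current += 1
            elif record == "ENDMDL":
                counts.append(current or 0)
                current = None
    if current is not None:
        counts.append(current)
    if counts and any(c != counts[0] for c in counts):
        bad = next(i for i, c in enumerate(counts) if c != counts[0])
        raise StructureParseError(
            f"{path}: model {bad + 1} has {counts[bad]} atoms, "
            f"model 1 has {counts[0]}"
        )


def read_structure(path, format: str = "pdb_multimodel") -> tuple[Topology, Trajectory]:
    """Read a (multi-model) PDB file into a topology skeleton and trajectory.

    The returned topology carries identities only; parameters come from
    :func:`read_parameters`.  MODEL order is preserved as frame order and
    coordinates are in Å.  Atoms with an unknown element get one inferred
    from the atom name, with a warning.
    """
    if format != "pdb_multimodel":
        raise ValueError(f"unsupported structure format '{format}'")
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    _check_model_consistency(path)
    pdb = PDBFile.read(str(path))
    stack = pdb.get_structure(model=None)  # AtomArrayStack, frames x atoms

    element = np.asarray(stack.element, dtype="U4")
    blank = element == ""
    if blank.any():
        inferred = [
            struc.infer_elements([n])[0] for n in np.asarray(stack.atom_name)[blank]
        ]
        warnings.warn(
            f"{path}: {int(blank.sum())} atoms without element; "
            "inferred from atom names"
        )
        element[blank] = inferred

    topology = Topology(
        atom_name=np.asarray(stack.atom_name, dtype="U6"),
        element=element,
        res_name=np.asarray(stack.res_name, dtype="U5"),
        res_id=np.asarray(stack.res_id, dtype=int),
        chain_id=np.asarray(stack.chain_id, dtype="U4"),
    )
    trajectory = Trajectory(coords=np.asarray(stack.coord, dtype=float))
    return topology, trajectory


def write_structure(path, topology: Topology, trajectory: Trajectory) -> None:
    """Write a topology + trajectory as a multi-model PDB file."""
    trajectory.check_compatible(topology)
    n_frames, n_atoms = trajectory.n_frames, trajectory.n_atoms
    stack = struc.AtomArrayStack(n_frames, n_atoms)
    stack.atom_name = np.asarray(topology.atom_name, dtype="U6")
    stack.element = np.asarray(topology.element, dtype="U2")
    stack.res_name = np.asarray(topology.res_name, dtype="U5")
    stack.res_id = np.asarray(topology.res_id, dtype=int)
    stack.chain_id = np.asarray(topology.chain_id, dtype="U4")
    stack.hetero = ~topology.protein_mask()
    stack.coord = np.asarray(trajectory.coords, dtype=np.float32)
    pdb = PDBFile()
    pdb.set_structure(stack)
    pdb.write(str(path))


# ---------------------------------------------------------------------------
# parameter sidecar


def read_parameters(path, topology: Topology) -> Topology:
    """Merge a per-atom parameter table into a topology skeleton.

    The sidecar is tab-separated with columns
    ``chain_id res_id atom_name charge rmin_half epsilon flags`` where
    ``flags`` is a comma-joined subset of donor/acceptor/hydrophobic/
    backbone/ligand (``-`` for none).  Every topology atom must be covered
    exactly once; unmatched table rows are reported with a warning.
    """
    table = pd.read_csv(path, sep="\t", dtype={"chain_id": str, "atom_name": str})
    missing_cols = set(PARAMETER_COLUMNS) - set(table.columns)
    if missing_cols:
        raise ParameterError(f"{path}: missing columns {sorted(missing_cols)}")
    keys = list(
        zip(table["chain_id"], table["res_id"].astype(int), table["atom_name"])
    )
    dupes = table.loc[pd.Index(keys).duplicated()]
    if len(dupes):
        first = dupes.iloc[0]
        raise ParameterError(
            f"{path}: duplicate parameter key "
            f"({first['chain_id']}, {first['res_id']}, {first['atom_name']})"
        )
    rows = {k: i for i, k in enumerate(keys)}

    n = topology.n_atoms
    charge = np.zeros(n)
    rmin_half = np.zeros(n)
    epsilon = np.zeros(n)
    flags = {name: np.zeros(n, dtype=bool) for name in FLAG_NAMES}
    unparameterized: list[str] = []
    matched = np.zeros(len(table), dtype=bool)
    for i in range(n):
        key = (str(topology.chain_id[i]), int(topology.res_id[i]),
               str(topology.atom_name[i]))
        j = rows.get(key)
        if j is None:
            unparameterized.append(str(topology.atom(i)))
            continue
        matched[j] = True
        row = table.iloc[j]
        charge[i] = float(row["charge"])
        rmin_half[i] = float(row["rmin_half"])
        epsilon[i] = float(row["epsilon"])
        raw = str(row["flags"])
        if raw not in ("-", "nan", ""):
            for f in raw.split(","):
                f = f.strip()
                if f not in FLAG_NAMES:
                    raise ParameterError(f"{path}: unknown flag '{f}'")
                flags[f][i] = True
    if unparameterized:
        raise ParameterError(
            f"{path}: no parameters for atoms: " + ", ".join(unparameterized)
        )
    if not matched.all():
        extra = [keys[j] for j in np.flatnonzero(~matched)]
        warnings.warn(f"{path}: {len(extra)} parameter rows match no atom: {extra[:5]}")

    out = Topology(
        atom_name=topology.atom_name.copy(),
        element=topology.element.copy(),
        res_name=topology.res_name.copy(),
        res_id=topology.res_id.copy(),
        chain_id=topology.chain_id.copy(),
        charge=charge,
        rmin_half=rmin_half,
        epsilon=epsilon,
        flags=flags,
    )
    out.validate_groups()
    return out


def write_parameters(path, topology: Topology) -> None:
    """Write the parameter sidecar for a fully parameterized topology."""
    if not topology.is_parameterized:
        raise ParameterError("topology carries no parameters to write")
    records = []
    for atom in topology.atoms():
        records.append(
            {
                "chain_id": atom.chain_id,
                "res_id": atom.residue_number,
                "atom_name": atom.atom_name,
                "charge": f"{atom.charge:.6f}",
                "rmin_half": f"{atom.rmin_half:.4f}",
                "epsilon": f"{atom.epsilon:.4f}",
                "flags": ",".join(sorted(atom.flags)) or "-",
            }
        )
    pd.DataFrame(records, columns=PARAMETER_COLUMNS).to_csv(
        path, sep="\t", index=False
    )


# ---------------------------------------------------------------------------
# run manifests


@dataclass(frozen=True)
class RunEntry:
    """One independent production run."""

    trajectory: str
    seed: int


@dataclass
class RunManifest:
    """All independent runs of one (state, charge-state) condition.

    ``state`` is ``bound_P`` (ligand in the solvated binding site) or
    ``free_W`` (ligand alone in solvent); ``charge_state`` is ``q``
    (sampled with real ligand charges) or ``zero`` (sampled with ligand
    charges switched off).  All runs share one structure/parameter pair.
    """

    state: str
    charge_state: str
    parameters: str
    runs: list[RunEntry] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.state not in ("bound_P", "free_W"):
            raise ValueError(f"unknown state '{self.state}'")
        if self.charge_state not in ("q", "zero"):
            raise ValueError(f"unknown charge_state '{self.charge_state}'")
        if not self.runs:
            raise ValueError("manifest must list at least one run")

    @classmethod
    def load(cls, path) -> "RunManifest":
        path = Path(path)
        with open(path) as fh:
            doc = yaml.safe_load(fh)
        runs = [RunEntry(str(r["trajectory"]), int(r["seed"])) for r in doc["runs"]]
        return cls(
            state=doc["state"],
            charge_state=doc["charge_state"],
            parameters=str(doc["parameters"]),
            runs=runs,
        )

    def save(self, path) -> None:
        doc = {
            "state": self.state,
            "charge_state": self.charge_state,
            "parameters": self.parameters,
            "runs": [
                {"trajectory": r.trajectory, "seed": r.seed} for r in self.runs
            ],
        }
        with open(path, "w") as fh:
            yaml.safe_dump(doc, fh, sort_keys=False)

    def resolve(self, base) -> "RunManifest":
        """Return a copy with paths made absolute relative to ``base``."""
        base = Path(base)
        return RunManifest(
            state=self.state,
            charge_state=self.charge_state,
            parameters=str(base / self.parameters),
            runs=[
                RunEntry(str(base / r.trajectory), r.seed) for r in self.runs
            ],
        )
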