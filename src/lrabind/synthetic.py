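"""Synthetic ensembles with known statistical structure.

Two desk-scale systems make every pipeline stage testable without
external trajectories:

* a **harmonic bath** — one bath coordinate x with energy ½k_s·x² coupled
  to a "ligand charge" q through U = c·q·x.  Completing the square gives
  the exact charging free energy ΔG = −c²q²/(2k_s), together with the
  linear-response identities ⟨U⟩_q = −c²q²/k_s = 2ΔG and ⟨U⟩₀ = 0, so the
  endpoint estimator can be validated against a closed form;

* a **toy ligand–pocket complex** — a three-atom dipolar ligand inside a
  ring of four polar pseudo-residues (backbone-named atoms, dipoles
  oriented toward the ligand site, i.e. an electrostatically preorganized
  pocket) plus a shell of dipolar solvent molecules.  The free state is
  the same ligand in the solvent shell alone.  Every atom is harmonically
  restrained near a home position, standing in for the confining effect
  of bonded structure that the model deliberately omits.

Configurations are drawn by Metropolis Monte-Carlo single-atom moves with
acceptance min(1, exp(−ΔE/k_BT)) — exact Boltzmann sampling with tiny
code, replacing a molecular-dynamics engine whose integration machinery
would affect only sampling efficiency, not the estimator under test.  In
the ``zero`` charge state the *sampling* energy uses zero ligand charges
while emitted coordinates are unmodified, exactly the ensemble the
preorganization term is defined over.  All randomness flows from explicit
integer seeds via numpy seed sequences; there is no global random state.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .energetics import COULOMB_CONSTANT
from .io import RunEntry, RunManifest, write_parameters, write_structure
from .topology import Topology, Trajectory

__all__ = [
    "BOLTZMANN_KCAL",
    "HarmonicBathSpec",
    "ChargingFreeEnergy",
    "SamplerConfig",
    "BathSeries",
    "analytic_charging_free_energy",
    "sample_harmonic_bath",
    "ToyComplexSpec",
    "ToySystem",
    "build_toy_complex",
    "metropolis_sample",
    "generate_fixture_suite",
]

#: Boltzmann constant in kcal/(mol·K)
BOLTZMANN_KCAL = 0.0019872041


class SamplingError(RuntimeError):
    """The Markov chain failed to move."""


@dataclass(frozen=True)
class HarmonicBathSpec:
    """Bath coordinate with spring k_s coupled as U = c·q·x.

    Units: coupling kcal/(mol·Å·e); spring kcal/(mol·Å²); charge e;
    temperature K.
    """

    coupling: float = 1.5
    spring: float = 1.2
    ligand_charge: float = 1.0
    temperature: float = 298.15

    def __post_init__(self) -> None:
        if self.spring <= 0:
            raise ValueError("spring constant must be positive")
        if self.temperature <= 0:
            raise ValueError("temperature must be positive")


@dataclass(frozen=True)
class ChargingFreeEnergy:
    """Closed-form charging thermodynamics of the harmonic bath."""

    dG: float
    mean_U_q: float
    mean_U_0: float


def analytic_charging_free_energy(spec: HarmonicBathSpec) -> ChargingFreeEnergy:
    """Exact ΔG and ensemble averages for switching the coupling on.

    For U = c·q·x against bath energy ½k_s·x², Gaussian integration gives
    ΔG = −(cq)²/(2k_s), ⟨U⟩_q = −(cq)²/k_s (twice ΔG, the linear-response
    identity) and ⟨U⟩₀ = 0.
    """
    cq = spec.coupling * spec.ligand_charge
    return ChargingFreeEnergy(
        dG=-(cq**2) / (2.0 * spec.spring),
        mean_U_q=-(cq**2) / spec.spring,
        mean_U_0=0.0,
    )


@dataclass(frozen=True)
class SamplerConfig:
    """Metropolis chain settings.

    ``steps`` counts attempted moves; frames are recorded every
    ``thinning`` moves after ``burn_in``.  The proposal is a uniform
    displacement of one coordinate (bath) or one atom (complex) by up to
    ``step`` Å per axis.
    """

    temperature: float = 298.15
    step: float = 1.0
    steps: int = 100_000
    burn_in: int = 1_000
    thinning: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.steps > self.burn_in >= 0:
            raise ValueError("need steps > burn_in >= 0")
        if self.thinning < 1:
            raise ValueError("thinning must be >= 1")
        if self.temperature <= 0 or self.step <= 0:
            raise ValueError("temperature and step must be positive")

    @property
    def n_frames(self) -> int:
        return (self.steps - self.burn_in) // self.thinning


@dataclass
class BathSeries:
    """Sampled bath positions and real-charge interaction energies."""

    x: np.ndarray
    u: np.ndarray
    spec: HarmonicBathSpec
    charge_state: str
    acceptance: float

    @property
    def mean_u(self) -> float:
        return float(self.u.mean())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "frame_index": np.arange(len(self.x)),
                "x": self.x,
                "u": self.u,
                "charge_state": self.charge_state,
            }
        )

    def write_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False, float_format="%.10g")


def sample_harmonic_bath(
    spec: HarmonicBathSpec,
    config: SamplerConfig,
    charge_state: str = "q",
) -> BathSeries:
    """Metropolis-sample the bath coordinate; emit U = c·q·x per frame.

    In the ``zero`` charge state the chain samples the bare bath (no
    coupling term) while the emitted energies still use the real charge —
    the preorganization convention.
    """
    if charge_state not in ("q", "zero"):
        raise ValueError(f"unknown charge_state '{charge_state}'")
    rng = np.random.Generator(np.random.PCG64(np.random.SeedSequence(config.seed)))
    kt = BOLTZMANN_KCAL * config.temperature
    cq_sample = (
        spec.coupling * spec.ligand_charge if charge_state == "q" else 0.0
    )
    cq_real = spec.coupling * spec.ligand_charge
    k = spec.spring

    proposals = rng.uniform(-config.step, config.step, config.steps)
    accept_u = rng.random(config.steps)
    x = 0.0
    xs = np.empty(config.n_frames)
    n_accept = 0
    n_frames = 0
    for i in range(config.steps):
        x_new = x + proposals[i]
        delta = 0.5 * k * (x_new**2 - x**2) + cq_sample * (x_new - x)
        if delta <= 0 or accept_u[i] < np.exp(-delta / kt):
            x = x_new
            n_accept += 1
        if i == config.burn_in - 1 and config.burn_in > 0 and n_accept == 0:
            raise SamplingError(
                "no accepted moves during burn-in; reduce the proposal step"
            )
        if i >= config.burn_in and (i - config.burn_in) % config.thinning == 0:
            if n_frames < len(xs):
                xs[n_frames] = x
                n_frames += 1
    xs = xs[:n_frames]
    return BathSeries(
        x=xs,
        u=cq_real * xs,
        spec=spec,
        charge_state=charge_state,
        acceptance=n_accept / config.steps,
    )


# ---------------------------------------------------------------------------
# toy ligand-pocket complex


# nonbonded parameters by element class (GAFF-like magnitudes)
_LJ = {
    "C": (1.908, 0.086),
    "N": (1.824, 0.170),
    "O": (1.661, 0.210),
}


@dataclass(frozen=True)
class ToyComplexSpec:
    """Geometry, charges and restraints of the toy bound/free systems.

    Four pseudo-residues surround a three-atom dipolar ligand at
    ``pocket_radius`` Å.  The two residues on the ligand's dipole axis
    face it pole-on — a donor nitrogen (δ+) restrained toward the
    ligand's negative oxygen and an acceptor oxygen (δ−) toward its
    positive carbon — so the site is electrostatically preorganized: the
    ligand–pocket electrostatic energy is negative even over the ensemble
    sampled with zero ligand charges.  The two flanking residues present
    apolar carbons to the ligand's hydrophobic atom with their polar
    atoms arranged as a distant, nearly field-free pair.
    ``ligand_charge_scale`` scales the ligand's partial charges (0 gives
    an apolar ligand whose charged and zero ensembles coincide).
    Restraint constants are kcal/(mol·Å²) for an energy ½k|r−r₀|².
    """

    pocket_radius: float = 4.5
    solvent_radius: float = 5.5
    n_solvent: int = 8
    ligand_charge_scale: float = 1.0
    restraint_k_ligand: float = 5.0
    restraint_k_pocket: float = 3.0
    restraint_k_solvent: float = 1.0

    def __post_init__(self) -> None:
        if self.pocket_radius <= 0 or self.solvent_radius <= 0:
            raise ValueError("radii must be positive")
        if min(self.restraint_k_ligand, self.restraint_k_pocket,
               self.restraint_k_solvent) <= 0:
            raise ValueError("restraint constants must be positive")


@dataclass
class ToySystem:
    """A parameterized topology plus home positions and restraints."""

    state: str
    topology: Topology
    home: np.ndarray
    restraint_k: np.ndarray

    @property
    def n_atoms(self) -> int:
        return self.topology.n_atoms


class _SystemBuilder:
    def __init__(self) -> None:
        self.rows: list[dict] = []
        self.home: list[tuple[float, float, float]] = []
        self.restraint: list[float] = []

    def add(self, name, element, res_name, res_id, chain, charge, pos, k,
            flags=()):
        rmin_half, eps = _LJ[element]
        self.rows.append(
            dict(atom_name=name, element=element, res_name=res_name,
                 res_id=res_id, chain_id=chain, charge=charge,
                 rmin_half=rmin_half, epsilon=eps, flags=set(flags))
        )
        self.home.append(tuple(pos))
        self.restraint.append(k)

    def build(self, state: str) -> ToySystem:
        n = len(self.rows)
        flags = {name: np.zeros(n, dtype=bool)
                 for name in ("donor", "acceptor", "hydrophobic", "ligand")}
        for i, row in enumerate(self.rows):
            for f in row["flags"]:
                flags[f][i] = True
        topology = Topology(
            atom_name=np.array([r["atom_name"] for r in self.rows], dtype="U6"),
            element=np.array([r["element"] for r in self.rows], dtype="U4"),
            res_name=np.array([r["res_name"] for r in self.rows], dtype="U5"),
            res_id=np.array([r["res_id"] for r in self.rows], dtype=int),
            chain_id=np.array([r["chain_id"] for r in self.rows], dtype="U4"),
            charge=np.array([r["charge"] for r in self.rows], dtype=float),
            rmin_half=np.array([r["rmin_half"] for r in self.rows]),
            epsilon=np.array([r["epsilon"] for r in self.rows]),
            flags=flags,
        )
        total_charge = float(topology.charge.sum())
        if abs(total_charge) > 1e-9:
            raise ValueError(f"system net charge {total_charge:+.6f} e != 0")
        return ToySystem(
            state=state,
            topology=topology,
            home=np.asarray(self.home, dtype=float),
            restraint_k=np.asarray(self.restraint, dtype=float),
        )


def _add_ligand(builder: _SystemBuilder, scale: float) -> None:
    builder.add("O1", "O", "LIG", 1, "L", -0.40 * scale, (-1.3, 0.0, 0.0),
                k=5.0, flags=("ligand", "donor", "acceptor"))
    builder.add("C1", "C", "LIG", 1, "L", +0.40 * scale, (1.3, 0.0, 0.0),
                k=5.0, flags=("ligand",))
    builder.add("C2", "C", "LIG", 1, "L", 0.0, (0.0, 1.0, 0.0),
                k=5.0, flags=("ligand", "hydrophobic"))


def _add_solvent(builder: _SystemBuilder, spec: ToyComplexSpec) -> None:
    # dipolar pseudo-solvent on cube-vertex directions: negative pole
    # inward (bulk-like, not preorganized for any particular ligand sign)
    directions = np.array(
        [(sx, sy, sz) for sx in (-1, 1) for sy in (-1, 1) for sz in (-1, 1)],
        dtype=float,
    ) / np.sqrt(3.0)
    for m in range(spec.n_solvent):
        u = directions[m % len(directions)]
        ring = 1 + m // len(directions)
        r_in = spec.solvent_radius * ring
        res_id = 200 + m + 1
        builder.add("OD", "O", "SOL", res_id, "W", -0.25, r_in * u,
                    k=spec.restraint_k_solvent, flags=("acceptor",))
        builder.add("CD", "C", "SOL", res_id, "W", +0.25, (r_in + 1.2) * u,
                    k=spec.restraint_k_solvent)


def build_toy_complex(spec: ToyComplexSpec | None = None
                      ) -> tuple[ToySystem, ToySystem]:
    """Construct the bound (ligand+pocket+shell) and free (ligand+shell)
    systems with identical ligand parameters."""
    spec = spec or ToyComplexSpec()

    bound = _SystemBuilder()
    _add_ligand(bound, spec.ligand_charge_scale)
    r = spec.pocket_radius
    k = spec.restraint_k_pocket
    # residue 1 (−x): donor N faces the ligand oxygen pole-on
    bound.add("N", "N", "SER", 101, "A", +0.30, (-r, 0.0, 0.0), k,
              flags=("donor",))
    bound.add("CA", "C", "SER", 101, "A", 0.0, (-r - 0.4, 0.8, 0.0), k)
    bound.add("C", "C", "SER", 101, "A", 0.0, (-r - 0.4, -0.8, 0.0), k)
    bound.add("O", "O", "SER", 101, "A", -0.30, (-r - 1.2, 0.0, 0.0), k)
    # residue 2 (+x): acceptor O faces the ligand's positive carbon
    bound.add("O", "O", "ASP", 102, "A", -0.30, (r, 0.0, 0.0), k,
              flags=("acceptor",))
    bound.add("CA", "C", "ASP", 102, "A", 0.0, (r + 0.4, 0.8, 0.0), k)
    bound.add("C", "C", "ASP", 102, "A", 0.0, (r + 0.4, -0.8, 0.0), k)
    bound.add("N", "N", "ASP", 102, "A", +0.30, (r + 1.2, 0.0, 0.0), k)
    # residue 3 (+y): apolar carbons toward the ligand's hydrophobic atom,
    # polar atoms as a distant tangential pair (weak far field)
    bound.add("CA", "C", "ASN", 103, "A", 0.0, (0.8, r - 0.3, 0.0), k,
              flags=("hydrophobic",))
    bound.add("C", "C", "ASN", 103, "A", 0.0, (-0.8, r - 0.3, 0.0), k,
              flags=("hydrophobic",))
    bound.add("N", "N", "ASN", 103, "A", +0.30, (1.0, r + 0.9, 0.0), k,
              flags=("donor",))
    bound.add("O", "O", "ASN", 103, "A", -0.30, (-1.0, r + 0.9, 0.0), k,
              flags=("acceptor",))
    # residue 4 (−y): mirror image with the polar pair swapped so the two
    # flanking residues' far fields cancel
    bound.add("CA", "C", "GLN", 104, "A", 0.0, (0.8, -(r - 0.3), 0.0), k,
              flags=("hydrophobic",))
    bound.add("C", "C", "GLN", 104, "A", 0.0, (-0.8, -(r - 0.3), 0.0), k,
              flags=("hydrophobic",))
    bound.add("N", "N", "GLN", 104, "A", +0.30, (-1.0, -r - 0.9, 0.0), k,
              flags=("donor",))
    bound.add("O", "O", "GLN", 104, "A", -0.30, (1.0, -r - 0.9, 0.0), k,
              flags=("acceptor",))
    _add_solvent(bound, spec)

    free = _SystemBuilder()
    _add_ligand(free, spec.ligand_charge_scale)
    _add_solvent(free, spec)

    bound_sys = bound.build("bound_P")
    free_sys = free.build("free_W")
    # ligand restraints from the spec (builder used the default)
    for system in (bound_sys, free_sys):
        system.restraint_k[system.topology.ligand_mask()] = spec.restraint_k_ligand
    return bound_sys, free_sys


def metropolis_sample(
    system: ToySystem,
    config: SamplerConfig,
    charge_state: str = "q",
    run_id: str = "",
) -> Trajectory:
    """Sample the toy system with single-atom Metropolis moves.

    The sampling energy is the sum of ligand–environment nonbonded terms
    (Coulomb with the charge-state's sampling charges plus Lennard-Jones)
    and the per-atom harmonic restraints.  Emitted frames are raw
    coordinates; the chain is reproducible bit-for-bit per seed.
    """
    if charge_state not in ("q", "zero"):
        raise ValueError(f"unknown charge_state '{charge_state}'")
    top = system.topology
    rng = np.random.Generator(np.random.PCG64(np.random.SeedSequence(config.seed)))
    kt = BOLTZMANN_KCAL * config.temperature

    q_sample = top.charge.copy()
    ligand = top.ligand_mask()
    if charge_state == "zero":
        q_sample[ligand] = 0.0

    lig_idx = np.flatnonzero(ligand)
    env_idx = np.flatnonzero(~ligand)
    n = top.n_atoms
    # per-atom partner tables (ligand atoms see the environment and
    # vice versa; environment-environment terms are not modelled)
    partners = [env_idx if ligand[a] else lig_idx for a in range(n)]
    qfac = [COULOMB_CONSTANT * q_sample[a] * q_sample[partners[a]]
            for a in range(n)]
    rmin = [top.rmin_half[a] + top.rmin_half[partners[a]] for a in range(n)]
    eps = [np.sqrt(top.epsilon[a] * top.epsilon[partners[a]])
           for a in range(n)]

    coords = system.home.copy()
    moves = rng.integers(0, n, config.steps)
    deltas = rng.uniform(-config.step, config.step, (config.steps, 3))
    accept_u = rng.random(config.steps)

    def _nonbonded(a: int, pos: np.ndarray) -> float:
        p = partners[a]
        r = np.linalg.norm(coords[p] - pos, axis=1)
        s6 = (rmin[a] / r) ** 6
        return float((qfac[a] / r).sum() + (eps[a] * (s6 * s6 - 2.0 * s6)).sum())

    def _restraint(a: int, pos: np.ndarray) -> float:
        d = pos - system.home[a]
        return 0.5 * system.restraint_k[a] * float(d @ d)

    frames = np.empty((config.n_frames, n, 3))
    n_frames = 0
    n_accept = 0
    for i in range(config.steps):
        a = int(moves[i])
        new_pos = coords[a] + deltas[i]
        delta_e = (
            _nonbonded(a, new_pos) - _nonbonded(a, coords[a])
            + _restraint(a, new_pos) - _restraint(a, coords[a])
        )
        if delta_e <= 0 or accept_u[i] < np.exp(-delta_e / kt):
            coords[a] = new_pos
            n_accept += 1
        if i == config.burn_in - 1 and config.burn_in > 0 and n_accept == 0:
            raise SamplingError(
                "no accepted moves during burn-in; reduce the proposal step"
            )
        if i >= config.burn_in and (i - config.burn_in) % config.thinning == 0:
            if n_frames < len(frames):
                frames[n_frames] = coords
                n_frames += 1
    return Trajectory(coords=frames[:n_frames], run_id=run_id)


# ---------------------------------------------------------------------------
# fixture suite


def _child_seeds(master_seed: int, count: int) -> list[int]:
    """Split one master seed into independent 31-bit integer seeds."""
    state = np.random.SeedSequence(master_seed).generate_state(count, dtype=np.uint32)
    return [int(s & 0x7FFFFFFF) for s in state]


@dataclass(frozen=True)
class FixtureSamplerSettings:
    """Chain lengths used when emitting fixture trajectories."""

    frames_per_run: int = 120
    thinning: int = 60
    burn_in: int = 600
    step: float = 0.35
    temperature: float = 298.15

    def config(self, seed: int) -> SamplerConfig:
        return SamplerConfig(
            temperature=self.temperature,
            step=self.step,
            steps=self.burn_in + self.frames_per_run * self.thinning,
            burn_in=self.burn_in,
            thinning=self.thinning,
            seed=seed,
        )


def generate_fixture_suite(
    output_dir,
    master_seed: int,
    n_runs: int = 4,
    complex_spec: ToyComplexSpec | None = None,
    bath_spec: HarmonicBathSpec | None = None,
    sampler: FixtureSamplerSettings | None = None,
    bath_steps: int = 20_000,
) -> dict:
    """Write a deterministic, self-describing bundle of synthetic data.

    The bundle contains the harmonic-bath series (charged and zero
    ensembles), ``n_runs`` independent bound/free toy-complex
    trajectories per charge state as multi-model PDB, the parameter
    sidecars and run manifests the analysis pipeline consumes, and a
    provenance file recording every spec and seed.  The same master seed
    yields a byte-identical bundle.
    """
    output_dir = Path(output_dir)
    output_dir.mkdir(parents=True, exist_ok=True)
    complex_spec = complex_spec or ToyComplexSpec()
    bath_spec = bath_spec or HarmonicBathSpec()
    sampler = sampler or FixtureSamplerSettings()

    conditions = [
        ("bound_P", "q"), ("bound_P", "zero"),
        ("free_W", "q"), ("free_W", "zero"),
    ]
    seeds = _child_seeds(master_seed, 2 + len(conditions) * n_runs)
    bath_seeds, run_seeds = seeds[:2], seeds[2:]

    bath_config = SamplerConfig(
        temperature=bath_spec.temperature, step=1.5 * np.sqrt(
            BOLTZMANN_KCAL * bath_spec.temperature / bath_spec.spring),
        steps=bath_steps, burn_in=bath_steps // 10, thinning=1,
        seed=bath_seeds[0],
    )
    paths: dict = {"bath": {}, "manifests": {}, "parameters": {}}
    for cs, seed in (("q", bath_seeds[0]), ("zero", bath_seeds[1])):
        series = sample_harmonic_bath(
            bath_spec,
            SamplerConfig(**{**asdict(bath_config), "seed": seed}),
            charge_state=cs,
        )
        path = output_dir / f"bath_{cs}.tsv"
        series.write_tsv(path)
        paths["bath"][cs] = str(path)

    bound, free = build_toy_complex(complex_spec)
    systems = {"bound_P": bound, "free_W": free}
    for state, system in systems.items():
        ppath = output_dir / f"params_{state}.tsv"
        write_parameters(ppath, system.topology)
        paths["parameters"][state] = str(ppath)

    seed_iter = iter(run_seeds)
    for state, cs in conditions:
        system = systems[state]
        entries = []
        for run in range(n_runs):
            seed = next(seed_iter)
            run_id = f"{state}_{cs}_run{run + 1}"
            trajectory = metropolis_sample(
                system, sampler.config(seed), charge_state=cs, run_id=run_id,
            )
            tpath = output_dir / f"{run_id}.pdb"
            write_structure(tpath, system.topology, trajectory)
            entries.append(RunEntry(trajectory=tpath.name, seed=seed))
        manifest = RunManifest(
            state=state, charge_state=cs,
            parameters=f"params_{state}.tsv", runs=entries,
        )
        mpath = output_dir / f"manifest_{state}_{cs}.yaml"
        manifest.save(mpath)
        paths["manifests"][f"{state}_{cs}"] = str(mpath)

    provenance = {
        "master_seed": master_seed,
        "n_runs": n_runs,
        "complex_spec": asdict(complex_spec),
        "bath_spec": asdict(bath_spec),
        "sampler": asdict(sampler),
        "bath_steps": bath_steps,
        "bath_seeds": bath_seeds,
        "run_seeds": run_seeds,
    }
    ppath = output_dir / "provenance.json"
    with open(ppath, "w") as fh:
        json.dump(provenance, fh, indent=2, sort_keys=True)
    paths["provenance"] = str(ppath)
    return paths
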