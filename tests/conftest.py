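import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from lrabind.pipeline import PipelineConfig, run_pipeline
from lrabind.synthetic import FixtureSamplerSettings, generate_fixture_suite
from lrabind.topology import FLAG_NAMES, Topology

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


def build_topology(atoms):
    """Build a parameterized Topology from a list of atom dicts.

    Each dict: name, element, res_name, res_id, chain (default A),
    charge, rmin_half, epsilon, flags (iterable).
    """
    n = len(atoms)
    flags = {name: np.zeros(n, dtype=bool) for name in FLAG_NAMES}
    for i, a in enumerate(atoms):
        for f in a.get("flags", ()):
            flags[f][i] = True
    return Topology(
        atom_name=np.array([a["name"] for a in atoms], dtype="U6"),
        element=np.array([a.get("element", "C") for a in atoms], dtype="U4"),
        res_name=np.array([a.get("res_name", "LIG") for a in atoms], dtype="U5"),
        res_id=np.array([a.get("res_id", 1) for a in atoms], dtype=int),
        chain_id=np.array([a.get("chain", "A") for a in atoms], dtype="U4"),
        charge=np.array([a.get("charge", 0.0) for a in atoms]),
        rmin_half=np.array([a.get("rmin_half", 1.9) for a in atoms]),
        epsilon=np.array([a.get("epsilon", 0.1) for a in atoms]),
        flags=flags,
    )


def random_system(rng, n_ligand=3, n_env=8):
    """A random parameterized two-group system for oracle comparisons."""
    atoms = []
    for i in range(n_ligand):
        atoms.append(
            dict(name=f"L{i}", res_name="LIG", res_id=1, chain="L",
                 charge=rng.uniform(-0.5, 0.5),
                 rmin_half=rng.uniform(1.2, 2.1),
                 epsilon=rng.uniform(0.02, 0.3), flags=("ligand",))
        )
    for i in range(n_env):
        atoms.append(
            dict(name=f"E{i}", res_name="ENV", res_id=100 + i,
                 charge=rng.uniform(-0.5, 0.5),
                 rmin_half=rng.uniform(1.2, 2.1),
                 epsilon=rng.uniform(0.02, 0.3))
        )
    top = build_topology(atoms)
    # keep groups a few Å apart so energies stay well conditioned
    coords = np.concatenate(
        [
            rng.uniform(-1.5, 1.5, (n_ligand, 3)),
            rng.uniform(-1.5, 1.5, (n_env, 3)) + np.array([6.0, 0.0, 0.0]),
        ]
    )
    return top, coords


@pytest.fixture(scope="session")
def bundle(tmp_path_factory):
    """A deterministic synthetic data bundle shared across tests."""
    out = tmp_path_factory.mktemp("bundle")
    paths = generate_fixture_suite(
        out, master_seed=2024,
        sampler=FixtureSamplerSettings(frames_per_run=60),
    )
    return out, paths


@pytest.fixture(scope="session")
def pipeline_result(bundle):
    """The pipeline run once on the shared bundle."""
    out, _ = bundle
    config_path = out / "config.yaml"
    config_path.write_text(
        "manifests:\n"
        "  bound_q: manifest_bound_P_q.yaml\n"
        "  bound_zero: manifest_bound_P_zero.yaml\n"
        "  free_q: manifest_free_W_q.yaml\n"
        "output_dir: out\n"
        "criteria: {heavy_atom_only: true}\n"
    )
    config = PipelineConfig.from_yaml(config_path)
    return config, run_pipeline(config)
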