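"""Run the full analysis pipeline on generated toy-complex ensembles.

Generates bound (ligand + preorganized pocket + solvent shell) and free
(ligand + shell) Metropolis ensembles - four independent runs each for
the charged and zero-ligand-charge conditions - then computes per-frame
interaction energies, assembles the LRA thermodynamic cycle per run,
aggregates across runs, and profiles stability metrics and contacts.
"""

import tempfile
from pathlib import Path

from lrabind.pipeline import PipelineConfig, run_pipeline
from lrabind.synthetic import generate_fixture_suite

with tempfile.TemporaryDirectory() as tmp:
    bundle = Path(tmp) / "bundle"
    generate_fixture_suite(bundle, master_seed=2024)
    (bundle / "config.yaml").write_text(
        "manifests:\n"
        "  bound_q: manifest_bound_P_q.yaml\n"
        "  bound_zero: manifest_bound_P_zero.yaml\n"
        "  free_q: manifest_free_W_q.yaml\n"
        "output_dir: out\n"
        "criteria: {heavy_atom_only: true}\n"
    )
    result = run_pipeline(PipelineConfig.from_yaml(bundle / "config.yaml"))

agg = result.aggregate
print("LRA thermodynamic cycle, mean over 4 independent runs (kcal/mol):")
for name in ("mean_vdw_P_q", "mean_vdw_W_q", "mean_ele_P_q",
             "mean_ele_W_q", "mean_ele_P_0", "dG_binding"):
    print(f"  {name:<14} {agg.mean[name]:+8.3f} +- {agg.sd[name]:.3f}")
print(f"cycle closure residual: {max(abs(r) for r in result.cycle_residuals):.1e}")

print("\nstability metrics (mean over runs, Angstrom):")
for name, metric in result.metrics.items():
    print(f"  {name:<14} {metric.mean:.3f} +- {metric.sd:.3f}")

print("\ntop contacts (occupancy over all frames):")
for report in result.occupancy[:4]:
    print(
        f"  {report.kind:<12} {report.residue:<12} "
        f"{100 * report.occupancy:5.1f}%  {report.mean_distance:.2f} A"
    )
print(
    "\nThe negative dG and negative preorganization term show the polar\n"
    "pocket binding the dipolar ligand; the persistent SER101 hydrogen\n"
    "bond anchors the pose, mirroring how occupancy reports read for\n"
    "real binding sites."
)
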