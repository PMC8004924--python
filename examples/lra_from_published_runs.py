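"""Aggregate the published per-run LRA tables for PDE4D-polyphenol binding.

The study reports, for each of four natural polyphenols, the five
ensemble-average interaction-energy components and the assembled binding
free energy of four independent production runs.  This script recomputes
the cross-run means and sample standard deviations and compares each
ligand's mean binding free energy with the experimental value of the
positive-control inhibitor rolipram (-9.86 kcal/mol).
"""

from lrabind.lra import compare_to_reference
from lrabind.reference_data import (
    LIGANDS,
    ROLIPRAM_EXPERIMENTAL_DG,
    lra_run_table,
)
from lrabind.stats import mean_sd, round_half_up

print(f"{'ligand':<14} {'dG mean':>8} {'sd':>6} {'vs rolipram':>12}")
for ligand in LIGANDS:
    table = lra_run_table(ligand)
    mean_dg, sd_dg = mean_sd(table["dG"])
    gap = compare_to_reference(mean_dg, ROLIPRAM_EXPERIMENTAL_DG)
    print(
        f"{ligand:<14} {round_half_up(mean_dg, 2):>8.2f} "
        f"{round_half_up(sd_dg, 2):>6.2f} {gap:>+12.2f}"
    )

print(
    "\nEach row: cross-run mean and sample sd (n-1) of the four per-run\n"
    "binding free energies (kcal/mol), and the difference to rolipram's\n"
    "experimental -9.86 kcal/mol (negative = stronger predicted binding)."
)
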