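"""Published per-run reference tables for PDE4D–polyphenol binding.

These are the per-production-run values reported in a published LRA study
of four natural polyphenols (curcumin, 6-gingerol, capsaicin and
resveratrol) binding to phosphodiesterase 4D: the five ensemble-average
interaction-energy components and the assembled binding free energy for
each of four independent 10 ns runs, the run-average rows as printed, and
the per-run average RMSD/RMSF stability metrics.  The underlying
trajectories are not deposited, so these printed per-run values are the
inputs from which the package's aggregation and comparison operations
recompute the study's summary statistics.

All energies are kcal/mol, all lengths Å.  Component keys follow
:mod:`lrabind.lra`: ``mean_vdw_P_q`` etc.; ``dG`` is the per-run binding
free energy as printed.
"""

from __future__ import annotations

import pandas as pd

__all__ = [
    "LIGANDS",
    "ROLIPRAM_EXPERIMENTAL_DG",
    "lra_run_table",
    "lra_printed_averages",
    "rmsd_run_means",
    "rmsf_run_means",
]

LIGANDS = ("curcumin", "6-gingerol", "capsaicin", "resveratrol")

#: experimental binding free energy of the positive-control inhibitor
#: rolipram, kcal/mol
ROLIPRAM_EXPERIMENTAL_DG = -9.86

# per-run LRA components: columns are
# (vdw_P, vdw_W, ele_P, ele_W, ele_P_0, dG)
_LRA_RUNS = {
    "curcumin": [
        (-53.72, -33.43, -60.10, -40.34, -0.66, -10.83),
        (-52.38, -33.41, -62.07, -40.55, -0.73, -11.24),
        (-52.33, -33.52, -61.04, -39.43, -0.69, -11.22),
        (-52.94, -33.41, -60.43, -40.23, -0.69, -10.85),
    ],
    "6-gingerol": [
        (-49.25, -24.38, -49.89, -43.84, -0.49, -6.97),
        (-50.71, -24.49, -49.37, -43.16, -0.51, -7.27),
        (-49.11, -25.40, -50.58, -44.17, -0.47, -6.85),
        (-48.15, -24.36, -49.98, -43.53, -0.44, -6.85),
    ],
    "capsaicin": [
        (-50.33, -28.20, -38.69, -35.67, -0.38, -5.36),
        (-52.33, -27.72, -37.29, -35.81, -0.35, -5.27),
        (-52.62, -27.74, -37.39, -35.76, -0.36, -5.37),
        (-50.67, -28.30, -38.37, -36.70, -0.38, -4.96),
    ],
    "resveratrol": [
        (-31.64, -16.53, -51.15, -47.18, -0.53, -4.57),
        (-30.18, -16.44, -51.90, -47.04, -0.50, -4.58),
        (-29.80, -16.46, -52.68, -47.61, -0.48, -4.56),
        (-30.58, -16.49, -52.48, -47.59, -0.49, -4.65),
    ],
}

# the study's printed "average of all runs" cells (a few differ from the
# recomputed per-run means; both are therefore kept available)
_LRA_PRINTED_AVERAGES = {
    "curcumin": (-52.84, -33.44, -60.66, -40.14, -0.69, -11.03),
    "6-gingerol": (-49.56, -24.66, -49.96, -43.67, -0.48, -6.99),
    "capsaicin": (-51.49, -27.99, -37.93, -35.99, -0.37, -5.24),
    "resveratrol": (-30.55, -16.48, -52.05, -47.36, -0.51, -4.59),
}

_COLUMNS = (
    "mean_vdw_P_q",
    "mean_vdw_W_q",
    "mean_ele_P_q",
    "mean_ele_W_q",
    "mean_ele_P_0",
    "dG",
)

# per-run average RMSD values (Å): (ligand, backbone) per run
_RMSD_RUNS = {
    "curcumin": {
        "ligand": (0.93, 0.87, 0.88, 0.99),
        "backbone": (0.69, 0.75, 0.68, 0.72),
    },
    "6-gingerol": {
        "ligand": (1.53, 1.82, 1.72, 1.90),
        "backbone": (0.76, 0.68, 0.72, 0.71),
    },
    "capsaicin": {
        "ligand": (1.95, 1.83, 2.10, 2.08),
        "backbone": (0.71, 0.82, 0.81, 0.81),
    },
    "resveratrol": {
        "ligand": (0.47, 0.35, 0.36, 0.43),
        "backbone": (0.58, 0.63, 0.67, 0.64),
    },
}

# per-run average ligand RMSF values (Å)
_RMSF_RUNS = {
    "curcumin": (1.08, 1.07, 0.92, 0.85),
    "6-gingerol": (1.30, 0.97, 1.07, 1.10),
    "capsaicin": (1.71, 1.91, 1.67, 1.86),
    "resveratrol": (1.00, 0.88, 0.95, 1.05),
}


def _check_ligand(ligand: str) -> str:
    if ligand not in LIGANDS:
        raise KeyError(f"unknown ligand '{ligand}'; choose from {LIGANDS}")
    return ligand


def lra_run_table(ligand: str) -> pd.DataFrame:
    """Per-run LRA components and printed ΔG for one ligand."""
    rows = _LRA_RUNS[_check_ligand(ligand)]
    df = pd.DataFrame(rows, columns=_COLUMNS)
    df.insert(0, "run", [f"run{i + 1}" for i in range(len(rows))])
    return df


def lra_printed_averages(ligand: str) -> dict:
    """The study's printed run-average row for one ligand."""
    values = _LRA_PRINTED_AVERAGES[_check_ligand(ligand)]
    return dict(zip(_COLUMNS, values))


def rmsd_run_means(ligand: str, selection: str = "ligand") -> tuple[float, ...]:
    """Per-run average RMSD values (Å); selection 'ligand' or 'backbone'."""
    table = _RMSD_RUNS[_check_ligand(ligand)]
    if selection not in table:
        raise KeyError("selection must be 'ligand' or 'backbone'")
    return table[selection]


def rmsf_run_means(ligand: str) -> tuple[float, ...]:
    """Per-run average ligand RMSF values (Å)."""
    return _RMSF_RUNS[_check_ligand(ligand)]
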