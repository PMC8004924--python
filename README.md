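# lrabind

Endpoint binding free-energy analysis of protein–ligand ensembles with
the **linear response approximation (LRA)**, together with the
trajectory analysis that surrounds it in practice: ligand/backbone RMSD
and per-atom RMSF after optimal superposition, and geometric
hydrogen-bond / hydrophobic-contact profiling with per-contact
occupancies.

It is written for computational chemists and structural bioinformaticians
who have sampled bound and free ensembles of a ligand (for example for a
PDE4D inhibitor candidate) and want the post-sampling analysis — from
per-frame intermolecular energies to an assembled thermodynamic cycle
with cross-run statistics — as a tested, scriptable library.

## The estimator

Because a fully *decoupled* ligand (all nonbonded interactions switched
off) binds with zero free energy, a thermodynamic cycle over decoupling
gives

```
ΔG_bind = ΔG_decouple(L–W) − ΔG_decouple(L–P),
```

with W the ligand free in solvent and P the solvated binding site, and
each decoupling term equal to minus a solvation free energy.  LRA
approximates those legs linearly in ensemble averages of the
intermolecular interaction energies:

```
ΔG_bind = α(⟨V_vdW^{L–P}⟩_q − ⟨V_vdW^{L–W}⟩_q)
        + β(⟨V_ele^{L–P}⟩_q − ⟨V_ele^{L–W}⟩_q)
        + β′⟨V_ele^{L–P}⟩_0
```

where ⟨·⟩_q averages over configurations sampled with the ligand's real
partial charges and ⟨V_ele^{L–P}⟩₀ is the *preorganization* term: the
real-charge electrostatic energy averaged over configurations sampled
with all ligand charges set to zero.  A binding site whose dipoles are
pre-oriented for the ligand has ⟨V_ele⟩₀ < 0; a polar solvent is not
preorganized, so the corresponding free-state term is identically zero.
Defaults are α = 0.18 and β = β′ = 0.33 (the refined coefficient for
neutral ligands with two or more polar groups); β = β′ = 0.5 is the pure
linear-response limit.

Because the study-scale MD trajectories such analyses are run on are
rarely redistributable, the package ships a first-class synthetic module:
Metropolis-sampled toy ligand–pocket/solvent systems and a harmonic bath
whose charging free energy is known in closed form
(ΔG = −c²q²/2k_s), so every stage — sampler, energies, estimator,
metrics, contact profiling — is validated against independent oracles.

## Worked example

`python examples/toy_complex_pipeline.py` generates four independent
bound and free Metropolis runs of a dipolar three-atom ligand in a polar
four-residue pocket plus solvent shell (charged and zero-charge
ensembles), then runs the full pipeline:

```
LRA thermodynamic cycle, mean over 4 independent runs (kcal/mol):
  mean_vdw_P_q     -1.511 +- 0.282
  mean_vdw_W_q     -0.767 +- 0.055
  mean_ele_P_q    -13.864 +- 0.388
  mean_ele_W_q    -10.420 +- 1.950
  mean_ele_P_0     -2.624 +- 0.331
  dG_binding       -2.136 +- 0.586
cycle closure residual: 0.0e+00

stability metrics (mean over runs, Angstrom):
  rmsd_ligand    0.759 +- 0.050
  rmsd_backbone  0.892 +- 0.073
  rmsf_ligand    0.567 +- 0.045

top contacts (occupancy over all frames):
  hbond        A/SER101     100.0%  3.08 A
  hydrophobic  A/ASN103      94.4%  3.54 A
```

Reading the numbers: the bound-state averages are more negative than the
free-state ones (both interaction classes favor binding), the negative
preorganization term shows the pocket's dipoles are pre-oriented for the
ligand, and the assembled ΔG_bind = −2.14 ± 0.59 kcal/mol (mean ± n−1 sd
over the four runs) closes the thermodynamic cycle to machine precision.
RMSD/RMSF below 1 Å and a persistent SER101 hydrogen bond (100 %
occupancy at 3.08 Å) indicate a stable pose.

The other examples each exercise one capability:
`lra_from_published_runs.py` (cross-run aggregation of a published
per-run table for four PDE4D polyphenol inhibitors and comparison to the
rolipram reference), `harmonic_bath_validation.py` (estimator vs closed
form) and `trajectory_metrics.py` (RMSD/RMSF conventions).

A thin CLI mirrors the library: `lrabind run --config config.yaml`,
plus `fixtures`, `lra`, and `validate` subcommands.

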