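# Methods

## Model and assumptions

`lrabind` estimates binding free energies with the linear response
approximation (LRA), an endpoint method: only the two physical end
states are sampled (ligand bound in the solvated site, P, and ligand
free in solvent, W), and the free energy of decoupling the ligand's
nonbonded interactions is approximated linearly in ensemble averages of
the intermolecular interaction energies.  The working expression is

ΔG_bind = α(⟨V_vdW⟩_P − ⟨V_vdW⟩_W) + β(⟨V_ele⟩_P − ⟨V_ele⟩_W) + β′⟨V_ele⟩₀,

with all averages over the ligand–environment terms only.  The method
assumes (i) the electrostatic response of the environment is linear in
the ligand's charges — exact for a harmonic environment, approximate
otherwise — and (ii) the van der Waals contribution can be captured by
an empirical scaling α of its ensemble average.  ⟨V_ele⟩₀, the
*preorganization* term, is the electrostatic energy evaluated with the
ligand's real charges over configurations sampled with those charges
set to zero; it is nonzero for a folded binding site whose dipoles are
pre-oriented and identically zero for the free state in a polar solvent,
which is why no free-state zero-charge ensemble is required.

### Cycle bookkeeping

The decoupling identities (ΔG_decouple = −ΔG_solv per state, ΔG_bind =
ΔG_dec,W − ΔG_dec,P, zero for a decoupled ligand) are enforced exactly:
the preorganization term is carried inside the bound-state solvation
free energy, where it physically belongs, so `cycle_residual` is zero to
rounding for every assembled result.  `lra_solvation` itself is the pure
two-term form α⟨V_vdW⟩_q + β⟨V_ele⟩_q.

### Parameters

| parameter | default | meaning |
|---|---|---|
| α | 0.18 | empirical van der Waals coefficient (dimensionless) |
| β | 0.33 | electrostatic response coefficient; 0.5 is pure linear response, 0.33 the refined value for neutral ligands with ≥ 2 polar/hydroxyl groups |
| β′ | = β | coefficient on the preorganization term; exposed separately because published tables assembled from these components are not always reproducible with a single β, and users may want to probe sensitivity |
| k_C | 332.0636 kcal·Å/(mol·e²) | Coulomb constant (configurable) |
| k_B | 0.0019872041 kcal/(mol·K) | Boltzmann constant |

## Interaction energies

Energies are plain pairwise sums over ligand × environment atom pairs:
point-charge Coulomb and 12-6 Lennard-Jones with AMBER-convention mixing
(R_ij = Rmin/2_i + Rmin/2_j, ε_ij = √(ε_i ε_j)).  No cutoff is applied
by default: engine-side cutoffs and long-range corrections are sampling
machinery, whereas the estimator is defined over the full pairwise sums;
a cutoff flag exists for experimentation.  "Environment" defaults to
everything except the ligand (the solvated site, including solvent and
ions), with a protein-only option.  Intramolecular ligand terms, 1–4
scaling and polarization are excluded by construction.  The
`charge_state` tag on an energy series records how the ensemble was
*sampled*; evaluation always uses the real charges, which is exactly the
definition of ⟨V_ele⟩₀.

## Stability metrics

Superposition uses the closed-form least-squares proper rotation
(Kabsch, via scipy's `align_vectors`; reflections excluded; the residual
is recomputed from fitted coordinates to avoid precision loss near
zero).  Fit and measure selections are independent: ligand RMSD is
measured after fitting the protein backbone (N, CA, C, O of protein
residues — the standard convention, configurable), against the first
frame as reference.  RMSF fits every frame to the first frame on the fit
selection and measures each atom's root-mean-square displacement from
its time-averaged fitted position; the reference frame is selectable.
Ligand selections include hydrogens when present, with a heavy-atom
option.  Cross-run aggregation reports per-run means, then the cross-run
mean and *sample* standard deviation (n−1); a single run is reported
with sd 0 and an explicit flag.

## Interaction profiling

Hydrogen bonds: flagged donor/acceptor heavy-atom pairs within 4.1 Å
whose D–H···A angle is ≥ 100° when hydrogens are resolvable (attachment
inferred geometrically at ≤ 1.3 Å within the residue); in heavy-atom
mode the angle test is skipped — trajectories often store no hydrogens.
Hydrophobic contacts: flagged apolar-carbon pairs within 4.0 Å,
collapsed to the closest pair per environment residue per frame.  These
thresholds are the PLIP-style defaults and are all configurable.  Roles
(donor/acceptor/hydrophobic) come from the parameter sidecar rather than
on-the-fly chemical perception: detection stays exact on synthetic
systems and auditable on real ones.  Occupancy is the fraction of frames
a contact (kind, ligand atom, environment residue) is present; the
reported distance is the mean over *present* frames only (means over all
frames can be recovered from the per-event tables).  Occupancies over
concatenated runs equal the frame-weighted mean of per-run occupancies.

## Synthetic systems

The generator emulates the study conditions such analyses are run under:
bound and free ensembles, a charged and a zero-ligand-charge ensemble
per state, four independent runs per condition, T = 298.15 K, and energy
fluctuations consistent with the linear-response assumption.

*Harmonic bath* — one coordinate x with energy ½k_s x², coupled as
U = c·q·x.  Exactly, ΔG = −(cq)²/(2k_s), ⟨U⟩_q = 2ΔG, ⟨U⟩₀ = 0, giving a
closed-form oracle for the estimator's electrostatic treatment,
including the "solvent is not preorganized" property at the level where
it is literally testable.

*Toy complex* — a three-atom dipolar ligand (±0.4 e poles, one apolar
carbon; net charge zero) in a pocket of four backbone-named
pseudo-residues at 4.5 Å whose two axial residues face the ligand's
poles head-on (donor N toward the O⁻ pole, acceptor O toward the C⁺
pole): the geometry itself makes the site electrostatically
preorganized, so ⟨V_ele⟩₀ < 0 over the sampled zero-charge ensemble.
The two flanking residues present apolar carbons for hydrophobic
contacts with their polar atoms arranged as mutually cancelling distant
pairs.  Eight dipolar two-atom solvent molecules sit on a 5.5 Å shell
(negative pole inward, bulk-like).  The free state is the same ligand
and shell without the pocket.  Every atom is harmonically restrained to
a home position (ligand 5.0, pocket 3.0, solvent 1.0 kcal/mol/Å²),
standing in for the bonded structure the model omits; per-residue
charges sum to zero, mirroring system electroneutrality.

Sampling is Metropolis Monte-Carlo — single-atom uniform displacements,
acceptance min(1, e^(−ΔE/k_BT)) — which targets the Boltzmann
distribution exactly; a molecular-dynamics engine's machinery (SHAKE,
boundary potentials, long-range treatments) affects sampling efficiency,
not the estimator being tested, so it is deliberately out of scope.  The
sampling energy is ligand–environment nonbonded plus restraints;
environment–environment interactions are omitted (environment atoms are
independently restrained), which keeps moves O(ligand size) and the
zero-ensemble distribution analytically transparent.  In the zero
ensemble the chain runs with ligand charges off while emitted frames are
raw coordinates.  All randomness flows from one master seed through
numpy seed sequences; identical seeds give byte-identical bundles.

What the toy systems do **not** emulate: real force-field parameters,
conformational ligand flexibility, discrete solvent structure and
hydrogen-bond networks, slow collective protein motions, or sampling
nonergodicity.  Passing tests therefore demonstrate the correctness of
the estimator and analysis machinery under ideal sampling, not the
physical accuracy of LRA on any real target.

## Numerical choices and problem sizes

- Report tables round at 2 decimals, half-up; machine-readable outputs
  keep full precision.
- Cross-run spread is always the sample sd (n−1).
- Monte-Carlo standard errors use block averaging (20 blocks) to absorb
  chain autocorrelation; validation criteria are 3-SE bands.
- Bath validation runs 10⁵ Metropolis steps per ensemble over a grid of
  six (c, k_s, q) settings; fixture trajectories use 4 runs × 120 frames
  (60 in the test suite) thinned every 60 moves after a 600-move
  burn-in, sizes chosen so the statistical checks are sharp while the
  whole suite runs in seconds.
- Degenerate inputs fail loudly: < 3 or collinear fit points, empty
  selections used for fitting, non-finite energy components, overlapping
  atom pairs (< 0.1 Å, warning with the pair identity), inconsistent
  per-model atom counts (error names the model).
- Trajectories travel as multi-model PDB: the text format keeps fixtures
  inspectable and diffable, and coordinate round-trips are exact to the
  format's 10⁻³ Å.  Residue numbers follow the source file verbatim;
  internal atom indexing is 0-based.
- `within R of SEL` selections include the reference atoms themselves
  (distance 0); selections are returned in ascending atom order.

## Known limitations

- The estimator's published coefficient sets are system-class empirical;
  the package does not fit α/β to experimental affinities.
- Published summary tables for the PDE4D polyphenol study embedded as
  reference inputs contain internal inconsistencies (run-average cells
  that differ from their per-run means; a ±0.64 spread whose exact n−1
  value is 0.6471; per-run ΔG values not reproducible from their printed
  components with the printed coefficients — the components give −10.49
  for curcumin where the table prints −11.03).  The package asserts its
  own arithmetic and keeps both the per-run rows and the printed
  averages available rather than guessing an undocumented coefficient.
- No salt-bridge, π-stacking, halogen-bond, water-bridge or
  metal-coordination detection; no FEP/TI estimators; no binary
  trajectory formats (PSF/PRMTOP/XTC/DCD).
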