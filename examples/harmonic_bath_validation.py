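"""Validate the endpoint estimator against an exactly solvable system.

A single bath coordinate x with energy 0.5*k_s*x^2 couples to a ligand
charge q through U = c*q*x.  The charging free energy is exactly
-(cq)^2/(2 k_s), and linear response holds exactly: dG = (U_q + U_0)/2
with ensemble averages U_q (charged sampling) and U_0 (zero-charge
sampling, real-charge evaluation).  The script samples both ensembles
with Metropolis Monte-Carlo and assembles the LRA estimate with
alpha=0, beta=beta'=0.5.
"""

import numpy as np

from lrabind.energetics import StateEnergySummary
from lrabind.lra import LRAParams, lra_binding
from lrabind.stats import block_standard_error
from lrabind.synthetic import (
    BOLTZMANN_KCAL,
    HarmonicBathSpec,
    SamplerConfig,
    analytic_charging_free_energy,
    sample_harmonic_bath,
)

spec = HarmonicBathSpec(coupling=1.5, spring=1.2, ligand_charge=1.0)
exact = analytic_charging_free_energy(spec)

step = 1.5 * np.sqrt(BOLTZMANN_KCAL * spec.temperature / spec.spring)
base = dict(step=step, steps=100_000, burn_in=2000, thinning=1)
series_q = sample_harmonic_bath(spec, SamplerConfig(**base, seed=11), "q")
series_0 = sample_harmonic_bath(spec, SamplerConfig(**base, seed=12), "zero")

result = lra_binding(
    StateEnergySummary(state="bound_P", mean_vdw_q=0.0,
                       mean_ele_q=series_q.mean_u,
                       mean_ele_0=series_0.mean_u),
    StateEnergySummary(state="free_W", mean_vdw_q=0.0, mean_ele_q=0.0),
    LRAParams(alpha=0.0, beta=0.5, beta_preorg=0.5),
)
se = 0.5 * np.hypot(block_standard_error(series_q.u),
                    block_standard_error(series_0.u))

print(f"<U>_q  sampled: {series_q.mean_u:+.4f}   exact: {exact.mean_U_q:+.4f}")
print(f"<U>_0  sampled: {series_0.mean_u:+.4f}   exact: {exact.mean_U_0:+.4f}")
print(f"dG LRA estimate: {result.dG_binding:+.4f} +- {se:.4f} (1 SE)")
print(f"dG exact:        {exact.dG:+.4f}")
print(
    "\nThe sampled <U>_0 is statistically zero (a structureless bath is\n"
    "not preorganized) and the estimate agrees with the closed form\n"
    "within Monte-Carlo error."
)
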