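"""Estimate a relative binding free energy from nonequilibrium work values.

Generates Crooks-consistent forward/reverse work samples for the
protein-complex and water legs of the thermodynamic cycle (three
replicas of 80+80 works each, the standard fast-switching protocol),
estimates ΔG per leg with the CFT maximum-likelihood (BAR) estimator,
and assembles ΔΔG = ΔG(protein) − ΔG(water), averaged over replicas.
"""

import rbfebench as rb
from rbfebench.units import KT_298, kj_to_kcal

DG_PROTEIN, DG_WATER = 10.0, 3.0  # true leg ΔG values, kJ/mol

ddgs = []
for replica in range(3):
    legs = {}
    for name, dg, offset in (("protein", DG_PROTEIN, 0), ("water", DG_WATER, 5)):
        ws = rb.gen_work_distributions(
            rb.WorkGenSpec(dg_true=dg, sigma_w=2 * KT_298, seed=10 + offset + replica),
            leg=name,
            replica_id=replica,
        )
        legs[name] = rb.estimate_dg(ws)
        print(f"replica {replica} {name:7s} leg: dG = {legs[name].dg:6.2f} kJ/mol "
              f"(asymptotic se {legs[name].se:.2f})")
    ddgs.append(rb.assemble_ddg(legs["protein"], legs["water"]))

ddg = rb.average_replicas(ddgs)
print(f"\nreplica-averaged ddG = {ddg:.2f} kJ/mol = {kj_to_kcal(ddg):.2f} kcal/mol")
print(f"true ddG             = {DG_PROTEIN - DG_WATER:.2f} kJ/mol")
# Each leg estimate lands within a few tenths of kT of its true value at
# this sample size; the ΔΔG error is their combined statistical noise.
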