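"""Extract structure-quality features from a PDB file.

Writes a synthetic protein–ligand–water structure to PDB text, parses it
back, and computes the four quality features: resolution, ligand mean
B-factor, binding-site water count, and the mean B-factor of protein
residues within 5 Å of the ligand.
"""

import rbfebench as rb

ref, _ = rb.gen_structure_fixture(
    rb.FixtureSpec(n_pocket_atoms=32, n_waters=6, resolution=1.9,
                   bfactor_mean=28.0, bfactor_sd=6.0, seed=11)
)
pdb_text = rb.structure_to_pdb(ref)
print(pdb_text.splitlines()[1])  # the REMARK 2 resolution record

structure = rb.parse_structure(pdb_text, ligand="LIG")
fv = rb.compute_features(structure)
print(f"Res     = {fv.res:.2f} A     (crystallographic resolution)")
print(f"Lig_Bf  = {fv.lig_bf:.1f} A^2  (ligand mean B-factor)")
print(f"n_Wat   = {fv.n_wat}         (waters within 5 A of ligand)")
print(f"Prot_Bf = {fv.prot_bf:.1f} A^2  (pocket-residue mean B-factor)")
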